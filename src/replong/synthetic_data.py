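"""Synthetic study generator: reference with planted repeats, X-linked
pedigree genotypes, capture + CCS-like reads, and expression matrices.

The generator reproduces the statistical structure the analysis assumes:

* captured fragments of 800-1000 bp carrying a repeat with at least 20 bp
  of one flank, so alleles shorter than the fragment are spanned and
  larger expansions yield only partial reads;
* CCS-like residual error as independent substitutions (no
  homopolymer-specific model — a documented simplification), PCR stutter
  shifting an allele by one unit per read with small probability, 32-base
  adaptors at both read ends, and a minimum subread-pass requirement;
* GC-dependent capture dropout following a logistic decline (midpoint
  0.70 GC, floor ~0.3 recovery);
* hemizygous male genotypes on an X-linked pedigree with one designated
  causal compound repeat whose CT sub-repeat exceeds the normal pool, and
  a male control allele pool;
* an expression matrix with one strongly down-regulated miRNA-like gene
  and up-regulated target genes against a small control group.

Every generator is a pure function of (config, seed): the same seed gives
byte-identical outputs.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .genotyper import compound_total_length
from .read_prep import ReadRecord
from .repeat_catalog import GeneModel, RepeatLocus, purity_of_region
from .util import gc_fraction, revcomp

# fixed synthetic adaptors, 32 bases each
ADAPTOR_5P = "ATCTCTCTCTTTTCCTCCTCCTCCGTTGTTGT"
ADAPTOR_3P = "ACAACAACGGAGGAGGAGGAAAAGAGAGAGAT"


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CompoundSpec:
    """Adjacent sub-repeats separated by a short spacer, e.g.
    (CT)a TTT (GT)b."""

    sub_units: tuple[str, ...] = ("CT", "GT")
    separator: str = "TTT"


@dataclass(frozen=True)
class PlantedLocusSpec:
    """One repeat planted in the reference.

    Simple loci draw normal alleles uniformly from `pool_range` copies;
    compound loci draw each sub-repeat from `sub_pool_ranges` and the
    causal allele is `causal_sub_copies` (its first motif exceeding the
    normal pool, mirroring a CT-sub-repeat expansion next to a miRNA
    gene).
    """

    name: str
    unit_seq: str = "AC"
    ref_copies: int = 15
    purity: float = 100.0
    pool_range: tuple[int, int] = (12, 18)
    compound: CompoundSpec | None = None
    ref_sub_copies: tuple[int, ...] | None = None
    sub_pool_ranges: tuple[tuple[int, int], ...] | None = None
    causal: bool = False
    causal_copies: int | None = None
    causal_sub_copies: tuple[int, ...] | None = None
    in_linkage: bool = False
    feature: str | None = None  # annotation feature planted next to/around it


@dataclass(frozen=True)
class FamilySpec:
    name: str
    n_affected: int = 2  # affected males besides the proband
    n_unaffected: int = 2
    n_carriers: int = 2
    causal: bool = False  # does the family segregate the causal allele?


@dataclass(frozen=True)
class ReadModelConfig:
    fragment_len: tuple[int, int] = (800, 1000)
    coverage: int = 10
    substitution_rate: float = 0.01
    stutter_prob: float = 0.05
    min_passes: int = 6
    passes_mean: float = 15.0
    flank_pad: int = 20


@dataclass(frozen=True)
class CaptureModelConfig:
    """Logistic GC->recovery curve: high recovery at moderate GC, dropping
    toward `floor` above the midpoint."""

    midpoint: float = 0.70
    floor: float = 0.30
    slope: float = 25.0

    def recovery(self, gc: float) -> float:
        return self.floor + (1.0 - self.floor) / (
            1.0 + math.exp(self.slope * (gc - self.midpoint))
        )


@dataclass(frozen=True)
class ExpressionModelConfig:
    n_null_genes: int = 40
    n_up_targets: int = 8
    n_controls: int = 3
    down_gene: str = "MIRX"
    down_fold: float = 6.0  # "at least 5-fold" decrease
    up_fold: float = 2.5
    control_cv: float = 0.15


def default_locus_specs() -> tuple[PlantedLocusSpec, ...]:
    return (
        PlantedLocusSpec(
            name="TR_A", unit_seq="AC", ref_copies=15, pool_range=(12, 18),
            in_linkage=True, feature="ThreePrimeUTR",
        ),
        PlantedLocusSpec(
            name="XLIDC", unit_seq="GT", causal=True, in_linkage=True,
            compound=CompoundSpec(),
            ref_sub_copies=(16, 30),
            sub_pool_ranges=((11, 20), (24, 37)),
            causal_sub_copies=(21, 33),
            feature="miRNA",  # planted 65 bp upstream of the repeat
        ),
        PlantedLocusSpec(
            name="TR_B", unit_seq="GT", ref_copies=20, pool_range=(17, 23),
            feature="intron",
        ),
        PlantedLocusSpec(
            name="TR_C", unit_seq="GAT", ref_copies=10, pool_range=(8, 13),
        ),
    )


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    chrom: str = "chrX_sim"
    locus_spacing: int = 2600
    margin: int = 1500
    context_gc: float = 0.45
    loci: tuple[PlantedLocusSpec, ...] = field(default_factory=default_locus_specs)
    families: tuple[FamilySpec, ...] = (
        FamilySpec("FAM1", causal=True),
        FamilySpec("FAM2", n_affected=1, n_unaffected=1, n_carriers=0),
        FamilySpec("FAM3", n_affected=1, n_unaffected=1, n_carriers=0),
    )
    n_controls: int = 100
    read_model: ReadModelConfig = ReadModelConfig()
    capture_model: CaptureModelConfig = CaptureModelConfig()
    expression_model: ExpressionModelConfig = ExpressionModelConfig()

    @property
    def chrom_length(self) -> int:
        return 2 * self.margin + len(self.loci) * self.locus_spacing


# ---------------------------------------------------------------------------
# Reference simulation
# ---------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_sequence(n: int, gc: float, rng: np.random.Generator) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=n, p=p).tobytes().decode()


def _repeat_tract(
    spec: PlantedLocusSpec,
    copies: int | None,
    sub_copies: Sequence[int] | None,
    rng: np.random.Generator,
) -> str:
    """Build one allele sequence, applying the spec's purity as random
    substitutions off the perfect tiling."""
    if spec.compound is not None:
        assert sub_copies is not None
        parts = []
        for c, motif in zip(sub_copies, spec.compound.sub_units):
            parts.append(motif * int(c))
        seq = spec.compound.separator.join(parts)
    else:
        assert copies is not None
        seq = spec.unit_seq * int(copies)
    n_sub = int(round(len(seq) * (1.0 - spec.purity / 100.0)))
    if n_sub > 0:
        seq_l = list(seq)
        for pos in rng.choice(len(seq_l), size=n_sub, replace=False):
            alternatives = [b for b in "ACGT" if b != seq_l[pos]]
            seq_l[pos] = alternatives[rng.integers(len(alternatives))]
        seq = "".join(seq_l)
    return seq


def simulate_reference(
    config: SimulationConfig,
) -> tuple[dict[str, str], list[RepeatLocus], GeneModel]:
    """Reference sequence with planted repeats, truth catalog and
    annotation model.

    Loci are spaced `locus_spacing` apart; the causal compound locus gets
    a miRNA feature planted so the repeat sits 65 bp downstream of the
    gene on the plus strand.
    """
    rng = np.random.default_rng(config.seed)
    positions = [
        config.margin + i * config.locus_spacing for i in range(len(config.loci))
    ]
    if len(set(config.loci)) != len(config.loci):
        raise ValueError("duplicate locus specs")
    background = _random_sequence(config.chrom_length, config.context_gc, rng)
    seq = list(background)
    catalog: list[RepeatLocus] = []
    features: dict[str, list[tuple[int, int, str, str]]] = {config.chrom: []}
    for spec, pos in zip(config.loci, positions):
        tract = _repeat_tract(spec, spec.ref_copies, spec.ref_sub_copies, rng)
        end = pos + len(tract)
        if end + config.margin > config.chrom_length:
            raise ValueError("planted locus extends beyond the chromosome")
        seq[pos:end] = tract
        purity = purity_of_region(tract, spec.unit_seq)
        catalog.append(
            RepeatLocus(
                id=spec.name,
                chrom=config.chrom,
                start=pos,
                end=end,
                unit_seq=spec.unit_seq,
                copies=len(tract) / len(spec.unit_seq),
                purity=purity,
                gc=gc_fraction(tract),
            )
        )
        if spec.feature == "miRNA":
            # 80 bp miRNA gene ending 65 bp before the repeat (plus strand)
            features[config.chrom].append((pos - 65 - 80, pos - 65, "miRNA", "+"))
        elif spec.feature == "intron":
            features[config.chrom].append((pos - 200, end + 200, "intron", "+"))
        elif spec.feature is not None:
            features[config.chrom].append((pos - 50, end + 50, spec.feature, "+"))
    ref = {config.chrom: "".join(seq)}
    return ref, catalog, GeneModel(features=features)


# ---------------------------------------------------------------------------
# Pedigree and genotype truth
# ---------------------------------------------------------------------------


def _draw_normal_allele(
    spec: PlantedLocusSpec, rng: np.random.Generator
) -> tuple[int, tuple[int, ...] | None]:
    """(allele_bp, sub_copies) for one normal chromosome."""
    if spec.compound is not None:
        assert spec.sub_pool_ranges is not None
        subs = tuple(
            int(rng.integers(lo, hi + 1)) for lo, hi in spec.sub_pool_ranges
        )
        bp = compound_total_length(subs, spec.compound.sub_units, spec.compound.separator)
        return bp, subs
    lo, hi = spec.pool_range
    copies = int(rng.integers(lo, hi + 1))
    return copies * len(spec.unit_seq), None


def _causal_allele(spec: PlantedLocusSpec) -> tuple[int, tuple[int, ...] | None]:
    if spec.compound is not None:
        assert spec.causal_sub_copies is not None
        bp = compound_total_length(
            spec.causal_sub_copies, spec.compound.sub_units, spec.compound.separator
        )
        return bp, spec.causal_sub_copies
    copies = spec.causal_copies if spec.causal_copies is not None else spec.ref_copies
    return copies * len(spec.unit_seq), None


def simulate_pedigree_genotypes(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, list[tuple[str, int, int]]]:
    """Truth alleles for every family member and control male.

    Returns (truth genotypes, pedigree, controls, linkage intervals).
    Affected males of the causal family share the causal allele at the
    designated locus; unaffected males draw from the normal pool; carrier
    females are heterozygous causal/normal; every other locus is an
    independent normal draw for everyone.  Controls are a pool of
    `n_controls` hemizygous males.
    """
    rng = np.random.default_rng(config.seed + 1)
    _, catalog, _ = simulate_reference(config)
    coords = {l.id: (l.chrom, l.start, l.end) for l in catalog}
    specs = {s.name: s for s in config.loci}
    causal_spec = next((s for s in config.loci if s.causal), None)

    ped_rows = []
    gt_rows = []

    def add_member(sample: str, family: str, sex: str, phenotype: str,
                   carries_causal: int) -> None:
        # carries_causal: number of causal-allele copies (0/1; females get
        # a second, normal allele)
        ped_rows.append(
            {"sample": sample, "family": family, "sex": sex, "phenotype": phenotype}
        )
        n_alleles = 2 if sex == "F" else 1
        for spec in config.loci:
            for allele_idx in range(n_alleles):
                if spec.causal and causal_spec is not None and allele_idx < carries_causal:
                    bp, subs = _causal_allele(spec)
                else:
                    bp, subs = _draw_normal_allele(spec, rng)
                gt_rows.append(
                    {
                        "sample": sample,
                        "family": family,
                        "locus": spec.name,
                        "allele_bp": bp,
                        "sub_copies": ",".join(map(str, subs)) if subs else None,
                    }
                )

    for fam in config.families:
        causal_here = fam.causal and causal_spec is not None
        add_member(f"{fam.name}_P", fam.name, "M", "affected", int(causal_here))
        for i in range(fam.n_affected):
            add_member(f"{fam.name}_A{i+1}", fam.name, "M", "affected", int(causal_here))
        for i in range(fam.n_unaffected):
            add_member(f"{fam.name}_U{i+1}", fam.name, "M", "unaffected", 0)
        for i in range(fam.n_carriers):
            add_member(f"{fam.name}_C{i+1}", fam.name, "F", "carrier", int(causal_here))

    control_rows = []
    for i in range(config.n_controls):
        for spec in config.loci:
            bp, subs = _draw_normal_allele(spec, rng)
            control_rows.append(
                {
                    "sample": f"CTRL{i+1:03d}",
                    "locus": spec.name,
                    "allele_bp": bp,
                    "sub_copies": ",".join(map(str, subs)) if subs else None,
                }
            )

    linked = [specs[s.name] for s in config.loci if s.in_linkage]
    intervals: list[tuple[str, int, int]] = []
    if linked:
        starts = [coords[s.name][1] for s in linked]
        ends = [coords[s.name][2] for s in linked]
        intervals.append((config.chrom, max(0, min(starts) - 500), max(ends) + 500))

    return (
        pd.DataFrame(gt_rows),
        pd.DataFrame(ped_rows),
        pd.DataFrame(control_rows),
        intervals,
    )


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------


def _haplotype(
    ref_chrom: str,
    locus: RepeatLocus,
    allele_seq: str,
    context: int,
) -> tuple[str, int]:
    """Sample-specific local haplotype: reference context around the repeat
    with the repeat tract replaced by the sample allele.  Returns the
    haplotype and the offset of the allele within it."""
    left = ref_chrom[max(0, locus.start - context) : locus.start]
    right = ref_chrom[locus.end : locus.end + context]
    return left + allele_seq + right, len(left)


def _apply_substitutions(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for pos in hits:
        alternatives = _BASES[_BASES != arr[pos]]
        arr[pos] = alternatives[rng.integers(3)]
    return arr.tobytes().decode()


def allele_sequence_for(
    spec: PlantedLocusSpec,
    allele_bp: int,
    sub_copies: tuple[int, ...] | None,
    rng: np.random.Generator,
) -> str:
    """Sequence of one truth allele (purity substitutions re-sampled)."""
    if spec.compound is not None:
        return _repeat_tract(spec, None, sub_copies, rng)
    copies = allele_bp // len(spec.unit_seq)
    return _repeat_tract(spec, copies, None, rng)


def simulate_reads(
    sample: str,
    truth: pd.DataFrame,
    ref: dict[str, str],
    catalog: Sequence[RepeatLocus],
    config: SimulationConfig,
    seed_offset: int = 0,
) -> list[ReadRecord]:
    """Capture + CCS-like reads for one (hemizygous male) sample.

    Per locus, `coverage` fragments of 800-1000 bp are placed so that each
    carries the repeat with at least `flank_pad` bases of one flank; when
    the fragment is long enough the repeat is fully spanned, otherwise the
    read runs off inside the repeat (the partial-read signature of an
    expansion).  Fragments then pass GC-dependent capture dropout, receive
    per-base substitutions, a +/-1-unit stutter with the configured
    probability, random strand, 32-base adaptors and a subread-pass draw.
    """
    rng = np.random.default_rng(
        (config.seed + 10_007 * (seed_offset + 1) + zlib.crc32(sample.encode()) % 100_003)
        % 2**31
    )
    rm = config.read_model
    specs = {s.name: s for s in config.loci}
    chrom_seq = ref[config.chrom]
    sample_truth = truth[truth["sample"] == sample]
    reads: list[ReadRecord] = []
    context = rm.fragment_len[1] + 120
    for locus in catalog:
        spec = specs[locus.id]
        rows = sample_truth[sample_truth["locus"] == locus.id]
        if len(rows) == 0:
            continue
        row = rows.iloc[0]  # hemizygous male: one allele
        subs = (
            tuple(int(x) for x in row["sub_copies"].split(","))
            if isinstance(row["sub_copies"], str)
            else None
        )
        for i in range(rm.coverage):
            allele_bp = int(row["allele_bp"])
            sub_now = subs
            # PCR stutter: one whole-unit slip in either direction
            if rng.random() < rm.stutter_prob:
                shift = 1 if rng.random() < 0.5 else -1
                if sub_now is not None:
                    last = max(0, sub_now[-1] + shift)
                    sub_now = sub_now[:-1] + (last,)
                else:
                    copies = max(1, allele_bp // len(spec.unit_seq) + shift)
                    allele_bp = copies * len(spec.unit_seq)
            allele_seq = allele_sequence_for(spec, allele_bp, sub_now, rng)
            hap, rep_off = _haplotype(chrom_seq, locus, allele_seq, context)
            frag = _place_fragment(hap, rep_off, len(allele_seq), rm, rng)
            if frag is None:
                continue
            if rng.random() > config.capture_model.recovery(gc_fraction(frag)):
                continue  # capture dropout
            if int(rng.poisson(rm.passes_mean)) < rm.min_passes:
                continue  # not enough subread passes for a consensus read
            frag = _apply_substitutions(frag, rm.substitution_rate, rng)
            if rng.random() < 0.5:
                frag = revcomp(frag)
            read_seq = ADAPTOR_5P + frag + ADAPTOR_3P
            reads.append(
                ReadRecord(
                    id=f"{sample}.{locus.id}.{i}",
                    seq=read_seq,
                    qual="I" * len(read_seq),
                )
            )
    return reads


def _place_fragment(
    hap: str,
    rep_off: int,
    rep_len: int,
    rm: ReadModelConfig,
    rng: np.random.Generator,
) -> str | None:
    pad = rm.flank_pad
    flen = int(rng.integers(rm.fragment_len[0], rm.fragment_len[1] + 1))
    if flen >= rep_len + 2 * pad:
        # fragment spans the repeat with >= pad bases of both flanks
        lo = rep_off + rep_len + pad - flen
        hi = rep_off - pad
    elif rng.random() < 0.5:
        # left-anchored partial: covers the left flank, runs off inside
        lo, hi = rep_off + pad - flen, rep_off - pad
    else:
        # right-anchored partial: covers the right flank
        lo, hi = rep_off + rep_len + pad - flen, rep_off + rep_len - pad
    lo = max(0, lo)
    hi = min(len(hap) - flen, hi)
    if hi < lo:
        return None
    start = int(rng.integers(lo, hi + 1))
    return hap[start : start + flen]


def write_fastq(reads: Sequence[ReadRecord], path: str) -> None:
    with open(path, "w") as fh:
        for read in reads:
            qual = read.qual or "I" * len(read.seq)
            fh.write(f"@{read.id}\n{read.seq}\n+\n{qual}\n")


def write_fasta(ref: dict[str, str], path: str, width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom, seq in ref.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Expression simulation
# ---------------------------------------------------------------------------


def simulate_expression(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Expression matrix (genes x samples), target-membership table and
    truth-effect table.

    Controls scatter around per-gene means with the configured CV; the
    patient matches that distribution for null genes, is decreased
    `down_fold`-fold (beyond the control minimum) for the designated
    miRNA-like gene and increased `up_fold`-fold for its target genes.
    """
    em = config.expression_model
    if em.n_controls < 3:
        raise ValueError("at least 3 control samples required")
    rng = np.random.default_rng(config.seed + 2)
    genes = (
        [em.down_gene]
        + [f"TGT{i+1:03d}" for i in range(em.n_up_targets)]
        + [f"GENE{i+1:03d}" for i in range(em.n_null_genes)]
    )
    samples = ["PATIENT"] + [f"CTRL{i+1}" for i in range(em.n_controls)]
    values = {}
    truth_rows = []
    target_rows = []
    for gene in genes:
        mean = float(np.exp(rng.normal(3.0, 1.0)))
        controls = mean * (1.0 + em.control_cv * rng.standard_normal(em.n_controls))
        controls = np.clip(controls, mean * 0.2, None)
        if gene == em.down_gene:
            patient = controls.min() / em.down_fold
            effect = "down"
        elif gene.startswith("TGT"):
            patient = controls.max() * em.up_fold
            effect = "up"
        else:
            patient = mean * (1.0 + em.control_cv * rng.standard_normal())
            effect = "null"
        values[gene] = [patient] + list(controls)
        truth_rows.append({"gene": gene, "effect": effect})
        # the miRNA's predicted targets: all up-regulated genes plus a
        # random third of the null genes
        is_target = gene.startswith("TGT") or (
            gene.startswith("GENE") and rng.random() < 1 / 3
        )
        target_rows.append({"gene": gene, "is_target": is_target})
    matrix = pd.DataFrame.from_dict(values, orient="index", columns=samples)
    return matrix, pd.DataFrame(target_rows), pd.DataFrame(truth_rows)


def simulate_ct_tables(
    config: SimulationConfig,
    n_replicates: int = 2,
    down_fold: float | None = None,
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """qPCR Ct tables for the down-regulated gene with two endogenous
    controls; Ct = const - log2(quantity), so a 5-fold decrease raises Ct
    by log2(5)."""
    em = config.expression_model
    fold = down_fold if down_fold is not None else em.down_fold
    rng = np.random.default_rng(config.seed + 3)
    samples = ["PATIENT"] + [f"CTRL{i+1}" for i in range(em.n_controls)]
    base = 24.0
    rows = {}
    for sample in samples:
        ct = base + (math.log2(fold) if sample == "PATIENT" else 0.0)
        rows[sample] = ct + 0.05 * rng.standard_normal(n_replicates)
    target = pd.DataFrame.from_dict(rows, orient="index")
    endo = {}
    for gene, level in (("REF1", 20.0), ("REF2", 22.0)):
        endo[gene] = pd.DataFrame.from_dict(
            {s: level + 0.05 * rng.standard_normal(n_replicates) for s in samples},
            orient="index",
        )
    return target, endo
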