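"""Tandem-repeat cataloguing: detection, purity, variability scoring,
gene-model annotation and tiered target selection.

A tandem repeat is a head-to-tail repetition of a 1-50 bp unit.  Detection
scores a candidate region against the best-phase perfect tiling of its unit
(match +1, mismatch -k, ETANDEM-like); purity is the percentage of positions
agreeing with that tiling; the variability score is a pluggable linear form
in unit length, log copy number and purity standing in for a SERV-style
predictor.  Selection applies six tiered criteria combining annotation
class, score thresholds, structural bounds and probe availability.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .util import gc_fraction, validate_sequence

# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

REGULATORY_CLASSES = (
    "CpG",
    "TFBS",
    "UTR",
    "FivePrimeUTR",
    "ThreePrimeUTR",
    "upstream",
    "downstream",
    "miRNA",
)

ANNOTATION_PRECEDENCE = ("coding", "regulatory", "intronic", "intergenic")


@dataclass
class RepeatLocus:
    """One catalogued tandem repeat (coordinates 0-based half-open)."""

    id: str
    chrom: str
    start: int
    end: int
    unit_seq: str
    copies: float
    purity: float
    gc: float = 0.0
    annotation: str | None = None
    annotation_subtype: str | None = None
    serv: float | None = None
    group: int | None = None
    score: float | None = None  # detection score, used for overlap resolution

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"{self.id}: end must exceed start")
        if not 1 <= len(self.unit_seq) <= 50:
            raise ValueError(f"{self.id}: unit length must be in [1, 50]")

    @property
    def unit_len(self) -> int:
        return len(self.unit_seq)

    @property
    def span(self) -> int:
        return self.end - self.start

    @property
    def start_1based(self) -> int:
        return self.start + 1

    @property
    def end_1based(self) -> int:
        """1-based inclusive end, as printed in genome-browser-style tables."""
        return self.end


def copies_from_printed_coords(start_1based: int, end_1based: int, unit_len: int) -> float:
    """Copy number implied by 1-based inclusive printed coordinates.

    chrX:45,606,270-45,606,355 with a 2 bp unit spans 86 bases = 43 copies.
    """
    if end_1based < start_1based:
        raise ValueError("end before start")
    if unit_len < 1:
        raise ValueError("unit_len must be >= 1")
    return (end_1based - start_1based + 1) / unit_len


@dataclass
class GeneModel:
    """Per-chromosome annotation intervals.

    ``features`` maps chrom -> list of (start, end, feature_class, strand)
    with 0-based half-open coordinates.  Feature classes are free-form BED
    names; classes listed in REGULATORY_CLASSES map to the regulatory
    annotation, ``coding`` to coding, ``intron``/``gene`` to intronic.
    """

    features: dict[str, list[tuple[int, int, str, str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, feats in self.features.items():
            for start, end, cls, strand in feats:
                if end <= start:
                    raise ValueError(f"invalid interval {chrom}:{start}-{end} ({cls})")
            feats.sort(key=lambda f: (f[0], f[1]))

    @classmethod
    def from_bed(cls, path: str) -> "GeneModel":
        feats: dict[str, list[tuple[int, int, str, str]]] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                cols = line.split("\t")
                chrom, start, end = cols[0], int(cols[1]), int(cols[2])
                name = cols[3] if len(cols) > 3 else "gene"
                strand = cols[5] if len(cols) > 5 else "+"
                feats.setdefault(chrom, []).append((start, end, name, strand))
        return cls(features=feats)

    def to_bed(self, path: str) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self.features):
                for start, end, name, strand in self.features[chrom]:
                    fh.write(f"{chrom}\t{start}\t{end}\t{name}\t0\t{strand}\n")


# ---------------------------------------------------------------------------
# Purity
# ---------------------------------------------------------------------------


def purity_of_region(region: str, unit_seq: str) -> float:
    """Percent of positions matching the best cyclic phase of a perfect
    tiling of `unit_seq` over `region` (truncated final unit allowed)."""
    span = len(region)
    u = len(unit_seq)
    if span < u:
        raise ValueError("region shorter than the repeat unit")
    best = 0
    for phase in range(u):
        matches = sum(
            1 for j, base in enumerate(region) if base == unit_seq[(j + phase) % u]
        )
        if matches > best:
            best = matches
    return 100.0 * best / span


def compute_purity(locus: RepeatLocus, seq: str) -> float:
    """Purity of a locus against its own unit, evaluated on `seq`."""
    if locus.start < 0 or locus.end > len(seq):
        raise ValueError(f"{locus.id}: coordinates outside the sequence")
    return purity_of_region(seq[locus.start : locus.end], locus.unit_seq)


# ---------------------------------------------------------------------------
# Detection
# ---------------------------------------------------------------------------


def _phase_score(region: str, unit: str, penalty: int) -> tuple[int, int]:
    """(score, matches) of `region` against the phase-0 tiling of `unit`."""
    u = len(unit)
    matches = sum(1 for j, base in enumerate(region) if base == unit[j % u])
    mismatches = len(region) - matches
    return matches - penalty * mismatches, matches


def find_tandem_repeats(
    seq: str,
    min_unit: int = 1,
    max_unit: int = 6,
    min_total_len: int = 8,
    min_copies: float = 2.0,
    min_purity: float = 85.0,
    mismatch_penalty: int = 3,
    xdrop: int = 30,
    chrom: str = "chr",
    id_prefix: str = "TR",
) -> list[RepeatLocus]:
    """Detect maximal tandem repeats in `seq`.

    Every position with an exact adjacent unit copy seeds an extension: the
    region is grown left and right to the endpoints maximising the tiling
    score (match +1, mismatch -`mismatch_penalty`), preferring the longer
    extension on ties, with an X-drop bound on how far a deficit may run.
    Candidates below the length/copy/purity thresholds are discarded and
    overlapping survivors are resolved deterministically: highest score,
    then smallest unit, then leftmost.
    """
    if not seq:
        raise ValueError("empty sequence")
    if not (1 <= min_unit <= max_unit <= 50):
        raise ValueError("require 1 <= min_unit <= max_unit <= 50")
    if min_total_len < 2 or min_copies < 2:
        raise ValueError("min_total_len >= 2 and min_copies >= 2 required")
    seq = validate_sequence(seq)
    n = len(seq)

    candidates: dict[tuple[int, int, int], RepeatLocus] = {}
    for u in range(min_unit, max_unit + 1):
        if 2 * u > n:
            break
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        adj = arr[: n - u] == arr[u:]
        if u == 1:
            anchor_ok = adj[: n - 2 * u + 1] if n - 2 * u + 1 > 0 else adj[:0]
        else:
            # anchor i needs seq[i:i+u] == seq[i+u:i+2u]
            win = np.lib.stride_tricks.sliding_window_view(adj, u)
            anchor_ok = win.all(axis=1)
        for i in np.nonzero(anchor_ok)[0]:
            i = int(i)
            unit = seq[i : i + u]
            if "N" in unit:
                continue
            # extend right from i+2u
            best_e, best_score = i + 2 * u, 2 * u
            run = best_score
            j = i + 2 * u
            while j < n and run > best_score - xdrop:
                run += 1 if seq[j] == unit[(j - i) % u] else -mismatch_penalty
                j += 1
                if run >= best_score:
                    best_score, best_e = run, j
            # extend left from i
            best_s = i
            left_best = 0
            run = 0
            j = i - 1
            while j >= 0 and run > left_best - xdrop:
                run += 1 if seq[j] == unit[(j - i) % u] else -mismatch_penalty
                j -= 1
                if run >= left_best:
                    left_best, best_s = run, j + 1
            s, e = best_s, best_e
            span = e - s
            if span < min_total_len or span / u < min_copies:
                continue
            # report the unit in the phase of the locus start
            shift = (s - i) % u
            unit_rot = unit[shift:] + unit[:shift]
            region = seq[s:e]
            purity = purity_of_region(region, unit_rot)
            if purity < min_purity:
                continue
            score, _ = _phase_score(region, unit_rot, mismatch_penalty)
            key = (s, e, u)
            if key not in candidates or score > (candidates[key].score or 0):
                candidates[key] = RepeatLocus(
                    id="",
                    chrom=chrom,
                    start=s,
                    end=e,
                    unit_seq=unit_rot,
                    copies=span / u,
                    purity=purity,
                    gc=gc_fraction(region),
                    score=float(score),
                )

    return _resolve_overlaps(candidates.values(), id_prefix)


def _resolve_overlaps(
    candidates: Iterable[RepeatLocus], id_prefix: str
) -> list[RepeatLocus]:
    """Greedy overlap resolution: highest score, smallest unit, leftmost."""
    ordered = sorted(
        candidates, key=lambda c: (-(c.score or 0.0), c.unit_len, c.start, c.end)
    )
    kept: list[RepeatLocus] = []
    for cand in ordered:
        if all(cand.end <= k.start or k.end <= cand.start for k in kept):
            kept.append(cand)
    kept.sort(key=lambda c: c.start)
    for idx, locus in enumerate(kept, start=1):
        locus.id = f"{id_prefix}{idx:04d}"
    return kept


# ---------------------------------------------------------------------------
# Variability score
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ServCoefficients:
    """Linear variability-score coefficients.

    score = intercept + log_copies*ln(copies) + purity*(purity/100)
            + unit_len*unit_len

    The shipped defaults place pure dinucleotide repeats of >=15 copies
    above 1 (the classic "useful for genotyping" band) and short or impure
    loci near zero; they are a documented stand-in and fully overridable.
    """

    intercept: float = -2.0
    log_copies: float = 1.0
    purity: float = 1.0
    unit_len: float = -0.05


DEFAULT_SERV = ServCoefficients()


def score_variability(
    locus: RepeatLocus, coefficients: ServCoefficients = DEFAULT_SERV
) -> float:
    """Predicted length variability of a repeat; higher = more mutable.

    Monotone non-decreasing in copies and purity at fixed unit length as
    long as the corresponding coefficients are non-negative (the default).
    """
    if locus.copies is None or locus.purity is None:
        raise ValueError("locus must have copies and purity populated")
    if locus.copies < 1:
        raise ValueError("copies must be >= 1")
    return (
        coefficients.intercept
        + coefficients.log_copies * math.log(locus.copies)
        + coefficients.purity * (locus.purity / 100.0)
        + coefficients.unit_len * locus.unit_len
    )


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------


def classify_annotation(
    locus: RepeatLocus, models: GeneModel, window: int = 1000
) -> tuple[str, str | None]:
    """Assign one annotation class with precedence
    coding > regulatory > intronic > intergenic.

    Regulatory membership covers direct overlap with a regulatory feature
    and strand-aware up-/downstream windows of `window` bases around gene
    and miRNA features (a repeat 65 bp downstream of a miRNA gene is
    regulatory/downstream).  Returns (class, subtype).
    """
    feats = models.features.get(locus.chrom, [])
    hit_coding = False
    hit_intronic = False
    reg_subtype: str | None = None

    def overlaps(fs: int, fe: int) -> bool:
        return locus.start < fe and fs < locus.end

    for fs, fe, cls, strand in feats:
        if overlaps(fs, fe):
            if cls == "coding":
                hit_coding = True
            elif cls in REGULATORY_CLASSES:
                if reg_subtype is None:
                    reg_subtype = cls
            elif cls in ("intron", "gene"):
                hit_intronic = True
        if cls in ("gene", "miRNA"):
            # strand-aware promoter-proximal windows
            if strand == "+":
                up = (max(0, fs - window), fs)
                down = (fe, fe + window)
            else:
                up = (fe, fe + window)
                down = (max(0, fs - window), fs)
            if reg_subtype is None and overlaps(*up):
                reg_subtype = "upstream"
            if reg_subtype is None and overlaps(*down):
                reg_subtype = "downstream"

    if hit_coding:
        return "coding", None
    if reg_subtype is not None:
        return "regulatory", reg_subtype
    if hit_intronic:
        return "intronic", None
    return "intergenic", None


def annotate_catalog(
    catalog: Sequence[RepeatLocus],
    models: GeneModel,
    window: int = 1000,
    coefficients: ServCoefficients = DEFAULT_SERV,
) -> list[RepeatLocus]:
    """Populate annotation and variability score for every locus."""
    out = []
    for locus in catalog:
        ann, sub = classify_annotation(locus, models, window=window)
        out.append(
            replace(
                locus,
                annotation=ann,
                annotation_subtype=sub,
                serv=score_variability(locus, coefficients),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Target selection
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SelectionConfig:
    """Thresholds of the six selection tiers.

    Tier 1: coding, span <= max_span.
    Tier 2: regulatory, serv >= serv_high, span <= max_span.
    Tier 3: regulatory, serv_low < serv < serv_high (any span).
    Tier 4: regulatory within `near_gene_window` of a listed disease gene.
    Tier 5: intronic, serv > serv_intronic, copies >= min_copies,
            unit >= 2, span <= max_span, GC in [gc_lo, gc_hi],
            >= min_probes probes; thinned to `group5_quota` evenly by
            position.
    Tier 6: intergenic, serv > serv_intergenic, same structural bounds.
    """

    max_span: int = 500
    serv_high: float = 1.0
    serv_low: float = 0.4
    serv_intronic: float = 0.8
    serv_intergenic: float = 1.0
    min_copies: float = 15.0
    min_unit: int = 2
    gc_lo: float = 0.30
    gc_hi: float = 0.70
    min_probes: int = 3
    near_gene_window: int = 1000
    group5_quota: int = 1000
    chrom_length: int | None = None


def _near_listed_gene(locus: RepeatLocus, genes: GeneModel, window: int) -> bool:
    for fs, fe, _cls, _strand in genes.features.get(locus.chrom, []):
        if locus.start < fe + window and fs - window < locus.end:
            return True
    return False


def _structural_ok(locus: RepeatLocus, cfg: SelectionConfig) -> bool:
    return (
        locus.copies >= cfg.min_copies
        and locus.unit_len >= cfg.min_unit
        and locus.span <= cfg.max_span
        and cfg.gc_lo <= locus.gc <= cfg.gc_hi
    )


def select_targets(
    catalog: Sequence[RepeatLocus],
    xlid_genes: GeneModel,
    probe_counts: Mapping[str, int],
    config: SelectionConfig = SelectionConfig(),
) -> list[RepeatLocus]:
    """Label each locus with at most one selection group (first match 1->6).

    Group 5 eligibility is additionally thinned to `group5_quota` loci
    spread evenly along the chromosome: the chromosome is cut into
    quota-many equal bins, the highest-scoring eligible locus per bin is
    kept, and unfilled bins are back-filled round-robin from the remaining
    eligible loci by descending score.
    """
    labelled = [replace(loc, group=None) for loc in catalog]
    group5_pool: list[RepeatLocus] = []
    for locus in labelled:
        if locus.serv is None or locus.annotation is None:
            raise ValueError(f"{locus.id}: serv and annotation must be populated")
        ann = locus.annotation
        if ann == "coding" and locus.span <= config.max_span:
            locus.group = 1
        elif ann == "regulatory" and locus.serv >= config.serv_high and locus.span <= config.max_span:
            locus.group = 2
        elif ann == "regulatory" and config.serv_low < locus.serv < config.serv_high:
            locus.group = 3
        elif ann == "regulatory" and _near_listed_gene(
            locus, xlid_genes, config.near_gene_window
        ):
            locus.group = 4
        elif (
            ann == "intronic"
            and locus.serv > config.serv_intronic
            and _structural_ok(locus, config)
            and probe_counts.get(locus.id, 0) >= config.min_probes
        ):
            group5_pool.append(locus)
        elif (
            ann == "intergenic"
            and locus.serv > config.serv_intergenic
            and _structural_ok(locus, config)
            and probe_counts.get(locus.id, 0) >= config.min_probes
        ):
            locus.group = 6

    # even positional thinning of group 5
    quota = config.group5_quota
    if group5_pool:
        if len(group5_pool) <= quota:
            if len(group5_pool) < quota:
                warnings.warn(
                    f"group-5 quota {quota} exceeds {len(group5_pool)} eligible loci; "
                    "keeping all eligible"
                )
            for locus in group5_pool:
                locus.group = 5
        else:
            length = config.chrom_length or max(l.end for l in labelled)
            bin_size = length / quota
            by_bin: dict[int, list[RepeatLocus]] = {}
            for locus in group5_pool:
                b = min(int(locus.start // bin_size), quota - 1)
                by_bin.setdefault(b, []).append(locus)
            chosen: list[RepeatLocus] = []
            leftovers: list[RepeatLocus] = []
            for b in range(quota):
                loci = sorted(
                    by_bin.get(b, []), key=lambda l: (-(l.serv or 0), l.start)
                )
                if loci:
                    chosen.append(loci[0])
                    leftovers.extend(loci[1:])
            leftovers.sort(key=lambda l: (-(l.serv or 0), l.start))
            chosen.extend(leftovers[: quota - len(chosen)])
            for locus in chosen:
                locus.group = 5
    return labelled


# ---------------------------------------------------------------------------
# Table I/O
# ---------------------------------------------------------------------------

CATALOG_COLUMNS = [
    "id",
    "chrom",
    "start",
    "end",
    "start_1based",
    "end_1based",
    "unit",
    "unit_len",
    "copies",
    "purity",
    "gc",
    "annotation",
    "annotation_subtype",
    "serv",
    "group",
]


def catalog_to_frame(catalog: Sequence[RepeatLocus]) -> pd.DataFrame:
    rows = [
        {
            "id": l.id,
            "chrom": l.chrom,
            "start": l.start,
            "end": l.end,
            "start_1based": l.start_1based,
            "end_1based": l.end_1based,
            "unit": l.unit_seq,
            "unit_len": l.unit_len,
            "copies": round(l.copies, 2),
            "purity": round(l.purity, 2),
            "gc": round(l.gc, 4),
            "annotation": l.annotation,
            "annotation_subtype": l.annotation_subtype,
            "serv": None if l.serv is None else round(l.serv, 4),
            "group": l.group,
        }
        for l in catalog
    ]
    return pd.DataFrame(rows, columns=CATALOG_COLUMNS)


def frame_to_catalog(frame: pd.DataFrame) -> list[RepeatLocus]:
    catalog = []
    for _, row in frame.iterrows():
        catalog.append(
            RepeatLocus(
                id=str(row["id"]),
                chrom=str(row["chrom"]),
                start=int(row["start"]),
                end=int(row["end"]),
                unit_seq=str(row["unit"]),
                copies=float(row["copies"]),
                purity=float(row["purity"]),
                gc=float(row.get("gc", 0.0)),
                annotation=row.get("annotation") if pd.notna(row.get("annotation")) else None,
                serv=float(row["serv"]) if pd.notna(row.get("serv")) else None,
                group=int(row["group"]) if pd.notna(row.get("group")) else None,
            )
        )
    return catalog


def write_catalog(catalog: Sequence[RepeatLocus], path: str) -> None:
    catalog_to_frame(catalog).to_csv(path, sep="\t", index=False)


def read_catalog(path: str) -> list[RepeatLocus]:
    return frame_to_catalog(pd.read_csv(path, sep="\t"))
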