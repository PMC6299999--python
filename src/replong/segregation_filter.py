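"""Candidate filtering for an X-linked recessive pedigree study.

The cascade narrows repeat genotypes to disease-candidate loci:

1. restrict to the family's linkage interval(s);
2. keep loci discordant between the sequenced affected and unaffected male;
3. require segregation with the phenotype across the family (all affected
   males share the proband allele, no unaffected male carries it, carrier
   females are heterozygous for it);
4. require the proband allele to be absent from the other families;
5. screen a control population (fragment-analysis scale), optionally
   resolving alleles of equal total length by sub-repeat decomposition.

Genotype tables are long-format DataFrames with one row per allele:
columns sample, family, locus, allele_bp and an optional `sub_copies`
string (e.g. "21,33") carrying a compound decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .util import intervals_overlap

GENOTYPE_COLUMNS = ["sample", "family", "locus", "allele_bp", "sub_copies"]

STAGES = (
    "outside_interval",
    "concordant",
    "non_segregating",
    "shared_across_families",
    "found_in_controls",
    "candidate",
)


@dataclass(frozen=True)
class PedigreeSample:
    sample_id: str
    family_id: str
    sex: str  # M | F
    phenotype: str  # affected | unaffected | carrier | unknown

    def __post_init__(self) -> None:
        if self.phenotype == "carrier" and self.sex != "F":
            raise ValueError("carriers are female under the X-linked model")


def read_pedigree(path: str) -> pd.DataFrame:
    ped = pd.read_csv(path, sep="\t")
    required = {"sample", "family", "sex", "phenotype"}
    missing = required - set(ped.columns)
    if missing:
        raise ValueError(f"pedigree table missing columns: {sorted(missing)}")
    bad = ped[(ped.phenotype == "carrier") & (ped.sex != "F")]
    if len(bad):
        raise ValueError("carriers must be female under the X-linked model")
    return ped


# ---------------------------------------------------------------------------
# Allele comparison
# ---------------------------------------------------------------------------


def _parse_sub(value) -> tuple[int, ...] | None:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    if isinstance(value, str):
        if not value:
            return None
        return tuple(int(x) for x in value.split(","))
    return tuple(value)


def alleles_match(
    a_bp: float,
    b_bp: float,
    a_sub=None,
    b_sub=None,
    mode: str = "total_length",
    tol_bp: float = 0.0,
) -> bool:
    """Allele equality at the requested resolution.

    `total_length` compares base-pair length within `tol_bp` (fragment
    analysis rounds to the nearest base, so +/-1 bp is typical for
    instrument-scale inputs); `sub_repeat` compares per-motif copy numbers
    exactly when both sides carry a decomposition, falling back to total
    length otherwise.
    """
    if mode not in ("total_length", "sub_repeat"):
        raise ValueError("mode must be 'total_length' or 'sub_repeat'")
    a_sub, b_sub = _parse_sub(a_sub), _parse_sub(b_sub)
    if mode == "sub_repeat" and a_sub is not None and b_sub is not None:
        return a_sub == b_sub
    return abs(a_bp - b_bp) <= tol_bp


def _sample_alleles(gts: pd.DataFrame, sample: str, locus: str) -> pd.DataFrame:
    return gts[(gts["sample"] == sample) & (gts["locus"] == locus)]


# ---------------------------------------------------------------------------
# Cascade stages
# ---------------------------------------------------------------------------


def interval_restrict(
    genotypes: pd.DataFrame,
    intervals: Sequence[tuple[str, int, int]],
    locus_coords: Mapping[str, tuple[str, int, int]],
) -> pd.DataFrame:
    """Keep genotype rows whose locus overlaps any linkage interval."""
    keep_loci = {
        locus
        for locus, (chrom, start, end) in locus_coords.items()
        if any(
            chrom == ichrom and intervals_overlap(start, end, istart, iend)
            for ichrom, istart, iend in intervals
        )
    }
    return genotypes[genotypes["locus"].isin(keep_loci)].copy()


def discordant_loci(
    genotypes: pd.DataFrame,
    affected: str,
    unaffected: str,
    unit_lens: Mapping[str, int],
    min_diff_units: int = 1,
    mode: str = "total_length",
    tol_bp: float = 0.0,
) -> list[str]:
    """Loci where the two sequenced males differ by >= min_diff_units.

    Both samples are hemizygous (one allele each); loci missing a call in
    either sample are excluded.
    """
    out = []
    for locus in sorted(genotypes["locus"].unique()):
        a = _sample_alleles(genotypes, affected, locus)
        u = _sample_alleles(genotypes, unaffected, locus)
        if len(a) != 1 or len(u) != 1:
            continue
        a_row, u_row = a.iloc[0], u.iloc[0]
        unit = unit_lens.get(locus, 1)
        diff_bp = abs(a_row["allele_bp"] - u_row["allele_bp"])
        same = alleles_match(
            a_row["allele_bp"], u_row["allele_bp"],
            a_row.get("sub_copies"), u_row.get("sub_copies"),
            mode=mode, tol_bp=tol_bp,
        )
        if diff_bp >= min_diff_units * unit and not same:
            out.append(locus)
        elif not same and mode == "sub_repeat" and diff_bp < min_diff_units * unit:
            # equal length but different sub-repeat composition still counts
            out.append(locus)
    return out


def segregation_check(
    locus: str,
    genotypes: pd.DataFrame,
    pedigree: pd.DataFrame,
    proband: str,
    mode: str = "total_length",
    tol_bp: float = 0.0,
) -> str:
    """'consistent' | 'inconsistent' | 'unevaluable' under the X-linked
    recessive model.

    Consistency requires every affected male to carry the proband allele,
    no unaffected male to carry it, and carrier females to carry it
    heterozygously (exactly one of two alleles).  Members without a
    genotype make the locus unevaluable rather than failed; a carrier
    with only one called allele is likewise unevaluable.
    """
    prob_rows = _sample_alleles(genotypes, proband, locus)
    if len(prob_rows) != 1:
        return "unevaluable"
    p_bp = prob_rows.iloc[0]["allele_bp"]
    p_sub = prob_rows.iloc[0].get("sub_copies")
    family = pedigree[pedigree["family"] == _family_of(pedigree, proband)]

    def carries(rows: pd.DataFrame) -> list[bool]:
        return [
            alleles_match(r["allele_bp"], p_bp, r.get("sub_copies"), p_sub,
                          mode=mode, tol_bp=tol_bp)
            for _, r in rows.iterrows()
        ]

    for _, member in family.iterrows():
        sample = member["sample"]
        rows = _sample_alleles(genotypes, sample, locus)
        if member["phenotype"] == "affected":
            if len(rows) != 1:
                return "unevaluable"
            if not any(carries(rows)):
                return "inconsistent"
        elif member["phenotype"] == "unaffected" and member["sex"] == "M":
            if len(rows) != 1:
                return "unevaluable"
            if any(carries(rows)):
                return "inconsistent"
        elif member["phenotype"] == "carrier":
            if len(rows) != 2:
                return "unevaluable"
            if sum(carries(rows)) != 1:
                return "inconsistent"
    return "consistent"


def cross_family_unique(
    locus: str,
    proband_allele_bp: float,
    genotypes: pd.DataFrame,
    pedigree: pd.DataFrame,
    family: str,
    proband_sub=None,
    mode: str = "total_length",
    tol_bp: float = 0.0,
) -> bool:
    """True when the proband allele is absent from every sample of every
    other family."""
    other_samples = set(pedigree.loc[pedigree["family"] != family, "sample"])
    others = genotypes[
        (genotypes["locus"] == locus) & (genotypes["sample"].isin(other_samples))
    ]
    for _, row in others.iterrows():
        if alleles_match(row["allele_bp"], proband_allele_bp,
                         row.get("sub_copies"), proband_sub,
                         mode=mode, tol_bp=tol_bp):
            return False
    return True


def control_screen(
    locus: str,
    proband_allele_bp: float,
    controls: pd.DataFrame,
    proband_sub=None,
    mode: str = "total_length",
    tol_bp: float = 1.0,
) -> tuple[str, int]:
    """Screen a control genotype table for the proband allele.

    `total_length` emulates fragment analysis (+/-`tol_bp`); `sub_repeat`
    additionally resolves equal-length alleles by their per-motif copy
    numbers.  Returns ('unique'|'common', match count); an empty control
    table is a parameter error — the screen would be undefined.
    """
    rows = controls[controls["locus"] == locus] if "locus" in controls else controls
    if len(rows) == 0:
        raise ValueError(f"control table has no genotypes for locus {locus}")
    matches = sum(
        alleles_match(row["allele_bp"], proband_allele_bp,
                      row.get("sub_copies"), proband_sub,
                      mode=mode, tol_bp=tol_bp)
        for _, row in rows.iterrows()
    )
    return ("unique" if matches == 0 else "common"), int(matches)


# ---------------------------------------------------------------------------
# Cascade orchestration
# ---------------------------------------------------------------------------


def _family_of(pedigree: pd.DataFrame, sample: str) -> str:
    rows = pedigree[pedigree["sample"] == sample]
    if len(rows) != 1:
        raise ValueError(f"sample {sample} not uniquely present in the pedigree")
    return rows.iloc[0]["family"]


def candidate_report(
    genotypes: pd.DataFrame,
    pedigree: pd.DataFrame,
    intervals: Sequence[tuple[str, int, int]],
    locus_coords: Mapping[str, tuple[str, int, int]],
    unit_lens: Mapping[str, int],
    controls: pd.DataFrame,
    proband: str,
    affected: str,
    unaffected: str,
    mode: str = "total_length",
    tol_bp: float = 0.0,
    control_tol_bp: float = 1.0,
    min_diff_units: int = 1,
) -> pd.DataFrame:
    """Run the full cascade and audit every locus's terminal stage.

    Every locus with a genotype is assigned exactly one terminal stage;
    `candidate` marks loci surviving all filters.
    """
    family = _family_of(pedigree, proband)
    all_loci = sorted(genotypes["locus"].unique())
    in_interval = set(
        interval_restrict(genotypes, intervals, locus_coords)["locus"].unique()
    )
    discordant = set(
        discordant_loci(
            genotypes[genotypes["locus"].isin(in_interval)],
            affected,
            unaffected,
            unit_lens,
            min_diff_units=min_diff_units,
            mode=mode,
            tol_bp=tol_bp,
        )
    )
    rows = []
    for locus in all_loci:
        stage = None
        detail = ""
        if locus not in in_interval:
            stage = "outside_interval"
        elif locus not in discordant:
            stage = "concordant"
        else:
            seg = segregation_check(
                locus, genotypes, pedigree, proband, mode=mode, tol_bp=tol_bp
            )
            if seg != "consistent":
                stage = "non_segregating"
                detail = seg
            else:
                prob_row = _sample_alleles(genotypes, proband, locus).iloc[0]
                p_bp, p_sub = prob_row["allele_bp"], prob_row.get("sub_copies")
                if not cross_family_unique(
                    locus, p_bp, genotypes, pedigree, family,
                    proband_sub=p_sub, mode=mode, tol_bp=tol_bp,
                ):
                    stage = "shared_across_families"
                else:
                    verdict, n_matches = control_screen(
                        locus, p_bp, controls, proband_sub=p_sub,
                        mode=mode, tol_bp=control_tol_bp,
                    )
                    detail = f"control_matches={n_matches}"
                    stage = "candidate" if verdict == "unique" else "found_in_controls"
        rows.append({"locus": locus, "stage": stage, "detail": detail})
    report = pd.DataFrame(rows, columns=["locus", "stage", "detail"])
    assert set(report["stage"]) <= set(STAGES)
    return report


def candidates(report: pd.DataFrame) -> list[str]:
    return report.loc[report["stage"] == "candidate", "locus"].tolist()
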