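"""Patient-versus-controls expression deregulation statistics.

The ranking statistic is the deregulation ratio

    R = |P - C| / (Cmax - Cmin)

where P is the patient's expression value, C the control value closest to
P, and Cmax - Cmin the control range.  R is zero exactly when the patient
matches a control value and is invariant under affine rescaling of the
expression axis, making it comparable across genes.  Target-set enrichment
against an expected background rate uses an exact one-sided binomial test,
and a ddCt utility normalises qPCR Ct values against the geometric mean of
endogenous controls.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


# ---------------------------------------------------------------------------
# Deregulation ratio
# ---------------------------------------------------------------------------


def deregulation_ratio(patient: float, controls: Sequence[float]) -> tuple[float, float]:
    """R = |P - C| / (Cmax - Cmin) with C the control closest to P.

    Requires at least two controls with a non-degenerate range.  Exact
    ties in closeness take the larger control value (R is unaffected).
    Returns (R, C).
    """
    controls = [float(c) for c in controls]
    if len(controls) < 2:
        raise ValueError("at least two controls required")
    if not all(math.isfinite(c) for c in controls) or not math.isfinite(patient):
        raise ValueError("expression values must be finite")
    c_max, c_min = max(controls), min(controls)
    if c_max == c_min:
        raise ValueError("control range is zero; R undefined")
    closest = max(
        controls, key=lambda c: (-abs(patient - c), c)
    )  # smallest |P-C|, ties -> larger C
    return abs(patient - closest) / (c_max - c_min), closest


def rank_deregulated(
    matrix: pd.DataFrame,
    patient: str,
    prefilter: pd.Series | None = None,
    r_threshold: float = 0.9,
) -> pd.DataFrame:
    """Rank genes by R descending (stable for ties, preserving input order).

    `matrix` is genes x samples with the patient in column `patient`;
    `prefilter` is an optional boolean flag column from an upstream
    differential-expression run (consumed, not computed here).  The result
    carries R, the closest control value, the flag and an `above_threshold`
    column for the reported subset.
    """
    if patient not in matrix.columns:
        raise ValueError(f"patient column {patient!r} not in matrix")
    control_cols = [c for c in matrix.columns if c != patient]
    if len(control_cols) < 2:
        raise ValueError("at least two control samples required")
    rows = []
    for gene, row in matrix.iterrows():
        r, closest = deregulation_ratio(row[patient], [row[c] for c in control_cols])
        rows.append(
            {
                "gene": gene,
                "R": r,
                "patient": row[patient],
                "closest_control": closest,
                "flag": bool(prefilter.get(gene, False)) if prefilter is not None else True,
            }
        )
    out = pd.DataFrame(rows)
    out["above_threshold"] = (out["R"] >= r_threshold) & out["flag"]
    out = out.sort_values("R", ascending=False, kind="stable").reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# Target enrichment
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EnrichmentResult:
    n_genes: int
    n_targets: int
    proportion: float
    expected_rate: float
    p_value: float


def target_enrichment(
    gene_set: Sequence[str],
    target_membership: Mapping[str, bool] | set,
    expected_rate: float,
) -> EnrichmentResult:
    """Observed predicted-target proportion in a gene set versus an
    expected background rate, with an exact one-sided ('greater')
    binomial test.

    21 predicted targets among 31 deregulated brain-expressed genes give a
    proportion of 67.7% against an expected 30%.
    """
    if not 0.0 < expected_rate < 1.0:
        raise ValueError("expected_rate must lie strictly between 0 and 1")
    genes = list(gene_set)
    if not genes:
        raise ValueError("gene set is empty")
    if isinstance(target_membership, Mapping):
        is_target = [bool(target_membership.get(g, False)) for g in genes]
    else:
        is_target = [g in target_membership for g in genes]
    k, n = sum(is_target), len(genes)
    test = stats.binomtest(k, n, expected_rate, alternative="greater")
    return EnrichmentResult(
        n_genes=n,
        n_targets=k,
        proportion=k / n,
        expected_rate=expected_rate,
        p_value=float(test.pvalue),
    )


# ---------------------------------------------------------------------------
# Relative expression (ddCt) with endogenous controls
# ---------------------------------------------------------------------------


def relative_expression(
    target_ct: pd.DataFrame,
    endogenous_ct: Mapping[str, pd.DataFrame],
    calibrator: str,
) -> pd.DataFrame:
    """Normalised expression via the ddCt method.

    `target_ct` is samples x replicates of the gene of interest;
    `endogenous_ct` maps each endogenous-control gene to a matching table.
    Per replicate, dCt = Ct_target - mean(Ct_controls) (the arithmetic
    mean in Ct space is the geometric mean of the control quantities);
    ddCt subtracts the calibrator's mean dCt and fold = 2^(-ddCt).
    Samples missing a control Ct are skipped with a warning.  Returns one
    row per sample with the mean fold and the SD across replicates.
    """
    if not endogenous_ct:
        raise ValueError("at least one endogenous control required")
    if calibrator not in target_ct.index:
        raise ValueError(f"calibrator {calibrator!r} not among samples")

    def dct_for(sample: str) -> np.ndarray | None:
        t = target_ct.loc[sample].to_numpy(dtype=float)
        ctrl_rows = []
        for gene, table in endogenous_ct.items():
            if sample not in table.index or table.loc[sample].isna().any():
                warnings.warn(f"sample {sample}: missing Ct for control {gene}; skipped")
                return None
            ctrl_rows.append(table.loc[sample].to_numpy(dtype=float))
        return t - np.mean(ctrl_rows, axis=0)

    cal_dct = dct_for(calibrator)
    if cal_dct is None:
        raise ValueError("calibrator sample is missing control Ct values")
    cal_mean = float(np.mean(cal_dct))
    rows = []
    for sample in target_ct.index:
        dct = dct_for(sample)
        if dct is None:
            continue
        ddct = dct - cal_mean
        folds = 2.0 ** (-ddct)
        rows.append(
            {
                "sample": sample,
                "fold": float(np.mean(folds)),
                "sd": float(np.std(folds, ddof=1)) if len(folds) > 1 else 0.0,
                "n_replicates": len(folds),
            }
        )
    return pd.DataFrame(rows).set_index("sample")
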