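"""Capture probe design for repeat targets.

Four probe types per target: left flank, right flank, a spanning probe
centred on the repeat midpoint, and a double probe concatenating half-length
segments of both flanks.  Probes are screened for genomic uniqueness with a
mismatch-bounded exhaustive window scan (a seed of 15 bases tolerating up to
3 mismatches plus an overall mismatch cap), failed flanking probes may be
rescued by shifting outward up to 500 bp, and probes with extreme GC content
are replicated fourfold in the final design.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .repeat_catalog import RepeatLocus
from .util import gc_fraction, revcomp, seq_to_array, sliding_mismatch_counts

PROBE_TYPES = ("left_flank", "right_flank", "spanning", "double")


@dataclass
class Probe:
    """One capture probe; `segments` holds two intervals for double probes."""

    target_id: str
    ptype: str
    chrom: str
    segments: list[tuple[int, int]]
    seq: str
    gc: float = 0.0
    verdict: str | None = None  # unique | ambiguous | cluster_specific
    shift: int = 0
    replication: int = 1

    def __post_init__(self) -> None:
        if self.ptype not in PROBE_TYPES:
            raise ValueError(f"unknown probe type {self.ptype}")
        if self.shift > 500:
            raise ValueError("shift must not exceed 500 bp")

    @property
    def unique(self) -> bool | None:
        if self.verdict is None:
            return None
        return self.verdict in ("unique", "cluster_specific")

    @property
    def start(self) -> int:
        return self.segments[0][0]

    @property
    def end(self) -> int:
        return self.segments[-1][1]


@dataclass(frozen=True)
class UniquenessParams:
    """Mismatch-bounded hit definition for the uniqueness screen.

    A genomic window (either strand) counts as a hit when its first
    `seed_len` bases show at most `seed_max_mismatch` mismatches and the
    full window at most `total_max_mismatch`.
    """

    seed_len: int = 15
    seed_max_mismatch: int = 3
    total_max_mismatch: int = 6


DEFAULT_UNIQUENESS = UniquenessParams()


# ---------------------------------------------------------------------------
# Probe generation
# ---------------------------------------------------------------------------


def generate_probes(
    locus: RepeatLocus, ref: Mapping[str, str], probe_len: int = 120
) -> list[Probe]:
    """Up to four candidate probes for one target, one per type.

    The left flank ends exactly at the repeat start, the right flank starts
    at the repeat end, the spanning probe is centred on the repeat midpoint
    and the double probe joins probe_len/2 from each flank.  Types falling
    off the contig are omitted with a warning.
    """
    if probe_len < 2 or probe_len % 2:
        raise ValueError("probe_len must be an even integer >= 2")
    chrom_seq = ref[locus.chrom]
    n = len(chrom_seq)
    half = probe_len // 2
    mid = (locus.start + locus.end) // 2
    probes: list[Probe] = []

    def add(ptype: str, segments: list[tuple[int, int]]) -> None:
        if any(s < 0 or e > n for s, e in segments):
            warnings.warn(f"{locus.id}: {ptype} probe out of contig range; omitted")
            return
        seq = "".join(chrom_seq[s:e] for s, e in segments)
        probes.append(
            Probe(
                target_id=locus.id,
                ptype=ptype,
                chrom=locus.chrom,
                segments=segments,
                seq=seq,
                gc=gc_fraction(seq),
            )
        )

    add("left_flank", [(locus.start - probe_len, locus.start)])
    add("right_flank", [(locus.end, locus.end + probe_len)])
    add("spanning", [(mid - half, mid + half)])
    add(
        "double",
        [(locus.start - half, locus.start), (locus.end, locus.end + half)],
    )
    return probes


# ---------------------------------------------------------------------------
# Uniqueness screen
# ---------------------------------------------------------------------------


def _hits_one_strand(
    probe_arr: np.ndarray, chrom_arr: np.ndarray, params: UniquenessParams
) -> np.ndarray:
    seed = probe_arr[: params.seed_len]
    seed_mm = sliding_mismatch_counts(chrom_arr, seed)
    total_mm = sliding_mismatch_counts(chrom_arr, probe_arr)
    if len(total_mm) == 0:
        return np.zeros(0, dtype=np.int64)
    ok = (seed_mm[: len(total_mm)] <= params.seed_max_mismatch) & (
        total_mm <= params.total_max_mismatch
    )
    return np.nonzero(ok)[0]


def find_genomic_hits(
    probe_seq: str,
    ref: Mapping[str, str],
    params: UniquenessParams = DEFAULT_UNIQUENESS,
) -> list[tuple[str, int, str]]:
    """All (chrom, start, strand) placements of `probe_seq` in `ref` under
    the mismatch-bounded hit definition, both strands."""
    if len(probe_seq) < params.seed_len:
        raise ValueError("probe shorter than the seed length")
    if not ref or all(len(s) == 0 for s in ref.values()):
        raise ValueError("empty reference")
    fwd = seq_to_array(probe_seq.upper())
    rev = seq_to_array(revcomp(probe_seq.upper()))
    hits: list[tuple[str, int, str]] = []
    for chrom, seq in ref.items():
        chrom_arr = seq_to_array(seq.upper())
        for strand, arr in (("+", fwd), ("-", rev)):
            for pos in _hits_one_strand(arr, chrom_arr, params):
                hits.append((chrom, int(pos), strand))
    return hits


def uniqueness_screen(
    probe: Probe,
    ref: Mapping[str, str],
    clusters: Sequence[tuple[str, int, int]] | None = None,
    params: UniquenessParams = DEFAULT_UNIQUENESS,
) -> str:
    """Classify a probe as unique, cluster_specific or ambiguous.

    A probe is unique when exactly one genomic placement passes the hit
    definition; when secondary placements exist but all fall inside a
    declared duplication-cluster interval the probe is cluster_specific
    (usable for every member of the cluster); anything else is ambiguous.
    Double probes are screened per flank segment and take the worse verdict.
    """
    if probe.ptype == "double":
        half = len(probe.seq) // 2
        verdicts = []
        for sub_seq, seg in zip((probe.seq[:half], probe.seq[half:]), probe.segments):
            sub = Probe(
                target_id=probe.target_id,
                ptype="left_flank",
                chrom=probe.chrom,
                segments=[seg],
                seq=sub_seq,
            )
            verdicts.append(uniqueness_screen(sub, ref, clusters, params))
        order = {"unique": 0, "cluster_specific": 1, "ambiguous": 2}
        probe.verdict = max(verdicts, key=lambda v: order[v])
        return probe.verdict

    hits = find_genomic_hits(probe.seq, ref, params)
    own = [
        h
        for h in hits
        if h[0] == probe.chrom and abs(h[1] - probe.start) < len(probe.seq)
    ]
    secondary = [h for h in hits if h not in own]
    if not secondary:
        verdict = "unique"
    elif clusters and all(
        any(
            chrom == c_chrom and c_start <= pos < c_end
            for c_chrom, c_start, c_end in clusters
        )
        for chrom, pos, _strand in secondary
    ):
        verdict = "cluster_specific"
    else:
        verdict = "ambiguous"
    probe.verdict = verdict
    return verdict


# ---------------------------------------------------------------------------
# Outward-shift rescue
# ---------------------------------------------------------------------------


def _shifted_probe(
    locus: RepeatLocus,
    ref: Mapping[str, str],
    ptype: str,
    probe_len: int,
    shift: int,
) -> Probe | None:
    chrom_seq = ref[locus.chrom]
    n = len(chrom_seq)
    half = probe_len // 2
    if ptype == "left_flank":
        segments = [(locus.start - probe_len - shift, locus.start - shift)]
    elif ptype == "right_flank":
        segments = [(locus.end + shift, locus.end + probe_len + shift)]
    elif ptype == "double":
        segments = [
            (locus.start - half - shift, locus.start - shift),
            (locus.end + shift, locus.end + half + shift),
        ]
    else:
        return None  # spanning probes cannot shift off the repeat
    if any(s < 0 or e > n for s, e in segments):
        return None
    seq = "".join(chrom_seq[s:e] for s, e in segments)
    return Probe(
        target_id=locus.id,
        ptype=ptype,
        chrom=locus.chrom,
        segments=segments,
        seq=seq,
        gc=gc_fraction(seq),
        shift=shift,
    )


def shift_and_rescue(
    locus: RepeatLocus,
    ref: Mapping[str, str],
    probe_len: int = 120,
    max_shift: int = 500,
    step: int = 10,
    clusters: Sequence[tuple[str, int, int]] | None = None,
    params: UniquenessParams = DEFAULT_UNIQUENESS,
    ptypes: Sequence[str] = ("left_flank", "right_flank", "double"),
) -> list[Probe]:
    """Rescue failed flanking/double probes by the most proximal outward
    shift (<= max_shift) that passes the uniqueness screen.

    The shift is searched coarsely in `step`-bp increments and then refined
    base-by-base below the first passing shift, so the reported shift is
    the minimal passing one.  Already-unique probes come back with shift 0.
    """

    def passes(shift: int, ptype: str) -> Probe | None:
        probe = _shifted_probe(locus, ref, ptype, probe_len, shift)
        if probe is None:
            return None
        if uniqueness_screen(probe, ref, clusters, params) != "ambiguous":
            return probe
        return None

    rescued: list[Probe] = []
    for ptype in ptypes:
        found: Probe | None = None
        coarse = None
        for shift in range(0, max_shift + 1, step):
            probe = passes(shift, ptype)
            if probe is not None:
                coarse = shift
                found = probe
                break
        if coarse is not None and coarse > 0:
            for shift in range(max(0, coarse - step + 1), coarse):
                probe = passes(shift, ptype)
                if probe is not None:
                    found = probe
                    break
        if found is not None:
            rescued.append(found)
    return rescued


# ---------------------------------------------------------------------------
# GC-based replication and design table
# ---------------------------------------------------------------------------


def replicate_probes(
    probes: Sequence[Probe],
    base_replication: int = 1,
    gc_low: float = 0.40,
    gc_high: float = 0.70,
    multiplier: int = 4,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply GC-based replication: strictly below `gc_low` or strictly above
    `gc_high` GC multiplies a probe by `multiplier`; otherwise the base
    replication applies.  Returns the design table and summary totals."""
    rows = []
    for i, probe in enumerate(probes, start=1):
        rep = multiplier if (probe.gc < gc_low or probe.gc > gc_high) else base_replication
        probe.replication = rep
        rows.append(
            {
                "probe_id": f"{probe.target_id}_{probe.ptype}_{i}",
                "target_id": probe.target_id,
                "type": probe.ptype,
                "chrom": probe.chrom,
                "start": probe.start,
                "end": probe.end,
                "segments": ";".join(f"{s}-{e}" for s, e in probe.segments),
                "seq": probe.seq,
                "gc": round(probe.gc, 4),
                "verdict": probe.verdict,
                "shift": probe.shift,
                "replication": rep,
                "efficiency": None,  # populated from sequencing yield downstream
            }
        )
    table = pd.DataFrame(rows)
    totals = {
        "probe_count": int(sum(p.replication for p in probes)),
        "capture_size_bp": int(sum(p.replication * len(p.seq) for p in probes)),
    }
    return table, totals


def design_targets(
    catalog: Sequence[RepeatLocus],
    ref: Mapping[str, str],
    probe_len: int = 120,
    clusters: Sequence[tuple[str, int, int]] | None = None,
    params: UniquenessParams = DEFAULT_UNIQUENESS,
    max_shift: int = 500,
    base_replication: int = 1,
) -> tuple[pd.DataFrame, dict[str, int], dict[str, int]]:
    """Full design pass: generate, screen, rescue and replicate.

    Returns (design table, totals, per-target surviving probe-type counts).
    At most one probe per type survives for a target.
    """
    final: list[Probe] = []
    per_target: dict[str, int] = {}
    for locus in catalog:
        survivors: dict[str, Probe] = {}
        failed_types: list[str] = []
        for probe in generate_probes(locus, ref, probe_len):
            if uniqueness_screen(probe, ref, clusters, params) != "ambiguous":
                survivors[probe.ptype] = probe
            else:
                failed_types.append(probe.ptype)
        shiftable = [t for t in failed_types if t != "spanning"]
        if shiftable:
            for probe in shift_and_rescue(
                locus,
                ref,
                probe_len=probe_len,
                max_shift=max_shift,
                clusters=clusters,
                params=params,
                ptypes=shiftable,
            ):
                survivors[probe.ptype] = probe
        per_target[locus.id] = len(survivors)
        final.extend(survivors[t] for t in PROBE_TYPES if t in survivors)
    table, totals = replicate_probes(final, base_replication=base_replication)
    return table, totals, per_target
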