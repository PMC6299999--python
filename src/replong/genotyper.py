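"""Flank-anchored repeat genotyping from consensus long reads.

Each target carries a locus library: the 20 bases immediately left and
right of the repeat in the reference plus the repeat unit.  A read yields a
spanning allele when both flanks are found (mismatch-tolerant, either
orientation); a single flank yields a partial call whose length is a lower
bound on the true allele — the signature of an expansion exceeding the
captured fragment size.  Per-locus genotypes take the modal spanning length
with +/-1-unit stutter pooling; expansions are flagged when a locus yields
exclusively partial reads longer than the reference allele.  Compound
repeats such as (CT)n TTT (GT)n are decomposed into per-motif copy numbers
by a greedy left-to-right parse.
"""

from __future__ import annotations

import logging
import math
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .read_prep import AlignmentRecord, ReadRecord
from .repeat_catalog import RepeatLocus
from .util import interval_distance, revcomp, seq_to_array, sliding_mismatch_counts

logger = logging.getLogger(__name__)


@dataclass
class LocusLibrary:
    """Flanks and unit of one target, fetched from the reference."""

    target_id: str
    left_flank: str
    right_flank: str
    unit_seq: str
    ref_copies: float
    copy_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not self.left_flank or not self.right_flank:
            raise ValueError("flanks must be non-empty")
        if self.copy_range is None:
            # expected range defaults to the reference copy number alone
            self.copy_range = (self.ref_copies, self.ref_copies)

    @property
    def unit_len(self) -> int:
        return len(self.unit_seq)


@dataclass
class AlleleCall:
    """One read's evidence at one locus."""

    target_id: str
    read_id: str
    status: str  # spanning | partial_left | partial_right | absent
    length_bp: int = 0
    copies: float = 0.0
    is_lower_bound: bool = False
    multimatch: bool = False
    allele_seq: str | None = None

    def __post_init__(self) -> None:
        if self.status == "spanning" and self.is_lower_bound:
            raise ValueError("spanning calls are exact, not lower bounds")
        if self.status.startswith("partial") and not self.is_lower_bound:
            raise ValueError("partial calls are lower bounds")
        if self.length_bp < 0:
            raise ValueError("length_bp must be >= 0")


@dataclass
class Genotype:
    """Per-sample, per-locus consensus allele(s)."""

    target_id: str
    sample_id: str
    alleles: list[tuple[int, float, int]] = field(default_factory=list)
    # (length_bp, copies, support)
    informative: int = 0
    called: bool = False
    tie_flag: bool = False
    expanded: bool = False
    expansion_bound_copies: float | None = None
    expansion_bound_bp: int | None = None


# ---------------------------------------------------------------------------
# Library construction and read filtering
# ---------------------------------------------------------------------------


def build_locus_library(
    locus: RepeatLocus, ref: Mapping[str, str], flank_len: int = 20
) -> LocusLibrary:
    """Fetch the `flank_len` bases immediately 5' and 3' of the repeat.

    At a contig edge the flank is shortened with a warning, down to a
    minimum of 12 bases.
    """
    if flank_len <= 0:
        raise ValueError("flank_len must be positive")
    chrom_seq = ref[locus.chrom]
    left_start = locus.start - flank_len
    right_end = locus.end + flank_len
    if left_start < 0 or right_end > len(chrom_seq):
        left_start = max(0, left_start)
        right_end = min(len(chrom_seq), right_end)
        if locus.start - left_start < 12 or right_end - locus.end < 12:
            raise ValueError(f"{locus.id}: flank shorter than 12 bases at contig edge")
        warnings.warn(f"{locus.id}: flank truncated at contig edge")
    return LocusLibrary(
        target_id=locus.id,
        left_flank=chrom_seq[left_start : locus.start],
        right_flank=chrom_seq[locus.end : right_end],
        unit_seq=locus.unit_seq,
        ref_copies=locus.copies,
    )


def filter_reads_near_target(
    alignments: Sequence[AlignmentRecord],
    target: RepeatLocus,
    distance: int = 300,
) -> set[str]:
    """Read ids whose alignment interval comes within `distance` bases of
    the target interval (touching counts; 300 away is in, 301 is out)."""
    return {
        rec.read_id
        for rec in alignments
        if rec.chrom == target.chrom
        and interval_distance(rec.start, rec.end, target.start, target.end) <= distance
    }


# ---------------------------------------------------------------------------
# Per-read allele calling
# ---------------------------------------------------------------------------


def _flank_positions(read_arr: np.ndarray, flank: str, tol: int) -> list[int]:
    counts = sliding_mismatch_counts(read_arr, seq_to_array(flank))
    return [int(i) for i in np.nonzero(counts <= tol)[0]]


def call_allele_per_read(
    read: ReadRecord,
    lib: LocusLibrary,
    max_mismatch_frac: float = 0.1,
) -> AlleleCall:
    """Locate the locus flanks in a (trimmed) read and measure the repeat.

    Both orientations are tried; the orientation finding more flanks wins
    (spanning beats partial).  Flank matching tolerates
    ceil(max_mismatch_frac * flank_len) substitutions and no indels.  With
    both flanks found the allele is the sequence between the flank inner
    edges (ambiguous multiple placements take the outermost pair and set
    the multimatch flag); a single flank yields a partial call measured to
    the read end — a lower bound on the allele length.
    """
    best: AlleleCall | None = None
    for seq in (read.seq, revcomp(read.seq)):
        call = _call_one_orientation(seq, read.id, lib, max_mismatch_frac)
        if best is None or _call_rank(call) > _call_rank(best):
            best = call
    return best  # type: ignore[return-value]


_STATUS_RANK = {"absent": 0, "partial_right": 1, "partial_left": 1, "spanning": 2}


def _call_rank(call: AlleleCall) -> tuple[int, int]:
    return (_STATUS_RANK[call.status], call.length_bp)


def _call_one_orientation(
    seq: str, read_id: str, lib: LocusLibrary, max_mismatch_frac: float
) -> AlleleCall:
    arr = seq_to_array(seq)
    left_tol = math.ceil(max_mismatch_frac * len(lib.left_flank))
    right_tol = math.ceil(max_mismatch_frac * len(lib.right_flank))
    lefts = _flank_positions(arr, lib.left_flank, left_tol)
    rights = _flank_positions(arr, lib.right_flank, right_tol)

    if lefts and rights:
        # outermost pair maximising the inter-flank distance
        left = min(lefts)
        left_end = left + len(lib.left_flank)
        valid_rights = [r for r in rights if r >= left_end]
        if valid_rights:
            right = max(valid_rights)
            multi = len(lefts) > 1 or len(valid_rights) > 1
            length = right - left_end
            return AlleleCall(
                target_id=lib.target_id,
                read_id=read_id,
                status="spanning",
                length_bp=length,
                copies=round(length / lib.unit_len, 2),
                is_lower_bound=False,
                multimatch=multi,
                allele_seq=seq[left_end:right],
            )
    if lefts:
        left_end = min(lefts) + len(lib.left_flank)
        length = len(seq) - left_end
        return AlleleCall(
            target_id=lib.target_id,
            read_id=read_id,
            status="partial_left",
            length_bp=length,
            copies=round(length / lib.unit_len, 2),
            is_lower_bound=True,
            multimatch=len(lefts) > 1,
            allele_seq=seq[left_end:],
        )
    if rights:
        right = max(rights)
        return AlleleCall(
            target_id=lib.target_id,
            read_id=read_id,
            status="partial_right",
            length_bp=right,
            copies=round(right / lib.unit_len, 2),
            is_lower_bound=True,
            multimatch=len(rights) > 1,
            allele_seq=seq[:right],
        )
    return AlleleCall(target_id=lib.target_id, read_id=read_id, status="absent")


# ---------------------------------------------------------------------------
# Locus genotyping
# ---------------------------------------------------------------------------


def genotype_locus(
    calls: Sequence[AlleleCall],
    unit_len: int,
    sample_id: str = "",
    min_support: int = 5,
    sex_model: str = "hemizygous",
    minor_fraction: float = 0.2,
) -> Genotype:
    """Consensus allele(s) from one sample's calls at one locus.

    Spanning lengths vote; the modal length wins with ties broken toward
    the longer allele (flagged).  Calls within one unit of the mode are
    pooled as stutter into its support.  A genotype is emitted only when
    modal support reaches `min_support`.  The diploid model extracts up to
    two modes, the minor one additionally needing `minor_fraction` of the
    informative reads.
    """
    if sex_model not in ("hemizygous", "diploid"):
        raise ValueError("sex_model must be 'hemizygous' or 'diploid'")
    target_id = calls[0].target_id if calls else ""
    spanning = [c.length_bp for c in calls if c.status == "spanning"]
    informative = sum(1 for c in calls if c.status != "absent")
    gt = Genotype(target_id=target_id, sample_id=sample_id, informative=informative)
    if not spanning:
        return gt

    def take_mode(lengths: list[int]) -> tuple[int, int, bool]:
        counts = Counter(lengths)
        top = max(counts.values())
        modes = [l for l, c in counts.items() if c == top]
        tie = len(modes) > 1
        mode = max(modes)  # longer allele on ties
        support = sum(c for l, c in counts.items() if abs(l - mode) <= unit_len)
        return mode, support, tie

    mode, support, tie = take_mode(spanning)
    if support >= min_support:
        gt.alleles.append((mode, round(mode / unit_len, 2), support))
        gt.called = True
        gt.tie_flag = tie
    if sex_model == "diploid" and gt.called:
        rest = [l for l in spanning if abs(l - mode) > unit_len]
        if rest:
            mode2, support2, tie2 = take_mode(rest)
            if support2 >= min_support and support2 >= minor_fraction * informative:
                gt.alleles.append((mode2, round(mode2 / unit_len, 2), support2))
                gt.tie_flag = gt.tie_flag or tie2
    gt.alleles.sort(key=lambda a: -a[2])
    return gt


def detect_expansion(
    calls: Sequence[AlleleCall],
    lib: LocusLibrary,
    genotype: Genotype | None = None,
) -> tuple[bool, float | None, int | None]:
    """Flag a locus as expanded when it yields exclusively partial reads
    longer than the reference allele.

    Returns (expanded, max lower-bound copies, bound in bp); the bound is
    a floor on the true allele size — a 35-copy partial of a 26 bp unit
    demonstrates at least 910 bp of repeat.
    """
    has_spanning = any(c.status == "spanning" for c in calls)
    partials = [c for c in calls if c.status.startswith("partial")]
    if has_spanning or not partials:
        if genotype is not None:
            genotype.expanded = False
        return False, None, None
    over_ref = [c for c in partials if c.copies > lib.ref_copies]
    if not over_ref:
        if genotype is not None:
            genotype.expanded = False
        return False, None, None
    bound_copies = max(c.copies for c in over_ref)
    bound_bp = int(round(bound_copies * lib.unit_len))
    if genotype is not None:
        genotype.expanded = True
        genotype.expansion_bound_copies = bound_copies
        genotype.expansion_bound_bp = bound_bp
    return True, bound_copies, bound_bp


# ---------------------------------------------------------------------------
# Compound sub-repeat decomposition
# ---------------------------------------------------------------------------


def decompose_compound(
    allele_seq: str,
    sub_units: Sequence[str] = ("CT", "GT"),
    separator: str = "TTT",
) -> tuple[tuple[int, ...], bool]:
    """Greedy left-to-right parse of a compound repeat into per-motif copy
    numbers.

    Maximal runs of each motif are consumed in order with the separator
    expected between consecutive runs; a mismatched residue ends a run.
    When the separator is absent the parse stops with a warning flag set
    and the remaining motifs report zero (single-motif fallback).
    """
    if not sub_units:
        raise ValueError("at least one sub-unit motif required")
    counts: list[int] = []
    pos = 0
    warned = False
    for idx, motif in enumerate(sub_units):
        m = len(motif)
        run = 0
        while allele_seq[pos : pos + m] == motif:
            run += 1
            pos += m
        counts.append(run)
        if idx < len(sub_units) - 1:
            if allele_seq[pos : pos + len(separator)] == separator:
                pos += len(separator)
            else:
                warned = True
                warnings.warn(
                    "separator not found after motif "
                    f"{motif}; falling back to the motifs parsed so far"
                )
                counts.extend([0] * (len(sub_units) - idx - 1))
                break
    return tuple(counts), warned


def compound_total_length(
    sub_copies: Sequence[int], sub_units: Sequence[str], separator: str
) -> int:
    """Total repeat-tract length in bp implied by a sub-repeat decomposition."""
    total = sum(c * len(u) for c, u in zip(sub_copies, sub_units))
    if len(sub_units) > 1:
        total += len(separator) * (len(sub_units) - 1)
    return total
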