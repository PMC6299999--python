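"""Read preparation: adaptor trimming, desk-scale local alignment to target
windows, duplicate removal and sequencing-yield categorisation.

Consensus reads carry 32 synthetic adaptor bases at each end which are
trimmed positionally.  Alignment is affine-gap local alignment
(Bio.Align.PairwiseAligner) against +/-1000 bp windows around each target,
with a shared-k-mer prefilter choosing the candidate window; both strands
are tried.  Yield categories mirror a capture experiment's accounting:
total, unmapped, within 1000 bases of a target, intersecting a repeat,
spanning it, and "useful" (spanning the repeat plus 20 nt of each flank,
where a soft-clipped tail re-matching the missing flank also counts).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import Align

from .repeat_catalog import RepeatLocus
from .util import (
    interval_distance,
    intervals_overlap,
    revcomp,
    seq_to_array,
    sliding_mismatch_counts,
)

logger = logging.getLogger(__name__)

ADAPTOR_LEN = 32


@dataclass
class ReadRecord:
    """One consensus read of insert."""

    id: str
    seq: str
    qual: str | None = None
    passes: int | None = None


@dataclass
class AlignmentRecord:
    """A read's best local placement against one target window."""

    read_id: str
    chrom: str
    start: int
    end: int
    strand: str
    score: float
    clip5: int
    clip3: int
    segments: list[tuple[int, int]] = field(default_factory=list)
    duplicate: bool = False
    read_seq: str = ""

    def __post_init__(self) -> None:
        if self.clip5 < 0 or self.clip3 < 0:
            raise ValueError("soft-clip lengths must be >= 0")


# ---------------------------------------------------------------------------
# Adaptor trimming
# ---------------------------------------------------------------------------


def trim_adaptors(read: ReadRecord, n: int = ADAPTOR_LEN) -> ReadRecord | None:
    """Remove `n` bases from both read ends; reads of length <= 2n are
    dropped (returned as None) and counted by the caller."""
    if len(read.seq) <= 2 * n:
        return None
    return ReadRecord(
        id=read.id,
        seq=read.seq[n:-n],
        qual=read.qual[n:-n] if read.qual else None,
        passes=read.passes,
    )


def trim_all(reads: Iterable[ReadRecord], n: int = ADAPTOR_LEN) -> tuple[list[ReadRecord], int]:
    """Trim a batch; returns (kept reads, dropped count)."""
    kept, dropped = [], 0
    for read in reads:
        trimmed = trim_adaptors(read, n)
        if trimmed is None:
            dropped += 1
        else:
            kept.append(trimmed)
    if dropped:
        logger.info("trim_adaptors dropped %d reads of length <= %d", dropped, 2 * n)
    return kept, dropped


# ---------------------------------------------------------------------------
# Window alignment
# ---------------------------------------------------------------------------


@dataclass
class TargetWindow:
    target_id: str
    chrom: str
    start: int  # window start on the chromosome
    end: int
    seq: str
    k: int = 13
    kmer_pos: dict[str, list[int]] = field(default_factory=dict)


def build_windows(
    catalog: Sequence[RepeatLocus],
    ref: Mapping[str, str],
    pad: int = 1000,
    k: int = 13,
) -> list[TargetWindow]:
    """Extract +/-`pad` windows around each catalogued repeat and index
    their k-mer positions for the alignment prefilter."""
    windows = []
    for locus in catalog:
        chrom_seq = ref[locus.chrom]
        start = max(0, locus.start - pad)
        end = min(len(chrom_seq), locus.end + pad)
        seq = chrom_seq[start:end]
        kmer_pos: dict[str, list[int]] = {}
        for i in range(0, len(seq) - k + 1):
            kmer_pos.setdefault(seq[i : i + k], []).append(i)
        windows.append(
            TargetWindow(
                target_id=locus.id, chrom=locus.chrom, start=start, end=end,
                seq=seq, k=k, kmer_pos=kmer_pos,
            )
        )
    return windows


def make_aligner(
    match: float = 1.0,
    mismatch: float = -3.0,
    gap_open: float = -5.0,
    gap_extend: float = -2.0,
) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def _kmer_hits(read_seq: str, window: TargetWindow) -> list[tuple[int, int]]:
    """(read_pos, window_pos) pairs of shared k-mers, capping
    high-multiplicity window k-mers (repeat interiors) at 8 placements."""
    k = window.k
    hits = []
    for i in range(0, len(read_seq) - k + 1):
        positions = window.kmer_pos.get(read_seq[i : i + k])
        if positions and len(positions) <= 4:
            for j in positions:
                hits.append((i, j))
    return hits


def _diagonal_alignment(
    read_seq: str,
    window: TargetWindow,
    hits: Sequence[tuple[int, int]],
    match: float = 1.0,
    mismatch: float = -3.0,
) -> tuple[float, int, int, int, int] | None:
    """Ungapped local alignment along the best-supported diagonal.

    Shared k-mers vote for diagonals (window_pos - read_pos); the
    top-voted diagonal is scanned with a maximal-scoring-subsegment
    (Kadane) pass.  Returns (score, read0, read1, win0, win1) or None when
    the votes spread over several diagonals (an indel is likely) or the
    matched segment identity is poor — callers then fall back to gapped
    dynamic programming.
    """
    votes: dict[int, int] = {}
    for i, j in hits:
        d = j - i
        votes[d] = votes.get(d, 0) + 1
    if not votes:
        return None
    d, top = max(votes.items(), key=lambda kv: (kv[1], -kv[0]))
    others = sum(v for dd, v in votes.items() if abs(dd - d) > 3)
    if others >= max(5, 0.2 * top):
        return None  # competing diagonal: likely indel, use DP
    seg = _kadane_on_diagonal(read_seq, window, d, match, mismatch)
    if seg is None:
        return None
    score, r0, r1 = seg
    return score, r0, r1, r0 + d, r1 + d


def _kadane_on_diagonal(
    read_seq: str,
    window: TargetWindow,
    d: int,
    match: float,
    mismatch: float,
    min_identity: float = 0.9,
) -> tuple[float, int, int] | None:
    """Maximal-scoring ungapped subsegment of the read along diagonal `d`
    (window_pos = read_pos + d).  Returns (score, read0, read1)."""
    i_lo = max(0, -d)
    i_hi = min(len(read_seq), len(window.seq) - d)
    if i_hi - i_lo < window.k:
        return None
    read_arr = seq_to_array(read_seq)[i_lo:i_hi]
    win_arr = seq_to_array(window.seq)[i_lo + d : i_hi + d]
    scores = np.where(read_arr == win_arr, match, mismatch)
    best = run = 0.0
    best_end = run_start = 0
    best_start = 0
    for idx, s in enumerate(scores):
        if run <= 0:
            run = 0.0
            run_start = idx
        run += s
        if run > best:
            best, best_start, best_end = run, run_start, idx + 1
    if best <= 0:
        return None
    seg = scores[best_start:best_end]
    if float((seg > 0).mean()) < min_identity:
        return None
    return best, i_lo + best_start, i_lo + best_end


def _two_diagonal_alignment(
    read_seq: str,
    window: TargetWindow,
    hits: Sequence[tuple[int, int]],
    match: float,
    mismatch: float,
    gap_open: float,
    gap_extend: float,
    max_gap: int = 300,
) -> tuple[float, list[tuple[int, int, int, int]]] | None:
    """Stitched placement over exactly two diagonals.

    A read whose repeat allele differs from the reference by whole units
    aligns on one diagonal before the repeat and a shifted diagonal after
    it — a single internal gap.  When the k-mer votes form two clean
    clusters, each side is placed by an ungapped scan and joined with one
    affine gap, avoiding full dynamic programming.  Returns
    (score, [(read0, read1, win0, win1), ...]) with two segments.
    """
    votes: dict[int, int] = {}
    for i, j in hits:
        votes[j - i] = votes.get(j - i, 0) + 1
    clusters = sorted(votes.items(), key=lambda kv: (-kv[1], kv[0]))
    strong = [(d, v) for d, v in clusters if v >= 3]
    if len(strong) < 2:
        return None
    (d1, _v1), (d2, _v2) = strong[0], strong[1]
    gap = abs(d1 - d2)
    if gap == 0 or gap > max_gap:
        return None
    noise = sum(v for d, v in votes.items() if abs(d - d1) > 3 and abs(d - d2) > 3)
    if noise >= 5:
        return None
    seg1 = _kadane_on_diagonal(read_seq, window, d1, match, mismatch)
    seg2 = _kadane_on_diagonal(read_seq, window, d2, match, mismatch)
    if seg1 is None or seg2 is None:
        return None
    (sc_a, r0a, r1a), (sc_b, r0b, r1b) = seg1, seg2
    da, db = d1, d2
    if r0b < r0a:  # order segments left-to-right on the read
        (sc_a, r0a, r1a, da), (sc_b, r0b, r1b, db) = (
            (sc_b, r0b, r1b, d2),
            (sc_a, r0a, r1a, d1),
        )
    if r1a > r0b:  # repeat interior matches both diagonals: split the overlap
        overlap = r1a - r0b
        cut = overlap // 2
        r1a -= overlap - cut
        r0b += cut
    if r1a <= r0a or r1b <= r0b:
        return None
    score = sc_a + sc_b - (abs(gap_open) + abs(gap_extend) * (gap - 1))
    segments = [(r0a, r1a, r0a + da, r1a + da), (r0b, r1b, r0b + db, r1b + db)]
    if segments[1][2] < segments[0][3]:  # window coords must stay ordered
        return None
    return score, segments


def align_to_windows(
    reads: Iterable[ReadRecord],
    windows: Sequence[TargetWindow],
    min_score: float = 30.0,
    min_shared_kmers: int = 3,
    aligner: Align.PairwiseAligner | None = None,
    band_pad: int = 150,
) -> list[AlignmentRecord]:
    """Best-window local placement for each read.

    The window sharing the most k-mers with the read (either orientation)
    is aligned: near-exact reads resolve on a single diagonal and are
    placed by an ungapped scan, anything with a likely indel or poor
    diagonal identity goes through affine-gap local dynamic programming
    over a k-mer-banded stretch of the window.  Reads whose best score
    falls below `min_score` are unmapped and omitted.
    """
    if aligner is None:
        aligner = make_aligner()
    records: list[AlignmentRecord] = []
    for read in reads:
        best: AlignmentRecord | None = None
        for strand, seq in (("+", read.seq), ("-", revcomp(read.seq))):
            scored = []
            for wi, window in enumerate(windows):
                hits = _kmer_hits(seq, window)
                if len(hits) >= min_shared_kmers:
                    scored.append((len(hits), wi, hits))
            scored.sort(key=lambda t: -t[0])
            for _share, wi, hits in scored[:2]:
                window = windows[wi]
                rec = _align_one(seq, window, hits, aligner, band_pad)
                if rec is not None and (best is None or rec.score > best.score):
                    rec.read_id = read.id
                    rec.strand = strand
                    best = rec
        if best is not None and best.score >= min_score:
            records.append(best)
    return records


def _align_one(
    seq: str,
    window: TargetWindow,
    hits: Sequence[tuple[int, int]],
    aligner: Align.PairwiseAligner,
    band_pad: int,
) -> AlignmentRecord | None:
    fast = _diagonal_alignment(
        seq, window, hits, aligner.match_score, aligner.mismatch_score
    )
    if fast is not None:
        score, r0, r1, w0, w1 = fast
        return AlignmentRecord(
            read_id="",
            chrom=window.chrom,
            start=window.start + w0,
            end=window.start + w1,
            strand="+",
            score=float(score),
            clip5=r0,
            clip3=len(seq) - r1,
            segments=[(window.start + w0, window.start + w1)],
            read_seq=seq,
        )
    stitched = _two_diagonal_alignment(
        seq,
        window,
        hits,
        aligner.match_score,
        aligner.mismatch_score,
        aligner.open_gap_score,
        aligner.extend_gap_score,
    )
    if stitched is not None:
        score, segs = stitched
        return AlignmentRecord(
            read_id="",
            chrom=window.chrom,
            start=window.start + segs[0][2],
            end=window.start + segs[-1][3],
            strand="+",
            score=float(score),
            clip5=segs[0][0],
            clip3=len(seq) - segs[-1][1],
            segments=[(window.start + w0, window.start + w1) for _r0, _r1, w0, w1 in segs],
            read_seq=seq,
        )
    # banded affine-gap DP over the k-mer-supported stretch of the window
    w_lo = max(0, min(j for _i, j in hits) - band_pad)
    w_hi = min(len(window.seq), max(j for _i, j in hits) + window.k + band_pad)
    sub = window.seq[w_lo:w_hi]
    alignments = aligner.align(sub, seq)
    if alignments.score <= 0:
        return None
    top = alignments[0]
    t_blocks, q_blocks = top.aligned
    if len(t_blocks) == 0:
        return None
    t0, tn = int(t_blocks[0][0]), int(t_blocks[-1][1])
    q0, qn = int(q_blocks[0][0]), int(q_blocks[-1][1])
    return AlignmentRecord(
        read_id="",
        chrom=window.chrom,
        start=window.start + w_lo + t0,
        end=window.start + w_lo + tn,
        strand="+",
        score=float(top.score),
        clip5=q0,
        clip3=len(seq) - qn,
        segments=[
            (window.start + w_lo + int(a), window.start + w_lo + int(b))
            for a, b in t_blocks
        ],
        read_seq=seq,
    )


# ---------------------------------------------------------------------------
# Duplicate removal
# ---------------------------------------------------------------------------


def remove_duplicates(alignments: Sequence[AlignmentRecord]) -> list[AlignmentRecord]:
    """Keep one record per identical (chrom, start, end, strand) placement:
    the highest-scoring one, ties broken by lexicographic read id.
    Idempotent."""
    by_placement: dict[tuple[str, int, int, str], AlignmentRecord] = {}
    for rec in alignments:
        key = (rec.chrom, rec.start, rec.end, rec.strand)
        cur = by_placement.get(key)
        if cur is None or (rec.score, _neg_id(rec)) > (cur.score, _neg_id(cur)):
            by_placement[key] = rec
    kept = sorted(by_placement.values(), key=lambda r: (r.chrom, r.start, r.end, r.read_id))
    return kept


def _neg_id(rec: AlignmentRecord):
    # lexicographically smallest id wins at equal score
    return tuple(-ord(c) for c in rec.read_id)


# ---------------------------------------------------------------------------
# Yield summary
# ---------------------------------------------------------------------------


def _clip_matches_flank(clip_seq: str, flank_seq: str, max_mismatch_frac: float = 0.1) -> bool:
    """Does a soft-clipped tail re-match a repeat flank (<=10% mismatches
    over at least 20 bases)?  Both orientations are tried."""
    m = len(flank_seq)
    if m < 20 or len(clip_seq) < m:
        return False
    tol = int(max_mismatch_frac * m)
    flank = seq_to_array(flank_seq)
    for probe in (clip_seq, revcomp(clip_seq)):
        counts = sliding_mismatch_counts(seq_to_array(probe), flank)
        if len(counts) and counts.min() <= tol:
            return True
    return False


def yield_summary(
    alignments: Sequence[AlignmentRecord],
    catalog: Sequence[RepeatLocus],
    ref: Mapping[str, str] | None = None,
    total_reads: int | None = None,
    flank: int = 20,
    near: int = 1000,
) -> dict[str, int]:
    """Per-sample read-category counts.

    Categories are nested: useful <= spanning <= intersecting <=
    within_1000 <= mapped <= total.  A read whose alignment covers the
    repeat and one flank while its soft-clipped tail re-matches the
    opposite flank counts as both spanning and useful (the clipped portion
    demonstrates the read physically spans the repeat).
    """
    counts = {
        "total": total_reads if total_reads is not None else len(alignments),
        "mapped": len(alignments),
        "unmapped": 0,
        "within_1000": 0,
        "intersecting": 0,
        "spanning": 0,
        "useful": 0,
    }
    counts["unmapped"] = counts["total"] - counts["mapped"]
    for rec in alignments:
        near_any = inter_any = span_any = useful_any = False
        for locus in catalog:
            if locus.chrom != rec.chrom:
                continue
            if interval_distance(rec.start, rec.end, locus.start, locus.end) <= near:
                near_any = True
            if intervals_overlap(rec.start, rec.end, locus.start, locus.end):
                inter_any = True
            else:
                continue
            covers_repeat = rec.start <= locus.start and rec.end >= locus.end
            covers_left = rec.start <= locus.start - flank
            covers_right = rec.end >= locus.end + flank
            if covers_repeat:
                span_any = True
                if covers_left and covers_right:
                    useful_any = True
                elif ref is not None:
                    useful_any = useful_any or _softclip_rescue(
                        rec, locus, ref, flank, covers_left, covers_right
                    )
            elif ref is not None:
                # alignment stops inside the repeat: clipped tail may still
                # demonstrate spanning by re-matching the opposite flank
                if covers_left and rec.end > locus.start and rec.clip3 >= flank:
                    right_flank = ref[locus.chrom][locus.end : locus.end + flank]
                    if _clip_matches_flank(rec.read_seq[len(rec.read_seq) - rec.clip3 :], right_flank):
                        span_any = useful_any = True
                if covers_right and rec.start < locus.end and rec.clip5 >= flank:
                    left_flank = ref[locus.chrom][max(0, locus.start - flank) : locus.start]
                    if _clip_matches_flank(rec.read_seq[: rec.clip5], left_flank):
                        span_any = useful_any = True
        counts["within_1000"] += near_any
        counts["intersecting"] += inter_any
        counts["spanning"] += span_any
        counts["useful"] += useful_any
    return counts


def _softclip_rescue(
    rec: AlignmentRecord,
    locus: RepeatLocus,
    ref: Mapping[str, str],
    flank: int,
    covers_left: bool,
    covers_right: bool,
) -> bool:
    """Alignment covers the repeat but stops short of one 20 nt flank;
    accept when the adjacent soft clip re-matches that flank."""
    chrom_seq = ref[locus.chrom]
    if not covers_left and rec.clip5 >= flank:
        left_flank = chrom_seq[max(0, locus.start - flank) : locus.start]
        if _clip_matches_flank(rec.read_seq[: rec.clip5], left_flank):
            covers_left = True
    if not covers_right and rec.clip3 >= flank:
        right_flank = chrom_seq[locus.end : locus.end + flank]
        if _clip_matches_flank(rec.read_seq[len(rec.read_seq) - rec.clip3 :], right_flank):
            covers_right = True
    return covers_left and covers_right


# ---------------------------------------------------------------------------
# FASTA/FASTQ I/O (Biopython-backed)
# ---------------------------------------------------------------------------


def read_sequences(path: str) -> list[ReadRecord]:
    """Load FASTA or FASTQ reads (format chosen by extension)."""
    from Bio import SeqIO

    fmt = "fastq" if str(path).endswith(("fastq", "fq")) else "fasta"
    reads = []
    for rec in SeqIO.parse(path, fmt):
        qual = None
        if fmt == "fastq":
            qual = "".join(
                chr(q + 33) for q in rec.letter_annotations["phred_quality"]
            )
        reads.append(ReadRecord(id=rec.id, seq=str(rec.seq).upper(), qual=qual))
    return reads


def write_alignment_table(alignments: Sequence[AlignmentRecord], path: str) -> None:
    import pandas as pd

    rows = [
        {
            "read_id": a.read_id,
            "chrom": a.chrom,
            "start": a.start,
            "end": a.end,
            "strand": a.strand,
            "score": a.score,
            "clip5": a.clip5,
            "clip3": a.clip3,
            "duplicate": a.duplicate,
        }
        for a in alignments
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
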