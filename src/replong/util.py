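"""Small shared sequence and design-arithmetic helpers.

Conventions used throughout the package:

* coordinates are 0-based half-open internally; genome-browser-style tables are
  1-based inclusive and converted at the I/O boundary;
* ``N`` bases count as mismatches in any comparison and as non-GC.
"""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

VALID_BASES = frozenset("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N self-complements)."""
    return seq.translate(_COMPLEMENT)[::-1]


def validate_sequence(seq: str) -> str:
    """Uppercase `seq` and reject characters outside ACGTN."""
    seq = seq.upper()
    bad = set(seq) - VALID_BASES
    if bad:
        raise ValueError(f"non-ACGTN characters in sequence: {sorted(bad)}")
    return seq


def gc_fraction(seq: str) -> float:
    """G+C fraction over the full string; N counts as non-GC."""
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C") + seq.count("g") + seq.count("c")) / len(seq)


def seq_to_array(seq: str) -> np.ndarray:
    """Byte view of a sequence for vectorised comparisons."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def sliding_mismatch_counts(haystack: np.ndarray, needle: np.ndarray) -> np.ndarray:
    """Mismatch count of `needle` against every window of `haystack`.

    Returns an array of length ``len(haystack) - len(needle) + 1``; empty when
    the haystack is shorter than the needle.
    """
    n, m = len(haystack), len(needle)
    if n < m:
        return np.zeros(0, dtype=np.int32)
    windows = np.lib.stride_tricks.sliding_window_view(haystack, m)
    return (windows != needle).sum(axis=1).astype(np.int32)


def interval_distance(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Gap in bases between two half-open intervals; 0 when they touch or overlap."""
    if a_end <= b_start:
        return b_start - a_end
    if b_end <= a_start:
        return a_start - b_end
    return 0


def intervals_overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    """True when two half-open intervals share at least one base."""
    return a_start < b_end and b_start < a_end


def cooccurrence_probability(prevalence: float, n_factors: int) -> float:
    """Probability that `n_factors` independent causes of a sporadic condition
    with the given population prevalence co-occur within one family.

    With a 2% prevalence, two and three independent factors give 4e-4 and
    8e-6 respectively, which is why a single segregating cause is the
    parsimonious model for a multiplex family.
    """
    if not 0.0 <= prevalence <= 1.0:
        raise ValueError("prevalence must lie in [0, 1]")
    if n_factors < 1:
        raise ValueError("n_factors must be >= 1")
    return prevalence**n_factors


def max_measurable_insert(polymerase_read_len: float, min_passes: int) -> float:
    """Longest insert (and hence repeat tract) measurable as a consensus read.

    Circular-consensus sequencing needs `min_passes` polymerase passes over
    the insert; a 15 kb polymerase read at 6 passes caps measurable inserts
    at 2.5 kb.
    """
    if min_passes < 1:
        raise ValueError("min_passes must be >= 1")
    if polymerase_read_len <= 0:
        raise ValueError("polymerase_read_len must be positive")
    return polymerase_read_len / min_passes
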