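"""Repeat detection, purity, variability scoring, annotation and tiered
target selection."""

import math

import numpy as np
import pytest

from replong.repeat_catalog import (
    GeneModel,
    RepeatLocus,
    SelectionConfig,
    ServCoefficients,
    classify_annotation,
    compute_purity,
    copies_from_printed_coords,
    find_tandem_repeats,
    purity_of_region,
    score_variability,
    select_targets,
)

from conftest import random_seq


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def oracle_purity(region, unit):
    """Position-by-position comparison against every cyclic phase."""
    u = len(unit)
    best = 0
    for phase in range(u):
        tiling = "".join(unit[(j + phase) % u] for j in range(len(region)))
        matches = sum(a == b for a, b in zip(region, tiling))
        best = max(best, matches)
    return 100.0 * best / len(region)


def oracle_scan(seq, min_unit, max_unit, min_total_len, min_copies,
                min_purity=85.0, penalty=3, reach=400):
    """Exhaustive window-scan tandem-repeat finder.

    For every unit size and every exactly-duplicated anchor, all left/right
    window extents within `reach` are enumerated and the score-maximal
    extent kept (ties: leftmost start, rightmost end).  Thresholds and the
    deterministic overlap resolution (highest score, smallest unit,
    leftmost) are then applied.
    """
    n = len(seq)
    cands = {}
    for u in range(min_unit, max_unit + 1):
        for i in range(n - 2 * u + 1):
            unit = seq[i : i + u]
            if "N" in unit or seq[i + u : i + 2 * u] != unit:
                continue
            lo = max(0, i - reach)
            hi = min(n, i + 2 * u + reach)
            # prefix sums of the per-position tiling score: score(s, e) =
            # P[e] - P[s]; the optimum factorises into min-prefix start
            # (ties: leftmost) and max-prefix end (ties: rightmost)
            prefix = [0]
            for j in range(lo, hi):
                step = 1 if seq[j] == unit[(j - i) % u] else -penalty
                prefix.append(prefix[-1] + step)
            starts = range(lo, i + 1)
            ends = range(i + 2 * u, hi + 1)
            s = min(starts, key=lambda x: (prefix[x - lo], x))
            e = max(ends, key=lambda x: (prefix[x - lo], x))
            score = prefix[e - lo] - prefix[s - lo]
            span = e - s
            if span < min_total_len or span / u < min_copies:
                continue
            shift = (s - i) % u
            unit_rot = unit[shift:] + unit[:shift]
            if oracle_purity(seq[s:e], unit_rot) < min_purity:
                continue
            k = (s, e, u)
            if k not in cands or score > cands[k][0]:
                cands[k] = (score, unit_rot)
    ordered = sorted(
        ((score, u, s, e, unit) for (s, e, u), (score, unit) in cands.items()),
        key=lambda t: (-t[0], t[1], t[2], t[3]),
    )
    kept = []
    for score, u, s, e, unit in ordered:
        if all(e <= ks or ke <= s for _su, ks, ke in kept):
            kept.append((u, s, e))
    return sorted((s, e, u) for u, s, e in kept)


# speed: the quadratic extent enumeration in the oracle is fine below 2 kb


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------


class TestFindTandemRepeats:
    def test_perfect_dinucleotide(self):
        loci = find_tandem_repeats("ACACACAC", 1, 6, 8, 2)
        assert len(loci) == 1
        locus = loci[0]
        assert (locus.unit_seq, locus.copies, locus.purity) == ("AC", 4.0, 100.0)
        assert (locus.start, locus.end) == (0, 8)

    def test_random_sequence_matches_exhaustive_scan(self, rng):
        """A 1 kb random sequence holds no >=30 bp repeat, and the fast
        finder agrees with the exhaustive window scan."""
        seq = random_seq(rng, 1000)
        fast = find_tandem_repeats(seq, 1, 4, 30, 2)
        slow = oracle_scan(seq, 1, 4, 30, 2)
        assert [(l.start, l.end, l.unit_len) for l in fast] == slow
        assert slow == []

    @pytest.mark.parametrize("planted,unit", [("GT" * 33, "GT"), ("CAG" * 20, "CAG")])
    def test_planted_repeat_recovered_exactly(self, rng, planted, unit):
        # guard bases break every tiling phase so the planted tract is
        # maximal at exactly its planted coordinates
        guard = "CCAA" if unit == "GT" else "TTCC"
        ctx = random_seq(rng, 400)
        seq = ctx[:200] + guard + planted + guard + ctx[200:]
        start = 200 + len(guard)
        loci = find_tandem_repeats(seq, 1, 6, 20, 5)
        assert len(loci) == 1
        locus = loci[0]
        assert (locus.start, locus.end) == (start, start + len(planted))
        assert locus.copies == len(planted) / len(unit)
        assert locus.unit_len == len(unit)

    def test_impure_planted_repeat_matches_oracle(self, rng):
        seqs = []
        for trial in range(3):
            tract = list("AC" * 30)
            for pos in rng.choice(60, size=3, replace=False):
                tract[pos] = "T"
            ctx = random_seq(rng, 300)
            seqs.append(ctx[:150] + "".join(tract) + ctx[150:])
        for seq in seqs:
            fast = find_tandem_repeats(seq, 1, 4, 20, 5)
            slow = oracle_scan(seq, 1, 4, 20, 5)
            assert [(l.start, l.end, l.unit_len) for l in fast] == slow

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            find_tandem_repeats("ACGT", 0, 6, 8, 2)
        with pytest.raises(ValueError):
            find_tandem_repeats("", 1, 6, 8, 2)
        with pytest.raises(ValueError):
            find_tandem_repeats("ACGTXACGT", 1, 6, 8, 2)

    def test_returned_loci_satisfy_thresholds(self, rng):
        seq = random_seq(rng, 500) + "TTAA" * 12 + random_seq(rng, 500)
        for locus in find_tandem_repeats(seq, 1, 6, 12, 3):
            assert locus.span >= 12
            assert locus.copies >= 3
            assert locus.purity >= 85.0


# ---------------------------------------------------------------------------
# purity
# ---------------------------------------------------------------------------


class TestPurity:
    def test_perfect_repeat(self):
        assert purity_of_region("CA" * 10, "CA") == 100.0

    def test_two_substitutions_of_twenty(self):
        region = list("CA" * 10)
        region[4] = "T"
        region[13] = "G"
        assert purity_of_region("".join(region), "CA") == 90.0

    def test_randomized_regions_match_bruteforce(self, rng):
        for _ in range(25):
            u = int(rng.integers(1, 7))
            unit = random_seq(rng, u)
            copies = int(rng.integers(3, 15))
            region = list(unit * copies)
            for pos in rng.choice(len(region), size=int(rng.integers(0, 5)), replace=False):
                region[pos] = "ACGT"[rng.integers(4)]
            region = "".join(region)
            assert purity_of_region(region, unit) == pytest.approx(
                oracle_purity(region, unit)
            )

    def test_span_shorter_than_unit_rejected(self):
        locus = RepeatLocus(id="x", chrom="c", start=0, end=2, unit_seq="ACG",
                            copies=2, purity=100)
        with pytest.raises(ValueError):
            compute_purity(locus, "AC")


# ---------------------------------------------------------------------------
# printed-coordinate arithmetic
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "start,end,unit_len,copies",
    [
        (45_606_270, 45_606_355, 2, 43),  # GT compound repeat next to a miRNA
        (84_343_323, 84_343_351, 1, 29),  # mononucleotide T run
        (70_151_351, 70_151_390, 2, 20),
        (74_743_332, 74_743_375, 2, 22),
        (84_499_126, 84_499_197, 3, 24),
        (106_184_602, 106_184_641, 2, 20),
        (44_007_461, 44_007_502, 2, 21),
        (45_046_714, 45_046_751, 2, 19),
        (45_386_687, 45_386_738, 2, 26),
        (45_709_592, 45_709_631, 2, 20),
    ],
)
def test_printed_coordinates_imply_printed_copies(start, end, unit_len, copies):
    """1-based inclusive spans of the published X-chromosome loci divide
    exactly into their printed unit lengths and copy numbers."""
    assert copies_from_printed_coords(start, end, unit_len) == copies


# ---------------------------------------------------------------------------
# variability score
# ---------------------------------------------------------------------------


class TestScoreVariability:
    def _locus(self, copies=10.0, purity=100.0, unit="AC"):
        return RepeatLocus(id="v", chrom="c", start=0, end=int(copies * len(unit)),
                           unit_seq=unit, copies=copies, purity=purity)

    def test_monotone_in_copies(self):
        assert score_variability(self._locus(copies=20)) >= score_variability(
            self._locus(copies=10)
        )

    def test_monotone_in_purity(self):
        assert score_variability(self._locus(purity=100)) >= score_variability(
            self._locus(purity=80)
        )

    def test_linear_form_against_independent_evaluation(self, rng):
        coeff = ServCoefficients(intercept=-1.5, log_copies=0.9, purity=1.2,
                                 unit_len=-0.04)
        for _ in range(10):
            copies = float(rng.uniform(2, 50))
            purity = float(rng.uniform(60, 100))
            u = int(rng.integers(1, 10))
            locus = self._locus(copies=copies, purity=purity, unit="A" * u)
            expected = -1.5 + 0.9 * math.log(copies) + 1.2 * purity / 100 - 0.04 * u
            assert score_variability(locus, coeff) == pytest.approx(expected, abs=1e-9)

    def test_default_band_for_variable_dinucleotide(self):
        # a pure 15-copy dinucleotide sits in the highly-variable band
        assert score_variability(self._locus(copies=15)) > 0.8


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------


@pytest.fixture
def gene_model():
    return GeneModel(
        features={
            "chr1": [
                (1000, 1500, "coding", "+"),
                (2000, 2100, "CpG", "+"),
                (3000, 3080, "miRNA", "+"),
                (5000, 6000, "intron", "+"),
            ]
        }
    )


class TestClassifyAnnotation:
    def _locus(self, start, end):
        return RepeatLocus(id="a", chrom="chr1", start=start, end=end,
                           unit_seq="AC", copies=(end - start) / 2, purity=100)

    def test_coding_beats_everything(self, gene_model):
        assert classify_annotation(self._locus(1100, 1150), gene_model)[0] == "coding"

    def test_downstream_of_mirna_is_regulatory(self, gene_model):
        # repeat 65 bp downstream of the miRNA gene end (3080)
        ann, sub = classify_annotation(self._locus(3145, 3231), gene_model)
        assert (ann, sub) == ("regulatory", "downstream")

    def test_intronic_and_intergenic(self, gene_model):
        assert classify_annotation(self._locus(5500, 5550), gene_model)[0] == "intronic"
        assert classify_annotation(self._locus(9000, 9050), gene_model)[0] == "intergenic"

    def test_no_model_features_means_intergenic(self):
        assert classify_annotation(self._locus(10, 60), GeneModel())[0] == "intergenic"


# ---------------------------------------------------------------------------
# target selection
# ---------------------------------------------------------------------------


def _locus(id, annotation, serv, span=400, copies=20.0, unit="AC", gc=0.5, start=0):
    end = start + span
    return RepeatLocus(id=id, chrom="chrX", start=start, end=end, unit_seq=unit,
                       copies=copies, purity=100.0, gc=gc, annotation=annotation,
                       serv=serv)


class TestSelectTargets:
    def test_tier_predicates(self):
        catalog = [
            _locus("coding_ok", "coding", 0.2, span=400, start=0),
            _locus("coding_long", "coding", 0.2, span=501, start=1000),
            _locus("reg_high", "regulatory", 1.2, span=300, start=2000),
            _locus("reg_mid", "regulatory", 0.7, span=900, start=3000),
            _locus("intron_ok", "intronic", 0.9, span=400, copies=16, start=4000),
            _locus("intron_gc", "intronic", 0.9, span=400, copies=16, gc=0.75, start=5000),
            _locus("intergenic_ok", "intergenic", 1.1, span=400, copies=16, start=6000),
            _locus("intergenic_low", "intergenic", 0.9, span=400, copies=16, start=7000),
        ]
        probe_counts = {l.id: 3 for l in catalog}
        out = {l.id: l.group for l in select_targets(
            catalog, GeneModel(), probe_counts,
            SelectionConfig(group5_quota=10, chrom_length=10_000),
        )}
        assert out["coding_ok"] == 1
        assert out["coding_long"] is None
        assert out["reg_high"] == 2
        assert out["reg_mid"] == 3
        assert out["intron_ok"] == 5
        assert out["intron_gc"] is None  # GC 75% violates the 30-70% band
        assert out["intergenic_ok"] == 6
        assert out["intergenic_low"] is None

    def test_near_gene_tier_catches_remaining_regulatory(self):
        xlid = GeneModel(features={"chrX": [(2500, 2600, "gene", "+")]})
        locus = _locus("reg_near", "regulatory", 0.1, span=600, start=2000)
        out = select_targets([locus], xlid, {}, SelectionConfig(chrom_length=10_000))
        assert out[0].group == 4

    def test_probe_availability_gates_tier5(self):
        locus = _locus("intron_ok", "intronic", 0.9, span=400, copies=16, start=0)
        out = select_targets([locus], GeneModel(), {"intron_ok": 2},
                             SelectionConfig(chrom_length=1000))
        assert out[0].group is None

    def test_selection_order_invariant(self, rng):
        catalog = [
            _locus(f"L{i}", ann, serv, span=400, copies=16, start=i * 1000)
            for i, (ann, serv) in enumerate(
                [("coding", 0.5), ("regulatory", 1.5), ("regulatory", 0.6),
                 ("intronic", 1.2), ("intergenic", 1.3), ("intergenic", 0.2)]
            )
        ]
        probe_counts = {l.id: 4 for l in catalog}
        cfg = SelectionConfig(group5_quota=3, chrom_length=6000)
        base = {l.id: l.group for l in select_targets(catalog, GeneModel(), probe_counts, cfg)}
        perm = [catalog[i] for i in rng.permutation(len(catalog))]
        shuffled = {l.id: l.group for l in select_targets(perm, GeneModel(), probe_counts, cfg)}
        assert base == shuffled

    def test_group5_even_thinning_respects_quota(self):
        catalog = [
            _locus(f"I{i}", "intronic", 0.85 + 0.01 * i, span=100, copies=16,
                   start=i * 500)
            for i in range(8)
        ]
        probe_counts = {l.id: 3 for l in catalog}
        out = select_targets(catalog, GeneModel(), probe_counts,
                             SelectionConfig(group5_quota=4, chrom_length=4000))
        chosen = [l for l in out if l.group == 5]
        assert len(chosen) == 4
        # one locus per chromosome bin of 1000 bp
        bins = sorted(l.start // 1000 for l in chosen)
        assert bins == [0, 1, 2, 3]
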