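"""PWM construction, exact p-value DP, scanning and peak annotation."""

import itertools

import numpy as np
import pytest

from polpause import motif_peaks as mp
from polpause.genome_io import GeneModel, Interval
from polpause.synthetic_data import gaga_count_matrix


def brute_force_tail(pwm, lattice_threshold):
    """Enumerate all 4^w words; total background probability of words whose
    lattice score reaches the threshold."""
    total = 0.0
    for word in itertools.product(range(4), repeat=pwm.width):
        q = sum(int(pwm.lattice[b, j]) for j, b in enumerate(word))
        if q >= lattice_threshold:
            total += float(np.prod([pwm.background[b] for b in word]))
    return total


class TestPwmFromCounts:
    def test_stated_formula_instantiation(self):
        counts = np.array([[0.0], [0.0], [10.0], [0.0]])
        pwm = mp.pwm_from_counts(counts, pseudocount=1.0)
        # G probability = (10 + 1*0.25) / (10 + 1)
        assert 2 ** pwm.log_odds[2, 0] * 0.25 == pytest.approx(10.25 / 11)
        assert 2 ** pwm.log_odds[0, 0] * 0.25 == pytest.approx(0.25 / 11)

    def test_uniform_counts_give_zero_log_odds(self):
        pwm = mp.pwm_from_counts(np.full((4, 3), 7.0))
        assert np.allclose(pwm.log_odds, 0.0)

    def test_hand_computed_two_column_matrix(self):
        counts = np.array([[3.0, 0.0], [1.0, 1.0], [0.0, 2.0], [0.0, 1.0]])
        pwm = mp.pwm_from_counts(counts, pseudocount=1.0)
        # column 0: A prob (3 + .25)/5, log2(prob/.25)
        assert pwm.log_odds[0, 0] == pytest.approx(np.log2((3.25 / 5) / 0.25))
        assert pwm.log_odds[2, 1] == pytest.approx(np.log2((2.25 / 5) / 0.25))

    def test_column_probabilities_sum_to_one(self):
        rng = np.random.default_rng(20)
        pwm = mp.pwm_from_counts(rng.integers(0, 40, (4, 6)).astype(float))
        probs = 0.25 * 2.0 ** pwm.log_odds
        assert np.allclose(probs.sum(axis=0), 1.0)


class TestNullDistribution:
    def test_pmf_sums_to_one(self):
        rng = np.random.default_rng(21)
        for _ in range(5):
            pwm = mp.pwm_from_counts(rng.integers(0, 50, (4, 8)).astype(float))
            pmf, _ = pwm.null_pmf
            assert pmf.sum() == pytest.approx(1.0, abs=1e-9)

    def test_width_one_exact_single_letter_tail(self):
        counts = np.array([[8.0], [4.0], [2.0], [1.0]])
        pwm = mp.pwm_from_counts(counts)
        # order of single-letter scores: A > C > G > T
        thr = mp.pwm_score_threshold(pwm, 0.30)
        assert pwm.lattice_pvalue(int(round(thr / pwm.score_step))) == pytest.approx(0.25)

    def test_dp_equals_enumeration_small_widths(self):
        rng = np.random.default_rng(22)
        for _ in range(8):
            w = int(rng.integers(1, 7))
            pwm = mp.pwm_from_counts(rng.integers(0, 30, (4, w)).astype(float))
            alpha = 10.0 ** rng.uniform(-3, -0.5)
            thr = mp.pwm_score_threshold(pwm, alpha)
            thr_lat = int(round(thr / pwm.score_step))
            dp = pwm.lattice_pvalue(thr_lat)
            assert dp == pytest.approx(brute_force_tail(pwm, thr_lat), abs=1e-12)
            assert dp <= alpha
            if thr_lat - 1 > pwm.lattice.min(axis=0).sum():
                assert pwm.lattice_pvalue(thr_lat - 1) > alpha

    def test_alpha_one_gives_minimum_score(self):
        pwm = mp.pwm_from_counts(gaga_count_matrix())
        thr = mp.pwm_score_threshold(pwm, 1.0)
        assert thr == pytest.approx(pwm.lattice.min(axis=0).sum() * pwm.score_step)

    def test_unattainable_alpha_warns(self):
        pwm = mp.pwm_from_counts(np.full((4, 2), 5.0))  # all scores equal 0
        with pytest.warns(UserWarning, match="unattainable"):
            thr = mp.pwm_score_threshold(pwm, 1e-6)
        assert thr > 0


class TestScanSequence:
    def test_all_n_sequence_has_no_hits(self):
        pwm = mp.pwm_from_counts(gaga_count_matrix())
        assert mp.scan_sequence("N" * 200, pwm, 1e-4) == []

    def test_planted_repeat_found_on_plus_strand(self):
        rng = np.random.default_rng(23)
        bg = "".join(rng.choice(list("ACGT"), size=300))
        seq = bg[:150] + "GAGAGAGAGA" + bg[150:]
        pwm = mp.pwm_from_counts(gaga_count_matrix())
        hits = mp.scan_sequence(seq, pwm, 1e-4)
        assert any(h.start == 150 and h.strand == "+" for h in hits)

    def test_strand_symmetry_under_reverse_complement(self):
        rng = np.random.default_rng(24)
        seq = "".join(rng.choice(list("ACGT"), size=400)) + "GAGAGAGAGA" + "CT" * 30
        rc = seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        pwm = mp.pwm_from_counts(gaga_count_matrix())
        hits = mp.scan_sequence(seq, pwm, 1e-4)
        hits_rc = mp.scan_sequence(rc, pwm, 1e-4)
        L, w = len(seq), pwm.width
        mapped = sorted((L - h.start - w, "-" if h.strand == "+" else "+") for h in hits)
        assert mapped == sorted((h.start, h.strand) for h in hits_rc)

    def test_hits_respect_alpha(self):
        rng = np.random.default_rng(25)
        seq = "".join(rng.choice(list("ACGT"), size=5000))
        pwm = mp.pwm_from_counts(gaga_count_matrix())
        for h in mp.scan_sequence(seq, pwm, 1e-2):
            assert h.p <= 1e-2

    def test_brute_force_per_position_equivalence(self):
        """Threshold scanning equals per-word p-value computation (width <= 6)."""
        rng = np.random.default_rng(26)
        counts = rng.integers(0, 30, (4, 5)).astype(float)
        pwm = mp.pwm_from_counts(counts)
        seq = "".join(rng.choice(list("ACGT"), size=800))
        alpha = 0.01
        hits = {(h.start, h.strand) for h in mp.scan_sequence(seq, pwm, alpha)}
        expected = set()
        comp = str.maketrans("ACGT", "TGCA")
        for i in range(len(seq) - pwm.width + 1):
            word = seq[i:i + pwm.width]
            if pwm.lattice_pvalue(pwm.lattice_score_word(word)) <= alpha:
                expected.add((i, "+"))
            if pwm.lattice_pvalue(pwm.lattice_score_word(
                    word.translate(comp)[::-1])) <= alpha:
                expected.add((i, "-"))
        assert hits == expected


class TestPeakAnnotation:
    @pytest.fixture
    def genes(self):
        return [GeneModel("gp", "c", 10_000, 16_000, "+", 15_500),
                GeneModel("gm", "c", 30_000, 36_000, "-", 30_500)]

    def test_promoter_upstream_classification(self, genes):
        # 100bp upstream of the plus-strand TSS at 10_000
        pk = mp.Peak("c", 9_850, 9_950, 9_900)
        assert mp.classify_peak_location(pk, genes) == "promoter"
        # minus-strand upstream is rightward of the TSS at 35_999
        pk2 = mp.Peak("c", 36_050, 36_150, 36_100)
        assert mp.classify_peak_location(pk2, genes) == "promoter"

    def test_gene_body_and_intergenic(self, genes):
        assert mp.classify_peak_location(mp.Peak("c", 12_000, 12_200, 12_100), genes) \
            == "gene_body"
        assert mp.classify_peak_location(mp.Peak("c", 50_000, 50_200, 50_100), genes) \
            == "intergenic"

    def test_promoter_precedence_over_body(self):
        genes = [GeneModel("a", "c", 1_000, 5_000, "+", 4_500),
                 GeneModel("b", "c", 5_100, 9_000, "+", 8_500)]
        # overlaps gene a's body AND gene b's promoter [4600, 5100)
        pk = mp.Peak("c", 4_900, 5_050, 4_950)
        assert mp.classify_peak_location(pk, genes) == "promoter"

    def test_hc_requires_both_criteria(self):
        pk = mp.Peak("c", 100, 300, 200)
        ext = [Interval("c", 250, 400)]
        hit = [mp.MotifHit("c", 150, "+", 10.0, 1e-5)]
        w = 10
        assert mp.designate_hcgaf([pk], ext, hit, w) == [True]
        assert mp.designate_hcgaf([pk], ext, [], w) == [False]
        assert mp.designate_hcgaf([pk], [], hit, w) == [False]
        # hit outside the peak does not count
        outside = [mp.MotifHit("c", 295, "+", 10.0, 1e-5)]
        assert mp.designate_hcgaf([pk], ext, outside, w) == [False]

    def test_hc_monotone_in_external_regions(self):
        rng = np.random.default_rng(27)
        peaks = [mp.Peak("c", s, s + 200, s + 100)
                 for s in rng.integers(0, 50_000, size=20) * 1]
        hits = [mp.MotifHit("c", p.start + 50, "+", 9.0, 1e-5) for p in peaks[::2]]
        ext1 = [Interval("c", p.start, p.end) for p in peaks[:5]]
        ext2 = ext1 + [Interval("c", p.start, p.end) for p in peaks[5:12]]
        f1 = mp.designate_hcgaf(peaks, ext1, hits, 10)
        f2 = mp.designate_hcgaf(peaks, ext2, hits, 10)
        assert all(b or not a for a, b in zip(f1, f2))

    def test_orientation_majority_and_tie(self):
        pk = mp.Peak("c", 0, 1000, 500)

        def h(start, strand):
            return mp.MotifHit("c", start, strand, 8.0, 1e-5)

        hits = [h(10, "+"), h(30, "+"), h(50, "+"), h(70, "-")]
        assert mp.orient_peak(pk, hits, 10) == ("+", False)
        hits2 = [h(10, "+"), h(30, "+"), h(50, "-"), h(70, "-")]
        assert mp.orient_peak(pk, hits2, 10) == ("+", True)
        assert mp.orient_peak(pk, [], 10) == ("+", True)
        hits3 = [h(10, "-"), h(30, "-"), h(50, "+")]
        assert mp.orient_peak(pk, hits3, 10) == ("-", False)
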