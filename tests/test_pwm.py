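import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import brute_force_distribution, brute_force_uniform_counts
from regvar import pwm
from regvar.errors import InvalidBackgroundError


def random_pwm(width: int, seed: int, background=None) -> pwm.PWM:
    rng = np.random.default_rng(seed)
    probs = rng.dirichlet(np.ones(4), size=width)
    kwargs = {} if background is None else {"background": background}
    return pwm.PWM.from_rows(f"rand{seed}", probs, **kwargs)


class TestBuildLogOdds:
    def test_uniform_pwm_gives_zero_matrix(self):
        p = pwm.PWM.from_rows("u", np.full((5, 4), 0.25))
        lom = pwm.build_log_odds(p)
        assert np.allclose(lom.entries, 0.0)
        assert (lom.int_entries == 0).all()

    def test_degenerate_column_closed_form(self):
        # p=1 for A with c=0.1 and uniform background:
        # log2(1.025/0.275) for A, log2(0.025/0.275) for the rest
        p = pwm.PWM.from_rows("d", [[1, 0, 0, 0]])
        lom = pwm.build_log_odds(p, pseudocount_frac=0.1, scale=1000)
        assert lom.entries[0, 0] == pytest.approx(np.log2(1.025 / 0.275))
        assert lom.entries[0, 1] == pytest.approx(np.log2(0.025 / 0.275))
        assert lom.int_entries[0, 0] == 1898
        assert lom.int_entries[0, 1] == -3459

    def test_zero_background_rejected(self):
        p = pwm.PWM.from_rows("b", [[1, 0, 0, 0]], background=(0.5, 0.5, 0, 0))
        with pytest.raises(InvalidBackgroundError):
            pwm.build_log_odds(p)

    @given(st.integers(1, 12), st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_discretization_bound(self, width, seed):
        lom = pwm.build_log_odds(random_pwm(width, seed))
        err = np.abs(lom.entries - lom.int_entries / lom.scale)
        # per-entry rounding error is at most half a grid step, so a window's
        # total error is at most w / (2 * scale)
        assert err.max() <= 0.5 / lom.scale + 1e-12


class TestScoreWindow:
    def test_uniform_pwm_scores_zero(self):
        lom = pwm.build_log_odds(pwm.PWM.from_rows("u", np.full((4, 4), 0.25)))
        assert pwm.score_window(lom, "ACGT") == 0.0
        assert pwm.score_window(lom, "TTTT", "-") == 0.0

    def test_single_position_lookup(self):
        lom = pwm.build_log_odds(pwm.PWM.from_rows("d", [[0.97, 0.01, 0.01, 0.01]]))
        assert pwm.score_window(lom, "A") == pytest.approx(float(lom.entries[0, 0]))
        # minus strand scores the complement: "T" -> "A"
        assert pwm.score_window(lom, "T", "-") == pytest.approx(float(lom.entries[0, 0]))

    def test_palindromic_matrix_strand_symmetric(self):
        rng = np.random.default_rng(3)
        half = rng.dirichlet(np.ones(4), size=3)
        probs = np.vstack([half, half[::-1, ::-1]])  # reverse-complement symmetric
        lom = pwm.build_log_odds(pwm.PWM.from_rows("pal", probs))
        for seed in range(20):
            window = "".join(
                np.random.default_rng(seed).choice(list("ACGT"), size=6)
            )
            assert pwm.score_window(lom, window, "+") == pytest.approx(
                pwm.score_window(lom, window, "-")
            )

    def test_ambiguous_base_rejected(self):
        lom = pwm.build_log_odds(random_pwm(4, 0))
        with pytest.raises(ValueError, match="ambiguous"):
            pwm.score_window(lom, "ACNT")


class TestExactPvalueTable:
    def test_single_position_enumeration(self):
        lom = pwm.build_log_odds(pwm.PWM.from_rows("d", [[1, 0, 0, 0]]))
        dist = pwm.exact_pvalue_table(lom)
        assert dist.pvalue(int(lom.int_entries[0, 0])) == 0.25
        assert dist.pvalue(int(lom.int_entries[0, 1])) == 1.0

    @pytest.mark.parametrize("width,seed", [(4, 1), (5, 2), (6, 3)])
    def test_matches_enumeration_uniform_background(self, width, seed):
        lom = pwm.build_log_odds(random_pwm(width, seed))
        dist = pwm.exact_pvalue_table(lom)
        lo, pmf, survival = brute_force_uniform_counts(lom)
        assert lo == dist.min_score
        assert np.array_equal(pmf, dist.pmf)
        assert np.array_equal(survival, dist.survival)

    def test_matches_enumeration_nonuniform_background(self):
        lom = pwm.build_log_odds(random_pwm(5, 11, background=(0.3, 0.2, 0.2, 0.3)))
        dist = pwm.exact_pvalue_table(lom)
        lo, pmf, survival = brute_force_distribution(lom)
        assert lo == dist.min_score
        assert np.allclose(pmf, dist.pmf, atol=1e-12)
        assert np.allclose(survival, dist.survival, atol=1e-12)

    @given(st.integers(1, 8), st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_normalization_and_monotonicity(self, width, seed):
        lom = pwm.build_log_odds(random_pwm(width, seed))
        dist = pwm.exact_pvalue_table(lom)
        assert dist.pmf.sum() == pytest.approx(1.0, abs=1e-9)
        assert (np.diff(dist.survival) <= 1e-15).all()
        assert dist.survival[0] == pytest.approx(1.0, abs=1e-9)


class TestPvalueThreshold:
    def test_alpha_one_gives_minimum_support(self):
        lom = pwm.build_log_odds(random_pwm(3, 5))
        dist = pwm.exact_pvalue_table(lom)
        support = np.nonzero(dist.pmf > 0)[0]
        assert pwm.pvalue_threshold_score(dist, 1.0) == dist.min_score + support[0]

    def test_single_position_case(self):
        lom = pwm.build_log_odds(pwm.PWM.from_rows("d", [[1, 0, 0, 0]]))
        dist = pwm.exact_pvalue_table(lom)
        assert pwm.pvalue_threshold_score(dist, 0.25) == int(lom.int_entries[0, 0])

    def test_unreachable_alpha_gives_sentinel(self):
        lom = pwm.build_log_odds(pwm.PWM.from_rows("d", [[1, 0, 0, 0]]))
        dist = pwm.exact_pvalue_table(lom)
        assert pwm.pvalue_threshold_score(dist, 0.1) == pwm.NO_PASSING_SCORE


class TestScanSequence:
    def test_planted_consensus_is_top_match(self):
        rng = np.random.default_rng(42)
        p = random_pwm(8, 7)
        lom = pwm.build_log_odds(p)
        dist = pwm.exact_pvalue_table(lom)
        flank = "".join(rng.choice(list("ACGT"), size=30))
        seq = flank + p.consensus() + flank[::-1]
        matches = pwm.scan_sequence(lom, dist, seq, alpha=1.0)
        best = min(matches, key=lambda m: (m.pvalue, -m.score))
        assert best.window_start == 30
        assert best.strand == "+"
        consensus_score = pwm.score_window(lom, p.consensus())
        assert best.score == pytest.approx(consensus_score)

    def test_alpha_one_counts_all_windows(self):
        lom = pwm.build_log_odds(random_pwm(5, 9))
        dist = pwm.exact_pvalue_table(lom)
        seq = "ACGTACGTACGTACGTACGT"
        matches = pwm.scan_sequence(lom, dist, seq, alpha=1.0)
        assert len(matches) == 2 * (len(seq) - 5 + 1)

    def test_n_windows_skipped(self):
        lom = pwm.build_log_odds(random_pwm(5, 9))
        dist = pwm.exact_pvalue_table(lom)
        seq = "ACGTNACGTACGT"
        matches = pwm.scan_sequence(lom, dist, seq, alpha=1.0)
        # 9 window starts, those covering index 4 (starts 0..4) are skipped
        assert len(matches) == 2 * 4

    def test_uniform_pwm_never_matches_below_one(self):
        lom = pwm.build_log_odds(pwm.PWM.from_rows("u", np.full((4, 4), 0.25)))
        dist = pwm.exact_pvalue_table(lom)
        assert pwm.scan_sequence(lom, dist, "ACGTACGTAC", alpha=0.999) == []

    def test_strand_consistency_on_reverse_complement(self):
        p = random_pwm(6, 13)
        lom = pwm.build_log_odds(p)
        dist = pwm.exact_pvalue_table(lom)
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("ACGT"), size=40))
        fwd = pwm.scan_sequence(lom, dist, seq, alpha=1.0)
        rev = pwm.scan_sequence(lom, dist, pwm.reverse_complement(seq), alpha=1.0)
        # a match at (start, strand) mirrors to (L - w - start, other strand)
        mirrored = {
            (len(seq) - 6 - m.window_start, {"+": "-", "-": "+"}[m.strand], round(m.score, 9), m.pvalue)
            for m in rev
        }
        original = {
            (m.window_start, m.strand, round(m.score, 9), m.pvalue) for m in fwd
        }
        assert original == mirrored

    def test_pvalue_monotone_in_score(self):
        lom = pwm.build_log_odds(random_pwm(6, 17))
        dist = pwm.exact_pvalue_table(lom)
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list("ACGT"), size=200))
        matches = pwm.scan_sequence(lom, dist, seq, alpha=1.0)
        ordered = sorted(matches, key=lambda m: m.score)
        # monotone up to the discretization bound: scores separated by more
        # than one grid step per position must not invert their p-values
        bound = lom.width / lom.scale
        for i, a in enumerate(ordered):
            for b in ordered[i + 1 :]:
                if b.score - a.score > bound:
                    assert a.pvalue >= b.pvalue - 1e-12
                    break
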