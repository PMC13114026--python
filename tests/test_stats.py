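"""Gated comparison rule, summary t-tests, and exact Mann-Whitney."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from sevoeeg import ValidationError, gated_compare, mann_whitney_exact, t_from_summary


def brute_force_mw_p(a, b):
    """Label-permutation oracle: two-sided tail of the rank-sum statistic."""
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    n_a = len(a)
    obs = ranks[:n_a].sum()
    mu = n_a * (len(pooled) + 1) / 2.0
    sums = [
        sum(combo) for combo in itertools.combinations(ranks, n_a)
    ]
    extreme = [s for s in sums if abs(s - mu) >= abs(obs - mu) - 1e-9]
    return len(extreme) / len(sums)


class TestMannWhitneyExact:
    def test_separated_samples(self):
        res = mann_whitney_exact([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(0.1)  # 2 of C(6,3)=20 orderings

    def test_small_samples_refused(self):
        with pytest.raises(ValidationError):
            mann_whitney_exact([1.0], [2.0, 3.0, 4.0])

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = rng.normal(size=rng.integers(3, 8))
            b = rng.normal(loc=rng.uniform(-1, 1), size=rng.integers(3, 8))
            ours = mann_whitney_exact(a, b)
            ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
            assert ours.p_value == pytest.approx(ref.pvalue, abs=1e-12)
            assert ours.statistic == pytest.approx(ref.statistic)

    def test_matches_permutation_oracle_with_ties(self):
        rng = np.random.default_rng(1)
        for _ in range(15):
            n_a, n_b = rng.integers(3, 7), rng.integers(3, 7)
            a = rng.integers(0, 4, size=n_a).astype(float)  # heavy ties
            b = rng.integers(0, 4, size=n_b).astype(float)
            ours = mann_whitney_exact(a, b)
            assert ours.p_value == pytest.approx(brute_force_mw_p(a, b), abs=1e-12)

    def test_symmetric_under_group_swap(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=5), rng.normal(size=7)
        assert mann_whitney_exact(a, b).p_value == pytest.approx(
            mann_whitney_exact(b, a).p_value, abs=1e-12
        )

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(size=5), rng.normal(size=6)
        p1 = mann_whitney_exact(a, b).p_value
        p2 = mann_whitney_exact(np.exp(a), np.exp(b)).p_value
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_oversize_falls_back_with_note(self):
        rng = np.random.default_rng(3)
        res = mann_whitney_exact(rng.normal(size=13), rng.normal(size=13))
        assert "approximation" in res.note


class TestTFromSummary:
    def test_equal_means(self):
        res = t_from_summary(1.0, 0.2, 10, 1.0, 0.2, 10)
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1.0)
        assert res.df == 18

    def test_immobility_endpoint_summaries(self):
        """Printed MAC summaries (2.67+/-0.05 vs 2.68+/-0.10, n=10/10)
        reproduce the published p ~ 0.785 up to summary rounding."""
        res = t_from_summary(2.67, 0.05, 10, 2.68, 0.10, 10)
        assert res.p_value == pytest.approx(0.785, abs=0.01)

    def test_righting_endpoint_summaries(self):
        res = t_from_summary(1.65, 0.13, 8, 1.10, 0.10, 8)
        assert res.p_value < 0.001

    def test_invalid_inputs(self):
        with pytest.raises(ValidationError):
            t_from_summary(1, 0.0, 10, 1, 0.1, 10)
        with pytest.raises(ValidationError):
            t_from_summary(1, 0.1, 1, 1, 0.1, 10)

    def test_agrees_with_gated_t_branch_on_raw_samples(self):
        """Feeding raw samples with exactly the summary moments through the
        gated rule's t branch gives the same statistic and p."""
        rng = np.random.default_rng(4)
        for _ in range(5):
            a = rng.normal(size=10)
            b = rng.normal(size=12)
            a = (a - a.mean()) / a.std(ddof=1) * 0.7 + 3.0
            b = (b - b.mean()) / b.std(ddof=1) * 0.9 + 3.2
            summary = t_from_summary(3.0, 0.7, 10, 3.2, 0.9, 12)
            raw = sps.ttest_ind(a, b, equal_var=True)
            assert summary.statistic == pytest.approx(raw.statistic)
            assert summary.p_value == pytest.approx(raw.pvalue)


class TestGatedCompare:
    def test_identical_normalish_samples(self):
        a = np.array([1.0, 1.4, 0.8, 1.1, 0.9, 1.2, 1.05, 0.95, 1.3, 0.7])
        res = gated_compare(a, a.copy())
        assert res.test_name == "student_t"
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)
        assert res.gate.all_pass

    def test_constant_sample_falls_to_mann_whitney(self):
        res = gated_compare([1.0] * 5, [1.0, 1.1, 0.9, 1.2, 0.8])
        assert res.test_name == "mann_whitney"
        assert not res.gate.normal_a

    def test_exponential_samples_select_mann_whitney_mostly(self):
        """Shapiro has decent power against exponential data at n=10."""
        rng = np.random.default_rng(5)
        picks = [
            gated_compare(rng.exponential(size=10), rng.exponential(size=10)).test_name
            for _ in range(100)
        ]
        assert picks.count("mann_whitney") > 60

    def test_normal_samples_select_t_mostly(self):
        """Under a normal null each gate passes ~95%, so the t branch is
        taken in roughly (0.95)^3 of replicates."""
        rng = np.random.default_rng(6)
        picks = [
            gated_compare(rng.normal(size=10), rng.normal(size=10)).test_name
            for _ in range(400)
        ]
        frac_t = picks.count("student_t") / len(picks)
        assert frac_t == pytest.approx(0.95**3, abs=0.06)

    def test_small_n_rejected(self):
        with pytest.raises(ValidationError):
            gated_compare([1.0, 2.0], [1.0, 2.0, 3.0])

    def test_unequal_variance_blocks_t(self):
        rng = np.random.default_rng(7)
        a = rng.normal(scale=0.1, size=12)
        b = rng.normal(scale=10.0, size=12)
        res = gated_compare(a, b)
        assert not res.gate.equal_var
        assert res.test_name == "mann_whitney"

    def test_levene_variant_runs(self):
        rng = np.random.default_rng(8)
        res = gated_compare(
            rng.normal(size=10), rng.normal(size=10), variance_test="levene"
        )
        assert res.test_name in ("student_t", "mann_whitney")
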