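"""Normality gating, correlations, BH adjustment and Kruskal-Wallis."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from wavecline.associations import (
    bh_adjust,
    correlate,
    kruskal_wallis,
    normality_gate,
    pairwise_residual_correlations,
    residual_correlation_table,
)


def brute_force_bh(p):
    """Step-up definition computed directly: adj_i = min_{j>=i} p_(j) m / j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj_sorted = np.minimum.accumulate(
        (p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj_sorted, 1.0)
    return out


class TestNormalityGate:
    def test_gaussian_sample_passes_to_pearson(self):
        x = np.random.default_rng(5).normal(size=75)
        assert normality_gate(x) == "pearson"

    def test_lognormal_sample_routes_to_spearman(self):
        x = np.exp(np.random.default_rng(5).normal(size=75) * 1.5)
        assert normality_gate(x) == "spearman"

    def test_too_small_sample_errors(self):
        with pytest.raises(ValueError):
            normality_gate([1.0, 2.0])

    def test_constant_vector_errors(self):
        with pytest.raises(ValueError):
            normality_gate(np.ones(10))


class TestCorrelate:
    @pytest.mark.parametrize("method", ["pearson", "spearman"])
    def test_identity_gives_one(self, method, rng):
        x = rng.normal(size=30)
        assert correlate(x, x, method).coefficient == pytest.approx(1.0)

    def test_monotone_transform(self, rng):
        x = rng.normal(size=50)
        y = np.exp(x)
        assert correlate(x, y, "spearman").coefficient == pytest.approx(1.0)
        assert correlate(x, y, "pearson").coefficient < 1.0

    def test_hand_rank_computation(self):
        """x=(1..5), y=(2,1,4,3,5): d=(-1,1,-1,1,0), sum d^2=4 -> rho = 0.8."""
        res = correlate([1, 2, 3, 4, 5], [2, 1, 4, 3, 5], "spearman")
        assert res.coefficient == pytest.approx(1 - 6 * 4 / (5 * 24), abs=1e-12)
        assert res.coefficient == pytest.approx(0.8)

    def test_spearman_equals_pearson_on_ranks(self, rng):
        x = rng.normal(size=40)
        y = rng.normal(size=40)  # continuous draws: tie-free a.s.
        rho = correlate(x, y, "spearman").coefficient
        r_ranks = correlate(stats.rankdata(x), stats.rankdata(y),
                            "pearson").coefficient
        assert rho == pytest.approx(r_ranks, abs=1e-12)

    def test_errors(self):
        with pytest.raises(ValueError):
            correlate([1, 2, 3], [1, 2], "pearson")
        with pytest.raises(ValueError):
            correlate([1, 1, 1], [1, 2, 3], "pearson")


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_all_equal_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.2] * 5), [0.2] * 5)

    def test_matches_brute_force_step_up(self, rng):
        for _ in range(20):
            p = rng.uniform(0, 1, size=rng.integers(2, 15))
            np.testing.assert_allclose(bh_adjust(p), brute_force_bh(p), atol=1e-12)

    def test_worked_example(self):
        p = [0.01, 0.02, 0.03, 0.04, 0.05, 0.9]
        np.testing.assert_allclose(bh_adjust(p), brute_force_bh(p), atol=1e-12)

    def test_monotone_in_raw_p(self, rng):
        p = rng.uniform(0, 1, 12)
        adj = bh_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)
        assert np.all(adj >= p - 1e-12) and np.all(adj <= 1 + 1e-12)

    def test_invalid_p_errors(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestPairwise:
    def test_identical_columns_and_symmetry(self, rng):
        a = rng.normal(size=40)
        df = pd.DataFrame({"t1": a, "t2": a, "t3": rng.normal(size=40)})
        out = pairwise_residual_correlations(df)
        coef = out["coefficient"]
        assert coef.loc["t1", "t2"] == pytest.approx(1.0)
        np.testing.assert_allclose(coef.values, coef.values.T)
        np.testing.assert_allclose(np.diag(coef.values), 1.0)

    def test_independent_columns_stay_weak(self):
        """Mean |coefficient| across null simulations is far from 1."""
        vals = []
        for seed in range(100):
            r = np.random.default_rng(seed)
            df = pd.DataFrame({"a": r.normal(size=75), "b": r.normal(size=75)})
            vals.append(abs(pairwise_residual_correlations(df)["coefficient"]
                            .loc["a", "b"]))
        assert np.mean(vals) < 0.25


class TestKruskalWallis:
    def test_identical_groups_give_zero(self):
        res = kruskal_wallis([[1, 2, 3], [1, 2, 3]])
        assert res.statistic == pytest.approx(0.0)

    def test_hand_evaluation(self):
        """Groups {1,2,3},{4,5,6}: H = (12/42)(3*4 + 3*25) - 21 = 27/7."""
        res = kruskal_wallis([[1, 2, 3], [4, 5, 6]])
        assert res.statistic == pytest.approx(27.0 / 7.0, abs=1e-9)
        assert res.df == 1

    def test_monotone_transform_invariance(self, rng):
        a, b = rng.normal(size=12), rng.normal(1.0, 1.0, size=15)
        base = kruskal_wallis([a, b])
        trans = kruskal_wallis([np.exp(a), np.exp(b)])
        assert trans.statistic == pytest.approx(base.statistic, abs=1e-9)

    def test_tied_ladder_statistic_matches_rank_formula(self):
        """H on heavily tied ladder data equals the tie-corrected rank formula."""
        a = np.array([0.75, 0.75, 1.42, 1.88, 2.69])
        b = np.array([0.75, 1.42, 1.42, 1.88, 1.88, 2.54, 2.69])
        pooled = np.concatenate([a, b])
        ranks = stats.rankdata(pooled)
        n = len(pooled)
        rbar_a, rbar_b = ranks[:5].mean(), ranks[5:].mean()
        h = 12 / (n * (n + 1)) * (5 * rbar_a**2 + 7 * rbar_b**2) - 3 * (n + 1)
        _, counts = np.unique(pooled, return_counts=True)
        tie = 1 - np.sum(counts**3 - counts) / (n**3 - n)
        assert kruskal_wallis([a, b]).statistic == pytest.approx(h / tie, abs=1e-10)

    @pytest.mark.parametrize("a,b", [
        ([1, 3, 5, 7, 9], [2, 4, 6, 8, 10, 11, 12]),
        ([1, 2, 3, 4, 5], [6, 7, 8, 9, 10, 11, 12]),
    ])
    def test_p_matches_permutation_null(self, a, b, rng):
        """Chi-square p tracks a 1e4-shuffle permutation p on small instances.

        The chi-square reference is asymptotic, so agreement holds up to a
        small approximation allowance on top of Monte-Carlo error (heavily
        tied tiny samples deviate more; see the tied-ladder statistic test).
        """
        a, b = np.array(a, float), np.array(b, float)
        res = kruskal_wallis([a, b])
        pooled = np.concatenate([a, b])
        n_shuffles = 10_000
        count = 0
        for _ in range(n_shuffles):
            perm = rng.permutation(pooled)
            h = kruskal_wallis([perm[:len(a)], perm[len(a):]]).statistic
            count += h >= res.statistic - 1e-12
        perm_p = count / n_shuffles
        mc_err = 3 * np.sqrt(max(perm_p * (1 - perm_p), 1e-6) / n_shuffles)
        assert res.p_value == pytest.approx(perm_p, abs=mc_err + 0.05)

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2], []])


def test_residual_correlation_table_structure(rng):
    n = 60
    sfr = rng.normal(size=n)
    df = pd.DataFrame({
        "RFA": 0.5 * sfr + rng.normal(size=n),
        "SA": rng.normal(size=n),
        "SFR": sfr,
    })
    df.loc[df.index[:5], "RFA"] = np.nan  # missing foot areas drop pairwise
    table = residual_correlation_table(df, response="SFR")
    assert set(table["trait"]) == {"RFA", "SA"}
    assert (table.set_index("trait").loc["RFA", "n"]) == n - 5
    assert ((table["p_adjusted"] >= table["p_value"] - 1e-12).all())
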