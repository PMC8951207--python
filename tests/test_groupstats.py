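"""Group statistics: t tests, effect sizes, FDR, threshold averaging, NBS."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sst

from plinet.groupstats import (
    average_significant, cohens_d_from_t, cohens_d_pooled, compare_topology,
    fdr_bh, nbs_test, ttest_ind, wilcoxon_rank_sum,
)
from plinet.network import TopologyCurve, default_sparsity_grid


def make_curves(values, metric="eglobal", subjects=None):
    """TopologyCurves over the default grid from a (subjects x 36) array."""
    grid = default_sparsity_grid()
    values = np.asarray(values, dtype=float)
    out = []
    for s in range(values.shape[0]):
        row = values[s]
        metrics = {m: np.zeros(grid.size) for m in ("lp", "cc", "eglobal", "elocal")}
        metrics[metric] = row
        # keep untested metrics non-degenerate so their t-tests are defined
        rng = np.random.default_rng(1000 + s)
        for m in metrics:
            if m != metric:
                metrics[m] = rng.normal(1.0, 0.1, grid.size)
        out.append(TopologyCurve(
            grid, metrics["lp"], metrics["cc"], metrics["eglobal"], metrics["elocal"],
            np.zeros(grid.size, dtype=bool), band="beta2",
            subject=(subjects[s] if subjects else f"S{s}"),
        ))
    return out


class TestTTest:
    def test_identical_groups(self):
        t, df, p = ttest_ind([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == pytest.approx(1.0)
        assert df == 4

    def test_hand_computed_pooled_t(self):
        # means 2 vs 5, pooled sd 1, se = sqrt(2/3): t = -3/0.8165 = -3.674
        t, df, p = ttest_ind([1, 2, 3], [4, 5, 6])
        assert t == pytest.approx(-3.674, abs=5e-4)
        assert df == 4
        assert p == pytest.approx(0.0214, abs=5e-4)

    def test_swap_antisymmetry(self, rng):
        a, b = rng.normal(0, 1, (2, 10))
        t1, _, p1 = ttest_ind(a, b)
        t2, _, p2 = ttest_ind(b, a)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_zero_pooled_variance_with_unequal_means(self):
        with pytest.raises(ValueError, match="variance"):
            ttest_ind([1.0, 1.0], [2.0, 2.0])


class TestCohensD:
    @pytest.mark.parametrize("t,df,d", [
        (2.25, 61, 0.58), (3.07, 61, 0.79), (3.02, 61, 0.77),
        (-2.84, 61, 0.73), (-2.81, 61, 0.72),
    ])
    def test_equal_n_conversion_on_reported_pairs(self, t, df, d):
        assert round(cohens_d_from_t(t, df), 2) == d

    def test_zero_t_gives_zero(self):
        assert cohens_d_from_t(0.0, 10) == 0.0

    def test_nonpositive_df_rejected(self):
        with pytest.raises(ValueError):
            cohens_d_from_t(1.0, 0)

    def test_pooled_d_hand_formula_and_conversion_ratio(self, rng):
        a = rng.normal(0.0, 1.0, 15)
        b = rng.normal(0.8, 1.0, 15)
        na = a.size
        sp = np.sqrt(((na - 1) * a.var(ddof=1) + (na - 1) * b.var(ddof=1)) / (2 * na - 2))
        assert cohens_d_pooled(a, b) == pytest.approx((a.mean() - b.mean()) / sp)
        # the 2t/sqrt(df) conversion differs from pooled d by sqrt(1 - 1/n) at equal n
        t, df, _ = ttest_ind(a, b)
        ratio = abs(cohens_d_pooled(a, b)) / cohens_d_from_t(t, df)
        assert ratio == pytest.approx(np.sqrt(1 - 1 / na), rel=1e-10)


class TestFdrBH:
    def test_hand_stepup(self):
        np.testing.assert_allclose(fdr_bh([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_all_ones_unchanged(self):
        np.testing.assert_allclose(fdr_bh([1.0, 1.0]), [1.0, 1.0])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(fdr_bh([0.2]), [0.2])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_bh([0.5, 1.5])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=30))
    def test_never_decreases_and_order_invariant(self, ps):
        ps = np.asarray(ps)
        adj = fdr_bh(ps)
        assert np.all(adj >= ps - 1e-12)
        perm = np.random.default_rng(0).permutation(ps.size)
        np.testing.assert_allclose(fdr_bh(ps[perm]), adj[perm], atol=1e-12)


class TestWilcoxon:
    def test_matches_scipy_exact(self, rng):
        a = rng.normal(0, 1, 10)
        b = rng.normal(1, 1, 12)
        u, p = wilcoxon_rank_sum(a, b)
        ref = sst.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        assert p == pytest.approx(ref.pvalue)


class TestAverageSignificant:
    def test_planted_difference_recovered_with_same_sign(self, rng):
        base = np.linspace(0.3, 0.7, 36)
        va = base + 0.10 + rng.normal(0, 0.02, (12, 36))
        vb = base + rng.normal(0, 0.02, (12, 36))
        res = average_significant(make_curves(va), make_curves(vb), "eglobal")
        assert res is not None
        assert res.t > 0 and res.p < 0.01
        assert res.significant_sparsities.size > 30

    def test_identical_groups_usually_empty(self):
        empty = 0
        runs = 40
        for s in range(runs):
            rng = np.random.default_rng(s)
            va = rng.normal(0.5, 0.05, (10, 36))
            vb = rng.normal(0.5, 0.05, (10, 36))
            if average_significant(make_curves(va), make_curves(vb), "eglobal") is None:
                empty += 1
        assert empty >= int(0.90 * runs)

    def test_single_significant_threshold_average_is_that_value(self, rng):
        va = np.tile(0.5, (10, 36)) + rng.normal(0, 0.05, (10, 36))
        vb = va + rng.normal(0, 0.01, (10, 36))
        va[:, 17] = 0.9 + rng.normal(0, 0.01, 10)   # huge difference at one sparsity
        vb[:, 17] = 0.1 + rng.normal(0, 0.01, 10)
        res = average_significant(make_curves(va), make_curves(vb), "eglobal")
        assert res is not None
        np.testing.assert_allclose(res.significant_sparsities, [default_sparsity_grid()[17]])
        np.testing.assert_allclose(res.values_a, va[:, 17])

    def test_compare_topology_has_fdr_within_metric(self, rng):
        va = rng.normal(0.5, 0.05, (8, 36))
        vb = rng.normal(0.5, 0.05, (8, 36))
        frame = compare_topology(make_curves(va), make_curves(vb))
        assert len(frame) == 4 * 36
        assert (frame.p_fdr >= frame.p - 1e-12).all()


def _pli_stack(rng, n, bump_edges=(), bump=0.0):
    mats = []
    for _ in range(n):
        w = rng.uniform(0.1, 0.4, (20, 20))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0.0)
        for i, j in bump_edges:
            w[i, j] += bump
            w[j, i] = w[i, j]
        mats.append(w)
    return mats


class TestNbs:
    PLANTED = [(0, 1), (0, 2), (0, 3), (0, 4), (0, 5)]  # 5-edge star: connected

    def test_planted_component_recovered(self, rng):
        a = _pli_stack(rng, 12, self.PLANTED, 0.3)
        b = _pli_stack(rng, 12)
        res = nbs_test(a, b, primary_t=3.0, n_perm=200, seed=3)
        assert len(res.components) >= 1
        top = set(res.components[0])
        assert set(self.PLANTED) <= top
        assert res.component_p[0] <= 0.05

    def test_deterministic_under_seed(self, rng):
        a = _pli_stack(rng, 6, self.PLANTED, 0.2)
        b = _pli_stack(rng, 6)
        r1 = nbs_test(a, b, n_perm=150, seed=9)
        r2 = nbs_test(a, b, n_perm=150, seed=9)
        np.testing.assert_array_equal(r1.component_p, r2.component_p)
        assert r1.components == r2.components

    def test_too_few_permutations_rejected(self, rng):
        a = _pli_stack(rng, 4)
        b = _pli_stack(rng, 4)
        with pytest.raises(ValueError, match="n_perm"):
            nbs_test(a, b, n_perm=0)

    def test_degenerate_constant_edge_rejected(self, rng):
        a = _pli_stack(rng, 4)
        b = _pli_stack(rng, 4)
        for m in a + b:
            m[2, 3] = m[3, 2] = 0.5
        with pytest.raises(ValueError, match="degenerate"):
            nbs_test(a, b)

    def test_null_false_positive_rate_controlled(self):
        hits = 0
        runs = 60
        for s in range(runs):
            rng = np.random.default_rng(10_000 + s)
            a = _pli_stack(rng, 10)
            b = _pli_stack(rng, 10)
            res = nbs_test(a, b, primary_t=2.0, n_perm=100, seed=s)
            if res.component_p.size and res.component_p.min() <= 0.05:
                hits += 1
        # expected 5% of 60 = 3; allow 2 SE of slack
        assert hits <= 60 * (0.05 + 2 * np.sqrt(0.05 * 0.95 / 60))
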