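"""PLS-DA, VIP, and the VIP > 1 & p < 0.05 metabolite screen."""

import numpy as np
import pandas as pd
import pytest
from sklearn.cross_decomposition import PLSRegression

from plinet.metabolomics import (
    MetaboliteTable, pls_da, preprocess_intensities, univariate_screen, vip,
)
from plinet.synth import SynthCohortSpec, contrast_cohort_spec, generate_cohort


def random_table(rng, n_a=10, n_b=10, p=20, lfc=0.0, affected=()):
    logx = rng.normal(8.0, 0.5, (n_a + n_b, p))
    for f in affected:
        logx[:n_a, f] += lfc
    ids = [f"S{i}" for i in range(n_a + n_b)]
    groups = pd.Series(["A"] * n_a + ["B"] * n_b, index=ids)
    return MetaboliteTable(
        pd.DataFrame(np.exp(logx), index=ids, columns=[f"M{j}" for j in range(p)]),
        groups,
    )


class TestMetaboliteTable:
    def test_nonpositive_intensities_rejected(self, rng):
        tab = random_table(rng)
        bad = tab.intensities.copy()
        bad.iloc[0, 0] = 0.0
        with pytest.raises(ValueError, match="positive"):
            MetaboliteTable(bad, tab.groups)

    def test_more_than_two_groups_rejected(self, rng):
        tab = random_table(rng)
        g = tab.groups.copy()
        g.iloc[0] = "C"
        with pytest.raises(ValueError, match="binary"):
            MetaboliteTable(tab.intensities, g)


class TestPreprocess:
    def test_unit_variance_scaling(self, rng):
        x = preprocess_intensities(random_table(rng))
        np.testing.assert_allclose(x.std(axis=0, ddof=1), 1.0, atol=1e-9)
        np.testing.assert_allclose(x.mean(axis=0), 0.0, atol=1e-9)

    def test_scale_none_centres_only(self, rng):
        tab = random_table(rng)
        x = preprocess_intensities(tab, scale="none")
        np.testing.assert_allclose(x.mean(axis=0), 0.0, atol=1e-9)
        raw_sd = np.log10(tab.intensities).std(axis=0, ddof=1)
        np.testing.assert_allclose(x.std(axis=0, ddof=1), raw_sd, atol=1e-9)

    def test_constant_feature_flagged_zero(self, rng):
        tab = random_table(rng)
        raw = tab.intensities.copy()
        raw["M0"] = 5.0
        x = preprocess_intensities(MetaboliteTable(raw, tab.groups))
        assert x.attrs["constant"] == ["M0"]
        np.testing.assert_allclose(x["M0"], 0.0, atol=1e-12)


class TestPlsDa:
    def test_scores_and_weights_match_sklearn(self, rng):
        tab = random_table(rng, lfc=0.8, affected=(0, 3, 7))
        model = pls_da(tab, n_components=2)
        x = preprocess_intensities(tab).to_numpy()
        y = np.where(tab.group_mask(), 1.0, -1.0)
        sk = PLSRegression(n_components=2, scale=False).fit(x, y - y.mean())
        for a in range(2):
            assert abs(np.corrcoef(model.scores[:, a], sk.x_scores_[:, a])[0, 1]) > 0.999
            assert abs(np.corrcoef(model.weights[:, a], sk.x_weights_[:, a])[0, 1]) > 0.999

    def test_single_separating_feature_dominates_first_weight(self, rng):
        y = np.array([1.0] * 10 + [-1.0] * 10)
        x = 0.05 * rng.standard_normal((20, 10))
        x[:, 4] = y  # the only feature carrying the class
        xdf = pd.DataFrame(x, columns=[f"M{j}" for j in range(10)])
        model = pls_da(xdf, n_components=1, y=y)
        w = model.weights[:, 0]
        assert abs(w[4]) / np.linalg.norm(w) > 0.99

    def test_class_orthogonal_data_explains_nothing(self, rng):
        y = np.array([1.0] * 8 + [-1.0] * 8)
        x = rng.standard_normal((16, 6))
        x -= np.outer(y, y @ x) / (y @ y)  # project y out of every column
        xdf = pd.DataFrame(x, columns=[f"M{j}" for j in range(6)])
        model = pls_da(xdf, n_components=2, y=y)
        assert model.explained_y_variance == pytest.approx(0.0, abs=1e-20)
        with pytest.raises(ValueError, match="VIP"):
            vip(model)

    def test_deterministic(self, rng):
        tab = random_table(rng, lfc=0.5, affected=(1,))
        m1 = pls_da(tab)
        m2 = pls_da(tab)
        np.testing.assert_array_equal(m1.weights, m2.weights)

    def test_orthogonal_correction_concentrates_first_component(self, rng):
        # class signal on one feature, strong class-orthogonal structure on others
        y = np.array([1.0] * 12 + [-1.0] * 12)
        ortho = rng.standard_normal(24)
        ortho -= ortho @ y / (y @ y) * y
        x = 0.3 * rng.standard_normal((24, 10))
        x[:, 0] += 0.8 * y
        for j in range(1, 6):
            x[:, j] += 2.0 * ortho
        xdf = pd.DataFrame(x, columns=[f"M{j}" for j in range(10)])
        plain = pls_da(xdf, 2, y=y)
        osc = pls_da(xdf, 2, y=y, orthogonal_correction=True)
        share = lambda m: m.ssy[0] / m.ssy.sum()
        assert share(osc) > share(plain)
        assert share(osc) > 0.95


class TestVip:
    def test_mean_square_is_one(self, rng):
        model = pls_da(random_table(rng, lfc=0.6, affected=(0, 5)), n_components=2)
        v = vip(model)
        assert (v ** 2).mean() == pytest.approx(1.0, abs=1e-8)

    def test_single_informative_feature_approaches_sqrt_p(self, rng):
        p = 16
        y = np.array([1.0] * 10 + [-1.0] * 10)
        x = rng.standard_normal((20, p)) * 0.01
        x[:, 2] = y
        xdf = pd.DataFrame(x, columns=[f"M{j}" for j in range(p)])
        v = vip(pls_da(xdf, n_components=1, y=y))
        assert v.iloc[2] == pytest.approx(np.sqrt(p), rel=0.01)

    def test_exchangeable_features_all_one(self):
        y = np.array([1.0] * 6 + [-1.0] * 6)
        x = np.tile(y[:, None], (1, 5)) + 0.0
        xdf = pd.DataFrame(x, columns=[f"M{j}" for j in range(5)])
        v = vip(pls_da(xdf, n_components=1, y=y))
        np.testing.assert_allclose(v, 1.0, atol=1e-10)


class TestScreen:
    def test_planted_features_recovered(self):
        hits = []
        for seed in range(7):
            spec = contrast_cohort_spec(20, 20, seed=seed)
            cohort = generate_cohort(spec, make_recordings=False)
            screen = univariate_screen(cohort.table)
            planted = {cohort.table.feature_names[i] for i in spec.affected_features}
            hits.append(len(planted & set(screen.selected)))
        assert np.median(hits) >= 4

    def test_null_table_selects_few(self):
        rates = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            tab = random_table(rng, n_a=20, n_b=20, p=50)
            screen = univariate_screen(tab)
            rates.append(screen.frame["selected"].mean())
        assert np.mean(rates) <= 0.10

    def test_fold_change_of_unshifted_feature_near_one(self):
        fcs = []
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            tab = random_table(rng, n_a=20, n_b=20, p=10)
            fcs.append(univariate_screen(tab).frame["fold_change"].to_numpy())
        assert np.abs(np.mean(fcs) - 1.0) < 0.1

    def test_fold_change_direction_matches_planted_sign(self):
        spec = contrast_cohort_spec(20, 20, seed=5)
        cohort = generate_cohort(spec, make_recordings=False)
        screen = univariate_screen(cohort.table)
        planted = [cohort.table.feature_names[i] for i in spec.affected_features]
        assert (screen.frame.loc[planted, "fold_change"] > 1.0).all()

    def test_selection_rule_is_vip_and_raw_p(self, rng):
        tab = random_table(rng, n_a=15, n_b=15, p=30, lfc=1.2, affected=(0, 1))
        screen = univariate_screen(tab)
        f = screen.frame
        np.testing.assert_array_equal(
            f["selected"].to_numpy(), ((f["vip"] > 1) & (f["p"] < 0.05)).to_numpy()
        )
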