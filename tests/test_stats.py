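import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from tvdmri.dti import ScalarMap
from tvdmri.stats import (
    bonferroni,
    correlate,
    erode_mask,
    fa_threshold_analysis,
    masked_histogram,
    rm_anova,
    roi_mean,
)


# ----------------------------------------------------------------------
# independent GLM oracle: plain numpy least squares, full-vs-reduced F
# ----------------------------------------------------------------------

def _ols_rss(X, y):
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r), np.linalg.matrix_rank(X)


def glm_f_test(y, full_cols, drop_cols):
    """F for dropping columns from a design, built without statsmodels."""
    X_full = np.column_stack(full_cols)
    X_red = np.column_stack([c for i, c in enumerate(full_cols) if i not in drop_cols])
    rss_f, rank_f = _ols_rss(X_full, y)
    rss_r, rank_r = _ols_rss(X_red, y)
    df1 = rank_f - rank_r
    df2 = len(y) - rank_f
    f = ((rss_r - rss_f) / df1) / (rss_f / df2)
    return f, df1, df2, float(sps.f.sf(f, df1, df2))


def random_roi_table(rng, n_per_group=(9, 8, 7)):
    rows = []
    for g, n in zip(("HC", "RRMS", "PPMS"), n_per_group):
        for i in range(n):
            age = rng.uniform(25, 65)
            sex = "F" if rng.random() < 0.5 else "M"
            base = rng.normal(0.8, 0.05)
            for hemi in ("left", "right"):
                rows.append(
                    {
                        "id": f"{g}{i}",
                        "group": g,
                        "age": age,
                        "sex": sex,
                        "hemisphere": hemi,
                        "roi": "NAWM",
                        "uFA": base + rng.normal(0, 0.02),
                    }
                )
    return pd.DataFrame(rows)


def oracle_mixed_anova(df, metric="uFA"):
    """Split-plot decomposition computed directly with numpy."""
    wide = df.pivot_table(
        index=["id", "group", "age", "sex"], columns="hemisphere", values=metric
    ).reset_index()
    y_b = wide[["left", "right"]].mean(axis=1).to_numpy()
    y_w = (wide["left"] - wide["right"]).to_numpy()
    age = (wide["age"] - wide["age"].mean()).to_numpy()
    sex = (wide["sex"] == "F").astype(float)
    sex = (sex - sex.mean()).to_numpy()
    groups = sorted(wide["group"].unique())
    # sum-to-zero group coding
    gcols = []
    for g in groups[:-1]:
        col = (wide["group"] == g).astype(float).to_numpy()
        col = col - (wide["group"] == groups[-1]).astype(float).to_numpy()
        gcols.append(col)
    ones = np.ones(len(wide))
    full = [ones] + gcols + [age, sex]
    drop = set(range(1, 1 + len(gcols)))
    out = {}
    out["group"] = glm_f_test(y_b, full, drop)
    out["hemisphere:group"] = glm_f_test(y_w, full, drop)
    out["hemisphere"] = glm_f_test(y_w, full, {0})
    return out


class TestErosion:
    def test_single_voxel_vanishes(self):
        m = np.zeros((3, 3, 3), dtype=bool)
        m[1, 1, 1] = True
        assert not erode_mask(m, 1).any()

    def test_cube_erosion_count(self):
        """5^3 solid cube loses its faces: 3^3 = 27 voxels remain."""
        m = np.zeros((7, 7, 7), dtype=bool)
        m[1:6, 1:6, 1:6] = True
        out = erode_mask(m, 1)
        assert out.sum() == 27
        # brute-force oracle: a voxel survives iff all 6 neighbours are set
        expect = np.zeros_like(m)
        for i, j, k in np.argwhere(m):
            nbrs = [(i - 1, j, k), (i + 1, j, k), (i, j - 1, k),
                    (i, j + 1, k), (i, j, k - 1), (i, j, k + 1)]
            expect[i, j, k] = all(m[a, b, c] for a, b, c in nbrs)
        np.testing.assert_array_equal(out, expect)

    def test_zero_iterations_identity(self):
        m = np.random.default_rng(0).random((4, 4, 4)) > 0.5
        np.testing.assert_array_equal(erode_mask(m, 0), m)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            erode_mask(np.ones((2, 2, 2), dtype=bool), -1)


def _map_of(values, mask=None):
    data = np.asarray(values, dtype=float)
    if mask is None:
        mask = np.ones(data.shape, dtype=bool)
    return ScalarMap(data, "FA", mask)


class TestRoiMean:
    def test_constant_map(self):
        m = _map_of(np.full((3, 3, 1), 0.6))
        res = roi_mean(m, np.ones((3, 3, 1), dtype=bool), "NAWM")
        assert res.mean == pytest.approx(0.6)

    def test_two_voxel_mean(self):
        data = np.zeros((2, 1, 1))
        data[0], data[1] = 0.2, 0.4
        res = roi_mean(_map_of(data), np.ones((2, 1, 1), dtype=bool))
        assert res.mean == pytest.approx(0.3)

    def test_disjoint_mask_raises(self):
        valid = np.zeros((2, 1, 1), dtype=bool)
        valid[0] = True
        m = _map_of(np.full((2, 1, 1), 0.5), valid)
        roi = np.zeros((2, 1, 1), dtype=bool)
        roi[1] = True
        with pytest.raises(ValueError, match="CST"):
            roi_mean(m, roi, "CST")


class TestHistograms:
    def test_single_subject_equals_its_histogram(self):
        rng = np.random.default_rng(1)
        m = _map_of(rng.random((4, 4, 4)))
        mask = np.ones((4, 4, 4), dtype=bool)
        group = masked_histogram([m], [mask])
        own, _ = np.histogram(m.data, bins=np.linspace(0, 1, 65))
        np.testing.assert_allclose(group, own / own.sum())

    def test_group_histogram_sums_to_one(self):
        rng = np.random.default_rng(2)
        maps = [_map_of(rng.random((3, 3, 3))) for _ in range(5)]
        masks = [np.ones((3, 3, 3), dtype=bool)] * 5
        assert masked_histogram(maps, masks).sum() == pytest.approx(1.0)

    def test_disjoint_single_bins_average(self):
        edges = np.linspace(0, 1, 11)
        a = _map_of(np.full((2, 1, 1), 0.15))
        b = _map_of(np.full((2, 1, 1), 0.75))
        mask = np.ones((2, 1, 1), dtype=bool)
        h = masked_histogram([a, b], [mask, mask], edges)
        assert h[1] == pytest.approx(0.5)
        assert h[7] == pytest.approx(0.5)
        assert h.sum() == pytest.approx(1.0)


class TestThresholdAnalysis:
    def _maps(self):
        rng = np.random.default_rng(3)
        fa = _map_of(rng.random((6, 6, 6)))
        ufa = _map_of(rng.random((6, 6, 6)))
        return fa, ufa, np.ones((6, 6, 6), dtype=bool)

    def test_zero_threshold_matches_unrestricted(self):
        fa, ufa, mask = self._maps()
        tab = fa_threshold_analysis(fa, ufa, mask, thresholds=(0.0,))
        assert tab.loc[0, "mean_fa"] == pytest.approx(fa.data.mean())
        assert tab.loc[0, "mean_ufa"] == pytest.approx(ufa.data.mean())

    def test_mean_fa_monotone_in_threshold(self):
        fa, ufa, mask = self._maps()
        tab = fa_threshold_analysis(fa, ufa, mask)
        means = tab["mean_fa"].to_numpy()
        assert np.all(np.diff(means) >= -1e-12)

    def test_binary_map_selection(self):
        data = np.where(np.arange(8).reshape(2, 2, 2) < 4, 0.1, 0.5)
        fa = _map_of(data)
        tab = fa_threshold_analysis(fa, fa, np.ones((2, 2, 2), dtype=bool), thresholds=(0.4,))
        assert tab.loc[0, "n_voxels"] == 4
        assert tab.loc[0, "mean_fa"] == pytest.approx(0.5)

    def test_empty_threshold_flagged(self):
        fa, ufa, mask = self._maps()
        tab = fa_threshold_analysis(fa, ufa, mask, thresholds=(2.0,))
        assert bool(tab.loc[0, "empty"])
        assert np.isnan(tab.loc[0, "mean_fa"])


class TestMixedAnova:
    def test_matches_independent_glm_oracle(self):
        """F statistics agree with a hand-built numpy GLM on 20 datasets."""
        rng = np.random.default_rng(10)
        for _ in range(20):
            df = random_roi_table(rng)
            ours = rm_anova(df, "uFA", roi="NAWM")
            oracle = oracle_mixed_anova(df)
            for effect in ("group", "hemisphere", "hemisphere:group"):
                f_o, df1, df2, p_o = oracle[effect]
                assert ours[effect].F == pytest.approx(f_o, abs=1e-8), effect
                assert ours[effect].p == pytest.approx(p_o, abs=1e-8)
                assert ours[effect].df == (df1, df2)

    def test_pairwise_bonferroni_relation(self):
        rng = np.random.default_rng(11)
        df = random_roi_table(rng)
        res = rm_anova(df, "uFA")
        pw = res["group"].pairwise
        assert len(pw) == 3
        np.testing.assert_allclose(pw["p_bonf"], np.minimum(1.0, 3 * pw["p"]))

    def test_missing_hemisphere_dropped(self):
        rng = np.random.default_rng(12)
        df = random_roi_table(rng)
        df = df[~((df["id"] == "HC0") & (df["hemisphere"] == "left"))]
        res = rm_anova(df, "uFA")
        # 23 complete subjects, 3 groups, 2 covariates
        assert res["group"].df[1] == 23 - 5

    def test_null_p_uniformity(self):
        """Under identical group distributions, group-effect p is uniform."""
        rng = np.random.default_rng(13)
        ps = []
        for _ in range(200):
            df = random_roi_table(rng, n_per_group=(8, 8, 8))
            ps.append(rm_anova(df, "uFA")["group"].p)
        ks = sps.kstest(ps, "uniform")
        assert ks.pvalue > 0.01


class TestCorrelate:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        res = correlate(x, 2 * x + 1, "pearson")
        assert res.r == pytest.approx(1.0)
        assert res.p == pytest.approx(0.0, abs=1e-12)

    def test_monotone_nonlinear_spearman(self):
        x = np.arange(1.0, 11.0)
        y = 1.0 / x  # strictly decreasing, nonlinear
        res = correlate(x, y, "spearman")
        assert res.r == pytest.approx(-1.0)

    def test_matches_scipy(self):
        rng = np.random.default_rng(20)
        x, y = rng.normal(size=50), rng.normal(size=50)
        p = correlate(x, y, "pearson")
        s = correlate(x, y, "spearman")
        rp, pp = sps.pearsonr(x, y)
        rs, ps = sps.spearmanr(x, y)
        assert p.r == pytest.approx(rp, abs=1e-12)
        assert p.p == pytest.approx(pp, abs=1e-10)
        assert s.r == pytest.approx(rs, abs=1e-12)
        assert s.p == pytest.approx(ps, abs=1e-10)

    def test_spearman_average_ranks_for_ties(self):
        x = np.array([1.0, 1.0, 2.0, 3.0, 3.0, 4.0])
        y = np.array([2.0, 1.0, 3.0, 5.0, 4.0, 6.0])
        res = correlate(x, y, "spearman")
        rs, _ = sps.spearmanr(x, y)
        assert res.r == pytest.approx(rs, abs=1e-12)

    def test_partial_matches_residual_oracle(self):
        rng = np.random.default_rng(21)
        z = rng.normal(size=60)
        x = 0.5 * z + rng.normal(size=60)
        y = -0.3 * z + rng.normal(size=60)
        res = correlate(x, y, "partial_pearson", control=z)
        Z = np.column_stack([np.ones(60), z])
        rx = x - Z @ np.linalg.lstsq(Z, x, rcond=None)[0]
        ry = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
        assert res.r == pytest.approx(np.corrcoef(rx, ry)[0, 1], abs=1e-12)

    def test_partial_matches_pingouin(self):
        """Independent cross-check of the partial correlation."""
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(23)
        z = rng.normal(size=40)
        x = 0.4 * z + rng.normal(size=40)
        y = 0.6 * z + rng.normal(size=40)
        ours = correlate(x, y, "partial_pearson", control=z)
        df = pd.DataFrame({"x": x, "y": y, "z": z})
        ref = pingouin.partial_corr(df, x="x", y="y", covar="z")
        assert ours.r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        assert ours.p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-8)

    def test_degenerate_control_flagged(self):
        rng = np.random.default_rng(22)
        z = rng.normal(size=20)
        y = rng.normal(size=20)
        res = correlate(z, y, "partial_pearson", control=z)
        assert not res.defined

    def test_zero_variance_flagged(self):
        res = correlate(np.ones(10), np.arange(10.0), "pearson")
        assert not res.defined

    def test_too_few_observations(self):
        with pytest.raises(ValueError):
            correlate([1.0, 2.0], [1.0, 2.0], "pearson")


class TestBonferroni:
    @pytest.mark.parametrize(
        "p,m,expected",
        [(0.01, 3, 0.03), (0.5, 3, 1.0), (0.2, 1, 0.2)],
    )
    def test_values(self, p, m, expected):
        assert bonferroni(p, m) == pytest.approx(expected)

    def test_vector_and_default_m(self):
        out = bonferroni([0.01, 0.4, 0.9])
        np.testing.assert_allclose(out, [0.03, 1.0, 1.0])

    def test_invalid(self):
        with pytest.raises(ValueError):
            bonferroni(1.5, 2)
        with pytest.raises(ValueError):
            bonferroni(0.5, 0)
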