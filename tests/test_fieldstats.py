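import numpy as np
import pandas as pd
import pytest
import statsmodels.formula.api as smf

from radeff import (
    AugmentedDesignModel,
    generate_design,
    ndvi_senescence_slope,
    pca,
    pearson_matrix,
    regress_on_pcs,
    ward_cluster,
)


class TestSenescenceSlope:
    def test_flat_series_gives_zero(self):
        daps = np.arange(28, 119, 7)
        ndvi = np.where(daps < 60, 0.3 + 0.01 * daps, 0.8)
        ndvi = np.minimum(ndvi, 0.8)
        assert ndvi_senescence_slope(daps, ndvi) == pytest.approx(0.0)

    def test_exact_linear_decline(self):
        daps = np.arange(0, 100, 10)
        peak = 40
        ndvi = np.where(daps <= peak, 0.02 * daps, 0.8 - 0.004 * (daps - peak))
        assert ndvi_senescence_slope(daps, ndvi) == pytest.approx(-0.004)

    def test_noisy_decline_within_two_se(self):
        rng = np.random.default_rng(12)
        daps = np.arange(0, 80, 10)
        truth = -0.004
        ndvi = 0.8 + truth * daps + rng.normal(0, 0.02, len(daps))
        ndvi[0] = 0.85  # make the first point the maximum
        slope = ndvi_senescence_slope(daps, ndvi)
        se = 0.02 / np.sqrt(np.sum((daps - daps.mean()) ** 2))
        assert abs(slope - truth) < 2 * se + 1e-3

    def test_too_few_post_peak_points(self):
        with pytest.raises(ValueError, match=">= 3 flights"):
            ndvi_senescence_slope([10, 20, 30], [0.2, 0.5, 0.8])


def _augmented_frame(seed=0, block_shift=None, n_new=8, n_checks=3, n_blocks=4):
    """Random augmented layout with additive accession and block effects."""
    rng = np.random.default_rng(seed)
    design = generate_design(n_new, n_checks, n_blocks, n_new // n_blocks, seed=seed)
    e = design.entries.copy()
    acc_eff = {a: rng.normal(0, 5) for a in e["accession"].unique()}
    blk_eff = block_shift or {j: rng.normal(0, 3) for j in e["block"].unique()}
    e["y"] = [
        50 + acc_eff[a] + blk_eff[b] + rng.normal(0, 1.0)
        for a, b in zip(e["accession"], e["block"])
    ]
    return e


class TestAugmentedDesign:
    def test_zero_block_effects_leave_raw_means(self):
        design = generate_design(4, 2, 2, 2, seed=1)
        e = design.entries.copy()
        vals = {a: 10.0 + i for i, a in enumerate(sorted(e["accession"].unique()))}
        e["y"] = e["accession"].map(vals)  # checks identical across blocks
        res = AugmentedDesignModel(e, "y").fit()
        for acc, v in vals.items():
            assert res.adjusted_means[acc] == pytest.approx(v)

    def test_hand_computed_block_adjustment(self):
        # two blocks; checks shifted +10 in block 2 -> entries there adjusted -5
        # relative to the check grand mean (block effect = +5)
        rows = []
        for blk, shift in [(1, 0.0), (2, 10.0)]:
            rows += [
                {"accession": "C1", "block": blk, "is_check": True, "y": 20.0 + shift},
                {"accession": "C2", "block": blk, "is_check": True, "y": 30.0 + shift},
            ]
        rows.append({"accession": "N1", "block": 1, "is_check": False, "y": 40.0})
        rows.append({"accession": "N2", "block": 2, "is_check": False, "y": 40.0})
        res = AugmentedDesignModel(pd.DataFrame(rows), "y").fit()
        assert res.block_effects[1] == pytest.approx(-5.0)
        assert res.block_effects[2] == pytest.approx(5.0)
        assert res.adjusted_means["N1"] == pytest.approx(45.0)
        assert res.adjusted_means["N2"] == pytest.approx(35.0)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_adjusted_means_match_linear_model_oracle(self, seed):
        e = _augmented_frame(seed=seed)
        res = AugmentedDesignModel(e, "y").fit()
        ols = smf.ols("y ~ C(accession) + C(block)", data=e).fit()
        # predict every accession averaged over blocks: equals adjusted mean
        # up to a common constant; compare centred vectors
        blocks = sorted(e["block"].unique())
        preds = {}
        for acc in e["accession"].unique():
            grid = pd.DataFrame({"accession": acc, "block": blocks})
            preds[acc] = ols.predict(grid).mean()
        oracle = pd.Series(preds)
        mine = res.adjusted_means.reindex(oracle.index)
        assert np.allclose(
            mine - mine.mean(), oracle - oracle.mean(), atol=1e-8
        )

    def test_anova_partition_and_error(self):
        e = _augmented_frame(seed=7)
        res = AugmentedDesignModel(e, "y").fit()
        a = res.anova
        assert set(a.index) == {
            "block (checks)", "check", "augmented", "check vs augmented",
            "error (checks)",
        }
        assert a.loc["error (checks)", "df"] == (3 - 1) * (4 - 1)
        assert (a["SS"] >= 0).all()
        assert res.tukey_groups.notna().all()

    def test_missing_check_in_block_rejected(self):
        e = _augmented_frame(seed=0)
        e = e[~((e["accession"] == "CHK1") & (e["block"] == 2))]
        with pytest.raises(ValueError, match="every block"):
            AugmentedDesignModel(e, "y")


class TestPearson:
    def test_hand_computed_toy(self):
        x = np.array([1.0, 2, 3, 4, 5])
        y = np.array([2.0, 1, 4, 3, 6])
        t = pd.DataFrame({"x": x, "y": y})
        m = pearson_matrix(t)
        cov = np.mean((x - x.mean()) * (y - y.mean()))
        r = cov / (x.std() * y.std())
        assert m.loc["x", "y"] == pytest.approx(r)
        assert m.loc["x", "x"] == 1.0

    def test_perfect_anticorrelation(self):
        x = np.arange(5.0)
        t = pd.DataFrame({"x": x, "y": -x})
        assert pearson_matrix(t).loc["x", "y"] == pytest.approx(-1.0)


class TestPCA:
    def _table(self, n=40, p=5, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            rng.normal(size=(n, p)), columns=[f"t{i}" for i in range(p)]
        )

    def test_eigenvalues_sum_to_trait_count(self):
        t = self._table()
        res = pca(t, list(t.columns))
        assert res.eigenvalues.sum() == pytest.approx(5.0)
        assert np.all(np.diff(res.cumulative_variance) >= -1e-12)

    def test_independent_traits_isotropic(self):
        t = self._table(n=4000, seed=1)
        res = pca(t, list(t.columns))
        assert np.all(np.abs(res.eigenvalues - 1.0) < 0.15)

    def test_duplicated_trait_gives_leading_eigenvalue_at_least_two(self):
        t = self._table()
        t["dup"] = t["t0"]
        res = pca(t, list(t.columns))
        assert res.eigenvalues[0] >= 2.0 - 1e-9

    def test_scores_variance_equals_eigenvalues(self):
        t = self._table(seed=3)
        res = pca(t, list(t.columns))
        assert np.allclose(res.scores.var(ddof=1).to_numpy(), res.eigenvalues)
        assert np.allclose(res.scores.mean().to_numpy(), 0.0, atol=1e-12)

    def test_loadings_orthonormal_and_reconstruction_exact(self):
        t = self._table(seed=4)
        res = pca(t, list(t.columns))
        L = res.loadings.to_numpy()
        assert np.allclose(L.T @ L, np.eye(5), atol=1e-10)
        z = (t - t.mean()) / t.std(ddof=1)
        assert np.allclose(res.scores.to_numpy() @ L.T, z.to_numpy(), atol=1e-10)

    def test_deterministic_sign_rule(self):
        t = self._table(seed=5)
        res = pca(t, list(t.columns))
        for j in range(5):
            col = res.loadings.iloc[:, j].to_numpy()
            assert col[np.argmax(np.abs(col))] > 0

    def test_missing_rows_excluded_with_flag(self):
        t = self._table(n=20)
        t.iloc[0, 0] = np.nan
        res = pca(t, list(t.columns))
        assert res.excluded == [0]
        assert len(res.scores) == 19


class TestWard:
    def test_two_separated_blobs(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 0.3, (20, 3))
        b = rng.normal(8, 0.3, (15, 3))
        scores = pd.DataFrame(np.vstack([a, b]))
        labels, heights = ward_cluster(scores, 2)
        assert labels.iloc[:20].nunique() == 1
        assert labels.iloc[20:].nunique() == 1
        assert labels.iloc[0] != labels.iloc[-1]
        assert np.all(np.diff(heights) >= -1e-9)

    def test_duplicate_points_merge_at_zero(self):
        scores = pd.DataFrame(np.zeros((5, 2)))
        _, heights = ward_cluster(scores, 1)
        assert np.allclose(heights, 0.0)

    def test_k_equals_n(self):
        scores = pd.DataFrame(np.arange(12.0).reshape(6, 2))
        labels, _ = ward_cluster(scores, 6)
        assert labels.nunique() == 6

    def test_k_beyond_n_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            ward_cluster(pd.DataFrame(np.zeros((3, 2))), 5)


class TestPCRegression:
    def _scores(self, n=30, seed=0):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(n, 3))
        x -= x.mean(axis=0)
        q, _ = np.linalg.qr(x)
        return pd.DataFrame(q * np.sqrt(n), columns=["PC1", "PC2", "PC3"])

    def test_intercept_equals_mean_response(self):
        s = self._scores()
        rng = np.random.default_rng(1)
        ty = 300 + 70 * s["PC1"] + rng.normal(0, 5, len(s))
        res = regress_on_pcs(ty, s)
        assert res.params["const"] == pytest.approx(ty.mean())

    def test_coefficient_recovery(self):
        s = self._scores(n=200, seed=2)
        rng = np.random.default_rng(3)
        ty = 300 + 70 * s["PC1"] + rng.normal(0, 5, len(s))
        res = regress_on_pcs(ty, s)
        lo, hi = res.conf_int().loc["PC1"]
        assert lo < 70 < hi
        # orthogonal centred regressors: slope = cov/var
        manual = np.cov(ty, s["PC1"], ddof=1)[0, 1] / s["PC1"].var(ddof=1)
        assert res.params["PC1"] == pytest.approx(manual)

    def test_orthogonal_response_gives_null_r2(self):
        s = self._scores(n=100, seed=4)
        rng = np.random.default_rng(5)
        ty = rng.normal(0, 1, len(s))
        res = regress_on_pcs(ty, s)
        assert res.rsquared < 0.15

    def test_overparameterized_rejected(self):
        s = self._scores(n=30).iloc[:2]
        with pytest.raises(ValueError, match="more regressors"):
            regress_on_pcs([1.0, 2.0], s)
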