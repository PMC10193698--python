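import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from cpfetoscan.mfa import (
    MFAInput,
    build_mfa_input,
    confidence_ellipse,
    dimension_description,
    ellipses_disjoint,
    fit_mfa,
    supplementary_categories,
    variable_factor_map,
)


def standardized_pca_oracle(x):
    """Independent PCA oracle: eigen-decomposition of the population
    correlation matrix, coordinates from projection."""
    x = np.asarray(x, float)
    z = (x - x.mean(0)) / x.std(0)
    c = z.T @ z / len(z)
    eigval, eigvec = np.linalg.eigh(c)
    order = np.argsort(eigval)[::-1]
    return eigval[order], z @ eigvec[:, order]


def random_input(seed=0, n=12, p=4, groups=None):
    rng = np.random.default_rng(seed)
    cols = [f"v{i}" for i in range(p)]
    data = pd.DataFrame(rng.normal(size=(n, p)), columns=cols)
    groups = groups or {"g1": cols}
    return MFAInput(data=data, groups=groups)


class TestFitMfa:
    def test_single_group_equals_standardized_pca(self):
        inp = random_input(seed=1, n=10, p=4)
        res = fit_mfa(inp, n_dims=4)
        eig_pca, coords_pca = standardized_pca_oracle(inp.data.to_numpy())
        lam1 = eig_pca[0]
        # group weighting rescales the whole matrix by 1/sqrt(lambda1):
        # inertia proportions identical, eigenvalues/coords scaled
        np.testing.assert_allclose(res.eigenvalues[:4], eig_pca / lam1, atol=1e-8)
        np.testing.assert_allclose(
            res.inertia_pct[:4], 100 * eig_pca / eig_pca.sum(), atol=1e-8
        )
        got = res.individual_coords.to_numpy()
        want = coords_pca / np.sqrt(lam1)
        for d in range(4):
            assert min(
                np.abs(got[:, d] - want[:, d]).max(),
                np.abs(got[:, d] + want[:, d]).max(),
            ) < 1e-8

    def test_two_identical_single_variable_groups(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=20)
        data = pd.DataFrame({"a": v, "b": v})
        inp = MFAInput(data=data, groups={"g1": ["a"], "g2": ["b"]})
        res = fit_mfa(inp, n_dims=1)
        assert res.eigenvalues[0] == pytest.approx(2.0, abs=1e-10)
        assert res.eigenvalues[1:].max() == pytest.approx(0.0, abs=1e-10)
        assert res.inertia_pct[0] == pytest.approx(100.0)

    def test_duplication_invariance(self):
        # duplicating a group's variables k times leaves coordinates
        # unchanged: the defining balancing property of the group weights
        rng = np.random.default_rng(3)
        data = pd.DataFrame(rng.normal(size=(15, 5)), columns=list("abcde"))
        base = MFAInput(data=data, groups={"g1": list("abc"), "g2": list("de")})
        dup_data = data.copy()
        for k in range(2):
            for c in "de":
                dup_data[f"{c}_{k}"] = data[c]
        dup = MFAInput(
            data=dup_data,
            groups={"g1": list("abc"), "g2": ["d", "e", "d_0", "e_0", "d_1", "e_1"]},
        )
        r1 = fit_mfa(base, n_dims=3)
        r2 = fit_mfa(dup, n_dims=3)
        c1 = r1.individual_coords.to_numpy()
        c2 = r2.individual_coords.to_numpy()
        for d in range(3):
            assert min(
                np.abs(c1[:, d] - c2[:, d]).max(), np.abs(c1[:, d] + c2[:, d]).max()
            ) < 1e-8

    def test_constant_column_rejected(self):
        inp = random_input(seed=2)
        inp.data["v0"] = 1.0
        with pytest.raises(ValueError, match="constant"):
            fit_mfa(inp, n_dims=2)

    def test_ndims_beyond_rank_rejected(self):
        with pytest.raises(ValueError, match="rank"):
            fit_mfa(random_input(n=5, p=4), n_dims=5)

    def test_orthogonality_and_total_inertia(self):
        inp = random_input(seed=4, n=20, p=6, groups={"g1": ["v0", "v1", "v2"], "g2": ["v3", "v4", "v5"]})
        res = fit_mfa(inp, n_dims=5)
        coords = res.individual_coords.to_numpy()
        gram = coords.T @ coords
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8
        # total inertia = sum over groups of p_g / lambda1_g
        z = res.standardized.to_numpy() * res.column_weights.to_numpy()
        assert res.eigenvalues.sum() == pytest.approx(np.trace(z.T @ z / len(z)), rel=1e-10)

    def test_group_balance_first_dimension(self):
        # after weighting, no group's own first axis exceeds inertia 1
        inp = random_input(seed=5, n=30, p=6, groups={"g1": ["v0", "v1", "v2", "v3"], "g2": ["v4", "v5"]})
        res = fit_mfa(inp, n_dims=2)
        for gname, gcols in inp.groups.items():
            zg = res.standardized[gcols].to_numpy() * res.column_weights[gcols].to_numpy()
            lam1 = np.linalg.svd(zg / np.sqrt(len(zg)), compute_uv=False)[0] ** 2
            assert lam1 <= 1.0 + 1e-10

    def test_sign_convention_reproducible(self):
        inp = random_input(seed=6, n=15, p=4)
        r1 = fit_mfa(inp, n_dims=2)
        r2 = fit_mfa(inp, n_dims=2)
        pd.testing.assert_frame_equal(r1.individual_coords, r2.individual_coords)
        j = r1.variable_correlations["dim1"].abs().idxmax()
        assert r1.variable_correlations.loc[j, "dim1"] > 0


class TestSupplementaryCategories:
    def test_barycentre_at_origin_zero_vtest(self):
        inp = random_input(seed=7, n=12, p=4)
        res = fit_mfa(inp, n_dims=2)
        # symmetric factor: pair each individual with its mirror
        coords = res.individual_coords
        fac = pd.Series(["a"] * 12, index=coords.index)
        mirrored = coords.copy()
        mirrored.iloc[:, :] = -coords.to_numpy()
        res.individual_coords = pd.concat([coords, mirrored])
        res.n_individuals = 24
        fac = pd.Series(["a"] * 12 + ["b"] * 12, index=res.individual_coords.index)
        fac.iloc[:6] = "b"
        fac.iloc[12:18] = "a"
        cats = supplementary_categories(res, fac)
        # each level contains an individual and its mirror -> barycentre 0
        assert np.abs(cats[["vtest_dim1", "vtest_dim2"]].to_numpy()).max() < 1e-8

    def test_vtest_matches_permutation_null(self):
        rng = np.random.default_rng(8)
        inp = random_input(seed=8, n=40, p=5)
        res = fit_mfa(inp, n_dims=2)
        coords = res.individual_coords["dim1"].to_numpy()
        n, n_k = 40, 14
        # closed-form sd of a random barycentre (without replacement)
        sd_formula = np.sqrt(res.eigenvalues[0] * (n - n_k) / (n_k * (n - 1)))
        draws = np.array([rng.choice(coords, n_k, replace=False).mean() for _ in range(4000)])
        assert draws.std() == pytest.approx(sd_formula, rel=0.08)

    def test_full_level_rejected(self):
        inp = random_input(seed=9, n=10, p=3)
        res = fit_mfa(inp, n_dims=2)
        fac = pd.Series(["only"] * 10, index=res.individual_coords.index)
        with pytest.raises(ValueError):
            supplementary_categories(res, fac)


class TestDimensionDescription:
    def test_two_level_r2_is_squared_point_biserial(self):
        inp = random_input(seed=10, n=24, p=4)
        res = fit_mfa(inp, n_dims=2)
        rng = np.random.default_rng(0)
        fac = pd.Series(rng.choice(["a", "b"], size=24), index=res.individual_coords.index)
        dd = dimension_description(res, fac).set_index("dimension")
        y = res.individual_coords["dim1"].to_numpy()
        x = (fac == "a").astype(float).to_numpy()
        r_pb = np.corrcoef(x, y)[0, 1]
        assert dd.loc["dim1", "r2"] == pytest.approx(r_pb**2, rel=1e-9)

    def test_random_labels_null_scale(self):
        rng = np.random.default_rng(11)
        r2s = []
        for seed in range(30):
            inp = random_input(seed=100 + seed, n=64, p=4)
            res = fit_mfa(inp, n_dims=1)
            fac = pd.Series(rng.choice(["a", "b"], size=64), index=res.individual_coords.index)
            r2s.append(dimension_description(res, fac)["r2"].iloc[0])
        assert np.mean(r2s) == pytest.approx(1 / 63, abs=3 / 63)

    def test_single_level_rejected(self):
        inp = random_input(seed=12, n=8, p=3)
        res = fit_mfa(inp, n_dims=2)
        fac = pd.Series(["x"] * 8, index=res.individual_coords.index)
        with pytest.raises(ValueError):
            dimension_description(res, fac)


class TestConfidenceEllipse:
    def _result_with_coords(self, coords):
        inp = random_input(seed=13, n=len(coords), p=3)
        res = fit_mfa(inp, n_dims=2)
        res.individual_coords = pd.DataFrame(coords, columns=["dim1", "dim2"])
        res.n_individuals = len(coords)
        return res

    def test_semi_axes_shrink_with_sqrt_n(self):
        rng = np.random.default_rng(14)
        big = rng.normal(size=(1000, 2))
        res = self._result_with_coords(big)
        fac = pd.Series(["a"] * 1000)
        e_big = confidence_ellipse(res, fac, "a")
        res2 = self._result_with_coords(big[:250])
        e_small = confidence_ellipse(res2, pd.Series(["a"] * 250), "a")
        ratio = e_small["semi_axes"].mean() / e_big["semi_axes"].mean()
        assert ratio == pytest.approx(2.0, rel=0.15)

    def test_zero_coverage_degenerates_to_point(self):
        rng = np.random.default_rng(15)
        res = self._result_with_coords(rng.normal(size=(50, 2)))
        e = confidence_ellipse(res, pd.Series(["a"] * 50), "a", coverage=0.0)
        assert np.allclose(e["semi_axes"], 0.0)

    def test_collinear_coordinates_rejected(self):
        pts = np.stack([np.arange(10.0), 2 * np.arange(10.0)], axis=1)
        res = self._result_with_coords(pts)
        with pytest.raises(ValueError, match="degenerate"):
            confidence_ellipse(res, pd.Series(["a"] * 10), "a")

    def test_well_separated_groups_disjoint(self):
        rng = np.random.default_rng(16)
        a = rng.normal(size=(40, 2)) * 0.5
        b = rng.normal(size=(40, 2)) * 0.5 + np.array([8.0, 0.0])
        res = self._result_with_coords(np.vstack([a, b]))
        fac = pd.Series(["a"] * 40 + ["b"] * 40)
        e1 = confidence_ellipse(res, fac, "a")
        e2 = confidence_ellipse(res, fac, "b")
        assert ellipses_disjoint(e1, e2)


class TestVariableFactorMap:
    def test_variable_equal_to_dim1(self):
        rng = np.random.default_rng(17)
        inp = random_input(seed=17, n=30, p=4)
        res = fit_mfa(inp, n_dims=2)
        # append the dim1 coordinate itself as a variable and refit
        data = inp.data.copy()
        data["mirror"] = res.individual_coords["dim1"].to_numpy()
        res2 = fit_mfa(MFAInput(data=data, groups={"g1": list(inp.data.columns), "g2": ["mirror"]}), n_dims=2)
        vmap = variable_factor_map(res2)
        assert abs(vmap.loc["mirror", "dim1"]) > 0.95

    def test_all_points_within_unit_circle(self):
        for seed in range(20):
            inp = random_input(seed=200 + seed, n=10, p=5)
            res = fit_mfa(inp, n_dims=2)
            vmap = variable_factor_map(res)
            assert (vmap["quality"] <= 1 + 1e-10).all()

    def test_variable_orthogonal_to_both_dims_at_origin(self):
        # build a fit, then orthogonalise a probe variable against the
        # first two dimensions: its factor-map point must sit at the origin
        inp = random_input(seed=18, n=40, p=4)
        res = fit_mfa(inp, n_dims=2)
        rng = np.random.default_rng(18)
        probe = rng.normal(size=40)
        dims = res.individual_coords[["dim1", "dim2"]].to_numpy()
        q, _ = np.linalg.qr(np.column_stack([dims - dims.mean(0), np.ones(40)]))
        resid = probe - q @ (q.T @ probe)
        zs = (resid - resid.mean()) / resid.std()
        for d in range(2):
            f = dims[:, d]
            corr = np.corrcoef(zs, f)[0, 1]
            assert abs(corr) < 1e-10


class TestBuildInput:
    def test_groups_and_listwise_drop(self):
        from cpfetoscan.quantify import derive_biometry
        from cpfetoscan.synthetic import OrganEffectProfile, StudyDesign, simulate_densities

        t = simulate_densities(StudyDesign(seed=5, n_dams_per_group=3), OrganEffectProfile())
        t = derive_biometry(t.assign(cp_load=t.true_density))
        inp = build_mfa_input(t, factors=("group", "sex"))
        assert set(inp.groups) == {"cp_load", "organ_weight", "weight_ratio"}
        assert not any("gonad" in c for c in inp.groups["organ_weight"])
        assert len(inp.data) == 24  # no missing active variables at defaults
        res = fit_mfa(inp, n_dims=2)
        cats = supplementary_categories(res, inp.factors["group"])
        assert set(cats["level"]) == {"C", "DE"}
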