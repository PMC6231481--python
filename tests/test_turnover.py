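"""Gradient-forest turnover functions, maps, Procrustes and genetic offset."""
import numpy as np
import pandas as pd
import pytest

from landgen.grids import CLIMATE_VARS, ClimateGrid
from landgen.popgen import PopAlleleFreq
from landgen.turnover import (
    GeneticSpace,
    GfSettings,
    fit_turnover,
    genetic_offset,
    map_pca_rgb,
    prepare_responses,
    procrustes_residuals,
    sample_range_points,
    transform_points,
)


def make_freqs(freq):
    freq = np.asarray(freq, float)
    P, L = freq.shape
    return PopAlleleFreq(freq, np.full((P, L), 12, dtype=np.int64),
                         [f"p{j}" for j in range(P)], [f"l{i}" for i in range(L)],
                         np.ones(L, dtype=bool))


class TestPrepareResponses:
    def test_polymorphism_boundary(self):
        P = 17
        f = np.zeros((P, 2))
        f[:3, 0] = 0.4   # polymorphic in exactly 3 pops -> removed
        f[:4, 1] = 0.4   # in 4 -> kept
        out = prepare_responses(make_freqs(f))
        assert list(out.columns) == ["l1"]
        assert out.attrs["n_removed"] == 1

    def test_monomorphic_removed(self):
        f = np.zeros((6, 2))
        f[:, 1] = np.linspace(0.1, 0.6, 6)
        out = prepare_responses(make_freqs(f), min_polymorphic_pops=2)
        assert list(out.columns) == ["l1"]

    def test_study_like_fixture_loses_almost_nothing(self, fixture_system):
        from landgen.popgen import pop_allele_freqs

        _, _, _, m = fixture_system
        freqs = pop_allele_freqs(m)
        out = prepare_responses(freqs)
        assert out.attrs["n_removed"] / m.n_loci <= 0.01

    def test_empty_result_raises(self):
        with pytest.raises(ValueError):
            prepare_responses(make_freqs(np.zeros((6, 3))))


def breakpoint_problem(seed=0, n=17, vstar=5.2, noise=0.03):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame({
        "bio15": np.linspace(0, 10, n),
        "bio4": rng.normal(size=n),
        "mem1": rng.normal(size=n),
    }, index=[f"p{j}" for j in range(n)])
    y = (X["bio15"] > vstar).astype(float) + rng.normal(0, noise, n)
    return X, pd.DataFrame({"snp1": y})


class TestFitTurnover:
    def test_planted_breakpoint_recovery(self):
        X, resp = breakpoint_problem()
        model = fit_turnover(resp, X, GfSettings(n_trees=2000, seed=1))
        imp = model.importance_frame()
        assert imp.iloc[0]["predictor"] == "bio15"
        vals = np.sort(X["bio15"].unique())
        lo, hi = vals[vals < 5.2].max(), vals[vals > 5.2].min()
        F = lambda v: model.turnover("bio15", np.array([v]))[0]
        assert (F(hi) - F(lo)) / model.importance["bio15"] >= 0.6

    def test_pure_noise_null_calibration(self):
        rng = np.random.default_rng(0)
        pos = 0
        r2s = []
        for seed in range(10):
            X, _ = breakpoint_problem(seed)
            resp = pd.DataFrame({f"s{i}": rng.normal(size=17) for i in range(10)},
                                index=X.index)
            m = fit_turnover(resp, X, GfSettings(n_trees=300, seed=seed))
            r2s.append(np.nanmean(m.snp_r2))
            pos += (m.snp_r2 > 0.1).sum()
        assert np.mean(r2s) <= 0.05
        assert pos / 100 <= 0.1  # hardly any meaningfully predictive noise SNP

    def test_functions_nondecreasing_and_conserve_importance(self):
        X, resp = breakpoint_problem(3)
        model = fit_turnover(resp, X, GfSettings(n_trees=500, seed=2))
        for f in model.predictor_names:
            cum = model.cumulative[f]
            assert np.all(np.diff(cum) >= -1e-12)
            assert model.importance[f] == pytest.approx(cum[-1])

    def test_nonpositive_r2_snps_contribute_nothing(self):
        rng = np.random.default_rng(1)
        X, _ = breakpoint_problem(1)
        resp = pd.DataFrame({f"s{i}": rng.normal(size=17) for i in range(5)},
                            index=X.index)
        model = fit_turnover(resp, X, GfSettings(n_trees=200, seed=3))
        if len(model.positive_r2_snps) == 0:
            assert all(v == 0 for v in model.importance.values())

    def test_constant_predictor_excluded_with_warning(self):
        X, resp = breakpoint_problem(2)
        X["flat"] = 1.0
        with pytest.warns(UserWarning, match="constant"):
            model = fit_turnover(resp, X, GfSettings(n_trees=100, seed=1))
        assert "flat" not in model.predictor_names

    def test_bio15_driven_loci_rank_bio15_or_mem1_top(self):
        # when the responding loci all follow the east-west precipitation-
        # seasonality cline, that variable (or the collinear broad-scale
        # spatial axis MEM-1) carries the top importance
        from landgen.mem import mem_predictors
        from landgen.popgen import pop_allele_freqs
        from landgen.simulate import simulate_genotypes, simulate_landscape
        from conftest import small_config

        cfg = small_config(n_neutral=0, n_highfst=0, n_clim=120,
                           clim_effect=2.0, seed=31)
        _, sites = simulate_landscape(cfg)
        m = simulate_genotypes(sites, cfg)
        keep = (m.truth["clim_var"] == "bio15").to_numpy()
        freqs = pop_allele_freqs(m.subset_loci(keep))
        resp = prepare_responses(freqs)
        mems = mem_predictors(sites)
        predictors = pd.concat(
            [sites.set_index("pop")[list(CLIMATE_VARS)], mems], axis=1
        )
        model = fit_turnover(resp, predictors, GfSettings(n_trees=400, seed=2))
        top = model.importance_frame().iloc[0]["predictor"]
        assert top in {"bio15", "MEM-1"}

    def test_seeded_reproducibility(self):
        X, resp = breakpoint_problem(4)
        m1 = fit_turnover(resp, X, GfSettings(n_trees=200, seed=9))
        m2 = fit_turnover(resp, X, GfSettings(n_trees=200, seed=9))
        for f in m1.predictor_names:
            np.testing.assert_array_equal(m1.cumulative[f], m2.cumulative[f])


@pytest.fixture(scope="module")
def model():
    X, resp = breakpoint_problem(5)
    return X, fit_turnover(resp, X, GfSettings(n_trees=500, seed=4))


class TestTransform:
    def test_minimum_maps_to_zero(self, model):
        X, m = model
        pt = pd.DataFrame({f: [X[f].min()] for f in m.predictor_names})
        space = transform_points(m, pt)
        np.testing.assert_allclose(space.values.to_numpy(), 0.0)

    def test_maximum_maps_to_total_importance(self, model):
        X, m = model
        pt = pd.DataFrame({f: [X[f].max()] for f in m.predictor_names})
        space = transform_points(m, pt)
        for f in m.predictor_names:
            assert space.values[f].iloc[0] == pytest.approx(m.importance[f])

    def test_componentwise_monotonicity(self, model):
        X, m = model
        rng = np.random.default_rng(0)
        a = {f: rng.uniform(X[f].min(), X[f].max(), 20) for f in m.predictor_names}
        lo = pd.DataFrame(a)
        hi = lo + rng.uniform(0, 2, size=lo.shape)
        va = transform_points(m, lo).values.to_numpy()
        vb = transform_points(m, hi).values.to_numpy()
        assert np.all(vb >= va - 1e-12)

    def test_unknown_predictor_rejected(self, model):
        _, m = model
        with pytest.raises(KeyError):
            transform_points(m, pd.DataFrame({"nope": [1.0]}))


class TestPcaRgb:
    def test_duplicated_points_identical_colors(self):
        rng = np.random.default_rng(0)
        V = rng.random((10, 3))
        V[7] = V[2]
        space = GeneticSpace(pd.DataFrame(), pd.DataFrame(V, columns=list("abc")))
        _, rgb = map_pca_rgb(space)
        np.testing.assert_array_equal(rgb[7], rgb[2])

    def test_rank_one_variation(self):
        t = np.linspace(0, 1, 20)
        V = pd.DataFrame({"a": t, "b": 0.0, "c": 0.0})
        with pytest.warns(UserWarning):
            scores, rgb = map_pca_rgb(GeneticSpace(pd.DataFrame(), V))
        var = scores.var(axis=0)
        assert var[0] / var.sum() > 0.999
        assert np.all(rgb[:, 1] == rgb[0, 1]) and np.all(rgb[:, 2] == rgb[0, 2])

    def test_scores_match_eigendecomposition_oracle(self):
        M = np.array([[1.0, 2.0, 0.5], [2.0, 0.0, 1.0],
                      [0.0, 1.0, 3.0], [4.0, 1.0, 0.0]])
        space = GeneticSpace(pd.DataFrame(), pd.DataFrame(M, columns=list("xyz")))
        scores = space.pca_scores(3)
        Mc = M - M.mean(axis=0)
        vals, vecs = np.linalg.eigh(Mc.T @ Mc)
        order = np.argsort(vals)[::-1]
        oracle = Mc @ vecs[:, order]
        for k in range(3):
            assert min(np.abs(scores[:, k] - oracle[:, k]).max(),
                       np.abs(scores[:, k] + oracle[:, k]).max()) < 1e-8


class TestProcrustes:
    def _space(self, V):
        return GeneticSpace(pd.DataFrame(), pd.DataFrame(V))

    def test_identity_zero_residuals(self):
        rng = np.random.default_rng(0)
        V = rng.random((15, 3))
        r = procrustes_residuals(self._space(V), self._space(V.copy()))
        np.testing.assert_allclose(r, 0.0, atol=1e-12)

    def test_similarity_transform_invariance(self):
        rng = np.random.default_rng(1)
        A = rng.random((12, 3))
        Q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        B = 2.7 * A @ Q + np.array([5.0, -3.0, 1.0])
        sa, sb = self._space(A), self._space(B)
        # PCA scores of B are a rotated/scaled copy of A's: residuals ~ 0
        r = procrustes_residuals(sa, sb)
        np.testing.assert_allclose(r, 0.0, atol=1e-8)

    def test_single_displaced_point_gets_residual_one(self):
        A = np.array([[0, 0], [1, 0], [1, 1], [0, 1], [0.5, 0.5]], float)
        B = A.copy()
        B[4] = [0.9, 0.1]
        # direct 2-D computation, padding a zero third axis
        A3 = np.column_stack([A, np.zeros(5)])
        B3 = np.column_stack([B, np.zeros(5)])
        r = procrustes_residuals(self._space(A3), self._space(B3))
        assert np.argmax(r) == 4 and r[4] == pytest.approx(1.0)


def flat_grid(values: dict, nx=8, ny=6):
    data = {v: np.full((ny, nx), val, float) for v, val in values.items()}
    return ClimateGrid(data, x0=-104.0, y0=18.5, cell=0.25)


@pytest.fixture(scope="module")
def system():
    X, resp = breakpoint_problem(6)
    X.columns = ["bio15", "bio4", "bio6"]
    model = fit_turnover(resp, X, GfSettings(n_trees=500, seed=5))
    points = pd.DataFrame({"lon": np.linspace(-103.9, -102.1, 30),
                           "lat": np.full(30, 19.0)})
    return model, points, X


class TestOffset:
    def test_future_equals_current_offset_zero(self, system):
        model, points, X = system
        rng = np.random.default_rng(0)
        vals = {f: float(X[f].mean()) for f in model.predictor_names}
        cur = flat_grid(vals)
        fut = ClimateGrid({k: v.copy() for k, v in cur.data.items()},
                          cur.x0, cur.y0, cur.cell, epoch="future-mean")
        off = genetic_offset(model, cur, fut, points)
        np.testing.assert_allclose(off["offset"], 0.0)

    def test_shift_on_flat_plateau_gives_zero_offset(self, system):
        model, points, X = system
        # bio4/bio6 turnover functions are ~flat (no importance): a shift
        # confined to them produces no offset
        base = {f: float(X[f].mean()) for f in model.predictor_names}
        cur = flat_grid(base)
        shifted = dict(base)
        for f in model.predictor_names:
            if model.importance[f] == 0:
                shifted[f] = base[f] + 0.5
        fut = flat_grid(shifted)
        fut.epoch = "future-mean"
        off = genetic_offset(model, cur, fut, points)
        flat_fs = [f for f in model.predictor_names if model.importance[f] == 0]
        if flat_fs:
            np.testing.assert_allclose(off["offset"], 0.0, atol=1e-12)

    def test_misaligned_grids_rejected(self, system):
        model, points, X = system
        vals = {f: 1.0 for f in model.predictor_names}
        cur = flat_grid(vals, nx=8)
        fut = flat_grid(vals, nx=9)
        with pytest.raises(ValueError, match="misaligned"):
            genetic_offset(model, cur, fut, points)

    def test_regional_change_raises_regional_offset(self, fixture_system):
        # an eastern-only increase of an influential predictor must push the
        # eastern offsets above the western ones
        from landgen.mem import mem_predictors
        from landgen.popgen import pop_allele_freqs
        from landgen.simulate import make_future_climate

        cfg, grid, sites, m = fixture_system
        freqs = pop_allele_freqs(m)
        resp = prepare_responses(freqs)
        mems = mem_predictors(sites)
        predictors = pd.concat(
            [sites.set_index("pop")[list(CLIMATE_VARS)], mems], axis=1
        )
        model = fit_turnover(resp.iloc[:, :80], predictors,
                             GfSettings(n_trees=300, seed=7))
        ny, nx = grid.shape
        lon, _ = grid.cell_centers()
        east = lon > np.quantile(lon, 2 / 3)
        fut_data = {v: a.copy() for v, a in grid.data.items()}
        fut_data["bio15"] = fut_data["bio15"] + 12.0 * east
        fut = ClimateGrid(fut_data, grid.x0, grid.y0, grid.cell, epoch="future-mean")
        points = sample_range_points(sites, n_points=400, seed=1, grid=grid)
        mems.attrs["coords"] = sites.set_index("pop").loc[mems.index, ["lon", "lat"]]
        off = genetic_offset(model, grid, fut, points, mem_values=mems)
        thr = np.quantile(points["lon"], [1 / 3, 2 / 3])
        east_mean = off.loc[points["lon"] > thr[1], "offset"].mean()
        west_mean = off.loc[points["lon"] < thr[0], "offset"].mean()
        assert east_mean > west_mean
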