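"""Gradient-forest turnover modelling and genetic offset.

Each SNP's per-population minor-allele frequency is regressed on climate and
spatial (MEM) predictors with an ensemble of shallow CART regression trees,
each grown on a random ~63.2% training subset of populations. The impurity
reduction of every split is recorded at its split value; per predictor these
split-importance masses, standardised by the predictor's sampling density,
accumulate into a monotone non-decreasing *turnover function* whose total
rise is the predictor's importance. Only SNPs with positive out-of-bag R^2
contribute, weighted by R^2. Turnover functions transform any location's
predictor values into "genetic importance values"; the Euclidean distance
between a location's current and future transformed climate is its *genetic
offset*, a proxy for the expected disruption of gene-environment
relationships under climate change.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import log2

import numpy as np
import pandas as pd

from .grids import ClimateGrid
from .popgen import PopAlleleFreq


# ---------------------------------------------------------------------------
# settings and response preparation


@dataclass
class GfSettings:
    """Ensemble settings. ``max_depth=None`` derives the depth limit from the
    number of training populations n as round(log2(0.368 n)/2), floored at 1."""

    n_trees: int = 2000
    correlation_threshold: float = 0.5
    train_fraction: float = 0.632
    n_bins: int = 200
    max_depth: int | None = None
    n_perm: int = 3
    seed: int = 0

    def depth_for(self, n: int) -> int:
        if self.max_depth is not None:
            return self.max_depth
        return max(1, round(log2(max(0.368 * n, 2.0)) / 2))


def prepare_responses(freqs: PopAlleleFreq, min_polymorphic_pops: int = 3) -> pd.DataFrame:
    """Minor-allele-frequency response table, dropping sparse SNPs.

    A SNP polymorphic (0 < freq < 1) in ``min_polymorphic_pops`` or fewer
    populations is removed; monomorphic SNPs always are.
    """
    df = freqs.to_frame()
    poly = ((df > 0) & (df < 1)).sum(axis=0)
    keep = poly > min_polymorphic_pops
    out = df.loc[:, keep]
    out.attrs["n_removed"] = int((~keep).sum())
    if out.shape[1] == 0:
        raise ValueError("no SNPs left after the polymorphism filter")
    return out


# ---------------------------------------------------------------------------
# vectorised shallow forest


def _candidate_splits(X: np.ndarray):
    """Global candidate splits: midpoints of consecutive sorted unique values
    per feature. Returns (feat_idx, thresholds, indicator[C, n])."""
    feats, thrs = [], []
    for f in range(X.shape[1]):
        u = np.unique(X[:, f])
        if len(u) < 2:
            continue
        mids = (u[:-1] + u[1:]) / 2
        feats.extend([f] * len(mids))
        thrs.extend(mids)
    feat_idx = np.array(feats, dtype=np.int64)
    thr = np.array(thrs, dtype=float)
    ind = X[:, feat_idx].T <= thr[:, None]       # (C, n)
    return feat_idx, thr, ind


class _Forest:
    """A fitted ensemble of complete-depth trees for one response."""

    def __init__(self, X, y, settings: GfSettings, rng: np.random.Generator):
        n, P = X.shape
        T = settings.n_trees
        depth = settings.depth_for(n)
        self.X, self.y, self.depth = X, y, depth
        feat_idx, thr, ind = _candidate_splits(X)
        C = len(feat_idx)
        mtry = max(P // 3, 1)

        n_train = max(2, round(settings.train_fraction * n))
        inbag = np.zeros((T, n), dtype=bool)
        for t in range(T):
            inbag[t, rng.choice(n, size=n_train, replace=False)] = True
        self.inbag = inbag

        self.feats = [np.full((T, 2**d), -1, dtype=np.int64) for d in range(depth)]
        self.thrs = [np.full((T, 2**d), np.inf) for d in range(depth)]
        # importance mass per candidate split actually used
        self.split_gain = np.zeros((T, C))
        self.feat_idx, self.thr = feat_idx, thr

        W = inbag.astype(float)
        node = np.zeros((T, n), dtype=np.int64)
        for d in range(depth):
            for k in range(2**d):
                Wk = W * (node == k)
                ntot = Wk.sum(axis=1)
                stot = Wk @ y
                sqtot = Wk @ (y**2)
                if C == 0:
                    continue
                nL = Wk @ ind.T.astype(float)          # (T, C)
                sL = (Wk * y) @ ind.T.astype(float)
                nR = ntot[:, None] - nL
                sR = stot[:, None] - sL
                with np.errstate(invalid="ignore", divide="ignore"):
                    gain = (
                        sL**2 / nL + sR**2 / nR - (stot**2 / np.maximum(ntot, 1e-12))[:, None]
                    )
                gain[(nL < 1) | (nR < 1)] = -np.inf
                gain = np.nan_to_num(gain, nan=-np.inf, neginf=-np.inf)
                # mtry: per tree, restrict candidates to a random feature subset
                allowed = np.zeros((T, P), dtype=bool)
                for t in range(T):  # cheap: P is small
                    allowed[t, rng.choice(P, size=mtry, replace=False)] = True
                gain[~allowed[:, feat_idx]] = -np.inf

                best = np.argmax(gain, axis=1)
                best_gain = gain[np.arange(T), best]
                node_var = sqtot - stot**2 / np.maximum(ntot, 1e-12)
                do_split = (ntot >= 2) & (best_gain > 1e-12) & (node_var > 1e-12)
                tt = np.flatnonzero(do_split)
                self.feats[d][tt, k] = feat_idx[best[tt]]
                self.thrs[d][tt, k] = thr[best[tt]]
                self.split_gain[tt, best[tt]] += best_gain[tt]
            # route all samples to the next level (-1 nodes pass left)
            f_d = self.feats[d][np.arange(T)[:, None], node]      # (T, n)
            t_d = self.thrs[d][np.arange(T)[:, None], node]
            xv = X[np.arange(n)[None, :], np.maximum(f_d, 0)]
            go_right = (f_d >= 0) & (xv > t_d)
            node = 2 * node + go_right

        # leaf means from in-bag samples; empty leaf -> tree's in-bag mean
        n_leaves = 2**depth
        leaf_sum = np.zeros((T, n_leaves))
        leaf_n = np.zeros((T, n_leaves))
        for t in range(T):
            np.add.at(leaf_sum[t], node[t][inbag[t]], y[inbag[t]])
            np.add.at(leaf_n[t], node[t][inbag[t]], 1)
        tree_mean = (W @ y) / np.maximum(W.sum(axis=1), 1)
        with np.errstate(invalid="ignore"):
            self.leaf_val = np.where(leaf_n > 0, leaf_sum / np.maximum(leaf_n, 1),
                                     tree_mean[:, None])
        self.train_node = node

    def predict_matrix(self, X: np.ndarray) -> np.ndarray:
        """(T, n_samples) per-tree predictions."""
        T = self.inbag.shape[0]
        n = X.shape[0]
        node = np.zeros((T, n), dtype=np.int64)
        for d in range(self.depth):
            f_d = self.feats[d][np.arange(T)[:, None], node]
            t_d = self.thrs[d][np.arange(T)[:, None], node]
            xv = X[np.arange(n)[None, :], np.maximum(f_d, 0)]
            node = 2 * node + ((f_d >= 0) & (xv > t_d))
        return self.leaf_val[np.arange(T)[:, None], node]

    def oob_mse(self, X: np.ndarray | None = None) -> float:
        preds = self.predict_matrix(self.X if X is None else X)
        oob = ~self.inbag
        cnt = oob.sum(axis=0)
        ok = cnt > 0
        yhat = (preds * oob).sum(axis=0)[ok] / cnt[ok]
        return float(np.mean((self.y[ok] - yhat) ** 2))


@dataclass
class TurnoverModel:
    """Fitted per-predictor turnover functions and importance weights."""

    predictor_names: list[str]
    bin_edges: dict[str, np.ndarray]         # per predictor, n_bins+1 edges
    cumulative: dict[str, np.ndarray]        # ensemble cumulative, len n_bins
    importance: dict[str, float]             # total rise per predictor
    snp_r2: pd.Series                        # OOB R^2 per SNP
    snp_importance: pd.DataFrame             # SNPs x predictors
    settings: GfSettings = field(default_factory=GfSettings)

    @property
    def positive_r2_snps(self) -> list[str]:
        return list(self.snp_r2.index[self.snp_r2 > 0])

    def turnover(self, predictor: str, values: np.ndarray) -> np.ndarray:
        """Step-function lookup: F(v) is the cumulative split mass of bins
        entirely below v, so F(min) = 0 and F(max) = the predictor's total
        importance; values outside the training range are clamped."""
        if predictor not in self.cumulative:
            raise KeyError(f"unknown predictor {predictor!r}")
        edges = self.bin_edges[predictor]
        cum = np.concatenate([[0.0], self.cumulative[predictor]])
        v = np.clip(np.asarray(values, dtype=float), edges[0], edges[-1])
        idx = np.searchsorted(edges[1:], v, side="right")
        return cum[idx]

    def importance_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"predictor": list(self.importance), "importance": list(self.importance.values())}
        ).sort_values("importance", ascending=False, ignore_index=True)


def _strata_labels(X: np.ndarray, f: int, corr_threshold: float) -> np.ndarray:
    """Joint quartile strata of predictors correlated with feature f."""
    n, P = X.shape
    labels = np.zeros(n, dtype=np.int64)
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(X.T) if P > 1 else np.ones((1, 1))
    partners = [g for g in range(P) if g != f and abs(corr[f, g]) > corr_threshold]
    for g in partners:
        qs = np.quantile(X[:, g], [0.25, 0.5, 0.75])
        labels = labels * 4 + np.searchsorted(qs, X[:, g])
    return labels


def fit_turnover(
    responses: pd.DataFrame,
    predictors: pd.DataFrame,
    settings: GfSettings | None = None,
) -> TurnoverModel:
    """Fit the gradient-forest model.

    ``responses``: populations x SNPs allele-frequency table;
    ``predictors``: populations x predictors (climate + MEM), same row order.
    Per-SNP predictor importance comes from conditional permutation of
    out-of-bag predictions (permuting within quartile strata of predictors
    correlated above the threshold); split-impurity masses build the
    turnover functions.
    """
    settings = settings or GfSettings()
    if len(responses) != len(predictors):
        raise ValueError("responses and predictors disagree in population count")
    if len(responses) < 5:
        raise ValueError("need >= 5 populations")
    keep = [c for c in predictors.columns if predictors[c].nunique() > 1]
    dropped = set(predictors.columns) - set(keep)
    if dropped:
        warnings.warn(f"constant predictors excluded: {sorted(dropped)}", stacklevel=2)
    predictors = predictors[keep]
    names = list(predictors.columns)
    X = predictors.to_numpy(dtype=float)
    n, P = X.shape
    rng = np.random.default_rng(settings.seed)

    nb = settings.n_bins
    bin_edges = {}
    density = {}
    for j, f in enumerate(names):
        lo, hi = X[:, j].min(), X[:, j].max()
        edges = np.linspace(lo, hi, nb + 1)
        bin_edges[f] = edges
        centers = (edges[:-1] + edges[1:]) / 2
        # smoothed sampling density of the predictor (kernel estimate), so
        # split mass falling between observations is standardised sensibly
        try:
            from scipy.stats import gaussian_kde

            d = gaussian_kde(X[:, j])(centers)
        except np.linalg.LinAlgError:
            d = np.ones(nb)
        d = d / d.sum()
        density[f] = np.maximum(d, 1e-3 * d.max())

    r2 = {}
    snp_imp = {}
    snp_cum = {}
    for snp in responses.columns:
        y = responses[snp].to_numpy(dtype=float)
        ok = np.isfinite(y)
        if ok.sum() < 5 or np.var(y[ok]) == 0:
            r2[snp] = -np.inf
            snp_imp[snp] = dict.fromkeys(names, 0.0)
            continue
        Xs, ys = X[ok], y[ok]
        forest = _Forest(Xs, ys, settings, rng)
        mse = forest.oob_mse()
        r2[snp] = 1.0 - mse / np.var(ys)

        # conditional permutation importance
        imp = {}
        for j, f in enumerate(names):
            strata = _strata_labels(Xs, j, settings.correlation_threshold)
            inc = 0.0
            for _ in range(settings.n_perm):
                Xp = Xs.copy()
                for lab in np.unique(strata):
                    sel = np.flatnonzero(strata == lab)
                    Xp[sel, j] = Xs[rng.permutation(sel), j]
                inc += forest.oob_mse(Xp) - mse
            imp[f] = max(inc / settings.n_perm, 0.0)
        tot = sum(imp.values())
        share = {f: (imp[f] / tot if tot > 0 else 1.0 / P) for f in names}
        snp_imp[snp] = {f: max(r2[snp], 0.0) * share[f] for f in names}

        # split-mass densities -> per-SNP cumulative functions
        cums = {}
        for j, f in enumerate(names):
            sel = forest.feat_idx == j
            mass = np.zeros(nb)
            if sel.any():
                gains = forest.split_gain[:, sel].sum(axis=0)
                idx = np.clip(
                    np.searchsorted(bin_edges[f], forest.thr[sel], side="right") - 1,
                    0, nb - 1,
                )
                np.add.at(mass, idx, gains)
            dens = np.where(density[f] > 0, density[f], np.nan)
            std_mass = np.where(np.isnan(dens), 0.0, mass / np.where(np.isnan(dens), 1, dens))
            cum = np.cumsum(std_mass)
            total = cum[-1]
            target = snp_imp[snp][f]
            cums[f] = cum * (target / total) if total > 0 else np.zeros(nb)
        snp_cum[snp] = cums

    snp_r2 = pd.Series(r2).replace(-np.inf, np.nan)
    pos = [s for s in responses.columns if np.isfinite(snp_r2.get(s, np.nan)) and snp_r2[s] > 0]
    weights = snp_r2[pos]
    wsum = float(weights.sum()) if len(pos) else 0.0

    cumulative = {}
    importance = {}
    for f in names:
        if wsum > 0:
            ens = sum((weights[s] / wsum) * snp_cum[s][f] for s in pos)
        else:
            ens = np.zeros(nb)
        cumulative[f] = np.asarray(ens)
        importance[f] = float(cumulative[f][-1])

    return TurnoverModel(
        predictor_names=names,
        bin_edges=bin_edges,
        cumulative=cumulative,
        importance=importance,
        snp_r2=snp_r2,
        snp_importance=pd.DataFrame(snp_imp).T.reindex(columns=names),
        settings=settings,
    )


# ---------------------------------------------------------------------------
# genetic space, maps, Procrustes, offset


@dataclass
class GeneticSpace:
    """Transformed ("genetic importance") values at a set of points."""

    points: pd.DataFrame       # lon, lat
    values: pd.DataFrame       # points x predictors, transformed
    epoch: str = "current"

    def pca_scores(self, n_pcs: int = 3) -> np.ndarray:
        """Centered (unscaled) PCA scores of the transformed values."""
        V = self.values.to_numpy(dtype=float)
        Vc = V - V.mean(axis=0)
        U, s, _ = np.linalg.svd(Vc, full_matrices=False)
        scores = U * s
        if scores.shape[1] < n_pcs:
            scores = np.pad(scores, ((0, 0), (0, n_pcs - scores.shape[1])))
        return scores[:, :n_pcs]


def transform_points(model: TurnoverModel, points: pd.DataFrame,
                     epoch: str = "current") -> GeneticSpace:
    """Map each predictor column through its turnover function.

    Values outside the training range are clamped to the function
    endpoints. ``points`` must contain every model predictor (plus optional
    ``lon``/``lat`` carried through).
    """
    missing = [f for f in model.predictor_names if f not in points.columns]
    if missing:
        raise KeyError(f"points table lacks predictors: {missing}")
    vals = {
        f: model.turnover(f, points[f].to_numpy(dtype=float))
        for f in model.predictor_names
    }
    coords = points[[c for c in ("lon", "lat") if c in points.columns]].copy()
    return GeneticSpace(coords, pd.DataFrame(vals, index=points.index), epoch=epoch)


def map_pca_rgb(space: GeneticSpace) -> tuple[np.ndarray, np.ndarray]:
    """Centered-PCA scores and an RGB colour per point (PC1/2/3 min-max
    scaled to 0-255). Degenerate axes map to mid-scale."""
    if len(space.values) < 3:
        raise ValueError("need >= 3 points for a PCA map")
    nz = (space.values.std(axis=0) > 0).sum()
    if nz < 3:
        warnings.warn("fewer than 3 varying predictors; trailing PCs padded",
                      stacklevel=2)
    scores = space.pca_scores(3)
    rgb = np.empty_like(scores)
    for k in range(3):
        col = scores[:, k]
        rng_ = np.ptp(col)
        rgb[:, k] = 127.5 if rng_ == 0 else (col - col.min()) / rng_ * 255
    return scores, rgb.astype(np.uint8)


def procrustes_residuals(space_a: GeneticSpace, space_b: GeneticSpace,
                         n_pcs: int = 3) -> np.ndarray:
    """Per-point Procrustes residuals between two genetic spaces, in [0,1].

    The PCA scores of B are superimposed on A's by least-squares
    translation, rotation/reflection and isotropic scaling
    (scipy.spatial.procrustes); residuals are per-point Euclidean distances
    after superimposition, min-max rescaled to [0, 1].
    """
    from scipy.spatial import procrustes

    if len(space_a.values) != len(space_b.values):
        raise ValueError("spaces must share the same point set")
    A = space_a.pca_scores(n_pcs)
    B = space_b.pca_scores(n_pcs)
    if np.allclose(A, 0) or np.allclose(B, 0):
        return np.zeros(len(A))
    m1, m2, _disp = procrustes(A, B)
    resid = np.linalg.norm(m1 - m2, axis=1)
    # numerically-zero disparity (identical shapes up to similarity) -> 0
    if resid.max() <= 1e-9:
        return np.zeros_like(resid)
    return resid / resid.max()


def sample_range_points(sites: pd.DataFrame, n_points: int = 10000,
                        buffer_deg: float = 0.5, seed: int = 0,
                        grid: ClimateGrid | None = None) -> pd.DataFrame:
    """Uniform random points within the buffered convex hull of the sites,
    optionally restricted to a climate grid's extent."""
    from scipy.spatial import ConvexHull

    pts = sites[["lon", "lat"]].to_numpy(dtype=float)
    hull = ConvexHull(pts)
    eqs = hull.equations                       # (n_facets, 3): a, b, offset
    norms = np.linalg.norm(eqs[:, :2], axis=1)
    rng = np.random.default_rng(seed)
    lo = pts.min(axis=0) - buffer_deg
    hi = pts.max(axis=0) + buffer_deg
    if grid is not None:
        ny, nx = grid.shape
        lo = np.maximum(lo, [grid.x0, grid.y0])
        hi = np.minimum(hi, [grid.x0 + nx * grid.cell, grid.y0 + ny * grid.cell])
    out = []
    while sum(len(o) for o in out) < n_points:
        cand = rng.uniform(lo, hi, size=(max(n_points, 1000), 2))
        # inside the hull dilated by the buffer distance
        dist = (cand @ eqs[:, :2].T + eqs[:, 2]) / norms
        inside = (dist <= buffer_deg).all(axis=1)
        out.append(cand[inside])
    cand = np.concatenate(out)[:n_points]
    return pd.DataFrame({"lon": cand[:, 0], "lat": cand[:, 1]})


def points_predictor_table(grid: ClimateGrid, points: pd.DataFrame,
                           mem_values: pd.DataFrame | None = None) -> pd.DataFrame:
    """Predictor values at points: climate read off the grid, plus optional
    fixed spatial (MEM) columns interpolated by nearest site."""
    out = points[["lon", "lat"]].copy()
    for var in grid.variables:
        out[var] = grid.value_at(var, points["lon"].to_numpy(), points["lat"].to_numpy())
    if mem_values is not None:
        # nearest-site assignment keeps the spatial basis fixed across epochs
        sites = mem_values.attrs.get("coords")
        if sites is None:
            raise ValueError("mem_values needs .attrs['coords'] with lon/lat per site")
        d2 = (
            (points["lon"].to_numpy()[:, None] - sites["lon"].to_numpy()[None, :]) ** 2
            + (points["lat"].to_numpy()[:, None] - sites["lat"].to_numpy()[None, :]) ** 2
        )
        nearest = np.argmin(d2, axis=1)
        for col in mem_values.columns:
            out[col] = mem_values[col].to_numpy()[nearest]
    return out


def genetic_offset(model: TurnoverModel, current: ClimateGrid, future: ClimateGrid,
                   points: pd.DataFrame,
                   mem_values: pd.DataFrame | None = None) -> pd.DataFrame:
    """Euclidean distance between current and future genetic importance values.

    MEM predictors are held fixed across epochs (geography does not change),
    so they contribute zero to the distance; the offset is driven by the
    climate dimensions only.
    """
    if not current.aligned_with(future):
        raise ValueError("current and future grids are misaligned")
    cur_tab = points_predictor_table(current, points, mem_values)
    fut_tab = points_predictor_table(future, points, mem_values)
    cur_space = transform_points(model, cur_tab, epoch=current.epoch)
    fut_space = transform_points(model, fut_tab, epoch=future.epoch)
    delta = cur_space.values.to_numpy() - fut_space.values.to_numpy()
    out = points[["lon", "lat"]].copy()
    out["offset"] = np.linalg.norm(delta, axis=1)
    return out
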