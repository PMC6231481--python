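"""Genotype-environment association with latent-factor correction.

Each climate variable is tested separately: individual genotypes are
regressed on the (population-level, standardised) environmental value while
K latent factors absorb neutral population structure. K can be chosen by a
principal-component analysis with the Tracy-Widom test on the leading
eigenvalues (Patterson normalisation) or supplied directly. Per-locus |z|
scores are medians over several randomly initialised runs, rescaled by the
genomic inflation factor, and candidates are selected by Benjamini-Hochberg
FDR within each variable.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genio import MISSING, GenotypeMatrix

#: Tracy-Widom (GOE, beta=1) upper-tail quantile anchors: (upper tail prob, x).
#: Standard published significance points; p-values between anchors are
#: interpolated on the log scale, beyond them extrapolated from the nearest
#: pair.  Adequate for threshold decisions at conventional alpha levels.
_TW1_TAIL = [
    (0.50, -1.27),
    (0.25, -0.59),
    (0.10, 0.4501),
    (0.05, 0.9793),
    (0.01, 2.0234),
    (0.001, 3.2724),
    (0.0001, 4.4283),
]


def tw1_pvalue(x: float) -> float:
    """Approximate upper-tail probability of the Tracy-Widom TW1 statistic."""
    xs = np.array([t[1] for t in _TW1_TAIL])
    logp = np.log([t[0] for t in _TW1_TAIL])
    if x <= xs[0]:
        return 1.0
    return float(np.exp(np.interp(x, xs, logp)))


def _impute_standardize(matrix: GenotypeMatrix) -> np.ndarray:
    """Mean-imputed, Patterson-normalised genotype matrix (individuals x loci)."""
    G = matrix.genotypes.astype(float)
    G[matrix.genotypes == MISSING] = np.nan
    mu = np.nanmean(G, axis=0)
    inds = np.where(np.isnan(G))
    G[inds] = mu[inds[1]]
    p_hat = mu / 2.0
    sd = np.sqrt(np.clip(p_hat * (1 - p_hat), 1e-12, None))
    Y = (G - mu) / sd
    keep = np.nanstd(G, axis=0) > 0
    return Y[:, keep]


def choose_k_tracy_widom(matrix: GenotypeMatrix, alpha: float = 0.05,
                         max_k: int | None = None) -> int:
    """Number of significant structure axes by the sequential TW test.

    Eigenvalues of the individual covariance of mean-imputed, normalised
    genotypes are tested one at a time: the leading eigenvalue is
    standardised with the Patterson effective-marker normalisation and
    compared to TW1; on significance it is removed and the test repeats.
    """
    if matrix.n_individuals < 3:
        raise ValueError("need >= 3 individuals")
    Y = _impute_standardize(matrix)
    m = Y.shape[0]
    C = Y @ Y.T / Y.shape[1]
    vals = np.linalg.eigvalsh(C)[::-1]
    vals = vals[: m - 1]  # last eigenvalue is ~0 after centering
    vals = np.clip(vals, 1e-12, None)

    K = 0
    limit = max_k if max_k is not None else len(vals) - 2
    ell = vals.copy()
    while K < limit and len(ell) > 2:
        mprime = len(ell)
        s1, s2 = ell.sum(), (ell**2).sum()
        # effective marker count, with a = mprime + 1 "samples" for rank mprime
        a = mprime + 1
        n_eff = (a + 1) * s1**2 / ((a - 1) * s2 - s1**2)
        if n_eff <= 1:
            break
        x = mprime * ell[0] / s1
        mu = (np.sqrt(n_eff - 1) + np.sqrt(mprime)) ** 2 / n_eff
        sigma = (
            (np.sqrt(n_eff - 1) + np.sqrt(mprime)) / n_eff
            * (1 / np.sqrt(n_eff - 1) + 1 / np.sqrt(mprime)) ** (1 / 3)
        )
        tw = (x - mu) / sigma
        if tw1_pvalue(tw) >= alpha:
            break
        K += 1
        ell = ell[1:]
    return K


# ---------------------------------------------------------------------------
# latent factor fit


def _center_impute(matrix: GenotypeMatrix) -> np.ndarray:
    G = matrix.genotypes.astype(float)
    G[matrix.genotypes == MISSING] = np.nan
    mu = np.nanmean(G, axis=0)
    inds = np.where(np.isnan(G))
    G[inds] = mu[inds[1]]
    return G - G.mean(axis=0)


def env_to_individuals(matrix: GenotypeMatrix, sites: pd.DataFrame, var: str) -> np.ndarray:
    """Broadcast a site-level climate value to individuals, standardised."""
    lookup = sites.set_index("pop")[var]
    x = np.array([lookup[p] for p in matrix.population_ids], dtype=float)
    if np.ptp(x) == 0:
        raise ValueError(f"no environmental contrast: {var} is constant across sites")
    return (x - x.mean()) / x.std(ddof=0)


def fit_latent_factor_model(
    matrix: GenotypeMatrix,
    env: np.ndarray,
    K: int,
    n_runs: int = 5,
    seed: int = 0,
    n_iter: int = 15,
    ridge: float = 1e-6,
) -> pd.DataFrame:
    """Median per-locus |z| for one environmental variable across runs.

    Each run alternates (i) a randomised truncated SVD of the genotype
    residual after removing the current environmental effect, giving factor
    scores U, with (ii) per-locus least squares of the genotype column on
    [x, U]; ``z_l = b_l / SE(b_l)`` from the final regression. Runs differ
    only in the random subspace initialisation, mirroring a multi-run
    median-|z| design. Returns a DataFrame with ``median_abs_z``, ``z_cv``
    (coefficient of variation of |z| across runs) and ``b_median``.
    """
    if K < 0:
        raise ValueError("K must be >= 0")
    Y = _center_impute(matrix)
    x = np.asarray(env, dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("no environmental contrast")
    n, L = Y.shape
    rng = np.random.default_rng(seed)

    zs = np.empty((n_runs, L))
    bs = np.empty((n_runs, L))
    for run in range(n_runs):
        run_rng = np.random.default_rng(rng.integers(2**31))
        b = np.zeros(L)
        U = np.zeros((n, 0))
        for _ in range(max(n_iter, 1) if K > 0 else 1):
            R = Y - np.outer(x, b)
            if K > 0:
                # randomised range finder: per-run rotation of the sketch
                Omega = run_rng.standard_normal((L, min(K + 4, n)))
                Q, _ = np.linalg.qr(R @ Omega)
                Uu, _s, _Vt = np.linalg.svd(Q.T @ R, full_matrices=False)
                U = Q @ Uu[:, :K]
            X = np.column_stack([x, U])
            XtX = X.T @ X + ridge * np.eye(X.shape[1])
            coefs = np.linalg.solve(XtX, X.T @ Y)
            b = coefs[0]
        # final per-locus OLS of Y_l on [x, U] for b and its SE
        X = np.column_stack([x, U])
        XtX_inv = np.linalg.inv(X.T @ X + ridge * np.eye(X.shape[1]))
        coefs = XtX_inv @ (X.T @ Y)
        resid = Y - X @ coefs
        dof = max(n - X.shape[1] - 1, 1)
        sigma2 = (resid**2).sum(axis=0) / dof
        se = np.sqrt(np.clip(XtX_inv[0, 0] * sigma2, 1e-300, None))
        zs[run] = coefs[0] / se
        bs[run] = coefs[0]

    abs_z = np.abs(zs)
    med = np.median(abs_z, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = np.where(med > 0, abs_z.std(axis=0, ddof=0) / abs_z.mean(axis=0), 0.0)
    return pd.DataFrame(
        {"locus": matrix.locus_ids(), "median_abs_z": med, "z_cv": cv,
         "b_median": np.median(bs, axis=0)}
    )


def genomic_adjust(z: np.ndarray) -> tuple[float, np.ndarray]:
    """Genomic-control rescaling of median |z| scores.

    lambda = median(z^2) / median(chi2_1); adjusted p is the chi2_1 upper
    tail of z^2 / lambda.
    """
    z = np.asarray(z, dtype=float)
    if len(z) < 10:
        raise ValueError("need >= 10 loci for genomic control")
    if np.all(z == 0):
        raise ValueError("degenerate z vector (all zero)")
    lam = float(np.median(z**2) / stats.chi2.ppf(0.5, df=1))
    p_adj = stats.chi2.sf(z**2 / lam, df=1)
    return lam, p_adj


@dataclass
class EaScanResult:
    """Per locus x variable medians, inflation factors and candidate calls."""

    z: pd.DataFrame                 # loci x variables, median |z|
    lam: dict[str, float]
    p_adj: pd.DataFrame             # loci x variables
    candidates: pd.DataFrame        # locus, variable (strongest), median |z|
    significant: pd.DataFrame       # loci x variables bool
    settings: dict = field(default_factory=dict)


def select_candidates(z: pd.DataFrame, p_adj: pd.DataFrame,
                      fdr: float = 0.05) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Benjamini-Hochberg at ``fdr`` within each variable; a locus
    significant for several variables is assigned the one with max |z|."""
    sig = pd.DataFrame(False, index=p_adj.index, columns=p_adj.columns)
    for var in p_adj.columns:
        rej, *_ = multipletests(p_adj[var].to_numpy(), alpha=fdr, method="fdr_bh")
        sig[var] = rej
    rows = []
    for locus in sig.index[sig.any(axis=1)]:
        vars_sig = [v for v in sig.columns if sig.at[locus, v]]
        best = max(vars_sig, key=lambda v: z.at[locus, v])
        rows.append({"locus": locus, "variable": best,
                     "median_abs_z": z.at[locus, best]})
    cand = pd.DataFrame(rows, columns=["locus", "variable", "median_abs_z"])
    return cand, sig


def ea_scan(
    matrix: GenotypeMatrix,
    sites: pd.DataFrame,
    variables: list[str],
    K: int,
    n_runs: int = 5,
    fdr: float = 0.05,
    seed: int = 0,
) -> EaScanResult:
    """Full scan over variables: fit, genomic control, candidate selection."""
    z = {}
    lam = {}
    p_adj = {}
    for i, var in enumerate(variables):
        env = env_to_individuals(matrix, sites, var)
        fit = fit_latent_factor_model(matrix, env, K, n_runs=n_runs,
                                      seed=seed + 1000 * i)
        z[var] = fit.set_index("locus")["median_abs_z"]
        lam[var], p_adj[var] = genomic_adjust(z[var].to_numpy())
    z_df = pd.DataFrame(z)
    p_df = pd.DataFrame({v: p_adj[v] for v in variables}, index=z_df.index)
    cand, sig = select_candidates(z_df, p_df, fdr=fdr)
    return EaScanResult(
        z_df, lam, p_df, cand, sig,
        settings=dict(K=K, n_runs=n_runs, fdr=fdr, seed=seed, variables=variables),
    )
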