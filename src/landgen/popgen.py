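"""Classical population-genetic summaries.

Per-population minor-allele frequencies, unbiased gene diversity (HE) and
FIS, the Weir & Cockerham (1984) FST estimator (per-locus variance
components a, b, c; multilocus ratio-of-sums; pairwise matrices), Rousset's
isolation-by-distance regression of FST/(1-FST) on ln(distance), and a
one-sided Mantel permutation test.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genio import MISSING, GenotypeMatrix

EARTH_RADIUS_KM = 6371.0


# ---------------------------------------------------------------------------
# allele frequencies


@dataclass
class PopAlleleFreq:
    """Populations x loci minor-allele frequencies with per-cell allele counts.

    The minor allele is defined once per locus from the pooled counts over
    all individuals; cells with zero called genotypes are NaN with count 0.
    """

    freq: np.ndarray          # (n_pops, n_loci), NaN where absent
    n_alleles: np.ndarray     # (n_pops, n_loci) called-allele counts (2 x called)
    populations: list[str]
    locus_ids: list[str]
    minor_is_alt: np.ndarray  # (n_loci,) bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.freq, index=self.populations, columns=self.locus_ids)


def _pop_blocks(matrix: GenotypeMatrix) -> tuple[list[str], list[np.ndarray]]:
    pops = matrix.populations
    idx = [np.array([i for i, p in enumerate(matrix.population_ids) if p == pop])
           for pop in pops]
    return pops, idx


def pop_allele_freqs(matrix: GenotypeMatrix) -> PopAlleleFreq:
    """Per-population frequency of the globally minor allele at each locus."""
    pops, blocks = _pop_blocks(matrix)
    G = matrix.genotypes
    called = G != MISSING
    alt_total = np.where(called, G, 0).sum(axis=0).astype(np.int64)
    allele_total = 2 * called.sum(axis=0).astype(np.int64)
    with np.errstate(invalid="ignore"):
        pooled_alt = alt_total / allele_total
    minor_is_alt = pooled_alt <= 0.5  # tie at 0.5 -> alt by convention

    freq = np.full((len(pops), matrix.n_loci), np.nan)
    n_alleles = np.zeros((len(pops), matrix.n_loci), dtype=np.int64)
    for j, rows in enumerate(blocks):
        g = G[rows]
        c = g != MISSING
        alt = np.where(c, g, 0).sum(axis=0)
        tot = 2 * c.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            f_alt = np.where(tot > 0, alt / np.maximum(tot, 1), np.nan)
        freq[j] = np.where(minor_is_alt, f_alt, 1.0 - f_alt)
        n_alleles[j] = tot
    return PopAlleleFreq(freq, n_alleles, pops, matrix.locus_ids(), minor_is_alt)


# ---------------------------------------------------------------------------
# diversity and FIS


def diversity_fis(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Per-population unbiased gene diversity and FIS.

    HE per locus is the sample-size-corrected gene diversity
    ``2n/(2n-1) * (1 - p^2 - q^2)`` over called alleles; the population value
    is its mean over loci. FIS = 1 - sum(HO)/sum(HE) over loci
    (ratio-of-sums), the within-population heterozygote deficit.
    """
    pops, blocks = _pop_blocks(matrix)
    rows = []
    for pop, sel in zip(pops, blocks):
        g = matrix.genotypes[sel]
        called = g != MISSING
        n_ind = called.sum(axis=0)
        ok = n_ind >= 2
        if not ok.any():
            raise ValueError(f"population {pop} has <2 called individuals at every locus")
        g, called, n_ind = g[:, ok], called[:, ok], n_ind[ok]
        p = np.where(called, g, 0).sum(axis=0) / (2 * n_ind)
        two_n = 2 * n_ind
        he = two_n / (two_n - 1) * (1.0 - p**2 - (1 - p) ** 2)
        ho = np.where(called, g == 1, False).sum(axis=0) / n_ind
        he_sum = he.sum()
        fis = 1.0 - ho.sum() / he_sum if he_sum > 0 else np.nan
        rows.append({"pop": pop, "HE": he.mean(), "HO": ho.mean(), "FIS": fis,
                     "n_loci": int(ok.sum())})
    df = pd.DataFrame(rows).set_index("pop")
    df.attrs["HE_mean"], df.attrs["HE_sd"] = float(df["HE"].mean()), float(df["HE"].std())
    return df


# ---------------------------------------------------------------------------
# Weir & Cockerham FST


@dataclass
class FstResult:
    """Weir-Cockerham variance components and derived FST estimates."""

    a: np.ndarray            # among-population component, per locus
    b: np.ndarray            # among-individual-within-population
    c: np.ndarray            # within-individual
    locus_ids: list[str]
    populations: list[str]
    pairwise: pd.DataFrame | None = None

    @property
    def per_locus_fst(self) -> np.ndarray:
        denom = self.a + self.b + self.c
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(denom != 0, self.a / denom, np.nan)

    @property
    def multilocus_fst(self) -> float:
        denom = self.a + self.b + self.c
        ok = np.isfinite(denom) & (denom != 0)
        return float(self.a[ok].sum() / denom[ok].sum())


def _wc_components(matrix: GenotypeMatrix, loci_subset=None):
    """Vectorised Weir & Cockerham (1984) a, b, c for diallelic loci."""
    pops, blocks = _pop_blocks(matrix)
    G = matrix.genotypes
    if loci_subset is not None:
        G = G[:, loci_subset]
    r_max, L = len(pops), G.shape[1]

    n = np.zeros((r_max, L))        # called individuals per pop per locus
    p = np.zeros((r_max, L))        # alt-allele frequency
    h = np.zeros((r_max, L))        # observed heterozygote proportion
    for j, sel in enumerate(blocks):
        g = G[sel]
        called = g != MISSING
        nj = called.sum(axis=0)
        n[j] = nj
        with np.errstate(invalid="ignore", divide="ignore"):
            p[j] = np.where(nj > 0, np.where(called, g, 0).sum(axis=0) / (2 * np.maximum(nj, 1)), 0.0)
            h[j] = np.where(nj > 0, np.where(called, g == 1, False).sum(axis=0) / np.maximum(nj, 1), 0.0)

    present = n > 0
    r = present.sum(axis=0).astype(float)            # populations with data
    n_tot = n.sum(axis=0)
    valid = (r >= 2) & (n_tot > r)                    # need n_bar > 1
    nbar = n_tot / np.maximum(r, 1)
    sum_n2 = (n**2).sum(axis=0)
    nc = (n_tot - sum_n2 / np.maximum(n_tot, 1)) / np.maximum(r - 1, 1)
    pbar = (n * p).sum(axis=0) / np.maximum(n_tot, 1)
    s2 = (n * (p - pbar) ** 2).sum(axis=0) / np.maximum((r - 1) * nbar, 1e-12)
    hbar = (n * h).sum(axis=0) / np.maximum(n_tot, 1)

    pq = pbar * (1 - pbar)
    a = (nbar / np.maximum(nc, 1e-12)) * (
        s2 - (pq - (r - 1) / r * s2 - hbar / 4) / np.maximum(nbar - 1, 1e-12)
    )
    b = (nbar / np.maximum(nbar - 1, 1e-12)) * (
        pq - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2

    # monomorphic across included pops: all components zero (excluded later)
    mono = pq + hbar == 0
    for arr in (a, b, c):
        arr[mono | ~valid] = 0.0
    return a, b, c


def wc_fst(matrix: GenotypeMatrix, loci_subset=None, pairwise: bool = False) -> FstResult:
    """Weir-Cockerham FST: per-locus components, multilocus ratio-of-sums,
    and optionally the pairwise population matrix."""
    pops = matrix.populations
    if len(pops) < 2:
        raise ValueError("need >= 2 populations")
    a, b, c = _wc_components(matrix, loci_subset)
    ids = matrix.locus_ids()
    if loci_subset is not None:
        sub = np.asarray(loci_subset)
        if sub.dtype == bool:
            sub = np.flatnonzero(sub)
        ids = [ids[i] for i in sub]
    result = FstResult(a, b, c, ids, pops)

    if pairwise:
        P = len(pops)
        M = np.zeros((P, P))
        pop_arr = np.array(matrix.population_ids)
        for i in range(P):
            for j in range(i + 1, P):
                keep = np.isin(pop_arr, [pops[i], pops[j]])
                sub_m = matrix.subset_individuals(keep)
                aij, bij, cij = _wc_components(sub_m, loci_subset)
                denom = aij + bij + cij
                ok = denom != 0
                M[i, j] = M[j, i] = aij[ok].sum() / denom[ok].sum()
        result.pairwise = pd.DataFrame(M, index=pops, columns=pops)
    return result


# ---------------------------------------------------------------------------
# distances, IBD, Mantel


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in km on a sphere of radius 6371 km."""
    lat1, lon1, lat2, lon2 = map(np.radians, (lat1, lon1, lat2, lon2))
    dlat, dlon = lat2 - lat1, lon2 - lon1
    h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(h))


def geo_distance_matrix(sites: pd.DataFrame) -> np.ndarray:
    """Symmetric haversine distance matrix (km) between site coordinates."""
    lat = sites["lat"].to_numpy(dtype=float)
    lon = sites["lon"].to_numpy(dtype=float)
    D = haversine_km(lat[:, None], lon[:, None], lat[None, :], lon[None, :])
    np.fill_diagonal(D, 0.0)
    off = ~np.eye(len(D), dtype=bool)
    if np.any(D[off] == 0):
        raise ValueError("duplicate coordinates: zero distance between distinct sites")
    return D


@dataclass
class IbdResult:
    slope: float
    intercept: float
    r_regression: float
    mantel_z: float
    mantel_r: float
    mantel_p: float
    n_permutations: int
    seed: int


def _offdiag(M: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(M.shape[0], k=1)
    return M[iu]


def mantel_test(A: np.ndarray, B: np.ndarray, n_perm: int = 9999,
                seed: int = 0) -> tuple[float, float, float]:
    """One-sided (greater) Mantel test between two symmetric matrices.

    z is the sum over unordered pairs of products of corresponding cells;
    r is the Pearson correlation of the off-diagonal vectors;
    p = (1 + #{permuted z >= observed}) / (1 + n_perm) under simultaneous
    random row/column permutations of one matrix.
    """
    A, B = np.asarray(A, float), np.asarray(B, float)
    x, y = _offdiag(A), _offdiag(B)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("degenerate Mantel input: a matrix is constant off-diagonal")
    z_obs = float(x @ y)
    r = float(np.corrcoef(x, y)[0, 1])
    rng = np.random.default_rng(seed)
    n = A.shape[0]
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        z_perm = float(_offdiag(A[np.ix_(perm, perm)]) @ y)
        if z_perm >= z_obs:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return z_obs, r, p


def ibd_mantel(fst: FstResult, sites: pd.DataFrame, n_perm: int = 9999,
               seed: int = 0) -> IbdResult:
    """Isolation-by-distance: FST/(1-FST) ~ ln(km) regression + Mantel test."""
    if fst.pairwise is None:
        raise ValueError("pairwise FST matrix required (run wc_fst(pairwise=True))")
    if len(sites) < 4:
        raise ValueError("need >= 4 populations for IBD")
    sites = sites.set_index("pop").loc[fst.populations].reset_index()
    D = geo_distance_matrix(sites)
    F = fst.pairwise.to_numpy(copy=True)
    lin = F / (1.0 - F)
    logD = np.zeros_like(D)
    off = ~np.eye(len(D), dtype=bool)
    logD[off] = np.log(D[off])

    x, y = _offdiag(logD), _offdiag(lin)
    reg = stats.linregress(x, y)
    z, r, p = mantel_test(logD, lin, n_perm=n_perm, seed=seed)
    return IbdResult(float(reg.slope), float(reg.intercept), float(reg.rvalue),
                     z, r, p, n_perm, seed)
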