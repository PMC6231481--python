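"""Moran's eigenvector maps (PCNM) from site coordinates.

Spatial eigenfunctions are built from the truncated geographic distance
matrix: distances beyond the minimum-spanning-tree threshold ``t`` are
replaced by ``4t``, the matrix ``-0.5 * D*^2`` is Gower double-centered, and
the eigenvectors with positive eigenvalues form an orthonormal spatial
basis. The leading ("broad-scale") half of the basis serves as spatial
predictors for turnover modelling.
"""
from __future__ import annotations

from dataclasses import dataclass
from math import ceil

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import minimum_spanning_tree

from .popgen import geo_distance_matrix  # noqa: F401  (re-exported; shared geometry)

POSITIVE_EIG_RTOL = 1e-10


@dataclass
class MEMBasis:
    """Orthonormal spatial eigenfunctions with positive eigenvalues.

    ``vectors[:, k]`` is MEM-(k+1); eigenvalues are in descending order and
    ``truncation`` is the MST-derived distance threshold t.
    """

    vectors: np.ndarray       # (n_sites, m)
    eigenvalues: np.ndarray   # (m,), descending, all positive
    truncation: float
    site_ids: list[str]

    @property
    def m(self) -> int:
        return len(self.eigenvalues)

    def names(self) -> list[str]:
        return [f"MEM-{k + 1}" for k in range(self.m)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.vectors, index=self.site_ids, columns=self.names())


def build_mem(distances: np.ndarray, site_ids: list[str] | None = None) -> MEMBasis:
    """Build the PCNM basis from a symmetric distance matrix.

    Truncation t = longest edge of the minimum spanning tree; D > t is
    replaced by 4t; B = -0.5 * C D*^2 C with C the centering matrix; the
    eigenvectors of B with eigenvalue above ``POSITIVE_EIG_RTOL * max``
    are retained in descending eigenvalue order.
    """
    D = np.asarray(distances, dtype=float)
    n = D.shape[0]
    if n < 4:
        raise ValueError("need >= 4 sites for a spatial basis")
    if site_ids is None:
        site_ids = [f"site{i + 1}" for i in range(n)]

    mst = minimum_spanning_tree(D).toarray()
    t = float(mst.max())
    if t <= 0:
        raise ValueError("degenerate distances: minimum spanning tree has no extent")
    Dstar = np.where(D > t, 4.0 * t, D)
    np.fill_diagonal(Dstar, 0.0)

    C = np.eye(n) - np.full((n, n), 1.0 / n)
    B = -0.5 * C @ (Dstar**2) @ C
    B = (B + B.T) / 2
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > POSITIVE_EIG_RTOL * vals.max()
    if not pos.any():
        raise ValueError("no positive eigenvalues: degenerate configuration")
    # deterministic sign: make the largest-magnitude loading positive
    vecs = vecs[:, pos]
    for k in range(vecs.shape[1]):
        j = np.argmax(np.abs(vecs[:, k]))
        if vecs[j, k] < 0:
            vecs[:, k] = -vecs[:, k]
    return MEMBasis(vecs, vals[pos], t, site_ids)


def select_broad_scale(basis: MEMBasis) -> pd.DataFrame:
    """First half (ceiling) of the positive eigenfunctions, largest first."""
    k = ceil(basis.m / 2)
    return basis.to_frame().iloc[:, :k]


def mem_predictors(sites: pd.DataFrame) -> pd.DataFrame:
    """Convenience: haversine distances -> MEM basis -> broad-scale subset."""
    D = geo_distance_matrix(sites)
    basis = build_mem(D, site_ids=list(sites["pop"]))
    return select_broad_scale(basis)
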