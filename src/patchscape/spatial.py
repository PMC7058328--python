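"""Spatial autocorrelation diagnostics and the PCNM autocovariate.

Model residuals (conditional-occupancy residuals from the occupancy fit)
are tested for spatial autocorrelation with Global Moran's I under a
permutation null. When significant autocorrelation is found, a spatial
autocovariate is built by principal coordinates of neighbour matrices
(PCNM): the pairwise distance matrix is truncated at the longest edge of
the minimum spanning tree, double-centered, and eigen-decomposed; the
positive-eigenvalue eigenvector most correlated (Spearman) with the
residuals becomes one extra occupancy covariate.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse, stats
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "MoranResult",
    "PCNMResult",
    "global_morans_i",
    "pcnm",
    "pcnm_autocovariate",
]


@dataclass
class MoranResult:
    I: float
    expected: float
    p_value: float
    n_permutations: int


def global_morans_i(
    residuals,
    coords,
    n_permutations: int = 999,
    seed: int = 0,
) -> MoranResult:
    """Global Moran's I with inverse-distance weights and a permutation test.

    ``I = (n / S0) * Σ_ij w_ij (r_i - r̄)(r_j - r̄) / Σ_i (r_i - r̄)²`` with
    ``w_ij = 1 / d_ij`` off-diagonal. The two-sided p-value counts permuted
    statistics at least as far from the null expectation ``−1/(n−1)`` as
    the observed one (add-one correction).
    """
    r = np.asarray(residuals, dtype=float)
    coords = np.asarray(coords, dtype=float)
    n = r.size
    if n < 4:
        raise ValueError("need at least 4 sites")
    if not np.isfinite(r).all():
        raise ValueError("residuals must be finite")
    rc = r - r.mean()
    denom = float(rc @ rc)
    if denom == 0:
        raise ValueError("constant residuals: Moran's I undefined")
    D = squareform(pdist(coords))
    if np.any(D[np.triu_indices(n, 1)] == 0):
        raise ValueError("coincident site coordinates")
    with np.errstate(divide="ignore"):
        W = 1.0 / D
    np.fill_diagonal(W, 0.0)
    S0 = W.sum()

    def moran(x: np.ndarray) -> float:
        xc = x - x.mean()
        return float(n / S0 * (xc @ W @ xc) / (xc @ xc))

    I_obs = moran(r)
    expected = -1.0 / (n - 1)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        Ib = moran(rng.permutation(r))
        if abs(Ib - expected) >= abs(I_obs - expected):
            count += 1
    p = (count + 1) / (n_permutations + 1)
    return MoranResult(I=I_obs, expected=expected, p_value=p, n_permutations=n_permutations)


@dataclass
class PCNMResult:
    eigenvalues: np.ndarray  # positive eigenvalues, descending
    vectors: np.ndarray      # (n, k) unit-norm eigenvectors, same order
    threshold: float         # truncation distance (longest MST edge)


def pcnm(coords) -> PCNMResult:
    """Spatial eigenvectors from the truncated pairwise distance matrix.

    Distances beyond the truncation threshold ``t`` (the longest edge of
    the minimum spanning tree over sites) are replaced by ``4t``; the
    matrix ``−D²/2`` is double-centered (Gower) and eigen-decomposed.
    Eigenvectors with positive eigenvalues are retained, sorted by
    descending eigenvalue.
    """
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    if n < 4:
        raise ValueError("need at least 4 sites")
    D = squareform(pdist(coords))
    off = D[np.triu_indices(n, 1)]
    if np.allclose(off, off[0]):
        raise ValueError("all pairwise distances equal: PCNM undefined")
    mst = sparse.csgraph.minimum_spanning_tree(D)
    t = float(mst.data.max())
    Dt = D.copy()
    Dt[D > t] = 4.0 * t
    np.fill_diagonal(Dt, 0.0)
    A = -0.5 * Dt ** 2
    H = np.eye(n) - np.ones((n, n)) / n
    G = H @ A @ H
    w, v = np.linalg.eigh((G + G.T) / 2.0)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    keep = w > max(1e-12, abs(w).max() * 1e-10)
    if not keep.any():
        raise ValueError("no positive PCNM eigenvalue")
    return PCNMResult(eigenvalues=w[keep], vectors=v[:, keep], threshold=t)


def pcnm_autocovariate(coords, residuals) -> tuple[np.ndarray, PCNMResult, int, float]:
    """The single PCNM eigenvector best matching the residual pattern.

    Returns ``(autocovariate, pcnm_result, index, rho)`` where ``index``
    is the position of the chosen eigenvector among the retained ones and
    ``rho`` its Spearman correlation with the residuals.
    """
    res = pcnm(coords)
    r = np.asarray(residuals, dtype=float)
    rhos = np.array(
        [stats.spearmanr(res.vectors[:, j], r).statistic for j in range(res.vectors.shape[1])]
    )
    j = int(np.nanargmax(np.abs(rhos)))
    return res.vectors[:, j], res, j, float(rhos[j])
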