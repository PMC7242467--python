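"""Spatial eigenfunctions and matrix-correlation tests.

PCNM (principal coordinates of neighbour matrices) turns a geographic
distance matrix into orthogonal spatial eigenvectors: distances beyond a
truncation threshold (by default the longest edge of the minimum spanning
tree) are replaced by four times the threshold, the matrix is
double-centered and eigendecomposed, and axes with positive eigenvalues are
kept. The partial Mantel test correlates two distance matrices after
removing the (triangle-wise) linear effect of a third.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import skbio
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import pdist, squareform

from . import _stats

logger = logging.getLogger(__name__)


@dataclass
class MantelResult:
    r: float
    p_value: float
    n_permutations: int
    method: str
    conditioned: bool = False


@dataclass
class PcnmAxes:
    """Positive spatial eigenvectors of a truncated distance matrix."""

    axes: pd.DataFrame  # samples x axes, principal-coordinate scaling
    eigenvalues: np.ndarray  # positive, descending
    truncation: float


def mantel(
    d1: skbio.DistanceMatrix,
    d2: skbio.DistanceMatrix,
    method: str = "pearson",
    n_permutations: int = 999,
    seed: int | None = None,
    *,
    alternative: str = "two-sided",
) -> MantelResult:
    """Matrix correlation with a label-permutation Mantel test."""
    a, b = _stats.align_ids(d1, d2)
    r, p = _stats.mantel_correlation(
        a,
        b,
        method=method,
        n_permutations=n_permutations,
        seed=seed,
        alternative=alternative,
    )
    return MantelResult(r, p, n_permutations, method)


def _residualize(y: np.ndarray, z: np.ndarray) -> np.ndarray:
    design = np.column_stack([np.ones_like(z), z])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    return resid


def partial_mantel(
    d1: skbio.DistanceMatrix,
    d2: skbio.DistanceMatrix,
    d3: skbio.DistanceMatrix,
    method: str = "pearson",
    n_permutations: int = 999,
    seed: int | None = None,
    *,
    alternative: str = "two-sided",
) -> MantelResult:
    """Correlation of d1 and d2 controlling for d3 (residual method).

    Both triangles are residualised on d3's triangle (after ranking, for
    ``method="spearman"``); significance permutes d1's sample labels and
    re-residualises before correlating.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")
    a, b, c = _stats.align_ids(d1, d2, d3)
    n = a.shape[0]
    if n < 4:
        raise ValueError("need at least 4 samples")
    if method == "spearman":
        a, b, c = (_stats.rank_square(m) for m in (a, b, c))
    il, jl = np.tril_indices(n, k=-1)
    z = c[il, jl]
    if np.ptp(z) == 0:
        raise ValueError("conditioning matrix has zero triangle variance")
    ry = _residualize(b[il, jl], z)
    rx = _residualize(a[il, jl], z)
    if np.allclose(rx, 0) or np.allclose(ry, 0):
        raise ValueError("conditioning matrix is collinear with an input")
    r_obs = _stats._pearson(rx, ry)
    if n_permutations <= 0:
        return MantelResult(r_obs, float("nan"), 0, method, conditioned=True)
    if seed is None:
        raise ValueError("seed is required for the permutation test")
    rng = np.random.default_rng(seed)
    perms = np.empty(n_permutations)
    for t in range(n_permutations):
        idx = rng.permutation(n)
        xp = a[idx[:, None], idx[None, :]][il, jl]
        perms[t] = _stats._pearson(_residualize(xp, z), ry)
    p = _stats.permutation_pvalue(r_obs, perms, alternative)
    return MantelResult(r_obs, p, n_permutations, method, conditioned=True)


def pcnm(
    geo: skbio.DistanceMatrix, truncation: float | None = None
) -> PcnmAxes:
    """Spatial eigenvectors from a truncated geographic distance matrix.

    ``truncation=None`` uses the longest edge of the minimum spanning tree,
    the standard choice that keeps the neighbour graph connected. Axes are
    returned in principal-coordinate scaling (eigenvector times the square
    root of its eigenvalue), orthogonal by construction, and sign-fixed so
    the entry of largest magnitude is positive.
    """
    d = _stats.as_square(geo)
    n = d.shape[0]
    if n < 3:
        raise ValueError("need at least 3 samples for PCNM")
    if truncation is None:
        mst = minimum_spanning_tree(d)
        truncation = float(mst.data.max())
    if truncation <= 0:
        raise ValueError("truncation threshold must be positive")
    w = np.where(d > truncation, 4.0 * truncation, d)
    np.fill_diagonal(w, 0.0)
    a = -0.5 * w**2
    centering = np.eye(n) - np.ones((n, n)) / n
    g = centering @ a @ centering
    g = 0.5 * (g + g.T)
    eigval, eigvec = np.linalg.eigh(g)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = max(abs(eigval[0]), abs(eigval[-1])) * 1e-10
    keep = eigval > tol
    eigval, eigvec = eigval[keep], eigvec[:, keep]
    scores = eigvec * np.sqrt(eigval)
    for k in range(scores.shape[1]):  # reproducible up to sign -> fix sign
        imax = int(np.argmax(np.abs(scores[:, k])))
        if scores[imax, k] < 0:
            scores[:, k] = -scores[:, k]
    ids = list(geo.ids) if isinstance(geo, skbio.DistanceMatrix) else list(range(n))
    axes = pd.DataFrame(
        scores,
        index=ids,
        columns=[f"PCNM{i + 1}" for i in range(scores.shape[1])],
    )
    return PcnmAxes(axes=axes, eigenvalues=eigval, truncation=float(truncation))


def pcnm_distance(axes: PcnmAxes) -> skbio.DistanceMatrix:
    """Euclidean distance between samples in retained-PCNM space.

    Condenses the spatial eigenvectors into a single spatial distance
    matrix, the conditioning/input matrix for (partial) Mantel tests.
    """
    scores = axes.axes.to_numpy()
    return skbio.DistanceMatrix(
        squareform(pdist(scores)), ids=list(axes.axes.index)
    )


def vif_filter(
    env: pd.DataFrame, threshold: float = 10.0
) -> tuple[list[str], pd.Series]:
    """Iteratively drop the most collinear variable until all VIF <= threshold.

    ``VIF_j = 1 / (1 - R^2_j)`` from regressing variable j on the others
    (with intercept). Removal is worst-first; ties break by column order.
    Returns the retained column names and their final VIFs.
    """
    if env.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    x = env.apply(pd.to_numeric, errors="coerce")
    if x.isna().any().any():
        bad = x.columns[x.isna().any()].tolist()
        raise ValueError(f"non-numeric values in variables: {bad}")
    sd = x.std(ddof=0)
    constant = sd.index[sd == 0].tolist()
    if constant:
        raise ValueError(f"constant (zero-variance) variables: {constant}")

    def vif_of(col: str, cols: list[str]) -> float:
        others = [c for c in cols if c != col]
        if not others:
            return 1.0
        y = x[col].to_numpy(dtype=float)
        design = np.column_stack(
            [np.ones(len(y))] + [x[c].to_numpy(dtype=float) for c in others]
        )
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot
        if r2 >= 1.0 - 1e-12:
            return float("inf")
        return 1.0 / (1.0 - r2)

    cols = list(x.columns)
    while True:
        vifs = pd.Series({c: vif_of(c, cols) for c in cols})
        if len(cols) == 1 or vifs.max() <= threshold:
            return cols, vifs[cols]
        worst = vifs.idxmax()  # first occurrence wins on ties (column order)
        logger.info("removing %s (VIF=%.3g)", worst, vifs[worst])
        cols.remove(worst)
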