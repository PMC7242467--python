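"""Shared permutation-test machinery for matrix correlations.

Matrix-correlation p-values here follow the Mantel convention: the rows and
columns of one matrix are jointly permuted (sample-label permutation), never
the pairs themselves, because pairwise distances are not exchangeable. The
permutation p-value is ``(1 + #{perm stat >= observed}) / (1 + n_perm)`` so
its floor is ``1/(n_perm + 1)``.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import permutations as _permutations

import numpy as np
import skbio
from scipy.stats import rankdata

#: float tolerance when comparing permuted to observed statistics
TIE_EPS = 1e-12


def as_square(dm) -> np.ndarray:
    if isinstance(dm, skbio.DistanceMatrix):
        return np.asarray(dm.data, dtype=float)
    arr = np.asarray(dm, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError("expected a square distance matrix")
    return arr


def align_ids(*dms: skbio.DistanceMatrix) -> list[np.ndarray]:
    """Reorder matrices to the first matrix's id order; ids must match."""
    ref = list(dms[0].ids)
    out = []
    for dm in dms:
        if set(dm.ids) != set(ref):
            raise ValueError(
                f"distance matrix ids do not match: {sorted(set(dm.ids) ^ set(ref))[:10]}"
            )
        out.append(np.asarray(dm.filter(ref).data, dtype=float))
    return out


def condensed(square: np.ndarray) -> np.ndarray:
    """Lower-triangle (off-diagonal) entries as a vector."""
    i, j = np.tril_indices(square.shape[0], k=-1)
    return square[i, j]


def rank_square(square: np.ndarray) -> np.ndarray:
    """Square matrix whose off-diagonal entries are replaced by their ranks.

    Because a label permutation only rearranges which unordered pair each
    triangle slot holds, ranking once and gathering per permutation yields
    exactly the Spearman ranks of the permuted triangle.
    """
    n = square.shape[0]
    i, j = np.tril_indices(n, k=-1)
    ranks = rankdata(square[i, j])
    out = np.zeros((n, n))
    out[i, j] = ranks
    out[j, i] = ranks
    return out


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        raise ValueError("zero variance in a distance-matrix triangle")
    return float((xc @ yc) / denom)


def permutation_pvalue(
    observed: float, permuted: np.ndarray, alternative: str
) -> float:
    n = len(permuted)
    if alternative == "greater":
        hits = int(np.sum(permuted >= observed - TIE_EPS))
    elif alternative == "less":
        hits = int(np.sum(permuted <= observed + TIE_EPS))
    elif alternative == "two-sided":
        hits = int(np.sum(np.abs(permuted) >= abs(observed) - TIE_EPS))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return (1 + hits) / (1 + n)


def mantel_correlation(
    a: np.ndarray,
    b: np.ndarray,
    method: str = "pearson",
    *,
    n_permutations: int = 999,
    seed: int | None = None,
    alternative: str = "two-sided",
) -> tuple[float, float]:
    """Correlation between two aligned square matrices with a Mantel test.

    Returns ``(r, p)``. For ``method="spearman"`` the triangles are ranked
    once and label permutations gather the pre-ranked entries.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")
    n = a.shape[0]
    if n < 4:
        raise ValueError("need at least 4 samples for a Mantel-type test")
    if method == "spearman":
        a_use, b_use = rank_square(a), rank_square(b)
    else:
        a_use, b_use = a, b
    x = condensed(a_use)
    r_obs = _pearson(x, condensed(b_use))
    if n_permutations <= 0:
        return r_obs, float("nan")
    if seed is None:
        raise ValueError("seed is required when permutations are requested")
    rng = np.random.default_rng(seed)
    il, jl = np.tril_indices(n, k=-1)
    perms = np.empty(n_permutations)
    for t in range(n_permutations):
        idx = rng.permutation(n)
        perms[t] = _pearson(x, b_use[idx[:, None], idx[None, :]][il, jl])
    return r_obs, permutation_pvalue(r_obs, perms, alternative)


@lru_cache(maxsize=8)
def exact_spearman_d2_distribution(n: int) -> np.ndarray:
    """Sorted exact null distribution of ``sum d_i^2`` for tie-free ranks.

    The Spearman statistic for tie-free data is a monotone function of the
    integer ``sum of squared rank differences``, so the exact permutation
    p-value reduces to integer comparisons against this distribution,
    computed once per sample count.
    """
    base = np.arange(n)
    vals = np.fromiter(
        (int(((np.array(p) - base) ** 2).sum()) for p in _permutations(range(n))),
        dtype=np.int64,
    )
    return np.sort(vals)


def exact_spearman_pvalue(rank_x: np.ndarray, rank_y: np.ndarray) -> float:
    """Two-sided exact Spearman p for tie-free integer ranks (small n)."""
    n = len(rank_x)
    d2 = int(((rank_x - rank_y) ** 2).sum())
    dist = exact_spearman_d2_distribution(n)
    m = n * (n * n - 1) // 3  # max of sum d^2; distribution symmetric about m/2
    mirror = m - d2
    lo, hi = min(d2, mirror), max(d2, mirror)
    hits = int(np.searchsorted(dist, lo, side="right"))
    hits += len(dist) - int(np.searchsorted(dist, hi, side="left"))
    return min(1.0, hits / len(dist))
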