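"""Shared rank statistics used across the pipeline.

The Spearman screen is implemented once, as a vectorised Pearson correlation of
average ranks (tie-corrected by construction) with the usual t-approximation on
n - 2 degrees of freedom for two-sided p-values. Pairwise operations (target
linking, ATAC coupling) reuse the same implementation so every reported rho is
numerically identical across stages.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

__all__ = [
    "spearman_matrix",
    "spearman_pair",
    "mann_whitney_greater",
    "hypergeom_tail",
    "bh_adjust",
]


def _rank_rows(a: np.ndarray) -> np.ndarray:
    return sps.rankdata(a, axis=1)


def _t_sf_two_sided(rho: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p from the t-approximation on n-2 df; rho = +/-1 -> p = 0."""
    rho = np.asarray(rho, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * sps.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(rho) >= 1.0, 0.0, p)
    p = np.where(np.isnan(rho), np.nan, p)
    return p


def spearman_matrix(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs Spearman rho and two-sided p between rows of ``x`` and rows of ``y``.

    Parameters
    ----------
    x : (p, n) array — e.g. TF expression rows.
    y : (q, n) array — e.g. CpG methylation rows.

    Returns
    -------
    rho, p : (p, q) arrays. Rows with zero variance yield NaN rho and NaN p
    (degenerate pairs are never significant downstream).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 2 or y.ndim != 2 or x.shape[1] != y.shape[1]:
        raise ValueError("x and y must be 2-D with the same number of columns")
    n = x.shape[1]
    if n < 3:
        raise ValueError("need at least 3 samples")
    rx = _rank_rows(x)
    ry = _rank_rows(y)
    rx = rx - rx.mean(axis=1, keepdims=True)
    ry = ry - ry.mean(axis=1, keepdims=True)
    nx = np.linalg.norm(rx, axis=1)
    ny = np.linalg.norm(ry, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = (rx @ ry.T) / np.outer(nx, ny)
    rho[np.isclose(nx, 0.0), :] = np.nan
    rho[:, np.isclose(ny, 0.0)] = np.nan
    rho = np.clip(rho, -1.0, 1.0, out=rho)
    return rho, _t_sf_two_sided(rho, n)


def spearman_pair(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rho/p for one pair of vectors with pairwise-complete observations.

    Returns ``(nan, nan)`` when fewer than 3 complete pairs remain or either
    vector is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = ~(np.isnan(x) | np.isnan(y))
    if mask.sum() < 3:
        return float("nan"), float("nan")
    rho, p = spearman_matrix(x[mask][None, :], y[mask][None, :])
    return float(rho[0, 0]), float(p[0, 0])


def mann_whitney_greater(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """One-sided Mann-Whitney U test (alternative: ``x`` stochastically greater).

    Exact null enumeration when ``min(n1, n2) <= 8`` and there are no ties;
    otherwise the normal approximation with tie and continuity corrections.

    Returns
    -------
    (U, p); ``(nan, nan)`` when either group is empty.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if len(x) == 0 or len(y) == 0:
        return float("nan"), float("nan")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (min(len(x), len(y)) <= 8 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(
        x, y, alternative="greater", method=method, use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


def hypergeom_tail(k: int, population: int, successes: int, draws: int) -> float:
    """Upper hypergeometric tail P(X >= k) for overlap/enrichment tests."""
    if k <= 0:
        return 1.0
    return float(sps.hypergeom.sf(k - 1, population, successes, draws))


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (NaN passed through)."""
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if mask.sum() == 0:
        return out
    from statsmodels.stats.multitest import multipletests

    out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out
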