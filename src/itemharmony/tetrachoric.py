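"""Tetrachoric correlations for binary item pairs.

The tetrachoric correlation is the correlation of the latent bivariate
normal assumed to underlie a 2x2 table. Estimation here is the standard
two-step maximum likelihood: thresholds fixed at the normal quantiles of
the margins, then the table's multinomial likelihood maximized over the
correlation, with a 0.5 continuity correction added to every cell when
any cell is zero.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import optimize, stats

from .core import is_missing

__all__ = ["tetrachoric_from_table", "pair_table", "tetrachoric_matrix"]


def _bvn_cdf(h: float, k: float, rho: float) -> float:
    """P(X <= h, Y <= k) for standard bivariate normal with correlation rho."""
    cov = np.array([[1.0, rho], [rho, 1.0]])
    return float(
        stats.multivariate_normal(mean=[0.0, 0.0], cov=cov, allow_singular=True).cdf([h, k])
    )


def table_loglik(table: np.ndarray, rho: float) -> float:
    """Multinomial log-likelihood of a 2x2 table under the latent-normal model.

    ``table[i, j]`` counts respondents with (item1 = i, item2 = j),
    i, j in {0, 1}. Thresholds come from the table's own margins.
    """
    t = np.asarray(table, dtype=float)
    n = t.sum()
    p1 = (t[1, 0] + t[1, 1]) / n  # P(item1 = 1)
    p2 = (t[0, 1] + t[1, 1]) / n
    h = stats.norm.ppf(1.0 - p1)  # item1 = 1 iff latent > h
    k = stats.norm.ppf(1.0 - p2)
    p00 = _bvn_cdf(h, k, rho)
    p01 = stats.norm.cdf(h) - p00
    p10 = stats.norm.cdf(k) - p00
    p11 = 1.0 - p00 - p01 - p10
    probs = np.array([[p00, p01], [p10, p11]])
    probs = np.clip(probs, 1e-12, 1.0)
    return float((t * np.log(probs)).sum())


def tetrachoric_from_table(table) -> float:
    """ML tetrachoric correlation of a 2x2 contingency table.

    Zero cells get a 0.5 continuity correction (applied to all cells to
    preserve the table's structure). Degenerate tables -- an empty margin
    -- return NaN.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("expected a non-negative 2x2 table")
    if np.any(t == 0):
        t = t + 0.5
    margins = [t[0].sum(), t[1].sum(), t[:, 0].sum(), t[:, 1].sum()]
    if min(margins) <= 0:
        return float("nan")
    res = optimize.minimize_scalar(
        lambda r: -table_loglik(t, r),
        bounds=(-0.999, 0.999),
        method="bounded",
        options={"xatol": 1e-6},
    )
    return float(res.x)


def pair_table(x, y) -> np.ndarray:
    """2x2 cross-table of two binary vectors over pairwise-complete cases."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~is_missing(x) & ~is_missing(y)
    xi = x[ok].astype(int)
    yi = y[ok].astype(int)
    t = np.zeros((2, 2))
    for i in (0, 1):
        for j in (0, 1):
            t[i, j] = np.sum((xi == i) & (yi == j))
    return t


def tetrachoric_matrix(responses, item_names=None, min_overlap: int = 20) -> np.ndarray:
    """Pairwise tetrachoric correlation matrix of a binary response matrix.

    Pairs with fewer than ``min_overlap`` joint observations, or with an
    empty margin even after continuity correction, get NaN (and a logged
    warning). Diagonal is 1.
    """
    X = np.asarray(responses, dtype=float)
    n_items = X.shape[1]
    R = np.eye(n_items)
    for j in range(n_items):
        for l in range(j + 1, n_items):
            t = pair_table(X[:, j], X[:, l])
            if t.sum() < min_overlap:
                R[j, l] = R[l, j] = np.nan
                continue
            rho = tetrachoric_from_table(t)
            if np.isnan(rho):
                name_j = item_names[j] if item_names else j
                name_l = item_names[l] if item_names else l
                warnings.warn(
                    f"degenerate 2x2 table for pair ({name_j}, {name_l}); entry left missing",
                    stacklevel=2,
                )
            R[j, l] = R[l, j] = rho
    return R
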