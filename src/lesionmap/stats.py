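"""Permutation two-sample tests, effect sizes and FDR correction.

The permutation t-test permutes group labels and recomputes the two-sample
statistic (pooled-variance by default, Welch optional). Monte-Carlo p-values
use the add-one convention p = (1 + #{|t*| >= |t|}) / (n_perm + 1), which is
valid (never zero) and conservative under ties. When the number of distinct
relabelings C(n, n1) does not exceed ``n_perm`` the test enumerates all of
them instead of sampling; the enumeration includes the identity assignment,
so the smallest attainable two-sided p is 3 / (C(n, n1) + 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
from statsmodels.stats.multitest import multipletests

__all__ = ["permutation_t_test", "cohens_d", "d_from_t", "bh_fdr", "PermutationTTestResult"]

_TIE_TOL = 1e-9  # relative tolerance when counting |t*| >= |t| (ties count)


def _t_statistic(x: np.ndarray, y: np.ndarray, equal_var: bool = True) -> np.ndarray:
    """Two-sample t along the last axis; 0/inf handling for zero variance."""
    n1, n2 = x.shape[-1], y.shape[-1]
    mx, my = x.mean(-1), y.mean(-1)
    vx = x.var(-1, ddof=1)
    vy = y.var(-1, ddof=1)
    if equal_var:
        sp2 = ((n1 - 1) * vx + (n2 - 1) * vy) / (n1 + n2 - 2)
        denom = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    else:
        denom = np.sqrt(vx / n1 + vy / n2)
    diff = mx - my
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / denom
        t = np.where((denom == 0) & (diff == 0), 0.0, t)
        t = np.where((denom == 0) & (diff != 0), np.sign(diff) * np.inf, t)
    return t


@dataclass
class PermutationTTestResult:
    t: float
    p: float
    n_perm: int
    exhaustive: bool

    def __iter__(self):  # allow ``t, p = permutation_t_test(...)``
        return iter((self.t, self.p))


def _count_ge(abs_t_perm: np.ndarray, abs_t_obs: float) -> int:
    if np.isinf(abs_t_obs):
        return int(np.isinf(abs_t_perm).sum())
    return int((abs_t_perm >= abs_t_obs * (1.0 - _TIE_TOL) - _TIE_TOL).sum())


def permutation_t_test(
    x,
    y,
    n_perm: int = 100_000,
    seed: int | None = None,
    alternative: str = "two-sided",
    equal_var: bool = True,
    exhaustive: bool | None = None,
) -> PermutationTTestResult:
    """Permutation two-sample t-test on group labels.

    Parameters
    ----------
    x, y
        Samples for the two groups (each of size >= 2).
    n_perm
        Number of random relabelings; also the budget below which full
        enumeration is used.
    exhaustive
        Force (True) or forbid (False) enumeration of all C(n, n1)
        relabelings; default decides by comparing C(n, n1) with ``n_perm``.
    """
    if alternative not in ("two-sided", "two_sided"):
        raise ValueError("only the two-sided alternative is supported")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")

    n1, n = x.size, x.size + y.size
    data = np.concatenate([x, y])
    t_obs = float(_t_statistic(x, y, equal_var))
    abs_obs = abs(t_obs)

    if exhaustive is None:
        exhaustive = comb(n, n1) <= n_perm

    if exhaustive:
        b = 0
        total = comb(n, n1)
        chunk: list[tuple[int, ...]] = []
        for combo in combinations(range(n), n1):
            chunk.append(combo)
            if len(chunk) == 4096:
                b += _count_chunk(data, np.array(chunk), equal_var, abs_obs)
                chunk = []
        if chunk:
            b += _count_chunk(data, np.array(chunk), equal_var, abs_obs)
        p = (1.0 + b) / (1.0 + total)
        return PermutationTTestResult(t=t_obs, p=float(p), n_perm=total, exhaustive=True)

    rng = np.random.default_rng(seed)
    b = 0
    remaining = n_perm
    while remaining > 0:
        block = min(remaining, 20_000)
        perm = rng.permuted(np.broadcast_to(np.arange(n), (block, n)), axis=1)
        d = data[perm]
        t_star = _t_statistic(d[:, :n1], d[:, n1:], equal_var)
        b += _count_ge(np.abs(t_star), abs_obs)
        remaining -= block
    p = (1.0 + b) / (1.0 + n_perm)
    return PermutationTTestResult(t=t_obs, p=float(p), n_perm=n_perm, exhaustive=False)


def _count_chunk(data, combos, equal_var, abs_obs) -> int:
    mask = np.zeros((combos.shape[0], data.size), dtype=bool)
    np.put_along_axis(mask, combos, True, axis=1)
    xs = data[combos]
    ys = data[np.where(~mask)[1]].reshape(combos.shape[0], data.size - combos.shape[1])
    t_star = _t_statistic(xs, ys, equal_var)
    return _count_ge(np.abs(t_star), abs_obs)


def cohens_d(x, y) -> float:
    """Cohen's d with the pooled (n1 + n2 - 2)-denominator standard deviation.

    Returns NaN (with a warning) when the pooled SD is zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 observations")
    n1, n2 = x.size, y.size
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
    if sp2 == 0:
        warnings.warn("pooled SD is zero; Cohen's d undefined", stacklevel=2)
        return float("nan")
    return float((x.mean() - y.mean()) / np.sqrt(sp2))


def d_from_t(t: float, n1: int, n2: int) -> float:
    """Convert a two-sample t statistic to Cohen's d: d = t * sqrt(1/n1 + 1/n2)."""
    if n1 < 2 or n2 < 2:
        raise ValueError("group sizes must be >= 2")
    return float(t * np.sqrt(1.0 / n1 + 1.0 / n2))


def bh_fdr(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up FDR correction.

    Returns ``(adjusted p-values, rejection flags)`` where rejection means
    adjusted p <= q. Empty input yields empty output.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, reject
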