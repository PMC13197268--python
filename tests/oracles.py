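"""Independent brute-force oracles used to validate the fast implementations.

These deliberately share no code with the package: the permutation test is
enumerated with scipy's t statistic, BH-FDR follows the step-up definition
literally, and cluster labeling is a breadth-first flood fill.
"""

from itertools import combinations

import numpy as np
from scipy import stats

_TIE_TOL = 1e-9


def exhaustive_permutation_p(x, y, equal_var=True):
    """Two-sided permutation p over all C(n, n1) relabelings, add-one
    convention with the enumeration counted as the permutation set."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    data = np.concatenate([x, y])
    n, n1 = data.size, x.size

    def tstat(a, b):
        with np.errstate(divide="ignore", invalid="ignore"):
            t = stats.ttest_ind(a, b, equal_var=equal_var).statistic
        if np.isnan(t):
            d = a.mean() - b.mean()
            t = 0.0 if d == 0 else np.sign(d) * np.inf
        return t

    t_obs = abs(tstat(x, y))
    b = 0
    total = 0
    for combo in combinations(range(n), n1):
        sel = np.zeros(n, dtype=bool)
        sel[list(combo)] = True
        t_star = abs(tstat(data[sel], data[~sel]))
        if np.isinf(t_obs):
            b += int(np.isinf(t_star))
        else:
            b += int(t_star >= t_obs * (1.0 - _TIE_TOL) - _TIE_TOL)
        total += 1
    return t_obs, (1.0 + b) / (1.0 + total)


def brute_force_bh(p_values):
    """Literal step-up BH: p_adj(i) = min_{j >= rank(i)} (m / j) p_(j), capped."""
    p = np.asarray(p_values, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    for rank_pos, idx in enumerate(order):
        candidates = [(m / (j + 1)) * p[order[j]] for j in range(rank_pos, m)]
        adj[idx] = min(1.0, min(candidates))
    return adj


_NEIGHBOR_OFFSETS = {
    6: [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)],
}
_NEIGHBOR_OFFSETS[18] = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if 0 < abs(dx) + abs(dy) + abs(dz) <= 2
]
_NEIGHBOR_OFFSETS[26] = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]


def flood_fill_clusters(z_map, tested_mask, z_thr, connectivity):
    """Sign-separated supra-threshold components by BFS flood fill.

    Returns a list of ``(sign, frozenset of ijk, mass)`` tuples.
    """
    z_map = np.asarray(z_map, float)
    tested = np.asarray(tested_mask, bool)
    offsets = _NEIGHBOR_OFFSETS[connectivity]
    out = []
    for sign, supra in (
        (+1, (z_map >= z_thr) & tested),
        (-1, (z_map <= -z_thr) & tested),
    ):
        visited = np.zeros_like(supra)
        for start in zip(*np.nonzero(supra)):
            if visited[start]:
                continue
            queue = [start]
            visited[start] = True
            members = []
            while queue:
                cur = queue.pop()
                members.append(cur)
                for off in offsets:
                    nb = tuple(c + o for c, o in zip(cur, off))
                    if any(c < 0 or c >= s for c, s in zip(nb, supra.shape)):
                        continue
                    if supra[nb] and not visited[nb]:
                        visited[nb] = True
                        queue.append(nb)
            mass = float(sum(abs(z_map[m]) for m in members))
            out.append((sign, frozenset(members), mass))
    return out


def logit_2x2_beta(a, b, c, d):
    """Closed-form log odds ratio of a 2x2 table: resected/ILAE-I counts."""
    return np.log((a * d) / (b * c))
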