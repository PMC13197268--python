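"""Voxel-based lesion-outcome mapping (VLOM).

At every testable voxel, seizure freedom (ILAE I vs II-VI) is regressed on
whether that voxel was resected, adjusting for sex, overall resection volume,
surgery type (ATLR vs other) and lesion type (hippocampal sclerosis vs
other). Wald z maps are thresholded at a two-sided cluster-forming p (default
0.001), supra-threshold voxels are grouped into sign-homogeneous connected
components, and family-wise error is controlled at the cluster level by a
permutation test on the maximum cluster mass (sum of |z| over the cluster):
per permutation the outcome vector is shuffled across subjects, the full
model refit at every voxel, and the largest mass over both signs recorded.

The per-voxel fits share the covariate block of the design, so all voxels
(and, during permutation, many shuffled outcome vectors at once) are fit by
one batched iteratively reweighted least squares routine.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.special import expit
from scipy.stats import norm

from .errors import GridMismatchError
from .volumes import save_mask, save_volume, voxel_volume_ul

logger = logging.getLogger(__name__)

BETA_CAP = 15.0  # |log-odds| beyond this is treated as separation


def _ridge(dtype) -> float:
    # keeps the batched Newton solvable under separation; must stay above
    # the dtype's resolution relative to typical Hessian entries (~n/4)
    return 1e-9 if dtype == np.float64 else 1e-4

CONNECTIVITY_STRUCTS = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


# ---------------------------------------------------------------------------
# Design matrix
# ---------------------------------------------------------------------------


@dataclass
class DesignMatrix:
    """Outcome vector plus encoded covariate columns (no intercept column;
    the intercept is added by the fitting routine)."""

    outcome: np.ndarray
    covariates: np.ndarray
    names: list[str]
    dropped: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.outcome)


def build_design(table: pd.DataFrame, masks: np.ndarray, affine: np.ndarray) -> DesignMatrix:
    """Encode the covariate design from a cohort table and its masks.

    sex (female=1), surgery (ATLR=1), lesion (HS=1) are binary; overall
    resection volume (ul, from mask and affine) is centered and scaled by its
    SD. Constant columns are dropped with a warning so the design stays full
    rank.
    """
    outcome = (table["ilae_class"].to_numpy() == 1).astype(float)
    if outcome.min() == outcome.max():
        raise ValueError("outcome has a single class; logistic model undefined")

    vox_ul = voxel_volume_ul(affine)
    volume = np.asarray(masks).reshape(len(masks), -1).sum(axis=1) * vox_ul
    columns = {
        "sex_female": (table["sex"] == "female").to_numpy(float),
        "resection_volume": volume,
        "surgery_atlr": (table["surgery"] == "ATLR").to_numpy(float),
        "lesion_hs": (table["lesion"] == "HS").to_numpy(float),
    }
    kept, names, dropped = [], [], []
    for name, col in columns.items():
        if np.ptp(col) == 0:
            dropped.append(name)
            warnings.warn(f"covariate {name!r} is constant and was dropped", stacklevel=2)
            continue
        if name == "resection_volume":
            col = (col - col.mean()) / col.std(ddof=0)
        names.append(name)
        kept.append(col)
    X = np.column_stack(kept) if kept else np.empty((len(outcome), 0))
    return DesignMatrix(outcome=outcome, covariates=X, names=names, dropped=dropped)


def _check_design_rank(Z: np.ndarray, names: list[str]) -> None:
    """Z includes the intercept column; raise naming collinear columns."""
    rank = np.linalg.matrix_rank(Z)
    if rank < Z.shape[1]:
        _, r = np.linalg.qr(Z)
        small = np.abs(np.diag(r)) < 1e-8 * max(1.0, np.abs(np.diag(r)).max())
        offenders = [(["intercept"] + names)[i] for i in np.flatnonzero(small)]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {offenders}")


# ---------------------------------------------------------------------------
# Batched logistic fits
# ---------------------------------------------------------------------------


def _logistic_cov_only(Z: np.ndarray, Y: np.ndarray, max_iter: int = 30, tol: float | None = None):
    """Logistic fit of each outcome row on the shared columns alone.

    Z : (n, pz); Y : (B, n). Returns beta (B, pz). Used as a warm start for
    the per-voxel fits.
    """
    n, pz = Z.shape
    B = Y.shape[0]
    if tol is None:
        tol = 1e-10 if Z.dtype == np.float64 else 1e-6
    beta = np.zeros((B, pz), dtype=Z.dtype)
    ybar = Y.mean(axis=1).clip(1e-6, 1 - 1e-6)
    beta[:, 0] = np.log(ybar / (1 - ybar))
    eye = np.eye(pz, dtype=Z.dtype) * _ridge(Z.dtype)
    for _ in range(max_iter):
        eta = beta @ Z.T  # (B, n)
        mu = expit(eta)
        W = mu * (1.0 - mu) + 1e-12
        g = (Y - mu) @ Z
        H = np.einsum("bn,np,nq->bpq", W, Z, Z, optimize=True) + eye
        step = np.linalg.solve(H, g[..., None])[..., 0]
        np.clip(step, -4.0, 4.0, out=step)
        beta += step
        if np.abs(step).max() < tol:
            break
    return beta


def _newton_core(Z, Rb, Y, beta, eye, max_iter, tol, trust=4.0):
    """Damped Newton iterations for batched logistic fits.

    Z : (n, pz); Rb : resection predictor broadcastable to (B, V, n);
    Y : (B, n); beta : (B, V, pz+1) updated in place. The Newton step is
    scaled (direction-preserving) so its largest component is at most
    ``trust``; coordinate-wise clipping is avoided because it can 2-cycle.
    Returns (last_step (B,V), runaway (B,V), H) at exit.
    """
    n, pz = Z.shape
    p = pz + 1
    ZZ = (Z[:, :, None] * Z[:, None, :]).reshape(n, pz * pz)
    B, V = beta.shape[:2]
    last_step = np.full((B, V), np.inf, dtype=Z.dtype)
    runaway = np.zeros((B, V), dtype=bool)
    H = None
    for _ in range(max_iter):
        eta = np.matmul(beta[..., :pz], Z.T)
        eta += beta[..., pz:] * Rb  # (B,V,n)
        mu = expit(eta)
        W = mu * (1.0 - mu)
        W += 1e-12
        resid = Y[:, None, :] - mu

        g = np.empty((B, V, p), dtype=Z.dtype)
        g[..., :pz] = np.matmul(resid, Z)
        g[..., pz] = (resid * Rb).sum(-1)

        H = np.empty((B, V, p, p), dtype=Z.dtype)
        H[..., :pz, :pz] = np.matmul(W, ZZ).reshape(B, V, pz, pz)
        WR = W * Rb
        H_zr = np.matmul(WR, Z)
        H[..., :pz, pz] = H_zr
        H[..., pz, :pz] = H_zr
        H[..., pz, pz] = (WR * Rb).sum(-1)
        H += eye

        step = np.linalg.solve(H, g[..., None])[..., 0]
        scale = np.minimum(1.0, trust / np.maximum(np.abs(step).max(-1), 1e-30))
        step *= scale[..., None].astype(Z.dtype)
        beta += step
        last_step = np.abs(step).max(-1)
        runaway |= np.abs(beta).max(-1) > BETA_CAP
        if not np.any(last_step[~runaway] >= tol):
            break
    return last_step, runaway, H


def _se_last(H, pz):
    """SE of the last coefficient from the observed information."""
    p = pz + 1
    rhs = np.zeros(H.shape[:-2] + (p,), dtype=H.dtype)
    rhs[..., pz] = 1.0
    with np.errstate(invalid="ignore"):
        inv_last = np.linalg.solve(H, rhs[..., None])[..., 0]
        return np.sqrt(inv_last[..., pz])


def _batched_logistic(
    Z: np.ndarray,
    Rt: np.ndarray,
    Y: np.ndarray,
    max_iter: int = 60,
    tol: float = 1e-8,
    dtype=np.float64,
    dedup: bool = True,
    full_iters: int | None = None,
):
    """Maximum-likelihood logistic fits of many (outcome, voxel) pairs.

    Z : (n, pz) shared columns, intercept first. Rt : (V, n) per-voxel binary
    predictor. Y : (B, n) outcome vectors (rows are e.g. permutations).
    Returns ``(beta (B,V,p), se_r (B,V), converged (B,V))`` where the
    resection coefficient is the last parameter.

    Strategy: voxels sharing an identical resection pattern are fitted once
    and broadcast back; all pairs run a few damped-Newton sweeps in the
    requested dtype from a covariate-only warm start; the few stragglers
    (near-separated fits) are then compacted into one small float64 batch
    and iterated to convergence or to the separation cap. Pairs that still
    have not converged are flagged (separation / nonconvergence) for the
    caller to exclude.
    """
    Rt = np.asarray(Rt)
    if dedup:
        uniq, inv = np.unique(Rt, axis=0, return_inverse=True)
        if uniq.shape[0] < Rt.shape[0]:
            beta_u, se_u, conv_u = _batched_logistic(
                Z, uniq, Y, max_iter, tol, dtype, dedup=False, full_iters=full_iters
            )
            return beta_u[:, inv], se_u[:, inv], conv_u[:, inv]

    Z = np.asarray(Z, dtype=dtype)
    Rt = Rt.astype(dtype)
    Y = np.asarray(Y, dtype=dtype)
    n, pz = Z.shape
    V = Rt.shape[0]
    B = Y.shape[0]
    p = pz + 1

    beta = np.zeros((B, V, p), dtype=dtype)
    beta[..., :pz] = _logistic_cov_only(Z, Y)[:, None, :]

    # float32 gradient sums carry rounding noise ~1e-5, so steps bottom out
    # there; the float64 tail below finishes whatever needs more precision
    eff_tol = tol if dtype == np.float64 else max(tol, 1e-4)
    conv_thresh = 1e-5 if dtype == np.float64 else 1e-3
    if full_iters is None:
        full_iters = max_iter if dtype == np.float64 else 12

    eye = np.eye(p, dtype=dtype) * _ridge(dtype)
    last_step, runaway, H = _newton_core(
        Z, Rt[None], Y, beta, eye, full_iters, eff_tol
    )
    se_r = _se_last(H, pz)
    converged = (last_step < conv_thresh) & np.isfinite(beta).all(-1) & ~runaway

    active = ~converged & ~runaway
    if active.any() and active.mean() < 0.25:
        # compact stragglers into per-pair problems and finish in float64
        ab, av = np.nonzero(active)
        Z64 = Z.astype(np.float64)
        beta_a = beta[ab, av].astype(np.float64)[:, None, :]
        ls_a, run_a, H_a = _newton_core(
            Z64,
            Rt[av].astype(np.float64)[:, None, :],
            Y[ab].astype(np.float64),
            beta_a,
            np.eye(p) * _ridge(np.float64),
            max_iter,
            tol,
        )
        beta[ab, av] = beta_a[:, 0]
        se_r[ab, av] = _se_last(H_a, pz)[:, 0]
        last_step[ab, av] = ls_a[:, 0]
        runaway[ab, av] = run_a[:, 0]
        converged[ab, av] = (
            (ls_a[:, 0] < 1e-5) & np.isfinite(beta_a[:, 0]).all(-1) & ~run_a[:, 0]
        )
    elif active.any():
        # too many stragglers to compact profitably: keep iterating in bulk
        ls, run, H = _newton_core(Z, Rt[None], Y, beta, eye, max_iter, eff_tol)
        se_r = _se_last(H, pz)
        runaway |= run
        last_step = ls
        converged = (last_step < conv_thresh) & np.isfinite(beta).all(-1) & ~runaway

    return beta, se_r, converged


def fit_voxel_logistic(resected: np.ndarray, design: DesignMatrix) -> dict:
    """Logistic fit of outcome on one voxel's resection status plus covariates.

    Returns ``{"beta", "se", "z", "p", "converged"}`` for the resection
    predictor; a non-converged or runaway fit flags separation.
    """
    resected = np.asarray(resected, dtype=float)
    if resected.min() == resected.max():
        raise ValueError("resected vector is constant across subjects")
    Z = np.column_stack([np.ones(design.n), design.covariates])
    _check_design_rank(Z, design.names)
    beta, se, conv = _batched_logistic(Z, resected[None, :], design.outcome[None, :])
    b = float(beta[0, 0, -1])
    s = float(se[0, 0])
    ok = bool(conv[0, 0])
    z = b / s if ok and s > 0 else np.nan
    return {
        "beta": b if ok else np.nan,
        "se": s if ok else np.nan,
        "z": z,
        "p": 2 * norm.sf(abs(z)) if ok else np.nan,
        "converged": ok,
    }


# ---------------------------------------------------------------------------
# Voxel inclusion, maps and clusters
# ---------------------------------------------------------------------------


def voxel_inclusion_mask(masks: np.ndarray, min_per_cell: int = 10) -> np.ndarray:
    """Voxels testable for lesion-outcome association: resected in at least
    ``min_per_cell`` subjects and spared in at least ``min_per_cell``."""
    masks = np.asarray(masks) > 0
    counts = masks.sum(axis=0)
    n = masks.shape[0]
    return (counts >= min_per_cell) & ((n - counts) >= min_per_cell)


@dataclass
class VoxelModelResult:
    """Per-voxel logistic maps for the resection predictor."""

    beta: np.ndarray
    se: np.ndarray
    z: np.ndarray
    p: np.ndarray
    tested_mask: np.ndarray
    qc_excluded: int

    @property
    def or_map(self) -> np.ndarray:
        """Odds-ratio map OR = exp(beta); zero outside tested voxels."""
        out = np.zeros_like(self.beta)
        t = self.tested_mask.astype(bool)
        out[t] = np.exp(self.beta[t])
        return out


@dataclass
class Cluster:
    """Supra-threshold sign-homogeneous connected component."""

    cluster_id: int
    sign: str
    indices: tuple
    size: int
    mass: float
    peak_z: float
    peak_ijk: tuple[int, int, int]
    p_fwe: float | None = None


def label_clusters(
    z_map: np.ndarray,
    tested_mask: np.ndarray,
    cluster_forming_p: float = 0.001,
    connectivity: int = 26,
) -> list[Cluster]:
    """Partition supra-threshold voxels (|z| >= z(alpha/2), two-sided) into
    sign-homogeneous connected components; mass = sum of |z|."""
    if connectivity not in CONNECTIVITY_STRUCTS:
        raise ValueError(f"connectivity must be one of {sorted(CONNECTIVITY_STRUCTS)}")
    z_map = np.asarray(z_map, dtype=float)
    tested = np.asarray(tested_mask) > 0
    if z_map.shape != tested.shape:
        raise GridMismatchError("z map and tested mask disagree in shape")
    z_thr = float(norm.isf(cluster_forming_p / 2.0))
    struct = CONNECTIVITY_STRUCTS[connectivity]

    clusters: list[Cluster] = []
    cid = 0
    for sign, supra in (("positive", (z_map >= z_thr) & tested), ("negative", (z_map <= -z_thr) & tested)):
        lab, n = ndimage.label(supra, structure=struct)
        for k in range(1, n + 1):
            idx = np.nonzero(lab == k)
            zs = z_map[idx]
            peak = int(np.argmax(np.abs(zs)))
            cid += 1
            clusters.append(
                Cluster(
                    cluster_id=cid,
                    sign=sign,
                    indices=idx,
                    size=len(zs),
                    mass=float(np.abs(zs).sum()),
                    peak_z=float(zs[peak]),
                    peak_ijk=tuple(int(a[peak]) for a in idx),
                )
            )
    clusters.sort(key=lambda c: -c.mass)
    for i, c in enumerate(clusters, start=1):
        c.cluster_id = i
    return clusters


def _z_from_fit(beta, se, conv, pz):
    """Wald z for the resection coefficient; separation-flagged voxels get 0."""
    with np.errstate(divide="ignore", invalid="ignore"):
        z = beta[..., pz] / se
    z = np.where(conv & np.isfinite(z) & (se > 0), z, 0.0)
    return z


def _max_mass_per_row(z_rows, shape, tested_idx, z_thr, struct):
    """Max cluster mass over both signs for each row of a (B, V) z matrix."""
    out = np.empty(len(z_rows))
    zmap = np.zeros(shape)
    for b, zv in enumerate(z_rows):
        best = 0.0
        if np.any(np.abs(zv) >= z_thr):  # most null rows have no supra voxels
            zmap[tested_idx] = zv
            for supra in ((zmap >= z_thr), (zmap <= -z_thr)):
                lab, n = ndimage.label(supra, structure=struct)
                if n:
                    masses = ndimage.sum_labels(np.abs(zmap), lab, index=np.arange(1, n + 1))
                    best = max(best, float(np.max(masses)))
            zmap[tested_idx] = 0.0
        out[b] = best
    return out


def _score_z(Z: np.ndarray, Rt: np.ndarray, Y: np.ndarray):
    """Efficient-score z statistics for the resection predictor.

    Closed form given the covariate-only fit of each outcome row: no
    per-voxel iteration. Returns ``(z_score (B, V), beta0 (B, pz))``. Used
    only to pre-screen voxels that could pass the cluster-forming threshold;
    the reported statistic is always the full-model Wald z.
    """
    beta0 = _logistic_cov_only(Z, Y)
    mu0 = expit(beta0 @ Z.T)
    W0 = mu0 * (1.0 - mu0) + 1e-12
    resid0 = Y - mu0
    score = resid0 @ Rt.T  # (B, V)
    rWr = W0 @ (Rt * Rt).T
    C = np.einsum("bn,np,vn->bpv", W0, Z, Rt, optimize=True)
    A = np.einsum("bn,np,nq->bpq", W0, Z, Z, optimize=True)
    A += np.eye(Z.shape[1]) * _ridge(np.float64)
    quad = (C * np.linalg.solve(A, C)).sum(1)
    var = np.maximum(rWr - quad, 1e-12)
    return score / np.sqrt(var), beta0


def cluster_mass_permutation(
    masks: np.ndarray,
    design: DesignMatrix,
    n_perm: int = 5000,
    cluster_forming_p: float = 0.001,
    connectivity: int = 26,
    seed: int | None = None,
    min_per_cell: int = 10,
    perm_block: int = 128,
    voxel_block: int = 4096,
    screen: bool = True,
):
    """Observed clusters with FWE-corrected p plus the permutation null.

    Returns ``(result: VoxelModelResult, clusters, null_max_mass)``. The null
    records, per permutation of the outcome vector, the maximum cluster mass
    over both signs; ``p_fwe = (1 + #{max-mass* >= mass}) / (n_perm + 1)``.

    With ``screen=True`` each permutation first computes closed-form score-z
    statistics and only voxels with |score z| above 85% of the
    cluster-forming threshold receive the full Wald refit. The Wald z of the
    full model never exceeds the score z in these designs (checked in the
    test suite against the exhaustive path), so the screened null maxima are
    identical to the exhaustive computation at a fraction of the cost.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    masks = np.asarray(masks) > 0
    n = masks.shape[0]
    shape = masks.shape[1:]
    tested = voxel_inclusion_mask(masks, min_per_cell)
    tested_idx = np.nonzero(tested)
    V = int(tested.sum())

    beta_map = np.zeros(shape)
    se_map = np.zeros(shape)
    z_map = np.zeros(shape)
    p_map = np.ones(shape)

    if V == 0:
        warnings.warn("no testable voxels; returning empty result", stacklevel=2)
        result = VoxelModelResult(beta_map, se_map, z_map, p_map, tested.astype(np.uint8), 0)
        return result, [], np.zeros(n_perm)

    Rt = masks.reshape(n, -1).T[tested.ravel()].astype(float)  # (V, n)
    uniq_Rt, uniq_inv = np.unique(Rt, axis=0, return_inverse=True)
    U = uniq_Rt.shape[0]
    Z = np.column_stack([np.ones(n), design.covariates])
    _check_design_rank(Z, design.names)
    pz = Z.shape[1]
    struct = CONNECTIVITY_STRUCTS[connectivity]
    z_thr = float(norm.isf(cluster_forming_p / 2.0))

    # observed fit
    obs_z = np.empty(V)
    obs_beta = np.empty(V)
    obs_se = np.empty(V)
    obs_conv = np.empty(V, dtype=bool)
    for v0 in range(0, V, voxel_block):
        sl = slice(v0, min(v0 + voxel_block, V))
        beta, se, conv = _batched_logistic(Z, Rt[sl], design.outcome[None, :])
        obs_beta[sl] = beta[0, :, -1]
        obs_se[sl] = se[0]
        obs_conv[sl] = conv[0]
    obs_z[:] = _z_from_fit(
        np.concatenate([np.zeros((V, pz)), obs_beta[:, None]], axis=1), obs_se, obs_conv, pz
    )
    qc_excluded = int((~obs_conv).sum())

    beta_map[tested_idx] = np.where(obs_conv, obs_beta, 0.0)
    se_map[tested_idx] = np.where(obs_conv, obs_se, 0.0)
    z_map[tested_idx] = obs_z
    p_map[tested_idx] = np.where(obs_conv, 2 * norm.sf(np.abs(obs_z)), 1.0)

    clusters = label_clusters(z_map, tested, cluster_forming_p, connectivity)

    # permutation null of the maximum cluster mass
    rng = np.random.default_rng(seed)
    perms = np.stack([rng.permutation(n) for _ in range(n_perm)])
    null_max = np.empty(n_perm)
    for b0 in range(0, n_perm, perm_block):
        bsl = slice(b0, min(b0 + perm_block, n_perm))
        Yb = design.outcome[perms[bsl]]
        Bb = Yb.shape[0]
        if screen:
            z_s, beta0 = _score_z(Z, uniq_Rt, Yb)
            zu = np.zeros((Bb, U))
            cb, cv = np.nonzero(np.abs(z_s) >= 0.85 * z_thr)
            if cb.size:
                beta_a = np.zeros((cb.size, 1, pz + 1))
                beta_a[:, 0, :pz] = beta0[cb]
                ls, run, Hc = _newton_core(
                    Z, uniq_Rt[cv][:, None, :], Yb[cb], beta_a,
                    np.eye(pz + 1) * _ridge(np.float64), 60, 1e-8,
                )
                se_a = _se_last(Hc, pz)[:, 0]
                conv_a = (ls[:, 0] < 1e-5) & np.isfinite(beta_a[:, 0]).all(-1) & ~run[:, 0]
                zu[cb, cv] = _z_from_fit(beta_a[:, 0], se_a, conv_a, pz)
        else:
            zu = np.empty((Bb, U))
            for v0 in range(0, U, voxel_block):
                sl = slice(v0, min(v0 + voxel_block, U))
                beta, se, conv = _batched_logistic(Z, uniq_Rt[sl], Yb, dedup=False)
                zu[:, sl] = _z_from_fit(beta, se, conv, pz)
        zb = zu[:, uniq_inv]
        null_max[bsl] = _max_mass_per_row(zb, shape, tested_idx, z_thr, struct)

    for c in clusters:
        c.p_fwe = float((1 + (null_max >= c.mass).sum()) / (n_perm + 1))

    result = VoxelModelResult(
        beta=beta_map, se=se_map, z=z_map, p=p_map,
        tested_mask=tested.astype(np.uint8), qc_excluded=qc_excluded,
    )
    return result, clusters, null_max


# ---------------------------------------------------------------------------
# Hemisphere flipping and the model/results surface
# ---------------------------------------------------------------------------


def flip_right_to_left(mask: np.ndarray) -> np.ndarray:
    """Mirror a volume across the mid-sagittal voxel plane: (i,j,k) ->
    (Nx-1-i, j, k). Requires an even first dimension; involutive."""
    mask = np.asarray(mask)
    if mask.shape[0] % 2:
        raise ValueError(
            "grid is not symmetric about a mid-sagittal voxel plane (odd first "
            "dimension); resample to an even grid before flipping"
        )
    return mask[::-1].copy()


@dataclass
class VoxelOutcomeModel:
    """Voxelwise lesion-outcome model for one pooled analysis group.

    ``masks`` is the subject x grid stack of binary resection masks (already
    flipped if pooling hemispheres), ``design`` the covariate design. Use
    :func:`vlom_pipeline` for the laterality-split / flip-and-pool drivers.
    """

    masks: np.ndarray
    design: DesignMatrix
    affine: np.ndarray | None = None
    min_per_cell: int = 10

    @classmethod
    def from_arrays(cls, masks, table: pd.DataFrame, affine, min_per_cell: int = 10):
        design = build_design(table, masks, affine)
        return cls(masks=np.asarray(masks) > 0, design=design, affine=affine,
                   min_per_cell=min_per_cell)

    def fit(
        self,
        n_perm: int = 5000,
        cluster_forming_p: float = 0.001,
        connectivity: int = 26,
        seed: int | None = None,
    ) -> "VoxelOutcomeResults":
        result, clusters, null_max = cluster_mass_permutation(
            self.masks, self.design, n_perm=n_perm,
            cluster_forming_p=cluster_forming_p, connectivity=connectivity,
            seed=seed, min_per_cell=self.min_per_cell,
        )
        return VoxelOutcomeResults(
            model=self, maps=result, clusters=clusters, null_max_mass=null_max,
            n_perm=n_perm, cluster_forming_p=cluster_forming_p,
            connectivity=connectivity, seed=seed,
        )


@dataclass
class VoxelOutcomeResults:
    """Maps, clusters and permutation null from a fitted voxel model."""

    model: VoxelOutcomeModel = field(repr=False)
    maps: VoxelModelResult = field(repr=False)
    clusters: list[Cluster]
    null_max_mass: np.ndarray
    n_perm: int
    cluster_forming_p: float
    connectivity: int
    seed: int | None

    def cluster_table(self) -> pd.DataFrame:
        rows = [
            {
                "cluster_id": c.cluster_id,
                "sign": c.sign,
                "size": c.size,
                "mass": c.mass,
                "peak_z": c.peak_z,
                "peak_ijk": f"{c.peak_ijk[0]} {c.peak_ijk[1]} {c.peak_ijk[2]}",
                "p_fwe": c.p_fwe,
            }
            for c in self.clusters
        ]
        return pd.DataFrame(
            rows,
            columns=["cluster_id", "sign", "size", "mass", "peak_z", "peak_ijk", "p_fwe"],
        )

    def summary(self) -> str:
        n_sig = sum(1 for c in self.clusters if (c.p_fwe or 1) <= 0.05)
        lines = [
            "Voxel-based lesion-outcome mapping "
            f"(n={self.model.design.n}, {int(self.maps.tested_mask.sum())} tested voxels, "
            f"{self.n_perm} permutations, cluster-forming p={self.cluster_forming_p}, "
            f"{self.connectivity}-connectivity)",
            f"separation-excluded voxels: {self.maps.qc_excluded}",
            f"clusters: {len(self.clusters)} ({n_sig} with FWE p <= 0.05)",
        ]
        if self.clusters:
            lines.append(self.cluster_table().to_string(index=False))
        return "\n".join(lines)

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        affine = self.model.affine if self.model.affine is not None else np.eye(4)
        save_volume(self.maps.beta, affine, out / "beta.nii.gz")
        save_volume(self.maps.or_map, affine, out / "or.nii.gz")
        save_volume(self.maps.z, affine, out / "z.nii.gz")
        save_volume(self.maps.p, affine, out / "p_unc.nii.gz")
        save_mask(self.maps.tested_mask, affine, out / "tested_mask.nii.gz")
        self.cluster_table().to_csv(out / "clusters.tsv", sep="\t", index=False,
                                    lineterminator="\n")
        pd.DataFrame({"max_mass": self.null_max_mass}).to_csv(
            out / "null_max_mass.tsv", sep="\t", index=False, lineterminator="\n"
        )


def vlom_pipeline(
    cohort,
    mode: str = "split_by_laterality",
    n_perm: int = 5000,
    cluster_forming_p: float = 0.001,
    connectivity: int = 26,
    min_per_cell: int = 10,
    seed: int | None = None,
    lesion: str | None = None,
    out_dir: str | Path | None = None,
) -> dict[str, VoxelOutcomeResults]:
    """Run the full voxel mapping on a cohort.

    ``split_by_laterality`` analyses left- and right-operated subjects
    separately; ``flip_and_pool`` mirrors right-hemisphere masks onto the
    left and pools everyone in one analysis (optionally restricted to one
    lesion type, e.g. HS). Returns a dict of results bundles keyed by
    subgroup name; with ``out_dir`` each bundle is also written to disk.
    """
    if mode not in ("split_by_laterality", "flip_and_pool"):
        raise ValueError(f"unknown mode {mode!r}")
    if lesion is not None:
        cohort = cohort.filter(lesion=lesion)
    masks, affine = cohort.load_masks()
    table = cohort.table

    analyses: dict[str, tuple[np.ndarray, pd.DataFrame]] = {}
    if mode == "split_by_laterality":
        for side in ("left", "right"):
            sel = (table["laterality"] == side).to_numpy()
            if sel.sum():
                analyses[side] = (masks[sel], table[sel].reset_index(drop=True))
    else:
        flipped = masks.copy()
        right = (table["laterality"] == "right").to_numpy()
        for i in np.flatnonzero(right):
            flipped[i] = flip_right_to_left(masks[i])
        analyses["pooled_left"] = (flipped, table.reset_index(drop=True))

    out: dict[str, VoxelOutcomeResults] = {}
    for name, (m, t) in analyses.items():
        logger.info("vlom analysis %s: n=%d", name, len(t))
        model = VoxelOutcomeModel.from_arrays(m, t, affine, min_per_cell=min_per_cell)
        res = model.fit(
            n_perm=n_perm, cluster_forming_p=cluster_forming_p,
            connectivity=connectivity, seed=seed,
        )
        out[name] = res
        if out_dir is not None:
            res.save(Path(out_dir) / name)
    return out
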