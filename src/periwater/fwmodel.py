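"""Two-compartment (free-water) diffusion model fitting for single-shell DWI.

The signal attenuation in each voxel is modelled as

    A_i = f_t * exp(-b_i g_i' D_t g_i) + (1 - f_t) * exp(-b_i d_w)

with a tissue compartment (volume fraction ``f_t``, anisotropic tensor
``D_t``) and an isotropic extracellular free-water compartment of fixed
body-temperature diffusivity ``d_w`` (3.0e-3 mm^2/s). The free-water
fraction is ``fw = 1 - f_t`` and the free-water-corrected tissue FA (FA_T)
is the fractional anisotropy of ``D_t``.

Fitting is a constrained nonlinear least-squares run jointly over all
masked voxels (batched Levenberg-Marquardt): ``f_t`` is box-constrained to
[eps, 1-eps] through a logistic transform and ``D_t`` is kept positive
semidefinite through a triangular (Cholesky) factor.

At a single b-value the tissue fraction and tissue mean diffusivity trade
off along a nearly flat valley of the objective, so the voxelwise problem
is only weakly identified. Two regularizers address this: a tissue-MD
anchor (a weak penalty pulling trace(D_t)/3 toward a healthy-tissue value,
on by default and analogous to the fixed-diffusivity assumptions of
published single-shell free-water estimators) and an optional spatial
penalty coupling ``f_t`` to the 6-neighbor mean of the previous outer
cycle's field (``lambda_reg``). Initialization profiles the objective over
a grid of tissue fractions with a conditional log-linear tensor fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.special import expit, logit

from .gradients import GradientTable, InvalidAcquisitionError, MIN_DIRECTIONS

log = logging.getLogger(__name__)

#: isotropic diffusivity of free water at body temperature, mm^2/s
D_WATER = 3.0e-3

# lower-triangle index pairs of the Cholesky factor, parameter order
_TRI = [(0, 0), (1, 0), (1, 1), (2, 0), (2, 1), (2, 2)]


# ---------------------------------------------------------------------------
# tensor utilities


def compute_fa(tensor: np.ndarray) -> np.ndarray:
    """Fractional anisotropy of symmetric tensor(s), shape (..., 3, 3).

    Negative eigenvalues are clamped to zero before the formula; the
    all-zero tensor maps to FA = 0.
    """
    tensor = np.asarray(tensor, dtype=float)
    if tensor.shape[-2:] != (3, 3):
        raise ValueError("expected shape (..., 3, 3)")
    if not np.allclose(tensor, np.swapaxes(tensor, -1, -2), atol=1e-10):
        raise ValueError("tensor must be symmetric")
    evals = np.linalg.eigvalsh(tensor)
    return fa_from_eigenvalues(evals)


def fa_from_eigenvalues(evals: np.ndarray) -> np.ndarray:
    """FA = sqrt(3/2) * ||lambda - mean|| / ||lambda|| with clamping at 0."""
    evals = np.asarray(evals, dtype=float)
    n_neg = int(np.count_nonzero(evals < -1e-12))
    if n_neg:
        log.warning("clamped %d negative eigenvalues to 0 for FA", n_neg)
    evals = np.clip(evals, 0.0, None)
    norm2 = (evals**2).sum(axis=-1)
    mean = evals.mean(axis=-1, keepdims=True)
    dev2 = ((evals - mean) ** 2).sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5 * dev2 / norm2)
    return np.where(norm2 > 0, fa, 0.0)


def cylinder_tensor(fa: np.ndarray, md: np.ndarray, axis: np.ndarray) -> np.ndarray:
    """Cylindrically symmetric tensor(s) with exact target FA and MD.

    Eigenvalues are the closed-form inversion of the FA formula at fixed
    mean diffusivity: with a = FA / sqrt(3 - 2 FA^2),
    lambda_1 = MD (1 + 2a), lambda_2 = lambda_3 = MD (1 - a); the principal
    eigenvector is ``axis`` (shape (..., 3), need not be normalized).
    """
    fa = np.asarray(fa, dtype=float)
    md = np.asarray(md, dtype=float)
    if np.any(fa < 0) or np.any(fa >= 1):
        raise ValueError("target FA must lie in [0, 1)")
    a = fa / np.sqrt(3.0 - 2.0 * fa**2)
    lam_par = md * (1.0 + 2.0 * a)
    lam_perp = md * (1.0 - a)
    e = np.asarray(axis, dtype=float)
    e = e / np.linalg.norm(e, axis=-1, keepdims=True)
    outer = e[..., :, None] * e[..., None, :]
    eye = np.eye(3)
    return (
        lam_perp[..., None, None] * eye
        + (lam_par - lam_perp)[..., None, None] * outer
    )


# ---------------------------------------------------------------------------
# model containers


@dataclass(frozen=True)
class BiTensorParams:
    """Single-voxel bi-tensor parameters (tissue fraction + tissue tensor)."""

    f_t: float
    D_t: np.ndarray
    d_w: float = D_WATER

    def __post_init__(self) -> None:
        D = np.asarray(self.D_t, dtype=float)
        if D.shape != (3, 3):
            raise ValueError("D_t must be 3x3")
        if not np.allclose(D, D.T, atol=1e-10):
            raise ValueError("D_t must be symmetric")
        if np.min(np.linalg.eigvalsh(D)) < -1e-12:
            raise ValueError("D_t must be positive semidefinite")
        if not 0.0 <= self.f_t <= 1.0:
            raise ValueError("f_t must lie in [0, 1]")
        object.__setattr__(self, "D_t", D)

    @property
    def fw(self) -> float:
        return 1.0 - self.f_t


@dataclass
class FreeWaterFit:
    """Voxelwise free-water fit results. Values outside ``mask`` are NaN."""

    fw_map: np.ndarray
    fat_map: np.ndarray
    md_t_map: np.ndarray
    residual_map: np.ndarray  # per-voxel RMS attenuation residual
    n_iter_map: np.ndarray
    mask: np.ndarray
    tensors: np.ndarray | None = None  # (..., 3, 3) tissue tensors
    s0_map: np.ndarray | None = None
    converged: np.ndarray | None = None


@dataclass
class FitConfig:
    """Tunable knobs of the bi-tensor fit (all exposed on the CLI)."""

    d_w: float = D_WATER
    epsilon: float = 0.01  # box margin on f_t
    lambda_reg: float = 0.0  # optional neighbor-mean coupling weight for f_t
    outer_iterations: int = 4  # regularization cycles (1 when lambda_reg == 0)
    tol: float = 1e-6  # convergence threshold on parameter change
    ftol: float = 1e-10  # relative cost-decrease threshold (plateau stop)
    max_iter: int = 200  # total LM iteration budget per voxel
    md_tissue_ref: float = 0.6e-3  # healthy-tissue MD anchor for initialization
    signal_floor: float = 1e-6  # relative floor for nonpositive signals
    init_mode: str = "profile"  # "profile" (f_t grid search) or "md" heuristic
    # tissue-MD anchor: resolves the single-shell f_t/MD_t degeneracy by
    # penalizing sqrt(w) * (MD_t / md_anchor - 1); one residual against ~64
    # data residuals, so informative voxels are barely distorted
    md_anchor: float = 0.7e-3
    md_anchor_weight: float = 0.5


# ---------------------------------------------------------------------------
# forward model


def predict_signal(params: BiTensorParams, table: GradientTable) -> np.ndarray:
    """Noise-free attenuation A_i for each volume of the gradient table."""
    b = table.bvals
    g = table.bvecs
    q = np.einsum("ij,jk,ik->i", g, params.D_t, g)
    return params.f_t * np.exp(-b * q) + (1.0 - params.f_t) * np.exp(-b * params.d_w)


def _predict_batch(f: np.ndarray, L: np.ndarray, b: np.ndarray, g: np.ndarray,
                   ew: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Attenuations for (nv,) fractions and (nv,3,3) Cholesky factors."""
    v = np.matmul(g, L)  # (nv, nd, 3): v[n,i,k] = sum_j g[i,j] L[n,j,k]
    q = (v * v).sum(axis=-1)
    et = np.exp(-b[None, :] * q)
    a = f[:, None] * et + (1.0 - f)[:, None] * ew[None, :]
    return a, et, v


# ---------------------------------------------------------------------------
# DTI initialization


def fit_dti_loglinear(
    dwi: np.ndarray,
    table: GradientTable,
    mask: np.ndarray,
    signal_floor: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray]:
    """Ordinary least-squares diffusion-tensor fit on log-attenuations.

    Returns ``(tensors, s0)`` where ``tensors`` has shape mask.shape+(3,3)
    (NaN outside the mask) and ``s0`` is the geometric mean of the b=0
    volumes. Nonpositive signals are clamped to a relative floor with a
    logged count rather than raising.
    """
    mask = np.asarray(mask, dtype=bool)
    if dwi.shape[:-1] != mask.shape:
        raise ValueError("DWI and mask grids disagree")
    if dwi.shape[-1] != len(table):
        raise ValueError("DWI volume count does not match the gradient table")
    b0 = table.b0_mask
    if not b0.any():
        raise InvalidAcquisitionError("need at least one b=0 volume")
    dw = ~b0
    g = table.bvecs[dw]
    b = table.bvals[dw]
    # design for ln A = -b g' D g, D in (xx, yy, zz, xy, xz, yz) order
    X = np.column_stack(
        [
            b * g[:, 0] ** 2,
            b * g[:, 1] ** 2,
            b * g[:, 2] ** 2,
            2 * b * g[:, 0] * g[:, 1],
            2 * b * g[:, 0] * g[:, 2],
            2 * b * g[:, 1] * g[:, 2],
        ]
    )
    if table.n_directions < MIN_DIRECTIONS or np.linalg.matrix_rank(X) < 6:
        raise InvalidAcquisitionError(
            "gradient scheme does not identify the 6 tensor components"
        )
    sig = dwi[mask]  # (nv, nvol)
    s0 = np.exp(np.log(np.clip(sig[:, b0], 1e-300, None)).mean(axis=1))
    n_bad = int(np.count_nonzero(sig[:, b0] <= 0))
    att = sig[:, dw] / np.clip(s0[:, None], 1e-300, None)
    n_bad += int(np.count_nonzero(att <= 0))
    if n_bad:
        log.warning("clamped %d nonpositive signals to the floor", n_bad)
    att = np.clip(att, signal_floor, None)
    coeffs = -np.linalg.lstsq(X, np.log(att).T, rcond=None)[0]  # (6, nv)
    dxx, dyy, dzz, dxy, dxz, dyz = coeffs
    tensors_flat = np.empty((sig.shape[0], 3, 3))
    tensors_flat[:, 0, 0] = dxx
    tensors_flat[:, 1, 1] = dyy
    tensors_flat[:, 2, 2] = dzz
    tensors_flat[:, 0, 1] = tensors_flat[:, 1, 0] = dxy
    tensors_flat[:, 0, 2] = tensors_flat[:, 2, 0] = dxz
    tensors_flat[:, 1, 2] = tensors_flat[:, 2, 1] = dyz
    tensors = np.full(mask.shape + (3, 3), np.nan)
    tensors[mask] = tensors_flat
    s0_map = np.full(mask.shape, np.nan)
    s0_map[mask] = s0
    return tensors, s0_map


def init_freewater(
    md_map: np.ndarray,
    d_w: float = D_WATER,
    md_tissue_ref: float = 0.6e-3,
    epsilon: float = 0.01,
) -> np.ndarray:
    """Initial tissue fraction from mean diffusivity.

    Linearly interpolates between pure tissue (MD at ``md_tissue_ref``) and
    pure free water (MD at ``d_w``), clipped to [eps, 1-eps]:
    ``f_t = clip((d_w - MD) / (d_w - md_tissue_ref), eps, 1-eps)``.
    """
    if not d_w > md_tissue_ref > 0:
        raise ValueError("require d_w > md_tissue_ref > 0")
    f = (d_w - np.asarray(md_map, dtype=float)) / (d_w - md_tissue_ref)
    return np.clip(f, epsilon, 1.0 - epsilon)


def profile_init(
    y: np.ndarray,
    b: np.ndarray,
    g: np.ndarray,
    d_w: float = D_WATER,
    epsilon: float = 0.01,
    n_grid: int = 24,
    signal_floor: float = 1e-6,
    md_anchor: float = 0.7e-3,
    md_anchor_weight: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Grid-profiled initialization of the tissue fraction and tensor.

    For each candidate f_t on a grid, the free-water contribution is
    subtracted from the attenuations, the tissue tensor is fitted
    log-linearly, and the candidate minimizing the full bi-tensor residual
    is kept. Profiling across f_t avoids the initialization bias of purely
    MD-based heuristics, which underestimate the free-water content of
    partial-volume voxels at a single b-value.

    Returns ``(f_t, tensors)`` for the (nv, nd) attenuation array ``y``.
    """
    nv, nd = y.shape
    ew = np.exp(-b * d_w)
    X = np.column_stack(
        [
            b * g[:, 0] ** 2,
            b * g[:, 1] ** 2,
            b * g[:, 2] ** 2,
            2 * b * g[:, 0] * g[:, 1],
            2 * b * g[:, 0] * g[:, 2],
            2 * b * g[:, 1] * g[:, 2],
        ]
    )
    P = np.linalg.pinv(X)  # (6, nd)
    fgrid = np.linspace(epsilon, 1.0 - epsilon, n_grid)
    best_cost = np.full(nv, np.inf)
    best_f = np.full(nv, 0.5)
    best_d = np.zeros((nv, 6))
    for fcand in fgrid:
        at = (y - (1.0 - fcand) * ew[None, :]) / fcand
        at = np.clip(at, signal_floor, None)
        d6 = -(np.log(at) @ P.T)  # (nv, 6)
        q = d6 @ X.T  # b_i g_i' D g_i (X columns already carry b)
        pred = fcand * np.exp(-q) + (1.0 - fcand) * ew[None, :]
        cost = ((pred - y) ** 2).sum(axis=1)
        if md_anchor_weight > 0:
            md_t = (d6[:, 0] + d6[:, 1] + d6[:, 2]) / 3.0
            cost = cost + md_anchor_weight * (md_t / md_anchor - 1.0) ** 2
        take = cost < best_cost
        best_cost[take] = cost[take]
        best_f[take] = fcand
        best_d[take] = d6[take]
    dxx, dyy, dzz, dxy, dxz, dyz = best_d.T
    tensors = np.empty((nv, 3, 3))
    tensors[:, 0, 0] = dxx
    tensors[:, 1, 1] = dyy
    tensors[:, 2, 2] = dzz
    tensors[:, 0, 1] = tensors[:, 1, 0] = dxy
    tensors[:, 0, 2] = tensors[:, 2, 0] = dxz
    tensors[:, 1, 2] = tensors[:, 2, 1] = dyz
    return best_f, tensors


# ---------------------------------------------------------------------------
# batched Levenberg-Marquardt bi-tensor fit


def _chol_from_tensors(tensors: np.ndarray, lam_floor: float = 1e-6) -> np.ndarray:
    """Cholesky factors of tensors after projecting eigenvalues to >= floor."""
    evals, evecs = np.linalg.eigh(tensors)
    evals = np.clip(evals, lam_floor * 1e-3, None)  # floor in mm^2/s scale
    psd = np.einsum("...ij,...j,...kj->...ik", evecs, evals, evecs)
    return np.linalg.cholesky(psd)


def _neighbor_mean(field: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Mean over the 6 face neighbors, restricted to masked voxels."""
    filled = np.where(mask, field, 0.0)
    kernel = ndimage.generate_binary_structure(3, 1).astype(float)
    kernel[1, 1, 1] = 0.0
    s = ndimage.convolve(filled, kernel, mode="constant")
    n = ndimage.convolve(mask.astype(float), kernel, mode="constant")
    with np.errstate(invalid="ignore", divide="ignore"):
        nb = s / n
    return np.where((n > 0) & mask, nb, field)


def _lm_fit(
    y: np.ndarray,
    b: np.ndarray,
    g: np.ndarray,
    u: np.ndarray,
    L: np.ndarray,
    cfg: FitConfig,
    max_iter: int,
    f_prior: np.ndarray | None = None,
    w_prior: float = 0.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Batched LM on (u, chol(D_t)); returns (u, L, cost, n_iter, converged).

    When ``f_prior``/``w_prior`` are given, the objective carries one extra
    residual ``sqrt(w_prior) * (f_t - f_prior)`` per voxel, coupling the
    tissue fraction to its spatial prior (the regularization term).
    """
    nv, nd = y.shape
    ew = np.exp(-b * cfg.d_w)
    scale = 1.0 - 2.0 * cfg.epsilon
    sqw = np.sqrt(w_prior) if w_prior > 0 and f_prior is not None else 0.0
    sqa = np.sqrt(cfg.md_anchor_weight) if cfg.md_anchor_weight > 0 else 0.0
    anchor3 = 3.0 * cfg.md_anchor

    def unpack(theta):
        uu = theta[:, 0]
        LL = np.zeros((theta.shape[0], 3, 3))
        for idx, (j, k) in enumerate(_TRI):
            LL[:, j, k] = theta[:, 1 + idx]
        return uu, LL

    theta = np.zeros((nv, 7))
    theta[:, 0] = u
    for idx, (j, k) in enumerate(_TRI):
        theta[:, 1 + idx] = L[:, j, k]

    # characteristic scales: logistic coordinate ~1, Cholesky entries ~sqrt(MD)
    par_scale = np.array([1.0] + [np.sqrt(cfg.md_tissue_ref)] * 6)

    def residuals(theta, yy, fp):
        uu, LL = unpack(theta)
        f = cfg.epsilon + scale * expit(uu)
        a, et, v = _predict_batch(f, LL, b, g, ew)
        cols = [a - yy]
        if sqw > 0.0:
            cols.append((sqw * (f - fp))[:, None])
        if sqa > 0.0:
            tr = (LL**2).sum(axis=(1, 2))  # trace(L L') = ||L||_F^2
            cols.append((sqa * (tr / anchor3 - 1.0))[:, None])
        r = np.concatenate(cols, axis=1) if len(cols) > 1 else cols[0]
        return r, f, et, v

    fprior = f_prior if sqw > 0.0 else np.zeros(nv)
    r, f, et, v = residuals(theta, y, fprior)
    cost = np.einsum("ni,ni->n", r, r)
    lam = np.full(nv, 1e-3)
    n_iter = np.zeros(nv, dtype=int)
    converged = np.zeros(nv, dtype=bool)
    active = np.ones(nv, dtype=bool)

    diag_idx = np.arange(7)
    for _ in range(max_iter):
        if not active.any():
            break
        idx_a = np.flatnonzero(active)
        ra, fa_, eta, va = r[idx_a], f[idx_a], et[idx_a], v[idx_a]
        sig = (fa_ - cfg.epsilon) / scale
        fprime = scale * sig * (1.0 - sig)
        n_res = nd + (sqw > 0.0) + (sqa > 0.0)
        J = np.zeros((idx_a.size, n_res, 7))
        J[:, :nd, 0] = (eta - ew[None, :]) * fprime[:, None]
        damp_core = -fa_[:, None] * b[None, :] * eta
        for t_idx, (j, k) in enumerate(_TRI):
            J[:, :nd, 1 + t_idx] = damp_core * (2.0 * g[None, :, j] * va[:, :, k])
        col = nd
        if sqw > 0.0:
            J[:, col, 0] = sqw * fprime
            col += 1
        if sqa > 0.0:
            _, LL_a = unpack(theta[idx_a])
            for t_idx, (j, k) in enumerate(_TRI):
                J[:, col, 1 + t_idx] = sqa * 2.0 * LL_a[:, j, k] / anchor3
        Jt = J.transpose(0, 2, 1)
        grad = np.matmul(Jt, ra[..., None])[..., 0]
        H = np.matmul(Jt, J)
        diag = np.maximum(H[:, diag_idx, diag_idx], 1e-12)
        A = H.copy()
        A[:, diag_idx, diag_idx] += lam[idx_a, None] * diag
        try:
            delta = np.linalg.solve(A, -grad[..., None])[..., 0]
        except np.linalg.LinAlgError:
            A[:, diag_idx, diag_idx] += 1e-10
            delta = np.linalg.solve(A, -grad[..., None])[..., 0]
        trial = theta[idx_a] + delta
        r_t, f_t_, et_t, v_t = residuals(trial, y[idx_a], fprior[idx_a])
        cost_t = (r_t * r_t).sum(axis=1)
        better = cost_t <= cost[idx_a]
        acc = idx_a[better]
        rej = idx_a[~better]
        theta[acc] = trial[better]
        r[acc], f[acc], et[acc], v[acc] = (
            r_t[better], f_t_[better], et_t[better], v_t[better],
        )
        old_cost = cost[acc].copy()
        cost[acc] = cost_t[better]
        lam[acc] = np.maximum(lam[acc] / 3.0, 1e-12)
        lam[rej] = np.minimum(lam[rej] * 4.0, 1e12)
        n_iter[idx_a] += 1
        if better.any():
            step_small = (
                np.abs(delta[better] / par_scale[None, :]).max(axis=1) < cfg.tol
            )
            plateau = (old_cost - cost[acc]) <= cfg.ftol * np.maximum(cost[acc], 1e-30)
            done = acc[step_small | plateau]
            converged[done] = True
            active[done] = False
        # voxels stuck at maximal damping are treated as converged-in-place
        stalled = idx_a[lam[idx_a] >= 1e12]
        active[stalled] = False
    u_out, L_out = unpack(theta)
    return u_out, L_out, cost, n_iter, converged


def fit_bitensor(
    dwi: np.ndarray,
    table: GradientTable,
    mask: np.ndarray,
    config: FitConfig | None = None,
    init: tuple[np.ndarray, np.ndarray] | None = None,
) -> FreeWaterFit:
    """Fit the bi-tensor model to every voxel in ``mask``.

    Parameters
    ----------
    dwi:
        4-D signal array, last axis matching the gradient table.
    table:
        Acquisition scheme (single shell plus b=0 volumes).
    mask:
        Boolean array of voxels to fit.
    config:
        :class:`FitConfig`; defaults are suitable for b=1500 s/mm^2 data.
    init:
        Optional ``(f_t_map, tensor_field)`` initialization (e.g. ground
        truth in simulations). By default the fit is initialized from a
        log-linear DTI fit with the MD-based free-water heuristic.

    Voxels that exhaust the iteration budget keep their best iterate and are
    flagged (``converged`` False, count logged); the volume never aborts.
    """
    cfg = config or FitConfig()
    mask = np.asarray(mask, dtype=bool)
    dti_tensors, s0_map = fit_dti_loglinear(dwi, table, mask, cfg.signal_floor)
    b0 = table.b0_mask
    s0 = s0_map[mask]
    y = dwi[mask][:, ~b0] / np.clip(s0[:, None], 1e-300, None)
    y = np.clip(y, 0.0, None)
    b = table.bvals[~b0]
    g = table.bvecs[~b0]

    if init is not None:
        f0_map, tens0 = init
        f0 = np.clip(f0_map[mask], cfg.epsilon, 1.0 - cfg.epsilon)
        L = _chol_from_tensors(tens0[mask])
    elif cfg.init_mode == "md":
        D = dti_tensors[mask]
        md = np.trace(D, axis1=-2, axis2=-1) / 3.0
        f0 = init_freewater(md, cfg.d_w, cfg.md_tissue_ref, cfg.epsilon)
        # free-water-correct the DTI tensor for the tissue-tensor start
        Dt0 = (D - (1.0 - f0)[:, None, None] * cfg.d_w * np.eye(3)) / f0[:, None, None]
        L = _chol_from_tensors(Dt0)
    else:
        f0, Dt0 = profile_init(y, b, g, cfg.d_w, cfg.epsilon,
                               signal_floor=cfg.signal_floor,
                               md_anchor=cfg.md_anchor,
                               md_anchor_weight=cfg.md_anchor_weight)
        L = _chol_from_tensors(Dt0)

    u = logit(np.clip((f0 - cfg.epsilon) / (1.0 - 2.0 * cfg.epsilon), 1e-9, 1 - 1e-9))

    n_outer = cfg.outer_iterations if cfg.lambda_reg > 0 else 1
    inner = max(1, int(np.ceil(cfg.max_iter / n_outer)))
    total_iter = np.zeros(u.shape[0], dtype=int)
    ew = np.exp(-b * cfg.d_w)
    # first cycle is unpenalized; later cycles couple f_t to the 6-neighbor
    # mean of the previous cycle's field, with strength lambda_reg relative
    # to the data curvature in f_t
    u, L, cost, n_iter, conv = _lm_fit(y, b, g, u, L, cfg, inner)
    total_iter += n_iter
    for _cycle in range(1, n_outer):
        f = cfg.epsilon + (1 - 2 * cfg.epsilon) * expit(u)
        f_field = np.full(mask.shape, np.nan)
        f_field[mask] = f
        f_nb = np.clip(_neighbor_mean(f_field, mask)[mask], cfg.epsilon,
                       1 - cfg.epsilon)
        _, et, _ = _predict_batch(f, L, b, g, ew)
        h_ff = ((et - ew[None, :]) ** 2).sum(axis=1)
        w = cfg.lambda_reg * float(np.median(h_ff))
        u, L, cost, n_iter, conv = _lm_fit(
            y, b, g, u, L, cfg, inner, f_prior=f_nb, w_prior=w
        )
        total_iter += n_iter

    n_fail = int(np.count_nonzero(~conv))
    if n_fail:
        log.info("%d/%d voxels did not reach tol; best iterates retained",
                 n_fail, conv.size)

    f = cfg.epsilon + (1 - 2 * cfg.epsilon) * expit(u)
    D_t = np.einsum("njk,nlk->njl", L, L)
    evals = np.linalg.eigvalsh(D_t)
    fat = fa_from_eigenvalues(evals)
    md_t = np.clip(evals, 0.0, None).mean(axis=-1)
    # report the data-term residual only (penalty excluded)
    att, _, _ = _predict_batch(f, L, b, g, ew)
    rms = np.sqrt(((att - y) ** 2).sum(axis=1) / y.shape[1])

    def full(vals, fill=np.nan):
        out = np.full(mask.shape, fill)
        out[mask] = vals
        return out

    tensors = np.full(mask.shape + (3, 3), np.nan)
    tensors[mask] = D_t
    return FreeWaterFit(
        fw_map=full(1.0 - f),
        fat_map=full(fat),
        md_t_map=full(md_t),
        residual_map=full(rms),
        n_iter_map=full(total_iter, fill=0).astype(int),
        mask=mask,
        tensors=tensors,
        s0_map=s0_map,
        converged=full(conv.astype(float)) == 1.0,
    )
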