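"""Asymptotic time-domain fluorescence tomography.

Forward sensitivity model (diffusion-approximation slab Green's functions
with extrapolated-boundary image sources), per-pair amplitude unmixing,
Tikhonov-regularized inversion of the linear yield model
``a_pair = sum_voxels W * eta``, yield thresholding/ratio metrics, and the
intensity-tomography comparator. The Jacobian provider is an interface: any
object exposing ``W`` (pairs x voxels) can replace the diffusion backend.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import nnls

from .gating import GateSequence
from .synth import SDGeometry, SlabPhantom3D
from . import tdfit

__all__ = [
    "Jacobian",
    "PairAmplitudes",
    "YieldReconstruction",
    "diffusion_green",
    "build_jacobian",
    "fit_pair_amplitudes",
    "tikhonov_invert",
    "threshold_yield",
    "yield_ratio",
    "intensity_tomography",
    "tumor_depth",
    "reconstruct_yields",
]


def _boundary_reflection(n: float) -> float:
    """Effective internal reflection coefficient for refractive mismatch."""
    return -1.440 / n**2 + 0.710 / n + 0.668 + 0.0636 * n


def _optics(phantom: SlabPhantom3D) -> tuple[float, float, float]:
    """(D, mu_eff, z_b) for the phantom's homogeneous optical properties."""
    mua, musp, n = phantom.mu_a, phantom.mu_s_prime, phantom.n_tissue
    D = 1.0 / (3.0 * (mua + musp))
    mu_eff = np.sqrt(3.0 * mua * (mua + musp))
    reff = _boundary_reflection(n)
    zb = 2.0 * D * (1.0 + reff) / (1.0 - reff)
    return D, mu_eff, zb


def _g0(d: np.ndarray, D: float, mu_eff: float) -> np.ndarray:
    return np.exp(-mu_eff * d) / (4.0 * np.pi * D * d)


def _slab_green_oneway(
    p: np.ndarray,
    q: np.ndarray,
    L: float,
    D: float,
    mu_eff: float,
    zb: float,
    n_image_pairs: int,
    d_min: float,
) -> np.ndarray:
    """Fluence Green's function from point ``p`` to points ``q`` in a slab
    ``0 <= z <= L`` using extrapolated-boundary image sources."""
    q = np.atleast_2d(q)
    rho2 = (q[:, 0] - p[0]) ** 2 + (q[:, 1] - p[1]) ** 2
    zq = q[:, 2]
    ext = L + 2.0 * zb
    acc = np.zeros(len(q))
    for m in range(-n_image_pairs, n_image_pairs + 1):
        z_pos = 2.0 * m * ext + p[2]
        z_neg = 2.0 * m * ext - 2.0 * zb - p[2]
        d_pos = np.maximum(np.sqrt(rho2 + (zq - z_pos) ** 2), d_min)
        d_neg = np.maximum(np.sqrt(rho2 + (zq - z_neg) ** 2), d_min)
        acc += _g0(d_pos, D, mu_eff) - _g0(d_neg, D, mu_eff)
    return np.clip(acc, 0.0, None)


def diffusion_green(
    phantom: SlabPhantom3D,
    p1,
    p2,
    n_image_pairs: int = 5,
    infinite: bool = False,
) -> np.ndarray | float:
    """CW diffusion Green's function between two points (or one point and
    many), symmetrized so reciprocity holds exactly under image truncation.

    ``infinite=True`` drops the slab boundaries and returns the bare kernel
    ``exp(-mu_eff d) / (4 pi D d)``. Zero separations are capped at one
    voxel radius.
    """
    D, mu_eff, zb = _optics(phantom)
    d_min = 0.5 * float(np.mean(phantom.voxel_size))
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    scalar = p1.ndim == 1 and p2.ndim == 1
    if infinite:
        a = np.atleast_2d(p1)
        b = np.atleast_2d(p2)
        d = np.maximum(np.linalg.norm(a[:, None, :] - b[None, :, :], axis=-1), d_min)
        out = _g0(d, D, mu_eff).squeeze()
        return out.item() if scalar else out
    L = phantom.thickness
    if p1.ndim == 1 and p2.ndim == 1:
        g12 = _slab_green_oneway(p1, p2, L, D, mu_eff, zb, n_image_pairs, d_min)
        g21 = _slab_green_oneway(p2, p1, L, D, mu_eff, zb, n_image_pairs, d_min)
        return float(0.5 * (g12[0] + g21[0]))
    if p1.ndim == 1:
        point, cloud, flip = p1, np.atleast_2d(p2), False
    elif p2.ndim == 1:
        point, cloud, flip = p2, np.atleast_2d(p1), True
    else:
        raise ValueError("at least one argument must be a single point")
    g = _slab_green_oneway(point, cloud, L, D, mu_eff, zb, n_image_pairs, d_min)
    # symmetrize against the reversed direction (cloud points as sources)
    g_rev = np.array(
        [
            _slab_green_oneway(c, point[None, :], L, D, mu_eff, zb, n_image_pairs, d_min)[0]
            for c in cloud
        ]
    )
    out = 0.5 * (g + g_rev)
    return out


@dataclass
class Jacobian:
    """Born-type sensitivity matrix ``W`` (pairs x voxels) plus provenance."""

    W: np.ndarray
    geometry: SDGeometry
    optics: tuple[float, float, float]  # (mu_a, mu_s_prime, n)
    grid_shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float]
    wavelengths: tuple[str, str] = ("excitation", "emission")

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        if not np.isfinite(self.W).all():
            raise ValueError("Jacobian entries must be finite")
        if (self.W < 0).any():
            raise ValueError("Jacobian entries must be >= 0")
        if self.W.shape[0] != self.geometry.n_pairs:
            raise ValueError("Jacobian row count must equal number of pairs")


def build_jacobian(
    phantom: SlabPhantom3D,
    geom: SDGeometry,
    normalize: bool = False,
    n_image_pairs: int = 5,
) -> Jacobian:
    """Assemble the Born sensitivity matrix.

    Each row is ``G_x(rs, r') * G_m(r', rd) * voxel_volume`` over all voxel
    centers, optionally normalized by the pair's excitation transmittance
    ``G_x(rs, rd)``. Sources and detectors sit on the slab faces and are
    inset by one transport mean free path before evaluating the diffusion
    kernel. Identical optics are assumed at the excitation and emission
    wavelengths.
    """
    voxels = phantom.voxel_centers()
    if voxels.size == 0:
        raise ValueError("voxel grid is empty")
    D, mu_eff, zb = _optics(phantom)
    d_min = 0.5 * float(np.mean(phantom.voxel_size))
    L = phantom.thickness
    ltr = 1.0 / phantom.mu_s_prime

    def _inset(p: np.ndarray) -> np.ndarray:
        p = p.copy()
        if p[2] >= L:
            p[2] = L - ltr
        elif p[2] <= 0:
            p[2] = ltr
        return p

    def _green(point: np.ndarray) -> np.ndarray:
        return _slab_green_oneway(
            point, voxels, L, D, mu_eff, zb, n_image_pairs, d_min
        )

    g_src = {}
    src_in = {}
    for si in {s for s, _ in geom.pairing}:
        src_in[si] = _inset(geom.sources[si])
        g_src[si] = _green(src_in[si])
    g_det = {}
    det_in = {}
    for di in {d for _, d in geom.pairing}:
        det_in[di] = _inset(geom.detectors[di])
        g_det[di] = _green(det_in[di])

    vol = phantom.voxel_volume
    W = np.empty((geom.n_pairs, len(voxels)))
    for row, (si, di) in enumerate(geom.pairing):
        W[row] = g_src[si] * g_det[di] * vol
        if normalize:
            t = _slab_green_oneway(
                src_in[si], det_in[di][None, :], L, D, mu_eff, zb, n_image_pairs, d_min
            )[0]
            if t > 0:
                W[row] /= t
    return Jacobian(
        W=W,
        geometry=geom,
        optics=(phantom.mu_a, phantom.mu_s_prime, phantom.n_tissue),
        grid_shape=phantom.shape,
        voxel_size=phantom.voxel_size,
    )


@dataclass
class PairAmplitudes:
    """Per-pair decay amplitudes at a fixed lifetime basis."""

    a0: np.ndarray
    aT: np.ndarray
    aNS: np.ndarray
    tau_t: float
    tau_ns: float
    ok: np.ndarray  # per-pair fit success

    @property
    def n_pairs(self) -> int:
        return len(self.aT)


def traces_to_array(traces: pd.DataFrame, gates: GateSequence) -> np.ndarray:
    """Reshape a long-form trace table to ``(n_pairs, n_gates)`` preserving
    first-appearance pair order."""
    key = pd.Series(
        list(zip(traces["source_id"], traces["detector_id"]))
    )
    codes, _ = pd.factorize(key)
    n_pairs = codes.max() + 1
    out = np.zeros((n_pairs, gates.n_gates))
    out[codes, traces["gate_index"].to_numpy()] = traces["counts"].to_numpy()
    return out


def fit_pair_amplitudes(
    traces: pd.DataFrame | np.ndarray,
    gates: GateSequence,
    tau_t: float,
    tau_ns: float,
    window: str | tuple[int, int] | None = "auto",
) -> PairAmplitudes:
    """Dual-basis fit of each source-detector pair's asymptotic decay.

    Pairs whose decay window cannot be established are flagged ``ok=False``
    (and should be dropped from the inversion). The decay window is selected
    on a peak-normalized copy of each trace so the choice is invariant to
    source power and the arbitrary scale of the forward model.
    """
    arr = (
        traces_to_array(traces, gates)
        if isinstance(traces, pd.DataFrame)
        else np.asarray(traces, dtype=float)
    )
    n_pairs = arr.shape[0]
    a0 = np.zeros(n_pairs)
    aT = np.zeros(n_pairs)
    aNS = np.zeros(n_pairs)
    ok = np.ones(n_pairs, dtype=bool)
    for i in range(n_pairs):
        if window == "auto":
            peak = arr[i].max()
            if peak <= 0:
                ok[i] = False
                continue
            win = tdfit.select_decay_window(arr[i] * (1e4 / peak), gates)
            if win is None:
                ok[i] = False
                continue
        else:
            win = window
        a0[i], aT[i], aNS[i] = tdfit.fit_dual_basis(
            arr[i], gates, win, tau_t, tau_ns
        )
    return PairAmplitudes(a0, aT, aNS, tau_t, tau_ns, ok)


def _largest_sq_singular_value(W: np.ndarray, iters: int = 100) -> float:
    """Largest eigenvalue of W^T W by power iteration (deterministic start)."""
    v = np.ones(W.shape[1]) / np.sqrt(W.shape[1])
    s = 0.0
    for _ in range(iters):
        v = W.T @ (W @ v)
        s = np.linalg.norm(v)
        if s == 0:
            return 0.0
        v /= s
    return float(s)


LAMBDA_GRID = (1e-1, 1e-2, 1e-3, 1e-4, 1e-5, 1e-6)


def tikhonov_invert(
    jacobian,
    amplitudes: np.ndarray,
    lambda_rel: float | str = 1e-2,
    clip_negative: bool = True,
    nonneg: bool = False,
    keep: np.ndarray | None = None,
    sensitivity_scaled: bool = False,
    auto_rtol: float = 1e-2,
) -> np.ndarray:
    """Solve ``min ||W eta - a||^2 + lambda ||eta||^2`` with the identity
    regularizer, ``lambda = lambda_rel * max eig(W^T W)``.

    The solve uses the dual normal equations
    ``eta = W^T (W W^T + lambda I)^{-1} a`` (exact for identity Tikhonov),
    so the cost scales with the number of pairs, not voxels. Negative voxels
    are clipped to zero after the solve; ``nonneg=True`` instead solves the
    augmented system with NNLS (small problems only). ``keep`` selects the
    pair subset to invert (e.g. successful fits). Accepts a
    :class:`Jacobian` (returns a volume) or a bare matrix (returns a flat
    vector).

    ``sensitivity_scaled=True`` applies the standard depth-compensation for
    diffuse tomography: columns of ``W`` are normalized to unit norm before
    the solve and the solution is rescaled back, which removes the bias of
    the minimum-norm solution toward the high-sensitivity voxels next to
    the sources and detectors.

    ``lambda_rel="auto"`` selects the regularization strength by the
    discrepancy principle: the largest value on a fixed log grid whose
    relative residual ``||W eta - a|| / ||a||`` does not exceed
    ``auto_rtol``. For noise-free data this admits the weak regularization
    the problem supports instead of over-smoothing.
    """
    if lambda_rel != "auto" and lambda_rel <= 0:
        raise ValueError("lambda_rel must be > 0")
    is_jac = isinstance(jacobian, Jacobian)
    W = jacobian.W if is_jac else np.asarray(jacobian, dtype=float)
    a = np.asarray(amplitudes, dtype=float)
    if keep is not None:
        W = W[keep]
        a = a[keep]
    col_scale = None
    if sensitivity_scaled:
        col_scale = np.linalg.norm(W, axis=0)
        col_scale[col_scale == 0] = 1.0
        W = W / col_scale
    s1sq = _largest_sq_singular_value(W)
    if s1sq == 0:
        raise ValueError("Jacobian has rank 0")
    if lambda_rel == "auto":
        if nonneg:
            raise ValueError("lambda_rel='auto' is not supported with nonneg")
        a_norm = np.linalg.norm(a)
        eta = np.zeros(W.shape[1])
        for lr in LAMBDA_GRID:
            K = W @ W.T + lr * s1sq * np.eye(W.shape[0])
            eta = W.T @ cho_solve(cho_factor(K), a)
            if a_norm == 0 or np.linalg.norm(W @ eta - a) <= auto_rtol * a_norm:
                break
        if clip_negative:
            eta = np.clip(eta, 0.0, None)
    else:
        lam = lambda_rel * s1sq
        if nonneg:
            A = np.vstack([W, np.sqrt(lam) * np.eye(W.shape[1])])
            rhs = np.concatenate([a, np.zeros(W.shape[1])])
            eta, _ = nnls(A, rhs)
        else:
            K = W @ W.T + lam * np.eye(W.shape[0])
            eta = W.T @ cho_solve(cho_factor(K), a)
            if clip_negative:
                eta = np.clip(eta, 0.0, None)
    if col_scale is not None:
        eta = eta / col_scale
    if is_jac:
        return eta.reshape(jacobian.grid_shape)
    return eta


def threshold_yield(
    eta: np.ndarray, keep_frac: float = 0.8, mode: str = "max"
) -> tuple[np.ndarray, float]:
    """Keep high-yield voxels and return ``(mask, mean over mask)``.

    ``mode="max"`` keeps voxels with ``eta >= keep_frac * max(eta)`` (the
    default reading of an "80% threshold"); ``mode="percentile"`` instead
    drops the lowest ``1 - keep_frac`` quantile.
    """
    if not 0.0 < keep_frac < 1.0:
        raise ValueError("keep_frac must be in (0, 1)")
    eta = np.asarray(eta, dtype=float)
    if eta.max() <= 0:
        raise ValueError("yield volume is identically zero")
    if mode == "max":
        mask = eta >= keep_frac * eta.max()
    elif mode == "percentile":
        mask = eta >= np.quantile(eta, 1.0 - keep_frac)
    else:
        raise ValueError(f"unknown threshold mode {mode!r}")
    return mask, float(eta[mask].mean())


@dataclass
class YieldReconstruction:
    """Reconstructed specific/nonspecific/intensity yields plus metrics."""

    etaT: np.ndarray
    etaNS: np.ndarray
    etaI: np.ndarray | None
    tumor_mask: np.ndarray
    ns_mask: np.ndarray
    mean_etaT: float
    mean_etaNS: float
    mean_etaI: float | None
    ratio: float
    depth_mm: float | None


def yield_ratio(recon: YieldReconstruction | tuple, keep_frac: float = 0.8) -> float:
    """Normalized mean-yield ratio.

    ``mean etaT`` is taken over the top-``keep_frac``-of-max etaT voxels
    (the tumor mask); ``mean etaNS`` over the top fraction of the etaNS
    values restricted to those tumor voxels. The ratio is invariant to any
    global positive rescaling of both volumes.
    """
    if isinstance(recon, YieldReconstruction):
        etaT, etaNS = recon.etaT, recon.etaNS
    else:
        etaT, etaNS = recon
    tumor_mask, mean_t = threshold_yield(etaT, keep_frac)
    ns_in_tumor = np.asarray(etaNS)[tumor_mask]
    if ns_in_tumor.max() <= 0:
        raise ValueError("nonspecific yield is zero over the tumor mask")
    ns_sel = ns_in_tumor >= keep_frac * ns_in_tumor.max()
    mean_ns = float(ns_in_tumor[ns_sel].mean())
    if mean_ns == 0:
        raise ValueError("zero denominator in yield ratio")
    return mean_t / mean_ns


def intensity_tomography(
    traces: pd.DataFrame | np.ndarray,
    gates: GateSequence,
    jacobian,
    lambda_rel: float | str = 1e-2,
    sensitivity_scaled: bool = False,
) -> np.ndarray:
    """Comparator reconstruction from time-summed (intensity) data using the
    same Jacobian and regularization policy."""
    arr = (
        traces_to_array(traces, gates)
        if isinstance(traces, pd.DataFrame)
        else np.asarray(traces, dtype=float)
    )
    summed = arr.sum(axis=1)
    if not summed.any():
        W = jacobian.W if isinstance(jacobian, Jacobian) else np.asarray(jacobian)
        zero = np.zeros(W.shape[1])
        return zero.reshape(jacobian.grid_shape) if isinstance(jacobian, Jacobian) else zero
    return tikhonov_invert(
        jacobian, summed, lambda_rel, sensitivity_scaled=sensitivity_scaled
    )


def tumor_depth(
    eta: np.ndarray,
    mask: np.ndarray,
    voxel_centers: np.ndarray,
    surface_points: np.ndarray,
) -> float:
    """Distance (mm) from the reconstruction's central voxel to the nearest
    surface point.

    The central voxel is the yield-weighted center of mass over the kept
    mask, snapped to the nearest voxel center.
    """
    mask = np.asarray(mask, dtype=bool).ravel()
    if not mask.any():
        raise ValueError("empty mask")
    eta = np.asarray(eta, dtype=float).ravel()
    centers = np.asarray(voxel_centers, dtype=float)
    wts = np.clip(eta[mask], 0.0, None)
    if wts.sum() == 0:
        wts = np.ones(mask.sum())
    com = (centers[mask] * wts[:, None]).sum(axis=0) / wts.sum()
    central = centers[np.argmin(((centers - com) ** 2).sum(axis=1))]
    d = np.sqrt(((np.asarray(surface_points) - central) ** 2).sum(axis=1))
    return float(d.min())


def reconstruct_yields(
    traces: pd.DataFrame | np.ndarray,
    gates: GateSequence,
    jacobian: Jacobian,
    phantom: SlabPhantom3D,
    tau_t: float,
    tau_ns: float,
    lambda_rel: float | str = "auto",
    keep_frac: float = 0.8,
    with_intensity: bool = True,
    sensitivity_scaled: bool = True,
) -> YieldReconstruction:
    """End-to-end ATD reconstruction: pair amplitudes -> Tikhonov inversion
    of etaT and etaNS (sensitivity-scaled by default) -> threshold masks,
    yield ratio, and tumor depth."""
    amps = fit_pair_amplitudes(traces, gates, tau_t, tau_ns)
    etaT = tikhonov_invert(
        jacobian, amps.aT, lambda_rel, keep=amps.ok,
        sensitivity_scaled=sensitivity_scaled,
    )
    etaNS = tikhonov_invert(
        jacobian, amps.aNS, lambda_rel, keep=amps.ok,
        sensitivity_scaled=sensitivity_scaled,
    )
    tumor_mask, mean_t = threshold_yield(etaT, keep_frac)
    ns_in_tumor = etaNS[tumor_mask]
    ns_sel = (
        ns_in_tumor >= keep_frac * ns_in_tumor.max()
        if ns_in_tumor.max() > 0
        else np.ones_like(ns_in_tumor, dtype=bool)
    )
    ns_mask = np.zeros_like(tumor_mask)
    ns_mask[tumor_mask] = ns_sel
    mean_ns = float(ns_in_tumor[ns_sel].mean()) if ns_in_tumor.size else np.nan
    etaI = None
    mean_i = None
    if with_intensity:
        etaI = intensity_tomography(
            traces, gates, jacobian, lambda_rel,
            sensitivity_scaled=sensitivity_scaled,
        )
        if etaI.max() > 0:
            _, mean_i = threshold_yield(etaI, keep_frac)
    else:
        etaI = None
    depth = tumor_depth(
        etaT, tumor_mask, phantom.voxel_centers(), phantom.surface_points()
    )
    ratio = mean_t / mean_ns if mean_ns and mean_ns > 0 else np.nan
    return YieldReconstruction(
        etaT=etaT,
        etaNS=etaNS,
        etaI=etaI,
        tumor_mask=tumor_mask,
        ns_mask=ns_mask,
        mean_etaT=mean_t,
        mean_etaNS=mean_ns,
        mean_etaI=mean_i,
        ratio=ratio,
        depth_mm=depth,
    )
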