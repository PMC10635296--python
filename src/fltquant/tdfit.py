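"""Per-pixel analysis of gated image stacks.

Turns a gated photon-count cube into summed-intensity images, single-
exponential lifetime (FLT) maps, and dual-basis amplitude maps obtained by
decomposing each decay into two fixed-lifetime exponentials plus a constant
offset::

    U(t) = a0 + aT * exp(-t / tauT) + aNS * exp(-t / tauNS)

Counts are gate integrals, so the fitted basis functions are the per-gate
integrals of the exponentials; amplitudes are then reported in the same
units as the generative (rate) amplitudes. For a single exponential the gate
factor is delay-independent and the fitted lifetime is unaffected.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit, lsq_linear

from .gating import GateSequence, TDImageStack
from .synth import gate_basis

__all__ = [
    "TDImageStack",
    "FLTMap",
    "DualBasisResult",
    "SingleExpFit",
    "sum_gates",
    "intensity_mask",
    "select_decay_window",
    "fit_single_exp",
    "flt_map",
    "fit_dual_basis",
    "dual_basis_maps",
]

TAU_BOUNDS = (0.05, 10.0)
MIN_BASIS_SEPARATION = 0.02  # ns


def sum_gates(stack: TDImageStack) -> np.ndarray:
    """Summed-intensity image: per-pixel sum over the gate axis."""
    return stack.data.sum(axis=0)


def intensity_mask(stack: TDImageStack, frac: float = 0.20) -> np.ndarray:
    """Keep pixels whose summed intensity is at least ``frac`` of the maximum
    summed intensity anywhere in the dataset (>= comparison, boundary kept).
    """
    if not 0.0 < frac < 1.0:
        raise ValueError("frac must be in (0, 1)")
    total = sum_gates(stack)
    mask = total >= frac * total.max()
    if not mask.any():
        warnings.warn("all pixels fall below the intensity threshold")
    return mask


def select_decay_window(
    decay: np.ndarray,
    gates: GateSequence,
    skip: int = 1,
    min_length: int = 4,
) -> tuple[int, int] | None:
    """Pick the asymptotic (decay-portion) gate window for tail fitting.

    The window starts ``skip`` gates after the peak gate and ends at the last
    gate whose counts exceed a noise floor estimated from the final three
    gates (``a0_est + 3*sqrt(a0_est)``). Returns ``None`` when fewer than
    ``min_length`` gates qualify. With an IRF the window must additionally
    start after ``3 * irf_sigma``.
    """
    decay = np.asarray(decay, dtype=float)
    first = int(np.argmax(decay)) + skip
    if gates.irf_sigma > 0:
        t = gates.times
        t_min = 3.0 * gates.irf_sigma
        first = max(first, int(np.searchsorted(t, t_min)))
    a0_est = max(float(decay[-3:].mean()), 0.0)
    floor = a0_est + 3.0 * np.sqrt(a0_est)
    above = np.nonzero(decay > floor)[0]
    above = above[above >= first]
    if above.size == 0:
        return None
    last = int(above[-1])
    if last - first + 1 < min_length:
        return None
    return first, last


@dataclass
class SingleExpFit:
    tau: float
    amplitude: float
    offset: float
    r2: float
    ok: bool


def _model_single(t, a0, a, tau):
    return a0 + a * np.exp(-t / tau)


def fit_single_exp(
    decay: np.ndarray,
    gates: GateSequence,
    window: tuple[int, int] | None,
    weighted: bool = True,
) -> SingleExpFit:
    """Weighted nonlinear least-squares fit of ``a0 + a*exp(-t/tau)``.

    The fit is initialized from the log-linear slope of background-
    subtracted counts; ``tau`` is bounded to ``(0.05, 10)`` ns. Poisson
    weighting uses ``sigma = sqrt(max(counts, 1))``. Returns NaN estimates
    with ``ok=False`` on failure.
    """
    nan = SingleExpFit(np.nan, np.nan, np.nan, np.nan, False)
    if window is None:
        return nan
    first, last = window
    if not (0 <= first <= last < gates.n_gates) or last - first + 1 < 3:
        return nan
    decay = np.asarray(decay, dtype=float)
    t = gates.times[first : last + 1]
    y = decay[first : last + 1]

    a0_init = max(float(decay[-3:].mean()), 0.0)
    resid = np.clip(y - a0_init, 1e-12, None)
    with np.errstate(all="ignore"):
        slope, intercept = np.polyfit(t, np.log(resid), 1)
    tau_init = float(np.clip(-1.0 / slope if slope < 0 else 1.0, *TAU_BOUNDS))
    a_init = max(float(np.exp(intercept)), 1e-12)

    sigma = np.sqrt(np.maximum(y, 1.0)) if weighted else None
    try:
        popt, _ = curve_fit(
            _model_single,
            t,
            y,
            p0=(a0_init, a_init, tau_init),
            sigma=sigma,
            absolute_sigma=False,
            bounds=([0.0, 0.0, TAU_BOUNDS[0]], [np.inf, np.inf, TAU_BOUNDS[1]]),
            maxfev=2000,
            xtol=1e-13,
            ftol=1e-13,
            gtol=1e-13,
        )
    except (RuntimeError, ValueError):
        return nan
    a0, a, tau = popt
    pred = _model_single(t, *popt)
    ss_res = float(((y - pred) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return SingleExpFit(float(tau), float(a), float(a0), r2, True)


@dataclass
class FLTMap:
    """Per-pixel lifetime map; NaN marks masked or unfittable pixels."""

    tau: np.ndarray
    fit_window: np.ndarray  # (2, rows, cols), -1 where undefined
    r2_fit: np.ndarray


def flt_map(stack: TDImageStack, mask: np.ndarray, weighted: bool = True) -> FLTMap:
    """Fit every kept pixel with :func:`fit_single_exp`."""
    gates = stack.gates
    rows, cols = stack.data.shape[1:]
    tau = np.full((rows, cols), np.nan)
    r2 = np.full((rows, cols), np.nan)
    win = np.full((2, rows, cols), -1, dtype=int)
    for r, c in zip(*np.nonzero(mask)):
        decay = stack.data[:, r, c]
        window = select_decay_window(decay, gates)
        fit = fit_single_exp(decay, gates, window, weighted=weighted)
        if fit.ok:
            tau[r, c] = fit.tau
            r2[r, c] = fit.r2
            win[:, r, c] = window
    return FLTMap(tau, win, r2)


def fit_dual_basis(
    decay: np.ndarray,
    gates: GateSequence,
    window: tuple[int, int] | None,
    tau_t: float,
    tau_ns: float,
    nonneg: bool = True,
    weighted: bool = True,
) -> tuple[float, float, float]:
    """Linear decomposition of a decay into the fixed two-lifetime basis.

    Solves for ``(a0, aT, aNS)`` by (weighted) linear least squares with the
    gate-integrated exponential regressors; ``aT`` and ``aNS`` are
    constrained non-negative unless ``nonneg=False``. ``window=None`` uses
    all gates.

    Raises ``ValueError`` when the basis lifetimes are closer than 0.02 ns
    (ill-conditioned basis).
    """
    if tau_t <= 0 or tau_ns <= 0:
        raise ValueError("basis lifetimes must be > 0")
    if abs(tau_t - tau_ns) < MIN_BASIS_SEPARATION:
        raise ValueError(
            f"basis lifetimes separated by < {MIN_BASIS_SEPARATION} ns"
        )
    decay = np.asarray(decay, dtype=float)
    if window is None:
        first, last = 0, gates.n_gates - 1
    else:
        first, last = window
    sl = slice(first, last + 1)
    y = decay[sl]
    A = np.column_stack(
        [
            np.full(y.size, gates.gate_width),
            gate_basis(tau_t, gates)[sl],
            gate_basis(tau_ns, gates)[sl],
        ]
    )
    if weighted:
        wts = 1.0 / np.sqrt(np.maximum(y, 1.0))
        Aw, yw = A * wts[:, None], y * wts
    else:
        Aw, yw = A, y
    # normalize the data scale so the solver tolerances are scale-free
    scale = float(np.abs(yw).max()) or 1.0
    coef, *_ = np.linalg.lstsq(Aw, yw / scale, rcond=None)
    if nonneg and (coef[1] < 0 or coef[2] < 0):
        dust = -1e-9 * max(float(np.abs(coef).max()), 1e-30)
        if min(coef[1], coef[2]) >= dust:
            coef[1:] = np.clip(coef[1:], 0.0, None)
        else:
            res = lsq_linear(
                Aw,
                yw / scale,
                bounds=([-np.inf, 0.0, 0.0], [np.inf, np.inf, np.inf]),
                tol=1e-14,
            )
            coef = res.x
    coef = coef * scale
    return float(coef[0]), float(coef[1]), float(coef[2])


@dataclass
class DualBasisResult:
    """Exposure-scaled amplitude maps at a fixed lifetime basis."""

    a0_map: np.ndarray
    aT_map: np.ndarray
    aNS_map: np.ndarray
    tau_t: float
    tau_ns: float
    ratio_map: np.ndarray


def dual_basis_maps(
    stack: TDImageStack,
    mask: np.ndarray,
    tau_t: float,
    tau_ns: float,
    exposure: float | None = None,
    window: str | tuple[int, int] | None = "auto",
    nonneg: bool = True,
    ratio_floor_frac: float = 1e-6,
) -> DualBasisResult:
    """Per-pixel dual-basis fit with exposure scaling.

    Amplitudes are divided by the camera exposure so maps from different
    acquisitions are comparable; the ratio map is ``aT/aNS`` with NaN where
    ``aNS`` falls below ``ratio_floor_frac`` of the map's maximum ``aNS``.
    ``window="auto"`` selects the decay portion per pixel.
    """
    exposure = stack.exposure if exposure is None else exposure
    if exposure <= 0:
        raise ValueError("exposure must be > 0")
    gates = stack.gates
    rows, cols = stack.data.shape[1:]
    a0 = np.full((rows, cols), np.nan)
    aT = np.full((rows, cols), np.nan)
    aNS = np.full((rows, cols), np.nan)
    for r, c in zip(*np.nonzero(mask)):
        decay = stack.data[:, r, c]
        if window == "auto":
            win = select_decay_window(decay, gates)
            if win is None:
                continue
        else:
            win = window
        v0, vT, vNS = fit_dual_basis(
            decay, gates, win, tau_t, tau_ns, nonneg=nonneg
        )
        a0[r, c] = v0 / exposure
        aT[r, c] = vT / exposure
        aNS[r, c] = vNS / exposure
    with np.errstate(invalid="ignore"):
        floor = ratio_floor_frac * np.nanmax(aNS) if np.isfinite(aNS).any() else 0.0
        ratio = np.where(aNS >= floor, aT / np.where(aNS > 0, aNS, np.nan), np.nan)
    return DualBasisResult(a0, aT, aNS, tau_t, tau_ns, ratio)
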