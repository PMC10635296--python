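"""Synthetic phantom and data generators with known ground truth.

Everything the downstream stages consume can be generated here: gated decay
vectors, 2-D wide-field phantoms with heterogeneous specific/nonspecific
amplitudes, 3-D slab phantoms with a transmission source-detector layout for
tomography, and microscopy-scale FLIM + IHC slide pairs. All generators are
pure functions of ``(config, seed)``.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import erfc

from . import reference
from .gating import DecaySpec, GateSequence, TDImageStack

__all__ = [
    "GateSequence",
    "DecaySpec",
    "Phantom2D",
    "SlabPhantom3D",
    "SDGeometry",
    "MicroscopySlide",
    "WidefieldConfig",
    "TomoConfig",
    "MicroscopyConfig",
    "RegionSpec",
    "REGION_LABELS",
    "gate_basis",
    "simulate_decay",
    "generate_widefield_phantom",
    "generate_widefield_cohort",
    "generate_tomo_phantom",
    "simulate_tomo_data",
    "pair_amplitude_truth",
    "generate_microscopy_slide",
]


# ---------------------------------------------------------------------------
# gated decay model
# ---------------------------------------------------------------------------

def gate_basis(tau: float, gates: GateSequence) -> np.ndarray:
    """Per-gate integral of a unit-amplitude exponential ``exp(-t/tau)``.

    For ideal gating the integral over ``[t, t+w]`` has the closed form
    ``tau * (1 - exp(-w/tau)) * exp(-t/tau)``; the gate factor is independent
    of the delay ``t``, so single-exponential tail fits are unaffected by
    gate integration. With a Gaussian IRF of width ``irf_sigma`` the
    IRF-convolved decay is integrated numerically over each gate.
    """
    if tau <= 0:
        raise ValueError("tau must be > 0")
    t = gates.times
    w = gates.gate_width
    sigma = gates.irf_sigma
    if sigma == 0:
        return tau * (1.0 - np.exp(-w / tau)) * np.exp(-t / tau)
    # exponentially modified Gaussian, integrated on a fine sub-grid per gate
    sub = np.linspace(0.0, w, 65)  # 64 intervals
    s = t[:, None] + sub[None, :]
    arg = sigma**2 / (2 * tau**2) - s / tau
    # stable form of exp(arg) * erfc((sigma/tau - s/sigma)/sqrt(2)) / 2
    emg = 0.5 * np.exp(arg) * erfc((sigma / tau - s / sigma) / np.sqrt(2.0))
    return np.trapezoid(emg, sub, axis=1)


def simulate_decay(
    spec: DecaySpec,
    gates: GateSequence,
    noise: str = "none",
    seed: int | None = None,
) -> np.ndarray:
    """Simulate a gated decay, returning one count value per gate.

    ``noise="none"`` is bit-reproducible; ``noise="poisson"`` draws Poisson
    counts from the expected values and is reproducible per ``seed``.
    """
    expected = spec.a0 * gates.gate_width * np.ones(gates.n_gates)
    for amp, tau in spec.components:
        expected = expected + amp * gate_basis(tau, gates)
    if np.any(expected < 0):
        raise ValueError("decay spec yields negative expected counts")
    if noise == "none":
        return expected
    if noise == "poisson":
        rng = np.random.default_rng(seed)
        return rng.poisson(expected).astype(float)
    raise ValueError(f"unknown noise model {noise!r}")


# ---------------------------------------------------------------------------
# wide-field 2-D phantom
# ---------------------------------------------------------------------------

@dataclass
class Phantom2D:
    """Ground truth for a 2-D wide-field phantom.

    ``label_map``: 0 background, 1 normal tissue, 2 tumor. Amplitudes are in
    counts per unit exposure; ``aT_map`` is zero outside tissue.
    ``expression_score`` is a scalar stand-in for an ex vivo band-density
    measurement and, for a single-subject phantom, is a fixed monotone
    function of the mean tumor ``aT``.
    """

    label_map: np.ndarray
    aT_map: np.ndarray
    aNS_map: np.ndarray
    a0_map: np.ndarray
    expression_score: float
    exposure: float = 1.0

    @property
    def tumor_mask(self) -> np.ndarray:
        return self.label_map == 2

    @property
    def normal_mask(self) -> np.ndarray:
        return self.label_map == 1


@dataclass
class WidefieldConfig:
    shape: tuple[int, int] = (48, 48)
    tumor_radius: float = 10.0
    tumor_center: tuple[float, float] | None = None
    margin: int = 2
    a0: float = 20.0
    aT_tumor: float = 6000.0
    aNS: float = 3000.0
    tau_t: float = reference.IN_VIVO_TUMOR_FLT_NS
    tau_ns: float = reference.IN_VIVO_NORMAL_FLT_NS
    gates: GateSequence = field(default_factory=GateSequence)
    exposure: float = 1.0
    noise: str = "poisson"
    amp_jitter: float = 0.05
    #: scale of the expression_score link (score = link * mean tumor aT)
    expression_link: float = 0.01


def generate_widefield_phantom(
    config: WidefieldConfig, seed: int | None = None
) -> tuple[Phantom2D, TDImageStack]:
    """Generate a two-region phantom and its gated image stack."""
    rng = np.random.default_rng(seed)
    rows, cols = config.shape
    cy, cx = config.tumor_center or ((rows - 1) / 2.0, (cols - 1) / 2.0)
    m = config.margin
    if (
        cy - config.tumor_radius < m
        or cx - config.tumor_radius < m
        or cy + config.tumor_radius > rows - 1 - m
        or cx + config.tumor_radius > cols - 1 - m
    ):
        raise ValueError("tumor region does not fit inside the tissue area")

    label = np.zeros((rows, cols), dtype=int)
    label[m : rows - m, m : cols - m] = 1
    yy, xx = np.mgrid[0:rows, 0:cols]
    tumor = (yy - cy) ** 2 + (xx - cx) ** 2 <= config.tumor_radius**2
    label[tumor] = 2

    def _jitter(shape):
        return np.clip(1.0 + config.amp_jitter * rng.standard_normal(shape), 0.0, None)

    tissue = label > 0
    aT = np.zeros((rows, cols))
    aT[label == 2] = config.aT_tumor * _jitter(int((label == 2).sum()))
    aNS = np.zeros((rows, cols))
    aNS[tissue] = config.aNS * _jitter(int(tissue.sum()))
    a0 = np.full((rows, cols), config.a0)

    fT = gate_basis(config.tau_t, config.gates)
    fNS = gate_basis(config.tau_ns, config.gates)
    w = config.gates.gate_width
    expected = config.exposure * (
        a0[None] * w + aT[None] * fT[:, None, None] + aNS[None] * fNS[:, None, None]
    )
    if config.noise == "poisson":
        data = rng.poisson(expected).astype(float)
    elif config.noise == "none":
        data = expected
    else:
        raise ValueError(f"unknown noise model {config.noise!r}")

    score = config.expression_link * float(aT[label == 2].mean())
    phantom = Phantom2D(
        label_map=label,
        aT_map=aT,
        aNS_map=aNS,
        a0_map=a0,
        expression_score=score,
        exposure=config.exposure,
    )
    return phantom, TDImageStack(data, config.gates, config.exposure)


@dataclass
class CohortSubject:
    subject_id: str
    expression: float
    phantom: Phantom2D
    stack: TDImageStack


def generate_widefield_cohort(
    n_subjects: int,
    seed: int,
    base: WidefieldConfig | None = None,
    expressions: np.ndarray | None = None,
    gain_sigma: float = 0.6,
    ans_jitter: float = 0.15,
    exposure_range: tuple[float, float] = (0.5, 2.0),
) -> list[CohortSubject]:
    """Generate a cohort in which only ``aT`` tracks expression.

    Each subject carries an unrecorded multiplicative gain (log-normal,
    ``gain_sigma``) applied to every amplitude — standing in for dose and
    uptake variability — plus a recorded camera exposure drawn from
    ``exposure_range`` and a jittered nonspecific amplitude. Raw intensity
    is therefore corrupted subject-to-subject while the specific/nonspecific
    amplitude ratio is not. ``expression`` is stored as the subject's ground
    truth score.
    """
    if base is None:
        base = WidefieldConfig()
    if expressions is None:
        expressions = np.linspace(0.5, 2.5, n_subjects)
    expressions = np.asarray(expressions, dtype=float)
    if len(expressions) != n_subjects:
        raise ValueError("expressions length must equal n_subjects")
    rng = np.random.default_rng(seed)
    subjects = []
    for i, expr in enumerate(expressions):
        gain = float(rng.lognormal(0.0, gain_sigma))
        ans = base.aNS * gain * float(
            np.clip(1.0 + ans_jitter * rng.standard_normal(), 0.1, None)
        )
        cfg = dataclasses.replace(
            base,
            aT_tumor=base.aT_tumor * expr * gain,
            aNS=ans,
            a0=base.a0 * gain,
            exposure=float(rng.uniform(*exposure_range)),
        )
        child_seed = int(rng.integers(0, 2**31 - 1))
        phantom, stack = generate_widefield_phantom(cfg, child_seed)
        phantom.expression_score = float(expr)
        subjects.append(CohortSubject(f"S{i + 1:02d}", float(expr), phantom, stack))
    return subjects


# ---------------------------------------------------------------------------
# tomographic slab phantom and geometry
# ---------------------------------------------------------------------------

@dataclass
class SlabPhantom3D:
    """Voxelized optical slab. z runs from the ventral (detector) face at
    z=0 toward the dorsal (source) face at z=thickness. x and y are centered
    on the slab axis. Arrays are indexed ``(ix, iy, iz)``.
    """

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float]
    mu_a: float
    mu_s_prime: float
    n_tissue: float
    etaT_true: np.ndarray
    etaNS_true: np.ndarray
    inclusion_mask: np.ndarray

    def __post_init__(self) -> None:
        if self.mu_a <= 0 or self.mu_s_prime <= 0:
            raise ValueError("optical properties must be > 0")
        if np.any(self.etaT_true < 0) or np.any(self.etaNS_true < 0):
            raise ValueError("yields must be >= 0")

    @property
    def thickness(self) -> float:
        return self.shape[2] * self.voxel_size[2]

    @property
    def voxel_volume(self) -> float:
        dx, dy, dz = self.voxel_size
        return dx * dy * dz

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        nx, ny, nz = self.shape
        dx, dy, dz = self.voxel_size
        xs = (np.arange(nx) + 0.5) * dx - nx * dx / 2.0
        ys = (np.arange(ny) + 0.5) * dy - ny * dy / 2.0
        zs = (np.arange(nz) + 0.5) * dz
        return xs, ys, zs

    def voxel_centers(self) -> np.ndarray:
        """All voxel centers, shape ``(N, 3)``, C-order over ``(ix, iy, iz)``."""
        xs, ys, zs = self.axes()
        gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
        return np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)

    def surface_points(self) -> np.ndarray:
        """Points on the physical slab boundary (face centers of boundary
        voxels projected onto the outer planes)."""
        xs, ys, zs = self.axes()
        nx, ny, nz = self.shape
        dx, dy, dz = self.voxel_size
        pts = []
        gx, gy = np.meshgrid(xs, ys, indexing="ij")
        for zface in (0.0, self.thickness):
            pts.append(
                np.stack([gx.ravel(), gy.ravel(), np.full(gx.size, zface)], axis=1)
            )
        gy2, gz2 = np.meshgrid(ys, zs, indexing="ij")
        for xface in (-nx * dx / 2.0, nx * dx / 2.0):
            pts.append(
                np.stack([np.full(gy2.size, xface), gy2.ravel(), gz2.ravel()], axis=1)
            )
        gx3, gz3 = np.meshgrid(xs, zs, indexing="ij")
        for yface in (-ny * dy / 2.0, ny * dy / 2.0):
            pts.append(
                np.stack([gx3.ravel(), np.full(gx3.size, yface), gz3.ravel()], axis=1)
            )
        return np.concatenate(pts, axis=0)


@dataclass
class SDGeometry:
    """Transmission source-detector layout: sources on the dorsal face,
    detectors on the ventral face, with an explicit pairing list."""

    sources: np.ndarray
    detectors: np.ndarray
    pairing: list[tuple[int, int]]

    def __post_init__(self) -> None:
        self.sources = np.asarray(self.sources, dtype=float)
        self.detectors = np.asarray(self.detectors, dtype=float)
        for si, di in self.pairing:
            if not (0 <= si < len(self.sources) and 0 <= di < len(self.detectors)):
                raise ValueError("pairing index out of range")

    @property
    def n_pairs(self) -> int:
        return len(self.pairing)


@dataclass
class TomoConfig:
    thickness: float = 18.6
    voxel_size: float = 1.0
    lateral: tuple[float, float] = (25.0, 25.0)
    inclusion_center: tuple[float, float, float] = (0.0, 0.0, 6.3)
    inclusion_radius: float = 2.5
    etaT: float = 1.0
    etaNS_background: float = 0.2
    #: optional liver-like region of elevated nonspecific yield: a sphere of
    #: ``liver_radius`` centered on the inclusion (None disables it)
    etaNS_liver: float | None = None
    liver_radius: float = 6.0
    mu_a: float = 0.03
    mu_s_prime: float = 1.0
    n_tissue: float = 1.37
    source_grid: tuple[int, int] = (4, 4)
    source_pitch: float = 5.0
    det_grid: tuple[int, int] = (6, 7)
    det_pitch: float = 2.0


def generate_tomo_phantom(
    config: TomoConfig, seed: int | None = None
) -> tuple[SlabPhantom3D, SDGeometry]:
    """Build the default slab phantom and transmission geometry.

    The default acquisition uses a 4x4 grid of sources at 5 mm pitch on the
    dorsal face with a 6x7 detector patch per source on the ventral face —
    42 detectors per source, 672 source-detector pairs in total. The
    inclusion carries ``etaT_true > 0`` on top of a homogeneous liver-like
    ``etaNS_true`` background. Deterministic; ``seed`` is accepted for
    interface symmetry with the other generators.
    """
    nx = int(round(config.lateral[0] / config.voxel_size))
    ny = int(round(config.lateral[1] / config.voxel_size))
    nz = int(round(config.thickness / config.voxel_size))
    dx = config.lateral[0] / nx
    dy = config.lateral[1] / ny
    dz = config.thickness / nz

    cx, cy, cz = config.inclusion_center
    r = config.inclusion_radius
    if (
        cz - r < 0
        or cz + r > config.thickness
        or abs(cx) + r > config.lateral[0] / 2.0
        or abs(cy) + r > config.lateral[1] / 2.0
    ):
        raise ValueError("inclusion extends outside the slab")

    xs = (np.arange(nx) + 0.5) * dx - config.lateral[0] / 2.0
    ys = (np.arange(ny) + 0.5) * dy - config.lateral[1] / 2.0
    zs = (np.arange(nz) + 0.5) * dz
    gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
    inclusion = (gx - cx) ** 2 + (gy - cy) ** 2 + (gz - cz) ** 2 <= r**2

    etaT = np.where(inclusion, config.etaT, 0.0)
    etaNS = np.full((nx, ny, nz), config.etaNS_background)
    if config.etaNS_liver is not None:
        liver = (
            (gx - cx) ** 2 + (gy - cy) ** 2 + (gz - cz) ** 2
            <= config.liver_radius**2
        )
        etaNS[liver] = config.etaNS_liver

    phantom = SlabPhantom3D(
        shape=(nx, ny, nz),
        voxel_size=(dx, dy, dz),
        mu_a=config.mu_a,
        mu_s_prime=config.mu_s_prime,
        n_tissue=config.n_tissue,
        etaT_true=etaT,
        etaNS_true=etaNS,
        inclusion_mask=inclusion,
    )

    gsx, gsy = config.source_grid
    src = []
    for i in range(gsx):
        for j in range(gsy):
            src.append(
                (
                    (i - (gsx - 1) / 2.0) * config.source_pitch,
                    (j - (gsy - 1) / 2.0) * config.source_pitch,
                    config.thickness,
                )
            )
    gdx, gdy = config.det_grid
    det_index: dict[tuple[float, float], int] = {}
    detectors: list[tuple[float, float, float]] = []
    pairing: list[tuple[int, int]] = []
    for si, (sx, sy, _) in enumerate(src):
        for i in range(gdx):
            for j in range(gdy):
                px = sx + (i - (gdx - 1) / 2.0) * config.det_pitch
                py = sy + (j - (gdy - 1) / 2.0) * config.det_pitch
                key = (round(px, 6), round(py, 6))
                if key not in det_index:
                    det_index[key] = len(detectors)
                    detectors.append((px, py, 0.0))
                pairing.append((si, det_index[key]))
    geom = SDGeometry(np.asarray(src), np.asarray(detectors), pairing)
    return phantom, geom


def pair_amplitude_truth(phantom: SlabPhantom3D, jacobian) -> tuple[np.ndarray, np.ndarray]:
    """Ground-truth per-pair amplitudes ``(W @ etaT, W @ etaNS)``."""
    W = np.asarray(jacobian.W)
    return W @ phantom.etaT_true.ravel(), W @ phantom.etaNS_true.ravel()


def simulate_tomo_data(
    phantom: SlabPhantom3D,
    geom: SDGeometry,
    gates: GateSequence,
    lifetimes: tuple[float, float] = (
        reference.IN_SITU_TUMOR_FLT_NS,
        reference.IN_SITU_LIVER_FLT_NS,
    ),
    jacobian=None,
    noise: str = "none",
    seed: int | None = None,
    a0: float = 0.0,
    source_power: float = 1.0,
) -> pd.DataFrame:
    """Simulate per-pair gated time traces with the asymptotic decay model.

    Each pair's specific and nonspecific amplitudes are the sensitivity-
    weighted sums of the true yields; the trace is the gate-integrated
    two-exponential decay on the supplied gate sequence. Requires a Jacobian
    provider (see :func:`fltquant.tomo.build_jacobian`).
    """
    if jacobian is None:
        raise ValueError("a Jacobian provider is required")
    W = np.asarray(jacobian.W)
    n_vox = int(np.prod(phantom.shape))
    if W.shape != (geom.n_pairs, n_vox):
        raise ValueError(
            f"Jacobian shape {W.shape} does not match geometry/phantom "
            f"({geom.n_pairs} pairs, {n_vox} voxels)"
        )
    tau_t, tau_ns = lifetimes
    aT, aNS = pair_amplitude_truth(phantom, jacobian)
    fT = gate_basis(tau_t, gates)
    fNS = gate_basis(tau_ns, gates)
    traces = (
        a0 * gates.gate_width
        + source_power * (aT[:, None] * fT[None, :] + aNS[:, None] * fNS[None, :])
    )
    if noise == "poisson":
        rng = np.random.default_rng(seed)
        traces = rng.poisson(np.clip(traces, 0.0, None)).astype(float)
    elif noise != "none":
        raise ValueError(f"unknown noise model {noise!r}")

    n_gates = gates.n_gates
    src_ids = np.repeat([si for si, _ in geom.pairing], n_gates)
    det_ids = np.repeat([di for _, di in geom.pairing], n_gates)
    return pd.DataFrame(
        {
            "source_id": src_ids,
            "detector_id": det_ids,
            "gate_index": np.tile(np.arange(n_gates), geom.n_pairs),
            "t_ns": np.tile(gates.times, geom.n_pairs),
            "counts": traces.ravel(),
        }
    )


# ---------------------------------------------------------------------------
# microscopy-scale FLIM + IHC slide
# ---------------------------------------------------------------------------

REGION_LABELS = {
    "background": 0,
    "muscle": 1,
    "vessel": 2,
    "adipose": 3,
    "tumor_neg": 4,
    "tumor_pos": 5,
}


@dataclass(frozen=True)
class RegionSpec:
    """Per-region generator parameters for a microscopy slide."""

    flt_mean: float
    flt_sd: float
    intensity: float
    dab_od: float
    hema_od: float
    pos_frac: float = 0.0


def default_regions() -> dict[str, RegionSpec]:
    return {
        "muscle": RegionSpec(reference.MICRO_MUSCLE_FLT_NS, 0.02, 600.0, 0.02, 0.25),
        "vessel": RegionSpec(reference.MICRO_VESSEL_FLT_NS, 0.03, 800.0, 0.02, 0.25),
        "adipose": RegionSpec(reference.MICRO_ADIPOSE_FLT_NS, 0.05, 300.0, 0.02, 0.15),
        "tumor_neg": RegionSpec(0.70, 0.03, 700.0, 0.60, 0.35, pos_frac=0.02),
        "tumor_pos": RegionSpec(
            reference.MICRO_TUMOR_FLT_NS, 0.04, 900.0, 0.80, 0.35, pos_frac=0.90
        ),
    }


@dataclass
class MicroscopyConfig:
    shape: tuple[int, int] = (500, 500)
    layout: str = "bands"  # "bands" or "blocks"
    regions: dict[str, RegionSpec] = field(default_factory=default_regions)
    block: int = 100
    #: blocks layout only: intensity independent of expression plus a small
    #: expression-linked term (nonspecific background dominates)
    nonspecific_intensity: float = 500.0
    specific_intensity_gain: float = 100.0
    intensity_noise_sd: float = 40.0
    #: blocks layout: log-normal sigma of the per-block nonspecific
    #: background level (patchy probe retention between regions)
    block_intensity_sigma: float = 0.35
    nuclei_per_block: int = 25
    nucleus_radius: int = 3
    flt_bounds: tuple[float, float] = (1e-3, 10.0 - 1e-3)


@dataclass
class MicroscopySlide:
    """Co-registered synthetic FLIM + stain-density images with labels."""

    flt_image: np.ndarray
    intensity_image: np.ndarray
    dapi_image: np.ndarray
    region_label_map: np.ndarray
    hema_od: np.ndarray
    dab_od: np.ndarray
    #: blocks layout: per-block expression fraction keyed by (row, col) block
    block_expression: dict[tuple[int, int], float] = field(default_factory=dict)


def _scatter_nuclei(rng, mask, n, radius, dapi, hema, hema_od):
    rows, cols = np.nonzero(mask)
    if rows.size == 0 or n <= 0:
        return
    idx = rng.integers(0, rows.size, size=n)
    yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    disk = yy**2 + xx**2 <= radius**2
    h, w = mask.shape
    for cy, cx in zip(rows[idx], cols[idx]):
        y0, y1 = max(cy - radius, 0), min(cy + radius + 1, h)
        x0, x1 = max(cx - radius, 0), min(cx + radius + 1, w)
        sub = disk[
            y0 - (cy - radius) : disk.shape[0] - ((cy + radius + 1) - y1),
            x0 - (cx - radius) : disk.shape[1] - ((cx + radius + 1) - x1),
        ]
        dapi[y0:y1, x0:x1][sub] = 1000.0
        hema[y0:y1, x0:x1][sub] = hema_od


def generate_microscopy_slide(
    config: MicroscopyConfig, seed: int | None = None
) -> tuple[MicroscopySlide, np.ndarray]:
    """Generate a registered FLIM/IHC slide pair and its rendered RGB image.

    ``layout="bands"`` tiles the image with one horizontal band per region
    in ``config.regions`` (fixed lifetimes and stain densities per region).
    ``layout="blocks"`` assigns square blocks to regions at random; tumor
    blocks carry a uniform random expression fraction ``e`` that drives both
    the DAB-positive pixel fraction and the lifetime (interpolated between
    the negative and positive tumor region means), while intensity is
    dominated by an expression-independent nonspecific background.

    Returns the slide plus a float RGB image (0..255, unquantized) rendered
    from the stain densities by Beer-Lambert transmission.
    """
    from .micro import DEFAULT_STAIN_MODEL, render_rgb

    for name in config.regions:
        if name not in REGION_LABELS:
            raise ValueError(f"unknown region name {name!r}")
    rng = np.random.default_rng(seed)
    h, w = config.shape
    label = np.zeros((h, w), dtype=int)
    flt = np.full((h, w), np.nan)
    intensity = np.zeros((h, w))
    dapi = np.full((h, w), 10.0)
    hema = np.zeros((h, w))
    dab = np.zeros((h, w))
    block_expression: dict[tuple[int, int], float] = {}

    lo, hi = config.flt_bounds

    def _fill(mask, spec: RegionSpec, flt_mean=None, pos_frac=None, intens=None):
        n = int(mask.sum())
        mu = spec.flt_mean if flt_mean is None else flt_mean
        flt[mask] = np.clip(mu + spec.flt_sd * rng.standard_normal(n), lo, hi)
        base = spec.intensity if intens is None else intens
        intensity[mask] = np.clip(
            base + config.intensity_noise_sd * rng.standard_normal(n), 0.0, None
        )
        pf = spec.pos_frac if pos_frac is None else pos_frac
        pos = mask & (rng.random((h, w)) < pf)
        dab[pos] = spec.dab_od
        dab[mask & ~pos] = 0.02
        _scatter_nuclei(
            rng,
            mask,
            int(config.nuclei_per_block * mask.sum() / config.block**2),
            config.nucleus_radius,
            dapi,
            hema,
            spec.hema_od,
        )

    if config.layout == "bands":
        names = list(config.regions)
        band = h // len(names)
        for k, name in enumerate(names):
            r0 = k * band
            r1 = h if k == len(names) - 1 else (k + 1) * band
            mask = np.zeros((h, w), dtype=bool)
            mask[r0:r1, :] = True
            label[mask] = REGION_LABELS[name]
            _fill(mask, config.regions[name])
    elif config.layout == "blocks":
        if "tumor_pos" not in config.regions or "tumor_neg" not in config.regions:
            raise ValueError("blocks layout requires tumor_pos and tumor_neg regions")
        tn = config.regions["tumor_neg"]
        tp = config.regions["tumor_pos"]
        others = [n for n in config.regions if n not in ("tumor_pos", "tumor_neg")]
        nbr, nbc = h // config.block, w // config.block
        if nbr == 0 or nbc == 0:
            raise ValueError("image smaller than one block")
        for br in range(nbr):
            for bc in range(nbc):
                mask = np.zeros((h, w), dtype=bool)
                r1 = h if br == nbr - 1 else (br + 1) * config.block
                c1 = w if bc == nbc - 1 else (bc + 1) * config.block
                mask[br * config.block : r1, bc * config.block : c1] = True
                nonspec = config.nonspecific_intensity * float(
                    rng.lognormal(0.0, config.block_intensity_sigma)
                )
                if others and rng.random() < 0.25:
                    name = others[int(rng.integers(0, len(others)))]
                    label[mask] = REGION_LABELS[name]
                    _fill(mask, config.regions[name], intens=nonspec)
                else:
                    e = float(rng.random())
                    block_expression[(br, bc)] = e
                    name = "tumor_pos" if e >= 0.5 else "tumor_neg"
                    label[mask] = REGION_LABELS[name]
                    _fill(
                        mask,
                        tp,
                        flt_mean=tn.flt_mean + e * (tp.flt_mean - tn.flt_mean),
                        pos_frac=e,
                        intens=nonspec + config.specific_intensity_gain * e,
                    )
    else:
        raise ValueError(f"unknown layout {config.layout!r}")

    slide = MicroscopySlide(
        flt_image=flt,
        intensity_image=intensity,
        dapi_image=dapi,
        region_label_map=label,
        hema_od=hema,
        dab_od=dab,
        block_expression=block_expression,
    )
    rgb = render_rgb(hema, dab, DEFAULT_STAIN_MODEL)
    return slide, rgb
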