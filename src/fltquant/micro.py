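"""Microscopy-scale FLIM vs IHC analysis.

Color deconvolution of brightfield stain images into hematoxylin and DAB
optical densities, ROI tiling with a tissue-fraction filter, per-ROI
metrics (mean intensity, windowed mean lifetime, DAB-positive area
percentage, expression category), and the FLIM-vs-IHC correlation analysis.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu

from . import quant
from .quant import ROISet

__all__ = [
    "StainModel",
    "StainMaps",
    "ROIMetrics",
    "DEFAULT_STAIN_MODEL",
    "render_rgb",
    "color_deconvolve",
    "tile_rois",
    "roi_flt_mean",
    "pdl1_percent_area",
    "categorize_pdl1",
    "compute_roi_metrics",
    "correlate_flim_ihc",
]

CATEGORIES = ("negative", "moderate", "high")


@dataclass(frozen=True)
class StainModel:
    """Unit-norm stain vectors (RGB optical-density triplets) plus the
    background (unstained) intensity per channel."""

    hematoxylin: tuple[float, float, float] = (0.650, 0.704, 0.286)
    dab: tuple[float, float, float] = (0.269, 0.568, 0.779)
    background: tuple[float, float, float] = (255.0, 255.0, 255.0)

    def __post_init__(self) -> None:
        for name in ("hematoxylin", "dab"):
            v = np.asarray(getattr(self, name), dtype=float)
            n = np.linalg.norm(v)
            if n == 0:
                raise ValueError(f"{name} stain vector is zero")
            object.__setattr__(self, name, tuple(v / n))
        if np.linalg.norm(np.cross(self.hematoxylin, self.dab)) < 1e-8:
            raise ValueError("stain vectors are linearly dependent")

    @property
    def matrix(self) -> np.ndarray:
        """Stain matrix, shape (2, 3): rows are unit OD vectors."""
        return np.array([self.hematoxylin, self.dab])


DEFAULT_STAIN_MODEL = StainModel()


def render_rgb(
    hema_od: np.ndarray, dab_od: np.ndarray, model: StainModel = DEFAULT_STAIN_MODEL
) -> np.ndarray:
    """Render stain densities to a float RGB image by Beer-Lambert
    transmission: ``channel = background * 10^(-sum(density * stain))``."""
    hema_od = np.asarray(hema_od, dtype=float)
    dab_od = np.asarray(dab_od, dtype=float)
    if np.any(hema_od < 0) or np.any(dab_od < 0):
        raise ValueError("stain densities must be >= 0")
    od = (
        hema_od[..., None] * np.asarray(model.hematoxylin)
        + dab_od[..., None] * np.asarray(model.dab)
    )
    return np.asarray(model.background) * 10.0 ** (-od)


class StainMaps(NamedTuple):
    hematoxylin: np.ndarray
    dab: np.ndarray


def color_deconvolve(
    rgb: np.ndarray,
    model: StainModel = DEFAULT_STAIN_MODEL,
    clip_negative: bool = True,
) -> StainMaps:
    """Separate an RGB brightfield image into per-stain optical densities.

    Per-pixel OD is ``-log10(channel / background)``; densities are the
    least-squares projection onto the stain matrix (pseudo-inverse).
    Accepts 8-bit or float images.
    """
    rgb = np.asarray(rgb, dtype=float)
    if rgb.ndim != 3 or rgb.shape[-1] != 3:
        raise ValueError("expected an (..., 3) RGB image")
    M = model.matrix
    if np.linalg.matrix_rank(M) < 2:
        raise ValueError("singular stain matrix")
    bg = np.asarray(model.background)
    od = -np.log10(np.clip(rgb, 1e-8, None) / bg)
    dens = od.reshape(-1, 3) @ np.linalg.pinv(M)
    if clip_negative:
        dens = np.clip(dens, 0.0, None)
    dens = dens.reshape(rgb.shape[:-1] + (2,))
    return StainMaps(dens[..., 0], dens[..., 1])


def tile_rois(
    intensity_image: np.ndarray,
    tile: int = 100,
    min_tissue_frac: float = 0.10,
    tissue_mask: np.ndarray | None = None,
) -> tuple[ROISet, np.ndarray]:
    """Partition an image into non-overlapping square tiles and keep those
    with enough tissue.

    Tissue is defined by an Otsu threshold on the intensity channel unless
    an explicit ``tissue_mask`` is given; trailing partial tiles are
    dropped. Returns the retained tiles as an ROI set plus the tissue mask.
    """
    img = np.asarray(intensity_image, dtype=float)
    h, w = img.shape
    if h < tile or w < tile:
        raise ValueError("image smaller than one tile")
    if tissue_mask is None:
        if img.max() == img.min():
            tissue_mask = np.full(img.shape, img.max() > 0)
        else:
            tissue_mask = img > threshold_otsu(img)
    else:
        tissue_mask = np.asarray(tissue_mask, dtype=bool)
    masks: dict[str, np.ndarray] = {}
    for br in range(h // tile):
        for bc in range(w // tile):
            sl = (slice(br * tile, (br + 1) * tile), slice(bc * tile, (bc + 1) * tile))
            frac = tissue_mask[sl].mean()
            if frac >= min_tissue_frac:
                m = np.zeros((h, w), dtype=bool)
                m[sl] = True
                masks[f"tile_{br}_{bc}"] = m
    return ROISet(masks), tissue_mask


def roi_flt_mean(
    flt_image: np.ndarray,
    roi: np.ndarray,
    window: tuple[float, float] = (0.3, 1.6),
) -> float:
    """Mean of in-window, non-NaN lifetimes inside the ROI (NaN if none)."""
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise ValueError("empty ROI")
    vals = np.asarray(flt_image, dtype=float)[roi]
    lo, hi = window
    with np.errstate(invalid="ignore"):
        vals = vals[np.isfinite(vals) & (vals >= lo) & (vals <= hi)]
    return float(vals.mean()) if vals.size else float("nan")


def pdl1_percent_area(
    dab_od: np.ndarray, roi: np.ndarray, od_threshold: float = 0.15
) -> float:
    """Percentage of ROI pixels whose DAB optical density reaches the
    positivity threshold."""
    if od_threshold <= 0:
        raise ValueError("od_threshold must be > 0")
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise ValueError("empty ROI")
    vals = np.asarray(dab_od, dtype=float)[roi]
    return 100.0 * float((vals >= od_threshold).sum()) / vals.size


def categorize_pdl1(percent_area: float) -> str:
    """Clinical-style expression category from % positive area:
    negative < 1, moderate in [1, 50), high >= 50."""
    if not 0.0 <= percent_area <= 100.0:
        raise ValueError("percent_area must be within [0, 100]")
    if percent_area < 1.0:
        return "negative"
    if percent_area < 50.0:
        return "moderate"
    return "high"


@dataclass
class ROIMetrics:
    roi_id: str
    bounds: tuple[int, int, int, int]  # (row0, col0, row1, col1)
    mean_intensity: float
    mean_flt: float
    pdl1_percent_area: float
    category: str
    tissue_fraction: float


def _roi_bounds(mask: np.ndarray) -> tuple[int, int, int, int]:
    rows, cols = np.nonzero(mask)
    return int(rows.min()), int(cols.min()), int(rows.max()) + 1, int(cols.max()) + 1


def compute_roi_metrics(
    flt_image: np.ndarray,
    intensity_image: np.ndarray,
    dab_od: np.ndarray,
    rois: ROISet,
    tissue_mask: np.ndarray | None = None,
    od_threshold: float = 0.15,
    flt_window: tuple[float, float] = (0.3, 1.6),
) -> list[ROIMetrics]:
    """Per-ROI metric table for the FLIM-vs-IHC comparison."""
    out = []
    for name, mask in rois:
        pct = pdl1_percent_area(dab_od, mask, od_threshold)
        tf = (
            float(np.asarray(tissue_mask, dtype=bool)[mask].mean())
            if tissue_mask is not None
            else 1.0
        )
        vals = np.asarray(intensity_image, dtype=float)[mask]
        vals = vals[np.isfinite(vals)]
        out.append(
            ROIMetrics(
                roi_id=name,
                bounds=_roi_bounds(mask),
                mean_intensity=float(vals.mean()) if vals.size else float("nan"),
                mean_flt=roi_flt_mean(flt_image, mask, flt_window),
                pdl1_percent_area=pct,
                category=categorize_pdl1(pct),
                tissue_fraction=tf,
            )
        )
    return out


def metrics_frame(metrics: list[ROIMetrics]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "roi": [m.roi_id for m in metrics],
            "mean_intensity": [m.mean_intensity for m in metrics],
            "mean_flt": [m.mean_flt for m in metrics],
            "percent_area": [m.pdl1_percent_area for m in metrics],
            "category": [m.category for m in metrics],
            "tissue_fraction": [m.tissue_fraction for m in metrics],
        }
    )


def correlate_flim_ihc(metrics: list[ROIMetrics] | pd.DataFrame) -> dict:
    """Correlate per-ROI mean intensity and mean FLT against the IHC-based
    percent positive area, with between-category group tests.

    Returns ``{"intensity": CorrelationReport, "flt": CorrelationReport,
    "groups": {(cat_a, cat_b): {"flt": GroupComparison, "intensity": ...}}}``.
    ROIs with undefined (NaN) metrics are excluded; degenerate variance
    raises ``ValueError``.
    """
    df = metrics if isinstance(metrics, pd.DataFrame) else metrics_frame(metrics)
    df = df.dropna(subset=["mean_intensity", "mean_flt", "percent_area"])
    if len(df) < 3:
        raise ValueError("need >= 3 ROIs with defined metrics")
    area = df["percent_area"].to_numpy()
    reports = {
        "intensity": quant.pearson_r2(df["mean_intensity"].to_numpy(), area),
        "flt": quant.pearson_r2(df["mean_flt"].to_numpy(), area),
    }
    groups: dict[tuple[str, str], dict] = {}
    for a, b in (("negative", "moderate"), ("moderate", "high"), ("negative", "high")):
        ga = df[df["category"] == a]
        gb = df[df["category"] == b]
        if len(ga) and len(gb):
            groups[(a, b)] = {
                "flt": quant.mann_whitney_u(ga["mean_flt"], gb["mean_flt"]),
                "intensity": quant.mann_whitney_u(
                    ga["mean_intensity"], gb["mean_intensity"]
                ),
            }
    reports["groups"] = groups
    return reports
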