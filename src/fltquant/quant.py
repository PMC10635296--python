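"""ROI statistics, expression metrics, correlations and group tests."""
from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import remove_small_objects
from skimage.segmentation import watershed

__all__ = [
    "ROISet",
    "CorrelationReport",
    "GroupComparison",
    "roi_stats",
    "lifetime_pair_estimate",
    "positive_area_fraction",
    "count_nuclei",
    "pearson_r2",
    "mann_whitney_u",
    "cohort_report",
    "analyze_widefield_cohort",
]

EXACT_U_LIMIT = 16  # exact enumeration of the U null up to this combined n


@dataclass
class ROISet:
    """Named boolean masks over a common image shape."""

    masks: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {m.shape for m in self.masks.values()}
        if len(shapes) > 1:
            raise ValueError("all ROI masks must share one shape")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.masks[name]

    def __iter__(self):
        return iter(self.masks.items())

    def __len__(self) -> int:
        return len(self.masks)


def roi_stats(map_: np.ndarray, roi: np.ndarray) -> tuple[float, float, int]:
    """NaN-excluding mean, sample (n-1) SD, and pixel count inside a ROI."""
    vals = np.asarray(map_, dtype=float)[np.asarray(roi, dtype=bool)]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("ROI contains no finite pixels")
    sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    return float(vals.mean()), sd, int(vals.size)


def lifetime_pair_estimate(
    flt_map: np.ndarray,
    roi_tumor: np.ndarray,
    roi_normal: np.ndarray,
) -> tuple[float, float, bool]:
    """ROI-mean lifetimes ``(tau_T, tau_NS)`` for the dual basis.

    Returns a contrast-inversion flag (True when ``tau_T <= tau_NS``, also
    raised as a warning). Average the per-subject pairs arithmetically for a
    cohort estimate.
    """
    tau_t, _, _ = roi_stats(flt_map, roi_tumor)
    tau_ns, _, _ = roi_stats(flt_map, roi_normal)
    inverted = tau_t <= tau_ns
    if inverted:
        warnings.warn("lifetime contrast inversion: tau_T <= tau_NS")
    return tau_t, tau_ns, inverted


def positive_area_fraction(
    flt_map: np.ndarray,
    n_nuclei: int,
    lo: float = 0.6,
    hi: float = 0.7,
) -> float:
    """Pixels with lifetime in ``[lo, hi]`` (inclusive) per nucleus."""
    if n_nuclei < 1:
        raise ValueError("n_nuclei must be >= 1")
    vals = np.asarray(flt_map, dtype=float)
    with np.errstate(invalid="ignore"):
        n_pos = int(((vals >= lo) & (vals <= hi)).sum())
    return n_pos / n_nuclei


def count_nuclei(
    dapi_image: np.ndarray,
    min_area: int = 20,
    split_touching: bool = False,
) -> int:
    """Count nuclei in a DAPI channel.

    Global Otsu threshold, connected components, minimum-area filter; with
    ``split_touching=True`` a distance-transform watershed separates merged
    blobs. A blank (constant) image counts zero.
    """
    img = np.asarray(dapi_image, dtype=float)
    if img.size == 0 or img.max() == img.min():
        return 0
    binary = img > threshold_otsu(img)
    # max_size semantics: removes objects <= threshold, hence min_area - 1
    binary = remove_small_objects(binary, max_size=min_area - 1)
    if not binary.any():
        return 0
    if split_touching:
        distance = ndimage.distance_transform_edt(binary)
        peaks = distance >= 0.6 * distance.max()
        markers = cc_label(peaks)
        labels = watershed(-distance, markers, mask=binary)
    else:
        labels = cc_label(binary)
    ids, counts = np.unique(labels[labels > 0], return_counts=True)
    return int((counts >= min_area).sum())


@dataclass
class CorrelationReport:
    r: float
    r2_signed: float
    n: int
    pairs: list[tuple[float, float]]

    @property
    def r2(self) -> float:
        """Plain (unsigned) coefficient of determination."""
        return self.r**2


def pearson_r2(x: Sequence[float], y: Sequence[float]) -> CorrelationReport:
    """Product-moment correlation with the signed-r^2 convention
    ``r2_signed = sign(r) * r**2``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need >= 3 paired points")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in x or y")
    r = float(stats.pearsonr(x, y).statistic)
    return CorrelationReport(
        r=r,
        r2_signed=float(np.sign(r) * r**2),
        n=int(x.size),
        pairs=list(zip(x.tolist(), y.tolist())),
    )


@dataclass
class GroupComparison:
    U: float
    p_two_tailed: float
    n1: int
    n2: int
    method: str


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Mann-Whitney U of sample a, with 1/2 credit for ties."""
    gt = (a[:, None] > b[None, :]).sum()
    eq = (a[:, None] == b[None, :]).sum()
    return float(gt) + 0.5 * float(eq)


def mann_whitney_u(a: Sequence[float], b: Sequence[float]) -> GroupComparison:
    """Two-tailed Mann-Whitney U test.

    For combined sample sizes up to 16 the null distribution of U is built
    by exhaustive enumeration of all group assignments of the observed
    values (a permutation test, exact also under ties); larger samples use
    the normal approximation with tie correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = a.size, b.size
    if n1 < 1 or n2 < 1:
        raise ValueError("both samples must be non-empty")
    u = _u_statistic(a, b)
    if n1 + n2 <= EXACT_U_LIMIT:
        values = np.concatenate([a, b])
        total = values.size
        us = []
        for idx in itertools.combinations(range(total), n1):
            sel = np.zeros(total, dtype=bool)
            sel[list(idx)] = True
            us.append(_u_statistic(values[sel], values[~sel]))
        us = np.asarray(us)
        # two-tailed by doubling the smaller tail (null symmetric about n1*n2/2)
        p = float(min(2.0 * min(np.mean(us <= u), np.mean(us >= u)), 1.0))
        method = "exact"
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        p = float(res.pvalue)
        method = "asymptotic"
    return GroupComparison(U=u, p_two_tailed=p, n1=int(n1), n2=int(n2), method=method)


def cohort_report(
    subject_metrics: pd.DataFrame,
    truth: Mapping[str, float],
) -> tuple[pd.DataFrame, dict[str, CorrelationReport]]:
    """Correlate per-subject imaging metrics against ground-truth expression.

    ``subject_metrics`` must contain a ``subject`` column plus one column
    per metric (e.g. ``mean_intensity``, ``mean_flt``, ``mean_ratio``);
    ``truth`` maps subject id to the expression score. Returns the table
    augmented with the truth column and one :class:`CorrelationReport` per
    metric. Subject sets must match exactly.
    """
    if len(subject_metrics) < 3:
        raise ValueError("need >= 3 subjects")
    ids = list(subject_metrics["subject"])
    if set(ids) != set(truth):
        raise ValueError("subject IDs in metrics and truth do not match")
    table = subject_metrics.copy()
    table["expression"] = [truth[s] for s in ids]
    reports = {}
    for col in table.columns:
        if col in ("subject", "expression"):
            continue
        reports[col] = pearson_r2(table[col].to_numpy(), table["expression"].to_numpy())
    return table, reports


def analyze_widefield_cohort(
    cohort,
    mask_frac: float = 0.20,
    tau_t: float | None = None,
    tau_ns: float | None = None,
    compute_flt: bool = True,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-subject tumor-ROI metrics for a synthetic wide-field cohort.

    For each subject: exposure-scaled mean summed intensity, mean FLT
    (optional), and the tumor amplitude ratio. ``mean_ratio`` is the ratio
    of ROI-mean amplitudes (mean aT / mean aNS), which is robust to the
    heavy-tailed noise of per-pixel ratios; the pixelwise-mean of the ratio
    map is reported alongside as ``mean_ratio_map``. Returns the metrics
    table and the subject->expression truth map.
    """
    from . import reference, tdfit

    tau_t = reference.IN_VIVO_TUMOR_FLT_NS if tau_t is None else tau_t
    tau_ns = reference.IN_VIVO_NORMAL_FLT_NS if tau_ns is None else tau_ns
    rows = []
    truth = {}
    for subj in cohort:
        stack, phantom = subj.stack, subj.phantom
        mask = tdfit.intensity_mask(stack, mask_frac)
        tumor = phantom.tumor_mask & mask
        intensity = tdfit.sum_gates(stack) / stack.exposure
        mean_int, _, _ = roi_stats(intensity, tumor)
        dual = tdfit.dual_basis_maps(stack, mask, tau_t, tau_ns)
        mean_ratio_map, _, _ = roi_stats(dual.ratio_map, tumor)
        mean_aT, _, _ = roi_stats(dual.aT_map, tumor)
        mean_aNS, _, _ = roi_stats(dual.aNS_map, tumor)
        row = {
            "subject": subj.subject_id,
            "mean_intensity": mean_int,
            "mean_ratio": mean_aT / mean_aNS if mean_aNS > 0 else np.nan,
            "mean_ratio_map": mean_ratio_map,
        }
        if compute_flt:
            fmap = tdfit.flt_map(stack, mask)
            row["mean_flt"], _, _ = roi_stats(fmap.tau, tumor)
        rows.append(row)
        truth[subj.subject_id] = subj.expression
    return pd.DataFrame(rows), truth
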