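"""Marker-positive cell and co-localization quantification from multichannel micrographs.

The workflow mirrors a standard immunofluorescence quantification protocol:
each channel is Otsu-thresholded, the binary mask is quality-controlled by
correlating it against the raw intensities (Pearson r >= 0.8 passes, otherwise
a deterministic re-threshold fallback runs), nuclei are counted on the DNA
channel, and a cell is called marker-positive when its nucleus centroid falls
inside a sufficiently large marker-mask component.  Co-localization between two
marker channels is the Pearson correlation coefficient

    r = sum_i (R_i - Rbar)(G_i - Gbar)
        / sqrt( sum_i (R_i - Rbar)^2 * sum_i (G_i - Gbar)^2 )

computed over a configurable pixel set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import scipy.ndimage as ndi
from skimage.feature import peak_local_max
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.segmentation import watershed

from .errors import (
    DegenerateImageError,
    UndefinedCorrelationError,
    UndefinedPercentageError,
)

__all__ = [
    "Micrograph",
    "SegmentationResult",
    "MarkerQuantification",
    "ColocalizationResult",
    "otsu_threshold",
    "pearson_cc",
    "threshold_with_qc",
    "count_nuclei",
    "quantify_marker",
    "colocalize",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class Micrograph:
    """A calibrated multichannel fluorescence image.

    ``channels`` maps a role name (``"nuclei"``, plus one or two marker names)
    to a 2-D non-negative intensity array; all channels share one shape.
    """

    channels: Mapping[str, np.ndarray]
    pixel_size_um: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("Micrograph needs at least one channel")
        shapes = {np.asarray(c).shape for c in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"channel shapes differ: {shapes}")
        (shape,) = shapes
        if len(shape) != 2:
            raise ValueError("channels must be 2-D arrays")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        for name, c in self.channels.items():
            a = np.asarray(c)
            if np.any(a < 0):
                raise ValueError(f"channel {name!r} has negative intensities")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def marker_names(self) -> list[str]:
        return [k for k in self.channels if k != "nuclei"]


@dataclass
class SegmentationResult:
    """Binary mask for one channel plus the threshold-QC audit trail."""

    mask: np.ndarray
    threshold: float
    qc_pcc: float
    qc_passed: bool
    fallback_applied: bool
    method: str
    exclusion_mask: Optional[np.ndarray] = None

    @property
    def valid(self) -> np.ndarray:
        """Boolean mask of unexcluded pixels."""
        if self.exclusion_mask is None:
            return np.ones(self.mask.shape, dtype=bool)
        return ~self.exclusion_mask


@dataclass
class MarkerQuantification:
    """Per-image read-outs for one marker channel."""

    marker: str
    n_positive_cells: int
    n_nuclei: int
    cells_per_mm2: float
    percent_positive_cells: float
    percent_area: float
    percent_area_per_avg_cell: float
    denominator: str = "nuclei"  # the % positive denominator is the Hoechst count


@dataclass
class ColocalizationResult:
    """Pearson co-localization between two marker channels."""

    pcc: float
    channel_a: str
    channel_b: str
    n_pixels: int
    mask_policy: str


# ---------------------------------------------------------------------------
# primitive operations
# ---------------------------------------------------------------------------


def otsu_threshold(channel: np.ndarray, nbins: int = 256) -> float:
    """Histogram threshold maximizing between-class variance.

    Candidate thresholds are the histogram bin centers; ties are broken toward
    the lower threshold.  Pixels strictly above the returned value belong to
    the foreground class.

    Raises
    ------
    DegenerateImageError
        If the image is constant (no separating threshold exists).
    """
    a = np.asarray(channel, dtype=float).ravel()
    if a.size == 0:
        raise DegenerateImageError("empty image")
    if not np.all(np.isfinite(a)):
        raise ValueError("image contains non-finite intensities")
    lo, hi = a.min(), a.max()
    if lo == hi:
        raise DegenerateImageError("constant image has no separating threshold")
    counts, edges = np.histogram(a, bins=nbins, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    w = counts / counts.sum()
    cum_w = np.cumsum(w)
    cum_m = np.cumsum(w * centers)
    mu_total = cum_m[-1]
    w0 = cum_w[:-1]
    w1 = 1.0 - w0
    num = (mu_total * w0 - cum_m[:-1]) ** 2
    denom = w0 * w1
    bcv = np.zeros_like(num)
    ok = denom > 0
    bcv[ok] = num[ok] / denom[ok]
    # np.argmax returns the first maximum -> lowest threshold on ties
    return float(centers[int(np.argmax(bcv))])


def pearson_cc(
    a: np.ndarray, b: np.ndarray, mask: Optional[np.ndarray] = None
) -> float:
    """Pearson correlation coefficient between two equally-shaped intensity arrays.

    Implements r = sum((R-Rbar)(G-Gbar)) / sqrt(sum (R-Rbar)^2 * sum (G-Gbar)^2)
    directly.  A value of 1 means the two stains vary together pixel-for-pixel,
    -1 means they are perfectly anti-correlated, 0 means no linear relation.

    Raises
    ------
    UndefinedCorrelationError
        If either input is constant over the (masked) pixel set.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    x = x.ravel()
    y = y.ravel()
    if mask is not None:
        m = np.asarray(mask, dtype=bool).ravel()
        if m.shape != x.shape:
            raise ValueError("mask shape does not match inputs")
        x = x[m]
        y = y[m]
    if x.size < 2:
        raise ValueError("need at least 2 pixels to correlate")
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(np.dot(xc, xc))
    syy = float(np.dot(yc, yc))
    if sxx == 0.0 or syy == 0.0:
        raise UndefinedCorrelationError("constant input: correlation undefined")
    r = float(np.dot(xc, yc)) / math.sqrt(sxx * syy)
    return float(min(1.0, max(-1.0, r)))


# ---------------------------------------------------------------------------
# thresholding with PCC-based quality control
# ---------------------------------------------------------------------------


def _remove_small(mask: np.ndarray, min_size: int) -> np.ndarray:
    """Drop connected components with area < min_size pixels."""
    labels = cc_label(mask)
    if labels.max() == 0:
        return mask.copy()
    areas = np.bincount(labels.ravel())
    keep = areas >= min_size
    keep[0] = False
    return keep[labels]


def _qc_pcc(raw: np.ndarray, mask: np.ndarray, valid: np.ndarray) -> float:
    """PCC of raw intensities against the 0/1 mask over unexcluded pixels."""
    try:
        return pearson_cc(raw[valid], mask[valid].astype(float))
    except UndefinedCorrelationError:
        return float("nan")


def threshold_with_qc(
    channel: np.ndarray,
    exclusion_mask: Optional[np.ndarray] = None,
    *,
    qc_min_pcc: float = 0.8,
    background_sigma: float = 50.0,
    sweep_candidates: int = 64,
    nbins: int = 256,
) -> SegmentationResult:
    """Otsu-threshold a channel and QC the mask by correlating it with the raw image.

    The mask passes QC when PCC(raw, mask) >= ``qc_min_pcc`` (0.8 by default).
    On failure a deterministic fallback runs: a large-scale Gaussian background
    estimate (``background_sigma`` px) is subtracted (clipped at zero) and Otsu
    is re-applied; if QC still fails, the threshold is swept over the intensity
    quantiles of the background-subtracted image and the mask maximizing the QC
    PCC is kept.  ``qc_passed`` records whether the final mask reached the bar.

    ``exclusion_mask`` marks artifact pixels (True = excluded); they are removed
    from the mask before QC and from all downstream area denominators.
    """
    img = np.asarray(channel, dtype=float)
    if img.ndim != 2:
        raise ValueError("channel must be 2-D")
    if exclusion_mask is not None:
        excl = np.asarray(exclusion_mask, dtype=bool)
        if excl.shape != img.shape:
            raise ValueError("exclusion mask shape mismatch")
    else:
        excl = None
    valid = np.ones(img.shape, dtype=bool) if excl is None else ~excl
    if valid.sum() < 2:
        raise DegenerateImageError("fewer than 2 unexcluded pixels")

    thr = otsu_threshold(img[valid], nbins=nbins)
    mask = (img > thr) & valid
    qc = _qc_pcc(img, mask, valid)
    if np.isfinite(qc) and qc >= qc_min_pcc:
        return SegmentationResult(mask, thr, qc, True, False, "otsu", excl)

    # fallback 1: background-subtract, then Otsu again
    background = ndi.gaussian_filter(img, sigma=background_sigma)
    sub = np.clip(img - background, 0.0, None)
    best = (qc, mask, thr, "otsu")
    try:
        thr2 = otsu_threshold(sub[valid], nbins=nbins)
        mask2 = (sub > thr2) & valid
        qc2 = _qc_pcc(img, mask2, valid)
        if not np.isfinite(best[0]) or (np.isfinite(qc2) and qc2 > best[0]):
            best = (qc2, mask2, thr2, "otsu+background")
    except DegenerateImageError:
        qc2 = float("nan")

    if not (np.isfinite(best[0]) and best[0] >= qc_min_pcc):
        # fallback 2: sweep thresholds, directly optimizing the QC score
        vals = sub[valid]
        qs = np.unique(np.quantile(vals, np.linspace(0.05, 0.995, sweep_candidates)))
        for cand in qs:
            m = (sub > cand) & valid
            q = _qc_pcc(img, m, valid)
            if np.isfinite(q) and (not np.isfinite(best[0]) or q > best[0]):
                best = (q, m, float(cand), "qc-sweep")

    qc_f, mask_f, thr_f, method = best
    if not np.isfinite(qc_f):
        raise DegenerateImageError("no informative threshold found")
    passed = bool(qc_f >= qc_min_pcc)
    return SegmentationResult(mask_f, thr_f, float(qc_f), passed, True, method, excl)


# ---------------------------------------------------------------------------
# nuclei counting
# ---------------------------------------------------------------------------


def count_nuclei(
    nuclei_channel: np.ndarray,
    exclusion_mask: Optional[np.ndarray] = None,
    *,
    min_size: int = 30,
    min_peak_distance: int = 5,
    **qc_kwargs,
) -> tuple[int, list[tuple[float, float]]]:
    """Count nuclei and return their centroids.

    Segments the DNA channel with :func:`threshold_with_qc`, removes components
    below ``min_size`` pixels, splits touching nuclei with one round of
    distance-transform watershed (peaks at least ``min_peak_distance`` px
    apart seed the basins), and reports connected regions.  Residual merges
    count as a single nucleus.
    """
    img = np.asarray(nuclei_channel, dtype=float)
    if exclusion_mask is not None:
        valid = ~np.asarray(exclusion_mask, dtype=bool)
        if valid.sum() < 2 or img[valid].size == 0:
            return 0, []
    seg = threshold_with_qc(img, exclusion_mask, **qc_kwargs)
    mask = _remove_small(seg.mask, min_size)
    mask = ndi.binary_fill_holes(mask)
    if exclusion_mask is not None:
        mask &= seg.valid
    if not mask.any():
        return 0, []
    distance = ndi.distance_transform_edt(mask)
    peaks = peak_local_max(
        distance,
        min_distance=min_peak_distance,
        labels=cc_label(mask),
        exclude_border=False,
    )
    markers = np.zeros(mask.shape, dtype=int)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    labels = watershed(-distance, markers, mask=mask)
    centroids = [tuple(p.centroid) for p in regionprops(labels)]
    return len(centroids), centroids


# ---------------------------------------------------------------------------
# marker quantification and co-localization
# ---------------------------------------------------------------------------


def quantify_marker(
    marker_seg: SegmentationResult,
    nuclei_centroids: Sequence[tuple[float, float]],
    pixel_size_um: float,
    *,
    marker: str = "marker",
    min_component_size: int = 30,
) -> MarkerQuantification:
    """Derive the per-image marker read-outs from a QC'd segmentation.

    A cell is marker-positive iff a nucleus centroid falls inside a marker-mask
    connected component of at least ``min_component_size`` pixels.  The percent
    of positive cells uses the nuclei count as denominator; percent area is
    relative to all unexcluded pixels; cells per mm^2 uses ``pixel_size_um``.
    """
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    n_nuclei = len(nuclei_centroids)
    if n_nuclei == 0:
        raise UndefinedPercentageError(
            "no nuclei: percent of positive cells is undefined"
        )
    mask = _remove_small(marker_seg.mask, min_component_size)
    valid = marker_seg.valid
    labels = cc_label(mask)
    nrows, ncols = mask.shape
    n_positive = 0
    for r, c in nuclei_centroids:
        ri = min(max(int(round(r)), 0), nrows - 1)
        ci = min(max(int(round(c)), 0), ncols - 1)
        if labels[ri, ci] > 0:
            n_positive += 1
    total_px = int(valid.sum())
    percent_area = 100.0 * float(mask.sum()) / total_px
    percent_positive = 100.0 * n_positive / n_nuclei
    per_avg_cell = percent_area / n_positive if n_positive > 0 else 0.0
    area_mm2 = total_px * (pixel_size_um / 1000.0) ** 2
    return MarkerQuantification(
        marker=marker,
        n_positive_cells=n_positive,
        n_nuclei=n_nuclei,
        cells_per_mm2=n_positive / area_mm2,
        percent_positive_cells=percent_positive,
        percent_area=percent_area,
        percent_area_per_avg_cell=per_avg_cell,
    )


def colocalize(
    marker_a: np.ndarray,
    marker_b: np.ndarray,
    *,
    policy: str = "all",
    masks: Optional[tuple[np.ndarray, np.ndarray]] = None,
    exclusion_mask: Optional[np.ndarray] = None,
    names: tuple[str, str] = ("marker_1", "marker_2"),
) -> ColocalizationResult:
    """Pearson co-localization between two co-registered marker channels.

    ``policy`` selects the pixel set: ``"all"`` (default) correlates every
    unexcluded pixel of the field; ``"union"`` restricts to the union of the
    two segmentation ``masks``.
    """
    a = np.asarray(marker_a, dtype=float)
    b = np.asarray(marker_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("channels are not co-registered (shape mismatch)")
    valid = (
        np.ones(a.shape, dtype=bool)
        if exclusion_mask is None
        else ~np.asarray(exclusion_mask, dtype=bool)
    )
    if policy == "all":
        sel = valid
    elif policy == "union":
        if masks is None:
            raise ValueError("policy 'union' requires the two segmentation masks")
        sel = (np.asarray(masks[0], bool) | np.asarray(masks[1], bool)) & valid
    else:
        raise ValueError(f"unknown mask policy {policy!r}")
    r = pearson_cc(a, b, sel)
    return ColocalizationResult(
        pcc=r,
        channel_a=names[0],
        channel_b=names[1],
        n_pixels=int(sel.sum()),
        mask_policy=policy,
    )
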