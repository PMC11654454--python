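"""Movie -> per-cell F/F0 traces.

Implements the automated extraction stage: a maximum ΔF/F0 projection
summarises total activity per pixel, cells are segmented on that
projection (Otsu threshold, connected components, minimum-area filter,
optional watershed split of touching cells), and each ROI's mean
intensity is normalised by its pre-stimulus baseline to give F/F0.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import remove_small_objects
from skimage.segmentation import watershed

from .errors import ParameterError
from .traces import TraceField

__all__ = ["Movie", "RoiSet", "max_dff_projection", "segment_cells", "extract_traces"]

log = logging.getLogger(__name__)


@dataclass
class Movie:
    """A single-channel time-lapse stack (time x rows x cols)."""

    stack: np.ndarray
    frame_rate_hz: float

    def __post_init__(self):
        self.stack = np.asarray(self.stack)
        if self.stack.ndim != 3:
            raise ParameterError("movie stack must be 3-D (time, rows, cols)")
        if self.stack.shape[0] < 2:
            raise ParameterError("movie must have at least 2 frames")
        if self.frame_rate_hz <= 0:
            raise ParameterError("frame_rate_hz must be > 0")

    @property
    def n_frames(self) -> int:
        return self.stack.shape[0]


@dataclass
class RoiSet:
    """Labelled cell footprints: 0 = background, k = cell k (contiguous 1..K)."""

    label_image: np.ndarray

    def __post_init__(self):
        self.label_image = np.asarray(self.label_image)
        labels = np.unique(self.label_image)
        labels = labels[labels > 0]
        expected = np.arange(1, labels.size + 1)
        if not np.array_equal(labels, expected):
            raise ParameterError("ROI labels must be contiguous 1..K")

    @property
    def n_rois(self) -> int:
        return int(self.label_image.max(initial=0))

    @property
    def areas(self) -> np.ndarray:
        return np.bincount(self.label_image.ravel(), minlength=self.n_rois + 1)[1:]


def _check_f0_window(f0_window: tuple[int, int], n_frames: int) -> tuple[int, int]:
    start, stop = int(f0_window[0]), int(f0_window[1])
    if not (0 <= start < stop <= n_frames):
        raise ParameterError(
            f"f0_window {f0_window} invalid for a {n_frames}-frame movie"
        )
    return start, stop


def max_dff_projection(movie: Movie, f0_window: tuple[int, int]) -> np.ndarray:
    """Per-pixel max over time of (F - F0)/F0, F0 = mean over ``f0_window``.

    Pixels whose baseline F0 is not strictly positive cannot be normalised;
    they are returned as NaN and must be excluded from segmentation.
    """
    start, stop = _check_f0_window(f0_window, movie.n_frames)
    stack = movie.stack.astype(float)
    f0 = stack[start:stop].mean(axis=0)
    bad = f0 <= 0
    if bad.any():
        log.warning("%d pixel(s) with F0 <= 0 flagged as NaN", int(bad.sum()))
    with np.errstate(divide="ignore", invalid="ignore"):
        dff = (stack - f0) / f0
    proj = dff.max(axis=0)
    proj[bad] = np.nan
    return proj


def segment_cells(
    image: np.ndarray,
    min_area: int = 16,
    threshold_method: str = "otsu",
    split_touching: bool = False,
) -> RoiSet:
    """Segment cell footprints on a 2-D activity map.

    Intensity threshold (Otsu by default, or a float for a fixed absolute
    threshold), connected components, ``min_area`` filter.  With
    ``split_touching`` a distance-transform watershed separates merged
    cells.  An image where nothing survives yields an empty RoiSet with a
    warning rather than an exception.
    """
    image = np.asarray(image, dtype=float)
    valid = np.isfinite(image)
    if not valid.any():
        log.warning("segmentation input has no finite pixels; empty RoiSet")
        return RoiSet(np.zeros(image.shape, dtype=np.int32))

    if isinstance(threshold_method, (int, float)):
        thr = float(threshold_method)
    elif threshold_method == "otsu":
        vals = image[valid]
        if np.ptp(vals) == 0:
            log.warning("flat image; empty RoiSet")
            return RoiSet(np.zeros(image.shape, dtype=np.int32))
        thr = threshold_otsu(vals)
    else:
        raise ParameterError(f"unknown threshold_method {threshold_method!r}")

    mask = valid & (image > thr)
    mask = remove_small_objects(mask, max(int(min_area), 1))
    if not mask.any():
        log.warning("no region above threshold survives min_area; empty RoiSet")
        return RoiSet(np.zeros(image.shape, dtype=np.int32))

    if split_touching:
        dist = ndimage.distance_transform_edt(mask)
        # markers at local maxima of the distance map, one per putative cell
        footprint = np.ones((5, 5))
        maxima = (dist == ndimage.maximum_filter(dist, footprint=footprint)) & mask
        markers = cc_label(maxima)
        labels = watershed(-dist, markers, mask=mask)
    else:
        labels = cc_label(mask)

    # drop undersized regions and relabel to contiguous 1..K
    counts = np.bincount(labels.ravel())
    keep = np.nonzero(counts >= max(int(min_area), 1))[0]
    keep = keep[keep > 0]
    out = np.zeros_like(labels, dtype=np.int32)
    for new, old in enumerate(keep, start=1):
        out[labels == old] = new
    return RoiSet(out)


def extract_traces(
    movie: Movie,
    rois: RoiSet,
    f0_window: tuple[int, int],
    group_label: str = "",
    concentration_nmol: float = float("nan"),
    saturation_level: float | None = None,
) -> TraceField:
    """Per-ROI mean intensity over time, normalised to the baseline window.

    For each cell ``k``, ``trace(t) = mean(stack[t][roi k]) / F0_k`` with
    ``F0_k`` the mean of that series over ``f0_window``.  ROIs whose F0 is
    not strictly positive are dropped (logged).  Pixels at or above
    ``saturation_level`` are excluded from the ROI means, since clipped
    pixels flatten oscillations.
    """
    start, stop = _check_f0_window(f0_window, movie.n_frames)
    if rois.label_image.shape != movie.stack.shape[1:]:
        raise ParameterError("ROI label image does not match movie geometry")
    n_rois = rois.n_rois
    if n_rois == 0:
        return TraceField(
            time_s=np.arange(movie.n_frames) / movie.frame_rate_hz,
            traces=np.empty((0, movie.n_frames)),
            group_label=group_label,
            concentration_nmol=concentration_nmol,
            f0_window=(start, stop),
            cell_ids=np.empty(0, dtype=int),
        )

    labels = rois.label_image
    idx = np.arange(1, n_rois + 1)
    stack = movie.stack.astype(float)
    means = np.empty((n_rois, movie.n_frames))
    if saturation_level is not None:
        for ti in range(movie.n_frames):
            frame = stack[ti].copy()
            frame[frame >= saturation_level] = np.nan
            sums = ndimage.sum_labels(np.nan_to_num(frame), labels, idx)
            counts = ndimage.sum_labels(np.isfinite(frame).astype(float), labels, idx)
            with np.errstate(invalid="ignore", divide="ignore"):
                means[:, ti] = sums / counts
    else:
        for ti in range(movie.n_frames):
            means[:, ti] = ndimage.mean(stack[ti], labels, idx)

    f0 = means[:, start:stop].mean(axis=1)
    keep = np.isfinite(f0) & (f0 > 0) & np.all(np.isfinite(means), axis=1)
    for k in np.nonzero(~keep)[0]:
        log.warning("ROI %d dropped: baseline F0 <= 0 or undefined", k + 1)

    traces = means[keep] / f0[keep, None]
    return TraceField(
        time_s=np.arange(movie.n_frames) / movie.frame_rate_hz,
        traces=traces,
        group_label=group_label,
        concentration_nmol=concentration_nmol,
        f0_window=(start, stop),
        cell_ids=idx[keep],
    )
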