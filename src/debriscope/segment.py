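"""Debris-map segmentation: minimum auto-threshold, fiber extraction,
watershed separation of aggregates.

The histogram-minimum threshold (Prewitt & Mendelsohn) iteratively smooths
the 256-bin intensity histogram with a 3-point mean until exactly two local
maxima remain, then thresholds at the minimum between them.  Connected
components of the binary debris map are split into fibers — components that
touch two distinct image borders and whose skeleton spans at least the
smaller image dimension — and particulates, which are then separated at
aggregate necks by a distance-transform watershed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
import scipy.ndimage as ndi
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra
from skimage.feature import peak_local_max
from skimage.morphology import skeletonize
from skimage.segmentation import watershed

from .specs import AcquisitionSpec

__all__ = [
    "BinaryMask",
    "FiberComponent",
    "SegmentationResult",
    "UnimodalHistogramError",
    "minimum_threshold",
    "minimum_threshold_hist",
    "extract_fibers",
    "separate_aggregates",
    "segment_debris_map",
    "SLIT_WIDTH_UM",
]

#: Fiber size-bin boundary: the 8 μm slit width of the filter.
SLIT_WIDTH_UM = 8.0

#: Connected components smaller than this (px²) are discarded as
#: sub-resolution speckle before fiber/particle analysis.
MIN_OBJECT_AREA_PX = 2


class UnimodalHistogramError(ValueError):
    """The histogram never becomes bimodal: no between-modes minimum exists."""


@dataclass
class BinaryMask:
    """Thresholded foreground plus the provenance of the threshold."""

    mask: np.ndarray
    threshold_bin: int
    threshold_value: float
    n_bins: int

    @property
    def shape(self):
        return self.mask.shape


@dataclass
class FiberComponent:
    mask: np.ndarray
    diameter_um: float
    length_um: float
    size_bin: str  # "large" (> 8 um) or "small" (<= 8 um)
    borders_touched: Tuple[str, ...]


@dataclass
class SegmentationResult:
    fibers: List[FiberComponent]
    particle_labels: np.ndarray
    particulate_mask: np.ndarray
    threshold_bin: int
    threshold_value: float
    min_object_area_px: int = MIN_OBJECT_AREA_PX
    marker_min_distance_px: int = 2


# ---------------------------------------------------------------------------
# histogram-minimum auto-threshold


def _count_maxima(h: np.ndarray) -> List[int]:
    """Plateau-aware local maxima of a 1-D histogram.

    A run of equal values is one maximum iff the nearest unequal neighbours
    on both sides are lower (array ends count as lower).  Returns one
    representative index (run centre) per maximum.
    """
    n = len(h)
    maxima: List[int] = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and h[j + 1] == h[i]:
            j += 1
        left_lower = i == 0 or h[i - 1] < h[i]
        right_lower = j == n - 1 or h[j + 1] < h[j]
        if left_lower and right_lower and h[i] > 0:
            maxima.append((i + j) // 2)
        i = j + 1
    return maxima


def minimum_threshold_hist(counts: np.ndarray, max_iter: int = 10_000) -> int:
    """Between-modes minimum bin of a histogram, by iterative 3-point mean
    smoothing until exactly two maxima remain.

    Ties among minima between the two modes break to the lowest bin index.
    Raises :class:`UnimodalHistogramError` if the histogram is (or becomes)
    unimodal, or fails to become bimodal within ``max_iter`` smoothings.
    """
    h = np.asarray(counts, dtype=np.float64).copy()
    if h.ndim != 1 or len(h) < 3:
        raise ValueError("histogram must be 1-D with at least 3 bins")
    for _ in range(max_iter + 1):
        maxima = _count_maxima(h)
        if len(maxima) == 2:
            lo, hi = maxima
            between = h[lo : hi + 1]
            return lo + int(np.argmin(between))
        if len(maxima) < 2:
            raise UnimodalHistogramError(
                "histogram is unimodal; no between-modes minimum exists"
            )
        # replicate-edge 3-point mean
        h = (np.concatenate([h[:1], h[:-1]]) + h + np.concatenate([h[1:], h[-1:]])) / 3.0
    raise UnimodalHistogramError(
        f"histogram did not become bimodal within {max_iter} smoothing iterations"
    )


def minimum_threshold(map_: np.ndarray, n_bins: int = 256) -> Tuple[BinaryMask, float]:
    """Binarise a grayscale map at the histogram-minimum auto-threshold.

    The histogram spans the map's full value range with ``n_bins`` bins;
    foreground is strictly above the threshold bin.  Returns the mask (with
    provenance) and the threshold value on the map's intensity scale.
    """
    data = np.asarray(getattr(map_, "data", map_), dtype=np.float64)
    vmin, vmax = float(data.min()), float(data.max())
    if vmin == vmax:
        raise UnimodalHistogramError("map is constant; it cannot be thresholded")
    idx = ((data - vmin) / (vmax - vmin) * n_bins).astype(np.int64)
    np.clip(idx, 0, n_bins - 1, out=idx)
    counts = np.bincount(idx.ravel(), minlength=n_bins)
    t = minimum_threshold_hist(counts)
    value = vmin + (t + 1) * (vmax - vmin) / n_bins
    bm = BinaryMask(mask=idx > t, threshold_bin=t, threshold_value=value, n_bins=n_bins)
    return bm, value


# ---------------------------------------------------------------------------
# fiber extraction


def _skeleton_span_px(comp: np.ndarray) -> float:
    """Geodesic diameter of a component's skeleton (px), end-compensated.

    Measured as the longest shortest path along the skeleton (8-connected,
    diagonal weight √2, double-sweep Dijkstra) plus the distance-transform
    radius at both extremal skeleton pixels, which restores the roughly one
    radius that skeletonization trims from each end of a tube.
    """
    skel = skeletonize(comp)
    rows, cols = np.nonzero(skel)
    npix = rows.size
    if npix == 0:
        return 0.0
    if npix == 1:
        r = ndi.distance_transform_edt(comp)[rows[0], cols[0]]
        return float(2 * r)
    index = -np.ones(comp.shape, dtype=np.int64)
    index[rows, cols] = np.arange(npix)
    src, dst, wgt = [], [], []
    for dr, dc, wt in ((0, 1, 1.0), (1, 0, 1.0), (1, 1, np.sqrt(2)), (1, -1, np.sqrt(2))):
        rr, cc = rows + dr, cols + dc
        ok = (rr >= 0) & (rr < comp.shape[0]) & (cc >= 0) & (cc < comp.shape[1])
        nb = np.full(npix, -1, dtype=np.int64)
        nb[ok] = index[rr[ok], cc[ok]]
        sel = nb >= 0
        src.extend(np.arange(npix)[sel])
        dst.extend(nb[sel])
        wgt.extend(np.full(sel.sum(), wt))
    g = coo_matrix((wgt, (src, dst)), shape=(npix, npix)).tocsr()
    d0 = dijkstra(g, directed=False, indices=0)
    d0[~np.isfinite(d0)] = -1
    u = int(np.argmax(d0))
    du = dijkstra(g, directed=False, indices=u)
    du[~np.isfinite(du)] = -1
    v = int(np.argmax(du))
    edt = ndi.distance_transform_edt(comp)
    ends = edt[rows[u], cols[u]] + edt[rows[v], cols[v]]
    return float(du[v] + ends)


def _fiber_diameter_px(comp: np.ndarray) -> float:
    """2 × mean distance-transform value along the skeleton."""
    skel = skeletonize(comp)
    edt = ndi.distance_transform_edt(comp)
    vals = edt[skel]
    if vals.size == 0:
        return 0.0
    return float(2.0 * vals.mean())


def _borders_touched(comp: np.ndarray) -> Tuple[str, ...]:
    names = []
    if comp[0, :].any():
        names.append("top")
    if comp[-1, :].any():
        names.append("bottom")
    if comp[:, 0].any():
        names.append("left")
    if comp[:, -1].any():
        names.append("right")
    return tuple(names)


def extract_fibers(
    mask, acq: AcquisitionSpec, min_object_area_px: int = MIN_OBJECT_AREA_PX
) -> Tuple[List[FiberComponent], np.ndarray]:
    """Split a binary debris mask into fiber components and a particulate mask.

    A connected component is a fiber iff it touches two distinct image
    borders *and* its skeleton's end-to-end geodesic span is at least the
    smaller image dimension (less a 2 px rasterization allowance) — i.e. it
    spans the field of view.  Fiber diameter is twice the mean
    distance-transform value along the skeleton, converted to μm, and the
    size bin is "large" for diameters above the 8 μm slit width, else
    "small".  All fiber pixels are removed from the returned particulate
    mask.  Components below ``min_object_area_px`` are dropped as speckle.
    """
    m = np.asarray(getattr(mask, "mask", mask), dtype=bool)
    h, w = m.shape
    labels, n = ndi.label(m, structure=np.ones((3, 3), dtype=int))
    particulate = np.zeros_like(m)
    fibers: List[FiberComponent] = []
    span_needed = min(h, w) - 2
    for obj_slice, lab in zip(ndi.find_objects(labels), range(1, n + 1)):
        comp_local = labels[obj_slice] == lab
        if comp_local.sum() < min_object_area_px:
            continue
        borders = _borders_touched_global(obj_slice, comp_local, (h, w))
        is_fiber = False
        if len(borders) >= 2:
            comp = np.zeros((h, w), dtype=bool)
            comp[obj_slice] = comp_local
            if _skeleton_span_px(comp) >= span_needed:
                is_fiber = True
        if is_fiber:
            d_px = _fiber_diameter_px(comp)
            d_um = d_px / acq.pixel_scale
            skel_len = _skeleton_span_px(comp)
            fibers.append(
                FiberComponent(
                    mask=comp,
                    diameter_um=d_um,
                    length_um=skel_len / acq.pixel_scale,
                    size_bin="large" if d_um > SLIT_WIDTH_UM else "small",
                    borders_touched=borders,
                )
            )
        else:
            particulate[obj_slice] |= comp_local
    return fibers, particulate


def _borders_touched_global(obj_slice, comp_local, shape) -> Tuple[str, ...]:
    h, w = shape
    rs, cs = obj_slice
    names = []
    if rs.start == 0 and comp_local[0, :].any():
        names.append("top")
    if rs.stop == h and comp_local[-1, :].any():
        names.append("bottom")
    if cs.start == 0 and comp_local[:, 0].any():
        names.append("left")
    if cs.stop == w and comp_local[:, -1].any():
        names.append("right")
    return tuple(names)


# ---------------------------------------------------------------------------
# watershed aggregate separation


def separate_aggregates(mask, marker_min_distance_px: int = 2) -> np.ndarray:
    """Split touching convex objects by a distance-transform watershed.

    Labels are the watershed of the negated Euclidean distance transform,
    seeded at its regional maxima with maxima closer than
    ``marker_min_distance_px`` merged; every connected component receives at
    least one marker, so components are never merged, only split.
    Deterministic.
    """
    m = np.asarray(getattr(mask, "mask", mask), dtype=bool)
    if not m.any():
        return np.zeros(m.shape, dtype=np.int32)
    edt = ndi.distance_transform_edt(m)
    cc_labels, n_cc = ndi.label(m, structure=np.ones((3, 3), dtype=int))
    coords = peak_local_max(
        edt,
        min_distance=marker_min_distance_px,
        labels=cc_labels,
        exclude_border=False,
    )
    markers = np.zeros(m.shape, dtype=np.int32)
    markers[tuple(coords.T)] = np.arange(1, len(coords) + 1)
    # guarantee one marker per connected component
    have = np.unique(cc_labels[tuple(coords.T)]) if len(coords) else np.empty(0, int)
    missing = np.setdiff1d(np.arange(1, n_cc + 1), have)
    nxt = len(coords) + 1
    for lab in missing:
        flat = np.argmax(np.where(cc_labels == lab, edt, -1.0))
        markers.flat[flat] = nxt
        nxt += 1
    return watershed(-edt, markers=markers, mask=m).astype(np.int32)


def segment_debris_map(
    prob_map: np.ndarray,
    acq: AcquisitionSpec,
    n_bins: int = 256,
    min_object_area_px: int = MIN_OBJECT_AREA_PX,
    marker_min_distance_px: int = 2,
    despeckle_size: int = 3,
) -> SegmentationResult:
    """Full debris segmentation: threshold → despeckle → fiber split →
    watershed.

    The binary median despeckle (``despeckle_size`` window, 0 disables)
    conditions the thresholded map against per-pixel classifier noise
    before object analysis; the partition invariant (fiber pixels ⊎
    particulate pixels = above-speckle debris pixels) then holds for the
    conditioned mask by construction.
    """
    bm, _ = minimum_threshold(prob_map, n_bins=n_bins)
    mask = bm.mask
    if despeckle_size:
        mask = ndi.median_filter(mask.astype(np.uint8), size=despeckle_size).astype(bool)
    fibers, particulate = extract_fibers(mask, acq, min_object_area_px)
    labels = separate_aggregates(particulate, marker_min_distance_px)
    return SegmentationResult(
        fibers=fibers,
        particle_labels=labels,
        particulate_mask=particulate,
        threshold_bin=bm.threshold_bin,
        threshold_value=bm.threshold_value,
        min_object_area_px=min_object_area_px,
        marker_min_distance_px=marker_min_distance_px,
    )
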