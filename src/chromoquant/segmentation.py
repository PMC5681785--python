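"""Nucleus and focus segmentation on 2-D projections.

Nuclei are segmented from the DAPI projection by the classical bright-object
recipe: circular-average smoothing, a foreground intensity threshold, seeds
from an h-maxima transform, and a seeded watershed on the inverted smoothed
image constrained to the foreground.  Sub-nuclear foci are segmented by the
same recipe applied independently inside each nucleus on the chromatin-mark
channel, so a focus can never cross a nucleus boundary.

Thresholds may be given as numbers (the per-image manual mode) or as the
token ``"auto"``, which falls back to Otsu's method — a reproducible default
where a human would otherwise pick the value by eye.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import morphology
from skimage.filters import threshold_otsu
from skimage.segmentation import watershed

from .image_io import Projection2D

logger = logging.getLogger(__name__)

# 8-connectivity for components, plateaus and watershed flooding.
_STRUCT8 = np.ones((3, 3), bool)


@dataclass
class SegmentationParams:
    """Tunables for nucleus segmentation.

    ``h`` is the depth of the h-maxima transform used to seed the watershed;
    when ``None`` it defaults to 0.1 x the smoothed image's maximum, scaling
    the seed criterion with the image's dynamic range.  ``fg_threshold`` is
    a raw-intensity cutoff or ``"auto"`` (Otsu on the smoothed projection).
    """

    smooth_radius_px: int = 3
    h: float | None = None
    fg_threshold: float | str = "auto"
    min_nucleus_area_px: int = 30
    exclude_border: bool = True

    def __post_init__(self) -> None:
        if self.smooth_radius_px < 1:
            raise ValueError("smooth_radius_px must be >= 1")
        if self.h is not None and self.h <= 0:
            raise ValueError("h must be > 0")
        if self.min_nucleus_area_px < 1:
            raise ValueError("min_nucleus_area_px must be >= 1")


@dataclass
class FociParams:
    """Tunables for focus segmentation within a nucleus.

    ``focus_h`` defaults to 0.05 x the in-nucleus maximum when ``None``;
    ``focus_threshold`` is a raw cutoff or ``"auto"`` (Otsu over the pixels
    of that nucleus only).
    """

    focus_h: float | None = None
    focus_threshold: float | str = "auto"
    min_focus_area_px: int = 2

    def __post_init__(self) -> None:
        if self.focus_h is not None and self.focus_h <= 0:
            raise ValueError("focus_h must be > 0")
        if self.min_focus_area_px < 1:
            raise ValueError("min_focus_area_px must be >= 1")


@dataclass
class LabelMap:
    """Integer label image: 0 = background, k >= 1 = object k.

    For focus maps, ``owners`` maps each focus label to the label of the
    nucleus that contains it.
    """

    labels: np.ndarray
    n_objects: int
    owners: dict[int, int] | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("label map must be 2-D")
        present = np.unique(self.labels)
        expected = np.arange(0, self.n_objects + 1)
        if not np.array_equal(present, expected[np.isin(expected, present)]) or (
            present.size and present.max() > self.n_objects
        ):
            raise ValueError(
                f"labels must lie in {{0..{self.n_objects}}}; found {present}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def mask(self, label: int) -> np.ndarray:
        return self.labels == label


def _as_array(img: Projection2D | np.ndarray) -> np.ndarray:
    return img.pixels if isinstance(img, Projection2D) else np.asarray(img)


def smooth_image(
    img: Projection2D | np.ndarray, radius: int = 3
) -> Projection2D | np.ndarray:
    """Circular averaging filter: each pixel becomes the mean over the
    discrete disk of the given radius centred there, with reflective padding
    at the borders.  Returns the same type it was given."""
    arr = _as_array(img).astype(float)
    if radius < 1:
        raise ValueError("radius must be >= 1")
    if radius * 2 + 1 > min(arr.shape):
        raise ValueError(
            f"radius {radius} too large for image of shape {arr.shape}"
        )
    footprint = morphology.disk(radius).astype(float)
    kernel = footprint / footprint.sum()
    out = ndi.convolve(arr, kernel, mode="reflect")
    if isinstance(img, Projection2D):
        return Projection2D(out, img.source_z_range, img.channel_role)
    return out


def _h_maxima_seeds(img: np.ndarray, h: float, restrict: np.ndarray) -> np.ndarray:
    """Connected components (8-conn) of the h-maxima of *img*, restricted to
    the boolean mask *restrict*.  Returns an int32 marker image."""
    maxima = morphology.h_maxima(img, h, footprint=_STRUCT8)
    maxima &= restrict
    markers, _ = ndi.label(maxima, structure=_STRUCT8)
    return markers


def _drop_small(labels: np.ndarray, min_area: int) -> np.ndarray:
    """Zero out labelled objects with fewer than *min_area* pixels."""
    if labels.max() == 0:
        return labels
    counts = np.bincount(labels.ravel())
    lut = np.where(counts >= min_area, np.arange(counts.size), 0)
    lut[0] = 0
    return lut[labels]


def _renumber_by_area(labels: np.ndarray) -> tuple[np.ndarray, int]:
    """Renumber labels 1..n by descending area; ties broken by the (row, col)
    of each object's topmost-leftmost pixel."""
    ids = np.unique(labels)
    ids = ids[ids > 0]
    if ids.size == 0:
        return np.zeros_like(labels, dtype=np.int32), 0
    areas = ndi.sum_labels(np.ones_like(labels, dtype=np.int64), labels, index=ids)
    order_keys = []
    for lab, area in zip(ids, areas):
        rows, cols = np.nonzero(labels == lab)
        top = rows.min()
        left = cols[rows == top].min()
        order_keys.append((-int(area), int(top), int(left), int(lab)))
    order = sorted(range(len(ids)), key=lambda i: order_keys[i])
    lut = np.zeros(int(ids.max()) + 1, dtype=np.int32)
    for new, i in enumerate(order, start=1):
        lut[ids[i]] = new
    return lut[labels], len(ids)


def segment_nuclei(dapi: Projection2D | np.ndarray, params: SegmentationParams) -> LabelMap:
    """Segment nuclei from a DAPI projection.

    Pipeline: smooth with a circular averaging filter; threshold the
    smoothed image (Otsu when ``fg_threshold="auto"``); seed from connected
    h-maxima restricted to the foreground; watershed the inverted smoothed
    image from those seeds within the foreground; drop objects below
    ``min_nucleus_area_px`` and (by default) objects touching the image
    border; renumber survivors by descending area.

    An image with no foreground yields an empty map, not an error.
    """
    raw = _as_array(dapi).astype(float)
    if not np.all(np.isfinite(raw)):
        raise ValueError("image contains non-finite pixels")
    smoothed = smooth_image(raw, params.smooth_radius_px)

    if params.fg_threshold == "auto":
        if np.ptp(smoothed) == 0:
            return LabelMap(np.zeros(raw.shape, dtype=np.int32), 0)
        thr = threshold_otsu(smoothed)
    else:
        thr = float(params.fg_threshold)
    foreground = smoothed >= thr
    if not foreground.any():
        return LabelMap(np.zeros(raw.shape, dtype=np.int32), 0)

    h = params.h if params.h is not None else 0.1 * float(smoothed.max())
    markers = _h_maxima_seeds(smoothed, h, foreground)
    labels = watershed(-smoothed, markers=markers, mask=foreground, connectivity=2)

    labels = _drop_small(labels, params.min_nucleus_area_px)
    if params.exclude_border:
        border_labels = np.unique(
            np.concatenate(
                [labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]]
            )
        )
        labels[np.isin(labels, border_labels[border_labels > 0])] = 0

    labels, n = _renumber_by_area(labels)
    return LabelMap(labels, n)


def classify_gfp(
    nuclei: LabelMap,
    compartment: Projection2D | np.ndarray,
    gfp_threshold: float,
) -> dict[int, str]:
    """Gate nuclei into GFP-positive / GFP-negative compartments.

    A nucleus is ``"positive"`` iff its *mean* compartment-channel intensity
    over its pixels is >= *gfp_threshold* (inclusive); the mean makes the
    call independent of nucleus size.
    """
    comp = _as_array(compartment).astype(float)
    if comp.shape != nuclei.shape:
        raise ValueError(
            f"shape mismatch: compartment {comp.shape} vs nuclei {nuclei.shape}"
        )
    out: dict[int, str] = {}
    if nuclei.n_objects == 0:
        return out
    ids = np.arange(1, nuclei.n_objects + 1)
    means = ndi.mean(comp, labels=nuclei.labels, index=ids)
    for lab, m in zip(ids, means):
        out[int(lab)] = "positive" if m >= gfp_threshold else "negative"
    return out


def segment_foci(
    mark: Projection2D | np.ndarray,
    nuclei: LabelMap,
    params: FociParams,
) -> LabelMap:
    """Segment foci independently within each nucleus of a label map.

    Per nucleus: the in-nucleus foreground is ``mark >= focus_threshold``
    (Otsu over that nucleus's pixels when ``"auto"``); seeds come from the
    h-maxima transform at depth ``focus_h`` within the nucleus; a seeded
    watershed on the inverted mark image, constrained to that foreground,
    separates touching foci; foci below ``min_focus_area_px`` are removed.
    Output labels are globally unique and ``owners`` records each focus's
    nucleus; no focus crosses a nucleus boundary.
    """
    img = _as_array(mark).astype(float)
    if img.shape != nuclei.shape:
        raise ValueError(
            f"shape mismatch: mark {img.shape} vs nuclei {nuclei.shape}"
        )
    out = np.zeros(img.shape, dtype=np.int32)
    owners: dict[int, int] = {}
    next_label = 1

    slices = ndi.find_objects(nuclei.labels)
    for nucleus_id in range(1, nuclei.n_objects + 1):
        sl = slices[nucleus_id - 1]
        if sl is None:
            continue
        nuc_mask = nuclei.labels[sl] == nucleus_id
        crop = img[sl]
        in_vals = crop[nuc_mask]

        if params.focus_threshold == "auto":
            if np.ptp(in_vals) == 0:
                continue  # flat signal: nothing to segment
            thr = threshold_otsu(in_vals)
        else:
            thr = float(params.focus_threshold)
        fg = (crop >= thr) & nuc_mask
        if not fg.any():
            continue

        h = (
            params.focus_h
            if params.focus_h is not None
            else 0.05 * float(in_vals.max())
        )
        if h <= 0:
            continue
        # suppress signal outside the nucleus so h-maxima are intra-nuclear
        masked = np.where(nuc_mask, crop, in_vals.min())
        markers = _h_maxima_seeds(masked, h, fg)
        if markers.max() == 0:
            continue
        local = watershed(-crop, markers=markers, mask=fg, connectivity=2)
        local = _drop_small(local, params.min_focus_area_px)
        local, n_local = _renumber_by_area(local)
        if n_local == 0:
            continue
        region = out[sl]
        region[local > 0] = local[local > 0] + (next_label - 1)
        for k in range(1, n_local + 1):
            owners[next_label - 1 + k] = nucleus_id
        next_label += n_local

    return LabelMap(out, next_label - 1, owners=owners)
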