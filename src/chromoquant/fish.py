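"""FISH readouts: locus area and spot-to-chromocenter distance.

Two measurements are supported, mirroring the two probe types used on wing
nuclei:

* the total segmented area of a repetitive locus (e.g. the rDNA internal
  transcribed spacer), which distinguishes extended from compact loci; and
* the distance from a satellite spot (e.g. the AACAC pericentromeric
  repeat) to the chromocenter — the DAPI-brightest region of the nucleus —
  normalised by the nuclear radius so nuclei of different sizes are
  comparable.

Distances are measured in 2-D within the single z-section carrying the
strongest FISH signal for that nucleus.  The nuclear radius is the
equivalent-circle radius ``sqrt(area / pi)`` of the nucleus mask.  The
normalised distance is reported unclamped: a value above 1 means the spot
centroid falls outside the equivalent circle and is flagged, not truncated.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .image_io import ImageStack, Projection2D
from .segmentation import FociParams, LabelMap, segment_foci

logger = logging.getLogger(__name__)


@dataclass
class FishMeasurement:
    """One nucleus's FISH readout."""

    nucleus_id: int
    z_used: int
    spot_centroid: tuple[float, float]
    chromocenter_centroid: tuple[float, float]
    nuclear_radius_px: float
    normalized_distance: float
    locus_area_px: int

    @property
    def outside_equivalent_circle(self) -> bool:
        return self.normalized_distance > 1.0


def _mask_to_single_label(mask: np.ndarray) -> LabelMap:
    return LabelMap(mask.astype(np.int32), 1)


def select_strongest_z(stack: ImageStack, nucleus_mask: np.ndarray) -> int:
    """The z-section with the largest integrated FISH intensity over the
    nucleus region; ties resolve to the smallest z."""
    if not stack.has_role("fish"):
        raise ValueError("stack has no fish channel")
    if not nucleus_mask.any():
        raise ValueError("nucleus region is empty")
    fish = stack.channel("fish")
    per_z = fish[:, nucleus_mask].sum(axis=1)
    return int(np.argmax(per_z))  # argmax returns the first (smallest z) tie


def locate_chromocenter(
    dapi_section: Projection2D | np.ndarray,
    nucleus_mask: np.ndarray,
    params: FociParams | None = None,
) -> tuple[float, float]:
    """Intensity-weighted centroid of the DAPI-brightest region of a nucleus.

    DAPI foci are segmented within the nucleus; the centroid of the focus
    with the greatest integrated intensity is returned.  If no DAPI focus
    passes threshold (flat or near-flat DAPI), falls back to the single
    brightest DAPI pixel with a logged warning.
    """
    img = dapi_section.pixels if isinstance(dapi_section, Projection2D) else np.asarray(dapi_section)
    img = img.astype(float)
    if not nucleus_mask.any():
        raise ValueError("nucleus region is empty")
    params = params or FociParams()
    foci = segment_foci(img, _mask_to_single_label(nucleus_mask), params)
    if foci.n_objects > 0:
        ids = np.arange(1, foci.n_objects + 1)
        sums = ndi.sum_labels(img, foci.labels, index=ids)
        best = int(ids[np.argmax(sums)])
        cen = ndi.center_of_mass(img, foci.labels, index=best)
        return float(cen[0]), float(cen[1])
    logger.warning(
        "no DAPI focus passed threshold in nucleus; falling back to the "
        "brightest in-nucleus pixel"
    )
    vals = np.where(nucleus_mask, img, -np.inf)
    r, c = np.unravel_index(np.argmax(vals), img.shape)
    return float(r), float(c)


def normalized_spot_distance(
    spot: tuple[float, float],
    chromocenter: tuple[float, float],
    nuclear_radius_px: float,
) -> float:
    """Euclidean spot-to-chromocenter distance divided by the nuclear
    radius (dimensionless, unclamped)."""
    if nuclear_radius_px <= 0:
        raise ValueError("nuclear_radius_px must be > 0")
    dr = spot[0] - chromocenter[0]
    dc = spot[1] - chromocenter[1]
    return math.hypot(dr, dc) / nuclear_radius_px


def rdna_locus_area(
    fish_projection: Projection2D | np.ndarray,
    nuclei: LabelMap,
    params: FociParams | None = None,
) -> dict[int, int]:
    """Per nucleus, the total area (px) of all FISH foci segmented inside
    it.  Extended loci give larger totals than compact loci of equal
    brightness."""
    img = fish_projection.pixels if isinstance(fish_projection, Projection2D) else np.asarray(fish_projection)
    if img.shape != nuclei.shape:
        raise ValueError(
            f"shape mismatch: fish {img.shape} vs nuclei {nuclei.shape}"
        )
    params = params or FociParams()
    foci = segment_foci(img, nuclei, params)
    areas: dict[int, int] = {n: 0 for n in range(1, nuclei.n_objects + 1)}
    if foci.n_objects:
        ids = np.arange(1, foci.n_objects + 1)
        sizes = ndi.sum_labels(
            np.ones_like(img, dtype=float), foci.labels, index=ids
        )
        for lab, size in zip(ids, sizes):
            areas[foci.owners[int(lab)]] += int(size)
    return areas


def measure_fish(
    stack: ImageStack,
    nuclei: LabelMap,
    fish_params: FociParams | None = None,
    dapi_params: FociParams | None = None,
) -> list[FishMeasurement]:
    """Full spot-to-chromocenter readout for every nucleus of a field.

    For each nucleus: pick the strongest-FISH z-section; locate the
    chromocenter on the DAPI channel of that section; locate the FISH spot
    as the intensity-weighted centroid of the brightest FISH focus in that
    section; compute the radius-normalised distance and the FISH-positive
    locus area.  Nuclei with no detectable FISH signal are skipped with a
    warning.
    """
    fish_params = fish_params or FociParams()
    dapi_params = dapi_params or FociParams()
    dapi = stack.channel("dapi")
    results: list[FishMeasurement] = []
    slices = ndi.find_objects(nuclei.labels)
    for nucleus_id in range(1, nuclei.n_objects + 1):
        if slices[nucleus_id - 1] is None:
            continue
        mask = nuclei.labels == nucleus_id
        z = select_strongest_z(stack, mask)
        fish_sec = stack.channel("fish")[z].astype(float)

        single = _mask_to_single_label(mask)
        fish_foci = segment_foci(fish_sec, single, fish_params)
        if fish_foci.n_objects == 0:
            logger.warning(
                "nucleus %d: no FISH focus above threshold; skipped", nucleus_id
            )
            continue
        ids = np.arange(1, fish_foci.n_objects + 1)
        sums = ndi.sum_labels(fish_sec, fish_foci.labels, index=ids)
        best = int(ids[np.argmax(sums)])
        spot = ndi.center_of_mass(fish_sec, fish_foci.labels, index=best)
        locus_area = int((fish_foci.labels > 0).sum())

        chromo = locate_chromocenter(dapi[z].astype(float), mask, dapi_params)
        radius = math.sqrt(mask.sum() / math.pi)
        dist = normalized_spot_distance(
            (float(spot[0]), float(spot[1])), chromo, radius
        )
        if dist > 1.0:
            logger.warning(
                "nucleus %d: FISH spot outside the equivalent circle "
                "(normalized distance %.2f)", nucleus_id, dist,
            )
        results.append(
            FishMeasurement(
                nucleus_id=nucleus_id,
                z_used=z,
                spot_centroid=(float(spot[0]), float(spot[1])),
                chromocenter_centroid=chromo,
                nuclear_radius_px=radius,
                normalized_distance=dist,
                locus_area_px=locus_area,
            )
        )
    return results
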