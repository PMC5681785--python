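"""Per-nucleus and per-focus intensity readouts.

The central quantity everywhere is the *integrated intensity*: the raw sum
of pixel values over a segmented region, in arbitrary fluorescence units.
From label maps this module builds flat per-nucleus and per-focus record
tables, per-nucleus focus counts, three-range binned intensity
distributions, and the grouped distribution vectors used to read out
heterochromatin clustering (coalescence): fewer, individually brighter foci
at conserved per-nucleus totals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .image_io import Projection2D
from .segmentation import LabelMap


@dataclass
class NucleusRecord:
    """One segmented nucleus and its mark-channel readouts."""

    nucleus_id: int
    compartment: str  # "positive" | "negative" | "unassigned"
    area_px: int
    integrated_intensity: float
    centroid: tuple[float, float]  # (row, col)
    equivalent_radius_px: float


@dataclass
class FocusRecord:
    """One sub-nuclear focus: its owner, footprint and total intensity."""

    focus_id: int
    nucleus_id: int
    area_px: int
    integrated_intensity: float


@dataclass
class BinnedDistribution:
    """Three-range binned intensity distribution.

    Ranges are ``[min, e1)``, ``[e1, e2)``, ``[e2, inf)`` for interior cut
    points ``edges = (e1, e2)``.
    """

    edges: tuple[float, float]
    fractions: tuple[float, float, float]
    n: int

    def __post_init__(self) -> None:
        e1, e2 = self.edges
        if not e1 < e2:
            raise ValueError(f"edges must be strictly increasing, got {self.edges}")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")
        if any(not 0 <= f <= 1 for f in self.fractions):
            raise ValueError("fractions must lie in [0, 1]")


def _img_array(img: Projection2D | np.ndarray) -> np.ndarray:
    return img.pixels if isinstance(img, Projection2D) else np.asarray(img)


def integrated_intensity(region, img: Projection2D | np.ndarray) -> float:
    """Exact sum of image values over a pixel region.

    *region* is either a boolean mask of the image's shape, or a pair
    ``(rows, cols)`` of index arrays.  An empty region sums to 0.
    """
    arr = _img_array(img)
    if isinstance(region, np.ndarray) and region.dtype == bool:
        if region.shape != arr.shape:
            raise ValueError(
                f"mask shape {region.shape} does not match image {arr.shape}"
            )
        return float(arr[region].sum())
    rows, cols = region
    rows = np.asarray(rows, dtype=np.intp)
    cols = np.asarray(cols, dtype=np.intp)
    if rows.size == 0:
        return 0.0
    if (
        rows.min() < 0
        or cols.min() < 0
        or rows.max() >= arr.shape[0]
        or cols.max() >= arr.shape[1]
    ):
        raise IndexError("region contains out-of-bounds pixels")
    return float(arr[rows, cols].sum())


def measure_nuclei(
    nuclei: LabelMap,
    mark: Projection2D | np.ndarray,
    compartments: dict[int, str] | None = None,
) -> list[NucleusRecord]:
    """One record per nucleus: area, mark-channel integrated intensity,
    centroid, and equivalent-circle radius ``sqrt(area / pi)``."""
    img = _img_array(mark).astype(float)
    if img.shape != nuclei.shape:
        raise ValueError(
            f"shape mismatch: mark {img.shape} vs nuclei {nuclei.shape}"
        )
    compartments = compartments or {}
    records: list[NucleusRecord] = []
    if nuclei.n_objects == 0:
        return records
    ids = np.arange(1, nuclei.n_objects + 1)
    areas = ndi.sum_labels(np.ones_like(img), nuclei.labels, index=ids)
    sums = ndi.sum_labels(img, nuclei.labels, index=ids)
    centroids = ndi.center_of_mass(np.ones_like(img), nuclei.labels, index=ids)
    for lab, area, total, cen in zip(ids, areas, sums, centroids):
        records.append(
            NucleusRecord(
                nucleus_id=int(lab),
                compartment=compartments.get(int(lab), "unassigned"),
                area_px=int(area),
                integrated_intensity=float(total),
                centroid=(float(cen[0]), float(cen[1])),
                equivalent_radius_px=math.sqrt(area / math.pi),
            )
        )
    return records


def measure_foci(
    foci: LabelMap,
    mark: Projection2D | np.ndarray,
    ownership: dict[int, int] | None = None,
    nucleus_ids: list[int] | None = None,
) -> tuple[list[FocusRecord], dict[int, int]]:
    """Per-focus area and integrated intensity, plus per-nucleus focus counts.

    *ownership* maps focus label -> nucleus label (defaults to the map
    carried by the focus :class:`~chromoquant.segmentation.LabelMap`); every
    focus must have an owner.  *nucleus_ids*, when given, ensures nuclei
    with zero foci appear in the count dict with count 0.
    """
    img = _img_array(mark).astype(float)
    if img.shape != foci.shape:
        raise ValueError(f"shape mismatch: mark {img.shape} vs foci {foci.shape}")
    ownership = ownership if ownership is not None else (foci.owners or {})
    records: list[FocusRecord] = []
    counts: dict[int, int] = {int(n): 0 for n in (nucleus_ids or [])}
    if foci.n_objects:
        ids = np.arange(1, foci.n_objects + 1)
        areas = ndi.sum_labels(np.ones_like(img), foci.labels, index=ids)
        sums = ndi.sum_labels(img, foci.labels, index=ids)
        for lab, area, total in zip(ids, areas, sums):
            if int(lab) not in ownership:
                raise ValueError(f"focus label {lab} has no owning nucleus")
            owner = int(ownership[int(lab)])
            records.append(
                FocusRecord(
                    focus_id=int(lab),
                    nucleus_id=owner,
                    area_px=int(area),
                    integrated_intensity=float(total),
                )
            )
            counts[owner] = counts.get(owner, 0) + 1
    return records, counts


def bin_three_ranges(values, edges: tuple[float, float]) -> BinnedDistribution:
    """Bin intensities into low / mid / high ranges at two interior cut
    points and return the fraction falling in each."""
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0:
        raise ValueError("cannot bin an empty value list")
    e1, e2 = edges
    if not e1 < e2:
        raise ValueError(f"edges must be strictly increasing, got {edges}")
    low = int((vals < e1).sum())
    mid = int(((vals >= e1) & (vals < e2)).sum())
    high = int((vals >= e2).sum())
    n = vals.size
    return BinnedDistribution(
        edges=(float(e1), float(e2)),
        fractions=(low / n, mid / n, high / n),
        n=n,
    )


def tertile_edges(values) -> tuple[float, float]:
    """Empirical tertiles of *values* — the default three-range cut points,
    chosen so a reference group lands near (1/3, 1/3, 1/3)."""
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0:
        raise ValueError("cannot take tertiles of an empty value list")
    e1, e2 = np.quantile(vals, [1 / 3, 2 / 3])
    if not e1 < e2:
        raise ValueError("degenerate tertiles: values too concentrated")
    return float(e1), float(e2)


def clustering_summary(
    nucleus_records: list[NucleusRecord],
    focus_records: list[FocusRecord],
    focus_counts: dict[int, int],
    group_by: str = "compartment",
) -> dict[str, dict[str, np.ndarray]]:
    """The three clustering readouts, per group.

    For each group (e.g. GFP compartment) returns the vector of individual-
    focus integrated intensities, the vector of per-nucleus focus counts,
    and the vector of per-nucleus overall (mark) integrated intensities.
    Coalescence shifts the first up and the second down while leaving the
    third unchanged.
    """
    if group_by != "compartment":
        raise KeyError(f"unknown group key {group_by!r}")
    nucleus_group = {r.nucleus_id: r.compartment for r in nucleus_records}
    groups = sorted({r.compartment for r in nucleus_records})
    out: dict[str, dict[str, np.ndarray]] = {}
    for g in groups:
        nuclei_in_g = [r for r in nucleus_records if r.compartment == g]
        out[g] = {
            "focus_intensity": np.array(
                [
                    f.integrated_intensity
                    for f in focus_records
                    if nucleus_group.get(f.nucleus_id) == g
                ]
            ),
            "focus_count": np.array(
                [focus_counts.get(r.nucleus_id, 0) for r in nuclei_in_g]
            ),
            "nucleus_intensity": np.array(
                [r.integrated_intensity for r in nuclei_in_g]
            ),
        }
    return out


def nuclei_table(
    records: list[NucleusRecord],
    focus_counts: dict[int, int] | None = None,
    image: str = "",
) -> pd.DataFrame:
    """Flat per-nucleus table (one row per nucleus) for CSV export."""
    focus_counts = focus_counts or {}
    return pd.DataFrame(
        {
            "image": image,
            "nucleus_id": [r.nucleus_id for r in records],
            "compartment": [r.compartment for r in records],
            "area_px": [r.area_px for r in records],
            "integrated_intensity": [r.integrated_intensity for r in records],
            "centroid_row": [r.centroid[0] for r in records],
            "centroid_col": [r.centroid[1] for r in records],
            "equivalent_radius_px": [r.equivalent_radius_px for r in records],
            "focus_count": [focus_counts.get(r.nucleus_id, 0) for r in records],
        }
    )


def foci_table(records: list[FocusRecord], image: str = "") -> pd.DataFrame:
    """Flat per-focus table (one row per focus) for CSV export."""
    return pd.DataFrame(
        {
            "image": image,
            "focus_id": [r.focus_id for r in records],
            "nucleus_id": [r.nucleus_id for r in records],
            "area_px": [r.area_px for r in records],
            "integrated_intensity": [r.integrated_intensity for r in records],
        }
    )
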