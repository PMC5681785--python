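"""End-to-end pipeline: images (or simulations) to flat CSV readout tables.

One run executes, per image or simulated condition: load/generate ->
maximum-project -> segment nuclei -> gate GFP compartments (optional) ->
segment foci -> measure nuclei and foci -> FISH metrics (optional) ->
three-range binning -> between-group t-tests.  Outputs are flat tables
(nuclei.csv, foci.csv, bins.csv, comparisons.csv, and fish.csv when a FISH
channel is configured) plus a run log recording every resolved parameter
and seed, so any figure-style aggregate can be rebuilt from the tables.

The run is a pure function of (config, inputs, seed): repeating it
reproduces byte-identical tables.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, fields
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .config import config_for_image, load_config
from .fish import measure_fish
from .image_io import ImageStack, load_stack, max_project
from .quantification import (
    bin_three_ranges,
    clustering_summary,
    foci_table,
    measure_foci,
    measure_nuclei,
    nuclei_table,
    tertile_edges,
)
from .segmentation import (
    FociParams,
    SegmentationParams,
    classify_gfp,
    segment_foci,
    segment_nuclei,
)
from .simulate import SimConfig, generate_field, truth_table
from .stats import unpaired_t

logger = logging.getLogger(__name__)

#: Readout vectors compared between groups.  Per-focus and per-nucleus
#: statistical units are both emitted, since figure-style panels use either.
COMPARE_METRICS = (
    "focus_intensity",          # per-focus integrated intensity
    "focus_count",              # per-nucleus focus count
    "nucleus_intensity",        # per-nucleus integrated intensity
)


class PipelineError(RuntimeError):
    """Raised when a stage fails, naming the stage and the image."""

    def __init__(self, stage: str, image: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed on image {image!r}: {cause}")
        self.stage = stage
        self.image = image


def _sim_config(cfg_sim: dict[str, Any], overrides: dict[str, Any], seed: int) -> SimConfig:
    valid = {f.name for f in fields(SimConfig)}
    base = {k: v for k, v in cfg_sim.items() if k in valid}
    base.update({k: v for k, v in (overrides or {}).items() if k in valid})
    base["seed"] = seed
    if "field_shape" in base:
        base["field_shape"] = tuple(base["field_shape"])
    for tup in ("nucleus_radius_px", "foci_per_nucleus", "focus_amp"):
        if tup in base:
            base[tup] = tuple(base[tup])
    return SimConfig(**base)


def _quantify_one(
    image_id: str,
    stack: ImageStack,
    cfg: dict[str, Any],
) -> dict[str, Any]:
    """Run segmentation + measurement for one field; returns its tables."""
    img_cfg = cfg["image"]
    z_start = img_cfg.get("z_start", 0)
    z_count = img_cfg.get("z_count")

    def _stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - rewrapped with context
            raise PipelineError(name, image_id, exc) from exc

    dapi = _stage("project", max_project, stack, "dapi", z_start, z_count)
    mark = (
        _stage("project", max_project, stack, "mark", z_start, z_count)
        if stack.has_role("mark")
        else dapi
    )

    seg_params = SegmentationParams(**cfg["segmentation"])
    foci_params = FociParams(**cfg["foci"])
    nuclei = _stage("segment_nuclei", segment_nuclei, dapi, seg_params)

    compartments: dict[int, str] = {}
    gfp_threshold = (cfg.get("gfp") or {}).get("threshold")
    if stack.has_role("compartment") and gfp_threshold is not None:
        comp = _stage("project", max_project, stack, "compartment", z_start, z_count)
        compartments = _stage("classify_gfp", classify_gfp, nuclei, comp, gfp_threshold)

    foci = _stage("segment_foci", segment_foci, mark, nuclei, foci_params)
    nucleus_records = _stage("measure_nuclei", measure_nuclei, nuclei, mark, compartments)
    focus_records, counts = _stage(
        "measure_foci", measure_foci, foci, mark,
        nucleus_ids=list(range(1, nuclei.n_objects + 1)),
    )

    fish_df = None
    if stack.has_role("fish") and cfg.get("fish") is not None:
        fish_params = FociParams(**cfg["fish"])
        measurements = _stage(
            "fish", measure_fish, stack, nuclei,
            fish_params=fish_params, dapi_params=foci_params,
        )
        fish_df = pd.DataFrame(
            {
                "image": image_id,
                "nucleus_id": [m.nucleus_id for m in measurements],
                "z_used": [m.z_used for m in measurements],
                "spot_row": [m.spot_centroid[0] for m in measurements],
                "spot_col": [m.spot_centroid[1] for m in measurements],
                "chromocenter_row": [m.chromocenter_centroid[0] for m in measurements],
                "chromocenter_col": [m.chromocenter_centroid[1] for m in measurements],
                "nuclear_radius_px": [m.nuclear_radius_px for m in measurements],
                "normalized_distance": [m.normalized_distance for m in measurements],
                "outside_equivalent_circle": [
                    m.outside_equivalent_circle for m in measurements
                ],
                "locus_area_px": [m.locus_area_px for m in measurements],
            }
        )

    return {
        "nuclei": nuclei_table(nucleus_records, counts, image=image_id),
        "foci": foci_table(focus_records, image=image_id),
        "fish": fish_df,
        "records": (nucleus_records, focus_records, counts),
    }


def run_pipeline(
    config: dict[str, Any] | str | Path | None,
    out_dir: str | Path,
    images: list[str | Path] | None = None,
    simulate: bool = False,
    seed: int | None = None,
) -> Path:
    """Execute the full pipeline and write output tables to *out_dir*.

    *config* may be a path to a YAML file or an already-loaded dict.  In
    ``simulate`` mode each condition in the config's ``simulate`` section
    becomes one synthetic field (with its own derived seed); otherwise
    *images* are loaded per the ``image`` section.
    """
    cfg = config if isinstance(config, dict) else load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if seed is None:
        seed = int((cfg.get("simulate") or {}).get("seed", 0))

    per_image: list[dict[str, Any]] = []
    groups: list[str] = []

    if simulate:
        sim_cfg = dict(cfg.get("simulate") or {})
        conditions = sim_cfg.pop("conditions", None) or [
            {"name": "sim", "overrides": {}}
        ]
        for idx, cond in enumerate(conditions):
            name = cond.get("name", f"condition{idx}")
            sc = _sim_config(sim_cfg, cond.get("overrides", {}), seed=seed + idx)
            stack, truth = generate_field(sc)
            truth_table(truth).to_csv(out / f"truth_{name}.csv", index=False)
            result = _quantify_one(name, stack, config_for_image(cfg, name))
            per_image.append(result)
            groups.append(name)
    else:
        if not images:
            raise ValueError("no images given and simulate not requested")
        for path in images:
            image_id = Path(path).stem
            local = config_for_image(cfg, image_id)
            stack = load_stack(
                path,
                channel_roles=local["image"]["channel_roles"],
                voxel_z_um=local["image"].get("voxel_z_um", 0.13),
                pixel_xy_um=local["image"].get("pixel_xy_um", 1.0),
                axis_order=local["image"].get("axis_order", "CZYX"),
            )
            per_image.append(_quantify_one(image_id, stack, local))
            groups.append(image_id)

    nuclei_df = pd.concat([r["nuclei"] for r in per_image], ignore_index=True)
    foci_df = pd.concat([r["foci"] for r in per_image], ignore_index=True)
    nuclei_df.to_csv(out / "nuclei.csv", index=False)
    foci_df.to_csv(out / "foci.csv", index=False)

    fish_frames = [r["fish"] for r in per_image if r["fish"] is not None]
    if fish_frames:
        pd.concat(fish_frames, ignore_index=True).to_csv(out / "fish.csv", index=False)

    # --- three-range binning of the configured metric, per group ---
    bins_cfg = cfg.get("bins") or {}
    metric = bins_cfg.get("metric", "focus_intensity")
    group_values: dict[str, np.ndarray] = {}
    for name, r in zip(groups, per_image):
        nrec, frec, counts = r["records"]
        if metric == "focus_intensity":
            vals = np.array([f.integrated_intensity for f in frec])
        elif metric == "nucleus_intensity":
            vals = np.array([n.integrated_intensity for n in nrec])
        elif metric == "focus_count":
            vals = np.array([counts.get(n.nucleus_id, 0) for n in nrec], dtype=float)
        else:
            raise ValueError(f"unknown bin metric {metric!r}")
        group_values[name] = vals

    bins_rows = []
    edges_cfg = bins_cfg.get("edges", "tertiles")
    reference = groups[0] if groups else None
    edges = None
    if edges_cfg == "tertiles":
        if reference is not None and group_values[reference].size >= 3:
            try:
                edges = tertile_edges(group_values[reference])
            except ValueError:
                logger.warning("degenerate reference distribution; binning skipped")
    else:
        edges = (float(edges_cfg[0]), float(edges_cfg[1]))
    if edges is not None:
        for name in groups:
            vals = group_values[name]
            if vals.size == 0:
                continue
            dist = bin_three_ranges(vals, edges)
            for rng_name, frac in zip(("low", "mid", "high"), dist.fractions):
                bins_rows.append(
                    {
                        "group": name, "metric": metric, "range": rng_name,
                        "edge_low": dist.edges[0], "edge_high": dist.edges[1],
                        "fraction": frac, "n": dist.n,
                    }
                )
    pd.DataFrame(
        bins_rows,
        columns=["group", "metric", "range", "edge_low", "edge_high", "fraction", "n"],
    ).to_csv(out / "bins.csv", index=False)

    # --- between-group comparisons (first group vs each other group) ---
    comp_rows = []
    equal_var = bool((cfg.get("compare") or {}).get("equal_var", False))
    if len(groups) >= 2:
        summaries = {}
        for name, r in zip(groups, per_image):
            nrec, frec, counts = r["records"]
            summaries[name] = {
                "focus_intensity": np.array([f.integrated_intensity for f in frec]),
                "focus_count": np.array(
                    [counts.get(n.nucleus_id, 0) for n in nrec], dtype=float
                ),
                "nucleus_intensity": np.array(
                    [n.integrated_intensity for n in nrec]
                ),
            }
        ref = groups[0]
        for other in groups[1:]:
            for m in COMPARE_METRICS:
                a, b = summaries[ref][m], summaries[other][m]
                if a.size < 2 or b.size < 2:
                    continue
                try:
                    res = unpaired_t(
                        a, b, equal_var=equal_var,
                        group_a=ref, group_b=other, metric=m,
                    )
                except ValueError as exc:
                    logger.warning("comparison %s %s-vs-%s skipped: %s",
                                   m, ref, other, exc)
                    continue
                comp_rows.append(
                    {
                        "metric": m, "group_a": ref, "group_b": other,
                        "n_a": res.n_a, "n_b": res.n_b,
                        "mean_a": res.mean_a, "mean_b": res.mean_b,
                        "t_stat": res.t_stat, "p_value": res.p_value,
                        "stars": res.stars, "equal_var": res.equal_var,
                    }
                )
    pd.DataFrame(
        comp_rows,
        columns=["metric", "group_a", "group_b", "n_a", "n_b", "mean_a",
                 "mean_b", "t_stat", "p_value", "stars", "equal_var"],
    ).to_csv(out / "comparisons.csv", index=False)

    log = {
        "chromoquant_version": __version__,
        "seed": seed,
        "simulate": simulate,
        "images": [str(p) for p in images] if images else [],
        "groups": groups,
        "resolved_config": cfg,
        "note": (
            "p-values are per-comparison; no multiple-testing correction is "
            "applied. Statistical units are nuclei/foci, not animals."
        ),
    }
    with open(out / "run_log.yaml", "w") as fh:
        yaml.safe_dump(log, fh, sort_keys=True)
    return out
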