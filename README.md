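# chromoquant

Quantification of heterochromatin foci clustering in fluorescence-microscopy
images of *Drosophila* nuclei (and similar round-nucleus preparations).

When cells exit the cell cycle and mature into a deep quiescent state, their
constitutive and facultative heterochromatin domains — HP1/H3K9me3 foci,
Polycomb/H3K27me3 bodies, the DAPI-bright chromocenter — progressively
coalesce: many small foci fuse into fewer, larger, individually brighter
ones while the total amount of signal per nucleus stays constant.
`chromoquant` is a reusable, tested implementation of the image-analysis
pipeline that turns confocal z-stacks of such nuclei into that readout,
aimed at labs quantifying nuclear-body clustering, chromocenter geometry or
locus compaction from multi-channel fluorescence stacks.

## What it computes

Starting from a multi-channel z-stack (DAPI plus a chromatin-mark channel,
optionally a GFP compartment channel and a FISH channel):

1. **Maximum projection** over 12 contiguous 0.13-µm z-sections (both
   defaults configurable).
2. **Nucleus segmentation** on the DAPI projection: circular-average
   smoothing, foreground threshold (manual per image, or Otsu as the
   reproducible default), seeds from the *h*-maxima transform, and a
   seeded watershed on the inverted intensity:

   nuclei = watershed(−I<sub>smooth</sub>, markers = CC(H<sub>h</sub>(I<sub>smooth</sub>)) , mask = I<sub>smooth</sub> ≥ t)

3. **GFP gating** of nuclei into compartments by mean-intensity threshold.
4. **Focus segmentation** inside each nucleus by the same recipe on the
   mark channel; foci never cross nucleus boundaries.
5. **Integrated intensities**: for region R, I(R) = Σ<sub>(r,c)∈R</sub> I(r,c),
   in raw camera counts. Per nucleus: total intensity, area, equivalent
   radius √(A/π), focus count. Per focus: area and total intensity. The
   clustering signature is the joint shift of the individual-focus
   intensity distribution (up) and the per-nucleus focus count (down) at
   conserved per-nucleus totals.
6. **Three-range binning** of any intensity distribution at two cut points
   (default: empirical tertiles of the reference group).
7. **FISH geometry**: per nucleus, the single z-section with the strongest
   FISH signal is selected; the satellite-spot centroid distance to the
   chromocenter (the DAPI-brightest body), normalised by the equivalent
   nuclear radius, d = ‖x<sub>spot</sub> − x<sub>cc</sub>‖ / √(A/π); and the
   total segmented FISH-positive area per nucleus (locus compaction).
8. **Statistics**: unpaired two-sample *t* tests between groups (Welch by
   default, pooled-variance on request), with the conventional star
   thresholds (\*<0.05, \*\*<0.01, \*\*\*<0.001, \*\*\*\*<0.0001).

Because raw wing-disc stacks are rarely shareable, the package ships a
synthetic-field generator (`chromoquant.simulate`) producing fields of
soft-edged nuclei with chromocenters, Gaussian foci with a controllable
**merge fraction** (coalescence), compartment boundaries and FISH spots —
with exact ground truth, so every stage of the pipeline is testable and its
recovery quantifiable.

## Worked example

The packaged demo simulates two 50-nucleus conditions that differ only in
coalescence (`merge_fraction` 0 vs 1, same per-nucleus truth totals), then
runs the full pipeline:

```bash
chromoquant run --simulate --out demo_out --seed 1
```

`demo_out/comparisons.csv` (reformatted):

```
metric             group_a    group_b    n_a  n_b  mean_a    mean_b    t_stat  p_value   stars
focus_intensity    dispersed  coalesced  186   96  1762.7    3256.5    -9.98   4.8e-17   ****
focus_count        dispersed  coalesced   50   50  3.72      1.92       8.14   5.0e-12   ****
nucleus_intensity  dispersed  coalesced   50   50  12501.3   12533.7   -0.045  0.96      ns
```

Reading: the coalesced condition has individually brighter foci (mean
integrated intensity 3256 vs 1763 counts, per-focus units) and fewer foci
per nucleus section (1.92 vs 3.72), while the per-nucleus totals are
statistically indistinguishable (p = 0.96) — the clustering signature.
`bins.csv` shows the same shift as three-range fractions: the dispersed
group binned at its own tertiles sits at (0.33, 0.33, 0.33), the coalesced
group at (0.15, 0.05, 0.80) — 80% of its foci fall in the high-intensity
range. `nuclei.csv` and `foci.csv` hold the flat per-object tables
(label, compartment, area, integrated intensity, centroid, focus count)
from which any such aggregate can be rebuilt, and `run_log.yaml` records
every resolved parameter and seed.

The same pipeline runs on real data via
`chromoquant quantify img1.tif img2.tif --config my.yaml --out results`,
with per-image manual thresholds in the config's `per_image` section, and
`chromoquant fish` for the FISH readout.

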