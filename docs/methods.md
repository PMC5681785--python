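# Methods

## Image model and conventions

All quantification runs on 2-D maximum-intensity projections of contiguous
z-ranges of a `(channel, z, row, col)` stack. The default projection depth
is 12 sections; at the default 0.13 µm spacing that is ≈1.6 µm, the depth
over which a wing-nucleus monolayer stays in focus. Stacks shallower than
12 sections project in full, with a warning. Pixel coordinates are 0-based
`(row, col)`; z-ranges are half-open; pixel values are raw camera counts
and are never rescaled at load time, so every threshold and every
integrated intensity is in the instrument's own units. Lateral pixel size
defaults to 1.0, i.e. distances are reported in pixels unless calibrated.

## Nucleus segmentation

The DAPI projection is smoothed with a circular averaging filter (discrete
disk of radius `smooth_radius_px`, default 3; borders use edge-repeating
reflective padding). Foreground is `smoothed ≥ fg_threshold`; the default
`"auto"` threshold is Otsu's method on the smoothed projection. This is a
deliberate substitute for per-image manual thresholding: a numeric
`fg_threshold` (globally or per image via the config's `per_image`
section) is the faithful manual mode, Otsu the reproducible default.

Seeds are the 8-connected components of the *h*-maxima transform of the
smoothed image restricted to the foreground. `h` defaults to 0.1 × the
smoothed image's maximum, scaling the seed criterion with the dynamic
range; an explicit numeric `h` makes segmentation exactly invariant under
adding a constant to both image and threshold. A watershed on the inverted
smoothed image, flooded from the seeds and constrained to the foreground,
separates touching nuclei. Objects under `min_nucleus_area_px` (default
30 px) are removed; border-touching nuclei are excluded by default because
truncation biases both area and integrated intensity. Surviving labels are
renumbered 1..n by descending area (ties by topmost-leftmost pixel), which
fixes the output bit-for-bit for identical inputs.

Foci are segmented by the same recipe independently inside each nucleus on
the mark channel (`focus_threshold` "auto" = Otsu over that nucleus's
pixels only; `focus_h` default 0.05 × the in-nucleus maximum;
`min_focus_area_px` default 2). Restricting both threshold and h-maxima to
the nucleus guarantees a focus never crosses a nucleus boundary. A nucleus
whose in-nucleus mark signal is flat yields zero foci rather than an
error.

GFP gating compares each nucleus's **mean** compartment-channel intensity
to the threshold (inclusive ≥). The mean rather than the sum makes the
call independent of nucleus size.

## Intensity readouts

Integrated intensity is the exact raw-count sum over a region's pixels. No
background subtraction is applied by default, matching the raw-integration
convention; the per-nucleus readouts are therefore directly comparable
only within an acquisition setting. Three-range binning uses half-open
intervals `[min, e1)`, `[e1, e2)`, `[e2, ∞)`; the default edges are the
empirical tertiles of the reference group, so that group sits at
(1/3, 1/3, 1/3) and shifts in other groups are directly interpretable.
The cut points of any published three-range figure are in general not
recoverable, so they are explicit configuration here.

## FISH geometry

Distances are measured in 2-D within the single z-section with the
strongest integrated FISH signal over the nucleus (ties → smallest z). The
chromocenter is the DAPI focus with the greatest integrated intensity in
that section, located by the focus segmenter run on the DAPI channel; its
position is the intensity-weighted centroid, which is robust for
asymmetric bodies. If no DAPI focus passes threshold the brightest
in-nucleus pixel is used, with a warning. The nuclear radius is the
equivalent-circle radius √(area/π) of the segmented nucleus mask — a
reproducible substitute for manual vendor-software measurement; the
normalised distance is not clamped, and values > 1 (spot outside the
equivalent circle) are flagged in the output rather than truncated.
rDNA-style locus size is the summed area of all FISH foci in the nucleus,
which separates extended from compact loci of equal brightness.

## Statistics

Between-group comparisons use the unpaired two-sample t-test. Welch's
unequal-variance form is the default; `equal_var` restores the
pooled-variance Student's form. p-values are two-sided; stars are assigned
at 0.05/0.01/0.001/0.0001. No multiple-testing correction is applied — each
comparison stands alone and the run log states this. Statistical units are
nuclei and foci (both groupings are emitted), not animals; treating
within-animal objects as independent overstates effective n, a caveat that
applies equally to the figure-style outputs this package reproduces.

## Synthetic fields

The generator emulates the phenotypes the pipeline must read out, not
chromatin physics. Nuclei are soft-edged disks (sigmoid edge, scale 0.8 px)
of radius 10 ± 1.5 px placed with ≥ 12 px edge-to-edge separation (4 × the
default smoothing radius) in a 600 × 600 field; each carries one Gaussian
chromocenter (σ 2.5 px, peak 150 counts) offset 0.25 r from the centre.
Foci are isotropic Gaussians (σ 1.6 px, peak 150 ± 30 counts over a
background of 10, Gaussian noise SD 2) with Poisson(4) counts per nucleus,
placed within 0.7 r at ≥ 5 px (≈3σ) pairwise separation — the dispersed
baseline is resolvable by construction, and clustering enters only through
the explicit `merge_fraction` knob. Foci carry Gaussian z-profiles (σ 1.5
sections) peaking at exactly 1 on an integer centre section, so the
maximum projection reproduces each focus's analytic projected mass
T = A·2πσ² up to truncation (<10⁻³ relative at the 4σ render cutoff); the
recorded truth intensity is that analytic mass, recorded before noise.

`merge_fraction f` fuses ⌊f·⌊n/2⌋ + ½⌋ random focus pairs per nucleus
(round half up, so a single pair merges at f = 0.5) into one spot at the
pair's intensity-weighted midpoint carrying the summed intensity — the
generative model of coalescence: per-nucleus totals are conserved exactly
while focus count drops and individual-focus intensity rises. Each nucleus
draws from an RNG stream keyed `(seed, nucleus index)`, so enlarging a
field leaves existing nuclei untouched; noise has its own keyed stream per
channel. Truth records are platform-independent; rendered images are
bit-identical within a platform.

Segmentations are scored against rasterised truth (nuclei as their hard
disks, foci as disks of radius max(1, round σ)) by greedy one-to-one
matching on truth-area overlap, requiring ≥ 50% coverage; an empty
prediction scores precision 1 (zero false positives) by convention, with a
log note.

What the generator does **not** model — realistic PSFs, Poisson-dominated
shot noise at low counts (Poisson noise is available behind a flag but off
by default), uneven illumination, nuclear shape irregularity, z-dependent
attenuation, touching/overlapping nuclei in crowded epithelia — bounds
what passing tests show: they validate the measurement logic and its
contrasts (count vs intensity at conserved totals, distance ratios,
area vs brightness), not robustness to every real-acquisition artefact.
Real images should be spot-checked with per-image thresholds as usual.

## Numerical choices and degenerate inputs

Otsu on a constant region is undefined; constant foregrounds/nuclei yield
zero objects rather than errors. Watershed ties are resolved
deterministically by scikit-image's flooding order; label renumbering by
(area, position) removes any residual order dependence. All-zero images
segment to empty maps; non-finite pixels are rejected. `unpaired_t`
refuses samples of n < 2 and pairs of zero-variance samples instead of
returning NaN. Intensity sums are accumulated in float64; on float32
images they agree with brute-force mask sums to well under 10⁻⁹ relative.

## Problem sizes used in the shipped checks

The test-suite and acceptance-script simulations use: 50 small fields
(128² px, 4 nuclei) for the exact-sum oracle; one default 100-nucleus
field for segmentation recovery; three renders of one 100-nucleus truth at
merge fractions 0/0.5/1 for the coalescence readout; four 50-nucleus
fields for FISH ratios 0.2–0.8; 1000 null simulations (n = 40 per arm) for
t-test calibration; and the 2 × 50-nucleus demo config for end-to-end
determinism. These sizes give stable population means (focus-count SE
≈ 0.2, FISH-distance SE ≈ 0.01) while keeping any single check in the
tens of seconds.

## Known limitations

2-D only: foci and distances are quantified on projections/sections, so
axially stacked foci can merge and distances are projections of 3-D
distances. The equivalent-circle radius under-estimates the radius along
the spot axis for elongated nuclei. Otsu defaults can differ from a
careful manual threshold on images with strong background gradients — the
per-image numeric override exists for exactly that case. The t-test
treats objects as independent within groups (see Statistics).
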