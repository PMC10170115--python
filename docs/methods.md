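# Methods

This note documents the models, estimators, and numerical choices in
`enteromap`, and what the synthetic ground truth does and does not
establish about real tissue.

## Coordinate and unit conventions

All physical quantities are in micrometres and seconds.  Wholemount
fields use x = circumferential, y = longitudinal (oral at y = 0), with
a half-open observation window [0, W) × [0, H); the default field is
800 × 800 µm, imaged at 1 µm/px with 3 µm optical sections.  Images are
indexed (z, row, col) = (z, y, x).  Motility videos use x =
longitudinal position along the tube (distal = increasing x) and run at
3.75 frames/s.

## Synthetic point patterns

`points.generate_point_pattern` draws hard-core patterns by sequential
dart-throwing: uniform proposals, rejected when closer than `d_min`
(default 5 µm — somata do not overlap) to any accepted point, with a
cap of 10,000 attempts per point after which a `PackingError` is raised
rather than silently relaxing the constraint.  A feasibility guard
rejects requests whose disk packing would exceed half the window area.

Striped patterns confine points to circumferential bands (period
150 µm, width 40 µm by default) with probability `p_in` = 0.9, the
hard core enforced across all points.  Grid patterns additionally force
a `bridging_fraction` (0.25) of points *between* the stripes, confined
to periodic circumferential bridge columns, and assign them a deeper z
position (12 µm; stripe points 0 µm) — bridging neurons sit nearer the
longitudinal muscle, stripe neurons nearer the circular muscle.  The
stripe/bridge geometry, per-point band membership, bridging flags and
subtype Bernoulli draws are all recorded in the returned ground truth.

## Rendering

Somata are painted as anti-aliased disks of the calibrated counting
area (138 µm², the field's area-per-neuron convention derived from a
9.374 µm mean soma diameter; the generator treats the unit area as the
primitive and parameterises it) into the z-slice nearest each point's
depth, then lightly blurred (0.5 µm) and noised (additive Gaussian
background, optional Poisson).  The painted radius is shrunk by
`edge_compensation_um` (0.4 µm): global thresholds sit slightly below
the half-maximum of a blurred disk edge, so an uncompensated disk would
measure ~10–13 % too large under the default measurement chain.  The
compensation was calibrated once against that chain (blur σ = 2 µm,
Otsu) and is stable across soma counts 50–400; with it, measured
foreground area per isolated soma is within ~1 % of the nominal
138 µm².

Cross-sections stack horizontal bands — mucosa, submucosal plexus,
circular muscle (CM), myenteric plexus (MP), longitudinal muscle (LM) —
at stated thicknesses, with hard-core-packed nuclei (Sox10 channel,
Poisson-drawn count at the requested density) and neuron somata
(HuC/D, with a Bernoulli "apoptotic" Caspase-3 subset) inside the MP
band.

Motility videos are rendered from an analytic diameter field
D(x, t) = baseline − Σ travelling Gaussian indentations.  Ripples are
shallow (300 µm) bidirectional indentations launched at near-regular
intervals (rate/min with 0.5 s onset jitter) from random interior
origins at 750 µm/s; neurogenic activity is either bidirectional bursts
gated by active/quiet windows (the whole preparation, ripples included,
is quiet between bursts) or exclusively distal waves (800 µm
amplitude, ~2000 µm/s).  A `ttx` flag removes all neurogenic structure
and can raise the ripple rate.  Frames show the dark tube on a light
background at 25 µm/px; the analytic field and the full event list are
the ground truth.

## Conditional intensity maps and the z-score difference

`cif.compute_cif` bins all ordered pair offsets into a (2L/bin)² lag
grid (defaults L = 200 µm, bin = 4 µm).  Edge correction is
translation-type, computed from the data: each lag bin is divided by
the fraction of reference points for which that lag stays inside the
window, symmetrised over lag negation so the corrected map retains the
raw map's point symmetry (each unordered pair enters once per
direction and shares one weight).  By default the map is normalised
per reference point.  Smoothing is Gaussian with SD 20 µm and
reflective boundaries, applied last.

The clustering statistic is the coefficient of variation (SD/mean) of
the smoothed map: zero for a flat map, scale-free, and sensitive to any
spatial structuring of the neighbourhood density.  The Monte Carlo
null regenerates hard-core CSR patterns matched to the data's n and
window (500 replicates by default; one master seed spawns a substream
per replicate).  Because the CV is right-skewed under CSR (skewness
≈ 0.8), z-scores are taken on the monotone transform x → −1/√x, which
brings the null skewness to ≈ 0 and the null z-scores close to
standard normal; the transform preserves ordering, so power and
band-exceedance logic are unchanged (log and identity scales remain
available).  Each null sample is standardised leave-one-out against
the remaining samples; the z-score difference is z(data) minus the
mean null z, and the null z's 2.5–97.5 percentile range is reported as
the random band.  Measured calibration at n = 300 with 100-sample
nulls: mean z_diff ≈ −0.06 over 100 CSR runs, |z| < 3 in ≈ 99 %.

### Stripe periodicity

The estimator collapses the *unsmoothed* corrected map along the
circumferential lag axis (smoothing would multiply the lag spectrum by
a strong transfer function and bias the detector), whitens the profile
by its per-lag noise SD (edge correction amplifies count noise at
extreme lags by 1/weight), keeps the non-negative-lag half (the map is
symmetric; the full profile would make the Fourier coefficients purely
real and halve the median magnitude), and evaluates the DFT magnitude
on a fine grid of periods between `min_period` (50 µm) and the
one-sided span.  The period is the inverse of the dominant frequency;
estimates at one cycle per span are flagged at-range-limit.

Significance uses the peak-to-median spectral ratio compared against
its own Monte Carlo null (59 matched hard-core CSR patterns, 5 %
level).  Lighter nulls were tested and rejected: a fixed ratio cutoff
and value permutations both run far too hot because point-count noise
is positively correlated across lags (density fluctuations), leaving
genuine low-frequency power in CSR maps.  Measured behaviour at
n = 300, L = 400 µm: period 150 µm recovered within ±10 % in 40/40
striped runs, false flags 4/40 on CSR.

## Image measurements

Segmentation operates on the maximum-intensity projection: Gaussian
blur (σ = 2 µm, sub-soma scale), Otsu threshold (a fixed value can be
passed; the projection is declared degenerate — empty result plus
warning, never an exception — if nothing clears the threshold or if
the "foreground" covers more than half the field, which is the
signature of Otsu splitting pure noise), removal of objects under
20 µm², and an optional watershed on the (slightly smoothed, to break
plateau ties deterministically) distance transform with markers at
regional maxima at least 5 µm apart.  Centroids are continuous area
centroids, 0-based, converted to µm by the pixel size.

Area-based counting divides total foreground area by the 138 µm² unit;
fractions above 1 are flagged, not clipped.  Colocalization intersects
the two thresholded projections and counts components, applying the
same watershed by default — without it, touching double-positive
somata merge and the estimated subtype fraction biases low by several
points at high prevalence.  Subtype fractions divide the double-
positive count by the area-based total, optionally restricted to a
polygon ROI (e.g. isolating the MP band on a cross-section).  Measured
accuracy against the generated field's realized positive fraction:
error −0.002 ± 0.005 at a 0.4 prevalence, n = 200 — when such an
estimate is compared to the generator's Bernoulli *parameter* instead,
the binomial draw (SD ≈ 0.035 at n = 200) dominates the error budget
by an order of magnitude.  Depth
projection assigns `z_step × argmax slice` to foreground pixels (NaN
elsewhere) and is invariant to uniform intensity scaling; per-soma
depth is the median over the soma's pixels.  Muscle thickness is the
foreground run length of the selected band (CM = first, LM = second
run from the luminal side) at n evenly spaced vertical transects
(default 2 per section, two sections per sample in practice); a
missing band names the failing transect.  Nuclear density counts
components in a rectangular ROI (~100,000 µm²) and divides by its
area.

## Spatiotemporal maps and events

`motility.compute_stm` thresholds each frame at the midpoint between
the robust (1st/99th percentile) dark and light levels — this cuts the
tube edge at half coverage, making the extent measurement exact to one
pixel, where a global Otsu would drift with the tube/background area
ratio — and takes the per-column foreground extent (last minus first
dark row, robust to interior holes) as the diameter.  Columns with no
foreground anywhere are invalid; more than 20 % invalid raises a
quality error naming them.  Measured accuracy: ≤ 1 px on noiseless
renders, ≤ ~1.1 px at default noise.

Events are 8-connected components of the contracted mask (diameter
below the per-column temporal median minus a 100 µm depth threshold,
configurable) lasting at least 1 s.  Per frame the component's left
edge, right edge, and minimum-diameter position are tracked.  Edge
slopes are fitted on the first contiguous run (≥ 3 frames) in which
both edges are interior to the tube — once a branch runs off an end
the clamped edge stops tracking the wave.  Opposite edge slopes
(each exceeding 50 µm/s) mark one bidirectional event with per-branch
velocities and the onset midpoint as origin; otherwise the direction
and velocity come from a least-squares line through the
minimum-diameter track, with 10 % of frames trimmed at each end to
avoid entry/exit clamping.  Components whose origins coincide within
2 bins and 2 frames are merged.  Measured recovery: velocity within
10 % (typically ≲ 3 %) for 200–5000 µm/s, direction 100 % correct on
single-wave videos, and time reversal maps distal events to proximal
one-to-one.

Ripple frequency counts diameter minima (prominence 100 µm) per 60 s
window at five interior positions and averages, in events/min;
unbiased within ±0.5 events/min at 2–12/min over 10-minute
recordings.  Stage classification is rule-based with configurable
thresholds: `distal_propagating` when the direction asymmetry
(distal − proximal)/(distal + proximal) over directional events
exceeds 0.8 with ≥ 3 such events; else `intermittent_neurogenic` when
the quiescent-time fraction (share of frames with no contracted
column) exceeds 0.2 with bidirectional events present; else
`ripples_only` (flagged low-activity when no events at all).  The
asymmetry and quiescence thresholds are package choices — the
underlying biology is described only qualitatively — and the ordering
matters: mature distal-propagating recordings are sparse in time and
would otherwise satisfy the quiescence rule.

`compare_conditions` pairs recordings sharing spatial calibration
(e.g. baseline vs 1 µM TTX, with washout supported as a third tag) and
reports per-condition summaries plus deltas.  In the synthetic TTX
scenarios, blockade ablates quiescent periods in the immature
(burst-gated) phenotype and removes distal waves while raising ripple
rate in the mature one.

## Pipelines and determinism

Both pipelines consume a manifest CSV and a flat `RunConfig` (unknown
keys rejected; config echoed into the output directory).  One master
seed spawns a substream per manifest row, so reruns are bit-identical;
per-sample failures are logged and skipped, and a run fails only when
every sample does.  Aggregation is limited to means per region ×
gestational-age bin (13–15, 18–20, 21–23 postconceptional weeks), the
form in which such data are plotted; inferential statistics are out of
scope.

## What the synthetic data does and does not show

The generators reproduce the *geometry* the estimators rely on —
hard-core soma packing, stripe/grid organization at two depths,
calibrated soma area, layered cross-sections, travelling-indentation
kymographs — under mild, well-behaved noise.  They do not emulate
uneven illumination, labelling variability, soma shape irregularity,
out-of-focus light, tissue deformation during recording, or lumen
content.  Passing tests therefore establishes the correctness and
calibration of the estimators on data satisfying their stated
assumptions, not robustness to every artefact of real microscopy;
thresholds (blur, depth, prominence) are exposed precisely so they can
be re-tuned on real material.

## Problem sizes used in tests and the acceptance script

The test suite runs the Monte Carlo checks at the sizes quoted above
(200 calibration runs with 100-sample nulls, 100-run power and
recovery checks, 20 segmentation fields, 50 seeds per subtype
fraction, 10-minute videos).  `scripts/acceptance.py` exercises the
same chain end to end at reduced replicate counts (e.g. 60 calibration
runs with 60-sample nulls, 8 fields, 12 seeds per fraction) so a full
from-scratch reproduction completes in a few minutes on one CPU; every
random draw descends from the `--seed` argument.
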