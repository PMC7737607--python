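# Methods

`endopos` quantifies the intracellular positioning of early endosomes (EEs)
and late endosomes (LEs) in single adherent cells imaged by confocal
microscopy, and the direction and speed of EE transport in live movies. This
note describes the model behind each stage, the parameters that matter, what
the synthetic generator does and does not emulate, and the numerical choices
made where the design was open.

## Fixed-image segmentation

All fixed-image analysis operates on 2-D maximum-intensity projections, one
cell per field, with three channels: a nuclear stain, an EE marker (e.g.
EEA-1) and an LE marker (e.g. LAMP-1). Intensities are nominally 8-bit
(0–255) but are held as floats internally so threshold statistics are not
quantized.

**Thresholding.** A channel is binarized at

```
T = mean(positive pixels) + n · SD(positive pixels)
```

where "positive" means strictly greater than zero and the SD is the
population standard deviation of those pixels. A pixel is foreground iff its
intensity strictly exceeds `T`. The multiplier `n` has no universal value —
it depends on staining intensity and detector settings — so it is a
per-experiment parameter (`n_sigma_nucleus`, `n_sigma_endosome`; default 2,
always logged). This rule implicitly assumes the image contains a sizeable
population of dim positive pixels (cytoplasmic background staining) below
the structure of interest; on an image whose positive pixels are uniformly
bright the statistic lands above the maximum and the mask is empty.

**Nucleus.** Threshold the nuclear channel, connect spatially near pixels by
morphological closing (`closing_radius_px`, default 2), label 8-connected
components, keep the largest (ties broken by raster order of the first
pixel, which is deterministic), and record the mask and its centroid (the
arithmetic mean of the mask's pixel coordinates). The mask blanks the
nuclear area during endosome detection; the centroid anchors all
distance-to-nucleus measurements.

**Cell.** The pixel-wise mean of the EE and LE channels is thresholded at
zero (any signal counts, maximizing the covered area), closed, hole-filled
and reduced to its largest component — a single solid object whose pixel
count, scaled by the pixel area, is the cell area in µm². This works because
photon-counting confocal detectors leave true extracellular background at
(near) zero counts while the cytoplasm carries diffuse fluorescence.

**Endosomes.** Per channel: threshold, blank the nucleus footprint, label
8-connected objects, then

1. *EE only* — split merged spots by watershed on the Euclidean distance
   transform. Only objects larger than `split_area_factor` (default 4) times
   the median object area are candidates; seeds are local maxima of the
   distance transform at least `split_min_seed_separation_px` apart. The
   default separation is 4 px (about one median spot diameter): at smaller
   separations the distance-transform ridge of a single slightly elongated
   spot carries two maxima ~2 px apart and lone spots get split, inflating
   counts. Splitting is not applied to the LE channel, whose fused
   structures are handled by the grape decomposition below.
2. Discard objects smaller than the channel's minimum size `s_min`
   (pixels): 3 for EEs, 10 for LEs (20 as the documented alternative for
   experiments with larger LEs).
3. Fill ring-like objects: enclosed background holes are converted to
   foreground. A hole is a 4-connected background region not connected to
   the image border (the complementary connectivity to the 8-connected
   foreground). On the LE channel only holes smaller than `s_min` are filled
   at this step, so that larger holes survive for the grape decomposition —
   filling everything first would leave the decomposition nothing to
   operate on.
4. *LE only* — decompose "grape-like" clusters (fused rings, recognized by a
   per-object Euler number below 1, i.e. at least one enclosed hole): each
   hole smaller than `s_min` is absorbed into the body; each hole of at
   least `s_min` pixels becomes a new object — the hole plus its immediately
   surrounding ring of object pixels, filled solid — and once any extraction
   happens the unassigned remainder of the grape is discarded. A single ring
   with one large hole therefore comes out as the filled ring, so this step
   subsumes ring filling for large rings.
5. *LE only* — circularity test: keep objects with `c` in `[0.6, 1.5]`
   (inclusive; a flag extends the test to EEs).

**Circularity.** `c = P² / (4π A)`, with `P` the object's boundary perimeter
and `A` its pixel area, calibrated so an analytic circle scores exactly 1
(`P = 2πr`, `A = πr²`). An off-by-π variant `c = P²/(4A)` is available
behind the `circularity_four_a` flag for compatibility with the literal
perimeter-squared-over-four-area convention; under that reading a circle
scores π, which is inconsistent with a `[0.6, 1.5]` acceptance band, so the
4π normalization is the default. The perimeter is the Freeman chain-code
length of the Moore-traced outer boundary (axial steps 1, diagonal steps
√2); 1–2-pixel objects fall back to the bounding-rectangle perimeter. This
estimator overestimates the perimeter of a smooth digitized circle by a
small factor that converges to ≈1.05 as the radius grows, so digitized discs
score ≈1.07–1.10 — comfortably inside the band; corrected chain-code
estimators were deliberately not used because the plain chain length is the
simplest reproducible convention.

**Euler number.** For a labeled set: (number of 8-connected objects) −
(number of 4-connected enclosed holes). Verified in the test suite against
an exhaustive flood-fill oracle.

## Per-cell quantification

For every endosome: the Euclidean distance between its centroid and the
nucleus centroid (µm), and the normalized metrics

* `distance_norm = distance / cell equivalent diameter`, with the
  equivalent diameter `2·sqrt(area/π)` — a length, commensurate with a
  distance. Normalizing by a diameter (rather than radius or √area) is a
  convention choice; the raw distance is always emitted alongside so any
  convention can be re-derived, and the choice is recorded in the output
  metadata (`distance_normalizer`).
* `size_norm = endosome area / cell area`; per-cell counts are reported per
  µm² of cell area.

Pearson colocalization between two channels is the product-moment
correlation of their intensities restricted to the cell mask; zero variance
in either channel is an explicit error, not a silent NaN.

## Live-imaging tracking

Movies are single-channel time-lapses at a fixed frame interval (0.5 s) and
~170 nm pixels. Per frame, objects are detected with a threshold of
`mean + n·SD` over *all* pixels (not only positives — movies are sparse and
the all-pixel statistic is the stable choice there; default `n` = 3) and a
3-pixel minimum size.

**Centroids.** The default per-detection position is the
background-subtracted intensity-weighted centroid (weight = intensity −
threshold over the object's pixels). Binary-mask centroids carry ~0.1 px
digitization jumps as boundary pixels flicker across the threshold; summed
over a trajectory these jumps inflate the path-length velocity estimate by
tens of percent at drift speeds of 0.02 µm/s, where the true per-frame step
is only ~0.06 px. The subtracted weighting gives boundary pixels near-zero
weight and tracks sub-pixel motion to <1% path error. The plain binary
centroid remains available (`centroid_mode="binary"`).

**Linking.** Frame-to-frame nearest-neighbour assignment within a 5-pixel
radius: all (active track, detection) pairs within the radius are assigned
one-to-one in ascending distance (ties: lower track id, then detection
raster order — the result is invariant to detection ordering within a
frame). Unmatched detections start new tracks; unmatched tracks terminate.
There is no gap closing: an endosome that disappears and reappears is a new
endosome. A track needs at least two detections.

**Persistence.** Only tracks lasting at least `persistence_s` are analyzed
(60 s for silencing-style comparisons, 30 s for acute-treatment ones); each
kept track is truncated to its first window so all trajectories share a
duration. "Appearing from 30 s" is read as "persisting for at least 30 s".

**Direction and velocity.** Ordinary least squares of distance-to-nucleus
(µm) against time (s): negative slope = retrograde (centripetal), positive =
anterograde (centrifugal); |slope| < 1e-12 µm/s (float round-off on constant
distances) is degenerate and excluded. For retrograde tracks the velocity is
the effective path — the sum of inter-frame displacement magnitudes over the
first 30 s — divided by 30 s. Because positional jitter and diffusion only
add to path length, this estimator is biased upward for non-ballistic
motion; the net-displacement velocity (start-to-end distance over the
window) is reported in the same table (`velocity_net_um_per_s`) so the two
readings can be compared. The nucleus centroid is supplied once per movie
and not re-segmented per frame; it may lie outside the field for wide cells.

## Statistics

* Two unpaired groups: two-tailed Welch (heteroscedastic) t-test with
  Welch–Satterthwaite degrees of freedom. Two constant equal samples give
  p = 1 by convention, flagged in the result.
* More than two groups: one-way ANOVA; post hoc pairwise t-tests
  (pooled-variance by default, Welch optional) with Bonferroni adjustment
  `min(1, m·p)` where `m` counts the comparisons actually requested.
* Tail contrast: one-sided two-sample Kolmogorov–Smirnov test of the
  alternative "the first sample is stochastically larger / has the longer
  right tail", statistic `D⁺ = sup_t [ECDF_y(t) − ECDF_x(t)]`, p-value the
  asymptotic bound `exp(−2 D⁺² n_x n_y/(n_x+n_y))`, labeled as asymptotic.
  Exact small-sample p-values are out of scope. Note that with equal sample
  sizes `n` the statistic lives on the lattice `k/n`, and at `n = 100` the
  achievable test size nearest 0.05 is exactly 0.0391 (next: 0.0556) for
  *any* correctly computed p-value; calibration exercises therefore use
  unequal sizes (100 vs 150), where the finer lattice brings the size to
  ≈0.044.
* Reporting: sample SD (n−1) and SEM = SD/√n; stars ns/*/**/*** at
  0.05/0.01/0.001.

## Synthetic data

The generator renders what the analysis assumes, with full ground truth:

* one elliptical cell per field with one circular nucleus; a dim cytoplasmic
  haze (default 10% of spot peak) fills the cell in every channel — in the
  endosome channels it gives the zero-threshold cell segmentation support,
  in the nuclear channel it supplies the dim positive population the
  threshold statistic needs;
* EE/LE vesicles as isotropic Gaussian spots (σ = radius/2, truncated at
  3σ), radii lognormal with a per-population floor; positions drawn along a
  radial Beta(a, b) law scaled to the corridor between nucleus edge and cell
  edge, so a < b is perinuclear and a > b peripheral; rejection sampling
  keeps spots clear of the nucleus and of each other (separation factor 3,
  emulating resolvable vesicles);
* LE "grapes" as fused annular rings with controllable hole sizes, placed
  like vesicles; the ground truth records the measured hole areas;
* noise: Gaussian of configurable SD added *on signal-bearing pixels only*
  (photon-counting detectors leave true background at zero counts), then
  clipping to [0, 255]; the noiseless render is capped at 255 first, so
  rendered structure never exceeds the 8-bit range;
* movies: particles take a radial drift step (`drift_speed·Δt`, negative =
  toward the nucleus) plus an isotropic Gaussian diffusion step of variance
  `2DΔt` per axis; optional geometric lifetimes with replacement births keep
  the population constant; everything is deterministic given the seed.

What the generator does **not** emulate: photobleaching, z-drift, camera
gain and read-noise structure, multi-cell fields, non-elliptical cell
shapes, spatially varying background, vesicle fission/fusion, and motion
along curved microtubule tracks (drift is straight-line radial). Passing the
recovery tests therefore demonstrates the correctness of the algorithms
under the stated imaging model, not robustness to every artifact of real
microscopy.

**Calibration of the detection threshold.** For the signal-to-noise regime
used in the recovery exercises (spot amplitude 5× the noise SD), a
pre-build sweep of `n_sigma_endosome` over 2–4 on three seeds showed that
n = 2 admits a handful of ≥3-px noise clusters while n = 3 yields zero false
positives with all spots recovered (centroid RMSE ≈ 0.4 px); those exercises
therefore run at n = 3, which is the kind of per-experiment adjustment the
threshold rule anticipates. The package default remains 2.

## Problem sizes used in the test suite

Recovery runs use 512×512 px scenes with 50 EEs; the positioning contrast
uses 500 measured endosomes per condition (10 scenes each); drift recovery
uses 61-frame movies at 0.02–0.10 µm/s; the null direction balance uses
~1,000 diffusion-only tracks (128 movies × 8 particles, D = 0.01 µm²/s,
initial distances 26–36 µm from the nucleus — far enough that the outward
`D/r` bias of radial Brownian motion is negligible against slope noise);
statistical calibrations use 10,000 null replicates per test. These sizes
were chosen as the smallest that make the pass/fail bands statistically
meaningful.

## Known limitations

* The threshold rule fails on images without a dim positive population
  (uniformly bright structures); `n_sigma` must then be lowered manually.
* The path-length velocity is upward-biased under diffusion; use the net
  velocity column for diffusive populations.
* Grape decomposition discards the un-extracted remainder of a grape even
  when that remainder is itself larger than `s_min` (the literal reading of
  the procedure it implements); vesicle counts in heavily clustered LE
  populations are therefore conservative.
* The asymptotic KS p-value is conservative at small samples and
  lattice-limited at equal sample sizes (see above).
* One cell per image is assumed and enforced; fields with several cells must
  be cropped upstream.
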