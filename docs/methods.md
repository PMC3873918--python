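# Methods

This note records the models, conventions, numerical choices and known
limitations behind `celltrax`. It is the design rationale a maintainer needs;
empirical claims here are limited to what the test suite and
`scripts/acceptance.py` themselves compute.

## Coordinate and angle conventions

Positions are stored in pixels, origin at the center of the top-left pixel,
x rightward, y downward (image convention), frames 0-based. All unit
conversion happens in the kinematics layer through `AcquisitionConfig`
(pixel size in µm, frame interval in minutes). Angles, however, are reported
in the compass frame users read off a microscope field: counterclockwise
from +x with y **up**, so that a cell moving up-and-right at equal rates has
a trajectory angle of 45°. The y-flip is applied in exactly one place,
`kinematics.angle_of_trajectory`, to keep the two conventions from leaking
into each other.

The angle of deflection is the signed smallest rotation from the previous
trajectory leg to the current one, clockwise positive, in (−180°, 180°].
Exact 180° reversals map to +180° (the clockwise branch) to keep the range
half-open; on sub-pixel centroids this choice affects a measure-zero set.
Zero displacement yields an undefined (NaN) angle rather than 0°, so
stationary cells do not register as moving east; undefined values are
excluded from every aggregate and from the direction histogram.

At interval size *a*, the deflection at frame n compares the legs
(n−a, n) and (n, n+a) — consecutive, non-overlapping legs sharing the
turning point — with n sliding by one frame. Overlapping intervals trade no
time resolution for substantial suppression of centroid jitter; the package
verifies (on straight tracks with added isotropic jitter) that both the mean
and SD of |deflection| are non-increasing in a over 1–5 and that most of the
gain arrives by a = 3, the conventional default.

The population table reports the plain arithmetic mean of trajectory angles,
reproducing the historical output field, even though that mean is
discontinuous at the 0°/360° wrap; `circular_mean_deg` is exposed separately
for users who need a wrap-safe average.

## Detection

The chain is the standard single-particle recipe: restoration, percentile
thresholding with non-maximum suppression, iterative intensity-weighted
centroid refinement, and moment-based discrimination.

Restoration subtracts a (2w+1)² boxcar background estimate and applies a
Gaussian low-pass of scale max(0.5, w/4), clamping negatives to zero, where
w is the cell outer radius in pixels. The low-pass scale is a compromise
measured during development: stronger smoothing (matched filter at the
nucleus scale) buys detection robustness in noise, but smears single-pixel
artifacts into nucleus-sized blobs, destroying the moment discrimination
step; w/4 keeps both properties at the SNRs the tests certify (≥ 5).

The percentile parameter is the fraction of image pixels expected to carry
nuclear signal and is interpreted **per frame**, so photobleaching does not
starve late frames. Detection accuracy depends on setting it near the true
signal fraction; the threshold is taken as an actual data value (upper
quantile, `method="higher"`) so the vanishing-percentile limit yields no
candidates. Candidates must also be local maxima within the (2w+1)²
neighborhood; plateau ties keep the lexicographically smallest (y, x).
Centroids are refined by iterating the intensity-weighted mean within the
disk of radius w until the shift drops below 0.5 px (max 10 iterations).
m0 (total intensity) and m2 (intensity-weighted squared radius) are computed
on the final support; detections with effective radius sqrt(m2/m0) below the
minimum-radius cutoff are dropped (cutoff 0 disables this). Because
thresholding is percentile-based, the detector is exactly invariant under
positive affine intensity rescaling.

## Linking

Detections are linked per frame pair by greedy ascending-cost assignment on
squared displacement, gated at max_disp × (frames stepped); conflicts break
by smaller cost, then smaller detection index, and detections are pre-sorted
by (y, x) within each frame, which makes the track set independent of input
order. At nuclear densities where spacing (tens of µm) far exceeds per-frame
motion (a few µm) the greedy assignment agrees with a global optimum while
being much easier to audit; the simulation tests certify ≥ 99% link purity
under the spacing condition (nearest-neighbor distance > 2× the gate).
Unmatched detections start tracks; tracks not extended within `link_range`
frames terminate (default 1 = no gap closing). Gaps are kept as genuine
frame skips — positions are never interpolated — and downstream code uses
actual frame differences. Colliding nuclei that swap identities are accepted
errors. Tracks shorter than the minimum track length are discarded.

## Persistence time

The persistent-random-walk MSD model, MSD(t) = n_d S² P (t − P(1 − e^(−t/P)))
with n_d = 2, is fitted by unweighted nonlinear least squares
(`scipy.optimize.least_squares`, tolerances 1e-10) with multiple starts in
P (7, 30, 120, 480 min) and S seeded from the ballistic limit of the first
MSD point, because the model's large-t plateau traps single-start
optimizers. The default fit window is all lags up to 240 minutes: persistence
measurements conventionally sample MSD behavior over 2–4 hours of lags, and
the small-lag region is where P is identified. The fit is performed on the
population-averaged MSD by default (pooled over all tracks and overlapping
start frames, weighting cells by the windows they contribute); per-cell
fitting is available but noisy at 7-minute sampling. A fit is flagged
non-converged when the optimizer fails from every start or when the fitted
P exceeds the largest fitted lag — a ballistic track produces exactly this
signature, since its MSD never leaves the t² regime.

Two known, quantified biases: (i) fitting the continuous-time formula to a
discrete-step walk is biased low, by about 4% at P = 2·dt and under 1% for
P ≥ 8·dt (measured on exact discrete-model curves); (ii) centroid
localization noise adds a constant to all MSD lags, inflating S and
deflating P — fits on tracker output are noisier than fits on ground-truth
tracks.

The right-turn fraction (percentage of a cell's deflections that are
clockwise) excludes exactly-zero deflections from the denominator; with
sub-pixel centroids these have measure ~0.

## Collective migration (PRMI)

For each frame, every cell with a defined trajectory angle is paired with
its single nearest other cell, the pair kept when the inter-centroid
distance is within 100 µm (the conventional neighbor radius); reciprocal
duplicates collapse to one unordered pair. An all-pairs-within-radius mode
is available, and the mode used is recorded in the result. The pairwise
statistic is the two-point *sample* standard deviation |Θa − Θb|/√2 — the
n−1 denominator is the only choice consistent with the ≈ 85° uniform-angle
ceiling (120/√2 = 84.85; the population-SD choice would give 60). Values are
compared raw, without circular wrapping; instead, pairs with one angle in
[0°, 90°] and the other in [270°, 360°) are excluded, because their raw
difference is inflated by the wrap. Pairs are pooled across all frames of
the analysis window, and results with ≤ 100 pooled pairs carry a warning.

The random-pairing control redraws each cell's partner uniformly among the
same frame's cells (distances ignored, exclusion still applied; per-frame
cell sets are respected because that states the null most cleanly). The
random-angles control replaces every angle by an independent uniform draw
**without** applying the exclusion rule: with exclusion the uniform ceiling
would be (120 − 270/8)/(7/8)/√2 ≈ 69.7°, not the ≈ 85° null the statistic
is calibrated against. Whether exclusion was applied is recorded in the
result. Both controls consume an explicit seed and are bit-reproducible.

Note the corollary, visible in the worked example: a *non-collective*
population evaluated through nearest-neighbor or random pairing (exclusion
on) sits near 69.7°, while its random-angle control sits near 84.85°. The
leading-edge profile assigns cells to distance bins (along a user-chosen
axis, edge at the extreme occupied coordinate or a supplied position) at
each window's start, then computes the nearest-neighbor PRMI within each
bin; bins under the minimum pair count report NaN, never zero.

PRMI is exactly invariant under global rotation of all directions when the
exclusion rule is off and no pair difference crosses the wrap; with
exclusion on, rotation changes which pairs straddle the wrap, and for
tightly aligned populations the variation stays within ~2°.

## Synthetic data

The generator emulates the experimental regime the statistics were designed
for: by default 300 cells seeded uniformly in a 1000×1000 µm arena
(300 cells/mm², the low-density imaging condition), 1.314 µm pixels,
7-minute frames, speed 0.5 µm/min, and wrapped-normal turning noise of
39.128°/step. Wrapped-normal noise was chosen over von Mises because its
directional autocorrelation is exp(−σ²/2) in closed form, giving an analytic
link to persistence time, P_true = 2·dt/σ_rad²; the default σ corresponds to
P_true = 30 min, a representative epithelial value. Each step the heading
gains noise and the cell advances S·dt; boundaries are reflective (a field
of view cells do not wrap around), mirroring both position and heading.
Collective flow adds, before the noise, relaxation of each heading toward
the circular-mean heading of neighbors within a coupling radius (weight in
[0, 1]); an optional edge gradient grows the noise SD linearly with distance
from the x = 0 edge, emulating collective order decaying away from a sheet's
leading edge. With weight 0 and no gradient the collective engine consumes
the identical random stream as the plain walk, so the degenerate case is
bit-identical under the same seed.

The renderer draws each nucleus as an isotropic Gaussian spot (default
σ = 3 px) at its sub-pixel position on a constant background with additive
Gaussian pixel noise, clipped to 16 bits. All generators are pure functions
of (params, seed).

What the generator does **not** model — and hence what passing tests do not
certify on real data: mitosis and apoptosis, cell–cell exclusion volumes
(simulated nuclei can overlap; accuracy tests therefore condition on a
well-separated subset, which is the spacing regime the detector is specified
for), photobleaching, non-Gaussian PSFs, uneven illumination, and motion
blur. Real videos also violate the persistent-random-walk model at long
times (confinement, interactions), which is why the fit window is bounded.

## Problem sizes

Test and acceptance computations are sized for a laptop-class single core:
populations of 150–1000 cells, 20–101 frames, fields up to ~760² px, and
brute-force oracles on 0.1° (trajectory) and 1°×1° (deflection) grids. The
acceptance script simulates 1000 cells × 100 steps. At these sizes the whole
suite runs in well under a minute and all Monte-Carlo tolerances are set
from binomial or half-normal error propagation at 3–4σ.

## Interface notes

The CLI mirrors the historical GUI parameter surface (cell outer radius,
minimum-radius cutoff, percentile of pixels with nuclear signal, tolerated
displacement per frame, frame binning, minimum track length, threads, input
folder). The `--threads` flag is accepted and validated but videos are
processed sequentially; each video is analyzed in full isolation with fixed
seeds, so results are identical for any worker count, which is the contract
that matters. Output is CSV rather than a spreadsheet workbook — bit
inspectable and diffable — with the per-cell and population column orders
fixed; the 360-bin direction histogram is stored semicolon-joined in a
single column. Reports are written with shortest round-trip float formatting,
so write → read is numerically exact and reruns with equal configs are
byte-identical.
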