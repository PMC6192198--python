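# Methods

This note records the models behind each pipeline stage, the defaults and
why they were chosen, and what the synthetic data does and does not emulate.

## Study design being modeled

Six groups (two tissues × three prostate-cancer cell lines) are observed
weekly for 21 days through transparent chambers: 15 femur windows (FW, bone)
or 20 dorsal skinfold chambers (DSC, striated muscle) implanted per group.
Animals without engraftment on day 7 are excluded (they remain in the
take-rate denominator); animals whose tumor-induced femur fracture mandates
sacrifice are censored after their last observed day — bone LnCap after
day 14, bone Pc3 after day 21. Growth is expressed per animal relative to
its own day-7 area (day 7 ≡ 100 %).

## Synthetic cohorts

Engraftment is Bernoulli per animal with the group's take probability
(14/15, 14/15, 10/15 in bone; 14/20, 14/20, 9/20 in muscle). Engrafted
areas follow

    area(day) = A7 · rel(day)/100 · exp(ε),   ε ~ N(0, σ²),

with σ = 0.15 by default. Noise is multiplicative log-normal because areas
are strictly positive and span a ~7-fold range over the observation period;
an additive model would allow negative areas for small day-7 tumors.

The relative-growth anchors rel(day) are the groups' weekly values; where a
muscle day-14 value is not separately established, it is the log-linear
(geometric) interpolation of the day-7/day-21 anchors — growth over a week
is better modeled as a multiplicative than an additive process. Absolute
day-7 areas are set to 1.0 mm² in bone versus 2.0 mm² in muscle (muscle
tumors start 2-fold larger), with Pc3 at half the burden of the other lines
(0.5 / 1.0 mm²).

Note one deliberate property of these conditions: with independent
log-normal errors at both days, the expected per-animal ratio
E[rel·exp(ε_d − ε_7)] = rel·exp(σ²) ≈ 1.023·rel, so Monte-Carlo means of
relative growth sit ~2.3 % above the anchors. This is a property of
mean-of-ratios normalization, not an estimator bias.

Relative growth is computed **per animal and then averaged**
(mean-of-ratios), matching normalization of each tumor to its own day-7
value; ratio-of-means would weight large tumors more heavily.

## Tumor rendering and segmentation

Rendered tumor frames are soft-edged disks: radial profile
`0.5·(1 + erf((r₀ − r)/(√2 σ_e)))` with edge width σ_e = 3 µm, so the
half-maximum contour sits exactly at the true radius and threshold-based
area recovery is unbiased in the noise-free limit. Segmentation is Otsu
threshold → hole filling → largest connected component → pixel count ×
pixel_size². The interactive vendor-software outlining used at the
microscope is replaced by this automatic, reproducible rule. Frames whose
foreground is not separable from the noise floor (blank or noise-only)
return area 0 with a warning rather than segmenting noise.

Growth imaging is low-magnification; the default calibration for rendered
cohort frames is 8 µm/pixel, at which the discretization error of a ≥0.3 mm²
disk is well under 1 %.

## Synthetic vessel fields

Vessels are straight tubes with Gaussian cross-section whose FWHM equals the
true diameter, placed without overlap (rejection sampling; a field too small
for the request raises an error). Perfused tubes (Bernoulli with the
preset's perfused fraction) carry an *aperiodic* train of dark gaps —
unlabeled erythrocytes in bright plasma — advected at the true centerline
velocity; the jittered gap spacing (35–80 µm) makes the advection pattern
unambiguous under cross-correlation, where a strictly periodic train would
alias once the per-frame displacement exceeded half a period. Unperfused
tubes are static. Additive Gaussian noise is optional.

Default imaging parameters — 0.5 µm/pixel, 30 frames/s, 10-s duration,
160 × 160 µm fields — are declared defaults, not measured values; only the
10-s recording length is anchored in the protocol. Per-tissue regimes
(muscle: more, narrower, slower capillaries; bone: fewer, wider, faster
sinusoidal vessels) encode the qualitative ordering only.

## Vessel quantification

*Extraction.* Sato tubeness (multi-scale ridge filter) on the time-averaged
frame → Otsu threshold for detection → refinement of the support to the
half-maximum intensity contour → skeletonization → decomposition of the
skeleton into centerline paths between branch/end points. Two numerical
details matter. First, the 8-connected pixel chain overestimates the
Euclidean length of oblique lines by up to ~8 %, so paths are decimated to
chords (every 4th pixel) before measuring length. Second, thresholding at
half maximum makes the rounded end cap extend ~D/2 beyond the true endpoint
while skeletonization retracts by about the local half-width; the two
roughly cancel, leaving endpoint localization good to about a quarter
diameter per end (≈1 % of a 500-µm vessel).

*Diameter.* Median over ≥5 positions in the central 70 % of the centerline
of the FWHM of the perpendicular intensity profile, background-subtracted
with a low (10th) percentile of the profile — robust to neighboring vessels
crossing the profile tails. The peak is searched within ±5 µm of the
centerline so a brighter neighbor cannot capture the measurement. Profiles
that never fall to half maximum yield NaN and an `unmeasurable_diameter`
flag.

*Velocity.* A kymograph (intensity along the centerline × time) is built by
bilinear sampling; the outer 12 % of positions are dropped (end caps are
static). For every successive-frame pair the cross-correlation is computed
with per-lag normalization by the energies of the overlapping windows —
unnormalized correlation is biased toward small lags, which matters when
fast flow shifts the pattern by a large fraction of the vessel length per
frame. The normalized curves are averaged over all pairs before the peak is
taken (with parabolic sub-sample interpolation): the true displacement is
consistent across pairs, so averaging suppresses spurious single-pair peaks
at low-overlap lags. Velocity = |peak lag| × spacing × frame rate. A vessel
with no temporal intensity variation returns 0 µm/s.

*Perfusion.* A segment is counted perfused when its estimated velocity
exceeds 10 µm/s; the threshold is configurable. The round-trip accuracy on
noise-free fields is ≤5 % for VD, D, Vmean, BFR and TPR (the acceptance
property), with typical errors ≤2 %.

*TPR.* Realized as Σ BFR_i / A over perfused segments. When segment lengths
are equal this equals VD × mean(BFR)/mean(length), i.e. the quantity "blood
flow per area obtained using VD and BFR"; the per-segment sum is exact for
unequal lengths and is intensive under tiling.

*ROIs.* Three per tumor (border_1, border_2, center); the aggregate is the
unweighted mean of each metric, and a missing ROI is an error naming the
label.

## Permeability

The printed form of the permeability formula in the source literature is
typographically garbled (unbalanced parentheses; (I₀ − I_b) appears as a
factor rather than a divisor, which cannot be dimensionally consistent).
The canonical form of the referenced methodology is implemented:

    P = (1 − HT) · (V/S) · ( (dI/dt)/(I₀ − I_b) + 1/K )

with dI/dt the OLS slope of the mean image intensity over the ~10-min
intermittent recording (default one sample per 30 s, 21 samples), HT = 0.19
used in both tissues (a single configurable default; tissue-specific
microvessel hematocrit is not separately established), K = 9.1 × 10³ s, and
V/S in µm converted to cm/s via 1 µm/s = 10⁻⁴ cm/s. A negative computed P
(noisy flat traces) is reported with a quality flag, never clipped. When I₀
and I_b are not recorded separately, I₀ is the maximum of the first three
samples and I_b a pre-injection frame if available, else the 1st percentile
of the trace. The trace generator is the exact inverse of this model, so the
noise-free round trip is an identity to numerical precision; the slope's
standard error is calibrated (3·SE covers the true slope in ≥99 % of noisy
traces).

## Statistics

One-way within-subject ANOVA from sums of squares; Mauchly's test (W
statistic, chi-square approximation) decides sphericity at α = 0.05, and on
violation both degrees of freedom are multiplied by the Greenhouse–Geisser
epsilon computed from the double-centered sample covariance of the time
points (bounded in [1/(k−1), 1]). Subjects with incomplete series
(fracture-censored) are listwise-deleted — classical RM-ANOVA requires
complete cases — which matches the per-day n reporting of the cohort
summaries. Bonferroni post-tests (paired t, p_adj = min(1, m·p)) run only
once the omnibus test is significant at 0.05. Under a null with mildly
heterogeneous variances (Greenhouse–Geisser ε ≈ 0.93, n = 15 subjects, k = 3
days) the two-stage procedure's empirical type-I error is within
[0.035, 0.065] at nominal 0.05 (2000-replicate calibration). The
implementation agrees with pingouin's repeated-measures ANOVA to machine
precision on F, ε and W; Mauchly p-values differ only in higher-order terms
of the chi-square approximation.

Between-tissue contrasts at a fixed day use the same machinery degenerating
to a paired comparison; the contrast set is configurable since the original
per-metric contrast choices are not fully specified.

## Problem sizes

Monte-Carlo growth recovery uses the study cohort sizes (15/20 animals),
σ = 0.15, and 200 seeded replicates per group; vessel round-trip checks use
160 × 160 µm three-vessel fields at 0.5 µm/pixel, 10 s × 30 fps; slope
calibration uses 1000 traces; the ANOVA calibration 2000 replicates. These
sizes give Monte-Carlo standard errors well below the tolerances they are
checked against.

## What the synthetic data does not emulate

No point-spread-function optics beyond the Gaussian cross-section, no
breathing-motion artifacts (the real chamber is clamped), no vessel
curvature, branching hierarchies or angiogenic morphologies (sprouts,
loops), no 3-D volumes, no osteolytic/osteoblastic lesion structure, and no
spatial heterogeneity of permeability. Passing round-trip tests therefore
demonstrates correctness of the estimators under the stated image-formation
model, not robustness to every artifact of real intravital recordings.
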