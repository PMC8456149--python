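# Methods

## The experimental setting this package models

Migrating hoverflies (*Scaeva pyrastri*, *S. selenitica*) caught on a
Pyrenean mountain pass are flown in a tethered flight simulator: each fly
rotates freely about a vertical magnetic tether while a camera below
records its body orientation at 5 frames s⁻¹ for 5 minutes. Three
treatments are analysed: a **sun compass** group that can see the sun but
no landscape, a **restricted view** group with the sun occluded, and a
**clock shift** group whose circadian clock was advanced 6 h. If the
animals steer by a time-compensated sun compass, clock-shifted flies
should rotate their headings by the change in solar azimuth over the
shift interval — at this site and season, 91–105° clockwise depending on
date and time.

## Angle extraction (track)

Body angles are read off each video frame by exhaustive rotation search.
The user supplies the silhouette as an ellipse over the abdomen unified
with a circle over the thorax; the tether point is the thorax-circle
centre. For every frame all 360 integer rotations of this kernel are
scored by Pearson correlation between the binary kernel raster and the
inverted, contrast-enhanced frame (dark body on light background scores
positively). The argmax is the angle, to the nearest degree.

Numerical choices:

* **Score** — correlation over the full raster rather than plain
  convolution: invariant to global intensity shifts and gain, so the same
  kernel works across frames with drifting exposure.
* **Rotated kernels are re-rasterized analytically** from the parametric
  shapes rather than image-resampled; there is no interpolation blur, and
  at the reference pose the rotated raster equals the drawn mask exactly.
* **Ties** are broken toward the previous frame's angle (circularly
  nearest), suppressing ±1° flicker between equal-scoring neighbours;
  the first frame falls back to the smallest angle.
* **Head/tail ambiguity** — the abdomen trailing the tether point makes
  the kernel asymmetric under 180° rotation; frames where the score ratio
  between the best angle and its antipode is below 1.02 are flagged, as
  are frames with a best score below 0.2 or no contrast at all (the angle
  is still reported).
* **Contrast enhancement** clips intensities above the
  (1 − clip_fraction) quantile and rescales to [0, 255]. The manual
  procedure ("lower the maximum until background detail disappears")
  corresponds to a clip fraction exceeding the background's pixel share;
  the default 0.05 is a gentle denoising clip that leaves dim features
  intact. On rendered fixtures (fly ≈ 10 % of pixels) a clip fraction of
  0.8 collapses background variance by ≈ 88 %.
* Image angles are clockwise from image-up; a single per-session
  calibration offset maps image-up to compass north.

Measured accuracy on rendered silhouettes (64 × 64 px, default body
shape): RMS error 0.35° noiseless, 0.36° at additive noise sd 20 — the
quantization floor of a 1° search.

## Circular statistics (circstats)

Angles are compass bearings, internally radians. Per-fly summaries are
mean vectors (θ, r) with r the mean resultant length.

**Moore's modified Rayleigh test.** For n flies with vectors (θᵢ, rᵢ),
lengths are ranked ascending (average ranks on ties) and

    X = Σ rankᵢ cos θᵢ / n^{3/2},  Y = Σ rankᵢ sin θᵢ / n^{3/2},
    R* = √(X² + Y²)

with the weighted mean direction atan2(Y, X). R* is bounded by
(n+1)/(2√n), attained when all directions coincide. Instead of the 1980
printed probability table, the p-value is Monte Carlo: under the null the
directions are iid uniform and independent of the lengths, so the null
distribution of R* is sampled by pairing the fixed ranks 1..n with
uniform directions (default 10⁵ draws, seeded, plus-one corrected). The
sampler is vectorized and chunked; type-I error at α = 0.05 measures
0.05 ± 0.01 at n = 15 and 30.

**Rayleigh test** uses the standard series approximation
p = e^{−Z}[1 + (2Z−Z²)/(4n) − (24Z−132Z²+76Z³−9Z⁴)/(288n²)], Z = n r²,
which reproduces published exact values (e.g. p = 0.011 at n = 30,
r = 0.384) at printed precision.

**Bootstrap CI for the weighted mean.** Flies are resampled with
replacement, lengths re-ranked within each resample, and the interval is
the percentile band of signed circular deviations from the point
estimate, re-centred — correct across the 0/360 wrap. Default B = 10⁴
(10⁶ matches the original reporting; 2 × 10³ is used in simulation-heavy
tests). Measured coverage of a nominal 95 % interval at the study scale
(n = 30, between-fly concentration 0.82) is 94 %; at n = 15 the
percentile method undercovers slightly (≈ 92 %), a known small-sample
limitation.

**Mardia–Watson–Wheeler test** uses uniform scores of pooled ranks,
W = 2 Σⱼ (Cⱼ² + Sⱼ²)/nⱼ against χ² with 2(k−1) df; a warning flag is set
whenever a group has fewer than 10 observations. Null calibration
measures mean W ≈ 2.1 and type-I ≈ 5 % at n = 15 per group.

**Axial analysis** doubles each direction modulo 360 (lengths unchanged),
runs the rank-weighted test, and halves the weighted mean onto [0, 180) —
appropriate for cues such as polarized light whose e-vector is a line,
not an arrow.

Degenerate inputs: r = 0 leaves the mean direction undefined (NaN,
flagged) rather than an arbitrary 0°; identical vectors give a zero-width
bootstrap interval.

## Solar ephemeris and sun-relative frames (solar)

Solar azimuth (degrees clockwise from true north) comes from the NOAA
solar-position equations (low-precision Meeus reduction: Julian century,
equation of centre, apparent longitude, corrected obliquity, equation of
time, hour angle). Cross-checked against an independent implementation of
the PSA algorithm the two agree to < 0.01° over the study window; the
azimuth at local solar transit is 180° and the curve is symmetric about
transit on the equinox.

Three transforms build on it:

* **rectification**: (angle − azimuth + 180) mod 360, putting the sun at
  180° so flights at different times are comparable; a rigid rotation per
  fly. Note that rectifying each fly at its own experiment time is *not*
  a rigid rotation of the group, so group R* may change — only a shared
  azimuth preserves it exactly.
* **clock-shift difference**: Δ(t) = az(t) − az(t − shift), the rotation
  a fully compensating clock-shifted animal should show. Over the
  experimental window (14:29–16:42 local, 7–11 Oct 2019) the 1-minute
  grid gives 91.3–104.2°, matching the reported 91.1–104.5° range to
  within 0.3°. The reference time must be after sunrise.
* **back-transformation** subtracts Δ(t) from clock-shifted headings so
  they can be compared with controls.

A 4-parameter logistic fit of azimuth against time of day
(c + (d−c)/(1 + e^{b(t−e)}), scipy least squares) is provided for
workflows whose azimuths come from a printed table; it predicts the
ephemeris to < 0.35° RMS over a 09:00–17:00 window but is off by default
because the internal ephemeris supersedes it.

The study site is 42.7038793° N, 0.0641454° W (the coordinate is west of
Greenwich; local civil time on the study dates is CEST, UTC+2,
configurable).

## Synthetic experiments (synth)

The generator is the test bed for every downstream stage. Per fly:

* a true heading from a von Mises around the group mean (von Mises is the
  canonical circular analogue of the normal; the original study reports
  no between-fly distribution). Default concentration κ_between = 0.82,
  chosen so the expected group mean-vector length is ≈ 0.38, the scale
  observed for the 30-fly sun-compass group. Under clock shift the
  effective mean is mu + c·Δ(t_fly) with compensation c ∈ [0, 1];
  restricted view draws uniformly.
* an angle series of iid von Mises draws around the heading
  (κ_within = 2 → per-fly r ≈ 0.70). A log-normal per-fly multiplier on
  κ_within (σ = 0.5) spreads per-fly r over ≈ 0.4–0.9: without length
  heterogeneity the rank weighting would be degenerate.
* evenly spaced start times inside each treatment's historical daily
  window (sun compass 10:37–16:34, restricted view 16:17–18:45, clock
  shift 14:29–16:42; 7–11 Oct 2019), representative species/sex labels,
  and optional whole-frame shadow events so the 70 s/10 s selection rule
  has realistic input.
* reproducibility: every quantity comes from a substream keyed on
  (experiment seed, fly index, purpose), so records are bit-identical
  across runs and independent of group size.

The renderer rasterizes the same ellipse∪circle geometry the tracker
uses, on a flat background with optional Gaussian noise — it emulates
silhouette pose, not photorealism: no wings, no lighting gradients, no
motion blur, no off-centre drift of the tether. Tracker accuracy numbers
on these fixtures are therefore a floor for rendering-related error only;
real video adds segmentation and calibration error the synthetic stack
cannot exhibit.

At the calibrated study conditions (group r ≈ 0.38, n = 30) the
rank-weighted test's measured power is ≈ 0.6 at α = 0.05 — lower than the
classical Rayleigh test on the same draws (≈ 0.79) because the simulated
vector lengths are independent of heading accuracy, so the rank weights
add variance without adding signal. A design in which better-oriented
flies also fly more steadily would reverse that ordering.

## Pipeline

Selection: the longest flight interval with perturbation intervals cut
out must reach 70 s; its first 10 s are discarded; ties prefer the
earlier segment. Group summaries mirror the standard reporting format
(weighted and unweighted means, bootstrap CIs — suppressed for groups not
significant at α, printed as "—" —, R*, Rayleigh r, both p-values), with
a config hash attached for provenance. Group comparisons run the MWW test
on per-fly mean angles in a chosen frame (geographic / rectified /
back-transformed, the latter applied only to clock-shifted flies). The
virtual path integrates headings at a constant ground speed (default
5 m s⁻¹, the low end of mark–recapture estimates for migrating
hoverflies) with step = speed/rate; cumulative distance is exactly
n·speed/rate. Time-of-day splits are a median split on start time rather
than a hard-coded clock boundary.

## Problem sizes used in the test suite

Simulation-based tests run at reduced but statistically meaningful sizes
chosen as package defaults: 20–80 s synthetic recordings (the selection
rule needs > 70 s where it is in play), bootstrap B = 2000, Monte-Carlo
nulls of 10⁵–2×10⁵ draws, 300 replicates for end-to-end recovery, 1000
for CI coverage, and 5000 for type-I calibration. The full suite runs in
well under a minute on one CPU except the property-heavy acceptance
tests (a few minutes).

## Known limitations

* The Monte-Carlo MMR p-value is exact only up to simulation error
  (±0.0007 at 10⁵ draws for p ≈ 0.05); printed-table brackets are
  reproduced, not digit-identical historical interpolations.
* The percentile bootstrap undercovers slightly below n ≈ 15.
* The ephemeris omits atmospheric refraction (irrelevant for azimuth at
  the elevations used) and magnetic declination (angles are relative to
  true north).
* The tracker assumes a single animal, a fixed tether point, and a
  darker-than-background body; it searches integer degrees only.
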