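# Methods

This note records the models, conventions and numerical choices behind
`eddyforage`, in the order data flows through the pipeline. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Eddy atlas

An atlas record is one eddy on one calendar day: center, polarity (AE
anticyclonic = sea-surface-height high, CE cyclonic = low), amplitude (the
absolute-dynamic-topography difference between edge and center, meters),
effective contour (outermost closed boundary), speed contour (where the
rotational current peaks), radii, area, rotational speed, first detection
date and lifespan. Longitudes are normalized to [−180, 180). Eddies with
lifespan below 14 days are discarded (inclusive bound: 14 days is kept) —
shorter tracks are likely detection noise.

**Water-mass trapping.** The non-linearity metric is U/c: rotational speed
over translation speed, with c the great-circle path length of the center
over a centered 5-day window divided by elapsed time (windows truncated at
trajectory ends; a stationary center yields +inf with a warning). Values
above 1 indicate the eddy rotates faster than it translates and can carry
a trapped water mass. The alternative literal reading "distance covered
over rotational speed" is not dimensionless; it remains available as
`trapping_definition="paper_literal"` purely for audit. Distances use the
haversine formula on a sphere of radius 6371 km, which makes the metric
invariant under rigid rotations of the sphere (verified to 1e-6 relative).
The atlas-provided rotational speed is used as-is; whether it should be a
contour mean or maximum is a property of the upstream product.

**Eddy age** is counted at the day of acoustic sampling (0 on the
detection day).

## Acoustic preparation

Profiles are NASC (m² nmi⁻²) on 73 half-open 10-m bins covering
[20, 750) m plus the closing bin; values are attributed to bin centers
(25, 35, …, 745 m). Raw profiles are linearly interpolated onto the
centers after discarding samples outside [20, 750] m; bins outside raw
coverage stay missing (no extrapolation). Hull-mounted transducers cannot
sample the top ~20 m (bubble contamination), so the "epipelagic" layer is
operationally 20–200 m.

**Solar geometry.** Day/night labels come from the apparent solar
elevation computed with the NOAA solar-calculator algorithm (geometric
mean solar longitude/anomaly and equation of center on Julian centuries,
then declination, equation of time and local hour angle). Accuracy against
an independent low-precision almanac ephemeris is ~0.01°, far inside the
0.5° contract; atmospheric refraction (~0.5° at the horizon) is ignored
because the twilight band is 18° wide and the thresholds are astronomical
conventions. Timestamps must be timezone-aware UTC; naive (possibly local)
times are rejected, not guessed.

**Filters.** Elevation > 0° is day, < −18° night, and the inclusive band
[−18°, 0°] twilight; twilight profiles are removed per-profile (not per
transect segment). Profiles with seabed strictly shallower than 1000 m are
removed (a seabed at exactly 1000 m is retained); unknown seabed depths
are retained with a flag — silently dropping them would empty synthetic
fixtures without bathymetry — and `--drop-unknown-seabed` inverts that.

## Collocation

Attribution uses the same-day atlas record only (no temporal interpolation
of contours). The nearest eddy by great-circle center distance is searched
within twice the largest radius present that day; exact ties break to the
smaller eddy id so runs are reproducible. Inside/outside is decided
against the effective contour with boundary points counting as inside;
polygons are tested in a local tangent plane about the eddy center after
unwrapping longitudes, so dateline-crossing contours work. A profile lying
inside *some* eddy's contour is attributed to that containing eddy even
when another center is nearer.

**Zones.** Along the ray from center through the point, with D the
center-to-contour distance and d = D − r the inward distance from the
contour: the outer 30% of the effective span (outside the speed contour)
is the effective border; the outer 30% of the speed span is the speed
border; the innermost 30% of the speed span is the core (the convention
mirrors the 30% border rule, since "core" has no standard definition); the
rest is the intern. Precedence core > speed border > effective border >
intern resolves overlapping bands in thin eddies. For circles this reduces
to radius fractions; the ray construction generalizes it to irregular
contours.

**Control ribbon.** Outside points within twice the effective radius of
the center (the radius of the collocation day, not a lifetime mean) form
the control. A contamination guard excludes control points lying inside a
neighboring eddy's contour — otherwise a neighbor's signal leaks into the
"outside" reference; `--no-control-guard` disables it for sensitivity
checks. An eddy is retained only with ≥ 2 distinct inside zones sampled
and ≥ 1 control profile ("two sampled regions" is read as two distinct
inside zones), and additionally needs at least one day/night period
sampled on both sides, else no coherent comparison exists.

## Anomalies

Per eddy, the per-bin anomaly is (mean inside − mean outside)/mean
outside, computed separately for day and night and only for periods
present on both sides; bins with outside mean ≤ 0 or missing data are
flagged missing. When both periods exist the final anomaly is the
unweighted mean of the two period anomalies (the combination rule is a
package choice; matching is structural — a mixed-period pair never enters
the formula). Layer anomalies apply the same formula to unweighted layer
means of the period mean profiles; a custom (a, b) layer supports checks
such as 450–600 m. Surface (SST, chlorophyll) anomalies use the same
relative form on along-track samples, with an additive option (°C) for
SST because surface temperature effects are conventionally reported in
degrees; a relative SST anomaly with an outside mean ≤ 0 raises rather
than returning sign-flipped values.

Across eddies, each eddy contributes one anomaly (equal weights, not
profile counts), aggregated per polarity as mean, sample sd (n−1), n and
the 95% normal half-width 1.96·sd/√n (flagged absent at n = 1).

## Classification

Per eddy and variable (epipelagic NASC, mesopelagic NASC, SST,
chlorophyll), the per-profile inside values are compared with the control
values by a two-sided rank-sum test; p < α with the inside stochastically
larger is an increase, smaller a decrease, else null (α = 0.05). A single
two-sided test with a sign read-out is used rather than two one-sided
tests. No multiple-testing correction is applied across eddies — each eddy
is an independent question, so ~5% of truly unaffected eddies are expected
non-null by construction; the type-I calibration below confirms it.

**Numerics.** Ties get midranks. While C(n+m, n) ≤ 60,000 the null
distribution is enumerated exhaustively (vectorized; ≤ 20 ms at the
cutoff) and the two-sided p is twice the smaller one-sided tail, clipped
at 1 — the R/scipy convention; with ties the permutation distribution is
not symmetric, so the symmetric-tail definition would differ. Beyond the
cutoff a normal approximation with tie correction and continuity
correction is used; the cutoff was placed where the two branches agree to
|Δp| ≤ 0.01 at the first approximated sizes. Two identical constant
samples give p = 1 by convention. When both day and night are sampled on
both sides, per-period rank sums are combined van-Elteren style (stratum
weights 1/(nₛ+mₛ+1), normal reference); a pooled switch ignores periods
for sensitivity analysis.

Effect groups (increasing / decreasing vs null, AE and CE pooled, on the
epipelagic NASC outcome) are compared on the six characteristics with the
same two-sided rank-sum test, reporting quartiles and 1.5·IQR whiskers.

## Synthetic ocean

The generator emulates the three real inputs with known ground truth.

* **Eddies**: circular 64-vertex contours (speed radius = 0.7 × effective
  radius), placed so control ribbons never overlap (bounded retries, then
  a domain-too-small error), drifting linearly at 3 km/day along a random
  bearing; no merging or splitting. Amplitudes, radii and lifespans are
  drawn uniformly from ranges inside the envelope of the sampled real-eddy
  population (amplitude [0.004, 0.698] m, area [2464, 107984] km²,
  lifespan [14, 1000] d); defaults are amplitude 0.02–0.4 m, effective
  radius 40–100 km, lifespan 60–365 d. Rotational speed follows the
  geostrophic scaling U = gA/(f·R_spd) with the Coriolis latitude floored
  at 5° and U capped at 2 m/s — any monotone rule would serve; this one is
  physically interpretable.
* **Backscatter column**: epipelagic Gaussian (60 ± 40 m) plus a deep
  scattering layer Gaussian (500 ± 80 m), shapes normalized to unit sum
  then scaled to 500 and 1500 NASC units — magnitudes representative of
  38 kHz echo integration. At night half the DSL mass migrates into the
  epipelagic shape, conserving the column integral exactly (the basis of
  the mass-conservation test). Inside an effect eddy every bin is
  multiplied by the configured factor (default 1.5 on 30% of eddies).
* **Noise**: one lognormal factor per profile multiplying the whole
  column, parameterized so the multiplicative median is 1 and the CV is
  `noise_cv` (default 0.3); the mean is then √(1+cv²), which the
  Monte-Carlo calibration test corrects for explicitly. Per-profile (not
  per-bin) noise is what drives the between-profile variance the rank
  tests see.
* **Surface fields**: constant backgrounds (18 °C, 0.15 mg m⁻³) with
  polarity-signed signatures inside *every* eddy — AE +0.3 °C and
  chlorophyll ÷1.18, CE −0.3 °C and ×1.18 — reflecting that surface
  signatures are near-universal even where forage-fauna effects are rare;
  Gaussian SST noise (sd 0.2 °C) and lognormal chlorophyll noise (CV 0.2).
* **Survey**: great-circle legs crossing each eddy through its center,
  entering/exiting at 2.2 effective radii; the planner predicts arrival
  days from ship speed (default 18.5 km/h ≈ 10 kn) and aims at the drifted
  center. Profile spacing defaults to 1 km.

All randomness flows from the single config seed through named substreams;
identical configs give byte-identical outputs (CSV readers use
round-trip float parsing so fixtures survive serialization exactly).

**What the generator does not emulate** — and hence what passing tests do
not show about real data: irregular and evolving contour shapes, eddy
merging/splitting, chlorophyll stirring filaments and other
non-eddy-centric surface structure, spatial autocorrelation of backscatter
along the track (profiles are exchangeable given the eddy), multi-frequency
acoustics, bathymetry, and any dynamical ocean. The calibration results
(type-I ≈ 5%, full recovery of ×1.5 effects at 30 profiles/side) are
therefore statements about the pipeline's correctness, not about the
detectability of effects in real surveys, where along-track correlation
inflates the effective type-I rate of profile-level tests.

## Problem sizes and runtime choices

The statistical calibrations run at 500 null eddies (type-I) and 300
eddies with 30% effect carriers (recovery), 30 profiles per side, through
the per-eddy sampling model directly — full ship-track geometry adds
nothing to those experiments. The geometric end-to-end path runs at 4–12
eddies with ~5,000–14,000 profiles. The geometry oracle uses 10,000 random
point/polygon pairs (40% dateline-crossing), the ephemeris check 100
random time/position pairs over 2001–2021, and the rank-sum oracle 200
tied cases at n, m ≤ 7 plus 50 cases at the approximation crossover.

## Known limitations

* Zone geometry assumes star-shaped contours (every boundary point visible
  from the center along its ray); strongly non-convex real contours could
  yield multiple ray crossings, of which the outermost is used.
* The equirectangular tangent-plane projection is adequate at eddy scale
  but would distort polar contours (|lat| ≳ 75°).
* The van-Elteren combination is asymptotic; eddies whose both-period
  strata are tiny (< ~5 per side) get an approximate p where a single
  stratum would have been exact.
* SST relative anomalies depend on the temperature scale origin (°C);
  the additive form is the interpretable one and both are reported.
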