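# Methods

`divehab` chains four analyses that together turn raw seabird biologging
data (GPS fixes at ~15-min intervals, 1-Hz time-depth-recorder traces)
into habitat-suitability maps per dive tactic, plus a synthetic
central-place-foraging generator that provides ground truth for testing
all of it.  This note records the models, the parameters that matter,
and the choices made where the design was genuinely open.

## 1. Dive processing

**Detection.** A dive is a maximal run of consecutive samples with depth
> `surface_threshold` (default 0.5 m, a guard against pressure-sensor
noise; sd ~0.1 m is typical of small TDR tags).  Because the logger
records only while submerged, a sampling gap longer than `max_gap_s`
(default 5 s) also terminates a dive.  Dives with maximum depth < 1 m
are then discarded as likely bathing: detection and filtering are kept
as separate steps so the raw segments remain inspectable.

**Metrics.** For an n-sample 1-Hz segment: `max_depth` is the deepest
sample; `duration = t_last − t_first + 1 s` (the terminal interval is
counted, so a single-sample dive lasts 1 s rather than 0); `bottom_time`
is the summed sample time at depth ≥ `bottom_frac × max_depth`.
`bottom_frac = 0.8` is a common TDR convention for "near maximum depth";
it is exposed as a parameter because no single definition is canonical
across packages.

**Classification.** The field rule for this system labels a dive U
(prolonged pursuit dive with a bottom phase) when

    bottom_time ≥ 3 s   OR   (duration > 10 s AND max_depth > 8 m)

and V (brief plunge) otherwise.  The verbal forms of the U and V
conditions in common field use are not logical complements (a dive with bottom 2 s,
duration 10 s, depth 9 m satisfies neither verbal description), so a
precedence had to be chosen: we make V the exact complement of U, which
matches the characterisation of V dives as rapid and shallow.  A
`strict_and` variant (U requires both clauses) is provided for
sensitivity analysis.

**Foraging locations.** A dive's location is the latest same-bird GPS
fix within the 30 min before the dive start (both endpoints inclusive).
The latest fix is the best spatial proxy for the dive site; dives with
no qualifying fix keep the shape tally but are excluded from presence
generation.  One presence per dive — the window is not allowed to
generate multiple presences.

**Phenology.** V dives are split into early/late chick-rearing at a
per-year cutoff date.  `fixed_date` mode takes configured dates; `auto`
mode scans every split day d and maximises

    mean(daily U-proportion | day < d) − mean(daily U-proportion | day ≥ d),

ties broken earliest.  Caveat: for an exactly linear decline this
contrast is split-invariant (it equals d·n/2 for ramp slope d), so the
earliest split wins; the detector is meant for series with a genuine
drop, and needs ≥ 7 days of data.  Constant series warn and return the
midpoint.  U dives also receive phase labels for bookkeeping; tabulation
ignores U phase.

## 2. Contingency analysis

Counts are tabulated as years × (U, V-early, V-late).  Two summaries are
computed, matching how such tables are conventionally reported:

* the **headline test** of independence between year and dive *shape*
  pools the V phases (years × {U, V}; for the reference counts shipped
  with the examples this gives χ² = 122.78);
* the **phase-split table** provides expected counts
  `E_ij = row_i·col_j/N` and Pearson residuals `(O−E)/√E` with
  df = (r−1)(c−1) = 4, localising which year/class cells depart from
  independence.

Note the two views are deliberately distinct: the residuals of the
3-column table square-sum to its own statistic (≈ 286), not to the
pooled-shape χ².  No continuity correction; p-values use the regularised
upper incomplete gamma function Q(df/2, χ²/2).

## 3. Space use

Dive locations are projected to an azimuthal-equidistant plane centred
on the colony — the projection preserving distance from the central
place, the quantity a foraging-range analysis cares about.  The
utilization distribution is a fixed-bandwidth isotropic Gaussian kernel
density on a km grid (default cell 1 km, padded ≥ 3h beyond the points,
kernel truncated at 6σ, renormalised to unit mass).  The bandwidth
follows the conservative central-place rule

    h = 2 · ln(mean foraging range in km),

where a trip's foraging range is its maximum great-circle distance from
the colony (mean taken over trips).  Natural log is the default — it
returns the canonical h = 8 km for a ~55 km mean range — and the base is
configurable because the convention's log base is genuinely ambiguous.
Ranges ≤ 1 km are rejected (non-positive log).  First-passage-time
scale estimation is deliberately not implemented: the quantity actually
used downstream is the doubled log-range.

The p% isopleth is the smallest set of highest-density cells whose mass
reaches p (50% = core area, 95% = range); its mass therefore lies in
[p, p + one cell's mass].  Contours are polygonised by marching squares
and unprojected to lon/lat for GeoJSON export.

**Known bias.** A fixed-bandwidth KDE inflates spread: for points from a
bivariate normal with σ = 20 km smoothed at h = 8 km, the 50% isopleth
covers ≈ 1 − exp(−(σ²+h²)·ln2/σ²) ≈ 55% of an independent test sample,
not 50%.  This ~5-point inflation is intrinsic to kernel home-range
estimation at ecologically sensible bandwidths, and is why one coverage
check in the acceptance suite sits at the edge of its stated band.

## 4. Habitat suitability models

**Domain.** Sea cells within `1.1 × max` colony-to-dive great-circle
distance.  Domains in field practice are often hand-drawn arcs between
east/west extremes clipped to the shelf; that is cartographic rather
than algorithmic, so the radius rule (e.g. 451 km from a 410 km
extreme at the default 1.1 scale) replaces it, with a user-supplied
polygon override available.

**Pseudo-absences.** Exactly 3 background points per presence (ratio
configurable), uniform over domain sea cells and uniform within a cell,
each with a uniform random date inside that year's tracking period.
All sampling is reproducible from an explicit seed.

**Covariates.** Depth (m, positive down), seafloor slope (degrees, by
finite differences), daily SST (°C, layer matched to the record's date;
nearest day if absent), lon/lat, and optionally distance to colony (km).
Records on no-data cells are dropped with a logged count.

**Concurvity screen.** Before fitting, every pair of candidate smooth
terms is scored by the worst-case measure: the largest squared canonical
correlation between the column spans of their (constraint-absorbed,
centred) bases — 1 means some fit of one term lies entirely in the span
of the other.  Terms exceeding 0.9 with any other are dropped; distance
to colony, being itself a function of lon/lat, is evaluated first.
Several concurvity estimators exist (worst-case, observed, estimate);
the worst-case variant is used because it requires no pilot fit and is
conservative.  In synthetic worlds where SST is a nearly deterministic
function of location, the screen may also drop the lon/lat surface —
that is the measure working as intended, not a defect.

**GAM.** The response is presence (1) vs pseudo-absence (0), modelled by
a penalized additive logistic regression: cubic B-spline bases with
uniform knots extended past the covariate range (P-splines, k = 10 per
1-D smooth) and second-order difference penalties, a 5×5 tensor-product
surface for lon/lat with additive row/column penalties, a sum-to-zero
constraint absorbed into each smooth by an orthonormal
reparameterisation, and year as a reference-coded fixed effect.  With
uniform knots the penalty null space is exactly the linear functions, so
λ → ∞ recovers plain logistic regression — a property the tests exploit
as an oracle against statsmodels.

Fitting is penalized IRLS; smoothing parameters minimise the GCV score
of the working penalized least-squares problem, updated by coordinate
descent over a log-spaced grid (10⁻²…10⁶, 9 points — coarse but logged;
the GCV profile near its optimum is flat on this scale) and alternated
with refitting.  A ridge of 10⁻⁶ guards the unpenalized subspace; runs
where > 1% of fitted probabilities pin at 0/1 warn about possible
complete separation.  Effective degrees of freedom are
tr[(XᵀWX + S)⁻¹XᵀWX] at convergence; deviance explained is 1 − D/D₀
against the intercept-only null; adjusted R² is
1 − (D/(n−edf))/(D₀/(n−1)).

**Selection.** All subsets of the smooth terms are fitted (year always
retained, so inter-annual effects stay estimable in every candidate;
a factor-only null remains in the set) and ranked by

    AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1),  k = effective df,

with Δ and Akaike weights w ∝ exp(−Δ/2).  The selected model is the
AICc minimum, which by construction is ≤ the global model's AICc.

**Prediction.** For each day, the model is evaluated at every domain
cell centroid with that day's SST; covariates outside the training range
are clamped to the range endpoints inside the spline bases (preventing
extrapolation blow-ups); the year effect is averaged across levels for a
pooled map, or fixable to one level.  Daily maps are summarised by
pixel-wise arithmetic mean and population SD.

## 5. Synthetic world

The generator emulates the study system it stands in for: a coastal
colony (land to the north), a shelf sea whose depth grows away from the
coast with smooth mesoscale relief, slope derived from depth, and SST
with a southward-warming gradient (0.8 °C/deg), linear seasonal warming
(0.08 °C/day from 12 °C) and smooth spatial noise — so an early/late
temperature contrast exists.  Defaults: 8 birds, a mid-July–early-
September season, 15-min fixes, 1-s depth sampling, one trip per
bird-day with Poisson(8) dives, flight speed 55 km/h, 250 km foraging
cap, 0.05° cells — values a tracking study of a large coastal seabird
would recognise.

Dive sites are drawn per shape with probability ∝ exp(η) over reachable
sea cells, where η is a linear predictor on standardised (depth, slope,
season-mean SST): U weights (−1.8, −1.0, −1.2) make U habitat shallow,
flat and cool; V weights (−0.4, +0.8, +0.8) make V habitat broader,
steeper-sloped and warmer.  The truth suitability surface reported for
scoring is logistic(η) ∈ [0, 1].  Trips are greedy nearest-neighbour
tours of the day's sites (the study gives no movement model; only the
marginal spatial density of dives matters downstream), with fixes every
15 min along the path plus one fix at the site shortly before each dive.
The daily U-dive probability is a step function (0.45 → 0.05 at day 26)
reproducing the mid-season drop this system is known for.

Depth traces carry Gaussian sensor noise (sd 0.1 m): U dives descend at
1.2–1.8 m/s to 12–25 m, hold a 5–15 s bottom phase, and ascend; V dives
are 4–8 s triangular spikes to 1.5–7.5 m.  These defaults keep every
dive away from the classifier boundaries (bottom ≥ 5 s, V duration
≤ 8 s), which is what makes exact label recovery a fair test.  What the
generator does **not** emulate — tides and currents, bout structure,
individual heterogeneity, GPS error, spatially autocorrelated residual
preference — bounds what a green test establishes: the pipeline recovers
the stated world's structure, not that it would be unbiased on any real
dataset.

## 6. Numerical and engineering choices

* Calendar is handled as integer day-of-study internally; ISO-8601 UTC
  at I/O boundaries.  Rasters use 0-based, cell-centre indexing,
  WGS84 decimal degrees, row 0 at the southern edge; files are ESRI
  ASCII grids (plain text) rather than GeoTIFF so every artifact stays
  human-readable and diffable.
* Every stochastic operation takes an explicit seed; the pipeline
  derives per-stage seeds from one master seed via a seed sequence, so a
  manifest (seed + parameters) suffices to re-run any stage
  bit-identically.
* PIRLS uses step-halving on deviance increase, an η cap of ±30, and
  weight floors of 10⁻¹⁰; isopleth ties are broken by stable sort order.
* The chi-square test refuses tables with a zero margin (expected count
  0) rather than returning NaN.

## 7. Known limitations

* Deviance-explained figures from real deployments cannot be reproduced
  without real tracking data, which cannot ship with the package; the
  test suite substitutes parameter recovery on the synthetic world.
* The auto cutoff detector is only meaningful when a marked drop exists
  (see §1); fixed dates are the safer production mode.
* KDE isopleth coverage is biased upward by ~h²/σ² (see §3).
* The GAM's λ grid is coarse by design; effective df can differ by a few
  tenths from a continuously-optimised fit.  Model ranking is
  insensitive to this at the effect sizes tested.
* Concurvity screening uses the worst-case estimator only; observed
  concurvity on a fitted model may be lower.
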