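# Methods

## Polar cluster analysis

Each retained hour of an hourly air-quality table is mapped to a point
(x, y, c): x = r sin θ, y = r cos θ with θ the wind direction
(meteorological convention, direction the wind blows FROM, drawn with
north at +y and east at +x) and r a radial variable, and c the analyzed
pollutant concentration. The radial variable is wind speed by default;
for sites where a ubiquitous low-wind source must be separated from
directional sources the radius is temperature shifted by the series
minimum (r = T − min T ≥ 0), keeping wind direction as the angle. The
clustering outcome is invariant to the fixed rotation/reflection implied
by the drawing convention; the choice only affects reporting.

All three coordinates are standardized to sample mean 0 and sample sd 1
(ddof = 1) before clustering, because wind components (m/s or °C) and
concentrations (µg/m³) are on incommensurate scales. Standardization is
idempotent and stores the inverse transform, which the geometry
diagnostics use to reason about the physical origin.

k-means uses Lloyd iterations to an assignment fixed point (cap 300),
initialized by sampling k distinct data points from the run seed, with
ties in nearest-centroid assignment broken toward the lowest cluster
index and an emptied cluster reseeded with the globally farthest point.
The best of `n_restarts` (default 20) runs by inertia is kept. When the
number of distinct k-subsets of points is small (≤ max(64, n_restarts)),
every distinct point-seeding is tried instead of sampling, so on tiny
inputs the best-of-restarts solution is exhaustive over seeded starts —
this is what makes the solver match exhaustive partition enumeration on
enumerable fixtures. Clusters are relabeled 1..k by decreasing mean
concentration so outputs are invariant to restart order.

The k sweep fits each k in a user-chosen range, warm-starting each k from
the previous solution's centroids plus the farthest point; combined with
Lloyd's monotone descent this forces inertia to be nonincreasing in k
(asserted). The sweep reports inertia, adjusted-Rand agreement between
consecutive assignments, and central-cluster emergence; **k is never
auto-selected** — choosing it is the analyst's decision, informed by this
evidence.

Cluster contributions follow the additive convention: contribution of
cluster k at hour t equals the observed concentration if hour t is
assigned to k, else zero. Period means are taken over *all* retained
hours of the period (zeros included), so cluster means sum exactly to the
period-mean concentration — the property the comparison tables rely on.
This convention is recorded in output metadata. SE of a period mean is
sd/√n over the period's retained hours; hours are treated as
exchangeable and autocorrelation is ignored, a documented limitation
(hourly PM series are positively autocorrelated, so these SEs are
somewhat optimistic).

## Identification rules

Each cluster is summarized by computable diagnostics: 24-hour diurnal
profile and its top hours; weekend/weekday ratio; ratio of the 4 coldest
to the 4 warmest calendar months (months ranked by the input's own
temperature climatology, making the rule hemisphere-agnostic); lower and
upper limiting edge lines of the PM2.5-vs-PM10 scatter, estimated as the
0.05/0.95 empirical quantiles of the per-hour ratio over pairs with
PM10 ≥ 5 µg/m³ (ratio quantiles rather than regressions through the
origin: simpler, monotone in the data, robust to outliers); OLS slope,
Pearson correlation and r² of the contribution on wind speed,
temperature and relative humidity; sector coverage at low radius and an
origin-in-convex-hull test (computed in the raw polar plane, where the
origin is physically meaningful); each gas's mass share by cluster and
the within-cluster NO2/NOx ratio; and the fraction of the cluster's
contribution falling below a calm-wind cut (default 4 m/s).

Labels are assigned by scoring archetype clause lists — every clause a
named, thresholded predicate collected in one overridable `RuleConfig`:

- **rwb**: fine-dominated *single-source band* (upper edge ≥ 0.7 **and**
  lower edge ≥ 0.5 — both edges high, because traffic's exhaust end
  member also reaches an upper edge near 1:1 and only the narrow
  straight-line band separates wood smoke from it); cold/warm ratio ≥ 2;
  hull encloses the origin; negative temperature slope; diurnal peak in
  {22..1}.
- **traffic**: weekend ratio ≤ 0.85; morning *and* evening rush-window
  maxima within 75 % of the global diurnal maximum, which itself falls in
  a rush window; negative wind-speed slope; lower edge ≤ 0.3 (road-dust
  end member).
- **industrial**: positive wind-speed slope (fumigation); confined sector
  (coverage ≤ 0.25); the largest SO2 share of all clusters; steady
  weekends (ratio in [0.85, 1.15]).
- **aeolian**: contribution share below the calm cut ≤ 0.05; positive
  wind-speed slope; coarse-dominated edges (upper ≤ 0.5, lower ≤ 0.25).
- **regional**: confined sector; steady weekends; SO2 share at least the
  uniform share; NO2/NOx at least 1.25× the across-cluster median (aged
  air).

Scores are unweighted clause counts; the label is the argmax with ties
resolved by a fixed priority (rwb, traffic, aeolian, industrial,
regional), falling back to `unidentified` below a floor of 2 fired
clauses. Only the 0.7 wood-smoke fine-fraction cut is anchored in
receptor-model practice; every other threshold is a declared
implementation default, visible and overridable, and the emitted
rationale lists every fired clause. The relative-humidity response of
wood smoke is reported as a sign only and excluded from scoring — no
magnitude for it is established.

## Receptor models

**CMB (effective variance).** Per sample, contributions solve weighted
least squares with per-species weights 1/V_eff,j,
V_eff,j = σ_j² + Σ_k g_k² σ_fkj², iterated because the weights depend on
the current estimate; convergence when the largest relative change in g
is < 1e-6 (cap 100 iterations). With zero profile uncertainty this is a
single weighted solve. Contributions are unconstrained in sign (classic
CMB); negatives are counted and warned about. SEs come from the weighted
normal-equations covariance. Rank-deficient profile matrices are
rejected naming the collinear sources. Missing species values are not
supported in CMB.

**PMF (uncertainty-weighted NNMF).** Q = Σ ((X − GF)/σ)² is minimized by
alternating exact non-negative least squares over the rows of G and the
columns of F, which cannot increase Q — an increase beyond round-off is
treated as an internal error. Restarts (default 5) from seeded random
non-negative initials; best Q kept; outer loop stops when the Q decrease
falls below 1e-8 relative (cap 500). The factorization is
scale-ambiguous, so after convergence each profile row is normalized to
sum 1 with the scale moved into G, and factors are ordered by decreasing
mean contribution. Missing X entries are down-weighted via σ = 10⁶.
PMF standard errors are out of scope and reported as unavailable;
rotational diagnostics (Fpeak, bootstrap, displacement) are not
implemented. Tests resolve the permutation ambiguity by best-correlation
matching of factors to truth before comparing.

Degrees of freedom are reported as n·m − p·(n+m); a correctly specified
fit has Q/dof near 1.

## Comparison and fusion

Clusters sharing a label are summed into per-source hourly series
(additivity preserved exactly). For campaign comparisons the CA series
is averaged over only the campaign's scheduled days (e.g. the same five
days per week), so CA and RM estimates cover identical air. Comparison
tables carry mean ± SE per (source, method), a footer of arithmetic
column averages with SEs combined in quadrature divided by the period
count, and a per-row agreement flag |CA − RM| ≤ 2·√(SE_CA² + SE_RM²).
Printed-precision checks round half away from zero, matching how such
tables are typeset.

## Synthetic scenarios

The generator emulates the statistical signatures the rules key on — not
dispersion physics. Calendar: naive local hourly time starting Monday
2018-01-01, no DST, so weekday logic is unambiguous. Temperature is
seasonal + diurnal sinusoids (minimum centered on the configured coldest
month; diurnal maximum at 14:00) plus Gaussian noise; wind is a mixture
of regimes (wrapped-normal direction, Rayleigh-like speed) gated by hour
and month windows; RH is a diurnal sinusoid anti-phased with
temperature, clipped to [0, 100].

Source archetypes (PM10 driver → PM2.5 via an emitted fine/coarse ratio,
gases via per-source mass ratios):

- traffic: base × diurnal profile × weekend factor ÷ (1 + 0.3·ws)
  ventilation;
- rwb: (base + sensitivity × max(0, 15 °C − T)) heating-degree driver ×
  near-midnight diurnal profile, emitted at all directions and amplified
  (1 + 0.5·e^(−ws)) under calm winds, so the generated cluster encloses
  the polar origin;
- aeolian: base × max(0, ws − 5 m/s)²;
- industrial: nonzero only for winds from the stack sector at ≥ the
  activation speed, growing linearly with wind speed;
- regional: steady, weekday-invariant, SO2-bearing with elevated
  NO2/NOx.

The per-hour fine/coarse ratio is jittered uniformly within
`fine_coarse_spread` of the archetype ratio. For traffic (0.5 ± 0.4) this
reproduces the two-end-member mixing signature — an upper edge near 1:1
(exhaust) and a lower edge near 0.1 (road dust) — that a single scalar
ratio cannot produce; for wood smoke (0.82 ± 0.06) it yields the narrow
single-source band.

Observation noise is multiplicative and lognormal-like: exp(σz − σ²/2)
with z truncated at ±4 sd and σ = √log(1+cv²), giving unit mean and the
stated coefficient of variation on a positive scale (no noise model is
established for these monitors; this is the package's choice). Default
cv 0.1, typical of continuous PM monitors. PM2.5 > PM10 after noise is
repaired by clipping PM2.5 down, with clip events logged.

Two reference scenarios fix the study conditions. The *wood-smoke city*
(temperate, coldest month July, seasonal amplitude 8 °C) combines one
traffic archetype arriving under two directional wind regimes with a
wood-smoke archetype (sensitivity 3 µg/m³ per heating degree); analyzed
as PM2.5 with the temperature radial at k = 3 it produces a central
high-concentration RWB cluster and two directional traffic clusters, with
winter PM2.5 means near 40 µg/m³. The *desert city* combines a strong
traffic/road-dust archetype under three calm directional regimes with an
aeolian archetype fed by two strong-wind regimes (year-round afternoon
W-NW winds and a cold-season NNW regime); analyzed as PM10 with the
wind-speed radial at k = 5. Magnitudes were chosen once to reproduce the
qualitative orderings of the corresponding field situations (no
quantitative emission magnitudes are established for these source types);
the end-to-end tests then ask whether clustering plus rules recover the
construction.

What the generator does **not** emulate — chemistry, plume rise,
long-range transport dynamics, autocorrelated measurement drift,
instrument-specific artifacts (e.g. volatilization losses in heated-inlet
monitors) — bounds what passing tests show: they validate the statistical
machinery and its internal consistency, not performance on any real
monitoring record.

## Numerical choices and edge cases

- Seeds: every stochastic stage takes an explicit seed; the pipeline
  derives stage seeds from one run seed by fixed offsets. Identical
  inputs and seed give bit-identical outputs.
- Outlier screening caps (concentrations ≥ 0, PM10 ≤ 2000 µg/m³,
  PM2.5 ≤ 1000, ws ≤ 60 m/s, RH ∈ [0,100], T ∈ [−40, 55] °C) set cells
  missing rather than deleting rows; the spike rule (> 10× the 24-h
  rolling median) only flags. No criteria are established for this
  screening; the defaults are declared, configurable and logged.
- Calm winds keep their reported direction; near-origin points are
  treated identically by k-means regardless of angle.
- Edge-line and met-dependence diagnostics require ≥ 30 usable pairs,
  otherwise they are reported unavailable and simply fail their clauses.
- Clusters with < 3 points skip the hull test (flagged); degenerate
  (collinear) clusters likewise.
- Zero-variance standardization inputs and uncovered scenario hours are
  errors naming the offender, not silent repairs.

## Problem sizes used

Reference runs use 730-day (2-year) scenarios at ~17,520 hours, k = 3 or
5, 10 pipeline restarts; speciation campaigns use 8 weekly samples of
5×24 hours; receptor benchmarks use 50–60 samples of 4–8 species. These
sizes keep the full suite and the acceptance script fast while leaving
every estimate comfortably inside its tolerance.

## Known limitations

- The additive contribution convention attributes *all* of an hour's
  concentration to its cluster's source; hours with genuinely mixed
  sources bias cluster means toward the dominant source. The synthetic
  recovery tests quantify this (CA traffic means run ~20 % above truth
  when wood smoke is present in traffic hours).
- SEs ignore autocorrelation (above).
- The rule engine is a transparent scorer, not a probabilistic
  classifier; ambiguous clusters tie and resolve by priority, and the
  scores/rationale should be inspected rather than trusted blindly.
- Units pass through unchanged; no ppm/ppb ↔ µg/m³ conversion.
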