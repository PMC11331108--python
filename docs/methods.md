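# Methods

This note documents the statistical procedure, the simulators, the default
parameters and the numerical choices in `rangelaw`, and what the synthetic
validation does and does not establish about real data.

## Exceedance curves

For a set of per-taxon values v₁…vₙ (durations in My, or maximum range
sizes in km or km²) the exceedance curve evaluates
p(t) = #{vᵢ > t}/n at every unique observed value t. The strict
inequality matters: taxa known from a single locality have duration and
range exactly zero by construction, and with strict counting they produce a
leading row at threshold 0 whose proportion is the fraction of non-singleton
taxa. Singletons therefore stay in the denominator — they are real taxa and
are needed to estimate the surviving/expanding fraction — without ever
contributing a positive threshold.

Before fitting, the first and last rows are discarded: the first because the
zero threshold is a singleton artifact, the last because its proportion is
exactly 0 (and log 0 is undefined). After trimming, proportions lie
strictly in (0, 1) and thresholds are strictly positive, so every transform
is well defined. A curve is *sufficient* for classification only if at
least `min_points` (default 10) rows remain; insufficient curves are
reported as a dash, never force-fitted.

## The best-transform test

Linear decay is straight in the plain plot, exponential decay in the
semilog plot, power-law decay in the log–log plot. The test projects the
trimmed curve into each candidate coordinate system, fits a straight line
by OLS, and selects the transform with the highest R². This is a *relative*
comparison by design: the curve's points are cumulative and therefore not
independent, which inflates every R² equally but leaves the ranking
meaningful. No nonlinear least squares is run on the untransformed models —
the procedure is linear OLS after transformation, and the classification is
to the nearest of the three basic types only (no intermediate types).

For duration curves there are three candidates. For range curves, plain and
semilog are fitted separately on the width axis (x = w) and the area axis
(x = w²), while log–log collapses the two (log w² = 2·log w is an affine
change of x, under which R² is exactly invariant), giving five candidates:
`Pln`, `Pln2`, `LAW`, `LAW2`, `Pow`.

Numerical choices:

- Logs are base 10 (readability; the base provably does not affect R²).
- Ties in R² within 1e−9 break toward semilog, then plain, then log–log —
  i.e. toward the memoryless null — and within a coordinate system toward
  the width axis. The rule is explicit and configurable in code because no
  principled ordering exists at exact ties.
- A zero-variance response is assigned R² = 0 (no explanatory power) rather
  than the indeterminate 0/0; zero variance in x is an error.
- A best R² below 0.9 flags the label as statistically weak, rendered in
  parentheses.

Survival-probability algebra of the fitted forms: exponential decay gives
P(survive t→t+1) = e^(−λ), independent of t; linear decay gives
1 − c/(N₀ − ct), which falls with t (aging); power decay gives
((t+1)/t)^(−k), which rises with t (rich get richer). The same reading
applies to expansion with range size in place of age.

## Occurrence preprocessing

- Identification filter: indeterminate (`indet.`) and unnamed (`sp.`,
  `gen.`) records are discarded at the analysis level; uncertain but named
  identifications (`cf.`, `aff.`) are retained. The token sets are a
  configurable dialect because exports vary. The rule is applied at the
  genus qualifier for genus-level analyses and at both genus and species
  qualifiers for species-level analyses (a species identity includes its
  genus).
- Age-span filter (fossil only): localities whose age range exceeds 3 My
  are dropped — coarser dating indicates time averaging or uncertainty.
  The bound is inclusive (a span of exactly 3 My is kept), reading "does
  not exceed" literally. Rows without ages cannot be vetted and are
  dropped by this filter (logged).
- Aquatic exclusion (present-day): order Sirenia plus the pinniped
  families Otariidae, Phocidae and Odobenidae — Pinnipedia is a clade, not
  an order, so it is expressed as a configurable family list.
- Rows with missing coordinates are kept for duration analysis and skipped
  by range estimators (logged), rather than dropped wholesale.
- Analyses run per order, the operational approximation of an adaptive
  zone; genus-level and species-level runs are fully independent.

## Duration and range estimation

Duration = max − min of locality age-range midpoints, in My; real-valued,
no time binning. Range = rectangular bounding box on the extreme latitudes
and longitudes, with 1° ≈ 111 km in both directions (square-pixel
approximation; an optional cos(mean latitude) correction of the
longitudinal extent is available, and a convex-hull estimator is provided
as a supplementary variant). Width = √area. Longitudes are used as-is —
ranges straddling ±180° would be mis-measured, a known limitation inherited
deliberately (no terrestrial mammal record spans the antimeridian).
Present-day ranges use hexagon-grid cell centers under the same bounding
box, with a secondary estimator of hexagon count × 1,643 km² per cell.

## Preservation simulator

World defaults: one species per 2,000 y over 12 My (6,000 species);
durations ~ Exp(3.33 My); peak ranges ~ Exp(694 km²); triangular range
trajectory (zero at origination and extinction, peak at mid-duration);
population density 10 individuals/km² with individual lifespan 14 y and
immediate replacement — an adaptive zone of ~75 kg herbivores. Deaths per
year per species = area(t) × density / lifespan, and each death fossilizes
with a fixed probability.

Implementation: rather than iterating ~2×10¹⁰ species-years, fossilization
is drawn exactly as an inhomogeneous Poisson process — a Poisson count with
the analytic mean (probability × density/lifespan × ∫area dt, where the
triangular integral is peak × duration/2) and event times from the
triangular density. This is the exact continuous-time limit of per-death
Bernoulli thinning at the tiny probabilities involved, at a fraction of the
cost. Species alive at the end of the window are censored there: their
sampling window is truncated, their true duration retained.

Observed duration = last − first fossil occurrence, zero for species with a
single event — exactly how singletons behave in real occurrence data. At
the printed world parameters the expected yield is ~0.006 fossils per
species at probability 1e−11, so validation runs that need hundreds of
sampled species use probabilities around 1e−8–1e−9; the probability is a
free parameter precisely because realistic record sizes require tuning it
to the world size simulated.

## Expansion simulator

One species originates per step; each grows one unit per step until a
decline onset and then shrinks one unit per step to extinction. The decline
onset is memoryless by default — a constant per-step hazard (default 0.02),
the reading of "decline starts at a random point" consistent with
Red-Queen-style competition — so peak sizes are Geometric(0.02) with mean
50 units; a uniform-onset alternative with the same mean sits behind a
flag. Defaults n_steps = 20,000 with snapshot at n/2 give a stationary
standing assemblage (~100 species alive, ~2/hazard) and peak-range curves of
~300 distinct thresholds.

Case A interprets the units as km of width, Case B as km² of area; the R²
grid fits Type I/II/III on both the width and the area axis for peak and
for snapshot ranges. Curves are assembled in each case's native unit so
that, under a shared seed, Case A's width-axis rows and Case B's area-axis
rows are bit-identical — the same draw reinterpreted. Because geometric
peaks have exponential exceedance in their native unit, Case A is expected
to win on semilog-width and Case B on semilog-area; snapshot sizes inherit
the memorylessness (the standing-size exceedance of a geometric/triangular
process is again geometric) but with ~100 species the fits are visibly
weaker — which is the point of the comparison: one-time observational data
still identify the growth mode.

## Synthetic occurrence generator

The generator emulates the fossil export and hexagon-grid dialects with
known ground truth. Defaults mirror the preservation world: exponential
durations (mean 3.33 My) and exponential peak widths (mean √694 ≈ 26.3 km);
1 + Poisson(4) localities per species; locality dating spans uniform on
[0, 2] My (inside the 3 My screen); an Old-World-sized region. Present-day
tables default to exponential widths of mean 400–500 km, the scale of
extant mammal ranges. Heavy-tailed (Pareto) variants generate power-law
ground truth for discrimination tests.

Two placement choices make recovery exact rather than approximate: locality
ages are centered on true occurrence times with symmetric spans, so
age-range midpoints estimate the true times without bias (matching the
pipeline's midpoint rule); and the first two localities sit at opposite
corners of a square of the species' true width, so the bounding box
recovers the width exactly. Identification noise marks a configurable
fraction of rows `indet.` (removed by filtering) or `cf.` (retained).

What the generator does *not* emulate — and hence what passing tests do not
establish about real data: spatial autocorrelation of localities, realistic
phylogenies or taxonomy (one species per genus), dating error that is
asymmetric or correlated with age, discontinuous ranges, and preservation
that varies in space or time. The synthetic validation shows the inference
machinery recovers known ground truth through the full I/O chain; it cannot
certify the ground truth of any real fossil record.

## Problem sizes

Validation runs use 2,000–5,000 species for curve recovery (semilog slope
of an exponential-duration curve converges within ~3% of −1/(μ ln 10) at
n = 5,000), the full 6,000-species world for preservation runs, and 20,000
steps for expansion runs — sizes at which every stochastic check is stable
across seeds while the whole suite stays fast.

## Known limitations

- No antimeridian unwrapping; no paleocoordinate rotation (present-day
  coordinates only).
- R² comparison only; no information-criterion or likelihood-based model
  selection, matching the transform-comparison design.
- Estimating preservation rate from fitted intercepts is out of scope,
  though the simulator exposes the monotone intercept–rate relationship.
- The ten-genus worked example is reproduced for the duration protocol
  only; its printed range variant is internally inconsistent (nine listed
  genera against ten-step proportions) and is not used as an oracle.
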