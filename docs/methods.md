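# Methods

## Kinetic model

Each quality index *I* is modelled as pseudo zero-order in storage time
*t* (days): *I*(*t*) = *I*₀ + *k*·*t*, with *k* in index units per day.
Zero-order behaviour is an empirical description, not a mechanistic
claim — lipid oxidation is a radical-chain process whose indices can
rise, saturate or stay flat depending on oxygen availability; in sealed
bottles with little headspace the primary oxidation indices (peroxide
value, K232) typically do not move at all, while secondary indices
(K270, conjugated trienes, hexanal) and the pigment marker
pyropheophytin a rise approximately linearly until substrate or pigment
pools deplete.

**Increasing-segment selection.** Only the rising part of a trajectory
carries rate information; %PPP in particular saturates at a plateau at
high temperature. The retained segment is the prefix of at least
`min_points` observations whose OLS line has positive slope and maximal
R², ties broken toward the longest prefix; if no prefix rises, the full
series is fitted and the non-positive slope reported unchanged. This
rule is a pragmatic choice: with small noise a marginally shorter rising
prefix can out-score the full rising segment by chance, so tests check
exact agreement with an exhaustive prefix search plus the location of
the typical (median) cut, not a per-realization cut position.

**Estimation.** *k*, its standard error, R² and a two-sided slope test
(*t* distribution, *n* − 2 df) come from closed-form OLS. Replicate
determinations at the same sampling day enter as separate observations
by default (`average_replicates=True` collapses them to means first —
this changes degrees of freedom, not the point estimate when replicate
counts are balanced). `min_points` defaults to 4: three points fit a
line but leave one residual degree of freedom; four is the minimum that
supports any goodness-of-fit reading on short series.

**Diagnostics.** An index is *responsive* when its slope at the highest
tested temperature is positive with *p* < α (α = 0.05); the label is
advisory and never blocks fitting. A *lag-phase* flag fires when the
first observation lies more than two RMS residuals below the fitted
line and dropping it improves R² — i.e. when the linear regime's
back-extrapolation overshoots the initial observation. Note the flag is
deliberately conservative: a long flat start followed by a rise (a
convex trajectory) leaves the first point *above* the overall OLS line
and is handled by segment logic and visual inspection, not this flag.
The flag never modifies the estimate.

## Temperature dependence

Rates follow the Arrhenius law *k* = *k*₀·exp(−*E*ₐ/*RT*), fitted in the
reparametrized form

ln *k* = ln *k*_ref − (*E*ₐ/*R*)(1/*T* − 1/*T*_ref)

with the reference temperature chosen mid-range so that (ln *k*_ref,
*E*ₐ) are nearly uncorrelated. Defaults: *T*_ref = 318.15 K (45 °C,
centre of a 25–60 °C design) and *R* = 8.31 J K⁻¹ mol⁻¹, configurable
to 8.314. Both choices affect only how *E*ₐ and *k*₀ are reported:
refitting at a different *T*_ref changes *k*_ref but leaves *E*ₐ, *k*₀
and every rate prediction identical (a tested invariance), and *R*
cancels out of rate and shelf-life predictions entirely.

Two routes:

* **two-step** (default): per-temperature rate constants first, then
  closed-form OLS of ln *k* on (1/*T* − 1/*T*_ref). It is exactly
  reproducible, needs only the per-temperature rates (often the only
  published artifact), and on the reference K270/CT/hexanal rate tables
  matches the published activation energies within 1%. A nonlinear
  variant (`fit_space="nonlinear"`) refits *k* itself in data space,
  initialized from the log-linear solution, for when absolute rather
  than relative rate errors are homoscedastic.
* **one-step**: a single Levenberg–Marquardt least-squares fit of all
  raw observations across temperatures, value(*t*, *T*) = *I*₀,T +
  *k*_ref·exp(−(*E*ₐ/*R*)(1/*T* − 1/*T*_ref))·*t*, with shared
  (*E*ₐ, *k*_ref) and free per-temperature intercepts (optionally one
  shared intercept). Initialized from the two-step solution; relative
  tolerances 1e-10, at most 10 000 evaluations; non-convergence raises
  with the last iterate attached. It weights information optimally when
  raw data are available but is sensitive to pre-truncation of
  plateaued segments, which the kinetics module performs first.

The pre-exponential factor is recovered as *k*₀ = exp(ln *k*_ref +
*E*ₐ/(*RT*_ref)) and satisfies *k*(T) = *k*₀·exp(−*E*ₐ/*RT*)
identically. The covariance of (ln *k*_ref, *E*ₐ) comes from the OLS
(or Gauss–Newton J'J) sandwich and propagates to predictions by the
delta method.

Two-step Ea estimates treat the four rate constants as equally precise;
weighting by the published per-rate standard errors was considered and
rejected as the published tables do not state the per-temperature
degrees of freedom needed to calibrate the weights.

## Shelf-life

SL(*T*) = (*I*_lim − *I*₀)/*k*(*T*) for an index rising from *I*₀
toward an upper acceptability limit *I*_lim. Whole-day values use
**floor** (the conservative rounding: the limit is certainly not
exceeded at the reported day count); the real-valued SL is always kept
alongside. A non-positive predicted rate raises a non-degrading error —
shelf-life is unbounded and deliberately never reported as a number.

Built-in limits: K270 0.22 (EU Reg. 2568/91, initial 0.15 for the
reference oil), PV 20 meq O₂/kg, K232 2.50, %PPP 17% (Australian
standard; no published initial value, so *I*₀ falls back to the fitted
intercept at the coldest temperature).

Confidence intervals on SL: delta method on ln SL (se(ln SL) =
se(ln *k*(T)), default) or a seeded parametric bootstrap over
(ln *k*_ref, *E*ₐ) (1000 draws by default).

**Shelf-life plot.** ln SL regressed on storage temperature in °C —
the field's customary extrapolation chart — with an Arrhenius-consistent
1/*T*(K) variant behind `on_inverse_T=True`. On the °C axis an exact
Arrhenius SL curve is slightly convex, so plot-based extrapolation to
20 °C sits a few percent below the direct Arrhenius prediction
(≈523 vs ≈564 days for the reference K270 model); the 1/*T* variant
reproduces the Arrhenius prediction exactly. The acceleration factor
*k*(test)/*k*(market) equals SL(market)/SL(test) for any shared limit
and is transitive across temperatures (tested to machine precision).

## Synthetic studies

The generator emulates a 60-bottle accelerated design: four storage
temperatures (25/40/50/60 °C), 15 sampling occasions within 300 days,
two determinations per occasion. Each observation is

clamp(*I*₀ + *k*(*T*)·max(0, *t* − lag), plateau) + ε,  ε ~ N(0, σ²)

with *k*(*T*) Arrhenius-generated per index (zero for non-responsive
indices). Defaults carry the published activation energies and initial
values; *k*_ref is backed out of the published per-temperature rates.
Quantities never published are fixed once at realistic magnitudes:
initial values CT 0.10 mg/kg, hexanal 0.50 mg/kg, %PPP 1.0% (fresh oil
carries at most trace pyropheophytin), %PPP plateau 26%; noise SDs are
calibrated so that OLS slope standard errors under the default design
match the published ones (σ ≈ se_k·√Sxx): K270 0.005 AU, CT 0.005
mg/kg, hexanal 0.18 mg/kg, %PPP 1.0%. Flat-index SDs (PV 0.2, K232
0.02, phenols 8, tocopherols 5) only exercise the responsiveness test.

**Sampling schedule.** Published bottle counts fix 15 occasions per
temperature but not the dates. The default schedule (0, 1, 2, 4, 7, 14,
21, 35, 50, 75, 100, 150, 200, 250, 300 days) is dense early, as is
customary in stability testing: at 60 °C %PPP reaches its plateau
within days, so only early sampling observes its rising phase at all,
while slow indices keep full 300-day leverage. An evenly spaced
schedule would leave a single pre-plateau %PPP point at 60 °C and make
its rate unidentifiable.

What the generator does **not** emulate: heteroscedastic or correlated
measurement error, between-bottle variability, oxygen-depletion
curvature, antioxidant-consumption coupling, or day-to-day analytical
drift. Passing recovery tests therefore show the estimators are correct
under the stated noise model at the stated design — not that real
trajectories are this clean.

Determinism: one `numpy` generator seeded from the config drives all
draws in a fixed iteration order (index, then temperature), so the same
config and seed reproduce every series bit for bit.

## Numerical choices and degenerate inputs

* OLS everywhere in closed form (normal equations / `lstsq`); R² is
  defined as 1 for an exact fit (including zero-variance response) and
  0 for a zero-variance response with residuals.
* All-identical sampling times raise a degenerate-design error; fewer
  than `min_points` observations raise a precondition error naming the
  series.
* °C → K conversion is +273.15 everywhere.
* Zero-residual fits report se = 0 and p = 0 (nonzero slope) or 1
  (zero slope); the lag flag returns false on zero-RMSE fits.
* CSV round-trips are bit-exact: floats are written as `repr` and
  re-parsed with numpy's correctly rounded parser.

## Problem sizes in tests

Monte-Carlo checks use 200 synthetic studies for two-step Ea recovery
(median within 5% of each generating value), 40 for the one-step fit,
500 null series for the slope-test size, and 10⁴ draws for the
noise-SD law-of-large-numbers check — sizes at which the checked
statistics are stable to well inside the asserted tolerances.

## Known limitations

* Ea values are descriptive of temperature sensitivity in 25–60 °C;
  they carry no mechanistic meaning for a complex radical-chain process
  and should not be extrapolated far outside the tested range.
* The two-step and one-step routes agree on clean data but can differ
  when plateau truncation removes unequal shares of the design across
  temperatures; the package reports which route produced a model.
* The %PPP shelf-life depends on an initial value that real studies
  often do not report; the intercept fallback is clearly labelled in
  the limit's provenance field.
* The pre-exponential factor *k*₀ spans many orders of magnitude and is
  numerically delicate — it is exp of an extrapolation to 1/*T* = 0;
  comparisons between studies are only meaningful in identical units.
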