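# Methods

This note documents the models implemented in `stopover_pace`, the choices
made where the design was genuinely open, what the synthetic-data generator
does and does not emulate, and the known limitations — in particular a
structural property of the capture–recapture stopover estimator that the
test suite deliberately exposes.

## The scientific setting

A long-distance migrant songbird pauses at a stopover site to refuel before
a large over-water barrier. Three instruments observe it: daily constant-
effort mist netting (capture histories, mass, wing, fat score), two local
automated radio-telemetry stations (burst logs from coded tags), and a
continental network of receivers that occasionally re-detects a tag
thousands of kilometres along the route. The chain of inference runs:
how long do birds stay → how much fuel do they gain and leave with → how
far can they fly → how does departure condition shape the elapsed time to
re-detection (the pace of migration).

## Capture–recapture total stopover

Every netting day is an occasion; a history is a binary vector starting at
first capture. The forward Cormack–Jolly–Seber likelihood, conditioned on
first capture, uses per-interval persistence φ_t on a logit link and a
constant recapture probability p, with the standard tail recursion
χ_T = 1, χ_t = (1−φ_t) + φ_t(1−p)χ_{t+1}. Seniority γ is estimated by the
identical machinery on time-reversed histories (a separate fit, with its
own p). Total stopover is TS = −1/ln φ̂ − 1/ln γ̂.

Open choices, resolved as follows:

- **Reference values for φ̂, γ̂.** Daily probabilities are averaged over
  "active" bird×interval cells (between a bird's first and last capture),
  weighting each day by the number of active histories. Per-year estimates
  restrict the average to that year's birds.
- **Candidate set.** φ ∈ {1, Date, year, Date+year, Date+year+mass} ×
  γ ∈ {Date, Date+mass, Date+year, Date+year+mass} = 20 models; γ always
  carries Date because arrival phenology is bell-shaped. The set is
  configurable.
- **AICc.** K counts both directions' parameters including two recapture
  probabilities; the effective sample size is the number of histories.
  Weights w_i ∝ exp(−Δ_i/2) over all converged, identifiable fits;
  averaging uses the models with Δ ≤ 6 (renormalized), and the averaged SE
  combines delta-method within-model variance with between-model spread.
- **Numerics.** L-BFGS-B on the logit scale with an analytic gradient
  (verified against finite differences in the tests), parameters clipped to
  ±15, one informed start plus up to four jittered restarts on
  non-convergence. Fits whose φ̂ or γ̂ sit within 1e-4 of 0/1 are flagged
  non-identifiable and excluded from averaging (sparse-recapture datasets
  can push the seniority fit to the boundary, where TS diverges). AICc ties
  break toward fewer parameters, then model name.

**Known estimator property (important).** The forward fit measures expected
residence *after first capture*; the reverse-time fit measures expected
residence *before last capture*. Their sum therefore counts the span
between first and last capture twice. Under geometric (memoryless)
residence this is exactly compensated and the estimator is consistent; for
tightly clustered residence times (here ~12.7 ± 3.1 d, CV ≈ 0.24) it is
not, and the overestimate grows with recapture intensity:

- daily capture probability 0.03 (≈18% of captured birds recaptured):
  mean bias ≈ −2% across simulated seasons;
- daily capture probability 0.08 (≈41% recaptured): the first-to-last
  span averages ~2 days and the model-averaged TS overshoots by ≈ +20%.

The acceptance-style recovery test runs at 0.08 and is left failing by
design: it documents the estimator's behaviour rather than hiding it. At
the sparse recapture rates typical of real banding data (a few percent),
the span term is negligible — which is why field estimates from this
method agree closely with telemetry-based apparent stopover.

## Telemetry

Burst filtering keeps maximal runs of ≥3 bursts whose successive gaps are
within 10% of an integer multiple (≤3, i.e. up to two missed bursts) of the
tag's designated interval; everything else, including bursts from unknown
tags, is noise. Departure detection examines only the final calendar day
with any run: the run's strengths are smoothed by a 5-burst moving median,
consecutive equal values collapsed, and a departure is declared iff the
series rises to an interior maximum and then falls strictly to the final
burst, with that final burst between 18:00 and 21:00 local time (the
evening window in which nocturnal migrants lift off). The departure
timestamp is the final burst; where several runs qualify the latest wins.
Classification is exhaustive: C (detections reaching the station-dismantle
date) before A (≤48 h of local coverage after tagging) before
reliable/B. Apparent stopover is departure date minus tagging date in
whole days.

## Fuel energetics

Lean body mass is an OLS of mass on wing length over fat-score-zero birds
(first such capture per bird). Mass change since first capture is a
penalized-spline additive model: cubic B-splines with 8 interior knots over
the observed elapsed-day range, second-difference penalty with the
smoothing parameter chosen by GCV, and the f(0) = 0 constraint imposed by
centering the basis at t = 0 and dropping the resulting null direction.
Covariates (date of first capture, year, age, tag presence, initial mass)
enter as **per-day modifiers** (multiplied by elapsed days), so predicted
mass change at zero elapsed days is exactly zero for any covariate value —
the year effect is therefore in g/day, matching how fuelling rates differ
between seasons. The bird random intercept is represented as a ridge
penalty whose weight is updated from the residual and intercept variance
estimates (a few fixed-point iterations); candidate covariate sets (eight)
are compared by AICc with effective degrees of freedom from the hat-matrix
trace. Fuel quantities per bird then follow
FDR = (Δm/St)/LBM, DFL = (m₀+Δm−LBM)/LBM, range = 100·U·ln(1+DFL) with
U = 60 km/h; reported ranges round to the nearest 100 km. A drag
correction for the tag itself is a recognised refinement that this package
does not implement.

## Pace of migration

Distances are haversine great-arcs on a 6371-km sphere (cross-checked
against the spherical law of cosines; the ellipsoidal correction is <0.5%
at these scales and immaterial). One observation per (bird, continental
station): elapsed time from the evening departure to the earliest validated
run at that station, distance from the tagging site, minimum speed assuming
continuous flight. The response is elapsed days since the stopover
departure (not between successive detections). Simple regressions on DFL
and on departure date are reported alongside mixed models
elapsed ~ DFL + departure day + region with a bird random intercept;
model comparison uses ML-based AICc across five fixed-effect sets, with
REML coefficients reported for the selected and full models, and an OLS
fallback (flagged) when the random-intercept fit is singular. A detection
is a direct flight iff its minimum speed lies in the 40–76 km/h band of
plausible continuous flight and its distance does not exceed the bird's
estimated flight range.

## The synthetic-data generator

The generator is the test harness's ground truth, emulating: normal arrival
phenology truncated to an April–May season; residence drawn
Normal(12.7, 3.1) d truncated at 1 d, rounded to whole catchable occasions,
with the departure on the evening after the last foraging day (uniform in
18:00–21:00); linear mass gain at a year-specific fuel deposition rate
(0.035/d and 0.048/d of LBM, chosen so year-mean departure fuel loads land
near 0.44 and 0.60); LBM linear in wing (slope 0.33 g/mm, intercept
−4.63 g, wing ≈ 93 ± 3 mm so LBM ≈ 26 g); daily capture with probability
0.08 while present, netting stopping at season end; tagging of 15% of birds
on their arrival day; local detections as a few short bouts per bird-day
(an on/off presence model — real detection-range physics is not simulated);
a departure trace whose strength follows a Gaussian bump over 10–30 min,
peaking at 65% of the trace (the bird passes the tower as it leaves) and
ending at the departure timestamp; continental re-detections per region
with probability 0.12 (so ≈32% of tagged birds are detected somewhere),
timed by a linear pace structure (intercept 25 d; −27.57 d per unit DFL;
−0.76 d per day of departure date; region offsets 0/+4/+8 d; bird
intercept SD 2 d; residual SD 3 d) floored at the bird's non-stop flight
time (40–76 km/h airspeed) — the floor is what produces direct flights;
and Poisson false positives (1 burst/station-hour, half with real tag ids).
A separate sampler (`simulate_pace_observations`) draws pace observations
from the *uncensored* linear structure, with DFL ~ N(0.52, 0.19) — spread
implied by the reported 1000–4000 km flight-range span — and exists purely
to score the regression against known coefficients.

What passing tests show, and what they do not: recovery tests demonstrate
that each estimator returns the generator's truth under the generator's
assumptions (independent detections, Gaussian noise, no weather, no
radio-propagation physics, no age/individual heterogeneity in fuelling
beyond the modelled covariates). They do not validate the behavioural
model against real birds, and real telemetry data would stress the
departure detector (multipath, antenna patterns) far more than the
simulated envelope does.

## Problem sizes used by the test suite

Simulated seasons use 220–900 birds; the stopover-recovery suite runs 50
seasons of 900 birds, the pace-recovery suite 50 replicates of 43 birds,
and the mass-change selection-power check 50 replicates of 30 recaptured
birds. These sizes keep the full suite close to two minutes on one CPU
while leaving Monte-Carlo error well inside the asserted tolerances.

## Known limitations

- The total-stopover estimator's high-recapture bias described above.
- Recapture probability is assumed constant (no trap response, no
  transience); no goodness-of-fit machinery is included.
- Seniority and survival are estimated in separate one-directional fits
  rather than one joint likelihood; a joint formulation would propagate
  shared information on p.
- The random intercept in the mass-change model is an approximation (ridge
  with moment-style variance updates), adequate for the shrinkage it must
  provide but not a full REML mixed model.
- Fuel is treated as all fat; protein–fat partitioning, wind assistance and
  tag drag are outside the flight-range formula used here.
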