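# Methods

## The problem

Wind-pollinated weeds can export herbicide-resistance alleles to nearby
susceptible populations through pollen. The system modelled here is a
concentric (Nelder-wheel) field trial: a circular block of
glyphosate-resistant pollen donors in the centre, rings of susceptible
receptor stations at fixed distances (0.1–35 m on all eight compass arms,
plus 50 m on the ordinal arms) measured from the donor block's *edge*.
Seed harvested per station is screened with a discriminating glyphosate
dose; survivors carry the dominant resistance marker, so each
(year, direction, distance) cell yields a binomial count — plants screened
`n` and resistant survivors `y` — and the gene-flow frequency is `y / n`.

## The dispersal kernel

The frequency `p` at distance `d` is modelled on the log-odds scale as

```
logit(p) = β₀ + exp(β₁ + γ₁·d) + exp(β₂(dir:year) + γ₂(dir:year)·d)
```

with `logit(p) = ln(p / (1−p))` and its stable inverse for
back-transformation. The structure encodes three biological features:

* `inv_logit(β₀)` is the *background* frequency far from the source (with
  β₀ = −3.50 that is ≈ 0.029, matching the observed 0.03–0.04 at 50 m);
* the first exponential is a fast near-source decay (γ₁ strongly
  negative) producing the sharp peak of a leptokurtic profile;
* the second exponential decays slowly (|γ₂| small) and carries the factor
  structure — its intercept and decay rate take treatment-coded offsets by
  direction, year, and direction×year relative to East / year 1 — giving
  the fat directional tail.

Candidate models vary the number of exponential terms (0, 1, 2), the
factor coding on the codable term (none, year, direction, additive, full
interaction), and optionally one scalar wind covariate (per-sector speed,
frequency, or wind run) on the term intercept in place of direction
factors (the two are collinear by construction). The full grid is a
deterministic enumeration of 24 specifications; the published roster of 43
is not recoverable from the study text, and the count itself is
meaningless — what matters is that the grid spans the hypotheses (distance
only, direction, year, wind) and contains the selected specification.

## Estimation

Cell counts are binomial, so the model is fitted by direct maximum
likelihood (the cell-level binomial likelihood is equivalent to per-plant
Bernoulli rows). The log-likelihood includes the binomial normalising
constant, so −2LL + 2K is comparable across every candidate. Gradients
are analytic; optimisation is multi-start L-BFGS-B (a heuristic start —
background log-odds from the pooled far-field frequency, the near-field
excess split across the exponential terms, decay rates at −1 and −0.05 —
plus seeded random perturbations; 8 starts by default for single fits, 4
per spec during grid selection, where the heuristic start converges
reliably on well-identified data).

Numerical choices:

* Exponential-term arguments are clipped at 50 during optimisation:
  `exp(50)` on the log-odds scale is already p = 1 to machine precision,
  and the clip keeps gradient products finite while the optimizer
  explores. The public likelihood evaluator refuses arguments above 700
  (naming the offending cell) rather than clipping.
* *Decay constraint.* By default the reference-level decay rates (γ₁ and
  the γ₂ reference entry) are box-bounded ≤ 0 — this is a decay model, and
  sparse data can otherwise invert signs. Treatment offsets stay free:
  the published fit itself implies a *positive* combined decay rate for
  one direction-year level (NE in year 1), so constraining every combined
  rate would contradict the reference coefficients. Box bounds were
  chosen over a log-reparameterisation because they keep the natural
  parameter scale, which the covariance and Wald machinery need.
* *Label switching.* With no factor coding the two exponential terms are
  exchangeable; fits are canonicalised post hoc so |γ₁| ≥ |γ₂| (the first
  term is the fast one). Factor-coded fits are not exchangeable and are
  left alone.
* *Covariance.* The observed information is obtained by central finite
  differences of the analytic gradient (step 1e-5 relative) and inverted;
  a rank-deficient information leaves the fit usable but flags the
  covariance unavailable. Standard errors are Wald (z = estimate/SE),
  an assumption the coefficient table inherits.
* Convergence requires an optimizer success flag; non-convergence after
  all starts raises with the full per-start trace, never silently.

Goodness of fit is the grouped-binomial Pearson statistic
`Σ nᵢ(yᵢ−μ̂ᵢ)²/(μ̂ᵢ(nᵢ−μ̂ᵢ))` with μ̂ᵢ the fitted count and df = cells −
K − 1; degenerate cells (fitted count 0 or n) are excluded with a warning
and reduce the df. Dispersion (χ²/df) is reported, not modelled.

## Model selection

Candidates are ranked by AIC = −2LL + 2K; ties break by smaller K, then
name. Each spec receives a child seed derived from the root seed and the
spec's position in name-sorted order, so the ranking is invariant to input
order. Inestimable specs (e.g. year coding on one-year data) are skipped
with a recorded reason.

## Reduction distances (O50 / O90)

O50 and O90 are the distances where the predicted frequency falls to 50%
and 10% of its value at a *reference* distance — a multiplicative
reduction, with the reference taken as the closest analysed distance
(0.5 m in year 1, whose 0.1 m cell was under-powered and excluded; 0.1 m
in year 2). Both the reference distance and the reduction scale are
arguments, since the study states neither precisely. The root of
`p(d) = (1−reduction)·p(ref)` is found by geometric bracket expansion and
Brent's method (tolerance 1e-6 m), verified in the tests against a 1e-4 m
grid search. A target below the far-field asymptote `inv_logit(β₀)` — or
an arm whose combined decay rate is positive — is reported as explicitly
*unattainable*, mirroring how reductions beyond the measured 50 m range
were flagged rather than extrapolated.

Confidence intervals use a parametric bootstrap: coefficient vectors drawn
from MVN(estimate, covariance), the 2.5/97.5 percentiles of the per-draw
distances (400 draws by default, seeded). The study says only that a
prediction function was used; the parametric bootstrap is this package's
reproducible choice. Unattainable draws are counted, and an interval with
more than half its draws unattainable is flagged unreliable.

The published O50/O90 values are *not* reproducible from the published
coefficients: with the slow decay rate printed to two decimals
(−0.03 ± 0.01) the derived distances are numerically unstable, so
reduction distances are validated by method (oracle and coverage
behaviour), not by value.

## Detection power and sample size

Screening `n` seedlings when the true frequency is `p` detects at least
one resistant survivor with probability `1 − (1−p)ⁿ`; the minimum sample
size for target power is `ceil(ln(1−power)/ln(1−p))` (e.g. 1,609 plants
for p = 0.001 at 0.8 power), cross-checked against a linear scan. The
study cites an external procedure without restating it; this
at-least-one-detection formulation is the package's clearly-labelled
choice, and the published per-row power column is therefore not a
reproduction target.

## Descriptive statistics

* *Frequencies by distance* pool counts over directions first (sum of
  survivors over sum screened) — the published per-distance frequencies
  match their printed count ratios under this convention — with
  mean-of-ratios behind a flag. The under-powered year-1 0.1 m cell is
  excluded by default (configurable).
* *Flowering synchrony* has two conventions in circulation, with inverted
  numerator/denominator roles: `receptor_over_donor` averages receptor-flowering over
  donor-shed percentages (a percentage, 100 = perfect) and `donor_over_receptor`
  averages donor-shed over receptor-flowering (a ratio, 1.0 = perfect).
  Both are implemented and named; per-station capping at full synchrony is
  a flag, since a receptor flowering at least as much as the donor sheds
  is fully synchronised.
* *Wind roses* bin hours into half-open 45° sectors centred on the eight
  compass points (a boundary azimuth belongs to the clockwise-next
  sector); per-sector frequency (%), mean speed, and wind run
  (speed × frequency fraction) divide by observed hours, tolerating logger
  gaps. Correlation of per-direction PMGF with a wind parameter is
  plain Pearson with a t-distribution p-value; the default arm-wind
  pairing is *downwind* (wind FROM the south carries pollen INTO the
  north arm) with the same-sector pairing available, since the study never
  states its pairing. Zero-variance inputs yield an explicit
  undefined-correlation flag.

## Synthetic data

The generator emulates the study's three data streams under one root seed
with per-stream child seeds (`SeedSequence([root, stream_id, ...])`), so
streams are independently reproducible.

* *Screening*: binomial draws per design cell with p from the kernel; the
  default truth is the published coefficient set, and the default per-cell
  effort splits the published per-distance screening marginals across the
  arms carrying each distance (thousands of plants at 50 m, where
  detection demands them). Per-direction effort is split uniformly, as
  the study publishes only distance marginals.
* *Weather*: hourly streams with sector-categorical wind (S/SE-dominated
  default weights), gamma-distributed speeds (shape 2, scale set by the
  per-year mean — 1.2 and 2.8 m/s; any non-negative unimodal marginal
  would do, gamma is the realistic choice), and a diurnal temperature
  cycle inside the observed 17–30 °C flowering band.
* *Flowering*: logistic progress curves at a 5-day cadence over six weeks;
  receptor flowering tracks the donor's pollen-shed curve scaled by a
  synchrony target, delayed 3–6 days at stations ≥ 10 m (sparser stands
  flower later), with donor receptivity preceding shed (protogyny).

What passing tests on this generator do *not* show: the screening
generator is exactly the model the fitting stage assumes, so parameter
recovery and selection consistency validate the estimation machinery, not
the model's adequacy for real pollen dispersal; the weather stream has no
serial correlation or gusts; and no atmospheric transport physics links
the wind stream to the screening counts (which is why the simulated
PMGF–wind correlations are null).

## Problem sizes used in checks

Parameter recovery simulates the full 152-cell two-year design at 5,000
plants per station and refits the selected spec (20 replicates in the test
suite; 10 in the acceptance script). Selection consistency fits the full
24-spec grid per replicate (10 replicates in the suite, 5 in the script).
These sizes give recovery and selection rates at or near 1.0 with
replicate-level Monte-Carlo noise well below the asserted thresholds.

## Known limitations

* The covariance is asymptotic; bootstrap CIs inherit it.
* Quasi-separation (cells with all survivors under a near-1 predicted
  frequency, which the published coefficient set produces for one
  direction-year level at far distances) inflates the affected offsets'
  standard errors; estimates remain finite because near cells anchor them.
* No over-dispersion modelling (pure binomial, as fitted in the study);
  dispersion is only reported.
* The wind covariate enters as a per-direction scalar modifier of the
  codable term's intercept — the most natural reading of including wind
  summaries — with other placements out of scope.
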