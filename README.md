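# pmgf — pollen-mediated gene flow modelling

Tools for quantifying how far wind-borne pollen carries a dominant
herbicide-resistance marker from a central donor block into surrounding
susceptible receptors, built around a two-year concentric (Nelder-wheel)
field trial on glyphosate-resistant giant ragweed: receptor stations on
eight compass arms at 0.1–35 m (plus 50 m on the ordinal arms), each
yielding a binomial count of screened vs. surviving seedlings.

For field ecologists and weed scientists who need the full chain:
descriptive gene-flow and flowering-synchrony statistics, wind-rose
summaries, a mechanistically-shaped dispersal kernel fitted by maximum
likelihood, AIC model selection, dispersal-distance quantiles with
bootstrap confidence intervals, and the binomial power analysis that sizes
a screening campaign — plus a synthetic-data generator so everything is
testable without the original raw data.

## The model

Gene-flow frequency *p* at distance *d* follows a double-exponential
binomial logit kernel,

```
logit(p) = β₀ + exp(β₁ + γ₁·d) + exp(β₂(dir:yr) + γ₂(dir:yr)·d)
```

where `inv_logit(β₀)` is the background frequency far from the source, the
first term is a fast near-source decay, and the second, slowly-decaying
term carries direction/year structure — together producing the sharp peak
and fat directional tail (leptokurtic profile) typical of wind
pollination. Candidate models (0/1/2 exponential terms × factor codings ×
wind covariates) are ranked by AIC = −2LL + 2K. From the selected fit,
O50/O90 — the distances where *p* drops to 50%/10% of its value at the
closest analysed distance — are solved by root finding with parametric
bootstrap CIs. Detection power for screening *n* plants at true frequency
*p* is `1 − (1−p)ⁿ`. See `docs/methods.md` for assumptions and numerical
choices.

## Worked example

```python
from pmgf import (GeneratorTruth, generate_screening, fit, WINNING_SPEC,
                  reduction_distance, min_sample_size, PowerSpec)

truth = GeneratorTruth(n_per_cell=5000, seed=1)      # bundled reference kernel
records = generate_screening(truth)                   # 152 binomial cells
result = fit(records, WINNING_SPEC, seed=1)
print(f"K={result.k} AIC={result.aic:.1f}")
print(f"beta0={result.coefficients['beta0']:.2f}")
o50 = reduction_distance(result.coefficients, "E", 2014, 0.5, 0.5)
print(f"O50 East/2014 = {o50:.1f} m")
print(min_sample_size(PowerSpec(true_frequency=0.001, power_target=0.8)))
```

prints

```
K=35 AIC=1336.6
beta0=-3.50
O50 East/2014 = 15.2 m
1609
```

i.e. the 35-parameter double-exponential direction-by-year model refitted
to a simulated season recovers the generating background log-odds (−3.50),
gene flow along the east arm halves by ~15 m, and detecting a 1-in-1000
gene-flow frequency with 80% power requires screening at least 1,609
seedlings.

The `analysis/` directory holds the same flow as numbered narrative
scripts (simulate → summarise → select/fit → dispersal metrics), each
writing tidy CSVs under `results/`. A `pmgf` command-line tool exposes
`simulate`, `summarize`, `fit`, `select`, `predict`, `power`, and `run`
(full pipeline from a YAML config, with a manifest recording seeds and
checksums).

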