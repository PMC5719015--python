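"""Derived dispersal quantities and detection-power analysis.

*Reduction distances*: O50 / O90 are the distances at which the modelled
gene-flow frequency drops to 50% / 10% of its value at a reference
(closest analysed) distance — a multiplicative reduction on the
probability scale.  They are found by bracketing + Brent root finding on
the fitted kernel; confidence intervals come from a parametric bootstrap of
the coefficient vector (multivariate normal on the estimate and its
observed-information covariance).  A reduction target that lies below the
kernel's far-field asymptote is reported as explicitly unattainable, never
as a number.

*Detection power*: screening n offspring when the true gene-flow frequency
is p detects at least one resistant plant with probability 1 - (1-p)^n;
the minimum sample size for a target power is the closed-form ceiling
ln(1 - power) / ln(1 - p).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .decay import DecayCoefficients, FitSummary, inv_logit, predict_frequency


class UnattainableReductionError(ValueError):
    """The requested reduction lies below the model's far-field asymptote."""


@dataclass(frozen=True)
class ReductionDistances:
    """O50/O90 (m) with confidence intervals for one direction and year."""

    direction: str
    year: int
    o50_m: float
    o90_m: float
    ci50: tuple[float, float] | None
    ci90: tuple[float, float] | None
    reference_distance_m: float


class ReductionCI(NamedTuple):
    lower: float
    upper: float
    n_unattainable: int
    n_boot: int
    reliable: bool


def reduction_distance(
    coefficients: DecayCoefficients,
    direction: str,
    year: int,
    reduction: float,
    reference_distance_m: float,
    *,
    xtol: float = 1e-6,
) -> float:
    """Distance at which predicted frequency falls by ``reduction``.

    Solves p(d) = (1 - reduction) * p(reference) for d >= reference by
    geometric bracket expansion and Brent's method (tolerance ``xtol`` m).
    Raises :class:`UnattainableReductionError` if the target is never
    reached (at or below the asymptote, or the kernel grows along this
    arm).
    """
    from scipy.optimize import brentq

    if not 0 < reduction < 1:
        raise ValueError("reduction must be in (0, 1)")
    if reference_distance_m < 0:
        raise ValueError("reference_distance_m must be >= 0")
    p_ref = predict_frequency(coefficients, reference_distance_m, direction, year)
    target = (1.0 - reduction) * p_ref
    asymptote = inv_logit(coefficients["beta0"])
    if target <= asymptote:
        raise UnattainableReductionError(
            f"target frequency {target:.4g} is at or below the far-field "
            f"asymptote {asymptote:.4g} for {direction}/{year}")

    def g(d: float) -> float:
        return predict_frequency(coefficients, d, direction, year) - target

    lo = float(reference_distance_m)
    hi = max(lo, 1.0)
    for _ in range(60):
        hi *= 2.0
        if g(hi) < 0:
            break
    else:
        raise UnattainableReductionError(
            f"predicted frequency never falls to {target:.4g} along "
            f"{direction}/{year} (non-decaying arm)")
    return float(brentq(g, lo, hi, xtol=xtol))


def reduction_ci(
    fit_result: FitSummary,
    direction: str,
    year: int,
    reduction: float,
    reference_distance_m: float,
    n_boot: int = 400,
    seed: int = 0,
) -> ReductionCI:
    """Parametric-bootstrap 95% CI for a reduction distance.

    Coefficient vectors are drawn from MVN(estimate, vcov); the 2.5/97.5
    percentiles of the per-draw distances form the interval.  Draws whose
    target is unattainable are counted; if they exceed half the draws the
    interval is flagged unreliable.
    """
    if n_boot < 200:
        raise ValueError("n_boot must be >= 200 for stable percentiles")
    coef = fit_result.coefficients
    if coef.vcov is None:
        raise ValueError("fit has no covariance matrix; CI unavailable")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xB007]))
    draws = rng.multivariate_normal(coef.values, coef.vcov, size=n_boot,
                                    method="svd")
    dists = []
    n_unatt = 0
    for row in draws:
        c = DecayCoefficients(
            spec=coef.spec, names=coef.names, values=row,
            ref_direction=coef.ref_direction,
            direction_levels=coef.direction_levels,
            year_levels=coef.year_levels, wind_lookup=coef.wind_lookup)
        try:
            dists.append(reduction_distance(c, direction, year, reduction,
                                            reference_distance_m))
        except UnattainableReductionError:
            n_unatt += 1
    reliable = n_unatt <= n_boot / 2
    if not dists:
        return ReductionCI(math.nan, math.nan, n_unatt, n_boot, False)
    lo, hi = np.percentile(dists, [2.5, 97.5])
    return ReductionCI(float(lo), float(hi), n_unatt, n_boot, reliable)


def reduction_table(
    fit_result: FitSummary,
    reference_distance_by_year: dict[int, float],
    *,
    n_boot: int = 400,
    seed: int = 0,
    with_ci: bool = True,
) -> pd.DataFrame:
    """O50/O90 (+CIs) for every direction-by-year level of a fit.

    Unattainable entries are reported as NaN with a note column, mirroring
    how reductions beyond the measured range were flagged in the field
    study rather than extrapolated to a number.
    """
    coef = fit_result.coefficients
    rows = []
    for year in coef.year_levels:
        ref = reference_distance_by_year[int(year)]
        for direction in coef.direction_levels:
            entry = {"direction": direction, "year": int(year),
                     "reference_distance_m": ref, "note": ""}
            for pct, red in (("o50", 0.5), ("o90", 0.9)):
                try:
                    entry[f"{pct}_m"] = reduction_distance(
                        coef, direction, year, red, ref)
                    if with_ci and coef.vcov is not None:
                        ci = reduction_ci(fit_result, direction, year, red,
                                          ref, n_boot=n_boot, seed=seed)
                        entry[f"{pct}_lo"], entry[f"{pct}_hi"] = ci.lower, ci.upper
                except UnattainableReductionError:
                    entry[f"{pct}_m"] = math.nan
                    entry["note"] = (entry["note"] + f" {pct} unattainable").strip()
            rows.append(entry)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# detection power

@dataclass(frozen=True)
class PowerSpec:
    """Settings for an at-least-one-detection binomial power analysis."""

    alpha: float = 0.05
    power_target: float = 0.8
    true_frequency: float = 0.001

    def __post_init__(self) -> None:
        for name, v in (("alpha", self.alpha), ("power_target", self.power_target),
                        ("true_frequency", self.true_frequency)):
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1), got {v}")


def detection_power(n: int, true_frequency: float) -> float:
    """P(detect >= 1 resistant plant among n) = 1 - (1-p)^n."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 < true_frequency < 1:
        raise ValueError("true_frequency must be in (0, 1)")
    return float(-math.expm1(n * math.log1p(-true_frequency)))


def min_sample_size(spec: PowerSpec, *, cap: int = 10 ** 9) -> int:
    """Smallest n with detection power >= target; closed form, scan-verified.

    n = ceil(ln(1 - power_target) / ln(1 - p)).  The closed form is nudged
    by the local scan to absorb floating-point edge cases.  Targets so
    strict that n would exceed ``cap`` raise instead of looping forever.
    """
    p, target = spec.true_frequency, spec.power_target
    n = math.ceil(math.log1p(-target) / math.log1p(-p))
    n = max(1, n)
    if n > cap:
        raise OverflowError(f"required sample size exceeds cap {cap}")
    while n > 1 and detection_power(n - 1, p) >= target:
        n -= 1
    while detection_power(n, p) < target:
        n += 1
        if n > cap:
            raise OverflowError(f"required sample size exceeds cap {cap}")
    return n


def sample_size_table(
    frequencies: Sequence[float],
    power_targets: Sequence[float] = (0.8, 0.9, 0.95),
) -> pd.DataFrame:
    """Minimum screening effort for theoretical gene-flow frequencies."""
    rows = [
        {"true_frequency": p, "power_target": t,
         "min_n": min_sample_size(PowerSpec(power_target=t, true_frequency=p))}
        for p in frequencies for t in power_targets
    ]
    return pd.DataFrame(rows)
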