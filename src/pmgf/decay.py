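"""Double-exponential-decay binomial logit model for pollen-mediated gene flow.

The gene-flow frequency ``p`` in a (year, direction, distance) cell is
modelled on the log-odds scale as the sum of an overall intercept and one or
two exponential-decay terms,

    logit(p) = beta0 + exp(beta1 + gamma1*d) + exp(b_dy + g_dy*d),

where ``d`` is distance (m) from the donor edge and ``b_dy``/``g_dy`` carry
the factor structure (direction, year, or their interaction) of the chosen
:class:`~pmgf.specs.ModelSpec`.  Far from the source both exponential terms
vanish (negative decay rates), so ``inv_logit(beta0)`` is the background
frequency; near the source the exponential terms lift the log-odds, giving
the sharp-peaked, fat-tailed (leptokurtic) profile typical of wind-borne
pollen.

Counts per cell are binomial, and the model is fitted by direct maximum
likelihood with analytic gradients, multi-start L-BFGS-B, and a
finite-difference observed-information covariance matrix.  The likelihood
includes the binomial normalising constant, so log-likelihoods and AICs are
comparable across all candidate specifications.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, gammaln

from .records import DIRECTIONS, ScreeningRecord, screening_frame
from .specs import ModelSpec, REF_DIRECTION, factor_design

log = logging.getLogger(__name__)

_EXP_CLIP = 700.0  # exp() overflow guard on the log-odds scale
# During optimisation the exp arguments are clipped far lower: exp(50) on the
# log-odds scale is already p = 1 to machine precision, and the tighter clip
# keeps gradient products finite while the optimizer explores.
_FIT_CLIP = 50.0


def logit(p):
    """Log-odds ln(p / (1-p)); domain (0, 1) strictly."""
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("logit requires 0 < p < 1")
    out = np.log(p) - np.log1p(-p)
    return float(out) if out.ndim == 0 else out

def inv_logit(eta):
    """Numerically stable inverse logit e^eta / (1 + e^eta)."""
    out = expit(np.asarray(eta, dtype=float))
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class DecayCoefficients:
    """A complete coefficient set (and optionally its covariance) for a spec.

    ``names`` orders the free parameters: ``beta0``; the scalar fast-term
    pair ``beta1``/``gamma1`` (double-exponential only); the coded term's
    intercept block then decay block (reference level first, then treatment
    offsets); finally the wind coefficient if present.  Offsets are relative
    to ``ref_direction`` and the first of ``year_levels``.
    """

    spec: ModelSpec
    names: tuple[str, ...]
    values: np.ndarray
    ref_direction: str = REF_DIRECTION
    direction_levels: tuple[str, ...] = DIRECTIONS
    year_levels: tuple[int, ...] = (2014, 2015)
    vcov: np.ndarray | None = None
    wind_lookup: Mapping[tuple[str, int], float] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if len(self.names) != self.values.size:
            raise ValueError("names and values length mismatch")
        if self.vcov is not None:
            v = np.asarray(self.vcov, dtype=float)
            if v.shape != (self.values.size, self.values.size):
                raise ValueError("vcov shape mismatch")
            object.__setattr__(self, "vcov", v)

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.names.index(name)])

    @property
    def k(self) -> int:
        return self.values.size

    @property
    def se(self) -> np.ndarray | None:
        if self.vcov is None:
            return None
        return np.sqrt(np.clip(np.diag(self.vcov), 0, None))

    def as_frame(self) -> pd.DataFrame:
        """Coefficient table: estimate, Wald SE, z, two-sided p.

        z and p assume asymptotic-normal (Wald) standard errors from the
        observed information.
        """
        from scipy.stats import norm

        df = pd.DataFrame({"coefficient": self.names,
                           "estimate": self.values})
        se = self.se
        if se is not None:
            with np.errstate(divide="ignore", invalid="ignore"):
                z = self.values / se
            df["std_error"] = se
            df["z_value"] = z
            df["p_value"] = 2 * norm.sf(np.abs(z))
        return df


@dataclass(frozen=True)
class FitSummary:
    """Result of one maximum-likelihood fit."""

    coefficients: DecayCoefficients
    loglik: float
    k: int
    converged: bool
    n_obs: int
    optimizer_trace: tuple[dict, ...] = ()

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.k

    @property
    def spec(self) -> ModelSpec:
        return self.coefficients.spec


@dataclass(frozen=True)
class GofResult:
    """Pearson chi-squared goodness of fit for grouped binomial data."""

    chisq: float
    df: int
    n_cells_used: int

    @property
    def dispersion(self) -> float:
        return self.chisq / self.df if self.df > 0 else float("nan")

    @property
    def valid(self) -> bool:
        return self.df >= 1


# ---------------------------------------------------------------------------
# model machinery

class _ModelData:
    """Design arrays and parameter layout for one spec on one dataset."""

    def __init__(
        self,
        spec: ModelSpec,
        df: pd.DataFrame,
        *,
        ref_direction: str = REF_DIRECTION,
        direction_levels: Sequence[str] | None = None,
        year_levels: Sequence[int] | None = None,
        wind_lookup: Mapping[tuple[str, int], float] | None = None,
        require_variation: bool = True,
    ) -> None:
        self.spec = spec
        self.dist = df["distance_m"].to_numpy(float)
        self.y = df["n_resistant"].to_numpy(float)
        self.n = df["n_screened"].to_numpy(float)
        dirs = df["direction"].tolist()
        years = df["year"].astype(int).tolist()
        self.ref_direction = ref_direction
        self.direction_levels = tuple(direction_levels) if direction_levels \
            else tuple(sorted(set(dirs)))
        self.year_levels = tuple(year_levels) if year_levels \
            else tuple(sorted(set(years)))

        prefix_b, prefix_g = ("beta2", "gamma2") if spec.n_exp_terms == 2 \
            else ("beta1", "gamma1")
        names: list[str] = ["beta0"]
        if spec.n_exp_terms == 2:
            names += ["beta1", "gamma1"]
        if spec.n_exp_terms >= 1:
            self.X_int, names_b = factor_design(
                dirs, years, spec.intercept_coding, prefix=prefix_b,
                ref_direction=ref_direction,
                direction_levels=self.direction_levels,
                year_levels=self.year_levels,
                require_variation=require_variation)
            self.X_dec, names_g = factor_design(
                dirs, years, spec.decay_coding, prefix=prefix_g,
                ref_direction=ref_direction,
                direction_levels=self.direction_levels,
                year_levels=self.year_levels,
                require_variation=require_variation)
            self.i_int = slice(len(names), len(names) + len(names_b))
            names += names_b
            self.i_dec = slice(len(names), len(names) + len(names_g))
            names += names_g
            if spec.wind_covariate is not None:
                if wind_lookup is None:
                    raise ValueError(
                        f"spec {spec.name!r} needs per-sector wind summaries")
                try:
                    self.wind_vals = np.array(
                        [wind_lookup[(d, y)] for d, y in zip(dirs, years)])
                except KeyError as exc:
                    raise ValueError(f"wind lookup missing sector/year {exc}")
                names.append("delta_wind")
                self.i_wind = len(names) - 1
            else:
                self.wind_vals = None
                self.i_wind = None
        self.names = tuple(names)
        self.k = len(names)
        # binomial normalising constant (full log-likelihood)
        self.log_const = float(np.sum(
            gammaln(self.n + 1) - gammaln(self.y + 1) - gammaln(self.n - self.y + 1)))

    # -- linear predictor ---------------------------------------------------
    def eta_terms(self, theta: np.ndarray, *, clip: bool = True):
        """Return (eta, t1, t2): log-odds and each exponential term."""
        spec = self.spec
        eta = np.full_like(self.dist, theta[0])
        t1 = t2 = None
        cap = _FIT_CLIP if clip else None
        if spec.n_exp_terms == 2:
            a1 = theta[1] + theta[2] * self.dist
            t1 = np.exp(np.clip(a1, None, cap) if clip else a1)
            eta = eta + t1
        if spec.n_exp_terms >= 1:
            a2 = self.X_int @ theta[self.i_int] + (self.X_dec @ theta[self.i_dec]) * self.dist
            if self.i_wind is not None:
                a2 = a2 + theta[self.i_wind] * self.wind_vals
            t2 = np.exp(np.clip(a2, None, cap) if clip else a2)
            eta = eta + t2
        return eta, t1, t2

    def nll_grad(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        eta, t1, t2 = self.eta_terms(theta)
        ll = float(np.sum(self.y * eta - self.n * np.logaddexp(0.0, eta))) + self.log_const
        resid = self.y - self.n * expit(eta)  # d loglik / d eta
        grad = np.zeros(self.k)
        grad[0] = resid.sum()
        if self.spec.n_exp_terms == 2:
            grad[1] = np.sum(resid * t1)
            grad[2] = np.sum(resid * t1 * self.dist)
        if self.spec.n_exp_terms >= 1:
            grad[self.i_int] = self.X_int.T @ (resid * t2)
            grad[self.i_dec] = self.X_dec.T @ (resid * t2 * self.dist)
            if self.i_wind is not None:
                grad[self.i_wind] = np.sum(resid * t2 * self.wind_vals)
        if not np.isfinite(ll):
            return 1e300, np.zeros(self.k)
        return -ll, -grad


def _model_data_for(
    coefficients: DecayCoefficients, records: Iterable[ScreeningRecord]
) -> _ModelData:
    df = screening_frame(records)
    md = _ModelData(
        coefficients.spec, df,
        ref_direction=coefficients.ref_direction,
        direction_levels=coefficients.direction_levels,
        year_levels=coefficients.year_levels,
        wind_lookup=coefficients.wind_lookup,
        require_variation=False,
    )
    if md.names != coefficients.names:
        raise ValueError(
            "coefficient layout does not match the records' factor levels: "
            f"{md.names} vs {coefficients.names}")
    return md


def predict_frequency(
    coefficients: DecayCoefficients,
    distance_m,
    direction: str,
    year: int,
):
    """Model frequency p at given distance(s) for one direction and year."""
    direction = str(direction).upper()
    year = int(year)
    if direction not in coefficients.direction_levels:
        raise KeyError(f"direction {direction!r} not among fitted levels "
                       f"{coefficients.direction_levels}")
    if year not in coefficients.year_levels:
        raise KeyError(f"year {year} not among fitted levels "
                       f"{coefficients.year_levels}")
    dist = np.atleast_1d(np.asarray(distance_m, dtype=float))
    df = pd.DataFrame({
        "year": year, "direction": direction, "distance_m": dist,
        "n_screened": 1, "n_resistant": 0,
    })
    md = _ModelData(
        coefficients.spec, df,
        ref_direction=coefficients.ref_direction,
        direction_levels=coefficients.direction_levels,
        year_levels=coefficients.year_levels,
        wind_lookup=coefficients.wind_lookup,
        require_variation=False,
    )
    eta, _, _ = md.eta_terms(coefficients.values)
    p = expit(eta)
    return float(p[0]) if np.isscalar(distance_m) else p


def linear_predictor_overflow(
    coefficients: DecayCoefficients, distance_m: float, direction: str, year: int
) -> bool:
    """True if an exponential-term argument exceeds the overflow guard."""
    df = pd.DataFrame({"year": int(year), "direction": direction,
                       "distance_m": [float(distance_m)],
                       "n_screened": 1, "n_resistant": 0})
    md = _ModelData(coefficients.spec, df,
                    ref_direction=coefficients.ref_direction,
                    direction_levels=coefficients.direction_levels,
                    year_levels=coefficients.year_levels,
                    wind_lookup=coefficients.wind_lookup,
                    require_variation=False)
    th = coefficients.values
    args = []
    if coefficients.spec.n_exp_terms == 2:
        args.append(th[1] + th[2] * distance_m)
    if coefficients.spec.n_exp_terms >= 1:
        a2 = md.X_int @ th[md.i_int] + (md.X_dec @ th[md.i_dec]) * distance_m
        if md.i_wind is not None:
            a2 = a2 + th[md.i_wind] * md.wind_vals
        args.append(float(a2[0]))
    return any(a > _EXP_CLIP for a in np.atleast_1d(args).ravel())


def negative_log_likelihood(
    coefficients: DecayCoefficients, records: Sequence[ScreeningRecord]
) -> float:
    """Full binomial negative log-likelihood over the given cells.

    Includes the binomial normalising constant, so ``-2 * (-NLL) + 2K``
    reproduces the AIC reported by :func:`fit`.
    """
    md = _model_data_for(coefficients, records)
    eta, _, _ = md.eta_terms(coefficients.values, clip=False)
    bad = ~np.isfinite(eta)
    if np.any(bad):
        i = int(np.argmax(bad))
        r = list(records)[i]
        raise FloatingPointError(
            f"non-finite linear predictor in cell "
            f"{r.year}/{r.direction}/{r.distance_m} m")
    nll, _ = md.nll_grad(coefficients.values)
    return float(nll)


# ---------------------------------------------------------------------------
# fitting

def _heuristic_start(md: _ModelData) -> np.ndarray:
    dist, y, n = md.dist, md.y, md.n
    far = dist >= np.quantile(dist, 0.7)
    near = dist <= np.quantile(dist, 0.3)
    def pooled(mask):
        tot = n[mask].sum()
        return float(np.clip(y[mask].sum() / tot if tot else 0.5, 1e-4, 1 - 1e-4))
    beta0 = float(logit(pooled(far)))
    excess = max(float(logit(pooled(near))) - beta0, 0.2)
    theta = np.zeros(md.k)
    theta[0] = beta0
    if md.spec.n_exp_terms == 2:
        theta[1] = np.log(excess / 2)          # beta1
        theta[2] = -1.0                        # gamma1: fast decay
        theta[md.i_int.start] = np.log(excess / 2)
        theta[md.i_dec.start] = -0.05
    elif md.spec.n_exp_terms == 1:
        theta[md.i_int.start] = np.log(excess)
        theta[md.i_dec.start] = -0.1
    return theta


def _bounds(md: _ModelData, constraints: bool):
    if not constraints:
        return None
    bounds = [(None, None)] * md.k
    if md.spec.n_exp_terms == 2:
        bounds[2] = (None, 0.0)                      # gamma1
    if md.spec.n_exp_terms >= 1:
        bounds[md.i_dec.start] = (None, 0.0)         # reference-level decay
    return bounds


def _observed_information_vcov(md: _ModelData, theta: np.ndarray):
    """Covariance from central finite differences of the analytic gradient."""
    k = md.k
    H = np.zeros((k, k))
    for j in range(k):
        h = 1e-5 * (1.0 + abs(theta[j]))
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h
        tm[j] -= h
        _, gp = md.nll_grad(tp)
        _, gm = md.nll_grad(tm)
        H[:, j] = (gp - gm) / (2 * h)
    H = 0.5 * (H + H.T)
    if not np.all(np.isfinite(H)):
        return None
    try:
        vcov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        vcov = np.linalg.pinv(H)
    if not np.all(np.isfinite(vcov)) or np.any(np.diag(vcov) < 0):
        return None
    return vcov


def _maybe_swap_terms(names, theta, vcov, spec: ModelSpec):
    """Order exchangeable exponential terms so |gamma1| >= |gamma2|.

    With no factor coding and no wind covariate the two terms of the double
    exponential are interchangeable; the fast-decay term is canonically the
    first.  Factor-coded fits are not exchangeable and are left untouched.
    """
    if spec.n_exp_terms != 2 or spec.intercept_coding != "1" \
            or spec.decay_coding != "1" or spec.wind_covariate is not None:
        return theta, vcov
    i1, i2 = names.index("gamma1"), names.index("gamma2")
    if abs(theta[i1]) >= abs(theta[i2]):
        return theta, vcov
    perm = list(range(len(names)))
    b1, b2 = names.index("beta1"), names.index("beta2")
    perm[b1], perm[b2] = perm[b2], perm[b1]
    perm[i1], perm[i2] = perm[i2], perm[i1]
    theta = theta[perm]
    if vcov is not None:
        vcov = vcov[np.ix_(perm, perm)]
    return theta, vcov


class FitError(RuntimeError):
    """No optimizer start converged; carries the per-start trace."""

    def __init__(self, message: str, trace):
        super().__init__(message)
        self.trace = tuple(trace)


def fit(
    records: Sequence[ScreeningRecord],
    spec: ModelSpec,
    *,
    init: np.ndarray | None = None,
    constraints: bool = True,
    n_starts: int = 8,
    seed: int = 0,
    ref_direction: str = REF_DIRECTION,
    wind_lookup: Mapping[tuple[str, int], float] | None = None,
    gtol: float = 1e-8,
) -> FitSummary:
    """Maximum-likelihood fit of one candidate spec to screening cells.

    A heuristic start (background log-odds from the pooled far-field
    frequency, near-field excess split across the exponential terms) plus
    ``n_starts - 1`` seeded random perturbations guard against the
    nonconvex double-exponential surface.  With ``constraints`` on, the
    reference-level decay rates are bounded <= 0 (decay, not growth);
    treatment offsets remain free, so individual direction-by-year levels
    may still come out positive if the data demand it.
    """
    df = screening_frame(records)
    if df.empty:
        raise ValueError("no screening records to fit")
    if df["distance_m"].nunique() < 2 and spec.n_exp_terms >= 1:
        raise ValueError("need >= 2 distinct distances to identify a decay rate")
    md = _ModelData(spec, df, ref_direction=ref_direction, wind_lookup=wind_lookup)
    theta0 = _heuristic_start(md) if init is None else np.asarray(init, float)
    if theta0.size != md.k:
        raise ValueError(f"init has {theta0.size} entries, spec needs {md.k}")
    bounds = _bounds(md, constraints)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5EED]))

    starts = [theta0]
    for _ in range(max(0, n_starts - 1)):
        pert = theta0 + rng.normal(scale=0.5, size=md.k)
        if bounds is not None:
            for j, (_, ub) in enumerate(bounds):
                if ub is not None:
                    pert[j] = min(pert[j], ub - 1e-3)
        starts.append(pert)

    best = None
    trace = []
    for s_idx, start in enumerate(starts):
        res = optimize.minimize(
            md.nll_grad, start, jac=True, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 20000, "maxfun": 100000, "ftol": 1e-13,
                     "gtol": gtol},
        )
        trace.append({"start": s_idx, "nll": float(res.fun),
                      "converged": bool(res.success), "nit": int(res.nit)})
        if res.success and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise FitError(f"no start converged for spec {spec.name!r}", trace)

    theta = best.x
    vcov = _observed_information_vcov(md, theta)
    if vcov is None:
        log.warning("observed information for %s is rank-deficient; "
                    "vcov unavailable", spec.name)
    theta, vcov = _maybe_swap_terms(list(md.names), theta, vcov, spec)
    coef = DecayCoefficients(
        spec=spec, names=md.names, values=theta,
        ref_direction=ref_direction,
        direction_levels=md.direction_levels,
        year_levels=md.year_levels,
        vcov=vcov, wind_lookup=wind_lookup,
    )
    return FitSummary(
        coefficients=coef, loglik=-float(best.fun), k=md.k,
        converged=True, n_obs=len(df), optimizer_trace=tuple(trace),
    )


def pearson_gof(fit_result: FitSummary, records: Sequence[ScreeningRecord]) -> GofResult:
    """Pearson chi-squared on grouped binomial cells.

    chisq = sum_i n_i (y_i - mu_i)^2 / (mu_i (n_i - mu_i)) with fitted
    counts mu_i = n_i * p_i; df = cells - k - 1.  Cells whose fitted count
    is degenerate (0 or n_i to machine precision) are excluded with a
    warning and reduce the df.
    """
    coef = fit_result.coefficients
    md = _model_data_for(coef, records)
    eta, _, _ = md.eta_terms(coef.values)
    mu = md.n * expit(eta)
    ok = (mu > 1e-12) & (mu < md.n - 1e-12)
    dropped = int((~ok).sum())
    if dropped:
        log.warning("pearson_gof: excluded %d degenerate cell(s)", dropped)
    chisq = float(np.sum(
        md.n[ok] * (md.y[ok] - mu[ok]) ** 2 / (mu[ok] * (md.n[ok] - mu[ok]))))
    df_ = int(ok.sum()) - fit_result.k - 1
    return GofResult(chisq=chisq, df=df_, n_cells_used=int(ok.sum()))
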