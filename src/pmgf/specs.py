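"""Symbolic candidate-model specifications for the dispersal kernel.

A candidate model for the gene-flow frequency ``p`` at distance ``d`` is

    logit(p) = beta0 [+ exp(beta1 + gamma1 * d)] + exp(b(x) + g(x) * d)

where the optional bracketed term is a second, scalar "fast" exponential
(``n_exp_terms == 2``) and ``b(x)``/``g(x)`` are linear predictors in the
factor covariates direction and year (treatment coding, reference level
East / first year), optionally augmented with one scalar wind covariate
(per-sector wind speed, frequency, or run) on the intercept ``b``.

The coding strings are:

``"1"``               intercept only
``"year"``            intercept + year offsets
``"direction"``       intercept + direction offsets
``"direction+year"``  additive main effects
``"direction:year"``  full interaction (one level per direction x year)
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .records import DIRECTIONS

CODINGS = ("1", "year", "direction", "direction+year", "direction:year")
WIND_COVARIATES = ("speed", "frequency", "run")

#: Default reference direction for treatment coding.
REF_DIRECTION = "E"


@dataclass(frozen=True)
class ModelSpec:
    """One candidate dispersal model.

    ``n_exp_terms`` = 0 gives the intercept-only (constant-frequency) model,
    1 a single exponential decay, 2 the double exponential.  Factor codings
    apply to the (codable) exponential term; the extra term of the double
    model is always scalar.  ``wind_covariate`` adds one scalar coefficient
    multiplying a per-direction wind summary on the term intercept; it is
    never combined with direction factors (collinear with them).
    """

    n_exp_terms: int = 2
    intercept_coding: str = "1"
    decay_coding: str = "1"
    wind_covariate: str | None = None

    def __post_init__(self) -> None:
        if self.n_exp_terms not in (0, 1, 2):
            raise ValueError("n_exp_terms must be 0, 1 or 2")
        for c in (self.intercept_coding, self.decay_coding):
            if c not in CODINGS:
                raise ValueError(f"unknown coding {c!r}")
        if self.wind_covariate is not None:
            if self.wind_covariate not in WIND_COVARIATES:
                raise ValueError(f"unknown wind covariate {self.wind_covariate!r}")
            if "direction" in self.intercept_coding or "direction" in self.decay_coding:
                raise ValueError(
                    "wind covariates and direction factors are collinear; "
                    "a spec may not include both"
                )
        if self.n_exp_terms == 0 and (
            self.intercept_coding != "1" or self.decay_coding != "1"
            or self.wind_covariate is not None
        ):
            raise ValueError("the intercept-only model takes no covariates")

    @property
    def name(self) -> str:
        if self.n_exp_terms == 0:
            return "constant"
        kernel = "double-exp" if self.n_exp_terms == 2 else "single-exp"
        parts = [kernel, f"b~{self.intercept_coding}", f"g~{self.decay_coding}"]
        if self.wind_covariate:
            parts.append(f"wind={self.wind_covariate}")
        return "|".join(parts)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


#: The specification selected by the field study: double exponential with
#: full direction-by-year structure on both the intercept and the decay rate
#: of the codable term.
WINNING_SPEC = ModelSpec(2, "direction:year", "direction:year")


def factor_design(
    directions: Sequence[str],
    years: Sequence[int],
    coding: str,
    *,
    prefix: str,
    ref_direction: str = REF_DIRECTION,
    direction_levels: Sequence[str] | None = None,
    year_levels: Sequence[int] | None = None,
    require_variation: bool = True,
) -> tuple[np.ndarray, list[str]]:
    """Treatment-coded design matrix for one coded term.

    Returns (X, names) where X has one row per observation and the first
    column is the all-ones reference-level intercept.  Direction offsets are
    relative to ``ref_direction``; year offsets relative to the first of the
    sorted ``year_levels``.  Level sets default to those observed in the
    data; pass them explicitly (with ``require_variation=False``) to build
    prediction rows against an existing coefficient layout.
    """
    directions = [str(d) for d in directions]
    years = [int(y) for y in years]
    if year_levels is None:
        year_levels = sorted(set(years))
    year_levels = [int(y) for y in year_levels]
    if direction_levels is None:
        direction_levels = sorted(set(directions) | {ref_direction})
    ref_year = year_levels[0]
    dir_levels = [d for d in sorted(direction_levels) if d != ref_direction]
    off_years = [y for y in year_levels if y != ref_year]

    n = len(directions)
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = [prefix]

    want_dir = "direction" in coding
    want_year = "year" in coding
    want_inter = coding == "direction:year"

    if require_variation:
        if want_dir and len(set(directions)) < 2:
            raise ValueError(f"coding {coding!r} needs >= 2 directions in the data")
        if want_year and len(set(years)) < 2:
            raise ValueError(f"coding {coding!r} needs >= 2 years in the data")

    dir_arr = np.asarray(directions)
    year_arr = np.asarray(years)
    if want_dir:
        for d in dir_levels:
            cols.append((dir_arr == d).astype(float))
            names.append(f"{prefix}:dir[{d}]")
    if want_year:
        for y in off_years:
            cols.append((year_arr == y).astype(float))
            names.append(f"{prefix}:year[{y}]")
    if want_inter:
        for d in dir_levels:
            for y in off_years:
                cols.append(((dir_arr == d) & (year_arr == y)).astype(float))
                names.append(f"{prefix}:dir[{d}]:year[{y}]")
    return np.column_stack(cols), names


def build_candidate_set(
    *,
    directions_available: bool = True,
    years_available: bool = True,
    wind_available: bool = True,
) -> tuple[ModelSpec, ...]:
    """Deterministic, duplicate-free enumeration of the candidate family.

    The default grid crosses single/double exponentials with the factor
    codings estimable from the available covariates (decay coding either
    scalar or matching the intercept coding), plus, when wind summaries are
    supplied, double-exponential variants carrying one wind covariate in
    place of direction factors.
    """
    codings = ["1"]
    if years_available:
        codings.append("year")
    if directions_available:
        codings.append("direction")
    if directions_available and years_available:
        codings += ["direction+year", "direction:year"]

    specs: list[ModelSpec] = []
    for n_terms in (1, 2):
        for ic in codings:
            for dc in dict.fromkeys(["1", ic]):
                specs.append(ModelSpec(n_terms, ic, dc))
    if wind_available:
        wind_codings = ["1"] + (["year"] if years_available else [])
        for w in WIND_COVARIATES:
            for ic in wind_codings:
                specs.append(ModelSpec(2, ic, "1", wind_covariate=w))
    if not specs:
        raise ValueError("empty candidate grid")
    # dict preserves insertion order and drops accidental duplicates
    return tuple(dict.fromkeys(specs))
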