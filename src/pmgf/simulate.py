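"""Synthetic field season with the statistical structure the analysis assumes.

Three generators emulate the study's data streams:

* **screening counts** — binomial draws per (year, direction, distance)
  station with success probability given by the double-exponential logit
  kernel, by default the bundled reference coefficients over the concentric
  design (0.1-35 m on eight arms, 50 m on the ordinal arms only);
* **hourly weather** — a flowering-period stream with a prevailing-sector
  wind distribution (south / southeast dominated, as observed), gamma
  wind speeds with per-year means (1.2 and 2.8 m/s), and daily temperature
  cycling within the observed 17-30 deg C flowering-period band;
* **flowering progress** — logistic donor and receptor curves observed at a
  5-day cadence over a ~6-week flowering period, with receptor onset
  optionally delayed 3-6 days beyond 10 m from the source.

Reproducibility: one root seed; each stream draws from a child generator
derived as ``SeedSequence([root_seed, stream_id, ...])`` so the three
streams are independently reproducible.

This is a statistical emulator, not an aerobiological one: there is no
pollen settling velocity or plume physics, and the screening generator is
exactly the model the fitting stage assumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Callable, Mapping

import numpy as np

from .decay import DecayCoefficients, linear_predictor_overflow, predict_frequency
from .records import (DIRECTIONS, FieldDesign, FloweringObservation,
                      ScreeningRecord, WeatherRecord, DONOR_BLOCK)
from .reference import default_n_per_cell, reference_coefficients

# stream ids for child-seed derivation
_STREAM_SCREENING = 1
_STREAM_WEATHER = 2
_STREAM_FLOWERING = 3

#: Default wind-FROM sector distribution: S/SE-dominated prevailing wind.
DEFAULT_SECTOR_WEIGHTS: dict[str, float] = {
    "N": 0.07, "NE": 0.06, "E": 0.10, "SE": 0.22,
    "S": 0.28, "SW": 0.12, "W": 0.08, "NW": 0.07,
}

#: Observed flowering-period mean wind speeds by study year (m/s).
DEFAULT_MEAN_SPEED_MS: dict[int, float] = {2014: 1.2, 2015: 2.8}


@dataclass(frozen=True)
class GeneratorTruth:
    """Generating model and design for one synthetic study.

    ``n_per_cell`` may be an int (same effort everywhere), a mapping from
    distance to count, or a callable ``(year, direction, distance) -> int``;
    ``None`` uses the bundled per-distance screening-effort profile (large
    samples at far distances, where detection needs thousands of plants).
    """

    coefficients: DecayCoefficients = field(default_factory=reference_coefficients)
    design: FieldDesign = field(default_factory=FieldDesign)
    n_per_cell: int | Mapping[float, int] | Callable[[int, str, float], int] | None = None
    seed: int = 0
    prevailing_sector_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SECTOR_WEIGHTS))
    mean_speed_ms: float | Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_MEAN_SPEED_MS))

    def __post_init__(self) -> None:
        w = np.array([self.prevailing_sector_weights.get(d, 0.0) for d in DIRECTIONS])
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("prevailing_sector_weights must be non-negative "
                             "and sum to 1 within 1e-9")

    @property
    def years(self) -> tuple[int, ...]:
        return tuple(self.coefficients.year_levels)

    def cell_n(self, year: int, direction: str, distance_m: float) -> int:
        n = self.n_per_cell
        if n is None:
            val = default_n_per_cell(year, distance_m)
        elif callable(n):
            val = n(year, direction, distance_m)
        elif isinstance(n, Mapping):
            val = n[distance_m]
        else:
            val = int(n)
        if val < 0:
            raise ValueError(f"negative sample size for cell "
                             f"{year}/{direction}/{distance_m} m")
        return int(val)

    def sector_mean_speed(self, year: int) -> float:
        if isinstance(self.mean_speed_ms, Mapping):
            ms = self.mean_speed_ms
            return float(ms.get(int(year), next(iter(ms.values()))))
        return float(self.mean_speed_ms)

    def metadata(self) -> dict:
        """Sidecar-ready record of the generating truth and seed."""
        return {
            "seed": self.seed,
            "years": list(self.years),
            "coefficients": {n: float(v) for n, v in
                             zip(self.coefficients.names, self.coefficients.values)},
            "spec": self.coefficients.spec.name,
            "prevailing_sector_weights": dict(self.prevailing_sector_weights),
            "mean_speed_ms": (dict(self.mean_speed_ms)
                              if isinstance(self.mean_speed_ms, Mapping)
                              else float(self.mean_speed_ms)),
        }


def _child_rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, key)]))


def generate_screening(truth: GeneratorTruth) -> list[ScreeningRecord]:
    """Binomial screening counts for every design cell in every year."""
    rng = _child_rng(truth.seed, _STREAM_SCREENING)
    out: list[ScreeningRecord] = []
    for year in truth.years:
        for direction, dist in truth.design.cells():
            if linear_predictor_overflow(truth.coefficients, dist, direction, year):
                raise OverflowError(
                    f"exponential-term argument exceeds 700 in cell "
                    f"{year}/{direction}/{dist} m; check generating coefficients")
            p = predict_frequency(truth.coefficients, dist, direction, year)
            n = truth.cell_n(year, direction, dist)
            y = int(rng.binomial(n, p)) if n > 0 else 0
            out.append(ScreeningRecord(year, direction, dist, n, y))
    return out


def generate_weather(
    truth: GeneratorTruth,
    start: date,
    weeks: int,
    *,
    year: int | None = None,
) -> list[WeatherRecord]:
    """Hourly flowering-period weather stream of ``weeks`` weeks.

    Wind sectors are drawn from the prevailing-sector distribution with the
    direction uniform within the 45-degree sector; speeds are gamma
    (shape 2) with the per-year sector mean; temperature follows a diurnal
    cycle inside the 17-30 deg C flowering band.
    """
    if weeks < 1:
        raise ValueError("weeks must be >= 1")
    year = int(year) if year is not None else int(start.year)
    rng = _child_rng(truth.seed, _STREAM_WEATHER, year)
    n_hours = int(weeks) * 7 * 24
    weights = np.array([truth.prevailing_sector_weights.get(d, 0.0)
                        for d in DIRECTIONS])
    centers = np.array([0, 45, 90, 135, 180, 225, 270, 315], dtype=float)
    sector_idx = rng.choice(8, size=n_hours, p=weights / weights.sum())
    wind_dir = (centers[sector_idx] + rng.uniform(-22.5, 22.5, n_hours)) % 360.0
    mean_speed = truth.sector_mean_speed(year)
    speed = rng.gamma(shape=2.0, scale=mean_speed / 2.0, size=n_hours)
    hour = np.arange(n_hours) % 24
    temp = 23.5 + 5.5 * np.sin(2 * np.pi * (hour - 9) / 24) \
        + rng.normal(0, 0.8, n_hours)
    temp = np.clip(temp, 17.0, 30.0)
    rh = np.clip(95 - 3.5 * (temp - 17) + rng.normal(0, 5, n_hours), 25, 100)
    wet = rng.random(n_hours) < 0.04
    precip = np.where(wet, rng.exponential(2.0, n_hours), 0.0)

    t0 = date(year, start.month, start.day)
    base = np.datetime64(t0.isoformat()) + np.timedelta64(0, "h")
    out = []
    for i in range(n_hours):
        ts = (base + np.timedelta64(i, "h")).astype("datetime64[s]").item()
        out.append(WeatherRecord(ts, float(temp[i]), float(precip[i]),
                                 float(rh[i]), float(speed[i]), float(wind_dir[i])))
    return out


def generate_flowering(
    design: FieldDesign,
    synchrony_target: float = 1.0,
    seed: int = 0,
    *,
    start: date = date(2014, 7, 25),
    weeks: int = 6,
    cadence_days: int = 5,
    delayed: bool = True,
    delay_from_m: float = 10.0,
    delay_range_days: tuple[float, float] = (3.0, 6.0),
) -> list[FloweringObservation]:
    """Logistic flowering-progress curves for donor and receptor stations.

    The donor's pollen-shed curve is the synchrony baseline; receptor
    flowering tracks it scaled by ``synchrony_target`` and, when ``delayed``,
    shifted 3-6 days later at stations ``>= delay_from_m`` (sparser stands
    flower later).  With ``synchrony_target=1`` and no delay every receptor
    matches the donor exactly (perfect synchrony).
    """
    if not 0 < synchrony_target <= 1:
        raise ValueError("synchrony_target must be in (0, 1]")
    rng = _child_rng(seed, _STREAM_FLOWERING)

    t50_shed = 21.0       # peak progress ~3 weeks after floral initiation
    scale = 4.0
    def shed_pct(t: float) -> float:
        return float(100.0 / (1.0 + np.exp(-(t - t50_shed) / scale)))

    days = list(range(0, int(weeks) * 7, int(cadence_days)))
    out: list[FloweringObservation] = []
    delays: dict[tuple[str, float], float] = {}
    for direction, dist in design.cells():
        delays[(direction, dist)] = (
            float(rng.uniform(*delay_range_days))
            if delayed and dist >= delay_from_m else 0.0)
    for t in days:
        obs_date = start + timedelta(days=t)
        # donor: receptivity precedes shed by ~3 days (protogyny)
        out.append(FloweringObservation(
            date=obs_date, block=DONOR_BLOCK,
            pct_flowering=shed_pct(t + 3.0),
            pct_shedding=shed_pct(t)))
        for direction, dist in design.cells():
            pct = synchrony_target * shed_pct(t - delays[(direction, dist)])
            out.append(FloweringObservation(
                date=obs_date,
                block=FloweringObservation.receptor_block(direction, dist),
                pct_flowering=pct))
    return out
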