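"""Domain records for a concentric (Nelder-wheel) pollen-dispersal field study.

The experimental unit is a *station*: a group of pollen-receptor plants at a
given distance along one of eight directional arms around a central pollen
donor block.  Distances are measured from the EDGE of the donor block, not
its centre.  Seed harvested per station is screened with a discriminating
herbicide dose, so each (year, direction, distance) cell yields a binomial
count: plants screened and plants surviving (carrying the resistance
marker).

Three plain-CSV inputs are supported: screening counts, hourly weather, and
flowering-progress observations.  CSVs are comma-separated UTF-8 with a
header row and decimal-point number formatting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date, datetime
from typing import Iterable, Sequence

import pandas as pd

log = logging.getLogger(__name__)

#: The eight compass sectors, clockwise from north.
DIRECTIONS: tuple[str, ...] = ("N", "NE", "E", "SE", "S", "SW", "W", "NW")
CARDINAL: tuple[str, ...] = ("N", "E", "S", "W")
ORDINAL: tuple[str, ...] = ("NE", "SE", "SW", "NW")

#: Compass-sector centre azimuths in degrees (wind-FROM convention).
SECTOR_CENTERS_DEG: dict[str, float] = {
    "N": 0.0, "NE": 45.0, "E": 90.0, "SE": 135.0,
    "S": 180.0, "SW": 225.0, "W": 270.0, "NW": 315.0,
}

#: Sector opposite each sector; wind FROM the opposite sector blows pollen
#: INTO a receptor arm (the "downwind" pairing used in correlation analysis).
OPPOSITE_SECTOR: dict[str, str] = {
    "N": "S", "S": "N", "E": "W", "W": "E",
    "NE": "SW", "SW": "NE", "SE": "NW", "NW": "SE",
}


class SchemaError(ValueError):
    """A CSV is missing a required column or has an unusable layout."""


class ValidationError(ValueError):
    """A parsed value violates a record invariant."""


def canonical_direction(token: str) -> str:
    """Normalise a compass token (case-insensitive) to canonical uppercase."""
    tok = str(token).strip().upper()
    if tok not in DIRECTIONS:
        raise ValidationError(
            f"unknown direction token {token!r}; expected one of {DIRECTIONS}"
        )
    return tok


@dataclass(frozen=True)
class ScreeningRecord:
    """Binomial screening outcome for one (year, direction, distance) cell."""

    year: int
    direction: str
    distance_m: float
    n_screened: int
    n_resistant: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "direction", canonical_direction(self.direction))
        if self.distance_m <= 0:
            raise ValidationError(f"distance_m must be > 0, got {self.distance_m}")
        if self.n_screened < 0 or self.n_resistant < 0:
            raise ValidationError("counts must be non-negative")
        if self.n_resistant > self.n_screened:
            raise ValidationError(
                f"n_resistant ({self.n_resistant}) exceeds n_screened "
                f"({self.n_screened}) for {self.year}/{self.direction}/{self.distance_m} m"
            )


@dataclass(frozen=True)
class WeatherRecord:
    """One hourly surface-weather observation.

    ``wind_dir_deg`` follows the meteorological convention: the azimuth the
    wind blows FROM, degrees in [0, 360).
    """

    timestamp: datetime
    air_temp_c: float
    precip_mm: float
    rh_pct: float
    wind_speed_ms: float
    wind_dir_deg: float

    def __post_init__(self) -> None:
        if self.wind_speed_ms < 0:
            raise ValidationError(f"negative wind speed {self.wind_speed_ms}")
        if not 0 <= self.wind_dir_deg < 360:
            raise ValidationError(
                f"wind_dir_deg must be in [0, 360), got {self.wind_dir_deg}"
            )


#: Block label of the central pollen-donor circle in flowering CSVs.
DONOR_BLOCK = "donor"


@dataclass(frozen=True)
class FloweringObservation:
    """Flowering progress at one block on one date (~5-day cadence).

    ``block`` is either ``"donor"`` or ``"<direction>:<distance_m>"`` for a
    receptor station.  ``pct_shedding`` (pollen shed) is meaningful for the
    donor block only and may be None elsewhere.
    """

    date: date
    block: str
    pct_flowering: float
    pct_shedding: float | None = None

    def __post_init__(self) -> None:
        for name, val in (("pct_flowering", self.pct_flowering),
                          ("pct_shedding", self.pct_shedding)):
            if val is not None and not 0 <= val <= 100:
                raise ValidationError(f"{name} must be in [0, 100], got {val}")

    @property
    def is_donor(self) -> bool:
        return self.block == DONOR_BLOCK

    @staticmethod
    def receptor_block(direction: str, distance_m: float) -> str:
        return f"{canonical_direction(direction)}:{distance_m:g}"


@dataclass(frozen=True)
class FieldDesign:
    """Concentric receptor layout around a central circular donor block.

    Receptor stations sit at fixed distances from the donor EDGE along all
    eight arms, with extra far stations on the ordinal arms only.
    """

    donor_radius_m: float = 5.0
    cardinal_distances_m: tuple[float, ...] = (0.1, 0.5, 1, 2, 4, 10, 15, 25, 35)
    ordinal_extra_m: tuple[float, ...] = (50.0,)
    plants_per_station: int = 6

    def __post_init__(self) -> None:
        if self.donor_radius_m <= 0:
            raise ValidationError("donor_radius_m must be > 0")
        for seq in (self.cardinal_distances_m, self.ordinal_extra_m):
            lst = list(seq)
            if any(d <= 0 for d in lst) or lst != sorted(set(lst)):
                raise ValidationError(
                    "distances must be positive and strictly increasing"
                )

    def distances_for(self, direction: str) -> tuple[float, ...]:
        d = canonical_direction(direction)
        if d in ORDINAL:
            return tuple(self.cardinal_distances_m) + tuple(self.ordinal_extra_m)
        return tuple(self.cardinal_distances_m)

    def cells(self) -> Iterable[tuple[str, float]]:
        """Yield every (direction, distance) station in canonical order."""
        for direction in DIRECTIONS:
            for dist in self.distances_for(direction):
                yield direction, dist


# ---------------------------------------------------------------------------
# CSV I/O

_SCREEN_COLS = ["year", "direction", "distance_m", "n_screened", "n_resistant"]
_WEATHER_COLS = ["timestamp", "air_temp_c", "precip_mm", "rh_pct",
                 "wind_speed_ms", "wind_dir_deg"]
_FLOWER_COLS = ["date", "block", "pct_flowering", "pct_shedding"]


def _require_columns(df: pd.DataFrame, cols: Sequence[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} CSV is missing column(s): {', '.join(missing)}")


def read_screening(path) -> list[ScreeningRecord]:
    """Read screening counts; row order preserved, invariants enforced."""
    df = pd.read_csv(path)
    _require_columns(df, _SCREEN_COLS, "screening")
    out = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            out.append(ScreeningRecord(
                year=int(row.year),
                direction=str(row.direction),
                distance_m=float(row.distance_m),
                n_screened=int(row.n_screened),
                n_resistant=int(row.n_resistant),
            ))
        except ValidationError as exc:
            raise ValidationError(f"screening row {i}: {exc}") from exc
    return out


def write_screening(records: Iterable[ScreeningRecord], path) -> None:
    screening_frame(records).to_csv(path, index=False)


def screening_frame(records: Iterable[ScreeningRecord]) -> pd.DataFrame:
    """Tidy DataFrame view of screening records (one row per cell)."""
    return pd.DataFrame(
        [(r.year, r.direction, r.distance_m, r.n_screened, r.n_resistant)
         for r in records],
        columns=_SCREEN_COLS,
    )


def read_weather(path) -> list[WeatherRecord]:
    """Read an hourly weather stream, sorted chronologically.

    Gaps are tolerated (field loggers drop hours); the number of missing
    hours relative to the observed span is reported at INFO level.
    """
    df = pd.read_csv(path)
    if df.empty:
        log.warning("weather CSV %s is empty", path)
        return []
    _require_columns(df, _WEATHER_COLS, "weather")
    out = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            ts = pd.Timestamp(row.timestamp).to_pydatetime()
        except (ValueError, TypeError) as exc:
            raise ValidationError(f"weather row {i}: unparseable timestamp "
                                  f"{row.timestamp!r}") from exc
        try:
            out.append(WeatherRecord(
                timestamp=ts,
                air_temp_c=float(row.air_temp_c),
                precip_mm=float(row.precip_mm),
                rh_pct=float(row.rh_pct),
                wind_speed_ms=float(row.wind_speed_ms),
                wind_dir_deg=float(row.wind_dir_deg),
            ))
        except ValidationError as exc:
            raise ValidationError(f"weather row {i}: {exc}") from exc
    out.sort(key=lambda r: r.timestamp)
    span_hours = (out[-1].timestamp - out[0].timestamp).total_seconds() / 3600
    missing = int(span_hours) + 1 - len(out)
    if missing > 0:
        log.info("weather stream has %d missing hour(s) over its span", missing)
    return out


def write_weather(records: Iterable[WeatherRecord], path) -> None:
    pd.DataFrame(
        [(r.timestamp.isoformat(), r.air_temp_c, r.precip_mm, r.rh_pct,
          r.wind_speed_ms, r.wind_dir_deg) for r in records],
        columns=_WEATHER_COLS,
    ).to_csv(path, index=False)


def read_flowering(path) -> list[FloweringObservation]:
    """Read flowering observations (donor + receptor blocks)."""
    df = pd.read_csv(path)
    _require_columns(df, _FLOWER_COLS[:3], "flowering")
    out = []
    for i, row in enumerate(df.itertuples(index=False)):
        shed = getattr(row, "pct_shedding", None)
        if shed is not None and pd.isna(shed):
            shed = None
        try:
            out.append(FloweringObservation(
                date=pd.Timestamp(row.date).date(),
                block=str(row.block),
                pct_flowering=float(row.pct_flowering),
                pct_shedding=None if shed is None else float(shed),
            ))
        except ValidationError as exc:
            raise ValidationError(f"flowering row {i}: {exc}") from exc
    return out


def write_flowering(records: Iterable[FloweringObservation], path) -> None:
    pd.DataFrame(
        [(r.date.isoformat(), r.block, r.pct_flowering,
          "" if r.pct_shedding is None else r.pct_shedding) for r in records],
        columns=_FLOWER_COLS,
    ).to_csv(path, index=False)
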