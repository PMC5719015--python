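"""Descriptive statistics: gene-flow frequency, flowering synchrony,
wind-rose aggregation, and PMGF-wind correlation.

Conventions that matter here:

* Per-distance frequencies pool counts over directions FIRST (sum resistant
  / sum screened), because a ratio of summed counts is what the study's
  per-distance table prints; a mean-of-per-direction-ratios alternative is
  available behind a flag.
* Two synchrony conventions coexist in the field literature and in the
  study: ``receptor_over_donor`` averages receptor-flowering over donor-shed percentages
  and reports a percentage; ``donor_over_receptor`` averages donor-shed over
  receptor-flowering percentages and reports a ratio (1.0 = perfect
  synchrony).  Both are implemented; neither is silently preferred.
* Wind sectors are half-open 45-degree bins centred on the eight compass
  points; a boundary azimuth (e.g. 22.5) belongs to the clockwise-next
  sector (NE).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .records import (DIRECTIONS, OPPOSITE_SECTOR, ScreeningRecord,
                      WeatherRecord, screening_frame)

log = logging.getLogger(__name__)

#: (year, distance) cells dropped from analysis by default: the 2014/0.1 m
#: cell lacked the sample size for 0.8 detection power in the study.
DEFAULT_EXCLUSIONS: tuple[tuple[int, float], ...] = ((2014, 0.1),)


class UndefinedFrequencyError(ZeroDivisionError):
    """Gene-flow frequency is undefined when nothing was screened."""


class UndefinedSynchronyError(ZeroDivisionError):
    """Synchrony is undefined when its denominator percentage is zero."""


def gene_flow_frequency(n_resistant: int, n_screened: int) -> float:
    """Fraction of screened plants carrying the resistance marker."""
    if n_screened <= 0:
        raise UndefinedFrequencyError(
            "frequency undefined for n_screened = 0; exclude the cell upstream")
    if not 0 <= n_resistant <= n_screened:
        raise ValueError("need 0 <= n_resistant <= n_screened")
    return n_resistant / n_screened


def pooled_frequency_by_distance(
    records: Iterable[ScreeningRecord],
    year: int,
    *,
    method: str = "pooled",
    exclusions: Sequence[tuple[int, float]] = DEFAULT_EXCLUSIONS,
) -> pd.DataFrame:
    """Per-distance gene-flow table for one year, ordered by distance.

    Columns: distance_m, total_screened, total_resistant, frequency.
    ``method="pooled"`` (default) is the ratio of summed counts;
    ``method="mean_of_ratios"`` averages per-direction ratios instead.
    """
    if method not in ("pooled", "mean_of_ratios"):
        raise ValueError(f"unknown method {method!r}")
    df = screening_frame(records)
    df = df[df["year"] == int(year)]
    if df.empty:
        raise ValueError(f"no records for year {year}")
    mask = np.zeros(len(df), dtype=bool)
    for ex_year, ex_dist in exclusions:
        mask |= ((df["year"] == ex_year) & (df["distance_m"] == ex_dist)).to_numpy()
    df = df[~mask]
    g = df.groupby("distance_m", sort=True)
    out = g.agg(total_screened=("n_screened", "sum"),
                total_resistant=("n_resistant", "sum")).reset_index()
    if method == "pooled":
        out["frequency"] = out["total_resistant"] / out["total_screened"]
    else:
        ratios = df.assign(ratio=df["n_resistant"] / df["n_screened"]) \
            .groupby("distance_m", sort=True)["ratio"].mean()
        out["frequency"] = ratios.to_numpy()
    return out


def per_direction_frequency(
    records: Iterable[ScreeningRecord], year: int
) -> pd.DataFrame:
    """Cell-level frequencies for one year (direction x distance)."""
    df = screening_frame(records)
    df = df[df["year"] == int(year)].copy()
    df["frequency"] = df["n_resistant"] / df["n_screened"]
    return df[["direction", "distance_m", "frequency"]]


# ---------------------------------------------------------------------------
# flowering synchrony

@dataclass(frozen=True)
class SynchronyResult:
    direction: str
    date: object
    value: float
    convention: str


def flowering_synchrony(
    receptor_pcts: Sequence[float],
    donor_pct: float,
    convention: str = "receptor_over_donor",
    *,
    cap: bool = False,
) -> float:
    """Flowering synchrony between donor and the stations of one arm.

    ``receptor_over_donor``: mean over stations of (receptor % / donor shed %) x 100,
    a percentage.  ``donor_over_receptor``: mean over stations of (donor shed % /
    receptor %), a ratio with 1.0 = perfect synchrony.  With ``cap`` each
    per-station term is capped at full synchrony (100% resp. 1.0), since a
    receptor flowering at least as much as the donor sheds is fully
    synchronised.
    """
    receptors = np.asarray(receptor_pcts, dtype=float)
    if receptors.size == 0:
        raise ValueError("need at least one receptor percentage")
    if np.any(receptors < 0) or donor_pct < 0:
        raise ValueError("percentages must be non-negative")
    if convention == "receptor_over_donor":
        if donor_pct == 0:
            raise UndefinedSynchronyError("donor shed percentage is zero")
        terms = receptors / donor_pct * 100.0
        if cap:
            terms = np.minimum(terms, 100.0)
    elif convention == "donor_over_receptor":
        if np.any(receptors == 0):
            raise UndefinedSynchronyError("a receptor percentage is zero")
        terms = donor_pct / receptors
        if cap:
            terms = np.minimum(terms, 1.0)
    else:
        raise ValueError(f"unknown convention {convention!r}")
    return float(terms.mean())


def synchrony_table(
    observations,
    convention: str = "donor_over_receptor",
    *,
    cap: bool = False,
) -> pd.DataFrame:
    """Direction-by-date synchrony from flowering observations.

    Donor rows supply the shed percentage; receptor rows are grouped into
    their directional arm by their ``"<direction>:<distance>"`` block label.
    Dates where the convention's denominator is zero are skipped.
    """
    donor = {o.date: o.pct_shedding for o in observations if o.is_donor}
    rows = []
    by_key: dict[tuple[str, object], list[float]] = {}
    for o in observations:
        if o.is_donor:
            continue
        direction = o.block.split(":", 1)[0]
        by_key.setdefault((direction, o.date), []).append(o.pct_flowering)
    for (direction, when), pcts in sorted(by_key.items(),
                                          key=lambda kv: (str(kv[0][1]), kv[0][0])):
        shed = donor.get(when)
        if shed is None:
            continue
        try:
            val = flowering_synchrony(pcts, shed, convention, cap=cap)
        except UndefinedSynchronyError:
            continue
        rows.append((direction, when, val, convention))
    return pd.DataFrame(rows, columns=["direction", "date", "value", "convention"])


# ---------------------------------------------------------------------------
# wind

@dataclass(frozen=True)
class WindSummary:
    """Aggregate wind behaviour for one compass sector.

    ``frequency_pct`` is the percentage of observed hours with wind FROM
    this sector; ``wind_run`` is mean speed times frequency (fraction form),
    an exposure-weighted speed.
    """

    sector: str
    frequency_pct: float
    mean_speed_ms: float
    wind_run: float


def sector_of(wind_dir_deg: float) -> str:
    """Compass sector of an azimuth; boundary goes to the clockwise-next."""
    idx = int(((float(wind_dir_deg) + 22.5) % 360.0) // 45.0)
    return DIRECTIONS[idx]


def wind_rose(records: Sequence[WeatherRecord], sectors: int = 8) -> list[WindSummary]:
    """Eight-sector wind summary: frequency (%), mean speed, wind run."""
    if sectors != 8:
        raise ValueError("only the 8-sector compass rose is supported")
    if not records:
        raise ValueError("empty weather stream")
    labels = [sector_of(r.wind_dir_deg) for r in records]
    speeds = np.array([r.wind_speed_ms for r in records])
    n = len(records)
    out = []
    for d in DIRECTIONS:
        mask = np.array([lab == d for lab in labels])
        count = int(mask.sum())
        freq = count / n * 100.0
        mean_speed = float(speeds[mask].mean()) if count else 0.0
        out.append(WindSummary(sector=d, frequency_pct=freq,
                               mean_speed_ms=mean_speed,
                               wind_run=mean_speed * freq / 100.0))
    return out


def wind_rose_frame(summaries: Iterable[WindSummary]) -> pd.DataFrame:
    return pd.DataFrame([(s.sector, s.frequency_pct, s.mean_speed_ms, s.wind_run)
                         for s in summaries],
                        columns=["sector", "frequency_pct", "mean_speed_ms",
                                 "wind_run"])


_WIND_PARAMS = {"speed": "mean_speed_ms", "frequency": "frequency_pct",
                "run": "wind_run"}


def wind_parameter_by_arm(
    summaries: Sequence[WindSummary],
    parameter: str,
    mapping: str = "downwind",
) -> dict[str, float]:
    """Wind parameter value attributed to each receptor arm.

    ``downwind`` (default) pairs an arm with wind blowing FROM the opposite
    sector — wind from the south carries pollen into the north arm;
    ``sector`` pairs an arm with its own sector.
    """
    if parameter not in _WIND_PARAMS:
        raise ValueError(f"unknown wind parameter {parameter!r}")
    if mapping not in ("downwind", "sector"):
        raise ValueError(f"unknown mapping {mapping!r}")
    attr = _WIND_PARAMS[parameter]
    by_sector = {s.sector: getattr(s, attr) for s in summaries}
    out = {}
    for arm in DIRECTIONS:
        src = OPPOSITE_SECTOR[arm] if mapping == "downwind" else arm
        out[arm] = float(by_sector[src])
    return out


def make_wind_lookup(
    summaries_by_year: Mapping[int, Sequence[WindSummary]],
    parameter: str,
    mapping: str = "downwind",
) -> dict[tuple[str, int], float]:
    """(direction, year) -> wind covariate value, for model fitting."""
    out = {}
    for year, summaries in summaries_by_year.items():
        per_arm = wind_parameter_by_arm(summaries, parameter, mapping)
        for arm, val in per_arm.items():
            out[(arm, int(year))] = val
    return out


@dataclass(frozen=True)
class CorrelationResult:
    distance_m: float
    n: int
    r: float
    p_value: float
    defined: bool


def correlate_pmgf_wind(
    frequencies: pd.DataFrame,
    wind: Sequence[WindSummary],
    parameter: str = "run",
    mapping: str = "downwind",
) -> list[CorrelationResult]:
    """Pearson correlation of per-direction PMGF with a wind parameter.

    ``frequencies`` has columns direction, distance_m, frequency (one row
    per direction at each distance, e.g. from
    :func:`per_direction_frequency`).  Returns one result per distance;
    zero-variance inputs are flagged ``defined=False`` rather than silently
    NaN.
    """
    per_arm = wind_parameter_by_arm(wind, parameter, mapping)
    out = []
    for dist, grp in frequencies.groupby("distance_m", sort=True):
        x = grp["frequency"].to_numpy(float)
        w = np.array([per_arm[d] for d in grp["direction"]])
        if len(x) < 3:
            raise ValueError(f"need >= 3 direction pairs at {dist} m, got {len(x)}")
        if np.ptp(x) == 0 or np.ptp(w) == 0:
            out.append(CorrelationResult(float(dist), len(x),
                                         float("nan"), float("nan"), False))
            continue
        r, p = stats.pearsonr(x, w)
        out.append(CorrelationResult(float(dist), len(x), float(r), float(p), True))
    return out
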