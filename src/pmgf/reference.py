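"""Bundled reference data from a two-year giant ragweed gene-flow field study.

Two small published summary tables are packaged as in-code fixtures so the
full pipeline is exercisable without any download:

* the per-distance screening marginals (plants screened and plants
  confirmed resistant, pooled over the eight directional arms, one table
  per study year); the 0.1 m row of year 2014 was excluded by the study
  because its sample size fell short of the 0.8 detection-power threshold,
  so that year prints nine distance rows and the other ten;
* the fitted coefficient table of the selected double-exponential dispersal
  model (full direction-by-year structure, reference level East / 2014),
  used as the default generating truth for the synthetic-data module.

These are summary fixtures, not the study's raw per-direction data.
"""

from __future__ import annotations

import pandas as pd

from .decay import DecayCoefficients
from .records import DIRECTIONS
from .specs import WINNING_SPEC

REFERENCE_YEARS: tuple[int, int] = (2014, 2015)

# (distance_m, n_screened, n_resistant), pooled over the 8 arms
_COUNTS_2014 = (
    (0.5, 2_591, 1_546),
    (1, 2_157, 1_154),
    (2, 3_201, 1_281),
    (4, 2_456, 781),
    (10, 2_325, 498),
    (15, 2_182, 282),
    (25, 3_385, 315),
    (35, 5_585, 519),
    (50, 23_820, 941),
)
_COUNTS_2015 = (
    (0.1, 5_198, 2_218),
    (0.5, 5_941, 1_645),
    (1, 5_247, 1_120),
    (2, 6_696, 1_535),
    (4, 6_376, 1_488),
    (10, 2_003, 247),
    (15, 4_782, 437),
    (25, 3_661, 278),
    (35, 3_285, 202),
    (50, 10_047, 326),
)


def pooled_screening_counts() -> pd.DataFrame:
    """Per-distance screening marginals, both years (19 rows).

    Columns: year, distance_m, n_screened, n_resistant.  Grand totals are
    100,938 screened and 16,813 resistant.
    """
    rows = [(2014, *r) for r in _COUNTS_2014] + [(2015, *r) for r in _COUNTS_2015]
    return pd.DataFrame(rows, columns=["year", "distance_m",
                                       "n_screened", "n_resistant"])


# Selected-model coefficient table (estimate, Wald SE), reference level
# East / 2014.  Offsets are changes from the reference level.
_B0 = (-3.50, 0.09)
_B1 = (0.26, 0.10)
_G1 = (-5.35, 1.06)
_B2_REF = (1.59, 0.07)
_G2_REF = (-0.03, 0.01)
_B2_DIR = {"N": (-0.25, 0.12), "NE": (-0.59, 0.09), "NW": (1.04, 0.10),
           "S": (0.09, 0.11), "SE": (-0.12, 0.12), "SW": (1.21, 0.10),
           "W": (-0.17, 0.08)}
_G2_DIR = {"N": (-0.02, 0.02), "NE": (0.24, 0.04), "NW": (-0.52, 0.06),
           "S": (-0.02, 0.02), "SE": (-0.02, 0.02), "SW": (-0.05, 0.03),
           "W": (0.02, 0.01)}
_B2_YEAR2 = (-0.23, 0.04)
_G2_YEAR2 = (-0.02, 0.01)
_B2_DIR_YEAR2 = {"N": (-0.04, 0.06), "NE": (0.31, 0.05), "NW": (-0.78, 0.06),
                 "S": (-0.23, 0.06), "SE": (-0.02, 0.06), "SW": (-0.94, 0.07),
                 "W": (0.12, 0.04)}
_G2_DIR_YEAR2 = {"N": (0.03, 0.00), "NE": (-0.23, 0.03), "NW": (0.27, 0.03),
                 "S": (0.02, 0.01), "SE": (0.02, 0.01), "SW": (0.01, 0.02),
                 "W": (-0.01, 0.00)}


def marginal_screening_records() -> list:
    """The pooled marginals re-expressed as per-direction screening records.

    Counts at each (year, distance) are split evenly across the arms that
    carry that distance (8 arms up to 35 m, the 4 ordinal arms at 50 m),
    remainders going to the first arms, so per-distance and grand totals
    are preserved exactly.  Useful for exercising the pooling path; the
    split itself is synthetic (the study's per-direction raw counts are not
    published).
    """
    from .records import DIRECTIONS, ORDINAL, ScreeningRecord

    out = []
    for year, counts in ((2014, _COUNTS_2014), (2015, _COUNTS_2015)):
        for dist, n_total, y_total in counts:
            arms = list(ORDINAL) if dist >= 50 else list(DIRECTIONS)
            k = len(arms)
            for i, arm in enumerate(arms):
                n = n_total // k + (1 if i < n_total % k else 0)
                y = y_total // k + (1 if i < y_total % k else 0)
                out.append(ScreeningRecord(year, arm, dist, n, y))
    return out


def reference_coefficients() -> DecayCoefficients:
    """The selected-model coefficient set as a :class:`DecayCoefficients`.

    No covariance matrix is attached (the published table prints only
    marginal standard errors, not a full covariance).
    """
    off_dirs = [d for d in sorted(DIRECTIONS) if d != "E"]
    year2 = REFERENCE_YEARS[1]

    names = ["beta0", "beta1", "gamma1"]
    values = [_B0[0], _B1[0], _G1[0]]
    for prefix, ref, by_dir, by_year2, by_inter in (
        ("beta2", _B2_REF, _B2_DIR, _B2_YEAR2, _B2_DIR_YEAR2),
        ("gamma2", _G2_REF, _G2_DIR, _G2_YEAR2, _G2_DIR_YEAR2),
    ):
        names.append(prefix)
        values.append(ref[0])
        for d in off_dirs:
            names.append(f"{prefix}:dir[{d}]")
            values.append(by_dir[d][0])
        names.append(f"{prefix}:year[{year2}]")
        values.append(by_year2[0])
        for d in off_dirs:
            names.append(f"{prefix}:dir[{d}]:year[{year2}]")
            values.append(by_inter[d][0])

    return DecayCoefficients(
        spec=WINNING_SPEC,
        names=tuple(names),
        values=values,
        ref_direction="E",
        direction_levels=tuple(sorted(DIRECTIONS)),
        year_levels=REFERENCE_YEARS,
    )


def reference_standard_errors() -> dict[str, float]:
    """Published marginal standard errors, keyed like the coefficient names."""
    off_dirs = [d for d in sorted(DIRECTIONS) if d != "E"]
    year2 = REFERENCE_YEARS[1]
    out = {"beta0": _B0[1], "beta1": _B1[1], "gamma1": _G1[1]}
    for prefix, ref, by_dir, by_year2, by_inter in (
        ("beta2", _B2_REF, _B2_DIR, _B2_YEAR2, _B2_DIR_YEAR2),
        ("gamma2", _G2_REF, _G2_DIR, _G2_YEAR2, _G2_DIR_YEAR2),
    ):
        out[prefix] = ref[1]
        for d in off_dirs:
            out[f"{prefix}:dir[{d}]"] = by_dir[d][1]
        out[f"{prefix}:year[{year2}]"] = by_year2[1]
        for d in off_dirs:
            out[f"{prefix}:dir[{d}]:year[{year2}]"] = by_inter[d][1]
    return out


def default_n_per_cell(year: int, distance_m: float) -> int:
    """Realistic per-station screening effort for the synthetic generator.

    Splits the published per-distance marginals evenly across the arms that
    carry that distance (8 arms up to 35 m, 4 ordinal arms at 50 m).  The
    missing 2014 / 0.1 m marginal borrows the 2015 profile.
    """
    table = {2014: dict((d, n) for d, n, _ in _COUNTS_2014),
             2015: dict((d, n) for d, n, _ in _COUNTS_2015)}
    year = int(year) if int(year) in table else REFERENCE_YEARS[0]
    per_dist = table[year]
    if distance_m not in per_dist:
        per_dist = table[2015]
    n_total = per_dist.get(distance_m)
    if n_total is None:
        raise KeyError(f"no reference marginal at {distance_m} m")
    arms = 4 if distance_m >= 50 else 8
    return max(1, round(n_total / arms))
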