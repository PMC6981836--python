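"""Calendar stratifications for the case-crossover variants.

A stratum is a small group of days treated as exchangeable for the slope
comparison; the regression eliminates each stratum's nuisance level, so
temporal confounding that is constant within a stratum vanishes by design.
Supported schemes:

``CC2D``
    pairs of consecutive days within a year: (1,2), (3,4), ... — the
    shortest possible window; a 365-day year gives 183 strata (182 pairs
    plus one trailing singleton).
``CC3D``
    triples of consecutive days within a year.
``CC2W``
    <year : two-week block : day-of-week>; each stratum holds the same
    weekday of two adjacent weeks (at most 2 days).
``CC2CW``
    chained (overlapping) week pairs (1,2), (2,3), (3,4), ... crossed with
    day-of-week; interior weeks' days are deliberately duplicated into the
    two neighbouring strata.
``CCM``
    the classical time-stratified scheme <calendar year : month :
    day-of-week> (4–5 days per stratum).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .dataio import DailySeries

logger = logging.getLogger(__name__)

SCHEME_NAMES = ("CC2D", "CC3D", "CC2W", "CC2CW", "CCM")
YEAR_RULES = ("calendar", "fixed365")

# Weekday names indexed as pandas dayofweek (Monday=0).
_DOW = ("Mon", "Tue", "Wed", "Thu", "Fri", "Sat", "Sun")


@dataclass(frozen=True)
class StratumScheme:
    """A named calendar-stratification rule.

    Parameters
    ----------
    name:
        One of ``CC2D, CC3D, CC2W, CC2CW, CCM``.
    year_rule:
        ``"calendar"`` uses calendar years (day-of-year 1..366, real data);
        ``"fixed365"`` splits the series into consecutive 365-day blocks, as
        appropriate for simulated series built from 365-day years.
    allow_partial_years:
        Under ``fixed365``, permit a trailing block shorter than 365 days.
    """

    name: str
    year_rule: str = "calendar"
    allow_partial_years: bool = False

    def __post_init__(self) -> None:
        name = self.name.upper()
        object.__setattr__(self, "name", name)
        if name not in SCHEME_NAMES:
            raise ValueError(f"unknown scheme {self.name!r}; expected one of {SCHEME_NAMES}")
        if self.year_rule not in YEAR_RULES:
            raise ValueError(f"year_rule must be one of {YEAR_RULES}")
        if name == "CCM" and self.year_rule != "calendar":
            raise ValueError("CCM strata need calendar months; use year_rule='calendar'")

    @property
    def block_days(self) -> int | None:
        """Window length in days for the consecutive-day schemes."""
        return {"CC2D": 2, "CC3D": 3}.get(self.name)


@dataclass(frozen=True)
class StratifiedDataset:
    """Day-level records labelled with stratum ids.

    ``records`` has one row per (day, stratum) membership with columns
    ``day_index, date, outcome, exposure, temperature, dow, stratum``.  For
    the chained scheme (CC2CW) interior days appear in two strata, so rows
    may be duplicated; all other schemes partition the retained days.
    """

    records: pd.DataFrame
    scheme: StratumScheme
    removed: dict = field(default_factory=dict)

    @property
    def n_strata(self) -> int:
        return int(self.records["stratum"].nunique())

    @property
    def n_records(self) -> int:
        return int(len(self.records))

    @property
    def duplication_factor(self) -> pd.Series:
        """Number of strata containing each source day (indexed by day_index)."""
        return self.records.groupby("day_index").size()

    def stratum_sizes(self) -> pd.Series:
        return self.records.groupby("stratum").size()

    def to_csv(self, path: str | Path) -> None:
        """Audit export: one row per record with its stratum id."""
        self.records.to_csv(path, index=False)


def _years_and_doy(series: DailySeries, scheme: StratumScheme) -> tuple[np.ndarray, np.ndarray]:
    """Return per-day (year label, day-of-year) under the scheme's year rule."""
    if scheme.year_rule == "calendar":
        return series.dates.year.to_numpy(), series.dates.dayofyear.to_numpy()
    idx = series.day_index
    n_span = int(idx[-1]) + 1
    if n_span % 365 != 0 and not scheme.allow_partial_years:
        raise ValueError(
            f"fixed365 year rule needs a day span divisible by 365 (got {n_span}); "
            "set allow_partial_years=True to permit a short trailing block"
        )
    return idx // 365, idx % 365 + 1


def assign_strata(series: DailySeries, scheme: StratumScheme) -> StratifiedDataset:
    """Label every usable day of ``series`` with its stratum under ``scheme``.

    Days with missing outcome or exposure (or missing temperature, when the
    series carries temperature) are excluded before grouping.  Stratum ids
    are deterministic strings ``"<year>:<block>"`` or
    ``"<year>:<block>:<dow>"`` so that repeated runs are bit-reproducible.
    """
    if len(series) == 0:
        raise ValueError("cannot stratify an empty series")
    years, doy = _years_and_doy(series, scheme)
    df = pd.DataFrame(
        {
            "day_index": series.day_index,
            "date": series.dates,
            "outcome": series.outcome,
            "exposure": series.exposure,
            "temperature": series.temperature if series.temperature is not None else np.nan,
            "dow": series.dates.dayofweek,
            "year": years,
            "doy": doy,
        }
    )
    usable = df["outcome"].notna() & df["exposure"].notna()
    if series.temperature is not None:
        usable &= df["temperature"].notna()
    n_dropped = int((~usable).sum())
    if n_dropped:
        logger.info("excluded %d day(s) with missing values before grouping", n_dropped)
    df = df[usable].copy()
    if len(df) == 0:
        raise ValueError("no usable days after removing missing values")

    name = scheme.name
    if name in ("CC2D", "CC3D"):
        b = scheme.block_days
        block = (df["doy"] - 1) // b + 1
        df["stratum"] = df["year"].astype(str) + ":" + block.map("{:03d}".format)
    elif name == "CC2W":
        week = (df["doy"] - 1) // 7 + 1
        block = (week - 1) // 2 + 1
        df["stratum"] = (
            df["year"].astype(str)
            + ":"
            + block.map("{:02d}".format)
            + ":"
            + df["dow"].map(lambda d: _DOW[d])
        )
    elif name == "CC2CW":
        week = (df["doy"] - 1) // 7 + 1
        # chained pairs (1,2),(2,3),...: week w joins pair w-1 and pair w
        max_week = df.groupby("year")["doy"].transform(lambda s: ((s - 1) // 7 + 1).max())
        as_first = df[week < max_week].copy()
        as_first["pair"] = week[week < max_week]
        as_second = df[week > 1].copy()
        as_second["pair"] = week[week > 1] - 1
        df = pd.concat([as_first, as_second], ignore_index=True)
        df["stratum"] = (
            df["year"].astype(str)
            + ":"
            + df["pair"].map("{:02d}".format)
            + ":"
            + df["dow"].map(lambda d: _DOW[d])
        )
        df = df.drop(columns="pair")
    else:  # CCM
        df["stratum"] = (
            df["year"].astype(str)
            + ":"
            + df["date"].dt.month.map("{:02d}".format)
            + ":"
            + df["dow"].map(lambda d: _DOW[d])
        )
    df = df.drop(columns=["year", "doy"]).sort_values(["stratum", "day_index"], kind="stable")
    df = df.reset_index(drop=True)
    return StratifiedDataset(records=df, scheme=scheme, removed={"missing_values": n_dropped})


def informative_strata(ds: StratifiedDataset, family: str = "gaussian") -> StratifiedDataset:
    """Drop strata that cannot contribute to the slope's conditional likelihood.

    Removed: strata with fewer than 2 records; strata whose exposure is
    constant across records; and, under the Poisson family, strata whose
    total outcome is zero (their multinomial contribution is identically 1).
    The removal counts are recorded on the returned dataset.
    """
    rec = ds.records
    g = rec.groupby("stratum")
    size = g["exposure"].transform("size")
    exp_range = g["exposure"].transform("max") - g["exposure"].transform("min")
    keep = (size >= 2) & (exp_range > 1e-12)
    removed = {
        "too_small": int(rec.loc[size < 2, "stratum"].nunique()),
        "constant_exposure": int(rec.loc[(size >= 2) & (exp_range <= 1e-12), "stratum"].nunique()),
    }
    if family == "poisson":
        total_y = g["outcome"].transform("sum")
        removed["zero_total_outcome"] = int(rec.loc[keep & (total_y <= 0), "stratum"].nunique())
        keep &= total_y > 0
    out = rec[keep].reset_index(drop=True)
    return StratifiedDataset(records=out, scheme=ds.scheme, removed={**ds.removed, **removed})


def scheme_from_method(method: str, year_rule: str = "calendar", **kw) -> StratumScheme:
    """Convenience: build a scheme from a method label like ``"cc2d"``."""
    return StratumScheme(name=method.upper(), year_rule=year_rule, **kw)
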