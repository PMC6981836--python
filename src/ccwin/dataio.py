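"""Daily time-series I/O: the :class:`DailySeries` container and CSV round-trip.

A :class:`DailySeries` holds aligned per-day vectors — calendar date, outcome
(a count for Poisson-family analyses, real-valued otherwise), exposure
concentration and, optionally, ambient temperature.  Every other module
consumes this container.  Reading is configuration-driven
(:class:`SeriesConfig`) because published daily-series CSVs do not share a
column layout.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

FAMILIES = ("gaussian", "poisson")


class DataError(ValueError):
    """Raised when input data violate a series invariant."""


class ConfigError(ValueError):
    """Raised when a configuration does not match the data."""


@dataclass(frozen=True)
class SeriesConfig:
    """How to read a daily-series CSV and which model family it feeds.

    Parameters
    ----------
    column_map:
        Maps the roles ``date``, ``outcome``, ``exposure`` and (optionally)
        ``temperature`` to column names in the file.
    date_format:
        ``strptime`` pattern; ``None`` lets pandas infer (ISO dates).
    family:
        ``"gaussian"`` or ``"poisson"``.  Under ``"poisson"`` the outcome
        must be non-negative integers.
    lag:
        Non-negative exposure lag in days, applied with :func:`apply_lag`.
    """

    column_map: Mapping[str, str] = field(
        default_factory=lambda: {"date": "date", "outcome": "outcome", "exposure": "exposure"}
    )
    date_format: str | None = None
    family: str = "gaussian"
    lag: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ConfigError(f"family must be one of {FAMILIES}, got {self.family!r}")
        if self.lag < 0:
            raise ConfigError(f"lag must be >= 0, got {self.lag}")
        for role in ("date", "outcome", "exposure"):
            if role not in self.column_map:
                raise ConfigError(f"column_map must name a {role!r} column")

    @classmethod
    def from_file(cls, path: str | Path) -> "SeriesConfig":
        """Load a config from a YAML or JSON file mirroring the field names."""
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: expected a mapping at top level")
        return cls(**data)


@dataclass(frozen=True)
class DailySeries:
    """Aligned daily vectors of date, outcome, exposure and optional temperature.

    Invariants: all vectors share one length >= 1; dates are strictly
    increasing calendar dates (gaps are allowed but flagged via
    :attr:`has_gaps`); under the Poisson family the outcome is integer >= 0.
    Missing values (NaN) in outcome/exposure/temperature are retained here
    and excluded later, at stratification time.
    """

    dates: pd.DatetimeIndex
    outcome: np.ndarray
    exposure: np.ndarray
    temperature: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        dates = pd.DatetimeIndex(self.dates)
        object.__setattr__(self, "dates", dates)
        object.__setattr__(self, "outcome", np.asarray(self.outcome, dtype=float))
        object.__setattr__(self, "exposure", np.asarray(self.exposure, dtype=float))
        if self.temperature is not None:
            object.__setattr__(self, "temperature", np.asarray(self.temperature, dtype=float))
        n = len(dates)
        if n < 1:
            raise DataError("series must contain at least one day")
        for name in ("outcome", "exposure", "temperature"):
            vec = getattr(self, name)
            if vec is not None and len(vec) != n:
                raise DataError(f"{name} length {len(vec)} != dates length {n}")
        diffs = np.diff(dates.values.astype("datetime64[D]").astype(int))
        if n > 1 and not (diffs > 0).all():
            raise DataError("dates must be strictly increasing with no duplicates")
        if self.has_gaps:
            logger.warning("series has %d missing calendar day(s)", int((diffs - 1).sum()))

    def __len__(self) -> int:
        return len(self.dates)

    @property
    def has_gaps(self) -> bool:
        """True when the dates skip at least one calendar day."""
        if len(self.dates) < 2:
            return False
        d = np.diff(self.dates.values.astype("datetime64[D]").astype(int))
        return bool((d > 1).any())

    @property
    def day_index(self) -> np.ndarray:
        """0-based day offsets from the first date (gap-aware)."""
        days = self.dates.values.astype("datetime64[D]").astype(int)
        return days - days[0]

    def validate_family(self, family: str) -> None:
        """Check outcome values against the model family's constraints."""
        if family == "poisson":
            y = self.outcome[~np.isnan(self.outcome)]
            if (y < 0).any() or not np.allclose(y, np.round(y)):
                raise DataError("poisson family requires non-negative integer outcomes")

    def to_frame(self) -> pd.DataFrame:
        cols = {"date": self.dates, "outcome": self.outcome, "exposure": self.exposure}
        if self.temperature is not None:
            cols["temperature"] = self.temperature
        return pd.DataFrame(cols)


def read_daily_csv(path: str | Path, config: SeriesConfig | None = None) -> DailySeries:
    """Read a daily series from CSV, validating against ``config``.

    Rows whose date fails to parse are rejected with a logged count;
    duplicate dates are an error, as is a fractional count under the
    Poisson family.  Missing calendar days are permitted but logged.
    """
    config = config or SeriesConfig()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, float_precision="round_trip")
    cmap = config.column_map
    for role in ("date", "outcome", "exposure"):
        if cmap[role] not in df.columns:
            raise ConfigError(f"{path.name}: missing mapped column {cmap[role]!r} for {role!r}")
    dates = pd.to_datetime(df[cmap["date"]], format=config.date_format, errors="coerce")
    bad = dates.isna()
    if bad.any():
        logger.warning("%s: rejected %d row(s) with unparseable dates", path.name, int(bad.sum()))
        df, dates = df[~bad], dates[~bad]
    if len(df) == 0:
        raise DataError(f"{path.name}: no rows with parseable dates")
    if dates.duplicated().any():
        raise DataError(f"{path.name}: duplicate dates")
    order = np.argsort(dates.values, kind="stable")
    df, dates = df.iloc[order], dates.iloc[order]
    temp_col = cmap.get("temperature")
    temperature = (
        pd.to_numeric(df[temp_col], errors="raise").to_numpy()
        if temp_col and temp_col in df.columns
        else None
    )
    try:
        outcome = pd.to_numeric(df[cmap["outcome"]]).to_numpy(dtype=float)
        exposure = pd.to_numeric(df[cmap["exposure"]]).to_numpy(dtype=float)
    except (ValueError, TypeError) as exc:
        raise DataError(f"{path.name}: non-numeric outcome/exposure value ({exc})") from exc
    series = DailySeries(
        dates=pd.DatetimeIndex(dates),
        outcome=outcome,
        exposure=exposure,
        temperature=temperature,
        meta={"source": str(path)},
    )
    series.validate_family(config.family)
    return series


def write_daily_csv(series: DailySeries, path: str | Path, config: SeriesConfig | None = None) -> None:
    """Write ``series`` to CSV with the same dialect :func:`read_daily_csv` reads.

    Values round-trip at full precision (dates as ISO, floats via repr).
    """
    config = config or SeriesConfig()
    cmap = dict(config.column_map)
    df = series.to_frame()
    df["date"] = df["date"].dt.strftime("%Y-%m-%d")
    for col in df.columns:
        if df[col].dtype == float:
            # repr is the shortest exactly round-tripping decimal form
            df[col] = df[col].map(repr)
    rename = {"date": cmap["date"], "outcome": cmap["outcome"], "exposure": cmap["exposure"]}
    if "temperature" in df.columns:
        rename["temperature"] = cmap.get("temperature", "temperature")
    df.rename(columns=rename).to_csv(path, index=False)


def apply_lag(series: DailySeries, lag: int) -> DailySeries:
    """Lag the exposure by ``lag`` days: day *t*'s exposure becomes day *t - lag*'s.

    The first ``lag`` days (which have no lagged exposure) are dropped from
    every vector.  ``lag=0`` returns the series unchanged.
    """
    if lag < 0:
        raise ValueError(f"lag must be >= 0, got {lag}")
    if lag == 0:
        return series
    if lag >= len(series):
        raise ValueError(f"lag {lag} >= series length {len(series)}")
    return replace(
        series,
        dates=series.dates[lag:],
        outcome=series.outcome[lag:],
        exposure=series.exposure[:-lag],
        temperature=None if series.temperature is None else series.temperature[lag:],
        meta={**series.meta, "lag": series.meta.get("lag", 0) + lag},
    )
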