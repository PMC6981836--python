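"""Study harness: estimator x scenario grids, summary tables, epi runner.

``run_simulation_study`` applies any subset of the stratified estimators
(CC2D, CC3D, CC2W, CC2CW, CCM — Gaussian family for simulated continuous
outcomes) and the spline-GLM comparators (GLM6, GLM12) to a common set of
generated samples, then condenses the per-sample slopes and standard errors
into distribution summaries (min, quartiles, median, mean, max, sd).
``run_epi_analysis`` is the single-dataset path for real daily counts:
stratify, filter, fit the conditional Poisson model with optional
temperature spline and exposure lag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .condreg import (
    FitError,
    FitResult,
    ModelSpec,
    fit_conditional_gaussian,
    fit_conditional_poisson,
    fit_time_series_glm,
)
from .dataio import DailySeries, apply_lag
from .simdata import SimulatedSample
from .strata import StratumScheme, assign_strata, informative_strata

logger = logging.getLogger(__name__)

CC_METHODS = ("CC2D", "CC3D", "CC2W", "CC2CW", "CCM")
GLM_METHODS = {"GLM6": 6.0, "GLM12": 12.0}
METHODS = CC_METHODS + tuple(GLM_METHODS)

_STAT_LABELS = ("Minimum", "1stQuartile", "Median", "Mean", "3rdQuartile", "Maximum")


@dataclass
class StudySummary:
    """Distribution of slope estimates and SEs for one method on one scenario."""

    method: str
    sim_id: int | str
    stats_beta: dict[str, float]
    stats_se: dict[str, float]
    sd_beta: float
    n_samples: int
    n_failed: int
    valid: bool = True
    betas: np.ndarray = field(default_factory=lambda: np.array([]), repr=False)
    ses: np.ndarray = field(default_factory=lambda: np.array([]), repr=False)


def _order_stats(values: np.ndarray) -> dict[str, float]:
    """Min, quartiles (linear interpolation), median, mean, max."""
    if len(values) == 0:
        return {k: float("nan") for k in _STAT_LABELS}
    q1, med, q3 = np.quantile(values, [0.25, 0.5, 0.75])
    return {
        "Minimum": float(np.min(values)),
        "1stQuartile": float(q1),
        "Median": float(med),
        "Mean": float(np.mean(values)),
        "3rdQuartile": float(q3),
        "Maximum": float(np.max(values)),
    }


def fit_method(
    sample_series: DailySeries,
    method: str,
    family: str = "gaussian",
    year_rule: str = "fixed365",
    spec: ModelSpec | None = None,
) -> FitResult:
    """Fit one method (stratified or GLM comparator) to one daily series."""
    method = method.upper()
    if method in GLM_METHODS:
        spec = spec or ModelSpec(family=family)
        return fit_time_series_glm(sample_series, spec, df_per_year=GLM_METHODS[method])
    if method not in CC_METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    scheme = StratumScheme(name=method, year_rule=year_rule)
    spec = spec or ModelSpec(family=family)
    ds = informative_strata(assign_strata(sample_series, scheme), family=family)
    if family == "poisson":
        return fit_conditional_poisson(ds, spec)
    return fit_conditional_gaussian(ds, spec)


def run_simulation_study(
    samples: Sequence[SimulatedSample],
    methods: Sequence[str],
    sim_id: int | str | None = None,
    year_rule: str = "fixed365",
) -> list[StudySummary]:
    """Fit every method to every sample; summarize betas and SEs per method.

    Non-converged or failed fits are excluded from the summaries and
    counted in ``n_failed``; a method for which every fit fails yields a
    summary flagged ``valid=False``.
    """
    if len(samples) == 0:
        raise ValueError("samples must be non-empty")
    label = sim_id if sim_id is not None else samples[0].series.meta.get("sim_id", "?")
    out: list[StudySummary] = []
    for method in methods:
        betas, ses, n_failed = [], [], 0
        for s in samples:
            try:
                fr = fit_method(s.series, method, family="gaussian", year_rule=year_rule)
            except (FitError, ValueError) as exc:
                logger.warning("%s failed on a sample: %s", method, exc)
                n_failed += 1
                continue
            if not fr.converged:
                n_failed += 1
                continue
            betas.append(fr.beta)
            ses.append(fr.se)
        b, se = np.asarray(betas), np.asarray(ses)
        out.append(
            StudySummary(
                method=method.upper(),
                sim_id=label,
                stats_beta=_order_stats(b),
                stats_se=_order_stats(se),
                sd_beta=float(np.std(b, ddof=1)) if len(b) > 1 else float("nan"),
                n_samples=len(samples),
                n_failed=n_failed,
                valid=len(b) > 0,
                betas=b,
                ses=se,
            )
        )
        if len(b) == 0:
            logger.error("all %d fits failed for method %s", len(samples), method)
    return out


def summarize_to_table(summaries: Sequence[StudySummary]) -> pd.DataFrame:
    """Arrange summaries in the per-method Beta1–Beta4 / SE1–SE4 layout.

    One block of six rows (Minimum, 1stQuartile, Median, Mean, 3rdQuartile,
    Maximum) per method, with a ``Beta<k>`` and an ``SE<k>`` column per
    scenario; missing scenario/method cells render as NA.
    """
    if len(summaries) == 0:
        raise ValueError("summaries must be non-empty")
    sims = sorted({s.sim_id for s in summaries}, key=str)
    sim_col = {sid: i + 1 for i, sid in enumerate(sims)}
    rows = []
    for method in dict.fromkeys(s.method for s in summaries):
        by_sim = {s.sim_id: s for s in summaries if s.method == method}
        for stat in _STAT_LABELS:
            row: dict[str, object] = {"Method": method, "Parameter": stat}
            for sid in sims:
                k = sim_col[sid]
                s = by_sim.get(sid)
                row[f"Beta{k}"] = s.stats_beta[stat] if s and s.valid else float("nan")
                row[f"SE{k}"] = s.stats_se[stat] if s and s.valid else float("nan")
            rows.append(row)
    cols = ["Method", "Parameter"]
    cols += [f"Beta{k}" for k in range(1, len(sims) + 1)]
    cols += [f"SE{k}" for k in range(1, len(sims) + 1)]
    return pd.DataFrame(rows)[cols]


def table_to_csv(table: pd.DataFrame, path) -> None:
    """Write a summary table with the 4-decimal presentation convention."""
    table.to_csv(path, index=False, float_format="%.4f")


def table_to_markdown(table: pd.DataFrame) -> str:
    """Render a summary table as a GitHub-style markdown table (4 decimals)."""

    def fmt(v) -> str:
        if isinstance(v, float):
            return "NA" if np.isnan(v) else f"{v:.4f}"
        return str(v)

    header = list(table.columns)
    lines = ["| " + " | ".join(header) + " |", "|" + "|".join("---" for _ in header) + "|"]
    for _, row in table.iterrows():
        lines.append("| " + " | ".join(fmt(v) for v in row) + " |")
    return "\n".join(lines)


def run_epi_analysis(
    series: DailySeries,
    scheme: StratumScheme,
    spec: ModelSpec | None = None,
    lag: int = 0,
) -> FitResult:
    """Stratified conditional Poisson analysis of a real daily count series.

    Applies the exposure lag, builds and filters the strata, and fits the
    conditional Poisson model.  Day-of-week enters as a covariate for the
    consecutive-day schemes and is absorbed by the design (auto-dropped)
    for the schemes whose strata fix day-of-week.
    """
    spec = spec or ModelSpec(family="poisson")
    if spec.family != "poisson":
        raise ValueError("run_epi_analysis fits daily counts; use family='poisson'")
    series.validate_family("poisson")
    if spec.temperature_spline_df and series.temperature is None:
        raise FitError("temperature spline requested but series has no temperature")
    lagged = apply_lag(series, lag)
    ds = informative_strata(assign_strata(lagged, scheme), family="poisson")
    return fit_conditional_poisson(ds, spec)
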