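"""Synthetic exposure–response series with shared mid-frequency periodicities.

The generator emulates the structure that defeats fixed-df spline adjustment
in time-series regression: exposure and outcome share sinusoidal components
at periods of a few months (too fast for the smooth-function-of-time term to
absorb, too slow for day-to-day contrasts to feel), so an unconditional
regression picks up the confounder while a short-window stratified fit does
not.  Four scenarios:

* **Sim1** — exposure/confounder periodicities at 183 and 75 days, white noise.
* **Sim2** — Sim1 plus further shared periodicities at 105 and 68 days.
* **Sim3** — Sim2's signal structure with AR(1) background noise.
* **Sim4** — Sim3 with both background noise scales doubled.

The outcome is continuous (Gaussian family), built as

    y_t = beta_true * x_t + confounder_t + noise_t,
    x_t = sum_k a_k sin(2 pi t / P_k + phi_k) + e_t,
    confounder_t = sum_k b_k sin(2 pi t / P_k + phi_k + delta) ,

with a fixed phase offset ``delta`` between the exposure's and the
confounder's periodic parts, so the shared periodicities genuinely confound
rather than cancel.  Every constant is an overridable, documented default
(see :class:`SimulationConfig`); none is taken from a published table.  The
module can also wrap externally published per-sample CSVs via
:func:`load_published_samples` for exact-reproduction workflows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .dataio import DailySeries, DataError, SeriesConfig, read_daily_csv

logger = logging.getLogger(__name__)

NOISE_MODELS = ("white", "ar1")

#: default shared periodicities (days) per scenario
SIM_PERIODS = {1: (183.0, 75.0), 2: (183.0, 75.0, 105.0, 68.0)}
SIM_PERIODS[3] = SIM_PERIODS[2]
SIM_PERIODS[4] = SIM_PERIODS[2]

#: fixed per-period exposure phases (radians); arbitrary but frozen for determinism
DEFAULT_PHASES = (0.0, 1.3, 2.1, 0.7)

#: phase offset between exposure and confounder sinusoids (radians)
DEFAULT_PHASE_OFFSET = 2.0 * np.pi / 3.0


@dataclass(frozen=True)
class SimulationConfig:
    """Generative constants for one simulation scenario.

    Defaults (amplitudes 2.0, exposure noise sd 1.0, outcome noise sd 0.5,
    phase offset 2*pi/3, AR(1) rho 0.6 for Sim3/4, noise scale factor 2 for
    Sim4) are package choices documented in the methods note; they produce a
    strongly confounded series on which a 6 df/year spline GLM is badly
    biased while the two-day stratified estimator stays near truth.
    """

    sim_id: int = 1
    n_years: int = 10
    days_per_year: int = 365
    beta_true: float = 1.0
    periods: tuple[float, ...] | None = None
    exposure_amplitudes: tuple[float, ...] | None = None
    confounder_amplitudes: tuple[float, ...] | None = None
    phases: tuple[float, ...] | str = "default"
    phase_offset: float = DEFAULT_PHASE_OFFSET
    noise_model: str = "default"
    exposure_noise_sd: float = 1.0
    outcome_noise_sd: float = 0.5
    ar1_rho: float = 0.6
    noise_scale_factor: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sim_id not in (1, 2, 3, 4):
            raise ValueError(f"sim_id must be 1..4, got {self.sim_id}")
        if self.noise_model == "default":
            object.__setattr__(self, "noise_model", "ar1" if self.sim_id >= 3 else "white")
        if self.noise_model not in NOISE_MODELS:
            raise ValueError(f"noise_model must be one of {NOISE_MODELS}")
        if self.sim_id == 4 and self.noise_scale_factor == 1.0:
            object.__setattr__(self, "noise_scale_factor", 2.0)
        if self.periods is None:
            object.__setattr__(self, "periods", SIM_PERIODS[self.sim_id])
        if any(p < 2 for p in self.periods):
            raise ValueError("periods must all be >= 2 days")
        k = len(self.periods)
        if self.exposure_amplitudes is None:
            object.__setattr__(self, "exposure_amplitudes", (2.0,) * k)
        if self.confounder_amplitudes is None:
            object.__setattr__(self, "confounder_amplitudes", (2.0,) * k)
        if self.phases == "default":
            object.__setattr__(self, "phases", DEFAULT_PHASES[:k])
        for name in ("exposure_amplitudes", "confounder_amplitudes"):
            amps = getattr(self, name)
            if len(amps) != k:
                raise ValueError(f"{name} must have one entry per period")
            if any(a < 0 for a in amps):
                raise ValueError(f"{name} must be non-negative")
        if self.phases != "random" and len(self.phases) != k:
            raise ValueError("phases must have one entry per period (or 'random')")

    @property
    def n_days(self) -> int:
        return self.n_years * self.days_per_year


@dataclass(frozen=True)
class SimulatedSample:
    """One generated series with its latent decomposition retained.

    Invariant: ``outcome == beta_true * exposure + confounder + noise``
    exactly (the components are stored, not re-derived).
    """

    series: DailySeries
    beta_true: float
    components: dict = field(default_factory=dict)

    def reconstruct_outcome(self) -> np.ndarray:
        c = self.components
        return self.beta_true * self.series.exposure + c["confounder"] + c["outcome_noise"]


def _noise(rng: np.random.Generator, n: int, sd: float, model: str, rho: float) -> np.ndarray:
    if sd == 0:
        return np.zeros(n)
    z = rng.standard_normal(n)
    if model == "white":
        return sd * z
    # AR(1) with marginal sd equal to `sd`; innovations scaled accordingly
    innov = sd * np.sqrt(1.0 - rho**2) * z
    innov[0] = sd * z[0]
    return lfilter([1.0], [1.0, -rho], innov)


def generate_sample(config: SimulationConfig, sample_index: int = 0) -> SimulatedSample:
    """Generate one exposure–response series under ``config``.

    The random stream is derived from ``(config.seed, sample_index)`` so a
    study set regenerates bit-identically and samples are independent.  The
    sinusoidal signal components are deterministic when phases are fixed;
    only the noise (and phases, if ``phases='random'``) varies by sample.
    """
    if sample_index < 0:
        raise ValueError("sample_index must be >= 0")
    rng = np.random.default_rng([config.seed, sample_index])
    n = config.n_days
    t = np.arange(n, dtype=float)
    if config.phases == "random":
        phases = rng.uniform(0.0, 2.0 * np.pi, size=len(config.periods))
    else:
        phases = np.asarray(config.phases, dtype=float)
    x_per = np.zeros(n)
    conf = np.zeros(n)
    for P, a, b, phi in zip(
        config.periods, config.exposure_amplitudes, config.confounder_amplitudes, phases
    ):
        ang = 2.0 * np.pi * t / P
        x_per += a * np.sin(ang + phi)
        conf += b * np.sin(ang + phi + config.phase_offset)
    scale = config.noise_scale_factor
    e = _noise(rng, n, scale * config.exposure_noise_sd, config.noise_model, config.ar1_rho)
    eps = _noise(rng, n, scale * config.outcome_noise_sd, config.noise_model, config.ar1_rho)
    exposure = x_per + e
    outcome = config.beta_true * exposure + conf + eps
    dates = pd.date_range("2001-01-01", periods=n, freq="D")
    series = DailySeries(
        dates=dates,
        outcome=outcome,
        exposure=exposure,
        meta={"sim_id": config.sim_id, "sample_index": sample_index, "seed": config.seed},
    )
    return SimulatedSample(
        series=series,
        beta_true=config.beta_true,
        components={
            "exposure_periodic": x_per,
            "exposure_noise": e,
            "confounder": conf,
            "outcome_noise": eps,
        },
    )


def generate_study_set(config: SimulationConfig, n_samples: int) -> list[SimulatedSample]:
    """Generate ``n_samples`` independent samples (deterministic per-sample seeds)."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    return [generate_sample(config, i) for i in range(n_samples)]


def load_published_samples(
    directory: str | Path, mapping: SeriesConfig | None = None, beta_true: float = 1.0
) -> list[SimulatedSample]:
    """Wrap a directory of per-sample CSV files as :class:`SimulatedSample` s.

    Intended for externally published simulation datasets; each file becomes
    a sample with the stated true slope and no latent decomposition.  Files
    are taken in sorted name order.  Unreadable or malformed files abort
    with a :class:`DataError` naming the offenders.
    """
    directory = Path(directory)
    files = sorted(directory.glob("*.csv"))
    if not files:
        logger.warning("no CSV files found in %s", directory)
        return []
    samples: list[SimulatedSample] = []
    bad: list[str] = []
    for f in files:
        try:
            series = read_daily_csv(f, mapping)
        except Exception as exc:  # noqa: BLE001 - collect per-file failures
            logger.error("failed to load %s: %s", f.name, exc)
            bad.append(f.name)
            continue
        samples.append(SimulatedSample(series=series, beta_true=beta_true, components={}))
    if bad:
        raise DataError(f"failed to load {len(bad)} file(s): {', '.join(bad)}")
    return samples
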