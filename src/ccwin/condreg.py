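"""Conditional regression with stratum nuisance elimination, plus comparators.

Two sklearn-style estimators form the core:

:class:`ConditionalPoissonRegressor`
    maximizes the Poisson likelihood conditioned on each stratum's total
    count.  Conditioning turns each stratum into a multinomial in the linear
    predictor, so the per-stratum intercepts drop out:

        l(theta) = sum_s [ sum_{i in s} y_i eta_i  -  Y_s log sum_{i in s} e^{eta_i} ]

    with eta_i = x_i' theta and Y_s the stratum total.  The log-likelihood is
    concave; Newton–Raphson with the analytic gradient and Hessian converges
    in a handful of steps.  This is the count analogue of conditional
    logistic regression on matched sets.

:class:`ConditionalGaussianRegressor`
    least squares with one intercept per stratum, computed by within-stratum
    centering of response and regressors (Frisch–Waugh) followed by OLS on
    the centered data.  Standard errors use residual df
    n_records − n_strata − n_parameters.

Also here: a hand-constructed natural cubic spline basis (B-splines under
natural boundary constraints, linear extrapolation) and the classical
time-series GLM comparator — outcome on exposure + day-of-week + a natural
spline of time at a chosen df/year — fitted through statsmodels.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.interpolate import BSpline
from scipy.linalg import null_space
from sklearn.base import BaseEstimator, RegressorMixin, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .dataio import DailySeries, FAMILIES
from .strata import StratifiedDataset

logger = logging.getLogger(__name__)

_DOW_NAMES = ("Mon", "Tue", "Wed", "Thu", "Fri", "Sat", "Sun")


class FitError(RuntimeError):
    """Raised when a model cannot be fitted on the given data."""


class IdentifiabilityError(FitError):
    """Raised when the exposure is collinear with retained covariates."""


@dataclass(frozen=True)
class ModelSpec:
    """What goes into the linear predictor besides the stratum levels.

    ``dow_factor`` adds day-of-week treatment dummies (Monday reference);
    under schemes whose strata already hold day-of-week fixed (CC2W, CC2CW,
    CCM) these are constant within every stratum and are auto-dropped with a
    notice — the design itself adjusts for day of week.
    ``temperature_spline_df`` adds a natural cubic spline of temperature
    with that many degrees of freedom (3 in typical use).
    """

    family: str = "gaussian"
    dow_factor: bool = True
    temperature_spline_df: int | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}")
        if self.temperature_spline_df is not None and self.temperature_spline_df < 1:
            raise ValueError("temperature_spline_df must be >= 1 when set")


@dataclass
class FitResult:
    """Slope estimate and diagnostics from a conditional or GLM fit."""

    method: str
    beta: float
    se: float
    ci95: tuple[float, float]
    covariate_estimates: dict[str, tuple[float, float]]
    loglik: float
    n_strata_used: int
    n_records_used: int
    converged: bool
    n_iter: int
    notes: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        d = dict(self.__dict__)
        d["ci95"] = list(self.ci95)
        d["covariate_estimates"] = {k: list(v) for k, v in self.covariate_estimates.items()}
        return json.dumps(d, indent=2)

    def to_csv_row(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "method": self.method,
                    "beta": self.beta,
                    "se": self.se,
                    "ci_lo": self.ci95[0],
                    "ci_hi": self.ci95[1],
                    "n_strata_used": self.n_strata_used,
                    "converged": self.converged,
                }
            ]
        )


# ---------------------------------------------------------------------------
# Natural cubic spline basis
# ---------------------------------------------------------------------------


class NaturalSpline(TransformerMixin, BaseEstimator):
    """Natural cubic spline basis with ``df`` columns.

    Boundary knots sit at the min/max of the training values and interior
    knots at the ``df - 1`` equally spaced interior quantiles.  The basis is
    built from cubic B-splines constrained to zero second derivative at (and
    linear extrapolation beyond) the boundary knots; one further constraint
    (value zero at the left boundary) removes the constant so the ``df``
    columns complement an explicit intercept.
    """

    def __init__(self, df: int = 3):
        self.df = df

    def fit(self, X, y=None):
        x = np.asarray(X, dtype=float).ravel()
        if self.df < 1:
            raise ValueError("df must be >= 1")
        if np.unique(x).size < self.df + 1:
            raise ValueError(f"need at least df+1={self.df + 1} distinct values, got {np.unique(x).size}")
        lo, hi = float(np.min(x)), float(np.max(x))
        if self.df > 1:
            probs = np.arange(1, self.df) / self.df
            interior = np.quantile(x, probs)
            # knots must be strictly inside and non-duplicated for a valid basis
            interior = np.unique(interior[(interior > lo) & (interior < hi)])
        else:
            interior = np.array([])
        t = np.concatenate([[lo] * 4, interior, [hi] * 4])
        m = len(interior) + 4
        # constraints: S''(lo)=S''(hi)=0 (natural) and S(lo)=0 (drop constant)
        C = np.empty((3, m))
        for j in range(m):
            coef = np.zeros(m)
            coef[j] = 1.0
            b = BSpline(t, coef, 3)
            C[0, j] = b.derivative(2)(lo)
            C[1, j] = b.derivative(2)(hi)
            C[2, j] = b(lo)
        N = null_space(C)
        if N.shape[1] != self.df:
            raise RuntimeError(f"degenerate knot layout: basis rank {N.shape[1]} != df {self.df}")
        self.knots_, self.lo_, self.hi_, self.coefs_ = t, lo, hi, N
        # boundary values/slopes of each basis column, for linear extrapolation
        self._b_lo = np.array([BSpline(t, N[:, k], 3)(lo) for k in range(self.df)])
        self._b_hi = np.array([BSpline(t, N[:, k], 3)(hi) for k in range(self.df)])
        self._s_lo = np.array([BSpline(t, N[:, k], 3).derivative(1)(lo) for k in range(self.df)])
        self._s_hi = np.array([BSpline(t, N[:, k], 3).derivative(1)(hi) for k in range(self.df)])
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "coefs_")
        x = np.asarray(X, dtype=float).ravel()
        inside = np.clip(x, self.lo_, self.hi_)
        B = BSpline.design_matrix(inside, self.knots_, 3).toarray()
        out = B @ self.coefs_
        below, above = x < self.lo_, x > self.hi_
        if below.any():
            out[below] = self._b_lo + np.outer(x[below] - self.lo_, self._s_lo)
        if above.any():
            out[above] = self._b_hi + np.outer(x[above] - self.hi_, self._s_hi)
        return out

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        return np.array([f"ns{k + 1}" for k in range(self.df)])


def natural_spline_basis(values: Sequence[float], df: int) -> np.ndarray:
    """n x df natural cubic spline basis of ``values`` (see :class:`NaturalSpline`)."""
    return NaturalSpline(df=df).fit_transform(np.asarray(values, dtype=float))


# ---------------------------------------------------------------------------
# Conditional estimators
# ---------------------------------------------------------------------------


def _group_codes(strata) -> tuple[np.ndarray, int]:
    codes, uniques = pd.factorize(np.asarray(strata), sort=True)
    return codes, len(uniques)


def _drop_stratum_constant(X: np.ndarray, codes: np.ndarray, names: list[str]):
    """Split columns into those varying within some stratum and those constant in all."""
    df = pd.DataFrame(X)
    g = df.groupby(codes)
    spread = (g.transform("max") - g.transform("min")).to_numpy()
    varies = spread.max(axis=0) > 1e-12
    dropped = [n for n, v in zip(names, varies) if not v]
    return X[:, varies], [n for n, v in zip(names, varies) if v], dropped


class ConditionalGaussianRegressor(RegressorMixin, BaseEstimator):
    """Linear regression with per-stratum intercepts profiled out.

    Equivalent to OLS with one indicator per stratum; computed by centering
    the response and every regressor within its stratum and running OLS on
    the centered data.  ``fit`` requires ``strata`` (per-row stratum labels).

    Attributes
    ----------
    coef_ : (p,) slope estimates (stratum intercepts are eliminated, not stored)
    se_ : (p,) standard errors at residual df = n - n_strata - p
    loglik_ : Gaussian log-likelihood at the MLE variance
    """

    def __init__(self, drop_constant_terms: bool = True):
        self.drop_constant_terms = drop_constant_terms

    def fit(self, X, y, strata=None):
        if strata is None:
            raise ValueError("strata (per-row stratum labels) are required")
        X, y = check_X_y(X, y, ensure_min_samples=2)
        codes, n_strata = _group_codes(strata)
        names = [f"x{j}" for j in range(X.shape[1])]
        dropped: list[str] = []
        if self.drop_constant_terms:
            X, kept, dropped = _drop_stratum_constant(X, codes, names)
            if dropped:
                logger.info("dropped stratum-constant column(s): %s", dropped)
            if X.shape[1] == 0:
                raise IdentifiabilityError("all regressors are constant within every stratum")
        n, p = X.shape
        ym = y - pd.Series(y).groupby(codes).transform("mean").to_numpy()
        Xm = X - pd.DataFrame(X).groupby(codes).transform("mean").to_numpy()
        df_resid = n - n_strata - p
        if df_resid <= 0:
            raise FitError(f"zero or negative residual df ({df_resid})")
        XtX = Xm.T @ Xm
        rank = np.linalg.matrix_rank(XtX)
        if rank < p:
            raise IdentifiabilityError("centered design is rank-deficient (collinear within strata)")
        coef = np.linalg.solve(XtX, Xm.T @ ym)
        resid = ym - Xm @ coef
        rss = float(resid @ resid)
        s2 = rss / df_resid
        cov = s2 * np.linalg.inv(XtX)
        sigma2_mle = rss / n
        self.coef_ = coef
        self.se_ = np.sqrt(np.diag(cov))
        self.cov_ = cov
        self.df_resid_ = df_resid
        self.loglik_ = -0.5 * n * (np.log(2 * np.pi * max(sigma2_mle, 1e-300)) + 1.0)
        self.rss_ = rss
        self.n_strata_ = n_strata
        self.n_features_in_ = p
        self.dropped_ = dropped
        self.converged_ = True
        self.n_iter_ = 1
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = check_array(X)
        # stratum levels are eliminated; predictions are relative (slope part only)
        return X @ self.coef_


class ConditionalPoissonRegressor(RegressorMixin, BaseEstimator):
    """Poisson regression conditioned on stratum totals (multinomial form).

    Newton–Raphson on the concave conditional log-likelihood with analytic
    gradient and Hessian; step-halving guards against overshoot.  A stratum
    contributes nothing when it has a zero total count or a single record,
    so such strata are harmless but are best filtered upstream.

    Attributes mirror :class:`ConditionalGaussianRegressor`; ``converged_``
    is False on monotone-likelihood divergence (infinite MLE), with the
    drift direction recorded in ``notes_``.
    """

    def __init__(
        self,
        max_iter: int = 100,
        tol_score: float = 1e-8,
        tol_step: float = 1e-10,
        drop_constant_terms: bool = True,
    ):
        self.max_iter = max_iter
        self.tol_score = tol_score
        self.tol_step = tol_step
        self.drop_constant_terms = drop_constant_terms

    @staticmethod
    def _loglik_parts(theta, X, y, codes, n_strata):
        eta = X @ theta
        df = pd.DataFrame({"eta": eta, "y": y})
        g = df.groupby(codes)
        # log-sum-exp within stratum, stabilized
        emax = g["eta"].transform("max").to_numpy()
        w = np.exp(eta - emax)
        sw = pd.Series(w).groupby(codes).transform("sum").to_numpy()
        logZ_per_record = np.log(sw) + emax  # stratum log-sum-exp, broadcast
        p_rec = w / sw  # within-stratum multinomial probabilities
        Ys = g["y"].transform("sum").to_numpy()
        first = np.zeros(len(eta), dtype=bool)
        first[np.unique(codes, return_index=True)[1]] = True
        ll = float(y @ eta - (Ys * logZ_per_record)[first].sum())
        return ll, p_rec, Ys

    @staticmethod
    def _information(X, mu, Ys, codes):
        """Observed information: sum_s Y_s [ X'diag(p)X - (X'p)(X'p)' ]."""
        info = X.T @ (X * mu[:, None])
        xbar = pd.DataFrame(X * mu[:, None]).groupby(codes).sum().to_numpy()  # = Y_s * xbar_s
        ybar = pd.Series(Ys).groupby(codes).first().to_numpy()
        info -= np.einsum("sj,sk->jk", xbar, xbar / np.maximum(ybar, 1e-300)[:, None])
        return info

    def fit(self, X, y, strata=None):
        if strata is None:
            raise ValueError("strata (per-row stratum labels) are required")
        X, y = check_X_y(X, y)
        if (y < 0).any() or not np.allclose(y, np.round(y)):
            raise ValueError("conditional Poisson requires non-negative integer outcomes")
        codes, n_strata = _group_codes(strata)
        names = [f"x{j}" for j in range(X.shape[1])]
        dropped: list[str] = []
        if self.drop_constant_terms:
            X, kept, dropped = _drop_stratum_constant(X, codes, names)
            if dropped:
                logger.info("dropped stratum-constant column(s): %s", dropped)
            if X.shape[1] == 0:
                raise IdentifiabilityError("all regressors are constant within every stratum")
        n, p = X.shape
        theta = np.zeros(p)
        ll, p_rec, Ys = self._loglik_parts(theta, X, y, codes, n_strata)
        converged = False
        notes: list[str] = []
        it = 0
        for it in range(1, self.max_iter + 1):
            mu = Ys * p_rec  # conditional expected counts
            score = X.T @ (y - mu)
            info = self._information(X, mu, Ys, codes)
            # concavity guard: the negated Hessian must stay PSD at every iterate
            min_eig = float(np.linalg.eigvalsh(info).min())
            if min_eig < -1e-8 * max(1.0, float(np.trace(info))):
                raise FitError(f"information matrix not PSD (min eigenvalue {min_eig:.3e})")
            if np.max(np.abs(score)) < self.tol_score:
                converged = True
                break
            try:
                step = np.linalg.solve(info + 1e-12 * np.eye(p), score)
            except np.linalg.LinAlgError as exc:
                raise IdentifiabilityError("singular information matrix") from exc
            # step-halving on likelihood decrease (concave ll: rarely triggers)
            for _ in range(30):
                new_theta = theta + step
                new_ll, new_p, _ = self._loglik_parts(new_theta, X, y, codes, n_strata)
                if new_ll >= ll - 1e-12:
                    break
                step = step / 2.0
            if np.max(np.abs(step)) < self.tol_step:
                theta, ll, p_rec = new_theta, new_ll, new_p
                converged = True
                break
            theta, ll, p_rec = new_theta, new_ll, new_p
        if np.max(np.abs(theta)) > 15.0:
            # score can fall below tolerance while the MLE sits at infinity
            # (monotone conditional likelihood); report as non-convergence.
            converged = False
            j = int(np.argmax(np.abs(theta)))
            notes.append(
                f"monotone likelihood: coefficient {j} diverges to "
                f"{'+inf' if theta[j] > 0 else '-inf'}"
            )
        mu = Ys * p_rec
        info = self._information(X, mu, Ys, codes)
        try:
            cov = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            cov = np.full((p, p), np.nan)
        self.coef_ = theta
        self.se_ = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
        self.cov_ = cov
        self.loglik_ = ll
        self.n_strata_ = n_strata
        self.n_features_in_ = p
        self.dropped_ = dropped
        self.converged_ = converged
        self.n_iter_ = it
        self.notes_ = notes
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = check_array(X)
        return np.exp(X @ self.coef_)


# ---------------------------------------------------------------------------
# Design-matrix assembly from a StratifiedDataset and high-level fit wrappers
# ---------------------------------------------------------------------------


def _build_design(ds: StratifiedDataset, spec: ModelSpec) -> tuple[np.ndarray, list[str]]:
    rec = ds.records
    cols = [rec["exposure"].to_numpy(dtype=float)]
    names = ["exposure"]
    if spec.dow_factor:
        for d in range(1, 7):  # Monday (0) is the reference level
            cols.append((rec["dow"].to_numpy() == d).astype(float))
            names.append(f"dow[{_DOW_NAMES[d]}]")
    if spec.temperature_spline_df:
        temp = rec["temperature"].to_numpy(dtype=float)
        if np.isnan(temp).any():
            raise FitError("temperature spline requested but temperature is missing")
        basis = natural_spline_basis(temp, spec.temperature_spline_df)
        for k in range(basis.shape[1]):
            cols.append(basis[:, k])
            names.append(f"temp_ns{k + 1}")
    return np.column_stack(cols), names


def _to_fit_result(est, ds: StratifiedDataset, names: list[str], method: str) -> FitResult:
    kept = [n for n in names if n not in est.dropped_]
    beta = float(est.coef_[kept.index("exposure")]) if "exposure" in kept else np.nan
    se = float(est.se_[kept.index("exposure")]) if "exposure" in kept else np.nan
    if "exposure" not in kept:
        raise IdentifiabilityError("exposure is constant within every stratum")
    cov_est = {
        n: (float(est.coef_[i]), float(est.se_[i])) for i, n in enumerate(kept) if n != "exposure"
    }
    notes = list(getattr(est, "notes_", []))
    if est.dropped_:
        notes.append(f"dropped stratum-constant terms: {', '.join(est.dropped_)}")
    return FitResult(
        method=method,
        beta=beta,
        se=se,
        ci95=(beta - 1.96 * se, beta + 1.96 * se),
        covariate_estimates=cov_est,
        loglik=float(est.loglik_),
        n_strata_used=int(est.n_strata_),
        n_records_used=int(ds.n_records),
        converged=bool(est.converged_),
        n_iter=int(est.n_iter_),
        notes=notes,
    )


def fit_conditional_gaussian(ds: StratifiedDataset, spec: ModelSpec | None = None) -> FitResult:
    """Fit the stratum-eliminated Gaussian model on a stratified dataset."""
    spec = spec or ModelSpec(family="gaussian")
    if ds.n_records == 0:
        raise FitError("no informative strata")
    X, names = _build_design(ds, spec)
    est = ConditionalGaussianRegressor().fit(
        X, ds.records["outcome"].to_numpy(dtype=float), strata=ds.records["stratum"].to_numpy()
    )
    # map generic x{j} back to term names for the dropped report
    est.dropped_ = [names[int(d[1:])] for d in est.dropped_]
    return _to_fit_result(est, ds, names, method=ds.scheme.name)


def fit_conditional_poisson(ds: StratifiedDataset, spec: ModelSpec | None = None) -> FitResult:
    """Fit the stratum-conditional Poisson (multinomial) model."""
    spec = spec or ModelSpec(family="poisson")
    if ds.n_records == 0:
        raise FitError("no informative strata")
    y = ds.records["outcome"].to_numpy(dtype=float)
    X, names = _build_design(ds, spec)
    est = ConditionalPoissonRegressor().fit(X, y, strata=ds.records["stratum"].to_numpy())
    est.dropped_ = [names[int(d[1:])] for d in est.dropped_]
    return _to_fit_result(est, ds, names, method=ds.scheme.name)


def fit_time_series_glm(
    series: DailySeries, spec: ModelSpec | None = None, df_per_year: float = 6.0
) -> FitResult:
    """Classical time-series regression: outcome ~ exposure + dow + ns(time).

    The smooth function of time is a natural cubic spline of the day index
    with ``round(df_per_year * n_years)`` degrees of freedom, where the
    years-span is the series length in days divided by 365.  Gaussian family
    uses OLS; Poisson uses a log-link GLM (statsmodels).
    """
    spec = spec or ModelSpec(family="gaussian")
    n_years = len(series) / 365.0
    df_time = int(round(df_per_year * n_years))
    if df_time < 1:
        raise ValueError("df_per_year x years must be >= 1")
    t = series.day_index.astype(float)
    cols = [np.ones(len(series)), series.exposure]
    names = ["const", "exposure"]
    if spec.dow_factor:
        dow = series.dates.dayofweek.to_numpy()
        for d in range(1, 7):
            cols.append((dow == d).astype(float))
            names.append(f"dow[{_DOW_NAMES[d]}]")
    basis = natural_spline_basis(t, df_time)
    for k in range(basis.shape[1]):
        cols.append(basis[:, k])
        names.append(f"time_ns{k + 1}")
    if spec.temperature_spline_df:
        if series.temperature is None:
            raise FitError("temperature spline requested but series has no temperature")
        tb = natural_spline_basis(series.temperature, spec.temperature_spline_df)
        for k in range(tb.shape[1]):
            cols.append(tb[:, k])
            names.append(f"temp_ns{k + 1}")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise IdentifiabilityError("time-series design matrix is rank-deficient")
    y = series.outcome
    keep = ~np.isnan(y) & ~np.isnan(series.exposure)
    X, y = X[keep], y[keep]
    if spec.family == "gaussian":
        res = sm.OLS(y, X).fit()
    else:
        res = sm.GLM(y, X, family=sm.families.Poisson()).fit()
    j = names.index("exposure")
    beta, se = float(res.params[j]), float(res.bse[j])
    return FitResult(
        method=f"GLM{df_per_year:g}",
        beta=beta,
        se=se,
        ci95=(beta - 1.96 * se, beta + 1.96 * se),
        covariate_estimates={
            n: (float(res.params[i]), float(res.bse[i])) for i, n in enumerate(names) if i != j
        },
        loglik=float(res.llf),
        n_strata_used=0,
        n_records_used=int(keep.sum()),
        converged=True,
        n_iter=int(getattr(res, "fit_history", {}).get("iteration", 1)) if spec.family == "poisson" else 1,
        notes=[f"time spline df={df_time} ({df_per_year:g}/year x {n_years:.2f} years)"],
    )
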