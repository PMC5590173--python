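"""Quasi-Poisson time-series regression of daily death counts on temperature.

The outcome model is

    Y_t ~ quasi-Poisson(mu_t)
    log mu_t = alpha + s(x_t; eta) + sum_j h_j(u_jt; gamma_j)

where s() is the cross-basis contribution of temperature and its lags and the
h_j are the confounder terms: day-of-week indicators and a natural cubic
spline of calendar time with 8 degrees of freedom per year absorbing seasonal
and long-term mortality patterns.  Point estimates coincide with the Poisson
maximum-likelihood fit; overdispersion phi is estimated by Pearson chi2 over
residual degrees of freedom and inflates the coefficient covariance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .basis import BasisMatrix, SplineSpec, evaluate_spline

__all__ = [
    "TimeSeriesData",
    "ConfounderDesign",
    "GLMFit",
    "build_confounders",
    "fit_quasipoisson",
]


@dataclass
class TimeSeriesData:
    """Daily mortality series: consecutive dates, death counts, mean temperature."""

    dates: pd.DatetimeIndex
    deaths: np.ndarray
    temperature: np.ndarray

    def __post_init__(self) -> None:
        self.dates = pd.DatetimeIndex(self.dates)
        self.deaths = np.asarray(self.deaths)
        self.temperature = np.asarray(self.temperature, dtype=float)
        n = len(self.dates)
        if len(self.deaths) != n or len(self.temperature) != n:
            raise ValueError("dates, deaths and temperature must have equal length")
        if n == 0:
            raise ValueError("empty series")
        gaps = np.flatnonzero(np.diff(self.dates.values) != np.timedelta64(1, "D"))
        if gaps.size:
            missing = self.dates[gaps[0]] + pd.Timedelta(days=1)
            raise ValueError(f"dates are not consecutive: gap after {self.dates[gaps[0]].date()}"
                             f" (missing {missing.date()})")
        if np.any(self.deaths < 0):
            i = int(np.flatnonzero(self.deaths < 0)[0])
            raise ValueError(f"negative death count at {self.dates[i].date()}")
        if not np.issubdtype(self.deaths.dtype, np.integer):
            if not np.allclose(self.deaths, np.round(self.deaths)):
                raise ValueError("death counts must be integers")
            self.deaths = self.deaths.astype(np.int64)

    def __len__(self) -> int:
        return len(self.dates)

    @property
    def n_years(self) -> float:
        return len(self.dates) / 365.25

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"date": self.dates, "deaths": self.deaths, "temperature": self.temperature}
        )


@dataclass
class ConfounderDesign:
    """Day-of-week indicators plus a smooth function of calendar time."""

    dow: np.ndarray  # (n, 6) indicator contrasts, Monday as reference
    time_spline: np.ndarray  # (n, df) natural cubic basis of the day index
    column_labels: list[str] = field(default_factory=list)
    extra_terms: np.ndarray | None = None

    @property
    def values(self) -> np.ndarray:
        blocks = [self.dow, self.time_spline]
        if self.extra_terms is not None:
            blocks.append(self.extra_terms)
        return np.column_stack(blocks)


def build_confounders(dates: pd.DatetimeIndex, df_per_year: float = 8.0) -> ConfounderDesign:
    """Indicator contrasts for day of week and a time spline with
    ``round(df_per_year * n_years)`` columns (knots at day-index quantiles)."""
    dates = pd.DatetimeIndex(dates)
    n = len(dates)
    if n < 365:
        raise ValueError("need at least one year of dates")
    dow = np.zeros((n, 6))
    dow_codes = dates.dayofweek.values  # Monday=0 reference
    for j in range(6):
        dow[:, j] = dow_codes == j + 1

    df = int(round(df_per_year * n / 365.25))
    day = np.arange(n, dtype=float)
    # natural cubic basis without intercept: df columns need df - 1 internal knots
    probs = np.linspace(0, 1, df + 1)[1:-1]
    internal = tuple(np.quantile(day, probs))
    spec = SplineSpec(
        family="natural_cubic",
        internal_knots=internal,
        boundary_knots=(0.0, float(n - 1)),
        intercept=False,
    )
    ts = evaluate_spline(day, spec).values
    labels = [f"dow{j + 1}" for j in range(6)] + [f"time{j + 1}" for j in range(df)]
    return ConfounderDesign(dow=dow, time_spline=ts, column_labels=labels)


@dataclass
class GLMFit:
    """Fitted quasi-Poisson model: cross-basis coefficients, their
    dispersion-scaled covariance, confounder coefficients and phi."""

    eta_hat: np.ndarray
    vcov_eta: np.ndarray
    gamma_hat: np.ndarray
    dispersion: float
    converged: bool
    n_obs: int
    fitted_means: np.ndarray
    vcov_eta_poisson: np.ndarray


class ConvergenceError(RuntimeError):
    pass


def fit_quasipoisson(
    data: TimeSeriesData,
    crossbasis: BasisMatrix,
    confounders: ConfounderDesign,
) -> GLMFit:
    """Fit the quasi-Poisson GLM with intercept + cross-basis + confounders.

    Rows lost to the lag history (``crossbasis.first_row``) are dropped from
    all blocks.  Raises on non-convergence or a rank-deficient design.
    """
    L = crossbasis.first_row
    y = data.deaths[L:]
    X_cb = crossbasis.values
    X_conf = confounders.values[L:]
    if X_cb.shape[0] != y.shape[0] or X_conf.shape[0] != y.shape[0]:
        raise ValueError("misaligned design blocks after dropping lag history")
    n = y.shape[0]
    X = np.column_stack([np.ones(n), X_cb, X_conf])
    p = X.shape[1]
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        # identify the offending block for the error message
        cb_rank = np.linalg.matrix_rank(np.column_stack([np.ones(n), X_cb]))
        block = "cross-basis" if cb_rank < X_cb.shape[1] + 1 else "confounder"
        raise np.linalg.LinAlgError(
            f"design matrix is rank deficient (rank {rank} < {p}); "
            f"collinearity in the {block} block"
        )

    res = sm.GLM(y, X, family=sm.families.Poisson()).fit(maxiter=100, tol=1e-8)
    if not res.converged:
        raise ConvergenceError("IRLS did not converge within 100 iterations")

    k = X_cb.shape[1]
    dof = n - p
    dispersion = float(res.pearson_chi2 / dof) if dof > 0 else 0.0
    cov = np.asarray(res.cov_params())  # Poisson (scale = 1) covariance
    vcov_poisson = cov[1 : 1 + k, 1 : 1 + k]
    return GLMFit(
        eta_hat=res.params[1 : 1 + k],
        vcov_eta=dispersion * vcov_poisson,
        gamma_hat=np.concatenate([[res.params[0]], res.params[1 + k :]]),
        dispersion=dispersion,
        converged=bool(res.converged),
        n_obs=n,
        fitted_means=np.asarray(res.fittedvalues),
        vcov_eta_poisson=vcov_poisson,
    )
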