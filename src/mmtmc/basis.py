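"""Spline bases, the DLNM cross-basis, and reduction to lag-cumulated coefficients.

The exposure-response dimension uses a quadratic B-spline basis phi_1..phi_vx
and the lag dimension a natural cubic spline basis psi_1..psi_vl (or a plain
moving average as the degenerate one-column case).  The cross-basis couples
the two: column (j, k) of the design holds

    sum_{l=0..L} phi_j(x_{t-l}) psi_k(l)

for day t, so the linear predictor contribution is the bilinear form of the
coefficient vector eta with the two bases.  Summing the fitted surface over
lags collapses eta to the coefficients beta of the lag-cumulated curve via
the linear map beta = M eta with M = 1'C (x) I, where C holds the lag-basis
evaluations at lags 0..L.  All downstream minimum-mortality-temperature and
relative-risk inference operates on beta and its covariance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.interpolate import BSpline

__all__ = [
    "SplineSpec",
    "CrossBasisSpec",
    "BasisMatrix",
    "ReducedFit",
    "evaluate_spline",
    "lag_basis_matrix",
    "build_crossbasis",
    "reduce_coefficients",
    "log_knots",
    "InvalidSpecError",
    "ExtrapolationError",
    "InsufficientDataError",
]


class InvalidSpecError(ValueError):
    """Raised for malformed spline or cross-basis specifications."""


class ExtrapolationError(ValueError):
    """Raised when a basis is evaluated outside its boundary knots."""


class InsufficientDataError(ValueError):
    """Raised when a series is too short for the requested lag structure."""


SplineFamily = Literal["quadratic_bspline", "natural_cubic"]


@dataclass(frozen=True)
class SplineSpec:
    """A one-dimensional spline basis specification.

    Parameters
    ----------
    family
        ``"quadratic_bspline"`` (degree-2 B-spline, de Boor evaluation) or
        ``"natural_cubic"`` (cubic with zero second derivative at and linear
        extrapolation beyond the boundary knots).
    internal_knots
        Strictly increasing knots strictly inside the boundary interval.
    boundary_knots
        ``(lower, upper)`` limits of the basis domain.
    intercept
        Whether the basis spans constants.  Without the intercept the first
        basis function is dropped (the R ``bs()``/``ns()`` convention), which
        anchors the spanned curve to zero at the lower boundary.
    """

    family: SplineFamily
    internal_knots: tuple[float, ...]
    boundary_knots: tuple[float, float]
    intercept: bool = False

    def __post_init__(self) -> None:
        knots = tuple(float(k) for k in self.internal_knots)
        lo, hi = (float(b) for b in self.boundary_knots)
        object.__setattr__(self, "internal_knots", knots)
        object.__setattr__(self, "boundary_knots", (lo, hi))
        if not lo < hi:
            raise InvalidSpecError(f"boundary knots must increase: {lo} >= {hi}")
        if any(b <= a for a, b in zip(knots, knots[1:])):
            raise InvalidSpecError(f"internal knots must strictly increase: {knots}")
        if knots and not (lo < knots[0] and knots[-1] < hi):
            raise InvalidSpecError(
                f"internal knots {knots} must lie strictly inside ({lo}, {hi})"
            )
        if self.family not in ("quadratic_bspline", "natural_cubic"):
            raise InvalidSpecError(f"unknown spline family {self.family!r}")

    @property
    def dim(self) -> int:
        """Number of basis columns."""
        n = len(self.internal_knots)
        if self.family == "quadratic_bspline":
            full = n + 3  # n + degree + 1
        else:
            full = n + 2  # all knots (internal + 2 boundary)
        return full if self.intercept else full - 1


@dataclass(frozen=True)
class CrossBasisSpec:
    """Bidimensional (temperature x lag) basis specification.

    ``moving_average=True`` is the degenerate single-lag-column case in which
    the temperature basis is applied to the (L+1)-day trailing moving average
    of the exposure; the cross-basis coefficients then already are the
    lag-cumulated coefficients.
    """

    temp_spline: SplineSpec
    max_lag: int
    lag_spline: SplineSpec | None = None
    moving_average: bool = False

    def __post_init__(self) -> None:
        if self.max_lag < 0:
            raise InvalidSpecError("max_lag must be nonnegative")
        if not self.moving_average and self.lag_spline is None and self.max_lag > 0:
            raise InvalidSpecError("need a lag spline or the moving-average flag when max_lag > 0")

    @property
    def v_x(self) -> int:
        return self.temp_spline.dim

    @property
    def v_l(self) -> int:
        if self.moving_average or self.lag_spline is None:
            return 1
        return self.lag_spline.dim

    @property
    def dim(self) -> int:
        return self.v_x * self.v_l


@dataclass
class BasisMatrix:
    """Evaluated basis: rows are evaluation points, columns basis functions."""

    values: np.ndarray
    column_labels: list[str]
    spec: SplineSpec | CrossBasisSpec
    first_row: int = 0  # index of the first usable day in the source series

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size and not np.all(np.isfinite(self.values)):
            raise ValueError("basis matrix contains non-finite entries")


def _bspline_design(x: np.ndarray, spec: SplineSpec) -> np.ndarray:
    degree = 2
    lo, hi = spec.boundary_knots
    t = np.concatenate(
        [np.repeat(lo, degree + 1), spec.internal_knots, np.repeat(hi, degree + 1)]
    )
    if x.size == 0:
        return np.empty((0, len(spec.internal_knots) + degree + 1))
    mat = BSpline.design_matrix(x, t, degree, extrapolate=False).toarray()
    return mat


def _natural_cubic_design(x: np.ndarray, spec: SplineSpec) -> np.ndarray:
    # Truncated-power natural basis: 1, x, then K-2 functions d_k - d_{K-1}
    # built from (x - xi)^3_+ differences; linear beyond the boundary knots.
    lo, hi = spec.boundary_knots
    xi = np.asarray((lo, *spec.internal_knots, hi))
    K = len(xi)
    cols = [np.ones_like(x), x]

    def d(k: int) -> np.ndarray:
        num = np.clip(x - xi[k], 0.0, None) ** 3 - np.clip(x - xi[K - 1], 0.0, None) ** 3
        return num / (xi[K - 1] - xi[k])

    d_last = d(K - 2)
    for k in range(K - 2):
        cols.append(d(k) - d_last)
    return np.column_stack(cols)


def evaluate_spline(
    x: np.ndarray, spec: SplineSpec, *, extrapolate: bool = False
) -> BasisMatrix:
    """Evaluate the spline basis at the points ``x``.

    By default points outside the boundary knots raise
    :class:`ExtrapolationError` (in normal use the boundary knots sit at the
    observed data range, so this never triggers).  With ``extrapolate=True``
    the natural cubic basis extends linearly and the B-spline basis by its
    boundary polynomial pieces.
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.size and not np.all(np.isfinite(x)):
        raise ValueError("evaluation points must be finite")
    lo, hi = spec.boundary_knots
    tol = 1e-10 * max(1.0, abs(lo), abs(hi))
    if x.size and not extrapolate:
        if x.min() < lo - tol or x.max() > hi + tol:
            raise ExtrapolationError(
                f"points in [{x.min():.4g}, {x.max():.4g}] fall outside the "
                f"boundary knots ({lo:.4g}, {hi:.4g})"
            )
    xc = np.clip(x, lo, hi) if not extrapolate else x

    if spec.family == "quadratic_bspline":
        if extrapolate:
            # extend by the outermost polynomial pieces
            t = np.concatenate([np.repeat(lo, 3), spec.internal_knots, np.repeat(hi, 3)])
            n_basis = len(spec.internal_knots) + 3
            full = np.column_stack(
                [
                    BSpline(t, np.eye(n_basis)[j], 2, extrapolate=True)(x)
                    for j in range(n_basis)
                ]
            ) if x.size else np.empty((0, n_basis))
        else:
            full = _bspline_design(xc, spec)
        labels = [f"bs{j + 1}" for j in range(full.shape[1])]
    else:
        full = _natural_cubic_design(x if extrapolate else xc, spec)
        labels = [f"ns{j + 1}" for j in range(full.shape[1])]

    if not spec.intercept:
        full = full[:, 1:]
        labels = labels[1:]
    return BasisMatrix(values=full, column_labels=labels, spec=spec)


def log_knots(max_lag: int, n_knots: int = 3) -> tuple[float, ...]:
    """Internal lag knots at equally spaced points on the log scale.

    Knots are exp of equally spaced values between log(1) and log(max_lag)
    excluding both endpoints, the standard placement for distributed-lag
    bases over lags 0..L.
    """
    if max_lag < 2:
        raise InvalidSpecError("log-scale lag knots need max_lag >= 2")
    pts = np.linspace(np.log(1.0), np.log(float(max_lag)), n_knots + 2)[1:-1]
    return tuple(np.exp(pts))


def lag_basis_matrix(spec: CrossBasisSpec) -> np.ndarray:
    """The (L+1) x v_l matrix C of lag-basis evaluations at lags 0..L."""
    lags = np.arange(spec.max_lag + 1, dtype=float)
    if spec.moving_average or spec.lag_spline is None:
        # constant lag weight 1/(L+1): the moving-average special case
        return np.full((spec.max_lag + 1, 1), 1.0 / (spec.max_lag + 1))
    return evaluate_spline(lags, spec.lag_spline, extrapolate=True).values


def build_crossbasis(temps: np.ndarray, spec: CrossBasisSpec) -> BasisMatrix:
    """Assemble the cross-basis design from a daily temperature series.

    Row ``i`` corresponds to day ``L + i`` of the input series (the first L
    days lack a complete lag history and are dropped).  Columns are ordered
    with the temperature-basis index fastest and the lag-basis index slowest,
    i.e. column ``k * v_x + j`` holds sum_l phi_j(x_{t-l}) psi_k(l); this
    matches the Kronecker structure of the reducing matrix 1'C (x) I.
    """
    temps = np.asarray(temps, dtype=float).ravel()
    L = spec.max_lag
    if temps.size < L + 1:
        raise InsufficientDataError(
            f"series of length {temps.size} is shorter than max_lag + 1 = {L + 1}"
        )
    n_out = temps.size - L

    if spec.moving_average:
        # temperature basis applied to the (L+1)-day trailing moving average
        ma = np.convolve(temps, np.full(L + 1, 1.0 / (L + 1)), mode="valid")
        tb = evaluate_spline(ma, spec.temp_spline)
        return BasisMatrix(
            values=tb.values,
            column_labels=[f"cb.{lab}" for lab in tb.column_labels],
            spec=spec,
            first_row=L,
        )

    B = evaluate_spline(temps, spec.temp_spline).values  # (N, v_x)
    C = lag_basis_matrix(spec)  # (L+1, v_l)
    # stacked lagged temperature bases: S[i, l, j] = phi_j(x_{L+i-l})
    S = np.stack([B[L - l : temps.size - l] for l in range(L + 1)], axis=1)
    X = np.einsum("ilj,lk->ikj", S, C).reshape(n_out, spec.v_l * spec.v_x)
    labels = [
        f"cb.l{k + 1}.t{j + 1}" for k in range(spec.v_l) for j in range(spec.v_x)
    ]
    return BasisMatrix(values=X, column_labels=labels, spec=spec, first_row=L)


@dataclass
class ReducedFit:
    """Lag-cumulated coefficients beta with covariance V(beta).

    The substrate of all MMT and RR inference: the lag-cumulated log relative
    risk at temperature x is Q_x beta where Q_x is the temperature-basis row
    vector at x.  ``temp_grid`` is the evaluation grid spanning the observed
    temperature range; ``observed_percentiles`` maps percentiles of the
    observed exposure series to temperatures (linear interpolation between
    order statistics).
    """

    beta: np.ndarray
    vcov: np.ndarray
    temp_spline: SplineSpec
    temp_grid: np.ndarray
    observed_temps: np.ndarray | None = None
    observed_percentiles: dict[float, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float).ravel()
        self.vcov = np.asarray(self.vcov, dtype=float)
        self.temp_grid = np.asarray(self.temp_grid, dtype=float).ravel()
        v_x = self.temp_spline.dim
        if self.beta.size != v_x:
            raise InvalidSpecError(
                f"beta has length {self.beta.size}, expected v_x = {v_x}"
            )
        if self.vcov.shape != (v_x, v_x):
            raise InvalidSpecError(f"vcov has shape {self.vcov.shape}, expected ({v_x}, {v_x})")
        if not np.allclose(self.vcov, self.vcov.T, atol=1e-8):
            raise InvalidSpecError("vcov is not symmetric")
        if np.any(np.diff(self.temp_grid) <= 0):
            raise InvalidSpecError("temp_grid must be strictly increasing")
        if self.observed_temps is not None:
            self.observed_temps = np.sort(np.asarray(self.observed_temps, dtype=float))
            if not self.observed_percentiles:
                ps = [0, 1, 2.5, 5, 10, 25, 50, 75, 90, 95, 97.5, 99, 100]
                self.observed_percentiles = {
                    float(p): float(np.percentile(self.observed_temps, p)) for p in ps
                }

    def percentile(self, p: float) -> float:
        """Observed-temperature percentile by linear order-statistic interpolation."""
        p = float(p)
        if p in self.observed_percentiles:
            return self.observed_percentiles[p]
        if self.observed_temps is None:
            raise ValueError("no observed temperature series attached to this fit")
        return float(np.percentile(self.observed_temps, p))

    def q_matrix(self, x: np.ndarray) -> np.ndarray:
        """Rows Q_x of temperature-basis evaluations at ``x``."""
        return evaluate_spline(np.asarray(x, dtype=float), self.temp_spline).values


def default_grid(temps: np.ndarray, step: float = 0.1) -> np.ndarray:
    """Evaluation grid from min to max observed temperature at ``step`` degC."""
    temps = np.asarray(temps, dtype=float)
    lo, hi = float(temps.min()), float(temps.max())
    grid = np.arange(lo, hi, step)
    if grid.size == 0 or grid[-1] < hi - 1e-12:
        grid = np.append(grid, hi)
    return grid


def reduce_coefficients(
    eta: np.ndarray,
    vcov_eta: np.ndarray,
    spec: CrossBasisSpec,
    temps: np.ndarray | None = None,
    grid_step: float = 0.1,
) -> ReducedFit:
    """Collapse cross-basis coefficients to lag-cumulated coefficients.

    Computes beta = M eta and V(beta) = M V(eta) M' with the reducing matrix
    M = 1'C (x) I_{v_x}, C the lag-basis evaluation matrix.  For the
    moving-average special case M is the identity.  If ``temps`` (the raw
    daily series) is given, the moving-average exposure metric, evaluation
    grid and observed percentiles are attached to the result.
    """
    eta = np.asarray(eta, dtype=float).ravel()
    vcov_eta = np.asarray(vcov_eta, dtype=float)
    if eta.size != spec.dim:
        raise InvalidSpecError(f"eta has length {eta.size}, expected {spec.dim}")
    if vcov_eta.shape != (spec.dim, spec.dim):
        raise InvalidSpecError(
            f"vcov_eta has shape {vcov_eta.shape}, expected ({spec.dim}, {spec.dim})"
        )

    if spec.moving_average:
        M = np.eye(spec.v_x)
    else:
        C = lag_basis_matrix(spec)  # (L+1, v_l)
        ones_C = np.sum(C, axis=0)[None, :]  # 1'C, shape (1, v_l)
        M = np.kron(ones_C, np.eye(spec.v_x))  # (v_x, v_l * v_x)
    beta = M @ eta
    vcov = M @ vcov_eta @ M.T
    vcov = 0.5 * (vcov + vcov.T)

    if temps is not None:
        temps = np.asarray(temps, dtype=float).ravel()
        L = spec.max_lag
        exposure = (
            np.convolve(temps, np.full(L + 1, 1.0 / (L + 1)), mode="valid")
            if spec.moving_average
            else temps
        )
        grid = default_grid(exposure, grid_step)
        return ReducedFit(
            beta=beta,
            vcov=vcov,
            temp_spline=spec.temp_spline,
            temp_grid=grid,
            observed_temps=exposure,
        )
    lo, hi = spec.temp_spline.boundary_knots
    return ReducedFit(
        beta=beta,
        vcov=vcov,
        temp_spline=spec.temp_spline,
        temp_grid=default_grid(np.array([lo, hi]), grid_step),
    )
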