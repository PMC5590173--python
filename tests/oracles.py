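"""Independent reference implementations used to pin the package's algebra.

Each oracle is a deliberately literal, loop-based computation kept separate
from the library code paths it checks.
"""

from __future__ import annotations

import numpy as np


def deboor_bspline(x: float, t: np.ndarray, degree: int, j: int) -> float:
    """B_{j,degree}(x) by the Cox-de Boor recursion, evaluated pointwise."""
    if degree == 0:
        # half-open intervals, closed at the right end of the base interval
        if t[j] <= x < t[j + 1]:
            return 1.0
        if x == t[-1] and t[j] < t[j + 1] and t[j + 1] == t[-1]:
            return 1.0
        return 0.0
    left = 0.0
    if t[j + degree] > t[j]:
        left = (x - t[j]) / (t[j + degree] - t[j]) * deboor_bspline(x, t, degree - 1, j)
    right = 0.0
    if t[j + degree + 1] > t[j + 1]:
        right = (t[j + degree + 1] - x) / (t[j + degree + 1] - t[j + 1]) * deboor_bspline(
            x, t, degree - 1, j + 1
        )
    return left + right


def quadratic_bspline_design(x: np.ndarray, internal: tuple, boundary: tuple) -> np.ndarray:
    """Full (intercept-included) quadratic B-spline basis via the recursion."""
    lo, hi = boundary
    t = np.concatenate([[lo] * 3, list(internal), [hi] * 3])
    n_basis = len(internal) + 3
    out = np.empty((len(x), n_basis))
    for i, xi in enumerate(x):
        for j in range(n_basis):
            out[i, j] = deboor_bspline(float(xi), t, 2, j)
    return out


def crossbasis_triple_loop(
    temps: np.ndarray, phi: callable, psi: callable, L: int, v_x: int, v_l: int
) -> np.ndarray:
    """Cross-basis design by the literal double sum over basis indices with an
    explicit lag loop: column (j, k) of row t is sum_l phi_j(x_{t-l}) psi_k(l)."""
    n = len(temps)
    out = np.zeros((n - L, v_l * v_x))
    for row, tt in enumerate(range(L, n)):
        for k in range(v_l):
            for j in range(v_x):
                s = 0.0
                for lag in range(L + 1):
                    s += phi(temps[tt - lag], j) * psi(lag, k)
                out[row, k * v_x + j] = s
    return out


def lag_cumulated_curve(
    x: float, eta: np.ndarray, phi: callable, psi: callable, L: int, v_x: int, v_l: int
) -> float:
    """Brute-force lag-cumulated log RR at constant temperature x:
    sum_l sum_j sum_k phi_j(x) psi_k(l) eta_{jk}."""
    s = 0.0
    for lag in range(L + 1):
        for k in range(v_l):
            for j in range(v_x):
                s += phi(x, j) * psi(lag, k) * eta[k * v_x + j]
    return s


def poisson_irls(y: np.ndarray, X: np.ndarray, tol: float = 1e-10,
                 maxiter: int = 200) -> np.ndarray:
    """Plain Poisson IRLS (log link), coded independently of statsmodels."""
    beta = np.zeros(X.shape[1])
    beta[0] = np.log(max(y.mean(), 1e-8))
    dev_old = np.inf
    for _ in range(maxiter):
        eta = X @ beta
        mu = np.exp(np.clip(eta, -30, 30))
        W = mu
        z = eta + (y - mu) / mu
        XtW = X.T * W
        beta = np.linalg.solve(XtW @ X, XtW @ z)
        with np.errstate(divide="ignore", invalid="ignore"):
            dev = 2 * np.sum(np.where(y > 0, y * np.log(y / mu), 0.0) - (y - mu))
        if abs(dev_old - dev) < tol * (abs(dev) + 0.1):
            break
        dev_old = dev
    return beta


def rr_samples_literal(
    Q_of, x: float, thetas: np.ndarray, betas: np.ndarray
) -> np.ndarray:
    """Literal per-draw relative-risk computation: for each i,
    zeta_i = (Q_x - Q_{theta_i}) beta_i and RR_i = exp(zeta_i)."""
    Qx = Q_of(np.array([x]))[0]
    out = np.empty(len(thetas))
    for i in range(len(thetas)):
        Qt = Q_of(np.array([thetas[i]]))[0]
        out[i] = np.exp(float((Qx - Qt) @ betas[i]))
    return out


def fine_grid_argmin(fit, step: float = 0.001) -> float:
    """Exhaustive brute-force scan of Q_x beta at ``step`` resolution."""
    lo, hi = fit.temp_grid[0], fit.temp_grid[-1]
    fine = np.append(np.arange(lo, hi, step), hi)
    curve = fit.q_matrix(fine) @ fit.beta
    return float(fine[int(np.argmin(curve))])
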