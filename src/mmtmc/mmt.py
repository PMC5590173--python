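"""Point and interval estimation of the minimum mortality temperature (MMT).

Four estimators operate on a :class:`~mmtmc.basis.ReducedFit`:

* ``Argmin1`` — the grid temperature minimising the fitted lag-cumulated
  curve Q_x beta-hat over the full observed range (point only).
* ``Argmin2`` — the same, constrained to the 1st-99th observed temperature
  percentiles (point only).
* ``Empirical1`` — an approximate parametric bootstrap: draw
  beta_(i) ~ MVN(beta-hat, V(beta-hat)) and take theta_(i) = argmin Q_x beta_(i);
  the empirical mean (or median) and percentiles of theta_(i) give point and
  interval estimates.
* ``Empirical2`` — the same proposal mechanism filtered through a Uniform
  prior on the MMT with support (alpha1, alpha2): draws whose argmin falls
  outside the support are rejected, yielding the posterior MMT distribution
  under that prior.

All argmins are grid argmins (0.1 degC default step); ties break toward the
lowest temperature.  For a highly right-skewed empirical distribution the
interval percentile pair can be switched from (2.5, 97.5) to (0, 95); sample
skewness is reported so callers can judge, but no automatic switch is made.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .basis import ReducedFit

__all__ = [
    "PriorSupport",
    "MMTResult",
    "log_rr_curve",
    "argmin_mmt",
    "sample_mmt",
    "summarize_mmt",
    "IncompatiblePriorError",
]

#: proposal budget multiplier and acceptance floor for the rejection sampler
REJECTION_BUDGET = 100
ACCEPTANCE_FLOOR = 0.005
DEFAULT_N_SIM = 5000
DEFAULT_PAIR = (2.5, 97.5)
SKEW_ADJUSTED_PAIR = (0.0, 95.0)


class IncompatiblePriorError(RuntimeError):
    """The prior support is (nearly) disjoint from the sampled MMT distribution."""


@dataclass(frozen=True)
class PriorSupport:
    """Uniform prior support (alpha1, alpha2) for the MMT.

    ``mode="percentile"`` interprets the bounds as percentiles of the
    observed temperature distribution; ``mode="absolute"`` as degrees C.
    """

    lower: float
    upper: float
    mode: str = "percentile"

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError(f"prior support must have lower < upper, got ({self.lower}, {self.upper})")
        if self.mode not in ("percentile", "absolute"):
            raise ValueError(f"unknown prior mode {self.mode!r}")
        if self.mode == "percentile" and not (0 <= self.lower and self.upper <= 100):
            raise ValueError("percentile bounds must lie in [0, 100]")

    def resolve(self, fit: ReducedFit) -> tuple[float, float]:
        """Support in degrees C for a given fit."""
        if self.mode == "absolute":
            return float(self.lower), float(self.upper)
        return fit.percentile(self.lower), fit.percentile(self.upper)


@dataclass
class MMTResult:
    """MMT estimate: point, interval (empirical methods), and the Monte Carlo
    samples theta_(i) paired with their generating coefficient draws."""

    method: str
    point: float
    interval: tuple[float, float] | None = None
    samples: np.ndarray | None = None
    beta_samples: np.ndarray | None = None
    n_proposed: int = 0
    n_accepted: int = 0
    percentile_pair: tuple[float, float] | None = None
    point_rule: str | None = None
    skewness: float | None = None

    @property
    def length(self) -> float | None:
        if self.interval is None:
            return None
        return self.interval[1] - self.interval[0]


def log_rr_curve(fit: ReducedFit, grid: np.ndarray | None = None) -> np.ndarray:
    """Lag-cumulated log relative risk Q_x beta on the grid (unreferenced scale)."""
    g = fit.temp_grid if grid is None else np.asarray(grid, dtype=float)
    return fit.q_matrix(g) @ fit.beta


def _constrained_grid(fit: ReducedFit, constraint: tuple[float, float] | None) -> np.ndarray:
    grid = fit.temp_grid
    if constraint is None:
        return grid
    lo, hi = (fit.percentile(p) for p in constraint)
    mask = (grid >= lo) & (grid <= hi)
    if not np.any(mask):
        # degenerate: constraint narrower than the grid step
        mask = np.isclose(grid, grid[np.argmin(np.abs(grid - 0.5 * (lo + hi)))])
    return grid[mask]


def argmin_mmt(fit: ReducedFit, constraint: tuple[float, float] | None = None) -> float:
    """Grid argmin of the fitted curve (Argmin1), optionally constrained to a
    percentile window such as (1, 99) (Argmin2).  Ties break toward the
    lowest temperature."""
    grid = _constrained_grid(fit, constraint)
    curve = fit.q_matrix(grid) @ fit.beta
    return float(grid[int(np.argmin(curve))])


def _mvn_factor(vcov: np.ndarray) -> np.ndarray:
    """Symmetric PSD factor A with A A' = vcov; eigenvalues clipped at
    -1e-8 relative (reduction can leave the covariance numerically indefinite)."""
    w, V = np.linalg.eigh(0.5 * (vcov + vcov.T))
    wmax = max(float(w.max()), 0.0)
    if w.min() < -1e-8 * max(wmax, 1e-300):
        raise ValueError(f"covariance is not PSD: min eigenvalue {w.min():.3e}")
    w = np.clip(w, 0.0, None)
    return V * np.sqrt(w)


def sample_mmt(
    fit: ReducedFit,
    n_sim: int = DEFAULT_N_SIM,
    prior: PriorSupport | None = None,
    rng_seed: int | np.random.Generator | None = None,
    point_rule: str = "mean",
    percentile_pair: tuple[float, float] = DEFAULT_PAIR,
) -> MMTResult:
    """Monte Carlo MMT distribution (Empirical1, or Empirical2 with a prior).

    Draws beta_(i) ~ MVN(beta-hat, V(beta-hat)) and records the grid argmin
    theta_(i) of each sampled curve.  With a prior, draws whose theta_(i)
    falls outside the support are rejected; proposals continue (same stream)
    until ``n_sim`` are accepted or the budget of ``100 * n_sim`` proposals
    is exhausted.  Because proposals are consumed from a single seeded
    stream, an Empirical2 run with the same seed filters exactly the
    proposal sequence an Empirical1 run would produce.
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    A = _mvn_factor(fit.vcov)
    Q = fit.q_matrix(fit.temp_grid)  # (G, v_x)
    grid = fit.temp_grid

    support = prior.resolve(fit) if prior is not None else None
    if support is not None and (support[0] > grid[-1] or support[1] < grid[0]):
        raise IncompatiblePriorError(
            f"prior support ({support[0]:.3g}, {support[1]:.3g}) does not overlap "
            f"the temperature grid [{grid[0]:.3g}, {grid[-1]:.3g}]"
        )

    thetas: list[np.ndarray] = []
    betas: list[np.ndarray] = []
    n_proposed = 0
    n_accepted = 0
    budget = REJECTION_BUDGET * n_sim if support is not None else n_sim
    while n_accepted < n_sim and n_proposed < budget:
        chunk = min(n_sim, budget - n_proposed)
        Z = rng.standard_normal((chunk, fit.beta.size))
        beta_i = fit.beta + Z @ A.T
        idx = np.argmin(beta_i @ Q.T, axis=1)  # first minimum = lowest temperature
        theta_i = grid[idx]
        if support is None:
            keep = np.ones(chunk, dtype=bool)
        else:
            keep = (theta_i >= support[0]) & (theta_i <= support[1])
        # count proposals only up to the one producing the n_sim-th acceptance
        hits = np.flatnonzero(keep)
        needed = n_sim - n_accepted
        if hits.size >= needed:
            used = int(hits[needed - 1]) + 1
            keep = keep[:used]
            theta_i, beta_i = theta_i[:used], beta_i[:used]
        else:
            used = chunk
        n_proposed += used
        thetas.append(theta_i[keep])
        betas.append(beta_i[keep])
        n_accepted += int(keep.sum())

    samples = np.concatenate(thetas)[:n_sim]
    beta_samples = np.vstack(betas)[:n_sim] if betas else np.empty((0, fit.beta.size))
    n_accepted = samples.size
    if support is not None:
        rate = samples.size / n_proposed if n_proposed else 0.0
        if samples.size == 0 or (samples.size < n_sim and rate < ACCEPTANCE_FLOOR):
            raise IncompatiblePriorError(
                f"acceptance rate {rate:.2%} below floor {ACCEPTANCE_FLOOR:.1%}: prior "
                f"support ({support[0]:.3g}, {support[1]:.3g}) is incompatible with the data"
            )

    method = "Empirical2" if prior is not None else "Empirical1"
    return summarize_mmt(
        samples,
        point_rule=point_rule,
        percentile_pair=percentile_pair,
        method=method,
        beta_samples=beta_samples,
        n_proposed=n_proposed,
        n_accepted=int(samples.size),
    )


def summarize_mmt(
    samples: np.ndarray,
    point_rule: str = "mean",
    percentile_pair: tuple[float, float] = DEFAULT_PAIR,
    method: str = "Empirical1",
    beta_samples: np.ndarray | None = None,
    n_proposed: int = 0,
    n_accepted: int | None = None,
) -> MMTResult:
    """Point and percentile-interval summary of an empirical MMT sample.

    Interval endpoints are empirical percentiles with linear interpolation
    between order statistics; ``percentile_pair=(0, 95)`` is the
    skew-adjusted choice for highly right-skewed distributions.
    """
    samples = np.asarray(samples, dtype=float).ravel()
    if samples.size == 0:
        raise ValueError("cannot summarize an empty sample")
    if point_rule == "mean":
        point = float(samples.mean())
    elif point_rule == "median":
        point = float(np.median(samples))
    else:
        raise ValueError(f"unknown point rule {point_rule!r}")
    if samples.size >= 2:
        lo, hi = np.percentile(samples, percentile_pair)
        interval = (float(lo), float(hi))
    else:
        interval = (float(samples[0]), float(samples[0]))
    if samples.size < 3 or np.ptp(samples) == 0:
        skew = None if samples.size < 3 else 0.0
    else:
        skew = float(stats.skew(samples))
    return MMTResult(
        method=method,
        point=point,
        interval=interval,
        samples=samples,
        beta_samples=beta_samples,
        n_proposed=n_proposed,
        n_accepted=samples.size if n_accepted is None else n_accepted,
        percentile_pair=tuple(float(p) for p in percentile_pair),
        point_rule=point_rule,
        skewness=skew,
    )


def resummarize(result: MMTResult, point_rule: str | None = None,
                percentile_pair: tuple[float, float] | None = None) -> MMTResult:
    """Re-summarize an existing Monte Carlo sample under a different point
    rule or percentile pair (e.g. the skew-adjusted (0, 95))."""
    if result.samples is None:
        raise ValueError("result carries no samples to re-summarize")
    out = summarize_mmt(
        result.samples,
        point_rule=point_rule or result.point_rule or "mean",
        percentile_pair=percentile_pair or result.percentile_pair or DEFAULT_PAIR,
        method=result.method,
        beta_samples=result.beta_samples,
        n_proposed=result.n_proposed,
        n_accepted=result.n_accepted,
    )
    return out
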