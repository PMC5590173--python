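"""Cold- and heat-related relative risks referenced to the MMT.

The log relative risk comparing temperature x with a reference m is the
contrast (Q_x - Q_m) beta.  Two inference modes are provided:

* fixed reference — the conventional approach: m is a single MMT point
  estimate, the contrast variance follows from V(beta-hat) by the delta
  method, and the 95% CI uses the normal approximation.  This ignores the
  uncertainty in the MMT itself.
* empirical reference — MMT uncertainty propagated: for each Monte Carlo
  draw, zeta_(i) = (Q_x - Q_{theta_(i)}) beta_(i) with the paired draw
  beta_(i) that generated theta_(i), and RR_(i) = exp(zeta_(i)); point and
  interval come from the empirical RR distribution exactly as for the MMT.

Cold- and heat-related RRs compare the 1st and 99th observed temperature
percentiles against the MMT reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .basis import ReducedFit
from .mmt import DEFAULT_PAIR, MMTResult

__all__ = ["RRResult", "rr_empirical", "rr_fixed", "cold_heat_rr"]


@dataclass
class RRResult:
    """Relative risk at a comparison temperature against the MMT reference."""

    comparison_temperature: float
    reference: float | str  # MMT in degC (fixed mode) or "empirical"
    point: float
    interval: tuple[float, float]
    samples: np.ndarray | None = None

    @property
    def length(self) -> float:
        return self.interval[1] - self.interval[0]


def rr_empirical(
    fit: ReducedFit,
    mmt_samples: MMTResult,
    x: float,
    percentile_pair: tuple[float, float] = DEFAULT_PAIR,
    point_rule: str = "mean",
) -> RRResult:
    """RR at ``x`` with MMT uncertainty propagated through the paired draws."""
    if mmt_samples.samples is None or mmt_samples.beta_samples is None:
        raise ValueError("MMT result carries no paired (theta, beta) samples")
    if len(mmt_samples.samples) != len(mmt_samples.beta_samples):
        raise ValueError("theta and beta samples are unpaired")
    Qx = fit.q_matrix(np.array([x]))[0]
    Qtheta = fit.q_matrix(mmt_samples.samples)  # (n, v_x)
    zeta = np.einsum("ij,ij->i", Qx[None, :] - Qtheta, mmt_samples.beta_samples)
    rr = np.exp(zeta)
    if point_rule == "mean":
        point = float(rr.mean())
    elif point_rule == "median":
        point = float(np.median(rr))
    else:
        raise ValueError(f"unknown point rule {point_rule!r}")
    lo, hi = np.percentile(rr, percentile_pair)
    return RRResult(
        comparison_temperature=float(x),
        reference="empirical",
        point=point,
        interval=(float(lo), float(hi)),
        samples=rr,
    )


def rr_fixed(
    fit: ReducedFit, mmt_point: float, x: float, level: float = 0.95
) -> RRResult:
    """RR at ``x`` against a fixed MMT reference, normal-approximation CI."""
    contrast = fit.q_matrix(np.array([x]))[0] - fit.q_matrix(np.array([mmt_point]))[0]
    log_rr = float(contrast @ fit.beta)
    var = float(contrast @ fit.vcov @ contrast)
    z = stats.norm.ppf(0.5 + level / 2)
    half = z * np.sqrt(max(var, 0.0))
    return RRResult(
        comparison_temperature=float(x),
        reference=float(mmt_point),
        point=float(np.exp(log_rr)),
        interval=(float(np.exp(log_rr - half)), float(np.exp(log_rr + half))),
    )


def cold_heat_rr(
    fit: ReducedFit,
    mmt: MMTResult,
    percentile_pair: tuple[float, float] = DEFAULT_PAIR,
    point_rule: str = "mean",
) -> tuple[RRResult, RRResult]:
    """Cold (1st percentile vs MMT) and heat (99th percentile vs MMT) RRs.

    Uses the empirical propagation when the MMT result carries Monte Carlo
    samples (Empirical methods) and the fixed-reference normal approximation
    otherwise (Argmin methods).
    """
    cold_x = fit.percentile(1)
    heat_x = fit.percentile(99)
    if mmt.samples is not None and mmt.beta_samples is not None:
        cold = rr_empirical(fit, mmt, cold_x, percentile_pair, point_rule)
        heat = rr_empirical(fit, mmt, heat_x, percentile_pair, point_rule)
    else:
        cold = rr_fixed(fit, mmt.point, cold_x)
        heat = rr_fixed(fit, mmt.point, heat_x)
    return cold, heat
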