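"""Weighted statistics, simultaneous confidence intervals and tests.

The weighted risk-difference statistic is ``T(w) = w' D_hat`` with standard
error ``(w' V_hat w)^{1/2}``.  All intervals have the Wald form

    w' D_hat  -/+  eta^{1/2} (w' V_hat w)^{1/2}

where the squared critical value ``eta`` is either the 1 - alpha/2 quantile
of the chi-bar-squared distribution for the chosen weight cone (simultaneous
over all cone weights), the 1 - alpha quantile of chi-squared with K degrees
of freedom (Scheffe, simultaneous over all contrasts), or the 1 - alpha
quantile of chi-squared with 1 df (unadjusted, pointwise).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .chibarsq import (
    ChiBarWeights,
    Cone,
    CriticalValue,
    chibar_quantile,
    chibar_tail,
    chibar_weights_exact,
    chibar_weights_mc,
)
from .estimation import DifferenceEstimate

__all__ = [
    "WeightVector",
    "IntervalResult",
    "weighted_stat",
    "critical_value",
    "simultaneous_ci",
    "simultaneous_test",
    "relative_efficiency",
    "power_optimal_direction",
]

Z_UNADJ = 1.959963984540054  # standard normal 0.975 quantile


@dataclass(frozen=True)
class WeightVector:
    """A weight vector over event types, optionally checked against a cone."""

    w: np.ndarray
    cone_member: bool | None = None

    def __post_init__(self):
        w = np.asarray(self.w, dtype=float)
        if np.allclose(w, 0.0):
            raise ValueError("weight vector must not be zero")
        object.__setattr__(self, "w", w)


@dataclass(frozen=True)
class IntervalResult:
    estimate: float
    se: float
    lower: float
    upper: float
    eta: CriticalValue
    sided: str  # "one" | "two"


def weighted_stat(w, diff: DifferenceEstimate):
    """Point estimate w'D and its standard error (w'Vw)^{1/2}."""
    w = np.asarray(getattr(w, "w", w), dtype=float)
    if w.shape != diff.D.shape:
        raise ValueError("weight vector dimension mismatch")
    var = float(w @ diff.V @ w)
    if var <= 0:
        raise ValueError("weight vector lies in a zero-variance direction")
    return float(w @ diff.D), float(np.sqrt(var))


def critical_value(
    method: str,
    cone: Cone | None = None,
    V=None,
    alpha: float = 0.05,
    *,
    K: int | None = None,
    weights: ChiBarWeights | None = None,
    mc_reps: int = 100_000,
    seed=None,
) -> CriticalValue:
    """Squared critical value eta for the chosen method.

    chi-bar uses the (1 - alpha/2) quantile of the mixture implied by the
    cone and covariance (exact weights when feasible, else Monte Carlo);
    Scheffe the (1 - alpha) chi-squared quantile with K df; unadjusted the
    (1 - alpha) chi-squared quantile with 1 df, i.e. 1.96^2 at alpha=0.05.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if method == "unadjusted":
        return CriticalValue(float(stats.chi2.ppf(1 - alpha, 1)), 1 - alpha, method)
    if method == "scheffe":
        if K is None:
            K = cone.K if cone is not None else np.asarray(V).shape[0]
        return CriticalValue(float(stats.chi2.ppf(1 - alpha, K)), 1 - alpha, method)
    if method == "chibar":
        if weights is None:
            if cone is None or V is None:
                raise ValueError("chibar requires a cone and covariance")
            if cone.K - cone.s <= 10:
                weights = chibar_weights_exact(cone, V)
            else:
                weights = chibar_weights_mc(cone, V, mc_reps, seed)
        eta = chibar_quantile(1 - alpha / 2.0, weights)
        return CriticalValue(eta, 1 - alpha / 2.0, method, weights=weights)
    raise ValueError(f"unknown method {method!r}")


def simultaneous_ci(
    w, diff: DifferenceEstimate, eta: CriticalValue, sided: str = "two"
) -> IntervalResult:
    """Wald-form interval with squared critical value eta."""
    est, se = weighted_stat(w, diff)
    half = float(np.sqrt(eta.eta)) * se
    if sided == "two":
        return IntervalResult(est, se, est - half, est + half, eta, sided)
    if sided == "one":
        return IntervalResult(est, se, est - half, np.inf, eta, sided)
    raise ValueError("sided must be 'one' or 'two'")


def _adjusted_p(t2: float, eta: CriticalValue, sided: str) -> float:
    """Smallest alpha at which the test rejects, via the monotone map from
    alpha to the critical value (closed form through the mixture tail)."""
    if eta.method == "chibar":
        tail = chibar_tail(t2, eta.weights)
        p = 2.0 * tail if sided == "two" else tail
    elif eta.method == "scheffe":
        p = float(stats.chi2.sf(t2, int(round(_df_from_eta(eta)))))
    else:  # unadjusted
        p = float(stats.chi2.sf(t2, 1))
    return float(min(1.0, p))


def _df_from_eta(eta: CriticalValue) -> float:
    # invert eta = chi2.ppf(level, K) for the Scheffe df
    for K in range(1, 200):
        if abs(stats.chi2.ppf(eta.level, K) - eta.eta) < 1e-9:
            return K
    raise ValueError("cannot recover Scheffe degrees of freedom")


def simultaneous_test(
    w, diff: DifferenceEstimate, eta: CriticalValue, sided: str = "two"
):
    """Reject iff zero lies outside the simultaneous interval.

    Returns ``(reject, adjusted_p)``, the adjusted p-value being the
    smallest alpha at which rejection occurs.
    """
    ci = simultaneous_ci(w, diff, eta, sided)
    if sided == "two":
        reject = ci.lower > 0.0 or ci.upper < 0.0
    else:
        reject = ci.lower > 0.0
    t2 = (ci.estimate / ci.se) ** 2
    if sided == "one" and ci.estimate <= 0:
        p = 1.0
    else:
        p = _adjusted_p(t2, ci.eta, sided)
    return bool(reject), float(p)


def relative_efficiency(eta) -> float:
    """Interval-width inflation factor sqrt(eta)/1.96 relative to the
    unadjusted Wald interval."""
    e = eta.eta if isinstance(eta, CriticalValue) else float(eta)
    if e <= 0:
        raise ValueError("eta must be positive")
    return float(np.sqrt(e) / Z_UNADJ)


def power_optimal_direction(diff: DifferenceEstimate) -> WeightVector:
    """Direction maximising w'D / (w'Vw)^{1/2}, i.e. w proportional to
    V^{-1} D, normalised to sum to one.

    Advisory only: weights for a confirmatory analysis should be chosen on
    clinical grounds, not power.
    """
    w = np.linalg.solve(diff.V, diff.D)
    s = w.sum()
    if abs(s) < 1e-12:
        raise ValueError("optimal direction has zero weight sum; cannot normalise")
    # dividing by a negative sum would flip the maximising orientation, so
    # scale by |sum|; the weights then sum to sign(sum)
    return WeightVector(w / abs(s))
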