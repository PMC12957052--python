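"""Nested-model hypothesis tests and chi-square sensitivity analysis.

Equality restrictions on MPT parameters are tested by the increase in the
G² statistic between a base model and a nested restricted model (ΔG²,
asymptotically chi-square with df equal to the number of restrictions).
Sensitivity analysis inverts the noncentral chi-square power function to
find the smallest effect size (Cohen's w) detectable at a given alpha and
power for a given number of observations, with noncentrality λ = w²·N.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import optimize, stats

from .estimation import EstimationError, FitResult

__all__ = [
    "InferenceError",
    "RestrictionTest",
    "SensitivityResult",
    "nested_test",
    "power_of_w",
    "minimal_detectable_w",
]

_DELTA_TOL = 1e-6  # ΔG² within this of zero is clamped to zero


class InferenceError(Exception):
    """Raised for invalid nested comparisons or power-analysis inputs."""


@dataclass(frozen=True)
class RestrictionTest:
    """ΔG² comparison of a nested (restricted) fit against a base fit."""

    description: str
    delta_g_squared: float
    delta_df: int
    p_value: float
    base_fit: FitResult
    restricted_fit: FitResult

    def to_dict(self) -> dict:
        return {
            "description": self.description,
            "delta_g_squared": self.delta_g_squared,
            "delta_df": self.delta_df,
            "p_value": self.p_value,
            "base": self.base_fit.to_dict(),
            "restricted": self.restricted_fit.to_dict(),
        }


@dataclass(frozen=True)
class SensitivityResult:
    """Effect size w, alpha, power, df and N of a chi-square power analysis."""

    w: float
    alpha: float
    power: float
    df: int
    n_obs: int


def nested_test(
    base: FitResult, restricted: FitResult, description: str = ""
) -> RestrictionTest:
    """Compare a restricted fit against the base fit it is nested in.

    The restricted model's constraint set must imply the base model's and
    both fits must use the same data.  ΔG² = restricted G² − base G²,
    referred to a chi-square distribution with Δdf degrees of freedom.
    """
    if restricted.data.counts != base.data.counts:
        raise InferenceError("base and restricted fits use different data")
    if not restricted.constraints.implies(base.constraints):
        raise InferenceError(
            "restricted model's constraints do not imply the base model's: "
            "the models are not nested"
        )
    delta_df = restricted.df - base.df
    if delta_df <= 0 and restricted.constraints != base.constraints:
        raise InferenceError(
            f"restricted model has no fewer free parameters (Δdf = {delta_df})"
        )
    delta = restricted.g_squared - base.g_squared
    if delta < -_DELTA_TOL:
        raise EstimationError(
            f"restricted G² {restricted.g_squared:.6f} below base G² "
            f"{base.g_squared:.6f}: optimization failure, refit with more starts"
        )
    delta = max(delta, 0.0)
    if delta_df == 0:  # identical constraint sets: trivial comparison
        return RestrictionTest(description, 0.0, 0, 1.0, base, restricted)
    p_value = float(stats.chi2.sf(delta, delta_df))
    return RestrictionTest(description, delta, delta_df, p_value, base, restricted)


def power_of_w(w: float, alpha: float, df: int, n_obs: int) -> float:
    """Power of the chi-square test for effect size w with N observations.

    The test statistic is noncentral chi-square with noncentrality
    λ = w²·N under the alternative; power is the probability that it
    exceeds the central critical value at level alpha.
    """
    if w < 0:
        raise InferenceError(f"effect size w must be nonnegative, got {w}")
    if not (0 < alpha < 1):
        raise InferenceError(f"alpha must be in (0, 1), got {alpha}")
    if df < 1 or n_obs < 1:
        raise InferenceError("df and n_obs must be positive")
    critical = stats.chi2.ppf(1.0 - alpha, df)
    lam = w * w * n_obs
    if lam == 0.0:
        return float(alpha)
    return float(stats.ncx2.sf(critical, df, lam))


def minimal_detectable_w(
    alpha: float, power: float, df: int, n_obs: int
) -> SensitivityResult:
    """Smallest Cohen's w detectable at the given alpha, power, df and N.

    Solves power_of_w(w) = power by monotone bisection (power is strictly
    increasing in w at fixed N).
    """
    if not (0 < alpha < 1):
        raise InferenceError(f"alpha must be in (0, 1), got {alpha}")
    if not (alpha < power < 1):
        raise InferenceError(
            f"target power {power} must lie strictly between alpha ({alpha}) and 1"
        )
    if df < 1 or n_obs < 1:
        raise InferenceError("df and n_obs must be positive")

    def gap(w: float) -> float:
        return power_of_w(w, alpha, df, n_obs) - power

    hi = 1.0
    while gap(hi) < 0 and hi < 1e6:
        hi *= 2.0
    w = float(optimize.brentq(gap, 1e-12, hi, xtol=1e-10, rtol=1e-12))
    return SensitivityResult(w=w, alpha=alpha, power=power, df=df, n_obs=n_obs)
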