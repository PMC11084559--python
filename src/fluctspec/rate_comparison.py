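"""Low-to-high mutation-rate ratios and z-tests.

The plastic response of the mutation rate to glucose is summarised as the
ratio R of the rate at low glucose to the rate at high glucose.  The
variance of R comes from the first-order delta method ("sigma method")
for a ratio of independent estimates:

    var(R) = R^2 * (se_a^2 / a^2 + se_b^2 / b^2).

R is tested against 1 (no plasticity) by a z-test, and two strains'
ratios are contrasted with z = (R1 - R2) / sqrt(var_R1 + var_R2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "RatioTestResult",
    "RatioContrast",
    "sigma_ratio",
    "z_ratio_vs_1",
    "z_ratio_diff",
    "normal_sf",
    "chisq_sf",
    "compare_conditions",
]

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class RatioTestResult:
    strain: str
    R: float
    var_R: float
    ci95: tuple[float, float]
    z_vs_1: float
    p_vs_1: float
    sidedness: str


@dataclass(frozen=True)
class RatioContrast:
    z: float
    p: float
    sidedness: str


def normal_sf(z: float) -> float:
    """Upper-tail probability of the standard normal."""
    return float(stats.norm.sf(z))


def chisq_sf(x: float, df: int) -> float:
    """Upper-tail probability of the chi-square distribution."""
    if df < 1:
        raise ValueError("df must be >= 1")
    if x < 0:
        raise ValueError("x must be >= 0")
    return float(stats.chi2.sf(x, df))


def sigma_ratio(a: float, se_a: float, b: float, se_b: float):
    """Delta-method ratio R = a/b with variance and 95% CI.

    Numerator and denominator are assumed independent (separate cultures
    per condition).
    """
    if a <= 0 or b <= 0:
        raise ValueError("rates must be positive")
    if se_a < 0 or se_b < 0:
        raise ValueError("standard errors must be non-negative")
    r = a / b
    var_r = r * r * ((se_a / a) ** 2 + (se_b / b) ** 2)
    half = Z_95 * np.sqrt(var_r)
    return r, var_r, (r - half, r + half)


def _p_from_z(z: float, sidedness: str) -> float:
    if sidedness == "one-sided":
        return normal_sf(z)
    if sidedness == "two-sided":
        return 2.0 * normal_sf(abs(z))
    raise ValueError("sidedness must be 'one-sided' or 'two-sided'")


def z_ratio_vs_1(r: float, var_r: float, sidedness: str = "two-sided"):
    """z-test of H0: R = 1."""
    if var_r <= 0:
        raise ValueError("degenerate test: var_R must be > 0")
    z = (r - 1.0) / np.sqrt(var_r)
    return float(z), _p_from_z(z, sidedness)


def z_ratio_diff(r1: float, var_r1: float, r2: float, var_r2: float,
                 sidedness: str = "one-sided") -> RatioContrast:
    """z-test of H0: R1 = R2 for independent ratios.

    Default one-sided: the directional hypothesis that the first (wild
    type) ratio exceeds the second.
    """
    if var_r1 + var_r2 <= 0:
        raise ValueError("degenerate test: both variances are zero")
    z = (r1 - r2) / np.sqrt(var_r1 + var_r2)
    return RatioContrast(z=float(z), p=_p_from_z(z, sidedness), sidedness=sidedness)


def compare_conditions(rate_low, rate_high, strain: str = "",
                       sidedness: str = "two-sided") -> RatioTestResult:
    """Low-to-high ratio test for one strain from two RateEstimates."""
    r, var_r, ci = sigma_ratio(rate_low.mu_hat, rate_low.se_mu,
                               rate_high.mu_hat, rate_high.se_mu)
    z, p = z_ratio_vs_1(r, var_r, sidedness)
    return RatioTestResult(strain=strain or rate_low.strain, R=r, var_R=var_r,
                           ci95=ci, z_vs_1=z, p_vs_1=p, sidedness=sidedness)
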