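"""Luria–Delbrück mutant-count model and mutation-rate estimators.

The number of resistant mutants observed in one parallel culture of a
fluctuation assay follows a compound-Poisson law: mutation events arrive
as a Poisson process with mean ``m`` per culture, and each event founds a
resistant clone whose final size follows the Lea–Coulson clone-size law

    q_k = rho * Gamma(k) * Gamma(rho + 1) / Gamma(k + rho + 1),   k >= 1,

where ``rho`` is the growth rate of mutants relative to the wild type
(``rho = 1`` recovers the classical q_k = 1/(k(k+1))).  The probability
mass function of the mutant count is obtained from the clone-size law by
the Panjer recursion

    p_0 = exp(-m),
    p_n = (m / n) * sum_{k=1..n} k * q_k * p_{n-k},

which is exact for compound-Poisson sums.  Mutation number ``m`` is
estimated by maximum likelihood over this pmf (counts winsorised at a cap
to tame the heavy tail) or by the classical P0 method, and converted to a
per-cell, per-generation rate ``mu = m / Nt`` with ``Nt`` the final
population size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize, minimize_scalar
from scipy.special import gammaln

__all__ = [
    "CultureSet",
    "LDParams",
    "RateEstimate",
    "clone_size_pmf",
    "clone_size_sf",
    "ld_pmf",
    "simulate_counts",
    "log_likelihood",
    "estimate_ml",
    "estimate_p0",
    "rate_from_m",
]

DEFAULT_WINSOR_CAP = 1024


@dataclass(frozen=True)
class CultureSet:
    """One strain x glucose fluctuation experiment.

    ``counts`` are rifampicin-resistant mutant counts per parallel culture;
    ``cfu_totals`` are final viable population sizes from replicate platings.
    """

    strain: str
    glucose: str
    counts: np.ndarray
    cfu_totals: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        cfu = np.asarray(self.cfu_totals, dtype=float)
        if counts.size < 2:
            raise ValueError("need at least 2 parallel cultures")
        if np.any(counts < 0) or not np.all(counts == np.floor(counts)):
            raise ValueError("mutant counts must be non-negative integers")
        if cfu.size < 1 or np.any(cfu <= 0):
            raise ValueError("cfu_totals must be non-empty and positive")
        object.__setattr__(self, "counts", counts.astype(np.int64))
        object.__setattr__(self, "cfu_totals", cfu)


@dataclass(frozen=True)
class LDParams:
    """Parameters of the mutant-count distribution.

    m: expected mutation events per culture (>= 0).
    fitness: mutant growth rate relative to wild type, rho (> 0).
    winsor_cap: counts above this cap are replaced by the cap during
        likelihood evaluation.
    """

    m: float
    fitness: float = 1.0
    winsor_cap: int = DEFAULT_WINSOR_CAP

    def __post_init__(self) -> None:
        if self.m < 0:
            raise ValueError("m must be >= 0")
        if self.fitness <= 0:
            raise ValueError("fitness must be > 0")
        if self.winsor_cap < 1:
            raise ValueError("winsor_cap must be >= 1")


@dataclass(frozen=True)
class RateEstimate:
    """Mutation number and rate for one condition.

    mu_hat = m_hat / Nt; standard errors are on the same scale.
    A ``converged`` flag of False marks a result that must not be used
    silently (boundary or optimiser failure); ``note`` says why.
    """

    strain: str
    glucose: str
    m_hat: float
    se_m: float
    Nt: float
    mu_hat: float
    se_mu: float
    n_cultures: int
    method: str
    fitness_mode: str = "fixed"
    fitness_hat: float = 1.0
    se_fitness: float = float("nan")
    converged: bool = True
    note: str = ""


def clone_size_pmf(k, fitness: float = 1.0):
    """Probability that one mutant clone has final size ``k``.

    Lea–Coulson law generalised with relative fitness rho:
    q_k = rho * B(k, rho + 1) where B is the beta function.
    Accepts scalar or array ``k``.
    """
    k_arr = np.asarray(k)
    if np.any(k_arr < 1) or not np.all(k_arr == np.floor(k_arr)):
        raise ValueError("clone size k must be an integer >= 1")
    if fitness <= 0:
        raise ValueError("fitness must be > 0")
    rho = float(fitness)
    logq = (
        math.log(rho)
        + gammaln(k_arr)
        + gammaln(rho + 1.0)
        - gammaln(k_arr + rho + 1.0)
    )
    out = np.exp(logq)
    return float(out) if np.isscalar(k) or out.ndim == 0 else out


def clone_size_sf(k, fitness: float = 1.0):
    """P(clone size >= k) = Gamma(k) Gamma(rho+1) / Gamma(k+rho).

    Telescoping of the clone-size law; reduces to 1/k at rho = 1.
    """
    k_arr = np.asarray(k, dtype=float)
    rho = float(fitness)
    logs = gammaln(k_arr) + gammaln(rho + 1.0) - gammaln(k_arr + rho)
    out = np.exp(logs)
    return float(out) if np.isscalar(k) or out.ndim == 0 else out


def ld_pmf(params: LDParams, n_max: int) -> np.ndarray:
    """Mutant-count pmf p_0..p_{n_max} by the Panjer recursion."""
    if n_max < 0:
        raise ValueError("n_max must be >= 0")
    m = params.m
    p = np.zeros(n_max + 1)
    p[0] = math.exp(-m)
    if n_max == 0 or m == 0:
        if m == 0:
            p[0] = 1.0
        return p
    k = np.arange(1, n_max + 1)
    kq = k * clone_size_pmf(k, params.fitness)
    for n in range(1, n_max + 1):
        # p_n = (m/n) * sum_{k=1..n} k q_k p_{n-k}
        p[n] = (m / n) * np.dot(kq[:n], p[n - 1 :: -1])
    return p


def _sample_clone_sizes(n: int, fitness: float, nt_cap: int, rng: np.random.Generator) -> np.ndarray:
    """Draw clone sizes by inverting the survival function P(K >= k)."""
    if n == 0:
        return np.zeros(0, dtype=np.int64)
    u = rng.random(n)
    if fitness == 1.0:
        # P(K >= k) = 1/k  =>  K = floor(1/U), truncated at nt_cap
        return np.minimum(np.floor(1.0 / u), float(nt_cap)).astype(np.int64)
    # General rho: K = max{k : sf(k) > u}, sf monotone decreasing; bisect.
    lo = np.ones(n, dtype=np.int64)  # sf(1) = 1 > u always
    hi = np.full(n, nt_cap, dtype=np.int64)
    while np.any(hi - lo > 0):
        mid = (lo + hi + 1) // 2
        ge = clone_size_sf(mid.astype(float), fitness) > u
        lo = np.where(ge, mid, lo)
        hi = np.where(ge, hi, mid - 1)
    return lo


def simulate_counts(
    n_cultures: int,
    params: LDParams,
    nt_cap: int = 10**9,
    seed: int = 0,
) -> np.ndarray:
    """Simulate mutant counts for parallel cultures.

    M ~ Poisson(m) mutation events per culture; the count is the sum of M
    clone sizes drawn from the clone-size law, each truncated at nt_cap.
    """
    if n_cultures < 1:
        raise ValueError("n_cultures must be >= 1")
    rng = np.random.default_rng(seed)
    n_events = rng.poisson(params.m, size=n_cultures)
    total = int(n_events.sum())
    sizes = _sample_clone_sizes(total, params.fitness, nt_cap, rng)
    counts = np.zeros(n_cultures, dtype=np.int64)
    idx = np.repeat(np.arange(n_cultures), n_events)
    np.add.at(counts, idx, sizes)
    return counts


def log_likelihood(counts: Sequence[int], params: LDParams) -> float:
    """Log-likelihood of mutant counts under the LD pmf.

    Counts are winsorised at ``params.winsor_cap`` before evaluation.
    """
    counts = np.minimum(np.asarray(counts, dtype=np.int64), params.winsor_cap)
    if params.m == 0:
        return 0.0 if np.all(counts == 0) else -math.inf
    n_max = int(counts.max())
    p = ld_pmf(params, n_max)
    with np.errstate(divide="ignore"):
        logp = np.log(p)
    return float(logp[counts].sum())


def _observed_info_se(f, x: float) -> float:
    """Standard error from the numerical observed information of f at x."""
    h = 1e-4 * max(abs(x), 1.0)
    d2 = (f(x + h) - 2.0 * f(x) + f(x - h)) / h**2
    if d2 >= 0 or not math.isfinite(d2):
        return float("nan")
    return math.sqrt(-1.0 / d2)


def estimate_ml(
    counts: Sequence[int],
    fitness_mode: str = "fixed",
    fitness: float = 1.0,
    winsor_cap: int = DEFAULT_WINSOR_CAP,
):
    """Maximum-likelihood estimate of the mutation number m.

    fitness_mode "fixed": rho held at ``fitness``; returns
    (m_hat, se_m, converged, note).
    fitness_mode "joint": (m, rho) estimated together; returns
    (m_hat, se_m, fitness_hat, se_fitness, converged, note).
    Standard errors come from the inverse observed information at the
    optimum.  All-zero data sit on the m = 0 boundary: m_hat = 0 with an
    undefined (NaN) standard error and converged = False.
    """
    counts = np.asarray(counts, dtype=np.int64)
    if counts.size < 2:
        raise ValueError("need at least 2 cultures")
    if fitness_mode not in ("fixed", "joint"):
        raise ValueError("fitness_mode must be 'fixed' or 'joint'")

    if np.all(counts == 0):
        note = "all counts zero: m_hat at boundary, se undefined"
        if fitness_mode == "fixed":
            return 0.0, float("nan"), False, note
        return 0.0, float("nan"), float("nan"), float("nan"), False, note

    if fitness_mode == "joint" and not np.any(counts > 0):
        raise ValueError("joint estimation needs at least one positive count")

    mean_c = float(np.minimum(counts, winsor_cap).mean())
    upper = max(10.0, 3.0 * mean_c + 10.0)

    if fitness_mode == "fixed":
        def negll(m):
            return -log_likelihood(counts, LDParams(m, fitness, winsor_cap))

        res = minimize_scalar(negll, bounds=(1e-8, upper), method="bounded",
                              options={"xatol": 1e-8})
        m_hat = float(res.x)
        se = _observed_info_se(
            lambda m: log_likelihood(counts, LDParams(m, fitness, winsor_cap)), m_hat
        )
        converged = bool(res.success) and math.isfinite(se)
        note = "" if converged else "optimizer or information matrix failure"
        return m_hat, se, converged, note

    def negll2(theta):
        m, rho = math.exp(theta[0]), math.exp(theta[1])
        return -log_likelihood(counts, LDParams(m, rho, winsor_cap))

    x0 = np.array([math.log(max(mean_c, 0.1)), 0.0])
    res = minimize(negll2, x0, method="Nelder-Mead",
                   options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000})
    m_hat = float(math.exp(res.x[0]))
    rho_hat = float(math.exp(res.x[1]))

    def ll_m(m):
        return log_likelihood(counts, LDParams(m, rho_hat, winsor_cap))

    def ll_rho(rho):
        return log_likelihood(counts, LDParams(m_hat, rho, winsor_cap))

    se_m = _observed_info_se(ll_m, m_hat)
    se_rho = _observed_info_se(ll_rho, rho_hat)
    converged = bool(res.success) and math.isfinite(se_m)
    note = "" if converged else "optimizer or information matrix failure"
    return m_hat, se_m, rho_hat, se_rho, converged, note


def estimate_p0(counts: Sequence[int]):
    """P0 estimate of m: m = -ln(fraction of zero-count cultures).

    Delta-method standard error sqrt((1 - p0) / (n * p0)).
    """
    counts = np.asarray(counts, dtype=np.int64)
    n = counts.size
    if n < 1:
        raise ValueError("need at least one culture")
    n_zero = int(np.sum(counts == 0))
    if n_zero == 0:
        raise ValueError("P0 estimator undefined: no zero-count cultures")
    p0 = n_zero / n
    m_hat = -math.log(p0)
    se = math.sqrt((1.0 - p0) / (n * p0))
    return m_hat, se


def rate_from_m(
    m_hat: float,
    se_m: float,
    cfu_totals: Sequence[float],
    *,
    strain: str = "",
    glucose: str = "",
    n_cultures: int = 0,
    method: str = "ml",
    fitness_mode: str = "fixed",
    fitness_hat: float = 1.0,
    se_fitness: float = float("nan"),
    converged: bool = True,
    note: str = "",
) -> RateEstimate:
    """Convert a mutation-number estimate to a per-cell rate mu = m / Nt.

    Nt is the arithmetic mean of the replicate CFU totals and is treated as
    fixed, so se_mu = se_m / Nt.
    """
    cfu = np.asarray(cfu_totals, dtype=float)
    if cfu.size == 0 or np.any(cfu <= 0):
        raise ValueError("cfu_totals must be non-empty and positive")
    nt = float(cfu.mean())
    return RateEstimate(
        strain=strain,
        glucose=glucose,
        m_hat=m_hat,
        se_m=se_m,
        Nt=nt,
        mu_hat=m_hat / nt,
        se_mu=se_m / nt if math.isfinite(se_m) else float("nan"),
        n_cultures=n_cultures,
        method=method,
        fitness_mode=fitness_mode,
        fitness_hat=fitness_hat,
        se_fitness=se_fitness,
        converged=converged,
        note=note,
    )


def estimate_rates(culture_set: CultureSet, method: str = "ml",
                   fitness_mode: str = "fixed") -> RateEstimate:
    """Estimate the mutation rate for one culture set, end to end."""
    if method == "ml":
        out = estimate_ml(culture_set.counts, fitness_mode=fitness_mode)
        if fitness_mode == "fixed":
            m_hat, se_m, converged, note = out
            fit_hat, se_fit = 1.0, float("nan")
        else:
            m_hat, se_m, fit_hat, se_fit, converged, note = out
    elif method == "p0":
        m_hat, se_m = estimate_p0(culture_set.counts)
        fit_hat, se_fit, converged, note = 1.0, float("nan"), True, ""
    else:
        raise ValueError("method must be 'ml' or 'p0'")
    return rate_from_m(
        m_hat, se_m, culture_set.cfu_totals,
        strain=culture_set.strain, glucose=culture_set.glucose,
        n_cultures=int(culture_set.counts.size), method=method,
        fitness_mode=fitness_mode, fitness_hat=fit_hat, se_fitness=se_fit,
        converged=converged, note=note,
    )
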