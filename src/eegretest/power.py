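"""Study-design power for the one-way reliability F-test of an ICC.

For n subjects with k visits each, the test of H0: ICC = rho0 against
H1: ICC > rho0 rejects when F = MSB/MSW exceeds C(rho0) * F_crit, where
C(rho) = 1 + k*rho/(1-rho). Because F/C(rho) follows a central
F(n-1, n(k-1)) distribution at the true rho, the exact power at rho1 is

    power = P[ F(n-1, n(k-1)) > (C(rho0)/C(rho1)) * F_crit(1-alpha; n-1, n(k-1)) ].

The test is one-sided at level alpha by default (the conventional
reliability-design test); pass ``two_sided=True`` to spend alpha/2.
:func:`detectable_icc` inverts the power function in rho1 by bracketed
root-finding; :func:`required_n` searches the smallest n meeting a target
power, with the Walter-Eliasziw-Donner log-F normal approximation
available for comparison.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import optimize, stats

from ._exceptions import ConfigurationError, InfeasibleDesignError

__all__ = [
    "icc_test_power",
    "detectable_icc",
    "required_n",
    "required_n_approx",
    "simulate_rejection_rate",
]

_N_CAP = 10**6


def _check_design(n: int, k: int, rho0: float, alpha: float) -> None:
    if n < 2 or k < 2:
        raise ConfigurationError("need n >= 2 subjects and k >= 2 visits")
    if not 0.0 <= rho0 < 1.0:
        raise ConfigurationError("rho0 must lie in [0, 1)")
    if not 0.0 < alpha < 0.5:
        raise ConfigurationError("alpha must lie in (0, 0.5)")


def _c(rho: float, k: int) -> float:
    return 1.0 + k * rho / (1.0 - rho)


def icc_test_power(
    n: int,
    k: int,
    rho0: float,
    rho1: float,
    alpha: float = 0.05,
    two_sided: bool = False,
) -> float:
    """Exact power of the F-test of H0: ICC = rho0 at true ICC rho1."""
    _check_design(n, k, rho0, alpha)
    if not rho0 <= rho1 < 1.0:
        raise ConfigurationError("rho1 must lie in [rho0, 1)")
    a = alpha / 2.0 if two_sided else alpha
    df1, df2 = n - 1, n * (k - 1)
    f_crit = stats.f.ppf(1.0 - a, df1, df2)
    return float(stats.f.sf(_c(rho0, k) / _c(rho1, k) * f_crit, df1, df2))


def detectable_icc(
    n: int,
    k: int,
    rho0: float,
    target_power: float = 0.80,
    alpha: float = 0.05,
    two_sided: bool = False,
    xtol: float = 1e-6,
) -> float:
    """The alternative ICC detectable with ``target_power``.

    The unique rho1 in (rho0, 1) at which the exact F-test power equals
    ``target_power``, found by bracketed root-finding (power is strictly
    increasing in rho1). Raises InfeasibleDesignError when no root exists
    in the open interval.
    """
    _check_design(n, k, rho0, alpha)
    a = alpha / 2.0 if two_sided else alpha
    if not a < target_power < 1.0:
        raise ConfigurationError("target_power must lie in (alpha, 1)")
    hi = 1.0 - 1e-12
    f = lambda r: icc_test_power(n, k, rho0, r, alpha, two_sided) - target_power
    if f(hi) < 0.0:
        raise InfeasibleDesignError(
            f"power {target_power} unreachable for any ICC < 1 at n={n}, k={k}"
        )
    return float(optimize.brentq(f, rho0 + 1e-12, hi, xtol=xtol))


def required_n(
    k: int,
    rho0: float,
    rho1: float,
    target_power: float = 0.80,
    alpha: float = 0.05,
    two_sided: bool = False,
) -> int:
    """Smallest n whose exact power reaches ``target_power``.

    Exponential bracketing then bisection over the integer n (power is
    increasing in n). Raises InfeasibleDesignError beyond n = 10^6.
    """
    _check_design(2, k, rho0, alpha)
    if not rho0 < rho1 < 1.0:
        raise ConfigurationError("rho1 must lie in (rho0, 1)")
    if not 0.0 < target_power < 1.0:
        raise ConfigurationError("target_power must lie in (0, 1)")
    lo, hi = 2, 2
    while icc_test_power(hi, k, rho0, rho1, alpha, two_sided) < target_power:
        lo = hi
        hi *= 2
        if hi > _N_CAP:
            raise InfeasibleDesignError(f"required n exceeds {_N_CAP}")
    while lo < hi:
        mid = (lo + hi) // 2
        if icc_test_power(mid, k, rho0, rho1, alpha, two_sided) >= target_power:
            hi = mid
        else:
            lo = mid + 1
    return int(hi)


def required_n_approx(
    k: int,
    rho0: float,
    rho1: float,
    target_power: float = 0.80,
    alpha: float = 0.05,
    two_sided: bool = False,
) -> int:
    """Walter-Eliasziw-Donner closed-form sample-size approximation.

    Normal approximation to ln F: n ~ 1 + 2k(z_a + z_b)^2 / ((k-1) ln^2(C1/C0)).
    Kept for comparison with the exact search.
    """
    _check_design(2, k, rho0, alpha)
    if not rho0 < rho1 < 1.0:
        raise ConfigurationError("rho1 must lie in (rho0, 1)")
    a = alpha / 2.0 if two_sided else alpha
    z_a = stats.norm.ppf(1.0 - a)
    z_b = stats.norm.ppf(target_power)
    log_ratio = math.log(_c(rho1, k) / _c(rho0, k))
    n = 1.0 + 2.0 * k * (z_a + z_b) ** 2 / ((k - 1.0) * log_ratio**2)
    return int(math.ceil(n))


def simulate_rejection_rate(
    n: int,
    k: int,
    rho0: float,
    rho1: float,
    alpha: float = 0.05,
    n_reps: int = 10_000,
    rng: np.random.Generator | None = None,
    two_sided: bool = False,
) -> float:
    """Monte-Carlo rejection rate of the F-test on one-way normal data.

    Simulates y_ij = u_i + e_ij with var(u)/var total = rho1, forms
    F = MSB/MSW per replicate and rejects when F/C(rho0) exceeds the
    critical value. Serves as the simulation oracle for the analytic
    power.
    """
    _check_design(n, k, rho0, alpha)
    rng = rng or np.random.default_rng()
    a = alpha / 2.0 if two_sided else alpha
    df1, df2 = n - 1, n * (k - 1)
    f_crit = stats.f.ppf(1.0 - a, df1, df2)
    u = rng.normal(0.0, math.sqrt(rho1), (n_reps, n, 1))
    e = rng.normal(0.0, math.sqrt(1.0 - rho1), (n_reps, n, k))
    y = u + e
    row_means = y.mean(axis=2)
    grand = y.mean(axis=(1, 2))
    msb = k * ((row_means - grand[:, None]) ** 2).sum(axis=1) / (n - 1)
    msw = ((y - row_means[:, :, None]) ** 2).sum(axis=(1, 2)) / (n * (k - 1))
    rejected = msb / msw > _c(rho0, k) * f_crit
    return float(rejected.mean())
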