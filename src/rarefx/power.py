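"""Analytic power and sample size for allelic case-control tests.

Balanced designs only: ``n1 = n2 = n`` alleles per group (``n/2``
subjects per arm). Two alternatives are supported:

* an odds ratio ``c`` at control MAF ``p2`` for the two-proportion test
  of H0: p1 = p2, with ``p1 = c·p2 / (c·p2 − p2 + 1)``;
* a Cohen's h effect ``δ`` for the test of H0: h = 0, whose power
  depends on the design only through ``δ`` and ``n`` — the payoff of
  variance stabilization.

The two-proportion power can be computed under two variance
conventions. The default ``"hybrid"`` uses the pooled null variance
``2·p̄q̄`` inside the critical-value term and the unpooled alternative
variance in the denominator — the form matching a score test carried
out at level α and evaluated under the alternative. The ``"wald"``
convention uses the unpooled variance in both places. The two differ by
well under 1% power in the rare-variant regime.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .core_effects import h_given_or_maf, or_to_case_maf

__all__ = [
    "power_two_proportion",
    "power_h",
    "min_sample_size",
    "power_ratio_table",
]

GENOME_WIDE_ALPHA = 5e-8


def _z_crit(alpha: float) -> float:
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    # ndtri is accurate deep in the tail, stable down to alpha ~ 1e-300
    return -ndtri(alpha / 2.0)


def power_two_proportion(
    p2: float,
    odds_ratio: float,
    n_alleles: float,
    alpha: float = GENOME_WIDE_ALPHA,
    convention: str = "hybrid",
) -> float:
    """Power of the two-sided two-proportion test of H0: p1 = p2.

    Parameters
    ----------
    p2
        Control-group MAF in (0, 1).
    odds_ratio
        Alternative allelic odds ratio ``c``; the case MAF is derived as
        ``p1 = c·p2 / (c·p2 − p2 + 1)``.
    n_alleles
        Allele count per group (2 × subjects per arm).
    alpha
        Two-sided significance level (default genome-wide 5e-8).
    convention
        ``"hybrid"`` (pooled-null critical term, default) or ``"wald"``.
    """
    if not 0.0 < p2 < 1.0:
        raise ValueError(f"p2 must be in (0, 1), got {p2}")
    p1 = or_to_case_maf(odds_ratio, p2)
    if not 0.0 < p1 < 1.0:
        raise ValueError(f"implied case MAF {p1} outside (0, 1)")
    z = _z_crit(alpha)
    d = abs(p1 - p2)
    va = p1 * (1 - p1) + p2 * (1 - p2)
    if convention == "hybrid":
        pbar = 0.5 * (p1 + p2)
        crit = z * math.sqrt(2.0 * pbar * (1.0 - pbar))
    elif convention == "wald":
        crit = z * math.sqrt(va)
    else:
        raise ValueError(f"unknown convention {convention!r}")
    rootn = math.sqrt(n_alleles)
    sa = math.sqrt(va)
    return float(ndtr((d * rootn - crit) / sa) + ndtr((-d * rootn - crit) / sa))


def power_h(
    delta: float,
    n_alleles: float,
    alpha: float = GENOME_WIDE_ALPHA,
) -> float:
    """Power of the two-sided Cohen's h test of H0: h = 0 vs |h| = δ.

    With equal arms the test statistic has unit variance around
    ``δ·√(n/2)``, so power = Φ(|δ|√(n/2) − z) + Φ(−|δ|√(n/2) − z); no
    frequency enters beyond δ itself.
    """
    z = _z_crit(alpha)
    a = abs(delta) * math.sqrt(n_alleles / 2.0)
    return float(ndtr(a - z) + ndtr(-a - z))


def min_sample_size(
    target_power: float,
    p2: float,
    odds_ratio: float | None = None,
    delta: float | None = None,
    alpha: float = GENOME_WIDE_ALPHA,
    method: str = "two_proportion",
    convention: str = "hybrid",
) -> int:
    """Smallest even total subject count reaching the target power.

    Equal arms are assumed, so a total of ``n`` subjects means ``n/2``
    per arm and ``n`` alleles per group. The search is exact: the
    returned total satisfies power(n) ≥ target and power(n − 2) < target.

    Exactly one of ``odds_ratio`` / ``delta`` fixes the alternative; for
    ``method="h"`` with an odds ratio, δ is derived at ``p2``.
    """
    if not 0.0 < target_power < 1.0:
        raise ValueError("target_power must be in (0, 1)")
    if (odds_ratio is None) == (delta is None):
        raise ValueError("specify exactly one of odds_ratio or delta")
    if method == "two_proportion":
        if odds_ratio is None:
            raise ValueError("two_proportion needs an odds_ratio alternative")
        if odds_ratio == 1.0:
            raise ValueError("null alternative: target power unreachable")

        def pw(n: int) -> float:
            return power_two_proportion(p2, odds_ratio, n, alpha, convention)

    elif method == "h":
        if delta is None:
            delta = h_given_or_maf(odds_ratio, p2)
        if delta == 0.0:
            raise ValueError("null alternative: target power unreachable")

        def pw(n: int) -> float:
            return power_h(delta, n, alpha)

    else:
        raise ValueError(f"unknown method {method!r}")

    # exponential bracket then binary search over even totals
    hi = 2
    while pw(hi) < target_power:
        hi *= 2
        if hi > 10**9:
            raise RuntimeError("sample-size search did not converge")
    lo = hi // 2 if hi > 2 else 0
    while hi - lo > 2:
        mid = (lo + hi) // 2
        mid -= mid % 2
        if mid <= lo:
            mid = lo + 2
        if pw(mid) >= target_power:
            hi = mid
        else:
            lo = mid
    return hi


def power_ratio_table(
    p2_grid,
    n_grid,
    odds_ratio: float,
    alpha: float = GENOME_WIDE_ALPHA,
    convention: str = "hybrid",
) -> pd.DataFrame:
    """Power of the h test vs the two-proportion test over a design grid.

    For each ``(p2, n)`` grid point the h alternative is the δ implied
    by the shared odds ratio at that ``p2``, so the two tests face the
    same truth. Columns: p2, n, power_h, power_2prop, ratio. Degenerate
    grid values (p2 outside (0, 1), n ≤ 0) are skipped with a warning.
    """
    import warnings

    p2s = list(np.atleast_1d(np.asarray(p2_grid, dtype=float)))
    ns = list(np.atleast_1d(np.asarray(n_grid, dtype=float)))
    if not p2s or not ns:
        raise ValueError("grids must be non-empty")
    rows = []
    for p2 in p2s:
        if not 0.0 < p2 < 1.0:
            warnings.warn(f"skipping degenerate p2={p2}", stacklevel=2)
            continue
        delta = h_given_or_maf(odds_ratio, p2)
        for n in ns:
            if n <= 0:
                warnings.warn(f"skipping degenerate n={n}", stacklevel=2)
                continue
            ph = power_h(delta, n, alpha)
            p2p = power_two_proportion(p2, odds_ratio, n, alpha, convention)
            rows.append((p2, int(n), ph, p2p, ph / p2p))
    return pd.DataFrame(
        rows, columns=["p2", "n", "power_h", "power_2prop", "ratio"]
    )
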