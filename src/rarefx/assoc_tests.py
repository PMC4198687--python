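"""Per-variant association tests and the whole-table genome scan.

Each effect-size measure comes with its own two-sided asymptotic test on
the allelic 2×2 table:

* ``h_test``      — z = ĥ / √(1/n1 + 1/n2)           (variance-stabilized)
* ``rd_score_test`` — z = d̂ / √(p̄q̄(1/n1 + 1/n2))     (pooled score form;
  z² is exactly the Pearson chi-square of the table)
* ``or_wald_test`` — z = log(ÔR) / se_log_or          (Wald form; undefined
  on zero cells)

Asymptotic normality is unreliable for extremely rare alleles, so
``test_variant`` falls back to a two-sided Fisher exact test whenever the
smaller MAF estimate drops below a threshold (default 0.002) or the table
has an empty cell. Both the asymptotic and the exact p-values are kept;
the significance flag uses the exact one when the fallback fired.

Multiple testing across a scan is controlled by Bonferroni or
Benjamini–Hochberg adjustment.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, ndtr
from statsmodels.stats.multitest import multipletests

from .core_effects import (
    AlleleCounts2x2,
    EffectEstimates,
    maf_pair_from_counts,
    standard_errors,
)

__all__ = [
    "TestResult",
    "VariantResult",
    "ScanConfig",
    "h_test",
    "rd_score_test",
    "or_wald_test",
    "fisher_exact_allelic",
    "test_variant",
    "adjust_pvalues",
    "genome_scan",
]

ASYMPTOTIC_METHODS = ("h", "rd", "or")


@dataclass(frozen=True)
class TestResult:
    """One two-sided test of H0: no case/control frequency difference."""

    method: str  # "h", "rd", "or" or "fisher"
    estimate: float  # effect estimate on the method's scale (nan if undefined)
    z_statistic: float  # nan for exact tests or degenerate tables
    p_value: float
    two_sided: bool = True


@dataclass
class VariantResult:
    """All tests and estimates for one variant in a scan."""

    variant_id: str
    counts: AlleleCounts2x2
    estimates: EffectEstimates
    tests: dict[str, TestResult]
    fallback_used: bool
    adjusted_p: dict[str, float] = field(default_factory=dict)
    significant: dict[str, bool] = field(default_factory=dict)


@dataclass(frozen=True)
class ScanConfig:
    """Scan-level settings: family-wise level, adjustment, fallback rule."""

    alpha_family: float = 0.05
    adjustment: str = "bonferroni"  # "bonferroni", "bh" or "none"
    maf_fallback_threshold: float = 0.002

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha_family < 1.0:
            raise ValueError("alpha_family must be in (0, 1)")
        if self.adjustment not in ("bonferroni", "bh", "none"):
            raise ValueError(f"unknown adjustment {self.adjustment!r}")
        if not 0.0 < self.maf_fallback_threshold < 1.0:
            raise ValueError("maf_fallback_threshold must be in (0, 1)")


# ---------------------------------------------------------------------------
# vectorized kernels (shared with the simulation module)

def _two_sided_p(z):
    # 2 * upper normal tail of |z|; ndtr keeps relative accuracy deep in
    # the tail, which matters at genome-wide alpha levels
    return 2.0 * ndtr(-np.abs(z))


def _z_h(x1, n1, x2, n2):
    h = 2.0 * np.arcsin(np.sqrt(x1 / n1)) - 2.0 * np.arcsin(np.sqrt(x2 / n2))
    return h / np.sqrt(1.0 / n1 + 1.0 / n2)


def _z_rd(x1, n1, x2, n2):
    """Pooled score z; nan where the pooled frequency is degenerate."""
    p1, p2 = x1 / n1, x2 / n2
    pbar = (x1 + x2) / (n1 + n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(pbar * (1.0 - pbar) * (1.0 / n1 + 1.0 / n2))
        return np.where(se > 0, (p1 - p2) / np.where(se > 0, se, 1.0), np.nan)


def _z_lor(x1, n1, x2, n2):
    """Wald z for log OR; nan on zero cells."""
    a, b, c, d = x1, n1 - x1, x2, n2 - x2
    ok = (a > 0) & (b > 0) & (c > 0) & (d > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        lor = np.log((a * d) / (b * c))
        se = np.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
        return np.where(ok, lor / se, np.nan)


# ---------------------------------------------------------------------------
# scalar tests

def h_test(counts: AlleleCounts2x2) -> TestResult:
    """Two-sided test of H0: h = 0 using the stabilized variance."""
    est = standard_errors(counts)
    z = est.h / est.se_h
    return TestResult("h", est.h, z, float(_two_sided_p(z)))


def rd_score_test(counts: AlleleCounts2x2) -> TestResult:
    """Two-sided pooled-variance score test of H0: p1 = p2.

    The squared statistic equals the Pearson chi-square of the 2×2
    table. Degenerate tables (every allele minor, or none) give p = 1
    with an undefined z.
    """
    est = standard_errors(counts)
    if est.se_d_null == 0.0:
        return TestResult("rd", est.d, math.nan, 1.0)
    z = est.d / est.se_d_null
    return TestResult("rd", est.d, z, float(_two_sided_p(z)))


def or_wald_test(counts: AlleleCounts2x2) -> TestResult:
    """Two-sided Wald test of H0: OR = 1 on the log scale.

    Estimate, z and p are all ``nan`` when the table has a zero cell.
    """
    est = standard_errors(counts)
    if not est.or_defined:
        return TestResult("or", math.nan, math.nan, math.nan)
    z = est.log_or / est.se_log_or
    return TestResult("or", est.odds_ratio, z, float(_two_sided_p(z)))


def fisher_exact_allelic(
    counts: AlleleCounts2x2, *, rel_tol: float = 1e-7
) -> TestResult:
    """Two-sided Fisher exact test on the 2×2 allele table.

    Conditional on both margins, the minor-allele count in cases follows
    a hypergeometric law; the two-sided p-value sums the probabilities
    of every table whose point probability is at most that of the
    observed table (within relative tolerance ``rel_tol``, guarding the
    comparisons of mathematically tied tables against rounding).
    """
    p = float(
        _fisher_two_sided_from_margins(
            counts.n1, counts.n2, counts.x1 + counts.x2, rel_tol=rel_tol
        )[counts.x1 - max(0, counts.x1 + counts.x2 - counts.n2)]
    )
    est = allelic_or_or_nan(counts)
    return TestResult("fisher", est, math.nan, min(1.0, p))


def allelic_or_or_nan(counts: AlleleCounts2x2) -> float:
    """Allelic OR from counts, nan on any zero cell."""
    if counts.has_zero_cell:
        return math.nan
    return standard_errors(counts).odds_ratio


def _fisher_two_sided_from_margins(
    n1: int, n2: int, s: int, *, rel_tol: float = 1e-7
) -> np.ndarray:
    """Two-sided exact p for every admissible x1 at fixed margins.

    Returns the p-value vector indexed over the hypergeometric support
    ``x1 ∈ [max(0, s−n2), min(n1, s)]``. Computing the whole support at
    once makes exhaustive validation of the test cheap.
    """
    lo, hi = max(0, s - n2), min(n1, s)
    k = np.arange(lo, hi + 1)
    logpmf = (
        gammaln(n1 + 1) - gammaln(k + 1) - gammaln(n1 - k + 1)
        + gammaln(n2 + 1) - gammaln(s - k + 1) - gammaln(n2 - s + k + 1)
    )
    logpmf -= logpmf.max()
    pmf = np.exp(logpmf)
    pmf /= pmf.sum()
    # p[i] = sum of pmf over tables no more probable than table i
    thresh = pmf * (1.0 + rel_tol)
    p = np.array([pmf[pmf <= t].sum() for t in thresh])
    return np.minimum(p, 1.0)


def test_variant(
    counts: AlleleCounts2x2, config: ScanConfig = ScanConfig()
) -> VariantResult:
    """Run all three asymptotic tests, with exact fallback where needed.

    The Fisher fallback is attached when ``min(p̂1, p̂2)`` is below
    ``config.maf_fallback_threshold`` or any 2×2 cell is zero — the
    regimes where the normal approximation (and the OR itself) break
    down.
    """
    p1, p2 = maf_pair_from_counts(counts)
    tests = {
        "h": h_test(counts),
        "rd": rd_score_test(counts),
        "or": or_wald_test(counts),
    }
    fallback = (
        min(p1, p2) < config.maf_fallback_threshold or counts.has_zero_cell
    )
    if fallback:
        tests["fisher"] = fisher_exact_allelic(counts)
    return VariantResult(
        variant_id="",
        counts=counts,
        estimates=standard_errors(counts),
        tests=tests,
        fallback_used=fallback,
    )


def adjust_pvalues(pvals, method: str = "bonferroni") -> np.ndarray:
    """Multiple-testing adjusted p-values, input order preserved.

    ``bonferroni``: min(1, m·p). ``bh``: Benjamini–Hochberg step-up
    adjusted values (monotone after sorting).
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must be in [0, 1]")
    sm_method = {"bonferroni": "bonferroni", "bh": "fdr_bh"}.get(method)
    if sm_method is None:
        raise ValueError(f"unknown adjustment method {method!r}")
    return multipletests(p, method=sm_method)[1]


def genome_scan(table, config: ScanConfig = ScanConfig()) -> list[VariantResult]:
    """Test every variant of a ``(variant_id, AlleleCounts2x2)`` table.

    Adjusted p-values are computed per method across the whole scan
    (family size = number of variants; Fisher p-values of variants
    without a fallback enter as 1). The per-method significance flag
    compares the adjusted p — the adjusted exact p where the fallback
    fired — against ``config.alpha_family``.
    """
    rows = list(table)
    if not rows:
        raise ValueError("genome_scan requires a non-empty table")
    seen: set[str] = set()
    results: list[VariantResult] = []
    for i, row in enumerate(rows):
        try:
            variant_id, counts = row
            if not isinstance(counts, AlleleCounts2x2):
                counts = AlleleCounts2x2(*counts)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"malformed scan row {i} ({row!r}): {exc}") from exc
        if variant_id in seen:
            warnings.warn(f"duplicate variant_id {variant_id!r}", stacklevel=2)
        seen.add(str(variant_id))
        res = test_variant(counts, config)
        res.variant_id = str(variant_id)
        results.append(res)

    m = len(results)
    for method in (*ASYMPTOTIC_METHODS, "fisher"):
        raw = np.array(
            [
                r.tests[method].p_value
                if method in r.tests and not math.isnan(r.tests[method].p_value)
                else 1.0
                for r in results
            ]
        )
        if config.adjustment == "none":
            adj = raw
        else:
            adj = adjust_pvalues(raw, config.adjustment)
        for r, a in zip(results, adj):
            defined = method in r.tests and not math.isnan(r.tests[method].p_value)
            r.adjusted_p[method] = float(a) if defined else math.nan
    for r in results:
        for method in ASYMPTOTIC_METHODS:
            decisive = "fisher" if r.fallback_used else method
            a = r.adjusted_p.get(decisive, math.nan)
            r.significant[method] = bool(a <= config.alpha_family) if not math.isnan(a) else False
    assert m == len(results)
    return results
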