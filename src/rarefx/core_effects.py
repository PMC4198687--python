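"""Effect-size estimators for case-control minor-allele frequencies.

Three effect-size (ES) measures are computed on the allele scale (each
diploid subject contributes two alleles):

* the risk difference ``d = p1 - p2``,
* Cohen's h, ``h = 2·arcsin(√p1) − 2·arcsin(√p2)``, the difference of
  arcsine-square-root transformed MAFs, and
* the allelic odds ratio ``OR = p1(1−p2) / (p2(1−p1))``,

where ``p1`` and ``p2`` are the minor-allele frequencies (MAFs) of the case
and control groups. The arcsine square root transform is variance
stabilizing: the asymptotic variance of ``ĥ`` is ``1/n1 + 1/n2`` regardless
of the underlying frequencies, which is what makes h attractive for rare
variants, where the variance of the log odds ratio blows up.

Undefined quantities (the OR and its standard error when any cell of the
2×2 allele table is empty) are represented as ``nan`` — never silently
continuity-corrected.
"""

from __future__ import annotations

import math
import operator
from dataclasses import dataclass

__all__ = [
    "AlleleCounts2x2",
    "EffectEstimates",
    "maf_pair_from_counts",
    "cohens_h",
    "risk_difference",
    "allelic_odds_ratio",
    "standard_errors",
    "or_to_case_maf",
    "h_given_or_maf",
]

#: (p1, p2) case/control minor-allele frequency pair.
MafPair = tuple[float, float]


@dataclass(frozen=True)
class AlleleCounts2x2:
    """Minor-allele counts of a biallelic variant in cases and controls.

    Parameters
    ----------
    x1, n1
        Minor-allele count and total allele count in cases.
    x2, n2
        Minor-allele count and total allele count in controls.

    Total allele counts are twice the subject counts for diploid data.
    """

    x1: int
    n1: int
    x2: int
    n2: int

    def __post_init__(self) -> None:
        for name in ("x1", "n1", "x2", "n2"):
            v = getattr(self, name)
            try:
                iv = operator.index(v)
            except TypeError:
                if isinstance(v, float) and v.is_integer():
                    iv = int(v)
                else:
                    raise ValueError(f"{name} must be an integer, got {v!r}") from None
            object.__setattr__(self, name, iv)
        if self.n1 <= 0 or self.n2 <= 0:
            raise ValueError(
                f"total allele counts must be positive (n1={self.n1}, n2={self.n2})"
            )
        if not (0 <= self.x1 <= self.n1):
            raise ValueError(f"need 0 <= x1 <= n1, got x1={self.x1}, n1={self.n1}")
        if not (0 <= self.x2 <= self.n2):
            raise ValueError(f"need 0 <= x2 <= n2, got x2={self.x2}, n2={self.n2}")

    @classmethod
    def from_subjects(cls, x1: int, cases: int, x2: int, controls: int) -> "AlleleCounts2x2":
        """Build from subject counts (two alleles per diploid subject)."""
        return cls(x1=x1, n1=2 * cases, x2=x2, n2=2 * controls)

    @property
    def has_zero_cell(self) -> bool:
        """True if any cell of the 2×2 allele table is empty."""
        return 0 in (self.x1, self.n1 - self.x1, self.x2, self.n2 - self.x2)


@dataclass(frozen=True)
class EffectEstimates:
    """Point estimates and asymptotic standard errors for one variant.

    ``log_or`` and ``se_log_or`` are ``nan`` when the 2×2 table has an
    empty cell; everything else is always defined. ``se_h`` depends only
    on the allele totals, never on the frequencies (variance
    stabilization).
    """

    d: float
    h: float
    log_or: float
    se_d_wald: float
    se_d_null: float
    se_h: float
    se_log_or: float

    @property
    def or_defined(self) -> bool:
        return not math.isnan(self.log_or)

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.log_or) if self.or_defined else math.nan


def maf_pair_from_counts(counts: AlleleCounts2x2) -> MafPair:
    """Maximum-likelihood MAF estimates ``(x1/n1, x2/n2)``."""
    return counts.x1 / counts.n1, counts.x2 / counts.n2


def cohens_h(mafs: MafPair) -> float:
    """Cohen's h: ``2·arcsin(√p1) − 2·arcsin(√p2)``.

    Positive when the case MAF exceeds the control MAF; bounded by ±π.
    Defined on the full closed unit square.
    """
    p1, p2 = mafs
    _check_prob(p1, "p1")
    _check_prob(p2, "p2")
    return 2.0 * math.asin(math.sqrt(p1)) - 2.0 * math.asin(math.sqrt(p2))


def risk_difference(mafs: MafPair) -> float:
    """Risk difference ``d = p1 − p2``."""
    p1, p2 = mafs
    _check_prob(p1, "p1")
    _check_prob(p2, "p2")
    return p1 - p2


def allelic_odds_ratio(mafs: MafPair) -> float:
    """Allelic odds ratio ``p1(1−p2) / (p2(1−p1))``.

    Returns ``nan`` whenever either frequency sits on the boundary of
    [0, 1] — there the ratio is 0, infinite, or indeterminate, and any
    backing 2×2 count table has an empty cell. No continuity correction
    is applied.
    """
    p1, p2 = mafs
    _check_prob(p1, "p1")
    _check_prob(p2, "p2")
    if p1 in (0.0, 1.0) or p2 in (0.0, 1.0):
        return math.nan
    return p1 * (1.0 - p2) / (p2 * (1.0 - p1))


def standard_errors(counts: AlleleCounts2x2) -> EffectEstimates:
    """All three estimates with their asymptotic standard errors.

    * ``se_h = √(1/n1 + 1/n2)`` — free of the frequencies.
    * ``se_d_wald = √(p̂1q̂1/n1 + p̂2q̂2/n2)`` — unpooled (Wald) form.
    * ``se_d_null = √(p̄q̄·(1/n1 + 1/n2))`` with pooled
      ``p̄ = (x1+x2)/(n1+n2)`` — the score-test form.
    * ``se_log_or = √(1/x1 + 1/(n1−x1) + 1/x2 + 1/(n2−x2))`` — undefined
      (``nan``, along with ``log_or``) on any zero cell.
    """
    x1, n1, x2, n2 = counts.x1, counts.n1, counts.x2, counts.n2
    p1, p2 = maf_pair_from_counts(counts)
    q1, q2 = 1.0 - p1, 1.0 - p2
    pbar = (x1 + x2) / (n1 + n2)
    qbar = 1.0 - pbar
    if counts.has_zero_cell:
        log_or = se_log_or = math.nan
    else:
        log_or = math.log(p1 * q2 / (p2 * q1))
        se_log_or = math.sqrt(1 / x1 + 1 / (n1 - x1) + 1 / x2 + 1 / (n2 - x2))
    return EffectEstimates(
        d=p1 - p2,
        h=cohens_h((p1, p2)),
        log_or=log_or,
        se_d_wald=math.sqrt(p1 * q1 / n1 + p2 * q2 / n2),
        se_d_null=math.sqrt(pbar * qbar * (1 / n1 + 1 / n2)),
        se_h=math.sqrt(1 / n1 + 1 / n2),
        se_log_or=se_log_or,
    )


def or_to_case_maf(or_value: float, p2: float) -> float:
    """Case MAF implied by an allelic odds ratio and the control MAF.

    Inverts the OR definition: ``p1 = OR·p2 / (OR·p2 − p2 + 1)``.
    """
    if not or_value > 0:
        raise ValueError(f"odds ratio must be positive, got {or_value}")
    if not 0.0 <= p2 < 1.0:
        raise ValueError(f"control MAF must be in [0, 1), got {p2}")
    return or_value * p2 / (or_value * p2 - p2 + 1.0)


def h_given_or_maf(or_value: float, p2: float) -> float:
    """Cohen's h implied by an odds ratio at a given control MAF.

    Strictly increasing in ``or_value`` at fixed ``p2``, and — unlike the
    OR↔h map at fixed h — increasing in ``p2`` at fixed OR > 1, which is
    why a single OR cut maps to larger h for common than for rare
    variants.
    """
    return cohens_h((or_to_case_maf(or_value, p2), p2))


def _check_prob(p: float, name: str) -> None:
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"{name} must be in [0, 1], got {p}")
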