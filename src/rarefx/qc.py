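"""SNP-level quality control for case-control genotype matrices.

Four exclusion criteria, applied per variant, mirror standard
array-GWAS practice:

1. minor-allele frequency in the shared controls below a floor
   (default 0.002 — below which fewer than a handful of minor-allele
   carriers exist and calling is unreliable);
2. genotype call rate below 95%;
3. Hardy–Weinberg equilibrium exact-test p-value in controls below
   5.7e-7 (a genotyping-failure signature);
4. allele-frequency difference between the two control sub-cohorts
   (two-proportion score test) with p below 5.7e-7 — frequency
   heterogeneity where none should exist flags batch artifacts.

Every violated criterion is reported; evaluation never short-circuits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .assoc_tests import _two_sided_p, _z_rd

__all__ = [
    "GenotypeMatrix",
    "QCThresholds",
    "hwe_exact_test",
    "snp_qc",
    "classify_rare_common",
]


@dataclass
class GenotypeMatrix:
    """Subjects × variants matrix of minor-allele dosage codes.

    ``codes`` holds values in {0, 1, 2} with ``NaN`` for missing calls;
    rows are subjects, columns variants. ``cohort`` labels each subject
    (e.g. two control sub-cohorts plus a case group).
    """

    codes: pd.DataFrame
    cohort: pd.Series

    def __post_init__(self) -> None:
        self.cohort = self.cohort.reindex(self.codes.index)
        if self.cohort.isna().any():
            missing = list(self.codes.index[self.cohort.isna()])[:3]
            raise ValueError(f"subjects without cohort label: {missing}")
        vals = self.codes.to_numpy(dtype=float)
        bad = ~(np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0)))
        if bad.any():
            raise ValueError("genotype codes must be 0/1/2 or missing")

    @property
    def subjects(self) -> list:
        return list(self.codes.index)

    @property
    def variants(self) -> list:
        return list(self.codes.columns)

    def subset(self, cohorts) -> pd.DataFrame:
        """Codes of the subjects belonging to the given cohort labels."""
        unknown = set(cohorts) - set(self.cohort.unique())
        if unknown:
            raise ValueError(f"unknown cohort labels: {sorted(unknown)}")
        return self.codes.loc[self.cohort.isin(cohorts)]


@dataclass(frozen=True)
class QCThresholds:
    """Cut-offs for the four exclusion criteria."""

    min_maf: float = 0.002
    min_call_rate: float = 0.95
    hwe_p: float = 5.7e-7
    cohort_het_p: float = 5.7e-7


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact conditional test of Hardy–Weinberg genotype proportions.

    Conditions on the observed allele counts: with ``n`` subjects and
    ``na`` copies of the rarer allele, the heterozygote count ranges
    over values of the same parity as ``na``, with conditional
    probability P(het = k) ∝ n! / (nAA! k! naa!) · 2^k. The two-sided
    p-value sums the probabilities of all heterozygote counts no more
    probable than the observed one (point-probability rule).
    """
    for name, v in (("n_AA", n_AA), ("n_Aa", n_Aa), ("n_aa", n_aa)):
        if v < 0 or v != int(v):
            raise ValueError(f"{name} must be a non-negative integer, got {v}")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("no genotypes observed")
    na = 2 * min(n_AA, n_aa) + n_Aa  # copies of the rarer allele
    k = np.arange(na % 2, min(na, 2 * n - na) + 1, 2)
    n_rare_hom = (na - k) // 2
    n_common_hom = n - n_rare_hom - k
    logpmf = (
        k * math.log(2.0)
        - gammaln(n_rare_hom + 1)
        - gammaln(k + 1)
        - gammaln(n_common_hom + 1)
    )
    logpmf -= logpmf.max()
    pmf = np.exp(logpmf)
    pmf /= pmf.sum()
    obs = pmf[np.searchsorted(k, n_Aa)]
    return float(min(1.0, pmf[pmf <= obs * (1.0 + 1e-7)].sum()))


def _fold_to_minor(ctrl: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Fold codes so they count the control-minor allele; return freqs."""
    freq = ctrl.mean(axis=0) / 2.0
    flip = freq > 0.5
    folded = ctrl.copy()
    folded.loc[:, flip] = 2.0 - folded.loc[:, flip]
    return folded, freq.where(~flip, 1.0 - freq)


def snp_qc(
    g: GenotypeMatrix,
    thresholds: QCThresholds = QCThresholds(),
    control_cohorts=("58C", "NBS"),
) -> pd.DataFrame:
    """Apply the four per-SNP exclusion criteria.

    Returns one row per variant with columns ``maf_controls``,
    ``call_rate``, ``hwe_p_controls``, ``cohort_het_p``, ``pass`` and
    ``fail_reasons`` (comma-joined subset of
    {maf, call_rate, hwe, cohort_het}). Criterion 4 compares allele
    frequencies between the first two control cohorts and is skipped
    (p = NaN) when only one control cohort is given. MAF, HWE and the
    cohort comparison are computed on controls after folding to the
    control-minor allele; missing genotypes are excluded from allele
    and genotype counts, while the call rate is over all subjects.
    """
    control_cohorts = tuple(control_cohorts)
    ctrl = g.subset(control_cohorts)
    folded, maf = _fold_to_minor(ctrl)
    call_rate = g.codes.notna().mean(axis=0)

    hwe_p = pd.Series(index=g.codes.columns, dtype=float)
    for v in g.codes.columns:
        col = folded[v].dropna()
        counts = col.value_counts()
        n_aa = int(counts.get(2.0, 0))  # rare-allele homozygote
        n_Aa = int(counts.get(1.0, 0))
        n_AA = int(counts.get(0.0, 0))
        hwe_p[v] = hwe_exact_test(n_AA, n_Aa, n_aa) if (n_AA + n_Aa + n_aa) else math.nan

    if len(control_cohorts) >= 2:
        a = g.subset(control_cohorts[:1])
        b = g.subset(control_cohorts[1:2])
        x1 = a.sum(axis=0, skipna=True).to_numpy()
        n1 = 2.0 * a.notna().sum(axis=0).to_numpy()
        x2 = b.sum(axis=0, skipna=True).to_numpy()
        n2 = 2.0 * b.notna().sum(axis=0).to_numpy()
        with np.errstate(invalid="ignore"):
            z = _z_rd(x1, np.where(n1 > 0, n1, np.nan), x2, np.where(n2 > 0, n2, np.nan))
        het_p = pd.Series(np.where(np.isnan(z), 1.0, _two_sided_p(z)), index=g.codes.columns)
    else:
        het_p = pd.Series(math.nan, index=g.codes.columns)

    report = pd.DataFrame(
        {
            "maf_controls": maf,
            "call_rate": call_rate,
            "hwe_p_controls": hwe_p,
            "cohort_het_p": het_p,
        }
    )
    reasons = []
    for v, row in report.iterrows():
        fails = []
        if not row.maf_controls >= thresholds.min_maf:
            fails.append("maf")
        if row.call_rate < thresholds.min_call_rate:
            fails.append("call_rate")
        if row.hwe_p_controls < thresholds.hwe_p:
            fails.append("hwe")
        if row.cohort_het_p < thresholds.cohort_het_p:
            fails.append("cohort_het")
        reasons.append(",".join(fails))
    report["fail_reasons"] = reasons
    report["pass"] = report["fail_reasons"] == ""
    return report


def classify_rare_common(maf: float, cut: float = 0.05) -> str:
    """"rare" iff the folded MAF is below the cut; the boundary is common."""
    import warnings

    if not 0.0 <= maf <= 1.0:
        raise ValueError(f"MAF must be in [0, 1], got {maf}")
    if maf > 0.5:
        warnings.warn(f"frequency {maf} > 0.5 folded to the minor allele", stacklevel=2)
        maf = 1.0 - maf
    return "rare" if maf < cut else "common"
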