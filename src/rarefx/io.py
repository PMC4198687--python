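"""Tabular input/output: counts tables, genotype matrices, result TSVs.

Formats are deliberately plain:

* counts table — TSV with header columns ``variant_id x1 n1 x2 n2``
  (optional ``chrom``/``pos`` carried through);
* genotype matrix — TSV with ``subject`` and ``cohort`` columns followed
  by one column per variant holding 0/1/2/NA minor-allele dosages, or a
  minimal biallelic VCF (GT field only; multi-allelic records are
  skipped with a warning);
* scan results — one row per input variant, column names following the
  usual per-SNP report layout (MAF_controls, MAF_cases, OR, P_OR, RD,
  P_RD, h, P_h, P_exact, ...).

Output is byte-stable for fixed inputs: fixed column order, floats at
6 significant digits, scientific notation for p < 1e-4, and p-values
below the double floor written as ``<1e-300``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .assoc_tests import ScanConfig, VariantResult
from .core_effects import AlleleCounts2x2
from .qc import GenotypeMatrix, classify_rare_common
from .thresholds import COMMON_SCHEME, RARE_SCHEME, classify_effect

__all__ = [
    "RunConfig",
    "read_counts_table",
    "counts_table_rows",
    "write_counts_table",
    "read_genotypes",
    "write_genotypes_tsv",
    "write_scan_results",
    "fmt_value",
    "fmt_pvalue",
]

COUNT_COLUMNS = ("variant_id", "x1", "n1", "x2", "n2")


@dataclass(frozen=True)
class RunConfig:
    """Toolkit-wide run settings shared by the CLI subcommands."""

    alpha_family: float = 0.05
    adjustment: str = "bonferroni"
    maf_fallback_threshold: float = 0.002
    rare_common_cut: float = 0.05
    power_convention: str = "hybrid"
    seed: int = 0

    def scan_config(self) -> ScanConfig:
        return ScanConfig(
            alpha_family=self.alpha_family,
            adjustment=self.adjustment,
            maf_fallback_threshold=self.maf_fallback_threshold,
        )


def read_counts_table(path) -> pd.DataFrame:
    """Read and validate a per-variant allele-counts TSV."""
    df = pd.read_csv(path, sep="\t", dtype={"variant_id": str})
    missing = [c for c in COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"counts table missing columns: {missing}")
    for col in ("x1", "n1", "x2", "n2"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals % 1 != 0)
        if bad.any():
            row = int(np.argmax(bad.to_numpy()))
            raise ValueError(f"non-integer count in column {col!r}, row {row}")
        df[col] = vals.astype("int64")
    for row_i, row in df.iterrows():
        try:
            AlleleCounts2x2(row.x1, row.n1, row.x2, row.n2)
        except ValueError as exc:
            raise ValueError(f"invalid counts at row {row_i}: {exc}") from exc
    if df["variant_id"].duplicated().any():
        dups = df["variant_id"][df["variant_id"].duplicated()].unique()[:3]
        warnings.warn(f"duplicate variant ids: {list(dups)}", stacklevel=2)
    return df


def counts_table_rows(df: pd.DataFrame):
    """Yield ``(variant_id, AlleleCounts2x2)`` pairs for genome_scan."""
    for row in df.itertuples(index=False):
        yield row.variant_id, AlleleCounts2x2(row.x1, row.n1, row.x2, row.n2)


def write_counts_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_genotypes(path, format: str = "tsv", cohort_map=None) -> GenotypeMatrix:
    """Load a genotype matrix from TSV or minimal biallelic VCF.

    For VCF input cohort labels are taken from ``cohort_map``
    (subject → label); unmapped subjects default to ``"control"``.
    Multi-allelic records are skipped with a warning.
    """
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", na_values=["NA"], dtype={0: str, 1: str})
        if df.shape[1] < 3 or list(df.columns[:2]) != ["subject", "cohort"]:
            raise ValueError(
                "genotype TSV must start with 'subject' and 'cohort' columns"
            )
        codes = df.set_index("subject").drop(columns=["cohort"]).astype(float)
        bad = ~(codes.isna() | codes.isin((0.0, 1.0, 2.0)))
        if bad.any().any():
            col = bad.any(axis=0).idxmax()
            raise ValueError(f"unknown genotype code in variant column {col!r}")
        cohort = df.set_index("subject")["cohort"]
        codes.index.name = cohort.index.name = None
        return GenotypeMatrix(codes=codes, cohort=cohort)
    if format == "vcf":
        return _read_vcf(path, cohort_map)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_vcf(path, cohort_map) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    columns: dict[str, np.ndarray] = {}
    for variant in vcf:
        if len(variant.ALT) != 1:
            warnings.warn(
                f"skipping multi-allelic record {variant.CHROM}:{variant.POS}",
                stacklevel=2,
            )
            continue
        vid = variant.ID or f"{variant.CHROM}:{variant.POS}"
        # gt_types: 0 hom-ref, 1 het, 2 unknown, 3 hom-alt -> alt dosage
        gt = np.asarray(variant.gt_types, dtype=float)
        dosage = np.select([gt == 0, gt == 1, gt == 3], [0.0, 1.0, 2.0], np.nan)
        columns[vid] = dosage
    codes = pd.DataFrame(columns, index=samples)
    cohort_map = cohort_map or {}
    cohort = pd.Series([cohort_map.get(s, "control") for s in samples], index=samples)
    return GenotypeMatrix(codes=codes, cohort=cohort)


def write_genotypes_tsv(g: GenotypeMatrix, path) -> None:
    out = g.codes.copy()
    out.insert(0, "cohort", g.cohort)
    out.index.name = "subject"
    with_na = out.reset_index()
    for c in with_na.columns[2:]:
        with_na[c] = with_na[c].map(
            lambda v: "NA" if (isinstance(v, float) and math.isnan(v)) else str(int(v))
        )
    with_na.to_csv(path, sep="\t", index=False)


def fmt_value(x: float) -> str:
    """Fixed 6-significant-digit rendering; NA for undefined."""
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return "NA"
    return f"{x:.6g}"


def fmt_pvalue(p: float) -> str:
    """P-value rendering: scientific below 1e-4, never truncated to 0."""
    if p is None or (isinstance(p, float) and math.isnan(p)):
        return "NA"
    if p != 0.0 and p < 1e-300:
        return "<1e-300"
    if p == 0.0:
        return "<1e-300"
    if p < 1e-4:
        return f"{p:.6e}"
    return f"{p:.6g}"


RESULT_COLUMNS = [
    "variant_id", "x1", "n1", "x2", "n2",
    "MAF_cases", "MAF_controls", "variant_class",
    "RD", "SE_RD", "P_RD",
    "h", "SE_h", "P_h",
    "OR", "P_OR",
    "P_exact", "fallback",
    "P_adj_RD", "P_adj_h", "P_adj_OR",
    "sig_RD", "sig_h", "sig_OR",
    "ES_band_h",
]


def write_scan_results(
    results: list[VariantResult], path, rare_common_cut: float = 0.05
) -> None:
    """Serialize genome-scan results as a TSV, one row per variant."""
    lines = ["\t".join(RESULT_COLUMNS)]
    for r in results:
        c, e = r.counts, r.estimates
        p1, p2 = c.x1 / c.n1, c.x2 / c.n2
        vclass = classify_rare_common(min(p2, 1 - p2), rare_common_cut)
        scheme = RARE_SCHEME if vclass == "rare" else COMMON_SCHEME
        fisher = r.tests.get("fisher")
        vals = {
            "variant_id": r.variant_id,
            "x1": str(c.x1), "n1": str(c.n1), "x2": str(c.x2), "n2": str(c.n2),
            "MAF_cases": fmt_value(p1), "MAF_controls": fmt_value(p2),
            "variant_class": vclass,
            "RD": fmt_value(e.d), "SE_RD": fmt_value(e.se_d_null),
            "P_RD": fmt_pvalue(r.tests["rd"].p_value),
            "h": fmt_value(e.h), "SE_h": fmt_value(e.se_h),
            "P_h": fmt_pvalue(r.tests["h"].p_value),
            "OR": fmt_value(e.odds_ratio),
            "P_OR": fmt_pvalue(r.tests["or"].p_value),
            "P_exact": fmt_pvalue(fisher.p_value) if fisher else "NA",
            "fallback": str(r.fallback_used).lower(),
            "P_adj_RD": fmt_pvalue(r.adjusted_p.get("rd", math.nan)),
            "P_adj_h": fmt_pvalue(r.adjusted_p.get("h", math.nan)),
            "P_adj_OR": fmt_pvalue(r.adjusted_p.get("or", math.nan)),
            "sig_RD": str(r.significant.get("rd", False)).lower(),
            "sig_h": str(r.significant.get("h", False)).lower(),
            "sig_OR": str(r.significant.get("or", False)).lower(),
            "ES_band_h": classify_effect(e.h, scheme, "h"),
        }
        lines.append("\t".join(vals[c2] for c2 in RESULT_COLUMNS))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
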