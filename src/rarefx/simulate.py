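"""Monte-Carlo machinery: null calibration and empirical power.

The generator emulates a balanced biallelic case-control panel under
Hardy–Weinberg equilibrium: for each variant a control MAF ``p2`` is
drawn from a configurable spectrum, the case MAF ``p1`` is implied by
the alternative odds ratio (``p1 = p2`` under the null), and minor-
allele counts are sampled binomially on the allele scale,
``x_g ~ Binomial(2·subjects_g, p_g)``. This mirrors a pseudo
case-control experiment — randomly splitting a homogeneous control pool
into artificial arms so that every variant is null by construction —
without requiring the original genotypes. The default arm sizes, 1,480
pseudo-cases and 1,458 pseudo-controls, are those of that design.

What the generator does not emulate: linkage disequilibrium between
variants, population stratification, differential genotyping error —
the real-data forces that inflate type I error beyond the binomial
ideal.

Reported calibration indices per measure (RD, Cohen's h, log OR):

* bias — mean estimate over replicate × variant cells (truth 0 under
  the null);
* MSE — mean squared estimate; for Cohen's h the variance-stabilized
  prediction is ``1/n1 + 1/n2`` allele-scale, independent of the MAF
  spectrum;
* type I error — fraction of cells with p below the nominal level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .assoc_tests import _two_sided_p, _z_h, _z_lor, _z_rd
from .core_effects import or_to_case_maf

__all__ = [
    "SimSpec",
    "MeasureStats",
    "CalibrationReport",
    "simulate_counts",
    "pseudo_case_control",
    "null_calibration",
    "empirical_power",
]


@dataclass(frozen=True)
class SimSpec:
    """Design of a simulated case-control panel.

    ``maf_model`` is a fixed control MAF, a ``(low, high)`` uniform
    range, or an explicit sequence cycled over variants. ``or_alt = 1``
    gives a null panel. One replicate redraws every variant's allele
    counts at fixed per-variant MAFs.
    """

    n_case_subjects: int = 1480
    n_control_subjects: int = 1458
    maf_model: object = (0.05, 0.5)
    or_alt: float = 1.0
    n_variants: int = 1000
    n_replicates: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_case_subjects, self.n_control_subjects) <= 0:
            raise ValueError("subject counts must be positive")
        if min(self.n_variants, self.n_replicates) <= 0:
            raise ValueError("n_variants and n_replicates must be positive")
        if not self.or_alt > 0:
            raise ValueError("or_alt must be positive")

    def control_mafs(self, rng: np.random.Generator) -> np.ndarray:
        m = self.maf_model
        if np.isscalar(m):
            p2 = np.full(self.n_variants, float(m))
        elif isinstance(m, tuple) and len(m) == 2:
            p2 = rng.uniform(m[0], m[1], size=self.n_variants)
        else:
            vals = np.asarray(m, dtype=float)
            p2 = np.resize(vals, self.n_variants)
        if np.any((p2 <= 0) | (p2 >= 1)):
            raise ValueError("control MAFs must lie strictly inside (0, 1)")
        return p2


@dataclass(frozen=True)
class MeasureStats:
    bias: float
    mse: float
    type1_rate: float
    n_undefined: int = 0


@dataclass(frozen=True)
class CalibrationReport:
    """Null-calibration indices per measure, plus the run provenance."""

    rd: MeasureStats
    h: MeasureStats
    log_or: MeasureStats
    n_cells: int
    level: float
    seed: int

    def as_dict(self) -> dict:
        out: dict = {"n_cells": self.n_cells, "level": self.level, "seed": self.seed}
        for name in ("rd", "h", "log_or"):
            s: MeasureStats = getattr(self, name)
            out[name] = {
                "bias": s.bias,
                "mse": s.mse,
                "type1_rate": s.type1_rate,
                "n_undefined": s.n_undefined,
            }
        return out


def simulate_counts(spec: SimSpec, rng: np.random.Generator | None = None):
    """Draw allele-count arrays for one panel.

    Returns ``(x1, x2, n1, n2, p2)`` where ``x1`` and ``x2`` have shape
    ``(n_replicates, n_variants)`` and ``p2`` the per-variant control
    MAFs. Deterministic given ``spec.seed`` (or an explicit generator).
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    n1 = 2 * spec.n_case_subjects
    n2 = 2 * spec.n_control_subjects
    p2 = spec.control_mafs(rng)
    p1 = np.array([or_to_case_maf(spec.or_alt, v) for v in p2])
    if np.any((p1 <= 0) | (p1 >= 1)):
        raise ValueError("implied case MAF outside (0, 1)")
    shape = (spec.n_replicates, spec.n_variants)
    x2 = rng.binomial(n2, np.broadcast_to(p2, shape))
    x1 = rng.binomial(n1, np.broadcast_to(p1, shape))
    return x1, x2, n1, n2, p2


def pseudo_case_control(subjects, n_pseudo_cases: int, seed: int = 0):
    """Random exhaustive split of a subject pool into two pseudo-arms.

    ``subjects`` is a label sequence or a total count. Returns
    ``(pseudo_cases, pseudo_controls)`` as label arrays — a disjoint,
    exhaustive partition of sizes ``(n_pseudo_cases, rest)``.
    """
    labels = np.arange(subjects) if np.isscalar(subjects) else np.asarray(list(subjects))
    total = labels.size
    if not 0 < n_pseudo_cases < total:
        raise ValueError(
            f"n_pseudo_cases must be in (0, {total}), got {n_pseudo_cases}"
        )
    perm = np.random.default_rng(seed).permutation(total)
    return labels[perm[:n_pseudo_cases]], labels[perm[n_pseudo_cases:]]


def _measure_arrays(x1, n1, x2, n2):
    """Estimates and z statistics for all three measures, vectorized."""
    p1, p2 = x1 / n1, x2 / n2
    d = p1 - p2
    h = 2.0 * np.arcsin(np.sqrt(p1)) - 2.0 * np.arcsin(np.sqrt(p2))
    with np.errstate(divide="ignore", invalid="ignore"):
        a, b, c, e = x1, n1 - x1, x2, n2 - x2
        ok = (a > 0) & (b > 0) & (c > 0) & (e > 0)
        lor = np.where(ok, np.log(np.where(ok, (a * e) / (b * c), 1.0)), np.nan)
    z = {
        "rd": _z_rd(x1, n1, x2, n2),
        "h": _z_h(x1, n1, x2, n2),
        "log_or": _z_lor(x1, n1, x2, n2),
    }
    return {"rd": d, "h": h, "log_or": lor}, z


def null_calibration(spec: SimSpec, level: float = 0.05) -> CalibrationReport:
    """Bias, MSE and empirical type I error on a null panel.

    Undefined log-OR cells (zero-cell tables) are excluded from the OR
    bias/MSE and counted; the corresponding test cell is treated as a
    non-rejection (its Wald p is undefined, and the asymptotic
    calibration deliberately runs without the exact fallback).
    """
    if spec.or_alt != 1.0:
        raise ValueError("null_calibration requires or_alt = 1")
    est, z = _simulated_stats(spec)
    return _report(est, z, level, spec)


def empirical_power(spec: SimSpec, level: float = 0.05) -> dict:
    """Per-measure empirical rejection rates on an alternative panel.

    Returns ``{measure: (power, mc_se)}`` with binomial Monte-Carlo
    standard errors over all replicate × variant cells.
    """
    est, z = _simulated_stats(spec)
    out = {}
    for name, zz in z.items():
        p = _two_sided_p(zz)
        rej = np.where(np.isnan(p), False, p < level)
        n = p.size
        rate = float(np.mean(rej))
        out[name] = (rate, math.sqrt(max(rate * (1 - rate), 1e-12) / n))
    return out


def _simulated_stats(spec: SimSpec):
    x1, x2, n1, n2, _ = simulate_counts(spec)
    return _measure_arrays(x1.astype(float), float(n1), x2.astype(float), float(n2))


def _report(est, z, level, spec) -> CalibrationReport:
    stats = {}
    for name in ("rd", "h", "log_or"):
        e = est[name]
        undef = int(np.isnan(e).sum())
        ok = e[~np.isnan(e)]
        p = _two_sided_p(z[name])
        rej = np.where(np.isnan(p), False, p < level)
        stats[name] = MeasureStats(
            bias=float(ok.mean()),
            mse=float((ok**2).mean()),
            type1_rate=float(np.mean(rej)),
            n_undefined=undef,
        )
    n_cells = est["h"].size
    return CalibrationReport(
        rd=stats["rd"], h=stats["h"], log_or=stats["log_or"],
        n_cells=n_cells, level=level, seed=spec.seed,
    )
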