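"""Effect-size interpretation bands for Cohen's h and the odds ratio.

Cohen's conventional small/medium/large cuts for h (0.2 / 0.5 / 0.8)
were calibrated for proportions near 0.5 and are far too coarse for
GWAS, where nearly every variant would be labelled "small". The bands
used here are instead anchored to the odds-ratio cuts practitioners
already use, translated to the h scale by averaging the OR→h map over a
MAF range:

* common variants (MAF ≥ 0.05): OR cuts 1.2 / 1.5 ↔ |h| cuts 0.075 / 0.15
* rare variants  (MAF < 0.05): OR cuts 1.5 / 2  ↔ |h| cuts 0.05 / 0.1

Boundary values fall into the lower band (a value exactly at a cut is
"mild"/"moderate", not the next band up).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core_effects import EffectEstimates, h_given_or_maf

__all__ = [
    "ThresholdScheme",
    "COMMON_SCHEME",
    "RARE_SCHEME",
    "COHEN_CONVENTIONAL_SCHEME",
    "scheme_for",
    "derive_h_thresholds",
    "classify_effect",
]


@dataclass(frozen=True)
class ThresholdScheme:
    """Mild/moderate band edges on the |h| and |log OR| scales."""

    name: str
    mild_max_h: float
    moderate_max_h: float
    mild_max_logor: float | None = None
    moderate_max_logor: float | None = None

    def __post_init__(self) -> None:
        if not 0 < self.mild_max_h < self.moderate_max_h:
            raise ValueError("need 0 < mild_max_h < moderate_max_h")
        if self.mild_max_logor is not None and not (
            0 < self.mild_max_logor < (self.moderate_max_logor or math.inf)
        ):
            raise ValueError("need 0 < mild_max_logor < moderate_max_logor")


COMMON_SCHEME = ThresholdScheme(
    "common", 0.075, 0.15, math.log(1.2), math.log(1.5)
)
RARE_SCHEME = ThresholdScheme("rare", 0.05, 0.1, math.log(1.5), math.log(2.0))
#: Cohen's original small/medium cuts; no OR counterpart was defined.
COHEN_CONVENTIONAL_SCHEME = ThresholdScheme("cohen", 0.2, 0.5)

_SCHEMES = {s.name: s for s in (COMMON_SCHEME, RARE_SCHEME, COHEN_CONVENTIONAL_SCHEME)}


def scheme_for(variant_class: str) -> ThresholdScheme:
    """Look up a named scheme ("rare", "common" or "cohen")."""
    try:
        return _SCHEMES[variant_class]
    except KeyError:
        raise ValueError(f"unknown threshold scheme {variant_class!r}") from None


def derive_h_thresholds(or_cuts, p2_range, grid_step: float = 0.001):
    """Map OR cut points to h cut points by averaging over a MAF range.

    For each OR cut the returned threshold is the mean of
    ``h_given_or_maf(cut, p2)`` over a uniform grid on
    ``p2_range = (low, high]`` with the given step. Monotone in the cut
    (and in the upper range end), since h grows with both OR and MAF.
    """
    low, high = p2_range
    if not 0.0 < low < high <= 0.5:
        raise ValueError(f"need 0 < low < high <= 0.5, got {p2_range}")
    grid = np.arange(low + grid_step, high + grid_step / 2, grid_step)
    grid = grid[grid <= high]
    if grid.size == 0:
        raise ValueError("MAF grid is empty; reduce grid_step")
    return [float(np.mean([h_given_or_maf(c, p2) for p2 in grid])) for c in or_cuts]


def classify_effect(
    estimates: EffectEstimates | float,
    scheme: ThresholdScheme,
    scale: str = "h",
) -> str:
    """Band ("mild", "moderate" or "large") of an effect estimate.

    ``estimates`` may be an :class:`EffectEstimates` or a bare value on
    the requested scale (h, or an odds ratio for ``scale="or"``).
    Classification uses the absolute value (log-scale for OR); an
    undefined estimate on the requested scale raises.
    """
    if scale == "h":
        value = estimates.h if isinstance(estimates, EffectEstimates) else float(estimates)
        if math.isnan(value):
            raise ValueError("h estimate is undefined; cannot classify on the h scale")
        mild, moderate = scheme.mild_max_h, scheme.moderate_max_h
        mag = abs(value)
    elif scale == "or":
        if isinstance(estimates, EffectEstimates):
            if not estimates.or_defined:
                raise ValueError(
                    "odds ratio is undefined (zero cell); cannot classify on the OR scale"
                )
            mag = abs(estimates.log_or)
        else:
            value = float(estimates)
            if math.isnan(value) or value <= 0:
                raise ValueError("odds ratio must be positive and defined")
            mag = abs(math.log(value))
        if scheme.mild_max_logor is None:
            raise ValueError(f"scheme {scheme.name!r} has no OR-scale cuts")
        mild, moderate = scheme.mild_max_logor, scheme.moderate_max_logor
    else:
        raise ValueError(f"unknown scale {scale!r}")
    if mag <= mild:
        return "mild"
    if mag <= moderate:
        return "moderate"
    return "large"
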