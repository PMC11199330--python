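"""Volumetric primary production Pe(z) from 14C light/dark-bottle counts.

The carbon fixed per unit volume and hour at depth z is

    Pe(z) = <dpma(z)> * TCO2 * 13.356 * k1 * k2 * k3 / dpmb   [mgC m^-3 h^-1]

where <dpma(z)> is the mean light-minus-dark bottle activity (dpm), dpmb the
activity of the added tracer, TCO2 the total inorganic carbon (mM dm^-3),
and 13.356 = 12 (atomic weight of carbon) x 1.05 (14C uptake discrimination)
x 1.06 (respiratory loss during incubation).  k1 corrects subsampling, k2
converts per-exposure to per-hour rates, and k3 rescales dm^-3 to m^-3.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import fmean
from typing import Sequence

from .carbonate import CarbonateState
from .profiles import BottleSet

__all__ = [
    "ProductionConstants",
    "PeResult",
    "composite_constant",
    "mean_dpm_excess",
    "compute_pe",
    "microcurie_to_dpm",
    "DPM_PER_MICROCURIE",
]

#: 1 uCi = 2.22e6 dpm (definition of the curie).
DPM_PER_MICROCURIE = 2.22e6


class RadiocarbonError(ValueError):
    pass


@dataclass(frozen=True)
class ProductionConstants:
    """Fixed factors of the production equation."""

    c_atomic: float = 12.0
    f_discrimination: float = 1.05  # 14C taken up 5% slower than 12C
    f_respiration: float = 1.06    # 6% respiratory loss at optimal photosynthesis


def composite_constant(constants: ProductionConstants = ProductionConstants()) -> float:
    """Product of the three fixed factors, rounded to 3 decimals (13.356)."""
    if min(constants.c_atomic, constants.f_discrimination, constants.f_respiration) <= 0:
        raise RadiocarbonError("production-constant factors must be positive")
    return round(
        constants.c_atomic * constants.f_discrimination * constants.f_respiration, 3
    )


def mean_dpm_excess(dpm_light: Sequence[float], dpm_dark: Sequence[float]) -> float:
    """Mean light-minus-dark activity <dpma>, in dpm.

    With equal replicate counts this is the mean of pairwise differences;
    with unequal counts, the difference of the replicate means.  The two
    conventions have identical expectations — the pairwise form is kept for
    determinism when counts match.  May be negative (dark uptake exceeding
    light uptake is measurement noise, handled downstream).
    """
    if len(dpm_light) == 0 or len(dpm_dark) == 0:
        raise RadiocarbonError("empty replicate list")
    if len(dpm_light) == len(dpm_dark):
        return fmean(l - d for l, d in zip(dpm_light, dpm_dark))
    return fmean(dpm_light) - fmean(dpm_dark)


@dataclass(frozen=True)
class PeResult:
    pe_mgC_m3_h: float
    raw_pe: float          # before any clamping
    clamped: bool
    mean_dpm_excess: float
    total_co2_mM: float


def compute_pe(
    bottles: BottleSet,
    carbonate: CarbonateState,
    constants: ProductionConstants = ProductionConstants(),
    clamp_negative: bool = True,
) -> PeResult:
    """Evaluate the production equation for one depth level.

    Negative raw rates (dark > light) are clamped to zero with a flag when
    ``clamp_negative`` — no negative production is physically meaningful.
    """
    if carbonate is None:
        raise RadiocarbonError("missing carbonate state")
    excess = mean_dpm_excess(bottles.dpm_light, bottles.dpm_dark)
    raw = (
        excess
        * carbonate.total_co2_mM
        * composite_constant(constants)
        * bottles.k1_subsample
        * bottles.k2
        * bottles.k3_dimension
        / bottles.dpm_added
    )
    clamped = clamp_negative and raw < 0.0
    return PeResult(
        pe_mgC_m3_h=0.0 if clamped else raw,
        raw_pe=raw,
        clamped=clamped,
        mean_dpm_excess=excess,
        total_co2_mM=carbonate.total_co2_mM,
    )


def microcurie_to_dpm(uci: float) -> float:
    """Convert a tracer activity from uCi to dpm (8 uCi -> 1.776e7 dpm)."""
    if uci <= 0:
        raise RadiocarbonError("tracer activity must be positive")
    return uci * DPM_PER_MICROCURIE
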