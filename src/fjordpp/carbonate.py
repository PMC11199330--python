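"""Total inorganic carbon from in-situ temperature, salinity and pH.

The 14C method needs the total CO2 concentration of the incubated sample.
Following the classical titration-free shipboard approach, carbonate
alkalinity is estimated from salinity through a specific-alkalinity factor,
bicarbonate is obtained from alkalinity and pH, and total CO2 follows from
the apparent dissociation constants of carbonic acid in seawater:

    CA    = f_SA * S                          [meq L^-1]
    h     = 10^(-pH)
    HCO3  = CA / (1 + 2 K2'/h)                [mmol L^-1]
    TCO2  = HCO3 * (h/K1' + 1 + K2'/h)        [mM dm^-3]

K1' and K2' are evaluated at (T, S) from a named published fit; the choice
of fit and of the specific-alkalinity factor are configuration, recorded in
the returned state, because different hydrochemical handbooks tabulate
slightly different values.  Borate and other minor alkalinity contributions
are deliberately ignored (carbonate alkalinity, not total alkalinity).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["CarbonateState", "CarbonateOptions", "apparent_constants", "total_co2"]

#: meq L^-1 per salinity unit; classical surface-ocean specific alkalinity.
DEFAULT_SPECIFIC_ALKALINITY = 0.068

CONSTANT_SETS = ("lueker2000", "mehrbach_dm87")


class CarbonateError(ValueError):
    pass


@dataclass(frozen=True)
class CarbonateOptions:
    specific_alkalinity_factor: float = DEFAULT_SPECIFIC_ALKALINITY
    constant_set: str = "lueker2000"

    def __post_init__(self) -> None:
        if self.specific_alkalinity_factor <= 0:
            raise CarbonateError("specific alkalinity factor must be positive")
        if self.constant_set not in CONSTANT_SETS:
            raise CarbonateError(
                f"unknown constant set {self.constant_set!r}; choose from {CONSTANT_SETS}"
            )


@dataclass(frozen=True)
class CarbonateState:
    """Carbonate speciation at one level, with provenance of the constants."""

    temperature_C: float
    salinity_psu: float
    pH: float
    total_co2_mM: float
    carbonate_alkalinity_meq_l: float
    K1_app: float
    K2_app: float
    constant_set: str
    specific_alkalinity_factor: float


def apparent_constants(temperature_C: float, salinity_psu: float,
                       constant_set: str = "lueker2000") -> tuple[float, float]:
    """Apparent K1', K2' of carbonic acid in seawater at (T, S).

    ``lueker2000``: Lueker, Dickson & Keeling (2000) refit of the Mehrbach
    constants (total pH scale, mol kg-SW^-1) — the set recommended for
    oceanic conditions.  ``mehrbach_dm87``: the Dickson & Millero (1987)
    refit of Mehrbach et al. (1973).  Both fits are valid across the
    sub-polar T/S range sampled in fjords.
    """
    T = temperature_C + 273.15
    S = salinity_psu
    if constant_set == "lueker2000":
        pK1 = 3633.86 / T - 61.2172 + 9.67770 * math.log(T) \
            - 0.011555 * S + 0.0001152 * S * S
        pK2 = 471.78 / T + 25.9290 - 3.16967 * math.log(T) \
            - 0.01781 * S + 0.0001122 * S * S
    elif constant_set == "mehrbach_dm87":
        pK1 = 3670.7 / T - 62.008 + 9.7944 * math.log(T) \
            - 0.0118 * S + 0.000116 * S * S
        pK2 = 1394.7 / T + 4.777 - 0.0184 * S + 0.000118 * S * S
    else:
        raise CarbonateError(f"unknown constant set {constant_set!r}")
    return 10.0 ** -pK1, 10.0 ** -pK2


def total_co2(temperature_C: float, salinity_psu: float, pH: float,
              options: CarbonateOptions | None = None) -> CarbonateState:
    """Total CO2 (mM dm^-3) from T, S and total-scale pH.

    Raises if pH is outside the routine's validity window [6, 9] or the
    sample is fresh (S = 0: alkalinity cannot be estimated from salinity).
    """
    options = options or CarbonateOptions()
    if not math.isfinite(temperature_C + salinity_psu + pH):
        raise CarbonateError("non-finite carbonate input")
    if not 6.0 <= pH <= 9.0:
        raise CarbonateError(f"pH {pH} out of carbonate-routine range [6, 9]")
    if salinity_psu <= 0.0:
        raise CarbonateError("alkalinity undefined from salinity (S <= 0)")
    K1, K2 = apparent_constants(temperature_C, salinity_psu, options.constant_set)
    ca = options.specific_alkalinity_factor * salinity_psu  # meq L^-1
    h = 10.0 ** -pH
    bicarbonate = ca / (1.0 + 2.0 * K2 / h)  # mmol L^-1
    tco2 = bicarbonate * (h / K1 + 1.0 + K2 / h)
    return CarbonateState(
        temperature_C=temperature_C,
        salinity_psu=salinity_psu,
        pH=pH,
        total_co2_mM=tco2,
        carbonate_alkalinity_meq_l=ca,
        K1_app=K1,
        K2_app=K2,
        constant_set=options.constant_set,
        specific_alkalinity_factor=options.specific_alkalinity_factor,
    )
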