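"""Spectrophotometric chlorophyll-a from extract absorbances.

Chlorophyll a is extracted (96% ethanol here, 90% acetone classically),
the extract absorbance read at 665 nm against a 750 nm turbidity blank,
and the concentration in the filtered seawater obtained from the
monochromatic equation

    Ca [mg m^-3] = 1e6 * (A665 - A750) * v_extract[mL]
                   / (a* [L g^-1 cm^-1] * l[cm] * V_filtered[L] * 1e3)

with a* the solvent-specific specific-absorption coefficient of
chlorophyll a.  The coefficient is explicit configuration (default
83.4 L g^-1 cm^-1 for 96% ethanol; 87.67 for 90% acetone) because
handbooks differ at the percent level between solvents and authors.
No phaeopigment (acidification) correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

from .profiles import PigmentSample

__all__ = ["chlorophyll_a", "ChlResult", "SPECIFIC_ABSORPTION"]

#: L g^-1 cm^-1, by solvent.
SPECIFIC_ABSORPTION = {"ethanol96": 83.4, "acetone90": 87.67}


class PigmentError(ValueError):
    pass


@dataclass(frozen=True)
class ChlResult:
    chl_mgm3: float
    clamped: bool          # True when A750 exceeded A665 (flagged, set to 0)
    coefficient: float


def chlorophyll_a(sample: PigmentSample, coefficient: float | None = None) -> ChlResult:
    """Chlorophyll-a concentration (mg m^-3) for one pigment sample.

    A blank exceeding the 665 nm reading (turbid extract) clamps the result
    to zero with a flag rather than reporting negative pigment.
    """
    if sample.filtered_vol_l <= 0:
        raise PigmentError("zero filtered volume")
    if coefficient is None:
        try:
            coefficient = SPECIFIC_ABSORPTION[sample.solvent]
        except KeyError:
            raise PigmentError(f"no default coefficient for solvent {sample.solvent!r}")
    if coefficient <= 0:
        raise PigmentError("specific-absorption coefficient must be positive")
    diff = sample.A665 - sample.A750
    clamped = diff < 0.0
    if clamped:
        diff = 0.0
    ca = 1.0e6 * diff * sample.extract_vol_ml / (
        coefficient * sample.cuvette_cm * sample.filtered_vol_l * 1.0e3
    )
    return ChlResult(chl_mgm3=ca, clamped=clamped, coefficient=coefficient)


def absorbance_for_chl(chl_mgm3: float, sample_geometry: PigmentSample,
                       coefficient: float | None = None) -> float:
    """Inverse of :func:`chlorophyll_a`: the A665-A750 difference that a given
    concentration would produce with the sample's volumes and cuvette.

    Used by the synthetic-cast generator to back-compute raw absorbances.
    """
    if coefficient is None:
        coefficient = SPECIFIC_ABSORPTION[sample_geometry.solvent]
    return chl_mgm3 * coefficient * sample_geometry.cuvette_cm \
        * sample_geometry.filtered_vol_l * 1.0e3 / (1.0e6 * sample_geometry.extract_vol_ml)
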