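"""Synthetic zone-structured fjord casts with hidden ground truth.

Each scenario describes one (fjord, zone) stratum of a glacier-influenced
fjord in summer:

* a low-salinity meltwater surface layer over saltier deep water, joined by
  a logistic halocline in the top ~10 m (temperature analogous);
* a subsurface chlorophyll maximum (Gaussian peak over a background) that
  deepens seaward, from ~7 m near glacier fronts to ~15 m at the fjord
  mouth;
* turbidity-controlled exponential light attenuation (high Kd near the
  glacier suppresses production below a few metres);
* volumetric production from a saturating hyperbolic-tangent
  photosynthesis-irradiance response,
  Pe(z) = Chl(z) * PBmax * tanh(alpha * PAR(z) / PBmax).

Observables are then *back-computed* by inverting the measurement
equations: bottle activities from Pe via the production equation at the
scenario's tracer activity and the carbonate chemistry of the generated
T/S/pH, and extract absorbances from chlorophyll via the monochromatic
pigment equation.  Multiplicative mean-one log-normal noise models
counting/reading error; a per-cast log-normal biomass factor models
cast-to-cast (interannual) variability.  At zero noise the analysis
pipeline recovers the truth exactly (round-trip identity).

Every generated cast carries a truth record (true Pe profile, true Pi,
true peak depths) for test harnesses; truth records are synthetic
constructions, not observations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import integrate as _spi

from .carbonate import CarbonateOptions, total_co2
from .pigments import absorbance_for_chl
from .profiles import BottleSet, Cast, Level, PigmentSample
from .radiocarbon import ProductionConstants, composite_constant, microcurie_to_dpm

__all__ = ["ZoneScenario", "CastTruth", "generate_cast", "generate_campaign",
           "default_campaign", "SAMPLING_DEPTHS"]

#: The 10 sampling depths (m) used for the 0-50 m bottle casts.
SAMPLING_DEPTHS = (0.0, 2.0, 3.0, 5.0, 7.0, 10.0, 15.0, 20.0, 30.0, 50.0)


class ScenarioError(ValueError):
    pass


@dataclass(frozen=True)
class ZoneScenario:
    """Generator configuration for one (fjord, zone) stratum."""

    fjord: str
    zone: str
    n_casts: int = 30
    # hydrography
    surface_salinity_mean: float = 30.0
    surface_salinity_sd: float = 1.0
    deep_salinity: float = 34.5
    surface_temp_mean: float = 3.5
    surface_temp_sd: float = 1.0
    deep_temp_C: float = 1.5
    halocline_depth_m: float = 5.0
    halocline_width_m: float = 1.2
    pH: float = 8.10
    # optics and biology
    kd_per_m: float = 0.3
    chl_max_depth_m: float = 10.0
    chl_max_mgm3: float = 2.0          # total chlorophyll at the peak depth
    chl_background_mgm3: float = 0.5
    chl_peak_width_m: float = 3.0
    pbmax_mgC_per_mgchl_h: float = 3.0  # assimilation number
    alpha_pi: float = 15.0              # initial P-I slope per relative-PAR unit
    surface_par: float = 1.0            # relative units
    # measurement model
    noise_cv: float = 0.10
    biomass_cv: float = 0.30            # between-cast log-normal biomass factor
    tracer_uci: float = 8.0             # NaH14CO3 added per subsample
    dark_dpm: float = 80.0
    exposure_hours: float = 2.0
    n_replicates: int = 2
    depths: tuple[float, ...] = SAMPLING_DEPTHS

    def __post_init__(self) -> None:
        if self.n_casts < 1:
            raise ScenarioError("n_casts must be >= 1")
        if self.kd_per_m <= 0:
            raise ScenarioError("kd must be positive")
        if min(self.surface_salinity_sd, self.surface_temp_sd,
               self.noise_cv, self.biomass_cv) < 0:
            raise ScenarioError("spread parameters must be non-negative")
        if self.chl_max_depth_m < 0 or self.chl_max_depth_m > max(self.depths):
            raise ScenarioError("chl_max_depth must lie within the sampled depth span")
        if self.chl_max_mgm3 < self.chl_background_mgm3:
            raise ScenarioError("chlorophyll peak below background")
        if any(b <= a for a, b in zip(self.depths, self.depths[1:])):
            raise ScenarioError("depths must be strictly increasing")

    # --- closed-form truth fields -------------------------------------
    def salinity(self, z, surface: float | None = None):
        s0 = self.surface_salinity_mean if surface is None else surface
        return self.deep_salinity - (self.deep_salinity - s0) / (
            1.0 + np.exp((np.asarray(z) - self.halocline_depth_m) / self.halocline_width_m)
        )

    def temperature(self, z, surface: float | None = None):
        t0 = self.surface_temp_mean if surface is None else surface
        return self.deep_temp_C - (self.deep_temp_C - t0) / (
            1.0 + np.exp((np.asarray(z) - self.halocline_depth_m) / self.halocline_width_m)
        )

    def chlorophyll(self, z, biomass_scale: float = 1.0):
        amp = self.chl_max_mgm3 - self.chl_background_mgm3
        peak = amp * np.exp(
            -((np.asarray(z) - self.chl_max_depth_m) ** 2) / (2.0 * self.chl_peak_width_m**2)
        )
        return biomass_scale * (self.chl_background_mgm3 + peak)

    def par(self, z):
        return self.surface_par * np.exp(-self.kd_per_m * np.asarray(z))

    def pe(self, z, biomass_scale: float = 1.0):
        """True volumetric production (mgC m^-3 h^-1) at depth z."""
        pb = self.pbmax_mgC_per_mgchl_h
        light = np.tanh(self.alpha_pi * self.par(z) / pb)
        return self.chlorophyll(z, biomass_scale) * pb * light


@dataclass(frozen=True)
class CastTruth:
    """Hidden ground truth for one generated cast (synthetic, non-observational)."""

    cast_id: str
    depths: tuple[float, ...]
    chl_mgm3: tuple[float, ...]
    pe_mgC_m3_h: tuple[float, ...]
    pe0: float
    z_max_pe_m: float
    chl_max_depth_m: float
    pi_mgC_m2_day: float        # 24 h * high-resolution quadrature of Pe over 0-30 m
    pi_grid_mgC_m2_day: float   # 24 h * trapezoid of true Pe on the sampled grid
    biomass_scale: float


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    """Mean-one multiplicative log-normal noise with coefficient of variation cv."""
    if cv == 0.0:
        return np.ones(size) if size is not None else 1.0
    sigma = math.sqrt(math.log1p(cv * cv))
    return np.exp(rng.normal(-0.5 * sigma * sigma, sigma, size=size))


def generate_cast(scenario: ZoneScenario, rng: np.random.Generator,
                  cast_id: str = "synthetic-000",
                  carbonate_options: CarbonateOptions | None = None,
                  ) -> tuple[Cast, CastTruth]:
    """One synthetic cast plus its hidden truth record.

    Bottle activities invert the production equation at the scenario's
    tracer activity and the carbonate state of the generated T/S/pH, so a
    noise-free cast round-trips exactly through the analysis pipeline.
    """
    z = np.asarray(scenario.depths)
    s0 = float(np.clip(
        rng.normal(scenario.surface_salinity_mean, scenario.surface_salinity_sd),
        1.0, min(35.9, scenario.deep_salinity),
    ))
    t0 = float(np.clip(
        rng.normal(scenario.surface_temp_mean, scenario.surface_temp_sd), -1.9, 14.9))
    biomass = float(_lognormal_factor(rng, scenario.biomass_cv))

    sal = scenario.salinity(z, s0)
    temp = scenario.temperature(z, t0)
    chl = scenario.chlorophyll(z, biomass)
    pe = scenario.pe(z, biomass)

    dpm_added = microcurie_to_dpm(scenario.tracer_uci)
    k2 = 1.0 / scenario.exposure_hours
    const = composite_constant(ProductionConstants())
    levels: list[Level] = []
    for i, depth in enumerate(z):
        carb = total_co2(float(temp[i]), float(sal[i]), scenario.pH, carbonate_options)
        # invert Pe = excess * TCO2 * const * k1 * k2 * k3 / dpm_added
        excess = pe[i] * dpm_added / (carb.total_co2_mM * const * 1.0 * k2 * 1.0e3)
        dark = scenario.dark_dpm * _lognormal_factor(
            rng, scenario.noise_cv, scenario.n_replicates)
        light = (scenario.dark_dpm + excess) * _lognormal_factor(
            rng, scenario.noise_cv, scenario.n_replicates)
        geometry = PigmentSample(A665=0.0, A750=0.0)  # default volumes/cuvette
        diff = absorbance_for_chl(float(chl[i]), geometry)
        a750 = 0.005
        a665 = a750 + diff * float(_lognormal_factor(rng, scenario.noise_cv))
        levels.append(Level(
            depth_m=float(depth),
            temperature_C=float(temp[i]),
            salinity_psu=float(sal[i]),
            pH=scenario.pH,
            bottles=BottleSet(
                dpm_light=tuple(float(x) for x in light),
                dpm_dark=tuple(float(x) for x in dark),
                dpm_added=dpm_added,
                exposure_hours=scenario.exposure_hours,
            ),
            chl_inputs=PigmentSample(A665=a665, A750=a750,
                                     extract_vol_ml=geometry.extract_vol_ml,
                                     filtered_vol_l=geometry.filtered_vol_l,
                                     cuvette_cm=geometry.cuvette_cm,
                                     solvent=geometry.solvent),
        ))

    cast = Cast(cast_id=cast_id, fjord=scenario.fjord, zone=scenario.zone,
                date_utc="2008-07-15", levels=levels)

    pe_grid = [(float(d), float(p)) for d, p in zip(z, pe)]
    pi_quad = 24.0 * _spi.quad(lambda x: float(scenario.pe(x, biomass)), 0.0, 30.0,
                               limit=200)[0]
    inside = z <= 30.0
    pi_grid = 24.0 * float(np.trapezoid(pe[inside], z[inside]))
    truth = CastTruth(
        cast_id=cast_id,
        depths=tuple(float(d) for d in z),
        chl_mgm3=tuple(float(c) for c in chl),
        pe_mgC_m3_h=tuple(float(p) for p in pe),
        pe0=float(pe[0]),
        z_max_pe_m=float(z[int(np.argmax(pe))]),
        chl_max_depth_m=float(z[int(np.argmax(chl))]),
        pi_mgC_m2_day=pi_quad,
        pi_grid_mgC_m2_day=pi_grid,
        biomass_scale=biomass,
    )
    return cast, truth


def generate_campaign(scenarios: list[ZoneScenario], seed: int
                      ) -> tuple[list[Cast], list[CastTruth]]:
    """All casts of a multi-zone campaign, with independent per-scenario
    substreams derived from one master seed."""
    if not scenarios:
        raise ScenarioError("no scenarios given")
    keys = [(s.fjord, s.zone) for s in scenarios]
    if len(set(keys)) != len(keys):
        raise ScenarioError("duplicate (fjord, zone) scenarios")
    casts: list[Cast] = []
    truths: list[CastTruth] = []
    streams = np.random.SeedSequence(seed).spawn(len(scenarios))
    for scenario, stream in zip(scenarios, streams):
        rng = np.random.default_rng(stream)
        for i in range(scenario.n_casts):
            cid = f"{scenario.fjord[:1]}-{scenario.zone[:1]}-{i:03d}"
            cast, truth = generate_cast(scenario, rng, cast_id=cid)
            casts.append(cast)
            truths.append(truth)
    return casts, truths


def default_campaign(n_casts: int = 30, noise_cv: float = 0.10) -> list[ZoneScenario]:
    """The six-stratum (2 fjords x 3 zones) summer campaign.

    Surface T/S/chlorophyll targets are the observed zone means of the two
    fjords; assimilation numbers are derived so the expected surface
    production matches the observed zone means (PBmax = Pe(0)/Chl(0), in
    the 1.5-6 mgC (mg chl)^-1 h^-1 range typical of Arctic summer
    assemblages); Kd decreases seaward from turbid glacier fronts
    (0.8 m^-1) to clear outer waters (~0.1 m^-1), and the chlorophyll
    maximum deepens from 7 m to 15 m.  Integrated production is emergent,
    not calibrated.
    """

    def scenario(fjord, zone, pe0, s0, s0_sd, t0, t0_sd, ca0, amp, zc, kd,
                 deep_s, deep_t, halocline):
        width = 3.0
        bg = ca0 - amp * math.exp(-zc**2 / (2.0 * width**2))
        chl0 = bg + amp * math.exp(-zc**2 / (2.0 * width**2))  # == ca0
        pbmax = pe0 / chl0
        return ZoneScenario(
            fjord=fjord, zone=zone, n_casts=n_casts, noise_cv=noise_cv,
            surface_salinity_mean=s0, surface_salinity_sd=s0_sd,
            surface_temp_mean=t0, surface_temp_sd=t0_sd,
            deep_salinity=deep_s, deep_temp_C=deep_t,
            halocline_depth_m=halocline,
            kd_per_m=kd, chl_max_depth_m=zc,
            chl_max_mgm3=bg + amp, chl_background_mgm3=bg,
            chl_peak_width_m=width,
            pbmax_mgC_per_mgchl_h=pbmax,
            alpha_pi=5.0 * pbmax,  # saturating light at the surface
        )

    return [
        #        fjord        zone      Pe0   S0     sd    T0    sd    Ca0   amp  zc  kd   deepS deepT hc
        scenario("Kongsfjord", "Glacier", 2.18, 29.65, 1.36, 3.23, 2.96, 0.58, 1.0, 7.0, 0.80, 33.9, 1.5, 3.0),
        scenario("Kongsfjord", "Inner",   2.20, 30.40, 1.25, 3.76, 1.23, 0.68, 1.5, 10.0, 0.30, 34.5, 1.8, 5.0),
        scenario("Kongsfjord", "Outer",   1.53, 33.48, 1.93, 5.69, 0.97, 0.67, 1.5, 15.0, 0.12, 35.0, 4.0, 8.0),
        scenario("Hornsund",   "Glacier", 6.00, 30.28, 0.52, 3.99, 0.54, 1.05, 2.0, 7.0, 0.80, 34.82, 0.8, 3.0),
        scenario("Hornsund",   "Inner",   3.49, 31.61, 0.87, 3.61, 1.13, 1.86, 4.0, 10.0, 0.30, 34.5, 1.5, 5.0),
        scenario("Hornsund",   "Outer",   1.77, 33.78, 0.06, 4.46, 0.64, 1.15, 2.0, 15.0, 0.15, 34.6, 1.6, 8.0),
    ]
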