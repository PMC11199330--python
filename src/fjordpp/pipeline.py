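"""End-to-end analysis: raw cast tables -> production, classification,
integration and zone summaries.

Stage order mirrors the shipboard workflow: chlorophyll from extract
absorbances, total CO2 from T/S/pH, volumetric production Pe(z) from the
bottle counts, water-mass classification, 0-30 m integration to Pi, then
zone-wise summaries, between-fjord fold-ratios and the gated
ANOVA / Kruskal-Wallis comparison.  Every output row carries provenance
(configuration hash, package version, option values are logged).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .carbonate import CarbonateOptions, total_co2
from .integration import IntegrationOptions, integrate_pi
from .pigments import chlorophyll_a
from .profiles import Cast, ProductionProfile, depth_of_maximum, surface_value
from .radiocarbon import ProductionConstants, compute_pe
from .watermass import classify, default_ruleset, load_ruleset
from .zonestats import compare_zones, fold_ratio, summarize_zone

__all__ = ["RunConfig", "run_pipeline", "PipelineResult"]

log = logging.getLogger("fjordpp")


class PipelineError(RuntimeError):
    pass


@dataclass(frozen=True)
class RunConfig:
    """Options for one pipeline run (all stages)."""

    carbonate: CarbonateOptions = CarbonateOptions()
    integration: IntegrationOptions = IntegrationOptions()
    chl_coefficient: float | None = None     # None -> solvent default
    k1_subsample: float = 1.0
    clamp_negative: bool = True
    alpha: float = 0.05
    ruleset_path: str | None = None          # None -> packaged water-mass boxes
    seed: int = 0

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class PipelineResult:
    levels: pd.DataFrame        # one row per (cast, depth)
    casts: pd.DataFrame         # one row per cast: Pe0, z_max_Pe, Pi
    zone_summary: pd.DataFrame  # per (fjord, zone, variable)
    fold_ratios: pd.DataFrame   # Hornsund / Kongsfjord per zone
    watermass_summary: pd.DataFrame  # mean Pe +/- SE per (fjord, water mass)
    comparisons: pd.DataFrame   # gated zone test per (fjord, variable)
    report: dict = field(default_factory=dict)


def _profile_from_levels(rows: list[dict]) -> list[tuple[float, float]]:
    return [(r["depth_m"], r["pe_mgC_m3_h"]) for r in rows
            if r["pe_mgC_m3_h"] is not None and np.isfinite(r["pe_mgC_m3_h"])]


def run_pipeline(casts: list[Cast], config: RunConfig = RunConfig()) -> PipelineResult:
    """Run every stage on a list of casts and aggregate by (fjord, zone)."""
    if not casts:
        raise PipelineError("no casts to process")
    chash = config.config_hash()
    ruleset = load_ruleset(config.ruleset_path) if config.ruleset_path else default_ruleset()
    constants = ProductionConstants()

    level_rows: list[dict] = []
    cast_rows: list[dict] = []
    counts = {"levels": 0, "levels_without_bottles": 0, "clamped_negative_pe": 0,
              "surface_substituted": 0, "casts_without_pi": 0}

    for cast in casts:
        stage = "per-level"
        try:
            rows = []
            for lv in cast.levels:
                counts["levels"] += 1
                chl = None
                if lv.chl_inputs is not None:
                    chl = chlorophyll_a(lv.chl_inputs, config.chl_coefficient).chl_mgm3
                carb = None
                if lv.pH is not None and lv.salinity_psu > 0:
                    carb = total_co2(lv.temperature_C, lv.salinity_psu, lv.pH,
                                     config.carbonate)
                pe = None
                clamped = False
                if lv.bottles is not None and carb is not None:
                    bset = lv.bottles
                    if config.k1_subsample != bset.k1_subsample:
                        bset = dataclasses.replace(bset, k1_subsample=config.k1_subsample)
                    res = compute_pe(bset, carb, constants,
                                     clamp_negative=config.clamp_negative)
                    pe, clamped = res.pe_mgC_m3_h, res.clamped
                    counts["clamped_negative_pe"] += int(clamped)
                else:
                    counts["levels_without_bottles"] += int(lv.bottles is None)
                rows.append({
                    "cast_id": cast.cast_id, "fjord": cast.fjord, "zone": cast.zone,
                    "depth_m": lv.depth_m, "temp_C": lv.temperature_C,
                    "sal_psu": lv.salinity_psu, "pH": lv.pH,
                    "chl_mgm3": chl,
                    "total_co2_mM": carb.total_co2_mM if carb else None,
                    "pe_mgC_m3_h": pe, "pe_clamped": clamped,
                    "water_mass": classify(lv.temperature_C, lv.salinity_psu, ruleset),
                })

            stage = "profile-summary"
            prof = _profile_from_levels(rows)
            pe0 = z_max = pi = None
            substituted = False
            if prof:
                pe0, substituted = surface_value(prof)
                counts["surface_substituted"] += int(substituted)
                z_max = depth_of_maximum(prof)
                stage = "integration"
                if len(prof) >= 2:
                    pi = integrate_pi(prof, config.integration)
                else:
                    counts["casts_without_pi"] += 1
            chl_prof = [(r["depth_m"], r["chl_mgm3"]) for r in rows
                        if r["chl_mgm3"] is not None]
            cast_rows.append({
                "cast_id": cast.cast_id, "fjord": cast.fjord, "zone": cast.zone,
                "pe0_mgC_m3_h": pe0, "pe0_substituted": substituted,
                "z_max_pe_m": z_max, "pi_mgC_m2_day": pi,
                "chl0_mgm3": chl_prof[0][1] if chl_prof and chl_prof[0][0] == 0 else None,
                "z_max_chl_m": depth_of_maximum(chl_prof) if chl_prof else None,
                "temp0_C": cast.levels[0].temperature_C if cast.levels[0].depth_m == 0 else None,
                "sal0_psu": cast.levels[0].salinity_psu if cast.levels[0].depth_m == 0 else None,
            })
            level_rows.extend(rows)
        except Exception as exc:
            raise PipelineError(
                f"stage {stage!r} failed for cast {cast.cast_id}: {exc}") from exc

    levels = pd.DataFrame(level_rows)
    casts_df = pd.DataFrame(cast_rows)

    # --- zone aggregation -------------------------------------------------
    summary_rows, ratio_rows, comparison_rows = [], [], []
    variables = [("pe0_mgC_m3_h", "Pe0"), ("pi_mgC_m2_day", "Pi"),
                 ("chl0_mgm3", "Ca0"), ("temp0_C", "T0"), ("sal0_psu", "S0")]
    for (fjord, zone), grp in casts_df.groupby(["fjord", "zone"]):
        for col, var in variables:
            vals = grp[col].dropna().to_numpy(dtype=float)
            if vals.size:
                s = summarize_zone(vals, fjord, zone, var)
                summary_rows.append(dataclasses.asdict(s))
    zone_summary = pd.DataFrame(summary_rows)

    for zone in casts_df["zone"].unique():
        for var, rounding in (("Pe0", "one_decimal"), ("Pi", "nearest_half")):
            a = zone_summary.query("fjord == 'Hornsund' and zone == @zone and variable == @var")
            b = zone_summary.query("fjord == 'Kongsfjord' and zone == @zone and variable == @var")
            if a.empty or b.empty or b.iloc[0]["mean"] <= 0:
                continue
            fr = fold_ratio(summarize_zone([a.iloc[0]["mean"]], "Hornsund", zone, var),
                            summarize_zone([b.iloc[0]["mean"]], "Kongsfjord", zone, var),
                            rounding)
            ratio_rows.append({
                "variable": var, "zone": zone,
                "numerator_fjord": fr.numerator_fjord,
                "denominator_fjord": fr.denominator_fjord,
                "hornsund_mean": a.iloc[0]["mean"], "kongsfjord_mean": b.iloc[0]["mean"],
                "ratio": fr.ratio, "rounding": rounding,
            })
    fold_ratios = pd.DataFrame(ratio_rows)

    for fjord, grp in casts_df.groupby("fjord"):
        for col, var in (("pi_mgC_m2_day", "Pi"), ("pe0_mgC_m3_h", "Pe0")):
            groups = [g[col].dropna().to_numpy(dtype=float)
                      for _, g in grp.groupby("zone")]
            groups = [g for g in groups if g.size >= 3]
            if len(groups) < 2:
                continue
            res = compare_zones(groups, alpha=config.alpha)
            comparison_rows.append({
                "fjord": fjord, "variable": var, "test_used": res.test_used,
                "statistic": res.statistic, "p_value": res.p_value,
                "levene_p": res.variance_homogeneity_p, "alpha": res.alpha,
            })
    comparisons = pd.DataFrame(comparison_rows)

    wm_rows = []
    pe_levels = levels.dropna(subset=["pe_mgC_m3_h"])
    for (fjord, wm), grp in pe_levels.groupby(["fjord", "water_mass"]):
        v = grp["pe_mgC_m3_h"].to_numpy(dtype=float)
        wm_rows.append({
            "fjord": fjord, "water_mass": wm, "n": v.size,
            "mean_pe_mgC_m3_h": float(v.mean()),
            "se_pe_mgC_m3_h": float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else 0.0,
        })
    watermass_summary = pd.DataFrame(wm_rows)

    for df in (levels, casts_df, zone_summary, fold_ratios, watermass_summary, comparisons):
        if not df.empty:
            df["config_hash"] = chash
            df["fjordpp_version"] = __version__

    report = {
        "n_casts": len(casts), "config_hash": chash, "version": __version__,
        "options": dataclasses.asdict(config), **counts,
    }
    log.info("pipeline complete: %s", report)
    return PipelineResult(levels=levels, casts=casts_df, zone_summary=zone_summary,
                          fold_ratios=fold_ratios, watermass_summary=watermass_summary,
                          comparisons=comparisons, report=report)
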