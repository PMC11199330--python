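"""Synthetic fjord campaign: round-trip identity, determinism, structure."""

import dataclasses

import numpy as np
import pytest

import fjordpp as fp
from fjordpp.profiles import depth_of_maximum, envelope
from fjordpp.synthetic import ScenarioError, ZoneScenario


class TestGenerateCast:
    def test_zero_noise_round_trip_is_exact(self, noiseless_glacier_scenario, rng):
        """With every stochastic term off, the pipeline inverts the
        measurement equations back to the true Pe and chlorophyll."""
        cast, truth = fp.generate_cast(noiseless_glacier_scenario, rng)
        res = fp.run_pipeline([cast])
        pe = res.levels["pe_mgC_m3_h"].to_numpy(dtype=float)
        chl = res.levels["chl_mgm3"].to_numpy(dtype=float)
        assert np.allclose(pe, truth.pe_mgC_m3_h, rtol=1e-9, atol=1e-12)
        assert np.allclose(chl, truth.chl_mgm3, rtol=1e-9, atol=1e-12)
        assert res.casts["pi_mgC_m2_day"][0] == pytest.approx(
            truth.pi_grid_mgC_m2_day, rel=1e-9)

    def test_glacier_turbidity_suppresses_deep_production(self, campaign_scenarios):
        """Kd = 0.8 m^-1 near the glacier front: true production at 10 m is
        below 1% of the surface value."""
        for sc in campaign_scenarios:
            if sc.zone == "Glacier":
                assert sc.kd_per_m == 0.8
                assert sc.pe(10.0) < 0.01 * sc.pe(0.0)

    def test_fixed_seed_is_bit_identical(self, noiseless_glacier_scenario):
        sc = dataclasses.replace(noiseless_glacier_scenario, noise_cv=0.1)
        c1, t1 = fp.generate_cast(sc, np.random.default_rng(99))
        c2, t2 = fp.generate_cast(sc, np.random.default_rng(99))
        assert t1 == t2
        for l1, l2 in zip(c1.levels, c2.levels):
            assert l1 == l2

    def test_inconsistent_scenario_rejected(self):
        with pytest.raises(ScenarioError):
            ZoneScenario(fjord="Hornsund", zone="Glacier", chl_max_depth_m=80.0)

    def test_peak_below_background_rejected(self):
        with pytest.raises(ScenarioError):
            ZoneScenario(fjord="Hornsund", zone="Glacier",
                         chl_max_mgm3=0.1, chl_background_mgm3=0.5)


class TestGenerateCampaign:
    def test_duplicate_strata_rejected(self, campaign_scenarios):
        with pytest.raises(ScenarioError, match="duplicate"):
            fp.generate_campaign([campaign_scenarios[0], campaign_scenarios[0]], seed=1)

    def test_distinct_seeds_give_distinct_campaigns(self, campaign_scenarios):
        a, _ = fp.generate_campaign(campaign_scenarios[:1], seed=1)
        b, _ = fp.generate_campaign(campaign_scenarios[:1], seed=2)
        assert a[0].levels[0].bottles != b[0].levels[0].bottles

    def test_single_cast_campaign_degrades_gracefully(self):
        scenarios = fp.default_campaign(n_casts=1)
        casts, truths = fp.generate_campaign(scenarios, seed=3)
        res = fp.run_pipeline(casts)
        pe0 = res.zone_summary.query("variable == 'Pe0'")
        assert (pe0["n"] == 1).all()
        assert pe0["single_value"].all()
        assert (pe0["sd"] == 0.0).all()

    def test_production_maximum_deepens_seaward_in_kongsfjord(self, campaign):
        """Recovered Pe envelope argmax shifts Glacier -> Inner -> Outer,
        mirroring the seaward deepening imposed by the light/biomass fields."""
        casts, _ = campaign
        res = fp.run_pipeline(casts)
        grid = np.array(fp.synthetic.SAMPLING_DEPTHS[:7])  # 0-15 m
        argmax_depth = {}
        for zone in ("Glacier", "Inner", "Outer"):
            lv = res.levels.query("fjord == 'Kongsfjord' and zone == @zone")
            profs = [list(zip(g["depth_m"], g["pe_mgC_m3_h"]))
                     for _, g in lv.groupby("cast_id")]
            env = envelope(profs, grid)
            argmax_depth[zone] = grid[int(np.argmax(env.median))]
        assert argmax_depth["Glacier"] < argmax_depth["Inner"] < argmax_depth["Outer"]

    def test_chlorophyll_maximum_recovered_at_generated_depth(self, campaign):
        """50-cast Glacier chlorophyll envelope peaks at the imposed 7 m
        (within one grid step)."""
        scenarios = [dataclasses.replace(fp.default_campaign()[3], n_casts=50)]
        casts, _ = fp.generate_campaign(scenarios, seed=11)
        res = fp.run_pipeline(casts)
        grid = np.array(fp.synthetic.SAMPLING_DEPTHS)
        profs = [list(zip(g["depth_m"], g["chl_mgm3"]))
                 for _, g in res.levels.groupby("cast_id")]
        env = envelope(profs, grid)
        peak = grid[int(np.argmax(env.median))]
        i_true = list(grid).index(7.0)
        assert peak in grid[max(0, i_true - 1):i_true + 2]

    def test_zone_means_match_configured_targets_within_2se(self, campaign):
        """Law of large numbers at n=30: recovered Pe(0) zone means sit
        within 2 SE of the configured calibration targets."""
        casts, _ = campaign
        res = fp.run_pipeline(casts)
        targets = {("Kongsfjord", "Glacier"): 2.18, ("Kongsfjord", "Inner"): 2.20,
                   ("Kongsfjord", "Outer"): 1.53, ("Hornsund", "Glacier"): 6.00,
                   ("Hornsund", "Inner"): 3.49, ("Hornsund", "Outer"): 1.77}
        pe0 = res.zone_summary.query("variable == 'Pe0'")
        for (fjord, zone), target in targets.items():
            row = pe0.query("fjord == @fjord and zone == @zone").iloc[0]
            se = row["sd"] / np.sqrt(row["n"])
            assert abs(row["mean"] - target) < 2.0 * se, (fjord, zone)


class TestParameterRecovery:
    def test_peak_depths_and_pi_recovered_under_study_noise(self, campaign):
        """noise_cv = 0.1, 30 casts/zone: median recovered peak depths within
        one grid step of truth; mean Pi within 10% of the per-cast truth."""
        casts, truths = campaign
        truth_by_id = {t.cast_id: t for t in truths}
        res = fp.run_pipeline(casts)
        grid = list(fp.synthetic.SAMPLING_DEPTHS)
        df = res.casts.set_index("cast_id")
        for sc in fp.default_campaign():
            ids = [t.cast_id for t in truths
                   if t.cast_id.startswith(f"{sc.fjord[:1]}-{sc.zone[:1]}")]
            sub = df.loc[ids]
            t0 = truth_by_id[ids[0]]
            for col, true_depth in (("z_max_pe_m", t0.z_max_pe_m),
                                    ("z_max_chl_m", t0.chl_max_depth_m)):
                rec = float(np.median(sub[col]))
                i_true = grid.index(true_depth)
                neighbours = grid[max(0, i_true - 1):i_true + 2]
                assert min(abs(rec - d) for d in neighbours) < 1e-9, (sc.zone, col, rec)
            pi_ratio = float(np.mean(
                [df.loc[i, "pi_mgC_m2_day"] / truth_by_id[i].pi_mgC_m2_day for i in ids]))
            assert abs(pi_ratio - 1.0) < 0.10, (sc.fjord, sc.zone, pi_ratio)
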