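# fjordpp

In-situ ¹⁴C primary-production analysis for glacier-influenced Arctic
fjords: from light/dark-bottle scintillation counts to volumetric
production profiles Pe(z), depth-integrated daily production Pi, and
zone-wise comparison of fjord strata (Glacier / Inner / Outer), with the
supporting carbonate-system, chlorophyll-*a*, and T–S water-mass stages.
It is written for biological oceanographers working with bottle-incubation
campaigns in stratified, meltwater-influenced coastal systems
(e.g. the west-Spitsbergen fjords Hornsund and Kongsfjord).

## The computation

**Volumetric production** at the incubation depth *z*:

```
Pe(z) = <dpma(z)> · totalCO₂ · 13.356 · k₁ · k₂ · k₃ / dpmb    [mgC m⁻³ h⁻¹]
```

where `<dpma(z)>` is the mean light-minus-dark bottle activity (dpm),
`dpmb` the activity of the inoculated NaH¹⁴CO₃ tracer (8 μCi ≡ 1.776×10⁷
dpm), and 13.356 = 12 (atomic weight of C) × 1.05 (¹⁴C uptake
discrimination) × 1.06 (respiratory loss). `k₁` corrects subsampling,
`k₂` converts per-exposure to per-hour rates (2 h → 0.5), `k₃` = 10³
rescales dm⁻³ → m⁻³.

**Total CO₂** comes from in-situ T, S and pH by the classical
specific-alkalinity route: CA = 0.068·S meq L⁻¹, bicarbonate from CA and
pH, DIC from the apparent carbonic-acid dissociation constants K₁′, K₂′
(Lueker 2000 or Mehrbach/D&M87 fits — a recorded configuration choice).

**Chlorophyll *a*** from extract absorbances (96 % ethanol, monochromatic
equation): Ca = 10⁶·(A₆₆₅−A₇₅₀)·v / (a*·l·V·10³) mg m⁻³.

**Integrated production** `Pi = day_factor · ∫₀³⁰ Pe(z) dz`
(trapezoid on the sampled depths; `day_factor` defaults to 24 h day⁻¹
under the polar day and is explicit configuration).

**Water masses** are classified per level on the T–S plane
(SW/AW/TAW/IW/ArW/LW boxes; SW ≡ S < 34.00 ∧ T > 1 °C), and zones are
compared by a Shapiro–Wilk + Levene gated one-way ANOVA with
Kruskal–Wallis as the non-parametric fallback.

A synthetic-campaign generator produces zone-structured casts (logistic
halocline, Gaussian subsurface chlorophyll maximum deepening seaward,
turbidity-controlled light attenuation, tanh photosynthesis–irradiance
response) by *inverting* the measurement equations, so every pipeline
stage can be tested against known ground truth.

## Worked example

```sh
fjordpp simulate --seed 42 --out sim/          # 6 strata × 30 casts
fjordpp run-all sim/casts.csv --out results/
```

`results/fold_ratios.csv` then holds the Hornsund : Kongsfjord zone-mean
ratios, e.g. (seed 42):

```
variable    zone  hornsund_mean  kongsfjord_mean  ratio
     Pe0 Glacier       6.232347         2.172390    2.9
     Pe0   Inner       3.416350         2.290020    1.5
     Pe0   Outer       2.064918         1.426682    1.4
      Pi Glacier     636.343819       215.299426    3.0
```

Surface production near the Hornsund glacier front averages
6.23 mgC m⁻³ h⁻¹ against 2.17 in Kongsfjord — a 2.9-fold contrast
(the generator is calibrated to observed zone means of 6.0 and 2.18,
whose exact ratio is 2.8; the sampled campaign scatters around it).
`zone_summary.csv` carries the min–max/mean/SD tables per stratum,
`zone_comparisons.csv` the gated test decisions (here Kruskal–Wallis,
p < 10⁻⁶ for between-zone differences in both fjords), and
`watermass_summary.csv` the mean Pe ± SE per water mass — e.g. (same run)
production concentrates in meltwater-influenced surface water
(Hornsund SW: 3.65 ± 0.10 mgC m⁻³ h⁻¹, n = 358) and is negligible in
Local Water at depth (0.007 ± 0.001).

The same stages are available piecemeal: `calc-pp`, `classify`,
`integrate --day-factor 12`, `summarize --by water_mass`,
`compare-zones --variable pi`, each accepting `--config FILE` (YAML) for
the carbonate constant set, chlorophyll coefficient, integration options
and statistical alpha. All outputs carry the configuration hash and
package version; cast tables are plain CSV (schema in
`fjordpp/io.py`), and the pipeline refuses to re-ingest its own outputs.

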