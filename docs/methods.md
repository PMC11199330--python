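# Methods

This note records the scientific model behind each pipeline stage, the
parameters that matter, the numerical choices, and what the synthetic
campaign does and does not demonstrate.

## Production equation

The ¹⁴C bottle method measures carbon fixation from the uptake of labelled
bicarbonate during an in-situ incubation:

    Pe(z) = <dpma(z)> · TCO₂ · 13.356 · k₁ · k₂ · k₃ / dpmb   [mgC m⁻³ h⁻¹]

* `<dpma(z)>` — mean light-minus-dark activity. With equal replicate
  counts the mean of pairwise differences is used; with unequal counts the
  difference of replicate means. The two have identical expectations; the
  convention is fixed for determinism.
* `dpmb` — tracer activity. Accepted in dpm or μCi (1 μCi = 2.22×10⁶ dpm,
  the definition of the curie); the standard 8 μCi inoculation is
  1.776×10⁷ dpm.
* 13.356 = 12 × 1.05 × 1.06 (carbon atomic weight, isotope-discrimination
  correction, respiratory-loss correction), reproduced exactly by
  `composite_constant`.
* `k₁` (subsampling) defaults to 1.0 — campaigns that split subsamples set
  it in configuration. `k₂` defaults to 1/exposure_hours (2 h → 0.5).
  `k₃` = 10³ converts mgC dm⁻³ to mgC m⁻³.
* Negative raw rates (dark > light, counting noise) are clamped to zero
  and flagged; the raw value is retained.

## Carbonate system

Total CO₂ is obtained titration-free from T, S, pH: carbonate alkalinity
CA = f_SA·S with the classical surface-ocean specific-alkalinity factor
f_SA = 0.068 meq L⁻¹ per salinity unit; then with h = 10^(−pH),

    HCO₃⁻ = CA / (1 + 2K₂′/h),   TCO₂ = HCO₃⁻ · (h/K₁′ + 1 + K₂′/h).

K₁′, K₂′ are apparent dissociation constants evaluated at (T, S) from a
named published fit — `lueker2000` (default; the set recommended for open
oceanic conditions) or `mehrbach_dm87`. Both the fit and f_SA are recorded
in every output because different handbooks tabulate slightly different
values; outputs therefore claim a documented configuration, not
bit-compatibility with any particular historical dataset. Borate,
phosphate and water alkalinity are deliberately excluded (this is
carbonate alkalinity, not total alkalinity), as is full speciation
(pCO₂, saturation states). Guards: pH outside [6, 9] and S ≤ 0 (alkalinity
cannot be estimated from salinity in fresh water) are errors. The test
suite checks the routine against an independent root-finding inversion of
the DIC→alkalinity mass-action identity using the *other* constant set;
agreement is within 5 % over T ∈ [−1, 10] °C, S ∈ [28, 35], pH ∈ [7.8, 8.3].

## Chlorophyll a

The monochromatic equation with a solvent-specific specific-absorption
coefficient:

    Ca [mg m⁻³] = 10⁶ (A₆₆₅ − A₇₅₀) v / (a* · l · V · 10³)

with v the extract volume (mL), V the filtered volume (L), l the cuvette
path (cm). a* defaults to 83.4 L g⁻¹ cm⁻¹ for 96 % ethanol and
87.67 for 90 % acetone, and is explicit configuration: ethanol-extract
campaigns in the literature vary in the exact coefficient applied, so the
equation family and coefficient are surfaced rather than hidden. A blank
exceeding the 665 nm reading clamps to zero with a flag. No phaeopigment
(acidification) correction is implemented.

## Water masses

Classification is a priority-ordered scan of rectangular T–S boxes. The
surface-water box is definitional — SW ≡ S < 34.00 ∧ T > 1 °C, strict
inequalities — and holds the highest priority so no other box can shadow
it. The remaining boxes (AW, TAW, IW, ArW, LW) follow the Cottier-type
fjord taxonomy and ship as an editable CSV
(`fjordpp/data/watermass_rules.csv`) with explicit per-bound inclusivity,
because the literature revises these boundaries; they are configuration,
not claims. ArW and LW overlap by construction; priority (ArW first)
resolves the tie deterministically. Anything outside all boxes is
`Unclassified`. The partition property (exactly one label per finite
(T, S)) is enforced by a brute-force oracle over a dense grid in the tests.

## Depth integration

Pi = day_factor × trapezoid of Pe over [0, 30] m on the sampled depths.
Numerical choices:

* surface gap: constant extension of the shallowest sample to 0 m
  ("surface" in summaries always means the 0 m *sample* when present,
  never an interpolation);
* below the deepest sample: `extend_zero` by default (production below
  the euphotic depth is negligible, especially in turbid glacier water);
  `extend_constant` and `truncate` available;
* samples below 30 m are clipped with linear interpolation at the cut;
* `day_factor` defaults to 24 h day⁻¹ — under the polar day of a
  77–79° N summer, hourly rates apply around the clock. The 06:00–18:00
  incubation window (12 h) is the documented alternative; because the
  hourly→daily conversion is the single largest scale factor in Pi it is
  always explicit configuration, echoed in the output.

On the non-uniform 10-depth sampling grid {0, 2, 3, 5, 7, 10, 15, 20, 30,
50} m, trapezoid error depends on whether profile curvature is resolved:
profiles whose curvature length scale is at least the local grid spacing
integrate within 2 % of high-resolution quadrature, while the Inner/Outer
campaign strata carry a ~3 % positive bias from their 3 m-wide chlorophyll
peak under the 5 m gap between 10 and 15 m. That bias is a property of
the sampling design (kept realistic on purpose), not of the integrator,
and sits well inside the 10 % recovery tolerance used for Pi.

## Zone statistics

Per (fjord, zone): min–max, arithmetic mean, sample SD (n−1); n = 1 groups
report SD 0 with a flag. Between-fjord contrasts are fold-ratios of zone
means, rounded one-decimal for surface production and to the nearest 0.5
for integrated production (the conventional printing precisions).
The comparison procedure gates a one-way ANOVA on Shapiro–Wilk normality
in *every* group and Levene homogeneity (all p > α), else falls back to
Kruskal–Wallis; gates and main test share α = 0.05. The conjunction rule
and the shared α are design choices; the composed procedure holds its
type-I error near nominal (checked by 2000-replicate Monte-Carlo in the
tests). No post-hoc tests are performed.

## Synthetic campaign

The generator emulates the summer hydrographic structure of two
glaciated fjords, three zones each:

* S(z), T(z): logistic profiles between a drawn surface value
  (N(mean, sd) per cast, clipped to physical ranges) and a fixed deep
  value, with the halocline at 3 m (Glacier), 5 m (Inner), 8 m (Outer) —
  within the top 10 m throughout;
* Chl(z): background + Gaussian peak (width 3 m) whose depth deepens
  seaward, 7 → 10 → 15 m; peak and background per stratum are set so the
  surface concentration matches the observed zone means;
* PAR(z) = exp(−Kd·z), with Kd = 0.8 m⁻¹ at turbid glacier fronts
  (production at 10 m < 1 % of surface), 0.3 m⁻¹ Inner, 0.12–0.15 m⁻¹
  Outer;
* Pe(z) = Chl·PBmax·tanh(α·PAR/PBmax): a saturating tanh P–I curve
  without photoinhibition — the minimal model producing surface-intensified
  glacier profiles and deep outer maxima. PBmax is derived per stratum as
  (target surface Pe)/(surface Chl), landing in the 1.5–6
  mgC (mg chl)⁻¹ h⁻¹ range typical of Arctic summer assemblages; α is set
  so surface light is saturating (α·PAR(0)/PBmax = 5).

Observables are back-computed by inverting the measurement equations:
bottle activities from Pe through the production equation (dark bottles
at an 80 dpm baseline), absorbances from Chl through the pigment
equation. Noise is multiplicative mean-one log-normal
(`noise_cv`, default 0.10) on every activity and absorbance —
count-like, positive, unbiased — plus a per-cast mean-one log-normal
biomass factor (`biomass_cv`, default 0.30) representing interannual
variability; the truth record stores the *scaled* profile, so recovery
tests measure measurement error only. The deep temperature endpoint and
the biomass factor are generator additions needed to close the profile
model; everything else follows the observed stratification statements.

Seeding: one master seed spawns independent substreams per stratum
(`numpy` SeedSequence), making campaigns bit-reproducible and strata
statistically independent.

What passing tests show — and what they do not: zero-noise round-trips
prove the analysis inverts the measurement model exactly; noisy recovery
(peak depths within one grid step, mean Pi within 10 % at n = 30) proves
robustness to unbiased multiplicative measurement error. Real casts
additionally contain vertical sensor mismatch, bottle-depth errors,
phaeopigment interference, non-lognormal outliers and alkalinity
anomalies near glacier outflows, none of which the generator emulates;
conclusions about real data rest on the method, not on these simulations.

## Calibration targets

Surface-value calibration of the default campaign (zone means):

| Fjord | Zone | Pe(0) | S(0) | T(0) | Ca(0) |
|---|---|---|---|---|---|
| Kongsfjord | Glacier | 2.18 | 29.65 | 3.23 | 0.58 |
| Kongsfjord | Inner | 2.20 | 30.40 | 3.76 | 0.68 |
| Kongsfjord | Outer | 1.53 | 33.48 | 5.69 | 0.67 |
| Hornsund | Glacier | 6.00 | 30.28 | 3.99 | 1.05 |
| Hornsund | Inner | 3.49 | 31.61 | 3.61 | 1.86 |
| Hornsund | Outer | 1.77 | 33.78 | 4.46 | 1.15 |

Deep layers are chosen so the classifier reproduces the observed
water-mass inventories (SW throughout glacier zones with LW at depth in
Hornsund, IW at depth in inner zones, Atlantic Water in the outer
Kongsfjord: deep T = 4 °C, S = 35). Integrated production is emergent
from these choices, not calibrated: the day-length factor a field
campaign used for its printed Pi values is rarely recoverable, so Pi
comparisons are always reported alongside the configured `day_factor`.

## Problem sizes

Default test/analysis sizes: 6 strata × 30 casts × 10 depths (1800
incubation levels) for campaign-level checks; a 0.1 °C × 0.1 psu grid
(~8700 points) for the classifier partition check; 2000 three-group
null replicates for the type-I-error check. The full suite runs in well
under a minute on one core.

## Known limitations

* Carbonate constants mix the total/seawater pH scales at the ~0.01 pH
  level; immaterial at the 5 % DIC tolerance but not suitable for
  high-precision CO₂-system work.
* The SW/LW/ArW boxes beyond SW are literature conventions; users
  comparing against differently drawn T–S diagrams should supply their
  own ruleset CSV.
* No photoinhibition, nutrient limitation or plume dynamics in the
  generator; glacier-zone realism is limited to optics and stratification.
* `Pi` is sensitive to the bottom-boundary policy when casts stop short
  of 30 m; the default (`extend_zero`) is conservative.
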