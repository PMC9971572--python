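# Methods

`canophot` connects three scales of C3 (rice) photosynthesis: instrument-level
leaf measurements, the biochemical leaf model, and a diurnal sunlit/shaded
canopy integration, plus a scenario engine that perturbs the canopy state to
rank trait-improvement targets. This note records the models, the defaults
and why, the numerical choices, and the known limitations.

## Leaf biochemistry (`canophot.fvcb`)

Net assimilation follows the Farquhar–von Caemmerer–Berry model:
`A = min(Wc, Wj, Wp) − Rd`, with

* `Wc = Vcmax (Cc − Γ*) / (Cc + Kc(1 + O/Ko))` — Rubisco-limited,
* `Wj = J (Cc − Γ*) / (4Cc + 8Γ*)` — RuBP-regeneration-limited,
* `Wp = 3·TPU` — triose-phosphate-utilisation-limited (simplest standard
  form, no glycolate-export term),

ties broken in the order rubisco < rubp < tpu. Electron transport responds
to light through a non-rectangular hyperbola with curvature `theta`
(default 0.7, the standard literature value; not measured here).

Temperature responses are simple Arrhenius,
`p(T) = p25 · exp[Ea(Tk − 298.15)/(298.15 R Tk)]`, with an optional peaked
deactivation term for Jmax (off by default). Default kinetic constants are
the tobacco-derived set used across the C3 literature: Kc25 = 404.9 µmol
mol⁻¹, Ko25 = 278.4 mmol mol⁻¹, Γ*25 = 42.75 µmol mol⁻¹, O = 210 mmol
mol⁻¹, with activation energies (J mol⁻¹) 65330 (Vcmax), 43540 (Jmax),
53100 (TPU), 46390 (Rd), 79430 (Kc), 36380 (Ko), 37830 (Γ*), 49600 (gm).
All are config-exposed (`KineticConstants`, serialisable via
`canophot.io.save_config`).

The coupled diffusion solver closes `Ci` (fixed Ci/Ca ratio, a stomatal
conductance value with the 1.6 H₂O→CO₂ factor, or a Ball–Berry coupling)
and `Cc = Ci − A/gm` against the biochemistry. Each hyperbolic limitation
along the CO2 supply line `Cc = X − rA` reduces to a quadratic
`rA² − [X + b + r(a − Rd)]A + a(X − Γ*) − Rd(X + b) = 0` whose smaller
root is the physical branch; the min rule is applied across the per-state
solutions. This closed form matches a bisection oracle to <10⁻⁶ over wide
random parameter draws (tested). The Ball–Berry mode uses damped
fixed-point iteration (tolerance 10⁻¹¹) and is provided uncalibrated — the
default canopy coupling is the fixed ratio Ci/Ca = 0.7, which matches the
measured Ci ≈ 272–293 µmol mol⁻¹ at Ca = 400 for these cultivars.

## Estimation chain (`canophot.estimation`)

The chain mirrors the combined gas-exchange/fluorescence protocol
(saturating PPFD 1500 µmol m⁻² s⁻¹, leaf temperature 35 °C):

1. **Calibration.** Under 2% O₂ (no photorespiration) net assimilation is
   linear in `ΦPSII·PPFD/4`: the OLS slope is the absorptance×PSII-fraction
   product α·β and −intercept is the day respiration Rd. Rd is stored
   positive; a small negative estimate (< 0.2 µmol m⁻² s⁻¹) is clamped to
   zero with a warning, a larger one rejected as a data-quality error.
2. **Variable-J gm.** `gm = A / (Ci − Γ*(J + 8(A+Rd))/(J − 4(A+Rd)))` with
   J from fluorescence. gm is computed per point and summarised as the
   median over the reliable window 100 < Ci < 400 µmol mol⁻¹ (summary
   statistic configurable). Points violating `J > 4(A+Rd)` or with Ci below
   the implied drawdown raise descriptive errors.
3. **A/Ci → A/Cc** via `Cc = Ci − A/gm`, order- and count-preserving.
4. **FvCB fit.** Bounded trust-region least squares of A against
   `min(Wc, Wj, Wp) − Rd` over (Vcmax, Jmax, TPU), with Jmax entering
   through the NRH response at the measurement light so the capacity (not
   the realised J) is estimated. Three fixed starting points, best SSE
   wins; deterministic. Because the min-rule model is only piecewise
   smooth, optimizer tolerances are left at library defaults and candidates
   are accepted on cost rather than on the convergence flag. TPU is only a
   free parameter when the curve reaches Cc ≥ 300 µmol mol⁻¹, and is
   reported absent (never guessed) if no point is TPU-limited at the
   optimum.

**Kinetic convention.** The protocol fixes Γ* = 40.0 µmol mol⁻¹ at the
35 °C measurement leaf, i.e. it applies reference-scale constants at
measurement temperature; the chain follows suit (Kc/Ko un-adjusted,
Km = 710.3 µmol mol⁻¹). Fitted capacities are therefore
reference-normalised "measurement-scale" values. The explicit bridge to
the canopy model's 25 °C inputs is
`fvcb.measured_leaf_to_reference(...)` (inverse Arrhenius at 35 °C); it is
applied once, visibly, when the trial fixture is built.

`sln_ave` computes the canopy-average specific leaf nitrogen as total leaf
N over total leaf area,
`(N_o/100·DM_o + N_other/100·DM_other)/(LA_o + LA_other)` — the
dimensionally consistent form of the two-stratum harvest calculation.

## Diurnal environment (`canophot.diurnal`)

Daily weather (latitude, day of year, global radiation, Tmax/Tmin,
humidity) is disaggregated deterministically: radiation ∝ sin(solar
elevation) normalised to the daily total (conservation tested to <0.1%);
hourly diffuse fraction from the clearness index via the three-segment
Erbs correlation; PAR = 0.5 of global energy at 4.57 µmol J⁻¹; air
temperature a piecewise cosine with minimum at sunrise and maximum at
14:00 solar time; VPD from Tetens saturation pressure against a
day-constant vapour pressure. Solar time throughout (no
equation-of-time correction — scenario comparisons are invariant to it);
latitudes beyond ±66° are rejected rather than treated.

## Two-leaf canopy model (`canophot.canopy`)

Each daylight hour the canopy (LAI_can) is split into a sunlit fraction
`LAI_sun = (1 − e^{−kb·LAI})/kb` and a shaded remainder. The beam
extinction coefficient kb comes from the ellipsoidal leaf-angle
distribution (Campbell), with the distribution parameter mapped from the
measured mean leaf inclination; the diffuse coefficient kd defaults
to 0.78. Absorbed PAR per fraction follows the de Pury–Farquhar
single-layer bookkeeping (leaf scattering σ = 0.15, diffuse canopy
reflectance 0.036): the sunlit fraction takes the unscattered beam plus
depth-weighted shares of diffuse and scattered beam; the shaded fraction
the remainder. The per-fraction expressions are exactly the closed-form
depth integrals of the per-leaf profiles used by the multilayer reference.

Nitrogen declines with relative depth, `SLN(ℓ) = SLN_top·e^{−KN·ℓ/LAI}`
with `SLN_top = SLN_ave·KN/(1 − e^{−KN})`; KN is defined over the whole
canopy depth so `SLN_ave/SLN_top = (1 − e^{−KN})/KN` is dimensionless.
Photosynthetic capacity is linear in nitrogen above a structural floor:
`Vcmax25 = χ_v (SLN − SLN_b)` (and Jmax25 with χ_J), with **SLN_b = 0.3 g
N m⁻²** by default — a literature-standard structural leaf N for rice.
The floor matters: with SLN_b = 0 total canopy capacity is invariant to
LAI at fixed total nitrogen, and diluting nitrogen over more leaf area
would be cost-free, contradicting the consistently negative LAI response
this model class reports. χ slopes are derived from a cultivar's measured
top-leaf capacities as `χ = capacity25 / (SLN_top − SLN_b)`.

Per fraction and hour, capacities, Rd (= 0.015·Vcmax25 per fraction) and
gm (scaled by fraction LAI) are temperature-adjusted to air temperature
(used as leaf temperature), electron transport comes from the NRH at the
fraction's absorbed PAR (0.5 e⁻ per absorbed photon by default, i.e.
α·β/absorptance), and the coupled solver closes the CO2 supply. TPU is not
limiting at canopy scale (A = min(Ac, Aj) only). Hourly rates are summed
at interval midpoints over daylight (night respiration excluded;
sunrise-to-sunset integral), giving `A_can,day` in mol CO2 m⁻² d⁻¹ and

    AM_DAY = A_can,day × 44 × 0.41 × 0.85   [g biomass m⁻² ground d⁻¹]

(molecular weight of CO2; biomass per g CO2 after respiratory losses;
aboveground partitioning). A 1-hour step agrees with 0.5 h to <1%.

### Multilayer reference and the aggregation gap

`canophot.multilayer` resolves 100 layers × {sunlit, shaded} with the
identical leaf model, radiation profiles and nitrogen distribution, so any
disagreement with the two-leaf model is purely big-leaf aggregation error.
The sunlit fraction agrees with its layer-resolved aggregate to <1% (all
sunlit leaves share the dominant beam). The shaded fraction does not: with
the whole-depth KN convention the nitrogen (hence capacity) profile is
nearly uniform (SLN_top/SLN_ave ≈ 1.2 at KN = 0.4 — realistic for rice,
whose measured N gradients are much shallower than light gradients), while
per-leaf irradiance inside the shade spans ~30×. The concave NRH response
then makes the single-evaluation shaded big leaf overestimate the
layer-resolved canopy (Jensen's inequality) by roughly 3–20% of
`A_can,day`, largest on diffuse-dominated days. This is a structural
property of the single-layer sunlit/shade method itself, which is the
method under study; it is kept as-is (no sub-layer quadrature, no deflated
canopy-scale curvature) and quantified by tests and the acceptance script
rather than hidden. Consequence: two-leaf daily totals sit systematically
above the multilayer's, and conclusions that depend on absolute canopy
totals at better than ~10–20% should use the multilayer reference.

## Scenario engine (`canophot.scenarios`)

Nine targets; 20% enhancement by default. Single-field targets (β, gm,
χ_v, χ_J, KN) scale one field. Because TNC = SLN_ave × LAI, the
nitrogen-linked targets carry conservation rules: the SLN_ave (LAI_can)
scenario multiplies its field by f and divides the other by f, keeping TNC
constant to machine precision — the stated intent ("TNC kept constant")
wins over the literal "decrease by 20%" (×0.8, a −4% TNC drift), which
remains available behind `literal_compensation=True` for sensitivity
checks. TNC_SLNave/TNC_LAIcan scale one factor alone. SLN_top and
SLN_ratio_top are always re-derived from (SLN_ave, KN), so KN never
changes unless targeted. Substitution sets a recipient's target to the
donor's value by applying the enhancement with factor donor/recipient —
identity substitution is exactly neutral, and enhancement∘inverse is the
identity to 10⁻¹². Suites share one weather realisation per state; rows
are deterministic and order-independent.

## Synthetic data (`canophot.synthetic`)

The generators emulate the study conditions:

* **A/Ci curves**: the instrument CO2 sequence (400, 300, 250, 200, 100,
  100, 400, 450, 500, 550, 650, 800, 1000 µmol mol⁻¹; 13 points, two
  duplicates), constant stomatal conductance per curve, forward-model
  (A, Ci, Cc) at the truth parameters, Gaussian noise on A. Fluorescence
  is emitted so that the fluorescence-based J equals the *realised*
  electron demand `(A+Rd)(4Cc+8Γ*)/(Cc−Γ*)` — fluorescence tracks realised
  linear electron flow, which makes the variable-J chain exactly
  invertible at zero noise in every limiting state. Any (Fs, Fm′) pair
  consistent with ΦPSII carries the same information; Fm′ sits on a
  plausible scale.
* **Low-O2 light responses**: the five protocol light levels (200, 150,
  75, 50, 30 µmol m⁻² s⁻¹) with ΦPSII on a gently declining light curve
  and A from the non-photorespiratory identity, so calibration is exact at
  zero noise regardless of the ΦPSII profile chosen.
* **Weather days**: deterministic clear/typical/overcast profiles scaling
  the extraterrestrial daily total (65/45/28%), clipped to 8–28 MJ m⁻²
  d⁻¹, with a smooth seasonal temperature climatology for the subtropical
  site (32.44° N; tillering DOY 207, flowering DOY 245). The *typical*
  profile (≈18 MJ m⁻² d⁻¹ in late July) is the simulation default — the
  rice belt's monsoon-season climate normal, not a cloudless day.
  Optional seeded jitter (sd 1 MJ, 0.5 °C).
* **Trial fixture**: four cultivars × two stages. Leaf capacities sit at
  the published cultivar means on the measurement scale (e.g. tillering
  Vcmax 90.0–152.3, Jmax 155.0–214.7, TPU 9.08–12.3 µmol m⁻² s⁻¹, gm
  0.136–0.250 mol m⁻² s⁻¹) and are referred to 25 °C through the inverse
  Arrhenius step; canopy descriptors (LAI 4.8–6.8, SLN_ave 1.38–1.70 g
  m⁻², inclination 52–66°, KN 0.4) are *assumed* plausible values —
  tagged as such per field — chosen once to reproduce the reported
  qualitative ordering (hybrids ~15% higher LAI; inbreds most erect;
  SLN_ave equal across cultivars at tillering, higher in the inbreds at
  flowering; flowering canopies flatter). All generators are pure
  functions of (arguments, seed).

**What passing tests do and do not show.** The synthetic curves are
FvCB-consistent by construction: round-trip tests demonstrate estimator
correctness and noise propagation, not robustness to real-instrument
artifacts (leaks, drift, non-steady leaves, alternative electron sinks —
all outside the generator). The fixture's canopy descriptors are documented
stand-ins, so canopy-scale outputs are magnitude anchors, not predictions
for the named cultivars.

## Problem sizes and determinism

Default problem sizes: 13-point curves; 50 noise replicates for the
estimation study; 24 hourly steps per simulated day; 100 layers in the
multilayer reference; 20 randomized draws for the model comparison. All
randomness flows through explicit integer seeds; fitting uses fixed
multi-starts, so every reported number is reproducible bit-for-bit.

## Known limitations

* Air temperature stands in for leaf temperature (no energy balance).
* The Ball–Berry option is structural, not calibrated for these cultivars.
* The measurement-scale → 25 °C conversion uses generic activation
  energies; under them the converted capacities understate the measured
  light-saturated rates at 35 °C by roughly a factor of two, a direct
  consequence of applying reference-constant kinetics during fitting. The
  two scales are kept explicitly separate so this assumption is visible.
* The shaded-fraction aggregation bias described above.
* Single representative days per stage; no multi-day crop growth, water
  stress, row geometry or 3-D architecture.
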