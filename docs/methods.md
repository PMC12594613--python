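# Methods

## Scope and model

`darkdic` implements the inference chain that turns raw dark-incubation
observables from oceanographic stations into a partitioned, depth-integrated
dark dissolved-inorganic-carbon (DIC) fixation budget. The chain has five
stages:

1. **Tracer rate estimation.** Ammonia and nitrite oxidation rates from
   ¹⁵N source/product-pool bookkeeping; DIC fixation from ¹³C-bicarbonate
   (particulate organic carbon enrichment) or ¹⁴C-bicarbonate
   (scintillation counts); heterotrophic production from ³H-leucine
   incorporation.
2. **Inhibitor-difference partitioning.** Phenylacetylene irreversibly
   inhibits the ammonia monooxygenase enzyme, so the control-minus-inhibited
   difference of DIC fixation is the ammonia-fuelled fraction.
3. **Yield regression.** OLS of ammonia-fuelled DIC fixation on ammonia
   oxidation rate; the slope is the environmental DIC fixation yield
   *y*<sub>AOA</sub> (mol C per mol N).
4. **Depth integration.** Trapezoidal quadrature of volumetric profiles
   (nM d⁻¹ × m → µmol m⁻² d⁻¹), restricted to the sampled range.
5. **Four-term budget.** Depth-integrated total DIC fixation is compared
   against ammonia-fuelled (measured), nitrite-fuelled
   (0.036 × nitrite oxidation), sulfur-fuelled (ammonia-fuelled / 17 ×
   0.35 / *y*<sub>AOA</sub>), and heterotrophic (0.10 × heterotrophic
   production) components.

### Rate equations

For a ¹⁵N tracer incubation, the product-pool atom fraction rises linearly
while tracer transfers, so per replicate

  R = (dAF_excess/dt) · [pool] / f_label,

with AF_excess the measured atom fraction minus that replicate's 0 h value,
[pool] the product pool (NO₂⁻+NO₃⁻ for ammonia oxidation, NO₃⁻ for nitrite
oxidation) and f_label the post-spike heavy-isotope atom fraction of the
substrate pool, f_label = (added·a_lab + ambient·a_nat)/(added + ambient).
The slope is a per-replicate OLS fit over the timepoints; replicate
statistics are taken across biological replicates rather than from a pooled
regression, because replicate incubations are reported as mean ± s.d. of
bottles. The product pool is held at its initial value and tracer dilution
by remineralised ¹⁴NH₄⁺ is ignored — the classic simplification, which the
synthetic generator mirrors so that recovery tests are well posed.

δ-values convert to atom fractions through AF = R/(1+R),
R = R_ref·(δ/1000 + 1), with reference ratios R¹⁵_air = 0.0036765 and
R¹³_VPDB = 0.011180 (standard community constants).

Radiotracer assays subtract the mean killed-control blank from live DPM:

  ¹⁴C: R = (DPM_live − DPM_blank)/DPM_total · [DIC]/t  (nM C d⁻¹)
  ³H: mol leu = (DPM_live − DPM_blank)/(2.22×10¹² DPM Ci⁻¹ · SA),

the latter converted to carbon with 1.5 kg C per mol leucine and
12.011 g mol⁻¹ C. No ¹⁴C isotope-discrimination factor is applied by
default (a multiplier is exposed); blank-mean uncertainty is folded into
the replicate s.d. in quadrature when at least two killed controls exist.

Detection limits are uniformly "the rate producing a signal change of
3 × sd of the time-zero measurements over the full incubation", pushed
through the same rate transformation. For the ¹⁵N assay that gives
DL = 3·sd(AF_T0)/t · [pool]/f_label; with sd = 4×10⁻⁴, 24 h, 500 nM and
f_label = 0.8 this is 0.75 nM d⁻¹, the magnitude reported for shipboard
campaigns.

### Statistics

Paired treatment comparisons use the pooled-variance Student's t-test
(Welch by flag), one-sided for inhibition (H₁: control > treated),
two-sided when stimulation is also of interest. The propagated uncertainty
of the difference is √(sd_c² + sd_t²). Multiple comparisons submitted as
one batch form a Bonferroni family (p_adj = min(1, m·p)); family membership
is whatever the caller batches together, since no natural family definition
exists — this is logged prominently. Shapiro–Wilk normality checks are
advisory and never gate a test. Percent inhibition of a below-detection
control is reported as undefined (NaN) rather than 0 or 100, to avoid
division-by-noise artefacts.

Yield and cross-process regressions are ordinary least squares with an
intercept (through-origin by flag); significance of the model fit uses the
F statistic. The reported yield is the slope, not a mean of y/x ratios.

## Zone and station conventions

Depth is in metres, positive down. The euphotic base is the shallowest
depth below the global fluorescence maximum where fluorescence first
reaches ≤ 10 % of the maximum, linearly interpolated between the bracketing
samples; ties in the maximum resolve to the shallowest sample, and a
profile that never crosses the threshold is an error, not an extrapolation.
The euphotic boundary is inclusive (depth ≤ z_eu), the upper mesopelagic is
z_eu < z < 200 m, and 200 m belongs to the lower mesopelagic ("above
200 m" wording). Oxygen-deficient water is O₂ ≤ 10 µM and anoxic water
O₂ < 1 µM, evaluated pointwise with no smoothing.

## Key parameters

| Parameter | Default | Units | Meaning |
|---|---|---|---|
| `yield_nob` | 0.036 | mol C (mol N)⁻¹ | nitrite-oxidizer culture yield |
| `yield_sox` | 0.35 | mol C (mol S)⁻¹ | sulfide-oxidizer yield (literature range 0.15–0.35) |
| `n_to_s` | 17 | mol mol⁻¹ | N:S of sinking particulate organic matter |
| `hetero_dic_fraction` | 0.10 | – | DIC share of heterotrophic production (range 0.01–0.10) |
| `yield_aoa_culture` | 0.09 | mol C (mol N)⁻¹ | ammonia-oxidizer culture yield |
| `leucine_to_c` | 1.5 | kg C (mol leu)⁻¹ | leucine-to-carbon conversion |
| `dpm_per_ci` | 2.22×10¹² | DPM Ci⁻¹ | activity conversion |

With `yield_sox` at its maximum (0.35) and a measured ammonia-oxidizer
yield of 0.05, the sulfur-fuelled term is exactly 7/17 ≈ 0.41 of the
ammonia-fuelled term, a closed-form bound the tests assert.

## Synthetic generator

`SyntheticTruth` defines a station with known ground truth: a Gaussian
ammonia-oxidation peak (default 30 nM d⁻¹, within the observed
0.4–64 nM d⁻¹ span) at the euphotic base (default 90 m) with an exponential
deep tail; nitrite oxidation coupled 1:1 to ammonia oxidation (local
steady-state NO₂⁻ supply from ammonia oxidizers); heterotrophic production
declining exponentially from 20 nM C d⁻¹ at the surface (e-folding 100 m);
and total dark DIC fixation composed exactly as the budget assumes.
Environmental context (subsurface chlorophyll maximum whose 10 % level sits
at the configured euphotic depth, an optional oxygen-deficient layer,
nutrient and DIC profiles) is generated alongside. The default grid is 12
depths from 20 to 600 m.

Observables invert the estimators: atom fractions grow linearly at the
replicate's rate, net DPM are the exact inverse of the scintillation unit
chains, tracer additions follow the shipboard protocol (70–200 nM ¹⁵N at
98–99 atom %, a 50 µCi ¹⁴C spike at 56 mCi mmol⁻¹, 20 nM ³H-leucine at
44.9 Ci mmol⁻¹, 0/12/24 h timepoints, triplicate bottles). The
phenylacetylene treatment removes exactly *y*<sub>AOA</sub>·R_AO from DIC
fixation and zeroes the ¹⁵NH₄⁺ series; DMSO equals the control in
expectation; killed bottles fix nothing.

Noise is multiplicative lognormal (mean 1) on replicate rates — applied
**independently per metabolic component** of a DIC bottle, since the
populations carrying the different processes fluctuate independently
between bottles — plus small additive measurement noise (atom-fraction
s.d. 4×10⁻⁶, DPM counting s.d. 5, floored at zero). Replicate CV defaults
to 10 %, a free parameter exposed in the configuration since replicate CVs
are not otherwise constrained. Control and +PA arms at one depth share the
same killed-control bottles, mirroring the real incubation design (7–8
bottles per depth with 1–2 shared killed controls); this matters: an
arm-specific blank would shift all replicates of an arm together and
inflate the false-positive rate of the treatment comparison.

`simulate_yield_study` emulates the cross-station ensemble behind the
yield regression: 12 experiments at ammonia-oxidation peaks log-spaced over
2–60 nM d⁻¹, with station productivity co-varying (heterotrophy, deep tail
and background scale with the ammonia peak, as rates track overall
productivity across real stations). This keeps the inhibitor-sensitive
fraction of each experiment at ~41 % — the level at which paired
comparisons register as significant, i.e. these are qualifying experiments.

**What the generator does not emulate:** advection/diffusion and any
mechanistic biogeochemistry, N-loss processes, nitrite supply from nitrate
reduction in oxygen-deficient zones, tracer-pool dilution during
incubations, urea-derived nitrification, inhibitor off-target effects, and
community composition. Passing recovery tests therefore demonstrate
estimator correctness under the estimators' own assumptions, not robustness
to violations of those assumptions in real seawater.

## Numerical choices

- Negative rate estimates are reported as computed and flagged
  below-detection, never clipped at the estimation stage; clipping (to 0)
  is an explicit option of depth integration, where below-detection noise
  would otherwise bias integrals.
- Integration uses the trapezoid rule with no extrapolation beyond the
  sampled range; bounds are explicit in the output. The ammonia-fuelled
  integrand uses control-minus-treated differences at all measured depths
  with negatives clipped (a significant-only mode exists; the
  significance filter demonstrably belongs to the yield regression, not
  the integration, and both modes are logged).
- Budget components keep full precision internally; report values round to
  integer µmol m⁻² d⁻¹ and integer percent. After rounding, the component
  sum may differ from the rounded total by up to 2 µmol m⁻² d⁻¹.
- Zero-variance, equal-mean treatment comparisons return p = 1 by
  convention (logged). A replicate lacking its 0 h sample is excluded and
  n decremented.
- CSV round-trips are bit-exact: floats are written shortest-repr and read
  with round-trip precision.

## Monte Carlo test design and problem sizes

The suite verifies stochastic properties at sizes chosen to finish a full
run in well under a minute per property: yield recovery over 500 seeds of
12 experiments (observed ≥ 95 % of fitted slopes within [0.04, 0.06] for a
true yield of 0.05 at CV 10 %, exact to 10⁻¹⁰ at zero noise); type-I error
control over 1000 simulated null families of 7 one-sided comparisons.
For the latter, exact Bonferroni control implies a family-wise rate of
1−(1−0.05/7)⁷ ≈ 0.0488, so a 1000-draw estimate has binomial s.d. 0.0068
and a sharp p̂ ≤ 0.05 cut-off would fail ~40 % of the time even under
exact control; the test therefore asserts the per-comparison false-positive
fraction directly and verifies the family-wise bound with an exact
one-sided binomial test at the 1 % level — the standard way simulation
studies check error control.

## Known limitations

- The detection-limit rule (3 × sd of T0) is adopted uniformly across
  assays; published shipboard limits derive from a related but not
  necessarily identical formulation, so only magnitudes are asserted.
- The Bonferroni family is operational (per submitted batch), not a claim
  about how any particular study grouped its comparisons.
- Whether killed-control scatter was propagated into published rate
  uncertainties is unknowable from summaries; it is propagated here when
  two or more killed controls exist, else omitted.
- Reported R² values of field regressions depend on the actual cruise data
  and are not reproducible from synthetic stations; only parameter
  recovery and oracle agreement are asserted.
- The 10 %-fluorescence euphotic rule is taken as the operational
  definition; no reconciliation with percent-of-surface-irradiance
  criteria is attempted.
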