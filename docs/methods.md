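# Methods

`acidocest` implements, end to end, the analysis behind ratiometric
CEST-MRI tumor pH imaging in a preclinical treatment study: from saturated
image stacks to pixel-wise extracellular pH (pHe) maps and per-tumor
acidity scores, together with the Bloch–McConnell physics used both to
calibrate the method and to generate digital phantoms with known ground
truth, and the cohort statistics used to declare treatment efficacy.

## Physical model

### Bloch–McConnell propagation (`bmsim`)

Each tissue voxel is a set of exchanging proton pools: bulk water
(fraction 1, chemical shift 0), an optional broad semi-solid
magnetization-transfer (MT) pool, endogenous amides at 3.5 ppm, and — in
the post-contrast phase — the two amide sites of iopamidol at 4.2 and
5.5 ppm. Under continuous-wave (CW) irradiation of amplitude ω₁ = γB₁ at
offset Δω, the coupled magnetizations obey the linear Bloch–McConnell
system dM/dt = A M + b, with solute↔water exchange entering by detailed
balance (k_water→i = fᵢ·k_i→water). The propagator is the exact solution
over the saturation interval,

    M(t_sat) = M_ss + e^{A t_sat}(M₀ − M_ss),   M_ss = −A⁻¹ b,

computed per offset with a matrix exponential — no steady-state
assumption, because 5 s of saturation need not equilibrate slow pools.
The Z-spectrum is Z(Δω) = |M_z,water(t_sat)|/M₀. The magnitude is
deliberate: MRI readouts are magnitude acquisitions, and weak on-resonance
CW irradiation can nutate M_z through zero; |M_z| keeps Z in [0, 1], which
downstream processing assumes. The readout itself (fast single-shot after
saturation) is modelled as an instantaneous sample of M_z. Saturation is
an ideal CW block pulse; shaped or pulsed trains are out of scope.

The propagator is verified against an independently coded explicit
adaptive Runge-Kutta integration of the same equations to 10⁻⁶ (tests).

Default tissue parameters (all config-overridable; package defaults, not
measured values):

| pool | shift (ppm) | T1 (s) | T2 (s) | fraction | k (s⁻¹) |
|---|---|---|---|---|---|
| water | 0 | 2.4 | 0.05 | 1 | — |
| MT (semi-solid) | −1.0 | 1.0 | 1e−5 | 0.05 | 30 |
| endogenous amide | 3.5 | 1.1 | 0.01 | 0.002 | 40 |

The acquisition emulates a 7 T scanner with 3 µT CW saturation for 5 s.
The saturation offset grid is an implementation choice (no standard list
exists): −10…+10 ppm at 0.25 ppm, refined to 0.1 ppm over 3.9–5.8 ppm
(the label region) and ±1 ppm around water (113 offsets).

### Iopamidol ratiometric calibration (`calibration`)

Iopamidol's two amide sites exchange at base-catalysed, pH-dependent
rates, modelled as the log-linear law

    k(pH) = k_ref · 10^{η (pH − pH_ref)},  pH_ref = 7.0,

with defaults k_ref = 300 s⁻¹, η = 0.9 for the 4.2 ppm site (2 protons
per molecule) and k_ref = 2500 s⁻¹, η = 1.0 for the 5.5 ppm site
(1 proton), at 30 mM tissue concentration. These constants are *package
defaults with the correct monotone structure*, not literature-fitted
values; they were chosen by a forward design study so that (a) the
contrast ratio is strictly monotone over pH 6.0–7.4, (b) both
contrast-difference effects exceed the 2% reliability floor across the
phantom pH range at the default concentration, and (c) the recovered
group-mean pH bias at SNR 40 stays well inside the recovery tolerance.
The pH sensitivity arises because the faster 5.5 ppm site loses labelling
efficiency α = ω₁²/(ω₁² + k(k + R₂)) at lower pH than the 4.2 ppm site;
the ratio rises from ≈0.43 at pH 6.0 to ≈3.1 at pH 7.4.

The calibration curve maps ΔST(4.2)/ΔST(5.5) → pH, where ΔST is the
*contrast-difference* saturation transfer: ST with agent minus ST of the
same tissue without agent, exactly mirroring the in-vivo post-minus-pre
subtraction (the endogenous background is included in both phases of the
forward model and cancels in the difference). Two builders exist:
`build_calibration` reads the model ST at the exact label offsets;
`build_pipeline_calibration` pushes full simulated spectra through the
same smoothing-spline measurement operator used on image data, so
spline-amplitude bias cancels between calibration and measurement — the
pipeline default. Strict monotonicity is enforced at build time; a
non-monotone grid is truncated to the largest monotone window containing
pH 6.9, and a fully non-monotone model fails loudly. The curve carries a
fingerprint (hash of protocol + model + background) to guard against
stale-calibration reuse. Inversion is monotone piecewise-linear, exact on
grid nodes; ratios outside the calibrated range map to NaN (the voxel is
excluded and counted against coverage).

**Concentration dependence — a known, quantified limitation.** Ratiometric
imaging cancels agent concentration only to first order when the metric is
ST = 1 − Z. The measured maximum ratio shift under ×0.5/×2 concentration
at the 30 mM default is ≈8.5%/12.6% (few-percent at 10 mM), equivalent to
roughly 0.05–0.1 pH per twofold concentration change. The coupling is
structural: the shift per concentration doubling is approximately
(ΔST₄.₂ − ΔST₅.₅)·D/R₁w (D the total water saturation-rate denominator),
so pushing it below 1% across the full grid forces ΔST ≲ 0.005 — far
below the 2% per-voxel detectability floor. The pipeline is insensitive
to this coupling as long as phantoms and calibration share one
concentration (they do by default); applying the calibration to tissue at
a very different concentration biases pH accordingly. Inverse-metric
(1/Z-based) ratios would linearize this, at the cost of departing from the
ST definition used here.

## Digital phantoms (`phantom`)

The generator emulates the study's acquisition: 128×128 matrix over a
30 mm field of view, 8 slices of 1.5 mm (tests and the validation studies
use reduced matrices — 64×64×2 or 32×32×1 — to keep problem sizes small;
nothing else changes). One animal comprises:

* an ellipsoidal tumor (default semi-axes 4.5×4.0×4.5 mm) in a uniform
  tissue background (S₀ = 1 everywhere);
* a truth pH field: mean (default 6.75, the acidic range typical of
  solid tumors) + a core→rim gradient (default +0.2, rim less acidic
  following perfusion geometry) + voxel-wise Gaussian heterogeneity
  (default SD 0.05), clipped to the calibration range [6.0, 7.4]. The
  heterogeneity draw is de-meaned over the mask so the truth mean equals
  the configured mean exactly — convenient for recovery tests;
* a smooth B0 field: random low-order 2-D polynomial scaled to a
  ±0.05 ppm amplitude (typical post-shim inhomogeneity at 7 T);
* pre/post stacks: per voxel, the Z-spectrum is taken from a cached
  Bloch–McConnell table (pre: background only; post: background + agent
  at the local truth pH, linearly interpolated on a 0.02 pH grid),
  sampled at the nominal offsets shifted by the local B0, and degraded
  with Rician noise (two-channel Gaussian of SD S₀/SNR in quadrature;
  default SNR 40 on S₀). Agent is present only inside the tumor; washout
  kinetics over the acquisition are not modelled;
* ground truth (pH map, mask, B0, mean pH, acidity score) and, at cohort
  level, caliper follow-up: exponential volume growth (control default
  0.22/day, ~3-day doubling), perpendicular diameters A ≥ B with 0.2 mm
  caliper noise, V = A·B²/2, and a survival endpoint at the first
  measurement day with V > 800 mm³ (the source protocol states this
  limit with volume units while calling it a diameter; it is treated as
  a volume — flagged here because the units are ambiguous). Animals never
  reaching it are censored at study end (day 28).

Everything is reproducible from `PhantomSpec.seed`; cohorts spawn
per-animal seeds from one `SeedSequence`.

What the phantoms do *not* emulate: real anatomy, motion, B1
inhomogeneity, perfusion/washout, partial volume at the tumor rim, or
between-scan registration error. Passing recovery tests therefore
demonstrates the *numerical* correctness and noise behavior of the
processing chain under the stated physics, not robustness to those
real-data effects.

## Processing pipeline (`cestproc`, `phmap`, `pipeline`)

Per voxel inside the tumor mask (processing is mask-local by
construction):

1. normalize by S₀ and fit a cubic smoothing spline (scipy
   `make_smoothing_spline`) to both Z-spectra. The penalty λ = 0.01 is a
   fixed default rather than cross-validated, for determinism; it
   suppresses SNR-40 noise while leaving the ≈1 ppm-wide amide features
   intact (λ → 0 interpolates exactly). All voxels of a stack are fitted
   in one banded solve (the spline is linear in the data);
2. estimate the voxel B0 shift from the water dip of the *pre*-contrast
   spectrum and reuse it for the post spectrum (the agent perturbs the
   spectrum near water, so a post-contrast estimate would be biased).
   The dip center is the midpoint of the two half-depth crossings of the
   smoothed dip: at 3 µT the dip floor is direct-saturation-flattened
   and its argmin is noise-driven, while the walls stay steep and
   symmetric. At the imaging power the information bound on the dip
   position at SNR 50 is ≈0.03 ppm; shift errors of this size are
   tolerated because the ST features are ≳0.5 ppm wide (and the recovery
   error budget confirms it). The standalone `water_shift_of` reaches
   ≈0.012 ppm MAE on a 1 µT B0-mapping spectrum;
3. ST = 1 − Z_smoothed at 4.2 + δ and 5.5 + δ ppm (δ the B0 shift),
   clamped to [−0.05, 1]; offsets leaving the sampled support are
   missing values;
4. ΔST = ST_post − ST_pre per offset. A voxel is *reliable* only when
   ΔST > max(noise floor, 0.02) at **both** offsets; 0.02 is the
   conventional CEST detectability floor (a default, not a measured
   value), and the data-driven floor can be estimated as the spatial SD
   of pre-contrast ST over tissue outside the tumor;
5. pH = curve⁻¹(ΔST₄.₂/ΔST₅.₅) on reliable voxels; out-of-range ratios
   and zero denominators are excluded, never fatal. `coverage` is the
   fraction of mask voxels with defined pH; `mean_pHe` averages defined
   voxels only.

The acidity score condenses intratumoral heterogeneity: class 1 for
pH ≥ 6.9, class 2 for 6.7 ≤ pH < 6.9, class 3 for pH < 6.7, and the
score is the mean class over defined voxels (1 = least, 3 = most acidic,
whole-tumor aggregation across slices). The thresholds are a
reconstruction — chosen inside the typical tumor pHe band (≈6.5–6.8)
— and are config-overridable; only the 1–3 range and the direction
(more acidic → higher) are externally constrained.

## Cohort statistics (`cohortstats`, `reports`)

Group summaries are mean ± SD. Comparisons use the classic pooled-variance
unpaired Student t (equal-variance; Welch available behind a flag), with a
summary-statistic form that reproduces printed mean ± SD comparisons
exactly — degenerate zero-variance input yields t = 0, p = 1 for equal
means and an error otherwise. One-way ANOVA comes with Bonferroni-adjusted
pairwise tests (pure α-splitting, p_adj = min(1, m·p); no step-down), a
two-factor group × time ANOVA (statsmodels, type II) serves the
longitudinal volume comparisons, Shapiro–Wilk (3 ≤ n ≤ 5000) checks
normality, and survival uses Kaplan–Meier with the log-rank test
(lifelines); an all-censored group is flagged unstable rather than
rejected. Identities (summary-t ≡ raw-t, F ≡ t² for two groups, KM step
products, asymptotic vs exact-permutation log-rank at n = 12) are pinned
by tests against independent oracles.

## Validation results the package computes about itself

(Computed by `acidocest.validation` / `scripts/acceptance.py`; numbers
below from seed 1.)

* The three published control-vs-treated summaries (tumor weight
  1.16±0.15 vs 0.74±0.09 g; week-1 pHe 6.83±0.02 vs 6.76±0.03; week-2
  pHe 6.89±0.04 vs 6.77±0.04, n = 6/arm) give pooled-t p = 1.5·10⁻⁴,
  7.7·10⁻⁴ and 4.0·10⁻⁴ — all below the stated 0.001.
* 20 SNR-40 phantoms (64×64×2, truth means uniform in 6.6–7.0): mean
  absolute error of recovered mean pHe ≈ 0.014; noiseless uniform
  phantom ≈ 10⁻⁵; coverage ≥ 0.82.
* Endogenous removal: ΔST of identical stacks is exactly 0; a noiseless
  agent phantom has ΔST > 0.04 at both offsets everywhere in the mask.
* Bonferroni family-wise error ≈ 0.047–0.051 on 1000 null replicates.
* Power: with a +0.12 pH effect, n = 6/group, 0.04 voxel heterogeneity
  at SNR 40, the pipeline-level t-test reaches p < 0.001 in 100/100
  seeded replicates.
* Concentration robustness: the ×0.5/×2 ratio shift is 8.5%/12.6% —
  reported honestly as the method's main systematic limitation (see the
  calibration section).

## Numerical and design notes

* Degenerate inputs fail loudly and specifically: empty masks, single-pH
  calibration grids, unordered acidity bins, A < B diameters (with the
  offending TSV line number), missing NIfTI sidecars.
* Matrix exponentials of stiff systems (MT pool, R₂ = 10⁵ s⁻¹) are
  handled by scipy's scaling-and-squaring `expm`; the steady state is
  obtained by a direct solve, never by long integration.
* Phantom Z-tables are cached per (protocol, model, background) so a
  cohort costs one Bloch–McConnell sweep plus per-voxel interpolation.
* Coordinates are voxel-indexed, slice-major, 0-based; NIfTI affines
  carry only the isotropic in-plane spacing and slice thickness.
* Problem sizes in tests and validation studies (reduced matrices,
  100-replicate power runs, 1000-replicate FWE runs) were chosen as the
  package's own balance of Monte-Carlo error against desk-scale runtimes.
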