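# acidocest

Ratiometric CEST-MRI tumor pH mapping and preclinical cohort statistics.

Solid tumors acidify their extracellular space (pHe ≈ 6.5–6.8 vs ~7.4 in
normal tissue), and drugs that block proton export should make tumors
*less* acidic — if they work. Chemical exchange saturation transfer (CEST)
MRI with iopamidol measures pHe pixel by pixel: the agent's two amide
sites (4.2 and 5.5 ppm from water) exchange protons with water at
pH-dependent rates, so the ratio of their saturation-transfer effects

    ST(Δω) = 1 − S_sat(Δω)/S0,
    ratio  = ΔST(4.2 ppm) / ΔST(5.5 ppm),   ΔST = ST_post − ST_pre,

is a monotone function of pH that largely cancels the (unknown) local
agent concentration. This package implements the complete analysis for a
two-arm mouse treatment study — and, because raw preclinical scans of
this kind are rarely shared, a Bloch–McConnell digital-phantom generator
that stands in for the scanner, with known ground truth for every
quantity the pipeline estimates.

Who it is for: researchers analyzing (or simulating) CW-saturation CEST
stacks who need pixel-wise pHe maps, per-tumor acidity scores, and the
standard efficacy statistics (caliper volumes, ANOVA, survival) in one
reproducible toolchain.

What is inside (`src/acidocest/`):

| module | role |
|---|---|
| `bmsim` | N-pool Bloch–McConnell CW-saturation simulator (exact matrix-exponential propagation) |
| `calibration` | iopamidol two-site model; monotone ratio→pH calibration curves |
| `phantom` | digital mouse-tumor cohorts: pH fields, B0, Rician noise, caliper/survival tables |
| `cestproc` | smoothing-spline Z-spectrum processing, B0 correction, ST and ΔST maps |
| `phmap` | pixel-wise pHe maps, coverage, 1–3 acidity scores, montages |
| `cohortstats`, `reports` | pooled t (incl. from printed mean±SD), ANOVA+Bonferroni, Shapiro–Wilk, Kaplan–Meier/log-rank |
| `pipeline`, `validation` | per-animal orchestration and the self-validation studies |
| `cli`, `io`, `config` | `acidocest simulate\|process\|stats`, NIfTI+JSON-sidecar and TSV plumbing |

The analysis itself is laid out as numbered drivers in `analysis/`
(01 calibration → 02 simulate cohort → 03 process → 04 statistics →
05 validation studies), each writing its tables under `results/`.

## Worked example

Simulate a 12-animal two-arm study (treated arm +0.12 pH, slower growth),
process it, and test the arms:

```bash
python analysis/02_simulate_cohort.py
python analysis/03_process_cohort.py
python analysis/04_cohort_stats.py
```

The processing step prints one line per animal, e.g.

```
control_00   truth 6.764 -> recovered 6.764 (coverage 0.92, acidity 2.14)
...
treated_04   truth 6.890 -> recovered 6.886 (coverage 0.89, acidity 1.68)

mean |recovered - truth| = 0.0121 pH units over 12 animals
```

— recovered whole-tumor mean pHe tracks the known truth to ~0.01 pH at
SNR 40, with ~90% of tumor voxels yielding a reliable pH. The statistics
step then reports, among others,

```
Imaging endpoints:
  mean_pHe week 2: control 6.773+-0.010 vs treated 6.864+-0.014  t=-12.54 p=1.93e-07
  acidity_score week 2: control 2.097+-0.044 vs treated 1.745+-0.059  t= 11.67 p=3.79e-07
Log-rank test: chi2=10.135 p=0.001455
```

i.e. the simulated treatment raises tumor pHe, lowers the acidity score,
and prolongs survival to the 800 mm³ size endpoint — the qualitative
pattern such a study is designed to detect. The same driver re-tests the
published group summaries directly from their printed mean ± SD (n = 6),
each giving p < 0.001 by pooled t.

The equivalent CLI round trip:

```bash
acidocest simulate --out runs/demo --seed 1
acidocest process  --indir runs/demo
acidocest stats    --cohort runs/demo/cohort.tsv --out runs/demo/stats
```

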