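# nirmetab

Calibration and accuracy analysis for an implantable near-infrared (NIR)
multi-metabolite sensor, driven by a synthetic clinical-visit simulator.

An implanted ATR spectrometer measures interstitial-fluid absorbance at 24
wavelengths between 1680 and 2400 nm; partial least squares regression
links each spectrum to glucose, β-hydroxybutyrate (ketones), lactate and
ethanol, using blood analyzer draws as reference. This package rebuilds
that analysis chain for researchers in NIR chemometrics and continuous
glucose monitoring (CGM) who want a tested, reproducible pipeline —
the original sensor data are not public, so a forward simulator stands in
for the instrument.

The pieces:

- **Visit simulator** — 8-hour metabolic-challenge visits on a 1-minute
  grid: induced hyper-/hypoglycemia confined to 40–400 mg/dl with a
  100 mg/dl/h descent cap and 4 mg/dl/min 5-minute rate cap, ketone-ester
  drinks (≥3.5 mM BHB), exercise lactate (13 mM plateau), ethanol intake
  (~20 mM), and eight interferent compounds with one-compartment kinetics.
- **Forward model** — Beer–Lambert mixture spectra
  `A(λ) = baseline + L·Σ ε_c(λ)·c_c` with Gaussian channel noise and slow
  baseline drift; reference analyzers with their measuring ranges and CVs,
  sampled every 5 min (2.5 min while glucose < 70 mg/dl).
- **PLS1 / NIPALS** — per-analyte latent-variable regression,
  `ŷ = ȳ + (x − x̄)·b`, component count chosen by inner contiguous-blocks
  cross-validation (smallest k within 2% of the minimum RMSECV).
- **Contiguous-blocks CV** — 8 consecutive blocks of 12–15 pairs; each
  block predicted by a model trained on the other seven; RMSECV =
  √(mean out-of-block squared residual).
- **Accuracy metrics** — MAD, MARD (overall and per glycemic stratum),
  consensus (Parkes) error-grid zones for type 1 diabetes, a rate-of-change
  error grid, and a Welch/TOST equivalence test of interferent impact
  against the ±10.5 mg/dl iCGM threshold.

## Worked example

Run the full pipeline on one simulated type-1-diabetes visit containing
all four metabolic challenges plus a paracetamol bolus at minute 60:

```python
from nirmetab import RunConfig, default_t1d_protocol, run_pipeline

proto = default_t1d_protocol(confounders=[("paracetamol", 60.0)])
report = run_pipeline(RunConfig(seed=42, protocol=proto))

g = report.accuracy["glucose"]
print(f"n={g.n}  MAD={g.mad:.2f} mg/dl  MARD={g.mard:.2f}%")
print("Parkes zone A fraction:", g.parkes_fractions["A"])
print("k per fold:", report.cv["glucose"].k_per_fold)
e = report.equivalence["paracetamol"]
print(f"paracetamol: diff={e.mean_difference:.2f} mg/dl "
      f"CI=[{e.ci_low:.2f}, {e.ci_high:.2f}]  -> {e.verdict}")
```

prints

```
n=106  MAD=3.62 mg/dl  MARD=2.69%
Parkes zone A fraction: 1.0
k per fold: (5, 4, 4, 4, 4, 4, 4, 4)
paracetamol: diff=1.72 mg/dl CI=[0.64, 2.79]  -> equivalent
```

Reading this: 106 reference draws were paired to spectra; the
cross-validated glucose predictions are off the blood analyzer by
3.6 mg/dl (2.7%) on average — comfortably under the 10% MARD bound cited
for non-adjunctive CGM use — and all points land in consensus-grid zone A
(clinically accurate). The inner CV selects 4–5 latent variables: four
varying analytes plus the paracetamol absorber/drift. The paracetamol
bolus shifts the mean absolute error by 1.7 mg/dl with a 95% CI well
inside ±10.5 mg/dl, so interferent equivalence is demonstrated for this
visit. (These numbers describe the synthetic instrument model, not the
physical sensor; see `docs/methods.md`.)

The same run is available from a shell:

```bash
nirmetab run --seed 42 --out results/visit42   # report JSON on stdout
nirmetab simulate --seed 1 --out results/raw   # visit CSVs only
nirmetab metrics results/visit42/cv_glucose.csv
```

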