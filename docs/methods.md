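# Methods

`nirmetab` is a synthetic re-creation of the analysis pipeline behind an
implantable near-infrared (NIR) multi-metabolite sensor study: metabolic
challenge visits produce ground-truth concentration time courses, a
Beer–Lambert forward model turns them into 24-channel absorbance spectra,
partial least squares (PLS1) models calibrated per visit link spectra to
reference analyzer values, and contiguous-blocks cross-validation plus CGM
accuracy statistics quantify how well the calibration works. The raw
clinical sensor data are not public, so every quantity the package reports
is computed on synthetic visits whose design mirrors the clinical protocol.

## Visit generator

One visit is 8 hours (480 min) on a 1-minute grid. The type 1 diabetes
(T1D) arm always contains a sequential hyper-/hypoglycemia excursion;
optional challenges raise β-hydroxybutyrate (BHB), lactate and ethanol, and
interferent boluses add one of eight named compounds.

**Glucose excursion.** The protocol constrains the trace, not its exact
shape: glucose must stay in 40–400 mg/dl, descend no faster than
100 mg/dl/h, and keep any 5-minute rate below 4 mg/dl/min. The trace is
built from smooth constant-rate moves with trapezoidal velocity profiles
(velocity ramps over 10 min, holds, ramps back), because an S-shaped ramp
that satisfies the downward cap with margin cannot complete both excursions
inside the visit. Defaults: start 100 mg/dl, peak 340 mg/dl at a
2.8 mg/dl/min ramp, nadir 45 mg/dl reached at 1.2 mg/dl/min (72 mg/dl/h,
leaving headroom under the 100 mg/dl/h cap for jitter), recovery to
100 mg/dl at 2.0 mg/dl/min. The only randomness is a smooth jitter (cubic
spline through Gaussian knots 25 min apart, sd 0.6 mg/dl), so the trace is
seed-independent when jitter is disabled, and the rate caps hold for every
seed with margin. Visits shorter than the time the rate caps require raise
a protocol-infeasibility error.

**Challenges.** Drinks (ketone ester, ethanol) follow one-compartment
first-order absorption/elimination kinetics scaled so the profile peaks at
the target level exactly at the configured time-to-peak (absorption rate
solved numerically from the elimination half-life). Exercise lactate rises
with a smoothstep, holds a plateau, then decays exponentially. Defaults:
ketone peak 3.6 mM (the protocol requires *at least* 3.5 mM; the target
sits just above the floor so the superposed visit trace clears it),
time-to-peak 30 min, half-life 60 min; lactate peak 13 mM, plateau 60 min,
half-life 20 min; ethanol peak 20 mM, time-to-peak 45 min, half-life
90 min. Challenge peaks are absolute analyte levels: the generator
superposes the increment above basal (glucose 100/90 mg/dl T1D/healthy,
BHB 0.1 mM, lactate 1.0 mM, ethanol 0) so the visit peaks at the stated
target.

**Interferents.** The study lists doses (paracetamol 1000 mg, aspartame
2 g, acetylsalicylic acid 1000 mg, ibuprofen 1000 mg, sorbitol 20 g,
caffeine ≈260 mg, fructose 50 g, vitamin C 2 g) but never the interstitial
concentrations reached. The dose-to-peak-concentration scale constants are
therefore invented, physiologically plausible config entries (e.g.
paracetamol 1000 mg → 0.13 mM peak) with shared default kinetics
(time-to-peak 30 min, elimination half-life 120 min). They exist to make
the interference problem real, not to predict pharmacokinetics.

Each visit component draws from its own spawned child of the master seed,
so adding a challenge never perturbs the others and output is byte-stable
for a given (protocol, seed).

## Forward model

Spectra are Beer–Lambert mixtures on a fixed 24-channel grid spanning
1680–2400 nm: `A(λ) = baseline(λ) + L·Σ ε_c(λ)·c_c` with pathlength
L = 1 mm and concentrations in mM (glucose converted at
18.016 mg/dl per mmol/l). Absorptivity profiles are sums of 2–3 Gaussian
bands placed at literature NIR combination-band positions (glucose
~2100/2270 nm, BHB ~2150 nm, lactate ~2250 nm, ethanol ~2260/1690 nm);
amplitudes make a full physiological swing move the spectrum by roughly
ten times the default channel noise. Interferent bands deliberately
overlap the glucose bands, so an uncompensated interferent genuinely
biases glucose prediction and a calibration trained during exposure must
compensate. The four analyte profiles are verified numerically linearly
independent, so noiseless spectra identify the analytes uniquely.

Noise model: i.i.d. Gaussian channel noise (default sd 1e-3 AU) plus a
slow sinusoidal baseline drift (default amplitude 1e-3 AU, one period per
visit, random phase, fixed smooth spectral shape — a rank-one nuisance the
per-visit calibration absorbs). There is no scattering, temperature or
hydration modeling.

Reference analyzers: blood draws every 5 min, tightening to 2.5 min while
ground-truth glucose is below 70 mg/dl; the breath ethanol analyzer runs on
its own 10-minute schedule. Values get multiplicative Gaussian noise at the
device CV — 1.5% for the glucose/lactate analyzer, a ketone-strip CV
interpolated from 10.1% at 0.1 mM to 3.0% at 8.0 mM, 5% for the
breathalyzer (not printed anywhere; config-overridable) — and are clipped
to the device measuring ranges (glucose 0.5–50 mmol/l, lactate
0.5–40 mmol/l, ketones 0.1–8.0 mmol/l). The pipeline evaluates the forward
model at the exact blood-draw times in addition to the visit grid, so each
reference sample has a simultaneous spectrum to pair with.

## Calibration and validation

PLS1 via classical NIPALS, one model per analyte, centering only
(autoscaling off by default: the channels share units; no derivative or
SNV preprocessing — baseline drift is left for the model). The cumulative
regression vectors for 1..k components are cached so truncated predictions
need no refit. If the response variance is exhausted before the requested
k (noiseless low-rank data), later components are frozen rather than
raising, since component search routinely probes past the true rank.

The component count, when set to `auto`, is chosen per training fold by an
inner contiguous-blocks CV (5 blocks): the smallest k whose inner RMSECV is
within 2% of the minimum over 1..k_max (default 10), a parsimony rule that
resists chasing noise.

Outer validation mirrors the study: reference samples are paired to the
nearest spectrum within 60 s, the pairs split into 8 consecutive blocks
(floor/ceil sizes, larger blocks first — 12–15 pairs per block for the
96–120 pairs a visit yields), and every block is predicted by a model
fitted on the other seven. The full 8-fold rotation is used so each pair
is scored exactly once by a model that never saw its block; pooled RMSECV
is the root mean square of all out-of-block residuals.

**Interferent equivalence.** Out-of-block absolute glucose errors are
split by an exposure flag (administration time to administration plus two
elimination half-lives) and compared by a Welch two-sample test. The
verdict is driven by the confidence-interval rule: "equivalent" exactly
when the 95% CI of the mean error difference lies inside ±10.5 mg/dl (the
iCGM non-significant-delta threshold); two one-sided (TOST) p-values
against the band edges are reported alongside. Whether the threshold
applies to the mean difference or per-pair errors is ambiguous in the
source description; the CI-of-the-mean reading is adopted here.

## Accuracy metrics

MAD is the mean absolute difference, MARD the mean absolute relative
difference in percent. Glycemic strata are half-open, left-closed
([40,70), [70,180), ≥180 mg/dl), with references below 40 mg/dl reported
in an extra "<40" stratum rather than dropped. MARD is computed over pairs
with strictly positive reference (the ethanol reference is exactly zero
before intake), with that count reported separately.

The consensus (Parkes) error grid for type 1 diabetes is encoded as the
published zone-boundary vertex table in a versioned CSV
(`nirmetab/data/parkes_t1d.csv`). Classification counts how many nested
boundaries a point strictly crosses away from the identity line, so
boundary points fall in the lower-risk zone; the tests cross-check this
against an independent shapely point-in-polygon construction from the same
vertices. The "rate error grid" is not defined in the source text; it is
implemented as symmetric bands on the rate-difference |predicted rate −
reference rate| (A ≤ 1, B ≤ 2, C ≤ 3, D ≤ 4, E > 4 mg/dl/min), stored as an
equally versioned, swappable CSV.

## Problem sizes and what the tests show

The default pipeline run is one 480-minute visit (≈481 spectra plus draw
times, ≈106 paired samples per blood analyte, ≈49 breathalyzer pairs), and
the property suites sweep up to 100 generator seeds and ten full pipeline
runs — sizes chosen so the whole suite exercises every stage in seconds
while matching the study's per-visit data volume.

Passing tests show the pipeline is internally consistent — noiseless
spectra are inverted exactly, noise propagates as configured, the CV never
leaks, the metrics match hand computations — under a linear, well-specified
forward model. They do not show that a real implanted sensor achieves any
particular MARD: real ATR spectra have scattering, temperature and
tissue-composition structure, plasma–interstitial lag, and connection
losses that this generator deliberately omits. The study's published
real-data figures (overall MARD printed as 7.4% in one aggregation and
7.1% in another; lactate MAD 0.16 vs 0.11 mM, ethanol MAD 0.18 vs 0.02 mM
in different summaries) are context for what the instrument achieved, not
quantities this package can reproduce.

## Known limitations

- Profiles are protocol-shaped, not mechanistic: no insulin–glucose
  dynamics, no plasma↔interstitial lag, fixed hyper→hypo order.
- The dose-to-concentration mapping for interferents is invented.
- The forward model is exactly linear; nonlinear instrument response and
  wavelength-selection questions are out of scope.
- One visit per run: day-to-day calibration transfer is not evaluated
  (the study trained per visit).
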