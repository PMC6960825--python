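# Methods

This note documents the models, defaults and numerical choices behind
`physioact`, and what the synthetic cohorts do and do not establish.

## Protocol and decision grid

A session is one continuous recording of four equal activity segments in
fixed order (neutral, emotional, mental, physical; default 280 s each).
Decisions are taken every `shift_s = 10 s`; each decision is labelled with
the activity of the 10 s slot just completed, and its analysis window
reaches back `W ∈ {10, 20, 40, 60} s` from the decision time, truncated
only at the session start.  Because the recording is continuous, a window
anchored shortly after an activity boundary legitimately contains data
from the previous activity; this is a property of the protocol, not a
labelling error, and it makes the decision count independent of `W`
(4 × 28 = 112 decisions per subject at the default segment length).

## Synthetic cohorts

The generator emulates the session structure and the activity dependence
of cardiac, respiratory and electrodermal physiology:

- **ECG**: a train of Gaussian-shaped P/Q/R/S/T templates at beat times.
  Beat intervals are lognormal around 60/HR with coefficient of variation
  `hr_sd / hr_mean`; R amplitudes are modulated (~10%) by a respiratory
  phase proxy plus noise so amplitude features carry information.
- **TEB**: baseline impedance + unit-amplitude quasi-sinusoidal
  respiration (piecewise-linear phase between jittered breath times,
  interval CV 0.08) + a small cardiac-frequency ripple + activity-dependent
  broadband noise.
- **EDA** (two sites): a smoothed per-activity tonic step (~30 s
  transition), a slow sinusoidal drift, Poisson-arriving SCRs with a
  fast-rise/slow-decay kernel (τ_rise 0.75 s, τ_decay 3 s, amplitudes
  0.2–0.6 µS), and measurement noise.

Default per-activity profiles (generator choices, config-exposed, not
measured values): neutral HR 70 / resp 14 / tonic 2 µS / 1 SCR·min⁻¹;
emotional 78 / 16 / 3 / 4; mental 74 / 17 / 2.8 / 3; physical 110 / 25 /
5 / 6.  Emotional and mental are deliberately close so that classifiers
confuse them much more than they confuse physical with neutral — the
qualitative error structure a four-activity protocol produces in practice.
Cohorts add per-subject factors (HR ×N(1, 0.05), respiration ×N(1, 0.06),
tonic ×lognormal(0, 0.15), SCR rate ×N(1, 0.15)) drawn from seeds derived
deterministically from the cohort seed.

What the generator does **not** emulate: motion artifacts, electrode
contact changes, pathological ECG morphology, textile-sensor noise, or
realistic long-range HRV correlation structure (beat intervals are
independent lognormals, so DFA features carry little class signal here).
Passing tests therefore demonstrate that the pipeline is correct and
leakage-free and that it recovers class structure that exists; they do not
predict error rates on human recordings.

## Measurement derivation

- **R peaks**: 5–15 Hz band-pass, squared derivative, 150 ms integration,
  adaptive threshold at 20% of the median detected peak energy, 0.25 s
  refractory period, apex refinement on the raw signal (±60 ms).  On
  synthetic sessions every beat is found within ±20 ms with no false
  positives.
- **Respiration**: zero-phase 0.7 Hz low-pass of the TEB; breath peaks
  with 1.2 s refractory and prominence 0.3×SD; RF = 60/interval at each
  breath; BRV = successive interval differences.
- **EDA**: tonic = zero-phase 0.05 Hz low-pass; phasic ("Processed") =
  raw − tonic; SCR = phasic local maximum whose rise from the preceding
  trough exceeds 0.05 µS (config-exposed), onset placed at the trough;
  band-limited LF (0.01–0.08 Hz) and HF (0.08–0.5 Hz) components.
- **Band-power series**: event-indexed series (RR, breath intervals) are
  cubic-resampled to 4 Hz; EDA is decimated to 4 Hz (its bands end at
  0.5 Hz).  Periodograms of linearly detrended 30 s sub-windows, hopped
  every 5 s, are integrated per band; each estimate is stamped with the
  sub-window end.  Bands for interval series: VLLF 0.003–0.02, VLF
  0.02–0.04, LF 0.04–0.08, MF 0.08–0.15, HF 0.15–0.5 Hz (the conventional
  HRV bands with the low side split so that MF-based ratios exist).
  A band narrower than one frequency bin (VLLF at 30 s sub-windows)
  receives the interpolated density at its midpoint times its width — the
  nearest-bin mass — rather than exactly zero; bands that do contain bins
  partition the total power exactly (Parseval check in the tests).
- **Conventions**: all times in seconds from session start; every
  interval-derived value is attributed to its later endpoint; "Original"
  measurements are the raw samples.

## Feature catalog

Every measurement gets the 13-statistic SSSP plus the baseline value
(14 parameters).  The baseline filter `y_i = z_i·β + y_{i−1}·(1−β)` runs
causally over the whole session; the per-window feature is its value at
the decision time.  β = Δt/1200 s (uniform streams) or mean-interval/1200 s
(event streams), clamped to (0, 1] — a ~20 min memory.  Extras:

- ECG RR: log(SD), DFA1, DFA2, RMSSD, SDSD, NN50, pNN50, pNN20;
  HR: DFA1, DFA2; HRV: log(SD), RMSSD; PSD ratios HF/LF, LF/HF,
  (LF+MF)/HF, MF/HF and normalized powers VLFnu/LFnu/MFnu/HFnu (20 extras,
  total 11×14+20 = 174).
- TEB RF: average breath rate (breaths in window / duration);
  BRV: log(SD), RMSSD; the same 8 PSD ratio/normalized extras
  (11 extras, total 10×14+11 = 151).
- EDA per site: SCR count, mean SCR amplitude, and PNS/NZC/PZC on the
  first difference of the windowed phasic signal (proportion of negative
  samples; positive-to-negative and negative-to-positive zero crossings);
  PSD HF/LF (6 extras, total 7×14+6 = 104).

DFA integrates the mean-removed series and fits log F(n) against log n
with per-box linear detrending; DFA1 uses box sizes 4–16 samples, DFA2
8–32 (both truncated at n/4; fewer than three usable scales yields a
missing value).  The 8–32 range for DFA2 is a design choice: the classical
long-range 16–64 boxes are uncomputable on the ~50-beat series a 40 s
window contains, which would make the feature permanently missing at the
default window.

Degenerate-input rules: SD/skewness/kurtosis are 0 for constant or
single-sample vectors (excess kurtosis convention); geometric/harmonic
means of data containing non-positive values are computed on the vector
shifted by (1 − min); percentiles interpolate linearly; the 25% trimmed
mean removes 25% of mass from each tail.  Parameters uncomputable in a
window (empty event stream, too-short series, zero-power denominator) are
NaN in the feature matrix and imputed with **design-set** column means at
training time.

## Classifiers

LSLC fits per-class linear discriminants against one-hot {0,1} targets by
solving the normal equations with a 1e-8 ridge for numerical safety
(minimum-norm fallback if singular); predict is the argmax.  LSQC is the
same solver on the quadratic expansion (features, squares, pairwise
products).  CDNN finds the k Euclidean nearest design patterns and
returns the class whose neighbour centroid moves least when the test point
joins it (for m neighbours at centroid c the displacement is
‖x − c‖/(m+1)); ties go to the lowest class index.

kNN, SVMs (one-against-all; box constraint grid {0.1, 1, 10, 100}, RBF
scale {0.5, 1, 2, 4} × median pairwise distance), MLPs and random forests
wrap scikit-learn.  MLPs use one hidden layer of 8/12/16 units, Adam with
learning rate 0.01 (appropriate for z-scored inputs), and early stopping
monitored on 20% of the design data.  Random forests grow 200 unpruned
CART trees with F = ⌊log₂ d + 1⌋ candidate features per node (d = input
features); each tree is grown on the full design set without replacement,
the deterministic limit of without-replacement subsampling, because the
underlying library offers no fractional without-replacement option.

All classifiers receive features z-scored with design-set statistics —
mandatory only for the distance/kernel-based rules, but applied uniformly
because it is harmless for the rest and keeps the pipeline simple.
Hyperparameters are chosen by subject-wise cross-validation inside the
design set (each design subject once as validation fold), ties breaking
toward the simpler grid point.

## GA wrapper selection

Population 100; duplicates perturbed by replacing one random feature;
chromosomes above Nmax randomly pruned; fitness = design-set LSLC MSE
(identical, by construction, to `LeastSquaresClassifier.design_mse_` on
the same columns — a Gram-matrix formulation makes each subset evaluation
O(|S|³)); the best 10 survive as parents and regenerate the other 90 by
random crossover (each feature of two parents' union kept with probability
1/2, empty child → one random union feature); per-gene mutation 1%
(replacement by a random non-member), the best individual exempt.
Initial chromosome sizes are uniform on [1, Nmax].  Defaults of 100
generations and a 4-branch elimination tournament are config-exposed; the
final tournament GA is seeded with the branch winners' parent sets plus
their random crossovers, so the tournament result is never worse than the
best branch.

## Evaluation

Leave-one-subject-out: folds are subjects, so no identity leaks from
design to test.  Per fold, imputation means, z-scoring statistics, GA
selection, hyperparameters and the trained model are all functions of the
design rows only (the test subject's rows are only transformed with the
stored statistics and scored).  The pooled confusion matrix gives the mean
error (1 − trace/total, identical to the unweighted fold mean on balanced
cohorts); repetitions re-seed the GA and stochastic learners while the
fold partition stays fixed by subject identity.  Configurations are
compared with a one-sided paired t-test over the (fold, repetition) error
vector; identical vectors give p = 0.5 by convention.  Per-activity errors
are 1 − recall from the pooled confusion matrix, and feature-selection
frequency is the fraction of (fold × repetition) runs containing each
feature.

## Problem sizes

The test suite and `scripts/acceptance.py` run at desk scale by choice:
protocol counting uses the full 40-subject default cohort (signal
generation only), while the end-to-end LOSO runs use 8 subjects × 4 × 280 s
with Nmax = 10, 20 GA generations, single branch, 2 repetitions, and the
planted-signal benchmark uses 200 rows × 20 features with 20 seeded GA
runs cross-checked against exhaustive C(20,3) search.  Larger cohorts,
deeper GAs and the full classifier × signal-combination × window grid run
through the same interfaces (`run_experiment_grid`, the `evaluate` CLI).

## Limitations

- Synthetic physiology is stylized; error rates on synthetic cohorts are
  not predictions for human data.  The evaluation runner accepts any
  cohort serialized in the session format, including real recordings.
- The ECG model has no P/T-wave pathology, ectopy or artifact, so the
  beat detector's perfect synthetic performance overstates robustness.
- DFA features are nearly uninformative on the generator's memoryless
  interval processes.
- SCR detection is threshold-based; overlapping SCRs closer than ~1 s
  merge.
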