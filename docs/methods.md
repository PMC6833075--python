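# Methods

## The task and the model family

The package targets subject-independent recognition of calibrated heat-pain
stimulation levels from peripheral physiology. Each subject undergoes a
protocol of randomized elicitations — per level T0…T4, `reps_per_level`
(default 20) stimulations with a 4 s plateau followed by an 8–12 s rest —
while EDA, ECG and EMG are recorded. Classification operates on 4.5 s
windows placed 4 s after each elicitation onset (the physiological response,
in particular the skin-conductance response, peaks several seconds after
stimulus onset), i.e. 1152 samples at 256 Hz per window and modality.

Four architectures are provided: two uni-modal 1D-CNN layouts (kernel 3 for
EDA; kernel 11 with extra dropout for EMG/ECG), an early-fusion 2D CNN over
the modality-stacked input, a mid-level fusion of concatenated penultimate
representations, and a late fusion with a constrained trainable aggregation
layer, `e_j = (1/3) Σ_i α_i θ_ij` with `α ≥ 0, Σα = 1`. All convolutional
and dense layers use ELU (α = 1); outputs are softmax; dropout is 0.25;
optimisation is Adam on cross-entropy (for late fusion, the weighted
four-term loss `Σ λ_i L_i + λ_agg L_agg`, defaults 0.2/0.2/0.2/0.4).

### Design choices in ambiguous corners

* **Padding.** Convolutions are stride-1 "same" along time, so seven
  pool-2 stages map 1152 → 9 and the flatten widths are 9·128 = 1152
  (uni-modal) and 36·64 = 2304 (early fusion). The early-fusion net is
  "valid" along the 3-row modality axis, which is the only reading under
  which its two 2×11 convolutions purposefully collapse 3 → 2 → 1 rows.
* **Batch-norm order.** conv (linear) → batch norm → ELU → pool.
* **Simplex constraint on α.** Enforced structurally by parameterising
  α = softmax(a) over three trainable logits initialised to zero (equal
  weights); non-negativity and the unit sum therefore hold at every
  training step, not just at convergence.
* **The literal 1/3 factor** in the aggregation is kept (the aggregated
  scores then sum to 1/3; argmax and clipped cross-entropy are unaffected);
  `average_factor=False` drops it.
* **Input scaling.** Raw windows are z-scored per modality with scalar
  statistics from the training fold (`standardize=True` by default); the
  statistics are part of the fitted estimator and test data reuse them.
* **Inference batch-norm** uses running statistics with momentum 0.9 —
  small-step training runs (tens of optimizer steps) still converge the
  running estimates.
* **Ties** in argmax resolve to the lowest class index (NumPy argmax).

### The training engine

No deep-learning framework is used: `painfusion.nn` is a compact NumPy
engine implementing exactly the required layer vocabulary with explicit
forward/backward passes and Adam. Convolutions are evaluated as sums of
time-shifted batched GEMMs (single-channel layers use a sliding-window
view), which is what makes CPU training of the full-depth networks
practical. Correctness is established by central-difference gradient checks
over every layer kind in float64 (`tests/test_nn.py`) and by closed-form
oracles for the activations, losses and aggregation arithmetic.

## The synthetic cohort

The generator emulates the *structure* of the real stimulation protocol and
the *qualitative phenomenology* of the three channels:

* **EDA** — tonic level (3–7 µS) + slow sinusoidal drift + per-stimulus
  skin-conductance responses: Bateman-type bi-exponential kernel
  (τ_rise = 0.75 s, τ_decay = 2 s, unit peak), onset-latency 1.5–3 s,
  amplitude = subject gain × a monotone per-level effect profile
  (0, 0.3, 0.6, 1.0, 1.5) that is zero at T0 by definition; additive
  Gaussian noise (0.02 µS).
* **ECG** — Gaussian R-waves (σ = 12 ms, 800 µV) at beat times from an
  integrated instantaneous rate (baseline 60–85 bpm, raised during/after
  plateaus by a per-level bump of a few bpm), plus **baseline wander
  injected as a scaled copy of the standardized EDA trace** (150 µV/SD).
  This reproduces the EDA-correlated ECG drift that the per-segment
  polynomial detrending stage exists to remove, so that stage is exercised
  against exactly the artefact it targets.
* **EMG** — band-limited (20–120 Hz) Gaussian noise whose variance rises
  modestly with level around each plateau.

Per-subject random effects (log-normal gains, uniform latencies and
baselines) model inter-subject variability — the reason LOSO evaluation is
the honest protocol. Generation defaults to 512 Hz so the preprocessing
path (filter at native rate, then decimate to 256 Hz) is exercised;
`fs_hz=256` generates directly at the analysis rate, in which case
recordings are treated as already preprocessed by the evaluation harness.

Effect sizes per level are not documented for real recordings anywhere we
could anchor them; the defaults are calibrated once to a single target — the
separability ordering (a trivial threshold classifier on per-window EDA
range beats the same classifier on EMG and ECG), which makes the
fusion-weight-recovery experiment well-posed. EDA carries a strong,
within-window effect; EMG a weak one; ECG the weakest. The generator makes
no claim of matching the statistics of any real database: passing tests
demonstrate that the pipeline recovers planted structure, not that it
attains any published accuracy on clinical data.

What the simulator deliberately does **not** model: P/T waves and heart-rate
variability spectra, electrode artefacts, movement artefacts, thermode
temperature traces, spontaneous (non-stimulus-locked) SCRs, and facial/video
channels.

## Evaluation protocol

One fold per subject; training uses all other subjects' windows (plus
time-shift augmented copies when enabled — augmented windows are *training
material only*, enforced by contract and audited inside the harness);
testing uses the held-out subject's base windows. Per-fold accuracy is
window-level; the cohort figure is the unweighted mean over folds. Binary
metrics use the positive class (the higher level by default); multi-class
metrics are class-averaged one-vs-rest with macro F1. Zero denominators
yield 0 with a warning (conservative). Paired model comparisons use the
two-sided Wilcoxon signed-rank test on per-fold accuracies with
zero-difference exclusion (exact null for small n); fewer than six non-zero
differences is flagged as insufficient for significance at 5 %.

## Study sizes

The repository's self-contained studies are sized for a single CPU with the
NumPy engine, chosen up front as the package's own problem sizes:

* **Fusion-weight recovery** — 10 subjects, 5 reps/level (T0-vs-T4 → 10
  base windows per subject), no augmentation, 30 epochs, batch 16, Adam
  lr 1e-3, LOSO. The published defaults (lr 1e-5, 100 epochs, batch 100)
  are tuned for a full-scale database of 8700 trials; at this reduced scale
  a conventional Adam rate of 1e-3 and small batches give the optimiser a
  comparable number of useful steps.
* **Null-effect control** — identical pipeline on a cohort with all level
  effects and wander removed (10 subjects, 10 reps/level, 5 epochs);
  held-out accuracy should lie within binomial noise of 0.5.

Full-cohort bookkeeping (87 subjects × 100 trials) is verified at the
schedule/label level without synthesising signal samples, which keeps the
arithmetic checks instantaneous.

## Known limitations

* The NumPy engine targets clarity and test-coverage, not GPU-scale
  throughput; full-scale (87-subject, 100-epoch) training is out of reach
  on one CPU and is not attempted.
* The synthetic EMG/ECG effects are stationary variance/rate modulations;
  real signals carry richer, subject-specific discriminative structure.
* Published accuracies on the real clinical database cannot be reproduced
  here because that database is access-restricted; the tests assert
  structural and qualitative properties instead.
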