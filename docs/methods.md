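# Methods

## The diagnostic model

The pipeline infers color vision status from which of two
frequency-tagged Ishihara plates a subject attends. Its core assumption is
the standard SSVEP one: sustained attention to a stimulus flickering at
f Hz produces a narrowband EEG response at f and its harmonics, strongest
over occipital cortex (O1/O2), weaker parietally (Pz), weakest centrally
(Cz). Given that, the subject's plate choice is decodable from the
spectrum, and the plate table converts choices into a diagnosis: normal
vision reads the target plate, red-green CVD reads the non-target plate
(sessions 1, 3, 5) or a hidden-digit plate invisible to normal vision
(sessions 2, 4, 6). The number of hidden-digit plates recognized (0–3)
serves as a severity index.

Two inference routes are provided on the same features:

1. **Rule-based** (`diagnosis`): per session, the attended frequency is
   the argmax over {15, 18} Hz of a detection score (channel-mean Welch
   PSD at the bin, channel-mean CCA ρ, or their min-max-fused mean,
   CCA by default). A subject is called CVD when ≥ 4 of 6 sessions match
   the CVD expectation, normal when ≤ 2 do, indeterminate otherwise. The
   threshold is symmetric so the indeterminate band is unbiased; exact
   score ties resolve to the session's target frequency, deliberately
   biasing ties *away* from a deficiency call. This route exists to make
   the paradigm logic testable in isolation; no formal subject-level rule
   is standard for this paradigm, so the majority threshold is this
   package's own construction.
2. **Learned** (`ml`): 16 features per subject feed SMOTE-balanced
   DT/KNN/SVM classifiers under stratified 5-fold cross-validation.

## Feature construction

Sessions are grouped by their **target** frequency (15 Hz tags the target
plate in odd sessions, 18 Hz in even sessions, both overridable per
`SessionPlan`). The surviving trials of each group are averaged, and the
PSD/CCA features *at* a frequency are measured on *that frequency's* group
average. This grouping is what makes the features diagnostic: within the
15 Hz-target group, normal subjects attended 15 Hz (high PSD/ρ at 15)
while CVD subjects attended 18 Hz (low at 15), and symmetrically for the
18 Hz group. A grand average over all six sessions would instead give both
groups three sessions at each frequency and erase the class difference —
so the per-target-frequency construction is the only one under which the
16-feature classification task is well-posed. The canonical feature order
is PSD(O1,O2,Pz,Cz @ 15), PSD(@ 18), CCA(@ 15), CCA(@ 18); the two
8-feature per-frequency subsets are the first/second half of each block
(`FEATURE_SETS` slices cover psd, cca and psd+cca).

## Signal conditioning

Defaults follow the acquisition protocol: 4th-order Butterworth band-pass
5–30 Hz, 60 Hz IIR notch (Q = 30 — narrow enough to spare the 5–50 Hz
band's upper edge), a second 5–50 Hz band-pass stage retained for chain
fidelity although spectrally redundant after the first, common-average
re-reference,
trigger-driven segmentation into 10-s trials, rejection of any trial
whose absolute amplitude exceeds 100 µV on any channel (inclusive bound:
exactly ±100 µV is kept), and per-session trial averaging. Filters run
zero-phase (forward–backward, doubling effective order) so group delay
cannot smear trial boundaries; `zero_phase=False` gives the strict causal
4th-order behavior of an online filter. Epochs within ±2 samples of
nominal length are trimmed/zero-padded (trigger edges jitter by a sample);
shorter epochs are skipped with a warning. Independent-component artifact
removal is out of scope — its component selection is inherently visual and
irreproducible — and the amplitude criterion is the implemented rejection
path.

## Spectral and CCA numerics

- The periodogram is computed per mean-detrended, Hann-windowed segment
  and scaled as a one-sided density (divide by fs·Σw², double non-DC,
  non-Nyquist bins) so units are genuinely µV²/Hz; `density=False`
  recovers the unscaled |X(k)|²/M textbook form. Detrending removes DC
  leakage into the low bins.
- Welch = arithmetic mean of segment periodograms; at the defaults a
  2,500-sample trial gives N = 19 segments and 1 Hz bins, so 15/18 Hz are
  exact bins. `psd_feature` uses nearest-bin lookup with ties toward the
  lower frequency.
- Per-channel CCA against the 2H-row harmonic bank reduces to the multiple
  correlation coefficient; it is solved via the reference-side normal
  equations with a relative ridge of 1e-10 on the Gram matrix. The
  per-channel formulation is what yields exactly 8 CCA features
  (4 channels × 2 frequencies); a multichannel variant
  (`cca_max_correlation_multichannel`) is provided for exploration only.
  H = 3 harmonics; harmonics at or above Nyquist are rejected with the
  offender named.
- Reference sampling is t = m/fs, m = 0..n−1.

## The synthetic cohort

The generator emulates the statistical structure the analysis relies on,
with defaults chosen as a plausible mid-band SSVEP regime:

| parameter | default | rationale |
|---|---|---|
| SSVEP amplitude | O1 = O2 = 2, Pz = 1, Cz = 0.5 µV | occipital-dominant topography |
| harmonic decay | 0.5 per harmonic, 3 harmonics | falling harmonic energy |
| alpha/display tone | 2 µV at 10 Hz | the non-target ~10 Hz peak mid-band displays induce |
| background | 1/f, 5 µV RMS | standard EEG broadband model |
| line noise | 1 µV at 60 Hz | removed by the notch anyway |
| artifacts | 0.5/min, 150 µV, 0.5 s pulses | blink-scale transients that trip the ±100 µV criterion |

SSVEP phases are drawn once per session and held across its ten trials:
the response is stimulus-onset-locked, which is precisely why trial
averaging improves SNR; per-trial random phase would cancel the evoked
component under averaging and contradict the averaging stage's purpose.
Phases differ across channels (cortical propagation delays), which also
prevents the common-average reference from subtracting a fully coherent
evoked component. Nuisance components (alpha, noise, line phase, artifact
timing) are redrawn per trial. The ~10 Hz peak is modeled as an additive
tone: it reproduces the observable (a spectral peak) without modeling
display hardware.

The behavioral model: with probability `lapse_rate` a session's choice is
uniformly random; otherwise normal vision picks the target plate, and CVD
picks the non-target plate — for hidden-digit sessions only with
probability `severity`, falling back to the target plate when the hidden
digit goes unrecognized. Severity is driven solely by the hidden-digit
sessions; session 5's possible severity signal has no stated rule and is
deliberately not modeled.

**What passing tests show — and don't.** The synthetic cohort has exact
trigger edges, stationary Gaussian-ish backgrounds, linear superposition,
and a behavioral model with no attention drift, eye movements, or
inter-subject spectral variability beyond seeded randomness. Perfect
label recovery and near-ceiling cross-validated accuracy on it establish
that the pipeline's logic, numerics and bookkeeping are correct under the
model's assumptions; they are not evidence about real-EEG effect sizes,
where lower SNR, non-stationarity and artifacts will reduce performance.

## Machine-learning choices

- SMOTE is applied **fold-internally** by default (training portion only)
  so synthetic samples never leak into test folds; `global` mode balances
  before splitting for fidelity with balance-first protocols, and the two
  can differ noticeably at n = 16. k defaults to 5, clamped with a warning
  to minority − 1 (4 at study scale, where k = 5 is infeasible).
- Features are z-scored per column (fit on the training fold) before
  KNN/SVM; PSD (µV²/Hz) and CCA ([0, 1]) otherwise differ by orders of
  magnitude and would dominate distances and margins.
- DT: entropy criterion (information gain), depth cap 5, no pruning.
  KNN: k = 5, Euclidean; vote ties resolve by smallest summed neighbor
  distance, then lexicographic label. SVM: inhomogeneous polynomial kernel
  (1 + ⟨x, x′⟩)^d with d = 3, C = 1.
- CVD is the positive class in all confusion-matrix metrics; undefined
  ratios (zero denominators) are reported as 0 with an explanatory flag
  rather than NaN.

## Problem sizes and determinism

The acceptance script and the heavier tests run the full study-scale
protocol — 16 subjects × 1,200 s × 4 channels at 250 Hz — which completes
in seconds; unit tests use a 3-trial-per-session variant of the same
model. All stochastic operations accept a seed or Generator; cohort
subjects get independent spawned streams so results are insensitive to
subject order, and identical config + seed reproduces outputs
bit-identically (the determinism tests compare written CSV bytes).

## Known limitations

- The OpenBCI-style text dialect (header `%` lines; columns: sample index,
  EEG channels, trigger) is a declared convention for interoperability,
  not a claim about any particular exporter's files.
- The rule-based subject call (4/6 threshold) is a package construction;
  its operating characteristics on real data are unvalidated.
- No ICA, EOG regression, bad-channel interpolation, resampling, or
  protan/deutan subtype separation.
- The generator does not render stimuli or model photometry, eye
  movements, or electrode impedance drift.
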