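# Methods

This note documents the models, processing rules, numerical choices and
known limitations of `pulsemorph`. Everything stated here is computed by
the package's own code; the test suite and `scripts/acceptance.py`
re-derive the quantitative claims at run time.

## Problem

Continuous arterial blood pressure (ABP) is the gold standard for
haemodynamic monitoring but requires an arterial catheter. The fingertip
photoplethysmogram (PPG) is cheap and non-invasive and shares much of the
ABP pulse's temporal structure. `pulsemorph` estimates the *average ABP
pulse morphology* — a per-time-step pressure value plus a cardiac-cycle
class label — from a raw 5-s PPG excerpt and optional demographics (age,
gender). From the estimated pulse the clinically used markers follow:
diastolic pressure (DBP), systolic pressure (SBP), the dicrotic-notch
pressure and time (DN, DNTO), and the pulse duration.

## Record and segment selection

Records must last at least 15 min, carry both channels at 125 Hz, and have
demographics with age in [18, 89] years. Within a record, two 15-s windows
(1875 samples, half-open `[start, start + 15 s)`) with a 5-min
start-to-start gap are proposed, the first pair beginning after a 10-min
rest interval. A rejected pair advances the cursor by 60 s; a record whose
cursor is exhausted is excluded. The 5-min gap is interpreted
start-to-start (the alternative end-to-start reading would only shift the
second window by 15 s and change no thresholds).

## Signal quality

Per window, in order:

* **Flat** — runs with successive differences within `tol` (default 0,
  i.e. exact repetition, "null data") lasting at least 0.2 s, plus NaN
  runs. Runs sitting on the global extremes of a non-constant window are
  left to the saturation stage, so the two stages report disjoint regions.
* **Peak** — clipped plateaus: runs of at least 3 samples at the window's
  global maximum or minimum.
* **PPG-SQ** — zero-phase Butterworth band-pass [0.5, 8] Hz (order 4,
  forward-backward so landmark timing is preserved), min-max normalization
  to [0, 1], then pulse delineation; failure to find onsets rejects the
  window.
* **ABP-SQ** — pulse-by-pulse checks on the ABP window: every pulse
  duration in [0.5, 1.5] s (inclusive), 10–30 pulses per window
  (inclusive), pulse pressure strictly above 10 mmHg, and moment skewness
  strictly positive, evaluated per pulse (the per-pulse reading is the
  stricter of the two possible readings).

Onset delineation uses a slope-sum-function (SSF) detector: positive
slopes are accumulated over a 128-ms window; SSF peaks at least 40% of the
median peak height and separated by at least 0.4 s mark systolic
upstrokes; each onset is the waveform minimum within the 0.3 s preceding
its upstroke. Upstrokes whose search window is truncated by the segment
edge are discarded. The contract the rest of the pipeline relies on — and
the property the tests pin — is onset recovery within ±3 samples on clean
signals, not numerical equivalence with any published delineator.

## Average pulse morphology

Accepted ABP pulses are onset-aligned into a ragged matrix. Per column the
mean μ_i and the population (divide-by-n) standard deviation σ_i are
computed over the contributing pulses; the reported average keeps only
contributors inside μ_i ± 1.25 σ_i (inclusive, single pass — the inclusive
band makes σ = 0 columns well defined, and iterating the rejection was
judged an unstated extrapolation). The average's length is the median
contributing pulse length; beyond it the few long pulses would dominate.

Landmarks on the average: the systolic peak is the global maximum; the
dicrotic notch is the most prominent local minimum after it, falling back
to the point of maximal smoothed curvature when the decay is monotone.
Classes: `[onset, SP] → C[O,SP]`, `(SP, DN] → C[SP,DN]`,
`(DN, end] → C[DN,E]`.

Dataset-level post-filters: maximum pressure ≤ 180 mmHg, duration ≤ 1.2 s,
moment skewness of the averaged pulse > 0.2. Each subject then contributes
at most 10 segments (random subsample, seeded).

## Model inputs and targets

The 15-s raw PPG is band-passed [0.5, 45] Hz, differentiated with a
Savitzky–Golay filter (window 7, degree 3, analytic first-derivative
coefficients, applied after the band-pass), and trimmed by 1 s per end to
discard filter transients, leaving 13 s (1625 samples). Model inputs are
5-s windows (625 steps) with uniformly random start, each channel min-max
scaled over the window; demographics are encoded as (age − 18)/71 and a
binary gender indicator (female 0, male 1 — the encoding is a package
choice, any fixed binary coding is equivalent up to a sign).

Targets are scaled to [0, 1] by one affine map fitted on the training
collection's global minimum and maximum. Each scaled pulse is cyclically
repeated to the fixed length T = (longest pulse + 15 steps); repeated
steps carry the fourth class ("ended"), and the value loss is masked to
the first (pulse length + 15) steps. The class loss runs over all T steps
so the model must emit "ended" on the repetition.

## Architecture

Encoder: three bidirectional GRU layers (default 4, 20, 100 units per
direction) with dense connections — every layer reads the module input
concatenated with all previous layer outputs. Decoder: three
unidirectional GRU layers (8, 40, 200); each is initialized from the
concatenated forward/backward final states of the matching encoder layer
(the widths match exactly because decoder layers are twice the encoder
width). The GRU follows the standard update/reset-gate equations;
learnable biases are included (initialized to zero, so the bias-free
textbook form holds exactly at initialization) and can be disabled.

Attention is the general bilinear score `h_tᵀ W h̄_s` between the top
decoder state and each encoder output, softmax-normalized into weights
whose weighted sum of *encoder outputs* is the context vector (the
standard Luong formulation; summing decoder states instead would make the
context independent of the input sequence). The value head is a single
ELU unit on `[context ‖ h_t]`; the class head is four ELU units on `h_t`
followed by a softmax — the softmax is meaningful only on the
multi-output head, a softmax over one unit being identically 1. The first
decoder input is a vector of ones; afterwards the previous output
(optionally concatenated with the demographic vector) is fed back. At
inference the fed-back class probabilities are hardened to the argmax
one-hot by default, matching the one-hot input distribution seen during
teacher-forced training; soft feedback is available as an option.

## Training

Loss: `MSE + λ·CE` with λ = 0.01; masked per-sample value MSE (each sample
averaged over its own mask length, then over the batch) and categorical
cross-entropy over all T steps with probabilities clipped at 1e-8. The
cross-entropy carries the conventional negative sign so it is non-negative
and minimized exactly at the truth. Adam at 1e-3; the learning rate halves
after 25 epochs without strict improvement of the (training) epoch loss
and training stops after 50; batch size 48. Dense/attention weights start
from U(−w, w) with w = 1/√fan-in, GRU input weights from U(−k, k) with
k = 1/√units, recurrent transition matrices random orthogonal, biases
zero.

Teacher forcing is the default (`teacher_forcing = 1.0`): the decoder
sees the ground-truth previous output during training, inference is
always autoregressive. A scheduled-sampling ratio below 1 makes the
corresponding fraction of optimization steps run the decoder
autoregressively (feeding back its own detached predictions); this is the
standard remedy for exposure bias and is what the reduced-scale studies
use, since at small sample sizes a purely teacher-forced model learns to
copy its input sequence instead of generating one.

Scenarios: `Mixno` and `Mixno+DI` use subject-disjoint 5-fold splits
(each test fold holds all segments of ~20% of subjects); `Mixyes+DI`
splits 20% of segments regardless of subject. Folds are disjoint by
default; independent 80/20 resampling is available as an option.

## Evaluation

Predictions are restored to mmHg with the training-set scaler. Markers
from a predicted sequence: in-pulse steps are those before the first
"ended" class (absent that class, the whole sequence, logged); DBP is the
mean of the first and last in-pulse value, SBP the in-pulse maximum, DN
the value at the last peak-to-notch step, DNTO that step's time, duration
the first "ended" step's time. The sentence-level ambiguity between
defining DNTO by the last peak-to-notch step versus the last notch-to-end
step is resolved in favour of the former, which is self-consistent with
the DN-value rule. Metrics: RMSE, MAE, error STD (n−1), R² with squared
residuals, Pearson R for waveforms with truncation to the shorter
sequence. BHS grading uses the cumulative percentage of absolute errors
below 5/10/15 mmHg; a grade requires all three thresholds of its row.
Bland–Altman limits are mean difference ± 1.96 × sample SD.

## Synthetic data

The generator emulates exactly the study conditions the pipeline expects:
125 Hz paired records, subject ages uniform over [18, 89], DBP ~ N(64, 8)
and SBP ~ N(125, 14) mmHg (clipped to keep pulse pressure above 25 mmHg
and maxima under the 180 mmHg post-filter with margin), resting heart
periods uniform over [0.65, 1.10] s. Each beat is a sum of two Gaussian
lobes (systolic and diastolic) separated by a local minimum serving as
the dicrotic notch, plus a 2% upward tilt that pins the global minimum to
the onset; beats concatenate with ≤5% multiplicative jitter on period and
pulse pressure. The PPG is derived from the ABP by a fixed transform:
unit normalization, 80 ms delay, 2nd-order 8 Hz low-pass, x^0.9.
Artifacts (flatline, saturation, noise bursts) are injectable with exact
extents.

What the generator does *not* model: respiratory modulation, reflected
-wave variability, arrhythmia, pathology-specific morphologies,
sensor-specific PPG distortions, or any real difference in transfer
between subjects beyond amplitude/timing jitter. Passing tests therefore
demonstrate that the pipeline and model implement the method correctly
and that the fixed synthetic transform is learnable — not that the
published error levels transfer to clinical data.

## Reduced-scale study sizes

The test suite and the acceptance script size their computations for a
single CPU: the learnability study trains a compact model with the same
topology (encoder 4/16/32, decoder 8/32/64 units), batch 8, learning rate
2e-3, a 25% teacher-forcing ratio (three quarters of the optimizer steps
decode autoregressively), and ~750 optimizer updates (30 epochs) on 200
processed synthetic segments, evaluating autoregressively on held-out
segments. Free-running pulse-duration inference from the PPG beat
spacing is the slowest skill to emerge and dictates this budget. The full-scale defaults (4/20/100, 8/40/200, batch 48,
1e-3, patience 25/50) remain the package defaults used by the CLI.

## Known limitations

* The slope-sum-function onset detector honours a recovery contract
  (±3 samples on clean signals); it is not a numerical replica of any
  published delineator.
* The WFDB-style reader/writer covers only the subset of the format this
  package emits (format-16 two-channel records with gain/baseline).
* The hand-written autodiff engine implements exactly the operations the
  model needs; it is validated by central-difference checks but is not a
  general-purpose framework.
* Exposure bias: with pure teacher forcing at small scale the
  autoregressive decode degrades; the scheduled-sampling option exists
  for precisely this reason.
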