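# Methods

`mwlcnn` classifies the momentary mental workload (MWL) of a human operator
from multichannel physiological recordings made while the operator controls
a simulated process plant. This note documents the models and procedures the
package implements, the choices made where the design was genuinely open,
and what the synthetic-data experiments do and do not demonstrate.

## Problem setting

An operator supervises four subsystems (O₂ concentration, pressure, CO₂
concentration, temperature) of a cabin air-management simulation. Task load
is manipulated by two factors: the number of subsystems under manual control
(NOS ∈ {0, 2, 3, 4}) and the actuator sensitivity (AS ∈ {low, high}). A
session consists of ten 300-s conditions — four automatic baselines
(conditions 1, 4, 7, 10; NOS = 0) interleaved with six manual conditions of
increasing difficulty — while 17 channels of electrophysiological data are
recorded at 500 Hz.

Two labelings of workload are supported:

* **Case 1 (4 classes)** from NOS alone: Unloaded (0), Low (2), Normal (3),
  High (4).
* **Case 2 (7 classes)** from (NOS, AS): Unloaded, Very Low (2, low),
  Low (2, high), Medium (3, low), High (3, high), Very High (4, low),
  Overloaded (4, high).

With 2-s epochs, 5-s trims at both ends of every condition, and two
sessions per participant, the class sizes are 1160/580/580/580 (Case 1) and
1160 plus six classes of 290 (Case 2), out of 2 × 1450 epochs.

## Preprocessing and features

Signals are low-pass filtered with a 4th-order Butterworth filter at 40 Hz,
applied forward–backward (`sosfiltfilt`) so the phase is preserved — band
*power* features are insensitive to phase, but zero-phase filtering keeps
epoch boundaries aligned with the schedule. Each condition is trimmed by
5 s at both ends and tiled with non-overlapping, left-aligned 2-s windows:
`floor((300 − 10)/2) = 145` epochs per condition, 1450 per session.

Each epoch channel is transformed with a short-time Fourier transform and
reduced to the mean power in six rhythm bands: delta 1–4, theta 5–8, alpha
9–13, lower beta 14–16, higher beta 17–30 and gamma 31–40 Hz. Band
membership is by bin-center inclusion in the closed interval, and a band
that captures no bins raises an error rather than silently contributing
zeros.

**Frame layout.** The feature matrix has ten time frames per 2-s epoch.
The frame length is a free design parameter subject to
`(epoch_len − frame_length)/hop + 1 = 10`. Ten *non-overlapping* 100-sample
frames would satisfy the constraint but give 5 Hz spectral resolution: the
1–4 Hz delta band then contains no bins at all, and a Hann-tapered 10 Hz
tone keeps only ~58% of its 1–40 Hz power inside the alpha band — band
powers would be dominated by leakage rather than band content. The package
therefore uses ten *overlapping* 550-sample Hann frames with hop 50
(0.91 Hz bins): every band contains bins and a pure tone concentrates >99%
of its power in its own band. Frame length, hop, taper and FFT length are
all exposed in `STFTConfig`.

Stacking the per-channel 6 × 10 blocks row-wise (channel-major, band-minor)
gives the 102 × 10 input matrix of the classifiers.

## Task-performance labels (the clustering route)

Besides the condition mapping, labels can be derived from task performance.
The time-in-range score TIR is the mean over time instants of the fraction
of the four subsystems inside their target zones (a value in [0, 1]); the
performance indicator combines it with task difficulty,

    PI = c₁·TIR + c₂·NOS,  c₁ = 0.7, c₂ = 0.3.

NOS enters on its native 0–4 scale — no normalization is applied, so the
NOS term dominates the spread of PI and k-means on per-epoch PI values
recovers the NOS groups first. The number of classes is chosen by the
average silhouette index

    S(i) = (b(i) − a(i)) / max{a(i), b(i)},

with a(i) the mean Euclidean distance of point i to the rest of its own
cluster and b(i) the smallest mean distance to any other cluster; points in
singleton clusters score 0 (a common convention — the definition is
otherwise indeterminate there). k-means runs with 20 restarts and a fixed
seed per candidate k ∈ {2, …, 10}; silhouette ties break toward smaller k.
TIR/PI are computed per 2-s epoch so the clustering labels align 1:1 with
the feature epochs.

## Classifiers

Five fixed convolutional architectures of increasing depth map the
102 × 10 matrix to class posteriors. All convolutions are valid-padding
with stride 1 and ReLU activations; pooling is average pooling with floor
semantics (trailing rows/columns that do not fill a window are dropped);
every stack ends in a fully-connected ReLU layer of width 256 and a softmax
output. Filter counts default to 15/25/40 in the three convolutional groups
and are overridable. The stacks (conv field × filters, pool field):

| id   | stack |
|------|-------|
| CNN1 | 3×3–15, pool 4×2 |
| CNN2 | 3×3–15, pool 4×2, 4×1–25, pool 2×2, 4×1–40 |
| CNN3 | 3×3–15, 1×1–15, pool 4×2, 4×1–25, 1×1–25, pool 2×2, 2×2–40, 1×1–40 |
| CNN4 | 3×3–15, 3×3–15, pool 2×2, 4×1–25, 5×1–25, pool 2×1, 2×2–40, 2×2–40 |
| CNN5 | 3×(3×3–15), pool 4×2, 3×(4×1–25), pool 3×1, 3×(2×1–40) |

All five stay dimensionally consistent from a 102 × 10 input (e.g. CNN1:
3×3 conv → 100×8, 4×2 pool → 25×4); the shape audit is a unit test.

The networks are implemented directly in numpy (float64) with analytic
gradients, verified against central differences to <1e−4 relative error.
This keeps training bit-reproducible from a seed — initialization, batch
shuffling and updates all draw from one seeded generator — and the models
are small enough (≤ ~1 M parameters, 102 × 10 inputs) that vectorized
numpy is entirely adequate on one CPU core.

**Training.** Mean cross-entropy is minimized over shuffled mini-batches
(default batch 32, 100 epochs — both unspecified upstream and
config-exposed). Optimizers: Nesterov momentum (lr 1e−4, momentum 0.9),
Adagrad (lr 1e−4), Adadelta (decay 0.95, ε 1e−6, no learning rate) and
Adam (lr 1e−4, decays 0.9/0.999). Weights are initialized from a symmetric
uniform distribution with fan-in scaling, bound √(6/fan_in): the
He-style bound preserves signal variance through the ReLU stacks, which
the deeper architectures need at these small learning rates.
Inputs are z-scored per matrix entry using training-set statistics (stored
with the model); raw band powers span orders of magnitude and unscaled
inputs stall the small fixed learning rates.

## Ensembles

Base members are diversified by training each on its own bootstrap
resample — floor(0.8·n) training indices drawn without replacement — and by
varying (architecture, optimizer). Member accuracy for ranking is measured
on a validation slice of the training half (20% by default); which split
"accuracy" refers to was left open upstream, and a held-out slice avoids
both the optimism of training accuracy and contamination of the test half.

* **Rank-weighted averaging.** Members are ranked by accuracy (best of K
  gets rank K; ties get average ranks, keeping the weights
  order-independent and summing to 1) and combined as
  S′(i) = Σⱼ αⱼ yⱼ(i) with αⱼ = R(Aⱼ)/Σₖ R(Aₖ); yⱼ(i) is the full
  posterior vector, not a hard label. The predicted class is the argmax of
  the combined posterior. User-supplied weight vectors are also accepted.
* **Majority voting.** Modal predicted label; ties go to the vote of the
  most accurate member.
* **Stacking.** Members are refitted per fold of a 5-fold split; the
  out-of-fold predicted labels form an n × K meta-table. The
  meta-classifier — a multinomial logistic regression on the one-hot
  encoding of that table (the simplest standard choice) — maps member
  outputs to the target, and members are finally refitted on the full
  training set.

Member selection from the scored 5 × 4 grid supports four strategies: best
per architecture family (5), best and worst per family (10), top half
overall (10), and all (20).

## Evaluation

Confusion matrices have target classes as rows and estimated classes as
columns. With N the total, tr_i the diagonal, n_i row sums and tp_i column
sums: accuracy = tr/N; macro precision = (1/c)·Σ tr_i/tp_i; macro
F = (2/c)·Σ P_iR_i/(P_i+R_i); G-mean = (Π tr_i/n_i)^(1/c). Zero
denominators contribute 0 for the affected class, and any class with an
empty diagonal zeroes the G-mean. The per-class accuracy reported with the
reference confusion tables is tr_i/tp_i — the precision-like column
convention, which reproduces every printed value exactly (e.g.
585/601 = 97.3%).

The evaluation protocol draws unstratified uniform 50/50 train/test splits,
repeats for five seeded runs, and reports per-run metrics plus mean ± std
per (architecture, optimizer) combination, ranked by mean accuracy with
ties broken by precision then F (the composite used for the published
rankings is under-specified; this rule is config-exposed).

## Synthetic data

The study's recordings are private, so the generator emulates their
statistical skeleton: per condition, each channel is a sum of six
band-limited oscillations — band-pass-filtered Gaussian noise, *not* pure
tones, so class separation rests on band power rather than spectral lines —
plus white noise (σ = 2) and 1/f noise (σ = 4), with a fixed per-channel
gain in [0.8, 1.2]. Baseline band standard deviations default to
(4, 8, 10, 5, 4, 2) signal units for delta…gamma, an EEG-like profile with
dominant low-frequency power.

Workload enters through the band amplitudes: at load level l (class
index / 3 for the four NOS classes) theta and alpha are multiplied by
1 + (gap − 1)·l and the two beta bands divided by the same factor; delta
and gamma stay flat. The default `amplitude_gap` is 3. The direction of
the modulation and its size are *free parameters of the simulation*, not
physiological claims — no quantitative band-power-vs-load effect sizes are
available to calibrate against.

Zone flags are drawn per 0.25-s instant and subsystem as Bernoulli with a
per-condition probability drawn once per session from a Beta distribution
centered on the published per-condition mean TIR (0.959, 0.795, 0.945,
0.732, 0.863, 0.571 for the six manual conditions; 0.98 assumed for the
automatic baselines, which have no published value) with concentration 100,
reproducing both the printed averages and a session-to-session spread
comparable to the printed per-session tables. The 0.25-s instant spacing
matters for the clustering route: with only two flag instants per 2-s
epoch, per-epoch TIR collapses onto nine lattice values, duplicate PI
points get silhouette 1 by construction, and the class-count selection
drifts to the top of its range; at eight instants per epoch the silhouette
curve over pooled sessions peaks at small k, with k = 4 — the four NOS
workload levels — a recurring maximum (global or local depending on the
session draws, since the two hardest conditions sometimes separate).  The
multi-modal curve mirrors what is reported for the real performance data,
where several class counts are defensible.

**What passing tests show.** On this generator the full pipeline recovers
the class structure (a Nesterov-trained CNN3 exceeds 90% test accuracy at a
3× gap) and rank-weighted ensembles are at least as accurate as their
average member in ≥ 90% of seeded repetitions. These are statements about
the pipeline's correctness and the qualitative ensemble effect — not
reproductions of the accuracies reported on the private recordings, since
the synthetic class signal has no claim to matching the real effect size,
channel covariance, artifacts or non-stationarity of operator EEG.

## Problem sizes and numerical choices

Tests and the acceptance script run reduced problem sizes chosen to keep a
single-CPU run comfortable while leaving the statistics clear: synthetic
classification uses 60-s conditions (25 epochs per condition, 500 epochs
over two sessions) and 150 training epochs for the single-model check, 60
for the five-member ensemble; epoch-count and class-size checks use
full-length 300-s sessions. Posterior rows sum to 1 within 1e−6; ensemble
weights within 1e−12. Degenerate inputs fail loudly: constant series for
clustering, conditions too short for one window, bands without bins,
non-finite losses (with the offending training epoch named).

## Known limitations

* No artifact handling (blinks, EMG), re-referencing or channel
  interpolation — out of scope of the modeled pipeline.
* The channel montage is opaque: channels are anonymous labels, and no
  spatial structure is simulated or exploited.
* Adadelta's insensitivity to the learning-rate setting and the fixed
  1e−4 rates of the other optimizers are kept as given; no learning-rate
  schedules or early stopping.
* The stacking meta-table uses hard member labels (one-hot encoded for the
  meta-model); feeding full posteriors is a straightforward extension but
  changes the documented n × K table shape.
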