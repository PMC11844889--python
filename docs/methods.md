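# Methods

`spontlfp` implements an analysis for detecting a latent behavioural
context — social grooming touch versus computer-controlled airflow —
from *spontaneous* local field potentials (LFP) recorded between
stimuli, together with the accompanying autonomic (heart-rate /
respiratory sinus arrhythmia) analysis. Because the recordings the
analysis was designed for are not publicly deposited, the package ships
a first-class synthetic-session generator with known ground truth; all
statistical claims verified by the test suite are claims about recovery
of that ground truth.

## Experimental design being modelled

A session alternates blocks of two tactile modalities applied to the
face: airflow (sequences of 11 one-second presentations at rigid 4 s
offset-to-onset gaps, repeated 10× for 110 presentations per block) and
grooming touch (20 presentations at ~4 s jittered gaps, repeated 5× for
100 per block), with a quiet gap of a few minutes (default 120 s)
between blocks. The premise is that context is a *block-long latent
state*: its signature persists in the inter-stimulus intervals, not
only peri-stimulus.

Spacing convention: "separated by 4 s" is read as offset-to-onset
(onset-to-onset = 4 s + stimulus duration); an onset-to-onset
interpretation is available via `spacing_convention="onset"`. Touch
jitter is uniform ±0.75 s, truncated by construction so every
inter-stimulus interval still admits the analysis window plus buffers.

## Synthetic sessions

Each channel is built as

* unit-variance 1/f^β background noise (β = 1 by default, amplitude
  profile flattened below 0.5 Hz to keep variance finite), mixed from a
  within-nucleus shared process and a private process with variance
  fractions `shared_fraction` / `1 − shared_fraction` (default 0.5);
* a context gain: the band content of the signal (default 10–25 Hz,
  extracted with a zero-phase FFT mask whose cosine transitions lie
  entirely *outside* the band) is multiplied by `sqrt(power_ratio)`
  throughout touch blocks, so the measured band-power ratio between
  contexts equals `power_ratio` by construction (default 1.5);
* stimulus-evoked transients: a deterministic damped 10 Hz onset
  response (150 ms) plus a post-offset rebound with per-trial random
  amplitude decaying ~400 ms into the inter-stimulus interval. The
  transient shape is arbitrary; it exists so that stable-window
  selection is a non-trivial operation.

The sampling rate defaults to 1000 Hz — standard for LFP and
comfortably above Nyquist for the 1–50 Hz analysis grid. One integer
master seed drives a fixed `SeedSequence` hierarchy (protocol, LFP
noise, evoked transients, spikes, heartbeats), so identical seed and
configuration give byte-identical sessions.

Heartbeat series follow inter-beat intervals
`ibi0 (1 + d(t) sin 2π f_resp t)` with `ibi0 = 60 / HR`; the modulation
depth `d` is context-dependent in `simulate_context_ibi` (default 0.1
in touch, 0 in airflow, plus 2% white beat-to-beat jitter emulating the
broadband variability real heart rate always carries — without it,
zero-depth blocks would have an exactly constant heart rate and a
degenerate spectrum). Optional artifact beats violate the 250–1500 ms
physiological limits and must be removed by the cleaning stage.
Optional spike trains are inhomogeneous Poisson processes (thinning)
whose intensity may be modulated by the Hilbert phase of a chosen LFP
band.

What the generator does **not** emulate: biophysical LFP generation,
volume conduction, referencing artifacts, line noise, non-stationary
background statistics, electrode drift, and any nucleus-specific
physiology (all nuclei receive statistically identical signals). A
passing recovery test therefore shows the *pipeline* is correct and
calibrated, not that real LFP is this easy to decode.

## Stable-window selection

Inter-stimulus segments run from 200 ms after one stimulus' offset to
200 ms before the next onset of the *same* type within one block (no
segment before a block's first stimulus; none across block gaps). The
original selection of a "stable" window was done by visual inspection
of trial-averaged traces; we formalize it: segments of one label are
aligned on their start, truncated to the shortest survivor, the
across-trial standard deviation is computed per timepoint and channel,
normalized per channel by its own mean (making the criterion invariant
to channel amplitude rescaling), averaged over channels, and the window
offset on a 10 ms grid minimizing the windowed mean of that aggregate
is applied to every trial of the label. Ties break to the earliest
offset. One offset per label per session is used (the alternative —
per block — is not distinguishable from the published description).
Window length is 500 ms, with an automatic session-wide fallback to
400 ms when a label has no admissible segment.

## Time–frequency representation

Single-trial spectrograms are the magnitude of the continuous wavelet
transform x̂(f,t) = (1/a)∫x(τ) ψ̄((τ−t)/a) dτ with the complex Morlet
ψ(t) = (π f_b)^(−1/2) exp(−t²/f_b) exp(2πj f_c t), evaluated on a
1–50 Hz grid at 1 Hz steps (the step is a convention; only the range
is prescribed). The dimensionless central frequency defaults to
f₀ = 5 in the standard radian convention, i.e. f_c = f₀/2π, with
bandwidth f_b = 2(f₀/2π)² (≈ f₀ cycles under the Gaussian envelope).
Two frequency→scale rules are implemented: the conventional
central-frequency rule a = f_c·Fs/f (default; places the wavelet's
spectral peak exactly at the grid frequency, consistent with using a
standard Morlet routine at central frequency 5) and the fixed rule
a = 2Fs/f behind `scale_rule="printed"`; the two are mutually
inconsistent in the source material, and the rule in force is recorded
in every spectrogram's metadata. Wavelets are sampled analytically,
truncated at ±5 envelope standard deviations, and applied by FFT
convolution — which is *exactly* the direct discrete convolution up to
floating-point error, and is verified against an independent O(N²)
direct-sum oracle at 1e-8 relative tolerance. No padding is applied
and the cone of influence is not masked. Magnitude (not power) images
feed the classifiers; a power option exists.

For classifier input, spectrogram columns are block-averaged in groups
of `time_decim` samples (default 25 → 40 Hz image time resolution;
the acceptance computations use 50 → 20 Hz). This is a dimensionality
choice for CPU-scale training; the underlying transform is always
computed at full resolution.

Spike-triggered averages use only spikes whose full ±80 ms
neighbourhood lies inside a spontaneous window; the mean STA per
context is averaged over units, its periodogram is compared between
contexts, and contiguous frequency runs of largest integrated absolute
difference are reported as candidate discriminative bands (a
formalization of what was originally a visual choice).

## Decoding

Spectrograms from all channels of one nucleus in one session form one
dataset. The minority class is bootstrapped (resampled with
replacement) to match the majority; an 80-10-10
train/validation/test split preserves equal class counts in every
split; per-feature min–max scaling is fit on the training split only.

The CNN follows the published architecture exactly: Conv 3×3 → ReLU →
BatchNorm → Conv 3×3 → ReLU → MaxPool 2×2 (stride 1, as printed —
a conventional stride-2 option exists) → BatchNorm → Flatten → FC 64 →
Dropout → FC 2, with 24 and 48 feature maps, valid (unpadded)
stride-1 convolutions. Unstated hyperparameters: dropout 0.5, Adam at
lr 1e-3 with default moments, uniform fan-in initialization
U(±1/√fan_in) reseeded per repetition. Training: cross-entropy,
batches of 20, 40 epochs, and the parameter snapshot with the lowest
validation loss is kept. The engine is a compact numpy implementation
(im2col convolutions over BLAS, float32) with analytically verified
gradients; it exists because the pipeline is deliberately CPU-scale.

The SVM operates on flattened scaled images: RBF kernel (dual
formulation via scikit-learn's SVC), C = 1, kernel width by the
variance-scale rule (`gamma="scale"`); a linear kernel is available as
the negative control. The train/evaluate cycle is repeated (default
50×) with fresh splits and initializations; accuracies are summarized
by 10/50/90% quantiles, and AUROC is computed per repetition from the
touch-class score (softmax probability or decision function).

## Null model and cross-nucleus statistics

The significance reference is a shuffled-label bootstrap: per shuffle,
a fresh split is drawn, training *and* validation labels are permuted
(class counts preserved; whether validation labels were originally
shuffled is unstated — shuffling both is recorded in metadata), the
model is trained per protocol, and accuracy is evaluated on the
true-labelled test set. The default of 20 shuffles is a desk-scale
choice. Per-nucleus accuracy distributions are compared with the
tie-corrected Kruskal–Wallis H-test on per-repetition accuracies (a
per-session-median variant is possible by passing medians); the fully
degenerate all-tied case returns H = 0, p = 1 by convention. The
dependence of accuracy on electrode yield is summarized by a Spearman
rank correlation (the relation is monotone, not asserted linear).

## Autonomic analysis

Intervals outside 250–1500 ms (240–40 BPM) are removed from the
inter-beat tachogram; each removed entry takes its terminating beat
with it, so stored interval values are never re-differenced across
gaps. Instantaneous heart rate 60000/IBI is placed at each interval's
terminating beat and interpolated to a 1 ms grid with the modified
Akima cubic Hermite polynomial (`scipy`'s `makima`).

RSA strength uses sliding 60 s windows. "Overlap of 3 s" is read as
consecutive windows sharing 3 s (hop 57 s); the alternative 3 s hop is
available via `step_mode="step"`. The HR grid is decimated
(anti-aliased) to 4 Hz before spectral estimation — a 1 kHz grid is
wasteful for a 0.5 Hz band; the choice is recorded in the function
signature. Per window, a multitaper PSD is computed with 7 Slepian
tapers at half-bandwidth W = 0.07 Hz (time-bandwidth product
NW = 4.2 for 60 s windows, so k = 7 ≤ 2NW − 1): the tapers are the
symmetric discrete prolate spheroidal sequences (verified against a
dense eigen-solve of the sinc concentration kernel), and the
eigenspectra are Δt·|FFT(g_k ⊙ x)|², averaged over k. The squared
modulus is the standard definition of a periodogram; a printed variant
without the square is treated as a typographical slip. The PSD is
rescaled to unit area on 0.25–0.5 Hz (15–30 breaths/min); raw strength
P_rsa is the mean normalized power within ±W of the largest in-band
peak (local maximum with prominence above a small configurable floor,
default 0.1 normalized-density units; no criterion was published), or
the in-band mean when no peak exists. Normalized strength
P̃_rsa = (P_rsa − μ)/μ with μ the across-window median, so
median(P̃_rsa) = 0 exactly for odd window counts.

Context comparison is a *paired* one-sided t-test (grooming > airflow)
on per-session block means — paired because every session contains
both block types. Degenerate zero-variance differences are reported as
p = 0 (all favouring the alternative), p = 1 (all opposing), or
t = 0, p = 0.5 (all zero), with a warning.

## Problem sizes used by the test suite and acceptance script

The CNN protocol (40 epochs, batch 20, 50 repetitions) on full-size
sessions is a long-running computation; the shipped verification runs
use reduced problem sizes, chosen once as the package's desk scale:

* acceptance script: one default-protocol session (110 + 100 stimuli),
  two basal contacts, spectrogram time decimation 50, 10 CNN
  repetitions and a 20-shuffle null;
* the in-suite CNN check uses shortened blocks (55/60 stimuli);
* property tests use the cheap SVM decoder wherever the property being
  checked (balance, monotonicity, null behaviour, channel-count
  correlation) does not depend on the classifier family.

## Known limitations

* The numpy CNN engine is single-threaded CPU code; it matches the
  published architecture but not the training throughput of a GPU
  framework, which is why repetition counts are configurable.
* Bootstrap balancing duplicates minority-class images before the
  split, so duplicates of one image can appear in different splits;
  this mirrors the published procedure ("bootstrapping was used to
  sample the images so that there was an equal number ... then split")
  but mildly optimistic test estimates are possible on tiny datasets.
* The generator's context effect is exactly band-limited and
  stationary within blocks; real context signatures need not be either.
* Cross-session generalization of trained decoders is explicitly out
  of scope (decoders are session- and nucleus-specific).
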