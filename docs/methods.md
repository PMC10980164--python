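# Methods

This note documents the models, parameter defaults, numerical choices
and known limitations of the pipeline. Everything quantitative stated
here is computed by the test suite or by `scripts/acceptance.py`.

## Conventions

All timestamps are seconds from recording start. The scoring grid is
2.5 s epochs; epoch *i* covers the half-open interval [2.5 i, 2.5 (i+1)).
EEG/EMG amplitudes are µV. Spectrogram time stamps mark window *starts*,
so epoch *i*'s features are computed from the window [2.5 i, 2.5 i + 5):
the staged hypnogram is therefore one epoch shorter than the signal's
epoch count (the last epoch has no complete window).

## Scoring spectrogram

One PSD per half-overlapping 5 s window (2.5 s step). Within a window,
Welch's method averages Hann-tapered, half-overlapping 2 s segments
(0.5 Hz resolution, plain grid without zero-padding). Detrending removes
the segment mean only; signals are used unfiltered (no notch). Powers
are one-sided densities (µV²/Hz).

Band power integrates the density over a **closed** interval on the
frequency grid: the sum of bins with lo ≤ f ≤ hi times the 0.5 Hz bin
width, both edge bins included (band limits are stated inclusively). For
a flat 1 µV²/Hz spectrum this makes the δ (0.5–4 Hz) power 4.0 µV²
(8 bins × 0.5 Hz); a trapezoidal convention would give 3.5 µV². The
rectangular closed-interval rule is used everywhere.

## Staging

Features per epoch: δ, θ, σ(12–20 Hz) and γ EEG band powers, θ/δ ratio,
and EMG power over 50–500 Hz. Epochs with δ = 0 get ratio 0 (they can
never score as "high θ/δ"). Thresholds: the temporal mean, except EMG
power and θ/δ which use mean + 1 population (divide-by-n) SD — the
threshold describes the observed series, not a parent-distribution
estimate. "High" is strictly greater; ties are "low".

Rule precedence follows the order the rules are stated, with the
explicit REM carve-out for γ wake: REM → NREM → NREM(σ) → Wake(EMG) →
Wake(γ) → undefined. Undefined epochs carry the previous resolved state
forward; leading undefined epochs become Wake. The classifier is
deterministic and is verified exactly against an independent
plain-conditional evaluator on 10⁴ random feature vectors.

On synthetic recordings at the generator's default amplitudes the
classifier recovers ≥ 90 % of ground-truth epochs (measured ≈ 95–97 %);
residual errors sit at state transitions where the 5 s window straddles
two states. This recovery figure characterizes agreement on *synthetic*
data with idealized state-switched spectra; it does not certify accuracy
against manual scoring of real recordings.

## Architecture

Bouts are maximal runs of one state. A microarousal is a wake run with
duration ≤ 20 s **and** NREM immediately on both sides; wake runs at a
recording edge or flanked by REM do not count. Consolidated NREM bouts
bridge NREM runs across qualifying MAs and keep spans ≥ 120 s; the span
includes embedded MA time ("bouts … possibly interrupted by MAs" is read
as the bridged span). Any REM epoch or wake run > 20 s terminates a
span. MA wake time still counts toward wake occupancy percentages —
the accounting follows the classifier's labels. Episode frequency is
denominated per hour of recording; the MA rate additionally per hour of
NREM time.

Object-recognition metrics: preference % = T_novel/(T_fam+T_novel)×100,
discrimination = (T_novel−T_fam)/(T_fam+T_novel); sessions with total
exploration below 2 s are flagged excluded, and zero exploration leaves
the metrics NaN.

## Infraslow σ rhythm

The normalized spectrogram (each frequency row divided by its temporal
mean) is averaged over σ = 10.5–16 Hz. Note the deliberate band split:
staging uses σ = 12–20 Hz, the infraslow analysis 10.5–16 Hz, spindle
detection 10–16.67 Hz; all three are configurable and no reconciliation
is attempted.

Per consolidated bout the σ series is mean-removed, Hann-tapered and
transformed as a **single segment** (no Welch splitting): bouts barely
exceed the ~100 s needed to resolve 0.01 Hz, so segmentation would
destroy the resolution that the strength metric depends on. Bout PSDs
are linearly interpolated onto the grid of the longest bout and
averaged. Strength = trapezoidal area over 0.01–0.04 Hz minus area over
0.08–0.12 Hz (with range endpoints interpolated onto the grid; the
metric is linear in the density — note the two ranges have unequal
widths, 0.03 vs 0.04 Hz, so equal *density* yields a slightly negative
strength). Peak frequency is the argmax in a search range (default
0.005–0.12 Hz); ties resolve to the lowest frequency.

Recovery: on sessions with a single long consolidated bout the full
pipeline recovers modulation frequencies 0.015/0.02/0.03 Hz within one
grid step, strength grows monotonically with modulation depth, and
moving the modulation to 0.10 Hz flips the strength's sign.

## Spindle detection

Detector defaults (treated as the method's optimized operating point):
600 ms windows every 100 ms (Hann taper — taper choice is ours), σ band
10–16.67 Hz, 96th-percentile σ-peak threshold, σ-peak > 0.5 × the
0–10 Hz peak, fuse gaps < 300 ms, discard durations ≤ 200 ms, and ≥ half
of an event's bins must peak in-band. "Peak" is the maximum of the bin's
spectrum restricted to the band; duration counts bins × 100 ms with
fused gaps included. When a hypnogram is supplied, detection *and* the
percentile threshold are computed over NREM bins only, which keeps the
threshold meaningful for the bins actually scanned.

A calibration utility (`grid_search_params`) scores parameter grids by
F1 against ground-truth events; it replaces calibration against manual
annotations, whose objective function is not available to us.

The detection benchmark injects Hann-windowed 12 Hz bursts (500–800 ms)
into pink noise with burst σ-band RMS = 3 × the background's σ-band RMS.
The benchmark's default burst rate is 5/min: the fixed 96th-percentile
rule unconditionally flags the top 4 % of bins, so precision ≥ 0.9 is
attainable only when true burst bins occupy at least roughly that share
of the scanned signal — at 5/min (~5 % occupancy) the detector scores
precision and recall ≥ 0.9 at 300 ms matching tolerance.

## Photometry

ΔF/F: both channels are decimated to 100 Hz when acquired faster (the
1/15 Hz Butterworth is numerically ill-conditioned at 1.5 kHz), low-pass
filtered at 2 Hz with a 4th-order zero-phase (forward–backward)
Butterworth — zero-phase is applied to *both* filters for phase
consistency, though stated only for the slow one — then the 405 nm
channel is fitted to the 465 nm channel by least squares (slope +
intercept) and ΔF/F = (F465 − fit)/fit. A constant reference or a
non-positive fitted baseline raises an error. When the two channels are
exactly affinely related the output is identically zero.

Transients: local maxima of the 1/15 Hz zero-phase-filtered ΔF/F with
topographic prominence ≥ 0.05 × (p99 − p1) of the *filtered* signal
(the percentile scale on the filtered signal makes the detector exactly
invariant under positive affine rescaling). With a hypnogram, only peaks
during NREM or inside MAs are kept — matching the convention of counting
transients during NREM sleep; without one, all peaks are returned.
Transient–MA overlap uses a ±10 s window around each MA (window
configurable; transients live on a ~15 s timescale, and no narrower
printed value exists).

A known limitation of the single global affine fit: motion common to
both channels is removed exactly only on a flat baseline. Riding on a
decaying (bleaching) baseline, the product motion × bleach cannot be
captured by one slope, and a fraction of the motion leaks into ΔF/F.
Time-varying (e.g. piecewise) fits would fix this and are out of scope.

## Sound-evoked arousal

A tone trial is eligible iff the animal is in NREM at onset and the
MA-bridged NREM time **preceding the onset** exceeds 120 s (the quantity
causally available at stimulus time). Whether the criterion should
instead use the whole episode's length is ambiguous; both modes exist
behind the `eligibility` flag (`"pre_onset"` default, `"episode"`
alternative). Outcome: *arousal* iff any wake epoch overlaps
[onset, onset + 20 s) — no latency criterion is applied. Pre-tone σ
traces are aligned on the 2.5 s grid over [−60 s, 0], NaN-padded at
recording edges, and averaged per class with per-timepoint counts. The
summary slope is fitted over the final 20 s before onset, where the
phase-conditioned σ trace is monotone on average.

## Synthetic-data generator

The generator defines the study conditions for every recovery test.

*Hypnogram*: semi-Markov chain Wake → NREM → {REM (p = 0.25) | Wake},
REM → Wake; exponential dwells with means W 120 s, N 300 s, R 60 s,
rounded up to whole epochs. Spontaneous wake dwells are floored at 25 s
so that *every* wake run ≤ 20 s flanked by NREM is an injected,
ground-truth-recorded MA (default 1 per NREM minute, durations 2.5–20 s,
placed interior to NREM runs). 24 h occupancies match the embedded
chain's analytic stationary fractions (with the epoch-rounding and
floor corrections) within 5 percentage points.

*EEG/EMG*: sums of band-limited Gaussian noise (δ 0.5–4, θ 5–12,
σ 10.5–16, γ 100–150 Hz, plus broadband) with state-switched RMS
amplitudes — δ-dominant NREM (60 µV), θ-dominant REM (50 µV),
broadband + γ wake — and EMG as > 50 Hz noise with state-dependent RMS
(W 40 ≫ N 8 ≥ R 5 µV). The NREM σ component is amplitude-modulated at
the infraslow frequency (default 0.02 Hz, depth 0.4). Spindles are
Hann-windowed 12 Hz bursts (500–800 ms, 90 µV peak, 3/min of NREM) with
recorded times. What this emulates — and what it does not: spectra are
stationary within a state, transitions are instantaneous, and there are
no artifacts, electrode drift or true 1/f structure in the staging
bands; passing recovery tests therefore demonstrates the pipeline's
correctness on data satisfying its assumptions, not performance on real
recordings.

*Photometry*: 465 nm = baseline × exp(−t/τ) × (1 + state offset +
transient kernels + motion) + noise; 405 nm shares bleaching and motion
but carries no calcium activity. State offsets (W 0.15, N 0.05, R 0)
are Gaussian-smoothed (σ 5 s) to emulate indicator kinetics —
instantaneous steps would ring through the 1/15 Hz detection filter.
MA epochs keep the NREM offset: the calcium surge at an MA is modelled
once, by the transient kernel coupled to the MA onset
(p = 0.5 by default), not a second time via the wake offset. Transient
kernels are Gaussians with σ 6 s (width of order the 15 s detection
timescale; much narrower bumps leave filter sidelobes near the 5 %
prominence threshold), amplitude 0.1 ΔF/F, minimum separation 20 s
(closer candidates are dropped *before* entering the ground truth).
Shared motion defaults to 0.002 RMS — the animal is asleep, and (see the
photometry limitation above) a global affine fit cannot remove motion on
a decaying baseline, so the generator treats large motion as outside the
method's operating regime. Bleaching τ defaults to 7200 s.

*Tones*: i.i.d. uniform gaps in [240 s, 1200 s] (4–20 min). The
arousal-coupling mode wakes the animal after a tone in NREM with a
probability depending on the sign of the σ-modulation derivative at
onset (defaults 0.9 descending / 0.1 ascending; a phase-independent mode
uses a flat probability). Inserted awakenings start 5 s after onset and
last > 20 s so they score as wake bouts, not MAs.

All generators are deterministic given a seed, and every recovery test
consumes only generator outputs.

## Problem sizes

Recovery experiments run at desk scale, chosen to keep the full suite
fast while leaving comfortable statistical margins: staging recovery on
five 1 h sessions; infraslow recovery on 30 min near-continuous NREM
sessions; spindle benchmark on five 10 min signals; photometry recovery
pooled over twenty 20 min sessions; arousal analyses on 6–12 h
hypnograms (EEG synthesized for the 6 h phase-signature run).
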