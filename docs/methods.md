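# Methods

## Scope

`neurocx` reimplements a resting-EEG nonlinear-complexity analysis as a
reusable pipeline: per-epoch Higuchi fractal dimension (HFD) and sample
entropy (SampEn), spectral band power, group-level ANOVA with
Bonferroni post hoc (globally and per electrode), and PCA separability
of the feature ensemble. Because no clinical recordings ship with the
package, a synthetic cohort generator with controllable ground-truth
complexity stands in for patient data; every downstream stage is
validated against it.

## Synthetic signal model

Each channel is

    x(t) = noise_scale · P_H(t) + alpha_amp · sin(2π f_α t)

where `P_H` is a standardized fractional-Brownian-motion trace with
Hurst exponent `H ∈ (0, 1)` and `f_α` defaults to 10 Hz.

The trace is built in two steps. `generate_fgn` draws exact
fractional Gaussian noise (fGn) by circulant embedding (Davies–Harte):
realisations have the theoretical autocovariance
`γ(k) = ½(|k+1|^{2H} − 2|k|^{2H} + |k−1|^{2H})` exactly, which the test
suite checks through the lag-1 autocorrelation `2^{2H−1} − 1` and a
variance bound computed from `γ`. `generate_fractal_path` then
integrates (cumulative sum) and standardizes. The distinction matters:
the *increments* (fGn) are noise-like and their Higuchi dimension is
near 2 for every `H`, while the *integrated trace* has graph fractal
dimension exactly `2 − H`. All fractal-dimension ground truth in this
package therefore refers to the trace, and the recovery tests confirm
the Higuchi estimator reproduces `2 − H` within ±0.01 at `N = 5000`
for `H ∈ {0.3, 0.5, 0.8}`.

Channels are independent realisations (no spatial correlation model, no
blink/EMG artifacts, no volume conduction); per-channel seeds derive
deterministically from `SeedSequence(entropy=cohort_seed,
spawn_key=(subject_index, channel_index))`, so cohorts are bit-identical
across platforms. Amplitudes are dimensionless; the microvolt scale of
real EEG is a labelling convention.

### Calibration of the default cohort

The default three-group cohort (20/11/11 subjects, 19-channel 10–20
montage, 1 kHz, 180 s) uses Hurst exponents

    H_C = 0.936, H_E = 0.834, H_R = 0.770,

i.e. `H = 2 − FD` for target group mean HFD ≈ 1.064 / 1.166 / 1.230 —
the published group means the cohort emulates. A calibration run with
the package's own estimator confirms per-epoch means within ~0.005 of
the targets. SampEn then orders the groups the same way
(≈ 0.005 / 0.011 / 0.018 per epoch) but its magnitudes are far below
the published 0.21 / 0.48 / 0.56: a single smooth fractal trace cannot
match both measures at once, because real EEG carries broadband
irregularity this model deliberately omits. Passing recovery tests
therefore demonstrate that the pipeline detects and orders group
complexity differences of realistic HFD size — not that the generator
reproduces every statistical property of clinical EEG.

The alpha sinusoid defaults to amplitude 0 in the calibrated cohort.
At 1 kHz the millisecond-scale increments of a smooth standardized
trace are tiny (≈ n^{−H}), so a sinusoid of any visible amplitude
dominates the small scales probed by the Higuchi delays `k = 1..8` and
pins HFD near 1 regardless of `H`. Spectral-stage experiments set
`alpha_amp > 0` explicitly (the band-power tests use group-specific
alpha amplitudes on an `H = 0.5` background).

## Preprocessing

Epochs are half-open windows `[offset, offset + 5000)` at offsets
25,000 / 85,000 / 145,000 samples — three 5-s epochs per channel of a
3-min, 1 kHz recording; the half-open convention makes "samples
25,000–30,000" exactly 5,000 samples. Extraction is pure slicing, so
epochs reproduce the source samples bit-for-bit.

A 4th-order Butterworth 0.5–70 Hz band-pass applied forward–backward
(zero phase, reflect padding of about three f_lo time constants) is
available, but the pipeline computes complexity on the unfiltered
signal by default. Two reasons: the acquisition passband of the
emulated protocol is a hardware property the generator already
represents, and — decisive for synthetic data — a 70 Hz low-pass at
1 kHz smooths exactly the 1–8 ms scales the Higuchi regression probes,
driving every HFD to ≈ 1.005 and erasing the ground-truth ordering.
The `--band/--no-filter` options expose both paths. Note also that the
0.5 Hz corner rings for a few seconds at record edges; the default
epoch offsets start 25 s into the recording, well clear of the
transient.

Ocular-artifact removal by ICA is delegated to existing tooling (e.g.
mne) and not reimplemented; a peak-amplitude rejection hook
(`reject_epochs`) provides a simple, fully tested kept/rejected
partition for synthetic spikes.

## Complexity measures

**HFD** follows the original curve-length construction: 1-based offsets
`m = 1..k`, floor normalisation `(N−1)/(⌊(N−m)/k⌋·k)`, `L(k)` the mean
over offsets, and an unweighted natural-log OLS slope over
`k = 1..k_max` with `k_max = 8`. A linear ramp gives exactly 1
(`L(k) = (N−1)/k`); a constant signal has zero curve length and is
flagged undefined rather than fabricated.

**SampEn** uses the Richman–Moorman conventions: Chebyshev distance,
closed tolerance (`≤ r`), both match counts over the same `N − m`
template start positions, unordered pairs `i < j` (self-matches
excluded), and `r = 0.15 ×` the epoch's population SD. `A = 0` or
`B = 0` is reported as undefined and excluded listwise downstream with
a logged count; a constant signal yields `r = 0` with all templates
matching, hence SampEn 0. The compiled inner loop (numba) evaluates a
5,000-sample epoch in ~50 ms, so a full cohort finishes in minutes; an
`O(N²)` enumeration oracle in the test suite checks exact count
equality on random signals.

Two analytic anchors validate the estimators beyond hand-worked
examples: white Gaussian noise has Higuchi dimension 2.0, and iid
Gaussian SampEn converges to `−ln(2Φ(0.15/√2) − 1) ≈ 2.47`.

## Spectral band power

Welch PSD with 2-s Hann windows, 50% overlap, constant detrend;
band power integrates the PSD over half-open bands `[f_lo, f_hi)`
(defaults: low-alpha 8–10, high-alpha 10–12, beta 13–30 Hz). The 2-s
window (0.5 Hz resolution) keeps the Hann main lobe of an on-bin alpha
tone inside a 2-Hz band; with 1-s windows, one sixth of a 9 Hz tone's
power leaks into the neighbouring band. Band powers over a partition
of the axis sum to the total Welch power (Parseval check within 1%).

## Statistics

Values are log10-normalised (non-positive values are rejected by name,
so undefined/zero SampEn epochs must be excluded upstream, which the
ensemble builder does). The KS normality check is one-sample against a
normal with sample-estimated moments (a Lilliefors-style plug-in whose
p-value is approximate; fixed-reference mode is available). One-way
ANOVA is the standard between/within-F; post hoc comparisons are
pooled-variance two-sample t-tests with p multiplied by `C(groups, 2)`
and capped at 1; α defaults to 0.05.

The analysis ensemble treats every (subject, epoch, channel) value as
an observation — a documented simplification that mirrors the emulated
design (its global df of (2, 123) implies 126 electrode-averaged
units; `aggregate="channels"` reproduces exactly that unit structure,
`aggregate="none"` is the default). Per-electrode ANOVA repeats the
chain independently per channel and reports the channels significant
for *all* pairwise contrasts.

PCA mean-centres the observations × variables matrix (observations =
subject × epoch, variables = channel × measure), eigendecomposes the
sample covariance, and reports top-3 loadings, scores and the explained
variance ratio `(λ₁+λ₂+λ₃)/Σλ` over all original variables. Rank-
deficient input returns the available components with a flag. Group
separation in score space is quantified by the ratio of between-group
to pooled within-group scatter (trace form); values above 1 indicate
visible separation.

## Problem sizes in the validation suite

The recovery study in the test suite uses ten replicate cohorts of
5/3/3 subjects, 19 channels, 30 s at 1 kHz with epochs at
5,000/15,000/25,000 — the same epoch length, estimator settings and
calibrated effect sizes as the full-scale protocol, at a cohort size
chosen to keep the whole suite fast on one CPU. Recovery (ordering,
all pairwise Bonferroni significances, PCA scatter ratio > 1) is
required in at least 9 of 10 replicates. Monte-Carlo anchors use 20
seeds at N = 5,000; the null FWER check uses 1,000 replicates.

## Known limitations

- The generator produces smooth fractal traces, not broadband EEG: no
  1/f band-shaping beyond the fBm spectrum, no artifacts, no spatial
  correlation, and SampEn magnitudes well below clinical values (see
  Calibration).
- Epochs of a subject enter the ensemble as independent observations;
  with strongly correlated epochs the nominal p-values are optimistic.
- The Lilliefors caveat above applies to the KS p-value.
- EDF/EDF+ files are read (via mne) but not written; the synthetic
  writer emits the plain CSV dialect.
- HFD of heavily low-pass-filtered signals saturates near 1 at high
  sampling rates; choose `k_max` (or decimate) so the probed scales
  carry signal structure.
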