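# Methods

This note records the models, conventions and defaults behind `neurogait`,
the reasoning where a choice was genuinely open, and what the synthetic
benchmark does and does not establish.

## Signal model and conventions

A *trial* is a `channels × samples` matrix in microvolts at 500 Hz with
gait `start`/`stop` event marks (seconds from the first sample; the marks
stand for the instant an inertial motion-capture reference flags movement
onset/offset).  Sample `k` covers the half-open interval `[k/fs, (k+1)/fs)`,
so epoch slicing is unambiguous: a 1-s epoch starting at `t` holds samples
`round(t·fs) … round(t·fs)+499`.

Frequency bands are half-open, `lo ≤ f < hi`, so the adjacent analysis
bands 8–13, 13–32 and 32–50 Hz never double-count a shared edge.

## Electrode geometry and the surface Laplacian

The Laplacian weight of electrode `j` on `i` is `(1/d_ij)/Σ_k≠i(1/d_ik)`
with `d_ij` the 3-D chord distance on a unit sphere.  The filter runs over
the **full 31-channel montage** before any subsetting — the subtraction is
meant to see every recorded neighbour — and only then are the nine
analysis electrodes kept.

The montage geometry is not part of the protocol's public record, so the
bundled table (`data/electrodes_1010.tsv`) is an explicit modelling
choice: the standard 10/05 template positions shipped with MNE-Python,
least-squares sphere-fitted, projected to the unit sphere and rotated so
Cz is exactly the vertex.  Only relative distances enter the weights, and
those are insensitive to overall head scale; they would change somewhat
with digitized per-subject positions, which nobody has for this data.

## High-pass filtering

The FFT path removes drift with a 4th-order 0.2 Hz Butterworth high-pass.
It is applied **zero-phase** (forward–backward) and **per trial**, not per
epoch: the epochs overlap by 80%, and per-epoch filtering would smear
0.2 Hz edge transients into every feature.  Whether the original analysis
filtered causally or zero-phase is unknowable from its description; for
buffered offline/pseudo-online replay, zero-phase avoids group-delay
misalignment between signal and event labels, which we judged the greater
evil.  A practical numerical point: a 0.2 Hz filter settles over seconds,
so the implementation extends `sosfiltfilt` padding to `3·fs/cutoff`
samples; tests treat the outer ~4 s of a signal as edge region.  The
Hilbert–Huang and Stockwell paths skip the filter entirely — they operate
on instantaneous amplitude, which DC does not disturb (the DC voice/bin is
excluded from their spectra).

## Analysis windows

For event time `e` (seconds):

| protocol | active (state 1) | non-active (state 0) |
|---|---|---|
| offline | `[e−4, e]` | `[e−8.5, e−4.5]` (matched 4 s) |
| pseudo-online | `[e−2, e+2]` | whole preceding phase → `e−2.5` |

A 0.5-s guard gap always separates the non-active end from the active
start.  The preceding phase is rest for the start model and gait for the
stop model; its onset is the previous opposite-kind event (or the trial
start).  Events whose windows would cross a trial boundary are dropped and
counted — epochs are never truncated, because the classifier consumes a
fixed 500-sample input.  A 4-s window yields exactly 16 epochs at the
0.2-s hop.

The offline active placement at `[e−4, e]` covers the pre-movement
intention period: it is the span the pseudo-online analysis interrogates,
consolidated into one window.

## FFT band features

"Harmonic content" is implemented as one-sided band power: for bin `k`,
`(2/N²)|X_k|²` (DC and Nyquist not doubled), summed over the band.  A
unit-amplitude sinusoid thus contributes its mean-square power 0.5 µV²,
and the bins sum to the epoch's mean square (Parseval, tested at 1e-9).
No taper is applied; with 1-s epochs the bins fall on integer frequencies
and the band edges align with bin boundaries.  A `peak` mode (largest
single bin) exists for parity experiments with the peak-picking of the
other two methods.

## Empirical Mode Decomposition and the Hilbert spectrum

Sifting uses natural cubic-spline envelopes through local maxima/minima,
with the two extrema nearest each edge mirrored across the boundary before
fitting (standard end-effect mitigation; the method's description is
silent on boundaries).  The stopping rule is the Rilling amplitude
criterion — `σ(t) = |m(t)|/a(t)` with `m` the envelope mean and `a` the
envelope half-range; accept when `σ < θ1` on ≥ 95% of samples and
`σ < θ2` everywhere — **and** the IMF count condition (extrema vs
zero-crossings differing by ≤1), both held for 3 consecutive sifting
passes to avoid accidental modes.  Defaults `θ1 = 0.05`, `θ2 = 0.5`,
`α = 0.05` are the values in common use for this criterion; safety caps
are 10 IMFs and 100 sifts per IMF.  Completeness (ΣIMF + residue = input)
holds to float round-off by construction and is asserted at 1e-9.

Each IMF's analytic signal gives amplitude `a(t)` and instantaneous
frequency `ω(t)/2π` (unwrapped phase differentiated by central
differences).  The Hilbert spectrum deposits `a²(t)` into 1-Hz bins
centred on integer frequencies over (0, 250] — the same resolution as the
1-s FFT, deliberately, so the three feature paths are comparable.  Samples
with non-positive instantaneous frequency (a known phase artifact of
riding waves) are dropped and counted rather than clamped.  The marginal
spectrum integrates over the 1-s epoch by the rectangle rule; note its
total is the *analytic-signal* energy (squared envelope), i.e. twice the
mean-square signal energy for a tone.

## Stockwell transform

The voice at DFT bin `n > 0` is computed in the spectral domain:
`ifft_m( X[m+n] · exp(−2π²m²/n²) )`, `X` the input DFT and `m` the signed
bin offset; the `n = 0` voice is the signal mean.  This corresponds to the
Gaussian-window normalization `|f|/√(2π)` — the only normalization under
which the voices collapse over time to the Fourier spectrum
(`Σ_τ S(τ,f) = X(f)`, asserted at 1e-6), which is the transform's defining
property.  Voices are computed at every DFT bin up to the highest band
edge (no decimation; 1-s epochs are cheap), and squared voice amplitude
feeds the same marginal-spectrum/peak feature recipe as the HHT path.

The frequency-scaled window means frequency resolution degrades as `f`
grows: a 10 Hz tone leaks `exp(−2π²·3²/13²) ≈ 0.35` of its amplitude into
the 13 Hz voice, so an alpha tone's beta feature can reach ~1/8 of its
alpha feature.  This is inherent to the transform, harmless for
classification (features shift consistently), and pinned down in tests.

## Classifier

An RBF-kernel SVM on the 27-value feature vector.  Unstated
hyperparameters default to `C = 1`, `gamma = 'scale'`; class weights are
balanced because pseudo-online non-active spans contribute several times
more epochs than the 4-s active windows.  Standardization statistics are
fitted on the training folds only (no leakage); zero-variance features
are dropped and the count recorded in the model metadata.

## Detection and indices

"More than five consecutive" hits/misses is implemented as runs of
length ≥ 5: five consecutive 0.2-s decisions span 1 s, exactly the
pseudo-online single-FP duration of 1/60 min used in
`FPR = FP/min × duration`.  One maximal miss-run counts one false
activation regardless of its length — a sustained spurious command
triggers a device once (`floor_div` counting is available as a config
alternative).  Offline, a non-active window can contribute at most one
false positive (majority rule in a fixed 4-s window) and the FP duration
is 4/60 min.

`Acc` is undefined (not zero) when a trial produces no detections at all;
undefined entries are excluded and counted when averaging across trials.
This matters: setting them to 0 or 100 would bias across-trial means in
opposite directions, and excluding them keeps the mean WD interpretable as
"WD of the trials that produced any decision".  Reported indices are
rounded to two decimals, half away from zero.

## Synthetic benchmark

The generator's defaults are the study conditions of the package's own
validation: 4 cycles per trial; rest and gait phases 11 ± 1 s (uniform
jitter) — long enough to host the offline `[e−8.5, e]` windows with
margin; 1/f background (exponent 1, 8 µV RMS); narrow-band oscillators at
10, 22 and 40 Hz with 16, 12 and 8 µV RMS at Cz, ±2 Hz bandwidth, and
Gaussian spatial falloff (σ = 1.0 unit-sphere distance) mimicking the
sensorimotor focus; ERD depth 0.8.  The modulation gate spans
`[e−4, e+2]` (lead 4 s, duration 6 s, 0.2-s raised-cosine edges): the
pre-movement desynchronization is modelled as building through the whole
intention period both protocols interrogate and persisting 2 s past
onset.  Start events desynchronize (×(1−depth)), stop events rebound
(×(1+depth)); both are configurable.

What passing the end-to-end test shows: the chain recovers a known
band-power modulation from realistic noise levels (per-band SNR ≈ 0.5–2
on the analysis ring) and stays at chance (|mean WD| ≤ 0.25 over seeds)
when the modulation is absent — i.e. the pipeline's signal path, labels
and scoring are wired correctly and do not hallucinate structure.  What it
does **not** show: performance on real EEG.  The generator has no
volume-conduction correlations between channels, no ocular/muscular/cable
artifacts (walking EEG is notoriously artifact-laden), no gait-cycle
kinematic rhythmicity, and its modulation timing is exact where real
intention timing jitters relative to movement onset.  Real-data WD will be
substantially below the synthetic ceiling.

Problem sizes in the shipped tests were chosen to exercise every code
path at meaningful statistical power while staying light: the effect-run
uses 10 trials × 9 channels, the null check 10 seeds × 4 trials, both
through the Stockwell path (the fastest of the three and the package's
centrepiece).

## Degenerate inputs and numerical guards

Coincident electrodes (zero distance) raise a geometry error; trials too
short for the filter raise rather than return garbage; EMD of a monotone
signal returns zero IMFs with the input as residue; an epoch whose
decomposition yields no IMFs reports zero features; empty detection
windows contribute nothing and are counted; zero non-active time makes
FP/min an error, not infinity.  All randomness flows through
`numpy.random.Generator` objects seeded from a single configuration seed,
and reruns are byte-identical.

## Known limitations

* The EMD is the classic single-realization algorithm; on noisy epochs
  mode mixing is expected (it is part of the method being studied, and
  the reason the Hilbert path is the least stable of the three).
* The pseudo-online replay processes pre-recorded buffers; it reproduces
  the decision logic of a live system but not its latency or drift.
* The Stockwell voice phase is computed but unused by the features, which
  rely on squared amplitude only.
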