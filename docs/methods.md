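# Methods

## Pipeline

The analysis chain, in execution order:

1. **High-pass, 50 Hz.** 4th-order Butterworth applied forward–backward
   (`scipy.signal.sosfiltfilt`). Zero-phase filtering is mandatory here:
   burst phase is the measured quantity, and a causal filter would add a
   frequency-dependent phase shift to the envelopes.
2. **Stimulus-artifact blanking.** Samples in a window around each stimulus
   time (default 2 ms before to 8 ms after) are replaced by linear
   interpolation between the boundary samples; overlapping windows are
   merged, windows at the record edge are clipped. Linear interpolation is
   the simplest scheme that leaves no spectral signature at the stimulus
   rate; the artifact's exact shape is irrelevant once it is removed.
3. **Rectification.** Half-wave by default (negative samples zeroed);
   full-wave available.
4. **Envelope.** 4th-order zero-phase Butterworth low-pass at 5 Hz, then
   polyphase resampling to 50 Hz. The 5 Hz filter recovers the envelope of
   multi-unit spiking and doubles as the anti-alias filter for the
   decimation. Filter undershoot below zero is clipped at 0. The
   `Envelope` type is terminal: feeding it back into the preprocessing
   chain raises, rather than silently re-filtering integrated data.
5. **Morlet CWT.** See below.
6. **Cross-wavelet spectrum, normalization, significance, phase filter,
   pair average, S and P.** See below.

## The wavelet transform

The mother wavelet is the complex Morlet (a sinusoid modulated by a
Gaussian) with central angular frequency ω₀ = 6, the standard choice for
which the admissibility correction is negligible and the scale–frequency
relation is `f ≈ (ω₀ + sqrt(2 + ω₀²)) / (4π s)`. The transform is computed
in the frequency domain with the unit-energy normalization

```
psihat(s, ω) = sqrt(2π s / dt) · π^(−1/4) · exp(−(s ω − ω₀)² / 2),  ω > 0,
```

so that for Gaussian white noise of variance σ² the expected coefficient
power E|W|² equals σ² at every scale — the property the analytic
significance threshold relies on, and one the test suite verifies
empirically. The analysis grid is log-spaced, 12 voices per octave, over
0.1–5 Hz by default: this brackets the 0.46–1.4 Hz locomotor range with
margin on both sides while staying well under the 25 Hz envelope Nyquist.
Records shorter than four periods of the lowest analysis frequency (40 s at
0.1 Hz) are rejected.

The record is zero-padded to a power of two at least eight e-folding times
of the largest wavelet beyond the data, so interior coefficients equal the
open-boundary convolution to near machine precision (the test suite checks
agreement with an O(N²) direct time-domain convolution to < 10⁻⁶ relative).
The cone of influence (COI) is the region within sqrt(2)·s of either edge;
it is computed always and kept by default (`coi_policy="keep"`), with
`"zero"` available to exclude it from the significance mask.

## Cross-spectrum, significance and phase filtering

`W_xy = W_x · conj(W_y)` element-wise; "power" throughout means the modulus
(vector length) of a coefficient, and the argument is the phase difference
between the two envelopes at that frequency–time location. Coefficients
are divided by the crossvariance σ_x σ_y of the two envelopes, which makes
spectra comparable across preparations and cancels any joint amplitude
scaling exactly.

For two independent white-noise records under the normalization above, the
normalized cross power |W_x||W_y|/(σ_x σ_y) is the geometric mean of two
independent exponential variates, with survival function
`P(> z) = 2 z K₁(2 z)` (K₁ the modified Bessel function of the second
kind). The significance threshold solves this for the configured level;
at 5% it is z ≈ 2.00, identical to the Z_ν(95%)/ν = 3.999/2 value of the
chi-square construction for complex wavelets. Coefficients below threshold
are zeroed and the retained bins recorded in a mask.

The phase filter zeroes coefficients whose argument falls outside
180° ± 60° on the circle, with **inclusive** bounds (an argument of exactly
120° is retained). Band membership is evaluated mod 360°, so arbitrary
centers work; the operation is idempotent and commutes with the
significance mask (both are element-wise zeroings).

Summaries: the global power spectrum is the time-sum of power per
frequency, normalized by its maximum, with the peak frequency its argmax;
the phase distribution is a power-weighted circular histogram whose mean
angle is the argument of the power-weighted vector sum; the instantaneous
frequency ridge is the per-time-step argmax of power over retained bins,
with gaps (NaN) where nothing survives.

## Strength and coupling

`S = sqrt(|ΣΣ W_avg|)` over the element-wise mean of the four alternating
pair spectra. The square root follows the verbal definition of the
statistic ("the square root of the length of the resultant vector");
`apply_sqrt=False` (CLI `--no-sqrt`) reproduces the plain-modulus variant.
The choice is a monotone rescaling and affects no ordering or comparison.
The per-pair coupling quantifier `P = |ΣΣ W_alt|` deliberately takes no
square root, reproducing each printed formula faithfully; the discrepancy
between the two conventions is isolated in configuration rather than
harmonized silently.

Partial episodes (fewer than four usable roots) must be requested
explicitly (`allow_partial`) and are flagged in provenance. Laterality
(ipsi/contra) for coupling groups is resolved from stimulated-side
metadata only, never inferred from the signals. Condition normalization
divides by the reference-condition mean (reference mean becomes exactly 1);
coupling standardization divides by the ipsilateral flexor/extensor group
mean. Two-condition comparisons use the Wilcoxon rank-sum test, three or
more the Kruskal–Wallis test (scipy implementations); the post-hoc option
runs pairwise two-group Kruskal–Wallis contrasts with the chi-square
approximation — the exact post-hoc procedure behind published
"Kruskal–Wallis followed by χ² statistic" phrasings is underdetermined, and
this is documented as an interpretation.

## Synthetic neurograms

Each channel is `amplitude · gate(t) · carrier(t) + noise + artifacts`:

- **gate** — raised-cosine burst of duty 0.5 per locomotor cycle (smooth,
  avoids harmonic splatter; real bursts are roughly half-duty but have no
  canonical shape), with the channel's phase offset (defaults fL=0,
  eL=180°, fR=180°, eR=0°, i.e. alternation for all four canonical pairs)
  and independent per-cycle Gaussian timing jitter;
- **carrier** — Gaussian noise band-passed to 100–1000 Hz, unit SD,
  emulating multi-unit discharge whose rectified envelope the 5 Hz low-pass
  recovers;
- **noise** — white Gaussian background (SD 1 by convention, so burst
  amplitude is an SNR);
- **artifacts** — biphasic rectangular transients (default 0.25 ms,
  amplitude 50 ≫ signal) at the stimulus rate (default 4 Hz), added
  identically to every channel, with pulse times recorded.

Defaults: 5 kHz sampling, 0.77 Hz locomotor frequency, burst amplitude 5,
phase jitter SD 5°. A seed expands into substreams keyed by (seed, stream,
canonical role), so outputs are bit-reproducible and adding a channel never
perturbs the others. The fixture suite covers strong alternation, an
in-phase control, jitter SDs {10, 30, 60, 90}°, a 0.46 → 1.4 Hz mid-episode
frequency step, a five-level amplitude ladder {1.25, 2.5, 5, 10, 20}, a
noise-only episode and a white-noise pair. The jitter series and the
ladder each share one noise realization (paired design), so the programmed
parameter is the only thing that varies along a series. Fixture records
are 40–60 s — long enough for the 0.1 Hz band edge and for a few dozen
locomotor cycles, short enough that the whole suite simulates and analyses
in seconds.

What the generator does **not** emulate: slow DC potentials, electrode
drift, bursts riding on tonic discharge, amplitude asymmetry within a
burst, non-stationary background noise, and co-modulated (rather than
independent) per-channel jitter. Passing tests therefore demonstrate that
the machinery recovers known ground truth under clean, stationary
conditions, not that it is robust to every pathology of real recordings.

## Calibration

The type-I calibration generates seeded pairs of independent Gaussian
white-noise envelopes at the analysis rate (50 Hz, 100 s), applies the
normalized cross-wavelet transform and the significance mask, and counts
the fraction of bins retained **outside the cone of influence**. Edge bins
are excluded from the count because zero padding attenuates coefficient
variance there, so the stationary white-noise null — hence the analytic
threshold — only holds outside the COI; this is the standard practice for
wavelet significance testing. With 50 pairs the retention matches the 5%
level within Monte-Carlo error.

Two calibration caveats worth knowing:

- The white-noise null is calibrated for *white* inputs. Real (and
  simulated) burst envelopes are strongly autocorrelated after the 5 Hz
  low-pass, so a rhythm-free episode still retains more than 5% of bins
  and has a nonzero strength floor (roughly a third of a strong episode's
  S in the fixture suite). S values are therefore comparable between
  episodes, not absolute zero-based magnitudes — which is exactly why
  condition normalization and reference-group standardization exist.
- An in-phase (synchronous) episode, by contrast, yields S = 0 in
  practice: its power is concentrated at phase 0° and the phase filter
  removes all of it.

## Numerical choices and limitations

- Phase convention: arguments in [0°, 360°); the default band centered at
  180° never wraps, arbitrary centers are handled on the circle. Inclusive
  band bounds carry a 10⁻⁹-degree tolerance so exact boundary arguments
  survive floating-point round trips.
- Frequency grid points are exact `fmin · 2^(k/voices)` values; "within one
  voice" is the natural resolution statement for any recovered frequency.
- Degenerate inputs: constant envelopes (zero SD) are a normalization
  error; all-zero spectra produce flagged NaN peaks/phases and all-gap
  ridges rather than exceptions.
- Episode boundaries are user-supplied; there is no automatic episode
  detection. No wavelet coherence is computed (cross-wavelet power only).
- Text neurogram I/O preserves 6 significant digits; the HDF5 spectrum
  container is lossless. Proprietary acquisition formats are out of scope;
  convert to CSV (one header row naming channels, `# rate_hz=` comment,
  optional `# stim_times_s=` comment) or pass arrays directly.
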