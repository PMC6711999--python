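# Methods

## The estimator

`tfpac` measures phase-amplitude coupling (PAC) from the RID-Rihaczek
complex time-frequency distribution.  For a signal *x(t)* with Fourier
transform *X(f)* the Rihaczek surface is *C(t,f) = x(t)X\*(f)e^{−j2πft}*,
a complex energy density whose sum over frequency is the instantaneous
power |x(t)|² and whose sum over time is the energy spectrum |X(f)|² —
both exactly.  Because the surface is bilinear, pairs of components
produce oscillatory cross-terms; the reduced-interference variant
multiplies the signal's ambiguity function A(θ,τ) (the 2-D transform over
doppler θ and lag τ) by the Choi–Williams weighting exp(−(θτ)²/σ) before
transforming back.  The weighting is identity on the two ambiguity axes —
where auto-term structure and the marginals live — and decays away from
them, where cross-terms and most wideband noise live.

From one surface the pipeline reads:

1. **Envelope** — the frequency-constrained time marginal
   A(t) = |Σ_{f∈band} C(t,f)|, a quadratic envelope approximating
   |A(t)|² over the band ("power" convention; its square root is the
   "magnitude" convention used when comparing against linear-envelope
   methods).  The default band half-width is f_p + 2 Hz, wide enough to
   hold both modulation sidebands f_a ± f_p.
2. **Coupled frequency** — the peak of the envelope's mean-removed,
   Hann-tapered periodogram inside the candidate slow-frequency range
   (ties break to the lower frequency; a peak/median prominence ratio
   flags unconvincing detections).
3. **Phase** — arg C(t, f_p) at the nearest bin.  This is a *demodulated*
   phase: for an analytic tone it is constant, because the surface's
   phase is referenced to the bin's own carrier and spectral phase.  The
   advancing instantaneous phase used in the coupling sum re-adds the
   carrier term 2πf_p t.  For irregular oscillations, whose instantaneous
   frequency wanders, a band form is used instead: the marginal identity
   Σ_{band} C(t,f) = x_a(t)·conj(x_band(t)) gives the band's analytic
   series as x_a(t)·conj(marginal) = |x_a|²·x_band(t), whose angle is the
   exact band instantaneous phase.
4. **Coupling** — the mean vector length
   MVL = |1/N Σ_t A(t)e^{jφ(t)}|.  The phase-locking value (envelope
   phase extracted through the same machinery) and the Tort modulation
   index (KL divergence of the mean-envelope-per-phase-bin distribution
   from uniform, 18 bins of 20° by default) are alternatives: MVL scales
   with envelope amplitude, PLV/MI are scale-free.

A comodulogram evaluates the MVL on a (f_p, f_a) grid (1 Hz steps by
default) reusing a single surface; its concentration is scored by the
Shannon entropy of the normalised map (log₂ of the cell count for a
uniform map, 0 for a delta).

## Discretisation

The analytic signal (one-sided spectrum) is formed first, so envelopes
and phases of real recordings are meaningful.  All lag products are
circular on the sample grid.  The Rihaczek half-lag kernel e^{jθτ/2} is
folded exactly into the asymmetric lag product
A(θ,τ) = Σ_v x(v)x\*(v−τ)e^{jθv}, keeping every quantity on integer
grids; with the kernel set to 1 the 2-D inverse transform reproduces
x(t)X\*(f)e^{−j2πft}/N to machine precision (asserted in the tests).
The overall normalisation is chosen so the plain-kernel time marginal
equals |x_a(t)|² exactly; this normalisation is the module's single
source of truth.

The Choi–Williams argument must be made dimensionless.  Both ambiguity
coordinates are taken as angles on their DFT circles (θ = 2πk/N,
τ̂ = 2πm/N).  Under this convention σ = 0.001 — the default used for
every result in the package — preserves amplitude-modulation structure
of the auto-terms, suppresses cross-terms and roughly an order of
magnitude of broadband noise, and changing σ by one or two decades moves
PAC values only marginally.  Conventions with physical units (rad/s × s)
make the same σ destroy the modulation content itself, so they were
rejected; this choice is load-bearing and documented here deliberately.

Only the non-negative frequency half of the surface is stored (the
analytic signal has no content above Nyquist).  One subtlety: the RID
marginal identity cancels only on the full circular frequency grid, so
the time marginal is evaluated before truncation and carried with the
surface.  The frequency grid is 1/duration; no zero padding is applied
by default because the kernel normalisation ties to the record length
and short padded records behave measurably worse.

The full surface is an O(N²) complex matrix.  Long records are decimated
first (zero-phase FIR) to the largest integer factor keeping the rate at
≥ 4× the highest analysed frequency; at 1 kHz with a 77 Hz band edge
this is a factor of 3.  The first and last three cycles of the slow
frequency — capped at 10% of the record per side, so the shortest
records keep usable data — are excluded from all coupling sums, for the
time-frequency and filter-based estimators alike.

## Synthetic models

**Coupled sinusoids.**  x(t) = K_fp sin(2πf_p t) + A(t) sin(2πf_a t) + ε(t)
with A(t) = K_fa((1−χ)sin(2πf_p t − φ_c) + χ + 1)/2.  χ ∈ [0,1] is the
uncoupled envelope fraction; coupling strength is 1−χ.  Defaults:
f_p = 5 Hz, f_a = 70 Hz, fs = 1 kHz, K_fp = K_fa = 1 (the equal-amplitude
convention of this simulation literature), φ_c = 0.  ε is 1/f ("pink")
background plus white measurement noise at half the pink power, scaled so
the realised SNR matches the request exactly (the tests hold it to
0.1 dB).  The pink exponent is a parameter; β = 1 distinguishes the
background from the explicitly Brownian second model.

**Brownian-noise bursts.**  Brownian noise (cumulative sum of white
Gaussian steps, mean-removed, unit variance; log-periodogram slope −2)
is bandpass filtered (zero-phase 4th-order Butterworth) into a slow band
(default 8–10 Hz) and a fast band (50–70 Hz).  At each relative maximum
of the slow series the fast series is multiplied by a DC-shifted Hanning
window of 42 ms (baseline 1, peak 1 + I, I ∈ [0,1]; overlapping windows
compose multiplicatively).  Independently drawn, band-matched Brownian
noise is added at the requested SNR.  Windows longer than the slow
band's upper-edge period are rejected as pathologically overlapping.

What these models do *not* emulate: multichannel structure and volume
conduction, non-sinusoidal slow rhythms (whose harmonics can mimic PAC),
nonstationary coupling strength, and biphasic coupling.  Tests passing
on them demonstrate correct estimator behaviour under the stated
generative assumptions, not robustness to every artefact of real EEG.

## Coupling-strength readout and calibration

The benchmark requires mapping an MVL to the planted strength 1−χ.  For
the coupled-sinusoid envelope the power-convention statistic
r = MVL/mean(envelope) has the closed form
(1−χ²)/(1.5(1+χ²)+χ) — notably *not* the naive modulation-depth identity
(2·MVL/mean = (1−χ)/(1+χ) on a magnitude envelope, which equals 1−χ only
at the endpoints).  Rather than inverting the idealised formula, the
readout inverts the estimator's *own response*: the identical pipeline is
run on noise-free model signals over a 12-point strength grid and the
measured statistic is interpolated through that monotone curve.  This
absorbs every deterministic distortion — kernel smoothing of sidebands,
band-edge weighting, edge trimming — and recovers noise-free strengths to
~0.2% mean error.

Under noise the statistic is debiased spectrally before inversion: the
numerator's noise floor is estimated from envelope-modulation bins 2–7 Hz
off the coupled frequency (avoiding its harmonic) and removed in
quadrature; the envelope's noise background is estimated from flanking
frequency bands of equal width on either side of the analysis band
(half-weighted, a deliberately conservative subtraction).  Both pieces
are classical noise-floor estimation, not model fitting.

The Hilbert baseline deliberately keeps the field's conventional readout:
zero-phase Butterworth bands f_a ± 0.4f_a and f_p ± 1 Hz, analytic
envelope and phase, and detected strength = 2·MVL/mean(envelope) — the
normalized MVL as used in the comparison literature, without model-based
calibration or debiasing.  Its systematic bias χ/(1+χ) plus its wide
band's noise inflation are what the accuracy benchmark quantifies.  The
Morse-wavelet baseline (β = 6, γ = 3, 120 log-spaced scales, unit-peak
bandpass normalisation) takes envelope and phase from the scales nearest
f_a and f_p.

## Significance testing

Block-swap surrogates: the envelope is split at a point drawn uniformly
from the middle 80% of the record and the two blocks are swapped,
destroying the envelope-phase alignment while preserving each series'
statistics; 200 surrogates yield a 95% cutoff, and the p-value uses the
(1+k)/(1+n) correction.  Restricting the split to the middle 80% avoids
near-identity swaps that would deflate the null.  Two properties are
worth knowing.  First, the test is conservative: its empirical
false-positive rate sits below the nominal 5% (asserted ≤ 10% over 100
null runs).  Second, a block swap is a circular shift, and the MVL of a
*strictly periodic* coupling is invariant to envelope shifts — the
modulus absorbs the rotation — so the test has power only for irregular
(e.g. Brownian-model or real) oscillations; for deterministic sinusoidal
toys the surrogate distribution collapses onto the observed value.

## Benchmark studies and scales

* SNR sweep: strength 0.9, 2-s records, −5…10 dB, 50 replicates per
  level.  The time-frequency readout's error stays within a few percent
  over most of the range (~25% at −5 dB); the baseline readout runs
  3–10× higher throughout.
* Strength sweep: strengths 0.1…1.0 at 6 dB, 50 replicates, 4-s records.
  The generation protocol for fixed-duration experiments produces 10-s
  records; 4 s keeps the O(N²) surfaces affordable at 500 evaluations
  while staying in that regime (accuracy improves monotonically with
  record length, so the reported errors are, if anything, conservative).
* Record-length sweep: Brownian model, intensity 0.9, 6 dB, lengths
  0.4…6 s in 0.4-s steps, 20 realisations; per realisation the first
  length whose observed MVL clears its 200-surrogate cutoff, summarised
  by the median.

Replicate seeds are spawned deterministically from the master seed, so
every study is bit-reproducible from its configuration.

## Known limitations

* The O(N² log N) surface makes records beyond ~10⁴ samples (after
  decimation) impractical; a sliding-window approach would be the
  extension for long recordings.
* The quadratic envelope couples additively to in-band noise power; the
  flanking-band subtraction compensates on average but cannot remove
  realisation noise, which dominates the error at weak coupling.
* The calibrated strength readout is specific to the coupled-sinusoid
  generative model; for other envelope models the response curve must be
  rebuilt against that model.
* Surrogate significance requires irregular phase evolution (see above).
* The comodulogram's concentration entropy discriminates coupled from
  phase-scrambled surfaces in the clear majority of realisations, but a
  single Fourier surrogate occasionally concentrates by chance; compare
  medians over seeds, not single pairs.
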