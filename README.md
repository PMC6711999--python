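# tfpac — time-frequency phase-amplitude coupling

Phase-amplitude coupling (PAC) is the modulation of a fast neural
oscillation's amplitude (e.g. gamma, 30–100 Hz) by the phase of a slow
rhythm (e.g. theta/alpha, 5–12 Hz).  The conventional estimate bandpass
filters the signal twice and reads amplitude and phase off Hilbert
transforms — making the result hostage to the filter design.  `tfpac`
implements a time-frequency alternative for researchers analysing EEG/LFP
style recordings: both quantities come from one complex energy
distribution, with no bandpass filtering.

## The estimator

For a signal *x(t)* with spectrum *X(f)*, the Rihaczek distribution

&nbsp;&nbsp;&nbsp;&nbsp;*C(t, f) = x(t) X\*(f) e^{−j2πft}*

is a complex surface with exact time and frequency marginals.  Its
reduced-interference variant (RID-Rihaczek) multiplies the signal's
ambiguity function *A(θ, τ)* by the Choi–Williams kernel
*exp(−(θτ)²/σ)* (default σ = 0.001) before transforming back, which
suppresses cross-terms and most broadband noise while leaving the
marginals intact.  From this surface:

* **amplitude**: the frequency-constrained time marginal
  *A_{f_a}(t) = |Σ_{f∈[f_a1, f_a2]} C(t, f)|* — a quadratic envelope
  approximating |A(t)|²;
* **phase**: *φ_{f_p}(t) = arg C(t, f_p)* plus the carrier term *2πf_p t*
  (a band form is provided for irregular oscillations);
* **coupling**: the mean vector length
  *MVL = |1/N Σ_t A_{f_a}(t) e^{jφ_{f_p}(t)}|*
  (phase-locking value and the Tort modulation index are also available).

The package also ships the two standard synthetic PAC generators (coupled
sinusoids in pink+white noise; bandpass-filtered Brownian noise with
Hanning-window burst coupling), the bandpass+Hilbert and generalized
Morse wavelet (β = 6, γ = 3) reference estimators, block-swap surrogate
significance testing, comodulograms with a concentration-entropy score,
and a calibrated coupling-strength readout for the coupled-sinusoid
model.

## Worked example

```bash
python examples/01_simulate_and_measure_pac.py
```

```
signal: 2000 samples at 1000 Hz, planted coupling strength 0.8
tf-MVL       = 0.1758  (f_p=4.9975 Hz, amplitude band 63-77 Hz)
Hilbert-MVL  = 0.1935  (f_p=5 Hz, amplitude band 42-98 Hz)
Wavelet-MVL  = 0.1859  (f_p=5.02097 Hz, amplitude band 70-70 Hz)
calibrated tf coupling-strength estimate: 0.795 (true 0.8)
```

A 5 Hz rhythm drives the envelope of a 70 Hz carrier at strength 0.8 in
6 dB of noise.  All three estimators detect the coupling (non-zero MVL on
comparable magnitude-envelope scales); the calibrated time-frequency
readout recovers the planted strength to within ~1%.  The other examples
map coupling over a frequency grid (`02`), test significance against
block-swap surrogates on the Brownian-noise model (`03`), and run a
small-scale accuracy sweep (`04`).

The same functionality is scriptable from the shell:

```bash
tfpac simulate --config gen1.yml --seed 7 --out run/
tfpac pac --signal run/signal.txt --f-p 5 --f-a 70 --surrogates 200 --out run/
tfpac comodulogram --signal run/signal.txt --out run/
tfpac sweep --config sweep.yml --out run/
```

Every command writes a JSON manifest sufficient to reproduce the run.

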