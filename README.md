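# fifnmr

Automatic baseline correction of 1D NMR spectra by Fast Iterative
Filtering (FIF).

Baseline distortions — receiver dead time, pulse imperfections, probe
background — produce broad, slowly varying artifacts under the narrow
peaks of a solution NMR spectrum. They are especially severe for
paramagnetic samples acquired over very wide spectral windows, where
polynomial or spline corrections need manual tuning. `fifnmr` separates
peaks from baseline by *scale*: the spectrum is decomposed into
intrinsic mode functions (IMFs) ordered from fast- to slow-oscillating,

    s(x) = I_1(x) + ... + I_m(x) + r(x),

where each IMF is the fixed point of iterated moving-average
subtraction, computed in closed form in Fourier space as
`I = iFFT[(1 − ŵ)^N0 FFT(s)]` with `ŵ` the transfer function of a
smooth compactly supported low-pass mask. The sum of all components
reproduces the spectrum exactly, so nothing is lost or distorted by the
decomposition itself. The fastest `k` components form the corrected
spectrum and the rest the baseline, with `k` chosen automatically from
the curvature-to-power ratio of the candidate baselines,

    CPR(b) = ‖b″‖ / ‖b‖²,

whose profile against the number of excluded components drops sharply
once the last non-smooth content leaves the baseline. The package is
aimed at NMR spectroscopists (and anyone with spiky-signal-over-broad-
background data) who want a reproducible, parameter-light alternative
to manual baseline fitting.

It also ships the synthetic machinery to evaluate such corrections:
a seven-peak benchmark spectrum with erf-sigmoid or dead-time-induced
"rolling" baselines over SBR/SNR grids, synthetic FIDs with dead-time
alteration, and the standard figures of merit (χ², r², signed
correlation, peak-integral RMSD).

## Worked example

Simulate a wide-window spectrum of six Lorentzian lines whose FID lost
its first 16 points to receiver dead time, then correct it:

```python
import numpy as np
from fifnmr import PeakSpec, gen_fid, apply_dead_time, add_noise, correct

peaks = [PeakSpec(-60, 180), PeakSpec(-20, 120), PeakSpec(10, 150),
         PeakSpec(45, 100), PeakSpec(90, 250), PeakSpec(120, 140)]
fid = gen_fid(peaks, 8192, sw_ppm=200.0)   # ppm centres, FWHM in Hz
fid[0] *= 0.5                              # first-point halving
distorted = np.fft.fftshift(np.fft.fft(apply_dead_time(fid, 16))).real
spectrum, sigma = add_noise(distorted, snr=1000.0, seed=0)

result = correct(spectrum)
dec = result.decomposition
print(f"IMFs extracted : {dec.n_imfs} (mask half-lengths {dec.mask_lengths})")
print(f"signal IMFs    : {result.k_signal}  (auto-selected: {result.auto_selected})")

clean = np.fft.fftshift(np.fft.fft(fid)).real
off = np.abs(clean) < 1e-3 * clean.max()
before = np.sqrt(np.mean(spectrum[off] ** 2))
after = np.sqrt(np.mean(result.signal_estimate[off] ** 2))
print(f"off-peak RMS   : {before:.2f} -> {after:.2f}  ({before/after:.1f}x flatter)")
```

Output:

```
IMFs extracted : 9 (mask half-lengths [5, 10, 20, 57, 252, 504, 1008, 2016, 4032])
signal IMFs    : 4  (auto-selected: True)
off-peak RMS   : 3.34 -> 0.43  (7.8x flatter)
```

The decomposition found nine scales; the four fastest (the peak cores)
were kept as signal, everything slower — the dead-time roll — went into
the baseline, and the off-peak region of the corrected spectrum is
nearly eight times flatter. `result.baseline_estimate` holds the
subtracted baseline, `result.cpr_profile` the CPR values used for the
automatic choice, and `fifnmr.complex_baseline` recovers the
imaginary-channel baseline via the Hilbert transform when the spectrum
is complex.

The same pipeline is available from the shell:

```sh
fifnmr simulate --dead-points 4,8,16,32 --out sim/
fifnmr correct sim/deadtime_016.tsv --out corrected/
fifnmr benchmark --sw 12 --distortion rolling --out bench/
```

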