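# Methods

`fifnmr` separates narrow spectral peaks from broad baseline distortions
in 1D NMR spectra by Fast Iterative Filtering (FIF) decomposition and a
curvature-based automatic split. This note records the model, the
numerical choices, and what the synthetic tests do and do not
demonstrate.

## The decomposition model

A real discrete spectrum `s` (treated as a generic 1D signal; channel
index, not ppm, is the working coordinate) is decomposed as

    s = I_1 + ... + I_m + r

where each intrinsic mode function (IMF) `I_j` collects oscillations on
one characteristic scale, ordered fastest to slowest, and the remainder
`r` is a trend (at most one interior extremum at the resolvable
scales). One IMF is the fixed point of repeatedly subtracting a
compactly supported moving average `L(s)(x) = ∫ s(x+t) w(t) dt` from the
current signal. Because subtraction of a circular convolution is
diagonal in Fourier space, the whole inner loop is a single elementwise
power:

    I = iFFT[ (1 − ŵ)^N0 · FFT(s) ],

with `ŵ` the transfer function of the mask `w` and `N0` the number of
iterations at which the candidate stops changing. The outer loop
subtracts the converged IMF, re-estimates the mask length on the
remainder, and repeats until only a trend is left. The decomposition is
exactly additive: reconstruction holds to float round-off by
construction, and every IMF has exactly zero mean because `ŵ(0) = 1`
annihilates the DC multiplier.

### Filter mask

The mask is the autocorrelation of the smooth compactly supported bump
`u(x) = exp(−c/(1−x²))` with flatness `c = 0.25`, sampled at integer
lags over support `[−l, l]`. The autocorrelation structure matters: by
Poisson summation the sampled mask's transfer function is a folded
square of a real spectrum, hence `0 ≤ ŵ ≤ 1` exactly, and the inner
loop contracts in every frequency bin — the same self-convolution
("double filter") structure under which FIF convergence is guaranteed.
The mask is symmetric, nonnegative, unit-sum (constants are fixed
points), vanishes at `±l`, and has its first spectral zero near
`1.2/l` with sidelobes below `3·10⁻²`. Flatness trades first-zero
position against sidelobe height; 0.25 keeps the effective averaging
window wide without raising sidelobes above the per cent level.

### Mask length

For the current remainder with `k` strict interior extrema on `n`
samples, the mask half-length is `l = max(1, floor(xi·n/k))`, capped at
`(n−1)/2`, with default `xi = 3.2`. The value is not arbitrary: the
dominant oscillation has frequency `k/2n`, and it survives into the
extracted IMF only if it lies beyond the mask's first spectral zero
`≈1.2/l`; `xi = 3.2` places the mask across ≈1.6 periods of the
dominant oscillation, which satisfies that condition with margin. With
`xi` near 1.6 the dominant component is provably annihilated instead of
extracted.

Successive mask lengths are additionally forced to grow geometrically
(`mask_growth`, default 2.0, i.e. octave spacing). The extrema rule
alone stalls on noisy signals: thin spectral slivers near the transfer
function's zeros survive every inner loop, keep the extrema count
high, and produce many redundant IMFs per scale. The geometric floor
yields one component per scale, which is also what makes the CPR
profile (below) interpretable.

### Inner loop depth

The inner loop stops when the relative L2 change of the candidate falls
below `delta_stop` (default `10⁻³`) or at `max_inner_iterations`
(default 20, usually binding). The cap is a regularity control, not
just a budget: each iteration sharpens the band edge of
`(1 − ŵ)^N0`, and a near-brickwall edge (hundreds of iterations) makes
narrow spectral lines ring across the entire window — the ringing ends
up in the "baseline" components and ruins the correction. Around 20
iterations gives edges sharp enough for scale separation without
visible ringing.

### Termination and boundaries

The outer loop stops when the remainder has at most one *significant*
interior extremum, where significance means peak prominence above
`delta_stop` times the input RMS: each extraction leaves ripple of that
order, and counting it as oscillation would keep the loop running on
tolerance artifacts. The strict extremum count is still what
`is_trend` reports.

The FFT implies circular convolution, so the default boundary handling
is periodic. A non-periodic signal (e.g. a spectrum whose baseline
differs at the two edges) is then implicitly a sawtooth, and
decomposition scatters the wrap discontinuity across scales, producing
boundary wiggles in slow components. The half-sine window
(`apply_window`) is the intended remedy: it zeroes both edges so the
filtered signal is genuinely periodic, at the cost of reporting all
estimates in the windowed domain (no un-windowing division is performed
— it would amplify noise without bound near the window zeros). A
reflect extension mode is also available; it preserves continuity at
the boundary but not the exact zero-mean property of cropped IMFs.

## The curvature-to-power ratio and the automatic split

A candidate baseline `b` (a partial sum of slow IMFs plus the
remainder) is scored by

    CPR(b) = ‖b''‖ / ‖b‖²

with Euclidean norms and the unit-spacing second central difference
(one-sided at the two edge channels). CPR is zero exactly for affine
baselines and grows with oscillatory content relative to power. The
profile `CPR(j)`, `j = 0..m`, scores the baseline left after excluding
the `j` fastest IMFs.

The auto-selection looks for the profile's dominant discontinuity.
Because the profile decays geometrically over several decades, jumps
are measured on the logarithmic scale (the largest multiplicative
drop), which is how a discontinuity presents itself on the log-scale
plots one actually inspects. Two eligibility rules bracket the search:

* trailing non-oscillating components (trend-like IMFs) are excluded,
  and
* the search stops at the profile's first rise — once CPR grows again,
  further exclusions are stripping power from the candidate rather
  than making it smoother.

The component at the selected discontinuity `j*` carries the slowest
non-smooth content, i.e. the distortion itself; the smoothest baseline
that still removes the distortion must contain it. The split therefore
assigns the `k = max(1, j*−1)` fastest components to the signal and
everything else to the baseline (the fastest component, noise at the
sampling scale, is never baseline). This reading was fixed by
cross-checking three scenarios with known ground truth: dead-time
rolling distortions (the corrected spectrum must flatten off the
peaks), pure peaks with no baseline (almost everything is signal), and
a pure broad hump (almost everything is baseline).

When the profile has no usable jump the result is flagged
`auto_selected = False` with `k = 0`, and the CPR profile itself is the
diagnostic: a profile without a clear discontinuity (low SNR, heavy
congestion) means the split should be chosen manually (`k_override`).
For windowed spectra the CPR can be restricted to a channel range
(`cpr_range`), e.g. the peaks region.

### Complex spectra

The package corrects the real (absorption) channel. The imaginary
channel's baseline is recovered as the discrete Hilbert transform of
the real-channel baseline (`complex_baseline`), exploiting the
absorption/dispersion pairing of phased lineshapes; the alternative of
decomposing the imaginary channel independently is available through
the CLI. Native FIF on complex arrays is out of scope.

## Synthetic data

Two families are generated, and they define the conditions under which
the package is validated.

**Frequency-domain benchmark.** Seven unit-height Lorentzians at
channels 340, 455, 432, 584, 618, 641, 656 (FWHM 5.7, except 10 for the
340 peak) on a 1001-channel block, convolved with a unit-area Gaussian
of FWHM 5 channels. The erf-sigmoid baseline is
`b(x) = 1 + slope·erf(√π/2·(x−500))`: a step of fixed transition width
(a few channels, independent of the spectral width) whose amplitude
above the unit offset equals its analytic midpoint slope — one
parameter is simultaneously the midpoint slope and the baseline maximum
above the offset, which is why the family is quoted by a single number
(0.1, 0.3, 1.0; 0 is the flat baseline of ones). Peak heights are set
by SBR = max(signal)/max(baseline); noise is white Gaussian with
`sigma = max(signal)/SNR` (baseline-referenced when SBR = 0, where no
signal exists). The rolling variant replaces the erf baseline with the
distortion obtained by zeroing the first `N ∈ {4, 8, 16, 32}` samples
of the time-domain equivalent of the clean spectrum — the classic
receiver-dead-time roll; `N = 0` reproduces the flat baseline exactly.
Wider spectral windows (30, 54, 72 ppm versus the base 12 ppm) extend
the grid proportionally (`round(1001·SW/12)` channels) while the peak
block and the figure-of-merit region stay the central 1001 channels.

**Time-domain FIDs.** Sums of decaying complex exponentials
(`R2 = π·FWHM`), with dead-time alteration of the first points, for the
wide-window paramagnetic scenario. The test fixture uses six lines of
100–250 Hz width across a 200 ppm window at 14.1 T (8192 points, so
every line decays fully within the acquisition), first-point halving
(the standard correction for the half-weight of the `t = 0` sample),
and SNR 1000 — dead-time rolls are studied on visually clean spectra,
and the flattening criterion is meaningless once noise exceeds a fifth
of the distortion.

What the generator does *not* emulate: phase errors (spectra are
assumed phased), solvent signals, temperature/field drift, correlated
(apodized) noise, probe background other than through the generic
distortion shapes, and multiplet structure. Passing tests therefore
show that scale separation and the CPR split work when peaks are
spectrally faster than the distortion and the noise is white; they do
not certify behavior on unphased or heavily congested experimental
data, where the CPR profile must be inspected (the package flags these
cases rather than guessing).

## Figures of merit

Over an inclusive channel region, `r2_printed = SSreg/SStot` with the
region mean of the true baseline as the reference (NaN, never an
exception, when the true baseline is flat), alongside the signed
product-moment correlation — the sum-of-squares ratio cannot be
negative, so the signed correlation is what comparisons of estimated
versus true curves should use when anti-correlation is possible. `χ² = Σ (Ŷ_i − Y_i)²` over all 1001 region channels,
unnormalized. Peak-integral RMSD compares channel-sum integrals over
disjoint peak intervals. The uncongested/congested sub-regions are
channels 0–560 and 561–1000 (0-based inclusive).

The grid runner simulates SBR × SNR × (slope or dead-points) cells,
corrects each instance (windowing only for the windowed family, and
skipped for the flat baseline where it has nothing to make periodic),
scores estimates against the truth — in the windowed domain against
window-multiplied truths, because a windowed baseline is what gets
reconstructed — and averages, excluding and counting undefined
entries.

The acceptance script runs four cells (asymmetric at 12/54/72 ppm,
rolling at 12 ppm), each 5 SBR × 5 SNR × 4 slope-or-dead-point values ×
3 noise seeds = 300 spectra of 1001–6006 channels, about half a minute
in total on one CPU.

## Known limitations

* Tall Lorentzians leak their broad bases into every slow component:
  no frequency-scale split can keep the base of an intense peak out of
  the baseline, so baseline χ² in high-SBR conditions has a floor that
  no split choice removes (measurable by scanning `k` exhaustively).
* With white noise at low SNR the CPR profile is a smooth noise
  cascade; the discontinuity can be genuinely absent, and the
  auto-selection then picks the largest of several comparable drops.
  The CPR profile should be inspected in such runs.
* The erf-step benchmark baseline is spectrally *fast* (transition of a
  few channels) and sits at the same scales as the peaks; it is a
  deliberately adversarial case for scale-separation methods, and
  reconstruction quality there is bounded for any IMF split.
* Periodic boundary handling turns edge mismatches into broadband
  artifacts; window (or reflect-extend) non-periodic spectra.
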