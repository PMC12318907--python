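"""Synthetic NMR inputs: benchmark spectra and dead-time-distorted FIDs.

Two families are generated here.

* A frequency-domain benchmark of seven Gaussian-convolved Lorentzian
  peaks on a 1001-channel block, over either an erf-sigmoid
  ("asymmetric") baseline or a dead-time-induced oscillatory ("rolling")
  baseline, with Gaussian noise at a prescribed signal-to-noise ratio
  and peak heights set by a signal-to-baseline ratio.  Wider spectral
  windows extend the channel grid proportionally while the peak block
  (and the region used for figures of merit) stays 1001 channels.

* Time-domain free induction decays (FIDs) as sums of decaying complex
  exponentials, with an optional dead-time alteration of the first few
  points, whose Fourier transform exhibits the broad rolling baseline
  distortion characteristic of receiver dead time.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
from scipy.special import erf

__all__ = [
    "PeakSpec",
    "BenchmarkSpec",
    "BenchmarkInstance",
    "SCHULZE_CENTERS",
    "schulze_peaks",
    "schulze_baseline",
    "add_noise",
    "build_benchmark",
    "gen_fid",
    "apply_dead_time",
]

# Peak centres (channels) of the seven-peak benchmark signal; the peak
# at 340 is broader (FWHM 10) than the others (FWHM 5.7).
SCHULZE_CENTERS = (340, 455, 432, 584, 618, 641, 656)
_SCHULZE_FWHM = (10.0, 5.7, 5.7, 5.7, 5.7, 5.7, 5.7)

# proton gyromagnetic ratio, MHz per tesla
_GAMMA_1H_MHZ_PER_T = 42.577478461

Distortion = Literal["asymmetric", "asymmetric_windowed", "rolling"]


@dataclass(frozen=True)
class PeakSpec:
    """One spectral line.

    ``center`` is in channels for frequency-domain synthesis and in ppm
    for FID synthesis; ``fwhm`` correspondingly in channels or Hz.
    """

    center: float
    fwhm: float
    amplitude: float = 1.0
    lineshape: Literal["lorentzian", "gaussian_convolved_lorentzian"] = "lorentzian"

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ValueError("fwhm must be positive")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")


@dataclass(frozen=True)
class BenchmarkSpec:
    """Full parameterization of one synthetic benchmark spectrum."""

    sbr: float
    snr: float
    seed: int
    sw_ppm: float = 12.0
    slope: float = 0.0
    distortion: Distortion = "asymmetric"
    dead_points: int = 0
    n_channels_fom: int = 1001

    def __post_init__(self) -> None:
        if self.sbr < 0:
            raise ValueError("sbr must be >= 0")
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        if self.sw_ppm < 12:
            raise ValueError("sw_ppm must be >= 12 (the base window)")
        if self.n_channels_fom != 1001:
            raise ValueError("the FoM region is fixed at 1001 channels")
        if self.distortion == "rolling":
            if self.slope != 0.0:
                raise ValueError("rolling distortion uses dead_points, not slope")
            if self.dead_points < 0:
                raise ValueError("dead_points must be >= 0")
        else:
            if self.dead_points != 0:
                raise ValueError(f"{self.distortion} distortion uses slope, not dead_points")
            if self.slope < 0:
                raise ValueError("slope must be >= 0")

    @property
    def n_channels_total(self) -> int:
        """Total grid size: extended proportionally to the spectral width."""
        return int(round(self.n_channels_fom * self.sw_ppm / 12.0))


@dataclass
class BenchmarkInstance:
    """A realized benchmark spectrum with its ground truth.

    ``spectrum = true_signal + true_baseline + noise`` exactly by
    construction; ``fom_start`` is the first channel of the central
    1001-channel block on which figures of merit are computed.
    """

    spectrum: np.ndarray
    true_baseline: np.ndarray
    true_signal: np.ndarray
    noise_sigma: float
    spec: BenchmarkSpec
    fom_start: int

    @property
    def fom_slice(self) -> slice:
        return slice(self.fom_start, self.fom_start + self.spec.n_channels_fom)


def _lorentzian(x: np.ndarray, center: float, fwhm: float) -> np.ndarray:
    hwhm = fwhm / 2.0
    return hwhm**2 / ((x - center) ** 2 + hwhm**2)


def schulze_peaks(n_channels: int = 1001, gaussian_fwhm: float = 5.0) -> np.ndarray:
    """The seven-peak benchmark signal on ``n_channels`` channels.

    Unit-height Lorentzians at channels 340, 455, 432, 584, 618, 641 and
    656 (FWHM 5.7, except 10 for the 340 peak), convolved with a
    unit-area Gaussian of FWHM ``gaussian_fwhm`` channels.
    """
    if n_channels < 700:
        raise ValueError("n_channels too small to contain all peak centers")
    x = np.arange(n_channels, dtype=float)
    signal = np.zeros(n_channels)
    for center, fwhm in zip(SCHULZE_CENTERS, _SCHULZE_FWHM):
        signal += _lorentzian(x, center, fwhm)
    sigma = gaussian_fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    half = int(np.ceil(6 * sigma))
    t = np.arange(-half, half + 1, dtype=float)
    kernel = np.exp(-0.5 * (t / sigma) ** 2)
    kernel /= kernel.sum()
    return np.convolve(signal, kernel, mode="same")


def schulze_baseline(
    slope: float, n_channels: int = 1001, center: float = 500.0
) -> np.ndarray:
    """Erf-sigmoid benchmark baseline with a given midpoint slope.

    ``b(x) = 1 + slope * erf(sqrt(pi)/2 * (x - center))``: a sigmoid
    step of fixed transition width (a few channels, independent of the
    spectral width) whose amplitude above the unit offset equals its
    analytic midpoint slope in baseline units per channel — the family
    is parameterized by one number that is simultaneously the midpoint
    slope and the baseline maximum above the offset.  ``slope = 0``
    returns the flat baseline of ones.
    """
    if slope < 0:
        raise ValueError("slope must be >= 0")
    x = np.arange(n_channels, dtype=float)
    if slope == 0:
        return np.ones(n_channels)
    return 1.0 + slope * erf(np.sqrt(np.pi) / 2.0 * (x - center))


def add_noise(
    signal: np.ndarray, snr: float, seed: int, reference_height: float | None = None
) -> tuple[np.ndarray, float]:
    """Add zero-mean Gaussian noise at the requested SNR.

    ``sigma = reference_height / snr`` where the reference defaults to
    the maximum of ``signal``.  Deterministic under a fixed seed.
    """
    y = np.asarray(signal, dtype=float)
    if snr <= 0:
        raise ValueError("snr must be positive")
    ref = float(np.max(y)) if reference_height is None else float(reference_height)
    if ref <= 0:
        raise ValueError("noise reference height must be positive")
    sigma = ref / snr
    rng = np.random.default_rng(seed)
    return y + rng.normal(0.0, sigma, size=y.size), sigma


def gen_fid(
    peaks: Sequence[PeakSpec],
    n_points: int,
    sw_ppm: float,
    field_T: float = 14.1,
    carrier_ppm: float = 4.7,
) -> np.ndarray:
    """Time-domain FID: a sum of decaying complex exponentials.

    Each peak contributes ``A exp(2 pi i f t - R2 t)`` with the
    frequency ``f`` from its ppm offset to the carrier and the decay
    ``R2 = pi * fwhm`` (fwhm in Hz), so its Fourier transform is a
    Lorentzian of the stated width at the stated position.
    """
    if sw_ppm <= 0:
        raise ValueError("sw_ppm must be positive")
    larmor_mhz = _GAMMA_1H_MHZ_PER_T * field_T
    sw_hz = sw_ppm * larmor_mhz  # ppm * MHz = Hz
    dt = 1.0 / sw_hz
    t = np.arange(n_points) * dt
    fid = np.zeros(n_points, dtype=complex)
    for pk in peaks:
        freq_hz = (pk.center - carrier_ppm) * larmor_mhz
        r2 = np.pi * pk.fwhm
        fid += pk.amplitude * np.exp((2j * np.pi * freq_hz - r2) * t)
    return fid


def apply_dead_time(
    fid: np.ndarray,
    n_altered: int,
    mode: Literal["zero", "scale"] = "zero",
    scale_factor: float = 0.5,
) -> np.ndarray:
    """Alter the intensity of the first ``n_altered`` FID points.

    ``mode="zero"`` zeroes them (lost during the receiver dead time);
    ``mode="scale"`` multiplies them by ``scale_factor``.  The spectrum
    of the altered FID shows a broad rolling baseline distortion whose
    amplitude grows with ``n_altered``.
    """
    fid = np.asarray(fid)
    if n_altered < 0:
        raise ValueError("n_altered must be >= 0")
    if n_altered >= fid.size:
        raise ValueError("n_altered must be smaller than the FID length")
    out = fid.copy()
    if mode == "zero":
        out[:n_altered] = 0.0
    elif mode == "scale":
        out[:n_altered] *= scale_factor
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return out


def build_benchmark(spec: BenchmarkSpec) -> BenchmarkInstance:
    """Realize one benchmark spectrum from its parameterization.

    Peaks are scaled so that ``max(true_signal) / max(reference
    baseline) = sbr`` (reference = the erf baseline for the asymmetric
    families, the undistorted flat baseline of 1 for rolling; ``sbr = 0``
    means no peaks).  For the rolling family the baseline is the
    spectral distortion obtained by zeroing the first ``dead_points``
    samples of the time-domain equivalent of the clean spectrum.  The
    windowed family is constructed identically to the asymmetric one:
    windowing is a preprocessing step applied at correction time, not a
    property of the data.  Noise sigma is referenced to the peak height
    (or the baseline height when ``sbr = 0``).
    """
    n = spec.n_channels_total
    block = spec.n_channels_fom
    fom_start = (n - block) // 2

    peaks_unit = np.zeros(n)
    peaks_unit[fom_start : fom_start + block] = schulze_peaks(block)
    peak_max_unit = float(np.max(peaks_unit))

    if spec.distortion in ("asymmetric", "asymmetric_windowed"):
        baseline = schulze_baseline(spec.slope, n, center=fom_start + 500.0)
        ref_base_max = float(np.max(baseline))
        scale = spec.sbr * ref_base_max / peak_max_unit
        true_signal = peaks_unit * scale
        true_baseline = baseline
        clean = true_signal + true_baseline
    elif spec.distortion == "rolling":
        ref_base_max = 1.0
        scale = spec.sbr * ref_base_max / peak_max_unit
        true_signal = peaks_unit * scale
        undistorted = true_signal + 1.0
        fid = np.fft.ifft(undistorted)
        fid = apply_dead_time(fid, spec.dead_points, mode="zero")
        clean = np.fft.fft(fid).real
        true_baseline = clean - true_signal
    else:  # pragma: no cover - guarded by BenchmarkSpec validation
        raise ValueError(f"unknown distortion {spec.distortion!r}")

    ref_height = float(np.max(true_signal)) if spec.sbr > 0 else ref_base_max
    noisy, sigma = add_noise(clean, spec.snr, spec.seed, reference_height=ref_height)
    return BenchmarkInstance(
        spectrum=noisy,
        true_baseline=true_baseline,
        true_signal=true_signal,
        noise_sigma=sigma,
        spec=spec,
        fom_start=fom_start,
    )
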