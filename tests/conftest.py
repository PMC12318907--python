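import numpy as np
import pytest

from fifnmr import PeakSpec, add_noise, apply_dead_time, gen_fid


@pytest.fixture(scope="session")
def deadtime_family():
    """Figure-style dead-time scenario: narrow peaks on a wide window.

    Returns (clean_spectrum, off_peak_mask, make_distorted) where
    ``make_distorted(n_altered, seed)`` yields the noisy distorted
    spectrum.
    """
    peaks = [
        PeakSpec(c, f)
        for c, f in [(-60, 180), (-20, 120), (10, 150), (45, 100), (90, 250), (120, 140)]
    ]
    n = 8192
    fid = gen_fid(peaks, n, sw_ppm=200.0)
    # standard first-point halving: removes the constant offset the
    # one-sided FID otherwise puts under the whole spectrum
    fid[0] *= 0.5
    clean = np.fft.fftshift(np.fft.fft(fid)).real
    # off-peak region: beyond the point where Lorentzian wings fall
    # under the noise, so it probes only the baseline distortion
    off_peak = np.ones(n, bool)
    for i in np.where(np.abs(clean) > 1e-3 * clean.max())[0]:
        off_peak[max(0, i - 80) : i + 81] = False

    def make_distorted(n_altered: int, seed: int) -> np.ndarray:
        distorted = np.fft.fftshift(np.fft.fft(apply_dead_time(fid, n_altered))).real
        noisy, _ = add_noise(distorted, snr=1000.0, seed=seed)
        return noisy

    return clean, off_peak, make_distorted
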