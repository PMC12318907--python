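"""Signal/baseline separation of a FIF decomposition via the
curvature-to-power ratio (CPR).

A decomposed spectrum is split into a "signal" group (the fastest IMFs,
holding the narrow peaks and the noise) and a "baseline" group (the slow
IMFs plus the trend remainder).  Candidate baselines obtained by
excluding progressively more fast IMFs are scored with

    CPR(b) = ||b''|| / ||b||^2

(L2 norms, second central finite difference): a smooth, low-curvature
baseline scores low, and the CPR profile as a function of the number of
excluded IMFs shows a sharp jump where peak-carrying components stop
leaking into the baseline.  The split is auto-selected at the largest
jump, excluding trailing non-oscillating components from the search.

For spectra whose baseline is not periodic at the edges (the normal
case in NMR), a half-period sine window can be applied before the
decomposition so that the circular filtering of FIF sees a periodic
signal; estimates are then reported in the windowed domain.  The
imaginary channel of a complex spectrum can be recovered from the real
channel's baseline with a Hilbert transform (absorption/dispersion
pair).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.signal

from .fif import Decomposition, FIFConfig, decompose, is_trend

__all__ = [
    "BaselineSplit",
    "UndefinedCPRError",
    "SplitSelectionError",
    "cpr",
    "cpr_profile",
    "select_split",
    "split",
    "apply_window",
    "correct",
    "complex_baseline",
]


class UndefinedCPRError(ZeroDivisionError):
    """CPR of an identically zero baseline candidate is undefined."""


class SplitSelectionError(ValueError):
    """No eligible point in the CPR profile to auto-select a split."""


@dataclass
class BaselineSplit:
    """A chosen signal/baseline split of a decomposition.

    ``signal_estimate + baseline_estimate`` reproduces the decomposed
    input (possibly in the windowed domain).  ``k_signal`` is the number
    of fastest IMFs assigned to the signal; ``cpr_profile[j]`` is the
    CPR of the baseline obtained after excluding the ``j`` fastest IMFs.
    """

    k_signal: int
    cpr_profile: np.ndarray
    signal_estimate: np.ndarray
    baseline_estimate: np.ndarray
    auto_selected: bool
    decomposition: Decomposition | None = None
    window: np.ndarray | None = field(default=None, repr=False)


def _second_difference(b: np.ndarray) -> np.ndarray:
    """Second finite difference, unit spacing; one-sided at the ends."""
    d2 = np.empty_like(b)
    d2[1:-1] = b[2:] - 2.0 * b[1:-1] + b[:-2]
    d2[0] = b[0] - 2.0 * b[1] + b[2]
    d2[-1] = b[-1] - 2.0 * b[-2] + b[-3]
    return d2


def cpr(b: np.ndarray) -> float:
    """Curvature-to-power ratio ``||b''|| / ||b||^2`` of a baseline.

    Zero for any affine ``b``; raises :class:`UndefinedCPRError` for an
    identically zero ``b``.
    """
    b = np.asarray(b, dtype=float)
    if b.size < 3:
        raise ValueError("need at least 3 samples to form b''")
    power = float(np.linalg.norm(b) ** 2)
    if power == 0.0:
        raise UndefinedCPRError("CPR undefined for an all-zero baseline")
    return float(np.linalg.norm(_second_difference(b))) / power


def cpr_profile(
    decomposition: Decomposition, channel_range: tuple[int, int] | None = None
) -> np.ndarray:
    """CPR of the candidate baseline vs number of excluded IMFs.

    Entry ``j`` scores the baseline formed by IMFs ``j+1..m`` plus the
    remainder, i.e. after excluding the ``j`` fastest IMFs
    (``j = 0 .. m``).  ``channel_range`` optionally restricts the CPR
    evaluation to a half-open channel slice (e.g. the peaks region of a
    windowed spectrum).  Undefined entries (all-zero candidate) are NaN.
    """
    m = decomposition.n_imfs
    candidate = decomposition.remainder.copy()
    profile = np.empty(m + 1)
    sl = slice(None) if channel_range is None else slice(*channel_range)

    def _score(v: np.ndarray) -> float:
        try:
            return cpr(v[sl])
        except UndefinedCPRError:
            return np.nan

    profile[m] = _score(candidate)
    for j in range(m - 1, -1, -1):
        candidate += decomposition.imfs[j]
        profile[j] = _score(candidate)
    return profile


def select_split(profile: np.ndarray, n_nonoscillating: int = 0) -> int:
    """Auto-select the split from a CPR profile.

    Returns the index ``j`` (number of signal IMFs) whose profile point
    exhibits the largest jump from the preceding point, excluding the
    jumps that involve dropping one of the last ``n_nonoscillating``
    components; ties break toward smaller ``j``.  CPR profiles decay
    over several decades, so jumps are measured on the logarithmic
    scale (the largest multiplicative drop), which is how a
    discontinuity presents itself on the log-scale plots the profile is
    normally inspected on.
    """
    profile = np.asarray(profile, dtype=float)
    if profile.size < 2:
        raise SplitSelectionError("profile too short to select a split")
    if n_nonoscillating < 0:
        raise ValueError("n_nonoscillating must be >= 0")
    with np.errstate(invalid="ignore"):
        finite = profile[np.isfinite(profile)]
        floor = finite.max() * 1e-15 if finite.size and finite.max() > 0 else 1e-300
        logs = np.log(np.maximum(profile, floor))
        logs[~np.isfinite(profile)] = np.nan
    jumps = np.abs(np.diff(logs))  # jumps[j-1] involves profile[j]
    hi = jumps.size - n_nonoscillating
    eligible = jumps[:hi]
    if eligible.size == 0 or not np.any(np.isfinite(eligible)):
        raise SplitSelectionError("no eligible CPR jump to select")
    return int(np.nanargmax(eligible)) + 1


def split(decomposition: Decomposition, k_signal: int) -> BaselineSplit:
    """Assign the ``k_signal`` fastest IMFs to the signal, the rest plus
    the remainder to the baseline."""
    m = decomposition.n_imfs
    if not 0 <= k_signal <= m:
        raise ValueError(f"k_signal must be in [0, {m}], got {k_signal}")
    n = decomposition.input_length
    signal = np.zeros(n)
    for imf in decomposition.imfs[:k_signal]:
        signal += imf
    baseline = decomposition.remainder.copy()
    for imf in decomposition.imfs[k_signal:]:
        baseline += imf
    return BaselineSplit(
        k_signal=k_signal,
        cpr_profile=cpr_profile(decomposition),
        signal_estimate=signal,
        baseline_estimate=baseline,
        auto_selected=False,
        decomposition=decomposition,
    )


def apply_window(spectrum: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Multiply the spectrum by a half-period sine window.

    The window is zero at both endpoints (making the product periodic
    at the boundaries, as circular filtering assumes) and one at the
    centre.  Returns ``(windowed, window)``.
    """
    y = np.asarray(spectrum, dtype=float)
    n = y.size
    if n < 3:
        raise ValueError("spectrum must have at least 3 samples")
    window = np.sin(np.pi * np.arange(n) / (n - 1))
    window[0] = 0.0
    window[-1] = 0.0
    return y * window, window


def correct(
    spectrum: np.ndarray,
    config: FIFConfig | None = None,
    use_window: bool = False,
    k_override: int | None = None,
    cpr_range: tuple[int, int] | None = None,
) -> BaselineSplit:
    """End-to-end baseline correction of a real spectrum.

    Decomposes the (optionally windowed) spectrum, scores the CPR
    profile and auto-selects the split: the dominant (log-scale) CPR
    discontinuity is located, skipping trailing non-oscillating
    components and everything past the profile's first rise, and the
    baseline keeps the component at the discontinuity together with all
    slower ones (see the methods note for the rationale).  With
    ``use_window`` the estimates refer to the windowed domain; no
    division by the window is attempted near its zeros.  ``k_override``
    bypasses the auto-selection.
    """
    y = np.asarray(spectrum, dtype=float)
    window = None
    if use_window:
        y, window = apply_window(y)
    dec = decompose(y, config)
    profile = cpr_profile(dec, channel_range=cpr_range)

    if k_override is not None:
        result = split(dec, k_override)
        result.auto_selected = False
    else:
        n_nonosc = 0
        for imf in reversed(dec.imfs):
            if is_trend(imf):
                n_nonosc += 1
            else:
                break
        # Once the profile starts rising, further exclusions strip so
        # much power from the candidate that its CPR grows again: those
        # candidates are not smoother baselines, so the discontinuity
        # search stops at the first rise (falling back to the full
        # range if that leaves nothing to choose from).
        rises = np.where(np.diff(profile) > 0)[0]
        n_excl = n_nonosc
        if rises.size:
            n_excl = max(n_nonosc, dec.n_imfs - int(rises[0]))
        try:
            j_star = select_split(profile, n_nonoscillating=n_excl)
        except SplitSelectionError:
            try:
                j_star = select_split(profile, n_nonoscillating=n_nonosc)
            except SplitSelectionError:
                # no usable jump (e.g. trend-only decomposition):
                # everything is baseline, flagged as non-automatic for
                # manual review
                result = split(dec, 0)
                result.auto_selected = False
                result.cpr_profile = profile
                result.window = window
                return result
        # The component at the discontinuity carries the slowest
        # non-smooth content (the distortion itself, or the slow residue
        # of the peaks): the smoothest baseline that still contains the
        # distortion keeps it, so the baseline gets the boundary
        # component and the signal keeps the j*-1 fastest.  The fastest
        # component (noise at the sampling scale) is never baseline.
        k = max(1, j_star - 1)
        result = split(dec, k)
        result.auto_selected = True
    result.cpr_profile = profile
    result.window = window
    return result


def complex_baseline(baseline_real: np.ndarray) -> np.ndarray:
    """Recover the complex baseline from the real-channel correction.

    Returns ``b + i H(b)`` with ``H`` the discrete Hilbert transform,
    so the imaginary part carries the dispersion-mode counterpart of the
    absorption-mode baseline.  The real part equals the input exactly.
    """
    b = np.asarray(baseline_real, dtype=float)
    if b.size == 0:
        return b.astype(complex)
    analytic = scipy.signal.hilbert(b)
    return b + 1j * analytic.imag
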