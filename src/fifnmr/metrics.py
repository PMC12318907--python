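"""Figures of merit for baseline reconstruction and the benchmark grid runner.

The benchmark literature scores an estimated baseline ``Y_hat`` against
the true baseline ``Y`` over a channel region ``[ns, nf]`` with

    r2      = SSreg / SStot,
    SSreg   = sum_i (Y_hat_i - Y_mean)^2,
    SStot   = sum_i (Y_i     - Y_mean)^2,
    chi2    = sum_i (Y_hat_i - Y_i)^2          (all 1001 channels),

where ``Y_mean`` is the mean of the true baseline over the region.
This ``r2`` is a ratio of sums of squares and cannot be negative, so a
signed product-moment (Pearson) correlation is computed alongside it;
comparisons that need a sign (anti-correlated estimates) use the
Pearson variant.  The grid runner simulates a full SBR x SNR x (slope or
dead-time) grid per spectral-width/distortion cell, corrects every
instance and averages the figures of merit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .baseline import correct
from .fif import FIFConfig
from .simulate import BenchmarkInstance, BenchmarkSpec, build_benchmark

__all__ = [
    "FoMResult",
    "UNCONGESTED",
    "CONGESTED",
    "r2_printed",
    "pearson",
    "chi2",
    "integral_rmsd",
    "evaluate_instance",
    "run_grid",
]

# inclusive channel regions of the 1001-channel benchmark block:
# three peaks below channel 560, four peaks above
UNCONGESTED = (0, 560)
CONGESTED = (561, 1000)


@dataclass
class FoMResult:
    """Figures of merit of one corrected benchmark instance."""

    r2_total: float
    r2_uncongested: float
    r2_congested: float
    pearson_total: float
    chi2: float
    pearson_signal: float = np.nan
    integral_rmsd: float | None = None


def _region(y: np.ndarray, start: int, end: int) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if not 0 <= start <= end < y.size:
        raise ValueError(f"region [{start}, {end}] out of bounds for length {y.size}")
    return y[start : end + 1]


def r2_printed(y_true: np.ndarray, y_est: np.ndarray, start: int, end: int) -> float:
    """``SSreg / SStot`` over the inclusive channel region ``[start, end]``.

    Returns NaN (undefined) when the true baseline is flat over the
    region (``SStot = 0``) instead of raising, so grid averages can
    simply skip it.
    """
    yt = _region(y_true, start, end)
    ye = _region(y_est, start, end)
    if yt.size != ye.size:
        raise ValueError("y_true and y_est must have equal length")
    mean = yt.mean()
    ss_tot = float(np.sum((yt - mean) ** 2))
    if ss_tot == 0.0:
        return np.nan
    ss_reg = float(np.sum((ye - mean) ** 2))
    return ss_reg / ss_tot


def pearson(y_true: np.ndarray, y_est: np.ndarray, start: int, end: int) -> float:
    """Signed product-moment correlation over ``[start, end]``; NaN if
    either input has zero variance there."""
    yt = _region(y_true, start, end)
    ye = _region(y_est, start, end)
    if yt.size != ye.size:
        raise ValueError("y_true and y_est must have equal length")
    if np.ptp(yt) == 0.0 or np.ptp(ye) == 0.0:
        return np.nan
    return float(np.corrcoef(yt, ye)[0, 1])


def chi2(y_true: np.ndarray, y_est: np.ndarray) -> float:
    """Sum of squared differences over all channels, no normalization."""
    yt = np.asarray(y_true, dtype=float)
    ye = np.asarray(y_est, dtype=float)
    if yt.shape != ye.shape:
        raise ValueError("y_true and y_est must have equal length")
    return float(np.sum((ye - yt) ** 2))


def integral_rmsd(
    peak_regions: list[tuple[int, int]],
    corrected: np.ndarray,
    reference: np.ndarray,
) -> float:
    """RMS over peaks of the peak-integral differences.

    Each region is an inclusive channel interval; the regions must be
    disjoint and within bounds.  The integral is the plain channel sum.
    """
    corrected = np.asarray(corrected, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if corrected.shape != reference.shape:
        raise ValueError("corrected and reference must have equal length")
    regions = sorted(peak_regions)
    for (a1, b1), (a2, _) in zip(regions, regions[1:]):
        if a2 <= b1:
            raise ValueError("peak regions must be disjoint")
    diffs = []
    for a, b in regions:
        if not 0 <= a <= b < corrected.size:
            raise ValueError(f"region [{a}, {b}] out of bounds")
        diffs.append(corrected[a : b + 1].sum() - reference[a : b + 1].sum())
    return float(np.sqrt(np.mean(np.square(diffs))))


def evaluate_instance(
    instance: BenchmarkInstance,
    config: FIFConfig | None = None,
    use_window: bool | None = None,
) -> FoMResult:
    """Correct one benchmark instance and score it.

    Windowing is applied when the instance belongs to the windowed
    family (unless overridden), except for flat baselines where it
    brings nothing and is skipped; scores of windowed runs are computed
    in the windowed domain against window-multiplied truths, because a
    windowed baseline is what gets reconstructed.
    """
    spec = instance.spec
    if use_window is None:
        use_window = spec.distortion == "asymmetric_windowed" and spec.slope != 0.0
    result = correct(instance.spectrum, config=config, use_window=use_window)

    sl = instance.fom_slice
    true_base = instance.true_baseline
    true_sig = instance.true_signal
    if use_window:
        true_base = true_base * result.window
        true_sig = true_sig * result.window
    bt = true_base[sl]
    be = result.baseline_estimate[sl]
    st = true_sig[sl]
    se = result.signal_estimate[sl]
    last = spec.n_channels_fom - 1
    return FoMResult(
        r2_total=r2_printed(bt, be, 0, last),
        r2_uncongested=r2_printed(bt, be, *UNCONGESTED),
        r2_congested=r2_printed(bt, be, *CONGESTED),
        pearson_total=pearson(bt, be, 0, last),
        chi2=chi2(bt, be),
        pearson_signal=pearson(st, se, 0, last),
    )


_FOM_COLUMNS = [
    "r2_total",
    "r2_uncongested",
    "r2_congested",
    "pearson_total",
    "chi2",
    "pearson_signal",
]


def run_grid(
    specs: list[BenchmarkSpec], config: FIFConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate, correct and score a list of benchmark specs.

    Returns ``(summary, results)``: ``results`` holds one row per
    instance with its parameters and figures of merit; ``summary``
    averages the figures of merit per ``(sw_ppm, distortion)`` cell
    (NaN entries from undefined figures are excluded and counted).
    """
    if not specs:
        raise ValueError("spec list must not be empty")
    rows = []
    for spec in specs:
        instance = build_benchmark(spec)
        fom = evaluate_instance(instance, config=config)
        row = {
            "sw_ppm": spec.sw_ppm,
            "distortion": spec.distortion,
            "sbr": spec.sbr,
            "snr": spec.snr,
            "slope": spec.slope,
            "dead_points": spec.dead_points,
            "seed": spec.seed,
        }
        row.update({c: getattr(fom, c) for c in _FOM_COLUMNS})
        rows.append(row)
    results = pd.DataFrame(rows)
    grouped = results.groupby(["sw_ppm", "distortion"])
    summary = grouped[_FOM_COLUMNS].mean()
    for col in _FOM_COLUMNS:
        summary[f"n_undefined_{col}"] = grouped[col].apply(lambda s: int(s.isna().sum()))
    summary["n_instances"] = grouped.size()
    return summary.reset_index(), results
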