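"""Welch power-spectral-density estimation and band-power extraction.

Applies identically to channel signals and source time courses: the PSD
is the average of tapered periodograms of 50%-overlapping 2-s Hamming
windows, one-sided and density-normalized so its integral over frequency
approximates the signal variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .core import ConditionSegment, InvalidBandError, InvalidInputError


@dataclass
class SpectrumSet:
    """One-sided PSD per location on a uniform frequency grid.

    psd is [locations x frequency bins] in signal**2/Hz.
    """

    psd: np.ndarray
    freqs: np.ndarray
    window_sec: float
    overlap: float
    n_windows: int

    @property
    def resolution(self) -> float:
        return 1.0 / self.window_sec


@dataclass
class BandPower:
    """Mean PSD over a closed frequency band, per location."""

    power: np.ndarray
    band: tuple[float, float]


def welch_psd(
    seg: ConditionSegment,
    window_sec: float = 2.0,
    overlap: float = 0.5,
    taper: str = "hamming",
) -> SpectrumSet:
    """Welch PSD of every channel/vertex of a segment.

    No detrending (DC removal happens upstream) and no zero-padding, so a
    2-s window at fs 512 is a 1024-point transform with 0.5-Hz bins.
    """
    nperseg = int(round(window_sec * seg.fs))
    if seg.n_samples < nperseg:
        raise InvalidInputError(
            f"segment ({seg.n_samples} samples) shorter than one "
            f"{window_sec}-s window ({nperseg} samples)"
        )
    noverlap = int(round(overlap * nperseg))
    freqs, psd = sps.welch(
        seg.data, fs=seg.fs, window=taper, nperseg=nperseg,
        noverlap=noverlap, detrend=False, scaling="density", axis=-1,
    )
    step = nperseg - noverlap
    n_windows = (seg.n_samples - noverlap) // step
    return SpectrumSet(psd, freqs, window_sec, overlap, int(n_windows))


def band_power(spec: SpectrumSet, lo: float = 8.0, hi: float = 13.0) -> BandPower:
    """Arithmetic mean of the PSD over all bins with lo <= f <= hi."""
    mask = (spec.freqs >= lo) & (spec.freqs <= hi)
    if not mask.any():
        raise InvalidBandError(f"no frequency bins in [{lo}, {hi}] Hz")
    return BandPower(spec.psd[..., mask].mean(axis=-1), (lo, hi))


def band_integral(spec: SpectrumSet, lo: float, hi: float) -> np.ndarray:
    """Trapezoidal integral of the PSD over [lo, hi] (power, signal**2)."""
    mask = (spec.freqs >= lo) & (spec.freqs <= hi)
    if mask.sum() < 2:
        raise InvalidBandError(f"need >= 2 bins in [{lo}, {hi}] Hz to integrate")
    return np.trapezoid(spec.psd[..., mask], spec.freqs[mask], axis=-1)
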