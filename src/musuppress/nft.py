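"""Four-band neurofeedback threshold protocol.

The feedback signal is a derived channel (sum of C3 and C4).  Per-band
amplitudes are estimated by zero-phase band-pass filtering followed by a
sliding-window RMS (x sqrt(2), amplitude convention).  Success requires
all four bands to stay strictly below their thresholds for at least a
minimum hold time (1 s); thresholds are calibrated on an initial baseline
period as a common quantile of the band amplitude distributions, found by
bisection so the baseline success fraction lands in a target range
(75-80% for early sessions, 65-75% for late ones).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.ndimage import uniform_filter1d


@lru_cache(maxsize=64)
def _bandpass_sos(fs: float, lo: float, hi: float) -> np.ndarray:
    return sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")

from .core import CalibrationError, InconsistentInputError, InvalidBandError


@dataclass(frozen=True)
class BandDefinition:
    name: str
    lo: float
    hi: float


#: the four trained bands
DEFAULT_BANDS = (
    BandDefinition("theta", 4.0, 7.0),
    BandDefinition("mu", 8.0, 13.0),
    BandDefinition("beta", 14.0, 30.0),
    BandDefinition("high_beta", 20.0, 40.0),
)


@dataclass
class NFTSession:
    """One training session: per-band amplitude series plus span bookkeeping.

    Spans are half-open [start, stop) sample ranges into the amplitude
    series; montage_signal is the derived C3 + C4 channel the amplitudes
    were computed from (may be omitted once amplitudes exist).
    """

    amplitudes: dict[str, np.ndarray]
    fs: float
    baseline_span: tuple[int, int]
    feedback_span: tuple[int, int]
    thresholds: dict[str, float] = field(default_factory=dict)
    montage_signal: np.ndarray | None = None
    success_fraction: float = np.nan


def c3c4_montage(c3: np.ndarray, c4: np.ndarray) -> np.ndarray:
    """The trained derived channel: sum of the C3 and C4 signals."""
    c3 = np.asarray(c3, dtype=float)
    c4 = np.asarray(c4, dtype=float)
    if c3.shape != c4.shape:
        raise InconsistentInputError("C3 and C4 series differ in length")
    return c3 + c4


def band_amplitude(
    signal: np.ndarray,
    band: BandDefinition,
    fs: float,
    window_sec: float = 0.25,
) -> np.ndarray:
    """Instantaneous band amplitude: zero-phase band-pass, sliding RMS.

    The RMS is scaled by sqrt(2) so a pure sinusoid of amplitude A in the
    band reads ~A.  Output is on the input sampling grid, edge-padded by
    the filter/window (nearest-sample extension).
    """
    if fs <= 2 * band.hi:
        raise InvalidBandError(
            f"band {band.name} upper edge {band.hi} Hz at or above Nyquist"
        )
    x = np.asarray(signal, dtype=float)
    y = sps.sosfiltfilt(_bandpass_sos(fs, band.lo, band.hi), x)
    win = max(int(round(window_sec * fs)), 1)
    ms = uniform_filter1d(y**2, size=win, mode="nearest")
    return np.sqrt(2.0 * np.clip(ms, 0.0, None))


def _stack(amplitudes: dict[str, np.ndarray],
           thresholds: dict[str, float]) -> tuple[np.ndarray, np.ndarray]:
    names = list(amplitudes)
    lengths = {len(amplitudes[k]) for k in names}
    if len(lengths) != 1:
        raise InconsistentInputError("band amplitude series differ in length")
    missing = [k for k in names if k not in thresholds]
    if missing:
        raise InconsistentInputError(f"thresholds missing for bands {missing}")
    amps = np.vstack([np.asarray(amplitudes[k], dtype=float) for k in names])
    thr = np.array([float(thresholds[k]) for k in names])
    return amps, thr


def success_fraction(
    amplitudes: dict[str, np.ndarray],
    thresholds: dict[str, float],
    fs: float,
    min_hold: float = 1.0,
) -> float:
    """Fraction of samples inside runs of >= min_hold seconds where every
    band is strictly below its threshold.

    min_hold = 0 reduces to the plain below-threshold sample fraction.
    """
    amps, thr = _stack(amplitudes, thresholds)
    below = np.all(amps < thr[:, None], axis=0)
    n = below.size
    if n == 0:
        raise InconsistentInputError("empty amplitude series")
    min_run = max(int(np.ceil(min_hold * fs)), 1)
    # run-length encode the boolean series
    edges = np.flatnonzero(np.diff(below.astype(np.int8)))
    starts = np.concatenate(([0], edges + 1))
    stops = np.concatenate((edges + 1, [n]))
    good = 0
    for s, e in zip(starts, stops):
        if below[s] and (e - s) >= min_run:
            good += e - s
    return good / n


def calibrate_thresholds(
    baseline_amplitudes: dict[str, np.ndarray],
    fs: float,
    target: tuple[float, float] = (0.75, 0.80),
    min_hold: float = 1.0,
    max_iter: int = 60,
) -> tuple[dict[str, float], float]:
    """Set per-band thresholds as a common baseline-amplitude quantile q,
    with q found by bisection so the baseline success fraction falls in
    target.  Returns (thresholds, achieved_fraction).

    success_fraction is monotone non-decreasing in every threshold, hence
    in q, so bisection is exact up to the step structure of the data;
    a target the data cannot reach raises CalibrationError.
    """
    t_lo, t_hi = target
    if not 0.0 <= t_lo < t_hi <= 1.0:
        raise CalibrationError(f"invalid target range {target}")

    def thresholds_at(q: float) -> dict[str, float]:
        return {k: float(np.quantile(np.asarray(v, dtype=float), q))
                for k, v in baseline_amplitudes.items()}

    def achieved(q: float) -> tuple[dict[str, float], float]:
        thr = thresholds_at(q)
        return thr, success_fraction(baseline_amplitudes, thr, fs, min_hold)

    thr_hi, f_hi = achieved(1.0)
    if f_hi < t_lo:
        raise CalibrationError(
            f"target {target} unreachable: success at q=1 is {f_hi:.3f} "
            "(degenerate or heavily tied amplitudes)"
        )
    if f_hi <= t_hi:
        return thr_hi, f_hi
    lo, hi = 0.0, 1.0
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        thr, f_mid = achieved(mid)
        if f_mid < t_lo:
            lo = mid
        elif f_mid > t_hi:
            hi = mid
        else:
            return thr, f_mid
    raise CalibrationError(
        f"bisection did not land in {target}; last fraction {f_mid:.3f} at "
        f"q={mid:.4f} — amplitude distribution too discrete for the target"
    )


def session_course(sessions: list[NFTSession]) -> pd.DataFrame:
    """Per-session, per-band feedback-minus-baseline mean amplitudes.

    Long-format table (session, band, baseline_mean, feedback_mean,
    difference) ready for a session x band x feedback-condition
    repeated-measures ANOVA.
    """
    rows = []
    for i, sess in enumerate(sessions):
        b0, b1 = sess.baseline_span
        f0, f1 = sess.feedback_span
        if b1 <= b0 or f1 <= f0:
            raise InconsistentInputError(f"session {i} has an empty span")
        for band, series in sess.amplitudes.items():
            series = np.asarray(series, dtype=float)
            if b1 > series.size or f1 > series.size:
                raise InconsistentInputError(
                    f"session {i} span exceeds series length"
                )
            base = float(series[b0:b1].mean())
            feed = float(series[f0:f1].mean())
            rows.append({"session": i, "band": band, "baseline_mean": base,
                         "feedback_mean": feed, "difference": feed - base})
    return pd.DataFrame(rows)
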