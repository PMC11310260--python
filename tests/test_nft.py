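import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from musuppress.core import (
    CalibrationError,
    InconsistentInputError,
    InvalidBandError,
)
from musuppress.nft import (
    DEFAULT_BANDS,
    BandDefinition,
    NFTSession,
    band_amplitude,
    c3c4_montage,
    calibrate_thresholds,
    session_course,
    success_fraction,
)

MU = BandDefinition("mu", 8.0, 13.0)
THETA = BandDefinition("theta", 4.0, 7.0)


def brute_force_success(amps: dict, thresholds: dict, fs: float,
                        min_hold: float) -> float:
    """Independent run-scan oracle: walk the samples, count those lying in
    any maximal all-below run of at least min_hold seconds."""
    names = list(amps)
    n = len(amps[names[0]])
    below = [all(amps[k][i] < thresholds[k] for k in names) for i in range(n)]
    min_run = max(int(np.ceil(min_hold * fs)), 1)
    good = 0
    i = 0
    while i < n:
        if not below[i]:
            i += 1
            continue
        j = i
        while j < n and below[j]:
            j += 1
        if j - i >= min_run:
            good += j - i
        i = j
    return good / n


class TestDefaultBands:
    def test_four_trained_bands(self):
        bands = {b.name: (b.lo, b.hi) for b in DEFAULT_BANDS}
        assert bands == {"theta": (4.0, 7.0), "mu": (8.0, 13.0),
                         "beta": (14.0, 30.0), "high_beta": (20.0, 40.0)}


class TestBandAmplitude:
    def test_pure_mu_sinusoid_reads_its_amplitude(self):
        fs = 256.0
        t = np.arange(int(30 * fs)) / fs
        x = 2.5 * np.sin(2 * np.pi * 10.0 * t)
        amp = band_amplitude(x, MU, fs)
        steady = amp[int(5 * fs):-int(5 * fs)]
        assert np.median(steady) == pytest.approx(2.5, rel=0.02)

    def test_zero_signal_zero_amplitude(self):
        amp = band_amplitude(np.zeros(1024), MU, 256.0)
        assert np.allclose(amp, 0.0)

    def test_out_of_band_suppression(self):
        # 10-Hz sinusoid must barely register in the theta band (>= 20 dB)
        fs = 256.0
        t = np.arange(int(30 * fs)) / fs
        x = np.sin(2 * np.pi * 10.0 * t)
        mu_amp = np.median(band_amplitude(x, MU, fs)[512:-512])
        th_amp = np.median(band_amplitude(x, THETA, fs)[512:-512])
        assert 20 * np.log10(mu_amp / th_amp) >= 20.0

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(InvalidBandError):
            band_amplitude(np.zeros(100), BandDefinition("hb", 20, 40), 64.0)

    def test_montage_is_sum(self, rng):
        c3 = rng.standard_normal(100)
        c4 = rng.standard_normal(100)
        assert np.allclose(c3c4_montage(c3, c4), c3 + c4)
        with pytest.raises(InconsistentInputError):
            c3c4_montage(c3, c4[:50])


class TestSuccessFraction:
    def test_infinite_thresholds_full_success(self, rng):
        amps = {"mu": rng.random(256), "theta": rng.random(256)}
        thr = {"mu": np.inf, "theta": np.inf}
        assert success_fraction(amps, thr, fs=64.0) == 1.0

    def test_zero_thresholds_zero_success(self, rng):
        amps = {"mu": rng.random(256) + 0.1}
        assert success_fraction(amps, {"mu": 0.0}, fs=64.0) == 0.0

    def test_hand_constructed_runs(self):
        fs = 4.0  # min_hold 1 s -> runs must be >= 4 samples
        mu = np.array([0.1] * 5 + [9.0] + [0.1] * 3 + [9.0] + [0.1] * 6,
                      dtype=float)
        amps = {"mu": mu}
        thr = {"mu": 1.0}
        # runs: 5 (counts), 3 (too short), 6 (counts) -> 11/16
        assert success_fraction(amps, thr, fs, min_hold=1.0) == 11 / 16

    def test_matches_brute_force_oracle(self, rng):
        fs = 32.0
        amps = {b.name: np.abs(rng.standard_normal(640)) for b in DEFAULT_BANDS}
        thr = {b.name: float(np.quantile(amps[b.name], 0.8))
               for b in DEFAULT_BANDS}
        mine = success_fraction(amps, thr, fs, min_hold=0.25)
        assert mine == brute_force_success(amps, thr, fs, 0.25)

    def test_min_hold_zero_is_plain_fraction(self, rng):
        amps = {"mu": rng.random(500)}
        thr = {"mu": 0.4}
        plain = float(np.mean(amps["mu"] < 0.4))
        assert success_fraction(amps, thr, 64.0, min_hold=0.0) == plain

    def test_length_mismatch_rejected(self, rng):
        amps = {"mu": rng.random(100), "theta": rng.random(99)}
        with pytest.raises(InconsistentInputError):
            success_fraction(amps, {"mu": 1, "theta": 1}, 64.0)

    @settings(max_examples=25, deadline=None)
    @given(bump=st.floats(0.0, 2.0))
    def test_monotone_in_thresholds(self, bump):
        rng = np.random.default_rng(5)
        amps = {"mu": np.abs(rng.standard_normal(400)),
                "beta": np.abs(rng.standard_normal(400))}
        base = {"mu": 0.8, "beta": 0.8}
        raised = {"mu": 0.8 + bump, "beta": 0.8}
        f0 = success_fraction(amps, base, 32.0)
        f1 = success_fraction(amps, raised, 32.0)
        assert f1 >= f0


class TestCalibration:
    def _baseline(self, rng, n=7680, n_bands=4):
        # smooth positive amplitude series (AR-filtered absolute noise)
        from scipy.ndimage import uniform_filter1d

        names = [b.name for b in DEFAULT_BANDS][:n_bands]
        return {
            name: np.abs(uniform_filter1d(rng.standard_normal(n), 9)) + 0.01
            for name in names
        }

    def test_single_band_no_hold_converges_near_quantile(self, rng):
        amps = {"mu": self._baseline(rng)["mu"]}
        thr, achieved = calibrate_thresholds(amps, fs=64.0,
                                             target=(0.75, 0.80), min_hold=0.0)
        assert 0.75 <= achieved <= 0.80
        # with min_hold 0 the common quantile is the success fraction itself
        direct = float(np.mean(amps["mu"] < thr["mu"]))
        assert direct == pytest.approx(achieved)

    def test_four_band_calibration_self_consistent(self, rng):
        amps = self._baseline(rng)
        thr, achieved = calibrate_thresholds(amps, fs=64.0,
                                             target=(0.65, 0.75), min_hold=1.0)
        assert 0.65 <= achieved <= 0.75
        recomputed = success_fraction(amps, thr, 64.0, min_hold=1.0)
        assert recomputed == pytest.approx(achieved)

    def test_constant_amplitudes_fail(self):
        amps = {"mu": np.full(1000, 2.0)}
        with pytest.raises(CalibrationError):
            calibrate_thresholds(amps, fs=64.0)

    def test_recalibration_idempotent(self, rng):
        amps = self._baseline(rng)
        thr, achieved = calibrate_thresholds(amps, fs=64.0,
                                             target=(0.75, 0.80))
        again = success_fraction(amps, thr, 64.0, min_hold=1.0)
        assert 0.75 <= again <= 0.80


class TestSessionCourse:
    def _session(self, amps, fs=64.0):
        n = len(next(iter(amps.values())))
        return NFTSession(amplitudes=amps, fs=fs, baseline_span=(0, n // 4),
                          feedback_span=(n // 4, n))

    def test_identical_spans_zero_difference(self, rng):
        x = rng.random(400)
        sess = NFTSession(amplitudes={"mu": x}, fs=64.0,
                          baseline_span=(0, 100), feedback_span=(0, 100))
        course = session_course([sess])
        assert course.difference.iloc[0] == 0.0

    def test_uniform_offset_recovered(self, rng):
        base = rng.random(100) + 1.0
        feed = base - 0.5
        sess = NFTSession(amplitudes={"mu": np.concatenate([base, feed])},
                          fs=64.0, baseline_span=(0, 100),
                          feedback_span=(100, 200))
        course = session_course([sess])
        assert course.difference.iloc[0] == pytest.approx(-0.5)

    def test_declining_mu_trend_recovered(self, rng):
        # 15 sessions with linearly declining feedback-minus-baseline mu
        sessions = []
        for k in range(15):
            base = np.full(100, 2.0) + 0.01 * rng.standard_normal(100)
            feed = base - 0.03 * k + 0.01 * rng.standard_normal(100)
            sessions.append(NFTSession(
                amplitudes={"mu": np.concatenate([base, feed])}, fs=64.0,
                baseline_span=(0, 100), feedback_span=(100, 200)))
        course = session_course(sessions)
        slope = np.polyfit(course.session, course.difference, 1)[0]
        assert slope < 0

    def test_missing_span_rejected(self, rng):
        sess = NFTSession(amplitudes={"mu": rng.random(100)}, fs=64.0,
                          baseline_span=(0, 0), feedback_span=(0, 100))
        with pytest.raises(InconsistentInputError):
            session_course([sess])
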