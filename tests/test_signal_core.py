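"""Filtering, velocity and stable-value extraction contracts."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import bridgepress as bp
from bridgepress.signal_core import find_zero_crossing
from bridgepress.types import PressureTrace, TrialWindow

FS = 28.0


def _trace(samples, fs=FS, t0=0.0, channel="RK"):
    return PressureTrace(channel, fs, t0, np.asarray(samples, dtype=float))


def _sine(freq_hz, duration_s=30.0, fs=FS, amplitude=1.0, offset=0.0):
    t = np.arange(int(duration_s * fs)) / fs
    return _trace(offset + amplitude * np.sin(2 * np.pi * freq_hz * t)), t


def _fit_amplitude(samples, t, freq_hz, edge_s=5.0, fs=FS):
    """Least-squares sinusoid amplitude on interior samples."""
    k = int(edge_s * fs)
    y, tt = samples[k:-k], t[k:-k]
    design = np.column_stack(
        [np.sin(2 * np.pi * freq_hz * tt), np.cos(2 * np.pi * freq_hz * tt), np.ones_like(tt)]
    )
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return float(np.hypot(coef[0], coef[1]))


class TestFilter:
    def test_constant_trace_passes_unchanged(self):
        out = bp.filter_dualpass(_trace(np.full(300, 50.0)))
        np.testing.assert_allclose(out.samples, 50.0, atol=1e-9)

    def test_amplitude_halved_at_cutoff(self):
        """Each Butterworth pass attenuates the cutoff frequency to
        2^(-1/2); forward-backward squares it to exactly 1/2."""
        trace, t = _sine(2.0)
        out = bp.filter_dualpass(trace)
        amp = _fit_amplitude(out.samples, t, 2.0)
        assert amp == pytest.approx(0.5, rel=0.02)

    def test_passband_nearly_transparent(self):
        trace, t = _sine(0.1, duration_s=60.0)
        out = bp.filter_dualpass(trace)
        assert _fit_amplitude(out.samples, t, 0.1) > 0.99

    def test_magnitude_response_monotone_non_increasing(self):
        freqs = [0.25, 0.5, 1.0, 1.5, 2.0, 3.0, 5.0, 8.0, 12.0]
        amps = []
        for f in freqs:
            trace, t = _sine(f, duration_s=40.0)
            amps.append(_fit_amplitude(bp.filter_dualpass(trace).samples, t, f))
        assert all(a >= b - 1e-6 for a, b in zip(amps, amps[1:]))

    def test_time_reversal_symmetry(self):
        rng = np.random.default_rng(0)
        x = np.cumsum(rng.normal(size=600)) + 30.0
        fwd = bp.filter_dualpass(_trace(x)).samples
        rev = bp.filter_dualpass(_trace(x[::-1])).samples[::-1]
        k = int(2 * FS)  # interior: away from reflection padding
        np.testing.assert_allclose(fwd[k:-k], rev[k:-k], atol=1e-8)

    def test_cutoff_at_or_above_nyquist_rejected(self):
        trace = _trace(np.zeros(100) + 1.0)
        with pytest.raises(ValueError, match="Nyquist"):
            bp.filter_dualpass(trace, bp.FilterSpec(cutoff_hz=14.0))

    def test_too_short_trace_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            bp.filter_dualpass(_trace([1.0, 2.0, 3.0]))


class TestVelocity:
    def test_linear_ramp_exact(self):
        t = np.arange(100) / FS
        v = bp.compute_velocity(_trace(10.0 + 5.0 * t))
        np.testing.assert_allclose(v.values, 5.0, atol=1e-9)

    def test_constant_zero(self):
        v = bp.compute_velocity(_trace(np.full(50, 7.0)))
        np.testing.assert_allclose(v.values, 0.0, atol=1e-12)

    def test_quadratic_exact_on_interior(self):
        """Central differences are exact for polynomials up to degree 2."""
        t = np.arange(200) / FS
        v = bp.compute_velocity(_trace(t**2))
        np.testing.assert_allclose(v.values[1:-1], 2.0 * t[1:-1], atol=1e-9)

    def test_short_input_rejected(self):
        with pytest.raises(ValueError):
            bp.compute_velocity(_trace([1.0, 2.0]))


class TestZeroCrossing:
    @settings(derandomize=True, max_examples=300)
    @given(
        values=st.lists(
            st.floats(min_value=-10, max_value=10, allow_nan=False), min_size=2, max_size=200
        ),
        data=st.data(),
    )
    def test_matches_bruteforce_linear_scan(self, values, data):
        v = np.asarray(values)
        start = data.draw(st.integers(min_value=0, max_value=len(values) - 1))
        expected = None
        s0 = np.sign(v[start])
        if s0 == 0:
            expected = start
        else:
            for k in range(start + 1, len(v)):
                if np.sign(v[k]) != s0:
                    expected = k
                    break
        assert find_zero_crossing(v, start) == expected


def _single_trial(delta, baseline=30.0, ramp=1.5, hold=10.0, fs=FS, noise_sd=0.0, seed=0):
    """One isolated trial starting 5 s into a 20 s trace."""
    t = np.arange(int(20 * fs)) / fs
    x = np.clip((t - 5.0) / ramp, 0, 1)
    up = x * x * (3 - 2 * x)
    y = baseline + delta * up
    if noise_sd:
        y = y + np.random.default_rng(seed).normal(0, noise_sd, t.size)
    trace = _trace(y)
    window = TrialWindow("BB", 1, 5.0, hold)
    filtered = bp.filter_dualpass(trace)
    velocity = bp.compute_velocity(filtered)
    return filtered, velocity, window


class TestExtractStableValue:
    def test_noiseless_increase_trial_recovers_plateau(self):
        filtered, velocity, window = _single_trial(+20.0)
        sv = bp.extract_stable_value(filtered, velocity, window, "increase")
        assert sv.valid
        assert sv.value_mmHg == pytest.approx(50.0, abs=0.5)
        assert 5.0 <= sv.t_peak_velocity_s <= 6.5  # inside the ramp
        assert sv.t_zero_cross_s == pytest.approx(6.5, abs=0.3)  # ~ramp end
        assert sv.t_zero_cross_s >= sv.t_peak_velocity_s
        assert sv.avg_window_s[0] == pytest.approx(sv.t_zero_cross_s + 1.0)
        assert sv.avg_window_s[1] - sv.avg_window_s[0] == pytest.approx(4.0)

    def test_noiseless_decrease_trial_recovers_low_plateau(self):
        """A back channel dropping from 12 to 9.3 mmHg is recovered with
        the signed-minimum velocity convention."""
        filtered, velocity, window = _single_trial(-2.7, baseline=12.0)
        sv = bp.extract_stable_value(filtered, velocity, window, "decrease")
        assert sv.valid and sv.direction == "decrease"
        assert sv.value_mmHg == pytest.approx(9.30, abs=0.5)

    def test_auto_direction_resolves_sign(self):
        filtered, velocity, window = _single_trial(-8.0, baseline=20.0)
        sv = bp.extract_stable_value(filtered, velocity, window, "auto")
        assert sv.valid and sv.direction == "decrease"
        assert sv.value_mmHg == pytest.approx(12.0, abs=0.5)

    def test_constant_trace_flagged_no_movement(self):
        filtered, velocity, window = _single_trial(0.0)
        sv = bp.extract_stable_value(filtered, velocity, window, "increase")
        assert not sv.valid and sv.invalid_reason == "no_movement"
        assert np.isnan(sv.value_mmHg)

    def test_short_hold_flagged_window_truncated(self):
        filtered, velocity, _ = _single_trial(+20.0)
        sv = bp.extract_stable_value(
            filtered, velocity, TrialWindow("BB", 1, 5.0, 3.0), "increase"
        )
        assert not sv.valid and sv.invalid_reason == "window_truncated"

    def test_monotone_drift_flagged_no_zero_crossing(self):
        t = np.arange(int(20 * FS)) / FS
        trace = _trace(30.0 + 3.0 * t)  # velocity never returns to zero
        filtered = bp.filter_dualpass(trace)
        velocity = bp.compute_velocity(filtered)
        sv = bp.extract_stable_value(
            filtered, velocity, TrialWindow("BB", 1, 5.0, 10.0), "increase"
        )
        assert not sv.valid and sv.invalid_reason == "no_zero_crossing"

    def test_window_outside_trace_rejected(self):
        filtered, velocity, _ = _single_trial(+20.0)
        with pytest.raises(ValueError, match="outside"):
            bp.extract_stable_value(
                filtered, velocity, TrialWindow("BB", 1, 15.0, 10.0), "increase"
            )

    @pytest.mark.parametrize("shift", [-25.0, 3.7, 100.0])
    def test_shift_equivariance(self, shift):
        """Adding a constant shifts the stable value by that constant and
        leaves every timing mark unchanged."""
        filtered, velocity, window = _single_trial(+20.0, noise_sd=0.5, seed=4)
        base = bp.extract_stable_value(filtered, velocity, window, "increase")
        shifted = filtered.with_samples(filtered.samples + shift)
        sv = bp.extract_stable_value(
            shifted, bp.compute_velocity(shifted), window, "increase"
        )
        assert sv.value_mmHg == pytest.approx(base.value_mmHg + shift, abs=1e-9)
        assert sv.t_peak_velocity_s == base.t_peak_velocity_s
        assert sv.t_zero_cross_s == base.t_zero_cross_s

    def test_zc_search_limit_restricts_search(self):
        """With the crossing search capped shortly after the peak, a slow
        return to zero is no longer found."""
        t = np.arange(int(30 * FS)) / FS
        # velocity stays positive for ~6 s after the cue, then plateaus
        y = 30 + 20 * np.clip((t - 5.0) / 8.0, 0, 1)
        filtered = bp.filter_dualpass(_trace(y))
        velocity = bp.compute_velocity(filtered)
        window = TrialWindow("BB", 1, 5.0, 20.0)
        free = bp.extract_stable_value(filtered, velocity, window, "increase")
        capped = bp.extract_stable_value(
            filtered, velocity, window, "increase", zc_search_limit_s=2.0
        )
        assert free.valid
        assert not capped.valid and capped.invalid_reason == "no_zero_crossing"


class TestSessionExtraction:
    def test_zero_noise_session_recovers_every_plateau(self, zero_noise_session, zero_noise_values):
        assert len(zero_noise_values) == 18 * 4
        for v in zero_noise_values:
            assert v.valid
            truth = zero_noise_session.truth.plateau(v.task, v.trial_index, v.channel)
            assert v.value_mmHg == pytest.approx(truth, abs=0.05)
            assert v.baseline_mmHg is not None

    def test_convention_mode_flags_unloaded_knee_as_no_movement(self, zero_noise_session):
        values = bp.extract_session(
            zero_noise_session.traces, zero_noise_session.windows, direction_mode="convention"
        )
        unloaded = [v for v in values if (v.task, v.channel) in (("URB", "LK"), ("ULB", "RK"))]
        assert unloaded and all(
            (not v.valid and v.invalid_reason == "no_movement") for v in unloaded
        )
        rest = [v for v in values if (v.task, v.channel) not in (("URB", "LK"), ("ULB", "RK"))]
        assert all(v.valid for v in rest)


class TestSummarize:
    def _mk(self, value, valid=True, trial=1):
        return bp.StableValue(
            channel="RK",
            task="BB",
            trial_index=trial,
            value_mmHg=value,
            direction="increase",
            t_peak_velocity_s=0.5,
            t_zero_cross_s=1.5,
            avg_window_s=(2.5, 6.5),
            valid=valid,
            invalid_reason=None if valid else "no_movement",
        )

    def test_mean_over_valid_trials_only(self):
        vals = [self._mk(v, trial=i + 1) for i, v in enumerate([50, 52, 48, 50, 51])]
        vals.append(self._mk(999.0, valid=False, trial=6))
        cell = bp.summarize_trials(vals).cell("BB", "RK")
        assert cell.mean_mmHg == pytest.approx(np.mean([50, 52, 48, 50, 51]))
        assert cell.n_valid == 5 and not cell.missing

    def test_identical_values(self):
        vals = [self._mk(50.84, trial=i + 1) for i in range(6)]
        cell = bp.summarize_trials(vals).cell("BB", "RK")
        assert cell.mean_mmHg == pytest.approx(50.84) and cell.n_valid == 6

    def test_all_invalid_cell_flagged_missing(self):
        vals = [self._mk(0.0, valid=False, trial=i + 1) for i in range(6)]
        cell = bp.summarize_trials(vals).cell("BB", "RK")
        assert cell.missing and cell.n_valid == 0 and np.isnan(cell.mean_mmHg)
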