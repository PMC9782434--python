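"""Feature extraction: gravity removal, displacement, ROM, coupling."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from posturebench.cohort import (
    SEGMENTS,
    GRAVITY,
    Segment,
    SensorStream,
    simulate_session,
)
from posturebench.features import (
    FEATURE_NAMES,
    assemble_features,
    coupling_indices,
    displacement_from_acceleration,
    dominant_frequency,
    extract_session_features,
    range_of_motion,
    world_linear_acceleration,
    zero_lag_highpass_gain,
)
from posturebench.protocol import PerturbationSpec, make_schedule

from conftest import LINK_GAINS, LINK_PHASES, make_profile

FS = 100.0


def _stream(quat, accel, fs=FS):
    n = len(quat)
    t = np.arange(n) / fs
    return SensorStream(segment=Segment.TRUNK, time=t,
                        quaternion=np.asarray(quat, float),
                        accel_body=np.asarray(accel, float),
                        gyro_body=np.zeros((n, 3)))


class TestWorldLinearAcceleration:
    def test_gravity_cancels_for_any_constant_orientation(self):
        rot = Rotation.from_euler("zyx", [25.0, 10.0, -40.0], degrees=True)
        q = rot.as_quat(scalar_first=True)
        g_body = rot.inv().apply([0.0, 0.0, GRAVITY])
        n = 50
        stream = _stream(np.tile(q, (n, 1)), np.tile(g_body, (n, 1)))
        out = world_linear_acceleration(stream)
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_identity_orientation_passthrough(self):
        n = 10
        q = np.tile([1.0, 0.0, 0.0, 0.0], (n, 1))
        a = np.tile([0.0, 0.0, GRAVITY + 1.0], (n, 1))
        out = world_linear_acceleration(_stream(q, a))
        np.testing.assert_allclose(out, [[0.0, 0.0, 1.0]] * n, atol=1e-12)

    def test_rolled_gravity_cancels(self):
        """90 deg roll: gravity appears on the body Y axis, still cancels."""
        rot = Rotation.from_euler("x", 90.0, degrees=True)
        q = rot.as_quat(scalar_first=True)
        g_body = rot.inv().apply([0.0, 0.0, GRAVITY])
        np.testing.assert_allclose(g_body, [0.0, GRAVITY, 0.0], atol=1e-12)
        stream = _stream(np.tile(q, (20, 1)), np.tile(g_body, (20, 1)))
        np.testing.assert_allclose(world_linear_acceleration(stream), 0.0,
                                   atol=1e-12)

    def test_bad_quaternion_rejected(self):
        q = np.tile([1.1, 0.0, 0.0, 0.0], (5, 1))
        with pytest.raises(ValueError, match="quaternion"):
            world_linear_acceleration(_stream(q, np.zeros((5, 3))))


class TestDisplacementFromAcceleration:
    def test_sinusoid_amplitude_matches_filter_response(self):
        """Recovered amplitude equals A times the chain's analytic gain.

        Independent oracle: each zero-lag pass of a first-order high-pass
        has magnitude (f/fc)^2 / (1 + (f/fc)^2); the chain applies two.
        """
        f, amp = 1.0, 0.004  # m
        t = np.arange(0, 40, 1 / FS)
        acc = -amp * (2 * np.pi * f) ** 2 * np.sin(2 * np.pi * f * t)
        disp = displacement_from_acceleration(acc, FS)
        ratio = (f / 0.2) ** 2
        analytic_pass = ratio / (1.0 + ratio)
        expected = amp * 1000.0 * analytic_pass**2
        measured = np.max(np.abs(disp[500:-500]))
        assert measured == pytest.approx(expected, rel=0.01)

    def test_zero_acceleration_gives_zero_displacement(self):
        disp = displacement_from_acceleration(np.zeros(4000), FS)
        np.testing.assert_allclose(disp, 0.0, atol=1e-9)

    def test_constant_bias_drift_is_suppressed(self):
        """A constant 1 m/s^2 bias must not grow quadratically.

        Unfiltered double integration over 60 s would reach 1.8e6 mm; the
        high-pass chain keeps the response within the filtered-ramp bound
        ~ bias * tau^2 with tau = 1/(2*pi*fc).
        """
        acc = np.ones(int(60 * FS))
        disp = displacement_from_acceleration(acc, FS)
        tau = 1.0 / (2 * np.pi * 0.2)
        bound = 2.0 * tau**2 * 1000.0  # mm, safety factor 2
        assert np.max(np.abs(disp)) < bound

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="warm-up"):
            displacement_from_acceleration(np.zeros(100), FS)

    def test_zero_lag_no_phase_distortion(self):
        """Cross-correlation of input and filtered sinusoid peaks at lag 0."""
        f = 0.8
        t = np.arange(0, 40, 1 / FS)
        x = np.sin(2 * np.pi * f * t)
        from posturebench.features import _zero_lag_highpass
        y = _zero_lag_highpass(x, FS, 0.2)
        inner = slice(500, -500)
        lags = range(-20, 21)
        cc = [np.dot(x[inner], np.roll(y, lag)[inner]) for lag in lags]
        assert lags[int(np.argmax(cc))] == 0


class TestRangeOfMotion:
    def test_peak_to_peak_of_sinusoid(self):
        t = np.arange(0, 10, 0.01)
        assert range_of_motion(5.0 * np.sin(2 * np.pi * t)) \
            == pytest.approx(10.0, rel=1e-4)

    def test_constant_series_is_zero(self):
        assert range_of_motion(np.full(100, 3.3)) == 0.0

    def test_window_excludes_artifact(self):
        t = np.arange(0, 10, 0.01)
        x = 5.0 * np.sin(2 * np.pi * t)
        x[:50] += 40.0  # step artifact confined to the excluded region
        assert range_of_motion(x, slice(100, 900)) == pytest.approx(10.0,
                                                                    rel=1e-3)

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            range_of_motion(np.arange(10.0), slice(5, 5))


class TestCouplingIndices:
    t = np.arange(0, 30, 1 / FS)

    def test_identity_signals(self):
        x = np.sin(2 * np.pi * 0.5 * self.t)
        ci = coupling_indices(x, x, FS)
        assert ci.gain_ratio == pytest.approx(1.0, abs=1e-9)
        assert ci.phase_shift_deg == pytest.approx(0.0, abs=1e-9)
        assert ci.fundamental_hz == pytest.approx(0.5, abs=1e-9)

    def test_scaled_distal(self):
        x = np.sin(2 * np.pi * 0.5 * self.t)
        ci = coupling_indices(0.8 * x, x, FS)
        assert ci.gain_ratio == pytest.approx(0.8, abs=1e-9)
        assert ci.phase_shift_deg == pytest.approx(0.0, abs=1e-9)

    def test_quarter_period_delay_is_plus_90(self):
        """A delayed distal signal has positive phase shift (it lags)."""
        f = 0.5
        x = np.sin(2 * np.pi * f * self.t)
        delayed = np.sin(2 * np.pi * f * (self.t - 1 / (4 * f)))
        ci = coupling_indices(delayed, x, FS)
        assert ci.phase_shift_deg == pytest.approx(90.0, abs=1e-6)

    def test_anticipation_is_negative(self):
        f = 0.5
        x = np.sin(2 * np.pi * f * self.t)
        ahead = np.sin(2 * np.pi * f * (self.t + 0.2))
        ci = coupling_indices(ahead, x, FS)
        assert ci.phase_shift_deg == pytest.approx(-0.2 * 360 * f, abs=1e-6)

    def test_zero_proximal_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            coupling_indices(np.ones(3000), np.zeros(3000), FS)

    def test_noise_robust_fundamental_pick(self):
        rng = np.random.default_rng(0)
        x = np.sin(2 * np.pi * 0.3 * self.t)
        noisy = x + 0.05 * rng.standard_normal(x.size)
        ci = coupling_indices(0.9 * noisy, noisy, FS)
        assert ci.fundamental_hz == pytest.approx(0.3, abs=0.05)


class TestEndToEndRecovery:
    def test_noise_free_session_recovers_profile(self, clean_profile,
                                                 clean_session):
        """Gain/phase within 1%/1 deg; ROM within 2% of 2a (round trip)."""
        feats = extract_session_features(clean_session)
        for seg in SEGMENTS:
            assert feats[f"gain_{seg.value}"] == pytest.approx(
                LINK_GAINS[seg], rel=0.01)
            assert feats[f"phase_{seg.value}"] == pytest.approx(
                LINK_PHASES[seg], abs=1.0)
            assert feats[f"rom_ml_{seg.value}"] == pytest.approx(12.0,
                                                                 rel=0.02)
            assert feats[f"rom_ap_{seg.value}"] == pytest.approx(16.0,
                                                                 rel=0.02)

    def test_time_shift_invariance(self, clean_profile):
        """Shifting the whole session in time leaves the features unchanged."""
        spec = PerturbationSpec.standard("HP")
        s = simulate_session(clean_profile, spec, rng=0)
        f0 = extract_session_features(s)
        for stream in s.streams.values():
            stream.time = stream.time + 123.4
        s.trajectory.time = s.trajectory.time + 123.4
        f1 = extract_session_features(s)
        for k in f0:
            assert f1[k] == pytest.approx(f0[k], rel=1e-9)


class TestAssembleFeatures:
    def _sessions(self, profile, reps=1, seed=0):
        rng = np.random.default_rng(seed)
        out = []
        for _, spec in make_schedule(seed, n_repetitions=reps):
            out.append(simulate_session(profile, spec, rng=rng))
        return out

    def test_complete_set_yields_72_features(self, clean_profile):
        vec = assemble_features(self._sessions(clean_profile), group="HC")
        assert len(vec.features) == 72
        assert set(vec.features) == set(FEATURE_NAMES)

    def test_missing_test_type_rejected(self, clean_profile):
        sessions = self._sessions(clean_profile)
        kept = [s for s in sessions if s.spec.test_type != "HP_left"]
        with pytest.raises(ValueError, match="HP_left"):
            assemble_features(kept, group="HC")

    def test_order_invariance_and_idempotent_averaging(self, clean_profile):
        sessions = self._sessions(clean_profile)
        v1 = assemble_features(sessions, group="HC")
        v2 = assemble_features(sessions[::-1], group="HC")
        assert v1.features == v2.features
        doubled = assemble_features(sessions + sessions, group="HC")
        for k in v1.features:
            assert doubled.features[k] == pytest.approx(v1.features[k])


def test_dominant_frequency_respects_search_band():
    """A strong component outside the 0.05-2 Hz band is ignored."""
    t = np.arange(0, 40, 1 / FS)
    x = 0.5 * np.sin(2 * np.pi * 0.3 * t) + 3.0 * np.sin(2 * np.pi * 5.0 * t)
    f, _ = dominant_frequency(x, FS)
    assert f == pytest.approx(0.3, abs=0.02)


def test_zero_lag_gain_matches_analog_formula():
    for f in (0.4, 0.6, 1.0, 2.0):
        ratio = (f / 0.2) ** 2
        analog = ratio / (1 + ratio)
        assert zero_lag_highpass_gain(f, FS) == pytest.approx(analog,
                                                              rel=5e-3)
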