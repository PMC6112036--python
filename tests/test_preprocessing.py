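"""Preprocessing: gravity decomposition, magnitude, angles, features."""

from __future__ import annotations

import numpy as np
import pytest

from actispot.preprocessing import (
    PreprocessConfig,
    apply_preprocess,
    axis_angles,
    decompose_acceleration,
    reduce_to_magnitude,
    resample_uniform,
    unify_bilateral,
    windowed_features,
    _window_features,
)
from conftest import make_stream


class TestResample:
    def test_linear_interpolation(self):
        s = make_stream([0, 100], [[0.0], [10.0]])
        out = resample_uniform(s, 20.0)
        np.testing.assert_array_equal(out.timestamps, [0, 50, 100])
        np.testing.assert_allclose(out.values[:, 0], [0.0, 5.0, 10.0])

    def test_identity_on_matching_grid(self):
        ts = np.arange(0, 200, 25)
        s = make_stream(ts, np.arange(8.0))
        out = resample_uniform(s, 40.0)
        np.testing.assert_array_equal(out.timestamps, ts)
        np.testing.assert_allclose(out.values, s.values)

    def test_constant_stays_constant(self):
        s = make_stream([3, 47, 95], [[7.0], [7.0], [7.0]])
        out = resample_uniform(s, 40.0)
        np.testing.assert_allclose(out.values, 7.0)

    def test_needs_two_samples(self):
        with pytest.raises(ValueError):
            resample_uniform(make_stream([0], [[1.0]]), 40.0)


class TestDecompose:
    def test_constant_input_is_pure_gravity(self):
        s = make_stream([0, 25, 50], np.full((3, 3), 2.5), channels=["x", "y", "z"])
        grav, lin = decompose_acceleration(s, 0.8)
        np.testing.assert_allclose(grav.values, 2.5)
        np.testing.assert_allclose(lin.values, 0.0, atol=1e-12)

    def test_hand_evaluated_recurrence(self):
        # g[0]=0, g[1] = 0.5*0 + 0.5*1 = 0.5; linear = raw - gravity
        s = make_stream([0, 25], [[0.0], [1.0]])
        grav, lin = decompose_acceleration(s, 0.5)
        np.testing.assert_allclose(grav.values[:, 0], [0.0, 0.5])
        np.testing.assert_allclose(lin.values[:, 0], [0.0, 0.5])

    def test_components_sum_to_raw(self, xyz_stream):
        grav, lin = decompose_acceleration(xyz_stream, 0.8)
        np.testing.assert_allclose(
            grav.values + lin.values, xyz_stream.values, atol=1e-9
        )

    def test_alpha_bounds(self, xyz_stream):
        for bad in (0.0, 1.0, -0.5, 2.0):
            with pytest.raises(ValueError):
                decompose_acceleration(xyz_stream, bad)


class TestMagnitude:
    def test_pythagorean_samples(self):
        s = make_stream([0, 25, 50], [[3, 4, 0], [0, 0, 0], [1, 1, 1]],
                        channels=["x", "y", "z"])
        out = reduce_to_magnitude(s)
        assert out.channels == ["mag"]
        np.testing.assert_allclose(out.values[:, 0], [5.0, 0.0, np.sqrt(3)])

    def test_rotation_invariance(self, xyz_stream):
        from scipy.spatial.transform import Rotation

        R = Rotation.from_euler("xyz", [31, -57, 112], degrees=True).as_matrix()
        rotated = make_stream(
            xyz_stream.timestamps, xyz_stream.values @ R.T, channels=["x", "y", "z"]
        )
        np.testing.assert_allclose(
            reduce_to_magnitude(rotated).values,
            reduce_to_magnitude(xyz_stream).values,
            atol=1e-9,
        )

    def test_requires_three_channels(self):
        with pytest.raises(ValueError):
            reduce_to_magnitude(make_stream([0], [[1.0]]))


class TestAxisAngles:
    def test_axis_aligned_vector(self):
        s = make_stream([0], [[0.0, 0.0, 9.81]], channels=["x", "y", "z"])
        out = axis_angles(s)
        np.testing.assert_allclose(
            out.values[0], [np.pi / 2, np.pi / 2, 0.0], atol=1e-12
        )

    def test_diagonal_and_scalar_cases(self):
        s = make_stream([0, 25], [[1, 1, 0], [3, 4, 0]], channels=["x", "y", "z"])
        out = axis_angles(s)
        np.testing.assert_allclose(
            out.values[0], [np.pi / 4, np.pi / 4, np.pi / 2], atol=1e-12
        )
        assert out.values[1, 0] == pytest.approx(np.arccos(0.6), abs=1e-9)

    def test_zero_sample_maps_to_zero_angles(self, caplog):
        s = make_stream([0], [[0.0, 0.0, 0.0]], channels=["x", "y", "z"])
        out = axis_angles(s)
        np.testing.assert_array_equal(out.values[0], [0.0, 0.0, 0.0])


class TestUnifyBilateral:
    def test_concatenates_channels_on_shared_grid(self):
        ts = np.arange(0, 1000, 25)
        left = make_stream(ts, np.random.default_rng(0).normal(size=(40, 3)),
                           channels=["x", "y", "z"], device="wrist_left")
        right = make_stream(ts, np.random.default_rng(1).normal(size=(40, 3)),
                            channels=["x", "y", "z"], device="wrist_right")
        out = unify_bilateral(left, right)
        assert len(out.channels) == 6
        assert out.n_samples == 40

    def test_overlap_only(self):
        l = make_stream(np.arange(0, 500, 25), np.zeros((20, 1)), device="a")
        r = make_stream(np.arange(250, 750, 25), np.zeros((20, 1)), device="b")
        out = unify_bilateral(l, r)
        assert out.timestamps[0] >= 250
        assert out.timestamps[-1] <= 475

    def test_self_unification_duplicates(self, xyz_stream):
        out = unify_bilateral(xyz_stream, xyz_stream)
        np.testing.assert_allclose(out.values[:, :3], out.values[:, 3:])

    def test_disjoint_streams_rejected(self):
        l = make_stream([0, 25], np.zeros((2, 1)), device="a")
        r = make_stream([5000, 5025], np.zeros((2, 1)), device="b")
        with pytest.raises(ValueError):
            unify_bilateral(l, r)


class TestWindowedFeatures:
    def test_constant_window_zero_features(self):
        ts = np.arange(0, 1600, 25)
        s = make_stream(ts, np.full((64, 2), 3.3))
        fs = windowed_features(s, 800, 400)
        np.testing.assert_allclose(fs.features, 0.0, atol=1e-18)

    def test_mad_of_simple_window(self):
        # median 2, deviations [1, 0, 1] -> mad 1 (window helper directly)
        feats = _window_features(np.array([[1.0], [2.0], [3.0], [4.0]]))
        med = np.median([1, 2, 3, 4])
        expected_mad = np.median(np.abs(np.array([1, 2, 3, 4]) - med))
        assert feats[1] == pytest.approx(expected_mad)

    def test_sinusoid_energy_matches_variance_oracle(self):
        # energy of a mean-removed window must equal its mean power,
        # computed independently as the time-domain variance
        rate, n = 40.0, 80
        t = np.arange(n) / rate
        amp = 2.7
        x = amp * np.sin(2 * np.pi * 2.0 * t)  # integer periods in window
        s = make_stream((t * 1000).astype(int), x)
        fs = windowed_features(s, 2000, 2000)
        assert fs.features[0, 0] == pytest.approx(amp**2 / 2, rel=1e-9)
        assert fs.features[0, 0] == pytest.approx(np.var(x), rel=1e-9)

    def test_offset_invariance(self, xyz_stream):
        fs0 = windowed_features(xyz_stream, 800, 400)
        shifted = make_stream(
            xyz_stream.timestamps, xyz_stream.values + np.array([5.0, -3.0, 11.0]),
            channels=xyz_stream.channels,
        )
        fs1 = windowed_features(shifted, 800, 400)
        np.testing.assert_allclose(fs0.features[:, :3], fs1.features[:, :3], atol=1e-9)
        np.testing.assert_allclose(fs0.features[:, 3:], fs1.features[:, 3:], atol=1e-9)

    def test_trailing_partial_window_dropped(self):
        ts = np.arange(0, 1200, 25)  # 48 samples
        s = make_stream(ts, np.arange(48.0))
        fs = windowed_features(s, 800, 400)  # third window would overrun
        np.testing.assert_array_equal(fs.window_starts_ms, [0, 400])

    def test_too_short_window_rejected(self, xyz_stream):
        with pytest.raises(ValueError):
            windowed_features(xyz_stream, 50, 25)


class TestApplyPreprocess:
    def test_raw_unreduced_is_identity(self, xyz_stream, raw_cfg):
        out = apply_preprocess(xyz_stream, raw_cfg)
        np.testing.assert_array_equal(out.values, xyz_stream.values)

    def test_linear_reduced_constant_input_is_zero(self):
        s = make_stream(np.arange(0, 250, 25), np.full((10, 3), 4.0),
                        channels=["x", "y", "z"])
        cfg = PreprocessConfig(acceleration_type="linear", reduce_dimensions=True)
        np.testing.assert_allclose(apply_preprocess(s, cfg).values, 0.0, atol=1e-12)

    def test_gravity_reduced_recovers_gravity_norm(self):
        s = make_stream(np.arange(0, 250, 25), np.tile([0, 0, 9.81], (10, 1)),
                        channels=["x", "y", "z"])
        cfg = PreprocessConfig(acceleration_type="gravity", reduce_dimensions=True)
        np.testing.assert_allclose(apply_preprocess(s, cfg).values, 9.81)

    def test_fingerprint_distinguishes_configs(self):
        a = PreprocessConfig("linear", True, 0.8)
        b = PreprocessConfig("linear", True, 0.9)
        c = PreprocessConfig("raw", True, 0.8)
        d = PreprocessConfig("raw", True, 0.9)  # alpha irrelevant for raw
        assert a.fingerprint() != b.fingerprint()
        assert a.fingerprint() != c.fingerprint()
        assert c.fingerprint() == d.fingerprint()

    def test_unknown_keys_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            PreprocessConfig.from_dict({"acceleration_type": "raw", "typo": 1})
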