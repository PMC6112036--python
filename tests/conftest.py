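"""Shared fixtures: tiny hand-built streams and seeded synthetic recordings."""

from __future__ import annotations

import numpy as np
import pytest

from actispot import PreprocessConfig, SensorStream, SimConfig, generate_recording
from actispot.synthetic import picking_motif_classes


def make_stream(timestamps, values, channels=None, rate=40.0, device="wrist_right"):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if values.shape[0] != len(timestamps):
        values = values.T
    if channels is None:
        channels = [f"c{i}" for i in range(values.shape[1])]
    return SensorStream(
        recording_id="test",
        device=device,
        sample_rate_hz=rate,
        timestamps=np.asarray(timestamps, dtype=np.int64),
        channels=list(channels),
        values=values,
    )


@pytest.fixture
def xyz_stream():
    """Uniform 40 Hz three-axis stream, 2 s."""
    rng = np.random.default_rng(42)
    ts = np.arange(80) * 25
    vals = rng.normal(0.0, 1.0, size=(80, 3)) + np.array([0.0, 0.0, 9.81])
    return make_stream(ts, vals, channels=["x", "y", "z"])


@pytest.fixture
def raw_cfg():
    return PreprocessConfig(acceleration_type="raw", reduce_dimensions=False)


@pytest.fixture
def linear_mag_cfg():
    return PreprocessConfig(acceleration_type="linear", reduce_dimensions=True)


@pytest.fixture
def picking_recording():
    """One noiseless grab in an otherwise idle 60 s recording."""
    cfg = SimConfig(
        seed=7,
        duration_s=60,
        n_activities=1,
        noise_sd=0.0,
        motif_classes=picking_motif_classes(),
    )
    return generate_recording(cfg)


@pytest.fixture
def noisy_picking_recording():
    cfg = SimConfig(
        seed=8,
        duration_s=60,
        n_activities=1,
        motif_classes=picking_motif_classes(),
    )
    return generate_recording(cfg)
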