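"""Signal representations used for template matching.

Raw wrist acceleration mixes the gravity component (posture) with the
linear component (motion).  Matching quality depends strongly on which
representation is compared, so the preprocessing is configurable along the
two axes the matching grid sweeps:

* ``acceleration_type`` — ``raw``, ``gravity`` (low-pass output) or
  ``linear`` (raw minus gravity).  The gravity estimate is the conventional
  first-order exponential IIR used on Android devices,
  ``g[t] = alpha * g[t-1] + (1 - alpha) * a[t]``.
* ``reduce_dimensions`` — collapse the three axes to the vector magnitude,
  discarding orientation so that templates generalise across wrist poses.

Two further representations serve specific stages: per-axis inclination
angles (arccos of the normalised components), and windowed
energy / median-absolute-deviation features for complex activities whose
motion character matters more than the raw waveform.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import lfilter

from .signal_model import SensorStream

__all__ = [
    "PreprocessConfig",
    "FeatureSequence",
    "resample_uniform",
    "decompose_acceleration",
    "reduce_to_magnitude",
    "axis_angles",
    "unify_bilateral",
    "windowed_features",
    "apply_preprocess",
]

logger = logging.getLogger(__name__)

ACCELERATION_TYPES = ("raw", "gravity", "linear")


@dataclass(frozen=True)
class PreprocessConfig:
    """One cell of the preprocessing half of the matching configuration grid.

    Parameters
    ----------
    acceleration_type : {"raw", "gravity", "linear"}
        Which component of the acceleration feeds the matcher.
    reduce_dimensions : bool
        Collapse 3-axis samples to their Euclidean magnitude.
    lowpass_alpha : float in (0, 1)
        Smoothing factor of the gravity IIR filter; ignored for ``raw``.
        0.8 is the conventional Android default.
    resample_hz : float, optional
        Resample to this uniform rate before anything else (Android pushes
        samples with jitter; windowed operations need a fixed rate).
    """

    acceleration_type: str = "linear"
    reduce_dimensions: bool = True
    lowpass_alpha: float = 0.8
    resample_hz: float | None = None

    def __post_init__(self) -> None:
        if self.acceleration_type not in ACCELERATION_TYPES:
            raise ValueError(
                f"acceleration_type must be one of {ACCELERATION_TYPES}, "
                f"got {self.acceleration_type!r}"
            )
        if self.acceleration_type != "raw" and not 0.0 < self.lowpass_alpha < 1.0:
            raise ValueError("lowpass_alpha must lie in (0, 1)")
        if self.resample_hz is not None and self.resample_hz <= 0:
            raise ValueError("resample_hz must be positive")

    def fingerprint(self) -> str:
        """Stable hash identifying this configuration.

        Templates record the fingerprint of the config they were built
        under; matching refuses templates built under a different one.
        """
        payload = {
            "acceleration_type": self.acceleration_type,
            "reduce_dimensions": bool(self.reduce_dimensions),
            # alpha is irrelevant for raw: exclude it so equivalent configs hash equal
            "lowpass_alpha": None if self.acceleration_type == "raw" else self.lowpass_alpha,
            "resample_hz": self.resample_hz,
        }
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def to_dict(self) -> dict:
        return {
            "acceleration_type": self.acceleration_type,
            "reduce_dimensions": self.reduce_dimensions,
            "lowpass_alpha": self.lowpass_alpha,
            "resample_hz": self.resample_hz,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PreprocessConfig":
        allowed = {"acceleration_type", "reduce_dimensions", "lowpass_alpha", "resample_hz"}
        unknown = set(d) - allowed
        if unknown:
            raise ValueError(f"unknown preprocess keys: {sorted(unknown)}")
        return cls(**d)


@dataclass
class FeatureSequence:
    """Windowed feature vectors for a stream (complex-activity matching).

    Per window and channel the vector holds the signal energy (mean power
    of the mean-removed window, via the FFT) and the median absolute
    deviation, concatenated ``[energy_c1..energy_cn, mad_c1..mad_cn]``.
    """

    window_starts_ms: np.ndarray
    features: np.ndarray  # (n_windows, 2 * n_channels)
    window_len_ms: int
    hop_ms: int

    def __post_init__(self) -> None:
        self.window_starts_ms = np.asarray(self.window_starts_ms, dtype=np.int64)
        self.features = np.atleast_2d(np.asarray(self.features, dtype=np.float64))
        if self.window_starts_ms.shape[0] != self.features.shape[0]:
            raise ValueError("one feature vector per window required")


def resample_uniform(stream: SensorStream, rate_hz: float) -> SensorStream:
    """Linear interpolation onto the uniform grid ``k * 1000 / rate_hz`` ms.

    Grid points are rounded to integer milliseconds and restricted to the
    span of the input.
    """
    if stream.n_samples < 2:
        raise ValueError("resampling needs at least 2 samples")
    if rate_hz <= 0:
        raise ValueError("rate_hz must be positive")
    step = 1000.0 / rate_hz
    first, last = stream.timestamps[0], stream.timestamps[-1]
    k0 = int(np.ceil(first / step - 1e-9))
    k1 = int(np.floor(last / step + 1e-9))
    grid = np.round(np.arange(k0, k1 + 1) * step).astype(np.int64)
    out = np.empty((grid.size, len(stream.channels)))
    for c in range(len(stream.channels)):
        out[:, c] = np.interp(grid, stream.timestamps, stream.values[:, c])
    return replace(stream, sample_rate_hz=rate_hz, timestamps=grid, values=out)


def decompose_acceleration(
    stream: SensorStream, alpha: float
) -> tuple[SensorStream, SensorStream]:
    """Split raw acceleration into gravity and linear components.

    ``gravity[t] = alpha * gravity[t-1] + (1 - alpha) * raw[t]`` with
    ``gravity[0] = raw[0]``; ``linear = raw - gravity``.  Returns
    ``(gravity, linear)`` with timestamps preserved.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    raw = stream.values
    if raw.shape[0] == 0:
        grav = raw.copy()
    else:
        # first-order IIR; zi chosen so that y[0] == x[0]
        b, a = [1.0 - alpha], [1.0, -alpha]
        grav = np.empty_like(raw)
        for c in range(raw.shape[1]):
            zi = np.array([alpha * raw[0, c]])
            grav[:, c], _ = lfilter(b, a, raw[:, c], zi=zi)
    gravity = replace(stream, values=grav)
    linear = replace(stream, values=raw - grav)
    return gravity, linear


def reduce_to_magnitude(stream: SensorStream) -> SensorStream:
    """Replace (x, y, z) samples by their Euclidean length, channel ``mag``."""
    if len(stream.channels) != 3:
        raise ValueError(
            f"magnitude reduction expects 3 channels, got {len(stream.channels)}"
        )
    mag = np.linalg.norm(stream.values, axis=1, keepdims=True)
    return replace(stream, channels=["mag"], values=mag)


def axis_angles(stream: SensorStream) -> SensorStream:
    """Angles (radians) between the acceleration vector and each +axis.

    ``theta_a = arccos(a / |v|)``.  All-zero samples are mapped to zero
    angles and logged; they carry no orientation information.
    """
    if len(stream.channels) != 3:
        raise ValueError("axis angles require exactly 3 channels")
    norms = np.linalg.norm(stream.values, axis=1, keepdims=True)
    zero = norms[:, 0] == 0.0
    if np.any(zero):
        logger.warning(
            "%s: %d all-zero samples mapped to zero angles",
            stream.device, int(zero.sum()),
        )
    safe = np.where(norms == 0.0, 1.0, norms)
    ang = np.arccos(np.clip(stream.values / safe, -1.0, 1.0))
    ang[zero, :] = 0.0
    return replace(stream, channels=["theta_x", "theta_y", "theta_z"], values=ang)


def unify_bilateral(
    left: SensorStream, right: SensorStream, rate_hz: float | None = None
) -> SensorStream:
    """Join both wrists into one vector stream on a shared uniform grid.

    Each stream is resampled to the common rate (default: the lower of the
    two nominal rates) and samples are kept on the intersection of the two
    grids.  Channels are the left channels followed by the right channels,
    prefixed with the device name to stay unique.
    """
    if rate_hz is None:
        rate_hz = min(left.sample_rate_hz, right.sample_rate_hz)
    lr = resample_uniform(left, rate_hz)
    rr = resample_uniform(right, rate_hz)
    common, li, ri = np.intersect1d(lr.timestamps, rr.timestamps, return_indices=True)
    if common.size == 0:
        raise ValueError("streams share no overlapping time span")
    channels = [f"{left.device}_{c}" for c in left.channels] + [
        f"{right.device}_{c}" for c in right.channels
    ]
    values = np.hstack([lr.values[li], rr.values[ri]])
    return SensorStream(
        recording_id=left.recording_id,
        device=f"{left.device}+{right.device}",
        sample_rate_hz=rate_hz,
        timestamps=common,
        channels=channels,
        values=values,
    )


def _window_features(window: np.ndarray) -> np.ndarray:
    """[energy per channel, mad per channel] for one (n, c) window."""
    centered = window - window.mean(axis=0, keepdims=True)
    spectrum = np.fft.rfft(centered, axis=0)
    n = window.shape[0]
    # mean power of the mean-removed signal via Parseval; DC bin is 0 already
    power = np.abs(spectrum) ** 2
    if n % 2 == 0:
        power[1:-1] *= 2.0  # interior rfft bins represent conjugate pairs
    else:
        power[1:] *= 2.0
    energy = power[1:].sum(axis=0) / n**2
    med = np.median(window, axis=0, keepdims=True)
    mad = np.median(np.abs(window - med), axis=0)
    return np.concatenate([energy, mad])


def windowed_features(
    stream: SensorStream, window_len_ms: int, hop_ms: int
) -> FeatureSequence:
    """Sliding-window energy + MAD features over a uniformly sampled stream.

    The trailing partial window is dropped.  Energy is the mean power of
    the mean-removed window (so constant offsets such as gravity do not
    dominate); MAD is the median absolute deviation of the raw window.
    """
    if stream.n_samples < 2:
        raise ValueError("windowed features need at least 2 samples")
    step = stream.step_ms()
    win = int(round(window_len_ms / step))
    hop = int(round(hop_ms / step))
    if win < 4:
        raise ValueError(
            f"window of {window_len_ms} ms holds {win} samples; at least 4 required"
        )
    if hop < 1:
        raise ValueError("hop_ms shorter than one sample period")
    starts, feats = [], []
    for s in range(0, stream.n_samples - win + 1, hop):
        starts.append(stream.timestamps[s])
        feats.append(_window_features(stream.values[s : s + win]))
    if not feats:
        raise ValueError("stream shorter than one window")
    return FeatureSequence(
        window_starts_ms=np.asarray(starts),
        features=np.asarray(feats),
        window_len_ms=window_len_ms,
        hop_ms=hop_ms,
    )


def apply_preprocess(stream: SensorStream, cfg: PreprocessConfig) -> SensorStream:
    """Apply one configuration cell: resample → component → magnitude."""
    out = stream
    if cfg.resample_hz is not None:
        out = resample_uniform(out, cfg.resample_hz)
    if cfg.acceleration_type != "raw":
        gravity, linear = decompose_acceleration(out, cfg.lowpass_alpha)
        out = gravity if cfg.acceleration_type == "gravity" else linear
    if cfg.reduce_dimensions:
        out = reduce_to_magnitude(out)
    return out
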