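"""Template extraction from labeled recordings.

A template is the preprocessed sensor trace of one annotated activity
span, carrying its label and provenance.  A zeroline template is the same
thing cut from a period of no movement (recordings start and end with the
wearer standing idle); it serves as the null pattern in candidate
filtering: a stretch of data that matches "doing nothing" better than it
matches the activity template is not worth recommending.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocessing import PreprocessConfig, apply_preprocess, reduce_to_magnitude
from .signal_model import LabelInterval, Recording, SensorStream, slice_stream

__all__ = [
    "Template",
    "ZerolineTemplate",
    "ZEROLINE_LABEL",
    "extract_templates",
    "detect_zeroline",
    "extract_zeroline_template",
    "save_templates",
    "load_templates",
]

ZEROLINE_LABEL = "__zeroline__"


@dataclass
class Template:
    """A labeled, preprocessed signal segment used as a matching query."""

    template_id: str
    label: str
    hand: str
    source_recording: str
    span_ms: tuple[int, int]
    sequence: np.ndarray  # (n, d) preprocessed samples
    sample_rate_hz: float
    preprocess_fingerprint: str

    def __post_init__(self) -> None:
        self.sequence = np.atleast_2d(np.asarray(self.sequence, dtype=np.float64))
        if self.sequence.shape[0] == 0:
            raise ValueError(f"template {self.template_id}: empty sequence")

    @property
    def duration_ms(self) -> int:
        return self.span_ms[1] - self.span_ms[0]


class ZerolineTemplate(Template):
    """Idle-period template; label is fixed to the zeroline sentinel."""


def _stream_for_hand(recording: Recording, hand: str, default_device: str | None) -> SensorStream:
    by_hand = {"left": "wrist_left", "right": "wrist_right"}
    if hand in by_hand and by_hand[hand] in recording.streams:
        return recording.streams[by_hand[hand]]
    return recording.primary_stream(
        default_device if default_device in recording.streams else None
    )


def extract_templates(
    recording: Recording,
    cfg: PreprocessConfig,
    labels_filter: set[str] | None = None,
    leading_ms: int | None = None,
    default_device: str | None = None,
) -> list[Template]:
    """One template per (matching) label interval of the recording.

    ``leading_ms`` truncates each span to its initial portion: for
    similar-motion activity sets (eat / drink / take medicine) only the
    shared reaching motion is matched and the specific activity is left to
    the annotator, so templates cover just the first arm movement.
    """
    if not recording.labels:
        return []
    out = []
    for idx, lab in enumerate(recording.labels):
        if labels_filter is not None and lab.label not in labels_filter:
            continue
        stream = _stream_for_hand(recording, lab.hand, default_device)
        end = lab.end_ms
        if leading_ms is not None:
            end = min(end, lab.start_ms + leading_ms)
        if stream.n_samples == 0 or lab.start_ms < stream.timestamps[0] or end > stream.timestamps[-1] + round(stream.step_ms()):
            raise ValueError(
                f"label '{lab.label}' [{lab.start_ms}, {lab.end_ms}) lies outside "
                f"stream '{stream.device}' of recording {recording.recording_id}"
            )
        piece = slice_stream(stream, lab.start_ms, end)
        if piece.n_samples == 0:
            raise ValueError(
                f"label '{lab.label}' [{lab.start_ms}, {end}) selects no samples"
            )
        seq = apply_preprocess(piece, cfg).values
        out.append(
            Template(
                template_id=f"{recording.recording_id}:{idx}:{lab.label}",
                label=lab.label,
                hand=lab.hand,
                source_recording=recording.recording_id,
                span_ms=(lab.start_ms, end),
                sequence=seq,
                sample_rate_hz=stream.sample_rate_hz,
                preprocess_fingerprint=cfg.fingerprint(),
            )
        )
    return out


def detect_zeroline(
    stream: SensorStream,
    min_len_ms: int = 2000,
    mag_std_threshold: float = 0.05,
    window_ms: int = 1000,
) -> list[LabelInterval]:
    """Maximal idle intervals: rolling std of the magnitude stays below threshold.

    The rolling window (default 1 s, centered) runs over the magnitude of
    the acceleration vector (or the single channel, if already reduced).
    """
    if stream.n_samples == 0:
        return []
    mag_stream = reduce_to_magnitude(stream) if len(stream.channels) == 3 else stream
    mag = mag_stream.values[:, 0]
    win = max(2, int(round(window_ms / stream.step_ms())))
    rolling = pd.Series(mag).rolling(win, center=True, min_periods=max(2, win // 2)).std()
    quiet = (rolling < mag_std_threshold).to_numpy()
    quiet[np.isnan(rolling.to_numpy())] = False
    intervals = []
    step = int(round(stream.step_ms()))
    i = 0
    n = quiet.size
    while i < n:
        if quiet[i]:
            j = i
            while j + 1 < n and quiet[j + 1]:
                j += 1
            start = int(stream.timestamps[i])
            end = int(stream.timestamps[j]) + step  # half-open
            if end - start >= min_len_ms:
                intervals.append(LabelInterval(start, end, ZEROLINE_LABEL))
            i = j + 1
        else:
            i += 1
    return intervals


def extract_zeroline_template(
    recording: Recording,
    cfg: PreprocessConfig,
    span: LabelInterval | None = None,
    activity_templates: list[Template] | None = None,
    default_device: str | None = None,
    mag_std_threshold: float = 0.05,
) -> ZerolineTemplate:
    """Cut an idle-period template, sized like the activity templates.

    Uses the explicitly given span, else the first detected idle interval.
    The cut is truncated to the median duration of ``activity_templates``
    so idle and activity matches accumulate over comparable path lengths.
    """
    stream = recording.primary_stream(
        default_device if default_device in recording.streams else None
    )
    if span is None:
        found = detect_zeroline(stream, mag_std_threshold=mag_std_threshold)
        if not found:
            raise ValueError(
                f"recording {recording.recording_id}: no idle period detected; "
                "annotate a zeroline span manually and pass it as `span`"
            )
        span = found[0]
    end = span.end_ms
    if activity_templates:
        med = int(np.median([t.duration_ms for t in activity_templates]))
        end = min(end, span.start_ms + med)
    piece = slice_stream(stream, span.start_ms, end)
    if piece.n_samples == 0:
        raise ValueError("zeroline span selects no samples")
    seq = apply_preprocess(piece, cfg).values
    return ZerolineTemplate(
        template_id=f"{recording.recording_id}:zeroline",
        label=ZEROLINE_LABEL,
        hand="unknown",
        source_recording=recording.recording_id,
        span_ms=(span.start_ms, end),
        sequence=seq,
        sample_rate_hz=stream.sample_rate_hz,
        preprocess_fingerprint=cfg.fingerprint(),
    )


def save_templates(templates: list[Template], directory: str | Path) -> None:
    """Serialize a template store: metadata JSON + one CSV per template."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for t in templates:
        safe = t.template_id.replace(":", "_").replace("/", "_")
        meta = {
            "template_id": t.template_id,
            "label": t.label,
            "hand": t.hand,
            "source_recording": t.source_recording,
            "span_ms": list(t.span_ms),
            "sample_rate_hz": t.sample_rate_hz,
            "preprocess_fingerprint": t.preprocess_fingerprint,
            "n_channels": int(t.sequence.shape[1]),
        }
        (directory / f"{safe}.json").write_text(json.dumps(meta, indent=2) + "\n")
        cols = [f"c{i}" for i in range(t.sequence.shape[1])]
        pd.DataFrame(t.sequence, columns=cols).to_csv(
            directory / f"{safe}.csv", index=False, float_format="%.9g",
            lineterminator="\n",
        )


def load_templates(directory: str | Path) -> list[Template]:
    directory = Path(directory)
    out = []
    for meta_path in sorted(directory.glob("*.json")):
        meta = json.loads(meta_path.read_text())
        if "template_id" not in meta:
            continue  # some other JSON (e.g. a run manifest)
        seq = pd.read_csv(meta_path.with_suffix(".csv")).to_numpy(dtype=np.float64)
        cls = ZerolineTemplate if meta["label"] == ZEROLINE_LABEL else Template
        out.append(
            cls(
                template_id=meta["template_id"],
                label=meta["label"],
                hand=meta["hand"],
                source_recording=meta["source_recording"],
                span_ms=tuple(meta["span_ms"]),
                sequence=seq,
                sample_rate_hz=meta["sample_rate_hz"],
                preprocess_fingerprint=meta["preprocess_fingerprint"],
            )
        )
    return out
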