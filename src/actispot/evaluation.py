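"""Evaluation of label recommendations against ground truth.

The primary question for an annotation aid is *how close* each suggestion
lands to a real label, not classification accuracy: a recommendation a
second off is trivially corrected, a missing one is not.  Hence the
metrics here are span-based: temporal overlap (Jaccard), start/duration
deltas, candidate-to-nearest-label distance (min/median/max per
configuration), recall with any-overlap counted as a true positive, a
windowed ROC over match distances, a (template count × k) sweep, and
leave-one-recording-out orchestration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_curve as _sk_roc_curve

from .matching import MatchCandidate, SelectionConfig, recommend
from .preprocessing import PreprocessConfig
from .signal_model import LabelInterval, Recording
from .templates import ZEROLINE_LABEL, Template, extract_templates, extract_zeroline_template

__all__ = [
    "OverlapReport",
    "DistanceReport",
    "RocCurve",
    "interval_overlap",
    "boundary_deltas",
    "candidate_label_distance",
    "recall_at_k",
    "roc_curve",
    "score_windows",
    "sweep",
    "leave_one_out",
]

Span = tuple[int, int]


@dataclass
class OverlapReport:
    """Per-recording best-match agreement with ground truth."""

    recording_id: str
    overlap: float
    motion_duration_s: list[float]
    delta_start_s: list[float]
    delta_duration_s: list[float]


@dataclass
class DistanceReport:
    """Min/median/max candidate-to-label distance for one configuration."""

    min_s: float
    median_s: float
    max_s: float
    n_candidates: int
    config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.min_s <= self.median_s <= self.max_s):
            raise ValueError("expected min <= median <= max")


@dataclass
class RocCurve:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray


def interval_overlap(a: Span, b: Span) -> float:
    """Temporal Jaccard of two half-open spans: |a ∩ b| / |a ∪ b|."""
    inter = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    union = (a[1] - a[0]) + (b[1] - b[0]) - inter
    return inter / union if union > 0 else 0.0


def boundary_deltas(pred: Span, truth: Span) -> tuple[float, float]:
    """(|Δstart|, |Δduration|) in seconds."""
    ds = abs(pred[0] - truth[0]) / 1000.0
    dd = abs((pred[1] - pred[0]) - (truth[1] - truth[0])) / 1000.0
    return ds, dd


def candidate_label_distance(
    candidate: MatchCandidate, labels: list[LabelInterval]
) -> float:
    """Seconds from a candidate span to the nearest label; 0 if they overlap."""
    if not labels:
        raise ValueError("labels must be non-empty")
    best = np.inf
    for lab in labels:
        if min(candidate.end_ms, lab.end_ms) > max(candidate.start_ms, lab.start_ms):
            return 0.0
        gap = max(lab.start_ms - candidate.end_ms, candidate.start_ms - lab.end_ms)
        best = min(best, gap / 1000.0)
    return float(best)


def recall_at_k(candidates: list[MatchCandidate], labels: list[LabelInterval]) -> float:
    """Fraction of ground-truth labels overlapped by at least one candidate."""
    if not labels:
        raise ValueError("labels must be non-empty")
    hit = 0
    for lab in labels:
        if any(
            min(c.end_ms, lab.end_ms) > max(c.start_ms, lab.start_ms)
            for c in candidates
        ):
            hit += 1
    return hit / len(labels)


def score_windows(
    recording: Recording,
    candidates: list[MatchCandidate],
    window_s: float = 1.0,
    device: str | None = None,
) -> list[tuple[float, bool]]:
    """Discretize the timeline into fixed windows and score each one.

    A window is positive iff it overlaps a ground-truth label; its score
    is minus the smallest distance of any candidate overlapping it (no
    candidate → -inf, i.e. maximally activity-unlike).  The scored
    windows feed :func:`roc_curve`.
    """
    stream = recording.primary_stream(device)
    if stream.n_samples == 0:
        raise ValueError("empty stream")
    w = int(round(window_s * 1000))
    out = []
    for start in range(int(stream.timestamps[0]), int(stream.timestamps[-1]), w):
        end = start + w
        positive = any(
            min(end, lab.end_ms) > max(start, lab.start_ms) for lab in recording.labels
        )
        dists = [
            c.distance
            for c in candidates
            if min(end, c.end_ms) > max(start, c.start_ms)
        ]
        score = -min(dists) if dists else -np.inf
        out.append((score, positive))
    return out


def roc_curve(scored_windows: list[tuple[float, bool]]) -> RocCurve:
    """Threshold sweep over window scores (higher score = more activity-like)."""
    scores = np.array([s for s, _ in scored_windows], dtype=np.float64)
    y = np.array([bool(p) for _, p in scored_windows])
    if y.all() or not y.any():
        raise ValueError("need at least one positive and one negative window")
    finite_min = scores[np.isfinite(scores)].min() if np.isfinite(scores).any() else -1.0
    scores = np.where(np.isneginf(scores), finite_min - 1.0, scores)
    fpr, tpr, thr = _sk_roc_curve(y, scores)
    return RocCurve(thresholds=thr, fpr=fpr, tpr=tpr)


def _fold_templates(
    recordings: list[Recording],
    held_out: Recording,
    cfg: PreprocessConfig,
    leading_ms: int | None,
) -> list[Template]:
    pool: list[Template] = []
    for rec in recordings:
        if rec.recording_id == held_out.recording_id:
            continue
        pool.extend(extract_templates(rec, cfg, leading_ms=leading_ms))
    return pool


def leave_one_out(
    recordings: list[Recording],
    cfg: PreprocessConfig,
    sel: SelectionConfig,
    n_templates: int | None = None,
    leading_ms: int | None = None,
    seed: int = 0,
    zeroline_std_threshold: float = 0.05,
) -> list[dict]:
    """Hold each recording out; recommend with templates from the others.

    Returns one record per fold with the recommendations, their distances
    to the nearest ground-truth label, and the fold recall.  When
    ``n_templates`` is given, that many templates are sampled (seeded)
    from the fold's pool.
    """
    if len(recordings) < 2:
        raise ValueError("leave-one-out needs at least 2 recordings")
    rng = np.random.default_rng(seed)
    folds = []
    for rec in recordings:
        pool = _fold_templates(recordings, rec, cfg, leading_ms)
        if not pool:
            raise ValueError(f"no templates available for fold {rec.recording_id}")
        templates = pool
        if n_templates is not None and n_templates < len(pool):
            idx = rng.choice(len(pool), size=n_templates, replace=False)
            templates = [pool[i] for i in sorted(idx)]
        if sel.method == "zeroline":
            donor = next(
                r for r in recordings if r.recording_id != rec.recording_id
            )
            templates = templates + [
                extract_zeroline_template(
                    donor, cfg, activity_templates=templates,
                    mag_std_threshold=zeroline_std_threshold,
                )
            ]
        candidates = recommend(rec, templates, cfg, sel)
        dists = [candidate_label_distance(c, rec.labels) for c in candidates]
        folds.append(
            {
                "held_out_id": rec.recording_id,
                "candidates": candidates,
                "distances_s": dists,
                "recall": recall_at_k(candidates, rec.labels) if rec.labels else np.nan,
                "n_templates": len([t for t in templates if t.label != ZEROLINE_LABEL]),
            }
        )
    return folds


def summarize_distances(folds: list[dict], config: dict | None = None) -> DistanceReport:
    """Pool all candidate-to-label distances of a fold list into one report."""
    dists = [d for f in folds for d in f["distances_s"]]
    if not dists:
        raise ValueError("no candidates to summarize")
    return DistanceReport(
        min_s=float(np.min(dists)),
        median_s=float(np.median(dists)),
        max_s=float(np.max(dists)),
        n_candidates=len(dists),
        config=config or {},
    )


def sweep(
    recordings: list[Recording],
    template_counts: list[int],
    k_values: list[int],
    cfg: PreprocessConfig,
    sel_method: str = "delta",
    delta_ms: int = 2000,
    leading_ms: int | None = None,
    seed: int = 0,
) -> dict[tuple[int, int], DistanceReport]:
    """(template count × k) grid of distance reports, leave-one-out inside."""
    grid: dict[tuple[int, int], DistanceReport] = {}
    for n_t in template_counts:
        for k in k_values:
            sel = SelectionConfig(method=sel_method, k=k, delta_ms=delta_ms)
            folds = leave_one_out(
                recordings, cfg, sel, n_templates=n_t,
                leading_ms=leading_ms, seed=seed,
            )
            grid[(n_t, k)] = summarize_distances(
                folds,
                config={
                    "acceleration_type": cfg.acceleration_type,
                    "reduce_dimensions": cfg.reduce_dimensions,
                    "method": sel_method,
                    "k": k,
                    "n_templates": n_t,
                },
            )
    return grid
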