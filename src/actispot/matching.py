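"""Label-candidate generation and top-k selection.

Each template is matched against the preprocessed target stream with
subsequence DTW; the resulting candidate spans are then thinned with one
of two selection rules before being shown to the annotator:

* **zeroline** — keep only candidates whose activity-template distance is
  smaller than the idle-template distance ending at the same position
  (regions that look more like "no movement" than like the activity are
  discarded), then take the k best.
* **delta** — greedy non-maximum suppression in time: walk candidates in
  ascending distance and accept one only if its start lies at least δ away
  from every already-accepted start; stop after k.  δ defaults to 2 s,
  below which two distinct activities are not expected to begin.

For the single-activity picking scenario a fixed-length sliding matcher
and an exhaustive best-subset selector (mutual-overlap argmax over all
size-k subsets of per-template best matches) are provided.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np

from .dtw import best_subsequence_matches, dtw_full, subsequence_profile
from .preprocessing import PreprocessConfig, apply_preprocess
from .signal_model import Recording, SensorStream
from .templates import Template, ZEROLINE_LABEL

__all__ = [
    "MatchCandidate",
    "SelectionConfig",
    "match_template",
    "select_topk_zeroline",
    "select_topk_delta",
    "sliding_fixed_match",
    "best_subset",
    "recommend",
]


@dataclass
class MatchCandidate:
    """A proposed half-open span ``[start_ms, end_ms)`` in the target stream."""

    start_ms: int
    end_ms: int
    distance: float
    template_label: str
    template_id: str
    end_index: int | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.start_ms >= self.end_ms:
            raise ValueError("candidate span must have start_ms < end_ms")
        if self.distance < 0:
            raise ValueError("distance must be non-negative")

    @property
    def span(self) -> tuple[int, int]:
        return (self.start_ms, self.end_ms)


@dataclass(frozen=True)
class SelectionConfig:
    """Candidate-selection half of the matching configuration.

    ``method`` is ``"zeroline"`` or ``"delta"``; ``k`` the number of
    recommendations (the evaluation sweeps 5–20); ``delta_ms`` the minimal
    start separation for the delta rule (default 2000 ms).
    """

    method: str = "delta"
    k: int = 10
    delta_ms: int = 2000

    def __post_init__(self) -> None:
        if self.method not in ("zeroline", "delta"):
            raise ValueError("method must be 'zeroline' or 'delta'")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.delta_ms <= 0:
            raise ValueError("delta_ms must be positive")

    def to_dict(self) -> dict:
        return {"method": self.method, "k": self.k, "delta_ms": self.delta_ms}

    @classmethod
    def from_dict(cls, d: dict) -> "SelectionConfig":
        allowed = {"method", "k", "delta_ms"}
        unknown = set(d) - allowed
        if unknown:
            raise ValueError(f"unknown selection keys: {sorted(unknown)}")
        return cls(**d)


def _index_span_to_ms(stream: SensorStream, start_idx: int, end_idx: int) -> tuple[int, int]:
    """Inclusive sample-index span → half-open ms span."""
    start_ms = int(stream.timestamps[start_idx])
    if end_idx + 1 < stream.n_samples:
        end_ms = int(stream.timestamps[end_idx + 1])
    else:
        end_ms = int(stream.timestamps[end_idx]) + int(round(stream.step_ms()))
    return start_ms, end_ms


def match_template(
    template: Template,
    stream: SensorStream,
    cfg: PreprocessConfig,
    normalize: bool = True,
) -> list[MatchCandidate]:
    """All subsequence match candidates of one template, best first."""
    if template.preprocess_fingerprint != cfg.fingerprint():
        raise ValueError(
            f"template {template.template_id} was built under a different "
            "preprocessing configuration than the one supplied"
        )
    prepped = apply_preprocess(stream, cfg)
    matches = best_subsequence_matches(template.sequence, prepped.values, normalize=normalize)
    out = []
    for m in matches:
        start_ms, end_ms = _index_span_to_ms(prepped, m.start_index, m.end_index)
        out.append(
            MatchCandidate(
                start_ms=start_ms,
                end_ms=end_ms,
                distance=m.normalized_distance if normalize else m.distance,
                template_label=template.label,
                template_id=template.template_id,
                end_index=m.end_index,
            )
        )
    return out


def select_topk_zeroline(
    candidates: list[MatchCandidate],
    zeroline_last_row: np.ndarray,
    k: int,
) -> list[MatchCandidate]:
    """Keep candidates that beat the idle template at their end position.

    ``zeroline_last_row`` must be on the same scale as the candidate
    distances (i.e. both normalized, or both raw) and computed over the
    same preprocessed stream, so positions index identically.  Survivors
    are ranked by distance; ties go to the earlier start.  The result may
    be empty — when idle explains the whole recording better than the
    activity template does, there is nothing worth recommending.
    """
    zeroline_last_row = np.asarray(zeroline_last_row, dtype=np.float64)
    survivors = []
    for c in candidates:
        if c.end_index is None:
            raise ValueError("zeroline selection needs candidates with end_index set")
        if c.distance < zeroline_last_row[c.end_index]:
            survivors.append(c)
    survivors.sort(key=lambda c: (c.distance, c.start_ms))
    return survivors[:k]


def select_topk_delta(
    candidates: list[MatchCandidate], k: int, delta_ms: int = 2000
) -> list[MatchCandidate]:
    """Greedy top-k with temporal non-maximum suppression on start times."""
    ranked = sorted(candidates, key=lambda c: (c.distance, c.start_ms))
    accepted: list[MatchCandidate] = []
    for c in ranked:
        if len(accepted) >= k:
            break
        if all(abs(c.start_ms - a.start_ms) >= delta_ms for a in accepted):
            accepted.append(c)
    return accepted


def sliding_fixed_match(
    template: Template,
    stream: SensorStream,
    cfg: PreprocessConfig,
    stride_samples: int = 5,
) -> MatchCandidate:
    """Slide a fixed-length window over the stream; return the best window.

    The window length equals the template length in samples, so the
    recommended span inherits the template's duration — adequate when at
    least one instance of the activity is known to occur (the picking
    scenario) but a source of boundary error when the performed activity
    is faster or slower than the template.
    """
    if template.preprocess_fingerprint != cfg.fingerprint():
        raise ValueError(
            f"template {template.template_id} preprocessing fingerprint mismatch"
        )
    if stride_samples < 1:
        raise ValueError("stride_samples must be >= 1")
    prepped = apply_preprocess(stream, cfg)
    n_t = template.sequence.shape[0]
    n_s = prepped.n_samples
    if n_s < n_t:
        raise ValueError("stream shorter than template")
    best = None
    for s in range(0, n_s - n_t + 1, stride_samples):
        res = dtw_full(template.sequence, prepped.values[s : s + n_t])
        d = res.normalized_distance
        if best is None or d < best[0]:
            best = (d, s)
    d, s = best
    start_ms, end_ms = _index_span_to_ms(prepped, s, s + n_t - 1)
    return MatchCandidate(
        start_ms=start_ms,
        end_ms=end_ms,
        distance=d,
        template_label=template.label,
        template_id=template.template_id,
        end_index=s + n_t - 1,
    )


def _jaccard(a: tuple[int, int], b: tuple[int, int]) -> float:
    inter = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    union = (a[1] - a[0]) + (b[1] - b[0]) - inter
    return inter / union if union > 0 else 0.0


def best_subset(per_template_best: list[MatchCandidate], k: int) -> list[MatchCandidate]:
    """Most mutually consistent k of the per-template best matches.

    Exhaustively scores every size-k subset by its mean pairwise temporal
    overlap (Jaccard) and returns the argmax; the idea is that templates
    that found the real activity agree with each other while mislocalized
    matches are scattered.  Ties resolve to the lexicographically smallest
    index set.
    """
    n = len(per_template_best)
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < k:
        raise ValueError(f"need at least k={k} candidates, got {n}")
    if comb(n, k) > 10**6:
        raise ValueError(
            f"C({n},{k}) subsets exceed the exhaustive-search limit of 1e6"
        )
    spans = [c.span for c in per_template_best]
    best_score, best_idx = -1.0, None
    for idx in combinations(range(n), k):
        pairs = list(combinations(idx, 2))
        score = sum(_jaccard(spans[a], spans[b]) for a, b in pairs) / len(pairs)
        if score > best_score:  # strict: first (lexicographic) subset wins ties
            best_score, best_idx = score, idx
    return [per_template_best[i] for i in best_idx]


def recommend(
    recording: Recording,
    templates: list[Template],
    cfg: PreprocessConfig,
    sel: SelectionConfig,
    device: str | None = None,
    normalize: bool = True,
) -> list[MatchCandidate]:
    """End-to-end recommendation for one recording.

    Matches every activity template against the (preprocessed) target
    stream, pools all candidates, applies the configured selection rule
    once on the pooled list, and returns the picks sorted by start time.
    For the zeroline rule the template list must include a zeroline
    template (label ``__zeroline__``); it contributes the idle profile and
    is never recommended itself.
    """
    activity = [t for t in templates if t.label != ZEROLINE_LABEL]
    zerolines = [t for t in templates if t.label == ZEROLINE_LABEL]
    if not activity:
        raise ValueError("no activity templates supplied")
    stream = recording.primary_stream(device)
    pooled: list[MatchCandidate] = []
    for t in activity:
        pooled.extend(match_template(t, stream, cfg, normalize=normalize))
    if sel.method == "delta":
        picked = select_topk_delta(pooled, sel.k, sel.delta_ms)
    else:
        if not zerolines:
            raise ValueError("zeroline selection requires a zeroline template")
        zt = zerolines[0]
        if zt.preprocess_fingerprint != cfg.fingerprint():
            raise ValueError("zeroline template preprocessing fingerprint mismatch")
        prepped = apply_preprocess(stream, cfg)
        norm_row, raw_row = subsequence_profile(zt.sequence, prepped.values)
        row = norm_row if normalize else raw_row
        picked = select_topk_zeroline(pooled, row, sel.k)
    return sorted(picked, key=lambda c: (c.start_ms, c.end_ms))
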