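"""Grouping complex-activity templates by motion similarity.

Complex activities (kitchen work: *take oil*, *open cupboard*, ...) share
sub-motions, so templates of semantically different activities can be
nearly identical in motion.  Clustering the templates by DTW distance
makes those groups visible: each template is converted to a sequence of
windowed energy/MAD feature vectors, pairwise normalized DTW distances
are computed over those sequences, and agglomerative clustering builds a
dendrogram that can be cut into flat clusters or exported as Newick.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .dtw import pairwise_dtw_matrix
from .preprocessing import FeatureSequence, windowed_features
from .signal_model import SensorStream
from .templates import Template

__all__ = ["Dendrogram", "cluster_templates", "cut_dendrogram", "export_newick"]

LINKAGES = ("average", "complete", "single")


@dataclass
class Dendrogram:
    """Merge tree of agglomerative clustering over template distances."""

    leaf_ids: list[str]
    merges: np.ndarray  # scipy linkage matrix, shape (n-1, 4)
    linkage_method: str

    def __post_init__(self) -> None:
        self.merges = np.asarray(self.merges, dtype=np.float64)
        n = len(self.leaf_ids)
        if self.merges.shape != (n - 1, 4):
            raise ValueError("linkage matrix must have n-1 rows of 4 columns")

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]


def _template_feature_sequence(
    t: Template, window_len_ms: int, hop_ms: int
) -> FeatureSequence:
    step = 1000.0 / t.sample_rate_hz
    ts = np.round(np.arange(t.sequence.shape[0]) * step).astype(np.int64)
    stream = SensorStream(
        recording_id=t.source_recording,
        device="template",
        sample_rate_hz=t.sample_rate_hz,
        timestamps=ts,
        channels=[f"c{i}" for i in range(t.sequence.shape[1])],
        values=t.sequence,
    )
    try:
        return windowed_features(stream, window_len_ms, hop_ms)
    except ValueError as exc:
        raise ValueError(
            f"template {t.template_id} is too short for one "
            f"{window_len_ms} ms feature window"
        ) from exc


def _standardize(seqs: list[np.ndarray]) -> list[np.ndarray]:
    """Z-score each feature dimension over all windows of all templates.

    Energy scales with squared amplitude, so raw feature distances are
    dominated by the most vigorous templates; standardizing puts every
    dimension on a comparable footing before the Euclidean DTW cost.
    """
    stacked = np.vstack(seqs)
    mean = stacked.mean(axis=0)
    sd = stacked.std(axis=0)
    sd[sd == 0] = 1.0
    return [(s - mean) / sd for s in seqs]


def cluster_templates(
    templates: list[Template],
    window_len_ms: int = 800,
    hop_ms: int = 400,
    linkage_method: str = "average",
    use_features: bool = True,
    standardize: bool = True,
) -> Dendrogram:
    """Agglomerative clustering of templates under normalized DTW distance.

    With ``use_features`` (default) DTW runs over windowed energy/MAD
    feature sequences, which express the character of complex motions
    better than raw samples; ``use_features=False`` clusters the raw
    preprocessed signals instead, for comparison.
    """
    if len(templates) < 2:
        raise ValueError("need at least 2 templates to cluster")
    if linkage_method not in LINKAGES:
        raise ValueError(f"linkage must be one of {LINKAGES}")
    if use_features:
        seqs = [
            _template_feature_sequence(t, window_len_ms, hop_ms).features
            for t in templates
        ]
        if standardize:
            seqs = _standardize(seqs)
    else:
        seqs = [t.sequence for t in templates]
    dist = pairwise_dtw_matrix(seqs)
    Z = linkage(squareform(dist, checks=False), method=linkage_method)
    return Dendrogram(
        leaf_ids=[t.template_id for t in templates],
        merges=Z,
        linkage_method=linkage_method,
    )


def cut_dendrogram(dend: Dendrogram, n_clusters: int) -> dict[str, int]:
    """Flat clusters; ids are renumbered by each cluster's smallest leaf index."""
    n = len(dend.leaf_ids)
    if not 1 <= n_clusters <= n:
        raise ValueError(f"n_clusters must lie in [1, {n}]")
    raw = fcluster(dend.merges, t=n_clusters, criterion="maxclust")
    # scipy may return fewer clusters only on degenerate ties; renumber stably
    order: dict[int, int] = {}
    for leaf_idx in range(n):
        order.setdefault(int(raw[leaf_idx]), len(order))
    return {dend.leaf_ids[i]: order[int(raw[i])] for i in range(n)}


def export_newick(dend: Dendrogram) -> str:
    """Rooted Newick with branch lengths from merge heights.

    A leaf's branch length is its parent's merge height; an internal
    node's branch length is the difference between its parent's and its
    own height.
    """
    n = len(dend.leaf_ids)

    def node_height(idx: int) -> float:
        return 0.0 if idx < n else float(dend.merges[idx - n, 2])

    def render(idx: int, parent_height: float) -> str:
        length = parent_height - node_height(idx)
        if idx < n:
            name = dend.leaf_ids[idx].replace("(", "_").replace(")", "_").replace(
                ",", "_").replace(":", "_").replace(";", "_").replace(" ", "_")
            return f"{name}:{length:.9g}"
        a, b = int(dend.merges[idx - n, 0]), int(dend.merges[idx - n, 1])
        h = node_height(idx)
        return f"({render(a, h)},{render(b, h)}):{length:.9g}"

    root = n + dend.merges.shape[0] - 1
    h = node_height(root)
    a, b = int(dend.merges[root - n, 0]), int(dend.merges[root - n, 1])
    return f"({render(a, h)},{render(b, h)});"
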