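"""Evaluation of detected brain states: purity, change points, ablations.

Purity is the standard clustering-accuracy score against a known task
schedule: each predicted cluster is credited with its majority true class,
``purity = (1/T) * sum_clusters max_class |cluster intersect class|``.
Change points are read off the per-window label sequence after suppressing
segments shorter than a minimum duration.  The ablation harness mirrors the
component on/off analysis: the feature-learning network and/or the
mean-shift stage are disabled and replaced by the identity and by plain
spectral clustering, respectively.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.cluster import SpectralClustering

from .meanshift import StateLabeling
from .riemann import pairwise_geodesic
from .training import pairwise_similarity

#: shortest label run kept as a genuine state visit (in windows)
DEFAULT_MIN_DURATION = 5


def purity_score(pred: StateLabeling | np.ndarray, truth: Sequence | np.ndarray) -> float:
    """Clustering purity of predicted state labels against true classes.

    Invariant under relabeling of either argument; equals 1 when every
    predicted cluster is pure (a refinement of the truth counts as perfect).
    """
    y = pred.labels if isinstance(pred, StateLabeling) else np.asarray(pred)
    t = np.asarray(truth)
    if len(y) != len(t):
        raise ValueError(f"length mismatch: {len(y)} predictions, {len(t)} truths")
    total = 0
    for c in np.unique(y):
        _, counts = np.unique(t[y == c], return_counts=True)
        total += counts.max()
    return total / len(y)


def extract_change_points(labels: np.ndarray, min_duration: int = DEFAULT_MIN_DURATION) -> list[int]:
    """Indices where the state label changes, after minimum-duration filtering.

    Runs shorter than ``min_duration`` are merged into the preceding
    segment (the leading run is always kept); the returned indices are the
    first index of each surviving segment after the first.  Adjacent
    segments that end up with the same label after a merge are fused.
    """
    y = np.asarray(labels)
    if len(y) == 0:
        raise ValueError("labels must be nonempty")
    # run-length encode
    breaks = np.flatnonzero(np.diff(y)) + 1
    starts = np.concatenate([[0], breaks])
    ends = np.concatenate([breaks, [len(y)]])
    segs = [(int(s), int(e), int(y[s])) for s, e in zip(starts, ends)]
    # merge short runs into the preceding segment
    merged: list[list[int]] = []
    for s, e, lab in segs:
        if merged and (e - s) < min_duration:
            merged[-1][1] = e
        elif merged and merged[-1][2] == lab:
            merged[-1][1] = e
        else:
            merged.append([s, e, lab])
    # fuse neighbours that became same-label after merging
    fused: list[list[int]] = []
    for s, e, lab in merged:
        if fused and fused[-1][2] == lab:
            fused[-1][1] = e
        else:
            fused.append([s, e, lab])
    return [s for s, _, _ in fused[1:]]


def spectral_cluster_labels(logs: np.ndarray, n_clusters: int,
                            seed: int = 0) -> np.ndarray:
    """Spectral clustering baseline on the geodesic-similarity affinity.

    Affinity between two windows is ``1 / (1 + g)`` on their log-matrix
    distance — the same similarity the contrastive objective uses — so the
    ablation isolates the learning stages rather than the metric.
    """
    g = pairwise_geodesic(logs)
    affinity = pairwise_similarity(g)
    sc = SpectralClustering(n_clusters=n_clusters, affinity="precomputed",
                            random_state=seed, assign_labels="kmeans")
    return sc.fit_predict(affinity)


@dataclass
class AblationResult:
    """Mean/STD purity of one component configuration over a test split."""

    use_spd_dnn: bool
    use_ms_rnn: bool
    purities: np.ndarray

    @property
    def mean(self) -> float:
        return float(self.purities.mean())

    @property
    def std(self) -> float:
        return float(self.purities.std())

    def as_dict(self) -> dict:
        return {
            "use_spd_dnn": self.use_spd_dnn,
            "use_ms_rnn": self.use_ms_rnn,
            "purity_mean": self.mean,
            "purity_std": self.std,
            "n_series": int(len(self.purities)),
        }


def ablation_run(dataset, cfg, use_spd_dnn: bool, use_ms_rnn: bool) -> AblationResult:
    """Purity over the test split with components switched on or off.

    With the network off, raw aligned window-FC trajectories feed the next
    stage; with the mean-shift stage off, spectral clustering with the true
    number of states replaces mode grouping; with both off, spectral
    clustering runs on the raw aligned FC matrices.
    """
    from .pipeline import fit_pipeline, detect_series  # lazy: avoids cycle

    fitted = fit_pipeline(dataset.train, cfg,
                          use_spd_dnn=use_spd_dnn, use_ms_rnn=use_ms_rnn)
    purities = []
    for series, truth in dataset.test:
        res = detect_series(series, fitted, cfg,
                            use_spd_dnn=use_spd_dnn, use_ms_rnn=use_ms_rnn)
        truth_w = truth[res.trajectory_times]
        purities.append(purity_score(res.labels, truth_w))
    return AblationResult(use_spd_dnn, use_ms_rnn, np.asarray(purities))
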