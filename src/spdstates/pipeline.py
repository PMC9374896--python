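"""End-to-end orchestration: config, fitting, and per-series detection.

The full pipeline is

    series -> sliding-window FC -> parallel-transport alignment
           -> SPD network -> mean-shift recurrence -> mode grouping
           -> state labels + change points

:func:`fit_pipeline` estimates everything population-level (the alignment
center and, optionally, trained network weights and bandwidths) from a
training split; :func:`detect_series` applies the fitted pipeline to one
held-out series.  Components can be switched off for ablations: without
the network the aligned window correlations feed the mean-shift stage
directly; without the mean-shift stage, spectral clustering with a known
state count replaces mode grouping.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .evaluation import (
    DEFAULT_MIN_DURATION,
    extract_change_points,
    spectral_cluster_labels,
)
from .meanshift import (
    DEFAULT_N_LAYERS,
    DEFAULT_SIGMA,
    MSRNNParams,
    StateLabeling,
    group_modes,
    msrnn_forward,
)
from .network import DEFAULT_EPSILON, SPDNetModel, spdnet_forward
from .riemann import (
    Metric,
    Trajectory,
    align_trajectories,
    frechet_mean,
    parallel_transport,
)
from .training import LossConfig, train
from .windows import BoldSeries, sliding_window_fc


@dataclass
class PipelineConfig:
    """All tunable parameters of the pipeline, JSON/YAML round-trippable.

    Defaults follow the simulated benchmark: window 25 on 10 regions, a
    10->8->6->4 network with spectrum floor 1e-4, five mean-shift layers at
    bandwidth 0.5, margin 0.5, learning rate 0.01.
    """

    window: int = 25
    stride: int = 1
    dims: tuple[int, ...] = (10, 8, 6, 4)
    epsilon: float = DEFAULT_EPSILON
    n_ms_layers: int = DEFAULT_N_LAYERS
    sigma: float = DEFAULT_SIGMA
    alpha: float = 0.5
    lr: float = 0.01
    epochs: int = 0
    label_source: str = "ms_grouping"
    grouping_tol: float | None = None
    min_duration: int | None = None
    n_states: int = 4
    metric: Metric = "log_euclidean"
    seed: int = 0

    def __post_init__(self) -> None:
        self.dims = tuple(int(d) for d in self.dims)

    @property
    def effective_min_duration(self) -> int:
        """Shortest label run treated as a genuine state visit.

        Defaults to half the window width (windows straddling a transition
        are ambiguous over that corridor, so transient modes scale with the
        window), floored at 5 windows.
        """
        if self.min_duration is not None:
            return self.min_duration
        return max(DEFAULT_MIN_DURATION, self.window // 2)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValueError(f"config {path} must be a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_file(self, path) -> None:
        d = asdict(self)
        d["dims"] = list(d["dims"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


@dataclass
class FittedPipeline:
    """Population-level state estimated from the training split."""

    pop_mean: np.ndarray
    model: SPDNetModel | None
    ms: MSRNNParams | None
    loss_history: list[float] = field(default_factory=list)

    def save(self, directory) -> None:
        """Checkpoint: population mean, model weights and bandwidths."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        np.savetxt(d / "pop_mean.tsv", self.pop_mean, delimiter="\t")
        meta = {"has_model": self.model is not None,
                "sigmas": None if self.ms is None else self.ms.sigmas.tolist(),
                "loss_history": self.loss_history}
        (d / "pipeline.json").write_text(json.dumps(meta, indent=2))
        if self.model is not None:
            self.model.save(d / "model")

    @classmethod
    def load(cls, directory) -> "FittedPipeline":
        d = Path(directory)
        meta = json.loads((d / "pipeline.json").read_text())
        model = SPDNetModel.load(d / "model") if meta["has_model"] else None
        ms = (MSRNNParams(np.asarray(meta["sigmas"]))
              if meta["sigmas"] is not None else None)
        return cls(pop_mean=np.loadtxt(d / "pop_mean.tsv", delimiter="\t"),
                   model=model, ms=ms,
                   loss_history=list(meta.get("loss_history", [])))


@dataclass
class DetectionResult:
    """Per-series output of the fitted pipeline.

    ``labels`` carries the raw per-window mode assignment (every grouped
    mode, including transient ones from windows straddling a transition);
    ``n_states`` is the number of brain states the pipeline reports: the
    distinct states that survive the minimum-duration rule, i.e. the states
    of the segmentation whose boundaries are ``change_points`` (in series
    time).
    """

    labels: StateLabeling
    trajectory_times: np.ndarray
    change_points: list[int]
    n_states: int
    stratified: Trajectory | None = None


def _as_series(item) -> BoldSeries:
    return item[0] if isinstance(item, tuple) else item


def fc_trajectories(items: Sequence, cfg: PipelineConfig) -> list[Trajectory]:
    """Sliding-window FC for a batch of series (or (series, truth) pairs)."""
    return [
        sliding_window_fc(_as_series(it), cfg.window, cfg.stride)
        for it in items
    ]


def fit_pipeline(
    train_items: Sequence,
    cfg: PipelineConfig,
    *,
    use_spd_dnn: bool = True,
    use_ms_rnn: bool = True,
) -> FittedPipeline:
    """Fit the population alignment center and (optionally) train the model.

    ``train_items`` is a list of :class:`BoldSeries` or
    ``(BoldSeries, truth)`` pairs; truths are only consumed when
    ``cfg.label_source == 'known_schedule'``.  With ``cfg.epochs == 0`` the
    network keeps its seeded semi-orthogonal initialization — projection
    through random semi-orthogonal congruences already preserves the state
    geometry; training sharpens the separation.
    """
    trajs = fc_trajectories(train_items, cfg)
    aligned, pop_mean = align_trajectories(trajs, cfg.metric)

    model = None
    ms = None
    history: list[float] = []
    if use_spd_dnn:
        model = SPDNetModel.create(list(cfg.dims), epsilon=cfg.epsilon,
                                   seed=cfg.seed)
    if use_ms_rnn:
        ms = MSRNNParams.create(cfg.n_ms_layers, cfg.sigma)
    if use_spd_dnn and use_ms_rnn and cfg.epochs > 0:
        loss_cfg = LossConfig(alpha=cfg.alpha, label_source=cfg.label_source,
                              lr=cfg.lr, epochs=cfg.epochs, seed=cfg.seed,
                              grouping_tol=cfg.grouping_tol)
        schedules = None
        if cfg.label_source == "known_schedule":
            schedules = []
            for it, traj in zip(train_items, trajs):
                if not isinstance(it, tuple):
                    raise ValueError(
                        "known_schedule training needs (series, truth) pairs")
                schedules.append(np.asarray(it[1])[traj.times])
        model, ms, history = train(model, ms, aligned, loss_cfg, schedules)
    return FittedPipeline(pop_mean=pop_mean, model=model, ms=ms,
                          loss_history=history)


def detect_series(
    series: BoldSeries,
    fitted: FittedPipeline,
    cfg: PipelineConfig,
    *,
    use_spd_dnn: bool = True,
    use_ms_rnn: bool = True,
) -> DetectionResult:
    """Label the windows of one series with the fitted pipeline.

    The series' trajectory is transported from its own Fréchet mean to the
    fitted population mean before the network is applied, matching how the
    training split was aligned.
    """
    traj = sliding_window_fc(series, cfg.window, cfg.stride)
    subj_mean = frechet_mean(traj.matrices, cfg.metric)
    mats = np.stack([
        parallel_transport(X, subj_mean, fitted.pop_mean)
        for X in traj.matrices
    ])
    traj = Trajectory(mats, traj.times, series.subject_id)

    if use_spd_dnn:
        if fitted.model is None:
            raise ValueError("pipeline was fitted without the SPD network")
        traj = spdnet_forward(fitted.model, traj)

    stratified = None
    if use_ms_rnn:
        if fitted.ms is None:
            raise ValueError("pipeline was fitted without the mean-shift stage")
        stratified = msrnn_forward(fitted.ms, traj)
        labeling = group_modes(stratified, cfg.grouping_tol)
    else:
        y = spectral_cluster_labels(traj.logs(), cfg.n_states, seed=cfg.seed)
        modes = [
            frechet_mean(traj.matrices[y == q], cfg.metric)
            for q in np.unique(y)
        ]
        labeling = StateLabeling(y, modes, len(modes))

    cps_w = extract_change_points(labeling.labels, cfg.effective_min_duration)
    change_points = [int(traj.times[j]) for j in cps_w]
    # states of the cleaned segmentation: majority label of each segment
    bounds = [0] + cps_w + [len(labeling.labels)]
    seg_labels = [
        int(np.bincount(labeling.labels[a:b]).argmax())
        for a, b in zip(bounds, bounds[1:])
    ]
    return DetectionResult(labels=labeling, trajectory_times=traj.times,
                           change_points=change_points,
                           n_states=len(set(seg_labels)),
                           stratified=stratified)
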