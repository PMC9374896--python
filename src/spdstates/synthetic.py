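"""Synthetic multichannel series with block-modular connectivity states.

Emulates the simulated-fMRI benchmark this pipeline is evaluated on:
10 regions, four brain states, each state a correlation template made of
three modules (blocks) along the diagonal — within-module connectivity 1,
cross-module 0 — occupied for 100 consecutive time points, giving state
change points at t = 100, 200 and 300.

Rather than modelling haemodynamics and events, the generator draws each
segment from a zero-mean multivariate normal whose covariance interpolates
between the SPD-lifted state template and the identity:

    cov = noise_sd^2 * (lam * template_spd + (1 - lam) * I)

``lam`` (default 0.7) sets the within-module correlation of the observed
signal and thereby the effective noise level; ``noise_sd`` only rescales
amplitudes and leaves correlations untouched.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .windows import BoldSeries, ensure_spd

#: default module partitions of the four states: block boundaries over
#: 10 regions, rotated so every template is distinct
DEFAULT_PARTITIONS: tuple[tuple[int, ...], ...] = (
    (3, 3, 4),
    (4, 3, 3),
    (2, 5, 3),
    (5, 2, 3),
)


@dataclass
class SimDesign:
    """Parameters of the block-modular state design.

    ``states`` lists, per state, the module sizes (a partition of
    ``n_regions``); ``durations`` the number of time points spent in each
    state; ``lam`` the template/identity interpolation weight.
    """

    n_regions: int = 10
    states: Sequence[Sequence[int]] = DEFAULT_PARTITIONS
    durations: Sequence[int] = (100, 100, 100, 100)
    lam: float = 0.7
    noise_sd: float = 1.0
    window: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.states) != len(self.durations):
            raise ValueError("one duration per state required")
        if any(d <= 0 for d in self.durations):
            raise ValueError("durations must be positive")
        for q, part in enumerate(self.states):
            if any(p <= 0 for p in part) or sum(part) != self.n_regions:
                raise ValueError(
                    f"state {q}: module sizes {part} must be a partition "
                    f"of {self.n_regions} regions"
                )
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError("lam must be in [0, 1]")

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def change_points(self) -> list[int]:
        """True state-transition times (first index of each later segment)."""
        return list(np.cumsum(self.durations)[:-1])


def make_state_templates(design: SimDesign) -> list[np.ndarray]:
    """Binary block correlation templates, one per state.

    Entry (i, j) is 1 when regions i and j share a module (and on the
    diagonal), else 0.  Templates are pairwise distinct by construction of
    the default partitions; a duplicate partition list raises.
    """
    templates = []
    for part in design.states:
        T = np.zeros((design.n_regions, design.n_regions))
        start = 0
        for size in part:
            T[start : start + size, start : start + size] = 1.0
            start += size
        templates.append(T)
    for a in range(len(templates)):
        for b in range(a + 1, len(templates)):
            if np.array_equal(templates[a], templates[b]):
                raise ValueError(f"states {a} and {b} have identical templates")
    return templates


def template_covariance(design: SimDesign, template: np.ndarray) -> np.ndarray:
    """Segment covariance: SPD-lifted template blended toward the identity."""
    spd = ensure_spd(template)
    n = design.n_regions
    cov = design.lam * spd + (1.0 - design.lam) * np.eye(n)
    return design.noise_sd ** 2 * cov


def simulate_series(
    design: SimDesign, seed: int | None = None
) -> tuple[BoldSeries, np.ndarray]:
    """Draw one series from the design.

    Returns the concatenated series (length = sum of durations) and the
    true per-time-point state labels, with transitions exactly at the
    cumulative duration boundaries.
    """
    rng = np.random.default_rng(design.seed if seed is None else seed)
    templates = make_state_templates(design)
    segments = []
    labels = []
    for q, (tpl, dur) in enumerate(zip(templates, design.durations)):
        cov = template_covariance(design, tpl)
        segments.append(rng.multivariate_normal(
            np.zeros(design.n_regions), cov, size=dur, method="cholesky"))
        labels.append(np.full(dur, q, dtype=int))
    values = np.vstack(segments)
    series = BoldSeries(values=values, subject_id=f"sim-{seed if seed is not None else design.seed}")
    return series, np.concatenate(labels)


@dataclass
class Dataset:
    """Train/validation/test bundle of simulated series."""

    train: list[tuple[BoldSeries, np.ndarray]]
    val: list[tuple[BoldSeries, np.ndarray]]
    test: list[tuple[BoldSeries, np.ndarray]]


def make_dataset(
    design: SimDesign,
    n_series: int = 2000,
    split: tuple[int, int, int] = (900, 100, 1000),
) -> Dataset:
    """Simulate ``n_series`` independent series and partition them.

    The default sizes mirror the benchmark protocol (2000 series split
    900/100/1000).  Each series uses its own child seed of ``design.seed``,
    so splits are disjoint and the whole bundle is reproducible.
    """
    if sum(split) != n_series:
        raise ValueError(f"split {split} must sum to n_series={n_series}")
    seeds = np.random.SeedSequence(design.seed).generate_state(n_series)
    all_series = [
        simulate_series(design, seed=int(s) % (2 ** 31)) for s in seeds
    ]
    a, b, _ = split
    return Dataset(
        train=all_series[:a],
        val=all_series[a : a + b],
        test=all_series[a + b :],
    )


def truth_at_window_centers(truth: np.ndarray, times: np.ndarray) -> np.ndarray:
    """True labels sampled at window-center time indices."""
    return np.asarray(truth)[np.asarray(times, dtype=int)]
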