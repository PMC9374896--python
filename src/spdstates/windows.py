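"""Sliding-window functional connectivity from multichannel time series.

Turns a BOLD-like series (T time points x N regions) into a trajectory of
Pearson-correlation matrices, one per sliding window, regularized to be
strictly positive definite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .riemann import Trajectory, _symmetrize

#: eigenvalue floor applied to every window correlation matrix
SPD_FLOOR = 1e-6


@dataclass
class BoldSeries:
    """A multichannel regional time series.

    ``values`` is (T, N): rows are time points, columns are regions.
    """

    values: np.ndarray
    region_ids: list[str] = field(default_factory=list)
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError(f"values must be 2-D (T, N), got {self.values.shape}")
        if np.isnan(self.values).any():
            raise ValueError("series contains missing values")
        if not self.region_ids:
            self.region_ids = [f"r{i}" for i in range(self.values.shape[1])]
        if len(self.region_ids) != self.values.shape[1]:
            raise ValueError("region_ids length must match number of columns")

    @property
    def n_time(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_file(cls, path, subject_id: str = "") -> "BoldSeries":
        """Read a delimited-text series (rows = time, columns = regions).

        A header row of region names is auto-detected.
        """
        df = pd.read_csv(path, sep=None, engine="python", header=None)
        first = df.iloc[0]
        if first.apply(lambda v: isinstance(v, str)).any():
            region_ids = [str(v) for v in first]
            values = df.iloc[1:].to_numpy(dtype=float)
        else:
            region_ids = []
            values = df.to_numpy(dtype=float)
        return cls(values=values, region_ids=region_ids,
                   subject_id=subject_id or str(path))

    def to_file(self, path) -> None:
        pd.DataFrame(self.values, columns=self.region_ids).to_csv(
            path, sep="\t", index=False
        )


def ensure_spd(C: np.ndarray, floor: float = SPD_FLOOR) -> np.ndarray:
    """Clip eigenvalues of a symmetric matrix up to ``floor``.

    Leaves the matrix untouched when it is already comfortably positive
    definite; otherwise eigenvalues below ``floor`` are raised to ``floor``,
    preserving eigenvectors.
    """
    C = _symmetrize(np.asarray(C, dtype=float))
    w, U = np.linalg.eigh(C)
    if w[0] >= floor:
        return C
    return _symmetrize((U * np.maximum(w, floor)) @ U.T)


def sliding_window_fc(
    series: BoldSeries,
    window: int,
    stride: int = 1,
    *,
    floor: float = SPD_FLOOR,
) -> Trajectory:
    """Sliding-window Pearson correlation trajectory.

    Windows are centered: the window starting at row ``i`` covers
    ``[i, i + window)`` and is indexed by its center ``i + window // 2``
    (0-based), yielding ``T - window + 1`` matrices at stride 1.  Each
    correlation matrix is eigenvalue-floored via :func:`ensure_spd` so short
    windows (``window < N``) still produce SPD matrices.
    """
    if window <= 0 or stride <= 0:
        raise ValueError("window and stride must be positive")
    T, N = series.values.shape
    if window > T:
        raise ValueError(f"window {window} exceeds series length {T}")
    starts = range(0, T - window + 1, stride)
    mats = np.empty((len(starts), N, N))
    times = np.empty(len(starts), dtype=int)
    for j, i in enumerate(starts):
        chunk = series.values[i : i + window]
        sd = chunk.std(axis=0)
        if np.any(sd == 0.0):
            bad = [series.region_ids[k] for k in np.flatnonzero(sd == 0.0)]
            raise ValueError(
                f"zero-variance region(s) {bad} in window starting at t={i}"
            )
        C = np.corrcoef(chunk, rowvar=False)
        mats[j] = ensure_spd(C, floor)
        times[j] = i + window // 2
    return Trajectory(mats, times, series.subject_id)
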