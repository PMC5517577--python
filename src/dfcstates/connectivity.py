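"""Windowed correlation matrices and window-level stage labels.

Front end of the staging pipeline: slice each subject's BOLD matrix into
time windows (non-overlapping by default, sliding for short scans),
compute the pairwise Pearson correlation matrix per window, and label
each window with the majority sleep stage of its volumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .simulate import STAGE_ORDER, Hypnogram, RoiTimeSeries

logger = logging.getLogger(__name__)


class WindowError(ValueError):
    """Series too short for the requested window."""


@dataclass(frozen=True)
class WindowSpec:
    """Window length and step, in volumes.

    ``step == length`` gives non-overlapping windows; ``step == 1`` gives
    maximally overlapping sliding windows.
    """

    length: int = 50
    step: int | None = None

    def __post_init__(self) -> None:
        if self.step is None:
            object.__setattr__(self, "step", self.length)
        if self.length < 2:
            raise ValueError("window length must be >= 2 volumes")
        if not 1 <= self.step <= self.length:
            raise ValueError("step must satisfy 1 <= step <= length")

    @property
    def mode(self) -> str:
        return "nonoverlapping" if self.step == self.length else "sliding"


def sliding_window_spec(length: int = 50) -> WindowSpec:
    return WindowSpec(length=length, step=1)


def window_series(ts: RoiTimeSeries | np.ndarray, spec: WindowSpec) -> list[tuple[int, int]]:
    """Half-open ``[start, stop)`` volume ranges at starts 0, step, 2*step, ...

    The trailing partial window is discarded.
    """
    t = ts.n_volumes if isinstance(ts, RoiTimeSeries) else len(ts)
    if t < spec.length:
        raise WindowError(
            f"series of {t} volumes is shorter than window length {spec.length}"
        )
    return [(s, s + spec.length) for s in range(0, t - spec.length + 1, spec.step)]


@dataclass(frozen=True)
class ConnectivityMatrix:
    """One window's R x R Pearson correlation matrix."""

    matrix: np.ndarray
    subject: str = ""
    window_index: int = 0
    start: int = 0
    stop: int = 0

    def validate(self) -> None:
        m = self.matrix
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(m), 1.0, atol=1e-10):
            raise ValueError("correlation matrix must have unit diagonal")
        if (np.abs(m) > 1.0 + 1e-10).any():
            raise ValueError("correlation entries must lie in [-1, 1]")


def correlation_matrix(window_data: np.ndarray) -> np.ndarray:
    """Pairwise Pearson correlations over one window (rows = volumes).

    A zero-variance region yields undefined correlations; these are set
    to 0 (diagonal stays 1) and a warning is logged, so one flat region
    does not fail a whole cohort.
    """
    if window_data.shape[0] < 2:
        raise WindowError("need at least two volumes to correlate")
    sd = window_data.std(axis=0)
    flat = sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.corrcoef(window_data, rowvar=False)
    if flat.any():
        logger.warning(
            "zero-variance region(s) %s in window; correlations set to 0",
            np.nonzero(flat)[0].tolist(),
        )
        c[flat, :] = 0.0
        c[:, flat] = 0.0
    np.fill_diagonal(c, 1.0)
    return np.clip(c, -1.0, 1.0)


def windowed_connectivity(ts: RoiTimeSeries, spec: WindowSpec) -> list[ConnectivityMatrix]:
    """All window correlation matrices of one subject."""
    out = []
    for w, (start, stop) in enumerate(window_series(ts, spec)):
        out.append(
            ConnectivityMatrix(
                matrix=correlation_matrix(ts.data[start:stop]),
                subject=ts.subject,
                window_index=w,
                start=start,
                stop=stop,
            )
        )
    return out


def connectivity_vectors(ts: RoiTimeSeries, spec: WindowSpec) -> np.ndarray:
    """Stacked upper-triangle vectors, one row per window (fast path)."""
    windows = window_series(ts, spec)
    r = ts.n_regions
    iu = np.triu_indices(r, 1)
    out = np.empty((len(windows), r * (r - 1) // 2))
    for w, (start, stop) in enumerate(windows):
        out[w] = correlation_matrix(ts.data[start:stop])[iu]
    return out


# --------------------------------------------------------------------------
# Vectorization
# --------------------------------------------------------------------------

def vectorize_upper(matrix: ConnectivityMatrix | np.ndarray) -> np.ndarray:
    """Upper triangle (above the diagonal) in row-major order."""
    m = matrix.matrix if isinstance(matrix, ConnectivityMatrix) else matrix
    return m[np.triu_indices(m.shape[0], 1)]


def _triangular_dim(p: int) -> int:
    r = int(round((1 + np.sqrt(1 + 8 * p)) / 2))
    if r * (r - 1) // 2 != p:
        raise ValueError(f"length {p} is not a triangular number")
    return r


def devectorize(vector: np.ndarray) -> np.ndarray:
    """Rebuild the symmetric unit-diagonal matrix from its upper triangle."""
    r = _triangular_dim(len(vector))
    m = np.eye(r)
    iu = np.triu_indices(r, 1)
    m[iu] = vector
    m[(iu[1], iu[0])] = vector
    return m


# --------------------------------------------------------------------------
# Stage labels for windows
# --------------------------------------------------------------------------

def stage_label_for_window(
    hypnogram: Hypnogram, start: int, stop: int, tr: float
) -> str:
    """Majority stage over a window's volumes; ties go to the lighter stage.

    Each volume takes the stage of its containing 30-s epoch; stages are
    ordered W < N1 < N2 < N3 < REM for tie-breaking.
    """
    if stop <= start:
        raise ValueError("empty window")
    if (stop - 1) * tr >= hypnogram.duration:
        raise ValueError("window extends beyond hypnogram duration")
    counts: dict[str, int] = {}
    for v in range(start, stop):
        s = hypnogram.stages[int(v * tr // hypnogram.epoch_length)]
        counts[s] = counts.get(s, 0) + 1
    return min(counts, key=lambda s: (-counts[s], STAGE_ORDER.index(s)))


def window_stage_labels(
    hypnogram: Hypnogram, windows: list[tuple[int, int]], tr: float
) -> list[str]:
    """Majority stage label for every window."""
    return [stage_label_for_window(hypnogram, a, b, tr) for a, b in windows]
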