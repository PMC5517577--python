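"""Plain-text readers and writers for the pipeline's on-disk formats.

Time series are TSV (volumes x regions, header = region names) with a
JSON sidecar carrying the subject id and TR; hypnograms are two-column
TSV (epoch_start_seconds, stage); structural matrices and label tables
are square/two-column TSV.  All writers round-trip losslessly through
full-precision text.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import STAGE_ORDER, Hypnogram, RoiTimeSeries


class ParseError(ValueError):
    """Malformed on-disk input; the message names the offending location."""


# --------------------------------------------------------------------------
# Time series
# --------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_timeseries(ts: RoiTimeSeries, path: str | Path) -> None:
    path = Path(path)
    pd.DataFrame(ts.data, columns=list(ts.regions)).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )
    _sidecar_path(path).write_text(
        json.dumps({"subject": ts.subject, "tr": ts.tr}) + "\n"
    )


def read_timeseries(path: str | Path) -> RoiTimeSeries:
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise ParseError(f"missing TR sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    if "tr" not in meta:
        raise ParseError(f"sidecar {sidecar} lacks 'tr'")
    try:
        frame = pd.read_csv(path, sep="\t", float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    data = frame.to_numpy()
    if data.dtype == object or not np.issubdtype(data.dtype, np.number):
        bad = frame.map(lambda v: isinstance(v, str)).to_numpy()
        row, col = np.argwhere(bad)[0]
        raise ParseError(
            f"{path}: non-numeric cell at row {row + 1}, column '{frame.columns[col]}'"
        )
    if np.isnan(data).any():
        row, col = np.argwhere(np.isnan(data))[0]
        raise ParseError(
            f"{path}: missing value at row {row + 1}, column '{frame.columns[col]}'"
        )
    return RoiTimeSeries(
        subject=str(meta.get("subject", path.stem)),
        data=data,
        tr=float(meta["tr"]),
        regions=tuple(frame.columns),
    )


# --------------------------------------------------------------------------
# Hypnograms
# --------------------------------------------------------------------------

def write_hypnogram(hyp: Hypnogram, path: str | Path) -> None:
    rows = [
        (i * hyp.epoch_length, s) for i, s in enumerate(hyp.stages)
    ]
    pd.DataFrame(rows, columns=["epoch_start_seconds", "stage"]).to_csv(
        Path(path), sep="\t", index=False, float_format="%.17g"
    )


def read_hypnogram(path: str | Path, subject: str | None = None) -> Hypnogram:
    path = Path(path)
    frame = pd.read_csv(path, sep="\t")
    expected = ["epoch_start_seconds", "stage"]
    if list(frame.columns) != expected:
        raise ParseError(f"{path}: expected columns {expected}, got {list(frame.columns)}")
    stages = [str(s) for s in frame["stage"]]
    bad = sorted(set(stages) - set(STAGE_ORDER))
    if bad:
        raise ParseError(
            f"{path}: unknown stage code(s) {bad}; allowed codes: {list(STAGE_ORDER)}"
        )
    starts = frame["epoch_start_seconds"].to_numpy(dtype=float)
    if len(starts) > 1:
        steps = np.diff(starts)
        if (steps <= 0).any():
            raise ParseError(f"{path}: epoch start times must increase monotonically")
        if not np.allclose(steps, steps[0]):
            raise ParseError(f"{path}: epoch start times must be evenly spaced")
        epoch = float(steps[0])
    else:
        epoch = 30.0
    if not np.isclose(starts[0], 0.0):
        raise ParseError(f"{path}: first epoch must start at 0 s")
    return Hypnogram(
        subject=subject or path.stem, stages=tuple(stages), epoch_length=epoch
    )


# --------------------------------------------------------------------------
# Matrices, labels, window stacks
# --------------------------------------------------------------------------

def write_matrix(matrix: np.ndarray, path: str | Path, labels: list[str] | None = None) -> None:
    """Square matrix as TSV with row/column labels."""
    labels = labels or [f"n{i}" for i in range(len(matrix))]
    pd.DataFrame(matrix, index=labels, columns=labels).to_csv(
        Path(path), sep="\t", float_format="%.17g"
    )


def read_matrix(path: str | Path) -> tuple[np.ndarray, list[str]]:
    frame = pd.read_csv(Path(path), sep="\t", index_col=0,
                        float_precision="round_trip")
    mat = frame.to_numpy(dtype=float)
    if mat.shape[0] != mat.shape[1]:
        raise ParseError(f"{path}: matrix is not square")
    return mat, [str(c) for c in frame.columns]


def read_region_labels(path: str | Path) -> dict[str, str]:
    """Two-column TSV mapping region -> label (e.g. resting-state network)."""
    frame = pd.read_csv(Path(path), sep="\t")
    if frame.shape[1] != 2:
        raise ParseError(f"{path}: expected exactly two columns")
    return dict(zip(frame.iloc[:, 0].astype(str), frame.iloc[:, 1].astype(str)))


def write_window_stack(
    matrices: list, path: str | Path
) -> None:
    """Stacked window matrices in long TSV format (window, i, j, r)."""
    rows = []
    for m in matrices:
        r = m.matrix.shape[0]
        iu = np.triu_indices(r, 1)
        for i, j in zip(*iu):
            rows.append((m.window_index, int(i), int(j), m.matrix[i, j]))
    pd.DataFrame(rows, columns=["window", "i", "j", "r"]).to_csv(
        Path(path), sep="\t", index=False, float_format="%.17g"
    )


def read_window_stack(path: str | Path) -> list[np.ndarray]:
    """Rebuild the per-window matrices written by :func:`write_window_stack`."""
    from .connectivity import devectorize

    frame = pd.read_csv(Path(path), sep="\t", float_precision="round_trip")
    out = []
    for _, group in frame.groupby("window", sort=True):
        group = group.sort_values(["i", "j"])
        out.append(devectorize(group["r"].to_numpy()))
    return out
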