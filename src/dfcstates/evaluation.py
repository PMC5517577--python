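"""Accuracy, chance levels, bootstrap distributions and parameter sweeps.

Staging accuracy is the fraction of correctly labeled volumes, taking
the (synthetic) hypnogram as the reference.  Because k-means divides the
data space approximately evenly, the accuracy expected by chance is
``1/k`` independent of class balance; the label-permutation bootstrap
reproduces this null empirically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clustering import cluster_states
from .connectivity import WindowSpec, connectivity_vectors, window_series, \
    window_stage_labels
from .matching import match_by_profile, occurrence_profile
from .simulate import STAGE_ORDER, Hypnogram, RoiTimeSeries

logger = logging.getLogger(__name__)

#: Collapse map for wake-vs-sleep (k = 2) staging.
WAKE_SLEEP_COLLAPSE = {"W": "W", "N1": "S", "N2": "S", "N3": "S", "R": "S"}

#: Ordering used for tie-breaks on collapsed labels.
_CLASS_ORDER = ("W", "S") + STAGE_ORDER[1:]


def chance_accuracy(k: int) -> float:
    """Expected accuracy of an approximately even k-way division: ``1/k``."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return 1.0 / k


@dataclass(frozen=True)
class EvaluationReport:
    """Volume-level staging accuracy with per-stage confusion counts."""

    accuracy: float
    confusion: pd.DataFrame   # rows = true stage, columns = predicted stage
    n_volumes: int
    k: int | None = None
    chance: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.accuracy <= 1.0:
            raise ValueError("accuracy must lie in [0, 1]")
        if int(self.confusion.to_numpy().sum()) != self.n_volumes:
            raise ValueError("confusion counts must sum to evaluated volumes")


def staging_accuracy(
    predicted: list[str] | np.ndarray,
    truth: list[str] | np.ndarray,
    k: int | None = None,
) -> EvaluationReport:
    """Fraction of correctly staged volumes, with a confusion matrix."""
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.shape != truth.shape:
        raise ValueError("predicted and true label sequences differ in length")
    stages = [s for s in _CLASS_ORDER if s in set(truth) | set(predicted)]
    confusion = pd.crosstab(
        pd.Categorical(truth, categories=stages),
        pd.Categorical(predicted, categories=stages),
        rownames=["true"],
        colnames=["predicted"],
        dropna=False,
    )
    acc = float((predicted == truth).mean())
    return EvaluationReport(
        accuracy=acc,
        confusion=confusion,
        n_volumes=len(truth),
        k=k,
        chance=chance_accuracy(k) if k else None,
    )


# --------------------------------------------------------------------------
# Windowed-cohort container
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class WindowedSubject:
    """One subject's precomputed window vectors and labels."""

    subject: str
    vectors: np.ndarray             # (n_windows, R(R-1)/2)
    window_stages: tuple[str, ...]  # majority true stage per window
    windows: tuple[tuple[int, int], ...]
    volume_stages: tuple[str, ...]  # true stage per volume
    spec: WindowSpec


def prepare_windows(
    cohort: list[tuple[RoiTimeSeries, Hypnogram]],
    spec: WindowSpec | None = None,
    collapse: dict[str, str] | None = None,
) -> list[WindowedSubject]:
    """Window every subject once so resampling schemes can reuse the work.

    ``spec`` defaults to non-overlapping 50-volume windows for sessions
    longer than 7 minutes and to sliding (step 1) windows for shorter
    sessions, where non-overlapping windows would starve the clustering.
    ``collapse`` optionally maps stages onto coarser classes (e.g. all
    NREM stages onto "S" for wake-vs-sleep staging).
    """
    if spec is None:
        min_dur = min(ts.n_volumes * ts.tr for ts, _ in cohort)
        spec = WindowSpec(50, step=1 if min_dur <= 420.0 else None)
    out = []
    for ts, hyp in cohort:
        windows = window_series(ts, spec)
        stages = window_stage_labels(hyp, windows, ts.tr)
        n_covered = windows[-1][1]
        vol = hyp.stage_per_volume(n_covered, ts.tr)
        if collapse:
            stages = [collapse[s] for s in stages]
            vol = [collapse[s] for s in vol]
        out.append(
            WindowedSubject(
                subject=ts.subject,
                vectors=connectivity_vectors(ts, spec),
                window_stages=tuple(stages),
                windows=tuple(windows),
                volume_stages=tuple(vol),
                spec=spec,
            )
        )
    return out


def volume_predictions(
    subject: WindowedSubject, window_labels: np.ndarray | list[str]
) -> tuple[list[str], list[str]]:
    """Expand window labels to volume labels; returns (predicted, truth).

    Every volume inherits its window's label; with sliding windows a
    volume is covered by several windows and takes the majority vote
    (ties to the lighter stage).  Volumes after the last full window are
    excluded.
    """
    labels = sorted(set(window_labels), key=str)
    index = {l: i for i, l in enumerate(labels)}
    n_vol = len(subject.volume_stages)
    votes = np.zeros((n_vol, len(labels)), dtype=int)
    for (start, stop), lab in zip(subject.windows, window_labels):
        votes[start:stop, index[lab]] += 1
    covered = votes.sum(axis=1) > 0
    order = {l: i for i, l in enumerate(_CLASS_ORDER)}
    predicted = []
    for v in np.nonzero(covered)[0]:
        top = votes[v].max()
        cands = [labels[i] for i in range(len(labels)) if votes[v, i] == top]
        predicted.append(min(cands, key=lambda l: order.get(l, len(order))))
    truth = [subject.volume_stages[v] for v in np.nonzero(covered)[0]]
    return predicted, truth


# --------------------------------------------------------------------------
# Bootstrap
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class BootstrapResult:
    """Accuracy values over bootstrap iterations, with summary statistics."""

    accuracies: np.ndarray
    subset_size: int
    iterations: int
    k: int
    randomized_labels: bool
    seed: int

    def __post_init__(self) -> None:
        if len(self.accuracies) != self.iterations:
            raise ValueError("one accuracy per iteration required")
        if ((self.accuracies < 0) | (self.accuracies > 1)).any():
            raise ValueError("accuracies must lie in [0, 1]")

    @property
    def mode(self) -> float:
        """Histogram peak: center of the fullest of 20 bins on [0, 1]."""
        hist, edges = np.histogram(self.accuracies, bins=20, range=(0.0, 1.0))
        b = int(np.argmax(hist))
        return float((edges[b] + edges[b + 1]) / 2.0)

    @property
    def mean(self) -> float:
        return float(self.accuracies.mean())

    @property
    def sd(self) -> float:
        return float(self.accuracies.std(ddof=1)) if self.iterations > 1 else 0.0


def _stage_classes(subjects: list[WindowedSubject], k: int) -> list[str]:
    present = sorted(
        {s for subj in subjects for s in subj.window_stages},
        key=lambda s: _CLASS_ORDER.index(s) if s in _CLASS_ORDER else 99,
    )
    if len(present) > k:
        raise ValueError(
            f"{len(present)} stage classes present but k={k}; "
            "collapse stages before clustering"
        )
    # pad with canonical absent classes so the matching stays bijective
    for s in _CLASS_ORDER:
        if len(present) == k:
            break
        if s not in present:
            present.append(s)
    return present


def _score_subset(
    subset: list[WindowedSubject],
    window_stage_seqs: list[list[str]],
    k: int,
    replicates: int,
    seed: int,
    randomized: bool = False,
) -> float:
    """Cluster a subset's windows, match states to stages, score volumes."""
    vectors = np.vstack([s.vectors for s in subset])
    model = cluster_states(vectors, k, replicates=replicates, seed=seed)
    splits = np.cumsum([len(s.vectors) for s in subset])[:-1]
    per_subject_clusters = np.split(model.assignments, splits)

    classes = _stage_classes(subset, k)
    cluster_profiles = occurrence_profile(
        [c.tolist() for c in per_subject_clusters], labels=range(k)
    )
    stage_profiles = occurrence_profile(window_stage_seqs, labels=classes)
    matching = match_by_profile(cluster_profiles, stage_profiles)

    correct = total = 0
    for subj, clusters, stage_seq in zip(subset, per_subject_clusters, window_stage_seqs):
        window_pred = [matching.mapping[c] for c in clusters]
        pred, truth = volume_predictions(subj, window_pred)
        if randomized:
            # null construction: truth is the permuted window labels,
            # expanded to volumes the same way predictions are
            truth, _ = volume_predictions(subj, list(stage_seq))
        correct += sum(p == t for p, t in zip(pred, truth))
        total += len(pred)
    return correct / total


def bootstrap_accuracy(
    subjects: list[WindowedSubject],
    subset_size: int = 10,
    iterations: int = 100,
    k: int = 2,
    randomize_labels: bool = False,
    seed: int = 0,
    replicates: int = 100,
) -> BootstrapResult:
    """Accuracy distribution over random subject subsets.

    Each iteration samples ``subset_size`` subjects without replacement,
    re-clusters their pooled windows into ``k`` states, matches states to
    stages by occurrence profile, and scores volume-level accuracy.  With
    ``randomize_labels`` each subject's window-stage sequence is permuted
    before matching and scoring, which empirically reproduces the ``1/k``
    chance level.
    """
    if subset_size > len(subjects):
        raise ValueError("subset_size exceeds cohort size")
    rng = np.random.default_rng(seed)
    accs = np.empty(iterations)
    for it in range(iterations):
        idx = rng.choice(len(subjects), size=subset_size, replace=False)
        subset = [subjects[i] for i in idx]
        if randomize_labels:
            stage_seqs = [
                list(rng.permutation(np.asarray(s.window_stages))) for s in subset
            ]
        else:
            stage_seqs = [s.window_stages for s in subset]
        accs[it] = _score_subset(
            subset, stage_seqs, k, replicates,
            seed=int(rng.integers(2**31 - 1)), randomized=randomize_labels,
        )
    return BootstrapResult(
        accuracies=accs,
        subset_size=subset_size,
        iterations=iterations,
        k=k,
        randomized_labels=randomize_labels,
        seed=seed,
    )


# --------------------------------------------------------------------------
# Sweeps
# --------------------------------------------------------------------------

def window_length_sweep(
    cohort: list[tuple[RoiTimeSeries, Hypnogram]],
    lengths: list[int],
    k: int = 4,
    seed: int = 0,
    replicates: int = 100,
    collapse: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Full-pipeline staging accuracy as a function of window length.

    Returns one row per length with the pooled window count, the
    accuracy, and a flag marking degenerate runs (fewer windows than
    clusters), whose accuracy is reported as NaN.
    """
    rows = []
    for length in lengths:
        spec = WindowSpec(length)
        subjects = prepare_windows(cohort, spec, collapse=collapse)
        n_windows = sum(len(s.vectors) for s in subjects)
        if n_windows < k:
            logger.warning(
                "window length %d yields %d windows < k=%d; flagged",
                length, n_windows, k,
            )
            rows.append({"length": length, "n_windows": n_windows,
                         "accuracy": np.nan, "insufficient_windows": True})
            continue
        acc = _score_subset(
            subjects, [s.window_stages for s in subjects], k, replicates, seed
        )
        rows.append({"length": length, "n_windows": n_windows,
                     "accuracy": acc, "insufficient_windows": False})
    return pd.DataFrame(rows)


def sample_size_curve(
    subjects: list[WindowedSubject],
    sizes: list[int],
    iterations: int = 100,
    k: int = 2,
    seed: int = 0,
    replicates: int = 100,
    randomize_labels: bool = False,
) -> tuple[pd.DataFrame, dict[int, BootstrapResult]]:
    """Mean +/- SD bootstrap accuracy per sample size.

    Thin wrapper around :func:`bootstrap_accuracy`; windowing mode (e.g.
    sliding windows for short scans) is fixed upstream by
    :func:`prepare_windows`.
    """
    if max(sizes) > len(subjects):
        raise ValueError("largest sample size exceeds cohort size")
    results = {}
    rows = []
    for i, size in enumerate(sizes):
        res = bootstrap_accuracy(
            subjects,
            subset_size=size,
            iterations=iterations,
            k=k,
            randomize_labels=randomize_labels,
            seed=seed + i,
            replicates=replicates,
        )
        results[size] = res
        rows.append({"size": size, "mean": res.mean, "sd": res.sd, "mode": res.mode})
    return pd.DataFrame(rows), results
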