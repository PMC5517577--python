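"""Matching dynamic connectivity states to sleep stages.

Two fMRI-only criteria are implemented: (1) correlation between the
occurrence-probability profiles over the session of each cluster and of
each scored stage, and (2) correlation between the cluster-mean and
stage-mean connectivity matrices.  Both solve the cluster-to-stage
assignment exactly by enumerating all bijections (k <= 5, at most 120).
A third, label-free heuristic flags as wakefulness the state whose
occurrence probability is higher at the beginning than at the end of
the recording.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Hashable, Mapping, Sequence

import numpy as np

from .connectivity import vectorize_upper

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# Occurrence profiles
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class OccurrenceProfiles:
    """P(label, time bin) across subjects, one time bin per window index."""

    labels: tuple[Hashable, ...]
    probs: np.ndarray          # (n_labels, n_bins)
    counts: np.ndarray         # subjects contributing per bin

    def get(self, label: Hashable) -> np.ndarray:
        return self.probs[self.labels.index(label)]

    @property
    def n_bins(self) -> int:
        return self.probs.shape[1]

    def smoothed(self, width: int = 3) -> "OccurrenceProfiles":
        """Moving-average smoothing over ``width`` bins (off by default)."""
        kernel = np.ones(width) / width
        sm = np.apply_along_axis(
            lambda p: np.convolve(p, kernel, mode="same"), 1, self.probs
        )
        return OccurrenceProfiles(self.labels, sm, self.counts)


def occurrence_profile(
    label_sequences: Sequence[Sequence[Hashable]],
    labels: Sequence[Hashable] | None = None,
) -> OccurrenceProfiles:
    """Fraction of subjects carrying each label at each window index.

    Subjects' windows are aligned on a common session clock (window index
    0 at session start).  Bins no subject reaches are excluded with a
    warning.  At every retained bin the probabilities over all observed
    labels sum to 1.
    """
    if labels is None:
        labels = sorted({l for seq in label_sequences for l in seq}, key=str)
    labels = tuple(labels)
    n_bins = max(len(seq) for seq in label_sequences)
    counts = np.zeros(n_bins)
    hits = np.zeros((len(labels), n_bins))
    index = {l: i for i, l in enumerate(labels)}
    for seq in label_sequences:
        for b, lab in enumerate(seq):
            counts[b] += 1
            if lab in index:
                hits[index[lab], b] += 1
    covered = counts > 0
    if not covered.all():
        logger.warning("excluding %d empty time bins", int((~covered).sum()))
    probs = hits[:, covered] / counts[covered]
    return OccurrenceProfiles(labels=labels, probs=probs, counts=counts[covered])


# --------------------------------------------------------------------------
# Assignment
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class StateMatching:
    """Bijection cluster -> stage with its k x k similarity matrix."""

    mapping: dict[Hashable, Hashable]
    similarity: np.ndarray
    cluster_labels: tuple[Hashable, ...]
    stage_labels: tuple[Hashable, ...]
    method: str

    @property
    def total_similarity(self) -> float:
        idx = {s: j for j, s in enumerate(self.stage_labels)}
        return float(
            sum(
                self.similarity[i, idx[self.mapping[c]]]
                for i, c in enumerate(self.cluster_labels)
            )
        )


def _safe_pearson(u: np.ndarray, v: np.ndarray) -> float:
    """Pearson r, with constant inputs contributing 0 similarity."""
    if np.std(u) == 0 or np.std(v) == 0:
        return 0.0
    return float(np.corrcoef(u, v)[0, 1])


def best_assignment(similarity: np.ndarray) -> tuple[int, ...]:
    """Exact assignment maximizing total similarity over all bijections.

    Returns, for each row (cluster), the assigned column (stage).  With
    k <= 5 there are at most 120 bijections, so exhaustive enumeration is
    both exact and cheap; ties resolve to the lexicographically smallest
    permutation.
    """
    k = similarity.shape[0]
    if similarity.shape != (k, k):
        raise ValueError("similarity matrix must be square")
    best_perm, best_total = None, -np.inf
    for perm in itertools.permutations(range(k)):
        total = sum(similarity[i, perm[i]] for i in range(k))
        if total > best_total + 1e-12:
            best_perm, best_total = perm, total
    return best_perm


def _match(
    cluster_labels: Sequence[Hashable],
    stage_labels: Sequence[Hashable],
    similarity: np.ndarray,
    method: str,
) -> StateMatching:
    if len(cluster_labels) != len(stage_labels):
        raise ValueError("need equal numbers of clusters and stages")
    perm = best_assignment(similarity)
    mapping = {c: stage_labels[perm[i]] for i, c in enumerate(cluster_labels)}
    return StateMatching(
        mapping=mapping,
        similarity=similarity,
        cluster_labels=tuple(cluster_labels),
        stage_labels=tuple(stage_labels),
        method=method,
    )


def match_by_profile(
    cluster_profiles: OccurrenceProfiles,
    stage_profiles: OccurrenceProfiles,
) -> StateMatching:
    """Match clusters to stages by occurrence-profile correlation."""
    if cluster_profiles.n_bins != stage_profiles.n_bins:
        raise ValueError("profiles must share the same time-bin grid")
    k = len(cluster_profiles.labels)
    sim = np.empty((k, k))
    for i, c in enumerate(cluster_profiles.labels):
        for j, s in enumerate(stage_profiles.labels):
            sim[i, j] = _safe_pearson(cluster_profiles.get(c), stage_profiles.get(s))
    return _match(cluster_profiles.labels, stage_profiles.labels, sim, "profile")


def match_by_matrix_similarity(
    state_matrices: Mapping[Hashable, np.ndarray],
    stage_matrices: Mapping[Hashable, np.ndarray],
) -> StateMatching:
    """Match clusters to stages by mean-matrix correlation.

    Similarity is the Pearson correlation of the vectorized upper
    triangles; the full k x k similarity matrix is retained so the
    diagonal-dominance of a good match can be inspected.
    """
    clusters = tuple(state_matrices)
    stages = tuple(stage_matrices)
    k = len(clusters)
    sim = np.empty((k, k))
    for i, c in enumerate(clusters):
        for j, s in enumerate(stages):
            sim[i, j] = _safe_pearson(
                vectorize_upper(state_matrices[c]), vectorize_upper(stage_matrices[s])
            )
    return _match(clusters, stages, sim, "matrix")


def identify_wake_heuristic(profiles: OccurrenceProfiles) -> Hashable:
    """Label-free wakefulness detector for EEG-free datasets.

    Returns the cluster whose occurrence probability drops the most from
    the first half to the second half of the session; works because
    wakefulness is most prevalent at the start of a resting-state scan.
    Ties go to the first label in order.
    """
    if len(profiles.labels) < 2:
        raise ValueError("need at least two clusters")
    b = profiles.n_bins
    first = profiles.probs[:, : b // 2].mean(axis=1)
    second = profiles.probs[:, (b + 1) // 2 :].mean(axis=1)
    scores = first - second
    best = float(scores.max())
    winners = [l for l, s in zip(profiles.labels, scores) if s >= best - 1e-12]
    if len(winners) > 1:
        logger.info("wake-heuristic tie between %s; returning first", winners)
    return winners[0]
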