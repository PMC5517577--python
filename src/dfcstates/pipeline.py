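"""End-to-end orchestration: simulate/load -> window -> cluster -> match -> score.

`run_pipeline` drives the whole unsupervised staging analysis from one
validated configuration object and returns (and optionally writes) a
report bundle.  All randomness flows from the explicit seed in the
configuration, so identical configurations produce identical bundles.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import evaluation, io, matching, simulate
from .clustering import cluster_states, state_mean_matrix
from .connectivity import WindowSpec, windowed_connectivity
from .evaluation import (WAKE_SLEEP_COLLAPSE, prepare_windows,
                         staging_accuracy, volume_predictions)
from .matching import (identify_wake_heuristic, match_by_matrix_similarity,
                       match_by_profile, occurrence_profile)

logger = logging.getLogger(__name__)

_PROFILES = tuple(simulate.STAGE_MODELS)


@dataclass(frozen=True)
class PipelineConfig:
    """Validated configuration of a full pipeline run."""

    n_subjects: int = 10
    n_regions: int = 20
    duration: float = simulate.DEFAULT_DURATION
    tr: float = simulate.DEFAULT_TR
    profile: str = "sleep"
    window_length: int = 50
    window_step: int | None = None
    k: int = 2
    replicates: int = 100
    noise_sd: float = 0.5
    seed: int = 0
    out_dir: str | None = None
    heuristic_only: bool = False

    def __post_init__(self) -> None:
        if self.profile not in _PROFILES:
            raise ValueError(f"profile must be one of {_PROFILES}")
        if not 1 <= self.k <= 5:
            raise ValueError("k must lie in 1..5")
        if self.n_subjects < 1 or self.n_regions < 2:
            raise ValueError("need >= 1 subject and >= 2 regions")
        WindowSpec(self.window_length, self.window_step)  # validates

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**d)


@dataclass(frozen=True)
class PipelineResult:
    """Report bundle of one pipeline run."""

    config: PipelineConfig
    cluster_inertia: float
    wake_cluster: int
    profile_matching: matching.StateMatching | None
    matrix_matching: matching.StateMatching | None
    report: evaluation.EvaluationReport | None
    state_matrices: dict[int, np.ndarray]

    @property
    def accuracy(self) -> float | None:
        return self.report.accuracy if self.report else None


def _build_cohort(config: PipelineConfig):
    if config.profile == "sleep":
        covs = simulate.two_state_covariances(config.n_regions, seed=config.seed)
        model = simulate.sleep_stage_model()
    elif config.profile == "wake":
        covs = simulate.two_state_covariances(
            config.n_regions, seed=config.seed, stages=("W",)
        )
        model = simulate.wake_stage_model()
    elif config.profile == "wake_n1":
        return simulate.wake_n1_cohort(
            config.n_subjects, config.n_regions, config.duration,
            seed=config.seed, noise_sd=config.noise_sd,
        )
    else:  # narcolepsy
        covs = simulate.make_state_covariances(
            config.n_regions,
            modularity_grade={"W": 0.2, "N1": 0.35, "N2": 0.5, "N3": 0.65, "R": 0.3},
            inter_state_similarity=0.5,
            seed=config.seed,
        )
        model = simulate.narcolepsy_stage_model()
    return simulate.generate_cohort(
        config.n_subjects, model, covs,
        duration=config.duration, tr=config.tr,
        noise_sd=config.noise_sd, seed=config.seed,
    )


def run_pipeline(config: PipelineConfig, cohort=None) -> PipelineResult:
    """Run the full unsupervised staging pipeline.

    ``cohort`` (a list of ``(RoiTimeSeries, Hypnogram)`` pairs) overrides
    the simulated cohort, so the same orchestration serves real data read
    with :mod:`dfcstates.io`.  With ``heuristic_only`` no hypnograms are
    consulted: clusters are formed and wakefulness is identified from the
    occurrence-profile trend alone.
    """
    if cohort is None:
        logger.info("simulating %d-subject '%s' cohort (seed %d)",
                    config.n_subjects, config.profile, config.seed)
        cohort = _build_cohort(config)

    spec = WindowSpec(config.window_length, config.window_step)
    collapse = WAKE_SLEEP_COLLAPSE if config.k == 2 else None
    subjects = prepare_windows(cohort, spec, collapse=collapse)
    logger.info("windowed %d subjects (%s windows, %d total)",
                len(subjects), spec.mode, sum(len(s.vectors) for s in subjects))

    vectors = np.vstack([s.vectors for s in subjects])
    model = cluster_states(vectors, config.k, replicates=config.replicates,
                           seed=config.seed)
    logger.info("clustered %d windows into k=%d states (inertia %.3f)",
                len(vectors), config.k, model.inertia)
    splits = np.cumsum([len(s.vectors) for s in subjects])[:-1]
    per_subject_clusters = np.split(model.assignments, splits)
    cluster_profiles = occurrence_profile(
        [c.tolist() for c in per_subject_clusters], labels=range(config.k)
    )
    wake_cluster = identify_wake_heuristic(cluster_profiles) if config.k >= 2 else 0

    all_mats = np.stack([
        m.matrix for ts, _ in cohort for m in windowed_connectivity(ts, spec)
    ])
    state_mats = {c: state_mean_matrix(model, c, all_mats) for c in range(config.k)}

    profile_match = matrix_match = report = None
    if not config.heuristic_only:
        classes = evaluation._stage_classes(subjects, config.k)
        stage_profiles = occurrence_profile(
            [list(s.window_stages) for s in subjects], labels=classes
        )
        profile_match = match_by_profile(cluster_profiles, stage_profiles)
        stage_mats = {}
        for stage in classes:
            members = [
                all_mats[i]
                for i, s in enumerate(
                    lab for subj in subjects for lab in subj.window_stages
                )
                if s == stage
            ]
            stage_mats[stage] = (
                np.mean(members, axis=0) if members else np.eye(config.n_regions)
            )
        matrix_match = match_by_matrix_similarity(state_mats, stage_mats)
        if profile_match.mapping != matrix_match.mapping:
            logger.warning("profile and matrix matchers disagree: %s vs %s",
                           profile_match.mapping, matrix_match.mapping)

        pred_all, true_all = [], []
        for subj, clusters in zip(subjects, per_subject_clusters):
            window_pred = [profile_match.mapping[c] for c in clusters]
            pred, true = volume_predictions(subj, window_pred)
            pred_all.extend(pred)
            true_all.extend(true)
        report = staging_accuracy(pred_all, true_all, k=config.k)
        logger.info("volume-level accuracy %.3f (chance %.3f)",
                    report.accuracy, report.chance)

    result = PipelineResult(
        config=config,
        cluster_inertia=model.inertia,
        wake_cluster=int(wake_cluster),
        profile_matching=profile_match,
        matrix_matching=matrix_match,
        report=report,
        state_matrices=state_mats,
    )
    if config.out_dir:
        _write_bundle(result, cohort, Path(config.out_dir))
    return result


def _write_bundle(result: PipelineResult, cohort, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    for ts, hyp in cohort:
        io.write_timeseries(ts, out / f"{ts.subject}_bold.tsv")
        io.write_hypnogram(hyp, out / f"{ts.subject}_hypnogram.tsv")
    for c, m in result.state_matrices.items():
        io.write_matrix(m, out / f"state_{c}_mean.tsv")
    summary = {
        "config": dataclasses.asdict(result.config),
        "inertia": result.cluster_inertia,
        "wake_cluster": result.wake_cluster,
        "accuracy": result.accuracy,
        "profile_mapping": (
            {str(k): v for k, v in result.profile_matching.mapping.items()}
            if result.profile_matching else None
        ),
        "matrix_mapping": (
            {str(k): v for k, v in result.matrix_matching.mapping.items()}
            if result.matrix_matching else None
        ),
    }
    (out / "report.json").write_text(json.dumps(summary, indent=2) + "\n")
    logger.info("report bundle written to %s", out)
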