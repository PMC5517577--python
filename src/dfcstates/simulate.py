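"""Synthetic EEG-fMRI sleep cohorts: hypnograms and stage-driven BOLD signals.

The generator emulates the statistical structure of an overnight-onset
resting-state experiment: subjects start awake, drift through the NREM
cycle (W -> N1 -> N2 -> N3) over a ~52 minute session, and their
region-averaged BOLD signals switch covariance structure with the active
sleep stage.  Stage dynamics follow a time-inhomogeneous first-order
Markov chain with three rate regimes (session thirds); signals are
multivariate Gaussian with a stage-switched covariance, plus isotropic
noise, band-pass filtered to the ultra-slow 0.01-0.1 Hz band.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as _signal

logger = logging.getLogger(__name__)

#: Canonical stage ordering, lightest first (used for tie-breaks).
STAGE_ORDER = ("W", "N1", "N2", "N3", "R")

DEFAULT_TR = 2.08          # seconds per volume
DEFAULT_EPOCH = 30.0       # seconds per scoring epoch
DEFAULT_DURATION = 3120.0  # 52 minutes -> 1500 volumes at TR 2.08


class ConfigurationError(ValueError):
    """Invalid generator configuration (stages, rates, durations)."""


# --------------------------------------------------------------------------
# Stage dynamics
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class StageModel:
    """Markov model of per-epoch sleep-stage dynamics.

    Parameters
    ----------
    stages
        Ordered stage labels, a subset of ``STAGE_ORDER``.
    transition_rates
        One row-stochastic matrix per regime.  Regimes partition the
        session into equal thirds; a single matrix means homogeneous
        dynamics.
    initial
        Distribution over ``stages`` at the first epoch.
    target_prevalence
        Stage fractions the model was calibrated to (informational).
    epoch_length
        Epoch duration in seconds (30 s scoring epochs by default).
    """

    stages: tuple[str, ...]
    transition_rates: tuple[np.ndarray, ...]
    initial: np.ndarray
    target_prevalence: np.ndarray | None = None
    epoch_length: float = DEFAULT_EPOCH

    def __post_init__(self) -> None:
        if self.epoch_length <= 0:
            raise ConfigurationError("epoch_length must be positive")
        unknown = set(self.stages) - set(STAGE_ORDER)
        if unknown:
            raise ConfigurationError(
                f"unknown stage labels {sorted(unknown)}; allowed: {STAGE_ORDER}"
            )
        n = len(self.stages)
        for p in self.transition_rates:
            if p.shape != (n, n):
                raise ConfigurationError("transition matrix shape mismatch")
            if not np.allclose(p.sum(axis=1), 1.0, atol=1e-12):
                raise ConfigurationError("transition rows must sum to 1")
            if (p < 0).any():
                raise ConfigurationError("transition probabilities must be >= 0")
        if self.initial.shape != (n,) or not np.isclose(self.initial.sum(), 1.0, atol=1e-12):
            raise ConfigurationError("initial distribution must sum to 1")
        if self.target_prevalence is not None and not np.isclose(
            self.target_prevalence.sum(), 1.0, atol=1e-12
        ):
            raise ConfigurationError("target prevalences must sum to 1")

    def regime_for(self, epoch: int, n_epochs: int) -> np.ndarray:
        """Transition matrix in force at ``epoch`` of an ``n_epochs`` session."""
        r = min(int(len(self.transition_rates) * epoch / n_epochs),
                len(self.transition_rates) - 1)
        return self.transition_rates[r]


def sleep_stage_model() -> StageModel:
    """Four-stage (W/N1/N2/N3) model of a sleep-prone 52-min session.

    Rates were calibrated so that, over a 104-epoch session started awake,
    expected stage occupancy is ~48% W, 23% N1, 19% N2 and 10% N3, with
    wakefulness declining monotonically and N1 peaking before N2 and N3.
    """
    p1 = np.array([
        [0.945, 0.055, 0.000, 0.000],
        [0.180, 0.788, 0.032, 0.000],
        [0.020, 0.105, 0.835, 0.040],
        [0.000, 0.000, 0.150, 0.850],
    ])
    p2 = np.array([
        [0.893, 0.107, 0.000, 0.000],
        [0.105, 0.772, 0.123, 0.000],
        [0.030, 0.085, 0.820, 0.065],
        [0.000, 0.000, 0.135, 0.865],
    ])
    p3 = np.array([
        [0.915, 0.085, 0.000, 0.000],
        [0.080, 0.765, 0.155, 0.000],
        [0.010, 0.065, 0.845, 0.080],
        [0.000, 0.000, 0.105, 0.895],
    ])
    return StageModel(
        stages=("W", "N1", "N2", "N3"),
        transition_rates=(p1, p2, p3),
        initial=np.array([1.0, 0.0, 0.0, 0.0]),
        target_prevalence=np.array([0.48, 0.23, 0.19, 0.10]),
    )


def wake_stage_model() -> StageModel:
    """Degenerate model for subjects who never fall asleep."""
    return StageModel(
        stages=("W",),
        transition_rates=(np.array([[1.0]]),),
        initial=np.array([1.0]),
        target_prevalence=np.array([1.0]),
    )


def wake_n1_stage_model() -> StageModel:
    """Two-stage W/N1 model for short (~7 min) light-sleep-onset sessions.

    Homogeneous rates; wake probability declines from 1 towards the
    stationary level 0.625, matching the declining wakefulness trend seen
    in the opening minutes of sleep-prone resting-state sessions.
    """
    p = np.array([
        [0.94, 0.06],
        [0.10, 0.90],
    ])
    return StageModel(
        stages=("W", "N1"),
        transition_rates=(p,),
        initial=np.array([1.0, 0.0]),
    )


def narcolepsy_stage_model() -> StageModel:
    """Five-stage model (adds REM) with abrupt wake/sleep transitions.

    Calibrated to ~28% W, 19% N1, 14% N2, 23% N3, 16% REM occupancy and
    frequent sleep-onset transitions, emulating a narcolepsy-like cohort.
    """
    p = np.array([
        [0.820, 0.125, 0.000, 0.000, 0.055],
        [0.115, 0.715, 0.115, 0.000, 0.055],
        [0.015, 0.055, 0.765, 0.140, 0.025],
        [0.008, 0.000, 0.048, 0.924, 0.020],
        [0.115, 0.050, 0.020, 0.000, 0.815],
    ])
    return StageModel(
        stages=("W", "N1", "N2", "N3", "R"),
        transition_rates=(p,),
        initial=np.array([1.0, 0.0, 0.0, 0.0, 0.0]),
        target_prevalence=np.array([0.28, 0.19, 0.14, 0.23, 0.16]),
    )


STAGE_MODELS = {
    "sleep": sleep_stage_model,
    "wake": wake_stage_model,
    "wake_n1": wake_n1_stage_model,
    "narcolepsy": narcolepsy_stage_model,
}


@dataclass(frozen=True)
class Hypnogram:
    """Per-epoch stage labels for one subject."""

    subject: str
    stages: tuple[str, ...]
    epoch_length: float = DEFAULT_EPOCH

    @property
    def n_epochs(self) -> int:
        return len(self.stages)

    @property
    def duration(self) -> float:
        return self.n_epochs * self.epoch_length

    def stage_at(self, t_seconds: float) -> str:
        """Stage of the epoch containing time ``t_seconds``."""
        if t_seconds < 0 or t_seconds >= self.duration:
            raise ValueError(f"time {t_seconds} outside hypnogram [0, {self.duration})")
        return self.stages[int(t_seconds // self.epoch_length)]

    def stage_per_volume(self, n_volumes: int, tr: float) -> list[str]:
        """Stage of each volume (a volume takes its containing epoch's stage)."""
        if (n_volumes - 1) * tr >= self.duration:
            raise ValueError("volumes extend beyond hypnogram duration")
        return [self.stages[int(v * tr // self.epoch_length)] for v in range(n_volumes)]


def generate_hypnogram(
    model: StageModel,
    duration: float = DEFAULT_DURATION,
    seed: int = 0,
    subject: str = "sub-00",
) -> Hypnogram:
    """Sample a stage sequence from ``model`` covering ``duration`` seconds."""
    if duration < model.epoch_length:
        raise ConfigurationError("duration must cover at least one epoch")
    n = int(duration // model.epoch_length)
    rng = np.random.default_rng(seed)
    idx = np.empty(n, dtype=int)
    idx[0] = rng.choice(len(model.stages), p=model.initial)
    for t in range(1, n):
        p = model.regime_for(t, n)
        idx[t] = rng.choice(len(model.stages), p=p[idx[t - 1]])
    return Hypnogram(
        subject=subject,
        stages=tuple(model.stages[i] for i in idx),
        epoch_length=model.epoch_length,
    )


# --------------------------------------------------------------------------
# Stage covariance templates
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class StateCovarianceSet:
    """Per-stage connectivity templates (correlation form) and their grading.

    ``modularity_grade`` scales the strength of a planted module structure;
    ``sc_coupling`` scales the template's resemblance to a structural
    template.  ``inter_state_similarity`` records the measured pairwise
    Pearson correlation between the vectorized templates of the distinct
    underlying states.
    """

    templates: dict[str, np.ndarray]
    modularity_grade: dict[str, float]
    sc_coupling: dict[str, float]
    inter_state_similarity: np.ndarray
    state_labels: tuple[str, ...]
    structural: np.ndarray | None = None
    module_partition: np.ndarray | None = None
    seed: int = 0

    @property
    def n_regions(self) -> int:
        return next(iter(self.templates.values())).shape[0]


def nearest_correlation(mat: np.ndarray, eig_floor: float = 1e-10) -> np.ndarray:
    """Project a symmetric matrix to a valid correlation matrix.

    Eigenvalues are clipped at ``eig_floor`` and the result renormalized
    to unit diagonal.
    """
    sym = (mat + mat.T) / 2.0
    vals, vecs = np.linalg.eigh(sym)
    fixed = (vecs * np.clip(vals, eig_floor, None)) @ vecs.T
    d = np.sqrt(np.diag(fixed))
    out = fixed / np.outer(d, d)
    np.fill_diagonal(out, 1.0)
    return out


def make_structural_template(
    n_regions: int, seed: int = 0, density: float = 0.6
) -> np.ndarray:
    """Synthetic region-level structural connectivity: symmetric, non-negative.

    Log-normal edge weights with the weakest entries zeroed to reach the
    requested density.  Weights are drawn independently of region index,
    so the template carries only weak intrinsic community structure and
    the modularity planted separately per stage remains identifiable.
    """
    rng = np.random.default_rng(seed)
    noise = rng.lognormal(0.0, 0.5, size=(n_regions, n_regions))
    w = (noise + noise.T) / 2.0
    np.fill_diagonal(w, 0.0)
    off = w[np.triu_indices(n_regions, 1)]
    thr = np.quantile(off, 1.0 - density)
    w[w < thr] = 0.0
    return w


def _structural_to_correlation(sc: np.ndarray, scale: float = 0.7) -> np.ndarray:
    """Rescale a non-negative structural matrix to correlation form."""
    off_max = sc[~np.eye(len(sc), dtype=bool)].max()
    if off_max <= 0:
        raise ConfigurationError("structural template has no off-diagonal weight")
    c = sc / off_max * scale
    np.fill_diagonal(c, 1.0)
    return nearest_correlation(c)


def _module_correlation(
    n_regions: int, n_modules: int, rng: np.random.Generator, within: float = 0.6
) -> tuple[np.ndarray, np.ndarray]:
    """Block correlation matrix: ``within`` inside modules, 0 between.

    Compound symmetry within each block keeps the matrix PSD.  Module
    membership is shuffled so the planted community structure is
    uncorrelated with the index-distance backbone of the structural
    template (keeping the modularity and coupling gradings orthogonal).
    """
    labels = np.repeat(np.arange(n_modules), int(np.ceil(n_regions / n_modules)))[:n_regions]
    labels = rng.permutation(labels)
    same = labels[:, None] == labels[None, :]
    pattern = np.where(same, within, 0.0)
    np.fill_diagonal(pattern, 1.0)
    return pattern, labels


def make_state_covariances(
    n_regions: int,
    modularity_grade: dict[str, float],
    sc_coupling: dict[str, float] | None = None,
    structural: np.ndarray | None = None,
    inter_state_similarity: float = 0.5,
    seed: int = 0,
    n_modules: int = 4,
    signature_weight: float = 0.35,
    modularity_weight: float = 0.50,
    sc_weight: float = 0.40,
    signature_rank: int | None = None,
) -> StateCovarianceSet:
    """Build one correlation template per stage with graded planted structure.

    Each template is a convex combination of valid correlation matrices,

        C_s = a * Sig_s + b_s * Mod + c_s * SC + (1 - a - b_s - c_s) * Uni,

    where ``Sig_s`` is a stage-specific random (Wishart-derived)
    signature with a fixed weight ``a`` for every stage, ``Mod`` a shared
    block-modular correlation weighted by ``b_s = modularity_weight *
    modularity_grade[s]``, ``SC`` the structural template in correlation
    form weighted by ``c_s = sc_weight * sc_coupling[s]``, and ``Uni`` a
    uniform (compound-symmetry) correlation absorbing the rest.
    Convexity guarantees a valid correlation matrix with no projection
    step.  Keeping ``a`` fixed makes the gradings independent of the
    signature's intrinsic (spurious) modularity, and the uniform filler
    is neutral for both planted readouts: a globally constant edge
    weight promotes integration (near-zero modularity) and, being
    constant, leaves the Pearson correlation with the structural pattern
    untouched.  The shared fraction of the
    signatures is calibrated by bisection so the mean pairwise
    correlation of the vectorized templates matches
    ``inter_state_similarity``.  A coupling grade of exactly 1 returns
    the structural template in correlation form.
    """
    if n_regions < 2:
        raise ConfigurationError("need at least two regions")
    stages = tuple(modularity_grade)
    if sc_coupling is None:
        sc_coupling = {s: 0.0 for s in stages}
    if set(sc_coupling) != set(stages):
        raise ConfigurationError("modularity_grade and sc_coupling must share stages")
    for g in list(modularity_grade.values()) + list(sc_coupling.values()):
        if not 0.0 <= g <= 1.0:
            raise ConfigurationError("grades must lie in [0, 1]")
    for s in stages:
        total = (signature_weight + modularity_weight * modularity_grade[s]
                 + sc_weight * sc_coupling[s])
        if total > 1.0 + 1e-12 and sc_coupling[s] < 1.0:
            raise ConfigurationError(
                f"mixture weights for stage {s} exceed 1 ({total:.2f}); "
                "reduce grades or component weights"
            )

    rng = np.random.default_rng(seed)
    if structural is None and any(g > 0 for g in sc_coupling.values()):
        structural = make_structural_template(n_regions, seed=seed + 7)
    sc_corr = _structural_to_correlation(structural) if structural is not None else None

    block, module_labels = _module_correlation(n_regions, n_modules, rng)
    iu = np.triu_indices(n_regions, 1)

    # orthogonalize signatures against the planted patterns so chance
    # alignment cannot bias the modularity / coupling readouts
    basis = []
    b0 = block[iu] - block[iu].mean()
    if b0 @ b0 > 1e-12:  # degenerate (e.g. singleton modules) -> skip
        basis.append(b0)
    if sc_corr is not None:
        v = sc_corr[iu] - sc_corr[iu].mean()
        for u in basis:
            v = v - (v @ u) / (u @ u) * u
        if v @ v > 1e-12:
            basis.append(v)

    def _wishart_correlation(g: np.ndarray) -> np.ndarray:
        w = g @ g.T / g.shape[1]
        d = np.sqrt(np.diag(w))
        c = w / np.outer(d, d)
        np.fill_diagonal(c, 1.0)
        off = c[iu]
        for u in basis:
            off = off - (off @ u) / (u @ u) * u
        c = np.eye(n_regions)
        c[iu] = off
        c[(iu[1], iu[0])] = off
        return nearest_correlation(c)

    # fewer factor columns -> coarser, higher-amplitude signature patterns
    # (well-separated states); more columns -> subtler patterns
    rank = signature_rank if signature_rank is not None else n_regions
    if rank < 1:
        raise ConfigurationError("signature_rank must be >= 1")
    shared = rng.standard_normal((n_regions, rank))
    unique = {s: rng.standard_normal((n_regions, rank)) for s in stages}

    uniform = np.full((n_regions, n_regions), 0.3)
    np.fill_diagonal(uniform, 1.0)

    def _build(rho: float) -> dict[str, np.ndarray]:
        out = {}
        for s in stages:
            g_sc = sc_coupling[s]
            if sc_corr is not None and g_sc >= 1.0:
                out[s] = sc_corr.copy()
                continue
            sig = _wishart_correlation(
                np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * unique[s]
            )
            b = modularity_weight * modularity_grade[s]
            c = sc_weight * g_sc
            tpl = signature_weight * sig + b * block
            if sc_corr is not None and c > 0:
                tpl = tpl + c * sc_corr
            else:
                c = 0.0
            tpl = tpl + (1.0 - signature_weight - b - c) * uniform
            out[s] = tpl
        return out

    def _mean_similarity(templates: dict[str, np.ndarray]) -> float:
        vecs = np.array([templates[s][iu] for s in stages])
        if len(vecs) < 2:
            return 1.0
        c = np.corrcoef(vecs)
        return float(c[np.triu_indices(len(vecs), 1)].mean())

    if len(stages) >= 2:
        lo, hi = 0.0, 1.0
        for _ in range(40):
            mid = (lo + hi) / 2.0
            if _mean_similarity(_build(mid)) < inter_state_similarity:
                lo = mid
            else:
                hi = mid
        rho = (lo + hi) / 2.0
        templates = _build(rho)
        measured = _mean_similarity(templates)
        if abs(measured - inter_state_similarity) > 0.05:
            warnings.warn(
                f"inter-state similarity target {inter_state_similarity:.2f} "
                f"unreachable; achieved {measured:.2f}",
                stacklevel=2,
            )
    else:
        templates = _build(0.0)

    for s, tpl in templates.items():
        vals = np.linalg.eigvalsh((tpl + tpl.T) / 2)
        if vals.min() < -1e-8:
            raise RuntimeError(f"template for stage {s} not PSD after repair")

    vecs = np.array([templates[s][iu] for s in stages])
    sim = np.corrcoef(vecs) if len(stages) > 1 else np.ones((1, 1))
    return StateCovarianceSet(
        templates=templates,
        modularity_grade=dict(modularity_grade),
        sc_coupling=dict(sc_coupling),
        inter_state_similarity=sim,
        state_labels=stages,
        structural=structural,
        module_partition=module_labels,
        seed=seed,
    )


def two_state_covariances(
    n_regions: int = 20,
    seed: int = 0,
    similarity: float = 0.5,
    stages: tuple[str, ...] = ("W", "N1", "N2", "N3"),
) -> StateCovarianceSet:
    """Wake vs. sleep templates: all non-wake stages share one template.

    This is the default covariance set of the synthetic sleep cohort: two
    planted connectivity states (one for wakefulness, one shared by the
    NREM stages), with the sleep state more modular than wake.
    """
    base = make_state_covariances(
        n_regions,
        modularity_grade={"W": 0.25, "S": 0.55},
        inter_state_similarity=similarity,
        seed=seed,
    )
    templates = {
        s: (base.templates["W"] if s == "W" else base.templates["S"]) for s in stages
    }
    return StateCovarianceSet(
        templates=templates,
        modularity_grade={s: base.modularity_grade["W" if s == "W" else "S"] for s in stages},
        sc_coupling={s: 0.0 for s in stages},
        inter_state_similarity=base.inter_state_similarity,
        state_labels=("W", "S"),
        structural=None,
        module_partition=base.module_partition,
        seed=seed,
    )


#: Stage-grading defaults: wake least modular, deeper NREM more modular;
#: structure-function coupling dips in light (N1) sleep and is strongest in
#: deep (N3) sleep.
DEFAULT_MODULARITY_GRADES = {"W": 0.05, "N1": 0.30, "N2": 0.50, "N3": 0.70}
DEFAULT_SC_GRADES = {"W": 0.30, "N1": 0.15, "N2": 0.55, "N3": 0.75}


def graded_state_covariances(
    n_regions: int = 20,
    seed: int = 0,
    inter_state_similarity: float = 0.5,
    structural: np.ndarray | None = None,
) -> StateCovarianceSet:
    """Four distinct stage templates with graded modularity and SC coupling."""
    return make_state_covariances(
        n_regions,
        modularity_grade=DEFAULT_MODULARITY_GRADES,
        sc_coupling=DEFAULT_SC_GRADES,
        structural=structural,
        inter_state_similarity=inter_state_similarity,
        seed=seed,
    )


# --------------------------------------------------------------------------
# BOLD signal synthesis
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RoiTimeSeries:
    """One subject's region-averaged BOLD matrix (volumes x regions)."""

    subject: str
    data: np.ndarray
    tr: float = DEFAULT_TR
    regions: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.tr <= 0:
            raise ConfigurationError("TR must be positive")
        if self.data.ndim != 2 or self.data.shape[1] < 2:
            raise ConfigurationError("time series must be T x R with R >= 2")
        if np.isnan(self.data).any():
            raise ConfigurationError("time series contains missing values")
        if not self.regions:
            object.__setattr__(
                self,
                "regions",
                tuple(f"R{i + 1:03d}" for i in range(self.data.shape[1])),
            )
        if len(self.regions) != self.data.shape[1]:
            raise ConfigurationError("region names do not match column count")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[0]

    @property
    def n_regions(self) -> int:
        return self.data.shape[1]


def bandpass_filter(
    data: np.ndarray,
    tr: float,
    low: float = 0.01,
    high: float = 0.1,
    order: int = 6,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the time axis.

    ``order`` is the overall filter order of the band-pass (an order-6
    band-pass has three pole pairs); applied forward-backward, so the
    effective attenuation is doubled and no phase distortion is
    introduced across stage boundaries.
    """
    sos = _signal.butter(order // 2, [low, high], btype="bandpass", fs=1.0 / tr,
                         output="sos")
    return _signal.sosfiltfilt(sos, data, axis=0)


def generate_bold(
    hypnogram: Hypnogram,
    covs: StateCovarianceSet,
    tr: float = DEFAULT_TR,
    noise_sd: float = 0.5,
    seed: int = 0,
    bandpass: bool = True,
) -> RoiTimeSeries:
    """Sample stage-switched Gaussian BOLD signals for one subject.

    Each volume is drawn from the active stage's covariance template plus
    isotropic noise of standard deviation ``noise_sd``; the concatenated
    series is then band-pass filtered (0.01-0.1 Hz, zero phase), as a
    continuous recording would be.
    """
    if tr <= 0:
        raise ConfigurationError("TR must be positive")
    missing = set(hypnogram.stages) - set(covs.templates)
    if missing:
        raise ConfigurationError(f"no covariance template for stages {sorted(missing)}")
    n_volumes = int(hypnogram.duration / tr)
    n_regions = covs.n_regions
    rng = np.random.default_rng(seed)

    chol = {}
    for s in set(hypnogram.stages):
        tpl = covs.templates[s]
        chol[s] = np.linalg.cholesky(tpl + 1e-9 * np.eye(n_regions))

    stage_per_vol = hypnogram.stage_per_volume(n_volumes, tr)
    z = rng.standard_normal((n_volumes, n_regions))
    x = np.empty_like(z)
    for s, l in chol.items():
        mask = np.fromiter((sv == s for sv in stage_per_vol), bool, n_volumes)
        x[mask] = z[mask] @ l.T
    if noise_sd > 0:
        x += noise_sd * rng.standard_normal((n_volumes, n_regions))
    if bandpass:
        x = bandpass_filter(x, tr)
    return RoiTimeSeries(subject=hypnogram.subject, data=x, tr=tr)


# --------------------------------------------------------------------------
# Cohorts
# --------------------------------------------------------------------------

def generate_cohort(
    n_subjects: int,
    model: StageModel,
    covs: StateCovarianceSet,
    duration: float = DEFAULT_DURATION,
    tr: float = DEFAULT_TR,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> list[tuple[RoiTimeSeries, Hypnogram]]:
    """Generate ``n_subjects`` independent (time series, hypnogram) pairs.

    Per-subject seeds are derived as ``seed + index``, so the cohort is
    reproducible and each subject individually regenerable.
    """
    if n_subjects < 1:
        raise ConfigurationError("need at least one subject")
    cohort = []
    for i in range(n_subjects):
        sid = f"sub-{i:02d}"
        hyp = generate_hypnogram(model, duration, seed=seed + i, subject=sid)
        ts = generate_bold(hyp, covs, tr=tr, noise_sd=noise_sd, seed=seed + i)
        cohort.append((ts, hyp))
    return cohort


def sleep_cohort(
    n_subjects: int = 58,
    n_regions: int = 20,
    duration: float = DEFAULT_DURATION,
    seed: int = 0,
    noise_sd: float = 0.5,
    covariances: str = "two_state",
) -> list[tuple[RoiTimeSeries, Hypnogram]]:
    """The default synthetic sleep cohort (58 subjects, 52 min, R regions).

    ``covariances='two_state'`` plants a wake and a shared sleep
    connectivity state (the default for wake-vs-sleep staging);
    ``'graded'`` plants four distinct stage templates with graded
    modularity and structure-function coupling.
    """
    if covariances == "two_state":
        covs = two_state_covariances(n_regions, seed=seed)
    elif covariances == "graded":
        covs = graded_state_covariances(n_regions, seed=seed)
    else:
        raise ConfigurationError("covariances must be 'two_state' or 'graded'")
    return generate_cohort(
        n_subjects, sleep_stage_model(), covs,
        duration=duration, noise_sd=noise_sd, seed=seed,
    )


def truncate_cohort(
    cohort: list[tuple[RoiTimeSeries, Hypnogram]], seconds: float
) -> list[tuple[RoiTimeSeries, Hypnogram]]:
    """Keep only the first ``seconds`` of every subject (short-scan scenario)."""
    out = []
    for ts, hyp in cohort:
        n = int(seconds // ts.tr)
        n_epochs = int(np.ceil(n * ts.tr / hyp.epoch_length))
        out.append(
            (
                RoiTimeSeries(ts.subject, ts.data[:n], ts.tr, ts.regions),
                Hypnogram(hyp.subject, hyp.stages[:n_epochs], hyp.epoch_length),
            )
        )
    return out


def wake_n1_cohort(
    n_subjects: int = 58,
    n_regions: int = 20,
    duration: float = DEFAULT_DURATION,
    seed: int = 0,
    noise_sd: float = 0.5,
) -> list[tuple[RoiTimeSeries, Hypnogram]]:
    """Cohort with wake/N1 structure only (short-experiment scenario)."""
    model = wake_n1_stage_model()
    base = make_state_covariances(
        n_regions,
        modularity_grade={"W": 0.15, "N1": 0.55},
        inter_state_similarity=0.5,
        seed=seed,
        signature_rank=max(2, n_regions // 3),
    )
    return generate_cohort(
        n_subjects, model, base, duration=duration, noise_sd=noise_sd, seed=seed
    )
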