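"""Stage-wise network characterization of functional connectivity.

Stage-mean correlation matrices are treated as weighted, fully connected,
signed networks.  Integration is quantified with the signed weighted
modularity

    Q_W = (1/v+) sum_ij (w+_ij - e+_ij) delta(M_i, M_j)
        - (1/(v+ + v-)) sum_ij (w-_ij - e-_ij) delta(M_i, M_j)

where w+/w- are the positive/negative weight magnitudes, v+/v- their
totals (over all ordered pairs), and e(+/-)_ij = s_i s_j / v the usual
configuration-model null built separately per sign.  Q_W is maximized
with a Louvain-style greedy algorithm whose local moves use the signed
gain; the best of many randomized restarts is kept.  Also provided:
node strength, node-to-region structural aggregation, structure-function
coupling, and edgewise stage contrasts with FDR control.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .connectivity import vectorize_upper

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class WeightedNetwork:
    """Symmetric signed weighted network with zero diagonal."""

    weights: np.ndarray
    nodes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weight matrix must be square")
        if not np.allclose(w, w.T, atol=1e-10):
            raise ValueError("weight matrix must be symmetric")
        w = (w + w.T) / 2.0
        w = w.copy()
        np.fill_diagonal(w, 0.0)
        object.__setattr__(self, "weights", w)
        if not self.nodes:
            object.__setattr__(
                self, "nodes", tuple(f"n{i}" for i in range(w.shape[0]))
            )
        if len(self.nodes) != w.shape[0]:
            raise ValueError("node names do not match matrix size")

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


def _as_weights(net: WeightedNetwork | np.ndarray) -> np.ndarray:
    if isinstance(net, WeightedNetwork):
        return net.weights
    return WeightedNetwork(np.asarray(net, dtype=float)).weights


def signed_modularity(
    net: WeightedNetwork | np.ndarray, membership: np.ndarray
) -> float:
    """Evaluate Q_W for a given partition.

    For all-positive networks this reduces to classical weighted Newman
    modularity; a single-module partition then scores exactly 0 (the
    null term telescopes).  An all-zero network scores 0 with a warning.
    """
    w = _as_weights(net)
    membership = np.asarray(membership)
    if membership.shape != (w.shape[0],):
        raise ValueError("partition must assign every node")
    wp = np.clip(w, 0.0, None)
    wn = np.clip(-w, 0.0, None)
    vp, vn = wp.sum(), wn.sum()
    if vp == 0 and vn == 0:
        warnings.warn("all-zero network; Q_W defined as 0", stacklevel=2)
        return 0.0
    delta = membership[:, None] == membership[None, :]

    def layer_sum(wl: np.ndarray, vl: float) -> float:
        if vl == 0:
            return 0.0
        s = wl.sum(axis=1)
        return float((wl[delta].sum()) - (np.outer(s, s)[delta].sum()) / vl)

    q = 0.0
    if vp > 0:
        q += layer_sum(wp, vp) / vp
    if vn > 0:
        q -= layer_sum(wn, vn) / (vp + vn)
    return q


@dataclass(frozen=True)
class ModularityResult:
    """Best partition found and its Q_W."""

    partition: np.ndarray
    q: float
    iterations: int
    seed: int

    @property
    def n_modules(self) -> int:
        return len(np.unique(self.partition))


# --------------------------------------------------------------------------
# Louvain maximization with signed gains
# --------------------------------------------------------------------------

def _move_phase(
    wp: np.ndarray,
    wn: np.ndarray,
    vp: float,
    vn: float,
    rng: np.random.Generator,
    init: np.ndarray | None = None,
) -> np.ndarray:
    """Greedy local moves on the (possibly aggregated) signed layers.

    The positive and negative layers ``wp``/``wn`` are carried separately
    through aggregation (their mixture under a net-weight aggregate would
    corrupt the objective).  ``vp``/``vn`` are the totals of the original
    network (invariant under aggregation); the move gain is the exact
    change in Q_W.
    """
    n = len(wp)
    sp = wp.sum(axis=1)
    sn = wn.sum(axis=1)
    comm = np.arange(n) if init is None else init.copy()
    comm_sp = np.bincount(comm, weights=sp, minlength=n)
    comm_sn = np.bincount(comm, weights=sn, minlength=n)
    wp_off = wp.copy()
    wn_off = wn.copy()
    np.fill_diagonal(wp_off, 0.0)
    np.fill_diagonal(wn_off, 0.0)

    improved = True
    while improved:
        improved = False
        for i in rng.permutation(n):
            a = comm[i]
            comm_sp[a] -= sp[i]
            comm_sn[a] -= sn[i]
            kp = np.bincount(comm, weights=wp_off[i], minlength=n)
            kn = np.bincount(comm, weights=wn_off[i], minlength=n)

            gain = np.zeros(n)
            if vp > 0:
                gain += (2.0 * kp - 2.0 * sp[i] * comm_sp / vp) / vp
            if vn > 0:
                gain -= (2.0 * kn - 2.0 * sn[i] * comm_sn / vn) / (vp + vn)
            stay = gain[a]
            best = int(np.argmax(gain))
            if gain[best] > stay + 1e-12:
                comm[i] = best
                improved = True
            comm_sp[comm[i]] += sp[i]
            comm_sn[comm[i]] += sn[i]
    return comm


def _aggregate(w: np.ndarray, comm: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Collapse communities into super-nodes, summing weights (with self-loops)."""
    labels, renum = np.unique(comm, return_inverse=True)
    c = len(labels)
    m = np.zeros((len(w), c))
    m[np.arange(len(w)), renum] = 1.0
    return m.T @ w @ m, renum


def _louvain_once(
    w: np.ndarray, rng: np.random.Generator, random_init: bool = False
) -> np.ndarray:
    wp = np.clip(w, 0.0, None)
    wn = np.clip(-w, 0.0, None)
    vp, vn = wp.sum(), wn.sum()
    mapping = np.arange(len(w))
    first = True
    while True:
        init = None
        if first and random_init:
            # random starting partition diversifies the restarts beyond
            # what node-visit order alone achieves on small dense nets
            init = rng.integers(0, max(2, len(wp) // 2 + 1), len(wp))
        first = False
        comm = _move_phase(wp, wn, vp, vn, rng, init=init)
        agg_p, renum = _aggregate(wp, comm)
        if len(agg_p) == len(wp):
            break
        agg_n, _ = _aggregate(wn, comm)
        mapping = renum[mapping]
        wp, wn = agg_p, agg_n
    return mapping


def louvain_maximize(
    net: WeightedNetwork | np.ndarray,
    iterations: int = 100,
    seed: int = 0,
) -> ModularityResult:
    """Best-of-``iterations`` Louvain maximization of Q_W.

    Each restart visits nodes in a different random order.  The returned
    Q_W is re-evaluated with :func:`signed_modularity` on the original
    network, and never falls below the single-module partition (0 for
    all-positive networks).
    """
    w = _as_weights(net)
    if len(w) < 2:
        raise ValueError("need at least two nodes")
    rng = np.random.default_rng(seed)
    best_partition = np.zeros(len(w), dtype=int)
    if np.abs(w).sum() == 0:
        return ModularityResult(best_partition, 0.0, iterations, seed)
    best_q = signed_modularity(w, best_partition)
    for restart in range(iterations):
        partition = _louvain_once(w, rng, random_init=restart > 0)
        q = signed_modularity(w, partition)
        if q > best_q + 1e-12:
            best_q, best_partition = q, partition
    return ModularityResult(best_partition, best_q, iterations, seed)


# --------------------------------------------------------------------------
# Node strength, structural aggregation, SC-FC coupling
# --------------------------------------------------------------------------

def node_strength(net: WeightedNetwork | np.ndarray) -> np.ndarray:
    """Sum of the weights attached to each node's links."""
    return _as_weights(net).sum(axis=1)


def aggregate_structural(
    node_sc: np.ndarray, membership: list | np.ndarray
) -> tuple[np.ndarray, list]:
    """Sum node-level structural weights into region-level weights.

    ``membership[i]`` names the region of node ``i``; the region-level
    weight W_AB is the sum of all node weights starting in A and ending
    in B.  The within-region diagonal is set to 0.  Region order in the
    output follows first appearance in ``membership``.
    """
    node_sc = np.asarray(node_sc, dtype=float)
    membership = list(membership)
    if len(membership) != len(node_sc):
        raise ValueError("every node must be mapped to exactly one region")
    if any(m is None for m in membership):
        raise ValueError("unmapped node in membership")
    regions = list(dict.fromkeys(membership))
    idx = {r: i for i, r in enumerate(regions)}
    m = np.zeros((len(node_sc), len(regions)))
    for i, r in enumerate(membership):
        m[i, idx[r]] = 1.0
    out = m.T @ node_sc @ m
    out = (out + out.T) / 2.0
    np.fill_diagonal(out, 0.0)
    return out, regions


def sc_fc_correlation(
    fc: np.ndarray, sc: np.ndarray, subset: np.ndarray | list | None = None
) -> float:
    """Pearson r between structural and functional connectivity.

    Computed over the vectorized upper triangles, optionally restricted
    to a common node subset (e.g. cortical regions only, when the
    structural network lacks sub-cortical and cerebellar nodes).
    """
    fc = np.asarray(fc, dtype=float)
    sc = np.asarray(sc, dtype=float)
    if subset is not None:
        subset = np.asarray(subset)
        if len(subset) < 3:
            raise ValueError("subset must contain at least 3 nodes")
        fc = fc[np.ix_(subset, subset)]
        sc = sc[np.ix_(subset, subset)]
    if fc.shape != sc.shape:
        raise ValueError("FC and SC must share node set")
    u, v = vectorize_upper(fc), vectorize_upper(sc)
    if np.std(u) == 0 or np.std(v) == 0:
        raise ValueError("constant connectivity vector; correlation undefined")
    return float(np.corrcoef(u, v)[0, 1])


# --------------------------------------------------------------------------
# Stage contrasts
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class StageContrast:
    """Edgewise paired contrast between two stages, FDR-controlled."""

    mean_difference: np.ndarray
    t_statistic: np.ndarray
    p_values: np.ndarray
    significant: np.ndarray
    n_participants: int
    alpha: float
    block_mean: pd.DataFrame | None = None
    block_sig_count: pd.DataFrame | None = None


def stage_contrast(
    matrices_a: np.ndarray | list[np.ndarray],
    matrices_b: np.ndarray | list[np.ndarray],
    rsn_labels: list[str] | None = None,
    alpha: float = 0.05,
) -> StageContrast:
    """Paired edgewise t-test of stage A vs stage B across participants.

    ``matrices_a`` and ``matrices_b`` are participant-aligned stacks of
    R x R connectivity matrices.  P-values are Benjamini-Hochberg
    corrected at ``alpha``.  With ``rsn_labels`` (one resting-state
    network name per region) the edge differences are additionally
    aggregated into within/between-network blocks, reported both as the
    block mean difference and as the count of significant edges.
    """
    a = np.asarray(matrices_a, dtype=float)
    b = np.asarray(matrices_b, dtype=float)
    if a.shape != b.shape or a.ndim != 3:
        raise ValueError("need participant-aligned stacks of equal shape")
    n, r, _ = a.shape
    if n < 4:
        raise ValueError("need at least 4 participants with both stages")
    iu = np.triu_indices(r, 1)
    a_up = a[:, iu[0], iu[1]]
    b_up = b[:, iu[0], iu[1]]
    diff_up = (a_up - b_up).mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_rel(a_up, b_up, axis=0)
    p = np.where(np.isnan(p), 1.0, p)
    reject, _, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")

    def to_matrix(flat: np.ndarray, fill: float = 0.0) -> np.ndarray:
        m = np.full((r, r), fill)
        m[iu] = flat
        m[(iu[1], iu[0])] = flat
        return m

    block_mean = block_count = None
    if rsn_labels is not None:
        if len(rsn_labels) != r:
            raise ValueError("one RSN label per region required")
        nets = list(dict.fromkeys(rsn_labels))
        labels = np.asarray(rsn_labels)
        mean_bl = np.zeros((len(nets), len(nets)))
        cnt_bl = np.zeros((len(nets), len(nets)), dtype=int)
        edge_net_i = labels[iu[0]]
        edge_net_j = labels[iu[1]]
        for x, na in enumerate(nets):
            for y, nb in enumerate(nets):
                if y < x:
                    continue
                mask = ((edge_net_i == na) & (edge_net_j == nb)) | (
                    (edge_net_i == nb) & (edge_net_j == na)
                )
                if mask.any():
                    mean_bl[x, y] = mean_bl[y, x] = diff_up[mask].mean()
                    cnt_bl[x, y] = cnt_bl[y, x] = int(reject[mask].sum())
        block_mean = pd.DataFrame(mean_bl, index=nets, columns=nets)
        block_count = pd.DataFrame(cnt_bl, index=nets, columns=nets)

    return StageContrast(
        mean_difference=to_matrix(diff_up),
        t_statistic=to_matrix(np.where(np.isnan(t), 0.0, t)),
        p_values=to_matrix(p, fill=1.0),
        significant=to_matrix(reject.astype(float)).astype(bool),
        n_participants=n,
        alpha=alpha,
        block_mean=block_mean,
        block_sig_count=block_count,
    )


# --------------------------------------------------------------------------
# Stage-wise summaries over a windowed cohort
# --------------------------------------------------------------------------

def stage_mean_matrices(
    cohort,
    spec=None,
    collapse: dict[str, str] | None = None,
) -> dict[str, dict[str, np.ndarray]]:
    """Per-participant mean connectivity matrix for each stage.

    Windows are non-overlapping; each participant contributes to a stage
    only if at least one of their windows carries that stage label.
    Returns ``{stage: {subject: matrix}}``.
    """
    from .connectivity import (WindowSpec, window_stage_labels,
                               windowed_connectivity)

    spec = spec or WindowSpec(50)
    out: dict[str, dict[str, np.ndarray]] = {}
    for ts, hyp in cohort:
        mats = windowed_connectivity(ts, spec)
        stages = window_stage_labels(hyp, [(m.start, m.stop) for m in mats], ts.tr)
        if collapse:
            stages = [collapse[s] for s in stages]
        for stage in set(stages):
            members = [m.matrix for m, s in zip(mats, stages) if s == stage]
            out.setdefault(stage, {})[ts.subject] = np.mean(members, axis=0)
    return out


def stage_modularity(
    summary: dict[str, dict[str, np.ndarray]],
    iterations: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Q_W of every participant's stage-mean network (Louvain best-of-N)."""
    rows = []
    for stage, per_subject in sorted(summary.items()):
        for subject, matrix in sorted(per_subject.items()):
            res = louvain_maximize(matrix, iterations=iterations, seed=seed)
            rows.append({"stage": stage, "subject": subject,
                         "q_w": res.q, "n_modules": res.n_modules})
    return pd.DataFrame(rows)


def stage_sc_fc(
    summary: dict[str, dict[str, np.ndarray]],
    sc: np.ndarray,
    subset: np.ndarray | list | None = None,
) -> pd.DataFrame:
    """SC-FC coupling of every participant's stage-mean network."""
    rows = []
    for stage, per_subject in sorted(summary.items()):
        for subject, matrix in sorted(per_subject.items()):
            rows.append({
                "stage": stage,
                "subject": subject,
                "r": sc_fc_correlation(matrix, sc, subset=subset),
            })
    return pd.DataFrame(rows)
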