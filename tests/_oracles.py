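"""Independent brute-force oracles used to validate the implementation."""

import itertools

import numpy as np


def pearson_pairwise(data: np.ndarray) -> np.ndarray:
    """Per-pair Pearson correlation from the textbook formula."""
    t, r = data.shape
    out = np.eye(r)
    for i in range(r):
        for j in range(i + 1, r):
            x, y = data[:, i], data[:, j]
            xm, ym = x - x.mean(), y - y.mean()
            out[i, j] = out[j, i] = (xm @ ym) / np.sqrt((xm @ xm) * (ym @ ym))
    return out


def set_partitions(n: int):
    """All partitions of {0..n-1} as membership arrays (restricted growth)."""
    def rec(prefix, n_blocks):
        i = len(prefix)
        if i == n:
            yield np.array(prefix)
            return
        for b in range(n_blocks + 1):
            yield from rec(prefix + [b], max(n_blocks, b + 1))

    yield from rec([], 0)


def signed_q_direct(w: np.ndarray, membership: np.ndarray) -> float:
    """Term-by-term evaluation of the signed weighted modularity."""
    w = np.asarray(w, dtype=float)
    n = len(w)
    wp = np.where(w > 0, w, 0.0)
    wn = np.where(w < 0, -w, 0.0)
    vp = wp.sum()
    vn = wn.sum()
    q = 0.0
    for i in range(n):
        for j in range(n):
            if membership[i] != membership[j]:
                continue
            if vp > 0:
                ep = wp[i].sum() * wp[:, j].sum() / vp
                q += (wp[i, j] - ep) / vp
            if vn > 0:
                en = wn[i].sum() * wn[:, j].sum() / vn
                q -= (wn[i, j] - en) / (vp + vn)
    return q


def best_partition_exhaustive(w: np.ndarray):
    """Global optimum of signed modularity by enumerating all partitions."""
    best_q, best_m = -np.inf, None
    for m in set_partitions(len(w)):
        q = signed_q_direct(w, m)
        if q > best_q:
            best_q, best_m = q, m
    return best_q, best_m


def best_bijection_exhaustive(sim: np.ndarray):
    """Max-total-similarity assignment by checking all k! bijections."""
    k = len(sim)
    best, best_perm = -np.inf, None
    for perm in itertools.permutations(range(k)):
        total = sum(sim[i, perm[i]] for i in range(k))
        if total > best:
            best, best_perm = total, perm
    return best, best_perm
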