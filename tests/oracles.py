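"""Independent oracles used to freeze expected values.

These deliberately avoid the code paths they check: score distributions
come from exhaustive enumeration of all outcome combinations, cross-sample
aggregation from dict-based convolution, and tail sums from plain Python.
"""

from __future__ import annotations

import itertools

import numpy as np


def brute_force_sample_pmf(P: np.ndarray, S: np.ndarray, cap: int | None) -> dict[int, float]:
    """Enumerate all 4^m outcome combinations for one sample.

    The observed-score statistic is computed literally: unmutated positions
    contribute their NO_MUT score, and only the ``cap`` largest *realized*
    mutation scores are summed.
    """
    m = P.shape[0]
    pmf: dict[int, float] = {}
    for combo in itertools.product(range(4), repeat=m):
        prob = 1.0
        base = 0
        mut_scores = []
        for i, o in enumerate(combo):
            prob *= P[i, o]
            if o == 0:
                base += int(S[i, 0])
            else:
                mut_scores.append(int(S[i, o]))
        kept = sorted(mut_scores)[-cap:] if cap else mut_scores
        score = base + sum(kept)
        pmf[score] = pmf.get(score, 0.0) + prob
    return pmf


def brute_force_sample_pmf_fast(P: np.ndarray, S: np.ndarray, cap: int | None) -> dict[int, float]:
    """Vectorized version of :func:`brute_force_sample_pmf` (still pure
    enumeration, no dynamic programming)."""
    m = P.shape[0]
    combos = np.array(list(itertools.product(range(4), repeat=m)), dtype=np.int64)
    idx = np.arange(m)
    probs = P[idx, combos].prod(axis=1)
    picked = S[idx, combos]
    is_mut = combos > 0
    base = np.where(~is_mut, S[idx, 0][None, :], 0).sum(axis=1)
    mut_scores = np.where(is_mut, picked, -1)
    mut_sorted = np.sort(mut_scores, axis=1)
    if cap:
        kept = np.clip(mut_sorted[:, -cap:], 0, None).sum(axis=1)
    else:
        kept = np.clip(mut_sorted, 0, None).sum(axis=1)
    totals = base + kept
    pmf: dict[int, float] = {}
    for s, p in zip(totals.tolist(), probs.tolist()):
        pmf[s] = pmf.get(s, 0.0) + p
    return pmf


def dict_convolve(a: dict[int, float], b: dict[int, float]) -> dict[int, float]:
    out: dict[int, float] = {}
    for sa, pa in a.items():
        for sb, pb in b.items():
            out[sa + sb] = out.get(sa + sb, 0.0) + pa * pb
    return out


def combine_pmfs(pmfs: list[dict[int, float]]) -> dict[int, float]:
    out = {0: 1.0}
    for pmf in pmfs:
        out = dict_convolve(out, pmf)
    return out


def tail_probability(pmf: dict[int, float], s_obs: int) -> float:
    return sum(p for s, p in pmf.items() if s >= s_obs)


def total_variation(dense: np.ndarray, pmf: dict[int, float]) -> float:
    size = max(dense.size, (max(pmf) + 1) if pmf else 1)
    a = np.zeros(size)
    a[: dense.size] = dense
    b = np.zeros(size)
    for s, p in pmf.items():
        b[s] = p
    return 0.5 * float(np.abs(a - b).sum())


def prob_at_least_k_events(P: np.ndarray, k: int) -> float:
    """P(at least k mutation events across positions), by enumeration-free
    exact Poisson-binomial recursion on event counts."""
    pm = P[:, 1:].sum(axis=1)
    dist = np.zeros(P.shape[0] + 1)
    dist[0] = 1.0
    for p in pm:
        dist[1:] = dist[1:] * (1 - p) + dist[:-1] * p
        dist[0] *= 1 - p
    return float(dist[k:].sum())


def bh_by_hand(pvals: list[float]) -> list[float]:
    """Step-up BH computed with explicit loops."""
    n = len(pvals)
    order = sorted(range(n), key=lambda i: pvals[i])
    q = [0.0] * n
    prev = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        val = min(prev, pvals[i] * n / rank)
        q[i] = val
        prev = val
    return q


def fisher_closed_form_df4(p1: float, p2: float) -> float:
    """Chi-square upper tail at 4 df: exp(-X/2) * (1 + X/2)."""
    x = -2.0 * (np.log(p1) + np.log(p2))
    return float(np.exp(-x / 2) * (1 + x / 2))
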