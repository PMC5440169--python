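"""Significance engine: exact background score distributions by dynamic
programming with a top-2-per-sample mutation cap, cross-sample convolution,
inclusive tail p-values and BH q-values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.signal

from .io import ElementTestResult
from .scoring import ScoreMatrix

#: Default cap on scored mutation events per sample.
EVENT_CAP = 2

#: pmf entries below this are pruned into the tracked tail mass.
PRUNE_THRESHOLD = 1e-16

#: Above this product of support sizes, cross-sample convolution switches
#: from exact polynomial multiplication to FFT.
FFT_CUTOVER = 1_000_000


@dataclass
class DPCost:
    """Hardware-free cost meter: number of DP cells touched."""

    cells: int = 0


@dataclass
class ScoreDistribution:
    """Sparse pmf over non-negative integer scores, stored densely from 0.

    ``eps`` tracks truncated/pruned tail mass; it is added to p-values so
    truncation is always conservative.
    """

    probs: np.ndarray
    eps: float = 0.0

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 1:
            raise ValueError("pmf must be one-dimensional")
        if (self.probs < 0).any():
            raise ValueError("negative probability mass")

    @property
    def total_mass(self) -> float:
        return float(self.probs.sum()) + self.eps

    @property
    def support_max(self) -> int:
        nz = np.nonzero(self.probs)[0]
        return int(nz[-1]) if nz.size else 0

    def as_dict(self) -> dict[int, float]:
        return {int(s): float(p) for s, p in enumerate(self.probs) if p > 0}

    def pruned(self, threshold: float = PRUNE_THRESHOLD) -> "ScoreDistribution":
        small = (self.probs > 0) & (self.probs < threshold)
        if not small.any():
            return self
        probs = self.probs.copy()
        dropped = float(probs[small].sum())
        probs[small] = 0.0
        return ScoreDistribution(probs, self.eps + dropped)

    @classmethod
    def from_dict(cls, pmf: dict[int, float], eps: float = 0.0) -> "ScoreDistribution":
        size = max(pmf) + 1 if pmf else 1
        probs = np.zeros(size)
        for s, p in pmf.items():
            if s < 0:
                raise ValueError("scores must be non-negative")
            probs[s] = p
        return cls(probs, eps)


def observed_score(mutation_scores: Sequence[int], base: int = 0, cap: int = EVENT_CAP) -> int:
    """Sum of the ``cap`` largest observed mutation scores (all if fewer),
    plus the no-mutation base score of the remaining positions."""
    top = sorted(int(s) for s in mutation_scores)[-cap:] if cap else []
    return int(base) + sum(top)


def sample_background_distribution(
    P: np.ndarray,
    S: np.ndarray,
    cap: Optional[int] = EVENT_CAP,
    cost: Optional[DPCost] = None,
) -> ScoreDistribution:
    """Exact distribution of one sample's element score by DP over positions.

    ``P`` and ``S`` are (m, 4) probability and integer-score arrays with
    outcome order NO_MUT, TS, TV_AT_GT, TV_AC_GC.  With ``cap`` set,
    positions are processed in descending order of maximum attainable
    mutation score and the DP state is (accumulated score, scored-event
    count): once ``cap`` events are counted, further mutation outcomes
    contribute probability but zero score.  With ``cap=None`` the result is
    the plain exact convolution of the per-position score variables.
    """
    P = np.asarray(P, dtype=float)
    S = np.asarray(S, dtype=np.int64)
    if P.shape != S.shape or P.ndim != 2 or P.shape[1] != 4:
        raise ValueError(f"probability/score shape mismatch: {P.shape} vs {S.shape}")
    m = P.shape[0]
    smax = int(S.max(axis=1).sum()) if m else 0

    if cap is None:
        pmf = np.zeros(smax + 1)
        pmf[0] = 1.0
        for i in range(m):
            new = np.zeros_like(pmf)
            for o in range(4):
                if P[i, o]:
                    s = S[i, o]
                    new[s:] += pmf[: pmf.size - s if s else pmf.size] * P[i, o]
            pmf = new
            if cost is not None:
                cost.cells += pmf.size
        return ScoreDistribution(pmf)

    order = np.argsort(-S[:, 1:].max(axis=1), kind="stable")
    width = smax + 1
    levels = [np.zeros(width) for _ in range(cap + 1)]
    levels[0][0] = 1.0
    for i in order:
        p0, s0 = P[i, 0], S[i, 0]
        new = [np.zeros(width) for _ in range(cap + 1)]
        for e in range(cap + 1):
            if s0:
                new[e][s0:] += levels[e][:-s0] * p0
            else:
                new[e] += levels[e] * p0
            if e == cap:
                # capped: mutation outcomes keep probability, add no score
                new[e] += levels[e] * P[i, 1:].sum()
            if e > 0:
                for o in range(1, 4):
                    if P[i, o]:
                        s = S[i, o]
                        src = levels[e - 1]
                        if s:
                            new[e][s:] += src[:-s] * P[i, o]
                        else:
                            new[e] += src * P[i, o]
        levels = new
        if cost is not None:
            cost.cells += width * (cap + 1)
    pmf = np.sum(levels, axis=0)
    return ScoreDistribution(pmf)


def batch_sample_distributions(
    P: np.ndarray,
    position_scores: np.ndarray,
    cap: int = EVENT_CAP,
    cost: Optional[DPCost] = None,
) -> list[ScoreDistribution]:
    """Vectorized per-sample DP for position-uniform score schemes.

    Requires every mutation outcome at a position to share one score and
    NO_MUT to score zero (true for the burden and conservation schemes).
    ``P`` is (m, k, 4); ``position_scores`` is (m,).  Equivalent to calling
    :func:`sample_background_distribution` per sample, but iterates
    positions once for all samples; with scores sorted descending the
    first ``cap`` events encountered are exactly the ``cap`` largest
    realized scores, so the capped DP is exact.
    """
    if cap != 2:
        raise ValueError("fast path supports cap=2 only")
    P = np.asarray(P, dtype=float)
    s = np.asarray(position_scores, dtype=np.int64)
    m, k, _ = P.shape
    top = np.sort(s)[::-1]
    width = int(top[:2].sum()) + 1 if m else 1
    w1 = int(top[0]) + 1 if m else 1

    A0 = np.ones(k)
    A1 = np.zeros((k, w1))
    A2 = np.zeros((k, width))
    # positions sharing a score are processed as one block: with a common
    # score only the within-block event count (0, 1, >=2) matters
    for si in np.unique(s)[::-1]:
        si = int(si)
        if si == 0:
            break  # zero-score positions cannot change any accumulated score
        block = np.nonzero(s == si)[0]
        p0 = P[block, :, 0]  # (g, k)
        pm = P[block, :, 1:].sum(axis=2)
        P0 = p0.prod(axis=0)
        P1 = P0 * (pm / p0).sum(axis=0)
        P2 = np.clip(1.0 - P0 - P1, 0.0, 1.0)
        end = min(si + w1, width)
        A2[:, si:end] += A1[:, : end - si] * (1.0 - P0)[:, None]
        if 2 * si < width:
            A2[:, 2 * si] += A0 * P2
        # else: the block is the single highest-scoring position, where
        # two within-block events are impossible (P2 is fp noise)
        A1 *= P0[:, None]
        A1[:, si] += A0 * P1
        A0 = A0 * P0
        if cost is not None:
            cost.cells += block.size * k * (cap + 1) * width
    out = []
    for j in range(k):
        pmf = A2[j].copy()
        pmf[:w1] += A1[j]
        pmf[0] += A0[j]
        out.append(ScoreDistribution(pmf))
    return out


def _convolve_pmf(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, float]:
    """Convolve two pmfs; returns (pmf, mass clipped by FFT round-off)."""
    if a.size * b.size <= FFT_CUTOVER:
        return np.convolve(a, b), 0.0
    out = scipy.signal.fftconvolve(a, b)
    neg = out < 0
    clipped = float(-out[neg].sum())
    out[neg] = 0.0
    return out, clipped


def combine_samples(distributions: Sequence[ScoreDistribution]) -> ScoreDistribution:
    """Exact convolution across independent samples (balanced tree)."""
    if not distributions:
        raise ValueError("need at least one sample distribution")
    items = [(d.probs, d.eps) for d in distributions]
    while len(items) > 1:
        paired = []
        for i in range(0, len(items) - 1, 2):
            (pa, ea), (pb, eb) = items[i], items[i + 1]
            pmf, clipped = _convolve_pmf(pa, pb)
            paired.append((pmf, ea + eb + clipped))
        if len(items) % 2:
            paired.append(items[-1])
        items = paired
    probs, eps = items[0]
    return ScoreDistribution(probs, eps)


def p_value(distribution: ScoreDistribution, s_obs: int) -> float:
    """Inclusive upper tail P(S >= s_obs) plus the truncated tail mass.

    The tail is read off a reversed cumulative sum, so p is exactly
    monotone non-increasing in the observed score; a score at or below the
    minimum support gives exactly 1.
    """
    s_obs = int(s_obs)
    if s_obs <= 0:
        return 1.0
    if s_obs >= distribution.probs.size:
        tail = 0.0
    else:
        rc = np.cumsum(distribution.probs[::-1])[::-1]
        tail = float(rc[s_obs])
    p = tail + distribution.eps
    return float(min(max(p, np.finfo(float).tiny), 1.0))


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    n = p.size
    if n == 0:
        return np.array([])
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(n)
    q[order] = q_sorted
    return q


def qq_data(p_values: Sequence[float]) -> pd.DataFrame:
    """Expected-vs-observed quantile pairs for a QQ plot.

    Observed p-values are sorted ascending and paired with the uniform
    quantiles (i - 0.5)/n; -log10 transforms are included for plotting.
    """
    p = np.sort(np.asarray(p_values, dtype=float))
    if p.size == 0:
        raise ValueError("need at least one p-value")
    n = p.size
    expected = (np.arange(1, n + 1) - 0.5) / n
    return pd.DataFrame(
        {
            "expected": expected,
            "observed": p,
            "neglog10_expected": -np.log10(expected),
            "neglog10_observed": -np.log10(np.maximum(p, np.finfo(float).tiny)),
        }
    )


@dataclass
class ElementTest:
    """Raw per-element test output (before multiple-testing correction)."""

    observed_score: int
    p_value: float
    n_mut_observed: int
    n_mut_expected: float
    per_sample_scores: np.ndarray
    distribution: ScoreDistribution = field(repr=False)


def test_element(
    P: np.ndarray,
    scores: ScoreMatrix,
    observed: Sequence[tuple[int, int, int]],
    cap: Optional[int] = EVENT_CAP,
    cost: Optional[DPCost] = None,
) -> ElementTest:
    """Full significance evaluation of one element.

    ``P`` is the (m, k, 4) probability matrix (optionally overdispersion
    adjusted), ``scores`` the matching score matrix and ``observed`` the
    element's mutations as (position_index, sample_index, outcome_code)
    with outcome codes 1..3.  Orchestrates the per-sample DP, cross-sample
    convolution and inclusive-tail p-value.
    """
    P = np.asarray(P, dtype=float)
    m, k, _ = P.shape
    if m == 0:
        raise ValueError("element has zero usable positions")
    S = scores.S

    per_sample_obs = np.zeros(k, dtype=np.int64)
    muts_by_sample: dict[int, list[int]] = {}
    for pos_i, sample_i, outcome in observed:
        muts_by_sample.setdefault(sample_i, []).append((pos_i, outcome))
    for j in range(k):
        base = int(S[:, j, 0].sum())
        mut_scores = []
        for pos_i, outcome in muts_by_sample.get(j, []):
            base -= int(S[pos_i, j, 0])  # mutated position loses its NO_MUT score
            mut_scores.append(int(S[pos_i, j, outcome]))
        per_sample_obs[j] = observed_score(mut_scores, base=base, cap=cap or len(mut_scores))

    if cap == EVENT_CAP and scores.position_uniform:
        dists = batch_sample_distributions(P, S[:, 0, 1], cap=cap, cost=cost)
    else:
        dists = [
            sample_background_distribution(P[:, j, :], S[:, j, :], cap=cap, cost=cost)
            for j in range(k)
        ]
    overall = combine_samples([d.pruned() for d in dists])
    s_obs = int(per_sample_obs.sum())
    return ElementTest(
        observed_score=s_obs,
        p_value=p_value(overall, s_obs),
        n_mut_observed=len(observed),
        n_mut_expected=float(P[:, :, 1:].sum()),
        per_sample_scores=per_sample_obs,
        distribution=overall,
    )


def finalize_results(
    raw: Sequence[tuple[str, str, int, ElementTest]], fdr: float = 0.10
) -> list[ElementTestResult]:
    """Attach BH q-values per element type (each category is tested as its
    own family) and produce result records."""
    results: list[ElementTestResult] = []
    by_type: dict[str, list[int]] = {}
    for idx, (eid, etype, length, t) in enumerate(raw):
        results.append(
            ElementTestResult(
                element_id=eid,
                element_type=etype,
                length_bp=length,
                n_mut_observed=t.n_mut_observed,
                n_mut_expected=t.n_mut_expected,
                observed_score=t.observed_score,
                p_value=t.p_value,
            )
        )
        by_type.setdefault(etype, []).append(idx)
    for indices in by_type.values():
        qs = bh_fdr([results[i].p_value for i in indices])
        for i, q in zip(indices, qs):
            results[i].q_value = float(q)
    return results
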