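"""Position/sample/outcome scores under the three schemes.

All schemes emit non-negative integers on a shared deci-grid (values are
floored at 0.1 resolution and multiplied by 10), so the detection engine
is scheme-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

SCHEMES = ("nmut", "loglik", "phylop")

#: phyloP values are shifted by this constant before integerization so all
#: scores are non-negative.
PHYLOP_SHIFT = 20.0

#: Score assigned to a mutation under the mutation-count scheme ("one" on
#: the deci-grid; dividing by 10 recovers counts exactly).
NMUT_SCORE = 10


@dataclass
class ScoreMatrix:
    """Integer scores S[position, sample, outcome] plus the scheme tag."""

    S: np.ndarray  # (m, k, 4) int64; outcome axis: NO_MUT, TS, TV_AT_GT, TV_AC_GC
    scheme: str

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=np.int64)
        if self.S.ndim != 3 or self.S.shape[2] != 4:
            raise ValueError(f"score matrix must be (m, k, 4), got {self.S.shape}")
        if self.scheme not in SCHEMES and self.scheme != "custom":
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if (self.S < 0).any():
            raise ValueError("scores must be non-negative")

    @property
    def position_uniform(self) -> bool:
        """True when, at every position, all samples and mutation outcomes
        share one score and NO_MUT scores zero — enables the fast
        convolution path."""
        if (self.S[:, :, 0] != 0).any():
            return False
        mut = self.S[:, :, 1:]
        return bool((mut == mut[:, :1, :1]).all())


def floor_deci(x: np.ndarray | float) -> np.ndarray | float:
    """Floor at 0.1 resolution, then scale to the integer deci-grid.

    A relative epsilon absorbs representation error so exactly-on-grid
    inputs (e.g. -ln(e^-5) = 5.0) land on their grid point.
    """
    scaled = np.asarray(x, dtype=float) * 10.0
    out = np.floor(scaled + 1e-9).astype(np.int64)
    return out if out.ndim else int(out)


def score_nmut(P: np.ndarray) -> ScoreMatrix:
    """Burden scheme: every mutation outcome scores NMUT_SCORE, NO_MUT 0."""
    m, k, _ = P.shape
    S = np.zeros((m, k, 4), dtype=np.int64)
    S[:, :, 1:] = NMUT_SCORE
    return ScoreMatrix(S, "nmut")


def score_loglik(P: np.ndarray) -> ScoreMatrix:
    """Goodness-of-fit scheme: minus log predicted probability, floored to
    the deci-grid.  The NO_MUT outcome gets its own (near-zero) score."""
    P = np.asarray(P, dtype=float)
    if (P <= 0).any():
        raise ValueError("cannot score an impossible event (probability 0)")
    if (P > 1).any():
        raise ValueError("probabilities must be <= 1")
    return ScoreMatrix(floor_deci(-np.log(P)), "loglik")


def score_phylop(phylop: np.ndarray, n_samples: int) -> ScoreMatrix:
    """Conservation scheme: shifted phyloP, same for all mutation outcomes
    at a position; NO_MUT scores zero.

    Missing (NaN) phyloP values are treated as 0 (neutral conservation).
    """
    phylop = np.asarray(phylop, dtype=float).copy()
    phylop[np.isnan(phylop)] = 0.0
    if (phylop < -PHYLOP_SHIFT).any():
        raise ValueError(f"phyloP below {-PHYLOP_SHIFT} breaks score non-negativity")
    per_pos = floor_deci(phylop + PHYLOP_SHIFT)
    m = phylop.shape[0]
    S = np.zeros((m, n_samples, 4), dtype=np.int64)
    S[:, :, 1:] = np.asarray(per_pos).reshape(m, 1, 1)
    return ScoreMatrix(S, "phylop")


def score_custom(table: np.ndarray, scheme: str = "custom") -> ScoreMatrix:
    """Wrap a user-provided (m, k, 4) integer score array."""
    return ScoreMatrix(np.asarray(table), scheme)
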