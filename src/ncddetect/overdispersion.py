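"""Extra-binomial variation of observed vs predicted mutation counts.

Window-level counts are modelled beta-binomially; the fitted intra-class
correlation drives an empirical-Bayes correction factor per window that
shrinks observed/expected ratios toward one and rescales the position- and
sample-specific mutation probabilities so long-element p-values calibrate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import scipy.optimize
import scipy.stats

#: Pooling window for the correction (bp).
DEFAULT_WINDOW_SIZE = 100_000


@dataclass
class OverdispersionModel:
    """Beta-binomial dispersion fit and derived shrinkage strength."""

    rho: float  # intra-class correlation, in [0, 1)
    window_size: int = DEFAULT_WINDOW_SIZE

    def __post_init__(self) -> None:
        if not 0 <= self.rho < 1:
            raise ValueError(f"rho={self.rho} outside [0, 1)")

    @property
    def nu(self) -> float:
        """Beta prior strength (alpha + beta) implied by rho; infinite at rho=0."""
        if self.rho == 0:
            return np.inf
        return (1.0 - self.rho) / self.rho

    def correction_factors(
        self, n_w: np.ndarray, e_w: np.ndarray, exposures: np.ndarray
    ) -> np.ndarray:
        """Posterior-mean rate multipliers per window.

        c_w = (n_w + nu*mu_w) / (e_w + nu*mu_w) with mu_w = e_w / N_w: the
        beta posterior mean over the window's mutation rate divided by its
        prior mean.  rho -> 0 gives factors -> 1; n_w == e_w gives exactly 1.
        """
        n_w = np.asarray(n_w, dtype=float)
        e_w = np.asarray(e_w, dtype=float)
        exposures = np.asarray(exposures, dtype=float)
        if np.isinf(self.nu):
            return np.ones_like(e_w)
        mu_w = e_w / exposures
        prior = self.nu * mu_w
        return (n_w + prior) / (e_w + prior)


def _betabinom_negloglik(
    rho: float, n_w: np.ndarray, e_w: np.ndarray, exposures: np.ndarray
) -> float:
    mu = e_w / exposures
    if rho < 1e-12:
        return -scipy.stats.binom.logpmf(n_w, exposures.astype(np.int64), mu).sum()
    nu = (1.0 - rho) / rho
    a = mu * nu
    b = (1.0 - mu) * nu
    return -scipy.stats.betabinom.logpmf(n_w, exposures.astype(np.int64), a, b).sum()


def estimate_dispersion(
    n_w: np.ndarray,
    e_w: np.ndarray,
    exposures: np.ndarray,
    window_size: int = DEFAULT_WINDOW_SIZE,
) -> OverdispersionModel:
    """Maximum-likelihood beta-binomial dispersion over windowed counts.

    ``n_w`` are observed counts, ``e_w`` predicted expectations and
    ``exposures`` the number of (position, sample) trials per window; the
    beta-binomial mean is matched to ``e_w``.  Returns rho ~ 0 when the
    counts are binomial.
    """
    n_w = np.asarray(n_w, dtype=float)
    e_w = np.asarray(e_w, dtype=float)
    exposures = np.asarray(exposures, dtype=float)
    if n_w.size < 2:
        raise ValueError("dispersion estimation needs at least 2 windows")
    if (e_w <= 0).any():
        raise ValueError("all window expectations must be positive")

    # optimize on log10(rho) to resolve the near-zero regime
    def nll_log(log_rho: float) -> float:
        return _betabinom_negloglik(10.0**log_rho, n_w, e_w, exposures)

    res = scipy.optimize.minimize_scalar(
        nll_log, bounds=(-10.0, -0.005), method="bounded", options={"xatol": 1e-6}
    )
    rho = float(10.0**res.x)
    # accept rho=0 when the binomial likelihood is at least as good
    if _betabinom_negloglik(0.0, n_w, e_w, exposures) <= res.fun + 1e-9:
        rho = 0.0
    return OverdispersionModel(rho=rho, window_size=window_size)


def adjust_probabilities(
    P: np.ndarray,
    model: OverdispersionModel,
    window_assignment: np.ndarray,
    n_w: np.ndarray,
    e_w: np.ndarray,
    exposures: np.ndarray,
) -> np.ndarray:
    """Scale mutation-outcome probabilities by their window's correction
    factor and reset NO_MUT so each 4-vector still sums to one exactly.

    ``window_assignment`` maps each position (axis 0 of P) to an index
    into the per-window count arrays.
    """
    P = np.asarray(P, dtype=float)
    factors = model.correction_factors(n_w, e_w, exposures)
    c = factors[np.asarray(window_assignment, dtype=np.int64)]
    adjusted = P.copy()
    adjusted[..., 1:] = P[..., 1:] * c.reshape((-1,) + (1,) * (P.ndim - 1))
    mut_total = adjusted[..., 1:].sum(axis=-1)
    if (mut_total >= 1).any():
        raise ValueError("adjusted mutation probability >= 1 (pathological input)")
    adjusted[..., 0] = 1.0 - mut_total
    return adjusted


def window_index(
    positions: np.ndarray, window_size: int = DEFAULT_WINDOW_SIZE
) -> np.ndarray:
    """Window id for each 0-based position (single chromosome)."""
    return np.asarray(positions, dtype=np.int64) // window_size


def windowed_counts(
    positions: np.ndarray,
    mutation_positions: np.ndarray,
    P_mut: np.ndarray,
    n_samples: Optional[int] = None,
    window_size: int = DEFAULT_WINDOW_SIZE,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Pool observed counts and predicted expectations into windows.

    ``P_mut`` is the per-position total mutation probability summed over
    samples and mutation outcomes (same length as ``positions``); the
    exposure of a window is its position count times ``n_samples``.

    Returns (window_ids, n_w, e_w, exposures) over occupied windows.
    """
    positions = np.asarray(positions, dtype=np.int64)
    wins = window_index(positions, window_size)
    uniq, inverse = np.unique(wins, return_inverse=True)
    e_w = np.bincount(inverse, weights=P_mut, minlength=uniq.size)
    mut_wins = window_index(np.asarray(mutation_positions, dtype=np.int64), window_size)
    n_w = np.zeros(uniq.size)
    lookup = {w: i for i, w in enumerate(uniq)}
    for w in mut_wins:
        if int(w) in lookup:
            n_w[lookup[int(w)]] += 1
    pos_per_win = np.bincount(inverse, minlength=uniq.size)
    exposures = pos_per_win * (n_samples or 1)
    return uniq, n_w, e_w, exposures
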