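"""Background mutation model: count table, multinomial-via-binomial fits,
multiple imputation of replication timing, and 4-outcome prediction.

The multinomial logistic model is decomposed into three one-vs-reference
binomial logits (one per mutation outcome against no-mutation) and
recombined at prediction time as ``p_o = q_o / (1 + sum_j q_j)`` with
``q_o = exp(x' beta_o)``.  An exact multinomial fit is provided as a slow
validation path.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.sparse as sp
from scipy.special import expit, logit

from .annotate import (
    CENTRAL_LEVELS,
    FLANK_LEVELS,
    N_BINS,
    POSITION_COVARIATES,
    SEGMENT_LEVELS,
    BinBoundaries,
    collapse_mutation,
)
from .io import CandidateElement, MutationRecord

#: Count-table columns holding mutation counts, index-aligned with
#: outcome codes 1..3 (TS, TV_AT_GT, TV_AC_GC).
COUNT_COLUMNS = ("n_ts", "n_tv_at_gt", "n_tv_ac_gc")

_OUTCOME_TO_COLUMN = {1: "n_ts", 2: "n_tv_at_gt", 3: "n_tv_ac_gc"}

BIN_LEVELS = tuple(range(1, N_BINS + 1))

#: Fixed factor levels for every covariate except sample id.
FACTOR_LEVELS: dict[str, tuple] = {
    "rep_bin": BIN_LEVELS,
    "central": CENTRAL_LEVELS,
    "flanks": FLANK_LEVELS,
    "segment": tuple(sorted(SEGMENT_LEVELS)),
    "expr_bin": BIN_LEVELS,
    "rate_bin": BIN_LEVELS,
}


def full_factorial_size(
    n_samples: int,
    n_rep: int = N_BINS,
    n_central: int = len(CENTRAL_LEVELS),
    n_flanks: int = len(FLANK_LEVELS),
    n_segments: int = len(SEGMENT_LEVELS),
    n_expr: int = N_BINS,
    n_rate: int = N_BINS,
) -> int:
    """Number of possible covariate combinations in the full count table."""
    return n_samples * n_rep * n_central * n_flanks * n_segments * n_expr * n_rate


class FitError(RuntimeError):
    """Non-convergence or separation during model fitting."""


@dataclass(frozen=True)
class ModelConfig:
    """Which covariates enter the model (the forward-selection ladder is
    expressible purely through this configuration)."""

    covariates: tuple[str, ...] = ("sample", "rep_bin", "central", "flanks", "segment", "expr_bin", "rate_bin")
    signature_interaction: bool = False

    PRESETS = {
        "basic": ("sample", "rep_bin", "central", "flanks"),
        "1a": ("sample", "rep_bin", "central", "flanks", "rate_bin"),
        "1b": ("sample", "rep_bin", "central", "flanks", "segment"),
        "1c": ("sample", "rep_bin", "central", "flanks", "segment", "expr_bin", "rate_bin"),
        "final": ("sample", "rep_bin", "central", "flanks", "segment", "expr_bin", "rate_bin"),
    }

    @classmethod
    def preset(cls, name: str, signature_interaction: bool = False) -> "ModelConfig":
        return cls(covariates=cls.PRESETS[name], signature_interaction=signature_interaction)

    def __post_init__(self) -> None:
        known = {"sample"} | set(FACTOR_LEVELS)
        unknown = set(self.covariates) - known
        if unknown:
            raise ValueError(f"unknown covariates {sorted(unknown)}")


@dataclass
class CountTable:
    """Aggregated exposure and mutation counts per covariate combination.

    One row per (covariate combination, sample); ``n_positions`` is the
    exposure (each position contributes one trial per sample) and the
    three count columns hold the classed mutation counts.  A ``rep_bin``
    of 0 marks a missing replication-timing value (pre-imputation).
    """

    df: pd.DataFrame

    KEY_COLUMNS = ("sample",) + POSITION_COVARIATES

    def __post_init__(self) -> None:
        need = set(self.KEY_COLUMNS) | {"n_positions"} | set(COUNT_COLUMNS)
        missing = need - set(self.df.columns)
        if missing:
            raise ValueError(f"count table lacks columns {sorted(missing)}")

    @property
    def total_exposure(self) -> int:
        return int(self.df["n_positions"].sum())

    @property
    def total_mutations(self) -> int:
        return int(self.df[list(COUNT_COLUMNS)].to_numpy().sum())

    def has_missing_replication(self) -> bool:
        return bool((self.df["rep_bin"] == 0).any())

    def to_tsv(self, path: str | os.PathLike) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | os.PathLike) -> "CountTable":
        return cls(pd.read_csv(path, sep="\t", dtype={"sample": str, "central": str, "flanks": str, "segment": str}))


def _positions_in_elements(
    df: pd.DataFrame, elements: Iterable[CandidateElement]
) -> np.ndarray:
    mask = np.zeros(len(df), dtype=bool)
    chrom = df["chrom"].to_numpy()
    pos = df["pos"].to_numpy()
    for el in elements:
        for c, s, e in el.intervals:
            mask |= (chrom == c) & (pos >= s) & (pos < e)
    return mask


def build_count_table(
    position_table: pd.DataFrame,
    sample_ids: Sequence[str],
    mutations: Sequence[MutationRecord],
    exclude_elements: Optional[Iterable[CandidateElement]] = None,
) -> CountTable:
    """Aggregate a position covariate table and classed mutations.

    Positions (and their mutations) overlapping ``exclude_elements`` are
    dropped before counting, as are unusable positions.  A mutation at a
    position absent from the table raises, naming the locus.
    """
    pt = position_table
    keep = pt["usable"].to_numpy(dtype=bool).copy()
    if exclude_elements is not None:
        excluded = _positions_in_elements(pt, exclude_elements)
        keep &= ~excluded
    pt = pt.loc[keep]

    combo_cols = list(POSITION_COVARIATES)
    combos = pt.groupby(combo_cols, sort=True).size().rename("n_positions").reset_index()
    combos["combo_id"] = np.arange(len(combos))
    pos_to_combo = pt.merge(combos, on=combo_cols, how="left").set_index(
        pd.MultiIndex.from_arrays([pt["chrom"], pt["pos"]])
    )["combo_id"]

    sample_ids = list(sample_ids)
    sample_index = {s: i for i, s in enumerate(sample_ids)}
    counts = np.zeros((len(combos), len(sample_ids), 3), dtype=np.int64)
    dropped_index = set(
        zip(position_table.loc[~keep, "chrom"], position_table.loc[~keep, "pos"])
    )
    for m in mutations:
        key = (m.chrom, m.pos)
        if key in dropped_index:
            continue  # excluded element or unusable position
        try:
            combo_id = int(pos_to_combo.loc[key])
        except KeyError:
            raise ValueError(
                f"mutation at {m.chrom}:{m.pos + 1} has no covariates in the position table"
            ) from None
        if m.sample_id not in sample_index:
            raise ValueError(f"mutation sample {m.sample_id!r} not in sample_ids")
        _, outcome = collapse_mutation(m.ref, m.alt)
        counts[combo_id, sample_index[m.sample_id], int(outcome) - 1] += 1

    n_combo = len(combos)
    k = len(sample_ids)
    rows = combos.loc[combos.index.repeat(k)].reset_index(drop=True)
    rows["sample"] = np.tile(sample_ids, n_combo)
    for j, col in enumerate(COUNT_COLUMNS):
        rows[col] = counts[:, :, j].reshape(-1)
    rows = rows.drop(columns="combo_id")
    cols = list(CountTable.KEY_COLUMNS) + ["n_positions"] + list(COUNT_COLUMNS)
    return CountTable(rows[cols].reset_index(drop=True))


def impute_replication_timing(
    count_table: CountTable, k: int = 3, seed: Optional[int] = None
) -> list[CountTable]:
    """Multiple imputation of missing replication-timing bins.

    Each row with ``rep_bin == 0`` gets a bin drawn from the marginal
    distribution of observed bins (weighted by exposure); ``k`` completed
    tables are returned.  Deterministic given ``seed``.
    """
    df = count_table.df
    observed = df[df["rep_bin"] != 0]
    if observed.empty:
        raise ValueError("cannot impute: no observed replication timing values")
    marginal = observed.groupby("rep_bin")["n_positions"].sum()
    levels = marginal.index.to_numpy()
    probs = marginal.to_numpy() / marginal.to_numpy().sum()
    rng = np.random.default_rng(seed)
    missing = (df["rep_bin"] == 0).to_numpy()
    out = []
    for _ in range(k):
        completed = df.copy()
        if missing.any():
            draws = rng.choice(levels, size=int(missing.sum()), p=probs)
            completed.loc[missing, "rep_bin"] = draws
            completed = (
                completed.groupby(list(CountTable.KEY_COLUMNS), sort=True)
                .sum(numeric_only=True)
                .reset_index()
            )
        out.append(CountTable(completed[df.columns.tolist()].reset_index(drop=True)))
    return out


@dataclass
class Encoding:
    """Sparse one-hot design-matrix builder with explicit reference levels.

    The reference level of every factor is its first level (alphabetical
    for strings, lowest for bins); unseen levels at prediction time raise.
    """

    factors: list[tuple[str, tuple]]
    interactions: list[tuple[str, str]] = field(default_factory=list)

    @classmethod
    def for_config(cls, config: ModelConfig, sample_levels: Sequence[str]) -> "Encoding":
        factors: list[tuple[str, tuple]] = []
        for cov in config.covariates:
            if cov == "sample":
                factors.append(("sample", tuple(sorted(sample_levels))))
            else:
                factors.append((cov, FACTOR_LEVELS[cov]))
        interactions = []
        if config.signature_interaction:
            names = [f for f, _ in factors]
            if "sample" in names and "flanks" in names:
                interactions.append(("sample", "flanks"))
            if "sample" in names and "central" in names:
                interactions.append(("sample", "central"))
        return cls(factors=factors, interactions=interactions)

    @property
    def column_names(self) -> list[str]:
        names = ["(intercept)"]
        for fname, levels in self.factors:
            names.extend(f"{fname}[{lv}]" for lv in levels[1:])
        for fa, fb in self.interactions:
            la = dict(self.factors)[fa][1:]
            lb = dict(self.factors)[fb][1:]
            names.extend(f"{fa}[{a}]:{fb}[{b}]" for a in la for b in lb)
        return names

    def _codes(self, df: pd.DataFrame, fname: str, levels: tuple) -> np.ndarray:
        index = {lv: i for i, lv in enumerate(levels)}
        values = df[fname].to_numpy()
        codes = np.empty(len(values), dtype=np.int64)
        for i, v in enumerate(values):
            try:
                codes[i] = index[v]
            except KeyError:
                raise ValueError(f"unseen level {v!r} for factor {fname!r}") from None
        return codes

    def build(self, df: pd.DataFrame) -> sp.csr_matrix:
        n = len(df)
        blocks: list[sp.spmatrix] = [sp.csr_matrix(np.ones((n, 1)))]
        codes_cache: dict[str, np.ndarray] = {}
        for fname, levels in self.factors:
            codes = self._codes(df, fname, levels)
            codes_cache[fname] = codes
            nlev = len(levels)
            mask = codes > 0
            rows = np.nonzero(mask)[0]
            cols = codes[mask] - 1
            blocks.append(
                sp.csr_matrix(
                    (np.ones(rows.size), (rows, cols)), shape=(n, nlev - 1)
                )
            )
        fdict = dict(self.factors)
        for fa, fb in self.interactions:
            la, lb = len(fdict[fa]) - 1, len(fdict[fb]) - 1
            ca, cb = codes_cache[fa], codes_cache[fb]
            mask = (ca > 0) & (cb > 0)
            rows = np.nonzero(mask)[0]
            cols = (ca[mask] - 1) * lb + (cb[mask] - 1)
            blocks.append(
                sp.csr_matrix((np.ones(rows.size), (rows, cols)), shape=(n, la * lb))
            )
        return sp.hstack(blocks, format="csr")


def _irls_binomial(
    X: sp.csr_matrix,
    successes: np.ndarray,
    trials: np.ndarray,
    column_names: Sequence[str],
    max_iter: int = 100,
    tol: float = 1e-10,
    ridge: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray]:
    """Weighted-binomial logistic IRLS on a sparse design.

    Returns (coefficients, covariance).  Hand-rolled because the installed
    GLM stacks require dense design matrices; validated against the exact
    multinomial path in the test suite.  The small ridge keeps
    quasi-separated levels (factor levels that never mutate) finite
    without measurably biasing identified coefficients; convergence is
    declared on the penalized score equations.
    """
    n, p = X.shape
    if successes.sum() == 0 or successes.sum() >= trials.sum():
        raise FitError("separation: an outcome has zero (or saturated) counts")
    beta = np.zeros(p)
    rate = successes.sum() / max(trials.sum(), 1)
    beta[0] = logit(min(max(rate, 1e-12), 1 - 1e-12))
    grad_tol = 1e-9 * (1.0 + successes.sum())
    A = None
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        mu = np.clip(mu, 1e-15, 1 - 1e-15)
        w = trials * mu * (1 - mu)
        z = eta + (successes - trials * mu) / w
        Xw = X.multiply(w[:, None])
        A = (X.T @ Xw).toarray() + ridge * np.eye(p)
        b = X.T @ (w * z)
        new_beta = np.linalg.solve(A, b)
        if not np.all(np.isfinite(new_beta)):
            raise FitError("binomial fit diverged (non-finite step)")
        delta = np.max(np.abs(new_beta - beta))
        beta = new_beta
        grad = X.T @ (successes - trials * expit(X @ beta)) - ridge * beta
        if delta < tol or np.max(np.abs(grad)) < grad_tol:
            converged = True
            break
    if not converged:
        worst = column_names[int(np.argmax(np.abs(beta)))]
        raise FitError(f"binomial fit did not converge; check covariate {worst!r}")
    if np.max(np.abs(beta)) > 35:
        worst = column_names[int(np.argmax(np.abs(beta)))]
        raise FitError(f"separation suspected on covariate {worst!r}")
    cov = np.linalg.inv(A)
    return beta, cov


@dataclass
class NullModel:
    """Fitted background model: three binomial coefficient vectors per
    imputed count table, plus everything needed to rebuild covariates."""

    config: ModelConfig
    encoding: Encoding
    coef_sets: list[np.ndarray]  # each (3, p): rows TS, TV_AT_GT, TV_AC_GC
    se_sets: list[np.ndarray]  # matching standard errors, (3, p)
    boundaries: Optional[BinBoundaries] = None
    seed: Optional[int] = None

    @property
    def column_names(self) -> list[str]:
        return self.encoding.column_names

    def predict(self, covariates: pd.DataFrame) -> np.ndarray:
        """4-outcome probability matrix, rows summing to one.

        Probabilities (not coefficients) are averaged across imputations.
        """
        X = self.encoding.build(covariates)
        acc = np.zeros((len(covariates), 4))
        for coefs in self.coef_sets:
            q = np.exp(np.column_stack([X @ coefs[j] for j in range(3)]))
            denom = 1.0 + q.sum(axis=1)
            probs = np.empty((len(covariates), 4))
            probs[:, 0] = 1.0 / denom
            probs[:, 1:] = q / denom[:, None]
            acc += probs
        acc /= len(self.coef_sets)
        return acc

    def save(self, path: str | os.PathLike) -> None:
        payload = {
            "format_version": 1,
            "config": {
                "covariates": list(self.config.covariates),
                "signature_interaction": self.config.signature_interaction,
            },
            "factors": [[f, list(lv)] for f, lv in self.encoding.factors],
            "interactions": [list(i) for i in self.encoding.interactions],
            "coef_sets": [c.tolist() for c in self.coef_sets],
            "se_sets": [s.tolist() for s in self.se_sets],
            "boundaries": self.boundaries.to_dict() if self.boundaries else None,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path: str | os.PathLike) -> "NullModel":
        with open(path) as fh:
            payload = json.load(fh)
        config = ModelConfig(
            covariates=tuple(payload["config"]["covariates"]),
            signature_interaction=payload["config"]["signature_interaction"],
        )
        encoding = Encoding(
            factors=[(f, tuple(lv)) for f, lv in payload["factors"]],
            interactions=[tuple(i) for i in payload["interactions"]],
        )
        return cls(
            config=config,
            encoding=encoding,
            coef_sets=[np.asarray(c) for c in payload["coef_sets"]],
            se_sets=[np.asarray(s) for s in payload["se_sets"]],
            boundaries=BinBoundaries.from_dict(payload["boundaries"])
            if payload["boundaries"]
            else None,
            seed=payload["seed"],
        )


def _check_levels(df: pd.DataFrame, config: ModelConfig) -> None:
    if "rep_bin" in config.covariates and (df["rep_bin"] == 0).any():
        raise FitError("count table has missing replication timing; impute first")
    for cov in config.covariates:
        if df[cov].nunique() < 2 and cov != "segment":
            raise FitError(f"covariate {cov!r} has fewer than 2 observed levels")


def fit_null_model(
    count_tables: Sequence[CountTable] | CountTable,
    config: Optional[ModelConfig] = None,
    boundaries: Optional[BinBoundaries] = None,
    seed: Optional[int] = None,
) -> NullModel:
    """Fit the three one-vs-reference binomial logits on each imputed table.

    Exposure per row is ``n_positions`` (the three mutation outcomes are
    rare, mutually exclusive events against a common no-mutation
    reference).
    """
    if isinstance(count_tables, CountTable):
        count_tables = [count_tables]
    if not count_tables:
        raise ValueError("no count tables supplied")
    config = config or ModelConfig()
    sample_levels = sorted(
        set().union(*(set(ct.df["sample"].unique()) for ct in count_tables))
    )
    encoding = Encoding.for_config(config, sample_levels)
    names = encoding.column_names
    coef_sets, se_sets = [], []
    for ct in count_tables:
        df = ct.df
        _check_levels(df, config)
        X = encoding.build(df)
        trials = df["n_positions"].to_numpy(dtype=float)
        coefs = np.empty((3, X.shape[1]))
        ses = np.empty((3, X.shape[1]))
        for j, col in enumerate(COUNT_COLUMNS):
            successes = df[col].to_numpy(dtype=float)
            beta, cov = _irls_binomial(X, successes, trials, names)
            coefs[j] = beta
            ses[j] = np.sqrt(np.diag(cov))
        coef_sets.append(coefs)
        se_sets.append(ses)
    return NullModel(
        config=config,
        encoding=encoding,
        coef_sets=coef_sets,
        se_sets=se_sets,
        boundaries=boundaries,
        seed=seed,
    )


def predict_probabilities(model: NullModel, covariates: pd.DataFrame) -> np.ndarray:
    """Convenience wrapper over :meth:`NullModel.predict`."""
    probs = model.predict(covariates)
    np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-12)
    return probs


def fit_multinomial_exact(
    count_table: CountTable, config: Optional[ModelConfig] = None
) -> NullModel:
    """Exact multinomial logistic fit (slow validation path).

    Maximizes the full multinomial likelihood over the stacked coefficient
    vectors of the three mutation outcomes; used in tests to bound the
    error of the binomial decomposition.
    """
    config = config or ModelConfig()
    df = count_table.df
    _check_levels(df, config)
    encoding = Encoding.for_config(config, sorted(df["sample"].unique()))
    X = encoding.build(df)
    n, p = X.shape
    muts = df[list(COUNT_COLUMNS)].to_numpy(dtype=float)
    trials = df["n_positions"].to_numpy(dtype=float)
    counts = np.column_stack([trials - muts.sum(axis=1), muts])  # [n, 4]

    def negloglik_and_grad(theta: np.ndarray):
        betas = theta.reshape(3, p)
        eta = np.column_stack([X @ betas[j] for j in range(3)])
        # log-sum-exp over [0, eta1, eta2, eta3]
        m = np.maximum(eta.max(axis=1), 0.0)
        lse = m + np.log(np.exp(-m) + np.exp(eta - m[:, None]).sum(axis=1))
        ll = (counts[:, 1:] * eta).sum() - (trials * lse).sum()
        probs = np.exp(eta - lse[:, None])  # mutation-outcome probabilities
        resid = trials[:, None] * probs - counts[:, 1:]
        grad = np.vstack([X.T @ resid[:, j] for j in range(3)])
        return -ll, grad.reshape(-1)

    theta0 = np.zeros(3 * p)
    rate = max(muts.sum() / max(trials.sum(), 1.0), 1e-12) / 3
    theta0.reshape(3, p)[:, 0] = np.log(rate)
    res = scipy.optimize.minimize(
        negloglik_and_grad,
        theta0,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": 5000, "ftol": 1e-16, "gtol": 1e-12},
    )
    theta = res.x
    # Newton polish to machine precision (L-BFGS stalls in flat directions)
    Xd = X.toarray()
    for _ in range(50):
        betas = theta.reshape(3, p)
        eta = Xd @ betas.T
        m = np.maximum(eta.max(axis=1), 0.0)
        lse = m + np.log(np.exp(-m) + np.exp(eta - m[:, None]).sum(axis=1))
        probs = np.exp(eta - lse[:, None])
        grad = np.concatenate(
            [Xd.T @ (trials * probs[:, j] - counts[:, j + 1]) for j in range(3)]
        )
        if np.max(np.abs(grad)) < 1e-9:
            break
        H = np.empty((3 * p, 3 * p))
        for a in range(3):
            for b in range(3):
                w = trials * probs[:, a] * ((a == b) - probs[:, b])
                H[a * p : (a + 1) * p, b * p : (b + 1) * p] = Xd.T @ (w[:, None] * Xd)
        step = np.linalg.solve(H + 1e-9 * np.eye(3 * p), grad)
        if not np.all(np.isfinite(step)):
            break
        theta = theta - step
    else:
        raise FitError("exact multinomial fit failed to converge")
    coefs = theta.reshape(3, p)
    return NullModel(
        config=config,
        encoding=encoding,
        coef_sets=[coefs],
        se_sets=[np.full((3, p), np.nan)],
    )
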