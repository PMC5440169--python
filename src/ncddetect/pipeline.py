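"""End-to-end orchestration: annotate -> fit -> adjust -> test.

Probabilities are computed once per covariate combination and sample
(never per position and sample), which keeps the memory footprint
proportional to the number of realized combinations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import detect, overdispersion as od, scoring
from .annotate import POSITION_COVARIATES, BinBoundaries, collapse_mutation, position_covariate_table
from .io import CandidateElement, ElementTestResult, GenomeTrack, MutationRecord, ReferenceGenome
from .nullmodel import CountTable, ModelConfig, NullModel, build_count_table, fit_null_model, impute_replication_timing
from .scoring import ScoreMatrix


def annotate_genome(
    genome: ReferenceGenome,
    rep_track: GenomeTrack,
    expr_track: GenomeTrack,
    elements: Sequence[CandidateElement],
    mutations: Sequence[MutationRecord],
    chroms: Optional[Sequence[str]] = None,
    boundaries: Optional[BinBoundaries] = None,
) -> tuple[pd.DataFrame, BinBoundaries]:
    """Position covariate table over whole chromosomes."""
    tables = []
    for chrom in chroms or genome.chroms():
        tbl, boundaries = position_covariate_table(
            chrom,
            np.arange(genome.length(chrom)),
            genome,
            rep_track,
            expr_track,
            elements,
            mutations,
            boundaries=boundaries,
        )
        tables.append(tbl)
    return pd.concat(tables, ignore_index=True), boundaries


def fit_pipeline(
    position_table: pd.DataFrame,
    sample_ids: Sequence[str],
    mutations: Sequence[MutationRecord],
    config: Optional[ModelConfig] = None,
    boundaries: Optional[BinBoundaries] = None,
    exclude_elements: Optional[Sequence[CandidateElement]] = None,
    k_imputations: int = 3,
    seed: Optional[int] = None,
) -> tuple[NullModel, CountTable]:
    """Count-table construction, imputation (when needed) and model fit."""
    ct = build_count_table(position_table, sample_ids, mutations, exclude_elements)
    if ct.has_missing_replication():
        tables = impute_replication_timing(ct, k=k_imputations, seed=seed)
    else:
        tables = [ct]
    model = fit_null_model(tables, config=config, boundaries=boundaries, seed=seed)
    return model, ct


@dataclass
class ProbabilityIndex:
    """Per-position combo ids plus the combo x sample probability tensor."""

    position_index: pd.DataFrame  # usable positions: chrom, pos, combo_id
    P_combo: np.ndarray  # (n_combos, k, 4)
    sample_ids: list[str]
    factors: Optional[np.ndarray] = None  # per-window correction factors
    window_lookup: Optional[dict[tuple[str, int], int]] = None
    window_size: int = od.DEFAULT_WINDOW_SIZE

    def row_lookup(self) -> dict[tuple[str, int], int]:
        return {
            (c, int(p)): i
            for i, (c, p) in enumerate(
                zip(self.position_index["chrom"], self.position_index["pos"])
            )
        }


def predict_probability_index(
    model: NullModel, position_table: pd.DataFrame, sample_ids: Sequence[str]
) -> ProbabilityIndex:
    """Predict the 4-outcome probabilities for every realized combination."""
    pt = position_table[position_table["usable"]].reset_index(drop=True)
    combo_cols = list(POSITION_COVARIATES)
    combos = pt[combo_cols].drop_duplicates().reset_index(drop=True)
    combos["combo_id"] = np.arange(len(combos))
    merged = pt.merge(combos, on=combo_cols, how="left")
    sample_ids = list(sample_ids)
    k = len(sample_ids)
    rows = combos.loc[combos.index.repeat(k)].reset_index(drop=True)
    rows["sample"] = np.tile(sample_ids, len(combos))
    P = model.predict(rows).reshape(len(combos), k, 4)
    return ProbabilityIndex(
        position_index=merged[["chrom", "pos", "combo_id"]],
        P_combo=P,
        sample_ids=sample_ids,
    )


def fit_adjustment(
    index: ProbabilityIndex,
    mutations: Sequence[MutationRecord],
    window_size: int = od.DEFAULT_WINDOW_SIZE,
) -> tuple[od.OverdispersionModel, ProbabilityIndex]:
    """Estimate window-level overdispersion and attach correction factors.

    Windows pool positions and samples; observed counts come from the
    cohort's mutations, expectations from the predicted probabilities.
    """
    pi = index.position_index
    pmut_per_pos = index.P_combo[:, :, 1:].sum(axis=(1, 2))[pi["combo_id"].to_numpy()]
    win_keys = list(zip(pi["chrom"], pi["pos"].to_numpy() // window_size))
    uniq = sorted(set(win_keys))
    lookup = {wk: i for i, wk in enumerate(uniq)}
    widx = np.array([lookup[wk] for wk in win_keys])
    e_w = np.bincount(widx, weights=pmut_per_pos, minlength=len(uniq))
    exposures = np.bincount(widx, minlength=len(uniq)) * len(index.sample_ids)
    n_w = np.zeros(len(uniq))
    usable_pos = set(zip(pi["chrom"], pi["pos"].astype(int)))
    for m in mutations:
        wk = (m.chrom, m.pos // window_size)
        if wk in lookup and (m.chrom, m.pos) in usable_pos:
            n_w[lookup[wk]] += 1
    model = od.estimate_dispersion(n_w, e_w, exposures, window_size=window_size)
    factors = model.correction_factors(n_w, e_w, exposures)
    adjusted = ProbabilityIndex(
        position_index=index.position_index,
        P_combo=index.P_combo,
        sample_ids=index.sample_ids,
        factors=factors,
        window_lookup=lookup,
        window_size=window_size,
    )
    return model, adjusted


def _element_probabilities(index: ProbabilityIndex, rows: np.ndarray) -> np.ndarray:
    sub = index.position_index.iloc[rows]
    P = index.P_combo[sub["combo_id"].to_numpy()]
    if index.factors is None:
        return P
    widx = np.array(
        [
            index.window_lookup.get((c, int(p) // index.window_size), -1)
            for c, p in zip(sub["chrom"], sub["pos"])
        ]
    )
    pos_factors = np.where(widx >= 0, index.factors[np.maximum(widx, 0)], 1.0)
    adjusted = P.copy()
    adjusted[:, :, 1:] *= pos_factors[:, None, None]
    mut_total = adjusted[:, :, 1:].sum(axis=2)
    if (mut_total >= 1).any():
        raise ValueError("adjusted mutation probability >= 1")
    adjusted[:, :, 0] = 1.0 - mut_total
    return adjusted


def _element_scores(
    scheme: str,
    P: np.ndarray,
    chrom_pos: pd.DataFrame,
    phylop_track: Optional[GenomeTrack],
) -> ScoreMatrix:
    if scheme == "nmut":
        return scoring.score_nmut(P)
    if scheme == "loglik":
        return scoring.score_loglik(P)
    if scheme == "phylop":
        if phylop_track is None:
            raise ValueError("phylop scheme requires a conservation track")
        values = np.concatenate(
            [
                phylop_track.values_at(chrom, grp["pos"].to_numpy())
                for chrom, grp in chrom_pos.groupby("chrom", sort=False)
            ]
        )
        return scoring.score_phylop(values, P.shape[1])
    raise ValueError(f"unknown scheme {scheme!r}")


def run_detection(
    elements: Sequence[CandidateElement],
    index: ProbabilityIndex,
    mutations: Sequence[MutationRecord],
    scheme: str = "phylop",
    phylop_track: Optional[GenomeTrack] = None,
    fdr: float = 0.10,
    cap: Optional[int] = detect.EVENT_CAP,
    cost: Optional[detect.DPCost] = None,
) -> list[ElementTestResult]:
    """Significance-test every element and attach per-category q-values."""
    row_of = index.row_lookup()
    sample_index = {s: j for j, s in enumerate(index.sample_ids)}
    muts_by_pos: dict[tuple[str, int], list[tuple[str, int]]] = {}
    for m in mutations:
        _, outcome = collapse_mutation(m.ref, m.alt)
        muts_by_pos.setdefault((m.chrom, m.pos), []).append((m.sample_id, int(outcome)))

    raw = []
    for el in elements:
        rows, local_keys = [], []
        for chrom, pos in el.positions():
            key = (chrom, pos)
            if key in row_of:
                local_keys.append(key)
                rows.append(row_of[key])
        if not rows:
            raise ValueError(f"element {el.element_id} has zero usable positions")
        rows = np.asarray(rows)
        P = _element_probabilities(index, rows)
        chrom_pos = index.position_index.iloc[rows][["chrom", "pos"]]
        S = _element_scores(scheme, P, chrom_pos, phylop_track)
        observed = []
        for i, key in enumerate(local_keys):
            for sample_id, outcome in muts_by_pos.get(key, ()):
                if sample_id in sample_index:
                    observed.append((i, sample_index[sample_id], outcome))
        result = detect.test_element(P, S, observed, cap=cap, cost=cost)
        raw.append((el.element_id, el.element_type, el.length, result))
    return detect.finalize_results(raw, fdr=fdr)
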