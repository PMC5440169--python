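"""Explanatory variables for any genomic position and sample.

Implements the strand-symmetric outcome classing, trinucleotide context,
burden-normalized local mutation rate, segment assignment, quantile
binning of numeric tracks, and assembly of the covariate table.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .io import (
    ELEMENT_TYPES,
    CandidateElement,
    GenomeTrack,
    MutationRecord,
    ReferenceGenome,
    ValidationError,
    revcomp,
)


class OutcomeClass(IntEnum):
    """The four position outcomes of the strand-symmetric model."""

    NO_MUT = 0
    TS = 1          # A>G / G>A (and complements)
    TV_AT_GT = 2    # A>T / G>T
    TV_AC_GC = 3    # A>C / G>C


#: The three mutation outcomes, index-aligned with probability columns 1..3.
MUTATION_OUTCOMES = (OutcomeClass.TS, OutcomeClass.TV_AT_GT, OutcomeClass.TV_AC_GC)

#: The six collapsed substitution classes (weak bp reported as A, strong as G).
SIX_CLASSES = ("A>C", "A>G", "A>T", "G>T", "G>C", "G>A")

_CLASS_TO_OUTCOME = {
    "A>G": OutcomeClass.TS,
    "G>A": OutcomeClass.TS,
    "A>T": OutcomeClass.TV_AT_GT,
    "G>T": OutcomeClass.TV_AT_GT,
    "A>C": OutcomeClass.TV_AC_GC,
    "G>C": OutcomeClass.TV_AC_GC,
}

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: Factor levels of the segment covariate: the five element categories + 'other'.
SEGMENT_LEVELS = ELEMENT_TYPES + ("other",)

#: Central-base classes after strand collapsing: weak (A:T) and strong (G:C).
CENTRAL_LEVELS = ("A", "G")

#: The 16 flank-pair levels, 'AA' .. 'TT'.
FLANK_LEVELS = tuple(l + r for l in "ACGT" for r in "ACGT")

#: Numeric covariates are discretized into this many bins.
N_BINS = 5

# local mutation rate window geometry (bp)
SKIP_FLANK = 10_000
RATE_WINDOW = 20_000


def collapse_mutation(ref: str, alt: str) -> tuple[str, OutcomeClass]:
    """Collapse a substitution onto the six strand-symmetric classes.

    Pyrimidine references are reverse-complemented so the reported
    reference base is A (weak) or G (strong).
    """
    if ref not in "ACGT" or alt not in "ACGT":
        raise ValidationError(f"non-nucleotide substitution {ref!r}>{alt!r}")
    if ref == alt:
        raise ValidationError(f"ref == alt ({ref})")
    if ref in "CT":
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    label = f"{ref}>{alt}"
    return label, _CLASS_TO_OUTCOME[label]


# base -> code lookup over raw bytes; 255 marks non-ACGT
_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i
_COMP_CODE = np.array([3, 2, 1, 0], dtype=np.uint8)  # A<->T, C<->G

#: flank-pair string for code 4*left + right
_FLANK_BY_CODE = np.array([l + r for l in "ACGT" for r in "ACGT"], dtype=object)


def encode_trinucleotides(sequence: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized strand-collapsed context codes for a whole chromosome.

    Returns (central_code, flank_code, usable): central_code is 0 for weak
    (A:T) and 1 for strong (G:C) base pairs; flank_code indexes the 16
    flank-pair levels after strand collapsing; usable is False at edges and
    wherever the trinucleotide contains a non-ACGT base.
    """
    raw = np.frombuffer(sequence.encode(), dtype=np.uint8)
    code = _BASE_CODE[raw]
    n = code.size
    usable = np.zeros(n, dtype=bool)
    central_code = np.zeros(n, dtype=np.uint8)
    flank_code = np.zeros(n, dtype=np.uint8)
    if n < 3:
        return central_code, flank_code, usable
    c = code[1:-1]
    l = code[:-2]
    r = code[2:]
    ok = (c != 255) & (l != 255) & (r != 255)
    flip = ok & ((c == 1) | (c == 3))  # central C or T: reverse-complement
    cc = c.copy()
    ll = l.copy()
    rr = r.copy()
    cc[flip] = _COMP_CODE[c[flip]]
    ll[flip] = _COMP_CODE[r[flip]]
    rr[flip] = _COMP_CODE[l[flip]]
    usable[1:-1] = ok
    # after collapsing the central base is A (0) or G (2) -> classes 0/1
    central_code[1:-1] = np.where(cc == 2, 1, 0)
    flank_code[1:-1] = np.where(ok, ll * 4 + rr, 0)
    return central_code, flank_code, usable


def trinucleotide_context(
    genome: ReferenceGenome, chrom: str, pos: int
) -> Optional[tuple[str, str]]:
    """(central_class, flank_pair) at 0-based ``pos``; ``None`` when unusable.

    If the central base is a pyrimidine the whole trinucleotide is
    reverse-complemented before reading central class and flank pair, so
    exactly 2 x 16 combinations are possible.
    """
    if pos < 1 or pos + 1 >= genome.length(chrom):
        return None
    tri = genome.sequence(chrom, pos - 1, pos + 2)
    if len(tri) != 3 or any(b not in "ACGT" for b in tri):
        return None
    if tri[1] in "CT":
        tri = revcomp(tri)
    return tri[1], tri[0] + tri[2]


def local_mutation_rate(
    chrom: str,
    pos: int,
    mutations: Iterable[MutationRecord],
    sample_totals: Mapping[str, int],
) -> float:
    """Burden-normalized mutation density around ``pos``.

    The position and +/-10 kb around it are skipped; each sample's mutation
    count in the next 20 kb on either side is divided by that sample's
    total burden and the contributions are summed.
    """
    left_lo, left_hi = pos - SKIP_FLANK - RATE_WINDOW, pos - SKIP_FLANK  # [lo, hi)
    right_lo, right_hi = pos + SKIP_FLANK + 1, pos + SKIP_FLANK + RATE_WINDOW + 1  # [lo, hi)
    value = 0.0
    for m in mutations:
        if m.chrom != chrom:
            continue
        if left_lo <= m.pos < left_hi or right_lo <= m.pos < right_hi:
            value += 1.0 / sample_totals[m.sample_id]
    return value


def local_rate_array(
    chrom: str,
    chrom_length: int,
    mutations: Sequence[MutationRecord],
    sample_totals: Mapping[str, int],
) -> np.ndarray:
    """Vectorized local mutation rate for every position of a chromosome.

    Same window arithmetic as :func:`local_mutation_rate`, computed with a
    cumulative sum of burden-normalized mutation weights.
    """
    weights = np.zeros(chrom_length)
    for m in mutations:
        if m.chrom == chrom:
            weights[m.pos] += 1.0 / sample_totals[m.sample_id]
    cum = np.concatenate([[0.0], np.cumsum(weights)])  # cum[i] = sum of weights[:i]

    def window_sum(lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
        lo = np.clip(lo, 0, chrom_length)
        hi = np.clip(hi, 0, chrom_length)
        return cum[hi] - cum[lo]

    idx = np.arange(chrom_length)
    left = window_sum(idx - SKIP_FLANK - RATE_WINDOW, idx - SKIP_FLANK)
    right = window_sum(idx + SKIP_FLANK + 1, idx + SKIP_FLANK + RATE_WINDOW + 1)
    return left + right


def assign_segment(chrom: str, pos: int, elements: Sequence[CandidateElement]) -> str:
    """Element category covering ``pos``, else ``'other'``.

    ``elements`` must already be hierarchy-resolved (pairwise disjoint).
    """
    for el in elements:
        if el.contains(chrom, pos):
            return el.element_type
    return "other"


def segment_array(
    chrom: str, chrom_length: int, elements: Sequence[CandidateElement]
) -> np.ndarray:
    """Per-position segment level for a whole chromosome (object dtype)."""
    out = np.full(chrom_length, "other", dtype=object)
    for el in elements:
        for c, s, e in el.intervals:
            if c == chrom:
                out[max(s, 0) : min(e, chrom_length)] = el.element_type
    return out


def discretize(values: np.ndarray, n_bins: int = N_BINS) -> tuple[np.ndarray, np.ndarray]:
    """Quantile (equal-count) binning; returns (labels, boundaries).

    Boundaries sit at the interior quantiles of the non-missing values
    (20/40/60/80th percentiles for five bins). Labels are 1..n_bins with 0
    marking missing input. Boundaries must be persisted so prediction-time
    binning matches training time (:func:`apply_bins`).
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    values = np.asarray(values, dtype=float)
    observed = values[~np.isnan(values)]
    if observed.size == 0:
        raise ValueError("cannot discretize an all-missing track")
    qs = np.arange(1, n_bins) / n_bins
    boundaries = np.quantile(observed, qs)
    return apply_bins(values, boundaries), boundaries


def apply_bins(values: np.ndarray, boundaries: np.ndarray) -> np.ndarray:
    """Bin labels 1..len(boundaries)+1 using persisted boundaries; 0 = missing."""
    values = np.asarray(values, dtype=float)
    labels = np.zeros(values.shape, dtype=np.int64)
    ok = ~np.isnan(values)
    labels[ok] = np.searchsorted(boundaries, values[ok], side="left") + 1
    return labels


#: Covariate column names of the position-level table.
POSITION_COVARIATES = ("rep_bin", "central", "flanks", "segment", "expr_bin", "rate_bin")


@dataclass(frozen=True)
class CovariateVector:
    """The six explanatory-variable values for one (position, sample) pair.

    ``rep_bin`` may be 0, marking a missing replication-timing value that
    the model imputes downstream.
    """

    sample_id: str
    rep_bin: int
    central: str
    flanks: str
    segment: str
    expr_bin: int
    rate_bin: int

    def __post_init__(self) -> None:
        if self.central not in CENTRAL_LEVELS:
            raise ValidationError(f"central class {self.central!r} not in {CENTRAL_LEVELS}")
        if self.flanks not in FLANK_LEVELS:
            raise ValidationError(f"flank pair {self.flanks!r} invalid")
        if self.segment not in SEGMENT_LEVELS:
            raise ValidationError(f"segment {self.segment!r} not in {SEGMENT_LEVELS}")
        for name, value in (("rep_bin", self.rep_bin), ("expr_bin", self.expr_bin), ("rate_bin", self.rate_bin)):
            if not 0 <= value <= N_BINS:
                raise ValidationError(f"{name}={value} outside 0..{N_BINS}")


@dataclass
class BinBoundaries:
    """Persisted quantile boundaries fitted on the modelled positions."""

    replication: np.ndarray
    expression: np.ndarray
    local_rate: np.ndarray

    def to_dict(self) -> dict:
        return {
            "replication": self.replication.tolist(),
            "expression": self.expression.tolist(),
            "local_rate": self.local_rate.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BinBoundaries":
        return cls(
            np.asarray(d["replication"], dtype=float),
            np.asarray(d["expression"], dtype=float),
            np.asarray(d["local_rate"], dtype=float),
        )


def position_covariate_table(
    chrom: str,
    positions: np.ndarray,
    genome: ReferenceGenome,
    rep_track: GenomeTrack,
    expr_track: GenomeTrack,
    elements: Sequence[CandidateElement],
    mutations: Sequence[MutationRecord],
    boundaries: Optional[BinBoundaries] = None,
    intergenic_expression: float = 0.0,
) -> tuple[pd.DataFrame, BinBoundaries]:
    """Position-level covariates for one chromosome, vectorized.

    Returns a DataFrame indexed like ``positions`` with columns ``chrom``,
    ``pos``, ``usable`` and the position-level covariate factors. Rows with
    unreadable trinucleotide context are flagged unusable. When
    ``boundaries`` is None, quantile boundaries are fitted on these
    positions and returned for reuse at prediction time.

    Expression for positions outside any covered gene interval is set to
    ``intergenic_expression`` (default 0, the lowest bin) before binning.
    """
    positions = np.asarray(positions, dtype=np.int64)
    chrom_len = genome.length(chrom)

    seq = genome.sequence(chrom, 0, chrom_len)
    central_code, flank_code, usable_all = encode_trinucleotides(seq)
    tri_ok = usable_all[positions]
    central = np.where(tri_ok, np.array(CENTRAL_LEVELS, dtype=object)[central_code[positions]], "A")
    flanks = np.where(tri_ok, _FLANK_BY_CODE[flank_code[positions]], "AA")

    rep = rep_track.values_at(chrom, positions)
    expr = expr_track.values_at(chrom, positions)
    expr = np.where(np.isnan(expr), intergenic_expression, expr)

    sample_totals: dict[str, int] = {}
    for m in mutations:
        sample_totals[m.sample_id] = sample_totals.get(m.sample_id, 0) + 1
    rate_full = local_rate_array(chrom, chrom_len, mutations, sample_totals)
    rate = rate_full[positions]

    if boundaries is None:
        _, rep_b = discretize(rep) if np.any(~np.isnan(rep)) else (None, np.array([]))
        _, expr_b = discretize(expr)
        _, rate_b = discretize(rate)
        boundaries = BinBoundaries(rep_b, expr_b, rate_b)

    rep_bin = apply_bins(rep, boundaries.replication) if boundaries.replication.size else np.zeros(n, dtype=np.int64)
    df = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": positions,
            "usable": tri_ok,
            "rep_bin": rep_bin,
            "central": central,
            "flanks": flanks,
            "segment": segment_array(chrom, chrom_len, elements)[positions],
            "expr_bin": apply_bins(expr, boundaries.expression),
            "rate_bin": apply_bins(rate, boundaries.local_rate),
        }
    )
    return df, boundaries


def build_covariates(
    positions: Sequence[tuple[str, int]],
    sample_ids: Sequence[str],
    genome: ReferenceGenome,
    tracks: Mapping[str, GenomeTrack],
    elements: Sequence[CandidateElement],
    mutations: Sequence[MutationRecord],
    boundaries: Optional[BinBoundaries] = None,
) -> Iterator[tuple[tuple[str, int], str, Optional[CovariateVector]]]:
    """Stream one CovariateVector per (position, sample) pair.

    ``tracks`` must contain 'replication' and 'expression'. Unusable
    positions (N bases, chromosome edges) yield ``None`` vectors. This is
    the record-at-a-time facade over :func:`position_covariate_table`.
    """
    by_chrom: dict[str, list[int]] = {}
    for chrom, pos in positions:
        by_chrom.setdefault(chrom, []).append(pos)
    tables = []
    for chrom, plist in by_chrom.items():
        tbl, boundaries = position_covariate_table(
            chrom,
            np.asarray(sorted(set(plist))),
            genome,
            tracks["replication"],
            tracks["expression"],
            elements,
            mutations,
            boundaries=boundaries,
        )
        tables.append(tbl)
    lookup = {
        (row.chrom, row.pos): row
        for tbl in tables
        for row in tbl.itertuples(index=False)
    }
    for chrom, pos in positions:
        row = lookup[(chrom, pos)]
        for sample in sample_ids:
            if not row.usable:
                yield (chrom, pos), sample, None
            else:
                yield (chrom, pos), sample, CovariateVector(
                    sample_id=sample,
                    rep_bin=int(row.rep_bin),
                    central=row.central,
                    flanks=row.flanks,
                    segment=row.segment,
                    expr_bin=int(row.expr_bin),
                    rate_bin=int(row.rate_bin),
                )
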