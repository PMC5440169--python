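"""Candidate element derivation from transcript annotations.

Five categories are built per transcript, collapsed per gene, and resolved
through the hierarchy protein_coding > splice_site > utr3 > utr5 > promoter
so that every base pair belongs to at most one category.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import pandas as pd

from .io import ELEMENT_TYPES, CandidateElement

#: Half-width of promoter regions around the TSS (bp in either direction).
PROMOTER_FLANK = 500

#: Intronic bases taken on either side of internal exons.
SPLICE_SITE_WIDTH = 2


def merge_intervals(intervals: Iterable[tuple[str, int, int]]) -> list[tuple[str, int, int]]:
    """Union of possibly-overlapping intervals, per chromosome."""
    out: list[tuple[str, int, int]] = []
    for chrom, start, end in sorted(intervals):
        if out and out[-1][0] == chrom and start <= out[-1][2]:
            prev = out.pop()
            out.append((chrom, prev[1], max(prev[2], end)))
        else:
            out.append((chrom, start, end))
    return out


def subtract_intervals(
    intervals: Sequence[tuple[str, int, int]], mask: Sequence[tuple[str, int, int]]
) -> list[tuple[str, int, int]]:
    """Remove every bp of ``mask`` from ``intervals`` (both merged, sorted)."""
    out = []
    for chrom, start, end in intervals:
        cuts = [(s, e) for c, s, e in mask if c == chrom and s < end and e > start]
        cursor = start
        for s, e in sorted(cuts):
            if s > cursor:
                out.append((chrom, cursor, min(s, end)))
            cursor = max(cursor, e)
            if cursor >= end:
                break
        if cursor < end:
            out.append((chrom, cursor, end))
    return out


def _transcript_regions(tx: pd.DataFrame) -> dict[str, list[tuple[str, int, int]]]:
    """Raw (pre-hierarchy) regions of one transcript, keyed by category."""
    exons = tx[tx["feature"] == "exon"].sort_values("start")
    if len(exons) < 1:
        raise ValueError(f"transcript {tx['transcript'].iloc[0]!r} has no exons")
    chrom = tx["chrom"].iloc[0]
    strand = tx["strand"].iloc[0]
    regions: dict[str, list[tuple[str, int, int]]] = {t: [] for t in ELEMENT_TYPES}

    for feature, key in (("CDS", "protein_coding"), ("UTR3", "utr3"), ("UTR5", "utr5")):
        for _, row in tx[tx["feature"] == feature].iterrows():
            regions[key].append((chrom, int(row["start"]), int(row["end"])))

    # Promoter: PROMOTER_FLANK bp in either direction from the TSS,
    # inclusive of the TSS base itself; strand-aware; clipped at 0.
    if strand == "-":
        tss = int(exons["end"].max()) - 1
    else:
        tss = int(exons["start"].min())
    regions["promoter"].append((chrom, max(tss - PROMOTER_FLANK, 0), tss + PROMOTER_FLANK + 1))

    # Splice sites: the two intronic bases on either side of internal exons
    # (exons that are neither first nor last in the transcript).
    starts = exons["start"].astype(int).tolist()
    ends = exons["end"].astype(int).tolist()
    for i in range(1, len(starts) - 1):
        regions["splice_site"].append((chrom, starts[i] - SPLICE_SITE_WIDTH, starts[i]))
        regions["splice_site"].append((chrom, ends[i], ends[i] + SPLICE_SITE_WIDTH))
    return regions


def define_candidate_elements(transcripts: pd.DataFrame) -> list[CandidateElement]:
    """Derive hierarchy-resolved candidate elements from a transcript table.

    Regions are defined per transcript, collapsed per gene (interval union
    within each category), and then resolved across categories so a bp kept
    in a higher-ranked category is dropped from all lower-ranked ones.
    """
    per_gene: dict[str, dict[str, list[tuple[str, int, int]]]] = {}
    for (gene, _), tx in transcripts.groupby(["gene", "transcript"], sort=True):
        regions = _transcript_regions(tx)
        bucket = per_gene.setdefault(gene, {t: [] for t in ELEMENT_TYPES})
        for key, ivs in regions.items():
            bucket[key].extend(ivs)

    collapsed: dict[str, dict[str, list[tuple[str, int, int]]]] = {
        gene: {key: merge_intervals(ivs) for key, ivs in cats.items()}
        for gene, cats in per_gene.items()
    }

    # Cross-gene hierarchy: a bp in >=2 categories (from any gene) survives
    # only in the highest-ranked one.
    category_union = {
        key: merge_intervals(iv for cats in collapsed.values() for iv in cats[key])
        for key in ELEMENT_TYPES
    }
    out: list[CandidateElement] = []
    for gene in sorted(collapsed):
        for rank, key in enumerate(ELEMENT_TYPES):
            ivs = collapsed[gene][key]
            for higher in ELEMENT_TYPES[:rank]:
                ivs = subtract_intervals(ivs, category_union[higher])
            if ivs:
                out.append(CandidateElement(f"{gene}:{key}", gene, key, ivs))
    return out


def filter_elements(
    elements: Iterable[CandidateElement], exclude_chroms: set[str]
) -> list[CandidateElement]:
    """Drop elements with any interval on an excluded chromosome."""
    return [el for el in elements if not (el.chroms & set(exclude_chroms))]
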