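"""Mutational-signature statistics: the uracil-DNA-glycosylase (UDG)
deficiency signature and Fisher's-method p-value combination.

Counting is materialized over the 192 strand-specific context-resolved
substitution categories (4 left flanks x 4 reference bases x 4 right
flanks x 3 alternate bases); the signature reads off the relevant cells.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import scipy.stats

from .io import MutationRecord, ReferenceGenome


def mutation_context_categories() -> list[tuple[str, str, str, str]]:
    """All strand-specific (left, ref, right, alt) point-mutation categories."""
    cats = []
    for left in "ACGT":
        for ref in "ACGT":
            for right in "ACGT":
                for alt in "ACGT":
                    if alt != ref:
                        cats.append((left, ref, right, alt))
    return cats


@dataclass(frozen=True)
class ContextMutation:
    """A mutation with its immediate reference flanks (strand-specific)."""

    sample_id: str
    left: str
    ref: str
    right: str
    alt: str


def with_context(
    mutations: Sequence[MutationRecord], genome: ReferenceGenome
) -> list[ContextMutation]:
    """Annotate mutations with their 5'/3' reference flanks."""
    out = []
    for m in mutations:
        left = genome.sequence(m.chrom, m.pos - 1, m.pos) or "N"
        right = genome.sequence(m.chrom, m.pos + 1, m.pos + 2) or "N"
        out.append(ContextMutation(m.sample_id, left, m.ref, right, m.alt))
    return out


def count_context_categories(mutations: Sequence[ContextMutation]) -> dict[tuple, int]:
    """Counts over the 192 categories (flanks must be unambiguous)."""
    counts = {cat: 0 for cat in mutation_context_categories()}
    for m in mutations:
        key = (m.left, m.ref, m.right, m.alt)
        if key in counts:
            counts[key] += 1
    return counts


@dataclass
class SignatureResult:
    """Per-sample UDG deficiency signature value."""

    sample_id: str
    n_total_mutations: int
    n_qualifying: int

    @property
    def statistic(self) -> float:
        return self.n_qualifying / self.n_total_mutations


def _qualifies(m: ContextMutation, melanoma: bool, melanoma_mode: str) -> bool:
    # qualifying event: G>A on either strand representation
    if m.ref == "G" and m.alt == "A":
        if m.left == "C":  # CpG on the opposite strand
            return False
        if melanoma and melanoma_mode == "cc_context" and m.right == "G":
            return False  # reverse complement of C>T with 5' C neighbour
        return True
    if m.ref == "C" and m.alt == "T":
        if m.right == "G":  # CpG site
            return False
        if melanoma and melanoma_mode == "cc_context" and m.left == "C":
            return False  # C>T in a CC context (UV signature)
        return True
    return False


def udg_signature(
    mutations: Sequence[ContextMutation],
    is_melanoma: bool = False,
    melanoma_mode: str = "cc_context",
    sample_id: Optional[str] = None,
) -> SignatureResult:
    """Proportion of G>A (including C>T) mutations outside CpG sites.

    For melanoma samples, C>T mutations in a CC context (or its reverse
    complement) are additionally excluded as UV-induced
    (``melanoma_mode='cc_context'``, default).  ``melanoma_mode='cc_tt_pairs'``
    instead excludes only mutations that are part of adjacent same-sample
    CC>TT dinucleotide events.
    """
    mutations = list(mutations)
    if not mutations:
        raise ValueError("signature statistic undefined for zero mutations")
    if melanoma_mode not in ("cc_context", "cc_tt_pairs"):
        raise ValueError(f"unknown melanoma_mode {melanoma_mode!r}")
    sid = sample_id if sample_id is not None else mutations[0].sample_id
    n_qual = sum(1 for m in mutations if _qualifies(m, is_melanoma, melanoma_mode))
    return SignatureResult(sid, len(mutations), n_qual)


def udg_signature_cc_tt(
    mutations: Sequence[MutationRecord],
    genome: ReferenceGenome,
    is_melanoma: bool = False,
    sample_id: Optional[str] = None,
) -> SignatureResult:
    """UDG signature with melanoma exclusion of adjacent CC>TT pair events.

    Detects same-sample C>T mutations at adjacent positions (or the G>A
    reverse complement) and excludes both partners for melanoma samples.
    """
    ctx = with_context(mutations, genome)
    if not ctx:
        raise ValueError("signature statistic undefined for zero mutations")
    positions = {(m.chrom, m.pos, m.ref, m.alt) for m in mutations}
    in_pair = set()
    if is_melanoma:
        for m in mutations:
            if m.ref == "C" and m.alt == "T":
                if (m.chrom, m.pos + 1, "C", "T") in positions:
                    in_pair.add((m.chrom, m.pos))
                    in_pair.add((m.chrom, m.pos + 1))
            if m.ref == "G" and m.alt == "A":
                if (m.chrom, m.pos - 1, "G", "A") in positions:
                    in_pair.add((m.chrom, m.pos))
                    in_pair.add((m.chrom, m.pos - 1))
    sid = sample_id if sample_id is not None else mutations[0].sample_id
    n_qual = 0
    for rec, m in zip(mutations, ctx):
        if (rec.chrom, rec.pos) in in_pair:
            continue
        if _qualifies(m, melanoma=False, melanoma_mode="cc_context"):
            n_qual += 1
    return SignatureResult(sid, len(mutations), n_qual)


def fisher_combine(p_values: Sequence[float]) -> float:
    """Fisher's method: X = -2 sum(ln p) against chi-square with 2k df."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to combine")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    stat = -2.0 * np.log(p).sum()
    return float(scipy.stats.chi2.sf(stat, df=2 * p.size))
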