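"""Core records and readers/writers for the standard formats the pipeline touches.

All internal coordinates are 0-based half-open; user-facing mutation
positions in TSV files are 1-based.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

NUCLEOTIDES = frozenset("ACGT")

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: Element categories in hierarchy order (highest priority first).
ELEMENT_TYPES = ("protein_coding", "splice_site", "utr3", "utr5", "promoter")


class ParseError(ValueError):
    """Malformed input file; message names the offending line."""


class ValidationError(ValueError):
    """Record-level constraint violation (non-ACGT base, ref==alt, genome mismatch)."""


def revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


@dataclass(frozen=True)
class MutationRecord:
    """One somatic point mutation. ``pos`` is internal, 0-based."""

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    cancer_type: Optional[str] = None

    def __post_init__(self) -> None:
        if self.ref not in NUCLEOTIDES or self.alt not in NUCLEOTIDES:
            raise ValidationError(
                f"non-ACGT allele {self.ref}>{self.alt} at {self.chrom}:{self.pos + 1}"
            )
        if self.ref == self.alt:
            raise ValidationError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos + 1}")


class ReferenceGenome:
    """Minimal random-access reference. Wraps a chrom -> sequence mapping.

    Use :meth:`from_fasta` for FASTA files (via pyfaidx); plain dicts are
    accepted directly, which keeps tests free of temp files.
    """

    def __init__(self, sequences: Mapping[str, str]):
        self._seqs = sequences

    @classmethod
    def from_fasta(cls, path: str | os.PathLike) -> "ReferenceGenome":
        from pyfaidx import Fasta

        return cls(_FaidxAdapter(Fasta(str(path), sequence_always_upper=True)))

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def chroms(self) -> list[str]:
        return list(self._seqs.keys())

    def length(self, chrom: str) -> int:
        return len(self._seqs[chrom])

    def base(self, chrom: str, pos: int) -> str:
        """Upper-case base at 0-based ``pos``."""
        return str(self._seqs[chrom][pos]).upper()

    def sequence(self, chrom: str, start: int, end: int) -> str:
        """Upper-case sequence on [start, end), clipped to the chromosome."""
        start = max(start, 0)
        end = min(end, self.length(chrom))
        if end <= start:
            return ""
        return str(self._seqs[chrom][start:end]).upper()


class _FaidxAdapter:
    def __init__(self, fasta):
        self._fasta = fasta

    def __contains__(self, chrom):
        return chrom in self._fasta

    def __getitem__(self, chrom):
        return self._fasta[chrom]

    def keys(self):
        return self._fasta.keys()


MUTATION_COLUMNS = ("sample", "chrom", "pos", "ref", "alt")


def read_mutations(
    path: str | os.PathLike, genome: Optional[ReferenceGenome] = None
) -> list[MutationRecord]:
    """Read a MAF-like mutation TSV.

    Expected header columns: sample, chrom, pos, ref, alt [, cancer_type];
    ``pos`` is 1-based and converted to the internal 0-based convention.
    When ``genome`` is given, every ref allele is checked against it.
    """
    records: list[MutationRecord] = []
    with open(path) as fh:
        header_line = fh.readline()
        if not header_line:
            raise ParseError(f"{path}: empty file, expected a header line")
        header = header_line.rstrip("\n").split("\t")
        missing = [c for c in MUTATION_COLUMNS if c not in header]
        if missing:
            raise ParseError(f"{path}: header lacks required columns {missing}")
        idx = {c: header.index(c) for c in header}
        has_ct = "cancer_type" in idx
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(header):
                raise ParseError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(fields)}"
                )
            try:
                pos1 = int(fields[idx["pos"]])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer position") from exc
            if pos1 < 1:
                raise ParseError(f"{path}:{lineno}: position must be >= 1 (1-based)")
            rec = MutationRecord(
                sample_id=fields[idx["sample"]],
                chrom=fields[idx["chrom"]],
                pos=pos1 - 1,
                ref=fields[idx["ref"]].upper(),
                alt=fields[idx["alt"]].upper(),
                cancer_type=fields[idx["cancer_type"]] if has_ct else None,
            )
            if genome is not None:
                actual = genome.base(rec.chrom, rec.pos)
                if actual != rec.ref:
                    raise ValidationError(
                        f"{path}:{lineno}: ref {rec.ref} does not match genome "
                        f"base {actual} at {rec.chrom}:{pos1}"
                    )
            records.append(rec)
    return records


def write_mutations(records: Iterable[MutationRecord], path: str | os.PathLike) -> None:
    """Write mutations as the MAF-like TSV read by :func:`read_mutations`."""
    records = list(records)
    has_ct = any(r.cancer_type is not None for r in records)
    cols = list(MUTATION_COLUMNS) + (["cancer_type"] if has_ct else [])
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in records:
            row = [r.sample_id, r.chrom, str(r.pos + 1), r.ref, r.alt]
            if has_ct:
                row.append(r.cancer_type or "")
            fh.write("\t".join(row) + "\n")


class GenomeTrack:
    """Numeric genome track with interval resolution and first-class missingness.

    Queries outside covered intervals (or on unknown chromosomes) return NaN.
    """

    def __init__(self, intervals: Mapping[str, tuple[np.ndarray, np.ndarray, np.ndarray]]):
        # chrom -> (starts, ends, values); starts sorted, intervals non-overlapping
        self._data = {}
        for chrom, (starts, ends, values) in intervals.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            values = np.asarray(values, dtype=float)
            order = np.argsort(starts, kind="stable")
            starts, ends, values = starts[order], ends[order], values[order]
            if np.any(starts[1:] < ends[:-1]):
                raise ParseError(f"overlapping intervals on {chrom}")
            self._data[chrom] = (starts, ends, values)

    @classmethod
    def from_bedgraph(cls, path: str | os.PathLike) -> "GenomeTrack":
        """Standard bedGraph: chrom, start, end, value (0-based half-open)."""
        per_chrom: dict[str, list[tuple[int, int, float]]] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith(("track", "#", "browser")):
                    continue
                fields = line.split()
                if len(fields) < 4:
                    raise ParseError(f"{path}:{lineno}: expected 4 bedGraph fields")
                chrom, start, end, value = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
                per_chrom.setdefault(chrom, []).append((start, end, value))
        return cls(
            {
                chrom: (
                    np.array([r[0] for r in rows]),
                    np.array([r[1] for r in rows]),
                    np.array([r[2] for r in rows]),
                )
                for chrom, rows in per_chrom.items()
            }
        )

    @classmethod
    def from_fixedstep(cls, path: str | os.PathLike) -> "GenomeTrack":
        """Wiggle fixedStep blocks (1-based start; span defaults to 1)."""
        per_chrom: dict[str, list[tuple[int, int, float]]] = {}
        chrom = None
        pos = step = span = None
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith(("track", "#")):
                    continue
                if line.startswith("fixedStep"):
                    params = dict(kv.split("=") for kv in line.split()[1:])
                    chrom = params["chrom"]
                    pos = int(params["start"]) - 1  # to 0-based
                    step = int(params.get("step", 1))
                    span = int(params.get("span", 1))
                    continue
                if chrom is None:
                    raise ParseError(f"{path}:{lineno}: data before fixedStep declaration")
                per_chrom.setdefault(chrom, []).append((pos, pos + span, float(line)))
                pos += step
        return cls(
            {
                c: (
                    np.array([r[0] for r in rows]),
                    np.array([r[1] for r in rows]),
                    np.array([r[2] for r in rows]),
                )
                for c, rows in per_chrom.items()
            }
        )

    def to_bedgraph(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            for chrom, (starts, ends, values) in self._data.items():
                for s, e, v in zip(starts, ends, values):
                    fh.write(f"{chrom}\t{s}\t{e}\t{float(v)!r}\n")

    def value_at(self, chrom: str, pos: int) -> float:
        """Value covering 0-based ``pos``, or NaN when uncovered/unknown."""
        if chrom not in self._data:
            return float("nan")
        starts, ends, values = self._data[chrom]
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        if i >= 0 and pos < ends[i]:
            return float(values[i])
        return float("nan")

    def values_at(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Vectorized :meth:`value_at`; NaN where uncovered."""
        positions = np.asarray(positions, dtype=np.int64)
        out = np.full(positions.shape, np.nan)
        if chrom not in self._data:
            return out
        starts, ends, values = self._data[chrom]
        idx = np.searchsorted(starts, positions, side="right") - 1
        ok = idx >= 0
        hit = np.zeros_like(ok)
        hit[ok] = positions[ok] < ends[idx[ok]]
        out[hit] = values[idx[hit]]
        return out


@dataclass
class CandidateElement:
    """A candidate driver element: one or more genomic intervals of one category."""

    element_id: str
    gene: str
    element_type: str
    intervals: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.element_type not in ELEMENT_TYPES:
            raise ValidationError(f"unknown element type {self.element_type!r}")
        self.intervals = sorted(self.intervals)
        for (c1, s1, e1), (c2, s2, e2) in zip(self.intervals, self.intervals[1:]):
            if c1 == c2 and s2 < e1:
                raise ValidationError(f"{self.element_id}: overlapping intervals")
        if self.length < 1:
            raise ValidationError(f"{self.element_id}: empty element")

    @property
    def length(self) -> int:
        return sum(e - s for _, s, e in self.intervals)

    @property
    def chroms(self) -> set[str]:
        return {c for c, _, _ in self.intervals}

    def positions(self) -> Iterator[tuple[str, int]]:
        for chrom, start, end in self.intervals:
            for pos in range(start, end):
                yield chrom, pos

    def contains(self, chrom: str, pos: int) -> bool:
        return any(c == chrom and s <= pos < e for c, s, e in self.intervals)


def write_elements_bed(elements: Iterable[CandidateElement], path: str | os.PathLike) -> None:
    """BED-style TSV: chrom, start, end, element_id, element_type, gene."""
    with open(path, "w") as fh:
        for el in elements:
            for chrom, start, end in el.intervals:
                fh.write(f"{chrom}\t{start}\t{end}\t{el.element_id}\t{el.element_type}\t{el.gene}\n")


def read_elements_bed(path: str | os.PathLike) -> list[CandidateElement]:
    """Read the extended BED written by :func:`write_elements_bed`.

    Plain 4-column BED is accepted: the name field becomes the element id
    and gene, and the element type defaults to ``protein_coding``.
    """
    grouped: dict[str, CandidateElement] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: expected >= 4 BED fields")
            chrom, start, end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
            etype = fields[4] if len(fields) > 4 else "protein_coding"
            gene = fields[5] if len(fields) > 5 else name
            if name in grouped:
                grouped[name].intervals.append((chrom, start, end))
                grouped[name].intervals.sort()
            else:
                grouped[name] = CandidateElement(name, gene, etype, [(chrom, start, end)])
    return list(grouped.values())


TRANSCRIPT_COLUMNS = ("gene", "transcript", "chrom", "strand", "feature", "start", "end")

#: Recognized feature flags in the transcript table.
TRANSCRIPT_FEATURES = ("exon", "CDS", "UTR5", "UTR3")


def read_transcripts(path: str | os.PathLike) -> pd.DataFrame:
    """Read a GTF-like transcript table.

    TSV columns: gene, transcript, chrom, strand (+/-), feature
    (exon/CDS/UTR5/UTR3), start, end (0-based half-open).
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "transcript": str, "chrom": str})
    missing = [c for c in TRANSCRIPT_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: transcript table lacks columns {missing}")
    bad = ~df["feature"].isin(TRANSCRIPT_FEATURES)
    if bad.any():
        raise ParseError(f"{path}: unknown feature values {sorted(df.loc[bad, 'feature'].unique())}")
    return df


def write_transcripts(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index=False)


@dataclass
class ElementTestResult:
    """Per-element outcome of the significance test."""

    element_id: str
    element_type: str
    length_bp: int
    n_mut_observed: int
    n_mut_expected: float
    observed_score: int
    p_value: float
    q_value: float = float("nan")


RESULT_COLUMNS = (
    "element_id",
    "element_type",
    "length_bp",
    "n_mutations_observed",
    "n_mutations_expected",
    "observed_score",
    "p_value",
    "q_value",
)


def write_results(results: Sequence[ElementTestResult], path: str | os.PathLike) -> None:
    """Results TSV, deterministically ordered by (p_value, element_id)."""
    rows = sorted(results, key=lambda r: (r.p_value, r.element_id))
    with open(path, "w") as fh:
        fh.write("\t".join(RESULT_COLUMNS) + "\n")
        for r in rows:
            fh.write(
                f"{r.element_id}\t{r.element_type}\t{r.length_bp}\t{r.n_mut_observed}\t"
                f"{r.n_mut_expected!r}\t{r.observed_score}\t{r.p_value!r}\t{r.q_value!r}\n"
            )


def read_results(path: str | os.PathLike) -> list[ElementTestResult]:
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != RESULT_COLUMNS:
            raise ParseError(f"{path}: unexpected results header {header}")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            out.append(
                ElementTestResult(
                    element_id=f[0],
                    element_type=f[1],
                    length_bp=int(f[2]),
                    n_mut_observed=int(f[3]),
                    n_mut_expected=float(f[4]),
                    observed_score=int(f[5]),
                    p_value=float(f[6]),
                    q_value=float(f[7]),
                )
            )
    return out


def read_mutations_vcf(path: str | os.PathLike, sample_id: str) -> list[MutationRecord]:
    """Thin single-sample VCF adapter: SNVs only, multi-allelic sites split."""
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 5:
                raise ParseError(f"{path}:{lineno}: expected >= 5 VCF fields")
            chrom, pos1, _, ref, alts = fields[0], int(fields[1]), fields[2], fields[3], fields[4]
            if len(ref) != 1:
                continue
            for alt in alts.split(","):
                if len(alt) == 1 and alt in NUCLEOTIDES and ref in NUCLEOTIDES:
                    records.append(MutationRecord(sample_id, chrom, pos1 - 1, ref, alt))
    return records
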