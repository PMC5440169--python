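"""Synthetic cohort generator: genome, tracks, transcripts, mutations and
optional spiked driver elements with the statistical structure the
background model assumes, so the whole pipeline is testable offline.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .elements import define_candidate_elements
from .io import CandidateElement, GenomeTrack, MutationRecord, ReferenceGenome

#: alt allele for (ref base, outcome code 1..3), consistent with the
#: strand-symmetric collapse.
ALT_TABLE = {
    ("A", 1): "G", ("A", 2): "T", ("A", 3): "C",
    ("G", 1): "A", ("G", 2): "T", ("G", 3): "C",
    ("T", 1): "C", ("T", 2): "A", ("T", 3): "G",
    ("C", 1): "T", ("C", 2): "A", ("C", 3): "G",
}


@dataclass
class SimulationConfig:
    """Knobs of the synthetic cohort; ``seed`` is mandatory.

    The default desk-scale configuration (2 Mb genome, 50 samples,
    ~20 mutations/Mb/sample) runs in minutes on one CPU.  Per-sample
    burdens are log-normal; the default sigma reproduces a mean/median
    burden ratio of about four, mimicking heavily skewed real cohorts.
    """

    seed: int
    chrom_lengths: dict[str, int] = field(default_factory=lambda: {"chr1": 2_000_000})
    n_samples: int = 50
    n_cancer_types: int = 3
    gc_content: float = 0.41
    n_genes: int = 40
    mutations_per_mb: float = 20.0
    burden_sigma: float = 1.67
    outcome_weights: tuple[float, float, float] = (0.5, 0.25, 0.25)
    central_effect: float = 0.4  # strong (G:C) vs weak log-odds shift
    flank_sigma: float = 0.3  # sd of per-flank-pair log-odds effects
    rep_slope: float = 1.0  # log-odds per unit replication timing
    segment_effects: dict[str, float] = field(default_factory=lambda: {"other": 0.25})
    overdispersion: float = 0.0  # variance of window-level rate multipliers
    window_size: int = 100_000
    rep_missing_fraction: float = 0.0
    drivers: tuple[tuple[str, float], ...] = ()

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.n_samples < 1:
            raise ValueError("need at least one sample")
        if any(l <= 0 for l in self.chrom_lengths.values()):
            raise ValueError("zero-length genome")
        if any(f < 1 for _, f in self.drivers):
            raise ValueError("driver spike factors must be >= 1")
        self.outcome_weights = tuple(float(w) for w in self.outcome_weights)
        self.drivers = tuple((str(e), float(f)) for e, f in self.drivers)
        self.chrom_lengths = {str(c): int(l) for c, l in self.chrom_lengths.items()}

    @property
    def sample_ids(self) -> list[str]:
        return [f"S{i:03d}" for i in range(self.n_samples)]

    def cancer_type(self, sample_index: int) -> str:
        return f"CT{sample_index % self.n_cancer_types + 1}"

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "drivers" in raw:
            raw["drivers"] = tuple((str(e), float(f)) for e, f in raw["drivers"])
        return cls(**raw)

    def to_yaml(self, path: str | os.PathLike) -> None:
        raw = asdict(self)
        raw["drivers"] = [list(d) for d in self.drivers]
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh)


@dataclass
class ReferenceBundle:
    """Everything the pipeline reads: genome, tracks and transcript table."""

    genome: ReferenceGenome
    rep_track: GenomeTrack
    expr_track: GenomeTrack
    phylop: dict[str, np.ndarray]
    transcripts: pd.DataFrame

    def elements(self) -> list[CandidateElement]:
        return define_candidate_elements(self.transcripts)

    def phylop_track(self) -> GenomeTrack:
        return GenomeTrack(
            {
                chrom: (np.arange(v.size), np.arange(v.size) + 1, v)
                for chrom, v in self.phylop.items()
            }
        )


def _simulate_gene_rows(gene_id: str, chrom: str, start: int, strand: str) -> list[dict]:
    """One three-exon transcript yielding all five element categories."""
    e1, e2, e3 = (start, start + 200), (start + 500, start + 800), (start + 1100, start + 1400)
    if strand == "+":
        utr5, cds1, utr3 = (e1[0], e1[0] + 150), (e1[0] + 150, e1[1]), (e3[0] + 50, e3[1])
        cds3 = (e3[0], e3[0] + 50)
    else:
        utr3, cds1, utr5 = (e1[0], e1[0] + 150), (e1[0] + 150, e1[1]), (e3[0] + 50, e3[1])
        cds3 = (e3[0], e3[0] + 50)
    tx = f"{gene_id}.t1"
    rows = []
    for s, e in (e1, e2, e3):
        rows.append(dict(gene=gene_id, transcript=tx, chrom=chrom, strand=strand, feature="exon", start=s, end=e))
    for s, e in (cds1, e2, cds3):
        rows.append(dict(gene=gene_id, transcript=tx, chrom=chrom, strand=strand, feature="CDS", start=s, end=e))
    rows.append(dict(gene=gene_id, transcript=tx, chrom=chrom, strand=strand, feature="UTR5", start=utr5[0], end=utr5[1]))
    rows.append(dict(gene=gene_id, transcript=tx, chrom=chrom, strand=strand, feature="UTR3", start=utr3[0], end=utr3[1]))
    return rows


def simulate_reference(config: SimulationConfig) -> ReferenceBundle:
    """Random genome, smooth tracks and a transcript table (deterministic
    for a fixed seed)."""
    rng = np.random.default_rng(config.seed)
    genome_seqs: dict[str, str] = {}
    rep_intervals: dict[str, tuple] = {}
    phylop: dict[str, np.ndarray] = {}
    tx_rows: list[dict] = []
    gene_counter = 0
    for chrom, length in config.chrom_lengths.items():
        p_gc = config.gc_content / 2
        p_at = (1 - config.gc_content) / 2
        bases = rng.choice(np.array(list("ACGT")), size=length, p=[p_at, p_gc, p_gc, p_at])
        genome_seqs[chrom] = "".join(bases)

        n_win = (length + config.window_size - 1) // config.window_size
        centers = (np.arange(n_win) + 0.5) / n_win
        values = np.clip(
            0.5 + 0.4 * np.sin(2 * np.pi * 2 * centers) + rng.normal(0, 0.05, n_win), 0.0, 1.0
        )
        keep = rng.random(n_win) >= config.rep_missing_fraction
        if not keep.any():
            keep[0] = True
        starts = np.arange(n_win) * config.window_size
        ends = np.minimum(starts + config.window_size, length)
        rep_intervals[chrom] = (starts[keep], ends[keep], values[keep])

        phylop[chrom] = np.clip(rng.normal(0.3, 1.2, size=length), -5.0, 8.0)

        margin = min(20_000, length // 10)
        span = 1400 + 600  # gene body + promoter clearance
        n_here = max(int(round(config.n_genes * length / sum(config.chrom_lengths.values()))), 1)
        spacing = max((length - 2 * margin) // n_here, span + 200)
        for i in range(n_here):
            start = margin + i * spacing
            if start + span > length - margin:
                break
            gene_counter += 1
            strand = "+" if gene_counter % 2 else "-"
            tx_rows.extend(_simulate_gene_rows(f"G{gene_counter:04d}", chrom, start, strand))

    transcripts = pd.DataFrame(tx_rows)
    expr_intervals = {}
    gene_values = {
        gene: float(np.log2(1.0 + rng.lognormal(4.0, 2.0)))
        for gene in sorted(transcripts["gene"].unique())
    }
    for chrom in config.chrom_lengths:
        sub = transcripts[(transcripts["chrom"] == chrom) & (transcripts["feature"] == "exon")]
        spans = sub.groupby("gene").agg(start=("start", "min"), end=("end", "max"))
        expr_intervals[chrom] = (
            spans["start"].to_numpy(),
            spans["end"].to_numpy(),
            np.array([gene_values[g] for g in spans.index]),
        )
    return ReferenceBundle(
        genome=ReferenceGenome(genome_seqs),
        rep_track=GenomeTrack(rep_intervals),
        expr_track=GenomeTrack(expr_intervals),
        phylop=phylop,
        transcripts=transcripts,
    )


def _position_logits(
    config: SimulationConfig,
    bundle: ReferenceBundle,
    chrom: str,
    elements: Sequence[CandidateElement],
    flank_effects: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """(usable mask, per-position log rate-multiplier) for one chromosome."""
    from .annotate import encode_trinucleotides, segment_array

    length = bundle.genome.length(chrom)
    central_code, flank_code, usable = encode_trinucleotides(bundle.genome.sequence(chrom, 0, length))
    rep = bundle.rep_track.values_at(chrom, np.arange(length))
    rep_filled = np.where(np.isnan(rep), 0.5, rep)
    eta = np.zeros(length)
    eta += np.where(central_code == 1, config.central_effect, 0.0)
    eta += flank_effects[flank_code]
    eta += config.rep_slope * (rep_filled - 0.5)
    seg = segment_array(chrom, length, elements)
    for name, effect in config.segment_effects.items():
        eta += np.where(seg == name, effect, 0.0)
    return usable, eta


def simulate_mutations(
    config: SimulationConfig,
    bundle: ReferenceBundle,
    elements: Optional[Sequence[CandidateElement]] = None,
) -> list[MutationRecord]:
    """Draw somatic mutations from the generative 4-outcome model.

    For each (position, sample) the outcome is multinomial with mutation
    probabilities built from the config's covariate effects, the sample's
    log-normal burden multiplier, a shared window-level rate multiplier
    when ``overdispersion`` > 0, and the driver spike factors.
    """
    rng = np.random.default_rng(config.seed + 1)
    if elements is None:
        elements = bundle.elements()
    driver_map = dict(config.drivers)
    unknown = set(driver_map) - {el.element_id for el in elements}
    if unknown:
        raise ValueError(f"driver ids not among elements: {sorted(unknown)}")

    k = config.n_samples
    burdens = rng.lognormal(mean=-config.burden_sigma**2 / 2, sigma=config.burden_sigma, size=k)
    flank_effects = rng.normal(0.0, config.flank_sigma, size=16)
    flank_effects -= flank_effects.mean()
    base_rate = config.mutations_per_mb * 1e-6
    weights = np.asarray(config.outcome_weights, dtype=float)
    weights = weights / weights.sum()

    records: list[MutationRecord] = []
    for chrom, length in config.chrom_lengths.items():
        usable, eta = _position_logits(config, bundle, chrom, elements, flank_effects)
        window = np.arange(length) // config.window_size
        n_win = int(window.max()) + 1
        if config.overdispersion > 0:
            shape = 1.0 / config.overdispersion
            win_mult = rng.gamma(shape, scale=1.0 / shape, size=n_win)
        else:
            win_mult = np.ones(n_win)
        spike = np.ones(length)
        for el in elements:
            factor = driver_map.get(el.element_id)
            if factor:
                for c, s, e in el.intervals:
                    if c == chrom:
                        spike[s:e] *= factor

        rate = base_rate * np.exp(eta) * win_mult[window] * spike
        rate[~usable] = 0.0
        # group positions by identical rate for batched multinomial draws
        uniq_rates, inverse = np.unique(rate, return_inverse=True)
        order = np.argsort(inverse, kind="stable")
        group_sizes = np.bincount(inverse, minlength=uniq_rates.size)
        offsets = np.concatenate([[0], np.cumsum(group_sizes)])
        seq = bundle.genome.sequence(chrom, 0, length)
        for g, r in enumerate(uniq_rates):
            if r <= 0:
                continue
            group_pos = order[offsets[g] : offsets[g + 1]]
            n_g = group_pos.size
            p_mut = r * burdens * np.exp(0.0)  # per-sample total mutation prob
            if np.any(p_mut * weights.max() >= 1.0) or np.any(p_mut >= 1.0):
                raise ValueError("mutation probability >= 1 after spiking")
            for j in range(k):
                probs = np.concatenate([[1.0 - p_mut[j]], p_mut[j] * weights])
                counts = rng.multinomial(n_g, probs)
                total = int(counts[1:].sum())
                if total == 0:
                    continue
                chosen = rng.choice(group_pos, size=total, replace=False)
                outcome_codes = np.repeat([1, 2, 3], counts[1:])
                for pos, code in zip(chosen, outcome_codes):
                    ref = seq[pos]
                    records.append(
                        MutationRecord(
                            sample_id=config.sample_ids[j],
                            chrom=chrom,
                            pos=int(pos),
                            ref=ref,
                            alt=ALT_TABLE[(ref, int(code))],
                            cancer_type=config.cancer_type(j),
                        )
                    )
    records.sort(key=lambda r: (r.chrom, r.pos, r.sample_id))
    return records


def simulate_count_table(
    coefficients: np.ndarray,
    config,
    sample_ids: Sequence[str],
    n_rows: int,
    exposure_per_row: int,
    seed: int,
):
    """Draw a count table from known multinomial-logit coefficients.

    Rows get uniformly random covariate levels; outcome counts are exact
    multinomial draws from ``p_o = q_o / (1 + sum q)``.  Used as the
    parameter-recovery oracle for the model-fitting path.
    """
    from .nullmodel import COUNT_COLUMNS, CountTable, Encoding, FACTOR_LEVELS

    rng = np.random.default_rng(seed)
    data = {}
    for cov in config.covariates:
        levels = sample_ids if cov == "sample" else FACTOR_LEVELS[cov]
        data[cov] = rng.choice(np.asarray(levels, dtype=object), size=n_rows)
    for cov in set(FACTOR_LEVELS) - set(config.covariates):
        data[cov] = np.full(n_rows, FACTOR_LEVELS[cov][0], dtype=object)
    if "sample" not in config.covariates:
        data["sample"] = np.full(n_rows, sample_ids[0], dtype=object)
    df = pd.DataFrame(data)
    encoding = Encoding.for_config(config, sample_ids)
    X = encoding.build(df)
    coefficients = np.asarray(coefficients, dtype=float)
    q = np.exp(np.column_stack([X @ coefficients[j] for j in range(3)]))
    denom = 1.0 + q.sum(axis=1)
    probs = np.column_stack([1.0 / denom, q / denom[:, None]])
    counts = np.array([rng.multinomial(exposure_per_row, p) for p in probs])
    df["n_positions"] = exposure_per_row
    for j, col in enumerate(COUNT_COLUMNS):
        df[col] = counts[:, j + 1]
    cols = ["sample"] + [c for c in FACTOR_LEVELS] + ["n_positions"] + list(COUNT_COLUMNS)
    return CountTable(df[cols]), encoding


def truth_table(
    config: SimulationConfig, element_ids: Sequence[str]
) -> list[tuple[str, bool, float]]:
    """Ground-truth driver labels for power/FDR evaluation."""
    driver_map = dict(config.drivers)
    return [(eid, eid in driver_map, float(driver_map.get(eid, 1.0))) for eid in element_ids]


def write_reference(bundle: ReferenceBundle, outdir: str | os.PathLike) -> dict[str, str]:
    """Write the bundle as FASTA/bedGraph/TSV; returns the path map."""
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "genome": os.path.join(outdir, "genome.fa"),
        "replication": os.path.join(outdir, "replication.bedgraph"),
        "expression": os.path.join(outdir, "expression.bedgraph"),
        "phylop": os.path.join(outdir, "phylop.bedgraph"),
        "transcripts": os.path.join(outdir, "transcripts.tsv"),
    }
    with open(paths["genome"], "w") as fh:
        for chrom in bundle.genome.chroms():
            fh.write(f">{chrom}\n")
            seq = bundle.genome.sequence(chrom, 0, bundle.genome.length(chrom))
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    bundle.rep_track.to_bedgraph(paths["replication"])
    bundle.expr_track.to_bedgraph(paths["expression"])
    bundle.phylop_track().to_bedgraph(paths["phylop"])
    bundle.transcripts.to_csv(paths["transcripts"], sep="\t", index=False)
    return paths
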