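"""Aligned-read and coverage simulation with planted truncations and
junction-spanning soft-clipped reads.

Reads are placed uniformly over expressed gene bodies (introns included —
the FFPE pre-mRNA regime) plus a genome-wide uniform background. The split
between gene-body and background reads is solved analytically so the
realized exon-mapped fraction matches the configured target in expectation.
For a truncated/fused gene no reads fall 3' of the breakpoint
(transcriptional orientation); a configurable number of junction reads end
at the breakpoint and carry a clipped segment whose sequence originates
from the partner locus, or from random sequence when the partner is
unknown.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..genes import GeneModel, overlap_length
from ..peakclass import CoverageTrack
from ..fusionscan import ReadRecord, UNKNOWN
from .genome import SyntheticGenome
from .cohort import CohortConfig, SyntheticCohort, ConfigurationError

#: Relative expression weight of each expressed gene, per oncogene class.
DEFAULT_EXPRESSION: dict[str, dict[str, float]] = {
    "MYB": {"MYB": 0.30, "SOX4": 0.10, "EN1": 0.07, "NFIB": 0.15,
            "HK1": 0.14, "HK2": 0.12, "HK3": 0.12},
    "MYBL1": {"MYBL1": 0.30, "SOX4": 0.10, "EN1": 0.07, "NFIB": 0.15,
              "HK1": 0.14, "HK2": 0.12, "HK3": 0.12},
    "NEITHER": {"VGLL3": 0.18, "NFIB": 0.17,
                "HK1": 0.22, "HK2": 0.21, "HK3": 0.22},
}

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class ReadSimResult:
    sample_id: str
    tracks: dict[str, CoverageTrack]
    clipped_reads: list[ReadRecord]
    n_reads: int
    exon_fraction_realized: float
    gene_reads: dict[str, int] = field(default_factory=dict)


def _expressed_region(gene: GeneModel, breakpoint: int | None) -> tuple[int, int]:
    """Genomic extent of transcription: full body, or 5' side of a breakpoint."""
    if breakpoint is None:
        return gene.start, gene.end
    if not gene.start < breakpoint < gene.end:
        raise ConfigurationError(
            f"breakpoint {breakpoint} outside gene body of {gene.gene_id}"
        )
    return (gene.start, breakpoint) if gene.strand == "+" else (breakpoint, gene.end)


def simulate_reads(
    genome: SyntheticGenome,
    expression: dict[str, float],
    config: CohortConfig,
    rng: np.random.Generator,
    sample_id: str = "S",
    truncated_gene: str | None = None,
    breakpoint: int | None = None,
    partner: str | None = None,
    partner_breakpoint: int | None = None,
) -> ReadSimResult:
    """Simulate one sample's coverage tracks and clipped reads."""
    L = config.read_length
    genome_len = genome.total_length
    exon_masks = genome.exon_mask()
    total_exon = sum(int(m.sum()) for m in exon_masks.values())
    b = total_exon / genome_len

    regions: dict[str, tuple[int, int]] = {}
    for gid in expression:
        g = genome.gene(gid)
        bp = breakpoint if gid == truncated_gene else None
        regions[gid] = _expressed_region(g, bp)
    if truncated_gene is not None and truncated_gene not in expression:
        # validate the breakpoint even for a silent gene
        _expressed_region(genome.gene(truncated_gene), breakpoint)

    weights = np.array([expression[g] for g in expression], dtype=float)
    if weights.sum() > 0:
        weights = weights / weights.sum()
        exon_frac_per_gene = []
        for gid in expression:
            g = genome.gene(gid)
            lo, hi = regions[gid]
            in_region = sum(overlap_length(s, e, lo, hi) for s, e in g.exons)
            exon_frac_per_gene.append(in_region / (hi - lo))
        e = float(np.dot(weights, exon_frac_per_gene))
        f_gene = 0.0 if e <= b else float(np.clip(
            (config.exon_fraction - b) / (e - b), 0.0, 1.0))
    else:
        f_gene = 0.0

    n_total = int(rng.poisson(config.depth_mean))
    n_gene = int(rng.binomial(n_total, f_gene)) if n_total else 0
    n_bg = n_total - n_gene

    cov = {c: np.zeros(len(s) + 1, dtype=np.int64) for c, s in genome.sequences.items()}
    starts_by_chrom: dict[str, list[np.ndarray]] = {c: [] for c in cov}
    gene_reads: dict[str, int] = {}

    if n_gene:
        per_gene = rng.multinomial(n_gene, weights)
        for gid, n_g in zip(expression, per_gene):
            gene_reads[gid] = int(n_g)
            if n_g == 0:
                continue
            g = genome.gene(gid)
            lo, hi = regions[gid]
            hi_start = max(hi - L, lo + 1)
            starts = rng.integers(lo, hi_start, size=n_g)
            ends = np.minimum(starts + L, len(genome.sequences[g.chrom]))
            np.add.at(cov[g.chrom], starts, 1)
            np.add.at(cov[g.chrom], ends, -1)
            starts_by_chrom[g.chrom].append(starts)

    if n_bg:
        chroms = list(genome.sequences)
        lens = np.array([len(genome.sequences[c]) for c in chroms], dtype=float)
        per_chrom = rng.multinomial(n_bg, lens / lens.sum())
        for c, n_c in zip(chroms, per_chrom):
            if n_c == 0:
                continue
            starts = rng.integers(0, len(genome.sequences[c]) - L, size=n_c)
            np.add.at(cov[c], starts, 1)
            np.add.at(cov[c], starts + L, -1)
            starts_by_chrom[c].append(starts)

    clipped: list[ReadRecord] = []
    if truncated_gene is not None and config.n_junction_reads > 0:
        g = genome.gene(truncated_gene)
        aln_len = max(L - config.clip_length, 20)
        if partner is not None and partner != UNKNOWN:
            if partner_breakpoint is None:
                raise ConfigurationError("known partner requires a partner breakpoint")
            pg = genome.gene(partner)
            pseq = genome.sequences[pg.chrom]
            clip_seq = pseq[partner_breakpoint: partner_breakpoint + config.clip_length]
        else:
            clip_seq = None  # drawn fresh per read below
        for _ in range(config.n_junction_reads):
            seq = clip_seq or rng.choice(_BASES, size=config.clip_length).tobytes().decode()
            if g.strand == "+":
                rec = ReadRecord(sample_id, g.chrom, breakpoint - aln_len, breakpoint,
                                 "+", "right", seq)
            else:
                rec = ReadRecord(sample_id, g.chrom, breakpoint, breakpoint + aln_len,
                                 "+", "left", seq)
            clipped.append(rec)
            np.add.at(cov[g.chrom], rec.start, 1)
            np.add.at(cov[g.chrom], rec.end, -1)

    tracks: dict[str, CoverageTrack] = {}
    exonic = 0
    for c in cov:
        depth = np.cumsum(cov[c][:-1])
        tracks[c] = CoverageTrack(sample_id, c, 0, depth, n_total)
        if starts_by_chrom[c]:
            mids = np.concatenate(starts_by_chrom[c]) + L // 2
            exonic += int(exon_masks[c][np.clip(mids, 0, len(exon_masks[c]) - 1)].sum())
    realized = exonic / n_total if n_total else 0.0

    return ReadSimResult(sample_id, tracks, clipped, n_total, realized, gene_reads)


def simulate_cohort_reads(
    cohort: SyntheticCohort,
    expression: dict[str, dict[str, float]] | None = None,
) -> dict[str, ReadSimResult]:
    """Simulate reads for every sample, one child RNG per sample."""
    expression = expression or DEFAULT_EXPRESSION
    seeds = cohort.config.seed_children()[2].spawn(len(cohort.samples))
    out: dict[str, ReadSimResult] = {}
    for (sid, row), ss in zip(cohort.samples.iterrows(), seeds):
        rng = np.random.default_rng(ss)
        bp = int(row["breakpoint"]) if row["truncated"] else None
        pbp = (int(row["partner_breakpoint"])
               if row["truncated"] and row["partner"] != UNKNOWN
               and row["partner_breakpoint"] is not None else None)
        out[sid] = simulate_reads(
            cohort.genome,
            expression[row["class_label"]],
            cohort.config,
            rng,
            sample_id=sid,
            truncated_gene=row["class_label"] if row["truncated"] else None,
            breakpoint=bp,
            partner=row["partner"] if row["truncated"] else None,
            partner_breakpoint=pbp,
        )
    return out
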