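"""Fusion-partner identification from soft-clipped (chimeric) reads.

Reads anchored in a 5' oncogene whose terminal bases were clipped at the
alignment boundary carry the other side of a fusion junction; matching the
clipped segment back to the annotated reference (both strands, exact match
at desk scale) identifies the partner locus. A partner is accepted when
enough independent reads agree on the same gene within a breakpoint
cluster; otherwise the partner is UNKNOWN — mirroring tumors with obvious
truncations but insufficient chimeric evidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections import defaultdict

import numpy as np
import pandas as pd

from .genes import GeneModel, find_gene_at
from .promoseq import reverse_complement

UNKNOWN = "UNKNOWN"


@dataclass(frozen=True)
class ReadRecord:
    sample_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    clip_side: str = ""          # "" (no clip), "left" or "right" of the alignment
    clip_seq: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("empty aligned interval")
        if self.clip_side and not self.clip_seq:
            raise ValueError("clip side declared without clip sequence")


@dataclass(frozen=True)
class ClippedSegment:
    sample_id: str
    anchor_gene: str
    chrom: str
    breakpoint: int              # clip-side boundary of the alignment
    seq: str


@dataclass
class FusionEvidence:
    sample_id: str
    five_prime_gene: str
    partner: str                 # gene id or UNKNOWN
    breakpoint_5p: int | None
    breakpoint_partner: int | None
    support: int
    ambiguous: bool = False


@dataclass
class FusionCatalog:
    case_counts: pd.DataFrame    # rows: (five_prime_gene, partner) -> n cases
    totals: pd.Series
    n_samples: int


def reads_from_frame(df: pd.DataFrame) -> list[ReadRecord]:
    return [
        ReadRecord(r.sample_id, r.chrom, int(r.start), int(r.end), r.strand,
                   r.clip_side or "", r.clip_seq or "")
        for r in df.itertuples(index=False)
    ]


def extract_clips(
    reads: list[ReadRecord], genes: list[GeneModel], min_clip_len: int = 12
) -> list[ClippedSegment]:
    """Clipped segments of at least ``min_clip_len`` nt, annotated with the
    gene their aligned portion falls in. Reads without a sufficient clip, or
    anchored outside any gene model, yield nothing."""
    out: list[ClippedSegment] = []
    for r in reads:
        if not r.clip_side or len(r.clip_seq) < min_clip_len:
            continue
        gene = find_gene_at(genes, r.chrom, r.start, r.end)
        if gene is None:
            continue
        bp = r.start if r.clip_side == "left" else r.end
        out.append(ClippedSegment(r.sample_id, gene.gene_id, r.chrom, bp, r.clip_seq))
    return out


def _find_all(haystack: str, needle: str) -> list[int]:
    hits, i = [], haystack.find(needle)
    while i != -1:
        hits.append(i)
        i = haystack.find(needle, i + 1)
    return hits


def assign_partner(
    segments: list[ClippedSegment],
    reference: dict[str, str],
    genes: list[GeneModel],
    min_support: int = 2,
    cluster_window: int = 50,
) -> FusionEvidence:
    """Resolve the fusion partner for clips anchored in one gene of one sample.

    Each clip is exact-matched against every contig on both strands; matches
    inside a gene body vote for that gene, with votes clustered by match
    position (one vote per read per gene). The best gene needs >=
    ``min_support`` reads within one ``cluster_window``; a tie between genes
    at equal top support yields UNKNOWN with the ambiguity flag.
    """
    if not segments:
        raise ValueError("no clipped segments supplied")
    anchor = segments[0].anchor_gene
    sample = segments[0].sample_id
    votes: dict[str, list[int]] = defaultdict(list)
    for seg in segments:
        seen: set[str] = set()
        for chrom, seq in reference.items():
            for probe in (seg.seq, reverse_complement(seg.seq)):
                for pos in _find_all(seq, probe):
                    g = find_gene_at(genes, chrom, pos, pos + len(probe))
                    if g is not None and g.gene_id != anchor and g.gene_id not in seen:
                        votes[g.gene_id].append(pos)
                        seen.add(g.gene_id)

    def best_cluster(positions: list[int]) -> tuple[int, int]:
        pos = sorted(positions)
        best_n, best_pos = 0, pos[0]
        for i, p in enumerate(pos):
            n = sum(1 for q in pos[i:] if q - p <= cluster_window)
            if n > best_n:
                best_n, best_pos = n, p
        return best_n, best_pos

    bp5 = int(np.median([s.breakpoint for s in segments]))
    scored = {g: best_cluster(v) for g, v in votes.items()}
    if not scored:
        return FusionEvidence(sample, anchor, UNKNOWN, bp5, None, 0)
    top = max(n for n, _ in scored.values())
    winners = [g for g, (n, _) in scored.items() if n == top]
    if top < min_support:
        return FusionEvidence(sample, anchor, UNKNOWN, bp5, None, top)
    if len(winners) > 1:
        return FusionEvidence(sample, anchor, UNKNOWN, bp5, None, top, ambiguous=True)
    g = winners[0]
    return FusionEvidence(sample, anchor, g, bp5, scored[g][1], top)


def scan_sample(
    reads: list[ReadRecord],
    reference: dict[str, str],
    genes: list[GeneModel],
    min_clip_len: int = 12,
    min_support: int = 2,
    cluster_window: int = 50,
) -> list[FusionEvidence]:
    """Extract clips for one sample and resolve a partner per anchored gene."""
    clips = extract_clips(reads, genes, min_clip_len)
    by_gene: dict[str, list[ClippedSegment]] = defaultdict(list)
    for c in clips:
        by_gene[c.anchor_gene].append(c)
    return [
        assign_partner(segs, reference, genes, min_support, cluster_window)
        for segs in by_gene.values()
    ]


def build_catalog(calls, fusions: list[FusionEvidence]) -> FusionCatalog:
    """Tabulate fusion cases and the cohort partition totals.

    Totals follow the reference cohort's table: per oncogene, samples with
    apparent truncation OR an identified fusion; samples over-expressing
    without truncation evidence; samples expressing neither oncogene. The
    three categories partition the cohort.
    """
    call_ids = {c.sample_id for c in calls}
    if len(call_ids) != len(calls):
        raise ValueError("duplicate sample ids")
    stray = [f.sample_id for f in fusions if f.sample_id not in call_ids]
    if stray:
        raise ValueError(f"fusion evidence for unknown samples: {sorted(set(stray))}")

    fused: dict[str, dict[str, FusionEvidence]] = defaultdict(dict)
    for f in fusions:
        fused[f.sample_id][f.five_prime_gene] = f

    pair_counts: dict[tuple[str, str], int] = defaultdict(int)
    trunc_or_transloc = {"MYB": 0, "MYBL1": 0}
    overexpr_no_trunc = 0
    neither = 0
    for c in calls:
        if c.group == "NEITHER":
            neither += 1
            continue
        status = c.myb if c.group == "MYB" else c.mybl1
        ev = fused.get(c.sample_id, {}).get(c.group)
        truncated = bool(status is not None and status.truncated)
        has_fusion = ev is not None and ev.partner != UNKNOWN
        if truncated or has_fusion:
            trunc_or_transloc[c.group] += 1
            partner = ev.partner if ev is not None else UNKNOWN
            pair_counts[(c.group, partner)] += 1
        else:
            overexpr_no_trunc += 1

    rows = [
        {"five_prime_gene": g, "partner": p, "cases": n}
        for (g, p), n in sorted(pair_counts.items())
    ]
    case_counts = pd.DataFrame(rows, columns=["five_prime_gene", "partner", "cases"])
    totals = pd.Series(
        {
            "myb_truncation_or_translocation": trunc_or_transloc["MYB"],
            "mybl1_truncation_or_translocation": trunc_or_transloc["MYBL1"],
            "overexpressed_no_truncation": overexpr_no_trunc,
            "neither_oncogene": neither,
        }
    )
    return FusionCatalog(case_counts, totals, n_samples=len(calls))
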