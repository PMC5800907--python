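"""A desk-scale synthetic genome with the loci the analysis needs.

Contigs are a few tens of kilobases; the gene complement covers the two
interchangeable driver oncogenes (MYB on a plus strand, MYBL1 on a minus
strand, so strand handling is always exercised), the recurrent fusion
partners (NFIB, PDCD1LG2, EFR3A), the Myb-correlated targets (SOX4, EN1),
the neither-class marker VGLL3 and housekeeping genes for background
expression. Sequence is i.i.d. uniform ACGT from a fixed seed, which makes
exact-match fusion-clip search essentially collision-free at this scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..genes import GeneModel

_BASES = np.frombuffer(b"ACGT", dtype="S1")

#: Seed for the reference sequence itself (the genome is a fixed reference,
#: not a per-cohort random object).
GENOME_SEQ_SEED = 20170923

_CONTIGS = {
    "chr2": 60_000,
    "chr3": 70_000,
    "chr6": 90_000,
    "chr8": 80_000,
    "chr9": 80_000,
    "chr12": 60_000,
}


def _gene(gene_id, chrom, strand, start, end, n_exons, exon_frac=0.12) -> GeneModel:
    """Evenly spaced exons totalling ``exon_frac`` of the gene body."""
    body = end - start
    exon_len = max(int(body * exon_frac / n_exons), 10)
    gap = (body - n_exons * exon_len) // max(n_exons - 1, 1) if n_exons > 1 else 0
    exons = []
    pos = start
    for _ in range(n_exons):
        exons.append((pos, pos + exon_len))
        pos += exon_len + gap
    if exons[-1][1] > end:
        exons[-1] = (exons[-1][0], end)
    return GeneModel(gene_id, chrom, strand, start, end, tuple(exons))


@dataclass
class SyntheticGenome:
    sequences: dict[str, str]
    genes: list[GeneModel]

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def gene(self, gene_id: str) -> GeneModel:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def exon_mask(self) -> dict[str, np.ndarray]:
        masks = {c: np.zeros(n, dtype=bool) for c, n in
                 ((c, len(s)) for c, s in self.sequences.items())}
        for g in self.genes:
            for s, e in g.exons:
                masks[g.chrom][s:e] = True
        return masks

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for chrom, seq in self.sequences.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i:i + 80] + "\n")


def default_genome() -> SyntheticGenome:
    """The package's reference synthetic genome (deterministic)."""
    rng = np.random.default_rng(GENOME_SEQ_SEED)
    sequences = {
        chrom: rng.choice(_BASES, size=n).tobytes().decode()
        for chrom, n in _CONTIGS.items()
    }
    genes = [
        _gene("EN1", "chr2", "-", 20_000, 26_000, 2),
        _gene("VGLL3", "chr3", "+", 20_000, 28_000, 3),
        _gene("EFR3A", "chr3", "+", 45_000, 52_000, 4),
        _gene("MYB", "chr6", "+", 20_000, 35_000, 8),
        _gene("SOX4", "chr6", "+", 50_000, 55_000, 1),
        _gene("MYBL1", "chr8", "-", 20_000, 34_000, 8),
        _gene("NFIB", "chr9", "-", 15_000, 40_000, 6),
        _gene("PDCD1LG2", "chr9", "+", 55_000, 62_000, 4),
        _gene("HK1", "chr12", "+", 10_000, 20_000, 5),
        _gene("HK2", "chr12", "-", 30_000, 38_000, 4),
        _gene("HK3", "chr12", "+", 45_000, 52_000, 4),
    ]
    return SyntheticGenome(sequences, genes)
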