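"""Promoter-fragment arithmetic, Myb-response-element scanning and
luciferase fold-activation normalization.

The EN1 and SOX4 promoter fragments studied in the reporter-gene assays are
bundled as module constants (hg19 coordinates, 1-based inclusive). The EN1
fragment carries the common rs3731613 polymorphism, conventionally printed
as a lowercase 'g'; sequences are uppercased on ingest.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

#: Myb response element consensus (Py-A-A-C-G/T-G)
MRE_CONSENSUS = "YAACKG"

SOX4_LUC_INTERVAL = ("chr6", 21593929, 21594089)
SOX4_LUC_SEQ = (
    "GCTGCAGCCAAGACTGTGAAAGGATAAAGAGGCGCGAGGCGGAATTGGGGTCTGCTCTAAGCTGCAGCAAGAG"
    "AAACTGTGTGTGAGGGGAAGAGGCCTGTTTCGCTGTCGGGTCTCTAGTTCTTGCACGCTCTTTAAGAGTCTGC"
    "ACTGGAGGAACTCCT"
)

EN1_LUC_INTERVAL = ("chr2", 119605727, 119606071)
EN1_LUC_SEQ = (
    "AACGTAAACGTGCGACGCTAGCTAGGCGCAGCGGGCCTTTCAGATTTTGCTATTTGTGAAAAACAAATTGCGC"
    "CTCTGAAAGTAACCAACTCTAGGTCTATTTCACATCACCGACCTCCCTGTCTCACTCCCCCTCCCTCCACTAC"
    "ACACACCCAAACCCACACCCACCCACAAACACACAAACCGGCAGTGACAACAACCACCCATCCTTCAATAACA"
    "GCAACCAGAGACAGAGGAGAAAATAAAAAGCTGAGTTTCTTAGGCGTGGGGGTGCAAAACAGCCAGGCTCCTG"
    "CCTACTGCCCCTGCTCCCGGAGCTCACAGACCCATAATCCTGCATTTCTCTAA"
)


@dataclass(frozen=True)
class GenomicInterval:
    """A genomic interval with an explicit coordinate convention.

    ``one_based=True`` means 1-based fully-closed (the GTF / genome-browser
    convention); ``False`` means 0-based half-open (the BED / internal one).
    """

    chrom: str
    start: int
    end: int
    one_based: bool = True

    def __post_init__(self) -> None:
        if self.one_based and self.end < self.start:
            raise ValueError("1-based inclusive interval requires end >= start")
        if not self.one_based and self.end < self.start:
            raise ValueError("half-open interval requires end >= start")

    def to_zero_based(self) -> "GenomicInterval":
        if not self.one_based:
            return self
        return GenomicInterval(self.chrom, self.start - 1, self.end, one_based=False)


@dataclass(frozen=True)
class MotifHit:
    position: int  # 0-based offset in the scanned sequence (forward coords)
    strand: str
    matched: str
    consensus: str


@dataclass
class ReporterMeasurement:
    condition: str
    replicates: Sequence[float]
    background: float = 0.0

    def __post_init__(self) -> None:
        if len(self.replicates) < 2:
            raise ValueError("at least two replicates required")


def interval_length(iv: GenomicInterval) -> int:
    """Length in bp under the interval's declared convention."""
    if iv.one_based:
        return iv.end - iv.start + 1
    return iv.end - iv.start


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _matches(window: str, consensus: str) -> bool:
    return all(b in IUPAC[c] for b, c in zip(window, consensus))


def scan_mre(sequence: str, consensus: str = MRE_CONSENSUS,
             both_strands: bool = True) -> list[MotifHit]:
    """Scan a sequence for a degenerate consensus on one or both strands.

    Hits are reported in forward coordinates; a '-' hit at position i means
    the reverse complement of sequence[i:i+k] matches the consensus.
    """
    seq = sequence.upper()
    cons = consensus.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"sequence contains non-ACGTN characters: {sorted(bad)}")
    if any(c not in IUPAC for c in cons):
        raise ValueError("consensus contains invalid IUPAC codes")
    k = len(cons)
    rc_cons = reverse_complement(cons)
    hits: list[MotifHit] = []
    for i in range(len(seq) - k + 1):
        window = seq[i:i + k]
        if "N" in window:
            # N in the subject never satisfies a non-N consensus position
            fwd = all(c == "N" or (b != "N" and b in IUPAC[c])
                      for b, c in zip(window, cons))
            rev = both_strands and all(c == "N" or (b != "N" and b in IUPAC[c])
                                       for b, c in zip(window, rc_cons))
        else:
            fwd = _matches(window, cons)
            rev = both_strands and _matches(window, rc_cons)
        if fwd:
            hits.append(MotifHit(i, "+", window, consensus))
        if rev:
            hits.append(MotifHit(i, "-", window, consensus))
    return hits


def fold_activation(m: ReporterMeasurement, control: ReporterMeasurement) -> float:
    """Background-subtracted luminescence, normalized to the control condition.

    fold = (mean(m) - background) / (mean(control) - background); the two
    measurements share the background estimate of ``m`` if control carries
    none of its own.
    """
    bg = m.background
    ctrl_mean = float(np.mean(control.replicates))
    if ctrl_mean <= bg:
        raise ZeroDivisionError("control signal does not exceed background")
    return (float(np.mean(m.replicates)) - bg) / (ctrl_mean - bg)
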