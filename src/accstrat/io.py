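"""Readers and writers for the package's plain-text formats.

Formats: gene annotation as GTF (1-based inclusive) and BED (0-based
half-open); counts as TSV (genes x samples); clinical tables as CSV; aligned
reads as a small TSV dialect (chrom, start, end, strand, clip_side,
clip_seq) that an optional adapter can convert to/from BAM.
"""

from __future__ import annotations

import os
from typing import Iterable

import pandas as pd

from .genes import GeneModel

READS_COLUMNS = ["sample_id", "chrom", "start", "end", "strand", "clip_side", "clip_seq"]


def write_gtf(genes: Iterable[GeneModel], path: str | os.PathLike, source: str = "accstrat") -> None:
    rows = []
    for g in genes:
        attrs = f'gene_id "{g.gene_id}";'
        rows.append((g.chrom, source, "gene", g.start + 1, g.end, ".", g.strand, ".", attrs))
        for s, e in g.exons:
            rows.append((g.chrom, source, "exon", s + 1, e, ".", g.strand, ".", attrs))
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False, quoting=3)


def read_gtf(path: str | os.PathLike) -> list[GeneModel]:
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "source", "feature", "start", "end", "score", "strand", "frame", "attrs"],
        dtype={"chrom": str},
    )
    df["gene_id"] = df["attrs"].str.extract(r'gene_id "([^"]+)"')
    genes: list[GeneModel] = []
    for gid, grp in df.groupby("gene_id", sort=False):
        body = grp[grp["feature"] == "gene"]
        exon = grp[grp["feature"] == "exon"].sort_values("start")
        if len(body) != 1:
            raise ValueError(f"gene {gid}: expected exactly one gene record")
        b = body.iloc[0]
        exons = tuple((int(s) - 1, int(e)) for s, e in zip(exon["start"], exon["end"]))
        genes.append(GeneModel(str(gid), str(b["chrom"]), str(b["strand"]),
                               int(b["start"]) - 1, int(b["end"]), exons))
    return genes


def write_bed(intervals: Iterable[tuple], path: str | os.PathLike) -> None:
    """Write (chrom, start, end[, name[, score[, strand]]]) tuples as BED."""
    pd.DataFrame(list(intervals)).to_csv(path, sep="\t", header=False, index=False)


def write_counts(counts: pd.DataFrame, path: str | os.PathLike) -> None:
    counts.to_csv(path, sep="\t", index_label="gene")


def read_counts(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any() or df.columns.duplicated().any():
        raise ValueError("duplicate gene or sample ids in count matrix")
    return df


def write_clinical(clinical: pd.DataFrame, path: str | os.PathLike) -> None:
    clinical.to_csv(path, index_label="sample_id")


def read_clinical(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)


def write_reads(reads: pd.DataFrame, path: str | os.PathLike) -> None:
    reads.reindex(columns=READS_COLUMNS).to_csv(path, sep="\t", index=False)


def read_reads(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"clip_side": str, "clip_seq": str}, keep_default_na=False)
    missing = set(READS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"reads table missing columns: {sorted(missing)}")
    return df


def write_gmt(sets: dict[str, list[str]], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, "na", *members]) + "\n")


def read_gmt(path: str | os.PathLike) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            if parts[0] in sets:
                raise ValueError(f"duplicate gene-set name: {parts[0]}")
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets
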