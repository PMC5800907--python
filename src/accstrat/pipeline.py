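"""End-to-end orchestration: simulate -> QC -> peak classification ->
fusion scan -> DE/PCA -> clustering -> survival -> GSEA.

Each stage writes plain-text artifacts into the output directory and the
run report indexes every file with a sha256 checksum, so a re-run from the
same configuration and seed is verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import exprmat, fusionscan, gseakit, io, peakclass, survclust
from .synthgen import (
    CohortConfig, default_genome, default_signature, generate_cohort,
    simulate_cohort_reads, simulate_counts, simulate_survival, SurvivalSpec,
)

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "qc", "peakclass", "fusionscan", "de",
              "clustering", "survival", "gsea")

DEFAULT_MARKERS = [
    "MYB", "EN1", "SOX4", "CXXC4", "VGLL3", "KLF4", "FOXO1", "JUNB", "FOSB",
    "SETBP1", "EGFR", "TP63", "PIGR",
    "G0001", "G0002", "G0003", "G0004", "G0005", "G0006", "G0007",
]


@dataclass
class RunConfig:
    seed: int = 0
    n_samples: int = 68
    class_proportions: tuple[float, float, float] = (0.72, 0.10, 0.18)
    depth_mean: float = 20_000.0
    exon_fraction: float = 0.09
    stages: dict[str, bool] = field(default_factory=lambda: {s: True for s in ALL_STAGES})
    qc_fraction: float = 0.10
    min_count: int = 250
    min_samples: int = 10
    lfc_threshold: float = 1.0
    de_alpha: float = 0.05
    cluster_k: int = 2
    gsea_n_perm: int = 1000
    gsea_min_size: int = 15
    sam_n_perm: int = 200
    min_clip_len: int = 12
    min_support: int = 2
    markers: list[str] = field(default_factory=lambda: list(DEFAULT_MARKERS))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**{k: v for k, v in data.items() if k in cls.__dataclass_fields__})
        if isinstance(cfg.class_proportions, list):
            cfg.class_proportions = tuple(cfg.class_proportions)
        return cfg

    def cohort_config(self) -> CohortConfig:
        return CohortConfig(
            n_samples=self.n_samples,
            class_proportions=self.class_proportions,
            depth_mean=self.depth_mean,
            exon_fraction=self.exon_fraction,
            seed=self.seed,
        )


@dataclass
class RunReport:
    config: dict
    stages_run: list[str] = field(default_factory=list)
    summary: dict = field(default_factory=dict)
    artifacts: dict[str, str] = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"config": self.config, "stages_run": self.stages_run,
                 "summary": self.summary, "artifacts": self.artifacts},
                fh, indent=2, default=_jsonable,
            )


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    return str(o)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage


def classify_cohort(reads, genome, params=None) -> list[peakclass.OncogeneCall]:
    """Peak-call every sample's coverage and assign MYB/MYBL1/NEITHER."""
    params = params or peakclass.PeakParams(effective_genome_length=genome.total_length)
    myb_gene, mybl1_gene = genome.gene("MYB"), genome.gene("MYBL1")
    calls = []
    for sid, res in reads.items():
        st_myb = peakclass.gene_status(
            peakclass.call_regions(res.tracks[myb_gene.chrom], params),
            myb_gene, res.tracks[myb_gene.chrom])
        st_mybl1 = peakclass.gene_status(
            peakclass.call_regions(res.tracks[mybl1_gene.chrom], params),
            mybl1_gene, res.tracks[mybl1_gene.chrom])
        calls.append(peakclass.classify_sample(sid, st_myb, st_mybl1))
    return calls


def run_all(config: RunConfig, outdir) -> RunReport:
    """Execute the enabled stages in order; any failure halts with the stage name."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=asdict(config))
    written: list[Path] = []

    def emit(name: str, writer) -> Path:
        path = out / name
        writer(path)
        written.append(path)
        return path

    on = lambda s: config.stages.get(s, True)

    # ------------------------------------------------------------ simulate
    if not on("simulate"):
        raise PipelineError("simulate", "pipeline currently starts from simulation")
    genome = default_genome()
    cohort = generate_cohort(config.cohort_config(), genome)
    sig = default_signature()
    counts = simulate_counts(cohort, sig)
    clinical = simulate_survival(cohort, SurvivalSpec())
    reads = simulate_cohort_reads(cohort)
    emit("genes.gtf", lambda p: io.write_gtf(genome.genes, p))
    emit("genes.bed", lambda p: io.write_bed(
        [(g.chrom, g.start, g.end, g.gene_id, 0, g.strand) for g in genome.genes], p))
    emit("counts.tsv", lambda p: io.write_counts(counts, p))
    emit("clinical.csv", lambda p: io.write_clinical(clinical, p))
    clip_frame = pd.DataFrame(
        [(r.sample_id, r.chrom, r.start, r.end, r.strand, r.clip_side, r.clip_seq)
         for res in reads.values() for r in res.clipped_reads],
        columns=io.READS_COLUMNS,
    )
    emit("reads_clipped.tsv", lambda p: io.write_reads(clip_frame, p))
    emit("truth.csv", lambda p: cohort.samples.to_csv(p))
    report.stages_run.append("simulate")
    report.summary["n_samples"] = len(cohort.samples)
    report.summary["mean_exon_fraction"] = float(
        np.mean([r.exon_fraction_realized for r in reads.values()]))

    # ------------------------------------------------------------------ qc
    if on("qc"):
        qc = exprmat.qc_samples(counts, clinical, config.qc_fraction)
        emit("qc.tsv", lambda p: qc.to_csv(p, sep="\t"))
        report.stages_run.append("qc")
        report.summary["qc_failures"] = int(qc["low_reads_fail"].sum())
        report.summary["sex_discordant"] = int(qc["sex_discordant"].sum())

    # ----------------------------------------------------------- peakclass
    calls: list[peakclass.OncogeneCall] = []
    if on("peakclass"):
        calls = classify_cohort(reads, genome)
        summary = peakclass.cohort_classification(calls)
        emit("classification_summary.tsv", lambda p: summary.to_csv(p, sep="\t"))
        emit("calls.tsv", lambda p: peakclass.classification_table(calls)
             .to_csv(p, sep="\t", index=False))
        truth = cohort.samples["class_label"]
        acc = float(np.mean([c.group == truth[c.sample_id] for c in calls]))
        report.stages_run.append("peakclass")
        report.summary["classification_accuracy"] = acc
        report.summary["class_counts"] = summary["count"].to_dict()

    # ---------------------------------------------------------- fusionscan
    if on("fusionscan"):
        if not calls:
            raise PipelineError("fusionscan", "requires peak classification")
        evidence: list[fusionscan.FusionEvidence] = []
        for sid, res in reads.items():
            if res.clipped_reads:
                evidence.extend(fusionscan.scan_sample(
                    res.clipped_reads, genome.sequences, genome.genes,
                    config.min_clip_len, config.min_support))
        catalog = fusionscan.build_catalog(calls, evidence)
        emit("fusion_evidence.tsv", lambda p: pd.DataFrame(
            [(f.sample_id, f.five_prime_gene, f.partner, f.breakpoint_5p,
              f.breakpoint_partner, f.support, f.ambiguous) for f in evidence],
            columns=["sample_id", "five_prime_gene", "partner", "breakpoint_5p",
                     "breakpoint_partner", "support", "ambiguous"],
        ).to_csv(p, sep="\t", index=False))
        emit("fusion_catalog.tsv", lambda p: catalog.case_counts.to_csv(p, sep="\t", index=False))
        emit("fusion_totals.tsv", lambda p: catalog.totals.to_csv(p, sep="\t", header=False))
        report.stages_run.append("fusionscan")
        report.summary["fusion_totals"] = catalog.totals.to_dict()

    # ------------------------------------------------------------------ de
    filtered = exprmat.filter_high_expression(counts, config.min_count, config.min_samples)
    log_cpm = exprmat.normalize_log_cpm(filtered)
    groups_onco = cohort.samples["class_label"]
    if on("de"):
        a = list(groups_onco.index[groups_onco.isin(["MYB", "MYBL1"])])
        b = list(groups_onco.index[groups_onco == "NEITHER"])
        de = exprmat.differential_expression(log_cpm, a, b,
                                             config.lfc_threshold, config.de_alpha)
        pca_res = exprmat.pca(log_cpm)
        sam = exprmat.sam_correlate(log_cpm, pca_res.scores["PC1"],
                                    n_perm=config.sam_n_perm, seed=config.seed)
        emit("de.tsv", lambda p: de.to_csv(p, sep="\t"))
        emit("pca_scores.tsv", lambda p: pca_res.scores.to_csv(p, sep="\t"))
        emit("sam_pc1.tsv", lambda p: sam.table.to_csv(p, sep="\t"))
        report.stages_run.append("de")
        report.summary["n_genes_filtered"] = int(filtered.shape[0])
        report.summary["n_de_significant"] = int(de["significant"].sum())

    # ---------------------------------------------------------- clustering
    groups = None
    if on("clustering"):
        dendro = survclust.hierarchical_cluster(log_cpm)
        groups = survclust.cut_groups(dendro, config.cluster_k)
        emit("dendrogram.txt", lambda p: p.write_text(dendro.to_newick() + "\n"))
        emit("merges.tsv", lambda p: pd.DataFrame(
            dendro.linkage, columns=["left", "right", "height", "size"]
        ).to_csv(p, sep="\t", index=False))
        emit("groups.tsv", lambda p: groups.to_csv(p, sep="\t"))
        report.stages_run.append("clustering")
        report.summary["group_sizes"] = groups.value_counts().to_dict()

    # ------------------------------------------------------------ survival
    if on("survival"):
        if groups is None:
            raise PipelineError("survival", "requires clustering groups")
        km_all = survclust.km_estimate(clinical["os_months"], clinical["event"])
        g1 = groups.index[groups == 1]
        g2 = groups.index[groups == 2]
        km1 = survclust.km_estimate(clinical.loc[g1, "os_months"], clinical.loc[g1, "event"])
        km2 = survclust.km_estimate(clinical.loc[g2, "os_months"], clinical.loc[g2, "event"])
        stat, p = survclust.logrank_test(clinical["os_months"], clinical["event"],
                                         groups.loc[clinical.index])
        mv = survclust.multivariate_fit(clinical, groups)
        screen = survclust.marker_screen(
            [m for m in config.markers if m in log_cpm.index], log_cpm, clinical)
        for name, km in (("km_all", km_all), ("km_group1", km1), ("km_group2", km2)):
            emit(f"{name}.tsv", lambda p, km=km: pd.DataFrame(
                {"time": km.times, "survival": km.survival, "std_err": km.std_err,
                 "ci_lower": km.ci_lower, "ci_upper": km.ci_upper}
            ).to_csv(p, sep="\t", index=False))
        emit("cox_multivariate.tsv", lambda p: mv.summary.to_csv(p, sep="\t"))
        emit("marker_screen.tsv", lambda p: screen.to_csv(p, sep="\t"))
        report.stages_run.append("survival")
        report.summary.update({
            "km_median_all": km_all.median,
            "km_median_group1": km1.median,
            "km_median_group2": km2.median,
            "logrank_statistic": stat,
            "logrank_p": p,
            "cox_multivariate_hr": mv.summary["hr"].to_dict() if mv.converged else None,
        })

    # ---------------------------------------------------------------- gsea
    if on("gsea"):
        if groups is None:
            raise PipelineError("gsea", "requires clustering groups")
        sets = _default_gene_sets(sig)
        emit("sets.gmt", lambda p: io.write_gmt(sets, p))
        myb_ids = groups_onco.index[groups_onco == "MYB"]
        labels = pd.Series(np.where(groups.loc[myb_ids] == 1, "group1", "group2"),
                           index=myb_ids)
        if (labels == "group1").sum() >= 3 and (labels == "group2").sum() >= 3:
            results = gseakit.gsea(log_cpm[myb_ids], labels, sets,
                                   n_perm=config.gsea_n_perm, seed=config.seed,
                                   min_size=config.gsea_min_size,
                                   positive_class="group1")
            table = gseakit.results_table(results)
            emit("gsea.tsv", lambda p: table.to_csv(p, sep="\t", index=False))
            report.summary["gsea_top_set"] = results[0].name if results else None
            report.summary["gsea_top_p"] = results[0].nominal_p if results else None
        else:
            logger.warning("gsea skipped: fewer than 3 samples in a phenotype class")
            report.summary["gsea_top_set"] = None
        report.stages_run.append("gsea")

    for path in written:
        report.artifacts[path.name] = _checksum(path)
    report.to_json(out / "report.json")
    return report


def _default_gene_sets(sig) -> dict[str, list[str]]:
    """Planted ES-like and good-outcome sets plus deterministic decoy sets."""
    es = [g for g in sig.genes if g.startswith("ES_")]
    good = [g for g in sig.genes if g.startswith("GO_")] + ["SETBP1", "EGFR", "TP63", "PIGR"]
    import re

    background = [g for g in sig.genes if re.fullmatch(r"G\d{4}", g)]
    rng = np.random.default_rng(4242)
    sets = {"ES_H3K27ME3_LIKE": es, "GOOD_OUTCOME_UP": good}
    for i in range(8):
        sets[f"RANDOM_{i + 1:02d}"] = sorted(
            rng.choice(background, size=30, replace=False).tolist())
    return sets
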