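"""Cohort-level truth generation: classes, clusters and fusion events.

Seed-splitting scheme: ``SeedSequence(seed)`` spawns four children, used in
order for (0) cohort structure, (1) count simulation, (2) read simulation
(which spawns one grandchild per sample) and (3) survival times. Identical
seed and configuration therefore reproduce every artifact byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import SyntheticGenome, default_genome

UNKNOWN = "UNKNOWN"

CLASSES = ("MYB", "MYBL1", "NEITHER")

#: Default per-class fusion/truncation mixture. Probabilities within a class
#: may sum to less than 1; the remainder is "over-expressed, not truncated".
#: The mixture follows the reference cohort's fusion table: of 49 MYB tumors,
#: 11 NFIB fusions, 1 PDCD1LG2, 1 EFR3A and 29 truncations with no
#: identifiable partner; all 7 MYBL1 tumors truncated (3 NFIB, 4 unknown).
DEFAULT_FUSION_SPEC: dict[str, list[tuple[str, float]]] = {
    "MYB": [("NFIB", 11 / 49), ("PDCD1LG2", 1 / 49), ("EFR3A", 1 / 49),
            (UNKNOWN, 29 / 49)],
    "MYBL1": [("NFIB", 3 / 7), (UNKNOWN, 4 / 7)],
    "NEITHER": [],
}


class ConfigurationError(ValueError):
    pass


@dataclass
class CohortConfig:
    n_samples: int = 68
    class_proportions: tuple[float, float, float] = (0.72, 0.10, 0.18)
    fusion_spec: dict[str, list[tuple[str, float]]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_FUSION_SPEC.items()}
    )
    #: fraction of MYB-class samples in the poor-outcome cluster (14 of 49)
    poor_outcome_fraction: float = 14 / 49
    exon_fraction: float = 0.09
    depth_mean: float = 20_000.0
    n_junction_reads: int = 6
    clip_length: int = 24
    read_length: int = 100
    female_fraction: float = 30 / 68
    seed: int = 0

    def __post_init__(self) -> None:
        p = np.asarray(self.class_proportions, dtype=float)
        if p.min() < 0 or p.max() > 1 or abs(p.sum() - 1.0) > 1e-9:
            raise ConfigurationError("class proportions must be in [0,1] and sum to 1")
        for frac, name in ((self.poor_outcome_fraction, "poor_outcome_fraction"),
                           (self.exon_fraction, "exon_fraction"),
                           (self.female_fraction, "female_fraction")):
            if not 0.0 <= frac <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1]")
        if self.depth_mean <= 0:
            raise ConfigurationError("depth_mean must be positive")
        for cls, pairs in self.fusion_spec.items():
            if cls not in CLASSES:
                raise ConfigurationError(f"unknown class in fusion_spec: {cls}")
            tot = sum(q for _, q in pairs)
            if any(q < 0 for _, q in pairs) or tot > 1 + 1e-9:
                raise ConfigurationError(f"fusion probabilities for {cls} invalid")

    def seed_children(self) -> list[np.random.SeedSequence]:
        return np.random.SeedSequence(self.seed).spawn(4)


@dataclass(frozen=True)
class FusionTruth:
    sample_id: str
    five_prime_gene: str
    partner: str                  # gene id or UNKNOWN
    breakpoint: int               # genomic position inside the 5' gene
    partner_breakpoint: int | None


@dataclass
class SyntheticCohort:
    config: CohortConfig
    genome: SyntheticGenome
    samples: pd.DataFrame         # class_label, cluster, sex, age, fusion fields
    fusions: list[FusionTruth]
    clinical: pd.DataFrame | None = None

    @property
    def sample_ids(self) -> list[str]:
        return list(self.samples.index)


def generate_cohort(config: CohortConfig,
                    genome: SyntheticGenome | None = None) -> SyntheticCohort:
    """Draw the cohort truth tracks from the configuration.

    Class labels are i.i.d. categorical (so class counts are multinomial
    with the configured proportions); the poor-outcome cluster is drawn only
    among MYB-class samples; each MYB/MYBL1 sample independently receives a
    truncation/fusion event per ``fusion_spec``. Oncogene-class exclusivity
    holds by construction: a sample carries exactly one class label.
    """
    genome = genome or default_genome()
    rng = np.random.default_rng(config.seed_children()[0])
    n = config.n_samples
    ids = [f"S{i + 1:03d}" for i in range(n)]
    labels = rng.choice(len(CLASSES), size=n, p=np.asarray(config.class_proportions))
    classes = [CLASSES[i] for i in labels]
    poor = np.array([
        cls == "MYB" and rng.random() < config.poor_outcome_fraction
        for cls in classes
    ])
    sex = np.where(rng.random(n) < config.female_fraction, "F", "M")
    age = np.clip(rng.normal(50.1, 14.1, size=n), 18.0, 90.0)

    fusions: list[FusionTruth] = []
    partner_col, bp_col, pbp_col, trunc_col = [], [], [], []
    for sid, cls in zip(ids, classes):
        partner, bp, pbp = None, None, None
        if cls in ("MYB", "MYBL1"):
            pairs = config.fusion_spec.get(cls, [])
            probs = [q for _, q in pairs]
            u = rng.random()
            cum = 0.0
            for (cand, q) in pairs:
                cum += q
                if u < cum:
                    partner = cand
                    break
            if partner is not None:
                gene = genome.gene(cls)
                # breakpoint in the middle of the body, transcriptional coords:
                # far enough in that the 5' bin stays covered, early enough
                # that the 3' bin stays empty
                tx_frac = rng.uniform(0.40, 0.65)
                lo, hi = gene.tx_interval(tx_frac, min(tx_frac + 0.01, 1.0))
                bp = int(lo) if gene.strand == "+" else int(hi)
                if not gene.start < bp < gene.end:
                    raise ConfigurationError("breakpoint outside gene body")
                if partner != UNKNOWN:
                    pg = genome.gene(partner)
                    pbp = int(rng.integers(pg.start + 500,
                                           pg.end - 500 - config.clip_length))
                fusions.append(FusionTruth(sid, cls, partner, bp, pbp))
        partner_col.append(partner)
        bp_col.append(bp)
        pbp_col.append(pbp)
        trunc_col.append(partner is not None)

    samples = pd.DataFrame(
        {
            "class_label": classes,
            "cluster": np.where(poor, "high_risk", "standard"),
            "sex": sex,
            "age": np.round(age, 1),
            "truncated": trunc_col,
            "partner": partner_col,
            "breakpoint": pd.array(bp_col, dtype="Int64"),
            "partner_breakpoint": pd.array(pbp_col, dtype="Int64"),
        },
        index=pd.Index(ids, name="sample_id"),
    )
    return SyntheticCohort(config, genome, samples, fusions)
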