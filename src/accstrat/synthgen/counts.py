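"""Negative-binomial count simulation with class/cluster signature offsets.

The generative model: counts ~ NB(mu, dispersion) with
log2 mu = log2 baseline + class offset + cluster offset + sex offset
          + log2 library factor,
library factors log-normal across samples. Dispersion is the NB
overdispersion alpha (variance = mu + alpha * mu^2); alpha -> 0 recovers
Poisson noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import SyntheticCohort, ConfigurationError

#: Seed for the fixed gene panel (baselines/dispersions are part of the
#: signature definition, not per-cohort noise).
PANEL_SEED = 8891

ES_SET_SIZE = 30
GOOD_SET_SIZE = 20
PROGRAM_SET_SIZE = 150


@dataclass
class SignatureSpec:
    """Gene panel with per-class and per-cluster log2 offsets."""

    baseline: pd.Series                 # mean counts at library factor 1
    dispersion: pd.Series               # NB alpha per gene
    class_offsets: pd.DataFrame         # genes x (MYB, MYBL1, NEITHER), log2
    cluster_offsets: pd.Series          # log2, applied to high-risk samples
    sex_offsets: pd.Series              # log2, applied to female samples
    library_sigma: float = 0.25

    def __post_init__(self) -> None:
        if (self.dispersion <= 0).any():
            raise ConfigurationError("dispersions must be > 0")
        idx = self.baseline.index
        for other in (self.dispersion, self.cluster_offsets, self.sex_offsets):
            if not other.index.equals(idx):
                raise ConfigurationError("signature gene panels are inconsistent")
        if not self.class_offsets.index.equals(idx):
            raise ConfigurationError("signature gene panels are inconsistent")

    @property
    def genes(self) -> pd.Index:
        return self.baseline.index

    @property
    def es_genes(self) -> list[str]:
        return [g for g in self.genes if g.startswith("ES_")]


def default_signature(n_background: int = 1200) -> SignatureSpec:
    """The default panel: driver/marker genes, a poor-outcome (embryonic
    stem-cell-like) up-set, a good-outcome up-set and log-uniform background.

    Effect sizes are free parameters of the generator, chosen at the scale
    of clear class-specific expression (2-5 log2 units); the reference study
    reports none, so these are not estimates of real tumors.
    """
    rng = np.random.default_rng(PANEL_SEED)
    es_genes = [f"ES_{i + 1:03d}" for i in range(ES_SET_SIZE)]
    good_named = ["SETBP1", "EGFR", "TP63", "PIGR"]
    good_genes = good_named + [f"GO_{i + 1:03d}" for i in range(GOOD_SET_SIZE - len(good_named))]
    program_genes = [f"DM_{i + 1:03d}" for i in range(PROGRAM_SET_SIZE)]
    named = ["MYB", "MYBL1", "SOX4", "EN1", "CXXC4",
             "VGLL3", "KLF4", "FOXO1", "JUNB", "FOSB", "XIST"]
    background = [f"G{i + 1:04d}" for i in range(n_background)]
    genes = pd.Index(named + es_genes + good_genes + program_genes + background,
                     name="gene")

    baseline = pd.Series(10.0, index=genes)
    baseline[named] = [30, 30, 120, 60, 80, 40, 50, 60, 70, 50, 0.02]
    baseline[es_genes] = rng.uniform(300, 1000, size=len(es_genes)).round(1)
    baseline[good_genes] = rng.uniform(300, 1000, size=len(good_genes)).round(1)
    baseline[program_genes] = rng.uniform(300, 1000, size=len(program_genes)).round(1)
    baseline[background] = np.exp(
        rng.uniform(np.log(5.0), np.log(2000.0), size=len(background))
    ).round(1)

    dispersion = pd.Series(rng.uniform(0.08, 0.25, size=len(genes)).round(3), index=genes)

    offsets = pd.DataFrame(0.0, index=genes, columns=["MYB", "MYBL1", "NEITHER"])
    offsets.loc["MYB", ["MYB"]] = 4.0
    offsets.loc["MYBL1", ["MYBL1"]] = 4.0
    for g, eff in (("SOX4", 2.0), ("EN1", 2.5), ("CXXC4", 2.0)):
        offsets.loc[g, ["MYB", "MYBL1"]] = eff
    for g, eff in (("VGLL3", 3.0), ("KLF4", 2.0), ("FOXO1", 2.0),
                   ("JUNB", 2.0), ("FOSB", 2.0)):
        offsets.loc[g, "NEITHER"] = eff
    # the broad MYB/MYBL1-vs-neither expression program: hundreds of genes
    # moderately up or down in the oncogene-expressing classes
    prog_eff = (rng.uniform(1.0, 1.8, size=len(program_genes))
                * rng.choice([-1.0, 1.0], size=len(program_genes))).round(2)
    offsets.loc[program_genes, "MYB"] = prog_eff
    offsets.loc[program_genes, "MYBL1"] = prog_eff

    cluster = pd.Series(0.0, index=genes)
    cluster[es_genes] = rng.uniform(3.0, 4.0, size=len(es_genes)).round(2)
    cluster[good_genes] = -rng.uniform(3.0, 4.0, size=len(good_genes)).round(2)
    cluster["MYB"] = 1.0
    cluster["SOX4"] = 1.0

    sex = pd.Series(0.0, index=genes)
    sex["XIST"] = 12.0

    return SignatureSpec(baseline, dispersion, offsets, cluster, sex)


def simulate_counts(
    cohort: SyntheticCohort,
    sig: SignatureSpec | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw the genes x samples count matrix for a cohort."""
    sig = sig or default_signature()
    if rng is None:
        rng = np.random.default_rng(cohort.config.seed_children()[1])
    classes = cohort.samples["class_label"]
    missing = [c for c in classes.unique() if c not in sig.class_offsets.columns]
    if missing:
        raise ConfigurationError(f"classes without signature offsets: {missing}")

    log2mu = sig.class_offsets[classes].to_numpy()  # genes x samples
    high = (cohort.samples["cluster"] == "high_risk").to_numpy()
    female = (cohort.samples["sex"] == "F").to_numpy()
    log2mu = (log2mu
              + np.outer(sig.cluster_offsets.to_numpy(), high)
              + np.outer(sig.sex_offsets.to_numpy(), female))
    lib = np.exp(rng.normal(0.0, sig.library_sigma, size=len(classes)))
    mu = sig.baseline.to_numpy()[:, None] * (2.0 ** log2mu) * lib[None, :]

    alpha = sig.dispersion.to_numpy()[:, None]
    nb_n = 1.0 / alpha
    nb_p = nb_n / (nb_n + mu)
    counts = rng.negative_binomial(nb_n, nb_p)
    return pd.DataFrame(counts, index=sig.genes, columns=cohort.sample_ids)
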