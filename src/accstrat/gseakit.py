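"""Gene-set enrichment analysis: weighted running-sum enrichment scores,
phenotype-permutation nominal p-values and FDR q-values.

This is the standard weighted Kolmogorov–Smirnov-style formulation: genes
are ranked by a signal-to-noise metric between two phenotype classes; for
each set the running sum gains |metric|^p (normalized over in-set genes) at
hits and loses 1/(N - N_set) at misses; the enrichment score (ES) is the
signed maximum deviation. Null distributions come from permuting phenotype
labels; NES and FDR q follow the positive/negative-pool normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class EnrichmentResult:
    name: str
    size: int
    es: float
    nes: float
    nominal_p: float
    fdr_q: float
    leading_edge: list[str] = field(default_factory=list)
    running_sum: np.ndarray | None = field(default=None, repr=False)


def enrichment_score(
    ranked: pd.Series, gene_set, weight: float = 1.0
) -> tuple[float, np.ndarray]:
    """ES and running-sum profile for one gene set.

    ``ranked`` maps gene id -> ranking metric, ordered descending. Hit
    increments are |metric|^weight normalized over in-set genes; miss
    decrements are uniform 1/(N - N_set). ES is the running-sum value of
    largest magnitude. The sum starts and ends at 0; ES is in [-1, 1].
    """
    genes = np.asarray(ranked.index)
    metric = ranked.to_numpy(dtype=float)
    in_set = np.isin(genes, list(gene_set))
    n_hit = int(in_set.sum())
    n = len(genes)
    if n_hit == 0:
        raise ValueError("gene set does not intersect the ranked universe")
    w = np.abs(metric) ** weight
    hit_mass = w * in_set
    denom = hit_mass.sum()
    if denom == 0:  # all in-set metrics exactly zero: fall back to equal mass
        hit_mass = in_set.astype(float)
        denom = float(n_hit)
    steps = hit_mass / denom
    if n > n_hit:
        steps = steps - (~in_set) / (n - n_hit)
    running = np.cumsum(steps)
    es = float(running[np.argmax(np.abs(running))])
    return es, running


def _signal_to_noise(X: np.ndarray, mask_a: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    A, B = X[:, mask_a], X[:, ~mask_a]
    mu_a, mu_b = A.mean(axis=1), B.mean(axis=1)
    sd_a, sd_b = A.std(axis=1, ddof=1), B.std(axis=1, ddof=1)
    return (mu_a - mu_b) / (sd_a + sd_b + eps)


def rank_genes(matrix: pd.DataFrame, labels: pd.Series, positive_class) -> pd.Series:
    """Signal-to-noise ranking of genes for positive_class vs the rest."""
    mask = (labels.loc[matrix.columns] == positive_class).to_numpy()
    s2n = _signal_to_noise(matrix.to_numpy(dtype=float), mask)
    ranked = pd.Series(s2n, index=matrix.index).sort_values(ascending=False, kind="stable")
    return ranked


def gsea(
    matrix: pd.DataFrame,
    labels: pd.Series,
    sets: dict[str, list[str]],
    n_perm: int = 1000,
    seed: int = 0,
    min_size: int = 15,
    positive_class=None,
    weight: float = 1.0,
) -> list[EnrichmentResult]:
    """Phenotype-permutation GSEA over a gene-set collection.

    Sets whose intersection with the expression matrix has fewer than
    ``min_size`` genes are excluded. Nominal p is the fraction of same-sign
    permutation ES at least as extreme as the observed ES; NES divides ES by
    the mean same-sign permutation ES; FDR q compares the pooled permutation
    NES tail with the observed NES tail. Deterministic given ``seed``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    lab = labels.loc[matrix.columns]
    classes = lab.unique()
    if len(classes) != 2:
        raise ValueError("gsea requires exactly two phenotype classes")
    if positive_class is None:
        positive_class = classes[0]
    counts = lab.value_counts()
    if counts.min() < 3:
        raise ValueError("each class needs >= 3 samples for a stable metric")

    universe = set(matrix.index)
    kept = {name: sorted(universe & set(members)) for name, members in sets.items()}
    kept = {name: m for name, m in kept.items() if len(m) >= min_size}
    if not kept:
        return []

    X = matrix.to_numpy(dtype=float)
    genes = np.asarray(matrix.index)
    mask_obs = (lab == positive_class).to_numpy()
    n_pos = int(mask_obs.sum())

    def all_es(mask: np.ndarray) -> dict[str, float]:
        s2n = _signal_to_noise(X, mask)
        order = np.argsort(-s2n, kind="stable")
        ranked = pd.Series(s2n[order], index=genes[order])
        return {name: enrichment_score(ranked, members, weight)[0]
                for name, members in kept.items()}

    es_obs: dict[str, tuple[float, np.ndarray, list[str]]] = {}
    s2n = _signal_to_noise(X, mask_obs)
    order = np.argsort(-s2n, kind="stable")
    ranked = pd.Series(s2n[order], index=genes[order])
    for name, members in kept.items():
        es, running = enrichment_score(ranked, members, weight)
        in_set = np.isin(ranked.index.to_numpy(), members)
        peak = int(np.argmax(np.abs(running)))
        if es >= 0:
            le = [g for g, h in zip(ranked.index[: peak + 1], in_set[: peak + 1]) if h]
        else:
            le = [g for g, h in zip(ranked.index[peak:], in_set[peak:]) if h]
        es_obs[name] = (es, running, le)

    rng = np.random.default_rng(seed)
    idx = np.arange(X.shape[1])
    perm_es = {name: np.empty(n_perm) for name in kept}
    for b in range(n_perm):
        perm = rng.permutation(idx)
        mask = np.zeros(X.shape[1], dtype=bool)
        mask[perm[:n_pos]] = True
        for name, es in all_es(mask).items():
            perm_es[name][b] = es

    # normalize: divide by mean same-sign permutation ES magnitude
    def nes_of(es: float, null: np.ndarray) -> float:
        same = null[null >= 0] if es >= 0 else null[null < 0]
        if len(same) == 0:
            return np.nan
        return float(es / np.abs(same).mean())

    nes_obs = {name: nes_of(es_obs[name][0], perm_es[name]) for name in kept}
    nes_null: list[float] = []
    for name in kept:
        null = perm_es[name]
        for v in null:
            nes_null.append(nes_of(v, null))
    nes_null_arr = np.asarray([v for v in nes_null if np.isfinite(v)])
    nes_obs_arr = np.asarray([v for v in nes_obs.values() if np.isfinite(v)])

    results = []
    for name, members in kept.items():
        es, running, le = es_obs[name]
        null = perm_es[name]
        same = null[null >= 0] if es >= 0 else null[null < 0]
        if len(same) == 0:
            p = 1.0 / n_perm
        else:
            p = float((np.abs(same) >= abs(es)).sum()) / len(same)
        nes = nes_obs[name]
        if not np.isfinite(nes):
            q = 1.0
        elif nes >= 0:
            num = (nes_null_arr >= nes).mean() if len(nes_null_arr) else 1.0
            den = (nes_obs_arr >= nes).mean()
            q = num / den if den > 0 else 1.0
        else:
            num = (nes_null_arr <= nes).mean() if len(nes_null_arr) else 1.0
            den = (nes_obs_arr <= nes).mean()
            q = num / den if den > 0 else 1.0
        results.append(
            EnrichmentResult(name, len(members), es, nes, min(p, 1.0),
                             float(min(q, 1.0)), le, running)
        )
    results.sort(key=lambda r: (-abs(r.nes) if np.isfinite(r.nes) else 0.0))
    return results


def results_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    """Tabular view with the conventional column names."""
    return pd.DataFrame(
        [
            {
                "GENESET NAME": r.name,
                "SIZE": r.size,
                "ES": r.es,
                "NES": r.nes,
                "NOM p-val": r.nominal_p,
                "FDR q-val": r.fdr_q,
            }
            for r in results
        ]
    )
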