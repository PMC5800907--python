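"""Count-matrix QC, filtering, normalization, PCA and differential expression.

The count matrix convention throughout the package is a pandas DataFrame of
non-negative integers with genes as rows and samples as columns; library
size is the column sum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


class QCError(ValueError):
    pass


def _validate_counts(counts: pd.DataFrame) -> None:
    if counts.index.duplicated().any():
        raise ValueError("duplicate gene ids")
    if counts.columns.duplicated().any():
        raise ValueError("duplicate sample ids")


def qc_samples(
    counts: pd.DataFrame,
    clinical: pd.DataFrame,
    qc_fraction: float = 0.10,
    xist_gene: str = "XIST",
    xist_cpm_threshold: float = 1.0,
    total_reads: pd.Series | None = None,
    exon_reads: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-sample QC: low-read flag and XIST-based sex concordance.

    A sample fails when its total reads fall below ``qc_fraction`` of the
    cohort median (total reads default to the library size when no mapping
    totals are supplied). Sex discordance: XIST CPM above threshold with
    reported male, or below with reported female. Exon fraction is reported
    but never gates.
    """
    _validate_counts(counts)
    missing = [s for s in counts.columns if s not in clinical.index]
    if missing:
        raise QCError(f"samples missing from clinical table: {missing}")
    lib = counts.sum(axis=0).astype(float)
    total = lib if total_reads is None else total_reads.reindex(counts.columns).astype(float)
    exon = lib if exon_reads is None else exon_reads.reindex(counts.columns).astype(float)
    median_total = float(total.median())
    fail = total < qc_fraction * median_total

    if xist_gene in counts.index:
        xist_cpm = counts.loc[xist_gene] / lib * 1e6
    else:
        xist_cpm = pd.Series(np.nan, index=counts.columns)
    sex = clinical.loc[counts.columns, "sex"].astype(str).str.upper().str[0]
    xist_female = xist_cpm > xist_cpm_threshold
    discordant = (xist_female & (sex == "M")) | (~xist_female & (sex == "F"))
    discordant[xist_cpm.isna()] = False

    return pd.DataFrame(
        {
            "total_reads": total,
            "exon_reads": exon,
            "exon_fraction": exon / total,
            "low_reads_fail": fail,
            "xist_cpm": xist_cpm,
            "reported_sex": sex,
            "sex_discordant": discordant,
        },
        index=counts.columns,
    )


def filter_high_expression(
    counts: pd.DataFrame, min_count: int = 250, min_samples: int = 10
) -> pd.DataFrame:
    """Keep genes with >= min_count reads in >= min_samples samples."""
    _validate_counts(counts)
    keep = (counts >= min_count).sum(axis=1) >= min_samples
    return counts.loc[keep]


def normalize_log_cpm(counts: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """log2(count * 1e6 / library_size + pseudocount)."""
    lib = counts.sum(axis=0).astype(float)
    if (lib <= 0).any():
        bad = list(lib.index[lib <= 0])
        raise ValueError(f"zero library size for samples: {bad}")
    return np.log2(counts / lib * 1e6 + pseudocount)


@dataclass
class PCAResult:
    scores: pd.DataFrame       # samples x components
    loadings: pd.DataFrame     # genes x components
    explained_variance_ratio: np.ndarray


def pca(matrix: pd.DataFrame, n_components: int | None = None) -> PCAResult:
    """PCA of samples from the gene-wise centered matrix, via SVD.

    Sign convention: on each component the loading with largest absolute
    value is made positive, so results are fully deterministic.
    """
    if matrix.shape[1] < 2:
        raise ValueError("PCA requires at least two samples")
    X = matrix.to_numpy(dtype=float).T  # samples x genes
    Xc = X - X.mean(axis=0)
    total_var = float((Xc ** 2).sum()) / (X.shape[0] - 1)
    if total_var == 0:
        raise ValueError("matrix has zero variance; PCA undefined")
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    k = n_components or len(s)
    U, s, Vt = U[:, :k], s[:k], Vt[:k]
    flip = np.sign(Vt[np.arange(len(s)), np.abs(Vt).argmax(axis=1)])
    flip[flip == 0] = 1.0
    Vt = Vt * flip[:, None]
    U = U * flip[None, :]
    comp = [f"PC{i + 1}" for i in range(len(s))]
    return PCAResult(
        scores=pd.DataFrame(U * s, index=matrix.columns, columns=comp),
        loadings=pd.DataFrame(Vt.T, index=matrix.index, columns=comp),
        explained_variance_ratio=s ** 2 / (X.shape[0] - 1) / total_var,
    )


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(pvals, dtype=float)
    if p.size and ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def differential_expression(
    matrix: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    lfc_threshold: float = 1.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Welch two-sample test per gene on a log2 expression matrix.

    log2FC = mean(A) - mean(B); significance requires |log2FC| >=
    ``lfc_threshold`` (2-fold by default) AND BH-adjusted p <= ``alpha``.
    """
    if set(group_a) & set(group_b):
        raise ValueError("groups overlap")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least two samples")
    A = matrix[group_a].to_numpy(dtype=float)
    B = matrix[group_b].to_numpy(dtype=float)
    lfc = A.mean(axis=1) - B.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = stats.ttest_ind(A, B, axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)
    adj = bh_adjust(p)
    return pd.DataFrame(
        {
            "log2fc": lfc,
            "pvalue": p,
            "adj_pvalue": adj,
            "significant": (np.abs(lfc) >= lfc_threshold) & (adj <= alpha),
        },
        index=matrix.index,
    )


@dataclass
class SamResult:
    table: pd.DataFrame  # per gene: slope, se, d, fdr
    s0: float


def sam_correlate(
    matrix: pd.DataFrame,
    response,
    n_perm: int = 1000,
    seed: int = 0,
    s0: float | None = None,
) -> SamResult:
    """SAM-style regularized regression statistic against a quantitative response.

    Per gene, d = slope / (se + s0) from the least-squares regression of the
    gene's expression on the response (e.g. a PCA score). s0 defaults to the
    median per-gene slope standard error. The per-gene FDR is the
    median-false-call permutation estimate at the cutoff |d_gene|: the
    median over permutations of the number of null |d| at least as large,
    divided by the observed count.
    """
    y = np.asarray(response, dtype=float)
    if len(y) != matrix.shape[1]:
        raise ValueError("response length must equal the number of samples")
    if np.ptp(y) == 0:
        raise ValueError("constant response")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    X = matrix.to_numpy(dtype=float)
    n = len(y)

    def slope_se(yv: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        yc = yv - yv.mean()
        sxx = float(yc @ yc)
        slopes = X @ yc / sxx
        resid = X - X.mean(axis=1, keepdims=True) - slopes[:, None] * yc[None, :]
        mse = (resid ** 2).sum(axis=1) / max(n - 2, 1)
        return slopes, np.sqrt(mse / sxx)

    slopes, se = slope_se(y)
    s0_val = float(np.median(se)) if s0 is None else float(s0)
    d = slopes / (se + s0_val)

    rng = np.random.default_rng(seed)
    abs_d = np.abs(d)
    order = np.argsort(abs_d)[::-1]
    # observed count at cutoff |d_i| = rank of i among descending |d|
    obs_count = np.empty(len(d), dtype=float)
    obs_count[order] = np.arange(1, len(d) + 1)
    null_counts = np.zeros((n_perm, len(d)))
    for b in range(n_perm):
        sl_p, se_p = slope_se(rng.permutation(y))
        d_p = np.abs(sl_p / (se_p + s0_val))
        null_counts[b] = np.searchsorted(np.sort(d_p), abs_d, side="left")
        null_counts[b] = len(d) - null_counts[b]
    fdr = np.clip(np.median(null_counts, axis=0) / obs_count, 0.0, 1.0)
    table = pd.DataFrame(
        {"slope": slopes, "se": se, "d": d, "fdr": fdr}, index=matrix.index
    )
    return SamResult(table=table, s0=s0_val)
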