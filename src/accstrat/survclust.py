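"""Unsupervised clustering into risk groups and survival statistics.

Kaplan–Meier estimation (product-limit, Greenwood variance, log-transformed
CIs, median = smallest event time with S <= 0.5) and Cox
proportional-hazards fitting (Newton–Raphson on the Efron- or Breslow-tied
partial likelihood) are implemented directly so their conventions and
convergence tolerances are fully pinned down; the log-rank test is
delegated to lifelines behind this module's interface.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from scipy.stats import norm

from lifelines.statistics import multivariate_logrank_test

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------- clustering

@dataclass
class Dendrogram:
    """Agglomerative merge tree over samples.

    ``linkage`` is the scipy (n-1, 4) merge table; ``labels`` the leaf
    sample ids in input order.
    """

    linkage: np.ndarray
    labels: list[str]

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    @property
    def leaf_order(self) -> list[str]:
        return [self.labels[i] for i in hierarchy.leaves_list(self.linkage)]

    def to_newick(self) -> str:
        """Nested-parenthesis text rendering with merge heights as lengths."""
        n = len(self.labels)
        nodes: dict[int, tuple[str, float]] = {i: (self.labels[i], 0.0) for i in range(n)}
        for k, (a, b, h, _) in enumerate(self.linkage):
            (na, ha), (nb, hb) = nodes[int(a)], nodes[int(b)]
            rep = f"({na}:{h - ha:.6g},{nb}:{h - hb:.6g})"
            nodes[n + k] = (rep, float(h))
        return nodes[n + len(self.linkage) - 1][0] + ";"


def hierarchical_cluster(matrix: pd.DataFrame) -> Dendrogram:
    """Complete-linkage clustering of samples with Euclidean distance.

    ``matrix`` is genes x samples; samples are clustered on their gene
    vectors.
    """
    X = matrix.to_numpy(dtype=float).T
    if np.isnan(X).any():
        raise ValueError("NaN values in clustering matrix")
    if X.shape[0] < 2:
        raise ValueError("need at least two samples")
    Z = hierarchy.linkage(pdist(X, metric="euclidean"), method="complete")
    return Dendrogram(linkage=Z, labels=list(matrix.columns))


def cut_groups(dendro: Dendrogram, k: int) -> pd.Series:
    """Cut into exactly k clusters; groups numbered by size, smallest first.

    The minority cluster becomes Group 1 (the poor-outcome convention);
    ties in size are broken by the leftmost leaf.
    """
    n = len(dendro.labels)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    raw = hierarchy.fcluster(dendro.linkage, t=k, criterion="maxclust")
    if len(np.unique(raw)) != k:
        raise ValueError(
            f"cannot produce exactly {k} clusters (tied merge heights yield "
            f"{len(np.unique(raw))})"
        )
    sizes = pd.Series(raw).value_counts()
    first_leaf = {c: int(np.argmax(raw == c)) for c in sizes.index}
    ordered = sorted(sizes.index, key=lambda c: (sizes[c], first_leaf[c]))
    remap = {c: i + 1 for i, c in enumerate(ordered)}
    return pd.Series([remap[c] for c in raw], index=dendro.labels, name="group")


# ------------------------------------------------------------ Kaplan–Meier

@dataclass
class KMCurve:
    times: np.ndarray            # distinct event times
    survival: np.ndarray         # S(t) just after each event time
    std_err: np.ndarray          # Greenwood SE of S(t)
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    median: float | None
    n: int = 0
    n_events: int = 0

    def survival_at(self, t: float) -> float:
        """Step-function value of S at time t."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(times, events, alpha: float = 0.05) -> KMCurve:
    """Product-limit estimate with Greenwood variance and log-transformed CIs.

    Median survival is the smallest observed event time with S <= 0.5, or
    None when the curve never reaches 0.5.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.shape != e.shape:
        raise ValueError("times and events must have equal length")
    if (t < 0).any():
        raise ValueError("negative survival times")
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    if e.sum() == 0:
        logger.warning("all observations censored; KM curve is degenerate")
        return KMCurve(np.array([]), np.array([]), np.array([]), np.array([]),
                       np.array([]), None, n=len(t), n_events=0)

    event_times = np.unique(t[e == 1])
    n_at_risk = np.array([(t >= u).sum() for u in event_times], dtype=float)
    d = np.array([((t == u) & (e == 1)).sum() for u in event_times], dtype=float)
    surv = np.cumprod(1.0 - d / n_at_risk)
    # Greenwood: Var(S) = S^2 * sum d / (n (n - d)); log CI uses Var(log S)
    with np.errstate(divide="ignore", invalid="ignore"):
        var_log = np.cumsum(np.where(n_at_risk > d, d / (n_at_risk * (n_at_risk - d)), np.inf))
    with np.errstate(invalid="ignore"):
        se = surv * np.sqrt(var_log)
    z = float(-norm.ppf(alpha / 2))
    with np.errstate(divide="ignore", invalid="ignore"):
        lo = surv * np.exp(-z * np.sqrt(var_log))
        hi = surv * np.exp(z * np.sqrt(var_log))
    lo = np.clip(np.where(np.isfinite(lo), lo, 0.0), 0.0, 1.0)
    hi = np.clip(np.where(np.isfinite(hi), hi, 1.0), 0.0, 1.0)
    below = surv <= 0.5
    median = float(event_times[below][0]) if below.any() else None
    return KMCurve(event_times, surv, np.where(np.isfinite(se), se, 0.0),
                   lo, hi, median, n=len(t), n_events=int(e.sum()))


def logrank_test(times, events, groups) -> tuple[float, float]:
    """Log-rank chi-square test across k groups (k-1 df)."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    g = np.asarray(groups)
    if len(np.unique(g)) < 2:
        raise ValueError("log-rank test requires at least two groups")
    if e.sum() < 1:
        raise ValueError("log-rank test requires at least one event")
    res = multivariate_logrank_test(t, g, e)
    return float(res.test_statistic), float(res.p_value)


# -------------------------------------------------------------------- Cox

@dataclass
class CoxFit:
    summary: pd.DataFrame        # coef, hr, ci_lower, ci_upper, se, p per covariate
    log_likelihood: float
    converged: bool
    n: int
    n_events: int


def _cox_ll_grad_hess(beta, X, t, e, ties):
    """Partial log-likelihood, gradient and Hessian (Efron or Breslow ties).

    Observations must be pre-sorted by time. The risk set at event time u is
    everyone with t >= u; Efron down-weights tied events' own contribution
    within the tie group.
    """
    n, p = X.shape
    eta = X @ beta
    w = np.exp(eta)
    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    for u in np.unique(t[e == 1]):
        dead = (t == u) & (e == 1)
        risk = t >= u
        d = int(dead.sum())
        Xd, wd = X[dead], w[dead]
        Xr, wr = X[risk], w[risk]
        s0_r = wr.sum()
        s1_r = wr @ Xr
        s2_r = (wr[:, None] * Xr).T @ Xr
        s0_d = wd.sum()
        s1_d = wd @ Xd
        s2_d = (wd[:, None] * Xd).T @ Xd
        ll += eta[dead].sum()
        fracs = (np.arange(d) / d) if ties == "efron" else np.zeros(d)
        for frac in fracs:
            phi0 = s0_r - frac * s0_d
            phi1 = s1_r - frac * s1_d
            phi2 = s2_r - frac * s2_d
            ll -= np.log(phi0)
            m = phi1 / phi0
            grad -= m
            hess -= phi2 / phi0 - np.outer(m, m)
        grad += Xd.sum(axis=0)
    return ll, grad, hess


def cox_fit(covariates: pd.DataFrame, times, events, ties: str = "efron",
            tol: float = 1e-8, max_iter: int = 60) -> CoxFit:
    """Cox proportional-hazards fit by Newton–Raphson on the partial likelihood.

    ``ties`` selects the Efron (default) or Breslow approximation; iteration
    stops when the gradient sup-norm drops below ``tol``. Constant covariates
    or datasets with no events are rejected; non-convergence (e.g. monotone
    likelihood under separation) is flagged on the result, not silently
    reported.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError("ties must be 'efron' or 'breslow'")
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if e.sum() == 0:
        raise ValueError("no events; Cox model undefined")
    const = [c for c in covariates.columns if covariates[c].nunique() <= 1]
    if const:
        raise ValueError(f"constant covariates: {const}")
    names = list(covariates.columns)
    X = covariates.to_numpy(dtype=float)
    order = np.argsort(t, kind="stable")
    X, t, e = X[order], t[order], e[order]
    # center covariates for numerical stability (shift-invariant estimates)
    center = X.mean(axis=0)
    Xc = X - center

    beta = np.zeros(X.shape[1])
    converged = False
    ll = -np.inf
    for _ in range(max_iter):
        ll_new, grad, hess = _cox_ll_grad_hess(beta, Xc, t, e, ties)
        if not np.isfinite(ll_new) or np.abs(beta).max() > 50:
            break
        if np.abs(grad).max() < tol:
            ll = ll_new
            converged = True
            break
        try:
            step = np.linalg.solve(hess, -grad)
        except np.linalg.LinAlgError:
            break
        # step-halving safeguard; the acceptance slack must exceed the
        # floating-point noise floor of the log-likelihood itself
        slack = 1e-10 * (1.0 + abs(ll_new))
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            ll_cand, _, _ = _cox_ll_grad_hess(cand, Xc, t, e, ties)
            if np.isfinite(ll_cand) and ll_cand >= ll_new - slack:
                break
            scale /= 2.0
        beta = beta + scale * step
        ll = ll_new
    else:
        converged = False

    if converged and np.abs(beta).max() > 20:
        # gradient can vanish numerically on a monotone likelihood plateau
        logger.warning("Cox fit drifted to |coef| > 20: monotone likelihood "
                       "(separation) suspected")
        converged = False

    if not converged:
        logger.warning("Cox fit did not converge (possible separation)")
        return CoxFit(pd.DataFrame(), float("nan"), False, len(t), int(e.sum()))

    _, _, hess = _cox_ll_grad_hess(beta, Xc, t, e, ties)
    info = -hess
    se = np.sqrt(np.diag(np.linalg.inv(info)))
    z = beta / se
    pvals = 2.0 * norm.sf(np.abs(z))
    summary = pd.DataFrame(
        {
            "coef": beta,
            "hr": np.exp(beta),
            "ci_lower": np.exp(beta - 1.96 * se),
            "ci_upper": np.exp(beta + 1.96 * se),
            "se": se,
            "pvalue": pvals,
        },
        index=pd.Index(names, name="covariate"),
    )
    return CoxFit(summary, float(ll), True, len(t), int(e.sum()))


def marker_screen(genes: list[str], log_cpm: pd.DataFrame,
                  clinical: pd.DataFrame) -> pd.DataFrame:
    """Univariate Cox screen of candidate prognosis markers.

    Each gene's standardized log2-CPM enters a univariate Cox model against
    overall survival; output rows carry (gene, HR, 95% CI, p). Zero-variance
    genes are flagged and not fitted.
    """
    missing = [g for g in genes if g not in log_cpm.index]
    if missing:
        raise ValueError(f"genes absent from matrix: {missing}")
    samples = [s for s in log_cpm.columns if s in clinical.index]
    t = clinical.loc[samples, "os_months"]
    e = clinical.loc[samples, "event"]
    rows = []
    for g in genes:
        x = log_cpm.loc[g, samples].astype(float)
        if x.std(ddof=0) == 0:
            rows.append((g, np.nan, np.nan, np.nan, np.nan, "zero_variance"))
            continue
        z = (x - x.mean()) / x.std(ddof=0)
        fit = cox_fit(pd.DataFrame({"expr": z.to_numpy()}), t.to_numpy(), e.to_numpy())
        if not fit.converged or fit.summary.empty:
            rows.append((g, np.nan, np.nan, np.nan, np.nan, "no_convergence"))
            continue
        r = fit.summary.iloc[0]
        rows.append((g, r["hr"], r["ci_lower"], r["ci_upper"], r["pvalue"], "ok"))
    return pd.DataFrame(rows, columns=["gene", "hr", "ci_lower", "ci_upper",
                                       "pvalue", "status"]).set_index("gene")


def multivariate_fit(clinical: pd.DataFrame, groups: pd.Series) -> CoxFit:
    """Multivariate Cox model: age per decade, metastasis status, cluster group.

    Rows with missing covariates are dropped (with a logged count); the
    cluster covariate is an indicator for the poor-outcome Group 1.
    """
    df = clinical.copy()
    df["group1"] = (groups.reindex(df.index) == 1).astype(float)
    met = df["metastasis"]
    if met.dtype == object:
        met = met.astype(str).str.lower().map({"yes": 1.0, "no": 0.0})
    cov = pd.DataFrame(
        {
            "age_per_10y": df["age"].astype(float) / 10.0,
            "metastasis": met.astype(float),
            "group1": df["group1"],
        },
        index=df.index,
    )
    keep = cov.notna().all(axis=1) & df["os_months"].notna() & df["event"].notna()
    dropped = int((~keep).sum())
    if dropped:
        logger.info("multivariate_fit: dropped %d incomplete rows", dropped)
    cov = cov[keep]
    return cox_fit(cov, df.loc[keep, "os_months"].to_numpy(),
                   df.loc[keep, "event"].to_numpy())
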