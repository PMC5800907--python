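"""Independent brute-force oracles used by the test suite.

These deliberately reimplement the algorithms with naive loops so they stay
independent of the library code paths they check.
"""

import itertools

import numpy as np
from scipy import stats
from scipy.spatial.distance import pdist, squareform


def brute_force_regions(track, params):
    """Naive window-scan + merge region caller."""
    genome_len = params.effective_genome_length or len(track.depth)
    lam = track.total_reads * params.window_size / genome_len
    w = params.window_size
    threshold = stats.poisson.isf(params.pvalue, lam)
    sig = []
    for start in range(0, len(track.depth), w):
        count = track.depth[start:start + w].sum() / params.read_length
        if count > threshold and count >= params.min_fold * lam:
            sig.append(start)
    merged = []
    for s in sig:
        if merged and s - merged[-1][1] < params.merge_distance:
            merged[-1] = (merged[-1][0], s + w)
        else:
            merged.append((s, s + w))
    return [(a, min(b, len(track.depth))) for a, b in merged]


def complete_linkage_oracle(X):
    """O(n^3) agglomerative complete linkage; yields (setA, setB, height)."""
    D = squareform(pdist(X))
    clusters = [frozenset([i]) for i in range(len(X))]
    merges = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            d = max(D[i, j] for i in clusters[a] for j in clusters[b])
            if best is None or d < best[0]:
                best = (d, a, b)
        d, a, b = best
        merges.append((clusters[a], clusters[b], d))
        merged_set = clusters[a] | clusters[b]
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)]
        clusters.append(merged_set)
    return merges


def merges_from_linkage(Z, n):
    members = {i: frozenset([i]) for i in range(n)}
    out = []
    for k, (a, b, h, _) in enumerate(Z):
        sa, sb = members[int(a)], members[int(b)]
        out.append((sa, sb, float(h)))
        members[n + k] = sa | sb
    return out


def efron_neg_loglik(beta, x, t, e):
    """Negative Efron-tied Cox partial log-likelihood, single covariate."""
    ll = 0.0
    for u in np.unique(t[e == 1]):
        dead = (t == u) & (e == 1)
        risk = t >= u
        d = int(dead.sum())
        s = x[dead].sum()
        sum_risk = np.exp(beta * x[risk]).sum()
        sum_dead = np.exp(beta * x[dead]).sum()
        ll += beta * s
        for l in range(d):
            ll -= np.log(sum_risk - (l / d) * sum_dead)
    return -ll


def brute_force_es(ranked, gene_set, p=1.0):
    """Hand-stepped GSEA running sum."""
    in_set = [g in gene_set for g in ranked.index]
    n, nh = len(ranked), sum(in_set)
    denom = sum(abs(m) ** p for m, h in zip(ranked, in_set) if h)
    run, best = 0.0, 0.0
    profile = []
    for m, h in zip(ranked, in_set):
        if h:
            run += abs(m) ** p / denom
        else:
            run -= 1.0 / (n - nh)
        profile.append(run)
        if abs(run) > abs(best):
            best = run
    return best, profile
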