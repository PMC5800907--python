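import numpy as np
import pandas as pd
import pytest

from accstrat import exprmat, peakclass
from accstrat.synthgen import (
    CohortConfig, SurvivalSpec, default_genome, default_signature,
    generate_cohort, simulate_counts, simulate_reads, simulate_survival,
)
from accstrat.synthgen.cohort import ConfigurationError
from accstrat.synthgen.reads import DEFAULT_EXPRESSION
from accstrat.survclust import km_estimate, logrank_test


# ------------------------------------------------------------- cohort

def test_cohort_determinism(genome):
    a = generate_cohort(CohortConfig(seed=5), genome)
    b = generate_cohort(CohortConfig(seed=5), genome)
    pd.testing.assert_frame_equal(a.samples, b.samples)
    assert a.fusions == b.fusions
    ca = simulate_counts(a)
    cb = simulate_counts(b)
    pd.testing.assert_frame_equal(ca, cb)


def test_invalid_proportions_rejected():
    with pytest.raises(ConfigurationError):
        CohortConfig(class_proportions=(0.5, 0.5, 0.5))
    with pytest.raises(ConfigurationError):
        CohortConfig(depth_mean=-1)


def test_no_poor_outcome_when_fraction_zero(genome):
    cohort = generate_cohort(CohortConfig(seed=3, poor_outcome_fraction=0.0), genome)
    assert (cohort.samples["cluster"] == "standard").all()


def test_class_counts_converge_to_proportions(genome):
    counts = np.zeros(3)
    seeds = range(30)
    for s in seeds:
        cohort = generate_cohort(CohortConfig(seed=s), genome)
        vc = cohort.samples["class_label"].value_counts()
        counts += [vc.get("MYB", 0), vc.get("MYBL1", 0), vc.get("NEITHER", 0)]
    mean = counts / len(list(seeds))
    assert mean[0] == pytest.approx(49, abs=2.5)
    assert mean[1] == pytest.approx(7, abs=1.5)
    assert mean[2] == pytest.approx(12, abs=2.0)


def test_oncogene_class_exclusivity(genome):
    for s in range(5):
        cohort = generate_cohort(CohortConfig(seed=s), genome)
        assert cohort.samples["class_label"].isin(["MYB", "MYBL1", "NEITHER"]).all()
        myb_trunc = cohort.samples.query("truncated and class_label == 'MYBL1'")
        assert (myb_trunc["partner"] != "MYB").all()  # fusions anchor in own class


# ------------------------------------------------------------- counts

def test_counts_null_offsets_give_no_de(genome, signature):
    sig = default_signature()
    sig.class_offsets.loc[:, :] = 0.0
    sig.cluster_offsets.loc[:] = 0.0
    cohort = generate_cohort(CohortConfig(seed=7, n_samples=40), genome)
    counts = simulate_counts(cohort, sig)
    log_cpm = exprmat.normalize_log_cpm(counts)
    cls = cohort.samples["class_label"]
    a = list(cls.index[cls.isin(["MYB", "MYBL1"])])
    b = list(cls.index[cls == "NEITHER"])
    de = exprmat.differential_expression(log_cpm, a, b)
    assert de["significant"].sum() <= 3


def test_counts_offset_gives_fold_change(genome):
    cohort = generate_cohort(CohortConfig(seed=2, n_samples=400,
                                          class_proportions=(0.5, 0.0, 0.5),
                                          poor_outcome_fraction=0.0), genome)
    sig = default_signature()
    sig.library_sigma = 0.0
    counts = simulate_counts(cohort, sig)
    cls = cohort.samples["class_label"]
    ratio = (counts.loc["SOX4", cls == "MYB"].mean()
             / counts.loc["SOX4", cls == "NEITHER"].mean())
    assert ratio == pytest.approx(4.0, rel=0.15)


def test_counts_poisson_limit_small_dispersion(genome):
    cohort = generate_cohort(CohortConfig(seed=4, n_samples=600), genome)
    sig = default_signature()
    sig.dispersion.loc[:] = 1e-8
    sig.class_offsets.loc[:, :] = 0.0
    sig.cluster_offsets.loc[:] = 0.0
    sig.library_sigma = 0.0
    counts = simulate_counts(cohort, sig)
    x = counts.loc["SOX4"]
    assert x.var() / x.mean() == pytest.approx(1.0, rel=0.25)


def test_counts_missing_class_offsets_error(genome, signature):
    cohort = generate_cohort(CohortConfig(seed=1, n_samples=10), genome)
    sig = default_signature()
    bad = sig.class_offsets.drop(columns=["NEITHER"])
    sig.class_offsets = bad
    with pytest.raises(ConfigurationError):
        simulate_counts(cohort, sig)


# -------------------------------------------------------------- reads

def test_reads_no_expression_only_background(genome):
    cfg = CohortConfig(seed=9, depth_mean=20_000)
    rng = np.random.default_rng(0)
    res = simulate_reads(genome, {}, cfg, rng)
    params = peakclass.PeakParams(effective_genome_length=genome.total_length)
    for chrom, track in res.tracks.items():
        assert peakclass.call_regions(track, params) == []


def test_reads_exon_fraction_hits_target(genome):
    cfg = CohortConfig(seed=9, depth_mean=100_000)
    rng = np.random.default_rng(1)
    res = simulate_reads(genome, DEFAULT_EXPRESSION["MYB"], cfg, rng)
    assert res.exon_fraction_realized == pytest.approx(0.09, abs=0.02)


def test_reads_planted_junction_reads_counted(genome):
    cfg = CohortConfig(seed=9, n_junction_reads=5)
    rng = np.random.default_rng(2)
    myb = genome.gene("MYB")
    nfib = genome.gene("NFIB")
    bp = myb.start + 8_000
    pbp = nfib.start + 3_000
    res = simulate_reads(genome, DEFAULT_EXPRESSION["MYB"], cfg, rng,
                         truncated_gene="MYB", breakpoint=bp,
                         partner="NFIB", partner_breakpoint=pbp)
    expected = genome.sequences[nfib.chrom][pbp: pbp + cfg.clip_length]
    matching = [r for r in res.clipped_reads if r.clip_seq == expected]
    assert len(matching) == 5


def test_reads_no_coverage_past_breakpoint(genome):
    cfg = CohortConfig(seed=9, n_junction_reads=0)
    rng = np.random.default_rng(3)
    myb = genome.gene("MYB")
    bp = myb.start + 8_000
    res = simulate_reads(genome, {"MYB": 1.0}, cfg, rng,
                         truncated_gene="MYB", breakpoint=bp, partner="UNKNOWN")
    track = res.tracks[myb.chrom]
    # plus-strand gene: past the breakpoint only uniform background remains
    after = track.depth[bp + cfg.read_length: myb.end].mean()
    before = track.depth[myb.start: bp].mean()
    assert before > 50 * max(after, 1e-9)


def test_reads_breakpoint_outside_body_errors(genome):
    cfg = CohortConfig(seed=9)
    with pytest.raises(ConfigurationError):
        simulate_reads(genome, {"MYB": 1.0}, cfg, np.random.default_rng(0),
                       truncated_gene="MYB", breakpoint=10, partner="UNKNOWN")


# ----------------------------------------------------------- survival

def test_survival_exponential_median_recovered(genome):
    cfg = CohortConfig(seed=6, n_samples=500, poor_outcome_fraction=1.0,
                       class_proportions=(1.0, 0.0, 0.0))
    cohort = generate_cohort(cfg, genome)
    spec = SurvivalSpec(rates={"high_risk": np.log(2) / 28.0,
                               "standard": np.log(2) / 147.0},
                        censoring_window=10_000.0,
                        metastasis_prob={"high_risk": 0.0, "standard": 0.0},
                        hr_age_per_10y=1.0, hr_metastasis=1.0)
    clin = simulate_survival(cohort, spec)
    km = km_estimate(clin["os_months"], clin["event"])
    assert km.median == pytest.approx(28.0, rel=0.15)


def test_survival_censoring_window_zero_rejected():
    with pytest.raises(ConfigurationError):
        SurvivalSpec(censoring_window=0.0)


def test_survival_equal_rates_null_logrank(genome):
    pvals = []
    for s in range(30):
        cfg = CohortConfig(seed=100 + s, n_samples=60, poor_outcome_fraction=0.3,
                           class_proportions=(1.0, 0.0, 0.0))
        cohort = generate_cohort(cfg, genome)
        rate = np.log(2) / 60.0
        spec = SurvivalSpec(rates={"high_risk": rate, "standard": rate},
                            metastasis_prob={"high_risk": 0.3, "standard": 0.3},
                            hr_age_per_10y=1.0, hr_metastasis=1.0)
        clin = simulate_survival(cohort, spec)
        groups = cohort.samples["cluster"]
        if groups.nunique() < 2 or clin["event"].sum() == 0:
            continue
        _, p = logrank_test(clin["os_months"], clin["event"], groups)
        pvals.append(p)
    pvals = np.asarray(pvals)
    # under the null, p-values are roughly uniform
    assert (pvals < 0.05).mean() <= 0.2
    assert pvals.mean() == pytest.approx(0.5, abs=0.25)


def test_survival_determinism(genome):
    cohort1 = generate_cohort(CohortConfig(seed=12), genome)
    cohort2 = generate_cohort(CohortConfig(seed=12), genome)
    pd.testing.assert_frame_equal(simulate_survival(cohort1),
                                  simulate_survival(cohort2))
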