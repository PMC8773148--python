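import numpy as np
import pandas as pd
import pytest

from conftest import make_records
from nemquant import (
    DataValidationError,
    ExcessOfAdaptation,
    InfeasibleSamplingError,
    MatchingScheme,
    excess_curve,
    generate_gene_stats,
    go_excess,
    matched_sample,
    preset_config,
    quantify_excess,
)
from nemquant.excess import gene_adaptation, group_adaptation, include_genes


# -- inclusion and adaptation means ----------------------------------------

def test_include_genes_threshold_one_keeps_all():
    rec = make_records(["a", "b"], ["NEM", "NONNEM"], [0.99, 1e-7], [0.1, 0.1])
    assert len(include_genes(rec, 1.0)) == 2
    with pytest.raises(DataValidationError):
        include_genes(rec, 0.0)


def test_include_genes_nested_thresholds():
    rec = generate_gene_stats(preset_config("null", n_nem=300, n_nonnem=700, seed=6))
    ids = lambda df: set(df["gene_id"])
    assert ids(include_genes(rec, 1e-5)) <= ids(include_genes(rec, 0.5)) <= ids(
        include_genes(rec, 0.9)
    )


def test_include_genes_count_matches_generator_mixture():
    rec = generate_gene_stats(preset_config("null", n_nem=2000, n_nonnem=8000, seed=6))
    share = 0.65 * 0.5 + 0.30 + 0.05  # null genes pass p<=0.5 half the time
    count = len(include_genes(rec, 0.5))
    se = np.sqrt(share * (1 - share) * 10000)
    assert abs(count - share * 10000) < 3 * se


def test_gene_adaptation_is_branch_mean():
    assert gene_adaptation([0.0, 0.0, 0.0]) == 0.0
    assert gene_adaptation([0.0, 0.1, 0.0, 0.3]) == pytest.approx(0.1)
    rng = np.random.default_rng(0)
    for _ in range(20):
        v = rng.uniform(size=rng.integers(1, 30))
        assert gene_adaptation(v) == pytest.approx(sum(v) / len(v))
    with pytest.raises(DataValidationError):
        gene_adaptation([])


def test_group_adaptation_oracle():
    rec = make_records(
        ["a", "b"],
        ["NEM", "NEM"],
        [0.1, 0.1],
        [0.1, 0.1],
        branch_sel_prop=[np.array([0.02]), np.array([0.06])],
    )
    assert group_adaptation(rec) == pytest.approx(0.04)
    rec100 = generate_gene_stats(preset_config("null", n_nem=50, n_nonnem=50, seed=1))
    double_loop = sum(sum(v) / len(v) for v in rec100["branch_sel_prop"]) / len(rec100)
    assert group_adaptation(rec100) == pytest.approx(double_loop)
    with pytest.raises(DataValidationError):
        group_adaptation(rec100.iloc[0:0])


# -- matching scheme and sampler -------------------------------------------

def test_scheme_interval_and_validation():
    scheme = MatchingScheme(alpha=0.95, x_period=3)
    lo, hi = scheme.interval(0.1)
    assert lo == pytest.approx(0.95 * 0.95 * 0.1)
    assert hi == pytest.approx(1.05 * 0.95 * 0.1)
    assert lo < hi
    for bad in (
        dict(alpha=0.0),
        dict(alpha=1.5),
        dict(x_period=0),
        dict(band_low=1.1, band_high=1.0),
    ):
        with pytest.raises(DataValidationError):
            MatchingScheme(**bad)


def test_degenerate_pool_any_sample_valid():
    scheme = MatchingScheme()
    pool = np.full(100, 0.95 * 0.2)  # every dN equals alpha * target
    rng = np.random.default_rng(0)
    idx = matched_sample(pool, scheme, 0.2, 30, rng)
    assert len(set(idx.tolist())) == 30
    lo, hi = scheme.interval(0.2)
    assert lo <= pool[idx].mean() <= hi


def test_x_period_one_still_meets_final_contract():
    scheme = MatchingScheme(alpha=1.0, x_period=1)
    rng = np.random.default_rng(1)
    pool = rng.gamma(2.0, 0.05, size=2000)
    lo, hi = scheme.interval(pool.mean())
    for _ in range(20):
        idx = matched_sample(pool, scheme, pool.mean(), 100, rng)
        assert lo <= pool[idx].mean() <= hi


def test_sampler_infeasible_pool_raises():
    pool = np.full(50, 10.0)
    with pytest.raises(InfeasibleSamplingError, match="infeasible"):
        matched_sample(pool, MatchingScheme(), 0.1, 10, np.random.default_rng(0))
    with pytest.raises(InfeasibleSamplingError):
        matched_sample(pool, MatchingScheme(), 10.5, 60, np.random.default_rng(0))


def test_draw_stream_uniform_over_pool():
    """On a pool where every candidate is acceptable (degenerate equal dN) the
    sampler's inclusion probability is uniform over the pool."""
    n_pool = 40
    scheme = MatchingScheme()
    pool = np.full(n_pool, scheme.alpha * 0.2)
    rng = np.random.default_rng(3)
    counts = np.zeros(n_pool)
    n_rep = 1500
    size = 10
    for _ in range(n_rep):
        counts[matched_sample(pool, scheme, 0.2, size, rng)] += 1
    p = size / n_pool
    se = np.sqrt(n_rep * p * (1 - p))
    assert np.all(np.abs(counts - n_rep * p) < 5 * se)


# -- quantification ---------------------------------------------------------

def _null_records(n_nem=80, n_pool=800, seed=0):
    rng = np.random.default_rng(seed)
    n = n_nem + n_pool
    status = ["NEM"] * n_nem + ["NONNEM"] * n_pool
    dn = rng.gamma(2.0, 0.05, size=n)
    props = [np.array([min(d * 0.2, 1.0), 0.0, 0.0]) for d in dn]
    return make_records(
        [f"g{i}" for i in range(n)],
        status,
        rng.uniform(size=n),
        dn,
        branch_sel_prop=props,
    )


def test_constant_records_give_zero_excess():
    n = 200
    rec = make_records(
        [f"g{i}" for i in range(n)],
        ["NEM"] * 50 + ["NONNEM"] * 150,
        [0.01] * n,
        [0.1] * n,
        branch_sel_prop=[np.array([0.05, 0.05])] * n,
    )
    est = quantify_excess(rec, threshold=0.5, scheme=MatchingScheme(alpha=1.0),
                          n_perm=200, seed=0)
    assert est.excess_pct == pytest.approx(0.0, abs=1e-9)
    assert est.p_perm > 0.9


def test_quantify_deterministic_under_seed():
    rec = _null_records(seed=5)
    a = quantify_excess(rec, threshold=0.5, n_perm=100, seed=11)
    b = quantify_excess(rec, threshold=0.5, n_perm=100, seed=11)
    assert a.excess_pct == b.excess_pct
    assert a.p_perm == b.p_perm
    np.testing.assert_array_equal(a.per_perm_excess, b.per_perm_excess)


def test_quantify_invariant_to_record_order():
    rec = _null_records(seed=7)
    shuffled = rec.sample(frac=1.0, random_state=3).reset_index(drop=True)
    a = quantify_excess(rec, threshold=0.5, n_perm=100, seed=11)
    b = quantify_excess(shuffled, threshold=0.5, n_perm=100, seed=11)
    assert a.excess_pct == pytest.approx(b.excess_pct)
    assert a.p_perm == b.p_perm


def test_permutation_p_floor_and_ci_ordering():
    rec = generate_gene_stats(preset_config("headline", n_nem=250, n_nonnem=2500, seed=21))
    est = quantify_excess(rec, threshold=0.5, n_perm=199, seed=4)
    assert 1 / 200 <= est.p_perm <= 1.0
    assert est.ci_low_pct <= np.median(est.per_perm_excess) <= est.ci_high_pct
    assert est.n_nem <= est.n_pool


def test_empty_class_raises():
    rec = make_records(["a"], ["NEM"], [0.1], [0.1])
    with pytest.raises(DataValidationError, match="empty class"):
        quantify_excess(rec, threshold=0.5, n_perm=10, seed=0)


# -- curves ------------------------------------------------------------------

def test_curve_counts_non_increasing_and_flags():
    rec = generate_gene_stats(preset_config("headline", n_nem=120, n_nonnem=1200, seed=31))
    curve = excess_curve(rec, thresholds=(0.9, 0.5, 0.01, 1e-5), n_perm=50, seed=2)
    counts = [e.n_nem for e in curve]
    assert counts == sorted(counts, reverse=True)
    strict = curve[-1]
    assert strict.n_nem < 10
    assert "low_n_nem" in strict.flags or any("failed" in f for f in strict.flags)


def test_curve_requires_descending_thresholds():
    rec = _null_records()
    with pytest.raises(DataValidationError, match="descending"):
        excess_curve(rec, thresholds=(0.1, 0.5), n_perm=10, seed=0)


def test_strong_evidence_effect_raises_curve():
    """When only strong-evidence genes carry the effect, the excess at the
    strict threshold exceeds the weak-threshold excess."""
    rec = generate_gene_stats(
        preset_config("strong_only", n_nem=1500, n_nonnem=15000, seed=13)
    )
    weak = quantify_excess(rec, threshold=0.5, n_perm=300, seed=1)
    strict = quantify_excess(rec, threshold=1e-5, n_perm=300, seed=2)
    assert strict.excess_pct > weak.excess_pct
    assert strict.excess_pct > 30.0
    assert weak.excess_pct < 30.0


# -- GO stratification -------------------------------------------------------

def test_go_excess_detects_boosted_category():
    rec = generate_gene_stats(preset_config("headline", n_nem=400, n_nonnem=4000, seed=41))
    # seed one category with a doubled NEM effect
    target = "GO:0000001"
    boosted = []
    for rec_row in rec.itertuples(index=False):
        v = rec_row.branch_sel_prop
        if rec_row.nem_status == "NEM" and target in rec_row.go_terms:
            v = np.minimum(v * 2.0, 1.0)
        boosted.append(v)
    rec = rec.assign(branch_sel_prop=boosted)
    results = go_excess(rec, threshold=0.5, n_perm=300, min_genes=20, top_k=5, seed=3)
    assert results, "expected at least one qualifying category"
    by_cat = {r.category: r for r in results}
    assert target in by_cat
    global_est = quantify_excess(rec, threshold=0.5, n_perm=300, seed=4)
    assert by_cat[target].estimate.excess_pct > global_est.excess_pct
    assert by_cat[target].estimate.p_perm < 0.05
    # sample sizes follow the restricted NEM count
    for r in results:
        assert r.estimate.n_nem == r.n_nem


def test_go_excess_null_categories_cover_zero():
    rec = generate_gene_stats(preset_config("null", n_nem=400, n_nonnem=4000, seed=43))
    results = go_excess(
        rec, threshold=0.5, scheme=MatchingScheme(alpha=1.0), n_perm=300,
        min_genes=20, top_k=10, seed=5,
    )
    covering = sum(r.estimate.ci_covers_zero for r in results)
    assert covering >= 0.7 * len(results)
    # and none of the categories shows strong spurious evidence
    assert min(r.q_value for r in results) > 0.05


def test_go_excess_top_k_not_padded():
    rec = generate_gene_stats(
        preset_config("null", n_nem=60, n_nonnem=600, seed=45, n_go_categories=3)
    )
    results = go_excess(rec, threshold=0.9, n_perm=50, min_genes=5, top_k=10, seed=6)
    assert 0 < len(results) <= 3
    # no qualifying category at an impossible min_genes
    assert go_excess(rec, threshold=0.9, n_perm=50, min_genes=10**6, seed=6) == []
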