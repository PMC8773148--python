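import logging

import numpy as np
import pytest

from nemquant import (
    DataValidationError,
    SyntheticConfig,
    classify_genes,
    compute_lag,
    generate_gene_stats,
    generate_paired_chronograms,
    generate_similarity_table,
    preset_config,
)
from nemquant.excess import group_adaptation


def test_determinism_byte_identical(tmp_path):
    from nemquant import write_gene_stats

    cfg = preset_config("headline", n_nem=50, n_nonnem=450, seed=123)
    a, b = generate_gene_stats(cfg), generate_gene_stats(cfg)
    pa, pb = tmp_path / "a.tsv", tmp_path / "b.tsv"
    write_gene_stats(a.drop(columns=["true_class", "true_mu"]), pa)
    write_gene_stats(b.drop(columns=["true_class", "true_mu"]), pb)
    assert pa.read_bytes() == pb.read_bytes()


def test_generated_invariants():
    rec = generate_gene_stats(preset_config("headline", n_nem=200, n_nonnem=800, seed=5))
    assert (rec["nem_status"] == "NEM").sum() == 200
    assert (rec["nem_status"] == "NONNEM").sum() == 800
    assert rec["busted_p"].between(0, 1).all()
    assert (rec["dn"] > 0).all() and (rec["ds"] > 0).all()
    for vec in rec["branch_sel_prop"]:
        assert len(vec) == 13
        assert vec.min() >= 0 and vec.max() <= 1
    assert all(len(t) == 2 for t in rec["go_terms"])


def test_invalid_configs_rejected():
    with pytest.raises(DataValidationError):
        SyntheticConfig(n_nem=0)
    with pytest.raises(DataValidationError):
        SyntheticConfig(class_probs=(0.5, 0.5, 0.5))
    with pytest.raises(DataValidationError):
        SyntheticConfig(effect_moderate=-1)
    with pytest.raises(DataValidationError, match="preset"):
        preset_config("no_such_scenario")


def test_effect_ratio_closed_form():
    """With no noise, no null class, and equal dN scales, the NEM/non-NEM
    group adaptation ratio equals effect_moderate in expectation."""
    cfg = SyntheticConfig(
        n_nem=20000,
        n_nonnem=80000,
        class_probs=(0.0, 1.0, 0.0),
        effect_moderate=1.5,
        noise_sigma=0.0,
        kappa=0.05,
        seed=77,
    )
    rec = generate_gene_stats(cfg)
    nem = rec[rec.nem_status == "NEM"]
    non = rec[rec.nem_status == "NONNEM"]
    ratio = group_adaptation(nem) / group_adaptation(non)
    # dN has CV 1/sqrt(2); 3 standard errors on the ratio of means
    se = 1.5 / np.sqrt(2) * np.sqrt(1 / 20000 + 1 / 80000)
    assert abs(ratio - 1.5) < 3 * se


def test_null_preset_is_symmetric():
    """Effect ratios of 1 leave the two groups with equal mean adaptation."""
    rec = generate_gene_stats(preset_config("null", n_nem=10000, n_nonnem=10000, seed=9))
    nem = rec[rec.nem_status == "NEM"]
    non = rec[rec.nem_status == "NONNEM"]
    diff = group_adaptation(nem) - group_adaptation(non)
    pooled_sd = np.std([v.mean() for v in rec["branch_sel_prop"]])
    assert abs(diff) < 3 * pooled_sd * np.sqrt(2 / 10000)


def test_saturation_warning(caplog):
    cfg = SyntheticConfig(n_nem=200, n_nonnem=200, kappa=5.0, seed=1)
    with caplog.at_level(logging.WARNING, logger="nemquant.simulate"):
        generate_gene_stats(cfg)
    assert any("saturated" in r.message for r in caplog.records)


# -- similarity tables ------------------------------------------------------

def test_noiseless_similarity_recovers_labels():
    rec = generate_gene_stats(preset_config("null", n_nem=150, n_nonnem=850, seed=2))
    sim = generate_similarity_table(rec, hit_rate_nem=1.0, false_hit_rate=0.0, seed=3)
    labels = classify_genes(sim, rec["gene_id"], evalue_cutoff=1e-5)
    assert all(labels[g] == s for g, s in zip(rec["gene_id"], rec["nem_status"]))


def test_zero_hit_rate_yields_no_nems():
    rec = generate_gene_stats(preset_config("null", n_nem=100, n_nonnem=100, seed=2))
    sim = generate_similarity_table(rec, hit_rate_nem=0.0, false_hit_rate=0.0, seed=3)
    labels = classify_genes(sim, rec["gene_id"])
    assert set(labels.values()) == {"NONNEM"}


def test_hit_rate_binomial():
    rec = generate_gene_stats(preset_config("null", n_nem=10000, n_nonnem=100, seed=4))
    sim = generate_similarity_table(rec, hit_rate_nem=0.9, false_hit_rate=0.05, seed=5)
    nem_ids = set(rec.loc[rec.nem_status == "NEM", "gene_id"])
    hits = sum(1 for g in sim["gene_id"] if g in nem_ids)
    se = np.sqrt(0.9 * 0.1 / 10000)
    assert abs(hits / 10000 - 0.9) < 3 * se
    # non-NEM false hits are weak (e-value >= 1e-3), NEM hits strong (<= 1e-10)
    strong = sim[sim["best_evalue"] <= 1e-10]
    assert set(strong["gene_id"]) <= nem_ids


def test_similarity_rate_validation():
    rec = generate_gene_stats(preset_config("null", n_nem=5, n_nonnem=5, seed=0))
    with pytest.raises(DataValidationError):
        generate_similarity_table(rec, hit_rate_nem=1.2, false_hit_rate=0.0, seed=1)


# -- paired chronograms -----------------------------------------------------

def test_zero_lag_pair():
    nem, org, clade_map = generate_paired_chronograms(6, 0.0, 500.0, seed=8)
    report = compute_lag(nem, org, clade_map)
    assert all(abs(c.lag) < 1e-9 for c in report.clades)


def test_constructed_lag_forty():
    nem, org, clade_map = generate_paired_chronograms(8, 40.0, 740.0, seed=8)
    report = compute_lag(nem, org, clade_map)
    assert report.min_lag == pytest.approx(40.0, abs=1e-9)
    assert report.max_lag == pytest.approx(40.0, abs=1e-9)
    assert org.root_age == pytest.approx(700.0)
    assert nem.root_age == pytest.approx(740.0)


@pytest.mark.parametrize("seed", range(20))
def test_lag_recovery_invariant_to_topology(seed):
    nem, org, clade_map = generate_paired_chronograms(7, 33.0, 600.0, seed=seed)
    report = compute_lag(nem, org, clade_map)
    assert report.min_lag == pytest.approx(33.0, abs=1e-9)
    assert report.max_lag == pytest.approx(33.0, abs=1e-9)


def test_chronogram_argument_validation():
    with pytest.raises(DataValidationError):
        generate_paired_chronograms(2, 40.0, 740.0, seed=0)
    with pytest.raises(DataValidationError):
        generate_paired_chronograms(5, 800.0, 740.0, seed=0)
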