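"""TE point estimates, interaction test, buffering, reporter relative TE."""

import numpy as np
import pandas as pd
import pytest

from ribote.de import estimate_size_factors, nb_wald_test
from ribote.io_formats import CountMatrix, ValidationError
from ribote.simulate import SimConfig, simulate_counts
from ribote.te import (buffering_correlation, classify_te, compute_te,
                       reporter_relative_te, te_interaction_test)

from conftest import make_samples, matrix_from_group_means, unit_size_factors


def test_equal_rpf_and_mrna_means_give_unit_te():
    means = {(c, a): np.array([100, 40])
             for c in ("heterotrophic", "autotrophic")
             for a in ("mRNA", "RPF")}
    cm = matrix_from_group_means(["g0", "g1"], means)
    sf = estimate_size_factors(cm)
    te = compute_te(cm, sf)
    assert np.allclose(te["te_het"], 1.0)
    assert np.allclose(te["te_auto"], 1.0)
    assert np.allclose(te["te_log2fc"], 0.0)


def test_te_arithmetic_worked_example():
    # mRNA means (100, 100), RPF means (50, 200) -> TE 0.5 and 2.0, lfc 2
    means = {("heterotrophic", "mRNA"): np.array([100]),
             ("autotrophic", "mRNA"): np.array([100]),
             ("heterotrophic", "RPF"): np.array([50]),
             ("autotrophic", "RPF"): np.array([200])}
    cm = matrix_from_group_means(["g0"], means)
    sf = unit_size_factors(cm)
    te = compute_te(cm, sf)
    assert te.loc[0, "te_het"] == pytest.approx(0.5)
    assert te.loc[0, "te_auto"] == pytest.approx(2.0)
    assert te.loc[0, "te_log2fc"] == pytest.approx(2.0)


def test_low_mrna_genes_excluded_not_dropped():
    means = {("heterotrophic", "mRNA"): np.array([0, 100]),
             ("autotrophic", "mRNA"): np.array([0, 100]),
             ("heterotrophic", "RPF"): np.array([10, 100]),
             ("autotrophic", "RPF"): np.array([10, 100])}
    cm = matrix_from_group_means(["low", "ok"], means)
    sf = estimate_size_factors(cm)
    te = compute_te(cm, sf, mrna_floor=1.0)
    assert te.loc[0, "excluded"] and np.isnan(te.loc[0, "te_log2fc"])
    assert not te.loc[1, "excluded"]


def test_missing_assay_rejected(sim_small):
    counts = sim_small["counts"]
    sub = counts.subset_samples(counts.sample_mask(assay="mRNA"))
    sf = estimate_size_factors(sub)
    with pytest.raises(ValidationError, match="RPF"):
        compute_te(sub, sf)


def test_te_lfc_equals_rpf_lfc_minus_mrna_lfc(sim_small):
    counts, sf = sim_small["counts"], sim_small["sf"]
    te = compute_te(counts, sf, mrna_floor=0.0)
    ok = ~te["excluded"] & (te[["rpf_het", "rpf_auto", "mrna_het",
                                "mrna_auto"]] > 0).all(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        rpf_lfc = np.log2(te["rpf_auto"] / te["rpf_het"])
        mrna_lfc = np.log2(te["mrna_auto"] / te["mrna_het"])
    assert np.allclose(te.loc[ok, "te_log2fc"],
                       (rpf_lfc - mrna_lfc)[ok], atol=1e-9)


def test_te_invariant_under_common_count_scaling(sim_small):
    counts = sim_small["counts"]
    sf1 = estimate_size_factors(counts)
    te1 = compute_te(counts, sf1)
    cm2 = CountMatrix(counts.gene_ids, counts.samples, counts.counts * 3)
    sf2 = estimate_size_factors(cm2)
    te2 = compute_te(cm2, sf2, mrna_floor=3.0)
    ok = ~te1["excluded"] & ~te2["excluded"]
    assert np.allclose(te1.loc[ok, "te_log2fc"], te2.loc[ok, "te_log2fc"],
                       atol=1e-9)


def test_planted_te_effect_recovered():
    cfg = SimConfig(n_genes=2000, frac_te=0.3, seed=41)
    counts, truth = simulate_counts(cfg)
    sf = estimate_size_factors(counts)
    te = compute_te(counts, sf)
    hi = (truth.base_mean >= 100) & truth.is_te & ~te["excluded"].to_numpy()
    assert hi.sum() > 200
    err = te["te_log2fc"].to_numpy()[hi] - truth.lfc_te[hi]
    assert abs(np.median(err)) < 0.1


def test_interaction_power_on_planted_effect():
    # delta = 2 at high expression: the interaction should be detected for
    # at least 90% of planted genes
    cfg = SimConfig(n_genes=200, frac_de=0.0, frac_te=0.0, seed=31,
                    base_mean_log_range=(2.5, 3.5), dispersion=(0.01, 0.05))
    counts, truth = simulate_counts(cfg)
    planted = np.zeros(200, dtype=bool)
    planted[:40] = True
    arr = counts.counts.copy()
    mask = counts.sample_mask(condition="autotrophic", assay="RPF")
    arr[np.ix_(planted, mask)] *= 4      # 2^2 on the interaction cell
    cm = CountMatrix(counts.gene_ids, counts.samples, arr)
    sf = estimate_size_factors(cm)
    res = te_interaction_test(cm, sf, truth.dispersion)
    hit = (res["p_adj"] < 0.05) & (res["interaction_log2fc"] > 1)
    assert hit.to_numpy()[planted].mean() >= 0.9
    assert (res["p_adj"] < 0.05).to_numpy()[~planted].mean() < 0.2


def test_condition_effect_in_both_assays_is_not_interaction():
    # translational-buffering confound control: a strong condition effect
    # shared by both assays must not trigger the interaction test
    hits = 0
    trials = 30
    for rep in range(trials):
        cfg = SimConfig(n_genes=20, n_operons=0, frac_de=0.0, frac_te=0.0,
                        seed=500 + rep, base_mean_log_range=(2.0, 3.0),
                        dispersion=0.05)
        counts, truth = simulate_counts(cfg)
        arr = counts.counts.copy()
        mask = counts.sample_mask(condition="autotrophic")
        arr[:, mask] *= 8                 # 2^3 condition effect, both assays
        cm = CountMatrix(counts.gene_ids, counts.samples, arr)
        sf = unit_size_factors(cm)
        res = te_interaction_test(cm, sf, truth.dispersion)
        hits += (res["p"] <= 0.05).sum()
    assert hits / (trials * 20) <= 0.10


def test_classify_te_thresholds():
    te = pd.DataFrame({"gene_id": ["a", "b", "c", "d"],
                       "te_log2fc": [2.0, -2.0, 2.0, 0.2],
                       "excluded": [False, False, False, False]})
    test = pd.DataFrame({"gene_id": ["a", "b", "c", "d"],
                         "p": [0.001, 0.001, 0.5, 0.001],
                         "p_adj": [0.01, 0.01, 0.9, 0.01],
                         "status": ["ok"] * 4})
    out = classify_te(te, test)
    assert list(out["te_class"]) == ["up", "down", "unchanged", "unchanged"]


def test_buffering_perfect_anticorrelation():
    de = pd.DataFrame({"gene_id": [f"g{i}" for i in range(20)],
                       "log2fc": np.linspace(-3, 3, 20)})
    te = pd.DataFrame({"gene_id": [f"g{i}" for i in range(20)],
                       "te_log2fc": -np.linspace(-3, 3, 20)})
    rho, _ = buffering_correlation(de, te)
    assert rho == pytest.approx(-1.0)


def test_buffering_independent_effects_near_zero():
    rng = np.random.default_rng(17)
    ids = [f"g{i}" for i in range(2000)]
    de = pd.DataFrame({"gene_id": ids, "log2fc": rng.normal(0, 2, 2000)})
    te = pd.DataFrame({"gene_id": ids, "te_log2fc": rng.normal(0, 1, 2000)})
    rho, _ = buffering_correlation(de, te)
    assert abs(rho) < 0.1


def test_buffering_recovery_from_simulation():
    cfg = SimConfig(n_genes=2000, frac_de=1.0, frac_te=1.0,
                    buffering_rho=-0.5, seed=5)
    counts, truth = simulate_counts(cfg)
    sf = estimate_size_factors(counts)
    de = nb_wald_test(counts, sf, truth.dispersion, assay="mRNA")
    te = compute_te(counts, sf)
    rho, p = buffering_correlation(de, te)
    assert -0.65 <= rho <= -0.35
    assert p < 1e-6


def test_reporter_relative_te_printed_values():
    ms = reporter_relative_te([("c1647", 1.01, 0.62),
                               ("c1650", 20.91, 0.99),
                               ("c1491", 2.75, 3.90),
                               ("x", 1.0, 1.0)])
    assert [m.relative_te for m in ms] == [0.61, 0.05, 1.42, 1.00]


def test_reporter_rounding_is_half_up():
    (m,) = reporter_relative_te([("c", 1.0, 0.125)])
    assert m.relative_te == 0.13


def test_reporter_nonpositive_fold_change_rejected():
    with pytest.raises(ValidationError, match="positive"):
        reporter_relative_te([("c", 0.0, 1.0)])
    with pytest.raises(ValidationError, match="positive"):
        reporter_relative_te([("c", 1.0, -2.0)])
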