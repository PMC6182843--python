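import numpy as np
import pandas as pd
import pytest

from helpers import make_matrix, oracle_bestkeeper_r, oracle_delta_ct_mean_sd
from refstab.cq import collapse_technical_reps, complete_case
from refstab.descriptive import bestkeeper, delta_ct_method, rank_bestkeeper
from refstab.simulate import default_panel, simulate_cq


def test_one_cycle_dispersion_at_calibrated_efficiency_doubles_on_linear_scale():
    # gene with Cq {19, 20, 21}: ddof-1 SD exactly 1.00; E = 10^(1/3.25) = 2.0309
    m = make_matrix([[19.0, 20.0, 21.0], [20.0, 20.0, 20.0]], genes=["tub", "flat"])
    res = bestkeeper(m, efficiencies={"tub": 2.0309, "flat": 2.0})
    assert res.stats.loc["tub", "sd"] == pytest.approx(1.0)
    assert round(res.stats.loc["tub", "xfold_sd"], 2) == 2.03


def test_constant_gene_statistics_are_degenerate_but_consistent():
    m = make_matrix([[20.0] * 4, [18.0, 19.0, 20.0, 21.0]], genes=["flat", "var"])
    s = bestkeeper(m).stats.loc["flat"]
    for col in ("gm", "am", "min", "max"):
        assert s[col] == pytest.approx(20.0, abs=1e-12)
    assert s["sd"] == 0 and s["cv_pct"] == 0
    assert s["xfold_sd"] == 1.0
    assert not s["inconsistent"]


def test_index_correlation_matches_brute_force():
    rng = np.random.default_rng(3)
    m = make_matrix(rng.normal(20, 1, size=(3, 6)))
    res = bestkeeper(m)
    expected = oracle_bestkeeper_r(m.cq)
    for g in m.genes:
        assert res.stats.loc[g, "r_index"] == pytest.approx(expected[g], abs=1e-12)


def test_xfold_extremes_bracket_unity_and_follow_sign_convention():
    m = make_matrix([[18.0, 20.0, 22.0], [19.0, 20.0, 21.0]])
    stats = bestkeeper(m).stats
    assert (stats["xfold_min"] < 0).all()   # lowest Cq = overexpression, negative
    assert (stats["xfold_max"] > 1).all()
    assert (stats["xfold_min"].abs() > 1).all()


def test_rank_descends_by_r_and_demotes_inconsistent_genes():
    stats = pd.DataFrame(
        {
            "r_index": [0.98, 0.92, 0.91, 0.99],
            "inconsistent": [False, False, False, True],
        },
        index=pd.Index(["a", "b", "c", "wild"], name="gene"),
    )
    assert rank_bestkeeper(stats) == ["a", "b", "c", "wild"]
    assert rank_bestkeeper(stats, demote_inconsistent=False) == ["wild", "a", "b", "c"]


def test_rank_ties_keep_input_order_with_warning():
    stats = pd.DataFrame(
        {"r_index": [0.9, 0.9, 0.95], "inconsistent": [False] * 3},
        index=pd.Index(["a", "b", "c"], name="gene"),
    )
    with pytest.warns(UserWarning, match="tied"):
        assert rank_bestkeeper(stats) == ["c", "a", "b"]


def test_dispersion_above_one_cycle_is_flagged_inconsistent():
    vals = np.array([[20.0, 21.5, 23.0, 18.5], [20.0, 20.3, 19.8, 20.1]])
    stats = bestkeeper(make_matrix(vals, genes=["wild", "calm"])).stats
    assert stats.loc["wild", "sd"] > 1 and stats.loc["wild", "inconsistent"]
    assert not stats.loc["calm", "inconsistent"]


def test_single_gene_panel_index_is_that_genes_cq():
    m = make_matrix([[20.0, 21.0, 19.5]])
    with pytest.warns(UserWarning, match="single-gene"):
        res = bestkeeper(m)
    np.testing.assert_allclose(res.index.to_numpy(), m.cq.iloc[0].to_numpy())


def test_sd_mode_choice_rarely_changes_the_ranking():
    # the index correlation itself is mode-independent; the two dispersion
    # statistics may disagree only through the one-cycle consistency flag,
    # so panels whose genes sit clear of that boundary must rank identically
    from refstab.simulate import CqSimConfig, GeneSpec

    genes = [
        GeneSpec("g1", 18.0, 0.15), GeneSpec("g2", 19.0, 0.3), GeneSpec("g3", 20.0, 0.5),
        GeneSpec("g4", 21.0, 0.7), GeneSpec("wild", 22.0, 1.3, delta=2.0),
    ]
    agree = 0
    for seed in range(100):
        cfg = CqSimConfig(genes=genes, sample_effect_sd=0.4, tech_noise_sd=0.2, seed=seed)
        m, _ = simulate_cq(cfg)
        comp, _ = complete_case(collapse_technical_reps(m))
        a = rank_bestkeeper(bestkeeper(comp, sd_mode="sample_sd").stats)
        b = rank_bestkeeper(bestkeeper(comp, sd_mode="mad").stats)
        agree += a == b
    assert agree >= 90


def test_nonpositive_cq_is_a_domain_error():
    with pytest.raises(ValueError, match="non-positive"):
        bestkeeper(make_matrix([[20.0, -1.0], [18.0, 19.0]]))


# ------------------------------------------------------------- delta-Ct


def test_shifted_copy_gene_pair_has_zero_sd():
    base = np.array([20.0, 21.0, 19.0, 20.5])
    m = make_matrix([base, base + 1.0, base * 1.1], genes=["ga", "gb", "gc"])
    res = delta_ct_method(m)
    assert res.pair_sd.loc["ga", "gb"] == pytest.approx(0.0, abs=1e-12)
    assert res.ranking[-1] == "gc"


def test_mean_sd_matches_brute_force_over_all_pairs():
    rng = np.random.default_rng(11)
    m = make_matrix(rng.normal(20, 1, size=(4, 7)))
    res = delta_ct_method(m)
    expected = oracle_delta_ct_mean_sd(m.cq)
    for g in m.genes:
        assert res.mean_sd[g] == pytest.approx(expected[g], abs=1e-10)


def test_pair_sd_invariant_to_per_gene_and_per_sample_shifts():
    # within-sample differences cancel loading constants; per-gene offsets
    # shift each difference by a constant, leaving its SD unchanged
    rng = np.random.default_rng(13)
    vals = rng.normal(20, 1, size=(3, 6))
    base = delta_ct_method(make_matrix(vals)).pair_sd
    gene_shift = vals + np.array([[1.0], [2.0], [-0.5]])
    np.testing.assert_allclose(
        delta_ct_method(make_matrix(gene_shift)).pair_sd.to_numpy(), base.to_numpy(), atol=1e-12
    )
    sample_shift = vals + rng.normal(0, 1, size=(1, 6))
    np.testing.assert_allclose(
        delta_ct_method(make_matrix(sample_shift)).pair_sd.to_numpy(), base.to_numpy(), atol=1e-12
    )


def test_size_guards():
    with pytest.raises(ValueError):
        delta_ct_method(make_matrix([[20.0, 21.0], [19.0, 20.0]]))
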