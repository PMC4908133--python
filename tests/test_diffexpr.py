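import numpy as np
import pandas as pd
import pytest

from tagdge.diffexpr import (ac_probability, ac_two_sided_p, call_degs,
                             deg_summary_from_counts, fdr_adjust)
from tagdge.mapping import ExpressionTable

from _oracles import ac_prob_oracle, ac_two_sided_oracle, stepup_fdr_oracle


def test_conditional_probability_closed_forms():
    assert ac_probability(0, 0, 10**6, 10**6) == pytest.approx(0.5, abs=1e-12)
    for n1, n2 in [(100, 300), (4_509_167, 2_990_048)]:
        assert ac_probability(0, 0, n1, n2) == pytest.approx(n1 / (n1 + n2), rel=1e-12)


@pytest.mark.parametrize("x,y", [(5, 15), (0, 7), (100, 100), (1000, 1500)])
def test_conditional_probability_matches_log_gamma_oracle(x, y):
    for n1, n2 in [(10**6, 10**6), (4_509_167, 2_990_048)]:
        assert ac_probability(x, y, n1, n2) == pytest.approx(
            ac_prob_oracle(x, y, n1, n2), rel=1e-10)


def test_conditional_distribution_normalizes():
    x, n1, n2 = 10, 10**6, 2 * 10**6
    total, y = 0.0, 0
    while True:
        p = ac_probability(x, y, n1, n2)
        total += p
        if y > x and p < 1e-13 and total > 0.5:
            break
        y += 1
    assert total == pytest.approx(1.0, abs=1e-11)


def test_two_sided_p_trivial_cases_and_symmetry():
    assert ac_two_sided_p(0, 0, 10**6, 10**6) == 1.0
    assert ac_two_sided_p(42, 42, 10**6, 10**6) == pytest.approx(1.0, abs=1e-12)
    # the conditional pmf is exactly symmetric under equal depths ...
    for x, y in [(3, 9), (10, 100), (0, 5)]:
        assert ac_probability(x, y, 10**6, 10**6) == pytest.approx(
            ac_probability(y, x, 10**6, 10**6), rel=1e-12)
    # ... while the doubled tail p-value is symmetric only up to the
    # discreteness of the conditioning (same call at any sane threshold)
    for x, y in [(3, 9), (10, 100), (0, 5)]:
        a = ac_two_sided_p(x, y, 10**6, 10**6)
        b = ac_two_sided_p(y, x, 10**6, 10**6)
        assert max(a, b) <= 2 * min(a, b)


def test_two_sided_p_matches_summation_oracle():
    assert ac_two_sided_p(10, 100, 10**6, 10**6) == pytest.approx(
        ac_two_sided_oracle(10, 100, 10**6, 10**6), rel=1e-10)
    grid = [(x, y) for x in (0, 1, 5, 20, 200) for y in (0, 1, 7, 50, 400)]
    for n1, n2 in [(10**6, 10**6), (4_509_167, 2_990_048)]:
        for x, y in grid:
            assert ac_two_sided_p(x, y, n1, n2) == pytest.approx(
                ac_two_sided_oracle(x, y, n1, n2), rel=1e-10), (x, y, n1, n2)


def test_two_sided_p_decreases_away_from_conditional_mean():
    x, n1, n2 = 50, 10**6, 10**6
    ys = np.arange(50, 200)
    ps = ac_two_sided_p(np.full_like(ys, x), ys, n1, n2)
    assert (np.diff(ps) <= 1e-12).all()
    ys_low = np.arange(0, 51)
    ps_low = ac_two_sided_p(np.full_like(ys_low, x), ys_low, n1, n2)
    assert (np.diff(ps_low) >= -1e-12).all()


def test_negative_counts_rejected():
    with pytest.raises(ValueError):
        ac_probability(-1, 0, 10, 10)
    with pytest.raises(ValueError):
        ac_two_sided_p(0, -2, 10, 10)


def test_bh_stepup_forces_equal_qvalues():
    assert fdr_adjust([0.01, 0.02, 0.03]).tolist() == pytest.approx([0.03] * 3)
    assert fdr_adjust([0.2]).tolist() == [0.2]


def test_fdr_matches_textbook_stepup_loop():
    rng = np.random.default_rng(3)
    p = rng.uniform(size=200)
    assert fdr_adjust(p, "BH") == pytest.approx(stepup_fdr_oracle(list(p)), rel=1e-12)
    assert fdr_adjust(p, "BY") == pytest.approx(stepup_fdr_oracle(list(p), by=True), rel=1e-12)


def test_by_dominates_bh_and_qvalues_are_rank_monotone():
    rng = np.random.default_rng(9)
    p = rng.uniform(size=50)
    bh, by = fdr_adjust(p, "BH"), fdr_adjust(p, "BY")
    assert (by >= bh - 1e-15).all()
    order = np.argsort(p)
    assert (np.diff(bh[order]) >= -1e-15).all()


def test_invalid_pvalues_rejected():
    with pytest.raises(ValueError):
        fdr_adjust([0.5, 1.5])
    with pytest.raises(ValueError):
        fdr_adjust([np.nan, 0.2])


def _toy_table(counts: pd.DataFrame, totals: dict) -> ExpressionTable:
    return ExpressionTable(counts, counts.div(pd.Series(totals)) * 1e6, totals,
                           len(counts))


def test_equal_counts_are_never_called():
    counts = pd.DataFrame({"MP": [50, 7], "HP": [50, 7]},
                          index=pd.Index(["a", "b"], name="gene_id"))
    de, summary = call_degs(_toy_table(counts, {"MP": 1000, "HP": 1000}), "MP", "HP")
    assert np.allclose(de.p, 1.0, atol=1e-12)
    assert (de.call == "unchanged").all()
    assert summary.n_up == summary.n_down == 0


def test_zero_in_both_stages_not_tested():
    counts = pd.DataFrame({"MP": [50, 0], "HP": [5, 0]},
                          index=pd.Index(["a", "b"], name="gene_id"))
    de, _ = call_degs(_toy_table(counts, {"MP": 1000, "HP": 1000}), "MP", "HP")
    assert list(de.index) == ["a"]


def test_stage_exclusive_gene_gets_large_finite_ratio():
    counts = pd.DataFrame({"MP": [0], "HP": [400]},
                          index=pd.Index(["a"], name="gene_id"))
    de, _ = call_degs(_toy_table(counts, {"MP": 10**6, "HP": 10**6}), "MP", "HP")
    assert np.isfinite(de.log2_ratio.iloc[0])
    assert de.call.iloc[0] == "up"


def test_deg_summary_percentage_of_expressed_genes():
    pg = deg_summary_from_counts("MPvsHP", n_up=128, n_down=990, n_expressed=13_017)
    assert pg.pct_down == 7.61
    assert pg.pct_up == 0.98
    ptg = deg_summary_from_counts("HPvsPT", n_up=741, n_down=609, n_expressed=13_017)
    assert (ptg.pct_up, ptg.pct_down) == (5.69, 4.68)


def test_unknown_stage_label_errors(small_table):
    with pytest.raises(ValueError, match="unknown stage"):
        call_degs(small_table, "MP", "XX")


def test_null_pvalues_are_superuniform():
    # equal true rates, equal depths: empirical type-I error at alpha=0.05
    # must not exceed alpha beyond 3 binomial SE
    rng = np.random.default_rng(21)
    lam = rng.uniform(5, 200, size=4000)
    x = rng.poisson(lam)
    y = rng.poisson(lam)
    p = ac_two_sided_p(x, y, 10**6, 10**6)
    alpha = 0.05
    rate = (p < alpha).mean()
    assert rate <= alpha + 3 * np.sqrt(alpha * (1 - alpha) / len(lam))


def test_planted_de_recovery_on_synthetic_study(small_table, small_study):
    truth = small_study["truth"]
    de, _ = call_degs(small_table, "MP", "HP")
    called = set(de.index[de.call != "unchanged"])
    td = truth.de["MPvsHP"]
    truly_de = set(td.index[td.is_de])
    planted = set(td.index[td.planted])
    fdp = len(called - truly_de) / max(len(called), 1)
    sens = len(called & planted) / len(planted)
    assert fdp <= 0.05
    assert sens >= 0.8
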