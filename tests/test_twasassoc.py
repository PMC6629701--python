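"""Logistic association, inflation statistics, conditioning, mediation,
replication tiers and fixed-effects meta-analysis."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from twaskit import (
    AssociationResult,
    classify_replication,
    compute_inflation,
    conditional_association,
    filter_pc_outliers,
    fit_logistic_association,
    fixed_effects_meta,
    mediation_proportion,
    resolve_conditioning_variants,
    run_twas,
)

from conftest import make_panel


# -- PC outlier filter -------------------------------------------------------


def test_constructed_outlier_removed():
    n = 100
    pcs = pd.DataFrame({"pc1": np.zeros(n), "pc2": np.zeros(n)})
    pcs.loc[:, "pc1"] = np.random.default_rng(0).normal(0, 1, n)
    pcs.loc[0, "pc1"] = 10 * pcs["pc1"].std() + pcs["pc1"].mean()
    kept = filter_pc_outliers(pcs, k_sd=5, n_pcs=1)
    assert 0 not in kept and len(kept) >= n - 2


def test_standard_normal_pcs_rarely_removed():
    rng = np.random.default_rng(1)
    pcs = pd.DataFrame({"pc1": rng.standard_normal(10_000),
                        "pc2": rng.standard_normal(10_000)})
    kept = filter_pc_outliers(pcs)
    # P(|Z| > 5) ~ 5.7e-7 per PC: essentially no removals expected
    assert len(kept) >= 9_998


def test_infinite_k_is_identity_and_zero_variance_errors():
    pcs = pd.DataFrame({"pc1": [1.0, 2.0, 3.0], "pc2": [0.0, 0.0, 0.0]})
    assert list(filter_pc_outliers(pcs, k_sd=np.inf, n_pcs=1)) == [0, 1, 2]
    with pytest.raises(ValueError, match="zero variance"):
        filter_pc_outliers(pcs, n_pcs=2)


# -- logistic fitting --------------------------------------------------------


def test_logistic_beta_matches_two_by_two_log_odds():
    # cases: 20 exposed / 80 unexposed; controls: 10 exposed / 90 unexposed
    x = np.r_[np.ones(20), np.zeros(80), np.ones(10), np.zeros(90)]
    y = np.r_[np.ones(100), np.zeros(100)]
    res = fit_logistic_association(x, y)
    assert res.beta == pytest.approx(np.log((20 * 90) / (80 * 10)), abs=1e-6)
    assert res.beta == pytest.approx(0.8109, abs=1e-4)
    assert res.se > 0 and res.converged


def test_null_wald_p_is_uniform():
    rng = np.random.default_rng(2)
    pvals = []
    for _ in range(500):
        x = rng.standard_normal(200)
        y = rng.integers(0, 2, 200)
        pvals.append(fit_logistic_association(x, y).p)
    assert stats.kstest(pvals, "uniform").pvalue > 0.01


def test_perfect_separation_flagged_not_estimated():
    x = np.r_[np.zeros(30), np.ones(30)]
    res = fit_logistic_association(x, (x > 0.5).astype(int))
    assert res.converged is False
    assert not np.isfinite(res.beta)


def test_single_class_and_collinear_design_raise():
    x = np.random.default_rng(3).standard_normal(50)
    with pytest.raises(ValueError, match="single class"):
        fit_logistic_association(x, np.ones(50))
    covs = pd.DataFrame({"age": x * 2.0})  # collinear with expression
    with pytest.raises(ValueError, match="age|expression"):
        fit_logistic_association(x, np.r_[np.ones(25), np.zeros(25)], covs)


def test_run_twas_thresholds_scale_with_gene_count():
    rng = np.random.default_rng(4)
    imputed = pd.DataFrame(rng.standard_normal((400, 25)),
                           columns=[f"g{i}" for i in range(25)])
    y = rng.integers(0, 2, 400)
    results, infl, thr = run_twas(imputed, y)
    assert thr["significant"] == pytest.approx(0.05 / 25)
    assert thr["suggestive"] == pytest.approx(0.5 / 25)
    assert len(results) == 25
    assert all(r.tier == "null" or r.p < thr["suggestive"] for r in results)
    assert infl.n_cases + infl.n_controls == 400


# -- inflation ---------------------------------------------------------------


def test_lambda_1000_reproduces_printed_rescaling():
    # a p-value vector whose chi-square median sits at exactly 1.146x null
    p = np.full(51, stats.chi2.sf(1.146 * 0.4549364, df=1))
    infl = compute_inflation(p, 7_963, 189_218)
    assert infl.lambda_gc == pytest.approx(1.146, abs=1e-6)
    assert round(infl.lambda_1000, 2) == 1.01


def test_lambda_gc_unity_is_fixed_point():
    # all p = 0.5 puts the chi-square median exactly at its null value
    infl = compute_inflation(np.full(101, 0.5), 1234, 5678)
    assert infl.lambda_gc == pytest.approx(1.0, abs=1e-6)
    assert infl.lambda_1000 == pytest.approx(1.0, abs=1e-6)


def test_uniform_pvalues_give_unit_lambda():
    rng = np.random.default_rng(5)
    infl = compute_inflation(rng.uniform(size=100_000), 500, 500)
    assert infl.lambda_gc == pytest.approx(1.0, abs=0.01)


def test_inflation_input_validation():
    with pytest.raises(ValueError):
        compute_inflation(np.array([]), 10, 10)
    with pytest.raises(ValueError):
        compute_inflation(np.array([0.0, 0.5]), 10, 10)


# -- conditional analysis ----------------------------------------------------


def _cohort_with_conditioning(seed, driven=True, n=4_000):
    """Disease risk either acts through the conditioning variant (expression a
    noisy proxy of it) or through expression orthogonal to the variant."""
    rng = np.random.default_rng(seed)
    dosage = rng.binomial(2, 0.3, n).astype(float)
    if driven:
        expr = dosage + rng.normal(0, 0.3, n)
        signal = dosage
    else:
        expr = rng.standard_normal(n)
        signal = expr
    eta = 0.5 * (signal - signal.mean()) / signal.std()
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
    return expr, y, dosage


def test_conditioning_attenuates_driven_signal():
    expr, y, dosage = _cohort_with_conditioning(6, driven=True)
    res = conditional_association(expr, y, None, dosage.reshape(-1, 1))
    assert abs(res.beta_conditional) < abs(res.beta_marginal)
    assert abs(res.beta_conditional) < 2 * res.se_conditional


def test_conditioning_spares_orthogonal_signal():
    expr, y, dosage = _cohort_with_conditioning(7, driven=False)
    res = conditional_association(expr, y, None, dosage.reshape(-1, 1))
    assert res.beta_conditional == pytest.approx(
        res.beta_marginal, abs=2 * res.se_conditional
    )
    assert res.p_conditional < 1e-6


def test_proxy_selection_respects_threshold_and_rank():
    rng = np.random.default_rng(8)
    n = 200
    lead = rng.binomial(2, 0.5, n).astype(float)
    # two candidates correlated with the absent lead at r2 ~0.85 and ~0.79
    good = np.where(rng.random(n) < 0.96, lead, rng.binomial(2, 0.5, n))
    weak = np.where(rng.random(n) < 0.7, lead, rng.binomial(2, 0.5, n))
    panel = make_panel(
        [
            ("good", "1", 100, "A", "G", 1.0),
            ("weak", "1", 200, "A", "G", 1.0),
        ],
        np.column_stack([good, weak]),
    )
    r2 = {
        "good": np.corrcoef(lead, good)[0, 1] ** 2,
        "weak": np.corrcoef(lead, weak)[0, 1] ** 2,
    }
    assert r2["good"] > 0.8 > r2["weak"]
    ld = pd.DataFrame(
        [[1.0, r2["good"], r2["weak"]]],
        index=["lead"], columns=["lead", "good", "weak"],
    )
    dosages, prov = resolve_conditioning_variants(["lead"], panel, ld)
    assert prov[0]["used"] == "good"
    assert np.array_equal(dosages[:, 0], good)


def test_no_proxy_above_threshold_drops_lead():
    panel = make_panel([("v", "1", 100, "A", "G", 1.0)],
                       np.random.default_rng(9).binomial(2, 0.4, (50, 1)))
    ld = pd.DataFrame([[1.0, 0.5]], index=["lead"], columns=["lead", "v"])
    with pytest.warns(UserWarning), pytest.raises(ValueError):
        resolve_conditioning_variants(["lead"], panel, ld)


def test_conditioning_set_pruned_to_low_ld():
    rng = np.random.default_rng(10)
    a = rng.binomial(2, 0.5, 500).astype(float)
    b = a.copy()  # r2 = 1 with a -> must be pruned
    c = rng.binomial(2, 0.5, 500).astype(float)
    panel = make_panel(
        [
            ("a", "1", 1, "A", "G", 1.0),
            ("b", "1", 2, "A", "G", 1.0),
            ("c", "1", 3, "A", "G", 1.0),
        ],
        np.column_stack([a, b, c]),
    )
    ld = panel.ld_r2()
    dosages, prov = resolve_conditioning_variants(["a", "b", "c"], panel, ld)
    assert [p["used"] for p in prov] == ["a", "c"]


def test_collinear_conditioning_raises_rank_error():
    expr, y, _ = _cohort_with_conditioning(11, driven=False, n=300)
    with pytest.raises(ValueError, match="rank deficient"):
        conditional_association(expr, y, None, expr.reshape(-1, 1))


# -- mediation ---------------------------------------------------------------


def test_mediator_identical_to_gene_caps_at_100():
    rng = np.random.default_rng(12)
    x = rng.standard_normal(500)
    y = (rng.random(500) < 1 / (1 + np.exp(-x))).astype(int)
    res = mediation_proportion(x, x.copy(), y, n_boot=10, seed=0)
    assert res.proportion_mediated == 100.0
    assert res.flagged


def test_independent_mediator_mediates_nothing():
    rng = np.random.default_rng(13)
    x = rng.standard_normal(3_000)
    m = rng.standard_normal(3_000)
    y = (rng.random(3_000) < 1 / (1 + np.exp(-0.8 * x))).astype(int)
    res = mediation_proportion(x, m, y, n_boot=100, seed=0)
    assert abs(res.proportion_mediated) < 15
    assert res.ci[0] <= 0.0 <= res.ci[1]


def test_mediation_requires_marginal_signal():
    rng = np.random.default_rng(14)
    x = rng.standard_normal(100)
    res = mediation_proportion(
        np.zeros(100) + 1e-14 * x, x, rng.integers(0, 2, 100), n_boot=5, seed=0
    )
    assert res.flagged


def test_mediation_bootstrap_deterministic_given_seed():
    rng = np.random.default_rng(15)
    m = rng.standard_normal(800)
    x = 0.5 * m + rng.standard_normal(800)
    y = (rng.random(800) < 1 / (1 + np.exp(-0.3 * x - 0.3 * m))).astype(int)
    r1 = mediation_proportion(x, m, y, n_boot=50, seed=99)
    r2 = mediation_proportion(x, m, y, n_boot=50, seed=99)
    assert r1.ci == r2.ci and r1.proportion_mediated == r2.proportion_mediated


# -- replication and meta ----------------------------------------------------


def _assoc(gene, beta, p):
    return AssociationResult(gene, beta, abs(beta) / 2 + 0.1, p)


@pytest.mark.parametrize(
    "beta_d,beta_r,p_r,expected",
    [
        (0.5, 0.4, 0.0005, "bonferroni_replicated"),
        (0.5, 0.4, 0.03, "nominal"),
        (0.5, -0.4, 0.0001, "not_replicated"),
        (-0.5, -0.4, 0.0005, "bonferroni_replicated"),
        (0.5, 0.4, 0.2, "not_replicated"),
    ],
)
def test_replication_tiers(beta_d, beta_r, p_r, expected):
    tier = classify_replication(
        _assoc("g", beta_d, 1e-8), _assoc("g", beta_r, p_r), n_tested=38
    )
    assert tier == expected
    # 0.05/38 ~ 0.0013: the Bonferroni boundary used above
    assert 0.05 / 38 == pytest.approx(0.0013, abs=5e-5)


def test_meta_equal_strata():
    m = fixed_effects_meta([(1.0, 1.0), (1.0, 1.0)])
    assert m.beta_meta == pytest.approx(1.0)
    assert m.se_meta == pytest.approx(1 / np.sqrt(2), abs=1e-4)


def test_meta_single_stratum_is_identity():
    m = fixed_effects_meta([(0.37, 0.21)])
    assert (m.beta_meta, m.se_meta) == (pytest.approx(0.37), pytest.approx(0.21))


def test_meta_closed_form():
    m = fixed_effects_meta([(0.5, 0.1), (0.3, 0.2)])
    assert m.beta_meta == pytest.approx((50 + 7.5) / 125)
    assert m.se_meta == pytest.approx(1 / np.sqrt(125), abs=1e-4)
    assert m.se_meta == pytest.approx(0.0894, abs=1e-4)


def test_meta_se_never_exceeds_best_stratum():
    rng = np.random.default_rng(16)
    for _ in range(50):
        inputs = [(rng.normal(), rng.uniform(0.05, 1.0)) for _ in range(4)]
        m = fixed_effects_meta(inputs)
        assert m.se_meta <= min(s for _, s in inputs) + 1e-12


def test_meta_input_validation():
    with pytest.raises(ValueError):
        fixed_effects_meta([])
    with pytest.raises(ValueError):
        fixed_effects_meta([(0.1, 0.0)])
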