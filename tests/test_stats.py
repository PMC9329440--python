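import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from prsconcord.engine import ScoreVector, assign_bins
from prsconcord.errors import FitError, ValidationError
from prsconcord.oracle import tail_concordance, tail_concordance_mc_se
from prsconcord.simulate import DiseaseModel, SimConfig, generate_all
from prsconcord.stats import (
    CrossTab,
    auc,
    bootstrap_ci,
    concordance_report,
    cross_classify,
    fit_logistic,
    nri_categorical,
    nri_continuous,
    or_at_cutpoints,
    pearson_r,
    topk_concordance,
)

from _oracles import brute_auc, enum_nri, optimize_logistic
from conftest import make_cohort


def vec(values, ids=None):
    values = np.asarray(values, dtype=float)
    ids = ids or [f"s{i}" for i in range(len(values))]
    return ScoreVector(sample_ids=ids, raw=values, n_variants_used=1)


# ---------------------------------------------------------------------------
# correlation / cross-classification / tail concordance


def test_pearson_r_trivial_cases():
    rng = np.random.default_rng(0)
    x = rng.standard_normal(100)
    assert pearson_r(vec(x), vec(x)) == pytest.approx(1.0)
    assert pearson_r(vec(x), vec(-x)) == pytest.approx(-1.0)


def test_crosstab_of_a_vector_with_itself_is_diagonal():
    rng = np.random.default_rng(1)
    v = vec(rng.standard_normal(1000))
    t = cross_classify(v, v)
    assert t.n == 1000
    assert (t.counts == np.diag(np.diag(t.counts))).all()
    assert np.allclose(np.diag(t.row_pct), 100.0)
    t.check()


def test_crosstab_percentage_invariants_on_published_counts(table3_counts):
    t = CrossTab.from_counts(table3_counts)
    t.check()
    assert t.n == 171_490
    np.testing.assert_allclose(t.row_pct.sum(axis=1), 100.0, atol=0.1)
    np.testing.assert_allclose(t.col_pct.sum(axis=0), 100.0, atol=0.1)
    assert t.cell_pct.sum() == pytest.approx(100.0, abs=0.1)


def test_independent_scores_put_one_percent_on_the_top_diagonal():
    rng = np.random.default_rng(2)
    n = 500_000
    a, b = rng.standard_normal(n), rng.standard_normal(n)
    t = cross_classify(assign_bins(vec(a)), assign_bins(vec(b)))
    assert t.row_pct[6, 6] == pytest.approx(1.0, abs=0.5)


def test_topk_concordance_trivial_and_symmetry():
    rng = np.random.default_rng(3)
    x = rng.standard_normal(2000)
    y = rng.standard_normal(2000)
    assert topk_concordance(x, x, 1) == 1.0
    assert topk_concordance(x, x, 5) == 1.0
    # distinct values: exact symmetry
    assert topk_concordance(x, y, 5) == topk_concordance(y, x, 5)


def test_topk_concordance_matches_gaussian_oracle():
    rho, k, n = 0.65, 1.0, 200_000
    rng = np.random.default_rng(4)
    x = rng.standard_normal(n)
    y = rho * x + np.sqrt(1 - rho**2) * rng.standard_normal(n)
    est = topk_concordance(x, y, k)
    expected = tail_concordance(rho, k)
    se = tail_concordance_mc_se(expected, k, n)
    assert abs(est - expected) < 3 * se


# ---------------------------------------------------------------------------
# logistic fits / ORs / AUC


def test_intercept_only_logistic_recovers_the_logit():
    y = np.r_[np.ones(25), np.zeros(75)]
    fit = fit_logistic(y, np.ones((100, 1)))
    assert fit.params.iloc[0] == pytest.approx(np.log(25 / 75), abs=1e-8)


def test_two_by_two_table_recovers_the_closed_form_or():
    # exposure x outcome counts (a,b,c,d) = (10,90,30,70): OR = (10*70)/(90*30)
    y = np.r_[np.ones(10), np.zeros(90), np.ones(30), np.zeros(70)]
    x = np.r_[np.ones(100), np.zeros(100)]
    X = pd.DataFrame({"const": np.ones(200), "x": x})
    fit = fit_logistic(y, X)
    assert np.exp(fit.params["x"]) == pytest.approx(700 / 2700, abs=1e-6)


def test_logistic_matches_independent_optimizer():
    rng = np.random.default_rng(5)
    X = np.column_stack([np.ones(400), rng.standard_normal((400, 3))])
    beta = np.array([-0.5, 0.8, -0.3, 0.1])
    y = (rng.random(400) < 1 / (1 + np.exp(-X @ beta))).astype(float)
    fit = fit_logistic(y, X)
    ref = optimize_logistic(y, X)
    np.testing.assert_allclose(fit.params.to_numpy(), ref, atol=1e-6)


def test_logistic_failure_modes_are_explicit():
    with pytest.raises(FitError, match="both classes"):
        fit_logistic(np.ones(10), np.ones((10, 1)))
    # perfectly separated predictor
    y = np.r_[np.zeros(20), np.ones(20)]
    X = np.column_stack([np.ones(40), np.r_[np.zeros(20), np.ones(20)]])
    with pytest.raises(FitError):
        fit_logistic(y, X)


def test_or_no_cases_in_reference_group_is_an_error():
    rng = np.random.default_rng(6)
    n = 1000
    raw = rng.standard_normal(n)
    pct = assign_bins(vec(raw))
    outcome = np.zeros(n, dtype=int)
    outcome[pct.percentile >= 99] = 1  # cases only in the top bin
    cohort = make_cohort(n, outcome=outcome, seed=6)
    with pytest.raises(FitError, match="no cases"):
        or_at_cutpoints(pct, cohort, cutpoints=(1.0,))


def test_auc_trivial_and_brute_force():
    assert auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0
    risk = [0.1, 0.4, 0.35, 0.8, 0.35, 0.9]
    outcome = [0, 0, 1, 1, 0, 1]
    assert auc(risk, outcome) == pytest.approx(brute_auc(risk, outcome), abs=1e-12)
    rng = np.random.default_rng(7)
    r = rng.random(60)
    y = rng.integers(0, 2, 60)
    assert auc(r, y) == pytest.approx(brute_auc(r, y), abs=1e-12)


def test_auc_of_uninformative_score_is_half():
    rng = np.random.default_rng(8)
    n = 20_000
    assert auc(rng.random(n), rng.integers(0, 2, n)) == pytest.approx(0.5, abs=0.01)


def test_auc_agrees_with_sklearn():
    from sklearn.metrics import roc_auc_score

    rng = np.random.default_rng(9)
    p = rng.random(500)
    y = rng.integers(0, 2, 500)
    assert auc(p, y) == pytest.approx(roc_auc_score(y, p), abs=1e-12)


# ---------------------------------------------------------------------------
# NRI


def test_nri_continuous_trivial_bounds():
    p = np.array([0.1, 0.5, 0.9, 0.3])
    y = np.array([1, 0, 1, 0])
    assert nri_continuous(p, p, y) == 0.0
    p_new = np.where(y == 1, p + 0.1, p - 0.1)
    assert nri_continuous(p, p_new, y) == 2.0


def test_nri_continuous_matches_enumeration():
    p_old = [0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8]
    p_new = [0.2, 0.2, 0.1, 0.6, 0.4, 0.7, 0.6, 0.9]
    y = [1, 0, 0, 1, 0, 1, 0, 1]
    assert nri_continuous(p_old, p_new, y) == pytest.approx(enum_nri(p_old, p_new, y), abs=1e-12)


@given(st.integers(0, 2**31 - 1))
def test_nri_invariant_under_joint_monotone_transform(seed):
    rng = np.random.default_rng(seed)
    p_old = rng.random(30)
    p_new = rng.random(30)
    y = rng.integers(0, 2, 30)
    if y.sum() in (0, 30):
        return
    base = nri_continuous(p_old, p_new, y)
    transformed = nri_continuous(np.log(p_old + 1), np.log(p_new + 1), y)
    assert transformed == pytest.approx(base, abs=1e-12)


def test_nri_categorical_trivial_and_enumeration():
    bins = np.array([0, 1, 2, 3, 4, 5, 2, 3])
    y = np.array([1, 0, 1, 0, 1, 0, 1, 0])
    assert nri_categorical(bins, bins, y) == 0.0
    # every case moves up one bin (none start at the top), controls fixed
    cases_up = np.where(y == 1, bins + 1, bins)
    assert nri_categorical(bins, cases_up, y) == pytest.approx(1.0)
    rng = np.random.default_rng(10)
    old = rng.integers(0, 7, 40)
    new = rng.integers(0, 7, 40)
    yy = rng.integers(0, 2, 40)
    assert nri_categorical(old, new, yy) == pytest.approx(enum_nri(old, new, yy), abs=1e-12)


def test_nri_categorical_accepts_labels():
    assert nri_categorical(["<1", "40-60"], ["1-20", "40-60"], [1, 0]) == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# bootstrap


def test_bootstrap_of_constant_statistic_has_zero_width():
    lo, hi = bootstrap_ci(lambda x: 1.23, np.arange(100), n_boot=200, seed=0)
    assert lo == hi == 1.23


def test_bootstrap_ci_width_matches_closed_form():
    rng = np.random.default_rng(11)
    x = rng.standard_normal(1000)
    lo, hi = bootstrap_ci(lambda v: v.mean(), x, n_boot=1000, seed=1)
    width = hi - lo
    expected = 2 * 1.96 / np.sqrt(1000)
    assert abs(width - expected) < 0.2 * expected
    assert lo < x.mean() < hi


def test_bootstrap_is_seed_reproducible():
    x = np.random.default_rng(12).random(200)
    a = bootstrap_ci(lambda v: np.median(v), x, n_boot=300, seed=42)
    b = bootstrap_ci(lambda v: np.median(v), x, n_boot=300, seed=42)
    assert a == b


# ---------------------------------------------------------------------------
# full report


def _small_analysis(seed=2, n=4000, **kw):
    cfg = SimConfig(
        n_individuals=n, n_blocks=25, block_size=4, n_snps_a=60, n_snps_b=60,
        prevalence_target=0.2, qc_flag_rates={}, seed=seed, **kw,
    )
    panel, (a, b), cohort = generate_all(cfg)
    from prsconcord.engine import compute_prs, standardize
    from prsconcord.qc import apply_variant_qc, harmonize_alleles

    vecs = []
    for s in (a, b):
        s1, _ = apply_variant_qc(s, panel)
        s2, _ = harmonize_alleles(s1, panel)
        vecs.append(assign_bins(standardize(compute_prs(s2, panel))))
    return vecs[0], vecs[1], cohort


def test_concordance_report_is_seed_reproducible():
    va, vb, cohort = _small_analysis()
    r1 = concordance_report(va, vb, cohort, n_boot=50, seed=9)
    r2 = concordance_report(va, vb, cohort, n_boot=50, seed=9)
    assert r1.to_dict() == r2.to_dict()


def test_concordance_report_internal_consistency():
    va, vb, cohort = _small_analysis()
    rep = concordance_report(va, vb, cohort, n_boot=50, seed=9)
    assert rep.crosstab.n == len(cohort)
    assert -1 <= rep.pearson_r <= 1
    for v in rep.topk_concordance.values():
        assert 0 <= v <= 1
    for d in rep.auc.values():
        for value, lo, hi in d.values():
            assert lo <= value <= hi
    v, lo, hi = rep.nri_continuous
    assert lo <= v <= hi
    for table in rep.or_table.values():
        for r in table.values():
            assert r.ci_lo <= r.odds_ratio <= r.ci_hi


def test_strong_effect_or_recovered_across_replicates():
    """Top-1%-vs-middle-quintile OR: the Wald CI covers the Monte-Carlo truth
    in >= 90 of 100 replicates.  Covariate effects are zero so the marginal
    OR over group membership is the estimand the adjusted fit targets."""
    from scipy.special import expit

    from prsconcord.engine import compute_prs, percentile_ranks, standardize
    from prsconcord.simulate import generate_cohort, generate_panel, generate_score_pair, solve_intercept

    dm = DiseaseModel(beta_prs=0.5, beta_age=0.0, beta_sex=0.0)
    base = dict(
        n_blocks=15, block_size=2, n_snps_a=30, n_snps_b=30, shared_fraction=1.0,
        prevalence_target=0.3, qc_flag_rates={}, disease_model=dm,
    )

    # Monte-Carlo integration of the generative model at large n: expected
    # case probability in the top-1% and middle-quintile groups
    big = SimConfig(n_individuals=400_000, seed=777, **base)
    panel = generate_panel(big)
    scores = generate_score_pair(panel, big)
    z = standardize(compute_prs(scores[0], panel)).standardized
    lp = dm.beta_prs * z
    c = solve_intercept(lp, big.prevalence_target)
    p = expit(c + lp)
    pct = percentile_ranks(z)
    p_top = p[pct >= 99].mean()
    p_mid = p[(pct >= 40) & (pct < 60)].mean()
    q_true = (p_top / (1 - p_top)) / (p_mid / (1 - p_mid))

    covered = 0
    for rep in range(100):
        cfg = SimConfig(n_individuals=6000, seed=5000 + rep, **base)
        panel = generate_panel(cfg)
        scores = generate_score_pair(panel, cfg)
        cohort = generate_cohort(panel, scores, cfg)
        v = assign_bins(standardize(compute_prs(scores[0], panel)))
        res = or_at_cutpoints(v, cohort, cutpoints=(1.0,))[1.0]
        covered += res.ci_lo <= q_true <= res.ci_hi
    assert covered >= 90
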