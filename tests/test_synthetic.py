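"""Synthetic-data generators: reproducibility, moments, missingness
mechanisms and the selective-reporting bias experiment."""

import math

import numpy as np
import pytest
from scipy import stats

import cutmeta as cm
from cutmeta.data_model import DataError


OMEGA = np.array([[0.49, 0.9 * 0.7 * 0.6], [0.9 * 0.7 * 0.6, 0.36]])
BETA = np.array([2.2, 2.0])


def test_bit_reproducible_under_seed():
    d1, t1 = cm.simulate_from_model(15, BETA, OMEGA, level_cutpoints=[3, 6], seed=4)
    d2, t2 = cm.simulate_from_model(15, BETA, OMEGA, level_cutpoints=[3, 6], seed=4)
    assert [(r.y, r.se) for r in d1.records] == [(r.y, r.se) for r in d2.records]
    np.testing.assert_array_equal(t1.theta, t2.theta)
    d3, _ = cm.simulate_from_model(15, BETA, OMEGA, level_cutpoints=[3, 6], seed=5)
    assert [r.y for r in d1.records] != [r.y for r in d3.records]


def test_no_heterogeneity_limit_matches_sampling_variance():
    """With Omega = 0 the spread of estimates equals the sampling part."""
    ds, _ = cm.simulate_from_model(
        3000, [1.0], np.array([[0.0]]), level_cutpoints=[3],
        se_range=(0.2, 0.2), within_rho=0.0, seed=10,
    )
    y = np.array([r.y for r in ds.records])
    assert np.var(y) == pytest.approx(0.04, rel=0.1)
    assert np.mean(y) == pytest.approx(1.0, abs=0.02)


def test_moments_match_hierarchy():
    ds, truth = cm.simulate_from_model(
        4000, BETA, OMEGA, level_cutpoints=[3, 6], se_range=(0.2, 0.2),
        within_rho=0.0, seed=11,
    )
    y = np.array([[ds.record(s, "3").y, ds.record(s, "6").y] for s in ds.study_ids])
    np.testing.assert_allclose(y.mean(axis=0), BETA, atol=0.05)
    np.testing.assert_allclose(np.var(y, axis=0), np.diag(OMEGA) + 0.04, rtol=0.08)


def test_diagonal_omega_zero_within_gives_uncorrelated_estimates():
    ds, _ = cm.simulate_from_model(
        3000, [1.0, 1.0], np.diag([0.2, 0.2]), level_cutpoints=[1, 2],
        within_rho=0.0, seed=12,
    )
    y = np.array([[ds.record(s, "1").y, ds.record(s, "2").y] for s in ds.study_ids])
    r = np.corrcoef(y.T)[0, 1]
    assert abs(r) < 0.05


def test_invalid_omega_rejected():
    with pytest.raises(DataError, match="positive semi-definite"):
        cm.simulate_from_model(5, [1.0, 1.0], np.array([[1.0, 2.0], [2.0, 1.0]]), seed=1)


def test_cohort_null_effect_gives_null_log_ors():
    _, ds, _ = cm.simulate_cohorts(
        20, [-0.5, 0.5], cohort_sizes=(300, 600), outcome_slope=0.0, seed=14
    )
    for lab in ds.registry.labels:
        res = cm.fit_univariate(ds.subset_level(lab))
        assert abs(res.beta_hat) < 2.5 * res.se_beta


def test_cohort_effect_matches_logistic_truth():
    """Pooled per-cut-point log odds ratios track the generating logistic
    model, verified against numerical integration over the factor
    distribution; the odds ratio shrinks as the cut-point rises through the
    risky low range (the classic low-score pattern)."""
    cuts = [-1.5, -0.75, 0.0]
    _, ds, _ = cm.simulate_cohorts(
        40, cuts, cohort_sizes=(500, 900), outcome_slope=-1.2, seed=15
    )
    pooled = [cm.fit_univariate(ds.subset_level(f"{c:g}")).beta_hat for c in cuts]
    assert pooled[0] > pooled[1] > pooled[2] > 0

    def true_log_or(cp, slope=-1.2, intercept=-1.0):
        xs = np.linspace(-6, 6, 4001)
        pdf = stats.norm.pdf(xs)
        p = 1 / (1 + np.exp(-(intercept + slope * xs)))
        low = xs <= cp
        e_low = np.trapezoid(pdf[low] * p[low], xs[low]) / np.trapezoid(pdf[low], xs[low])
        e_hi = np.trapezoid(pdf[~low] * p[~low], xs[~low]) / np.trapezoid(pdf[~low], xs[~low])
        return math.log(e_low / (1 - e_low)) - math.log(e_hi / (1 - e_hi))

    for got, cp in zip(pooled, cuts):
        assert got == pytest.approx(true_log_or(cp), abs=0.15)
    # analytic ordering agrees with the observed ordering
    truths = [true_log_or(c) for c in cuts]
    assert truths[0] > truths[1] > truths[2] > 0


def test_cohort_adjacent_cutpoints_bootstrap_correlation():
    sets, _, _ = cm.simulate_cohorts(
        1, [-0.2, 0.2], cohort_sizes=(600, 600), outcome_slope=-1.2, seed=16
    )
    res = cm.bootstrap_within_corr(list(sets.values())[0], n_boot=400, seed=1)
    assert res.corr[0, 1] > 0.5


def test_missingness_identity_at_zero_probability():
    ds, _ = cm.simulate_from_model(10, BETA, OMEGA, level_cutpoints=[3, 6], seed=17)
    out = cm.apply_missingness(ds, "mcar", p=0.0, seed=1)
    assert len(out.records) == len(ds.records)


def test_mcar_forced_pattern_with_protection():
    ds, _ = cm.simulate_from_model(10, BETA, OMEGA, level_cutpoints=[3, 6], seed=18)
    keep_study = ds.study_ids[0]
    out = cm.apply_missingness(
        ds, "mcar", p=1.0, target_level="6", protect=[keep_study], seed=1
    )
    left = [r.study_id for r in out.records if r.level_id == "6"]
    assert left == [keep_study]
    # without protection the level disappears entirely, with a warning
    with pytest.warns(UserWarning, match="lost every study"):
        gone = cm.apply_missingness(ds, "mcar", p=1.0, target_level="6", seed=1)
    assert all(r.level_id != "6" for r in gone.records)


def test_mnar_significance_predicate():
    """After MNAR-by-significance deletion, every deleted record was
    non-significant; all significant records survive."""
    ds, _ = cm.simulate_from_model(
        60, [0.3, 0.25], np.diag([0.1, 0.1]), level_cutpoints=[3, 6],
        se_range=(0.1, 0.5), seed=19,
    )
    out = cm.apply_missingness(ds, "mnar_significance", p=1.0, alpha=0.05, seed=2)
    kept = {(r.study_id, r.level_id) for r in out.records}
    z = stats.norm.ppf(0.975)
    for r in ds.records:
        if abs(r.y) / r.se > z:
            assert (r.study_id, r.level_id) in kept
        else:
            assert (r.study_id, r.level_id) not in kept


def test_mar_by_level_depends_on_observed_reference():
    ds, _ = cm.simulate_from_model(200, BETA, OMEGA, level_cutpoints=[3, 6], seed=20)
    out = cm.apply_missingness(
        ds, "mar_by_level", p=0.9, target_level="6", reference_level="3",
        slope=3.0, seed=3,
    )
    ref = {r.study_id: r.y for r in ds.records if r.level_id == "3"}
    missing = set(ds.study_ids) - {r.study_id for r in out.records if r.level_id == "6"}
    present = {r.study_id for r in out.records if r.level_id == "6"}
    # deletion targets studies with larger observed reference estimates
    assert np.mean([ref[s] for s in missing]) > np.mean([ref[s] for s in present])


def test_dropped_records_take_covariances_along():
    ds, _ = cm.simulate_from_model(10, BETA, OMEGA, level_cutpoints=[3, 6],
                                   within_rho=0.5, seed=21)
    assert len(ds.within_cov) == 10
    out = cm.apply_missingness(ds, "mcar", p=0.7, target_level="6", seed=4)
    for w in out.within_cov:
        assert any(r.study_id == w.study_id and r.level_id == w.level_b for r in out.records)
        assert any(r.study_id == w.study_id and r.level_id == w.level_a for r in out.records)


def test_selective_reporting_bias_reduced_by_joint_model():
    """Under significance-driven missingness of one cut-point, the
    univariate summary overshoots the truth; the joint multivariate model,
    using the correlated complete cut-point, stays closer (one-sided
    Monte-Carlo comparison over many replicates)."""
    truth = 0.35
    n_rep = 500
    uni_err, mv_err = [], []
    for rep in range(n_rep):
        ds, _ = cm.simulate_from_model(
            12, [0.4, truth], np.array([[0.09, 0.9 * 0.3 * 0.3], [0.9 * 0.3 * 0.3, 0.09]]),
            level_cutpoints=[3, 6], se_range=(0.15, 0.4), within_rho=0.6,
            seed=30000 + rep,
        )
        miss = cm.apply_missingness(ds, "mnar_significance", p=0.85,
                                    target_level="6", seed=60000 + rep)
        lvl = [r for r in miss.records if r.level_id == "6"]
        if len(lvl) < 2 or len(miss.study_ids) < 3:
            continue
        uni_err.append(cm.fit_univariate(lvl).beta_hat - truth)
        blocks = cm.assemble_blocks(miss, warn_missing=False)
        mv = cm.fit_mv(blocks, levels=["3", "6"], restarts=1)
        mv_err.append(mv.beta_hat[1] - truth)
    uni_err, mv_err = np.array(uni_err), np.array(mv_err)
    assert len(uni_err) >= 400
    # univariate is biased away from the null
    assert uni_err.mean() > 2 * uni_err.std(ddof=1) / math.sqrt(len(uni_err))
    # multivariate bias is smaller (one-sided Monte-Carlo test)
    diff = np.abs(uni_err.mean()) - np.abs(mv_err.mean())
    se_diff = np.std(uni_err - mv_err, ddof=1) / math.sqrt(len(uni_err))
    assert diff > 2 * se_diff
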