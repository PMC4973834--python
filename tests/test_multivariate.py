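"""Multivariate random-effects engine: REML surface, missing levels,
borrowing of strength, structured Omega."""

import math

import numpy as np
import pytest
from scipy import stats

import cutmeta as cm
from cutmeta.data_model import DataError
from cutmeta.multivariate import OmegaSpec, profile_restricted_loglik, restricted_loglik


def test_apgar_bivariate_fit(apgar_mv):
    """The joint fit pulls the sparsely reported cut-point 6 down toward the
    cut-point 3 evidence (borrowing of strength) with the between-study
    correlation on the +1 boundary."""
    res = apgar_mv
    assert res.levels == ("3", "6")
    assert res.beta_hat[0] == pytest.approx(2.16, abs=0.02)
    assert res.beta_hat[1] == pytest.approx(2.07, abs=0.02)
    assert res.se_beta[0] == pytest.approx(0.246, abs=0.01)
    assert res.tau[0] == pytest.approx(0.72, abs=0.02)
    assert res.tau[1] == pytest.approx(0.560, abs=0.02)
    assert res.between_corr[0, 1] > 1 - 1e-3
    assert res.boundary
    assert res.n_studies == {"3": 9, "6": 6}


def test_apgar_prediction_intervals(apgar_mv):
    pi3 = cm.mv_prediction_interval(apgar_mv, "3")
    pi6 = cm.mv_prediction_interval(apgar_mv, "6")
    assert pi3.df == 8
    assert pi3.lo_ratio == pytest.approx(1.50, rel=0.02)
    assert pi3.hi_ratio == pytest.approx(50.29, rel=0.02)
    assert pi6.lo_ratio == pytest.approx(2.01, rel=0.02)
    assert pi6.hi_ratio == pytest.approx(31.25, rel=0.02)


def test_microvessel_bivariate_fit(microvessel_mv):
    res = microvessel_mv
    by = dict(zip(res.levels, np.exp(res.beta_hat)))
    assert by["chalkley"] == pytest.approx(1.051, rel=0.02)
    assert by["all_vessels"] == pytest.approx(1.030, rel=0.02)
    taus = dict(zip(res.levels, res.tau))
    assert taus["all_vessels"] == pytest.approx(0.077, abs=0.02)
    assert taus["chalkley"] == pytest.approx(0.0025, abs=0.02)


def test_one_level_reduces_to_univariate(apgar):
    recs = apgar.subset_level("3")
    blocks = [
        cm.StudyBlock(r.study_id, ("3",), np.array([r.y]), np.array([[r.se**2]]))
        for r in recs
    ]
    mv = cm.fit_mv(blocks, OmegaSpec("unstructured", 1), levels=["3"])
    uni = cm.fit_univariate(recs)
    assert mv.beta_hat[0] == pytest.approx(uni.beta_hat, abs=1e-6)
    assert mv.omega_hat[0, 0] == pytest.approx(uni.tau2_hat, abs=1e-6)


def test_disconnected_levels_match_univariate():
    """With no study reporting both levels and zero within-study
    correlation, the joint fit separates into the two univariate fits."""
    rng = np.random.default_rng(5)
    recs = []
    for i in range(8):
        recs.append(cm.EffectRecord(f"A{i}", "1", float(rng.normal(1.0, 0.4)), 0.25, cutpoint=1.0))
    for i in range(8):
        recs.append(cm.EffectRecord(f"B{i}", "2", float(rng.normal(0.4, 0.3)), 0.3, cutpoint=2.0))
    ds = cm.MetaDataset(records=recs)
    mv = cm.fit_mv(cm.assemble_blocks(ds), levels=["1", "2"])
    u1 = cm.fit_univariate(ds.subset_level("1"))
    u2 = cm.fit_univariate(ds.subset_level("2"))
    assert mv.beta_hat[0] == pytest.approx(u1.beta_hat, abs=5e-3)
    assert mv.beta_hat[1] == pytest.approx(u2.beta_hat, abs=5e-3)


def test_restricted_loglik_scalar_reduction():
    """With one study and one level the criterion equals the closed-form
    restricted normal log-density."""
    y, se, tau2, beta = 1.2, 0.3, 0.2, 0.9
    b = cm.StudyBlock("A", ("1",), np.array([y]), np.array([[se**2]]))
    v = se**2 + tau2
    expected = (
        -0.5 * math.log(2 * math.pi * v)
        - 0.5 * (y - beta) ** 2 / v
        - 0.5 * math.log(1 / v)
        + 0.5 * math.log(2 * math.pi)
    )
    got = restricted_loglik(np.array([beta]), np.array([[tau2]]), [b], levels=["1"])
    assert got == pytest.approx(expected, abs=1e-10)


def test_restricted_loglik_dense_oracle():
    """Two complete 2-level studies: criterion matches an independently
    hand-coded dense evaluation."""
    S1 = np.array([[0.04, 0.01], [0.01, 0.09]])
    S2 = np.array([[0.05, 0.0], [0.0, 0.06]])
    y1 = np.array([1.0, 0.7])
    y2 = np.array([1.4, 1.0])
    omega = np.array([[0.3, 0.1], [0.1, 0.2]])
    beta = np.array([1.1, 0.8])
    blocks = [
        cm.StudyBlock("1", ("a", "b"), y1, S1),
        cm.StudyBlock("2", ("a", "b"), y2, S2),
    ]
    V1, V2 = omega + S1, omega + S2
    dens = stats.multivariate_normal.logpdf(y1, beta, V1) + stats.multivariate_normal.logpdf(
        y2, beta, V2
    )
    info = np.linalg.inv(V1) + np.linalg.inv(V2)
    expected = dens - 0.5 * np.linalg.slogdet(info)[1] + math.log(2 * math.pi)
    got = restricted_loglik(beta, omega, blocks, levels=["a", "b"])
    assert got == pytest.approx(expected, abs=1e-10)


def test_reml_optimum_beats_grid(apgar_blocks, apgar_mv):
    """Profiled REML at the fitted Omega is not beaten (beyond 1e-3) by a
    21x21 grid over the two variances at the fitted correlation."""
    rho = apgar_mv.between_corr[0, 1]
    best = apgar_mv.restricted_loglik
    taus1 = np.linspace(0.05, 1.5, 21) ** 2
    taus2 = np.linspace(0.05, 1.5, 21) ** 2
    grid_max = -np.inf
    for t1 in taus1:
        for t2 in taus2:
            om = np.array([[t1, rho * math.sqrt(t1 * t2)], [rho * math.sqrt(t1 * t2), t2]])
            grid_max = max(grid_max, profile_restricted_loglik(om, apgar_blocks, ["3", "6"]))
    assert best >= grid_max - 1e-3


def test_optimum_is_local_maximum(apgar_blocks, apgar_mv):
    base = apgar_mv.restricted_loglik
    om = apgar_mv.omega_hat
    # positive-definiteness-preserving scalings of the fitted Omega
    for f1, f2 in ((1.1, 1.0), (1.0, 1.1), (0.9, 0.9), (1.2, 0.85)):
        D = np.diag([math.sqrt(f1), math.sqrt(f2)])
        pert = D @ om @ D
        assert profile_restricted_loglik(pert, apgar_blocks, ["3", "6"]) <= base + 1e-8


def test_level_relabelling_permutes_results(apgar, apgar_mv):
    relabel = {"3": "6", "6": "3"}  # swap labels, keep data
    recs = [
        cm.EffectRecord(r.study_id, relabel[r.level_id], r.y, r.se,
                        cutpoint={"3": 6.0, "6": 3.0}[r.level_id], scale=r.scale)
        for r in apgar.records
    ]
    wc = [
        cm.WithinCovariance(w.study_id, relabel[w.level_a], relabel[w.level_b], rho=w.rho)
        for w in apgar.within_cov
    ]
    ds = cm.MetaDataset(records=recs, within_cov=wc)
    mv = cm.fit_mv(cm.assemble_blocks(ds), levels=["3", "6"])
    assert mv.beta_hat[0] == pytest.approx(apgar_mv.beta_hat[1], abs=1e-4)
    assert mv.beta_hat[1] == pytest.approx(apgar_mv.beta_hat[0], abs=1e-4)
    assert mv.tau[0] == pytest.approx(apgar_mv.tau[1], abs=1e-3)


def test_parameter_recovery_complete_data():
    """On a large complete synthetic dataset the REML estimates sit within
    two standard errors of the generating values."""
    beta = np.array([2.2, 2.0])
    omega = np.array([[0.49, 0.9 * 0.7 * 0.6], [0.9 * 0.7 * 0.6, 0.36]])
    ds, _ = cm.simulate_from_model(200, beta, omega, level_cutpoints=[3, 6],
                                   within_rho=0.5, seed=99)
    mv = cm.fit_mv(cm.assemble_blocks(ds, warn_missing=False), levels=["3", "6"])
    for j in range(2):
        assert abs(mv.beta_hat[j] - beta[j]) < 2 * mv.se_beta[j]
    assert mv.tau[0] == pytest.approx(0.7, abs=0.15)
    assert mv.tau[1] == pytest.approx(0.6, abs=0.15)
    assert mv.between_corr[0, 1] == pytest.approx(0.9, abs=0.1)


def test_structured_omega_builders():
    spec_c = OmegaSpec("common_var_common_corr", 3)
    om = spec_c.build(np.array([math.log(0.5), 0.0]))
    assert om[0, 0] == pytest.approx(0.25)
    assert om[0, 1] == pytest.approx(om[1, 2])
    assert np.linalg.eigvalsh(om).min() > 0
    spec_a = OmegaSpec("ar1", 4)
    om = spec_a.build(np.array([math.log(0.5), np.arctanh(0.6)]))
    assert om[0, 1] == pytest.approx(0.25 * 0.6)
    assert om[0, 3] == pytest.approx(0.25 * 0.6**3)
    assert spec_c.n_params == 2 and spec_a.n_params == 2
    assert OmegaSpec("unstructured", 3).n_params == 6


def test_structured_fit_smoke(apgar_blocks):
    res = cm.fit_mv(apgar_blocks, OmegaSpec("common_var_common_corr", 2), levels=["3", "6"])
    assert res.tau[0] == pytest.approx(res.tau[1])
    assert res.beta_hat[0] == pytest.approx(2.16, abs=0.1)


def test_errors_unobserved_level_and_too_few_studies(apgar_blocks):
    with pytest.raises(DataError, match="no study"):
        cm.fit_mv(apgar_blocks, levels=["3", "6", "9"])
    with pytest.raises(DataError, match="at least 2"):
        cm.fit_mv(apgar_blocks[:1])


def test_sensitivity_grid_default_zero_reproduces_baseline(microvessel):
    tab = cm.sensitivity_within_corr(microvessel, [0.0])
    mv = cm.fit_mv(cm.assemble_blocks(microvessel), levels=microvessel.registry.labels)
    for _, row in tab.iterrows():
        j = mv.levels.index(row["level"])
        assert row["beta"] == pytest.approx(mv.beta_hat[j], abs=1e-6)


def test_sensitivity_large_rho_barely_moves_summaries(microvessel):
    """Forcing every within-study correlation to +0.9 moves the summary
    hazard ratios by well under 1%."""
    tab = cm.sensitivity_within_corr(microvessel, [0.0, 0.9], override=True)
    piv = tab.pivot(index="level", columns="assumed_rho", values="ratio")
    assert np.all(np.abs(piv[0.9] - piv[0.0]) < 0.006)


def test_sensitivity_bias_smallest_near_true_rho():
    """With data generated at within-study correlation 0.5, the average
    absolute error of the sparse level's summary is no worse at the true
    value than at badly wrong assumed values."""
    errs = {0.0: [], 0.5: [], 0.95: []}
    for rep in range(30):
        ds, _ = cm.simulate_from_model(
            14, [2.2, 2.0], np.array([[0.49, 0.33], [0.33, 0.36]]),
            level_cutpoints=[3, 6], within_rho=0.5, seed=500 + rep,
        )
        ds = cm.MetaDataset(records=list(ds.records))  # drop stated correlations
        ds = cm.apply_missingness(ds, "mcar", p=0.6, target_level="6", seed=rep)
        if sum(r.level_id == "6" for r in ds.records) < 2:
            continue
        for rho in errs:
            blocks = cm.assemble_blocks(ds, impute_rho=rho, warn_missing=False)
            mv = cm.fit_mv(blocks, levels=["3", "6"], restarts=1)
            errs[rho].append(abs(mv.beta_hat[1] - 2.0))
    assert np.mean(errs[0.5]) <= np.mean(errs[0.0]) + 0.02
    assert np.mean(errs[0.5]) <= np.mean(errs[0.95]) + 0.02
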