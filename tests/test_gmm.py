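"""Trajectory mixture model: likelihood oracle, EM behaviour, stratification."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal

from gaitmix import CohortConfig, simulate_cohort
from gaitmix.gmm import (GMMError, GMMFit, GMMSpec, X_MINUTE, align_classes,
                         classify, fit_gmm, hrp_class_index, loso_cv,
                         marginal_loglik, permutation_accuracy,
                         prepare_baseline, select_classes, _loglik)

from .conftest import separated_config


def _random_instance(rng, n=5, K=2):
    Y = rng.normal(300, 40, (n, 6))
    W = rng.normal(27, 5, (n, 1))
    beta = rng.normal(0, 1, (K, 3)) + np.array([300.0, -5.0, 1.0])
    gamma = np.array([-3.0])
    pi = rng.dirichlet(np.ones(K))
    return Y, W, beta, gamma, pi


def _brute_force_loglik(Y, W, beta, gamma, pi, sb2, se2):
    """Dense 6x6 multivariate-normal mixture density, straight from the
    definition (the independent oracle for the closed-form likelihood)."""
    Sigma = sb2 * np.ones((6, 6)) + se2 * np.eye(6)
    ll = 0.0
    for i in range(len(Y)):
        dens = sum(
            pi[k] * multivariate_normal.pdf(
                Y[i], X_MINUTE @ beta[k] + (W[i] @ gamma) * np.ones(6), Sigma)
            for k in range(len(pi)))
        ll += np.log(dens)
    return ll


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_marginal_loglik_matches_brute_force(seed):
    rng = np.random.default_rng(seed)
    Y, W, beta, gamma, pi = _random_instance(rng)
    sb2, se2 = 30.0 ** 2, 10.0 ** 2
    ours = _loglik(Y, W, beta, gamma, pi, sb2, se2)
    oracle = _brute_force_loglik(Y, W, beta, gamma, pi, sb2, se2)
    assert abs(ours - oracle) < 1e-8


def test_loglik_diagonal_limit():
    """With zero random-intercept variance the joint density factorizes into
    per-minute univariate normals."""
    rng = np.random.default_rng(3)
    Y, W, beta, gamma, _ = _random_instance(rng, K=1)
    se2 = 144.0
    ours = _loglik(Y, W, beta, gamma, np.array([1.0]), 0.0, se2)
    mu = (X_MINUTE @ beta[0])[None, :] + (W @ gamma)[:, None]
    uni = -0.5 * (np.log(2 * np.pi * se2) + (Y - mu) ** 2 / se2).sum()
    assert abs(ours - uni) < 1e-8


def test_loglik_degenerate_mixture_weight():
    """pi = (1, 0) reduces to the single-class Gaussian log-likelihood."""
    rng = np.random.default_rng(4)
    Y, W, beta, gamma, _ = _random_instance(rng, K=2)
    sb2, se2 = 400.0, 100.0
    both = _loglik(Y, W, beta, gamma, np.array([1.0, 0.0]), sb2, se2)
    single = _loglik(Y, W, beta[:1], gamma, np.array([1.0]), sb2, se2)
    assert abs(both - single) < 1e-8


def test_separable_groups_recovered_exactly():
    """Two noiseless well-separated classes: posteriors ~1 to the correct
    class and curve coefficients recovered to 1e-2."""
    cfg = separated_config(noise=1e-3)
    subjects, gait, _ = simulate_cohort(cfg)
    # no covariate: in the exact-fit limit a covariate coefficient is on a
    # likelihood ridge with the random intercepts, so recovery is checked on
    # the pure trajectory mixture
    fit = fit_gmm(gait, subjects,
                  GMMSpec(n_classes=2, n_starts=3, seed=0, covariates=()))
    hrp = hrp_class_index(fit)
    truth = subjects.set_index("subject_id").loc[fit.subject_ids, "true_class"]
    tau_correct = np.where(truth == "HRP", fit.posterior[:, hrp],
                           fit.posterior[:, 1 - hrp])
    assert (tau_correct > 0.999).all()
    for curve in [(245.0, -5.0, 0.5), (320.0, -10.0, 2.0)]:
        assert min(np.abs(fit.beta - np.array(curve)).max(axis=1)) < 1e-2


def test_k1_equals_single_class_mixed_model(ms_cohort):
    """K=1 collapses to the ML linear-mixed-model fit (cross-checked against
    an independent mixed-model implementation)."""
    import statsmodels.formula.api as smf

    subjects, gait, _ = ms_cohort
    fit = fit_gmm(gait, subjects, GMMSpec(n_classes=1, seed=0))
    df = gait[gait.visit == 0].merge(subjects[["subject_id", "bmi"]],
                                     on="subject_id")
    df["minute2"] = df.minute ** 2
    m = smf.mixedlm("speed_ft_min ~ minute + minute2 + bmi", df,
                    groups=df["subject_id"]).fit(reml=False)
    assert abs(fit.loglik - m.llf) < 1e-4
    assert np.allclose(np.r_[fit.beta[0], fit.gamma],
                       m.fe_params.to_numpy(), atol=1e-3)
    Y, W, _ = prepare_baseline(gait, subjects)
    assert abs(marginal_loglik(fit, Y, W) - fit.loglik) < 1e-8


def test_em_monotone_and_posteriors_normalized(ms_fit2):
    h = ms_fit2.loglik_history
    slack = 1e-10 * np.abs(h[:-1])
    assert (np.diff(h) >= -slack - 1e-9).all()
    rows = ms_fit2.posterior.sum(axis=1)
    assert np.allclose(rows, 1.0, atol=1e-8)
    assert np.allclose(ms_fit2.pi, ms_fit2.posterior.mean(axis=0), atol=1e-6)
    # information criteria arithmetic
    p = ms_fit2.n_params
    n = len(ms_fit2.subject_ids)
    assert ms_fit2.aic == pytest.approx(-2 * ms_fit2.loglik + 2 * p)
    assert ms_fit2.bic == pytest.approx(-2 * ms_fit2.loglik + p * np.log(n))


def test_subject_order_permutation_invariance(ms_cohort):
    subjects, gait, _ = ms_cohort
    fit_a = fit_gmm(gait, subjects, GMMSpec(n_classes=2, n_starts=3, seed=2))
    rng = np.random.default_rng(0)
    perm_sub = subjects.sample(frac=1.0, random_state=1).reset_index(drop=True)
    fit_b = fit_gmm(gait, perm_sub, GMMSpec(n_classes=2, n_starts=3, seed=2))
    assert fit_a.loglik == pytest.approx(fit_b.loglik, rel=1e-6)
    order_a = np.argsort(fit_a.beta[:, 0])
    order_b = np.argsort(fit_b.beta[:, 0])
    assert np.allclose(fit_a.beta[order_a], fit_b.beta[order_b], atol=1e-3)
    # assignments agree subject-by-subject after label alignment
    la = pd.Series(classify(fit_a).table.set_index("subject_id").label)
    lb = pd.Series(classify(fit_b).table.set_index("subject_id").label)
    assert (la.sort_index() == lb.sort_index()).all()


def test_large_cohort_parameter_recovery():
    """At 10x the study size the ML fit recovers the generating mixture:
    weights, variance components and class curves."""
    cfg = CohortConfig(n_hc=0, n_lrp=470, n_hrp=150, seed=9)
    subjects, gait, _ = simulate_cohort(cfg)
    fit = fit_gmm(gait, subjects, GMMSpec(n_classes=2, n_starts=3, seed=1))
    hrp = hrp_class_index(fit)
    assert fit.pi[hrp] == pytest.approx(150 / 620, abs=0.04)
    assert fit.sigma_b2 == pytest.approx(35.0 ** 2, rel=0.15)
    assert fit.sigma_e2 == pytest.approx(10.0 ** 2, rel=0.10)
    truth = (subjects.set_index("subject_id")
             .loc[fit.subject_ids, "true_class"] == "HRP").to_numpy()
    acc = permutation_accuracy(truth.astype(int),
                               fit.posterior.argmax(axis=1))
    assert acc > 0.88


class TestClassify:
    def _fit(self, beta, posterior):
        n, K = posterior.shape
        return GMMFit(
            beta=np.asarray(beta, float), gamma=np.zeros(1),
            pi=posterior.mean(axis=0), sigma_b2=1.0, sigma_e2=1.0,
            loglik=0.0, aic=0.0, bic=0.0, posterior=np.asarray(posterior),
            subject_ids=[f"S{i}" for i in range(n)], covariates=("bmi",),
            converged=True, n_iter=1)

    def test_slower_class_is_hrp(self):
        beta = [[317.0, 0, 0], [245.0, 0, 0]]
        fit = self._fit(beta, np.array([[0.9, 0.1], [0.2, 0.8]]))
        strat = classify(fit)
        assert strat.hrp_class_index == 1
        assert list(strat.table.label) == ["LRP", "HRP"]

    def test_equal_curves_tie_breaks_to_lower_index(self):
        beta = [[300.0, -5, 1], [300.0, -5, 1]]
        fit = self._fit(beta, np.array([[0.6, 0.4]]))
        assert classify(fit).hrp_class_index == 0

    def test_boundary_posterior_goes_to_hrp(self):
        beta = [[317.0, 0, 0], [245.0, 0, 0]]
        fit = self._fit(beta, np.array([[0.5, 0.5]]))
        assert list(classify(fit).table.label) == ["HRP"]

    def test_k3_rejected(self):
        beta = [[1.0, 0, 0], [2.0, 0, 0], [3.0, 0, 0]]
        fit = self._fit(beta, np.ones((2, 3)) / 3)
        with pytest.raises(GMMError):
            classify(fit)


def test_select_classes_kmax1(ms_cohort):
    subjects, gait, _ = ms_cohort
    fits, chosen = select_classes(gait, subjects, 1,
                                  GMMSpec(n_starts=2, seed=0))
    assert chosen == 1 and set(fits) == {1}


def test_k_exceeding_subjects_rejected():
    cfg = separated_config(n_per_class=2, noise=1.0)
    subjects, gait, _ = simulate_cohort(cfg)
    with pytest.raises(GMMError):
        fit_gmm(gait, subjects, GMMSpec(n_classes=5, seed=0))


class TestLoso:
    def test_well_separated_agreement(self):
        """Held-out assignments agree with full-data assignments on a
        clearly separated cohort."""
        cfg = separated_config(n_per_class=8, noise=5.0, seed=2)
        cfg = dataclasses.replace(cfg, sd_random_intercept=10.0)
        subjects, gait, _ = simulate_cohort(cfg)
        rep = loso_cv(gait, subjects, GMMSpec(n_classes=2, n_starts=2, seed=0))
        assert rep.agreement >= 0.9
        assert len(rep.assignments) == 16

    def test_too_few_subjects(self):
        cfg = separated_config(n_per_class=1, noise=1.0)
        subjects, gait, _ = simulate_cohort(cfg)
        with pytest.raises(GMMError):
            loso_cv(gait, subjects, GMMSpec(n_classes=2, seed=0))

    def test_k1_agreement_is_one(self):
        cfg = separated_config(n_per_class=3, noise=1.0)
        subjects, gait, _ = simulate_cohort(cfg)
        rep = loso_cv(gait, subjects, GMMSpec(n_classes=1, seed=0))
        assert rep.agreement == 1.0


def test_permutation_accuracy_is_label_invariant():
    truth = np.array([0, 0, 1, 1, 1])
    pred = np.array([1, 1, 0, 0, 0])
    assert permutation_accuracy(truth, pred) == 1.0
    assert permutation_accuracy(truth, 1 - pred) == 1.0
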