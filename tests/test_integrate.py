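"""Elastic-net integration, the per-SNP weight conversion and weight ratio."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from metaprs import (
    combine_to_per_snp_weights, elastic_net_integration, elastic_net_logistic,
    elastic_net_path, lambda_grid, score_prs, weight_ratio,
)
from metaprs.integrate import MetaWeights
from metaprs.prs import ScoreSet, SNPWeightSet

from .conftest import irls_logistic, toy_cohort


def _logistic_data(seed=0, n=400, p=4, n_free=2):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p + n_free))
    eta = 0.8 * X[:, 0] - 0.5 * X[:, 1] - 0.4
    if n_free:
        eta = eta + 0.3 * X[:, p]
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
    pf = np.concatenate([np.ones(p), np.zeros(n_free)])
    return X, y, pf


def test_tiny_penalty_recovers_unpenalized_mle():
    X, y, pf = _logistic_data()
    lams = np.geomspace(0.5, 1e-9, 40)
    coefs, intercepts = elastic_net_path(X, y, pf, lams, l1_ratio=0.5, tol=1e-12)
    oracle = irls_logistic(np.column_stack([X, np.ones(len(y))]), y)
    np.testing.assert_allclose(coefs[-1], oracle[:-1], atol=1e-4)
    assert intercepts[-1] == pytest.approx(oracle[-1], abs=1e-4)


def test_strong_penalty_zeroes_noise_columns():
    rng = np.random.default_rng(1)
    n = 500
    signal = rng.standard_normal(n)
    noise = rng.standard_normal((n, 3))
    y = (rng.random(n) < 1 / (1 + np.exp(-2 * signal))).astype(float)
    X = np.column_stack([signal, noise])
    pf = np.ones(4)
    beta, _ = elastic_net_logistic(X, y, pf, lam=0.08, l1_ratio=0.5, tol=1e-12)
    assert beta[0] != 0.0
    np.testing.assert_allclose(beta[1:], 0.0, atol=1e-12)


def test_duplicated_columns_share_coefficient_under_ridge_component():
    rng = np.random.default_rng(2)
    n = 600
    x = rng.standard_normal(n)
    y = (rng.random(n) < 1 / (1 + np.exp(-1.5 * x))).astype(float)
    X = np.column_stack([x, x])
    beta, _ = elastic_net_logistic(X, y, np.ones(2), lam=0.02, l1_ratio=0.5,
                                   tol=1e-14)
    assert beta[0] == pytest.approx(beta[1], abs=1e-6)


def test_solver_matches_sklearn_at_matched_objective():
    """All-penalized case: sklearn saga minimizes C*loglik + elasticnet
    penalty, equal to our objective at C = 1/(n*lambda)."""
    from sklearn.linear_model import LogisticRegression

    X, y, _ = _logistic_data(seed=3, n=300, p=4, n_free=0)
    lam = 0.03
    sk = LogisticRegression(solver="saga", l1_ratio=0.5, C=1 / (len(y) * lam),
                            max_iter=200_000, tol=1e-12)
    sk.fit(X, y)
    beta, b0 = elastic_net_logistic(X, y, np.ones(4), lam, 0.5, tol=1e-13)
    np.testing.assert_allclose(beta, sk.coef_[0], atol=2e-6)
    assert b0 == pytest.approx(sk.intercept_[0], abs=2e-5)


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not available")
def test_solver_matches_glmnet(tmp_path):
    """Independent oracle: R glmnet at fixed lambda with penalty factors.

    glmnet rescales penalty factors to sum to nvars, so ours are pre-scaled
    to match its convention.
    """
    X, y, pf = _logistic_data(seed=4, n=250, p=3, n_free=2)
    np.savetxt(tmp_path / "X.csv", X, delimiter=",")
    np.savetxt(tmp_path / "y.csv", y, delimiter=",")
    lam = 0.02
    script = f"""
    suppressMessages(library(glmnet))
    X <- as.matrix(read.csv("{tmp_path}/X.csv", header=FALSE))
    y <- scan("{tmp_path}/y.csv", quiet=TRUE)
    f <- glmnet(X, y, family="binomial", alpha=0.5, lambda={lam},
                penalty.factor=c(1,1,1,0,0), standardize=FALSE, thresh=1e-14)
    cat(as.numeric(coef(f)), sep="\\n")
    """
    out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                         text=True, check=True)
    r_coef = np.array([float(v) for v in out.stdout.split()])
    pf_glmnet = pf * (len(pf) / pf.sum())
    beta, b0 = elastic_net_logistic(X, y, pf_glmnet, lam, 0.5, tol=1e-13)
    np.testing.assert_allclose(np.append(b0, beta), r_coef, atol=1e-5)


def _integration_setup(seed=5, n=500):
    rng = np.random.default_rng(seed)
    dos = rng.binomial(2, 0.4, size=(n, 4)).astype(float)
    cohort = toy_cohort(dos)
    cohort.set_label = pd.Series(["PRS"] * n, index=cohort.individuals)
    prs1 = dos[:, 0] - dos[:, 1] * 0.5
    prs2 = rng.standard_normal(n)
    eta = 0.9 * (prs1 - prs1.mean()) / prs1.std() - 0.5
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
    cohort.diseases = pd.DataFrame({"d": y}, index=cohort.individuals)

    def _ss(v, name):
        s = pd.Series(v, index=cohort.individuals)
        return ScoreSet(trait_id=name, raw=s,
                        standardized=(s - s.mean()) / s.std(ddof=0),
                        mean=float(s.mean()), sd=float(s.std(ddof=0)),
                        source_set="PRS")

    scores = {"rf_a": _ss(prs1, "rf_a"), "d_prs": _ss(prs2, "d_prs")}
    return cohort, scores


def test_integration_deterministic_under_seed():
    cohort, scores = _integration_setup()
    kw = dict(covariate_columns=[], folds=4, seed=9, n_lambdas=12)
    m1 = elastic_net_integration(scores, cohort, "d", "d_prs", **kw)
    m2 = elastic_net_integration(scores, cohort, "d", "d_prs", **kw)
    assert m1.gamma == m2.gamma and m1.lambda_ == m2.lambda_
    m3 = elastic_net_integration(scores, cohort, "d", "d_prs",
                                 covariate_columns=[], folds=4, seed=10,
                                 n_lambdas=12)
    # a different fold seed may select a different penalty
    assert set(m3.gamma) == set(m1.gamma)


def test_integration_validates_inputs():
    cohort, scores = _integration_setup()
    with pytest.raises(ValueError, match="folds"):
        elastic_net_integration(scores, cohort, "d", "d_prs", folds=1)
    with pytest.raises(ValueError, match="disease PRS"):
        elastic_net_integration({"rf_a": scores["rf_a"]}, cohort, "d", "d_prs")


def _meta(gamma, sigmas, disease_id="d", disease_prs_id="d_prs"):
    return MetaWeights(
        disease_id=disease_id, gamma=gamma, disease_prs_id=disease_prs_id,
        l1_ratio=0.5, lambda_=0.1, intercept=0.0, covariate_coefs={},
        cv_curve=pd.DataFrame({"lambda": [0.1], "mean_auc": [0.5]}),
        seed=0, sigmas=sigmas)


def _wset(ids, weights, trait="t"):
    return SNPWeightSet(trait_id=trait, method="ldpred_inf", table=pd.DataFrame({
        "id": ids, "effect_allele": ["A"] * len(ids),
        "other_allele": ["G"] * len(ids), "weight": weights}))


def test_combine_hand_arithmetic():
    """Single component, gamma=2, sigma=0.5, alpha=(0.1,-0.3) -> (0.4,-1.2)."""
    meta = _meta({"c1": 2.0, "d_prs": 0.0}, {"c1": 0.5, "d_prs": 1.0})
    combined = combine_to_per_snp_weights(meta, {
        "c1": _wset(["v1", "v2"], [0.1, -0.3]),
        "d_prs": _wset(["v1", "v2"], [9.9, 9.9]),
    })
    got = combined.table.set_index("id")["weight"]
    assert got["v1"] == pytest.approx(0.4)
    assert got["v2"] == pytest.approx(-1.2)


def test_combine_zero_gammas_give_zero_weights():
    meta = _meta({"c1": 0.0, "d_prs": 0.0}, {"c1": 1.0, "d_prs": 1.0})
    combined = combine_to_per_snp_weights(meta, {
        "c1": _wset(["v1"], [0.5]), "d_prs": _wset(["v1"], [0.7])})
    assert (combined.table["weight"] == 0).all()


def test_combine_rejects_nonpositive_sigma():
    meta = _meta({"c1": 1.0, "d_prs": 1.0}, {"c1": 0.0, "d_prs": 1.0})
    with pytest.raises(ValueError, match="sigma"):
        combine_to_per_snp_weights(meta, {
            "c1": _wset(["v1"], [0.5]), "d_prs": _wset(["v1"], [0.7])})


def test_combined_scoring_equals_weighted_component_sum():
    """The central linearity identity: scoring with combined per-SNP weights
    equals the gamma/sigma-weighted sum of component raw scores (up to the
    additive constant absorbed by standardization)."""
    rng = np.random.default_rng(7)
    dos = rng.binomial(2, 0.4, size=(60, 5)).astype(float)
    cohort = toy_cohort(dos)
    ids = list(cohort.variants["id"])
    w1 = _wset(ids[:4], rng.standard_normal(4), trait="c1")
    w2 = _wset(ids[2:], rng.standard_normal(3), trait="d_prs")
    gamma = {"c1": 0.7, "d_prs": -1.3}
    sigmas = {"c1": 0.9, "d_prs": 2.1}
    meta = _meta(gamma, sigmas)
    combined = combine_to_per_snp_weights(meta, {"c1": w1, "d_prs": w2})
    s_combined = score_prs(cohort, combined).raw
    s_expected = sum(gamma[c] / sigmas[c] * score_prs(cohort, w).raw
                     for c, w in (("c1", w1), ("d_prs", w2)))
    np.testing.assert_allclose(s_combined, s_expected, atol=1e-8)


@pytest.mark.parametrize("gamma, expected", [
    ({"rf_1": 0.2, "rf_2": -0.1, "d_prs": 0.05}, 2.0),
    ({"d_prs": 0.5}, 0.0),
    ({"rf_1": 0.3, "rf_2": -0.3, "d_prs": 0.7}, 0.0),  # cancellation
])
def test_weight_ratio_sum_convention(gamma, expected):
    meta = _meta(gamma, {k: 1.0 for k in gamma})
    assert weight_ratio(meta) == pytest.approx(expected)


def test_weight_ratio_undefined_and_per_term_mode():
    meta = _meta({"rf_1": 0.2, "d_prs": 0.0}, {"rf_1": 1.0, "d_prs": 1.0})
    assert weight_ratio(meta) is None
    meta2 = _meta({"rf_1": 0.3, "rf_2": -0.3, "d_prs": 0.1},
                  {"rf_1": 1.0, "rf_2": 1.0, "d_prs": 1.0})
    assert weight_ratio(meta2, mode="per_term_abs") == pytest.approx(6.0)
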