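"""Replicate studies: calibration, parameter recovery and the directional
comparison of the meta-score against the plain disease PRS.

These are the package's own experiments, run at desk scale on synthetic
cohorts. They are consumed by the acceptance script and the test suite, and
are reusable for sensitivity analyses (all sizes and architecture parameters
are arguments).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .evaluation import continuous_nri, fit_risk_models, r2_difference_test
from .gwas import gwas_linear, gwas_logistic
from .heritability import bonferroni_threshold, compute_ld_scores, ldsc_h2
from .integrate import combine_to_per_snp_weights, elastic_net_integration
from .prs import ld_corr_matrix, ldpred_inf_reweight, score_prs, standardize_scores
from .screen import run_screen
from .simulate import GWAS, PRS, VALIDATION, SimulationConfig, simulate_cohort

logger = logging.getLogger(__name__)


def threshold_battery(alpha: float = 0.05) -> dict[str, float]:
    """The Bonferroni thresholds of the analysis design, from alpha and the
    test counts of each screening family (112 risk factors, 247 disease
    GWASs, the 112 x 700 association screen, 72 meta-score associations,
    70 x 2 NRI models, 43 R^2-difference tests, 10 early-onset hazard
    models)."""
    return {
        f"bonferroni_{n}": bonferroni_threshold(alpha, n)
        for n in (112, 247, 78_400, 72, 140, 43, 10)
    }


def _derive_seed(seed: int, k: int) -> int:
    return int((seed * 100_003 + k) % (2 ** 31 - 1))


def h2_recovery_study(n_reps: int = 50, seed: int = 0, *, n_gwas: int = 5000,
                      n_snps: int = 500, n_blocks: int = 100,
                      rf_h2: float = 0.4) -> dict:
    """LD score regression recovery of a simulated SNP heritability.

    Each replicate simulates a fresh cohort, runs the linear GWAS in the
    GWAS set and regresses chi-square on in-sample LD scores. Reports the
    mean estimate, its spread and the standard error of the mean.
    """
    estimates = []
    for rep in range(n_reps):
        cfg = SimulationConfig(
            n_gwas=n_gwas, n_prs=2, n_validation=0, n_snps=n_snps,
            n_blocks=n_blocks, n_risk_factors=1, rf_h2=rf_h2,
            prevalence=[0.1], seed=_derive_seed(seed, rep))
        cohort = simulate_cohort(cfg)
        ss = gwas_linear(cohort, "rf_1", set_label=GWAS)
        ld = compute_ld_scores(cohort, set_label=GWAS)
        estimates.append(ldsc_h2(ss, ld).h2_raw)
    est = np.asarray(estimates)
    return {
        "true_h2": rf_h2, "mean": float(est.mean()), "sd": float(est.std(ddof=1)),
        "sem": float(est.std(ddof=1) / np.sqrt(n_reps)),
        "bias": float(est.mean() - rf_h2), "n_reps": n_reps,
        "estimates": est.tolist(),
    }


def logistic_null_calibration(seed: int = 0, *, n_gwas: int = 1500,
                              n_snps: int = 2000, n_blocks: int = 400,
                              alpha: float = 0.05) -> dict:
    """Type-I error of the logistic GWAS under a global-null disease.

    The disease has no mediated and no direct genetic component, so every
    per-variant association is a null test; the rejection rate at ``alpha``
    estimates the size of the test.
    """
    cfg = SimulationConfig(
        n_gwas=n_gwas, n_prs=2, n_validation=0, n_snps=n_snps,
        n_blocks=n_blocks, n_risk_factors=1, rf_h2=0.3,
        mediation_theta=[[0.0]], disease_direct_h2=[0.0],
        prevalence=[0.3], seed=seed)
    cohort = simulate_cohort(cfg)
    ss = gwas_logistic(cohort, "disease_1", set_label=GWAS,
                       covariate_columns=["age", "sex", "array"])
    p = ss.table["P"].to_numpy()
    rate = float((p < alpha).mean())
    se = float(np.sqrt(alpha * (1 - alpha) / len(p)))
    return {"alpha": alpha, "rate": rate, "binomial_se": se, "n_tests": int(len(p)),
            "pvalues": p.tolist()}


def delta_r2_type1_study(n_reps: int = 1000, seed: int = 0, *, n: int = 1000,
                         prevalence: float = 0.3, score_corr: float = 0.5,
                         alpha: float = 0.05) -> dict:
    """Size of the dependent-R^2-difference Wald test under the null.

    Two mutually correlated scores, both independent of the outcome, are
    compared; the rejection rate at ``alpha`` estimates the test's size.
    """
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_reps):
        z = rng.standard_normal((n, 2))
        a = z[:, 0]
        b = score_corr * z[:, 0] + np.sqrt(1 - score_corr ** 2) * z[:, 1]
        y = (rng.random(n) < prevalence).astype(float)
        res = r2_difference_test(a, b, y, method="wald", bootstrap=0)
        rejections += res["p"] < alpha
    rate = rejections / n_reps
    se = float(np.sqrt(alpha * (1 - alpha) / n_reps))
    return {"alpha": alpha, "rate": float(rate), "binomial_se": se,
            "n_reps": n_reps}


@dataclass
class ComparisonResult:
    delta_nri: list[float]
    delta_r2: list[float]
    auc_meta_minus_disease: list[float]

    def summary(self) -> dict:
        dn = np.asarray(self.delta_nri)
        dr = np.asarray(self.delta_r2)
        return {
            "n_reps": len(dn),
            "frac_delta_nri_positive": float((dn > 0).mean()),
            "frac_delta_r2_positive": float((dr > 0).mean()),
            "mean_delta_nri": float(dn.mean()),
            "mean_delta_r2": float(dr.mean()),
        }


def _default_arch(mediated: bool) -> dict:
    if mediated:
        # disease risk flows through the risk factors (plus a small direct term)
        return dict(n_risk_factors=3, rf_h2=0.5,
                    mediation_theta=[[0.40], [0.30], [0.25]],
                    disease_direct_h2=[0.05])
    # purely direct genetic architecture: risk factors carry no disease signal
    return dict(n_risk_factors=3, rf_h2=0.5,
                mediation_theta=[[0.0], [0.0], [0.0]],
                disease_direct_h2=[0.30])


def run_single_comparison(seed: int, *, mediated: bool = True,
                          n_gwas: int = 2000, n_prs: int = 2000,
                          n_validation: int = 1500, n_snps: int = 200,
                          n_blocks: int = 40, prevalence: float = 0.15,
                          folds: int = 5, n_lambdas: int = 15,
                          min_h2: float = 0.05) -> dict:
    """One full pipeline replicate comparing meta-score vs disease PRS.

    Runs GWAS, LDSC (estimates clipped below at ``min_h2`` -- the screening
    step of the full pipeline is deliberately bypassed here so that the
    comparison itself, not screening power at desk scale, is measured),
    LDpred-inf, scoring, the association screen, elastic-net integration and
    the validation-set evaluation. Returns delta-NRI, delta-R^2 and the AUC
    difference (meta minus disease PRS).
    """
    arch = _default_arch(mediated)
    cfg = SimulationConfig(
        n_gwas=n_gwas, n_prs=n_prs, n_validation=n_validation,
        n_snps=n_snps, n_blocks=n_blocks, prevalence=[prevalence],
        seed=seed, **arch)
    cohort = simulate_cohort(cfg)
    ld_scores = compute_ld_scores(cohort, set_label=GWAS)
    ld = ld_corr_matrix(cohort, set_label=GWAS)
    scores, weights = {}, {}
    for rf in cohort.risk_factors.columns:
        ss = gwas_linear(cohort, rf, set_label=GWAS)
        h2 = max(ldsc_h2(ss, ld_scores).h2, min_h2)
        weights[rf] = ldpred_inf_reweight(ss, ld, h2=h2, min_h2=min_h2)
        scores[rf] = standardize_scores(score_prs(cohort, weights[rf]),
                                        cohort, source_set=PRS)
    ssd = gwas_logistic(cohort, "disease_1", set_label=GWAS)
    h2d = max(ldsc_h2(ssd, ld_scores).h2, min_h2)
    weights["disease_prs"] = ldpred_inf_reweight(ssd, ld, h2=h2d, min_h2=min_h2)
    scores["disease_prs"] = standardize_scores(
        score_prs(cohort, weights["disease_prs"]), cohort, source_set=PRS)

    screen_tab = run_screen({r: scores[r] for r in cohort.risk_factors.columns},
                            cohort, ["disease_1"])
    selected = screen_tab.selected.get("disease_1", [])
    prs_scores = {r: scores[r] for r in selected}
    prs_scores["disease_prs"] = scores["disease_prs"]
    meta = elastic_net_integration(
        prs_scores, cohort, "disease_1", "disease_prs",
        folds=folds, seed=_derive_seed(seed, 1), n_lambdas=n_lambdas)
    combined = combine_to_per_snp_weights(
        meta, {pid: weights[pid if pid != "disease_prs" else "disease_prs"]
               for pid in meta.gamma})
    meta_std = standardize_scores(score_prs(cohort, combined), cohort,
                                  source_set=PRS)

    val_ids = cohort.individuals[cohort.set_mask(VALIDATION)]
    y = cohort.diseases.loc[val_ids, "disease_1"].to_numpy(dtype=int)
    models = fit_risk_models(cohort, "disease_1", {
        "diseasePRS": scores["disease_prs"].standardized,
        "metaPRS": meta_std.standardized})
    p_null = models["null"].probabilities
    nri_meta = continuous_nri(p_null, models["null+metaPRS"].probabilities, y)
    nri_dis = continuous_nri(p_null, models["null+diseasePRS"].probabilities, y)
    dr2 = r2_difference_test(
        scores["disease_prs"].standardized.loc[val_ids],
        meta_std.standardized.loc[val_ids], y, method="wald", bootstrap=0)
    from sklearn.metrics import roc_auc_score

    auc_meta = roc_auc_score(y, meta_std.standardized.loc[val_ids])
    auc_dis = roc_auc_score(y, scores["disease_prs"].standardized.loc[val_ids])
    return {
        "delta_nri": nri_meta.nri - nri_dis.nri,
        "delta_r2": dr2["delta_r2"],
        "delta_auc": auc_meta - auc_dis,
        "n_selected_rfprs": len(selected),
    }


def eq5_equivalence_deviation(seed: int = 0, *, n_prs: int = 800,
                              n_snps: int = 120, n_blocks: int = 20) -> dict:
    """Max per-individual deviation of the combined-per-SNP meta score from
    the gamma/sigma-weighted sum of component raw scores (identical up to an
    additive constant by linearity; the constant is removed before
    comparing)."""
    cfg = SimulationConfig(
        n_gwas=800, n_prs=n_prs, n_validation=400, n_snps=n_snps,
        n_blocks=n_blocks, n_risk_factors=2, rf_h2=0.5,
        mediation_theta=[[0.45], [0.35]], disease_direct_h2=[0.05],
        prevalence=[0.15], seed=seed)
    cohort = simulate_cohort(cfg)
    ld_scores = compute_ld_scores(cohort, set_label=GWAS)
    ld = ld_corr_matrix(cohort, set_label=GWAS)
    scores, weights = {}, {}
    for rf in cohort.risk_factors.columns:
        ss = gwas_linear(cohort, rf, set_label=GWAS)
        h2 = max(ldsc_h2(ss, ld_scores).h2, 0.05)
        weights[rf] = ldpred_inf_reweight(ss, ld, h2=h2)
        scores[rf] = standardize_scores(score_prs(cohort, weights[rf]),
                                        cohort, source_set=PRS)
    ssd = gwas_logistic(cohort, "disease_1", set_label=GWAS)
    weights["disease_prs"] = ldpred_inf_reweight(
        ssd, ld, h2=max(ldsc_h2(ssd, ld_scores).h2, 0.05))
    scores["disease_prs"] = standardize_scores(
        score_prs(cohort, weights["disease_prs"]), cohort, source_set=PRS)
    meta = elastic_net_integration(scores, cohort, "disease_1", "disease_prs",
                                   folds=5, seed=_derive_seed(seed, 2),
                                   n_lambdas=12)
    combined = combine_to_per_snp_weights(meta, weights)
    combined_score = score_prs(cohort, combined).raw
    linear_sum = sum(meta.gamma[pid] / meta.sigmas[pid] * scores[pid].raw
                     for pid in meta.gamma)
    diff = combined_score - linear_sum
    deviation = float(np.max(np.abs(diff - diff.mean())))
    return {"max_abs_deviation": deviation, "n_individuals": len(diff),
            "n_components": len(meta.gamma)}


def comparison_study(n_reps: int = 50, seed: int = 0, *, mediated: bool = True,
                     **kwargs) -> ComparisonResult:
    """Replicate the meta-vs-disease-PRS comparison across seeded cohorts."""
    dn, dr, da = [], [], []
    for rep in range(n_reps):
        out = run_single_comparison(_derive_seed(seed, 1000 + rep),
                                    mediated=mediated, **kwargs)
        dn.append(out["delta_nri"])
        dr.append(out["delta_r2"])
        da.append(out["delta_auc"])
        logger.debug("rep %d (mediated=%s): %s", rep, mediated, out)
    return ComparisonResult(delta_nri=dn, delta_r2=dr, auc_meta_minus_disease=da)
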