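"""Meta-score integration: elastic-net logistic regression over PRS columns.

The selected risk-factor PRSs and the disease PRS (all standardized in the
PRS sample set) enter a penalized logistic regression of the disease with
L1+L2 mixing, covariates included unpenalized, and the penalty strength
chosen by stratified 10-fold cross-validation maximizing the mean held-out
AUC (ties broken toward the smaller penalty). The per-PRS coefficients
gamma_1..gamma_c are then converted to a single per-SNP weight vector

    w_j = sum_c (gamma_c / sigma_c) * alpha_jc,

with sigma_c the PRS-set standard deviation of component c and alpha_jc its
per-SNP weight, so that scoring any cohort with the combined weights equals
the gamma/sigma-weighted sum of the component raw scores up to an additive
constant (exactly, by linearity).

The solver is a glmnet-convention coordinate descent: objective

    (1/n) sum_i [log(1 + exp(eta_i)) - y_i eta_i]
    + lambda * sum_j pf_j * (l1_ratio |b_j| + (1 - l1_ratio)/2 b_j^2),

with per-feature penalty factors pf_j (0 for covariates and the intercept),
an IRLS outer loop and soft-thresholding inner updates.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .gwas import covariate_design
from .prs import ScoreSet, SNPWeightSet
from .simulate import Cohort, PRS

logger = logging.getLogger(__name__)

_WMIN = 1e-5  # floor on IRLS weights, glmnet-style


@dataclass
class MetaWeights:
    """Elastic-net coefficients of one disease's meta-score."""

    disease_id: str
    gamma: dict[str, float]            # prs_id -> coefficient
    disease_prs_id: str
    l1_ratio: float
    lambda_: float
    intercept: float
    covariate_coefs: dict[str, float]
    cv_curve: pd.DataFrame             # columns: lambda, mean_auc, per-fold aucs
    seed: int
    sigmas: dict[str, float] = field(default_factory=dict)

    def validate(self) -> "MetaWeights":
        if not all(np.isfinite(v) for v in self.gamma.values()):
            raise ValueError("non-finite elastic-net coefficient")
        if self.lambda_ <= 0:
            raise ValueError("selected penalty strength must be positive")
        return self

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "disease_id": self.disease_id,
            "gamma": self.gamma,
            "disease_prs_id": self.disease_prs_id,
            "l1_ratio": self.l1_ratio,
            "lambda": self.lambda_,
            "intercept": self.intercept,
            "covariate_coefs": self.covariate_coefs,
            "sigmas": self.sigmas,
            "seed": self.seed,
            "cv_curve": self.cv_curve.to_dict(orient="list"),
        }
        path.write_text(json.dumps(payload, indent=2))
        return path


def _soft_threshold(z: float, g: float) -> float:
    if z > g:
        return z - g
    if z < -g:
        return z + g
    return 0.0


def elastic_net_logistic(X: np.ndarray, y: np.ndarray, penalty_factor: np.ndarray,
                         lam: float, l1_ratio: float,
                         coef0: np.ndarray | None = None,
                         intercept0: float = 0.0,
                         tol: float = 1e-10, max_outer: int = 200,
                         max_inner: int = 200) -> tuple[np.ndarray, float]:
    """Penalized logistic fit at one penalty strength (coordinate descent)."""
    n, p = X.shape
    beta = np.zeros(p) if coef0 is None else coef0.copy()
    b0 = intercept0
    xsq = X ** 2
    for _ in range(max_outer):
        eta = b0 + X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(mu * (1.0 - mu), _WMIN, None)
        z = eta + (y - mu) / w
        # inner coordinate descent on the weighted least-squares surrogate
        for _ in range(max_inner):
            max_delta = 0.0
            r = z - b0 - X @ beta
            # intercept (unpenalized)
            new_b0 = b0 + float(w @ r) / float(w.sum())
            r -= new_b0 - b0
            max_delta = max(max_delta, abs(new_b0 - b0))
            b0 = new_b0
            for j in range(p):
                wj = float(w @ xsq[:, j]) / n
                num = float(w * X[:, j] @ r) / n + wj * beta[j]
                pf = penalty_factor[j]
                if pf > 0:
                    new = _soft_threshold(num, lam * l1_ratio * pf) / (
                        wj + lam * (1.0 - l1_ratio) * pf)
                else:
                    new = num / wj if wj > 0 else 0.0
                if new != beta[j]:
                    r -= X[:, j] * (new - beta[j])
                    max_delta = max(max_delta, abs(new - beta[j]))
                    beta[j] = new
            if max_delta < tol:
                break
        eta_new = b0 + X @ beta
        if np.max(np.abs(eta_new - eta)) < tol * 10:
            break
    return beta, b0


def lambda_grid(X: np.ndarray, y: np.ndarray, penalty_factor: np.ndarray,
                l1_ratio: float, n_lambdas: int = 30,
                lambda_min_ratio: float = 1e-3) -> np.ndarray:
    """Descending penalty grid from the smallest all-zero lambda."""
    n = len(y)
    ybar = y.mean()
    grad = np.abs(X.T @ (y - ybar)) / n
    pen = penalty_factor > 0
    if not pen.any():
        raise ValueError("no penalized features")
    alpha_eff = max(l1_ratio, 1e-3)
    lam_max = float((grad[pen] / penalty_factor[pen]).max()) / alpha_eff
    lam_max = max(lam_max, 1e-8)
    return np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambdas)


def elastic_net_path(X: np.ndarray, y: np.ndarray, penalty_factor: np.ndarray,
                     lambdas: np.ndarray, l1_ratio: float,
                     tol: float = 1e-10) -> tuple[np.ndarray, np.ndarray]:
    """Warm-started path of fits over a descending penalty grid.

    For conditioning, columns are centered and *unpenalized* columns scaled
    to unit variance internally (the intercept absorbs centering and the
    rescaling of an unpenalized column leaves the optimum unchanged);
    coefficients are mapped back to the original scale.
    """
    p = X.shape[1]
    mu = X.mean(axis=0)
    scale = np.ones(p)
    free = penalty_factor == 0
    sds = X.std(axis=0)
    scale[free] = np.where(sds[free] > 0, sds[free], 1.0)
    Xw = (X - mu) / scale
    coefs = np.zeros((len(lambdas), p))
    intercepts = np.zeros(len(lambdas))
    beta, b0 = None, float(np.log(y.mean() / (1 - y.mean())))
    for k, lam in enumerate(lambdas):
        beta, b0 = elastic_net_logistic(
            Xw, y, penalty_factor, lam, l1_ratio, coef0=beta, intercept0=b0, tol=tol)
        coefs[k] = beta / scale
        intercepts[k] = b0 - float((beta / scale) @ mu)
    return coefs, intercepts


def _stratified_folds(y: np.ndarray, folds: int, seed: int):
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(len(y)), y))


def elastic_net_integration(prs_scores: dict[str, ScoreSet], cohort: Cohort,
                            disease_id: str, disease_prs_id: str,
                            covariate_columns: list[str] | None = None,
                            set_label: str | None = PRS,
                            folds: int = 10, l1_ratio: float = 0.5,
                            seed: int = 0, n_lambdas: int = 30,
                            lambda_min_ratio: float = 1e-3,
                            force_disease_prs: bool = False) -> MetaWeights:
    """Integrate PRS columns into meta-score coefficients via CV elastic net.

    ``prs_scores`` maps prs_id -> standardized ScoreSet and must contain
    ``disease_prs_id``; the others are the screened risk-factor PRSs.
    ``force_disease_prs=True`` leaves the disease-PRS column unpenalized.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if disease_prs_id not in prs_scores:
        raise ValueError("prs_scores must contain the disease PRS")
    mask = np.ones(cohort.n_individuals, dtype=bool) if set_label is None \
        else cohort.set_mask(set_label)
    ids = cohort.individuals[mask]
    prs_ids = list(prs_scores)
    cols, sigmas = [], {}
    for pid in prs_ids:
        s = prs_scores[pid]
        if s.standardized is None:
            raise ValueError(f"PRS {pid} is not standardized")
        v = s.standardized.reindex(ids)
        if v.isna().any():
            raise ValueError(f"PRS {pid} missing for some individuals in the set")
        cols.append(v.to_numpy())
        sigmas[pid] = float(s.sd) if s.sd is not None else np.nan
    y = cohort.diseases.loc[ids, disease_id].to_numpy(dtype=float)
    if y.min() == y.max():
        raise ValueError(f"{disease_id}: single-class outcome in the {set_label} set")
    cov = cohort.covariates.loc[ids] if cohort.covariates is not None else None
    if cov is not None and covariate_columns != []:
        C = covariate_design(cov, covariate_columns)[:, 1:]  # drop intercept col
        cov_names = (covariate_columns if covariate_columns is not None
                     else [c for c in cov.columns if c in _default_cov_cols(cov)])
    else:
        C = np.empty((len(ids), 0))
        cov_names = []
    X = np.column_stack([np.column_stack(cols), C]) if C.size else np.column_stack(cols)
    pf = np.concatenate([np.ones(len(prs_ids)), np.zeros(C.shape[1])])
    if force_disease_prs:
        pf[prs_ids.index(disease_prs_id)] = 0.0
    lambdas = lambda_grid(X, y, pf, l1_ratio, n_lambdas, lambda_min_ratio)

    fold_aucs = _cv_auc(X, y, pf, lambdas, l1_ratio, folds, seed)
    mean_auc = fold_aucs.mean(axis=0)
    best = int(np.flatnonzero(mean_auc == mean_auc.max())[-1])  # smallest lambda on ties
    coefs, intercepts = elastic_net_path(X, y, pf, lambdas, l1_ratio)
    beta, b0 = coefs[best], float(intercepts[best])
    curve = pd.DataFrame({"lambda": lambdas, "mean_auc": mean_auc})
    for f in range(folds):
        curve[f"fold_{f + 1}"] = fold_aucs[f]
    return MetaWeights(
        disease_id=disease_id,
        gamma={pid: float(beta[k]) for k, pid in enumerate(prs_ids)},
        disease_prs_id=disease_prs_id,
        l1_ratio=l1_ratio, lambda_=float(lambdas[best]), intercept=b0,
        covariate_coefs={name: float(beta[len(prs_ids) + k])
                         for k, name in enumerate(cov_names)},
        cv_curve=curve, seed=seed, sigmas=sigmas,
    ).validate()


def _default_cov_cols(cov: pd.DataFrame) -> list[str]:
    from .gwas import DEFAULT_COVARIATES

    return [c for c in DEFAULT_COVARIATES if c in cov.columns]


def _cv_auc(X, y, pf, lambdas, l1_ratio, folds, seed) -> np.ndarray:
    """Per-fold held-out AUC along the penalty path (stratified folds)."""
    for attempt_seed in (seed, seed + 1):
        splits = _stratified_folds(y, folds, attempt_seed)
        if all(len(np.unique(y[tr])) == 2 and len(np.unique(y[te])) == 2
               for tr, te in splits):
            if attempt_seed != seed:
                logger.warning("single-class fold; refolded once with seed+1")
            break
    else:
        raise ValueError("cannot form folds with both classes present")
    aucs = np.zeros((folds, len(lambdas)))
    for f, (tr, te) in enumerate(splits):
        coefs, intercepts = elastic_net_path(X[tr], y[tr], pf, lambdas, l1_ratio,
                                             tol=1e-8)
        for k in range(len(lambdas)):
            eta = intercepts[k] + X[te] @ coefs[k]
            aucs[f, k] = roc_auc_score(y[te], eta)
    return aucs


def combine_to_per_snp_weights(meta: MetaWeights,
                               component_weights: dict[str, SNPWeightSet],
                               sigmas: dict[str, float] | None = None
                               ) -> SNPWeightSet:
    """Convert per-PRS coefficients to one combined per-SNP weight vector.

    For each variant j: ``w_j = sum_c (gamma_c / sigma_c) alpha_jc`` over the
    components carrying that variant (others contribute 0). Components are
    aligned to a common effect-allele orientation (weights flipped in sign
    when a component reports the opposite allele).
    """
    sigmas = sigmas if sigmas is not None else meta.sigmas
    for pid in meta.gamma:
        if pid not in component_weights:
            raise ValueError(f"missing component weight set for {pid}")
        if pid not in sigmas or not np.isfinite(sigmas[pid]) or sigmas[pid] <= 0:
            raise ValueError(f"sigma for {pid} must be positive")
    orientation: dict[str, tuple[str, str]] = {}
    combined: dict[str, float] = {}
    for pid, gamma in meta.gamma.items():
        factor = gamma / sigmas[pid]
        for _, row in component_weights[pid].table.iterrows():
            vid = row["id"]
            ea, oa, w = row["effect_allele"], row["other_allele"], float(row["weight"])
            if vid not in orientation:
                orientation[vid] = (ea, oa)
                combined[vid] = 0.0
            ref_ea, ref_oa = orientation[vid]
            if (ea, oa) == (ref_ea, ref_oa):
                signed = w
            elif (ea, oa) == (ref_oa, ref_ea):
                signed = -w
            else:
                raise ValueError(f"allele mismatch for {vid} across components")
            combined[vid] += factor * signed
    table = pd.DataFrame({
        "id": list(combined),
        "effect_allele": [orientation[v][0] for v in combined],
        "other_allele": [orientation[v][1] for v in combined],
        "weight": list(combined.values()),
    })
    return SNPWeightSet(
        trait_id=f"{meta.disease_id}_meta", table=table, method="meta_combined",
        provenance={
            "components": {pid: {"gamma": meta.gamma[pid], "sigma": sigmas[pid]}
                           for pid in meta.gamma},
            "lambda": meta.lambda_, "l1_ratio": meta.l1_ratio,
        },
    ).validate()


def weight_ratio(meta: MetaWeights, mode: str = "sum") -> float | None:
    """Relative pull of the risk-factor PRSs versus the disease PRS.

    ``mode='sum'`` (default): ``|sum_rf gamma_rf| / |gamma_disease|``;
    ``mode='per_term_abs'``: ``sum_rf |gamma_rf| / |gamma_disease|``.
    Returns None (undefined) when the disease-PRS coefficient is zero.
    """
    g_dis = meta.gamma[meta.disease_prs_id]
    g_rf = [g for pid, g in meta.gamma.items() if pid != meta.disease_prs_id]
    if g_dis == 0:
        return None
    if not g_rf:
        return 0.0
    if mode == "sum":
        return float(abs(sum(g_rf)) / abs(g_dis))
    if mode == "per_term_abs":
        return float(sum(abs(g) for g in g_rf) / abs(g_dis))
    raise ValueError(f"unknown weight-ratio mode {mode!r}")
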