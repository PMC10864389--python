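"""Validation-set comparison of the meta-score against the plain disease PRS.

The battery mirrors common PRS-evaluation practice: three nested logistic
models (covariate-only null, null + disease PRS, null + meta-score) fitted on
the same individuals; Nagelkerke's max-rescaled pseudo-R^2; odds ratio per
1 SD of the standardized score; the continuous net reclassification
improvement between nested models (case and control components counted
directly, ties in neither direction); a Wald and paired-bootstrap test for
the difference of two dependent squared outcome-score correlations; the top
10% vs remaining 90% odds ratio with a Woolf confidence interval; and
Kaplan-Meier cumulative incidence over age per risk group with Greenwood
variance bands.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import KaplanMeierFitter
from scipy import stats

from .gwas import covariate_design
from .simulate import Cohort, VALIDATION

logger = logging.getLogger(__name__)


@dataclass
class RiskModel:
    disease_id: str
    label: str                     # "null", "null+diseasePRS", "null+metaPRS", ...
    coefficients: pd.Series
    probabilities: pd.Series       # fitted case probabilities per individual
    log_likelihood: float
    n: int
    prs_coef: float | None = None  # coefficient of the added standardized PRS
    prs_se: float | None = None

    def validate(self) -> "RiskModel":
        p = self.probabilities.to_numpy()
        if ((p <= 0) | (p >= 1)).any():
            raise ValueError("fitted probabilities must lie strictly in (0, 1)")
        if self.log_likelihood > 1e-9:
            raise ValueError("log-likelihood of a Bernoulli model cannot be positive")
        return self


@dataclass
class NRIResult:
    label_old: str
    label_new: str
    nri: float
    case_component: float
    control_component: float
    n_cases: int
    n_controls: int
    p: float | None = None

    def validate(self) -> "NRIResult":
        if abs(self.nri - (self.case_component + self.control_component)) > 1e-10:
            raise ValueError("NRI must equal the sum of its components")
        for c in (self.case_component, self.control_component):
            if not -1 - 1e-12 <= c <= 1 + 1e-12:
                raise ValueError("NRI components must lie in [-1, 1]")
        return self


def _logit_fit(y: np.ndarray, design: np.ndarray) -> sm.discrete.discrete_model.BinaryResults:
    with np.errstate(all="ignore"):
        fit = sm.Logit(y, design).fit(disp=0, maxiter=200)
    if not fit.mle_retvals.get("converged", True):
        raise RuntimeError("logistic fit did not converge")
    return fit


def fit_risk_models(cohort: Cohort, disease_id: str,
                    scores: dict[str, pd.Series],
                    covariate_columns: list[str] | None = None,
                    set_label: str | None = VALIDATION,
                    individuals: pd.Index | None = None) -> dict[str, RiskModel]:
    """Fit the covariate-only null model and one augmented model per score.

    ``scores`` maps a model label suffix (e.g. ``"diseasePRS"``) to a
    standardized per-individual score; each augmented model shares the null
    model's covariate design. Returns ``{"null": ..., "null+<label>": ...}``.
    """
    if individuals is None:
        mask = np.ones(cohort.n_individuals, dtype=bool) if set_label is None \
            else cohort.set_mask(set_label)
        individuals = cohort.individuals[mask]
    y = cohort.diseases.loc[individuals, disease_id].to_numpy(dtype=float)
    if y.min() == y.max():
        raise ValueError(f"{disease_id}: needs cases and controls for evaluation")
    cov = cohort.covariates.loc[individuals] if cohort.covariates is not None else None
    C = (covariate_design(cov, covariate_columns)
         if cov is not None and covariate_columns != []
         else np.ones((len(individuals), 1)))
    models: dict[str, RiskModel] = {}
    fit0 = _logit_fit(y, C)
    models["null"] = RiskModel(
        disease_id=disease_id, label="null",
        coefficients=pd.Series(fit0.params),
        probabilities=pd.Series(np.clip(fit0.predict(), 1e-12, 1 - 1e-12),
                                index=individuals),
        log_likelihood=float(fit0.llf), n=len(y),
    ).validate()
    for name, score in scores.items():
        s = score.reindex(individuals)
        if s.isna().any():
            raise ValueError(f"score {name} missing for evaluated individuals")
        design = np.column_stack([s.to_numpy(), C])
        fit = _logit_fit(y, design)
        models[f"null+{name}"] = RiskModel(
            disease_id=disease_id, label=f"null+{name}",
            coefficients=pd.Series(fit.params),
            probabilities=pd.Series(np.clip(fit.predict(), 1e-12, 1 - 1e-12),
                                    index=individuals),
            log_likelihood=float(fit.llf), n=len(y),
            prs_coef=float(fit.params[0]), prs_se=float(fit.bse[0]),
        ).validate()
    return models


def nagelkerke_r2(model: RiskModel, null: RiskModel) -> float:
    """Max-rescaled Cox-Snell pseudo-R^2 of a model against its null."""
    if model.n != null.n:
        raise ValueError("models must be fitted on the same individuals")
    if model.log_likelihood < null.log_likelihood - 1e-6:
        raise ValueError(
            "augmented model log-likelihood below the null's: nested MLE fits "
            "cannot do this; check the fitting"
        )
    n = model.n
    cox_snell = 1.0 - np.exp(2.0 * (null.log_likelihood - model.log_likelihood) / n)
    max_cs = 1.0 - np.exp(2.0 * null.log_likelihood / n)
    if max_cs <= 0:
        return 0.0
    return float(np.clip(cox_snell / max_cs, 0.0, 1.0))


def or_per_sd(model: RiskModel, alpha: float = 0.05
              ) -> tuple[float, tuple[float, float]]:
    """Odds ratio per 1 SD of the added standardized PRS, with Wald CI."""
    if model.prs_coef is None or model.prs_se is None:
        raise ValueError("model has no added PRS term")
    z = stats.norm.ppf(1 - alpha / 2)
    lo = np.exp(model.prs_coef - z * model.prs_se)
    hi = np.exp(model.prs_coef + z * model.prs_se)
    return float(np.exp(model.prs_coef)), (float(lo), float(hi))


def continuous_nri(risk_old: np.ndarray | pd.Series, risk_new: np.ndarray | pd.Series,
                   outcomes: np.ndarray | pd.Series,
                   bootstrap: int = 0, seed: int = 0,
                   label_old: str = "old", label_new: str = "new") -> NRIResult:
    """Continuous (category-free) net reclassification improvement.

    Case component: P(new > old | case) - P(new < old | case); control
    component: P(new < old | control) - P(new > old | control); ties count in
    neither direction. With ``bootstrap > 0`` a seeded percentile bootstrap
    p-value for NRI != 0 is attached.
    """
    old = np.asarray(risk_old, dtype=float)
    new = np.asarray(risk_new, dtype=float)
    y = np.asarray(outcomes, dtype=int)
    if not (len(old) == len(new) == len(y)):
        raise ValueError("risk and outcome vectors must have equal length")
    case, ctrl = y == 1, y == 0
    n_cases, n_controls = int(case.sum()), int(ctrl.sum())
    if n_cases == 0 or n_controls == 0:
        raise ValueError("need at least one case and one control")

    def _components(c_mask, t_mask):
        up_c = np.mean(new[c_mask] > old[c_mask])
        down_c = np.mean(new[c_mask] < old[c_mask])
        up_t = np.mean(new[t_mask] > old[t_mask])
        down_t = np.mean(new[t_mask] < old[t_mask])
        return (up_c - down_c), (down_t - up_t)

    cc, tc = _components(case, ctrl)
    p_val = None
    if bootstrap > 0:
        rng = np.random.default_rng(seed)
        idx_case, idx_ctrl = np.flatnonzero(case), np.flatnonzero(ctrl)
        draws = np.empty(bootstrap)
        for b in range(bootstrap):
            rc = rng.choice(idx_case, size=n_cases, replace=True)
            rt = rng.choice(idx_ctrl, size=n_controls, replace=True)
            c1, t1 = _components_at(new, old, rc, rt)
            draws[b] = c1 + t1
        frac = np.mean(draws <= 0) if (cc + tc) > 0 else np.mean(draws >= 0)
        p_val = float(min(1.0, max(2.0 * frac, 1.0 / bootstrap)))
    return NRIResult(
        label_old=label_old, label_new=label_new, nri=float(cc + tc),
        case_component=float(cc), control_component=float(tc),
        n_cases=n_cases, n_controls=n_controls, p=p_val,
    ).validate()


def _components_at(new, old, case_idx, ctrl_idx):
    up_c = np.mean(new[case_idx] > old[case_idx])
    down_c = np.mean(new[case_idx] < old[case_idx])
    up_t = np.mean(new[ctrl_idx] > old[ctrl_idx])
    down_t = np.mean(new[ctrl_idx] < old[ctrl_idx])
    return (up_c - down_c), (down_t - up_t)


def r2_difference_test(score_a: np.ndarray | pd.Series, score_b: np.ndarray | pd.Series,
                       outcomes: np.ndarray | pd.Series,
                       method: str = "bootstrap", bootstrap: int = 2000,
                       seed: int = 0, alpha: float = 0.05) -> dict:
    """Test the difference of squared outcome correlations of two scores.

    ``delta = r(y, B)^2 - r(y, A)^2``. The analytic backend ("wald") tests
    equality of the two dependent outcome correlations with the
    Hotelling-Williams t (well calibrated even when both correlations are
    near zero, where the delta-method variance of a difference of squared
    correlations degenerates); its CI comes from the delta method with the
    Pearson-Filon covariance. The bootstrap backend resamples individuals
    jointly and furnishes a percentile CI and p. Both are computed;
    ``method`` selects the headline. Equality of correlations coincides with
    equality of squared correlations when the two correlations share a sign
    (the usual situation for two polygenic scores of the same disease).
    """
    a = np.asarray(score_a, dtype=float)
    b = np.asarray(score_b, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    n = len(y)
    if not (len(a) == len(b) == n):
        raise ValueError("paired scores and outcomes must have equal length")
    if np.ptp(a) == 0 or np.ptp(b) == 0 or np.ptp(y) == 0:
        raise ValueError("constant score or outcome vector")
    if method not in ("wald", "bootstrap"):
        raise ValueError("method must be 'wald' or 'bootstrap'")

    def _delta(av, bv, yv):
        ra = np.corrcoef(yv, av)[0, 1]
        rb = np.corrcoef(yv, bv)[0, 1]
        return rb ** 2 - ra ** 2, ra, rb

    delta, ra, rb = _delta(a, b, y)
    rab = float(np.corrcoef(a, b)[0, 1])
    # Pearson-Filon covariance of two dependent correlations (shared y):
    # n cov(ra, rb) = rab (1 - ra^2 - rb^2) - ra rb (1 - ra^2 - rb^2 - rab^2) / 2
    cov_r = (rab * (1 - ra ** 2 - rb ** 2)
             - 0.5 * ra * rb * (1 - ra ** 2 - rb ** 2 - rab ** 2)) / n
    var_ra = (1 - ra ** 2) ** 2 / n
    var_rb = (1 - rb ** 2) ** 2 / n
    var_delta = 4 * rb ** 2 * var_rb + 4 * ra ** 2 * var_ra - 8 * ra * rb * cov_r
    var_delta = max(var_delta, 0.0)
    z_crit = stats.norm.ppf(1 - alpha / 2)
    wald_ci = (delta - z_crit * np.sqrt(var_delta), delta + z_crit * np.sqrt(var_delta))
    # Hotelling-Williams t for H0: r(y,A) = r(y,B) with shared y
    det_r = 1 - ra ** 2 - rb ** 2 - rab ** 2 + 2 * ra * rb * rab
    rbar = 0.5 * (ra + rb)
    denom = (2 * (n - 1) / (n - 3) * det_r + rbar ** 2 * (1 - rab) ** 3)
    if denom <= 0 or n <= 3:
        wald_p = 1.0
    else:
        t_stat = (rb - ra) * np.sqrt((n - 1) * (1 + rab) / denom)
        wald_p = float(max(2 * stats.t.sf(abs(t_stat), n - 3), np.finfo(float).tiny))

    rng = np.random.default_rng(seed)
    boot_p, boot_ci = None, (None, None)
    if bootstrap > 0:
        draws = np.empty(bootstrap)
        for k in range(bootstrap):
            idx = rng.integers(0, n, size=n)
            yv = y[idx]
            if np.ptp(yv) == 0:
                draws[k] = np.nan
                continue
            draws[k], _, _ = _delta(a[idx], b[idx], yv)
        draws = draws[np.isfinite(draws)]
        lo, hi = np.percentile(draws, [100 * alpha / 2, 100 * (1 - alpha / 2)])
        boot_ci = (float(lo), float(hi))
        frac = np.mean(draws <= 0) if delta > 0 else np.mean(draws >= 0)
        boot_p = float(min(1.0, max(2.0 * frac, 1.0 / len(draws))))
    headline_p = wald_p if method == "wald" or boot_p is None else boot_p
    headline_ci = wald_ci if method == "wald" or boot_p is None else boot_ci
    return {
        "delta_r2": float(delta), "r2_a": float(ra ** 2), "r2_b": float(rb ** 2),
        "p": headline_p, "ci": (float(headline_ci[0]), float(headline_ci[1])),
        "wald_p": wald_p, "wald_ci": (float(wald_ci[0]), float(wald_ci[1])),
        "bootstrap_p": boot_p, "bootstrap_ci": boot_ci, "method": method, "n": n,
    }


def top_decile_or(scores: np.ndarray | pd.Series, outcomes: np.ndarray | pd.Series,
                  top_fraction: float = 0.10, alpha: float = 0.05) -> dict:
    """Odds ratio of disease for the top score decile versus the rest.

    Group assignment is by stable rank (ties at the boundary resolved by
    original order, with the tie count logged); the OR gets a Woolf CI, with
    a 0.5 continuity correction iff any cell is zero.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes, dtype=int)
    n = len(s)
    if n < 10:
        raise ValueError("need at least 10 individuals")
    if len(y) != n:
        raise ValueError("scores and outcomes must have equal length")
    n_top = max(int(round(n * top_fraction)), 1)
    order = np.argsort(-s, kind="stable")
    top = np.zeros(n, dtype=bool)
    top[order[:n_top]] = True
    boundary = s[order[n_top - 1]]
    n_ties = int((s == boundary).sum())
    if n_ties > 1:
        logger.info("top-decile boundary has %d tied scores (stable rank applied)", n_ties)
    a = int((top & (y == 1)).sum())      # top cases
    b_ = int((top & (y == 0)).sum())     # top controls
    c = int((~top & (y == 1)).sum())     # rest cases
    d = int((~top & (y == 0)).sum())     # rest controls
    if (a + b_) == 0 or (c + d) == 0 or (a + c) == 0 or (b_ + d) == 0:
        return {"or": None, "ci": (None, None), "table": (a, b_, c, d),
                "note": "undefined (zero margin)"}
    cc = 0.5 if 0 in (a, b_, c, d) else 0.0
    if cc:
        logger.info("top-decile 2x2 has a zero cell; 0.5 continuity correction applied")
    orat = ((a + cc) * (d + cc)) / ((b_ + cc) * (c + cc))
    se_log = np.sqrt(sum(1.0 / (v + cc if cc else v) for v in (a, b_, c, d))) \
        if min(a, b_, c, d) + cc > 0 else np.inf
    z = stats.norm.ppf(1 - alpha / 2)
    ci = (float(np.exp(np.log(orat) - z * se_log)), float(np.exp(np.log(orat) + z * se_log)))
    return {"or": float(orat), "ci": ci, "table": (a, b_, c, d),
            "n_boundary_ties": n_ties}


def cumulative_incidence(onset_ages: np.ndarray | pd.Series,
                         groups: np.ndarray | pd.Series,
                         outcomes: np.ndarray | pd.Series,
                         censor_age: np.ndarray | pd.Series | float = 70.0,
                         alpha: float = 0.05) -> pd.DataFrame:
    """Kaplan-Meier cumulative incidence by age, per risk group.

    Cases contribute their onset age as an event time; controls are censored
    at ``censor_age`` (scalar study-end age or per-individual vector).
    Returns long-format rows (group, age, incidence, lo, hi) where the bands
    are plain Greenwood-variance normal intervals on 1 - S(t), clipped to
    [0, 1].
    """
    y = np.asarray(outcomes, dtype=int)
    g = np.asarray(groups)
    onset = np.asarray(onset_ages, dtype=float)
    n = len(y)
    censor = np.broadcast_to(np.asarray(censor_age, dtype=float), (n,))
    times = np.where(y == 1, onset, censor)
    if np.isnan(times[y == 1]).any():
        raise ValueError("cases must have an onset age")
    rows = []
    for grp in pd.unique(g):
        sel = g == grp
        if sel.sum() == 0:
            raise ValueError(f"group {grp!r} has zero individuals")
        kmf = KaplanMeierFitter()
        kmf.fit(times[sel], event_observed=y[sel])
        surv = kmf.survival_function_.iloc[:, 0]
        # plain Greenwood variance of S(t)
        tbl = kmf.event_table
        at_risk = tbl["at_risk"].to_numpy(dtype=float)
        d = tbl["observed"].to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(at_risk * (at_risk - d) > 0, d / (at_risk * (at_risk - d)), 0.0)
        greenwood = (surv.to_numpy() ** 2) * np.cumsum(terms)
        z = stats.norm.ppf(1 - alpha / 2)
        inc = 1.0 - surv.to_numpy()
        half = z * np.sqrt(greenwood)
        for t, i, h in zip(surv.index, inc, half):
            rows.append({"group": grp, "age": float(t), "incidence": float(i),
                         "lo": float(max(i - h, 0.0)), "hi": float(min(i + h, 1.0))})
    return pd.DataFrame(rows)
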