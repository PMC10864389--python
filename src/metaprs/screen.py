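"""Risk-factor-PRS x disease association screen with Bonferroni selection.

Each standardized risk-factor PRS is tested against each disease by logistic
regression with the full covariate adjustment (age, sex, array, PC1-10) in
the PRS sample set; associations clearing the Bonferroni threshold
``alpha / (n_rfprs * n_diseases)`` select that RFPRS into the disease's
meta-score. Diseases with no selected RFPRS still proceed downstream with
the disease PRS alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .gwas import covariate_design
from .heritability import bonferroni_threshold
from .prs import ScoreSet
from .simulate import Cohort, PRS

logger = logging.getLogger(__name__)


@dataclass
class AssociationResult:
    rfprs_id: str
    disease_id: str
    beta: float            # log-odds per 1 SD of the RFPRS
    se: float
    p: float
    n_cases: int
    n_controls: int
    failed: bool = False
    reason: str = ""

    @property
    def or_per_sd(self) -> float:
        return float(np.exp(self.beta))


@dataclass
class ScreenTable:
    results: list[AssociationResult]
    n_tests: int
    alpha: float = 0.05
    selected: dict[str, list[str]] = field(default_factory=dict)

    def frame(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            sel = (not r.failed) and r.rfprs_id in self.selected.get(r.disease_id, [])
            rows.append({
                "rfprs": r.rfprs_id, "disease": r.disease_id, "beta": r.beta,
                "se": r.se, "p": r.p, "or_per_sd": r.or_per_sd,
                "n_cases": r.n_cases, "n_controls": r.n_controls,
                "selected": int(sel), "failed": int(r.failed), "reason": r.reason,
            })
        return pd.DataFrame(rows)


def rfprs_disease_association(score_set: ScoreSet, cohort: Cohort,
                              disease_id: str,
                              covariate_columns: list[str] | None = None,
                              set_label: str | None = PRS) -> AssociationResult:
    """Logistic fit of a disease on one standardized RFPRS plus covariates."""
    if score_set.standardized is None:
        raise ValueError("screen requires standardized scores")
    mask = np.ones(cohort.n_individuals, dtype=bool) if set_label is None \
        else cohort.set_mask(set_label)
    ids = cohort.individuals[mask]
    s = score_set.standardized.reindex(ids)
    if s.isna().any():
        raise ValueError("scores missing for some individuals in the analysis set")
    if cohort.diseases is None or disease_id not in cohort.diseases.columns:
        raise KeyError(f"disease {disease_id!r} not in cohort")
    y = cohort.diseases.loc[ids, disease_id].to_numpy(dtype=float)
    n_cases, n_controls = int(y.sum()), int(len(y) - y.sum())
    if n_cases == 0 or n_controls == 0:
        raise ValueError(f"{disease_id}: needs cases and controls in the {set_label} set")
    cov = cohort.covariates.loc[ids] if cohort.covariates is not None else None
    C = (covariate_design(cov, covariate_columns)
         if cov is not None and covariate_columns != [] else np.ones((len(ids), 1)))
    design = np.column_stack([s.to_numpy(), C])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient design (RFPRS collinear with covariates)")
    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(y, design).fit(disp=0, maxiter=100)
        beta, se = float(fit.params[0]), float(fit.bse[0])
        if not fit.mle_retvals.get("converged", True) or not np.isfinite(se) \
                or se <= 0 or abs(beta) > 30:
            raise RuntimeError("non-convergence or separation")
    except Exception as exc:  # noqa: BLE001
        logger.info("screen %s~%s failed: %s", disease_id, score_set.trait_id, exc)
        return AssociationResult(
            rfprs_id=score_set.trait_id, disease_id=disease_id,
            beta=np.nan, se=np.nan, p=1.0, n_cases=n_cases,
            n_controls=n_controls, failed=True, reason=str(exc),
        )
    p = max(2 * stats.norm.sf(abs(beta / se)), float(np.finfo(float).tiny))
    return AssociationResult(
        rfprs_id=score_set.trait_id, disease_id=disease_id,
        beta=beta, se=se, p=p, n_cases=n_cases, n_controls=n_controls,
    )


def run_screen(rf_scores: dict[str, ScoreSet], cohort: Cohort,
               disease_ids: list[str],
               covariate_columns: list[str] | None = None,
               set_label: str | None = PRS,
               alpha: float = 0.05, n_tests: int | None = None) -> ScreenTable:
    """All RFPRS x disease associations plus Bonferroni selection."""
    results = [
        rfprs_disease_association(score, cohort, disease,
                                  covariate_columns=covariate_columns,
                                  set_label=set_label)
        for disease in disease_ids
        for score in rf_scores.values()
    ]
    n_tests = n_tests if n_tests is not None else len(rf_scores) * len(disease_ids)
    table = ScreenTable(results=results, n_tests=n_tests, alpha=alpha)
    bonferroni_select(table)
    return table


def bonferroni_select(table: ScreenTable) -> dict[str, list[str]]:
    """Select associations with p strictly below alpha / n_tests, per disease."""
    cut = bonferroni_threshold(table.alpha, table.n_tests)
    selected: dict[str, list[str]] = {}
    for r in table.results:
        selected.setdefault(r.disease_id, [])
        if not r.failed and r.p < cut:
            selected[r.disease_id].append(r.rfprs_id)
    # sorted for iteration-order independence
    selected = {d: sorted(ids) for d, ids in selected.items()}
    table.selected = selected
    return selected


def write_screen(table: ScreenTable, path: str | Path) -> Path:
    path = Path(path)
    table.frame().to_csv(path, sep="\t", index=False, float_format="%.10g")
    return path
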