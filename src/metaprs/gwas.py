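"""Variant quality control and per-variant association testing.

Linear GWAS of quantitative risk factors uses ordinary least squares with
covariate adjustment, computed by residualizing trait and dosages on the
covariate design (Frisch-Waugh-Lovell), which is algebraically identical to
the full multiple regression and vectorizes across variants. Logistic GWAS
of binary diseases fits a maximum-likelihood logit per variant through
statsmodels, with non-convergent or separated fits omitted and logged rather
than silently zeroed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .simulate import Cohort, GWAS

logger = logging.getLogger(__name__)

SUMSTAT_COLUMNS = ["SNP", "A1", "A2", "EAF", "BETA", "SE", "Z", "P", "N"]
DEFAULT_COVARIATES = ["age", "sex", "array"] + [f"PC{i}" for i in range(1, 11)]
_P_FLOOR = float(np.finfo(float).tiny)

_BASES = {"A", "C", "G", "T"}
_AMBIGUOUS = ({"A", "T"}, {"C", "G"})


@dataclass
class QCThresholds:
    """Variant-level exclusion rules applied before any association test."""

    max_missing_rate: float = 0.05
    min_maf: float = 0.01
    min_hwe_p: float = 1e-6
    drop_indels: bool = True
    drop_ambiguous: bool = True

    def validate(self) -> "QCThresholds":
        if not 0 <= self.max_missing_rate <= 1:
            raise ValueError("max_missing_rate must be in [0, 1]")
        if not 0 <= self.min_maf <= 0.5:
            raise ValueError("min_maf must be in [0, 0.5]")
        if not 0 <= self.min_hwe_p <= 1:
            raise ValueError("min_hwe_p must be in [0, 1]")
        return self


@dataclass
class SummaryStats:
    """Per-variant association results for one trait.

    ``table`` has the canonical columns SNP, A1 (effect allele), A2, EAF,
    BETA, SE, Z, P, N; ``omitted`` records variants dropped during fitting
    together with the reason.
    """

    trait_id: str
    model: str  # "linear" or "logistic"
    table: pd.DataFrame
    omitted: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["SNP", "reason"])
    )

    def validate(self) -> "SummaryStats":
        missing = [c for c in SUMSTAT_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"summary statistics missing mandatory column(s): {missing}")
        t = self.table
        if len(t) == 0:
            return self
        if t["SNP"].duplicated().any():
            raise ValueError("duplicate variant ids in summary statistics")
        if ((t["P"] <= 0) | (t["P"] > 1)).any():
            raise ValueError("p-values must lie in (0, 1]")
        if (t["SE"] <= 0).any():
            raise ValueError("standard errors must be positive")
        if (t["A1"] == t["A2"]).any():
            raise ValueError("effect and other allele identical for some variant")
        if np.nanmax(np.abs(t["Z"] - t["BETA"] / t["SE"])) > 1e-8:
            raise ValueError("Z inconsistent with BETA/SE")
        return self


def hwe_exact_p(n_het: int, n_hom_minor: int, n_hom_major: int) -> float:
    """Exact Hardy-Weinberg test (mid-free, two-sided by probability mass).

    Conditional on the observed minor-allele count, the probability of each
    possible heterozygote count is accumulated; the p-value is the total
    probability of genotype configurations no more likely than the observed
    one (the standard exact HWE test of Wigginton-type).
    """
    from scipy.special import gammaln

    n = n_het + n_hom_minor + n_hom_major
    n_minor = 2 * n_hom_minor + n_het
    if n == 0:
        return 1.0
    het_values = np.arange(n_minor % 2, min(n_minor, 2 * n - n_minor) + 1, 2)
    hom_min = (n_minor - het_values) // 2
    hom_maj = n - het_values - hom_min
    logp = (
        het_values * np.log(2)
        + gammaln(n + 1) - gammaln(het_values + 1) - gammaln(hom_min + 1)
        - gammaln(hom_maj + 1)
        - (gammaln(2 * n + 1) - gammaln(n_minor + 1) - gammaln(2 * n - n_minor + 1))
    )
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    p_obs = probs[het_values == n_het]
    if len(p_obs) == 0:
        raise ValueError("inconsistent genotype counts for HWE test")
    return float(min(1.0, probs[probs <= p_obs[0] * (1 + 1e-12)].sum()))


def _is_indel(a1: str, a2: str) -> bool:
    return len(a1) != 1 or len(a2) != 1 or a1 not in _BASES or a2 not in _BASES


def snp_qc(cohort: Cohort, thresholds: QCThresholds | None = None
           ) -> tuple[list[str], pd.DataFrame]:
    """Apply variant QC; returns surviving ids and a per-filter report.

    A variant survives iff its missing rate, minor-allele frequency and exact
    HWE p-value meet the thresholds and (optionally) it is neither an indel
    nor strand-ambiguous (allele pair A/T or C/G). Each excluded variant is
    attributed to the first failing filter in the order missing > indel >
    ambiguous > maf > hwe; the surviving set is independent of this order.
    """
    thresholds = (thresholds or QCThresholds()).validate()
    rows = []
    for j, var in cohort.variants.iterrows():
        x = cohort.dosages[:, j]
        obs = x[~np.isnan(x)]
        miss_rate = 1.0 - len(obs) / len(x)
        a1, a2 = str(var["effect_allele"]), str(var["other_allele"])
        reason = None
        if miss_rate > thresholds.max_missing_rate:
            reason = "missing_rate"
        elif thresholds.drop_indels and _is_indel(a1, a2):
            reason = "indel"
        elif thresholds.drop_ambiguous and {a1, a2} in _AMBIGUOUS:
            reason = "ambiguous"
        else:
            eaf = obs.mean() / 2.0 if len(obs) else 0.0
            maf = min(eaf, 1.0 - eaf)
            if maf < thresholds.min_maf:
                reason = "maf"
            else:
                n_hom_alt = int((obs == 2).sum())
                n_het = int((obs == 1).sum())
                n_hom_ref = int((obs == 0).sum())
                n_hom_minor, n_hom_major = (
                    (n_hom_alt, n_hom_ref) if eaf <= 0.5 else (n_hom_ref, n_hom_alt)
                )
                if hwe_exact_p(n_het, n_hom_minor, n_hom_major) < thresholds.min_hwe_p:
                    reason = "hwe"
        rows.append({"id": var["id"], "excluded_by": reason or ""})
    report = pd.DataFrame(rows)
    counts = report[report["excluded_by"] != ""]["excluded_by"].value_counts()
    for filt in ("missing_rate", "indel", "ambiguous", "maf", "hwe"):
        report.attrs[f"n_excluded_{filt}"] = int(counts.get(filt, 0))
    survivors = report.loc[report["excluded_by"] == "", "id"].tolist()
    report.attrs["n_pass"] = len(survivors)
    return survivors, report


def covariate_design(covariates: pd.DataFrame | None,
                     columns: list[str] | None = None) -> np.ndarray:
    """Build the adjustment design (intercept + covariate columns).

    Raises on duplicated/constant columns or rank deficiency, since a
    deficient adjustment design silently corrupts every variant's test.
    """
    if covariates is None:
        return np.ones((0, 1))  # caller substitutes correct n
    cols = columns if columns is not None else [
        c for c in DEFAULT_COVARIATES if c in covariates.columns
    ]
    mat = covariates[cols].to_numpy(dtype=float) if cols else np.empty((len(covariates), 0))
    design = np.column_stack([np.ones(len(covariates)), mat])
    if cols:
        if any(np.ptp(mat[:, k]) == 0 for k in range(mat.shape[1])):
            raise ValueError("constant covariate column in design")
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise ValueError("covariate design is rank deficient")
    return design


def _select_set(cohort: Cohort, set_label: str | None) -> np.ndarray:
    if set_label is None:
        return np.ones(cohort.n_individuals, dtype=bool)
    return cohort.set_mask(set_label)


def _trait_vector(cohort: Cohort, trait_id: str) -> np.ndarray:
    for table in (cohort.risk_factors, cohort.diseases):
        if table is not None and trait_id in table.columns:
            return table[trait_id].to_numpy(dtype=float)
    raise KeyError(f"trait {trait_id!r} not found in cohort phenotypes")


def gwas_linear(cohort: Cohort, trait_id: str,
                covariate_columns: list[str] | None = None,
                set_label: str | None = GWAS,
                variant_ids: list[str] | None = None) -> SummaryStats:
    """OLS association of a quantitative trait with each variant's dosage."""
    mask = _select_set(cohort, set_label)
    y_all = _trait_vector(cohort, trait_id)[mask]
    cov = cohort.covariates.loc[mask] if cohort.covariates is not None else None
    var_table = cohort.variants
    keep = (
        np.arange(cohort.n_variants)
        if variant_ids is None
        else var_table.index[var_table["id"].isin(variant_ids)].to_numpy()
    )
    X_all = cohort.dosages[np.ix_(mask, keep)]
    C = (covariate_design(cov, covariate_columns)
         if cov is not None else np.ones((mask.sum(), 1)))
    if covariate_columns == []:
        C = np.ones((int(mask.sum()), 1))

    rows, omitted = [], []
    p_design = C.shape[1]
    # fast path: complete variants, shared residualization
    Q, _ = np.linalg.qr(C)
    complete = ~np.isnan(X_all).any(axis=0)
    y_r = y_all - Q @ (Q.T @ y_all)
    yty = float(y_r @ y_r)
    n = len(y_all)
    df = n - p_design - 1
    if df <= 0:
        raise ValueError("not enough individuals for the linear GWAS design")

    def _one(xv: np.ndarray, yv: np.ndarray, Qm: np.ndarray, n_obs: int):
        x_r = xv - Qm @ (Qm.T @ xv)
        sxx = float(x_r @ x_r)
        if sxx <= 1e-12 * max(1.0, float(xv @ xv)):
            return None
        y_res = yv - Qm @ (Qm.T @ yv)
        beta = float(x_r @ y_res) / sxx
        rss = float(y_res @ y_res) - beta * beta * sxx
        dfe = n_obs - p_design - 1
        sigma2 = max(rss, 0.0) / dfe
        se = np.sqrt(sigma2 / sxx)
        return beta, se, dfe

    for k, j in enumerate(keep):
        var = var_table.iloc[j]
        xv = X_all[:, k]
        if complete[k]:
            res = _one(xv, y_all, Q, n)
            n_obs = n
        else:
            ok = ~np.isnan(xv)
            n_obs = int(ok.sum())
            if n_obs - p_design - 1 <= 0:
                res = None
            else:
                Qo, _ = np.linalg.qr(C[ok])
                res = _one(xv[ok], y_all[ok], Qo, n_obs)
        if res is None:
            omitted.append({"SNP": var["id"], "reason": "degenerate genotype or design"})
            logger.info("gwas_linear %s: variant %s omitted (degenerate)", trait_id, var["id"])
            continue
        beta, se, dfe = res
        if se == 0:
            z = np.sign(beta) * np.inf
            p = _P_FLOOR
        else:
            z = beta / se
            p = max(2 * stats.t.sf(abs(z), dfe), _P_FLOOR)
        obs = xv[~np.isnan(xv)]
        rows.append({
            "SNP": var["id"], "A1": var["effect_allele"], "A2": var["other_allele"],
            "EAF": obs.mean() / 2.0, "BETA": beta, "SE": se if se > 0 else np.nan,
            "Z": z, "P": p, "N": n_obs,
        })
    table = pd.DataFrame(rows, columns=SUMSTAT_COLUMNS)
    table = table[np.isfinite(table["SE"])]
    return SummaryStats(trait_id=trait_id, model="linear", table=table.reset_index(drop=True),
                        omitted=pd.DataFrame(omitted, columns=["SNP", "reason"])).validate()


def gwas_logistic(cohort: Cohort, disease_id: str,
                  covariate_columns: list[str] | None = None,
                  set_label: str | None = GWAS,
                  variant_ids: list[str] | None = None,
                  maxiter: int = 100) -> SummaryStats:
    """Per-variant maximum-likelihood logistic association for a disease."""
    mask = _select_set(cohort, set_label)
    y = _trait_vector(cohort, disease_id)[mask]
    if y.min() == y.max():
        raise ValueError(f"{disease_id}: needs at least one case and one control in the set")
    cov = cohort.covariates.loc[mask] if cohort.covariates is not None else None
    C = (covariate_design(cov, covariate_columns)
         if cov is not None and covariate_columns != [] else np.ones((int(mask.sum()), 1)))
    var_table = cohort.variants
    keep = (
        np.arange(cohort.n_variants)
        if variant_ids is None
        else var_table.index[var_table["id"].isin(variant_ids)].to_numpy()
    )
    rows, omitted = [], []
    for j in keep:
        var = var_table.iloc[j]
        xv = cohort.dosages[mask, j]
        ok = ~np.isnan(xv)
        xo, yo, Co = xv[ok], y[ok], C[ok]
        if np.ptp(xo) == 0:
            omitted.append({"SNP": var["id"], "reason": "degenerate genotype"})
            continue
        design = np.column_stack([xo, Co])
        try:
            with np.errstate(all="ignore"):
                fit = sm.Logit(yo, design).fit(disp=0, maxiter=maxiter)
            converged = fit.mle_retvals.get("converged", True)
            beta, se = float(fit.params[0]), float(fit.bse[0])
            if not converged or not np.isfinite(se) or se <= 0 or abs(beta) > 30:
                raise RuntimeError("non-convergence or separation")
        except Exception as exc:  # noqa: BLE001 - any fit failure is an omission
            omitted.append({"SNP": var["id"], "reason": f"fit failed: {exc}"})
            logger.info("gwas_logistic %s: variant %s omitted (%s)", disease_id, var["id"], exc)
            continue
        z = beta / se
        p = max(2 * stats.norm.sf(abs(z)), _P_FLOOR)
        rows.append({
            "SNP": var["id"], "A1": var["effect_allele"], "A2": var["other_allele"],
            "EAF": xo.mean() / 2.0, "BETA": beta, "SE": se, "Z": z, "P": p,
            "N": len(yo),
        })
    return SummaryStats(
        trait_id=disease_id, model="logistic",
        table=pd.DataFrame(rows, columns=SUMSTAT_COLUMNS),
        omitted=pd.DataFrame(omitted, columns=["SNP", "reason"]),
    ).validate()


def write_sumstats(stats_obj: SummaryStats, path: str | Path) -> Path:
    """Write summary statistics as TSV (lossless to 10 significant digits)."""
    stats_obj.validate()
    path = Path(path)
    stats_obj.table.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return path


def read_sumstats(path: str | Path, trait_id: str | None = None,
                  model: str = "linear") -> SummaryStats:
    """Read and validate a summary-statistics TSV written by write_sumstats."""
    path = Path(path)
    table = pd.read_csv(path, sep="\t", dtype={"A1": str, "A2": str})
    missing = [c for c in SUMSTAT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s): {missing}")
    return SummaryStats(
        trait_id=trait_id or path.stem, model=model, table=table
    ).validate()
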