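"""LD scores and LD score regression for SNP heritability screening.

The LD score of a variant is the sum of squared dosage correlations with
every variant in its LD block (including itself), with the standard
small-sample adjustment ``r2_adj = r2 - (1 - r2) / (n - 2)`` applied to the
cross terms. Heritability is estimated by regressing GWAS chi-square
statistics on LD scores: ``E[chi2_j] = intercept + (N h2 / M) ell_j``, the
slope being solved for h2, with a one-sided Wald test for a positive slope.
The screening rules retain traits whose heritability p-value clears a
Bonferroni threshold and diseases whose prevalence clears a floor.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .gwas import SummaryStats
from .simulate import Cohort


@dataclass
class LDScores:
    """Per-variant LD scores (``ell >= 1``, the self term)."""

    table: pd.DataFrame  # columns: id, ell

    def validate(self) -> "LDScores":
        if not {"id", "ell"}.issubset(self.table.columns):
            raise ValueError("LD scores need columns id, ell")
        if (self.table["ell"] < 1 - 1e-12).any():
            raise ValueError("LD scores must be >= 1 (self term)")
        return self


@dataclass
class HeritabilityEstimate:
    trait_id: str
    h2: float            # clipped to [0, 1] for reporting
    h2_raw: float        # unclipped slope-implied value (used for the Wald test)
    se: float
    p: float             # one-sided Wald p for slope > 0
    intercept: float
    n_snps: int          # M
    n_samples: int       # N

    def validate(self) -> "HeritabilityEstimate":
        if self.se <= 0:
            raise ValueError("heritability SE must be positive")
        if not 0 < self.p <= 1:
            raise ValueError("heritability p must lie in (0, 1]")
        return self


def compute_ld_scores(cohort: Cohort, set_label: str | None = None,
                      max_individuals: int | None = None,
                      seed: int = 0) -> LDScores:
    """LD scores from a cohort's dosages using its block structure.

    Missing dosages are not supported here (LD references are complete by
    construction); blocks need at least 3 individuals for the small-sample
    adjustment to be defined.
    """
    mask = np.ones(cohort.n_individuals, dtype=bool) if set_label is None \
        else cohort.set_mask(set_label)
    idx = np.flatnonzero(mask)
    if max_individuals is not None and len(idx) > max_individuals:
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(idx, size=max_individuals, replace=False))
    n = len(idx)
    if n < 3:
        raise ValueError("LD-score reference needs at least 3 individuals")
    dosages = cohort.dosages[idx]
    if np.isnan(dosages).any():
        raise ValueError("LD-score reference dosages contain missing values")
    blocks = cohort.variants["block"].to_numpy()
    ell = np.empty(cohort.n_variants)
    for b in np.unique(blocks):
        cols = np.flatnonzero(blocks == b)
        sub = dosages[:, cols]
        sds = sub.std(axis=0)
        if (sds == 0).any():
            bad = cohort.variants["id"].iloc[cols[sds == 0][0]]
            raise ValueError(f"constant dosage column in LD reference: {bad}")
        r = np.corrcoef(sub, rowvar=False).reshape(len(cols), len(cols))
        r2 = r ** 2
        adj = r2 - (1.0 - r2) / (n - 2)
        np.fill_diagonal(adj, 0.0)
        ell[cols] = np.maximum(1.0 + adj.sum(axis=1), 1.0)
    return LDScores(pd.DataFrame({"id": cohort.variants["id"], "ell": ell})).validate()


def ldsc_h2(stats_obj: SummaryStats, scores: LDScores,
            min_overlap: int = 50, weighted: bool = False,
            n_jackknife: int = 50, fit_intercept: bool = False
            ) -> HeritabilityEstimate:
    """LD score regression of chi-square on LD score.

    ``h2 = slope * M / N`` with M the number of overlapping variants and N
    the median GWAS sample size. By default the intercept is constrained to
    its no-confounding value of 1 (the synthetic cohorts this package
    targets have no uncorrected stratification, and at desk-scale variant
    counts a free intercept is nearly collinear with the narrow LD-score
    range and destroys all power); ``fit_intercept=True`` frees it, matching
    the convention used on real data. ``weighted=True`` applies 1/ell
    regression weights. The standard error comes from a delete-a-block
    jackknife over contiguous variant chunks (chi-square noise is correlated
    within LD blocks, so an i.i.d. OLS standard error would be badly
    anti-conservative); the p-value is a one-sided Wald test of a positive
    slope on that SE.
    """
    merged = stats_obj.table.merge(scores.table, left_on="SNP", right_on="id")
    if len(merged) < min_overlap:
        raise ValueError(
            f"only {len(merged)} variants shared between summary statistics and "
            f"LD scores (need >= {min_overlap})"
        )
    chi2 = (merged["Z"].to_numpy()) ** 2
    ell = merged["ell"].to_numpy()
    M = len(merged)
    N = float(np.median(merged["N"]))
    if fit_intercept:
        X = np.column_stack([np.ones(M), ell])
        y = chi2
    else:
        X = ell[:, None]
        y = chi2 - 1.0
    if weighted:
        w = 1.0 / np.sqrt(ell)
        Xw, yw = X * w[:, None], y * w
    else:
        Xw, yw = X, y

    def _slope(mask: np.ndarray) -> np.ndarray:
        return np.linalg.lstsq(Xw[mask], yw[mask], rcond=None)[0]

    coef = _slope(np.ones(M, dtype=bool))
    slope = float(coef[-1])
    # contiguous-chunk jackknife (variant order follows the LD blocks)
    g = int(min(n_jackknife, max(M // 2, 2)))
    bounds = np.linspace(0, M, g + 1).astype(int)
    thetas = []
    for k in range(g):
        mask = np.ones(M, dtype=bool)
        mask[bounds[k]:bounds[k + 1]] = False
        thetas.append(_slope(mask)[-1])
    thetas = np.asarray(thetas)
    slope_se = float(np.sqrt((g - 1) / g * ((thetas - thetas.mean()) ** 2).sum()))
    slope_se = max(slope_se, np.finfo(float).tiny)
    h2_raw = slope * M / N
    h2_se = max(slope_se * M / N, np.finfo(float).tiny)
    t_stat = slope / slope_se
    p = float(max(stats.t.sf(t_stat, g - 1), np.finfo(float).tiny))
    return HeritabilityEstimate(
        trait_id=stats_obj.trait_id,
        h2=float(np.clip(h2_raw, 0.0, 1.0)),
        h2_raw=h2_raw, se=h2_se, p=min(p, 1.0),
        intercept=float(coef[0]) if fit_intercept else 1.0,
        n_snps=M, n_samples=int(N),
    ).validate()


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    if n_tests <= 0:
        raise ValueError("n_tests must be positive")
    return alpha / n_tests


def screen_heritable(estimates: list[HeritabilityEstimate], n_tests: int,
                     alpha: float = 0.05) -> list[str]:
    """Retain traits with heritability p strictly below alpha / n_tests."""
    if n_tests < len(estimates):
        raise ValueError("n_tests must be at least the number of estimates")
    cut = bonferroni_threshold(alpha, n_tests)
    return [e.trait_id for e in estimates if e.p < cut]


def prevalence_filter(cohort: Cohort, min_prevalence: float = 0.001) -> list[str]:
    """Retain diseases whose full-cohort case fraction is >= min_prevalence."""
    if cohort.diseases is None:
        raise ValueError("cohort has no disease indicators")
    frac = cohort.diseases.mean(axis=0)
    return [d for d in cohort.diseases.columns if frac[d] >= min_prevalence]


def write_ld_scores(scores: LDScores, path: str | Path) -> Path:
    path = Path(path)
    scores.table.rename(columns={"id": "SNP", "ell": "L2"}).to_csv(
        path, sep="\t", index=False, float_format="%.10g")
    return path


def read_ld_scores(path: str | Path) -> LDScores:
    t = pd.read_csv(path, sep="\t")
    if not {"SNP", "L2"}.issubset(t.columns):
        raise ValueError(f"{path}: LD score file needs columns SNP, L2")
    return LDScores(t.rename(columns={"SNP": "id", "L2": "ell"})).validate()


def write_h2_report(estimates: list[HeritabilityEstimate], path: str | Path) -> Path:
    rows = [
        {"trait": e.trait_id, "h2": e.h2, "h2_raw": e.h2_raw, "se": e.se,
         "p": e.p, "intercept": e.intercept, "M": e.n_snps, "N": e.n_samples}
        for e in estimates
    ]
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.10g")
    return path
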