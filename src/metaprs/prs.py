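"""Polygenic score construction: LDpred-infinitesimal reweighting and scoring.

Marginal GWAS effects are converted to joint posterior-mean effects under the
infinitesimal model (all variants causal): per LD block with correlation
matrix D, the reweighted effects on the standardized-genotype scale solve

    (D + (M / (N h2)) I) b = beta_marginal_std,

which is the closed-form ridge system of LDpred-inf. Weights are returned on
the per-allele scale (divided by reference dosage SDs). A polygenic score is
then the weighted sum of allele dosages; standardization uses the mean/SD of
a designated source sample set (population SD convention) and those same
parameters are applied unchanged to any other set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .gwas import SummaryStats
from .simulate import Cohort

logger = logging.getLogger(__name__)


@dataclass
class LDCorrelationMatrix:
    """Block-diagonal LD: one dense symmetric correlation matrix per block."""

    blocks: list[tuple[list[str], np.ndarray]]  # (variant ids, correlation matrix)
    dosage_sd: pd.Series                        # per-variant reference dosage SD

    def validate(self) -> "LDCorrelationMatrix":
        for ids, mat in self.blocks:
            if mat.shape != (len(ids), len(ids)):
                raise ValueError("block matrix shape does not match its variant list")
            if not np.allclose(mat, mat.T, atol=1e-10):
                raise ValueError("LD block matrix not symmetric")
            if not np.allclose(np.diag(mat), 1.0, atol=1e-10):
                raise ValueError("LD block diagonal not unity")
            if len(ids) and np.linalg.eigvalsh(mat).min() < -1e-8:
                raise ValueError("LD block matrix not positive semidefinite")
        return self

    @property
    def variant_ids(self) -> list[str]:
        return [v for ids, _ in self.blocks for v in ids]


@dataclass
class SNPWeightSet:
    """Per-variant score weights on the per-allele (dosage) scale."""

    trait_id: str
    table: pd.DataFrame  # columns: id, effect_allele, other_allele, weight
    method: str          # marginal | ldpred_inf | meta_combined
    provenance: dict = field(default_factory=dict)

    def validate(self) -> "SNPWeightSet":
        need = {"id", "effect_allele", "other_allele", "weight"}
        if not need.issubset(self.table.columns):
            raise ValueError(f"weight table needs columns {sorted(need)}")
        if self.table["id"].duplicated().any():
            raise ValueError("duplicate variant ids in weight set")
        if not np.isfinite(self.table["weight"]).all():
            raise ValueError("non-finite score weights")
        return self


@dataclass
class ScoreSet:
    """Per-individual raw and standardized polygenic scores."""

    trait_id: str
    raw: pd.Series
    standardized: pd.Series | None = None
    mean: float | None = None
    sd: float | None = None            # population SD of the source set
    source_set: str | None = None

    def frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"raw": self.raw})
        if self.standardized is not None:
            out["standardized"] = self.standardized
        return out


def ld_corr_matrix(cohort: Cohort, set_label: str | None = None,
                   max_individuals: int | None = None,
                   seed: int = 0, min_individuals: int = 30) -> LDCorrelationMatrix:
    """Pearson dosage correlations within each LD block of a reference set."""
    mask = np.ones(cohort.n_individuals, dtype=bool) if set_label is None \
        else cohort.set_mask(set_label)
    idx = np.flatnonzero(mask)
    if max_individuals is not None and len(idx) > max_individuals:
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(idx, size=max_individuals, replace=False))
    if len(idx) < min_individuals:
        raise ValueError(f"LD reference needs >= {min_individuals} individuals, got {len(idx)}")
    dosages = cohort.dosages[idx]
    if np.isnan(dosages).any():
        raise ValueError("LD reference dosages contain missing values")
    blocks_col = cohort.variants["block"].to_numpy()
    ids_all = cohort.variants["id"].to_numpy()
    sds = dosages.std(axis=0)
    if (sds == 0).any():
        bad = ids_all[sds == 0]
        raise ValueError(f"constant dosage column(s) in LD reference: {list(bad)}")
    blocks = []
    for b in np.unique(blocks_col):
        cols = np.flatnonzero(blocks_col == b)
        sub = dosages[:, cols]
        mat = np.corrcoef(sub, rowvar=False).reshape(len(cols), len(cols))
        blocks.append((list(ids_all[cols]), mat))
    return LDCorrelationMatrix(
        blocks=blocks, dosage_sd=pd.Series(sds, index=ids_all)
    ).validate()


def ldpred_inf_reweight(stats_obj: SummaryStats, ld: LDCorrelationMatrix,
                        h2: float, n_samples: int | None = None,
                        min_h2: float = 0.01) -> SNPWeightSet:
    """Closed-form infinitesimal reweighting of marginal GWAS effects.

    ``h2`` below ``min_h2`` is clipped up with a warning (a vanishing h2
    makes the ridge term explode and the weights vanish, which is the
    correct limit but numerically pointless). N defaults to the median GWAS
    sample size in the summary statistics.
    """
    if h2 <= 0:
        raise ValueError("h2 must be positive for the infinitesimal reweighting")
    if h2 < min_h2:
        logger.warning("h2=%.4g below floor %.3g; clipping", h2, min_h2)
        h2 = min_h2
    t = stats_obj.table.set_index("SNP")
    ld_ids = set(ld.variant_ids)
    missing = [s for s in t.index if s not in ld_ids]
    if missing:
        raise ValueError(f"variants absent from the LD matrix: {missing[:5]}"
                         + ("..." if len(missing) > 5 else ""))
    N = float(n_samples) if n_samples is not None else float(np.median(t["N"]))
    M = len(t)
    ridge = M / (N * h2)
    rows = []
    for ids, mat in ld.blocks:
        present = [v for v in ids if v in t.index]
        if not present:
            continue
        sub_idx = [ids.index(v) for v in present]
        D = mat[np.ix_(sub_idx, sub_idx)]
        sd = ld.dosage_sd[present].to_numpy()
        beta_std = t.loc[present, "BETA"].to_numpy() * sd
        b_std = np.linalg.solve(D + ridge * np.eye(len(present)), beta_std)
        b_allele = b_std / sd
        for v, w in zip(present, b_allele):
            rows.append({
                "id": v, "effect_allele": t.loc[v, "A1"],
                "other_allele": t.loc[v, "A2"], "weight": w,
            })
    table = pd.DataFrame(rows)
    return SNPWeightSet(
        trait_id=stats_obj.trait_id, table=table, method="ldpred_inf",
        provenance={"h2": h2, "N": N, "M": M, "ridge": ridge},
    ).validate()


def marginal_weights(stats_obj: SummaryStats) -> SNPWeightSet:
    """Use raw marginal GWAS betas as score weights (no LD adjustment)."""
    t = stats_obj.table
    return SNPWeightSet(
        trait_id=stats_obj.trait_id,
        table=pd.DataFrame({
            "id": t["SNP"], "effect_allele": t["A1"],
            "other_allele": t["A2"], "weight": t["BETA"],
        }),
        method="marginal",
    ).validate()


def score_prs(cohort: Cohort, weights: SNPWeightSet,
              set_label: str | None = None) -> ScoreSet:
    """Raw polygenic scores: weighted sum of effect-allele dosages.

    Effect-allele orientation is resolved against the cohort variant table:
    a weight whose effect allele matches the cohort's *other* allele is
    applied to ``2 - dosage``. Variants missing from the cohort are a hard
    error (silent skipping changes scores irreproducibly).
    """
    weights.validate()
    var = cohort.variants.set_index("id")
    missing = [v for v in weights.table["id"] if v not in var.index]
    if missing:
        raise ValueError(f"weight variants absent from cohort: {missing}")
    mask = np.ones(cohort.n_individuals, dtype=bool) if set_label is None \
        else cohort.set_mask(set_label)
    idx = cohort.individuals[mask]
    col_of = {v: k for k, v in enumerate(cohort.variants["id"])}
    score = np.zeros(int(mask.sum()))
    for _, row in weights.table.iterrows():
        vid, w = row["id"], float(row["weight"])
        j = col_of[vid]
        x = cohort.dosages[mask, j]
        if np.isnan(x).any():
            raise ValueError(f"missing dosages for scored variant {vid}")
        ea, oa = var.loc[vid, "effect_allele"], var.loc[vid, "other_allele"]
        if row["effect_allele"] == ea:
            score += w * x
        elif row["effect_allele"] == oa and row["other_allele"] == ea:
            score += w * (2.0 - x)
        else:
            raise ValueError(
                f"allele mismatch for {vid}: weight {row['effect_allele']}/"
                f"{row['other_allele']} vs cohort {ea}/{oa}"
            )
    return ScoreSet(trait_id=weights.trait_id, raw=pd.Series(score, index=idx))


def standardize_scores(score_set: ScoreSet, cohort: Cohort,
                       source_set: str, weights: SNPWeightSet | None = None
                       ) -> ScoreSet:
    """Standardize scores with the mean/SD of the source sample set.

    If the score set does not already cover the source set, ``weights`` must
    be supplied so the source-set scores can be computed. The population-SD
    convention (divide by n) is used throughout, matching the per-SNP weight
    conversion of the meta-score.
    """
    source_ids = cohort.individuals[cohort.set_mask(source_set)]
    have = score_set.raw.index
    if source_ids.isin(have).all():
        src = score_set.raw.loc[source_ids]
    elif weights is not None:
        src = score_prs(cohort, weights, set_label=source_set).raw
    else:
        raise ValueError("source-set scores unavailable; pass the weight set")
    if len(src) < 2:
        raise ValueError("source set needs at least 2 individuals")
    mean, sd = float(src.mean()), float(src.std(ddof=0))
    if sd == 0:
        raise ValueError("degenerate score distribution (zero variance in source set)")
    return ScoreSet(
        trait_id=score_set.trait_id, raw=score_set.raw,
        standardized=(score_set.raw - mean) / sd,
        mean=mean, sd=sd, source_set=source_set,
    )


def prs_trait_correlation(score_set: ScoreSet, trait: pd.Series
                          ) -> tuple[float, float]:
    """Pearson correlation (and two-sided p) of a PRS with its trait."""
    common = score_set.raw.index.intersection(trait.index)
    if len(common) < 3:
        raise ValueError("need at least 3 paired observations")
    a = score_set.raw.loc[common].to_numpy()
    b = trait.loc[common].to_numpy(dtype=float)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant score or trait vector")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# scoring-file IO (PGS-Catalog-style column layout)
# ---------------------------------------------------------------------------

def write_weights(weights: SNPWeightSet, path: str | Path) -> Path:
    """Write a scoring file: '#' header lines, then rsID/alleles/weight."""
    weights.validate()
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"#trait_id={weights.trait_id}\n#method={weights.method}\n")
        for key, val in weights.provenance.items():
            if np.isscalar(val):
                fh.write(f"#{key}={val}\n")
        fh.write("rsID\teffect_allele\tother_allele\teffect_weight\n")
        for _, row in weights.table.iterrows():
            fh.write(f"{row['id']}\t{row['effect_allele']}\t{row['other_allele']}\t"
                     f"{row['weight']:.10g}\n")
    return path


def read_weights(path: str | Path) -> SNPWeightSet:
    path = Path(path)
    meta: dict[str, str] = {}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            if "=" in line:
                k, v = line[1:].strip().split("=", 1)
                meta[k] = v
            body_start = i + 1
        else:
            break
    from io import StringIO

    table = pd.read_csv(StringIO("".join(lines[body_start:])), sep="\t",
                        dtype={"effect_allele": str, "other_allele": str})
    table = table.rename(columns={"rsID": "id", "effect_weight": "weight"})
    return SNPWeightSet(
        trait_id=meta.get("trait_id", path.stem),
        table=table, method=meta.get("method", "unknown"), provenance=meta,
    ).validate()


def write_scores(score_set: ScoreSet, path: str | Path) -> Path:
    path = Path(path)
    score_set.frame().to_csv(path, sep="\t", index_label="iid", float_format="%.10g")
    return path
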