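"""Synthetic biobank-style cohorts for polygenic-score analyses.

This module generates diploid dosage genotypes with block-structured linkage
disequilibrium, quantitative risk factors with a prescribed SNP heritability,
binary diseases from a liability-threshold model with both risk-factor-mediated
and direct genetic components, covariates (age, sex, genotyping array, ten
principal components), and a disjoint GWAS / PRS / validation sample split.

The generative model is deliberately simple but exposes every statistical
handle the downstream pipeline consumes:

* LD is exchangeable within blocks (a shared latent Gaussian per haplotype,
  thresholded to alleles at the sampled minor-allele frequency) and exactly
  zero across blocks, so the LD matrix is block diagonal by construction.
* Each risk factor is ``sum_j b_j * std(x_j) + e`` with the causal component
  scaled to an exact empirical variance ``rf_h2`` and the noise orthogonalized
  against it, so the trait has mean 0 / variance 1 and the stored variance
  decomposition is exact.
* Disease liability is ``sum_k theta_k * RF_k + g_direct + eps``; components
  are orthogonalized and scaled so that they partition the unit liability
  variance exactly, and a case is declared when liability exceeds the normal
  quantile implied by the target prevalence.

Everything is bit-reproducible under a fixed ``SimulationConfig.seed``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

GWAS, PRS, VALIDATION, UNASSIGNED = "GWAS", "PRS", "VALIDATION", "UNASSIGNED"
SET_LABELS = (GWAS, PRS, VALIDATION)

# Non-strand-ambiguous allele pairs (effect, other); ambiguous / indel alleles
# are only produced by the explicit corruption helpers used in QC tests.
_ALLELE_PAIRS = [
    ("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
    ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T"),
]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort generator.

    Sample sizes follow the three-way biobank design (a GWAS set for summary
    statistics, a PRS set for score construction/integration, a validation
    set for evaluation). ``mediation_theta`` has one column per disease and
    one row per risk factor and acts on the *standardized total* risk factor,
    so risk-factor PRSs carry disease signal only through the genetic
    component of each risk factor.
    """

    n_gwas: int = 2500
    n_prs: int = 2500
    n_validation: int = 1000
    n_snps: int = 300
    n_blocks: int = 30
    block_corr: float = 0.5
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_risk_factors: int = 4
    rf_h2: float | Sequence[float] = 0.25
    n_causal_per_rf: int | None = None  # None = all variants causal (infinitesimal)
    mediation_theta: np.ndarray | Sequence[Sequence[float]] | None = None
    disease_direct_h2: float | Sequence[float] = 0.1
    prevalence: float | Sequence[float] = 0.1
    seed: int = 0
    # optional structure switches (off by default)
    confounding: float = 0.0      # weight of a genotype PC leaked into PC1
    rf_env_corr: float = 0.0      # exchangeable correlation of RF noise

    def __post_init__(self) -> None:
        self.prevalence = np.atleast_1d(np.asarray(self.prevalence, dtype=float))
        self.disease_direct_h2 = np.broadcast_to(
            np.asarray(self.disease_direct_h2, dtype=float), self.prevalence.shape
        ).copy()
        self.rf_h2 = np.broadcast_to(
            np.asarray(self.rf_h2, dtype=float), (self.n_risk_factors,)
        ).copy()
        if self.mediation_theta is None:
            # default: each disease mediated through all risk factors with a
            # total mediated liability variance of 0.3
            k = max(self.n_risk_factors, 1)
            self.mediation_theta = np.full(
                (self.n_risk_factors, self.n_diseases), np.sqrt(0.3 / k)
            )
        else:
            self.mediation_theta = np.asarray(self.mediation_theta, dtype=float)
            if self.mediation_theta.ndim == 1:
                self.mediation_theta = self.mediation_theta[:, None]

    @property
    def n_diseases(self) -> int:
        return len(self.prevalence)

    @property
    def n_total(self) -> int:
        return self.n_gwas + self.n_prs + self.n_validation

    def validate(self) -> "SimulationConfig":
        if min(self.n_gwas, self.n_prs) <= 0 or self.n_validation < 0:
            raise ValueError("sample-set sizes must be positive (validation >= 0)")
        if self.n_snps <= 0 or self.n_blocks <= 0 or self.n_blocks > self.n_snps:
            raise ValueError("need 0 < n_blocks <= n_snps")
        if not 0.0 <= self.block_corr < 1.0:
            raise ValueError(f"block_corr must be in [0, 1), got {self.block_corr}")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must satisfy 0 < lo <= hi <= 0.5, got {self.maf_range}")
        if np.any(self.rf_h2 < 0) or np.any(self.rf_h2 > 1):
            raise ValueError("rf_h2 must lie in [0, 1]")
        if self.n_causal_per_rf is not None and self.n_causal_per_rf > self.n_snps:
            raise ValueError("n_causal_per_rf exceeds n_snps")
        if np.any(self.prevalence <= 0) or np.any(self.prevalence >= 1):
            raise ValueError("prevalence must lie in (0, 1)")
        if np.any(self.disease_direct_h2 < 0) or np.any(self.disease_direct_h2 >= 1):
            raise ValueError("disease_direct_h2 must lie in [0, 1)")
        if self.mediation_theta.shape != (self.n_risk_factors, self.n_diseases):
            raise ValueError(
                "mediation_theta must have shape (n_risk_factors, n_diseases)="
                f"{(self.n_risk_factors, self.n_diseases)}, got {self.mediation_theta.shape}"
            )
        if not isinstance(self.seed, (int, np.integer)):
            raise ValueError("seed must be an integer")
        return self


@dataclass
class Cohort:
    """In-memory cohort: genotypes, phenotypes, covariates and set labels.

    ``dosages`` is individuals x variants with entries in {0, 1, 2} (NaN marks
    a missing call, only ever injected by :func:`inject_missing`). ``truth``
    holds generative parameters for simulated cohorts and is not serialized.
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    individuals: pd.Index
    risk_factors: pd.DataFrame | None = None
    diseases: pd.DataFrame | None = None
    covariates: pd.DataFrame | None = None
    set_label: pd.Series | None = None
    truth: dict = field(default_factory=dict)

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def set_mask(self, label: str) -> np.ndarray:
        if self.set_label is None:
            raise ValueError("cohort has no sample-set labels; run split_samples first")
        if label not in SET_LABELS:
            raise ValueError(f"unknown set label {label!r}; expected one of {SET_LABELS}")
        return (self.set_label == label).to_numpy()

    def block_index(self) -> pd.Series:
        return self.variants.set_index("id")["block"]


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), stream])


def simulate_genotypes(config: SimulationConfig) -> Cohort:
    """Draw Hardy-Weinberg dosages with exchangeable within-block LD.

    Per haplotype, variants of a block share a latent Gaussian factor with
    loading ``sqrt(block_corr)``; the allele indicator is the latent value
    falling below the normal quantile of the variant's MAF, so marginal
    allele frequencies are exact and the latent correlation within a block
    equals ``block_corr`` (zero across blocks).
    """
    config.validate()
    rng = _rng(config, 0)
    n, m = config.n_total, config.n_snps
    maf = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)
    thresh = stats.norm.ppf(maf)
    sizes = _block_sizes(m, config.n_blocks, config.seed)
    block = np.repeat(np.arange(config.n_blocks), sizes)
    rho = config.block_corr

    dosages = np.zeros((n, m), dtype=float)
    for hap in range(2):
        shared = rng.standard_normal((n, config.n_blocks))
        latent = np.sqrt(rho) * shared[:, block] + np.sqrt(1.0 - rho) * rng.standard_normal((n, m))
        dosages += latent < thresh

    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=m)
    within_block = np.concatenate([np.arange(s) for s in sizes])
    variants = pd.DataFrame(
        {
            "id": [f"snp_{i + 1:05d}" for i in range(m)],
            "chrom": (block + 1).astype(int),
            "pos": ((within_block + 1) * 1000).astype(int),
            "effect_allele": [_ALLELE_PAIRS[i][0] for i in pair_idx],
            "other_allele": [_ALLELE_PAIRS[i][1] for i in pair_idx],
            "maf": maf,
            "block": block.astype(int),
        }
    )
    individuals = pd.Index([f"ind_{i + 1:06d}" for i in range(n)], name="iid")
    cohort = Cohort(dosages=dosages, variants=variants, individuals=individuals)
    cohort.truth["maf"] = maf
    _simulate_covariates(cohort, config)
    return cohort


def _block_sizes(m: int, n_blocks: int, seed: int) -> np.ndarray:
    """Variable block sizes (each >= 1), drawn once per config seed.

    Unequal blocks spread the LD-score distribution, which is what gives LD
    score regression leverage; equal blocks would make every variant's LD
    score nearly identical.
    """
    rng = np.random.default_rng([int(seed), 9])
    extra = rng.multinomial(m - n_blocks, np.ones(n_blocks) / n_blocks)
    return 1 + extra


def _simulate_covariates(cohort: Cohort, config: SimulationConfig) -> None:
    rng = _rng(config, 4)
    n = cohort.n_individuals
    cov = pd.DataFrame(index=cohort.individuals)
    cov["age"] = rng.integers(40, 70, size=n).astype(float)
    cov["sex"] = rng.integers(0, 2, size=n).astype(float)
    cov["array"] = rng.integers(0, 2, size=n).astype(float)
    pcs = rng.standard_normal((n, 10))
    if config.confounding > 0:
        # leak the leading genotype axis into PC1 so covariate adjustment is testable
        g = cohort.dosages - cohort.dosages.mean(axis=0)
        axis = g @ rng.standard_normal(cohort.n_variants)
        axis = (axis - axis.mean()) / axis.std()
        pcs[:, 0] = np.sqrt(1 - config.confounding) * pcs[:, 0] + np.sqrt(config.confounding) * axis
    for k in range(10):
        cov[f"PC{k + 1}"] = pcs[:, k]
    cohort.covariates = cov


def _standardize_columns(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    return (x - mu) / sd


def _center_scale(v: np.ndarray, target_var: float) -> np.ndarray:
    """Center ``v`` and scale it to exact population variance ``target_var``."""
    v = v - v.mean()
    sd = v.std()
    if sd == 0:
        if target_var > 0:
            raise ValueError("cannot scale a constant vector to positive variance")
        return v
    return v * (np.sqrt(target_var) / sd)


def _orthogonalize(v: np.ndarray, basis: list[np.ndarray]) -> np.ndarray:
    v = v - v.mean()
    for b in basis:
        denom = float(b @ b)
        if denom > 0:
            v = v - (v @ b) / denom * b
    return v


def simulate_risk_factors(cohort: Cohort, config: SimulationConfig) -> Cohort:
    """Attach heritable quantitative risk factors to a genotyped cohort.

    Each risk factor is a sparse linear combination of standardized dosages
    plus noise; the genetic component is scaled to an exact empirical variance
    of ``rf_h2`` and the noise (orthogonalized against it) to ``1 - rf_h2``,
    so every trait has mean 0 and variance 1 in the full cohort.
    """
    config.validate()
    n_causal = config.n_causal_per_rf if config.n_causal_per_rf is not None \
        else cohort.n_variants
    if n_causal > cohort.n_variants:
        raise ValueError("n_causal_per_rf exceeds the number of simulated variants")
    rng = _rng(config, 1)
    n, m = cohort.n_individuals, cohort.n_variants
    x_std = _standardize_columns(cohort.dosages)
    rf = np.zeros((n, config.n_risk_factors))
    truth_rf = {}
    env = None
    if config.rf_env_corr > 0:
        env = rng.standard_normal(n)  # shared environmental factor across RFs
    for k in range(config.n_risk_factors):
        h2 = float(config.rf_h2[k])
        causal = np.sort(rng.choice(m, size=n_causal, replace=False))
        b = rng.standard_normal(n_causal)
        g = x_std[:, causal] @ b
        if h2 > 0:
            scale = np.sqrt(h2) / g.std() if g.std() > 0 else 0.0
            g = _center_scale(g, h2)
            b = b * scale
        else:
            g = np.zeros(n)
            b = np.zeros_like(b)
        e = rng.standard_normal(n)
        if env is not None:
            r = config.rf_env_corr
            e = np.sqrt(r) * env + np.sqrt(1 - r) * e
        e = _orthogonalize(e, [g]) if h2 > 0 else e - e.mean()
        e = _center_scale(e, 1.0 - h2) if h2 < 1 else np.zeros(n)
        rf[:, k] = g + e
        truth_rf[f"rf_{k + 1}"] = {
            "causal_idx": causal,
            "beta_std": b,
            "genetic_value": g,
            "h2": h2,
        }
    cohort.risk_factors = pd.DataFrame(
        rf, index=cohort.individuals,
        columns=[f"rf_{k + 1}" for k in range(config.n_risk_factors)],
    )
    cohort.truth["risk_factors"] = truth_rf
    return cohort


def simulate_diseases(cohort: Cohort, config: SimulationConfig) -> Cohort:
    """Attach liability-threshold diseases with mediated and direct genetics.

    Liability = sum_k theta_k RF_k + g_direct + eps, with the three components
    orthogonalized and scaled so their empirical variances partition 1
    exactly; an individual is a case when liability exceeds
    ``Phi^{-1}(1 - prevalence)``. True liabilities and the variance
    decomposition are stored in ``cohort.truth``.
    """
    config.validate()
    if cohort.risk_factors is None:
        raise ValueError("simulate_risk_factors must run before simulate_diseases")
    rng = _rng(config, 2)
    n, m = cohort.n_individuals, cohort.n_variants
    x_std = _standardize_columns(cohort.dosages)
    rf = cohort.risk_factors.to_numpy()
    dis = np.zeros((n, config.n_diseases), dtype=int)
    truth_dis = {}
    for d in range(config.n_diseases):
        theta = config.mediation_theta[:, d]
        direct_h2 = float(config.disease_direct_h2[d])
        prev = float(config.prevalence[d])
        mediated = rf @ theta if config.n_risk_factors else np.zeros(n)
        mediated = mediated - mediated.mean()
        var_med = float(mediated.var())
        if var_med + direct_h2 >= 1.0:
            raise ValueError(
                f"disease {d + 1}: mediated variance {var_med:.3f} + direct_h2 "
                f"{direct_h2:.3f} must be < 1"
            )
        if direct_h2 > 0:
            n_causal = (config.n_causal_per_rf if config.n_causal_per_rf is not None
                        else m)
            causal = np.sort(rng.choice(m, size=min(n_causal, m), replace=False))
            g = x_std[:, causal] @ rng.standard_normal(len(causal))
            g = _orthogonalize(g, [mediated])
            g = _center_scale(g, direct_h2)
        else:
            causal, g = np.array([], dtype=int), np.zeros(n)
        var_res = 1.0 - var_med - direct_h2
        eps = _orthogonalize(rng.standard_normal(n), [mediated, g])
        eps = _center_scale(eps, var_res)
        liability = mediated + g + eps
        threshold = stats.norm.ppf(1.0 - prev)
        y = (liability > threshold).astype(int)
        name = f"disease_{d + 1}"
        for label, size in (("GWAS", config.n_gwas), ("PRS", config.n_prs),
                            ("VALIDATION", config.n_validation)):
            if size and prev * size < 10:
                logger.warning(
                    "%s: expected cases in %s set < 10 (prevalence %.4g x n=%d); "
                    "downstream models may fail", name, label, prev, size,
                )
        dis[:, d] = y
        truth_dis[name] = {
            "theta": theta.copy(),
            "var_mediated": var_med,
            "direct_h2": direct_h2,
            "var_residual": var_res,
            "direct_causal_idx": causal,
            "liability": liability,
            "threshold": threshold,
            "prevalence_target": prev,
        }
    cohort.diseases = pd.DataFrame(
        dis, index=cohort.individuals,
        columns=[f"disease_{d + 1}" for d in range(config.n_diseases)],
    )
    cohort.truth["diseases"] = truth_dis
    return cohort


def split_samples(cohort: Cohort, config: SimulationConfig) -> Cohort:
    """Assign disjoint GWAS / PRS / VALIDATION labels of the configured sizes."""
    config.validate()
    n = cohort.n_individuals
    sizes = (config.n_gwas, config.n_prs, config.n_validation)
    if sum(sizes) > n:
        raise ValueError(f"requested set sizes {sizes} exceed cohort size {n}")
    rng = _rng(config, 3)
    perm = rng.permutation(n)
    labels = np.full(n, UNASSIGNED, dtype=object)
    start = 0
    for label, size in zip(SET_LABELS, sizes):
        labels[perm[start:start + size]] = label
        start += size
    cohort.set_label = pd.Series(labels, index=cohort.individuals, name="set_label")
    return cohort


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Full generator: genotypes, risk factors, diseases, covariates, split."""
    cohort = simulate_genotypes(config)
    simulate_risk_factors(cohort, config)
    simulate_diseases(cohort, config)
    split_samples(cohort, config)
    return cohort


def inject_missing(cohort: Cohort, rate: float, seed: int = 0,
                   variant_ids: Sequence[str] | None = None) -> Cohort:
    """Corruption helper for QC tests: set a fraction of calls to missing."""
    if not 0 <= rate <= 1:
        raise ValueError("missing rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    cols = (
        np.arange(cohort.n_variants)
        if variant_ids is None
        else cohort.variants.index[cohort.variants["id"].isin(variant_ids)].to_numpy()
    )
    mask = rng.random((cohort.n_individuals, len(cols))) < rate
    dos = cohort.dosages.copy()
    dos[:, cols] = np.where(mask, np.nan, dos[:, cols])
    return replace(cohort, dosages=dos)


# ---------------------------------------------------------------------------
# cohort serialization: plain TSV, variant-major dosage matrix + sidecars
# ---------------------------------------------------------------------------

_COHORT_FILES = ("variants.tsv", "dosages.tsv", "covariates.tsv", "samples.tsv")


def write_cohort(cohort: Cohort, directory: str | Path) -> Path:
    """Write a cohort as tab-separated text (lossless except ``truth``)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    cohort.variants.to_csv(directory / "variants.tsv", sep="\t", index=False)
    values = cohort.dosages.T
    with np.errstate(invalid="ignore"):
        txt = np.where(np.isnan(values), "NA",
                       values.astype(np.int64, copy=False).astype("U2"))
    dos_fmt = pd.DataFrame(txt, index=cohort.variants["id"], columns=cohort.individuals)
    dos_fmt.to_csv(directory / "dosages.tsv", sep="\t", index_label="id")
    samples = pd.DataFrame(index=cohort.individuals)
    if cohort.set_label is not None:
        samples["set_label"] = cohort.set_label
    samples.to_csv(directory / "samples.tsv", sep="\t", index_label="iid")
    for name, table in (
        ("risk_factors", cohort.risk_factors),
        ("diseases", cohort.diseases),
        ("covariates", cohort.covariates),
    ):
        if table is not None:
            table.to_csv(directory / f"{name}.tsv", sep="\t", index_label="iid",
                         float_format="%.12g")
    return directory


def read_cohort(directory: str | Path) -> Cohort:
    """Read a cohort written by :func:`write_cohort`, validating dosages."""
    directory = Path(directory)
    variants = pd.read_csv(directory / "variants.tsv", sep="\t",
                           dtype={"effect_allele": str, "other_allele": str})
    dos = pd.read_csv(directory / "dosages.tsv", sep="\t", index_col="id",
                      na_values=["NA"])
    if list(dos.index) != list(variants["id"]):
        raise ValueError("dosage matrix rows do not match the variant table")
    values = dos.to_numpy(dtype=float)
    bad = ~(np.isnan(values) | np.isin(values, (0.0, 1.0, 2.0)))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"invalid dosage value {values[i, j]:g} at variant {dos.index[i]}, "
            f"individual {dos.columns[j]} (must be 0, 1, 2 or NA)"
        )
    individuals = pd.Index(dos.columns, name="iid")
    cohort = Cohort(dosages=values.T, variants=variants, individuals=individuals)
    samples = pd.read_csv(directory / "samples.tsv", sep="\t", index_col="iid")
    if "set_label" in samples.columns:
        cohort.set_label = samples["set_label"].reindex(individuals)
    for name in ("risk_factors", "diseases", "covariates"):
        path = directory / f"{name}.tsv"
        if path.exists():
            table = pd.read_csv(path, sep="\t", index_col="iid").reindex(individuals)
            setattr(cohort, name, table)
    if cohort.diseases is not None:
        cohort.diseases = cohort.diseases.astype(int)
    return cohort
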