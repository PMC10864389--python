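import numpy as np
import pandas as pd
import pytest

from metaprs import SimulationConfig, simulate_cohort
from metaprs.simulate import Cohort


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(
        n_gwas=700, n_prs=700, n_validation=400, n_snps=80, n_blocks=12,
        n_risk_factors=2, rf_h2=0.45, prevalence=[0.15],
        mediation_theta=[[0.45], [0.35]], disease_direct_h2=[0.08], seed=42)


@pytest.fixture(scope="session")
def small_cohort(small_config) -> Cohort:
    return simulate_cohort(small_config)


def toy_cohort(dosages, effect_alleles=None, other_alleles=None, **tables):
    """Hand-built cohort around an explicit dosage matrix (individuals x variants)."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    ea = effect_alleles or ["A"] * m
    oa = other_alleles or ["G"] * m
    variants = pd.DataFrame({
        "id": [f"v{j + 1}" for j in range(m)],
        "chrom": [1] * m, "pos": [1000 * (j + 1) for j in range(m)],
        "effect_allele": ea, "other_allele": oa,
        "maf": np.nanmean(dosages, axis=0) / 2, "block": [0] * m,
    })
    individuals = pd.Index([f"i{k + 1}" for k in range(n)], name="iid")
    cohort = Cohort(dosages=dosages, variants=variants, individuals=individuals)
    for name, table in tables.items():
        if table is not None:
            setattr(cohort, name,
                    pd.DataFrame(table, index=individuals)
                    if not isinstance(table, pd.DataFrame) else table)
    return cohort


def irls_logistic(X: np.ndarray, y: np.ndarray, tol: float = 1e-12,
                  max_iter: int = 200) -> np.ndarray:
    """Independent iteratively-reweighted-least-squares logistic oracle."""
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        z = eta + (y - mu) / w
        new = np.linalg.solve(X.T @ (X * w[:, None]), X.T @ (w * z))
        if np.max(np.abs(new - beta)) < tol:
            return new
        beta = new
    return beta
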