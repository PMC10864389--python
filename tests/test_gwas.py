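"""QC rules and association-test correctness against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from metaprs import (
    QCThresholds, gwas_linear, gwas_logistic, hwe_exact_p, read_sumstats,
    snp_qc, write_sumstats,
)
from metaprs.gwas import SUMSTAT_COLUMNS, SummaryStats

from .conftest import irls_logistic, toy_cohort


def _hwe_enumeration_oracle(n_het, n_hom_min, n_hom_maj):
    """Brute-force exact HWE p: enumerate all genotype splits with the same
    allele count and sum the probability of configurations no more likely
    than the observed one."""
    from math import comb

    n = n_het + n_hom_min + n_hom_maj
    na = 2 * n_hom_min + n_het

    def prob(h):
        hmin = (na - h) // 2
        hmaj = n - h - hmin
        # multinomial count of genotype configurations x 2^het over allele perms
        return (2 ** h) * comb(n, h) * comb(n - h, hmin) / comb(2 * n, na)

    probs = {h: prob(h) for h in range(na % 2, min(na, 2 * n - na) + 1, 2)}
    total = sum(probs.values())
    p_obs = probs[n_het] / total
    return sum(p / total for p in probs.values() if p / total <= p_obs * (1 + 1e-12))


@pytest.mark.parametrize("counts", [(2, 1, 7), (10, 5, 85), (0, 5, 5), (6, 0, 4)])
def test_hwe_exact_matches_enumeration(counts):
    assert hwe_exact_p(*counts) == pytest.approx(_hwe_enumeration_oracle(*counts),
                                                 rel=1e-10)


def test_qc_toy_attributes_one_exclusion_per_filter():
    """Six variants: one failing each of the five filters, one clean survivor."""
    rng = np.random.default_rng(0)
    n = 400
    hw = rng.binomial(2, 0.3, size=(n, 6)).astype(float)
    hw[: int(n * 0.2), 0] = np.nan                      # v1: missing rate 20%
    hw[:, 1] = 0.0
    hw[:5, 1] = 1.0                                     # v2: MAF ~ 0.6% < 1%
    hw[:, 2] = np.where(rng.random(n) < 0.3, 2.0, 0.0)  # v3: het deficit, HWE fail
    cohort = toy_cohort(
        hw, effect_alleles=["A", "A", "A", "AT", "A", "A"],
        other_alleles=["G", "G", "G", "G", "T", "G"])   # v4 indel, v5 ambiguous
    survivors, report = snp_qc(cohort, QCThresholds())
    assert survivors == ["v6"]
    for filt in ("missing_rate", "maf", "hwe", "indel", "ambiguous"):
        assert report.attrs[f"n_excluded_{filt}"] == 1, filt


def test_qc_clean_variants_all_pass_and_ambiguous_toggle():
    rng = np.random.default_rng(1)
    dos = rng.binomial(2, 0.4, size=(500, 3)).astype(float)
    cohort = toy_cohort(dos, effect_alleles=["A", "T", "C"],
                        other_alleles=["G", "C", "G"])  # v3 is C/G ambiguous
    survivors, _ = snp_qc(cohort)
    assert survivors == ["v1", "v2"]
    survivors_keep, _ = snp_qc(cohort, QCThresholds(drop_ambiguous=False))
    assert survivors_keep == ["v1", "v2", "v3"]


def test_qc_surviving_set_is_filter_order_independent():
    """Each filter is a pure per-variant predicate, so applying thresholds
    one at a time in any order must give the same surviving set."""
    rng = np.random.default_rng(2)
    dos = rng.binomial(2, rng.uniform(0.05, 0.5, 6), size=(300, 6)).astype(float)
    dos[:40, 0] = np.nan
    cohort = toy_cohort(dos, effect_alleles=["A", "T", "C", "A", "G", "A"],
                        other_alleles=["G", "A", "G", "C", "T", "ACGT"])
    full, _ = snp_qc(cohort)
    single_filter_fails = set()
    neutral = QCThresholds(max_missing_rate=1.0, min_maf=0.0, min_hwe_p=0.0,
                           drop_indels=False, drop_ambiguous=False)
    for field, value in [("max_missing_rate", 0.05), ("min_maf", 0.01),
                         ("min_hwe_p", 1e-6), ("drop_indels", True),
                         ("drop_ambiguous", True)]:
        thr = QCThresholds(**{**neutral.__dict__, field: value})
        surv, _ = snp_qc(cohort, thr)
        single_filter_fails |= set(cohort.variants["id"]) - set(surv)
    assert set(full) == set(cohort.variants["id"]) - single_filter_fails


def test_linear_trait_equals_dosage_gives_unit_beta():
    rng = np.random.default_rng(3)
    dos = rng.binomial(2, 0.4, size=(50, 2)).astype(float)
    cohort = toy_cohort(dos, risk_factors={"t": dos[:, 0]})
    ss = gwas_linear(cohort, "t", covariate_columns=[], set_label=None)
    row = ss.table.set_index("SNP").loc["v1"]
    assert row["BETA"] == pytest.approx(1.0, abs=1e-12)
    assert row["P"] <= 1e-30


def test_linear_matches_normal_equations_oracle():
    """8-individual fixture: beta and SE equal the explicit (X'X)^-1 X'y fit."""
    dos = np.array([0, 1, 2, 1, 0, 2, 1, 1], dtype=float)[:, None]
    age = np.array([41, 55, 62, 47, 53, 68, 44, 59], dtype=float)
    y = np.array([1.2, 0.7, 2.4, 1.1, 0.3, 2.9, 0.8, 1.5])
    cohort = toy_cohort(dos, risk_factors={"t": y},
                        covariates=pd.DataFrame({"age": age}))
    ss = gwas_linear(cohort, "t", covariate_columns=["age"], set_label=None)
    X = np.column_stack([dos[:, 0], np.ones(8), age])
    coef = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ coef
    sigma2 = resid @ resid / (8 - 3)
    se = np.sqrt(sigma2 * np.linalg.inv(X.T @ X)[0, 0])
    row = ss.table.iloc[0]
    assert row["BETA"] == pytest.approx(coef[0], abs=1e-10)
    assert row["SE"] == pytest.approx(se, abs=1e-10)


def test_linear_standardized_beta_equals_pearson_r():
    rng = np.random.default_rng(4)
    x = rng.binomial(2, 0.3, 40).astype(float)
    y = x * 0.4 + rng.standard_normal(40)
    xs = (x - x.mean()) / x.std()
    ys = (y - y.mean()) / y.std()
    cohort = toy_cohort(xs[:, None], risk_factors={"t": ys})
    # standardized dosage is not {0,1,2}; gwas_linear only needs numerics
    ss = gwas_linear(cohort, "t", covariate_columns=[], set_label=None)
    assert ss.table.iloc[0]["BETA"] == pytest.approx(np.corrcoef(x, y)[0, 1],
                                                     abs=1e-10)


def test_linear_permuted_trait_pvalues_uniform(small_cohort):
    rng = np.random.default_rng(5)
    perm = small_cohort.risk_factors["rf_1"].sample(
        frac=1.0, random_state=7).to_numpy()
    cohort = small_cohort
    cohort.risk_factors["perm"] = perm
    ss = gwas_linear(cohort, "perm", set_label="GWAS")
    ks = stats.kstest(ss.table["P"], "uniform")
    assert ks.pvalue > 0.01
    cohort.risk_factors.drop(columns="perm", inplace=True)


def test_logistic_matches_irls_oracle():
    rng = np.random.default_rng(6)
    dos = rng.binomial(2, 0.45, size=(120, 1)).astype(float)
    age = rng.uniform(40, 70, 120)
    eta = 0.7 * dos[:, 0] - 3.0 + 0.02 * age
    y = (rng.random(120) < 1 / (1 + np.exp(-eta))).astype(int)
    cohort = toy_cohort(dos, diseases={"d": y},
                        covariates=pd.DataFrame({"age": age}))
    ss = gwas_logistic(cohort, "d", covariate_columns=["age"], set_label=None)
    X = np.column_stack([dos[:, 0], np.ones(120), age])
    beta_oracle = irls_logistic(X, y.astype(float))
    assert ss.table.iloc[0]["BETA"] == pytest.approx(beta_oracle[0], abs=1e-8)


def test_logistic_constant_dosage_omitted_with_reason():
    rng = np.random.default_rng(7)
    dos = np.column_stack([np.full(60, 1.0), rng.binomial(2, 0.4, 60)]).astype(float)
    y = rng.integers(0, 2, 60)
    cohort = toy_cohort(dos, diseases={"d": y})
    ss = gwas_logistic(cohort, "d", covariate_columns=[], set_label=None)
    assert list(ss.omitted["SNP"]) == ["v1"]
    assert "degenerate genotype" in ss.omitted.iloc[0]["reason"]
    assert list(ss.table["SNP"]) == ["v2"]


def test_sumstats_round_trip_and_validation(tmp_path):
    table = pd.DataFrame({
        "SNP": ["a", "b"], "A1": ["A", "T"], "A2": ["G", "C"],
        "EAF": [0.3, 0.41234567891], "BETA": [0.123456789012, -1.5e-4],
        "SE": [0.01, 0.02], "Z": [12.3456789012, -0.0075],
        "P": [1e-30, 0.994], "N": [100, 100],
    })
    table["Z"] = table["BETA"] / table["SE"]
    ss = SummaryStats(trait_id="t", model="linear", table=table).validate()
    path = write_sumstats(ss, tmp_path / "s.tsv")
    back = read_sumstats(path, trait_id="t")
    for col in SUMSTAT_COLUMNS:
        np.testing.assert_allclose(
            pd.to_numeric(back.table[col], errors="coerce").fillna(0),
            pd.to_numeric(ss.table[col], errors="coerce").fillna(0), rtol=1e-9)

    bad = table.copy()
    bad.loc[0, "P"] = 0.0
    (tmp_path / "bad.tsv").write_text(
        bad.to_csv(sep="\t", index=False))
    with pytest.raises(ValueError, match="p-values"):
        read_sumstats(tmp_path / "bad.tsv")

    same_allele = table.copy()
    same_allele.loc[0, "A2"] = "A"
    (tmp_path / "aa.tsv").write_text(same_allele.to_csv(sep="\t", index=False))
    with pytest.raises(ValueError, match="allele"):
        read_sumstats(tmp_path / "aa.tsv")

    missing_col = table.drop(columns=["SE"])
    (tmp_path / "mc.tsv").write_text(missing_col.to_csv(sep="\t", index=False))
    with pytest.raises(ValueError, match="SE"):
        read_sumstats(tmp_path / "mc.tsv")


def test_adding_independent_covariate_barely_moves_beta(small_cohort):
    ss0 = gwas_linear(small_cohort, "rf_1", covariate_columns=[],
                      set_label="GWAS")
    ss1 = gwas_linear(small_cohort, "rf_1", covariate_columns=["age", "sex"],
                      set_label="GWAS")
    merged = ss0.table.merge(ss1.table, on="SNP", suffixes=("_0", "_1"))
    shift = np.abs(merged["BETA_0"] - merged["BETA_1"]) / merged["SE_0"]
    assert shift.max() < 3.0
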