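"""LD matrices, the infinitesimal reweighting closed form, scoring and
standardization."""

import numpy as np
import pandas as pd
import pytest

from metaprs import (
    ld_corr_matrix, ldpred_inf_reweight, marginal_weights, prs_trait_correlation,
    read_weights, score_prs, standardize_scores, write_weights,
)
from metaprs.gwas import SummaryStats
from metaprs.prs import LDCorrelationMatrix, ScoreSet, SNPWeightSet
from metaprs.simulate import split_samples, SimulationConfig

from .conftest import toy_cohort


def _stats(ids, betas, alleles=None, n=1000):
    m = len(ids)
    se = np.full(m, 0.02)
    a1 = [a[0] for a in alleles] if alleles else ["A"] * m
    a2 = [a[1] for a in alleles] if alleles else ["G"] * m
    betas = np.asarray(betas, dtype=float)
    return SummaryStats(trait_id="t", model="linear", table=pd.DataFrame({
        "SNP": ids, "A1": a1, "A2": a2, "EAF": [0.3] * m,
        "BETA": betas, "SE": se, "Z": betas / se, "P": [0.5] * m, "N": [n] * m,
    })).validate()


def test_ld_matrix_duplicated_and_independent_variants():
    rng = np.random.default_rng(0)
    x = rng.binomial(2, 0.4, size=2000).astype(float)
    z = rng.binomial(2, 0.3, size=2000).astype(float)
    cohort = toy_cohort(np.column_stack([x, x, z]))
    ld = ld_corr_matrix(cohort)
    mat = ld.blocks[0][1]
    assert mat[0, 1] == pytest.approx(1.0, abs=1e-12)
    assert abs(mat[0, 2]) < 4 / np.sqrt(2000)


def test_ld_matrix_matches_brute_force():
    rng = np.random.default_rng(1)
    base = rng.standard_normal((200, 1))
    dos = np.clip(np.round(base + rng.standard_normal((200, 4)) + 1), 0, 2)
    cohort = toy_cohort(dos)
    ld = ld_corr_matrix(cohort)
    mat = ld.blocks[0][1]
    for j in range(4):
        for k in range(4):
            assert mat[j, k] == pytest.approx(
                np.corrcoef(dos[:, j], dos[:, k])[0, 1], abs=1e-12)


def test_ld_matrix_rejects_constant_column_by_name():
    dos = np.column_stack([np.full(50, 1.0),
                           np.random.default_rng(2).binomial(2, 0.4, 50)])
    with pytest.raises(ValueError, match="v1"):
        ld_corr_matrix(toy_cohort(dos.astype(float)))


def test_ldpred_identity_ld_is_uniform_shrinkage():
    """With D = I the solve reduces to beta / (1 + M/(N h2)) for every SNP."""
    ids = [f"v{j}" for j in range(3)]
    ld = LDCorrelationMatrix(blocks=[(ids, np.eye(3))],
                             dosage_sd=pd.Series(1.0, index=ids))
    stats_obj = _stats(ids, [0.5, -0.2, 0.1], n=1000)
    w = ldpred_inf_reweight(stats_obj, ld, h2=0.5, n_samples=1000)
    # M=3 here: shrink = 1/(1 + 3/(1000*0.5))
    shrink = 1 / (1 + 3 / (1000 * 0.5))
    np.testing.assert_allclose(w.table["weight"], np.array([0.5, -0.2, 0.1]) * shrink,
                               atol=1e-12)
    # the spec's M=100 worked example of the same scalar closed form
    assert 1 / (1 + 100 / (1000 * 0.5)) == pytest.approx(0.833333, abs=1e-6)


def test_ldpred_vanishing_ridge_limit_inverts_ld():
    rng = np.random.default_rng(3)
    A = rng.standard_normal((3, 3))
    D = A @ A.T
    d = np.sqrt(np.diag(D))
    D = D / np.outer(d, d)
    ids = ["a", "b", "c"]
    ld = LDCorrelationMatrix(blocks=[(ids, D)], dosage_sd=pd.Series(1.0, index=ids))
    beta = np.array([0.3, -0.1, 0.2])
    w = ldpred_inf_reweight(_stats(ids, beta), ld, h2=1.0, n_samples=10 ** 12)
    np.testing.assert_allclose(w.table["weight"], np.linalg.solve(D, beta),
                               atol=1e-6)


def test_ldpred_matches_dense_solve_oracle():
    """3-variant block with non-unit dosage SDs against an explicit inversion."""
    D = np.array([[1.0, 0.4, 0.2], [0.4, 1.0, 0.5], [0.2, 0.5, 1.0]])
    ids = ["a", "b", "c"]
    sd = pd.Series([0.8, 1.1, 0.6], index=ids)
    ld = LDCorrelationMatrix(blocks=[(ids, D)], dosage_sd=sd)
    beta = np.array([0.25, -0.15, 0.05])
    h2, N, M = 0.3, 2000, 3
    w = ldpred_inf_reweight(_stats(ids, beta, n=N), ld, h2=h2)
    beta_std = beta * sd.to_numpy()
    oracle_std = np.linalg.inv(D + (M / (N * h2)) * np.eye(3)) @ beta_std
    np.testing.assert_allclose(w.table["weight"], oracle_std / sd.to_numpy(),
                               atol=1e-10)


def test_ldpred_rejects_nonpositive_h2():
    ids = ["a"]
    ld = LDCorrelationMatrix(blocks=[(ids, np.eye(1))],
                             dosage_sd=pd.Series(1.0, index=ids))
    with pytest.raises(ValueError, match="h2"):
        ldpred_inf_reweight(_stats(ids, [0.1]), ld, h2=0.0)


def _weights(ids, values, alleles=None):
    a1 = [a[0] for a in alleles] if alleles else ["A"] * len(ids)
    a2 = [a[1] for a in alleles] if alleles else ["G"] * len(ids)
    return SNPWeightSet(trait_id="t", method="marginal", table=pd.DataFrame({
        "id": ids, "effect_allele": a1, "other_allele": a2, "weight": values,
    })).validate()


def test_scoring_hand_example_and_trivials():
    cohort = toy_cohort(np.array([[2.0, 1.0], [0.0, 2.0]]))
    scores = score_prs(cohort, _weights(["v1", "v2"], [0.5, -1.0]))
    assert scores.raw.iloc[0] == pytest.approx(0.0)     # 2*0.5 + 1*(-1)
    assert scores.raw.iloc[1] == pytest.approx(-2.0)
    zeros = score_prs(cohort, _weights(["v1", "v2"], [0.0, 0.0]))
    assert (zeros.raw == 0).all()
    single = score_prs(cohort, _weights(["v1"], [1.0]))
    np.testing.assert_allclose(single.raw, cohort.dosages[:, 0])


def test_scoring_missing_variant_is_hard_error():
    cohort = toy_cohort(np.array([[1.0]]))
    with pytest.raises(ValueError, match="ghost"):
        score_prs(cohort, _weights(["ghost"], [1.0]))


def test_scoring_is_linear_in_weights():
    rng = np.random.default_rng(4)
    dos = rng.binomial(2, 0.4, size=(30, 5)).astype(float)
    cohort = toy_cohort(dos)
    ids = list(cohort.variants["id"])
    w1 = rng.standard_normal(5)
    w2 = rng.standard_normal(5)
    s1 = score_prs(cohort, _weights(ids, w1)).raw
    s2 = score_prs(cohort, _weights(ids, w2)).raw
    s12 = score_prs(cohort, _weights(ids, w1 + w2)).raw
    np.testing.assert_allclose(s12, s1 + s2, atol=1e-10)


def test_allele_flip_invariance():
    """Flipping effect/other allele and negating beta shifts raw scores by a
    constant and leaves standardized scores unchanged."""
    rng = np.random.default_rng(5)
    dos = rng.binomial(2, 0.4, size=(40, 3)).astype(float)
    cohort = toy_cohort(dos)
    cfg = SimulationConfig(n_gwas=20, n_prs=20, n_validation=0, n_snps=3,
                           n_blocks=1, n_risk_factors=1, prevalence=[0.3], seed=0)
    split_samples(cohort, cfg)
    ids = list(cohort.variants["id"])
    w = np.array([0.5, -0.3, 0.2])
    plain = _weights(ids, w)
    flipped = _weights(ids, [-0.5, -0.3, 0.2],
                       alleles=[("G", "A"), ("A", "G"), ("A", "G")])
    s_plain = score_prs(cohort, plain).raw
    s_flip = score_prs(cohort, flipped).raw
    diffs = s_flip - s_plain
    assert np.ptp(diffs) < 1e-10  # constant offset
    z_plain = standardize_scores(score_prs(cohort, plain), cohort, "PRS")
    z_flip = standardize_scores(score_prs(cohort, flipped), cohort, "PRS")
    np.testing.assert_allclose(z_plain.standardized, z_flip.standardized,
                               atol=1e-8)


def test_standardize_population_sd_convention():
    cohort = toy_cohort(np.array([[0.0], [1.0], [2.0]]))
    cfg = SimulationConfig(n_gwas=3, n_prs=0, n_validation=0, n_snps=1,
                           n_blocks=1, n_risk_factors=1, prevalence=[0.3], seed=0)
    # label all three individuals as the source set
    cohort.set_label = pd.Series(["PRS"] * 3, index=cohort.individuals)
    raw = ScoreSet(trait_id="t", raw=pd.Series([1.0, 2.0, 3.0],
                                               index=cohort.individuals))
    std = standardize_scores(raw, cohort, source_set="PRS")
    # population SD of (1,2,3) is sqrt(2/3); spec convention fixes (-1,0,1)
    np.testing.assert_allclose(std.standardized,
                               (np.array([1, 2, 3]) - 2) / np.sqrt(2 / 3))
    assert std.sd == pytest.approx(np.sqrt(2 / 3))
    same = (raw.raw - std.mean) / std.sd
    assert abs(same.mean()) < 1e-8 and abs(same.std(ddof=0) - 1) < 1e-8


def test_standardize_rejects_constant_scores():
    cohort = toy_cohort(np.array([[1.0], [1.0]]))
    cohort.set_label = pd.Series(["PRS", "PRS"], index=cohort.individuals)
    raw = ScoreSet(trait_id="t", raw=pd.Series([2.0, 2.0], index=cohort.individuals))
    with pytest.raises(ValueError, match="degenerate score distribution"):
        standardize_scores(raw, cohort, source_set="PRS")


def test_prs_trait_correlation_trivials():
    idx = pd.Index([f"i{k}" for k in range(100)])
    rng = np.random.default_rng(6)
    v = pd.Series(rng.standard_normal(100), index=idx)
    scores = ScoreSet(trait_id="t", raw=v)
    r, p = prs_trait_correlation(scores, v)
    assert r == pytest.approx(1.0)
    r2, _ = prs_trait_correlation(scores, pd.Series(rng.standard_normal(100),
                                                    index=idx))
    assert abs(r2) < 4 / np.sqrt(100)
    with pytest.raises(ValueError, match="3"):
        prs_trait_correlation(ScoreSet(trait_id="t", raw=v.iloc[:2]), v.iloc[:2])


def test_weight_file_round_trip(tmp_path):
    w = _weights(["a", "b"], [0.123456789, -9.87654321e-5])
    path = write_weights(w, tmp_path / "w.txt")
    text = path.read_text()
    assert text.startswith("#trait_id=t")
    assert "rsID\teffect_allele\tother_allele\teffect_weight" in text
    back = read_weights(path)
    assert back.trait_id == "t" and back.method == "marginal"
    np.testing.assert_allclose(back.table["weight"], w.table["weight"], rtol=1e-9)


def test_marginal_weights_pass_through():
    ss = _stats(["a", "b"], [0.2, -0.1])
    w = marginal_weights(ss)
    np.testing.assert_allclose(w.table["weight"], [0.2, -0.1])
    assert w.method == "marginal"


def test_end_to_end_rfprs_correlates_with_its_risk_factor():
    """Full chain (GWAS -> LDSC -> infinitesimal reweighting -> scoring) on a
    heritable trait: the PRS correlates with the trait far beyond chance in
    the held-out PRS set."""
    from metaprs import (SimulationConfig, compute_ld_scores, gwas_linear,
                         ldsc_h2, simulate_cohort)

    cfg = SimulationConfig(n_gwas=2000, n_prs=2000, n_validation=0,
                           n_snps=150, n_blocks=30, n_risk_factors=1,
                           rf_h2=0.4, prevalence=[0.2], seed=23)
    cohort = simulate_cohort(cfg)
    ss = gwas_linear(cohort, "rf_1", set_label="GWAS")
    h2 = max(ldsc_h2(ss, compute_ld_scores(cohort, set_label="GWAS")).h2, 0.05)
    ld = ld_corr_matrix(cohort, set_label="GWAS")
    weights = ldpred_inf_reweight(ss, ld, h2=h2)
    scores = score_prs(cohort, weights, set_label="PRS")
    r, p = prs_trait_correlation(
        scores, cohort.risk_factors.loc[scores.raw.index, "rf_1"])
    assert r > 0 and p < 1e-6
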