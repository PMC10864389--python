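"""End-to-end orchestration: simulate -> qc -> gwas -> h2 -> reweight ->
score -> screen -> integrate -> evaluate, from one YAML config.

Each stage is a pure function of its inputs and a per-stage seed spawned
deterministically from the global seed; outputs are plain text files in the
run directory plus a manifest (config hash, stage seeds, file digests,
timings) that makes a run auditable and re-runnable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .evaluation import (
    continuous_nri, cumulative_incidence, fit_risk_models, nagelkerke_r2,
    or_per_sd, r2_difference_test, top_decile_or,
)
from .gwas import QCThresholds, gwas_linear, gwas_logistic, snp_qc, write_sumstats
from .heritability import (
    compute_ld_scores, ldsc_h2, prevalence_filter, screen_heritable,
    write_h2_report, write_ld_scores,
)
from .integrate import (
    combine_to_per_snp_weights, elastic_net_integration, weight_ratio,
)
from .prs import (
    ld_corr_matrix, ldpred_inf_reweight, score_prs, standardize_scores,
    write_scores, write_weights,
)
from .screen import run_screen, write_screen
from .simulate import (
    GWAS, PRS, VALIDATION, SimulationConfig, read_cohort, simulate_cohort,
    write_cohort,
)

logger = logging.getLogger(__name__)

SIM_KEYS = {
    "n_gwas", "n_prs", "n_validation", "n_snps", "n_blocks", "block_corr",
    "maf_range", "n_risk_factors", "rf_h2", "n_causal_per_rf",
    "mediation_theta", "disease_direct_h2", "prevalence", "seed",
    "confounding", "rf_env_corr",
}
PIPE_KEYS = {
    "folds", "l1_ratio", "alpha", "bootstrap", "min_prevalence",
    "ld_reference_size", "n_lambdas", "min_h2",
}
PIPE_DEFAULTS = {
    "folds": 10, "l1_ratio": 0.5, "alpha": 0.05, "bootstrap": 500,
    "min_prevalence": 0.001, "ld_reference_size": 10_000, "n_lambdas": 30,
    "min_h2": 0.01,
}

STAGES = ("simulate", "qc", "gwas", "h2", "reweight", "score", "screen",
          "integrate", "evaluate")


@dataclass
class PipelineConfig:
    sim: SimulationConfig
    folds: int = 10
    l1_ratio: float = 0.5
    alpha: float = 0.05
    bootstrap: int = 500
    min_prevalence: float = 0.001
    ld_reference_size: int = 10_000
    n_lambdas: int = 30
    min_h2: float = 0.01

    def validate(self) -> "PipelineConfig":
        self.sim.validate()
        if self.folds < 2:
            raise ValueError("folds must be >= 2 for cross-validation")
        if not 0 <= self.l1_ratio <= 1:
            raise ValueError("l1_ratio must lie in [0, 1]")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.bootstrap < 0:
            raise ValueError("bootstrap must be non-negative")
        if not 0 <= self.min_prevalence < 1:
            raise ValueError("min_prevalence must lie in [0, 1)")
        return self

    def normalized(self) -> dict:
        sim = {
            "n_gwas": self.sim.n_gwas, "n_prs": self.sim.n_prs,
            "n_validation": self.sim.n_validation, "n_snps": self.sim.n_snps,
            "n_blocks": self.sim.n_blocks, "block_corr": self.sim.block_corr,
            "maf_range": list(self.sim.maf_range),
            "n_risk_factors": self.sim.n_risk_factors,
            "rf_h2": np.asarray(self.sim.rf_h2).tolist(),
            "n_causal_per_rf": self.sim.n_causal_per_rf,
            "mediation_theta": np.asarray(self.sim.mediation_theta).tolist(),
            "disease_direct_h2": np.asarray(self.sim.disease_direct_h2).tolist(),
            "prevalence": np.asarray(self.sim.prevalence).tolist(),
            "seed": int(self.sim.seed),
            "confounding": self.sim.confounding,
            "rf_env_corr": self.sim.rf_env_corr,
        }
        sim.update({k: getattr(self, k) for k in sorted(PIPE_KEYS)})
        return sim


def validate_config(path: str | Path) -> PipelineConfig:
    """Load, type- and range-check a YAML run config (typo-safe)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a YAML mapping")
    unknown = set(raw) - SIM_KEYS - PIPE_KEYS
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    if "seed" not in raw:
        raise ValueError("config must set 'seed'")
    sim_kwargs = {k: v for k, v in raw.items() if k in SIM_KEYS}
    if "maf_range" in sim_kwargs:
        sim_kwargs["maf_range"] = tuple(sim_kwargs["maf_range"])
    sim = SimulationConfig(**sim_kwargs)
    pipe_kwargs = {k: raw.get(k, PIPE_DEFAULTS[k]) for k in PIPE_KEYS}
    return PipelineConfig(sim=sim, **pipe_kwargs).validate()


@dataclass
class RunManifest:
    config_hash: str
    version: str
    stage_seeds: dict = dc_field(default_factory=dict)
    digests: dict = dc_field(default_factory=dict)
    timings: dict = dc_field(default_factory=dict)
    funnel: dict = dc_field(default_factory=dict)

    def save(self, path: Path) -> Path:
        path.write_text(json.dumps(self.__dict__, indent=2, default=str))
        return path


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_seed(global_seed: int, stage: str) -> int:
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


class PipelineRun:
    """Stateful runner holding the config, output directory and manifest."""

    def __init__(self, config: PipelineConfig, out_dir: str | Path):
        self.config = config.validate()
        self.out = Path(out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        payload = json.dumps(config.normalized(), sort_keys=True)
        self.manifest = RunManifest(
            config_hash=hashlib.sha256(payload.encode()).hexdigest(),
            version=__version__,
        )
        self.cohort = None
        self.survivors: list[str] | None = None
        self.sumstats: dict = {}
        self.ld_scores = None
        self.ld = None
        self.h2: dict = {}
        self.weights: dict = {}
        self.scores: dict = {}
        self.screen_table = None
        self.kept_rf: list[str] = []
        self.kept_diseases: list[str] = []
        self.meta: dict = {}
        self.combined: dict = {}

    def _record(self, stage: str, t0: float, files: list[Path]) -> None:
        self.manifest.timings[stage] = round(time.time() - t0, 3)
        for f in files:
            self.manifest.digests[str(f.relative_to(self.out))] = _digest(f)

    # ----------------------------------------------------------------- stages
    def stage_simulate(self) -> None:
        t0 = time.time()
        self.manifest.stage_seeds["simulate"] = int(self.config.sim.seed)
        self.cohort = simulate_cohort(self.config.sim)
        cohort_dir = self.out / "cohort"
        write_cohort(self.cohort, cohort_dir)
        self._record("simulate", t0, sorted(cohort_dir.glob("*.tsv")))
        logger.info("simulate: n=%d individuals, m=%d variants, %d risk factors, "
                    "%d diseases", self.cohort.n_individuals, self.cohort.n_variants,
                    self.config.sim.n_risk_factors, self.config.sim.n_diseases)

    def _require_cohort(self):
        if self.cohort is None:
            cohort_dir = self.out / "cohort"
            if not cohort_dir.exists():
                raise RuntimeError("no cohort available; run the simulate stage first")
            self.cohort = read_cohort(cohort_dir)
            if "block" not in self.cohort.variants.columns:
                raise RuntimeError("cohort variant table lacks LD block assignments")
        return self.cohort

    def stage_qc(self) -> None:
        t0 = time.time()
        cohort = self._require_cohort()
        self.survivors, report = snp_qc(cohort, QCThresholds())
        path = self.out / "qc_report.tsv"
        report.to_csv(path, sep="\t", index=False)
        self.manifest.funnel["variants_total"] = cohort.n_variants
        self.manifest.funnel["variants_pass_qc"] = len(self.survivors)
        self._record("qc", t0, [path])
        logger.info("qc: %d / %d variants pass", len(self.survivors), cohort.n_variants)

    def stage_gwas(self) -> None:
        t0 = time.time()
        cohort = self._require_cohort()
        if self.survivors is None:
            self.stage_qc()
        files = []
        for rf in cohort.risk_factors.columns:
            ss = gwas_linear(cohort, rf, set_label=GWAS, variant_ids=self.survivors)
            self.sumstats[rf] = ss
            files.append(write_sumstats(ss, self.out / f"gwas_{rf}.tsv"))
        for dis in cohort.diseases.columns:
            ss = gwas_logistic(cohort, dis, set_label=GWAS, variant_ids=self.survivors)
            self.sumstats[dis] = ss
            files.append(write_sumstats(ss, self.out / f"gwas_{dis}.tsv"))
        self._record("gwas", t0, files)
        logger.info("gwas: %d traits tested on %d variants",
                    len(self.sumstats), len(self.survivors))

    def stage_h2(self) -> None:
        t0 = time.time()
        cohort = self._require_cohort()
        seed = _stage_seed(self.config.sim.seed, "h2")
        self.manifest.stage_seeds["h2"] = seed
        self.ld_scores = compute_ld_scores(
            cohort, set_label=GWAS,
            max_individuals=self.config.ld_reference_size, seed=seed)
        estimates = []
        min_overlap = min(50, max(3, len(self.survivors or []) // 2))
        for trait, ss in self.sumstats.items():
            est = ldsc_h2(ss, self.ld_scores, min_overlap=min_overlap)
            self.h2[trait] = est
            estimates.append(est)
        rf_ids = list(cohort.risk_factors.columns)
        dis_ids = list(cohort.diseases.columns)
        rf_est = [self.h2[r] for r in rf_ids if r in self.h2]
        dis_est = [self.h2[d] for d in dis_ids if d in self.h2]
        self.kept_rf = screen_heritable(rf_est, n_tests=max(len(rf_est), 1),
                                        alpha=self.config.alpha)
        prevalent = set(prevalence_filter(cohort, self.config.min_prevalence))
        heritable = set(screen_heritable(dis_est, n_tests=max(len(dis_est), 1),
                                         alpha=self.config.alpha))
        self.kept_diseases = [d for d in dis_ids if d in prevalent and d in heritable]
        files = [
            write_ld_scores(self.ld_scores, self.out / "ld_scores.tsv"),
            write_h2_report(estimates, self.out / "heritability.tsv"),
        ]
        self.manifest.funnel.update({
            "risk_factors_total": len(rf_ids),
            "risk_factors_heritable": len(self.kept_rf),
            "diseases_total": len(dis_ids),
            "diseases_prevalent": len(prevalent),
            "diseases_heritable": len(heritable & set(dis_ids)),
            "diseases_kept": len(self.kept_diseases),
        })
        self._record("h2", t0, files)
        logger.info("h2: %d/%d risk factors and %d/%d diseases pass screens",
                    len(self.kept_rf), len(rf_ids), len(self.kept_diseases), len(dis_ids))

    def stage_reweight(self) -> None:
        t0 = time.time()
        cohort = self._require_cohort()
        seed = _stage_seed(self.config.sim.seed, "reweight")
        self.manifest.stage_seeds["reweight"] = seed
        self.ld = ld_corr_matrix(cohort, set_label=GWAS,
                                 max_individuals=self.config.ld_reference_size,
                                 seed=seed)
        files = []
        for trait in self.kept_rf + self.kept_diseases:
            est = self.h2[trait]
            w = ldpred_inf_reweight(self.sumstats[trait], self.ld,
                                    h2=max(est.h2, self.config.min_h2),
                                    min_h2=self.config.min_h2)
            self.weights[trait] = w
            files.append(write_weights(w, self.out / f"weights_{trait}.txt"))
        self._record("reweight", t0, files)

    def stage_score(self) -> None:
        t0 = time.time()
        cohort = self._require_cohort()
        files = []
        for trait, w in self.weights.items():
            raw = score_prs(cohort, w)
            std = standardize_scores(raw, cohort, source_set=PRS)
            self.scores[trait] = std
            files.append(write_scores(std, self.out / f"scores_{trait}.tsv"))
        self._record("score", t0, files)

    def stage_screen(self) -> None:
        t0 = time.time()
        cohort = self._require_cohort()
        rf_scores = {r: self.scores[r] for r in self.kept_rf}
        self.screen_table = run_screen(
            rf_scores, cohort, self.kept_diseases,
            alpha=self.config.alpha,
            n_tests=max(len(rf_scores) * len(self.kept_diseases), 1))
        path = write_screen(self.screen_table, self.out / "screen.tsv")
        n_sel = sum(len(v) for v in self.screen_table.selected.values())
        self.manifest.funnel["screen_tests"] = self.screen_table.n_tests
        self.manifest.funnel["screen_selected"] = n_sel
        self._record("screen", t0, [path])
        logger.info("screen: %d significant of %d tests", n_sel, self.screen_table.n_tests)

    def stage_integrate(self) -> None:
        t0 = time.time()
        cohort = self._require_cohort()
        seed = _stage_seed(self.config.sim.seed, "integrate")
        self.manifest.stage_seeds["integrate"] = seed
        files = []
        for dis in self.kept_diseases:
            selected = self.screen_table.selected.get(dis, [])
            prs_scores = {r: self.scores[r] for r in selected}
            prs_scores[f"{dis}_prs"] = self.scores[dis]
            meta = elastic_net_integration(
                prs_scores, cohort, dis, f"{dis}_prs",
                folds=self.config.folds, l1_ratio=self.config.l1_ratio,
                seed=seed, n_lambdas=self.config.n_lambdas)
            self.meta[dis] = meta
            comp = {r: self.weights[r] for r in selected}
            comp[f"{dis}_prs"] = self.weights[dis]
            combined = combine_to_per_snp_weights(meta, comp)
            self.combined[dis] = combined
            files.append(meta.to_json(self.out / f"meta_{dis}.json"))
            files.append(write_weights(combined, self.out / f"weights_{dis}_meta.txt"))
        self._record("integrate", t0, files)

    def stage_evaluate(self) -> None:
        t0 = time.time()
        cohort = self._require_cohort()
        seed = _stage_seed(self.config.sim.seed, "evaluate")
        self.manifest.stage_seeds["evaluate"] = seed
        rows, curve_frames = [], []
        for dis in self.kept_diseases:
            meta_raw = score_prs(cohort, self.combined[dis])
            meta_std = standardize_scores(meta_raw, cohort, source_set=PRS)
            row = evaluate_disease(
                cohort, dis,
                disease_scores=self.scores[dis].standardized,
                meta_scores=meta_std.standardized,
                bootstrap=self.config.bootstrap, seed=seed)
            row["weight_ratio"] = weight_ratio(self.meta[dis])
            rows.append(row)
            curves = cumulative_incidence_by_group(cohort, dis, meta_std.standardized)
            curves.insert(0, "disease", dis)
            curve_frames.append(curves)
        report = pd.DataFrame(rows)
        files = []
        path = self.out / "evaluation_report.tsv"
        report.to_csv(path, sep="\t", index=False, float_format="%.6g")
        files.append(path)
        jpath = self.out / "evaluation_report.json"
        jpath.write_text(json.dumps(rows, indent=2, default=float))
        files.append(jpath)
        if curve_frames:
            cpath = self.out / "cumulative_incidence.tsv"
            pd.concat(curve_frames).to_csv(cpath, sep="\t", index=False,
                                           float_format="%.6g")
            files.append(cpath)
        self._record("evaluate", t0, files)

    def run(self) -> RunManifest:
        for stage in STAGES:
            try:
                getattr(self, f"stage_{stage}")()
            except Exception as exc:
                self.manifest.save(self.out / "manifest.json")
                raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
        self.manifest.save(self.out / "manifest.json")
        return self.manifest


def evaluate_disease(cohort, disease_id: str, disease_scores: pd.Series,
                     meta_scores: pd.Series, bootstrap: int = 500,
                     seed: int = 0) -> dict:
    """Full metric battery for one disease in the validation set.

    Nagelkerke R^2, OR per SD, the dependent-R^2 difference test and the
    top-decile OR use models fitted on the whole validation set; the NRI
    follows the modeling/evaluation halving design (models fitted on one
    half, reclassification counted on the other).
    """
    models = fit_risk_models(cohort, disease_id, {
        "diseasePRS": disease_scores, "metaPRS": meta_scores})
    r2_meta = nagelkerke_r2(models["null+metaPRS"], models["null"])
    r2_dis = nagelkerke_r2(models["null+diseasePRS"], models["null"])
    or_meta, ci_meta = or_per_sd(models["null+metaPRS"])
    or_dis, ci_dis = or_per_sd(models["null+diseasePRS"])

    # NRI: halve the validation set; fit on the modeling half, count on the other
    val_ids = cohort.individuals[cohort.set_mask(VALIDATION)]
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(val_ids))
    half = len(val_ids) // 2
    model_ids, eval_ids = val_ids[perm[:half]], val_ids[perm[half:]]
    y_eval = cohort.diseases.loc[eval_ids, disease_id].to_numpy(dtype=int)
    try:
        half_models = fit_risk_models(cohort, disease_id, {
            "diseasePRS": disease_scores, "metaPRS": meta_scores},
            individuals=model_ids)
        probs = {
            label: predict_risk(m, cohort, eval_ids,
                                disease_scores if "diseasePRS" in label
                                else (meta_scores if "metaPRS" in label else None))
            for label, m in half_models.items()
        }
        nri_meta = continuous_nri(probs["null"], probs["null+metaPRS"], y_eval,
                                  bootstrap=bootstrap, seed=seed)
        nri_dis = continuous_nri(probs["null"], probs["null+diseasePRS"], y_eval,
                                 bootstrap=bootstrap, seed=seed)
        nri_vals = {"nri_meta": nri_meta.nri, "nri_disease": nri_dis.nri,
                    "nri_meta_p": nri_meta.p, "nri_disease_p": nri_dis.p,
                    "delta_nri": nri_meta.nri - nri_dis.nri}
    except (ValueError, RuntimeError) as exc:
        logger.warning("%s: NRI halving failed (%s); reporting NaN", disease_id, exc)
        nri_vals = {"nri_meta": np.nan, "nri_disease": np.nan,
                    "nri_meta_p": None, "nri_disease_p": None, "delta_nri": np.nan}

    y_val = cohort.diseases.loc[val_ids, disease_id].to_numpy(dtype=int)
    dr2 = r2_difference_test(
        disease_scores.loc[val_ids], meta_scores.loc[val_ids], y_val,
        method="bootstrap", bootstrap=bootstrap, seed=seed)
    top_meta = top_decile_or(meta_scores.loc[val_ids], y_val)
    top_dis = top_decile_or(disease_scores.loc[val_ids], y_val)
    return {
        "disease": disease_id,
        "nagelkerke_meta": r2_meta, "nagelkerke_disease": r2_dis,
        "or_per_sd_meta": or_meta, "or_per_sd_disease": or_dis,
        **nri_vals,
        "delta_r2": dr2["delta_r2"], "delta_r2_p": dr2["p"],
        "delta_r2_ci_lo": dr2["ci"][0], "delta_r2_ci_hi": dr2["ci"][1],
        "top_decile_or_meta": top_meta["or"], "top_decile_or_disease": top_dis["or"],
    }


def predict_risk(model, cohort, individuals, score: pd.Series | None) -> np.ndarray:
    """Apply a fitted risk model's coefficients to new individuals."""
    from .gwas import covariate_design

    cov = cohort.covariates.loc[individuals]
    C = covariate_design(cov)
    if score is not None:
        design = np.column_stack([score.reindex(individuals).to_numpy(), C])
    else:
        design = C
    eta = design @ model.coefficients.to_numpy()
    return 1.0 / (1.0 + np.exp(-eta))


def cumulative_incidence_by_group(cohort, disease_id: str, scores: pd.Series,
                                  top_fraction: float = 0.10) -> pd.DataFrame:
    """Top-decile vs rest cumulative incidence over age in the validation set.

    Case onset is taken as the recruitment age (diagnosis observed by then);
    controls are censored at their recruitment age.
    """
    val_ids = cohort.individuals[cohort.set_mask(VALIDATION)]
    s = scores.reindex(val_ids).to_numpy()
    y = cohort.diseases.loc[val_ids, disease_id].to_numpy(dtype=int)
    age = cohort.covariates.loc[val_ids, "age"].to_numpy(dtype=float)
    n_top = max(int(round(len(s) * top_fraction)), 1)
    order = np.argsort(-s, kind="stable")
    group = np.full(len(s), "remaining 90%", dtype=object)
    group[order[:n_top]] = "top 10%"
    return cumulative_incidence(age, group, y, censor_age=age)


def run_pipeline(config_path: str | Path, out_dir: str | Path) -> RunManifest:
    """Validate the config and execute every stage in dependency order."""
    config = validate_config(config_path)
    return PipelineRun(config, out_dir).run()
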