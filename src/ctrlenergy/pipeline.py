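"""End-to-end pipeline: simulate -> energy -> nulls -> GAMs -> prediction -> mediation.

A single structured-text (YAML) config drives every stage; per-stage seeds are
derived from the global seed by fixed offsets so repeated runs are
byte-identical.  Each stage emits a tab-separated table into the output
directory and the run log records versions, seeds, parameters and wall time.
"""

from __future__ import annotations

import logging
import sys
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import (
    FP_SYSTEM,
    Cohort,
    SyntheticCohortSpec,
    generate_cohort,
    read_cohort,
    write_cohort,
)
from .control import build_state, cohort_energy
from .errors import CtrlEnergyError
from .nulls import NullEnsemble, real_vs_null_energy_test
from .prediction import PredictionConfig, nested_prediction
from .stats import (
    DEFAULT_COVARIATES,
    fit_age_gam_table,
    fit_cognition_gam_table,
    mediation_bootstrap,
)

logger = logging.getLogger(__name__)

SEED_OFFSETS = {"cohort": 0, "nulls": 1009, "prediction": 2003, "mediation": 3001}

COHORT_KEYS = {
    "n_subjects",
    "n_nodes",
    "age_effect_gamma",
    "within_weight_mean",
    "between_weight_mean",
    "weight_noise_sd",
    "latent_loading_a",
    "ef_loading_b",
    "ef_age_loading_f",
    "cingulate_loading_c",
    "motion_age_r",
}


@dataclass
class PipelineConfig:
    seed: int = 1
    output_dir: str = "ctrlenergy_out"
    cohort: dict = dc_field(default_factory=dict)
    cohort_dir: str | None = None  # read an existing cohort instead of simulating
    control: dict = dc_field(default_factory=dict)
    nulls: dict = dc_field(default_factory=dict)
    gam: dict = dc_field(default_factory=dict)
    prediction: dict = dc_field(default_factory=dict)
    mediation: dict = dc_field(default_factory=dict)


def validate_config(path: str | Path) -> tuple[PipelineConfig | None, list[str], list[str]]:
    """Parse and validate a YAML config; returns (config, errors, warnings).

    All problems are collected and reported at once rather than fail-fast;
    unknown keys produce warnings, type/value problems produce errors.
    """
    errors: list[str] = []
    warnings: list[str] = []
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known_sections = {
        "seed",
        "output_dir",
        "cohort",
        "cohort_dir",
        "control",
        "nulls",
        "gam",
        "prediction",
        "mediation",
    }
    for key in raw:
        if key not in known_sections:
            warnings.append(f"unknown top-level key {key!r} ignored")
    if "cohort" not in raw and "cohort_dir" not in raw:
        errors.append("missing section 'cohort' (or 'cohort_dir')")
    for key in raw.get("cohort", {}) or {}:
        if key not in COHORT_KEYS and key != "seed":
            warnings.append(f"unknown cohort key {key!r} ignored")
    control = raw.get("control", {}) or {}
    rho = control.get("rho", 1.0)
    if not isinstance(rho, (int, float)) or rho <= 0:
        errors.append("rho must be positive")
    dt = control.get("dt", 0.001)
    if not isinstance(dt, (int, float)) or dt <= 0:
        errors.append("dt must be positive")
    seed = raw.get("seed", 1)
    if not isinstance(seed, int):
        errors.append("seed must be an integer")
    for section in ("control", "nulls", "gam", "prediction", "mediation"):
        if section in raw and not isinstance(raw[section], dict):
            errors.append(f"section {section!r} must be a mapping")
    if raw.get("cohort_dir") and not Path(raw["cohort_dir"]).exists():
        errors.append(f"cohort_dir does not exist: {raw['cohort_dir']}")
    if isinstance(control, dict) and control.get("target_vector"):
        if not Path(control["target_vector"]).exists():
            errors.append(f"target_vector file not found: {control['target_vector']}")
    if errors:
        return None, errors, warnings
    cfg = PipelineConfig(
        seed=seed,
        output_dir=raw.get("output_dir", "ctrlenergy_out"),
        cohort={k: v for k, v in (raw.get("cohort", {}) or {}).items() if k in COHORT_KEYS},
        cohort_dir=raw.get("cohort_dir"),
        control=control,
        nulls=raw.get("nulls", {}) or {},
        gam=raw.get("gam", {}) or {},
        prediction=raw.get("prediction", {}) or {},
        mediation=raw.get("mediation", {}) or {},
    )
    return cfg, errors, warnings


def _setup_logging(out_dir: Path) -> None:
    root = logging.getLogger("ctrlenergy")
    root.setLevel(logging.INFO)
    for old in list(root.handlers):
        root.removeHandler(old)
        old.close()
    fmt = logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
    for handler in (logging.FileHandler(out_dir / "run.log"), logging.StreamHandler(sys.stderr)):
        handler.setFormatter(fmt)
        root.addHandler(handler)


def _stage_simulate(cfg: PipelineConfig, out: Path) -> Cohort:
    if cfg.cohort_dir:
        logger.info("reading cohort from %s", cfg.cohort_dir)
        return read_cohort(cfg.cohort_dir)
    spec = SyntheticCohortSpec(seed=cfg.seed + SEED_OFFSETS["cohort"], **cfg.cohort)
    cohort = generate_cohort(spec)
    write_cohort(cohort, out / "cohort")
    return cohort


def _stage_energy(cfg: PipelineConfig, cohort: Cohort, out: Path):
    c = cfg.control
    target_state = None
    if c.get("target_vector"):
        target_state = build_state(
            cohort.systems, "continuous_from_file", path=c["target_vector"]
        )
    res = cohort_energy(
        cohort.connectomes,
        cohort.phenotypes["subject_id"],
        cohort.systems,
        target_state=target_state,
        target_system=c.get("target_system", FP_SYSTEM),
        constrain=c.get("constrain", "fp"),
        rho=float(c.get("rho", 1.0)),
        horizon_T=float(c.get("horizon", 1.0)),
        dt=float(c.get("dt", 0.001)),
    )
    tidy = res.nodal.melt(id_vars="subject_id", var_name="node", value_name="energy")
    tidy.to_csv(out / "energy_nodal.tsv", sep="\t", index=False)
    res.summaries.to_csv(out / "energy_summary.tsv", sep="\t", index=False)
    return res


def _stage_nulls(cfg: PipelineConfig, cohort: Cohort, energy_res, out: Path) -> pd.DataFrame:
    n_null = int(cfg.nulls.get("n_null", 20))
    n_subj = int(cfg.nulls.get("n_subjects", min(50, cohort.n_subjects)))
    c = cfg.control
    rows = []
    rng = np.random.default_rng(cfg.seed + SEED_OFFSETS["nulls"])
    for i in range(n_subj):
        conn = cohort.connectomes[i]
        sid = cohort.phenotypes["subject_id"].iloc[i]
        ensemble = NullEnsemble(conn, n_null, int(rng.integers(2**31)))
        null_res = cohort_energy(
            ensemble.surrogates,
            [f"{sid}_null{j}" for j in range(n_null)],
            cohort.systems,
            target_system=c.get("target_system", FP_SYSTEM),
            constrain=c.get("constrain", "fp"),
            rho=float(c.get("rho", 1.0)),
            horizon_T=float(c.get("horizon", 1.0)),
            dt=float(c.get("dt", 0.001)),
        )
        rows.append(
            {
                "subject_id": sid,
                "real_energy": energy_res.summaries["whole_brain_energy"].iloc[i],
                "null_mean_energy": null_res.summaries["whole_brain_energy"].mean(),
                "min_strength_r": min(ensemble.strength_correlation),
            }
        )
    table = pd.DataFrame(rows)
    test = real_vs_null_energy_test(table["real_energy"], table["null_mean_energy"])
    for k, v in test.items():
        table[k] = v
    table.to_csv(out / "null_comparison.tsv", sep="\t", index=False)
    logger.info("null comparison: mean diff %.4g, p=%.3g", test["mean_difference"], test["p_value"])
    return table


def _stage_age_gam(cfg: PipelineConfig, cohort: Cohort, energy_res, out: Path) -> pd.DataFrame:
    covs = tuple(cfg.gam.get("covariates", DEFAULT_COVARIATES))
    pheno = cohort.phenotypes
    nodal = energy_res.nodal.drop(columns="subject_id")
    systems = cohort.systems
    sys_cols = {
        f"system_{lab}": nodal.to_numpy()[:, systems == lab].mean(axis=1)
        for lab in np.unique(systems)
    }
    features = pd.concat(
        [
            pd.DataFrame({"whole_brain": nodal.to_numpy().mean(axis=1), **sys_cols}),
            nodal,
        ],
        axis=1,
    )
    tables = []
    for scope, cols in (
        ("whole_brain", ["whole_brain"]),
        ("system", list(sys_cols)),
        ("node", list(nodal.columns)),
    ):
        t = fit_age_gam_table(features[cols], pheno, covariates=covs)
        t.insert(0, "scope", scope)
        tables.append(t)
    table = pd.concat(tables, ignore_index=True)
    table.to_csv(out / "age_gam.tsv", sep="\t", index=False)
    return table


def _stage_cognition_gam(cfg: PipelineConfig, cohort: Cohort, energy_res, out: Path) -> pd.DataFrame:
    covs = tuple(cfg.gam.get("covariates", DEFAULT_COVARIATES))
    nodal = energy_res.nodal.drop(columns="subject_id")
    table = fit_cognition_gam_table(nodal, cohort.phenotypes, covariates=covs)
    table.to_csv(out / "cognition_gam.tsv", sep="\t", index=False)
    return table


def _stage_prediction(cfg: PipelineConfig, cohort: Cohort, energy_res, out: Path):
    p = cfg.prediction
    config = PredictionConfig(
        split_mode=p.get("split_mode", "age_rank"),
        n_random_repeats=int(p.get("n_random_repeats", 100)),
        n_permutations=int(p.get("n_permutations", 1000)),
        seed=cfg.seed + SEED_OFFSETS["prediction"],
    )
    x = energy_res.nodal.drop(columns="subject_id").to_numpy()
    result = nested_prediction(
        x, cohort.phenotypes, config, run_permutations=bool(p.get("run_permutations", False))
    )
    pd.DataFrame(
        {
            "subject_id": cohort.phenotypes["subject_id"],
            "age": cohort.phenotypes["age"],
            "predicted_age": result.predictions,
        }
    ).to_csv(out / "prediction_predictions.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "fold": f.fold,
                "lambda_star": f.lambda_star,
                "r": f.r,
                "partial_r": f.partial_r,
                "mae": f.mae,
            }
            for f in result.fold_metrics
        ]
        + [
            {
                "fold": "mean",
                "lambda_star": result.lambda_full,
                "r": np.nan,
                "partial_r": result.mean_partial_r,
                "mae": result.mean_mae,
            }
        ]
    ).to_csv(out / "prediction_metrics.tsv", sep="\t", index=False)
    pd.DataFrame(
        {
            "node": energy_res.nodal.columns.drop("subject_id"),
            "weight": result.raw_weights,
            "haufe": result.haufe_weights,
        }
    ).to_csv(out / "prediction_weights.tsv", sep="\t", index=False)
    return result


def _stage_mediation(cfg: PipelineConfig, cohort: Cohort, energy_res, out: Path):
    spec_systems = np.asarray(cohort.systems)
    fp_nodes = np.flatnonzero(spec_systems == FP_SYSTEM)
    n_cing = int(cfg.mediation.get("n_cingulate", 2))
    cing = fp_nodes[:n_cing]
    nodal = energy_res.nodal.drop(columns="subject_id").to_numpy()
    m = nodal[:, cing].mean(axis=1)
    pheno = cohort.phenotypes
    covs = pheno[list(DEFAULT_COVARIATES)].to_numpy(dtype=float)
    res = mediation_bootstrap(
        pheno["age"].to_numpy(),
        m,
        pheno["ef_score"].to_numpy(),
        covariates=covs,
        n_boot=int(cfg.mediation.get("n_boot", 10000)),
        seed=cfg.seed + SEED_OFFSETS["mediation"],
    )
    pd.DataFrame(
        [
            {
                "mediator": "cingulate_energy",
                "path_a": res.path_a,
                "path_b": res.path_b,
                "path_c": res.path_c,
                "path_c_prime": res.path_c_prime,
                "indirect": res.indirect,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "p_value": res.p_value,
                "n_boot": res.n_boot,
            }
        ]
    ).to_csv(out / "mediation.tsv", sep="\t", index=False)
    return res


STAGES = (
    "simulate",
    "energy",
    "null-test",
    "age-gam",
    "cognition-gam",
    "predict-age",
    "mediate",
)


def run_pipeline(cfg: PipelineConfig, stages: tuple[str, ...] = STAGES) -> Path:
    """Run the requested stages in order; returns the output directory."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out)
    t0 = time.time()
    logger.info("ctrlenergy %s | seed=%d | stages=%s", __version__, cfg.seed, ",".join(stages))
    logger.info(
        "parameters: cohort=%s control=%s nulls=%s prediction=%s mediation=%s",
        cfg.cohort,
        cfg.control,
        cfg.nulls,
        cfg.prediction,
        cfg.mediation,
    )
    stage = "simulate"
    try:
        cohort = _stage_simulate(cfg, out)
        energy_res = None
        if set(stages) - {"simulate"}:
            stage = "energy"
            energy_res = _stage_energy(cfg, cohort, out)
        if "null-test" in stages:
            stage = "null-test"
            _stage_nulls(cfg, cohort, energy_res, out)
        if "age-gam" in stages:
            stage = "age-gam"
            _stage_age_gam(cfg, cohort, energy_res, out)
        if "cognition-gam" in stages:
            stage = "cognition-gam"
            _stage_cognition_gam(cfg, cohort, energy_res, out)
        if "predict-age" in stages:
            stage = "predict-age"
            _stage_prediction(cfg, cohort, energy_res, out)
        if "mediate" in stages:
            stage = "mediate"
            _stage_mediation(cfg, cohort, energy_res, out)
    except (CtrlEnergyError, RuntimeError, OSError) as exc:
        logger.error("stage %s failed: %s", stage, exc)
        raise CtrlEnergyError(f"stage {stage!r} failed: {exc}") from exc
    logger.info("pipeline finished in %.1f s", time.time() - t0)
    return out
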