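"""Pipeline orchestration: discovery, validation and reporting from one config.

Stages write plain TSV/JSON artifacts so any stage can be rerun standalone;
a single master seed deterministically derives every stage seed, and the
config (echoed verbatim, with its hash) accompanies every output directory.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import biosignature as bsig
from . import prediction
from .association import hpa_interaction_model, spearman_assoc
from .core import MethylationError
from .deconvolution import estimate_proportions, myeloid_fraction
from .simulate import MulticohortStudy, SimulationConfig, generate_multicohort_study

__all__ = ["PipelineConfig", "run_discovery", "run_validation", "write_report"]

log = logging.getLogger("ska2sig")


@dataclass
class PipelineConfig:
    simulation: dict = field(default_factory=dict)
    training_cohort: str = "train_blood"
    screen_orientation: str = "suicide_x_ska2m"
    p_cutoff: float = 0.005
    auc_percentile: float = 75.0
    auc_outcome: str = "suicide_attempt"
    validation_outcome: str = "suicidal_ideation"
    subset: str | None = None
    n_perm: int = 1000
    n_boot: int = 1000
    seed: int = 0
    output_dir: str = "ska2sig_output"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)

    def hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    def stage_seed(self, stage: str) -> int:
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2 ** 31)

    def build_study(self) -> MulticohortStudy:
        sim = dict(self.simulation)
        sim.setdefault("seed", self.stage_seed("simulate"))
        return generate_multicohort_study(SimulationConfig.from_dict(sim))


def _outdir(config: PipelineConfig) -> Path:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    return out


def run_discovery(config: PipelineConfig, study: MulticohortStudy | None = None):
    """Screen -> select -> AUC filter -> PCA train; writes every intermediate.

    Returns ``(model, reports)`` where reports holds the stage tables.
    Idempotent for a fixed config: the model JSON is byte-identical on
    reruns.
    """
    out = _outdir(config)
    if study is None:
        study = config.build_study()
    if "brain" not in study:
        raise MethylationError("discovery requires a 'brain' cohort")
    if config.training_cohort not in study:
        raise MethylationError(
            f"discovery requires training cohort {config.training_cohort!r}"
        )
    stage = "interaction_screen"
    try:
        screen = bsig.interaction_screen(study["brain"],
                                         orientation=config.screen_orientation)
        screen.write(out / "screen.tsv")
        log.info("screen: %d probes, %d defined", len(screen.table),
                 int(screen.table["defined"].sum()))

        stage = "select_candidates"
        candidates = bsig.select_candidates(screen, p_cutoff=config.p_cutoff)
        (out / "candidates.txt").write_text("\n".join(candidates) + "\n")
        log.info("candidates at P<%g: %d", config.p_cutoff, len(candidates))

        stage = "auc_filter"
        training = study[config.training_cohort]
        retained, auc_table = bsig.probewise_auc_filter(
            candidates, training, outcome=config.auc_outcome,
            percentile=config.auc_percentile,
        )
        auc_table.to_csv(out / "auc_filter.tsv", sep="\t", float_format="%.8g")
        log.info("retained above AUC percentile %g: %d probes",
                 config.auc_percentile, len(retained))

        stage = "train_pca"
        model = bsig.train_biosignature_pca(training, retained,
                                            cohort_name=config.training_cohort)
        model.to_json(out / "biosignature_model.json")
    except MethylationError as err:
        raise MethylationError(f"discovery failed at stage {stage!r}: {err}") from err
    reports = {"screen": screen, "candidates": candidates,
               "auc_table": auc_table, "retained": retained}
    return model, reports


def run_validation(config: PipelineConfig, model: bsig.BiosignatureModel,
                   study: MulticohortStudy | None = None) -> dict:
    """Project + evaluate every non-training cohort; association analyses.

    Produces per-cohort ROC results for the biosignature and myeloid state
    terms, driver-probe correlations across all peripheral cohorts, and
    Spearman/HPA associations where the phenotypes exist. Cohorts missing
    required phenotypes are skipped with a logged reason.
    """
    out = _outdir(config)
    if study is None:
        study = config.build_study()
    reference = getattr(study, "reference", None)
    results: dict = {"cohorts": {}, "skipped": {}, "config_hash": config.hash(),
                     "seed": config.seed, "n_perm": config.n_perm}
    peripheral = {n: c for n, c in study.items() if n != "brain"}
    eval_cohorts = {n: c for n, c in peripheral.items()
                    if n != config.training_cohort}

    for name, cohort in eval_cohorts.items():
        entry: dict = {}
        if config.validation_outcome not in cohort.samples.columns:
            results["skipped"][name] = f"no outcome {config.validation_outcome!r}"
            log.warning("skipping %s: no outcome %s", name,
                        config.validation_outcome)
            continue
        for term in ("biosignature", "myeloid"):
            if term == "myeloid" and reference is None:
                results["skipped"][f"{name}:{term}"] = "no cell reference"
                continue
            try:
                roc = prediction.evaluate_cohort(
                    cohort, term, biosignature_model=model,
                    reference=reference, outcome=config.validation_outcome,
                    subset=config.subset, n_perm=config.n_perm,
                    n_boot=config.n_boot,
                    seed=config.stage_seed(f"eval:{name}:{term}"),
                )
                entry[term] = roc
            except MethylationError as err:
                results["skipped"][f"{name}:{term}"] = str(err)
                log.warning("skipping %s/%s: %s", name, term, err)
        # associations on this cohort
        scores = bsig.project_biosignature(model, cohort)
        annotated = cohort.samples.assign(biosignature=scores)
        if reference is not None:
            myeloid = myeloid_fraction(estimate_proportions(cohort.beta, reference))
            entry["myeloid_spearman"] = spearman_assoc(scores, myeloid)
            for pheno in ("il6", "perceived_stress"):
                if pheno in annotated.columns:
                    entry[f"{pheno}_spearman"] = spearman_assoc(
                        scores, annotated[pheno])
        if {"ctq", "cortisol_auc_posttest"} <= set(annotated.columns):
            try:
                entry["hpa_trier"] = hpa_interaction_model(
                    annotated, "cortisol_auc_posttest")
            except MethylationError as err:
                results["skipped"][f"{name}:hpa"] = str(err)
                log.warning("skipping %s HPA model: %s", name, err)
        else:
            results["skipped"][f"{name}:hpa"] = "no CTQ / cortisol phenotypes"
            log.warning("skipping %s HPA model: missing phenotypes", name)
        results["cohorts"][name] = entry

    try:
        driver_table, consistent = bsig.driver_probe_correlations(
            model, peripheral)
        driver_table.to_csv(out / "driver_probes.tsv", sep="\t", index=False,
                            float_format="%.6g")
        results["driver_consistent"] = consistent
        results["driver_table"] = driver_table
    except MethylationError as err:
        results["skipped"]["driver_probes"] = str(err)
    return results


def _jsonify(obj):
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, prediction.RocResult):
        return _jsonify(obj.to_dict())
    if hasattr(obj, "to_dict"):
        return _jsonify(obj.to_dict())
    if isinstance(obj, pd.DataFrame):
        return {"n_rows": int(len(obj))}
    if isinstance(obj, pd.Series):
        return {k: _jsonify(v) for k, v in obj.to_dict().items()}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if hasattr(obj, "__dict__") and not isinstance(obj, (str, bytes)):
        return _jsonify(vars(obj))
    return obj


def write_report(results: dict, config: PipelineConfig, path=None) -> Path:
    """Machine-readable JSON report plus a markdown summary."""
    out = Path(path) if path is not None else _outdir(config)
    out.mkdir(parents=True, exist_ok=True)
    payload = _jsonify(results)
    payload["config_hash"] = config.hash()
    payload["seed"] = config.seed
    payload["n_perm"] = config.n_perm
    with open(out / "report.json", "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True, default=str)

    lines = ["# Validation report", "",
             f"- config hash: `{config.hash()}`",
             f"- master seed: {config.seed}",
             f"- permutations: {config.n_perm}", ""]
    cohorts = results.get("cohorts", {})
    if not cohorts:
        lines.append("No stages produced results.")
    else:
        lines += ["| cohort | term | AUC | 95% CI | Monte Carlo P |",
                  "|---|---|---|---|---|"]
        for name, entry in cohorts.items():
            for term in ("biosignature", "myeloid"):
                roc = entry.get(term)
                if roc is None:
                    continue
                lines.append(
                    f"| {name} | {term} | {roc.auc:.3f} | "
                    f"{roc.ci_lower:.2f}-{roc.ci_upper:.2f} | "
                    f"{roc.monte_carlo_p:.4g} |")
    skipped = results.get("skipped", {})
    if skipped:
        lines += ["", "Skipped:", ""]
        lines += [f"- {k}: {v}" for k, v in skipped.items()]
    (out / "report.md").write_text("\n".join(lines) + "\n")
    return out
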