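"""End-to-end orchestration: simulate, process, discover, train, evaluate.

The pipeline reproduces the two-stage design of a prognostic biomarker
study.  All model selection — the biomarker panel, SVM training,
hyper-parameters, score thresholds and composite weights — happens on
the discovery split only; the validation split is scored and evaluated
blinded, with no re-fitting, and the manifest asserts that the two
splits share no sample ids.
"""

from __future__ import annotations

import hashlib
import json
import time as _time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

import acspredict
from acspredict import classifier, discovery, evaluation, io, peptidome, synth
from acspredict.errors import AcsPredictError

__all__ = ["RunConfig", "RunManifest", "process_profiles", "run_pipeline"]


@dataclass
class RunConfig:
    """Parameters of one reproducible pipeline run."""

    out_dir: str = "acspredict_run"
    seed: int = 0
    # synthetic-cohort parameters (None field -> SimConfig default)
    sim: dict = field(default_factory=dict)
    # stage parameters
    split_ratio: float = 2 / 3
    match_age_window: float = 5.0
    freq_min: float = 0.70
    alpha: float = 0.05
    #: pre-specified panel peptide ids; skips the discovery stage
    panel_ids: list | None = None
    svm_C: float = classifier.DEFAULT_C
    svm_gamma: float = classifier.DEFAULT_GAMMA
    tune_grid: bool = False
    composite_weights: tuple[float, float, float] = (0.2, 2.6, 0.15)
    composite_threshold: float | None = None   # None -> Youden on discovery
    fit_composite: bool = True
    nri_categories: tuple[float, float] = (0.10, 0.20)
    normalization: str = "regression"
    mass_tol_ppm: float = 50.0
    write_outputs: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


@dataclass
class RunManifest:
    """Provenance record of one run (checksums, timings, warnings)."""

    seed: int
    package_version: str
    config_hash: str
    stages: dict = field(default_factory=dict)
    checksums: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    leakage_overlap: int = -1

    def as_dict(self) -> dict:
        return asdict(self)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_hash(config: RunConfig) -> str:
    text = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def process_profiles(profiles, catalog: pd.DataFrame,
                     normalization: str = "regression",
                     mass_tol_ppm: float = 50.0,
                     calibrate: bool = True
                     ) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Calibrate, normalize and cluster raw profiles onto the catalogue.

    Returns ``(matrix, match report, warnings)``.
    """
    warnings: list[str] = []
    processed = []
    for prof in profiles:
        p = prof
        if calibrate:
            p = peptidome.calibrate_migration_time(p, catalog,
                                                   mass_tol_ppm=mass_tol_ppm)
            if p.flags.get("calibration_warning"):
                warnings.append(
                    f"{p.sample_id}: calibration residual "
                    f"{p.flags['calibration_max_residual_min']:.3f} min "
                    "above bound")
        p = peptidome.normalize_amplitudes(p, catalog, method=normalization,
                                           mass_tol_ppm=mass_tol_ppm)
        processed.append(p)
    matrix, report = peptidome.match_to_catalog(processed, catalog,
                                                mass_tol_ppm=mass_tol_ppm)
    for sid in report.index[report["empty_profile"]]:
        warnings.append(f"{sid}: empty profile, matrix row of zeros")
    return matrix, report, warnings


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full study and return its results.

    Returns a dict with the manifest, the trained model, panels,
    per-split scores and the validation evaluation report.  When
    ``config.write_outputs`` is set, TSV/JSON artefacts and the
    manifest are written under ``config.out_dir``.
    """
    t_start = _time.time()
    manifest = RunManifest(seed=config.seed,
                           package_version=acspredict.__version__,
                           config_hash=_config_hash(config))
    out_dir = Path(config.out_dir)
    results: dict = {"manifest": manifest}

    def stage(name):
        manifest.stages[name] = {"started_s": round(_time.time() - t_start, 3)}
        return _time.time()

    def done(name, t0):
        manifest.stages[name]["elapsed_s"] = round(_time.time() - t0, 3)

    try:
        # -- simulate -----------------------------------------------------
        t0 = stage("simulate")
        sim_cfg = synth.SimConfig(**{"seed": config.seed, **config.sim})
        catalog = synth.generate_catalog(sim_cfg)
        cohort, truth = synth.generate_cohort(sim_cfg, catalog)
        profiles, planted, dilution = synth.generate_profiles(
            sim_cfg, catalog, cohort, mass_tol_ppm=config.mass_tol_ppm)
        done("simulate", t0)

        # -- process ------------------------------------------------------
        t0 = stage("process")
        matrix, match_report, warns = process_profiles(
            profiles, catalog, normalization=config.normalization,
            mass_tol_ppm=config.mass_tol_ppm)
        manifest.warnings += [f"process: {w}" for w in warns]
        done("process", t0)

        # -- split --------------------------------------------------------
        t0 = stage("split")
        split = synth.split_discovery_validation(
            cohort, ratio=config.split_ratio,
            match_age_window=config.match_age_window, seed=config.seed)
        disc_ids = split.discovery_ids
        val_ids = split.validation_ids
        overlap = len(set(disc_ids) & set(val_ids))
        manifest.leakage_overlap = overlap
        if overlap:
            raise AcsPredictError(
                f"{overlap} sample ids shared between discovery and "
                "validation splits")
        if split.unmatched_cases:
            manifest.warnings.append(
                f"split: {len(split.unmatched_cases)} cases unmatched")
        done("split", t0)

        # -- discover -----------------------------------------------------
        t0 = stage("discover")
        labels = cohort["is_case"]
        if config.panel_ids is not None:
            sel = pd.DataFrame(index=pd.Index(sorted(config.panel_ids),
                                              name="peptide_id"))
            panel = discovery.BiomarkerPanel(
                records=sel, selected=sel, freq_min=config.freq_min,
                alpha=config.alpha)
        else:
            candidates = catalog.index[~catalog["is_housekeeping"]]
            panel = discovery.discover_panel(
                matrix.loc[disc_ids], labels.loc[disc_ids],
                freq_min=config.freq_min, alpha=config.alpha,
                candidate_ids=candidates)
        if len(panel) == 0:
            raise AcsPredictError("discovery selected no biomarkers")
        done("discover", t0)

        # -- train --------------------------------------------------------
        t0 = stage("train")
        feats_disc = classifier.feature_transform(matrix.loc[disc_ids],
                                                  panel.peptide_ids)
        C, gamma = config.svm_C, config.svm_gamma
        if config.tune_grid:
            C, gamma, _ = classifier.tune_hyperparameters(
                feats_disc, labels.loc[disc_ids],
                C_grid=[10 ** k for k in range(0, 5)],
                gamma_grid=[10 ** k for k in range(-5, -1)],
                seed=config.seed)
        model = classifier.train_pattern(feats_disc, labels.loc[disc_ids],
                                         C=C, gamma=gamma, seed=config.seed)
        done("train", t0)

        # -- score --------------------------------------------------------
        t0 = stage("score")
        feats_val = classifier.feature_transform(matrix.loc[val_ids],
                                                 panel.peptide_ids)
        scores_disc = classifier.score_samples(model, feats_disc)
        scores_val = classifier.score_samples(model, feats_val)
        pattern_cut = evaluation.youden_threshold(
            scores_disc, labels.loc[disc_ids]).threshold
        done("score", t0)

        # -- composite ----------------------------------------------------
        t0 = stage("composite")
        if config.fit_composite:
            weights = classifier.fit_composite_weights(
                scores_disc, cohort.loc[disc_ids, "cad238"],
                cohort.loc[disc_ids, "age"], labels.loc[disc_ids])
            manifest.warnings += [f"composite: {w}" for w in weights.warnings]
        else:
            w = config.composite_weights
            weights = classifier.CompositeWeights(*w)
        comp_disc = pd.Series(
            classifier.composite_score(scores_disc,
                                       cohort.loc[disc_ids, "cad238"],
                                       cohort.loc[disc_ids, "age"], weights),
            index=scores_disc.index)
        comp_val = pd.Series(
            classifier.composite_score(scores_val,
                                       cohort.loc[val_ids, "cad238"],
                                       cohort.loc[val_ids, "age"], weights),
            index=scores_val.index)
        if config.composite_threshold is None:
            comp_cut = evaluation.youden_threshold(
                comp_disc, labels.loc[disc_ids]).threshold
        else:
            comp_cut = config.composite_threshold
        done("composite", t0)

        # -- evaluate (validation, blinded) -------------------------------
        t0 = stage("evaluate")
        report = evaluate_split(
            cohort.loc[val_ids], scores_val, comp_val,
            pattern_cut, comp_cut, nri_categories=config.nri_categories)
        manifest.warnings += [f"evaluate: {w}" for w in report.pop("warnings")]
        done("evaluate", t0)

        results.update({
            "catalog": catalog, "cohort": cohort, "truth": truth,
            "matrix": matrix, "planted_matrix": planted,
            "match_report": match_report, "split": split, "panel": panel,
            "model": model, "weights": weights,
            "scores_discovery": scores_disc, "scores_validation": scores_val,
            "composite_discovery": comp_disc, "composite_validation": comp_val,
            "pattern_threshold": pattern_cut,
            "composite_threshold": comp_cut,
            "validation_report": report,
        })
    except AcsPredictError:
        if config.write_outputs:
            out_dir.mkdir(parents=True, exist_ok=True)
            io.write_json_report(manifest.as_dict(),
                                 out_dir / "manifest.json")
        raise

    if config.write_outputs:
        out_dir.mkdir(parents=True, exist_ok=True)
        io.write_bundle(out_dir, cohort, matrix, catalog, truth)
        panel.selected.to_csv(out_dir / "panel.tsv", sep="\t")
        (out_dir / "model.json").write_text(model.to_json())
        pd.DataFrame({
            "score": pd.concat([scores_disc, scores_val]),
            "composite": pd.concat([comp_disc, comp_val]),
            "split": (["discovery"] * len(scores_disc)
                      + ["validation"] * len(scores_val)),
        }).to_csv(out_dir / "scores.tsv", sep="\t", index_label="sample_id")
        io.write_json_report(_jsonable(report), out_dir / "evaluation.json")
        for name in ("cohort.tsv", "matrix.tsv", "catalog.tsv", "panel.tsv",
                     "model.json", "scores.tsv", "evaluation.json"):
            manifest.checksums[name] = _sha256(out_dir / name)
        io.write_json_report(manifest.as_dict(), out_dir / "manifest.json")
    return results


def evaluate_split(cohort: pd.DataFrame, pattern_scores: pd.Series,
                   composite_scores: pd.Series, pattern_threshold: float,
                   composite_threshold: float,
                   nri_categories=(0.10, 0.20)) -> dict:
    """Blinded evaluation of one split at pre-specified thresholds."""
    warns: list[str] = []
    y = cohort["is_case"]
    t = cohort["time_years"]
    e = cohort["event"]

    auc_pattern, roc_pattern = evaluation.roc_auc(pattern_scores, y)
    auc_comp, _ = evaluation.roc_auc(composite_scores, y)
    auc_fcvrs, _ = evaluation.roc_auc(cohort["fcvrs"], y)

    diag_pattern = evaluation.diagnostic_summary(pattern_scores, y,
                                                 pattern_threshold)
    diag_comp = evaluation.diagnostic_summary(composite_scores, y,
                                              composite_threshold)

    c_pattern = evaluation.harrell_c(pattern_scores, t, e)
    c_comp = evaluation.harrell_c(composite_scores, t, e)
    c_fcvrs = evaluation.harrell_c(cohort["fcvrs"], t, e)

    high = (pattern_scores > pattern_threshold).astype(int)
    km = evaluation.km_estimate(t, e, high.map({0: "low", 1: "high"}))

    surv = pd.DataFrame({
        "time": t, "event": e, "score_high": high,
        "age": cohort["age"], "egfr": cohort["egfr"],
        "diabetes": cohort["diabetes"],
        "hypertension": cohort["hypertension"],
        "history_cvd": cohort["history_cvd"],
    })
    try:
        hr_unadj = evaluation.cox_fit(surv, "time", "event", ["score_high"])
        retained, hr_adj, trace = evaluation.stepwise_cox(
            surv, "time", "event",
            ["age", "egfr", "diabetes", "hypertension", "history_cvd"],
            forced=["score_high"])
    except evaluation.EvaluationError as exc:
        warns.append(f"cox: {exc}")
        hr_unadj = hr_adj = None
        retained, trace = [], []

    models = evaluation.nested_logistic_models(
        y, cohort["centre"], cohort["fcvrs"],
        pattern_scores=pattern_scores, composite_scores=composite_scores)
    warns += models["warnings"]
    reclass_pattern = evaluation.idi_nri(models["p1"], models["p2"], y,
                                         categories=nri_categories)
    reclass_comp = evaluation.idi_nri(models["p1"], models["p3"], y,
                                      categories=nri_categories)

    return {
        "n": int(len(cohort)),
        "n_cases": int(y.sum()),
        "auc": {"pattern": auc_pattern, "composite": auc_comp,
                "fcvrs": auc_fcvrs},
        "roc_curve_pattern": roc_pattern,
        "diagnostics": {"pattern": diag_pattern.as_dict(),
                        "composite": diag_comp.as_dict()},
        "harrell_c": {
            "pattern": {"c": c_pattern[0], "ci": list(c_pattern[1])},
            "composite": {"c": c_comp[0], "ci": list(c_comp[1])},
            "fcvrs": {"c": c_fcvrs[0], "ci": list(c_fcvrs[1])},
        },
        "km": km,
        "cox": {
            "unadjusted": hr_unadj,
            "adjusted": hr_adj,
            "retained": retained,
            "removal_trace": trace,
        },
        "reclassification": {
            "pattern_vs_base": reclass_pattern.as_dict(),
            "composite_vs_base": reclass_comp.as_dict(),
        },
        "warnings": warns,
    }


def _jsonable(report: dict) -> dict:
    out = {}
    for k, v in report.items():
        if isinstance(v, pd.DataFrame):
            out[k] = v.to_dict(orient="list")
        elif isinstance(v, dict):
            out[k] = _jsonable(v)
        elif isinstance(v, (np.integer, np.floating)):
            out[k] = v.item()
        else:
            out[k] = v
    return out
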