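"""End-to-end pipeline: synth -> cohort -> featurize -> train -> evaluate
-> alert-burden sweep.

Each stage writes its outputs plus a manifest (parameters, seed, input
checksums) into the run directory, so any stage can be re-run in
isolation and a finished directory is reconstructible from its manifests.
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

from . import burden as bd
from . import cohort as ch
from . import ensemble as es
from . import features as ft
from . import io as cio
from . import metrics as mt
from . import synth as sy

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Parameters binding the pipeline stages together."""

    seed: int = 0
    # cohort constants
    merge_gap_hours: float = ch.MERGE_GAP_HOURS
    uei_persist_hours: float = ch.UEI_PERSIST_HOURS
    dedup_lockout_hours: float = ch.DEDUP_LOCKOUT_HOURS
    early_exclude_hours: float = ch.EARLY_EXCLUDE_HOURS
    late_exclude_hours: float = ch.LATE_EXCLUDE_HOURS
    horizons: tuple = ch.HORIZONS
    split_boundary: str | None = None   # ISO date; None = 60% quantile
    # learner
    learner_family: str = "xgboost"
    grid: dict | None = None
    cv_folds: int = 10
    parsimonious_k: int | None = None
    # alert policy
    interval_hours: float = 1.0
    refractory_hours: float = 12.0
    censor_hours: float = 24.0
    window_hours: float = 24.0
    sweep_thresholds: tuple = tuple(np.round(np.linspace(0.02, 0.98, 25), 3))
    detection_target: float = 0.80
    # synthetic generation (used when no input CSVs are given)
    synth: sy.SyntheticConfig = field(default_factory=sy.SyntheticConfig)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        synth_doc = doc.pop("synth", {})
        cfg = cls(**doc)
        cfg.synth = sy.SyntheticConfig(**synth_doc)
        return cfg


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _write_manifest(out_dir: Path, stage: str, params: dict,
                    inputs: list[Path], outputs: list[Path]) -> None:
    manifest = {
        "stage": stage,
        "params": params,
        "inputs": {p.name: _checksum(p) for p in inputs if p.exists()},
        "outputs": {p.name: _checksum(p) for p in outputs if p.exists()},
    }
    cio.write_json(manifest, out_dir / f"manifest_{stage}.json")


def build_cohort(admissions_raw: pd.DataFrame, events_raw: pd.DataFrame,
                 config: RunConfig):
    """Merge, filter, confirm, deduplicate, split, and draw samples."""
    merged = ch.merge_admissions(admissions_raw, config.merge_gap_hours)
    cohort, flow = ch.apply_inclusion(merged)
    events_in = events_raw[
        events_raw["admission_id"].isin(set(cohort["admission_id"]))]
    confirmed = ch.confirm_events(events_in, cohort,
                                  config.uei_persist_hours)
    deduped = ch.deduplicate_events(confirmed, config.dedup_lockout_hours)
    boundary = config.split_boundary
    if boundary is None:
        boundary = pd.to_datetime(
            cohort["picu_start"]).quantile(0.6).normalize()
    split = ch.temporal_split(cohort, boundary)
    samples = ch.build_training_samples(
        cohort, deduped, config.horizons, config.seed,
        config.early_exclude_hours, config.late_exclude_hours)
    flow["n_confirmed_cde"] = int(len(deduped))
    flow["n_development"] = len(split.development)
    flow["n_validation"] = len(split.validation)
    flow["n_excluded_straddlers"] = len(split.excluded)
    return cohort, deduped, split, samples, flow


def predict_risk_series(model: es.EnsembleModel, admissions: pd.DataFrame,
                        observations: pd.DataFrame, spec: ft.FeatureSpec,
                        interval_hours: float) -> pd.DataFrame:
    """Ensemble probabilities on each admission's full prediction grid."""
    rows = []
    for _, r in admissions.iterrows():
        grid = bd.prediction_grid(r["picu_start"], r["picu_end"],
                                  interval_hours)
        rows.append(pd.DataFrame({"admission_id": r["admission_id"],
                                  "snapshot_time": grid}))
    snapshots = pd.concat(rows, ignore_index=True)
    X, _, _ = ft.build_matrix(snapshots, observations, admissions, spec)
    probs = model.predict_proba(X)
    return pd.DataFrame({"admission_id": snapshots["admission_id"],
                         "time": snapshots["snapshot_time"],
                         "probability": probs})


def evaluate_split(model: es.EnsembleModel, samples: pd.DataFrame,
                   X: np.ndarray, y: np.ndarray, horizons,
                   bootstrap: int = 200, seed: int = 0) -> dict:
    """AUROC / AUPRC with CIs per horizon subset and for the pooled ensemble."""
    out = {}
    scores = model.predict_proba(X)
    for horizon, mask in es.horizon_training_sets(samples, X, y, horizons):
        s, t = scores[mask], y[mask]
        if len(np.unique(t)) < 2:
            out[f"h{horizon}"] = None
            continue
        entry = {"auroc": mt.auroc(s, t), "auprc": mt.auprc(s, t),
                 "n": int(mask.sum()), "n_pos": int(t.sum())}
        entry["auroc_ci"] = mt.bootstrap_ci(mt.auroc, s, t, B=bootstrap,
                                            seed=seed)
        entry["auprc_ci"] = mt.bootstrap_ci(mt.auprc, s, t, B=bootstrap,
                                            seed=seed)
        out[f"h{horizon}"] = entry
    if len(np.unique(y)) == 2:
        out["pooled"] = {"auroc": mt.auroc(scores, y),
                         "auprc": mt.auprc(scores, y),
                         "n": int(len(y)), "n_pos": int(y.sum())}
    return out


def run_pipeline(config: RunConfig, out_dir,
                 admissions_path=None, events_path=None,
                 observations_path=None) -> dict:
    """Execute all stages; returns the evaluation + burden summary.

    With no input paths the bundled synthetic generator supplies the
    cohort (stage "synth"); otherwise the CSVs are validated and read.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    # --- stage: inputs -----------------------------------------------------
    if admissions_path is None:
        data = sy.generate_cohort(config.synth)
        admissions_raw, events_raw = data.admissions, data.events
        observations = data.observations
        cio.write_table(admissions_raw, out_dir / "admissions.csv")
        cio.write_table(events_raw, out_dir / "events.csv")
        cio.write_table(observations, out_dir / "observations.csv")
        cio.write_json(data.ground_truth, out_dir / "ground_truth.json")
        _write_manifest(out_dir, "synth", asdict(config.synth), [],
                        [out_dir / f for f in ("admissions.csv",
                                               "events.csv",
                                               "observations.csv")])
    else:
        issues = cio.validate_tables(admissions_path, events_path,
                                     observations_path)
        if issues:
            raise cio.TableValidationError(
                "input validation failed:\n" + "\n".join(issues[:20]))
        admissions_raw = cio.read_admissions(admissions_path)
        events_raw = cio.read_events(events_path)
        observations = cio.read_observations(observations_path)

    # --- stage: cohort ------------------------------------------------------
    cohort, cde, split, samples, flow = build_cohort(
        admissions_raw, events_raw, config)
    cio.write_table(cohort, out_dir / "cohort.csv")
    cio.write_table(cde, out_dir / "cde_confirmed.csv")
    cio.write_table(samples, out_dir / "samples.csv")
    cio.write_json(flow, out_dir / "flowchart.json")
    log.info("cohort: %s", flow)
    _write_manifest(out_dir, "cohort",
                    {"seed": config.seed,
                     "boundary": str(split.boundary_date)},
                    [out_dir / "admissions.csv"],
                    [out_dir / "cohort.csv", out_dir / "samples.csv"])

    # --- stage: featurize ---------------------------------------------------
    spec = ft.FeatureSpec.from_observations(observations)
    dev_mask = samples["admission_id"].isin(split.development).to_numpy()
    val_mask = samples["admission_id"].isin(split.validation).to_numpy()
    X, y, names = ft.build_matrix(samples, observations, cohort, spec)
    cio.write_json({"feature_names": names}, out_dir / "features_schema.json")
    patient_of = cohort.set_index("admission_id")["patient_id"]
    groups = patient_of.reindex(samples["admission_id"]).to_numpy()

    # --- stage: train -------------------------------------------------------
    spec_l = es.LearnerSpec(family=config.learner_family, grid=config.grid,
                            cv_folds=config.cv_folds)
    subsets = None
    if config.parsimonious_k:
        _, subsets = es.select_parsimonious(
            samples[dev_mask].reset_index(drop=True), X[dev_mask],
            y[dev_mask], names, config.parsimonious_k, config.horizons)
    model = es.train_ensemble(
        samples[dev_mask].reset_index(drop=True), X[dev_mask], y[dev_mask],
        groups[dev_mask], spec_l, config.seed, names, config.horizons,
        feature_subsets=subsets)
    (out_dir / "model.json").write_text(model.to_json())
    cio.write_json({f"h{m.horizon}": m.cv_scores for m in model.members},
                   out_dir / "cv_report.json")
    _write_manifest(out_dir, "train",
                    {"family": config.learner_family, "seed": config.seed},
                    [out_dir / "samples.csv"], [out_dir / "model.json"])

    # --- stage: evaluate ----------------------------------------------------
    results = {"flow": flow}
    if val_mask.any() and len(np.unique(y[val_mask])) == 2:
        results["validation"] = evaluate_split(
            model, samples[val_mask].reset_index(drop=True), X[val_mask],
            y[val_mask], config.horizons, seed=config.seed)
    cio.write_json(results.get("validation", {}), out_dir / "metrics.json")

    # --- stage: burden sweep ------------------------------------------------
    val_adm = cohort[cohort["admission_id"].isin(split.validation)]
    if len(val_adm):
        policy = bd.AlertPolicy(interval_hours=config.interval_hours,
                                refractory_hours=config.refractory_hours,
                                censor_hours=config.censor_hours,
                                window_hours=config.window_hours)
        series = predict_risk_series(
            model, val_adm,
            observations[observations["admission_id"].isin(
                set(val_adm["admission_id"]))],
            spec, config.interval_hours)
        cio.write_table(series, out_dir / "scores.csv")
        val_events = cde[cde["admission_id"].isin(split.validation)]
        curve = bd.sweep_thresholds(series, val_events, val_adm, policy,
                                    config.sweep_thresholds)
        curve.as_frame().to_csv(out_dir / "sweep.csv", index=False)
        results["sweep"] = curve.as_frame().to_dict(orient="records")
        try:
            thr, rep = bd.threshold_for_detection(curve,
                                                  config.detection_target)
            results["burden_at_target"] = rep.to_dict()
            cio.write_json(rep.to_dict(), out_dir / "burden.json")
        except bd.UnreachableDetectionError:
            log.warning("detection target %.2f unreachable",
                        config.detection_target)
        _write_manifest(out_dir, "burden",
                        {"policy": asdict(policy)},
                        [out_dir / "scores.csv"], [out_dir / "sweep.csv"])
    return results
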