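"""End-to-end pipeline: simulate -> extract -> compare -> train -> predict.

Every stage writes plain-text artifacts (TSV/JSON) stamped with the
configuration hash and seed; EDF is the only binary format touched.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .connectivity import extract_sync_features
from .edf import read_edf, write_edf
from .model import ClinicalRecord, assemble_matrix, fit_final_and_predict, nested_cv
from .recording import default_montage_for, sync_feature_names
from .simulate import CohortSpec, CouplingSpec, SeizureDiary, generate_cohort
from .stats import compare_clinical_by_group, compare_sync_all_metrics, label_responder

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage


def _stamp(config: PipelineConfig) -> dict:
    return {"config_hash": config.config_hash(), "seed": config.seed, "schema": 1}


def simulate_stage(config: PipelineConfig, out_dir: Path) -> Path:
    """Generate a cohort, write per-subject EDFs and the manifest TSV."""
    sc = config.simulate
    coupling = dict(band_name=sc.band_name, phase_lag=sc.phase_lag,
                    mixing_coefficient=sc.mixing_coefficient, noise_sd=sc.noise_sd)
    spec = CohortSpec(
        n_subjects=sc.n_subjects + sc.n_validation,
        responder_fraction=sc.responder_fraction,
        responder_coupling=CouplingSpec(coupling_strength=sc.responder_coupling, **coupling),
        nonresponder_coupling=CouplingSpec(coupling_strength=sc.nonresponder_coupling, **coupling),
        duration_s=sc.duration_s, fs=sc.fs, n_channels=sc.n_channels,
        seed=config.seed,
    )
    cohort = generate_cohort(spec)
    edf_dir = out_dir / "edf"
    edf_dir.mkdir(parents=True, exist_ok=True)
    # Random discovery/validation split, mirroring random selection of the
    # discovery cohort from all eligible subjects.
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xD15C]))
    split = np.array(["discovery"] * sc.n_subjects + ["validation"] * sc.n_validation)
    split = split[rng.permutation(len(split))]
    rows = []
    for subj, cohort_name in zip(cohort, split):
        edf_path = edf_dir / f"{subj.recording.subject_id}.edf"
        write_edf(subj.recording, edf_path)
        rows.append({
            "subject_id": subj.recording.subject_id,
            "edf_path": str(edf_path.relative_to(out_dir)),
            **subj.clinical.to_dict(),
            "baseline_freq": subj.diary.baseline_freq,
            "followup_freq": subj.diary.followup_freq,
            "true_label": subj.true_label,
            "cohort": cohort_name,
        })
    manifest = out_dir / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    (out_dir / "manifest.meta.json").write_text(json.dumps(_stamp(config)))
    return manifest


def extract_stage(config: PipelineConfig, out_dir: Path, manifest_path: Path) -> Path:
    """Read each subject's EDF and emit the 18-column sync feature table."""
    manifest = pd.read_csv(manifest_path, sep="\t")
    rows = []
    for _, row in manifest.iterrows():
        rec = read_edf(out_dir / row["edf_path"])
        montage = default_montage_for(rec.channel_labels)
        vec = extract_sync_features(
            rec, montage_pairs=montage, config=config.preprocess,
            trim_fraction=config.connectivity.trim_fraction,
            hilbert_mode=config.connectivity.hilbert_mode,
        )
        rows.append({"subject_id": row["subject_id"], **vec.values})
    table = out_dir / "sync_features.tsv"
    pd.DataFrame(rows).to_csv(table, sep="\t", index=False)
    sidecar = {**_stamp(config),
               "trim_fraction": config.connectivity.trim_fraction,
               "hilbert_mode": config.connectivity.hilbert_mode,
               "montage": "per-subject default (longitudinal when available)"}
    (out_dir / "sync_features.meta.json").write_text(json.dumps(sidecar))
    return table


def _load_tables(out_dir: Path, manifest_path: Path):
    manifest = pd.read_csv(manifest_path, sep="\t")
    sync = pd.read_csv(out_dir / "sync_features.tsv", sep="\t")
    merged = manifest.merge(sync, on="subject_id", validate="one_to_one")
    labels = np.array([
        label_responder(SeizureDiary(b, f)).responder
        for b, f in zip(merged["baseline_freq"], merged["followup_freq"])
    ])
    return merged, labels


def compare_stage(config: PipelineConfig, out_dir: Path, manifest_path: Path) -> Path:
    """Clinical (baseline-table) and synchronization group comparisons."""
    merged, labels = _load_tables(out_dir, manifest_path)
    if "cohort" in merged:
        keep = (merged["cohort"] == "discovery").to_numpy()
        merged, labels = merged[keep].reset_index(drop=True), labels[keep]
    sync_table = compare_sync_all_metrics(merged, labels, alpha=config.stats.alpha)
    sync_table.to_csv(out_dir / "sync_comparison.tsv", sep="\t", index=False)
    clin = compare_clinical_by_group(merged, labels, alpha=config.stats.alpha)
    clin_rows = [{
        "variable": r.variable, "test": r.test, "p": r.p_raw,
        "significant": r.significant, "summary": json.dumps(r.group_summary),
    } for r in clin]
    pd.DataFrame(clin_rows).to_csv(out_dir / "clinical_comparison.tsv", sep="\t", index=False)
    (out_dir / "comparison.meta.json").write_text(json.dumps(_stamp(config)))
    return out_dir / "sync_comparison.tsv"


def _matrices(config: PipelineConfig, merged: pd.DataFrame, labels: np.ndarray, mode: str):
    clinical = {
        row["subject_id"]: ClinicalRecord.from_dict(row.to_dict())
        for _, row in merged.iterrows()
    }
    names = sync_feature_names()
    sync = {row["subject_id"]: {n: row[n] for n in names} for _, row in merged.iterrows()}
    lab = {row["subject_id"]: bool(l) for (_, row), l in zip(merged.iterrows(), labels)}
    return assemble_matrix(clinical, sync, lab, mode=mode)


def train_stage(config: PipelineConfig, out_dir: Path, manifest_path: Path,
                mode: str = "integrated") -> Path:
    """Nested-CV model on the discovery cohort; report as JSON + ROC CSV."""
    merged, labels = _load_tables(out_dir, manifest_path)
    if "cohort" in merged:
        keep = (merged["cohort"] == "discovery").to_numpy()
        merged, labels = merged[keep].reset_index(drop=True), labels[keep]
    fm = _matrices(config, merged, labels, mode)
    mc = config.model
    report = nested_cv(fm, selector=mc.selector, outer_k=mc.outer_k,
                       inner_k=mc.inner_k, c_grid=mc.c_grid, k_grid=mc.k_grid,
                       seed=config.seed, min_select_fraction=mc.min_select_fraction)
    out = {
        **_stamp(config), "mode": mode,
        "accuracy": report.accuracy, "precision": report.precision,
        "auc": report.auc, "confusion": report.confusion.tolist(),
        "selected_per_fold": report.selected_per_fold,
        "chosen_params": report.chosen_params,
        "coefficients": report.coefficient_summary.to_dict(orient="records"),
    }
    (out_dir / f"model_report_{mode}.json").write_text(json.dumps(out, indent=1))
    pd.DataFrame({"fpr": report.roc_fpr, "tpr": report.roc_tpr}).to_csv(
        out_dir / f"roc_{mode}.csv", index=False)
    return out_dir / f"model_report_{mode}.json"


def predict_stage(config: PipelineConfig, out_dir: Path, manifest_path: Path,
                  mode: str = "integrated") -> Path:
    """Refit on all discovery subjects, predict the validation cohort."""
    merged, labels = _load_tables(out_dir, manifest_path)
    if "cohort" not in merged or (merged["cohort"] == "validation").sum() == 0:
        raise ValueError("no validation cohort in manifest")
    disc = (merged["cohort"] == "discovery").to_numpy()
    fm_train = _matrices(config, merged[disc].reset_index(drop=True), labels[disc], mode)
    fm_ext = _matrices(config, merged[~disc].reset_index(drop=True), labels[~disc], mode)
    mc = config.model
    model, pred, acc = fit_final_and_predict(
        fm_train, fm_ext.X, fm_ext.y, selector=mc.selector, inner_k=mc.inner_k,
        c_grid=mc.c_grid, k_grid=mc.k_grid, seed=config.seed)
    (out_dir / "model_bundle.json").write_text(model.to_json())
    pd.DataFrame({
        "subject_id": list(fm_ext.X.index),
        "predicted_responder": pred.astype(bool),
        "true_responder": fm_ext.y.astype(bool),
    }).to_csv(out_dir / "validation_predictions.csv", index=False)
    (out_dir / "validation_summary.json").write_text(json.dumps(
        {**_stamp(config), "mode": mode, "external_accuracy": acc,
         "n_external": int(len(pred))}))
    return out_dir / "validation_predictions.csv"


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict[str, Path]:
    """Run all stages in order; any failure halts with a stage-tagged error."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    try:
        manifest = simulate_stage(config, out_dir)
        artifacts["manifest"] = manifest
    except Exception as e:  # noqa: BLE001 - stage tagging
        raise StageError("simulate", e) from e
    for name, fn in (("extract", extract_stage), ("compare", compare_stage),
                     ("train", train_stage)):
        try:
            artifacts[name] = fn(config, out_dir, manifest)
        except Exception as e:  # noqa: BLE001
            raise StageError(name, e) from e
    if config.simulate.n_validation > 0:
        try:
            artifacts["predict"] = predict_stage(config, out_dir, manifest)
        except Exception as e:  # noqa: BLE001
            raise StageError("predict", e) from e
    return artifacts
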