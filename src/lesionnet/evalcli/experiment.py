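"""Cross-validated experiment orchestration and ablation comparison.

Per fold: train the segmenter, freeze it, train the attention classifier
with the composite objective, then evaluate the validation fold with
MC-dropout inference — metrics, rejection curve, calibration, explanation
overlays, and an out-of-distribution uncertainty probe.
"""

from __future__ import annotations

import hashlib
import json
import traceback
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from ..classifier import train_classifier
from ..config import ExperimentConfig
from ..data import (LesionSpec, default_class_specs, derive_seed,
                    generate_sample, load_dataset, resize_mask)
from ..data.generate import generate_dataset
from ..explain import align_explanation, explanation_coverage, grad_cam, render_overlay
from ..segmentation import (dice_coefficient, save_segmenter, train_segmenter)
from ..segmentation.train import _to_batch, evaluate_segmenter
from ..uncertainty import (calibration_report, mc_predict_batch,
                           rejection_analysis, select_threshold,
                           uncertainty_scores)
from .folds import stratified_kfold
from .metrics import evaluate


def _dataset_hash(config: ExperimentConfig, specs: Sequence[LesionSpec]) -> str:
    blob = json.dumps({
        "n_classes": config.n_classes,
        "n_per_class": config.n_per_class,
        "resolution": config.resolution,
        "seed": derive_seed(config.seed, 0),
        "specs": [s.to_dict() for s in specs],
        "dataset_dir": config.dataset_dir,
    }, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _ood_specs(n_classes: int) -> List[LesionSpec]:
    """Probes the training distribution never covers: lesion-free skin and an
    unseen morphology profile."""
    lesion_free = LesionSpec(class_id=-1, base_radius_frac=0.0,
                             hair_count=2, illumination_gradient=0.2,
                             noise_sigma=0.02, color_palette=[])
    unseen = LesionSpec(class_id=-2, base_radius_frac=0.42, asymmetry=0.9,
                        border_irregularity=0.9, n_boundary_harmonics=8,
                        color_palette=[(0.05, 0.35, 0.45), (0.9, 0.85, 0.2)],
                        heterogeneity=1.0, hair_count=6,
                        illumination_gradient=0.6, noise_sigma=0.08)
    return [lesion_free, unseen]


def run_experiment(config: ExperimentConfig, out_dir: Path) -> Path:
    """Execute the full experiment; artifacts land under ``out_dir``.

    Folds that fail are recorded in summary.json (``failed_folds``) and the
    run continues with the remaining folds.
    """
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    specs = default_class_specs(config.n_classes)
    if config.dataset_dir:
        samples = load_dataset(Path(config.dataset_dir))
    else:
        meta = generate_dataset(specs, config.n_per_class, config.resolution,
                                derive_seed(config.seed, 0), out_dir=None)
        samples = meta.attrs["samples"]
    labels = np.array([s.label for s in samples])
    ds_hash = _dataset_hash(config, specs)

    (out_dir / "config.json").write_text(json.dumps({
        "name": config.name,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "dataset_hash": ds_hash,
        "seed": config.seed,
    }, indent=2, sort_keys=True))

    folds = stratified_kfold(labels, config.k_folds, derive_seed(config.seed, 1))
    fold_summaries: List[Dict] = []
    failed: List[Dict] = []
    pooled_scores, pooled_correct = [], []
    ood_means: List[Dict[str, float]] = []

    for f, (tr_idx, va_idx) in enumerate(folds):
        fold_dir = out_dir / f"fold_{f}"
        fold_dir.mkdir(exist_ok=True)
        try:
            summary = _run_fold(config, samples, labels, tr_idx, va_idx,
                                f, fold_dir, pooled_scores, pooled_correct,
                                ood_means)
            fold_summaries.append(summary)
        except Exception as exc:                      # record and continue
            failed.append({"fold": f, "error": str(exc)})
            (fold_dir / "error.txt").write_text(traceback.format_exc())

    summary: Dict = {
        "name": config.name,
        "config_hash": config.config_hash(),
        "dataset_hash": ds_hash,
        "seed": config.seed,
        "n_folds": config.k_folds,
        "failed_folds": failed,
        "folds": fold_summaries,
    }
    if fold_summaries:
        for key in ("accuracy", "weighted_precision", "weighted_recall",
                    "weighted_f1", "macro_auc", "val_dice", "ece", "brier"):
            vals = [s[key] for s in fold_summaries if s.get(key) is not None]
            summary[f"mean_{key}"] = float(np.mean(vals)) if vals else None
        scores = np.concatenate(pooled_scores)
        correct = np.concatenate(pooled_correct)
        summary["mean_uncertainty_correct"] = float(scores[correct].mean())
        if (~correct).any():
            summary["mean_uncertainty_incorrect"] = float(scores[~correct].mean())
            summary["error_detection_auroc"] = float(
                roc_auc_score(~correct, scores))
        else:
            summary["mean_uncertainty_incorrect"] = None
            summary["error_detection_auroc"] = None
        summary["mean_uncertainty_in_distribution"] = float(scores.mean())
        for key in ("lesion_free", "unseen_morphology"):
            vals = [d[key] for d in ood_means]
            summary[f"mean_uncertainty_ood_{key}"] = float(np.mean(vals))

    (out_dir / "metrics.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True))
    return out_dir


def _run_fold(config: ExperimentConfig, samples, labels, tr_idx, va_idx,
              f: int, fold_dir: Path, pooled_scores, pooled_correct,
              ood_means) -> Dict:
    train_samples = [samples[i] for i in tr_idx]
    val_samples = [samples[i] for i in va_idx]
    y_val = labels[va_idx]

    seg_cfg = config.seg
    segmenter, seg_hist = train_segmenter(
        train_samples, seg_cfg, seed=derive_seed(config.seed, 10 + f))
    seg_hist.to_csv(fold_dir / "seg_history.csv", index=False)
    save_segmenter(segmenter, fold_dir)

    xv, gv = _to_batch(val_samples, config.resolution)
    val_dice = evaluate_segmenter(segmenter, xv, gv)

    pipe, cls_hist = train_classifier(
        train_samples, segmenter, config.cls,
        seed=derive_seed(config.seed, 100 + f))
    cls_hist.to_csv(fold_dir / "cls_history.csv", index=False)
    _save_classifier(pipe.classifier, fold_dir)

    # MC-dropout evaluation of the held-out fold
    images = [s.image for s in val_samples]
    _, mean, var = mc_predict_batch(pipe, images, config.mc_passes,
                                    derive_seed(config.seed, 200 + f))
    report = evaluate(mean, y_val)
    preds = mean.argmax(axis=1)
    correct = preds == y_val
    scores = uncertainty_scores(mean, var, config.uncertainty_method)
    confidences = mean.max(axis=1)
    pooled_scores.append(scores)
    pooled_correct.append(correct)

    pd.DataFrame({
        "sample_id": [s.sample_id for s in val_samples],
        "label": y_val,
        "predicted": preds,
        "confidence": confidences,
        "uncertainty": scores,
        "correct": correct,
    }).to_csv(fold_dir / "predictions.csv", index=False)

    thresholds = np.unique(np.quantile(scores, np.linspace(0.0, 1.0, 21)))
    curve = rejection_analysis(scores, correct, thresholds)
    curve.to_frame().to_csv(fold_dir / "rejection.csv", index=False)
    theta_u = select_threshold(scores, correct, max_correct_rejection=0.05)

    cal = calibration_report(confidences, correct, n_bins=config.n_bins,
                             probs=mean, labels=y_val)
    (fold_dir / "calibration.json").write_text(
        json.dumps(cal.to_dict(), indent=2))

    expl_rows = _explain_subset(config, pipe, val_samples, fold_dir)

    fold_summary = {
        "fold": f,
        "val_dice": val_dice,
        "accuracy": report.accuracy,
        "weighted_precision": report.weighted["precision"],
        "weighted_recall": report.weighted["recall"],
        "weighted_f1": report.weighted["f1"],
        "macro_auc": report.macro_auc,
        "ece": cal.ece,
        "brier": cal.brier,
        "theta_u": theta_u,
        "mean_coverage_gradcam": (float(np.mean([r["coverage_raw"]
                                                 for r in expl_rows]))
                                  if expl_rows else None),
        "best_cls_epoch": int(cls_hist.attrs["best_epoch"]),
    }
    (fold_dir / "metrics.json").write_text(json.dumps(
        {**fold_summary, **report.to_dict()}, indent=2, sort_keys=True))

    ood_means.append(_ood_probe(config, pipe, f))
    return fold_summary


def _explain_subset(config: ExperimentConfig, pipe, val_samples, fold_dir: Path
                    ) -> List[Dict]:
    rows: List[Dict] = []
    overlay_dir = fold_dir / "overlays"
    for s in val_samples[: config.n_explain]:
        cam = grad_cam(pipe, s.image)
        mask_pred = pipe.predict(
            [s.image]).masks[0]
        aligned = align_explanation(cam, mask_pred)
        gt = resize_mask(s.mask, config.resolution)
        if cam.sum() == 0:
            continue
        rows.append({
            "sample_id": s.sample_id,
            "target_class": int(pipe.predict([s.image]).probs[0].argmax()),
            "coverage_raw": explanation_coverage(cam, gt),
            "coverage_aligned": (explanation_coverage(aligned, gt)
                                 if aligned.sum() > 0 else np.nan),
        })
        from ..data.transforms import resize_image
        render_overlay(resize_image(s.image, config.resolution), cam,
                       overlay_dir / f"{s.sample_id}_gradcam.png")
    if rows:
        pd.DataFrame(rows).to_csv(fold_dir / "explanations.csv", index=False)
    return rows


def _ood_probe(config: ExperimentConfig, pipe, f: int, n: int = 24
               ) -> Dict[str, float]:
    out = {}
    for name, spec in zip(("lesion_free", "unseen_morphology"),
                          _ood_specs(config.n_classes)):
        images = [
            generate_sample(spec, config.resolution,
                            derive_seed(config.seed, 1000 + 100 * f + i)).image
            for i in range(n)
        ]
        _, mean, var = mc_predict_batch(pipe, images, config.mc_passes,
                                        derive_seed(config.seed, 300 + f))
        out[name] = float(uncertainty_scores(
            mean, var, config.uncertainty_method).mean())
    return out


def _load_pipeline(fold_dir: Path, config=None):
    """Rebuild a LesionPipeline from a fold directory's JSON checkpoints."""
    from ..classifier.model import LesionClassifier, LesionPipeline
    from ..config import ClsTrainConfig
    from ..segmentation import load_segmenter

    blob = json.loads((Path(fold_dir) / "classifier.json").read_text())
    model = LesionClassifier(blob["n_classes"], np.random.default_rng(0),
                             use_attention=blob["use_attention"])
    model.load_state_dict({k: np.asarray(v, dtype=np.float32)
                           for k, v in blob["state"].items()})
    model.eval()
    segmenter = load_segmenter(fold_dir)
    return LesionPipeline(segmenter, model, config or ClsTrainConfig.desk())


def _save_classifier(model, fold_dir: Path) -> None:
    state = {k: v.tolist() for k, v in model.state_dict().items()}
    (fold_dir / "classifier.json").write_text(json.dumps({
        "n_classes": model.n_classes,
        "use_attention": model.use_attention,
        "state": state,
    }))


def compare_runs(run_dirs: Sequence[Path]) -> pd.DataFrame:
    """Ablation delta table across runs sharing a dataset hash, ordered by
    descending accuracy; deltas are against the run named ``full`` (falling
    back to the first run given)."""
    rows = []
    hashes = set()
    for d in run_dirs:
        d = Path(d)
        cfg = json.loads((d / "config.json").read_text())
        met = json.loads((d / "metrics.json").read_text())
        hashes.add(cfg["dataset_hash"])
        rows.append({
            "name": cfg.get("name", d.name),
            "accuracy": met.get("mean_accuracy"),
            "precision": met.get("mean_weighted_precision"),
            "recall": met.get("mean_weighted_recall"),
            "f1": met.get("mean_weighted_f1"),
        })
    if len(hashes) > 1:
        raise ValueError("runs were produced on different datasets")
    base = next((r for r in rows if r["name"] == "full"), rows[0])
    for r in rows:
        r["delta_accuracy"] = (r["accuracy"] - base["accuracy"]
                               if r["accuracy"] is not None else None)
    df = pd.DataFrame(rows)
    return df.sort_values("accuracy", ascending=False).reset_index(drop=True)
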