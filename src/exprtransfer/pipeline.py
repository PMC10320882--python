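"""End-to-end pipeline: simulate -> prep -> train -> transfer -> evaluate.

A single YAML config (blocks: synthetic, classifier, transferor, evaluation)
and one master seed drive the whole run; the master seed fans out to fixed
per-stage seeds so each stage is independently reproducible. Every output
file is listed with its SHA-256 in a ``manifest.json`` in the run directory.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import evaluation as ev
from .classifier import ClassifierConfig, LossWeights, fit_classifier, \
    strip_reconstruction, train_classifier
from .io_prep import kfold_split, max_scale, write_expression, write_metadata
from .synthetic import SyntheticConfig, generate_dataset
from .transferor import TransferorConfig, assemble_transfer_matrices, train_transferor

logger = logging.getLogger("exprtransfer")

STAGES = ("simulate", "prep", "train_classifier", "train_transferor",
          "transfer", "evaluate", "baselines", "deg")


def stage_seed(master_seed: int, stage: str) -> int:
    """Fixed derivation of a per-stage seed from the master seed."""
    idx = STAGES.index(stage)
    return int(np.random.SeedSequence([master_seed, idx]).generate_state(1)[0]
               % (2 ** 31))


@dataclass
class EvaluationConfig:
    k: int = 5
    pca_dims: tuple[int, ...] = (90, 120, 150)
    alpha: float = 0.05
    lfc_threshold: float = 1.0
    run_baselines: bool = True


@dataclass
class RunConfig:
    seed: int = 0
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    transferor: TransferorConfig = field(default_factory=TransferorConfig)
    evaluation: EvaluationConfig = field(default_factory=EvaluationConfig)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {"seed", "synthetic", "classifier", "transferor", "evaluation"}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config blocks: {sorted(unknown)}")
        kwargs: dict = {"seed": int(raw.get("seed", 0))}
        for name, typ in (("synthetic", SyntheticConfig),
                          ("classifier", ClassifierConfig),
                          ("transferor", TransferorConfig),
                          ("evaluation", EvaluationConfig)):
            block = dict(raw.get(name, {}))
            try:
                if "loss_weights" in block:
                    block["loss_weights"] = LossWeights(**block["loss_weights"])
                for key in ("encoder_units", "decoder_units", "head_units",
                            "pca_dims"):
                    if key in block:
                        block[key] = tuple(block[key])
                kwargs[name] = typ(**block)
            except TypeError as exc:
                raise ValueError(f"invalid '{name}' config block: {exc}") from exc
        return cls(**kwargs)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Run every stage; returns a summary dict (also written as JSON).

    Artifacts: dataset TSVs + ground-truth JSON, training histories,
    per-fold metric tables, confusion matrices, ON_TT/OT_TN matrices,
    DEG tables, TPR JSON, PCA figures, manifest with checksums.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    summary: dict = {"seed": config.seed, "stages": {}}

    def _log_stage(name, start):
        summary["stages"][name] = {"seconds": round(time.time() - start, 2),
                                   "seed": stage_seed(config.seed, name)
                                   if name in STAGES else None}
        logger.info("stage %s done in %.1fs", name, time.time() - start)

    # simulate
    t = time.time()
    syn = dataclasses.replace(config.synthetic,
                              seed=stage_seed(config.seed, "simulate"))
    data, meta, truth = generate_dataset(syn)
    write_expression(data, out / "expression.tsv")
    write_metadata(meta, out / "metadata.tsv")
    truth.to_json(out / "ground_truth.json")
    _log_stage("simulate", t)

    # prep
    t = time.time()
    scaled = max_scale(data)
    folds = kfold_split(meta, config.evaluation.k,
                        stage_seed(config.seed, "prep"))
    _log_stage("prep", t)

    # classifier CV + evaluation of held-out predictions
    t = time.time()
    clf_cfg = dataclasses.replace(
        config.classifier, seed=stage_seed(config.seed, "train_classifier"))
    cv_models, clf_hist = train_classifier(scaled, meta, folds, clf_cfg)
    clf_hist.to_csv(out / "classifier_history.csv", index=False)
    tissue_cats = cv_models[0].tissue_categories
    type_cats = cv_models[0].type_categories
    per_t, per_y = [], []
    t_true_all, t_pred_all = [], []
    y_true_all, y_pred_all = [], []
    for f in range(folds.k):
        te = folds.test_indices(f)
        sub = scaled.subset_samples([scaled.sample_ids[i] for i in te])
        t_pred, y_pred = cv_models[f].predict_labels(sub)
        per_t.append(ev.metrics_from_confusion(
            ev.confusion(meta.tissue[te], t_pred, tissue_cats)))
        per_y.append(ev.metrics_from_confusion(
            ev.confusion(meta.type[te], y_pred, type_cats)))
        t_true_all.append(meta.tissue[te]); t_pred_all.append(t_pred)
        y_true_all.append(meta.type[te]); y_pred_all.append(y_pred)
    t_true_all = np.concatenate(t_true_all); t_pred_all = np.concatenate(t_pred_all)
    y_true_all = np.concatenate(y_true_all); y_pred_all = np.concatenate(y_pred_all)
    ev.aggregate_fold_metrics(per_t).to_csv(out / "classifier_tissue_metrics.tsv",
                                            sep="\t")
    ev.aggregate_fold_metrics(per_y).to_csv(out / "classifier_type_metrics.tsv",
                                            sep="\t")
    ev.confusion(t_true_all, t_pred_all, tissue_cats).to_frame().to_csv(
        out / "classifier_tissue_confusion.tsv", sep="\t")
    ev.confusion(y_true_all, y_pred_all, type_cats).to_frame().to_csv(
        out / "classifier_type_confusion.tsv", sep="\t")
    summary["classifier_tissue_macro_f1"] = ev.macro_f1(
        t_true_all, t_pred_all, tissue_cats)
    summary["classifier_type_macro_f1"] = ev.macro_f1(
        y_true_all, y_pred_all, type_cats)
    _log_stage("train_classifier", t)

    # discriminator: classifier trained on all data, reconstruction stripped
    t = time.time()
    full_clf, _ = fit_classifier(scaled, meta, clf_cfg)
    disc = strip_reconstruction(full_clf)
    tr_cfg = dataclasses.replace(
        config.transferor, seed=stage_seed(config.seed, "train_transferor"))
    transferor_model, tr_hist = train_transferor(scaled, meta, disc, tr_cfg)
    tr_hist.to_csv(out / "transferor_history.csv", index=False)
    _log_stage("train_transferor", t)

    # transfer + matrix assembly
    t = time.time()
    (on_tt, on_tt_meta), (ot_tn, ot_tn_meta) = assemble_transfer_matrices(
        transferor_model, scaled, meta)
    write_expression(on_tt, out / "ON_TT.tsv")
    write_metadata(on_tt_meta, out / "ON_TT_metadata.tsv")
    write_expression(ot_tn, out / "OT_TN.tsv")
    write_metadata(ot_tn_meta, out / "OT_TN_metadata.tsv")
    _log_stage("transfer", t)

    # evaluate transfers through the discriminator
    t = time.time()
    n_normal = int(np.sum(meta.type == "normal"))
    trans_ids = on_tt.sample_ids[n_normal:]
    trans_m = on_tt.subset_samples(trans_ids)
    trans_meta = on_tt_meta.subset(trans_ids)
    res_tt = ev.evaluate_transfer(disc, trans_m, trans_meta)
    res_tt["tissue_metrics"].to_csv(out / "transfer_TT_tissue_metrics.tsv", sep="\t")
    res_tt["type_metrics"].to_csv(out / "transfer_TT_type_metrics.tsv", sep="\t")
    summary["transfer_TT_tissue_accuracy"] = res_tt["tissue_confusion"].accuracy
    summary["transfer_TT_type_accuracy"] = res_tt["type_confusion"].accuracy
    ev.pca_plot(on_tt, on_tt_meta, path=out / "ON_TT_pca.png")
    ev.pca_plot(ot_tn, ot_tn_meta, path=out / "OT_TN_pca.png")
    _log_stage("evaluate", t)

    # baselines
    if config.evaluation.run_baselines:
        t = time.time()
        tables = {}
        for dim in config.evaluation.pca_dims:
            tbl = ev.run_baselines(scaled, meta.tissue, folds, pca_dim=dim,
                                   seed=stage_seed(config.seed, "baselines"))
            tbl.to_csv(out / f"baselines_pca{dim}.tsv", sep="\t")
            tables[dim] = tbl
        summary["baseline_best_accuracy"] = max(
            float(tbl["accuracy_mean"].max()) for tbl in tables.values())
        _log_stage("baselines", t)

    # DEG per tissue + TPR between ON_TT and OT_TN
    t = time.time()
    tprs = {}
    for tissue in sorted(set(meta.tissue)):
        sub_tt = on_tt.subset_samples(
            [s for s, ti in zip(on_tt.sample_ids, on_tt_meta.tissue) if ti == tissue])
        sub_tt_meta = on_tt_meta.subset(sub_tt.sample_ids)
        sub_tn = ot_tn.subset_samples(
            [s for s, ti in zip(ot_tn.sample_ids, ot_tn_meta.tissue) if ti == tissue])
        sub_tn_meta = ot_tn_meta.subset(sub_tn.sample_ids)
        deg_tt = ev.differential_expression(
            sub_tt, sub_tt_meta, alpha=config.evaluation.alpha,
            lfc_threshold=config.evaluation.lfc_threshold)
        deg_tn = ev.differential_expression(
            sub_tn, sub_tn_meta, alpha=config.evaluation.alpha,
            lfc_threshold=config.evaluation.lfc_threshold)
        deg_tt.to_csv(out / f"deg_ON_TT_{tissue}.tsv", sep="\t")
        deg_tn.to_csv(out / f"deg_OT_TN_{tissue}.tsv", sep="\t")
        r = ev.true_positive_rates(deg_tt, deg_tn)
        tprs[tissue] = {"tpr_up": r.tpr_up, "tpr_down": r.tpr_down,
                        "intersect_up": r.intersect_up,
                        "intersect_down": r.intersect_down}
    with open(out / "tpr.json", "w") as fh:
        json.dump(tprs, fh, indent=1, allow_nan=True)
    finite_up = [v["tpr_up"] for v in tprs.values() if np.isfinite(v["tpr_up"])]
    finite_dn = [v["tpr_down"] for v in tprs.values() if np.isfinite(v["tpr_down"])]
    summary["mean_tpr_up"] = float(np.mean(finite_up)) if finite_up else float("nan")
    summary["mean_tpr_down"] = float(np.mean(finite_dn)) if finite_dn else float("nan")
    _log_stage("deg", t)

    summary["total_seconds"] = round(time.time() - t0, 2)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1)

    manifest = {p.name: _sha256(p) for p in sorted(out.iterdir())
                if p.is_file() and p.name != "manifest.json"}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return summary
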