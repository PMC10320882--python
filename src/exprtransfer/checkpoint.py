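"""Model checkpoints: a single ``.npz`` holding all parameter arrays plus a
JSON header (config, category orders, gene ids, fitted flag), so a saved
model is self-describing and reload is exact to the byte."""

from __future__ import annotations

import dataclasses
import json

import numpy as np

from .classifier import ClassifierConfig, ClassifierModel, LossWeights
from .transferor import TransferorConfig, TransferorModel


def _config_to_dict(cfg) -> dict:
    d = dataclasses.asdict(cfg)
    return d


def _config_from_dict(cls, d: dict):
    d = dict(d)
    if "loss_weights" in d and isinstance(d["loss_weights"], dict):
        d["loss_weights"] = LossWeights(**d["loss_weights"])
    for key in ("encoder_units", "decoder_units", "head_units", "baseline_range"):
        if key in d and isinstance(d[key], list):
            d[key] = tuple(d[key])
    return cls(**d)


def _save(path, header: dict, params: list[np.ndarray]) -> None:
    arrays = {f"p{i:04d}": p for i, p in enumerate(params)}
    np.savez(path, header=np.asarray(json.dumps(header)), **arrays)


def _load_params(data) -> list[np.ndarray]:
    keys = sorted(k for k in data.files if k.startswith("p"))
    return [data[k] for k in keys]


def save_classifier(model: ClassifierModel, path) -> None:
    header = {
        "kind": "classifier",
        "config": _config_to_dict(model.config),
        "tissue_categories": model.tissue_categories,
        "type_categories": model.type_categories,
        "gene_ids": model.gene_ids,
        "n_genes": model.n_genes,
        "fitted": model.fitted,
    }
    _save(path, header, model.params)


def load_classifier(path) -> ClassifierModel:
    with np.load(path, allow_pickle=False) as data:
        header = json.loads(str(data["header"]))
        params = _load_params(data)
    if header["kind"] != "classifier":
        raise ValueError(f"not a classifier checkpoint: {path}")
    cfg = _config_from_dict(ClassifierConfig, header["config"])
    model = ClassifierModel(header["n_genes"], header["tissue_categories"],
                            header["type_categories"], cfg,
                            gene_ids=header["gene_ids"])
    live = model.params
    if len(live) != len(params):
        raise ValueError("checkpoint parameter count mismatch")
    for dst, src in zip(live, params):
        dst[...] = src
    model.fitted = header["fitted"]
    return model


def save_transferor(model: TransferorModel, path) -> None:
    header = {
        "kind": "transferor",
        "config": _config_to_dict(model.config),
        "type_categories": model.type_categories,
        "gene_ids": model.gene_ids,
        "n_genes": model.n_genes,
        "fitted": model.fitted,
    }
    _save(path, header, model.params)


def load_transferor(path) -> TransferorModel:
    with np.load(path, allow_pickle=False) as data:
        header = json.loads(str(data["header"]))
        params = _load_params(data)
    if header["kind"] != "transferor":
        raise ValueError(f"not a transferor checkpoint: {path}")
    cfg = _config_from_dict(TransferorConfig, header["config"])
    model = TransferorModel(header["n_genes"], header["type_categories"], cfg,
                            gene_ids=header["gene_ids"])
    live = model.params
    if len(live) != len(params):
        raise ValueError("checkpoint parameter count mismatch")
    for dst, src in zip(live, params):
        dst[...] = src
    model.fitted = header["fitted"]
    return model
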