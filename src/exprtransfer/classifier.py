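"""Multi-task autoencoder classifier and the frozen discriminator derived from it.

The network is a single encoder trunk down to a bottleneck, from which three
heads branch: a reconstruction head back to gene space (regression), a
tissue head and a type (normal/tumor) head. Training minimises

    w1 * MSE(input, reconstruction)
  + w2 * CosineDistance(type one-hot, type scores)
  + w3 * CosineDistance(tissue one-hot, tissue scores)

where the cosine distance is 1 - cosine similarity averaged over the batch.
The heads emit real-valued score vectors (the cosine loss does not require a
softmax); hard labels are the argmax. After training, removing the
reconstruction head yields the frozen discriminator that scores the
transferor's outputs.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import nn
from .io_prep import (
    ExpressionMatrix,
    FoldAssignment,
    SampleMetadata,
    one_hot,
)
from .nn import activation_fn  # noqa: F401  (re-exported: part of this module's surface)


@dataclass
class LossWeights:
    """Weights of the reconstruction / type / tissue loss terms."""

    w1: float = 1.0
    w2: float = 1.0
    w3: float = 1.0

    def __post_init__(self):
        if self.w1 < 0 or self.w2 < 0 or self.w3 < 0:
            raise ValueError("loss weights must be non-negative")
        if self.w1 == self.w2 == self.w3 == 0:
            raise ValueError("at least one loss weight must be positive")


@dataclass
class ClassifierConfig:
    encoder_units: tuple[int, ...] = (256,)
    bottleneck_dim: int = 64
    head_units: tuple[int, ...] = (32,)
    activation: str = "relu"
    dropout_rate: float = 0.1
    loss_weights: LossWeights = field(default_factory=LossWeights)
    epochs: int = 120
    batch_size: int = 32
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.bottleneck_dim < 1 or any(u < 1 for u in self.encoder_units):
            raise ValueError("layer widths must be >= 1")


def cosine_distance(u, v) -> float:
    """1 - cosine similarity of two vectors; in [0, 2].

    Undefined (raises) when either vector is all-zero.
    """
    u = np.asarray(u, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    if u.shape != v.shape:
        raise ValueError("vectors must have the same length")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine distance undefined for zero vectors")
    return float(1.0 - (u @ v) / (nu * nv))


def classifier_loss(batch_mRNA, recon, tissue_true, tissue_pred,
                    type_true, type_pred, w: LossWeights) -> float:
    """Weighted sum of reconstruction MSE and the two cosine-distance terms.

    MSE is the per-element mean over the batch; each cosine term is the mean
    over samples of 1 - cos(true one-hot, predicted scores).
    """
    terms = {}
    terms["mse"], _ = nn.mse_loss(recon, batch_mRNA)
    terms["type"], _ = nn.cosine_distance_rows(np.asarray(type_pred, dtype=float),
                                               np.asarray(type_true, dtype=float))
    terms["tissue"], _ = nn.cosine_distance_rows(np.asarray(tissue_pred, dtype=float),
                                                 np.asarray(tissue_true, dtype=float))
    for name, val in terms.items():
        if not np.isfinite(val):
            raise ValueError(f"non-finite {name} loss term")
    return w.w1 * terms["mse"] + w.w2 * terms["type"] + w.w3 * terms["tissue"]


class ClassifierModel:
    """Encoder trunk + reconstruction/tissue/type heads with fixed category orders."""

    def __init__(self, n_genes: int, tissue_categories, type_categories,
                 config: ClassifierConfig, gene_ids=None):
        self.config = config
        self.tissue_categories = list(tissue_categories)
        self.type_categories = list(type_categories)
        self.gene_ids = list(gene_ids) if gene_ids is not None else None
        self.n_genes = n_genes
        self.fitted = False
        rng = np.random.default_rng(config.seed)
        act, drop = config.activation, config.dropout_rate
        self.trunk = nn.MLP([n_genes, *config.encoder_units, config.bottleneck_dim],
                            activation=act, dropout=drop, out_activation=act, rng=rng)
        self.recon_head = nn.MLP(
            [config.bottleneck_dim, *reversed(config.encoder_units), n_genes],
            activation=act, dropout=drop, out_activation="linear", rng=rng)
        self.tissue_head = nn.MLP(
            [config.bottleneck_dim, *config.head_units, len(self.tissue_categories)],
            activation=act, dropout=drop, out_activation="linear", rng=rng)
        self.type_head = nn.MLP(
            [config.bottleneck_dim, *config.head_units, len(self.type_categories)],
            activation=act, dropout=drop, out_activation="linear", rng=rng)

    @property
    def params(self):
        return (self.trunk.params + self.recon_head.params
                + self.tissue_head.params + self.type_head.params)

    def _check_genes(self, m: ExpressionMatrix):
        if m.n_genes != self.n_genes:
            raise ValueError(f"expected {self.n_genes} genes, got {m.n_genes}")
        if self.gene_ids is not None and m.gene_ids != self.gene_ids:
            raise ValueError("gene order does not match the training data")

    def forward(self, x, train=False, rng=None):
        z, c_tr = self.trunk.forward(x, train=train, rng=rng)
        recon, c_re = self.recon_head.forward(z, train=train, rng=rng)
        tissue, c_ti = self.tissue_head.forward(z, train=train, rng=rng)
        type_, c_ty = self.type_head.forward(z, train=train, rng=rng)
        return (z, recon, tissue, type_), (c_tr, c_re, c_ti, c_ty)

    def predict(self, m: ExpressionMatrix):
        """Tissue scores, type scores and reconstruction for each sample."""
        self._check_genes(m)
        (_, recon, tissue, type_), _ = self.forward(m.values.T)
        return tissue, type_, recon.T

    def predict_labels(self, m: ExpressionMatrix):
        tissue, type_, _ = self.predict(m)
        t_lab = np.asarray([self.tissue_categories[j] for j in tissue.argmax(1)],
                           dtype=object)
        y_lab = np.asarray([self.type_categories[j] for j in type_.argmax(1)],
                           dtype=object)
        return t_lab, y_lab

    def embed(self, m: ExpressionMatrix) -> np.ndarray:
        """Bottleneck embedding, samples x bottleneck_dim."""
        self._check_genes(m)
        z, _ = self.trunk.forward(m.values.T)
        return z


class Discriminator:
    """The classifier with its reconstruction head removed and parameters frozen.

    Used to score the transferor's opposite-type outputs; frozenness is
    enforced by checksumming the parameters, which the transferor trainer
    verifies before and after training.
    """

    def __init__(self, trunk: nn.MLP, tissue_head: nn.MLP, type_head: nn.MLP,
                 tissue_categories, type_categories, n_genes: int, gene_ids=None):
        self.trunk = trunk
        self.tissue_head = tissue_head
        self.type_head = type_head
        self.tissue_categories = list(tissue_categories)
        self.type_categories = list(type_categories)
        self.n_genes = n_genes
        self.gene_ids = list(gene_ids) if gene_ids is not None else None
        self.frozen = True
        self._checksum = self.checksum()

    @property
    def params(self):
        return self.trunk.params + self.tissue_head.params + self.type_head.params

    def checksum(self) -> str:
        return nn.params_checksum(self.params)

    def verify_frozen(self):
        if self.checksum() != self._checksum:
            raise RuntimeError("frozen discriminator parameters were modified")

    def forward(self, x):
        """(tissue scores, type scores) with caches for backprop-through."""
        z, c_tr = self.trunk.forward(x)
        tissue, c_ti = self.tissue_head.forward(z)
        type_, c_ty = self.type_head.forward(z)
        return (tissue, type_), (c_tr, c_ti, c_ty)

    def backward_input(self, g_tissue, g_type, caches):
        """Gradient wrt the input expression batch; parameter grads discarded."""
        c_tr, c_ti, c_ty = caches
        dz_t, _ = self.tissue_head.backward(g_tissue, c_ti)
        dz_y, _ = self.type_head.backward(g_type, c_ty)
        dx, _ = self.trunk.backward(dz_t + dz_y, c_tr)
        return dx

    def predict(self, m: ExpressionMatrix):
        if m.n_genes != self.n_genes:
            raise ValueError(f"expected {self.n_genes} genes, got {m.n_genes}")
        (tissue, type_), _ = self.forward(m.values.T)
        return tissue, type_

    def predict_labels(self, m: ExpressionMatrix):
        tissue, type_ = self.predict(m)
        t_lab = np.asarray([self.tissue_categories[j] for j in tissue.argmax(1)],
                           dtype=object)
        y_lab = np.asarray([self.type_categories[j] for j in type_.argmax(1)],
                           dtype=object)
        return t_lab, y_lab


def strip_reconstruction(model: ClassifierModel) -> Discriminator:
    """Remove the reconstruction head; deep-copy and freeze the rest.

    The discriminator's tissue/type predictions equal the classifier's on
    any input. Idempotent in effect: stripping a model twice yields two
    discriminators with identical parameters.
    """
    if not model.fitted:
        raise ValueError("cannot strip an unfitted classifier")
    return Discriminator(
        copy.deepcopy(model.trunk),
        copy.deepcopy(model.tissue_head),
        copy.deepcopy(model.type_head),
        model.tissue_categories,
        model.type_categories,
        model.n_genes,
        model.gene_ids,
    )


def fit_classifier(data: ExpressionMatrix, meta: SampleMetadata,
                   cfg: ClassifierConfig,
                   sample_indices=None) -> tuple[ClassifierModel, pd.DataFrame]:
    """Train one classifier on (a subset of) the data; returns (model, history).

    ``data`` is expected max-scaled. History records the per-epoch mean
    training loss and its three terms. With ``epochs=0`` the initialized,
    unfitted-flagged model is returned and prediction still runs.
    """
    tissue_oh = one_hot(meta, "tissue")
    type_oh = one_hot(meta, "type")
    model = ClassifierModel(data.n_genes, tissue_oh.categories, type_oh.categories,
                            cfg, gene_ids=data.gene_ids)
    idx = np.arange(data.n_samples) if sample_indices is None else np.asarray(sample_indices)
    X = data.values.T[idx]
    T = tissue_oh.matrix[idx]
    Y = type_oh.matrix[idx]
    w = cfg.loss_weights
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    opt = nn.Adam(model.params, lr=cfg.learning_rate)
    history = []
    n = X.shape[0]
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        ep = {"loss": 0.0, "mse": 0.0, "type": 0.0, "tissue": 0.0}
        n_batches = 0
        for start in range(0, n, cfg.batch_size):
            b = order[start:start + cfg.batch_size]
            xb, tb, yb = X[b], T[b], Y[b]
            (z, recon, tis, typ), caches = model.forward(xb, train=True, rng=rng)
            c_tr, c_re, c_ti, c_ty = caches
            l_mse, g_re = nn.mse_loss(recon, xb)
            l_typ, g_ty = nn.cosine_distance_rows(typ, yb)
            l_tis, g_ti = nn.cosine_distance_rows(tis, tb)
            total = w.w1 * l_mse + w.w2 * l_typ + w.w3 * l_tis
            if not np.isfinite(total):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}: "
                    f"mse={l_mse}, type={l_typ}, tissue={l_tis}")
            dz_re, pg_re = model.recon_head.backward(w.w1 * g_re, c_re)
            dz_ti, pg_ti = model.tissue_head.backward(w.w3 * g_ti, c_ti)
            dz_ty, pg_ty = model.type_head.backward(w.w2 * g_ty, c_ty)
            _, pg_tr = model.trunk.backward(dz_re + dz_ti + dz_ty, c_tr)
            opt.step(pg_tr + pg_re + pg_ti + pg_ty)
            for k, v in (("loss", total), ("mse", l_mse), ("type", l_typ),
                         ("tissue", l_tis)):
                ep[k] += v
            n_batches += 1
        history.append({"epoch": epoch, **{k: v / n_batches for k, v in ep.items()}})
    hist = pd.DataFrame(history)
    if cfg.epochs > 0:
        model.fitted = True
        if len(hist) > 1 and hist["loss"].iloc[-1] >= hist["loss"].iloc[0]:
            import warnings
            warnings.warn("training loss did not decrease", stacklevel=2)
    return model, hist


def train_classifier(data: ExpressionMatrix, meta: SampleMetadata,
                     folds: FoldAssignment, cfg: ClassifierConfig):
    """Cross-validated training: one fitted classifier per fold.

    Each fold's model is trained on the training indices only; returns
    (models per fold, concatenated history with a fold column).
    """
    models, hists = [], []
    for f in range(folds.k):
        fold_cfg = copy.deepcopy(cfg)
        fold_cfg.seed = cfg.seed + f
        model, hist = fit_classifier(data, meta, fold_cfg,
                                     sample_indices=folds.train_indices(f))
        hist.insert(0, "fold", f)
        models.append(model)
        hists.append(hist)
    return models, pd.concat(hists, ignore_index=True)
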