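"""Type-conditioned autoencoder that translates tumor profiles to matched
normal and vice versa.

The encoder consumes an expression vector concatenated with its type one-hot
and emits a bottleneck embedding h. A single decoder (one parameter set,
used for both passes) decodes h twice: once concatenated with the original
type (same-type reconstruction) and once with the opposite type (the
transfer). Training minimises

    w1 * MSE(same-type decode, input)
  + w2 * CosineDistance(opposite type one-hot, discriminator type scores)
  + w3 * CosineDistance(true tissue one-hot, discriminator tissue scores)

where the discriminator — the stripped, frozen classifier — scores the
opposite-type decode. Gradients flow through the discriminator to the
transferor, but only transferor parameters are updated; the discriminator's
parameter checksum is verified unchanged after training.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import nn
from .classifier import Discriminator, LossWeights
from .io_prep import (
    ExpressionMatrix,
    OneHotLabels,
    SampleMetadata,
    one_hot,
)


@dataclass
class TransferorConfig:
    encoder_units: tuple[int, ...] = (256,)
    bottleneck_dim: int = 64
    decoder_units: tuple[int, ...] = (256,)
    activation: str = "relu"
    dropout_rate: float = 0.3
    loss_weights: LossWeights = field(default_factory=LossWeights)
    epochs: int = 600
    batch_size: int = 32
    learning_rate: float = 1e-3
    seed: int = 0
    # linear output clipped to >= 0 at decode time; a saturating non-negative
    # map (softplus) damps gradients for low-expressed genes and biases the
    # transfer of down-regulated genes, so the clipped-linear form is default
    output_activation: str = "linear"
    lr_decay: float = 0.9  # cosine decay of the learning rate toward lr*(1-lr_decay)

    def __post_init__(self):
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.bottleneck_dim < 1:
            raise ValueError("bottleneck_dim must be >= 1")


@dataclass
class TransferResult:
    """The two decodes of a batch: same-type reconstruction and opposite-type
    transfer, plus the per-sample original and implied opposite types."""

    recon_same: ExpressionMatrix
    transfer_opposite: ExpressionMatrix
    original_type: np.ndarray
    opposite_type: np.ndarray


class TransferorModel:
    """Conditioned encoder phi and shared dual-pass decoder psi."""

    def __init__(self, n_genes: int, type_categories, config: TransferorConfig,
                 gene_ids=None):
        if len(type_categories) != 2:
            raise ValueError("transferor requires exactly two type categories "
                             "(opposite type undefined otherwise)")
        self.config = config
        self.type_categories = list(type_categories)
        self.gene_ids = list(gene_ids) if gene_ids is not None else None
        self.n_genes = n_genes
        self.fitted = False
        rng = np.random.default_rng(config.seed)
        act, drop = config.activation, config.dropout_rate
        self.encoder = nn.MLP(
            [n_genes + 2, *config.encoder_units, config.bottleneck_dim],
            activation=act, dropout=drop, out_activation=act, rng=rng)
        self.decoder = nn.MLP(
            [config.bottleneck_dim + 2, *config.decoder_units, n_genes],
            activation=act, dropout=drop,
            out_activation=config.output_activation, rng=rng)

    @property
    def params(self):
        return self.encoder.params + self.decoder.params

    def _check_genes(self, m: ExpressionMatrix):
        if m.n_genes != self.n_genes:
            raise ValueError(f"expected {self.n_genes} genes, got {m.n_genes}")
        if self.gene_ids is not None and m.gene_ids != self.gene_ids:
            raise ValueError("gene order does not match the training data")

    def opposite_one_hot(self, types: OneHotLabels) -> np.ndarray:
        if list(types.categories) != self.type_categories:
            raise ValueError("type category order does not match the model")
        return types.matrix[:, ::-1].copy()


def encode(model: TransferorModel, m: ExpressionMatrix,
           types: OneHotLabels) -> np.ndarray:
    """Bottleneck embedding of each sample given its type (samples x dim)."""
    model._check_genes(m)
    if types.matrix.shape[0] != m.n_samples:
        raise ValueError("one type row required per sample")
    x = np.concatenate([m.values.T, types.matrix], axis=1)
    h, _ = model.encoder.forward(x)
    return h


def decode_both(model: TransferorModel, h: np.ndarray,
                types_original: OneHotLabels) -> TransferResult:
    """Decode an embedding with the original type and with its opposite.

    Both passes run through the identical decoder parameter set. Sample ids
    of the decodes carry ``__recon`` / ``__transfer`` suffixes on positional
    ids; use :func:`assemble_transfer_matrices` for the paired matrices.
    """
    if len(types_original.categories) != 2:
        raise ValueError("opposite type undefined for non-binary type sets")
    t_orig = types_original.matrix
    t_opp = model.opposite_one_hot(types_original)
    same, _ = model.decoder.forward(np.concatenate([h, t_orig], axis=1))
    opp, _ = model.decoder.forward(np.concatenate([h, t_opp], axis=1))
    # clipped-linear output mode: expression is non-negative by contract
    same = np.maximum(same, 0.0)
    opp = np.maximum(opp, 0.0)
    n = h.shape[0]
    gene_ids = model.gene_ids or [f"g{i}" for i in range(model.n_genes)]
    cats = types_original.categories
    orig_labels = np.asarray([cats[j] for j in t_orig.argmax(1)], dtype=object)
    opp_labels = np.asarray([cats[j] for j in t_opp.argmax(1)], dtype=object)
    return TransferResult(
        recon_same=ExpressionMatrix(same.T, gene_ids,
                                    [f"s{i}__recon" for i in range(n)]),
        transfer_opposite=ExpressionMatrix(opp.T, gene_ids,
                                           [f"s{i}__transfer" for i in range(n)]),
        original_type=orig_labels,
        opposite_type=opp_labels,
    )


def transferor_loss(result: TransferResult, input_mRNA: ExpressionMatrix,
                    disc: Discriminator, tissue_true: OneHotLabels,
                    w: LossWeights):
    """Total transferor loss and its three terms on an already-decoded batch.

    The discriminator (must be frozen) scores the opposite-type decode; its
    type scores are pulled toward the opposite type one-hot and its tissue
    scores toward the true tissue. Returns (total, {"mse", "type", "tissue"}).
    """
    if not getattr(disc, "frozen", False):
        raise ValueError("discriminator must be frozen")
    disc.verify_frozen()
    x = input_mRNA.values.T
    recon = result.recon_same.values.T
    transfer = result.transfer_opposite.values.T
    (tissue_out, type_out), _ = disc.forward(transfer)
    opp_oh = np.zeros((len(result.opposite_type), len(disc.type_categories)))
    for i, lab in enumerate(result.opposite_type):
        opp_oh[i, disc.type_categories.index(lab)] = 1.0
    terms = {}
    terms["mse"], _ = nn.mse_loss(recon, x)
    terms["type"], _ = nn.cosine_distance_rows(type_out, opp_oh)
    terms["tissue"], _ = nn.cosine_distance_rows(tissue_out, tissue_true.matrix)
    for name, val in terms.items():
        if not np.isfinite(val):
            raise ValueError(f"non-finite {name} loss term")
    total = w.w1 * terms["mse"] + w.w2 * terms["type"] + w.w3 * terms["tissue"]
    return total, terms


def train_transferor(data: ExpressionMatrix, meta: SampleMetadata,
                     disc: Discriminator, cfg: TransferorConfig):
    """Train the transferor against a frozen, fitted discriminator.

    ``data`` must be max-scaled and gene-aligned with the discriminator.
    Only transferor parameters are updated; the discriminator checksum is
    asserted bitwise identical before and after (hard failure otherwise).
    Returns (model, per-epoch history of the loss terms).
    """
    if not getattr(disc, "frozen", False):
        raise ValueError("discriminator must be frozen")
    if disc.n_genes != data.n_genes:
        raise ValueError("discriminator gene space does not match the data")
    checksum_before = disc.checksum()

    type_oh = one_hot(meta, "type")
    tissue_oh = one_hot(meta, "tissue", categories=disc.tissue_categories)
    model = TransferorModel(data.n_genes, type_oh.categories, cfg,
                            gene_ids=data.gene_ids)
    X = data.values.T
    T_orig = type_oh.matrix
    T_opp = T_orig[:, ::-1].copy()
    Tis = tissue_oh.matrix
    w = cfg.loss_weights
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    opt = nn.Adam(model.params, lr=cfg.learning_rate)
    history = []
    n = X.shape[0]
    n_enc = len(model.encoder.params)
    for epoch in range(cfg.epochs):
        if cfg.lr_decay > 0 and cfg.epochs > 1:
            frac = epoch / (cfg.epochs - 1)
            opt.lr = cfg.learning_rate * (
                1 - cfg.lr_decay * (1 - np.cos(np.pi * frac)) / 2)
        order = rng.permutation(n)
        ep = {"loss": 0.0, "mse": 0.0, "type": 0.0, "tissue": 0.0}
        n_batches = 0
        for start in range(0, n, cfg.batch_size):
            b = order[start:start + cfg.batch_size]
            xb, tob, tpb, tib = X[b], T_orig[b], T_opp[b], Tis[b]
            enc_in = np.concatenate([xb, tob], axis=1)
            h, c_enc = model.encoder.forward(enc_in, train=True, rng=rng)
            dec1, c_d1 = model.decoder.forward(
                np.concatenate([h, tob], axis=1), train=True, rng=rng)
            dec2, c_d2 = model.decoder.forward(
                np.concatenate([h, tpb], axis=1), train=True, rng=rng)
            (tis_out, typ_out), c_disc = disc.forward(dec2)

            l_mse, g_dec1 = nn.mse_loss(dec1, xb)
            l_typ, g_typ = nn.cosine_distance_rows(typ_out, tpb)
            l_tis, g_tis = nn.cosine_distance_rows(tis_out, tib)
            total = w.w1 * l_mse + w.w2 * l_typ + w.w3 * l_tis
            if not np.isfinite(total):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}: "
                    f"mse={l_mse}, type={l_typ}, tissue={l_tis}")

            g_dec2 = disc.backward_input(w.w3 * g_tis, w.w2 * g_typ, c_disc)
            din1, pg_d1 = model.decoder.backward(w.w1 * g_dec1, c_d1)
            din2, pg_d2 = model.decoder.backward(g_dec2, c_d2)
            dh = din1[:, :cfg.bottleneck_dim] + din2[:, :cfg.bottleneck_dim]
            _, pg_enc = model.encoder.backward(dh, c_enc)
            pg_dec = [a + b_ for a, b_ in zip(pg_d1, pg_d2)]
            opt.step(pg_enc + pg_dec)

            for k, v in (("loss", total), ("mse", l_mse), ("type", l_typ),
                         ("tissue", l_tis)):
                ep[k] += v
            n_batches += 1
        history.append({"epoch": epoch, **{k: v / n_batches for k, v in ep.items()}})
    if disc.checksum() != checksum_before:
        raise RuntimeError("discriminator parameters changed during transferor training")
    if cfg.epochs > 0:
        model.fitted = True
    return model, pd.DataFrame(history)


def transfer(model: TransferorModel, data: ExpressionMatrix,
             meta: SampleMetadata) -> TransferResult:
    """Encode and decode a dataset; convenience wrapper (dropout off)."""
    types = one_hot(meta, "type", categories=model.type_categories)
    h = encode(model, data, types)
    result = decode_both(model, h, types)
    gene_ids = data.gene_ids
    result.recon_same = ExpressionMatrix(
        result.recon_same.values, gene_ids,
        [f"{s}__recon" for s in data.sample_ids])
    result.transfer_opposite = ExpressionMatrix(
        result.transfer_opposite.values, gene_ids,
        [f"{s}__transfer" for s in data.sample_ids])
    return result


def assemble_transfer_matrices(model: TransferorModel, data: ExpressionMatrix,
                               meta: SampleMetadata):
    """Build the ON_TT and OT_TN matrices.

    ON_TT: original normal samples together with their opposite-type
    transfers labelled tumor ("transfer tumor", TT). OT_TN: original tumor
    samples with their transfers labelled normal ("transfer normal", TN).
    Each output has exactly twice the corresponding original sample count —
    half originals, half transfers — with transfer ids suffixed to preserve
    the pairing. Returns ((on_tt, on_tt_meta), (ot_tn, ot_tn_meta)).
    """
    if not model.fitted:
        raise ValueError("transferor model is not fitted")
    normal_label, tumor_label = "normal", "tumor"
    for lab in (normal_label, tumor_label):
        if lab not in model.type_categories:
            raise ValueError(f"type category {lab!r} missing from model")
    result = transfer(model, data, meta)
    out = []
    for orig_label, transfer_label, tag in ((normal_label, tumor_label, "TT"),
                                            (tumor_label, normal_label, "TN")):
        idx = np.where(meta.type == orig_label)[0]
        if idx.size == 0:
            raise ValueError(f"no samples of type {orig_label!r}")
        orig_ids = [data.sample_ids[i] for i in idx]
        trans_ids = [f"{s}__{tag}" for s in orig_ids]
        values = np.concatenate(
            [data.values[:, idx], result.transfer_opposite.values[:, idx]], axis=1)
        matrix = ExpressionMatrix(values, data.gene_ids, orig_ids + trans_ids)
        tissues = np.concatenate([meta.tissue[idx], meta.tissue[idx]])
        types = np.asarray([orig_label] * len(idx) + [transfer_label] * len(idx),
                           dtype=object)
        out.append((matrix, SampleMetadata(orig_ids + trans_ids, tissues, types)))
    return out[0], out[1]
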