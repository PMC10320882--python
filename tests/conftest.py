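"""Shared fixtures.

Small fixtures (tiny datasets, quick models) for unit tests; session-scoped
benchmark fixtures — the default-scale synthetic study with its trained
classifier, discriminator, transferor and assembled transfer matrices — that
the end-to-end tests share so each model is trained once per run.
"""

from __future__ import annotations

import numpy as np
import pytest

import exprtransfer as et

BENCH_SEED = 0


@pytest.fixture(scope="session")
def small_dataset():
    cfg = et.SyntheticConfig(n_tissues=3, genes=60, samples_per_cell=10, seed=11)
    return et.generate_dataset(cfg)


@pytest.fixture(scope="session")
def small_scaled(small_dataset):
    data, meta, truth = small_dataset
    return et.max_scale(data), meta, truth


def quick_classifier_config(seed=0, epochs=40):
    return et.ClassifierConfig(encoder_units=(48,), bottleneck_dim=12,
                               head_units=(12,), epochs=epochs, batch_size=16,
                               seed=seed)


def quick_transferor_config(seed=0, epochs=60):
    return et.TransferorConfig(encoder_units=(48,), bottleneck_dim=12,
                               decoder_units=(48,), epochs=epochs, batch_size=16,
                               seed=seed)


@pytest.fixture(scope="session")
def small_classifier(small_scaled):
    data, meta, _ = small_scaled
    model, hist = et.fit_classifier(data, meta, quick_classifier_config())
    return model, hist


@pytest.fixture(scope="session")
def small_discriminator(small_classifier):
    model, _ = small_classifier
    return et.strip_reconstruction(model)


# --- default-scale benchmark (the study conditions) ---


@pytest.fixture(scope="session")
def bench_dataset():
    return et.generate_dataset(et.SyntheticConfig(seed=BENCH_SEED))


@pytest.fixture(scope="session")
def bench_scaled(bench_dataset):
    data, meta, truth = bench_dataset
    return et.max_scale(data), meta, truth


@pytest.fixture(scope="session")
def bench_folds(bench_scaled):
    _, meta, _ = bench_scaled
    return et.kfold_split(meta, 5, seed=BENCH_SEED)


@pytest.fixture(scope="session")
def bench_cv_models(bench_scaled, bench_folds):
    data, meta, _ = bench_scaled
    return et.train_classifier(data, meta, bench_folds,
                               et.ClassifierConfig(seed=BENCH_SEED))


@pytest.fixture(scope="session")
def bench_discriminator(bench_scaled):
    data, meta, _ = bench_scaled
    model, _ = et.fit_classifier(data, meta, et.ClassifierConfig(seed=BENCH_SEED))
    return et.strip_reconstruction(model)


@pytest.fixture(scope="session")
def bench_transferor(bench_scaled, bench_discriminator):
    """Trained transferor plus the discriminator checksum from before training."""
    data, meta, _ = bench_scaled
    checksum_before = bench_discriminator.checksum()
    model, hist = et.train_transferor(data, meta, bench_discriminator,
                                      et.TransferorConfig(seed=BENCH_SEED))
    return model, hist, checksum_before


@pytest.fixture(scope="session")
def bench_transfer_matrices(bench_scaled, bench_transferor):
    data, meta, _ = bench_scaled
    model, _, _ = bench_transferor
    return et.assemble_transfer_matrices(model, data, meta)


@pytest.fixture(scope="session")
def bench_oracle_classifier(bench_scaled):
    """Independently initialized/trained classifier used only for judging."""
    data, meta, _ = bench_scaled
    model, _ = et.fit_classifier(data, meta,
                                 et.ClassifierConfig(seed=BENCH_SEED + 1000))
    return model


def tissue_subset(matrix, meta, tissue):
    ids = [s for s, t in zip(matrix.sample_ids, meta.tissue) if t == tissue]
    return matrix.subset_samples(ids), meta.subset(ids)


@pytest.fixture(scope="session")
def bench_tissue_degs(bench_transfer_matrices, bench_scaled):
    """Per-tissue DEG tables of ON_TT and OT_TN."""
    (on_tt, on_m), (ot_tn, ot_m) = bench_transfer_matrices
    _, meta, _ = bench_scaled
    out = {}
    for tissue in sorted(set(meta.tissue)):
        sub_a, meta_a = tissue_subset(on_tt, on_m, tissue)
        sub_b, meta_b = tissue_subset(ot_tn, ot_m, tissue)
        out[tissue] = (et.differential_expression(sub_a, meta_a),
                       et.differential_expression(sub_b, meta_b))
    return out
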