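"""Expression-matrix containers, TSV I/O, max-scaling, label encoding, K-folds.

The matrix dialect is plain tab-delimited text: genes as rows, first column
the gene identifier, header row of sample identifiers. Metadata is a
3-column TSV (sample_id, tissue, type). Expression values are non-negative
reals (TPM-like); the only normalisation applied anywhere in the package is
per-gene max-scaling, which maps each gene to [0, 1] by dividing by its
maximum across samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

NORMAL = "normal"
TUMOR = "tumor"
TYPE_CATEGORIES = (NORMAL, TUMOR)


@dataclass
class ExpressionMatrix:
    """Gene x sample matrix of non-negative expression values."""

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (genes x samples)")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dupes = sorted({g for g in self.gene_ids if self.gene_ids.count(g) > 1})
            raise ValueError(f"duplicate gene ids: {dupes[:5]}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")
        if np.any(self.values < 0):
            raise ValueError("expression values must be non-negative")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in sample_ids]
        return ExpressionMatrix(self.values[:, idx], self.gene_ids, list(sample_ids))


@dataclass
class SampleMetadata:
    """Per-sample tissue and type (normal/tumor) labels."""

    sample_ids: list[str]
    tissue: np.ndarray
    type: np.ndarray

    def __post_init__(self):
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.tissue = np.asarray(self.tissue, dtype=object)
        self.type = np.asarray(self.type, dtype=object)
        n = len(self.sample_ids)
        if len(self.tissue) != n or len(self.type) != n:
            raise ValueError("tissue/type lengths must match sample_ids")
        bad = sorted(set(self.type) - set(TYPE_CATEGORIES))
        if bad:
            raise ValueError(f"type labels must be in {TYPE_CATEGORIES}, got {bad}")

    def __len__(self) -> int:
        return len(self.sample_ids)

    @property
    def tissue_categories(self) -> list[str]:
        return sorted(set(self.tissue))

    @property
    def type_categories(self) -> list[str]:
        return list(TYPE_CATEGORIES)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": self.sample_ids, "tissue": self.tissue, "type": self.type}
        )

    def subset(self, sample_ids) -> "SampleMetadata":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in sample_ids]
        return SampleMetadata(list(sample_ids), self.tissue[idx], self.type[idx])


@dataclass
class OneHotLabels:
    """Binary indicator matrix, one row per sample, one column per category."""

    matrix: np.ndarray
    categories: list[str]

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(self.categories):
            raise ValueError("one-hot matrix shape does not match categories")
        if not np.all(np.isin(self.matrix, (0.0, 1.0))):
            raise ValueError("one-hot entries must be 0 or 1")
        if not np.all(self.matrix.sum(axis=1) == 1):
            raise ValueError("each one-hot row must sum to exactly 1")

    def decode(self) -> np.ndarray:
        return np.asarray(
            [self.categories[j] for j in self.matrix.argmax(axis=1)], dtype=object
        )


@dataclass
class FoldAssignment:
    """Stratified K-fold partition: per-sample fold index in 0..k-1."""

    fold: np.ndarray
    k: int
    seed: int
    sample_ids: list[str] = field(default_factory=list)

    def test_indices(self, f: int) -> np.ndarray:
        return np.where(self.fold == f)[0]

    def train_indices(self, f: int) -> np.ndarray:
        return np.where(self.fold != f)[0]


def write_expression(m: ExpressionMatrix, path) -> None:
    df = m.to_frame()
    df.index.name = "gene_id"
    # %.17g guarantees exact float64 round-trips through text
    df.to_csv(path, sep="\t", float_format="%.17g")


def write_metadata(meta: SampleMetadata, path) -> None:
    meta.to_frame().to_csv(path, sep="\t", index=False)


def read_expression(path_matrix, path_metadata=None):
    """Read a TSV matrix (and optionally metadata); validate consistency.

    Returns ``ExpressionMatrix`` alone, or ``(ExpressionMatrix,
    SampleMetadata)`` when a metadata path is given. Sample order follows the
    matrix file; a sample-set mismatch between the two files is an error
    naming the offending ids.
    """
    df = pd.read_csv(path_matrix, sep="\t", index_col=0,
                     float_precision="round_trip")
    gene_ids = [str(g) for g in df.index]
    if len(set(gene_ids)) != len(gene_ids):
        raise ValueError(f"duplicate gene ids in {path_matrix}")
    m = ExpressionMatrix(df.to_numpy(dtype=float), gene_ids, [str(c) for c in df.columns])
    if path_metadata is None:
        return m
    md = pd.read_csv(path_metadata, sep="\t", dtype=str)
    required = {"sample_id", "tissue", "type"}
    if not required.issubset(md.columns):
        raise ValueError(f"metadata must have columns {sorted(required)}")
    meta_ids = set(md["sample_id"])
    mat_ids = set(m.sample_ids)
    if meta_ids != mat_ids:
        missing = sorted(mat_ids - meta_ids)
        extra = sorted(meta_ids - mat_ids)
        raise ValueError(
            "sample sets differ between matrix and metadata: "
            f"missing from metadata {missing[:10]}, not in matrix {extra[:10]}"
        )
    md = md.set_index("sample_id").loc[m.sample_ids]
    meta = SampleMetadata(m.sample_ids, md["tissue"].to_numpy(), md["type"].to_numpy())
    return m, meta


def fit_gene_max(m: ExpressionMatrix) -> np.ndarray:
    """Per-gene maximum over samples (the scaling denominator)."""
    return m.values.max(axis=1)


def max_scale(m: ExpressionMatrix, gene_max: np.ndarray | None = None,
              clip: bool = True) -> ExpressionMatrix:
    """Divide each gene row by its maximum across samples.

    With ``gene_max`` given (fitted on training folds), that denominator is
    applied instead and values are clipped to [0, 1] — the leakage-free
    cross-validation mode. Rows with max 0 are left all-zero. Default
    (``gene_max=None``) scales by the whole-dataset maximum.
    """
    if np.any(m.values < 0):
        raise ValueError("max_scale requires non-negative values")
    gm = fit_gene_max(m) if gene_max is None else np.asarray(gene_max, dtype=float)
    if gm.shape != (m.n_genes,):
        raise ValueError("gene_max length must equal number of genes")
    denom = np.where(gm > 0, gm, 1.0)
    scaled = m.values / denom[:, None]
    if clip:
        scaled = np.clip(scaled, 0.0, 1.0)
    return ExpressionMatrix(scaled, m.gene_ids, m.sample_ids)


def one_hot(meta: SampleMetadata, which: str,
            categories: list[str] | None = None) -> OneHotLabels:
    """Encode tissue or type labels as one-hot rows.

    Category order is lexicographic unless an explicit category list is
    provided (used to re-encode against a fitted model's category order).
    """
    if which == "tissue":
        labels = meta.tissue
    elif which == "type":
        labels = meta.type
    else:
        raise ValueError("which must be 'tissue' or 'type'")
    cats = sorted(set(labels)) if categories is None else list(categories)
    index = {c: j for j, c in enumerate(cats)}
    unseen = sorted(set(labels) - set(cats))
    if unseen:
        raise ValueError(f"labels not in category set: {unseen}")
    mat = np.zeros((len(labels), len(cats)))
    for i, lab in enumerate(labels):
        mat[i, index[lab]] = 1.0
    return OneHotLabels(mat, cats)


def labels_to_one_hot(labels, categories) -> OneHotLabels:
    """One-hot encode an arbitrary label vector against a fixed category order."""
    index = {c: j for j, c in enumerate(categories)}
    unseen = sorted(set(labels) - set(categories))
    if unseen:
        raise ValueError(f"labels not in category set: {unseen}")
    mat = np.zeros((len(labels), len(categories)))
    for i, lab in enumerate(labels):
        mat[i, index[lab]] = 1.0
    return OneHotLabels(mat, list(categories))


def kfold_split(meta: SampleMetadata, k: int, seed: int) -> FoldAssignment:
    """Stratified K-fold assignment over (tissue, type) strata.

    Within each stratum samples are shuffled and dealt round-robin across
    folds with a rotating offset, so every (tissue, type) cell appears in
    every fold whenever its size permits and test fractions are 1/k within
    one sample per stratum. Strata smaller than k trigger a warning (they
    cannot reach all folds) but are still dealt deterministically.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    n = len(meta)
    if n < k:
        raise ValueError(f"cannot split {n} samples into {k} folds")
    rng = np.random.default_rng(seed)
    fold = np.full(n, -1, dtype=int)
    strata: dict[tuple, list[int]] = {}
    for i in range(n):
        strata.setdefault((meta.tissue[i], meta.type[i]), []).append(i)
    offset = 0
    for key in sorted(strata):
        idx = np.array(strata[key])
        if len(idx) < k:
            warnings.warn(
                f"stratum {key} has {len(idx)} samples < k={k}; "
                "it cannot appear in every fold",
                stacklevel=2,
            )
        rng.shuffle(idx)
        for j, i in enumerate(idx):
            fold[i] = (j + offset) % k
        offset = (offset + len(idx)) % k
    return FoldAssignment(fold, k, seed, list(meta.sample_ids))
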