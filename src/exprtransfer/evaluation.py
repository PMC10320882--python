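"""Performance and biological evaluation.

Confusion matrices and per-class precision/recall/F1 (mean +/- SD across
cross-validation folds), evaluation of transferred profiles through the
classifier, PCA + seven classic-ML baselines under shared K-fold splits,
per-gene differential expression between tumor and normal groups
(Welch t-test on log2 pseudocounted values, Benjamini-Hochberg adjusted,
|LFC| and adjusted-p thresholds), the up/down intersection true-positive
rates between the ON_TT and OT_TN DEG sets, and 2-D PCA sample plots.

Classes absent from both the true and predicted labels get NaN sentinels
for precision/recall/F1 rather than an error (an empty class in a fold is a
legitimate outcome, printed as NaN in the tables, serialized as null).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from statsmodels.stats.multitest import multipletests

from .io_prep import ExpressionMatrix, FoldAssignment, SampleMetadata


@dataclass
class ConfusionMatrix:
    """Square count matrix; rows = true category, columns = predicted."""

    counts: np.ndarray
    categories: list[str]

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        k = len(self.categories)
        if self.counts.shape != (k, k):
            raise ValueError("confusion matrix must be square over the categories")
        if np.any(self.counts < 0):
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.counts) / self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.categories, columns=self.categories)


def confusion(true_labels, pred_labels, categories) -> ConfusionMatrix:
    true_labels = np.asarray(true_labels, dtype=object)
    pred_labels = np.asarray(pred_labels, dtype=object)
    if len(true_labels) != len(pred_labels):
        raise ValueError("true and predicted label vectors differ in length")
    cats = list(categories)
    index = {c: i for i, c in enumerate(cats)}
    bad = sorted((set(true_labels) | set(pred_labels)) - set(cats))
    if bad:
        raise ValueError(f"labels outside the category set: {bad}")
    counts = np.zeros((len(cats), len(cats)), dtype=int)
    for t, p in zip(true_labels, pred_labels):
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts, cats)


def metrics_from_confusion(cm: ConfusionMatrix) -> pd.DataFrame:
    """Per-class precision, recall and F1 for one fold.

    Precision = TP/(TP+FP), recall = TP/(TP+FN), F1 their harmonic mean.
    A class with neither true nor predicted samples gets NaN for all three;
    a defined-but-degenerate ratio (0/0 with support present) is 0.
    """
    c = cm.counts.astype(float)
    tp = np.diag(c)
    fp = c.sum(axis=0) - tp
    fn = c.sum(axis=1) - tp
    rows = []
    for i, cat in enumerate(cm.categories):
        if tp[i] + fp[i] + fn[i] == 0:
            p = r = f1 = np.nan
        else:
            p = tp[i] / (tp[i] + fp[i]) if tp[i] + fp[i] > 0 else 0.0
            r = tp[i] / (tp[i] + fn[i]) if tp[i] + fn[i] > 0 else 0.0
            f1 = 2 * p * r / (p + r) if p + r > 0 else 0.0
        rows.append({"category": cat, "precision": p, "recall": r, "f1": f1})
    return pd.DataFrame(rows).set_index("category")


def aggregate_fold_metrics(per_fold: list[pd.DataFrame]) -> pd.DataFrame:
    """Mean and SD of each metric across folds (NaN-aware)."""
    stacked = pd.concat(per_fold, keys=range(len(per_fold)), names=["fold"])
    out = {}
    for col in ("precision", "recall", "f1"):
        grp = stacked[col].groupby(level="category")
        out[f"{col}_mean"] = grp.mean()
        out[f"{col}_sd"] = grp.std(ddof=0)
    return pd.DataFrame(out)


def macro_f1(true_labels, pred_labels, categories) -> float:
    m = metrics_from_confusion(confusion(true_labels, pred_labels, categories))
    return float(m["f1"].mean(skipna=True))


def evaluate_transfer(disc, transfer_matrix: ExpressionMatrix,
                      transfer_meta: SampleMetadata,
                      folds: FoldAssignment | None = None):
    """Score transferred profiles with the (frozen or plain) classifier.

    ``transfer_meta`` carries each transferred sample's expected labels
    (same tissue as its source, opposite type). Returns a dict with tissue
    and type confusion matrices and per-class metric tables; with ``folds``
    given, metrics are computed per fold and aggregated mean +/- SD.
    """
    t_pred, y_pred = disc.predict_labels(transfer_matrix)
    t_true, y_true = transfer_meta.tissue, transfer_meta.type
    tissue_cats = disc.tissue_categories
    type_cats = disc.type_categories
    out = {
        "tissue_confusion": confusion(t_true, t_pred, tissue_cats),
        "type_confusion": confusion(y_true, y_pred, type_cats),
    }
    if folds is None:
        out["tissue_metrics"] = metrics_from_confusion(out["tissue_confusion"])
        out["type_metrics"] = metrics_from_confusion(out["type_confusion"])
    else:
        per_t, per_y = [], []
        for f in range(folds.k):
            idx = folds.test_indices(f)
            per_t.append(metrics_from_confusion(
                confusion(t_true[idx], t_pred[idx], tissue_cats)))
            per_y.append(metrics_from_confusion(
                confusion(y_true[idx], y_pred[idx], type_cats)))
        out["tissue_metrics"] = aggregate_fold_metrics(per_t)
        out["type_metrics"] = aggregate_fold_metrics(per_y)
    return out


BASELINE_FACTORIES = {
    "SVC": lambda seed: SVC(random_state=seed),
    "LR": lambda seed: LogisticRegression(max_iter=2000, random_state=seed),
    "LDA": lambda seed: LinearDiscriminantAnalysis(),
    "NBayes": lambda seed: GaussianNB(),
    "DTree": lambda seed: DecisionTreeClassifier(random_state=seed),
    "RForest": lambda seed: RandomForestClassifier(random_state=seed),
    "KNN": lambda seed: KNeighborsClassifier(),
}


def run_baselines(m: ExpressionMatrix, labels, folds: FoldAssignment,
                  pca_dim: int, seed: int = 0) -> pd.DataFrame:
    """Seven classic classifiers on PCA-reduced expression under shared folds.

    PCA is fitted on the training folds only (no leakage into the test
    fold); every model sees the same fold assignment. Returns a table with
    per-model accuracy and macro-F1, mean +/- SD across folds.
    """
    labels = np.asarray(labels, dtype=object)
    X = m.values.T
    if pca_dim >= min(X.shape[0], X.shape[1]):
        raise ValueError(
            f"pca_dim={pca_dim} must be < min(samples, genes)={min(X.shape)}")
    cats = sorted(set(labels))
    acc: dict[str, list[float]] = {name: [] for name in BASELINE_FACTORIES}
    f1s: dict[str, list[float]] = {name: [] for name in BASELINE_FACTORIES}
    for f in range(folds.k):
        tr, te = folds.train_indices(f), folds.test_indices(f)
        pca = PCA(n_components=pca_dim, random_state=seed)
        Xtr = pca.fit_transform(X[tr])
        Xte = pca.transform(X[te])
        for name, factory in BASELINE_FACTORIES.items():
            clf = factory(seed)
            clf.fit(Xtr, labels[tr])
            pred = clf.predict(Xte)
            acc[name].append(float(np.mean(pred == labels[te])))
            f1s[name].append(macro_f1(labels[te], pred, cats))
    rows = []
    for name in BASELINE_FACTORIES:
        rows.append({
            "model": name,
            "accuracy_mean": float(np.mean(acc[name])),
            "accuracy_sd": float(np.std(acc[name])),
            "macro_f1_mean": float(np.mean(f1s[name])),
            "macro_f1_sd": float(np.std(f1s[name])),
        })
    return pd.DataFrame(rows).set_index("model")


def differential_expression(m: ExpressionMatrix, meta: SampleMetadata,
                            alpha: float = 0.05, lfc_threshold: float = 1.0,
                            pseudocount: float = 1e-6,
                            moderated: bool = False) -> pd.DataFrame:
    """Per-gene tumor-vs-normal differential expression.

    LFC is log2(mean tumor / mean normal) on pseudocounted values; the test
    is a per-gene Welch t-test on log2(pseudocount + value), with optional
    moderated variance (gene-wise variances shrunk halfway toward their
    mean, a simple empirical-Bayes stabilisation). P-values are BH-adjusted
    across all genes. Calls: up if adj p <= alpha and LFC >= +threshold,
    down if adj p <= alpha and LFC <= -threshold, else ns.
    """
    tumor_idx = np.where(meta.type == "tumor")[0]
    normal_idx = np.where(meta.type == "normal")[0]
    if tumor_idx.size < 2 or normal_idx.size < 2:
        raise ValueError("need at least 2 samples per group")
    vals = m.values + pseudocount
    lfc = np.log2(vals[:, tumor_idx].mean(axis=1) / vals[:, normal_idx].mean(axis=1))
    logv = np.log2(vals)
    a, b = logv[:, tumor_idx], logv[:, normal_idx]
    if moderated:
        va, vb = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
        va = 0.5 * va + 0.5 * va.mean()
        vb = 0.5 * vb + 0.5 * vb.mean()
        na, nb = a.shape[1], b.shape[1]
        se = np.sqrt(va / na + vb / nb)
        t = (a.mean(axis=1) - b.mean(axis=1)) / np.where(se > 0, se, np.inf)
        df = na + nb - 2
        p = 2 * stats.t.sf(np.abs(t), df)
    else:
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
        p = np.where(np.isnan(p), 1.0, p)
    _, adj_p, _, _ = multipletests(p, method="fdr_bh")
    call = np.where((adj_p <= alpha) & (lfc >= lfc_threshold), "up",
                    np.where((adj_p <= alpha) & (lfc <= -lfc_threshold), "down", "ns"))
    return pd.DataFrame(
        {"lfc": lfc, "p": p, "adj_p": adj_p, "call": call}, index=m.gene_ids
    ).rename_axis("gene")


@dataclass
class TPRResult:
    """Up/down DEG-set intersection true-positive rates between two analyses.

    tpr = |A intersect B| / mean(|A|, |B|); NaN when both sets are empty.
    """

    intersect_up: int
    intersect_down: int
    n_up_a: int
    n_up_b: int
    n_down_a: int
    n_down_b: int
    tpr_up: float
    tpr_down: float
    up_genes: list[str]
    down_genes: list[str]


def true_positive_rates(deg_a: pd.DataFrame, deg_b: pd.DataFrame) -> TPRResult:
    """Intersection-over-mean-size rates of the up and down DEG sets."""
    if set(deg_a.index) != set(deg_b.index):
        raise ValueError("DEG results must share the same gene universe")
    sets = {}
    for direction in ("up", "down"):
        sa = set(deg_a.index[deg_a["call"] == direction])
        sb = set(deg_b.index[deg_b["call"] == direction])
        inter = sa & sb
        mean_size = (len(sa) + len(sb)) / 2
        tpr = len(inter) / mean_size if mean_size > 0 else float("nan")
        sets[direction] = (sa, sb, inter, tpr)
    (ua, ub, ui, tu) = sets["up"]
    (da, db, di, td) = sets["down"]
    return TPRResult(len(ui), len(di), len(ua), len(ub), len(da), len(db),
                     tu, td, sorted(ui), sorted(di))


def pca_coordinates(m: ExpressionMatrix, n_components: int = 2) -> np.ndarray:
    """Deterministic PCA coordinates (sign fixed: largest-|loading| positive)."""
    X = m.values.T
    if X.shape[0] < n_components:
        raise ValueError("need at least n_components samples")
    if np.allclose(X.std(axis=0), 0):
        raise ValueError("matrix is constant; PCA undefined")
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(X)
    for j in range(n_components):
        comp = pca.components_[j]
        if comp[np.argmax(np.abs(comp))] < 0:
            coords[:, j] *= -1
    return coords


def pca_plot(m: ExpressionMatrix, meta: SampleMetadata, n_components: int = 2,
             path=None):
    """2-D PCA of samples, colored by type, marker by origin (original vs
    transfer, inferred from a ``__`` suffix in the sample id). Returns the
    coordinates; saves a figure when ``path`` is given."""
    coords = pca_coordinates(m, n_components)
    if path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 5))
        origin = np.asarray(["transfer" if "__" in s else "original"
                             for s in m.sample_ids])
        colors = {"normal": "tab:blue", "tumor": "tab:red"}
        markers = {"original": "o", "transfer": "^"}
        for type_label in sorted(set(meta.type)):
            for orig in ("original", "transfer"):
                sel = (meta.type == type_label) & (origin == orig)
                if sel.any():
                    ax.scatter(coords[sel, 0], coords[sel, 1], s=18, alpha=0.7,
                               c=colors.get(type_label, "gray"),
                               marker=markers[orig],
                               label=f"{type_label} ({orig})")
        ax.set_xlabel("PC1")
        ax.set_ylabel("PC2")
        ax.legend(fontsize=8)
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return coords
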