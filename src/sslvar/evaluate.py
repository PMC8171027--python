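"""Metrics and experiment drivers: ROC/AUC, feature-label correlations,
feature-group ablations, stratified k-fold cross-validation and cross-cell-line
transfer with Welch two-tailed t-tests.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold

from sslvar.features import (
    COMPOSITION_NAMES,
    FeatureTable,
    TABULAR_COLUMNS,
)
from sslvar.genomic_io import MARKS
from sslvar.network import ModelConfig
from sslvar.ssl_train import (
    DatasetSplit,
    PseudoLabelClassifier,
    SSLResults,
    TrainConfig,
    make_split,
)

logger = logging.getLogger(__name__)


class MetricError(ValueError):
    """A metric was asked to score an input it is undefined on."""


#: The functional feature groups: the six mark categories plus the two
#: input-branch groups (composition-only and sequence-only).
FEATURE_GROUPS: dict[str, tuple[str, ...]] = {
    "I": ("H3K4me1", "H3K27ac"),                 # enhancer marks
    "II": ("H3K4me2", "H3K4me3", "H3K9ac"),      # promoter marks
    "III": ("H3K36me3", "H3K79me2"),             # structural marks
    "IV": ("H3K9me3", "H3K27me3"),               # heterochromatin marks
    "V": ("H4K20me1",),                          # transcribed gene body
    "VI": ("DNase",),                            # DNA accessibility
    "Nuc-based": COMPOSITION_NAMES,
    "Seq-based": (),                             # one-hot branch only
}


@dataclass
class RocResult:
    """An ROC curve with its area; points come from every score threshold."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> RocResult:
    """ROC curve and AUC of positive-class scores against 0/1 labels.

    AUC is computed by the rank (Mann-Whitney) statistic with ties averaged,
    which equals the trapezoidal area under the stored ROC points.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if len(scores) != len(labels):
        raise MetricError("scores and labels differ in length")
    if len(np.unique(labels)) < 2:
        raise MetricError("roc_auc needs both classes present")
    fpr, tpr, thr = roc_curve(labels, scores)
    return RocResult(thr, fpr, tpr, float(_trapezoid_auc(fpr, tpr)))


def accuracy(predictions: np.ndarray, labels: np.ndarray) -> float:
    """Fraction of correctly predicted labels."""
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    if predictions.shape != labels.shape:
        raise MetricError(
            f"length mismatch: {predictions.shape} vs {labels.shape}"
        )
    if len(predictions) == 0:
        raise MetricError("accuracy of an empty prediction set is undefined")
    return float((predictions == labels).mean())


def feature_label_correlation(feature: np.ndarray, labels: np.ndarray) -> float:
    """Pearson r between one feature column and the 0/1 label vector.

    A constant feature has no defined correlation; it returns 0.0 with a
    warning so feature screens over many columns stay total.
    """
    feature = np.asarray(feature, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if np.std(feature) == 0 or np.std(labels) == 0:
        warnings.warn("constant input; returning r = 0", stacklevel=2)
        return 0.0
    r, _ = stats.pearsonr(feature, labels)
    return float(r)


def correlation_screen(table: FeatureTable) -> pd.Series:
    """Pearson r of every tabular column against the labels, labeled loci only."""
    mask = table.labels >= 0
    y = table.labels[mask]
    return pd.Series(
        {
            name: feature_label_correlation(table.tabular[mask, i], y)
            for i, name in enumerate(table.columns)
        },
        name="pearson_r",
    )


def _mask_table(
    table: FeatureTable, group: str, score_type: str, tabular_only: bool = False
) -> FeatureTable:
    """Restrict a table to one feature group: excluded tabular columns are
    zeroed (the architecture stays fixed); the one-hot branch is zeroed for
    every group except Seq-based, which conversely zeroes all tabular columns.
    """
    if group not in FEATURE_GROUPS:
        raise KeyError(f"unknown feature group {group!r}")
    tab = np.zeros_like(table.tabular)
    onehot = table.onehot
    if group == "Seq-based":
        pass  # tabular all zero, sequence kept
    elif group == "Nuc-based":
        keep = [i for i, c in enumerate(table.columns) if c in COMPOSITION_NAMES]
        tab[:, keep] = table.tabular[:, keep]
        onehot = np.zeros_like(table.onehot)
    else:
        cols = [f"{m}_{score_type.lower()}" for m in FEATURE_GROUPS[group]]
        keep = [i for i, c in enumerate(table.columns) if c in cols]
        tab[:, keep] = table.tabular[:, keep]
        if tabular_only:
            onehot = np.zeros_like(table.onehot)
    return FeatureTable(onehot, tab, table.labels, table.loci, table.columns)


def group_ablation(
    split: DatasetSplit,
    groups: Sequence[str] = tuple(FEATURE_GROUPS),
    score_type: str = "Max",
    model_config: Optional[ModelConfig] = None,
    train_config: Optional[TrainConfig] = None,
    tabular_only: bool = False,
) -> pd.DataFrame:
    """Train one model per feature group and report its validation AUC.

    Each run keeps the full architecture and the same seeds; only the input
    differs: mark groups keep their Peak/Max/Sum columns of ``score_type``
    (others zeroed), Nuc-based keeps only the composition columns, Seq-based
    keeps only the one-hot branch.  By default mark groups retain the sequence
    branch; ``tabular_only=True`` zeroes it.
    """
    if score_type not in ("Peak", "Max", "Sum"):
        raise KeyError(f"score_type must be Peak, Max or Sum, got {score_type!r}")
    rows = []
    for group in groups:
        masked = _mask_table(split.table, group, score_type, tabular_only)
        g_split = DatasetSplit(
            masked, split.labeled_idx, split.unlabeled_idx, split.val_idx
        )
        res = PseudoLabelClassifier(g_split, model_config, train_config).fit()
        rows.append({"group": group, "score_type": score_type,
                     "val_auc": res.val_auc, "val_acc": res.val_acc})
        logger.info("ablation group %s: AUC %.3f", group, res.val_auc)
    return pd.DataFrame(rows)


@dataclass
class CVResult:
    """Per-fold metrics with their mean and standard error (sd / sqrt(k))."""

    folds: pd.DataFrame
    results: list[SSLResults]

    def __getitem__(self, metric: str) -> tuple[float, float]:
        vals = self.folds[metric].to_numpy()
        return float(vals.mean()), float(vals.std(ddof=1) / np.sqrt(len(vals)))

    def summary(self) -> pd.DataFrame:
        rows = {}
        for metric in ("auc", "acc"):
            mean, se = self[metric]
            rows[metric] = {"mean": mean, "se": se}
        return pd.DataFrame(rows).T


def kfold_cv(
    table: FeatureTable,
    k: int = 5,
    n_labeled: Optional[int] = None,
    model_config: Optional[ModelConfig] = None,
    train_config: Optional[TrainConfig] = None,
    seed: int = 0,
) -> CVResult:
    """Stratified k-fold cross-validation, each fold trained from scratch.

    The held-out fold becomes the validation set (balanced by seeded
    subsampling of the majority class); the k-1 training folds are split into
    a balanced labeled part (``n_labeled`` loci, default: as many as balance
    allows) and an unlabeled remainder.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    labeled_mask = table.labels >= 0
    idx_all = np.flatnonzero(labeled_mask)
    y_all = table.labels[idx_all]
    if min((y_all == 1).sum(), (y_all == 0).sum()) < k:
        raise SizingErrorFromCV(k, y_all)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    rows, results = [], []
    for fold, (train_i, test_i) in enumerate(skf.split(idx_all, y_all)):
        rng = np.random.default_rng(seed + 1000 + fold)
        test_idx = idx_all[test_i]
        y_test = table.labels[test_idx]
        n_bal = min((y_test == 1).sum(), (y_test == 0).sum())
        val_idx = np.concatenate([
            rng.permutation(test_idx[y_test == 1])[:n_bal],
            rng.permutation(test_idx[y_test == 0])[:n_bal],
        ])
        train_idx = idx_all[train_i]
        y_train = table.labels[train_idx]
        n_lab = n_labeled
        if n_lab is None:
            n_lab = 2 * min((y_train == 1).sum(), (y_train == 0).sum())
        lab_idx = np.concatenate([
            rng.permutation(train_idx[y_train == 1])[: n_lab // 2],
            rng.permutation(train_idx[y_train == 0])[: n_lab // 2],
        ])
        pool_idx = np.setdiff1d(
            np.concatenate([train_idx, np.flatnonzero(table.labels == -1)]),
            lab_idx,
        )
        split = DatasetSplit(table, np.sort(lab_idx), pool_idx, np.sort(val_idx))
        res = PseudoLabelClassifier(split, model_config, train_config).fit()
        rows.append({"fold": fold, "auc": res.val_auc, "acc": res.val_acc})
        results.append(res)
    return CVResult(pd.DataFrame(rows), results)


class SizingErrorFromCV(ValueError):
    def __init__(self, k: int, y: np.ndarray):
        super().__init__(
            f"cannot build {k} stratified folds from "
            f"{(y == 1).sum()} positives / {(y == 0).sum()} negatives"
        )


@dataclass
class TransferMatrix:
    """Cross-cell-line transfer results.

    ``scores[train_cell][test_cell]`` holds the k per-fold AUC/accuracy pairs;
    ``table()`` renders means, standard errors and the Welch two-tailed t-test
    p-value comparing within-cell and cross-cell AUCs for each pair.
    """

    cells: list[str]
    scores: dict[str, dict[str, pd.DataFrame]]

    def table(self) -> pd.DataFrame:
        rows = []
        for tr in self.cells:
            within = self.scores[tr][tr]["auc"].to_numpy()
            for te in self.cells:
                df = self.scores[tr][te]
                aucs = df["auc"].to_numpy()
                k = len(aucs)
                row = {
                    "train_cell": tr,
                    "test_cell": te,
                    "auc_mean": aucs.mean(),
                    "auc_se": aucs.std(ddof=1) / np.sqrt(k),
                    "acc_mean": df["acc"].mean(),
                    "acc_se": df["acc"].std(ddof=1) / np.sqrt(k),
                }
                if te != tr:
                    row["p_value"] = float(
                        stats.ttest_ind(within, aucs, equal_var=False).pvalue
                    )
                else:
                    row["p_value"] = np.nan
                rows.append(row)
        return pd.DataFrame(rows)


def transfer_eval(
    tables: dict[str, FeatureTable],
    k: int = 5,
    n_labeled: Optional[int] = None,
    val_sizes: Optional[dict[str, tuple[int, Optional[int], int]]] = None,
    model_config: Optional[ModelConfig] = None,
    train_config: Optional[TrainConfig] = None,
    seed: int = 0,
) -> TransferMatrix:
    """Train per cell line with k-fold CV and score every fold's model on every
    other cell line's validation set.

    The diagonal uses each fold's own held-out loci (never its training data);
    off-diagonal entries score the same k models on a fixed balanced
    validation split of the other cell line, so each (train, test) pair yields
    k AUCs and a Welch two-tailed t-test against the k within-cell AUCs.
    """
    if len(tables) < 2:
        raise ValueError("transfer_eval needs at least two cell lines")
    cells = list(tables)
    # fixed balanced validation subset per cell for cross-cell scoring
    foreign_val: dict[str, FeatureTable] = {}
    for cell, table in tables.items():
        if val_sizes and cell in val_sizes:
            split = make_split(table, val_sizes[cell], seed)
        else:
            y = table.labels
            n_bal = min((y == 1).sum(), (y == 0).sum())
            n_val = 2 * (n_bal // 4)  # a quarter of the balanced capacity each
            split = make_split(table, (2 * (n_bal // 2) - n_val, None, n_val), seed)
        foreign_val[cell] = split.validation
    scores: dict[str, dict[str, pd.DataFrame]] = {}
    for cell in cells:
        cv = kfold_cv(tables[cell], k, n_labeled, model_config, train_config, seed)
        scores[cell] = {cell: cv.folds[["auc", "acc"]]}
        for other in cells:
            if other == cell:
                continue
            rows = []
            vt = foreign_val[other]
            for res in cv.results:
                probs = res.predict_proba(vt)
                rows.append({
                    "auc": roc_auc(probs[:, 1], vt.labels).auc,
                    "acc": accuracy(res.predict(vt), vt.labels),
                })
            scores[cell][other] = pd.DataFrame(rows)
    return TransferMatrix(cells, scores)
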