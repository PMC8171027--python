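"""Semi-supervised training with pseudo labels.

The loss is ``L = L_label + alpha(t) * L_unlabel`` where both terms are mean
cross-entropies — the labeled term against true labels, the unlabeled term
against the model's own argmax predictions (pseudo labels) — and ``alpha(t)``
ramps linearly from 0 to 1 between optimizer steps T1 and T2.  At the end of
every epoch, unlabeled examples whose predicted class probability reaches the
confidence threshold are promoted permanently into the labeled pool carrying
their pseudo label.  A supervised baseline mode runs the identical loop with
``alpha`` pinned to 0 and promotion disabled.

The modelling surface follows the familiar model/results pattern:
``PseudoLabelClassifier(split).fit()`` returns an :class:`SSLResults` holding
the trained network, the per-epoch history, the promotion audit trail and a
``summary()`` table.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from sslvar.features import FeatureTable, Preprocessor
from sslvar.network import ModelConfig, Network


class SizingError(ValueError):
    """Requested split sizes cannot be satisfied by the available loci."""


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation hyper-parameters.

    Defaults are the reference settings: SGD with learning rate 0.03 and no
    momentum; mini-batches of 16 labeled, 32 unlabeled and 20 validation
    examples; confidence threshold 0.95 for promoting pseudo-labels; the
    alpha(t) ramp between global steps T1 = 100 and T2 = 600.
    """

    learning_rate: float = 0.03
    batch_labeled: int = 16
    batch_unlabeled: int = 32
    batch_validation: int = 20
    confidence_threshold: float = 0.95
    T1: int = 100
    T2: int = 600
    epochs: int = 100
    mode: str = "ssl"                 # "ssl" or "supervised"
    momentum: float = 0.0
    seed: int = 0
    promotion: bool = True            # SSL only; False freezes the pool
    alpha_override: Optional[float] = None  # pin alpha (diagnostics)

    def __post_init__(self) -> None:
        if not (0 < self.confidence_threshold <= 1):
            raise ValueError("confidence_threshold must be in (0, 1]")
        if self.T1 >= self.T2:
            raise ValueError(f"T1 ({self.T1}) must be < T2 ({self.T2})")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.mode not in ("ssl", "supervised"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class DatasetSplit:
    """Labeled-train / unlabeled-train / validation partition of a FeatureTable.

    The three index sets are disjoint; labeled and validation parts are
    class-balanced.  True labels of the unlabeled part stay in the table but
    are used only for post-hoc audit, never during training.
    """

    table: FeatureTable
    labeled_idx: np.ndarray
    unlabeled_idx: np.ndarray
    val_idx: np.ndarray

    def __post_init__(self) -> None:
        parts = [self.labeled_idx, self.unlabeled_idx, self.val_idx]
        all_idx = np.concatenate(parts)
        if len(np.unique(all_idx)) != len(all_idx):
            raise ValueError("split parts are not disjoint")
        for name, idx in (("labeled", self.labeled_idx), ("validation", self.val_idx)):
            y = self.table.labels[idx]
            if np.any(y < 0):
                raise ValueError(f"{name} part contains unlabeled loci")
            if (y == 1).sum() != (y == 0).sum():
                raise ValueError(f"{name} part is not class-balanced")

    @property
    def labeled(self) -> FeatureTable:
        return self.table.subset(self.labeled_idx)

    @property
    def unlabeled(self) -> FeatureTable:
        return self.table.subset(self.unlabeled_idx)

    @property
    def validation(self) -> FeatureTable:
        return self.table.subset(self.val_idx)

    def counts(self) -> dict[str, tuple[int, int, int]]:
        """Per part: (total, positives, negatives) — negatives exclude hidden-unlabeled."""
        out = {}
        for name, idx in (("labeled", self.labeled_idx),
                          ("unlabeled", self.unlabeled_idx),
                          ("validation", self.val_idx)):
            y = self.table.labels[idx]
            out[name] = (len(idx), int((y == 1).sum()), int((y == 0).sum()))
        return out


def make_split(
    table: FeatureTable,
    sizes: tuple[int, Optional[int], int],
    seed: int = 0,
) -> DatasetSplit:
    """Stratified seeded split into (labeled, unlabeled, validation) parts.

    ``sizes`` is ``(n_labeled, n_unlabeled, n_validation)``; labeled and
    validation take equal numbers of positives and negatives (so both sizes
    must be even), and ``n_unlabeled=None`` sends every remaining locus to the
    unlabeled pool — which is therefore typically class-imbalanced.
    """
    n_labeled, n_unlabeled, n_val = sizes
    if n_labeled % 2 or n_val % 2:
        raise SizingError("labeled and validation sizes must be even (balanced halves)")
    rng = np.random.default_rng(seed)
    pos = rng.permutation(np.flatnonzero(table.labels == 1))
    neg = rng.permutation(np.flatnonzero(table.labels == 0))
    need_pos = n_labeled // 2 + n_val // 2
    need_neg = need_pos
    if len(pos) < need_pos or len(neg) < need_neg:
        raise SizingError(
            f"need {need_pos} positives and {need_neg} negatives for balanced "
            f"labeled+validation parts; have {len(pos)}/{len(neg)}"
        )
    lab = np.concatenate([pos[: n_labeled // 2], neg[: n_labeled // 2]])
    val = np.concatenate([pos[n_labeled // 2: need_pos], neg[n_labeled // 2: need_neg]])
    rest = np.concatenate([
        pos[need_pos:], neg[need_neg:], np.flatnonzero(table.labels == -1)
    ])
    rest = rng.permutation(rest)
    if n_unlabeled is not None:
        if len(rest) < n_unlabeled:
            raise SizingError(
                f"requested {n_unlabeled} unlabeled loci, only {len(rest)} remain"
            )
        rest = rest[:n_unlabeled]
    return DatasetSplit(table, np.sort(lab), np.sort(rest), np.sort(val))


def alpha_schedule(t: int, T1: int, T2: int) -> float:
    """Piecewise-linear unlabeled-loss weight: 0 before T1, 1 after T2.

    ``alpha(t) = (t - T1) / (T2 - T1)`` on the ramp; the boundary points t=T1
    and t=T2 take 0 and 1 by continuity.
    """
    if T1 >= T2:
        raise ValueError("alpha_schedule requires T1 < T2")
    if t <= T1:
        return 0.0
    if t >= T2:
        return 1.0
    return (t - T1) / (T2 - T1)


def pseudo_label(probs: np.ndarray) -> np.ndarray:
    """Per-row argmax class; exact ties break toward class 0."""
    probs = np.atleast_2d(probs)
    return (probs[:, 1] > probs[:, 0]).astype(np.int64)


def promote_confident(
    probs: np.ndarray, threshold: float = 0.95
) -> tuple[np.ndarray, np.ndarray]:
    """Select pool rows whose maximum class probability reaches the threshold.

    Returns ``(promote_mask, labels)``: a boolean mask over the pool (order
    preserved; the complement is the remaining pool) and the pseudo labels of
    every row.  Promotion is irreversible by contract — callers move masked
    rows into the labeled set permanently.
    """
    probs = np.atleast_2d(probs)
    return probs.max(axis=1) >= threshold, pseudo_label(probs)


@dataclass
class LossComponents:
    L_label: float
    L_unlabel: float
    alpha: float
    t: int

    @property
    def L(self) -> float:
        return self.L_label + self.alpha * self.L_unlabel


def combined_loss(
    labeled_batch: tuple[np.ndarray, np.ndarray, np.ndarray],
    unlabeled_batch: Optional[tuple[np.ndarray, np.ndarray]],
    model: Network,
    t: int,
    config: TrainConfig,
) -> LossComponents:
    """Evaluate ``L = L_label + alpha(t) * L_unlabel`` for one batch pair.

    Deterministic (evaluation-mode forward).  The unlabeled term is the
    cross-entropy of the model's predictions against their own argmax pseudo
    labels; an absent or empty unlabeled batch contributes 0.
    """
    oh, tab, y = labeled_batch
    probs = model.predict_proba(oh, tab)
    l_label = float(-np.log(np.clip(probs[np.arange(len(y)), y], 1e-12, None)).mean())
    l_unlabel = 0.0
    if unlabeled_batch is not None and len(unlabeled_batch[0]):
        u_oh, u_tab = unlabeled_batch
        u_probs = model.predict_proba(u_oh, u_tab)
        u_y = pseudo_label(u_probs)
        l_unlabel = float(
            -np.log(np.clip(u_probs[np.arange(len(u_y)), u_y], 1e-12, None)).mean()
        )
    alpha = 0.0 if config.mode == "supervised" else alpha_schedule(t, config.T1, config.T2)
    if config.alpha_override is not None:
        alpha = config.alpha_override
    return LossComponents(l_label, l_unlabel, alpha, t)


class PseudoLabelClassifier:
    """Model object: a two-branch network trained on a :class:`DatasetSplit`.

    Preprocessing statistics (log1p + z-score) are fitted on the labeled
    training part only and reapplied to the unlabeled pool and the validation
    set.  ``fit()`` runs the full training loop and returns
    :class:`SSLResults`.
    """

    def __init__(
        self,
        split: DatasetSplit,
        model_config: Optional[ModelConfig] = None,
        train_config: Optional[TrainConfig] = None,
    ):
        self.split = split
        self.model_config = model_config or ModelConfig()
        self.train_config = train_config or TrainConfig()
        self.preprocessor = Preprocessor().fit(split.labeled.tabular)

    @classmethod
    def from_feature_table(
        cls,
        table: FeatureTable,
        sizes: tuple[int, Optional[int], int],
        model_config: Optional[ModelConfig] = None,
        train_config: Optional[TrainConfig] = None,
        split_seed: int = 0,
    ) -> "PseudoLabelClassifier":
        return cls(make_split(table, sizes, split_seed), model_config, train_config)

    def fit(self) -> "SSLResults":
        cfg = self.train_config
        net = Network(self.model_config)
        rng = np.random.default_rng(cfg.seed)
        ssl = cfg.mode == "ssl"

        lab = self.split.labeled
        pool = self.split.unlabeled
        val = self.split.validation
        lab_oh, lab_tab = lab.onehot, self.preprocessor.transform(lab.tabular)
        lab_y = lab.labels.copy()
        pool_oh, pool_tab = pool.onehot, self.preprocessor.transform(pool.tabular)
        pool_hidden = pool.labels.copy()          # audit only
        pool_ids = self.split.unlabeled_idx.copy()
        val_oh, val_tab = val.onehot, self.preprocessor.transform(val.tabular)
        val_y = val.labels

        if len(lab_y) == 0:
            raise ValueError("labeled split is empty")

        t = 0
        history: list[dict] = []
        audit: list[dict] = []
        for epoch in range(1, cfg.epochs + 1):
            order = rng.permutation(len(lab_y))
            u_order = rng.permutation(len(pool_ids))
            u_cursor = 0
            step_l, step_u, n_steps = 0.0, 0.0, 0
            for start in range(0, len(order), cfg.batch_labeled):
                t += 1
                alpha = 0.0 if not ssl else alpha_schedule(t, cfg.T1, cfg.T2)
                if cfg.alpha_override is not None:
                    alpha = cfg.alpha_override
                bidx = order[start: start + cfg.batch_labeled]
                loss_l, grads, _ = net.loss_and_grads(
                    lab_oh[bidx], lab_tab[bidx], lab_y[bidx], training=True, rng=rng
                )
                loss_u = 0.0
                if alpha > 0.0 and len(pool_ids):
                    if u_cursor + cfg.batch_unlabeled > len(pool_ids):
                        u_order = rng.permutation(len(pool_ids))
                        u_cursor = 0
                    uidx = u_order[u_cursor: u_cursor + cfg.batch_unlabeled]
                    u_cursor += cfg.batch_unlabeled
                    # pseudo labels come from the same training-mode forward
                    # whose gradient is taken: the classical self-labelling step
                    u_probs, u_cache = net.forward(
                        pool_oh[uidx], pool_tab[uidx], training=True, rng=rng
                    )
                    u_y = pseudo_label(u_probs)
                    loss_u = float(-np.log(
                        np.clip(u_probs[np.arange(len(u_y)), u_y], 1e-12, None)
                    ).mean())
                    u_grads = net._backward(u_cache, pool_tab[uidx], u_y)
                    for k in grads:
                        grads[k] = grads[k] + alpha * u_grads[k]
                net.sgd_step(grads, cfg.learning_rate)
                step_l += loss_l
                step_u += loss_u
                n_steps += 1

            n_promoted = 0
            if ssl and cfg.promotion and len(pool_ids):
                probs = net.predict_proba(pool_oh, pool_tab)
                mask, labels = promote_confident(probs, cfg.confidence_threshold)
                n_promoted = int(mask.sum())
                if n_promoted:
                    for i in np.flatnonzero(mask):
                        audit.append({
                            "epoch": epoch,
                            "locus_index": int(pool_ids[i]),
                            "max_prob": float(probs[i].max()),
                            "pseudo_label": int(labels[i]),
                            "hidden_label": int(pool_hidden[i]),
                        })
                    lab_oh = np.concatenate([lab_oh, pool_oh[mask]])
                    lab_tab = np.concatenate([lab_tab, pool_tab[mask]])
                    lab_y = np.concatenate([lab_y, labels[mask]])
                    keep = ~mask
                    pool_oh, pool_tab = pool_oh[keep], pool_tab[keep]
                    pool_hidden, pool_ids = pool_hidden[keep], pool_ids[keep]

            val_probs = np.vstack([
                net.predict_proba(val_oh[i: i + cfg.batch_validation],
                                  val_tab[i: i + cfg.batch_validation])
                for i in range(0, len(val_y), cfg.batch_validation)
            ])
            history.append({
                "epoch": epoch,
                "L_label": step_l / n_steps,
                "L_unlabel": step_u / n_steps,
                "alpha": (0.0 if not ssl else alpha_schedule(t, cfg.T1, cfg.T2))
                if cfg.alpha_override is None else cfg.alpha_override,
                "pool_size": len(pool_ids),
                "n_promoted": n_promoted,
                "val_auc": float(roc_auc_score(val_y, val_probs[:, 1])),
                "val_acc": float((pseudo_label(val_probs) == val_y).mean()),
            })

        return SSLResults(
            model=self,
            network=net,
            history=pd.DataFrame(history),
            audit=pd.DataFrame(
                audit, columns=["epoch", "locus_index", "max_prob",
                                "pseudo_label", "hidden_label"]
            ),
            preprocessor=self.preprocessor,
        )


@dataclass
class SSLResults:
    """Fitted-model results: trained parameters, history and diagnostics.

    ``history`` has one row per epoch (L_label, L_unlabel, alpha, pool_size,
    n_promoted, val_auc, val_acc); ``audit`` records every promotion with its
    confidence and the hidden true label at promotion time.
    """

    model: PseudoLabelClassifier
    network: Network
    history: pd.DataFrame
    audit: pd.DataFrame
    preprocessor: Preprocessor

    def predict_proba(self, table: FeatureTable) -> np.ndarray:
        return self.network.predict_proba(
            table.onehot, self.preprocessor.transform(table.tabular)
        )

    def predict(self, table: FeatureTable) -> np.ndarray:
        return pseudo_label(self.predict_proba(table))

    @property
    def val_auc(self) -> float:
        return float(self.history["val_auc"].iloc[-1])

    @property
    def val_acc(self) -> float:
        return float(self.history["val_acc"].iloc[-1])

    def summary(self) -> str:
        cfg = self.model.train_config
        counts = self.model.split.counts()
        h = self.history
        lines = [
            "Pseudo-label semi-supervised classifier",
            "=" * 54,
            f"mode: {cfg.mode}    epochs: {cfg.epochs}    seed: {cfg.seed}",
            f"lr {cfg.learning_rate}  batches {cfg.batch_labeled}/"
            f"{cfg.batch_unlabeled}/{cfg.batch_validation}  "
            f"threshold {cfg.confidence_threshold}  T1 {cfg.T1}  T2 {cfg.T2}",
            "-" * 54,
        ]
        for part, (n, p, q) in counts.items():
            lines.append(f"{part:<11} n={n:<6} pos={p:<6} neg={q}")
        lines += [
            "-" * 54,
            f"final L_label   {h['L_label'].iloc[-1]:.4f}",
            f"final L_unlabel {h['L_unlabel'].iloc[-1]:.4f}",
            f"final alpha     {h['alpha'].iloc[-1]:.3f}",
            f"pool size       {int(h['pool_size'].iloc[-1])} "
            f"(promoted {len(self.audit)} in total)",
            f"validation AUC  {self.val_auc:.4f}",
            f"validation acc  {self.val_acc:.4f}",
            "=" * 54,
        ]
        return "\n".join(lines)

    def save(self, path) -> None:
        self.network.save(path, extra={
            "preprocessor": self.preprocessor.to_dict(),
            "train_config": dataclasses.asdict(self.model.train_config),
        })


def train(
    split: DatasetSplit,
    model_config: Optional[ModelConfig] = None,
    train_config: Optional[TrainConfig] = None,
) -> SSLResults:
    """Functional wrapper: ``PseudoLabelClassifier(split, ...).fit()``."""
    return PseudoLabelClassifier(split, model_config, train_config).fit()
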