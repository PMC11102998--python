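"""Model training (Adam + MSE with early stopping) and k-fold evaluation.

The protocol is transductive: similarity graphs and PCA are computed over
the full entity sets once, and only the labelled pairs are split into
folds.  Each fold trains on the complementary pairs (with a stratified 10%
validation split for early stopping) and is scored on its held-out pairs
with AUC, AUPR, precision, recall and F1.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from . import _autodiff as ad
from .attention_network import (
    BlockConfig,
    ModelParams,
    _encode_T,
    _mlp_T,
    _tensorize,
    _write_back,
    init_model_params,
    score_pairs,
)
from .containers import AdjacencyMatrix, FeatureMatrix, InteractionPair
from .errors import MifamError

log = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    """Optimization hyperparameters (defaults follow the published settings)."""

    epochs: int = 15
    patience: int = 5
    learning_rate: float = 1e-4
    batch_size: int = 128
    seed: int = 0
    threshold: float = 0.5
    val_fraction: float = 0.1

    def __post_init__(self) -> None:
        if min(self.epochs, self.patience, self.batch_size) < 1:
            raise MifamError("epochs, patience and batch_size must be positive")
        if self.learning_rate <= 0:
            raise MifamError("learning rate must be positive")
        if self.patience > self.epochs:
            raise MifamError("patience cannot exceed epochs")
        if not 0 < self.val_fraction < 1:
            raise MifamError("val_fraction must lie in (0, 1)")


@dataclass
class EntityInputs:
    """Fused features and fused adjacency for one entity type."""

    features: FeatureMatrix
    adjacency: AdjacencyMatrix

    def __post_init__(self) -> None:
        if self.features.ids != self.adjacency.ids:
            raise MifamError("entity features and adjacency ids do not match")


@dataclass
class MetricReport:
    """Classification metrics; AUC/AUPR are None when only one class is present."""

    auc: float | None
    aupr: float | None
    precision: float
    recall: float
    f1: float


@dataclass
class CVReport:
    folds: list[MetricReport]
    mean: MetricReport
    history: list[dict] = field(default_factory=list)


def make_folds(
    pairs: list[InteractionPair], k: int = 10, seed: int = 0
) -> list[list[InteractionPair]]:
    """k disjoint, label-stratified test partitions; deterministic given seed."""
    if k < 2:
        raise MifamError("k must be >= 2")
    if len(pairs) < k:
        raise MifamError(f"need at least k={k} pairs, got {len(pairs)}")
    labels = np.array([p.label for p in pairs])
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [
        [pairs[i] for i in test_idx]
        for _, test_idx in skf.split(np.zeros(len(pairs)), labels)
    ]


def _resolve(pairs: list[InteractionPair], drug_ids: list[str],
             target_ids: list[str]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    dmap = {d: i for i, d in enumerate(drug_ids)}
    tmap = {t: i for i, t in enumerate(target_ids)}
    missing = [(p.drug_id, p.protein_id) for p in pairs
               if p.drug_id not in dmap or p.protein_id not in tmap]
    if missing:
        raise MifamError(f"pairs reference unknown entities: {missing[:5]}")
    di = np.array([dmap[p.drug_id] for p in pairs], dtype=np.intp)
    ti = np.array([tmap[p.protein_id] for p in pairs], dtype=np.intp)
    y = np.array([p.label for p in pairs], dtype=np.float64)
    return di, ti, y


def _stratified_holdout(labels: np.ndarray, fraction: float,
                        rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Indices of (train, validation), validation stratified by label."""
    val: list[int] = []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        idx = rng.permutation(idx)
        n_val = max(1, int(round(fraction * len(idx)))) if len(idx) > 1 else 0
        val.extend(idx[:n_val])
    val_idx = np.sort(np.array(val, dtype=np.intp))
    train_idx = np.setdiff1d(np.arange(len(labels)), val_idx)
    if len(train_idx) == 0:
        raise MifamError("validation split left no training pairs")
    return train_idx, val_idx


def train_model(
    train_pairs: list[InteractionPair],
    drugs: EntityInputs,
    targets: EntityInputs,
    cfg: TrainConfig | None = None,
    block_cfg: BlockConfig | None = None,
    model: ModelParams | None = None,
) -> tuple[ModelParams, list[dict]]:
    """Train the full model on labelled pairs; returns best-validation weights.

    Every optimizer step re-encodes both entity sets on the full graphs,
    gathers the embeddings of a shuffled mini-batch of pairs, and takes an
    Adam step on the MSE between sigmoid scores and labels.  Training stops
    early when validation loss has not improved for ``patience`` epochs.
    """
    cfg = cfg or TrainConfig()
    block_cfg = block_cfg or BlockConfig()
    if not train_pairs:
        raise MifamError("no training pairs")
    rng = np.random.default_rng(cfg.seed)
    di, ti, y = _resolve(train_pairs, drugs.features.ids, targets.features.ids)

    if len(train_pairs) >= 10:
        tr_idx, val_idx = _stratified_holdout(y, cfg.val_fraction, rng)
    else:  # too few pairs to hold out: monitor training loss instead
        tr_idx = np.arange(len(train_pairs))
        val_idx = tr_idx

    if model is None:
        model = init_model_params(
            drugs.features.d, targets.features.d, block_cfg, seed=cfg.seed
        )
    mirror, tensors = _tensorize(model, trainable=True)
    opt = ad.Adam(tensors, lr=cfg.learning_rate)
    d_mask = drugs.adjacency.neighbor_mask()
    t_mask = targets.adjacency.neighbor_mask()
    Hd = ad.constant(drugs.features.matrix)
    Ht = ad.constant(targets.features.matrix)

    def forward_loss(idx: np.ndarray) -> ad.Tensor:
        zd = _encode_T(Hd, d_mask, mirror.drug_blocks)
        zt = _encode_T(Ht, t_mask, mirror.target_blocks)
        x = ad.concat_cols([ad.gather_rows(zd, di[idx]),
                            ad.gather_rows(zt, ti[idx])])
        return ad.mse(_mlp_T(x, mirror.mlp), y[idx][:, None])

    best = model.copy()
    _write_back(best, mirror)
    best_val = math.inf
    bad_epochs = 0
    history: list[dict] = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(tr_idx)
        batch_losses = []
        for start in range(0, len(order), cfg.batch_size):
            batch = order[start:start + cfg.batch_size]
            opt.zero_grad()
            loss = forward_loss(batch)
            if not np.isfinite(loss.value):
                raise MifamError(f"non-finite training loss at epoch {epoch}")
            loss.backward()
            opt.step()
            batch_losses.append(float(loss.value))
        val_loss = float(forward_loss(val_idx).value)
        history.append(
            dict(epoch=epoch, train_loss=float(np.mean(batch_losses)),
                 val_loss=val_loss)
        )
        log.debug("epoch %d train_loss %.5f val_loss %.5f", epoch,
                  history[-1]["train_loss"], val_loss)
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            _write_back(best, mirror)
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= cfg.patience:
                log.debug("early stop after epoch %d", epoch)
                break
    return best, history


def evaluate(scores: np.ndarray, labels: np.ndarray,
             threshold: float = 0.5) -> MetricReport:
    """AUC (rank statistic, half credit for ties), AUPR (step-interpolated),
    and thresholded precision/recall/F1."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if scores.size == 0:
        raise MifamError("cannot evaluate an empty score vector")
    if scores.shape != labels.shape:
        raise MifamError("scores and labels lengths differ")
    if len(np.unique(labels)) < 2:
        auc = aupr = None
    else:
        auc = float(roc_auc_score(labels, scores))
        aupr = float(average_precision_score(labels, scores))
    pred = (scores >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (labels == 1)))
    fp = int(np.sum((pred == 1) & (labels == 0)))
    fn = int(np.sum((pred == 0) & (labels == 1)))
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)
    return MetricReport(auc, aupr, precision, recall, f1)


def _mean_report(folds: list[MetricReport]) -> MetricReport:
    def mean_of(attr: str) -> float | None:
        vals = [getattr(f, attr) for f in folds if getattr(f, attr) is not None]
        return float(np.mean(vals)) if vals else None

    return MetricReport(*(mean_of(a) for a in ("auc", "aupr", "precision",
                                               "recall", "f1")))


def run_cv(
    pairs: list[InteractionPair],
    drugs: EntityInputs,
    targets: EntityInputs,
    cfg: TrainConfig | None = None,
    block_cfg: BlockConfig | None = None,
    k: int = 10,
) -> CVReport:
    """k-fold cross-validation over pairs; per-fold and mean metrics."""
    cfg = cfg or TrainConfig()
    folds = make_folds(pairs, k=k, seed=cfg.seed)
    all_keys = {(p.drug_id, p.protein_id) for p in pairs}
    reports: list[MetricReport] = []
    histories: list[dict] = []
    for fi, test_pairs in enumerate(folds):
        test_keys = {(p.drug_id, p.protein_id) for p in test_pairs}
        train_pairs = [p for p in pairs
                       if (p.drug_id, p.protein_id) not in test_keys]
        # fold-isolation audit: no held-out pair may reach the gradient step
        train_keys = {(p.drug_id, p.protein_id) for p in train_pairs}
        assert not (train_keys & test_keys)
        assert train_keys | test_keys == all_keys
        model, history = train_model(train_pairs, drugs, targets, cfg, block_cfg)
        di, ti, y = _resolve(test_pairs, drugs.features.ids, targets.features.ids)
        scores = score_pairs(model, drugs.features, drugs.adjacency,
                             targets.features, targets.adjacency, di, ti)
        rep = evaluate(scores, y.astype(int), cfg.threshold)
        log.info("fold %d: auc=%s aupr=%s f1=%.4f", fi, rep.auc, rep.aupr, rep.f1)
        reports.append(rep)
        histories.append({"fold": fi, "epochs": history})
    return CVReport(reports, _mean_report(reports), histories)
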