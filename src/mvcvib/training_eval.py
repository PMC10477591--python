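"""Training and evaluation protocol.

The cohort is split 8:2 into training and test sets, stratified by class.
Stratified 5-fold cross-validation on the training set selects the training
epoch: every fold is trained with early stopping while its validation AUC
is recorded per epoch, the epoch maximizing the mean validation AUC across
folds is chosen, the model is refit on the full training set for that many
epochs, and the held-out test AUC is reported from posterior-mean latents.

AUC uses the rank formula (the normalized Mann–Whitney statistic): with M
positive and N negative samples and ascending midranks over all scores,

    AUC = ( sum_{i in positives} rank_i - M(M+1)/2 ) / (M N).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import rankdata

from .io_tables import AbundanceTable
from .views import build_views
from .vib_model import (
    ModelConfig,
    init_params,
    loss_and_grads,
    predict_proba,
)
from ._autograd import Tensor

logger = logging.getLogger(__name__)

__all__ = [
    "SplitPlan",
    "EvalResult",
    "stratified_split",
    "stratified_kfold",
    "make_split_plan",
    "auc_score",
    "train_model",
]


@dataclass(frozen=True)
class SplitPlan:
    """A deterministic train/test partition with fold assignments."""

    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    folds: Mapping[str, int]
    seed: int

    def __post_init__(self):
        object.__setattr__(self, "train_ids", tuple(self.train_ids))
        object.__setattr__(self, "test_ids", tuple(self.test_ids))
        object.__setattr__(self, "folds", dict(self.folds))
        if set(self.train_ids) & set(self.test_ids):
            raise ValueError("train and test sets overlap")
        if set(self.folds) != set(self.train_ids):
            raise ValueError("folds must cover exactly the training ids")

    def to_dict(self) -> dict:
        return {
            "train_ids": list(self.train_ids),
            "test_ids": list(self.test_ids),
            "folds": dict(self.folds),
            "seed": self.seed,
        }


@dataclass
class EvalResult:
    """Cross-validation curves, the selected epoch and the test AUC."""

    fold_val_aucs: list[list[float]]
    best_epoch: int
    test_auc: float
    history: list[tuple[float, float, float]]  # refit (total, nll, kl) per epoch

    def to_dict(self) -> dict:
        return {
            "fold_val_aucs": [[float(a) for a in curve] for curve in self.fold_val_aucs],
            "best_epoch": int(self.best_epoch),
            "test_auc": float(self.test_auc),
            "history": [[float(v) for v in row] for row in self.history],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)


# ----------------------------------------------------------------------
# splitting


def stratified_split(
    labels: np.ndarray, test_fraction: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-class allocation of round(count * fraction) samples to the test
    set (at least 1 per class when the class has >= 2 members, never the
    whole class). Returns sorted (train_indices, test_indices)."""
    labels = np.asarray(labels)
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("stratified split requires both classes present")
    rng = np.random.default_rng(seed)
    test: list[int] = []
    for cls in classes:
        idx = np.flatnonzero(labels == cls)
        n_test = int(np.floor(idx.size * test_fraction + 0.5))  # round half up
        if idx.size >= 2:
            n_test = max(n_test, 1)
        n_test = min(n_test, idx.size - 1)  # keep at least one for training
        perm = rng.permutation(idx.size)
        test.extend(idx[perm[:n_test]])
    test_idx = np.sort(np.array(test, dtype=np.int64))
    train_idx = np.setdiff1d(np.arange(labels.size), test_idx)
    return train_idx, test_idx


def stratified_kfold(train_labels: np.ndarray, k: int = 5, seed: int = 0) -> np.ndarray:
    """Fold assignment by per-class round-robin after a seeded within-class
    shuffle. A single fold pointer continues across classes so fold sizes
    differ by at most one overall."""
    labels = np.asarray(train_labels)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > labels.size:
        raise ValueError("k exceeds the number of samples")
    rng = np.random.default_rng(seed)
    assignment = np.empty(labels.size, dtype=np.int64)
    pointer = 0
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        idx = idx[rng.permutation(idx.size)]
        for i in idx:
            assignment[i] = pointer % k
            pointer += 1
    return assignment


def make_split_plan(
    sample_ids: Sequence[str],
    labels: np.ndarray,
    test_fraction: float = 0.2,
    k: int = 5,
    seed: int = 42,
) -> SplitPlan:
    """Build the full 8:2 + 5-fold plan over named samples."""
    sample_ids = list(sample_ids)
    labels = np.asarray(labels)
    train_idx, test_idx = stratified_split(labels, test_fraction, seed)
    fold_assign = stratified_kfold(labels[train_idx], k=k, seed=seed)
    train_ids = [sample_ids[i] for i in train_idx]
    return SplitPlan(
        train_ids=tuple(train_ids),
        test_ids=tuple(sample_ids[i] for i in test_idx),
        folds={sid: int(f) for sid, f in zip(train_ids, fold_assign)},
        seed=seed,
    )


# ----------------------------------------------------------------------
# metric


def auc_score(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-formula AUC with midranks for ties (Mann–Whitney)."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    pos = labels == 1
    m = int(pos.sum())
    n = int(labels.size - m)
    if m == 0 or n == 0:
        raise ValueError("AUC requires both classes present")
    ranks = rankdata(scores, method="average")
    return float((ranks[pos].sum() - m * (m + 1) / 2.0) / (m * n))


# ----------------------------------------------------------------------
# training


class _Adam:
    """Adaptive-moment gradient descent (Adam, standard bias correction)."""

    def __init__(self, params: dict[str, Tensor], lr: float,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self, grads: Mapping[str, np.ndarray]) -> None:
        self.t += 1
        for k, p in self.params.items():
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _input_dims(train_table: AbundanceTable, config: ModelConfig) -> dict[str, int]:
    dims = {"abundance": train_table.n_features}
    if config.multi_view:
        dims["distance"] = train_table.n_samples
    return dims


def _fit(
    train_table: AbundanceTable,
    y_train: np.ndarray,
    config: ModelConfig,
    seed_seq: np.random.SeedSequence,
    n_epochs: int | None = None,
    val_table: AbundanceTable | None = None,
    y_val: np.ndarray | None = None,
):
    """Fit one model. With a validation set, train with early stopping and
    return the per-epoch validation AUC curve; otherwise train for exactly
    ``n_epochs``. The distance-view reference is always ``train_table``."""
    rng_init, rng_noise, rng_drop = (np.random.default_rng(s)
                                     for s in seed_seq.spawn(3))
    views_train = build_views(train_table, train_table, config)
    views_val = (build_views(val_table, train_table, config)
                 if val_table is not None else None)

    params = init_params(config, _input_dims(train_table, config), rng_init)
    opt = _Adam(params, lr=config.learning_rate)
    n, K = train_table.n_samples, config.latent_dim

    val_aucs: list[float] = []
    losses: list[tuple[float, float, float]] = []
    best_val, since_improve = -np.inf, 0
    max_epochs = config.max_epochs if n_epochs is None else n_epochs

    for epoch in range(1, max_epochs + 1):
        eps = rng_noise.standard_normal((n, K))
        (total, nll, kl), grads = loss_and_grads(
            views_train, y_train, params, config, eps,
            training=True, dropout_rng=rng_drop)
        if not np.isfinite(total):
            raise FloatingPointError(
                f"non-finite training loss (total={total}, nll={nll}, kl={kl})")
        opt.step(grads)
        losses.append((total, nll, kl))
        if views_val is not None:
            probs = predict_proba(views_val, params, config)
            if np.unique(y_val).size < 2:
                auc = 0.5  # degenerate validation fold carries no signal
            else:
                auc = auc_score(probs, y_val)
            val_aucs.append(auc)
            logger.info("epoch %d: total=%.5f nll=%.5f kl=%.3f val_auc=%.4f",
                        epoch, total, nll, kl, auc)
            if auc > best_val:
                best_val, since_improve = auc, 0
            else:
                since_improve += 1
                if since_improve >= config.patience:
                    break
        else:
            logger.info("epoch %d: total=%.5f nll=%.5f kl=%.3f",
                        epoch, total, nll, kl)
    return params, val_aucs, losses


def train_model(
    table: AbundanceTable,
    labels: np.ndarray,
    config: ModelConfig,
    plan: SplitPlan,
) -> tuple[dict[str, Tensor], EvalResult, AbundanceTable]:
    """Run the full protocol; returns (fitted params, result, reference table).

    The returned reference table is the full training-set abundance table
    the final model's distance view was built against; it is what a scorer
    of new samples must compute distances to.
    """
    labels = np.asarray(labels)
    index = {sid: i for i, sid in enumerate(table.sample_ids)}
    train_idx = np.array([index[s] for s in plan.train_ids])
    test_idx = np.array([index[s] for s in plan.test_ids])
    y_train, y_test = labels[train_idx], labels[test_idx]
    train_table = table.select_samples(plan.train_ids)
    test_table = table.select_samples(plan.test_ids)

    root = np.random.SeedSequence(config.seed)
    n_folds = max(f for f in plan.folds.values()) + 1
    fold_seeds = root.spawn(n_folds + 1)

    fold_curves: list[list[float]] = []
    for fold in range(n_folds):
        in_val = np.array([plan.folds[s] == fold for s in plan.train_ids])
        fold_train = train_table.select_samples(
            [s for s, v in zip(plan.train_ids, in_val) if not v])
        fold_val = train_table.select_samples(
            [s for s, v in zip(plan.train_ids, in_val) if v])
        _, val_aucs, _ = _fit(
            fold_train, y_train[~in_val], config, fold_seeds[fold],
            val_table=fold_val, y_val=y_train[in_val])
        fold_curves.append(val_aucs)

    # folds may stop at different epochs: freeze each stopped fold at its
    # last recorded AUC, then pick the epoch with the best mean
    longest = max(len(c) for c in fold_curves)
    padded = np.array([c + [c[-1]] * (longest - len(c)) for c in fold_curves])
    mean_curve = padded.mean(axis=0)
    best_epoch = int(np.argmax(mean_curve)) + 1  # earliest epoch wins ties

    params, _, losses = _fit(train_table, y_train, config, fold_seeds[n_folds],
                             n_epochs=best_epoch)
    test_views = build_views(test_table, train_table, config)
    test_probs = predict_proba(test_views, params, config)
    result = EvalResult(
        fold_val_aucs=fold_curves,
        best_epoch=best_epoch,
        test_auc=auc_score(test_probs, y_test),
        history=losses,
    )
    return params, result, train_table
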