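"""Subject-wise cross-validation, losses, metrics, training and transfer.

Evaluation is subject-wise throughout: every subject's trials live in exactly
one cross-validation fold, and a held-out group of test subjects appears in
no fold, so train/validation/test subject sets never intersect and the
reported accuracies are for *unseen subjects*.

Class imbalance is handled with a per-class loss penalty of
``1 - n_class / n_total``; ordinal (e.g. age-bin) targets may use neighbour
label smoothing (0.6 on the true class and 0.2 on each neighbour; 0.8/0.2 at
the boundaries).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import LinearSVC

from .autodiff import Adam, SGD, Tensor
from .data import TrialSet
from .rascnn import RaSCNN, RaSCNNConfig
from .scnn import SCNN, SCNNConfig

logger = logging.getLogger(__name__)

__all__ = [
    "FoldPlan",
    "TrainConfig",
    "FoldResult",
    "assign_folds",
    "class_weights",
    "smooth_labels",
    "one_off_accuracy",
    "confusion_matrix",
    "cross_entropy",
    "build_model",
    "train_model",
    "transfer_evaluate",
    "hyper_search",
]


# ---------------------------------------------------------------------------
# Fold assignment


@dataclass
class FoldPlan:
    n_folds: int
    fold_of_subject: dict
    test_subjects: frozenset
    fold_totals: list

    def fold_subjects(self, fold: int):
        return sorted(s for s, f in self.fold_of_subject.items() if f == fold)


def assign_folds(subject_trial_counts: dict, n_folds: int, test_subjects=()) -> FoldPlan:
    """Greedy balanced assignment of subjects to folds.

    Subjects (test subjects excluded) are sorted by trial count descending
    and each is assigned to the currently lightest fold (ties broken by the
    lowest fold index), approximately equalizing per-fold trial totals.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    test_subjects = frozenset(test_subjects)
    pool = [(s, c) for s, c in subject_trial_counts.items() if s not in test_subjects]
    if len(pool) < n_folds:
        raise ValueError(f"only {len(pool)} non-test subjects for {n_folds} folds")
    # descending count; deterministic subject-order tie-break
    pool.sort(key=lambda sc: (-sc[1], str(sc[0])))
    totals = [0] * n_folds
    fold_of = {}
    for s, c in pool:
        f = int(np.argmin(totals))  # argmin takes the lowest index on ties
        fold_of[s] = f
        totals[f] += c
    return FoldPlan(n_folds, fold_of, test_subjects, totals)


# ---------------------------------------------------------------------------
# Losses and metrics


def class_weights(labels) -> dict:
    """Per-class loss penalty 1 - n_class / n_total."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("empty labels")
    classes, counts = np.unique(labels, return_counts=True)
    total = counts.sum()
    return {int(c): 1.0 - n / total for c, n in zip(classes, counts)}


def smooth_labels(true_class: int, n_classes: int) -> np.ndarray:
    """Neighbour label smoothing for ordinal targets.

    Interior classes get 0.6 with 0.2 on each neighbour; boundary classes get
    0.8 with 0.2 on their single neighbour.  The distribution sums to 1.
    """
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    if not (0 <= true_class < n_classes):
        raise ValueError(f"true_class {true_class} out of range [0, {n_classes})")
    dist = np.zeros(n_classes)
    if true_class in (0, n_classes - 1):
        dist[true_class] = 0.8
        neighbour = 1 if true_class == 0 else n_classes - 2
        dist[neighbour] = 0.2
    else:
        dist[true_class] = 0.6
        dist[true_class - 1] = 0.2
        dist[true_class + 1] = 0.2
    return dist


def one_off_accuracy(true_labels, predicted_labels) -> float:
    """Fraction of ordinal predictions within one class of the truth."""
    t = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if t.shape != p.shape:
        raise ValueError("length mismatch")
    return float(np.mean(np.abs(p.astype(int) - t.astype(int)) <= 1))


def confusion_matrix(true_labels, predicted_labels, n_classes: int):
    """(rates, counts): per-actual-class prediction rates and raw counts.

    Rows are actual classes, columns predicted; rows with at least one
    example sum to 1, empty classes yield zero rows (flagged by a warning).
    """
    t = np.asarray(true_labels, dtype=int)
    p = np.asarray(predicted_labels, dtype=int)
    if t.shape != p.shape:
        raise ValueError("length mismatch")
    if t.size and (t.min() < 0 or t.max() >= n_classes or p.min() < 0 or p.max() >= n_classes):
        raise ValueError("label out of range")
    counts = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(counts, (t, p), 1)
    row_sums = counts.sum(axis=1)
    empty = row_sums == 0
    if empty.any():
        logger.warning("classes with no examples: %s", np.flatnonzero(empty).tolist())
    rates = counts / np.where(empty, 1, row_sums)[:, None]
    return rates, counts


def cross_entropy(logits: Tensor, targets: np.ndarray, sample_weights=None) -> Tensor:
    """Mean (optionally weighted) cross-entropy against target distributions."""
    logp = logits.log_softmax(axis=-1)
    per_example = -(logp * np.asarray(targets)).sum(axis=-1)
    if sample_weights is not None:
        per_example = per_example * np.asarray(sample_weights)
    return per_example.mean()


# ---------------------------------------------------------------------------
# Training


@dataclass(frozen=True)
class TrainConfig:
    optimizer: str = "adam"  # or "sgd"
    learning_rate: float = 1e-3
    batch_size: int = 32
    epochs: int = 10
    lr_decay: float = 1.0  # multiplicative step decay factor
    lr_decay_every: int = 0  # epochs between decays (0 = constant rate)
    class_weighting: bool = False
    label_smoothing: bool = False
    #: "dataset" scales by training-fold statistics; "per_trial" z-scores each
    #: trial per channel (removes per-subject gain differences); False = raw
    standardize: object = "dataset"
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0 or self.batch_size < 1 or self.epochs < 0:
            raise ValueError("learning_rate, batch_size must be positive; epochs >= 0")
        if self.optimizer.lower() not in ("adam", "sgd"):
            raise ValueError("optimizer must be 'adam' or 'sgd'")


@dataclass
class FoldResult:
    fold: int
    model: object
    val_accuracy: float
    test_accuracy: float
    epoch_losses: list
    status: str = "ok"
    #: callable applied to raw data before the model (None = identity)
    standardizer: object = None


def build_model(model_cfg, T: int, C: int):
    if isinstance(model_cfg, RaSCNNConfig):
        return RaSCNN(model_cfg, T, C)
    if isinstance(model_cfg, SCNNConfig):
        return SCNN(model_cfg, T, C)
    raise TypeError(f"unsupported model config {type(model_cfg)!r}")


def _targets(labels: np.ndarray, n_classes: int, smoothing: bool) -> np.ndarray:
    if smoothing and n_classes >= 2:
        return np.stack([smooth_labels(int(k), n_classes) for k in labels])
    return np.eye(n_classes)[labels]


def predict(model, data: np.ndarray, batch_size: int = 256) -> np.ndarray:
    """Predicted class labels in evaluation mode, batched."""
    out = []
    for i in range(0, len(data), batch_size):
        out.append(np.argmax(model.forward(data[i : i + batch_size]).data, axis=-1))
    return np.concatenate(out) if out else np.empty(0, dtype=int)


def _fit_standardizer(data: np.ndarray):
    mu = data.mean(axis=(0, 1), keepdims=True)
    sd = data.std(axis=(0, 1), keepdims=True)
    sd = np.where(sd == 0, 1.0, sd)
    return mu, sd


def per_trial_standardize(data: np.ndarray) -> np.ndarray:
    """Z-score each trial per channel (over time)."""
    mu = data.mean(axis=1, keepdims=True)
    sd = data.std(axis=1, keepdims=True)
    return (data - mu) / np.where(sd == 0, 1.0, sd)


def fit_fold(model, ts_train: TrialSet, cfg: TrainConfig, model_cfg) -> list:
    """Train ``model`` in place on ``ts_train``; returns per-epoch mean losses.

    Raises FloatingPointError on a non-finite loss (the caller aborts the
    fold with a diagnostic).
    """
    rng = np.random.default_rng(cfg.seed)
    n_classes = model.cfg.n_classes
    targets = _targets(ts_train.labels.astype(int), n_classes, cfg.label_smoothing)
    weights = None
    if cfg.class_weighting:
        cw = class_weights(ts_train.labels)
        weights = np.array([cw[int(k)] for k in ts_train.labels])
    params = model.parameters()
    opt = (
        Adam(params, lr=cfg.learning_rate)
        if cfg.optimizer.lower() == "adam"
        else SGD(params, lr=cfg.learning_rate, momentum=0.9)
    )
    l2 = getattr(model_cfg, "l2_penalty", 0.0) or getattr(
        getattr(model_cfg, "front_end", None), "l2_penalty", 0.0
    )
    losses = []
    n = ts_train.n_trials
    for ep in range(cfg.epochs):
        if cfg.lr_decay_every and ep and ep % cfg.lr_decay_every == 0:
            opt.lr *= cfg.lr_decay
        order = rng.permutation(n)
        ep_loss = 0.0
        n_batches = 0
        for i in range(0, n, cfg.batch_size):
            idx = order[i : i + cfg.batch_size]
            logits = model.forward(ts_train.data[idx], train=True)
            loss = cross_entropy(logits, targets[idx], None if weights is None else weights[idx])
            if l2:
                reg = Tensor(0.0)
                for w in model.regularized_parameters():
                    reg = reg + (w**2).sum()
                loss = loss + l2 * reg
            if not np.isfinite(loss.data):
                raise FloatingPointError(f"non-finite loss at epoch {ep}, batch {n_batches}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            ep_loss += float(loss.data)
            n_batches += 1
        losses.append(ep_loss / max(n_batches, 1))
        logger.info("epoch %d: mean loss %.4f", ep, losses[-1])
    return losses


def train_model(model_cfg, ts: TrialSet, plan: FoldPlan, cfg: TrainConfig) -> list:
    """Subject-wise k-fold training; returns a FoldResult per fold.

    For each fold, the model trains on all other folds' subjects, validates
    on the fold's subjects, and is evaluated on the held-out test subjects.
    """
    results = []
    test_mask = np.isin(ts.subject_ids, list(plan.test_subjects))
    for f in range(plan.n_folds):
        val_subjects = plan.fold_subjects(f)
        train_subjects = [s for s, ff in plan.fold_of_subject.items() if ff != f]
        assert not (set(val_subjects) & set(train_subjects))
        assert not plan.test_subjects & set(val_subjects) and not plan.test_subjects & set(
            train_subjects
        )
        tr = ts.select(np.isin(ts.subject_ids, train_subjects))
        va = ts.select(np.isin(ts.subject_ids, val_subjects))
        te = ts.select(test_mask)
        if cfg.standardize == "per_trial":
            _scale = per_trial_standardize
        elif cfg.standardize:
            mu_sd = _fit_standardizer(tr.data)

            def _scale(x, _s=mu_sd):
                return (x - _s[0]) / _s[1]

        if cfg.standardize:
            tr, va, te = (
                TrialSet(_scale(t.data), t.labels, t.subject_ids, t.task_ids,
                         t.event_index, t.sampling_rate)
                for t in (tr, va, te)
            )
        std = _scale if cfg.standardize else None
        fold_cfg = type(model_cfg)(**{**model_cfg.__dict__, "seed": model_cfg.seed + f})
        model = build_model(fold_cfg, ts.n_samples, ts.n_channels)
        try:
            losses = fit_fold(model, tr, cfg, fold_cfg)
        except FloatingPointError as e:
            logger.error("fold %d aborted: %s", f, e)
            results.append(FoldResult(f, model, np.nan, np.nan, [], status=f"aborted: {e}", standardizer=std))
            continue
        val_acc = float(np.mean(predict(model, va.data) == va.labels)) if va.n_trials else np.nan
        test_acc = float(np.mean(predict(model, te.data) == te.labels)) if te.n_trials else np.nan
        logger.info("fold %d: val %.3f test %.3f", f, val_acc, test_acc)
        results.append(FoldResult(f, model, val_acc, test_acc, losses, standardizer=std))
    return results


# ---------------------------------------------------------------------------
# Transfer evaluation


def transfer_evaluate(
    model, ts_train: TrialSet, ts_test: TrialSet, seed: int = 0, standardizer=None
) -> float:
    """Frozen-feature transfer: linear max-margin head on penultimate features.

    All model weights stay fixed; a linear SVM is trained on penultimate-stage
    features of ``ts_train`` and scored on ``ts_test`` (held-out subjects).
    """
    overlap = set(np.unique(ts_train.subject_ids)) & set(np.unique(ts_test.subject_ids))
    if overlap:
        raise ValueError(f"subject leakage between transfer train/test: {sorted(overlap)}")

    def prep(x):
        if standardizer is None:
            return x
        if callable(standardizer):
            return standardizer(x)
        return (x - standardizer[0]) / standardizer[1]

    def feats(ts, bs=256):
        return np.concatenate(
            [model.features(prep(ts.data[i : i + bs])) for i in range(0, ts.n_trials, bs)]
        )

    y_train = ts_train.labels.astype(int)
    if len(np.unique(y_train)) < 2:
        # degenerate head: a single training class is always predicted
        only = int(y_train[0])
        return float(np.mean(ts_test.labels.astype(int) == only))
    head = LinearSVC(random_state=seed)
    head.fit(feats(ts_train), y_train)
    return float(head.score(feats(ts_test), ts_test.labels.astype(int)))


# ---------------------------------------------------------------------------
# Hyperparameter search


def _sample(space: dict, rng: np.random.Generator) -> dict:
    cfg = {}
    for name, spec in space.items():
        kind = spec[0]
        if kind == "uniform":
            cfg[name] = float(rng.uniform(spec[1], spec[2]))
        elif kind == "loguniform":
            cfg[name] = float(np.exp(rng.uniform(np.log(spec[1]), np.log(spec[2]))))
        elif kind == "randint":
            cfg[name] = int(rng.integers(spec[1], spec[2]))
        elif kind == "choice":
            cfg[name] = spec[1][rng.integers(len(spec[1]))]
        else:
            raise ValueError(f"unknown dimension kind {kind!r} for {name!r}")
    return cfg


def hyper_search(space: dict, objective, n_iter: int, seed: int = 0, driver=None):
    """Hyperparameter search over ``space`` minimizing ``objective``.

    The driver is pluggable (``driver(space, objective, n_iter, seed)``);
    the built-in default is seeded random search.  A tree-structured Parzen
    estimator driver can be plugged in where available.  Returns
    (best_config, best_score, trial_log).
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if driver is not None:
        return driver(space, objective, n_iter, seed)
    rng = np.random.default_rng(seed)
    log = []
    best_cfg, best_score = None, np.inf
    for _ in range(n_iter):
        cfg = _sample(space, rng)
        score = float(objective(cfg))
        log.append({"config": cfg, "score": score})
        if score < best_score:
            best_cfg, best_score = cfg, score
    return best_cfg, best_score, log
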