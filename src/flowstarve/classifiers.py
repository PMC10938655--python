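"""Breath-severity classifiers and the repeated-holdout evaluation protocol.

Two 3-class sequence classifiers over the 80-sample inspiratory Paw vector:

* ``recurrent`` — two stacked LSTM layers of 128 units; the final hidden
  state feeds a fully connected 3-way output.
* ``conv1d`` — three 1-D convolution blocks (16/32/64 filters, kernel 5,
  ReLU, max-pool 2) followed by a fully connected 3-way output.

Evaluation follows repeated holdout: a fresh class-stratified 80/20
train-validation split per repetition, a freshly initialized model, and
median metrics across repetitions. Raw cmH2O values enter the network;
a fixed affine rescaling (x/20 − 1) inside the input layer keeps the
optimization well conditioned without altering per-breath information.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import _nn
from .io import N_SAMPLES, SEVERITY_CLASSES, X_COLUMNS, validate_breath_table

LABEL_TO_INT = {c: i for i, c in enumerate(SEVERITY_CLASSES)}

# fixed input conditioning constants (architecture, not data standardization)
INPUT_SCALE = 1.0 / 20.0
INPUT_SHIFT = -1.0


@dataclass
class ModelConfig:
    """Architecture and training hyperparameters."""

    architecture: str = "recurrent"  # recurrent | conv1d
    input_length: int = N_SAMPLES
    n_classes: int = 3
    recurrent_hidden_units: int = 128
    recurrent_layers: int = 2
    conv_channels: Sequence[int] = (16, 32, 64)
    conv_kernel_sizes: Sequence[int] = (5, 5, 5)
    epochs: int = 50
    batch_size: int = 64
    learning_rate: float = 1e-3
    early_stopping: bool = True
    patience: int = 5
    inner_holdout: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.architecture not in ("recurrent", "conv1d"):
            raise ValueError(f"unknown architecture '{self.architecture}'")
        if self.input_length != N_SAMPLES:
            raise ValueError(f"input_length must be {N_SAMPLES}")
        if self.n_classes != 3:
            raise ValueError("n_classes must be 3")
        if len(self.conv_channels) != len(self.conv_kernel_sizes):
            raise ValueError(
                "conv_channels and conv_kernel_sizes must have the same length"
            )


class RecurrentClassifier:
    """Stacked-LSTM sequence classifier over the 80-step Paw vector."""

    def __init__(self, config: ModelConfig, dtype=np.float32):
        rng = np.random.default_rng(config.seed)
        self.config = config
        self.dtype = dtype
        H = config.recurrent_hidden_units
        self.lstms = [
            _nn.LSTM(1 if k == 0 else H, H, rng, dtype)
            for k in range(config.recurrent_layers)
        ]
        self.head = _nn.Dense(H, config.n_classes, rng, dtype)
        self.layers = [*self.lstms, self.head]

    def forward(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=self.dtype)
        h = (x * INPUT_SCALE + INPUT_SHIFT)[:, :, None]
        for lstm in self.lstms:
            h = lstm.forward(h)
        return self.head.forward(h[:, -1, :])

    def backward(self, dlogits) -> None:
        dh_last = self.head.backward(dlogits)
        N, T = dh_last.shape[0], self.config.input_length
        dh = np.zeros((N, T, dh_last.shape[1]), dtype=self.dtype)
        dh[:, -1, :] = dh_last
        for lstm in reversed(self.lstms):
            dh = lstm.backward(dh)

    def n_parameters(self) -> int:
        return sum(p.size for ly in self.layers for p in ly.params.values())


class ConvClassifier:
    """1-D convolutional classifier over the 80-step Paw vector."""

    def __init__(self, config: ModelConfig, dtype=np.float32):
        rng = np.random.default_rng(config.seed)
        self.config = config
        self.dtype = dtype
        blocks = []
        n_in, length = 1, config.input_length
        for ch, k in zip(config.conv_channels, config.conv_kernel_sizes):
            blocks += [_nn.Conv1d(n_in, ch, k, rng, dtype), _nn.ReLU(), _nn.MaxPool1d()]
            n_in, length = ch, length // 2
        self.blocks = blocks
        self.head = _nn.Dense(n_in * length, config.n_classes, rng, dtype)
        self.layers = [*blocks, self.head]
        self._flat_shape = (n_in, length)

    def forward(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=self.dtype)
        h = (x * INPUT_SCALE + INPUT_SHIFT)[:, None, :]
        for block in self.blocks:
            h = block.forward(h)
        return self.head.forward(h.reshape(len(h), -1))

    def backward(self, dlogits) -> None:
        dh = self.head.backward(dlogits)
        dh = dh.reshape(len(dh), *self._flat_shape)
        for block in reversed(self.blocks):
            dh = block.backward(dh)

    def n_parameters(self) -> int:
        return sum(p.size for ly in self.layers for p in ly.params.values())


def build_model(config: ModelConfig):
    """Instantiate a freshly initialized classifier from its config."""
    if config.architecture == "recurrent":
        return RecurrentClassifier(config)
    return ConvClassifier(config)


def predict_proba(model, x: np.ndarray) -> np.ndarray:
    """Class probabilities for a batch of 80-vectors (rows sum to 1)."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if not np.all(np.isfinite(x)):
        raise ValueError("classifier input contains non-finite values")
    probs = []
    for start in range(0, len(x), 512):
        probs.append(_nn.softmax(model.forward(x[start : start + 512])))
    return np.concatenate(probs).astype(float)


def _argmax_severe(probs: np.ndarray) -> np.ndarray:
    """Row-wise argmax with ties broken toward the more severe class."""
    rev = probs[:, ::-1]
    return probs.shape[1] - 1 - rev.argmax(axis=1)


def predict_breath(model, x) -> tuple[str, np.ndarray]:
    """Predict the severity class of one breath; ties favor severity."""
    probs = predict_proba(model, np.atleast_2d(x))
    idx = _argmax_severe(probs)[0]
    return SEVERITY_CLASSES[idx], probs[0]


def predict_labels(model, x: np.ndarray) -> np.ndarray:
    """Integer class predictions for a batch."""
    return _argmax_severe(predict_proba(model, x))


def _table_xy(table: pd.DataFrame, require_labels: bool = True):
    x = table[X_COLUMNS].to_numpy(dtype=float)
    labels = table["label"]
    if require_labels and labels.isna().any():
        bad = table.loc[labels.isna(), "breath_id"].iloc[0]
        raise ValueError(f"unlabeled breath '{bad}' in a training table")
    y = labels.map(LABEL_TO_INT).to_numpy()
    return x, y


def train_model(model, table: pd.DataFrame, config: Optional[ModelConfig] = None):
    """Train a classifier on a labeled breath table.

    Minimizes multinomial cross-entropy with Adam. When early stopping is on,
    10% of the training data is held out internally and the parameters from
    the epoch with the best inner-holdout loss are restored. Deterministic
    given ``config.seed``. Returns ``(model, log)`` where ``log`` is a list
    of per-epoch records.
    """
    config = config or model.config
    x, y = _table_xy(validate_breath_table(table))
    return fit(model, x, y, config)


def fit(model, x: np.ndarray, y: np.ndarray, config: ModelConfig):
    """Array-level training loop (see :func:`train_model`)."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7919]))
    n = len(x)
    x_tr, y_tr, x_in, y_in = x, y, None, None
    if config.early_stopping and n >= 20:
        perm = rng.permutation(n)
        n_in = max(1, int(round(config.inner_holdout * n)))
        inner, outer = perm[:n_in], perm[n_in:]
        x_tr, y_tr = x[outer], y[outer]
        x_in, y_in = x[inner], y[inner]
    log = []
    best_loss, best_params, since_best = np.inf, None, 0
    opt = _nn.Adam(model.layers, lr=config.learning_rate)
    for epoch in range(config.epochs):
        order = rng.permutation(len(x_tr))
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, len(x_tr), config.batch_size):
            idx = order[start : start + config.batch_size]
            logits = model.forward(x_tr[idx])
            loss, dlogits = _nn.cross_entropy(logits, y_tr[idx])
            model.backward(dlogits.astype(model.dtype))
            opt.step()
            epoch_loss += loss
            n_batches += 1
        record = {"epoch": epoch, "train_loss": epoch_loss / max(n_batches, 1)}
        if x_in is not None:
            logits = model.forward(x_in)
            val_loss, _ = _nn.cross_entropy(logits, y_in)
            record["inner_val_loss"] = val_loss
            if val_loss < best_loss - 1e-5:
                best_loss = val_loss
                best_params = [
                    {k: v.copy() for k, v in ly.params.items()} for ly in model.layers
                ]
                since_best = 0
            else:
                since_best += 1
        log.append(record)
        if x_in is not None and since_best >= config.patience:
            break
    if best_params is not None:
        for ly, saved in zip(model.layers, best_params):
            for k in ly.params:
                ly.params[k][...] = saved[k]
    return model, log


def cap_breaths_per_patient(
    table: pd.DataFrame, cap: int = 350, seed: int = 0
) -> pd.DataFrame:
    """Cap each (patient, class) stratum at ``cap`` breaths.

    Strata above the cap are uniformly subsampled (deterministic given
    ``seed``); everything else is untouched. Prevents overrepresented
    patients from dominating the training set.
    """
    rng = np.random.default_rng(seed)
    keep = []
    for _, group in table.groupby(["patient_id", "label"], sort=True, dropna=False):
        if len(group) > cap:
            keep.append(group.iloc[np.sort(rng.permutation(len(group))[:cap])])
        else:
            keep.append(group)
    return pd.concat(keep).sort_index().reset_index(drop=True)


def confusion_matrix(true_labels, predicted_labels) -> np.ndarray:
    """3×3 count matrix, rows = true class, columns = predicted class.

    Accepts class names or integer codes; rows and columns are ordered
    normal_mild, moderate, severe.
    """

    def to_int(v):
        if isinstance(v, str):
            if v not in LABEL_TO_INT:
                raise ValueError(f"unknown label '{v}'")
            return LABEL_TO_INT[v]
        iv = int(v)
        if not 0 <= iv < 3:
            raise ValueError(f"unknown label code {v}")
        return iv

    t = np.array([to_int(v) for v in true_labels])
    p = np.array([to_int(v) for v in predicted_labels])
    if len(t) != len(p):
        raise ValueError("true and predicted label sequences differ in length")
    cm = np.zeros((3, 3), dtype=int)
    np.add.at(cm, (t, p), 1)
    return cm


def classification_metrics(cm: np.ndarray, average: str = "weighted") -> dict:
    """Accuracy, precision, recall and F1 (all in percent) from a 3×3 matrix.

    Per-class precision/recall/F1 are combined by support-weighted averaging
    by default (``average="macro"`` gives the unweighted mean). Classes with
    zero predicted (or true) count contribute a zero precision (recall).
    """
    cm = np.asarray(cm, dtype=float)
    total = cm.sum()
    if cm.shape != (3, 3) or total <= 0:
        raise ValueError("confusion matrix must be 3x3 with positive total")
    diag = np.diag(cm)
    row = cm.sum(axis=1)
    col = cm.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        recall = np.where(row > 0, diag / row, 0.0)
        precision = np.where(col > 0, diag / col, 0.0)
        f1 = np.where(
            precision + recall > 0,
            2 * precision * recall / (precision + recall),
            0.0,
        )
    if average == "weighted":
        w = row / total
    elif average == "macro":
        w = np.full(3, 1 / 3)
    else:
        raise ValueError(f"unknown averaging scheme '{average}'")
    accuracy = 100.0 * diag.sum() / total
    return {
        "accuracy": accuracy,
        "precision": 100.0 * float(precision @ w),
        "recall": 100.0 * float(recall @ w),
        "f1": 100.0 * float(f1 @ w),
        "misclassified_pct": 100.0 - accuracy,
        "per_class": {
            cls: {
                "precision": 100.0 * precision[i],
                "recall": 100.0 * recall[i],
                "f1": 100.0 * f1[i],
                "support": int(row[i]),
            }
            for i, cls in enumerate(SEVERITY_CLASSES)
        },
    }


@dataclass
class EvaluationReport:
    """Per-repetition confusion matrices and metrics, plus medians."""

    per_repetition: list
    median_metrics: dict
    n_repetitions: int
    split_fraction: float
    config: ModelConfig

    def to_dict(self) -> dict:
        return {
            "n_repetitions": self.n_repetitions,
            "split_fraction": self.split_fraction,
            "architecture": self.config.architecture,
            "median_metrics": self.median_metrics,
            "per_repetition": [
                {
                    "confusion_matrix": rep["confusion_matrix"].tolist(),
                    **{k: rep[k] for k in ("accuracy", "precision", "recall", "f1")},
                }
                for rep in self.per_repetition
            ],
        }


def _stratified_split(y: np.ndarray, split: float, rng) -> tuple[np.ndarray, np.ndarray]:
    train_idx, val_idx = [], []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        n_train = int(round(split * len(idx)))
        n_train = min(max(n_train, 1), len(idx) - 1)
        train_idx.append(idx[:n_train])
        val_idx.append(idx[n_train:])
    return np.concatenate(train_idx), np.concatenate(val_idx)


def repeated_holdout_evaluate(
    table: pd.DataFrame,
    config: ModelConfig,
    n_repetitions: int = 15,
    split: float = 0.8,
    seed: int = 0,
) -> EvaluationReport:
    """Repeated stratified holdout evaluation.

    Each repetition draws a fresh class-stratified ``split``/(1−split)
    train-validation partition, trains a freshly initialized model, and
    scores the validation set. Median metrics across repetitions summarize
    performance.
    """
    x, y = _table_xy(validate_breath_table(table))
    present = np.unique(y)
    if len(present) < 3:
        missing = [c for i, c in enumerate(SEVERITY_CLASSES) if i not in present]
        raise ValueError(f"classes absent from table: {missing}")
    ss = np.random.SeedSequence([seed, 104729])
    reps = []
    for rep, child in enumerate(ss.spawn(n_repetitions)):
        rep_seed = int(child.generate_state(1)[0] % (2**31 - 1))
        rng = np.random.default_rng(rep_seed)
        tr, va = _stratified_split(y, split, rng)
        cfg = replace(config, seed=rep_seed)
        model = build_model(cfg)
        fit(model, x[tr], y[tr], cfg)
        pred = predict_labels(model, x[va])
        cm = confusion_matrix(y[va], pred)
        metrics = classification_metrics(cm)
        reps.append(
            {
                "confusion_matrix": cm,
                "accuracy": metrics["accuracy"],
                "precision": metrics["precision"],
                "recall": metrics["recall"],
                "f1": metrics["f1"],
            }
        )
    median_metrics = {
        k: float(np.median([r[k] for r in reps]))
        for k in ("accuracy", "precision", "recall", "f1")
    }
    return EvaluationReport(
        per_repetition=reps,
        median_metrics=median_metrics,
        n_repetitions=n_repetitions,
        split_fraction=split,
        config=config,
    )


def learning_curve(
    table: pd.DataFrame,
    config: ModelConfig,
    sample_sizes: Sequence[int],
    n_repetitions: int = 5,
    seed: int = 0,
) -> list[tuple[int, float]]:
    """Median validation accuracy as a function of training-set size.

    For each size a class-stratified subsample of the table is drawn and
    evaluated with repeated holdout.
    """
    table = validate_breath_table(table)
    n = len(table)
    points = []
    rng = np.random.default_rng(np.random.SeedSequence([seed, 15485863]))
    for size in sample_sizes:
        if size > n:
            raise ValueError(f"sample size {size} exceeds table size {n}")
        if size < 3 * 2:
            raise ValueError(f"sample size {size} too small for 3 stratified classes")
        if size == n:
            sub = table
        else:
            frac = size / n
            parts = []
            for _, group in table.groupby("label", sort=True):
                k = max(2, int(round(frac * len(group))))
                idx = rng.permutation(len(group))[:k]
                parts.append(group.iloc[np.sort(idx)])
            sub = pd.concat(parts).reset_index(drop=True)
        report = repeated_holdout_evaluate(
            sub, config, n_repetitions=n_repetitions, seed=seed
        )
        points.append((int(len(sub)), report.median_metrics["accuracy"]))
    return points
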