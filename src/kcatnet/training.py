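"""Training loop, evaluation metrics, multi-round averaging, group contrasts.

The model is trained by minimising mean squared error on log10(kcat) with
Adam; the validation split drives early stopping and best-weight retention.
Evaluation uses three metrics on the log10 scale:

* R² = 1 − Σ(y_e − y_p)² / Σ(y_e − ȳ_e)²  (against the mean of the
  experimental values),
* RMSE = √(Σ(y_e − y_p)²/n)  in log10 units,
* PCC, the Pearson correlation coefficient.

Robustness to split sampling is assessed by repeating split → train →
evaluate over several seeded rounds (five by default) and averaging train
and test R². Group contrasts (e.g. mutant classes) use a two-sided
two-sample t-test, Welch by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import ConfigError, ShapeError, StatisticsError, TrainingError
from .features import FeaturizedRecord
from .network import KcatNetwork
from .records import KcatRecord, similarity_bin_label, max_identity_to_train

__all__ = [
    "TrainConfig",
    "MetricsReport",
    "compute_metrics",
    "train",
    "multi_round_evaluate",
    "grouped_metrics",
    "compare_groups",
    "Adam",
]


@dataclass
class TrainConfig:
    """Optimisation hyperparameters (loss is MSE on log10 kcat)."""

    epochs: int = 15
    batch_size: int = 16
    learning_rate: float = 5e-3
    weight_decay: float = 0.0
    seed: int = 0
    rounds: int = 5
    patience: int | None = None  # early stopping on validation loss; None = off

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1 or self.rounds < 1:
            raise ConfigError("epochs, batch_size and rounds must be >= 1")
        if self.learning_rate <= 0:
            raise ConfigError(f"learning_rate must be > 0, got {self.learning_rate}")


@dataclass
class MetricsReport:
    """R², RMSE (log10 units) and Pearson correlation for one record set."""

    r2: float | None
    rmse: float
    pcc: float | None
    n: int
    group: str | None = None
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "group": self.group,
            "n": self.n,
            "r2": self.r2,
            "rmse": self.rmse,
            "pcc": self.pcc,
            "notes": self.notes,
        }


def compute_metrics(
    y_exp: Sequence[float], y_pred: Sequence[float], group: str | None = None
) -> MetricsReport:
    """Evaluate R², RMSE and PCC of predictions against experimental values.

    When the experimental values are constant both R² and PCC are undefined;
    the report then carries ``None`` for those entries plus an explanatory
    note, while RMSE is always returned.
    """
    y_exp = np.asarray(y_exp, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_exp.shape != y_pred.shape or y_exp.ndim != 1:
        raise ShapeError(
            f"y_exp and y_pred must be equal-length 1-D, got {y_exp.shape} vs {y_pred.shape}"
        )
    if len(y_exp) < 2:
        raise ShapeError(f"need at least 2 values, got {len(y_exp)}")

    sse = float(np.sum((y_exp - y_pred) ** 2))
    rmse = math.sqrt(sse / len(y_exp))
    sst = float(np.sum((y_exp - y_exp.mean()) ** 2))
    notes: list[str] = []
    if sst == 0.0:
        r2 = None
        notes.append("r2 undefined: constant experimental values")
    else:
        r2 = 1.0 - sse / sst

    if np.std(y_exp) == 0.0 or np.std(y_pred) == 0.0:
        pcc = None
        notes.append("pcc undefined: zero variance")
    else:
        num = float(np.sum((y_exp - y_exp.mean()) * (y_pred - y_pred.mean())))
        den = math.sqrt(
            float(np.sum((y_exp - y_exp.mean()) ** 2))
            * float(np.sum((y_pred - y_pred.mean()) ** 2))
        )
        pcc = num / den
    return MetricsReport(r2=r2, rmse=rmse, pcc=pcc, n=len(y_exp), group=group, notes=notes)


class Adam:
    """Adam optimiser with optional decoupled weight decay."""

    def __init__(
        self,
        tensors,
        learning_rate: float = 5e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.0,
    ):
        self.tensors = list(tensors)
        self.lr = learning_rate
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(t.data) for t in self.tensors]
        self.v = [np.zeros_like(t.data) for t in self.tensors]

    def zero_grad(self) -> None:
        for t in self.tensors:
            t.zero_grad()

    def step(self) -> None:
        self.t += 1
        bias1 = 1.0 - self.beta1**self.t
        bias2 = 1.0 - self.beta2**self.t
        for i, tensor in enumerate(self.tensors):
            if tensor.grad is None:
                continue
            g = tensor.grad
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g * g
            m_hat = self.m[i] / bias1
            v_hat = self.v[i] / bias2
            if self.weight_decay:
                tensor.data *= 1.0 - self.lr * self.weight_decay
            tensor.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def _mse(network: KcatNetwork, feats: Sequence[FeaturizedRecord]) -> float:
    preds = network.predict(feats)
    targets = np.array([f.target for f in feats])
    return float(np.mean((preds - targets) ** 2))


def train(
    network: KcatNetwork,
    train_feats: Sequence[FeaturizedRecord],
    val_feats: Sequence[FeaturizedRecord] | None,
    config: TrainConfig,
) -> dict:
    """Fit the network by minibatch MSE descent; returns the loss history.

    The per-epoch history holds the running mean train loss and (when a
    validation set is supplied) the validation MSE; the parameters achieving
    the best validation loss are restored at the end. With
    ``config.patience`` set, training stops after that many epochs without
    validation improvement.
    """
    if not train_feats:
        raise TrainingError("empty training set")
    opt = Adam(
        [t for _, t in network.parameters()],
        learning_rate=config.learning_rate,
        weight_decay=config.weight_decay,
    )
    rng = np.random.default_rng(config.seed)
    history: dict = {"train_loss": [], "val_loss": []}
    best_val = math.inf
    best_state = None
    stale = 0

    for epoch in range(config.epochs):
        order = rng.permutation(len(train_feats))
        epoch_sse = 0.0
        for start in range(0, len(order), config.batch_size):
            batch = order[start : start + config.batch_size]
            losses = []
            for i in batch:
                feat = train_feats[i]
                pred, _ = network.forward(feat)
                diff = pred - feat.target
                losses.append((diff * diff).sum())
            loss = losses[0]
            for extra in losses[1:]:
                loss = loss + extra
            loss = loss * (1.0 / len(batch))
            if not np.isfinite(loss.numpy()).all():
                raise TrainingError(f"non-finite training loss at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_sse += float(loss.numpy()) * len(batch)
        history["train_loss"].append(epoch_sse / len(train_feats))

        if val_feats:
            val_loss = _mse(network, val_feats)
            if not math.isfinite(val_loss):
                raise TrainingError(f"non-finite validation loss at epoch {epoch}")
            history["val_loss"].append(val_loss)
            if val_loss < best_val - 1e-12:
                best_val = val_loss
                best_state = network.state_dict()
                stale = 0
            else:
                stale += 1
                if config.patience is not None and stale >= config.patience:
                    break

    if best_state is not None:
        network.load_state_dict(best_state)
    return history


def multi_round_evaluate(
    records: Sequence[KcatRecord],
    model_config,
    train_config: TrainConfig,
    structures=None,
    base_dir=None,
    resplit: bool = True,
) -> dict:
    """Average train/test R² over `train_config.rounds` seeded rounds.

    Each round re-splits the data with a new seed (``resplit=True``, the
    default) or keeps the split fixed and only re-seeds the model
    initialisation and batch order.
    """
    from .pipeline import fit_pipeline  # local import to avoid a cycle

    rounds = []
    for r in range(train_config.rounds):
        round_seed = train_config.seed + r
        result = fit_pipeline(
            records,
            model_config=type(model_config)(**{**model_config.to_dict(), "seed": round_seed}),
            train_config=TrainConfig(**{**train_config.__dict__, "seed": round_seed}),
            structures=structures,
            base_dir=base_dir,
            split_seed=round_seed if resplit else train_config.seed,
        )
        train_metrics = compute_metrics(
            [f.target for f in result.featurized["train"]],
            result.network.predict(result.featurized["train"]),
        )
        rounds.append(
            {
                "seed": round_seed,
                "train_r2": train_metrics.r2,
                "test_r2": result.test_metrics.r2,
            }
        )
    return {
        "rounds": rounds,
        "mean_train_r2": float(np.mean([x["train_r2"] for x in rounds])),
        "mean_test_r2": float(np.mean([x["test_r2"] for x in rounds])),
    }


_GROUP_KEYS = ("enzyme_type", "ec_class", "similarity_bin")


def grouped_metrics(
    test_records: Sequence[KcatRecord],
    y_pred: Sequence[float],
    group_by: str,
    train_records: Sequence[KcatRecord] | None = None,
) -> list[MetricsReport]:
    """Per-group metrics over the test set.

    `group_by` is one of ``enzyme_type``, ``ec_class`` or ``similarity_bin``
    (the last needs `train_records` to score max identities). Groups with
    fewer than two members are flagged and skipped (rmse reported as nan).
    """
    if group_by not in _GROUP_KEYS:
        raise ConfigError(f"group_by must be one of {_GROUP_KEYS}, got {group_by!r}")
    y_pred = np.asarray(y_pred, dtype=float)
    if len(y_pred) != len(test_records):
        raise ShapeError("predictions and records differ in length")

    if group_by == "similarity_bin":
        if not train_records:
            raise ConfigError("similarity_bin grouping requires train_records")
        identity = max_identity_to_train(test_records, train_records)
        labels = [similarity_bin_label(identity[r.record_id]) for r in test_records]
    elif group_by == "enzyme_type":
        labels = [r.enzyme_type.value for r in test_records]
    else:
        labels = [
            "unknown" if r.ec_class is None else f"EC{r.ec_class}" for r in test_records
        ]

    reports: list[MetricsReport] = []
    for label in sorted(set(labels)):
        idx = [i for i, l in enumerate(labels) if l == label]
        if len(idx) < 2:
            reports.append(
                MetricsReport(
                    r2=None,
                    rmse=float("nan"),
                    pcc=None,
                    n=len(idx),
                    group=label,
                    notes=["skipped: fewer than 2 records"],
                )
            )
            continue
        reports.append(
            compute_metrics(
                [test_records[i].log_kcat for i in idx], y_pred[idx], group=label
            )
        )
    return reports


def compare_groups(
    values_a: Sequence[float],
    values_b: Sequence[float],
    equal_var: bool = False,
) -> tuple[float, float]:
    """Two-sided two-sample t-test (Welch by default) on raw values.

    Returns ``(t, p)``. Raises when either group has fewer than two values
    or when both groups are degenerate (zero variance), where the statistic
    is undefined.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise StatisticsError("each group needs at least 2 values")
    if np.var(a) == 0.0 and np.var(b) == 0.0:
        raise StatisticsError("both groups have zero variance; t-test undefined")
    result = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(result.statistic), float(result.pvalue)
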