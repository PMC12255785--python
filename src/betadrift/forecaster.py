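"""Encoder–decoder attention forecaster for daily beta-power distributions.

Each min–max-normalised daily histogram is a token of dimension ``M``
(= number of bins); a sequence of ``N`` consecutive days is the source, and
the model predicts the distribution of day ``N + K`` (horizon K between 1
and 6 days) in a single non-autoregressive pass: the position-encoded
sequence is fed as both source and target of the encoder–decoder stack,
the representation of the last position summarises the sequence, and an
affine head with a sigmoid squashes the output back into [0, 1].

Training minimises the weighted mean absolute percentage error (wMAPE)
between predicted and observed distributions with RMSProp.  Two regimes are
supported: single-setting (train/validate within one aDBS parameter epoch)
and multi-setting quasi-leave-one-set-out (train on all epochs but one,
then fine-tune at a reduced learning rate on half of the held-out epoch and
validate on the other half).
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from ._autodiff import Tensor
from .distributions import DailyDistribution
from .evaluation import wmape

__all__ = [
    "ForecastExample",
    "ForecastDataset",
    "ForecasterConfig",
    "TrainedForecaster",
    "make_forecast_dataset",
    "split_train_val",
    "wmape_loss",
    "train_single_setting",
    "train_multi_setting",
    "predict_k_ahead",
    "select_optimal_history",
]


@dataclass(frozen=True)
class ForecastExample:
    input: np.ndarray        # (N, M) normalised distributions, consecutive days
    label: np.ndarray        # (M,) normalised distribution of day N + K
    input_dates: tuple[dt.date, ...]
    label_date: dt.date
    epoch_id: str = ""

    def __post_init__(self):
        x = np.asarray(self.input, dtype=float)
        y = np.asarray(self.label, dtype=float)
        object.__setattr__(self, "input", x)
        object.__setattr__(self, "label", y)
        if x.min() < 0 or x.max() > 1 or y.min() < 0 or y.max() > 1:
            raise ValueError("distributions must lie in [0, 1]")


@dataclass(frozen=True)
class ForecastDataset:
    examples: tuple[ForecastExample, ...]
    n_history: int
    horizon: int

    def __post_init__(self):
        object.__setattr__(self, "examples", tuple(self.examples))
        for ex in self.examples:
            if ex.input.shape[0] != self.n_history:
                raise ValueError("inhomogeneous history length")

    def __len__(self) -> int:
        return len(self.examples)

    @property
    def n_bins(self) -> int:
        return self.examples[0].input.shape[1]

    def inputs(self) -> np.ndarray:
        return np.stack([ex.input for ex in self.examples])

    def labels(self) -> np.ndarray:
        return np.stack([ex.label for ex in self.examples])


@dataclass(frozen=True)
class ForecasterConfig:
    n_bins: int = 206
    n_history: int = 2
    horizon: int = 1
    encoder_layers: int = 3
    decoder_layers: int = 6
    attention_heads: int = 2
    feedforward_width: int = 512
    dropout: float = 0.1
    learning_rate: float = 1e-4
    finetune_learning_rate: float = 1e-5
    epochs: int = 20000
    finetune_epochs: int | None = None
    train_fraction: float = 0.85
    eval_every: int = 1

    def __post_init__(self):
        if self.n_bins % self.attention_heads != 0:
            raise ValueError(
                f"attention_heads={self.attention_heads} must divide "
                f"n_bins={self.n_bins}")
        if not 1 <= self.horizon <= 6:
            raise ValueError(f"horizon K must lie in [1, 6], got {self.horizon}")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_history < 1:
            raise ValueError("n_history must be >= 1")


class DistributionTransformer(nn.Module):
    """The encoder–decoder stack plus the sigmoid output head.

    The output head uses prior-based initialisation: its weights are
    down-scaled and its bias set to the logit of the per-bin mean of the
    training labels (when provided), so the untrained model starts from
    the base-rate distribution instead of a flat 0.5 vector.  With sparse
    normalised histograms this removes a long plateau in which the
    optimiser only drifts the output bias.
    """

    def __init__(self, config: ForecasterConfig, seed: int,
                 output_prior: np.ndarray | None = None):
        rng = np.random.default_rng(seed)
        self.core = nn.EncoderDecoder(
            d_model=config.n_bins, n_heads=config.attention_heads,
            d_ff=config.feedforward_width,
            n_encoder_layers=config.encoder_layers,
            n_decoder_layers=config.decoder_layers,
            dropout=config.dropout, rng=rng,
            max_len=max(8, config.n_history + 2))
        self.head = nn.Linear(config.n_bins, config.n_bins, rng)
        self.head.weight.data *= 0.1
        if output_prior is not None:
            prior = np.clip(np.asarray(output_prior, dtype=float), 1e-3,
                            1.0 - 1e-3)
            self.head.bias.data[...] = np.log(prior / (1.0 - prior))
        self.config = config

    def forward(self, x: np.ndarray, training: bool = False) -> Tensor:
        x = np.asarray(x, dtype=float)
        if x.ndim == 2:
            x = x[None, :, :]
        expected = (self.config.n_history, self.config.n_bins)
        if x.shape[1:] != expected:
            raise ValueError(
                f"input shape {x.shape[1:]} does not match expected (N, M) = "
                f"{expected}")
        out = self.core(Tensor(x), training=training)
        return self.head(out[:, -1, :]).sigmoid()

    def predict(self, x: np.ndarray) -> np.ndarray:
        out = self.forward(x, training=False).data
        return out[0] if out.shape[0] == 1 else out


@dataclass
class TrainedForecaster:
    model: DistributionTransformer
    config: ForecasterConfig
    seed: int
    history: dict = field(default_factory=dict)  # epoch -> (train, val) losses
    validation_wmape: float = np.nan

    def predict(self, recent: np.ndarray) -> np.ndarray:
        return self.model.predict(recent)

    def save(self, path) -> None:
        arrays = {f"p{i}": p.data for i, p in enumerate(self.model.parameters())}
        cfg = json.dumps(self.config.__dict__)
        np.savez(Path(path), _config=cfg, _seed=self.seed, **arrays)

    @classmethod
    def load(cls, path) -> "TrainedForecaster":
        blob = np.load(Path(path), allow_pickle=False)
        cfg = ForecasterConfig(**json.loads(str(blob["_config"])))
        seed = int(blob["_seed"])
        tf = cls(model=DistributionTransformer(cfg, seed), config=cfg, seed=seed)
        for i, p in enumerate(tf.model.parameters()):
            p.data[...] = blob[f"p{i}"]
        return tf


# ---------------------------------------------------------------------------
# dataset construction
# ---------------------------------------------------------------------------

def _consecutive_runs(dists: list[DailyDistribution]) -> list[list[DailyDistribution]]:
    """Split a sorted day list into runs of strictly consecutive dates."""
    runs: list[list[DailyDistribution]] = []
    for d in sorted(dists, key=lambda x: x.date):
        if runs and (d.date - runs[-1][-1].date).days == 1:
            runs[-1].append(d)
        else:
            runs.append([d])
    return runs


def make_forecast_dataset(dists_by_epoch: dict[str, list[DailyDistribution]],
                          n_history: int, horizon: int) -> ForecastDataset:
    """Supervised (input, label) tuples from per-epoch daily distributions.

    One example per window of ``n_history`` consecutive days whose day
    ``n_history + horizon`` also exists in the same epoch; windows never
    span an epoch boundary or a calendar gap, so each consecutive run of
    D days contributes ``max(0, D - N - K + 1)`` examples.
    """
    if n_history < 1:
        raise ValueError("n_history must be >= 1")
    if not 1 <= horizon <= 6:
        raise ValueError(f"horizon K must lie in [1, 6], got {horizon}")
    examples: list[ForecastExample] = []
    n_days_seen = 0
    for epoch_id, dists in dists_by_epoch.items():
        n_days_seen += len(dists)
        for run in _consecutive_runs(list(dists)):
            span = n_history + horizon
            for i in range(len(run) - span + 1):
                window = run[i:i + n_history]
                label = run[i + span - 1]
                examples.append(ForecastExample(
                    input=np.stack([d.normalized for d in window]),
                    label=label.normalized,
                    input_dates=tuple(d.date for d in window),
                    label_date=label.date,
                    epoch_id=str(epoch_id)))
    if not examples:
        raise ValueError(
            f"no valid (N={n_history}, K={horizon}) windows in "
            f"{len(dists_by_epoch)} epoch(s) / {n_days_seen} usable day(s)")
    return ForecastDataset(tuple(examples), n_history, horizon)


def split_train_val(dataset: ForecastDataset, train_fraction: float = 0.85,
                    seed: int = 0) -> tuple[ForecastDataset, ForecastDataset]:
    """Chronological split (validation = latest label dates), shuffled train.

    Holding out the most recent examples keeps validation in the future of
    the training data; the training subset is then shuffled with ``seed``.
    """
    n = len(dataset)
    if n < 2:
        raise ValueError("need at least 2 examples to split")
    n_train = int(train_fraction * n)
    if n_train < 1 or n_train >= n:
        raise ValueError(
            f"train_fraction={train_fraction} leaves an empty subset for n={n}")
    ordered = sorted(dataset.examples, key=lambda ex: ex.label_date)
    train = list(ordered[:n_train])
    val = list(ordered[n_train:])
    np.random.default_rng(seed).shuffle(train)
    return (ForecastDataset(tuple(train), dataset.n_history, dataset.horizon),
            ForecastDataset(tuple(val), dataset.n_history, dataset.horizon))


# ---------------------------------------------------------------------------
# loss and training
# ---------------------------------------------------------------------------

def wmape_loss(y_true: np.ndarray, y_pred) -> float:
    """wMAPE between two distribution vectors (delegates to the shared metric)."""
    return wmape(y_true, y_pred.data if isinstance(y_pred, Tensor) else y_pred)


def _batch_wmape_tensor(pred: Tensor, labels: np.ndarray) -> Tensor:
    """Mean over examples of sum_i |y_i - yhat_i| / sum_i |y_i|."""
    denom = np.abs(labels).sum(axis=1)
    if (denom == 0).any():
        raise ValueError("wMAPE undefined: an all-zero target distribution")
    diff = (pred - Tensor(labels)).abs().sum(axis=1)
    return (diff * (1.0 / denom)).mean()


def _fit(model: DistributionTransformer, train: ForecastDataset,
         val: ForecastDataset | None, epochs: int, lr: float,
         eval_every: int) -> dict:
    opt = nn.RMSProp(model.parameters(), lr=lr)
    x_train, y_train = train.inputs(), train.labels()
    history: dict[int, tuple[float, float]] = {}
    val_loss = np.nan
    for epoch in range(epochs):
        pred = model.forward(x_train, training=True)
        loss = _batch_wmape_tensor(pred, y_train)
        train_loss = float(loss.data)
        if not np.isfinite(train_loss):
            raise RuntimeError(
                f"training diverged at epoch {epoch} (loss={train_loss})")
        opt.zero_grad()
        loss.backward()
        opt.step()
        if val is not None and (epoch % eval_every == 0 or epoch == epochs - 1):
            val_pred = model.forward(val.inputs(), training=False)
            val_loss = float(_batch_wmape_tensor(val_pred, val.labels()).data)
        history[epoch] = (train_loss, val_loss)
    return history


def evaluate_wmape(model: DistributionTransformer,
                   dataset: ForecastDataset) -> float:
    pred = model.forward(dataset.inputs(), training=False)
    return float(_batch_wmape_tensor(pred, dataset.labels()).data)


def train_single_setting(dataset: ForecastDataset, config: ForecasterConfig,
                         seed: int) -> TrainedForecaster:
    """Train on one epoch's examples with an 85/15 chronological split."""
    if dataset.n_history != config.n_history or dataset.horizon != config.horizon:
        raise ValueError("dataset (N, K) does not match the configuration")
    train, val = split_train_val(dataset, config.train_fraction, seed)
    model = DistributionTransformer(config, seed,
                                    output_prior=train.labels().mean(axis=0))
    history = _fit(model, train, val, config.epochs, config.learning_rate,
                   config.eval_every)
    return TrainedForecaster(model=model, config=config, seed=seed,
                             history=history,
                             validation_wmape=evaluate_wmape(model, val))


def train_multi_setting(datasets_by_epoch: dict[str, ForecastDataset],
                        heldout_epoch_id: str, config: ForecasterConfig,
                        seed: int) -> TrainedForecaster:
    """Quasi-leave-one-set-out training across aDBS parameter epochs.

    Phase 1 trains on every epoch except ``heldout_epoch_id``; phase 2
    fine-tunes at the reduced learning rate on a shuffled 50 % of the
    held-out epoch's examples and validates on the remaining 50 %.
    """
    if len(datasets_by_epoch) < 2:
        raise ValueError("multi-setting training requires >= 2 epochs")
    if heldout_epoch_id not in datasets_by_epoch:
        raise KeyError(f"unknown held-out epoch {heldout_epoch_id!r}")
    heldout = datasets_by_epoch[heldout_epoch_id]
    if len(heldout) < 2:
        raise ValueError("held-out epoch needs >= 2 examples")
    train_examples: list[ForecastExample] = []
    for eid, ds in datasets_by_epoch.items():
        if eid == heldout_epoch_id:
            continue
        if ds.n_history != config.n_history or ds.horizon != config.horizon:
            raise ValueError("dataset (N, K) does not match the configuration")
        train_examples.extend(ds.examples)
    rng = np.random.default_rng(seed)
    rng.shuffle(train_examples)
    phase1 = ForecastDataset(tuple(train_examples), config.n_history,
                             config.horizon)

    held = list(heldout.examples)
    rng.shuffle(held)
    n_ft = len(held) // 2
    finetune = ForecastDataset(tuple(held[:n_ft]), config.n_history,
                               config.horizon)
    final_val = ForecastDataset(tuple(held[n_ft:]), config.n_history,
                                config.horizon)

    model = DistributionTransformer(config, seed,
                                    output_prior=phase1.labels().mean(axis=0))
    hist1 = _fit(model, phase1, heldout, config.epochs, config.learning_rate,
                 config.eval_every)
    ft_epochs = config.finetune_epochs or config.epochs
    hist2 = _fit(model, finetune, final_val, ft_epochs,
                 config.finetune_learning_rate, config.eval_every)
    history = {"phase1": hist1, "phase2": hist2}
    return TrainedForecaster(model=model, config=config, seed=seed,
                             history=history,
                             validation_wmape=evaluate_wmape(model, final_val))


def predict_k_ahead(trained: TrainedForecaster, recent: np.ndarray,
                    horizon: int) -> np.ndarray:
    """Forecast day N + K from the last N daily distributions.

    One model is trained per (N, K) task, so ``horizon`` must match the
    horizon the model was trained for.
    """
    if not 1 <= horizon <= 6:
        raise ValueError(f"horizon K must lie in [1, 6], got {horizon}")
    if horizon != trained.config.horizon:
        raise ValueError(
            f"model was trained for K={trained.config.horizon}, not K={horizon}")
    recent = np.asarray(recent, dtype=float)
    if recent.shape != (trained.config.n_history, trained.config.n_bins):
        raise ValueError(
            f"expected (N, M) = ({trained.config.n_history}, "
            f"{trained.config.n_bins}), got {recent.shape}")
    return trained.predict(recent)


def select_optimal_history(wmape_by_n: dict[int, list[float]]) -> int:
    """Choose N*: the smallest N whose mean validation wMAPE is within one
    standard deviation of the best N's mean."""
    stats = {n: (float(np.mean(v)), float(np.std(v)))
             for n, v in wmape_by_n.items()}
    best_n = min(stats, key=lambda n: stats[n][0])
    best_mean, best_sd = stats[best_n]
    for n in sorted(stats):
        if stats[n][0] <= best_mean + best_sd:
            return n
    return best_n
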