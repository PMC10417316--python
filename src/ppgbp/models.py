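"""The three sequence-regression architectures and their training loop.

Each model maps one standardized 200-sample PPG segment to a single pressure
value (SBP or DBP, in mmHg); SBP and DBP use separately trained models.

* ``lstm`` — two stacked LSTM layers (25 then 50 units), dropout 0.2, batch
  normalization, dense scalar head.
* ``lstm_autoencoder`` — four encoder LSTM layers (128/64/32/16) ending in a
  bottleneck vector, a repeat-vector re-expansion to the input length, four
  mirrored decoder layers, dropout 0.2, dense head on the final decoder
  state; trained end-to-end on the pressure target.
* ``cnn_lstm`` — five (convolution, ReLU, max-pool-2) blocks, dropout 0.1,
  one LSTM layer over the pooled feature sequence, two dense layers ending
  in one scalar.

Training minimizes mean squared error with one of the four from-scratch
optimizer rules.  Targets are z-scored internally on the training labels
(predictions are mapped back to mmHg), which keeps the printed learning-rate
grid usable for both pressure targets; recorded losses are in mmHg^2.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn
from .errors import InvalidArgumentError, TrainingFailureError
from .optimizers import OPTIMIZER_IDS, Optimizer
from .preprocessing import TARGET_LENGTH, segments_to_arrays

__all__ = [
    "ModelSpec",
    "TrainConfig",
    "TrainedModel",
    "build_model",
    "build_lstm",
    "build_lstm_autoencoder",
    "build_cnn_lstm",
    "train_model",
    "predict_bp",
    "save_model",
    "load_model",
]

ARCHITECTURES = ("lstm", "lstm_autoencoder", "cnn_lstm")


@dataclass(frozen=True)
class ModelSpec:
    """Architecture hyperparameters.

    The per-architecture layer widths default to the published topology where
    it is stated (LSTM units, dropout rates) and to documented conventions
    where it is not (CNN filter counts and kernel width).
    """

    architecture: str = "cnn_lstm"
    input_length: int = TARGET_LENGTH
    lstm_units: tuple[int, int] = (25, 50)
    encoder_units: tuple[int, ...] = (128, 64, 32, 16)
    cnn_filters: tuple[int, ...] = (32, 64, 64, 128, 128)
    cnn_kernel: int = 5
    cnn_lstm_units: int = 64
    dense_units: int = 64
    lstm_dropout: float = 0.2
    cnn_dropout: float = 0.1

    def validate(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise InvalidArgumentError(
                f"unknown architecture {self.architecture!r}; expected one of {ARCHITECTURES}"
            )
        if self.input_length < 1:
            raise InvalidArgumentError("input_length must be positive")


@dataclass(frozen=True)
class TrainConfig:
    optimizer: str = "adam"
    learning_rate: float = 0.001
    batch_size: int = 32
    max_epochs: int = 100
    early_stop_patience: int = 10
    loss: str = "mse"
    seed: int = 0

    def validate(self) -> None:
        if self.optimizer not in OPTIMIZER_IDS:
            raise InvalidArgumentError(f"unknown optimizer {self.optimizer!r}")
        if self.loss != "mse":
            raise InvalidArgumentError("loss is fixed to mean squared error")
        if self.batch_size < 1 or self.max_epochs < 1:
            raise InvalidArgumentError("batch_size and max_epochs must be >= 1")


@dataclass
class TrainedModel:
    model: nn.Sequential
    spec: ModelSpec
    config: TrainConfig
    history: dict[str, list[float]]
    label_mean: float
    label_sd: float


def build_lstm(spec: ModelSpec, seed: int = 0) -> nn.Sequential:
    """Two stacked LSTM layers, dropout, batch norm, dense scalar head."""
    spec.validate()
    rng = np.random.default_rng(seed)
    u1, u2 = spec.lstm_units
    return nn.Sequential(
        [
            nn.LSTM(1, u1, rng, return_sequences=True),
            nn.LSTM(u1, u2, rng, return_sequences=False),
            nn.Dropout(spec.lstm_dropout),
            nn.BatchNorm(u2),
            nn.Dense(u2, 1, rng),
        ]
    )


def build_lstm_autoencoder(spec: ModelSpec, seed: int = 0) -> nn.Sequential:
    """Four-layer LSTM encoder, repeat vector, mirrored decoder, dense head."""
    spec.validate()
    rng = np.random.default_rng(seed)
    units = spec.encoder_units
    layers: list[nn.Layer] = []
    n_in = 1
    for i, u in enumerate(units):
        last = i == len(units) - 1
        layers.append(nn.LSTM(n_in, u, rng, return_sequences=not last))
        n_in = u
    layers.append(nn.Dropout(spec.lstm_dropout))
    layers.append(nn.RepeatVector(spec.input_length))
    for u in units[::-1]:
        layers.append(nn.LSTM(n_in, u, rng, return_sequences=True))
        n_in = u
    layers.append(nn.TakeLast())
    layers.append(nn.Dense(n_in, 1, rng))
    return nn.Sequential(layers)


def build_cnn_lstm(spec: ModelSpec, seed: int = 0) -> nn.Sequential:
    """Five conv/ReLU/max-pool blocks, dropout, one LSTM, two dense layers."""
    spec.validate()
    n_blocks = len(spec.cnn_filters)
    if spec.input_length < 2**n_blocks:
        raise InvalidArgumentError(
            f"input_length {spec.input_length} too short for {n_blocks} pooling halvings"
        )
    rng = np.random.default_rng(seed)
    layers: list[nn.Layer] = []
    c_in = 1
    for c_out in spec.cnn_filters:
        layers.append(nn.Conv1D(c_in, c_out, spec.cnn_kernel, rng))
        layers.append(nn.ReLU())
        layers.append(nn.MaxPool1D(2))
        c_in = c_out
    layers.append(nn.Dropout(spec.cnn_dropout))
    layers.append(nn.LSTM(c_in, spec.cnn_lstm_units, rng, return_sequences=False))
    layers.append(nn.Dense(spec.cnn_lstm_units, spec.dense_units, rng))
    layers.append(nn.ReLU())
    layers.append(nn.Dense(spec.dense_units, 1, rng))
    return nn.Sequential(layers)


_BUILDERS = {
    "lstm": build_lstm,
    "lstm_autoencoder": build_lstm_autoencoder,
    "cnn_lstm": build_cnn_lstm,
}


def build_model(spec: ModelSpec, seed: int = 0) -> nn.Sequential:
    spec.validate()
    return _BUILDERS[spec.architecture](spec, seed)


def _as_xy(data, target: str):
    """Accept (X, y) arrays or a list of Segments."""
    if isinstance(data, tuple):
        X, y = data
        return np.asarray(X, dtype=float), np.asarray(y, dtype=float)
    return segments_to_arrays(data, target)


def _mse(pred, target):
    return float(np.mean((pred - target) ** 2))


def train_model(
    model: nn.Sequential,
    train_data,
    val_data,
    config: TrainConfig,
    spec: ModelSpec | None = None,
    target: str = "sbp",
) -> TrainedModel:
    """Mini-batch MSE training with early stopping on validation loss.

    ``train_data``/``val_data`` are either (X, y) tuples — X of shape
    (n, input_length), y in mmHg — or lists of preprocessed segments, in
    which case ``target`` selects the label.  The run is deterministic under
    a fixed seed: shuffling and dropout both flow from one generator.
    """
    config.validate()
    X_train, y_train = _as_xy(train_data, target)
    X_val, y_val = _as_xy(val_data, target)
    if len(X_train) == 0:
        raise InvalidArgumentError("empty training set")
    X_train = X_train[:, :, None]
    X_val = X_val[:, :, None]

    mu = float(np.mean(y_train))
    sd = float(np.std(y_train))
    if sd == 0:
        sd = 1.0
    yt = (y_train - mu) / sd
    yv = (y_val - mu) / sd

    rng = np.random.default_rng(config.seed)
    params = [p for _, _, p in model.parameters()]
    opt = Optimizer(config.optimizer, config.learning_rate)
    opt.bind(params)

    history: dict[str, list[float]] = {"train_loss": [], "val_loss": []}
    best_val = np.inf
    best_weights = model.get_weights()
    patience_left = config.early_stop_patience
    n = len(X_train)

    for _epoch in range(config.max_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for i0 in range(0, n, config.batch_size):
            idx = order[i0 : i0 + config.batch_size]
            xb, yb = X_train[idx], yt[idx]
            pred = model.forward(xb, training=True, rng=rng)[:, 0]
            err = pred - yb
            loss = float(np.mean(err**2))
            epoch_loss += loss * len(idx)
            model.backward((2.0 * err / len(idx))[:, None])
            opt.update(params, model.gradients())
        train_loss = epoch_loss / n * sd**2
        if len(X_val):
            val_loss = _mse(model.forward(X_val)[:, 0], yv) * sd**2
        else:
            val_loss = train_loss
        if not (np.isfinite(train_loss) and np.isfinite(val_loss)):
            raise TrainingFailureError("loss became non-finite")
        history["train_loss"].append(train_loss)
        history["val_loss"].append(val_loss)
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_weights = model.get_weights()
            patience_left = config.early_stop_patience
        else:
            patience_left -= 1
            if patience_left <= 0:
                break
    model.set_weights(best_weights)
    return TrainedModel(
        model=model,
        spec=spec or ModelSpec(),
        config=config,
        history=history,
        label_mean=mu,
        label_sd=sd,
    )


def predict_bp(trained: TrainedModel, data, target: str = "sbp") -> np.ndarray:
    """Predicted pressures in mmHg, one per segment; inference is deterministic."""
    if isinstance(data, np.ndarray):
        X = data
    else:
        X, _ = _as_xy(data, target)
    X = np.asarray(X, dtype=float)
    if X.ndim == 2:
        X = X[:, :, None]
    out = trained.model.forward(X)[:, 0]
    return out * trained.label_sd + trained.label_mean


def save_model(trained: TrainedModel, path) -> None:
    """Weights as .npz plus a JSON sidecar with spec/config/label scaling."""
    path = str(path)
    weights = trained.model.get_weights()
    np.savez(path + ".npz", **{f"w{i}": w for i, w in enumerate(weights)})
    sidecar = {
        "spec": asdict(trained.spec),
        "config": asdict(trained.config),
        "history": trained.history,
        "label_mean": trained.label_mean,
        "label_sd": trained.label_sd,
    }
    with open(path + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=2)


def load_model(path) -> TrainedModel:
    path = str(path)
    with open(path + ".json") as fh:
        sidecar = json.load(fh)
    raw_spec = sidecar["spec"]
    for key in ("lstm_units", "encoder_units", "cnn_filters"):
        raw_spec[key] = tuple(raw_spec[key])
    spec = ModelSpec(**raw_spec)
    config = TrainConfig(**sidecar["config"])
    model = build_model(spec)
    data = np.load(path + ".npz")
    model.set_weights([data[f"w{i}"] for i in range(len(data.files))])
    return TrainedModel(
        model=model,
        spec=spec,
        config=config,
        history=sidecar["history"],
        label_mean=sidecar["label_mean"],
        label_sd=sidecar["label_sd"],
    )
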