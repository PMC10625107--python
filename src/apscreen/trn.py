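"""Transformer regression network (TRN) for aggregation-propensity prediction.

The model maps a tokenized peptide system (residues, the '+' mixture
joiner, and blank placeholder padding) to a scalar AP value:

* encoder — token embedding into ``embed_dim`` dimensions, fixed
  sinusoidal positional encoding, then ``n_blocks`` post-norm transformer
  encoder blocks (multi-head self-attention and a feed-forward sublayer,
  each with a residual connection and layer normalization);
* decoder — the encoder output is compressed to a 1D vector (flattened
  across positions by default, mean-pooled as an alternative) and passed
  through an MLP whose linear layers are followed by batch normalization,
  a leaky-rectifier activation and dropout, ending in a single output.

The reference protocol trains with plain SGD (learning rate 0.2, batch
512, 200 epochs, MSE loss), holds out a quarter of the training data as a
validation set for best-epoch selection, and averages metrics over
replicate seeds.  The ``full`` preset is the published architecture
(512-dim, 6 blocks, 8 heads); the ``scaled`` preset keeps the same
topology at desk-scale dimensions and is the default for testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from . import nn
from .scoring import ScoreSet
from .seqspace import PeptideSystem, VOCAB, tokenize_batch
from .surrogate import LabelledDataset


@dataclass(frozen=True)
class TrnConfig:
    """Architecture hyperparameters of the transformer regression network."""

    embed_dim: int = 512
    n_blocks: int = 6
    n_heads: int = 8
    head_dim: int = 64
    ffn_dim: int = 2048
    mlp_dims: tuple[int, ...] = (512, 256, 64, 32, 1)
    dropout_rate: float = 0.1
    leaky_slope: float = 0.01
    model_length: int = 5
    pooling: str = "flatten"  # or "mean"
    dtype: str = "float32"

    def __post_init__(self) -> None:
        if self.mlp_dims[-1] != 1:
            raise ValueError("mlp_dims must end at 1")
        if self.pooling not in ("flatten", "mean"):
            raise ValueError("pooling must be 'flatten' or 'mean'")
        if self.n_heads < 1 or self.head_dim < 1:
            raise ValueError("invalid attention head configuration")

    @property
    def vocab_size(self) -> int:
        return len(VOCAB)

    @property
    def decoder_input_dim(self) -> int:
        if self.pooling == "flatten":
            return self.model_length * self.embed_dim
        return self.embed_dim

    def with_(self, **kwargs) -> "TrnConfig":
        return replace(self, **kwargs)


FULL_PRESET = TrnConfig()

SCALED_PRESET = TrnConfig(
    embed_dim=64,
    n_blocks=2,
    n_heads=4,
    head_dim=16,
    ffn_dim=256,
    mlp_dims=(64, 32, 16, 8, 1),
)

TINY_PRESET = TrnConfig(
    embed_dim=32,
    n_blocks=1,
    n_heads=2,
    head_dim=16,
    ffn_dim=64,
    mlp_dims=(32, 8, 1),
)

PRESETS = {"full": FULL_PRESET, "scaled": SCALED_PRESET, "tiny": TINY_PRESET}


@dataclass(frozen=True)
class TrainConfig:
    """Optimization protocol (reference defaults: SGD 0.2, 200 epochs)."""

    learning_rate: float = 0.2
    epochs: int = 200
    batch_size: int = 512
    n_seeds: int = 10
    validation_fraction: float = 0.25
    loss: str = "mse"

    def __post_init__(self) -> None:
        if min(self.learning_rate, self.epochs, self.batch_size, self.n_seeds) <= 0:
            raise ValueError("training hyperparameters must be positive")
        if not 0.0 < self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must be in (0, 1)")
        if self.loss != "mse":
            raise ValueError("only the mse loss is supported")


#: Desk-scale protocol used with the scaled preset: identical optimizer and
#: batch size, shorter schedule and 3 replicate seeds.
SCALED_TRAIN = TrainConfig(epochs=60, n_seeds=3)


class TrnModel:
    """A built transformer regression network with its config and seed."""

    def __init__(self, config: TrnConfig, seed: int):
        self.config = config
        self.seed = int(seed)
        dtype = np.dtype(config.dtype)
        init_rng = np.random.default_rng([self.seed, 0x696E6974])
        self.dropout_rng = np.random.default_rng([self.seed, 0x64726F70])
        layers: list[nn.Layer] = [
            nn.Embedding(config.vocab_size, config.embed_dim, init_rng, dtype),
            nn.PositionalEncoding(config.model_length, config.embed_dim, dtype),
        ]
        for _ in range(config.n_blocks):
            layers.append(
                nn.TransformerBlock(
                    config.embed_dim, config.n_heads, config.head_dim,
                    config.ffn_dim, init_rng, dtype,
                )
            )
        layers.append(nn.Flatten() if config.pooling == "flatten" else nn.MeanPool())
        d_in = config.decoder_input_dim
        for i, d_out in enumerate(config.mlp_dims):
            layers.append(nn.Dense(d_in, d_out, init_rng, dtype))
            if i < len(config.mlp_dims) - 1:
                layers.append(nn.BatchNorm1d(d_out, dtype))
                layers.append(nn.LeakyReLU(config.leaky_slope))
                layers.append(nn.Dropout(config.dropout_rate, self.dropout_rng))
            d_in = d_out
        self.net = nn.Sequential(layers)

    # -- state -----------------------------------------------------------
    def params(self) -> list[nn.Param]:
        return self.net.params()

    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.params()))

    def state(self) -> list[np.ndarray]:
        return self.net.state_arrays()

    # -- compute ---------------------------------------------------------
    def forward(self, tokens: np.ndarray, train: bool) -> np.ndarray:
        return self.net.forward(tokens, train)[:, 0]

    def backward(self, dout: np.ndarray) -> None:
        self.net.backward(dout[:, None])

    def predict_tokens(self, tokens: np.ndarray, batch_size: int = 2048) -> np.ndarray:
        out = np.empty(len(tokens), dtype=float)
        for lo in range(0, len(tokens), batch_size):
            out[lo : lo + batch_size] = self.forward(
                tokens[lo : lo + batch_size], train=False
            )
        return out


def build_model(config: TrnConfig, seed: int) -> TrnModel:
    """Build a TRN with seeded parameter initialization."""
    return TrnModel(config, seed)


@dataclass
class TrainResult:
    """Per-seed and averaged outcomes of a training run."""

    per_seed: list[dict]
    averaged: dict
    models: list[TrnModel] = field(repr=False, default_factory=list)
    history: list[list[float]] = field(repr=False, default_factory=list)

    @property
    def model(self) -> TrnModel:
        """Model of the first replicate (convenience accessor)."""
        return self.models[0]


def _train_single(
    config: TrnConfig,
    tokens: np.ndarray,
    labels: np.ndarray,
    tcfg: TrainConfig,
    seed: int,
) -> tuple[TrnModel, dict, list[float]]:
    model = build_model(config, seed)
    dtype = np.dtype(config.dtype)
    rng = np.random.default_rng([int(seed), 0x7472])
    n = len(tokens)
    order = rng.permutation(n)
    n_val = max(1, int(round(n * tcfg.validation_fraction)))
    val_idx, trn_idx = order[:n_val], order[n_val:]
    if len(trn_idx) == 0:
        raise ValueError("training split is empty")
    x_trn, y_trn = tokens[trn_idx], labels[trn_idx].astype(dtype)
    x_val, y_val = tokens[val_idx], labels[val_idx]

    params = model.params()
    state = model.state()
    best = (np.inf, -1, None)
    history: list[float] = []
    for epoch in range(tcfg.epochs):
        perm = rng.permutation(len(x_trn))
        for lo in range(0, len(perm), tcfg.batch_size):
            idx = perm[lo : lo + tcfg.batch_size]
            xb, yb = x_trn[idx], y_trn[idx]
            pred = model.forward(xb, train=True)
            dout = (2.0 / len(idx)) * (pred - yb).astype(dtype)
            model.backward(dout)
            nn.sgd_step(params, tcfg.learning_rate)
        val_pred = model.predict_tokens(x_val)
        val_mae = float(np.abs(val_pred - y_val).mean())
        history.append(val_mae)
        if val_mae < best[0]:
            best = (val_mae, epoch, nn.snapshot(state))
    nn.restore(state, best[2])
    val_pred = model.predict_tokens(x_val)
    metrics = {
        "seed": int(seed),
        "best_epoch": int(best[1]),
        "val_mae": float(np.abs(val_pred - y_val).mean()),
        "val_r2": _r2(val_pred, y_val),
    }
    return model, metrics, history


def _r2(pred: np.ndarray, truth: np.ndarray) -> float:
    ss_res = float(((truth - pred) ** 2).sum())
    ss_tot = float(((truth - truth.mean()) ** 2).sum())
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")


def train(
    config_or_model: TrnConfig | TrnModel,
    data: LabelledDataset,
    tcfg: TrainConfig = SCALED_TRAIN,
    seed: int = 0,
    test_data: LabelledDataset | None = None,
) -> TrainResult:
    """Train the TRN on a labelled dataset with best-epoch selection.

    A quarter of the data (``validation_fraction``) is split off by a
    seeded shuffle; after every epoch the validation MAE is recorded and
    the parameters achieving the minimum are kept.  With ``n_seeds > 1``
    the run is replicated with derived seeds (seed, seed+1, ...) and the
    reported metrics are means over replicates.  ``test_data``, when
    given, is scored by every replicate's best model.
    """
    if len(data) == 0:
        raise ValueError("empty dataset")
    config = (
        config_or_model.config
        if isinstance(config_or_model, TrnModel)
        else config_or_model
    )
    tokens = tokenize_batch(data.systems, config.model_length)
    labels = data.labels
    test_tokens = test_labels = None
    if test_data is not None:
        test_tokens = tokenize_batch(test_data.systems, config.model_length)
        test_labels = test_data.labels

    per_seed, models, histories = [], [], []
    for i in range(tcfg.n_seeds):
        model, metrics, history = _train_single(
            config, tokens, labels, tcfg, seed + i
        )
        if test_tokens is not None:
            test_pred = model.predict_tokens(test_tokens)
            metrics["test_mae"] = float(np.abs(test_pred - test_labels).mean())
            metrics["test_r2"] = _r2(test_pred, test_labels)
        per_seed.append(metrics)
        models.append(model)
        histories.append(history)
    keys = [k for k in per_seed[0] if k not in ("seed", "best_epoch")]
    averaged = {k: float(np.mean([m[k] for m in per_seed])) for k in keys}
    return TrainResult(
        per_seed=per_seed, averaged=averaged, models=models, history=histories
    )


def predict(
    model: TrnModel,
    systems: Sequence[PeptideSystem | str],
    batch_size: int = 2048,
) -> ScoreSet:
    """Batched deterministic inference (dropout off, batch-norm in
    evaluation-statistics mode); returns a ScoreSet keyed by system string."""
    systems = [
        s if isinstance(s, PeptideSystem) else PeptideSystem.parse(s)
        for s in systems
    ]
    tokens = tokenize_batch(systems, model.config.model_length)
    preds = model.predict_tokens(tokens, batch_size=batch_size)
    return ScoreSet(
        values={str(s): float(p) for s, p in zip(systems, preds)},
        meta={"model_seed": model.seed, "preset_dims": model.config.embed_dim},
    )


def save_model(model: TrnModel, path) -> None:
    """Checkpoint a model (architecture config, seed, and all state)."""
    import json

    arrays = {f"arr{i}": a for i, a in enumerate(model.state())}
    cfg = {
        **{k: (list(v) if isinstance(v, tuple) else v)
           for k, v in model.config.__dict__.items()},
        "__seed__": model.seed,
    }
    np.savez(path, __config__=json.dumps(cfg), **arrays)


def load_model(path) -> TrnModel:
    import json

    with np.load(path, allow_pickle=False) as data:
        cfg = json.loads(str(data["__config__"]))
        seed = cfg.pop("__seed__")
        cfg["mlp_dims"] = tuple(cfg["mlp_dims"])
        model = build_model(TrnConfig(**cfg), seed)
        nn.restore(model.state(), [data[f"arr{i}"] for i in range(len(model.state()))])
    return model


@dataclass
class EvalMetrics:
    """MAE, R^2 and the binned error-ratio profile of predictions."""

    mae: float
    r2: float
    error_ratio_profile: list[dict]

    def as_dict(self) -> dict:
        return {"mae": self.mae, "r2": self.r2}


def evaluate(
    pred: ScoreSet, truth: ScoreSet, bins: Sequence[float] | None = None
) -> EvalMetrics:
    """Evaluate predictions against reference scores over their common keys.

    ``mae`` is mean |pred - truth|; ``r2 = 1 - SS_res/SS_tot``; the error
    ratio |pred - truth| / truth * 100% is averaged within bins of the
    reference value (default: 0.1-wide bins spanning the truth range).
    """
    p, t = pred.aligned(truth)
    mae = float(np.abs(p - t).mean())
    r2 = _r2(p, t)
    if bins is None:
        lo = np.floor(t.min() * 10) / 10
        hi = np.ceil(t.max() * 10) / 10
        bins = np.arange(lo, hi + 0.1, 0.1)
    bins = np.asarray(bins, dtype=float)
    ratio = np.abs(p - t) / t * 100.0
    profile = []
    for blo, bhi in zip(bins[:-1], bins[1:]):
        mask = (t >= blo) & (t < bhi)
        if mask.any():
            profile.append(
                {
                    "bin_low": float(blo),
                    "bin_high": float(bhi),
                    "n": int(mask.sum()),
                    "mean_error_ratio_pct": float(ratio[mask].mean()),
                }
            )
    return EvalMetrics(mae=mae, r2=r2, error_ratio_profile=profile)
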