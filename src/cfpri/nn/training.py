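"""Training loop, Adam optimiser, trained-model wrapper and inference.

The loss is mean absolute error between predicted and target probability
vectors. Training is mini-batch gradient descent with Adam; a held-out
validation split is scored (in inference mode) after every epoch. All
randomness — weight initialisation, validation split, shuffling, dropout —
derives from one seed, so single-threaded runs are bit-reproducible.
"""

from __future__ import annotations

import json
import logging
import platform
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from ..dataset import SyntheticDataset, SAMPLE_MAJOR
from ..io import ValidationError
from .layers import Parameter
from .models import Network, NetConfig, build_model

logger = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    """Optimisation hyperparameters (Adam on mean absolute error)."""

    learning_rate: float = 0.0005
    batch_size: int = 16
    epochs: int = 500
    validation_split: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.validation_split < 1.0):
            raise ValidationError("validation_split must be in (0, 1)")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValidationError("epochs and batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValidationError("learning_rate must be > 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        return cls(**d)


class Adam:
    def __init__(
        self,
        params: list[Parameter],
        lr: float,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad**2
            p.value -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


def mae_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean absolute error and its gradient w.r.t. the prediction."""
    diff = pred - target
    loss = float(np.abs(diff).mean())
    grad = np.sign(diff) / diff.size
    return loss, grad


@dataclass
class TrainedModel:
    """A fitted network plus its configuration and loss history."""

    network: Network
    net_config: NetConfig
    train_config: TrainConfig
    history: dict[str, list[float]]
    N: int

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Deterministic inference: dropout off, batch norm in running mode."""
        self.network.set_training(False)
        out = self.network.forward(x)
        return np.clip(out, 0.0, 1.0)

    def predict_pri(self, x: np.ndarray) -> np.ndarray:
        """Row-wise PRI: mean of the predicted probability vector."""
        return self.predict(x).mean(axis=1)

    # -- persistence ----------------------------------------------------
    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        with open(directory / "config.json", "w") as fh:
            json.dump(
                {
                    "net_config": self.net_config.to_dict(),
                    "train_config": self.train_config.to_dict(),
                    "N": self.N,
                },
                fh,
                indent=2,
            )
            fh.write("\n")
        with open(directory / "history.json", "w") as fh:
            json.dump(self.history, fh)
            fh.write("\n")
        arrays = {
            f"param_{i}": p.value for i, p in enumerate(self.network.parameters())
        }
        from .layers import BatchNorm

        for i, m in enumerate(self.network.modules()):
            if isinstance(m, BatchNorm):
                arrays[f"bn_{i}_mean"] = m.running_mean
                arrays[f"bn_{i}_var"] = m.running_var
        np.savez(directory / "parameters.npz", **arrays)

    @classmethod
    def load(cls, directory: str | Path) -> "TrainedModel":
        directory = Path(directory)
        with open(directory / "config.json") as fh:
            cfgs = json.load(fh)
        net_cfg = NetConfig.from_dict(cfgs["net_config"])
        train_cfg = TrainConfig.from_dict(cfgs["train_config"])
        network = build_model(net_cfg, cfgs["N"], seed=train_cfg.seed)
        data = np.load(directory / "parameters.npz")
        for i, p in enumerate(network.parameters()):
            p.value[...] = data[f"param_{i}"]
        from .layers import BatchNorm

        for i, m in enumerate(network.modules()):
            if isinstance(m, BatchNorm):
                m.running_mean = data[f"bn_{i}_mean"]
                m.running_var = data[f"bn_{i}_var"]
        with open(directory / "history.json") as fh:
            history = json.load(fh)
        return cls(
            network=network,
            net_config=net_cfg,
            train_config=train_cfg,
            history=history,
            N=cfgs["N"],
        )


def train(
    model: Network,
    dataset: SyntheticDataset,
    tcfg: TrainConfig | None = None,
) -> TrainedModel:
    """Fit a network on the generated training matrices.

    A ``validation_split`` fraction of training rows is held out and scored
    in inference mode after each epoch; history carries per-epoch training
    and validation loss. Raises on non-finite loss with a learning-rate
    hint.
    """
    tcfg = tcfg or TrainConfig()
    ds = dataset.as_layout(SAMPLE_MAJOR)
    x, y = ds.x_train, ds.y_train
    if x.shape[1] != model.N:
        raise ValidationError(
            f"dataset has {x.shape[1]} indicators, model expects {model.N}"
        )
    ss = np.random.SeedSequence(tcfg.seed)
    split_ss, shuffle_ss, dropout_ss = ss.spawn(3)
    model.reseed_dropout(dropout_ss)

    n = x.shape[0]
    n_val = max(1, int(round(tcfg.validation_split * n)))
    if n_val >= n:
        raise ValidationError("validation split leaves no training rows")
    perm = np.random.default_rng(split_ss).permutation(n)
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    x_tr, y_tr = x[train_idx], y[train_idx]
    x_val, y_val = x[val_idx], y[val_idx]

    opt = Adam(model.parameters(), lr=tcfg.learning_rate)
    shuffle_rng = np.random.default_rng(shuffle_ss)
    history: dict[str, list[float]] = {"train_loss": [], "val_loss": []}

    for epoch in range(tcfg.epochs):
        model.set_training(True)
        order = shuffle_rng.permutation(len(x_tr))
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, len(order), tcfg.batch_size):
            idx = order[start : start + tcfg.batch_size]
            pred = model.forward(x_tr[idx])
            loss, grad = mae_loss(pred, y_tr[idx])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}; try lowering the "
                    f"learning rate (currently {tcfg.learning_rate})"
                )
            opt.zero_grad()
            model.backward(grad)
            opt.step()
            epoch_loss += loss
            n_batches += 1
        model.set_training(False)
        val_pred = model.forward(x_val)
        val_loss = float(np.abs(val_pred - y_val).mean())
        history["train_loss"].append(epoch_loss / max(1, n_batches))
        history["val_loss"].append(val_loss)
        if (epoch + 1) % 10 == 0 or epoch == 0:
            logger.info(
                "epoch %d/%d train MAE %.4f val MAE %.4f",
                epoch + 1, tcfg.epochs,
                history["train_loss"][-1], val_loss,
            )
    return TrainedModel(
        network=model,
        net_config=model.config,
        train_config=tcfg,
        history=history,
        N=model.N,
    )


def benchmark_inference(
    model: TrainedModel, x: np.ndarray, repeats: int = 5
) -> dict:
    """Wall-clock inference time per sample; reported, never asserted."""
    if repeats < 1:
        raise ValidationError("repeats must be >= 1")
    x = np.asarray(x, dtype=float)
    model.predict(x[:1])  # warm-up
    times = []
    for _ in range(repeats):
        t0 = time.perf_counter()
        model.predict(x)
        times.append((time.perf_counter() - t0) / x.shape[0])
    return {
        "per_sample_seconds": float(np.mean(times)),
        "per_sample_seconds_std": float(np.std(times)),
        "repeats": repeats,
        "batch_rows": int(x.shape[0]),
        "hardware": f"{platform.machine()} / {platform.processor() or 'unknown cpu'}",
    }
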