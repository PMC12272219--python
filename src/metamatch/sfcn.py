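"""The multi-output 3D convolutional base model (SFCN-style) and its pretraining.

The base model jointly regresses all meta-training phenotypes from a
mean-normalized T1-like volume plus a z-scored intracranial-volume (ICV)
channel concatenated after global average pooling. Training minimizes mean
squared error over the *observed* phenotype entries only, with early stopping
on a held-out validation split; the parameters of the epoch with the lowest
validation loss are retained.

``SFCNRegressor`` follows the scikit-learn estimator protocol (``fit`` /
``predict`` / ``get_params``); the network itself is a compact NumPy
implementation (see ``metamatch.nn``).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .nn import SFCNNet, SGD
from .nn.network import pooled_extent
from .tables import NormStats, apply_norm_stats, fit_norm_stats

__all__ = [
    "SFCNConfig",
    "TrainConfig",
    "SFCNRegressor",
    "build_model",
    "masked_mse",
    "train_network",
    "save_model",
    "load_model",
]

_FORMAT_VERSION = 1


@dataclass(frozen=True)
class SFCNConfig:
    """Architecture of the base model.

    Defaults are a desk-scale layout (32×40×32 input, 4 blocks). The
    ``full_scale`` constructor gives the 160×192×160 / 6-block layout used for
    biobank-sized T1 images.
    """

    input_shape: tuple[int, int, int] = (32, 40, 32)
    channels: tuple[int, ...] = (8, 16, 32, 16)
    kernel_sizes: tuple[int, ...] = (3, 3, 3, 1)
    dropout_rate: float = 0.2
    n_outputs: int = 1
    use_icv: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "input_shape", tuple(int(s) for s in self.input_shape))
        object.__setattr__(self, "channels", tuple(int(c) for c in self.channels))
        object.__setattr__(self, "kernel_sizes", tuple(int(k) for k in self.kernel_sizes))
        if len(self.channels) < 2:
            raise ValueError("need at least 2 blocks")
        if len(self.channels) != len(self.kernel_sizes):
            raise ValueError("channels and kernel_sizes must have equal length")
        if self.n_outputs < 1:
            raise ValueError("n_outputs must be >= 1")
        if min(pooled_extent(self.input_shape, len(self.channels) - 1)) < 1:
            raise ValueError("spatial extent collapses below 1 voxel before the last block")

    @property
    def n_blocks(self) -> int:
        return len(self.channels)

    @classmethod
    def full_scale(cls, n_outputs: int, use_icv: bool = True) -> "SFCNConfig":
        return cls(input_shape=(160, 192, 160), channels=(32, 64, 128, 256, 256, 64),
                   kernel_sizes=(3, 3, 3, 3, 3, 1), dropout_rate=0.2,
                   n_outputs=n_outputs, use_icv=use_icv)


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings (SGD with momentum, step LR decay, early stopping)."""

    lr: float = 1e-2
    momentum: float = 0.9
    weight_decay: float = 1e-3
    batch_size: int = 16
    max_epochs: int = 50
    patience: int = 5
    lr_decay: float = 0.5
    lr_step: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


def build_model(config: SFCNConfig, seed: int = 0, dtype=np.float32) -> SFCNNet:
    """Instantiate the network with seeded He-normal initialization."""
    rng = np.random.default_rng(seed)
    return SFCNNet(config.input_shape, config.channels, config.kernel_sizes,
                   config.dropout_rate, config.n_outputs, config.use_icv, rng,
                   dtype=dtype)


def masked_mse(preds: np.ndarray, targets: np.ndarray, mask: np.ndarray) -> float:
    """MSE over observed entries; entries with mask False contribute nothing."""
    mask = np.asarray(mask, dtype=bool)
    n_obs = int(mask.sum())
    if n_obs == 0:
        return 0.0
    diff = np.where(mask, preds - np.where(mask, targets, 0.0), 0.0)
    return float(np.sum(diff ** 2) / n_obs)


def _masked_mse_grad(preds, targets, mask):
    n_obs = max(int(mask.sum()), 1)
    diff = np.where(mask, preds - np.where(mask, targets, 0.0), 0.0)
    return (2.0 * diff / n_obs).astype(preds.dtype)


def train_network(net: SFCNNet, X: np.ndarray, icv: np.ndarray | None,
                  Y: np.ndarray, mask: np.ndarray,
                  train_idx: np.ndarray, val_idx: np.ndarray,
                  tc: TrainConfig, start_block: int = 0) -> list[dict]:
    """Mini-batch SGD on the masked-MSE loss with early stopping.

    ``start_block > 0`` trains only blocks ≥ start_block plus the head, on
    pre-computed frozen-trunk feature tensors ``X`` (the finetuning path).
    Restores the parameters of the best validation epoch; returns the
    per-epoch training log.
    """
    if len(train_idx) == 0:
        raise ValueError("empty training set")
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("no observed target entries")
    rng = np.random.default_rng(tc.seed)
    opt = SGD(net.trainable_layers(from_block=start_block), lr=tc.lr,
              momentum=tc.momentum, weight_decay=tc.weight_decay,
              lr_decay=tc.lr_decay, lr_step=tc.lr_step)

    def _val_loss() -> float:
        if len(val_idx) == 0:
            return np.nan
        icv_v = None if icv is None else icv[val_idx]
        preds = net.predict(X[val_idx], icv_v, batch_size=tc.batch_size,
                            start_block=start_block)
        return masked_mse(preds, Y[val_idx], mask[val_idx])

    best_loss = np.inf
    best_state = net.state_dict()
    best_epoch = -1
    log: list[dict] = []
    stale = 0
    for epoch in range(tc.max_epochs):
        opt.set_epoch(epoch)
        order = rng.permutation(len(train_idx))
        epoch_loss = 0.0
        n_batches = 0
        for b0 in range(0, len(order), tc.batch_size):
            idx = train_idx[order[b0:b0 + tc.batch_size]]
            icv_b = None if icv is None else icv[idx]
            preds = net.forward(X[idx], icv_b, training=True, rng=rng,
                                start_block=start_block)
            m = mask[idx]
            epoch_loss += masked_mse(preds, Y[idx], m)
            n_batches += 1
            net.backward(_masked_mse_grad(preds, Y[idx], m))
            opt.step()
        val_loss = _val_loss()
        log.append({"epoch": epoch, "train_loss": epoch_loss / max(n_batches, 1),
                    "val_loss": val_loss, "lr": opt.lr})
        monitor = val_loss if np.isfinite(val_loss) else epoch_loss
        if monitor < best_loss - 1e-12:
            best_loss = monitor
            best_state = net.state_dict()
            best_epoch = epoch
            stale = 0
        else:
            stale += 1
            if stale >= tc.patience:
                break
    net.load_state_dict(best_state)
    log.append({"best_epoch": best_epoch, "best_val_loss": float(best_loss)})
    return log


class SFCNRegressor(BaseEstimator, RegressorMixin):
    """Multi-output 3D CNN phenotype regressor.

    Parameters
    ----------
    config : SFCNConfig or None
        Architecture; ``n_outputs`` is overridden by the number of target
        columns at fit time. None selects the desk-scale default.
    train_config : TrainConfig or None
        Optimization settings.
    val_fraction : float
        Fraction of fit participants held out (80/20 by default) for early
        stopping and hyperparameter monitoring.
    normalize_targets : bool
        Z-score targets internally using all fit participants (the stats are
        stored in ``target_norm_``; predictions live in z-space).

    Attributes
    ----------
    net_ : SFCNNet — the trained network.
    icv_norm_ : NormStats — ICV z-scoring stats from the training split.
    target_norm_ : NormStats or None — target z-scoring stats.
    training_log_ : list of per-epoch loss records.
    """

    def __init__(self, config: SFCNConfig | None = None,
                 train_config: TrainConfig | None = None,
                 val_fraction: float = 0.2,
                 normalize_targets: bool = True) -> None:
        self.config = config
        self.train_config = train_config
        self.val_fraction = val_fraction
        self.normalize_targets = normalize_targets

    def fit(self, X: np.ndarray, y: np.ndarray, icv: np.ndarray | None = None,
            observed: np.ndarray | None = None) -> "SFCNRegressor":
        X = np.asarray(X, dtype=float)
        y = np.atleast_2d(np.asarray(y, dtype=float))
        if y.shape[0] == 1 and X.shape[0] != 1:
            y = y.T
        n = X.shape[0]
        if y.shape[0] != n:
            raise ValueError("X and y disagree on the number of participants")
        if n == 0:
            raise ValueError("empty training set")
        cfg = self.config if self.config is not None else SFCNConfig()
        cfg = SFCNConfig(cfg.input_shape, cfg.channels, cfg.kernel_sizes,
                         cfg.dropout_rate, y.shape[1], cfg.use_icv)
        tc = self.train_config if self.train_config is not None else TrainConfig()
        if observed is None:
            observed = np.isfinite(y)
        observed = np.asarray(observed, dtype=bool)

        if self.normalize_targets:
            self.target_norm_ = fit_norm_stats(np.where(observed, y, np.nan))
            yz = np.where(observed, apply_norm_stats(
                np.where(observed, y, np.nan), self.target_norm_), 0.0)
        else:
            self.target_norm_ = None
            yz = np.where(observed, y, 0.0)

        rng = np.random.default_rng(tc.seed)
        perm = rng.permutation(n)
        n_val = int(round(self.val_fraction * n))
        val_idx, train_idx = perm[:n_val], perm[n_val:]

        if cfg.use_icv:
            if icv is None:
                raise ValueError("config.use_icv=True requires an icv array")
            icv = np.asarray(icv, dtype=float).reshape(-1)
            self.icv_norm_ = fit_norm_stats(icv[train_idx][:, None], names=["ICV"])
            icv_z = apply_norm_stats(icv[:, None], self.icv_norm_).ravel()
        else:
            self.icv_norm_ = None
            icv_z = None

        self.config_ = cfg
        self.net_ = build_model(cfg, seed=tc.seed)
        self.training_log_ = train_network(self.net_, X, icv_z, yz, observed,
                                           train_idx, val_idx, tc)
        return self

    def _icv_z(self, icv):
        if self.icv_norm_ is None:
            return None
        if icv is None:
            raise ValueError("model uses ICV; pass an icv array")
        icv = np.asarray(icv, dtype=float).reshape(-1)
        return apply_norm_stats(icv[:, None], self.icv_norm_).ravel()

    def predict(self, X: np.ndarray, icv: np.ndarray | None = None) -> np.ndarray:
        """Eval-mode predictions, (n, P), in the (z-scored) target space."""
        if not hasattr(self, "net_"):
            raise RuntimeError("fit the model first")
        return self.net_.predict(np.asarray(X, dtype=float), self._icv_z(icv))

    def trunk_features(self, X: np.ndarray, batch_size: int = 16) -> np.ndarray:
        """Frozen-trunk activations entering the last block (for finetuning)."""
        return self.net_.features(np.asarray(X, dtype=float),
                                  upto_block=self.config_.n_blocks - 1,
                                  batch_size=batch_size)


def save_model(model: SFCNRegressor, path: str | Path) -> None:
    """Versioned archive: JSON config + parameter arrays."""
    meta = {
        "format_version": _FORMAT_VERSION,
        "config": asdict(model.config_),
        "target_norm": None if model.target_norm_ is None else {
            "names": model.target_norm_.names,
            "mean": model.target_norm_.mean.tolist(),
            "std": model.target_norm_.std.tolist(),
            "n_source": model.target_norm_.n_source,
        },
        "icv_norm": None if model.icv_norm_ is None else {
            "mean": model.icv_norm_.mean.tolist(),
            "std": model.icv_norm_.std.tolist(),
            "n_source": model.icv_norm_.n_source,
        },
    }
    state = model.net_.state_dict()
    np.savez(Path(path), __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **state)


def load_model(path: str | Path) -> SFCNRegressor:
    path = Path(path)
    try:
        with np.load(path) as archive:
            meta = json.loads(bytes(archive["__meta__"].tobytes()).decode())
            state = {k: archive[k] for k in archive.files if k != "__meta__"}
    except (OSError, ValueError, KeyError) as e:
        raise ValueError(f"unreadable model archive {path}: {e}") from None
    if meta.get("format_version") != _FORMAT_VERSION:
        raise ValueError(
            f"model format version {meta.get('format_version')} not supported "
            f"(expected {_FORMAT_VERSION})")
    cfg_d = meta["config"]
    cfg = SFCNConfig(tuple(cfg_d["input_shape"]), tuple(cfg_d["channels"]),
                     tuple(cfg_d["kernel_sizes"]), cfg_d["dropout_rate"],
                     cfg_d["n_outputs"], cfg_d["use_icv"])
    model = SFCNRegressor(config=cfg)
    model.config_ = cfg
    model.net_ = build_model(cfg, seed=0)
    model.net_.load_state_dict(state)
    tn = meta["target_norm"]
    model.target_norm_ = None if tn is None else NormStats(
        tn["names"], np.array(tn["mean"]), np.array(tn["std"]), tn["n_source"])
    inorm = meta["icv_norm"]
    model.icv_norm_ = None if inorm is None else NormStats(
        ["ICV"], np.array(inorm["mean"]), np.array(inorm["std"]), inorm["n_source"])
    model.training_log_ = []
    return model
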