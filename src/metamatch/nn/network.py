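"""The SFCN-style multi-output 3D convolutional network.

VGG-like feature-extraction blocks — conv → batch norm → max pool → ReLU —
with the last block unpooled, followed by global average pooling, optional
concatenation of a z-scored intracranial-volume channel, dropout, and a dense
output map (the 1×1×1 convolution head) emitting one value per phenotype.
"""

from __future__ import annotations

import numpy as np

from .layers import BatchNorm, Conv3d, Dropout, GlobalAvgPool, Linear, MaxPool3d, ReLU


def pooled_extent(input_shape: tuple[int, int, int], n_halvings: int) -> tuple[int, int, int]:
    """Spatial extent after ``n_halvings`` rounds of floor-halving max pooling."""
    shape = tuple(int(s) for s in input_shape)
    for _ in range(n_halvings):
        shape = tuple(s // 2 for s in shape)
    return shape  # type: ignore[return-value]


class SFCNNet:
    """Parameter container + forward/backward for the base model.

    ``n_blocks`` blocks; blocks ``0..n_blocks−2`` pool, the last does not.
    ``forward`` can start from an intermediate block (``start_block``) so that
    finetuning of the last two layers can run on cached frozen features.
    """

    def __init__(self, input_shape: tuple[int, int, int], channels: tuple[int, ...],
                 kernel_sizes: tuple[int, ...], dropout_rate: float, n_outputs: int,
                 use_icv: bool, rng: np.random.Generator, dtype=np.float32) -> None:
        if len(channels) != len(kernel_sizes):
            raise ValueError("channels and kernel_sizes must have equal length")
        n_blocks = len(channels)
        if n_blocks < 2:
            raise ValueError("need at least 2 blocks")
        if n_outputs < 1:
            raise ValueError("need at least 1 output")
        if min(pooled_extent(input_shape, n_blocks - 1)) < 1:
            raise ValueError(
                f"input shape {input_shape} collapses below 1 voxel after "
                f"{n_blocks - 1} poolings")
        self.input_shape = tuple(int(s) for s in input_shape)
        self.channels = tuple(channels)
        self.kernel_sizes = tuple(kernel_sizes)
        self.dropout_rate = float(dropout_rate)
        self.n_outputs = int(n_outputs)
        self.use_icv = bool(use_icv)
        self.dtype = np.dtype(dtype)

        self.blocks: list[list] = []
        cin = 1
        for i, (cout, k) in enumerate(zip(channels, kernel_sizes)):
            block = [Conv3d(cin, cout, k, rng, dtype=self.dtype, input_grad=i > 0),
                     BatchNorm(cout, dtype=self.dtype)]
            if i < n_blocks - 1:
                block.append(MaxPool3d())
            block.append(ReLU())
            self.blocks.append(block)
            cin = cout
        self.gap = GlobalAvgPool()
        self.dropout = Dropout(dropout_rate)
        self.head = Linear(cin + (1 if use_icv else 0), n_outputs, rng,
                           dtype=self.dtype)

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    # ---- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray, icv: np.ndarray | None = None, *,
                training: bool = False, rng: np.random.Generator | None = None,
                start_block: int = 0) -> np.ndarray:
        """Batch of volumes (n, X, Y, Z[, C]) (+ z-scored ICV) → (n, P) predictions."""
        x = np.asarray(x, dtype=self.dtype)
        if x.ndim == 4:
            x = x[..., None]
        if x.ndim != 5:
            raise ValueError(f"expected (n, X, Y, Z) volumes, got shape {x.shape}")
        if not np.all(np.isfinite(x)):
            raise ValueError("non-finite voxel in input batch")
        if start_block == 0 and x.shape[1:4] != self.input_shape:
            raise ValueError(f"expected spatial shape {self.input_shape}, got {x.shape[1:4]}")
        if self.use_icv:
            if icv is None:
                raise ValueError("model was built with use_icv=True; pass icv")
            icv = np.asarray(icv, dtype=self.dtype).reshape(-1)
            if icv.size != x.shape[0]:
                raise ValueError("icv length does not match batch size")
        self._start_block = start_block
        h = x
        for block in self.blocks[start_block:]:
            for layer in block:
                h = layer.forward(h, training=training, rng=rng)
        h = self.gap.forward(h, training=training)
        if self.use_icv:
            h = np.concatenate([h, icv[:, None]], axis=1)
        h = self.dropout.forward(h, training=training, rng=rng)
        return self.head.forward(h, training=training)

    def backward(self, grad_preds: np.ndarray, *, down_to_block: int | None = None) -> None:
        """Accumulate parameter gradients for the last forward batch.

        ``down_to_block`` stops backpropagation before earlier (frozen)
        blocks; defaults to the forward call's ``start_block``.
        """
        if down_to_block is None:
            down_to_block = self._start_block
        g = self.head.backward(grad_preds)
        g = self.dropout.backward(g)
        if self.use_icv:
            g = g[:, :-1]
        g = self.gap.backward(g)
        for block in reversed(self.blocks[down_to_block:]):
            for layer in reversed(block):
                g = layer.backward(g)

    def features(self, x: np.ndarray, upto_block: int,
                 batch_size: int = 16) -> np.ndarray:
        """Eval-mode activations entering ``upto_block`` (frozen-trunk cache)."""
        x = np.asarray(x, dtype=self.dtype)
        if x.ndim == 4:
            x = x[..., None]
        outs = []
        for i in range(0, x.shape[0], batch_size):
            h = x[i:i + batch_size]
            if not np.all(np.isfinite(h)):
                raise ValueError("non-finite voxel in input batch")
            for block in self.blocks[:upto_block]:
                for layer in block:
                    h = layer.forward(h, training=False)
            outs.append(h)
        return np.concatenate(outs, axis=0)

    def predict(self, x: np.ndarray, icv: np.ndarray | None = None,
                batch_size: int = 16, start_block: int = 0) -> np.ndarray:
        """Deterministic eval-mode forward in mini-batches."""
        x = np.asarray(x, dtype=self.dtype)
        preds = []
        for i in range(0, x.shape[0], batch_size):
            icv_b = None if icv is None else np.asarray(icv).reshape(-1)[i:i + batch_size]
            preds.append(self.forward(x[i:i + batch_size], icv_b, training=False,
                                      start_block=start_block))
        return np.concatenate(preds, axis=0)

    # ---- parameter access ---------------------------------------------------

    def _layers(self) -> list:
        layers = [layer for block in self.blocks for layer in block]
        return layers + [self.gap, self.dropout, self.head]

    def trainable_layers(self, from_block: int = 0) -> list:
        """Layers with parameters in blocks ≥ from_block plus the output head."""
        layers = [layer for block in self.blocks[from_block:] for layer in block
                  if layer.params]
        return layers + [self.head]

    def state_dict(self) -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for i, layer in enumerate(self._layers()):
            for name, value in layer.params.items():
                state[f"layer{i}.{name}"] = value.copy()
            if isinstance(layer, BatchNorm):
                state[f"layer{i}.running_mean"] = layer.running_mean.copy()
                state[f"layer{i}.running_var"] = layer.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self._layers()):
            for name in layer.params:
                key = f"layer{i}.{name}"
                if state[key].shape != layer.params[name].shape:
                    raise ValueError(f"shape mismatch for {key}")
                layer.params[name] = state[key].copy()
            if isinstance(layer, BatchNorm):
                layer.running_mean = state[f"layer{i}.running_mean"].copy()
                layer.running_var = state[f"layer{i}.running_var"].copy()

    def parameter_count(self, from_block: int = 0) -> int:
        return sum(p.size for layer in self.trainable_layers(from_block)
                   for p in layer.params.values())
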