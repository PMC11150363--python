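"""The 3D attention-ResNet age-regression architecture.

The default network alternates three residual blocks and two attention
blocks, R(8) A(16) R(32) A(64) R(128), each halving the spatial grid with a
2x2x2/2 max-pool, so a 64x64x32 input leaves the block stack as a
2x2x1x128 feature map.  The head flattens (512), applies a dense layer of
128 units with l2 regularisation, ELU, dropout 0.2, concatenates the
subject's sex code, and a final linear unit emits the age estimate.  The
post-ELU dense activation (dropout off at inference) is the penultimate
feature vector F_l that the SVR head consumes, fused with sex as F_l (+) G.

Residual block (shortcut by pointwise sum, H(x) = shortcut(x) + F(x)):

    y1 = ELU(BN(conv3x3x3(x)));  y2 = BN(conv3x3x3(y1))
    s  = conv1x1x1(x)            # projection so the sum is well-typed
    out = maxpool(ELU(s + y2))

Attention block (queries and values are independent 3x3x3 convolutions;
the values act as their own keys; a third 3x3x3 convolution projects the
concatenation back to the block's stated width):

    Q = conv(x); V = conv(x); att = Attention(Q, V)
    out = maxpool(ELU(BN(conv(Q (+) att))))
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from ._layers import (
    Adam,
    Attention,
    BatchNorm,
    Conv3D,
    Dense,
    Dropout,
    ELU,
    Layer,
    MaxPool3D,
    Param,
)
from .io_manifest import VolumeImage

DEFAULT_BLOCKS: tuple[tuple[str, int], ...] = (
    ("res", 8), ("att", 16), ("res", 32), ("att", 64), ("res", 128),
)


@dataclass
class NetworkConfig:
    """Block layout and head hyperparameters.

    ``block_sequence`` is an ordered list of ("res"|"att", feature_count);
    feature counts must be strictly increasing.  Spatial input dims must be
    divisible by 2**len(block_sequence) since every block pools by 2.
    """

    block_sequence: tuple[tuple[str, int], ...] = DEFAULT_BLOCKS
    input_shape: tuple[int, int, int] = (64, 64, 32)
    conv_kernel: int = 3
    shortcut_kernel: int = 1
    elu_alpha: float = 1.0
    dense_units: int = 128
    dense_l2: float = 1e-4
    dropout_rate: float = 0.2
    use_scale: bool = False
    attention_chunk: int = 1024

    def __post_init__(self) -> None:
        self.block_sequence = tuple((str(k), int(f)) for k, f in self.block_sequence)
        feats = [f for _, f in self.block_sequence]
        if any(b <= a for a, b in zip(feats, feats[1:])):
            raise ValueError(f"block feature counts must be strictly increasing: {feats}")
        if any(k not in ("res", "att") for k, _ in self.block_sequence):
            raise ValueError("block kinds must be 'res' or 'att'")
        div = 2 ** len(self.block_sequence)
        if any(s % div or s < div for s in self.input_shape):
            raise ValueError(
                f"input shape {self.input_shape} must be divisible by 2^{len(self.block_sequence)}"
            )

    @property
    def final_spatial(self) -> tuple[int, int, int]:
        div = 2 ** len(self.block_sequence)
        return tuple(s // div for s in self.input_shape)

    @property
    def flatten_size(self) -> int:
        d, h, w = self.final_spatial
        return d * h * w * self.block_sequence[-1][1]

    def to_dict(self) -> dict:
        return {
            "block_sequence": [list(b) for b in self.block_sequence],
            "input_shape": list(self.input_shape),
            "conv_kernel": self.conv_kernel,
            "shortcut_kernel": self.shortcut_kernel,
            "elu_alpha": self.elu_alpha,
            "dense_units": self.dense_units,
            "dense_l2": self.dense_l2,
            "dropout_rate": self.dropout_rate,
            "use_scale": self.use_scale,
            "attention_chunk": self.attention_chunk,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        d = dict(d)
        d["block_sequence"] = tuple(tuple(b) for b in d["block_sequence"])
        d["input_shape"] = tuple(d["input_shape"])
        return cls(**d)


def test_scale_config() -> NetworkConfig:
    """A reduced configuration for desk-scale 32x32x16 phantoms."""
    return NetworkConfig(
        block_sequence=(("res", 4), ("att", 8), ("res", 16)),
        input_shape=(32, 32, 16),
        dense_units=64,
    )


class ResBlock(Layer):
    """Residual block per the pointwise-sum formulation H(x) = CNN(x) + F(x)."""

    def __init__(self, cin: int, cf: int, cfg: NetworkConfig, rng: np.random.Generator) -> None:
        self.conv_a = Conv3D(cin, cf, cfg.conv_kernel, rng)
        self.bn1 = BatchNorm(cf)
        self.elu1 = ELU(cfg.elu_alpha)
        self.conv_b = Conv3D(cf, cf, cfg.conv_kernel, rng)
        self.bn2 = BatchNorm(cf)
        self.shortcut = Conv3D(cin, cf, cfg.shortcut_kernel, rng)
        self.elu2 = ELU(cfg.elu_alpha)
        self.pool = MaxPool3D()
        self.prepool: Optional[np.ndarray] = None

    def forward(self, x: np.ndarray, train: bool = False,
                cache: bool | None = None) -> np.ndarray:
        if any(s % 2 for s in x.shape[1:4]):
            raise ValueError(f"res block needs even spatial dims, got {x.shape}")
        y = self.conv_a.forward(x, train, cache)
        y = self.bn1.forward(y, train, cache)
        y = self.elu1.forward(y, train, cache)
        y = self.conv_b.forward(y, train, cache)
        y = self.bn2.forward(y, train, cache)
        s = self.shortcut.forward(x, train, cache)
        h = s + y
        a = self.elu2.forward(h, train, cache)
        self.prepool = a if (cache or cache is None and train) else None
        return self.pool.forward(a, train, cache)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        g = self.pool.backward(gout)
        g = self.elu2.backward(g)
        gx = self.shortcut.backward(g)
        gy = self.bn2.backward(g)
        gy = self.conv_b.backward(gy)
        gy = self.elu1.backward(gy)
        gy = self.bn1.backward(gy)
        gx = gx + self.conv_a.backward(gy)
        return gx

    def backward_to_prepool(self, gout: np.ndarray) -> np.ndarray:
        """Gradient at the pre-pool activation (the Grad-CAM source map)."""
        return self.pool.backward(gout)

    def params(self) -> list[Param]:
        return (self.conv_a.params() + self.bn1.params() + self.conv_b.params()
                + self.bn2.params() + self.shortcut.params())


class AttentionBlock(Layer):
    """Attention block: Q/V convolutions, attention, concat, projection, BN, ELU, pool."""

    def __init__(self, cin: int, cf: int, cfg: NetworkConfig, rng: np.random.Generator) -> None:
        self.q_conv = Conv3D(cin, cf, cfg.conv_kernel, rng)
        self.v_conv = Conv3D(cin, cf, cfg.conv_kernel, rng)
        self.attention = Attention(use_scale=cfg.use_scale, inference_chunk=cfg.attention_chunk)
        self.proj = Conv3D(2 * cf, cf, cfg.conv_kernel, rng)
        self.bn = BatchNorm(cf)
        self.elu = ELU(cfg.elu_alpha)
        self.pool = MaxPool3D()
        self.cf = cf
        self.prepool: Optional[np.ndarray] = None

    def forward(self, x: np.ndarray, train: bool = False,
                cache: bool | None = None) -> np.ndarray:
        if any(s % 2 for s in x.shape[1:4]):
            raise ValueError(f"attention block needs even spatial dims, got {x.shape}")
        q = self.q_conv.forward(x, train, cache)
        v = self.v_conv.forward(x, train, cache)
        att = self.attention.forward(q, v, train, cache)
        con = np.concatenate([q, att], axis=-1)
        p = self.proj.forward(con, train, cache)
        b = self.bn.forward(p, train, cache)
        a = self.elu.forward(b, train, cache)
        self.prepool = a if (cache or cache is None and train) else None
        return self.pool.forward(a, train, cache)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        g = self.pool.backward(gout)
        g = self.elu.backward(g)
        g = self.bn.backward(g)
        gcon = self.proj.backward(g)
        gq = gcon[..., : self.cf]
        gatt = gcon[..., self.cf:]
        gq2, gv = self.attention.backward(gatt)
        return self.q_conv.backward(gq + gq2) + self.v_conv.backward(gv)

    def backward_to_prepool(self, gout: np.ndarray) -> np.ndarray:
        return self.pool.backward(gout)

    def params(self) -> list[Param]:
        return (self.q_conv.params() + self.v_conv.params() + self.proj.params()
                + self.bn.params())


class TrainedModel:
    """The block stack plus fused head, with its parameters and history.

    ``forward_batch`` is the workhorse; :meth:`forward` is the one-volume
    convenience returning the age estimate and the penultimate feature
    vector F_l.  The inference-mode forward pass is a pure function of
    (parameters, input).
    """

    def __init__(self, config: NetworkConfig, seed: int = 0) -> None:
        self.config = config
        self.training_seed = seed
        rng = np.random.default_rng(seed)
        self.blocks: list[Layer] = []
        cin = 1
        for kind, cf in config.block_sequence:
            cls = ResBlock if kind == "res" else AttentionBlock
            self.blocks.append(cls(cin, cf, config, rng))
            cin = cf
        self.dense = Dense(config.flatten_size, config.dense_units, rng, l2=config.dense_l2)
        self.head_elu = ELU(config.elu_alpha)
        self.dropout = Dropout(config.dropout_rate, np.random.default_rng(seed + 1))
        # final linear unit on F_l (+) G: one weight per feature plus the sex code
        self.out = Dense(config.dense_units + 1, 1, rng)
        self.history: dict[str, list[float]] = {"train_loss": [], "val_loss": []}

    # -- forward / backward -------------------------------------------------

    def forward_batch(self, x: np.ndarray, sex: np.ndarray, train: bool = False,
                      cache: bool | None = None) -> tuple[np.ndarray, np.ndarray]:
        """x: (B, D, H, W, 1) float array; sex: (B,) in {0,1}.

        Returns (age estimates (B,), penultimate features F_l (B, dense_units)).
        """
        if x.ndim == 4:
            x = x[..., None]
        if x.shape[1:4] != tuple(self.config.input_shape):
            raise ValueError(
                f"input spatial shape {x.shape[1:4]} != configured {self.config.input_shape}"
            )
        h = x
        for blk in self.blocks:
            h = blk.forward(h, train, cache)
        b = h.shape[0]
        self._flat_shape = h.shape
        flat = h.reshape(b, -1)
        f = self.dense.forward(flat, train, cache)
        f = self.head_elu.forward(f, train, cache)
        f_l = f  # post-ELU, pre-dropout: the inference-mode penultimate features
        f = self.dropout.forward(f, train, cache)
        fused = np.concatenate([f, np.asarray(sex, dtype=f.dtype).reshape(b, 1)], axis=1)
        pred = self.out.forward(fused, train, cache)[:, 0]
        return pred, f_l

    def backward_batch(self, gpred: np.ndarray) -> None:
        """Backprop from d(loss)/d(prediction); accumulates parameter grads."""
        g = np.asarray(gpred, dtype=np.float32).reshape(-1, 1)
        gfused = self.out.backward(g)
        gf = gfused[:, :-1]  # gradient w.r.t. sex input is discarded
        gf = self.dropout.backward(gf)
        gf = self.head_elu.backward(gf)
        gflat = self.dense.backward(gf)
        gh = gflat.reshape(self._flat_shape)
        for blk in reversed(self.blocks):
            gh = blk.backward(gh)

    def forward(self, volume: VolumeImage | np.ndarray, sex: int
                ) -> tuple[float, np.ndarray]:
        """Inference on one preprocessed volume -> (age estimate, F_l)."""
        grid = volume.grid if isinstance(volume, VolumeImage) else np.asarray(volume)
        if grid.shape != tuple(self.config.input_shape):
            raise ValueError(
                f"volume shape {grid.shape} != configured input {self.config.input_shape}"
            )
        x = grid.astype(np.float32)[None, ..., None]
        pred, f_l = self.forward_batch(x, np.array([sex]), train=False, cache=False)
        return float(pred[0]), f_l[0]

    # -- parameters ---------------------------------------------------------

    def params(self) -> list[Param]:
        out: list[Param] = []
        for blk in self.blocks:
            out.extend(blk.params())
        out.extend(self.dense.params())
        out.extend(self.out.params())
        return out

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0

    def l2_loss(self) -> float:
        return self.dense.l2_loss()

    def _bn_layers(self) -> list[BatchNorm]:
        bns: list[BatchNorm] = []
        for blk in self.blocks:
            for attr in ("bn", "bn1", "bn2"):
                if hasattr(blk, attr):
                    bns.append(getattr(blk, attr))
        return bns

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {f"param_{i}": p.value for i, p in enumerate(self.params())}
        for i, bn in enumerate(self._bn_layers()):
            state[f"bn_{i}_mean"] = bn.running_mean
            state[f"bn_{i}_var"] = bn.running_var
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.params()):
            p.value = np.array(state[f"param_{i}"], dtype=p.value.dtype)
            p.grad = np.zeros_like(p.value)
        for i, bn in enumerate(self._bn_layers()):
            bn.running_mean = np.array(state[f"bn_{i}_mean"], dtype=bn.running_mean.dtype)
            bn.running_var = np.array(state[f"bn_{i}_var"], dtype=bn.running_var.dtype)

    # -- serialisation ------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Single checkpoint file (.npz) with the config embedded as JSON."""
        meta = {
            "config": self.config.to_dict(),
            "training_seed": self.training_seed,
            "history": self.history,
        }
        np.savez_compressed(path, __meta__=json.dumps(meta), **self.state_dict())

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["__meta__"]))
            model = cls(NetworkConfig.from_dict(meta["config"]), seed=meta["training_seed"])
            model.history = meta["history"]
            model.load_state_dict({k: data[k] for k in data.files if k != "__meta__"})
        return model


def build_network(config: Optional[NetworkConfig] = None, seed: int = 0) -> TrainedModel:
    """Instantiate the (untrained) network with seeded initial parameters."""
    return TrainedModel(config or NetworkConfig(), seed=seed)


# re-exported building blocks used directly in tests and by the interpret module
def res_block_forward(block: ResBlock, x: np.ndarray, train: bool = False) -> np.ndarray:
    return block.forward(x, train)


def attention_block_forward(block: AttentionBlock, x: np.ndarray, train: bool = False) -> np.ndarray:
    return block.forward(x, train)
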