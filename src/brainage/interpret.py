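"""Volumetric Grad-CAM: which regions drive the age estimate.

The saliency of a block's feature map is the rectified, channel-weighted
sum of its activations, with each channel's weight the spatial mean of the
gradient of the scalar age output with respect to that channel.  The map
is trilinearly upsampled to the network input grid and min-max normalised
to [0, 1], so it is invariant to uniform rescaling of the head weights.
The default source is the final residual block's pre-pool activation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .io_manifest import VolumeImage
from .network import ResBlock, TrainedModel
from .preprocess import resize_volume

logger = logging.getLogger("brainage")


@dataclass
class SaliencyMap:
    """A [0,1]-normalised non-negative saliency grid on the input shape."""

    grid: np.ndarray
    source_block: int

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.min() < 0 or self.grid.max() > 1:
            raise ValueError("saliency values must lie in [0, 1]")


def gradcam(
    model: TrainedModel,
    volume: VolumeImage | np.ndarray,
    sex: int,
    source_block: Optional[int] = None,
) -> SaliencyMap:
    """Grad-CAM saliency of the age estimate for one preprocessed volume.

    ``source_block`` indexes the block whose pre-pool activation is used;
    the default is the last residual block.  A model whose output gradient
    vanishes at the source (e.g. a zeroed head) yields an all-zero map
    with a warning rather than an error.
    """
    n_blocks = len(model.blocks)
    if source_block is None:
        res_idx = [i for i, b in enumerate(model.blocks) if isinstance(b, ResBlock)]
        source_block = res_idx[-1] if res_idx else n_blocks - 1
    if not (0 <= source_block < n_blocks):
        raise IndexError(f"source_block {source_block} out of range [0, {n_blocks})")

    grid = volume.grid if isinstance(volume, VolumeImage) else np.asarray(volume)
    if grid.shape != tuple(model.config.input_shape):
        raise ValueError(
            f"volume shape {grid.shape} != configured input {model.config.input_shape}"
        )
    x = grid.astype(np.float32)[None, ..., None]

    # forward with inference statistics but gradient caches enabled
    model.forward_batch(x, np.array([sex]), train=False, cache=True)
    model.zero_grad()
    g = model.out.backward(np.ones((1, 1), dtype=np.float32))[:, :-1]
    g = model.dropout.backward(g)
    g = model.head_elu.backward(g)
    g = model.dense.backward(g).reshape(model._flat_shape)
    for blk in reversed(model.blocks[source_block + 1:]):
        g = blk.backward(g)
    src = model.blocks[source_block]
    gpre = src.backward_to_prepool(g)
    fmap = src.prepool
    model.zero_grad()

    weights = gpre.mean(axis=(1, 2, 3))                      # (1, C) channel weights
    cam = np.maximum((fmap * weights[:, None, None, None, :]).sum(axis=-1), 0.0)[0]

    up = resize_volume(VolumeImage(grid=cam), model.config.input_shape,
                       anti_alias=False).grid
    up = np.maximum(up, 0.0)
    peak = float(up.max())
    if peak <= 0:
        logger.warning("gradcam: zero saliency everywhere (vanishing gradients)")
        return SaliencyMap(grid=np.zeros_like(up), source_block=source_block)
    return SaliencyMap(grid=up / peak, source_block=source_block)
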