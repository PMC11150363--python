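"""Preprocessing chain: brain extraction, bias correction, resize, normalise.

The chain mirrors the standard structural-MRI recipe: strip the skull/scalp,
remove the smooth multiplicative intensity inhomogeneity, bring every scan
onto one network grid, and z-score the in-brain intensities.  Brain
extraction is a pluggable interface — a supplied mask wins, then an
optional external tool hook, then a threshold-plus-morphology fallback.
Bias correction is a log-domain polynomial surrogate satisfying the same
multiplicative smooth-field contract as N4; an ``n4_hook`` lets callers
substitute a full N4 implementation (e.g. SimpleITK's).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .io_manifest import VolumeImage

logger = logging.getLogger("brainage")


class ExtractionError(RuntimeError):
    """Fallback brain extraction produced an empty or degenerate mask."""


# ---------------------------------------------------------------------------
# brain extraction


def _fallback_mask(grid: np.ndarray) -> np.ndarray:
    """Threshold-based head/brain separation for shell-type phantoms.

    Otsu splits foreground from background; the largest connected component
    with filled holes is the head.  A second Otsu inside the foreground
    separates the bright shell from brain tissue; removing the shell and
    keeping the largest remaining component (closed and hole-filled, so the
    dark ventricle is retained) gives the brain.
    """
    finite = grid[np.isfinite(grid)]
    if finite.size == 0 or float(finite.max()) <= float(finite.min()):
        raise ExtractionError("volume has no intensity contrast; cannot extract a brain mask")
    t1 = threshold_otsu(finite)
    fg = grid > t1
    if not fg.any():
        raise ExtractionError("foreground empty after thresholding")
    lab, n = ndimage.label(fg)
    if n == 0:
        raise ExtractionError("no connected foreground component")
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    head = lab == (1 + int(np.argmax(sizes)))
    head = ndimage.binary_fill_holes(head)

    # the bright shell sits well above the tissue median; a quantile rule is
    # robust where Otsu degenerates on near-discrete intensity histograms
    fg_vals = grid[head]
    med = float(np.median(fg_vals))
    bright = float(np.percentile(fg_vals, 99.5))
    if bright > 1.1 * med:
        shell = head & (grid > 0.5 * (med + bright))
    else:  # no distinct bright shell present
        shell = np.zeros_like(head)
    brain = head & ~shell
    brain = ndimage.binary_opening(brain, iterations=1)
    lab, n = ndimage.label(brain)
    if n == 0:
        raise ExtractionError("brain mask empty after shell removal")
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    brain = lab == (1 + int(np.argmax(sizes)))
    brain = ndimage.binary_closing(brain, iterations=2)
    brain = ndimage.binary_fill_holes(brain)
    if not brain.any():
        raise ExtractionError("brain mask empty")
    return brain


def extract_brain(
    vol: VolumeImage,
    mask: Optional[np.ndarray] = None,
    tool_hook: Optional[Callable[[VolumeImage], np.ndarray]] = None,
) -> VolumeImage:
    """Zero everything outside the brain; store the mask on the volume.

    Mask precedence: explicit ``mask`` argument > ``tool_hook`` (an external
    skull-stripping tool returning a boolean grid) > threshold fallback.
    """
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != vol.grid.shape:
            raise ValueError(f"mask shape {mask.shape} != volume shape {vol.grid.shape}")
    elif tool_hook is not None:
        mask = np.asarray(tool_hook(vol), dtype=bool)
        if mask.shape != vol.grid.shape:
            raise ValueError("tool_hook returned a mask of the wrong shape")
    else:
        mask = _fallback_mask(np.asarray(vol.grid, dtype=float))
    out = vol.grid * mask
    return VolumeImage(grid=out, spacing=vol.spacing, mask=mask, affine=vol.affine)


# ---------------------------------------------------------------------------
# bias-field correction


def _poly_basis(shape: tuple[int, int, int], order: int) -> np.ndarray:
    """Monomial basis up to total degree ``order`` on [-1,1]^3, flattened."""
    coords = [np.linspace(-1.0, 1.0, n) for n in shape]
    x, y, z = np.meshgrid(*coords, indexing="ij")
    terms = []
    for i in range(order + 1):
        for j in range(order + 1 - i):
            for k in range(order + 1 - i - j):
                terms.append((x ** i) * (y ** j) * (z ** k))
    return np.stack([t.ravel() for t in terms], axis=1)


def correct_bias(vol: VolumeImage, mask: Optional[np.ndarray] = None, order: int = 2,
                 n4_hook: Optional[Callable[[VolumeImage, np.ndarray], VolumeImage]] = None
                 ) -> VolumeImage:
    """Divide out a smooth multiplicative intensity field.

    The field is estimated by least-squares fitting a polynomial of total
    degree ``order`` to the log-intensities inside the mask and exponentiated;
    the corrected volume is rescaled so the mean intensity inside the mask is
    preserved.  Intensities must be strictly positive inside the mask; if not,
    a positive shift is applied before the log and noted in the log output.
    ``n4_hook`` substitutes an external N4 implementation wholesale.
    """
    if mask is None:
        mask = vol.mask
    if mask is None:
        raise ValueError("correct_bias requires a mask (argument or vol.mask)")
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != vol.grid.shape:
        raise ValueError("correct_bias mask shape does not match the volume shape")
    if not mask.any():
        raise ValueError("empty mask")
    if order < 0:
        raise ValueError("polynomial order must be >= 0")
    if n4_hook is not None:
        return n4_hook(vol, mask)

    grid = np.asarray(vol.grid, dtype=float)
    inside = grid[mask]
    shift = 0.0
    mn = float(inside.min())
    if mn <= 0:
        shift = -mn + 1e-3 * max(1.0, float(np.abs(inside).max()))
        logger.info("correct_bias: applying positive shift %.4g before log", shift)
    logI = np.log(grid[mask] + shift)

    # fit only voxels at least half as bright as the in-mask median: dark
    # CSF-like structures (ventricles) would otherwise drag the smooth field
    # into fitting anatomy instead of the scanner artifact
    keep = logI >= np.median(logI) - np.log(2.0)
    if keep.sum() < 10:
        keep = np.ones_like(keep)
    basis = _poly_basis(grid.shape, order)
    flat_idx = np.flatnonzero(mask.ravel())
    A = basis[flat_idx][keep]
    coef, *_ = np.linalg.lstsq(A, logI[keep], rcond=None)
    log_field = (basis @ coef).reshape(grid.shape)
    log_field -= log_field[mask].mean()   # unit geometric mean inside the mask
    field = np.exp(log_field)

    corrected = (grid + shift) / field - shift
    scale = inside.mean() / corrected[mask].mean()
    corrected = corrected * scale
    out = grid.copy()
    out[mask] = corrected[mask]
    return VolumeImage(grid=out, spacing=vol.spacing, mask=mask, affine=vol.affine)


# ---------------------------------------------------------------------------
# resizing


def resize_volume(vol: VolumeImage, target_shape: tuple[int, int, int],
                  anti_alias: str | bool = "auto") -> VolumeImage:
    """Trilinear resample onto ``target_shape``; masks go nearest-neighbour.

    Sample points follow the pixel-centre convention
    ``src = (i + 0.5) * in/out - 0.5``.  With ``anti_alias="auto"`` a
    Gaussian prefilter (sigma = sqrt((f^2 - 1)/12) per axis) is applied to
    any axis downsampled by more than a factor of 2, suppressing aliasing
    when e.g. 256-voxel scanner grids drop to the 64x64x32 network grid.
    Spacing is rescaled so physical extent is preserved per axis.
    """
    target_shape = tuple(int(t) for t in target_shape)
    if len(target_shape) != 3 or any(t < 2 for t in target_shape):
        raise ValueError(f"target dims must be >= 2, got {target_shape}")
    grid = np.asarray(vol.grid, dtype=float)
    factors = [s / t for s, t in zip(grid.shape, target_shape)]

    smoothed = grid
    if anti_alias is True or anti_alias == "auto":
        thresh = 1.0 if anti_alias is True else 2.0
        sigmas = [np.sqrt(max(f * f - 1.0, 0.0) / 12.0) if f > thresh else 0.0
                  for f in factors]
        if any(s > 0 for s in sigmas):
            smoothed = ndimage.gaussian_filter(grid, sigma=sigmas, mode="nearest")

    coords = np.meshgrid(
        *[(np.arange(t) + 0.5) * f - 0.5 for t, f in zip(target_shape, factors)],
        indexing="ij",
    )
    out = ndimage.map_coordinates(smoothed, np.stack(coords), order=1, mode="nearest")
    new_mask = None
    if vol.mask is not None:
        new_mask = ndimage.map_coordinates(
            vol.mask.astype(np.uint8), np.stack(coords), order=0, mode="nearest"
        ).astype(bool)
    spacing = tuple(sp * f for sp, f in zip(vol.spacing, factors))
    return VolumeImage(grid=out, spacing=spacing, mask=new_mask, affine=vol.affine)


# ---------------------------------------------------------------------------
# intensity normalisation


def normalize_intensity(vol: VolumeImage) -> VolumeImage:
    """Z-score intensities inside the mask; voxels outside stay 0.

    A zero-variance masked region yields zeros with a warning rather than a
    division blow-up, so degenerate inputs propagate harmlessly.
    """
    mask = vol.mask if vol.mask is not None else np.ones(vol.grid.shape, dtype=bool)
    grid = np.asarray(vol.grid, dtype=float)
    inside = grid[mask]
    sd = float(inside.std())
    out = np.zeros_like(grid)
    if sd <= 0 or not np.isfinite(sd):
        logger.warning("normalize_intensity: zero variance inside mask; output zeros")
    else:
        out[mask] = (inside - inside.mean()) / sd
    return VolumeImage(grid=out, spacing=vol.spacing, mask=np.asarray(mask, bool),
                       affine=vol.affine)


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class PreprocessConfig:
    """Stage toggles and parameters for the fixed-order pipeline."""

    do_extract: bool = True
    do_bias: bool = True
    do_resize: bool = True
    do_normalize: bool = True
    bias_order: int = 2
    target_shape: tuple[int, int, int] = (64, 64, 32)
    anti_alias: str | bool = "auto"


def preprocess_pipeline(
    vol: VolumeImage,
    cfg: Optional[PreprocessConfig] = None,
    mask: Optional[np.ndarray] = None,
    tool_hook: Optional[Callable[[VolumeImage], np.ndarray]] = None,
) -> VolumeImage:
    """extract_brain -> correct_bias -> resize_volume -> normalize_intensity.

    The order is fixed; each stage can be switched off in ``cfg``.  Stage
    failures are re-raised with the stage name attached.
    """
    cfg = cfg or PreprocessConfig()
    out = vol
    stages: list[tuple[str, Callable[[VolumeImage], VolumeImage]]] = []
    if cfg.do_extract:
        stages.append(("extract_brain", lambda v: extract_brain(v, mask=mask, tool_hook=tool_hook)))
    if cfg.do_bias:
        stages.append(("correct_bias", lambda v: correct_bias(v, order=cfg.bias_order)))
    if cfg.do_resize:
        stages.append(("resize_volume",
                       lambda v: resize_volume(v, cfg.target_shape, anti_alias=cfg.anti_alias)))
    if cfg.do_normalize:
        stages.append(("normalize_intensity", normalize_intensity))
    for name, fn in stages:
        try:
            out = fn(out)
        except Exception as exc:
            raise type(exc)(f"[{name}] {exc}") from exc
    return out
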