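"""Image preprocessing: Lab conversion, CLAHE on luminance, resize, scale.

The enhancement pipeline mirrors what is done before feeding dermoscopy
images to the classifier: the image is moved from sRGB into CIE L*a*b*
(which separates luminance from chromaticity), contrast-limited adaptive
histogram equalization (CLAHE) is applied to the L* channel only, the image
is converted back to RGB, resized to the network input size, and scaled to
[0, 1]. The whole module is deterministic.

CLAHE here follows the classical formulation: the image is divided into a
grid of tiles; each tile's 256-bin histogram is clipped at
``clip_limit × (tile_area / 256)`` with the clipped excess redistributed
uniformly over all bins; each tile's mapping is the (midpoint-corrected)
cumulative distribution of the clipped histogram; and every pixel is
remapped by bilinear interpolation between the mappings of the four
surrounding tile centers. The midpoint correction (CDF evaluated at the
bin center rather than the bin's upper edge) makes the mapping unbiased,
so degenerate (constant) tiles are reproduced almost exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage import color
from skimage.transform import resize


class ShapeError(ValueError):
    """Raised when an image does not have the expected channel layout."""


class ParameterError(ValueError):
    """Raised when a configuration value is out of range for the input."""


@dataclass(frozen=True)
class PreprocessConfig:
    """Parameters of the enhancement pipeline.

    target_size : (height, width) of the network input, default (224, 224).
    clahe_clip_limit : histogram clip factor relative to the uniform bin
        height (a tile histogram bin is capped at clip × tile_area/256).
    clahe_tile_grid : (rows, cols) of the CLAHE tile grid.
    interpolation : resize interpolation order name.
    """

    target_size: tuple[int, int] = (224, 224)
    clahe_clip_limit: float = 2.0
    clahe_tile_grid: tuple[int, int] = (8, 8)
    interpolation: str = "bilinear"

    def __post_init__(self):
        if min(self.target_size) < 1:
            raise ParameterError("target_size must be positive")
        if self.clahe_clip_limit <= 0:
            raise ParameterError("clahe_clip_limit must be > 0")
        if min(self.clahe_tile_grid) < 1:
            raise ParameterError("clahe_tile_grid must be at least (1, 1)")
        if self.interpolation not in ("nearest", "bilinear", "bicubic"):
            raise ParameterError(f"unknown interpolation {self.interpolation!r}")


_INTERP_ORDER = {"nearest": 0, "bilinear": 1, "bicubic": 3}


def _check_rgb(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ShapeError(f"expected an H×W×3 RGB image, got shape {img.shape}")
    return img


def rgb_to_lab(img: np.ndarray) -> np.ndarray:
    """Convert an 8-bit sRGB image to CIE L*a*b* (D65), L* in [0, 100]."""
    img = _check_rgb(img)
    return color.rgb2lab(img.astype(np.float64) / 255.0)


def lab_to_rgb(lab: np.ndarray) -> np.ndarray:
    """Inverse Lab→sRGB transform, clipped to 8-bit [0, 255]."""
    lab = np.asarray(lab, dtype=np.float64)
    if lab.ndim != 3 or lab.shape[2] != 3:
        raise ShapeError(f"expected an H×W×3 Lab image, got shape {lab.shape}")
    with warnings.catch_warnings():
        # out-of-gamut Lab values are expected after CLAHE; clipping is
        # the documented behavior, so the conversion warning is noise
        warnings.filterwarnings("ignore", message=".*negative Z values.*")
        rgb = color.lab2rgb(lab)  # clips out-of-gamut values into [0, 1]
    return np.clip(np.round(rgb * 255.0), 0, 255).astype(np.uint8)


def _clahe_u8(channel: np.ndarray, clip_limit: float, grid: tuple[int, int]) -> np.ndarray:
    """CLAHE on a single uint8 channel. Returns uint8 of the same shape."""
    h, w = channel.shape
    gr, gc = grid
    if gr > h or gc > w:
        raise ParameterError(
            f"tile grid {grid} larger than image of shape {(h, w)}"
        )

    # Tile boundaries (last tiles absorb the remainder).
    row_edges = np.linspace(0, h, gr + 1).round().astype(int)
    col_edges = np.linspace(0, w, gc + 1).round().astype(int)

    luts = np.empty((gr, gc, 256), dtype=np.float64)
    centers_r = np.empty(gr)
    centers_c = np.empty(gc)
    for i in range(gr):
        r0, r1 = row_edges[i], row_edges[i + 1]
        centers_r[i] = (r0 + r1 - 1) / 2.0
        for j in range(gc):
            c0, c1 = col_edges[j], col_edges[j + 1]
            centers_c[j] = (c0 + c1 - 1) / 2.0
            tile = channel[r0:r1, c0:c1]
            area = tile.size
            hist = np.bincount(tile.ravel(), minlength=256).astype(np.float64)
            cap = max(clip_limit * area / 256.0, 1.0)
            excess = np.maximum(hist - cap, 0.0).sum()
            hist = np.minimum(hist, cap) + excess / 256.0
            cdf = np.cumsum(hist)
            # midpoint rule: evaluate the CDF at the bin center
            luts[i, j] = 255.0 * (cdf - hist / 2.0) / area

    # Bilinear blend of the four surrounding tile mappings per pixel.
    rows = np.arange(h, dtype=np.float64)
    cols = np.arange(w, dtype=np.float64)
    ri = np.clip(np.searchsorted(centers_r, rows, side="right") - 1, 0, gr - 1)
    ci = np.clip(np.searchsorted(centers_c, cols, side="right") - 1, 0, gc - 1)
    ri1 = np.minimum(ri + 1, gr - 1)
    ci1 = np.minimum(ci + 1, gc - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        wr = np.where(
            ri1 > ri, (rows - centers_r[ri]) / (centers_r[ri1] - centers_r[ri]), 0.0
        )
        wc = np.where(
            ci1 > ci, (cols - centers_c[ci]) / (centers_c[ci1] - centers_c[ci]), 0.0
        )
    wr = np.clip(wr, 0.0, 1.0)[:, None]
    wc = np.clip(wc, 0.0, 1.0)[None, :]

    v = channel.astype(int)
    rr0 = ri[:, None]
    rr1 = ri1[:, None]
    cc0 = ci[None, :]
    cc1 = ci1[None, :]
    top = (1 - wc) * luts[rr0, cc0, v] + wc * luts[rr0, cc1, v]
    bot = (1 - wc) * luts[rr1, cc0, v] + wc * luts[rr1, cc1, v]
    out = (1 - wr) * top + wr * bot
    return np.clip(np.round(out), 0, 255).astype(np.uint8)


def clahe_luminance(lab: np.ndarray, cfg: PreprocessConfig = PreprocessConfig()) -> np.ndarray:
    """Apply CLAHE to the L* channel of a Lab image; a*, b* pass through.

    L* is quantized to 8 bits for integer histogram semantics, equalized
    tile-wise, and rescaled back to [0, 100].
    """
    lab = np.asarray(lab, dtype=np.float64)
    if lab.ndim != 3 or lab.shape[2] != 3:
        raise ShapeError(f"expected an H×W×3 Lab image, got shape {lab.shape}")
    L8 = np.clip(np.round(lab[:, :, 0] * 255.0 / 100.0), 0, 255).astype(np.uint8)
    L8 = _clahe_u8(L8, cfg.clahe_clip_limit, cfg.clahe_tile_grid)
    out = lab.copy()
    out[:, :, 0] = L8.astype(np.float64) * 100.0 / 255.0
    return out


def resize_image(img: np.ndarray, cfg: PreprocessConfig) -> np.ndarray:
    """Resize an 8-bit RGB image to cfg.target_size, keeping uint8."""
    img = _check_rgb(img)
    order = _INTERP_ORDER[cfg.interpolation]
    out = resize(
        img.astype(np.float64),
        cfg.target_size,
        order=order,
        mode="edge",
        anti_aliasing=False,
        preserve_range=True,
    )
    return np.clip(np.round(out), 0, 255).astype(np.uint8)


def preprocess_image(img: np.ndarray, cfg: PreprocessConfig = PreprocessConfig()) -> np.ndarray:
    """Full pipeline: Lab → CLAHE(L*) → RGB → resize → scale to [0, 1].

    Returns a float64 tensor of shape ``(*cfg.target_size, 3)``.
    """
    img = _check_rgb(img)
    lab = rgb_to_lab(img)
    lab = clahe_luminance(lab, cfg)
    rgb = lab_to_rgb(lab)
    rgb = resize_image(rgb, cfg)
    return rgb.astype(np.float64) / 255.0
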