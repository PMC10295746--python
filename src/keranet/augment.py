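"""Label-preserving stochastic augmentation of training images.

One call to :func:`augment_image` draws a single random affine transform
(rotation, shift, isotropic zoom about the image center) plus optional
horizontal/vertical flips, in a fixed draw order so that streams are fully
reproducible from a seed. Augmentation operates on preprocessed [0, 1]
tensors and never changes image shape or class label.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np
from skimage.transform import AffineTransform, warp


@dataclass(frozen=True)
class AugmentConfig:
    """Augmentation magnitudes (all ranges symmetric around identity).

    rotation_range_deg : rotation drawn from U(−r, r) degrees.
    width_shift_frac / height_shift_frac : shifts drawn from U(−s, s)
        times the image width/height.
    zoom_range : zoom factor drawn from U(1−z, 1+z).
    horizontal_flip / vertical_flip : each applied with probability 0.5
        when enabled.
    fill_mode : how pixels revealed by the transform are filled
        ("nearest" = replicate edge, "reflect" = mirror).
    """

    rotation_range_deg: float = 20.0
    width_shift_frac: float = 0.1
    height_shift_frac: float = 0.1
    zoom_range: float = 0.1
    horizontal_flip: bool = True
    vertical_flip: bool = True
    fill_mode: str = "nearest"

    def __post_init__(self):
        if self.rotation_range_deg < 0 or self.zoom_range < 0:
            raise ValueError("ranges must be non-negative")
        if not (0 <= self.width_shift_frac < 1 and 0 <= self.height_shift_frac < 1):
            raise ValueError("shift fractions must lie in [0, 1)")
        if self.fill_mode not in ("nearest", "reflect"):
            raise ValueError(f"unknown fill_mode {self.fill_mode!r}")


_FILL_MODE = {"nearest": "edge", "reflect": "symmetric"}


def augment_image(img: np.ndarray, cfg: AugmentConfig, rng: np.random.Generator) -> np.ndarray:
    """Apply one random label-preserving transform to a [0, 1] tensor.

    The random draw order is fixed (rotation, x-shift, y-shift, zoom,
    h-flip, v-flip) so equal seeds give equal outputs. With all ranges at
    zero and flips disabled the input is returned unchanged.
    """
    img = np.asarray(img, dtype=np.float64)
    h, w = img.shape[:2]

    theta = np.deg2rad(rng.uniform(-cfg.rotation_range_deg, cfg.rotation_range_deg))
    tx = rng.uniform(-cfg.width_shift_frac, cfg.width_shift_frac) * w
    ty = rng.uniform(-cfg.height_shift_frac, cfg.height_shift_frac) * h
    zoom = rng.uniform(1.0 - cfg.zoom_range, 1.0 + cfg.zoom_range)
    hflip = cfg.horizontal_flip and rng.random() < 0.5
    vflip = cfg.vertical_flip and rng.random() < 0.5

    out = img
    if theta != 0.0 or tx != 0.0 or ty != 0.0 or zoom != 1.0:
        center = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
        t = (
            AffineTransform(translation=-center)
            + AffineTransform(rotation=theta, scale=(zoom, zoom))
            + AffineTransform(translation=center + np.array([tx, ty]))
        )
        out = warp(
            out,
            t.inverse,
            order=1,
            mode=_FILL_MODE[cfg.fill_mode],
            preserve_range=True,
        )
        out = np.clip(out, 0.0, 1.0)
    if hflip:
        out = out[:, ::-1]
    if vflip:
        out = out[::-1, :]
    return np.ascontiguousarray(out)


def augment_stream(
    fold: Sequence[tuple[np.ndarray, int]],
    cfg: AugmentConfig,
    seed: int,
    epochs: int = 1,
    shuffle: bool = True,
) -> Iterator[tuple[np.ndarray, int]]:
    """Yield augmented (image, label) pairs, one pass per source per epoch.

    Labels are carried through unchanged; within an epoch every source
    image is visited exactly once (in seeded shuffled order when
    ``shuffle`` is set).
    """
    if len(fold) == 0:
        raise ValueError("augment_stream requires a non-empty fold")
    rng = np.random.default_rng(seed)
    n = len(fold)
    for _ in range(epochs):
        order = rng.permutation(n) if shuffle else np.arange(n)
        for idx in order:
            img, label = fold[idx]
            yield augment_image(img, cfg, rng), label
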