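"""Synthetic two-class dermoscopy-like image corpus.

The generator writes a labeled PNG corpus plus a HAM10000-dialect
metadata CSV so the full pipeline (metadata reading, preprocessing,
augmentation, cross-validated training, evaluation) can run without any
download. It is **not** a clinical simulator: its only contracts are
seeded determinism and a monotone class-separability knob δ.

Image model
-----------
Each image is a smooth low-frequency skin-tone field with one elliptical
lesion (random center, axes, rotation). The class signal scales linearly
with δ ∈ [0, 1]:

* AK lesions receive additive high-frequency roughness texture of
  amplitude ∝ δ and a hue shift toward red-brown ∝ δ (mimicking the
  rough, erythematous surface of actinic keratosis);
* NAK lesions become smoother and more sharply bounded as δ grows
  (mimicking the waxy, well-demarcated look of benign keratoses).

At δ = 0 every class-specific term vanishes, so both classes draw from
the identical distribution and no classifier can beat chance.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter

from .dataio import DatasetIndex, Dialect, read_metadata

#: The AK:NAK ratio of the reference corpus (327 AK vs 1099 NAK images).
REFERENCE_COUNTS = (327, 1099)


@dataclass(frozen=True)
class SynthConfig:
    """Corpus parameters: class sizes, image size, separability δ, seed."""

    n_ak: int = 60
    n_nak: int = 60
    image_size: tuple[int, int] = (224, 224)
    separability: float = 1.0
    seed: int = 0
    out_dir: Path = Path("synthetic_corpus")

    def __post_init__(self):
        if self.n_ak < 0 or self.n_nak < 0:
            raise ValueError("class sizes must be non-negative")
        if not 0.0 <= self.separability <= 1.0:
            raise ValueError("separability must lie in [0, 1]")


def imbalance_preset(cfg: SynthConfig) -> SynthConfig:
    """Rescale class sizes to the reference 327:1099 imbalance.

    The requested total is ``cfg.n_ak + cfg.n_nak``; the AK count is the
    rounded proportional share and NAK takes the remainder.
    """
    total = cfg.n_ak + cfg.n_nak
    ref_ak, ref_nak = REFERENCE_COUNTS
    n_ak = int(round(total * ref_ak / (ref_ak + ref_nak)))
    return replace(cfg, n_ak=n_ak, n_nak=total - n_ak)


def _skin_base(rng: np.random.Generator, h: int, w: int) -> np.ndarray:
    """Smooth low-frequency skin-tone color field in [0, 1]."""
    base = np.array([0.82, 0.62, 0.52]) + rng.uniform(-0.05, 0.05, size=3)
    corners = base + rng.uniform(-0.06, 0.06, size=(2, 2, 3))
    yy = np.linspace(0, 1, h)[:, None, None]
    xx = np.linspace(0, 1, w)[None, :, None]
    field = (
        corners[0, 0] * (1 - yy) * (1 - xx)
        + corners[0, 1] * (1 - yy) * xx
        + corners[1, 0] * yy * (1 - xx)
        + corners[1, 1] * yy * xx
    )
    phase = rng.uniform(0, 2 * np.pi, size=2)
    wave = 0.02 * np.sin(2 * np.pi * yy[:, :, 0] + phase[0]) \
         + 0.02 * np.sin(2 * np.pi * xx[0, :, :].T + phase[1])
    return np.clip(field + wave[:, :, None], 0.0, 1.0)


def _lesion_geometry(rng: np.random.Generator, h: int, w: int):
    cy = rng.uniform(0.35, 0.65) * h
    cx = rng.uniform(0.35, 0.65) * w
    r = min(h, w)
    a = rng.uniform(0.18, 0.32) * r
    b = rng.uniform(0.18, 0.32) * r
    phi = rng.uniform(0, np.pi)
    yy, xx = np.mgrid[0:h, 0:w]
    dy, dx = yy - cy, xx - cx
    u = dx * np.cos(phi) + dy * np.sin(phi)
    v = -dx * np.sin(phi) + dy * np.cos(phi)
    q = np.sqrt((u / a) ** 2 + (v / b) ** 2)  # normalized elliptical radius
    return q


def _render(rng: np.random.Generator, h: int, w: int, label: str, delta: float) -> np.ndarray:
    base = _skin_base(rng, h, w)
    q = _lesion_geometry(rng, h, w)

    # Shared lesion appearance (identical across classes at delta = 0)
    lesion_color = base * rng.uniform(0.68, 0.78) + np.array([0.06, 0.02, 0.0])
    edge_width = 0.25
    if label == "AK":
        # hue shift toward red-brown, scaled by separability
        lesion_color = lesion_color + delta * np.array([0.12, -0.05, -0.08])
    else:
        # waxy sharp boundary: edge narrows with separability
        edge_width = edge_width * (1.0 - 0.8 * delta)
    mask = np.clip((1.0 + edge_width - q) / (2 * edge_width), 0.0, 1.0)[:, :, None]

    img = base * (1 - mask) + np.clip(lesion_color, 0, 1) * mask

    if label == "AK" and delta > 0:
        rough = gaussian_filter(rng.normal(size=(h, w)), sigma=0.8)
        rough /= max(rough.std(), 1e-9)
        img += (0.10 * delta) * rough[:, :, None] * mask
    if label == "NAK" and delta > 0:
        sheen = np.exp(-((q - rng.uniform(0.2, 0.5)) ** 2) / 0.08)
        img += (0.06 * delta) * sheen[:, :, None] * mask

    img += rng.normal(scale=0.01, size=img.shape)  # sensor noise, both classes
    return np.clip(np.round(img * 255.0), 0, 255).astype(np.uint8)


def generate_corpus(cfg: SynthConfig) -> DatasetIndex:
    """Write the corpus (PNGs + metadata.csv) and return its index.

    Images are written as PNG for byte-determinism across codecs; the
    metadata CSV uses the HAM10000 dialect (``dx`` = akiec / bkl). The
    same config always produces a byte-identical corpus.
    """
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    h, w = cfg.image_size
    ss = np.random.SeedSequence(cfg.seed)
    rows = []
    specs = [("AK", "akiec", i) for i in range(cfg.n_ak)] + \
            [("NAK", "bkl", i) for i in range(cfg.n_nak)]
    for child, (label, dx, i) in zip(ss.spawn(len(specs)), specs):
        rng = np.random.default_rng(child)
        img = _render(rng, h, w, label, cfg.separability)
        image_id = f"syn_{dx}_{i:05d}"
        Image.fromarray(img).save(out_dir / f"{image_id}.png")
        rows.append((image_id, dx))

    csv_path = out_dir / "metadata.csv"
    with open(csv_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["image_id", "dx"])
        writer.writerows(rows)
    return read_metadata(csv_path, out_dir, Dialect.SYNTHETIC)
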