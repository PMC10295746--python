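"""Reading and writing of image corpora, metadata and run reports.

Metadata dialects
-----------------
``HAM10000``
    A CSV with at least ``image_id`` and ``dx`` columns. ``dx == "akiec"``
    maps to the AK (actinic keratosis) class, ``dx == "bkl"`` (benign
    keratosis-like lesions) to NAK; every other diagnosis is dropped.
``ISIC2019``
    The ISIC-2019 ground-truth CSV: an ``image`` column plus one-hot
    diagnosis columns; ``AK == 1`` maps to AK, ``BKL == 1`` to NAK.
``SYNTHETIC``
    Corpora written by :mod:`keranet.synthetic`; same column layout as
    HAM10000.

All reading is deterministic: record order follows CSV row order, and any
shuffling happens downstream under an explicit seed.
"""

from __future__ import annotations

import enum
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from PIL import Image, UnidentifiedImageError

logger = logging.getLogger(__name__)

#: Class labels. AK (actinic keratosis) is the positive class throughout.
AK = "AK"
NAK = "NAK"
LABELS = (NAK, AK)  # index 0 = NAK, index 1 = AK

_IMAGE_EXTENSIONS = (".png", ".jpg", ".jpeg", ".PNG", ".JPG", ".JPEG")


class Dialect(str, enum.Enum):
    HAM10000 = "HAM10000"
    ISIC2019 = "ISIC2019"
    SYNTHETIC = "SYNTHETIC"


class DataFormatError(ValueError):
    """Raised when a metadata file violates its dialect's contract."""


class EmptyDatasetError(DataFormatError):
    """Raised when no records remain after dialect filtering."""


class ImageIOError(IOError):
    """Raised when an image file cannot be read; carries the image id."""

    def __init__(self, image_id: str, message: str):
        self.image_id = image_id
        super().__init__(f"{image_id}: {message}")


@dataclass(frozen=True)
class ImageRecord:
    """One labeled image: identifier, on-disk path and AK/NAK label."""

    image_id: str
    path: Path
    label: str

    def __post_init__(self):
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")


@dataclass(frozen=True)
class DatasetIndex:
    """Ordered catalog of labeled images with source-dialect provenance."""

    records: tuple[ImageRecord, ...]
    dialect: Dialect

    def __post_init__(self):
        ids = [r.image_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise DataFormatError(f"duplicate image_id values: {dupes}")

    @property
    def class_counts(self) -> Mapping[str, int]:
        counts = {lab: 0 for lab in LABELS}
        for r in self.records:
            counts[r.label] += 1
        return counts

    @property
    def labels(self) -> np.ndarray:
        """Integer labels (NAK=0, AK=1) in record order."""
        return np.array([LABELS.index(r.label) for r in self.records], dtype=int)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


def _resolve_path(image_dir: Path, image_id: str) -> Path:
    for ext in _IMAGE_EXTENSIONS:
        p = image_dir / f"{image_id}{ext}"
        if p.exists():
            return p
    raise DataFormatError(f"no image file found for id {image_id!r} in {image_dir}")


def read_metadata(csv_path, image_dir, dialect: Dialect | str = Dialect.HAM10000) -> DatasetIndex:
    """Read a metadata CSV and return a :class:`DatasetIndex`.

    The result is a pure function of the file bytes: record order follows
    CSV row order after dialect filtering.
    """
    dialect = Dialect(dialect)
    csv_path = Path(csv_path)
    image_dir = Path(image_dir)
    df = pd.read_csv(csv_path)

    if dialect in (Dialect.HAM10000, Dialect.SYNTHETIC):
        for col in ("image_id", "dx"):
            if col not in df.columns:
                raise DataFormatError(f"metadata is missing required column {col!r}")
        mapping = {"akiec": AK, "bkl": NAK}
        kept = df[df["dx"].isin(mapping)]
        ids = kept["image_id"].astype(str)
        labels = kept["dx"].map(mapping)
    else:  # ISIC2019 one-hot ground truth
        for col in ("image", "AK", "BKL"):
            if col not in df.columns:
                raise DataFormatError(f"metadata is missing required column {col!r}")
        is_ak = df["AK"] == 1
        is_bkl = df["BKL"] == 1
        kept = df[is_ak | is_bkl]
        ids = kept["image"].astype(str)
        labels = np.where(kept["AK"] == 1, AK, NAK)

    records = tuple(
        ImageRecord(image_id=i, path=_resolve_path(image_dir, i), label=lab)
        for i, lab in zip(ids, labels)
    )
    if not records:
        raise EmptyDatasetError(
            f"no AK/NAK records remained after filtering {csv_path} under dialect {dialect.value}"
        )
    return DatasetIndex(records=records, dialect=dialect)


def load_image(record: ImageRecord) -> np.ndarray:
    """Load an image as an 8-bit RGB array of shape (H, W, 3).

    Grayscale inputs are channel-replicated with a warning; 16-bit inputs
    are rescaled to 8 bits. Unreadable files raise :class:`ImageIOError`
    carrying the image id.
    """
    try:
        with Image.open(record.path) as im:
            im.load()
            if im.mode in ("L", "I", "I;16", "I;16B"):
                arr = np.asarray(im)
                if arr.dtype != np.uint8:
                    arr = (arr.astype(np.float64) * (255.0 / max(arr.max(), 1))).round()
                    arr = arr.astype(np.uint8)
                warnings.warn(
                    f"grayscale image {record.image_id}; replicating channel to RGB",
                    stacklevel=2,
                )
                return np.repeat(arr[:, :, None], 3, axis=2)
            rgb = im.convert("RGB")
            return np.asarray(rgb, dtype=np.uint8)
    except (OSError, UnidentifiedImageError, SyntaxError) as exc:
        raise ImageIOError(record.image_id, str(exc)) from exc


# ---------------------------------------------------------------------------
# Run reports
# ---------------------------------------------------------------------------

@dataclass
class RunReport:
    """Results of one k-fold cross-validated run.

    ``fold_metrics`` has one row per fold; ``summaries`` maps metric name to
    ``{"values": [...], "mean": m, "ci_half_width": h}`` with the 95% CI
    half-width from the Student-t distribution on the fold values.
    ``roc_points`` maps fold id to a list of (FPR, TPR) pairs.
    """

    k: int
    fold_metrics: list[dict]
    summaries: dict[str, dict]
    roc_points: dict[str, list[list[float]]]
    predictions: list[dict] = field(default_factory=list)
    config: dict = field(default_factory=dict)
    seeds: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("a run report needs at least one fold")
        if len(self.fold_metrics) != self.k:
            raise ValueError(
                f"fold_metrics has {len(self.fold_metrics)} rows but k={self.k}"
            )

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "fold_metrics": self.fold_metrics,
            "summaries": self.summaries,
            "roc_points": self.roc_points,
            "predictions": self.predictions,
            "config": self.config,
            "seeds": self.seeds,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunReport":
        return cls(
            k=d["k"],
            fold_metrics=d["fold_metrics"],
            summaries=d["summaries"],
            roc_points=d["roc_points"],
            predictions=d.get("predictions", []),
            config=d.get("config", {}),
            seeds=d.get("seeds", {}),
        )


def write_report(report: RunReport, out_path) -> None:
    """Write a report as JSON plus a per-fold CSV next to it.

    Floats are serialized with full repr precision, so a read-after-write
    round trip reproduces them bit-exactly.
    """
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    with open(out_path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=2)
    csv_path = out_path.with_suffix(".folds.csv")
    pd.DataFrame(report.fold_metrics).to_csv(csv_path, index=False)
    logger.info("wrote report to %s (folds table: %s)", out_path, csv_path)


def read_report(path) -> RunReport:
    with open(path) as fh:
        return RunReport.from_dict(json.load(fh))
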