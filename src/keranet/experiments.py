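"""Reference study on the synthetic corpus.

The scaled-down study exercises the full pipeline end to end: a seeded
synthetic corpus of 60 images per class at 64×64 pixels, a proportionally
truncated network (3 depthwise-separable blocks at quarter width), and
five-fold cross-validated training for up to 10 epochs under the standard
optimization protocol. At full separability (δ = 1) the corpus is
separable by construction and the classifier should approach perfect
validation accuracy; at δ = 0 the two classes are identically distributed
and validation accuracy must sit at chance.

The problem sizes keep a single study to a few minutes on one CPU while
leaving every moving part (preprocessing, augmentation, batch-norm
training, LR schedule, checkpointing, metrics) in play.
"""

from __future__ import annotations

import tempfile
from pathlib import Path
from typing import Optional

from .architecture import ModelConfig
from .augment import AugmentConfig
from .classifier import CVResults, DermoscopyClassifier
from .preprocess import PreprocessConfig
from .synthetic import SynthConfig
from .train import TrainConfig

STUDY_IMAGE_SIZE = (64, 64)
STUDY_N_PER_CLASS = 60


def study_configs(seed: int, epochs: int = 10) -> dict:
    """The scaled-down study conditions as config objects."""
    return {
        "preprocess": PreprocessConfig(target_size=STUDY_IMAGE_SIZE),
        "architecture": ModelConfig(
            input_size=(*STUDY_IMAGE_SIZE, 3),
            truncate_after_block=3,
            width_multiplier=0.25,
        ),
        "training": TrainConfig(epochs=epochs, seed=seed),
        "augmentation": AugmentConfig(),
    }


def synthetic_cv_study(
    delta: float,
    seed: int,
    n_per_class: int = STUDY_N_PER_CLASS,
    epochs: int = 10,
    out_dir: Optional[Path] = None,
) -> CVResults:
    """Run the five-fold CV study on a synthetic corpus at separability δ."""
    cfgs = study_configs(seed=seed, epochs=epochs)
    with tempfile.TemporaryDirectory() as tmp:
        corpus_dir = Path(out_dir) if out_dir is not None else Path(tmp) / "corpus"
        synth = SynthConfig(
            n_ak=n_per_class,
            n_nak=n_per_class,
            image_size=STUDY_IMAGE_SIZE,
            separability=delta,
            seed=seed,
            out_dir=corpus_dir,
        )
        model = DermoscopyClassifier.from_synthetic(synth, **cfgs)
        return model.fit()
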