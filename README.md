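# keranet

Auxiliary diagnosis of **actinic keratosis (AK)** from dermoscopy images.
AK is a UV-induced precancerous skin lesion that is easily confused with
benign, non-actinic keratoses (NAK, e.g. seborrheic keratosis); roughly one
in ten untreated AK lesions progresses to squamous cell carcinoma, so a
cheap, non-invasive screening aid matters clinically. `keranet` implements
a complete, tested AK-vs-NAK classification pipeline for researchers and
engineers working with dermoscopy corpora such as HAM10000 and ISIC-2019:

1. **Preprocessing** — images move from sRGB to CIE **L\*a\*b\*** (separating
   luminance from chromaticity), **CLAHE** (contrast-limited adaptive
   histogram equalization: tile-wise clipped-histogram equalization with
   bilinear blending between tile mappings) is applied to the L\* channel
   only, the image returns to RGB, is resized to the network input
   (224×224×3 by default) and scaled to [0, 1].
2. **Augmentation** — seeded, label-preserving random rotation,
   translation, zoom and horizontal/vertical flips on training folds only.
3. **Model** — a truncated depthwise-separable CNN: one standard 3×3
   convolution (32 filters, stride 2) plus the first 7 depthwise-separable
   blocks of the MobileNet family (depthwise 3×3 + pointwise 1×1, batch
   norm and ReLU after every convolution), i.e. **15 convolution layers**,
   then global average pooling, dropout 0.25, a 2-unit dense layer and
   softmax. The network and its backpropagation are implemented in NumPy;
   the architecture is described declaratively (`NetworkSpec`) with
   closed-form parameter counting, so the realized graph is audited
   against its description.
4. **Training** — stratified five-fold cross-validation; Adam with initial
   learning rate 0.01 and categorical cross-entropy; the rate is halved
   after 2 epochs without validation-accuracy improvement, floored at
   1e-5; the best-validation-accuracy weights are checkpointed per fold.
5. **Evaluation** — accuracy, cross-entropy loss, sensitivity
   TP/(TP+FN), specificity TN/(TN+FP), Matthews correlation coefficient

       MCC = (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN)),

   and ROC/AUC in the Mann–Whitney pair-counting form, aggregated over
   folds as mean ± 95% CI (Student-t on k−1 df). AK is the positive class.
6. **Synthetic corpus** — a seeded generator of two-class dermoscopy-like
   images with a separability knob δ ∈ [0, 1] and an imbalance preset
   matching the 327:1099 AK:NAK ratio of the reference corpus, so the
   whole pipeline is testable with no downloads.

## Worked example

```python
from keranet import DermoscopyClassifier, SynthConfig
from keranet.preprocess import PreprocessConfig
from keranet.architecture import ModelConfig
from keranet.train import TrainConfig

model = DermoscopyClassifier.from_synthetic(
    SynthConfig(n_ak=30, n_nak=30, image_size=(64, 64), separability=1.0,
                seed=0, out_dir="demo_corpus"),
    preprocess=PreprocessConfig(target_size=(64, 64)),
    architecture=ModelConfig(input_size=(64, 64, 3), truncate_after_block=3,
                             width_multiplier=0.25),
    training=TrainConfig(epochs=8, k_folds=5, seed=0),
)
results = model.fit()
print(results.summary())
```

prints (a separable synthetic corpus is learned perfectly; the loss column
is the mean validation cross-entropy, in nats):

```
Cross-validated dermoscopy classification results
==========================================================
folds: 5    records: 60
----------------------------------------------------------
metric              mean    95% CI ±   per-fold
accuracy          1.0000      0.0000   1.000 1.000 1.000 1.000 1.000
loss              0.4347      0.0832   0.427 0.531 0.348 0.411 0.456
auc               1.0000      0.0000   1.000 1.000 1.000 1.000 1.000
sensitivity       1.0000      0.0000   1.000 1.000 1.000 1.000 1.000
specificity       1.0000      0.0000   1.000 1.000 1.000 1.000 1.000
mcc               1.0000      0.0000   1.000 1.000 1.000 1.000 1.000
==========================================================
```

`results.fold_metrics` is a DataFrame, `results.plot_roc()` draws the
per-fold ROC curves, and `results.save("report.json")` writes the full
report (JSON + per-fold CSV) for bit-exact reload via `CVResults.load`.

The same pipeline is available from the shell:

```sh
keranet generate-synthetic --n-ak 30 --n-nak 30 --delta 1.0 \
    --image-size 64 --seed 0 --out corpus/
keranet train-cv --metadata corpus/metadata.csv --image-dir corpus/ \
    --dialect SYNTHETIC --config run.yaml --seed 0 --out report.json
keranet model summary
keranet evaluate --predictions preds.csv --roc-out roc.csv
```

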