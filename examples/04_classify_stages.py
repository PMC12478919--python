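"""Hybrid stage classification: CNN features -> multi-scale head -> SVM.

Feature maps from a convolutional backbone pass through three parallel
branches (3x3 / 5x5 / 7x7 kernels) whose pooled outputs concatenate into
one feature vector; after standardization a grid-searched RBF SVM makes
the one-vs-rest decision. Prints the grid-search table, the per-class
report, ROC AUCs, and a McNemar comparison against the softmax head alone.
"""

import numpy as np

from adstage import (
    HeadTrainConfig,
    MultiScaleConfig,
    MultiScaleHead,
    SmallCNNBackbone,
    SplitRatios,
    apply_scaler,
    evaluate_classifier,
    extract_features,
    fit_scaler,
    generate_dataset,
    grid_search_svm,
    mcnemar_test,
    multi_scale_forward,
    roc_one_vs_rest,
    split_dataset,
    svm_predict,
    train_head,
)
from adstage.classification import CLASSES

manifest, samples = generate_dataset(n_per_class=100, seed=0, image_size=64)
manifest = split_dataset(manifest, SplitRatios(), seed=42)


def arrays(tag):
    recs = [r for r in manifest.records if r.split == tag]
    x = np.stack([samples[r.id].image * samples[r.id].gm_mask for r in recs])
    return x, np.array([r.label for r in recs])


x_tr, y_tr = arrays("train")
x_te, y_te = arrays("test")

backbone = SmallCNNBackbone(input_size=64, out_channels=32, seed=0)
head = MultiScaleHead(32, MultiScaleConfig(branch_channels=64), seed=0)
train_head(backbone, head, (x_tr, y_tr),
           HeadTrainConfig(learning_rate=1e-3, epochs=5, seed=0))

f_tr = multi_scale_forward(head, extract_features(backbone, x_tr))
f_te = multi_scale_forward(head, extract_features(backbone, x_te))
print(f"feature vector length: {f_tr.shape[1]} (3 branches x 64 channels)")

scaler = fit_scaler(f_tr)
svm, table = grid_search_svm(apply_scaler(scaler, f_tr), y_tr, seed=42)
print("\ngrid search (5-fold CV accuracy, best first):")
print(table.to_string(index=False))

pred, scores = svm_predict(svm, apply_scaler(scaler, f_te))
report = evaluate_classifier(pred, y_te)
print(f"\ntest accuracy: {report.accuracy:.4f}")
for cls in CLASSES:
    d = report.per_class[cls]
    print(f"  {cls}: precision {d['precision']:.3f} recall {d['recall']:.3f} "
          f"f1 {d['f1']:.3f}")
print("confusion matrix (rows = truth):")
print(report.confusion.to_string())

for cls, roc in roc_one_vs_rest(scores, y_te, classes=svm.classes_).items():
    print(f"ROC {cls}: AUC {roc.auc:.4f}, optimal threshold {roc.optimal_threshold:.3f}")

logits = head.forward(extract_features(backbone, x_te), training=False)
head_pred = np.array([CLASSES[i] for i in logits.argmax(axis=1)])
mc = mcnemar_test(pred, head_pred, y_te)
print(f"\nMcNemar SVM vs softmax head: statistic {mc.statistic:.2f}, "
      f"p = {mc.p_value:.3g} (b = {mc.b}, c = {mc.c})")
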