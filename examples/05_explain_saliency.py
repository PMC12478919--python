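"""Gradient saliency: which pixels drive the stage decision?

Computes |d(class score)/d(pixel)| through the differentiable softmax head,
renders a class-colored overlay (AD red / MCI blue / CN green), and prints
the four-quadrant saliency table plus the gray-matter-vs-background
concentration, the quantitative check that the model looks at the ribbon
whose atrophy defines the disease stages.
"""

import numpy as np

from adstage import (
    DifferentiableClassifier,
    HeadTrainConfig,
    MultiScaleConfig,
    MultiScaleHead,
    SmallCNNBackbone,
    compute_saliency,
    generate_dataset,
    region_quantification,
    render_overlay,
    train_head,
)

manifest, samples = generate_dataset(n_per_class=40, seed=1, image_size=64)
X = np.stack([s.image * s.gm_mask for s in samples.values()])
G = np.stack([s.gm_mask for s in samples.values()])
y = np.array([s.label for s in samples.values()])

backbone = SmallCNNBackbone(input_size=64, out_channels=32, seed=1)
head = MultiScaleHead(32, MultiScaleConfig(branch_channels=64), seed=1)
train_head(backbone, head, (X, y),
           HeadTrainConfig(learning_rate=1e-3, epochs=10, seed=1))
model = DifferentiableClassifier(backbone, head)

maps, labels, gm_vals, bg_vals = [], [], [], []
for i in range(0, len(X), 6):
    sal = compute_saliency(model, X[i], y[i])
    maps.append(sal)
    labels.append(y[i])
    gm_vals.append(sal[G[i] == 1].mean())
    bg_vals.append(sal[G[i] == 0].mean())

print("four-quadrant mean saliency per class:")
print(region_quantification(maps, labels).round(4).to_string())
print(f"\nmean saliency inside GM ribbon: {np.mean(gm_vals):.4f}")
print(f"mean saliency in background:    {np.mean(bg_vals):.4f}")
print("a trained head concentrates saliency on the gray matter it classifies by")

overlay = render_overlay(maps[0], X[0], labels[0], blur_sigma=2.0, edge_on=True)
print(f"\noverlay rendered: shape {overlay.shape}, "
      f"class {labels[0]} tints channel {'RGB'[0 if labels[0] == 'AD' else (1 if labels[0] == 'CN' else 2)]}")
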