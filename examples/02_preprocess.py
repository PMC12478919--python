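"""Slice selection, normalization, augmentation and stratified splitting.

Mirrors a standard 2D MRI preprocessing recipe: keep the middle 40% of
axial slices, resize to 224 x 224 with per-slice min-max normalization,
expand classes by small rotations (+/-7 deg) and zooms (+/-10%), and split
60/20/20 stratified by class.
"""

import numpy as np

from adstage import (
    AugmentPolicy,
    SplitRatios,
    augment_to_count,
    generate_dataset,
    normalize_slice,
    select_middle_slices,
    split_dataset,
)

idx = select_middle_slices(n_slices=100, fraction=0.4)
print(f"middle 40% of a 100-slice volume: slices {idx.start}..{idx.stop - 1} "
      f"({len(idx)} slices)")

raw = np.random.default_rng(0).normal(120, 40, (91, 109))
norm = normalize_slice(raw, out_size=224)
print(f"normalized slice: shape {norm.shape}, range [{norm.min():.2f}, {norm.max():.2f}]")

manifest, samples = generate_dataset(n_per_class=20, seed=0, image_size=64)
split = split_dataset(manifest, SplitRatios(0.6, 0.2, 0.2), seed=42)
for tag in ("train", "val", "test"):
    n = sum(r.split == tag for r in split.records)
    print(f"{tag}: {n} records")

train_imgs = [samples[r.id].image for r in split.records
              if r.split == "train" and r.label == "AD"]
augmented = augment_to_count(train_imgs, AugmentPolicy(seed=42), target=40)
print(f"AD training slices expanded {len(train_imgs)} -> {len(augmented)} "
      "(originals kept, transforms appended)")
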