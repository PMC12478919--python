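"""Four-phase pipeline orchestration: phantoms -> preprocessing -> U-Net
segmentation -> hybrid classification -> saliency explanation.

``run_pipeline`` executes a requested subset of stages in canonical order
for each seed in the configured repeat list, persisting every artifact
under a per-seed directory inside the run directory (config snapshot, CSV
manifests, model checkpoints, JSON metrics, a log). A stage whose inputs
are missing fails with an error naming the stage that produces them. After
all repeats, per-metric mean and standard deviation are written to
``summary.csv``; the summary content is a pure function of the config and
seeds, so identical runs produce identical summaries.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import random
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import phantom as ph
from . import preprocess as pp
from . import segmentation as seg
from . import classification as clf
from . import saliency as xai

log = logging.getLogger("adstage")

STAGES = ("generate", "preprocess", "train-seg", "train-clf", "evaluate", "explain")

# which stage produces each artifact, for actionable error messages
_PRODUCER = {
    "manifest.csv": "generate",
    "manifest_split.csv": "preprocess",
    "seg_model.npz": "train-seg",
    "clf_artifacts.npz": "train-clf",
}


class PipelineError(RuntimeError):
    pass


def set_global_seeds(seed: int) -> None:
    """Seed every random source the package can draw from (idempotent)."""
    if seed < 0:
        raise ValueError("seed must be non-negative")
    np.random.seed(seed)
    random.seed(seed)


@dataclass
class PipelineConfig:
    """Resolved configuration of one pipeline run (YAML-serializable)."""

    out_root: str = "runs"
    # phantom generation
    n_per_class: int = 60
    image_size: int = 64
    noise_sigma: float = 0.02
    jitter: float = 0.03
    # preprocessing
    train_ratio: float = 0.60
    val_ratio: float = 0.20
    test_ratio: float = 0.20
    augment_target_per_class: int = 0     # 0 disables augmentation
    rotation_limit: float = 7.0
    zoom_limit: float = 0.10
    # segmentation (gray matter, multi-layer variant by default)
    seg_variant: str = "multilayer"       # or "vanilla"
    seg_target: str = "gm"               # or "brain"
    seg_loss: str = "balanced_bce"        # or "dice"
    seg_base_filters: int = 16
    seg_epochs: int = 4
    seg_batch_size: int = 8
    seg_learning_rate: float = 1e-3
    seg_beta: float | str = "auto"
    # classification
    backbone_channels: int = 32
    branch_channels: int = 64
    head_epochs: int = 5
    head_learning_rate: float = 1e-3
    head_batch_size: int = 32
    use_segmentation: bool = True
    single_scale: bool = False
    end_to_end: bool = False
    # explanation
    blur_sigma: float = 2.0
    explain_per_class: int = 5
    # repeats
    seeds: tuple[int, ...] = (42, 43, 44, 45, 46)
    run_repeats: int = 5

    def __post_init__(self):
        if len(set(self.seeds)) != len(self.seeds):
            raise PipelineError("seeds must be unique")
        if not 1 <= self.run_repeats <= len(self.seeds):
            raise PipelineError("run_repeats must be between 1 and len(seeds)")

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["seeds"] = list(d["seeds"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        d.update(overrides)
        if "seeds" in d:
            d["seeds"] = tuple(d["seeds"])
        return cls(**d)


def _setup_logging(run_dir: Path) -> None:
    log.setLevel(logging.INFO)
    # one file handler per run directory
    for h in [h for h in log.handlers if isinstance(h, logging.FileHandler)]:
        log.removeHandler(h)
        h.close()
    fh = logging.FileHandler(run_dir / "run.log")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)
    if not any(isinstance(h, logging.StreamHandler)
               and not isinstance(h, logging.FileHandler) for h in log.handlers):
        log.addHandler(logging.StreamHandler())


def _require(seed_dir: Path, filename: str) -> Path:
    p = seed_dir / filename
    if not p.exists():
        raise PipelineError(
            f"missing input {filename!r}; run stage {_PRODUCER[filename]!r} first")
    return p


def _load_split(seed_dir: Path, tags) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """images, brain masks, gm masks, labels for the requested split tags."""
    df = pd.read_csv(_require(seed_dir, "manifest_split.csv"))
    rows = df[df["split"].isin(tags)]
    images = np.stack([ph.load_image(p) for p in rows["image_path"]])
    brain = np.stack([ph.load_mask(p) for p in rows["brain_mask_path"]])
    gm = np.stack([ph.load_mask(p) for p in rows["gm_mask_path"]])
    return images, brain, gm, rows["label"].to_numpy()


# ---------------------------------------------------------------------------
# stage implementations (one seed)

def _stage_generate(cfg: PipelineConfig, seed_dir: Path, seed: int) -> dict:
    manifest, samples = ph.generate_dataset(
        cfg.n_per_class, seed=seed, image_size=cfg.image_size,
        noise_sigma=cfg.noise_sigma, jitter=cfg.jitter)
    ph.save_dataset(manifest, samples, seed_dir, fmt="png")
    log.info("generate: wrote %d samples to %s", len(manifest.records), seed_dir)
    return {"n_samples": len(manifest.records), **{f"n_{k}": v for k, v in manifest.counts.items()}}


def _stage_preprocess(cfg: PipelineConfig, seed_dir: Path, seed: int) -> dict:
    csv = _require(seed_dir, "manifest.csv")
    df = pd.read_csv(csv)
    records = [ph.ManifestRecord(**{k: ("" if pd.isna(v) else v)
                                    for k, v in row.items()})
               for row in df.to_dict("records")]
    manifest = ph.DatasetManifest(records=records, seed=seed)
    ratios = pp.SplitRatios(cfg.train_ratio, cfg.val_ratio, cfg.test_ratio)
    split = pp.split_dataset(manifest, ratios, seed=seed)
    split.to_frame().to_csv(seed_dir / "manifest_split.csv", index=False)
    counts = {}
    for tag in ("train", "val", "test"):
        counts[f"n_{tag}"] = sum(r.split == tag for r in split.records)
    log.info("preprocess: split %s", counts)
    return counts


def _stage_train_seg(cfg: PipelineConfig, seed_dir: Path, seed: int) -> dict:
    images_tr, brain_tr, gm_tr, _ = _load_split(seed_dir, ["train"])
    images_va, brain_va, gm_va, _ = _load_split(seed_dir, ["val"])
    target_tr = gm_tr if cfg.seg_target == "gm" else brain_tr
    target_va = gm_va if cfg.seg_target == "gm" else brain_va
    if cfg.seg_variant == "multilayer":
        config = seg.multilayer_config(cfg.image_size, cfg.seg_base_filters)
    else:
        config = seg.vanilla_config(cfg.image_size, cfg.seg_base_filters)
    model = seg.build_unet(config, seed=seed)
    tcfg = seg.SegTrainConfig(learning_rate=cfg.seg_learning_rate,
                              batch_size=cfg.seg_batch_size,
                              epochs=cfg.seg_epochs, loss=cfg.seg_loss,
                              beta=cfg.seg_beta, seed=seed)
    history = seg.train_segmenter(model, (images_tr, target_tr),
                                  (images_va, target_va), tcfg)
    model.save(seed_dir / "seg_model.npz")
    (seed_dir / "seg_history.json").write_text(json.dumps(
        {k: v for k, v in history.items()}, indent=2))
    val_dice = max(history["val_dice"])
    log.info("train-seg: %s/%s val dice %.4f", cfg.seg_variant, cfg.seg_target, val_dice)
    return {"val_dice": val_dice, "best_epoch": history["best_epoch"]}


def _load_seg_model(cfg: PipelineConfig, seed_dir: Path) -> seg.UNet:
    path = _require(seed_dir, "seg_model.npz")
    if cfg.seg_variant == "multilayer":
        config = seg.multilayer_config(cfg.image_size, cfg.seg_base_filters)
    else:
        config = seg.vanilla_config(cfg.image_size, cfg.seg_base_filters)
    model = seg.build_unet(config, seed=0)
    model.load(path)
    return model


def _clf_inputs(cfg: PipelineConfig, seed_dir: Path, tags) -> tuple[np.ndarray, np.ndarray]:
    """Classification inputs: GM-masked slices (predicted masks when a
    segmenter is available, ground truth otherwise) or raw slices."""
    images, _, gm, labels = _load_split(seed_dir, tags)
    if not cfg.use_segmentation:
        return images, labels
    if (seed_dir / "seg_model.npz").exists() and cfg.seg_target == "gm":
        model = _load_seg_model(cfg, seed_dir)
        masks = seg.predict_mask(model, images)
    else:
        masks = gm
    return images * masks, labels


def _build_clf(cfg: PipelineConfig, seed: int):
    backbone = clf.SmallCNNBackbone(input_size=cfg.image_size,
                                    out_channels=cfg.backbone_channels, seed=seed)
    kernels = (3,) if cfg.single_scale else None
    head = clf.MultiScaleHead(cfg.backbone_channels,
                              clf.MultiScaleConfig(branch_channels=cfg.branch_channels),
                              seed=seed, kernel_sizes=kernels)
    return backbone, head


def _augment_training_set(cfg: PipelineConfig, x: np.ndarray, y: np.ndarray,
                          seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Expand each class of training inputs to the configured target count
    by random rotation+zoom (training split only, so nothing leaks)."""
    target = cfg.augment_target_per_class
    xs, ys = [], []
    for ci, cls in enumerate(clf.CLASSES):
        imgs = [im for im, l in zip(x, y) if l == cls]
        policy = pp.AugmentPolicy(cfg.rotation_limit, cfg.zoom_limit,
                                  seed=seed + 1000 + ci)
        aug = pp.augment_to_count(imgs, policy, max(target, len(imgs)))
        xs.extend(aug)
        ys.extend([cls] * len(aug))
    return np.stack(xs), np.array(ys)


def _stage_train_clf(cfg: PipelineConfig, seed_dir: Path, seed: int) -> dict:
    x_tr, y_tr = _clf_inputs(cfg, seed_dir, ["train"])
    if cfg.augment_target_per_class > 0:
        x_tr, y_tr = _augment_training_set(cfg, x_tr, y_tr, seed)
    backbone, head = _build_clf(cfg, seed)
    hcfg = clf.HeadTrainConfig(learning_rate=cfg.head_learning_rate,
                               batch_size=cfg.head_batch_size,
                               epochs=cfg.head_epochs, seed=seed)
    history = clf.train_head(backbone, head, (x_tr, y_tr), hcfg)
    arrays = {f"head_{i}": p.data for i, p in enumerate(head.params())}
    np.savez(seed_dir / "clf_artifacts.npz", **arrays)
    result = {"head_final_loss": history["loss"][-1]}
    if not cfg.end_to_end:
        f_tr = clf.multi_scale_forward(head, clf.extract_features(backbone, x_tr))
        scaler = clf.fit_scaler(f_tr)
        model, table = clf.grid_search_svm(clf.apply_scaler(scaler, f_tr), y_tr,
                                           seed=seed)
        table.to_csv(seed_dir / "svm_grid.csv", index=False)
        import pickle
        with open(seed_dir / "svm_model.pkl", "wb") as fh:
            pickle.dump({"model": model, "scaler": scaler}, fh)
        result["svm_best_kernel"] = model.kernel
        result["svm_best_C"] = model.C
    log.info("train-clf: head loss %.4f", result["head_final_loss"])
    return result


def _stage_evaluate(cfg: PipelineConfig, seed_dir: Path, seed: int) -> dict:
    metrics: dict = {}
    if (seed_dir / "seg_model.npz").exists():
        model = _load_seg_model(cfg, seed_dir)
        images, brain, gm, _ = _load_split(seed_dir, ["test"])
        target = gm if cfg.seg_target == "gm" else brain
        preds = seg.predict_mask(model, images)
        per = [seg.evaluate_segmentation(p, t) for p, t in zip(preds, target)]
        metrics["dice"] = float(np.mean([m.dice for m in per]))
        metrics["iou"] = float(np.mean([m.iou for m in per]))
        metrics["seg_accuracy"] = float(np.mean([m.accuracy for m in per]))
    _require(seed_dir, "clf_artifacts.npz")
    x_te, y_te = _clf_inputs(cfg, seed_dir, ["test"])
    backbone, head = _build_clf(cfg, seed)
    with np.load(seed_dir / "clf_artifacts.npz") as z:
        for i, p in enumerate(head.params()):
            p.data[...] = z[f"head_{i}"]
    fmaps = clf.extract_features(backbone, x_te)
    if cfg.end_to_end:
        logits = head.forward(fmaps, training=False)
        pred = np.array([clf.CLASSES[i] for i in logits.argmax(axis=1)])
        scores = logits
    else:
        import pickle
        with open(seed_dir / "svm_model.pkl", "rb") as fh:
            bundle = pickle.load(fh)
        f_te = clf.apply_scaler(bundle["scaler"],
                                clf.multi_scale_forward(head, fmaps))
        pred, scores = clf.svm_predict(bundle["model"], f_te)
    report = clf.evaluate_classifier(pred, y_te)
    metrics["accuracy"] = report.accuracy
    for cls, d in report.per_class.items():
        metrics[f"f1_{cls}"] = d["f1"]
    rocs = clf.roc_one_vs_rest(np.asarray(scores, dtype=np.float64), y_te,
                               classes=bundle["model"].classes_ if not cfg.end_to_end
                               else clf.CLASSES)
    for cls, r in rocs.items():
        if r is not None:
            metrics[f"auc_{cls}"] = r.auc
    (seed_dir / "metrics.json").write_text(json.dumps(metrics, indent=2, sort_keys=True))
    report.confusion.to_csv(seed_dir / "confusion.csv")
    log.info("evaluate: accuracy %.4f", metrics["accuracy"])
    return metrics


def _stage_explain(cfg: PipelineConfig, seed_dir: Path, seed: int) -> dict:
    _require(seed_dir, "clf_artifacts.npz")
    x_te, y_te = _clf_inputs(cfg, seed_dir, ["test"])
    backbone, head = _build_clf(cfg, seed)
    with np.load(seed_dir / "clf_artifacts.npz") as z:
        for i, p in enumerate(head.params()):
            p.data[...] = z[f"head_{i}"]
    model = xai.DifferentiableClassifier(backbone, head)
    maps, labels = [], []
    for cls in clf.CLASSES:
        idx = np.where(y_te == cls)[0][:cfg.explain_per_class]
        for i in idx:
            maps.append(xai.compute_saliency(model, x_te[i], cls))
            labels.append(cls)
    table = xai.region_quantification(maps, labels)
    table.to_csv(seed_dir / "saliency_regions.csv")
    # directional summary: saliency inside the GM ribbon vs background
    _, _, gm, _ = _load_split(seed_dir, ["test"])
    gm_means, bg_means = [], []
    k = 0
    for cls in clf.CLASSES:
        idx = np.where(y_te == cls)[0][:cfg.explain_per_class]
        for i in idx:
            m = maps[k]; k += 1
            gm_means.append(float(m[gm[i] == 1].mean()))
            bg_means.append(float(m[gm[i] == 0].mean()))
    result = {"gm_saliency": float(np.mean(gm_means)),
              "background_saliency": float(np.mean(bg_means))}
    (seed_dir / "saliency_summary.json").write_text(json.dumps(result, indent=2))
    log.info("explain: GM saliency %.4f vs background %.4f",
             result["gm_saliency"], result["background_saliency"])
    return result


_STAGE_FN = {
    "generate": _stage_generate,
    "preprocess": _stage_preprocess,
    "train-seg": _stage_train_seg,
    "train-clf": _stage_train_clf,
    "evaluate": _stage_evaluate,
    "explain": _stage_explain,
}

# metrics included in the cross-seed summary table when present
_SUMMARY_METRICS = ("accuracy", "dice", "iou", "f1_AD", "f1_CN", "f1_MCI",
                    "val_dice", "gm_saliency", "background_saliency")


def run_pipeline(config: PipelineConfig, stages=None,
                 run_dir: str | Path | None = None) -> dict:
    """Execute the requested stages (canonical order) for each repeat seed.

    Returns ``{"run_dir", "per_seed", "summary"}`` where ``summary`` is a
    DataFrame with a mean and std column per metric, also written to
    ``summary.csv`` in the run directory.
    """
    if stages is None:
        stages = list(STAGES)
    else:
        unknown = set(stages) - set(STAGES)
        if unknown:
            raise PipelineError(f"unknown stages {sorted(unknown)}")
        stages = [s for s in STAGES if s in set(stages)]
    if run_dir is None:
        run_dir = Path(config.out_root) / time.strftime("run-%Y%m%d-%H%M%S")
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    _setup_logging(run_dir)
    config.to_yaml(run_dir / "config.yaml")
    seeds = list(config.seeds[:config.run_repeats])
    per_seed: dict[int, dict] = {}
    for s in seeds:
        seed_dir = run_dir / f"seed-{s}"
        seed_dir.mkdir(exist_ok=True)
        set_global_seeds(s)
        log.info("=== seed %d: stages %s ===", s, stages)
        results: dict[str, dict] = {}
        for stage in stages:
            results[stage] = _STAGE_FN[stage](config, seed_dir, s)
        per_seed[s] = results
    rows = {}
    for metric in _SUMMARY_METRICS:
        vals = []
        for s in seeds:
            for stage_result in per_seed[s].values():
                if metric in stage_result:
                    vals.append(stage_result[metric])
        if vals:
            rows[metric] = {"mean": float(np.mean(vals)),
                            "std": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0}
    summary = pd.DataFrame(rows).T
    summary.index.name = "metric"
    summary.to_csv(run_dir / "summary.csv", float_format="%.10g")
    (run_dir / "report.json").write_text(json.dumps(
        {"seeds": seeds, "stages": stages,
         "per_seed": {str(k): v for k, v in per_seed.items()}},
        indent=2, sort_keys=True))
    return {"run_dir": str(run_dir), "per_seed": per_seed, "summary": summary}


def read_report(run_dir: str | Path) -> dict:
    """Round-trip reader for the JSON run report."""
    return json.loads((Path(run_dir) / "report.json").read_text())
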