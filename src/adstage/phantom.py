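"""Synthetic brain-slice phantoms with ground-truth brain and gray-matter masks.

A phantom emulates a 2D axial T1 slice as five concentric tissue regions —
background, skull rim, CSF, a gray-matter (GM) ribbon, and a white-matter
(WM) core — plus a central elliptical ventricle filled with CSF. The three
diagnostic stages differ in the two classic structural biomarkers of
Alzheimer's disease: the GM ribbon thins and dims from cognitively normal
(CN) through mild cognitive impairment (MCI) to Alzheimer's disease (AD),
while the ventricle enlarges. Every sample carries its exact ground-truth
masks, so segmentation and classification stages can be validated without
access to restricted clinical data.

Geometry is parameterised by fractions of the image side, so the same class
effects hold at any resolution; ``ring_radii`` exposes the resolved radii
for a given spec so they can be checked independently.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

CLASSES = ("AD", "CN", "MCI")

# Tissue intensities (normalized units). Ventricles are CSF-filled.
INTENSITY = {"background": 0.0, "skull": 0.90, "csf": 0.15, "wm": 0.80}

# Ring geometry as fractions of the image side.
SKULL_OUTER_FRAC = 0.46
SKULL_THICKNESS_FRAC = 0.04
CSF_THICKNESS_FRAC = 0.03

# Ventricle aspect ratio (y-radius / x-radius) of the central ellipse.
VENTRICLE_ASPECT = 0.60

_REFERENCE_SIZE = 224


class PhantomParameterError(ValueError):
    """Raised for invalid phantom generation parameters."""


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one phantom; identical specs yield identical samples."""

    class_label: str
    gm_thickness: float
    ventricle_radius: float
    gm_intensity: float = 0.50
    image_size: int = 224
    noise_sigma: float = 0.02
    jitter: float = 0.03
    seed: int = 0

    def __post_init__(self):
        if self.image_size < 32:
            raise PhantomParameterError("image_size must be >= 32")
        if self.class_label not in CLASSES:
            raise PhantomParameterError(f"class_label must be one of {CLASSES}")
        if self.gm_thickness <= 0:
            raise PhantomParameterError("gm_thickness must be positive")
        if not 0.0 <= self.gm_intensity <= 1.0:
            raise PhantomParameterError("gm_intensity must be in [0, 1]")
        if self.noise_sigma < 0:
            raise PhantomParameterError("noise_sigma must be non-negative")
        if self.jitter < 0:
            raise PhantomParameterError("jitter must be non-negative")
        if self.ventricle_radius < 0:
            raise PhantomParameterError("ventricle_radius must be non-negative")


@dataclass
class PhantomSample:
    image: np.ndarray        # float32 in [0, 1], (H, W)
    brain_mask: np.ndarray   # uint8 {0, 1}
    gm_mask: np.ndarray      # uint8 {0, 1}
    label: str
    meta: PhantomSpec


@dataclass
class ManifestRecord:
    id: str
    label: str
    split: str = "unassigned"
    image_path: str = ""
    brain_mask_path: str = ""
    gm_mask_path: str = ""


@dataclass
class DatasetManifest:
    records: list[ManifestRecord]
    seed: int

    def __post_init__(self):
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise PhantomParameterError("manifest record ids must be unique")
        for r in self.records:
            if r.label not in CLASSES:
                raise PhantomParameterError(f"unknown label {r.label!r}")

    @property
    def counts(self) -> dict[str, int]:
        out = {c: 0 for c in CLASSES}
        for r in self.records:
            out[r.label] += 1
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [dataclasses.asdict(r) for r in self.records],
            columns=["id", "image_path", "brain_mask_path", "gm_mask_path",
                     "label", "split"],
        )


def default_class_table(image_size: int = 224) -> dict[str, dict[str, float]]:
    """Per-class phantom parameters: GM thickness/intensity and ventricle radius.

    At the 224 px reference resolution the GM ribbon means are 9/7/5 px and the
    ventricle radii 6/8/11 px for CN/MCI/AD; other resolutions scale linearly
    (with floors so structures stay resolvable).
    """
    s = image_size / _REFERENCE_SIZE
    return {
        "CN": {"gm_thickness": max(9.0 * s, 2.0), "gm_intensity": 0.55,
               "ventricle_radius": max(6.0 * s, 1.5)},
        "MCI": {"gm_thickness": max(7.0 * s, 1.7), "gm_intensity": 0.50,
                "ventricle_radius": max(8.0 * s, 2.0)},
        "AD": {"gm_thickness": max(5.0 * s, 1.4), "gm_intensity": 0.45,
               "ventricle_radius": max(11.0 * s, 2.7)},
    }


def ring_radii(spec: PhantomSpec) -> dict[str, float]:
    """Resolved ring radii (pixels) for a spec, before per-sample jitter."""
    s = spec.image_size
    skull_outer = SKULL_OUTER_FRAC * s
    brain = skull_outer - SKULL_THICKNESS_FRAC * s   # inner skull = brain boundary
    gm_outer = brain - CSF_THICKNESS_FRAC * s
    gm_inner = gm_outer - spec.gm_thickness
    if gm_inner <= spec.ventricle_radius:
        raise PhantomParameterError("gm ring collides with the ventricle; "
                                    "reduce gm_thickness or ventricle_radius")
    return {"skull_outer": skull_outer, "brain": brain,
            "gm_outer": gm_outer, "gm_inner": gm_inner,
            "ventricle": spec.ventricle_radius}


def generate_phantom(spec: PhantomSpec) -> PhantomSample:
    """Rasterize one phantom slice with its ground-truth masks.

    Per-sample shape jitter scales the x/y axes of every ring independently
    and offsets the center; with ``jitter=0`` and ``noise_sigma=0`` the image
    is piecewise constant over the five tissue regions.
    """
    radii = ring_radii(spec)
    rng = np.random.default_rng(spec.seed)
    s = spec.image_size
    center = (s - 1) / 2.0

    if spec.jitter > 0:
        sx = 1.0 + spec.jitter * rng.uniform(-1, 1)
        sy = 1.0 + spec.jitter * rng.uniform(-1, 1)
        cx = center + spec.jitter * 0.1 * s * rng.uniform(-1, 1)
        cy = center + spec.jitter * 0.1 * s * rng.uniform(-1, 1)
    else:
        sx = sy = 1.0
        cx = cy = center

    yy, xx = np.mgrid[0:s, 0:s].astype(np.float64)
    # normalized elliptical radius: r2 <= R^2 is membership in the R-ring
    r2 = ((xx - cx) / sx) ** 2 + ((yy - cy) / sy) ** 2

    in_skull = r2 <= radii["skull_outer"] ** 2
    in_brain = r2 <= radii["brain"] ** 2
    in_gm_outer = r2 <= radii["gm_outer"] ** 2
    in_wm = r2 <= radii["gm_inner"] ** 2
    rv = radii["ventricle"]
    in_vent = (((xx - cx) / sx) ** 2 / max(rv, 1e-9) ** 2
               + ((yy - cy) / sy) ** 2 / max(rv * VENTRICLE_ASPECT, 1e-9) ** 2) <= 1.0
    if rv == 0:
        in_vent[:] = False

    image = np.full((s, s), INTENSITY["background"], dtype=np.float32)
    image[in_skull] = INTENSITY["skull"]
    image[in_brain] = INTENSITY["csf"]
    image[in_gm_outer] = spec.gm_intensity
    image[in_wm] = INTENSITY["wm"]
    image[in_vent & in_brain] = INTENSITY["csf"]

    brain_mask = in_brain.astype(np.uint8)
    gm_mask = (in_gm_outer & ~in_wm).astype(np.uint8)

    if spec.noise_sigma > 0:
        image = image + rng.normal(0.0, spec.noise_sigma, image.shape).astype(np.float32)
        image = np.clip(image, 0.0, 1.0)

    return PhantomSample(image=image.astype(np.float32), brain_mask=brain_mask,
                         gm_mask=gm_mask, label=spec.class_label, meta=spec)


def generate_dataset(
    n_per_class: int,
    class_param_table: dict[str, dict[str, float]] | None = None,
    seed: int = 0,
    image_size: int = 224,
    noise_sigma: float = 0.02,
    jitter: float = 0.03,
) -> tuple[DatasetManifest, dict[str, PhantomSample]]:
    """Generate ``3 * n_per_class`` phantoms, ``n_per_class`` per diagnostic class.

    Per-sample seeds are ``seed + record_index`` so any record can be
    regenerated without replaying the whole dataset. Returns the manifest and
    a dict mapping record id to its in-memory sample; use ``save_dataset`` to
    materialize both to disk.
    """
    if n_per_class < 1:
        raise PhantomParameterError("n_per_class must be >= 1")
    table = class_param_table or default_class_table(image_size)
    records: list[ManifestRecord] = []
    samples: dict[str, PhantomSample] = {}
    index = 0
    for label in CLASSES:
        params = table[label]
        for i in range(n_per_class):
            rid = f"{label}_{i:05d}"
            spec = PhantomSpec(
                class_label=label,
                gm_thickness=params["gm_thickness"],
                gm_intensity=params.get("gm_intensity", 0.5),
                ventricle_radius=params["ventricle_radius"],
                image_size=image_size,
                noise_sigma=noise_sigma,
                jitter=jitter,
                seed=seed + index,
            )
            samples[rid] = generate_phantom(spec)
            records.append(ManifestRecord(id=rid, label=label))
            index += 1
    return DatasetManifest(records=records, seed=seed), samples


def save_dataset(manifest: DatasetManifest, samples: dict[str, PhantomSample],
                 out_dir: str | Path, fmt: str = "png") -> Path:
    """Write images and masks (PNG 8-bit or single-slice NIfTI), the CSV
    manifest, and a JSON sidecar with the generation parameters. Returns the
    manifest CSV path."""
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(exist_ok=True)
    for rec in manifest.records:
        sample = samples[rec.id]
        if fmt == "png":
            rec.image_path = str(out / "images" / f"{rec.id}.png")
            iio.imwrite(rec.image_path,
                        np.round(sample.image * 255).astype(np.uint8))
        elif fmt == "nifti":
            import nibabel as nib
            rec.image_path = str(out / "images" / f"{rec.id}.nii.gz")
            nib.save(nib.Nifti1Image(sample.image[..., None], np.eye(4)),
                     rec.image_path)
        else:
            raise PhantomParameterError(f"unknown format {fmt!r}")
        rec.brain_mask_path = str(out / "masks" / f"{rec.id}_brain.png")
        rec.gm_mask_path = str(out / "masks" / f"{rec.id}_gm.png")
        iio.imwrite(rec.brain_mask_path, sample.brain_mask * 255)
        iio.imwrite(rec.gm_mask_path, sample.gm_mask * 255)
    csv_path = out / "manifest.csv"
    manifest.to_frame().to_csv(csv_path, index=False)
    sidecar = {
        "seed": manifest.seed,
        "counts": manifest.counts,
        "format": fmt,
        "specs": {rec.id: dataclasses.asdict(samples[rec.id].meta)
                  for rec in manifest.records},
    }
    (out / "manifest.json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    return csv_path


def load_mask(path: str | Path) -> np.ndarray:
    """Read a {0,255} PNG mask back to {0,1} uint8."""
    return (np.asarray(iio.imread(path)) > 127).astype(np.uint8)


def load_image(path: str | Path) -> np.ndarray:
    """Read a slice image (PNG or NIfTI) back to float32 in [0,1]."""
    p = str(path)
    if p.endswith(".nii") or p.endswith(".nii.gz"):
        import nibabel as nib
        data = np.asanyarray(nib.load(p).dataobj).squeeze()
        return data.astype(np.float32)
    arr = np.asarray(iio.imread(p)).astype(np.float32)
    return arr / 255.0
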