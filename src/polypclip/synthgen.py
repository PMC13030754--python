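"""Procedural synthetic endoscopy-like corpus generator.

Produces three visually distinguishable lesion-texture classes on a shared
endoscopic canvas so every downstream stage (augmentation, prompting, losses,
training) is testable without any external data:

* ``adenoma`` — a raised mucosal blob carrying low-frequency lobulated bumps,
  the procedural stand-in for tubular/villous surface architecture;
* ``hyperplasia`` — the same raised blob carrying high-frequency serrated
  (triangular-wave) ridges, the stand-in for "saw-tooth" crypts;
* ``normal`` — smooth mucosa with only a gentle radial gradient.

All classes share an endoscopic vignette and 1-3 specular highlight spots.
Phase/position offsets are drawn once per patient and shared across that
patient's images, so images cluster by patient the way repeated frames of one
lesion do; per-image jitter and sensor noise keep them non-identical.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .corpus import CLASSES, ImageSample

__all__ = [
    "SyntheticConfig",
    "table_shape_config",
    "render_image",
    "generate_dataset",
    "write_dataset",
]

# class-conditional texture frequencies (cycles per image width); the wide
# separation forces the hyperplasia > adenoma > normal high-band FFT ordering
_BUMP_FREQ = (2.5, 4.0)  # adenoma: low-frequency lobules
_BUMP_DETAIL_FREQ = 7.5  # adenoma: faint granularity on the lobulated surface
_SERRATION_FREQ = (12.0, 16.0)  # hyperplasia: fine serrated ridges

_PATHOLOGY_TEXT = {
    "adenoma": "Biopsy: tubular adenoma with low-grade intraepithelial neoplasia.",
    "hyperplasia": "Biopsy: hyperplastic polyp with serrated crypt architecture.",
    "normal": "Biopsy: unremarkable colonic mucosa with regular crypts.",
}


@dataclass
class SyntheticConfig:
    """Shape and appearance of a generated corpus.

    Defaults give a desk-scale training corpus: 30 patients per class with 5
    images each at 64 x 64 — large enough for patient-level five-fold splits,
    small enough to train the bundled tiny backbone in seconds.
    """

    patients_per_class: tuple[int, int, int] = (30, 30, 30)
    images_per_patient: int | tuple[int, int] = 5
    image_size: int = 64
    texture_strength: float = 0.8
    label_noise: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if any(n < 1 for n in self.patients_per_class):
            raise ValueError("patients_per_class entries must be >= 1")
        if self.image_size < 32:
            raise ValueError("image_size must be >= 32")
        if not 0.0 <= self.texture_strength <= 1.0:
            raise ValueError("texture_strength must lie in [0, 1]")
        if not 0.0 <= self.label_noise < 1.0:
            raise ValueError("label_noise must lie in [0, 1)")
        if isinstance(self.images_per_patient, tuple):
            lo, hi = self.images_per_patient
            if lo < 1 or hi < lo:
                raise ValueError("invalid images_per_patient range")
        elif self.images_per_patient < 1:
            raise ValueError("images_per_patient must be >= 1")


def table_shape_config(seed: int = 0, image_size: int = 64) -> SyntheticConfig:
    """A corpus shaped like the study dataset: 39/36/16 patients per class.

    Combined with :func:`generate_dataset`'s per-class sample quotas this
    yields 154 adenoma, 147 hyperplasia and 88 normal images over 91 patients.
    """
    cfg = SyntheticConfig(
        patients_per_class=(39, 36, 16),
        images_per_patient=1,  # placeholder; quotas below drive the counts
        image_size=image_size,
        seed=seed,
    )
    cfg.samples_per_class = (154, 147, 88)  # type: ignore[attr-defined]
    return cfg


def _patient_appearance(rng: np.random.Generator) -> dict:
    """Latent appearance parameters shared by all images of one patient."""
    return {
        "blob_center": rng.uniform(-0.25, 0.25, size=2),
        "blob_radius": rng.uniform(0.45, 0.6),
        "phase": rng.uniform(0, 2 * np.pi, size=2),
        "orientation": rng.uniform(0, np.pi),
        "freq_jitter": rng.uniform(0.9, 1.1),
        "hue_jitter": rng.uniform(-0.03, 0.03, size=3),
    }


def render_image(
    label: str,
    rng: np.random.Generator,
    config: SyntheticConfig,
    appearance: dict | None = None,
) -> np.ndarray:
    """Render one H x W x 3 frame in [0, 1] for the given class.

    ``appearance`` carries the per-patient latent offsets; when omitted, a
    fresh patient appearance is drawn from ``rng``.
    """
    if label not in CLASSES:
        raise ValueError(f"unknown label {label!r}; allowed: {list(CLASSES)}")
    if appearance is None:
        appearance = _patient_appearance(rng)
    n = config.image_size
    yy0, xx0 = np.meshgrid(np.linspace(-1, 1, n), np.linspace(-1, 1, n), indexing="ij")
    # per-image probe motion: the mucosa frame tilts slightly between frames
    # of one lesion, while the vignette and highlights stay fixed to the lens;
    # consecutive frames of a lesion are near-duplicates, patients differ a lot
    tilt = rng.uniform(-np.pi / 60, np.pi / 60)
    xx = xx0 * np.cos(tilt) - yy0 * np.sin(tilt)
    yy = xx0 * np.sin(tilt) + yy0 * np.cos(tilt)

    # per-image jitter on top of the patient appearance
    cx, cy = appearance["blob_center"] + rng.uniform(-0.02, 0.02, size=2)
    r2 = (xx - cx) ** 2 + (yy - cy) ** 2
    blob = np.exp(-r2 / (2 * appearance["blob_radius"] ** 2))

    # base mucosa color with a gentle illumination gradient
    base = np.array([0.78, 0.52, 0.46]) + appearance["hue_jitter"]
    img = np.empty((n, n, 3))
    grad = 0.12 * (1 - np.sqrt(xx**2 + yy**2) / np.sqrt(2))
    for c in range(3):
        img[:, :, c] = base[c] + grad

    strength = config.texture_strength
    ang = appearance["orientation"]
    u = xx * np.cos(ang) + yy * np.sin(ang)
    v = -xx * np.sin(ang) + yy * np.cos(ang)
    # lesion classes are raised and tinted the way they present endoscopically:
    # adenomas redder and vascular, hyperplastic polyps pale/translucent
    tint = np.zeros(3)
    if label == "adenoma":
        f1, f2 = (f * appearance["freq_jitter"] for f in _BUMP_FREQ)
        lobules = 0.5 * np.sin(np.pi * f1 * u + appearance["phase"][0]) + 0.5 * np.sin(
            np.pi * f2 * v + appearance["phase"][1]
        )
        f3 = _BUMP_DETAIL_FREQ * appearance["freq_jitter"]
        lobules += 0.55 * np.sin(np.pi * f3 * v + appearance["phase"][0])
        relief = 0.22 * strength * lobules * blob + 0.15 * strength * blob
        tint = strength * np.array([0.08, -0.06, -0.05])
    elif label == "hyperplasia":
        f1, f2 = (f * appearance["freq_jitter"] for f in _SERRATION_FREQ)
        # triangular wave = serrated "saw-tooth" profile
        saw = 2 * np.abs(((f1 * u + appearance["phase"][0] / np.pi) % 1.0) - 0.5) - 0.5
        saw2 = np.sin(np.pi * f2 * v + appearance["phase"][1])
        relief = 0.20 * strength * (saw + 0.4 * saw2) * blob + 0.15 * strength * blob
        tint = strength * np.array([0.06, 0.09, 0.10])
    else:  # normal mucosa: smooth, no lesion relief
        relief = 0.05 * strength * (1 - np.sqrt(r2))

    for c, relief_tint in enumerate((1.0, 0.75, 0.7)):
        img[:, :, c] += relief * relief_tint + tint[c] * blob

    # per-frame illumination drift
    img *= rng.uniform(0.92, 1.08)

    # endoscopic vignette (lens-fixed frame)
    rr = np.sqrt(xx0**2 + yy0**2) / np.sqrt(2)
    img *= (1 - 0.55 * rr**4)[:, :, None]

    # 1-3 specular highlight spots
    for _ in range(int(rng.integers(1, 4))):
        hx, hy = rng.uniform(-0.7, 0.7, size=2)
        hr = rng.uniform(0.04, 0.08)
        spot = np.exp(-((xx0 - hx) ** 2 + (yy0 - hy) ** 2) / (2 * hr**2))
        img += 0.6 * spot[:, :, None]

    img += rng.normal(0, 0.01, size=img.shape)  # sensor noise
    return np.clip(img, 0.0, 1.0)


def _images_per_patient_counts(
    config: SyntheticConfig, n_patients: int, rng: np.random.Generator, cls_idx: int
) -> list[int]:
    quotas = getattr(config, "samples_per_class", None)
    if quotas is not None:
        total = quotas[cls_idx]
        base, extra = divmod(total, n_patients)
        return [base + 1 if i < extra else base for i in range(n_patients)]
    ipp = config.images_per_patient
    if isinstance(ipp, tuple):
        return [int(rng.integers(ipp[0], ipp[1] + 1)) for _ in range(n_patients)]
    return [int(ipp)] * n_patients


def generate_dataset(
    config: SyntheticConfig,
) -> tuple[list[ImageSample], pd.DataFrame]:
    """Generate a full corpus and its metadata table.

    Returns samples (in metadata row order) and a DataFrame with columns
    ``filename, label, patient_id, text, true_label``; ``true_label`` records
    provenance when ``label_noise`` flips a recorded label.
    """
    rng = np.random.default_rng(config.seed)
    samples: list[ImageSample] = []
    rows: list[dict] = []
    pid = 0
    for cls_idx, (cls, n_pat) in enumerate(zip(CLASSES, config.patients_per_class)):
        counts = _images_per_patient_counts(config, n_pat, rng, cls_idx)
        for p in range(n_pat):
            pid += 1
            patient_id = f"P{pid:03d}"
            appearance = _patient_appearance(rng)
            for k in range(counts[p]):
                img = render_image(cls, rng, config, appearance=appearance)
                fname = f"{patient_id}_{k:02d}.png"
                rows.append(
                    {
                        "filename": fname,
                        "label": cls,
                        "patient_id": patient_id,
                        "text": _PATHOLOGY_TEXT[cls],
                        "true_label": cls,
                    }
                )
                samples.append(
                    ImageSample(
                        image=img, label=cls, patient_id=patient_id,
                        text=_PATHOLOGY_TEXT[cls],
                    )
                )
    # label noise: flip a fraction of recorded labels to a different class
    if config.label_noise > 0:
        n_flip = int(round(config.label_noise * len(rows)))
        flip_idx = rng.choice(len(rows), size=n_flip, replace=False)
        for i in flip_idx:
            others = [c for c in CLASSES if c != rows[i]["true_label"]]
            new = others[int(rng.integers(len(others)))]
            rows[i]["label"] = new
            samples[i].label = new
    return samples, pd.DataFrame(rows)


def write_dataset(
    samples: list[ImageSample], metadata: pd.DataFrame, out_dir: str | Path
) -> Path:
    """Write PNG images plus ``metadata.tsv`` readable by ``corpus.load_dataset``."""
    out_dir = Path(out_dir)
    img_dir = out_dir / "images"
    img_dir.mkdir(parents=True, exist_ok=True)
    for sample, fname in zip(samples, metadata["filename"]):
        arr = (np.clip(sample.image, 0, 1) * 255).round().astype(np.uint8)
        Image.fromarray(arr).save(img_dir / fname)
    tsv = out_dir / "metadata.tsv"
    metadata.to_csv(tsv, sep="\t", index=False)
    return tsv
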