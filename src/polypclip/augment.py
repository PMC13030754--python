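"""Medical-aware augmentation: constrained affine geometry + photometric dither.

Geometry simulates endoscope probe motion with a similarity transform about
the image center — scale s ~ U(0.9, 1.1), tilt theta ~ U(-15deg, +15deg),
translation tx, ty ~ U(-0.1w, +0.1w) — ranges tight enough that the central
pathological structure stays in frame. Photometry simulates light-source
color-temperature drift with channel-separated gain/bias:
out_c = clip(beta_c * in_c + gamma_c, 0, 1), beta_c ~ U(0.9, 1.1),
gamma_c ~ U(-0.1, +0.1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage.transform import AffineTransform, resize, warp

from .corpus import ImageSample

__all__ = [
    "AffineParams",
    "PhotometricParams",
    "AugmentConfig",
    "sample_affine",
    "apply_affine",
    "sample_photometric",
    "apply_photometric",
    "augment_sample",
]


@dataclass(frozen=True)
class AffineParams:
    """Similarity-transform parameters: scale, rotation (radians), translation (px)."""

    s: float
    theta: float
    tx: float
    ty: float

    def __post_init__(self):
        for v in (self.s, self.theta, self.tx, self.ty):
            if not math.isfinite(v):
                raise ValueError("affine parameters must be finite")


@dataclass(frozen=True)
class PhotometricParams:
    """Per-RGB-channel multiplicative gain (beta) and additive bias (gamma)."""

    beta: tuple[float, float, float]
    gamma: tuple[float, float, float]

    def __post_init__(self):
        if len(self.beta) != 3 or len(self.gamma) != 3:
            raise ValueError("beta and gamma must have 3 channels")
        for v in (*self.beta, *self.gamma):
            if not math.isfinite(v):
                raise ValueError("photometric parameters must be finite")


@dataclass
class AugmentConfig:
    """Sampling ranges and geometric options; defaults are the clinical ranges."""

    scale_range: tuple[float, float] = (0.9, 1.1)
    angle_range_deg: tuple[float, float] = (-15.0, 15.0)
    translate_frac: float = 0.1  # of image width, both axes
    beta_range: tuple[float, float] = (0.9, 1.1)
    gamma_range: tuple[float, float] = (-0.1, 0.1)
    crop_valid_region: bool = False  # central crop to always-valid region, then resize
    fill_mode: str = "edge"  # out-of-canvas fill: nearest-edge replication

    @classmethod
    def identity(cls) -> "AugmentConfig":
        """Degenerate ranges that make augmentation a no-op (for testing)."""
        return cls(
            scale_range=(1.0, 1.0),
            angle_range_deg=(0.0, 0.0),
            translate_frac=0.0,
            beta_range=(1.0, 1.0),
            gamma_range=(0.0, 0.0),
        )


def sample_affine(
    rng: np.random.Generator, width: int, config: AugmentConfig | None = None
) -> AffineParams:
    """Draw affine parameters uniformly from the configured ranges."""
    if width <= 0:
        raise ValueError("width must be positive")
    cfg = config or AugmentConfig()
    t = cfg.translate_frac * width
    return AffineParams(
        s=float(rng.uniform(*cfg.scale_range)),
        theta=float(np.deg2rad(rng.uniform(*cfg.angle_range_deg))),
        tx=float(rng.uniform(-t, t)),
        ty=float(rng.uniform(-t, t)),
    )


def sample_photometric(
    rng: np.random.Generator, config: AugmentConfig | None = None
) -> PhotometricParams:
    """Draw per-channel gain/bias uniformly from the configured ranges."""
    cfg = config or AugmentConfig()
    return PhotometricParams(
        beta=tuple(float(rng.uniform(*cfg.beta_range)) for _ in range(3)),
        gamma=tuple(float(rng.uniform(*cfg.gamma_range)) for _ in range(3)),
    )


def _max_valid_crop_fraction(cfg: AugmentConfig) -> float:
    """Half-width fraction of the square region valid under every legal transform."""
    s_min = cfg.scale_range[0]
    a_max = math.radians(max(abs(a) for a in cfg.angle_range_deg))
    # worst case: minimum zoom, maximum tilt, maximum translation
    shrink = s_min / (abs(math.cos(a_max)) + abs(math.sin(a_max)))
    return max(shrink - 2 * cfg.translate_frac, 0.2)


def apply_affine(
    image: np.ndarray, params: AffineParams, config: AugmentConfig | None = None
) -> np.ndarray:
    """Warp by the scale-rotation-translation matrix about the image center.

    Bilinear interpolation; out-of-canvas samples are filled by nearest-edge
    replication (black borders would be a strong artificial cue absent from
    real endoscopy). With ``crop_valid_region`` the central always-valid square
    is cropped and resized back to the input size.
    """
    image = np.asarray(image, dtype=np.float64)
    cfg = config or AugmentConfig()
    h, w = image.shape[:2]
    center = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    fwd = (
        AffineTransform(translation=-center)
        + AffineTransform(scale=params.s, rotation=params.theta)
        + AffineTransform(translation=center + (params.tx, params.ty))
    )
    out = warp(image, fwd.inverse, order=1, mode=cfg.fill_mode, preserve_range=True)
    if cfg.crop_valid_region:
        frac = _max_valid_crop_fraction(cfg)
        half_h, half_w = int(h / 2 * frac), int(w / 2 * frac)
        ch, cw = h // 2, w // 2
        crop = out[ch - half_h : ch + half_h, cw - half_w : cw + half_w]
        out = resize(crop, image.shape, order=1, preserve_range=True, anti_aliasing=False)
    return np.clip(out, 0.0, 1.0)


def apply_photometric(image: np.ndarray, params: PhotometricParams) -> np.ndarray:
    """Channel-separated gain/bias, clipped back to [0, 1]."""
    image = np.asarray(image, dtype=np.float64)
    beta = np.asarray(params.beta)[None, None, :]
    gamma = np.asarray(params.gamma)[None, None, :]
    return np.clip(beta * image + gamma, 0.0, 1.0)


def augment_sample(
    sample: ImageSample,
    rng: np.random.Generator,
    config: AugmentConfig | None = None,
) -> ImageSample:
    """Fresh affine-then-photometric perturbation; metadata is untouched."""
    cfg = config or AugmentConfig()
    w = sample.image.shape[1]
    aff = sample_affine(rng, w, cfg)
    photo = sample_photometric(rng, cfg)
    img = apply_photometric(apply_affine(sample.image, aff, cfg), photo)
    return ImageSample(
        image=img,
        label=sample.label,
        patient_id=sample.patient_id,
        text=sample.text,
        source_path=sample.source_path,
    )
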