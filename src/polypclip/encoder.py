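"""Backbone-agnostic dual-encoder contract.

The training framework only requires that an image backbone map a batch of
frames to unit-normalized D-dimensional embeddings with a controllable number
of trainable blocks, and that a text backbone map prompt strings to
unit-normalized embeddings (frozen by default, mirroring the practice of
keeping a pretrained text encoder fixed during fine-tuning). Backbones are
looked up in a plugin registry by identifier, so a large pretrained
vision-language model can be dropped in behind the same contract.

Two implementations ship with the package:

* ``tiny_cnn`` — a small trainable patch-embedding network (a strided
  convolutional patchify realized as a reshape + linear map, ReLU, mean
  pooling over patches, and a linear output layer). Two blocks; the freeze
  policy trains only the deepest ``image_trainable_depth`` of them.
* ``class_embedding_table`` — maps each distinct prompt string to a fixed
  random unit vector (deterministic per string and seed). Class-level prompts
  make this a table of class anchors in the shared space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from hashlib import sha256

import numpy as np

from ._autodiff import Tensor, l2_normalize_rows
from .losses import ClassifierHead

__all__ = [
    "EncoderSpec",
    "TinyPatchNet",
    "ClassEmbeddingTable",
    "DualEncoder",
    "classify",
    "register_image_backbone",
    "register_text_backbone",
]

_IMAGE_BACKBONES: dict[str, type] = {}
_TEXT_BACKBONES: dict[str, type] = {}


def register_image_backbone(name: str, factory: type) -> None:
    _IMAGE_BACKBONES[name] = factory


def register_text_backbone(name: str, factory: type) -> None:
    _TEXT_BACKBONES[name] = factory


@dataclass
class EncoderSpec:
    """Which backbones to build and how deep fine-tuning may reach."""

    image_backbone: str = "tiny_cnn"
    text_backbone: str = "class_embedding_table"
    embed_dim: int = 32
    hidden_dim: int = 48
    freeze_text: bool = True
    image_trainable_depth: int = 2  # number of deepest trainable blocks

    def __post_init__(self):
        if self.embed_dim < 2:
            raise ValueError("embed_dim must be >= 2")
        if self.image_backbone not in _IMAGE_BACKBONES:
            raise ValueError(
                f"unknown image backbone {self.image_backbone!r}; "
                f"registered: {sorted(_IMAGE_BACKBONES)}"
            )
        if self.text_backbone not in _TEXT_BACKBONES:
            raise ValueError(
                f"unknown text backbone {self.text_backbone!r}; "
                f"registered: {sorted(_TEXT_BACKBONES)}"
            )


class TinyPatchNet:
    """Patch-embed -> ReLU -> mean-pool -> linear head, on the autodiff core.

    Block 1 is the patch embedding (a stride-equals-kernel convolution written
    as reshape + matmul over an 8 x 8 grid of patches); block 2 is the output
    projection. Each patch is contrast-standardized per channel before
    embedding (local contrast normalization), which makes the texture features
    largely invariant to illumination gain/bias; the per-patch channel means
    and standard deviations are appended so color and contrast remain
    available as explicit features. ReLU responses mean-pooled over patches
    give a translation-tolerant texture-energy summary, which is what
    separates lesion surface patterns.
    """

    n_blocks = 2

    def __init__(self, spec: EncoderSpec, image_size: int, rng: np.random.Generator):
        if image_size % 8 != 0:
            raise ValueError("image_size must be a multiple of 8")
        self.image_size = image_size
        self.patch = image_size // 8
        f_in = self.patch * self.patch * 3 + 6  # standardized pixels + mean/std per channel
        h, d = spec.hidden_dim, spec.embed_dim
        trainable = spec.image_trainable_depth
        # He-style init scaled for the ReLU layer
        self.W1 = Tensor(
            rng.normal(0, np.sqrt(2.0 / f_in), size=(f_in, h)),
            requires_grad=trainable >= 2,
        )
        self.b1 = Tensor(np.zeros(h), requires_grad=trainable >= 2)
        self.W2 = Tensor(
            rng.normal(0, np.sqrt(1.0 / h), size=(h, d)),
            requires_grad=trainable >= 1,
        )
        self.b2 = Tensor(np.zeros(d), requires_grad=trainable >= 1)

    @property
    def params(self) -> list[Tensor]:
        return [self.W1, self.b1, self.W2, self.b2]

    def _patchify(self, images: np.ndarray) -> np.ndarray:
        n, h, w, _ = images.shape
        p = self.patch
        x = images.reshape(n, 8, p, 8, p, 3)
        x = x.transpose(0, 1, 3, 2, 4, 5).reshape(n, 64, p * p, 3)
        mean = x.mean(axis=2, keepdims=True)
        std = x.std(axis=2, keepdims=True)
        standardized = (x - mean) / (std + 1e-5)
        return np.concatenate(
            [
                standardized.reshape(n, 64, p * p * 3),
                mean.reshape(n, 64, 3),
                std.reshape(n, 64, 3),
            ],
            axis=2,
        )

    def forward(self, images: np.ndarray) -> Tensor:
        """N x H x W x 3 in [0, 1] -> unit-normalized N x D embeddings."""
        images = np.asarray(images, dtype=np.float64)
        if images.ndim != 4 or images.shape[1:3] != (self.image_size,) * 2:
            raise ValueError(
                f"expected N x {self.image_size} x {self.image_size} x 3 images, "
                f"got shape {images.shape}"
            )
        n = images.shape[0]
        patches = self._patchify((images - 0.5) * 2.0)  # center the dynamic range
        x = Tensor(patches.reshape(n * 64, -1))
        hid = (x @ self.W1 + self.b1).relu()
        pooled = hid.reshape(n, 64, -1).mean(axis=1)
        out = pooled @ self.W2 + self.b2
        return l2_normalize_rows(out)


class ClassEmbeddingTable:
    """Deterministic bag-of-tokens random-feature embedding per prompt string.

    Every whitespace token maps to a fixed random Gaussian vector (seeded by
    the table seed and the SHA-256 of the token); a prompt embeds as the
    normalized mean of its token vectors. Identical strings therefore always
    map to identical rows, and prompts sharing boilerplate ("A photo of ...")
    produce correlated anchors while prompts rich in distinct clinical
    vocabulary produce near-orthogonal ones — the geometric reason structured
    clinical templates out-separate generic class names in this harness.
    Frozen by default; a trainable variant promotes each row to a parameter.
    """

    def __init__(self, spec: EncoderSpec, rng: np.random.Generator):
        self.embed_dim = spec.embed_dim
        self.frozen = spec.freeze_text
        self.seed = int(rng.integers(0, 2**31))
        self._cache: dict[str, Tensor] = {}

    def _token_vector(self, token: str) -> np.ndarray:
        digest = int.from_bytes(sha256(token.encode("utf-8")).digest()[:8], "big")
        sub = np.random.default_rng(np.random.SeedSequence([self.seed, digest]))
        return sub.normal(size=self.embed_dim)

    def _vector(self, prompt: str) -> np.ndarray:
        tokens = prompt.split() or [prompt]
        v = np.mean([self._token_vector(t) for t in tokens], axis=0)
        return v / np.linalg.norm(v)

    def _row(self, prompt: str) -> Tensor:
        if prompt not in self._cache:
            self._cache[prompt] = Tensor(
                self._vector(prompt), requires_grad=not self.frozen
            )
        return self._cache[prompt]

    @property
    def params(self) -> list[Tensor]:
        return [] if self.frozen else list(self._cache.values())

    def forward(self, prompts: list[str]) -> Tensor:
        """M prompt strings -> unit-normalized M x D embeddings."""
        if not prompts:
            raise ValueError("prompts must be non-empty")
        rows = [self._row(p) for p in prompts]
        stacked = np.stack([r.data for r in rows])
        if self.frozen:
            return Tensor(stacked)
        # differentiable stack: sum of padded rows keeps the graph connected
        out = Tensor(np.zeros((len(rows), self.embed_dim)))
        for i, r in enumerate(rows):
            mask = np.zeros((len(rows), 1))
            mask[i] = 1.0
            out = out + Tensor(mask) * r.reshape(1, -1)
        return l2_normalize_rows(out)


register_image_backbone("tiny_cnn", TinyPatchNet)
register_text_backbone("class_embedding_table", ClassEmbeddingTable)


@dataclass
class DualEncoder:
    """The paired image/text encoders plus the linear ID head."""

    spec: EncoderSpec
    image_net: object
    text_net: object
    head_W: Tensor = field(repr=False, default=None)
    head_b: Tensor = field(repr=False, default=None)

    @classmethod
    def build(
        cls, spec: EncoderSpec, image_size: int, n_classes: int,
        rng: np.random.Generator,
    ) -> "DualEncoder":
        image_net = _IMAGE_BACKBONES[spec.image_backbone](spec, image_size, rng)
        text_net = _TEXT_BACKBONES[spec.text_backbone](spec, rng)
        head_W = Tensor(
            rng.normal(0, 0.01, size=(spec.embed_dim, n_classes)), requires_grad=True
        )
        head_b = Tensor(np.zeros(n_classes), requires_grad=True)
        return cls(spec, image_net, text_net, head_W, head_b)

    @property
    def trainable_params(self) -> list[Tensor]:
        return [
            p
            for p in (*self.image_net.params, *self.text_net.params,
                      self.head_W, self.head_b)
            if p.requires_grad
        ]

    def encode_images(self, images: np.ndarray) -> Tensor:
        return self.image_net.forward(images)

    def encode_texts(self, prompts: list[str]) -> Tensor:
        return self.text_net.forward(prompts)

    def embed_images(self, images: np.ndarray) -> np.ndarray:
        """Numpy convenience wrapper (no gradient tracking needed by callers)."""
        return self.encode_images(images).data

    def embed_texts(self, prompts: list[str]) -> np.ndarray:
        return self.encode_texts(prompts).data

    @property
    def head(self) -> ClassifierHead:
        return ClassifierHead(W=self.head_W.data.copy(), b=self.head_b.data.copy())


def classify(
    image_embeddings: np.ndarray,
    class_prompt_embeddings: np.ndarray | None = None,
    head: ClassifierHead | None = None,
    rule: str = "similarity",
) -> np.ndarray:
    """Predict class indices by prompt similarity or by the ID head.

    ``similarity`` takes the argmax over classes of cosine(v_i, t_class);
    ``id_head`` takes the argmax of the linear head logits. Ties break to the
    lowest class index (numpy argmax order), deterministically.
    """
    V = np.asarray(image_embeddings, dtype=np.float64)
    if rule == "similarity":
        if class_prompt_embeddings is None:
            raise ValueError("similarity rule requires class prompt embeddings")
        sims = V @ np.asarray(class_prompt_embeddings, dtype=np.float64).T
        return np.argmax(sims, axis=1)
    if rule == "id_head":
        if head is None:
            raise ValueError("id_head rule requires a trained classifier head")
        logits = V @ head.W + head.b
        return np.argmax(logits, axis=1)
    raise ValueError(f"unknown inference rule {rule!r}")
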