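"""Training objectives for dual-encoder image-text alignment.

Three families, all over an N x N cosine-similarity matrix of unit-normalized
image embeddings V and text embeddings T at temperature tau:

* **InfoNCE** — the symmetric instance-level contrastive loss: the mean of the
  image-to-text and text-to-image softmax cross-entropies with the matched
  pair of each sample (the diagonal) as its only positive.
* **Cross-modal projection matching (CMPM)** — two selectable forms. The
  ``instance_softmax`` form is the per-direction diagonal-positive softmax
  cross-entropy, averaged over both directions. The ``label_aware_kl`` form
  (default) replaces the one-hot diagonal target with a normalized
  ground-truth match distribution q that spreads equal mass over every
  same-class column, and minimizes KL(p || q + eps) per direction. Two frames
  of the same polyp subtype therefore count as positives rather than
  negatives, which is the point: instance-level contrast is suboptimal when
  class-level compactness is what matters.
* **ID loss** — per-class softmax cross-entropy of a linear head on the image
  embeddings, enforcing intra-class compactness in the visual space.

The total objective is the (by default unweighted) sum of CMPM and ID.

Every public function accepts an :class:`EmbeddingBatch` of numpy arrays and
returns a float; the ``*_graph`` variants operate on autodiff tensors and are
what the trainer differentiates through.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autodiff import Tensor, as_tensor, log_softmax

__all__ = [
    "EmbeddingBatch",
    "ClassifierHead",
    "LossBreakdown",
    "infonce_loss",
    "cmpm_loss",
    "id_loss",
    "total_loss",
    "match_distribution",
    "infonce_graph",
    "cmpm_graph",
    "id_graph",
]

#: stabilizer added to the match distribution inside the KL logarithm
CMPM_EPS = 1e-8


@dataclass
class EmbeddingBatch:
    """Paired unit-normalized image/text embeddings with labels and temperature."""

    V: np.ndarray  # N x D image embeddings
    T: np.ndarray  # N x D text embeddings
    labels: np.ndarray  # N integer class ids
    tau: float = 0.02

    def __post_init__(self):
        self.V = np.asarray(self.V, dtype=np.float64)
        self.T = np.asarray(self.T, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.V.ndim != 2 or self.V.shape != self.T.shape:
            raise ValueError("V and T must be N x D matrices of equal shape")
        if len(self.labels) != self.V.shape[0]:
            raise ValueError("labels length must match batch size")
        if self.V.shape[0] < 1:
            raise ValueError("batch must contain at least one pair")
        if self.tau <= 0:
            raise ValueError("temperature tau must be positive")
        for name, mat in (("V", self.V), ("T", self.T)):
            norms = np.linalg.norm(mat, axis=1)
            if np.abs(norms - 1.0).max() > 1e-6:
                raise ValueError(f"rows of {name} must be unit-normalized (L2)")

    @classmethod
    def from_raw(cls, V, T, labels, tau: float = 0.02) -> "EmbeddingBatch":
        """Normalize rows of raw embeddings, then build the batch."""
        V = np.asarray(V, dtype=np.float64)
        T = np.asarray(T, dtype=np.float64)
        V = V / np.linalg.norm(V, axis=1, keepdims=True)
        T = T / np.linalg.norm(T, axis=1, keepdims=True)
        return cls(V=V, T=T, labels=labels, tau=tau)


@dataclass
class ClassifierHead:
    """Linear classification head over image embeddings: logits = V W + b."""

    W: np.ndarray  # D x C
    b: np.ndarray  # C

    def __post_init__(self):
        self.W = np.asarray(self.W, dtype=np.float64)
        self.b = np.asarray(self.b, dtype=np.float64)
        if not (np.isfinite(self.W).all() and np.isfinite(self.b).all()):
            raise ValueError("head parameters must be finite")
        if self.W.ndim != 2 or self.b.shape != (self.W.shape[1],):
            raise ValueError("W must be D x C and b length C")


@dataclass(frozen=True)
class LossBreakdown:
    cmpm: float
    id: float
    total: float


def match_distribution(labels: np.ndarray) -> np.ndarray:
    """Normalized ground-truth match matrix q: q_ij = [y_i == y_j] / n_same(i).

    Each row spreads equal probability over every column of the same class
    (including the diagonal); rows always sum to 1 because a sample matches
    itself.
    """
    labels = np.asarray(labels)
    match = (labels[:, None] == labels[None, :]).astype(np.float64)
    return match / match.sum(axis=1, keepdims=True)


def _diagonal_ce(logits: Tensor, n: int) -> Tensor:
    """Mean over the diagonal of -log softmax, in both the given orientation."""
    eye = np.eye(n)
    return -(log_softmax(logits, axis=1) * eye).sum() * (1.0 / n)


def infonce_graph(V: Tensor, T: Tensor, tau: float) -> Tensor:
    """Symmetric InfoNCE on autodiff tensors (diagonal pairs positive)."""
    if tau <= 0:
        raise ValueError("temperature tau must be positive")
    n = V.shape[0]
    logits = (V @ T.T) * (1.0 / tau)
    return (_diagonal_ce(logits, n) + _diagonal_ce(logits.T, n)) * 0.5


def cmpm_graph(
    V: Tensor,
    T: Tensor,
    labels: np.ndarray,
    tau: float,
    mode: str = "label_aware_kl",
    eps: float = CMPM_EPS,
) -> Tensor:
    """CMPM on autodiff tensors, in either the instance or label-aware form."""
    if tau <= 0:
        raise ValueError("temperature tau must be positive")
    n = V.shape[0]
    logits = (V @ T.T) * (1.0 / tau)
    if mode == "instance_softmax":
        return (_diagonal_ce(logits, n) + _diagonal_ce(logits.T, n)) * 0.5
    if mode != "label_aware_kl":
        raise ValueError(f"unknown CMPM mode {mode!r}")
    q = match_distribution(labels)
    assert (q.sum(axis=1) > 0).all()  # self-match makes all-zero rows impossible
    log_q = np.log(q + eps)

    def directed(lg: Tensor) -> Tensor:
        log_p = log_softmax(lg, axis=1)
        p = log_p.exp()
        return (p * (log_p - Tensor(log_q))).sum() * (1.0 / n)

    return (directed(logits) + directed(logits.T)) * 0.5


def id_graph(V: Tensor, labels: np.ndarray, W: Tensor, b: Tensor) -> Tensor:
    """Mean softmax cross-entropy of the linear head against the class labels."""
    labels = np.asarray(labels, dtype=np.int64)
    n, c = V.shape[0], W.shape[1]
    if labels.min() < 0 or labels.max() >= c:
        raise ValueError("label out of range for classifier head")
    onehot = np.zeros((n, c))
    onehot[np.arange(n), labels] = 1.0
    logits = V @ W + b
    return -(log_softmax(logits, axis=1) * onehot).sum() * (1.0 / n)


# -- float-returning public surface -------------------------------------------

def infonce_loss(batch: EmbeddingBatch) -> float:
    """Symmetric instance-level contrastive loss of the batch."""
    return float(infonce_graph(as_tensor(batch.V), as_tensor(batch.T), batch.tau))


def cmpm_loss(
    batch: EmbeddingBatch, mode: str = "label_aware_kl", eps: float = CMPM_EPS
) -> float:
    """Cross-modal projection matching loss of the batch."""
    return float(
        cmpm_graph(
            as_tensor(batch.V), as_tensor(batch.T), batch.labels, batch.tau,
            mode=mode, eps=eps,
        )
    )


def id_loss(V: np.ndarray, labels: np.ndarray, head: ClassifierHead) -> float:
    """Linear-head cross-entropy on image embeddings, averaged over the batch."""
    return float(
        id_graph(as_tensor(V), np.asarray(labels), as_tensor(head.W), as_tensor(head.b))
    )


def total_loss(
    batch: EmbeddingBatch,
    head: ClassifierHead,
    weights: tuple[float, float] = (1.0, 1.0),
    mode: str = "label_aware_kl",
    eps: float = CMPM_EPS,
) -> LossBreakdown:
    """Weighted CMPM + ID breakdown; default weights give the plain sum."""
    w_cmpm, w_id = weights
    if w_cmpm < 0 or w_id < 0:
        raise ValueError("loss weights must be non-negative")
    cmpm = cmpm_loss(batch, mode=mode, eps=eps)
    idv = id_loss(batch.V, batch.labels, head)
    return LossBreakdown(cmpm=cmpm, id=idv, total=w_cmpm * cmpm + w_id * idv)
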