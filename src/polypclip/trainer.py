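"""Training loop, learning-rate schedule, patient-level CV, and ablations.

The fine-tuning recipe is AdamW (beta1 0.9, beta2 0.98, eps 1e-8, weight decay
5e-4) with a linear warm-up over the first five iterations followed by a step
decay that halves the rate every 1000 iterations; batches of 8; temperature
0.02; the label-aware CMPM + ID objective by default. Package defaults scale
the recipe to the bundled tiny backbone and 64 x 64 synthetic corpus (learning
rate 1e-3, 30 epochs); :meth:`RunConfig.paper_scale` restores the settings
used for full-scale fine-tuning of a large pretrained dual encoder (learning
rate 1e-5, 60 epochs, 224 x 224 inputs).

Augmentation is applied to training batches only — evaluation never perturbs
an image — and every split is made at the patient level.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from skimage.transform import resize

from . import augment as _augment_mod
from ._optim import AdamW
from .corpus import CLASSES, ImageSample, Metrics, SplitPlan, compute_metrics, patient_level_folds
from .encoder import DualEncoder, EncoderSpec, classify
from .losses import cmpm_graph, id_graph, infonce_graph
from .prompts import TemplateRegistry, build_generic_prompt, build_prompt, default_registry

__all__ = [
    "RunConfig",
    "RunHistory",
    "CVResult",
    "FittedModel",
    "ABLATION_VARIANTS",
    "lr_at",
    "fit",
    "evaluate",
    "cross_validate",
    "run_ablation",
    "embedding_cosine_gap",
]

ABLATION_VARIANTS = ("full", "no_augment", "generic_prompts", "infonce_loss")


@dataclass
class RunConfig:
    """All knobs of one training run; defaults are the desk-scale recipe."""

    # optimizer
    lr: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.98
    adam_eps: float = 1e-8
    weight_decay: float = 0.0005
    # schedule
    warmup_iters: int = 5
    decay_factor: float = 0.5
    decay_every: int = 1000
    # loop
    epochs: int = 30
    batch_size: int = 8
    image_size: int = 64
    # objective
    tau: float = 0.02
    loss: str = "cmpm_id"  # or "infonce"
    cmpm_mode: str = "label_aware_kl"  # or "instance_softmax"
    cmpm_eps: float = 1e-8
    loss_weights: tuple[float, float] = (1.0, 1.0)
    # data / prompts
    augment: bool = True
    prompt_mode: str = "scst"  # or "generic"
    classes: tuple[str, ...] = CLASSES
    # model
    embed_dim: int = 32
    hidden_dim: int = 48
    image_backbone: str = "tiny_cnn"
    text_backbone: str = "class_embedding_table"
    freeze_text: bool = True
    image_trainable_depth: int = 2
    eval_rule: str = "similarity"  # or "id_head"
    grad_clip: float | None = 1.0  # global gradient-norm ceiling; None disables
    track_epoch_metrics: bool = True
    seed: int = 0

    def __post_init__(self):
        for name in ("lr", "tau", "adam_eps", "decay_factor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if self.loss not in ("cmpm_id", "infonce"):
            raise ValueError(f"unknown loss {self.loss!r}")
        if self.prompt_mode not in ("scst", "generic"):
            raise ValueError(f"unknown prompt_mode {self.prompt_mode!r}")
        if any(w < 0 for w in self.loss_weights):
            raise ValueError("loss weights must be non-negative")

    @classmethod
    def paper_scale(cls, **overrides) -> "RunConfig":
        """The full-scale fine-tuning recipe (large pretrained backbone sizes)."""
        base = dict(lr=1e-5, epochs=60, image_size=224, batch_size=8, tau=0.02)
        base.update(overrides)
        return cls(**base)

    def encoder_spec(self) -> EncoderSpec:
        return EncoderSpec(
            image_backbone=self.image_backbone,
            text_backbone=self.text_backbone,
            embed_dim=self.embed_dim,
            hidden_dim=self.hidden_dim,
            freeze_text=self.freeze_text,
            image_trainable_depth=self.image_trainable_depth,
        )


@dataclass
class RunHistory:
    """Per-iteration losses and learning rates, per-epoch training metrics."""

    iter_cmpm: list[float] = field(default_factory=list)
    iter_id: list[float] = field(default_factory=list)
    iter_total: list[float] = field(default_factory=list)
    lr_trace: list[float] = field(default_factory=list)
    epoch_train_accuracy: list[float] = field(default_factory=list)
    epoch_mean_loss: list[float] = field(default_factory=list)
    fold_id: int | None = None
    seed: int = 0


@dataclass
class FittedModel:
    """A trained dual encoder with its class prompt anchors."""

    encoder: DualEncoder
    class_prompts: list[str]
    class_prompt_embeddings: np.ndarray
    classes: tuple[str, ...]
    config: RunConfig

    def embed(self, images: np.ndarray) -> np.ndarray:
        return self.encoder.embed_images(images)

    def predict(self, samples: list[ImageSample]) -> list[str]:
        images = _stack_images(samples, self.config.image_size)
        V = self.encoder.embed_images(images)
        idx = classify(
            V,
            class_prompt_embeddings=self.class_prompt_embeddings,
            head=self.encoder.head,
            rule=self.config.eval_rule,
        )
        return [self.classes[i] for i in idx]


def lr_at(step: int, config: RunConfig) -> float:
    """Learning rate at 1-indexed iteration ``step``.

    Linear ramp from lr/warmup to lr over the first ``warmup_iters``
    iterations, then a step decay by ``decay_factor`` every ``decay_every``
    iterations counted after warm-up.
    """
    if step < 0:
        raise ValueError("step must be >= 0")
    w = config.warmup_iters
    if step <= w:
        return config.lr * max(step, 1) / w
    n_decays = (step - w) // config.decay_every
    return config.lr * config.decay_factor**n_decays


def _clip_grad_norm(params, max_norm: float) -> None:
    total = np.sqrt(
        sum(float((p.grad**2).sum()) for p in params if p.grad is not None)
    )
    if total > max_norm:
        scale = max_norm / total
        for p in params:
            if p.grad is not None:
                p.grad = p.grad * scale


def _stack_images(samples: list[ImageSample], size: int) -> np.ndarray:
    imgs = []
    for s in samples:
        img = s.image
        if img.shape[:2] != (size, size):
            img = np.clip(
                resize(img, (size, size, 3), order=1, preserve_range=True,
                       anti_aliasing=True),
                0.0, 1.0,
            )
        imgs.append(img)
    return np.stack(imgs)


def _class_prompts(
    config: RunConfig, registry: TemplateRegistry
) -> dict[str, str]:
    builder = build_prompt if config.prompt_mode == "scst" else build_generic_prompt
    return {c: builder(c, registry) for c in config.classes}


def fit(
    train_samples: list[ImageSample],
    config: RunConfig,
    registry: TemplateRegistry | None = None,
    augment_fn=None,
) -> tuple[FittedModel, RunHistory]:
    """Train a dual encoder on the given samples.

    Each step augments the batch (training only), builds each sample's class
    prompt, encodes both modalities, and descends the configured objective
    under the freeze policy. Three independent RNG streams (data order,
    augmentation, initialization) derive from the run seed so that ablations
    share identical data order. Fully reproducible for a fixed seed.
    """
    if not train_samples:
        raise ValueError("training set must be non-empty")
    registry = registry or default_registry()
    order_ss, aug_ss, init_ss = np.random.SeedSequence(config.seed).spawn(3)
    order_rng = np.random.default_rng(order_ss)
    aug_rng = np.random.default_rng(aug_ss)
    init_rng = np.random.default_rng(init_ss)

    spec = config.encoder_spec()
    model = DualEncoder.build(
        spec, config.image_size, len(config.classes), init_rng
    )
    prompts_warm = _class_prompts(config, registry)
    model.encode_texts(list(prompts_warm.values()))  # materialize text params
    opt = AdamW(
        model.trainable_params,
        lr=config.lr,
        beta1=config.beta1,
        beta2=config.beta2,
        eps=config.adam_eps,
        weight_decay=config.weight_decay,
    )
    prompts_by_class = prompts_warm
    label_to_idx = {c: i for i, c in enumerate(config.classes)}
    for s in train_samples:
        if s.label not in label_to_idx:
            raise ValueError(f"sample label {s.label!r} not in configured classes")

    history = RunHistory(seed=config.seed)
    n = len(train_samples)
    step = 0
    for _epoch in range(config.epochs):
        order = order_rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, config.batch_size):
            batch = [train_samples[i] for i in order[start : start + config.batch_size]]
            if config.augment:
                if augment_fn is None:
                    augment_fn_now = _augment_mod.augment_sample
                else:
                    augment_fn_now = augment_fn
                batch = [augment_fn_now(s, aug_rng) for s in batch]
            images = _stack_images(batch, config.image_size)
            labels = np.array([label_to_idx[s.label] for s in batch])
            prompts = [prompts_by_class[s.label] for s in batch]

            V = model.encode_images(images)
            T = model.encode_texts(prompts)

            w_cmpm, w_id = config.loss_weights
            cmpm_val = id_val = 0.0
            loss = None
            if config.loss == "infonce":
                loss = infonce_graph(V, T, config.tau)
                cmpm_val = float(loss)
            else:
                if w_cmpm > 0:
                    cmpm_t = cmpm_graph(
                        V, T, labels, config.tau,
                        mode=config.cmpm_mode, eps=config.cmpm_eps,
                    )
                    cmpm_val = float(cmpm_t)
                    loss = cmpm_t * w_cmpm
                if w_id > 0:
                    id_t = id_graph(V, labels, model.head_W, model.head_b)
                    id_val = float(id_t)
                    loss = id_t * w_id if loss is None else loss + id_t * w_id

            step += 1
            rate = lr_at(step, config)
            if loss is not None:
                opt.zero_grad()
                loss.backward()
                if config.grad_clip is not None:
                    _clip_grad_norm(opt.params, config.grad_clip)
                opt.step(lr=rate)
                total_val = float(loss)
            else:
                total_val = 0.0
            history.iter_cmpm.append(cmpm_val)
            history.iter_id.append(id_val)
            history.iter_total.append(total_val)
            history.lr_trace.append(rate)
            epoch_losses.append(total_val)

        history.epoch_mean_loss.append(float(np.mean(epoch_losses)))
        if config.track_epoch_metrics:
            history.epoch_train_accuracy.append(
                _quick_accuracy(model, train_samples, prompts_by_class, config,
                                label_to_idx)
            )

    class_prompts = [prompts_by_class[c] for c in config.classes]
    fitted = FittedModel(
        encoder=model,
        class_prompts=class_prompts,
        class_prompt_embeddings=model.embed_texts(class_prompts),
        classes=tuple(config.classes),
        config=config,
    )
    return fitted, history


def _quick_accuracy(model, samples, prompts_by_class, config, label_to_idx) -> float:
    images = _stack_images(samples, config.image_size)
    V = model.embed_images(images)
    anchors = model.embed_texts([prompts_by_class[c] for c in config.classes])
    pred = classify(V, class_prompt_embeddings=anchors, rule="similarity")
    truth = np.array([label_to_idx[s.label] for s in samples])
    return float(np.mean(pred == truth))


def evaluate(
    model: FittedModel,
    test_samples: list[ImageSample],
    train_patients: set[str] | None = None,
) -> Metrics:
    """Score the model on a patient-disjoint test set. No augmentation, ever.

    When ``train_patients`` is given, any overlap with the test patients is a
    hard error (defense in depth against identity leakage).
    """
    if not test_samples:
        raise ValueError("test set must be non-empty")
    if train_patients is not None:
        overlap = train_patients & {s.patient_id for s in test_samples}
        if overlap:
            raise ValueError(
                f"train/test patient overlap detected: {sorted(overlap)[:5]}"
            )
    predictions = model.predict(test_samples)
    truth = [s.label for s in test_samples]
    return compute_metrics(truth, predictions, classes=model.classes)


@dataclass
class CVResult:
    """Per-fold metrics with their across-fold mean and standard deviation."""

    per_fold: list[Metrics]
    plan: SplitPlan

    def _values(self, attr: str) -> np.ndarray:
        return np.array([getattr(m, attr) for m in self.per_fold])

    @property
    def mean_accuracy(self) -> float:
        return float(self._values("accuracy").mean())

    @property
    def std_accuracy(self) -> float:
        return float(self._values("accuracy").std())

    @property
    def mean_macro_f1(self) -> float:
        return float(self._values("macro_f1").mean())

    @property
    def std_macro_f1(self) -> float:
        return float(self._values("macro_f1").std())

    def summary(self) -> dict:
        return {
            "accuracy_mean": self.mean_accuracy,
            "accuracy_std": self.std_accuracy,
            "macro_f1_mean": self.mean_macro_f1,
            "macro_f1_std": self.std_macro_f1,
            "per_fold_accuracy": self._values("accuracy").tolist(),
            "per_fold_macro_f1": self._values("macro_f1").tolist(),
        }


def holdout_split(
    samples: list[ImageSample], config: RunConfig, k: int = 5
) -> tuple[list[ImageSample], list[ImageSample]]:
    """A single patient-level train/test split (fold 0 of a k-fold plan)."""
    plan = patient_level_folds(samples, k=k, seed=config.seed)
    train_p, test_p = plan.folds[0]
    train = [s for s in samples if s.patient_id in train_p]
    test = [s for s in samples if s.patient_id in test_p]
    return train, test


def cross_validate(
    samples: list[ImageSample],
    config: RunConfig,
    k: int = 5,
    registry: TemplateRegistry | None = None,
    augment_fn=None,
) -> CVResult:
    """Train k independent models on patient-level folds and pool metrics."""
    plan = patient_level_folds(samples, k=k, seed=config.seed)
    per_fold: list[Metrics] = []
    for fold_id, (train_p, test_p) in enumerate(plan.folds):
        train = [s for s in samples if s.patient_id in train_p]
        test = [s for s in samples if s.patient_id in test_p]
        model, history = fit(train, config, registry=registry, augment_fn=augment_fn)
        history.fold_id = fold_id
        per_fold.append(evaluate(model, test, train_patients=train_p))
    return CVResult(per_fold=per_fold, plan=plan)


def ablation_config(variant: str, config: RunConfig) -> RunConfig:
    """The run config for one ablation variant (same seed and splits)."""
    if variant == "full":
        return replace(config)
    if variant == "no_augment":
        return replace(config, augment=False)
    if variant == "generic_prompts":
        return replace(config, prompt_mode="generic")
    if variant == "infonce_loss":
        return replace(config, loss="infonce")
    raise ValueError(
        f"unknown ablation variant {variant!r}; allowed: {ABLATION_VARIANTS}"
    )


def run_ablation(
    samples: list[ImageSample],
    variant: str,
    config: RunConfig,
    eval_mode: str = "holdout",
    k: int = 5,
    registry: TemplateRegistry | None = None,
    augment_fn=None,
) -> Metrics | CVResult:
    """Train and score one ablation variant under identical seeds/splits.

    ``holdout`` trains once on a fixed patient-level split; ``cv`` runs the
    full k-fold protocol. Variants share the fold plan because it depends only
    on the seed and the patient list.
    """
    cfg = ablation_config(variant, config)
    if eval_mode == "cv":
        return cross_validate(samples, cfg, k=k, registry=registry,
                              augment_fn=augment_fn)
    if eval_mode != "holdout":
        raise ValueError(f"unknown eval_mode {eval_mode!r}")
    train, test = holdout_split(samples, cfg, k=k)
    model, _ = fit(train, cfg, registry=registry, augment_fn=augment_fn)
    return evaluate(model, test, train_patients={s.patient_id for s in train})


def embedding_cosine_gap(
    model: FittedModel, samples: list[ImageSample]
) -> float:
    """Mean within-class cosine minus mean between-class cosine.

    Positive gaps mean the embedding space is tightened within classes and
    separated between them; the default end-to-end run targets a gap >= 0.2.
    """
    images = _stack_images(samples, model.config.image_size)
    V = model.embed(images)
    labels = np.array([s.label for s in samples])
    sims = V @ V.T
    same = labels[:, None] == labels[None, :]
    off_diag = ~np.eye(len(labels), dtype=bool)
    within = sims[same & off_diag].mean()
    between = sims[~same].mean()
    return float(within - between)
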