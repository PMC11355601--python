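"""Adversarial training of DANN models and the source-only baseline.

The optimisation objective couples a label-prediction loss over *source*
samples with a domain-classification loss over *all* samples.  The domain
loss enters the parameter updates twice with opposite signs: the domain
classifier descends on it, while the feature extractor ascends, because the
gradient reversal layer multiplies the feature-bound gradient by ``-λ``.
Both reported scalar losses are therefore plain cross-entropies — the sign
flip lives entirely inside the GRL backward — and the optimiser is ordinary
Adam on ``class_loss + domain_loss``.

Each step makes two forward passes: a source-only pass for the class loss,
and one concatenated source+target pass (equal halves, so the domain task
stays balanced) for the domain loss, whose mixed-batch statistics drive the
batch-norm running buffers.  One epoch is one pass over the source set;
target images are (re)sampled with replacement per step.  Target class
labels are never read.

All randomness (weight init, batch order, dropout) derives from the config
seed through named streams, making runs bit-reproducible and making the
λ≡0 run of ``train_dann`` parameter-identical to ``train_baseline``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .models import DANNModel, SourceClassifier
from .nn import Adam, ForwardContext, Tensor
from .nn import functional as F
from .nn.layers import seed_rng

__all__ = [
    "LambdaSchedule", "TrainConfig", "TrainHistory", "lambda_at",
    "dann_step_loss", "train_dann", "train_baseline",
]

_STREAM_SOURCE_ORDER = 101
_STREAM_TARGET_ORDER = 102


@dataclass(frozen=True)
class LambdaSchedule:
    """Maps training progress p ∈ [0, 1] to the GRL coefficient λ.

    constant: λ(p) = lambda_max.
    annealed: λ(p) = lambda_max · (2 / (1 + exp(-gamma·p)) - 1), the standard
    warm-up from 0 toward lambda_max that lets the label predictor stabilise
    before the adversarial signal ramps up.
    """

    mode: str = "annealed"
    lambda_max: float = 1.0
    gamma: float = 10.0

    def __post_init__(self):
        if self.mode not in ("constant", "annealed"):
            raise ValueError(f"unknown schedule mode '{self.mode}'")
        if self.lambda_max < 0:
            raise ValueError("lambda_max must be >= 0")
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")


def lambda_at(schedule: LambdaSchedule, progress: float) -> float:
    if not 0.0 <= progress <= 1.0:
        raise ValueError(f"progress must lie in [0, 1], got {progress}")
    if schedule.mode == "constant":
        return schedule.lambda_max
    return schedule.lambda_max * (
        2.0 / (1.0 + math.exp(-schedule.gamma * progress)) - 1.0)


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters; defaults follow the published recipe
    (Adam, lr 1e-4, batch 16, 100 epochs)."""

    epochs: int = 100
    batch_size: int = 16
    learning_rate: float = 1e-4
    optimizer: str = "adam"
    lambda_schedule: LambdaSchedule = field(default_factory=LambdaSchedule)
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 2:
            raise ValueError("batch_size must be >= 2")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")


@dataclass
class EpochRecord:
    epoch: int
    class_loss: float
    domain_loss: float
    source_class_accuracy: float
    domain_accuracy: float
    lambda_value: float


@dataclass
class TrainHistory:
    records: list[EpochRecord] = field(default_factory=list)

    def __len__(self):
        return len(self.records)

    def column(self, name: str) -> np.ndarray:
        return np.array([getattr(r, name) for r in self.records])


# ---------------------------------------------------------------------------
# loss assembly
# ---------------------------------------------------------------------------

def dann_step_loss(class_probs_source: Tensor, class_labels_source,
                   domain_probs_all: Tensor, domain_labels_all,
                   lambda_value: float):
    """Per-step losses: (total, class, domain).

    The class loss is the mean cross-entropy over the source samples only;
    the domain loss is the mean cross-entropy over all samples.  The total is
    their plain sum — the ``-λ`` factor of the adversarial objective is
    applied by the GRL during backpropagation, not here — so ``lambda_value``
    only validates the caller's bookkeeping.
    """
    if lambda_value < 0:
        raise ValueError("lambda must be >= 0")
    y = np.asarray(class_labels_source)
    if y.size == 0:
        raise ValueError("class loss undefined: batch contains no source "
                         "samples")
    class_loss = F.cross_entropy_from_probs(class_probs_source, y)
    domain_loss = F.cross_entropy_from_probs(domain_probs_all,
                                             np.asarray(domain_labels_all))
    return F.add(class_loss, domain_loss), class_loss, domain_loss


# ---------------------------------------------------------------------------
# batching
# ---------------------------------------------------------------------------

def _epoch_batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n - batch_size + 1, batch_size):
        yield order[start:start + batch_size]


def _check_dataset(images, labels, what: str):
    images = np.asarray(images, dtype=np.float32)
    if images.ndim != 4 or images.shape[0] == 0:
        raise ValueError(f"{what} dataset is empty or not an image batch")
    if labels is not None:
        labels = np.asarray(labels)
        if labels.shape[0] != images.shape[0]:
            raise ValueError(f"{what} labels do not match image count")
    return images, labels


# ---------------------------------------------------------------------------
# training loops
# ---------------------------------------------------------------------------

def train_dann(model: DANNModel, source_images, source_labels, target_images,
               cfg: TrainConfig) -> tuple[DANNModel, TrainHistory]:
    """Adversarial training; target images are used unlabelled.

    Each step draws ``batch_size`` source and ``batch_size`` target images,
    computes the class loss on a source-only pass and the domain loss on a
    concatenated-mixture pass, and takes one Adam step on their sum.  λ is
    refreshed from the schedule every step using progress
    p = step / total_steps.
    """
    src, y_src = _check_dataset(source_images, source_labels, "source")
    tgt, _ = _check_dataset(target_images, None, "target")
    if src.shape[1:] != tgt.shape[1:]:
        raise ValueError(f"source and target image sizes differ: "
                         f"{src.shape[1:]} vs {tgt.shape[1:]}")

    opt = Adam(model.parameters(), lr=cfg.learning_rate)
    n_src, n_tgt = src.shape[0], tgt.shape[0]
    steps_per_epoch = max(n_src // cfg.batch_size, 1)
    total_steps = cfg.epochs * steps_per_epoch
    history = TrainHistory()
    step = 0
    for epoch in range(cfg.epochs):
        rng_src = seed_rng(cfg.seed, _STREAM_SOURCE_ORDER, epoch)
        rng_tgt = seed_rng(cfg.seed, _STREAM_TARGET_ORDER, epoch)
        sums = np.zeros(4)
        nb = 0
        for idx_s in _epoch_batches(n_src, cfg.batch_size, rng_src):
            idx_t = rng_tgt.integers(0, n_tgt, size=cfg.batch_size)
            lam = lambda_at(cfg.lambda_schedule, step / max(total_steps - 1, 1))
            model.grl_primary.value = lam
            if model.grl_secondary is not None:
                model.grl_secondary.value = lam

            # class path: a source-only pass, so that with λ = 0 the
            # parameter trajectory is exactly that of source-only training.
            # Its FE call leaves the running buffers untouched.
            ctx_cls_fe = ForwardContext(True, cfg.seed, step, tag=0,
                                        bn_stats="batch_nobuf")
            ctx_cls = ForwardContext(True, cfg.seed, step, tag=0)
            # domain path: one pass of the concatenated source+target batch,
            # as in canonical DANN.  Its batch statistics (which include the
            # between-domain variance) are what the running buffers track,
            # so eval-mode normalisation matches a distribution the network
            # actually trained on.
            ctx_mix = ForwardContext(True, cfg.seed, step, tag=1)
            ctx_mix_nobuf = ForwardContext(True, cfg.seed, step, tag=1,
                                           bn_stats="batch_nobuf")

            f_s = model.fe(Tensor(src[idx_s]), ctx_cls_fe)
            h1_s, cp_s = model.class_branch(f_s, ctx_cls)
            f_mix = model.fe(Tensor(np.concatenate([src[idx_s], tgt[idx_t]])),
                             ctx_mix)
            if model.variant == "two_grl_dann":
                tap = model.label_predictor.block1(f_mix, ctx_mix_nobuf)
            else:
                tap = None
            dp = model.domain_branch(f_mix, ctx_mix, cl_tap=tap)

            yb = y_src[idx_s]
            d_lab = np.r_[np.zeros(len(idx_s), np.int64),
                          np.ones(len(idx_t), np.int64)]
            total, closs, dloss = dann_step_loss(cp_s, yb, dp, d_lab, lam)
            opt.zero_grad()
            total.backward()
            opt.step()

            sums += (closs.item(), dloss.item(),
                     float((cp_s.data.argmax(1) == yb).mean()),
                     float((dp.data.argmax(1) == d_lab).mean()))
            nb += 1
            step += 1
        history.records.append(EpochRecord(
            epoch=epoch, class_loss=sums[0] / nb, domain_loss=sums[1] / nb,
            source_class_accuracy=sums[2] / nb, domain_accuracy=sums[3] / nb,
            lambda_value=model.grl_primary.value))
    return model, history


def train_baseline(model: SourceClassifier, source_images, source_labels,
                   cfg: TrainConfig) -> tuple[SourceClassifier, TrainHistory]:
    """Supervised source-only training: the comparison arm.

    Consumes the same source-order and dropout randomness streams as
    :func:`train_dann`, so with identical seeds the two runs see identical
    source batches and masks.
    """
    src, y_src = _check_dataset(source_images, source_labels, "source")
    opt = Adam(model.parameters(), lr=cfg.learning_rate)
    n_src = src.shape[0]
    history = TrainHistory()
    step = 0
    for epoch in range(cfg.epochs):
        rng_src = seed_rng(cfg.seed, _STREAM_SOURCE_ORDER, epoch)
        sums = np.zeros(2)
        nb = 0
        for idx_s in _epoch_batches(n_src, cfg.batch_size, rng_src):
            ctx_s = ForwardContext(True, cfg.seed, step, tag=0)
            probs = model.graph_forward(Tensor(src[idx_s]), ctx_s)
            yb = y_src[idx_s]
            loss = F.cross_entropy_from_probs(probs, yb)
            opt.zero_grad()
            loss.backward()
            opt.step()
            sums += (loss.item(), float((probs.data.argmax(1) == yb).mean()))
            nb += 1
            step += 1
        history.records.append(EpochRecord(
            epoch=epoch, class_loss=sums[0] / nb, domain_loss=float("nan"),
            source_class_accuracy=sums[1] / nb, domain_accuracy=float("nan"),
            lambda_value=0.0))
    return model, history
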