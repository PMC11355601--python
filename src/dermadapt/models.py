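"""Network architectures: feature extractors, label-predictor and
domain-classifier heads, and their assembly into DANN models.

Three branches make up a DANN: a convolutional feature extractor ``G_FE``, a
label predictor ``G_CL`` (three fully connected layers, softmax over
melanoma=1 vs non-melanoma=0) that consumes features directly, and a domain
classifier ``G_DL`` (two fully connected layers, softmax over source=0 vs
target=1) that sees features only through a gradient reversal layer.  The
two-GRL variant adds a second reversal path: the label predictor's
first-block activations are passed through a second GRL and concatenated
into the domain classifier's second block, pushing deeper task features
toward domain indistinguishability.

All architectures are trained from scratch — no pretrained weights.  Input
resolution is configurable (square, power of two, default 64); hidden widths
not fixed by the recipe are: 16/32/64 conv channels for the small CNN
(sized for single-CPU training), 256/128 for the label predictor, 256 for
the domain classifier.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .grl import GRLCoefficient, gradient_reversal
from .nn import ForwardContext, Tensor
from .nn import functional as F

__all__ = [
    "VALID_EXTRACTORS", "FeatureExtractorSpec", "DANNModel", "SourceClassifier",
    "build_feature_extractor", "build_label_predictor",
    "build_domain_classifier", "assemble_dann", "assemble_baseline",
    "forward", "summarize_parameters", "save_checkpoint", "load_checkpoint",
]

VALID_EXTRACTORS = ("cnn_dropout", "alexnet", "vgg11", "vgg13")

#: minimum input resolution per extractor (the AlexNet-style stem plus three
#: pooling stages needs 64 pixels to keep a non-degenerate spatial map)
_MIN_INPUT = {"cnn_dropout": 32, "alexnet": 64, "vgg11": 32, "vgg13": 32}


@dataclass(frozen=True)
class FeatureExtractorSpec:
    """Configuration of the convolutional branch ``G_FE``."""

    kind: str
    input_size: int = 64

    def __post_init__(self):
        if self.kind not in VALID_EXTRACTORS:
            raise ValueError(
                f"unknown feature extractor '{self.kind}'; "
                f"valid kinds: {', '.join(VALID_EXTRACTORS)}")
        s = self.input_size
        if s < 32 or (s & (s - 1)) != 0:
            raise ValueError(
                f"input_size must be a power of two >= 32, got {s}")
        if s < _MIN_INPUT[self.kind]:
            raise ValueError(
                f"{self.kind} requires input_size >= {_MIN_INPUT[self.kind]}, "
                f"got {s}")

    @property
    def feature_dim(self) -> int:
        s = self.input_size
        if self.kind == "cnn_dropout":
            return 64 * (s // 8) ** 2
        if self.kind == "alexnet":
            return 256 * (s // 16) ** 2
        # vgg11 / vgg13: five pooling stages, 512 channels out
        return 512 * (s // 32) ** 2


class FeatureExtractor(nn.Module):
    """Sequential conv stack with a known flattened output width."""

    def __init__(self, spec: FeatureExtractorSpec, seed: int):
        super().__init__(f"fe_{spec.kind}")
        self.spec = spec
        self.feature_dim = spec.feature_dim
        self.stack = self.add_child(_build_stack(spec, seed))

    def forward(self, x, ctx):
        if x.ndim != 4 or x.shape[1] != 3 or x.shape[2] != x.shape[3] \
                or x.shape[2] != self.spec.input_size:
            raise ValueError(
                f"expected image batch of shape (n, 3, {self.spec.input_size}, "
                f"{self.spec.input_size}), got {tuple(x.shape)}")
        # the engine's spatial ops run channels-last
        return self.stack(F.nchw_to_nhwc(x), ctx)


def _conv_block(name, cin, cout, seed, pool=False, k=3, stride=1, pad=1):
    layers = [
        nn.Conv2d(f"{name}.conv", cin, cout, k, seed, stride=stride, pad=pad),
        nn.BatchNorm(f"{name}.bn", cout),
        nn.ReLU(f"{name}.relu"),
    ]
    if pool:
        layers.append(nn.MaxPool2d(f"{name}.pool", 2))
    return layers


def _build_stack(spec: FeatureExtractorSpec, seed: int) -> nn.Sequential:
    k = spec.kind
    name = f"fe.{k}"
    layers: list[nn.Module] = []
    if k == "cnn_dropout":
        # three conv blocks, dropout after the last (p = 0.5)
        for i, (cin, cout) in enumerate([(3, 16), (16, 32), (32, 64)]):
            layers += _conv_block(f"{name}.b{i}", cin, cout, seed, pool=True)
        layers.append(nn.Dropout(f"{name}.drop", 0.5))
    elif k == "alexnet":
        # stride-2 stem then three pooled stages; no dropout
        layers += [
            nn.Conv2d(f"{name}.b0.conv", 3, 64, 5, seed, stride=2, pad=2),
            nn.BatchNorm(f"{name}.b0.bn", 64),
            nn.ReLU(f"{name}.b0.relu"),
            nn.MaxPool2d(f"{name}.b0.pool", 2),
        ]
        layers += _conv_block(f"{name}.b1", 64, 192, seed, pool=True)
        layers += _conv_block(f"{name}.b2", 192, 384, seed)
        layers += _conv_block(f"{name}.b3", 384, 256, seed)
        layers += _conv_block(f"{name}.b4", 256, 256, seed, pool=True)
    else:
        plan = {
            "vgg11": [(64,), (128,), (256, 256), (512, 512), (512, 512)],
            "vgg13": [(64, 64), (128, 128), (256, 256), (512, 512), (512, 512)],
        }[k]
        cin = 3
        for bi, widths in enumerate(plan):
            for ci, cout in enumerate(widths):
                layers += _conv_block(f"{name}.b{bi}.{ci}", cin, cout, seed)
                cin = cout
            layers.append(nn.MaxPool2d(f"{name}.b{bi}.pool", 2))
        if k == "vgg13":
            layers.append(nn.Dropout(f"{name}.drop", 0.5))
    layers.append(nn.Flatten(f"{name}.flatten"))
    return nn.Sequential(name, layers)


class LabelPredictor(nn.Module):
    """Three-layer FC head with batch norm, ReLU and dropout, then softmax.

    ``block1`` is exposed separately because the two-GRL variant taps its
    output for the second reversal path.
    """

    def __init__(self, feature_dim: int, seed: int):
        super().__init__("cl")
        self.block1 = self.add_child(nn.Sequential("cl.b1", [
            nn.Linear("cl.b1.fc", feature_dim, 256, seed),
            nn.BatchNorm("cl.b1.bn", 256),
            nn.ReLU("cl.b1.relu"),
            nn.Dropout("cl.b1.drop", 0.5),
        ]))
        self.block2 = self.add_child(nn.Sequential("cl.b2", [
            nn.Linear("cl.b2.fc", 256, 128, seed),
            nn.BatchNorm("cl.b2.bn", 128),
            nn.ReLU("cl.b2.relu"),
            nn.Dropout("cl.b2.drop", 0.5),
        ]))
        self.head = self.add_child(nn.Linear("cl.head", 128, 2, seed))

    def forward(self, x, ctx):
        return F.softmax(self.head(self.block2(self.block1(x, ctx), ctx), ctx))


class DomainClassifier(nn.Module):
    """Two-layer FC head; ``second_in`` widens block 2 for the two-GRL tap."""

    def __init__(self, feature_dim: int, seed: int, second_in: int = 256):
        super().__init__("dc")
        self.block1 = self.add_child(nn.Sequential("dc.b1", [
            nn.Linear("dc.b1.fc", feature_dim, 256, seed),
            nn.BatchNorm("dc.b1.bn", 256),
            nn.ReLU("dc.b1.relu"),
        ]))
        self.block2 = self.add_child(nn.Linear("dc.b2.fc", second_in, 2, seed))

    def forward(self, x, ctx):
        return F.softmax(self.block2(self.block1(x, ctx), ctx))


@dataclass
class DANNModel:
    """A feature extractor with label-predictor and domain-classifier heads.

    ``grl_primary`` sits between the features and the domain classifier;
    ``grl_secondary`` (two-GRL variant only) sits on the tap from the label
    predictor's first block into the domain classifier's second block.
    """

    fe: FeatureExtractor
    label_predictor: LabelPredictor
    domain_classifier: DomainClassifier
    grl_primary: GRLCoefficient
    variant: str
    seed: int
    grl_secondary: GRLCoefficient | None = None

    def __post_init__(self):
        if self.variant not in ("dann", "two_grl_dann"):
            raise ValueError(f"unknown variant '{self.variant}'")
        if (self.variant == "two_grl_dann") != (self.grl_secondary is not None):
            raise ValueError("grl_secondary must be present exactly for the "
                             "two_grl_dann variant")

    # -- graph builders ----------------------------------------------------
    def class_branch(self, feats: Tensor, ctx: ForwardContext):
        """Returns (block1 activations, class probabilities)."""
        h1 = self.label_predictor.block1(feats, ctx)
        h2 = self.label_predictor.block2(h1, ctx)
        probs = F.softmax(self.label_predictor.head(h2, ctx))
        return h1, probs

    def domain_branch(self, feats: Tensor, ctx: ForwardContext,
                      cl_tap: Tensor | None = None) -> Tensor:
        """Domain probabilities from features (through the primary GRL).

        ``cl_tap`` is the label-predictor block-1 output for the same rows;
        required for (and only for) the two-GRL variant.
        """
        rev = gradient_reversal(feats, self.grl_primary)
        h = self.domain_classifier.block1(rev, ctx)
        if self.variant == "two_grl_dann":
            if cl_tap is None:
                raise ValueError("two_grl_dann needs the label-predictor tap")
            tap = gradient_reversal(cl_tap, self.grl_secondary)
            h = F.concat([h, tap], axis=1)
        return F.softmax(self.domain_classifier.block2(h, ctx))

    def graph_forward(self, images: Tensor, ctx: ForwardContext):
        feats = self.fe(images, ctx)
        h1, class_probs = self.class_branch(feats, ctx)
        tap = h1 if self.variant == "two_grl_dann" else None
        domain_probs = self.domain_branch(feats, ctx, cl_tap=tap)
        return class_probs, domain_probs

    # -- bookkeeping -------------------------------------------------------
    def modules(self):
        return [self.fe, self.label_predictor, self.domain_classifier]

    def parameters(self):
        return [p for m in self.modules() for p in m.parameters()]

    def named_parameters(self):
        for m in self.modules():
            yield from m.named_parameters()

    def state_dict(self):
        state = {}
        for m in self.modules():
            state.update(m.state_dict())
        return state

    def load_state_dict(self, state):
        for m in self.modules():
            m.load_state_dict(state)

    @property
    def input_size(self) -> int:
        return self.fe.spec.input_size


class SourceClassifier:
    """Feature extractor + label predictor only: the source-only baseline.

    Built with the same layer names and seed derivation as the corresponding
    DANN, so its initial parameters coincide with the DANN's shared branch.
    """

    def __init__(self, fe: FeatureExtractor, label_predictor: LabelPredictor,
                 seed: int):
        self.fe = fe
        self.label_predictor = label_predictor
        self.seed = seed

    def graph_forward(self, images: Tensor, ctx: ForwardContext) -> Tensor:
        _, probs = DANNModel.class_branch(self, self.fe(images, ctx), ctx)
        return probs

    def class_branch(self, feats, ctx):  # shared implementation
        return DANNModel.class_branch(self, feats, ctx)

    def modules(self):
        return [self.fe, self.label_predictor]

    def parameters(self):
        return [p for m in self.modules() for p in m.parameters()]

    def named_parameters(self):
        for m in self.modules():
            yield from m.named_parameters()

    @property
    def input_size(self) -> int:
        return self.fe.spec.input_size


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------

def build_feature_extractor(spec: FeatureExtractorSpec,
                            seed: int) -> FeatureExtractor:
    """Deterministically initialised conv branch for the given spec."""
    return FeatureExtractor(spec, seed)


def build_label_predictor(feature_dim: int, seed: int) -> LabelPredictor:
    return LabelPredictor(feature_dim, seed)


def build_domain_classifier(feature_dim: int, seed: int,
                            two_grl: bool = False) -> DomainClassifier:
    return DomainClassifier(feature_dim, seed,
                            second_in=512 if two_grl else 256)


def assemble_dann(fe_spec: FeatureExtractorSpec, variant: str = "dann",
                  seed: int = 0) -> DANNModel:
    """Assemble a DANN or two-GRL DANN with deterministic initialisation."""
    if variant not in ("dann", "two_grl_dann"):
        raise ValueError(
            f"unknown variant '{variant}'; valid: dann, two_grl_dann")
    fe = build_feature_extractor(fe_spec, seed)
    cl = build_label_predictor(fe.feature_dim, seed)
    dc = build_domain_classifier(fe.feature_dim, seed,
                                 two_grl=(variant == "two_grl_dann"))
    return DANNModel(
        fe=fe, label_predictor=cl, domain_classifier=dc,
        grl_primary=GRLCoefficient(1.0), variant=variant, seed=seed,
        grl_secondary=GRLCoefficient(1.0) if variant == "two_grl_dann"
        else None)


def assemble_baseline(fe_spec: FeatureExtractorSpec,
                      seed: int = 0) -> SourceClassifier:
    fe = build_feature_extractor(fe_spec, seed)
    cl = build_label_predictor(fe.feature_dim, seed)
    return SourceClassifier(fe, cl, seed)


# ---------------------------------------------------------------------------
# inference & inspection
# ---------------------------------------------------------------------------

def forward(model: DANNModel, images) -> tuple[np.ndarray, np.ndarray]:
    """Eval-mode forward: (class probabilities, domain probabilities).

    ``images`` must be (n, 3, s, s) in [0, 1] with s = the configured input
    size; both outputs are (n, 2) row-stochastic matrices, independent of λ
    (the GRL is the identity forward).
    """
    x = Tensor(np.asarray(images, dtype=np.float32))
    cp, dp = model.graph_forward(x, ForwardContext(train=False))
    return cp.data, dp.data


def summarize_parameters(model) -> list[tuple[str, tuple, int]]:
    """Stable per-parameter summary: (name, shape, count)."""
    return [(name, tuple(p.data.shape), int(p.data.size))
            for name, p in model.named_parameters()]


# ---------------------------------------------------------------------------
# checkpoints: .npz state + JSON architecture manifest
# ---------------------------------------------------------------------------

def save_checkpoint(model: DANNModel, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path.with_suffix(".npz"), **model.state_dict())
    manifest = {
        "kind": model.fe.spec.kind,
        "input_size": model.fe.spec.input_size,
        "variant": model.variant,
        "seed": model.seed,
        "lambda_primary": model.grl_primary.value,
        "lambda_secondary": (model.grl_secondary.value
                             if model.grl_secondary else None),
    }
    path.with_suffix(".json").write_text(json.dumps(manifest, indent=2))
    return path.with_suffix(".npz")


def load_checkpoint(path) -> DANNModel:
    path = Path(path)
    manifest = json.loads(path.with_suffix(".json").read_text())
    model = assemble_dann(
        FeatureExtractorSpec(manifest["kind"], manifest["input_size"]),
        variant=manifest["variant"], seed=manifest["seed"])
    with np.load(path.with_suffix(".npz")) as state:
        model.load_state_dict(dict(state))
    model.grl_primary.value = manifest["lambda_primary"]
    if model.grl_secondary is not None:
        model.grl_secondary.value = manifest["lambda_secondary"]
    return model
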