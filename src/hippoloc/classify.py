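"""ROI / Global / Fusion classification with the integrated loss.

The integrated objective combines binary cross-entropy (C1) with a modified
contrastive term (C2) that pushes scores toward their class poles:

    C1 = -(1/N) sum_i [ y_i log(yhat_i) + (1 - y_i) log(1 - yhat_i) ]
    C2 =  (1/N) sum_i [ (1 - y_i) yhat_i^2 + m * y_i * max(1 - yhat_i, 0)^2 ]
    Loss = C1 + 2 * C2            (margin m defaults to 2)

ROI Net classifies the localized crop, Global Net the whole slice, and Fusion
Net concatenates both feature vectors (512 + 1024) into a small dense head.
All nets share the conv stack described in :mod:`hippoloc.dqn` and end in a
sigmoid, so scores live in (0, 1); the decision threshold is 0.5 with the
boundary assigned to the positive (disease) class.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from skimage.transform import resize as _sk_resize

from . import nn
from .dqn import QNetworkSpec, build_conv_net
from .preprocess import BoundingBox

__all__ = [
    "LossConfig",
    "ClassifierConfig",
    "crop_and_resize",
    "cross_entropy_C1",
    "contrastive_C2",
    "integrated_loss",
    "integrated_loss_grad",
    "build_roi_net",
    "build_global_net",
    "build_fusion_net",
    "FusionNet",
    "train_classifier",
    "predict",
    "FAST_CLASSIFIER_CONFIG",
]

_CLAMP = 1e-7


@dataclass(frozen=True)
class LossConfig:
    margin: float = 2.0
    contrastive_weight: float = 2.0
    tie_threshold: float = 0.5  # score >= threshold -> positive class

    def __post_init__(self) -> None:
        if self.margin <= 0:
            raise ValueError("margin must be positive")


@dataclass(frozen=True)
class ClassifierConfig:
    epochs: int = 60
    lr: float = 9e-5
    roi_feature_dim: int = 512
    global_feature_dim: int = 1024
    batch_size: int = 16
    crop_size: tuple[int, int] = (256, 256)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("epochs", "roi_feature_dim", "global_feature_dim", "batch_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.lr <= 0:
            raise ValueError("lr must be positive")


#: Scaled-down profile: 64x64 crops and a learning rate sized for ~100 updates.
FAST_CLASSIFIER_CONFIG = ClassifierConfig(epochs=20, lr=1e-3, crop_size=(64, 64))


def crop_and_resize(
    image: np.ndarray, box: BoundingBox, size: tuple[int, int] = (256, 256)
) -> np.ndarray:
    """Bilinear resize of the boxed region to ``size`` (default 256x256)."""
    if not box.within(image.shape):
        raise ValueError(f"box {box} lies outside image of shape {image.shape}")
    patch = image[box.as_slices()[-2:]] if not box.is_3d else image[box.as_slices()]
    if patch.size == 0:
        raise ValueError("degenerate box: empty crop")
    if patch.shape[-2:] == tuple(size) and patch.ndim == 2:
        return patch.astype(float).copy()
    if patch.ndim == 2:
        return _sk_resize(patch.astype(float), size, order=1, anti_aliasing=False,
                          preserve_range=True)
    return _sk_resize(patch.astype(float), (patch.shape[0],) + tuple(size), order=1,
                      anti_aliasing=False, preserve_range=True)


def _clamp(scores: np.ndarray) -> np.ndarray:
    return np.clip(np.asarray(scores, dtype=float), _CLAMP, 1.0 - _CLAMP)


def _check_batch(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels, dtype=float).ravel()
    if scores.shape != labels.shape or scores.size == 0:
        raise ValueError("scores and labels must be equal-length and non-empty")
    if not np.isin(labels, (0.0, 1.0)).all():
        raise ValueError("labels must be binary")
    return scores, labels


def cross_entropy_C1(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mean binary cross-entropy (scores clamped at 1e-7 for log safety)."""
    s, y = _check_batch(scores, labels)
    s = _clamp(s)
    return float(-np.mean(y * np.log(s) + (1.0 - y) * np.log(1.0 - s)))


def contrastive_C2(scores: np.ndarray, labels: np.ndarray,
                   config: LossConfig = LossConfig()) -> float:
    """Mean of (1-y) * s^2 + m * y * max(1-s, 0)^2."""
    s, y = _check_batch(scores, labels)
    return float(
        np.mean((1.0 - y) * s**2 + config.margin * y * np.clip(1.0 - s, 0.0, None) ** 2)
    )


def integrated_loss(scores: np.ndarray, labels: np.ndarray,
                    config: LossConfig = LossConfig()) -> float:
    """C1 + 2*C2 (the contrastive weight is part of the objective)."""
    return cross_entropy_C1(scores, labels) + config.contrastive_weight * contrastive_C2(
        scores, labels, config
    )


def integrated_loss_grad(scores: np.ndarray, labels: np.ndarray,
                         config: LossConfig = LossConfig()) -> tuple[float, np.ndarray]:
    """Loss value and d(loss)/d(score) for training (mean over the batch)."""
    s, y = _check_batch(scores, labels)
    n = s.size
    sc = _clamp(s)
    loss = integrated_loss(s, y, config)
    dce = -(y / sc - (1.0 - y) / (1.0 - sc)) / n
    dc2 = (2.0 * (1.0 - y) * s - 2.0 * config.margin * y * np.clip(1.0 - s, 0.0, None)) / n
    return loss, dce + config.contrastive_weight * dc2


def build_roi_net(
    mode: str = "2d",
    config: ClassifierConfig = ClassifierConfig(),
    input_shape: tuple[int, ...] | None = None,
    head: str = "classifier",
    spec: QNetworkSpec = QNetworkSpec(),
    seed_offset: int = 1,
) -> nn.Sequential:
    """ROI classifier / feature extractor over the localized crop.

    ``head='classifier'`` ends in a single sigmoid unit; ``head='feature'``
    emits ``roi_feature_dim`` sigmoid features for the Fusion Net.
    """
    if input_shape is None:
        input_shape = ((1,) + config.crop_size) if mode == "2d" else (1, 50) + config.crop_size
    out = 1 if head == "classifier" else config.roi_feature_dim
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, seed_offset)))
    return build_conv_net(spec, input_shape, out, rng, sigmoid_head=True)


def build_global_net(
    mode: str = "2d",
    config: ClassifierConfig = ClassifierConfig(),
    input_shape: tuple[int, ...] | None = None,
    head: str = "feature",
    spec: QNetworkSpec = QNetworkSpec(),
) -> nn.Sequential:
    """Whole-slice feature extractor (``global_feature_dim`` sigmoid features)."""
    if input_shape is None:
        input_shape = ((1,) + config.crop_size) if mode == "2d" else (1, 145) + config.crop_size
    out = 1 if head == "classifier" else config.global_feature_dim
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 2)))
    return build_conv_net(spec, input_shape, out, rng, sigmoid_head=True)


class FusionNet:
    """ROI + Global feature extractors feeding a two-layer dense head.

    The concatenated feature vector (512 + 1024 by default) passes through
    Dense(256) + ReLU and a single sigmoid output unit.  Training is
    end-to-end through both extractors.
    """

    def __init__(self, roi_net: nn.Sequential, global_net: nn.Sequential,
                 roi_dim: int, global_dim: int, seed: int = 0) -> None:
        if roi_dim < 1 or global_dim < 1:
            raise ValueError("feature dimensions must be positive")
        self.roi_net = roi_net
        self.global_net = global_net
        self.roi_dim = roi_dim
        self.global_dim = global_dim
        rng = np.random.default_rng(np.random.SeedSequence((seed, 3)))
        self.head = nn.Sequential(
            [
                nn.Dense(roi_dim + global_dim, 256, rng),
                nn.ReLU(),
                nn.Dense(256, 1, rng),
                nn.Sigmoid(),
            ]
        )

    #: when True, gradients stop at the concatenated features and only the
    #: dense head trains (the extractors stay frozen)
    freeze_extractors: bool = False

    def forward(self, crops: np.ndarray, slices: np.ndarray) -> np.ndarray:
        fr = self.roi_net.forward(crops)
        fg = self.global_net.forward(slices)
        if fr.shape[1] != self.roi_dim or fg.shape[1] != self.global_dim:
            raise ValueError(
                f"feature dims ({fr.shape[1]}, {fg.shape[1]}) do not match the "
                f"configured ({self.roi_dim}, {self.global_dim})"
            )
        self._split = fr.shape[1]
        return self.head.forward(np.concatenate([fr, fg], axis=1))

    def backward(self, dy: np.ndarray) -> None:
        dcat = self.head.backward(dy)
        if not self.freeze_extractors:
            self.roi_net.backward(dcat[:, : self._split])
            self.global_net.backward(dcat[:, self._split :])

    def params(self) -> list[nn.Param]:
        return self.roi_net.params() + self.global_net.params() + self.head.params()

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0


@dataclass
class TrainedClassifier:
    model: object  # nn.Sequential or FusionNet
    config: ClassifierConfig
    loss_config: LossConfig
    history: list[float]
    fusion: bool = False


def _as_batch(images: np.ndarray) -> np.ndarray:
    images = np.asarray(images, dtype=np.float32)
    if images.ndim == 3:  # (B, H, W) -> add channel axis
        images = images[:, None, :, :]
    elif images.ndim == 4 and images.shape[1] != 1:
        images = images[:, None, ...]
    return images


def train_classifier(
    inputs,
    labels: Sequence[int],
    config: ClassifierConfig = ClassifierConfig(),
    loss_config: LossConfig = LossConfig(),
    model=None,
    mode: str = "roi",
    freeze_extractors: bool = False,
) -> TrainedClassifier:
    """Minimize the integrated loss with Adam minibatches.

    ``mode='roi'`` (or ``'global'``) trains a single conv net on ``inputs`` as
    an array of images; ``mode='fusion'`` expects ``inputs = (crops, slices)``
    and trains a :class:`FusionNet` — end-to-end by default, or head-only when
    ``freeze_extractors`` is set.  The history records the mean per-epoch
    training loss.  Requires both classes in ``labels``.
    """
    y = np.asarray(labels, dtype=float).ravel()
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    fusion = mode == "fusion"
    if fusion:
        crops, slices = (_as_batch(inputs[0]), _as_batch(inputs[1]))
        n = crops.shape[0]
    else:
        images = _as_batch(inputs)
        n = images.shape[0]
    if n != y.size:
        raise ValueError("inputs and labels length mismatch")
    if model is None:
        if fusion:
            roi = build_roi_net("2d", config, input_shape=crops.shape[1:], head="feature")
            glob = build_global_net("2d", config, input_shape=slices.shape[1:], head="feature")
            model = FusionNet(roi, glob, config.roi_feature_dim,
                              config.global_feature_dim, seed=config.seed)
            model.freeze_extractors = freeze_extractors
            model._roi_input_shape = tuple(crops.shape[1:])
            model._global_input_shape = tuple(slices.shape[1:])
        else:
            model = build_roi_net("2d", config, input_shape=images.shape[1:],
                                  head="classifier")
            model._input_shape = tuple(images.shape[1:])
    optimizer = nn.Adam(model.params(), lr=config.lr)
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 4)))
    history = []
    for _ in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for i in range(0, n, config.batch_size):
            idx = order[i : i + config.batch_size]
            yb = y[idx]
            if fusion:
                scores = model.forward(crops[idx], slices[idx])[:, 0]
            else:
                scores = model.forward(images[idx])[:, 0]
            loss, dscore = integrated_loss_grad(scores, yb, loss_config)
            model.zero_grad()
            if fusion:
                model.backward(dscore[:, None].astype(np.float32))
            else:
                model.backward(dscore[:, None].astype(np.float32))
            optimizer.step()
            losses.append(loss)
        history.append(float(np.mean(losses)))
    return TrainedClassifier(model=model, config=config, loss_config=loss_config,
                             history=history, fusion=fusion)


def save_classifier(clf: TrainedClassifier, path) -> None:
    """Checkpoint a trained classifier (architecture metadata + weights)."""
    import dataclasses as _dc
    import json as _json

    if clf.fusion:
        params = clf.model.params()
        shapes = dict(roi=clf.model._roi_input_shape, glob=clf.model._global_input_shape)
    else:
        params = clf.model.params()
        shapes = dict(input=clf.model._input_shape)
    meta = dict(
        fusion=clf.fusion,
        config=_dc.asdict(clf.config),
        loss_config=_dc.asdict(clf.loss_config),
        shapes={k: list(v) for k, v in shapes.items()},
        history=clf.history,
    )
    np.savez_compressed(path, meta=_json.dumps(meta),
                        **{f"p{i}": p.value for i, p in enumerate(params)})


def load_classifier(path) -> TrainedClassifier:
    import json as _json

    data = np.load(path, allow_pickle=False)
    meta = _json.loads(str(data["meta"]))
    cfg_d = dict(meta["config"])
    cfg_d["crop_size"] = tuple(cfg_d["crop_size"])
    config = ClassifierConfig(**cfg_d)
    loss_config = LossConfig(**meta["loss_config"])
    if meta["fusion"]:
        roi = build_roi_net("2d", config, input_shape=tuple(meta["shapes"]["roi"]),
                            head="feature")
        glob = build_global_net("2d", config, input_shape=tuple(meta["shapes"]["glob"]),
                                head="feature")
        model = FusionNet(roi, glob, config.roi_feature_dim, config.global_feature_dim,
                          seed=config.seed)
        model._roi_input_shape = tuple(meta["shapes"]["roi"])
        model._global_input_shape = tuple(meta["shapes"]["glob"])
        params = model.params()
    else:
        model = build_roi_net("2d", config, input_shape=tuple(meta["shapes"]["input"]),
                              head="classifier")
        model._input_shape = tuple(meta["shapes"]["input"])
        params = model.params()
    weights = [data[f"p{i}"] for i in range(len(params))]
    for p, w in zip(params, weights):
        p.value[...] = w
    return TrainedClassifier(model=model, config=config, loss_config=loss_config,
                             history=list(meta["history"]), fusion=meta["fusion"])


def predict(clf: TrainedClassifier, inputs) -> tuple[np.ndarray, np.ndarray]:
    """Scores in (0,1) and hard labels (score >= 0.5 -> class 1)."""
    if clf.fusion:
        scores = clf.model.forward(_as_batch(inputs[0]), _as_batch(inputs[1]))[:, 0]
    else:
        scores = clf.model.forward(_as_batch(inputs))[:, 0]
    return scores, (scores >= clf.loss_config.tie_threshold).astype(int)
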