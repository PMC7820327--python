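"""Binary DR/healthy classifier: residual network + class weighting + CAM.

The classification head follows the residual-network family: a convolutional
stem, strided residual stages, global average pooling (GAP) and a single
linear layer over two logits.  Depth is parameterized — ``"34"``/``"18"``
give the standard stage layouts, ``"reduced"`` a narrow three-stage variant
that trains on a desk CPU — so the same code serves full-scale and test-scale
runs.

Class imbalance is handled by weighting the cross-entropy loss with
``N / count(class)`` where ``N`` is the minority-class training count, so the
minority class always has weight exactly 1.  Optimization is SGD with
momentum 0.9 at learning rate 1e-3, decayed by 0.1 every 7 epochs, for 25
epochs (defaults).

Because the head is GAP + linear, class activation maps (CAM) are the
weighted sum of the final convolutional feature maps with that class's linear
weights, upsampled to the input size.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from skimage.transform import resize

from . import nn
from .errors import UnsupportedArchitectureError, ValidationError

# residual blocks per stage for the named depths
STAGE_LAYOUTS = {
    "reduced": ((1, 1, 1), 8),      # (blocks per stage, base width)
    "18": ((2, 2, 2, 2), 64),
    "34": ((3, 4, 6, 3), 64),
}


@dataclass
class ClsTrainConfig:
    learning_rate: float = 1e-3
    momentum: float = 0.9
    lr_decay_factor: float = 0.1
    lr_decay_every: int = 7
    epochs: int = 25
    depth: str = "34"
    input_size: int = 64          # square model input; crops are resized to this
    batch_size: int = 4
    pretrained: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.epochs < 1:
            raise ValidationError("epochs must be >= 1")
        for name in ("learning_rate", "momentum", "lr_decay_factor"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if self.lr_decay_every < 1:
            raise ValidationError("lr_decay_every must be >= 1")
        if self.depth not in STAGE_LAYOUTS:
            raise ValidationError(f"depth must be one of {sorted(STAGE_LAYOUTS)}")


@dataclass
class ClassWeights:
    """Per-class loss weights from the minority-class count N."""

    n_minority: int
    weight_per_class: Dict[int, float]

    def as_array(self, n_classes: int) -> np.ndarray:
        return np.array([self.weight_per_class[c] for c in range(n_classes)])


def compute_class_weights(labels: Sequence[int]) -> ClassWeights:
    """``weight(c) = N / count(c)`` with N the minority-class count."""
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValidationError("need at least one sample of every class (>= 2 classes)")
    n_min = int(counts.min())
    return ClassWeights(
        n_minority=n_min,
        weight_per_class={int(c): n_min / int(k) for c, k in zip(classes, counts)},
    )


def lr_schedule(epoch: int, config: ClsTrainConfig) -> float:
    """Step decay: ``lr * factor^floor(epoch / every)``."""
    if epoch < 0:
        raise ValidationError("epoch must be >= 0")
    return config.learning_rate * config.lr_decay_factor ** (epoch // config.lr_decay_every)


class ResNetClassifier(nn.Module):
    """Stem + residual stages + GAP + linear, exposing features for CAM."""

    def __init__(self, depth: str = "reduced", in_ch: int = 3, n_classes: int = 2,
                 seed: int = 0):
        rng = np.random.default_rng(seed)
        blocks_per_stage, base = STAGE_LAYOUTS[depth]
        self.stem = nn.Conv2d(in_ch, base, 3, 1, rng, bias=False)
        self.stem_bn = nn.BatchNorm2d(base)
        self.stem_relu = nn.ReLU()
        self.blocks: List[nn.ResidualBlock] = []
        ch = base
        for stage, n_blocks in enumerate(blocks_per_stage):
            out_ch = base * (2 ** stage)
            for b in range(n_blocks):
                stride = 2 if b == 0 else 1
                self.blocks.append(nn.ResidualBlock(ch, out_ch, stride, rng))
                ch = out_ch
        self.gap = nn.GlobalAvgPool()
        self.fc = nn.Linear(ch, n_classes, rng)
        self.feature_channels = ch
        self._features: Optional[np.ndarray] = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        f = self.stem_relu.forward(self.stem_bn.forward(self.stem.forward(x)))
        for blk in self.blocks:
            f = blk.forward(f)
        self._features = f  # final conv feature maps, pre-GAP (for CAM)
        return self.fc.forward(self.gap.forward(f))

    def backward(self, g: np.ndarray) -> np.ndarray:
        g = self.gap.backward(self.fc.backward(g))
        for blk in reversed(self.blocks):
            g = blk.backward(g)
        return self.stem.backward(self.stem_bn.backward(self.stem_relu.backward(g)))


@dataclass
class ClsModel:
    net: ResNetClassifier
    config: ClsTrainConfig
    loss_history: List[float] = field(default_factory=list)

    def save(self, path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        np.savez(path.with_suffix(".npz"), *self.net.state())
        path.with_suffix(".json").write_text(json.dumps(
            {"config": asdict(self.config), "loss_history": self.loss_history}, indent=2))

    @classmethod
    def load(cls, path) -> "ClsModel":
        path = Path(path)
        manifest = json.loads(path.with_suffix(".json").read_text())
        config = ClsTrainConfig(**manifest["config"])
        net = ResNetClassifier(config.depth, seed=config.seed)
        with np.load(path.with_suffix(".npz")) as z:
            net.load_state([z[k] for k in z.files])
        return cls(net=net, config=config, loss_history=manifest["loss_history"])


def _to_input(crop_image: np.ndarray, input_size: int) -> np.ndarray:
    arr = np.asarray(crop_image, dtype=np.float32)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValidationError(f"expected HxWx3 crop, got shape {arr.shape}")
    h, w = arr.shape[:2]
    if h % input_size == 0 and w % input_size == 0:
        # exact block-mean pooling: proper anti-aliased downsampling, fast
        fh, fw = h // input_size, w // input_size
        small = arr.reshape(input_size, fh, input_size, fw, 3).mean(axis=(1, 3))
    else:
        small = resize(arr, (input_size, input_size), order=3, preserve_range=True,
                       anti_aliasing=h > input_size)
    return (np.clip(small, 0, 255) / 255.0).astype(np.float32).transpose(2, 0, 1)


def prepare_inputs(crops: Sequence, input_size: int) -> np.ndarray:
    """Stack field crops (FieldCrop or raw HxWx3 arrays) into a batch tensor."""
    imgs = [c.image if hasattr(c, "image") else c for c in crops]
    return np.stack([_to_input(im, input_size) for im in imgs])


def train_classifier(data: Sequence[Tuple[object, int]],
                     config: Optional[ClsTrainConfig] = None,
                     log=None) -> ClsModel:
    """Train on (crop, label) pairs with minority-count class weighting."""
    config = config or ClsTrainConfig()
    config.validate()
    if len(data) < 2:
        raise ValidationError("need at least 2 training samples")
    labels = np.array([int(lab) for _, lab in data])
    X = prepare_inputs([c for c, _ in data], config.input_size)
    return _train_on_tensors(X, labels, config, log=log)


def _train_on_tensors(X: np.ndarray, labels: np.ndarray,
                      config: ClsTrainConfig, log=None) -> ClsModel:
    """Training loop on an already-preprocessed (N, 3, S, S) batch tensor."""
    weights = compute_class_weights(labels).as_array(2)
    net = ResNetClassifier(config.depth, seed=config.seed)
    net.set_training(True)
    opt = nn.SGD(net.params(), lr=config.learning_rate, momentum=config.momentum)
    rng = np.random.default_rng(config.seed)
    history: List[float] = []
    n = len(labels)
    for epoch in range(config.epochs):
        opt.lr = lr_schedule(epoch, config)
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            net.zero_grad()
            logits = net.forward(X[idx])
            loss, dz = nn.weighted_cross_entropy(logits, labels[idx], weights)
            net.backward(dz)
            opt.step()
            losses.append(loss)
        history.append(float(np.mean(losses)))
        if log is not None:
            log(f"epoch {epoch + 1}/{config.epochs} lr={opt.lr:.2e} loss={history[-1]:.4f}")
    return ClsModel(net=net, config=config, loss_history=history)


def _scores_on_tensors(model: ClsModel, X: np.ndarray) -> np.ndarray:
    model.net.set_training(False)
    out = []
    for start in range(0, len(X), 64):
        out.append(nn.softmax(model.net.forward(X[start:start + 64]))[:, 1])
    return np.concatenate(out) if out else np.zeros(0)


def predict_scores(model: ClsModel, crops: Sequence) -> np.ndarray:
    """DR probability (softmax of class-1 logit) per crop, order-preserving."""
    if len(crops) == 0:
        return np.zeros(0)
    model.net.set_training(False)
    out = []
    for start in range(0, len(crops), 64):
        X = prepare_inputs(crops[start:start + 64], model.config.input_size)
        out.append(nn.softmax(model.net.forward(X))[:, 1])
    return np.concatenate(out)


@dataclass
class CamMap:
    """Class activation map, upsampled to the classifier input size."""

    grid: np.ndarray
    class_index: int


def compute_cam(model: ClsModel, crop, class_index: int = 1) -> CamMap:
    """CAM = sum_k w[class, k] * F_k over the final conv feature maps."""
    net = model.net
    if not (hasattr(net, "fc") and hasattr(net, "gap")):
        raise UnsupportedArchitectureError(
            "CAM requires a global-average-pooling head with a linear layer")
    net.set_training(False)
    X = prepare_inputs([crop], model.config.input_size)
    net.forward(X)
    feats = net._features[0]                   # (C, h, w)
    w = net.fc.W.data[class_index]             # (C,)
    cam = np.tensordot(w, feats, axes=([0], [0]))
    up = resize(cam, (model.config.input_size, model.config.input_size),
                order=1, preserve_range=True)
    return CamMap(grid=up.astype(np.float64), class_index=int(class_index))
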