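"""VGG16-CBAM fine-grained classifier and analytic parameter/MAC accounting.

The network is a VGG16 backbone with batch normalization after every
convolution, extended with two residual attention blocks inserted after the
third and fourth max-pooling stages.  Each block wraps a 7×7 convolution and
a convolutional block attention module (CBAM) in an identity skip:

    out = ReLU( x + CBAM( Conv_{7x7}(x) ) )

CBAM applies channel attention (global max/avg pooling through a shared
bottleneck perceptron, summed, sigmoid) followed by spatial attention
(per-pixel channel max/mean, 7×7 convolution over the 2-channel map,
sigmoid).  The classifier head replaces VGG's fully connected stack with a
1×1 convolution to 1024 channels, global average pooling, and a single
affine map to the class scores — this is what shrinks the model to ~22.7%
of the reference VGG16's parameters.

Design conventions that pin down the parameter count (31,353,869 with the
defaults): the attention perceptrons carry no bias terms, the spatial-
attention convolution does, the residual blocks and head contain no
normalization layers, and the block convolutions carry biases.

MAC accounting counts one multiply–accumulate per kernel-element per output
element of every convolution and affine layer; pooling, normalization and
activations are excluded.  ``FLOPs`` figures in the literature are either
1× or 2× this number depending on convention.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nn
from .nn import Tensor

__all__ = [
    "ModelConfig", "LayerBudget", "ChannelAttention", "SpatialAttention",
    "CBAM", "ResidualCBAMBlock", "VGG16CBAM", "VGG16Reference",
    "build_vgg16_cbam", "build_reference_vgg16", "count_parameters",
    "count_macs", "layer_budget", "softmax", "save_checkpoint",
    "load_checkpoint",
]

# Channel plan of the VGG16 convolutional backbone; "M" is a 2x2 max pool.
_VGG16_PLAN = [64, 64, "M", 128, 128, "M", 256, 256, 256, "M",
               512, 512, 512, "M", 512, 512, 512, "M"]

MIN_INPUT_SIZE = 32  # five 2x2 poolings must leave >= 1 pixel


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    Defaults reproduce the published configuration: 7 *Rhinolophus* classes,
    channel-attention bottleneck ratio 16, 7×7 spatial-attention and
    residual-block kernels, residual blocks at 256 and 512 channels, and a
    1024-channel 1×1 head convolution.
    """

    num_classes: int = 7
    reduction_ratio: int = 16
    sam_kernel: int = 7
    block_channels: tuple[int, int] = (256, 512)
    block_kernel: int = 7
    head_channels: int = 1024
    input_size: tuple[int, int] = (224, 224)

    def __post_init__(self):
        if self.num_classes < 2:
            raise ValueError("num_classes must be >= 2")
        if self.reduction_ratio < 1:
            raise ValueError("reduction_ratio must be positive")
        for c in self.block_channels:
            if c % self.reduction_ratio:
                raise ValueError(
                    f"reduction_ratio {self.reduction_ratio} must divide "
                    f"block channel width {c}")
        for k in (self.sam_kernel, self.block_kernel):
            if k % 2 == 0:
                raise ValueError("kernel sizes must be odd for same padding")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        for key in ("block_channels", "input_size"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class LayerBudget:
    name: str
    param_count: int
    mac_count: int
    out_shape: tuple[int, ...] | None = None


def _check_feature_map(x: Tensor) -> None:
    if x.ndim != 4:
        raise ValueError(f"expected a rank-4 (N,C,H,W) feature map, got {x.shape}")
    if not np.isfinite(x.data).all():
        raise ValueError("feature map contains non-finite values")


class ChannelAttention(nn.Module):
    """Channel attention: spatial max/avg squeeze -> shared perceptron -> sigmoid.

    The two pooled descriptors pass through one shared two-layer perceptron
    C -> C/r -> C (ReLU in between, no biases); the outputs are summed and
    squashed, giving per-channel weights in (0, 1) of shape (N, C, 1, 1).
    """

    def __init__(self, channels: int, reduction_ratio: int):
        super().__init__()
        if channels % reduction_ratio:
            raise ValueError(
                f"channels {channels} not divisible by reduction ratio "
                f"{reduction_ratio}")
        self.channels = channels
        self.fc1 = nn.Linear(channels, channels // reduction_ratio, bias=False)
        self.fc2 = nn.Linear(channels // reduction_ratio, channels, bias=False)

    def forward(self, x: Tensor) -> Tensor:
        _check_feature_map(x)
        if x.shape[1] != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {x.shape[1]}")
        avg = x.mean(axis=(2, 3))
        mx = x.amax(axis=(2, 3))
        a = self.fc2(self.fc1(avg).relu()) + self.fc2(self.fc1(mx).relu())
        n, c = a.shape
        return a.sigmoid().reshape(n, c, 1, 1)


class SpatialAttention(nn.Module):
    """Spatial attention: channel max/mean -> k×k conv on the 2-channel map -> sigmoid."""

    def __init__(self, kernel_size: int = 7):
        super().__init__()
        if kernel_size % 2 == 0:
            raise ValueError("spatial-attention kernel must be odd")
        self.conv = nn.Conv2d(2, 1, kernel_size, padding=kernel_size // 2, bias=True)

    def forward(self, x: Tensor) -> Tensor:
        _check_feature_map(x)
        mx = x.amax(axis=1, keepdims=True)
        avg = x.mean(axis=1, keepdims=True)
        return self.conv(nn.concat([mx, avg], axis=1)).sigmoid()


class CBAM(nn.Module):
    """Sequential channel-then-spatial attention refinement of a feature map.

    After each forward pass the attention maps are kept on
    ``last_channel_weights`` / ``last_spatial_weights`` for inspection.
    """

    def __init__(self, channels: int, reduction_ratio: int = 16, sam_kernel: int = 7):
        super().__init__()
        self.channel = ChannelAttention(channels, reduction_ratio)
        self.spatial = SpatialAttention(sam_kernel)
        self.last_channel_weights: Tensor | None = None
        self.last_spatial_weights: Tensor | None = None

    def forward(self, x: Tensor) -> Tensor:
        cw = self.channel(x)
        x = x * cw
        sw = self.spatial(x)
        out = x * sw
        object.__setattr__(self, "last_channel_weights", cw)
        object.__setattr__(self, "last_spatial_weights", sw)
        return out


class ResidualCBAMBlock(nn.Module):
    """Identity-skip block: ReLU( x + CBAM( Conv_{k×k}(x) ) ).

    The convolution preserves the channel count and spatial shape (same
    padding, stride 1, bias); the skip gives the attention block a direct
    gradient path.
    """

    def __init__(self, channels: int, kernel_size: int = 7,
                 reduction_ratio: int = 16, sam_kernel: int = 7):
        super().__init__()
        self.channels = channels
        self.conv = nn.Conv2d(channels, channels, kernel_size,
                              padding=kernel_size // 2, bias=True)
        self.cbam = CBAM(channels, reduction_ratio, sam_kernel)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.channels:
            raise ValueError(
                f"residual block expects {self.channels} channels, got {x.shape[1]}")
        return (x + self.cbam(self.conv(x))).relu()


class _ConvBNReLU(nn.Module):
    def __init__(self, cin: int, cout: int):
        super().__init__()
        self.conv = nn.Conv2d(cin, cout, 3, padding=1, bias=True)
        self.bn = nn.BatchNorm2d(cout)

    def forward(self, x: Tensor) -> Tensor:
        return self.bn(self.conv(x)).relu()


def _make_backbone() -> list[nn.Module]:
    layers: list[nn.Module] = []
    cin = 3
    for item in _VGG16_PLAN:
        if item == "M":
            layers.append(nn.MaxPool2d(2))
        else:
            layers.append(_ConvBNReLU(cin, item))
            cin = item
    return layers


class VGG16CBAM(nn.Module):
    """VGG16-BN backbone with residual CBAM blocks and a convolutional head.

    ``forward`` returns pre-softmax class scores; intermediate activations
    are recorded per forward pass in ``activations`` (keyed by layer name)
    so saliency methods can read both the value and, after a backward pass,
    the gradient of any convolutional feature map.  The network is fully
    convolutional up to global average pooling and accepts any input of at
    least 32×32 pixels.
    """

    def __init__(self, config: ModelConfig):
        super().__init__()
        self.config = config
        backbone = _make_backbone()
        # insert residual attention blocks after pool 3 and pool 4
        c1, c2 = config.block_channels
        pools = [i for i, m in enumerate(backbone) if isinstance(m, nn.MaxPool2d)]
        block1 = ResidualCBAMBlock(c1, config.block_kernel,
                                   config.reduction_ratio, config.sam_kernel)
        block2 = ResidualCBAMBlock(c2, config.block_kernel,
                                   config.reduction_ratio, config.sam_kernel)
        backbone.insert(pools[2] + 1, block1)
        backbone.insert(pools[3] + 2, block2)
        self.features = nn.Sequential(*backbone)
        self.head_conv = nn.Conv2d(512, config.head_channels, 1, bias=True)
        self.classifier = nn.Linear(config.head_channels, config.num_classes,
                                    bias=True)
        self.activations: dict[str, Tensor] = {}
        self._layer_names = self._name_features()

    def _name_features(self) -> list[str]:
        names = []
        stage, conv_in_stage = 1, 0
        for m in self.features:
            if isinstance(m, nn.MaxPool2d):
                names.append(f"pool{stage}")
                stage += 1
                conv_in_stage = 0
            elif isinstance(m, ResidualCBAMBlock):
                names.append(f"block{stage - 1}")
            else:
                conv_in_stage += 1
                names.append(f"stage{stage}.conv{conv_in_stage}")
        return names

    def gradcam_layers(self) -> list[str]:
        """Names of feature maps a saliency call may target."""
        return [n for n in self._layer_names if not n.startswith("pool")]

    @property
    def default_gradcam_layer(self) -> str:
        return "stage5.conv3"

    def forward(self, x: Tensor | np.ndarray) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(x)
        if x.ndim != 4 or x.shape[1] != 3:
            raise ValueError(f"expected (N, 3, H, W) input, got {x.shape}")
        if min(x.shape[2], x.shape[3]) < MIN_INPUT_SIZE:
            raise ValueError(
                f"input must be at least {MIN_INPUT_SIZE}px on each side")
        acts: dict[str, Tensor] = {}
        for name, m in zip(self._layer_names, self.features):
            x = m(x)
            acts[name] = x
        x = self.head_conv(x).relu()
        acts["head_conv"] = x
        x = x.mean(axis=(2, 3))  # global average pooling
        logits = self.classifier(x)
        object.__setattr__(self, "activations", acts)
        return logits

    def predict_proba(self, x: np.ndarray, batch_size: int = 16) -> np.ndarray:
        """Class probabilities (softmax over logits), batched, no autodiff."""
        self.eval()
        out = []
        with nn.no_grad():
            for i in range(0, len(x), batch_size):
                logits = self.forward(Tensor(x[i:i + batch_size]))
                out.append(softmax(logits.data))
        return np.concatenate(out, axis=0)


class VGG16Reference(nn.Module):
    """Stock VGG16 with batch normalization and the original three-layer
    fully connected classifier (4096 -> 4096 -> num_classes).

    With ``num_classes=1000`` the trainable-parameter count is the canonical
    138,365,992 ("138.37 M").  Dropout is omitted: it has no parameters and
    this reference exists for accounting and sanity forwards, not training.
    Requires 224×224 input (the classifier expects a 7×7×512 feature map).
    """

    def __init__(self, num_classes: int = 1000):
        super().__init__()
        self.num_classes = num_classes
        self.features = nn.Sequential(*_make_backbone())
        self.fc1 = nn.Linear(512 * 7 * 7, 4096)
        self.fc2 = nn.Linear(4096, 4096)
        self.fc3 = nn.Linear(4096, num_classes)

    def forward(self, x: Tensor | np.ndarray) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(x)
        x = self.features(x)
        n = x.shape[0]
        x = x.reshape(n, 512 * 7 * 7)
        x = self.fc1(x).relu()
        x = self.fc2(x).relu()
        return self.fc3(x)


def build_vgg16_cbam(config: ModelConfig | None = None,
                     init_seed: int = 0) -> VGG16CBAM:
    """Construct a VGG16-CBAM with He-uniform init from ``init_seed``."""
    config = config or ModelConfig()
    nn.manual_seed(init_seed)
    return VGG16CBAM(config)


def build_reference_vgg16(num_classes: int = 1000,
                          init_seed: int = 0) -> VGG16Reference:
    nn.manual_seed(init_seed)
    return VGG16Reference(num_classes)


def count_parameters(model: nn.Module) -> int:
    """Exact count of trainable scalars (BN running statistics excluded)."""
    return int(sum(p.data.size for p in model.parameters()))


def layer_budget(model: nn.Module,
                 input_size: tuple[int, int] = (224, 224)) -> list[LayerBudget]:
    """Per-layer parameter and MAC accounting from a real forward pass.

    MACs are output-elements × kernel-volume × input-channels for every
    convolution and affine layer at batch size 1; all other layers
    contribute zero MACs but still report their parameters.
    """
    leaves = [(name, m) for name, m in model.named_modules() if m._params]
    for name, m in leaves:
        object.__setattr__(m, "_prof_name", name)
    was_training = model.training
    model.eval()
    x = np.zeros((1, 3, input_size[0], input_size[1]), dtype=np.float32)
    with nn.no_grad(), nn.profiling() as records:
        model.forward(Tensor(x))
    model.train(was_training)
    macs: dict[str, int] = {}
    shapes: dict[str, tuple[int, ...]] = {}
    for r in records:
        macs[r.name] = macs.get(r.name, 0) + r.macs
        shapes[r.name] = r.out_shape
    rows = [LayerBudget(name, count_parameters(m), macs.get(name, 0),
                        shapes.get(name))
            for name, m in leaves]
    return rows


def count_macs(model: nn.Module,
               input_size: tuple[int, int] = (224, 224)) -> int:
    """Total multiply–accumulate operations for one forward pass."""
    return int(sum(r.mac_count for r in layer_budget(model, input_size)))


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def save_checkpoint(model: nn.Module, path: str | Path,
                    config: ModelConfig | None = None,
                    extra: dict | None = None) -> None:
    """Write weights as an ``.npz`` archive plus a JSON config sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **model.state_dict())
    config = config or getattr(model, "config", None)
    sidecar = {"model_config": config.to_dict() if config else None,
               "format": "noseleaf-npz-v1"}
    if extra:
        sidecar.update(extra)
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_checkpoint(path: str | Path) -> VGG16CBAM:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    if sidecar.get("model_config") is None:
        raise ValueError(f"checkpoint sidecar {path.with_suffix('.json')} "
                         "lacks a model_config")
    model = build_vgg16_cbam(ModelConfig.from_dict(sidecar["model_config"]))
    with np.load(path) as archive:
        model.load_state_dict(dict(archive))
    return model
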