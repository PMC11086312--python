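"""LTNet: a lightweight CNN for GAF-encoded gas-sensor images.

The architecture is a depthwise-separable ConvBN stem followed by a stack of
LTBlocks — each a run of ConvBN units with squeeze-and-excitation channel
attention and a residual connection, activated by hard-swish — then global
average pooling and a fully connected classification head.

Two parameter-accounting conventions are reported side by side:

* ``total`` — trainable tensors only (conv weights, BN gamma/beta, SE and FC
  weights and biases). This is the number quoted for model size.
* ``deployed_total`` — what an inference engine stores: conv weights plus
  all four BN per-channel vectors (gamma, beta, mean, variance) before
  fusion, or conv weights plus a bias after fusion. The conv-BN fusion
  saving of 3 * C_out per pair is expressed in this convention.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from importlib import resources

import numpy as np

from . import nn


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class LTBlockConfig:
    """One LTBlock: ``n_convbn`` depthwise-separable ConvBN units at width
    ``channels``, SE gating, and a residual skip around everything after the
    first unit (the skip source is the first unit's output, so it is always
    shape-compatible regardless of stride or channel change)."""

    channels: int
    n_convbn: int = 2
    se_ratio: int = 4
    use_residual: bool = True
    stride: int = 1

    def __post_init__(self):
        if self.channels < 1 or self.n_convbn < 1 or self.stride < 1:
            raise ValueError("channels, n_convbn and stride must be >= 1")
        if self.se_ratio < 1 or self.channels % self.se_ratio:
            raise ValueError(
                f"se_ratio {self.se_ratio} must divide channels {self.channels}")


@dataclass
class LTNetConfig:
    input_channels: int = 3
    input_size: tuple[int, int] = (16, 16)
    stem_channels: int = 32
    blocks: list[LTBlockConfig] = field(default_factory=list)
    n_classes: int = 3
    ablation_mode: str = "full"  # "full" or "original"
    bn_eps: float = 1e-5

    def __post_init__(self):
        if self.n_classes < 2:
            raise ValueError("need at least two classes")
        if self.ablation_mode not in ("full", "original"):
            raise ValueError("ablation_mode must be 'full' or 'original'")
        if self.input_channels not in (1, 3):
            raise ValueError("input_channels must be 1 or 3")
        self.blocks = [b if isinstance(b, LTBlockConfig) else LTBlockConfig(**b)
                       for b in self.blocks]
        self.input_size = tuple(self.input_size)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "LTNetConfig":
        return cls(**d)


def reference_config(ablation_mode: str = "full") -> LTNetConfig:
    """The frozen reference architecture shipped with the package."""
    with resources.files("ltnet.configs").joinpath("reference.json").open() as fh:
        d = json.load(fh)
    d["ablation_mode"] = ablation_mode
    return LTNetConfig.from_dict(d)


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

def _ds_convbn(in_ch, out_ch, stride, rng, name, eps, dtype):
    """Depthwise 3x3 ConvBN followed by pointwise 1x1 ConvBN, hard-swish after each."""
    return nn.Sequential(
        nn.Conv2d(in_ch, in_ch, 3, stride=stride, groups=in_ch, bias=False,
                  rng=rng, name=f"{name}.dw", dtype=dtype),
        nn.BatchNorm2d(in_ch, eps=eps, name=f"{name}.dw_bn", dtype=dtype),
        nn.Hswish(),
        nn.Conv2d(in_ch, out_ch, 1, bias=False, rng=rng, name=f"{name}.pw", dtype=dtype),
        nn.BatchNorm2d(out_ch, eps=eps, name=f"{name}.pw_bn", dtype=dtype),
        nn.Hswish(),
    )


def _std_convbn(in_ch, out_ch, stride, rng, name, eps, dtype):
    """Plain 3x3 ConvBN (the 'original' ablation's unit)."""
    return nn.Sequential(
        nn.Conv2d(in_ch, out_ch, 3, stride=stride, bias=False,
                  rng=rng, name=f"{name}.conv", dtype=dtype),
        nn.BatchNorm2d(out_ch, eps=eps, name=f"{name}.bn", dtype=dtype),
        nn.Hswish(),
    )


class LTBlock(nn.Layer):
    def __init__(self, in_ch: int, cfg: LTBlockConfig, full: bool,
                 rng, name: str, eps: float, dtype):
        make = _ds_convbn if full else _std_convbn
        self.units = [make(in_ch, cfg.channels, cfg.stride, rng, f"{name}.unit1", eps, dtype)]
        for i in range(1, cfg.n_convbn):
            self.units.append(make(cfg.channels, cfg.channels, 1, rng,
                                   f"{name}.unit{i + 1}", eps, dtype))
        self.se = (nn.SqueezeExcite(cfg.channels, cfg.se_ratio, rng=rng,
                                    name=f"{name}.se", dtype=dtype) if full else None)
        self.use_residual = cfg.use_residual and full

    def params(self):
        out = [p for u in self.units for p in u.params()]
        if self.se is not None:
            out += self.se.params()
        return out

    def forward(self, x, train=False):
        h = self.units[0].forward(x, train)
        z = h
        for u in self.units[1:]:
            z = u.forward(z, train)
        if self.se is not None:
            z = self.se.forward(z, train)
        return z + h if self.use_residual else z

    def backward(self, dy):
        dz = dy
        if self.se is not None:
            dz = self.se.backward(dz)
        for u in reversed(self.units[1:]):
            dz = u.backward(dz)
        if self.use_residual:
            dz = dz + dy
        return self.units[0].backward(dz)


class LTNet(nn.Layer):
    """The assembled network. ``forward`` maps (N, C, H, W) to (N, n_classes) logits."""

    def __init__(self, cfg: LTNetConfig, seed: int = 0, dtype=None):
        dtype = dtype or nn.DEFAULT_DTYPE
        rng = np.random.default_rng(seed)
        full = cfg.ablation_mode == "full"
        make = _ds_convbn if full else _std_convbn
        self.cfg = cfg
        self.stem = make(cfg.input_channels, cfg.stem_channels, 1, rng, "stem",
                         cfg.bn_eps, dtype)
        self.blocks = []
        in_ch = cfg.stem_channels
        for i, b in enumerate(cfg.blocks):
            self.blocks.append(LTBlock(in_ch, b, full, rng, f"block{i + 1}",
                                       cfg.bn_eps, dtype))
            in_ch = b.channels
        self.pool = nn.GlobalAvgPool()
        self.fc = nn.Linear(in_ch, cfg.n_classes, rng=rng, name="head.fc", dtype=dtype)

    def params(self):
        out = self.stem.params()
        for b in self.blocks:
            out += b.params()
        return out + self.fc.params()

    def forward(self, x, train=False):
        x = self.stem.forward(x, train)
        for b in self.blocks:
            x = b.forward(x, train)
        return self.fc.forward(self.pool.forward(x, train), train)

    def backward(self, dlogits):
        dy = self.pool.backward(self.fc.backward(dlogits))
        for b in reversed(self.blocks):
            dy = b.backward(dy)
        return self.stem.backward(dy)

    def predict(self, x, batch_size: int = 256) -> np.ndarray:
        """Class indices; ties break to the lowest index (first argmax)."""
        preds = []
        for i in range(0, len(x), batch_size):
            preds.append(np.argmax(self.forward(x[i:i + batch_size]), axis=1))
        return np.concatenate(preds) if preds else np.empty(0, dtype=int)

    # -- serialization ------------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {p.name: p.data.copy() for p in self.params()}
        for layer in self._all_layers():
            if isinstance(layer, nn.BatchNorm2d):
                state[layer.gamma.name.replace(".gamma", ".running_mean")] = layer.running_mean.copy()
                state[layer.gamma.name.replace(".gamma", ".running_var")] = layer.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]):
        for p in self.params():
            p.data = state[p.name].astype(p.data.dtype).copy()
        for layer in self._all_layers():
            if isinstance(layer, nn.BatchNorm2d):
                base = layer.gamma.name.replace(".gamma", "")
                layer.running_mean = state[f"{base}.running_mean"].copy()
                layer.running_var = state[f"{base}.running_var"].copy()

    def _iter_sequentials(self):
        """The conv-bearing Sequentials, in forward order (stem, block units)."""
        yield self.stem
        for b in self.blocks:
            yield from b.units

    def _all_layers(self):
        def walk(obj):
            if isinstance(obj, nn.Sequential):
                for l in obj.layers:
                    yield from walk(l)
            elif isinstance(obj, LTBlock):
                for u in obj.units:
                    yield from walk(u)
                if obj.se is not None:
                    yield obj.se
            else:
                yield obj
        yield from walk(self.stem)
        for b in self.blocks:
            yield from walk(b)
        yield self.fc

    def save(self, path):
        np.savez(path, **self.state_dict())

    def load(self, path):
        with np.load(path) as data:
            self.load_state_dict({k: data[k] for k in data.files})


def build_model(cfg: LTNetConfig, seed: int = 0, dtype=None) -> LTNet:
    """Build a seeded LTNet; identical (cfg, seed) give identical weights."""
    return LTNet(cfg, seed=seed, dtype=dtype)


# ---------------------------------------------------------------------------
# Parameter / FLOP accounting
# ---------------------------------------------------------------------------

def count_params_conv(k: int, c_in: int, c_out: int) -> int:
    """Weight count of a standard KxK convolution: K^2 * C_in * C_out."""
    return k * k * c_in * c_out


def count_params_dsc(k: int, c_in: int, c_out: int) -> int:
    """Weight count of a depthwise-separable convolution:
    K^2 * C_in (depthwise) + C_in * C_out (pointwise)."""
    return k * k * c_in + c_in * c_out


def count_flops(kind: str, h: int, w: int, k: int, c_in: int, c_out: int) -> int:
    """Multiply-accumulate count over an H x W output map.

    ``standard``: H*W*K^2*C_in*C_out; ``dsc``: H*W*(K^2*C_in + C_in*C_out).
    """
    if kind == "standard":
        return h * w * count_params_conv(k, c_in, c_out)
    if kind == "dsc":
        return h * w * count_params_dsc(k, c_in, c_out)
    raise ValueError("kind must be 'standard' or 'dsc'")


@dataclass
class ParamReport:
    per_layer: dict[str, int]
    total: int
    deployed_total: int
    flops: int | None = None

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def _iter_convbn_shapes(cfg: LTNetConfig):
    """Yield (name, kind, k, c_in, c_out, stride) for every conv+BN pair, in order."""
    full = cfg.ablation_mode == "full"

    def unit(name, c_in, c_out, stride):
        if full:
            yield (f"{name}.dw", "dw", 3, c_in, c_in, stride)
            yield (f"{name}.pw", "pw", 1, c_in, c_out, 1)
        else:
            yield (f"{name}.conv", "std", 3, c_in, c_out, stride)

    yield from unit("stem", cfg.input_channels, cfg.stem_channels, 1)
    c = cfg.stem_channels
    for i, b in enumerate(cfg.blocks):
        yield from unit(f"block{i + 1}.unit1", c, b.channels, b.stride)
        for j in range(1, b.n_convbn):
            yield from unit(f"block{i + 1}.unit{j + 1}", b.channels, b.channels, 1)
        c = b.channels


def count_params_model(cfg: LTNetConfig, flops_at: tuple[int, int] | None = None) -> ParamReport:
    """Analytic per-layer parameter breakdown for a configuration.

    Matches exactly the enumeration of trainable tensors in the built model;
    with global average pooling the total is independent of input size.
    """
    full = cfg.ablation_mode == "full"
    per_layer: dict[str, int] = {}
    deployed = 0
    for name, kind, k, c_in, c_out, _ in _iter_convbn_shapes(cfg):
        groups = c_in if kind == "dw" else 1
        w = k * k * (c_in // groups) * c_out
        per_layer[name] = w + 2 * c_out          # conv weight + BN gamma/beta
        deployed += w + 4 * c_out                # conv weight + 4 BN vectors
    if full:
        for i, b in enumerate(cfg.blocks):
            c, h = b.channels, b.channels // b.se_ratio
            n = (c * h + h) + (h * c + c)
            per_layer[f"block{i + 1}.se"] = n
            deployed += n
    last = cfg.blocks[-1].channels if cfg.blocks else cfg.stem_channels
    per_layer["head.fc"] = last * cfg.n_classes + cfg.n_classes
    deployed += per_layer["head.fc"]
    total = sum(per_layer.values())

    flops = None
    if flops_at is not None:
        h, w = flops_at
        flops = 0
        for _, kind, k, c_in, c_out, stride in _iter_convbn_shapes(cfg):
            h = -(-h // stride)
            w = -(-w // stride)
            groups = c_in if kind == "dw" else 1
            flops += h * w * k * k * (c_in // groups) * c_out
        if full:
            for b in cfg.blocks:
                c, hdn = b.channels, b.channels // b.se_ratio
                flops += 2 * c * hdn
        flops += last * cfg.n_classes
    return ParamReport(per_layer=per_layer, total=total,
                       deployed_total=deployed, flops=flops)


def enumerate_model_params(model: LTNet) -> int:
    """Independent count: sum of entries over the built model's trainable tensors."""
    return sum(p.size for p in model.params())
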