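"""Folding batch normalization into the preceding convolution.

At inference a BN layer is an affine per-channel map with frozen running
statistics, so a conv + BN pair collapses to a single convolution:

    W_f = gamma * W_c / sqrt(var + eps)        (per output channel)
    b_f = gamma * (b_c - mean) / sqrt(var + eps) + beta

Training always runs unfused; fusion is an inference-time transform. In
deployed-parameter terms each fused pair trades the four BN per-channel
vectors for one bias vector, a saving of exactly 3 * C_out.
"""

from __future__ import annotations

import copy
import hashlib
from dataclasses import dataclass

import numpy as np

from . import nn
from .model import LTNet


@dataclass
class FusedConvBN:
    W_f: np.ndarray
    b_f: np.ndarray
    provenance: str

    def __post_init__(self):
        if not (np.all(np.isfinite(self.W_f)) and np.all(np.isfinite(self.b_f))):
            raise ValueError("fused parameters must be finite")


def fuse(conv_weights: np.ndarray, conv_bias: np.ndarray | None,
         gamma: np.ndarray, beta: np.ndarray, mean: np.ndarray,
         var: np.ndarray, eps: float = 1e-5) -> FusedConvBN:
    """Fuse one conv + BN pair; ``conv_weights`` is (C_out, C_in/g, K, K)."""
    c_out = conv_weights.shape[0]
    for name, v in (("gamma", gamma), ("beta", beta), ("mean", mean), ("var", var)):
        if np.asarray(v).shape != (c_out,):
            raise ValueError(f"{name} must have length C_out={c_out}")
    if np.any(np.asarray(var) < 0):
        raise ValueError("variance must be nonnegative")
    if eps <= 0:
        raise ValueError("eps must be positive")
    if conv_bias is None:
        conv_bias = np.zeros(c_out, dtype=conv_weights.dtype)
    scale = gamma / np.sqrt(var + eps)
    w_f = conv_weights * scale[:, None, None, None]
    b_f = scale * (conv_bias - mean) + beta
    digest = hashlib.sha256(
        b"".join(np.ascontiguousarray(a, dtype=np.float64).tobytes()
                 for a in (conv_weights, conv_bias, gamma, beta, mean, var,
                           np.array([eps])))).hexdigest()[:16]
    return FusedConvBN(W_f=w_f.astype(conv_weights.dtype),
                       b_f=b_f.astype(conv_weights.dtype), provenance=digest)


def fusion_param_counts(k: int, c_in: int, c_out: int) -> tuple[int, int]:
    """Deployed parameter counts (pre-fusion, post-fusion) for one pair:

    U_p = C_out*C_in*K^2 + 4*C_out   (weights + gamma, beta, mean, var)
    F_p = C_out*C_in*K^2 + C_out     (weights + bias)

    The saving is always 3 * C_out.
    """
    w = c_out * c_in * k * k
    return w + 4 * c_out, w + c_out


def _fuse_sequential_inplace(seq: nn.Sequential) -> int:
    """Replace adjacent (Conv2d, BatchNorm2d) pairs inside a Sequential."""
    out_layers: list[nn.Layer] = []
    n_fused = 0
    i = 0
    while i < len(seq.layers):
        layer = seq.layers[i]
        nxt = seq.layers[i + 1] if i + 1 < len(seq.layers) else None
        if isinstance(layer, nn.Conv2d) and isinstance(nxt, nn.BatchNorm2d):
            fused = fuse(layer.weight.data,
                         layer.bias.data if layer.bias is not None else None,
                         nxt.gamma.data, nxt.beta.data,
                         nxt.running_mean, nxt.running_var, nxt.eps)
            layer.weight.data = fused.W_f
            layer.bias = nn.Param(layer.weight.name.replace(".weight", ".bias"),
                                  fused.b_f)
            out_layers.append(layer)
            n_fused += 1
            i += 2
        else:
            out_layers.append(layer)
            i += 1
    seq.layers = out_layers
    return n_fused


def fuse_model(model: LTNet) -> LTNet:
    """Return a fused copy of the model for inference.

    Every conv + BN pair becomes a single biased convolution; all other
    layers are untouched, so tensor shapes at module boundaries are
    preserved and eval-mode logits agree with the unfused model up to
    float round-off. Fusing an already-fused model is a no-op.
    """
    fused = copy.deepcopy(model)
    for seq in fused._iter_sequentials():
        _fuse_sequential_inplace(seq)
    return fused


def count_bn_channels(model: LTNet) -> int:
    """Sum of C_out over all remaining conv+BN pairs (0 after fusion)."""
    total = 0
    for seq in model._iter_sequentials():
        for a, b in zip(seq.layers, seq.layers[1:]):
            if isinstance(a, nn.Conv2d) and isinstance(b, nn.BatchNorm2d):
                total += b.channels
    return total


def deployed_param_total(model: LTNet) -> int:
    """Deployed storage count of the model under the fusion accounting:
    conv weights plus 4 per-channel BN vectors (unfused) or plus bias
    (fused); SE and FC tensors counted as stored."""
    total = 0
    for seq in model._iter_sequentials():
        i = 0
        while i < len(seq.layers):
            layer = seq.layers[i]
            nxt = seq.layers[i + 1] if i + 1 < len(seq.layers) else None
            if isinstance(layer, nn.Conv2d) and isinstance(nxt, nn.BatchNorm2d):
                total += layer.weight.size + 4 * nxt.channels
                if layer.bias is not None:
                    total += layer.bias.size
                i += 2
            else:
                total += sum(p.size for p in layer.params())
                i += 1
    for blk in model.blocks:
        if blk.se is not None:
            total += sum(p.size for p in blk.se.params())
    total += sum(p.size for p in model.fc.params())
    return total


def equivalence_report(model: LTNet, fused: LTNet, n_inputs: int = 100,
                       seed: int = 0) -> dict:
    """Max-abs logit deviation between unfused and fused models on random
    inputs, plus the deployed-parameter delta."""
    h, w = model.cfg.input_size
    rng = np.random.default_rng(seed)
    x = rng.uniform(0, 1, size=(n_inputs, model.cfg.input_channels, h, w)).astype(np.float32)
    max_dev = 0.0
    agree = True
    for i in range(0, n_inputs, 32):
        a = model.forward(x[i:i + 32])
        b = fused.forward(x[i:i + 32])
        max_dev = max(max_dev, float(np.abs(a - b).max()))
        agree = agree and bool(np.array_equal(a.argmax(1), b.argmax(1)))
    return {"max_abs_logit_deviation": max_dev,
            "argmax_agrees": agree,
            "deployed_params_unfused": deployed_param_total(model),
            "deployed_params_fused": deployed_param_total(fused),
            "param_delta": deployed_param_total(model) - deployed_param_total(fused)}
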