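"""Gramian Angular Field (and Markov Transition Field) encodings.

A snapshot — the 16 sensor readings of an e-nose array at one sampling
instant — is rescaled to [-1, 1] by min–max normalization,

    x~_i = ((x_i - max X) + (x_i - min X)) / (max X - min X),

mapped to polar angles phi_i = arccos(x~_i) in [0, pi], and expanded into a
Gramian matrix that exposes pairwise sensor relationships:

    GASF_ij = cos(phi_i + phi_j)      (symmetric; diagonal 2 x~_i^2 - 1)
    GADF_ij = sin(phi_i - phi_j)      (antisymmetric; zero diagonal)

The snapshot has no time axis, so no radial/timestamp encoding is used.
An MTF comparator (quantile-binned one-step transition probabilities along
the vector order) and a colormap renderer to H x W x 3 images are included.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

ARCCOS_CLAMP_TOL = 1e-12


class DegenerateSnapshotError(ValueError):
    """All sensor values equal: min–max normalization is undefined."""


@dataclass
class Snapshot:
    """One sensor-array reading: a length-n vector (n = 16 for the array
    used here) with an optional class label and provenance metadata."""

    values: np.ndarray
    class_label: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 2:
            raise ValueError("snapshot must be a 1-D vector of length >= 2")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("snapshot values must be finite")


@dataclass
class GafImage:
    matrix: np.ndarray
    encoding: str                      # "GASF" | "GADF" | "MTF"
    value_range: tuple[float, float]


@dataclass
class RenderedImage:
    pixels: np.ndarray                 # (H, W, 3) in [0, 1]
    colormap_name: str
    source_encoding: str


def minmax_normalize(snapshot: Snapshot | np.ndarray) -> np.ndarray:
    """Rescale to [-1, 1]; both endpoints are attained by construction."""
    x = snapshot.values if isinstance(snapshot, Snapshot) else np.asarray(snapshot, dtype=float)
    lo, hi = x.min(), x.max()
    if hi == lo:
        raise DegenerateSnapshotError(
            "all sensor values are equal; min-max normalization is undefined")
    return ((x - hi) + (x - lo)) / (hi - lo)


def to_polar(norm: np.ndarray) -> np.ndarray:
    """phi = arccos(x~), in [0, pi]. Values outside [-1, 1] by more than a
    round-off tolerance are rejected; within tolerance they are clamped."""
    norm = np.asarray(norm, dtype=float)
    if np.any(np.abs(norm) > 1.0 + ARCCOS_CLAMP_TOL):
        raise ValueError("normalized values must lie in [-1, 1]")
    return np.arccos(np.clip(norm, -1.0, 1.0))


def gasf(norm: np.ndarray) -> GafImage:
    """Gramian Angular Summation Field: M_ij = cos(phi_i + phi_j)."""
    phi = to_polar(norm)
    m = np.cos(phi[:, None] + phi[None, :])
    return GafImage(matrix=m, encoding="GASF", value_range=(-1.0, 1.0))


def gadf(norm: np.ndarray) -> GafImage:
    """Gramian Angular Difference Field: M_ij = sin(phi_i - phi_j)."""
    phi = to_polar(norm)
    m = np.sin(phi[:, None] - phi[None, :])
    return GafImage(matrix=m, encoding="GADF", value_range=(-1.0, 1.0))


def encode(snapshot: Snapshot | np.ndarray, method: str = "gasf",
           n_bins: int = 8) -> GafImage:
    """Normalize then encode with the named method ('gasf', 'gadf', 'mtf')."""
    method = method.lower()
    if method == "mtf":
        snap = snapshot if isinstance(snapshot, Snapshot) else Snapshot(np.asarray(snapshot))
        return mtf(snap, n_bins=n_bins)
    norm = minmax_normalize(snapshot)
    if method == "gasf":
        return gasf(norm)
    if method == "gadf":
        return gadf(norm)
    raise ValueError(f"unknown encoding {method!r}; choose gasf, gadf or mtf")


def mtf(snapshot: Snapshot, n_bins: int = 8) -> GafImage:
    """Markov Transition Field with quantile bins.

    Values are quantile-binned into ``n_bins`` states, the one-step
    transition matrix W along the vector order is estimated (rows normalized
    when they have any mass), and M_ij = W[q(x_i), q(x_j)].
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    x = snapshot.values
    n_distinct = np.unique(x).size
    if n_bins > n_distinct:
        warnings.warn(
            f"n_bins={n_bins} exceeds {n_distinct} distinct values; reducing",
            stacklevel=2)
        n_bins = n_distinct
    # quantile bin edges; digitize against interior edges
    edges = np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1])
    states = np.searchsorted(edges, x, side="right")
    w = np.zeros((n_bins, n_bins))
    for a, b in zip(states[:-1], states[1:]):
        w[a, b] += 1.0
    row_sums = w.sum(axis=1, keepdims=True)
    np.divide(w, row_sums, out=w, where=row_sums > 0)
    m = w[states[:, None], states[None, :]]
    return GafImage(matrix=m, encoding="MTF", value_range=(0.0, 1.0))


def render_color(img: GafImage, colormap_name: str = "viridis",
                 upscale: int = 1) -> RenderedImage:
    """Map the matrix through a matplotlib colormap to an RGB image in [0, 1].

    The encoding's value range (not the matrix's observed range) anchors the
    colormap, and upscaling is nearest-neighbour, so rendering is
    deterministic and resolution-faithful.
    """
    import matplotlib

    if upscale < 1:
        raise ValueError("upscale must be >= 1")
    try:
        cmap = matplotlib.colormaps[colormap_name]
    except KeyError:
        available = ", ".join(sorted(matplotlib.colormaps)[:20])
        raise ValueError(
            f"unknown colormap {colormap_name!r}; available include: {available}, ...")
    lo, hi = img.value_range
    unit = np.clip((img.matrix - lo) / (hi - lo), 0.0, 1.0)
    rgb = np.asarray(cmap(unit))[..., :3]
    if upscale > 1:
        rgb = np.repeat(np.repeat(rgb, upscale, axis=0), upscale, axis=1)
    return RenderedImage(pixels=rgb, colormap_name=colormap_name,
                         source_encoding=img.encoding)


def snapshot_to_tensor(snapshot: Snapshot | np.ndarray, method: str = "gasf",
                       channels: int = 3, colormap: str = "viridis") -> np.ndarray:
    """Encode a snapshot into a (C, n, n) float array ready for the CNN.

    ``channels=3`` renders through the colormap; ``channels=1`` returns the
    raw matrix rescaled to [0, 1] (ablation mode).
    """
    img = encode(snapshot, method=method)
    if channels == 3:
        return render_color(img, colormap).pixels.transpose(2, 0, 1)
    if channels == 1:
        lo, hi = img.value_range
        return ((img.matrix - lo) / (hi - lo))[None, :, :]
    raise ValueError("channels must be 1 or 3")
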