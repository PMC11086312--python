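"""Encode a 16-sensor snapshot as GASF / GADF / MTF images.

Prints the structural properties that make the encodings useful: GASF is
symmetric with diagonal 2*x~^2 - 1, GADF is antisymmetric with a zero
diagonal, and both live in [-1, 1] regardless of the raw sensor scale.
Pass an output path as argv[1] to also save a rendered PNG.
"""

import sys

import numpy as np

from ltnet import (GasExposure, SimConfig, encode, extract_snapshots,
                   render_color, simulate_exposure)

cfg = SimConfig(seed=3)
rec = simulate_exposure(cfg, GasExposure(5.0, 5.0, "mixture"), seed=3)
snap = extract_snapshots(rec, policy="end", exposure_s=cfg.exposure_s)[0]
print("snapshot (16 sensors):", np.round(snap.values, 2))

for method in ("gasf", "gadf", "mtf"):
    img = encode(snap, method=method)
    m = img.matrix
    print(f"{img.encoding}: shape {m.shape}, range [{m.min():+.3f}, {m.max():+.3f}], "
          f"symmetry error {np.abs(m - m.T).max():.2e}")

if len(sys.argv) > 1:
    from PIL import Image

    rgb = (render_color(encode(snap, "gasf"), "viridis", upscale=8).pixels * 255)
    Image.fromarray(rgb.astype(np.uint8)).save(sys.argv[1])
    print("saved rendered GASF image to", sys.argv[1])
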