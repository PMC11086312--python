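"""Why depthwise-separable convolution and conv-BN fusion make LTNet small.

Prints the parameter/FLOP closures for one layer shape, the full reference
model's per-layer budget, and the storage saved by folding BN into the
convolutions.
"""

from ltnet import (count_flops, count_params_conv, count_params_dsc,
                   count_params_model, fusion_param_counts, reference_config)

k, cin, cout = 3, 16, 32
print(f"standard {k}x{k} conv {cin}->{cout}:  {count_params_conv(k, cin, cout)} weights")
print(f"depthwise separable:       {count_params_dsc(k, cin, cout)} weights "
      f"(ratio = 1/{cout} + 1/{k * k} = {count_params_dsc(k, cin, cout) / count_params_conv(k, cin, cout):.4f})")
print(f"FLOPs on an 8x8 map:       {count_flops('standard', 8, 8, k, cin, cout):,} vs "
      f"{count_flops('dsc', 8, 8, k, cin, cout):,}")

u, f = fusion_param_counts(k, cin, cout)
print(f"conv+BN fusion for this shape: {u} -> {f} stored values (saves 3*C_out = {u - f})")

print("\nreference LTNet (full mode):")
rep = count_params_model(reference_config(), flops_at=(16, 16))
for name, n in rep.per_layer.items():
    print(f"  {name:22s} {n:7,d}")
print(f"  {'total trainable':22s} {rep.total:7,d}")
print(f"  deployed (pre-fusion)  {rep.deployed_total:7,d}")
print(f"  MACs at 16x16 input    {rep.flops:9,d}")

orig = count_params_model(reference_config("original")).total
print(f"\nablation without depthwise separation / SE / residuals: {orig:,} params "
      f"({orig / rep.total:.1f}x larger)")
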