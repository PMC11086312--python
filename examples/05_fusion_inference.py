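"""Fold BN into the convolutions and verify nothing changes at inference.

Builds the reference model, lets the BN running statistics settle on random
batches, fuses every conv+BN pair, and prints the logit deviation and the
deployed-parameter saving (exactly 3 values per BN output channel).
"""

import numpy as np

from ltnet import (build_model, equivalence_report, fuse_model,
                   reference_config)
from ltnet.fusion import count_bn_channels

model = build_model(reference_config(), seed=1)
rng = np.random.default_rng(1)
for _ in range(5):  # settle BN running statistics
    model.forward(rng.uniform(0, 1, (16, 3, 16, 16)).astype(np.float32), train=True)

fused = fuse_model(model)
rep = equivalence_report(model, fused, n_inputs=100, seed=1)
print(f"max |logit deviation| over 100 inputs: {rep['max_abs_logit_deviation']:.2e}")
print(f"argmax predictions identical: {rep['argmax_agrees']}")
print(f"deployed parameters: {rep['deployed_params_unfused']:,} -> "
      f"{rep['deployed_params_fused']:,} (saved {rep['param_delta']:,} "
      f"= 3 x {count_bn_channels(model)} BN output channels)")
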