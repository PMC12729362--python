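"""Run the token extractor and the fused window attention step by step.

The multiscale module turns the phase stack into a token matrix (448 x 784
at full scale; 112 x 16 at the desk scale used here); windows of W tokens
with stride S and fringe L are attended per window with a shared learnable
context token, and the per-window context outputs are averaged into one
fused feature.
"""

import numpy as np

from invadenet.fwam import WindowSpec, fuse_windows, partition_windows
from invadenet.model import InvasionNet, default_model_config, desk_model_config

desk = InvasionNet(desk_model_config(seed=0))
x = np.random.default_rng(0).standard_normal((1, 1, 5, 32, 32)).astype(np.float32)

tokens = desk.tokenizer(x)
print(f"desk-scale token matrix: {tokens.shape[1]} tokens x {tokens.shape[2]} features")

spec = desk.cfg.window_spec()
print(f"windows: W={spec.window}, S={spec.stride}, L={spec.fringe} "
      f"-> F=(T-W)/S+1 = {spec.n_windows}")

wins = partition_windows(tokens[0], spec)
print(f"window 0 base {wins[0].base.shape}, fringes {wins[0].left_fringe.shape} per side")

y_p = desk(x)
fused = fuse_windows(desk.aggregator.last_per_window[0])
print(f"fused feature (mean of {spec.n_windows} context outputs): {fused.fo.shape}, "
      f"invasion probability {y_p[0]:.3f}")

full = default_model_config()
print(f"\nfull-scale contract: {full.n_tokens} tokens x {full.feature_dim} features, "
      f"{InvasionNet(full).parameter_count() / 1e6:.2f} M parameters")
# The full-scale numbers (448 x 784 tokens, ~27.7 M parameters) are the
# published architecture contract; the desk model is the same design shrunk
# for CPU experiments.
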