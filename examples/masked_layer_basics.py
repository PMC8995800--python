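"""Effective weights of a masked layer, and post-training disorganization.

Masked layers renormalize by the retained fraction rho = sum(F)/N, so the
total weight mass is preserved: W_eff = (W * F) / rho.
"""

import numpy as np

from szlab import SzDenseLayer, WindowMatrix, disorganize, effective_weights, sz_dense_forward

W = np.array([[2.0, 4.0], [6.0, 8.0]])
F = WindowMatrix(np.eye(2), family="random", params={})  # keep the diagonal, rho = 0.5

eff = effective_weights(W, F)
print("raw weights:\n", W)
print("effective weights (masked, renormalized by rho=0.5):\n", eff)
print("weight sums: raw", W.sum(), "-> effective", eff.sum())
# The two retained weights are doubled (divided by rho), so the total weight
# sum is preserved here: 20 -> 20.

layer = SzDenseLayer(W=W, window=F, activation="linear")
print("forward pass of [1, 1]:", sz_dense_forward(np.array([1.0, 1.0]), layer))

# Post-training intervention: attach a window to an already-trained layer.
# The result shares the trained weights, has no bias, and is flagged as the
# disorganized (degeneration-after-formation) mode.
masked = disorganize(layer, F)
print("disorganized mode:", masked.mode, "| bias:", masked.b, "| shares W:", masked.W is W)
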