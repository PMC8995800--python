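"""Build weight windows of every family and inspect their reduction ratios.

A weight window is an n_in x n_out matrix in [0, 1] multiplied element-wise
onto a layer's weights.  Binary families snap a requested parameter reduction
(the eliminated share of weights) to the nearest exactly-achievable count.
"""

from szlab import NodeGeometry, achievable_retained_counts, solve_window

geom = NodeGeometry(3, 64)  # e.g. RGB input channels x 64 conv filters

print(f"geometry {geom.n_in}x{geom.n_out}: "
      f"{len(achievable_retained_counts(geom))} achievable retained counts")

for family in ("diagonal", "gaussian", "stripe", "centered", "random"):
    w = solve_window(geom, family, reduction=0.417, seed=0)
    print(
        f"{family:>9}: requested 41.7% reduction -> achieved "
        f"{100 * w.reduction:5.1f}%  (retained {int(round(w.values.sum()))} "
        f"of {geom.size} weights)"
    )

# The diagonal (band) window prints 41.7%: it retains exactly 112 of the 192
# channel connections — the snapped, exactly-achievable version of the
# requested ratio. The Gaussian window is graded, so it can match any
# reduction continuously.
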