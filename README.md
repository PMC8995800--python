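# szlab — distance-windowed ("schizophrenia-mimicking") neural network layers

Nanometre-scale imaging of brain tissue from schizophrenia cases shows
neurites that are thin and tortuous, suggesting that connections between
*distal* neurons are selectively suppressed. `szlab` turns that observation
into a network-level model: dense and convolution layers whose weight
matrices are masked by a fixed, distance-dependent **weight window**, plus
the machinery to measure what such masking does to image-classification
performance.

It is a library for computational-psychiatry and machine-learning researchers
who want to (a) build band-matrix masked layers in their own experiments and
(b) regenerate the published tolerance / outperformance curves at desk scale
without GPUs or dataset downloads.

## The model

Arrange the nodes of two consecutive layers on a line. Cell `(i, j)` of the
weight matrix gets the Euclidean distance to the matrix diagonal `j = r·i`,
`r = n_out/n_in`:

    d_ij = |r·i − j| / √(r² + 1)

A **window** `F ∈ [0,1]^{n_in×n_out}` built from these distances (binary band
`d ≤ t`, Gaussian `exp(−d²/2σ²)`, stripe, centered, or seeded random control)
masks the weights on every forward pass, renormalized by the retained
fraction `ρ = Σf/N` so the total weight mass is preserved:

    W_eff = (W ∘ F) / ρ

The **parameter reduction** is the eliminated share `1 − ρ`. Convolution
kernels are masked along the channel axes only (the same `c_in × c_out` band
at every spatial position). Two intervention protocols:

* **disorganized** — train a conventional network, then mask at evaluation
  (degeneration after network formation);
* **developmental** — train *under* the mask (concurrent pathology and
  development); masked weights receive exactly-zero gradients and never move.

Sweeps over the reduction grid, repeated across seeded sessions, are compared
with the exact two-sided Wilcoxon rank-sum test.

## A worked example

```python
from szlab import NodeGeometry, solve_window

geom = NodeGeometry(3, 64)            # 3 input channels x 64 conv filters
w = solve_window(geom, "diagonal", reduction=0.417)
print(round(100 * w.reduction, 1), int(w.values.sum()))
```

prints

```
41.7 112
```

the requested 41.7% reduction snapped to the exactly-achievable band: 112 of
the 192 channel connections retained, 80 eliminated — the ratio quoted for a
channel-masked 3-to-64 convolution. Training the windowed layer next to its
control (`examples/train_developmental.py`):

```
                 fully connected: test error 10.95%  (24576 of 24576 hidden connections active)
  diagonal window, 50% reduction: test error 10.70%  (12268 of 24576 hidden connections active)
```

— on the built-in synthetic task, removing half the hidden connections with a
band window costs nothing (here it even helps slightly), which is the core
published effect. The `examples/` directory has one short script per
capability: window construction, masked-layer algebra, developmental
training, and a disorganized sweep with a rank-sum comparison.

A thin CLI covers the shell-level tasks:

```bash
szlab window --family diagonal --nin 3 --nout 64 --reduction 0.417 --out window.csv
szlab synth --out data/                      # synthetic dataset as IDX files
szlab sweep --config cfg.yaml --protocol developmental --sessions 20 --seed 7 --out results/
szlab compare results_a.csv results_b.csv --col error
```

MNIST (IDX) and CIFAR-10 (binary batch) readers load local files only and
never download; without local data everything runs on the seeded synthetic
generator. Full-scale presets of the published configurations are in
`scripts/full_scale_mnist.py` and `scripts/full_scale_cifar.py` (CPU-hours;
not part of the test suite).

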