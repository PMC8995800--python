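# Methods

This note documents the models, numerical choices, and study designs behind
`szlab`, and states what the synthetic experiments do and do not show.

## The distance measure and the windows

Nodes of two consecutive layers are arranged on a line. For a weight matrix
with `n_in` rows and `n_out` columns, cell `(i, j)` (0-based) is assigned its
Euclidean distance to the matrix diagonal, the line `j = r·i` with
`r = n_out / n_in`:

    d_ij = |r·i − j| / √(r² + 1) = |n_out·i − n_in·j| / √(n_in² + n_out²)

The diagonal passes through `(0, 0)`, so `d = 0` at the first element. The
second form shows every distance is an integer multiple of a fixed unit; all
threshold comparisons therefore reduce to integer comparisons, and the set of
retained counts a band window can realize is exactly enumerable
(`achievable_retained_counts`).

A *window* `F` is an `n_in × n_out` matrix in `[0, 1]` applied element-wise
to the weights. Families:

| family   | rule | binary |
|----------|------|--------|
| full     | all ones | yes |
| diagonal | `f = 1` iff `d ≤ t` (inclusive) | yes |
| gaussian | `f = exp(−d²/2σ²)` | no |
| stripe   | union of parallel diagonal bands, centers offset by `n_out/n_bands` (wrapped); one band degenerates to the diagonal window | yes |
| centered | disc of radius `ρ` around the matrix center, axes scaled to `[0, 1]` | yes |
| random   | exactly `round(p·N)` ones at seeded uniform positions | yes |

The stripe and centered constructions are this package's concrete reading of
window shapes that are usually drawn rather than defined; both are labelled as
such in the code. Random windows use exact-count sampling (not iid Bernoulli)
so that the reduction axis of a sweep is exact and comparisons across families
are fair.

**Terminology.** Internally the package stores the *retained fraction*
`ρ = Σf / N`. Everything user-facing reports the *parameter reduction*
`1 − ρ` (the eliminated share), which is the axis the literature plots.

**Requested vs achieved.** Binary windows snap a requested reduction to the
nearest achievable retained count, ties toward more retention
(`solve_diagonal_threshold`; the same snapping applies to stripe/centered
through their own score fields). The Gaussian σ is found by bisection on the
strictly monotone map `σ ↦ Σf/N` to `|retained − target| ≤ 1e-6`; the sweep
axes always carry the achieved values.

## Masked layers

A windowed ("schizophrenia") layer keeps raw weights `W` and computes

    W_eff = (W ∘ F) / ρ

on every forward pass, with `F` and `ρ` constants fixed at attach time. The
`1/ρ` renormalization keeps the total weight mass unchanged — exactly when
mask and weights are uncorrelated (e.g. the worked 2×2 example), in
expectation in general. Because masking happens inside the forward graph, the
loss gradient at a masked raw weight is exactly zero under backpropagation:
masked weights never move, under any optimizer, for any number of steps. A
full window is bit-identical to a conventional layer.

Convolution kernels (layout `k_h × k_w × c_in × c_out`) are masked along the
channel axes only: the same `c_in × c_out` window divides and multiplies
every spatial position, so the zero pattern never varies across `(h, w)` —
this is a band structure *between channels*, not a spatial filter prior.

Two intervention modes:

* **developmental** — the window is attached before training and constrains
  every update (concurrent pathology and development). Biases allowed.
* **disorganized** — a conventionally trained layer is masked only at
  evaluation (degeneration after network formation). No bias: a bias cannot
  be attributed to an inter-node distance after the fact, so layers destined
  for post-training masking are built bias-free from the start.

Initialization is He's method on the raw weights with **full** fan-in (the
`1/ρ` renormalization compensates the scale of masked layers); the output
layer, whose initializer is conventionally unspecified, also uses He. Loss is
categorical cross-entropy under a softmax output — implied by the
architecture, recorded here as a choice.

## The training engine

All layers (dense, 3×3 convolution via im2col, 2×2 max-pooling, batch
normalization, inverted dropout, flatten) are implemented directly on numpy
float64 arrays with manual backpropagation, verified against central finite
differences to ~1e-8 relative error in the test suite. Optimizers: Adam
(β₁ 0.9, β₂ 0.999, ε 1e-7) and RMSprop (ρ 0.9, ε 1e-7) with the
multiplicative `lr/(1 + decay·t)` iteration decay. Max-pool gradients split
equally among tied maxima; batch normalization uses ε 1e-3 and momentum 0.99
running statistics. Everything is seeded through `numpy.random.Generator`;
two models with identical layer shapes and seed draw identical parameters,
which is what makes the full-window equivalence exact.

Layer state — weights, biases, batch-normalization statistics, and attached
windows — round-trips through a single `.npz` archive
(`save_state`/`load_state`), reproducing forward outputs bit for bit.

Network presets follow the published configuration table: A (one windowed
dense hidden of 512), B (twin equal-width hiddens, the second masked at
evaluation), C/D (two conv blocks 32/32/64/64 and a width-512 dense top,
windowed at build time for C, at evaluation for D), and E (the VGG16 conv
stack with the last three convolutions channel-masked, tops 4096/4096/1024).
E's batch-normalization placement (after every convolution) and dropout (0.5
after each top dense layer) are this package's defaults, overridable in the
config — the original regularization placement is not part of the published
main text. Schedules: Adam 1e-3/batch 32 for A and B; RMSprop 1e-4 with decay
1e-6/batch 32 for C and D; Adam 5e-4 switching to 1e-4 after 150 epochs,
batch 200, flip/±10%-shift augmentation for E. Reduced presets (`a_small`,
`c_small`, `e_small`) keep the topology at desk widths.

## Sweeps and statistics

A sweep runs one protocol over a reduction grid (grid point 0 = baseline,
always present). Cell seeds are hashes of
`(base_seed, protocol, family, grid index, session index)`, so every cell is
reproducible in isolation and results are independent of execution order.
The disorganized protocol trains once per session and reuses the trained
network across the grid (S trainings); the developmental protocol trains
every cell (G·S trainings). Mean (not median) session error is reported.
Diverged sessions (non-finite loss) are recorded as failures and excluded
from means.

Session samples are compared with the two-sided Wilcoxon rank-sum
(Mann–Whitney) test — rank-sum rather than signed-rank because sessions are
independent, unpaired runs. The null distribution is exact for tie-free
samples of ≤ 12 per side and a tie-corrected normal approximation otherwise;
two identical constant samples return p = 1 with a degeneracy note.
Significance is p < 0.05.

## The synthetic task

`make_synthetic` produces a K-class image task with no downloads: each class
has a template of 3 Gaussian blobs at seeded random positions (widths
0.085–0.17 of the image side, amplitudes 0.6–1, clipped to `[0, 1]`), and
each image is its template plus iid Gaussian pixel noise, clipped. Train and
test splits use independent noise draws; everything is reproducible from the
spec seed.

The default noise level (sd 1.5 at 28×28) is calibrated once so that a
multinomial logistic classifier reaches ≈ 78% test accuracy (target band
70–85%): hard enough that capacity effects are visible, easy enough that
small networks train in seconds. The localized-blob template rule matters:
class-discriminative information must be *spatially local* (as in handwritten
digits or natural images) for band windows to behave as published — with
globally smooth templates, contiguous input bands are statistically redundant
and window effects invert.

What the generator does **not** emulate: multi-scale structure, correlated
(non-iid) noise, label noise, class imbalance, and pose/deformation
variability (the overfitting study adds the last one explicitly, see below).
Passing the studies therefore shows that the masking algebra, protocols and
statistics reproduce the published *mechanisms* on a task with the right
locality structure — not that the specific error levels transfer to MNIST or
CIFAR.

## The three desk-scale studies

All studies run on 16×16 single-channel versions of the task (same template
rule) so that wide networks × ≥ 20 sessions complete in minutes on one CPU;
the noise level 0.95 corresponds to ≈ 83% linear-classifier accuracy, inside
the calibration band at its easier end — the tolerance phenomenon requires
the redundant, large-margin representations of a mostly-learnable task.

* **Tolerance (disorganized)** — twin-hidden width-512 network, 500 train /
  200 test per class, Adam 1e-3, 8 epochs, 20 sessions; diagonal masking at
  40% and 95% after training. Expected shape: ≈ +1.5 points at 40%, ≈ +35
  points (toward the 90% chance level) at 95%.
* **Window benefit (developmental)** — width-96 one-hidden network, 300 train
  / 200 test per class, Adam 1e-3, 15 epochs, 20 sessions; diagonal windows
  at {50, 60, 70}% against the full baseline, and a random window at 70%.
  Expected shape: the diagonal band stays within half a point of the baseline
  (often below it); the random window of equal sparsity is clearly worse —
  the *shape* of the window, not sparsity alone, carries the effect.
* **Overfitting (training dynamics)** — width-64 network trained slowly
  (RMSprop 1e-4, decay 1e-6, 120 epochs, 10 sessions) on a variant of the
  task whose *training* images carry a fixed random sub-image shift (±15% of
  the side, edge fill) while validation images are unshifted. The shifts are
  instance-specific geometric variability — the property of real image data
  that forces memorization. The fully connected baseline passes its
  validation minimum around epoch 90 and then degrades while its training
  error is still falling; the 50%-reduction band network is still improving
  when the budget ends. The epoch budget deliberately ends between the two
  overfitting onsets; that is the published situation (the control overfits
  mid-run, the windowed network declines through the end of training).

## Numerical details and edge cases

* Retention is inclusive (`d ≤ t`), so cells at tied distances enter
  together; this is what makes achievable counts exact.
* A window that retains nothing is invalid everywhere (`InvalidWindowError`);
  requesting a reduction whose nearest achievable count is zero fails rather
  than silently snapping to an empty mask.
* `solve_window` refuses a nonzero reduction for the `full` family.
* Degenerate geometries: a 1×1 matrix has achievable counts {0, 1}; the
  Gaussian solver reports a bracketing error for targets below its σ→0 floor
  (the fraction of exactly-on-diagonal cells).
* Image values are clipped to `[0, 1]` after adding noise, so extreme noise
  saturates rather than escaping the pixel range.
* The L1 control reports its reduction as the fraction of weights with
  `|w| < 1e-4` after training. Under subgradient descent the weights dither
  around zero with amplitude of order of the learning rate, so reductions
  approaching 1 require annealing the rate below the tolerance.

## Known limitations

* Stride-1 3×3 convolutions and 2×2 pooling only — enough for the published
  configurations, not a general conv library.
* Full-scale presets (B at width 512 on MNIST, VGG16 on CIFAR-10) build and
  run but are CPU-hours-scale; `scripts/full_scale_mnist.py` and
  `scripts/full_scale_cifar.py` are provided for local datasets and are not
  part of the test suite.
* The disorganized tolerance plateau is sensitive to task difficulty: at the
  hard end of the calibration band (≈ 78% linear accuracy) post-training
  masking at 40% costs 3–5 points for every width we tried — small-margin
  representations simply do not tolerate masking. This is a property of the
  phenomenon, not of the implementation.
* Windows over two-dimensional node layouts, trainable masks, and magnitude
  pruning are out of scope.
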