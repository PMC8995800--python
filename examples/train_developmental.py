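"""Train a band-windowed network next to its fully connected control.

The developmental protocol attaches the window before training, so the mask
constrains every update; masked raw weights receive exactly-zero gradients
and never move.  On the synthetic blob task the 50%-reduction band window
performs on par with the control while training only half the connections.
"""

import numpy as np

from szlab import (
    NetworkConfig,
    SynthSpec,
    TrainingSchedule,
    WindowSpec,
    build_network,
    evaluate,
    make_synthetic,
    train,
)

train_ds, test_ds = make_synthetic(
    SynthSpec(height=16, width=16, noise_sd=0.95, n_train=300, n_test=200, seed=0)
)
schedule = TrainingSchedule("adam", lr=1e-3, batch_size=32, epochs=15, seed=1)

for label, window in (
    ("fully connected", WindowSpec("full", 0.0)),
    ("diagonal window, 50% reduction", WindowSpec("diagonal", 0.5)),
):
    config = NetworkConfig("A", "developmental", (16, 16, 1), width=96, window=window)
    model = build_network(config, seed=2)
    trace = train(model, train_ds, test_ds, schedule, record_trace=False)
    layer = model.layers[model.sz_layer_index]
    active = (
        int((layer.effective_W() != 0).sum()) if layer.window is not None
        else layer.W.size
    )
    print(
        f"{label:>32}: test error {100 * evaluate(model, test_ds):5.2f}%  "
        f"({active} of {layer.W.size} hidden connections active)"
    )
# Typical output: both variants land within ~half a point of each other —
# eliminating half the hidden-layer connections costs essentially nothing.
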