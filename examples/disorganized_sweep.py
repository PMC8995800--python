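"""Post-training masking sweep with a rank-sum comparison of two grid points.

The disorganized protocol trains each session once, then masks the trained
layer at every reduction on the grid — mimicking degeneration of an already
formed network.  Error tolerates moderate reduction and collapses toward the
10-class chance level (90%) at extreme reduction.
"""

from szlab import (
    NetworkConfig,
    SynthSpec,
    TrainingSchedule,
    make_synthetic,
    run_disorganized_sweep,
    wilcoxon_compare,
)

train_ds, test_ds = make_synthetic(
    SynthSpec(height=16, width=16, noise_sd=0.95, n_train=200, n_test=200, seed=0)
)
config = NetworkConfig("B", "disorganized", (16, 16, 1), width=256)
schedule = TrainingSchedule("adam", lr=1e-3, batch_size=32, epochs=6)

sweep = run_disorganized_sweep(
    config, train_ds, test_ds,
    reductions=[0.0, 0.4, 0.8, 0.95],
    sessions=8,
    base_seed=7,
    schedule=schedule,
)
print(f"{sweep.n_trainings} trainings for {len(sweep.reductions)} grid points "
      f"(one per session — masking is evaluation-only)")
for r in sweep.reductions:
    print(f"  reduction {100 * r:4.0f}%: mean error {100 * sweep.mean_errors[r]:5.2f}%")

report = wilcoxon_compare(
    sweep.sessions_at(0.0), sweep.sessions_at(0.95),
    label_a="baseline", label_b="95% reduction",
)
print(
    f"rank-sum test baseline vs 95%: p = {report.p_value:.2e} "
    f"({'significant' if report.significant else 'not significant'} at 0.05, "
    f"{report.method})"
)
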