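"""Network builders, schedules, training loop, evaluation, L1 control."""

import numpy as np
import pytest

from szlab.data import ImageDataset, SynthSpec, make_synthetic
from szlab.errors import ContractError
from szlab.windows import NodeGeometry, solve_window
from szlab.zoo import (
    NetworkConfig,
    TrainingSchedule,
    WindowSpec,
    build_network,
    config_a,
    config_b,
    config_c,
    config_d,
    config_e,
    config_from_dict,
    disorganize_model,
    evaluate,
    l1_reduction,
    l1_variant,
    train,
)
from szlab.zoo import a_small, c_small, e_small


@pytest.fixture(scope="module")
def tiny_task():
    """Small, easily separable synthetic task for fast training checks."""
    spec = SynthSpec(k=4, height=12, width=12, noise_sd=0.3, n_train=20, n_test=20, seed=5)
    return make_synthetic(spec)


class TestBuilders:
    def test_config_a_parameter_count(self):
        model = build_network(config_a(width=512, window=WindowSpec("full", 0.0)), seed=0)
        assert model.count_params() == 784 * 512 + 512 + 512 * 10 + 10

    def test_windowed_config_keeps_raw_parameter_storage(self):
        full = build_network(config_a(width=64, window=WindowSpec("full", 0.0)), seed=0)
        masked = build_network(config_a(width=64, window=WindowSpec("diagonal", 0.5)), seed=0)
        assert full.count_params() == masked.count_params()
        layer = masked.layers[masked.sz_layer_index]
        eff = layer.effective_W()
        assert 0.4 < np.mean(eff == 0) < 0.6

    @pytest.mark.parametrize("width", [64, 1024])
    def test_config_b_width_range_builds_and_runs(self, width):
        model = build_network(config_b(width=width), seed=1)
        x = np.random.default_rng(2).random((3, 28, 28, 1))
        probs = model.forward(x)
        assert probs.shape == (3, 10)
        assert np.allclose(probs.sum(axis=1), 1.0)
        # the to-be-masked layer is bias-free from the start
        assert model.layers[model.sz_layer_index].b is None

    def test_conv_configs_forward_shapes(self):
        x = np.random.default_rng(3).random((2, 32, 32, 3))
        for cfg in (c_small(), config_d(top=32, filters=(4, 4, 8, 8))):
            model = build_network(cfg, seed=4)
            probs = model.forward(x)
            assert probs.shape == (2, 10)
            assert np.allclose(probs.sum(axis=1), 1.0)

    def test_e_small_builds_with_channel_window(self):
        model = build_network(e_small(), seed=5)
        x = np.random.default_rng(6).random((2, 32, 32, 3))
        assert model.forward(x).shape == (2, 10)
        from szlab.nn import Conv2D

        masked_convs = [
            l for l in model.layers if isinstance(l, Conv2D) and l.window is not None
        ]
        assert len(masked_convs) == 1

    def test_full_scale_e_plan(self):
        # build only (no training): 13 convs, last three channel-masked
        model = build_network(config_e(), seed=7)
        from szlab.nn import Conv2D

        convs = [l for l in model.layers if isinstance(l, Conv2D)]
        assert len(convs) == 13
        assert [c.window is not None for c in convs] == [False] * 10 + [True] * 3

    def test_config_from_dict_roundtrip(self):
        cfg = config_from_dict(
            {"config_id": "A", "width": 32, "window": {"family": "diagonal", "reduction": 0.5}}
        )
        assert cfg.width == 32
        assert cfg.window.family == "diagonal"


class TestTraining:
    def test_same_seed_gives_identical_traces(self, tiny_task):
        train_ds, test_ds = tiny_task
        sched = TrainingSchedule("adam", lr=1e-3, batch_size=16, epochs=3, seed=11)
        traces = []
        for _ in range(2):
            cfg = NetworkConfig("A", "developmental", (12, 12, 1), width=16,
                                window=WindowSpec("diagonal", 0.4), n_classes=4)
            model = build_network(cfg, seed=12)
            traces.append(train(model, train_ds, test_ds, sched))
        assert traces[0].train_errors == traces[1].train_errors
        assert traces[0].val_errors == traces[1].val_errors

    def test_easily_separable_task_is_learned(self, tiny_task):
        train_ds, test_ds = tiny_task
        cfg = NetworkConfig("A", "developmental", (12, 12, 1), width=32,
                            window=WindowSpec("full", 0.0), n_classes=4)
        model = build_network(cfg, seed=13)
        sched = TrainingSchedule("adam", lr=1e-3, batch_size=16, epochs=30, seed=14)
        trace = train(model, train_ds, test_ds, sched)
        assert trace.train_errors[-1] < 0.05

    def test_masked_effective_weights_zero_after_training(self, tiny_task):
        train_ds, test_ds = tiny_task
        cfg = NetworkConfig("A", "developmental", (12, 12, 1), width=24,
                            window=WindowSpec("diagonal", 0.5), n_classes=4)
        model = build_network(cfg, seed=15)
        sched = TrainingSchedule("adam", lr=1e-3, batch_size=16, epochs=4, seed=16)
        train(model, train_ds, test_ds, sched)
        layer = model.layers[model.sz_layer_index]
        assert np.all(layer.effective_W()[layer.window.values == 0] == 0.0)

    def test_rmsprop_schedule_runs(self, tiny_task):
        train_ds, test_ds = tiny_task
        cfg = NetworkConfig("A", "developmental", (12, 12, 1), width=16,
                            window=WindowSpec("full", 0.0), n_classes=4)
        model = build_network(cfg, seed=17)
        sched = TrainingSchedule("rmsprop", lr=1e-3, decay=1e-6, batch_size=16, epochs=2, seed=18)
        trace = train(model, train_ds, test_ds, sched)
        assert len(trace.val_errors) == 2


class TestEvaluate:
    def test_chance_level_for_untrained_uniform_predictor(self):
        rng = np.random.default_rng(19)
        images = rng.random((1000, 6, 6, 1))
        labels = rng.integers(0, 10, 1000)
        ds = ImageDataset(images, labels, 10)
        cfg = NetworkConfig("A", "developmental", (6, 6, 1), width=8,
                            window=WindowSpec("full", 0.0))
        model = build_network(cfg, seed=20)
        err = evaluate(model, ds)
        assert 0.82 <= err <= 0.97  # near 0.9 chance error on 10 classes

    def test_error_zero_on_memorized_set(self, tiny_task):
        train_ds, test_ds = tiny_task
        cfg = NetworkConfig("A", "developmental", (12, 12, 1), width=32,
                            window=WindowSpec("full", 0.0), n_classes=4)
        model = build_network(cfg, seed=21)
        sched = TrainingSchedule("adam", lr=1e-3, batch_size=16, epochs=40, seed=22)
        train(model, train_ds, test_ds, sched)
        assert evaluate(model, train_ds) == 0.0

    def test_evaluate_is_pure(self, tiny_task):
        train_ds, _ = tiny_task
        cfg = NetworkConfig("A", "developmental", (12, 12, 1), width=8,
                            window=WindowSpec("full", 0.0), n_classes=4)
        model = build_network(cfg, seed=23)
        assert evaluate(model, train_ds) == evaluate(model, train_ds)

    def test_empty_split_rejected(self, tiny_task):
        train_ds, _ = tiny_task
        empty = ImageDataset(np.zeros((0, 12, 12, 1)), np.zeros(0, dtype=int), 4)
        cfg = NetworkConfig("A", "developmental", (12, 12, 1), width=8,
                            window=WindowSpec("full", 0.0), n_classes=4)
        model = build_network(cfg, seed=24)
        with pytest.raises(ContractError):
            evaluate(model, empty)


class TestDisorganizeModel:
    def test_baseline_preserved_and_copy_masked(self, tiny_task):
        train_ds, test_ds = tiny_task
        cfg = NetworkConfig("B", "disorganized", (12, 12, 1), width=24, n_classes=4)
        model = build_network(cfg, seed=25)
        sched = TrainingSchedule("adam", lr=1e-3, batch_size=16, epochs=3, seed=26)
        train(model, train_ds, test_ds, sched)
        base_err = evaluate(model, test_ds)
        window = solve_window(NodeGeometry(24, 24), "diagonal", 0.5)
        masked = disorganize_model(model, window)
        assert evaluate(model, test_ds) == base_err  # original untouched
        layer = masked.layers[masked.sz_layer_index]
        assert layer.mode == "disorganized"
        assert np.all(layer.effective_W()[window.values == 0] == 0.0)

    def test_full_window_disorganization_is_identity(self, tiny_task):
        train_ds, test_ds = tiny_task
        cfg = NetworkConfig("B", "disorganized", (12, 12, 1), width=16, n_classes=4)
        model = build_network(cfg, seed=27)
        window = solve_window(NodeGeometry(16, 16), "diagonal", 0.0)
        masked = disorganize_model(model, window)
        x = train_ds.images[:8]
        assert np.array_equal(model.forward(x), masked.forward(x))


class TestL1Control:
    def test_zero_strength_reports_near_zero_reduction(self, tiny_task):
        train_ds, test_ds = tiny_task
        base = NetworkConfig("A", "developmental", (12, 12, 1), width=16,
                             window=WindowSpec("full", 0.0), n_classes=4)
        cfg, report = l1_variant(base, l1_strength=0.0)
        model = build_network(cfg, seed=28)
        sched = TrainingSchedule("adam", lr=1e-3, batch_size=16, epochs=5, seed=29)
        train(model, train_ds, test_ds, sched)
        assert report(model) < 0.05

    def test_large_strength_shrinks_most_weights(self, tiny_task):
        # anneal the learning rate so the sign-subgradient dither band falls
        # below the zero tolerance; most weights then count as eliminated
        train_ds, test_ds = tiny_task
        base = NetworkConfig("A", "developmental", (12, 12, 1), width=16,
                             window=WindowSpec("full", 0.0), n_classes=4)
        cfg, report = l1_variant(base, l1_strength=0.05)
        model = build_network(cfg, seed=30)
        sched = TrainingSchedule("adam", lr=1e-3, lr_switch=(60, 2e-5),
                                 batch_size=16, epochs=80, seed=31)
        train(model, train_ds, test_ds, sched)
        assert report(model) > 0.8

    def test_reduction_of_all_zero_matrix_is_one(self):
        assert l1_reduction(np.zeros((5, 5))) == 1.0

    def test_negative_strength_rejected(self):
        from szlab.errors import DomainError

        base = config_c()
        with pytest.raises(DomainError):
            l1_variant(base, l1_strength=-0.1)
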