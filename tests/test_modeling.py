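"""Model construction, training loops, transfer/freezing, and the RMSE metric."""

import time

import numpy as np
import pytest

import edassl as e
from edassl.nn import Conv1D, Dense
from edassl.simulate import ValidationError
from conftest import assert_weights_equal


class TestBuilders:
    def test_same_seed_gives_identical_initial_parameters(self, small_pretext_arch):
        a = e.build_pretext_model(small_pretext_arch, seed=3)
        b = e.build_pretext_model(small_pretext_arch, seed=3)
        assert_weights_equal(a.get_weights(), b.get_weights())

    def test_different_seeds_differ(self, small_pretext_arch):
        a = e.build_pretext_model(small_pretext_arch, seed=3)
        b = e.build_pretext_model(small_pretext_arch, seed=4)
        assert any(
            not np.array_equal(x, y) for x, y in zip(a.get_weights(), b.get_weights())
        )

    def test_default_conv_stack_frame_counts(self):
        assert e.conv_stack_frames(e.PretextArchitecture()) == [7000, 1747, 433, 105, 23]

    def test_forward_maps_window_to_horizon_and_is_finite_on_zeros(self):
        model = e.build_pretext_model(seed=0)
        out = model.forward(np.zeros((2, 7000, 1), dtype=np.float32))
        assert out.shape == (2, 40)
        assert np.isfinite(out).all()

    def test_downstream_scalar_output(self, small_downstream_arch):
        model = e.build_downstream_model(small_downstream_arch, seed=0)
        out = model.forward(np.zeros((3, 1400, 1), dtype=np.float32))
        assert out.shape == (3, 1)

    def test_too_deep_stack_for_short_input_is_a_construction_error(self):
        with pytest.raises(e.ConstructionError):
            e.build_pretext_model(e.PretextArchitecture(input_len=200), seed=0)


class TestPretrain:
    def test_constant_signal_reaches_near_zero_validation_rmse(self, small_params):
        flat = e.EDARecording(np.full(10000, 2.0), 700.0, "flat")
        scaled, _ = e.normalize_recording(flat)
        pairs = e.make_pretext_pairs(scaled, small_params)
        model = e.build_pretext_model(
            e.PretextArchitecture(input_len=1400, output_units=8), seed=0
        )
        hist = e.pretrain(model, pairs, e.pretext_train_config(max_epochs=5, patience=4))
        assert min(hist["val_rmse"]) < 1e-3

    def test_learns_structure_beyond_window_mean_baseline(
        self, tiny_dataset, tiny_pairs, small_pretext_arch
    ):
        model = e.build_pretext_model(small_pretext_arch, seed=0)
        hist = e.pretrain(
            model, tiny_pairs, e.pretext_train_config(max_epochs=12, patience=11, seed=0)
        )
        assert min(hist["val_rmse"]) < e.window_mean_baseline_rmse(tiny_pairs)

    def test_seeded_repetition_reproduces_final_weights(self, tiny_pairs, small_pretext_arch):
        cfg = e.pretext_train_config(max_epochs=2, patience=1, seed=9)
        runs = []
        for _ in range(2):
            m = e.build_pretext_model(small_pretext_arch, seed=1)
            e.pretrain(m, tiny_pairs, cfg)
            runs.append(m.get_weights())
        assert_weights_equal(*runs)

    def test_empty_pairs_rejected(self, small_pretext_arch):
        model = e.build_pretext_model(small_pretext_arch, seed=0)
        with pytest.raises(ValidationError):
            e.pretrain(model, [], e.pretext_train_config())


class TestTransferAndFreeze:
    def test_conv_weights_copied_bit_exactly_and_marked_frozen(self, small_pretext_arch, small_downstream_arch):
        src = e.build_pretext_model(small_pretext_arch, seed=0)
        dst = e.transfer_and_freeze(src, small_downstream_arch, seed=1)
        src_convs = [l for l in src.layers if isinstance(l, Conv1D)]
        dst_convs = [l for l in dst.layers if isinstance(l, Conv1D)]
        for s, d in zip(src_convs, dst_convs):
            np.testing.assert_array_equal(s.W, d.W)
            np.testing.assert_array_equal(s.b, d.b)
            assert not d.trainable

    def test_trainable_count_smaller_than_unfrozen_clone(self, small_pretext_arch, small_downstream_arch):
        src = e.build_pretext_model(small_pretext_arch, seed=0)
        frozen = e.transfer_and_freeze(src, small_downstream_arch, seed=1)
        clone = e.build_downstream_model(small_downstream_arch, seed=1)
        assert frozen.n_params(trainable_only=True) < clone.n_params(trainable_only=True)
        assert frozen.n_params() == clone.n_params()

    def test_architecture_mismatch_names_the_layer(self, small_pretext_arch):
        src = e.build_pretext_model(small_pretext_arch, seed=0)
        bad = e.DownstreamArchitecture(input_len=1400, conv_filters=(40, 30, 18, 31))
        with pytest.raises(e.ConstructionError, match="conv layer 3"):
            e.transfer_and_freeze(src, bad, seed=0)


class TestFinetuneAndSupervised:
    def test_finetune_changes_head_but_never_conv_weights(
        self, tiny_windows, small_pretext_arch, small_downstream_arch
    ):
        src = e.build_pretext_model(small_pretext_arch, seed=0)
        model = e.transfer_and_freeze(src, small_downstream_arch, seed=1)
        conv_before = [l.W.copy() for l in model.layers if isinstance(l, Conv1D)]
        dense_before = [
            l.W.copy() for l in model.layers if isinstance(l, Dense)
        ]
        e.finetune(model, tiny_windows, e.downstream_train_config(max_epochs=3, seed=0))
        conv_after = [l.W for l in model.layers if isinstance(l, Conv1D)]
        dense_after = [l.W for l in model.layers if isinstance(l, Dense)]
        for b, a in zip(conv_before, conv_after):
            np.testing.assert_array_equal(b, a)
        assert any(not np.array_equal(b, a) for b, a in zip(dense_before, dense_after))

    def test_identical_targets_converge_to_that_value(
        self, tiny_windows, small_pretext_arch, small_downstream_arch
    ):
        wins = [
            e.LabeledWindow(w.input, 0.5, w.question_id, w.segment_id, w.start_index)
            for w in tiny_windows
        ]
        src = e.build_pretext_model(small_pretext_arch, seed=0)
        model = e.transfer_and_freeze(src, small_downstream_arch, seed=1)
        e.finetune(
            model,
            wins,
            e.downstream_train_config(max_epochs=300, lr=1e-2, seed=0),
        )
        from edassl.modeling import windows_to_arrays

        x, _ = windows_to_arrays(wins)
        preds = model.predict(x).ravel()
        np.testing.assert_allclose(preds, 0.5, atol=0.01)

    def test_supervised_control_is_fully_trainable_and_fits_ten_windows(
        self, tiny_windows, small_downstream_arch
    ):
        model, hist = e.train_supervised(
            small_downstream_arch,
            tiny_windows[:10],
            e.downstream_train_config(max_epochs=5, seed=0),
            seed=2,
        )
        assert model.n_params(trainable_only=True) == model.n_params()
        assert len(hist["train_loss"]) == 5
        assert np.isfinite(hist["train_loss"]).all()

    def test_full_architecture_ten_window_finetune_fits_quickly(self):
        """Transfer + 25-epoch fine-tune of 10 full-size windows on one CPU."""
        rng = np.random.default_rng(0)
        wins = [
            e.LabeledWindow(
                input=rng.random(7000), target=0.25 * rng.integers(1, 5),
                question_id=1, segment_id=0, start_index=0,
            )
            for _ in range(10)
        ]
        src = e.build_pretext_model(seed=0)
        model = e.transfer_and_freeze(src, seed=1)
        t0 = time.monotonic()
        e.finetune(model, wins, e.downstream_train_config(seed=0))
        assert time.monotonic() - t0 < 60.0
        conv_src = [l.W for l in src.layers if isinstance(l, Conv1D)]
        conv_dst = [l.W for l in model.layers if isinstance(l, Conv1D)]
        for s, d in zip(conv_src, conv_dst):
            np.testing.assert_array_equal(s, d)

    def test_empty_windows_rejected(self, small_downstream_arch):
        with pytest.raises(ValidationError):
            e.train_supervised(small_downstream_arch, [], seed=0)


class TestRMSE:
    def test_zero_iff_equal(self):
        assert e.rmse([1.0, 2.0], [1.0, 2.0]) == 0.0
        assert e.rmse([0.0, 0.0], [1.0, 1.0]) == 1.0

    def test_hand_computed_value(self):
        assert e.rmse([0.25, 0.75], [0.5, 0.5]) == pytest.approx(0.25)

    def test_matches_loop_oracle_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(1, 50))
            a, b = rng.normal(size=n), rng.normal(size=n)
            acc = 0.0
            for x, y in zip(a, b):
                acc += (x - y) ** 2
            assert abs(e.rmse(a, b) - (acc / n) ** 0.5) < 1e-12

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValidationError):
            e.rmse([], [])
        with pytest.raises(ValidationError):
            e.rmse([1.0], [1.0, 2.0])
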