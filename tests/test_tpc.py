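"""Temporal predictive coding models: learning rules, inference dynamics,
and the linear-regime equivalence with the closed-form transition map."""

import numpy as np
import pytest

from seqmem import (
    DivergenceError,
    PatternSequence,
    TPCSingleLayer,
    TPCTwoLayer,
    closed_form_weights,
    generate_binary_sequence,
    generate_moving_bar,
    recall_single_layer,
    recall_two_layer,
    train_single_layer,
    train_two_layer,
)
from seqmem.tpc import (
    _infer_hidden,
    _recall_two_layer_batch,
    _relax_joint,
    _train_two_layer_batch,
)


class TestSingleLayerTraining:
    def test_one_gradient_step_from_zero_is_outer_product(self):
        x1 = np.array([1.0, -1.0, 2.0])
        x2 = np.array([0.5, 1.0, -1.0])
        seq = PatternSequence(np.stack([x1, x2]), "real")
        model = TPCSingleLayer(3, lr_weights=0.05)
        train_single_layer(seq, model, n_epochs=1)
        np.testing.assert_allclose(model.W, 0.05 * np.outer(x2, x1))

    def test_zero_sequence_leaves_weights_untouched(self):
        seq = PatternSequence(np.zeros((4, 5)), "real")
        model = TPCSingleLayer(5)
        train_single_layer(seq, model, n_epochs=10)
        assert not model.W.any()

    def test_converges_to_least_squares_map(self, small_binary_seq):
        model = TPCSingleLayer(12, lr_weights="auto")
        train_single_layer(small_binary_seq, model, n_epochs=20000, weight_tol=1e-12)
        W_cf = closed_form_weights(small_binary_seq, center=False)
        rel = np.linalg.norm(model.W - W_cf) / np.linalg.norm(W_cf)
        assert rel < 1e-3

    def test_divergence_raises_named_error(self, small_binary_seq):
        model = TPCSingleLayer(12, lr_weights=1.0)  # way past the stability bound
        with pytest.raises(DivergenceError, match="lr_weights"):
            train_single_layer(small_binary_seq, model, n_epochs=200)

    def test_training_is_deterministic(self, small_binary_seq):
        runs = []
        for _ in range(2):
            m = TPCSingleLayer(12, lr_weights="auto")
            train_single_layer(small_binary_seq, m, n_epochs=50)
            runs.append(m.W.copy())
        np.testing.assert_array_equal(runs[0], runs[1])


class TestSingleLayerRecall:
    @pytest.fixture
    def trained(self, small_binary_seq):
        model = TPCSingleLayer(12, lr_weights="auto")
        return train_single_layer(small_binary_seq, model, n_epochs=2000, weight_tol=1e-10)

    def test_converged_state_is_W_times_query(self, trained, small_binary_seq):
        rr = recall_single_layer(trained, small_binary_seq, "online")
        expected = small_binary_seq.patterns[:-1] @ trained.W.T
        assert np.max(np.abs(rr.recalled.patterns[1:] - expected)) < 1e-4

    def test_online_two_pattern_recall_is_exact(self):
        seq = generate_binary_sequence(8, 2, seed=4)
        model = train_single_layer(seq, TPCSingleLayer(8, lr_weights="auto"), 2000, 1e-12)
        rr = recall_single_layer(model, seq, "online")
        assert np.mean((rr.recalled.patterns[1] - seq.patterns[1]) ** 2) < 1e-3

    def test_offline_equals_online_at_second_step(self, trained, small_binary_seq):
        on = recall_single_layer(trained, small_binary_seq, "online")
        off = recall_single_layer(trained, small_binary_seq, "offline")
        np.testing.assert_allclose(on.recalled.patterns[1], off.recalled.patterns[1], atol=1e-9)

    def test_untrained_model_warns_and_returns_zeros(self, small_binary_seq):
        model = TPCSingleLayer(12)
        with pytest.warns(UserWarning, match="untrained"):
            rr = recall_single_layer(model, small_binary_seq, "online")
        assert not rr.recalled.patterns[1:].any()

    def test_attractor_property_small_p_large_n(self):
        # P << N, well conditioned: querying with ground truth recovers each
        # pattern almost exactly
        seq = generate_binary_sequence(40, 6, seed=11)
        model = train_single_layer(seq, TPCSingleLayer(40, lr_weights="auto"), 3000, 1e-12)
        rr = recall_single_layer(model, seq, "online")
        mse = np.mean((rr.recalled.patterns[1:] - seq.patterns[1:]) ** 2, axis=1)
        assert np.all(mse < 1e-4)

    def test_energy_monotone_during_inference(self, trained, small_binary_seq):
        model = trained
        model.lr_inference = 0.01
        model.n_inference_steps = 400
        rr = recall_single_layer(model, small_binary_seq, "online", record_energy=True)
        for traj in rr.diagnostics["energy_trajectories"]:
            assert np.all(np.diff(traj) <= 1e-12)


class TestTwoLayer:
    def test_zero_weights_inference_decays_to_zero(self):
        WH = np.zeros((1, 4, 4))
        WF = np.zeros((1, 6, 4))
        x = np.ones((1, 1, 6))
        z, eps_z, eps_x, _ = _infer_hidden(WH, WF, np.ones((1, 1, 4)), x, "tanh", 0.2, 500, 1e-10)
        assert np.max(np.abs(z)) < 1e-6

    def test_recall_shape_and_hidden_trajectory_contract(self, small_binary_seq):
        model = TPCTwoLayer(12, 8, seed=0)
        train_two_layer(small_binary_seq, model, n_epochs=30)
        rr = recall_two_layer(model, small_binary_seq, "offline")
        assert rr.recalled.patterns.shape == small_binary_seq.patterns.shape
        assert len(rr.hidden_trajectory) == small_binary_seq.length
        assert all(np.all(np.isfinite(z)) for z in rr.hidden_trajectory)

    def test_training_is_deterministic_and_seeded(self, small_binary_seq):
        ws = []
        for _ in range(2):
            m = TPCTwoLayer(12, 8, seed=3)
            train_two_layer(small_binary_seq, m, n_epochs=20)
            ws.append((m.W_H.copy(), m.W_F.copy()))
        np.testing.assert_array_equal(ws[0][0], ws[1][0])
        np.testing.assert_array_equal(ws[0][1], ws[1][1])
        m2 = TPCTwoLayer(12, 8, seed=4)
        assert not np.array_equal(ws[0][0], m2.W_H)

    def test_batched_training_matches_public_api(self, small_binary_seq):
        model = TPCTwoLayer(12, 8, seed=5, lr_weights=0.02)
        WH0, WF0 = model.W_H.copy(), model.W_F.copy()
        train_two_layer(small_binary_seq, model, n_epochs=15)
        WH, WF = _train_two_layer_batch(
            WH0[None], WF0[None], small_binary_seq.patterns[None, None],
            model.nonlinearity, model.lr_weights, model.lr_inference,
            model.n_inference_steps, model.inference_tol, 15,
        )
        np.testing.assert_allclose(WH[0], model.W_H)
        np.testing.assert_allclose(WF[0], model.W_F)

    def test_online_beats_offline_on_average(self):
        # offline recall feeds its own errors forward, so over several seeds
        # its MSE is at least the online MSE
        diffs = []
        for seed in range(4):
            seq = generate_binary_sequence(10, 6, seed=seed)
            m = TPCTwoLayer(10, 20, seed=seed, lr_weights=0.05)
            train_two_layer(seq, m, n_epochs=60)
            on = recall_two_layer(m, seq, "online")
            off = recall_two_layer(m, seq, "offline")
            mse = lambda rr: np.mean((rr.recalled.patterns[1:] - seq.patterns[1:]) ** 2)
            diffs.append(mse(off) - mse(on))
        assert np.mean(diffs) >= 0

    def test_joint_relaxation_energy_monotone(self):
        rng = np.random.default_rng(0)
        WH = rng.normal(0, 0.3, (1, 5, 5))
        WF = rng.normal(0, 0.3, (1, 7, 5))
        zprev = rng.normal(0, 1.0, (1, 1, 5))
        *_, energies = _relax_joint(WH, WF, zprev, "tanh", 0.01, 300, 1e-12, record_energy=True)
        traj = np.array([e[0, 0] for e in energies])
        assert np.all(np.diff(traj) <= 1e-10)

    def test_hidden_relaxation_energy_monotone(self):
        rng = np.random.default_rng(1)
        WH = rng.normal(0, 0.3, (1, 5, 5))
        WF = rng.normal(0, 0.3, (1, 7, 5))
        zprev = rng.normal(0, 1.0, (1, 1, 5))
        x = rng.normal(0, 1.0, (1, 1, 7))
        *_, energies = _infer_hidden(WH, WF, zprev, x, "tanh", 0.01, 300, 1e-12, record_energy=True)
        traj = np.array([e[0, 0] for e in energies])
        assert np.all(np.diff(traj) <= 1e-10)

    def test_divergence_raises(self, small_binary_seq):
        model = TPCTwoLayer(12, 8, seed=0, lr_weights=50.0)
        with pytest.raises(DivergenceError):
            train_two_layer(small_binary_seq, model, n_epochs=500)

    def test_moving_bar_aliased_hidden_states_differ(self):
        from seqmem.experiments import train_moving_bar_model

        bar = generate_moving_bar()
        model = train_moving_bar_model(seed=0, n_restarts=4, n_epochs=2000)
        rr = recall_two_layer(model, bar, "offline")
        z2, z4 = rr.hidden_trajectory[1], rr.hidden_trajectory[3]
        cos = z2 @ z4 / (np.linalg.norm(z2) * np.linalg.norm(z4))
        assert cos < 0.99
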