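"""Actor / Critic / TCN forward contracts, mask sampling and Hadamard masking."""

import numpy as np
import pytest

from sepselect.autodiff import Tensor
from sepselect.networks import (ActorNet, BaselineNet, CriticNet, ModelBundle,
                                TCN, apply_mask, sample_mask)

RNG = np.random.default_rng(42)


class TestActor:
    def setup_method(self):
        self.actor = ActorNet(np.random.default_rng(0), d=30)

    def test_output_shape_and_open_interval(self):
        S = self.actor(Tensor(RNG.normal(size=(7, 30)))).data
        assert S.shape == (7, 30)
        assert ((S > 0) & (S < 1)).all()

    def test_zeroed_final_layer_forces_sigmoid_of_bias(self):
        self.actor.out.W.data[:] = 0.0
        self.actor.out.b.data[:] = 0.3
        S = self.actor(Tensor(RNG.normal(size=(4, 30)))).data
        np.testing.assert_allclose(S, 1.0 / (1.0 + np.exp(-0.3)), atol=1e-12)

    def test_identical_rows_give_identical_probabilities(self):
        row = RNG.normal(size=30)
        S = self.actor(Tensor(np.tile(row, (5, 1)))).data
        np.testing.assert_array_equal(S, np.tile(S[0], (5, 1)))

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            self.actor(Tensor(np.zeros((2, 29))))


class TestMask:
    def test_threshold_mode_deterministic(self):
        S = np.array([[1 - 1e-9, 0.5, 0.49, 1e-9]])
        M = sample_mask(S, "threshold")
        np.testing.assert_array_equal(M, [[1, 1, 0, 0]])
        np.testing.assert_array_equal(M, sample_mask(S, "threshold"))

    def test_bernoulli_frequency_within_three_standard_errors(self):
        S = np.full((10_000, 1), 0.3)
        M = sample_mask(S, "bernoulli", np.random.default_rng(5))
        se = np.sqrt(0.3 * 0.7 / 10_000)
        assert abs(M.mean() - 0.3) < 3 * se

    def test_seeded_sampling_repeats(self):
        S = RNG.random((20, 30))
        a = sample_mask(S, "bernoulli", np.random.default_rng(9))
        b = sample_mask(S, "bernoulli", np.random.default_rng(9))
        np.testing.assert_array_equal(a, b)

    def test_apply_mask_identity_zero_and_column(self):
        X = Tensor(RNG.normal(size=(4, 6)))
        np.testing.assert_array_equal(
            apply_mask(X, np.ones((4, 6))).data, X.data)
        np.testing.assert_array_equal(
            apply_mask(X, np.zeros((4, 6))).data, np.zeros((4, 6)))
        M = np.ones((4, 6)); M[:, 2] = 0
        out = apply_mask(X, M).data
        assert (out[:, 2] == 0).all()
        np.testing.assert_array_equal(np.delete(out, 2, 1),
                                      np.delete(X.data, 2, 1))
        with pytest.raises(ValueError):
            apply_mask(X, np.ones((4, 5)))


class TestCritic:
    def setup_method(self):
        self.critic = CriticNet(np.random.default_rng(1), d=30)

    def test_eval_mode_deterministic_and_in_unit_interval(self):
        x = Tensor(RNG.normal(size=(6, 30)))
        p1 = self.critic(x, train_mode=False).data
        p2 = self.critic(x, train_mode=False).data
        np.testing.assert_array_equal(p1, p2)
        assert ((p1 >= 0) & (p1 <= 1)).all()

    def test_dropout_changes_training_forward(self):
        x = Tensor(RNG.normal(size=(6, 30)))
        p1 = self.critic(x, train_mode=True, rng=np.random.default_rng(1)).data
        p2 = self.critic(x, train_mode=True, rng=np.random.default_rng(2)).data
        assert not np.allclose(p1, p2)

    def test_fully_masked_input_gives_constant_bias_output(self):
        p = self.critic(Tensor(np.zeros((5, 30))), train_mode=False).data
        np.testing.assert_allclose(p, p[0], atol=1e-12)


class TestTCN:
    def test_constant_in_time_embedding_invariant_to_length(self):
        tcn = TCN(np.random.default_rng(2), n_signals=5, channels=8)
        v = RNG.normal(size=(3, 5, 1))
        e32 = tcn(Tensor(np.repeat(v, 32, axis=2))).data
        e64 = tcn(Tensor(np.repeat(v, 64, axis=2))).data
        np.testing.assert_allclose(e32, e64, atol=1e-6)

    def test_identical_patients_identical_embeddings(self):
        tcn = TCN(np.random.default_rng(3), n_signals=5, channels=8)
        x = np.tile(RNG.normal(size=(1, 5, 16)), (4, 1, 1))
        emb = tcn(Tensor(x)).data
        np.testing.assert_allclose(emb, np.tile(emb[0], (4, 1)), atol=1e-12)

    def test_pre_pooling_activations_are_causal(self):
        """A perturbation of the last step cannot reach earlier positions
        of the first residual block's output (before any pooling)."""
        tcn = TCN(np.random.default_rng(4), n_signals=2, channels=4)
        x = RNG.normal(size=(1, 2, 12))
        x2 = x.copy()
        x2[0, :, -1] += 5.0
        h1 = tcn.blocks[0](Tensor(x)).data
        h2 = tcn.blocks[0](Tensor(x2)).data
        np.testing.assert_array_equal(h1[:, :, :-1], h2[:, :, :-1])

    def test_empty_time_axis_rejected(self):
        tcn = TCN(np.random.default_rng(5), n_signals=2, channels=4)
        with pytest.raises(ValueError):
            tcn(Tensor(np.zeros((1, 2))))


class TestBaselineAndBundle:
    def test_baseline_output_unit_interval_and_bias_constant(self):
        rng = np.random.default_rng(6)
        net = BaselineNet(rng, d=30, emb=8)
        p = net(Tensor(RNG.normal(size=(5, 30))),
                Tensor(RNG.normal(size=(5, 8)))).data
        assert ((p >= 0) & (p <= 1)).all()
        pz = net(Tensor(np.zeros((3, 30))), Tensor(np.zeros((3, 8)))).data
        np.testing.assert_allclose(pz, pz[0], atol=1e-12)

    def test_forward_passes_are_pure(self):
        bundle = ModelBundle.create(seed=7)
        x = Tensor(RNG.normal(size=(4, 30)))
        v = Tensor(RNG.normal(size=(4, 5, 16)))
        s1 = bundle.actor(x).data.copy()
        e1 = bundle.tcn(v).data.copy()
        s2 = bundle.actor(x).data
        e2 = bundle.tcn(v).data
        np.testing.assert_array_equal(s1, s2)
        np.testing.assert_array_equal(e1, e2)

    def test_same_seed_same_parameters(self):
        b1 = ModelBundle.create(seed=3)
        b2 = ModelBundle.create(seed=3)
        for p, q in zip(b1.parameters(), b2.parameters()):
            np.testing.assert_array_equal(p.data, q.data)

    @pytest.mark.parametrize("selector,predictor", [
        ("attention", "attention"), ("attention", "feedforward"),
        ("feedforward", "attention"), ("feedforward", "feedforward")])
    def test_ablation_combinations_train_without_error(self, selector, predictor):
        from sepselect import SynthConfig, generate_synthetic_cohort
        from sepselect.training import TrainConfig, train
        cohort, signals = generate_synthetic_cohort(
            SynthConfig(n=200, positive_count=10, T=8, seed=0))
        bundle = ModelBundle.create(seed=0, selector_kind=selector,
                                    predictor_kind=predictor, tcn_channels=8)
        bundle, hist = train(bundle, cohort, signals,
                             TrainConfig(epochs=2, seed=0))
        assert len(hist["epochs"]) == 2
        assert np.isfinite(hist["epochs"][-1]["L_total"])
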