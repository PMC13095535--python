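"""Loss terms, reward, loss-algebra identities, and training-loop behavior."""

import numpy as np
import pytest

from sepselect import (SynthConfig, generate_synthetic_cohort, ModelBundle,
                       assemble_losses, compute_reward, cross_entropy,
                       selection_loss)
from sepselect.autodiff import Tensor
from sepselect.training import (TrainConfig, cross_entropy_with_logits,
                                featurize, predict_critic, train)


class TestCrossEntropy:
    @pytest.mark.parametrize("p,y,expected", [
        ([0.999999], [1], 1e-6),                       # near-certain hit
        ([0.5, 0.5], [1, 0], np.log(2)),
        ([0.9, 0.2], [1, 0], (-np.log(0.9) - np.log(0.8)) / 2),
    ])
    def test_hand_values(self, p, y, expected):
        assert cross_entropy(np.array(p), np.array(y)) \
            .item() == pytest.approx(expected, abs=1e-4)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cross_entropy(np.array([0.5]), np.array([1, 0]))

    def test_logits_form_agrees_with_probability_form(self):
        rng = np.random.default_rng(0)
        z = rng.normal(size=20) * 3
        y = (rng.random(20) < 0.3).astype(float)
        a = cross_entropy_with_logits(Tensor(z), y).item()
        b = cross_entropy(1 / (1 + np.exp(-z)), y).item()
        assert a == pytest.approx(b, abs=1e-9)

    def test_logits_gradient_is_sigmoid_minus_label(self):
        z = Tensor(np.array([2.0, -1.0, 0.0]), requires_grad=True)
        y = np.array([1.0, 0.0, 1.0])
        cross_entropy_with_logits(z, y).backward()
        s = 1 / (1 + np.exp(-z.data))
        np.testing.assert_allclose(z.grad, (s - y) / 3, atol=1e-12)


class TestSelectionLoss:
    def test_half_probabilities_give_log_two_for_any_mask(self):
        S = np.full((3, 4), 0.5)
        for M in (np.zeros((3, 4)), np.ones((3, 4))):
            assert selection_loss(S, M).item() == pytest.approx(np.log(2))

    def test_hand_value(self):
        S = np.array([[0.8, 0.3]])
        M = np.array([[1.0, 0.0]])
        expected = (-np.log(0.8) - np.log(0.7)) / 2
        assert selection_loss(S, M).item() == pytest.approx(expected, abs=1e-12)

    def test_confident_agreement_is_near_zero(self):
        S = np.array([[0.999999, 1e-6]])
        M = (S > 0.5).astype(float)
        assert selection_loss(S, M).item() < 1e-5


class TestRewardAndBundle:
    def test_reward_arithmetic_and_antisymmetry(self):
        assert compute_reward(0.5, 0.5) == 0.0
        assert compute_reward(0.3, 0.5) == pytest.approx(0.2)
        assert compute_reward(0.5, 0.3) == pytest.approx(-0.2)

    def test_hand_assembled_bundle(self):
        lb = assemble_losses(L_fcl=0.3, L_hsic=0.1, L_prediction=0.4,
                             L_fs=0.7, lam=0.1, S_d_mean=0.5)
        assert lb.R == pytest.approx(0.0, abs=1e-12)
        assert lb.L_actor == pytest.approx(-0.05, abs=1e-12)
        assert lb.L_critic == pytest.approx(0.8, abs=1e-12)
        assert lb.L_total == pytest.approx(0.75, abs=1e-12)

    def test_matched_losses_reduce_actor_to_regularizer(self):
        lb = assemble_losses(L_fcl=0.25, L_hsic=0.15, L_prediction=0.4,
                             L_fs=0.9, lam=0.2, S_d_mean=0.6)
        assert lb.R == pytest.approx(0.0, abs=1e-12)
        assert lb.L_actor == pytest.approx(-0.2 * 0.6, abs=1e-12)

    def test_zero_lambda_zero_fs_total_is_sum_of_critic_terms(self):
        lb = assemble_losses(L_fcl=0.3, L_hsic=0.1, L_prediction=0.2,
                             L_fs=0.0, lam=0.0, S_d_mean=0.5)
        assert lb.L_total == pytest.approx(0.6, abs=1e-12)

    def test_non_finite_part_aborts(self):
        with pytest.raises(FloatingPointError):
            assemble_losses(np.nan, 0.1, 0.2, 0.3, 0.1, 0.5)


@pytest.fixture(scope="module")
def smoke_run():
    cohort, signals = generate_synthetic_cohort(
        SynthConfig(n=200, positive_count=10, T=8, seed=4))
    bundle = ModelBundle.create(seed=4, tcn_channels=8)
    bundle, hist = train(bundle, cohort, signals,
                         TrainConfig(epochs=5, seed=4))
    return cohort, signals, bundle, hist


class TestTrainingLoop:
    def test_history_has_one_record_per_epoch(self, smoke_run):
        *_, hist = smoke_run
        assert len(hist["epochs"]) == 5

    def test_loss_identities_hold_at_every_step(self, smoke_run):
        *_, hist = smoke_run
        tol = 1e-9
        for s in hist["steps"]:
            assert abs(s["L_baseline"] - (s["L_fcl"] + s["L_hsic"])) <= tol
            assert abs(s["R"] + s["L_prediction"] - s["L_baseline"]) <= tol
            assert abs(s["L_critic"]
                       - (s["L_baseline"] + s["L_prediction"])) <= tol
            assert abs(s["L_actor"]
                       - (s["R"] * s["L_fs"] - s["lam"] * s["S_d_mean"])) <= tol
            assert abs(s["L_total"] - (s["L_actor"] + s["L_critic"])) <= tol

    def test_two_identical_seeds_identical_history(self):
        cohort, signals = generate_synthetic_cohort(
            SynthConfig(n=120, positive_count=6, T=8, seed=1))
        hists = []
        for _ in range(2):
            bundle = ModelBundle.create(seed=2, tcn_channels=8)
            _, hist = train(bundle, cohort, signals,
                            TrainConfig(epochs=3, seed=2))
            hists.append(hist)
        assert hists[0]["epochs"] == hists[1]["epochs"]
        assert hists[0]["steps"] == hists[1]["steps"]

    def test_no_gradient_path_from_prediction_into_actor(self, smoke_run):
        """With the reward detached, the Critic loss alone must not touch
        Actor parameters; only the score term and regularizer do."""
        cohort, signals, bundle, _ = smoke_run
        from sepselect.hsic import hsic_loss
        from sepselect.networks import apply_mask, sample_mask
        X_d = featurize(bundle, cohort, signals)
        xb = Tensor(X_d[:16])
        yb = cohort.y[:16].astype(float)
        rng = np.random.default_rng(0)
        S_d = bundle.actor(xb)
        M = sample_mask(S_d.data, "bernoulli", rng)
        z = bundle.critic.logits(apply_mask(xb, M), train_mode=True, rng=rng)
        L_pred = cross_entropy_with_logits(z, yb)
        for p in bundle.actor.parameters():
            p.grad = None
        L_pred.backward()
        assert all(p.grad is None for p in bundle.actor.parameters())

    def test_frozen_actor_reduces_critic_to_supervised_classifier(self):
        """lambda=0 and an all-ones mask: Critic training loss should be
        non-increasing (after the first epochs) on separable data."""
        rng = np.random.default_rng(3)
        n = 120
        X = np.r_[rng.normal(-2, 0.5, (n // 2, 30)),
                  rng.normal(2, 0.5, (n // 2, 30))]
        y = np.r_[np.zeros(n // 2), np.ones(n // 2)]
        from sepselect.networks import CriticNet
        from sepselect.autodiff import Adam
        critic = CriticNet(np.random.default_rng(0), d=30, dropout=0.0)
        opt = Adam(critic.parameters(), lr=0.01)
        losses = []
        for _ in range(30):
            z = critic.logits(Tensor(X), train_mode=False)
            loss = cross_entropy_with_logits(z, y)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        assert losses[-1] < losses[0]
        assert losses[-1] < 0.05

    def test_reward_turns_negative_when_critic_is_sabotaged(self, smoke_run):
        """Inflating L_prediction (scoring the Critic against shuffled
        labels) while the baseline keeps the honest ones drives R down."""
        cohort, signals, bundle, _ = smoke_run
        from sepselect.training import predict_baseline
        X_d = featurize(bundle, cohort, signals)
        p_crit, _, _ = predict_critic(bundle, X_d)
        p_base = predict_baseline(bundle, X_d, signals.X_v)
        y = cohort.y.astype(float)
        L_base = cross_entropy(p_base, y).item()
        r_honest = compute_reward(cross_entropy(p_crit, y).item(), L_base)
        rewards = []
        for seed in range(5):
            y_sh = np.random.default_rng(seed).permutation(y)
            rewards.append(compute_reward(
                cross_entropy(p_crit, y_sh).item(), L_base))
        assert np.mean(rewards) < r_honest
        assert np.mean(rewards) < 0

    def test_batch_size_below_two_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(batch_size=1).validate()
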