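"""Multi-task CNN: numerics (gradient checks), losses, training, observers."""

from dataclasses import replace

import numpy as np
import pytest

from erocio import (
    MultiTaskCNN,
    MultiTaskNetSpec,
    TrainConfig,
    UtilityFunction,
    detection_loss,
    estimation_loss,
    generate_dataset,
    hybrid_io_apply,
    posterior_to_likelihood_ratio,
    select_depth,
    subideal_apply,
    train_multitask,
)
from erocio.nn import sigmoid
from erocio.observers.learned import utility_gradient


def tiny_spec(theta_dim=1):
    return MultiTaskNetSpec(
        n_shared_conv=1, n_estimation_conv=1, filters=2, kernel=3,
        image_shape=(4, 4), theta_dim=theta_dim,
    )


def all_params(net):
    for seq in (net.shared, net.det_head, net.est_branch):
        for layer in seq.layers:
            for k in layer.params:
                yield layer, k


class TestGradients:
    """Backprop vs central finite differences on a tiny network."""

    @pytest.mark.parametrize("kind,param", [("gaussian", 2.0), ("quadratic", 5.0)])
    def test_estimation_branch_gradients(self, kind, param, rng):
        net = MultiTaskCNN(tiny_spec(theta_dim=2), seed=0)
        u = UtilityFunction(kind, param)
        x = rng.normal(size=(3, 16))
        theta = rng.normal(size=(3, 2))

        def loss():
            th = net.est_branch.forward(net.shared.forward(net._to_maps(x)))
            return estimation_loss(th, theta, u)

        # analytic gradients
        th = net.est_branch.forward(net.shared.forward(net._to_maps(x)))
        dth = -utility_gradient(u, th, theta) / theta.shape[0]
        net.shared.backward(net.est_branch.backward(dth))
        eps = 1e-6
        for seq in (net.shared, net.est_branch):
            for layer in seq.layers:
                for k, p in layer.params.items():
                    idx = np.unravel_index(rng.integers(p.size), p.shape)
                    orig = p[idx]
                    p[idx] = orig + eps
                    lp = loss()
                    p[idx] = orig - eps
                    lm = loss()
                    p[idx] = orig
                    fd = (lp - lm) / (2 * eps)
                    assert layer.grads[k][idx] == pytest.approx(fd, rel=1e-4, abs=1e-8)

    def test_detection_branch_gradients(self, rng):
        net = MultiTaskCNN(tiny_spec(), seed=1)
        x = rng.normal(size=(4, 16))
        y = np.array([1.0, 0.0, 1.0, 0.0])

        def loss():
            return detection_loss(sigmoid(net.detection_logits(x)), y)

        logits = net.detection_logits(x)
        p = sigmoid(logits)
        net.shared.backward(net.det_head.backward(((p - y) / y.size)[:, None]))
        eps = 1e-6
        for seq in (net.shared, net.det_head):
            for layer in seq.layers:
                for k, par in layer.params.items():
                    idx = np.unravel_index(rng.integers(par.size), par.shape)
                    orig = par[idx]
                    par[idx] = orig + eps
                    lp = loss()
                    par[idx] = orig - eps
                    lm = loss()
                    par[idx] = orig
                    fd = (lp - lm) / (2 * eps)
                    assert layer.grads[k][idx] == pytest.approx(fd, rel=1e-4, abs=1e-8)


class TestLosses:
    def test_confident_correct_predictions_drive_loss_to_zero(self):
        p = np.array([1 - 1e-9, 1e-9])
        y = np.array([1.0, 0.0])
        assert detection_loss(p, y) < 1e-8

    def test_uninformative_probability_gives_log_two(self):
        assert detection_loss(np.full(8, 0.5), np.array([1, 0, 1, 0, 1, 0, 1, 0])) == (
            pytest.approx(np.log(2))
        )

    def test_matches_hand_rolled_cross_entropy(self):
        p = np.array([0.9, 0.2, 0.6, 0.4])
        y = np.array([1.0, 0.0, 0.0, 1.0])
        by_hand = -np.mean(
            [np.log(0.9), np.log(0.8), np.log(0.4), np.log(0.4)]
        )
        assert detection_loss(p, y) == pytest.approx(by_hand, rel=1e-12)

    def test_perfect_estimates_give_minus_one(self):
        th = np.array([[1.0, 2.0]])
        assert estimation_loss(th, th, UtilityFunction("l1", 20.0)) == -1.0

    def test_quadratic_example(self):
        # single case, squared error 100, eps1 = 100 -> loss 0
        assert estimation_loss(
            np.array([[10.0]]), np.array([[0.0]]), UtilityFunction("quadratic", 100.0)
        ) == pytest.approx(0.0)

    def test_is_negative_mean_utility(self, rng):
        u = UtilityFunction("gaussian", 3.0)
        th = rng.normal(size=(6, 2))
        t = rng.normal(size=(6, 2))
        from erocio import evaluate_utility

        assert estimation_loss(th, t, u) == pytest.approx(-np.mean(evaluate_utility(u, th, t)))

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            estimation_loss(np.zeros((0, 1)), np.zeros((0, 1)), UtilityFunction("l1", 1.0))


class TestPosteriorToLikelihoodRatio:
    def test_values(self):
        assert posterior_to_likelihood_ratio(0.5) == 1.0
        assert posterior_to_likelihood_ratio(0.0) == 0.0

    def test_monotone(self):
        p = np.linspace(0.0, 0.99, 50)
        lam = posterior_to_likelihood_ratio(p)
        assert np.all(np.diff(lam) > 0)

    def test_unit_probability_warns_infinite(self):
        with pytest.warns(UserWarning):
            assert posterior_to_likelihood_ratio(1.0) == np.inf

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            posterior_to_likelihood_ratio(1.5)


class TestDepthSelection:
    def test_stops_after_sub_threshold_improvement(self):
        # improvements 10%, 5%, 0.5% -> select 3 layers
        losses = [1.0, 0.9, 0.855, 0.8507]
        assert select_depth(losses) == 3

    def test_no_significant_improvement_keeps_one_layer(self):
        assert select_depth([1.0, 0.999, 0.998]) == 1

    def test_all_significant_keeps_deepest(self):
        assert select_depth([1.0, 0.8, 0.6, 0.4]) == 4


@pytest.fixture(scope="module")
def toy_dataset():
    import erocio

    cfg = replace(
        erocio.bke_amplitude(), n_rows=8, n_cols=8,
        signal={"A_s": {"dist": "normal", "mu": 9.0, "sigma": 4.0},
                "w_s": 1.0, "r_s": [4.0, 4.0]},
    )
    return generate_dataset(cfg, 300, 300, seed=3, noiseless=True)


class TestTraining:
    def toy_net_spec(self):
        return MultiTaskNetSpec(
            n_shared_conv=1, n_estimation_conv=1, filters=4, kernel=3,
            image_shape=(8, 8), theta_dim=1, input_scale=1 / 40.0,
        )

    def test_zero_iterations_leave_network_unchanged(self, toy_dataset):
        spec = self.toy_net_spec()
        cfg = TrainConfig(batch_present=16, batch_absent=16, lr=1e-3, n_minibatches=0, seed=0)
        net = MultiTaskCNN(spec, seed=5)
        before = [p.copy() for _, p in [(l, l.params[k]) for l, k in all_params(net)]]
        trained, _ = train_multitask(toy_dataset, spec, cfg, net=net)
        after = [l.params[k] for l, k in all_params(trained)]
        for b, a in zip(before, after):
            np.testing.assert_array_equal(b, a)

    def test_short_training_reduces_detection_loss(self, toy_dataset):
        spec = self.toy_net_spec()
        cfg = TrainConfig(batch_present=32, batch_absent=32, lr=1e-3,
                          n_minibatches=150, seed=0)
        _, hist = train_multitask(toy_dataset, spec, cfg)
        assert np.mean(hist["det_loss"][-20:]) < np.mean(hist["det_loss"][:5])

    def test_training_is_seeded(self, toy_dataset):
        spec = self.toy_net_spec()
        cfg = TrainConfig(batch_present=8, batch_absent=8, lr=1e-3, n_minibatches=5, seed=7)
        n1, h1 = train_multitask(toy_dataset, spec, cfg)
        n2, h2 = train_multitask(toy_dataset, spec, cfg)
        np.testing.assert_array_equal(h1["det_loss"], h2["det_loss"])
        for (l1, k1), (l2, k2) in zip(all_params(n1), all_params(n2)):
            np.testing.assert_array_equal(l1.params[k1], l2.params[k2])

    def test_semi_online_noise_differs_across_iterations(self, toy_dataset):
        nm = toy_dataset.noise_model()
        a = nm.sample((4,), counter=0)
        b = nm.sample((4,), counter=2)
        assert not np.array_equal(a, b)
        np.testing.assert_array_equal(a, nm.sample((4,), counter=0))


class TestArchitectureSearch:
    def test_micro_search_runs_and_logs_depths(self, toy_dataset):
        from erocio import architecture_search

        spec = MultiTaskNetSpec(
            n_shared_conv=1, n_estimation_conv=1, filters=2, kernel=3,
            image_shape=(8, 8), theta_dim=1, input_scale=1 / 40.0,
        )
        cfg = TrainConfig(batch_present=8, batch_absent=8, lr=1e-3,
                          n_minibatches=20, seed=0, val_every=5)
        val = generate_dataset(toy_dataset.config, 20, 20, seed=11, noiseless=True)
        selected, trace = architecture_search(
            toy_dataset, cfg, val, spec, max_shared=2, max_estimation=2
        )
        assert 1 <= selected.n_shared_conv <= 2
        assert 1 <= selected.n_estimation_conv <= 2
        assert len(trace["shared_losses"]) >= 1
        assert len(trace["estimation_losses"]) >= 1


class TestObserverAssembly:
    def test_subideal_and_hybrid_share_estimates(self, rng):
        net = MultiTaskCNN(tiny_spec(), seed=2)
        g = rng.normal(size=16)
        _, th_sub = subideal_apply(net, g)
        sampler = lambda g_: np.zeros((10, 1))  # noqa: E731
        _, th_hyb, _, _ = hybrid_io_apply(net, sampler, UtilityFunction("l1", 5.0), g)
        np.testing.assert_array_equal(th_sub, th_hyb)

    def test_ranking_matches_detection_probability(self, rng):
        net = MultiTaskCNN(tiny_spec(), seed=3)
        G = rng.normal(size=(20, 16))
        t, _ = subideal_apply(net, G)
        p = net.detection_prob(G)
        assert np.array_equal(np.argsort(t), np.argsort(p))

    def test_hybrid_t_finite_with_samples(self, rng):
        net = MultiTaskCNN(tiny_spec(), seed=4)
        g = rng.normal(size=16)
        t, _, lam, u_hat = hybrid_io_apply(
            net, lambda g_: rng.normal(size=(25, 1)), UtilityFunction("gaussian", 3.0), g
        )
        assert np.isfinite(t) and np.isfinite(lam) and 0 < u_hat <= 1
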