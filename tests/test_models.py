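import copy

import numpy as np
import pytest

from dilipred.evaluate import auroc
from dilipred.models import (
    AttentionNetwork,
    DiliModel,
    SearchSpec,
    fit_baseline,
    search_architecture,
)
from dilipred.featurize import ScalerState


class TestAttentionForward:
    def test_weights_sum_to_one_random_draws(self):
        # softmax normalization holds for arbitrary parameters and inputs
        rng = np.random.default_rng(0)
        net = AttentionNetwork(input_dim=20, hidden=(8,), seed=1)
        for _ in range(100):
            net.params["Wa"] = rng.normal(scale=2.0, size=(20, 20))
            net.params["ba"] = rng.normal(size=20)
            s = net.attention(rng.normal(size=(3, 20)))
            assert (s > 0).all()
            np.testing.assert_allclose(s.sum(axis=1), 1.0, atol=1e-9)

    def test_zero_parameters_give_uniform_weights(self):
        net = AttentionNetwork(input_dim=10, seed=0)
        net.params["Wa"][:] = 0.0
        net.params["ba"][:] = 0.0
        s = net.attention(np.random.default_rng(1).normal(size=(2, 10)))
        np.testing.assert_allclose(s, 1.0 / 10, atol=1e-12)

    def test_zero_input_gives_zero_weighted_vector(self):
        net = AttentionNetwork(input_dim=6, seed=0)
        cache = net.forward(np.zeros((1, 6)))
        np.testing.assert_array_equal(cache["v"], 0.0)

    def test_dimension_mismatch(self):
        net = AttentionNetwork(input_dim=6, seed=0)
        with pytest.raises(ValueError, match="dim"):
            net.forward(np.zeros((1, 7)))

    def test_inference_deterministic_bitwise(self):
        rng = np.random.default_rng(3)
        net = AttentionNetwork(input_dim=12, seed=2)
        X = rng.normal(size=(5, 12))
        p1 = net.predict_proba(X)
        p2 = net.predict_proba(X)
        assert p1.tobytes() == p2.tobytes()

    def test_permutation_equivariance(self):
        # permuting features and parameters consistently permutes W_att
        # and leaves the probability unchanged
        rng = np.random.default_rng(4)
        D = 9
        net = AttentionNetwork(input_dim=D, hidden=(7,), seed=5)
        X = rng.normal(size=(3, D))
        perm = rng.permutation(D)
        net_p = copy.deepcopy(net)
        net_p.params["Wa"] = net.params["Wa"][np.ix_(perm, perm)]
        net_p.params["ba"] = net.params["ba"][perm]
        net_p.params["W0"] = net.params["W0"][:, perm]
        c = net.forward(X)
        c_p = net_p.forward(X[:, perm])
        np.testing.assert_allclose(c_p["s"], c["s"][:, perm], atol=1e-12)
        np.testing.assert_allclose(c_p["p"], c["p"], atol=1e-12)

    def test_gradients_match_finite_differences(self):
        rng = np.random.default_rng(6)
        net = AttentionNetwork(input_dim=5, hidden=(4,), dropout=0.0, seed=7)
        X = rng.normal(size=(6, 5))
        y = rng.integers(0, 2, 6)
        run0 = copy.deepcopy(net.running)
        _, grads, _ = net._loss_and_grads(X, y, training=True)
        net.running = copy.deepcopy(run0)
        eps = 1e-6
        for key in net.params:
            flat_idx = [np.unravel_index(i, net.params[key].shape)
                        for i in range(min(4, net.params[key].size))]
            for idx in flat_idx:
                orig = net.params[key][idx]
                for sign in (+1, -1):
                    net.params[key][idx] = orig + sign * eps
                    net.running = copy.deepcopy(run0)
                    loss, _, _ = net._loss_and_grads(X, y, training=True)
                    if sign > 0:
                        lp = loss
                    else:
                        lm = loss
                net.params[key][idx] = orig
                net.running = copy.deepcopy(run0)
                num = (lp - lm) / (2 * eps)
                assert num == pytest.approx(grads[key][idx], rel=1e-4, abs=1e-7), key


class TestAttentionTraining:
    def test_separable_toy_accuracy(self, toy_separable):
        X, y = toy_separable
        net = AttentionNetwork(2, hidden=(16,), seed=3)
        net.fit(X, y, epochs=60)
        acc = ((net.predict_proba(X)[:, 1] > 0.5) == y).mean()
        assert acc >= 0.95

    def test_training_improves_loss(self, toy_separable):
        X, y = toy_separable
        net = AttentionNetwork(2, hidden=(16,), seed=4)
        net.fit(X, y, epochs=30)
        assert net.history_[-1]["train_loss"] <= net.history_[0]["train_loss"]

    def test_same_seed_identical_history(self, toy_separable):
        X, y = toy_separable
        h = []
        for _ in range(2):
            net = AttentionNetwork(2, hidden=(8,), seed=9)
            net.fit(X, y, epochs=8)
            h.append(net.history_)
        assert h[0] == h[1]

    def test_single_epoch_single_history_entry(self, toy_separable):
        X, y = toy_separable
        net = AttentionNetwork(2, hidden=(8,), seed=1)
        net.fit(X, y, epochs=1)
        assert len(net.history_) == 1

    def test_single_class_rejected(self):
        net = AttentionNetwork(3, seed=0)
        with pytest.raises(ValueError, match="both classes"):
            net.fit(np.zeros((10, 3)), np.zeros(10))

    def test_early_stopping_caps_epochs(self, toy_separable):
        X, y = toy_separable
        net = AttentionNetwork(2, hidden=(8,), seed=2)
        net.fit(X, y, epochs=100, patience=3)
        assert len(net.history_) <= 100

    def test_state_dict_round_trip(self, toy_separable):
        X, y = toy_separable
        net = AttentionNetwork(2, hidden=(8,), seed=5)
        net.fit(X, y, epochs=5)
        clone = AttentionNetwork.from_state_dict(net.state_dict())
        np.testing.assert_array_equal(clone.predict_proba(X), net.predict_proba(X))


class TestBaselines:
    @pytest.mark.parametrize("kind", ["rf", "lgbm", "lr"])
    def test_separable_toy_auroc(self, toy_separable, kind):
        X, y = toy_separable
        m = fit_baseline(kind, X[:150], y[:150], seed=0)
        assert auroc(y[150:], m.predict_proba(X[150:])[:, 1]) >= 0.95

    def test_search_log_has_fifty_entries(self, toy_separable):
        X, y = toy_separable
        spec = SearchSpec(kind="lr", iterations=50, cv=3, seed=0)
        m = fit_baseline("lr", X, y, search=spec, seed=0)
        assert len(m.search_log) == 50
        assert all("mean_cv_auroc" in e for e in m.search_log)

    def test_duplicated_feature_near_equal_coefficients(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=(300, 1))
        X = np.hstack([x, x])
        y = (x.ravel() + 0.3 * rng.normal(size=300) > 0).astype(int)
        m = fit_baseline("lr", X, y, seed=0)
        c = m.model.coef_.ravel()
        assert c[0] == pytest.approx(c[1], rel=0.05)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            fit_baseline("rf", np.zeros((8, 2)), np.ones(8))

    def test_unknown_kind(self):
        with pytest.raises(ValueError, match="unknown baseline"):
            fit_baseline("svm", np.zeros((8, 2)), np.r_[np.zeros(4), np.ones(4)])


class TestArchitectureSearch:
    def test_budget_one_returns_single_evaluation(self, toy_separable):
        X, y = toy_separable
        best, log = search_architecture(X, y, layer_options=(1,), node_options=(4, 8),
                                        budget=1, seed=0, epochs=3)
        assert len(log) == 1
        assert best == (log[0]["layers"], log[0]["nodes"])

    def test_fixed_bounds_return_that_configuration(self, toy_separable):
        X, y = toy_separable
        best, log = search_architecture(X, y, layer_options=(2,), node_options=(8,),
                                        budget=4, seed=0, epochs=3)
        assert best == (2, 8) and len(log) == 1

    def test_empty_bounds_rejected(self, toy_separable):
        X, y = toy_separable
        with pytest.raises(ValueError, match="empty"):
            search_architecture(X, y, layer_options=(), node_options=(8,), budget=2)

    def test_beats_or_matches_random_baseline(self, toy_separable):
        X, y = toy_separable
        best, log = search_architecture(X, y, layer_options=(1, 2), node_options=(4, 8, 16),
                                        budget=5, seed=0, epochs=5)
        assert max(e["score"] for e in log) >= np.median([e["score"] for e in log])


class TestDiliModelArchive:
    def test_save_load_round_trip(self, toy_separable, tmp_path):
        X, y = toy_separable
        Xr = np.hstack([(X > 0).astype(float), np.tile(X, (1, 4))])  # 2 bits + 8 "descriptors"
        scaler = ScalerState(mean=np.zeros(8), sd=np.ones(8))
        m = fit_baseline("lr", Xr, y, seed=0)
        archive = DiliModel(kind="lr", model=m.model, scaler=scaler, n_bits=2)
        path = tmp_path / "model.joblib"
        archive.save(path)
        back = DiliModel.load(path)
        np.testing.assert_allclose(back.predict_proba(Xr), archive.predict_proba(Xr))
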