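"""Learning mode: BPTT gradients, adaptive rates, PB updates, training loop."""

import numpy as np
import pytest

from rnnpb.network import (
    ModelWeights,
    NetworkConfig,
    PBVector,
    forward_pass,
    sequence_cost,
    transfer_derivative_from_activation,
)
from rnnpb.training import (
    AdaptiveRateState,
    TrainingParams,
    adapt_learning_rates,
    bptt_gradients,
    train,
    update_pb_learning,
)
from rnnpb.trajectories import DatasetProtocol, SensorimotorSequence, make_sequence


def finite_difference_gradients(weights, pb, values, h=1e-6):
    """Independent oracle: central differences of the sequence cost."""

    def cost():
        fwd = forward_pass(weights, pb, values)
        return sequence_cost(fwd["s_o"], values[1:])

    fd = {}
    for name in ModelWeights.MATRIX_FIELDS:
        arr = getattr(weights, name)
        g = np.zeros_like(arr)
        it = np.nditer(arr, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            orig = arr[idx]
            arr[idx] = orig + h
            cp = cost()
            arr[idx] = orig - h
            cm = cost()
            arr[idx] = orig
            g[idx] = (cp - cm) / (2 * h)
        fd[name] = g
    fd_rho = {}
    for rho, key in ((pb.rho1, "rho1"), (pb.rho2, "rho2")):
        g = np.zeros_like(rho)
        for i in range(rho.size):
            orig = rho[i]
            rho[i] = orig + h
            pb.refresh()
            cp = cost()
            rho[i] = orig - h
            pb.refresh()
            cm = cost()
            rho[i] = orig
            pb.refresh()
            g[i] = (cp - cm) / (2 * h)
        fd_rho[key] = g
    return fd, fd_rho


@pytest.mark.parametrize("case_seed", range(8))
def test_bptt_matches_finite_differences(case_seed):
    """Analytic full-unroll gradients agree with central differences for
    every weight matrix and both PB groups on random tiny networks."""
    rng = np.random.default_rng(1000 + case_seed)
    cfg = NetworkConfig(
        n_in=int(rng.integers(1, 4)),
        n_d=int(rng.integers(1, 4)),
        n_v=int(rng.integers(1, 4)),
        n_pb1=int(rng.integers(1, 3)),
        n_pb2=int(rng.integers(1, 3)),
    )
    w = ModelWeights.random(cfg, rng, scale=0.6)
    pb = PBVector(rho1=rng.normal(size=cfg.n_pb1), rho2=rng.normal(size=cfg.n_pb2))
    values = rng.uniform(0, 1, size=(int(rng.integers(2, 6)), cfg.n_in))

    grads, deltas, _ = bptt_gradients(w, pb, values)
    fd, fd_rho = finite_difference_gradients(w, pb, values)
    for name in ModelWeights.MATRIX_FIELDS:
        np.testing.assert_allclose(
            grads[name], fd[name], rtol=1e-5, atol=1e-9, err_msg=name
        )
    # accumulated PB deltas are the negative cost gradient w.r.t. rho
    np.testing.assert_allclose(
        -deltas["delta1"].sum(axis=0), fd_rho["rho1"], rtol=1e-5, atol=1e-9
    )
    np.testing.assert_allclose(
        -deltas["delta2"].sum(axis=0), fd_rho["rho2"], rtol=1e-5, atol=1e-9
    )


def test_pb_delta_closed_form_single_step():
    """For a 1-unit-per-layer network and a length-2 sequence the group-2 PB
    delta reduces to e * x_v * u_d * f'(y_d) * f'(rho2) * wbar_d."""
    rng = np.random.default_rng(7)
    cfg = NetworkConfig(n_in=1, n_d=1, n_v=1, n_pb1=1, n_pb2=1)
    w = ModelWeights.random(cfg, rng, scale=0.8)
    pb = PBVector(rho1=rng.normal(size=1), rho2=rng.normal(size=1))
    values = rng.uniform(0, 1, size=(2, 1))

    _, deltas, _ = bptt_gradients(w, pb, values)
    fwd = forward_pass(w, pb, values)
    e = values[1, 0] - fwd["s_o"][0, 0]
    hand = (
        e
        * fwd["x_v"][0, 0]
        * w.u_d[0, 0]
        * transfer_derivative_from_activation(fwd["s_d"][0, 0])
        * transfer_derivative_from_activation(pb.act2[0])
        * w.wbar_d[0, 0]
    )
    assert deltas["delta2"][0, 0] == pytest.approx(hand, rel=1e-12)


def test_perfect_prediction_gives_zero_gradients():
    cfg = NetworkConfig(n_in=1, n_d=1, n_v=1, n_pb1=1, n_pb2=1)
    w = ModelWeights(
        w_d=[[0.0]], v_d=[[0.0]], wbar_d=[[0.0]],
        w_v=[[0.0]], v_v=[[0.0]], wbar_v=[[0.0]],
        u_d=[[0.0]], u_v=[[0.0]],
    )
    pb = PBVector.zeros(cfg)
    values = np.zeros((4, 1))  # all-zero weights predict the zero sequence
    grads, deltas, cost = bptt_gradients(w, pb, values)
    assert cost == 0.0
    assert all(np.all(g == 0) for g in grads.values())
    assert np.all(deltas["delta1"] == 0) and np.all(deltas["delta2"] == 0)


class TestAdaptiveRates:
    def _state(self, eta=1e-3):
        w = ModelWeights(
            w_d=np.zeros((1, 1)), v_d=np.zeros((1, 1)), wbar_d=np.zeros((1, 1)),
            w_v=np.zeros((1, 1)), v_v=np.zeros((1, 1)), wbar_v=np.zeros((1, 1)),
            u_d=np.zeros((1, 1)), u_v=np.zeros((1, 1)),
        )
        p = TrainingParams(eta_dorsal=eta, eta_ventral=eta, eta_output=eta)
        return AdaptiveRateState.initial(w, p)

    def grad(self, value):
        return {
            name: np.full((1, 1), value)
            for name in ModelWeights.MATRIX_FIELDS
        }

    def test_first_epoch_leaves_rates_unchanged(self):
        st = self._state()
        adapt_learning_rates(st, self.grad(1.0))
        assert st.eta["w_d"][0, 0] == 1e-3

    def test_same_sign_grows_capped_at_max(self):
        st = self._state(eta=1e-1)  # already at eta_max
        adapt_learning_rates(st, self.grad(1.0))
        adapt_learning_rates(st, self.grad(2.0))
        assert st.eta["w_d"][0, 0] == pytest.approx(1e-1)

    def test_sign_flip_shrinks_floored_at_min(self):
        st = self._state(eta=1e-7)  # already at eta_min
        adapt_learning_rates(st, self.grad(1.0))
        adapt_learning_rates(st, self.grad(-1.0))
        assert st.eta["w_d"][0, 0] == pytest.approx(1e-7)

    def test_growth_and_decay_factors(self):
        st = self._state(eta=1e-3)
        adapt_learning_rates(st, self.grad(1.0))
        adapt_learning_rates(st, self.grad(1.0))
        assert st.eta["w_d"][0, 0] == pytest.approx(1e-3 * 1.000001)
        adapt_learning_rates(st, self.grad(-1.0))
        assert st.eta["w_d"][0, 0] == pytest.approx(1e-3 * 1.000001 * 0.999999)

    def test_zero_gradient_leaves_rate_unchanged(self):
        st = self._state(eta=1e-3)
        adapt_learning_rates(st, self.grad(1.0))
        adapt_learning_rates(st, self.grad(0.0))
        assert st.eta["w_d"][0, 0] == 1e-3

    def test_rates_stay_within_bounds_under_random_gradients(self):
        st = self._state(eta=1e-3)
        rng = np.random.default_rng(0)
        for _ in range(200):
            adapt_learning_rates(st, self.grad(float(rng.normal())))
            for eta in st.eta.values():
                assert np.all(eta >= 1e-7) and np.all(eta <= 1e-1)


class TestPBUpdate:
    def test_zero_deltas_leave_pb_unchanged(self):
        pb = PBVector(rho1=[0.3], rho2=[-0.2])
        new = update_pb_learning(
            pb, {"delta1": np.zeros((5, 1)), "delta2": np.zeros((5, 1))}, 1e-2
        )
        np.testing.assert_array_equal(new.rho1, pb.rho1)
        np.testing.assert_array_equal(new.rho2, pb.rho2)

    def test_constant_delta_increment(self):
        # constant delta d over T steps: rho += m_gamma*|d| * (T*d)
        d, T, mg = 0.4, 6, 1e-2
        pb = PBVector(rho1=[0.0], rho2=[0.0])
        new = update_pb_learning(
            pb,
            {"delta1": np.full((T, 1), d), "delta2": np.zeros((T, 1))},
            mg,
        )
        assert new.rho1[0] == pytest.approx(mg * abs(d) * T * d, rel=1e-12)
        assert new.act1[0] == pytest.approx(1.7159 * np.tanh(2 / 3 * new.rho1[0]))

    @pytest.mark.parametrize("sign", [1.0, -1.0])
    def test_increment_sign_follows_delta_sum(self, sign):
        pb = PBVector(rho1=[0.0], rho2=[0.0])
        deltas = {
            "delta1": sign * np.abs(np.random.default_rng(3).normal(size=(7, 1))),
            "delta2": np.zeros((7, 1)),
        }
        new = update_pb_learning(pb, deltas, 1e-2)
        assert np.sign(new.rho1[0]) == sign


def _constant_sequence(value=0.5, T=8):
    vals = np.full((T, 4), 0.0)
    vals[:, 0] = value
    vals[:, 1] = value * 0.6
    return SensorimotorSequence(
        values=vals, color_label="yellow", curve_label="cosine", sequence_id="const"
    )


class TestTrain:
    small_cfg = NetworkConfig(n_in=4, n_d=6, n_v=6, n_pb1=1, n_pb2=1)

    def test_cost_non_increasing_on_constant_sequence(self):
        _, _, report = train(
            [_constant_sequence()],
            config=self.small_cfg,
            params=TrainingParams(max_epochs=50),
            seed=0,
        )
        c = np.array(report.cost_per_epoch)
        assert np.all(np.diff(c) <= 1e-12)

    def test_color_difference_separates_pb(self):
        a = make_sequence("cosine", "yellow", DatasetProtocol(), seed=1,
                          sequence_id="a")
        b = make_sequence("cosine", "green", DatasetProtocol(), seed=1,
                          sequence_id="b")
        _, pb_table, _ = train(
            [a, b], config=self.small_cfg,
            params=TrainingParams(max_epochs=1000), seed=2,
        )
        va = np.concatenate([pb_table["a"].rho1, pb_table["a"].rho2])
        vb = np.concatenate([pb_table["b"].rho1, pb_table["b"].rho2])
        # the codes need not be large this early, but they must have moved
        # apart by more than either has moved from the origin
        assert np.linalg.norm(va - vb) > 0.5 * max(
            np.linalg.norm(va), np.linalg.norm(vb)
        )

    def test_same_seed_reproducible(self):
        data = [_constant_sequence()]
        r1 = train(data, config=self.small_cfg,
                   params=TrainingParams(max_epochs=20), seed=5)
        r2 = train(data, config=self.small_cfg,
                   params=TrainingParams(max_epochs=20), seed=5)
        assert r1[2].cost_per_epoch == r2[2].cost_per_epoch
        for name in ModelWeights.MATRIX_FIELDS:
            np.testing.assert_array_equal(getattr(r1[0], name), getattr(r2[0], name))

    def test_frozen_pb_reduces_to_elman_bptt(self):
        _, pb_table, _ = train(
            [_constant_sequence()], config=self.small_cfg,
            params=TrainingParams(max_epochs=30), seed=0, pb_update=False,
        )
        pb = pb_table["const"]
        assert np.all(pb.rho1 == 0) and np.all(pb.rho2 == 0)

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            train([], config=self.small_cfg)

    def test_fast_path_matches_reference(self, monkeypatch):
        """The compiled epoch kernel reproduces the numpy reference path."""
        import rnnpb._fast as fast

        if not fast.HAVE_NUMBA:
            pytest.skip("numba unavailable; only one path exists")
        data = [
            make_sequence("cosine", "yellow", DatasetProtocol(), seed=3,
                          sequence_id="s1"),
            make_sequence("square", "green", DatasetProtocol(), seed=4,
                          sequence_id="s2"),
        ]
        params = TrainingParams(max_epochs=30)
        w_fast, pb_fast, rep_fast = train(data, config=self.small_cfg,
                                          params=params, seed=9)
        monkeypatch.setattr(fast, "HAVE_NUMBA", False)
        w_ref, pb_ref, rep_ref = train(data, config=self.small_cfg,
                                       params=params, seed=9)
        np.testing.assert_allclose(
            rep_fast.cost_per_epoch, rep_ref.cost_per_epoch, rtol=1e-10
        )
        for name in ModelWeights.MATRIX_FIELDS:
            np.testing.assert_allclose(
                getattr(w_fast, name), getattr(w_ref, name), rtol=1e-8, atol=1e-12
            )
        for sid in ("s1", "s2"):
            np.testing.assert_allclose(
                pb_fast[sid].rho1, pb_ref[sid].rho1, rtol=1e-8, atol=1e-14
            )
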