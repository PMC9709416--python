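"""Predictive-coding engine: forward phase, inference, local updates."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pcnet import core
from pcnet.errors import (ConfigurationError, DivergenceError, NumericError,
                          StructureError)
from pcnet.experiments import (gradset_rel_err, pc_equilibrium_gradients,
                               random_mlp_spec, run_energy_descent)
from pcnet.network import (LayerSpec, NetworkSpec, init_params, load_params,
                           save_params)


def identity_chain(n_layers, dim):
    spec = NetworkSpec(tuple(
        LayerSpec("affine", (dim,), (dim,), "identity")
        for _ in range(n_layers)))
    params = [{"W": np.eye(dim), "b": np.zeros(dim)} for _ in range(n_layers)]
    return spec, params


class TestForwardPass:
    def test_identity_chain_propagates_input(self):
        spec, params = identity_chain(3, 4)
        x = np.abs(np.random.default_rng(0).standard_normal((2, 4)))
        state = core.forward_pass(spec, params, x)
        for i in range(1, 4):
            np.testing.assert_allclose(state.vhat[i], x)

    def test_single_affine_relu(self):
        spec = NetworkSpec((LayerSpec("affine", (1,), (1,), "relu"),))
        params = [{"W": np.array([[2.0]]), "b": np.zeros(1)}]
        state = core.forward_pass(spec, params, np.array([[3.0]]))
        np.testing.assert_allclose(state.vhat[1], [[6.0]])

    def test_free_energy_zero_without_clamp(self, small_mlp, rng):
        spec, params = small_mlp
        state = core.forward_pass(spec, params, rng.standard_normal((4, 6)))
        assert core.free_energy(state) == 0.0

    def test_shape_mismatch_names_layer(self, small_mlp):
        spec, params = small_mlp
        with pytest.raises(StructureError, match="layer 0"):
            core.forward_pass(spec, params, np.zeros((2, 9)))

    def test_param_shape_mismatch_rejected(self, small_mlp):
        spec, params = small_mlp
        bad = [dict(p) for p in params]
        bad[1]["W"] = bad[1]["W"][:, :-1]
        with pytest.raises(StructureError, match="layer 1"):
            core.forward_pass(spec, bad, np.zeros((2, 6)))


class TestClampAndEnergy:
    def test_target_equal_to_prediction_gives_zero_error(self, small_mlp, rng):
        spec, params = small_mlp
        state = core.forward_pass(spec, params, rng.standard_normal((3, 6)))
        core.clamp_target(state, state.vhat[-1].copy(), "squared_error")
        np.testing.assert_allclose(state.e[-1], 0.0)
        assert core.free_energy(state) == 0.0

    def test_hand_evaluated_output_error(self):
        # f(x) = 2x, x = 1, y = 5  ->  e_1 = 2 - 5 = -3
        spec = NetworkSpec((LayerSpec("affine", (1,), (1,), "identity"),))
        params = [{"W": np.array([[2.0]]), "b": np.zeros(1)}]
        state = core.forward_pass(spec, params, np.array([[1.0]]))
        core.clamp_target(state, np.array([[5.0]]), "squared_error")
        np.testing.assert_allclose(state.e[1], [[-3.0]])

    def test_clamping_twice_is_idempotent(self, small_mlp, rng):
        spec, params = small_mlp
        y = rng.standard_normal((3, 3))
        state = core.forward_pass(spec, params, rng.standard_normal((3, 6)))
        core.clamp_target(state, y, "squared_error")
        e1, v1 = [np.copy(a) for a in state.e[1:]], [np.copy(a) for a in state.v]
        core.clamp_target(state, y, "squared_error")
        for a, b in zip(e1, state.e[1:]):
            np.testing.assert_array_equal(a, b)
        for a, b in zip(v1, state.v):
            np.testing.assert_array_equal(a, b)

    def test_hand_evaluated_free_energy(self, small_mlp):
        spec, params = small_mlp
        state = core.forward_pass(spec, params, np.zeros((1, 6)))
        # overwrite two error nodes by hand: e_1 = [1, 2, ...0], e_2 = [3, 0..]
        state.e[1][:] = 0.0
        state.e[1][0, :2] = [1.0, 2.0]
        state.e[2][:] = 0.0
        state.e[2][0, 0] = 3.0
        state.e[3][:] = 0.0
        assert core.free_energy(state) == pytest.approx(7.0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-10, 10), min_size=1, max_size=8), st.integers(1, 3))
    def test_free_energy_nonnegative_and_additive(self, errs, batch):
        """F >= 0 and F decomposes as the sum of per-layer contributions."""
        spec = NetworkSpec((
            LayerSpec("affine", (len(errs),), (len(errs),), "identity"),
            LayerSpec("affine", (len(errs),), (len(errs),), "identity"),
        ))
        params = [{"W": np.eye(len(errs)), "b": np.zeros(len(errs))}] * 2
        state = core.forward_pass(spec, params, np.zeros((batch, len(errs))))
        state.e[1][:] = np.array(errs)
        state.e[2][:] = 0.0
        f1 = core.free_energy(state)
        state.e[2][:] = np.array(errs)[::-1]
        f12 = core.free_energy(state)
        state.e[1][:] = 0.0
        f2 = core.free_energy(state)
        assert f1 >= 0 and f2 >= 0
        assert f12 == pytest.approx(f1 + f2, rel=1e-12, abs=1e-12)


class TestInference:
    def test_zero_errors_fixed_point(self, small_mlp, rng):
        spec, params = small_mlp
        state = core.forward_pass(spec, params, rng.standard_normal((2, 6)))
        core.clamp_target(state, state.vhat[-1].copy(), "squared_error")
        v_before = [np.copy(v) for v in state.v]
        core.inference_step(state, spec, params, eta_v=0.1)
        for a, b in zip(v_before, state.v):
            np.testing.assert_array_equal(a, b)
        grads = core.weight_gradient(state, spec, params)
        for g in grads.layers:
            for v in g.values():
                np.testing.assert_allclose(v, 0.0)

    def test_hand_computed_scalar_chain_step(self, scalar_chain):
        # w1=1.5, w2=0.8, x=2, y=1: vhat1=3, vhat2=2.4, e2=1.4;
        # dv1 = e1 - w2*e2 = -1.12; v1 <- 3 - 0.1*1.12 = 2.888; e1 = 0.112
        spec, params = scalar_chain
        state = core.forward_pass(spec, params, np.array([[2.0]]))
        core.clamp_target(state, np.array([[1.0]]), "squared_error")
        core.inference_step(state, spec, params, eta_v=0.1)
        assert state.v[1][0, 0] == pytest.approx(2.888)
        assert state.e[1][0, 0] == pytest.approx(0.112)
        assert state.e[2][0, 0] == pytest.approx(1.4)  # frozen predictions

    def test_equilibrium_errors_equal_bp_deltas(self, rng):
        """At the fixed-prediction equilibrium, e_i is the backprop delta."""
        from pcnet._layers import layer_vjp_input

        for _ in range(5):
            spec = random_mlp_spec(rng, max_units=10)
            params = init_params(spec, seed=int(rng.integers(2 ** 31)))
            x = rng.standard_normal((2,) + spec.in_shape)
            y = rng.standard_normal((2,) + spec.out_shape)
            state = core.forward_pass(spec, params, x)
            core.clamp_target(state, y, "squared_error")
            state, _ = core.run_inference(state, spec, params, eta_v=0.5,
                                          max_iters=2000, tol=1e-12)
            delta = state.e[-1]
            for i in range(state.n_layers - 1, 0, -1):
                delta = layer_vjp_input(spec.layers[i], params[i],
                                        state.caches[i + 1], delta)
                np.testing.assert_allclose(state.e[i], delta, rtol=1e-6,
                                           atol=1e-10)

    def test_trace_length_contract(self, small_mlp, rng):
        spec, params = small_mlp
        state = core.forward_pass(spec, params, rng.standard_normal((2, 6)))
        core.clamp_target(state, rng.standard_normal((2, 3)), "squared_error")
        _, trace = core.run_inference(state, spec, params, eta_v=0.05,
                                      max_iters=20, tol=0.0)
        assert trace.iterations == 20 and len(trace.energies) == 20
        assert not trace.converged

    def test_converged_target_stays_at_zero_energy(self, small_mlp, rng):
        spec, params = small_mlp
        state = core.forward_pass(spec, params, rng.standard_normal((2, 6)))
        core.clamp_target(state, state.vhat[-1].copy(), "squared_error")
        state, trace = core.run_inference(state, spec, params, eta_v=0.1,
                                          max_iters=20, tol=1e-12)
        assert trace.converged and trace.iterations == 1
        assert trace.energies[-1] == 0.0

    def test_energy_descent_with_reevaluated_predictions(self):
        res = run_energy_descent(n_instances=25, seed=3)
        assert res["fraction_monotone"] == 1.0

    def test_divergent_inference_raises(self, small_mlp, rng):
        spec, params = small_mlp
        state = core.forward_pass(spec, params, rng.standard_normal((2, 6)))
        core.clamp_target(state, 50.0 + rng.standard_normal((2, 3)),
                          "squared_error")
        with pytest.raises(DivergenceError, match="eta_v"):
            core.run_inference(state, spec, params, eta_v=40.0, max_iters=50,
                               explosion_factor=10.0)

    def test_nonfinite_nodes_raise_numeric_error(self, small_mlp, rng):
        spec, params = small_mlp
        state = core.forward_pass(spec, params, rng.standard_normal((2, 6)))
        core.clamp_target(state, rng.standard_normal((2, 3)), "squared_error")
        state.e[2][0, 0] = np.nan
        with pytest.raises(NumericError, match="layer"):
            core.inference_step(state, spec, params, eta_v=0.1)

    def test_invalid_eta_v_rejected(self, small_mlp, rng):
        spec, params = small_mlp
        state = core.forward_pass(spec, params, rng.standard_normal((1, 6)))
        with pytest.raises(ConfigurationError):
            core.inference_step(state, spec, params, eta_v=0.0)


class TestWeightGradient:
    def test_single_affine_matches_finite_differences(self, rng):
        spec = NetworkSpec((LayerSpec("affine", (4,), (3,), "identity"),))
        params = init_params(spec, seed=1)
        x = rng.standard_normal((5, 4))
        y = rng.standard_normal((5, 3))
        state = core.forward_pass(spec, params, x)
        core.clamp_target(state, y, "squared_error")
        grads = core.weight_gradient(state, spec, params)
        h = 1e-6
        for key in ("W", "b"):
            g = grads.layers[0][key]
            it = np.nditer(g, flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                for sgn, store in ((+1, "p"), (-1, "m")):
                    params[0][key][idx] += sgn * h
                    st_ = core.forward_pass(spec, params, x)
                    loss = 0.5 * float(((st_.vhat[1] - y) ** 2).sum()) / 5
                    params[0][key][idx] -= sgn * h
                    if store == "p":
                        lp = loss
                    else:
                        lm = loss
                fd = (lp - lm) / (2 * h)
                assert g[idx] == pytest.approx(-fd, rel=1e-5, abs=1e-8)

    def test_locality_ignores_other_layers_errors(self, small_mlp, rng):
        spec, params = small_mlp
        state = core.forward_pass(spec, params, rng.standard_normal((3, 6)))
        core.clamp_target(state, rng.standard_normal((3, 3)), "squared_error")
        state, _ = core.run_inference(state, spec, params, eta_v=0.2,
                                      max_iters=30)
        ref = core.weight_gradient(state, spec, params)
        for i in range(1, state.n_layers + 1):
            perturbed = core.forward_pass(spec, params, state.v[0])
            for j in range(1, state.n_layers + 1):
                perturbed.e[j] = state.e[j] + (0.0 if j == i else 7.7)
                perturbed.v[j] = state.v[j]
            got = core.weight_gradient(perturbed, spec, params)
            np.testing.assert_allclose(got.layers[i - 1]["W"],
                                       ref.layers[i - 1]["W"], rtol=1e-12)

    def test_deep_network_matches_bp_including_conv(self, rng):
        """Conv block + classifier: PC equilibrium update == -BP gradient."""
        spec = NetworkSpec((
            LayerSpec("conv_block", (1, 6, 6), (3, 3, 3), "relu",
                      has_batchnorm=True),
            LayerSpec("affine", (3, 3, 3), (4,), "identity"),
        ))
        params = init_params(spec, seed=2)
        x = rng.standard_normal((3, 1, 6, 6))
        y = rng.integers(0, 4, size=3)
        pc_grads, trace = pc_equilibrium_gradients(spec, params, x, y,
                                                   "cross_entropy")
        bp = core.bp_gradient(spec, params, x, y, "cross_entropy")
        assert gradset_rel_err(pc_grads, bp) < 1e-6


class TestApplyUpdate:
    def test_zero_gradient_and_zero_rate_leave_params(self, small_mlp):
        spec, params = small_mlp
        zeros = core.GradientSet([{k: np.zeros_like(v) for k, v in p.items()}
                                  for p in params])
        for eta in (0.5, 0.0):
            new = core.apply_update(params, zeros, eta)
            for a, b in zip(params, new):
                np.testing.assert_array_equal(a["W"], b["W"])

    def test_scalar_arithmetic(self):
        params = [{"W": np.array([[1.0]]), "b": np.zeros(1)}]
        grads = core.GradientSet([{"W": np.array([[0.5]]),
                                   "b": np.zeros(1)}])
        new = core.apply_update(params, grads, 0.1)
        assert new[0]["W"][0, 0] == pytest.approx(1.05)

    def test_gradient_shape_mismatch_rejected(self, small_mlp):
        spec, params = small_mlp
        bad = core.GradientSet([{"W": np.zeros((2, 2)), "b": np.zeros(2)}
                                for _ in params])
        with pytest.raises(StructureError):
            core.apply_update(params, bad, 0.1)


class TestObjectiveCoupling:
    def test_squared_error_reproduces_clamp(self, rng):
        z = rng.standard_normal((4, 3))
        y = rng.standard_normal((4, 3))
        np.testing.assert_allclose(
            core.output_error_from_objective(z, y, "squared_error"), z - y)

    def test_cross_entropy_error_is_softmax_minus_onehot(self, rng):
        from scipy.special import softmax

        z = rng.standard_normal((4, 5))
        y = rng.integers(0, 5, size=4)
        e = core.output_error_from_objective(z, y, "cross_entropy")
        onehot = np.eye(5)[y]
        np.testing.assert_allclose(e, softmax(z, axis=1) - onehot)

    def test_unknown_objective_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            core.output_error_from_objective(rng.standard_normal((2, 2)),
                                             np.array([0, 1]), "nonsense")


class TestCheckpoint:
    def test_roundtrip_is_bit_exact(self, small_mlp, tmp_path):
        spec, params = small_mlp
        path = tmp_path / "ckpt.npz"
        save_params(params, path)
        loaded = load_params(path)
        assert len(loaded) == len(params)
        for a, b in zip(params, loaded):
            for k in a:
                np.testing.assert_array_equal(a[k], b[k])
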