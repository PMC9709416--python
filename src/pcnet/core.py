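"""Predictive-coding engine.

A predictive-coding network maintains, for every layer ``i = 1..L``, an
activation node ``v_i``, a top-down prediction ``v_hat_i = f_i(v_{i-1})`` and
an error node ``e_i = v_hat_i - v_i``.  Learning minimizes the variational
free energy

    F = 1/2 sum_i ||e_i||^2        (batch mean)

in two phases.  The *inference* (backward) phase relaxes the activation
nodes by gradient descent on F,

    dv_i = -dF/dv_i = e_i - J_{i+1}^T e_{i+1},

with the input clamped to the stimulus and the output clamped to the target
(or its error node clamped to an objective gradient).  The *learning* phase
then applies the purely local weight update

    dtheta_i = -dF/dtheta_i = -e_i . df_i(v_{i-1}) / dtheta_i.

Under the fixed-prediction assumption (predictions and Jacobians frozen at
their feedforward values) the equilibrium of the inference phase makes
``e_i`` equal to the backpropagation delta of layer ``i``, so the local
update equals the backpropagation gradient; :func:`bp_gradient` implements
that chain rule directly and serves as the independent oracle.

The 1/2 energy convention makes the equivalence exact for the standard
mean-squared-error and cross-entropy losses without a factor-of-two
mismatch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._layers import layer_forward, layer_vjp_input, layer_vjp_params
from .errors import (ConfigurationError, DivergenceError, NumericError,
                     StructureError)
from .network import BUFFER_KEYS, NetworkSpec, check_params, copy_params
from .objectives import ObjectiveConfig, objective_value_and_grad, resolve_objective


@dataclass
class NodeState:
    """Per-minibatch node values; index 0 is the clamped input.

    ``v``, ``vhat``, ``e`` and ``caches`` are lists of length ``L + 1``;
    position 0 holds the input (``vhat[0]``, ``e[0]``, ``caches[0]`` are
    ``None``).  ``target`` is set by :func:`clamp_target`; ``error_clamped``
    marks an output error node pinned to an objective gradient instead of a
    value clamp.
    """

    v: list
    vhat: list
    e: list
    caches: list
    target: np.ndarray | None = None
    target_clamped: bool = False
    error_clamped: bool = False
    objective: ObjectiveConfig | None = None
    last_dv_max: float = np.inf

    @property
    def n_layers(self):
        return len(self.v) - 1

    @property
    def batch_size(self):
        return self.v[0].shape[0]

    @property
    def output(self):
        return self.vhat[-1]


@dataclass
class EnergyTrace:
    """Free energy recorded after each inference iteration."""

    energies: list = field(default_factory=list)
    iterations: int = 0
    converged: bool = False


@dataclass
class GradientSet:
    """Per-layer parameter increments, shaped exactly like the parameters."""

    layers: list

    def __getitem__(self, i):
        return self.layers[i]

    def __len__(self):
        return len(self.layers)


# ---------------------------------------------------------------------------
# forward phase

def forward_pass(spec: NetworkSpec, params, x, *, train=False, rng=None) -> NodeState:
    """Feedforward sweep; activations are initialized at the predictions.

    ``train=True`` draws dropout masks and uses batch statistics for batch
    norm (one draw per minibatch, frozen thereafter).
    """
    check_params(spec, params)
    x = np.asarray(x, dtype=float)
    first = spec.layers[0]
    expected = int(np.prod(first.in_shape))
    if first.transform_kind == "affine":
        if int(np.prod(x.shape[1:])) != expected:
            raise StructureError(
                f"layer 0: input has {int(np.prod(x.shape[1:]))} features, "
                f"expected {expected}")
    elif x.shape[1:] != first.in_shape:
        raise StructureError(
            f"layer 0: input shape {x.shape[1:]} does not match {first.in_shape}")
    if train and rng is None:
        rng = np.random.default_rng(0)
    v = [x]
    vhat: list = [None]
    e: list = [None]
    caches: list = [None]
    h = x
    for i, layer in enumerate(spec.layers):
        h, cache = layer_forward(layer, params[i], h, train=train, rng=rng)
        if not np.all(np.isfinite(h)):
            raise NumericError(f"non-finite prediction at layer {i + 1}")
        vhat.append(h)
        v.append(h.copy())
        e.append(np.zeros_like(h))
        caches.append(cache)
    return NodeState(v=v, vhat=vhat, e=e, caches=caches)


def clamp_target(state: NodeState, y, objective="squared_error") -> NodeState:
    """Couple a target into the output layer.

    For ``squared_error`` the output activation is clamped to ``y`` (one-hot
    for classification) and ``e_L = v_hat_L - y``.  For any other objective
    the output *error node* is set to the objective's logit gradient and the
    output activation stays free (it is simply never updated).
    """
    cfg = resolve_objective(objective)
    L = state.n_layers
    y = np.asarray(y)
    if cfg.name == "squared_error":
        t = y.astype(float)
        if t.shape != state.vhat[L].shape:
            raise StructureError(
                f"target shape {t.shape} does not match output {state.vhat[L].shape}")
        state.target = t
        state.target_clamped = True
        state.v[L] = t.copy()
        state.e[L] = state.vhat[L] - t
    else:
        if y.ndim >= 1 and y.shape[0] != state.batch_size:
            raise StructureError(
                f"target batch {y.shape[0]} does not match input batch "
                f"{state.batch_size}")
        state.target = y
        state.error_clamped = True
        state.e[L] = output_error_from_objective(state.vhat[L], y, cfg)
    state.objective = cfg
    return state


def clamp_output_error(state: NodeState, e_out) -> NodeState:
    """Pin the output error node to an externally computed cotangent.

    Used where the loss is not a per-logit objective (e.g. the episodic
    prototype loss, whose gradient couples support and query embeddings).
    ``e_out`` must be on the per-sample scale of an error node, i.e. the
    gradient of the *summed* loss.
    """
    L = state.n_layers
    e_out = np.asarray(e_out, dtype=float)
    if e_out.shape != state.vhat[L].shape:
        raise StructureError(
            f"error shape {e_out.shape} does not match output {state.vhat[L].shape}")
    state.error_clamped = True
    state.e[L] = e_out
    return state


def output_error_from_objective(vhat_L, y, objective) -> np.ndarray:
    """Gradient of the objective wrt the output prediction, per sample.

    Sign-aligned with ``e = prediction - target``: for squared error this is
    exactly ``vhat_L - y``; for cross-entropy, ``softmax(vhat_L) - onehot(y)``.
    """
    cfg = resolve_objective(objective)
    z = np.asarray(vhat_L, dtype=float)
    if z.ndim > 2:
        _, grad = objective_value_and_grad(z.reshape(z.shape[0], -1), y, cfg)
        return grad.reshape(z.shape)
    return objective_value_and_grad(z, y, cfg)[1]


# ---------------------------------------------------------------------------
# free energy and inference

def free_energy(state: NodeState) -> float:
    """F = 1/2 sum_i ||e_i||^2, averaged over the minibatch dimension."""
    B = state.batch_size
    return 0.5 * sum(float((ei ** 2).sum()) for ei in state.e[1:]) / B


def inference_step(state: NodeState, spec: NetworkSpec, params, eta_v,
                   fixed_predictions=True, _iteration=None) -> NodeState:
    """One gradient step of all unclamped activation nodes on F.

    All nodes are updated simultaneously from the current errors; errors are
    then refreshed.  With ``fixed_predictions`` the predictions, caches and
    Jacobians stay at their feedforward values and only the
    ``e_i = v_hat_i - v_i`` identity is re-evaluated; otherwise predictions
    are recomputed at the current activations (dropout masks and batch
    statistics stay frozen at their forward-phase draws).
    """
    if eta_v <= 0:
        raise ConfigurationError("eta_v must be positive")
    L = state.n_layers
    dv_max = 0.0
    dv: list = [None] * (L + 1)
    for i in range(1, L + 1):
        if i == L and (state.target_clamped or state.error_clamped):
            continue
        d = state.e[i].copy()
        if i < L:
            d -= layer_vjp_input(spec.layers[i], params[i],
                                 state.caches[i + 1], state.e[i + 1])
        dv[i] = d
        m = float(np.max(np.abs(d))) if d.size else 0.0
        dv_max = max(dv_max, m)
    for i in range(1, L + 1):
        if dv[i] is not None:
            state.v[i] = state.v[i] + eta_v * dv[i]
    if not fixed_predictions:
        for i in range(1, L + 1):
            h_out, cache = layer_forward(
                spec.layers[i - 1], params[i - 1], state.v[i - 1],
                train=False, rng=None, reuse=state.caches[i])
            state.vhat[i] = h_out
            state.caches[i] = cache
    for i in range(1, L + 1):
        if i == L and state.error_clamped:
            if not fixed_predictions and state.objective is not None:
                state.e[L] = output_error_from_objective(
                    state.vhat[L], state.target, state.objective)
            continue
        state.e[i] = state.vhat[i] - state.v[i]
    for i in range(1, L + 1):
        if not np.all(np.isfinite(state.v[i])) or not np.all(np.isfinite(state.e[i])):
            where = f" at iteration {_iteration}" if _iteration is not None else ""
            raise NumericError(f"non-finite node values in layer {i}{where}")
    state.last_dv_max = dv_max
    return state


def run_inference(state: NodeState, spec: NetworkSpec, params, eta_v=0.1,
                  max_iters=20, tol=0.0, fixed_predictions=True,
                  explosion_factor=1e3):
    """Iterate :func:`inference_step`; returns ``(state, EnergyTrace)``.

    Stops after ``max_iters`` iterations (default 20) or as soon as the
    max-norm of the node updates falls below ``tol``.  Raises
    :class:`DivergenceError` if F exceeds ``explosion_factor * (F0 + 1)``.
    """
    if max_iters < 1:
        raise ConfigurationError("max_iters must be >= 1")
    trace = EnergyTrace()
    f0 = free_energy(state)
    limit = explosion_factor * (f0 + 1.0)
    for t in range(max_iters):
        state = inference_step(state, spec, params, eta_v,
                               fixed_predictions=fixed_predictions,
                               _iteration=t)
        f = free_energy(state)
        trace.energies.append(f)
        trace.iterations = t + 1
        if not np.isfinite(f) or f > limit:
            raise DivergenceError(
                f"free energy {f:.3g} exceeded threshold {limit:.3g} at "
                f"iteration {t} (eta_v={eta_v})")
        if state.last_dv_max < tol:
            trace.converged = True
            break
    return state, trace


# ---------------------------------------------------------------------------
# learning phase

def weight_gradient(state: NodeState, spec: NetworkSpec, params) -> GradientSet:
    """Local weight increments dtheta_i = -e_i . df_i(v_{i-1})/dtheta_i.

    Each layer's increment depends only on its own error node and cached
    input (locality); increments are averaged over the batch, so at the
    fixed-prediction equilibrium ``dtheta`` equals minus the gradient of the
    batch-mean loss (see :func:`bp_gradient`).
    """
    B = state.batch_size
    layers = []
    for i, layer in enumerate(spec.layers):
        g = layer_vjp_params(layer, params[i], state.caches[i + 1],
                             state.e[i + 1])
        layers.append({k: -v / B for k, v in g.items()})
    return GradientSet(layers)


def apply_update(params, grads: GradientSet, eta_theta, weight_decay=0.0) -> list:
    """theta_i <- theta_i + eta_theta * dtheta_i  (optionally decayed).

    ``weight_decay`` subtracts ``weight_decay * W`` from weight matrices
    (biases and batch-norm parameters are not decayed).
    """
    new = copy_params(params)
    for i, g in enumerate(grads.layers):
        for k, dv in g.items():
            if k in BUFFER_KEYS:
                continue
            if new[i][k].shape != dv.shape:
                raise StructureError(
                    f"layer {i}: gradient {k!r} shape {dv.shape} does not "
                    f"match parameter {new[i][k].shape}")
            new[i][k] = new[i][k] + eta_theta * dv
        if weight_decay:
            new[i]["W"] = new[i]["W"] - weight_decay * new[i]["W"]
    return new


# ---------------------------------------------------------------------------
# backpropagation oracle / baseline

def bp_gradient(spec: NetworkSpec, params, x, y, objective="cross_entropy",
                *, train=False, rng=None, state: NodeState | None = None,
                output_grad=None) -> GradientSet:
    """Exact chain-rule gradients of the batch-mean objective.

    Returns ascent gradients (``+dL/dtheta``); the predictive-coding
    :func:`weight_gradient` returns the *negative* of this at equilibrium.
    A precomputed forward ``state`` (e.g. to share dropout masks with a PC
    step) or a direct ``output_grad`` cotangent may be supplied.
    """
    if state is None:
        state = forward_pass(spec, params, x, train=train, rng=rng)
    L = state.n_layers
    B = state.batch_size
    if output_grad is None:
        cfg = resolve_objective(objective)
        output_grad = output_error_from_objective(state.vhat[L], y, cfg)
    g = np.asarray(output_grad, dtype=float) / B
    layers: list = [None] * L
    for i in range(L, 0, -1):
        layer = spec.layers[i - 1]
        layers[i - 1] = layer_vjp_params(layer, params[i - 1],
                                         state.caches[i], g)
        if i > 1:
            g = layer_vjp_input(layer, params[i - 1], state.caches[i], g)
    return GradientSet(layers)
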