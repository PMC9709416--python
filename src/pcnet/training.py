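"""Shared minibatch training steps for the two learning algorithms.

``pc`` steps run the full predictive-coding cycle: feedforward phase,
output coupling, 20 fixed-prediction inference iterations (default), then
the local weight update.  ``bp`` steps are plain stochastic gradient
descent on the same objective via the chain-rule backward pass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import core
from .errors import ConfigurationError
from .network import NetworkSpec
from .objectives import (ObjectiveConfig, objective_value, one_hot,
                         resolve_objective)


@dataclass
class TrainConfig:
    """Hyperparameters for one training run.

    ``eta_theta`` is the weight learning rate (eta in the weight update);
    ``eta_v`` the inference (node) learning rate; ``n_iters`` the number of
    backward-phase iterations.  ``weight_decay`` is applied per update as a
    multiplicative shrink of the weight matrices.
    """

    algorithm: str = "pc"           # 'pc' | 'bp'
    objective: object = "cross_entropy"
    eta_theta: float = 0.1
    eta_v: float = 0.1
    n_iters: int = 20
    fixed_predictions: bool = True
    weight_decay: float = 0.0
    batch_size: int = 64
    epochs: int = 20

    def __post_init__(self):
        if self.algorithm not in ("pc", "bp"):
            raise ConfigurationError(f"unknown algorithm {self.algorithm!r}")


def _pc_target(y, cfg: ObjectiveConfig, n_classes):
    if cfg.name == "squared_error" and np.asarray(y).ndim == 1:
        return one_hot(y, n_classes)
    return y


def train_step(spec: NetworkSpec, params, xb, yb, cfg: TrainConfig, rng,
               lr=None, grad_hook=None):
    """One minibatch update; returns ``(params, batch loss)``.

    ``lr`` overrides ``cfg.eta_theta`` (used by schedules).  ``grad_hook``
    may modify the gradient set in place (consolidation penalties).
    """
    obj = resolve_objective(cfg.objective)
    eta = cfg.eta_theta if lr is None else lr
    n_classes = int(np.prod(spec.out_shape))
    state = core.forward_pass(spec, params, xb, train=True, rng=rng)
    if cfg.algorithm == "pc":
        core.clamp_target(state, _pc_target(yb, obj, n_classes), obj)
        loss = objective_value(state.output.reshape(len(xb), -1),
                               _pc_target(yb, obj, n_classes), obj)
        state, _ = core.run_inference(
            state, spec, params, eta_v=cfg.eta_v, max_iters=cfg.n_iters,
            fixed_predictions=cfg.fixed_predictions)
        grads = core.weight_gradient(state, spec, params)
    else:
        yd = _pc_target(yb, obj, n_classes)
        loss = objective_value(state.output.reshape(len(xb), -1), yd, obj)
        grads = core.bp_gradient(spec, params, xb, yd, obj, state=state)
        grads = core.GradientSet([{k: -v for k, v in g.items()}
                                  for g in grads.layers])
    if grad_hook is not None:
        grad_hook(params, grads)
    return core.apply_update(params, grads, eta,
                             weight_decay=eta * cfg.weight_decay), loss


def train_epoch(spec, params, X, y, cfg: TrainConfig, rng, lr=None,
                grad_hook=None, on_batch=None):
    """One pass over ``(X, y)`` in shuffled minibatches; returns mean loss."""
    n = len(X)
    order = rng.permutation(n)
    losses = []
    for start in range(0, n, cfg.batch_size):
        idx = order[start:start + cfg.batch_size]
        if on_batch is not None:
            on_batch(idx)
        params, loss = train_step(spec, params, X[idx], y[idx], cfg, rng,
                                  lr=lr, grad_hook=grad_hook)
        losses.append(loss)
    return params, float(np.mean(losses))


def predict_logits(spec, params, X, batch_size=512):
    outs = []
    for start in range(0, len(X), batch_size):
        state = core.forward_pass(spec, params, X[start:start + batch_size])
        outs.append(state.output.reshape(state.batch_size, -1))
    return np.concatenate(outs, axis=0)


def accuracy(spec, params, X, y) -> float:
    """Top-1 accuracy in percent."""
    logits = predict_logits(spec, params, X)
    return 100.0 * float((logits.argmax(axis=1) == np.asarray(y)).mean())


def mean_loss(spec, params, X, y, objective) -> float:
    obj = resolve_objective(objective)
    n_classes = int(np.prod(spec.out_shape))
    logits = predict_logits(spec, params, X)
    return objective_value(logits, _pc_target(y, obj, n_classes), obj)
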