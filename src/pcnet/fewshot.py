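"""Episodic few-shot recognition with prototypical networks.

An N-way k-shot episode draws N classes, k support and q query items per
class.  Queries are classified by a softmax over negative squared Euclidean
distances to the class prototypes (support-mean embeddings).  The encoder
is trained episodically by the query cross-entropy, either with
backpropagation or with predictive coding (the episode-loss gradient with
respect to every embedding enters the output error node; all other layers
learn locally).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import softmax

from . import core
from .errors import ConfigurationError
from .network import NetworkSpec, init_params
from .training import TrainConfig

DEFAULT_QUERIES = 15  # queries per class, following the episodic protocol


@dataclass
class Episode:
    """Support/query split of one episode; labels are 0..N-1."""

    support_x: np.ndarray
    support_y: np.ndarray
    query_x: np.ndarray
    query_y: np.ndarray
    classes: np.ndarray

    @property
    def n_way(self):
        return len(self.classes)


@dataclass
class PrototypeSet:
    prototypes: np.ndarray  # (N, D)


def sample_episode(bank, N, k, q=DEFAULT_QUERIES, seed=0, rng=None) -> Episode:
    """Seeded episode from a class bank shaped ``(C, V, ...)``.

    Sampling is without replacement: support and query items are disjoint
    and each class contributes exactly k + q items.
    """
    bank = np.asarray(bank)
    C, V = bank.shape[0], bank.shape[1]
    if N > C:
        raise ConfigurationError(f"requested {N} ways but bank has {C} classes")
    if k + q > V:
        raise ConfigurationError(
            f"requested {k}+{q} items but classes have only {V}")
    if rng is None:
        rng = np.random.default_rng(seed)
    classes = rng.choice(C, size=N, replace=False)
    sup, qry = [], []
    for c in classes:
        items = rng.choice(V, size=k + q, replace=False)
        sup.append(bank[c, items[:k]])
        qry.append(bank[c, items[k:]])
    item_shape = bank.shape[2:]
    return Episode(
        support_x=np.concatenate(sup).reshape((N * k,) + item_shape),
        support_y=np.repeat(np.arange(N), k),
        query_x=np.concatenate(qry).reshape((N * q,) + item_shape),
        query_y=np.repeat(np.arange(N), q),
        classes=classes)


def compute_prototypes(support_embeddings, labels) -> PrototypeSet:
    """Class-mean prototypes (permutation invariant in the support set)."""
    emb = np.asarray(support_embeddings)
    emb = emb.reshape(emb.shape[0], -1)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    protos = np.stack([emb[labels == c].mean(axis=0) for c in classes])
    return PrototypeSet(prototypes=protos)


def episode_logits(query_embeddings, protoset: PrototypeSet) -> np.ndarray:
    """Negative squared Euclidean distances, one row per query."""
    q = np.asarray(query_embeddings)
    q = q.reshape(q.shape[0], -1)
    p = protoset.prototypes
    d2 = ((q[:, None, :] - p[None, :, :]) ** 2).sum(axis=2)
    return -d2


def episode_probabilities(query_embeddings, protoset) -> np.ndarray:
    return softmax(episode_logits(query_embeddings, protoset), axis=1)


def episode_loss_and_grads(support_emb, support_y, query_emb, query_y):
    """Mean query cross-entropy and its gradients wrt every embedding.

    The prototype of class c is the support mean, so the loss gradient
    reaches support embeddings through the prototypes (divided by k).
    Returns ``(loss, d/d support_emb, d/d query_emb)`` with gradients of
    the *mean-over-queries* loss.
    """
    s = np.asarray(support_emb, dtype=float).reshape(len(support_emb), -1)
    qe = np.asarray(query_emb, dtype=float).reshape(len(query_emb), -1)
    protoset = compute_prototypes(s, support_y)
    p_mat = protoset.prototypes
    logits = episode_logits(qe, protoset)
    nq = len(qe)
    probs = softmax(logits, axis=1)
    onehot = np.zeros_like(probs)
    onehot[np.arange(nq), np.asarray(query_y)] = 1.0
    lse = np.log(np.exp(logits - logits.max(axis=1, keepdims=True)).sum(axis=1)) \
        + logits.max(axis=1)
    loss = float((lse - logits[np.arange(nq), np.asarray(query_y)]).mean())
    g_logit = (probs - onehot) / nq  # grad of mean loss wrt logits
    # logits_mc = -||q_m - p_c||^2
    diff = qe[:, None, :] - p_mat[None, :, :]          # (nq, N, D)
    g_query = (-2.0 * g_logit[:, :, None] * diff).sum(axis=1)
    g_proto = (2.0 * g_logit[:, :, None] * diff).sum(axis=0)
    support_y = np.asarray(support_y)
    g_support = np.zeros_like(s)
    for ci, c in enumerate(np.unique(support_y)):
        members = np.flatnonzero(support_y == c)
        g_support[members] = g_proto[ci] / len(members)
    return loss, g_support, g_query


@dataclass
class FewshotTrainConfig:
    """Episodic training protocol: lr 1e-3 stepped x0.1 every 20 epochs,
    weight decay 2e-4; PC adds inference rate 0.1 and 20 fixed-prediction
    iterations."""

    n_way: int = 5
    k_shot: int = 1
    q_queries: int = 5
    episodes_per_epoch: int = 50
    epochs: int = 3
    lr: float = 1e-3
    lr_step_epochs: int = 20
    lr_step_factor: float = 0.1
    weight_decay: float = 2e-4
    eta_v: float = 0.1
    n_iters: int = 20


def _embed(spec, params, X, batch_size=512):
    outs = []
    for start in range(0, len(X), batch_size):
        state = core.forward_pass(spec, params, X[start:start + batch_size])
        outs.append(state.output.reshape(state.batch_size, -1))
    return np.concatenate(outs, axis=0)


def train_fewshot(spec: NetworkSpec, bank, algorithm="pc",
                  config: FewshotTrainConfig | None = None, seed=0):
    """Train the encoder episodically; returns the trained parameters."""
    cfg = config if config is not None else FewshotTrainConfig()
    rng = np.random.default_rng(seed)
    params = init_params(spec, seed=seed)
    losses = []
    for epoch in range(cfg.epochs):
        lr = cfg.lr * cfg.lr_step_factor ** (epoch // cfg.lr_step_epochs)
        for _ in range(cfg.episodes_per_epoch):
            ep = sample_episode(bank, cfg.n_way, cfg.k_shot, cfg.q_queries,
                                rng=rng)
            X = np.concatenate([ep.support_x, ep.query_x])
            n_sup = len(ep.support_x)
            state = core.forward_pass(spec, params, X, train=True, rng=rng)
            emb = state.output.reshape(len(X), -1)
            loss, g_sup, g_qry = episode_loss_and_grads(
                emb[:n_sup], ep.support_y, emb[n_sup:], ep.query_y)
            losses.append(loss)
            g_emb = np.concatenate([g_sup, g_qry])
            if algorithm == "pc":
                # error nodes are per-sample: scale the mean-loss gradient
                e_out = (g_emb * len(X)).reshape(state.output.shape)
                core.clamp_output_error(state, e_out)
                state, _ = core.run_inference(
                    state, spec, params, eta_v=cfg.eta_v,
                    max_iters=cfg.n_iters, fixed_predictions=True)
                grads = core.weight_gradient(state, spec, params)
            else:
                grads = core.bp_gradient(
                    spec, params, X, None, state=state,
                    output_grad=(g_emb * len(X)).reshape(state.output.shape))
                grads = core.GradientSet([{k: -v for k, v in g.items()}
                                          for g in grads.layers])
            params = core.apply_update(params, grads, lr,
                                       weight_decay=lr * cfg.weight_decay)
    return params, losses


def evaluate_episode_bank(embedded_bank, N, k, q=DEFAULT_QUERIES,
                          episodes=1000, seed=0):
    """Episode accuracy over a bank already in embedding space (C, V, D)."""
    rng = np.random.default_rng(seed)
    accs = np.empty(episodes)
    for i in range(episodes):
        ep = sample_episode(embedded_bank, N, k, q, rng=rng)
        protos = compute_prototypes(ep.support_x, ep.support_y)
        pred = episode_logits(ep.query_x, protos).argmax(axis=1)
        accs[i] = 100.0 * float((pred == ep.query_y).mean())
    mean = float(accs.mean())
    se = float(accs.std(ddof=1) / np.sqrt(episodes))
    return {"mean": mean, "ci95": 1.96 * se, "se": se, "episodes": episodes}


def chance_calibration(N, k, q=DEFAULT_QUERIES, episodes=1000, seed=0,
                       dim=16):
    """Episode accuracy with input-independent embeddings.

    Support and query embeddings are drawn fresh per episode, so the
    expected accuracy is exactly 100/N %; this is the unbiased-machinery
    control for the episodic evaluator.
    """
    rng = np.random.default_rng(seed)
    accs = np.empty(episodes)
    qy = np.repeat(np.arange(N), q)
    sy = np.repeat(np.arange(N), k)
    for i in range(episodes):
        s = rng.standard_normal((N * k, dim))
        qe = rng.standard_normal((N * q, dim))
        protos = compute_prototypes(s, sy)
        pred = episode_logits(qe, protos).argmax(axis=1)
        accs[i] = 100.0 * float((pred == qy).mean())
    mean = float(accs.mean())
    se = float(accs.std(ddof=1) / np.sqrt(episodes))
    return {"mean": mean, "ci95": 1.96 * se, "se": se, "episodes": episodes}


def evaluate_fewshot(spec, params, bank, N, k, q=DEFAULT_QUERIES,
                     episodes=1000, seed=0):
    """Mean query accuracy (%) with a 95% interval over seeded episodes.

    The deterministic (evaluation-mode) encoder embeds the whole bank once;
    episodes are then sampled in embedding space.
    """
    bank = np.asarray(bank)
    C, V = bank.shape[0], bank.shape[1]
    flat = bank.reshape((C * V,) + bank.shape[2:])
    emb = _embed(spec, params, flat).reshape(C, V, -1)
    return evaluate_episode_bank(emb, N, k, q=q, episodes=episodes, seed=seed)
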