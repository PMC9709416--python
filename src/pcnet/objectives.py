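"""Classification objectives and their logit gradients.

Every objective provides a batch-mean value and a *per-sample* gradient with
respect to the network's output (the logits).  The gradient is sign-aligned
with the predictive-coding error convention ``e = prediction - target``, so
``squared_error`` reproduces output clamping and the gradient of mean
cross-entropy is the per-sample ``softmax(z) - onehot(y)`` divided by the
batch size.

Targets may be integer class labels of shape ``(B,)`` or dense (one-hot or
soft, e.g. mixup) arrays of shape ``(B, C)``.  The count-aware objectives
(class-balanced focal, LDAM, balanced softmax) additionally need per-class
training counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp, softmax

from .errors import ConfigurationError

OBJECTIVES = ("squared_error", "cross_entropy", "focal", "cb_focal",
              "ldam", "balanced_softmax")

_EPS = 1e-12


@dataclass
class ObjectiveConfig:
    """Objective name plus the hyperparameters the name needs.

    gamma_f : focusing exponent of the focal loss (>= 0).
    beta    : class-balancing factor in [0, 1); effective number of samples
              per class is (1 - beta**n) / (1 - beta).
    C       : LDAM margin scale; the margin of class j is C / n_j**0.25.
    alpha   : mixup Beta(alpha, alpha) concentration.
    counts  : per-class training counts for the count-aware objectives.
    """

    name: str = "cross_entropy"
    gamma_f: float = 0.0
    beta: float = 0.0
    C: float = 0.0
    alpha: float = 1.0
    counts: np.ndarray | None = None

    def __post_init__(self):
        if self.name not in OBJECTIVES:
            raise ConfigurationError(f"unknown objective {self.name!r}")
        if self.gamma_f < 0:
            raise ConfigurationError("gamma_f must be >= 0")
        if not 0.0 <= self.beta < 1.0:
            raise ConfigurationError("beta must be in [0, 1)")
        if self.C < 0:
            raise ConfigurationError("C must be >= 0")
        if self.alpha <= 0:
            raise ConfigurationError("alpha must be > 0")
        if self.counts is not None:
            self.counts = np.asarray(self.counts, dtype=float)


def _as_labels(y, n_classes):
    y = np.asarray(y)
    if y.ndim == 1:
        return y.astype(int)
    return y.argmax(axis=1)


def _as_dense(y, n_classes):
    y = np.asarray(y)
    if y.ndim == 2:
        return y.astype(float)
    out = np.zeros((y.shape[0], n_classes))
    out[np.arange(y.shape[0]), y.astype(int)] = 1.0
    return out


def one_hot(labels, n_classes):
    return _as_dense(np.asarray(labels), n_classes)


def _require_counts(cfg, n_classes):
    if cfg.counts is None:
        raise ConfigurationError(
            f"objective {cfg.name!r} needs per-class counts")
    counts = np.asarray(cfg.counts, dtype=float)
    if counts.shape != (n_classes,):
        raise ConfigurationError(
            f"counts must have length {n_classes}, got {counts.shape}")
    return counts


# ---------------------------------------------------------------------------
# individual objectives: each returns (mean value, per-sample gradient)

def squared_error(z, y):
    t = _as_dense(y, z.shape[1])
    e = z - t
    return 0.5 * float((e ** 2).sum()) / z.shape[0], e


def cross_entropy(z, y):
    t = _as_dense(y, z.shape[1])
    lse = logsumexp(z, axis=1, keepdims=True)
    value = float((t * (lse - z)).sum()) / z.shape[0]
    return value, softmax(z, axis=1) - t


def focal_loss(z, y, gamma_f):
    """-(1 - p_t)^gamma_f * log(p_t) with p = softmax(z)."""
    labels = _as_labels(y, z.shape[1])
    B = z.shape[0]
    p = softmax(z, axis=1)
    pt = np.clip(p[np.arange(B), labels], _EPS, 1.0)
    logpt = np.log(pt)
    value = float((-(1 - pt) ** gamma_f * logpt).sum()) / B
    # d loss / d p_t, then chain through softmax: dp_t/dz_j = p_t (1{j=y} - p_j)
    dl_dpt = gamma_f * (1 - pt) ** np.maximum(gamma_f - 1, 0) * logpt \
        - (1 - pt) ** gamma_f / pt
    if gamma_f == 0:
        dl_dpt = -1.0 / pt
    onehot = _as_dense(labels, z.shape[1])
    grad = (dl_dpt * pt)[:, None] * (onehot - p)
    return value, grad


def cb_focal_loss(z, y, beta, gamma_f, counts):
    """Focal loss weighted per class by (1 - beta) / (1 - beta**n_y)."""
    labels = _as_labels(y, z.shape[1])
    counts = np.asarray(counts, dtype=float)
    if beta == 0.0:
        w = np.ones_like(counts)
    else:
        w = (1.0 - beta) / (1.0 - beta ** counts)
    _, grad = focal_loss(z, y, gamma_f)
    B = z.shape[0]
    p = softmax(z, axis=1)
    pt = np.clip(p[np.arange(B), labels], _EPS, 1.0)
    per = -(1 - pt) ** gamma_f * np.log(pt)
    wy = w[labels]
    return float((wy * per).sum()) / B, wy[:, None] * grad


def ldam_loss(z, y, C, counts):
    """Cross-entropy with the target logit reduced by C / n_y**(1/4)."""
    labels = _as_labels(y, z.shape[1])
    counts = np.asarray(counts, dtype=float)
    margins = C / counts ** 0.25
    zm = z.copy()
    zm[np.arange(z.shape[0]), labels] -= margins[labels]
    return cross_entropy(zm, labels)


def balanced_softmax_loss(z, y, counts):
    """-log( n_y e^{z_y} / sum_j n_j e^{z_j} ): softmax over count-shifted logits."""
    counts = np.asarray(counts, dtype=float)
    return cross_entropy(z + np.log(counts)[None, :], y)


def mixup_batch(x1, y1, x2, y2, alpha, rng, n_classes=None):
    """Convex combination of two batches with lambda ~ Beta(alpha, alpha).

    Labels are returned dense (soft); a single lambda is drawn per sample.
    """
    if n_classes is None:
        n_classes = int(max(np.max(y1), np.max(y2))) + 1
    lam = rng.beta(alpha, alpha, size=x1.shape[0])
    lam_x = lam.reshape((-1,) + (1,) * (x1.ndim - 1))
    x = lam_x * x1 + (1.0 - lam_x) * x2
    t = lam[:, None] * _as_dense(y1, n_classes) \
        + (1.0 - lam)[:, None] * _as_dense(y2, n_classes)
    return x, t


# ---------------------------------------------------------------------------
# dispatch

def objective_value_and_grad(z, y, cfg: ObjectiveConfig):
    """(batch-mean loss, per-sample gradient wrt logits) for any objective."""
    z = np.asarray(z, dtype=float)
    if cfg.name == "squared_error":
        return squared_error(z, y)
    if cfg.name == "cross_entropy":
        return cross_entropy(z, y)
    if cfg.name == "focal":
        return focal_loss(z, y, cfg.gamma_f)
    if cfg.name == "cb_focal":
        return cb_focal_loss(z, y, cfg.beta, cfg.gamma_f,
                             _require_counts(cfg, z.shape[1]))
    if cfg.name == "ldam":
        return ldam_loss(z, y, cfg.C, _require_counts(cfg, z.shape[1]))
    if cfg.name == "balanced_softmax":
        return balanced_softmax_loss(z, y, _require_counts(cfg, z.shape[1]))
    raise ConfigurationError(f"unknown objective {cfg.name!r}")


def objective_value(z, y, cfg: ObjectiveConfig) -> float:
    return objective_value_and_grad(z, y, cfg)[0]


def resolve_objective(obj) -> ObjectiveConfig:
    if isinstance(obj, ObjectiveConfig):
        return obj
    if isinstance(obj, str):
        return ObjectiveConfig(name=obj)
    raise ConfigurationError(f"cannot interpret objective {obj!r}")
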