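"""Layer transforms and their vector-Jacobian products.

Each layer ``f_i`` maps the previous layer's activation to a prediction.
``forward`` returns ``(out, cache)``; ``vjp_input`` and ``vjp_params`` are
exact VJPs of the forward map at the cached point.  ``vjp_params`` returns
sums over the batch (callers divide by the batch size where a mean is
wanted); ``vjp_input`` is per-sample.

Dropout masks and batch-norm statistics are drawn in the forward pass and
stored in the cache; re-evaluating a layer during inference (the
non-fixed-prediction mode) reuses them, so the inference loop is
deterministic given the forward pass.
"""

from __future__ import annotations

import numpy as np

from .errors import StructureError
from .network import LayerSpec

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.1


def _relu(z):
    return np.maximum(z, 0.0)


# ---------------------------------------------------------------------------
# affine

def _affine_forward(layer, params, x, *, train, rng, reuse=None):
    B = x.shape[0]
    x2 = x.reshape(B, -1)
    W, b = params["W"], params["b"]
    if x2.shape[1] != W.shape[1]:
        raise StructureError(
            f"affine layer expected input of size {W.shape[1]}, got {x2.shape[1]}")
    z = x2 @ W.T + b
    a = _relu(z) if layer.nonlinearity == "relu" else z
    mask = None
    if reuse is not None and reuse.get("mask") is not None:
        mask = reuse["mask"]
    elif layer.dropout_rate > 0.0 and train:
        keep = rng.random(a.shape) >= layer.dropout_rate
        mask = keep / (1.0 - layer.dropout_rate)
    if mask is not None:
        a = a * mask
    cache = {"x2": x2, "z": z, "mask": mask, "in_shape": x.shape}
    return a, cache


def _affine_upstream(layer, cache, g):
    """Propagate an output cotangent back through dropout and nonlinearity."""
    if cache["mask"] is not None:
        g = g * cache["mask"]
    if layer.nonlinearity == "relu":
        g = g * (cache["z"] > 0)  # ReLU'(0) := 0
    return g


def _affine_vjp_input(layer, params, cache, g):
    gz = _affine_upstream(layer, cache, g.reshape(g.shape[0], -1))
    return (gz @ params["W"]).reshape(cache["in_shape"])


def _affine_vjp_params(layer, params, cache, g):
    gz = _affine_upstream(layer, cache, g.reshape(g.shape[0], -1))
    return {"W": gz.T @ cache["x2"], "b": gz.sum(axis=0)}


# ---------------------------------------------------------------------------
# convolution block: conv(3x3, same) -> [batchnorm] -> nonlinearity -> maxpool

def _im2col(x, k):
    """(B, C, H, W) -> (B, C*k*k, H*W) with same padding, stride 1."""
    B, C, H, W = x.shape
    pad = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    s = xp.strides
    cols = np.lib.stride_tricks.as_strided(
        xp, (B, C, k, k, H, W), (s[0], s[1], s[2], s[3], s[2], s[3]))
    return np.ascontiguousarray(cols).reshape(B, C * k * k, H * W)


def _col2im(gcols, x_shape, k):
    B, C, H, W = x_shape
    pad = k // 2
    gxp = np.zeros((B, C, H + 2 * pad, W + 2 * pad))
    gcols = gcols.reshape(B, C, k, k, H, W)
    for i in range(k):
        for j in range(k):
            gxp[:, :, i:i + H, j:j + W] += gcols[:, :, i, j]
    return gxp[:, :, pad:pad + H, pad:pad + W]


def _conv_forward(params, x, k):
    B, C, H, W = x.shape
    W_mat = params["W"].reshape(params["W"].shape[0], -1)
    cols = _im2col(x, k)
    z = (W_mat @ cols + params["b"][:, None]).reshape(B, -1, H, W)
    return z, cols


def _bn_forward(params, z, *, train, reuse=None):
    if reuse is not None and "bn_mu" in reuse:
        mu, var, frozen = reuse["bn_mu"], reuse["bn_var"], True
    elif train:
        mu = z.mean(axis=(0, 2, 3))
        var = z.var(axis=(0, 2, 3))
        frozen = False
        params["running_mean"] *= 1.0 - _BN_MOMENTUM
        params["running_mean"] += _BN_MOMENTUM * mu
        params["running_var"] *= 1.0 - _BN_MOMENTUM
        params["running_var"] += _BN_MOMENTUM * var
    else:
        mu, var, frozen = params["running_mean"], params["running_var"], True
    std = np.sqrt(var + _BN_EPS)
    xhat = (z - mu[:, None, None]) / std[:, None, None]
    out = params["gamma"][:, None, None] * xhat + params["beta"][:, None, None]
    cache = {"bn_mu": mu, "bn_var": var, "bn_std": std, "bn_xhat": xhat,
             "bn_frozen": frozen}
    return out, cache


def _bn_vjp(params, cache, g):
    """VJP through batch norm; returns (g_z, g_gamma, g_beta).

    With live batch statistics the Jacobian couples the whole batch; with
    frozen statistics it is diagonal per channel.
    """
    xhat, std = cache["bn_xhat"], cache["bn_std"]
    g_gamma = (g * xhat).sum(axis=(0, 2, 3))
    g_beta = g.sum(axis=(0, 2, 3))
    gs = params["gamma"][:, None, None] / std[:, None, None]
    if cache["bn_frozen"]:
        gz = g * gs
    else:
        m_ax = (0, 2, 3)
        gz = gs * (g - g.mean(axis=m_ax, keepdims=True)
                   - xhat * (g * xhat).mean(axis=m_ax, keepdims=True))
    return gz, g_gamma, g_beta


def _pool_forward(a, p):
    B, C, H, W = a.shape
    Hc, Wc = H - H % p, W - W % p
    if Hc == 0 or Wc == 0:
        raise StructureError(f"spatial size {H}x{W} too small for {p}x{p} pooling")
    Ho, Wo = Hc // p, Wc // p
    win = (a[:, :, :Hc, :Wc]
           .reshape(B, C, Ho, p, Wo, p)
           .transpose(0, 1, 2, 4, 3, 5)
           .reshape(B, C, Ho, Wo, p * p))
    idx = win.argmax(axis=-1)
    out = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]
    return out, idx


def _pool_backward(g, idx, a_shape, p):
    B, C, H, W = a_shape
    Ho, Wo = idx.shape[2], idx.shape[3]
    gwin = np.zeros((B, C, Ho, Wo, p * p))
    np.put_along_axis(gwin, idx[..., None], g[..., None], axis=-1)
    ga = np.zeros(a_shape)
    ga[:, :, :Ho * p, :Wo * p] = (gwin
                                  .reshape(B, C, Ho, Wo, p, p)
                                  .transpose(0, 1, 2, 4, 3, 5)
                                  .reshape(B, C, Ho * p, Wo * p))
    return ga


def _conv_block_forward(layer, params, x, *, train, rng, reuse=None):
    if x.shape[1:] != layer.in_shape:
        raise StructureError(
            f"conv block expected input shape {layer.in_shape}, got {x.shape[1:]}")
    k, p = layer.kernel_size, layer.pool_size
    z, cols = _conv_forward(params, x, k)
    cache = {"x_shape": x.shape, "cols": cols, "z": z}
    h = z
    if layer.has_batchnorm:
        h, bn_cache = _bn_forward(params, h, train=train, reuse=reuse)
        cache.update(bn_cache)
    cache["pre_act"] = h
    a = _relu(h) if layer.nonlinearity == "relu" else h
    out, idx = _pool_forward(a, p)
    cache["pool_idx"] = idx
    cache["a_shape"] = a.shape
    return out, cache


def _conv_block_to_gz(layer, params, cache, g):
    """Output cotangent -> cotangent of the convolution pre-activation."""
    ga = _pool_backward(g, cache["pool_idx"], cache["a_shape"], layer.pool_size)
    if layer.nonlinearity == "relu":
        ga = ga * (cache["pre_act"] > 0)
    if layer.has_batchnorm:
        gz, g_gamma, g_beta = _bn_vjp(params, cache, ga)
        return gz, g_gamma, g_beta
    return ga, None, None


def _conv_block_vjp_input(layer, params, cache, g):
    gz, _, _ = _conv_block_to_gz(layer, params, cache, g)
    B = gz.shape[0]
    W_mat = params["W"].reshape(params["W"].shape[0], -1)
    gcols = np.einsum("oc,bos->bcs", W_mat, gz.reshape(B, gz.shape[1], -1))
    return _col2im(gcols, cache["x_shape"], layer.kernel_size)


def _conv_block_vjp_params(layer, params, cache, g):
    gz, g_gamma, g_beta = _conv_block_to_gz(layer, params, cache, g)
    B, Co = gz.shape[0], gz.shape[1]
    gz2 = gz.reshape(B, Co, -1)
    gW = np.einsum("bos,bcs->oc", gz2, cache["cols"]).reshape(params["W"].shape)
    out = {"W": gW, "b": gz2.sum(axis=(0, 2))}
    if layer.has_batchnorm:
        out["gamma"] = g_gamma
        out["beta"] = g_beta
    return out


# ---------------------------------------------------------------------------
# dispatch

def layer_forward(layer: LayerSpec, params, x, *, train=False, rng=None,
                  reuse=None):
    """Evaluate ``f_i`` at ``x``; returns ``(output, cache)``.

    ``reuse`` is a previous cache whose dropout mask / batch statistics are
    to be kept fixed (used when re-evaluating predictions during inference).
    """
    if layer.transform_kind == "affine":
        return _affine_forward(layer, params, x, train=train, rng=rng, reuse=reuse)
    return _conv_block_forward(layer, params, x, train=train, rng=rng, reuse=reuse)


def layer_vjp_input(layer: LayerSpec, params, cache, g):
    """J_f(x)^T g at the cached evaluation point."""
    if layer.transform_kind == "affine":
        return _affine_vjp_input(layer, params, cache, g)
    return _conv_block_vjp_input(layer, params, cache, g)


def layer_vjp_params(layer: LayerSpec, params, cache, g):
    """d(g . f)/d(theta), summed over the batch."""
    if layer.transform_kind == "affine":
        return _affine_vjp_params(layer, params, cache, g)
    return _conv_block_vjp_params(layer, params, cache, g)
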