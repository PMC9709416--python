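"""Synthetic image-classification data.

Every pipeline in the package (balanced training, long-tailed subsampling,
incremental task splits, few-shot class banks) can run on synthetic data so
that no download is required.  Classes are smooth low-frequency random
fields ("templates"); samples are templates plus additive Gaussian noise
(optionally a small integer translation jitter).  Smooth templates carry
signal for both dense and convolutional architectures.

All generators are deterministic given their seed: the same call twice
returns bit-identical arrays.  The noise level sigma is the single
difficulty dial; :func:`difficulty_report` tabulates nearest-template
accuracy against sigma so experiments can pick a target difficulty.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .errors import ConfigurationError


@dataclass
class TemplateBank:
    """C class templates of a common image shape, plus their noise model."""

    templates: np.ndarray  # (C, *image_shape)
    seed: int
    sigma: float = 1.0
    jitter: int = 0
    min_separation: float = 0.0

    @property
    def n_classes(self):
        return self.templates.shape[0]

    @property
    def image_shape(self):
        return self.templates.shape[1:]


def _smooth_field(rng, shape):
    """Standardized low-frequency random field."""
    field = rng.standard_normal(shape)
    smooth_sigma = max(1.0, min(shape[-2:]) / 8.0)
    field = gaussian_filter(field, sigma=(0,) * (len(shape) - 2) + (smooth_sigma,) * 2)
    return (field - field.mean()) / (field.std() + 1e-12)


def make_templates(C, image_shape=(1, 8, 8), seed=0, min_separation=None,
                   max_tries=200) -> TemplateBank:
    """Seeded distinct class templates with enforced pairwise separation.

    ``min_separation`` defaults to ``sqrt(D)`` for D pixels, comfortably
    below the ~sqrt(2D) distance of independent standardized fields, so it
    only rejects near-duplicates.
    """
    if C < 2:
        raise ConfigurationError("need at least 2 classes")
    image_shape = tuple(image_shape)
    D = int(np.prod(image_shape))
    if min_separation is None:
        min_separation = float(np.sqrt(D))
    rng = np.random.default_rng(seed)
    templates = np.empty((C,) + image_shape)
    for c in range(C):
        for attempt in range(max_tries):
            t = _smooth_field(rng, image_shape)
            dists = [np.linalg.norm(t - templates[j]) for j in range(c)]
            if not dists or min(dists) >= min_separation:
                templates[c] = t
                break
        else:
            raise ConfigurationError(
                f"could not place template {c} with separation "
                f">= {min_separation:.3g} in {max_tries} tries")
    return TemplateBank(templates=templates, seed=seed,
                        min_separation=min_separation)


def sample_dataset(bank: TemplateBank, counts, sigma=None, seed=0, jitter=None):
    """Draw ``counts[c]`` noisy samples of each class; returns ``(X, y)``."""
    counts = np.asarray(counts, dtype=int)
    if counts.shape != (bank.n_classes,):
        raise ConfigurationError(
            f"counts must have length {bank.n_classes}, got {counts.shape}")
    if np.any(counts < 0):
        raise ConfigurationError("counts must be nonnegative")
    sigma = bank.sigma if sigma is None else sigma
    jitter = bank.jitter if jitter is None else jitter
    rng = np.random.default_rng(seed)
    n = int(counts.sum())
    X = np.empty((n,) + bank.image_shape)
    y = np.empty(n, dtype=int)
    pos = 0
    for c, m in enumerate(counts):
        for _ in range(m):
            img = bank.templates[c]
            if jitter:
                dy, dx = rng.integers(-jitter, jitter + 1, size=2)
                img = np.roll(img, (dy, dx), axis=(-2, -1))
            X[pos] = img + sigma * rng.standard_normal(bank.image_shape)
            y[pos] = c
            pos += 1
    return X, y


def make_fewshot_bank(C_chars, variants, image_shape=(1, 16, 16), sigma=0.3,
                      seed=0):
    """Bank of low-shot character classes: array ``(C, V, *image_shape)``.

    Emulates the structure of a large handwritten-character collection at
    small scale: many classes, few variants per class, within-class
    variation set by ``sigma``.
    """
    tb = make_templates(C_chars, image_shape, seed=seed)
    rng = np.random.default_rng(seed + 1)
    bank = (tb.templates[:, None]
            + sigma * rng.standard_normal((C_chars, variants) + tb.image_shape))
    return bank


def split_bank(bank, n_train_classes, seed=0):
    """Disjoint train/eval class partition of a few-shot bank."""
    C = bank.shape[0]
    if not 0 < n_train_classes < C:
        raise ConfigurationError("n_train_classes must be in (0, C)")
    perm = np.random.default_rng(seed).permutation(C)
    return bank[perm[:n_train_classes]], bank[perm[n_train_classes:]]


def nearest_template_accuracy(bank: TemplateBank, X, y) -> float:
    flat_t = bank.templates.reshape(bank.n_classes, -1)
    flat_x = X.reshape(X.shape[0], -1)
    d = ((flat_x[:, None, :] - flat_t[None, :, :]) ** 2).sum(axis=2)
    return float((d.argmin(axis=1) == y).mean())


def difficulty_report(bank: TemplateBank, sigma_grid, seed=0,
                      n_per_class=30) -> pd.DataFrame:
    """Nearest-template accuracy as a function of the noise level."""
    rows = []
    counts = np.full(bank.n_classes, n_per_class)
    for i, s in enumerate(sigma_grid):
        X, y = sample_dataset(bank, counts, sigma=s, seed=seed + i)
        rows.append({"sigma": float(s),
                     "accuracy": 100.0 * nearest_template_accuracy(bank, X, y)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# IDX and PNG interchange (so synthetic data can flow through the same
# readers as the real benchmarks)

def _to_uint8(X):
    lo, hi = X.min(), X.max()
    scale = 255.0 / (hi - lo) if hi > lo else 1.0
    return np.round((X - lo) * scale).astype(np.uint8)


def write_idx_images(X, path):
    """Write (N, H, W) or (N, 1, H, W) images as an IDX3 ubyte file."""
    X = np.asarray(X)
    if X.ndim == 4 and X.shape[1] == 1:
        X = X[:, 0]
    if X.ndim != 3:
        raise ConfigurationError("IDX images must be (N, H, W) single-channel")
    data = X if X.dtype == np.uint8 else _to_uint8(X)
    with open(path, "wb") as f:
        f.write(struct.pack(">IIII", 0x803, *data.shape))
        f.write(np.ascontiguousarray(data).tobytes())


def write_idx_labels(y, path):
    y = np.asarray(y)
    with open(path, "wb") as f:
        f.write(struct.pack(">II", 0x801, y.shape[0]))
        f.write(y.astype(np.uint8).tobytes())


def read_idx(path):
    """Read an IDX ubyte file (images or labels) into a numpy array."""
    raw = Path(path).read_bytes()
    magic = struct.unpack(">I", raw[:4])[0]
    ndim = magic & 0xFF
    dims = struct.unpack(">" + "I" * ndim, raw[4:4 + 4 * ndim])
    return np.frombuffer(raw[4 + 4 * ndim:], dtype=np.uint8).reshape(dims).copy()


def write_png_bank(bank, directory):
    """Write a few-shot bank as one directory of PNGs per class."""
    from PIL import Image

    directory = Path(directory)
    for c in range(bank.shape[0]):
        cdir = directory / f"class_{c:04d}"
        cdir.mkdir(parents=True, exist_ok=True)
        for v in range(bank.shape[1]):
            img = _to_uint8(bank[c, v, 0] if bank.ndim == 5 else bank[c, v])
            Image.fromarray(img, mode="L").save(cdir / f"{v:04d}.png")


def read_png_bank(directory):
    """Read a directory-of-PNG class bank into ``(C, V, 1, H, W)`` floats in [0, 1]."""
    from PIL import Image

    directory = Path(directory)
    classes = sorted(p for p in directory.iterdir() if p.is_dir())
    if not classes:
        raise ConfigurationError(f"no class directories under {directory}")
    bank = []
    for cdir in classes:
        items = [np.asarray(Image.open(p).convert("L"), dtype=float) / 255.0
                 for p in sorted(cdir.glob("*.png"))]
        bank.append(np.stack(items)[:, None])
    return np.stack(bank)
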