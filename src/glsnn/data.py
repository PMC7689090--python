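"""Dataset containers, IDX-format readers/writers, label encoding, and a
synthetic Gaussian-blob generator.

The IDX container is the layout MNIST and Fashion-MNIST ship in:
big-endian magic-number header (0x00000803 for image tensors,
0x00000801 for label vectors) followed by a uint8 payload.  The
synthetic generator emulates what the learner needs from such data —
bounded inputs in [0, 1] with class-conditional cluster structure — so
everything downstream trains and tests without any download.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "Dataset",
    "read_idx_images",
    "read_idx_labels",
    "write_idx_images",
    "write_idx_labels",
    "one_hot",
    "make_blobs",
]

IMAGE_MAGIC = 0x00000803
LABEL_MAGIC = 0x00000801


@dataclass
class Dataset:
    """Flattened samples ``X`` with values in [0, 1], integer labels
    ``y`` in [0, n_classes), and a display name."""

    X: np.ndarray
    y: np.ndarray
    n_classes: int
    name: str = "dataset"

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.int64)
        if len(self.X) != len(self.y):
            raise ValueError(f"X has {len(self.X)} rows but y has {len(self.y)}")
        if self.X.size and (self.X.min() < 0 or self.X.max() > 1):
            raise ValueError("X entries must lie in [0, 1]")
        if self.y.size and (self.y.min() < 0 or self.y.max() >= self.n_classes):
            raise ValueError(
                f"labels must lie in [0, {self.n_classes}), got range "
                f"[{self.y.min()}, {self.y.max()}]"
            )

    def __len__(self) -> int:
        return len(self.y)


class IDXFormatError(ValueError):
    """Malformed IDX file: wrong magic, truncated payload, or count mismatch."""


def read_idx_images(path: str | Path) -> np.ndarray:
    """Parse an IDX image file into an (n, rows*cols) float array in [0, 1].

    Pixels are scaled by 1/255.
    """
    raw = Path(path).read_bytes()
    if len(raw) < 16:
        raise IDXFormatError(f"{path}: header truncated ({len(raw)} bytes)")
    magic, n, rows, cols = struct.unpack(">IIII", raw[:16])
    if magic != IMAGE_MAGIC:
        raise IDXFormatError(
            f"{path}: bad magic 0x{magic:08x}, expected 0x{IMAGE_MAGIC:08x}"
        )
    expected = n * rows * cols
    payload = np.frombuffer(raw, dtype=np.uint8, offset=16)
    if payload.size != expected:
        raise IDXFormatError(
            f"{path}: payload has {payload.size} bytes, header promises {expected}"
        )
    return payload.reshape(n, rows * cols).astype(np.float64) / 255.0


def read_idx_labels(path: str | Path) -> np.ndarray:
    """Parse an IDX label file into an int64 vector."""
    raw = Path(path).read_bytes()
    if len(raw) < 8:
        raise IDXFormatError(f"{path}: header truncated ({len(raw)} bytes)")
    magic, n = struct.unpack(">II", raw[:8])
    if magic != LABEL_MAGIC:
        raise IDXFormatError(
            f"{path}: bad magic 0x{magic:08x}, expected 0x{LABEL_MAGIC:08x}"
        )
    payload = np.frombuffer(raw, dtype=np.uint8, offset=8)
    if payload.size != n:
        raise IDXFormatError(
            f"{path}: payload has {payload.size} labels, header promises {n}"
        )
    return payload.astype(np.int64)


def write_idx_images(path: str | Path, images: np.ndarray, rows: int, cols: int) -> None:
    """Write an (n, rows*cols) array of [0, 1] floats as a uint8 IDX image file."""
    images = np.asarray(images)
    n = images.shape[0]
    if images.size != n * rows * cols:
        raise ValueError(f"images shape {images.shape} inconsistent with {rows}x{cols}")
    pix = np.clip(np.round(images * 255.0), 0, 255).astype(np.uint8)
    with open(path, "wb") as fh:
        fh.write(struct.pack(">IIII", IMAGE_MAGIC, n, rows, cols))
        fh.write(pix.tobytes())


def write_idx_labels(path: str | Path, labels: np.ndarray) -> None:
    labels = np.asarray(labels)
    if labels.size and (labels.min() < 0 or labels.max() > 255):
        raise ValueError("IDX labels must fit in uint8")
    with open(path, "wb") as fh:
        fh.write(struct.pack(">II", LABEL_MAGIC, labels.size))
        fh.write(labels.astype(np.uint8).tobytes())


def one_hot(y: np.ndarray, n_classes: int, amplitude: float = 1.0) -> np.ndarray:
    """Encode integer labels as rows with ``amplitude`` at the class index."""
    y = np.asarray(y, dtype=np.int64).ravel()
    if y.size and (y.min() < 0 or y.max() >= n_classes):
        raise ValueError(f"labels out of range [0, {n_classes})")
    out = np.zeros((y.size, n_classes), dtype=np.float64)
    out[np.arange(y.size), y] = amplitude
    return out


def make_blobs(
    n_per_class: int = 200,
    dim: int = 20,
    n_classes: int = 3,
    separation: float = 6.0,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> tuple[Dataset, Dataset]:
    """Labeled Gaussian clusters squashed into [0, 1], split 2:1 train/test.

    Class centers are drawn on a sphere of radius ``separation·noise_sd``
    around the cube center and redrawn until every pairwise distance is
    at least ``separation·noise_sd`` (so nearest neighbours of a sample
    are overwhelmingly its own class at separation ≈ 6).  Samples are
    center + isotropic Gaussian noise, mapped by the fixed affine-clip
    map x ↦ clip(x + 1/2, 0, 1).  ``n_per_class`` training samples and
    half as many test samples per class; deterministic per seed.
    """
    if n_per_class < 1 or dim < 1 or n_classes < 1:
        raise ValueError("n_per_class, dim and n_classes must all be >= 1")
    if separation <= 0 or noise_sd <= 0:
        raise ValueError("separation and noise_sd must be positive")

    rng = np.random.default_rng(seed)
    radius = separation * noise_sd
    min_dist = separation * noise_sd
    centers = np.empty((n_classes, dim))
    for k in range(n_classes):
        for attempt in range(1000):
            c = rng.standard_normal(dim)
            c *= radius / np.linalg.norm(c)
            if k == 0 or np.linalg.norm(centers[:k] - c, axis=1).min() >= min_dist:
                centers[k] = c
                break
        else:
            raise ValueError(
                f"cannot place {n_classes} centers at pairwise distance "
                f">= {min_dist:.3g} on a radius-{radius:.3g} sphere in {dim} dims"
            )

    def draw(n_each: int, tag: str) -> Dataset:
        X = np.concatenate(
            [centers[k] + noise_sd * rng.standard_normal((n_each, dim))
             for k in range(n_classes)]
        )
        y = np.repeat(np.arange(n_classes), n_each)
        X = np.clip(X + 0.5, 0.0, 1.0)
        perm = rng.permutation(len(y))
        return Dataset(X[perm], y[perm], n_classes, name=f"blobs-{tag}")

    n_test = max(1, n_per_class // 2)
    return draw(n_per_class, "train"), draw(n_test, "test")
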