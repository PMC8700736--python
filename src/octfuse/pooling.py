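"""Multilevel multiple-pooling image decomposition.

Three non-overlapping block-pooling operators — max, max-mean and max-min —
are applied at three scales to a grayscale intensity image.  Between levels
the carrier image is downsampled by 2x2 max pooling, so one input image
yields nine compressed images (three operators x three levels).  Routing all
three statistics instead of the maximum alone preserves average and minimum
block structure that plain max pooling discards.

Blocks are k x k and non-overlapping; partial edge blocks (when the image
side is not a multiple of k) are discarded, so every output has shape
floor(H/k) x floor(W/k).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class DegenerateInputError(ValueError):
    """Raised when an image is too small for the requested pooling."""


def _as_image(image) -> np.ndarray:
    """Validate and coerce input to a finite 2-D float array.

    Color (H, W, 3) inputs are collapsed to grayscale by channel averaging
    before pooling, since the operators are defined on a single 2-D matrix.
    """
    arr = np.asarray(image, dtype=float)
    if arr.ndim == 3 and arr.shape[2] in (3, 4):
        arr = arr[..., :3].mean(axis=2)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D intensity image, got shape {arr.shape}")
    if arr.size == 0:
        raise DegenerateInputError("empty image")
    if not np.all(np.isfinite(arr)):
        raise ValueError("image contains non-finite intensities")
    return arr


def _blocks(image: np.ndarray, k: int) -> np.ndarray:
    """Tile the image into non-overlapping k x k blocks.

    Returns an array of shape (H//k, W//k, k, k) where axis 2 indexes rows
    within a block and axis 3 indexes columns.  Partial edge blocks are
    cropped away (floor semantics).
    """
    h, w = image.shape
    if h < k:
        raise DegenerateInputError(
            f"image height {h} is smaller than block side {k}"
        )
    if w < k:
        raise DegenerateInputError(
            f"image width {w} is smaller than block side {k}"
        )
    hb, wb = h // k, w // k
    cropped = image[: hb * k, : wb * k]
    return cropped.reshape(hb, k, wb, k).transpose(0, 2, 1, 3)


def max_pool(image, k: int = 3) -> np.ndarray:
    """Maximum pooling: each output cell is the maximum of its k x k block."""
    b = _blocks(_as_image(image), k)
    return b.max(axis=(2, 3))


def max_mean_pool(image, k: int = 3) -> np.ndarray:
    """Max-mean pooling: the maximum over columns of per-column block means.

    Within each block, the mean of every column is taken; the output cell is
    the largest of those k column means.
    """
    b = _blocks(_as_image(image), k)
    return b.mean(axis=2).max(axis=2)


def max_min_pool(image, k: int = 3) -> np.ndarray:
    """Max-min pooling: the maximum over columns of per-column block minima."""
    b = _blocks(_as_image(image), k)
    return b.min(axis=2).max(axis=2)


#: operator order within each decomposition level
LEVEL_OPERATORS = (max_pool, max_mean_pool, max_min_pool)

#: number of decomposition levels
N_LEVELS = 3

#: block side for within-level pooling
LEVEL_BLOCK = 3

#: block side for the between-level carrier downsampling
CARRIER_BLOCK = 2

#: minimum image side so the level-3 carrier still admits one 3x3 block
MIN_SIDE = 12


@dataclass
class DecompositionResult:
    """The nine compressed images c1..c9 plus the per-level carrier images.

    Level l (1-based) contributes ``compressed[3l-3]`` (max),
    ``compressed[3l-2]`` (max-mean) and ``compressed[3l-1]`` (max-min).
    ``carriers[l-1]`` is the image those three were pooled from: the original
    image for level 1, then its 2x2-max-pooled successors.
    """

    compressed: list = field(default_factory=list)
    carriers: list = field(default_factory=list)

    def __post_init__(self):
        if len(self.compressed) != N_LEVELS * len(LEVEL_OPERATORS):
            raise ValueError(
                f"expected {N_LEVELS * len(LEVEL_OPERATORS)} compressed images, "
                f"got {len(self.compressed)}"
            )

    def __len__(self) -> int:
        return len(self.compressed)

    def __iter__(self):
        return iter(self.compressed)


def decompose(image) -> DecompositionResult:
    """Three-level multiple-pooling decomposition of one intensity image.

    For each of three levels, the current carrier is pooled with 3x3 blocks
    by the max, max-mean and max-min operators (emitting three compressed
    images), then the carrier is replaced by its 2x2 max-pool.  Requires the
    input to be at least 12 x 12 so that the level-3 carrier still admits a
    3x3 block.
    """
    carrier = _as_image(image)
    h, w = carrier.shape
    if h < MIN_SIDE or w < MIN_SIDE:
        raise DegenerateInputError(
            f"image of shape {h}x{w} too small to decompose; "
            f"minimum supported size is {MIN_SIDE}x{MIN_SIDE}"
        )
    compressed: list = []
    carriers: list = []
    for _ in range(N_LEVELS):
        carriers.append(carrier)
        for op in LEVEL_OPERATORS:
            compressed.append(op(carrier, LEVEL_BLOCK))
        carrier = max_pool(carrier, CARRIER_BLOCK)
    return DecompositionResult(compressed=compressed, carriers=carriers)
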