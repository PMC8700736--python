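"""Synthetic OCT-like image datasets and deterministic mock extractors.

Real OCT B-scans show bright, roughly horizontal retinal layers whose
spacing and position shift with pathology.  The generator emulates that with
class-specific horizontal stripe patterns (per-class spatial frequency and
band offset) degraded by multiplicative speckle noise — enough structure
that the three pooling statistics and the multilevel carriers genuinely
differ, which is what the fusion framework exploits.  It makes no attempt
at physically realistic speckle statistics or lesion morphology.

Mock extractors replace ImageNet CNNs in tests: the ``informative`` kind
summarizes band energies and intensity structure (class signal survives),
the ``noise`` kind emits a reproducible pseudo-random vector per image
(no class signal at all), so extractor ranking has a planted ground truth.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
from skimage.transform import resize as _resize

from .features import FeatureExtractor


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic dataset.

    ``stripe_freqs``/``band_offsets`` hold one (cycles-per-image, phase)
    pair per class; defaults space classes apart in frequency.  ``sigma``
    is the speckle noise level (std of the multiplicative lognormal-ish
    field); 0 gives identical images within a class.
    """

    n_classes: int = 3
    n_per_class: int = 30
    height: int = 64
    width: int = 64
    sigma: float = 0.15
    seed: int = 0

    def __post_init__(self):
        if not (2 <= self.n_classes <= 4):
            raise ValueError("n_classes must be in 2..4")
        if self.height < 12 or self.width < 12:
            raise ValueError(
                "images must be at least 12x12 to admit the three-level "
                "pooling decomposition"
            )
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be positive")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")


#: per-class (stripe frequency in cycles per image height, band phase offset)
CLASS_STRIPES = ((3.0, 0.0), (6.0, 0.4), (10.0, 0.9), (15.0, 1.7))


def make_dataset(spec: SyntheticSpec):
    """Generate ``n_classes * n_per_class`` images and their labels.

    Each image is a class-specific horizontal stripe pattern (a vertical
    sinusoid of the class frequency, phase-offset per class) under
    multiplicative speckle, min-max rescaled to [0, 1].  Rescaling rather
    than clipping keeps intensities continuous, so no two noisy images share
    saturated regions.  Reproducible from the seed.
    """
    rng = np.random.default_rng(spec.seed)
    rows = np.arange(spec.height)[:, None] / spec.height
    images, labels = [], []
    for cls in range(spec.n_classes):
        freq, phase = CLASS_STRIPES[cls]
        clean = 0.5 + 0.4 * np.sin(2 * np.pi * freq * rows + phase)
        clean = np.broadcast_to(clean, (spec.height, spec.width))
        for _ in range(spec.n_per_class):
            if spec.sigma > 0:
                speckle = 1.0 + spec.sigma * rng.standard_normal(clean.shape)
                img = clean * speckle
            else:
                img = clean.copy()
            lo, hi = img.min(), img.max()
            images.append((img - lo) / (hi - lo))
            labels.append(cls)
    return images, np.asarray(labels)


@dataclass(frozen=True)
class MockExtractorSpec:
    """Recipe for a deterministic stand-in extractor."""

    kind: str = "informative"     # "informative" | "noise"
    D: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("informative", "noise"):
            raise ValueError(f"unknown mock kind {self.kind!r}")
        if self.D < 2:
            raise ValueError("D must be >= 2")


_STATS_SIZE = 32      # images are internally resized to this square
_N_BANDS = 8


def _image_stats(img: np.ndarray) -> np.ndarray:
    """Fixed-length band-energy / histogram summary of one image."""
    small = img
    if small.shape != (_STATS_SIZE, _STATS_SIZE):
        small = _resize(small, (_STATS_SIZE, _STATS_SIZE), order=1,
                        anti_aliasing=False, preserve_range=True)
    row_bands = small.reshape(_N_BANDS, -1, _STATS_SIZE).mean(axis=(1, 2))
    col_bands = small.T.reshape(_N_BANDS, -1, _STATS_SIZE).mean(axis=(1, 2))
    grad = np.abs(np.diff(small, axis=0)).mean(axis=1)
    grad = np.append(grad, grad[-1])      # pad to _STATS_SIZE rows
    grad_bands = grad.reshape(_N_BANDS, -1).mean(axis=1)
    hist, _ = np.histogram(small, bins=16, range=(small.min(), small.max() + 1e-12))
    return np.concatenate([
        row_bands, col_bands, grad_bands,
        hist / small.size,
        [small.mean(), small.std(), small.min(), small.max()],
    ])


def _stable_digest(img: np.ndarray, seed: int) -> int:
    """Platform-stable per-image integer for seeding the noise mock."""
    h = hashlib.blake2b(digest_size=8)
    h.update(np.ascontiguousarray(np.round(img, 9), dtype=np.float64).tobytes())
    h.update(str(seed).encode())
    return int.from_bytes(h.digest(), "little") % (2**31)


def make_extractor(spec: MockExtractorSpec) -> FeatureExtractor:
    """Build a deterministic mock extractor honouring the contract.

    informative
        Band-energy summary statistics projected to D dimensions by a
        fixed seeded Gaussian matrix — class structure passes through.
    noise
        A pseudo-random D-vector keyed to the image content, so the same
        image always maps to the same vector but nearby images of one class
        share nothing — cross-validated loss sits at chance.
    """
    if spec.kind == "informative":
        base = len(_image_stats(np.zeros((_STATS_SIZE, _STATS_SIZE))))
        proj = np.random.default_rng(spec.seed).standard_normal((spec.D, base))
        proj /= np.sqrt(base)

        def fn(img: np.ndarray) -> np.ndarray:
            return proj @ _image_stats(img)

        name = f"mock-informative-{spec.D}-s{spec.seed}"
    else:
        def fn(img: np.ndarray) -> np.ndarray:
            rng = np.random.default_rng(_stable_digest(img, spec.seed))
            return rng.standard_normal(spec.D)

        name = f"mock-noise-{spec.D}-s{spec.seed}"
    return FeatureExtractor(name=name, output_dim=spec.D, fn=fn)
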