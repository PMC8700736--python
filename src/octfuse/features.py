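"""Feature-extractor contract, registry, and fused deep-feature vectors.

A :class:`FeatureExtractor` is any deterministic map from a grayscale image
to a fixed-length feature vector.  The framework treats ImageNet-pre-trained
CNNs (used frozen, through their final fully-connected layer, D = 1000) and
the bundled mock extractors identically: for one image the decomposition's
nine compressed images plus the original are each pushed through the
extractor and the ten D-vectors are concatenated into a single 10*D fused
deep-feature vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from skimage.transform import resize as _resize

from .pooling import _as_image, decompose

N_SEGMENTS = 10  # original image + nine compressed images


class ExtractorOutputError(RuntimeError):
    """Raised when a backend emits non-finite or mis-sized features."""


@dataclass(frozen=True)
class FeatureExtractor:
    """A named deterministic image -> D-vector feature map.

    Parameters
    ----------
    name
        Identifier used in loss tables and provenance records.
    output_dim
        Length D of the emitted feature vector.
    fn
        The map itself.  It receives a 2-D float image already resized to
        ``input_size`` (when ``input_size`` is set) and must return a
        1-D array of length ``output_dim`` with finite entries.
    input_size
        Expected (H, W); images are resized to it by bilinear interpolation
        before ``fn`` is called.  ``None`` means the extractor accepts any
        size (the mocks do their own internal normalization).
    """

    name: str
    output_dim: int
    fn: Callable[[np.ndarray], np.ndarray]
    input_size: Optional[tuple] = None

    def __call__(self, image) -> np.ndarray:
        return extract(self, image)


def extract(extractor: FeatureExtractor, image) -> np.ndarray:
    """Apply one extractor to one image, returning its D-vector."""
    arr = _as_image(image)
    if extractor.input_size is not None and arr.shape != tuple(extractor.input_size):
        arr = _resize(arr, extractor.input_size, order=1, anti_aliasing=False,
                      preserve_range=True)
    out = np.asarray(extractor.fn(arr), dtype=float).ravel()
    if out.shape[0] != extractor.output_dim:
        raise ExtractorOutputError(
            f"extractor {extractor.name!r} emitted {out.shape[0]} features, "
            f"declared {extractor.output_dim}"
        )
    if not np.all(np.isfinite(out)):
        raise ExtractorOutputError(
            f"extractor {extractor.name!r} emitted non-finite features"
        )
    return out


def generate_deep_features(extractor: FeatureExtractor, image) -> np.ndarray:
    """Fused deep-feature vector of one image: 10 segments of length D.

    Segment 0 holds the features of the original image; segments 1..9 hold
    the features of the decomposition outputs c1..c9, in generation order.
    """
    arr = _as_image(image)
    parts = [extract(extractor, arr)]
    parts.extend(extract(extractor, c) for c in decompose(arr))
    return np.concatenate(parts)


@dataclass
class LabeledFeatureMatrix:
    """An n x p feature matrix with class labels and column provenance.

    ``provenance[j]`` is a ``(extractor_name, segment, within_segment_index)``
    triple describing where column j came from; selection and fusion carry
    it through so any final feature can be traced back to its source image
    segment.
    """

    X: np.ndarray
    y: np.ndarray
    provenance: list = field(default_factory=list)

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D")
        if self.y.shape[0] != self.X.shape[0]:
            raise ValueError(
                f"{self.X.shape[0]} rows but {self.y.shape[0]} labels"
            )
        if self.provenance and len(self.provenance) != self.X.shape[1]:
            raise ValueError("provenance length must match column count")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.y)


def build_dataset(extractor: FeatureExtractor, images, labels) -> LabeledFeatureMatrix:
    """Fused deep-feature matrix for a labeled image collection.

    Row k is ``generate_deep_features(extractor, images[k])``; provenance
    maps every column to its (extractor, segment, index) origin.
    """
    images = list(images)
    labels = np.asarray(labels)
    if len(images) != labels.shape[0]:
        raise ValueError(
            f"{len(images)} images but {labels.shape[0]} labels"
        )
    if len(images) < 2 or np.unique(labels).size < 2:
        raise ValueError("need at least two images spanning at least two classes")
    rows = [generate_deep_features(extractor, img) for img in images]
    X = np.vstack(rows)
    d = extractor.output_dim
    provenance = [
        (extractor.name, j // d, j % d) for j in range(N_SEGMENTS * d)
    ]
    return LabeledFeatureMatrix(X=X, y=labels, provenance=provenance)


# ---------------------------------------------------------------------------
# Registry

#: the 18 pre-trained CNN slots of the original framework, in its order
CNN_SLOTS = (
    "ResNet18", "ResNet50", "ResNet101", "DarkNet19", "MobileNetV2",
    "DarkNet53", "Xception", "EfficientNetB0", "ShuffleNet", "NasNetMobile",
    "NasNetLarge", "DenseNet201", "InceptionV3", "InceptionResNetV2",
    "GoogLeNet", "AlexNet", "VGG16", "VGG19",
)


class ExtractorUnavailableError(LookupError):
    """A registry slot exists but no backend can serve it here."""


_REGISTRY: dict = {}


def register_extractor(extractor: FeatureExtractor, overwrite: bool = False) -> None:
    if extractor.name in _REGISTRY and not overwrite:
        raise ValueError(f"extractor {extractor.name!r} already registered")
    _REGISTRY[extractor.name] = extractor


def available_extractors() -> list:
    """Names of extractors that can actually be instantiated here."""
    return sorted(_REGISTRY)


def list_cnn_slots() -> tuple:
    """The 18 named CNN extractor slots, whether or not a backend exists."""
    return CNN_SLOTS


def get_extractor(name: str) -> FeatureExtractor:
    """Resolve a name to an extractor.

    CNN slots resolve only when an optional deep-learning backend
    (torchvision/timm) is importable; otherwise they are reported
    unavailable with an explicit error rather than silently skipped.
    """
    if name in _REGISTRY:
        return _REGISTRY[name]
    if name in CNN_SLOTS:
        backend = _load_cnn_backend(name)
        if backend is None:
            raise ExtractorUnavailableError(
                f"CNN slot {name!r} has no importable backend "
                "(install the optional torchvision/timm extras to enable it)"
            )
        return backend
    raise LookupError(f"unknown extractor {name!r}")


def _load_cnn_backend(name: str) -> Optional[FeatureExtractor]:
    """Wrap a torchvision model as an extractor over its logits layer."""
    try:
        import torch  # noqa: F401
        import torchvision.models as tvm
    except ImportError:
        return None
    aliases = {
        "ResNet18": "resnet18", "ResNet50": "resnet50", "ResNet101": "resnet101",
        "MobileNetV2": "mobilenet_v2", "DenseNet201": "densenet201",
        "InceptionV3": "inception_v3", "GoogLeNet": "googlenet",
        "AlexNet": "alexnet", "VGG16": "vgg16", "VGG19": "vgg19",
        "ShuffleNet": "shufflenet_v2_x1_0", "EfficientNetB0": "efficientnet_b0",
    }
    if name not in aliases:
        return None
    import torch

    model = getattr(tvm, aliases[name])(weights="DEFAULT")
    model.eval()

    def fn(img: np.ndarray) -> np.ndarray:
        lo, hi = float(img.min()), float(img.max())
        scaled = (img - lo) / (hi - lo) if hi > lo else np.zeros_like(img)
        t = torch.from_numpy(np.repeat(scaled[None, None], 3, axis=1)).float()
        with torch.no_grad():
            return model(t).numpy().ravel()

    return FeatureExtractor(name=name, output_dim=1000, fn=fn,
                            input_size=(224, 224))
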