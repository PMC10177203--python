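"""Frozen convolutional feature extractors with multi-layer taps.

A backbone here is never trained and never classifies: it is a fixed
convolutional stack whose intermediate feature maps are read out ("tapped")
at named stages, reduced by global average pooling (GAP — the spatial mean,
one value per channel) and concatenated into a single feature vector per
image.  Downstream classifiers see only that vector.

Tap points follow the multi-layer readout scheme: for VGG16 the output of
each of the five convolutional blocks just before its max-pooling layer
(64 + 128 + 256 + 512 + 512 = 1472 features); for Inception v3 the first
two convolutional blocks and the first two inception blocks; for
EfficientNet-B4 the last map at each channel width before every channel
increase.  The exact stage names and channel counts live in
:data:`TAP_REGISTRY`; the Inception/EfficientNet entries resolve a verbal
rule against the published architecture definitions and are flagged as
interpretation in the registry itself.

Two weight sources exist.  ``seeded_random`` draws He-initialized weights
from a fixed seed and is available for the ``stub`` and ``vgg16``
architectures, which have a pure NumPy forward pass; random frozen
convolutions are a legitimate (if weak) feature map and make every
downstream stage testable with zero downloads.  ``pretrained`` requires the
published ImageNet weights, which this package does not bundle; requesting
them raises with an instruction to use the stub or supply a weights source.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

TAP_REGISTRY_VERSION = 1

#: architecture metadata: default input size, ordered tap names, channels per tap
TAP_REGISTRY: dict[str, dict] = {
    "vgg16": {
        "input_size": 224,
        "tap_points": ("block1", "block2", "block3", "block4", "block5"),
        "channels_at_taps": (64, 128, 256, 512, 512),
        "interpretation": False,
    },
    "inception_v3": {
        "input_size": 299,
        # first two conv blocks (Conv2d_1a-2b -> 64 ch; Conv2d_3b-4a -> 192 ch)
        # and first two inception blocks (Mixed_5b -> 256, Mixed_5c -> 288);
        # channel counts resolved against the published definition.
        "tap_points": ("conv_block1", "conv_block2", "inception1", "inception2"),
        "channels_at_taps": (64, 192, 256, 288),
        "interpretation": True,
    },
    "efficientnet_b4": {
        # last map at each channel width before every increase:
        # 24 -> 32 -> 56 -> 112 -> 160 -> 272 -> 448 (stage widths of B4)
        "input_size": 380,
        "tap_points": tuple(f"pre_increase_{c}" for c in (24, 32, 56, 112, 160, 272, 448)),
        "channels_at_taps": (24, 32, 56, 112, 160, 272, 448),
        "interpretation": True,
    },
    "stub": {
        "input_size": 96,
        "tap_points": ("stage1", "stage2", "stage3"),
        "channels_at_taps": None,  # taken from spec.stub_widths
        "interpretation": False,
    },
}

#: conv layer plan per VGG16 block (channels per layer; pool after each block)
_VGG16_BLOCKS = ((64, 64), (128, 128), (256, 256, 256),
                 (512, 512, 512), (512, 512, 512))


class BackboneError(ValueError):
    pass


@dataclass(frozen=True)
class BackboneSpec:
    name: str = "stub"
    input_size: int | None = None  # defaults to the registry value
    weights: str = "seeded_random"  # {seeded_random, pretrained}
    seed: int = 0
    stub_widths: tuple[int, ...] = (8, 16, 32)
    tap_points: tuple[str, ...] | None = None  # defaults to the registry value

    def __post_init__(self) -> None:
        if self.name not in TAP_REGISTRY:
            raise BackboneError(
                f"unknown backbone {self.name!r}; known: {sorted(TAP_REGISTRY)}"
            )
        if self.weights not in ("seeded_random", "pretrained"):
            raise BackboneError(f"unknown weight source {self.weights!r}")
        if self.tap_points is not None and len(self.tap_points) == 0:
            raise BackboneError("tap_points must be non-empty")
        if self.name == "stub" and not self.stub_widths:
            raise BackboneError("stub_widths must be non-empty")

    @property
    def resolved_input_size(self) -> int:
        return self.input_size or TAP_REGISTRY[self.name]["input_size"]

    @property
    def resolved_tap_points(self) -> tuple[str, ...]:
        return self.tap_points or TAP_REGISTRY[self.name]["tap_points"]

    @property
    def channels_at_taps(self) -> tuple[int, ...]:
        if self.name == "stub":
            return tuple(self.stub_widths)
        reg = TAP_REGISTRY[self.name]
        by_name = dict(zip(reg["tap_points"], reg["channels_at_taps"]))
        try:
            return tuple(by_name[t] for t in self.resolved_tap_points)
        except KeyError as exc:
            raise BackboneError(f"unknown tap point {exc.args[0]!r} for {self.name}") from None


def feature_dimension(spec: BackboneSpec) -> int:
    """Length of the concatenated GAP vector: sum of channels over taps."""
    return int(sum(spec.channels_at_taps))


def _he_conv(rng: np.random.Generator, c_in: int, c_out: int) -> tuple[np.ndarray, np.ndarray]:
    w = rng.standard_normal((3, 3, c_in, c_out)).astype(np.float32)
    w *= np.sqrt(2.0 / (9 * c_in)).astype(np.float32)
    b = np.zeros(c_out, dtype=np.float32)
    return w, b


def _conv3x3(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Same-padded 3x3 convolution via im2col matmul; x is H x W x Cin."""
    h, wd, c_in = x.shape
    xp = np.pad(x, ((1, 1), (1, 1), (0, 0)))
    win = sliding_window_view(xp, (3, 3), axis=(0, 1))  # H, W, Cin, 3, 3
    patches = win.transpose(0, 1, 3, 4, 2).reshape(h * wd, 9 * c_in)
    wm = w.reshape(9 * c_in, -1)
    return (patches @ wm + b).reshape(h, wd, -1)


def _maxpool2(x: np.ndarray) -> np.ndarray:
    h, w, c = x.shape
    h2, w2 = h // 2, w // 2
    return x[: h2 * 2, : w2 * 2].reshape(h2, 2, w2, 2, c).max(axis=(1, 3))


def _gap(feature_map: np.ndarray) -> np.ndarray:
    """Global average pooling: spatial mean, one value per channel."""
    return feature_map.mean(axis=(0, 1))


class FrozenExtractor:
    """A built, frozen backbone: ``extract`` maps images to feature vectors.

    Weights are materialized once at construction and never updated;
    extraction is a pure function of (weights, input).
    """

    def __init__(self, spec: BackboneSpec):
        self.spec = spec
        self.feature_dim = feature_dimension(spec)
        rng = np.random.default_rng(spec.seed)
        self._layers: list[list[tuple[np.ndarray, np.ndarray]]] = []
        if spec.name == "stub":
            block_plan: tuple[tuple[int, ...], ...] = tuple((w,) for w in spec.stub_widths)
        else:  # vgg16 (guarded in build_backbone)
            block_plan = _VGG16_BLOCKS
        c_in = 3
        for block in block_plan:
            layers = []
            for c_out in block:
                layers.append(_he_conv(rng, c_in, c_out))
                c_in = c_out
            self._layers.append(layers)
        self._n_taps = len(spec.resolved_tap_points)

    def extract(self, image: np.ndarray) -> np.ndarray:
        """GAP features at every tap, concatenated in tap order.

        ``image`` is the normalized H x W x 3 array at the spec's input
        size (any other spatial size is an error).
        """
        size = self.spec.resolved_input_size
        if image.ndim != 3 or image.shape[0] != size or image.shape[1] != size:
            raise BackboneError(
                f"input spatial size must be {size}x{size}, "
                f"got {image.shape[1]}x{image.shape[0]}"
            )
        x = image.astype(np.float32)
        pooled: list[np.ndarray] = []
        for b, layers in enumerate(self._layers):
            for w, bias in layers:
                x = np.maximum(_conv3x3(x, w, bias), 0.0)
            pooled.append(_gap(x))  # tap just before the pooling layer
            if b < len(self._layers) - 1:
                x = _maxpool2(x)
        vec = np.concatenate(pooled[: self._n_taps]).astype(np.float64)
        if not np.all(np.isfinite(vec)):
            raise BackboneError("non-finite feature values")
        return vec

    def extract_batch(self, images: list[np.ndarray]) -> np.ndarray:
        """Row-stacked features; independent of how the list is batched."""
        return np.stack([self.extract(im) for im in images]) if images else np.empty(
            (0, self.feature_dim)
        )


@dataclass(frozen=True)
class FeatureVector:
    """One extracted vector with its provenance within the pipeline."""

    values: np.ndarray
    image_id: str = ""
    replicate: int = 0
    crop_id: str = "train"

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise BackboneError("feature vector contains non-finite entries")


def build_backbone(spec: BackboneSpec) -> FrozenExtractor:
    """Materialize a frozen extractor for ``spec``.

    ``pretrained`` weights are not bundled and there is no offline source
    for them, so they always raise; use the stub (or seeded-random VGG16)
    for development and testing, or adapt a weights source in your own
    environment.
    """
    if not spec.resolved_tap_points:
        raise BackboneError("tap_points must be non-empty")
    if spec.weights == "pretrained":
        raise BackboneError(
            f"pretrained weights for {spec.name!r} are not available in this "
            "installation; use name='stub' (or vgg16 with "
            "weights='seeded_random') or supply a weights source"
        )
    if spec.name in ("stub", "vgg16"):
        return FrozenExtractor(spec)
    raise BackboneError(
        f"no bundled forward pass for {spec.name!r} with seeded_random weights; "
        "its tap registry entry (channel counts) is available via "
        "feature_dimension, but extraction requires name in {'stub', 'vgg16'}"
    )


def extract_features(
    handle: FrozenExtractor,
    image: np.ndarray,
    *,
    image_id: str = "",
    replicate: int = 0,
    crop_id: str = "train",
) -> FeatureVector:
    return FeatureVector(
        values=handle.extract(image),
        image_id=image_id,
        replicate=replicate,
        crop_id=crop_id,
    )


def save_features(
    path: str | Path,
    matrix: np.ndarray,
    meta_rows: list[dict],
    fingerprint: dict,
) -> None:
    """Compressed numeric container plus a JSON sidecar of row provenance."""
    path = Path(path)
    np.savez_compressed(path.with_suffix(".npz"), features=matrix)
    sidecar = {
        "tap_registry_version": TAP_REGISTRY_VERSION,
        "fingerprint": fingerprint,
        "rows": meta_rows,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1, sort_keys=True))


def load_features(path: str | Path) -> tuple[np.ndarray, list[dict], dict]:
    path = Path(path)
    matrix = np.load(path.with_suffix(".npz"))["features"]
    sidecar = json.loads(path.with_suffix(".json").read_text())
    return matrix, sidecar["rows"], sidecar["fingerprint"]
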