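"""Deep feature generation from frozen backbones.

Each of the 21 pyramid images is resized to a backbone's native input side,
channel-normalized, forward-passed, and the pre-softmax class-score (logits)
vector is kept.  The 21 per-image vectors are concatenated in pyramid order
into one case vector of width ``21 * output_dim`` (21,000 for the standard
ImageNet-pretrained networks, whose logits are 1000-wide).

Real backbones (MobileNetV2 and friends) are loaded lazily through
torchvision and are never required by the test suite: a seeded
random-projection stub extractor provides a deterministic, weight-free
drop-in with the same contract.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
from PIL import Image

from .dataset_io import DatasetManifest, resize_image
from .pyramid import PatchSet, build_pyramid

__all__ = [
    "BackboneExtractor",
    "BackboneLoadError",
    "FeatureMatrix",
    "extract_image_features",
    "concat_case_features",
    "extract_dataset",
    "make_stub_extractor",
    "get_backbone",
    "BACKBONE_NAMES",
    "save_feature_matrix",
    "load_feature_matrix",
]

IMAGENET_MEAN = (0.485, 0.456, 0.406)
IMAGENET_STD = (0.229, 0.224, 0.225)

#: torchvision constructor names for the supported ImageNet backbones.
_TORCHVISION_BACKBONES = {
    "mobilenet_v2": "mobilenet_v2",
    "alexnet": "alexnet",
    "densenet201": "densenet201",
    "googlenet": "googlenet",
    "vgg16": "vgg16",
    "resnet50": "resnet50",
    "squeezenet": "squeezenet1_1",
}

BACKBONE_NAMES = tuple(_TORCHVISION_BACKBONES)

_BACKBONE_INPUT_SIDE = {name: 224 for name in _TORCHVISION_BACKBONES}
_BACKBONE_INPUT_SIDE["alexnet"] = 227


class BackboneLoadError(RuntimeError):
    """Raised when pretrained weights or the torch runtime are unavailable."""


@dataclass
class BackboneExtractor:
    """A frozen feature extractor: image raster -> fixed-width score vector.

    ``forward`` receives a float32 array of shape (input_side, input_side, 3)
    that has already been resized and per-channel normalized, and must return
    a 1-D vector of exactly ``output_dim`` finite values, deterministically.
    """

    name: str
    input_side: int
    output_dim: int
    mean: tuple = IMAGENET_MEAN
    std: tuple = IMAGENET_STD
    forward: Callable[[np.ndarray], np.ndarray] = None  # type: ignore[assignment]


@dataclass
class FeatureMatrix:
    """n_cases x D feature matrix with column identity and labels attached.

    Column block for pyramid slot ``i`` (0-based) occupies columns
    ``i * output_dim`` .. ``(i + 1) * output_dim - 1``; ``column_origin`` holds
    one ``(pyramid_slot, within_backbone_index)`` pair per column.
    """

    values: np.ndarray
    labels: np.ndarray
    column_origin: np.ndarray | None = None
    case_ids: list | None = None

    @property
    def n_cases(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


def extract_image_features(extractor: BackboneExtractor, image: np.ndarray) -> np.ndarray:
    """Resize, normalize and forward one image; return the logits vector."""
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected HxWx3 image, got shape {img.shape}")
    resized = resize_image(img, extractor.input_side).astype(np.float32) / 255.0
    mean = np.asarray(extractor.mean, dtype=np.float32)
    std = np.asarray(extractor.std, dtype=np.float32)
    normalized = (resized - mean) / std
    vec = np.asarray(extractor.forward(normalized), dtype=np.float64).ravel()
    if vec.shape[0] != extractor.output_dim:
        raise RuntimeError(
            f"extractor {extractor.name!r} returned {vec.shape[0]} values, "
            f"expected {extractor.output_dim}"
        )
    if not np.all(np.isfinite(vec)):
        raise RuntimeError(f"extractor {extractor.name!r} returned non-finite values")
    return vec


def concat_case_features(extractor: BackboneExtractor, patchset: PatchSet) -> np.ndarray:
    """Concatenate per-image logits over the pyramid into one case vector.

    Slot ``i`` of the output (block of width ``output_dim``) holds the
    features of pyramid image ``i``, preserving pyramid order.
    """
    d = extractor.output_dim
    out = np.empty(len(patchset.images) * d, dtype=np.float64)
    for i, img in enumerate(patchset.images):
        out[i * d : (i + 1) * d] = extract_image_features(extractor, img)
    return out


def extract_dataset(
    extractor: BackboneExtractor,
    manifest: DatasetManifest,
    side: int = 512,
    pyramidal: bool = True,
) -> FeatureMatrix:
    """Extract the full feature matrix for a manifest, in manifest order.

    With ``pyramidal=False`` only the resized original image is embedded
    (one slot, width ``output_dim``), the non-pyramidal baseline.
    """
    n_slots = 21 if pyramidal else 1
    d = extractor.output_dim
    n = len(manifest.records)
    if n == 0:
        warnings.warn("extract_dataset called on an empty manifest")
    values = np.empty((n, n_slots * d), dtype=np.float64)
    labels = []
    case_ids = []
    for row, rec in enumerate(manifest.records):
        try:
            img = resize_image(rec.image, side)
            if pyramidal:
                ps = build_pyramid(img, case_id=rec.source_id, side=side)
                values[row] = concat_case_features(extractor, ps)
            else:
                values[row] = extract_image_features(extractor, img)
        except Exception as exc:
            raise RuntimeError(
                f"feature extraction failed for case {rec.source_id!r}: {exc}"
            ) from exc
        labels.append(rec.label)
        case_ids.append(rec.source_id)
    column_origin = np.stack(
        [np.repeat(np.arange(n_slots), d), np.tile(np.arange(d), n_slots)], axis=1
    )
    return FeatureMatrix(
        values=values,
        labels=np.asarray(labels, dtype=object),
        column_origin=column_origin,
        case_ids=case_ids,
    )


def make_stub_extractor(
    output_dim: int, seed: int = 0, grid_side: int = 32, name: str | None = None
) -> BackboneExtractor:
    """Deterministic weight-free extractor: downsample, flatten, project.

    The input is resized to a fixed ``grid_side`` square, flattened and
    multiplied by a seeded Gaussian projection matrix (columns scaled by
    1/sqrt(n_pixels)).  Two stubs with the same seed agree on every input;
    different seeds give different projections.
    """
    if output_dim < 1:
        raise ValueError(f"output_dim must be >= 1, got {output_dim}")
    rng = np.random.default_rng(seed)
    n_in = grid_side * grid_side * 3
    projection = rng.standard_normal((n_in, output_dim)) / np.sqrt(n_in)

    def forward(x: np.ndarray) -> np.ndarray:
        return x.ravel().astype(np.float64) @ projection

    return BackboneExtractor(
        name=name or f"stub{seed}",
        input_side=grid_side,
        output_dim=output_dim,
        mean=(0.5, 0.5, 0.5),
        std=(0.5, 0.5, 0.5),
        forward=forward,
    )


def get_backbone(name: str) -> BackboneExtractor:
    """Load a pretrained ImageNet backbone as a frozen logits extractor.

    Requires torch/torchvision and downloadable (or cached) weights; raises
    :class:`BackboneLoadError` otherwise — never a silent random init.
    """
    if name.startswith("stub"):
        seed = int(name[4:] or 0)
        return make_stub_extractor(output_dim=1000, seed=seed, name=name)
    if name == "darknet19":
        raise BackboneLoadError(
            "darknet19 has no torchvision port; choose another backbone"
        )
    if name not in _TORCHVISION_BACKBONES:
        raise BackboneLoadError(
            f"unknown backbone {name!r}; available: {sorted(BACKBONE_NAMES)}"
        )
    try:
        import torch
        import torchvision.models as tvm
    except ImportError as exc:
        raise BackboneLoadError(
            f"backbone {name!r} needs torch/torchvision, which are not installed; "
            "use a stub extractor instead"
        ) from exc
    try:
        model = getattr(tvm, _TORCHVISION_BACKBONES[name])(weights="IMAGENET1K_V1")
    except Exception as exc:
        raise BackboneLoadError(f"could not load pretrained weights for {name!r}: {exc}") from exc
    model.eval()

    def forward(x: np.ndarray) -> np.ndarray:
        with torch.no_grad():
            t = torch.from_numpy(np.ascontiguousarray(x.transpose(2, 0, 1))[None]).float()
            return model(t).numpy().ravel()

    return BackboneExtractor(
        name=name,
        input_side=_BACKBONE_INPUT_SIDE[name],
        output_dim=1000,
        forward=forward,
    )


def save_feature_matrix(fm: FeatureMatrix, prefix) -> tuple:
    """Persist as ``<prefix>.npy`` (values) + ``<prefix>.csv`` sidecar."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    npy = prefix.with_suffix(".npy")
    csv = prefix.with_suffix(".csv")
    np.save(npy, fm.values)
    side = pd.DataFrame({"label": fm.labels})
    if fm.case_ids is not None:
        side["case_id"] = fm.case_ids
    side.to_csv(csv, index=False)
    if fm.column_origin is not None:
        np.save(prefix.parent / (prefix.name + "_columns.npy"), fm.column_origin)
    return npy, csv


def load_feature_matrix(prefix) -> FeatureMatrix:
    prefix = Path(prefix)
    values = np.load(prefix.with_suffix(".npy"))
    side = pd.read_csv(prefix.with_suffix(".csv"))
    col_path = prefix.parent / (prefix.name + "_columns.npy")
    column_origin = np.load(col_path) if col_path.exists() else None
    case_ids = side["case_id"].tolist() if "case_id" in side else None
    return FeatureMatrix(
        values=values,
        labels=side["label"].to_numpy(dtype=object),
        column_origin=column_origin,
        case_ids=case_ids,
    )
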