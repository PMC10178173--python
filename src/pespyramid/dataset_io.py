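"""Two-class radiograph dataset handling.

Loads a directory of labeled JPEG/PNG images (one subdirectory per class),
resizes them to a square working resolution, applies seeded geometric
augmentation (rotation, isotropic scaling, mirroring) and balances class
counts by generating augmented copies of originals.  Every augmented record
carries a transform log that replays exactly, so the augmented dataset is a
pure function of the originals and the seed.
"""

from __future__ import annotations

import json
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image, UnidentifiedImageError

__all__ = [
    "ConfigurationError",
    "RadiographRecord",
    "DatasetManifest",
    "load_dataset",
    "save_manifest",
    "resize_image",
    "augment_geometric",
    "apply_transform",
    "replay_transforms",
    "balance_by_augmentation",
    "DEFAULT_AUGMENT_RANGES",
    "AUGMENT_OPS",
]

IMAGE_EXTENSIONS = {".jpg", ".jpeg", ".png"}

#: Augmentation parameter ranges.  The magnitudes are mild by design: the
#: class signal in a lateral foot radiograph is the arch geometry, which a
#: ±10 degree rotation or ±10% rescale perturbs without destroying.
DEFAULT_AUGMENT_RANGES = {
    "rotate": {"angle": (-10.0, 10.0)},
    "scale": {"factor": (0.9, 1.1)},
    "mirror": {"axis": ("horizontal",)},
}

AUGMENT_OPS = ("rotate", "scale", "mirror")


class ConfigurationError(ValueError):
    """Raised when the dataset directory layout or a config value is invalid."""


@dataclass
class RadiographRecord:
    """One labeled image plus its provenance.

    ``image`` is an H x W x 3 uint8 raster; ``label`` is the class tag taken
    from the directory name (e.g. ``normal`` / ``pes_planus``).  For augmented
    records ``transform_log`` lists the geometric ops (with parameters) that
    map the source original onto this image.
    """

    image: np.ndarray
    label: str
    source_id: str
    is_augmented: bool = False
    transform_log: list = field(default_factory=list)

    def __post_init__(self) -> None:
        img = np.asarray(self.image)
        if img.ndim != 3 or img.shape[2] != 3:
            raise ValueError(
                f"record {self.source_id!r}: image must be HxWx3, got shape {img.shape}"
            )
        if img.shape[0] < 1 or img.shape[1] < 1:
            raise ValueError(f"record {self.source_id!r}: empty image")
        if not self.is_augmented and self.transform_log:
            raise ValueError(
                f"record {self.source_id!r}: non-augmented record has a transform log"
            )
        self.image = img


@dataclass
class DatasetManifest:
    """Ordered collection of records plus a skip report from loading."""

    records: list = field(default_factory=list)
    skipped: list = field(default_factory=list)

    @property
    def class_counts(self) -> dict:
        return dict(Counter(r.label for r in self.records))

    def __len__(self) -> int:
        return len(self.records)


def load_dataset(root_dir) -> DatasetManifest:
    """Load a two-class image dataset laid out as ``root/<class>/*.{jpg,png}``.

    Records are ordered lexicographically by file path so that downstream fold
    assignment is reproducible.  Undecodable files are skipped with a warning
    and recorded in ``manifest.skipped``.
    """
    root = Path(root_dir)
    if not root.is_dir():
        raise ConfigurationError(f"dataset root {root} is not a directory")
    class_dirs = sorted(p for p in root.iterdir() if p.is_dir())
    if len(class_dirs) != 2:
        raise ConfigurationError(
            f"expected exactly 2 class subdirectories under {root}, "
            f"found {len(class_dirs)}: {[p.name for p in class_dirs]}"
        )

    manifest = DatasetManifest()
    for class_dir in class_dirs:
        files = sorted(
            p for p in class_dir.iterdir()
            if p.is_file() and p.suffix.lower() in IMAGE_EXTENSIONS
        )
        if not files:
            warnings.warn(f"class directory {class_dir} contains no images")
        n_before = len(manifest.records)
        for path in files:
            try:
                with Image.open(path) as im:
                    arr = np.asarray(im.convert("RGB"), dtype=np.uint8)
            except (UnidentifiedImageError, OSError) as exc:
                warnings.warn(f"skipping undecodable file {path}: {exc}")
                manifest.skipped.append(str(path))
                continue
            manifest.records.append(
                RadiographRecord(image=arr, label=class_dir.name, source_id=str(path))
            )
        if len(manifest.records) == n_before and not files:
            # empty class still appears in counts with 0 via explicit entry
            pass
    counts = manifest.class_counts
    for class_dir in class_dirs:
        counts.setdefault(class_dir.name, 0)
    # class_counts is computed from records; emptiness was already warned above
    return manifest


def save_manifest(manifest: DatasetManifest, root_dir) -> Path:
    """Write images as PNG under ``root/<label>/`` plus a ``manifest.csv``.

    The CSV has columns path, label, is_augmented, transform_log (JSON), so a
    saved manifest round-trips through :func:`load_dataset`.
    """
    root = Path(root_dir)
    root.mkdir(parents=True, exist_ok=True)
    rows = []
    per_class_counter: Counter = Counter()
    for rec in manifest.records:
        class_dir = root / rec.label
        class_dir.mkdir(exist_ok=True)
        idx = per_class_counter[rec.label]
        per_class_counter[rec.label] += 1
        path = class_dir / f"case_{idx:05d}.png"
        Image.fromarray(rec.image).save(path)
        rows.append(
            {
                "path": str(path),
                "label": rec.label,
                "is_augmented": rec.is_augmented,
                "transform_log": json.dumps(rec.transform_log),
            }
        )
    csv_path = root / "manifest.csv"
    pd.DataFrame(rows).to_csv(csv_path, index=False)
    return csv_path


def resize_image(image: np.ndarray, side: int) -> np.ndarray:
    """Resize to ``side x side x 3`` by bilinear interpolation.

    The image is stretched directly to the square target; aspect ratio is not
    preserved.  A same-size input is returned unchanged.
    """
    if side <= 0:
        raise ValueError(f"side must be positive, got {side}")
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3 or img.size == 0:
        raise ValueError(f"expected non-empty HxWx3 image, got shape {img.shape}")
    if img.shape[0] == side and img.shape[1] == side:
        return img.copy()
    out = Image.fromarray(img).resize((side, side), Image.BILINEAR)
    return np.asarray(out, dtype=np.uint8)


def _rotate(image: np.ndarray, angle: float) -> np.ndarray:
    if angle == 0:
        return image.copy()
    out = Image.fromarray(image).rotate(
        angle, resample=Image.BILINEAR, expand=False, fillcolor=(0, 0, 0)
    )
    return np.asarray(out, dtype=np.uint8)


def _scale(image: np.ndarray, factor: float) -> np.ndarray:
    if factor <= 0:
        raise ValueError(f"scale factor must be positive, got {factor}")
    if factor == 1.0:
        return image.copy()
    h, w = image.shape[:2]
    nh, nw = max(1, round(h * factor)), max(1, round(w * factor))
    scaled = np.asarray(
        Image.fromarray(image).resize((nw, nh), Image.BILINEAR), dtype=np.uint8
    )
    out = np.zeros_like(image)
    if factor > 1.0:  # center crop back to the original frame
        top, left = (nh - h) // 2, (nw - w) // 2
        out[:, :] = scaled[top : top + h, left : left + w]
    else:  # center pad with dark background
        top, left = (h - nh) // 2, (w - nw) // 2
        out[top : top + nh, left : left + nw] = scaled
    return out


def _mirror(image: np.ndarray, axis: str = "horizontal") -> np.ndarray:
    if axis == "horizontal":
        return image[:, ::-1].copy()
    if axis == "vertical":
        return image[::-1, :].copy()
    raise ValueError(f"unknown mirror axis {axis!r}")


def apply_transform(image: np.ndarray, op_name: str, params: dict) -> np.ndarray:
    """Apply one named geometric op; output frame equals the input frame."""
    if op_name == "rotate":
        return _rotate(image, float(params["angle"]))
    if op_name == "scale":
        return _scale(image, float(params["factor"]))
    if op_name == "mirror":
        return _mirror(image, params.get("axis", "horizontal"))
    raise ValueError(f"unknown augmentation op {op_name!r}")


def replay_transforms(image: np.ndarray, transform_log: list) -> np.ndarray:
    """Re-apply a record's transform log to its source image."""
    out = image
    for entry in transform_log:
        out = apply_transform(out, entry["op"], entry["params"])
    return out


def _draw_params(op_name: str, rng: np.random.Generator, ranges: dict) -> dict:
    spec = ranges[op_name]
    if op_name == "rotate":
        lo, hi = spec["angle"]
        return {"angle": float(rng.uniform(lo, hi))}
    if op_name == "scale":
        lo, hi = spec["factor"]
        return {"factor": float(rng.uniform(lo, hi))}
    if op_name == "mirror":
        axes = spec["axis"]
        return {"axis": axes[int(rng.integers(len(axes)))]}
    raise ValueError(f"unknown augmentation op {op_name!r}")


def augment_geometric(
    record: RadiographRecord,
    op_name: str,
    params: dict | None = None,
    rng_seed: int = 0,
    ranges: dict | None = None,
) -> RadiographRecord:
    """Return an augmented copy of ``record`` with one geometric op applied.

    If ``params`` is None the parameters are drawn from the configured ranges
    using ``rng_seed`` (byte-identical across runs for a fixed seed).
    """
    if op_name not in AUGMENT_OPS:
        raise ValueError(f"unknown augmentation op {op_name!r}; choose from {AUGMENT_OPS}")
    if params is None:
        rng = np.random.default_rng(rng_seed)
        params = _draw_params(op_name, rng, ranges or DEFAULT_AUGMENT_RANGES)
    image = apply_transform(record.image, op_name, params)
    return RadiographRecord(
        image=image,
        label=record.label,
        source_id=record.source_id,
        is_augmented=True,
        transform_log=list(record.transform_log) + [{"op": op_name, "params": params}],
    )


def balance_by_augmentation(
    manifest: DatasetManifest,
    target_per_class: int,
    rng_seed: int = 0,
    ranges: dict | None = None,
) -> DatasetManifest:
    """Grow every class to exactly ``target_per_class`` records.

    Originals are all retained; new records are produced by cycling over each
    class's originals in manifest order and applying one randomly drawn op
    (rotate / scale / mirror) per generated record.  Fully deterministic given
    ``rng_seed``.  Subsampling is never performed: a target below an existing
    class count is an error.
    """
    if target_per_class <= 0:
        raise ValueError("target_per_class must be positive")
    counts = manifest.class_counts
    over = {c: n for c, n in counts.items() if n > target_per_class}
    if over:
        raise ValueError(
            f"target_per_class={target_per_class} is below existing class counts {over}; "
            "subsampling is not supported"
        )
    rng = np.random.default_rng(rng_seed)
    out = DatasetManifest(records=list(manifest.records), skipped=list(manifest.skipped))
    for label in sorted(counts):
        originals = [r for r in manifest.records if r.label == label]
        deficit = target_per_class - len(originals)
        for i in range(deficit):
            src = originals[i % len(originals)]
            op = AUGMENT_OPS[int(rng.integers(len(AUGMENT_OPS)))]
            params = _draw_params(op, rng, ranges or DEFAULT_AUGMENT_RANGES)
            aug = augment_geometric(src, op, params=params)
            aug.source_id = f"{src.source_id}#aug{i}"
            out.records.append(aug)
    return out
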