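"""Synthetic test inputs with known structure.

Two generators:

* **Phantom radiographs** — geometric cartoons of a weight-bearing lateral
  foot X-ray: a dark noisy background with a bright bone-like polyline whose
  inferior arc angle (a proxy for the calcaneal inclination angle) is drawn
  from a per-class Gaussian.  Flatfoot phantoms get a shallow arc, normal
  phantoms a steep one; the default means (15 vs 25 degrees, SD 3) straddle
  the 18-degree diagnostic boundary used clinically.  Angles are truncated to
  their class's side of the midpoint so that a single threshold on the
  generated angle reproduces the labels exactly.

* **Labeled feature matrices** — n x D Gaussian matrices with q informative
  columns whose class means are separated by a standardized shift delta, the
  rest pure noise; the informative index set is returned for recovery tests.

Both are pure functions of their spec (seed included).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset_io import DatasetManifest, RadiographRecord
from .features import FeatureMatrix

__all__ = [
    "PhantomSpec",
    "SyntheticFeatureSpec",
    "generate_phantoms",
    "generate_feature_matrix",
]

LABEL_FLAT = "pes_planus"
LABEL_NORMAL = "normal"


@dataclass
class PhantomSpec:
    """Parameters of the phantom generator.

    ``angle_mean_flat`` / ``angle_mean_normal`` are the per-class mean arc
    angles in degrees; their difference is the class separation.  ``noise_sd``
    is the additive Gaussian pixel noise SD on the 0-255 scale.
    """

    n_per_class: int = 20
    side: int = 512
    angle_mean_flat: float = 15.0
    angle_mean_normal: float = 25.0
    angle_sd: float = 3.0
    noise_sd: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if self.side < 32:
            raise ValueError("side must be >= 32")
        if self.angle_sd < 0 or self.noise_sd < 0:
            raise ValueError("standard deviations must be non-negative")


@dataclass
class SyntheticFeatureSpec:
    """Parameters of the labeled feature-matrix generator."""

    n_per_class: int = 100
    n_features: int = 50
    n_informative: int = 5
    delta: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.n_informative <= self.n_features:
            raise ValueError("need 0 <= n_informative <= n_features")
        if self.delta < 0:
            raise ValueError("delta must be >= 0")


def _thick_segment(canvas: np.ndarray, p0, p1, width: float, intensity: float) -> None:
    """Add a bright bar of the given half-width between two points."""
    side = canvas.shape[0]
    yy, xx = np.mgrid[0:side, 0:side]
    p0 = np.asarray(p0, dtype=np.float64)
    p1 = np.asarray(p1, dtype=np.float64)
    d = p1 - p0
    norm2 = float(d @ d)
    if norm2 == 0:
        return
    # distance from each pixel to the segment
    t = ((xx - p0[0]) * d[0] + (yy - p0[1]) * d[1]) / norm2
    t = np.clip(t, 0.0, 1.0)
    px = p0[0] + t * d[0]
    py = p0[1] + t * d[1]
    dist = np.hypot(xx - px, yy - py)
    profile = intensity * np.clip(1.0 - dist / width, 0.0, 1.0)
    np.maximum(canvas, profile, out=canvas)


def _draw_phantom(side: int, angle_deg: float, rng: np.random.Generator,
                  noise_sd: float) -> np.ndarray:
    """Render one foot phantom whose inferior arc angle is ``angle_deg``."""
    canvas = np.zeros((side, side), dtype=np.float64)
    s = side / 512.0
    base_y = 420.0 * s
    heel = np.array([90.0 * s, base_y])
    forefoot = np.array([430.0 * s, base_y])
    # arch apex: rises from the heel along the arc angle toward midfoot
    theta = np.radians(angle_deg)
    run = 170.0 * s
    apex = heel + np.array([run * np.cos(theta), -run * np.sin(theta)])
    width = 16.0 * s
    _thick_segment(canvas, heel, apex, width, 190.0)        # calcaneal line
    _thick_segment(canvas, apex, forefoot, width, 190.0)    # midfoot to forefoot
    _thick_segment(canvas, heel, heel + np.array([0, -60.0 * s]), 14.0 * s, 160.0)  # ankle
    # calcaneus blob
    yy, xx = np.mgrid[0:side, 0:side]
    blob = 120.0 * np.exp(-(((xx - heel[0]) ** 2 + (yy - heel[1]) ** 2) / (2 * (22.0 * s) ** 2)))
    np.maximum(canvas, blob, out=canvas)
    img = 18.0 + canvas + rng.normal(0.0, noise_sd, size=canvas.shape)
    img = np.clip(img, 0, 255).astype(np.uint8)
    return np.repeat(img[:, :, None], 3, axis=2)


def _truncated_angle(rng: np.random.Generator, mean: float, sd: float,
                     midpoint: float, keep_low: bool) -> float:
    """Draw an angle from N(mean, sd), truncated to its class's side of the
    midpoint so the class rule stays exactly threshold-recoverable."""
    for _ in range(200):
        a = float(rng.normal(mean, sd))
        if keep_low and a < midpoint:
            return a
        if not keep_low and a > midpoint:
            return a
    return mean  # degenerate sd; fall back to the class mean


def generate_phantoms(spec: PhantomSpec) -> tuple:
    """Generate a two-class phantom manifest; returns (manifest, angles).

    Records come in class blocks (flatfoot first) with deterministic ids;
    ``angles`` is the per-record generated arc angle, the ground truth a
    threshold test can check against the labels.
    """
    rng = np.random.default_rng(spec.seed)
    manifest = DatasetManifest()
    angles = []
    separated = spec.angle_mean_flat != spec.angle_mean_normal
    midpoint = 0.5 * (spec.angle_mean_flat + spec.angle_mean_normal)
    flat_is_low = spec.angle_mean_flat < spec.angle_mean_normal
    for label, mean in ((LABEL_FLAT, spec.angle_mean_flat),
                        (LABEL_NORMAL, spec.angle_mean_normal)):
        for i in range(spec.n_per_class):
            if separated:
                keep_low = flat_is_low == (label == LABEL_FLAT)
                angle = _truncated_angle(rng, mean, spec.angle_sd, midpoint, keep_low)
            else:
                angle = float(rng.normal(mean, spec.angle_sd))
            img = _draw_phantom(spec.side, angle, rng, spec.noise_sd)
            manifest.records.append(
                RadiographRecord(image=img, label=label,
                                 source_id=f"{label}/phantom_{i:04d}")
            )
            angles.append(angle)
    return manifest, np.asarray(angles)


def generate_feature_matrix(spec: SyntheticFeatureSpec) -> tuple:
    """Generate (FeatureMatrix, informative_column_indices).

    Informative columns are N(-delta/2, 1) in one class and N(+delta/2, 1)
    in the other; noise columns are N(0, 1) in both.  Informative column
    positions are a seeded permutation so ranking tests cannot cheat on
    column order.
    """
    rng = np.random.default_rng(spec.seed)
    n, d, q = 2 * spec.n_per_class, spec.n_features, spec.n_informative
    X = rng.standard_normal((n, d))
    labels = np.asarray([LABEL_FLAT] * spec.n_per_class + [LABEL_NORMAL] * spec.n_per_class,
                        dtype=object)
    informative = np.sort(rng.permutation(d)[:q])
    X[: spec.n_per_class, informative] -= spec.delta / 2.0
    X[spec.n_per_class :, informative] += spec.delta / 2.0
    fm = FeatureMatrix(
        values=X,
        labels=labels,
        column_origin=None,
        case_ids=[f"synth_{i:04d}" for i in range(n)],
    )
    return fm, informative
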