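"""Pyramidal patch tiling.

A resized radiograph is expanded into an ordered 21-image pyramid: the
512x512 original, its 4 non-overlapping 256x256 quadrants (2x2 grid) and its
16 non-overlapping 128x128 tiles (4x4 grid).  Tiles are ordered row-major
(top-left first, rows before columns) and at each level jointly cover the
original exactly, so reassembly is pixel-exact.  The ordering is a
convention: it only fixes which feature columns a patch occupies downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = ["PatchSet", "tile", "build_pyramid", "export_patches", "PYRAMID_GRIDS"]

#: Grid subdivisions per pyramid level: the original, then 2x2, then 4x4.
PYRAMID_GRIDS = (1, 2, 4)


@dataclass
class PatchSet:
    """The ordered 21-image pyramid for one case.

    ``images[0]`` is the side x side original; ``images[1:5]`` the 2x2 tiles;
    ``images[5:21]`` the 4x4 tiles, each list row-major.
    """

    images: list = field(default_factory=list)
    case_id: str = ""
    sizes: tuple = (512, 256, 128)

    def __len__(self) -> int:
        return len(self.images)


def tile(image: np.ndarray, grid_n: int) -> list:
    """Split a square S x S x 3 image into ``grid_n**2`` row-major tiles.

    Each tile is a pixel-exact crop of size (S/grid_n) x (S/grid_n) x 3;
    ``grid_n`` must divide S.
    """
    img = np.asarray(image)
    if grid_n < 1:
        raise ValueError(f"grid_n must be >= 1, got {grid_n}")
    if img.ndim != 3 or img.shape[2] != 3 or img.shape[0] != img.shape[1]:
        raise ValueError(f"expected square SxSx3 image, got shape {img.shape}")
    side = img.shape[0]
    if side % grid_n != 0:
        raise ValueError(f"grid_n={grid_n} does not divide image side {side}")
    p = side // grid_n
    return [
        img[r * p : (r + 1) * p, c * p : (c + 1) * p].copy()
        for r in range(grid_n)
        for c in range(grid_n)
    ]


def build_pyramid(image: np.ndarray, case_id: str = "", side: int = 512) -> PatchSet:
    """Build the 21-image pyramid [original, 2x2 tiles, 4x4 tiles].

    The input must already be exactly ``side x side x 3``; resizing is the
    caller's responsibility so that patch geometry is unambiguous.
    """
    img = np.asarray(image)
    if img.shape != (side, side, 3):
        raise ValueError(
            f"build_pyramid expects a {side}x{side}x3 image, got shape {img.shape}; "
            "resize first"
        )
    images = [img.copy()]
    for grid_n in PYRAMID_GRIDS[1:]:
        images.extend(tile(img, grid_n))
    sizes = tuple(side // g for g in PYRAMID_GRIDS)
    return PatchSet(images=images, case_id=case_id, sizes=sizes)


def export_patches(patchset: PatchSet, out_dir) -> list:
    """Debug export: write every pyramid image as ``<case>_L<level>_<row>_<col>.png``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    i = 0
    for level, grid_n in enumerate(PYRAMID_GRIDS, start=1):
        for r in range(grid_n):
            for c in range(grid_n):
                path = out / f"{patchset.case_id}_L{level}_{r}_{c}.png"
                Image.fromarray(patchset.images[i]).save(path)
                paths.append(path)
                i += 1
    return paths
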