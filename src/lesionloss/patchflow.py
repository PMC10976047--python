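"""Sliding-window patch extraction and overlap-averaged reconstruction.

Training and inference operate on fixed-size 3D patches (default 32^3)
taken on a stride-16 sliding window over the brain bounding box, so that
most sampled voxels belong to the brain.  Conventions:

* coordinates are 0-based and windows are half-open ``[o, o + size)``;
* the last origin on each axis is clamped to ``hi - size`` so the grid
  covers the box completely even when the extent is not a multiple of the
  stride;
* training keeps only lesion-containing windows; evaluation uses every
  window and averages overlapping predictions voxelwise.

Boxes narrower than the patch on some axis are handled by centring a single
window on that axis; extraction zero-pads where the window leaves the
volume, and reconstruction ignores out-of-volume voxels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Sequence, Tuple

import nibabel as nib
import numpy as np

__all__ = [
    "BoundingBox",
    "PatchGrid",
    "bounding_box",
    "patch_grid",
    "filter_lesion_patches",
    "make_batches",
    "extract_patch",
    "extract_patches",
    "reconstruct",
    "read_nifti",
    "write_nifti_like",
]

Origin = Tuple[int, int, int]


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned half-open box ``[lo, hi)`` in voxel indices."""

    lo: Tuple[int, int, int]
    hi: Tuple[int, int, int]

    def __post_init__(self) -> None:
        if len(self.lo) != 3 or len(self.hi) != 3:
            raise ValueError("bounding box must be 3D")
        if any(h <= l for l, h in zip(self.lo, self.hi)):
            raise ValueError("bounding box must have hi > lo on every axis")

    @property
    def extent(self) -> Tuple[int, int, int]:
        return tuple(h - l for l, h in zip(self.lo, self.hi))


@dataclass(frozen=True)
class PatchGrid:
    """Sorted unique origins of equally sized windows."""

    origins: Tuple[Origin, ...]
    patch_size: int = 32
    stride: int = 16

    def __post_init__(self) -> None:
        if list(self.origins) != sorted(set(self.origins)):
            raise ValueError("origins must be unique and lexicographically sorted")

    def __len__(self) -> int:
        return len(self.origins)


def bounding_box(mask) -> BoundingBox:
    """Tightest axis-aligned box containing all nonzero voxels of a 3D mask."""
    m = np.asarray(mask)
    if m.ndim != 3:
        raise ValueError("mask must be 3D")
    nz = np.nonzero(m)
    if nz[0].size == 0:
        raise ValueError("cannot take the bounding box of an empty mask")
    lo = tuple(int(idx.min()) for idx in nz)
    hi = tuple(int(idx.max()) + 1 for idx in nz)
    return BoundingBox(lo=lo, hi=hi)


def _axis_origins(lo: int, hi: int, size: int, stride: int) -> List[int]:
    extent = hi - lo
    if extent < size:
        # single window centred on the short axis; may leave the box
        return [lo - (size - extent) // 2]
    last = hi - size
    origins = list(range(lo, last + 1, stride))
    if origins[-1] != last:
        origins.append(last)  # clamp so coverage reaches hi
    return origins


def patch_grid(box: BoundingBox, size: int = 32, stride: int = 16) -> PatchGrid:
    """All window origins covering a box with the given size and stride."""
    if size < 1 or stride < 1:
        raise ValueError("size and stride must be >= 1")
    per_axis = [_axis_origins(l, h, size, stride) for l, h in zip(box.lo, box.hi)]
    origins = tuple(
        (i, j, k) for i in per_axis[0] for j in per_axis[1] for k in per_axis[2]
    )
    return PatchGrid(origins=origins, patch_size=size, stride=stride)


def _window(volume: np.ndarray, origin: Origin, size: int) -> np.ndarray:
    """Read a half-open window, zero-padding outside the volume."""
    out = np.zeros((size,) * 3, dtype=volume.dtype)
    src, dst = [], []
    for ax, o in enumerate(origin):
        lo = max(o, 0)
        hi = min(o + size, volume.shape[ax])
        if hi <= lo:
            return out
        src.append(slice(lo, hi))
        dst.append(slice(lo - o, hi - o))
    out[tuple(dst)] = volume[tuple(src)]
    return out


def extract_patch(volume, origin: Origin, size: int = 32) -> np.ndarray:
    """Extract one window from a 3D volume (or stack of C 3D channels)."""
    v = np.asarray(volume)
    if v.ndim == 3:
        return _window(v, origin, size)
    if v.ndim == 4:
        return np.stack([_window(c, origin, size) for c in v])
    raise ValueError("volume must be 3D or (C, D, H, W)")


def extract_patches(volume, origins: Iterable[Origin], size: int = 32) -> np.ndarray:
    """Stack windows at each origin into a (n, [C,] size, size, size) array."""
    return np.stack([extract_patch(volume, o, size) for o in origins])


def filter_lesion_patches(grid: PatchGrid, lesion_mask) -> PatchGrid:
    """Keep only windows containing at least one lesion voxel."""
    m = np.asarray(lesion_mask)
    kept = tuple(
        o for o in grid.origins
        if _window(m, o, grid.patch_size).any()
    )
    return PatchGrid(origins=kept, patch_size=grid.patch_size, stride=grid.stride)


def make_batches(items: Sequence, batch_size: int = 16,
                 seed: int = 0) -> List[List]:
    """Deterministically shuffle items under seed, then group consecutively.

    The last group may be smaller than ``batch_size``.  Identical seeds give
    identical orderings.  Accepts a PatchGrid (its origins are batched) or
    any sequence.
    """
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    seq = list(items.origins) if isinstance(items, PatchGrid) else list(items)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(seq))
    shuffled = [seq[i] for i in order]
    return [shuffled[i:i + batch_size] for i in range(0, len(shuffled), batch_size)]


def reconstruct(patch_preds: Iterable[Tuple[Origin, np.ndarray]],
                volume_shape: Tuple[int, int, int]) -> np.ndarray:
    """Overlap-averaged reconstruction of a full volume from window
    predictions: each voxel is the arithmetic mean of every window value
    covering it; uncovered voxels are 0."""
    acc = np.zeros(volume_shape, dtype=np.float64)
    cnt = np.zeros(volume_shape, dtype=np.int64)
    for origin, patch in patch_preds:
        patch = np.asarray(patch)
        if patch.ndim == 4 and patch.shape[0] == 1:
            patch = patch[0]
        if patch.ndim != 3:
            raise ValueError("patch predictions must be 3D (single channel)")
        size = patch.shape
        src, dst = [], []
        ok = True
        for ax, o in enumerate(origin):
            lo, hi = max(o, 0), min(o + size[ax], volume_shape[ax])
            if hi <= lo:
                ok = False
                break
            dst.append(slice(lo, hi))
            src.append(slice(lo - o, hi - o))
        if not ok:
            continue
        acc[tuple(dst)] += patch[tuple(src)]
        cnt[tuple(dst)] += 1
    covered = cnt > 0
    acc[covered] /= cnt[covered]
    return acc


# ---------------------------------------------------------------------------
# NIfTI helpers
# ---------------------------------------------------------------------------

def read_nifti(path):
    """Load a NIfTI volume; returns (float64 data array, image object)."""
    img = nib.load(str(path))
    return np.asarray(img.get_fdata(), dtype=np.float64), img


def write_nifti_like(data, like: nib.Nifti1Image, path) -> None:
    """Write data with the affine/header of an existing image propagated."""
    out = nib.Nifti1Image(np.asarray(data), like.affine, like.header)
    nib.save(out, str(path))
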