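"""Core data types for binary label images and rater stacks.

A *label image* is a binary (0/1) raster on a 2D or 3D rectangular grid; a
*rater set* is an ordered stack of K such images of the same scene, one per
rater (a human expert or an automated segmentation).  Fusion algorithms
operate on the *disputed* elements only — pixels/voxels where at least two
raters disagree; unanimous elements bypass fusion and keep their common
label.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np


class GeometryError(ValueError):
    """Raised when images that must share a grid do not."""


def _as_binary(values: np.ndarray) -> np.ndarray:
    arr = np.asarray(values)
    if arr.ndim not in (2, 3):
        raise ValueError(f"label grid must be 2D or 3D, got {arr.ndim}D")
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("label values must be exactly 0 or 1")
    return arr.astype(np.int8, copy=False)


@dataclass(frozen=True)
class LabelImage:
    """A binary segmentation label on a rectangular grid.

    Parameters
    ----------
    values : ndarray of {0, 1}, 2D or 3D
        Per-element label; 1 marks the segmented object (foreground).
    spacing : tuple of float
        Element size along each axis, arbitrary units.  All fusion math is
        index-based; spacing is metadata for the simulators and file I/O.
    origin : tuple of float
        World coordinate of the first element.
    """

    values: np.ndarray
    spacing: tuple = None
    origin: tuple = None

    def __post_init__(self):
        object.__setattr__(self, "values", _as_binary(self.values))
        nd = self.values.ndim
        sp = self.spacing if self.spacing is not None else (1.0,) * nd
        og = self.origin if self.origin is not None else (0.0,) * nd
        if len(sp) != nd or len(og) != nd:
            raise ValueError("spacing/origin must have one entry per axis")
        object.__setattr__(self, "spacing", tuple(float(s) for s in sp))
        object.__setattr__(self, "origin", tuple(float(o) for o in og))

    @property
    def shape(self) -> tuple:
        return self.values.shape

    @property
    def ndim(self) -> int:
        return self.values.ndim

    @property
    def size(self) -> int:
        return self.values.size

    @property
    def foreground_size(self) -> int:
        """Number of foreground elements (|Z| in area/volume terms)."""
        return int(self.values.sum())

    def same_grid(self, other: "LabelImage") -> bool:
        return (
            self.shape == other.shape
            and self.spacing == other.spacing
            and self.origin == other.origin
        )

    def with_values(self, values: np.ndarray) -> "LabelImage":
        return LabelImage(values, self.spacing, self.origin)

    def __eq__(self, other):
        if not isinstance(other, LabelImage):
            return NotImplemented
        return self.same_grid(other) and np.array_equal(self.values, other.values)


@dataclass(frozen=True)
class RaterSet:
    """Ordered stack of K binary labels of one scene on a common grid."""

    raters: tuple

    def __post_init__(self):
        raters = tuple(self.raters)
        if len(raters) < 1:
            raise ValueError("need at least one rater")
        ref = raters[0]
        for r in raters[1:]:
            if not ref.same_grid(r):
                raise GeometryError("all raters must share shape/spacing/origin")
        object.__setattr__(self, "raters", raters)

    @property
    def K(self) -> int:
        return len(self.raters)

    @property
    def grid(self) -> LabelImage:
        return self.raters[0]

    def stack(self) -> np.ndarray:
        """Decision matrix as a (K, *shape) int8 array."""
        return np.stack([r.values for r in self.raters])

    def __iter__(self):
        return iter(self.raters)

    def __len__(self):
        return len(self.raters)

    def __getitem__(self, k):
        return self.raters[k]


@dataclass(frozen=True)
class DisputedMask:
    """Partition of the grid into disputed and unanimous elements.

    ``mask`` is True where at least two raters disagree; ``unanimous_label``
    carries the common label everywhere the mask is False (its values under
    the mask are irrelevant and set to 0).
    """

    mask: np.ndarray
    unanimous_label: LabelImage

    @property
    def n_disputed(self) -> int:
        return int(self.mask.sum())

    @property
    def disputed_indices(self):
        return np.nonzero(self.mask)


def compute_disputed_mask(raters: RaterSet) -> DisputedMask:
    """Find elements where the raters disagree.

    Unanimous elements keep the common label; disputed ones are flagged for
    the fusion algorithm.
    """
    stack = raters.stack()
    mask = stack.min(axis=0) != stack.max(axis=0)
    unanimous = np.where(mask, 0, stack[0]).astype(np.int8)
    return DisputedMask(mask=mask, unanimous_label=raters.grid.with_values(unanimous))


def assemble_fusion(disputed: DisputedMask, fused_disputed_labels: np.ndarray) -> LabelImage:
    """Recombine unanimous labels with fused labels on the disputed elements."""
    fused = np.asarray(fused_disputed_labels)
    if fused.shape != (disputed.n_disputed,):
        raise ValueError(
            f"expected {disputed.n_disputed} disputed labels, got {fused.shape}"
        )
    out = disputed.unanimous_label.values.copy()
    out[disputed.mask] = fused
    return disputed.unanimous_label.with_values(out)


# ---------------------------------------------------------------------------
# File I/O: NIfTI-1 for volumes (and optionally 2D), single-channel PNG for 2D.

def read_label(path: str | os.PathLike) -> LabelImage:
    """Read a binary label from NIfTI (.nii/.nii.gz) or PNG.

    PNG values may be coded 0/1 or 0/255; anything else, or any non-binary
    NIfTI voxel value, is a hard error — no silent thresholding.
    """
    path = os.fspath(path)
    if path.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        img = nib.load(path)
        data = np.asanyarray(img.dataobj)
        data = np.squeeze(data)
        vals = np.unique(data)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError(f"non-binary label values in {path}: {vals[:10]}")
        zooms = img.header.get_zooms()[: data.ndim]
        return LabelImage(data.astype(np.int8), spacing=tuple(zooms))
    if path.endswith(".png"):
        import imageio.v3 as iio

        data = iio.imread(path)
        if data.ndim != 2:
            raise ValueError(f"expected single-channel PNG, got shape {data.shape}")
        vals = set(np.unique(data).tolist())
        if vals <= {0, 1}:
            return LabelImage(data.astype(np.int8))
        if vals <= {0, 255}:
            return LabelImage((data > 0).astype(np.int8))
        raise ValueError(f"non-binary PNG values in {path}: {sorted(vals)[:10]}")
    raise ValueError(f"unsupported label format: {path}")


def write_label(label: LabelImage, path: str | os.PathLike) -> None:
    """Write a label to NIfTI or PNG (2D only for PNG, coded 0/255)."""
    path = os.fspath(path)
    if path.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        affine = np.diag(list(label.spacing) + [1.0] * (4 - label.ndim))
        img = nib.Nifti1Image(label.values.astype(np.uint8), affine)
        nib.save(img, path)
    elif path.endswith(".png"):
        import imageio.v3 as iio

        if label.ndim != 2:
            raise ValueError("PNG output is for 2D labels only")
        iio.imwrite(path, label.values.astype(np.uint8) * 255)
    else:
        raise ValueError(f"unsupported label format: {path}")
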