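"""4D EPI image and segmentation-label containers with NIfTI I/O.

An :class:`Image4D` carries a magnitude EPI time series (X, Y, Z, T) together
with its repetition time (TR, seconds per volume), voxel size and spatial
affine.  A :class:`LabelMap` carries an integer segmentation aligned to the
image, mapping labels to region names (``csf``, ``cgm``, ``cwm``, ...).
Segmentation itself is external; these types only transport its output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = ["Image4D", "LabelMap", "DEFAULT_LABEL_SCHEME", "load_image4d", "load_labelmap"]

#: Conventional label scheme: 0 is background ("other").
DEFAULT_LABEL_SCHEME = {1: "csf", 2: "cgm", 3: "cwm"}


@dataclass
class Image4D:
    """A 4D magnitude EPI time series.

    Parameters
    ----------
    data
        Array of shape (X, Y, Z, T), arbitrary units, non-negative and finite.
    tr
        Repetition time in seconds per volume; the temporal sampling interval.
    voxel_size
        Voxel edge lengths in mm (3-tuple).
    affine
        4x4 voxel-to-world transform.
    """

    data: np.ndarray
    tr: float
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"Image4D data must be 4D, got shape {self.data.shape}")
        if self.data.shape[-1] < 2:
            raise ValueError("Image4D needs at least 2 time points")
        if not self.tr > 0:
            raise ValueError(f"TR must be positive, got {self.tr}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("Image4D data contains non-finite values")
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[-1]

    @property
    def duration(self) -> float:
        """Scan duration in seconds (T * TR)."""
        return self.n_volumes * self.tr

    def to_nifti(self) -> nib.Nifti1Image:
        img = nib.Nifti1Image(np.asarray(self.data, dtype=np.float32), self.affine)
        img.header.set_zooms((*self.voxel_size, self.tr))
        return img

    def save(self, path) -> None:
        nib.save(self.to_nifti(), str(path))


@dataclass
class LabelMap:
    """Integer segmentation aligned to an :class:`Image4D`; 0 is background."""

    labels: np.ndarray
    scheme: dict[int, str] = field(default_factory=lambda: dict(DEFAULT_LABEL_SCHEME))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"LabelMap must be 3D, got shape {self.labels.shape}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("LabelMap labels must be integers")
        if self.labels.min() < 0:
            raise ValueError("LabelMap labels must be non-negative")

    def region_mask(self, region: str) -> np.ndarray:
        """Boolean mask of the named region."""
        matching = [lab for lab, name in self.scheme.items() if name == region]
        if not matching:
            raise KeyError(f"unknown region {region!r}; known: {sorted(set(self.scheme.values()))}")
        return np.isin(self.labels, matching)

    def brain_mask(self) -> np.ndarray:
        """All non-background voxels."""
        return self.labels > 0

    def to_nifti(self, affine: np.ndarray | None = None) -> nib.Nifti1Image:
        return nib.Nifti1Image(np.asarray(self.labels, dtype=np.int16),
                               np.eye(4) if affine is None else affine)

    def save(self, path, affine: np.ndarray | None = None) -> None:
        nib.save(self.to_nifti(affine), str(path))


def load_image4d(path, tr: float | None = None) -> Image4D:
    """Load a 4D NIfTI.

    ``tr`` given explicitly is authoritative; otherwise it is read from the
    NIfTI time-axis pixdim (must be positive there).
    """
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata())
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4D image, got shape {data.shape}")
    zooms = img.header.get_zooms()
    if tr is None:
        tr = float(zooms[3]) if len(zooms) > 3 else 0.0
        if not tr > 0:
            raise ValueError(f"{path}: TR not stored in header; pass tr explicitly")
    return Image4D(data=data, tr=float(tr),
                   voxel_size=tuple(float(z) for z in zooms[:3]),
                   affine=np.asarray(img.affine))


def load_labelmap(path, scheme: dict[int, str] | None = None) -> LabelMap:
    """Load an integer label NIfTI."""
    img = nib.load(str(path))
    labels = np.asarray(img.get_fdata()).astype(np.int32)
    return LabelMap(labels=labels, scheme=scheme or dict(DEFAULT_LABEL_SCHEME))
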