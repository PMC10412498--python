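"""Time-resolved voxel images (the Cine-MRI stand-in) and NIfTI I/O.

A :class:`VoxelSeries` is a scalar grid per frame on an axis-aligned,
anisotropically spaced lattice: in-plane resolution is typically 1 mm while
the cross-slice spacing of a short-axis stack is 8 mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["VoxelSeries"]


@dataclass
class VoxelSeries:
    """Scalar image stack over time.

    Attributes
    ----------
    values : (T, nx, ny, nz) array
        One 3-D scalar grid per frame.
    spacing : (3,) array, mm
        Voxel spacing per axis (strictly positive).
    origin : (3,) array, mm
        Physical position of voxel (0, 0, 0).
    times : (T,) array, s
        Frame times.
    """

    values: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    times: np.ndarray = field(default_factory=lambda: np.zeros(1))

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 3:
            self.values = self.values[None]
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        self.times = np.atleast_1d(np.asarray(self.times, dtype=float))
        if np.any(self.spacing <= 0):
            raise ValueError("voxel spacing must be strictly positive")
        if len(self.times) != self.values.shape[0]:
            raise ValueError("one frame time per frame required")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.values.shape[1:]

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Physical coordinates of voxel centers along each axis."""
        return tuple(
            self.origin[k] + self.spacing[k] * np.arange(self.values.shape[1 + k])
            for k in range(3)
        )

    def affine(self) -> np.ndarray:
        A = np.eye(4)
        A[:3, :3] = np.diag(self.spacing)
        A[:3, 3] = self.origin
        return A

    def to_nifti(self, path: str) -> None:
        """Write as 4-D NIfTI (frames on the last axis)."""
        import nibabel as nib

        data = np.moveaxis(self.values, 0, -1)
        img = nib.Nifti1Image(np.ascontiguousarray(data), self.affine())
        zooms = tuple(self.spacing) + (
            float(self.times[1] - self.times[0]) if self.n_frames > 1 else 1.0,
        )
        img.header.set_zooms(zooms)
        nib.save(img, path)

    @classmethod
    def from_nifti(cls, path: str, times: np.ndarray | None = None) -> "VoxelSeries":
        import nibabel as nib

        img = nib.load(path)
        data = np.asanyarray(img.dataobj, dtype=float)
        if data.ndim == 3:
            data = data[..., None]
        values = np.moveaxis(data, -1, 0)
        aff = img.affine
        spacing = np.linalg.norm(aff[:3, :3], axis=0)
        origin = aff[:3, 3]
        if times is None:
            dt = img.header.get_zooms()[3] if len(img.header.get_zooms()) > 3 else 1.0
            times = dt * np.arange(values.shape[0])
        return cls(values=values, spacing=spacing, origin=origin, times=times)
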