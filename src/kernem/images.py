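"""Voxel-grid containers.

A single lightweight :class:`Image` type carries every 2-D (or, in
principle, n-D) grid in the package: emission activity maps, CT-like
anatomical guidance images, kernel coefficient images and binary masks.
Geometry is just the voxel spacing in millimetres; images are compared by
shape and spacing, with the grid centred on the world origin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import GeometryError

__all__ = ["Image"]


@dataclass
class Image:
    """A voxel grid with isotropic-per-axis spacing in mm.

    Parameters
    ----------
    values
        Array of voxel values, any dimensionality (2-D in practice).
    voxel_size
        Spacing per axis in mm. A scalar is broadcast to every axis.
    """

    values: np.ndarray
    voxel_size: tuple[float, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.isscalar(self.voxel_size):
            self.voxel_size = (float(self.voxel_size),) * self.values.ndim
        else:
            self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != self.values.ndim:
            raise GeometryError(
                f"voxel_size has {len(self.voxel_size)} entries for a "
                f"{self.values.ndim}-D image"
            )
        if any(v <= 0 for v in self.voxel_size):
            raise GeometryError(f"voxel sizes must be positive, got {self.voxel_size}")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape

    @property
    def ndim(self) -> int:
        return self.values.ndim

    def copy(self) -> "Image":
        return Image(self.values.copy(), self.voxel_size)

    def with_values(self, values: np.ndarray) -> "Image":
        """Same geometry, new voxel values."""
        values = np.asarray(values, dtype=float)
        if values.shape != self.values.shape:
            raise GeometryError(
                f"replacement values shape {values.shape} != {self.values.shape}"
            )
        return Image(values, self.voxel_size)

    def same_geometry(self, other: "Image") -> bool:
        return self.shape == other.shape and np.allclose(
            self.voxel_size, other.voxel_size, rtol=1e-6, atol=0.0
        )

    def require_same_geometry(self, other: "Image", what: str = "image") -> None:
        if not self.same_geometry(other):
            raise GeometryError(
                f"{what} geometry mismatch: {self.shape}@{self.voxel_size} vs "
                f"{other.shape}@{other.voxel_size}"
            )

    def coords_mm(self) -> tuple[np.ndarray, ...]:
        """Voxel-centre coordinates in mm, origin at the grid centre.

        Returns one broadcastable coordinate array per axis (``np.meshgrid``
        with ``indexing='ij'``).
        """
        axes = [
            (np.arange(n) - (n - 1) / 2.0) * v
            for n, v in zip(self.values.shape, self.voxel_size)
        ]
        return tuple(np.meshgrid(*axes, indexing="ij"))
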