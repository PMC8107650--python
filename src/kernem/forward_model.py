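"""PET system model: parallel-beam projector with PSF, additive term, Poisson data.

The projector is a discrete 2-D parallel-beam Radon transform assembled once
as a sparse matrix with pixel-driven linear interpolation onto radial bins.
Scanner resolution is modelled as an isotropic Gaussian blur applied in image
space inside the projector (and, symmetrically, in its adjoint), so the pair
``forward_project`` / ``back_project`` is an exact adjoint pair — the property
every EM correctness argument rests on.

Ordered-subsets algorithms cycle through interleaved angular subsets produced
by :func:`make_subsets`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi
import scipy.sparse as sp

from .errors import ConfigurationError, ContractError, GeometryError
from .images import Image

__all__ = [
    "SinogramGeometry",
    "Sinogram",
    "AdditiveSinogram",
    "SystemModel",
    "forward_project",
    "back_project",
    "simulate_counts",
    "make_subsets",
    "uniform_additive",
]

#: FWHM of a Gaussian = FWHM_TO_SIGMA^-1 * sigma
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class SinogramGeometry:
    """Angles (degrees over [0, 180)) and radial binning of a sinogram."""

    angles_deg: tuple[float, ...]
    n_bins: int
    bin_spacing_mm: float

    @property
    def n_angles(self) -> int:
        return len(self.angles_deg)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_angles, self.n_bins)


@dataclass
class Sinogram:
    """Projection data: one row per angle, one column per radial bin (LOR)."""

    values: np.ndarray
    geometry: SinogramGeometry

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.geometry.shape:
            raise GeometryError(
                f"sinogram values {self.values.shape} != geometry {self.geometry.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ContractError("sinogram contains non-finite values")
        if np.any(self.values < 0):
            raise ContractError("sinogram contains negative values")


@dataclass
class AdditiveSinogram:
    """Expected randoms+scatter counts per LOR (the additive term s)."""

    values: np.ndarray
    geometry: SinogramGeometry

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.geometry.shape:
            raise GeometryError(
                f"additive values {self.values.shape} != geometry {self.geometry.shape}"
            )
        if np.any(self.values < 0) or not np.all(np.isfinite(self.values)):
            raise ContractError("additive term must be finite and >= 0")


class SystemModel:
    """Projection geometry + PSF + optional attenuation + subset partition.

    Parameters
    ----------
    grid_shape
        Image grid (rows, cols).
    voxel_size_mm
        Voxel spacing (scalar or per-axis) in mm.
    n_angles
        Number of projection angles, evenly spaced over [0, 180).
    psf_fwhm_mm
        Resolution model: isotropic Gaussian FWHM applied in image space
        inside the projector. 0 disables the PSF.
    n_bins, bin_spacing_mm
        Radial binning; defaults cover the grid diagonal at the finest voxel
        pitch.
    attenuation_map
        Optional per-voxel linear attenuation (mm^-1); applied as a
        multiplicative sinogram factor exp(-line integral).
    """

    def __init__(
        self,
        grid_shape: tuple[int, int],
        voxel_size_mm: float | tuple[float, float],
        n_angles: int = 56,
        psf_fwhm_mm: float = 4.4,
        n_bins: int | None = None,
        bin_spacing_mm: float | None = None,
        attenuation_map: Image | None = None,
    ) -> None:
        if len(grid_shape) != 2:
            raise ConfigurationError("SystemModel currently supports 2-D grids")
        if n_angles < 1:
            raise ConfigurationError("n_angles must be >= 1")
        if psf_fwhm_mm < 0:
            raise ConfigurationError("psf_fwhm_mm must be >= 0")
        self.grid_shape = tuple(int(n) for n in grid_shape)
        if np.isscalar(voxel_size_mm):
            voxel_size_mm = (float(voxel_size_mm),) * 2
        self.voxel_size_mm = tuple(float(v) for v in voxel_size_mm)
        self.psf_fwhm_mm = float(psf_fwhm_mm)

        if bin_spacing_mm is None:
            bin_spacing_mm = min(self.voxel_size_mm)
        if n_bins is None:
            diag = np.hypot(
                self.grid_shape[0] * self.voxel_size_mm[0],
                self.grid_shape[1] * self.voxel_size_mm[1],
            )
            n_bins = 2 * int(np.ceil(diag / (2.0 * bin_spacing_mm))) + 1
        angles = tuple(np.arange(n_angles) * 180.0 / n_angles)
        self.geometry = SinogramGeometry(angles, int(n_bins), float(bin_spacing_mm))
        self.subsets: list[np.ndarray] = [np.arange(n_angles)]
        self.attenuation_map = attenuation_map
        self._matrix: sp.csr_matrix | None = None
        self._att_sino: np.ndarray | None = None

    # -- geometry helpers -------------------------------------------------

    @property
    def n_voxels(self) -> int:
        return self.grid_shape[0] * self.grid_shape[1]

    def image_template(self) -> Image:
        return Image(np.zeros(self.grid_shape), self.voxel_size_mm)

    def check_image(self, image: Image) -> None:
        if image.shape != self.grid_shape or not np.allclose(
            image.voxel_size, self.voxel_size_mm
        ):
            raise GeometryError(
                f"image {image.shape}@{image.voxel_size} does not match model grid "
                f"{self.grid_shape}@{self.voxel_size_mm}"
            )

    def check_sinogram(self, sino: Sinogram | AdditiveSinogram) -> None:
        if sino.geometry != self.geometry:
            raise GeometryError("sinogram geometry does not match model")

    # -- sparse Radon matrix ----------------------------------------------

    @property
    def matrix(self) -> sp.csr_matrix:
        """Sparse (n_angles*n_bins, n_voxels) line-projection matrix (no PSF)."""
        if self._matrix is None:
            self._matrix = self._build_matrix()
        return self._matrix

    def _build_matrix(self) -> sp.csr_matrix:
        ny, nx = self.grid_shape
        vy, vx = self.voxel_size_mm
        yy = (np.arange(ny) - (ny - 1) / 2.0) * vy
        xx = (np.arange(nx) - (nx - 1) / 2.0) * vx
        Y, X = np.meshgrid(yy, xx, indexing="ij")
        yf = Y.ravel()
        xf = X.ravel()
        cols_base = np.arange(self.n_voxels)
        n_bins = self.geometry.n_bins
        spacing = self.geometry.bin_spacing_mm
        rows_all, cols_all, data_all = [], [], []
        for a, ang in enumerate(self.geometry.angles_deg):
            th = np.deg2rad(ang)
            s = xf * np.cos(th) + yf * np.sin(th)
            t = s / spacing + (n_bins - 1) / 2.0
            i0 = np.floor(t).astype(np.int64)
            w1 = t - i0
            for ib, w in ((i0, 1.0 - w1), (i0 + 1, w1)):
                ok = (ib >= 0) & (ib < n_bins) & (w > 0)
                rows_all.append(a * n_bins + ib[ok])
                cols_all.append(cols_base[ok])
                data_all.append(w[ok])
        mat = sp.coo_matrix(
            (
                np.concatenate(data_all),
                (np.concatenate(rows_all), np.concatenate(cols_all)),
            ),
            shape=(self.geometry.n_angles * n_bins, self.n_voxels),
        )
        return mat.tocsr()

    # -- PSF ---------------------------------------------------------------

    def _psf_sigma_vox(self) -> tuple[float, float]:
        s = self.psf_fwhm_mm * FWHM_TO_SIGMA
        return (s / self.voxel_size_mm[0], s / self.voxel_size_mm[1])

    def blur(self, values: np.ndarray) -> np.ndarray:
        """Image-space PSF. Zero boundary => exactly self-adjoint."""
        if self.psf_fwhm_mm == 0:
            return values
        return ndi.gaussian_filter(
            values, self._psf_sigma_vox(), mode="constant", cval=0.0
        )

    # -- attenuation -------------------------------------------------------

    def attenuation_factors(self) -> np.ndarray | None:
        """exp(-integral of mu) per LOR, flattened; None when no map is set."""
        if self.attenuation_map is None:
            return None
        if self._att_sino is None:
            self.check_image(self.attenuation_map)
            # weights sum to the path length in units of bin_spacing
            line = self.matrix @ self.attenuation_map.values.ravel()
            self._att_sino = np.exp(-line * self.geometry.bin_spacing_mm)
        return self._att_sino

    # -- subset bookkeeping -------------------------------------------------

    def subset_rows(self, subset: int | None) -> np.ndarray | None:
        """Flat sinogram-row indices of a subset (None = all)."""
        if subset is None:
            return None
        if not 0 <= subset < len(self.subsets):
            raise ContractError(f"subset {subset} out of range")
        angles = self.subsets[subset]
        n_bins = self.geometry.n_bins
        return (angles[:, None] * n_bins + np.arange(n_bins)[None, :]).ravel()

    # -- core linear maps ---------------------------------------------------

    def forward_flat(self, values: np.ndarray, subset: int | None = None) -> np.ndarray:
        """Projector applied to an image array; returns the flat sinogram.

        Outside-subset rows are zero.
        """
        flat = self.blur(values).ravel()
        rows = self.subset_rows(subset)
        att = self.attenuation_factors()
        if rows is None:
            out = self.matrix @ flat
            if att is not None:
                out = out * att
            return out
        out = np.zeros(self.matrix.shape[0])
        sub = self.matrix[rows] @ flat
        if att is not None:
            sub = sub * att[rows]
        out[rows] = sub
        return out

    def back_flat(self, sino_flat: np.ndarray, subset: int | None = None) -> np.ndarray:
        """Exact adjoint of :meth:`forward_flat`; returns an image array."""
        rows = self.subset_rows(subset)
        att = self.attenuation_factors()
        if rows is None:
            vec = sino_flat if att is None else sino_flat * att
            img = (self.matrix.T @ vec).reshape(self.grid_shape)
        else:
            vec = sino_flat[rows]
            if att is not None:
                vec = vec * att[rows]
            img = (self.matrix[rows].T @ vec).reshape(self.grid_shape)
        return self.blur(img)


def forward_project(
    image: Image, model: SystemModel, subset: int | None = None
) -> Sinogram:
    """Project an activity image into sinogram space (PSF included).

    With ``subset`` given, only that subset's angles are populated; the other
    rows are zero.
    """
    model.check_image(image)
    flat = model.forward_flat(image.values, subset)
    return Sinogram(flat.reshape(model.geometry.shape), model.geometry)


def back_project(
    sino: Sinogram, model: SystemModel, subset: int | None = None
) -> Image:
    """Adjoint of :func:`forward_project`."""
    model.check_sinogram(sino)
    vals = model.back_flat(sino.values.ravel(), subset)
    return Image(vals, model.voxel_size_mm)


def simulate_counts(
    truth: Image,
    model: SystemModel,
    additive: AdditiveSinogram,
    total_counts: float,
    seed: int,
) -> Sinogram:
    """Draw a Poisson realisation of the forward-projected truth.

    The noiseless projection is rescaled so its total equals ``total_counts``;
    the additive term is added on top, so the expected grand total is
    ``total_counts + additive.values.sum()``.
    """
    if total_counts <= 0:
        raise ContractError("total_counts must be > 0")
    model.check_image(truth)
    model.check_sinogram(additive)
    ybar = model.forward_flat(truth.values).reshape(model.geometry.shape)
    s = ybar.sum()
    if s > 0:
        ybar = ybar * (total_counts / s)
    rng = np.random.default_rng(seed)
    counts = rng.poisson(ybar + additive.values).astype(float)
    return Sinogram(counts, model.geometry)


def uniform_additive(model: SystemModel, total: float) -> AdditiveSinogram:
    """Flat randoms+scatter surrogate with the given expected total counts."""
    if total < 0:
        raise ContractError("additive total must be >= 0")
    shape = model.geometry.shape
    vals = np.full(shape, total / (shape[0] * shape[1]))
    return AdditiveSinogram(vals, model.geometry)


def make_subsets(model: SystemModel, n_subsets: int) -> SystemModel:
    """Partition the model's angles into interleaved ordered subsets.

    Subset k takes angles k, k+n, k+2n, ... (stride = n_subsets), which
    maximises angular coverage per subset. Returns the same model instance
    with its partition replaced.
    """
    n_angles = model.geometry.n_angles
    if n_subsets < 1:
        raise ConfigurationError("n_subsets must be >= 1")
    if n_subsets > n_angles:
        raise ConfigurationError(
            f"n_subsets={n_subsets} exceeds number of angles ({n_angles})"
        )
    model.subsets = [np.arange(k, n_angles, n_subsets) for k in range(n_subsets)]
    return model
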