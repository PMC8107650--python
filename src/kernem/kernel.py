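"""Sparse kernel operators for anatomically guided reconstruction.

The reconstructed activity is represented as lambda = K alpha, where K is a
sparse voxel-neighbourhood kernel matrix. The anatomical kernel K_m weights
each voxel pair by the similarity of intensity patches in the guidance (CT)
image and by spatial proximity; the functional kernel K_p does the same on
the current coefficient iterate, and the hybrid kernel is their elementwise
product on the shared sparsity pattern:

    k_m(v_j, v_f) = exp(-||v_j - v_f||^2 / 2 sigma_m^2)
                  * exp(-||x_j - x_f||^2 / 2 sigma_dm^2)
    k_p(z_j, z_f) = exp(-||z_j - z_f||^2 / 2 sigma_p^2)
                  * exp(-||x_j - x_f||^2 / 2 sigma_dp^2)
    K = K_m * K_p   (elementwise)

Feature vectors v, z are intensity patches normalised by the image's global
standard deviation, so the sigma scales are meaningful across images.
Neighbourhoods are the ``n_neighbors`` feature-nearest voxels inside a
square spatial search window; the centre voxel always belongs to its own
neighbourhood, so n_neighbors=1 yields the identity operator (KEM then
degenerates to MLEM).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, ContractError, GeometryError
from .images import Image

__all__ = [
    "KernelParams",
    "KernelModel",
    "extract_features",
    "build_anatomical_kernel",
    "build_functional_kernel",
    "compose_hybrid",
    "apply_kernel",
    "apply_kernel_adjoint",
    "identity_kernel",
]


@dataclass(frozen=True)
class KernelParams:
    """Tunable kernel hyper-parameters.

    n_neighbors : voxels kept per row (k-nearest in feature space).
    patch_radius : half-width of the intensity patch feature, in voxels.
    search_radius : half-width of the spatial candidate window, in voxels;
        defaults to max(patch_radius, 1).
    sigma_m / sigma_p : intensity scales for the anatomical / functional
        Gaussians (on std-normalised intensities).
    sigma_dm / sigma_dp : spatial scales in voxels.
    normalize_rows : scale each row of K to sum to 1 (count preservation
        under lambda = K alpha).
    hybrid : multiply in the functional kernel (HKEM) or not (KEM).
    """

    n_neighbors: int = 3
    patch_radius: int = 1
    sigma_m: float = 0.1
    sigma_p: float = 0.1
    sigma_dm: float = 3.0
    sigma_dp: float | None = None
    search_radius: int | None = None
    normalize_rows: bool = True
    hybrid: bool = True

    def __post_init__(self) -> None:
        if self.n_neighbors < 1:
            raise ConfigurationError("n_neighbors must be >= 1")
        if self.patch_radius < 0:
            raise ConfigurationError("patch_radius must be >= 0")
        for name in ("sigma_m", "sigma_p", "sigma_dm"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if self.sigma_dp is not None and self.sigma_dp <= 0:
            raise ConfigurationError("sigma_dp must be > 0")
        if self.search_radius is not None and self.search_radius < 0:
            raise ConfigurationError("search_radius must be >= 0")

    @property
    def effective_sigma_dp(self) -> float:
        return self.sigma_dm if self.sigma_dp is None else self.sigma_dp

    @property
    def effective_search_radius(self) -> int:
        if self.search_radius is not None:
            return self.search_radius
        return max(self.patch_radius, 1)


@dataclass
class KernelModel:
    """Sparse neighbour-weighted kernel operator.

    Row j holds the neighbour voxel ids and weights k_fj entering
    lambda_j = sum_f k_fj alpha_f. Stored densely as (n_voxels, k) arrays
    since every row has the same neighbour count.
    """

    neighbor_index: np.ndarray  # (V, k) int
    weights: np.ndarray  # (V, k) float, >= 0
    grid_shape: tuple[int, int]
    row_normalized: bool
    guidance_scale: float = 1.0

    def __post_init__(self) -> None:
        self.neighbor_index = np.asarray(self.neighbor_index, dtype=np.int64)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.neighbor_index.shape != self.weights.shape:
            raise ContractError("neighbor_index and weights shapes differ")
        if np.any(self.weights < 0):
            raise ContractError("kernel weights must be >= 0")

    @property
    def n_voxels(self) -> int:
        return self.neighbor_index.shape[0]

    @property
    def n_neighbors(self) -> int:
        return self.neighbor_index.shape[1]

    def same_pattern(self, other: "KernelModel") -> bool:
        return (
            self.grid_shape == other.grid_shape
            and self.neighbor_index.shape == other.neighbor_index.shape
            and np.array_equal(self.neighbor_index, other.neighbor_index)
        )

    def dense(self) -> np.ndarray:
        """Materialise K as a dense (V, V) matrix (tests / tiny grids only)."""
        K = np.zeros((self.n_voxels, self.n_voxels))
        rows = np.repeat(np.arange(self.n_voxels), self.n_neighbors)
        np.add.at(K, (rows, self.neighbor_index.ravel()), self.weights.ravel())
        return K


def _normalize_rows(weights: np.ndarray) -> np.ndarray:
    sums = weights.sum(axis=1, keepdims=True)
    sums[sums == 0] = 1.0
    return weights / sums


def extract_features(image: Image | np.ndarray, patch_radius: int) -> np.ndarray:
    """Per-voxel feature vectors: the (2r+1)^2 patch of normalised intensities.

    Intensities are divided by the image's global standard deviation (falls
    back to 1 for a constant image); the border is handled by edge
    replication. Returns an (n_voxels, (2r+1)^2) array.
    """
    values = image.values if isinstance(image, Image) else np.asarray(image, float)
    if not np.all(np.isfinite(values)):
        raise ContractError("image must be finite for feature extraction")
    scale = float(np.std(values))
    if scale == 0.0 or not np.isfinite(scale):
        scale = 1.0
    r = int(patch_radius)
    H, W = values.shape
    padded = np.pad(values, r, mode="edge") / scale
    feats = np.empty((H * W, (2 * r + 1) ** 2))
    col = 0
    for dy in range(-r, r + 1):
        for dx in range(-r, r + 1):
            feats[:, col] = padded[r + dy : r + dy + H, r + dx : r + dx + W].ravel()
            col += 1
    return feats


def _window_offsets(radius: int) -> list[tuple[int, int]]:
    # row-major order => candidate neighbour ids are increasing, which makes
    # the stable k-NN sort break feature-distance ties by voxel index
    return [
        (dy, dx)
        for dy in range(-radius, radius + 1)
        for dx in range(-radius, radius + 1)
    ]


def build_anatomical_kernel(anatomical: Image, params: KernelParams) -> KernelModel:
    """Build K_m from the guidance image.

    For every voxel, the ``n_neighbors`` candidates inside the spatial search
    window whose patch features are nearest (Euclidean) are kept; the weight
    is the product of the intensity Gaussian (sigma_m) and the spatial
    Gaussian (sigma_dm, voxel units). The centre voxel is always kept.
    """
    H, W = anatomical.shape
    V = H * W
    w = params.effective_search_radius
    # the smallest (corner) window must still hold n_neighbors candidates
    min_window = (w + 1) ** 2
    if params.n_neighbors > min_window:
        raise ConfigurationError(
            f"n_neighbors={params.n_neighbors} exceeds the smallest search "
            f"window ({min_window} candidates at the grid corner)"
        )
    feats = extract_features(anatomical, params.patch_radius)
    scale = float(np.std(anatomical.values)) or 1.0

    offsets = _window_offsets(w)
    C = len(offsets)
    idx = np.arange(V)
    yy, xx = np.divmod(idx, W)
    nbr = np.full((V, C), -1, dtype=np.int64)
    feat2 = np.full((V, C), np.inf)
    spat2 = np.full((V, C), np.inf)
    self_col = offsets.index((0, 0))
    for c, (dy, dx) in enumerate(offsets):
        ny = yy + dy
        nx = xx + dx
        ok = (ny >= 0) & (ny < H) & (nx >= 0) & (nx < W)
        nid = ny[ok] * W + nx[ok]
        nbr[ok, c] = nid
        d = feats[idx[ok]] - feats[nid]
        feat2[ok, c] = np.einsum("ij,ij->i", d, d)
        spat2[ok, c] = float(dy * dy + dx * dx)

    # force self-inclusion: rank the centre voxel below every other candidate
    rank = feat2.copy()
    rank[:, self_col] = -1.0
    order = np.argsort(rank, axis=1, kind="stable")[:, : params.n_neighbors]
    sel_nbr = np.take_along_axis(nbr, order, axis=1)
    sel_feat2 = np.take_along_axis(feat2, order, axis=1)
    sel_spat2 = np.take_along_axis(spat2, order, axis=1)

    weights = np.exp(-sel_feat2 / (2.0 * params.sigma_m**2)) * np.exp(
        -sel_spat2 / (2.0 * params.sigma_dm**2)
    )
    if params.normalize_rows:
        weights = _normalize_rows(weights)
    return KernelModel(
        sel_nbr, weights, (H, W), params.normalize_rows, guidance_scale=scale
    )


def build_functional_kernel(
    current: Image, params: KernelParams, neighbor_index: np.ndarray
) -> KernelModel:
    """Build K_p on the anatomical kernel's sparsity pattern.

    Features come from the current coefficient iterate (normalised by its own
    standard deviation); spatial distances are recomputed from the voxel
    indices, scaled by sigma_dp.
    """
    H, W = current.shape
    V = H * W
    neighbor_index = np.asarray(neighbor_index, dtype=np.int64)
    if neighbor_index.shape[0] != V or neighbor_index.min() < 0 or (
        neighbor_index.max() >= V
    ):
        raise ContractError("neighbor_index does not match the image grid")
    feats = extract_features(current, params.patch_radius)
    idx = np.arange(V)
    yy, xx = np.divmod(idx, W)
    fy, fx = np.divmod(neighbor_index, W)
    spat2 = (fy - yy[:, None]) ** 2 + (fx - xx[:, None]) ** 2
    d = feats[:, None, :] - feats[neighbor_index]
    feat2 = np.einsum("ijk,ijk->ij", d, d)
    sdp = params.effective_sigma_dp
    weights = np.exp(-feat2 / (2.0 * params.sigma_p**2)) * np.exp(
        -spat2 / (2.0 * sdp**2)
    )
    if params.normalize_rows:
        weights = _normalize_rows(weights)
    return KernelModel(
        neighbor_index.copy(), weights, (H, W), params.normalize_rows
    )


def compose_hybrid(km: KernelModel, kp: KernelModel) -> KernelModel:
    """Elementwise product K = K_m * K_p on the shared neighbour structure."""
    if not km.same_pattern(kp):
        raise ContractError("kernel sparsity patterns differ; cannot compose")
    weights = km.weights * kp.weights
    if km.row_normalized:
        weights = _normalize_rows(weights)
    return KernelModel(
        km.neighbor_index.copy(),
        weights,
        km.grid_shape,
        km.row_normalized,
        guidance_scale=km.guidance_scale,
    )


def _check_grid(k: KernelModel, arr: np.ndarray) -> None:
    if arr.shape != k.grid_shape:
        raise GeometryError(
            f"array shape {arr.shape} does not match kernel grid {k.grid_shape}"
        )


def apply_kernel(k: KernelModel, alpha: Image) -> Image:
    """lambda = K alpha: lambda_j = sum_f k_jf alpha_{f}."""
    _check_grid(k, alpha.values)
    flat = alpha.values.ravel()
    out = np.einsum("ij,ij->i", k.weights, flat[k.neighbor_index])
    return alpha.with_values(out.reshape(k.grid_shape))


def apply_kernel_adjoint(k: KernelModel, image: Image) -> Image:
    """K^T action: out_f = sum_j k_jf image_j (scatter-add over neighbours)."""
    _check_grid(k, image.values)
    flat = image.values.ravel()
    contrib = k.weights * flat[:, None]
    out = np.bincount(
        k.neighbor_index.ravel(), weights=contrib.ravel(), minlength=k.n_voxels
    )
    return image.with_values(out.reshape(k.grid_shape))


def identity_kernel(grid_shape: tuple[int, int]) -> KernelModel:
    """Self-only kernel: apply_kernel is the identity map."""
    V = grid_shape[0] * grid_shape[1]
    return KernelModel(
        np.arange(V, dtype=np.int64)[:, None],
        np.ones((V, 1)),
        tuple(grid_shape),
        row_normalized=True,
    )
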