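"""Iterative reconstruction: MLEM/OSEM baseline, KEM and hybrid KEM.

All three algorithms share one multiplicative EM update on the kernel
coefficients alpha (lambda = K alpha):

    alpha <- alpha * [K^T P^T (y / (P K alpha + s))] / [K^T P^T 1]

restricted to the active angular subset. OSEM uses the identity kernel and a
Gaussian post-filter on the stored images; KEM keeps the anatomical kernel
K_m fixed throughout; HKEM rebuilds the functional factor K_p from the
current iterate (per subset update by default, optionally once per full
iteration) and uses K = K_m * K_p.

Voxels with zero sensitivity (denominator 0) are frozen at their current
value rather than raising; the EM ratio denominators carry a small epsilon.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi

from .errors import ConfigurationError, ContractError
from .forward_model import (
    FWHM_TO_SIGMA,
    AdditiveSinogram,
    Sinogram,
    SystemModel,
)
from .images import Image
from .kernel import (
    KernelModel,
    KernelParams,
    apply_kernel,
    apply_kernel_adjoint,
    build_anatomical_kernel,
    build_functional_kernel,
    compose_hybrid,
    identity_kernel,
)

__all__ = [
    "ReconConfig",
    "ReconResult",
    "em_update",
    "reconstruct",
    "gaussian_post_filter",
    "poisson_log_likelihood",
]

ALGORITHMS = ("osem", "kem", "hkem")


@dataclass
class ReconConfig:
    """Reconstruction settings.

    algorithm : "osem", "kem" or "hkem".
    n_subsets / n_iterations : ordered subsets and full passes over the data.
    kernel : kernel hyper-parameters (kem/hkem only).
    post_filter_fwhm : Gaussian post-filter in mm applied to every stored
        OSEM image (0 disables).
    kernel_update : "subset" rebuilds K_p before every subset update,
        "iteration" once per full pass (hkem only).
    epsilon : stabiliser added to EM ratio denominators.
    """

    algorithm: str = "osem"
    n_subsets: int = 21
    n_iterations: int = 10
    kernel: KernelParams = field(default_factory=KernelParams)
    post_filter_fwhm: float = 5.0
    kernel_update: str = "subset"
    epsilon: float = 1e-10

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ConfigurationError(
                f"algorithm must be one of {ALGORITHMS}, got {self.algorithm!r}"
            )
        if self.n_subsets < 1 or self.n_iterations < 1:
            raise ConfigurationError("n_subsets and n_iterations must be >= 1")
        if self.epsilon <= 0:
            raise ConfigurationError("epsilon must be > 0")
        if self.kernel_update not in ("subset", "iteration"):
            raise ConfigurationError("kernel_update must be 'subset' or 'iteration'")
        if self.post_filter_fwhm < 0:
            raise ConfigurationError("post_filter_fwhm must be >= 0")


@dataclass
class ReconResult:
    """Stored per-full-iteration images, final coefficients and likelihood log."""

    images: list[Image]
    alpha: Image
    log_likelihood: list[float]
    algorithm: str

    def image_at(self, iteration: int) -> Image:
        """1-based full-iteration index."""
        return self.images[iteration - 1]


def poisson_log_likelihood(
    y: np.ndarray, expected: np.ndarray, eps: float = 1e-12
) -> float:
    """sum_i [y_i log(ybar_i) - ybar_i], the Poisson log-likelihood up to
    the data-dependent log(y!) constant."""
    ybar = np.maximum(expected, eps)
    return float(np.sum(y * np.log(ybar) - ybar))


def em_update(
    alpha: Image,
    kernel: KernelModel,
    subset_data: Sinogram,
    model: SystemModel,
    additive: AdditiveSinogram,
    subset: int | None = None,
    epsilon: float = 1e-10,
) -> Image:
    """One multiplicative kernel-EM step on the active subset.

    ``subset_data`` and ``additive`` are full-geometry sinograms; when
    ``subset`` is given only that subset's angles contribute. Voxels whose
    sensitivity K^T P^T 1 is zero are left unchanged.
    """
    if np.any(alpha.values < 0):
        raise ContractError("alpha must be nonnegative")
    model.check_sinogram(subset_data)
    model.check_sinogram(additive)
    lam = apply_kernel(kernel, alpha)
    model.check_image(lam)
    ybar = model.forward_flat(lam.values, subset) + additive.values.ravel()
    ratio = subset_data.values.ravel() / (ybar + epsilon)
    if subset is not None:
        # rows outside the subset must not contribute
        mask = np.zeros(ratio.shape, dtype=bool)
        mask[model.subset_rows(subset)] = True
        ratio = np.where(mask, ratio, 0.0)
    numerator = apply_kernel_adjoint(
        kernel, Image(model.back_flat(ratio, subset), model.voxel_size_mm)
    ).values
    ones = np.ones(model.geometry.n_angles * model.geometry.n_bins)
    sens = apply_kernel_adjoint(
        kernel, Image(model.back_flat(ones, subset), model.voxel_size_mm)
    ).values
    new = alpha.values.copy()
    active = sens > 0
    new[active] = alpha.values[active] * numerator[active] / (sens[active] + epsilon)
    return alpha.with_values(new)


def gaussian_post_filter(image: Image, fwhm_mm: float) -> Image:
    """Isotropic Gaussian post-reconstruction filter.

    fwhm=0 returns the input unchanged. Reflect boundary keeps the total
    image mass constant.
    """
    if fwhm_mm < 0:
        raise ConfigurationError("fwhm must be >= 0")
    if fwhm_mm == 0:
        return image
    sigma = tuple(fwhm_mm * FWHM_TO_SIGMA / v for v in image.voxel_size)
    return image.with_values(ndi.gaussian_filter(image.values, sigma, mode="reflect"))


class _EmLoop:
    """Shared OSEM/KEM/HKEM iteration engine with cached sensitivities."""

    def __init__(
        self,
        data: Sinogram,
        model: SystemModel,
        additive: AdditiveSinogram,
        config: ReconConfig,
    ) -> None:
        self.y = data.values.ravel()
        self.s = additive.values.ravel()
        self.model = model
        self.config = config
        self.n_rows = model.geometry.n_angles * model.geometry.n_bins
        # P^T 1 per subset, kernel-independent
        ones = np.ones(self.n_rows)
        self.bp_ones = [
            model.back_flat(ones, k) for k in range(len(model.subsets))
        ]
        self.subset_masks = []
        for k in range(len(model.subsets)):
            m = np.zeros(self.n_rows, dtype=bool)
            m[model.subset_rows(k)] = True
            self.subset_masks.append(m)

    def update(
        self, alpha: np.ndarray, kernel: KernelModel, subset: int
    ) -> np.ndarray:
        eps = self.config.epsilon
        lam = np.einsum(
            "ij,ij->i", kernel.weights, alpha.ravel()[kernel.neighbor_index]
        ).reshape(self.model.grid_shape)
        ybar = self.model.forward_flat(lam, subset) + self.s
        ratio = np.where(self.subset_masks[subset], self.y / (ybar + eps), 0.0)
        num_img = self.model.back_flat(ratio, subset)
        numerator = np.bincount(
            kernel.neighbor_index.ravel(),
            weights=(kernel.weights * num_img.ravel()[:, None]).ravel(),
            minlength=kernel.n_voxels,
        ).reshape(self.model.grid_shape)
        sens = np.bincount(
            kernel.neighbor_index.ravel(),
            weights=(kernel.weights * self.bp_ones[subset].ravel()[:, None]).ravel(),
            minlength=kernel.n_voxels,
        ).reshape(self.model.grid_shape)
        new = alpha.copy()
        active = sens > 0
        new[active] = alpha[active] * numerator[active] / (sens[active] + eps)
        return new

    def log_likelihood(self, lam: np.ndarray) -> float:
        ybar = self.model.forward_flat(lam) + self.s
        return poisson_log_likelihood(self.y, ybar)


def reconstruct(
    data: Sinogram,
    model: SystemModel,
    additive: AdditiveSinogram,
    anatomical: Image | None,
    config: ReconConfig,
) -> ReconResult:
    """Run the configured algorithm and store one image per full iteration.

    OSEM stores post-filtered lambda images; KEM/HKEM store lambda = K alpha.
    alpha is initialised to 1 everywhere. The Poisson log-likelihood of the
    full data is recorded after every full iteration.
    """
    from .forward_model import make_subsets

    model.check_sinogram(data)
    model.check_sinogram(additive)
    if config.algorithm in ("kem", "hkem"):
        if anatomical is None:
            raise ConfigurationError(
                f"{config.algorithm} requires an anatomical guidance image"
            )
        model.check_image(anatomical)
    make_subsets(model, config.n_subsets)
    loop = _EmLoop(data, model, additive, config)

    grid = model.grid_shape
    alpha = np.ones(grid)
    if config.algorithm == "osem":
        km = identity_kernel(grid)
    else:
        km = build_anatomical_kernel(anatomical, config.kernel)

    def hybrid_kernel(current: np.ndarray) -> KernelModel:
        kp = build_functional_kernel(
            Image(current, model.voxel_size_mm), config.kernel, km.neighbor_index
        )
        return compose_hybrid(km, kp)

    hkem = config.algorithm == "hkem" and config.kernel.hybrid
    kernel = hybrid_kernel(alpha) if hkem else km
    images: list[Image] = []
    loglik: list[float] = []
    for _ in range(config.n_iterations):
        if hkem and config.kernel_update == "iteration":
            kernel = hybrid_kernel(alpha)
        for subset in range(config.n_subsets):
            if hkem and config.kernel_update == "subset":
                kernel = hybrid_kernel(alpha)
            alpha = loop.update(alpha, kernel, subset)
        lam = np.einsum(
            "ij,ij->i", kernel.weights, alpha.ravel()[kernel.neighbor_index]
        ).reshape(grid)
        img = Image(lam, model.voxel_size_mm)
        if config.algorithm == "osem" and config.post_filter_fwhm > 0:
            img = gaussian_post_filter(img, config.post_filter_fwhm)
        images.append(img)
        loglik.append(loop.log_likelihood(lam))
    return ReconResult(
        images=images,
        alpha=Image(alpha, model.voxel_size_mm),
        log_likelihood=loglik,
        algorithm=config.algorithm,
    )
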