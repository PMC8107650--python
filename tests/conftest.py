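"""Shared fixtures and independent oracle implementations.

The oracles here deliberately re-derive quantities with plain loops or dense
linear algebra so they stay independent of the package's vectorised code
paths.
"""

from __future__ import annotations

import numpy as np
import pytest

from kernem.images import Image


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


# --------------------------------------------------------------------------
# dense kernel oracle: brute-force evaluation of the Gaussian-product kernel
# with k-NN neighbour selection, mirroring the mathematical definition.

def dense_kernel_oracle(
    guidance: np.ndarray,
    n_neighbors: int,
    patch_radius: int,
    search_radius: int,
    sigma_int: float,
    sigma_dist: float,
    normalize_rows: bool,
    pattern: list[list[int]] | None = None,
) -> np.ndarray:
    """Dense (V, V) kernel matrix built with explicit loops.

    When ``pattern`` is given (list of neighbour ids per voxel), neighbour
    selection is skipped and weights are evaluated on that pattern (this is
    how the functional kernel reuses the anatomical sparsity structure).
    """
    H, W = guidance.shape
    V = H * W
    scale = float(np.std(guidance))
    if scale == 0:
        scale = 1.0
    r = patch_radius
    padded = np.pad(guidance, r, mode="edge") / scale

    def feat(j):
        y, x = divmod(j, W)
        return padded[y : y + 2 * r + 1, x : x + 2 * r + 1].ravel()

    K = np.zeros((V, V))
    for j in range(V):
        y, x = divmod(j, W)
        if pattern is None:
            cands = []
            for dy in range(-search_radius, search_radius + 1):
                for dx in range(-search_radius, search_radius + 1):
                    ny, nx = y + dy, x + dx
                    if 0 <= ny < H and 0 <= nx < W:
                        cands.append(ny * W + nx)
            # k nearest by feature distance, self forced first, ties by id
            def key(f):
                d = feat(j) - feat(f)
                return (-1.0 if f == j else float(d @ d), f)

            cands_sorted = sorted(cands, key=key)
            chosen = cands_sorted[:n_neighbors]
        else:
            chosen = pattern[j]
        row = {}
        for f in chosen:
            fy, fx = divmod(f, W)
            d = feat(j) - feat(f)
            w = np.exp(-float(d @ d) / (2 * sigma_int**2)) * np.exp(
                -((y - fy) ** 2 + (x - fx) ** 2) / (2 * sigma_dist**2)
            )
            row[f] = w
        total = sum(row.values())
        for f, w in row.items():
            K[j, f] = w / total if (normalize_rows and total > 0) else w
    return K


@pytest.fixture
def kernel_oracle():
    return dense_kernel_oracle


# --------------------------------------------------------------------------
# dense projector oracle: direct interpolation arithmetic per voxel/angle

def dense_projector_oracle(model) -> np.ndarray:
    """Materialise the (no-PSF) line-projection matrix with scalar loops."""
    ny, nx = model.grid_shape
    vy, vx = model.voxel_size_mm
    n_bins = model.geometry.n_bins
    spacing = model.geometry.bin_spacing_mm
    A = np.zeros((model.geometry.n_angles * n_bins, ny * nx))
    for a, ang in enumerate(model.geometry.angles_deg):
        th = np.deg2rad(ang)
        for j in range(ny * nx):
            iy, ix = divmod(j, nx)
            ymm = (iy - (ny - 1) / 2) * vy
            xmm = (ix - (nx - 1) / 2) * vx
            t = (xmm * np.cos(th) + ymm * np.sin(th)) / spacing + (n_bins - 1) / 2
            i0 = int(np.floor(t))
            w = t - i0
            if 0 <= i0 < n_bins and (1 - w) > 0:
                A[a * n_bins + i0, j] += 1 - w
            if 0 <= i0 + 1 < n_bins and w > 0:
                A[a * n_bins + i0 + 1, j] += w
    return A


@pytest.fixture
def projector_oracle():
    return dense_projector_oracle


# --------------------------------------------------------------------------
# Mann-Whitney pair-count AUC oracle

def pair_count_auc(scores, labels) -> float:
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    pos = scores[labels]
    neg = scores[~labels]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


@pytest.fixture
def auc_oracle():
    return pair_count_auc


@pytest.fixture
def random_image(rng):
    def make(shape=(16, 16), voxel=2.0, positive=True):
        vals = rng.random(shape)
        if positive:
            vals = vals + 0.1
        return Image(vals, voxel)

    return make
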