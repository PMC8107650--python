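"""Synthetic abdominal phantoms for aneurysm PET studies.

One phantom is a 2-D axial slice through the abdomen containing the
structures that drive both the reconstruction problem and the ROI analysis:

* a hot **spine** (NaF is a bone tracer) sitting just posterior to the
  aorta — the spill-in hazard for target quantification;
* the **aneurysmal aorta**: a disc whose wall annulus is the target ROI T,
  with 0 or more small calcified **lesions** (hot foci) embedded in the
  wall — these are what the kernel methods are meant to recover;
* a **non-aneurysmal aorta** segment whose wall is the reference ROI A;
* the **vena cava**, the blood-pool normalisation ROI B.

Activities are unitless ratios relative to blood (= 1): controls carry
lesion_contrast = 1 so the maximum truth activity in T equals that in A;
positive subjects carry focal uptake of ``lesion_contrast`` in the wall.
Wall voxels closer than ``spine_margin_mm`` to the spine are excluded from
T, mirroring how analysts avoid spill-in when drawing the target ROI.

All randomness (lesion placement, cohort parameter draws) is driven by the
spec/cohort seed, so outputs are bit-identical across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigurationError, GeometryError
from .images import Image
from .metrics import ROISet

__all__ = ["PhantomSpec", "SubjectData", "CohortRanges", "generate_subject", "generate_cohort"]

# anatomical (CT-like) intensity levels, arbitrary units
_CT_BACKGROUND = 20.0
_CT_LUMEN = 45.0
_CT_WALL = 55.0
_CT_SPINE = 400.0


@dataclass(frozen=True)
class PhantomSpec:
    """Parametric description of one synthetic subject.

    Centres are (row, col) positions in mm relative to the grid centre; all
    radii in mm. Activities are unitless ratios against blood (= 1.0).
    ``noise_scale`` is the expected total true-coincidence count used when
    the phantom is projected to noisy data.
    """

    grid_shape: tuple[int, int] = (64, 64)
    voxel_size: float = 3.0
    aorta_center: tuple[float, float] = (2.0, 0.0)
    aorta_radius: float = 10.0
    aneurysm_radius: float = 24.0
    normal_aorta_center: tuple[float, float] = (-25.0, -40.0)
    spine_center: tuple[float, float] = (60.0, 0.0)
    spine_radius: float = 14.0
    vena_cava_center: tuple[float, float] = (-25.0, 40.0)
    vena_cava_radius: float = 8.0
    wall_thickness: float = 6.0
    spine_margin_mm: float = 6.0
    lesion_count: int = 2
    lesion_radius: float = 3.0
    lesion_contrast: float = 3.0
    lesion_ct_value: float = 150.0
    lesion_ct_visible_prob: float = 0.5
    spine_activity: float = 3.0
    background_activity: float = 0.5
    noise_scale: float = 5e5
    anatomical_blur_fwhm: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "aorta_radius",
            "aneurysm_radius",
            "spine_radius",
            "vena_cava_radius",
            "wall_thickness",
            "lesion_radius",
        ):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if self.lesion_count < 0:
            raise ConfigurationError("lesion_count must be >= 0")
        if self.lesion_contrast < 1.0:
            raise ConfigurationError("lesion_contrast must be >= 1")
        if self.background_activity <= 0 or self.spine_activity <= 0:
            raise ConfigurationError("activities must be > 0")
        if self.noise_scale <= 0:
            raise ConfigurationError("noise_scale must be > 0")
        if self.wall_thickness >= self.aneurysm_radius:
            raise ConfigurationError("wall_thickness must be < aneurysm_radius")

    @property
    def label(self) -> bool:
        """Aneurysm-positive = focal uptake present in the wall."""
        return self.lesion_count > 0 and self.lesion_contrast > 1.0

    @property
    def aneurysm_diameter(self) -> float:
        return 2.0 * self.aneurysm_radius


@dataclass
class SubjectData:
    """One simulated subject: guidance image, ground-truth activity, ROIs."""

    subject_id: str
    anatomical: Image
    activity_truth: Image
    rois: ROISet
    label: bool
    aneurysm_diameter: float
    spec: PhantomSpec


def _disc(Y: np.ndarray, X: np.ndarray, center: tuple[float, float], radius: float):
    return (Y - center[0]) ** 2 + (X - center[1]) ** 2 <= radius**2


def _check_inside(spec: PhantomSpec, center, radius, name: str) -> None:
    half = (
        spec.grid_shape[0] * spec.voxel_size / 2.0,
        spec.grid_shape[1] * spec.voxel_size / 2.0,
    )
    if abs(center[0]) + radius > half[0] or abs(center[1]) + radius > half[1]:
        raise GeometryError(
            f"{name} (centre {center}, radius {radius} mm) extends outside the "
            f"{spec.grid_shape} grid at {spec.voxel_size} mm voxels"
        )


def generate_subject(spec: PhantomSpec, subject_id: str = "s0") -> SubjectData:
    """Build the anatomical image, truth activity and ROI masks for one spec.

    Deterministic given ``spec.seed``. Lesions are discs of
    ``lesion_radius`` clipped to the aneurysm wall annulus, placed at
    rejection-sampled angles so that each lesion lies entirely inside T and
    lesions stay mutually separated (distinct connected components).
    """
    template = Image(np.zeros(spec.grid_shape), spec.voxel_size)
    Y, X = template.coords_mm()
    structures = [
        (spec.aorta_center, spec.aneurysm_radius, "aneurysmal aorta"),
        (spec.normal_aorta_center, spec.aorta_radius, "normal aorta"),
        (spec.spine_center, spec.spine_radius, "spine"),
        (spec.vena_cava_center, spec.vena_cava_radius, "vena cava"),
    ]
    for center, radius, name in structures:
        _check_inside(spec, center, radius, name)
    for i, (c1, r1, n1) in enumerate(structures):
        for c2, r2, n2 in structures[i + 1 :]:
            if np.hypot(c1[0] - c2[0], c1[1] - c2[1]) <= r1 + r2:
                raise GeometryError(f"structures {n1} and {n2} overlap")

    an_disc = _disc(Y, X, spec.aorta_center, spec.aneurysm_radius)
    an_lumen = _disc(Y, X, spec.aorta_center, spec.aneurysm_radius - spec.wall_thickness)
    an_wall = an_disc & ~an_lumen
    na_disc = _disc(Y, X, spec.normal_aorta_center, spec.aorta_radius)
    na_lumen = _disc(
        Y, X, spec.normal_aorta_center, max(spec.aorta_radius - spec.wall_thickness, 1.0)
    )
    na_wall = na_disc & ~na_lumen
    spine = _disc(Y, X, spec.spine_center, spec.spine_radius)
    cava = _disc(Y, X, spec.vena_cava_center, spec.vena_cava_radius)

    spine_dist = np.hypot(Y - spec.spine_center[0], X - spec.spine_center[1])
    mask_T = an_wall & (spine_dist > spec.spine_radius + spec.spine_margin_mm)
    mask_A = na_wall
    mask_B = cava

    # truth activity (blood = 1)
    act = np.full(spec.grid_shape, spec.background_activity)
    act[an_disc] = 1.0
    act[na_disc] = 1.0
    act[cava] = 1.0
    act[spine] = spec.spine_activity

    ana = np.full(spec.grid_shape, _CT_BACKGROUND)
    ana[an_disc] = _CT_LUMEN
    ana[an_wall] = _CT_WALL
    ana[na_disc] = _CT_LUMEN
    ana[na_wall] = _CT_WALL
    ana[cava] = _CT_LUMEN
    ana[spine] = _CT_SPINE

    hot = spec.lesion_count > 0 and spec.lesion_contrast > 1.0
    if spec.lesion_count > 0:
        rng = np.random.default_rng(spec.seed)
        ring_r = spec.aneurysm_radius - spec.wall_thickness / 2.0
        min_sep = (2.0 * spec.lesion_radius + 2.0 * spec.voxel_size) / ring_r
        placed: list[float] = []
        tries = 0
        while len(placed) < spec.lesion_count:
            tries += 1
            if tries > 2000:
                raise GeometryError(
                    f"could not place {spec.lesion_count} lesions of radius "
                    f"{spec.lesion_radius} mm in the wall annulus"
                )
            theta = rng.uniform(0.0, 2.0 * np.pi)
            if any(
                min(abs(theta - t), 2 * np.pi - abs(theta - t)) < min_sep
                for t in placed
            ):
                continue
            cy = spec.aorta_center[0] + ring_r * np.sin(theta)
            cx = spec.aorta_center[1] + ring_r * np.cos(theta)
            lesion = _disc(Y, X, (cy, cx), spec.lesion_radius) & an_wall
            if not lesion.any() or (lesion & ~mask_T).any():
                continue  # clipped away or too close to the spine margin
            placed.append(theta)
            if hot:
                act[lesion] = spec.lesion_contrast
            # NaF-avid microcalcification is frequently below CT resolution:
            # each lesion shows up in the guidance image only with
            # probability lesion_ct_visible_prob, so part of the cohort's
            # uptake foci have no anatomical counterpart and only the
            # functional kernel can preserve their edges
            if rng.uniform() < spec.lesion_ct_visible_prob:
                ana[lesion] = spec.lesion_ct_value

    anatomical = Image(ana, spec.voxel_size)
    if spec.anatomical_blur_fwhm > 0:
        from .recon import gaussian_post_filter

        anatomical = gaussian_post_filter(anatomical, spec.anatomical_blur_fwhm)
    return SubjectData(
        subject_id=subject_id,
        anatomical=anatomical,
        activity_truth=Image(act, spec.voxel_size),
        rois=ROISet(mask_T, mask_A, mask_B),
        label=spec.label,
        aneurysm_diameter=spec.aneurysm_diameter,
        spec=spec,
    )


@dataclass(frozen=True)
class CohortRanges:
    """Sampling ranges for cohort generation (uniform draws, units as in
    :class:`PhantomSpec`). The aneurysm-diameter default brackets a cohort
    mean near 49 mm; controls get normal-calibre aortas."""

    diameter_range: tuple[float, float] = (35.0, 65.0)
    control_diameter_range: tuple[float, float] = (18.0, 26.0)
    lesion_contrast_range: tuple[float, float] = (2.0, 4.0)
    lesion_count_range: tuple[int, int] = (1, 3)

    def __post_init__(self) -> None:
        for name in (
            "diameter_range",
            "control_diameter_range",
            "lesion_contrast_range",
            "lesion_count_range",
        ):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ConfigurationError(f"{name} is empty: {lo} > {hi}")
        if self.lesion_count_range[0] < 1:
            raise ConfigurationError("positive subjects need >= 1 lesion")


def generate_cohort(
    n_positive: int,
    n_control: int,
    ranges: CohortRanges | None = None,
    seed: int = 0,
    base_spec: PhantomSpec | None = None,
) -> list[SubjectData]:
    """Generate a cohort of positive subjects followed by controls.

    Positive subjects draw aneurysm diameter, lesion contrast and lesion
    count from ``ranges``; controls get a normal-calibre aorta and
    lesion_contrast = 1 (no focal uptake, label False). Deterministic per
    ``seed``; each subject receives its own placement seed.
    """
    if n_positive < 0 or n_control < 0:
        raise ConfigurationError("cohort sizes must be >= 0")
    ranges = ranges or CohortRanges()
    base = base_spec or PhantomSpec()
    rng = np.random.default_rng(seed)
    subjects: list[SubjectData] = []
    for i in range(n_positive + n_control):
        positive = i < n_positive
        dlo, dhi = (
            ranges.diameter_range if positive else ranges.control_diameter_range
        )
        diameter = rng.uniform(dlo, dhi)
        if positive:
            contrast = rng.uniform(*ranges.lesion_contrast_range)
            count = int(
                rng.integers(
                    ranges.lesion_count_range[0], ranges.lesion_count_range[1] + 1
                )
            )
        else:
            contrast, count = 1.0, 0  # no calcification at all in controls
        spec = replace(
            base,
            aneurysm_radius=diameter / 2.0,
            lesion_contrast=contrast,
            lesion_count=count,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        tag = "p" if positive else "c"
        subjects.append(generate_subject(spec, subject_id=f"{tag}{i:03d}"))
    return subjects
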