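"""ROI quantification: TBR_max, uptake increase, classification, CoV,
iteration selection and kernel-parameter sweep selection.

The clinical readout is the maximum target-to-blood-pool ratio

    TBR_max(T) = max(T) / mean(B)

for the aneurysm target ROI T and, analogously, for the non-aneurysmal aorta
ROI A, and the percentage uptake increase

    Increase = 100 * (TBR_max(T) - TBR_max(A)) / TBR_max(A).

An increase strictly above 25% classifies the subject as aneurysm-positive
(EORTC-style response threshold). Both quantities are invariant to any
positive rescaling of the image, so SUV calibration does not affect them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import ContractError, MetricError, SelectionError
from .images import Image

__all__ = [
    "ROISet",
    "CohortRecord",
    "tbr_max",
    "uptake_increase",
    "classify",
    "cov",
    "select_iteration",
    "select_kernel_params",
    "record_from_image",
]

EORTC_THRESHOLD = 25.0


@dataclass
class ROISet:
    """Boolean masks for the target AAA wall (T), non-AAA aorta (A) and
    blood pool / vena cava (B). Pairwise disjoint and each nonempty."""

    T: np.ndarray
    A: np.ndarray
    B: np.ndarray

    def __post_init__(self) -> None:
        self.T = np.asarray(self.T, dtype=bool)
        self.A = np.asarray(self.A, dtype=bool)
        self.B = np.asarray(self.B, dtype=bool)
        if not (self.T.shape == self.A.shape == self.B.shape):
            raise ContractError("ROI masks must share one grid")
        for name, mask in (("T", self.T), ("A", self.A), ("B", self.B)):
            if not mask.any():
                raise ContractError(f"ROI {name} is empty")
        if (
            (self.T & self.A).any()
            or (self.T & self.B).any()
            or (self.A & self.B).any()
        ):
            raise ContractError("ROI masks must be pairwise disjoint")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.T.shape


@dataclass
class CohortRecord:
    """One subject's quantification under one algorithm at one iteration."""

    subject_id: str
    tbr_T: float
    tbr_A: float
    increase: float
    predicted_positive: bool
    true_label: bool
    aneurysm_diameter: float
    algorithm: str = ""
    iteration: int = 0

    def __post_init__(self) -> None:
        if self.tbr_T <= 0 or self.tbr_A <= 0:
            raise ContractError("TBR values must be > 0")
        expected = uptake_increase(self.tbr_T, self.tbr_A)
        if not np.isclose(self.increase, expected, rtol=1e-9, atol=1e-9):
            raise ContractError(
                f"increase {self.increase} inconsistent with TBR fields "
                f"({expected:.6g} expected)"
            )


def _masked(values: np.ndarray, mask: np.ndarray, what: str) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != values.shape:
        raise MetricError(f"{what} mask shape {mask.shape} != image {values.shape}")
    if not mask.any():
        raise MetricError(f"{what} mask is empty")
    return values[mask]


def tbr_max(image: Image | np.ndarray, roi_T: np.ndarray, roi_B: np.ndarray) -> float:
    """max over T divided by mean over B (scale invariant)."""
    values = image.values if isinstance(image, Image) else np.asarray(image, float)
    t = _masked(values, roi_T, "T")
    b = _masked(values, roi_B, "B")
    denom = float(b.mean())
    if denom <= 0:
        raise MetricError(f"blood-pool mean must be > 0, got {denom}")
    return float(t.max()) / denom


def uptake_increase(tbr_T: float, tbr_A: float) -> float:
    """Percentage increase 100 * (TBR_T - TBR_A) / TBR_A."""
    if tbr_A <= 0:
        raise MetricError(f"TBR(A) must be > 0, got {tbr_A}")
    return 100.0 * (tbr_T - tbr_A) / tbr_A


def classify(increase: float, threshold: float = EORTC_THRESHOLD) -> bool:
    """Positive iff the increase is strictly higher than the threshold."""
    if not np.isfinite(threshold):
        raise MetricError("threshold must be finite")
    return bool(increase > threshold)


def cov(image: Image | np.ndarray, mask: np.ndarray) -> float:
    """Coefficient of variation over a mask: population std / mean."""
    values = image.values if isinstance(image, Image) else np.asarray(image, float)
    region = _masked(values, mask, "CoV")
    mean = float(region.mean())
    if mean <= 0:
        raise MetricError(f"CoV region mean must be > 0, got {mean}")
    return float(region.std()) / mean


def record_from_image(
    image: Image,
    rois: ROISet,
    subject_id: str,
    true_label: bool,
    aneurysm_diameter: float,
    algorithm: str = "",
    iteration: int = 0,
    threshold: float = EORTC_THRESHOLD,
) -> CohortRecord:
    """Quantify one reconstructed image into a cohort record."""
    t = tbr_max(image, rois.T, rois.B)
    a = tbr_max(image, rois.A, rois.B)
    inc = uptake_increase(t, a)
    return CohortRecord(
        subject_id=subject_id,
        tbr_T=t,
        tbr_A=a,
        increase=inc,
        predicted_positive=classify(inc, threshold),
        true_label=bool(true_label),
        aneurysm_diameter=float(aneurysm_diameter),
        algorithm=algorithm,
        iteration=int(iteration),
    )


def select_iteration(
    records_by_iteration: Mapping[int, Sequence[CohortRecord]],
) -> int:
    """Iteration with the highest true-positive count; ties -> earliest.

    A true positive is a subject with ``true_label`` whose prediction is
    positive.
    """
    if not records_by_iteration:
        raise ContractError("no iterations to select from")
    best_it, best_tp = None, -1
    for it in sorted(records_by_iteration):
        tp = sum(
            1
            for r in records_by_iteration[it]
            if r.true_label and r.predicted_positive
        )
        if tp > best_tp:
            best_it, best_tp = it, tp
    return best_it


def select_kernel_params(
    sweep_results: Sequence[tuple[object, float, float]],
    reference_cov: float,
    cov_tolerance: float = 0.10,
) -> object:
    """Sweep selection rule: highest TBR at (approximately) fixed CoV.

    ``sweep_results`` is a sequence of (params, tbr, cov). Candidates whose
    CoV lies within ``cov_tolerance`` (relative) of ``reference_cov``
    compete on TBR; ties keep the earliest candidate. If the band is empty a
    :class:`SelectionError` listing the nearest candidates is raised.
    """
    if not sweep_results:
        raise SelectionError("empty parameter sweep")
    if reference_cov <= 0:
        raise ContractError("reference_cov must be > 0")
    band = [
        (params, tbr, c)
        for params, tbr, c in sweep_results
        if abs(c - reference_cov) <= cov_tolerance * reference_cov
    ]
    if not band:
        nearest = sorted(sweep_results, key=lambda r: abs(r[2] - reference_cov))[:3]
        raise SelectionError(
            f"no sweep candidate within {cov_tolerance:.0%} of CoV "
            f"{reference_cov:.4g}; nearest: "
            + ", ".join(f"(cov={c:.4g}, tbr={t:.4g})" for _, t, c in nearest)
        )
    best = band[0]
    for cand in band[1:]:
        if cand[1] > best[1]:
            best = cand
    return best[0]
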