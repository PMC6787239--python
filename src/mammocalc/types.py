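"""Shared domain containers for the detection pipeline and the cohort statistics.

Coordinate convention throughout the package: (row, col), 0-based, origin at the
top-left of the image. Physical coordinates are in millimetres, obtained by
multiplying pixel coordinates by ``spacing_mm``.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "MammogramImage",
    "BreastMask",
    "EnhancedImage",
    "CandidateSpot",
    "Cluster",
    "ClusterSet",
    "SubjectRecord",
]


@dataclass
class MammogramImage:
    """A 2-D grayscale mammogram with physical pixel spacing.

    Parameters
    ----------
    pixels
        Non-negative intensity array. Film digitisers produce 8-16 bit data;
        intermediate pipeline stages store floats.
    spacing_mm
        Physical size of one pixel in mm. The reference film-digitiser
        geometry is 0.05 mm/pixel.
    bit_depth
        Nominal bit depth of the source data (informational for float stages).
    """

    pixels: np.ndarray
    spacing_mm: float = 0.05
    bit_depth: int = 16

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D array")
        if self.pixels.shape[0] < 64 or self.pixels.shape[1] < 64:
            raise ValueError("both image dimensions must be >= 64")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixels must be finite")
        if self.pixels.min() < 0:
            raise ValueError("intensities must be non-negative")
        if self.spacing_mm <= 0:
            raise ValueError("spacing_mm must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass
class BreastMask:
    """Binary breast-tissue mask on the same grid as its source image."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")
        if not self.mask.any():
            raise ValueError("mask must contain at least one foreground pixel")

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())


@dataclass
class EnhancedImage:
    """Band-pass enhanced image, values in [0, 1], with the DoG scales used."""

    pixels: np.ndarray
    dog_sigma_low_px: float
    dog_sigma_high_px: float
    spacing_mm: float = 0.05

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("enhanced pixels must be finite")
        if not 0 < self.dog_sigma_low_px < self.dog_sigma_high_px:
            raise ValueError("require 0 < sigma_low < sigma_high")


@dataclass
class CandidateSpot:
    """One putative microcalcification emitted by the detector.

    ``coords`` holds the (row, col) pixel coordinates of the component so the
    cleaning step can evaluate per-spot statistics (e.g. the ridge-response
    veto) without re-labelling the image.
    """

    centroid_rc: tuple[float, float]
    area_px: int
    eccentricity: float
    major_axis_px: float
    minor_axis_px: float
    mean_response: float
    blobness: float
    coords: np.ndarray = field(default_factory=lambda: np.empty((0, 2), dtype=int))

    def __post_init__(self) -> None:
        if self.area_px < 1:
            raise ValueError("area_px must be >= 1")
        if not 0.0 <= self.eccentricity <= 1.0:
            raise ValueError("eccentricity must be in [0, 1]")


@dataclass
class Cluster:
    """A group of spots accepted by DBSCAN."""

    member_indices: list[int]
    centroid_rc: tuple[float, float]
    hull_area_mm2: float


@dataclass
class ClusterSet:
    """Per-image grouping result: clusters, plus bookkeeping of discards."""

    clusters: list[Cluster]
    n_isolated_discarded: int = 0
    n_filtered_by_shape: int = 0

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def membership(self) -> list[list[int]]:
        return [list(c.member_indices) for c in self.clusters]


#: categorical levels accepted for SubjectRecord fields
HRT_LEVELS = ("never", "past", "current")
SMOKING_LEVELS = ("never", "ever")
DIABETES_LEVELS = ("no", "yes")
BREASTFEEDING_LEVELS = ("never", "ever")


@dataclass
class SubjectRecord:
    """One woman in the case-control study.

    ``mcc_total`` is the number of detected microcalcification clusters summed
    over the left and right MLO views. Reproductive fields that apply to
    parous women only (breastfeeding trio) may be None (missing).
    """

    subject_id: str
    status: str  # "case" or "control"
    age_yr: float
    bmi_kg_m2: float
    pd_percent: float
    hrt: str
    parity: int
    smoking: str
    diabetes: str
    age_menopause_yr: float
    breastfeeding: Optional[str] = None
    breastfeeding_months: Optional[float] = None
    age_first_birth_yr: Optional[float] = None
    mcc_left: int = 0
    mcc_right: int = 0

    def __post_init__(self) -> None:
        if self.status not in ("case", "control"):
            raise ValueError("status must be 'case' or 'control'")
        if self.hrt not in HRT_LEVELS:
            raise ValueError(f"hrt must be one of {HRT_LEVELS}")
        if self.smoking not in SMOKING_LEVELS:
            raise ValueError(f"smoking must be one of {SMOKING_LEVELS}")
        if self.diabetes not in DIABETES_LEVELS:
            raise ValueError(f"diabetes must be one of {DIABETES_LEVELS}")
        if self.breastfeeding is not None and self.breastfeeding not in BREASTFEEDING_LEVELS:
            raise ValueError(f"breastfeeding must be one of {BREASTFEEDING_LEVELS} or None")
        if not 0.0 <= self.pd_percent <= 100.0:
            raise ValueError("pd_percent must be in [0, 100]")
        if self.parity < 0:
            raise ValueError("parity must be >= 0")
        if self.mcc_left < 0 or self.mcc_right < 0:
            raise ValueError("per-breast cluster counts must be >= 0")

    @property
    def mcc_total(self) -> int:
        return self.mcc_left + self.mcc_right

    @property
    def is_case(self) -> int:
        return int(self.status == "case")
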