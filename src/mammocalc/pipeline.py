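"""End-to-end detection pipeline: image in, ClusterSet out.

Wires the stages in the published order: breast segmentation -> denoising
(opening + Anscombe-domain Wiener) -> cosine contrast stretch -> DoG band-pass
-> Hessian blob/ridge responses -> adaptive thresholding -> shape/ridge
filtering -> DBSCAN grouping.
"""
from __future__ import annotations

from dataclasses import dataclass

from . import cluster as cluster_mod
from . import detect as detect_mod
from . import enhance as enhance_mod
from . import preprocess as preprocess_mod
from .config import RunConfig
from .types import BreastMask, CandidateSpot, ClusterSet, MammogramImage

__all__ = ["PipelineResult", "detect_clusters"]


@dataclass
class PipelineResult:
    """Output of one image run, with per-stage counts for logging."""

    cluster_set: ClusterSet
    spots: list[CandidateSpot]       # spots surviving the shape filter
    n_candidates: int                # raw thresholded candidates
    removed_by_reason: dict[str, int]
    mask: BreastMask

    @property
    def n_clusters(self) -> int:
        return self.cluster_set.n_clusters


def detect_clusters(img: MammogramImage, config: RunConfig | None = None) -> PipelineResult:
    """Run the full detection chain on one mammogram."""
    cfg = config or RunConfig()
    sp = img.spacing_mm

    mask = preprocess_mod.segment_breast(
        img,
        n_classes=cfg.preprocess.n_classes,
        smooth_radius_px=cfg.preprocess.smooth_radius_px,
    )
    denoised = preprocess_mod.denoise(
        img,
        mask,
        window=cfg.preprocess.wiener_window,
        opening_radius_px=cfg.preprocess.opening_radius_px,
    )
    stretched = enhance_mod.cosine_stretch(denoised, mask)
    enhanced = enhance_mod.dog_filter(
        stretched,
        sigma_low_px=cfg.enhance.dog_sigma_low_mm / sp,
        sigma_high_px=cfg.enhance.dog_sigma_high_mm / sp,
        mask=mask,
    )
    blob_map, line_map = detect_mod.hessian_response(
        enhanced,
        sigma_px=cfg.detect.hog_sigma_mm / sp,
        line_ratio=cfg.detect.line_ratio,
        blobness_width=cfg.detect.blobness_width,
    )
    candidates = detect_mod.threshold_candidates(blob_map, mask, k_sigma=cfg.detect.k_sigma)
    survivors, removed = cluster_mod.shape_filter(
        candidates,
        min_area_px=cfg.cluster.min_area_px,
        max_area_px=cfg.cluster.max_area_px,
        max_eccentricity=cfg.cluster.max_eccentricity,
        line_map=line_map,
        line_veto=cfg.cluster.line_veto,
    )
    cluster_set = cluster_mod.dbscan_group(
        survivors,
        eps_mm=cfg.cluster.eps_mm,
        min_pts=cfg.cluster.min_pts,
        spacing_mm=sp,
        n_filtered_by_shape=sum(removed.values()),
    )
    return PipelineResult(
        cluster_set=cluster_set,
        spots=survivors,
        n_candidates=len(candidates),
        removed_by_reason=removed,
        mask=mask,
    )
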