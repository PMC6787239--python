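"""Image and result I/O: grayscale TIFF/PNG/PGM readers, mask/overlay writers."""
from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .types import BreastMask, ClusterSet, MammogramImage

__all__ = [
    "read_image",
    "write_mask_png",
    "write_float_tiff",
    "write_image_tiff",
    "cluster_set_to_dict",
    "write_cluster_json",
    "write_overlay_png",
    "spots_to_frame",
]


def read_image(path: str | Path, spacing_mm: float = 0.05) -> MammogramImage:
    """Read an 8/16-bit grayscale TIFF, PNG or PGM mammogram."""
    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:  # collapse any RGB(A) scan to luminance
        arr = arr[..., :3].mean(axis=-1)
    bit_depth = 16 if arr.dtype.itemsize >= 2 else 8
    return MammogramImage(pixels=arr.astype(float), spacing_mm=spacing_mm, bit_depth=bit_depth)


def write_mask_png(path: str | Path, mask: BreastMask) -> None:
    iio.imwrite(path, (mask.mask.astype(np.uint8) * 255))


def write_float_tiff(path: str | Path, pixels: np.ndarray) -> None:
    tifffile.imwrite(path, np.asarray(pixels, dtype=np.float32))


def write_image_tiff(path: str | Path, img: MammogramImage) -> None:
    tifffile.imwrite(path, np.clip(img.pixels, 0, 65535).astype(np.uint16))


def cluster_set_to_dict(
    image_id: str, result: ClusterSet, spacing_mm: float, config_hash: str = "", version: str = ""
) -> dict:
    return {
        "image_id": image_id,
        "n_clusters": result.n_clusters,
        "clusters": [
            {
                "centroid_mm": [c.centroid_rc[0] * spacing_mm, c.centroid_rc[1] * spacing_mm],
                "n_spots": len(c.member_indices),
                "hull_area_mm2": c.hull_area_mm2,
            }
            for c in result.clusters
        ],
        "n_isolated": result.n_isolated_discarded,
        "n_filtered": result.n_filtered_by_shape,
        "config_hash": config_hash,
        "version": version,
    }


def write_cluster_json(path: str | Path, payload: dict) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_overlay_png(path: str | Path, img: MammogramImage, spots, marker_px: int = 3) -> None:
    """8-bit grayscale render with magenta markers on detected spots."""
    pixels = np.asarray(img.pixels, dtype=float)
    lo, hi = pixels.min(), pixels.max()
    gray = np.zeros_like(pixels, dtype=np.uint8) if hi == lo else (
        (255 * (pixels - lo) / (hi - lo)).astype(np.uint8)
    )
    rgb = np.stack([gray, gray, gray], axis=-1)
    rows, cols = gray.shape
    for s in spots:
        r, c = int(round(s.centroid_rc[0])), int(round(s.centroid_rc[1]))
        rr = slice(max(r - marker_px, 0), min(r + marker_px + 1, rows))
        cc = slice(max(c - marker_px, 0), min(c + marker_px + 1, cols))
        rgb[rr, c, :] = (255, 0, 255)
        rgb[r, cc, :] = (255, 0, 255)
    iio.imwrite(path, rgb)


def spots_to_frame(image_id: str, spots) -> pd.DataFrame:
    """Candidate table: one row per spot, exportable as CSV."""
    return pd.DataFrame(
        {
            "image_id": image_id,
            "row": [s.centroid_rc[0] for s in spots],
            "col": [s.centroid_rc[1] for s in spots],
            "area_px": [s.area_px for s in spots],
            "eccentricity": [s.eccentricity for s in spots],
            "blobness": [s.blobness for s in spots],
        }
    )
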