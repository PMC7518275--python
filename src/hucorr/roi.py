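"""Circular-ROI statistics on simulated CT series and the contrast tables.

Measurements mirror the experimental protocol: a circular region of
interest concentric with an insert hole (shrunk to 70% of the hole radius
by default, keeping clear of edge partial-volume voxels), statistics pooled
over the eight slices nearest the axial midpoint, and per-condition means
averaged over repeated acquisitions.  Voxel membership is a centre-in-circle
test, matching common ROI tools.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .phantom import CTImage, PhantomSpec

__all__ = ["CircleROI", "ROIResult", "locate_hole_roi", "roi_stats", "central_slice_indices", "measurement_table"]

DEFAULT_SHRINK = 0.7
DEFAULT_CENTRAL_SLICES = 8


@dataclass(frozen=True)
class CircleROI:
    cx: float
    cy: float
    radius: float


@dataclass(frozen=True)
class ROIResult:
    mean_hu: float
    sd_hu: float
    n_voxels: int
    slices_used: tuple[int, ...]
    hole_index: int | None = None

    def __post_init__(self) -> None:
        if self.n_voxels <= 0:
            raise ValueError("n_voxels must be > 0")
        if self.sd_hu < 0:
            raise ValueError("sd_hu must be >= 0")
        if not self.slices_used:
            raise ValueError("slices_used must be non-empty")

    @property
    def se_hu(self) -> float:
        """Standard error of the ROI mean under independent voxel noise."""
        return self.sd_hu / np.sqrt(self.n_voxels)


def locate_hole_roi(spec: PhantomSpec, hole_index: int, shrink: float = DEFAULT_SHRINK) -> CircleROI:
    """Circle concentric with a hole, radius = shrink x hole radius."""
    if not (0.0 < shrink <= 1.0):
        raise ValueError("shrink must lie in (0, 1]")
    h = spec.hole(hole_index)  # raises for unknown holes
    return CircleROI(cx=h.cx, cy=h.cy, radius=shrink * h.radius)


def central_slice_indices(n_slices: int, central_slices: int) -> tuple[int, ...]:
    """The ``central_slices`` slice indices nearest the axial midpoint.

    On an even surplus the window is biased toward the inferior (low-index)
    side, e.g. 6 of 9 slices -> indices 1..6.
    """
    if central_slices < 1:
        raise ValueError("central_slices must be >= 1")
    if central_slices > n_slices:
        raise ValueError(f"{central_slices} central slices requested of a {n_slices}-slice image")
    start = (n_slices - central_slices) // 2
    return tuple(range(start, start + central_slices))


def roi_stats(img: CTImage, roi: CircleROI, central_slices: int = DEFAULT_CENTRAL_SLICES,
              hole_index: int | None = None) -> ROIResult:
    """Mean/SD over voxels whose centres fall in the circle, pooled across slices."""
    xs, ys = img.axis_coords()
    if (roi.cx - roi.radius < xs[0] or roi.cx + roi.radius > xs[-1]
            or roi.cy - roi.radius < ys[0] or roi.cy + roi.radius > ys[-1]):
        raise ValueError("ROI extends outside the image bounds")
    xg, yg = np.meshgrid(xs, ys)
    mask = (xg - roi.cx) ** 2 + (yg - roi.cy) ** 2 <= roi.radius**2
    if not mask.any():
        raise ValueError("ROI contains no voxel centres at this spacing")
    slices = central_slice_indices(img.n_slices, central_slices)
    voxels = img.values[list(slices)][:, mask].ravel()
    return ROIResult(
        mean_hu=float(voxels.mean()),
        sd_hu=float(voxels.std(ddof=1)) if voxels.size > 1 else 0.0,
        n_voxels=int(voxels.size),
        slices_used=slices,
        hole_index=hole_index,
    )


def _replicate_mean(images: Sequence[CTImage] | CTImage, roi: CircleROI,
                    central_slices: int, hole_index: int) -> tuple[float, float]:
    """Average ROI means over replicate images; returns (mean, standard error).

    The replicate means are averaged unweighted; the SE combines the
    per-replicate voxel-noise SEs (se_rep / sqrt(n_rep)).
    """
    imgs = [images] if isinstance(images, CTImage) else list(images)
    if not imgs:
        raise ValueError("no replicate images supplied")
    results = [roi_stats(im, roi, central_slices, hole_index) for im in imgs]
    means = np.array([r.mean_hu for r in results])
    ses = np.array([r.se_hu for r in results])
    return float(means.mean()), float(np.sqrt(np.mean(ses**2) / len(imgs)))


def measurement_table(
    images: Mapping[tuple[str, float, int, str], Sequence[CTImage] | CTImage],
    specs: Mapping[str, PhantomSpec],
    *,
    materials: Sequence[str] | None = None,
    kvps: Sequence[float] | None = None,
    contrasts: Sequence[str] = ("size", "depth"),
    shrink: float = DEFAULT_SHRINK,
    central_slices: int = DEFAULT_CENTRAL_SLICES,
) -> pd.DataFrame:
    """Assemble the tidy size/depth contrast table from simulated images.

    ``images`` maps (shape, kvp, insert_hole, material) to an image or a
    list of replicate images; ``specs`` maps shape name to its PhantomSpec.
    The "size" contrast is hole-6 large minus small; the "depth" contrast is
    hole-14 minus hole-6 within the large phantom.  Materials/kVps default
    to everything present in the keys.  A missing image for a requested
    contrast is a hard error listing the gap.

    Returns a DataFrame with columns material, kvp, contrast, delta_hu, se.
    """
    keys = list(images.keys())
    if materials is None:
        materials = sorted({k[3] for k in keys if k[3] != "water"})
    if kvps is None:
        kvps = sorted({k[1] for k in keys})

    def fetch(shape: str, kvp: float, hole: int, material: str):
        key = (shape, kvp, hole, material)
        if key not in images:
            raise ValueError(f"missing image for contrast: (shape={shape}, kvp={kvp:g}, hole={hole}, material={material})")
        return images[key]

    rows = []
    for contrast in contrasts:
        if contrast not in ("size", "depth"):
            raise ValueError(f"unknown contrast '{contrast}'; expected 'size' or 'depth'")
        for material in materials:
            for kvp in kvps:
                if contrast == "size":
                    roi_small = locate_hole_roi(specs["head"], 6, shrink)
                    roi_large = locate_hole_roi(specs["abdomen"], 6, shrink)
                    m1, se1 = _replicate_mean(fetch("head", kvp, 6, material), roi_small, central_slices, 6)
                    m2, se2 = _replicate_mean(fetch("abdomen", kvp, 6, material), roi_large, central_slices, 6)
                else:
                    roi_6 = locate_hole_roi(specs["abdomen"], 6, shrink)
                    roi_14 = locate_hole_roi(specs["abdomen"], 14, shrink)
                    m1, se1 = _replicate_mean(fetch("abdomen", kvp, 6, material), roi_6, central_slices, 6)
                    m2, se2 = _replicate_mean(fetch("abdomen", kvp, 14, material), roi_14, central_slices, 14)
                rows.append(
                    {
                        "material": material,
                        "kvp": kvp,
                        "contrast": contrast,
                        "delta_hu": m2 - m1,
                        "se": float(np.hypot(se1, se2)),
                    }
                )
    return pd.DataFrame(rows, columns=["material", "kvp", "contrast", "delta_hu", "se"])
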