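"""B-scan container, normalization, despeckling and target-region cropping.

The segmentation pipeline never classifies the whole frame: the air region
above the stratum corneum carries no anatomy, so a cheap gradient-based
detector finds the approximate air/SC interface and the frame is cropped to
a band around it (a few rows above, a fixed depth below).  All further
stages work in *region* coordinates; :class:`TargetRegion` records the
offset so traces can be mapped back exactly.

Coordinate convention: 0-based; row = axial depth increasing downward,
column = lateral position; regions are half-open ``[top, bottom)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import median_filter
from skimage.restoration import denoise_nl_means, estimate_sigma

__all__ = [
    "BScan",
    "TargetRegion",
    "normalize",
    "despeckle",
    "detect_air_boundary",
    "crop_target_region",
]

#: default physical pixel pitch (um per pixel)
AXIAL_PX_UM = 3.26
LATERAL_PX_UM = 4.0


@dataclass
class BScan:
    """One grayscale OCT B-scan with physical pixel spacing."""

    image: np.ndarray
    axial_px_um: float = AXIAL_PX_UM
    lateral_px_um: float = LATERAL_PX_UM
    source_id: str = ""

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image)
        if self.image.ndim != 2:
            raise ValueError(f"B-scan must be 2-D, got shape {self.image.shape}")

    @property
    def n_rows(self) -> int:
        return self.image.shape[0]

    @property
    def n_cols(self) -> int:
        return self.image.shape[1]

    def with_image(self, image: np.ndarray) -> "BScan":
        return BScan(
            image=image,
            axial_px_um=self.axial_px_um,
            lateral_px_um=self.lateral_px_um,
            source_id=self.source_id,
        )


@dataclass(frozen=True)
class TargetRegion:
    """Row band ``[row_top, row_bottom)`` retained from a parent B-scan."""

    row_top: int
    row_bottom: int
    parent_shape: tuple[int, int]

    def __post_init__(self) -> None:
        if not (0 <= self.row_top < self.row_bottom <= self.parent_shape[0]):
            raise ValueError(
                f"invalid region [{self.row_top}, {self.row_bottom}) for "
                f"parent of {self.parent_shape[0]} rows"
            )

    @property
    def height(self) -> int:
        return self.row_bottom - self.row_top

    def to_parent_rows(self, region_rows: np.ndarray) -> np.ndarray:
        """Map region row indices back to parent-image rows (exact inverse)."""
        return np.asarray(region_rows) + self.row_top

    def to_region_rows(self, parent_rows: np.ndarray) -> np.ndarray:
        return np.asarray(parent_rows) - self.row_top


def normalize(scan: BScan) -> BScan:
    """Min-max rescale intensities to [0, 1].

    Raises on constant or non-finite input, where the rescale is undefined.
    """
    img = np.asarray(scan.image, dtype=np.float64)
    if not np.isfinite(img).all():
        raise ValueError("B-scan contains non-finite values")
    lo, hi = img.min(), img.max()
    if hi == lo:
        raise ValueError("constant image: min-max normalization undefined")
    return scan.with_image((img - lo) / (hi - lo))


def despeckle(
    scan: BScan,
    patch_size: int = 7,
    patch_distance: int = 10,
    h_factor: float = 0.8,
) -> BScan:
    """Non-local-means speckle reduction.

    Filter strength ``h`` is tied to the estimated noise sigma
    (``h = h_factor * sigma``); the search window is
    ``2 * patch_distance + 1`` pixels (21 by default).
    """
    img = np.asarray(scan.image, dtype=np.float64)
    sigma = float(estimate_sigma(img))
    out = denoise_nl_means(
        img,
        patch_size=patch_size,
        patch_distance=patch_distance,
        h=max(h_factor * sigma, 1e-12),
        sigma=sigma,
        fast_mode=True,
    )
    return scan.with_image(np.clip(out, 0.0, 1.0))


def detect_air_boundary(
    scan: BScan,
    k_sigma: float = 3.0,
    smooth_window: int = 9,
) -> np.ndarray:
    """Approximate air/SC interface from the vertical intensity gradient.

    Per column, the trace is the first row (top-down) whose downward
    gradient exceeds an adaptive threshold ``median + k_sigma * std`` of
    that column's gradient; the trace is then median-filtered across
    columns.  The threshold adapts per column, so the detector is invariant
    to global affine intensity rescaling.
    """
    img = np.asarray(scan.image, dtype=np.float64)
    grad = np.diff(img, axis=0)  # grad[r] = img[r+1] - img[r]
    thresh = np.median(grad, axis=0) + k_sigma * grad.std(axis=0)
    above = grad > thresh[None, :]
    hit = above.any(axis=0)
    if not hit.all():
        bad = int(np.flatnonzero(~hit)[0])
        raise ValueError(
            f"no air/skin edge found in column {bad}: gradient never exceeds "
            "the adaptive threshold (is the image all air?)"
        )
    first = above.argmax(axis=0) + 1  # boundary row = one below the jump
    trace = median_filter(first, size=smooth_window, mode="nearest")
    return trace.astype(np.int64)


def crop_target_region(
    scan: BScan,
    air_trace: np.ndarray,
    margin_above: int = 10,
    depth_below: int = 300,
    min_height: int = 55,
) -> tuple[BScan, TargetRegion]:
    """Crop the row band that can contain both boundaries.

    ``row_top = max(0, min(air_trace) - margin_above)``;
    ``row_bottom = min(n_rows, max(air_trace) + depth_below)``.
    """
    air_trace = np.asarray(air_trace)
    if air_trace.min() < 0 or air_trace.max() >= scan.n_rows:
        raise ValueError("air trace leaves the image frame")
    row_top = int(max(0, air_trace.min() - margin_above))
    row_bottom = int(min(scan.n_rows, air_trace.max() + depth_below))
    region = TargetRegion(row_top, row_bottom, (scan.n_rows, scan.n_cols))
    if region.height < min_height:
        raise ValueError(
            f"target region of {region.height} rows is shorter than the "
            f"patch size ({min_height})"
        )
    return scan.with_image(scan.image[row_top:row_bottom]), region
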