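"""Per-class probability maps over the target region, with pixel-skip infill.

Predictions exist only at the evaluated (skip-sampled) centers; everywhere
else the maps hold 0 and the ``evaluated_mask`` is false.  The infill pass
fills each unevaluated pixel with the mean of its *evaluated* 4-neighbors
(the plus-shaped kernel mask ``[[0,1,0],[1,0,1],[0,1,0]]``); no additional
patches are ever classified, and the pass is single and non-iterative, so
the result is order-independent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ProbMaps", "assemble_maps", "infill_kernel"]


@dataclass
class ProbMaps:
    """Stack of per-class probability images plus the evaluated-pixel mask.

    ``maps`` has shape (n_classes, H, W); class indices follow the patch
    labels (0 non-boundary, 1 SC, 2 DEJ, 3 reserved).
    """

    maps: np.ndarray
    evaluated_mask: np.ndarray
    step: int = 1

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=np.float64)
        self.evaluated_mask = np.asarray(self.evaluated_mask, dtype=bool)
        if self.maps.ndim != 3 or self.maps.shape[1:] != self.evaluated_mask.shape:
            raise ValueError("maps and evaluated_mask shape mismatch")
        if self.maps.min() < -1e-9 or self.maps.max() > 1 + 1e-9:
            raise ValueError("probabilities must lie in [0, 1]")

    @property
    def region_shape(self) -> tuple[int, int]:
        return self.evaluated_mask.shape

    def class_map(self, class_id: int) -> np.ndarray:
        return self.maps[class_id]


def assemble_maps(
    predictions: np.ndarray,
    centers: np.ndarray,
    region_shape: tuple[int, int],
    step: int = 1,
) -> ProbMaps:
    """Scatter per-patch probability vectors onto the region grid."""
    predictions = np.asarray(predictions, dtype=np.float64)
    centers = np.asarray(centers, dtype=np.int64).reshape(-1, 2)
    if predictions.shape[0] != centers.shape[0]:
        raise ValueError(
            f"{predictions.shape[0]} predictions vs {centers.shape[0]} centers"
        )
    h, w = region_shape
    if centers.size:
        if (centers < 0).any() or (centers[:, 0] >= h).any() or (centers[:, 1] >= w).any():
            raise ValueError("center outside region")
    n_classes = predictions.shape[1]
    maps = np.zeros((n_classes, h, w), dtype=np.float64)
    mask = np.zeros((h, w), dtype=bool)
    maps[:, centers[:, 0], centers[:, 1]] = predictions.T
    mask[centers[:, 0], centers[:, 1]] = True
    return ProbMaps(maps=maps, evaluated_mask=mask, step=step)


def infill_kernel(maps: ProbMaps) -> ProbMaps:
    """Fill unevaluated pixels with the mean of their evaluated 4-neighbors.

    Evaluated pixels are never modified; unevaluated pixels with no evaluated
    4-neighbor stay 0 (cannot occur at skip steps <= 4 in raster order).
    The returned mask is all-true.
    """
    mask = maps.evaluated_mask
    if mask.all():
        return ProbMaps(maps=maps.maps.copy(), evaluated_mask=mask.copy(), step=maps.step)

    h, w = mask.shape
    neigh_sum = np.zeros_like(maps.maps)
    neigh_cnt = np.zeros((h, w), dtype=np.float64)
    m = mask.astype(np.float64)
    vals = maps.maps * m[None]
    # shift in the four cardinal directions (plus-shaped kernel)
    neigh_sum[:, 1:, :] += vals[:, :-1, :]
    neigh_cnt[1:, :] += m[:-1, :]
    neigh_sum[:, :-1, :] += vals[:, 1:, :]
    neigh_cnt[:-1, :] += m[1:, :]
    neigh_sum[:, :, 1:] += vals[:, :, :-1]
    neigh_cnt[:, 1:] += m[:, :-1]
    neigh_sum[:, :, :-1] += vals[:, :, 1:]
    neigh_cnt[:, :-1] += m[:, 1:]

    out = maps.maps.copy()
    fill = (~mask) & (neigh_cnt > 0)
    out[:, fill] = neigh_sum[:, fill] / neigh_cnt[fill][None]
    return ProbMaps(maps=out, evaluated_mask=np.ones_like(mask), step=maps.step)
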