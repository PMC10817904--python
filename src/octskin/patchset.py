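"""Labeled patch dictionaries for training and skip-sampled inference patchsets.

Each pixel of the target region is (conceptually) the center of one 55x55
patch; the patch class is decided by its *center pixel*: 1 on the SC trace,
2 on the DEJ trace, 0 elsewhere.  Borders are reflect-padded so boundary
pixels near the frame edge still own a full patch.

Pixel skipping builds the inference patchset from every ``step``-th pixel of
the region in row-major raster order, so the patchset shrinks to exactly
``ceil(N / step)`` patches (half at step 2, a quarter at step 4).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .preprocess import BScan

__all__ = [
    "PatchSpec",
    "PatchSet",
    "extract_training_patches",
    "balance_classes",
    "pixel_skip_centers",
    "extract_patches_at",
]


@dataclass(frozen=True)
class PatchSpec:
    """Patch geometry and label scheme of the patch classifier."""

    patch_size: int = 55
    n_model_outputs: int = 4  # softmax width; class 3 is reserved/unused
    class_labels: tuple[str, str, str] = ("non-boundary", "SC boundary", "DEJ boundary")

    def __post_init__(self) -> None:
        if self.patch_size % 2 == 0 or self.patch_size < 3:
            raise ValueError("patch_size must be odd and >= 3 (center pixel must exist)")
        if self.n_model_outputs < 3:
            raise ValueError("need at least 3 model outputs")

    @property
    def half(self) -> int:
        return self.patch_size // 2


@dataclass
class PatchSet:
    """A stack of square patches with center coordinates and optional labels."""

    centers: np.ndarray  # (n, 2) int — (row, col) in region coordinates
    patches: np.ndarray  # (n, patch_size, patch_size) float32
    spec: PatchSpec
    labels: np.ndarray | None = None  # (n,) int in {0,1,2}
    step: int = 1

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=np.int64).reshape(-1, 2)
        self.patches = np.asarray(self.patches, dtype=np.float32)
        if self.patches.shape[0] != self.centers.shape[0]:
            raise ValueError("patches and centers misaligned")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int64)
            if self.labels.shape[0] != self.centers.shape[0]:
                raise ValueError("labels and centers misaligned")
            if self.labels.size and not np.isin(self.labels, [0, 1, 2]).all():
                raise ValueError("labels must be in {0, 1, 2}")

    def __len__(self) -> int:
        return self.centers.shape[0]

    def class_counts(self) -> np.ndarray:
        if self.labels is None:
            raise ValueError("unlabeled patchset")
        return np.bincount(self.labels, minlength=3)

    def take(self, idx: np.ndarray) -> "PatchSet":
        return PatchSet(
            centers=self.centers[idx],
            patches=self.patches[idx],
            spec=self.spec,
            labels=None if self.labels is None else self.labels[idx],
            step=self.step,
        )


def _padded_windows(image: np.ndarray, patch_size: int) -> np.ndarray:
    """Reflect-pad and return a (H, W, p, p) view of all centered windows."""
    half = patch_size // 2
    padded = np.pad(image, half, mode="reflect")
    return sliding_window_view(padded, (patch_size, patch_size))


def label_centers(
    region_shape: tuple[int, int],
    trace_sc: np.ndarray,
    trace_dej: np.ndarray,
) -> np.ndarray:
    """Per-pixel class image: 1 on the SC trace, 2 on the DEJ trace, else 0."""
    h, w = region_shape
    trace_sc = np.asarray(trace_sc)
    trace_dej = np.asarray(trace_dej)
    if trace_sc.shape != (w,) or trace_dej.shape != (w,):
        raise ValueError("traces must have one row index per region column")
    for name, tr in (("SC", trace_sc), ("DEJ", trace_dej)):
        if tr.min() < 0 or tr.max() >= h:
            raise ValueError(f"{name} trace lies outside the region")
    lab = np.zeros((h, w), dtype=np.int64)
    cols = np.arange(w)
    lab[trace_sc, cols] = 1
    lab[trace_dej, cols] = 2
    return lab


def extract_training_patches(
    region: BScan,
    trace_sc: np.ndarray,
    trace_dej: np.ndarray,
    spec: PatchSpec | None = None,
    seed: int = 0,
    balance: bool = True,
    max_per_class: int | None = None,
) -> PatchSet:
    """Build the labeled patch dictionary for one region.

    Every pixel is a candidate patch center; labels follow the center-pixel
    rule.  With ``balance=True`` (default) the returned set is class-balanced
    by seeded subsampling (see :func:`balance_classes`); patch pixel data are
    only materialized for the selected centers, so balancing first keeps
    memory proportional to the balanced set.
    """
    spec = spec or PatchSpec()
    img = np.asarray(region.image, dtype=np.float32)
    lab_img = label_centers(img.shape, trace_sc, trace_dej)
    rows, cols = np.indices(img.shape)
    centers = np.stack([rows.ravel(), cols.ravel()], axis=1)
    labels = lab_img.ravel()

    if balance:
        counts = np.bincount(labels, minlength=3)
        if (counts == 0).any():
            missing = int(np.flatnonzero(counts == 0)[0])
            raise ValueError(f"class {missing} absent; cannot balance")
        n_keep = int(counts.min())
        if max_per_class is not None:
            n_keep = min(n_keep, max_per_class)
        rng = np.random.default_rng(seed)
        keep = []
        for c in range(3):
            members = np.flatnonzero(labels == c)
            keep.append(rng.choice(members, size=n_keep, replace=False))
        sel = np.sort(np.concatenate(keep))
        centers, labels = centers[sel], labels[sel]

    windows = _padded_windows(img, spec.patch_size)
    patches = windows[centers[:, 0], centers[:, 1]]
    return PatchSet(centers=centers, patches=patches, spec=spec, labels=labels, step=1)


def balance_classes(patches: PatchSet, seed: int = 0) -> PatchSet:
    """Equalize class counts by seeded subsampling without replacement.

    All three classes are reduced to the minority-class count; original
    ordering is preserved among kept patches.
    """
    if patches.labels is None:
        raise ValueError("cannot balance an unlabeled patchset")
    counts = patches.class_counts()
    if (counts == 0).any():
        missing = int(np.flatnonzero(counts == 0)[0])
        raise ValueError(f"class {missing} absent; cannot balance")
    n_keep = int(counts.min())
    rng = np.random.default_rng(seed)
    keep = []
    for c in range(3):
        members = np.flatnonzero(patches.labels == c)
        keep.append(rng.choice(members, size=n_keep, replace=False))
    sel = np.sort(np.concatenate(keep))
    return patches.take(sel)


def pixel_skip_centers(region_shape: tuple[int, int], step: int = 1) -> np.ndarray:
    """Centers of every ``step``-th pixel in row-major raster order.

    The count is exactly ``ceil(H * W / step)``: a single skipping sequence
    over the flattened region (not a 2-D grid stride, which would give
    ``1/step**2``).
    """
    if step < 1:
        raise ValueError("step must be >= 1")
    h, w = region_shape
    flat = np.arange(0, h * w, step)
    return np.stack(np.unravel_index(flat, (h, w)), axis=1).astype(np.int64)


def extract_patches_at(
    region: BScan,
    centers: np.ndarray,
    spec: PatchSpec | None = None,
    step: int = 1,
) -> PatchSet:
    """Materialize (unlabeled) patches at the given centers for inference."""
    spec = spec or PatchSpec()
    img = np.asarray(region.image, dtype=np.float32)
    centers = np.asarray(centers, dtype=np.int64).reshape(-1, 2)
    if centers.size:
        if centers.min() < 0 or (centers[:, 0] >= img.shape[0]).any() or (
            centers[:, 1] >= img.shape[1]
        ).any():
            raise ValueError("center outside region")
    windows = _padded_windows(img, spec.patch_size)
    patches = windows[centers[:, 0], centers[:, 1]]
    return PatchSet(centers=centers, patches=patches, spec=spec, labels=None, step=step)
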