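"""Synthetic skin-OCT B-scan phantoms with known boundary ground truth.

A phantom emulates the gross appearance of a dermatological OCT B-scan:
a dark air region on top, a bright specular line at the air / stratum
corneum (SC) interface, a darker epidermis band, and a brighter dermis
below the dermal-epidermal junction (DEJ).  Multiplicative gamma speckle
and a Gaussian blur give the image OCT-like texture.  Both boundary
traces are returned exactly, so every downstream stage can be scored
against known truth.

The default frame is 460 rows x 1500 columns at 3.26 um axial x 4 um
lateral pixel pitch, the geometry of a typical swept-source skin OCT
B-scan.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter, gaussian_filter1d

from .preprocess import BScan

logger = logging.getLogger(__name__)

__all__ = ["PhantomConfig", "generate_phantom", "generate_cohort", "split_indices"]


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, optical levels and noise of one synthetic B-scan.

    Intensities are reflectance levels in [0, 1].  ``speckle_shape`` is the
    shape parameter of the unit-mean gamma multiplier (larger = less
    speckle); ``blur_sigma`` is the PSF surrogate in pixels.
    """

    height: int = 460
    width: int = 1500
    sc_depth_mean: float = 80.0
    et_mean: float = 60.0
    curvature_amplitude: float = 8.0
    curvature_period: float = 500.0
    intensity_air: float = 0.05
    intensity_sc_line: float = 0.95
    intensity_epidermis: float = 0.40
    intensity_dermis: float = 0.65
    speckle_shape: float = 8.0
    blur_sigma: float = 1.0
    sc_line_px: int = 2
    walk_sigma: float = 0.3
    seed: int = 0

    @classmethod
    def for_frame(cls, height: int, width: int, **overrides) -> "PhantomConfig":
        """Defaults rescaled from the 460 x 1500 reference frame.

        Axial depths (SC depth, ET, curvature amplitude) scale with height,
        the curvature period with width, so small frames stay anatomically
        proportioned.
        """
        ref = cls()
        ry, rx = height / ref.height, width / ref.width
        scaled = dict(
            height=height,
            width=width,
            sc_depth_mean=ref.sc_depth_mean * ry,
            et_mean=ref.et_mean * ry,
            curvature_amplitude=ref.curvature_amplitude * ry,
            curvature_period=max(ref.curvature_period * rx, 8.0),
        )
        scaled.update(overrides)
        return cls(**scaled)

    def validate(self) -> None:
        if self.height <= 0 or self.width <= 0:
            raise ValueError("phantom frame must have positive height and width")
        if not (0 < self.sc_depth_mean < self.sc_depth_mean + self.et_mean < self.height):
            raise ValueError(
                "invalid geometry: need 0 < sc_depth_mean < sc_depth_mean + et_mean "
                f"< height, got sc_depth_mean={self.sc_depth_mean}, "
                f"et_mean={self.et_mean}, height={self.height}"
            )
        for name in ("intensity_air", "intensity_sc_line", "intensity_epidermis", "intensity_dermis"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not self.intensity_air < self.intensity_sc_line:
            raise ValueError("intensity_air must be below intensity_sc_line")
        if self.speckle_shape <= 0:
            raise ValueError("speckle_shape must be positive")
        if self.sc_line_px < 1:
            raise ValueError("sc_line_px must be >= 1")


def _smooth_walk(rng: np.random.Generator, n: int, sigma: float) -> np.ndarray:
    """Zero-mean smooth random walk used to perturb boundary traces."""
    if sigma <= 0:
        return np.zeros(n)
    steps = rng.normal(0.0, sigma, size=n)
    walk = np.cumsum(steps)
    walk = gaussian_filter1d(walk, max(n / 50.0, 1.0), mode="nearest")
    return walk - walk.mean()


def _boundary_traces(config: PhantomConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    cols = np.arange(config.width)
    if config.curvature_amplitude > 0:
        phase = rng.uniform(0, 2 * math.pi)
        sinus = config.curvature_amplitude * np.sin(
            2 * math.pi * cols / config.curvature_period + phase
        )
        walk_sc = _smooth_walk(rng, config.width, config.walk_sigma)
        walk_dej = _smooth_walk(rng, config.width, config.walk_sigma)
    else:
        sinus = np.zeros(config.width)
        walk_sc = np.zeros(config.width)
        walk_dej = np.zeros(config.width)
        rng.uniform(0, 2 * math.pi)  # keep the stream layout stable

    sc = config.sc_depth_mean + sinus + walk_sc
    dej = sc + config.et_mean + walk_dej

    sc = np.clip(np.rint(sc), 1, config.height - 3).astype(np.int64)
    dej = np.clip(np.rint(dej), 2, config.height - 2).astype(np.int64)
    dej = np.maximum(dej, sc + 1)  # strict ordering in every column
    if (sc <= 0).any() or (dej >= config.height).any():
        raise ValueError("boundaries out of frame; reduce curvature or depths")
    return sc, dej


def generate_phantom(config: PhantomConfig) -> tuple[BScan, np.ndarray, np.ndarray]:
    """Render one phantom B-scan plus its exact SC and DEJ traces.

    Returns
    -------
    scan : BScan
        Float image in [0, 1], shape ``(height, width)``.
    trace_sc, trace_dej : ndarray of int
        Per-column row index of each boundary; ``trace_sc < trace_dej``
        everywhere.  ``trace_sc`` is the first SC-line row, ``trace_dej``
        the first dermis row.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    sc, dej = _boundary_traces(config, rng)

    rows = np.arange(config.height)[:, None]
    img = np.full((config.height, config.width), config.intensity_air, dtype=np.float64)
    img[rows >= sc[None, :]] = config.intensity_sc_line
    img[rows >= (sc + config.sc_line_px)[None, :]] = config.intensity_epidermis
    img[rows >= dej[None, :]] = config.intensity_dermis

    if np.isfinite(config.speckle_shape):  # inf = noise-free phantom
        speckle = rng.gamma(config.speckle_shape, 1.0 / config.speckle_shape, size=img.shape)
        img = img * speckle
    if config.blur_sigma > 0:
        img = gaussian_filter(img, config.blur_sigma, mode="nearest")
    img = np.clip(img, 0.0, 1.0)

    scan = BScan(image=img, source_id=f"phantom-seed{config.seed}")
    return scan, sc, dej


def split_indices(n: int, train_frac: float = 0.70, val_frac: float = 0.15) -> dict[str, list[int]]:
    """Deterministic train/val/test split of ``range(n)``.

    Sizes round half-down for train and val; the remainder goes to test
    (n=10 gives 7/1/2).  Degenerate cohorts (empty val or test) are allowed
    with a warning.
    """
    n_train = max(0, math.ceil(train_frac * n - 0.5))
    n_val = max(0, math.ceil(val_frac * n - 0.5))
    n_train = min(n_train, n)
    n_val = min(n_val, n - n_train)
    n_test = n - n_train - n_val
    if n_val == 0 or n_test == 0:
        logger.warning("degenerate split for n=%d: train/val/test = %d/%d/%d", n, n_train, n_val, n_test)
    idx = list(range(n))
    return {
        "train": idx[:n_train],
        "val": idx[n_train : n_train + n_val],
        "test": idx[n_train + n_val :],
    }


@dataclass
class Cohort:
    """A deterministic collection of phantoms with a train/val/test split."""

    scans: list[BScan]
    traces_sc: list[np.ndarray]
    traces_dej: list[np.ndarray]
    configs: list[PhantomConfig]
    splits: dict[str, list[int]] = field(default_factory=dict)

    def subset(self, name: str) -> list[tuple[BScan, np.ndarray, np.ndarray]]:
        return [(self.scans[i], self.traces_sc[i], self.traces_dej[i]) for i in self.splits[name]]


def generate_cohort(
    n_images: int,
    config_ranges: dict[str, tuple[float, float]] | None = None,
    seed: int = 0,
    base_config: PhantomConfig | None = None,
    train_frac: float = 0.70,
    val_frac: float = 0.15,
) -> Cohort:
    """Generate ``n_images`` phantoms with per-image parameters drawn from ranges.

    ``config_ranges`` maps PhantomConfig field names to ``(low, high)``
    uniform ranges (e.g. ``{"et_mean": (40, 80)}``).  Every image gets its
    own seed derived from ``seed``, so the cohort is reproducible as a whole.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    base = base_config or PhantomConfig()
    config_ranges = config_ranges or {}
    int_fields = {"height", "width", "sc_line_px"}
    for name, rng_pair in config_ranges.items():
        if not hasattr(base, name):
            raise ValueError(f"unknown PhantomConfig field {name!r}")
        lo, hi = rng_pair
        if hi < lo:
            raise ValueError(f"empty range for {name!r}: ({lo}, {hi})")

    master = np.random.default_rng(seed)
    scans, traces_sc, traces_dej, configs = [], [], [], []
    for i in range(n_images):
        overrides: dict[str, float | int] = {}
        for name, (lo, hi) in sorted(config_ranges.items()):
            val = master.uniform(lo, hi)
            overrides[name] = int(round(val)) if name in int_fields else float(val)
        overrides["seed"] = int(master.integers(0, 2**31 - 1))
        cfg = replace(base, **overrides)
        scan, sc, dej = generate_phantom(cfg)
        scan.source_id = f"phantom-{i:04d}"
        scans.append(scan)
        traces_sc.append(sc)
        traces_dej.append(dej)
        configs.append(cfg)
    return Cohort(
        scans=scans,
        traces_sc=traces_sc,
        traces_dej=traces_dej,
        configs=configs,
        splits=split_indices(n_images, train_frac, val_frac),
    )
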