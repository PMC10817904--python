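"""Readers and writers: grayscale images, boundary-trace CSV/JSON, manifests.

Images round-trip as 8-bit PNG or 16-bit grayscale TIFF; floating-point
images in [0, 1] are scaled to the full integer range on write and back to
[0, 1] on read.  Trace files are 0-based, column-indexed CSV
(``column,row`` or ``column,row_sc,row_dej``).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml
from PIL import Image

from .boundary_graph import BoundaryTrace
from .preprocess import BScan

__all__ = [
    "read_bscan",
    "write_bscan",
    "write_trace_csv",
    "read_trace_csv",
    "write_traces_csv",
    "read_traces_csv",
    "write_trace_json",
    "write_manifest",
    "read_manifest",
    "render_overlay",
]


def read_bscan(path: str | Path, **meta) -> BScan:
    """Read a grayscale PNG/TIFF B-scan; integer data are scaled to [0, 1]."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image not found: {path}")
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(Image.open(path))
    if arr.ndim == 3:  # collapse accidental RGB
        arr = arr.mean(axis=2)
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(np.float64) / np.iinfo(arr.dtype).max
    return BScan(image=arr.astype(np.float64), source_id=path.stem, **meta)


def write_bscan(scan: BScan, path: str | Path) -> Path:
    """Write as 16-bit TIFF or 8-bit PNG depending on the suffix."""
    path = Path(path)
    img = np.clip(np.asarray(scan.image, dtype=np.float64), 0.0, 1.0)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, (img * 65535).round().astype(np.uint16))
    elif path.suffix.lower() == ".png":
        Image.fromarray((img * 255).round().astype(np.uint8), mode="L").save(path)
    else:
        raise ValueError(f"unsupported image suffix {path.suffix!r} (use .png/.tif)")
    return path


def write_trace_csv(trace, path: str | Path, column_name: str = "row") -> Path:
    rows = np.asarray(trace)
    pd.DataFrame({"column": np.arange(rows.size), column_name: rows}).to_csv(path, index=False)
    return Path(path)


def read_trace_csv(path: str | Path, column_name: str = "row") -> np.ndarray:
    df = pd.read_csv(path).sort_values("column")
    return df[column_name].to_numpy(dtype=np.int64)


def write_traces_csv(trace_sc, trace_dej, path: str | Path) -> Path:
    """Both boundaries of one image: ``column,row_sc,row_dej``."""
    sc, dej = np.asarray(trace_sc), np.asarray(trace_dej)
    pd.DataFrame(
        {"column": np.arange(sc.size), "row_sc": sc, "row_dej": dej}
    ).to_csv(path, index=False)
    return Path(path)


def read_traces_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path).sort_values("column")
    return df["row_sc"].to_numpy(np.int64), df["row_dej"].to_numpy(np.int64)


def write_trace_json(trace: BoundaryTrace, path: str | Path, provenance: dict | None = None) -> Path:
    payload = {
        "class_id": int(trace.class_id),
        "rows": [int(r) for r in trace.rows],
        "provenance": trace.provenance,
    }
    if provenance:
        payload["run"] = provenance
    Path(path).write_text(json.dumps(payload, indent=1))
    return Path(path)


def write_manifest(manifest: dict, path: str | Path) -> Path:
    Path(path).write_text(yaml.safe_dump(manifest, sort_keys=False))
    return Path(path)


def read_manifest(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text())


def render_overlay(scan: BScan, traces: dict[str, np.ndarray], path: str | Path) -> Path:
    """Paint boundary traces onto the B-scan and save an RGB PNG."""
    colors = {"sc": (255, 64, 64), "dej": (64, 160, 255)}
    img = np.clip(np.asarray(scan.image, dtype=np.float64), 0, 1)
    rgb = np.repeat((img * 255).astype(np.uint8)[:, :, None], 3, axis=2)
    for i, (name, trace) in enumerate(traces.items()):
        rows = np.clip(np.asarray(trace), 0, scan.n_rows - 1)
        color = colors.get(name.lower(), (0, 255, 0))
        rgb[rows, np.arange(rows.size)] = color
    Image.fromarray(rgb, mode="RGB").save(path)
    return Path(path)
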