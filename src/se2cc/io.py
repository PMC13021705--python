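"""Readers and writers for the package's on-disk formats.

Point clouds travel as CSV with header ``x,y,theta`` (radians).  Lifted
fields are stored as NPY arrays with axis order (x, y, theta) plus a JSON
sidecar holding the grid specification.  Label fields are written as 16-bit
multi-page TIFF (one page per orientation layer) with a CSV summary, and 2D
projections as indexed PNG.  Images are 8/16-bit grayscale PNG or TIFF,
normalized to [0, 1] on read.

Note the axis convention: in-memory 2D arrays are indexed (x, y); image
files store rows as y, so reads and writes transpose.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .fields import LabelField, LiftedBinarySet, LiftedField
from .se2 import LiftedGrid


def read_point_cloud(path) -> np.ndarray:
    """Read an (n, 3) SE(2) point cloud from CSV with header x,y,theta."""
    df = pd.read_csv(path)
    missing = {"x", "y", "theta"} - set(df.columns)
    if missing:
        raise ValueError(f"point-cloud CSV misses columns: {sorted(missing)}")
    return df[["x", "y", "theta"]].to_numpy(dtype=float)


def write_point_cloud(path, points: np.ndarray) -> None:
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    pd.DataFrame(pts, columns=["x", "y", "theta"]).to_csv(path, index=False)


def read_image(path) -> np.ndarray:
    """Read a grayscale image, normalize to [0, 1], return indexed (x, y)."""
    arr = np.asarray(iio.imread(path)).astype(float)
    if arr.ndim == 3:
        arr = arr.mean(axis=2)
    peak = arr.max()
    if peak > 0:
        arr = arr / peak
    return arr.T  # file rows are y; in-memory axis 0 is x


def write_image(path, image: np.ndarray) -> None:
    """Write an (x, y)-indexed float array in [0, 1] as 8-bit grayscale."""
    img = np.clip(np.asarray(image, dtype=float), 0.0, 1.0)
    iio.imwrite(path, (img.T * 255).astype(np.uint8))


def write_lifted_field(path, field: LiftedField) -> None:
    """NPY array + JSON sidecar with the grid spec."""
    path = Path(path)
    np.save(path, field.values)
    sidecar = path.with_suffix(".json")
    g = field.grid
    sidecar.write_text(json.dumps({
        "axes": ["x", "y", "theta"],
        "Nx": g.Nx, "Ny": g.Ny, "No": g.No, "dx": g.dx, "dy": g.dy,
    }, indent=2))


def read_lifted_field(path) -> LiftedField:
    path = Path(path)
    values = np.load(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    grid = LiftedGrid(Nx=meta["Nx"], Ny=meta["Ny"], No=meta["No"],
                      dx=meta.get("dx", 1.0), dy=meta.get("dy", 1.0))
    return LiftedField(grid, values)


def write_labels(path, labels: LabelField, diagnostics=None) -> None:
    """Multi-page 16-bit TIFF (one page per theta layer) + CSV summary."""
    path = Path(path)
    pages = np.transpose(labels.labels.astype(np.uint16), (2, 1, 0))  # k,y,x
    tifffile.imwrite(path, pages)
    rows = []
    sizes = labels.component_sizes()
    iters = getattr(diagnostics, "iterations", None)
    for c in range(labels.K):
        rows.append({"label": c + 1, "node_count": int(sizes[c]),
                     "iterations": (iters[c] if iters is not None
                                    and c < len(iters) else "")})
    pd.DataFrame(rows, columns=["label", "node_count", "iterations"]).to_csv(
        path.with_suffix(".csv"), index=False)


def read_labels(path) -> LabelField:
    pages = tifffile.imread(path)
    arr = np.transpose(np.atleast_3d(pages), (2, 1, 0)).astype(np.int32)
    No = arr.shape[2]
    grid = LiftedGrid(Nx=arr.shape[0], Ny=arr.shape[1], No=No)
    return LabelField(grid, arr)


def write_projection_png(path, labels_2d: np.ndarray) -> None:
    """Indexed 8-bit PNG of a 2D label projection (palette by label id)."""
    lab = np.asarray(labels_2d)
    if lab.max() > 255:
        raise ValueError("more than 255 labels; use the TIFF output")
    iio.imwrite(path, lab.T.astype(np.uint8))


def write_affinity_csv(path, A, component_ids=None) -> None:
    values = A.values if hasattr(A, "values") else np.asarray(A)
    ids = component_ids or [str(i + 1) for i in range(values.shape[0])]
    pd.DataFrame(values, index=ids, columns=ids).to_csv(path)


def write_persistence_csv(path, pairs) -> None:
    pd.DataFrame([{"component": p.component, "birth": p.birth,
                   "death": p.death} for p in pairs]).to_csv(path, index=False)


def write_sweep_csv(path, sw) -> None:
    pd.DataFrame({"delta": sw.deltas, "K": sw.counts}).to_csv(path,
                                                              index=False)


def write_provenance(path, config: dict, extra: dict | None = None) -> None:
    """JSON run record: config, package and dependency versions."""
    import hashlib

    import scipy
    import skimage

    from . import __version__
    blob = json.dumps(config, sort_keys=True, default=str)
    record = {
        "config": config,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "versions": {"se2cc": __version__, "numpy": np.__version__,
                     "scipy": scipy.__version__,
                     "scikit-image": skimage.__version__},
    }
    if extra:
        record.update(extra)
    Path(path).write_text(json.dumps(record, indent=2, default=str))
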