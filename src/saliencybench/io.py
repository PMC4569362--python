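"""On-disk formats: CSV point tables, grayscale PNG maps, JSON catalogs.

Point tables are UTF-8 CSV with the header
``image_id,observer_id,task,x,y,ordinal``.  Saliency maps and object masks
are single-channel PNG (8- or 16-bit); pixel values are scaled to [0, 1] on
read by dividing by the bit-depth maximum, and raw integers are never
exposed downstream.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .datatypes import (
    FormatError,
    ImageCatalog,
    PointTable,
    SaliencyMap,
    ValidationError,
    POINT_COLUMNS,
)


def read_point_table(path, catalog: ImageCatalog | None = None) -> PointTable:
    """Read a CSV point table, optionally validating coordinates.

    Raises :class:`FormatError` on a missing column and
    :class:`ValidationError` (naming the row) on an out-of-bounds point.
    """
    try:
        df = pd.read_csv(path, dtype={"image_id": str, "observer_id": str, "task": str})
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"cannot parse point table {path}: {exc}") from exc
    table = PointTable(df)
    if catalog is not None:
        table.validate_against(catalog)
    return table


def write_point_table(table: PointTable, path) -> None:
    """Write a point table as CSV; round-trips exactly through read."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.frame.loc[:, list(POINT_COLUMNS)].to_csv(path, index=False)


def read_map(path, image_id: str, algorithm_id: str = "") -> SaliencyMap:
    """Read a grayscale PNG as a SaliencyMap with values scaled to [0, 1]."""
    img = Image.open(path)
    if img.mode == "L":
        scale = 255.0
    elif img.mode in ("I;16", "I;16B", "I"):
        scale = 65535.0
    else:
        raise FormatError(
            f"{path}: expected single-channel grayscale PNG, got mode {img.mode!r}"
        )
    grid = np.asarray(img, dtype=float) / scale
    return SaliencyMap(image_id=image_id, grid=grid, algorithm_id=algorithm_id)


def write_map(smap: SaliencyMap, path, depth: int = 16) -> None:
    """Write a [0, 1]-valued map as an 8- or 16-bit grayscale PNG."""
    grid = smap.grid
    if grid.min() < 0.0 or grid.max() > 1.0:
        raise ValidationError(
            f"map values must lie in [0, 1] before writing "
            f"(got range [{grid.min():.4g}, {grid.max():.4g}]); rescale first"
        )
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if depth == 8:
        img = Image.fromarray(np.round(grid * 255.0).astype(np.uint8), mode="L")
    elif depth == 16:
        img = Image.fromarray(np.round(grid * 65535.0).astype(np.uint16))
    else:
        raise ValueError(f"depth must be 8 or 16, got {depth}")
    img.save(path, format="PNG")


def read_mask(path) -> np.ndarray:
    """Read a binary object mask: any non-zero pixel counts as foreground."""
    smap = read_map(path, image_id="mask")
    return smap.grid > 0.5


def write_mask(mask: np.ndarray, path) -> None:
    write_map(SaliencyMap("mask", mask.astype(float)), path, depth=8)


def read_catalog(path) -> ImageCatalog:
    """Read a JSON catalog ``{image_id: [width, height]}``."""
    with open(path, encoding="utf-8") as fh:
        raw = json.load(fh)
    return ImageCatalog({k: (int(v[0]), int(v[1])) for k, v in raw.items()})


def write_catalog(catalog: ImageCatalog, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {k: [int(w), int(h)] for k, (w, h) in catalog.sizes.items()}
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def export_real_map(smap: SaliencyMap, path, depth: int = 16) -> None:
    """Export an arbitrary-range map as PNG + JSON sidecar.

    De-biased maps take values outside [0, 1]; they are min-max rescaled for
    the PNG and the affine transform is recorded in ``<path>.json`` so the
    original values are recoverable as ``lo + pixel * (hi - lo)``.
    """
    lo = float(smap.grid.min())
    hi = float(smap.grid.max())
    span = hi - lo
    rescaled = (smap.grid - lo) / span if span > 0 else np.zeros_like(smap.grid)
    write_map(SaliencyMap(smap.image_id, rescaled, smap.algorithm_id), path, depth=depth)
    sidecar = {"image_id": smap.image_id, "algorithm_id": smap.algorithm_id,
               "min": lo, "max": hi}
    with open(str(path) + ".json", "w", encoding="utf-8") as fh:
        json.dump(sidecar, fh, indent=2, sort_keys=True)
        fh.write("\n")


def import_real_map(path, image_id: str, algorithm_id: str = "") -> SaliencyMap:
    """Inverse of :func:`export_real_map`: PNG + sidecar back to real values."""
    smap = read_map(path, image_id, algorithm_id)
    with open(str(path) + ".json", encoding="utf-8") as fh:
        sidecar = json.load(fh)
    lo, hi = sidecar["min"], sidecar["max"]
    return SaliencyMap(image_id, lo + smap.grid * (hi - lo), algorithm_id)
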