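"""Core in-memory containers shared by every other module.

Coordinate convention (used everywhere in this package): 0-based integer
pixel coordinates, ``x`` = column index, ``y`` = row index; 2-D grids are
indexed ``grid[y, x]`` (row, col).  Point sets are ``(n, 2)`` integer arrays
with columns ``(x, y)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: The four perceptual tasks: three gaze tasks recorded with an eye tracker
#: and one manual selection task ("most salient location", no eye tracking).
TASKS = ("free_view", "object_search", "saliency_view", "explicit_judgment")

POINT_COLUMNS = ("image_id", "observer_id", "task", "x", "y", "ordinal")


class ValidationError(ValueError):
    """Raised when data violates a structural invariant."""


class FormatError(ValueError):
    """Raised when an on-disk file does not match the expected format."""


@dataclass(frozen=True)
class ImageCatalog:
    """Registry of image dimensions, ``image_id -> (width, height)``."""

    sizes: Mapping[str, tuple[int, int]]

    def __post_init__(self) -> None:
        for image_id, (w, h) in self.sizes.items():
            if w < 1 or h < 1:
                raise ValidationError(
                    f"image {image_id!r}: width/height must be >= 1, got {(w, h)}"
                )

    def shape(self, image_id: str) -> tuple[int, int]:
        """Return ``(height, width)`` — the numpy grid shape — for an image."""
        if image_id not in self.sizes:
            raise KeyError(f"unknown image_id {image_id!r}")
        w, h = self.sizes[image_id]
        return (h, w)

    @property
    def image_ids(self) -> list[str]:
        return list(self.sizes)


def _as_points(points: Iterable) -> np.ndarray:
    pts = np.atleast_2d(np.asarray(points, dtype=np.int64))
    if pts.size == 0:
        return pts.reshape(0, 2)
    if pts.shape[1] != 2:
        raise ValidationError(f"points must be (n, 2) (x, y); got shape {pts.shape}")
    return pts


@dataclass
class PointTable:
    """Selection events: fixations and explicit-judgment picks.

    One row per selected location with columns
    ``image_id, observer_id, task, x, y, ordinal``.  ``ordinal`` is the
    fixation order within a trial (0-based); explicit-judgment selections
    carry ordinal 0.  ``(image_id, observer_id, task, ordinal)`` is unique.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in POINT_COLUMNS if c not in self.frame.columns]
        if missing:
            raise FormatError(f"point table missing column(s): {missing}")
        df = self.frame.loc[:, list(POINT_COLUMNS)].copy()
        df["image_id"] = df["image_id"].astype(str)
        df["observer_id"] = df["observer_id"].astype(str)
        df["task"] = df["task"].astype(str)
        for col in ("x", "y", "ordinal"):
            df[col] = df[col].astype(np.int64)
        bad_task = df.loc[~df["task"].isin(TASKS), "task"]
        if len(bad_task):
            raise ValidationError(
                f"unknown task value(s) {sorted(bad_task.unique())}; expected one of {TASKS}"
            )
        if (df["ordinal"] < 0).any():
            row = int(df.index[df["ordinal"] < 0][0])
            raise ValidationError(f"row {row}: ordinal must be >= 0")
        key = ["image_id", "observer_id", "task", "ordinal"]
        if df.duplicated(subset=key).any():
            row = int(df.index[df.duplicated(subset=key)][0])
            raise ValidationError(
                f"row {row}: duplicate (image_id, observer_id, task, ordinal) key"
            )
        df.reset_index(drop=True, inplace=True)
        self.frame = df

    def __len__(self) -> int:
        return len(self.frame)

    def validate_against(self, catalog: ImageCatalog) -> None:
        """Check every coordinate lies inside its image; raise naming the row."""
        for row in self.frame.itertuples():
            h, w = catalog.shape(row.image_id)
            if not (0 <= row.x < w and 0 <= row.y < h):
                raise ValidationError(
                    f"row {row.Index}: point ({row.x}, {row.y}) out of bounds "
                    f"for image {row.image_id!r} of size {w}x{h}"
                )

    def _mask(self, image_id=None, task=None, observer_id=None, exclude_observer=None):
        m = pd.Series(True, index=self.frame.index)
        if image_id is not None:
            m &= self.frame["image_id"] == image_id
        if task is not None:
            m &= self.frame["task"] == task
        if observer_id is not None:
            m &= self.frame["observer_id"] == observer_id
        if exclude_observer is not None:
            m &= self.frame["observer_id"] != exclude_observer
        return m

    def points(self, image_id=None, task=None, observer_id=None,
               exclude_observer=None) -> np.ndarray:
        """Return the matching ``(n, 2)`` array of (x, y), multiplicity kept."""
        sub = self.frame.loc[self._mask(image_id, task, observer_id, exclude_observer)]
        return sub[["x", "y"]].to_numpy(dtype=np.int64).reshape(-1, 2)

    def subset(self, image_id=None, task=None, observer_id=None,
               exclude_observer=None) -> "PointTable":
        sub = self.frame.loc[self._mask(image_id, task, observer_id, exclude_observer)]
        return PointTable(sub.reset_index(drop=True))

    def observers(self, image_id=None, task=None) -> list[str]:
        sub = self.frame.loc[self._mask(image_id, task)]
        return sorted(sub["observer_id"].unique())

    def image_ids(self, task=None) -> list[str]:
        sub = self.frame.loc[self._mask(task=task)]
        return sorted(sub["image_id"].unique())

    @classmethod
    def from_records(cls, records: Sequence[tuple]) -> "PointTable":
        return cls(pd.DataFrame.from_records(records, columns=list(POINT_COLUMNS)))

    @classmethod
    def concat(cls, tables: Sequence["PointTable"]) -> "PointTable":
        frames = [t.frame for t in tables]
        if not frames:
            return cls(pd.DataFrame(columns=list(POINT_COLUMNS)))
        return cls(pd.concat(frames, ignore_index=True))


@dataclass
class SaliencyMap:
    """A 2-D real-valued conspicuity grid aligned to one image."""

    image_id: str
    grid: np.ndarray
    algorithm_id: str = ""

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        if grid.ndim != 2:
            raise ValidationError(f"saliency grid must be 2-D, got ndim={grid.ndim}")
        if not np.all(np.isfinite(grid)):
            raise ValidationError(
                f"saliency map for image {self.image_id!r} contains non-finite values"
            )
        self.grid = grid

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    def values_at(self, points: Iterable) -> np.ndarray:
        pts = _as_points(points)
        h, w = self.grid.shape
        if len(pts) and (
            pts[:, 0].min() < 0 or pts[:, 0].max() >= w
            or pts[:, 1].min() < 0 or pts[:, 1].max() >= h
        ):
            raise ValidationError("point outside map bounds")
        return self.grid[pts[:, 1], pts[:, 0]]


@dataclass
class MapEnsemble:
    """All of one algorithm's maps over a dataset, in a fixed image order."""

    algorithm_id: str
    maps: list[SaliencyMap] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.maps) < 2:
            raise ValidationError(
                f"ensemble {self.algorithm_id!r} needs >= 2 maps, got {len(self.maps)}"
            )
        shapes = {m.shape for m in self.maps}
        if len(shapes) != 1:
            raise ValidationError(
                f"ensemble {self.algorithm_id!r} mixes grid shapes: {sorted(shapes)}"
            )

    @property
    def n(self) -> int:
        return len(self.maps)

    @property
    def shape(self) -> tuple[int, int]:
        return self.maps[0].shape

    def stack(self) -> np.ndarray:
        """Return the (N, H, W) stack of grids."""
        return np.stack([m.grid for m in self.maps])

    def image_ids(self) -> list[str]:
        return [m.image_id for m in self.maps]

    def with_stack(self, stack: np.ndarray, algorithm_id: str | None = None) -> "MapEnsemble":
        """Rebuild an ensemble from a transformed (N, H, W) stack."""
        aid = self.algorithm_id if algorithm_id is None else algorithm_id
        return MapEnsemble(
            aid,
            [SaliencyMap(m.image_id, g, aid) for m, g in zip(self.maps, stack)],
        )
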