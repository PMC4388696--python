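"""Localization-table I/O, image rendering and per-cell coordinate frames.

Single-molecule localization data are kept as flat tables of coordinates in
nanometres.  The canonical on-disk dialect is a comma-separated file with one
header row and columns ``x_nm, y_nm, z_nm, frame, channel, precision_nm``
(only ``x_nm`` and ``y_nm`` are mandatory); common SMLM column aliases such as
``x [nm]`` are accepted on input.

A :class:`CellFrame` describes a cell's mid-point, long-axis orientation and
length, and defines the per-cell coordinate system used throughout the
morphometry and colocalization analyses: x is the signed coordinate along the
long axis, y the signed coordinate along the short axis, both measured from
the cell centre (right-handed convention).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

__all__ = [
    "CellFrame",
    "LocalizationTable",
    "RenderedImage",
    "LocFormatError",
    "LocParseError",
    "EmptyTableError",
    "read_locs",
    "write_locs",
    "render_image",
    "to_cell_frame",
    "from_cell_frame",
]

#: canonical column order of the CSV dialect
CANONICAL_COLUMNS = ("x_nm", "y_nm", "z_nm", "frame", "channel", "precision_nm")

# aliases seen in common SMLM exports (ThunderSTORM-style headers etc.)
_COLUMN_ALIASES: Mapping[str, str] = {
    "x": "x_nm",
    "x [nm]": "x_nm",
    "x(nm)": "x_nm",
    "y": "y_nm",
    "y [nm]": "y_nm",
    "y(nm)": "y_nm",
    "z": "z_nm",
    "z [nm]": "z_nm",
    "z(nm)": "z_nm",
    "uncertainty [nm]": "precision_nm",
    "uncertainty_xy [nm]": "precision_nm",
    "precision": "precision_nm",
    "sigma [nm]": "precision_nm",
}


class LocFormatError(ValueError):
    """A localization table is structurally invalid (e.g. missing columns)."""


class LocParseError(ValueError):
    """A localization table contains unparseable cells."""


class EmptyTableError(ValueError):
    """An operation that needs localizations received an empty table."""


@dataclass(frozen=True)
class CellFrame:
    """Per-cell coordinate system: centre, long-axis angle and cell length.

    Parameters
    ----------
    center
        (x, y) of the cell mid-point in the lab frame, nm.
    axis_angle
        Orientation of the long axis in radians; normalised into [0, pi).
    length
        Cell length along the long axis, nm (> 0).
    """

    center: tuple[float, float]
    axis_angle: float
    length: float

    def __post_init__(self) -> None:
        if not (self.length > 0):
            raise ValueError("cell length must be positive")
        angle = float(self.axis_angle) % math.pi
        object.__setattr__(self, "axis_angle", angle)
        object.__setattr__(
            self, "center", (float(self.center[0]), float(self.center[1]))
        )


@dataclass
class RenderedImage:
    """A localization count image: ``counts[row, col]`` with row = y bin."""

    counts: np.ndarray
    pixel_size: float
    origin: tuple[float, float]

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def save_tiff(self, path) -> None:
        """Write the image as 16-bit TIFF (counts clipped at 65535)."""
        import tifffile

        scaled = np.clip(np.round(self.counts), 0, 65535).astype(np.uint16)
        tifffile.imwrite(str(path), scaled)


class LocalizationTable:
    """A set of single-molecule localizations in nm, backed by a DataFrame.

    The table always carries ``x_nm`` and ``y_nm``; ``z_nm``, ``frame``,
    ``channel`` and ``precision_nm`` are optional.  ``has_z`` is true iff a
    finite z coordinate is present for every record.
    """

    def __init__(self, df: pd.DataFrame):
        if "x_nm" not in df.columns or "y_nm" not in df.columns:
            missing = [c for c in ("x_nm", "y_nm") if c not in df.columns]
            raise LocFormatError(f"missing mandatory column(s): {', '.join(missing)}")
        df = df.reset_index(drop=True)
        for col in ("x_nm", "y_nm", "z_nm", "precision_nm"):
            if col in df.columns:
                values = pd.to_numeric(df[col], errors="coerce")
                bad = values.isna() & df[col].notna()
                if bad.any():
                    row = int(bad.idxmax())
                    raise LocParseError(
                        f"non-numeric value in column {col!r} at row {row}"
                    )
                df[col] = values.astype(float)
        if not np.isfinite(df["x_nm"]).all() or not np.isfinite(df["y_nm"]).all():
            raise ValueError("coordinates must be finite")
        if "precision_nm" in df.columns:
            prec = df["precision_nm"].dropna()
            if (prec <= 0).any():
                raise ValueError("localization precision must be > 0 when present")
        self._df = df

    # -- construction helpers ------------------------------------------------

    @classmethod
    def from_arrays(
        cls,
        x: Iterable[float],
        y: Iterable[float],
        z: Iterable[float] | None = None,
        frame: Iterable[int] | None = None,
        channel=None,
        precision=None,
    ) -> "LocalizationTable":
        data = {"x_nm": np.asarray(x, dtype=float), "y_nm": np.asarray(y, dtype=float)}
        n = len(data["x_nm"])
        if z is not None:
            data["z_nm"] = np.asarray(z, dtype=float)
        if frame is not None:
            data["frame"] = np.asarray(frame)
        if channel is not None:
            data["channel"] = (
                np.full(n, channel) if np.isscalar(channel) else np.asarray(channel)
            )
        if precision is not None:
            data["precision_nm"] = (
                np.full(n, float(precision))
                if np.isscalar(precision)
                else np.asarray(precision, dtype=float)
            )
        return cls(pd.DataFrame(data))

    # -- accessors -----------------------------------------------------------

    @property
    def df(self) -> pd.DataFrame:
        return self._df

    @property
    def x(self) -> np.ndarray:
        return self._df["x_nm"].to_numpy()

    @property
    def y(self) -> np.ndarray:
        return self._df["y_nm"].to_numpy()

    @property
    def z(self) -> np.ndarray:
        if not self.has_z:
            raise AttributeError("table has no z coordinates")
        return self._df["z_nm"].to_numpy()

    @property
    def precision(self) -> np.ndarray | None:
        if "precision_nm" in self._df.columns:
            return self._df["precision_nm"].to_numpy()
        return None

    @property
    def has_z(self) -> bool:
        return "z_nm" in self._df.columns and np.isfinite(
            self._df["z_nm"].to_numpy()
        ).all() and len(self._df) > 0

    @property
    def channels(self) -> list:
        if "channel" in self._df.columns:
            return sorted(pd.unique(self._df["channel"]).tolist())
        return []

    def select_channel(self, channel) -> "LocalizationTable":
        if "channel" not in self._df.columns:
            raise KeyError("table has no channel column")
        return LocalizationTable(self._df[self._df["channel"] == channel])

    def __len__(self) -> int:
        return len(self._df)

    def __repr__(self) -> str:
        dims = "3D" if self.has_z else "2D"
        return f"<LocalizationTable {len(self)} records, {dims}>"


def read_locs(path, dialect: str = "canonical") -> LocalizationTable:
    """Read a localization CSV, mapping common SMLM column aliases to the
    canonical ``x_nm``/``y_nm``/... names. Units are nm throughout."""
    df = pd.read_csv(path, float_precision="round_trip")
    rename = {}
    for col in df.columns:
        key = col.strip().lower()
        if key in _COLUMN_ALIASES:
            rename[col] = _COLUMN_ALIASES[key]
        elif key in CANONICAL_COLUMNS:
            rename[col] = key
    df = df.rename(columns=rename)
    return LocalizationTable(df[[c for c in CANONICAL_COLUMNS if c in df.columns]])


def write_locs(table: LocalizationTable, path):
    """Write a localization table in the canonical CSV dialect.

    Coordinates are printed with enough digits that a read/write round trip is
    lossless at double precision.
    """
    cols = [c for c in CANONICAL_COLUMNS if c in table.df.columns]
    table.df[cols].to_csv(path, index=False, float_format="%.17g")
    return path


def render_image(
    table: LocalizationTable, pixel_size: float = 15.0, smoothing_sd: float = 0.0
) -> RenderedImage:
    """Bin localizations into a 2D count image (half-open bins, origin at the
    minimum corner).  ``smoothing_sd`` (nm) optionally applies a Gaussian blur;
    with ``smoothing_sd=0`` the image holds exact integer counts and conserves
    the number of localizations."""
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    if len(table) == 0:
        raise EmptyTableError("cannot render an empty localization table")
    x, y = table.x, table.y
    origin = (float(x.min()), float(y.min()))
    ix = np.floor((x - origin[0]) / pixel_size).astype(int)
    iy = np.floor((y - origin[1]) / pixel_size).astype(int)
    shape = (iy.max() + 1, ix.max() + 1)
    counts = np.zeros(shape, dtype=float)
    np.add.at(counts, (iy, ix), 1.0)
    if smoothing_sd > 0:
        counts = gaussian_filter(counts, sigma=smoothing_sd / pixel_size)
    return RenderedImage(counts=counts, pixel_size=float(pixel_size), origin=origin)


def _rotate(dx: np.ndarray, dy: np.ndarray, angle: float):
    c, s = math.cos(angle), math.sin(angle)
    return c * dx + s * dy, -s * dx + c * dy


def to_cell_frame(table: LocalizationTable, frame: CellFrame) -> LocalizationTable:
    """Express localizations in the cell's own frame (rigid transform).

    Output x is the signed long-axis coordinate, y the signed short-axis
    coordinate, both relative to the cell centre.  z and all metadata columns
    are carried through unchanged.
    """
    dx = table.x - frame.center[0]
    dy = table.y - frame.center[1]
    lx, sy = _rotate(dx, dy, frame.axis_angle)
    df = table.df.copy()
    df["x_nm"] = lx
    df["y_nm"] = sy
    return LocalizationTable(df)


def from_cell_frame(table: LocalizationTable, frame: CellFrame) -> LocalizationTable:
    """Inverse of :func:`to_cell_frame`: map cell-frame coordinates back to
    the lab frame."""
    c, s = math.cos(frame.axis_angle), math.sin(frame.axis_angle)
    lx, sy = table.x, table.y
    dx = c * lx - s * sy
    dy = s * lx + c * sy
    df = table.df.copy()
    df["x_nm"] = dx + frame.center[0]
    df["y_nm"] = dy + frame.center[1]
    return LocalizationTable(df)
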