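"""Localization tables: in-memory container, CSV/TSV reading and writing.

SMLM datasets are tables with one row per detected molecule and coordinate
columns in nanometers (2D or 3D).  Everything downstream consumes a
:class:`LocalizationSet`; coordinates are stored in double precision
nanometers regardless of the on-disk unit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import EmptyInputError, FormatError, ParseError

__all__ = [
    "Box",
    "Dialect",
    "DEFAULT_DIALECT",
    "THUNDERSTORM_DIALECT",
    "LocalizationSet",
    "read_localizations",
    "write_localizations",
]


@dataclass(frozen=True)
class Box:
    """Axis-aligned box, nm.  ``lo``/``hi`` are length-``dim`` arrays."""

    lo: np.ndarray
    hi: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "lo", np.asarray(self.lo, dtype=float))
        object.__setattr__(self, "hi", np.asarray(self.hi, dtype=float))
        if self.lo.shape != self.hi.shape or self.lo.ndim != 1:
            raise ValueError("Box lo/hi must be 1-d arrays of equal length")
        if not np.all(np.isfinite(self.lo)) or not np.all(np.isfinite(self.hi)):
            raise ValueError("Box bounds must be finite")
        if np.any(self.hi <= self.lo):
            raise ValueError("Box must have positive extent on every axis")

    @property
    def dim(self) -> int:
        return self.lo.size

    @property
    def extent(self) -> np.ndarray:
        return self.hi - self.lo

    @property
    def measure(self) -> float:
        """Area (2D) or volume (3D), nm^dim."""
        return float(np.prod(self.extent))

    @property
    def diagonal(self) -> float:
        return float(np.linalg.norm(self.extent))

    def contains(self, coords: np.ndarray, atol: float = 0.0) -> np.ndarray:
        c = np.atleast_2d(np.asarray(coords, dtype=float))
        return np.all((c >= self.lo - atol) & (c <= self.hi + atol), axis=1)

    def expanded(self, fraction: float = 0.05) -> "Box":
        """Box grown by ``fraction`` of its extent on every side."""
        pad = fraction * self.extent
        return Box(self.lo - pad, self.hi + pad)

    @staticmethod
    def of_points(coords: np.ndarray) -> "Box":
        coords = np.atleast_2d(np.asarray(coords, dtype=float))
        lo = coords.min(axis=0)
        hi = coords.max(axis=0)
        # Degenerate (flat) extents get a token thickness so the box is a box.
        flat = hi <= lo
        hi = np.where(flat, lo + max(1.0, np.max(hi - lo, initial=1.0) * 1e-6), hi)
        return Box(lo, hi)


@dataclass(frozen=True)
class Dialect:
    """Column mapping for a localization table.

    ``coord_columns`` lists the x, y and (optionally) z column names; a z
    column absent from the file simply yields a 2D dataset.  ``unit`` is the
    on-disk coordinate unit (``"nm"`` or ``"um"``); coordinates are always
    converted to nm on read.
    """

    coord_columns: tuple[str, ...] = ("x", "y", "z")
    unit: str = "nm"
    sep: str = ","
    extra_columns: tuple[str, ...] = ()

    def __post_init__(self):
        if self.unit not in ("nm", "um", "µm"):
            raise ValueError(f"unsupported unit {self.unit!r}")
        if len(self.coord_columns) not in (2, 3):
            raise ValueError("dialect must name 2 or 3 coordinate columns")

    @property
    def scale_to_nm(self) -> float:
        return 1.0 if self.unit == "nm" else 1000.0


DEFAULT_DIALECT = Dialect()
#: ThunderSTORM export convention ("x [nm]", "y [nm]", "z [nm]").
THUNDERSTORM_DIALECT = Dialect(coord_columns=("x [nm]", "y [nm]", "z [nm]"))


@dataclass
class LocalizationSet:
    """n x d localization coordinates (nm) plus optional per-row extras."""

    coords: np.ndarray
    bounds: Box | None = None
    extras: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        self.coords = np.ascontiguousarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] not in (2, 3):
            raise ValueError("coords must be an (n, 2) or (n, 3) array")
        if self.coords.shape[0] < 1:
            raise EmptyInputError("a LocalizationSet needs at least one row")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if self.bounds is None:
            self.bounds = Box.of_points(self.coords)
        elif self.bounds.dim != self.coords.shape[1]:
            raise ValueError("bounds dimensionality does not match coords")
        elif not np.all(self.bounds.contains(self.coords)):
            raise ValueError("bounds must contain every localization")
        for name, col in self.extras.items():
            col = np.asarray(col)
            if col.shape[0] != self.n:
                raise ValueError(f"extras column {name!r} has wrong length")
            self.extras[name] = col

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    @property
    def dim(self) -> int:
        return self.coords.shape[1]

    def with_bounds(self, bounds: Box) -> "LocalizationSet":
        return LocalizationSet(self.coords, bounds=bounds, extras=dict(self.extras))


def read_localizations(
    path,
    dialect: Dialect = DEFAULT_DIALECT,
    bounds: Box | None = None,
) -> LocalizationSet:
    """Read a localization table into a :class:`LocalizationSet`.

    Parameters
    ----------
    path
        CSV/TSV file with a header row.
    dialect
        Column mapping and on-disk unit; see :class:`Dialect`.
    bounds
        Optional explicit bounding box (nm).  Defaults to the tight
        axis-aligned box of the data.
    """
    # round_trip parsing: shortest-repr doubles must come back bit-identical
    df = pd.read_csv(path, sep=dialect.sep, float_precision="round_trip")
    if len(df) == 0:
        raise EmptyInputError(f"{path}: no localizations")
    cols = [c for c in dialect.coord_columns if c in df.columns]
    required = dialect.coord_columns[:2]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing coordinate column(s) {missing}")
    coords = np.empty((len(df), len(cols)), dtype=float)
    for j, c in enumerate(cols):
        col = pd.to_numeric(df[c], errors="coerce").to_numpy(dtype=float)
        bad = np.flatnonzero(~np.isfinite(col))
        if bad.size:
            raise ParseError(
                f"{path}: non-numeric value in column {c!r} at data row {bad[0]}"
            )
        coords[:, j] = col
    coords *= dialect.scale_to_nm
    extras = {}
    for c in dialect.extra_columns:
        if c in df.columns:
            extras[c] = df[c].to_numpy()
    return LocalizationSet(coords, bounds=bounds, extras=extras)


def write_localizations(locs: LocalizationSet, path, sep: str = ",") -> None:
    """Write a LocalizationSet as CSV (header + full double precision rows).

    Coordinate columns come first (named x, y[, z]); extras follow in their
    declared order.  The shortest-repr float formatting round-trips exactly.
    """
    names = ("x", "y", "z")[: locs.dim]
    data = {name: locs.coords[:, j] for j, name in enumerate(names)}
    data.update(locs.extras)
    pd.DataFrame(data).to_csv(path, sep=sep, index=False)


def _stable_dedup(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Merge exact duplicate rows, keeping first occurrences in input order.

    Returns ``(unique_rows_index, inverse)`` with
    ``coords[unique_rows_index][inverse] == coords``.
    """
    _, first, inverse = np.unique(
        coords, axis=0, return_index=True, return_inverse=True
    )
    order = np.argsort(first, kind="stable")  # restore original row order
    rank = np.empty_like(order)
    rank[order] = np.arange(order.size)
    return first[order], rank[np.asarray(inverse).ravel()]
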