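"""Raster-stack and point-table I/O.

Rasters are single-band ESRI ASCII grids (``.asc``), a plain-text format
with a six-line header followed by ``nrows`` rows of values, row 0 at the
top. An optional ``.prj`` sidecar file carries a free-text CRS identifier.
All layers of a stack must be co-registered: same shape, origin, cell size
and CRS — a mismatch is an error, never a silent reprojection.

Point tables are UTF-8 CSV files with header ``id,x,y[,count]`` where
``count`` is a nonnegative integer burrow density (burrows/km^2).

Coordinate convention: cells are addressed ``(row, col)`` from the
upper-left corner; a point maps to the cell whose half-open extent
``[x0, x0+cs) x (y0-cs, y0]`` contains it, so boundary points resolve
deterministically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    AlignmentError,
    ContractError,
    DataValidationError,
    EmptyResultError,
    SchemaError,
)

logger = logging.getLogger(__name__)

DEFAULT_NODATA = -9999.0

# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular raster grid.

    ``x_origin``/``y_origin`` locate the *upper-left corner* of the grid in
    map units; ``cell_size`` is the square cell edge length.
    """

    n_rows: int
    n_cols: int
    x_origin: float
    y_origin: float
    cell_size: float
    crs_id: str = "unspecified"
    nodata: float = DEFAULT_NODATA

    def __post_init__(self):
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ContractError(
                f"grid shape must be positive, got {self.n_rows}x{self.n_cols}"
            )
        if not self.cell_size > 0:
            raise ContractError(f"cell_size must be > 0, got {self.cell_size}")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """Map coordinates of the center of cell ``(row, col)``."""
        x = self.x_origin + (col + 0.5) * self.cell_size
        y = self.y_origin - (row + 0.5) * self.cell_size
        return x, y

    def same_geometry(self, other: "GridSpec") -> bool:
        return (
            self.n_rows == other.n_rows
            and self.n_cols == other.n_cols
            and np.isclose(self.x_origin, other.x_origin)
            and np.isclose(self.y_origin, other.y_origin)
            and np.isclose(self.cell_size, other.cell_size)
            and self.crs_id == other.crs_id
        )


@dataclass
class EnvStack:
    """A co-registered stack of P >= 2 environmental layers.

    ``values`` has shape ``(P, n_rows, n_cols)``; ``valid_mask`` is True
    only where every layer carries data.
    """

    spec: GridSpec
    layer_names: list[str]
    values: np.ndarray
    valid_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ContractError("EnvStack values must be (P, n_rows, n_cols)")
        p, nr, nc = self.values.shape
        if (nr, nc) != self.spec.shape:
            raise ContractError("layer shape does not match GridSpec")
        if p < 2:
            raise ContractError(f"a stack needs at least 2 layers, got {p}")
        if len(self.layer_names) != p:
            raise ContractError("layer_names length must equal layer count")
        if self.valid_mask is None:
            nodata = self.spec.nodata
            self.valid_mask = np.all(
                (self.values != nodata) & np.isfinite(self.values), axis=0
            )
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.valid_mask.shape != self.spec.shape:
            raise ContractError("valid_mask shape does not match GridSpec")

    @property
    def n_layers(self) -> int:
        return self.values.shape[0]


class PointTable:
    """Georeferenced point records, optionally with abundance counts.

    Thin wrapper over a :class:`pandas.DataFrame` with columns
    ``id, x, y[, count]``; ids are unique and counts, when present, are
    nonnegative integers.
    """

    def __init__(self, frame: pd.DataFrame):
        required = {"id", "x", "y"}
        missing = required - set(frame.columns)
        if missing:
            raise SchemaError(f"point table missing columns: {sorted(missing)}")
        frame = frame.reset_index(drop=True).copy()
        if frame["id"].duplicated().any():
            dupes = frame.loc[frame["id"].duplicated(), "id"].tolist()
            raise DataValidationError(f"duplicate point ids: {dupes}")
        if "count" in frame.columns and len(frame):
            counts = frame["count"]
            numeric = pd.to_numeric(counts, errors="coerce")
            bad = numeric.isna() | (numeric < 0) | (numeric != np.round(numeric))
            if bad.any():
                raise DataValidationError(
                    "counts must be nonnegative integers; offending ids: "
                    f"{frame.loc[bad, 'id'].tolist()}"
                )
            frame["count"] = numeric.astype(int)
        self.frame = frame

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def has_counts(self) -> bool:
        return "count" in self.frame.columns

    @property
    def xy(self) -> np.ndarray:
        return self.frame[["x", "y"]].to_numpy(dtype=float)

    @property
    def counts(self) -> np.ndarray:
        if not self.has_counts:
            raise SchemaError("point table has no count column")
        return self.frame["count"].to_numpy(dtype=int)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# ESRI ASCII grid reader / writer
# ---------------------------------------------------------------------------

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "xllcenter", "yllcorner",
                "yllcenter", "cellsize", "nodata_value")


def read_ascii_grid(path) -> tuple[np.ndarray, GridSpec]:
    """Read one ``.asc`` raster; returns ``(values, spec)``.

    Nodata cells keep the sentinel value from the header. A ``.prj``
    sidecar next to the file, when present, supplies ``crs_id``.
    """
    path = Path(path)
    header: dict[str, float] = {}
    n_header = 0
    try:
        with open(path, "r", encoding="utf-8") as fh:
            for line in fh:
                parts = line.split()
                if len(parts) == 2 and parts[0].lower() in _HEADER_KEYS:
                    header[parts[0].lower()] = float(parts[1])
                    n_header += 1
                else:
                    break
        values = np.loadtxt(path, skiprows=n_header, dtype=float, ndmin=2)
    except OSError as exc:
        raise OSError(f"cannot read raster {path}: {exc}") from exc
    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise ContractError(f"{path}: malformed ASCII grid header (no {key})")
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    cs = header["cellsize"]
    if "xllcorner" in header:
        xll = header["xllcorner"]
    else:
        xll = header.get("xllcenter", 0.0) - cs / 2.0
    if "yllcorner" in header:
        yll = header["yllcorner"]
    else:
        yll = header.get("yllcenter", 0.0) - cs / 2.0
    nodata = header.get("nodata_value", DEFAULT_NODATA)
    if values.shape != (n_rows, n_cols):
        raise ContractError(
            f"{path}: data block is {values.shape}, header says {(n_rows, n_cols)}"
        )
    prj = path.with_suffix(".prj")
    crs_id = prj.read_text(encoding="utf-8").strip() if prj.exists() else "unspecified"
    spec = GridSpec(
        n_rows=n_rows,
        n_cols=n_cols,
        x_origin=xll,
        y_origin=yll + n_rows * cs,
        cell_size=cs,
        crs_id=crs_id,
        nodata=nodata,
    )
    return values, spec


def write_surface(values: np.ndarray, spec: GridSpec, path) -> Path:
    """Write one real-valued layer as an ESRI ASCII grid (+ ``.prj``).

    NaN cells are stored as the spec's nodata sentinel. Values round-trip
    bit-compatibly through :func:`read_ascii_grid` / :func:`read_stack`
    (written with ``repr`` precision).
    """
    values = np.asarray(values, dtype=float)
    if values.shape != spec.shape:
        raise ContractError(
            f"layer shape {values.shape} does not conform to grid {spec.shape}"
        )
    path = Path(path)
    out = np.where(np.isfinite(values), values, spec.nodata)
    header = (
        f"ncols {spec.n_cols}\n"
        f"nrows {spec.n_rows}\n"
        f"xllcorner {float(spec.x_origin)!r}\n"
        f"yllcorner {float(spec.y_origin - spec.n_rows * spec.cell_size)!r}\n"
        f"cellsize {float(spec.cell_size)!r}\n"
        f"NODATA_value {float(spec.nodata)!r}\n"
    )
    try:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(header)
            for row in out:
                fh.write(" ".join(repr(float(v)) for v in row) + "\n")
        if spec.crs_id != "unspecified":
            path.with_suffix(".prj").write_text(spec.crs_id + "\n", encoding="utf-8")
    except OSError as exc:
        raise OSError(f"cannot write raster {path}: {exc}") from exc
    return path


# ---------------------------------------------------------------------------
# Stack and point-table operations
# ---------------------------------------------------------------------------


def read_stack(paths, layer_names: list[str] | None = None) -> EnvStack:
    """Read >= 2 single-band rasters into a co-registered :class:`EnvStack`.

    Layers keep the input order; the valid mask is the conjunction of
    per-layer data masks. Any geometry mismatch raises
    :class:`AlignmentError` naming the offending file.
    """
    paths = [Path(p) for p in paths]
    if len(paths) < 2:
        raise ContractError(f"need at least 2 raster layers, got {len(paths)}")
    layers, spec = [], None
    for p in paths:
        vals, this_spec = read_ascii_grid(p)
        if spec is None:
            spec = this_spec
        elif not spec.same_geometry(this_spec) or not np.isclose(
            spec.nodata, this_spec.nodata
        ):
            raise AlignmentError(
                f"raster {p} does not align with {paths[0]} "
                f"(got {this_spec}, expected {spec})"
            )
        layers.append(vals)
    names = layer_names if layer_names is not None else [p.stem for p in paths]
    values = np.stack(layers, axis=0)
    mask = np.all((values != spec.nodata) & np.isfinite(values), axis=0)
    return EnvStack(spec=spec, layer_names=list(names), values=values,
                    valid_mask=mask)


def read_points(path, expect_counts: bool = False) -> PointTable:
    """Read a CSV with header ``id,x,y[,count]`` into a :class:`PointTable`."""
    try:
        frame = pd.read_csv(path)
    except OSError as exc:
        raise OSError(f"cannot read point table {path}: {exc}") from exc
    if expect_counts and "count" not in frame.columns:
        raise SchemaError(f"{path}: 'count' column required but absent")
    return PointTable(frame)


def point_to_cell(spec: GridSpec, x: float, y: float) -> tuple[int, int] | None:
    """Map a point to its containing ``(row, col)``; None when off-grid.

    Half-open convention: x in ``[x0+c*cs, x0+(c+1)*cs)`` gives column c;
    y in ``(y0-(r+1)*cs, y0-r*cs]`` gives row r.
    """
    cs = spec.cell_size
    col = int(np.floor((x - spec.x_origin) / cs))
    row = int(np.floor((spec.y_origin - y) / cs))
    if not (0 <= row < spec.n_rows and 0 <= col < spec.n_cols):
        return None
    return row, col


def extract_values(stack: EnvStack, points: PointTable
                   ) -> tuple[np.ndarray, list[int]]:
    """Sample every layer at each point's containing cell.

    Points must be in the stack's CRS. Points falling outside the grid or
    on masked (nodata) cells are dropped and reported via logging; the
    returned matrix rows align with the returned kept-point index list
    (positional indices into ``points``).
    """
    kept: list[int] = []
    rows, cols = [], []
    dropped: list[str] = []
    ids = points.frame["id"].tolist()
    for i, (x, y) in enumerate(points.xy):
        cell = point_to_cell(stack.spec, float(x), float(y))
        if cell is None or not stack.valid_mask[cell]:
            dropped.append(str(ids[i]))
            continue
        kept.append(i)
        rows.append(cell[0])
        cols.append(cell[1])
    if dropped:
        logger.warning(
            "dropped %d/%d points outside the grid or on nodata cells: %s",
            len(dropped), len(points), ", ".join(dropped),
        )
    if not kept:
        raise EmptyResultError("all points fall outside the usable grid")
    matrix = stack.values[:, rows, cols].T.copy()
    return matrix, kept


def thin_one_per_cell(points: PointTable, spec: GridSpec) -> PointTable:
    """Optionally thin points to one per raster cell (first record wins).

    Duplicate occurrences in one cell are kept by default throughout the
    package; this helper is the explicit opt-in alternative.
    """
    seen: set[tuple[int, int]] = set()
    keep_rows = []
    for i, (x, y) in enumerate(points.xy):
        cell = point_to_cell(spec, float(x), float(y))
        if cell is None or cell in seen:
            continue
        seen.add(cell)
        keep_rows.append(i)
    return PointTable(points.frame.iloc[keep_rows])
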