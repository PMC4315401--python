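"""Environmental predictor stacks and occurrence records.

An :class:`EnvStack` is a set of named single-band layers (continuous or
categorical) sharing one lon/lat analysis grid, with a joint validity
mask (cells where every layer is valid).  Heterogeneous inputs are
brought onto the grid by :func:`align_stack` — bilinear resampling for
continuous layers, majority/nearest for categorical ones.

Occurrence records arrive as delimited text with longitude/latitude
columns; :func:`clean_occurrences` drops flagged and off-grid records
and (by default) thins to one presence per grid cell, the standard
presence-background practice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

from .grid import GridGeometry, Raster, read_ascii_grid, write_ascii_grid

__all__ = [
    "EnvStack", "OccurrenceSet", "align_stack", "clean_occurrences",
    "extract", "read_occurrence_csv",
]

log = logging.getLogger(__name__)

CONTINUOUS = "continuous"
CATEGORICAL = "categorical"


@dataclass
class EnvStack:
    """Named predictor layers on one shared grid.

    ``layers`` maps name → 2-D float array (NaN = nodata); ``kinds`` maps
    name → ``"continuous"`` or ``"categorical"``.  Categorical layers hold
    integer codes (stored as floats for the shared NaN convention).
    """

    layers: dict[str, np.ndarray]
    kinds: dict[str, str]
    geometry: GridGeometry

    def __post_init__(self) -> None:
        for name, arr in self.layers.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != self.geometry.shape:
                raise ValueError(f"layer {name!r}: shape {arr.shape} != "
                                 f"grid {self.geometry.shape}")
            kind = self.kinds.get(name)
            if kind not in (CONTINUOUS, CATEGORICAL):
                raise ValueError(f"layer {name!r}: unknown kind {kind!r}")
            if kind == CATEGORICAL:
                vals = arr[~np.isnan(arr)]
                if vals.size and not np.allclose(vals, np.round(vals)):
                    raise ValueError(f"categorical layer {name!r} has "
                                     "non-integer codes")
            self.layers[name] = arr

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    @property
    def validity_mask(self) -> np.ndarray:
        """Boolean grid: cells where every layer is valid."""
        mask = np.ones(self.geometry.shape, dtype=bool)
        for arr in self.layers.values():
            mask &= ~np.isnan(arr)
        return mask

    def valid_cells(self) -> np.ndarray:
        """(n, 2) array of [row, col] for all jointly-valid cells."""
        return np.argwhere(self.validity_mask)

    def subset(self, names: list[str]) -> "EnvStack":
        missing = [n for n in names if n not in self.layers]
        if missing:
            raise KeyError(f"layers not in stack: {missing}")
        return EnvStack({n: self.layers[n] for n in names},
                        {n: self.kinds[n] for n in names}, self.geometry)

    def drop(self, names: list[str]) -> "EnvStack":
        keep = [n for n in self.layers if n not in set(names)]
        return self.subset(keep)

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, arr in self.layers.items():
            write_ascii_grid(Raster(arr, self.geometry),
                             directory / f"{name}.asc")
        kinds = pd.DataFrame({"layer": list(self.kinds),
                              "kind": list(self.kinds.values())})
        kinds.to_csv(directory / "layer_kinds.csv", index=False)

    @classmethod
    def read(cls, directory: str | Path) -> "EnvStack":
        directory = Path(directory)
        kinds_df = pd.read_csv(directory / "layer_kinds.csv")
        layers: dict[str, np.ndarray] = {}
        kinds: dict[str, str] = {}
        geometry: GridGeometry | None = None
        for _, row in kinds_df.iterrows():
            raster = read_ascii_grid(directory / f"{row['layer']}.asc")
            layers[row["layer"]] = raster.data
            kinds[row["layer"]] = row["kind"]
            geometry = raster.geometry
        assert geometry is not None
        return cls(layers, kinds, geometry)


@dataclass
class OccurrenceSet:
    """Cleaned presence records pinned to analysis-grid cells.

    ``cells`` is an (n, 2) int array of unique [row, col] presence cells;
    ``records`` keeps the surviving raw rows for provenance.
    """

    cells: np.ndarray
    records: pd.DataFrame
    geometry: GridGeometry

    def __len__(self) -> int:
        return len(self.cells)

    def lonlat(self) -> np.ndarray:
        """(n, 2) array of presence cell-center coordinates."""
        out = np.empty((len(self.cells), 2))
        for i, (r, c) in enumerate(self.cells):
            out[i] = self.geometry.cell_center(int(r), int(c))
        return out

    def to_csv(self, path: str | Path) -> None:
        lonlat = self.lonlat()
        pd.DataFrame({
            "row": self.cells[:, 0], "col": self.cells[:, 1],
            "longitude": lonlat[:, 0], "latitude": lonlat[:, 1],
        }).to_csv(path, index=False)


def _resample_continuous(raster: Raster, target: GridGeometry) -> np.ndarray:
    src = raster.geometry
    # source cell-center coordinate axes, increasing for the interpolator
    src_lat = src.north - (np.arange(src.nrows) + 0.5) * src.cellsize
    src_lon = src.west + (np.arange(src.ncols) + 0.5) * src.cellsize
    interp = RegularGridInterpolator(
        (src_lat[::-1], src_lon), raster.data[::-1, :],
        method="linear", bounds_error=False, fill_value=np.nan)
    lon, lat = target.cell_centers()
    pts = np.column_stack([lat.ravel(), lon.ravel()])
    return interp(pts).reshape(target.shape)


def _resample_categorical(raster: Raster, target: GridGeometry) -> np.ndarray:
    """Majority vote of source cells falling in each target cell, ties to
    the lowest code; nearest-neighbor where no source center falls inside."""
    src = raster.geometry
    out = np.full(target.shape, np.nan)
    lon, lat = src.cell_centers()
    vals = raster.data.ravel()
    lon, lat = lon.ravel(), lat.ravel()
    ok = ~np.isnan(vals)
    inside = ok & (lon >= target.west) & (lon < target.east) \
        & (lat > target.south) & (lat <= target.north)
    if np.any(inside):
        col = np.floor((lon[inside] - target.west) / target.cellsize).astype(int)
        row = np.floor((target.north - lat[inside]) / target.cellsize).astype(int)
        row = np.clip(row, 0, target.nrows - 1)
        col = np.clip(col, 0, target.ncols - 1)
        df = pd.DataFrame({"cell": row * target.ncols + col,
                           "code": vals[inside].astype(int)})
        counts = (df.groupby(["cell", "code"]).size()
                    .rename("n").reset_index()
                    .sort_values(["cell", "n", "code"],
                                 ascending=[True, False, True]))
        winners = counts.drop_duplicates("cell")
        out.ravel()[winners["cell"].to_numpy()] = winners["code"].to_numpy()

    # nearest-neighbor fill for target cells with no covering source center
    empty = np.isnan(out)
    if np.any(empty):
        tlon, tlat = target.cell_centers()
        rr = np.clip(np.floor((src.north - tlat[empty]) / src.cellsize).astype(int),
                     0, src.nrows - 1)
        cc = np.clip(np.floor((tlon[empty] - src.west) / src.cellsize).astype(int),
                     0, src.ncols - 1)
        covered = (tlon[empty] >= src.west) & (tlon[empty] < src.east) \
            & (tlat[empty] > src.south) & (tlat[empty] <= src.north)
        fill = np.where(covered, raster.data[rr, cc], np.nan)
        out[empty] = fill
    return out


def align_stack(layers: dict[str, Raster], kinds: dict[str, str],
                target: GridGeometry) -> EnvStack:
    """Resample every layer onto ``target`` and assemble an EnvStack.

    Continuous layers are interpolated bilinearly between source cell
    centers; categorical layers take the majority code of the source
    cells covering each target cell (ties broken by lowest code), with
    nearest-neighbor fallback when upsampling.  A layer already on the
    target geometry is passed through unchanged.
    """
    aligned: dict[str, np.ndarray] = {}
    for name, raster in layers.items():
        kind = kinds.get(name)
        if kind not in (CONTINUOUS, CATEGORICAL):
            raise ValueError(f"layer {name!r}: unknown kind {kind!r}")
        src = raster.geometry
        if (src.west > target.east or src.east < target.west
                or src.south > target.north or src.north < target.south):
            raise ValueError(f"layer {name!r}: extent disjoint from target")
        if src == target:
            aligned[name] = raster.data.copy()
        elif kind == CONTINUOUS:
            aligned[name] = _resample_continuous(raster, target)
        else:
            aligned[name] = _resample_categorical(raster, target)
    return EnvStack(aligned, dict(kinds), target)


def read_occurrence_csv(path: str | Path, delimiter: str = ",") -> pd.DataFrame:
    """Read occurrence records: columns longitude, latitude, and optionally
    species, source, date, excluded (truthy flag)."""
    df = pd.read_csv(path, delimiter=delimiter)
    cols = {c.lower(): c for c in df.columns}
    for required in ("longitude", "latitude"):
        if required not in cols:
            raise ValueError(f"occurrence file lacks a {required!r} column")
    return df.rename(columns={cols[k]: k for k in cols})


def clean_occurrences(records: pd.DataFrame, stack: EnvStack,
                      one_per_cell: bool = True) -> OccurrenceSet:
    """Screen raw records and pin them to presence cells.

    Drops records flagged in an ``excluded`` column (e.g. stopover
    sightings), records outside the grid extent, and records on invalid
    (nodata) cells, logging each count; optionally collapses duplicates
    within one grid cell.  Raises if nothing survives.
    """
    geom = stack.geometry
    mask = stack.validity_mask
    df = records.copy()
    n_raw = len(df)

    if "excluded" in df.columns:
        flagged = df["excluded"].fillna(False).astype(bool)
        df = df[~flagged]
        if flagged.sum():
            log.info("dropped %d flagged (excluded) records", int(flagged.sum()))

    rows, cols, keep_idx = [], [], []
    n_outside = n_invalid = 0
    for idx, rec in df.iterrows():
        lon, lat = float(rec["longitude"]), float(rec["latitude"])
        if not geom.contains(lon, lat):
            n_outside += 1
            continue
        r, c = geom.locate(lon, lat)
        if not mask[r, c]:
            n_invalid += 1
            continue
        rows.append(r)
        cols.append(c)
        keep_idx.append(idx)
    if n_outside:
        log.info("dropped %d records outside the grid extent", n_outside)
    if n_invalid:
        log.info("dropped %d records on nodata cells", n_invalid)

    cells = np.column_stack([rows, cols]) if rows else np.empty((0, 2), dtype=int)
    kept = df.loc[keep_idx]
    if one_per_cell and len(cells):
        # keep first record per cell; order-independent because the cell set
        # (not the representative record) is what the model consumes
        _, first = np.unique(cells[:, 0] * geom.ncols + cells[:, 1],
                             return_index=True)
        first.sort()
        cells = cells[first]
        kept = kept.iloc[first]
        n_dup = len(rows) - len(cells)
        if n_dup:
            log.info("collapsed %d duplicate records within cells", n_dup)
    if len(cells) == 0:
        raise ValueError(f"no records survive cleaning (started with {n_raw})")
    return OccurrenceSet(cells.astype(int), kept.reset_index(drop=True), geom)


def extract(stack: EnvStack, cells: np.ndarray) -> pd.DataFrame:
    """Per-cell predictor vectors for (n, 2) [row, col] cells.

    Returns a DataFrame with one column per layer (continuous as float,
    categorical as integer code).  Requests on nodata cells are errors.
    """
    cells = np.asarray(cells, dtype=int)
    if cells.ndim != 2 or cells.shape[1] != 2:
        raise ValueError("cells must be an (n, 2) [row, col] array")
    g = stack.geometry
    if (np.any(cells < 0) or np.any(cells[:, 0] >= g.nrows)
            or np.any(cells[:, 1] >= g.ncols)):
        raise IndexError("cell index outside grid")
    mask = stack.validity_mask
    bad = ~mask[cells[:, 0], cells[:, 1]]
    if np.any(bad):
        raise ValueError(f"{int(bad.sum())} requested cells are outside the "
                         "validity mask")
    data = {name: arr[cells[:, 0], cells[:, 1]]
            for name, arr in stack.layers.items()}
    df = pd.DataFrame(data)
    for name, kind in stack.kinds.items():
        if kind == CATEGORICAL:
            df[name] = df[name].astype(int)
    return df
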