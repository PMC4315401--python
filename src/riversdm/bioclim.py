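"""Bioclimatic variables (BIO1–BIO19) from monthly climate grids.

The 19 variables are the standard ANUCLIM-style summaries of monthly mean
daily minimum temperature, maximum temperature and precipitation:

====  =======================================================  =====
BIO1  annual mean temperature                                  °C
BIO2  mean diurnal range, mean over months of (tmax − tmin)    °C
BIO3  isothermality, 100·BIO2/BIO7                             —
BIO4  temperature seasonality, 100·SD of monthly mean temp     —
BIO5  max temperature of warmest month                         °C
BIO6  min temperature of coldest month                         °C
BIO7  annual temperature range, BIO5 − BIO6                    °C
BIO8  mean temperature of wettest quarter                      °C
BIO9  mean temperature of driest quarter                       °C
BIO10 mean temperature of warmest quarter                      °C
BIO11 mean temperature of coldest quarter                      °C
BIO12 annual precipitation                                     mm
BIO13 precipitation of wettest month                           mm
BIO14 precipitation of driest month                            mm
BIO15 precipitation seasonality (CV, %)                        —
BIO16 precipitation of wettest quarter                         mm
BIO17 precipitation of driest quarter                          mm
BIO18 precipitation of warmest quarter                         mm
BIO19 precipitation of coldest quarter                         mm
====  =======================================================  =====

A "quarter" is any of the 12 circular windows of three consecutive
months (Jan–Feb–Mar, …, Dec–Jan–Feb).  Warm/cold quarters are selected
by mean temperature, wet/dry quarters by precipitation sum; ties go to
the window with the earliest start month.  Temperatures are plain °C
floats (no ×10 integer packing).  Nodata (NaN) propagates cell-wise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .grid import GridGeometry, Raster, read_ascii_grid, write_ascii_grid

__all__ = ["MonthlyClimate", "BioclimStack", "derive_bioclim"]


@dataclass
class MonthlyClimate:
    """Twelve months of tmin/tmax (°C) and precipitation totals (mm).

    Arrays have shape (12, nrows, ncols) and share one geometry.
    """

    tmin: np.ndarray
    tmax: np.ndarray
    prec: np.ndarray
    geometry: GridGeometry

    def __post_init__(self) -> None:
        self.tmin = np.asarray(self.tmin, dtype=float)
        self.tmax = np.asarray(self.tmax, dtype=float)
        self.prec = np.asarray(self.prec, dtype=float)
        expected = (12, *self.geometry.shape)
        for name, arr in (("tmin", self.tmin), ("tmax", self.tmax),
                          ("prec", self.prec)):
            if arr.shape != expected:
                raise ValueError(
                    f"{name} has shape {arr.shape}, expected {expected} "
                    "(12 months on the shared geometry)")
        both = ~np.isnan(self.tmin) & ~np.isnan(self.tmax)
        if np.any(self.tmax[both] < self.tmin[both]):
            raise ValueError("tmax < tmin at some valid cells")
        if np.any(self.prec[~np.isnan(self.prec)] < 0):
            raise ValueError("negative precipitation")

    @property
    def tavg(self) -> np.ndarray:
        """Monthly mean temperature, (tmin + tmax) / 2."""
        return (self.tmin + self.tmax) / 2.0


@dataclass
class BioclimStack:
    """The 19 derived layers, keyed ``bio_1`` … ``bio_19``."""

    layers: dict[str, np.ndarray]
    geometry: GridGeometry

    def __getitem__(self, key: int | str) -> np.ndarray:
        if isinstance(key, int):
            key = f"bio_{key}"
        return self.layers[key]

    def as_rasters(self) -> dict[str, Raster]:
        return {name: Raster(arr, self.geometry) for name, arr in self.layers.items()}

    def write(self, directory: str | Path) -> None:
        """Write all 19 layers as ``bio_<k>.asc`` ESRI ASCII grids."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, raster in self.as_rasters().items():
            write_ascii_grid(raster, directory / f"{name}.asc")

    @classmethod
    def read(cls, directory: str | Path) -> "BioclimStack":
        directory = Path(directory)
        layers: dict[str, np.ndarray] = {}
        geometry: GridGeometry | None = None
        for k in range(1, 20):
            raster = read_ascii_grid(directory / f"bio_{k}.asc")
            layers[f"bio_{k}"] = raster.data
            geometry = raster.geometry
        assert geometry is not None
        return cls(layers, geometry)


def _quarter_windows(monthly: np.ndarray, how: str) -> np.ndarray:
    """Stack of the 12 circular 3-month aggregates, shape (12, ...).

    Window i covers months (i, i+1, i+2) mod 12.  ``how`` is "mean" or
    "sum".
    """
    stacked = np.stack([monthly[(np.arange(3) + i) % 12].sum(axis=0)
                        for i in range(12)])
    if how == "mean":
        stacked = stacked / 3.0
    return stacked


def _select(values: np.ndarray, selector: np.ndarray, how: str) -> np.ndarray:
    """Pick per-cell the value of the window that extremises the selector.

    ``np.nanargmax``/``nanargmin`` take the first window on ties, i.e.
    the earliest start month.  Cells where the selector is all-NaN give
    NaN.
    """
    flat_sel = selector.reshape(12, -1)
    flat_val = values.reshape(12, -1)
    out = np.full(flat_val.shape[1], np.nan)
    ok = ~np.all(np.isnan(flat_sel), axis=0)
    if np.any(ok):
        fn = np.nanargmax if how == "max" else np.nanargmin
        idx = fn(flat_sel[:, ok], axis=0)
        out[np.flatnonzero(ok)] = flat_val[idx, np.flatnonzero(ok)]
    return out.reshape(values.shape[1:])


def derive_bioclim(climate: MonthlyClimate) -> BioclimStack:
    """Compute all 19 bioclimatic layers from a :class:`MonthlyClimate`."""
    tavg = climate.tavg
    tmin, tmax, prec = climate.tmin, climate.tmax, climate.prec

    q_temp = _quarter_windows(tavg, "mean")   # mean temperature per window
    q_prec = _quarter_windows(prec, "sum")    # precipitation sum per window

    bio: dict[str, np.ndarray] = {}
    bio["bio_1"] = tavg.mean(axis=0)
    bio["bio_2"] = (tmax - tmin).mean(axis=0)
    bio["bio_5"] = tmax.max(axis=0)
    bio["bio_6"] = tmin.min(axis=0)
    bio["bio_7"] = bio["bio_5"] - bio["bio_6"]
    with np.errstate(divide="ignore", invalid="ignore"):
        bio["bio_3"] = np.where(bio["bio_7"] != 0,
                                100.0 * bio["bio_2"] / bio["bio_7"], np.nan)
    bio["bio_4"] = 100.0 * tavg.std(axis=0)   # population SD over 12 months
    bio["bio_8"] = _select(q_temp, q_prec, "max")
    bio["bio_9"] = _select(q_temp, q_prec, "min")
    bio["bio_10"] = _select(q_temp, q_temp, "max")
    bio["bio_11"] = _select(q_temp, q_temp, "min")
    bio["bio_12"] = prec.sum(axis=0)
    bio["bio_13"] = prec.max(axis=0)
    bio["bio_14"] = prec.min(axis=0)
    mean_p = 1.0 + bio["bio_12"] / 12.0       # +1 guards all-dry cells
    bio["bio_15"] = 100.0 * prec.std(axis=0) / mean_p
    bio["bio_16"] = _select(q_prec, q_prec, "max")
    bio["bio_17"] = _select(q_prec, q_prec, "min")
    bio["bio_18"] = _select(q_prec, q_temp, "max")
    bio["bio_19"] = _select(q_prec, q_temp, "min")

    # propagate nodata jointly: a cell missing any month is missing everywhere
    invalid = (np.any(np.isnan(tmin), axis=0) | np.any(np.isnan(tmax), axis=0)
               | np.any(np.isnan(prec), axis=0))
    for arr in bio.values():
        arr[invalid] = np.nan
    ordered = {f"bio_{k}": bio[f"bio_{k}"] for k in range(1, 20)}
    return BioclimStack(ordered, climate.geometry)
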