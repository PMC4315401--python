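"""Synthetic landscapes with known ground truth.

Every pipeline stage is testable without external downloads: this
module generates (i) monthly climate grids as latitudinal/longitudinal
gradients plus a seasonal sinusoid and a smooth Gaussian random field,
(ii) dendritic river networks grown by steepest descent on a synthetic
elevation surface with Strahler orders computed from the topology,
(iii) occurrence records sampled proportionally to a known logistic
suitability of bioclim variables, and (iv) line-transect survey counts
drawn Poisson around a known density.

The default landscape is a 100×100 grid of 0.01° cells whose annual
mean temperature spans roughly 13–21 °C and annual precipitation
840–1560 mm; the default niche is a strong Gaussian ridge centred at
17 °C and 1200 mm (mirroring the study species' preference for mild,
wet river valleys), and the default true density is 0.5 birds·km⁻¹ —
inside the 0.4–0.61 range observed in the field.  Everything is a
deterministic function of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage
from shapely.geometry import LineString

from .bioclim import MonthlyClimate, derive_bioclim
from .grid import GridGeometry, Raster, write_ascii_grid
from .rivers import RiverNetwork, geodesic_length, write_rivers_geojson
from .population import SurveyTable
from .stack import EnvStack

__all__ = [
    "SyntheticTruth", "default_geometry", "default_truth", "make_climate",
    "make_rivers", "sample_occurrences", "simulate_survey",
    "true_suitability", "write_fixture",
]


def default_geometry() -> GridGeometry:
    """100×100 cells of 0.01° — seconds-scale tests with real spatial
    structure."""
    return GridGeometry(west=110.0, north=30.0, cellsize=0.01,
                        nrows=100, ncols=100)


@dataclass
class SyntheticTruth:
    """Known data-generating parameters.

    ``niche`` maps a bioclim layer name to (optimum, width); the true
    suitability is logistic(intercept − Σ ((x−opt)/width)²).
    ``density_true`` is the birds·km⁻¹ rate behind survey counts.
    ``bias`` optionally names a multiplicative observation-bias field.
    """

    niche: dict[str, tuple[float, float]]
    intercept: float = 2.0
    density_true: float = 0.5
    bias: np.ndarray | None = None
    seed: int = 0

    def suitability(self, stack: EnvStack) -> np.ndarray:
        """True logistic suitability on the stack's grid (NaN off-mask)."""
        eta = np.full(stack.geometry.shape, self.intercept)
        for layer, (opt, width) in self.niche.items():
            x = stack.layers[layer]
            eta = eta - ((x - opt) / width) ** 2
        p = 1.0 / (1.0 + np.exp(-eta))
        p[~stack.validity_mask] = np.nan
        return p


def default_truth(seed: int = 0) -> SyntheticTruth:
    """Strong niche on annual mean temperature and annual precipitation."""
    return SyntheticTruth(niche={"bio_1": (17.0, 1.0),
                                 "bio_12": (1200.0, 80.0)}, seed=seed)


def true_suitability(stack: EnvStack, truth: SyntheticTruth) -> np.ndarray:
    return truth.suitability(stack)


def _smooth_field(shape: tuple[int, int], rng: np.random.Generator,
                  sigma: float = 5.0) -> np.ndarray:
    """Smooth unit-SD Gaussian random field (white noise, Gaussian blur)."""
    white = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(white, sigma=sigma, mode="nearest")
    sd = smooth.std()
    return smooth / sd if sd > 0 else smooth


def make_climate(geometry: GridGeometry | None = None, seed: int = 0,
                 t_south: float = 21.0, t_gradient: float = -8.0,
                 seasonal_amplitude: float = 10.0, diurnal_range: float = 8.0,
                 p_base: float = 70.0, p_gradient: float = 60.0,
                 p_seasonal: float = 50.0, noise_sd: float = 1.0,
                 noise_sigma: float = 5.0) -> MonthlyClimate:
    """Monthly climate: gradient + seasonal sinusoid + smooth noise.

    Monthly mean temperature at a cell is
    ``t_south + t_gradient·(lat − lat_south) − A·cos(2πm/12) + noise``
    (month 0 = January, coldest), with tmin/tmax at ∓ half the diurnal
    range.  Monthly precipitation is a west–east gradient plus a
    summer-peaking sinusoid, clipped at zero.  With ``noise_sd=0`` the
    fields are exact deterministic gradients, and the per-cell range of
    monthly mean temperature is exactly twice the seasonal amplitude.
    """
    geometry = geometry or default_geometry()
    rng = np.random.default_rng(seed)
    lon, lat = geometry.cell_centers()
    t_base = t_south + t_gradient * (lat - geometry.south)
    p_grad = p_base + p_gradient * (lon - geometry.west) \
        / (geometry.east - geometry.west)
    t_noise = noise_sd * _smooth_field(geometry.shape, rng, noise_sigma)
    p_noise = 10.0 * noise_sd * _smooth_field(geometry.shape, rng, noise_sigma)

    months = np.arange(12)
    season_t = -seasonal_amplitude * np.cos(2 * np.pi * months / 12)
    season_p = p_seasonal * -np.cos(2 * np.pi * months / 12)  # summer wet
    tmin = np.stack([t_base + s + t_noise - diurnal_range / 2 for s in season_t])
    tmax = tmin + diurnal_range
    prec = np.stack([np.clip(p_grad + s + p_noise, 0.0, None)
                     for s in season_p])
    return MonthlyClimate(tmin, tmax, prec, geometry)


# ---------------------------------------------------------------------------
# river network generation

_NEIGHBORS = [(-1, -1), (-1, 0), (-1, 1), (0, -1),
              (0, 1), (1, -1), (1, 0), (1, 1)]


def _strahler(children_orders: list[int]) -> int:
    """Strahler rule: leaf → 1; equal maxima joining → max+1; else max."""
    if not children_orders:
        return 1
    top = max(children_orders)
    return top + 1 if children_orders.count(top) >= 2 else top


def make_rivers(geometry: GridGeometry | None = None, n_sources: int = 400,
                seed: int = 0, noise_amplitude: float = 0.15
                ) -> tuple[RiverNetwork, dict]:
    """Dendritic network by steepest descent on a synthetic elevation.

    Elevation is a plane dipping towards the south-east corner plus a
    smooth random field; ``n_sources`` headwater cells are dropped on
    the high ground and each flows downhill (8-neighbour steepest
    descent), merging where paths meet.  Strahler orders follow the
    standard rule (headwater reach = 1; two equal orders joining
    increment the order; unequal orders keep the maximum).

    Returns the network (one polyline per reach, vertices at cell
    centers) and a topology dict mapping reach id → downstream reach id
    (−1 at outlets), which independent order checks can traverse.
    """
    geometry = geometry or default_geometry()
    if n_sources < 1:
        raise ValueError("need at least one source")
    rng = np.random.default_rng(seed)
    nr, nc = geometry.shape
    rr, cc = np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij")
    base = ((nr - 1 - rr) + (nc - 1 - cc)) / (nr + nc - 2)
    elev = base + noise_amplitude * _smooth_field(geometry.shape, rng, 4.0)
    if np.ptp(elev) == 0:
        raise ValueError("degenerate flat elevation field")

    def downhill(r: int, c: int) -> tuple[int, int] | None:
        best, best_drop = None, 0.0
        for dr, dc in _NEIGHBORS:
            r2, c2 = r + dr, c + dc
            if not (0 <= r2 < nr and 0 <= c2 < nc):
                continue
            drop = elev[r, c] - elev[r2, c2]
            if drop > best_drop:
                best, best_drop = (r2, c2), drop
        return best

    # sources on the highest quintile, spread by the rng
    order_idx = np.argsort(elev.ravel())[::-1]
    high = order_idx[: max(n_sources * 10, nr * nc // 5)]
    chosen = rng.choice(len(high), size=min(n_sources, len(high)),
                        replace=False)
    sources = [divmod(int(high[i]), nc) for i in chosen]

    downstream_cell: dict[tuple[int, int], tuple[int, int]] = {}
    on_network: set[tuple[int, int]] = set()
    for src in sources:
        cell = src
        path = []
        while cell not in on_network:
            path.append(cell)
            nxt = downhill(*cell)
            if nxt is None:          # local sink or edge: path terminates
                break
            downstream_cell[cell] = nxt
            cell = nxt
        on_network.update(path)

    # per-cell Strahler order via Kahn-style topological sweep
    indeg = {c: 0 for c in on_network}
    for cell, nxt in downstream_cell.items():
        if cell in on_network and nxt in on_network:
            indeg[nxt] += 1
    up_orders: dict[tuple[int, int], list[int]] = {}
    cell_order: dict[tuple[int, int], int] = {}
    queue = [c for c, d in indeg.items() if d == 0]
    while queue:
        cell = queue.pop()
        cell_order[cell] = _strahler(up_orders.get(cell, []))
        nxt = downstream_cell.get(cell)
        if nxt is None or nxt not in indeg:
            continue
        up_orders.setdefault(nxt, []).append(cell_order[cell])
        indeg[nxt] -= 1
        if indeg[nxt] == 0:
            queue.append(nxt)

    # carve reaches: maximal runs between junction cells
    junctions = {c for c, ups in up_orders.items() if len(ups) >= 2}
    leaves = [c for c in cell_order
              if not up_orders.get(c)]  # true headwaters (in-degree 0)
    heads = list(dict.fromkeys(leaves + sorted(junctions)))
    reach_of_head: dict[tuple[int, int], int] = {h: i for i, h in enumerate(heads)}
    rows, topo = [], {}
    for rid, head in enumerate(heads):
        cells = [head]
        cell = head
        while True:
            nxt = downstream_cell.get(cell)
            if nxt is None or nxt not in cell_order:
                topo[rid] = -1
                break
            cells.append(nxt)
            if nxt in junctions:
                topo[rid] = reach_of_head[nxt]
                break
            cell = nxt
        if len(cells) < 2:        # a junction immediately at an outlet
            nxt = downstream_cell.get(head)
            if nxt is not None:
                cells.append(nxt)
            else:
                continue
        coords = [geometry.cell_center(r, c) for r, c in cells]
        rows.append({"id": rid, "order": cell_order[head],
                     "name": f"reach-{rid}",
                     "geometry": LineString(coords)})
    network = RiverNetwork(pd.DataFrame(rows))
    return network, topo


def sample_occurrences(stack: EnvStack, truth: SyntheticTruth, n: int = 200,
                       bias: np.ndarray | None = None, seed: int = 0,
                       species: str = "synthetic-merganser") -> pd.DataFrame:
    """Occurrence records drawn ∝ true suitability × observation bias.

    Cells are drawn with replacement with probability proportional to
    the sampling weight; coordinates are jittered uniformly within the
    cell.  Returns a raw records DataFrame (species, longitude,
    latitude, row, col) ready for :func:`riversdm.stack.clean_occurrences`.
    """
    rng = np.random.default_rng(seed)
    p = truth.suitability(stack)
    weights = np.nan_to_num(p, nan=0.0)
    if bias is not None:
        weights = weights * np.asarray(bias, dtype=float)
    total = weights.sum()
    if total <= 0:
        raise ValueError("all sampling weights are zero")
    flat = weights.ravel() / total
    draws = rng.choice(flat.size, size=n, p=flat)
    g = stack.geometry
    rows, cols = np.divmod(draws, g.ncols)
    # jitter stays 1% of a cell away from the edges so float rounding can
    # never push a record into a neighbouring cell
    jitter_lon = rng.uniform(0.01 * g.cellsize, 0.99 * g.cellsize, size=n)
    jitter_lat = rng.uniform(0.01 * g.cellsize, 0.99 * g.cellsize, size=n)
    lon = g.west + cols * g.cellsize + jitter_lon
    lat = g.north - rows * g.cellsize - jitter_lat
    return pd.DataFrame({"species": species, "longitude": lon,
                         "latitude": lat, "row": rows, "col": cols})


def simulate_survey(network: RiverNetwork, sections: int,
                    truth: SyntheticTruth, seed: int = 0,
                    min_length_km: float = 5.0) -> SurveyTable:
    """Line-transect counts on ``sections`` reaches of the network.

    Sections are whole reaches (contiguous sub-lines) of at least
    ``min_length_km``, sampled without replacement; each count is
    Poisson(D_true × length).
    """
    rng = np.random.default_rng(seed)
    lengths = np.array([geodesic_length(g) for g in network.lines["geometry"]])
    eligible = np.flatnonzero(lengths >= min_length_km)
    if len(eligible) == 0:
        raise ValueError(f"no reach is at least {min_length_km} km long")
    k = min(sections, len(eligible))
    chosen = rng.choice(eligible, size=k, replace=False)
    rows = []
    for i in sorted(chosen):
        length = lengths[i]
        count = int(rng.poisson(truth.density_true * length))
        rows.append({"river": network.lines["name"].iloc[i],
                     "section": f"section-{int(network.lines['id'].iloc[i])}",
                     "length_km": float(length), "count": count})
    return SurveyTable(pd.DataFrame(rows))


def write_fixture(directory: str | Path, seed: int = 0, n_occurrences: int = 200,
                  n_sources: int = 400, n_sections: int = 8) -> dict:
    """Emit a complete fixture directory: climate and bioclim ASCII grids,
    occurrence CSV, river GeoJSON, survey CSV, and a truth manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    geometry = default_geometry()
    truth = default_truth(seed)
    climate = make_climate(geometry, seed=seed)
    bio = derive_bioclim(climate)
    bio.write(directory / "bioclim")
    (directory / "climate").mkdir(exist_ok=True)
    for m in range(12):
        for name, cube in (("tmin", climate.tmin), ("tmax", climate.tmax),
                           ("prec", climate.prec)):
            write_ascii_grid(Raster(cube[m], geometry),
                             directory / "climate" / f"{name}_{m + 1:02d}.asc")
    stack = EnvStack({"bio_1": bio["bio_1"], "bio_12": bio["bio_12"]},
                     {"bio_1": "continuous", "bio_12": "continuous"}, geometry)
    occ = sample_occurrences(stack, truth, n=n_occurrences, seed=seed + 1)
    occ.to_csv(directory / "occurrences.csv", index=False)
    network, _ = make_rivers(geometry, n_sources=n_sources, seed=seed + 2)
    write_rivers_geojson(network, directory / "rivers.geojson")
    survey = simulate_survey(network, n_sections, truth, seed=seed + 3)
    survey.to_csv(directory / "survey.csv")
    manifest = {
        "seed": seed,
        "niche": {k: list(v) for k, v in truth.niche.items()},
        "intercept": truth.intercept,
        "density_true": truth.density_true,
        "n_occurrences": n_occurrences,
        "n_sources": n_sources,
        "n_sections": n_sections,
    }
    with open(directory / "truth.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh)
    return manifest
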