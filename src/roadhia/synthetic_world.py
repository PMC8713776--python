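"""Seeded synthetic study region for exercising the impact pipeline.

The generator emulates the statistical structure the analysis assumes,
on a planar km grid rather than real geography:

* a rectangular grid of square cells partitioned into contiguous counties
  (seeded region growing), counties grouped into states and, for a
  configurable metropolitan fraction, into MSAs;
* census-block-like population points with urban density gradients; the
  tracked population is the adult (30+) population in twelve 5-year age
  bands, aging between the first and last scenario year (the 60–75 bands
  grow fastest);
* Gompertz-like age-specific nonaccidental mortality rates with county
  heterogeneity; 5-year death counts drawn Poisson so that small
  county × age cells naturally fall under small-count reporting rules;
* a baseline PM2.5 surface that increases with population density
  (plus spatially smooth noise) and declines between the first and last
  scenario year;
* distance-decaying source–receptor kernels per pollutant, with primary
  PM2.5 decaying over much shorter distances than NOx (local vs
  transported impacts);
* multi-year county × vehicle-type emission inventories in which
  air-pollutant emission factors decline over time while greenhouse-gas
  factors stay approximately flat and fleet VMT drifts toward trucks.

Everything is driven by one integer seed; a fixed config yields
byte-identical serialized output.
"""

from __future__ import annotations

import heapq
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.ndimage
import scipy.sparse
from scipy.spatial.distance import cdist

from .crf import GEMM_AGE_GROUPS
from .inventory import (
    AIR_POLLUTANTS,
    GHG_SPECIES,
    POLLUTANTS,
    VEHICLE_TYPES,
    EmissionInventory,
)

__all__ = [
    "WorldConfig",
    "GridCell",
    "PopulationBlock",
    "WorldBundle",
    "SRMatrix",
    "DEFAULT_SRM_PARAMS",
    "generate_world",
    "generate_srm",
    "generate_inventories",
]

AGE_GROUPS = GEMM_AGE_GROUPS
_AGE_MIDS = np.array([32.0 + 5 * i for i in range(11)] + [87.0])

# Base age-share profile (30+ population) and fractional growth of each band
# over the full first-to-last-year span: the 60-75 bands grow most, 75+ next,
# under-60 barely.
_AGE_BASE_SHARE = np.array([9.5, 9.5, 9.3, 9.0, 9.0, 8.8, 8.0, 7.0, 6.0, 5.0, 4.0, 3.0])
_AGE_GROWTH = np.array([0.02] * 6 + [0.38, 0.38, 0.38] + [0.16, 0.16, 0.16])
# Fractional change in age-specific mortality rates over the span: slight rise
# in the youngest band, modest decline elsewhere.
_RATE_TREND = np.array([0.02] + [-0.07] * 11)

_GOMPERTZ_R30 = 8.0e-4     # nonaccidental rate at age ~32, per person-year
_GOMPERTZ_SLOPE = 0.095    # per year of age

#: (peak μg/m³ per μg/s at the source cell, decay length km) per pollutant.
#: Primary PM2.5 is strong and local; NOx weaker per unit but far-travelling.
DEFAULT_SRM_PARAMS = {
    "PM25": (2.0e-7, 8.0),
    "NH3": (9.0e-8, 15.0),
    "VOC": (2.0e-8, 25.0),
    "SO2": (6.0e-9, 40.0),
    "NOX": (1.2e-8, 60.0),
}

_MILES_PER_ADULT = 12_000.0

_VMT_SHARE = {
    "Motorcycle": 0.008, "Passenger Car": 0.42, "Passenger Truck": 0.28,
    "Light Commercial Truck": 0.09, "Intercity Bus": 0.002, "Transit Bus": 0.004,
    "School Bus": 0.006, "Refuse Truck": 0.004, "Single Unit Short-haul Truck": 0.035,
    "Single Unit Long-haul Truck": 0.015, "Motor Home": 0.006,
    "Combination Short-haul Truck": 0.03, "Combination Long-haul Truck": 0.06,
}

# Reference-year emission factors, g/mile, per vehicle type:
# (PM25, SO2, NOX, NH3, VOC, CO2, CH4, N2O)
_BASE_EF = {
    "Motorcycle":                   (0.020, 0.003, 0.70, 0.005, 2.00, 200.0, 0.070, 0.005),
    "Passenger Car":                (0.010, 0.004, 0.25, 0.030, 0.25, 370.0, 0.020, 0.008),
    "Passenger Truck":              (0.015, 0.005, 0.35, 0.035, 0.30, 480.0, 0.025, 0.012),
    "Light Commercial Truck":       (0.020, 0.006, 0.50, 0.030, 0.35, 520.0, 0.025, 0.012),
    "Intercity Bus":                (0.120, 0.010, 6.00, 0.015, 0.40, 1400.0, 0.010, 0.006),
    "Transit Bus":                  (0.150, 0.010, 7.00, 0.015, 0.50, 1700.0, 0.150, 0.006),
    "School Bus":                   (0.100, 0.008, 4.00, 0.012, 0.45, 1100.0, 0.020, 0.006),
    "Refuse Truck":                 (0.180, 0.012, 8.00, 0.015, 0.60, 2200.0, 0.020, 0.008),
    "Single Unit Short-haul Truck": (0.120, 0.010, 4.50, 0.012, 0.50, 1300.0, 0.020, 0.007),
    "Single Unit Long-haul Truck":  (0.120, 0.010, 4.50, 0.012, 0.50, 1300.0, 0.020, 0.007),
    "Motor Home":                   (0.080, 0.008, 2.50, 0.012, 0.50, 900.0, 0.020, 0.007),
    "Combination Short-haul Truck": (0.200, 0.012, 9.00, 0.012, 0.55, 1800.0, 0.015, 0.008),
    "Combination Long-haul Truck":  (0.200, 0.012, 9.00, 0.012, 0.55, 1750.0, 0.015, 0.008),
}

_HEAVY_DUTY = {
    "Intercity Bus", "Transit Bus", "School Bus", "Refuse Truck",
    "Single Unit Short-haul Truck", "Single Unit Long-haul Truck",
    "Combination Short-haul Truck", "Combination Long-haul Truck",
}

_REFUELING_EF_VOC = 0.05  # g per total-fleet mile


@dataclass(frozen=True)
class WorldConfig:
    grid_nx: int = 20
    grid_ny: int = 20
    cell_km: float = 5.0
    n_counties: int = 16
    n_states: int = 4
    n_msas: int = 3
    seed: int = 0
    years: tuple[int, ...] = (2008, 2011, 2014, 2017)
    urban_fraction: float = 0.375

    def validate(self) -> None:
        n_cells = self.grid_nx * self.grid_ny
        if not (n_cells >= self.n_counties >= self.n_states >= 1):
            raise ValueError(
                f"need cells ({n_cells}) >= counties ({self.n_counties}) "
                f">= states ({self.n_states}) >= 1"
            )
        if self.n_msas < 0 or self.n_msas > self.n_counties:
            raise ValueError("n_msas must be between 0 and n_counties")
        if self.cell_km <= 0:
            raise ValueError("cell_km must be positive")
        if len(self.years) < 2 or list(self.years) != sorted(set(self.years)):
            raise ValueError("years must be >= 2 strictly increasing values")
        if not (0.0 <= self.urban_fraction <= 1.0):
            raise ValueError("urban_fraction must be in [0, 1]")


@dataclass(frozen=True)
class GridCell:
    id: int
    x: float
    y: float
    county_id: int


@dataclass(frozen=True)
class PopulationBlock:
    id: int
    x: float
    y: float
    county_id: int
    population: int


@dataclass
class WorldBundle:
    """Generated geography, demography, air quality, and region maps.

    Tables are long-form pandas DataFrames; ``population`` counts the adult
    (30+) population per county × age band × year, and ``mortality`` holds
    5-year nonaccidental death counts on the same index.
    """

    config: WorldConfig
    cells: pd.DataFrame       # cell, x, y, county
    blocks: pd.DataFrame      # block, x, y, county, population
    counties: pd.DataFrame    # county, state, msa (-1 = none), urban
    population: pd.DataFrame  # county, age_group, year, population
    mortality: pd.DataFrame   # county, age_group, year, deaths_5y
    pm25: pd.DataFrame        # year, cell, pm25

    @property
    def county_ids(self) -> np.ndarray:
        return self.counties["county"].to_numpy()

    @property
    def age_groups(self) -> tuple[str, ...]:
        return AGE_GROUPS

    def cell_list(self) -> list[GridCell]:
        return [GridCell(int(r.cell), float(r.x), float(r.y), int(r.county))
                for r in self.cells.itertuples()]

    def block_list(self) -> list[PopulationBlock]:
        return [PopulationBlock(int(r.block), float(r.x), float(r.y), int(r.county),
                                int(r.population))
                for r in self.blocks.itertuples()]

    def county_state(self) -> pd.Series:
        return self.counties.set_index("county")["state"]

    def county_msa(self) -> pd.Series:
        """county → MSA id, -1 meaning no MSA membership."""
        return self.counties.set_index("county")["msa"]

    def pm25_array(self, year: int) -> np.ndarray:
        sub = self.pm25[self.pm25["year"] == year].sort_values("cell")
        if sub.empty:
            raise KeyError(f"no PM2.5 surface for year {year}")
        return sub["pm25"].to_numpy()

    def _matrix(self, table: pd.DataFrame, value: str, year: int) -> np.ndarray:
        sub = table[table["year"] == year]
        if sub.empty:
            raise KeyError(f"no {value} data for year {year}")
        wide = sub.pivot(index="county", columns="age_group", values=value)
        wide = wide.loc[self.county_ids, list(AGE_GROUPS)]
        return wide.to_numpy(dtype=float)

    def population_matrix(self, year: int) -> np.ndarray:
        """counties × age-band person counts."""
        return self._matrix(self.population, "population", year)

    def deaths5_matrix(self, year: int) -> np.ndarray:
        """counties × age-band 5-year death counts."""
        return self._matrix(self.mortality, "deaths_5y", year)

    # --- serialization ---------------------------------------------------

    _TABLES = ("cells", "blocks", "counties", "population", "mortality", "pm25")

    def save(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        for name in self._TABLES:
            getattr(self, name).to_csv(d / f"{name}.csv", index=False,
                                       float_format="%.10g", lineterminator="\n")
        meta = {
            "config": asdict(self.config),
            "age_groups": list(AGE_GROUPS),
            "county_state": {str(k): int(v) for k, v in self.county_state().items()},
            "county_msa": {str(k): int(v) for k, v in self.county_msa().items()},
        }
        meta["config"]["years"] = list(self.config.years)
        (d / "meta.json").write_text(json.dumps(meta, indent=1, sort_keys=True) + "\n")

    @classmethod
    def load(cls, directory: str | Path) -> "WorldBundle":
        d = Path(directory)
        meta = json.loads((d / "meta.json").read_text())
        cfg = dict(meta["config"])
        cfg["years"] = tuple(cfg["years"])
        tables = {name: pd.read_csv(d / f"{name}.csv") for name in cls._TABLES}
        return cls(config=WorldConfig(**cfg), **tables)


@dataclass
class SRMatrix:
    """Sparse source–receptor matrix for one pollutant.

    ``matrix[i, j]`` is the steady-state concentration increase (μg/m³) at
    receptor cell j per 1 μg/s of sustained emissions at source cell i.
    """

    pollutant: str
    matrix: scipy.sparse.csr_array
    units: str = "ug/m3 per ug/s"
    peak: float = float("nan")
    decay_km: float = float("nan")

    def save(self, path: str | Path) -> None:
        """JSON header line followed by 'i j value' coordinate triplets."""
        coo = self.matrix.tocoo()
        header = json.dumps({
            "pollutant": self.pollutant, "units": self.units,
            "shape": list(self.matrix.shape),
            "peak": self.peak, "decay_km": self.decay_km,
        }, sort_keys=True)
        order = np.lexsort((coo.col, coo.row))
        lines = [header]
        lines += [f"{coo.row[k]} {coo.col[k]} {coo.data[k]:.10e}" for k in order]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "SRMatrix":
        lines = Path(path).read_text().splitlines()
        meta = json.loads(lines[0])
        rows, cols, vals = [], [], []
        for ln in lines[1:]:
            i, j, v = ln.split()
            rows.append(int(i)); cols.append(int(j)); vals.append(float(v))
        mat = scipy.sparse.csr_array(
            (vals, (rows, cols)), shape=tuple(meta["shape"]))
        return cls(pollutant=meta["pollutant"], matrix=mat, units=meta["units"],
                   peak=meta.get("peak", float("nan")),
                   decay_km=meta.get("decay_km", float("nan")))


# --------------------------------------------------------------------------
# world generation


def _grow_counties(nx: int, ny: int, n_counties: int, rng: np.random.Generator) -> np.ndarray:
    """Partition the grid into contiguous counties by round-robin region growth.

    Each county claims, in turn, the lowest-id unassigned cell adjacent to
    its current region, guaranteeing contiguity and near-equal sizes.
    """
    n = nx * ny
    county = np.full(n, -1, dtype=int)
    seeds = np.sort(rng.choice(n, size=n_counties, replace=False))
    heaps: list[list[int]] = [[] for _ in range(n_counties)]

    def neighbors(c: int):
        x, y = c % nx, c // nx
        if x > 0: yield c - 1
        if x < nx - 1: yield c + 1
        if y > 0: yield c - nx
        if y < ny - 1: yield c + nx

    for k, s in enumerate(seeds):
        county[s] = k
        for nb in neighbors(int(s)):
            heapq.heappush(heaps[k], nb)
    remaining = n - n_counties
    while remaining:
        progressed = False
        for k in range(n_counties):
            h = heaps[k]
            while h and county[h[0]] != -1:
                heapq.heappop(h)
            if not h:
                continue
            cell = heapq.heappop(h)
            county[cell] = k
            for nb in neighbors(cell):
                if county[nb] == -1:
                    heapq.heappush(h, nb)
            remaining -= 1
            progressed = True
            if not remaining:
                break
        if not progressed:  # pragma: no cover - grid is connected
            raise RuntimeError("region growth stalled")
    return county


def _largest_remainder(total: int, shares: np.ndarray) -> np.ndarray:
    """Integer allocation of `total` by `shares` that sums exactly to total."""
    raw = total * shares / shares.sum()
    base = np.floor(raw).astype(int)
    short = int(total - base.sum())
    if short > 0:
        order = np.argsort(-(raw - base), kind="stable")
        base[order[:short]] += 1
    return base


def generate_world(config: WorldConfig | None = None) -> WorldBundle:
    """Generate a complete synthetic study region from one seeded config."""
    config = config or WorldConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    nx, ny, ck = config.grid_nx, config.grid_ny, config.cell_km
    n_cells = nx * ny
    cell_ids = np.arange(n_cells)
    cx = (cell_ids % nx + 0.5) * ck
    cy = (cell_ids // nx + 0.5) * ck

    county_of_cell = _grow_counties(nx, ny, config.n_counties, rng)
    cells = pd.DataFrame({"cell": cell_ids, "x": cx, "y": cy, "county": county_of_cell})

    # states: split counties into contiguous-in-x bands of near-equal count
    county_cx = cells.groupby("county")["x"].mean()
    order = county_cx.sort_values(kind="stable").index.to_numpy()
    state_of = np.empty(config.n_counties, dtype=int)
    for s, chunk in enumerate(np.array_split(order, config.n_states)):
        state_of[chunk] = s

    # metropolitan counties and their MSA grouping
    msa_of = np.full(config.n_counties, -1, dtype=int)
    urban = np.zeros(config.n_counties, dtype=bool)
    if config.n_msas > 0:
        n_urban = min(config.n_counties,
                      max(config.n_msas, round(config.urban_fraction * config.n_counties)))
        urban_ids = np.sort(rng.choice(config.n_counties, size=n_urban, replace=False))
        urban[urban_ids] = True
        cores = np.sort(rng.choice(urban_ids, size=config.n_msas, replace=False))
        county_cy = cells.groupby("county")["y"].mean()
        pts = np.column_stack([county_cx.loc[urban_ids], county_cy.loc[urban_ids]])
        core_pts = np.column_stack([county_cx.loc[cores], county_cy.loc[cores]])
        nearest = np.argmin(cdist(pts, core_pts), axis=1)
        msa_of[urban_ids] = nearest

    counties = pd.DataFrame({
        "county": np.arange(config.n_counties),
        "state": state_of,
        "msa": msa_of,
        "urban": urban,
    })

    # population blocks: 1-3 per cell, urban counties much denser
    base_density = 30.0  # adults (30+) per km^2, rural
    urban_mult = 8.0
    rows = []
    bid = 0
    cell_area = ck * ck
    for c in cell_ids:
        k = int(rng.integers(1, 4))
        mean_pop = base_density * cell_area * (urban_mult if urban[county_of_cell[c]] else 1.0)
        mean_pop *= rng.lognormal(0.0, 0.5)
        weights = rng.dirichlet(np.ones(k))
        offs = rng.uniform(-0.45, 0.45, size=(k, 2)) * ck
        for b in range(k):
            pop = int(rng.poisson(mean_pop * weights[b]))
            rows.append((bid, cx[c] + offs[b, 0], cy[c] + offs[b, 1],
                         int(county_of_cell[c]), pop))
            bid += 1
    blocks = pd.DataFrame(rows, columns=["block", "x", "y", "county", "population"])

    county_pop0 = blocks.groupby("county")["population"].sum().reindex(
        np.arange(config.n_counties), fill_value=0)

    # county x age x year populations; first year matches block totals exactly
    y0, yN = config.years[0], config.years[-1]
    pop_rows = []
    for year in config.years:
        f = (year - y0) / (yN - y0)
        for c in range(config.n_counties):
            total0 = int(county_pop0[c])
            base_alloc = _largest_remainder(total0, _AGE_BASE_SHARE)
            grown = np.rint(base_alloc * (1.0 + f * _AGE_GROWTH)).astype(int) \
                if f > 0 else base_alloc
            for a, g in enumerate(AGE_GROUPS):
                pop_rows.append((c, g, year, int(grown[a])))
    population = pd.DataFrame(pop_rows, columns=["county", "age_group", "year", "population"])

    # mortality: Gompertz-like rates with county heterogeneity; Poisson 5-y counts
    county_mult = rng.lognormal(0.0, 0.12, size=config.n_counties)
    mort_rows = []
    for year in config.years:
        f = (year - y0) / (yN - y0)
        rates = _GOMPERTZ_R30 * np.exp(_GOMPERTZ_SLOPE * (_AGE_MIDS - 32.0))
        rates = rates * (1.0 + f * _RATE_TREND)
        pops = population[population["year"] == year].pivot(
            index="county", columns="age_group", values="population"
        ).loc[np.arange(config.n_counties), list(AGE_GROUPS)].to_numpy()
        lam = rates[None, :] * county_mult[:, None] * pops * 5.0
        draws = rng.poisson(lam)
        for c in range(config.n_counties):
            for a, g in enumerate(AGE_GROUPS):
                mort_rows.append((c, g, year, int(draws[c, a])))
    mortality = pd.DataFrame(mort_rows, columns=["county", "age_group", "year", "deaths_5y"])

    # PM2.5 surface: density-driven plus smooth noise, declining over time.
    # Blocks lie strictly inside their generating cell, so the cell of each
    # block can be recovered from its coordinates.
    cell_pop = np.zeros(n_cells)
    bx = np.clip((blocks["x"].to_numpy() / ck).astype(int), 0, nx - 1)
    by = np.clip((blocks["y"].to_numpy() / ck).astype(int), 0, ny - 1)
    np.add.at(cell_pop, by * nx + bx, blocks["population"].to_numpy())
    dens_norm = cell_pop / max(cell_pop.max(), 1.0)
    white = rng.normal(0.0, 1.0, size=(ny, nx))
    smooth = scipy.ndimage.gaussian_filter(white, sigma=1.5)
    smooth = smooth / max(smooth.std(), 1e-12)
    base_field = np.maximum(1.5, 6.0 + 9.0 * dens_norm + 0.8 * smooth.ravel())
    pm_rows = []
    for year in config.years:
        f = (year - y0) / (yN - y0)
        surf = base_field * (1.0 - 0.28 * f)
        for c in cell_ids:
            pm_rows.append((year, int(c), float(surf[c])))
    pm25 = pd.DataFrame(pm_rows, columns=["year", "cell", "pm25"])

    return WorldBundle(config=config, cells=cells, blocks=blocks, counties=counties,
                       population=population, mortality=mortality, pm25=pm25)


# --------------------------------------------------------------------------
# source-receptor kernels


def generate_srm(
    cells: pd.DataFrame,
    pollutant_params: dict[str, tuple[float, float]] | None = None,
    sparsity_cutoff: float = 1e-13,
) -> dict[str, SRMatrix]:
    """Exponential distance-decay source–receptor kernels, one per pollutant.

    Entry (i, j) = peak · exp(−dist(i, j)/decay_length), zeroed below the
    sparsity cutoff. The diagonal (self-receptor) entry is each row's
    maximum, and short-decay species concentrate impacts near the source.
    """
    params = pollutant_params if pollutant_params is not None else DEFAULT_SRM_PARAMS
    for p, (peak, decay) in params.items():
        if peak <= 0 or decay <= 0:
            raise ValueError(f"nonpositive kernel parameters for {p}")
    coords = cells.sort_values("cell")[["x", "y"]].to_numpy(dtype=float)
    d = cdist(coords, coords)
    out = {}
    for p, (peak, decay) in params.items():
        dense = peak * np.exp(-d / decay)
        dense[dense < sparsity_cutoff] = 0.0
        out[p] = SRMatrix(pollutant=p, matrix=scipy.sparse.csr_array(dense),
                          peak=peak, decay_km=decay)
    return out


# --------------------------------------------------------------------------
# inventories


def default_ef_trend() -> dict[tuple[str, str], float]:
    """Annual EF multipliers: air pollutants decline (heavy duty fastest),
    greenhouse gases stay approximately flat."""
    trend = {}
    for v in VEHICLE_TYPES:
        for p in AIR_POLLUTANTS:
            trend[(v, p)] = 0.88 if v in _HEAVY_DUTY else 0.92
        for p in GHG_SPECIES:
            trend[(v, p)] = 0.999
    return trend


def default_vmt_trend() -> dict[str, float]:
    """Annual VMT multipliers: cars shrink, trucks grow."""
    t = {v: 1.007 for v in VEHICLE_TYPES}
    t.update({
        "Passenger Car": 0.982,
        "Passenger Truck": 1.030,
        "Light Commercial Truck": 1.030,
        "Single Unit Short-haul Truck": 1.030,
        "Single Unit Long-haul Truck": 1.030,
        "Combination Short-haul Truck": 1.030,
        "Combination Long-haul Truck": 1.030,
        "Motor Home": 1.000,
        "Refuse Truck": 1.020,
    })
    return t


def generate_inventories(
    world: WorldBundle,
    trend: dict[tuple[str, str], float] | None = None,
    vmt_trend: dict[str, float] | None = None,
) -> list[EmissionInventory]:
    """Emission inventories for every scenario year of the world.

    Per-county VMT follows the first-year adult population and a fixed fleet
    share per vehicle type, then drifts with per-class annual VMT multipliers;
    emissions are EF(year) × VMT(year) with county-specific EF noise around
    the reference factors. Refueling is a VOC-dominated block proportional to
    total fleet VMT.
    """
    trend = trend if trend is not None else default_ef_trend()
    vmt_trend = vmt_trend if vmt_trend is not None else default_vmt_trend()
    cfg = world.config
    rng = np.random.default_rng((cfg.seed, 9173))
    y0 = cfg.years[0]
    county_ids = world.county_ids
    state_of = world.county_state()
    pop0 = world.population[world.population["year"] == y0] \
        .groupby("county")["population"].sum().reindex(county_ids, fill_value=0)

    # county-level EF heterogeneity, fixed across years
    ef_noise = {
        (c, v, p): rng.lognormal(0.0, 0.05)
        for c in county_ids for v in VEHICLE_TYPES for p in POLLUTANTS
    }
    vmt_noise = {(c, v): rng.lognormal(0.0, 0.10)
                 for c in county_ids for v in VEHICLE_TYPES}

    inventories = []
    for year in cfg.years:
        dy = year - y0
        em_rows, vmt_rows, ref_rows = [], [], []
        for c in county_ids:
            st = int(state_of[c])
            fleet_vmt = 0.0
            for v in VEHICLE_TYPES:
                vmt = (pop0[c] * _MILES_PER_ADULT * _VMT_SHARE[v]
                       * vmt_noise[(c, v)] * vmt_trend[v] ** dy)
                fleet_vmt += vmt
                vmt_rows.append((c, st, v, vmt))
                for ip, p in enumerate(POLLUTANTS):
                    ef = _BASE_EF[v][ip] * ef_noise[(c, v, p)] * trend[(v, p)] ** dy
                    em_rows.append((c, st, v, p, ef * vmt / 1e6))
            for p in AIR_POLLUTANTS:
                ef_ref = _REFUELING_EF_VOC if p == "VOC" else 0.0
                ef_ref *= trend[("Passenger Car", p)] ** dy
                ref_rows.append((c, st, p, ef_ref * fleet_vmt / 1e6))
        inventories.append(EmissionInventory(
            year=year,
            emissions=pd.DataFrame(
                em_rows, columns=["county", "state", "vehicle_type", "pollutant",
                                  "emissions_tons"]),
            vmt=pd.DataFrame(vmt_rows, columns=["county", "state", "vehicle_type",
                                                "vmt_miles"]),
            refueling=pd.DataFrame(ref_rows, columns=["county", "state", "pollutant",
                                                      "emissions_tons"]),
        ))
    return inventories
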