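"""Per-county baseline inputs: population weights, baseline PM2.5, mortality.

Three ingredients feed the marginal-impact engine:

* a population-weight matrix **P** (counties × grid cells) giving the
  fraction of each county's population residing in each cell — this is
  what maps cell-level concentration fields onto county populations and
  allocates county emissions to cells;
* county baseline PM2.5, computed by assigning each census block the
  inverse-distance-weighted mean of the four nearest cell values and
  population-averaging blocks within counties;
* a county × age-group mortality table built from 5-year death counts and
  person-years, with a small-count fallback: county × age cells with fewer
  than 50 deaths in the 5-year window use the state-level rate instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "PopulationWeightMatrix",
    "MortalityTable",
    "ConcentrationField",
    "build_population_weights",
    "county_baseline_pm25",
    "build_mortality_table",
    "percent_change",
]

logger = logging.getLogger(__name__)

_IDW_EPS_KM = 1e-9  # distance floor so a block on a cell centroid takes its value


@dataclass
class PopulationWeightMatrix:
    """Row-stochastic counties × cells matrix of population shares."""

    matrix: np.ndarray  # (n_counties, n_cells)
    county_ids: np.ndarray
    n_cells: int

    def __post_init__(self) -> None:
        rs = self.matrix.sum(axis=1)
        if not np.allclose(rs, 1.0, atol=1e-9):
            raise ValueError("population weight rows must sum to 1")
        if (self.matrix < 0).any() or (self.matrix > 1 + 1e-12).any():
            raise ValueError("population weights must lie in [0, 1]")


@dataclass
class MortalityTable:
    """Annual deaths by county × age group, and the rates that produced them.

    ``deaths[i, a] = rate[i, a] × target_population[i, a] / 1e5`` where the
    rate is per 100,000 person-years; ``state_fallback`` marks cells whose
    rate came from the state level under the small-count rule.
    """

    deaths: np.ndarray        # (n_counties, n_ages), deaths/year
    rates_per_100k: np.ndarray
    county_ids: np.ndarray
    age_groups: tuple[str, ...]
    state_fallback: np.ndarray  # boolean, same shape

    @property
    def total_deaths(self) -> float:
        return float(self.deaths.sum())


@dataclass
class ConcentrationField:
    """A PM2.5 field at cell resolution with its county aggregation (μg/m³)."""

    cell_values: np.ndarray
    county_values: np.ndarray
    county_ids: np.ndarray


def build_population_weights(
    blocks: pd.DataFrame,
    cells: pd.DataFrame,
    counties: np.ndarray | pd.DataFrame,
) -> PopulationWeightMatrix:
    """Fraction of each county's population nearest to each grid cell.

    Each block is assigned to the cell with the nearest centroid (ties to
    the lowest cell id); row i of the result distributes county i's
    population over cells. Counties with zero population fall back to a
    uniform row over their own cells; a county with neither blocks nor
    cells is an error.
    """
    county_ids = (counties["county"].to_numpy()
                  if isinstance(counties, pd.DataFrame) else np.asarray(counties))
    cells_sorted = cells.sort_values("cell")
    coords = cells_sorted[["x", "y"]].to_numpy(dtype=float)
    n_cells = len(cells_sorted)
    tree = cKDTree(coords)
    _, nearest = tree.query(blocks[["x", "y"]].to_numpy(dtype=float), k=1)

    mat = np.zeros((len(county_ids), n_cells))
    pop = blocks["population"].to_numpy(dtype=float)
    bcounty = blocks["county"].to_numpy()
    county_index = {c: i for i, c in enumerate(county_ids)}
    for b in range(len(blocks)):
        mat[county_index[bcounty[b]], nearest[b]] += pop[b]

    cell_county = cells_sorted["county"].to_numpy()
    for i, c in enumerate(county_ids):
        total = mat[i].sum()
        if total > 0:
            mat[i] /= total
        else:
            own = np.flatnonzero(cell_county == c)
            if own.size == 0:
                raise ValueError(f"county {c} has no population and no cells")
            mat[i, own] = 1.0 / own.size
    return PopulationWeightMatrix(matrix=mat, county_ids=county_ids, n_cells=n_cells)


def county_baseline_pm25(
    surface: np.ndarray,
    blocks: pd.DataFrame,
    cells: pd.DataFrame,
    counties: np.ndarray | pd.DataFrame,
) -> ConcentrationField:
    """Population-weighted county baseline PM2.5 from a cell surface.

    Each block takes the inverse-distance-weighted mean of the four nearest
    cell centroids (1/d weights with a 1e-9 km floor, so a coincident
    centroid dominates); county values population-average their blocks.
    Zero-population counties use the unweighted mean of their block values.
    """
    county_ids = (counties["county"].to_numpy()
                  if isinstance(counties, pd.DataFrame) else np.asarray(counties))
    cells_sorted = cells.sort_values("cell")
    coords = cells_sorted[["x", "y"]].to_numpy(dtype=float)
    if len(coords) < 4:
        raise ValueError("need at least 4 grid cells for 4-nearest interpolation")
    vals = np.asarray(surface, dtype=float)
    if vals.shape[0] != len(coords):
        raise ValueError("surface length must equal number of cells")

    tree = cKDTree(coords)
    dist, idx = tree.query(blocks[["x", "y"]].to_numpy(dtype=float), k=4)
    w = 1.0 / np.maximum(dist, _IDW_EPS_KM)
    block_vals = (w * vals[idx]).sum(axis=1) / w.sum(axis=1)

    pop = blocks["population"].to_numpy(dtype=float)
    bcounty = blocks["county"].to_numpy()
    county_vals = np.empty(len(county_ids))
    for i, c in enumerate(county_ids):
        sel = bcounty == c
        if not sel.any():
            raise ValueError(f"county {c} has no blocks")
        p = pop[sel]
        county_vals[i] = (np.average(block_vals[sel], weights=p) if p.sum() > 0
                          else block_vals[sel].mean())
    return ConcentrationField(cell_values=vals, county_values=county_vals,
                              county_ids=county_ids)


def build_mortality_table(
    death_counts_5y: np.ndarray,
    population_5y: np.ndarray,
    population_target: np.ndarray,
    age_groups,
    county_ids: np.ndarray,
    county_state: pd.Series | dict,
    min_counts: int = 50,
) -> MortalityTable:
    """Annual deaths per county × age group from 5-year counts and person-years.

    The county rate is deaths over the 5-year window divided by 5-year
    person-years (mid-period population × 5). County × age cells with fewer
    than ``min_counts`` deaths in the window are replaced by the state-level
    rate for that age group (state deaths over state person-years) before
    deaths are projected onto the target-year population.
    """
    d5 = np.asarray(death_counts_5y, dtype=float)
    p5 = np.asarray(population_5y, dtype=float)
    pt = np.asarray(population_target, dtype=float)
    if d5.shape != p5.shape or d5.shape != pt.shape:
        raise ValueError("death, person-year and target population shapes must match")
    if (d5 < 0).any() or (p5 < 0).any() or (pt < 0).any():
        raise ValueError("counts and populations must be nonnegative")
    if ((p5 == 0) & (d5 > 0)).any():
        raise ValueError("zero person-years with nonzero deaths")

    person_years = p5 * 5.0
    with np.errstate(divide="ignore", invalid="ignore"):
        county_rate = np.where(person_years > 0, d5 / person_years, 0.0)

    states = pd.Series(county_state).reindex(county_ids).to_numpy()
    state_rate = np.zeros_like(county_rate)
    for s in np.unique(states):
        sel = states == s
        sd = d5[sel].sum(axis=0)
        sp = person_years[sel].sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            sr = np.where(sp > 0, sd / sp, 0.0)
        state_rate[sel] = sr[None, :]

    fallback = d5 < min_counts
    n_fb = int(fallback.sum())
    if n_fb:
        logger.info("mortality table: %d county-age cells below %d deaths use state rates",
                    n_fb, min_counts)
    rate = np.where(fallback, state_rate, county_rate)
    deaths = rate * pt
    return MortalityTable(
        deaths=deaths,
        rates_per_100k=rate * 1e5,
        county_ids=np.asarray(county_ids),
        age_groups=tuple(age_groups),
        state_fallback=fallback,
    )


def percent_change(a: float, b: float) -> float:
    """Percent change from a to b: 100·(b−a)/a. Undefined at a = 0."""
    if a == 0:
        raise ZeroDivisionError("percent change from zero is undefined")
    return 100.0 * (b - a) / a
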