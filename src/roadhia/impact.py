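"""Marginal-impact engine: damages per ton by source and receptor county.

The production path is a linearized matrix computation. For one pollutant,

    MI = P · SRM · Pᵀ · Dg(m) · k          (deaths per metric ton), with
    m_i = Σ_a D[i, a] · S[i, a]            (deaths per μg/m³ in county i),

where P is the counties × cells population-weight matrix, SRM the cell
source–receptor matrix (μg/m³ per μg/s), D annual baseline deaths by
county × age, S the CRF slope matrix (fractional mortality increase per
μg/m³), and k = 10¹²/(24·3600·365) converts a 1 μg/s sustained emission
rate into 1 metric ton per year. MI[i, j] is the impact in receptor county
j per metric ton emitted in source county i; multiplying by VSL and the
cessation-lag NPV factor turns deaths into dollars.

The linearization is justified because realistic emission perturbations
move county concentrations by far less than the curvature scale of the
CRF; ``eq1_oracle`` keeps the exact nonlinear finite-perturbation sum
available as a validation reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse

from .baseline import PopulationWeightMatrix
from .crf import CRFModel, build_slope_matrix, hazard_ratio
from .inventory import EFTable, ScenarioEmissions, ghg_co2e
from .synthetic_world import SRMatrix
from .valuation import MonetizationParams

__all__ = [
    "K_UGS_PER_TON",
    "mortality_diagonal",
    "ImpactMatrix",
    "ImpactSummary",
    "marginal_impact_matrix",
    "eq1_oracle",
    "scenario_impacts",
    "partition_impacts",
    "impacts_per_mile",
]

#: Conversion from a 1 μg/s sustained emission rate to 1 metric ton/year.
K_UGS_PER_TON = 1e12 / (24 * 3600 * 365)


def mortality_diagonal(D: np.ndarray, S: np.ndarray) -> np.ndarray:
    """Per-county deaths per 1 μg/m³: the diagonal of D·Sᵀ, m_i = Σ_a D[i,a]·S[i,a]."""
    D = np.asarray(D, dtype=float)
    S = np.asarray(S, dtype=float)
    if D.shape != S.shape:
        raise ValueError("deaths and slope matrices must share shape (counties × ages)")
    return np.einsum("ia,ia->i", D, S)


@dataclass
class ImpactMatrix:
    """Source-county × receptor-county marginal damages for one pollutant.

    ``values[i, j]`` is deaths (or USD when monetized) in receptor county j
    per metric ton emitted in source county i.
    """

    pollutant: str
    values: np.ndarray
    county_ids: np.ndarray
    units: str = "deaths per metric ton"
    crf: str = "gemm"

    def per_ton(self) -> np.ndarray:
        """Total damage per ton by source county (row sums)."""
        return self.values.sum(axis=1)

    def monetized(self, valuation: MonetizationParams) -> "ImpactMatrix":
        if "USD" in self.units:
            raise ValueError("impact matrix is already monetized")
        return ImpactMatrix(
            pollutant=self.pollutant,
            values=self.values * valuation.value_per_death,
            county_ids=self.county_ids,
            units="USD per metric ton",
            crf=self.crf,
        )

    def save(self, path) -> None:
        import json
        from pathlib import Path
        header = json.dumps({"pollutant": self.pollutant, "units": self.units,
                             "crf": self.crf, "shape": list(self.values.shape)},
                            sort_keys=True)
        lines = [header]
        nz = np.argwhere(self.values != 0)
        for i, j in nz:
            lines.append(f"{i} {j} {self.values[i, j]:.10e}")
        Path(path).write_text("\n".join(lines) + "\n")


def marginal_impact_matrix(
    P: PopulationWeightMatrix,
    srm: SRMatrix,
    mdiag: np.ndarray,
    monetized: bool = False,
    valuation: MonetizationParams | None = None,
    crf_label: str = "gemm",
) -> ImpactMatrix:
    """Linearized county-to-county damages per metric ton for one pollutant."""
    W = P.matrix
    m = np.asarray(mdiag, dtype=float)
    if W.shape[0] != m.shape[0]:
        raise ValueError("population weights and mortality diagonal disagree on county count")
    if srm.matrix.shape != (W.shape[1], W.shape[1]):
        raise ValueError("source-receptor matrix does not match the cell grid")
    exposure = (srm.matrix.T @ W.T).T  # = W @ SRM, kept sparse-friendly
    county_to_county = exposure @ W.T
    values = county_to_county * m[None, :] * K_UGS_PER_TON
    units = "deaths per metric ton"
    if monetized:
        if valuation is None:
            raise ValueError("monetized impacts need valuation parameters")
        values = values * valuation.value_per_death
        units = "USD per metric ton"
    return ImpactMatrix(pollutant=srm.pollutant, values=values,
                        county_ids=np.arange(W.shape[0]), units=units, crf=crf_label)


def eq1_oracle(
    srm: SRMatrix,
    P: PopulationWeightMatrix,
    crf_model: CRFModel,
    county_pm25: np.ndarray,
    D: np.ndarray,
    emission_rate: float,
    source_county: int,
    age_groups=None,
) -> float:
    """Exact nonlinear attributable deaths for a finite emission perturbation.

    Emissions at ``emission_rate`` μg/s from one source county are spread
    over cells by population weight, propagated through the source–receptor
    matrix, aggregated back to county exposures, and pushed through the CRF
    as Σ_j Σ_a D[j,a] · (RR(C_j + ΔC_j) − RR(C_j)) / RR(C_j). As the rate
    tends to zero, the result per unit rate converges to the linearized
    engine's per-unit impact.
    """
    if not np.isfinite(emission_rate):
        raise ValueError("emission rate must be finite")
    if emission_rate == 0.0:
        return 0.0
    W = P.matrix
    groups = tuple(age_groups) if age_groups is not None else crf_model.age_groups
    cell_rates = emission_rate * W[source_county]           # μg/s per cell
    delta_cells = srm.matrix.T @ cell_rates                 # μg/m³ per receptor cell
    delta_county = W @ delta_cells                          # population-weighted μg/m³
    C = np.asarray(county_pm25, dtype=float)
    D = np.asarray(D, dtype=float)
    total = 0.0
    for a, g in enumerate(groups):
        rr0 = np.asarray(hazard_ratio(crf_model, C, g))
        rr1 = np.asarray(hazard_ratio(crf_model, C + delta_county, g))
        total += float(np.sum(D[:, a] * (rr1 - rr0) / rr0))
    return total


@dataclass
class ImpactSummary:
    """Scenario-level attributable deaths and damages, partitioned several ways."""

    scenario: str
    deaths_by: pd.DataFrame        # pollutant × vehicle_type (incl. Refueling), deaths/yr
    deaths_by_source: pd.Series    # source county → deaths/yr
    usd_by: pd.DataFrame           # same layout as deaths_by, 2017 USD
    ghg_usd_by_vehicle: pd.Series  # vehicle type → USD
    valuation: MonetizationParams = field(default_factory=MonetizationParams)

    @property
    def total_deaths(self) -> float:
        return float(self.deaths_by.to_numpy().sum())

    @property
    def air_usd(self) -> float:
        return float(self.usd_by.to_numpy().sum())

    @property
    def ghg_usd(self) -> float:
        return float(self.ghg_usd_by_vehicle.sum())

    @property
    def total_usd(self) -> float:
        return self.air_usd + self.ghg_usd


REFUELING_CLASS = "Refueling"


def scenario_impacts(
    mi_by_pollutant: dict[str, ImpactMatrix],
    scenario: ScenarioEmissions,
    valuation: MonetizationParams | None = None,
) -> ImpactSummary:
    """Attributable deaths and monetized damages for one emission scenario.

    deaths(p, v) = Σ_c emissions[c, v, p] · Σ_j MI_deaths[p][c, j]; refueling
    emissions are attributed to a pseudo vehicle class. GHG damages are
    CO2-equivalent tons × SCC and carry no spatial structure.
    """
    from .inventory import AIR_POLLUTANTS

    valuation = valuation or MonetizationParams()
    present = set(scenario.emissions["pollutant"].unique())
    lacking = [p for p in AIR_POLLUTANTS if p in present and p not in mi_by_pollutant]
    if lacking:
        raise ValueError(f"scenario pollutants without an impact matrix: {lacking}")
    pollutants = sorted(p for p in present if p in mi_by_pollutant)
    if not pollutants:
        raise ValueError("no pollutant in the scenario has an impact matrix")

    vehicles = list(scenario.emissions["vehicle_type"].unique())
    any_mi = next(iter(mi_by_pollutant.values()))
    n_counties = any_mi.values.shape[0]
    deaths_by = pd.DataFrame(0.0, index=pollutants, columns=vehicles + [REFUELING_CLASS])
    deaths_by_source = np.zeros(n_counties)

    for p in pollutants:
        mi = mi_by_pollutant[p]
        if "USD" in mi.units:
            raise ValueError("scenario_impacts needs deaths-valued impact matrices")
        per_ton = mi.per_ton()
        wide = scenario.emissions_wide(p).reindex(np.arange(n_counties), fill_value=0.0)
        for v in wide.columns:
            deaths_by.loc[p, v] = float(wide[v].to_numpy() @ per_ton)
        deaths_by_source += wide.sum(axis=1).to_numpy() * per_ton
        if scenario.refueling is not None:
            ref = scenario.refueling[scenario.refueling["pollutant"] == p]
            tons = ref.set_index("county")["emissions_tons"] \
                .reindex(np.arange(n_counties), fill_value=0.0).to_numpy()
            deaths_by.loc[p, REFUELING_CLASS] = float(tons @ per_ton)
            deaths_by_source += tons * per_ton

    co2e = ghg_co2e(scenario, valuation.gwp)
    ghg_usd = (co2e.groupby("vehicle_type")["co2e_tons"].sum() * valuation.scc)

    return ImpactSummary(
        scenario=scenario.label,
        deaths_by=deaths_by,
        deaths_by_source=pd.Series(deaths_by_source, index=np.arange(n_counties)),
        usd_by=deaths_by * valuation.value_per_death,
        ghg_usd_by_vehicle=ghg_usd,
        valuation=valuation,
    )


def partition_impacts(
    mi_by_pollutant: dict[str, ImpactMatrix],
    scenario: ScenarioEmissions,
    grouping: pd.Series,
    source_counties: np.ndarray | None = None,
    vehicle_types: list[str] | None = None,
) -> pd.DataFrame:
    """Share of impacts landing inside vs outside the source's own region.

    ``grouping`` maps county → region id (state or MSA; -1 means no MSA, so
    a non-MSA source has zero within-share). Sources are weighted by the
    scenario's emissions, optionally restricted to a set of source counties
    and/or vehicle types. Returns one row per pollutant plus "all", with
    within + outside = 1.
    """
    grouping = pd.Series(grouping)
    rows = []
    tot_within = tot_all = 0.0
    em = scenario.emissions
    if vehicle_types is not None:
        em = em[em["vehicle_type"].isin(vehicle_types)]
    for p, mi in sorted(mi_by_pollutant.items()):
        n = mi.values.shape[0]
        group_of = grouping.reindex(np.arange(n))
        if group_of.isna().any():
            raise ValueError("grouping is missing some counties")
        g = group_of.to_numpy()
        tons = em[em["pollutant"] == p].groupby("county")["emissions_tons"].sum() \
            .reindex(np.arange(n), fill_value=0.0).to_numpy()
        if scenario.refueling is not None and vehicle_types is None:
            ref = scenario.refueling[scenario.refueling["pollutant"] == p]
            tons = tons + ref.set_index("county")["emissions_tons"] \
                .reindex(np.arange(n), fill_value=0.0).to_numpy()
        if source_counties is not None:
            mask = np.zeros(n, dtype=bool)
            mask[np.asarray(source_counties)] = True
            tons = np.where(mask, tons, 0.0)
        same = (g[:, None] == g[None, :]) & (g[:, None] >= 0)
        impacts = tons[:, None] * mi.values
        within = float(impacts[same].sum())
        total = float(impacts.sum())
        if total > 0:
            rows.append({"pollutant": p, "within_share": within / total,
                         "outside_share": 1.0 - within / total, "total_impact": total})
        tot_within += within
        tot_all += total
    if tot_all > 0:
        rows.append({"pollutant": "all", "within_share": tot_within / tot_all,
                     "outside_share": 1.0 - tot_within / tot_all, "total_impact": tot_all})
    return pd.DataFrame(rows)


def impacts_per_mile(
    efs: EFTable,
    mi_usd_by_pollutant: dict[str, ImpactMatrix],
    valuation: MonetizationParams,
    county: int | None = None,
    vehicle_class: str = "Passenger Car",
) -> pd.Series | float:
    """Social cost of one vehicle-mile in cents, by county.

    Health component: Σ_p EF[c, v, p] (g/mile) × USD-per-gram damage of
    pollutant p sourced in county c. Climate component: CO2e grams/mile ×
    SCC, identical everywhere. Counties with a flagged-missing EF yield NaN.
    """
    ef = efs.ef[efs.ef["vehicle_type"] == vehicle_class]
    if ef.empty:
        raise ValueError(f"no EFs for vehicle class {vehicle_class!r}")
    any_mi = next(iter(mi_usd_by_pollutant.values()))
    n = any_mi.values.shape[0]
    counties = np.arange(n)

    cents = pd.Series(0.0, index=counties)
    for p, mi in mi_usd_by_pollutant.items():
        if "USD" not in mi.units:
            raise ValueError("impacts_per_mile needs monetized impact matrices")
        usd_per_gram = mi.per_ton() / 1e6
        sub = ef[ef["pollutant"] == p].set_index("county")
        g_per_mile = sub["ef_g_per_mile"].reindex(counties)
        flagged = sub["flagged"].reindex(counties, fill_value=False).astype(bool)
        g_per_mile = g_per_mile.mask(flagged)
        cents += 100.0 * g_per_mile.to_numpy() * usd_per_gram

    co2e_g = pd.Series(0.0, index=counties)
    for species, gwp in valuation.gwp.items():
        sub = ef[ef["pollutant"] == species].set_index("county")
        co2e_g += sub["ef_g_per_mile"].reindex(counties, fill_value=0.0) * gwp
    cents += 100.0 * co2e_g * valuation.scc / 1e6

    if county is not None:
        return float(cents.loc[county])
    return cents
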