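"""County emission inventories, per-mile emission factors, and counterfactual scenarios.

An inventory holds, for one calendar year, total emissions and vehicle
miles traveled (VMT) by county and vehicle type, plus county refueling
emissions reported separately from tailpipe/running processes. Emission
factors (EFs, grams per mile) are recovered as emissions / VMT; a
counterfactual scenario re-applies one year's EFs to another year's VMT,
so that "2008 EFs" means the target year's activity and fleet mix with
per-mile emission rates frozen at their 2008 values. Refueling, which has
no per-vehicle VMT, scales with total fleet VMT.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "VEHICLE_TYPES",
    "AIR_POLLUTANTS",
    "GHG_SPECIES",
    "POLLUTANTS",
    "EmissionInventory",
    "EFTable",
    "ScenarioEmissions",
    "compute_efs",
    "build_scenario",
    "ghg_co2e",
]

#: The 13 EPA/MOVES on-road source types.
VEHICLE_TYPES = (
    "Motorcycle",
    "Passenger Car",
    "Passenger Truck",
    "Light Commercial Truck",
    "Intercity Bus",
    "Transit Bus",
    "School Bus",
    "Refuse Truck",
    "Single Unit Short-haul Truck",
    "Single Unit Long-haul Truck",
    "Motor Home",
    "Combination Short-haul Truck",
    "Combination Long-haul Truck",
)

AIR_POLLUTANTS = ("PM25", "SO2", "NOX", "NH3", "VOC")
GHG_SPECIES = ("CO2", "CH4", "N2O")
POLLUTANTS = AIR_POLLUTANTS + GHG_SPECIES

_EMISSIONS_COLS = ["county", "state", "vehicle_type", "pollutant", "emissions_tons"]
_VMT_COLS = ["county", "state", "vehicle_type", "vmt_miles"]
_REFUELING_COLS = ["county", "state", "pollutant", "emissions_tons"]


def _require_cols(df: pd.DataFrame, cols: list[str], name: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{name} table is missing columns {missing}")


@dataclass
class EmissionInventory:
    """One year's county × vehicle-type × pollutant emissions and activity.

    ``emissions`` is long-form with columns (county, state, vehicle_type,
    pollutant, emissions_tons); ``vmt`` has (county, state, vehicle_type,
    vmt_miles); ``refueling`` has (county, state, pollutant, emissions_tons)
    or is None for years whose source data folds refueling into running
    emissions.
    """

    year: int
    emissions: pd.DataFrame
    vmt: pd.DataFrame
    refueling: pd.DataFrame | None = None
    vehicle_types: tuple[str, ...] = VEHICLE_TYPES

    def __post_init__(self) -> None:
        _require_cols(self.emissions, _EMISSIONS_COLS, "emissions")
        _require_cols(self.vmt, _VMT_COLS, "vmt")
        if self.refueling is not None:
            _require_cols(self.refueling, _REFUELING_COLS, "refueling")
        present_v = set(self.emissions["vehicle_type"].unique())
        missing_v = set(self.vehicle_types) - present_v
        if missing_v:
            raise ValueError(f"inventory {self.year} lacks vehicle types {sorted(missing_v)}")
        present_p = set(self.emissions["pollutant"].unique())
        missing_p = set(POLLUTANTS) - present_p
        if missing_p:
            raise ValueError(f"inventory {self.year} lacks pollutants {sorted(missing_p)}")
        if (self.emissions["emissions_tons"] < 0).any() or (self.vmt["vmt_miles"] < 0).any():
            raise ValueError("emissions and VMT must be nonnegative")

    @property
    def counties(self) -> np.ndarray:
        return np.sort(self.emissions["county"].unique())

    def state_of(self) -> pd.Series:
        """county → state mapping implied by the tables."""
        return self.vmt.drop_duplicates("county").set_index("county")["state"]

    def total_vmt(self) -> pd.Series:
        """Total fleet VMT per county."""
        return self.vmt.groupby("county")["vmt_miles"].sum()

    def emissions_wide(self, pollutant: str) -> pd.DataFrame:
        """county × vehicle_type matrix of tons for one pollutant (zero-filled)."""
        sub = self.emissions[self.emissions["pollutant"] == pollutant]
        return sub.pivot_table(index="county", columns="vehicle_type",
                               values="emissions_tons", aggfunc="sum", fill_value=0.0)


@dataclass
class EFTable:
    """Per-mile emission factors derived from one inventory year.

    ``ef`` columns: (county, state, vehicle_type, pollutant, ef_g_per_mile,
    flagged) where ``flagged`` marks entries with zero VMT but nonzero
    emissions — these have no defined EF and are excluded from scenarios.
    ``refueling_ef`` is per total-fleet mile, or None.
    """

    year: int
    ef: pd.DataFrame
    refueling_ef: pd.DataFrame | None = None


@dataclass
class ScenarioEmissions:
    """A counterfactual inventory: year-Y EFs applied to the target year's VMT."""

    label: str
    ef_year: int
    target_year: int
    emissions: pd.DataFrame
    vmt: pd.DataFrame
    refueling: pd.DataFrame | None = None
    fallback_log: list = field(default_factory=list)

    def emissions_wide(self, pollutant: str) -> pd.DataFrame:
        sub = self.emissions[self.emissions["pollutant"] == pollutant]
        return sub.pivot_table(index="county", columns="vehicle_type",
                               values="emissions_tons", aggfunc="sum", fill_value=0.0)

    def total_emissions(self, pollutant: str) -> float:
        tot = float(self.emissions.loc[self.emissions["pollutant"] == pollutant,
                                       "emissions_tons"].sum())
        if self.refueling is not None:
            tot += float(self.refueling.loc[self.refueling["pollutant"] == pollutant,
                                            "emissions_tons"].sum())
        return tot


def compute_efs(inv: EmissionInventory) -> EFTable:
    """Derive per-mile EFs: ef[c,v,p] = 1e6 · tons / VMT miles (grams per mile).

    County–vehicle cells with zero VMT but positive emissions cannot define
    an EF; they are flagged (EF set to NaN) with a warning and later skipped
    by scenario construction. Refueling EFs divide by total fleet VMT.
    """
    merged = inv.emissions.merge(inv.vmt[["county", "vehicle_type", "vmt_miles"]],
                                 on=["county", "vehicle_type"], how="left")
    merged["vmt_miles"] = merged["vmt_miles"].fillna(0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ef = 1e6 * merged["emissions_tons"] / merged["vmt_miles"]
    flagged = (merged["vmt_miles"] == 0) & (merged["emissions_tons"] > 0)
    ef = np.where(merged["vmt_miles"] == 0, np.where(flagged, np.nan, 0.0), ef)
    out = merged[["county", "state", "vehicle_type", "pollutant"]].copy()
    out["ef_g_per_mile"] = ef
    out["flagged"] = flagged.to_numpy()
    n_flagged = int(flagged.sum())
    if n_flagged:
        warnings.warn(
            f"inventory {inv.year}: {n_flagged} county-vehicle-pollutant cells have "
            "emissions but zero VMT; their EFs are undefined and excluded from scenarios",
            stacklevel=2,
        )

    ref_ef = None
    if inv.refueling is not None:
        tot = inv.total_vmt()
        ref = inv.refueling.merge(tot.rename("fleet_vmt"), left_on="county", right_index=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            ref["ef_g_per_mile"] = np.where(ref["fleet_vmt"] > 0,
                                            1e6 * ref["emissions_tons"] / ref["fleet_vmt"], 0.0)
        ref_ef = ref[["county", "state", "pollutant", "ef_g_per_mile"]]
    return EFTable(year=inv.year, ef=out, refueling_ef=ref_ef)


def build_scenario(efs_yearY: EFTable, target_inv: EmissionInventory,
                   label: str | None = None) -> ScenarioEmissions:
    """Apply year-Y per-mile EFs to the target year's VMT, county by county.

    County–vehicle cells present in the target year but missing (or flagged)
    in year Y fall back to the year-Y state-mean EF for that vehicle type and
    pollutant; each fallback is logged. Refueling is rescaled by the ratio of
    target to year-Y total fleet VMT via the per-fleet-mile EF; if year Y has
    no separate refueling block the scenario carries none.
    """
    ef = efs_yearY.ef
    usable = ef[~ef["flagged"]].copy()
    if usable.empty or usable.groupby("pollutant")["ef_g_per_mile"].count().eq(0).any():
        raise ValueError("no usable EFs for at least one pollutant")
    state_mean = (usable.groupby(["state", "vehicle_type", "pollutant"])
                  ["ef_g_per_mile"].mean().rename("state_ef"))

    base = target_inv.vmt.copy()
    pollutants = sorted(ef["pollutant"].unique())
    base = base.merge(pd.DataFrame({"pollutant": pollutants}), how="cross")
    base = base.merge(usable[["county", "vehicle_type", "pollutant", "ef_g_per_mile"]],
                      on=["county", "vehicle_type", "pollutant"], how="left")
    miss = base["ef_g_per_mile"].isna()
    fallback_log: list[dict] = []
    if miss.any():
        base = base.merge(state_mean, left_on=["state", "vehicle_type", "pollutant"],
                          right_index=True, how="left")
        filled = base["ef_g_per_mile"].fillna(base["state_ef"])
        for _, row in base.loc[miss & filled.notna(),
                               ["county", "vehicle_type", "pollutant"]].iterrows():
            fallback_log.append({"county": row["county"], "vehicle_type": row["vehicle_type"],
                                 "pollutant": row["pollutant"], "rule": "state-mean EF"})
        base["ef_g_per_mile"] = filled.fillna(0.0)
        base = base.drop(columns="state_ef")
    base["emissions_tons"] = base["ef_g_per_mile"] * base["vmt_miles"] / 1e6

    emissions = base[["county", "state", "vehicle_type", "pollutant", "emissions_tons"]]

    refueling = None
    if efs_yearY.refueling_ef is not None:
        tot = target_inv.total_vmt()
        ref = efs_yearY.refueling_ef.merge(tot.rename("fleet_vmt"),
                                           left_on="county", right_index=True, how="inner")
        ref["emissions_tons"] = ref["ef_g_per_mile"] * ref["fleet_vmt"] / 1e6
        refueling = ref[["county", "state", "pollutant", "emissions_tons"]]

    return ScenarioEmissions(
        label=label or f"{efs_yearY.year} EFs",
        ef_year=efs_yearY.year,
        target_year=target_inv.year,
        emissions=emissions.reset_index(drop=True),
        vmt=target_inv.vmt.copy(),
        refueling=refueling,
        fallback_log=fallback_log,
    )


def ghg_co2e(source: EmissionInventory | ScenarioEmissions,
             gwps: dict | None = None) -> pd.DataFrame:
    """CO2-equivalent tons by county and vehicle type under 100-y GWPs.

    Default factors: CO2 1, CH4 34, N2O 298 (climate-carbon feedback).
    Missing species are treated as zero with a warning.
    """
    if gwps is None:
        from .valuation import DEFAULT_GWP
        gwps = DEFAULT_GWP
    em = source.emissions
    present = set(em["pollutant"].unique())
    missing = [s for s in GHG_SPECIES if s not in present]
    if missing:
        warnings.warn(f"GHG species {missing} absent; treated as zero", stacklevel=2)
    sub = em[em["pollutant"].isin(gwps)].copy()
    sub["co2e_tons"] = sub["emissions_tons"] * sub["pollutant"].map(gwps)
    out = (sub.groupby(["county", "vehicle_type"], as_index=False)["co2e_tons"].sum())
    return out
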