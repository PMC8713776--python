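"""Configuration-driven end-to-end runs.

A full analysis generates (or loads) a world, derives per-mile emission
factors for every scenario year, re-applies each year's factors to the
target year's activity, pushes the resulting emissions through the
marginal-impact engine at target-year baselines, and writes report tables:
scenario impact summaries, a three-factor decomposition of the change in
impacts (baseline PM2.5, VMT/fleet, baseline mortality), within-region
impact shares, and per-mile social costs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .baseline import build_mortality_table, build_population_weights, county_baseline_pm25
from .crf import CRFModel, build_slope_matrix, gemm_model, loglinear_model
from .decomposition import factor_decomposition
from .impact import (
    ImpactMatrix,
    impacts_per_mile,
    marginal_impact_matrix,
    mortality_diagonal,
    partition_impacts,
    scenario_impacts,
)
from .inventory import AIR_POLLUTANTS, VEHICLE_TYPES, POLLUTANTS, build_scenario, compute_efs
from .synthetic_world import (
    DEFAULT_SRM_PARAMS,
    WorldBundle,
    WorldConfig,
    generate_inventories,
    generate_srm,
    generate_world,
)
from .valuation import MonetizationParams

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "Analysis", "run_full_analysis", "validate_inputs"]


class PipelineError(RuntimeError):
    """Raised when a pipeline stage fails; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}' failed: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Everything one analysis run needs.

    ``world_path`` loads a serialized world instead of generating one;
    ``crf`` is "gemm" (age-specific, nonaccidental) or "loglinear"
    (all-cause, slope set by ``loglinear_rr_per_10``).
    """

    world: WorldConfig = field(default_factory=WorldConfig)
    world_path: str | None = None
    crf: str = "gemm"
    loglinear_rr_per_10: float = 1.06
    valuation: MonetizationParams = field(default_factory=MonetizationParams)
    srm_params: dict = field(default_factory=lambda: dict(DEFAULT_SRM_PARAMS))
    outdir: str = "roadhia_out"

    def crf_model(self) -> CRFModel:
        if self.crf == "gemm":
            return gemm_model(age_specific=True)
        if self.crf == "loglinear":
            return loglinear_model(self.loglinear_rr_per_10)
        raise ValueError(f"unknown CRF choice {self.crf!r}")


class Analysis:
    """A world plus its derived structures, with methods for each stage.

    Keeping the intermediate objects (population weights, kernels,
    inventories) on one object lets the decomposition re-evaluate total
    impacts under substituted inputs without rebuilding everything.
    """

    def __init__(self, config: RunConfig):
        self.config = config
        if config.world_path:
            self.world = WorldBundle.load(config.world_path)
        else:
            self.world = generate_world(config.world)
        self.crf = config.crf_model()
        self.valuation = config.valuation
        self.P = build_population_weights(self.world.blocks, self.world.cells,
                                          self.world.counties)
        self.srms = generate_srm(self.world.cells, config.srm_params)
        self.inventories = {inv.year: inv for inv in generate_inventories(self.world)}
        self.years = self.world.config.years
        self.target_year = self.years[-1]
        self.base_year = self.years[0]

    # -- building blocks ---------------------------------------------------

    def mortality_for(self, year: int):
        """Annual county × age deaths at a given year's counts and population."""
        d5 = self.world.deaths5_matrix(year)
        p5 = self.world.population_matrix(year)
        table = build_mortality_table(
            d5, p5, p5, self.world.age_groups,
            self.world.county_ids, self.world.county_state(),
        )
        return table

    def deaths_matrix(self, year: int, scale: float = 1.0) -> np.ndarray:
        """Deaths matrix shaped for the configured CRF (12 bands or 1 column)."""
        deaths = self.mortality_for(year).deaths * scale
        if self.crf.applies_to == "all-cause":
            return deaths.sum(axis=1, keepdims=True)
        return deaths

    def county_pm25(self, year: int) -> np.ndarray:
        return county_baseline_pm25(self.world.pm25_array(year), self.world.blocks,
                                    self.world.cells, self.world.counties).county_values

    def impact_matrices(
        self,
        pm25_year: int | None = None,
        mort_year: int | None = None,
        deaths: np.ndarray | None = None,
        monetized: bool = False,
    ) -> dict[str, ImpactMatrix]:
        """Per-pollutant MI at the chosen baseline concentration/mortality years."""
        pm25_year = pm25_year if pm25_year is not None else self.target_year
        mort_year = mort_year if mort_year is not None else self.target_year
        conc = self.county_pm25(pm25_year)
        D = deaths if deaths is not None else self.deaths_matrix(mort_year)
        groups = (self.world.age_groups if self.crf.applies_to == "nonaccidental"
                  else ("all",))
        S = build_slope_matrix(self.crf, conc, groups)
        mdiag = mortality_diagonal(D, S)
        return {
            p: marginal_impact_matrix(self.P, srm, mdiag, monetized=monetized,
                                      valuation=self.valuation, crf_label=self.config.crf)
            for p, srm in self.srms.items() if p in AIR_POLLUTANTS
        }

    def scenario(self, ef_year: int):
        """Year-Y EFs applied to target-year VMT."""
        efs = compute_efs(self.inventories[ef_year])
        return build_scenario(efs, self.inventories[self.target_year])

    def total_deaths(
        self,
        ef_year: int | None = None,
        pm25_year: int | None = None,
        vmt_year: int | None = None,
        mort_year: int | None = None,
        deaths: np.ndarray | None = None,
    ) -> float:
        """Total attributable deaths for one factor configuration.

        EFs default to the base year; concentration, activity, and mortality
        each default to the target year and may be pinned to other years,
        which is exactly what the factorial decomposition switches.
        """
        ef_year = ef_year if ef_year is not None else self.base_year
        vmt_year = vmt_year if vmt_year is not None else self.target_year
        efs = compute_efs(self.inventories[ef_year])
        scen = build_scenario(efs, self.inventories[vmt_year])
        mi = self.impact_matrices(pm25_year=pm25_year, mort_year=mort_year, deaths=deaths)
        return scenario_impacts(mi, scen, self.valuation).total_deaths

    # -- stages ------------------------------------------------------------

    def scenario_summaries(self):
        mi = self.impact_matrices()
        out = {}
        for year in self.years:
            out[f"{year} EFs"] = scenario_impacts(mi, self.scenario(year), self.valuation)
        return out

    def decomposition(self):
        """Three-factor attribution of the base→target change in impacts,
        holding emission factors at the base year throughout."""
        y0, yN = self.base_year, self.target_year

        def impact_fn(levels):
            return self.total_deaths(
                ef_year=y0,
                pm25_year=levels["pm25"],
                vmt_year=levels["vmt"],
                mort_year=levels["mortality"],
            )

        return factor_decomposition(
            impact_fn,
            levels_base={"pm25": y0, "vmt": y0, "mortality": y0},
            levels_alt={"pm25": yN, "vmt": yN, "mortality": yN},
            factors=("pm25", "vmt", "mortality"),
        )

    def partitions(self, ef_year: int | None = None):
        mi = self.impact_matrices()
        scen = self.scenario(ef_year if ef_year is not None else self.target_year)
        return {
            "state": partition_impacts(mi, scen, self.world.county_state()),
            "msa": partition_impacts(mi, scen, self.world.county_msa()),
        }

    def per_mile_table(self, vehicle_class: str = "Passenger Car") -> pd.DataFrame:
        mi_usd = self.impact_matrices(monetized=True)
        efs = compute_efs(self.inventories[self.target_year])
        cents = impacts_per_mile(efs, mi_usd, self.valuation, vehicle_class=vehicle_class)
        out = self.world.counties[["county", "state", "msa", "urban"]].copy()
        out["vehicle_class"] = vehicle_class
        out["cents_per_mile"] = cents.to_numpy()
        return out


def run_full_analysis(config: RunConfig) -> dict:
    """Run every stage and write report tables under ``config.outdir``.

    Returns a manifest dict (also written as manifest.json). On any stage
    failure, partial outputs are removed and a PipelineError names the
    failing stage.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(name: str, df: pd.DataFrame) -> None:
        path = outdir / name
        df.to_csv(path, index=False, float_format="%.10g", lineterminator="\n")
        written.append(path)

    stage = "setup"
    try:
        analysis = Analysis(config)

        stage = "scenario_impacts"
        summaries = analysis.scenario_summaries()
        rows, detail = [], []
        for label, s in summaries.items():
            rows.append({"scenario": label, "deaths": s.total_deaths,
                         "air_usd": s.air_usd, "ghg_usd": s.ghg_usd,
                         "total_usd": s.total_usd})
            stacked = s.deaths_by.stack()
            for (pollutant, vehicle), deaths in stacked.items():
                detail.append({"scenario": label, "pollutant": pollutant,
                               "vehicle_class": vehicle, "deaths": deaths,
                               "usd": deaths * s.valuation.value_per_death})
        emit("scenario_summary.csv", pd.DataFrame(rows))
        emit("impacts_by_pollutant_vehicle.csv", pd.DataFrame(detail))

        stage = "decomposition"
        dec = analysis.decomposition()
        emit("decomposition.csv", pd.DataFrame(dec.as_table(),
                                               columns=["term", "value", "percent_of_base"]))

        stage = "partition"
        parts = analysis.partitions()
        for grouping, df in parts.items():
            emit(f"partition_{grouping}.csv", df)

        stage = "per_mile"
        emit("impacts_per_mile.csv", analysis.per_mile_table())

        stage = "manifest"
        manifest = {
            "version": __version__,
            "seed": config.world.seed,
            "crf": config.crf,
            "target_year": analysis.target_year,
            "base_year": analysis.base_year,
            "world": asdict(config.world) | {"years": list(config.world.years)},
            "valuation": {
                "vsl": config.valuation.vsl,
                "discount_rate": config.valuation.discount_rate,
                "npv_factor": config.valuation.npv_factor,
                "scc": config.valuation.scc,
                "gwp": config.valuation.gwp,
            },
            "outputs": [p.name for p in written],
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True)
                                              + "\n")
        return manifest
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, str(exc)) from exc


# --------------------------------------------------------------------------
# input validation


def validate_inputs(paths: list[str | Path]) -> list[dict]:
    """Schema, unit, and index-consistency checks on inventory tables.

    Returns machine-readable findings; an empty list means the inputs are
    clean. Unreadable files yield a fatal finding rather than an exception.
    """
    findings: list[dict] = []
    required = ["county", "state", "vehicle_type", "pollutant", "emissions_tons"]
    for path in paths:
        path = Path(path)
        try:
            df = pd.read_csv(path)
        except Exception as exc:
            findings.append({"file": str(path), "severity": "fatal", "kind": "unreadable",
                             "message": str(exc)})
            continue
        missing = [c for c in required if c not in df.columns]
        if missing:
            findings.append({"file": str(path), "severity": "error", "kind": "schema",
                             "message": f"missing columns {missing}"})
            continue
        bad_v = sorted(set(df["vehicle_type"].unique()) - set(VEHICLE_TYPES))
        if bad_v:
            findings.append({"file": str(path), "severity": "error", "kind": "schema",
                             "message": f"unknown vehicle_type values {bad_v}",
                             "column": "vehicle_type"})
        bad_p = sorted(set(df["pollutant"].unique()) - set(POLLUTANTS))
        if bad_p:
            findings.append({"file": str(path), "severity": "error", "kind": "schema",
                             "message": f"unknown pollutant values {bad_p}",
                             "column": "pollutant"})
        neg = df.index[df["emissions_tons"] < 0].tolist()
        if neg:
            findings.append({"file": str(path), "severity": "error", "kind": "range",
                             "message": "negative emissions", "rows": neg[:20]})
    return findings
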