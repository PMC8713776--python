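"""Concentration–response functions for chronic PM2.5 mortality.

Three CRF kinds are supported:

``gemm``
    The Global Exposure Mortality Model: a nonlinear, concave hazard-ratio
    curve with ``log RR(z) = theta * log(1 + z/alpha) * w(z)`` where
    ``w(z) = 1 / (1 + exp(-(z - mu)/nu))`` and ``z = max(0, C - cmin)``.
    The counterfactual concentration ``cmin`` is 2.4 μg/m³; exposures at or
    below it carry zero marginal risk. Coefficients (all-age plus twelve
    5-year age bands from 30–34 through 85+, for nonaccidental NCD+LRI
    mortality) ship as packaged constants.

``loglinear``
    A constant-slope model, ``log RR = beta * max(0, C - cmin)``, the form
    commonly used for large US cohort estimates reported as a relative risk
    per 10 μg/m³.

``custom``
    A user-supplied slope table (percent increase in mortality per μg/m³ as
    a function of concentration), interpolated linearly; the hazard ratio is
    recovered by integrating the slope from ``cmin``.

The "slope" of a CRF is the derivative of ``100 * log RR`` with respect to
concentration — the percent increase in mortality per 1 μg/m³ — which is
what enters the marginal-impact linearization. Because GEMM is concave, its
slope increases as baseline concentrations fall, so cleaner baseline air
raises the marginal damage of each emitted ton.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Callable, Mapping, Sequence

import numpy as np

__all__ = [
    "GemmParams",
    "CRFModel",
    "GEMM_AGE_GROUPS",
    "load_gemm_constants",
    "gemm_model",
    "loglinear_model",
    "custom_slope_model",
    "hazard_ratio",
    "slope",
    "build_slope_matrix",
]

#: Counterfactual (zero-marginal-risk) concentration in μg/m³.
DEFAULT_CMIN = 2.4

#: The twelve 5-year adult age bands the age-specific coefficients cover.
GEMM_AGE_GROUPS = (
    "30-34", "35-39", "40-44", "45-49", "50-54", "55-59",
    "60-64", "65-69", "70-74", "75-79", "80-84", "85+",
)

ALL_AGE = "all"


@dataclass(frozen=True)
class GemmParams:
    """Shape coefficients of one GEMM hazard-ratio curve.

    theta scales the log hazard; alpha (μg/m³) sets the curvature of the
    log term; mu and nu (μg/m³) locate and soften the logistic weighting;
    cmin is the counterfactual concentration below which risk is flat.
    """

    theta: float
    alpha: float
    mu: float
    nu: float
    cmin: float = DEFAULT_CMIN
    se: float = float("nan")  # standard error of theta; reference only

    def __post_init__(self) -> None:
        if not (self.theta > 0 and self.alpha > 0 and self.nu > 0 and self.cmin > 0):
            raise ValueError("GEMM coefficients theta, alpha, nu, cmin must be positive")

    def log_rr(self, conc: np.ndarray) -> np.ndarray:
        z = np.maximum(0.0, np.asarray(conc, dtype=float) - self.cmin)
        w = 1.0 / (1.0 + np.exp(-(z - self.mu) / self.nu))
        return self.theta * np.log1p(z / self.alpha) * w

    def dlog_rr(self, conc: np.ndarray) -> np.ndarray:
        """Analytic derivative of log RR w.r.t. concentration (0 below cmin)."""
        c = np.asarray(conc, dtype=float)
        z = c - self.cmin
        zp = np.maximum(z, 0.0)  # keep log1p in-domain below the counterfactual
        w = 1.0 / (1.0 + np.exp(-(zp - self.mu) / self.nu))
        d = w / (self.alpha + zp) + np.log1p(zp / self.alpha) * w * (1.0 - w) / self.nu
        return np.where(z > 0.0, self.theta * d, 0.0)


@dataclass(frozen=True)
class CRFModel:
    """A concentration–response model plus the age groups it applies to.

    ``applies_to`` is "nonaccidental" for the age-specific GEMM (mortality
    inputs must then be nonaccidental deaths by age band) and "all-cause"
    for single-group models.
    """

    kind: str  # "gemm" | "loglinear" | "custom"
    params: Mapping[str, GemmParams] = field(default_factory=dict)
    beta: float = 0.0  # log-slope per μg/m³ (loglinear)
    slope_fn: Callable[[np.ndarray], np.ndarray] | None = None  # %/(μg/m³) (custom)
    cmin: float = DEFAULT_CMIN
    applies_to: str = "nonaccidental"

    @property
    def age_groups(self) -> tuple[str, ...]:
        if self.kind == "gemm" and self.applies_to == "nonaccidental":
            return tuple(g for g in self.params if g != ALL_AGE)
        return (ALL_AGE,)

    def _params_for(self, age_group: str) -> GemmParams:
        try:
            return self.params[age_group]
        except KeyError:
            raise KeyError(f"no GEMM coefficients for age group {age_group!r}") from None


def load_gemm_constants() -> dict:
    """Load the packaged GEMM NCD+LRI coefficient file."""
    text = resources.files("roadhia.data").joinpath("gemm_ncd_lri.json").read_text()
    return json.loads(text)


def gemm_model(age_specific: bool = True) -> CRFModel:
    """Build the GEMM CRF from packaged constants.

    With ``age_specific=True`` (the production configuration) the model
    carries the twelve age-band coefficient sets plus the all-age set;
    otherwise it is a single all-age curve treated as all-age nonaccidental.
    """
    raw = load_gemm_constants()
    cmin = float(raw["cmin"])

    def mk(d: Mapping[str, float]) -> GemmParams:
        return GemmParams(theta=d["theta"], alpha=d["alpha"], mu=d["mu"],
                          nu=d["nu"], cmin=cmin, se=d.get("se", float("nan")))

    params: dict[str, GemmParams] = {ALL_AGE: mk(raw["all_age"])}
    applies = "all-cause"
    if age_specific:
        params.update({g: mk(v) for g, v in raw["age_groups"].items()})
        applies = "nonaccidental"
    return CRFModel(kind="gemm", params=params, cmin=cmin, applies_to=applies)


def loglinear_model(rr_per_10: float, cmin: float = DEFAULT_CMIN) -> CRFModel:
    """Constant-slope CRF from a relative risk per 10 μg/m³ (all-cause)."""
    if rr_per_10 <= 0:
        raise ValueError("rr_per_10 must be positive")
    return CRFModel(kind="loglinear", beta=np.log(rr_per_10) / 10.0,
                    cmin=cmin, applies_to="all-cause")


def custom_slope_model(
    conc_grid: Sequence[float],
    slope_percent: Sequence[float],
    cmin: float = DEFAULT_CMIN,
) -> CRFModel:
    """CRF from a tabulated slope (% mortality increase per μg/m³) vs concentration.

    The table is interpolated linearly and held constant beyond its ends;
    this is the entry point for metaregression-style slope curves.
    """
    grid = np.asarray(conc_grid, dtype=float)
    vals = np.asarray(slope_percent, dtype=float)
    if grid.ndim != 1 or grid.shape != vals.shape or grid.size < 2:
        raise ValueError("conc_grid and slope_percent must be 1-D, equal length >= 2")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("conc_grid must be strictly increasing")
    if np.any(vals < 0):
        raise ValueError("slopes must be nonnegative")

    def fn(c: np.ndarray) -> np.ndarray:
        return np.interp(np.asarray(c, dtype=float), grid, vals)

    return CRFModel(kind="custom", slope_fn=fn, cmin=cmin, applies_to="all-cause")


def _check_conc(conc) -> np.ndarray:
    c = np.asarray(conc, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be nonnegative")
    return c


def hazard_ratio(model: CRFModel, conc, age_group: str = ALL_AGE) -> np.ndarray | float:
    """Relative mortality risk RR(C) vs the counterfactual concentration.

    Equals 1 at or below ``cmin`` and is nondecreasing in C for every kind.
    For the custom kind RR is recovered as exp(∫ slope/100 dC) by adaptive
    trapezoid integration from cmin.
    """
    c = _check_conc(conc)
    if model.kind == "gemm":
        out = np.exp(model._params_for(age_group).log_rr(c))
    elif model.kind == "loglinear":
        out = np.exp(model.beta * np.maximum(0.0, c - model.cmin))
    elif model.kind == "custom":
        assert model.slope_fn is not None
        scalar_in = np.ndim(c) == 0
        cs = np.atleast_1d(c)
        out = np.empty_like(cs)
        for i, ci in enumerate(cs):
            if ci <= model.cmin:
                out[i] = 1.0
            else:
                grid = np.linspace(model.cmin, ci, 257)
                out[i] = np.exp(np.trapezoid(model.slope_fn(grid) / 100.0, grid))
        out = out[0] if scalar_in else out
    else:
        raise ValueError(f"unknown CRF kind {model.kind!r}")
    return float(out) if np.ndim(conc) == 0 else out


def slope(
    model: CRFModel,
    conc,
    age_group: str = ALL_AGE,
    method: str = "analytic",
) -> np.ndarray | float:
    """Percent increase in mortality per 1 μg/m³ at concentration C.

    The default is the analytic log-hazard derivative d(100·ln RR)/dC, which
    is the quantity the linearized impact engine consumes. ``method=
    "discrete"`` instead returns 100·(RR(C+1)/RR(C) − 1), a unit-step
    alternative. Both are exactly zero below the counterfactual ``cmin``.
    """
    c = _check_conc(conc)
    if method == "discrete":
        rr0 = hazard_ratio(model, c, age_group)
        rr1 = hazard_ratio(model, c + 1.0, age_group)
        out = np.where(c < model.cmin, 0.0, 100.0 * (np.asarray(rr1) / np.asarray(rr0) - 1.0))
    elif method == "analytic":
        if model.kind == "gemm":
            out = 100.0 * model._params_for(age_group).dlog_rr(c)
        elif model.kind == "loglinear":
            out = np.where(c > model.cmin, 100.0 * model.beta, 0.0)
        elif model.kind == "custom":
            assert model.slope_fn is not None
            out = np.where(c > model.cmin, model.slope_fn(c), 0.0)
        else:
            raise ValueError(f"unknown CRF kind {model.kind!r}")
    else:
        raise ValueError(f"unknown slope method {method!r}")
    return float(out) if np.ndim(conc) == 0 else out


def build_slope_matrix(
    model: CRFModel,
    county_pm25: np.ndarray,
    age_groups: Sequence[str] | None = None,
) -> np.ndarray:
    """Slope matrix S (counties × age groups), stored as a *fraction* per μg/m³.

    ``S[i, a]`` is the fractional increase in baseline mortality in county i
    and age group a per 1 μg/m³ of sustained concentration increase, i.e.
    slope(model, C_i, a) / 100. Counties at or below the counterfactual get
    zero rows.
    """
    c = _check_conc(county_pm25)
    if c.ndim != 1:
        raise ValueError("county_pm25 must be a 1-D per-county vector")
    groups = tuple(age_groups) if age_groups is not None else model.age_groups
    if model.kind == "gemm" and model.applies_to == "nonaccidental":
        missing = [g for g in groups if g not in model.params]
        if missing:
            raise ValueError(f"age groups without coefficients: {missing}")
    S = np.empty((c.size, len(groups)), dtype=float)
    for j, g in enumerate(groups):
        key = g if (model.kind == "gemm" and g in model.params) else ALL_AGE
        S[:, j] = np.asarray(slope(model, c, key)) / 100.0
    return S
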