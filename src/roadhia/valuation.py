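"""Monetization of mortality and greenhouse-gas damages.

Attributable deaths are valued with a value per statistical life (VSL),
discounted through a cessation-lag structure: after an emission reduction
the mortality benefit is assumed to arrive over 20 years (30% in year 1,
50% uniformly over years 2–5, 20% uniformly over years 6–20 — the EPA
advisory-council structure), and each year's share is discounted back to
the present. CO2-equivalent emissions are valued with a social cost of
carbon (SCC); non-CO2 gases convert via 100-year global warming potentials.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CessationLag",
    "MonetizationParams",
    "epa_cessation_lag",
    "cessation_lag_npv",
    "monetize_deaths",
    "adjust_vsl",
    "scc_damages",
    "DEFAULT_GWP",
]

#: 100-y global warming potentials with climate-carbon feedback.
DEFAULT_GWP = {"CO2": 1.0, "CH4": 34.0, "N2O": 298.0}


@dataclass(frozen=True)
class CessationLag:
    """Benefit-timing weights over years 1..n and a discount-timing convention.

    ``convention`` controls when within year t the benefit is booked:
    "midyear" discounts by (1+r)^-(t-0.5), "endyear" by (1+r)^-t,
    "startyear" by (1+r)^-(t-1).
    """

    weights: tuple[float, ...]
    convention: str = "midyear"

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if np.any(w < 0):
            raise ValueError("lag weights must be nonnegative")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError(f"lag weights must sum to 1, got {w.sum():.6f}")
        if self.convention not in ("midyear", "endyear", "startyear"):
            raise ValueError(f"unknown discount convention {self.convention!r}")


def epa_cessation_lag(convention: str = "midyear") -> CessationLag:
    """The EPA advisory-council 20-year lag: 0.30; 0.125 × 4; (0.2/15) × 15."""
    weights = (0.30,) + (0.50 / 4,) * 4 + (0.20 / 15,) * 15
    return CessationLag(weights=weights, convention=convention)


def cessation_lag_npv(lag: CessationLag | None = None, r: float = 0.03) -> float:
    """Net-present-value factor of a unit mortality benefit under a lag structure.

    Returns Σ_t w_t · (1+r)^-e(t) with e(t) set by the lag's timing
    convention. Equals 1 exactly at r = 0; strictly decreasing in r.
    """
    if lag is None:
        lag = epa_cessation_lag()
    if not (0.0 <= r < 1.0):
        raise ValueError("discount rate must be in [0, 1)")
    t = np.arange(1, len(lag.weights) + 1, dtype=float)
    if lag.convention == "midyear":
        expo = t - 0.5
    elif lag.convention == "endyear":
        expo = t
    else:  # startyear
        expo = t - 1.0
    return float(np.sum(np.asarray(lag.weights) * (1.0 + r) ** (-expo)))


@dataclass(frozen=True)
class MonetizationParams:
    """All valuation knobs in one place.

    vsl is in target-year USD per statistical life; scc in USD per metric
    ton CO2e; discount_rate applies to the cessation lag only (attributable
    deaths themselves are reported undiscounted).
    """

    vsl: float = 10.2e6
    discount_rate: float = 0.03
    lag: CessationLag = field(default_factory=epa_cessation_lag)
    scc: float = 49.0
    gwp: dict = field(default_factory=lambda: dict(DEFAULT_GWP))
    income_elasticity: float = 1.0

    def __post_init__(self) -> None:
        if self.vsl < 0 or self.scc < 0:
            raise ValueError("vsl and scc must be nonnegative")

    @property
    def npv_factor(self) -> float:
        return cessation_lag_npv(self.lag, self.discount_rate)

    @property
    def value_per_death(self) -> float:
        """Discounted dollar value of one attributable death (VSL × NPV)."""
        return self.vsl * self.npv_factor


def monetize_deaths(deaths, params: MonetizationParams) -> np.ndarray | float:
    """USD value of attributable deaths: deaths × VSL × cessation-lag NPV."""
    d = np.asarray(deaths, dtype=float)
    if np.any(d < 0):
        raise ValueError("deaths must be nonnegative")
    out = d * params.value_per_death
    return float(out) if np.ndim(deaths) == 0 else out


def adjust_vsl(
    base_vsl: float,
    deflator_ratio: float,
    earnings_ratio: float,
    elasticity: float = 1.0,
) -> float:
    """Re-base a VSL to another year for inflation and real income growth.

    value = base × deflator_ratio × earnings_ratio**elasticity; elasticity 0
    is an inflation-only adjustment.
    """
    if deflator_ratio <= 0 or earnings_ratio <= 0:
        raise ValueError("adjustment ratios must be positive")
    return base_vsl * deflator_ratio * earnings_ratio**elasticity


def scc_damages(co2e_tons, scc: float) -> np.ndarray | float:
    """Climate damages in USD: metric tons CO2e × SCC ($/t)."""
    t = np.asarray(co2e_tons, dtype=float)
    if np.any(t < 0):
        raise ValueError("CO2e tonnage must be nonnegative")
    out = t * scc
    return float(out) if np.ndim(co2e_tons) == 0 else out
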