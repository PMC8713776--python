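# Methods

## Scope and structure

The package implements a county-level counterfactual assessment of the
health and climate damages of on-road emissions. Its production path is
linear-algebraic: population weights map grid cells to counties, a
pollutant-specific source–receptor matrix propagates emissions to
concentrations, a concentration–response function (CRF) linearized at each
county's baseline PM2.5 converts sustained concentration increases to
deaths, and valuation converts deaths and CO2-equivalents to dollars. A
nonlinear finite-perturbation evaluator of the same attributable-death sum
is retained as a validation oracle; the two agree to first order because
realistic per-source perturbations move county concentrations by orders of
magnitude less than the curvature scale of the CRF.

## Concentration–response functions

The default CRF is the GEMM NCD+LRI hazard-ratio model (age-specific,
nonaccidental mortality), with the China-cohort-inclusive coefficient sets
shipped as a packaged JSON constants file: one all-age curve
(θ = 0.1430, α = 1.6 μg/m³, μ = 15.5 μg/m³, ν = 36.8 μg/m³) and twelve
5-year age bands (30–34 … 85+) sharing α, μ, ν with θ declining from
0.1585 to 0.1141 with age. The counterfactual concentration is 2.4 μg/m³:
hazard is flat and marginal impacts are exactly zero at or below it.

"Slope" means the analytic derivative d(100·ln RR)/dC — the percent
increase in mortality per 1 μg/m³ — because that is the quantity the
linearized engine consumes and it reproduces the calibration pair the
all-age curve is known for (0.84 %/(μg/m³) at 10.5 μg/m³, 1.05 at
7.5 μg/m³, a 26% increase). A discrete unit-step slope
100·(RR(C+1)/RR(C)−1) is available as an option but is not the default.
Alternative CRFs: a log-linear (constant-slope) model parameterized by a
relative risk per 10 μg/m³, applied to all-cause mortality in a single age
group; and a tabulated slope-vs-concentration curve (for metaregression
style estimates), integrated from the counterfactual to recover hazard
ratios. Coefficients for these alternatives are configuration inputs, not
packaged constants. CRF parametric uncertainty is not propagated.

## Baseline inputs

**Population weights.** Each block is assigned to the grid cell with the
nearest centroid; row i of P is county i's block populations aggregated to
cells and normalized. Zero-population counties receive a uniform row over
their own cells, keeping P row-stochastic. Nearest-centroid assignment is
the simplest population-conserving mapping; nothing downstream depends on
sub-cell detail.

**County baseline PM2.5.** Each block takes the inverse-distance-weighted
mean of the four nearest cell values (weights 1/d with a 10⁻⁹ km floor so
a block coincident with a centroid takes that cell's value exactly);
county values are population-weighted block means, falling back to the
unweighted mean for zero-population counties.

**Mortality table.** Age-specific county rates are 5-year death counts
over 5-year person-years (mid-period population × 5 — the averaging rule
is a package choice, as only "5 years of deaths and population" is
externally specified). County × age cells with fewer than 50 deaths in the
window use the state-level rate for that age group instead; annual deaths
are rate × target-year population. The small-count fallback threshold is
configurable (default 50).

## Emission factors and scenarios

Per-mile EFs are 10⁶ × tons / VMT (g/mile) per county × vehicle type ×
pollutant; refueling EFs divide by total fleet VMT since refueling has no
per-class activity. A scenario applies one year's EFs to the target year's
VMT. County–vehicle cells with zero VMT but nonzero emissions have no
defined EF: they are flagged, warned about, and excluded. Cells missing in
the EF year fall back to that year's state-mean EF for the same vehicle
type and pollutant (state means preserve totals better than zero-fill);
every fallback is logged on the scenario object. Years whose source data
fold refueling into running emissions are represented by a null refueling
block, and scenarios built from them carry none. Fleet-composition change
is expressed purely through per-class VMT.

## Impact engine

MI = P·SRM·Pᵀ·Dg(m)·k with m = diag(D·Sᵀ) and k = 10¹²/(24·3600·365)
≈ 31,709.79 (1 μg/s ≡ 1 t/yr). Within-county emissions are allocated to
cells by population — the same weights as receptors — so P appears on both
sides. Deaths are reported undiscounted; dollars multiply by VSL and the
cessation-lag NPV factor. Impacts landing outside the modelled grid do not
exist by construction (the synthetic kernels decay within the domain).
Both deaths-valued and monetized MI are first-class; monetization is a
scalar rescale and can be applied to an existing matrix.

Partitioning sums MI receptor columns by the source county's region
(state, or MSA with −1 meaning non-metropolitan, counted entirely as
"outside"), weighting sources by scenario emissions; within and outside
shares sum to one exactly. Per-mile social costs are Σ_p EF[c,v,p] ×
USD-per-gram[p][c] plus CO2e g/mile × SCC, in cents; the climate term is
identical in every county because CO2e damages carry no spatial structure.

## Decomposition

The attribution of impact changes to baseline PM2.5, VMT/fleet, and
baseline mortality is a full 2³ factorial inclusion–exclusion over an
arbitrary scalar impact function, with factors implemented as input
substitutions (year switches) inside closures. The reconstruction identity
— base + individual + two-way + three-way = all-switched — holds exactly
by construction, and terms are independent of factor ordering. Emission
factors are held at the base year throughout, so the decomposition
explains why impacts under frozen technology still change. No
order-independent (Shapley-type) variant is provided.

## Valuation

Defaults: VSL $10.2M (2017 USD); EPA cessation lag (30% of benefits in
year 1, 50% uniform over years 2–5, 20% uniform over years 6–20);
3%/year discount rate; SCC $49/t CO2e ($144 in the high-damage variant);
GWPs 34 (CH4) and 298 (N2O). The discount timing convention is selectable;
the default books year-t benefits at mid-year, (1+r)^−(t−0.5), which gives
an NPV factor of 0.89 at 3% (end-of-year gives 0.88, start-of-year 0.91
— the convention behind the canonical 0.89 is not documented, so mid-year
is a package default, not a claim about any particular prior analysis).
Monetized totals are homogeneous of degree 1 in VSL and SCC; no VSL
uncertainty range is propagated.

## Synthetic worlds

The generator produces, from one integer seed, the statistical structure
the analysis assumes; with the seed fixed, serialization is
byte-identical.

* **Geometry.** Planar Euclidean km grid (default 20×20 cells of 5 km);
  no projections, no real-map geometry. Counties are grown from seeded
  cells round-robin, each claiming the lowest-id unassigned adjacent cell,
  guaranteeing contiguity and near-equal size; counties are banded into
  states by longitude and a configurable metropolitan fraction is grouped
  into MSAs around randomly chosen cores.
* **Population.** 1–3 blocks per cell with Dirichlet-split, Poisson-drawn
  populations; metropolitan counties are ~8× denser. The tracked
  population is adults 30+ in twelve 5-year bands. Between the first and
  last scenario year the 60–74 bands grow by 38%, 75+ by 16%, under-60 by
  2%, so mean age strictly increases — an aging structure chosen to mirror
  the demographic shift a US-style decade exhibits.
* **Mortality.** Gompertz-like age-specific rates, 8×10⁻⁴·exp(0.095·(age−32))
  per person-year, with lognormal county heterogeneity (σ = 0.12) and a
  mild downward time trend except in the youngest band. 5-year death
  counts are Poisson, so small county × age cells naturally trip the
  <50-count state-rate fallback.
* **Air quality.** Cell PM2.5 = max(1.5, 6 + 9·(density/max density) +
  0.8·smoothed noise) μg/m³, declining 28% linearly over the scenario
  span. This yields county baselines of roughly 4–10 μg/m³, positively
  correlated with population density, mostly above the 2.4 μg/m³
  counterfactual.
* **Kernels.** Nonnegative exponentials peak·exp(−d/L) with cutoff
  sparsification; primary PM2.5 is strong and local (L = 8 km), NOx weak
  per unit but far-travelling (L = 60 km), the others in between. Real
  reduced-form source–receptor matrices can contain negative entries in
  some chemistry regimes; the synthetic kernels deliberately do not.
* **Inventories.** Per-class VMT follows first-year adult population ×
  12,000 miles per adult × fixed fleet shares, drifting 0.982×/yr for cars
  and 1.03×/yr for trucks; air-pollutant EFs decline 8–12%/yr, GHG EFs are
  flat to within 0.1%/yr; refueling is a VOC block at 0.05 g per fleet
  mile. Reference EF magnitudes are order-of-magnitude realistic g/mile
  values per vehicle class with 5% lognormal county noise.

What the synthetic data does **not** emulate: real geography and
meteorology, negative source–receptor chemistry, suppressed-cell reporting
rules beyond the small-count fallback, within-county correlation between
emissions and non-population land use, or the absolute scale of national
results — demo totals are hundreds of deaths, not tens of thousands.
Passing tests therefore demonstrate the correctness of the machinery
(identities, limits, monotonicities, calibration of the CRF and valuation
constants) and the qualitative behaviour of the pipeline, not the
reproduction of any national estimate.

## Numerical choices

* Demo problem sizes: 20×20 grid, 16 counties, 4 states, 3 MSAs, 4
  scenario years; the oracle-equivalence suite uses an 8×8 grid with 4
  counties so the brute-force triple loop stays exact and fast.
* Matrix-vs-oracle agreement is asserted at 10⁻⁸ relative (triple loop)
  and 10⁻³ relative for the nonlinear small-rate limit at ε = 1 μg/s —
  small enough that CRF curvature is negligible, large enough to avoid
  floating-point cancellation in RR differences.
* Decomposition reconstruction is asserted at 10⁻¹⁰ relative; partition
  share sums at 10⁻¹².
* Region-growth ties break to the lowest cell id; county/state/MSA ids are
  dense integers; −1 is the "no MSA" sentinel.
* Inverse-distance weights floor distances at 10⁻⁹ km; slope matrices
  store fractions (slope/100); CSV serialization uses a fixed %.10g float
  format to make determinism byte-exact.

## Known limitations

* The linearized engine applies one slope per county regardless of
  perturbation size; it overstates impacts of very large emission changes
  (the oracle quantifies this: the per-unit impact declines with
  perturbation size under the concave CRF).
* State-mean EF fallback can transfer urban EF character to rural counties
  within a state when a cell is missing.
* The MSA partition treats non-metropolitan sources as having no
  within-region impacts by definition, which understates "local" shares
  for those sources.
* Custom slope-table CRFs recover hazard ratios by numerical integration
  (fixed 257-point trapezoid), adequate for smooth tables but not for
  discontinuous ones.
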