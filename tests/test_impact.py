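"""Marginal-impact engine: matrix path vs brute-force oracles, partitioning."""

import numpy as np
import pandas as pd
import pytest

from roadhia.baseline import PopulationWeightMatrix
from roadhia.crf import build_slope_matrix, gemm_model
from roadhia.impact import (
    K_UGS_PER_TON,
    eq1_oracle,
    impacts_per_mile,
    marginal_impact_matrix,
    mortality_diagonal,
    partition_impacts,
    scenario_impacts,
)
from roadhia.inventory import EFTable, compute_efs
from roadhia.synthetic_world import SRMatrix, generate_srm
from roadhia.valuation import MonetizationParams

import scipy.sparse

GEMM = gemm_model()


def test_ton_conversion_constant():
    assert K_UGS_PER_TON == pytest.approx(1e12 / 31_536_000)
    assert K_UGS_PER_TON == pytest.approx(31_709.79, abs=0.01)


def test_mortality_diagonal_matches_manual_sum():
    rng = np.random.default_rng(11)
    D = rng.uniform(0, 100, size=(5, 12))
    S = rng.uniform(0, 0.02, size=(5, 12))
    m = mortality_diagonal(D, S)
    for i in range(5):
        assert m[i] == pytest.approx(sum(D[i, a] * S[i, a] for a in range(12)))
    # equivalently the diagonal of D·Sᵀ
    assert np.allclose(m, np.diag(D @ S.T))


def _identity_setup():
    """Two counties, one cell each, diagonal kernel."""
    P = PopulationWeightMatrix(matrix=np.eye(2), county_ids=np.arange(2), n_cells=2)
    srm = SRMatrix(pollutant="PM25",
                   matrix=scipy.sparse.csr_array(np.diag([3e-7, 5e-7])))
    return P, srm


def test_diagonal_kernel_gives_diagonal_impacts():
    P, srm = _identity_setup()
    mdiag = np.array([2.0, 4.0])
    mi = marginal_impact_matrix(P, srm, mdiag)
    expected = np.diag([3e-7 * 2.0, 5e-7 * 4.0]) * K_UGS_PER_TON
    assert np.allclose(mi.values, expected)


def test_matrix_engine_matches_triple_loop_oracle(small_analysis):
    """The Eq.-2-style matrix product must equal an independent summation
    over (source cell, receptor cell, age) with linearized hazard slopes."""
    a = small_analysis
    year = a.target_year
    conc = a.county_pm25(year)
    D = a.deaths_matrix(year)
    S = build_slope_matrix(a.crf, conc, a.world.age_groups)
    mdiag = mortality_diagonal(D, S)
    srm = a.srms["PM25"]
    mi = marginal_impact_matrix(a.P, srm, mdiag)

    W = a.P.matrix
    K = srm.matrix.toarray()
    n_counties, n_cells = W.shape
    brute = np.zeros((n_counties, n_counties))
    for i in range(n_counties):
        for j in range(n_counties):
            acc = 0.0
            for s in range(n_cells):
                ws = W[i, s]
                if ws == 0.0:
                    continue
                row = K[s]
                for r in range(n_cells):
                    wr = W[j, r]
                    if wr == 0.0 or row[r] == 0.0:
                        continue
                    acc += ws * row[r] * wr
            brute[i, j] = acc * mdiag[j] * K_UGS_PER_TON
    assert np.allclose(mi.values, brute, rtol=1e-8)


def test_eq1_zero_rate_and_small_rate_limit(small_analysis):
    a = small_analysis
    year = a.target_year
    conc = a.county_pm25(year)
    D = a.deaths_matrix(year)
    S = build_slope_matrix(a.crf, conc, a.world.age_groups)
    mdiag = mortality_diagonal(D, S)
    srm = a.srms["PM25"]
    mi = marginal_impact_matrix(a.P, srm, mdiag)

    assert eq1_oracle(srm, a.P, a.crf, conc, D, 0.0, source_county=0) == 0.0

    # per-unit nonlinear impact converges to the linearized per-unit impact
    eps = 1e-3  # μg/s
    for src in range(a.P.matrix.shape[0]):
        nonlinear = eq1_oracle(srm, a.P, a.crf, conc, D, eps, source_county=src) / eps
        linear = mi.per_ton()[src] / K_UGS_PER_TON
        assert nonlinear == pytest.approx(linear, rel=0.01)


def test_eq1_concavity_in_perturbation_size(small_analysis):
    a = small_analysis
    conc = a.county_pm25(a.target_year)
    D = a.deaths_matrix(a.target_year)
    srm = a.srms["PM25"]
    eps = 1e3
    one = eq1_oracle(srm, a.P, a.crf, conc, D, eps, source_county=0) / eps
    two = eq1_oracle(srm, a.P, a.crf, conc, D, 2 * eps, source_county=0) / (2 * eps)
    assert two <= one


def test_row_sums_are_total_per_ton_damages(small_analysis):
    mi = small_analysis.impact_matrices()["NOX"]
    assert np.allclose(mi.per_ton(), mi.values.sum(axis=1), rtol=1e-12)


def test_lower_baseline_pm25_raises_every_impact_entry(small_analysis):
    """Concave hazard: uniformly cleaner baseline air strictly increases
    marginal damages everywhere."""
    a = small_analysis
    year = a.target_year
    conc = a.county_pm25(year)
    D = a.deaths_matrix(year)
    S_hi = build_slope_matrix(a.crf, conc, a.world.age_groups)
    S_lo = build_slope_matrix(a.crf, conc - 1.0, a.world.age_groups)
    srm = a.srms["PM25"]
    mi_hi = marginal_impact_matrix(a.P, srm, mortality_diagonal(D, S_hi))
    mi_lo = marginal_impact_matrix(a.P, srm, mortality_diagonal(D, S_lo))
    assert (mi_lo.values > mi_hi.values).all()


def test_scenario_impacts_linear_and_homogeneous(small_analysis):
    a = small_analysis
    mi = a.impact_matrices()
    scen = a.scenario(a.base_year)
    s1 = scenario_impacts(mi, scen, a.valuation)

    doubled = type(scen)(
        label=scen.label, ef_year=scen.ef_year, target_year=scen.target_year,
        emissions=scen.emissions.assign(
            emissions_tons=scen.emissions["emissions_tons"] * 2),
        vmt=scen.vmt,
        refueling=scen.refueling.assign(
            emissions_tons=scen.refueling["emissions_tons"] * 2),
    )
    s2 = scenario_impacts(mi, doubled, a.valuation)
    assert s2.total_deaths == pytest.approx(2 * s1.total_deaths, rel=1e-12)
    assert s2.ghg_usd == pytest.approx(2 * s1.ghg_usd, rel=1e-12)

    # homogeneity in VSL and SCC
    v2 = MonetizationParams(vsl=2 * a.valuation.vsl, scc=3 * a.valuation.scc)
    s3 = scenario_impacts(mi, scen, v2)
    assert s3.air_usd == pytest.approx(2 * s1.air_usd, rel=1e-12)
    assert s3.ghg_usd == pytest.approx(3 * s1.ghg_usd, rel=1e-12)

    # homogeneity in the mortality diagonal
    D = a.deaths_matrix(a.target_year)
    assert a.total_deaths(deaths=5.0 * D) == pytest.approx(
        5.0 * a.total_deaths(deaths=D), rel=1e-12)


def test_zero_emissions_zero_impacts(small_analysis):
    a = small_analysis
    mi = a.impact_matrices()
    scen = a.scenario(a.base_year)
    zeroed = type(scen)(
        label="zero", ef_year=scen.ef_year, target_year=scen.target_year,
        emissions=scen.emissions.assign(emissions_tons=0.0),
        vmt=scen.vmt,
        refueling=scen.refueling.assign(emissions_tons=0.0),
    )
    s = scenario_impacts(mi, zeroed, a.valuation)
    assert s.total_deaths == 0.0
    assert s.ghg_usd == 0.0


def test_two_county_hand_summed_expected_deaths():
    P, srm = _identity_setup()
    mdiag = np.array([0.5, 1.5])
    mi = marginal_impact_matrix(P, srm, mdiag)
    emissions = pd.DataFrame({
        "county": [0, 1], "state": [0, 0],
        "vehicle_type": ["Passenger Car"] * 2,
        "pollutant": ["PM25"] * 2,
        "emissions_tons": [10.0, 20.0],
    })
    from roadhia.inventory import ScenarioEmissions
    scen = ScenarioEmissions(label="hand", ef_year=2008, target_year=2017,
                             emissions=emissions,
                             vmt=pd.DataFrame({"county": [0, 1], "state": [0, 0],
                                               "vehicle_type": ["Passenger Car"] * 2,
                                               "vmt_miles": [1.0, 1.0]}))
    s = scenario_impacts({"PM25": mi}, scen)
    expected = (10.0 * 3e-7 * 0.5 + 20.0 * 5e-7 * 1.5) * K_UGS_PER_TON
    assert s.total_deaths == pytest.approx(expected, rel=1e-12)


def test_missing_impact_matrix_for_pollutant_errors(small_analysis):
    a = small_analysis
    mi = a.impact_matrices()
    mi.pop("NOX")
    with pytest.raises(ValueError, match="NOX"):
        scenario_impacts(mi, a.scenario(a.base_year), a.valuation)


# --- partitioning ------------------------------------------------------------


def test_partition_shares_sum_to_one(small_analysis):
    a = small_analysis
    parts = partition_impacts(a.impact_matrices(), a.scenario(a.target_year),
                              a.world.county_state())
    assert np.allclose(parts["within_share"] + parts["outside_share"], 1.0,
                       atol=1e-12)


def test_diagonal_impacts_stay_within_group():
    P, srm = _identity_setup()
    mi = marginal_impact_matrix(P, srm, np.array([1.0, 1.0]))
    emissions = pd.DataFrame({"county": [0, 1], "state": [0, 1],
                              "vehicle_type": ["Passenger Car"] * 2,
                              "pollutant": ["PM25"] * 2,
                              "emissions_tons": [1.0, 1.0]})
    from roadhia.inventory import ScenarioEmissions
    scen = ScenarioEmissions(label="diag", ef_year=2008, target_year=2017,
                             emissions=emissions, vmt=pd.DataFrame({
                                 "county": [0, 1], "state": [0, 1],
                                 "vehicle_type": ["Passenger Car"] * 2,
                                 "vmt_miles": [1.0, 1.0]}))
    # same state → within-share 1; distinct states → within-share 1 too
    # (diagonal MI never crosses a county line)
    same = partition_impacts({"PM25": mi}, scen, pd.Series([0, 0]))
    distinct = partition_impacts({"PM25": mi}, scen, pd.Series([0, 1]))
    assert np.allclose(same["within_share"], 1.0)
    assert np.allclose(distinct["within_share"], 1.0)
    # all receptors outside the source's group → within-share 0
    offdiag = SRMatrix(pollutant="PM25", matrix=scipy.sparse.csr_array(
        np.array([[0.0, 1e-7], [1e-7, 0.0]])))
    mi_off = marginal_impact_matrix(P, offdiag, np.array([1.0, 1.0]))
    shares = partition_impacts({"PM25": mi_off}, scen, pd.Series([0, 1]))
    assert np.allclose(shares["within_share"], 0.0)


def test_local_pollutant_has_higher_within_share(small_analysis):
    """Short-decay primary PM2.5 should land nearer its source than NOx,
    under both state and MSA groupings."""
    a = small_analysis
    mi = a.impact_matrices()
    scen = a.scenario(a.target_year)
    for grouping in (a.world.county_state(), a.world.county_msa()):
        parts = partition_impacts(mi, scen, grouping).set_index("pollutant")
        assert parts.loc["PM25", "within_share"] > parts.loc["NOX", "within_share"]


def test_nonmsa_source_counts_as_outside(small_analysis):
    a = small_analysis
    msa = a.world.county_msa()
    non_msa = msa.index[msa == -1]
    if len(non_msa) == 0:
        pytest.skip("all counties are metropolitan in this world")
    parts = partition_impacts(a.impact_matrices(), a.scenario(a.target_year), msa,
                              source_counties=non_msa.to_numpy())
    assert np.allclose(parts["within_share"], 0.0)


# --- per-mile ----------------------------------------------------------------


def _uniform_eftable(n_counties, ef_map, vehicle="Passenger Car"):
    rows = []
    for c in range(n_counties):
        for p, g in ef_map.items():
            rows.append((c, 0, vehicle, p, g, False))
    return EFTable(year=2017, ef=pd.DataFrame(
        rows, columns=["county", "state", "vehicle_type", "pollutant",
                       "ef_g_per_mile", "flagged"]))


def test_zero_efs_zero_cents(small_analysis):
    a = small_analysis
    mi_usd = a.impact_matrices(monetized=True)
    n = len(a.world.county_ids)
    efs = _uniform_eftable(n, {p: 0.0 for p in
                               ("PM25", "SO2", "NOX", "NH3", "VOC", "CO2", "CH4", "N2O")})
    cents = impacts_per_mile(efs, mi_usd, a.valuation)
    assert np.allclose(cents, 0.0)


def test_ghg_only_vehicle_identical_everywhere(small_analysis):
    a = small_analysis
    mi_usd = a.impact_matrices(monetized=True)
    n = len(a.world.county_ids)
    efs = _uniform_eftable(n, {"PM25": 0.0, "SO2": 0.0, "NOX": 0.0, "NH3": 0.0,
                               "VOC": 0.0, "CO2": 400.0, "CH4": 0.02, "N2O": 0.01})
    cents = impacts_per_mile(efs, mi_usd, a.valuation)
    co2e_g = 400.0 + 0.02 * 34 + 0.01 * 298
    expected = 100.0 * co2e_g * a.valuation.scc / 1e6
    assert np.allclose(cents, expected)


def test_identical_efs_urban_county_costs_more(small_analysis):
    """With EFs equalized, driving where receptors are denser does more harm."""
    a = small_analysis
    mi_usd = a.impact_matrices(monetized=True)
    n = len(a.world.county_ids)
    efs = _uniform_eftable(n, {"PM25": 0.02, "SO2": 0.005, "NOX": 0.3, "NH3": 0.03,
                               "VOC": 0.3, "CO2": 400.0, "CH4": 0.02, "N2O": 0.01})
    cents = impacts_per_mile(efs, mi_usd, a.valuation)
    urban = a.world.counties.set_index("county")["urban"]
    assert cents[urban].min() > cents[~urban].max()


def test_flagged_ef_yields_missing_value(small_analysis):
    a = small_analysis
    mi_usd = a.impact_matrices(monetized=True)
    n = len(a.world.county_ids)
    efs = _uniform_eftable(n, {"PM25": 0.02, "SO2": 0.0, "NOX": 0.0, "NH3": 0.0,
                               "VOC": 0.0, "CO2": 0.0, "CH4": 0.0, "N2O": 0.0})
    efs.ef.loc[(efs.ef.county == 0) & (efs.ef.pollutant == "PM25"), "flagged"] = True
    cents = impacts_per_mile(efs, mi_usd, a.valuation)
    assert np.isnan(cents.loc[0])
    assert np.isfinite(cents.loc[1:]).all()
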