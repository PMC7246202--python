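"""Carbonate-system solver: constants against published check values,
closure and monotonicity properties, and a dual-route cross-check."""

import math

import numpy as np
import pytest
from scipy.optimize import brentq

from oameta.carbonate import (
    CarbonateState,
    _non_carbonate_alkalinity,
    equilibrium_constants,
    solve_pco2,
    solve_ph_from_pco2,
)

# Test grid: cold Southern Ocean surface conditions.
GRID_T = [-1.8, 0.0, 4.0]
GRID_S = [33.0, 34.0, 35.0]
GRID_TA = [2200.0, 2300.0, 2400.0]
GRID_PH = [7.4, 7.6, 7.8, 8.0, 8.2]


def pco2_independent_route(state: CarbonateState) -> float:
    """Oracle: instead of decomposing alkalinity in closed form, find the
    DIC that reproduces the record's TA at its pH by bracketed
    root-finding, then speciate that DIC.  Disjoint algebra from the
    shipped TA-branch solver."""
    assert state.alkalinity is not None
    ks = equilibrium_constants(state.temperature, state.salinity, 0.0, state.constants_set)
    from oameta.carbonate import _h_sws_from_ph

    h = _h_sws_from_ph(state.ph, state.ph_scale, ks, state.temperature, state.salinity)
    k1, k2 = ks["K1"], ks["K2"]
    ta = state.alkalinity * 1e-6

    def ta_minus_model(dic):
        denom = h * h + k1 * h + k1 * k2
        hco3 = dic * k1 * h / denom
        co3 = dic * k1 * k2 / denom
        return hco3 + 2 * co3 + _non_carbonate_alkalinity(h, ks) - ta

    dic = brentq(ta_minus_model, 1e-9, 0.1, xtol=1e-18)
    co2_star = dic * h * h / (h * h + k1 * h + k1 * k2)
    return co2_star / ks["K0"] * 1e6


class TestConstants:
    def test_k0_matches_high_precision_evaluation(self):
        """Weiss (1974) solubility at T=25, S=35, evaluated independently
        at 40-digit precision."""
        ks = equilibrium_constants(25.0, 35.0)
        assert ks["K0"] == pytest.approx(0.028391881804015793, rel=1e-12)

    def test_published_check_values_at_s35_t25(self):
        """Printed check values: Lueker pK1/pK2 (total scale) and the
        bisulfate constant, at S=35, 25 °C."""
        ks = equilibrium_constants(25.0, 35.0, constants_set="lueker2000")
        st = ks["sulfate_total"]
        total_to_sws = (1.0 + st / ks["KS"] + ks["fluoride_total"] / ks["KF"]) / (
            1.0 + st / ks["KS"]
        )
        pk1_total = -math.log10(ks["K1"] / total_to_sws)
        pk2_total = -math.log10(ks["K2"] / total_to_sws)
        assert pk1_total == pytest.approx(5.8472, abs=5e-4)
        assert pk2_total == pytest.approx(8.9660, abs=5e-4)
        assert -math.log10(ks["KS"]) == pytest.approx(0.9987, abs=5e-4)
        assert math.log(ks["K0"]) == pytest.approx(-3.5617, abs=5e-4)

    @pytest.mark.parametrize("t", GRID_T + [10.0, 25.0])
    @pytest.mark.parametrize("s", GRID_S + [5.0])
    def test_k1_exceeds_k2_and_all_positive(self, t, s):
        for cset in ("mehrbach_dm87", "lueker2000"):
            ks = equilibrium_constants(t, s, constants_set=cset)
            assert ks["K1"] > ks["K2"] > 0
            for key in ("K0", "KB", "KW", "KS", "KF"):
                assert ks[key] > 0

    def test_boron_proportional_to_salinity(self):
        b35 = equilibrium_constants(2.0, 35.0)["boron_total"]
        b7 = equilibrium_constants(2.0, 7.0)["boron_total"]
        assert b7 == pytest.approx(b35 / 5.0, rel=1e-12)
        assert equilibrium_constants(2.0, 0.0)["boron_total"] == 0.0

    def test_out_of_range_inputs_rejected(self):
        with pytest.raises(ValueError, match="temperature"):
            equilibrium_constants(45.0, 35.0)
        with pytest.raises(ValueError, match="salinity"):
            equilibrium_constants(2.0, 50.0)


class TestSolver:
    def test_reference_conditions_cross_route(self):
        """T=1 °C, S=34, TA=2300, pH(total)=8.05: the closed-form TA
        branch and the independent DIC-root route agree to < 0.5%."""
        state = CarbonateState(
            temperature=1.0, salinity=34.0, ph=8.05, ph_scale="total", alkalinity=2300.0
        )
        ours = solve_pco2(state)
        oracle = pco2_independent_route(state)
        assert ours == pytest.approx(oracle, rel=5e-3)
        assert 300.0 < ours < 500.0  # near-ambient water

    def test_cross_route_agreement_on_grid(self):
        """< 1% agreement between the two algebraic routes on the full
        cold-water grid, both constants sets."""
        worst = 0.0
        for cset in ("mehrbach_dm87", "lueker2000"):
            for t in GRID_T:
                for s in GRID_S:
                    for ta in GRID_TA:
                        for ph in GRID_PH:
                            state = CarbonateState(
                                temperature=t, salinity=s, ph=ph,
                                ph_scale="total", alkalinity=ta, constants_set=cset,
                            )
                            a = solve_pco2(state)
                            b = pco2_independent_route(state)
                            worst = max(worst, abs(a - b) / b)
        assert worst < 0.01

    def test_round_trip_closure_on_grid(self):
        """pCO2 -> pH -> pCO2 closes to < 0.1% everywhere on the grid."""
        worst = 0.0
        for t in GRID_T:
            for s in GRID_S:
                for ta in GRID_TA:
                    for ph in GRID_PH:
                        state = CarbonateState(
                            temperature=t, salinity=s, ph=ph,
                            ph_scale="total", alkalinity=ta,
                        )
                        p1 = solve_pco2(state)
                        ph_back = solve_ph_from_pco2(p1, ta, t, s, "total")
                        p2 = solve_pco2(state.model_copy(update={"ph": ph_back}))
                        worst = max(worst, abs(p2 - p1) / p1)
        assert worst < 1e-3

    def test_ph_round_trip_tight(self):
        state = CarbonateState(
            temperature=1.0, salinity=34.0, ph=8.05, ph_scale="total", alkalinity=2300.0
        )
        p = solve_pco2(state)
        assert abs(solve_ph_from_pco2(p, 2300.0, 1.0, 34.0, "total") - 8.05) < 1e-6

    def test_pco2_monotone_decreasing_in_ph(self):
        levels = [
            solve_pco2(
                CarbonateState(
                    temperature=1.0, salinity=34.0, ph=ph,
                    ph_scale="total", alkalinity=2300.0,
                )
            )
            for ph in np.arange(7.4, 8.21, 0.05)
        ]
        assert all(a > b for a, b in zip(levels, levels[1:]))

    def test_dic_branch_agrees_with_ta_branch(self):
        """Solving from (pH, TA) and from (pH, DIC-of-that-state) must
        give identical pCO2."""
        ks = equilibrium_constants(1.0, 34.0)
        state = CarbonateState(
            temperature=1.0, salinity=34.0, ph=7.9, ph_scale="total", alkalinity=2300.0
        )
        p_ta = solve_pco2(state)
        from oameta.carbonate import _h_sws_from_ph

        h = _h_sws_from_ph(7.9, "total", ks, 1.0, 34.0)
        co2_star = ks["K0"] * p_ta * 1e-6
        dic = co2_star * (1 + ks["K1"] / h + ks["K1"] * ks["K2"] / h**2) * 1e6
        p_dic = solve_pco2(
            CarbonateState(temperature=1.0, salinity=34.0, ph=7.9, ph_scale="total", dic=dic)
        )
        assert p_dic == pytest.approx(p_ta, rel=1e-10)

    def test_ph_scales_consistent(self):
        """The same water described on different pH scales gives the same
        pCO2."""
        ks = equilibrium_constants(1.0, 34.0)
        st, ft = ks["sulfate_total"], ks["fluoride_total"]
        free_to_total = 1.0 + st / ks["KS"]
        free_to_sws = free_to_total + ft / ks["KF"]
        ph_total = 8.0
        h_free = 10.0**-ph_total / free_to_total
        ph_free = -math.log10(h_free)
        ph_sws = -math.log10(h_free * free_to_sws)
        results = [
            solve_pco2(
                CarbonateState(
                    temperature=1.0, salinity=34.0, ph=ph, ph_scale=scale,
                    alkalinity=2300.0,
                )
            )
            for ph, scale in [(ph_total, "total"), (ph_free, "free"), (ph_sws, "seawater")]
        ]
        assert results[1] == pytest.approx(results[0], rel=1e-10)
        assert results[2] == pytest.approx(results[0], rel=1e-10)

    def test_fugacity_correction_small_and_downward(self):
        state = CarbonateState(
            temperature=1.0, salinity=34.0, ph=8.0, ph_scale="total", alkalinity=2300.0
        )
        p = solve_pco2(state)
        f = solve_pco2(state, fugacity=True)
        assert 0.99 < f / p < 1.0


class TestValidation:
    def test_needs_exactly_one_of_ta_dic(self):
        with pytest.raises(ValueError, match="exactly one"):
            CarbonateState(temperature=1.0, salinity=34.0, ph=8.0)
        with pytest.raises(ValueError, match="exactly one"):
            CarbonateState(
                temperature=1.0, salinity=34.0, ph=8.0, alkalinity=2300.0, dic=2100.0
            )

    def test_pathological_inputs_raise_with_diagnostics(self):
        # Basic water with almost no alkalinity: borate+hydroxide alone
        # exceed TA, leaving negative carbonate alkalinity.
        state = CarbonateState(
            temperature=1.0, salinity=34.0, ph=9.0, ph_scale="total", alkalinity=10.0
        )
        with pytest.raises(ArithmeticError, match="pH=9"):
            solve_pco2(state)
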