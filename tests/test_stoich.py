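"""Stoichiometric C-P allocation model: fluxes, limitation, sweeps."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from soilstore import stoich
from soilstore.errors import ValidationError
from soilstore.stoich import (
    BASALT_PARAMS,
    SANDSTONE_PARAMS,
    ModelParams,
    SubstrateState,
    classify_limitation,
    cue,
    simulate_point,
    sweep_gradient,
    threshold_element_ratio,
)

params_strategy = st.builds(
    ModelParams,
    e=st.floats(0.05, 0.95),
    r_B=st.floats(1.0, 500.0),
    f_res=st.floats(0.0, 0.6),
    phi_max=st.floats(0.05, 1.0),
    baseline_cp=st.floats(1.0, 2000.0),
)
substrate_strategy = st.builds(
    SubstrateState,
    c_avail=st.floats(0.01, 100.0),
    p_avail=st.floats(1e-4, 10.0),
)


def brute_force_alloc(mode, params, substrate, n_grid=200_001):
    """Independent oracle: grid-search the feasible (G, S) allocation that
    maximises growth subject to mass balance and the mode's storage rule."""
    u_c, u_p = substrate.c_avail, substrate.p_avail
    if mode == "reserve":
        s = params.f_res * u_c
    elif mode == "none":
        s = 0.0
    g_grid = np.linspace(0.0, params.r_B * u_p, n_grid)
    if mode == "surplus":
        # storage follows growth: all excess C up to the cap
        feasible = g_grid[g_grid / params.e <= u_c * (1 + 1e-12)]
        g = feasible.max()
        s = min(max(u_c - g / params.e, 0.0), params.phi_max * u_c)
        if g >= params.e * u_c * (1 - 1e-9):  # C-limited: no surplus to store
            s = 0.0
    else:
        feasible = g_grid[g_grid / params.e + s <= u_c + max(1e-15, 1e-12 * u_c)]
        g = feasible.max()
    overflow = max(u_c - g / params.e - s, 0.0)
    resp = (1 - params.e) / params.e * g + overflow
    return g, resp, s


class TestThresholdElementRatio:
    def test_basalt_parameterisation_sits_left_of_ter(self):
        ter = threshold_element_ratio(BASALT_PARAMS)
        assert ter == pytest.approx(29.4 / 0.45, abs=0.01)
        assert BASALT_PARAMS.baseline_cp < ter
        assert classify_limitation(BASALT_PARAMS.baseline_cp, BASALT_PARAMS) == "C_limited"

    def test_sandstone_parameterisation_sits_right_of_ter(self):
        ter = threshold_element_ratio(SANDSTONE_PARAMS)
        assert ter == pytest.approx(78.7 / 0.45, abs=0.01)
        assert SANDSTONE_PARAMS.baseline_cp > ter
        assert classify_limitation(SANDSTONE_PARAMS.baseline_cp, SANDSTONE_PARAMS) == "P_limited"

    def test_unit_efficiency_limit_approaches_biomass_cp(self):
        p = ModelParams(e=1 - 1e-12, r_B=50.0)
        assert threshold_element_ratio(p) == pytest.approx(50.0, rel=1e-9)

    def test_boundary_ratio_classified_c_limited(self):
        p = ModelParams()
        assert classify_limitation(threshold_element_ratio(p), p) == "C_limited"


class TestSimulatePoint:
    def test_surplus_mode_hand_example(self):
        p = ModelParams(e=0.5, r_B=50.0, f_res=0.0, phi_max=1.0, baseline_cp=100.0)
        f = simulate_point("surplus", p, SubstrateState(1.0, 1.0 / 200.0))
        assert f.u_p == pytest.approx(0.005)
        assert f.growth == pytest.approx(0.25)
        assert f.storage_net == pytest.approx(0.5)
        assert f.respiration == pytest.approx(0.25)
        assert f.limitation == "P_limited"

    def test_none_mode_at_ter_has_no_overflow(self):
        p = ModelParams(e=0.4, r_B=40.0, baseline_cp=50.0)
        ter = threshold_element_ratio(p)
        f = simulate_point("none", p, SubstrateState(1.0, 1.0 / ter))
        assert f.overflow == pytest.approx(0.0, abs=1e-12)
        assert f.storage_net == 0.0
        assert f.growth == pytest.approx(p.e * f.u_c)

    def test_reserve_mode_constitutive_fraction_when_c_limited(self):
        p = ModelParams(e=0.45, r_B=30.0, f_res=0.2, baseline_cp=10.0)
        f = simulate_point("reserve", p, SubstrateState(1.0, 1.0))  # C:P = 1, C-limited
        assert f.storage_net == pytest.approx(0.2 * f.u_c)
        assert f.growth == pytest.approx(p.e * 0.8 * f.u_c)
        assert f.overflow == pytest.approx(0.0, abs=1e-15)

    @given(params=params_strategy, substrate=substrate_strategy,
           mode=st.sampled_from(stoich.MODES))
    @settings(max_examples=300, derandomize=True)
    def test_carbon_mass_balance_everywhere(self, params, substrate, mode):
        f = simulate_point(mode, params, substrate)
        assert f.u_c == pytest.approx(
            f.growth + f.respiration + f.storage_net, rel=1e-12
        )
        for flux in (f.growth, f.respiration, f.storage_net, f.overflow):
            assert flux >= 0

    def test_agrees_with_brute_force_allocator_on_random_draws(self):
        rng = np.random.default_rng(2024)
        n_checked = 0
        for _ in range(120):
            params = ModelParams(
                e=rng.uniform(0.1, 0.9),
                r_B=rng.uniform(5, 300),
                f_res=rng.uniform(0, 0.5),
                phi_max=rng.uniform(0.1, 1.0),
                baseline_cp=rng.uniform(10, 1000),
            )
            substrate = SubstrateState(rng.uniform(0.1, 10), rng.uniform(1e-3, 2))
            mode = ("none", "reserve", "surplus")[rng.integers(3)]
            f = simulate_point(mode, params, substrate)
            g, r, s = brute_force_alloc(mode, params, substrate)
            tol = 2e-4 * max(substrate.c_avail, params.r_B * substrate.p_avail)
            assert f.growth == pytest.approx(g, abs=tol)
            assert f.respiration == pytest.approx(r, abs=tol)
            assert f.storage_net == pytest.approx(s, abs=tol)
            n_checked += 1
        assert n_checked >= 100

    def test_invalid_mode_rejected(self):
        with pytest.raises(ValidationError):
            simulate_point("hoard", ModelParams(), SubstrateState(1, 1))


def _curve(sweep, mode, field):
    return np.array([getattr(f, field) for f in sweep.curves[mode]])


@pytest.fixture(scope="module")
def basalt():
    return sweep_gradient("all", BASALT_PARAMS, 2.0, 2000.0, 161)


@pytest.fixture(scope="module")
def sandstone():
    return sweep_gradient("all", SANDSTONE_PARAMS, 20.0, 20000.0, 161)


class TestSweepGradient:
    def test_baseline_point_has_unit_uptake(self, basalt, sandstone):
        for sweep in (basalt, sandstone):
            i = int(np.argmin(np.abs(sweep.cp_ratios - sweep.baseline_cp)))
            assert sweep.cp_ratios[i] == pytest.approx(sweep.baseline_cp)
            for mode in stoich.MODES:
                assert sweep.curves[mode][i].u_c == pytest.approx(1.0)

    def test_basalt_p_addition_is_inert_for_all_modes(self, basalt):
        left = basalt.cp_ratios <= basalt.baseline_cp
        for mode in stoich.MODES:
            for field in ("growth", "respiration", "storage_net"):
                vals = _curve(basalt, mode, field)[left]
                assert np.ptp(vals) < 1e-9

    @staticmethod
    def _mode_switch(params, mode):
        # reserve's constitutive fraction shifts its C/P switch rightward
        ter = params.r_B / params.e
        return ter / (1 - params.f_res) if mode == "reserve" else ter

    def test_basalt_c_addition_raises_fluxes_until_ter_then_growth_flat(self, basalt):
        r = basalt.cp_ratios
        for mode in stoich.MODES:
            switch = self._mode_switch(BASALT_PARAMS, mode)
            below = (r >= basalt.baseline_cp) & (r <= switch)
            above = r > switch
            g = _curve(basalt, mode, "growth")
            assert np.all(np.diff(g[below]) > 0), f"{mode}: growth should rise below TER"
            assert np.ptp(g[above]) < 1e-9, f"{mode}: growth should be flat above TER"
            resp = _curve(basalt, mode, "respiration")
            assert np.all(np.diff(resp[below]) > 0)
        # net C-storage rises with C addition: throughout the C-limited range
        # for reserve (proportional to uptake), and past the TER for surplus
        # (no surplus exists while C-limited, so the curve starts at zero)
        res_below = (r >= basalt.baseline_cp) & (r <= self._mode_switch(BASALT_PARAMS, "reserve"))
        assert np.all(np.diff(_curve(basalt, "reserve", "storage_net")[res_below]) > 0)
        sur_above = (r >= basalt.ter) & (r <= 3 * basalt.ter)
        assert np.all(np.diff(_curve(basalt, "surplus", "storage_net")[sur_above][1:]) > 0)

    def test_sandstone_p_addition_raises_growth_and_drains_surplus_storage(self, sandstone):
        r = sandstone.cp_ratios
        for mode in stoich.MODES:
            switch = self._mode_switch(SANDSTONE_PARAMS, mode)
            idx = np.flatnonzero((r >= switch) & (r <= sandstone.baseline_cp))
            g = _curve(sandstone, mode, "growth")[idx]
            # moving right-to-left = adding P: growth increases
            assert np.all(np.diff(g[::-1]) > 0)
        idx = np.flatnonzero((r >= sandstone.ter) & (r <= sandstone.baseline_cp))
        s = _curve(sandstone, "surplus", "storage_net")[idx]
        assert np.all(np.diff(s[::-1]) < 0), "surplus storage declines as P is added"
        resp = _curve(sandstone, "surplus", "respiration")[idx]
        assert np.all(np.diff(resp[::-1]) > 0), "surplus respiration rises as P is added"

    def test_sandstone_c_addition_respiration_flat_only_for_surplus(self, sandstone):
        right = sandstone.cp_ratios >= sandstone.baseline_cp
        u = np.array([f.u_c for f in sandstone.curves["none"]])[right]
        for mode, slope_expect in (("none", 1.0), ("reserve", 1.0 - 0.15), ("surplus", 0.0)):
            resp = _curve(sandstone, mode, "respiration")[right]
            slopes = np.diff(resp) / np.diff(u)
            assert slopes == pytest.approx(slope_expect, abs=1e-9)

    def test_sandstone_growth_flat_under_p_limitation(self, sandstone):
        right = sandstone.cp_ratios >= sandstone.baseline_cp
        for mode in stoich.MODES:
            assert np.ptp(_curve(sandstone, mode, "growth")[right]) < 1e-9

    def test_storage_rises_faster_in_surplus_than_reserve_above_ter(self, sandstone):
        right = sandstone.cp_ratios >= sandstone.baseline_cp
        u = np.array([f.u_c for f in sandstone.curves["surplus"]])[right]
        ds_surplus = np.diff(_curve(sandstone, "surplus", "storage_net")[right]) / np.diff(u)
        ds_reserve = np.diff(_curve(sandstone, "reserve", "storage_net")[right]) / np.diff(u)
        assert np.all(ds_surplus > ds_reserve)

    @pytest.mark.parametrize("mode", stoich.MODES)
    @pytest.mark.parametrize("soil_params", [BASALT_PARAMS, SANDSTONE_PARAMS])
    def test_fluxes_continuous_at_mode_switch(self, mode, soil_params):
        # the growth switch sits at r_B/e except in reserve mode, where the
        # constitutive fraction shifts it to r_B/(e*(1-f_res))
        ter = soil_params.r_B / soil_params.e
        if mode == "reserve":
            ter = soil_params.r_B / (soil_params.e * (1 - soil_params.f_res))
        for delta in (1e-3, 1e-6, 1e-9):
            lo = simulate_point(mode, soil_params,
                                stoich.substrate_for_ratio(ter * (1 - delta), soil_params.baseline_cp))
            hi = simulate_point(mode, soil_params,
                                stoich.substrate_for_ratio(ter * (1 + delta), soil_params.baseline_cp))
            for field in ("growth", "respiration", "storage_net"):
                gap = abs(getattr(hi, field) - getattr(lo, field))
                assert gap < 50 * delta * max(1.0, ter / soil_params.baseline_cp)

    def test_baseline_outside_range_rejected(self):
        with pytest.raises(ValueError):
            sweep_gradient("none", BASALT_PARAMS, 100.0, 2000.0, 11)


class TestCue:
    def test_c_limited_reserve_cue_is_efficiency_times_growth_share(self):
        p = ModelParams(e=0.45, r_B=30.0, f_res=0.15, baseline_cp=10.0)
        f = simulate_point("reserve", p, SubstrateState(1.0, 1.0))
        assert cue(f, count_storage=False) == pytest.approx(0.45 * 0.85)

    def test_flags_agree_when_no_storage(self):
        f = simulate_point("none", BASALT_PARAMS, SubstrateState(1.0, 1.0))
        assert cue(f, True) == cue(f, False)

    def test_surplus_storage_raises_cue_over_storage_free_microbes(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            p = ModelParams(
                e=rng.uniform(0.2, 0.8), r_B=rng.uniform(10, 200),
                f_res=0.0, phi_max=1.0, baseline_cp=100.0,
            )
            cp = threshold_element_ratio(p) * rng.uniform(1.5, 20)
            sub = SubstrateState(1.0, 1.0 / cp)
            with_storage = cue(simulate_point("surplus", p, sub), count_storage=True)
            without = cue(simulate_point("none", p, sub), count_storage=True)
            assert with_storage > without
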