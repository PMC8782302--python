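"""SOM turnover (both pool structures) and mineral N bookkeeping."""

import numpy as np
import pytest

from agroens.nitrogen import (MineralNState, SomPools, init_som_from_profile,
                              initial_mineral_n, moisture_modifier,
                              step_mineral_n, step_som_turnover,
                              temperature_modifier)
from agroens.soil import SoilHorizon, SoilProfile, make_grid


class TestInitFromProfile:
    def test_adet_top_layer_carbon_matches_hand_conversion(self, adet_grid):
        # 4.17 % OC x 1.02 g/cm3 x 5 cm -> ~21,267 kg C/ha in the 0-5 cm cell
        pools = init_som_from_profile(adet_grid, "soiln3")
        assert pools.c[0].sum() == pytest.approx(21267.0, rel=1e-3)

    def test_zero_oc_gives_empty_pools(self):
        profile = SoilProfile("zero", [SoilHorizon(0, 30, 30, 30, 1.3, 6.5, 0.0,
                                                   15.0, 30.0, 20)])
        grid = make_grid(profile)
        for variant in ("soiln3", "daisy6"):
            assert init_som_from_profile(grid, variant).total_c == 0.0

    @pytest.mark.parametrize("variant", ["soiln3", "daisy6"])
    def test_partition_conserves_total(self, adet_grid, variant):
        pools = init_som_from_profile(adet_grid, variant)
        layer_c = adet_grid.oc / 100.0 * adet_grid.bd * adet_grid.thickness_cm * 1e5
        assert pools.c.sum(axis=1) == pytest.approx(layer_c, rel=1e-12)

    def test_unknown_variant_rejected(self, adet_grid):
        with pytest.raises(ValueError, match="variant"):
            init_som_from_profile(adet_grid, "century")


class TestTurnover:
    def test_zero_rates_change_nothing(self, adet_grid):
        pools = init_som_from_profile(adet_grid, "soiln3")
        pools.k[:] = 0.0
        out, net = step_som_turnover(pools, np.full(adet_grid.n_cells, 25.0),
                                     np.ones(adet_grid.n_cells))
        assert np.allclose(out.c, pools.c)
        assert np.allclose(net, 0.0)

    def test_isolated_pool_decays_exponentially(self):
        pools = SomPools("soiln3", ("humus", "litter", "manure"),
                         c=np.array([[0.0, 1000.0, 0.0]]),
                         cn=np.array([10.0, 25.0, 15.0]),
                         k=np.array([0.0, 0.01, 0.0]),
                         transfer=np.zeros((3, 3)))
        for _ in range(100):
            pools, _ = step_som_turnover(pools, np.array([25.0]), np.array([1.0]))
        assert pools.c[0, 1] == pytest.approx(1000.0 * np.exp(-1.0), rel=0.005)

    @pytest.mark.parametrize("variant", ["soiln3", "daisy6"])
    def test_mass_balance_audit_exact(self, adet_grid, variant):
        pools = init_som_from_profile(adet_grid, variant)
        temp = np.linspace(15, 30, adet_grid.n_cells)
        moist = np.linspace(0.5, 1.0, adet_grid.n_cells)
        for _ in range(20):
            c0 = pools.total_c
            n0 = pools.total_n
            new, net = step_som_turnover(pools, temp, moist)
            respired = c0 - new.total_c
            assert respired >= 0
            # organic N drops by exactly the net mineralization
            assert (n0 - new.total_n) == pytest.approx(net.sum(), abs=1e-9)
            pools = new

    def test_structure_reduction_identical_mineralization(self):
        """With identical total C, aggregate rates, C:N and a degenerate
        transfer matrix the two pool structures mineralize identically."""
        s3 = SomPools("soiln3", ("humus", "litter", "manure"),
                      c=np.array([[5000.0, 0.0, 0.0]]),
                      cn=np.array([10.0, 10.0, 10.0]),
                      k=np.array([0.01, 0.01, 0.01]),
                      transfer=np.zeros((3, 3)))
        d6 = SomPools("daisy6", tuple("abcdef"),
                      c=np.array([[5000.0, 0.0, 0.0, 0.0, 0.0, 0.0]]),
                      cn=np.full(6, 10.0), k=np.full(6, 0.01),
                      transfer=np.zeros((6, 6)))
        for _ in range(10):
            s3, n3 = step_som_turnover(s3, np.array([25.0]), np.array([1.0]))
            d6, n6 = step_som_turnover(d6, np.array([25.0]), np.array([1.0]))
            assert n3.sum() == pytest.approx(n6.sum(), abs=1e-12)

    def test_invalid_transfer_matrix_rejected(self):
        with pytest.raises(ValueError, match="transfer"):
            SomPools("soiln3", ("a", "b", "c"), c=np.zeros((1, 3)),
                     cn=np.full(3, 10.0), k=np.full(3, 0.01),
                     transfer=np.full((3, 3), 0.5))


class TestModifiers:
    def test_unity_at_reference_conditions(self, adet_grid):
        hyd = adet_grid.hydraulics
        assert temperature_modifier(np.array([25.0]))[0] == pytest.approx(1.0)
        f = moisture_modifier(hyd.theta_fc, hyd.theta_r, hyd.theta_fc, hyd.theta_s)
        assert np.allclose(f, 1.0)

    def test_bounded_in_0_to_1p2(self, adet_grid):
        hyd = adet_grid.hydraulics
        temps = np.linspace(-10, 60, 50)
        ft = temperature_modifier(temps)
        assert (ft >= 0).all() and (ft <= 1.2).all()
        thetas = np.linspace(0.0, 1.0, 50)
        for th in thetas:
            f = moisture_modifier(np.full(adet_grid.n_cells, th),
                                  hyd.theta_r, hyd.theta_fc, hyd.theta_s)
            assert ((f >= 0) & (f <= 1.2)).all()


class TestMineralN:
    def test_zero_drainage_zero_leaching(self, adet_grid):
        state = initial_mineral_n(adet_grid, 50.0)
        out = step_mineral_n(state, adet_grid, np.zeros(adet_grid.n_cells), 0.0,
                             np.zeros(adet_grid.n_cells),
                             np.zeros(adet_grid.n_cells),
                             adet_grid.hydraulics.theta_fc)
        assert out.fluxes.leached == 0.0

    def test_full_mixing_leach_fraction(self):
        profile = SoilProfile("one", [SoilHorizon(0, 50, 30, 30, 1.3, 6.5, 1.0,
                                                  15.0, 40.0, 20)])
        grid = make_grid(profile, max_cell_cm=50.0)
        state = MineralNState(no3=np.array([50.0]), nh4=np.array([0.0]))
        theta = np.array([0.4])  # 200 mm stored in a 500 mm column
        out = step_mineral_n(state, grid, np.zeros(1), 0.0, np.zeros(1),
                             np.array([20.0]), theta)
        assert out.fluxes.leached == pytest.approx(50.0 * 20.0 / 200.0)
        assert out.no3[0] == pytest.approx(45.0)

    def test_mass_balance_exact_under_random_forcing(self, adet_grid):
        rng = np.random.default_rng(4)
        state = initial_mineral_n(adet_grid, 10.0)
        theta = adet_grid.hydraulics.theta_fc
        for _ in range(100):
            t0 = state.total
            mineralization = rng.normal(0.2, 0.5, adet_grid.n_cells)
            state = step_mineral_n(state, adet_grid, mineralization,
                                   float(rng.uniform(0, 5)),
                                   rng.uniform(0, 0.5, adet_grid.n_cells),
                                   rng.uniform(0, 10, adet_grid.n_cells), theta)
            f = state.fluxes
            dt = state.total - t0
            assert dt == pytest.approx(
                f.net_mineralization + f.fertilizer - f.uptake - f.leached,
                abs=1e-9)
            assert (state.no3 >= 0).all() and (state.nh4 >= 0).all()

    def test_uptake_capped_at_stock(self, adet_grid):
        state = initial_mineral_n(adet_grid, 5.0)
        demand = np.full(adet_grid.n_cells, 100.0)
        out = step_mineral_n(state, adet_grid, np.zeros(adet_grid.n_cells), 0.0,
                             demand, np.zeros(adet_grid.n_cells),
                             adet_grid.hydraulics.theta_fc)
        assert out.fluxes.uptake == pytest.approx(state.total, rel=1e-9)
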