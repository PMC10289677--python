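"""Unit tests for the N-step pathway models."""

import math

import numpy as np
import pytest

from crowdcell.pathway import (
    PathwayParams,
    ScanGrid,
    evaluate_composition,
    km_star_decomposition_scan,
    metabolic_preset,
    pathway_occupancy,
    ribosomal_preset,
    scan_optimal_occupancy,
    vazquez_flux,
    vazquez_scan,
)
from crowdcell.units import UM_TO_NM3


def coarse_grid(n_shares: int = 200) -> ScanGrid:
    """Reduced grid for fast unit tests."""
    shares = np.geomspace(0.001, 0.977, n_shares)
    rhos = np.round(np.arange(0.02, 0.61, 0.02), 3)
    return ScanGrid(rho_values=rhos, substrate_share_values=shares)


class TestOccupancy:
    def test_empty_cytosol(self):
        assert pathway_occupancy(0.0, 0.0, metabolic_preset()) == 0.0

    def test_enzyme_only_hand_value(self):
        # number density 5.18e-3 nm^-3 of 2.4 nm spheres occupies ~30%
        conc_um = 5.18e-3 / UM_TO_NM3
        rho = pathway_occupancy(0.0, conc_um, metabolic_preset())
        assert rho == pytest.approx(0.2999, abs=2e-3)

    def test_linearity(self):
        params = metabolic_preset()
        a = pathway_occupancy(5000.0, 0.0, params)
        b = pathway_occupancy(0.0, 300.0, params)
        assert pathway_occupancy(5000.0, 300.0, params) == pytest.approx(a + b)

    def test_over_packed_rejected(self):
        with pytest.raises(ValueError, match="over-packed"):
            pathway_occupancy(0.0, 5e4, ribosomal_preset())


class TestFlux:
    def test_parallel_is_n_times_linear(self):
        lin = evaluate_composition(metabolic_preset(N=20), 4000.0, 300.0)
        kin = metabolic_preset(N=20).kinetics
        par = evaluate_composition(
            PathwayParams(N=20, kinetics=kin, topology="parallel"),
            4000.0, 300.0)
        assert par.mu == pytest.approx(20 * lin.mu, rel=1e-12)
        assert par.flux == pytest.approx(20 * lin.flux, rel=1e-12)

    def test_no_catalyst_no_flux(self):
        st = evaluate_composition(metabolic_preset(), 1000.0, 0.0)
        assert st.flux == 0.0 and st.mu == 0.0

    def test_dilute_single_step_matches_crowding_free_oracle(self):
        params = metabolic_preset(N=1)
        kin = params.kinetics
        s, e = 2e-4, 1e-4
        st = evaluate_composition(params, s, e)
        v0 = kin.kcat * s * e / (kin.KM0 + s)
        assert st.mu == pytest.approx(v0 / st.rho, rel=1e-4)


@pytest.fixture(scope="module")
def ribo_scan():
    return scan_optimal_occupancy(ribosomal_preset(20), coarse_grid())


class TestScan:
    def test_interior_optimum_for_large_molecules(self, ribo_scan):
        assert 0.05 < ribo_scan.rho_opt < 0.25

    def test_envelope_unimodal_for_ribosomal_system(self, ribo_scan):
        mu = ribo_scan.table["mu"].to_numpy()
        smooth = np.convolve(mu, np.ones(3) / 3, mode="valid")
        signs = np.sign(np.diff(smooth))
        flips = np.count_nonzero(np.diff(signs[signs != 0]) != 0)
        assert flips <= 1

    def test_all_scan_points_converged(self, ribo_scan):
        assert ribo_scan.table["converged"].all()

    def test_flux_optimum_above_mu_optimum(self, ribo_scan):
        flux_scan = scan_optimal_occupancy(ribosomal_preset(20), coarse_grid(),
                                           objective="flux")
        assert flux_scan.rho_opt > ribo_scan.rho_opt

    def test_pathway_length_preserves_optimum(self):
        grid = coarse_grid(120)
        r20 = scan_optimal_occupancy(ribosomal_preset(20), grid).rho_opt
        r100 = scan_optimal_occupancy(ribosomal_preset(100), grid).rho_opt
        assert abs(r20 - r100) <= 0.02

    def test_penalty_grows_with_pathway_length(self):
        grid = coarse_grid(120)
        losses = {}
        for n in (20, 100):
            res = scan_optimal_occupancy(ribosomal_preset(n), grid)
            t = res.table.set_index("rho")["mu"]
            half = t.index[np.argmin(np.abs(t.index.to_numpy()
                                            - res.rho_opt / 2))]
            losses[n] = 1.0 - t[half] / t[res.rho_opt]
        assert losses[100] > losses[20]

    def test_theta_doubling_has_only_small_effect(self):
        # The mu(rho) top is so flat that the argmax itself is
        # ill-conditioned; the robust statement is that each theta
        # variant loses almost nothing when run at the other's optimum.
        grid = coarse_grid(120)
        r23 = scan_optimal_occupancy(metabolic_preset(20, theta=2.3), grid)
        r46 = scan_optimal_occupancy(metabolic_preset(20, theta=4.6), grid)
        t46 = r46.table.set_index("rho")["mu"]
        t23 = r23.table.set_index("rho")["mu"]
        assert t46[r23.rho_opt] / t46[r46.rho_opt] > 0.99
        assert t23[r46.rho_opt] / t23[r23.rho_opt] > 0.99

    def test_invalid_objective_rejected(self):
        with pytest.raises(ValueError):
            scan_optimal_occupancy(metabolic_preset(), coarse_grid(), "speed")

    def test_invalid_grid_rejected(self):
        with pytest.raises(ValueError):
            ScanGrid(rho_values=np.array([0.3, 0.2]))
        with pytest.raises(ValueError):
            ScanGrid(rho_values=np.array([0.0, 0.5]))


@pytest.fixture(scope="module")
def decomp():
    grid = ScanGrid(rho_values=np.round(np.arange(0.02, 0.61, 0.04), 3),
                    substrate_share_values=np.geomspace(0.001, 0.977, 80))
    return km_star_decomposition_scan(metabolic_preset(20), grid)


class TestDecomposition:
    def test_transition_only_below_unity_diffusion_above(self, decomp):
        t = decomp.table
        assert (t["km_ratio_transition_only"] <= 1.0 + 1e-9).all()
        assert (t["km_ratio_diffusion_only"] >= 1.0 - 1e-9).all()

    def test_diffusion_only_monotone_increasing(self, decomp):
        vals = decomp.table["km_ratio_diffusion_only"].to_numpy()
        assert (np.diff(vals) > 0).all()

    def test_diffusion_dominates_at_high_occupancy(self, decomp):
        t = decomp.table.set_index("rho")
        assert t.loc[0.58, "km_ratio_full"] > 1.0

    def test_ribosomal_penalty_exceeds_metabolic_at_native_density(self):
        grid = ScanGrid(rho_values=np.array([0.3]),
                        substrate_share_values=np.geomspace(0.001, 0.977, 80))
        km_m = km_star_decomposition_scan(metabolic_preset(20), grid)
        km_r = km_star_decomposition_scan(ribosomal_preset(20), grid)
        assert (km_r.table["km_ratio_full"].iloc[0]
                > km_m.table["km_ratio_full"].iloc[0])


class TestVazquez:
    KIN = metabolic_preset().kinetics

    def test_zero_occupancy_reduces_to_michaelis_menten(self):
        v = vazquez_flux(4000.0, 300.0, 0.0, "saturated", self.KIN, N=1)
        assert v == pytest.approx(
            self.KIN.kcat * 4000 * 300 / (self.KIN.KM0 + 4000))

    def test_regime_ratio_is_exponential(self):
        for rho in (0.1, 0.3, 0.6):
            vs = vazquez_flux(100.0, 10.0, rho, "saturated", self.KIN)
            vd = vazquez_flux(100.0, 10.0, rho, "diffusion", self.KIN)
            assert vd / vs == pytest.approx(math.exp(-5.8 * rho), rel=1e-12)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            vazquez_flux(1.0, 1.0, 1.0, "saturated", self.KIN)
        with pytest.raises(ValueError):
            vazquez_flux(1.0, 1.0, 0.5, "bogus", self.KIN)

    def test_only_diffusion_regime_has_interior_optimum(self):
        grid = ScanGrid(rho_values=np.round(np.arange(0.02, 0.80, 0.02), 3),
                        substrate_share_values=np.geomspace(0.001, 0.977, 80))
        sat = vazquez_scan(metabolic_preset(20), grid, regime="saturated")
        diff = vazquez_scan(ribosomal_preset(20), grid, regime="diffusion")
        # saturated flux/mass keeps rising toward the packing limit
        assert sat.rho_opt == pytest.approx(grid.rho_values[-1])
        assert grid.rho_values[0] < diff.rho_opt < 0.4
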