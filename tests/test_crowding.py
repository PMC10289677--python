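"""Unit tests for the crowding-adjusted kinetics core."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crowdcell.crowding import (
    CrowdingConstants,
    MixtureState,
    ReactionKinetics,
    SphereSpecies,
    complex_of,
    diffusion_exponent_g,
    gibbs_perturbation_Gamma,
    hydrodynamic_radius,
    km_star,
    km_star_value,
    ln_activity_coefficient,
    solve_binding_equilibrium,
)


def monodisperse(radius: float, occupancy: float) -> MixtureState:
    sp = SphereSpecies("bg", radius)
    return MixtureState([(sp, occupancy / sp.volume)])


METABOLIC_KIN = ReactionKinetics(
    kcat=1.0, KM0=130.0, theta=2.3,
    substrate=SphereSpecies("s", 0.34), catalyst=SphereSpecies("E", 2.4))


class TestGeometry:
    @pytest.mark.parametrize("r, expected", [
        (0.0, 0.182), (0.34, 0.624), (2.4, 3.302)])
    def test_hydrodynamic_radius(self, r, expected):
        assert hydrodynamic_radius(r) == pytest.approx(expected, abs=1e-12)

    def test_negative_radius_rejected(self):
        with pytest.raises(ValueError):
            hydrodynamic_radius(-0.1)

    def test_complex_volume_additivity(self):
        c = complex_of(SphereSpecies("E", 2.4), SphereSpecies("s", 0.34))
        assert c.radius**3 == pytest.approx(2.4**3 + 0.34**3)

    def test_invalid_constants_rejected(self):
        with pytest.raises(ValueError):
            CrowdingConstants(rho_ref=1.5)
        with pytest.raises(ValueError):
            CrowdingConstants(xi=-1.0)


class TestDiffusionExponent:
    # frozen from hand evaluation of (xi^2/R^2 + xi^2/rh^2)^(-a/2) / 0.22
    @pytest.mark.parametrize("r, expected", [(0.34, 5.0581), (2.4, 12.2126)])
    def test_hand_values(self, r, expected):
        assert diffusion_exponent_g(r) == pytest.approx(expected, rel=1e-4)

    def test_strictly_increasing_in_radius(self):
        radii = np.linspace(0.05, 20.0, 50)
        gs = [diffusion_exponent_g(r) for r in radii]
        assert all(b > a for a, b in zip(gs, gs[1:]))

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(ValueError):
            diffusion_exponent_g(0.0)


class TestActivityCoefficient:
    def test_dilute_limit_is_zero(self):
        assert ln_activity_coefficient(2.4, MixtureState()) == 0.0

    def test_monodisperse_closed_form(self):
        # For a one-component hard-sphere fluid at packing fraction eta the
        # moment expression collapses to the closed form
        # -ln(1-eta) + 7 eta/(1-eta) + 7.5 eta^2/(1-eta)^2 + 3 eta^3/(1-eta)^3
        # (independent algebraic reduction; radius must drop out).
        for eta in (0.05, 0.1, 0.2, 0.35):
            expected = (-math.log(1 - eta) + 7 * eta / (1 - eta)
                        + 7.5 * eta**2 / (1 - eta) ** 2
                        + 3 * eta**3 / (1 - eta) ** 3)
            for r in (0.34, 2.4, 13.0):
                got = ln_activity_coefficient(r, monodisperse(r, eta))
                assert got == pytest.approx(expected, rel=1e-12)

    def test_increasing_in_probe_radius(self):
        mix = monodisperse(2.4, 0.2)
        assert (ln_activity_coefficient(4.8, mix)
                > ln_activity_coefficient(2.4, mix) > 0.0)

    def test_over_packed_rejected(self):
        sp = SphereSpecies("bg", 2.4)
        with pytest.raises(ValueError, match="over-packed"):
            MixtureState([(sp, 1.1 / sp.volume)])

    def test_non_crowding_species_excluded_from_moments(self):
        t = SphereSpecies("T", 2.4, crowds=False)
        mix = MixtureState([(t, 1e-3)])
        assert mix.m_V == 0.0
        assert ln_activity_coefficient(2.4, mix) == 0.0

    @settings(max_examples=40, deadline=None)
    @given(r=st.floats(0.1, 15.0), eta=st.floats(0.0, 0.5),
           r_bg=st.floats(0.1, 15.0))
    def test_nonnegative_property(self, r, eta, r_bg):
        assert ln_activity_coefficient(r, monodisperse(r_bg, eta)) >= 0.0


class TestGibbsPerturbation:
    def test_empty_mixture_gives_unity(self):
        assert gibbs_perturbation_Gamma(METABOLIC_KIN, MixtureState()) == 1.0

    def test_metabolic_geometry_exceeds_unity(self):
        # two separate spheres exclude more volume than their fused complex
        for r_bg in (0.34, 2.4, 13.0):
            assert gibbs_perturbation_Gamma(
                METABOLIC_KIN, monodisperse(r_bg, 0.2)) > 1.0

    def test_nondecreasing_under_density_scaling(self):
        sp = SphereSpecies("bg", 2.4)
        w0 = 0.2 / sp.volume
        gammas = [gibbs_perturbation_Gamma(METABOLIC_KIN,
                                           MixtureState([(sp, lam * w0)]))
                  for lam in np.linspace(0.0, 1.5, 16)]
        assert all(b >= a for a, b in zip(gammas, gammas[1:]))


class TestKMStar:
    @pytest.mark.parametrize("theta", [0.0, 1.0, 2.3, 50.0])
    def test_no_crowding_identity(self, theta):
        kin = ReactionKinetics(kcat=1, KM0=130.0, theta=theta,
                               substrate=SphereSpecies("s", 0.34),
                               catalyst=SphereSpecies("E", 2.4))
        bd = km_star(kin, Gamma=1.0, rho=0.0)
        assert bd.KM_star == pytest.approx(130.0, rel=1e-14)

    def test_pure_diffusion_limit(self):
        # theta = 0 with g*rho = 1 must give KM0 * e
        kin = ReactionKinetics(kcat=1, KM0=130.0, theta=0.0,
                               substrate=SphereSpecies("s", 0.34),
                               catalyst=SphereSpecies("E", 2.4))
        rho = 1.0 / diffusion_exponent_g(0.34)
        bd = km_star(kin, Gamma=3.7, rho=rho)   # Gamma must not matter
        assert bd.KM_star == pytest.approx(130.0 * math.e, rel=1e-12)

    def test_pure_transition_state_limit(self):
        kin = ReactionKinetics(kcat=1, KM0=130.0, theta=1e8,
                               substrate=SphereSpecies("s", 0.34),
                               catalyst=SphereSpecies("E", 2.4))
        bd = km_star(kin, Gamma=2.0, rho=0.3)
        assert bd.KM_star == pytest.approx(65.0, rel=1e-6)

    def test_diffusion_only_nondecreasing_in_rho(self):
        kin = METABOLIC_KIN
        vals = [km_star(kin, Gamma=5.0, rho=r, mode="diffusion_only").KM_star
                for r in np.linspace(0.0, 0.9, 30)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_transition_only_decreasing_with_plateau(self):
        kin = METABOLIC_KIN
        vals = [km_star(kin, Gamma=G, rho=0.5, mode="transition_only").KM_star
                for G in np.geomspace(1.0, 1e6, 25)]
        floor = kin.KM0 / (1.0 + kin.theta)
        assert all(b <= a for a, b in zip(vals, vals[1:]))
        assert all(v >= floor * (1 - 1e-12) for v in vals)
        assert vals[-1] == pytest.approx(floor, rel=1e-5)

    def test_diffusion_factor_in_unit_interval(self):
        for rho in (0.0, 0.3, 0.9):
            bd = km_star(METABOLIC_KIN, Gamma=2.0, rho=rho)
            assert 0.0 < bd.diffusion_factor <= 1.0

    @pytest.mark.parametrize("rho", [-0.1, 1.0, 1.5])
    def test_rho_domain_errors(self, rho):
        with pytest.raises(ValueError):
            km_star(METABOLIC_KIN, Gamma=1.0, rho=rho)

    def test_array_form_matches_scalar(self):
        rhos = np.array([0.0, 0.2, 0.5])
        arr = km_star_value(130.0, 2.3, 2.0, 5.0, rhos)
        for r, a in zip(rhos, arr):
            assert a == pytest.approx(
                km_star_value(130.0, 2.3, 2.0, 5.0, float(r)))


class TestBindingEquilibrium:
    def test_no_substrate(self):
        eq = solve_binding_equilibrium((50.0, 0.0), METABOLIC_KIN)
        assert eq.complex_conc == 0.0
        assert eq.free[0] == pytest.approx(50.0)

    def test_fixed_point_contract(self):
        eq = solve_binding_equilibrium((80.0, 4000.0), METABOLIC_KIN)
        e_tot, s_tot = eq.totals
        # re-evaluating the binding equation at the returned KM* must
        # reproduce the returned complex concentration
        es = e_tot * eq.free[1] / (eq.free[1] + eq.KM_star)
        assert es == pytest.approx(eq.complex_conc, rel=1e-4)
        # exact mass conservation
        assert eq.free[0] + eq.complex_conc == pytest.approx(e_tot, rel=1e-14)
        assert eq.free[1] + eq.complex_conc == pytest.approx(s_tot, rel=1e-14)
        assert eq.converged

    def test_dilute_matches_crowding_free_michaelis_menten(self):
        e_tot, s_tot = 1e-4, 2e-4     # occupancy < 1e-6
        eq = solve_binding_equilibrium((e_tot, s_tot), METABOLIC_KIN)
        b = e_tot + s_tot + METABOLIC_KIN.KM0
        es0 = 0.5 * (b - math.sqrt(b * b - 4 * e_tot * s_tot))
        assert eq.complex_conc == pytest.approx(es0, rel=1e-4)

    def test_negative_totals_rejected(self):
        with pytest.raises(ValueError):
            solve_binding_equilibrium((-1.0, 1.0), METABOLIC_KIN)
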