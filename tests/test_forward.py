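"""Forward model: conductivity law, boundary profiles, detector response, solver."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from mrbscan import (
    FARADAY,
    BoundaryState,
    ChannelGeometry,
    ConfigurationError,
    DomainError,
    ElectrodeWindow,
    IonSpecies,
    SpatialProfile,
    boundary_midpoint_mm,
    conductivity_from_species,
    erf_conductivity_profile,
    erf_front_concentration,
    linear_boundary_profile,
    scan_response,
    simulate_electromigration,
)

K = IonSpecies("K+", 1, 7.62e-8, 1.96e-9)
CL = IonSpecies("Cl-", -1, 7.91e-8, 2.03e-9)


class TestConductivityLaw:
    def test_empty_channel_is_nonconductive(self):
        assert conductivity_from_species({"K+": 0.0, "Cl-": 0.0}, [K, CL]) == 0.0

    def test_linearity_in_concentration(self):
        c1 = {"K+": 1.3, "Cl-": 2.1}
        c2 = {k: 2 * v for k, v in c1.items()}
        s1 = conductivity_from_species(c1, [K, CL])
        s2 = conductivity_from_species(c2, [K, CL])
        assert s2 == pytest.approx(2 * s1, rel=1e-14)

    def test_kcl_hand_summed_value(self):
        # independent scalar arithmetic: F*(mu+ c+ + mu- c-) for 1 mM KCl
        expected = 96485.33212 * (7.62e-8 * 1.0 + 7.91e-8 * 1.0)
        got = conductivity_from_species({"K+": 1.0, "Cl-": 1.0}, [K, CL])
        assert got == pytest.approx(expected, rel=1e-12)

    def test_vectorized_over_grids(self):
        c = {"K+": np.array([0.0, 1.0, 2.0]), "Cl-": np.array([0.0, 1.0, 2.0])}
        out = conductivity_from_species(c, [K, CL])
        assert out.shape == (3,)
        assert out[0] == 0.0 and out[2] == pytest.approx(2 * out[1], rel=1e-14)

    def test_negative_concentration_rejected(self):
        with pytest.raises(DomainError):
            conductivity_from_species({"K+": -1.0}, [K])

    def test_empty_species_rejected(self):
        with pytest.raises(ConfigurationError):
            conductivity_from_species({}, [])


class TestLinearBoundaryProfile:
    STATE = BoundaryState(sigma1=0.08, sigma2=0.10, U_mm_min=0.5)

    def test_midpoint_value(self):
        prof = linear_boundary_profile(self.STATE, 10.0, 12.0, np.linspace(0, 24, 49))
        assert prof.interp(11.0) == pytest.approx(0.09, abs=1e-15)

    def test_equal_zones_give_constant(self):
        state = BoundaryState(sigma1=0.09, sigma2=0.09, U_mm_min=0.5)
        prof = linear_boundary_profile(state, 5.0, 6.0, np.linspace(0, 24, 25))
        assert np.all(prof.sigma == 0.09)

    def test_matches_pointwise_two_point_interpolation(self):
        x1, x2 = 8.3, 13.7
        grid = np.linspace(0, 24, 97)
        prof = linear_boundary_profile(self.STATE, x1, x2, grid)
        s1, s2 = self.STATE.sigma1, self.STATE.sigma2
        for xi, si in zip(grid, prof.sigma):  # brute-force pointwise oracle
            if xi <= x1:
                expected = s1
            elif xi >= x2:
                expected = s2
            else:
                expected = s1 + (s2 - s1) * (xi - x1) / (x2 - x1)
            assert si == pytest.approx(expected, abs=1e-14)

    def test_inverted_interval_rejected(self):
        with pytest.raises(DomainError):
            linear_boundary_profile(self.STATE, 12.0, 10.0, np.linspace(0, 24, 10))


class TestErfFront:
    STATE = BoundaryState(sigma1=0.08, sigma2=0.10, U_mm_min=0.5, D=1e-9, c0=2.0)

    def test_center_value_is_c0(self):
        t = 10.0
        x = self.STATE.U_mm_min * t
        assert erf_front_concentration(x, t, self.STATE) == pytest.approx(2.0, rel=1e-12)

    def test_far_ahead_vanishes(self):
        assert erf_front_concentration(1e3, 10.0, self.STATE) == pytest.approx(0.0, abs=1e-12)

    def test_one_diffusion_length_matches_quadrature_oracle(self):
        # erf(1) evaluated independently by integrating the Gaussian kernel
        erf1, _ = quad(lambda u: 2.0 / math.sqrt(math.pi) * math.exp(-(u**2)), 0.0, 1.0)
        t = 10.0
        two_sqrt_dt_mm = 2.0 * math.sqrt(self.STATE.D * t * 60.0) / 1e-3
        x = self.STATE.U_mm_min * t + two_sqrt_dt_mm
        expected = self.STATE.c0 * (1.0 - erf1)
        assert erf_front_concentration(x, t, self.STATE) == pytest.approx(expected, rel=1e-9)

    def test_monotone_non_increasing_in_x(self):
        x = np.linspace(0, 24, 200)
        c = erf_front_concentration(x, 7.0, self.STATE)
        assert np.all(np.diff(c) <= 0)

    def test_nonpositive_time_rejected(self):
        with pytest.raises(DomainError):
            erf_front_concentration(1.0, 0.0, self.STATE)


class TestErfConductivityProfile:
    STATE = BoundaryState(sigma1=0.08, sigma2=0.10, U_mm_min=0.6, D=1e-9)

    def test_midpoint_at_boundary_center(self):
        t = 9.0
        grid = np.linspace(0, 24, 2401)
        prof = erf_conductivity_profile(grid, t, self.STATE)
        assert prof.interp(self.STATE.U_mm_min * t) == pytest.approx(0.09, rel=1e-9)

    def test_equal_zones_give_constant(self):
        state = BoundaryState(sigma1=0.09, sigma2=0.09, U_mm_min=0.6)
        prof = erf_conductivity_profile(np.linspace(0, 24, 100), 7.0, state)
        assert np.allclose(prof.sigma, 0.09, rtol=0, atol=1e-15)

    def test_matches_pointwise_scalar_oracle(self):
        t = 7.0
        grid = np.linspace(0, 24, 121)
        prof = erf_conductivity_profile(grid, t, self.STATE)
        s1, s2, u, d = 0.08, 0.10, 0.6, 1e-9
        for xi, si in zip(grid, prof.sigma):
            z = (xi - u * t) * 1e-3 / (2.0 * math.sqrt(d * t * 60.0))
            expected = s1 + 0.5 * (s2 - s1) * (1.0 + math.erf(z))
            assert si == pytest.approx(expected, rel=1e-12)

    def test_asymptotes_at_six_diffusion_lengths(self):
        t = 7.0
        ell_mm = 2.0 * math.sqrt(self.STATE.D * t * 60.0) / 1e-3
        xc = self.STATE.U_mm_min * t
        step = self.STATE.sigma2 - self.STATE.sigma1
        lo = erf_conductivity_profile(
            np.array([xc - 6 * ell_mm, xc + 6 * ell_mm]), t, self.STATE
        )
        assert abs(lo.sigma[0] - self.STATE.sigma1) <= 1e-9 * step
        assert abs(lo.sigma[1] - self.STATE.sigma2) <= 1e-9 * step

    def test_depletion_dip_is_localized_and_bounded(self):
        state = BoundaryState(
            sigma1=0.08, sigma2=0.10, U_mm_min=0.6, depletion_amp=0.08,
            depletion_width_mm=1.0,
        )
        t = 7.0
        prof = erf_conductivity_profile(np.linspace(0, 24, 2401), t, state)
        assert np.all(prof.sigma > 0)
        assert prof.sigma.min() < state.sigma1  # dip undercuts both zones
        # far away the dip has no effect
        assert prof.sigma[-1] == pytest.approx(state.sigma2, rel=1e-6)

    def test_overdeep_dip_rejected(self):
        state = BoundaryState(
            sigma1=0.08, sigma2=0.10, U_mm_min=0.6, depletion_amp=0.2
        )
        with pytest.raises(DomainError):
            erf_conductivity_profile(np.linspace(0, 24, 500), 7.0, state)


class TestScanResponse:
    def _profile(self, rng=None):
        grid = np.linspace(0, 24, 2401)
        state = BoundaryState(sigma1=0.08, sigma2=0.10, U_mm_min=0.6)
        return erf_conductivity_profile(grid, 9.0, state)

    def test_delta_window_equals_profile_resampling(self):
        prof = self._profile()
        delta = ElectrodeWindow(shape="delta")
        trace = scan_response(prof, delta, 1.0, 2.0, 50.0)
        expected = prof.interp(trace.positions_mm())
        np.testing.assert_allclose(trace.signal, expected, rtol=0, atol=1e-15)

    def test_constant_profile_normalized_window_gives_constant(self):
        grid = np.linspace(0, 24, 2401)
        prof = SpatialProfile(x_mm=grid, sigma=np.full_like(grid, 0.09), time_min=1.0)
        trace = scan_response(prof, ElectrodeWindow(), 1.0, 3.25, 20.0)
        np.testing.assert_allclose(trace.signal, 0.09, rtol=1e-12)

    @pytest.mark.parametrize("shape", ["unipolar_trapezoid", "bipolar_differential"])
    def test_matches_double_loop_convolution_oracle(self, shape, rng):
        grid = np.linspace(0, 24, 481)  # 50 um grid to keep the loop cheap
        sigma = 0.09 + 0.01 * rng.standard_normal(grid.size).cumsum() / 30
        sigma -= sigma.min() - 0.01
        prof = SpatialProfile(x_mm=grid, sigma=sigma, time_min=1.0)
        window = ElectrodeWindow(shape=shape)
        trace = scan_response(prof, window, 1.0, 4.0, 5.0, duration_s=12.0)
        offsets, w = window.weights(prof.dx_mm)
        for j, (t, s) in enumerate(zip(trace.t_s, trace.signal)):
            xc = 4.0 + 1.0 * t
            acc = 0.0
            for off_k, w_k in zip(offsets, w):  # brute-force sliding window
                acc += w_k * np.interp(xc + off_k, grid, sigma)
            assert s == pytest.approx(acc, abs=1e-12), f"sample {j}"

    def test_unipolar_trace_bounded_by_profile_range(self):
        prof = self._profile()
        trace = scan_response(prof, ElectrodeWindow(), 1.0, 3.25, 50.0)
        assert trace.signal.min() >= prof.sigma.min() - 1e-12
        assert trace.signal.max() <= prof.sigma.max() + 1e-12

    def test_window_wider_than_channel_rejected(self):
        grid = np.linspace(0, 5, 100)
        prof = SpatialProfile(x_mm=grid, sigma=np.full_like(grid, 0.1), time_min=1.0)
        with pytest.raises(ConfigurationError):
            scan_response(prof, ElectrodeWindow(), 1.0, 2.5, 10.0)


class TestElectromigrationSolver:
    def test_uniform_equilibrium_is_stationary(self):
        grid = np.linspace(0, 10, 101)
        na = IonSpecies("Na+", 1, 5.19e-8, 1.33e-9, 10.0, 10.0)
        cl = IonSpecies("Cl-", -1, 7.91e-8, 2.03e-9, 10.0, 10.0)
        res = simulate_electromigration([na, cl], 0.0, grid, 0.2, 1.0)
        assert np.allclose(res.profiles[-1].sigma, res.profiles[-1].sigma[0], rtol=1e-12)

    def test_neutral_pair_diffusion_conserves_mass(self):
        grid = np.linspace(0, 10, 101)
        na = IonSpecies("Na+", 1, 5.19e-8, 1.33e-9, 10.0, 0.0)
        cl = IonSpecies("Cl-", -1, 7.91e-8, 2.03e-9, 10.0, 0.0)
        res = simulate_electromigration(
            [na, cl], 0.0, grid, 0.2, 2.0, bc="noflux",
            output_times_min=[0.0, 2.0],
        )
        for name in ("Na+", "Cl-"):
            m0 = res.concentrations[0][name].sum()
            m1 = res.concentrations[-1][name].sum()
            assert abs(m1 - m0) / m0 <= 1e-8

    def test_advected_pulse_matches_analytic_displacement(self):
        grid = np.linspace(0, 10, 201)  # 50 um
        mu, e_field = 1.0e-8, 2000.0
        cv = IonSpecies("CV+", 1, mu, 3.0e-10)
        pulse = np.exp(-0.5 * ((grid - 2.0) / 0.3) ** 2)
        t_end = 2.0  # min
        res = simulate_electromigration(
            [cv], e_field, grid, 0.5, t_end, bc="noflux",
            initial_conc={"CV+": pulse}, output_times_min=[0.0, t_end],
        )
        com0 = np.average(grid, weights=res.concentrations[0]["CV+"])
        com1 = np.average(grid, weights=res.concentrations[-1]["CV+"])
        expected_mm = mu * e_field * t_end * 60.0 / 1e-3  # analytic mu*E*t
        assert com1 - com0 == pytest.approx(expected_mm, rel=0.01)

    def test_reaction_consumes_reactants_stoichiometrically(self):
        grid = np.linspace(0, 10, 101)
        cv = IonSpecies("CV+", 1, 1.0e-8, 3.0e-10, 5.0, 0.0)
        oh = IonSpecies("OH-", -1, 2.05e-7, 5.27e-9, 0.0, 5.0)
        na = IonSpecies("Na+", 1, 5.19e-8, 1.33e-9, 0.0, 5.0)
        ac = IonSpecies("acetate", -1, 4.24e-8, 1.09e-9, 5.0, 0.0)
        res = simulate_electromigration(
            [cv, oh, na, ac], 500.0, grid, 0.05, 1.0, reaction=True,
            bc="noflux", output_times_min=[0.0, 1.0],
        )
        d_cv = res.concentrations[0]["CV+"].sum() - res.concentrations[-1]["CV+"].sum()
        d_oh = res.concentrations[0]["OH-"].sum() - res.concentrations[-1]["OH-"].sum()
        assert d_cv > 0  # some titration happened
        assert abs(d_cv - d_oh) <= 1e-8 * max(d_cv, 1e-30)
        # a step-like conductivity transition exists at the meeting zone
        sig = res.profiles[-1].sigma
        assert sig.max() - sig.min() > 0.1 * sig.max()

    def test_cfl_violation_names_the_bound(self):
        grid = np.linspace(0, 10, 1001)  # 10 um
        oh = IonSpecies("OH-", -1, 2.05e-7, 5.27e-9, 5.0, 0.0)
        with pytest.raises(ConfigurationError, match="diffusion number"):
            simulate_electromigration([oh], 0.0, grid, 1.0, 1.0)
        with pytest.raises(ConfigurationError, match="advection number"):
            simulate_electromigration([oh], 5e4, grid, 0.005, 1.0)


class TestBoundaryMidpointKinematics:
    def test_erf_model_midpoint_advances_at_configured_velocity(self):
        state = BoundaryState(sigma1=0.08, sigma2=0.10, U_mm_min=0.7, D=1e-9)
        grid = np.linspace(0, 24, 2401)
        times = np.array([7.0, 9.0, 11.0, 13.0])
        pos = [
            boundary_midpoint_mm(
                erf_conductivity_profile(grid, t, state), 0.08, 0.10
            )
            for t in times
        ]
        slope = np.polyfit(times, pos, 1)[0]
        assert slope == pytest.approx(0.7, rel=0.05)

    def test_advected_front_midpoint_within_ten_percent(self):
        # single-cation conductivity front advected at mu*E
        grid = np.linspace(0, 12, 241)
        mu, e_field = 1.0e-8, 2000.0
        cv = IonSpecies("CV+", 1, mu, 3.0e-10, 8.0, 0.0)
        times = [0.5, 1.0, 1.5, 2.0]
        res = simulate_electromigration(
            [cv], e_field, grid, 0.5, 2.0, bc="fixed",
            output_times_min=times, interface_mm=3.0,
        )
        s_left = res.profiles[0].sigma.max()
        pos = []
        for prof in res.profiles:
            # falling front: midpoint where sigma crosses half the plateau
            target = 0.5 * s_left
            below = np.nonzero(prof.sigma < target)[0]
            i = below[0]
            frac = (prof.sigma[i - 1] - target) / (prof.sigma[i - 1] - prof.sigma[i])
            pos.append(prof.x_mm[i - 1] + frac * (prof.x_mm[i] - prof.x_mm[i - 1]))
        slope = np.polyfit(times, pos, 1)[0]
        expected = mu * e_field * 60.0 / 1e-3  # mm/min
        assert slope == pytest.approx(expected, rel=0.10)
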