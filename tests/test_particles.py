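"""Particle dynamics: force laws, integrators, stochastic limits, boundaries."""

import math

import numpy as np
import pytest

import lungchip as lc
from lungchip.particles import (
    ACTIVE_AIR,
    ACTIVE_MEDIA,
    DEPOSITED,
    EXITED_MEDIA,
    ParticleEnsemble,
    apply_boundaries,
    exponential_drag_update,
    run_tracing,
)
from lungchip.properties import KB


class TestForceLaws:
    def test_stokes_drag_reference(self):
        # 3 pi mu dp u = 3 pi * 1.9e-5 * 1e-6 * 1e-3
        F = lc.stokes_drag(1.9e-5, 1e-6, np.array([1e-3, 0.0]))
        assert F[0] == pytest.approx(1.79e-13, rel=0.01)
        assert F[1] == 0.0

    def test_stokes_drag_linearity_and_null(self):
        assert np.all(lc.stokes_drag(1.9e-5, 1e-6, np.zeros(2)) == 0.0)
        F1 = lc.stokes_drag(1.9e-5, 1e-6, np.array([1e-3, 2e-3]))
        F2 = lc.stokes_drag(1.9e-5, 2e-6, np.array([1e-3, 2e-3]))
        assert np.allclose(F2, 2.0 * F1)

    def test_brownian_force_null_cases(self):
        assert np.all(lc.brownian_force(1.9e-5, 0.0, 1e-7, 1e-4, np.ones(2)) == 0.0)
        assert np.all(lc.brownian_force(1.9e-5, 310.0, 1e-7, 1e-4, np.zeros(2)) == 0.0)
        with pytest.raises(ValueError):
            lc.brownian_force(1.9e-5, 310.0, 1e-7, -1e-4, np.ones(2))

    def test_brownian_force_variance(self):
        """Sample std of one component matches sqrt(6 pi kB mu T dp / dt) within 2%."""
        mu, T, dp, dt = 1.9e-5, 310.15, 100e-9, 1e-4
        rng = np.random.default_rng(1234)
        z = rng.standard_normal(100_000)
        F = lc.brownian_force(mu, T, dp, dt, z)
        expected = math.sqrt(6 * math.pi * KB * mu * T * dp / dt)
        assert expected == pytest.approx(3.9e-14, rel=0.02)  # closed-form amplitude
        assert F.std() == pytest.approx(expected, rel=0.02)

    def test_buoyant_weight(self):
        p = lc.ParticleProperties(900e-9, 1180.0)
        F = lc.buoyant_weight(p, 1.123, 9.81)
        assert F[0] == 0.0  # gravity is perpendicular to the flow
        assert F[1] == pytest.approx(-p.mp * (1 - 1.123 / 1180.0) * 9.81, rel=1e-12)
        assert np.all(lc.buoyant_weight(p, 1180.0, 9.81) == 0.0)  # neutral buoyancy

    @pytest.mark.parametrize("dp,rho_p,fluid,v_ref", [
        (900e-9, 1180.0, "air", 2.74e-5),
        (1e-6, 2200.0, "media", 9.11e-7),
        (10e-6, 1470.0, "media", 3.57e-5),
    ])
    def test_settling_velocity(self, dp, rho_p, fluid, v_ref):
        fl = lc.air_properties() if fluid == "air" else lc.media_properties()
        vs = lc.settling_velocity(lc.ParticleProperties(dp, rho_p), fl, 9.81)
        assert vs == pytest.approx(v_ref, rel=0.01)

    def test_settling_neutral(self):
        vs = lc.settling_velocity(
            lc.ParticleProperties(1e-6, 1000.0), lc.media_properties(), 9.81
        )
        assert vs == 0.0


class TestIntegrators:
    def test_exponential_relaxation_matches_analytic(self):
        """up(t) = U + (up0 - U) e^{-t/tau} to machine precision, any step size."""
        tau, U, up0 = 3.2e-7, np.array([1e-3, 0.0]), np.array([5e-3, -2e-3])
        for dt in (1e-9, 1e-7, 1e-3):  # spans dt << tau to dt >> tau
            up, disp = exponential_drag_update(up0, U, tau, dt)
            exact = U + (up0 - U) * math.exp(-dt / tau)
            np.testing.assert_allclose(up, exact, rtol=1e-13)
            exact_disp = U * dt + (up0 - U) * tau * (1 - math.exp(-dt / tau))
            np.testing.assert_allclose(disp, exact_disp, rtol=1e-13)

    def test_overdamped_passive_tracer_keeps_streamline(self, still_box):
        """No gravity, no Brownian: y never changes in a parallel flow."""
        geom, dom, _ = still_box
        ff = lc.solve_flow(dom, lc.air_properties(), lc.media_properties(),
                           0.3e-3, 0.0, inlet_profile="parabolic")
        ff.v[:] = 0.0  # exactly parallel flow: isolate the integrator property
        part = lc.ParticleProperties(200e-9, 1180.0)
        cfg = lc.SimulationConfig(u_air_inlet=0.3e-3, u_media_inlet=0.0,
                                  n_particles=40, seed=3, brownian=False,
                                  gravity=False, max_time=30.0)
        ens = ParticleEnsemble.empty(40)
        y0 = np.linspace(geom.y_membrane_top + 5e-6, geom.height - 5e-6, 40)
        ens.y[:] = y0
        ens.x[:] = 0.0
        for _ in range(200):
            idx, x1, y1 = lc.step(ens, ff, part, cfg, 1e-2)
            apply_boundaries(ens, dom, idx, x1, y1, ens.t[idx] + 1e-2)
        live = ens.status == ACTIVE_AIR
        np.testing.assert_allclose(ens.y[live], y0[live], rtol=1e-10)

    def test_gravity_only_fall_kinematics(self, still_box):
        """Quiescent fluid: overdamped falls at v_s t; inertial at the tau-corrected law."""
        geom, dom, ff = still_box
        part = lc.ParticleProperties(900e-9, 1180.0)
        vs = lc.settling_velocity(part, lc.air_properties(), 9.81)
        tau = part.relaxation_time(lc.air_properties())
        t_tot, nsteps = 0.5, 50
        dt = t_tot / nsteps
        for mode, expected in (
            ("overdamped", vs * t_tot),
            ("inertial", vs * t_tot - vs * tau * (1 - math.exp(-t_tot / tau))),
        ):
            cfg = lc.SimulationConfig(u_air_inlet=0.0, u_media_inlet=0.0,
                                      n_particles=1, seed=0, brownian=False,
                                      integrator_mode=mode, initial_velocity="zero")
            ens = ParticleEnsemble.empty(1)
            ens.x[:] = geom.l / 2
            ens.y[:] = geom.height - 5e-6
            for _ in range(nsteps):
                idx, x1, y1 = lc.step(ens, ff, part, cfg, dt)
                apply_boundaries(ens, dom, idx, x1, y1, ens.t[idx] + dt)
            fall = (geom.height - 5e-6) - ens.y[0]
            assert fall == pytest.approx(expected, rel=1e-6)

    def test_brownian_msd_stokes_einstein(self, still_box):
        """Free diffusion: per-axis MSD grows as 2 D t with D = kB T/(3 pi mu dp)."""
        geom, dom, ff = still_box
        part = lc.ParticleProperties(100e-9, 1180.0)
        D = part.diffusivity(lc.air_properties())
        n = 10_000
        cfg = lc.SimulationConfig(u_air_inlet=0.0, u_media_inlet=0.0, n_particles=n,
                                  seed=11, gravity=False)
        ens = ParticleEnsemble.empty(n)
        ens.x[:] = geom.l / 2
        ens.y[:] = geom.y_membrane_top + geom.h_air / 2
        x0, y0 = ens.x.copy(), ens.y.copy()
        rng = np.random.default_rng(99)
        dt, nsteps = 5e-3, 40
        for _ in range(nsteps):
            idx, x1, y1 = lc.step(ens, ff, part, cfg, dt, rng=rng)
            ens.x[idx] = x1  # free space: skip boundaries (drift ~ um << box)
            ens.y[idx] = y1
        t = dt * nsteps
        msd_x = np.mean((ens.x - x0) ** 2)
        msd_y = np.mean((ens.y - y0) ** 2)
        se = math.sqrt(2.0) * 2 * D * t / math.sqrt(n)
        assert msd_x == pytest.approx(2 * D * t, abs=4 * se)
        assert msd_y == pytest.approx(2 * D * t, abs=4 * se)

    def test_inertial_and_overdamped_agree_on_rates(self, small_domain, small_field):
        """For submicron particles (Stk << 1) the two integrators give the same fates."""
        part = lc.ParticleProperties(400e-9, 1180.0)
        rates = {}
        for mode in ("overdamped", "inertial"):
            cfg = lc.SimulationConfig(n_particles=400, seed=5, integrator_mode=mode,
                                      max_time=20.0)
            res = run_tracing(small_field, small_domain, part, cfg)
            rates[mode] = (lc.deposition_rate(res), lc.transfer_rate(res))
        se = math.sqrt(0.25 / 400) * math.sqrt(2.0)
        assert rates["overdamped"][0] == pytest.approx(rates["inertial"][0], abs=3 * se)
        assert rates["overdamped"][1] == pytest.approx(rates["inertial"][1], abs=3 * se)


class TestBoundaries:
    def _ensemble_at(self, xs, ys, status=ACTIVE_AIR):
        ens = ParticleEnsemble.empty(len(xs))
        ens.x[:] = xs
        ens.y[:] = ys
        ens.status[:] = status
        return ens

    def test_sticky_membrane_top(self, small_domain):
        """Crossing a solid membrane segment deposits at the wall."""
        g = small_domain.geometry
        ens = self._ensemble_at([14e-6], [g.y_membrane_top + 2e-6])
        apply_boundaries(ens, small_domain, np.array([0]),
                         np.array([15e-6]), np.array([g.y_membrane_top - 3e-6]),
                         np.array([0.1]))
        assert ens.status[0] == DEPOSITED
        assert ens.y[0] == g.y_membrane_top
        assert 14e-6 <= ens.deposit_x[0] <= 15e-6

    def test_pore_mouth_passes_through(self, small_domain):
        """Crossing inside a pore slot keeps the particle active (no deposition)."""
        g = small_domain.geometry
        ens = self._ensemble_at([5e-6], [g.y_membrane_top + 1e-6])
        apply_boundaries(ens, small_domain, np.array([0]),
                         np.array([5e-6]), np.array([g.y_membrane_top - 2e-6]),
                         np.array([0.1]))
        assert ens.status[0] == ACTIVE_AIR
        assert np.isnan(ens.t_transfer[0])

    def test_pore_exit_transfers_phase(self, small_domain):
        g = small_domain.geometry
        ens = self._ensemble_at([5e-6], [g.y_media_top + 2e-6])  # inside the slot
        apply_boundaries(ens, small_domain, np.array([0]),
                         np.array([5e-6]), np.array([g.y_media_top - 2e-6]),
                         np.array([0.7]))
        assert ens.status[0] == ACTIVE_MEDIA
        assert ens.t_transfer[0] == 0.7

    def test_ceiling_reflects_specularly(self, small_domain):
        g = small_domain.geometry
        y_try = g.height + 3e-6
        ens = self._ensemble_at([50e-6], [g.height - 1e-6])
        apply_boundaries(ens, small_domain, np.array([0]),
                         np.array([50e-6]), np.array([y_try]), np.array([0.1]))
        assert ens.status[0] == ACTIVE_AIR
        assert ens.y[0] == pytest.approx(2 * g.height - y_try)

    def test_pore_side_wall_reflects(self, small_domain):
        g = small_domain.geometry
        ens = self._ensemble_at([9e-6], [g.y_media_top + 5e-6])  # slot [0, 10] um
        apply_boundaries(ens, small_domain, np.array([0]),
                         np.array([11e-6]), np.array([g.y_media_top + 5e-6]),
                         np.array([0.1]))
        assert ens.status[0] == ACTIVE_AIR
        assert ens.x[0] == pytest.approx(9e-6, rel=1e-6)

    def test_media_outlet_records_exit(self, small_domain):
        g = small_domain.geometry
        ens = self._ensemble_at([g.l - 1e-6], [50e-6], status=ACTIVE_MEDIA)
        apply_boundaries(ens, small_domain, np.array([0]),
                         np.array([g.l + 1e-6]), np.array([52e-6]), np.array([2.5]))
        assert ens.status[0] == EXITED_MEDIA
        assert ens.t_exit[0] == 2.5
        assert 50e-6 <= ens.y_exit[0] <= 52e-6

    def test_membrane_underside_reflects_media_particles(self, small_domain):
        """Transfer is one-way: media particles cannot re-enter the pores."""
        g = small_domain.geometry
        ens = self._ensemble_at([5e-6], [g.y_media_top - 1e-6], status=ACTIVE_MEDIA)
        apply_boundaries(ens, small_domain, np.array([0]),
                         np.array([5e-6]), np.array([g.y_media_top + 2e-6]),
                         np.array([0.1]))
        assert ens.status[0] == ACTIVE_MEDIA
        assert ens.y[0] == pytest.approx(g.y_media_top - 2e-6)


class TestRunTracing:
    def test_deterministic_per_seed(self, small_domain, small_field):
        part = lc.ParticleProperties(200e-9, 1180.0)
        cfg = lc.SimulationConfig(n_particles=50, seed=42, max_time=15.0)
        r1 = run_tracing(small_field, small_domain, part, cfg)
        r2 = run_tracing(small_field, small_domain, part, cfg)
        np.testing.assert_array_equal(r1.deposits, r2.deposits)
        np.testing.assert_array_equal(r1.transfers, r2.transfers)
        np.testing.assert_array_equal(r1.media_exit_times, r2.media_exit_times)
        assert r1.counts() == r2.counts()

    def test_passive_tracers_all_exit(self):
        """Pores closed, Brownian and gravity off: plug flow carries everyone out."""
        geom = lc.ChannelGeometry(l=200e-6, d=0.0)
        dom = lc.build_domain(geom)
        ff = lc.solve_flow(dom, lc.air_properties(), lc.media_properties(), 0.3e-3, 0.3e-3)
        part = lc.ParticleProperties(200e-9, 1180.0)
        cfg = lc.SimulationConfig(n_particles=60, seed=7, brownian=False,
                                  gravity=False, max_time=10.0)
        res = run_tracing(ff, dom, part, cfg)
        assert res.n_exited_air == 60
        assert lc.deposition_rate(res) == 0.0
        assert lc.transfer_rate(res) == 0.0

    def test_fates_partition_ensemble(self, small_domain, small_field):
        part = lc.ParticleProperties(100e-9, 1180.0)
        cfg = lc.SimulationConfig(n_particles=200, seed=9, max_time=10.0)
        res = run_tracing(small_field, small_domain, part, cfg)
        c = res.counts()
        in_media = c["transferred"] - c["exited_media"] - c["incomplete_media"]
        assert in_media >= 0
        assert (c["deposited"] + c["exited_air"] + c["incomplete_air"]
                + c["transferred"]) == c["released"]

    def test_status_transitions_one_way(self, small_domain, small_field):
        """Deposited particles stay frozen; transfer times precede exit times."""
        part = lc.ParticleProperties(900e-9, 1180.0)
        cfg = lc.SimulationConfig(n_particles=150, seed=2, max_time=60.0)
        res = run_tracing(small_field, small_domain, part, cfg)
        ens = res.ensemble
        dep = ens.status == DEPOSITED
        assert np.all(ens.y[dep] == small_domain.geometry.y_membrane_top)
        exited = ens.status == EXITED_MEDIA
        assert np.all(ens.t_transfer[exited] <= ens.t_exit[exited])
        # t_transfer set iff the particle reached the media phase
        has_tt = ~np.isnan(ens.t_transfer)
        in_media_states = np.isin(ens.status, (ACTIVE_MEDIA, EXITED_MEDIA))
        np.testing.assert_array_equal(has_tt, in_media_states)

    def test_absorbing_floor_diffusion_oracle(self, still_box):
        """Brownian-only absorbed fraction tracks the 1D finite-difference solution."""
        from conftest import absorbed_fraction_fd

        geom, dom, ff = still_box
        part = lc.ParticleProperties(100e-9, 1180.0)
        D = part.diffusivity(lc.air_properties())
        cfg = lc.SimulationConfig(u_air_inlet=0.0, u_media_inlet=0.0,
                                  n_particles=2000, seed=21, gravity=False,
                                  dt=0.02, max_time=10.0, release_x=geom.l / 2)
        res = run_tracing(ff, dom, part, cfg)
        ens = res.ensemble
        t_dep = ens.t[ens.status == DEPOSITED]
        oracle = absorbed_fraction_fd(D, geom.h_air, [3.0, 6.0, 10.0])
        for t_chk, f_ref in oracle.items():
            f_sim = np.mean(t_dep <= t_chk) * len(t_dep) / 2000
            assert f_sim == pytest.approx(f_ref, abs=0.05)
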