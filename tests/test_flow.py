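"""Flow solver: analytic oracles, conservation, linearity, sampling contract."""

import numpy as np
import pytest

import lungchip as lc
from lungchip.flow import channel_fluxes, sample_velocity


class TestPoiseuilleProfile:
    def test_no_slip_ends(self):
        assert lc.poiseuille_profile(1e-3, 100e-6, 0.0) == 0.0
        assert lc.poiseuille_profile(1e-3, 100e-6, 100e-6) == 0.0

    def test_centerline_ratio(self):
        assert lc.poiseuille_profile(1e-3, 100e-6, 50e-6) == pytest.approx(1.5e-3)

    def test_integrates_to_mean(self):
        y = np.linspace(0, 100e-6, 2001)
        u = lc.poiseuille_profile(2e-3, 100e-6, y)
        assert np.trapezoid(u, y) / 100e-6 == pytest.approx(2e-3, rel=1e-5)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            lc.poiseuille_profile(1e-3, 100e-6, 101e-6)


class TestFlowRate:
    @pytest.mark.parametrize("u,w,h,q", [
        (0.03e-3, 2000e-6, 100e-6, 0.36),
        (0.1e-3, 2000e-6, 100e-6, 1.2),
        (0.1e-3, 2000e-6, 300e-6, 3.6),
        (0.3e-3, 2000e-6, 300e-6, 10.8),
        (0.0, 2000e-6, 100e-6, 0.0),
    ])
    def test_benchmark_cross_sections(self, u, w, h, q):
        assert lc.flow_rate(u, w, h) == pytest.approx(q, rel=1e-9)


class TestSolveFlow:
    def test_null_forcing(self, small_domain):
        ff = lc.solve_flow(small_domain, lc.air_properties(), lc.media_properties(), 0.0, 0.0)
        assert np.abs(ff.u).max() == 0.0
        assert np.abs(ff.v).max() == 0.0

    def test_poiseuille_agreement_within_1pc(self):
        """Impermeable membrane + developed inlet reproduces the parallel-plate parabola."""
        geom = lc.ChannelGeometry(l=400e-6, d=0.0)
        dom = lc.build_domain(geom)
        ff = lc.solve_flow(dom, lc.air_properties(), lc.media_properties(),
                           0.3e-3, 0.3e-3, inlet_profile="parabolic")
        y = np.linspace(geom.y_membrane_top, geom.height, 51)[1:-1]
        u_num, v_num = sample_velocity(ff, np.full_like(y, geom.l / 2), y)
        u_ref = lc.poiseuille_profile(0.3e-3, geom.h_air, y - geom.y_membrane_top)
        assert np.max(np.abs(u_num - u_ref)) / u_ref.max() < 0.01
        assert np.max(np.abs(v_num)) / u_ref.max() < 0.01

    def test_grid_convergence(self):
        """Profile error decreases monotonically under grid refinement."""
        geom = lc.ChannelGeometry(l=200e-6, d=0.0)
        dom = lc.build_domain(geom)
        errs = []
        for dy in (10e-6, 5e-6, 2.5e-6):
            ff = lc.solve_flow(dom, lc.air_properties(), lc.media_properties(),
                               0.3e-3, 0.3e-3, inlet_profile="parabolic", target_dy=dy)
            y = np.linspace(geom.y_membrane_top, geom.height, 41)[1:-1]
            u_num, _ = sample_velocity(ff, np.full_like(y, geom.l / 2), y)
            u_ref = lc.poiseuille_profile(0.3e-3, geom.h_air, y - geom.y_membrane_top)
            errs.append(np.max(np.abs(u_num - u_ref)) / u_ref.max())
        assert errs[0] > errs[1] > errs[2]

    def test_divergence_free(self, small_field, small_field_open):
        for ff in (small_field, small_field_open):
            scale = 0.3e-3
            assert np.abs(ff.divergence()).max() * ff.dx / scale < 1e-7

    def test_stokes_linearity(self, small_domain, small_field):
        """Doubling both inlet velocities doubles the whole field."""
        ff2 = lc.solve_flow(small_domain, lc.air_properties(), lc.media_properties(),
                            0.6e-3, 0.6e-3)
        assert np.allclose(ff2.u, 2.0 * small_field.u, rtol=1e-9, atol=1e-15)
        assert np.allclose(ff2.v, 2.0 * small_field.v, rtol=1e-9, atol=1e-15)

    def test_channel_reynolds_laminar(self, small_field):
        """Channel Re = rho u h / mu stays well below the laminar threshold."""
        air, media = lc.air_properties(), lc.media_properties()
        re_air = air.rho * 1e-3 * 100e-6 / air.mu
        re_media = media.rho * 1e-3 * 100e-6 / media.mu
        assert re_air < 0.01 and re_media < 0.2

    def test_global_conservation_per_channel(self, small_field_open):
        """Inlet flux = outlet flux + net pore loss for each channel (open mode)."""
        fx = channel_fluxes(small_field_open)
        scale = abs(fx["air_in"])
        # downward pore flux leaves the air channel and feeds the media channel
        assert abs(fx["air_in"] - fx["air_out"] - fx["pore_down_top"]) < 1e-4 * scale
        assert abs(fx["media_in"] - fx["media_out"] + fx["pore_down_bottom"]) < 1e-4 * scale

    def test_symmetric_case_zero_net_pore_flux(self, small_domain):
        """Identical fluids + equal inlets: symmetry kills the net pore exchange."""
        m = lc.media_properties()
        ff = lc.solve_flow(small_domain, m, m, 0.3e-3, 0.3e-3, membrane_flow="open")
        fx = channel_fluxes(ff)
        assert abs(fx["net_pore_flux"]) < 1e-6 * abs(fx["air_in"])

    def test_sealed_membrane_keeps_channel_flux(self, small_field):
        fx = channel_fluxes(small_field)
        assert fx["air_out"] == pytest.approx(fx["air_in"], rel=1e-6)
        assert abs(fx["net_pore_flux"]) < 1e-6 * abs(fx["air_in"])

    def test_shallow_channel_drag_flattens_profile(self):
        """The Hele-Shaw term leaves the mean flux intact but is felt at depth ~ h."""
        geom = lc.ChannelGeometry(l=200e-6, d=0.0)
        dom = lc.build_domain(geom)
        ff_inf = lc.solve_flow(dom, lc.air_properties(), lc.media_properties(), 0.3e-3, 0.3e-3)
        ff_sh = lc.solve_flow(dom, lc.air_properties(), lc.media_properties(), 0.3e-3, 0.3e-3,
                              shallow_depth=50e-6)
        mid = ff_inf.nx // 2
        umax_inf = ff_inf.u[:, mid].max()
        umax_sh = ff_sh.u[:, mid].max()
        assert umax_sh < umax_inf  # drag suppresses the centerline overshoot


class TestSampleVelocity:
    def test_node_identity(self, small_field):
        """Interpolation reproduces stored nodal values exactly at nodes."""
        j, i = 5, 7
        u, v = sample_velocity(small_field, small_field.x_nodes[i], small_field.y_nodes[j])
        assert u == pytest.approx(small_field.u[j, i], abs=1e-20)
        assert v == pytest.approx(small_field.v[j, i], abs=1e-20)

    def test_zero_on_walls(self, small_field):
        g = small_field.domain.geometry
        u, v = sample_velocity(small_field, g.l / 3, g.height)  # ceiling
        assert u == 0.0 and v == 0.0
        # membrane-top solid segment (between the first two pores)
        u, v = sample_velocity(small_field, 15e-6, g.y_membrane_top)
        assert u == 0.0 and v == 0.0

    def test_bilinear_reproduces_linear_fields(self, small_field):
        """Manufactured linear velocity interpolates exactly at cell centers."""
        ff = small_field
        X, Y = np.meshgrid(ff.x_nodes, ff.y_nodes)
        ff2 = lc.FlowField(
            domain=ff.domain, dx=ff.dx, dy=ff.dy, x_nodes=ff.x_nodes, y_nodes=ff.y_nodes,
            u=2.0 * X + 3.0 * Y, v=-1.0 * X + 0.5 * Y, p=ff.p,
            u_face=ff.u_face, v_face=ff.v_face,
            solid_cell=ff.solid_cell, media_cell=ff.media_cell,
            air=ff.air, media=ff.media,
        )
        x = ff.x_nodes[3] + ff.dx / 2
        y = ff.y_nodes[10] + ff.dy / 2
        u, v = sample_velocity(ff2, x, y, validate=False)
        assert u == pytest.approx(2.0 * x + 3.0 * y, rel=1e-12)
        assert v == pytest.approx(-1.0 * x + 0.5 * y, rel=1e-12)

    def test_solid_query_rejected(self, small_field):
        g = small_field.domain.geometry
        with pytest.raises(LookupError):
            sample_velocity(small_field, 15e-6, g.y_media_top + g.b / 2)
        with pytest.raises(LookupError):
            sample_velocity(small_field, -1e-6, 50e-6)
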