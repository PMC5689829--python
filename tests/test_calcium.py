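"""Deterministic Ca2+ transport: site fluxes, diffusion, totals."""

import numpy as np
import pytest

import sparkfiber.calcium as ca


def _uniform_site(p, value=0.1, jsr=0.8, shape=(3, 3, 6)):
    arr = np.full(shape, float(value))
    return ca.ReleaseSiteState(
        ca_d=arr.copy(), ca_jsr=np.full(shape, float(jsr)),
        ca_sm=arr.copy(),
        b_cam=ca.bound_rapid(arr, p.bt_cam_sm, p.koff_cam / p.kon_cam),
        b_sl=ca.bound_rapid(arr, p.bt_sl_sm, p.koff_sl / p.kon_sl))


class TestSiteDerivatives:
    def test_equilibrium_with_globals_is_stationary(self, transport_params):
        p = transport_params
        site = _uniform_site(p, value=0.1, jsr=0.8)
        glob = ca.GlobalCaState(ca_i=0.1, ca_nsr=0.8)
        d = ca.site_derivatives(site, 0, 0.0, glob, p)
        for key in ("ca_d", "ca_jsr", "ca_sm", "b_cam", "b_sl", "j_ryr"):
            assert np.allclose(d[key], 0.0, atol=1e-12), key

    def test_zero_gradient_means_zero_release(self, transport_params):
        p = transport_params
        site = _uniform_site(p, value=800.0, jsr=0.8)  # ca_d = 1000*ca_jsr
        glob = ca.GlobalCaState(ca_i=0.1, ca_nsr=0.8)
        d = ca.site_derivatives(site, 48, 0.0, glob, p)
        assert np.allclose(d["j_ryr"], 0.0, atol=1e-9)

    def test_release_flux_equals_permeability_times_gradient(
            self, transport_params):
        p = transport_params
        # scalar oracle: J = k_rel * (n/N) * (1000*jsr - ca_d)
        j = ca.release_flux(12, 1.2, 50.0, p)
        assert j == pytest.approx(p.k_rel * (12 / 48) * (1200.0 - 50.0))

    def test_negative_open_count_rejected(self, transport_params):
        p = transport_params
        site = _uniform_site(p)
        glob = ca.GlobalCaState(ca_i=0.1, ca_nsr=0.8)
        with pytest.raises(ValueError):
            ca.site_derivatives(site, -1, 0.0, glob, p)


class TestSmDiffusion:
    def test_uniform_field_has_zero_flux(self, transport_params):
        geom = ca.LatticeGeometry(nx=3, ny=3, nz=6)
        flux = ca.sm_diffusion_fluxes(np.full(geom.shape, 2.5), geom,
                                      transport_params)
        assert np.allclose(flux, 0.0)

    def test_conservation_on_random_fields(self, transport_params, rng):
        geom = ca.LatticeGeometry(nx=4, ny=3, nz=5)
        for _ in range(5):
            field = rng.uniform(0, 100, geom.shape)
            flux = ca.sm_diffusion_fluxes(field, geom, transport_params)
            assert abs(flux.sum()) < 1e-9 * np.abs(flux).sum() + 1e-12

    def test_two_site_equilibration_time_constant(self, transport_params):
        # closed-form: d(c1-c2)/dt = -2/tau (c1-c2) along one axis
        p = transport_params
        geom = ca.LatticeGeometry(nx=2, ny=1, nz=1)
        c = np.array([10.0, 0.0]).reshape(2, 1, 1)
        dt, steps = 0.01, 1000
        for _ in range(steps):
            c = c + dt * ca.sm_diffusion_fluxes(c, geom, p)
        expected = 5.0 + np.array([5.0, -5.0]).reshape(2, 1, 1) * np.exp(
            -2.0 * steps * dt / p.tau_sm_trans)
        assert np.allclose(c, expected, rtol=1e-3)

    def test_longitudinal_axis_twice_slower(self, transport_params):
        p = transport_params
        gx = ca.LatticeGeometry(nx=2, ny=1, nz=1)
        gz = ca.LatticeGeometry(nx=1, ny=1, nz=2)
        cx = np.array([1.0, 0.0]).reshape(2, 1, 1)
        cz = np.array([1.0, 0.0]).reshape(1, 1, 2)
        fx = ca.sm_diffusion_fluxes(cx, gx, p)
        fz = ca.sm_diffusion_fluxes(cz, gz, p)
        assert fx.ravel()[0] == pytest.approx(
            p.anisotropy * fz.ravel()[0], rel=1e-12)

    def test_shape_mismatch_rejected(self, transport_params):
        geom = ca.LatticeGeometry(nx=3, ny=3, nz=6)
        with pytest.raises(ValueError):
            ca.sm_diffusion_fluxes(np.zeros((2, 2, 2)), geom,
                                   transport_params)


class TestGlobals:
    def test_zero_fluxes_zero_derivatives(self, transport_params):
        glob = ca.GlobalCaState(ca_i=0.1, ca_nsr=0.8)
        dca_i, dca_nsr = ca.global_derivatives(glob, 0.0, 0.0, 0.0, 0.0,
                                               transport_params)
        assert dca_i == 0.0 and dca_nsr == 0.0

    def test_serca_moves_ca_from_cytosol_to_nsr(self, transport_params):
        p = transport_params
        glob = ca.GlobalCaState(ca_i=0.5, ca_nsr=0.8)
        j_serca = ca.serca_flux(0.5, p)
        dca_i, dca_nsr = ca.global_derivatives(glob, 0.0, 0.0, j_serca, 0.0, p)
        assert dca_i < 0 and dca_nsr > 0
        # amount balance: cytosol loss (free+buffered) equals NSR gain
        amount_out = -dca_i / ca.beta_cyto(0.5, p) * p.v_cyto
        amount_in = dca_nsr * 1000.0 * p.v_nsr
        assert amount_in == pytest.approx(amount_out, rel=1e-12)


class TestTotalCalcium:
    def test_empty_cell_is_zero(self, transport_params):
        p = transport_params
        shape = (2, 2, 2)
        site = ca.ReleaseSiteState(*(np.zeros(shape) for _ in range(5)))
        glob = ca.GlobalCaState(ca_i=0.0, ca_nsr=0.0)
        assert ca.total_cell_calcium(site, glob, p) == 0.0

    def test_brute_force_re_summation(self, transport_params, rng):
        """Independent per-site loop summation agrees with the fast path."""
        p = transport_params
        shape = (3, 2, 4)
        site = ca.ReleaseSiteState(
            ca_d=rng.uniform(0, 50, shape), ca_jsr=rng.uniform(0.2, 1.2, shape),
            ca_sm=rng.uniform(0, 30, shape), b_cam=rng.uniform(0, 20, shape),
            b_sl=rng.uniform(0, 500, shape))
        glob = ca.GlobalCaState(ca_i=0.2, ca_nsr=0.9)
        total = 0.0
        for idx in np.ndindex(shape):
            total += site.ca_d[idx] * p.v_d
            total += (site.ca_sm[idx] + site.b_cam[idx] + site.b_sl[idx]) * p.v_sm
            jsr = site.ca_jsr[idx]
            total += 1000.0 * (jsr + p.bt_csq * jsr / (p.kd_csq + jsr)) * p.v_jsr
            cyt = (0.2 + p.bt_cmdn * 0.2 / (p.kd_cmdn + 0.2)
                   + p.bt_trpn * 0.2 / (p.kd_trpn + 0.2))
            total += cyt * p.v_cyto + 0.9 * 1000.0 * p.v_nsr
        expected = total * 1e-6
        assert ca.total_cell_calcium(site, glob, p) == pytest.approx(
            expected, rel=1e-12)

    def test_linearity_under_doubling_of_free_and_bound(self, transport_params):
        p = transport_params
        shape = (2, 2, 3)
        site = ca.ReleaseSiteState(
            ca_d=np.full(shape, 5.0), ca_jsr=np.full(shape, 0.8),
            ca_sm=np.full(shape, 2.0), b_cam=np.full(shape, 4.0),
            b_sl=np.full(shape, 50.0))
        glob = ca.GlobalCaState(ca_i=0.2, ca_nsr=0.9)
        base = ca.total_cell_calcium(site, glob, p)
        # doubling all *amounts* (free and bound alike) must double the total;
        # rapid-buffered pools are linearized by doubling buffer totals too
        p2 = ca.TransportParams(**{**p.__dict__})
        site2 = ca.ReleaseSiteState(
            ca_d=site.ca_d * 2, ca_jsr=site.ca_jsr, ca_sm=site.ca_sm * 2,
            b_cam=site.b_cam * 2, b_sl=site.b_sl * 2)
        free_only = (np.sum(site.ca_d) * p.v_d
                     + np.sum(site.ca_sm + site.b_cam + site.b_sl) * p.v_sm)
        delta = ca.total_cell_calcium(site2, glob, p2) - base
        assert delta == pytest.approx(free_only * 1e-6, rel=1e-12)


class TestWholeCellJryr:
    def test_no_open_channels_gives_zero(self, transport_params):
        j = ca.whole_cell_jryr(np.zeros((3, 3, 6)), transport_params)
        assert j == 0.0

    def test_single_site_volume_rescaling(self, transport_params):
        p = transport_params
        field = np.zeros((2, 2, 2))
        field[0, 0, 0] = ca.release_flux(48, 1.0, 0.0, p)
        expected = field[0, 0, 0] * p.v_d / (p.v_cyto * 8)
        assert ca.whole_cell_jryr(field, p) == pytest.approx(expected)

    def test_additive_over_disjoint_sites(self, transport_params, rng):
        p = transport_params
        a = np.zeros((2, 2, 4))
        b = np.zeros((2, 2, 4))
        a[0, 0, :2] = rng.uniform(10, 100, 2)
        b[1, 1, 2:] = rng.uniform(10, 100, 2)
        assert ca.whole_cell_jryr(a + b, p) == pytest.approx(
            ca.whole_cell_jryr(a, p) + ca.whole_cell_jryr(b, p))


class TestGeometry:
    def test_full_scale_site_count(self):
        geom = ca.LatticeGeometry(nx=25, ny=20, nz=50)
        assert geom.n_sites == 25000

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            ca.LatticeGeometry(nx=0)
        with pytest.raises(ValueError):
            ca.LatticeGeometry(sm_inner_radius=200.0, sm_outer_radius=180.0)
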