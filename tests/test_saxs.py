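"""Form-factor models: spheres, hollow cylinders, smearing, lattice peaks."""

import numpy as np
import pytest
from scipy.optimize import brentq

from xpcskit.geometry import RadialProfile
from xpcskit.saxs import (
    FWHM_TO_SIGMA,
    SPHERE_FIRST_ZERO,
    LatticeModel,
    NoPeakError,
    SphereModel,
    TubeModel,
    annulus_amplitude,
    hollow_cylinder_intensity,
    lattice_peak_pattern,
    peak_spacing,
    polydisperse_sphere_intensity,
    smear_resolution,
    smeared_model,
    sphere_form_factor,
)


class TestSphereFormFactor:
    def test_forward_scattering_is_one(self):
        assert sphere_form_factor(np.array([0.0]), 100.0)[0] == pytest.approx(1.0)

    def test_small_argument_series_continuous(self):
        # straddle the series/direct crossover at qR = 1e-2
        x = np.array([2e-3, 5e-3, 9.9e-3, 1.01e-2, 2e-2, 5e-2])
        p = sphere_form_factor(x, 1.0)
        assert np.all(np.diff(p) < 0) and np.all(p < 1.0)
        np.testing.assert_allclose(p, (1 - x**2 / 10) ** 2, rtol=1e-7)

    def test_first_zero_matches_tan_x_equals_x(self):
        # independent oracle: bisection on tan(x) = x in (pi, 3pi/2)
        x_zero = brentq(lambda x: np.tan(x) - x, np.pi + 0.1, 1.5 * np.pi - 1e-9)
        assert x_zero == pytest.approx(SPHERE_FIRST_ZERO, abs=1e-9)
        r = 1.0
        qgrid = np.linspace(4.3, 4.7, 20001)
        p = sphere_form_factor(qgrid, r)
        assert qgrid[np.argmin(p)] == pytest.approx(x_zero, abs=1e-3)

    def test_first_minimum_position_for_micron_sphere(self):
        # R = 1015 nm puts the first minimum near 4.43e-3 nm^-1
        q = np.linspace(3e-3, 6e-3, 30001)
        p = sphere_form_factor(q, 1015.0)
        q_min = q[np.argmin(p)]
        assert q_min == pytest.approx(SPHERE_FIRST_ZERO / 1015.0, rel=1e-4)
        assert q_min == pytest.approx(4.43e-3, rel=1e-2)


class TestPolydisperseSphere:
    def test_monodisperse_limit(self):
        q = np.geomspace(1e-3, 5e-2, 50)
        m = SphereModel(mean_radius=500.0, radius_std=0.0, scale=2.0,
                        background=0.1)
        out = polydisperse_sphere_intensity(q, m)
        np.testing.assert_allclose(
            out, 2.0 * sphere_form_factor(q, 500.0) + 0.1, rtol=1e-12
        )

    def test_minima_fill_in_with_polydispersity(self):
        q_min = SPHERE_FIRST_ZERO / 1015.0
        depths = [
            polydisperse_sphere_intensity(
                np.array([q_min]), SphereModel(1015.0, s))[0]
            for s in (0.0, 3.0, 7.0, 14.0)
        ]
        assert np.all(np.diff(depths) > 0)

    def test_quadrature_matches_riemann_oracle(self):
        q = np.geomspace(1e-3, 3e-2, 40)
        m = SphereModel(mean_radius=1015.0, radius_std=7.0)
        out = polydisperse_sphere_intensity(q, m)
        # brute-force Riemann sum over the same truncated Gaussian
        radii = np.linspace(1015.0 - 35.0, 1015.0 + 35.0, 100_001)
        dens = np.exp(-0.5 * ((radii - 1015.0) / 7.0) ** 2)
        w = dens * radii**6
        oracle = np.array([
            np.sum(w * ((3 * (np.sin(qi * radii) - qi * radii * np.cos(qi * radii))
                         / (qi * radii) ** 3) ** 2)) / np.sum(w)
            for qi in q
        ])
        np.testing.assert_allclose(out, oracle, rtol=1e-6)

    def test_quadrature_order_refinement_invariant(self):
        q = np.geomspace(1e-3, 3e-2, 30)
        m = SphereModel(mean_radius=1015.0, radius_std=7.0)
        a = polydisperse_sphere_intensity(q, m, n_nodes=61)
        b = polydisperse_sphere_intensity(q, m, n_nodes=121)
        np.testing.assert_allclose(a, b, rtol=1e-5)

    def test_high_polydispersity_warns(self):
        with pytest.warns(UserWarning, match="polydispersity"):
            polydisperse_sphere_intensity(
                np.array([1e-3]), SphereModel(100.0, 40.0))

    def test_nonnegative_and_finite_over_working_range(self):
        q = np.geomspace(1e-4, 1.0, 200)
        out = polydisperse_sphere_intensity(q, SphereModel(1015.0, 7.0))
        assert np.all(np.isfinite(out)) and np.all(out >= 0)


class TestHollowCylinder:
    def test_forward_amplitude_is_one(self):
        assert annulus_amplitude(np.array([0.0]), 600.0, 500.0)[0] == pytest.approx(1.0)

    def test_filled_rod_reduces_to_solid_disc(self):
        q = np.geomspace(1e-4, 5e-2, 50)
        a_rod = annulus_amplitude(q, 600.0, 1e-9)
        disc = annulus_amplitude(q, 600.0, 0.0)
        np.testing.assert_allclose(a_rod, disc, rtol=1e-10, atol=1e-12)

    def test_nested_quadrature_matches_riemann_oracle(self):
        q = np.geomspace(2e-3, 2e-2, 25)
        m = TubeModel(mean_radius=585.0, wall_thickness=74.0,
                      radius_polydispersity=0.08, thickness_polydispersity=0.6)
        out = hollow_cylinder_intensity(q, m)
        # 2D Riemann oracle over (R_C, t_W) on the same truncated Gaussians
        sig_r, sig_t = 0.08 * 585.0, 0.6 * 74.0
        rc = np.linspace(585.0 - 5 * sig_r, 585.0 + 5 * sig_r, 801)
        tw = np.linspace(1e-3 * 74.0, 74.0 + 5 * sig_t, 801)
        wr = np.exp(-0.5 * ((rc - 585.0) / sig_r) ** 2)
        wt = np.exp(-0.5 * ((tw - 74.0) / sig_t) ** 2)
        num = np.zeros_like(q)
        den = 0.0
        for r, wri in zip(rc, wr):
            ro, ri = r + tw / 2, r - tw / 2
            ok = ri > 0
            for j in np.nonzero(ok)[0]:
                area2 = (ro[j] ** 2 - ri[j] ** 2) ** 2
                w = wri * wt[j] * area2
                a = annulus_amplitude(q, ro[j], ri[j])
                num += w * a * a
                den += w
        oracle = num / (den * q)
        np.testing.assert_allclose(out, oracle, rtol=1e-5)

    def test_geometry_error_when_wall_exceeds_diameter(self):
        with pytest.raises(ValueError):
            TubeModel(mean_radius=30.0, wall_thickness=80.0)

    def test_nonnegative_finite(self):
        q = np.geomspace(1e-4, 1.0, 100)
        m = TubeModel(585.0, 74.0, 0.08, 0.6)
        out = hollow_cylinder_intensity(q, m)
        assert np.all(np.isfinite(out)) and np.all(out >= 0)


class TestSmearing:
    def test_zero_width_is_identity(self):
        q = np.geomspace(1e-3, 1e-2, 50)
        fn = lambda qq: np.exp(-qq * 100)  # noqa: E731
        np.testing.assert_array_equal(smeared_model(fn, q, 0.0), fn(q))

    def test_narrow_triangle_becomes_gaussian_of_kernel_fwhm(self):
        q0, fwhm = 5e-3, 2.4e-4
        half = 6e-5  # narrow against the kernel, wide against the fine grid

        def triangle(qq):
            return np.maximum(1.0 - np.abs(qq - q0) / half, 0.0)

        q = np.linspace(q0 - 15 * fwhm, q0 + 15 * fwhm, 4001)
        # oversample so the narrow input feature is well resolved internally
        sm = smeared_model(triangle, q, fwhm, oversample=16)
        top = sm.max()
        above = q[sm >= top / 2]
        measured_fwhm = above[-1] - above[0]
        assert measured_fwhm == pytest.approx(fwhm, rel=0.05)
        assert q[np.argmax(sm)] == pytest.approx(q0, abs=5e-6)

    def test_integral_conserved_for_interior_peak(self):
        q0, fwhm = 5e-3, 2.4e-4
        sigma_peak = 2e-4

        def gauss(qq):
            return np.exp(-0.5 * ((qq - q0) / sigma_peak) ** 2)

        q = np.linspace(q0 - 20 * fwhm, q0 + 20 * fwhm, 8001)
        sm = smeared_model(gauss, q, fwhm)
        before = np.trapezoid(gauss(q), q)
        after = np.trapezoid(sm, q)
        assert after == pytest.approx(before, rel=1e-8)

    def test_tabulated_profile_warns_when_underresolved(self):
        prof = RadialProfile(q=np.linspace(1e-3, 1e-2, 10),
                             intensity=np.ones(10))
        with pytest.warns(UserWarning, match="smearing skipped"):
            out = smear_resolution(prof, 2.4e-4)
        np.testing.assert_array_equal(out.intensity, prof.intensity)


class TestLattice:
    def test_first_order_peak_position(self):
        # d = 2.3 um -> q1 = 2pi/2300 nm = 2.7318e-3 nm^-1
        m = LatticeModel(period=2.3)
        q = np.linspace(1e-3, 2e-2, 4000)
        i = lattice_peak_pattern(q, m)
        q1_expected = 2 * np.pi / 2300.0
        assert q1_expected == pytest.approx(2.7318e-3, rel=1e-4)
        assert q[np.argmax(i * (q < 4e-3))] == pytest.approx(q1_expected, abs=5e-6)

    def test_equidistant_orders(self):
        m = LatticeModel(period=1.0, n_orders=4)
        q = np.linspace(2e-3, 3e-2, 20000)
        i = lattice_peak_pattern(q, m)
        from scipy.signal import find_peaks
        idx, _ = find_peaks(i, height=0.5)
        spacings = np.diff(q[idx])
        np.testing.assert_allclose(spacings, 2 * np.pi / 1000.0, rtol=1e-3)

    def test_roundtrip_through_peak_spacing(self):
        m = LatticeModel(period=1.0, n_orders=3)
        q = np.linspace(2e-3, 2.2e-2, 8000)
        prof = RadialProfile(q=q, intensity=lattice_peak_pattern(q, m))
        assert peak_spacing(prof) == pytest.approx(1.0, rel=5e-3)

    def test_flat_profile_raises(self):
        prof = RadialProfile(q=np.linspace(1e-3, 1e-2, 100),
                             intensity=np.ones(100))
        with pytest.raises(NoPeakError):
            peak_spacing(prof)

    def test_single_gaussian_inverts_to_sarcomere_length(self):
        q = np.linspace(1e-3, 1e-2, 6000)
        q1 = 2.7318e-3
        sigma = 2.4e-4 * FWHM_TO_SIGMA
        prof = RadialProfile(q=q, intensity=np.exp(-0.5 * ((q - q1) / sigma) ** 2))
        assert peak_spacing(prof) == pytest.approx(2.3, rel=1e-3)
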