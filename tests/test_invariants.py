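import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from supertoroid.invariants import (
    compute_map,
    fractional_anisotropy,
    gaussian_curvature_profile,
    mean_diffusivity,
    normalize_map,
    toroid_params,
    toroidal_curvature,
    toroidal_volume,
    ScalarMap,
)
from supertoroid.tensor_model import TensorField

from conftest import random_sorted_eigenvalues


def numerical_gaussian_curvature(a, b, c, theta, phi, h=1e-5):
    """Independent oracle: K from first/second fundamental forms of the
    toroidal surface, derivatives by central differences.  Evaluated in
    extended precision so roundoff does not swamp the small step size."""
    a, b, c = np.longdouble(a), np.longdouble(b), np.longdouble(c)
    theta, phi, h = np.longdouble(theta), np.longdouble(phi), np.longdouble(h)

    def surf(t, p):
        r = a + b * np.cos(p)
        return np.array([np.cos(t) * r, np.sin(t) * r, c * np.sin(p)])

    Xu = (surf(theta + h, phi) - surf(theta - h, phi)) / (2 * h)
    Xv = (surf(theta, phi + h) - surf(theta, phi - h)) / (2 * h)
    Xuu = (surf(theta + h, phi) - 2 * surf(theta, phi) + surf(theta - h, phi)) / h**2
    Xvv = (surf(theta, phi + h) - 2 * surf(theta, phi) + surf(theta, phi - h)) / h**2
    Xuv = (
        surf(theta + h, phi + h)
        - surf(theta + h, phi - h)
        - surf(theta - h, phi + h)
        + surf(theta - h, phi - h)
    ) / (4 * h * h)
    n = np.cross(Xu, Xv)
    n /= np.linalg.norm(n)
    E, F, G = Xu @ Xu, Xu @ Xv, Xv @ Xv
    L, M, N = Xuu @ n, Xuv @ n, Xvv @ n
    return (L * N - M * M) / (E * G - F * F)


class TestDiffusivity:
    def test_mean_diffusivity_examples(self):
        assert mean_diffusivity(np.array([3e-3, 2e-3, 1e-3])) == pytest.approx(2e-3)
        assert mean_diffusivity(np.array([1.3e-3] * 3)) == pytest.approx(1.3e-3)
        assert mean_diffusivity(np.array([1.7e-3, 4e-4, 4e-4])) == pytest.approx(
            8.333333333e-4, abs=1e-9
        )

    @pytest.mark.parametrize(
        "lam,expected",
        [
            ((1.0, 1.0, 1.0), np.pi / 2),
            ((1.0, 0.7, 0.0), 0.0),
            ((2.0, 0.5, 0.0), 0.0),
            ((2e-3, 1e-3, 5e-4), (2e-3 * np.pi / 3) * (5e-7 + 1.25e-7)),
        ],
    )
    def test_toroidal_volume_examples(self, lam, expected):
        assert toroidal_volume(np.array(lam)) == pytest.approx(expected, rel=1e-12)

    def test_tv_nonlinear_md_affine_along_linear_path(self):
        """Along lam(t) = (1+t)*(1,1,1) the MD response is affine (zero second
        differences) while TV bends — the toroid volume is cubic in scale."""
        t = np.linspace(0.0, 1.0, 11)
        lam = (1 + t)[:, None] * np.ones(3) * 1e-3
        md = mean_diffusivity(lam)
        tv = toroidal_volume(lam)
        assert np.abs(np.diff(md, 2)).max() < 1e-12 * md.max()
        assert np.abs(np.diff(tv, 2)).min() > 1e-3 * tv.max() / len(t) ** 2

    def test_tv_and_fa_ranges_on_random_triples(self):
        rng = np.random.default_rng(11)
        lam = random_sorted_eigenvalues(rng, 100_000)
        assert toroidal_volume(lam).min() >= 0.0
        fa = fractional_anisotropy(lam)
        assert fa.min() >= 0.0 and fa.max() <= 1.0


class TestAnisotropy:
    @pytest.mark.parametrize(
        "lam,expected",
        [
            ((1.0, 1.0, 1.0), 0.0),
            ((1.0, 0.0, 0.0), 1.0),
            ((3.0, 2.0, 1.0), np.sqrt(3.0 / 14.0)),
        ],
    )
    def test_fa_examples(self, lam, expected):
        assert fractional_anisotropy(np.array(lam)) == pytest.approx(expected, abs=1e-12)

    def test_fa_zero_tensor_convention(self):
        assert fractional_anisotropy(np.zeros(3)) == 0.0


class TestToroidParams:
    @pytest.mark.parametrize(
        "lam,expected",
        [
            ((1.0, 1.0, 1.0), (0.75, 0.25, 0.5)),
            ((1.0, 0.0, 0.0), (0.0, 0.0, 0.5)),
            ((2e-3, 1e-3, 1e-3), (7.5e-4, 2.5e-4, 1e-3)),
        ],
    )
    def test_examples(self, lam, expected):
        p = toroid_params(np.array(lam))
        assert (p.alpha, p.beta, p.gamma) == pytest.approx(expected, rel=1e-14)

    def test_normalized_invariants(self):
        rng = np.random.default_rng(2)
        lam = random_sorted_eigenvalues(rng, 1000)
        lam = lam[lam[:, 0] > 0]
        p = toroid_params(lam)
        assert np.all(p.gamma_p == 0.5)
        assert np.all((p.beta_p >= 0) & (p.beta_p <= 0.25 + 1e-15))
        assert np.all(p.beta_p <= p.alpha_p + 1e-15)

    def test_degenerate_flag(self):
        p = toroid_params(np.zeros(3))
        assert p.degenerate


class TestCurvatureProfile:
    def test_circular_torus_closed_form(self):
        """With beta' = gamma' the profile must reduce to the classical torus
        Gaussian curvature cos(phi) / (beta (alpha + beta cos(phi)))."""
        a, b = 3.0, 1.0
        phi = np.linspace(0.0, 2 * np.pi, 101)
        got = gaussian_curvature_profile(a, b, b, phi)
        want = np.cos(phi) / (b * (a + b * np.cos(phi)))
        assert np.allclose(got, want, rtol=1e-13, atol=1e-13)

    def test_isotropic_value_at_phi_zero(self):
        assert gaussian_curvature_profile(0.75, 0.25, 0.5, 0.0) == pytest.approx(1.0)

    def test_zero_at_equator(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            l2 = rng.uniform(0.1, 1.0)
            l3 = rng.uniform(0.05, l2)
            p = toroid_params(np.array([1.0, l2, l3]))
            # numerator carries cos(phi); cos(pi/2) is ~6e-17 in floating point
            assert abs(
                gaussian_curvature_profile(p.alpha_p, p.beta_p, p.gamma_p, np.pi / 2)
            ) < 1e-9

    def test_matches_fundamental_forms_oracle(self):
        """Closed-form profile vs numerical curvature of the actual surface,
        >= 50 eigenvalue configurations x 64 angles, 1e-5 relative."""
        rng = np.random.default_rng(4)
        phis = np.linspace(0.0, np.pi, 64)
        worst = 0.0
        for _ in range(50):
            l2 = rng.uniform(0.05, 1.0)
            l3 = rng.uniform(0.01, l2)
            p = toroid_params(np.array([1.0, l2, l3]))
            got = gaussian_curvature_profile(p.alpha_p, p.beta_p, p.gamma_p, phis)
            for phi, g in zip(phis, got):
                k = numerical_gaussian_curvature(p.alpha_p, p.beta_p, 0.5, 0.9, phi)
                worst = max(worst, abs(g - k) / max(abs(k), 1e-9))
        assert worst < 1e-5

    def test_singular_geometry_raises(self):
        with pytest.raises(ValueError):
            gaussian_curvature_profile(0.5, 1.0, 0.5, np.pi)


class TestToroidalCurvature:
    def test_continuity_near_isotropy(self):
        tc_a = toroidal_curvature(np.array([1.0, 0.999999, 0.999999]))
        tc_b = toroidal_curvature(np.array([1.0, 1.0, 1.0]))
        assert tc_a == pytest.approx(tc_b, rel=1e-4)

    @settings(deadline=None, max_examples=25)
    @given(
        l2=st.floats(0.05, 1.0),
        l3frac=st.floats(0.05, 1.0),
        c=st.floats(1e-3, 1e3),
    )
    def test_scale_invariance(self, l2, l3frac, c):
        lam = np.array([1.0, l2, l2 * l3frac])
        assert toroidal_curvature(c * lam) == pytest.approx(
            toroidal_curvature(lam), rel=1e-9
        )

    def test_isotropic_maximum_is_interior(self):
        """For the ordinary torus the bracket term grows with cos^2(phi)
        (gamma' > beta'), pushing the curvature maximum off phi = 0."""
        lam = np.array([1.0, 1.0, 1.0])
        p = toroid_params(lam)
        tc = toroidal_curvature(lam)
        tc0 = gaussian_curvature_profile(p.alpha_p, p.beta_p, p.gamma_p, 0.0)
        assert tc > tc0
        # dense-grid oracle for the maximum itself
        phi = np.linspace(0.0, np.pi, 200_001)
        grid_max = gaussian_curvature_profile(p.alpha_p, p.beta_p, p.gamma_p, phi).max()
        assert tc == pytest.approx(grid_max, rel=1e-8)
        assert tc >= grid_max - 1e-12  # refinement never loses to the grid

    def test_strictly_increasing_from_isotropy_to_anisotropy(self):
        t = np.arange(1.0, 0.049, -0.05)
        tcs = np.array([toroidal_curvature(np.array([1.0, ti, ti])) for ti in t])
        assert np.all(np.diff(tcs) > 0)

    def test_degenerate_lambda1_zero(self):
        assert toroidal_curvature(np.zeros(3)) == 0.0


class TestMaps:
    def test_constant_isotropic_field(self):
        d = 1e-3
        D = np.zeros((4, 4, 2, 6))
        D[..., [0, 3, 5]] = d
        fld = TensorField(D=D)
        md = compute_map(fld, "MD")
        fa = compute_map(fld, "FA")
        assert np.allclose(md.values, d)
        assert np.allclose(fa.values, 0.0)

    def test_two_region_phantom_matches_per_voxel_calls(self):
        lam_wm = np.array([1.7e-3, 4e-4, 3e-4])
        lam_csf = np.array([3e-3, 2.9e-3, 2.9e-3])
        D = np.zeros((2, 1, 1, 6))
        D[0, 0, 0, [0, 3, 5]] = lam_wm
        D[1, 0, 0, [0, 3, 5]] = lam_csf
        fld = TensorField(D=D)
        for which, fn in [
            ("MD", mean_diffusivity),
            ("FA", fractional_anisotropy),
            ("TV", toroidal_volume),
            ("TC", toroidal_curvature),
        ]:
            m = compute_map(fld, which)
            assert m.values[0, 0, 0] == pytest.approx(fn(lam_wm), rel=1e-9)
            assert m.values[1, 0, 0] == pytest.approx(fn(lam_csf), rel=1e-9)
        md = compute_map(fld, "MD")
        fa = compute_map(fld, "FA")
        assert md.values[1, 0, 0] > md.values[0, 0, 0]
        assert fa.values[0, 0, 0] > fa.values[1, 0, 0]

    def test_masked_voxels_excluded_and_nan_free(self):
        D = np.zeros((2, 1, 1, 6))
        D[..., [0, 3, 5]] = 1e-3
        mask = np.array([True, False]).reshape(2, 1, 1)
        m = compute_map(TensorField(D=D, mask=mask), "TV")
        assert np.all(np.isfinite(m.values))
        assert not m.mask[1, 0, 0]

    def test_unknown_invariant_name(self):
        fld = TensorField(D=np.zeros((1, 1, 1, 6)))
        with pytest.raises(ValueError, match="unknown invariant"):
            compute_map(fld, "RA")


class TestNormalizeMap:
    def test_min_max_rescale(self):
        m = ScalarMap(values=np.array([2.0, 4.0, 6.0]).reshape(3, 1, 1))
        out = normalize_map(m)
        assert np.allclose(out.values.ravel(), [0.0, 0.5, 1.0])

    def test_constant_map_goes_to_zero(self):
        m = ScalarMap(values=np.full((3, 1, 1), 7.0))
        assert np.all(normalize_map(m).values == 0.0)

    def test_argmax_voxel_is_one(self, small_phantom):
        fld, _ = small_phantom
        tvn = normalize_map(compute_map(fld, "TV"))
        assert tvn.values[tvn.mask].max() == pytest.approx(1.0)
        assert tvn.values[tvn.mask].min() == pytest.approx(0.0)

    def test_empty_mask_errors(self):
        m = ScalarMap(values=np.zeros((2, 2, 1)), mask=np.zeros((2, 2, 1), dtype=bool))
        with pytest.raises(ValueError):
            normalize_map(m)


def test_toroid_mesh_volume_matches_analytic():
    """Divergence-theorem volume of a dense toroid mesh equals 2 pi^2 a b g to
    0.1%; its ratio to the printed TV formula is the constant 3 pi / 8."""
    from supertoroid.glyphs import tessellate, toroid_surface

    lam = np.array([1.5e-3, 1.0e-3, 0.5e-3])
    p = toroid_params(lam)
    mesh = tessellate(toroid_surface(lam, 256, 256)).trimesh
    analytic = 2 * np.pi**2 * p.alpha * p.beta * p.gamma
    assert mesh.volume == pytest.approx(analytic, rel=1e-3)
    ratio = analytic / toroidal_volume(lam)
    assert ratio == pytest.approx(3 * np.pi / 8, rel=1e-12)
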