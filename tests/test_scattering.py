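import numpy as np
import pytest

from absasfit.coarse_grain import SphereModel
from absasfit.scattering import (
    ScatteringCurve, baseline_subtract, cross_section_fit, debye_curve,
    guinier_fit, match_q, p_of_r, r_factor, read_curve, sphere_form_factor,
)


def sphere_model(centers, cube_side=0.5):
    return SphereModel(centers=np.atleast_2d(centers), cube_side=cube_side)


class TestReadCurve:
    def test_angstrom_conversion_and_sigma(self, tmp_path):
        p = tmp_path / "c.dat"
        rows = ["# comment", "0.015 100.0 1.0", "0.025 80.0 1.1",
                "0.035 60.0 1.2", "0.045 40.0 1.3", "0.055 30.0 1.4"]
        p.write_text("\n".join(rows))
        c = read_curve(str(p), q_units="A^-1")
        assert c.q[0] == pytest.approx(0.15)
        assert c.sigma is not None and c.sigma[0] == pytest.approx(1.0)

    def test_shuffled_rows_sorted(self, tmp_path):
        p = tmp_path / "c.dat"
        p.write_text("0.5 10\n0.1 50\n0.3 30\n0.2 40\n0.4 20\n")
        c = read_curve(str(p))
        assert np.all(np.diff(c.q) > 0)
        assert c.i[0] == 50

    def test_too_few_points(self, tmp_path):
        p = tmp_path / "c.dat"
        p.write_text("0.1 1\n0.2 2\n")
        with pytest.raises(ValueError, match="fewer than 5"):
            read_curve(str(p))


class TestBaseline:
    def _curve(self):
        q = np.linspace(0.01, 1.5, 100)
        return ScatteringCurve(q=q, i=100.0 * np.exp(-(5.0 ** 2 / 3) * q ** 2))

    def test_zero_fraction_identity(self):
        c = self._curve()
        out = baseline_subtract(c, 0.0, i0=100.0)
        np.testing.assert_array_equal(out.i, c.i)

    def test_printed_fraction(self):
        # 2.09% of I(0)=100 -> constant 2.09 subtracted everywhere
        c = self._curve()
        out = baseline_subtract(c, 0.0209, i0=100.0)
        np.testing.assert_allclose(c.i - out.i, 2.09, rtol=1e-12)

    def test_subtract_then_readd(self):
        c = self._curve()
        out = baseline_subtract(c, 0.013, i0=100.0)
        np.testing.assert_allclose(out.i + 1.3, c.i, atol=1e-12)


class TestDebye:
    def test_single_sphere_matches_closed_form(self):
        s = sphere_model([[0, 0, 0]], cube_side=0.6)
        q = np.linspace(0.05, 3.0, 120)
        c = debye_curve(s, q, method="exact")
        x = q * s.radius
        analytic = (3 * (np.sin(x) - x * np.cos(x)) / x ** 3) ** 2
        np.testing.assert_allclose(c.i, analytic, rtol=1e-6)

    def test_two_point_limit(self):
        d = 3.0
        s = sphere_model([[0, 0, 0], [d, 0, 0]], cube_side=0.01)
        q = np.linspace(0.05, 2.0, 80)
        c = debye_curve(s, q, method="exact")
        limit = (1 + np.sin(q * d) / (q * d)) / 2
        np.testing.assert_allclose(c.i / c.i.max() * limit.max(), limit,
                                   rtol=1e-4)

    def test_binned_matches_exact(self):
        rng = np.random.default_rng(1)
        s = sphere_model(rng.uniform(0, 6, size=(200, 3)), cube_side=0.5)
        q = np.linspace(0.05, 1.5, 100)
        exact = debye_curve(s, q, method="exact")
        binned = debye_curve(s, q, method="binned")
        np.testing.assert_allclose(binned.i, exact.i, rtol=5e-3)


class TestGuinier:
    def test_exact_line(self):
        q = np.linspace(0.05, 0.3, 60)
        c = ScatteringCurve(q=q, i=100.0 * np.exp(-(5.2 ** 2 / 3) * q ** 2))
        g = guinier_fit(c, (0.05, 0.28))
        assert g.rg == pytest.approx(5.2, rel=1e-9)
        assert g.i0 == pytest.approx(100.0, rel=1e-9)

    def test_solid_sphere_rg(self):
        # analytic sphere curve; fit restricted to Q*Rg <= 1
        R = 3.0
        rg_true = R * np.sqrt(3.0 / 5.0)
        q = np.linspace(0.01, 0.9 / rg_true, 80)
        c = ScatteringCurve(q=q, i=sphere_form_factor(q, R) ** 2)
        g = guinier_fit(c, (q[0], q[-1]))
        assert g.rg == pytest.approx(rg_true, rel=0.01)

    def test_validity_warning(self):
        q = np.linspace(0.05, 1.0, 80)
        c = ScatteringCurve(q=q, i=np.exp(-(4.0 ** 2 / 3) * q ** 2))
        with pytest.warns(UserWarning, match="1.5"):
            guinier_fit(c, (0.05, 1.0))

    def test_positive_slope_rejected(self):
        q = np.linspace(0.05, 0.3, 30)
        c = ScatteringCurve(q=q, i=np.exp(+q ** 2))
        with pytest.raises(ValueError, match="slope"):
            guinier_fit(c, (0.05, 0.3))


class TestCrossSection:
    def test_exact_line(self):
        q = np.linspace(0.3, 0.5, 40)
        # ln(I*Q) = c - (2.5^2/2) Q^2
        i = np.exp(1.7 - (2.5 ** 2 / 2) * q ** 2) / q
        c = ScatteringCurve(q=q, i=i)
        res = cross_section_fit(c, (0.3, 0.5), which="xs1")
        assert res.rxs == pytest.approx(2.5, rel=1e-9)


class TestPofR:
    def test_two_point_mode(self):
        d = 3.0
        s = sphere_model([[0, 0, 0], [d, 0, 0]], cube_side=0.05)
        q = np.linspace(0.005, 12.0, 2400)
        c = debye_curve(s, q, method="exact")
        p = p_of_r(c, 5.0, n_r=251)           # grid step 0.02 nm
        assert abs(p.mode - d) <= 0.02 + 1e-12

    def test_solid_sphere_length(self):
        R = 3.0
        q = np.linspace(0.01, 8.0, 900)
        c = ScatteringCurve(q=q, i=sphere_form_factor(q, R) ** 2)
        p = p_of_r(c, 10.0, n_r=501)
        assert p.length == pytest.approx(2 * R, abs=0.15)
        assert p.rg_real == pytest.approx(R * np.sqrt(3 / 5), rel=0.03)

    def test_real_space_rg_consistent_with_guinier(self):
        rng = np.random.default_rng(3)
        s = sphere_model(rng.uniform(0, 5, size=(150, 3)), cube_side=0.5)
        q = np.linspace(0.01, 8.0, 900)
        c = debye_curve(s, q, method="binned")
        g = guinier_fit(c, (0.01, 0.3))
        p = p_of_r(c, 12.0, n_r=501)
        assert p.rg_real == pytest.approx(g.rg, rel=0.03)


class TestMatchQ:
    def _theor(self):
        q = np.arange(0.01, 2.0, 0.01)
        return ScatteringCurve(q=q, i=np.exp(-q))

    def test_tie_toward_lower_q(self):
        theor = ScatteringCurve(q=np.array([0.15, 0.16]), i=np.array([2.0, 1.0]))
        expt = ScatteringCurve(q=np.array([0.155]), i=np.array([1.5]))
        _, _, it = match_q(theor, expt)
        assert it[0] == 2.0    # 0.155 is equidistant; lower Q wins

    def test_identity_pairing(self):
        theor = self._theor()
        _, ie, it = match_q(theor, theor)
        np.testing.assert_array_equal(ie, it)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(6)
        qt = np.sort(rng.uniform(0.01, 2.0, 300))
        qt = np.unique(qt)
        qe = np.sort(rng.uniform(0.05, 1.9, 40))
        theor = ScatteringCurve(q=qt, i=np.exp(-qt))
        expt = ScatteringCurve(q=qe, i=np.exp(-qe))
        _, _, it = match_q(theor, expt)
        brute = theor.i[[np.argmin(np.abs(qt - q)) for q in qe]]
        np.testing.assert_array_equal(it, brute)


class TestRFactor:
    def _curve(self, scale=1.0):
        q = np.linspace(0.01, 1.5, 200)
        return ScatteringCurve(q=q, i=scale * 100 * np.exp(-(5 ** 2 / 3) * q ** 2))

    def test_self_fit_zero(self):
        c = self._curve()
        f = r_factor(c, c)
        assert f.r_factor == pytest.approx(0.0, abs=1e-4)
        assert f.eta == pytest.approx(1.0, rel=1e-4)

    def test_scale_invariance(self):
        c = self._curve()
        half = self._curve(scale=0.5)
        f = r_factor(c, half)
        assert f.r_factor == pytest.approx(0.0, abs=1e-4)
        assert f.eta == pytest.approx(2.0, rel=1e-4)

    def test_rescaling_theoretical_leaves_r_unchanged(self):
        rng = np.random.default_rng(2)
        c = self._curve()
        pert = ScatteringCurve(q=c.q, i=c.i * (1 + rng.normal(0, 0.05, len(c))))
        r1 = r_factor(c, pert).r_factor
        pert2 = ScatteringCurve(q=c.q, i=pert.i * 37.5)
        r2 = r_factor(c, pert2).r_factor
        assert r1 == pytest.approx(r2, abs=1e-6)

    def test_matches_grid_search_oracle(self):
        rng = np.random.default_rng(12)
        c = self._curve()
        pert = ScatteringCurve(q=c.q, i=c.i * (1 + rng.normal(0, 0.1, len(c))))
        f = r_factor(c, pert)
        sel = c.q <= f.q_max
        ie, it = c.i[sel], pert.i[sel]
        etas = np.linspace(f.eta * 0.8, f.eta * 1.2, 200_001)
        r_grid = (np.abs(ie[None, :] - etas[:, None] * it[None, :]).sum(axis=1)
                  / np.abs(ie).sum() * 100)
        assert f.r_factor == pytest.approx(r_grid.min(), abs=1e-4)
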