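"""Karplus torsions, rotamer populations, NOE distances, anomer ratios."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from halopyranose import nmr
from halopyranose.nmr import (CouplingSet, KarplusParams, NOEBuildup,
                              anomer_fraction, c5c6_forward,
                              c6o6_gauche_trans, fit_sigma,
                              haasnoot_altona_params, karplus_forward,
                              karplus_invert, noe_distance, rotamers_c5c6,
                              rotamers_c6o6)


class TestKarplusForward:
    def test_constant_term_only(self):
        p = KarplusParams(C0=7.0)
        assert np.allclose(karplus_forward([0, 60, 123, -90], p), 7.0)

    def test_phi_zero_sums_cosines(self):
        p = KarplusParams(C0=7.0, C1=-1.0, C2=5.0, C3=0.3, S1=2.0, S2=-1.0)
        assert karplus_forward(0.0, p) == pytest.approx(7.0 - 1.0 + 5.0 + 0.3)

    @settings(deadline=None, derandomize=True)
    @given(st.floats(-180, 180), st.integers(0, 10 ** 6))
    def test_matches_term_by_term_oracle(self, phi, seed):
        rng = np.random.default_rng(seed)
        c = rng.uniform(-8, 8, 6)
        p = KarplusParams(*c)
        rad = np.radians(phi)
        oracle = (c[0] + c[1] * np.cos(rad) + c[2] * np.cos(2 * rad)
                  + c[3] * np.cos(3 * rad) + c[4] * np.sin(rad)
                  + c[5] * np.sin(2 * rad))
        assert karplus_forward(phi, p) == pytest.approx(oracle, abs=1e-12)

    def test_ha_projection_is_exact(self):
        """The Fourier form reproduces the Haasnoot-Altona curve exactly."""
        lams, xis = (1.3, 1.4, 0.4), (1, -1, 1)
        p = haasnoot_altona_params(lams, xis)
        P1, P2, P3, P4, P5, P6 = 13.70, -0.73, 0.0, 0.56, -2.47, 16.9
        phi = np.linspace(-180, 180, 721)
        rad = np.radians(phi)
        direct = P1 * np.cos(rad) ** 2 + P2 * np.cos(rad) + P3
        for lam, xi in zip(lams, xis):
            direct += lam * (P4 + P5 * np.cos(xi * rad
                                              + np.radians(P6 * abs(lam))) ** 2)
        np.testing.assert_allclose(karplus_forward(phi, p), direct, atol=1e-10)


class TestKarplusInvert:
    def test_roundtrip(self):
        p = haasnoot_altona_params([1.3, 1.4], [1, -1])
        J = float(karplus_forward(53.0, p))
        roots = karplus_invert(J, p)
        assert np.min(np.abs(roots - 53.0)) < 0.01

    def test_unattainable_value_empty(self):
        p = KarplusParams(C0=7.0, C2=5.0)
        assert karplus_invert(100.0, p, tol=0.05).size == 0

    def test_symmetric_params_give_sign_pairs(self):
        p = KarplusParams(C0=6.85, C1=-0.73, C2=6.85)
        roots = karplus_invert(5.0, p)
        assert roots.size > 0 and roots.size % 2 == 0
        np.testing.assert_allclose(np.sort(np.abs(roots[roots < 0])),
                                   np.sort(roots[roots > 0]), atol=1e-6)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.floats(-170, 170), st.integers(0, 10 ** 6))
    def test_every_root_reproduces_j(self, phi, seed):
        rng = np.random.default_rng(seed)
        p = KarplusParams(*rng.uniform(-6, 6, 6))
        J = float(karplus_forward(phi, p))
        roots = karplus_invert(J, p)
        assert np.min(np.abs(roots - phi)) < 0.01
        for r in roots:
            assert karplus_forward(r, p) == pytest.approx(J, abs=1e-6)


class TestRotamersC5C6:
    @pytest.mark.parametrize("JR,JS,expect", [
        (9.9, 1.5, (1, 0, 0)),        # pure gt limiting values
        (0.8, 1.3, (0, 1, 0)),        # pure gg
        (4.5, 10.8, (0, 0, 1)),       # pure tg
        ((9.9 + 0.8 + 4.5) / 3, (1.5 + 1.3 + 10.8) / 3, (1 / 3,) * 3),
    ])
    def test_limiting_and_midpoint_values(self, JR, JS, expect):
        pops = rotamers_c5c6(JR, JS)
        assert (pops.A, pops.B, pops.C) == pytest.approx(expect, abs=1e-9)
        assert not pops.constrained

    def test_simplex_recovery_grid(self):
        """Forward then inverse is exact over the whole simplex."""
        for a in np.arange(0, 1.0001, 0.05):
            for b in np.arange(0, 1.0001 - a, 0.05):
                c = 1.0 - a - b
                JR, JS = c5c6_forward(a, b, c)
                pops = rotamers_c5c6(JR, JS)
                assert abs(pops.A - a) < 1e-9
                assert abs(pops.B - b) < 1e-9
                assert abs(pops.C - c) < 1e-9

    def test_out_of_simplex_reports_raw_and_constrained(self):
        pops = rotamers_c5c6(12.0, 0.2)   # outside the attainable triangle
        assert pops.constrained
        assert max(pops.raw) > 1 or min(pops.raw) < 0
        assert 0 <= pops.A <= 1 and 0 <= pops.B <= 1 and 0 <= pops.C <= 1
        assert pops.A + pops.B + pops.C == pytest.approx(1.0, abs=1e-9)

    def test_nan_input_raises(self):
        with pytest.raises(ValueError):
            rotamers_c5c6(float("nan"), 3.0)


class TestRotamersC6O6:
    def test_pure_gauche_limit(self):
        pops = rotamers_c6o6(12.7, 0.6, 0.4, 0.0)
        assert pops.D == pytest.approx(1.0, abs=1e-12)

    def test_pure_trans_limit(self):
        pops = rotamers_c6o6(9.7, 0.6, 0.4, 0.0)
        assert pops.E == pytest.approx(1.0, abs=1e-12)

    def test_linear_midpoint(self):
        pops = rotamers_c6o6((12.7 + 9.7) / 2, 0.5, 0.5, 0.0)
        assert pops.D == pytest.approx(0.5, abs=1e-12)

    def test_limiting_couplings_depend_on_tg(self):
        assert c6o6_gauche_trans(0, 0, 1) == pytest.approx((11.5, -8.5))

    def test_system_never_degenerate_on_simplex(self):
        # J_gauche - J_trans = 3(A+B) + 20C > 0 whenever A+B+C = 1, so the
        # gauche/trans split is always well conditioned for valid fractions
        for a in np.arange(0, 1.0001, 0.1):
            for b in np.arange(0, 1.0001 - a, 0.1):
                jg, jt = c6o6_gauche_trans(a, b, 1 - a - b)
                assert jg - jt > 2.9

    def test_inconsistent_fractions_raise(self):
        with pytest.raises(ValueError, match="A\\+B\\+C"):
            rotamers_c6o6(11.0, 0.5, 0.2, 0.2)


class TestNOE:
    def test_exact_line_slope(self):
        t = np.array([0.1, 0.2, 0.35, 0.5, 0.6, 0.75])
        b = fit_sigma(NOEBuildup(pair=("H1", "H2"), mixing_times=t,
                                 intensities=0.4 * t))
        assert b.sigma == pytest.approx(0.4, abs=1e-12)

    def test_constant_intensity_zero_slope(self):
        t = np.array([0.1, 0.2, 0.35, 0.5])
        b = fit_sigma(NOEBuildup(pair=("a", "b"), mixing_times=t,
                                 intensities=np.full(4, 0.7)))
        assert b.sigma == pytest.approx(0.0, abs=1e-15)

    def test_noisy_slope_within_three_se(self):
        rng = np.random.default_rng(5)
        t = np.linspace(0.1, 0.75, 6)
        y = 0.25 * t + rng.normal(0, 0.005, t.size)
        b = fit_sigma(NOEBuildup(pair=("a", "b"), mixing_times=t,
                                 intensities=y))
        assert abs(b.sigma - 0.25) < 3 * b.sigma_se

    def test_matches_closed_form_ols(self):
        rng = np.random.default_rng(9)
        t = np.linspace(0.1, 0.75, 6)
        y = rng.normal(size=6)
        b = fit_sigma(NOEBuildup(pair=("a", "b"), mixing_times=t,
                                 intensities=y))
        slope = ((t - t.mean()) @ (y - y.mean())) / ((t - t.mean()) ** 2).sum()
        assert b.sigma == pytest.approx(slope, abs=1e-12)

    def test_too_few_points_raise(self):
        with pytest.raises(ValueError):
            fit_sigma(NOEBuildup(pair=("a", "b"), mixing_times=[0.1, 0.2],
                                 intensities=[1, 2]))

    def test_reference_distance(self):
        assert noe_distance(0.05, 0.05) == pytest.approx(1.77)

    def test_factor_64_halves_distance(self):
        assert noe_distance(64 * 0.03, 0.03) == pytest.approx(1.77 / 2)

    def test_monotone_in_sigma(self):
        rs = [noe_distance(s, 0.05) for s in np.linspace(0.01, 0.2, 25)]
        assert np.all(np.diff(rs) < 0)

    def test_inverse_identity(self):
        r = 2.43
        sigma = 0.05 * (r / 1.77) ** -6
        assert noe_distance(sigma, 0.05) == pytest.approx(r, abs=1e-12)

    def test_nonpositive_rate_raises(self):
        with pytest.raises(ValueError):
            noe_distance(-0.1, 0.05)


class TestAnomerFraction:
    def test_values(self):
        assert anomer_fraction(1.0, 1.0) == pytest.approx(0.5)
        assert anomer_fraction(0.49, 0.51) == pytest.approx(0.49)
        assert anomer_fraction(0.0, 1.0) == 0.0

    def test_both_zero_raises(self):
        with pytest.raises(ValueError):
            anomer_fraction(0.0, 0.0)


class TestCouplingSet:
    def test_sanity_bound(self):
        with pytest.raises(ValueError):
            CouplingSet(ring={"H1H2": 35.0})
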