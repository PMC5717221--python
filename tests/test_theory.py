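import math

import numpy as np
import pytest

import lgca_walks as lw


class TestVacfForms:
    def test_persistent_closed_form(self, cs4, scales16):
        # g(t) = exp(alpha t) with alpha = ln(lambda_1) / tau
        t = np.array([scales16.tau, 2 * scales16.tau, 1.0])
        curve = lw.vacf_persistent(t, 5.0, cs4, scales16)
        lam = math.tanh(2.5)
        expected = lam ** (t / scales16.tau)
        assert np.allclose(curve.values, expected, rtol=1e-12)
        # frozen value at k = 64 steps
        assert lam**64 == pytest.approx(0.422118, abs=5e-6)

    def test_generalized_vacf_is_tanh(self, cs4):
        spec = lw.VacfSpec(family="power_law", C0=0.5, Delta=0.016, phi=1.0)
        t = np.array([0.016, 0.16])
        curve = lw.vacf_generalized(t, spec, cs4.d)
        assert curve.values[0] == pytest.approx(math.tanh(0.5), rel=1e-12)
        assert curve.values[1] == pytest.approx(math.tanh(0.05), rel=1e-12)

    def test_target_vacf_undefined_below_crossover(self):
        spec = lw.VacfSpec(family="power_law", C0=0.5, Delta=0.016, phi=1.0)
        with pytest.raises(lw.ParameterError):
            lw.evaluate_target_vacf(spec, np.array([0.001]))

    def test_generalized_tail_exponent(self):
        # long-time effective exponent 2 C0 phi / sinh(2 C0)
        assert lw.generalized_tail_exponent(0.5, 0.1) == pytest.approx(
            2 * 0.5 * 0.1 / math.sinh(1.0), rel=1e-12
        )
        # C0 -> 0 limit is phi itself
        assert lw.generalized_tail_exponent(0.0, 0.7) == pytest.approx(0.7)
        assert lw.generalized_tail_exponent(1e-9, 0.7) == pytest.approx(0.7, rel=1e-6)


class TestMsdClassical:
    def test_linear(self, scales16):
        t = np.array([0.0, 1.0, 2.0])
        curve = lw.msd_classical(t, scales16)
        assert np.allclose(curve.values, 2 * 2 * 1.0 * t)

    def test_matches_discrete_step_values(self, scales16):
        # MSD(k tau) = eps^2 k for uncorrelated steps
        k = np.arange(1, 10)
        curve = lw.msd_classical(k * scales16.tau, scales16)
        assert np.allclose(curve.values, scales16.epsilon**2 * k, rtol=1e-12)


class TestMsdPersistent:
    def test_discrete_hand_value_k2(self, cs4, scales16):
        # MSD(2) = eps^2 [2 + 2 lambda] with lambda = tanh(2.5)
        expected = scales16.epsilon**2 * (2 + 2 * math.tanh(2.5))
        got = float(lw.msd_persistent_discrete(2, 5.0, cs4, scales16))
        assert got == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.2483268, abs=5e-7)

    def test_discrete_matches_brute_force(self, cs4, scales16):
        lam = math.tanh(2.5)
        eps = scales16.epsilon
        for k in (1, 2, 5, 20, 100):
            brute = eps**2 * (k + 2 * sum((k - m) * lam**m for m in range(1, k)))
            got = float(lw.msd_persistent_discrete(k, 5.0, cs4, scales16))
            assert got == pytest.approx(brute, rel=1e-12)

    def test_continuum_matches_quadrature(self, cs4, scales16):
        lam = math.tanh(2.5)
        alpha = scales16.v**2 * math.log(lam) / (2 * 2 * scales16.D_rw)
        g = lambda s: math.exp(alpha * s)
        t = np.geomspace(0.01, 5.0, 8)
        closed = lw.msd_persistent(t, 5.0, cs4, scales16).values
        oracle = np.array(
            [lw.msd_numeric_oracle(g, ti, scales16, form="stationary") for ti in t]
        )
        assert np.allclose(closed, oracle, rtol=1e-6)

    def test_long_time_diffusive(self, cs4, scales16):
        # slope of MSD at late times -> enhanced diffusion constant > 2 d D
        t = np.array([100.0, 110.0])
        y = lw.msd_persistent(t, 5.0, cs4, scales16).values
        slope = (y[1] - y[0]) / 10.0
        assert slope > 2 * 2 * 1.0


class TestMsdTimeCorrelated:
    @pytest.mark.parametrize("phi", [0.25, 0.5, 0.8, 1.0, 1.3])
    def test_closed_form_matches_nested_quadrature(self, scales16, phi):
        spec = lw.VacfSpec(family="power_law", C0=0.5, Delta=0.016, phi=phi)
        t = np.geomspace(0.016, 50.0, 6)
        closed = lw.msd_tc(t, spec, scales16).values
        oracle = np.array(
            [
                lw.msd_numeric_oracle(
                    spec.g, ti, scales16, lower_limit=spec.Delta, form="independent"
                )
                for ti in t
            ]
        )
        assert np.allclose(closed, oracle, rtol=1e-6)

    def test_phi_continuity_at_special_cases(self, scales16):
        # the generic expression must limit onto the phi = 1/2 and phi = 1 branches
        t = np.geomspace(0.016, 100.0, 10)
        for phi0 in (0.5, 1.0):
            base = lw.msd_tc(
                t, lw.VacfSpec(family="power_law", C0=0.5, Delta=0.016, phi=phi0),
                scales16,
            ).values
            # inside the snap neighborhood: exactly the special branch
            near = lw.msd_tc(
                t,
                lw.VacfSpec(family="power_law", C0=0.5, Delta=0.016, phi=phi0 + 1e-7),
                scales16,
            ).values
            assert np.array_equal(near, base)
            # outside it: the generic branch must approach the special one
            for dphi in (1e-4, -1e-4):
                near = lw.msd_tc(
                    t,
                    lw.VacfSpec(
                        family="power_law", C0=0.5, Delta=0.016, phi=phi0 + dphi
                    ),
                    scales16,
                ).values
                assert np.allclose(near, base, rtol=5e-3)

    def test_piecewise_ballistic_form(self, scales16):
        # t <= t*: pure ballistic (v t)^2; beyond: power-law tail attached
        spec = lw.VacfSpec(family="piecewise_ballistic", C0=0.5, Delta=0.5, phi=1.0)
        ts = spec.t_star
        t = np.array([0.1, 0.25])
        vals = lw.msd_tc(t, spec, scales16).values
        assert vals[0] == pytest.approx((scales16.v * 0.1) ** 2, rel=1e-12)
        assert vals[1] == pytest.approx((scales16.v * ts) ** 2, rel=1e-12)
        # continuity across t*
        after = lw.msd_tc(np.array([ts * (1 + 1e-9)]), spec, scales16).values[0]
        assert after == pytest.approx((scales16.v * ts) ** 2, rel=1e-6)

    def test_piecewise_matches_quadrature(self, scales16):
        # the tail integrals I1 = int g, I2 = int g^2 from t* are evaluated in
        # closed form; check them against adaptive quadrature in the full
        # expression 2dD[(t - t*) - 2 I2] + v^2 (t* + I1)^2.  (The generic
        # "independent" oracle does not apply across the deterministic
        # ballistic segment: there is no diffusive contribution before t*.)
        from scipy import integrate

        spec = lw.VacfSpec(family="piecewise_ballistic", C0=0.5, Delta=0.5, phi=1.0)
        ts = spec.t_star
        t = np.geomspace(0.3, 30.0, 6)
        closed = lw.msd_tc(t, spec, scales16).values
        g = lambda s: float(spec.g(s))
        oracle = []
        for ti in t:
            I1 = integrate.quad(g, ts, ti, limit=200)[0]
            I2 = integrate.quad(lambda s: g(s) ** 2, ts, ti, limit=200)[0]
            oracle.append(
                2 * 2 * 1.0 * ((ti - ts) - 2 * I2)
                + scales16.v**2 * (ts + I1) ** 2
            )
        assert np.allclose(closed, np.array(oracle), rtol=1e-6)


class TestMsdGeneralized:
    @pytest.mark.parametrize("phi", [0.1, 0.5, 1.0])
    def test_tanh_msd_matches_quadrature(self, scales16, phi):
        spec = lw.VacfSpec(family="power_law", C0=0.5, Delta=0.016, phi=phi)
        t = np.geomspace(0.05, 20.0, 5)
        closed = lw.msd_gtc(t, spec, scales16).values

        def g(s):
            if s == 0.0:
                return 1.0
            return math.tanh(spec.C0 * (spec.Delta / s) ** spec.phi)

        oracle = np.array(
            [lw.msd_numeric_oracle(g, ti, scales16, form="independent") for ti in t]
        )
        assert np.allclose(closed, oracle, rtol=1e-6)

    @pytest.mark.parametrize("phi", [0.7, 1.0, 1.5, 2.0, 2.6])
    def test_stationary_closed_matches_quadrature_method(self, scales16, phi):
        spec = lw.VacfSpec(family="power_law", C0=0.5, Delta=0.016, phi=phi)
        t = np.geomspace(0.016, 200.0, 7)
        closed = lw.msd_gtc_stationary(t, spec, scales16, method="closed").values
        # linearized-correlation integral the closed form actually closes
        from scipy import integrate

        oracle = np.array(
            [
                2 * 2 * 1.0 * ti
                + 2
                * scales16.v**2
                * integrate.quad(
                    lambda s: (ti - s) * spec.C0 * (spec.Delta / s) ** spec.phi,
                    spec.Delta,
                    ti,
                    limit=200,
                )[0]
                for ti in t
            ]
        )
        assert np.allclose(closed, oracle, rtol=1e-6)

    def test_stationary_phi_continuity(self, scales16):
        t = np.geomspace(0.016, 100.0, 8)
        for phi0 in (1.0, 2.0):
            base = lw.msd_gtc_stationary(
                t, lw.VacfSpec(family="power_law", C0=0.5, Delta=0.016, phi=phi0),
                scales16, method="closed",
            ).values
            snap = lw.msd_gtc_stationary(
                t,
                lw.VacfSpec(family="power_law", C0=0.5, Delta=0.016, phi=phi0 + 1e-7),
                scales16, method="closed",
            ).values
            assert np.array_equal(snap, base)
            near = lw.msd_gtc_stationary(
                t,
                lw.VacfSpec(family="power_law", C0=0.5, Delta=0.016, phi=phi0 + 1e-4),
                scales16, method="closed",
            ).values
            assert np.allclose(near, base, rtol=5e-3)


class TestRegimeSlopes:
    def test_tc_superdiffusive_below_one(self, scales16):
        # phi < 1: remainder ~ t^{2-2phi} dominates at long times
        spec = lw.VacfSpec(family="power_law", C0=0.5, Delta=0.016, phi=0.5)
        t = np.geomspace(1e4, 1e6, 20)
        y = lw.msd_tc(t, spec, scales16).values
        slope = np.polyfit(np.log(t), np.log(y), 1)[0]
        assert slope == pytest.approx(1.0, abs=0.05)  # 2-2phi = 1 -> marginal
        spec2 = lw.VacfSpec(family="power_law", C0=0.5, Delta=0.016, phi=0.25)
        y2 = lw.msd_tc(t, spec2, scales16).values
        slope2 = np.polyfit(np.log(t), np.log(y2), 1)[0]
        assert slope2 == pytest.approx(1.5, abs=0.05)  # 2 - 2*0.25

    def test_gtc_stationary_slopes(self, scales16):
        t = np.geomspace(1e4, 1e6, 20)
        # phi = 0.5 < 1: superdiffusive, MSD ~ t^{2-phi}
        spec = lw.VacfSpec(family="power_law", C0=0.5, Delta=0.016, phi=0.5)
        y = lw.msd_gtc_stationary(t, spec, scales16, method="closed").values
        slope = np.polyfit(np.log(t), np.log(y), 1)[0]
        assert slope == pytest.approx(1.5, abs=0.02)
        # phi = 2.5 > 2: diffusive
        spec2 = lw.VacfSpec(family="power_law", C0=0.5, Delta=0.016, phi=2.5)
        y2 = lw.msd_gtc_stationary(t, spec2, scales16, method="closed").values
        slope2 = np.polyfit(np.log(t), np.log(y2), 1)[0]
        assert slope2 == pytest.approx(1.0, abs=0.02)
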