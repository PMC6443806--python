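"""Multi-state denaturation population models and LEM fits."""

import numpy as np
import pytest
from scipy.optimize import brentq

from swapfold import (R_KCAL, TransitionParams, UnfoldingCurve,
                      UnfoldingSimSpec, ValidationError, fit_unfolding,
                      midpoint, populations, populations_three_state_dimer,
                      populations_three_state_monomer, populations_two_state,
                      simulate_unfolding_curve)

RT = R_KCAL * 310.0


class TestTwoState:
    def test_midpoint_is_half_unfolded(self):
        p = TransitionParams(8.9, 2.3)
        pops = populations_two_state(p, 8.9 / 2.3)
        assert pops["U"] == pytest.approx(0.5, abs=1e-12)

    def test_native_baseline_limit(self):
        # wild type at pH 5.0: essentially no unfolded protein in water
        pops = populations_two_state(TransitionParams(6.1, 1.7), 0.0)
        assert pops["U"] < 1e-4

    def test_full_denaturation_limit(self):
        pops = populations_two_state(TransitionParams(6.1, 1.7), 50.0)
        assert pops["U"] > 1 - 1e-9


class TestThreeStateDimer:
    def test_analytic_case_equal_populations(self):
        """K2 = 0 and K1 = P_t reduce the conservation quadratic to
        2x^2 + x - 1 = 0, i.e. equal N2/I monomer fractions of 1/2."""
        p_t = 1e-5
        dg1 = -RT * np.log(p_t)  # K1(0) = P_t
        pops = populations_three_state_dimer(
            TransitionParams(dg1, 1.0), TransitionParams(50.0, 1.0), 0.0, p_t)
        assert pops["N2"] == pytest.approx(0.5, abs=1e-9)
        assert pops["I"] == pytest.approx(0.5, abs=1e-9)
        assert pops["U"] == pytest.approx(0.0, abs=1e-9)

    def test_fully_native_limit(self):
        pops = populations_three_state_dimer(
            TransitionParams(25.0, 1.0), TransitionParams(25.0, 1.0),
            0.0, 15e-6)
        assert pops["N2"] == pytest.approx(1.0, abs=1e-6)

    def test_quadratic_equals_brute_force_and_mass_balance(self):
        """Closed-form root equals brute-force root finding of the
        conservation equation on 1000 random parameter draws."""
        rng = np.random.default_rng(42)
        for _ in range(1000):
            p1 = TransitionParams(rng.uniform(-5, 15), rng.uniform(0.5, 5))
            p2 = TransitionParams(rng.uniform(-5, 15), rng.uniform(0.5, 5))
            den = rng.uniform(0, 6)
            p_t = 10.0 ** rng.uniform(-7, -3)
            pops = populations_three_state_dimer(p1, p2, den, p_t)
            k1 = float(p1.k_eq(den, 310.0))
            k2 = float(p2.k_eq(den, 310.0))

            def excess(ci):
                return 2 * ci * ci / k1 + (1 + k2) * ci - p_t

            ci_oracle = brentq(excess, 0.0, p_t, xtol=1e-300, rtol=1e-15)
            assert pops["I"] == pytest.approx(ci_oracle / p_t, rel=1e-8)
            # monomer-unit mass balance
            total = pops.fractions.sum()
            assert total == pytest.approx(1.0, abs=1e-10)

    def test_midpoint_drops_with_protein_dilution(self):
        """Same thermodynamics, lower P_t -> earlier first transition."""
        p1, p2 = TransitionParams(7.9, 3.0), TransitionParams(5.0, 1.4)
        cm_15 = midpoint([p1, p2], "three_state_dimer", 0, 15e-6)
        cm_3 = midpoint([p1, p2], "three_state_dimer", 0, 3e-6)
        assert cm_3 < cm_15


class TestThreeStateMonomer:
    def test_equal_equilibrium_constants(self):
        dg = 0.0
        pops = populations_three_state_monomer(
            TransitionParams(dg, 1.0), TransitionParams(dg, 1.0), 0.0)
        np.testing.assert_allclose(pops.fractions, 1.0 / 3.0, atol=1e-12)

    def test_first_midpoint_with_negligible_k2(self):
        p1 = TransitionParams(2.0, 1.0)
        pops = populations_three_state_monomer(
            p1, TransitionParams(30.0, 1.0), 2.0)
        assert pops["N"] == pytest.approx(0.5, abs=1e-9)
        assert pops["I"] == pytest.approx(0.5, abs=1e-9)

    def test_high_denaturant_unfolds_reported_helix_params(self):
        # helix-3 local stability at pH 5.0: 5 M denaturant crosses the
        # second transition (ΔG2 - m2*5 < 0)
        pops = populations_three_state_monomer(
            TransitionParams(2.0, 3.2), TransitionParams(6.9, 1.4), 5.0)
        assert pops["U"] > 0.5


class TestPopulationProperties:
    @pytest.mark.parametrize("scheme", ["two_state_IU", "three_state_dimer",
                                        "three_state_monomer"])
    def test_unfolded_fraction_monotone_in_denaturant(self, scheme):
        p1, p2 = TransitionParams(7.9, 3.0), TransitionParams(5.0, 1.4)
        trans = [p1] if scheme == "two_state_IU" else [p1, p2]
        grid = np.linspace(0, 8, 200)
        f_u = [populations(scheme, trans, d, 15e-6)["U"] for d in grid]
        assert np.all(np.diff(f_u) >= -1e-12)


class TestFitting:
    def test_exact_recovery_of_noiseless_two_state(self):
        spec = UnfoldingSimSpec(
            scheme="two_state_IU",
            transitions=[TransitionParams(8.9, 2.3)],
            baselines=np.array([[1.0, -0.02], [0.25, 0.01]]),
        )
        fit = fit_unfolding(simulate_unfolding_curve(spec), "two_state_IU")
        assert fit.transitions[0].dg == pytest.approx(8.9, abs=1e-6)
        assert fit.transitions[0].m == pytest.approx(2.3, abs=1e-6)
        assert fit.midpoints[0] == pytest.approx(8.9 / 2.3, abs=1e-6)

    def test_dimer_scheme_concentration_dependence(self):
        """Identical thermodynamics fitted at 15 uM and 3 uM agree in ΔG1
        within joint uncertainties while the midpoints differ."""
        trans = [TransitionParams(7.9, 3.0), TransitionParams(5.0, 1.4)]
        base = np.array([[1.0, -0.01], [0.62, -0.005], [0.2, 0.005]])
        fits = []
        for p_t in (15e-6, 3e-6):
            spec = UnfoldingSimSpec(
                scheme="three_state_dimer", transitions=trans,
                baselines=base, p_total=p_t, noise_sd=0.002, seed=5,
                denaturant=np.linspace(0, 6, 40))
            fits.append(fit_unfolding(simulate_unfolding_curve(spec),
                                      "three_state_dimer"))
        dg_a, dg_b = (f.transitions[0].dg for f in fits)
        sig = np.hypot(fits[0].sigmas["dg1"], fits[1].sigmas["dg1"])
        assert abs(dg_a - dg_b) < 3 * max(sig, 0.05)
        assert fits[1].midpoints[0] < fits[0].midpoints[0]

    def test_too_few_points_for_three_state(self):
        curve = UnfoldingCurve(np.linspace(0, 6, 6), np.linspace(1, 0, 6))
        with pytest.raises(ValidationError):
            fit_unfolding(curve, "three_state_dimer")

    def test_midpoint_requires_positive_m(self):
        with pytest.raises(ValidationError):
            TransitionParams(5.0, 0.0)

    def test_unknown_scheme(self):
        curve = UnfoldingCurve(np.linspace(0, 6, 20), np.linspace(1, 0, 20))
        with pytest.raises(ValidationError):
            fit_unfolding(curve, "four_state")


class TestSignalModel:
    def test_two_state_midpoint_signal_is_baseline_mean(self):
        p = TransitionParams(6.0, 2.0)
        spec = UnfoldingSimSpec(
            scheme="two_state_IU", transitions=[p],
            baselines=np.array([[0.8, 0.0], [0.2, 0.0]]),
            denaturant=np.linspace(0.0, 6.0, 13))  # includes 3.0 = ΔG/m
        curve = simulate_unfolding_curve(spec)
        i = np.argmin(np.abs(curve.denaturant - 3.0))
        assert curve.signal[i] == pytest.approx(0.5, abs=1e-9)

    def test_affine_invariance(self):
        base = np.array([[1.0, -0.02], [0.2, 0.01]])
        spec1 = UnfoldingSimSpec(baselines=base)
        spec2 = UnfoldingSimSpec(baselines=3.0 * base)
        s1 = simulate_unfolding_curve(spec1).signal
        s2 = simulate_unfolding_curve(spec2).signal
        np.testing.assert_allclose(s2, 3.0 * s1, rtol=1e-12)
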