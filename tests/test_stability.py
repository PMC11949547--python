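"""Two-cell subsystem stability analysis: equilibria, Hopf roots, sweeps."""

import numpy as np
import pytest

from ca1prm import (SUBSYSTEMS, ModelParams, WeightSet, inverse_response,
                    find_equilibrium, characteristic_coefficients,
                    oscillation_frequency, bifurcation_delays,
                    frequency_at_delay, sweep)
from ca1prm.stability import find_equilibria, subsystem_params
from ca1prm.model import CellType, response


class TestEquilibrium:
    def test_decoupled_equals_closed_form(self, default_params):
        for spec in SUBSYSTEMS.values():
            x1, x2 = find_equilibrium(spec, default_params)
            p1 = default_params.cells[spec.cell1]
            p2 = default_params.cells[spec.cell2]
            assert x1 == pytest.approx(p1.r0 * response(p1.ie, p1.beta),
                                       abs=1e-8)
            assert x2 == pytest.approx(p2.r0 * response(p2.ie, p2.beta),
                                       abs=1e-8)

    def test_inverse_consistency_reproduces_excitabilities(self,
                                                           reference_model):
        # inserting the equilibrium into the fixed-point equations,
        # rearranged for the intrinsic excitabilities, must return them
        spec = SUBSYSTEMS["PYR+BiC"]
        p = subsystem_params(spec, reference_model)
        for (x1, x2) in find_equilibria(spec, reference_model):
            if not (0 < x1 < p["r1"] and 0 < x2 < p["r2"]):
                continue
            ie1 = (inverse_response(x1 / p["r1"], p["beta"])
                   - p["w11"] * x1 - p["w12"] * x2)
            ie2 = (inverse_response(x2 / p["r2"], p["beta"])
                   - p["w21"] * x1)
            assert ie1 == pytest.approx(p["ie1"], abs=1e-8)
            assert ie2 == pytest.approx(p["ie2"], abs=1e-8)

    def test_drift_vanishes_at_equilibrium(self, reference_model):
        from ca1prm import drift
        from ca1prm.stability import _subsystem_model
        for spec in SUBSYSTEMS.values():
            sub = _subsystem_model(spec, reference_model)
            x1, x2 = find_equilibrium(spec, reference_model)
            rates = np.zeros(4)
            rates[spec.cell1.value] = x1
            rates[spec.cell2.value] = x2
            d = drift(sub, rates, rates, stim=np.zeros(4))
            assert abs(d[spec.cell1.value]) < 1e-8
            assert abs(d[spec.cell2.value]) < 1e-8


class TestCharacteristicCoefficients:
    def test_zero_couplings_without_weights(self, default_params):
        spec = SUBSYSTEMS["PYR+BiC"]
        eq = find_equilibrium(spec, default_params)
        g = characteristic_coefficients(spec, default_params, eq)["gammas"]
        assert all(v == 0 for v in g.values())

    def test_kappa1_at_zero_frequency(self, reference_model):
        spec = SUBSYSTEMS["PYR+BiC"]
        eq = find_equilibrium(spec, reference_model)
        c = characteristic_coefficients(spec, reference_model, eq)
        g = c["gammas"]
        p = c["p"]
        k = c["kappas"](0.0)
        assert k[0] == pytest.approx(
            p["a1"] * p["a2"] * (1 - g["g12"] * g["g21"]
                                 + g["g11"] * g["g22"]))

    @pytest.mark.parametrize("name", list(SUBSYSTEMS))
    def test_gammas_match_finite_difference_jacobian(self, name,
                                                     reference_model):
        # the delayed-coupling gammas are the partial derivatives of the
        # nonlinear update map, scaled by alpha; check by central
        # differences of r0*f(I) at the analysis equilibrium
        spec = SUBSYSTEMS[name]
        res = oscillation_frequency(spec, reference_model)
        x1, x2 = res.equilibrium
        p = res.coeffs["p"]
        g = res.gammas
        h = 1e-6

        def F1(a, b):
            return p["r1"] * response(p["ie1"] + p["w11"] * a
                                      + p["w12"] * b, p["beta"])

        def F2(a, b):
            return p["r2"] * response(p["ie2"] + p["w21"] * a
                                      + p["w22"] * b, p["beta"])

        fd = {
            "g11": (F1(x1 + h, x2) - F1(x1 - h, x2)) / (2 * h),
            "g12": (F1(x1, x2 + h) - F1(x1, x2 - h)) / (2 * h),
            "g21": (F2(x1 + h, x2) - F2(x1 - h, x2)) / (2 * h),
            "g22": (F2(x1, x2 + h) - F2(x1, x2 - h)) / (2 * h),
        }
        for key in fd:
            assert g[key] == pytest.approx(fd[key], rel=1e-5, abs=1e-7)


class TestOscillationFrequency:
    def test_reference_theta_subsystem_in_band(self, reference_model):
        res = oscillation_frequency(SUBSYSTEMS["PYR+BiC"], reference_model)
        assert 3 <= res.frequency <= 12

    @pytest.mark.parametrize("name", ["PYR+PV", "CCK+PV"])
    def test_reference_gamma_subsystems_in_band_at_5ms(self, name,
                                                       reference_model):
        res = oscillation_frequency(SUBSYSTEMS[name], reference_model)
        f5 = frequency_at_delay(res, 0.005)
        assert f5 is not None
        assert 20 <= f5 <= 100

    def test_residuals_tiny_at_root(self, reference_model):
        for spec in SUBSYSTEMS.values():
            res = oscillation_frequency(spec, reference_model)
            assert max(res.residuals) <= 1e-6
            # trig identity holds by construction of the root
            assert res.G1**2 + res.G2**2 == pytest.approx(1.0, abs=1e-9)

    def test_no_root_for_decoupled_system(self, default_params):
        with pytest.raises(RuntimeError, match="no oscillation root"):
            oscillation_frequency(SUBSYSTEMS["PYR+BiC"], default_params)


class TestBifurcationDelays:
    def test_spacing_is_exactly_one_period(self):
        taus = bifurcation_delays(2 * np.pi * 50, 0.4, np.sqrt(1 - 0.16))
        diffs = np.diff(taus)
        assert np.allclose(diffs, 2 * np.pi / (2 * np.pi * 50))

    def test_all_positive(self, reference_model):
        for spec in SUBSYSTEMS.values():
            res = oscillation_frequency(spec, reference_model)
            assert all(t > 0 for t in res.bifurcation_delays)
            assert np.all(np.diff(res.bifurcation_delays) > 0)

    def test_inconsistent_root_rejected(self):
        with pytest.raises(ValueError, match="G1"):
            bifurcation_delays(100.0, 1.5, 0.0)

    def test_first_bifurcation_below_5ms_for_gamma_subsystems(
            self, reference_model):
        # sustained gamma exists at the working delay of 5 ms
        for name in ("PYR+PV", "CCK+PV"):
            res = oscillation_frequency(SUBSYSTEMS[name], reference_model)
            assert res.first_bifurcation < 0.005


class TestSweeps:
    def test_beta_sweep_increases_for_gamma_subsystems(self, reference_model):
        grid = [16.0, 18.0, 20.0, 22.0, 24.0]
        for name in ("PYR+PV", "CCK+PV"):
            out = sweep(SUBSYSTEMS[name], reference_model, beta_grid=grid)
            freqs = [pt["frequency_hz"] for pt in out["points"]]
            assert all(f is not None for f in freqs)
            assert all(np.diff(freqs) > 0)

    def test_tau_sweep_decreases_for_gamma_subsystems(self, reference_model):
        grid = [0.003, 0.004, 0.005, 0.006, 0.008]
        for name in ("PYR+PV", "CCK+PV"):
            out = sweep(SUBSYSTEMS[name], reference_model, tau_grid=grid)
            freqs = [pt["frequency_hz"] for pt in out["points"]]
            assert all(f is not None for f in freqs)
            assert all(np.diff(freqs) < 0)

    def test_theta_subsystem_stays_in_band_across_delays(self,
                                                         reference_model):
        grid = [0.003, 0.004, 0.005, 0.006, 0.008]
        out = sweep(SUBSYSTEMS["PYR+BiC"], reference_model, tau_grid=grid)
        freqs = [pt["frequency_hz"] for pt in out["points"]]
        assert all(f is not None and 3 <= f <= 12 for f in freqs)

    def test_exactly_one_grid_required(self, reference_model):
        with pytest.raises(ValueError):
            sweep(SUBSYSTEMS["PYR+BiC"], reference_model)
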