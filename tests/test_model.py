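"""Core model: response function, drives, drift."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ca1prm import (CellType, ModelParams, WeightSet, response,
                    inverse_response, presynaptic_drive, drift)
from ca1prm.model import MASK_EDGES, EXCITATORY_EDGES, DEFAULT_CELL_PARAMS


class TestResponse:
    @pytest.mark.parametrize("I,beta,expected", [
        (0.0, 20.0, 0.5),                       # sigmoid midpoint
        (0.1, 20.0, 1 / (1 + np.exp(-2.0))),    # closed form
        (100.0, 20.0, 1.0),                     # saturation high
        (-100.0, 20.0, 0.0),                    # saturation low
    ])
    def test_values(self, I, beta, expected):
        assert response(I, beta) == pytest.approx(expected, abs=1e-12)

    def test_stable_at_large_argument(self):
        # no overflow for |beta*I| up to 1e3
        assert response(50.0, 20.0) == 1.0
        assert response(-50.0, 20.0) == pytest.approx(0.0, abs=1e-300)
        assert np.isfinite(response(-50.0, 20.0))

    def test_rejects_nonfinite_drive(self):
        with pytest.raises(ValueError):
            response(np.nan, 20.0)
        with pytest.raises(ValueError):
            response(np.inf, 20.0)

    @given(st.floats(-50, 50), st.floats(-50, 50))
    @settings(max_examples=50, deadline=None)
    def test_monotone_and_symmetric(self, a, b):
        lo, hi = sorted((a, b))
        assert response(lo, 20.0) <= response(hi, 20.0)
        assert response(-a, 20.0) == pytest.approx(1 - response(a, 20.0),
                                                   abs=1e-12)


class TestInverseResponse:
    def test_midpoint(self):
        assert inverse_response(0.5, 20.0) == 0.0

    def test_round_trip_example(self):
        y = response(0.1, 20.0)
        assert inverse_response(y, 20.0) == pytest.approx(0.1, rel=1e-12)

    @pytest.mark.parametrize("y", [0.0, 1.0, -0.1, 1.1])
    def test_domain_error(self, y):
        with pytest.raises(ValueError):
            inverse_response(y, 20.0)

    def test_near_boundary_is_finite(self):
        v = inverse_response(1 - 1e-16, 20.0)
        assert np.isfinite(v)

    @given(st.floats(-2, 2))
    @settings(max_examples=50, deadline=None)
    def test_left_inverse_on_interval_unit_gain(self, I):
        y = response(I, 1.0)
        assert inverse_response(y, 1.0) == pytest.approx(I, abs=1e-10)

    @given(st.floats(-0.6, 0.6))
    @settings(max_examples=50, deadline=None)
    def test_left_inverse_at_working_gain(self, I):
        # at beta = 20 the response saturates to within float64 epsilon
        # of 1 beyond |I| ~ 1.8, so the round-trip is exercised on the
        # sub-saturation range where 1 - y is resolvable
        y = response(I, 20.0)
        assert inverse_response(y, 20.0) == pytest.approx(I, abs=1e-10)


class TestWeightSet:
    def test_sign_convention_enforced(self):
        with pytest.raises(ValueError):
            WeightSet({("PYR->PYR"): -0.1})
        with pytest.raises(ValueError):
            WeightSet({("PV->PYR"): 0.1})

    def test_non_mask_edge_rejected(self):
        with pytest.raises(ValueError):
            WeightSet({"BiC->CCK": 0.1})

    def test_missing_edges_default_zero(self):
        ws = WeightSet({"PYR->PYR": 0.1})
        assert ws["BiC->PYR"] == 0.0
        assert len(ws.w) == 9

    def test_matrix_vector_round_trip(self, rng):
        vec = rng.uniform(0, 0.1, 9)
        vec[3:] *= -1  # inhibitory edges come after the 3 excitatory ones
        ws = WeightSet.from_vector(vec)
        assert np.allclose(ws.as_vector(), vec)
        W = ws.as_matrix()
        for (src, tgt) in MASK_EDGES:
            assert W[tgt.value, src.value] == ws[(src, tgt)]


class TestPresynapticDrive:
    def test_decoupled(self, default_params):
        d = presynaptic_drive(default_params, np.zeros(4))
        assert np.allclose(d.I_syn, 0)
        assert np.allclose(d.I, default_params.ie)

    def test_single_edge(self, default_params):
        ws = WeightSet({"PYR->BiC": 0.5})
        p = default_params.with_weights(ws)
        d = presynaptic_drive(p, np.ones(4))
        assert d.I_syn[CellType.BiC.value] == pytest.approx(0.5)
        assert d.I_syn[CellType.PYR.value] == 0.0

    def test_matches_hand_dot_product(self, reference_model, rng):
        rates = rng.uniform(0, 30, 4)
        stim = rng.normal(0, 0.3, 4)
        d = presynaptic_drive(reference_model, rates, stim)
        w = reference_model.weights
        # hand-assembled per-target sums over the mask equations
        expected_pyr = (w["PYR->PYR"] * rates[0] + w["BiC->PYR"] * rates[1]
                        + w["PV->PYR"] * rates[3] + stim[0])
        expected_bic = w["PYR->BiC"] * rates[0] + stim[1]
        expected_cck = (w["CCK->CCK"] * rates[2] + w["PV->CCK"] * rates[3]
                        + stim[2])
        expected_pv = (w["CCK->PV"] * rates[2] + w["PV->PV"] * rates[3]
                       + w["PYR->PV"] * rates[0] + stim[3])
        assert np.allclose(
            d.I_syn, [expected_pyr, expected_bic, expected_cck, expected_pv])
        assert np.allclose(d.I - d.I_syn, reference_model.ie)

    def test_linearity_superposition(self, reference_model, rng):
        r1, r2 = rng.uniform(0, 20, (2, 4))
        s1, s2 = rng.normal(0, 0.5, (2, 4))
        d12 = presynaptic_drive(reference_model, r1 + r2, s1 + s2)
        d1 = presynaptic_drive(reference_model, r1, s1)
        d2 = presynaptic_drive(reference_model, r2, s2)
        assert np.allclose(d12.I_syn, d1.I_syn + d2.I_syn, atol=1e-12)

    def test_invalid_rates_rejected(self, default_params):
        with pytest.raises(ValueError):
            presynaptic_drive(default_params, [-1.0, 0, 0, 0])
        with pytest.raises(ValueError):
            presynaptic_drive(default_params, [50.0, 0, 0, 0])  # r0_PYR = 40


class TestDrift:
    def test_zero_at_decoupled_fixed_point(self, default_params):
        fp = default_params.r0 * response(default_params.ie,
                                          default_params.beta)
        d = drift(default_params, fp, fp)
        assert np.allclose(d, 0, atol=1e-10)

    def test_closed_form_from_rest(self, default_params):
        d = drift(default_params, np.zeros(4), np.zeros(4))
        pyr = DEFAULT_CELL_PARAMS[CellType.PYR]
        expected = pyr.alpha * pyr.r0 * response(pyr.ie, pyr.beta)
        assert d[0] == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(40 * 40 / (1 + np.exp(-0.6)),
                                         rel=1e-12)

    def test_linear_in_alpha(self, reference_model, rng):
        from dataclasses import replace
        from ca1prm.model import CellParams
        rates = rng.uniform(0, 30, 4)
        delayed = rng.uniform(0, 30, 4)
        d1 = drift(reference_model, rates, delayed)
        doubled = {c: CellParams(p.alpha * 2, p.r0, p.ie, p.beta)
                   for c, p in reference_model.cells.items()}
        d2 = drift(replace(reference_model, cells=doubled), rates, delayed)
        assert np.allclose(d2, 2 * d1)


class TestSerialization:
    def test_round_trip(self, reference_model):
        doc = reference_model.to_dict()
        back = ModelParams.from_dict(doc)
        assert back.to_dict() == doc
        assert back.fingerprint() == reference_model.fingerprint()

    def test_defaults_from_empty_document(self):
        p = ModelParams.from_dict({})
        assert p.cells[CellType.PYR].alpha == 40.0
        assert p.cells[CellType.BiC].ie == -1.45
        assert p.cells[CellType.PV].beta == 20.0
        assert p.tau_ms == 5.0
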