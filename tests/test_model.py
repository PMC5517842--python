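"""Pointwise kinetics: dosing, checkpoint closure, reactions, chemotaxis."""

import numpy as np
import pytest

from melsim.model import (
    FIELD_NAMES, IDX, N_FIELDS, DoseSchedule, dose_rate, pdl1_level,
    checkpoint_factors, reaction_terms, reaction_split, chemotactic_divergence,
)
from melsim.parameters import derive_checkpoint_params

# reference steady state: cells and cytokines at their half-saturation values
REFERENCE = {"D": 4e-4, "T1": 2e-3, "T8": 1e-3, "Tr": 5e-4, "M": 0.2, "C": 0.4,
             "I12": 8e-10, "I2": 2.37e-11, "Tb": 2.68e-13, "I6": 3.4e-11,
             "I10": 8.75e-11, "P": 8.466e-10, "A": 0.0, "B": 0.0}


def point_state(values: dict, n: int = 1) -> np.ndarray:
    fields = np.zeros((N_FIELDS, n))
    for name, v in values.items():
        fields[IDX[name]] = v
    return fields


class TestDoseSchedule:
    def test_piecewise_levels(self):
        s = DoseSchedule(0.3e-9)
        assert dose_rate(10.0, s) == 0.3e-9
        assert dose_rate(31.5, s) == pytest.approx(0.15e-9)  # ramp midpoint
        assert dose_rate(40.0, s) == 0.0
        assert dose_rate(30.0, s) == 0.3e-9

    def test_no_schedule_is_zero(self):
        assert dose_rate(5.0, None) == 0.0

    def test_validation(self):
        with pytest.raises(ValueError):
            dose_rate(-1.0, DoseSchedule(1e-9))
        with pytest.raises(ValueError):
            DoseSchedule(-1e-9)
        with pytest.raises(ValueError):
            DoseSchedule(1e-9, t_on=33.0, t_ramp_end=30.0)


class TestCheckpointClosure:
    def test_pdl1_reference_level(self, params):
        # rho_L*(3e-3 + 0.005*0.2 + 0.01*0.4) = 4.176e-9
        assert pdl1_level(2e-3, 1e-3, 0.2, 0.4, params) == pytest.approx(4.176e-9)
        assert pdl1_level(0, 0, 0, 0, params) == 0.0
        assert pdl1_level(2e-3, 1e-3, 0, 0, params) == pytest.approx(1.566e-9)

    def test_reference_complex_gives_third_and_half(self, params):
        # by construction P*L = 2*Kp_TQ = Kp_Q at the reference steady state
        ck = derive_checkpoint_params(params)
        p = params.with_overrides(Kp_TQ=ck["Kp_TQ"], Kp_Q=ck["Kp_Q"])
        inh, pro = checkpoint_factors(ck["Pbar"], ck["Lbar"], p)
        assert inh == pytest.approx(1.0 / 3.0)
        assert pro == pytest.approx(0.5)

    def test_no_complex_limit(self, params):
        inh, pro = checkpoint_factors(0.0, 5e-9, params)
        assert inh == 1.0 and pro == 0.0


class TestReactions:
    def test_split_is_consistent_with_rates(self, params):
        fields = point_state(REFERENCE)
        src, loss = reaction_split(fields, params)
        rates = reaction_terms(fields, params)
        assert np.allclose(src - loss * fields, rates)

    def test_cytokines_balance_at_reference_state(self, params):
        """Production cancels degradation at the assumed steady state."""
        fields = point_state(REFERENCE)
        rates = reaction_terms(fields, params)
        for name in ("I12", "I2", "Tb", "I6", "I10"):
            k = IDX[name]
            degradation = getattr(params, f"d_{name}") * fields[k, 0]
            assert abs(rates[k, 0]) < 0.01 * degradation, name

    def test_il6_decays_without_producer(self, params):
        values = dict(REFERENCE, C=0.0)
        rates = reaction_terms(point_state(values), params)
        k = IDX["I6"]
        assert rates[k, 0] == pytest.approx(-params.d_I6 * values["I6"])

    def test_logistic_stops_at_carrying_capacity(self, params):
        values = dict(REFERENCE, C=params.C_M, T1=0.0, T8=0.0)
        rates = reaction_terms(point_state(values), params)
        assert rates[IDX["C"], 0] == pytest.approx(-params.d_C * params.C_M)

    def test_drugs_stay_zero_without_sources(self, params):
        fields = point_state(REFERENCE)
        rates = reaction_terms(fields, params, t=10.0)
        assert rates[IDX["A"], 0] == 0.0
        assert rates[IDX["B"], 0] == 0.0

    def test_no_spontaneous_generation(self, params):
        """With every density at zero, only reservoir-free terms vanish."""
        rates = reaction_terms(np.zeros((N_FIELDS, 1)), params)
        assert np.all(rates == 0.0)  # no C -> no DC activation; no producers

    def test_pd1_guard_at_zero_t_cells(self, params):
        values = dict(REFERENCE, T1=0.0, T8=0.0, Tr=0.0, P=1e-10)
        rates = reaction_terms(point_state(values), params)
        assert np.isfinite(rates[IDX["P"], 0])
        assert rates[IDX["P"], 0] == 0.0  # no drug, no T cells -> defined as 0

    def test_braf_boost_raises_il12_production(self, params):
        boosted = dict(REFERENCE, B=params.K_B)
        r0 = reaction_terms(point_state(REFERENCE), params)[IDX["I12"], 0]
        r1 = reaction_terms(point_state(boosted), params)[IDX["I12"], 0]
        # factor (1 + lam_I12B/2) on production at B = K_B
        assert r1 - r0 == pytest.approx(
            0.5 * params.lam_I12B * params.lam_I12D * REFERENCE["D"])


class TestChemotaxis:
    def test_uniform_field_and_zero_chi(self, params):
        r = np.linspace(0.0, 0.01, 41)
        x = np.full_like(r, 0.2)
        i6 = np.full_like(r, 3.4e-11)
        div = chemotactic_divergence(x, i6, r, params.chi)
        # zero up to grid-weight roundoff; a physical signal here would be
        # of order chi*X*I6/R^2 ~ 1e-5
        assert np.allclose(div, 0.0, atol=1e-15)
        assert np.all(chemotactic_divergence(x, r ** 2, r, 0.0) == 0.0)

    def test_quadratic_profile_matches_closed_form(self):
        # I6 = a*r^2, X = const: div(chi X grad I6) = 6*a*chi*X exactly
        r = np.linspace(0.0, 1.0, 401)
        a, chi, x0 = 2.5, 10.0, 0.3
        div = chemotactic_divergence(np.full_like(r, x0), a * r ** 2, r, chi)
        assert np.allclose(div, 6.0 * a * chi * x0, rtol=1e-2)

    def test_small_grid_rejected(self):
        with pytest.raises(ValueError):
            chemotactic_divergence(np.ones(2), np.ones(2), np.array([0.0, 1.0]), 1.0)
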