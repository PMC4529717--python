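"""Closed-form estimators: published arithmetic, round trips, invariances."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from ckst.estimators import (
    CorrectionCoefficients,
    MissingSignalError,
    STSignals,
    SignalModelError,
    TABLE_COEFFICIENTS,
    dual_tr_fit,
    equivalent_twist_form,
    kf_q_trist,
    kf_q_twist,
    kf_trist,
    kf_twist,
    q_ratio,
    t1_intrinsic_apparent,
    t1_q_intrinsic,
)
from ckst.exchange import ExchangeSystem, saturated_recovery, t1_prime, two_pool_recovery


def _signals_from_system(sys_, tr_control=16.0, tr_long=10.0, tr_short=1.7, control=None):
    """Noise-free Q = 1 signal set generated by the closed-form model."""
    if control is None:
        control = two_pool_recovery(sys_, tr_control, (0.0, 0.0))[0]
    return STSignals(
        m0=control,
        m0_control=control,
        m_long=saturated_recovery(sys_, tr_long),
        m_short=saturated_recovery(sys_, tr_short),
        tr_control=tr_control,
        tr_long=tr_long,
        tr_short=tr_short,
    )


class TestQRatio:
    def test_plain_ratio(self):
        s = STSignals(m0=1.0, m0_control=0.84, m_long=0.3)
        assert q_ratio(s) == 0.84

    def test_clipped_above_one(self):
        s = STSignals(m0=1.0, m0_control=1.02, m_long=0.3)
        assert q_ratio(s) == 1.0

    def test_missing_m0_raises(self):
        with pytest.raises(MissingSignalError):
            q_ratio(STSignals(m0_control=1.0, m_long=0.3))


class TestDualTr:
    def test_inverts_saturated_recovery(self):
        t1p, m0p = dual_tr_fit(0.15078, 0.28018, 1.7, 10.0)
        assert t1p == pytest.approx(2.2392, abs=2e-3)
        assert m0p == pytest.approx(0.28344, abs=2e-4)

    def test_forward_then_invert_exact(self):
        t1_true, m0_true = 2.0, 1.0
        ms = m0_true * (1 - np.exp(-1.7 / t1_true))
        ml = m0_true * (1 - np.exp(-10.0 / t1_true))
        t1p, m0p = dual_tr_fit(ms, ml, 1.7, 10.0)
        assert t1p == pytest.approx(2.0, rel=1e-8)
        assert m0p == pytest.approx(1.0, rel=1e-8)

    @given(t1=st.floats(0.5, 20.0), m0=st.floats(0.1, 3.0))
    def test_round_trip_over_feasible_domain(self, t1, m0):
        ms = m0 * -np.expm1(-1.7 / t1)
        ml = m0 * -np.expm1(-10.0 / t1)
        t1p, m0p = dual_tr_fit(ms, ml, 1.7, 10.0)
        assert t1p == pytest.approx(t1, rel=1e-6)
        assert m0p == pytest.approx(m0, rel=1e-6)

    @pytest.mark.parametrize(
        "ms, ml",
        [
            (0.30, 0.30),  # ratio 1: T1' -> 0 boundary
            (0.052, 0.30),  # ratio just above tr_short/tr_long: T1' -> inf
            (0.35, 0.30),  # ratio > 1
        ],
    )
    def test_infeasible_ratios_raise(self, ms, ml):
        with pytest.raises(SignalModelError):
            dual_tr_fit(ms, ml, 1.7, 10.0)


class TestTrist:
    def test_recovers_rate_from_forward_simulation(self, nominal_system):
        est = kf_trist(_signals_from_system(nominal_system, control=1.0))
        assert est.kf == pytest.approx(0.32, abs=5e-4)
        assert est.t1_prime == pytest.approx(t1_prime(nominal_system), rel=1e-4)

    def test_recovers_hf_rate(self, hf_system):
        est = kf_trist(_signals_from_system(hf_system, control=1.0))
        assert est.kf == pytest.approx(0.21, abs=5e-4)

    def test_zero_rate_when_no_transfer(self):
        # M0' equal to the control signal means no saturation-transfer effect
        s = STSignals(m0_control=0.28344, m_long=0.28018, m_short=0.15078)
        est = kf_trist(s)
        assert est.kf == pytest.approx(0.0, abs=1e-4)

    def test_negative_rate_flagged_not_raised(self):
        s = STSignals(m0_control=0.25, m_long=0.28018, m_short=0.15078)
        est = kf_trist(s)
        assert est.kf < 0
        assert "non-positive rate" in est.warnings


class TestApparentT1:
    @pytest.mark.parametrize(
        "t1p, m0p", [(2.2392, 0.28344), (2.9711, 0.37609)]
    )
    def test_closes_exchange_identity(self, t1p, m0p):
        assert t1_intrinsic_apparent(t1p, m0p, 1.0) == pytest.approx(7.900, abs=2e-3)

    def test_equal_signals_give_t1_prime(self):
        assert t1_intrinsic_apparent(2.5, 0.4, 0.4) == 2.5


class TestTwist:
    def test_fully_relaxed_signals(self):
        s = STSignals(m0_control=1.0, m_long=0.28344)
        assert kf_twist(s, 7.9).kf == pytest.approx(0.3200, abs=1e-4)

    def test_truncation_bias_positive(self):
        # finite TR_long truncates M' more than the control, inflating the rate
        s = STSignals(m0_control=1.0, m_long=0.28018)
        assert kf_twist(s, 7.9).kf == pytest.approx(0.32521, abs=2e-4)

    def test_equal_signals_give_zero(self):
        s = STSignals(m0_control=0.5, m_long=0.5)
        est = kf_twist(s)
        assert est.kf == 0.0
        assert "non-positive rate" in est.warnings


class TestQCorrectedFormulae:
    def test_t1_q_intrinsic_published_coefficients(self):
        s = STSignals(m0=1.0, m0_control=1.0, m_long=0.28)
        got = t1_q_intrinsic(s, t1_prime=2.2392, m0_prime=0.28344)
        assert got == pytest.approx(7.285, abs=2e-3)

    def test_t1_q_intrinsic_structural_reduction(self):
        neutral = CorrectionCoefficients(a=1.0, b=0.0, c=0.0, d=0.0)
        s = STSignals(m0=1.0, m0_control=0.9, m_long=0.28)
        got = t1_q_intrinsic(s, t1_prime=2.0, m0_prime=0.3, coeffs=neutral)
        assert got == pytest.approx((0.3 / 0.9) * 0.9 * 2.0, rel=1e-12)

    @pytest.mark.parametrize(
        "t1_true, ratio, t1p, expected",
        [
            (7.9, 0.28344, 2.2392, 0.3346),
            (7.9, 0.37609, 2.9711, 0.2281),
        ],
    )
    def test_q_trist_published_coefficients(self, t1_true, ratio, t1p, expected):
        # signals constructed so the dual-TR fit returns (t1p, ratio)
        m_short = ratio * -np.expm1(-1.7 / t1p)
        m_long = ratio * -np.expm1(-10.0 / t1p)
        s = STSignals(m0=1.0, m0_control=1.0, m_long=m_long, m_short=m_short)
        assert kf_q_trist(s).kf == pytest.approx(expected, abs=2e-4)

    def test_q_trist_zero_scale(self):
        coeffs = TABLE_COEFFICIENTS.replace(f=0.0)
        s = _signals_from_system(ExchangeSystem())
        assert kf_q_trist(s, coeffs).kf == 0.0

    def test_q_twist_published_coefficients(self):
        s = STSignals(m0=1.0, m0_control=1.0, m_long=1.0 / 3.5281)
        assert kf_q_twist(s).kf == pytest.approx(0.30734, abs=5e-5)

    def test_q_twist_zero_scale(self):
        s = STSignals(m0=1.0, m0_control=1.0, m_long=0.3)
        assert kf_q_twist(s, TABLE_COEFFICIENTS.replace(l=0.0)).kf == 0.0

    @pytest.mark.parametrize("ratio", np.linspace(1.5, 6.0, 7))
    def test_q_twist_matches_equivalent_t1_form_at_unity_q(self, ratio):
        """At Q = 1 the corrected TwiST equals the plain form with the
        equivalent intrinsic T1 absorbed into the coefficients."""
        s = STSignals(m0=1.0, m0_control=1.0, m_long=1.0 / ratio)
        via_product = kf_q_twist(s).kf
        t1_equiv, offset = equivalent_twist_form()
        via_equivalent = (1.0 / round(t1_equiv, 2)) * (ratio - round(offset, 2))
        assert via_product == pytest.approx(via_equivalent, abs=1e-3)


class TestEquivalentForm:
    def test_published_values(self):
        t1_equiv, offset = equivalent_twist_form()
        assert round(t1_equiv, 2) == 8.13
        assert round(offset, 2) == 1.03
        assert t1_equiv == pytest.approx(8.1266, abs=2e-4)

    def test_trivial_coefficients(self):
        coeffs = CorrectionCoefficients(l=1.0, n=0.0, m=-1.0)
        assert equivalent_twist_form(coeffs) == (1.0, 1.0)

    def test_degenerate_raises(self):
        with pytest.raises(ValueError):
            equivalent_twist_form(CorrectionCoefficients(l=0.5, n=-1.0))


class TestInvariances:
    @pytest.mark.parametrize("kf", [0.1, 0.2, 0.32, 0.4])
    @pytest.mark.parametrize("t1", [6.5, 7.9, 9.5])
    def test_noiseless_recovery_across_range(self, kf, t1):
        """TRiST and TwiST recover the rate to <0.5% on ideal Q = 1 signals."""
        sys_ = ExchangeSystem(kf=kf, t1_intrinsic_pcr=t1)
        s = _signals_from_system(sys_, control=1.0)
        s = s.replace(m_long=saturated_recovery(sys_, 1000.0))  # fully relaxed M0'
        assert kf_trist(s.replace(m_long=saturated_recovery(sys_, 10.0))).kf == pytest.approx(
            kf, rel=5e-3
        )
        assert kf_twist(s, t1).kf == pytest.approx(kf, rel=5e-3)

    @given(scale=st.floats(0.01, 100.0))
    def test_scale_invariance(self, scale):
        """Multiplying every signal by a constant leaves every estimate unchanged."""
        sys_ = ExchangeSystem()
        s = _signals_from_system(sys_)
        scaled = s.scaled(scale)
        assert kf_trist(scaled).kf == pytest.approx(kf_trist(s).kf, rel=1e-9)
        assert kf_twist(scaled).kf == pytest.approx(kf_twist(s).kf, rel=1e-9)
        assert kf_q_trist(scaled).kf == pytest.approx(kf_q_trist(s).kf, rel=1e-9)
        assert kf_q_twist(scaled).kf == pytest.approx(kf_q_twist(s).kf, rel=1e-9)


class TestValidation:
    def test_tr_ordering_enforced(self):
        with pytest.raises(ValueError):
            STSignals(m0_control=1.0, m_long=0.3, tr_long=20.0, tr_control=16.0)

    def test_missing_short_tr_blocks_trist(self):
        with pytest.raises(MissingSignalError):
            kf_trist(STSignals(m0_control=1.0, m_long=0.3))

    def test_coefficients_round_trip(self):
        c = TABLE_COEFFICIENTS
        assert CorrectionCoefficients.from_json(c.to_json()) == c

    def test_unknown_coefficient_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            CorrectionCoefficients.from_dict({"z": 1.0})
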