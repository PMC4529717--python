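"""Closed-form saturation-transfer estimators of the CK forward rate.

Given PCr peak heights from up to four acquisitions --

* ``m0``          unsaturated, long TR (spill-over reference)
* ``m0_control``  control saturation mirrored at +delta_f, long TR
* ``m_long``      gamma-ATP saturated, long TR
* ``m_short``     gamma-ATP saturated, short TR

-- this module computes the spill-over ratio Q = m0_control/m0, the dual-TR
estimate of (T1', M0'), the three-acquisition TRiST rate

    kf_TRiST = (1/T1') (1 - M0'/M0_control),

the two-acquisition TwiST rate

    kf_TwiST = (1/T1_intrinsic) (M0_control/M'(TR_long) - 1),

the apparent intrinsic T1 = T1' * M0_control/M0', and the Q-corrected
variants built from triple/double products of affine terms whose published
coefficients (``TABLE_COEFFICIENTS``) were fitted over the cardiac 3 T
parameter range (see :mod:`ckst.correction` for the refitting machinery).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from typing import Optional, Tuple

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "STSignals",
    "CorrectionCoefficients",
    "KineticEstimate",
    "TABLE_COEFFICIENTS",
    "MissingSignalError",
    "SignalModelError",
    "q_ratio",
    "dual_tr_fit",
    "kf_trist",
    "t1_intrinsic_apparent",
    "kf_twist",
    "t1_q_intrinsic",
    "kf_q_trist",
    "kf_q_twist",
    "equivalent_twist_form",
]

DEFAULT_T1_INTRINSIC = 7.9  # s, assumed PCr intrinsic T1 for uncorrected TwiST


class MissingSignalError(ValueError):
    """A required acquisition is absent from the signal set."""


class SignalModelError(ValueError):
    """Signals are inconsistent with the saturation-recovery model."""


@dataclass(frozen=True)
class STSignals:
    """PCr peak heights of the (up to) four ST acquisitions with their TRs.

    ``m0`` and ``m_short`` are optional: TwiST needs neither, TRiST needs
    ``m_short``, and the Q-corrections need ``m0``.
    """

    m0_control: float
    m_long: float
    m_short: Optional[float] = None
    m0: Optional[float] = None
    tr_control: float = 16.0
    tr_long: float = 10.0
    tr_short: float = 1.7

    def __post_init__(self) -> None:
        for name in ("m0_control", "m_long", "m_short", "m0"):
            value = getattr(self, name)
            if value is not None and (not np.isfinite(value) or value <= 0.0):
                raise ValueError(f"{name} must be positive, got {value!r}")
        if not (0.0 < self.tr_short < self.tr_long <= self.tr_control):
            raise ValueError(
                "require 0 < tr_short < tr_long <= tr_control, got "
                f"{self.tr_short}, {self.tr_long}, {self.tr_control}"
            )

    def replace(self, **changes) -> "STSignals":
        return replace(self, **changes)

    def scaled(self, factor: float) -> "STSignals":
        """All signals multiplied by ``factor`` (TRs untouched)."""
        return self.replace(
            m0_control=self.m0_control * factor,
            m_long=self.m_long * factor,
            m_short=None if self.m_short is None else self.m_short * factor,
            m0=None if self.m0 is None else self.m0 * factor,
        )


@dataclass(frozen=True)
class CorrectionCoefficients:
    """Coefficients of the spill-over-corrected formulae.

    ``a..d`` correct the intrinsic T1, ``f..k`` the TRiST rate, ``l..n`` the
    TwiST rate.  Defaults are the published cardiac 3 T values fitted for the
    modulated-DANTE protocol; they are only valid for data acquired with that
    protocol over the fitted parameter range.
    """

    a: float = 4.2803
    b: float = -1.1344
    c: float = -1.6610
    d: float = 0.7862
    f: float = 0.0052
    g: float = -0.8730
    h: float = 27.5332
    k: float = -6.0647
    l: float = -0.2013
    m: float = -1.0305
    n: float = -1.6113

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if not np.isfinite(value):
                raise ValueError(f"coefficient {name} must be finite, got {value!r}")

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    @classmethod
    def from_dict(cls, data: dict) -> "CorrectionCoefficients":
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown coefficient names: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_json(cls, text: str) -> "CorrectionCoefficients":
        return cls.from_dict(json.loads(text))

    def replace(self, **changes) -> "CorrectionCoefficients":
        return replace(self, **changes)


TABLE_COEFFICIENTS = CorrectionCoefficients()


@dataclass(frozen=True)
class KineticEstimate:
    """Result of one estimator applied to one signal set."""

    kf: float
    method: str
    t1_prime: Optional[float] = None
    t1_intrinsic: Optional[float] = None
    q: Optional[float] = None
    q_raw: Optional[float] = None
    warnings: Tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not np.isfinite(self.kf):
            raise ValueError(f"kf must be finite, got {self.kf!r}")
        if self.q is not None and not (0.0 < self.q <= 1.0):
            raise ValueError(f"clipped q must lie in (0, 1], got {self.q!r}")


def q_ratio(s: STSignals) -> float:
    """Spill-over ratio Q = m0_control / m0, clipped at 1.

    Values above one (SNR fluctuations) are set to 1.0; the raw ratio is
    available from the signals directly.
    """
    if s.m0 is None:
        raise MissingSignalError("Q requires the unsaturated acquisition m0")
    return min(s.m0_control / s.m0, 1.0)


def _recovery_ratio(t1: float, tr_short: float, tr_long: float) -> float:
    return np.expm1(-tr_short / t1) / np.expm1(-tr_long / t1)


def dual_tr_fit(
    m_short: float,
    m_long: float,
    tr_short: float,
    tr_long: float,
    t1_bounds: Tuple[float, float] = (0.05, 50.0),
) -> Tuple[float, float]:
    """Estimate (T1', M0') from two saturation-recovery signals (dual-TR method).

    Solves ``m_short/m_long = (1-exp(-tr_short/T1'))/(1-exp(-tr_long/T1'))``
    for T1' by bracketed root finding; the ratio is monotone decreasing in T1'
    from 1 (T1'->0) to ``tr_short/tr_long`` (T1'->inf), so signals outside the
    open interval ``(tr_short/tr_long, 1)`` admit no solution and raise
    :class:`SignalModelError`.

    Returns ``(t1_prime [s], m0_prime [signal units])``.
    """
    if not (0.0 < tr_short < tr_long):
        raise ValueError("require 0 < tr_short < tr_long")
    if not (0.0 < m_short < m_long):
        raise SignalModelError(
            f"require 0 < m_short < m_long, got {m_short!r}, {m_long!r}"
        )
    r = m_short / m_long
    lo, hi = t1_bounds
    r_lo = _recovery_ratio(lo, tr_short, tr_long)
    r_hi = _recovery_ratio(hi, tr_short, tr_long)
    if not (r_hi < r < r_lo):
        raise SignalModelError(
            f"signal ratio {r:.4f} outside feasible interval "
            f"({r_hi:.4f}, {r_lo:.4f}) for T1' in {t1_bounds}"
        )
    t1p = brentq(
        lambda t1: _recovery_ratio(t1, tr_short, tr_long) - r, lo, hi, xtol=1e-10
    )
    m0p = m_long / -np.expm1(-tr_long / t1p)
    return t1p, m0p


def t1_intrinsic_apparent(t1_prime: float, m0_prime: float, m0_control: float) -> float:
    """Apparent intrinsic T1 of PCr: ``T1' * m0_control / M0'`` [s]."""
    if min(t1_prime, m0_prime, m0_control) <= 0:
        raise ValueError("all inputs must be positive")
    return t1_prime * m0_control / m0_prime


def _clipped_q(s: STSignals) -> Tuple[Optional[float], Optional[float]]:
    """(clipped, raw) Q when m0 is available, else (None, None)."""
    if s.m0 is None:
        return None, None
    raw = s.m0_control / s.m0
    return min(raw, 1.0), raw


def kf_trist(s: STSignals) -> KineticEstimate:
    """Three-acquisition TRiST estimate of k_f.

    T1' and M0' come from the dual-TR fit of the two gamma-ATP-saturated
    acquisitions; ``kf = (1/T1')(1 - M0'/m0_control)``.  Also reports the
    apparent intrinsic T1.  A non-positive rate (noise regime,
    M0' > m0_control) is returned flagged rather than raised so that Monte
    Carlo statistics can include it.
    """
    if s.m_short is None:
        raise MissingSignalError("TRiST requires the short-TR acquisition m_short")
    t1p, m0p = dual_tr_fit(s.m_short, s.m_long, s.tr_short, s.tr_long)
    kf = (1.0 / t1p) * (1.0 - m0p / s.m0_control)
    q, q_raw = _clipped_q(s)
    warnings = ("non-positive rate",) if kf <= 0 else ()
    return KineticEstimate(
        kf=kf,
        method="TRiST",
        t1_prime=t1p,
        t1_intrinsic=t1_intrinsic_apparent(t1p, m0p, s.m0_control),
        q=q,
        q_raw=q_raw,
        warnings=warnings,
    )


def kf_twist(
    s: STSignals, t1_intrinsic_assumed: float = DEFAULT_T1_INTRINSIC
) -> KineticEstimate:
    """Two-acquisition TwiST estimate of k_f with an assumed intrinsic T1.

    The short-TR acquisition is dropped; M0' is approximated by the long-TR
    saturated signal without truncation compensation, and
    ``kf = (1/T1_intrinsic)(m0_control/m_long - 1)``.
    """
    if t1_intrinsic_assumed <= 0:
        raise ValueError("t1_intrinsic_assumed must be positive")
    kf = (1.0 / t1_intrinsic_assumed) * (s.m0_control / s.m_long - 1.0)
    q, q_raw = _clipped_q(s)
    warnings = ("non-positive rate",) if kf <= 0 else ()
    return KineticEstimate(
        kf=kf,
        method="TwiST",
        t1_intrinsic=t1_intrinsic_assumed,
        q=q,
        q_raw=q_raw,
        warnings=warnings,
    )


def t1_q_intrinsic(
    s: STSignals,
    t1_prime: float,
    m0_prime: float,
    coeffs: CorrectionCoefficients = TABLE_COEFFICIENTS,
) -> float:
    """Spill-over-corrected intrinsic T1 [s].

    ``a (M0'/m0_control + b)(Q + c)(T1' + d)`` with Q clipped at 1.
    """
    q = q_ratio(s)
    return (
        coeffs.a
        * (m0_prime / s.m0_control + coeffs.b)
        * (q + coeffs.c)
        * (t1_prime + coeffs.d)
    )


def kf_q_trist(
    s: STSignals, coeffs: CorrectionCoefficients = TABLE_COEFFICIENTS
) -> KineticEstimate:
    """Q-corrected TRiST rate: ``f (M0'/m0_control + g)(Q + h)(T1' + k)``."""
    if s.m_short is None:
        raise MissingSignalError("Q-TRiST requires the short-TR acquisition m_short")
    t1p, m0p = dual_tr_fit(s.m_short, s.m_long, s.tr_short, s.tr_long)
    q, q_raw = _clipped_q(s)
    if q is None:
        raise MissingSignalError("Q-TRiST requires the unsaturated acquisition m0")
    kf = (
        coeffs.f
        * (m0p / s.m0_control + coeffs.g)
        * (q + coeffs.h)
        * (t1p + coeffs.k)
    )
    warnings = ("non-positive rate",) if kf <= 0 else ()
    return KineticEstimate(
        kf=kf,
        method="Q-TRiST",
        t1_prime=t1p,
        t1_intrinsic=t1_q_intrinsic(s, t1p, m0p, coeffs),
        q=q,
        q_raw=q_raw,
        warnings=warnings,
    )


def kf_q_twist(
    s: STSignals, coeffs: CorrectionCoefficients = TABLE_COEFFICIENTS
) -> KineticEstimate:
    """Q-corrected TwiST rate: ``l (m0_control/m_long + m)(Q + n)``.

    At Q = 1 this reduces to a TwiST formula with the equivalent intrinsic
    T1 ``1/(l (1 + n))`` and offset ``-m`` (see :func:`equivalent_twist_form`).
    """
    q, q_raw = _clipped_q(s)
    if q is None:
        raise MissingSignalError("Q-TwiST requires the unsaturated acquisition m0")
    kf = coeffs.l * (s.m0_control / s.m_long + coeffs.m) * (q + coeffs.n)
    warnings = ("non-positive rate",) if kf <= 0 else ()
    return KineticEstimate(
        kf=kf, method="Q-TwiST", q=q, q_raw=q_raw, warnings=warnings
    )


def equivalent_twist_form(
    coeffs: CorrectionCoefficients = TABLE_COEFFICIENTS,
) -> Tuple[float, float]:
    """Equivalent (intrinsic T1 [s], signal-ratio offset) of Q-TwiST at Q = 1.

    Expanding the corrected TwiST product at Q = 1 gives
    ``kf = l(1+n) * (m0_control/m_long + m)``, i.e. a plain TwiST form with
    ``T1_equivalent = 1/(l(1+n))`` and offset ``-m``.
    """
    scale = coeffs.l * (1.0 + coeffs.n)
    if scale == 0.0:
        raise ValueError("degenerate coefficients: l*(1+n) = 0")
    return 1.0 / scale, -coeffs.m
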