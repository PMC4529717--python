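"""Closed-form two-pool chemical-exchange relations for the creatine-kinase system.

The CK reaction PCr + ADP <-> ATP + Cr exchanges longitudinal magnetization
between the PCr and gamma-ATP resonances at a pseudo-first-order forward rate
``k_f``.  When gamma-ATP is held saturated, PCr relaxes with a shortened time
constant ``T1' = 1/(1/T1_intrinsic + k_f)`` toward a reduced steady state
``M0' = M0 * T1'/T1_intrinsic``.  These closed forms are the noise-free limit
of every saturation-transfer estimator in this package, and the no-RF limit of
the full Bloch-McConnell simulator in :mod:`ckst.bloch`.

All magnetizations are expressed relative to the PCr equilibrium value
(``m0_pcr`` defaults to 1.0); times are in seconds, rates in 1/s, frequencies
in Hz.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace
from typing import Tuple

import numpy as np
from scipy.linalg import expm

__all__ = [
    "ExchangeSystem",
    "t1_prime",
    "saturated_ratio",
    "saturated_recovery",
    "two_pool_recovery",
]


@dataclass(frozen=True)
class ExchangeSystem:
    """Two-pool CK exchange system (pool a = PCr, pool b = gamma-ATP).

    Parameters
    ----------
    m0_pcr, m0_atp:
        Equilibrium longitudinal magnetizations (arbitrary units; the PCr/ATP
        concentration ratio is ``m0_pcr / m0_atp``).
    t1_intrinsic_pcr, t1_intrinsic_atp:
        Intrinsic longitudinal relaxation times [s], i.e. the hypothetical T1
        of each pool in the absence of chemical exchange.
    t2_pcr, t2_atp:
        Transverse relaxation times [s].
    kf:
        Pseudo-first-order forward rate constant PCr -> gamma-ATP [1/s].
    delta_f:
        Chemical-shift separation between PCr and gamma-ATP [Hz]
        (130 Hz at 3 T, gamma-ATP at -2.5 ppm with PCr as reference).

    The reverse rate is never free: detailed balance fixes
    ``kr = kf * m0_pcr / m0_atp`` so that ``kf*m0_pcr == kr*m0_atp`` exactly.
    """

    m0_pcr: float = 1.0
    m0_atp: float = 1.0 / 1.5
    t1_intrinsic_pcr: float = 7.9
    t1_intrinsic_atp: float = 2.2
    t2_pcr: float = 0.25
    t2_atp: float = 0.05
    kf: float = 0.32
    delta_f: float = 130.0

    def __post_init__(self) -> None:
        for name in (
            "m0_pcr",
            "m0_atp",
            "t1_intrinsic_pcr",
            "t1_intrinsic_atp",
            "t2_pcr",
            "t2_atp",
            "kf",
            "delta_f",
        ):
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0.0:
                if name == "kf" and value == 0.0:
                    continue  # kf = 0 is the valid no-exchange limit
                raise ValueError(f"{name} must be strictly positive and finite, got {value!r}")

    @property
    def kr(self) -> float:
        """Reverse rate gamma-ATP -> PCr [1/s], from detailed balance."""
        return self.kf * self.m0_pcr / self.m0_atp

    @property
    def pcr_atp_ratio(self) -> float:
        return self.m0_pcr / self.m0_atp

    def replace(self, **changes) -> "ExchangeSystem":
        return replace(self, **changes)

    # --- flat-JSON serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=None, sort_keys=True)

    @classmethod
    def from_dict(cls, data: dict) -> "ExchangeSystem":
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown ExchangeSystem fields: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_json(cls, text: str) -> "ExchangeSystem":
        return cls.from_dict(json.loads(text))


def t1_prime(sys: ExchangeSystem) -> float:
    """PCr longitudinal relaxation time while gamma-ATP is saturated [s].

    ``1/T1' = 1/T1_intrinsic + k_f``; always shorter than the intrinsic T1
    for any nonzero exchange.
    """
    return 1.0 / (1.0 / sys.t1_intrinsic_pcr + sys.kf)


def saturated_ratio(sys: ExchangeSystem) -> float:
    """Steady-state PCr signal fraction ``M0'/M0`` under full gamma-ATP saturation.

    Equals ``T1'/T1_intrinsic``, in (0, 1].
    """
    return t1_prime(sys) / sys.t1_intrinsic_pcr


def saturated_recovery(sys: ExchangeSystem, tr: float) -> float:
    """PCr signal after saturation-recovery of duration ``tr`` with gamma-ATP saturated.

    Mono-exponential recovery from zero longitudinal magnetization toward the
    reduced steady state: ``M0' * (1 - exp(-tr/T1'))`` with
    ``M0' = m0_pcr * T1'/T1_intrinsic``.
    """
    if tr <= 0:
        raise ValueError(f"tr must be positive, got {tr!r}")
    t1p = t1_prime(sys)
    m0p = sys.m0_pcr * saturated_ratio(sys)
    return m0p * -np.expm1(-tr / t1p)


def _longitudinal_generator(sys: ExchangeSystem) -> Tuple[np.ndarray, np.ndarray]:
    """Longitudinal-only Bloch-McConnell generator ``dMz/dt = A Mz + b`` (no RF)."""
    kf, kr = sys.kf, sys.kr
    r1a = 1.0 / sys.t1_intrinsic_pcr
    r1b = 1.0 / sys.t1_intrinsic_atp
    A = np.array([[-r1a - kf, kr], [kf, -r1b - kr]])
    b = np.array([sys.m0_pcr * r1a, sys.m0_atp * r1b])
    return A, b


def two_pool_recovery(
    sys: ExchangeSystem, tr: float, start: Tuple[float, float] = (0.0, 0.0)
) -> np.ndarray:
    """Exact longitudinal recovery of the coupled (PCr, gamma-ATP) pair, no RF.

    Solves ``dMz/dt = A Mz + b`` with the exchange-coupled relaxation matrix
    via the 2x2 matrix exponential: ``Mz(tr) = M_eq + expm(A tr)(start - M_eq)``
    where the equilibrium ``M_eq = (m0_pcr, m0_atp)`` satisfies ``A M_eq + b = 0``
    by detailed balance.

    Returns ``array([Mz_pcr, Mz_atp])`` at time ``tr``.
    """
    if tr < 0:
        raise ValueError(f"tr must be non-negative, got {tr!r}")
    start = np.asarray(start, dtype=float)
    if tr == 0.0:
        return start.copy()
    A, _ = _longitudinal_generator(sys)
    m_eq = np.array([sys.m0_pcr, sys.m0_atp])
    return m_eq + expm(A * tr) @ (start - m_eq)
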