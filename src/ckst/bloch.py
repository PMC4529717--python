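"""Full Bloch-McConnell simulation of the saturation-transfer protocol.

The two-pool (PCr, gamma-ATP) magnetization evolves under exchange,
relaxation, and an amplitude-modulated DANTE saturation train: a comb of
short hard sub-pulses whose flip angles follow a cosine-sum envelope, so that
the small-tip frequency response consists of ``m`` saturation bands spaced
``delta`` Hz apart around the carrier.  Saturating at the gamma-ATP frequency
unavoidably bleeds onto PCr ("spill-over"); this module is the source of all
spill-over behaviour used to derive and evaluate the Q-corrected estimators.

The state is the 6-vector (Mx, My, Mz) of both pools.  Over each piecewise-
constant RF segment the evolution ``dM/dt = A M + b`` is solved exactly with
the matrix exponential of the homogeneous 7x7 generator ``[[A, b], [0, 0]]``.
Propagators are assembled per sub-pulse cycle, composed over one modulation
period, and powered over the repetition time; a readout is an ideal 90 deg
excitation with complete spoiling, so the periodic steady state starts each
TR from zero longitudinal magnetization.

Static-field (B0) inhomogeneity is emulated the way the protocol prescribes:
the saturation carrier is offset over a small grid and the per-offset signals
are averaged with Gaussian weights.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from functools import lru_cache
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .estimators import STSignals
from .exchange import ExchangeSystem, two_pool_recovery

__all__ = [
    "DanteTrain",
    "AcquisitionScheme",
    "B0Model",
    "DEFAULT_PROTOCOL",
    "subpulse_envelope",
    "interval_propagator",
    "steady_state_signal",
    "b0_weighted_signal",
    "simulate_protocol",
    "q_vs_beta_table",
    "beta_for_q",
]


# --------------------------------------------------------------------------- types


@dataclass(frozen=True)
class DanteTrain:
    """Amplitude-modulated DANTE saturation train.

    ``n_bands`` saturation bands separated by ``band_sep`` Hz around
    ``carrier_offset`` (Hz relative to PCr; -130 saturates gamma-ATP at 3 T,
    +130 is the mirrored control, 0 disables the train).  ``beta`` is the
    average flip per band accumulated per sub-pulse cycle, in degrees; the
    sub-pulse at time t has flip ``beta * sum_k cos(2 pi k band_sep t)`` with
    k over the band indices, so the envelope is signed (negative lobes are
    retained) and periodic with period ``1/band_sep``.
    """

    n_bands: int = 5
    band_sep: float = 9.0
    beta: float = 0.9
    subpulse_dur: float = 100e-6
    subpulse_gap: float = 0.91e-3
    carrier_offset: float = -130.0

    def __post_init__(self) -> None:
        if self.n_bands < 1 or self.n_bands % 2 == 0:
            raise ValueError(f"n_bands must be odd and >= 1, got {self.n_bands}")
        if self.subpulse_dur <= 0 or self.subpulse_gap <= 0:
            raise ValueError("subpulse_dur and subpulse_gap must be positive")
        if self.beta < 0:
            raise ValueError(f"beta must be non-negative, got {self.beta}")
        if self.n_bands > 1 and self.band_sep <= 0:
            raise ValueError("band_sep must be positive for a multi-band train")

    @property
    def cycle_dur(self) -> float:
        """Sub-pulse cycle duration [s]: hard pulse + inter-pulse gap."""
        return self.subpulse_dur + self.subpulse_gap

    @property
    def cycles_per_period(self) -> int:
        """Sub-pulse cycles per modulation period (1 for an unmodulated train).

        The modulation period is quantised to an integer cycle count so that
        one-period propagators can be powered exactly; with the nominal
        timing (9 Hz bands, 1.01 ms cycles) this shifts the band spacing by
        ~0.01%.
        """
        if self.n_bands == 1:
            return 1
        return max(1, round(1.0 / (self.band_sep * self.cycle_dur)))

    @property
    def active(self) -> bool:
        return self.beta > 0 and self.carrier_offset != 0

    def replace(self, **changes) -> "DanteTrain":
        return replace(self, **changes)


@dataclass(frozen=True)
class AcquisitionScheme:
    """One acquisition of the ST protocol: TR, saturation mode, averages."""

    tr: float
    saturation: str = "none"  # none | gamma_atp | control
    n_averages: int = 1

    def __post_init__(self) -> None:
        if self.tr <= 0:
            raise ValueError(f"tr must be positive, got {self.tr}")
        if self.saturation not in ("none", "gamma_atp", "control"):
            raise ValueError(f"unknown saturation mode {self.saturation!r}")
        if self.n_averages < 1:
            raise ValueError("n_averages must be >= 1")


#: The cardiac-gated human protocol: unsaturated M0, control, and the two
#: gamma-ATP-saturated acquisitions (long and short TR).
DEFAULT_PROTOCOL: Tuple[AcquisitionScheme, ...] = (
    AcquisitionScheme(16.0, "none", 2),
    AcquisitionScheme(16.0, "control", 2),
    AcquisitionScheme(10.0, "gamma_atp", 8),
    AcquisitionScheme(1.7, "gamma_atp", 18),
)


@dataclass(frozen=True)
class B0Model:
    """Static-field-offset grid with Gaussian weighting of the saturation carrier."""

    offsets: Tuple[float, ...] = (-20.0, -15.0, -10.0, -5.0, 0.0, 5.0, 10.0, 15.0, 20.0)
    fwhm: float = 20.0

    def __post_init__(self) -> None:
        if len(self.offsets) < 1:
            raise ValueError("need at least one offset")
        if self.fwhm <= 0:
            raise ValueError("fwhm must be positive")

    @property
    def weights(self) -> np.ndarray:
        """Gaussian weights over the offsets, normalised to sum to one."""
        x = np.asarray(self.offsets, dtype=float)
        w = np.exp(-4.0 * np.log(2.0) * (x / self.fwhm) ** 2)
        return w / w.sum()


#: Single-offset model (no B0 averaging), convenient for quick simulations.
SINGLE_OFFSET = B0Model(offsets=(0.0,), fwhm=20.0)


# ------------------------------------------------------------------- RF envelope


def subpulse_envelope(train: DanteTrain, t) -> np.ndarray:
    """Flip angle [deg] of the hard sub-pulse centred at time ``t`` [s].

    The cosine-sum (Dirichlet-kernel) envelope
    ``beta * sum_{k=-(m-1)/2}^{(m-1)/2} cos(2 pi k band_sep t)`` gives each of
    the ``m`` bands a demodulated time-average flip of exactly ``beta`` per
    sub-pulse cycle.  Signed values are returned (negative lobes retained).
    """
    t = np.asarray(t, dtype=float)
    half = (train.n_bands - 1) // 2
    w = np.ones_like(t)
    for k in range(1, half + 1):
        w = w + 2.0 * np.cos(2.0 * np.pi * k * train.band_sep * t)
    return train.beta * w


def _envelope_flips(train: DanteTrain) -> np.ndarray:
    """Per-cycle sub-pulse flips [deg] over one (quantised) modulation period."""
    n = train.cycles_per_period
    if train.n_bands == 1:
        return np.full(1, train.beta)
    # evaluate the envelope at the sub-pulse centres with the band spacing
    # quantised to the cycle grid, so cycle j = n behaves exactly like j = 0
    phases = (np.arange(n) + 0.5 * train.subpulse_dur / train.cycle_dur) / n
    half = (train.n_bands - 1) // 2
    w = np.ones(n)
    for k in range(1, half + 1):
        w = w + 2.0 * np.cos(2.0 * np.pi * k * phases)
    return train.beta * w


# ------------------------------------------------------- generators & exponentials

# Pade-13 coefficients for the scaling-and-squaring matrix exponential
_PADE13 = (
    64764752532480000.0,
    32382376266240000.0,
    7771770303897600.0,
    1187353796428800.0,
    129060195264000.0,
    10559470521600.0,
    670442572800.0,
    33522128640.0,
    1323241920.0,
    40840800.0,
    960960.0,
    16380.0,
    182.0,
    1.0,
)
_THETA13 = 4.25


def _expm_batch(a: np.ndarray) -> np.ndarray:
    """Matrix exponential of a stack ``(..., n, n)`` of real matrices.

    Scaling-and-squaring with a degree-13 Pade approximant, applied with a
    common scaling chosen from the largest infinity norm in the stack.  The
    generators handled here have norms of order one, so at most a few
    squarings occur.
    """
    a = np.asarray(a, dtype=float)
    norm = float(np.abs(a).sum(axis=-1).max()) if a.size else 0.0
    s = max(0, int(math.ceil(math.log2(norm / _THETA13)))) if norm > _THETA13 else 0
    a = a / (2.0**s)
    b = _PADE13
    eye = np.broadcast_to(np.eye(a.shape[-1]), a.shape)
    a2 = a @ a
    a4 = a2 @ a2
    a6 = a2 @ a4
    u = a @ (
        a6 @ (b[13] * a6 + b[11] * a4 + b[9] * a2)
        + b[7] * a6
        + b[5] * a4
        + b[3] * a2
        + b[1] * eye
    )
    v = (
        a6 @ (b[12] * a6 + b[10] * a4 + b[8] * a2)
        + b[6] * a6
        + b[4] * a4
        + b[2] * a2
        + b[0] * eye
    )
    r = np.linalg.solve(v - u, v + u)
    for _ in range(s):
        r = r @ r
    return r


def _homogeneous_generator(
    sys: ExchangeSystem, f_rf: float, omega1: np.ndarray
) -> np.ndarray:
    """Stack of 7x7 generators ``d(M, 1)/dt`` for RF amplitudes ``omega1`` [rad/s].

    The rotating frame is locked to the RF carrier at ``f_rf`` Hz (relative to
    PCr), so PCr precesses at ``-2 pi f_rf`` and gamma-ATP at
    ``-2 pi (f_rf + delta_f)``.  Exchange moves all three magnetization
    components between the pools at rates kf (PCr->ATP) and kr.
    """
    omega1 = np.atleast_1d(np.asarray(omega1, dtype=float))
    n = omega1.shape[0]
    kf, kr = sys.kf, sys.kr
    w_a = 2.0 * np.pi * (0.0 - f_rf)
    w_b = 2.0 * np.pi * (-sys.delta_f - f_rf)
    g = np.zeros((n, 7, 7))
    # pool a (PCr): rows 0..2
    g[:, 0, 0] = -1.0 / sys.t2_pcr - kf
    g[:, 0, 1] = w_a
    g[:, 1, 0] = -w_a
    g[:, 1, 1] = -1.0 / sys.t2_pcr - kf
    g[:, 1, 2] = omega1
    g[:, 2, 1] = -omega1
    g[:, 2, 2] = -1.0 / sys.t1_intrinsic_pcr - kf
    g[:, 2, 6] = sys.m0_pcr / sys.t1_intrinsic_pcr
    # pool b (gamma-ATP): rows 3..5
    g[:, 3, 3] = -1.0 / sys.t2_atp - kr
    g[:, 3, 4] = w_b
    g[:, 4, 3] = -w_b
    g[:, 4, 4] = -1.0 / sys.t2_atp - kr
    g[:, 4, 5] = omega1
    g[:, 5, 4] = -omega1
    g[:, 5, 5] = -1.0 / sys.t1_intrinsic_atp - kr
    g[:, 5, 6] = sys.m0_atp / sys.t1_intrinsic_atp
    # exchange cross terms (x, y, z alike)
    for i in range(3):
        g[:, 3 + i, i] += kf
        g[:, i, 3 + i] += kr
    return g


def interval_propagator(
    sys: ExchangeSystem, rf_amp: float, rf_offset: float, dt: float
) -> Tuple[np.ndarray, np.ndarray]:
    """Exact affine propagator over a piecewise-constant RF interval.

    ``rf_amp`` is the RF nutation frequency in Hz (flip rate ``2 pi rf_amp``
    rad/s), ``rf_offset`` the carrier frequency in Hz relative to PCr.
    Returns ``(matrix, vector)`` such that ``M(t+dt) = matrix @ M(t) + vector``
    on the 6-component magnetization.
    """
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    g = _homogeneous_generator(sys, rf_offset, 2.0 * np.pi * rf_amp)[0]
    e = _expm_batch(g * dt)
    if not np.all(np.isfinite(e)):
        raise FloatingPointError("propagator exponential did not evaluate finitely")
    return e[:6, :6], e[:6, 6]


# ------------------------------------------------------------ period machinery


def _prefix_maps(
    sys: ExchangeSystem, train: DanteTrain, f_rf_values: Sequence[float]
) -> np.ndarray:
    """Cumulative homogeneous maps over one modulation period, per carrier offset.

    Returns ``pref`` of shape ``(F, n_per + 1, 7, 7)`` where ``pref[o, j]``
    propagates the state through the first ``j`` sub-pulse cycles (pulse then
    gap) at carrier ``f_rf_values[o]``; ``pref[o, -1]`` is the one-period map.
    """
    flips_deg = _envelope_flips(train)
    omega1 = np.deg2rad(flips_deg) / train.subpulse_dur
    n_per = omega1.shape[0]
    f_rf_values = list(f_rf_values)
    n_f = len(f_rf_values)

    pulse_gens = np.empty((n_f, n_per, 7, 7))
    gap_gens = np.empty((n_f, 1, 7, 7))
    for i, f_rf in enumerate(f_rf_values):
        pulse_gens[i] = _homogeneous_generator(sys, f_rf, omega1)
        gap_gens[i] = _homogeneous_generator(sys, f_rf, np.zeros(1))
    pulse_props = _expm_batch(
        pulse_gens.reshape(n_f * n_per, 7, 7) * train.subpulse_dur
    ).reshape(n_f, n_per, 7, 7)
    gap_props = _expm_batch(gap_gens.reshape(n_f, 7, 7) * train.subpulse_gap)

    pref = np.empty((n_f, n_per + 1, 7, 7))
    cur = np.broadcast_to(np.eye(7), (n_f, 7, 7)).copy()
    pref[:, 0] = cur
    for j in range(n_per):
        cur = gap_props @ (pulse_props[:, j] @ cur)
        pref[:, j + 1] = cur
    return pref


def _free_propagator(sys: ExchangeSystem, f_rf: float, dt: float) -> np.ndarray:
    if dt <= 0:
        return np.eye(7)
    g = _homogeneous_generator(sys, f_rf, np.zeros(1))[0]
    return _expm_batch(g * dt)


def _tr_signal_from_prefix(
    sys: ExchangeSystem,
    train: DanteTrain,
    pref: np.ndarray,
    f_rf: float,
    tr: float,
) -> float:
    """PCr longitudinal signal at readout after one TR of saturation from zero start."""
    n_per = pref.shape[0] - 1
    cycle = train.cycle_dur
    n_cycles = int(math.floor(tr / cycle + 1e-9))
    n_periods, n_rem = divmod(n_cycles, n_per)
    leftover = tr - n_cycles * cycle
    t_map = np.linalg.matrix_power(pref[-1], n_periods)
    t_map = pref[n_rem] @ t_map
    if leftover > 1e-12:
        t_map = _free_propagator(sys, f_rf, leftover) @ t_map
    if not np.all(np.isfinite(t_map)):
        raise FloatingPointError("per-TR propagator did not evaluate finitely")
    # ideal 90 deg readout with complete spoiling: the periodic steady state
    # starts every TR from zero magnetization, so the readout value is the
    # inhomogeneous (drive) part of the affine per-TR map
    return float(t_map[2, 6])


@lru_cache(maxsize=512)
def _cached_prefix(
    sys: ExchangeSystem, train: DanteTrain, f_rf: float
) -> np.ndarray:
    return _prefix_maps(sys, train, [f_rf])[0]


def steady_state_signal(
    sys: ExchangeSystem, train: Optional[DanteTrain], tr: float, b0_offset: float = 0.0
) -> float:
    """Steady-state PCr signal (units of ``m0_pcr``) for one TR and one B0 offset.

    Saturation is applied throughout the TR; readout is an ideal 90 deg
    excitation with complete spoiling of both pools before the next TR, so
    the fixed point of the spoiled per-TR affine map is recovery from zero.
    With the train disabled this is exactly the closed-form two-pool recovery.
    """
    if train is None or not train.active:
        return float(two_pool_recovery(sys, tr, (0.0, 0.0))[0])
    period = train.cycles_per_period * train.cycle_dur
    if tr < period:
        raise ValueError(
            f"tr = {tr} s is shorter than one modulation period ({period:.4f} s)"
        )
    f_rf = train.carrier_offset + b0_offset
    pref = _cached_prefix(sys, train, f_rf)
    return _tr_signal_from_prefix(sys, train, pref, f_rf, tr)


def b0_weighted_signal(
    sys: ExchangeSystem, train: Optional[DanteTrain], tr: float, b0: B0Model
) -> float:
    """Gaussian-weighted average of :func:`steady_state_signal` over the B0 grid."""
    signals = [steady_state_signal(sys, train, tr, off) for off in b0.offsets]
    return float(b0.weights @ np.asarray(signals))


# ---------------------------------------------------------------- full protocol


def _weighted_signals(
    sys: ExchangeSystem,
    train: DanteTrain,
    carrier: float,
    trs: Sequence[float],
    b0: B0Model,
) -> list:
    """B0-weighted signals for several TRs sharing one saturation carrier."""
    f_rf_values = [carrier + off for off in b0.offsets]
    pref = _prefix_maps(sys, train, f_rf_values)
    weights = b0.weights
    out = []
    for tr in trs:
        vals = np.array(
            [
                _tr_signal_from_prefix(sys, train, pref[i], f_rf_values[i], tr)
                for i in range(len(f_rf_values))
            ]
        )
        out.append(float(weights @ vals))
    return out


def simulate_protocol(
    sys: ExchangeSystem,
    train: DanteTrain,
    b0: B0Model = B0Model(),
    protocol: Sequence[AcquisitionScheme] = DEFAULT_PROTOCOL,
) -> STSignals:
    """Simulate the (up to) four-acquisition ST protocol.

    The ``gamma_atp`` acquisitions use the train's own carrier; ``control``
    mirrors it to the opposite side of PCr.  Returns the PCr signals bundled
    with their TRs; ``m_short`` is ``None`` when the protocol holds a single
    gamma-ATP acquisition (TwiST-style).
    """
    sat = sorted((s.tr for s in protocol if s.saturation == "gamma_atp"), reverse=True)
    ctl = [s.tr for s in protocol if s.saturation == "control"]
    uns = [s.tr for s in protocol if s.saturation == "none"]
    if len(ctl) != 1 or len(uns) != 1 or len(sat) not in (1, 2):
        raise ValueError(
            "protocol must hold one unsaturated, one control and one or two "
            "gamma-ATP-saturated acquisitions"
        )
    m0 = float(two_pool_recovery(sys, uns[0], (0.0, 0.0))[0])
    if not train.active:
        m0_control = float(two_pool_recovery(sys, ctl[0], (0.0, 0.0))[0])
        sat_vals = [float(two_pool_recovery(sys, tr, (0.0, 0.0))[0]) for tr in sat]
    else:
        control_train = train.replace(carrier_offset=-train.carrier_offset)
        (m0_control,) = _weighted_signals(
            sys, control_train, control_train.carrier_offset, ctl, b0
        )
        sat_vals = _weighted_signals(sys, train, train.carrier_offset, sat, b0)
    return STSignals(
        m0=m0,
        m0_control=m0_control,
        m_long=sat_vals[0],
        m_short=sat_vals[1] if len(sat_vals) == 2 else None,
        tr_control=ctl[0],
        tr_long=sat[0],
        tr_short=sat[1] if len(sat) == 2 else min(1.7, sat[0] / 2),
    )


def q_vs_beta_table(
    sys: ExchangeSystem,
    b0: B0Model = B0Model(),
    betas: Sequence[float] = tuple(np.linspace(0.1, 6.0, 13)),
    train: DanteTrain = DanteTrain(),
    tr: float = 16.0,
) -> pd.DataFrame:
    """Calibration table of spill-over ratio Q versus DANTE flip angle beta.

    Q is computed from the simulated control and unsaturated signals at the
    given TR; the table (sorted by beta) supports inverting a target Q to the
    train amplitude that produces it (:func:`beta_for_q`).
    """
    if len(betas) == 0:
        raise ValueError("betas must be non-empty")
    m0 = float(two_pool_recovery(sys, tr, (0.0, 0.0))[0])
    rows = []
    for beta in sorted(betas):
        if beta == 0:
            q = 1.0
        else:
            control = train.replace(beta=float(beta), carrier_offset=abs(train.carrier_offset))
            m0_control = b0_weighted_signal(sys, control, tr, b0)
            q = min(m0_control / m0, 1.0)
        rows.append({"beta": float(beta), "q": q})
    return pd.DataFrame(rows)


def beta_for_q(table: pd.DataFrame, q: float) -> float:
    """Invert a Q-vs-beta calibration table by monotone interpolation.

    Values of ``q`` outside the table's range are clipped to its ends.
    """
    t = table.sort_values("q")
    return float(np.interp(q, t["q"].to_numpy(), t["beta"].to_numpy()))
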