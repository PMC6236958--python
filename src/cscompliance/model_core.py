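"""Lumped-parameter cranio-spinal circuit model.

The cranio-spinal (CS) system is modelled as a second-order linear circuit:
the net transcranial blood flow Q_A-V (arterial inflow minus venous outflow,
mL/s) drives oscillatory CSF flow Q_CSF (mL/s) between the cranium and the
spinal canal.  The circuit elements are two flow resistances (cranial R_C,
spinal R_S), two compliances (cranial C_C, spinal C_S) and the inertance L_S
of the CSF column entering the spinal canal.

The continuous transfer function is

    H(s) = Q_CSF(s) / Q_A-V(s)
         = (s*R_C/L_S + 1/(C_C*L_S)) / (s^2 + s*(R_C+R_S)/L_S + (1/C_C + 1/C_S)/L_S)

whose dc gain H(0) = C_S/(C_C+C_S) is the spinal share of total cranio-spinal
compliance — the quantity of clinical interest.  Its discrete counterpart,
obtained by pole-zero matched discretization at the cine sampling interval T,
is

    H(z) = (p1*z + p2) / (z^2 + q1*z + q2)

and shares the same dc gain at z = 1.  This module houses the physical
parameter container, both transfer-function representations, pole/stability
computations, the discretization, and a forward simulator producing the
periodic steady-state CSF response to a cyclic blood-flow input.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

from .errors import (
    DegenerateGainError,
    InvalidParameterError,
    UnstableModelError,
)

__all__ = [
    "PhysicalParameters",
    "ContinuousTF",
    "DiscreteQuartet",
    "CardiacCycleData",
    "continuous_transfer_function",
    "continuous_dc_gain",
    "poles_of",
    "is_stable",
    "discrete_dc_gain",
    "discretize_pole_zero_matched",
    "simulate_csf_response",
]


@dataclass(frozen=True)
class PhysicalParameters:
    """The five elements of the cranio-spinal circuit analog.

    Attributes
    ----------
    r_c : float
        Cranial flow resistance, mmHg*s/mL.
    r_s : float
        Spinal flow resistance, mmHg*s/mL.
    c_c : float
        Cranial compliance, mL/mmHg.
    c_s : float
        Spinal compliance, mL/mmHg.
    l_s : float
        Inertance of the CSF column, mmHg*s^2/mL.
    """

    r_c: float
    r_s: float
    c_c: float
    c_s: float
    l_s: float

    def __post_init__(self) -> None:
        for name in ("r_c", "r_s", "c_c", "c_s", "l_s"):
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and math.isfinite(v) and v > 0):
                raise InvalidParameterError(
                    f"{name} must be strictly positive and finite, got {v!r}"
                )

    @property
    def spinal_fraction(self) -> float:
        """C_S/(C_C+C_S), the spinal share of total compliance."""
        return self.c_s / (self.c_c + self.c_s)


@dataclass(frozen=True)
class ContinuousTF:
    """H(s) = (b1*s + b0)/(s^2 + a1*s + a0), coefficient form.

    ``num = (b1, b0)``, ``den = (a1, a0)``.  Built from a valid
    :class:`PhysicalParameters` all four coefficients are positive.
    """

    num: tuple[float, float]
    den: tuple[float, float]

    @property
    def dc_gain(self) -> float:
        """H(0) = b0/a0."""
        return self.num[1] / self.den[1]

    def poles(self) -> np.ndarray:
        """Roots of s^2 + a1*s + a0, as a length-2 complex array."""
        a1, a0 = self.den
        return np.roots([1.0, a1, a0]).astype(complex)


@dataclass(frozen=True)
class DiscreteQuartet:
    """Coefficients (p1, p2, q1, q2) of H(z) = (p1*z + p2)/(z^2 + q1*z + q2)."""

    p1: float
    p2: float
    q1: float
    q2: float

    def poles(self) -> tuple[complex, complex]:
        return poles_of(self.q1, self.q2)

    @property
    def stable(self) -> bool:
        return is_stable(self.q1, self.q2)


@dataclass(frozen=True)
class CardiacCycleData:
    """Paired periodic waveforms over one cardiac cycle.

    ``q_av`` is net transcranial blood flow and ``q_csf`` cervical CSF flow,
    both in mL/s, sampled at ``frame_count`` uniform phases of a cycle lasting
    ``cycle_duration`` seconds (cine MRI convention, default 32 frames).
    """

    q_av: np.ndarray
    q_csf: np.ndarray
    cycle_duration: float
    frame_count: int = field(default=0)  # 0 -> inferred from q_av

    def __post_init__(self) -> None:
        q_av = np.asarray(self.q_av, dtype=float)
        q_csf = np.asarray(self.q_csf, dtype=float)
        object.__setattr__(self, "q_av", q_av)
        object.__setattr__(self, "q_csf", q_csf)
        n = self.frame_count if self.frame_count else len(q_av)
        object.__setattr__(self, "frame_count", int(n))
        if len(q_av) != n or len(q_csf) != n:
            raise InvalidParameterError(
                f"waveform lengths ({len(q_av)}, {len(q_csf)}) must both equal "
                f"frame_count ({n})"
            )
        if n < 8:
            raise InvalidParameterError(f"frame_count must be >= 8, got {n}")
        if not (math.isfinite(self.cycle_duration) and self.cycle_duration > 0):
            raise InvalidParameterError(
                f"cycle_duration must be positive, got {self.cycle_duration!r}"
            )
        if not (np.isfinite(q_av).all() and np.isfinite(q_csf).all()):
            raise InvalidParameterError("waveforms contain non-finite values")

    @property
    def sampling_interval(self) -> float:
        """T = cycle_duration / frame_count, seconds per frame."""
        return self.cycle_duration / self.frame_count


def continuous_transfer_function(params: PhysicalParameters) -> ContinuousTF:
    """Build H(s) from the circuit elements.

    b1 = R_C/L_S, b0 = 1/(C_C*L_S), a1 = (R_C+R_S)/L_S,
    a0 = (1/C_C + 1/C_S)/L_S.
    """
    b1 = params.r_c / params.l_s
    b0 = 1.0 / (params.c_c * params.l_s)
    a1 = (params.r_c + params.r_s) / params.l_s
    a0 = (1.0 / params.c_c + 1.0 / params.c_s) / params.l_s
    return ContinuousTF(num=(b1, b0), den=(a1, a0))


def continuous_dc_gain(params: PhysicalParameters) -> float:
    """Spinal share of total compliance, H(0) = C_S/(C_C+C_S) in (0, 1)."""
    return params.spinal_fraction


def poles_of(q1: float, q2: float) -> tuple[complex, complex]:
    """Both roots of z^2 + q1*z + q2 = 0 by the quadratic formula.

    Returns a complex-conjugate pair when q1^2 < 4*q2.
    """
    disc = complex(q1 * q1 - 4.0 * q2)
    root = np.sqrt(disc)
    return ((-q1 + root) / 2.0, (-q1 - root) / 2.0)


def is_stable(q1: float, q2: float) -> bool:
    """True iff both poles of z^2 + q1*z + q2 lie strictly inside the unit circle.

    A pole with modulus exactly 1 counts as unstable (strict inequality).
    """
    zp = poles_of(q1, q2)
    return bool(max(abs(zp[0]), abs(zp[1])) < 1.0)


def discrete_dc_gain(quartet: DiscreteQuartet) -> float:
    """H(z=1) = (p1+p2)/(1+q1+q2), the candidate compliance ratio."""
    den = 1.0 + quartet.q1 + quartet.q2
    if den == 0.0:
        raise DegenerateGainError("H(z) has a pole at z=1; dc gain undefined")
    return (quartet.p1 + quartet.p2) / den


def discretize_pole_zero_matched(
    tf: ContinuousTF, sampling_interval: float
) -> DiscreteQuartet:
    """Pole-zero matched discretization of H(s) at sampling interval T.

    Each continuous pole s_i maps to exp(s_i*T); the single continuous zero
    s_z = -b0/b1 maps to exp(s_z*T); the gain is then fixed so that
    H(z=1) equals the continuous dc gain b0/a0 exactly.  The physical circuit
    always has strictly stable continuous poles (Re < 0), so the resulting
    quartet is stable.
    """
    if not sampling_interval > 0:
        raise InvalidParameterError(
            f"sampling_interval must be positive, got {sampling_interval!r}"
        )
    T = float(sampling_interval)
    b1, b0 = tf.num
    s_poles = tf.poles()
    if np.any(s_poles.real >= 0):
        raise UnstableModelError(
            f"continuous poles {s_poles} are not strictly in the left half-plane"
        )
    z_poles = np.exp(s_poles * T)
    q1 = float(-(z_poles[0] + z_poles[1]).real)
    q2 = float((z_poles[0] * z_poles[1]).real)
    s_zero = -b0 / b1
    z_zero = math.exp(s_zero * T)
    # Gain k in H(z) = k*(z - z_zero)/((z-z1)(z-z2)); choose k so H(1) = b0/a0.
    dc = tf.dc_gain
    k = dc * (1.0 + q1 + q2) / (1.0 - z_zero)
    return DiscreteQuartet(p1=k, p2=-k * z_zero, q1=q1, q2=q2)


def simulate_csf_response(
    quartet: DiscreteQuartet,
    q_av: np.ndarray,
    max_cycles: int = 500,
    tol: float = 1e-10,
) -> np.ndarray:
    """Periodic steady-state CSF flow response to a cyclic blood-flow input.

    Runs the difference equation

        Q_CSF(n) = -q1*Q_CSF(n-1) - q2*Q_CSF(n-2)
                   + p1*Q_A-V(n-1) + p2*Q_A-V(n-2)

    from zero initial state with the input repeated cyclically, one whole
    cycle at a time, until the output cycle changes by less than ``tol``
    (max absolute difference between consecutive cycles) or ``max_cycles``
    is reached.  Returns one steady-state cycle; the start-up transient is
    discarded, matching the cine-MRI convention of an averaged periodic beat.
    """
    q_av = np.asarray(q_av, dtype=float)
    if q_av.size == 0:
        raise InvalidParameterError("q_av must be non-empty")
    if not quartet.stable:
        raise UnstableModelError(
            f"quartet (q1={quartet.q1}, q2={quartet.q2}) is unstable; "
            "the recursion would diverge"
        )
    b = [0.0, quartet.p1, quartet.p2]
    a = [1.0, quartet.q1, quartet.q2]
    zi = np.zeros(2)
    prev = np.full_like(q_av, np.inf)
    out = prev
    for _ in range(max_cycles):
        out, zi = lfilter(b, a, q_av, zi=zi)
        if np.max(np.abs(out - prev)) < tol:
            break
        prev = out
    return out
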