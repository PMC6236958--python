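"""Synthetic cardiac-cycle waveforms and virtual cohorts.

Generates physiologically shaped arterial/venous/CSF flow waveforms from
known circuit parameters so every estimator path can be verified by
parameter recovery without MRI data.  The arterial pulse is a gamma-shaped
systolic wave on a baseline; venous outflow is the arterial waveform
dispersed by a causal smoothing kernel and cyclically delayed, rescaled so
the net blood volume over a full cycle is exactly zero (Monro-Kellie
conservation).  The CSF response is the periodic steady-state output of the
discretized cranio-spinal circuit, optionally plus Gaussian measurement
noise.

Absolute element magnitudes are not identifiable from flow data (only the
compliance ratio is); the defaults below are chosen once so that simulated
CSF stroke volumes land in the plausible 0.3-1.0 mL/cycle range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .errors import InvalidParameterError
from .model_core import (
    CardiacCycleData,
    PhysicalParameters,
    continuous_dc_gain,
    continuous_transfer_function,
    discretize_pole_zero_matched,
    simulate_csf_response,
)

__all__ = [
    "WaveformSpec",
    "SyntheticSubject",
    "DEFAULT_PARAMS",
    "params_for_spinal_fraction",
    "generate_cardiac_input",
    "generate_subject",
    "generate_cohort",
]

# Default circuit: spinal fraction 0.75; natural frequency ~1.8 Hz (just
# above the cardiac fundamental) at moderate damping (zeta ~ 0.45), so the
# CSF waveform visibly lags and reshapes relative to the blood waveform —
# a flat-gain circuit would make the inverse problem degenerate.
# Units: mmHg*s/mL, mL/mmHg, mmHg*s^2/mL.
DEFAULT_PARAMS = PhysicalParameters(r_c=0.3, r_s=0.2, c_c=0.2, c_s=0.6, l_s=0.05)

# Shape constants of the invented waveform (fractions of the cycle):
_PULSE_PEAK_FRACTION = 0.18  # systolic peak position
_PULSE_SHARPNESS = 12.0  # gamma exponent; sharp upstroke -> rich harmonics
_VENOUS_SMOOTH_FRACTION = 0.06  # causal dispersion kernel width
_ARTERIAL_BASELINE = 12.0  # mean cerebral arterial inflow, mL/s


@dataclass(frozen=True)
class WaveformSpec:
    """Acquisition-like description of one synthetic cardiac cycle.

    heart_rate in beats/min; arterial_peak is the amplitude of the pulsatile
    systolic component above baseline (mL/s); venous_delay_fraction the lag
    of venous outflow behind arterial inflow as a fraction of the cycle;
    noise_sd additive Gaussian noise on each CSF sample (mL/s).
    """

    heart_rate: float = 70.0
    frame_count: int = 32
    arterial_peak: float = 8.0
    venous_delay_fraction: float = 0.08
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 40.0 <= self.heart_rate <= 180.0:
            raise InvalidParameterError(
                f"heart_rate must be in [40, 180] bpm, got {self.heart_rate!r}"
            )
        if not 0.0 <= self.venous_delay_fraction <= 0.3:
            raise InvalidParameterError(
                "venous_delay_fraction must be in [0, 0.3], got "
                f"{self.venous_delay_fraction!r}"
            )
        if self.noise_sd < 0:
            raise InvalidParameterError(f"noise_sd must be >= 0, got {self.noise_sd!r}")
        if self.frame_count < 8:
            raise InvalidParameterError(
                f"frame_count must be >= 8, got {self.frame_count!r}"
            )
        if self.arterial_peak <= 0:
            raise InvalidParameterError(
                f"arterial_peak must be positive, got {self.arterial_peak!r}"
            )

    @property
    def cycle_duration(self) -> float:
        return 60.0 / self.heart_rate

    @property
    def sampling_interval(self) -> float:
        return self.cycle_duration / self.frame_count


@dataclass(frozen=True)
class SyntheticSubject:
    """One virtual subject: waveforms plus the generating ground truth."""

    cycle: CardiacCycleData
    truth_params: PhysicalParameters
    truth_spinal_percent: int
    age: int = 30
    sex: str = "F"
    pseudo_mr_icp: float | None = None
    arterial: np.ndarray | None = None
    venous: np.ndarray | None = None
    subject_id: str = "synthetic"


def params_for_spinal_fraction(
    spinal_fraction: float,
    total_compliance: float = 0.8,
    base: PhysicalParameters = DEFAULT_PARAMS,
) -> PhysicalParameters:
    """Circuit with a prescribed C_S/(C_C+C_S), other elements from ``base``."""
    if not 0.0 < spinal_fraction < 1.0:
        raise InvalidParameterError(
            f"spinal_fraction must be in (0, 1), got {spinal_fraction!r}"
        )
    return replace(
        base,
        c_s=spinal_fraction * total_compliance,
        c_c=(1.0 - spinal_fraction) * total_compliance,
    )


def generate_cardiac_input(
    spec: WaveformSpec,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Arterial inflow, venous outflow and their difference Q_A-V, mL/s.

    Arterial: baseline plus a gamma-shaped systolic pulse peaking at
    ~18% of the cycle.  Venous: the arterial waveform circularly convolved
    with a causal half-Hann kernel (dispersion through the venous bed) and
    cyclically delayed by ``venous_delay_fraction``, rescaled so that the
    venous and arterial cycle sums are identical — net transcranial blood
    volume change per cycle is exactly zero.
    """
    n = spec.frame_count
    u = np.arange(n) / n  # normalised cardiac phase in [0, 1)
    um, a = _PULSE_PEAK_FRACTION, _PULSE_SHARPNESS
    pulse = (u / um) ** a * np.exp(a * (1.0 - u / um))  # peak 1 at u = um
    arterial = _ARTERIAL_BASELINE + spec.arterial_peak * pulse

    width = max(2, int(round(_VENOUS_SMOOTH_FRACTION * n)))
    kernel = np.zeros(n)
    ramp = np.hanning(2 * width + 1)[width:]  # causal half-window
    kernel[: width + 1] = ramp / ramp.sum()
    venous = np.real(np.fft.ifft(np.fft.fft(arterial) * np.fft.fft(kernel)))
    venous = np.roll(venous, int(round(spec.venous_delay_fraction * n)))
    venous *= arterial.sum() / venous.sum()

    q_av = arterial - venous
    return arterial, venous, q_av


def generate_subject(
    params: PhysicalParameters,
    spec: WaveformSpec,
    age: int = 30,
    sex: str = "F",
    pseudo_mr_icp: float | None = None,
    subject_id: str = "synthetic",
) -> SyntheticSubject:
    """Forward-simulate one subject from known circuit parameters.

    Builds the blood-flow input, discretizes H(s) at the cine sampling
    interval T = 60/(heart_rate*frame_count), simulates the steady-state CSF
    response and adds seeded Gaussian noise of SD ``spec.noise_sd``.
    """
    arterial, venous, q_av = generate_cardiac_input(spec)
    tf = continuous_transfer_function(params)
    quartet = discretize_pole_zero_matched(tf, spec.sampling_interval)
    q_csf = simulate_csf_response(quartet, q_av)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        q_csf = q_csf + rng.normal(0.0, spec.noise_sd, size=q_csf.shape)
    cycle = CardiacCycleData(
        q_av=q_av, q_csf=q_csf, cycle_duration=spec.cycle_duration
    )
    truth_pct = int(math.floor(100.0 * continuous_dc_gain(params) + 0.5))
    return SyntheticSubject(
        cycle=cycle,
        truth_params=params,
        truth_spinal_percent=truth_pct,
        age=age,
        sex=sex,
        pseudo_mr_icp=pseudo_mr_icp,
        arterial=arterial,
        venous=venous,
        subject_id=subject_id,
    )


def draw_random_params(
    rng: np.random.Generator,
    spinal_range: tuple[float, float] = (0.3, 0.9),
) -> PhysicalParameters:
    """One random circuit around the default element magnitudes.

    The spinal fraction is uniform over ``spinal_range``; resistances,
    total compliance and inertance are jittered within a factor ~2 of the
    defaults, keeping the dynamics in the physiological band.
    """
    frac = rng.uniform(*spinal_range)
    ct = rng.uniform(0.5, 0.9)
    rsum = rng.uniform(0.35, 0.55)
    return PhysicalParameters(
        r_c=0.6 * rsum,
        r_s=0.4 * rsum,
        c_c=(1.0 - frac) * ct,
        c_s=frac * ct,
        l_s=rng.uniform(0.04, 0.065),
    )


def generate_cohort(
    n: int, seed: int, noise_sd: float = 0.0
) -> list[SyntheticSubject]:
    """A virtual cohort with a mild age trend in the compliance split.

    Ages are sampled over 3-60 years; the spinal fraction declines gently
    with age (children have a relatively more compliant spinal canal) around
    a noisy mean; a pseudo MR-ICP is generated inversely related to the
    cranial compliance share plus noise.  These trends exist to exercise the
    cohort reporting code (sign of correlations, stratified medians), not as
    physiological claims.
    """
    if n < 1:
        raise InvalidParameterError(f"cohort size must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    subjects: list[SyntheticSubject] = []
    for i in range(n):
        age = int(rng.integers(3, 61))
        sex = "M" if rng.random() < 0.5 else "F"
        frac = 0.70 - 0.004 * (age - 3) + rng.normal(0.0, 0.05)
        frac = float(np.clip(frac, 0.25, 0.90))
        params = params_for_spinal_fraction(frac, total_compliance=0.8)
        cranial_pct = 100.0 * (1.0 - frac)
        icp = 14.0 - 0.12 * (cranial_pct - 40.0) + rng.normal(0.0, 1.2)
        heart_rate = float(np.clip(115.0 - age, 55.0, 110.0))
        spec = WaveformSpec(
            heart_rate=heart_rate,
            arterial_peak=float(rng.uniform(6.0, 10.0)),
            venous_delay_fraction=float(rng.uniform(0.05, 0.12)),
            noise_sd=noise_sd,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        subjects.append(
            generate_subject(
                params,
                spec,
                age=age,
                sex=sex,
                pseudo_mr_icp=float(max(icp, 2.0)),
                subject_id=f"synthetic-{i:04d}",
            )
        )
    return subjects
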