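"""Acoustic dosimetry for rectangular ultrasound burst-pulse trains.

An ultrasound neuromodulation stimulus is described here as a train of
rectangular burst pulses: a carrier tone (typically 1 MHz) gated on and off
at a pulse repetition frequency (PRF), with a duty cycle giving the on
fraction of each PRF period, for a total train duration.  Intensity is
carried as I_SPTA, the spatial-peak temporal-average intensity in W/cm^2;
for rectangular gating the pulse-average intensity is
I_SPPA = I_SPTA / duty_cycle.

The module computes the derived dose quantities used to reason about
stimulus safety: the number of burst pulses in a train, I_SPPA, the acoustic
energy delivered per stimulus (I_SPTA x radiating area x duration), and the
adiabatic upper bound on the temperature rise of a small bath absorbing that
energy completely.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import InvalidSequenceError, MissingParameterError, ResolutionError

__all__ = [
    "PulseSequence",
    "ThermalContext",
    "burst_count",
    "isppa_from_ispta",
    "stimulus_energy",
    "adiabatic_temp_rise",
    "envelope_waveform",
    "round_sig",
]

#: relative tolerance for requiring duration * prf to be an integer
_BURST_COUNT_TOL = 1e-9


@dataclass(frozen=True)
class PulseSequence:
    """Parametric description of an ultrasound burst-pulse train.

    Parameters
    ----------
    carrier_frequency : float
        Carrier frequency in Hz (e.g. 1e6 for a 1-MHz transducer).
    prf : float
        Pulse repetition frequency in Hz.
    duty_cycle : float
        On fraction of each PRF period, in (0, 1].
    duration : float
        Train duration in seconds.  ``duration * prf`` must be a positive
        integer (the burst count) to within 1e-9.
    ispta : float, optional
        Spatial-peak temporal-average intensity in W/cm^2.
    radiating_area : float, optional
        Radiating surface area of the transducer face in cm^2.
    """

    carrier_frequency: float
    prf: float
    duty_cycle: float
    duration: float
    ispta: float | None = None
    radiating_area: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.duty_cycle <= 1.0):
            raise InvalidSequenceError(
                f"duty_cycle must be in (0, 1], got {self.duty_cycle}"
            )
        if self.duration <= 0:
            raise InvalidSequenceError(f"duration must be > 0, got {self.duration}")
        if self.prf <= 0:
            raise InvalidSequenceError(f"prf must be > 0, got {self.prf}")
        if self.carrier_frequency < self.prf:
            raise InvalidSequenceError(
                "carrier_frequency must be >= prf "
                f"({self.carrier_frequency} < {self.prf})"
            )
        if self.ispta is not None and self.ispta < 0:
            raise InvalidSequenceError(f"ispta must be >= 0, got {self.ispta}")
        if self.radiating_area is not None and self.radiating_area <= 0:
            raise InvalidSequenceError(
                f"radiating_area must be > 0, got {self.radiating_area}"
            )
        burst_count(self)  # raises if duration * prf is not integral


@dataclass(frozen=True)
class ThermalContext:
    """Thermal properties of the absorbing bath.

    Defaults are water at room temperature: density 1 g/mL and specific heat
    4.184 J/(g degC).
    """

    bath_volume: float  # mL
    density: float = 1.0  # g/mL
    specific_heat: float = 4.184  # J/(g degC)

    def __post_init__(self) -> None:
        for name in ("bath_volume", "density", "specific_heat"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")


def burst_count(seq: PulseSequence) -> int:
    """Number of burst pulses in the train: ``round(duration * prf)``.

    Raises
    ------
    InvalidSequenceError
        If ``duration * prf`` is not an integer to within 1e-9, or rounds
        to zero.
    """
    product = seq.duration * seq.prf
    n = round(product)
    if abs(product - n) > _BURST_COUNT_TOL * max(1.0, product):
        raise InvalidSequenceError(
            f"duration * prf = {product} is not integral: the train would "
            "contain a fractional burst pulse"
        )
    if n < 1:
        raise InvalidSequenceError(f"duration * prf = {product} rounds to zero bursts")
    return int(n)


def isppa_from_ispta(ispta: float, duty_cycle: float) -> float:
    """Pulse-average intensity from temporal-average intensity.

    For rectangular gating the carrier is on for a fraction ``duty_cycle``
    of the time, so I_SPPA = I_SPTA / duty_cycle.
    """
    if not (0.0 < duty_cycle <= 1.0):
        raise InvalidSequenceError(f"duty_cycle must be in (0, 1], got {duty_cycle}")
    if ispta < 0:
        raise InvalidSequenceError(f"ispta must be >= 0, got {ispta}")
    return ispta / duty_cycle


def stimulus_energy(seq: PulseSequence) -> float:
    """Acoustic energy of one stimulus train in joules.

    Energy = I_SPTA x radiating_area x duration.  The temporal-average
    intensity already folds in the duty cycle, so no further duty factor is
    applied.
    """
    if seq.ispta is None:
        raise MissingParameterError("stimulus_energy requires ispta to be set")
    if seq.radiating_area is None:
        raise MissingParameterError("stimulus_energy requires radiating_area to be set")
    return seq.ispta * seq.radiating_area * seq.duration


def adiabatic_temp_rise(energy: float, ctx: ThermalContext) -> float:
    """Upper-bound temperature rise (degC) of a bath absorbing ``energy``.

    Assumes total absorption with no conduction, convection, or perfusion
    loss: dT = E / (V * rho * c).  Real temperature rises are lower.
    """
    if energy < 0:
        raise ValueError(f"energy must be >= 0, got {energy}")
    return energy / (ctx.bath_volume * ctx.density * ctx.specific_heat)


def envelope_waveform(seq: PulseSequence, sample_rate: float) -> np.ndarray:
    """Idealized rectangular on/off envelope of the burst train.

    Returns a float array of length ``round(duration * sample_rate)`` with
    value 1.0 while the carrier is gated on (the first ``duty_cycle``
    fraction of each PRF period) and 0.0 otherwise.  No rise/fall ramping is
    modelled.

    Raises
    ------
    ResolutionError
        If ``sample_rate < 2 * prf`` (PRF periods would not be resolved).
    """
    if sample_rate < 2 * seq.prf:
        raise ResolutionError(
            f"sample_rate {sample_rate} Hz cannot resolve prf {seq.prf} Hz; "
            "need sample_rate >= 2 * prf"
        )
    n = round(seq.duration * sample_rate)
    phase = (np.arange(n) * (seq.prf / sample_rate)) % 1.0
    if seq.duty_cycle >= 1.0:
        return np.ones(n)
    return (phase < seq.duty_cycle).astype(float)


def round_sig(x: float, sig: int = 2) -> float:
    """Round ``x`` to ``sig`` significant figures (presentation only)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))
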