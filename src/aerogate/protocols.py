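"""Voltage protocols: periodic sweeps, constant holds, and pulse trains."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np

ProtocolKind = Literal["sinusoid", "triangle", "constant", "pulse_train", "custom"]


class ProtocolError(ValueError):
    """Invalid voltage protocol."""


@dataclass(frozen=True)
class VoltageProtocol:
    """A sampled transmembrane voltage programme.

    Periodic kinds (``sinusoid``, ``triangle``) start at V = 0 and sweep positive
    first; ``amplitude`` is the peak voltage ("200 mV" forcing means +/-0.2 V).
    ``pulse_train`` holds ``baseline`` and applies ``n_pulses`` rectangular pulses
    at absolute level ``amplitude``, each of ``pulse_width`` s followed by
    ``inter_pulse_wait`` s of baseline.  ``custom`` wraps explicit samples.
    """

    kind: ProtocolKind
    amplitude: float = 0.0  # V (pulse level for pulse_train)
    frequency: float = 0.0  # Hz, periodic kinds
    baseline: float = 0.0  # V
    pulse_width: float = 0.0  # s
    inter_pulse_wait: float = 0.0  # s
    n_pulses: int = 0
    duration: Optional[float] = None  # s
    sample_rate: float = 1.0e4  # Hz
    custom_time: Optional[np.ndarray] = field(default=None, repr=False)
    custom_voltage: Optional[np.ndarray] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ProtocolError("sample_rate must be positive")
        if self.kind in ("sinusoid", "triangle"):
            if self.frequency <= 0:
                raise ProtocolError("periodic protocols need a positive frequency")
            if self.sample_rate < 100 * self.frequency:
                raise ProtocolError("sample_rate must be >= 100x the frequency")
            if self.duration is not None and self.duration <= 0:
                raise ProtocolError("duration must be positive")
        elif self.kind == "constant":
            if self.duration is None or self.duration <= 0:
                raise ProtocolError("constant protocols need a positive duration")
        elif self.kind == "pulse_train":
            if self.n_pulses < 1 or self.pulse_width <= 0 or self.inter_pulse_wait <= 0:
                raise ProtocolError("pulse trains need n_pulses >= 1 and positive widths")
        elif self.kind == "custom":
            t, v = self.custom_time, self.custom_voltage
            if t is None or v is None or len(t) != len(v) or len(t) < 2:
                raise ProtocolError("custom protocols need matching time/voltage arrays")
            if not np.all(np.diff(t) > 0):
                raise ProtocolError("custom time axis must be strictly increasing")
        else:
            raise ProtocolError(f"unknown protocol kind {self.kind!r}")

    # -- derived quantities -------------------------------------------------
    @property
    def is_periodic(self) -> bool:
        return self.kind in ("sinusoid", "triangle")

    @property
    def period(self) -> float:
        if not self.is_periodic:
            raise ProtocolError("only periodic protocols have a period")
        return 1.0 / self.frequency

    @property
    def total_duration(self) -> float:
        if self.kind == "pulse_train":
            return self.n_pulses * (self.pulse_width + self.inter_pulse_wait)
        if self.kind == "custom":
            return float(self.custom_time[-1])
        if self.duration is None:
            return self.period  # one cycle by default
        return self.duration

    def voltage_at(self, t: np.ndarray) -> np.ndarray:
        """Ideal (noise-free) protocol voltage at arbitrary times."""
        t = np.asarray(t, float)
        if self.kind == "sinusoid":
            return self.amplitude * np.sin(2 * np.pi * self.frequency * t)
        if self.kind == "triangle":
            phase = np.mod(t * self.frequency, 1.0)
            v = np.where(
                phase < 0.25,
                4.0 * phase,
                np.where(phase < 0.75, 2.0 - 4.0 * phase, 4.0 * phase - 4.0),
            )
            return self.amplitude * v
        if self.kind == "constant":
            return np.full_like(t, self.baseline + self.amplitude, dtype=float)
        if self.kind == "pulse_train":
            cycle = self.pulse_width + self.inter_pulse_wait
            in_train = t < self.n_pulses * cycle
            in_pulse = np.mod(t, cycle) < self.pulse_width
            return np.where(in_train & in_pulse, self.amplitude, self.baseline)
        return np.interp(t, self.custom_time, self.custom_voltage)

    def samples(self) -> tuple[np.ndarray, np.ndarray]:
        """Uniformly sampled (time, voltage) arrays over the full duration."""
        if self.kind == "custom":
            return np.asarray(self.custom_time, float), np.asarray(
                self.custom_voltage, float
            )
        n = int(round(self.total_duration * self.sample_rate))
        if n < 2:
            raise ProtocolError("protocol too short for its sample rate")
        t = np.arange(n) / self.sample_rate
        return t, self.voltage_at(t)

    def n_complete_cycles(self, duration: float | None = None) -> int:
        d = self.total_duration if duration is None else duration
        return int(np.floor(d * self.frequency + 1e-9)) if self.is_periodic else 0


def sinusoid(amplitude: float, frequency: float, duration: float,
             sample_rate: float = 1.0e4) -> VoltageProtocol:
    return VoltageProtocol(kind="sinusoid", amplitude=amplitude, frequency=frequency,
                           duration=duration, sample_rate=sample_rate)


def triangle(amplitude: float, frequency: float, duration: float,
             sample_rate: float = 1.0e4) -> VoltageProtocol:
    return VoltageProtocol(kind="triangle", amplitude=amplitude, frequency=frequency,
                           duration=duration, sample_rate=sample_rate)


def constant(voltage: float, duration: float,
             sample_rate: float = 1.0e4) -> VoltageProtocol:
    return VoltageProtocol(kind="constant", amplitude=voltage, duration=duration,
                           sample_rate=sample_rate)


def pulse_train(level: float, pulse_width: float, inter_pulse_wait: float,
                n_pulses: int, baseline: float,
                sample_rate: float = 5.0e4) -> VoltageProtocol:
    return VoltageProtocol(kind="pulse_train", amplitude=level,
                           pulse_width=pulse_width, inter_pulse_wait=inter_pulse_wait,
                           n_pulses=n_pulses, baseline=baseline,
                           sample_rate=sample_rate)
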