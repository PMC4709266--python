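"""Stimulus protocols: current/voltage step families, sinewave-on-holding
current injections, and fluid-jet hair-bundle drives.

All protocols are declarative dataclasses that can be rendered to sampled
:class:`~ihc_encode.trace.Trace` command waveforms.  Durations are stored in
milliseconds (the native unit of patch-clamp protocol editors); traces are in
seconds.  Windows are half-open ``[start, end)`` and sweep time starts at 0.

Default rates follow standard whole-cell practice for hair cells: step
protocols at 5 kHz, sound-like sine protocols at 100 kHz, with 8-pole Bessel
low-pass anti-alias filters (2.5 kHz and 20 kHz respectively) applied
zero-phase so that filtering introduces no timing delay.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Union

import numpy as np
from scipy import signal as sps

from .trace import Trace

__all__ = [
    "FilterSpec",
    "StepProtocol",
    "SineProtocol",
    "FluidJetProtocol",
    "make_cc_steps",
    "make_vc_steps",
    "make_sine_protocol",
    "make_fluid_jet",
    "render",
    "bessel_lowpass",
    "protocol_to_dict",
    "protocol_from_dict",
]


# ----------------------------------------------------------------------
@dataclass(frozen=True)
class FilterSpec:
    """Low-pass Bessel filter description (order, cutoff in Hz)."""

    kind: str = "bessel_lowpass"
    order: int = 8
    cutoff: float = 2500.0

    def __post_init__(self) -> None:
        if self.kind != "bessel_lowpass":
            raise ValueError(f"unsupported filter kind {self.kind!r}")
        if self.order < 1:
            raise ValueError("filter order must be >= 1")
        if self.cutoff <= 0:
            raise ValueError("filter cutoff must be positive")


@dataclass(frozen=True)
class StepProtocol:
    """Family of rectangular command steps (voltage clamp or current clamp).

    ``holding_level`` / ``step_levels`` / ``tail_level`` are in mV (VC) or
    pA (CC).  Durations in ms.  One sweep per entry of ``step_levels``.
    """

    mode: str  # "VC" | "CC"
    holding_level: float
    pre_duration: float
    step_levels: tuple[float, ...]
    step_duration: float
    tail_level: Optional[float] = None
    tail_duration: float = 0.0
    post_duration: float = 0.0
    sample_rate: float = 5000.0
    stimulus_filter: Optional[FilterSpec] = None

    def __post_init__(self) -> None:
        if self.mode not in ("VC", "CC"):
            raise ValueError("mode must be 'VC' or 'CC'")
        if len(self.step_levels) == 0:
            raise ValueError("step_levels must be non-empty")
        for d in (self.pre_duration, self.step_duration, self.tail_duration, self.post_duration):
            if d < 0:
                raise ValueError("durations must be >= 0")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.tail_level is not None and self.tail_duration <= 0:
            raise ValueError("tail_level set but tail_duration is 0")

    @property
    def n_sweeps(self) -> int:
        return len(self.step_levels)

    @property
    def unit(self) -> str:
        return "mV" if self.mode == "VC" else "pA"

    def segments(self, sweep_index: int) -> list[tuple[float, float]]:
        """(level, duration_ms) segments for one sweep."""
        if not 0 <= sweep_index < self.n_sweeps:
            raise IndexError(f"sweep_index {sweep_index} out of range [0, {self.n_sweeps})")
        segs = [(self.holding_level, self.pre_duration),
                (self.step_levels[sweep_index], self.step_duration)]
        if self.tail_level is not None:
            segs.append((self.tail_level, self.tail_duration))
        if self.post_duration > 0:
            segs.append((self.holding_level, self.post_duration))
        return segs

    @property
    def total_duration(self) -> float:
        """Sweep length in ms."""
        return sum(d for _, d in self.segments(0))


@dataclass(frozen=True)
class SineProtocol:
    """Sinusoidal current (sound-like stimulus) on a holding current step.

    The sine starts at phase 0 (rising through the holding level) at the end
    of ``pre_duration``; this phase reference anchors all timing analyses.
    """

    holding_current: float  # pA
    sine_peak_to_peak: float  # pA
    frequency: float  # Hz
    pre_duration: float = 40.0  # ms
    sine_duration: float = 50.0  # ms
    post_duration: float = 40.0  # ms
    sample_rate: float = 100_000.0  # Hz
    stimulus_filter: Optional[FilterSpec] = None
    mode: str = "CC"

    def __post_init__(self) -> None:
        if self.mode != "CC":
            raise ValueError("sine protocols are current clamp only")
        if self.frequency <= 0:
            raise ValueError("frequency must be positive")
        if self.sine_peak_to_peak < 0:
            raise ValueError("sine_peak_to_peak must be >= 0")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.sine_duration * 1e-3 * self.frequency < 2:
            raise ValueError("sine_duration must cover at least 2 full cycles")
        if self.sample_rate < 10 * self.frequency:
            raise ValueError(
                f"sample_rate {self.sample_rate} Hz under-samples a {self.frequency} Hz "
                f"sine (need >= 10 samples/cycle)"
            )

    @property
    def n_sweeps(self) -> int:
        return 1

    @property
    def unit(self) -> str:
        return "pA"

    @property
    def sine_onset(self) -> float:
        """Sine onset time in ms."""
        return self.pre_duration

    @property
    def total_duration(self) -> float:
        return self.pre_duration + self.sine_duration + self.post_duration


@dataclass(frozen=True)
class FluidJetProtocol:
    """Sinusoidal fluid-jet driver voltage deflecting the hair bundle.

    The command is expressed as driver voltage (V); an 8-pole Bessel filter at
    0.5 kHz shapes the drive as in the stimulator hardware.
    """

    frequency: float = 50.0  # Hz
    driver_amplitude: float = 20.0  # V, peak
    n_cycles: int = 5
    pre_duration: float = 20.0  # ms at rest before the sine
    sample_rate: float = 5000.0
    stimulus_filter: Optional[FilterSpec] = field(
        default_factory=lambda: FilterSpec(order=8, cutoff=500.0)
    )
    mode: str = "FJ"

    def __post_init__(self) -> None:
        if abs(self.driver_amplitude) > 20:
            raise ValueError("driver amplitude limited to ±20 V")
        if self.frequency <= 0:
            raise ValueError("frequency must be positive")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")

    @property
    def n_sweeps(self) -> int:
        return 1

    @property
    def unit(self) -> str:
        return "V"

    @property
    def sine_onset(self) -> float:
        return self.pre_duration

    @property
    def total_duration(self) -> float:
        return self.pre_duration + self.n_cycles / self.frequency * 1e3 + self.pre_duration


Protocol = Union[StepProtocol, SineProtocol, FluidJetProtocol]


# ----------------------------------------------------------------------
# constructors
def _arith_levels(start: float, stop: float, increment: float) -> tuple[float, ...]:
    if increment == 0:
        raise ValueError("increment must be non-zero")
    span = stop - start
    n_float = span / increment
    n = round(n_float)
    if n < 0:
        raise ValueError(f"increment {increment} has the wrong sign for range {start}..{stop}")
    if abs(n_float - n) > 1e-9:
        remainder = span - n * increment
        raise ValueError(
            f"range {start}..{stop} is not divisible by increment {increment} "
            f"(remainder {remainder:g})"
        )
    return tuple(start + i * increment for i in range(n + 1))


def make_cc_steps(
    start: float,
    stop: float,
    increment: float = 100.0,
    holding: float = 0.0,
    pre_duration: float = 40.0,
    step_duration: float = 160.0,
    post_duration: float = 40.0,
    sample_rate: float = 5000.0,
    stimulus_filter: Optional[FilterSpec] = None,
) -> StepProtocol:
    """Current-clamp step family, e.g. 100 pA steps from -100 to 900 pA.

    Levels are relative to the cell's resting potential (holding = 0 pA
    injected by default).
    """
    return StepProtocol(
        mode="CC",
        holding_level=holding,
        pre_duration=pre_duration,
        step_levels=_arith_levels(start, stop, increment),
        step_duration=step_duration,
        post_duration=post_duration,
        sample_rate=sample_rate,
        stimulus_filter=stimulus_filter,
    )


def make_vc_steps(
    start: float = -144.0,
    stop: float = 36.0,
    increment: float = 10.0,
    holding: float = -64.0,
    tail: float = -124.0,
    pre_duration: float = 20.0,
    step_duration: float = 170.0,
    tail_duration: float = 50.0,
    sample_rate: float = 5000.0,
    stimulus_filter: Optional[FilterSpec] = None,
) -> StepProtocol:
    """Voltage-clamp step family with a fixed tail (deactivation) potential.

    Defaults follow the classic hair-cell K-current protocol: 10 mV
    increments from -144 mV, holding -64 mV, tails at -124 mV.  The default
    step duration (170 ms) guarantees the 160 ms steady-state measurement
    point exists.
    """
    for name, v in (("holding", holding), ("tail", tail)):
        if not -160 <= v <= 60:
            raise ValueError(f"{name} potential {v} mV outside [-160, +60] mV")
    return StepProtocol(
        mode="VC",
        holding_level=holding,
        pre_duration=pre_duration,
        step_levels=_arith_levels(start, stop, increment),
        step_duration=step_duration,
        tail_level=tail,
        tail_duration=tail_duration,
        sample_rate=sample_rate,
        stimulus_filter=stimulus_filter,
    )


#: Default holding currents (pA) for the sound-like protocol, equal to the
#: resting MT current measured in endolymph-like low Ca²⁺.
SINE_HOLDING_DEFAULTS = {"apical": 500.0, "basal": 50.0}


def make_sine_protocol(
    frequency: float = 300.0,
    peak_to_peak: float = 1000.0,
    holding: float = 500.0,
    pre_duration: float = 40.0,
    sine_duration: Optional[float] = None,
    post_duration: float = 40.0,
    sample_rate: float = 100_000.0,
    stimulus_filter: Optional[FilterSpec] = None,
) -> SineProtocol:
    """Sound-like sinewave (given peak-to-peak amplitude) on a holding current.

    If ``sine_duration`` is omitted it is chosen to cover >= 15 cycles and at
    least 50 ms, so that low-frequency protocols contain enough cycles for
    timing statistics.
    """
    if sine_duration is None:
        sine_duration = max(50.0, 15.0 / frequency * 1e3)
    return SineProtocol(
        holding_current=holding,
        sine_peak_to_peak=peak_to_peak,
        frequency=frequency,
        pre_duration=pre_duration,
        sine_duration=sine_duration,
        post_duration=post_duration,
        sample_rate=sample_rate,
        stimulus_filter=stimulus_filter,
    )


def make_fluid_jet(
    frequency: float = 50.0,
    driver_amplitude: float = 20.0,
    n_cycles: int = 5,
    sample_rate: float = 5000.0,
) -> FluidJetProtocol:
    return FluidJetProtocol(
        frequency=frequency,
        driver_amplitude=driver_amplitude,
        n_cycles=n_cycles,
        sample_rate=sample_rate,
    )


# ----------------------------------------------------------------------
# rendering
def protocol_to_dict(p: Protocol) -> dict:
    d = asdict(p)
    d["type"] = type(p).__name__
    if d.get("stimulus_filter") is not None:
        d["stimulus_filter"] = dict(d["stimulus_filter"])
    if isinstance(d.get("step_levels"), tuple):
        d["step_levels"] = list(d["step_levels"])
    return d


def protocol_from_dict(d: dict) -> Protocol:
    d = dict(d)
    kind = d.pop("type")
    if d.get("stimulus_filter") is not None:
        d["stimulus_filter"] = FilterSpec(**d["stimulus_filter"])
    if "step_levels" in d:
        d["step_levels"] = tuple(d["step_levels"])
    cls = {"StepProtocol": StepProtocol, "SineProtocol": SineProtocol,
           "FluidJetProtocol": FluidJetProtocol}[kind]
    return cls(**d)


def protocol_hash(p: Protocol) -> str:
    payload = json.dumps(protocol_to_dict(p), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _n_samples(p: Protocol) -> int:
    return int(round(p.total_duration * 1e-3 * p.sample_rate))


def render(protocol: Protocol, sweep_index: int = 0, sample_rate: Optional[float] = None) -> Trace:
    """Render one sweep of a protocol to a sampled command trace.

    ``sample_rate`` overrides the protocol's rate (used internally for
    oversampled simulation).  If the protocol declares a stimulus filter it is
    applied zero-phase to the command waveform.
    """
    rate = sample_rate if sample_rate is not None else protocol.sample_rate
    dt = 1.0 / rate
    n = int(round(protocol.total_duration * 1e-3 * rate))
    t = dt * np.arange(n)

    if isinstance(protocol, StepProtocol):
        samples = np.empty(n)
        t_edge = 0.0
        for level, dur_ms in protocol.segments(sweep_index):
            i0 = int(np.ceil(t_edge / dt - 1e-9))
            t_edge += dur_ms * 1e-3
            i1 = int(np.ceil(t_edge / dt - 1e-9))
            samples[i0:i1] = level
        samples[i1:] = protocol.segments(sweep_index)[-1][0]
        unit = protocol.unit
    elif isinstance(protocol, SineProtocol):
        if sweep_index != 0:
            raise IndexError("sine protocols have a single sweep")
        onset = protocol.pre_duration * 1e-3
        end = onset + protocol.sine_duration * 1e-3
        samples = np.full(n, protocol.holding_current)
        in_sine = (t >= onset - 1e-12) & (t < end - 1e-12)
        amp = protocol.sine_peak_to_peak / 2.0
        samples[in_sine] += amp * np.sin(2 * np.pi * protocol.frequency * (t[in_sine] - onset))
        unit = "pA"
    elif isinstance(protocol, FluidJetProtocol):
        if sweep_index != 0:
            raise IndexError("fluid-jet protocols have a single sweep")
        onset = protocol.pre_duration * 1e-3
        end = onset + protocol.n_cycles / protocol.frequency
        samples = np.zeros(n)
        in_sine = (t >= onset - 1e-12) & (t < end - 1e-12)
        samples[in_sine] = protocol.driver_amplitude * np.sin(
            2 * np.pi * protocol.frequency * (t[in_sine] - onset)
        )
        unit = "V"
    else:  # pragma: no cover
        raise TypeError(f"unknown protocol type {type(protocol).__name__}")

    trace = Trace(
        t0=0.0,
        dt=dt,
        samples=samples,
        unit=unit,
        label=f"{type(protocol).__name__} sweep {sweep_index}",
        meta={"protocol_hash": protocol_hash(protocol), "sweep_index": sweep_index,
              "mode": getattr(protocol, "mode", "FJ")},
    )
    if protocol.stimulus_filter is not None:
        trace = bessel_lowpass(trace, protocol.stimulus_filter)
    return trace


def bessel_lowpass(trace: Trace, spec: FilterSpec) -> Trace:
    """Zero-phase (forward-backward) Bessel low-pass of a trace.

    The forward-backward pass squares the magnitude response, so the
    effective attenuation at cutoff is ~6 dB rather than 3 dB; the passband
    is correspondingly flat and, critically for timing analyses, the filter
    introduces no delay.
    """
    nyquist = 0.5 / trace.dt
    if spec.cutoff >= nyquist:
        raise ValueError(
            f"filter cutoff {spec.cutoff} Hz must be below the Nyquist rate {nyquist} Hz"
        )
    sos = sps.bessel(spec.order, spec.cutoff, btype="low", norm="mag",
                     fs=trace.sample_rate, output="sos")
    filtered = sps.sosfiltfilt(sos, trace.samples)
    out = trace.copy(samples=filtered)
    out.meta["filter"] = {"kind": spec.kind, "order": spec.order, "cutoff": spec.cutoff,
                          "zero_phase": True}
    return out
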