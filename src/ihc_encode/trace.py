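"""Uniformly sampled time-series container used throughout the package.

A :class:`Trace` holds one sweep of one signal — membrane potential (mV),
membrane current (pA), fluid-jet driver voltage (V) or a dimensionless
derived quantity — together with its sampling grid and free-form metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

#: Units a trace is allowed to carry.
VALID_UNITS = ("mV", "pA", "nA", "V", "dimensionless")


@dataclass
class Trace:
    """One uniformly sampled sweep.

    Parameters
    ----------
    t0:
        Time of the first sample, in seconds (sweep-relative; 0 by convention).
    dt:
        Sampling interval in seconds. Must be positive.
    samples:
        Sample values; converted to a float64 array. Length >= 2.
    unit:
        One of ``mV``, ``pA``, ``nA``, ``V`` (driver voltage), ``dimensionless``.
    label:
        Free-text description.
    meta:
        Key->value mapping (preset, condition, sweep index, protocol hash ...).
    """

    t0: float
    dt: float
    samples: np.ndarray
    unit: str
    label: str = ""
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise ValueError("samples must be a 1-D array of length >= 2")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if self.unit not in VALID_UNITS:
            raise ValueError(f"unit must be one of {VALID_UNITS}, got {self.unit!r}")

    # ------------------------------------------------------------------
    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def sample_rate(self) -> float:
        """Sampling rate in Hz."""
        return 1.0 / self.dt

    @property
    def duration(self) -> float:
        """Total covered time in seconds (n * dt)."""
        return self.n * self.dt

    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.t0 + self.dt * np.arange(self.n)

    def index_at(self, t: float) -> int:
        """Index of the sample nearest to time ``t`` (seconds)."""
        i = int(round((t - self.t0) / self.dt))
        if i < 0 or i >= self.n:
            raise IndexError(f"time {t} s outside trace [{self.t0}, {self.t0 + self.duration}) s")
        return i

    def window(self, t_start: float, t_end: float) -> np.ndarray:
        """Samples in the half-open window [t_start, t_end) (seconds)."""
        i0 = int(np.ceil((t_start - self.t0) / self.dt - 1e-9))
        i1 = int(np.ceil((t_end - self.t0) / self.dt - 1e-9))
        i0 = max(i0, 0)
        if i1 <= i0 or i0 >= self.n:
            raise ValueError(f"window [{t_start}, {t_end}) s selects no samples")
        return self.samples[i0:min(i1, self.n)]

    def copy(self, **overrides: Any) -> "Trace":
        kw = dict(
            t0=self.t0,
            dt=self.dt,
            samples=self.samples.copy(),
            unit=self.unit,
            label=self.label,
            meta=dict(self.meta),
        )
        kw.update(overrides)
        return Trace(**kw)

    def __eq__(self, other: object) -> bool:  # value equality, used by round-trip tests
        if not isinstance(other, Trace):
            return NotImplemented
        return (
            self.t0 == other.t0
            and self.dt == other.dt
            and self.unit == other.unit
            and np.array_equal(self.samples, other.samples)
        )
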