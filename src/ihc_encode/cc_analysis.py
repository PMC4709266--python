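"""Current-clamp measurement procedures: onset time-constant fits,
peak/steady-state membrane potential, AC/DC decomposition of responses to
sinusoidal (sound-like) stimuli, per-half-cycle extrema detection, and the
timing statistics (equivalent-peak delays, phase angles, half-cycle-width
errors) used to compare phase-locking fidelity between cells.

All timing work is done in the time domain.  Extrema are assigned to
stimulus half-cycles referenced to the sine onset (the stimulus starts at
phase 0 rising), so "equivalent peaks" in two recordings are peaks with the
same half-cycle index, and timing differences are meaningful even when one
response lags by a substantial fraction of a cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Optional

import numpy as np
from scipy.optimize import curve_fit

from .trace import Trace

__all__ = [
    "TauFit",
    "Extremum",
    "ExtremaSeries",
    "TimingStats",
    "fit_onset_tau",
    "peak_and_steady_vm",
    "ac_dc_decompose",
    "detect_extrema",
    "timing_difference",
    "half_cycle_stats",
]


# ----------------------------------------------------------------------
@dataclass
class TauFit:
    """Single-exponential fit of the onset rise V(t) = V_inf − (V_inf − V0)·e^(−t/τ)."""

    tau: float  # ms
    V0: float  # mV
    V_inf: float  # mV
    window: tuple[float, float]  # ms
    rms_residual: float  # mV


@dataclass(frozen=True)
class Extremum:
    time: float  # ms
    value: float  # mV
    kind: str  # "max" | "min"
    half_cycle_index: int


@dataclass
class ExtremaSeries:
    """One refined extremum per stimulus half-cycle (absent ones skipped)."""

    events: list[Extremum]
    frequency: float  # Hz
    sine_onset: float  # ms
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        times = [e.time for e in self.events]
        if any(t1 <= t0 for t0, t1 in zip(times, times[1:])):
            raise ValueError("event times must be strictly increasing")
        for e0, e1 in zip(self.events, self.events[1:]):
            if e0.kind == e1.kind:
                raise ValueError("extrema kinds must alternate")

    def by_index(self) -> dict[int, Extremum]:
        return {e.half_cycle_index: e for e in self.events}


@dataclass
class TimingStats:
    """Timing comparison / accuracy statistics for periodic responses.

    ``delta_t`` pairs (peak index, ms): t_other − t_ref for equivalent peaks,
    so with the apical cell as reference, positive = apical lead.
    ``phase_deg`` is exactly 360·f·delta_t.  ``half_widths`` pairs
    (half-cycle index, ms) of consecutive-extrema separations and
    ``half_errors_pct`` their signed percentage deviation from the stimulus
    half period (0 = perfect).
    """

    frequency: float
    delta_t: list[tuple[int, float]] = field(default_factory=list)
    phase_deg: list[tuple[int, float]] = field(default_factory=list)
    half_widths: list[tuple[int, float]] = field(default_factory=list)
    half_errors_pct: list[tuple[int, float]] = field(default_factory=list)
    sign_convention: str = "positive delta_t = reference (apical) lead"

    def abs_half_errors_pct(self) -> list[tuple[int, float]]:
        return [(k, abs(v)) for k, v in self.half_errors_pct]


# ----------------------------------------------------------------------
def _exp_rise(t, tau, V0, V_inf):
    return V_inf - (V_inf - V0) * np.exp(-t / tau)


def fit_onset_tau(
    trace: Trace,
    step_onset: float,
    window_end_rule: str | float = "to-peak",
    search_span: float = 20.0,
) -> TauFit:
    """Fit a single exponential to the initial voltage rise after a step.

    The fit window runs from the step onset to the first peak of the
    response (``window_end_rule="to-peak"``, the default: the time of the
    maximum within ``search_span`` ms of onset) or to an explicit end time
    (ms after onset).  τ is initialized deterministically from the 63%
    crossing of the rise.
    """
    if trace.unit != "mV":
        raise ValueError("onset fits expect a current-clamp (mV) trace")
    onset_s = step_onset * 1e-3
    i0 = trace.index_at(onset_s)
    if window_end_rule == "to-peak":
        i_hi = trace.index_at(min(onset_s + search_span * 1e-3,
                                  trace.t0 + (trace.n - 1) * trace.dt))
        i1 = i0 + int(np.argmax(trace.samples[i0:i_hi + 1]))
    else:
        i1 = trace.index_at(onset_s + float(window_end_rule) * 1e-3)
    if i1 <= i0 + 3:
        raise ValueError("no usable rise window after step onset")
    t = (trace.times()[i0:i1 + 1] - onset_s) * 1e3  # ms
    y = trace.samples[i0:i1 + 1]
    V0, V_peak = y[0], y[-1]
    rise = V_peak - V0
    if rise < max(0.5, 3 * np.std(np.diff(y[: max(4, len(y) // 10)]))):
        raise ValueError("trace shows no rise after the step onset")
    # tau init: first crossing of 63% of the rise
    above = np.nonzero(y - V0 >= 0.632 * rise)[0]
    tau0 = t[above[0]] if len(above) else t[-1] / 2
    tau0 = max(tau0, trace.dt * 1e3)
    try:
        popt, _ = curve_fit(_exp_rise, t, y, p0=[tau0, V0, V_peak], maxfev=10000)
    except RuntimeError as exc:
        raise RuntimeError(f"onset fit failed to converge (tau0={tau0:.3g} ms): {exc}")
    if popt[0] <= 0:
        raise RuntimeError("onset fit returned non-positive tau")
    resid = _exp_rise(t, *popt) - y
    return TauFit(tau=float(popt[0]), V0=float(popt[1]), V_inf=float(popt[2]),
                  window=(step_onset, step_onset + t[-1]),
                  rms_residual=float(np.sqrt(np.mean(resid**2))))


def peak_and_steady_vm(
    trace: Trace,
    step_onset: float,
    step_end: float,
    peak_span: float = 20.0,
    ss_span: float = 10.0,
) -> tuple[float, float]:
    """Peak Vm (max within ``peak_span`` ms of onset) and steady-state Vm
    (mean over the last ``ss_span`` ms before step end)."""
    if step_end <= step_onset:
        raise ValueError("step_end must follow step_onset")
    if step_onset + peak_span > step_end - ss_span:
        raise ValueError("peak and steady-state windows overlap")
    v_peak = float(np.max(trace.window(step_onset * 1e-3,
                                       (step_onset + peak_span) * 1e-3)))
    v_ss = float(np.mean(trace.window((step_end - ss_span) * 1e-3, step_end * 1e-3)))
    return v_peak, v_ss


# ----------------------------------------------------------------------
def _cycle_slices(trace: Trace, frequency: float, sine_onset: float,
                  per: str = "cycle", offset_cycles: float = 0.0) -> list[tuple[int, int, int]]:
    """(index, i0, i1) sample slices per cycle or half cycle after onset.

    ``offset_cycles`` shifts all windows by that fraction of a full period
    (used by extrema detection to keep lagging response peaks mid-window)."""
    period_s = 1.0 / frequency if per == "cycle" else 0.5 / frequency
    onset_s = sine_onset * 1e-3 + offset_cycles / frequency
    out = []
    k = 0
    while True:
        t0 = onset_s + k * period_s
        t1 = t0 + period_s
        i0 = int(np.ceil((t0 - trace.t0) / trace.dt - 1e-9))
        i1 = int(np.ceil((t1 - trace.t0) / trace.dt - 1e-9))
        if i1 > trace.n:
            break
        out.append((k, i0, i1))
        k += 1
    return out


def ac_dc_decompose(
    trace: Trace, frequency: float, sine_onset: float
) -> tuple[Trace, np.ndarray]:
    """Split a periodic response into sustained (DC) and phasic (AC) parts.

    Returns a DC trace holding the per-cycle mean (one sample per cycle,
    assigned at cycle centres) and an array of per-cycle peak-to-peak AC
    amplitudes of the mean-subtracted cycles.  The pre-onset resting Vm is
    stored in the DC trace metadata so that DC shift = dc − rest.
    """
    cycles = _cycle_slices(trace, frequency, sine_onset, per="cycle")
    if len(cycles) < 2:
        raise ValueError(
            f"trace covers {len(cycles)} full cycles at {frequency} Hz after "
            f"onset; need >= 2"
        )
    dc = np.empty(len(cycles))
    ac = np.empty(len(cycles))
    for k, i0, i1 in cycles:
        seg = trace.samples[i0:i1]
        dc[k] = seg.mean()
        ac[k] = np.ptp(seg - dc[k])
    rest = float(np.mean(trace.window(trace.t0, sine_onset * 1e-3))) \
        if sine_onset > 0 else float("nan")
    dc_trace = Trace(
        t0=sine_onset * 1e-3 + 0.5 / frequency, dt=1.0 / frequency, samples=dc,
        unit=trace.unit, label=f"{trace.label} DC",
        meta={**trace.meta, "component": "dc", "rest_vm": rest,
              "frequency": frequency},
    )
    return dc_trace, ac


def _parabolic_refine(t: np.ndarray, y: np.ndarray, i: int) -> tuple[float, float]:
    """Vertex of the parabola through samples i-1, i, i+1 (falls back to i)."""
    if i <= 0 or i >= len(y) - 1:
        return t[i], y[i]
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return t[i], y[i]
    delta = 0.5 * (y0 - y2) / denom
    delta = float(np.clip(delta, -1, 1))
    dt = t[1] - t[0]
    return t[i] + delta * dt, y1 - 0.25 * (y0 - y2) * delta


def detect_extrema(
    trace: Trace,
    frequency: float,
    sine_onset: float,
    flat_tol: Optional[float] = None,
) -> ExtremaSeries:
    """One extremum per stimulus half-cycle, refined by 3-point parabolic
    interpolation.

    Half-cycle windows are referenced to the sine onset but shifted by an
    eighth of a period, so that a response extremum lagging the stimulus by
    anything from -45° to +135° (an RC membrane lags by 0–90°) stays inside
    the window of its half cycle.  Each window is assigned the interior
    extremum it actually contains (for lags under 135° that alternates
    max/min starting with a maximum, since the stimulus rises first; larger
    lags shift the pattern by a window).  A window with no interior
    extremum, or whose excursion is below ``flat_tol`` (default: 1e-9 of the
    trace range, i.e. effectively only exactly flat), is flagged absent and
    skipped.
    """
    if trace.dt > 0.1 / frequency:
        raise ValueError("need >= 10 samples per stimulus cycle")
    halves = _cycle_slices(trace, frequency, sine_onset, per="half",
                           offset_cycles=0.125)
    if flat_tol is None:
        flat_tol = 1e-9 * max(np.ptp(trace.samples), 1.0)
    times_ms = trace.times() * 1e3
    events: list[Extremum] = []
    absent: list[int] = []
    for k, i0, i1 in halves:
        seg = trace.samples[i0:i1]
        if len(seg) < 3 or np.ptp(seg) <= flat_tol:
            absent.append(k)
            continue
        mean = seg.mean()
        candidates = []
        for j, kind in ((int(np.argmax(seg)), "max"), (int(np.argmin(seg)), "min")):
            if 0 < j < len(seg) - 1:  # interior extremum, not a window-edge plateau
                candidates.append((abs(seg[j] - mean), j, kind))
        if not candidates:
            absent.append(k)
            continue
        _, j, kind = max(candidates)
        t_ref, v_ref = _parabolic_refine(times_ms[i0:i1], seg, j)
        events.append(Extremum(time=t_ref, value=v_ref, kind=kind,
                               half_cycle_index=k))
    # enforce alternation: consecutive present events of equal kind cannot
    # occur because kind is set by half-cycle parity and indices are unique,
    # but a gap can leave two same-kind neighbours; drop the later one.
    cleaned: list[Extremum] = []
    for e in events:
        if cleaned and cleaned[-1].kind == e.kind:
            absent.append(e.half_cycle_index)
            continue
        cleaned.append(e)
    return ExtremaSeries(events=cleaned, frequency=frequency, sine_onset=sine_onset,
                         meta={"absent_half_cycles": sorted(absent),
                               "label": trace.label})


def timing_difference(ref: ExtremaSeries, other: ExtremaSeries) -> TimingStats:
    """Equivalent-peak timing differences t_other − t_ref and phase angles.

    Peaks are matched by half-cycle index and kind: the equivalent of a
    reference maximum at index k is the other series' maximum at index k,
    or — when the other response lags by more than a half-cycle window — at
    index k+1.  With the apical series as ``ref``, positive values indicate
    an apical lead.  Indices present in only one series are skipped.
    """
    if abs(ref.frequency - other.frequency) > 1e-9:
        raise ValueError("series come from different stimulus frequencies")
    f = ref.frequency
    other_map = other.by_index()
    stats = TimingStats(frequency=f)
    used: set[int] = set()
    for e in ref.events:
        match = None
        for k in (e.half_cycle_index, e.half_cycle_index + 1):
            cand = other_map.get(k)
            if cand is not None and cand.kind == e.kind and k not in used:
                match = cand
                used.add(k)
                break
        if match is None:
            continue
        dt_ms = match.time - e.time
        stats.delta_t.append((e.half_cycle_index, dt_ms))
        stats.phase_deg.append((e.half_cycle_index, 360.0 * f * dt_ms * 1e-3))
    return stats


def half_cycle_stats(series: ExtremaSeries, frequency: Optional[float] = None) -> TimingStats:
    """Half-cycle widths (consecutive-extrema separations) and their signed
    percentage error relative to the stimulus half period 1/(2f)."""
    f = frequency if frequency is not None else series.frequency
    if len(series.events) < 2:
        raise ValueError("need >= 2 extrema for half-cycle widths")
    nominal_ms = 0.5 / f * 1e3
    stats = TimingStats(frequency=f)
    for e0, e1 in zip(series.events, series.events[1:]):
        if e1.half_cycle_index != e0.half_cycle_index + 1:
            continue  # gap: width would span missing half cycles
        width = e1.time - e0.time
        stats.half_widths.append((e0.half_cycle_index, width))
        stats.half_errors_pct.append(
            (e0.half_cycle_index, width / nominal_ms * 100.0 - 100.0)
        )
    return stats
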