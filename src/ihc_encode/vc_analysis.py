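"""Voltage-clamp measurement procedures: I-V extraction, slope conductance,
tail-current activation curves, Boltzmann fits, pharmacological subtraction,
holding-current shifts, and recording corrections.

Conventions follow standard hair-cell K⁺-current analysis: peak currents are
read at 2 ms after step onset (isolating the rapidly activating BK-type
current), steady-state currents as a 10 ms mean centred on 160 ms, and
activation curves are built from the instantaneous tail-current amplitude —
a single exponential fitted to the tail and back-extrapolated to tail onset,
which avoids the clamp-settling artifact — plotted against the preceding
step potential.  I-V curves are absolute (holding current not subtracted).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any, Optional

import numpy as np
from scipy.optimize import OptimizeWarning, curve_fit

from .model import SweepSet, replace_sweeps
from .protocols import StepProtocol
from .trace import Trace

__all__ = [
    "IVCurve",
    "ActivationCurve",
    "BoltzmannFit",
    "RecordingParams",
    "measure_iv",
    "slope_conductance",
    "tail_activation",
    "fit_boltzmann",
    "subtract_conditions",
    "holding_current_shift",
    "junction_correct",
    "vc_time_constant",
]


# ----------------------------------------------------------------------
@dataclass
class IVCurve:
    """Current-voltage relation, one point per sweep, ordered by V_step."""

    V: np.ndarray  # mV, strictly increasing
    I: np.ndarray  # pA
    measure: str  # "peak_2ms" | "ss_160ms"
    n_sweeps: int = 0
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.V = np.asarray(self.V, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        if self.V.shape != self.I.shape:
            raise ValueError("V and I must have the same shape")
        if np.any(np.diff(self.V) <= 0):
            raise ValueError("V must be strictly increasing")
        if not self.n_sweeps:
            self.n_sweeps = self.V.size


@dataclass
class ActivationCurve:
    """Instantaneous tail-current amplitude vs preceding step potential."""

    V_pre: np.ndarray  # mV, strictly increasing
    I_tail: np.ndarray  # pA
    tail_V: float  # mV
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.V_pre = np.asarray(self.V_pre, dtype=float)
        self.I_tail = np.asarray(self.I_tail, dtype=float)
        if np.any(np.diff(self.V_pre) <= 0):
            raise ValueError("V_pre must be strictly increasing")

    def normalized(self) -> "ActivationCurve":
        """Max-normalized copy (optional presentation form)."""
        span = self.I_tail.max() - self.I_tail.min()
        if span == 0:
            raise ValueError("flat activation curve cannot be normalized")
        out = ActivationCurve(self.V_pre.copy(),
                              (self.I_tail - self.I_tail.min()) / span,
                              self.tail_V, dict(self.meta))
        out.meta["normalized"] = True
        return out


@dataclass
class BoltzmannFit:
    """First-order Boltzmann fit I(V) = I_offset + I_max/(1+exp((V_half-V)/S))."""

    V_half: float  # mV
    S: float  # mV
    I_max: float  # pA
    I_offset: float  # pA
    rms_residual: float  # pA

    def __call__(self, V):
        return self.I_offset + self.I_max / (1.0 + np.exp((self.V_half - np.asarray(V)) / self.S))


_JUNCTION_DEFAULTS = {"KCl": -4.0, "K_aspartate": -10.0}


@dataclass
class RecordingParams:
    """Whole-cell recording corrections: residual series resistance after
    compensation, measured capacitance, and liquid junction potential for the
    named intracellular solution."""

    R_s: float  # MΩ
    C_m_measured: float  # pF
    solution: str = "KCl"  # "KCl" | "K_aspartate"
    junction_potential: Optional[float] = None  # mV; default per solution

    def __post_init__(self) -> None:
        if self.R_s < 0:
            raise ValueError("R_s must be >= 0")
        if self.C_m_measured <= 0:
            raise ValueError("C_m_measured must be positive")
        if self.junction_potential is None:
            if self.solution not in _JUNCTION_DEFAULTS:
                raise ValueError(
                    f"unknown solution {self.solution!r}; give junction_potential explicitly"
                )
            self.junction_potential = _JUNCTION_DEFAULTS[self.solution]


# ----------------------------------------------------------------------
def _require_vc_steps(sweeps: SweepSet) -> StepProtocol:
    p = sweeps.protocol
    if not isinstance(p, StepProtocol) or p.mode != "VC":
        raise ValueError("expected a voltage-clamp step SweepSet")
    return p


def measure_iv(
    sweeps: SweepSet,
    measure: str = "ss_160ms",
    t_peak: float = 2.0,
    t_ss: float = 160.0,
    ss_half_window: float = 5.0,
) -> IVCurve:
    """Extract an I-V curve from a voltage-step sweep family.

    ``peak_2ms``: single sample nearest to ``t_peak`` ms after step onset.
    ``ss_160ms``: mean over [t_ss - 5, t_ss + 5] ms after step onset.
    Currents are absolute (holding current included), as conventionally
    plotted for these step families.
    """
    p = _require_vc_steps(sweeps)
    if measure not in ("peak_2ms", "ss_160ms"):
        raise ValueError("measure must be 'peak_2ms' or 'ss_160ms'")
    onset_s = p.pre_duration * 1e-3
    if measure == "ss_160ms" and p.step_duration < t_ss + ss_half_window:
        raise ValueError(
            f"step duration {p.step_duration} ms too short for steady-state "
            f"measure at {t_ss} ms"
        )
    I = np.empty(p.n_sweeps)
    for i, r in enumerate(sweeps.responses):
        if measure == "peak_2ms":
            I[i] = r.samples[r.index_at(onset_s + t_peak * 1e-3)]
        else:
            I[i] = float(np.mean(r.window(onset_s + (t_ss - ss_half_window) * 1e-3,
                                          onset_s + (t_ss + ss_half_window) * 1e-3)))
    order = np.argsort(p.step_levels)
    return IVCurve(
        V=np.asarray(p.step_levels)[order], I=I[order], measure=measure,
        n_sweeps=p.n_sweeps,
        meta={"preset": sweeps.preset_label, "condition": sweeps.condition_name},
    )


def slope_conductance(iv: IVCurve, V0: float, half_window: float = 10.0) -> float:
    """Local slope conductance (nS) at ``V0`` from a least-squares line
    through the I-V points within ±``half_window`` mV of V0."""
    mask = np.abs(iv.V - V0) <= half_window + 1e-9
    if mask.sum() < 2:
        raise ValueError(
            f"need >= 2 I-V points within ±{half_window} mV of {V0} mV, "
            f"found {int(mask.sum())}"
        )
    return float(np.polyfit(iv.V[mask], iv.I[mask], 1)[0])


# ----------------------------------------------------------------------
def _exp_decay(t, A, tau, C):
    return A * np.exp(-t / tau) + C


def _instantaneous_tail(r: Trace, tail_onset_s: float, t_offset: float,
                        fit_span: float = 10.0) -> tuple[float, bool]:
    """Back-extrapolated tail amplitude at tail onset; returns (value, fitted)."""
    t0 = tail_onset_s + t_offset * 1e-3
    t1 = tail_onset_s + fit_span * 1e-3
    i0 = r.index_at(t0)
    i1 = max(r.index_at(min(t1, r.t0 + (r.n - 1) * r.dt)), i0 + 4)
    t = (r.times()[i0:i1] - tail_onset_s) * 1e3  # ms from tail onset
    y = r.samples[i0:i1]
    span = y.max() - y.min()
    C0 = y[-1]
    A0 = y[0] - C0
    if span < 1e-12 or abs(A0) < 1e-12:
        return float(np.mean(y)), True  # flat tail: constant is exact
    try:
        # crude tau init: time for |y - C| to fall to 1/e of initial
        resid = np.abs(y - C0)
        below = np.nonzero(resid < abs(A0) / np.e)[0]
        tau0 = t[below[0]] if len(below) else (t[-1] - t[0]) / 2
        tau0 = max(tau0, t[1] - t[0])
        with warnings.catch_warnings():
            # degenerate (perfectly flat or exactly-fit) tails have singular
            # covariance; only the point estimate is used
            warnings.simplefilter("ignore", OptimizeWarning)
            popt, _ = curve_fit(_exp_decay, t, y, p0=[A0, tau0, C0], maxfev=5000)
        if popt[1] <= 0:
            raise RuntimeError("non-positive tau")
        return float(_exp_decay(0.0, *popt)), True
    except Exception:
        # fallback: mean over the first 0.5 ms after the offset
        j1 = max(r.index_at(min(t0 + 0.5e-3, r.t0 + (r.n - 1) * r.dt)), i0 + 1)
        return float(np.mean(r.samples[i0:j1])), False


def tail_activation(sweeps: SweepSet, t_inst_offset: float = 0.3) -> ActivationCurve:
    """Activation curve from instantaneous tail-current amplitudes.

    For each sweep, a single exponential is fitted to the tail current over
    [tail onset + ``t_inst_offset`` ms, tail onset + 10 ms] and evaluated at
    tail onset; sweeps where the fit fails fall back to a short mean and are
    flagged in the metadata.
    """
    p = _require_vc_steps(sweeps)
    if p.tail_level is None:
        raise ValueError("protocol has no tail segment")
    tail_onset = (p.pre_duration + p.step_duration) * 1e-3
    amps = np.empty(p.n_sweeps)
    fallbacks = []
    for i, r in enumerate(sweeps.responses):
        amps[i], fitted = _instantaneous_tail(r, tail_onset, t_inst_offset)
        if not fitted:
            fallbacks.append(i)
    order = np.argsort(p.step_levels)
    return ActivationCurve(
        V_pre=np.asarray(p.step_levels)[order],
        I_tail=amps[order],
        tail_V=float(p.tail_level),
        meta={"preset": sweeps.preset_label, "condition": sweeps.condition_name,
              "fallback_sweeps": fallbacks, "t_inst_offset_ms": t_inst_offset},
    )


def _boltzmann(V, V_half, S, I_max, I_offset):
    return I_offset + I_max / (1.0 + np.exp((V_half - V) / S))


def fit_boltzmann(curve: ActivationCurve) -> BoltzmannFit:
    """Nonlinear least-squares Boltzmann fit of an activation curve.

    Deterministic initialization: V_half at the voltage where the curve
    crosses half of its range, S at a quarter of the voltage span.
    Requires >= 4 points spanning both sides of the inflection.
    """
    V, I = curve.V_pre, curve.I_tail
    if V.size < 4:
        raise ValueError(f"need >= 4 points for a Boltzmann fit, got {V.size}")
    half_level = I.min() + (I.max() - I.min()) / 2.0
    above = I >= half_level
    if above.all() or (~above).all():
        raise ValueError("activation curve does not span its inflection")
    v_half0 = float(V[np.argmin(np.abs(I - half_level))])
    s0 = float(np.ptp(V)) / 4.0
    p0 = [v_half0, s0, float(I.max() - I.min()), float(I.min())]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", OptimizeWarning)
            popt, _ = curve_fit(_boltzmann, V, I, p0=p0, maxfev=10000)
    except RuntimeError as exc:
        raise RuntimeError(
            f"Boltzmann fit failed to converge (init V_half={v_half0}, S={s0}): {exc}"
        ) from exc
    if popt[1] < 0:  # canonicalize: rising Boltzmann with S > 0
        popt[1] = -popt[1]
    resid = _boltzmann(V, *popt) - I
    return BoltzmannFit(V_half=float(popt[0]), S=float(popt[1]),
                        I_max=float(popt[2]), I_offset=float(popt[3]),
                        rms_residual=float(np.sqrt(np.mean(resid**2))))


# ----------------------------------------------------------------------
def subtract_conditions(a: SweepSet, b: SweepSet) -> SweepSet:
    """Per-sample difference a − b, isolating a blocker-sensitive current.

    Both sweep sets must share the protocol, preset, and time base (e.g.
    IbTx alone minus IbTx + linopirdine isolates the linopirdine-sensitive
    current)."""
    for fld in ("protocol", "preset_label"):
        if getattr(a, fld) != getattr(b, fld):
            raise ValueError(f"sweep sets differ in {fld}")
    if a.n_sweeps != b.n_sweeps:
        raise ValueError("sweep sets differ in sweep count")
    responses = []
    for ra, rb in zip(a.responses, b.responses):
        if ra.n != rb.n or abs(ra.dt - rb.dt) > 1e-15:
            raise ValueError("sweep sets differ in time base")
        out = ra.copy(samples=ra.samples - rb.samples)
        out.meta["subtraction"] = {"a": a.condition_name, "b": b.condition_name}
        responses.append(out)
    return replace_sweeps(
        a, responses=responses,
        condition_name=f"{a.condition_name} - {b.condition_name}",
        meta={**a.meta, "subtraction": (a.condition_name, b.condition_name)},
    )


def holding_current_shift(control: Trace, test: Trace,
                          window: tuple[float, float]) -> float:
    """mean(test) − mean(control) over ``window`` (ms); negative = inward.

    With ``control`` recorded after MT-channel block and ``test`` in low
    Ca²⁺, the (negated) shift estimates the resting MT current."""
    if control.unit != test.unit:
        raise ValueError(f"unit mismatch: {control.unit} vs {test.unit}")
    w0, w1 = window[0] * 1e-3, window[1] * 1e-3
    return float(np.mean(test.window(w0, w1)) - np.mean(control.window(w0, w1)))


def junction_correct(V: float, params: RecordingParams,
                     already_corrected: bool = False) -> float:
    """Apply the liquid junction potential correction (once) to a potential."""
    if already_corrected:
        raise ValueError("junction correction already applied")
    return V + params.junction_potential


def vc_time_constant(params: RecordingParams) -> float:
    """Voltage-clamp time constant R_s · C_m in µs."""
    return params.R_s * params.C_m_measured
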