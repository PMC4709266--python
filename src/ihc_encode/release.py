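"""Boltzmann synaptic transfer: membrane potential → vesicle release
probability.

Normalized exocytotic capacitance changes of mature gerbil IHCs approximate
a release probability that is a first-order Boltzmann of membrane potential,

    P_release(V) = 1 / (1 + exp((V_half − V) / S)),

with distinct parameters for apical (V_half −25.8 mV, S 5.5 mV) and basal
(V_half −31.4 mV, S 7.7 mV) cells.  The transform is memoryless and
instantaneous (a steady-state transfer function; no vesicle-pool depletion
or facilitation), so a voltage trace maps sample-wise onto a release
probability trace.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trace import Trace

__all__ = ["ReleaseParams", "ReleaseSummary", "APICAL_RELEASE", "BASAL_RELEASE",
           "p_release", "transform_trace", "summarize_release"]


@dataclass(frozen=True)
class ReleaseParams:
    label: str
    V_half: float  # mV
    S: float  # mV slope factor

    def __post_init__(self) -> None:
        if self.S <= 0:
            raise ValueError("slope factor S must be positive")


APICAL_RELEASE = ReleaseParams("apical", V_half=-25.8, S=5.5)
BASAL_RELEASE = ReleaseParams("basal", V_half=-31.4, S=7.7)


@dataclass
class ReleaseSummary:
    P_rest: float
    P_max: float
    P_min: float
    rest_window: tuple[float, float]  # ms


def p_release(V, params: ReleaseParams):
    """Release probability at membrane potential V (mV); in (0, 1), strictly
    increasing in V, 0.5 at V_half."""
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp((params.V_half - np.asarray(V, dtype=float)) / params.S))


def transform_trace(vm: Trace, params: ReleaseParams) -> Trace:
    """Sample-wise transform of a membrane-potential trace into P_release."""
    if vm.unit != "mV":
        raise ValueError(f"expected a membrane-potential trace in mV, got {vm.unit}")
    out = vm.copy(samples=p_release(vm.samples, params), unit="dimensionless",
                  label=f"{vm.label} P_release")
    out.meta["release_params"] = {"label": params.label, "V_half": params.V_half,
                                  "S": params.S}
    return out


def summarize_release(
    p: Trace,
    rest_window: tuple[float, float],
    stim_window: tuple[float, float] | None = None,
) -> ReleaseSummary:
    """Resting, maximal, and minimal release probability of a P_release trace.

    ``rest_window`` (ms) must precede the stimulus; ``stim_window`` defaults
    to everything after the rest window.
    """
    if rest_window[1] <= rest_window[0]:
        raise ValueError("empty rest window")
    if stim_window is None:
        stim_window = (rest_window[1], p.duration * 1e3)
    if stim_window[0] < rest_window[1]:
        raise ValueError("rest window must precede the stimulus window")
    rest = p.window(rest_window[0] * 1e-3, rest_window[1] * 1e-3)
    stim = p.window(stim_window[0] * 1e-3, stim_window[1] * 1e-3)
    return ReleaseSummary(
        P_rest=float(rest.mean()),
        P_max=float(stim.max()),
        P_min=float(stim.min()),
        rest_window=rest_window,
    )
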