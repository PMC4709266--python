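"""File formats, run configuration, and the simulate → analyze pipeline.

Sweep families are stored in an HDF5 container (one dataset per sweep,
protocol and provenance as JSON attributes) with CSV mirrors so every
artifact is inspectable without the container reader.  Config files are YAML
with explicit unit suffixes (``holding: 500pA``).
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import h5py
import numpy as np
import pandas as pd
import yaml

from . import cc_analysis, release, vc_analysis
from .model import SweepSet, get_condition, get_preset, load_preset, calibrate, simulate
from .protocols import (
    make_cc_steps,
    make_fluid_jet,
    make_sine_protocol,
    make_vc_steps,
    protocol_from_dict,
    protocol_to_dict,
)
from .trace import Trace

__all__ = [
    "SCHEMA_VERSION",
    "SchemaError",
    "ValidationError",
    "RunConfig",
    "ReportBundle",
    "read_trace_csv",
    "write_trace_csv",
    "read_sweepset",
    "write_sweepset",
    "parse_quantity",
    "build_protocol",
    "run_pipeline",
]

SCHEMA_VERSION = 1


class SchemaError(RuntimeError):
    pass


class ValidationError(RuntimeError):
    pass


# ----------------------------------------------------------------------
# traces
def write_trace_csv(trace: Trace, path: str | Path) -> None:
    """CSV with header ``time_s,value,unit`` (unit repeated per row)."""
    df = pd.DataFrame({"time_s": trace.times(), "value": trace.samples,
                       "unit": trace.unit})
    df.to_csv(path, index=False, float_format="%.12g")


def read_trace_csv(path: str | Path) -> Trace:
    df = pd.read_csv(path)
    for col in ("time_s", "value", "unit"):
        if col not in df.columns:
            raise SchemaError(f"trace CSV missing column {col!r}")
    t = df["time_s"].to_numpy(float)
    dt = float(np.median(np.diff(t)))
    return Trace(t0=float(t[0]), dt=dt, samples=df["value"].to_numpy(float),
                 unit=str(df["unit"].iloc[0]), label=str(path))


# ----------------------------------------------------------------------
# sweep container
def write_sweepset(sweeps: SweepSet, path: str | Path) -> None:
    """Lossless (bit-exact) HDF5 serialization of a sweep family."""
    with h5py.File(path, "w") as fh:
        fh.attrs["schema_version"] = SCHEMA_VERSION
        fh.attrs["protocol"] = json.dumps(protocol_to_dict(sweeps.protocol))
        fh.attrs["preset_label"] = sweeps.preset_label
        fh.attrs["condition_name"] = sweeps.condition_name
        fh.attrs["seed"] = -1 if sweeps.seed is None else int(sweeps.seed)
        fh.attrs["meta"] = json.dumps(sweeps.meta, default=str)
        for group_name, traces in (("stimuli", sweeps.stimuli),
                                   ("responses", sweeps.responses)):
            grp = fh.create_group(group_name)
            for i, tr in enumerate(traces):
                ds = grp.create_dataset(f"sweep{i:03d}", data=tr.samples)
                ds.attrs["t0"] = tr.t0
                ds.attrs["dt"] = tr.dt
                ds.attrs["unit"] = tr.unit
                ds.attrs["label"] = tr.label
                ds.attrs["meta"] = json.dumps(tr.meta, default=str)


def _read_traces(grp: h5py.Group) -> list[Trace]:
    out = []
    for key in sorted(grp.keys()):
        ds = grp[key]
        out.append(Trace(t0=float(ds.attrs["t0"]), dt=float(ds.attrs["dt"]),
                         samples=ds[...], unit=str(ds.attrs["unit"]),
                         label=str(ds.attrs["label"]),
                         meta=json.loads(ds.attrs["meta"])))
    return out


def read_sweepset(path: str | Path) -> SweepSet:
    try:
        fh = h5py.File(path, "r")
    except OSError as exc:
        raise SchemaError(f"not a readable sweep container: {exc}") from exc
    with fh:
        version = int(fh.attrs.get("schema_version", -1))
        if version != SCHEMA_VERSION:
            raise SchemaError(
                f"unsupported container schema version {version} "
                f"(expected {SCHEMA_VERSION})"
            )
        seed = int(fh.attrs["seed"])
        return SweepSet(
            protocol=protocol_from_dict(json.loads(fh.attrs["protocol"])),
            stimuli=_read_traces(fh["stimuli"]),
            responses=_read_traces(fh["responses"]),
            preset_label=str(fh.attrs["preset_label"]),
            condition_name=str(fh.attrs["condition_name"]),
            seed=None if seed < 0 else seed,
            meta=json.loads(fh.attrs["meta"]),
        )


# ----------------------------------------------------------------------
# configuration
_QTY_RE = re.compile(r"^\s*([-+0-9.eE]+)\s*([a-zA-Zµ%]*)\s*$")


def parse_quantity(value: Any, expect_unit: Optional[str] = None) -> float:
    """Parse ``"500pA"`` / ``"-64 mV"`` / plain numbers into a float.

    If ``expect_unit`` is given, a mismatching suffix raises."""
    if isinstance(value, (int, float)):
        return float(value)
    m = _QTY_RE.match(str(value))
    if not m:
        raise ValidationError(f"cannot parse quantity {value!r}")
    num, unit = float(m.group(1)), m.group(2)
    if expect_unit and unit and unit != expect_unit:
        raise ValidationError(
            f"expected unit {expect_unit!r} but got {unit!r} in {value!r}"
        )
    return num


_PROTOCOL_BUILDERS = {
    "cc_steps": make_cc_steps,
    "vc_steps": make_vc_steps,
    "sine": make_sine_protocol,
    "fluid_jet": make_fluid_jet,
}


def build_protocol(spec: dict[str, Any]):
    """Build a protocol from a config mapping with a ``kind`` key.

    Values may carry unit suffixes (``"1nA"`` is rejected — amplitudes are
    given in pA — but ``"1000pA"``, ``"300Hz"`` etc. are parsed)."""
    spec = dict(spec)
    kind = spec.pop("kind", None)
    if kind not in _PROTOCOL_BUILDERS:
        raise ValidationError(
            f"protocol kind must be one of {sorted(_PROTOCOL_BUILDERS)}, got {kind!r}"
        )
    kwargs = {k: parse_quantity(v) if not isinstance(v, (dict, type(None))) else v
              for k, v in spec.items()}
    return _PROTOCOL_BUILDERS[kind](**kwargs)


@dataclass
class RunConfig:
    """Declarative description of one simulate → analyze run."""

    preset: str  # "apical" | "basal" | path to a preset YAML
    condition: str
    protocol: dict[str, Any]
    seed: int = 0
    out_dir: str = "."
    analysis: dict[str, Any] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        missing = {"preset", "condition", "protocol"} - set(raw)
        if missing:
            raise ValidationError(f"config missing keys: {sorted(missing)}")
        return cls(**raw)

    def validate(self) -> None:
        if self.preset not in ("apical", "basal") and not Path(self.preset).exists():
            raise ValidationError(f"preset file not found: {self.preset}")
        build_protocol(self.protocol)  # raises on malformed spec
        get_condition(self.condition)  # raises on unknown condition

    def hash(self) -> str:
        payload = json.dumps(
            {"preset": self.preset, "condition": self.condition,
             "protocol": self.protocol, "seed": self.seed,
             "analysis": self.analysis}, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class ReportBundle:
    tables: dict[str, pd.DataFrame]
    provenance: dict[str, Any]

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in self.tables.items():
            df.to_csv(out / f"{name}.csv", index=False, float_format="%.10g")
        with open(out / "provenance.json", "w") as fh:
            json.dump(self.provenance, fh, indent=2, default=str)

    def hash(self) -> str:
        h = hashlib.sha256()
        for name in sorted(self.tables):
            h.update(name.encode())
            h.update(self.tables[name].to_csv(index=False).encode())
        return h.hexdigest()[:12]


# ----------------------------------------------------------------------
def _resolve_preset(name: str):
    if name in ("apical", "basal"):
        return get_preset(name)
    return calibrate(load_preset(name))


def run_pipeline(config: RunConfig, write: bool = False) -> ReportBundle:
    """Execute simulate → analysis → tables for one configuration.

    Voltage-clamp runs produce I-V curves (peak and steady state), slope
    conductances, the tail activation curve and its Boltzmann fit.
    Current-clamp sine runs produce AC/DC components, extrema, half-cycle
    statistics, and (optionally) the release-probability summary.
    Deterministic for a fixed seed.
    """
    config.validate()
    preset = _resolve_preset(config.preset)
    protocol = build_protocol(config.protocol)
    condition = get_condition(config.condition)
    sweeps = simulate(preset, condition, protocol, seed=config.seed)

    tables: dict[str, pd.DataFrame] = {}
    mode = getattr(protocol, "mode", "FJ")
    opts = config.analysis

    if mode == "VC":
        iv_tabs = {}
        for measure in ("peak_2ms", "ss_160ms"):
            iv = vc_analysis.measure_iv(sweeps, measure)
            iv_tabs[measure] = iv
            tables[f"iv_{measure}"] = pd.DataFrame({"V_mV": iv.V, "I_pA": iv.I})
        slope_rows = []
        for v0 in opts.get("slope_at_mV", [-64.0, -54.0]):
            g = vc_analysis.slope_conductance(iv_tabs["ss_160ms"], float(v0))
            slope_rows.append({"V0_mV": float(v0), "g_nS": g})
        tables["slope_conductance"] = pd.DataFrame(slope_rows)
        act = vc_analysis.tail_activation(sweeps)
        tables["activation"] = pd.DataFrame({"V_mV": act.V_pre, "I_pA": act.I_tail})
        try:
            fit = vc_analysis.fit_boltzmann(act)
            tables["activation_fit"] = pd.DataFrame([{
                "V_half_mV": fit.V_half, "S_mV": fit.S, "I_max_pA": fit.I_max,
                "I_offset_pA": fit.I_offset, "rms_pA": fit.rms_residual}])
        except (ValueError, RuntimeError):
            pass
    elif mode == "CC" and hasattr(protocol, "frequency"):
        r = sweeps.responses[0]
        f = protocol.frequency
        onset = protocol.sine_onset
        dc, ac = cc_analysis.ac_dc_decompose(r, f, onset)
        tables["ac_dc"] = pd.DataFrame({
            "cycle": np.arange(len(ac)),
            "dc_mV": dc.samples, "ac_p2p_mV": ac,
        })
        series = cc_analysis.detect_extrema(r, f, onset)
        tables["extrema"] = pd.DataFrame(
            [{"half_cycle": e.half_cycle_index, "t_ms": e.time,
              "Vm_mV": e.value, "kind": e.kind} for e in series.events])
        hc = cc_analysis.half_cycle_stats(series)
        tables["half_cycles"] = pd.DataFrame(
            [{"half_cycle": k, "width_ms": w, "error_pct": e}
             for (k, w), (_, e) in zip(hc.half_widths, hc.half_errors_pct)])
        if opts.get("release", False):
            params = release.APICAL_RELEASE if preset.label == "apical" \
                else release.BASAL_RELEASE
            p_tr = release.transform_trace(r, params)
            summ = release.summarize_release(
                p_tr, rest_window=(0.0, onset),
                stim_window=(onset, onset + protocol.sine_duration))
            tables["release_summary"] = pd.DataFrame([{
                "P_rest": summ.P_rest, "P_max": summ.P_max, "P_min": summ.P_min}])
    elif mode == "CC":
        rows = []
        for level, r in zip(protocol.step_levels, sweeps.responses):
            onset = protocol.pre_duration
            end = onset + protocol.step_duration
            v_peak, v_ss = cc_analysis.peak_and_steady_vm(r, onset, end)
            rows.append({"I_pA": level, "V_peak_mV": v_peak, "V_ss_mV": v_ss})
        tables["cc_steps"] = pd.DataFrame(rows)

    bundle = ReportBundle(
        tables=tables,
        provenance={"config_hash": config.hash(), "seed": config.seed,
                    "preset": config.preset, "condition": config.condition,
                    "package_version": _version()},
    )
    if write:
        out = Path(config.out_dir)
        bundle.write(out)
        write_sweepset(sweeps, out / "sweeps.h5")
        for i, r in enumerate(sweeps.responses):
            write_trace_csv(r, out / f"response{i:03d}.csv")
    return bundle


def _version() -> str:
    from . import __version__
    return __version__


def read_abf(path: str | Path):  # pragma: no cover - documented stub
    """Importer stub for proprietary acquisition formats (pClamp/ABF).

    Reading vendor binary formats is out of scope; convert recordings to the
    CSV/HDF5 container formats above, or attach an ABF reader here."""
    raise NotImplementedError("ABF import is not supported; convert to CSV/HDF5")
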