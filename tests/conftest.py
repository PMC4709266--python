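import numpy as np
import pytest

from ihc_encode.model import (
    CellPreset,
    Conductance,
    GatingParams,
    MTParams,
    get_preset,
)


@pytest.fixture(scope="session")
def apical():
    return get_preset("apical")


@pytest.fixture(scope="session")
def basal():
    return get_preset("basal")


def make_toy_preset(
    g_leak=10.0,
    E_leak=-70.0,
    C_m=12.0,
    gated=(),
    g_mt=0.0,
    resting_po=None,
    noise_vc=0.0,
    noise_cc=0.0,
    label="toy",
):
    """Hand-built calibrated preset for analytic comparisons.

    ``gated`` is a sequence of (name, g_max, E_rev, GatingParams).
    """
    conductances = [Conductance("leak", g_leak, E_leak, None)]
    conductances += [Conductance(n, g, e, gp) for n, g, e, gp in gated]
    return CellPreset(
        label=label,
        C_m=C_m,
        conductances=tuple(conductances),
        mt=MTParams(g_MT_max=g_mt,
                    resting_Po=resting_po or {"Ca1.3": 0.0, "lowCa40": 0.0}),
        noise_sd_vc=noise_vc,
        noise_sd_cc=noise_cc,
        calibrated=True,
    )


@pytest.fixture
def leak_cell():
    """Passive RC cell: 10 nS leak at -70 mV, 12 pF (tau = 1.2 ms)."""
    return make_toy_preset()


def single_channel_preset(rng: np.random.Generator) -> CellPreset:
    """One gated K conductance with randomized Boltzmann parameters, slow
    enough for tail-current analysis at 20 kHz sampling."""
    gp = GatingParams(
        V_half=float(rng.uniform(-95.0, -45.0)),
        S=float(rng.uniform(6.0, 12.0)),
        tau_base=float(rng.uniform(3.0, 6.0)),
        tau_amp=float(rng.uniform(5.0, 15.0)),
        tau_Vhalf=float(rng.uniform(-90.0, -60.0)),
        tau_sigma=float(rng.uniform(25.0, 40.0)),
    )
    g = float(rng.uniform(5.0, 30.0))
    return make_toy_preset(g_leak=1.0, E_leak=-70.0,
                           gated=[("K_n_neg", g, -82.0, gp)],
                           label=f"random-{gp.V_half:.1f}")
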