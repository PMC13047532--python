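import numpy as np
import pytest

from lipoxkin import AntioxidantSpec, OxTrace, analyze_trace
from lipoxkin.oximetry_sim import (
    DEFAULT_CHAIN,
    SimConfig,
    generate_experiment_set,
    simulate_trace,
)


@pytest.fixture(scope="session")
def chain():
    return DEFAULT_CHAIN


@pytest.fixture(scope="session")
def demo_traces():
    """The five-trace liposome experiment (seeded default noise)."""
    return generate_experiment_set(seed=1)


@pytest.fixture(scope="session")
def demo_reports(demo_traces, chain):
    control = demo_traces["control"]
    reference = demo_traces["PMHC"]
    return {
        name: analyze_trace(demo_traces[name], control, reference, chain,
                            is_reference=(name == "PMHC"))
        for name in ("PMHC", "TBG", "IBG", "DM506")
    }


@pytest.fixture(scope="session")
def atinit_trace():
    """Factory for noiseless traces with the antioxidant present from
    initiation (clean Eq-1 conditions: no pre-built radical pool)."""
    cache = {}

    def make(kinh, n, conc0, dt=4.0, extra_s=800.0):
        key = (kinh, n, conc0, dt, extra_s)
        if key not in cache:
            tau = n * conc0 / DEFAULT_CHAIN.Ri
            cfg = SimConfig(
                aox=AntioxidantSpec("aox", conc0, kinh, n),
                aox_at_initiation=True,
                total_s=2.4 * tau + extra_s,
                dt_sample=dt,
            )
            cache[key] = simulate_trace(cfg)
        return cache[key]

    return make


@pytest.fixture()
def sharp_break_trace():
    """Idealized two-slope trace: 20 nM/s for 408.16 s after the
    antioxidant injection, then 110 nM/s."""
    t = np.arange(0.0, 1500.0, 1.0)
    tau = 408.16
    o2 = np.where(t < tau,
                  200e-6 - 20e-9 * t,
                  200e-6 - 20e-9 * tau - 110e-9 * (t - tau))
    return OxTrace(t, o2, t_init=0.0, t_aox=0.0,
                   meta={"compound": "synthetic-two-slope"})
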