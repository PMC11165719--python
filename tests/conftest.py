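import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", derandomize=True, deadline=None, suppress_health_check=list(HealthCheck)
)
settings.load_profile("suite")

from sevilletor.lattice import GridState, NumericalScheme, ParameterFields, run_simulation
from sevilletor.models import load_preset, run_tail

REGIME_K1 = (0.0, 1.0, 2.3, 3.0, 4.0)
REGIME_LABELS = {
    0.0: "lateral_inhibition",
    1.0: "rotating_waves",
    2.3: "excitable_periodic_waves",
    3.0: "homogeneous_static",
    4.0: "bistable_frozen",
}


def square_regime_run(k1: float, seed: int, N: int = 100, duration: float = 600.0):
    """A square-domain run from seeded random initial conditions."""
    rng = np.random.default_rng(seed)
    g = GridState(rng.uniform(-0.1, 0.1, (N, N)), rng.uniform(-0.1, 0.1, (N, N)))
    p = ParameterFields(k1=np.full(N, k1), k3=np.ones(N), k4=np.ones(N), k2=1.0, D=0.3)
    s = NumericalScheme(dt=0.01, duration=duration, snapshot_interval=2.0)
    return run_simulation(g, p, s, seed=seed)


@pytest.fixture(scope="session")
def regime_records():
    """100x100 runs for the five reference k1 values, seeds 0-4."""
    return {
        (k1, seed): square_regime_run(k1, seed)
        for k1 in REGIME_K1
        for seed in range(5)
    }


@pytest.fixture(scope="session")
def tail_records():
    """Noise-free tail runs of the four model presets (+ CG without FG)."""
    out = {}
    for name in ("cws", "cg", "pord"):
        out[name] = (load_preset(name), run_tail(load_preset(name), seed=0))
    p_nofg = load_preset("cg", FG=None)
    out["cg_nofg"] = (p_nofg, run_tail(p_nofg, seed=0))
    return out


@pytest.fixture(scope="session")
def noisy_tail_records():
    """CWS and PORD tails with the default multiplicative noise, 3 seeds."""
    out = {}
    for name in ("cws", "pord"):
        p = load_preset(name)
        out[name] = (p, {s: run_tail(p, seed=s, with_noise=True) for s in (1, 2, 3)})
    return out
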