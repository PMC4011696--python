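import numpy as np
import pytest

import periflow as pf


@pytest.fixture
def const_spec3():
    """Three-site chain with all rates equal to one (autonomous)."""
    sched = pf.RateSchedule(3, [pf.constant(1.0)] * 4)
    return pf.ModelSpec(3, sched)


@pytest.fixture
def entrain_spec3():
    """Three-site chain under the fully periodic preset forcing."""
    sched, x0 = pf.make_scenario("entrain_demo", 3, seed=1)
    return pf.ModelSpec(3, sched), x0


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_periodic_schedule(n: int, rng: np.random.Generator) -> pf.RateSchedule:
    """A random all-sinusoid schedule whose minimal common period is 6."""
    T = 6.0
    specs = []
    for i in range(n + 1):
        baseline = float(rng.uniform(0.7, 1.5))
        amplitude = float(rng.uniform(0.15, 0.5)) * baseline
        sub = T if i == 0 else float(rng.choice([T, T / 2, T / 3]))
        phase = float(rng.uniform(0.0, sub))
        specs.append(pf.sinusoid(baseline, amplitude, sub, phase))
    return pf.RateSchedule(n, specs)
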