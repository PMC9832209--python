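import numpy as np
import pytest

from sarn.netbuild import ROITimeSeries, build_network
from sarn.synthgen import SynthConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(7)


@pytest.fixture
def tiny_ts(rng):
    """A 6-region, 16-timepoint subject."""
    return ROITimeSeries(
        values=rng.standard_normal((6, 16)),
        region_ids=[f"R{i}" for i in range(6)],
        subject_id="sub-000",
        label=1,
    )


@pytest.fixture
def tiny_net(tiny_ts):
    return build_network(tiny_ts, n_steps=4, k=2, max_dist=3)


@pytest.fixture
def small_dataset():
    """12-subject planted dataset small enough for fast training tests."""
    cfg = SynthConfig(
        n_regions=12,
        n_timepoints=80,
        n_control=6,
        n_addicted=6,
        k_planted=3,
        beta=2.0,
        seed=11,
    )
    return generate_dataset(cfg)


def finite_difference_grad(f, x, eps=1e-6):
    """Central-difference gradient of scalar f at array x."""
    x = np.asarray(x, dtype=np.float64)
    g = np.zeros_like(x)
    flat = x.ravel()
    gf = g.ravel()
    for i in range(flat.size):
        orig = flat[i]
        flat[i] = orig + eps
        hi = f(x)
        flat[i] = orig - eps
        lo = f(x)
        flat[i] = orig
        gf[i] = (hi - lo) / (2 * eps)
    return g
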