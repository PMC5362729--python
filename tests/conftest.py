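import numpy as np
import pytest

from lspsmap.synthdata import CircuitConfig, ipsc_kernel
from lspsmap.trace import Trace

SAMPLE_INTERVAL = 1e-4  # 10 kHz


@pytest.fixture
def quiet_config():
    """Circuit with evoked + spontaneous input and noise disabled."""
    return CircuitConfig(connect_prob0=0.0, spont_rate=0.0, noise_sd=0.0, seed=7)


@pytest.fixture
def kernel_50pA():
    """Unit-shape inward IPSC of 50 pA peak, default kinetics."""
    return ipsc_kernel(duration=150.0, sample_interval=0.1, amplitude=50.0,
                       tau_rise=1.0, tau_decay=15.0)


def plant_events(noise_sd, event_times_ms, amplitude=50.0, duration_ms=400.0,
                 t0_ms=-100.0, seed=0, tau_rise=1.0, tau_decay=15.0) -> Trace:
    """Trace with IPSC kernels planted at known onsets plus Gaussian noise."""
    rng = np.random.default_rng(seed)
    n = int(round(duration_ms / 0.1))
    x = rng.normal(0.0, noise_sd, n) if noise_sd > 0 else np.zeros(n)
    k = ipsc_kernel(duration=min(10 * tau_decay, duration_ms), sample_interval=0.1,
                    amplitude=amplitude, tau_rise=tau_rise, tau_decay=tau_decay).samples
    for t in np.atleast_1d(event_times_ms):
        i0 = int(round((t - t0_ms) / 0.1))
        m = min(k.size, n - i0)
        if m > 0:
            x[i0:i0 + m] += k[:m]
    return Trace(x, sample_interval=SAMPLE_INTERVAL, t0=t0_ms * 1e-3, units="pA")
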