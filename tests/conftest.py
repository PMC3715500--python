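import numpy as np
import pytest

from flimfret.model import DecayParams


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture(params=[0.25, 0.5, 0.75])
def study_params(request):
    """The three interacting-donor fractions of the study conditions."""
    return DecayParams(fd=request.param, tau_d=2.5, tau_f=1.5)


def noiseless_binned_counts(params, config, total=1.0):
    """Expected (noise-free) channel counts of the wrapped, binned mixture."""
    k = np.arange(config.n_ch)
    w, T = config.gate_width, config.window

    def p_k(tau):
        r = np.exp(-w / tau)
        return np.exp(-k * w / tau) * (1 - r) / (1 - np.exp(-T / tau))

    phi = params.phi
    return total * (phi * p_k(params.tau_f) + (1 - phi) * p_k(params.tau_d))
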