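"""Discrete estimators: quadrature, finite-gate corrections, masking."""

import numpy as np
import pytest

from flimfret.estimators import (
    background_subtract,
    corrected_estimates,
    estimate_batch,
    mask_moments,
    trapezoid_transforms,
)
from flimfret.model import DecayParams
from flimfret.simulate import (
    AcquisitionConfig,
    DecayHistogram,
    simulate_decays,
    tcspc_config,
)
from conftest import noiseless_binned_counts


def _cfg(n_ch):
    return AcquisitionConfig(mode="gated", n_ch=n_ch, irf_fwhm=0.0)


def test_single_spike_first_moment():
    cfg = _cfg(8)
    counts = np.zeros(8)
    counts[3] = 100.0
    h = DecayHistogram(counts=counts, config=cfg)
    u, v, m1, m2 = trapezoid_transforms(h)
    assert m1 == pytest.approx(cfg.gate_centers[3])
    assert m2 == pytest.approx(cfg.gate_centers[3] ** 2)


def test_empty_decay_raises():
    h = DecayHistogram(counts=np.zeros(8), config=_cfg(8))
    with pytest.raises(ValueError, match="empty"):
        trapezoid_transforms(h)
    with pytest.raises(ValueError, match="empty"):
        corrected_estimates(h, 2.5)


def test_raw_first_moment_is_biased_until_corrected():
    """The naive first moment carries finite-window/finite-gate bias.

    At 64 narrow channels the 12.5 ns window truncation makes the raw
    first moment underestimate the 2.5 ns lifetime; at 4 wide gates the
    gate-centre binning bias is several times larger.  The corrected mean
    lifetime removes both exactly (see the exactness tests below).
    """
    p = DecayParams(0.0, 2.5, 2.5)
    m1 = {}
    for n_ch in (4, 64):
        cfg = _cfg(n_ch)
        h = DecayHistogram(noiseless_binned_counts(p, cfg, 1000.0), cfg)
        m1[n_ch] = trapezoid_transforms(h)[2]
    assert m1[64] < 2.5  # truncation bias
    assert abs(m1[4] - 2.5) > abs(m1[64] - 2.5)  # wide gates are worse


@pytest.mark.parametrize("n_ch", [4, 8, 16, 32, 64])
def test_exact_inversion_of_noiseless_binned_decays(n_ch, study_params):
    """Corrected estimators invert the discrete forward operator exactly."""
    cfg = _cfg(n_ch)
    counts = noiseless_binned_counts(study_params, cfg, 1000.0)
    r = corrected_estimates(DecayHistogram(counts, cfg), 2.5)
    assert r.polar_ok
    assert abs(r.fd_polar - study_params.fd) < 1e-6
    assert abs(r.tauf_polar - 1.5) < 1e-6
    assert r.moments_ok
    assert abs(r.fd_moments - study_params.fd) < 1e-6
    assert abs(r.tauf_moments - 1.5) < 1e-6


@pytest.mark.parametrize("n_ch", [4, 8, 16, 32, 64])
def test_corrected_mean_lifetime_exact_for_mono_exponential(n_ch):
    cfg = _cfg(n_ch)
    p = DecayParams(0.0, 2.5, 2.5)
    counts = noiseless_binned_counts(p, cfg, 1000.0)
    r = corrected_estimates(DecayHistogram(counts, cfg), 2.5)
    assert r.tau_mean == pytest.approx(2.5, abs=1e-6)
    assert r.no_fret
    assert r.fd_polar == 0.0 and np.isnan(r.tauf_polar)


def test_uncorrected_degrades_with_few_gates_corrected_does_not():
    p = DecayParams(0.5, 2.5, 1.5)
    err_naive, err_corr = {}, {}
    for n_ch in (8, 64):
        cfg = _cfg(n_ch)
        counts = noiseless_binned_counts(p, cfg, 1000.0)[None, :]
        naive = estimate_batch(counts, cfg, 2.5, corrected=False).iloc[0]
        corr = estimate_batch(counts, cfg, 2.5, corrected=True).iloc[0]
        err_naive[n_ch] = abs(naive.fd_polar - 0.5)
        err_corr[n_ch] = abs(corr.fd_polar - 0.5)
    assert err_naive[8] > 0.05  # wide gates wreck the naive inversion
    assert err_naive[64] < 0.05  # narrow channels nearly continuous
    assert err_naive[8] > 10 * err_naive[64]
    assert err_corr[8] < 1e-6 and err_corr[64] < 1e-6


def test_moments_mask_threshold():
    import pandas as pd

    df = pd.DataFrame({
        "fd_polar": [0.1, 0.5, 0.2], "polar_ok": [True, True, True],
        "mfd": [0.1, 0.4, 0.2], "fd_moments": [0.3, 0.3, 0.3],
        "tauf_moments": [1.0, 1.0, 1.0], "moments_ok": [True, True, True],
    })
    out = mask_moments(df, threshold=0.2)
    assert out.loc[0, "moments_masked_low_fd"]  # below threshold
    assert not out.loc[1, "moments_masked_low_fd"]  # above
    assert out.loc[2, "moments_masked_low_fd"]  # exactly at: strictly greater
    assert np.isnan(out.loc[0, "fd_moments"])
    assert out.loc[1, "fd_moments"] == 0.3


def test_background_subtract_floor_and_roundtrip(rng):
    counts = rng.poisson(20.0, size=(50, 8)).astype(float)
    sub, n = background_subtract(counts + 5.0, 5.0)
    assert n == 0
    assert np.allclose(sub, counts)
    over, n = background_subtract(np.ones((2, 8)), 3.0)
    assert np.all(over == 0.0)
    assert n == 16


def test_background_length_validation():
    with pytest.raises(ValueError):
        background_subtract(np.ones((4, 8)), np.ones(5))


def test_noisy_median_converges_with_photons(rng):
    """Consistency: medians over many decays approach truth as N grows."""
    cfg = tcspc_config()
    p = DecayParams(0.5, 2.5, 1.5)
    err, spread = {}, {}
    for n in (200, 5000):
        counts = simulate_decays(p, n, 1024, cfg, rng)
        df = estimate_batch(counts, cfg, 2.5)
        vals = df.fd_polar[df.polar_ok & np.isfinite(df.fd_polar)]
        err[n] = abs(np.median(vals) - 0.5)
        q1, q3 = np.percentile(vals, [25, 75])
        spread[n] = q3 - q1
    assert err[5000] < 0.02
    assert spread[5000] < spread[200] / 2


def test_precision_ordering_on_simulated_data(rng):
    """mf_D is least noisy; moments (where valid) beat the polar spread."""
    cfg = tcspc_config()
    p = DecayParams(0.75, 2.5, 1.5)
    counts = simulate_decays(p, 1000, 2048, cfg, rng)
    df = estimate_batch(counts, cfg, 2.5)

    def iqr(col, okcol):
        v = df[col][df[okcol] & np.isfinite(df[col])] if okcol else \
            df[col][np.isfinite(df[col])]
        q1, q3 = np.percentile(v, [25, 75])
        return q3 - q1

    i_mfd = iqr("mfd", None)
    i_mom = iqr("fd_moments", "moments_ok")
    i_pol = iqr("fd_polar", "polar_ok")
    assert i_mfd < i_mom < i_pol
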