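"""Monte Carlo simulator: conservation, shape, determinism, image effects."""

import numpy as np
import pytest
from scipy.stats import chisquare

from flimfret.model import DecayParams, continuous_polar_of_model
from flimfret.simulate import (
    AcquisitionConfig,
    bin_histogram,
    gated_config,
    read_stack,
    sample_arrival_times,
    simulate_decays,
    simulate_flim_image,
    smooth_stack_3x3,
    tcspc_config,
    write_stack,
)
from conftest import noiseless_binned_counts


def test_empty_and_single_photon(rng):
    cfg = tcspc_config()
    p = DecayParams(0.5, 2.5, 1.5)
    assert sample_arrival_times(p, 0, cfg, rng).size == 0
    h = bin_histogram(np.array([0.1]), AcquisitionConfig(n_ch=4))
    assert h.counts.tolist() == [1, 0, 0, 0]
    h0 = bin_histogram(np.array([]), AcquisitionConfig(n_ch=4))
    assert h0.total == 0


def test_out_of_window_times_rejected():
    with pytest.raises(ValueError):
        bin_histogram(np.array([13.0]), AcquisitionConfig(n_ch=4))


def test_sample_mean_matches_model(rng):
    # unwindowed sampling: the empirical mean equals the intensity-weighted
    # mean lifetime within 3 standard errors
    cfg = AcquisitionConfig(irf_fwhm=0.0, edge="none")
    p = DecayParams(0.5, 2.5, 1.5)
    t = sample_arrival_times(p, 10**6, cfg, rng)
    sd = np.sqrt(9.5 - 2.125**2)  # from the model's first two moments
    assert abs(t.mean() - 2.125) < 3 * sd / 1000


def test_pure_donor_sample_mean(rng):
    cfg = AcquisitionConfig(irf_fwhm=0.0, edge="none")
    t = sample_arrival_times(DecayParams(0.0, 2.5, 1.5), 200_000, cfg, rng)
    assert abs(t.mean() - 2.5) < 3 * 2.5 / np.sqrt(200_000)


def test_uniform_binning_counts(rng):
    cfg = AcquisitionConfig(n_ch=10)
    times = rng.uniform(0, cfg.window, 10**6)
    h = bin_histogram(times, cfg)
    assert h.total == 10**6
    assert np.all(np.abs(h.counts - 1e5) < 3 * np.sqrt(1e5))


@pytest.mark.parametrize("edge", ["clip", "wrap"])
def test_photon_conservation(rng, edge):
    cfg = AcquisitionConfig(mode="gated", n_ch=8, irf_fwhm=0.2, edge=edge)
    counts = simulate_decays(DecayParams(0.5, 2.5, 1.5), 1000, 64, cfg, rng)
    assert np.all(counts.sum(axis=1) == 1000)


def test_histogram_shape_chi2(rng):
    """Large-N per-channel counts follow the wrapped binned model."""
    cfg = AcquisitionConfig(n_ch=64, irf_fwhm=0.0)
    p = DecayParams(0.5, 2.5, 1.5)
    counts = simulate_decays(p, 10**6, 1, cfg, rng)[0]
    expected = noiseless_binned_counts(p, cfg, total=10**6)
    stat, pval = chisquare(counts, expected * counts.sum() / expected.sum())
    assert pval > 1e-4


def test_wrapped_phasor_matches_continuous_model(rng):
    """Periodic wrapping preserves the phasor at the fundamental frequency."""
    cfg = AcquisitionConfig(n_ch=64, irf_fwhm=0.0, edge="wrap")
    p = DecayParams(0.5, 2.5, 1.5)
    counts = simulate_decays(p, 4 * 10**6, 1, cfg, rng)[0]
    t = cfg.gate_centers
    u = (counts * np.cos(cfg.omega * t)).sum() / counts.sum()
    v = (counts * np.sin(cfg.omega * t)).sum() / counts.sum()
    pc = continuous_polar_of_model(p, cfg.omega)
    assert abs(u - pc.u) < 1e-3
    assert abs(v - pc.v) < 1e-3


def test_seeded_determinism():
    cfg = gated_config(n_ch=8)
    p = DecayParams(0.25, 2.5, 1.5)
    a = simulate_flim_image(p, 300, cfg, shape=(8, 8), rng=42)
    b = simulate_flim_image(p, 300, cfg, shape=(8, 8), rng=42)
    assert np.array_equal(a.data, b.data)
    c = simulate_flim_image(p, 300, cfg, shape=(8, 8), rng=43)
    assert not np.array_equal(a.data, c.data)


def test_image_totals_and_offset(rng):
    p = DecayParams(0.5, 2.5, 1.5)
    # no offset, no smoothing: per-pixel totals conserved exactly
    cfg = AcquisitionConfig(mode="gated", n_ch=8, irf_fwhm=0.0)
    st = simulate_flim_image(p, 1000, cfg, shape=(16, 16), rng=rng)
    assert np.all(st.data.sum(axis=2) == 1000)
    # Poisson offset: mean excess over pixels equals the offset mean
    cfg = AcquisitionConfig(mode="gated", n_ch=8, irf_fwhm=0.0,
                            offset_mean=190.0)
    st = simulate_flim_image(p, 1000, cfg, shape=(64, 64), rng=rng)
    excess = st.data.sum(axis=2) - 1000
    assert abs(excess.mean() - 190.0) < 4 * np.sqrt(190.0 / 4096)


def test_smoothing_preserves_uniform_and_reduces_noise(rng):
    flat = np.full((16, 16, 4), 7.0)
    assert np.allclose(smooth_stack_3x3(flat), flat)
    noisy = rng.poisson(50.0, size=(32, 32, 4)).astype(float)
    sm = smooth_stack_3x3(noisy)
    interior = sm[1:-1, 1:-1]
    assert interior.var() < noisy[1:-1, 1:-1].var() / 5


def test_stack_tiff_roundtrip(tmp_path, rng):
    cfg = gated_config(n_ch=8)
    st = simulate_flim_image(DecayParams(0.5, 2.5, 1.5), 500, cfg,
                             shape=(8, 8), rng=rng)
    path = tmp_path / "stack.tif"
    write_stack(st, path)
    back = read_stack(path)
    assert np.allclose(back.data, st.data, atol=1e-4)
    assert back.config.n_ch == 8
    assert back.config.mode == "gated"
    assert back.truth["fd"] == 0.5
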