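"""Closed-form model transforms and their exact inversions."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from flimfret.model import (
    DecayParams,
    MomentPair,
    PolarCoordinate,
    continuous_moments_of_model,
    continuous_polar_of_model,
    fd_from_phi,
    mean_lifetime_model,
    mfd_from_mean_lifetime,
    moments_invert,
    mono_phasor,
    omega_from_rep_rate,
    phi_from_fd,
    polar_invert,
)

OMEGA = omega_from_rep_rate()  # 80 MHz fundamental


@pytest.mark.parametrize("fd,expected_phi", [
    (0.0, 0.0),
    (0.5, 0.375),
    (0.25, 0.1666667),
    (1.0, 1.0),
])
def test_intensity_fraction(fd, expected_phi):
    phi = phi_from_fd(fd, 2.5, 1.5)
    assert phi == pytest.approx(expected_phi, abs=1e-6)
    # round trip back to the molecular fraction
    assert fd_from_phi(phi, 2.5, 1.5) == pytest.approx(fd, abs=1e-12)


@pytest.mark.parametrize("fd,expected", [
    (0.0, 2.5), (0.5, 2.125), (0.75, 1.8571429),
])
def test_mean_lifetime(fd, expected):
    p = DecayParams(fd=fd, tau_d=2.5, tau_f=1.5)
    assert mean_lifetime_model(p) == pytest.approx(expected, abs=1e-6)
    # the mean lifetime is the first temporal moment
    assert continuous_moments_of_model(p).m1 == pytest.approx(
        mean_lifetime_model(p), abs=1e-12)


@pytest.mark.parametrize("tau_mean,expected", [
    (2.5, 0.0), (2.125, 0.45369), (1.8571429, 0.65083),
])
def test_minimal_fraction_closed_form(tau_mean, expected):
    mfd, ok = mfd_from_mean_lifetime(tau_mean, 2.5)
    assert ok
    assert mfd == pytest.approx(expected, abs=2e-5)


def test_minimal_fraction_is_the_minimum_over_tau_f():
    # independent oracle: minimize the candidate f_D over a dense tau_f grid
    tau_d, tau_mean = 2.5, 2.125
    tau_f = np.linspace(1e-4, tau_mean - 1e-4, 200001)
    cand = tau_d * (tau_d - tau_mean) / (
        tau_d * (tau_d - tau_mean) + tau_f * (tau_mean - tau_f)
    )
    mfd, _ = mfd_from_mean_lifetime(tau_mean, tau_d)
    assert mfd == pytest.approx(cand.min(), abs=1e-9)
    assert tau_f[cand.argmin()] == pytest.approx(tau_mean / 2, abs=1e-3)


def test_minimal_fraction_out_of_model():
    mfd, ok = mfd_from_mean_lifetime(2.6, 2.5)
    assert mfd == 0.0 and not ok


def test_mono_exponential_phasor_on_semicircle():
    for tau in np.geomspace(0.01, 50, 41):
        u, v = mono_phasor(tau, OMEGA)
        assert abs(u * u + v * v - u) < 1e-12


@pytest.mark.parametrize("fd,expected_uv", [
    (0.0, (0.38773, 0.48723)),
    (0.5, (0.48142, 0.48479)),
])
def test_polar_transform_values(fd, expected_uv):
    p = DecayParams(fd=fd, tau_d=2.5, tau_f=1.5)
    pc = continuous_polar_of_model(p, OMEGA)
    assert pc.u == pytest.approx(expected_uv[0], abs=1e-5)
    assert pc.v == pytest.approx(expected_uv[1], abs=1e-5)


@pytest.mark.parametrize("fd,expected_m", [
    (0.0, (2.5, 12.5)),
    (0.5, (2.125, 9.5)),
    (0.25, (2.33333, 11.16667)),
])
def test_moment_transform_values(fd, expected_m):
    p = DecayParams(fd=fd, tau_d=2.5, tau_f=1.5)
    m = continuous_moments_of_model(p)
    assert m.m1 == pytest.approx(expected_m[0], abs=1e-5)
    assert m.m2 == pytest.approx(expected_m[1], abs=1e-5)


def test_round_trip_exactness_on_grid():
    """Both inversions recover (f_D, tau_F) to 1e-9 from noiseless transforms."""
    for fd in np.arange(0.05, 0.96, 0.1):
        for tau_f in np.arange(0.1, 2.41, 0.23):
            p = DecayParams(fd=float(fd), tau_d=2.5, tau_f=float(tau_f))
            rp = polar_invert(continuous_polar_of_model(p, OMEGA), 2.5, OMEGA)
            rm = moments_invert(continuous_moments_of_model(p), 2.5)
            assert rp.ok and rm.ok
            assert abs(rp.fd - fd) < 1e-9 and abs(rp.tau_f - tau_f) < 1e-9
            assert abs(rm.fd - fd) < 1e-9 and abs(rm.tau_f - tau_f) < 1e-9


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    fd=st.floats(0.1, 0.9),
    tau_f_frac=st.floats(0.1, 0.9),
    tau_d=st.floats(1.5, 4.0),
)
def test_polar_inversion_matches_brute_force(fd, tau_f_frac, tau_d):
    """Inversion agrees with a grid-plus-refine search of the forward model."""
    tau_f = tau_f_frac * tau_d
    p = DecayParams(fd=fd, tau_d=tau_d, tau_f=tau_f)
    target = continuous_polar_of_model(p, OMEGA)
    r = polar_invert(target, tau_d, OMEGA)
    assert r.ok
    # oracle: coarse 2-D scan of phasor distance, then local refinement
    from scipy.optimize import minimize

    def dist(x):
        q = DecayParams(fd=min(max(x[0], 0.0), 1.0), tau_d=tau_d,
                        tau_f=min(max(x[1], 1e-3), tau_d - 1e-6))
        pc = continuous_polar_of_model(q, OMEGA)
        return (pc.u - target.u) ** 2 + (pc.v - target.v) ** 2

    grid = [(f, t) for f in np.linspace(0.05, 0.95, 19)
            for t in np.linspace(0.05, tau_d - 0.05, 19)]
    x0 = min(grid, key=dist)
    res = minimize(dist, x0, method="Nelder-Mead",
                   options={"xatol": 1e-12, "fatol": 1e-24,
                            "maxiter": 4000, "maxfev": 4000})
    # the oracle must actually have located the optimum to compare tightly
    assert res.fun < 1e-16
    assert abs(r.fd - res.x[0]) < 1e-4
    assert abs(r.tau_f - res.x[1]) < 1e-4


def test_no_fret_boundaries():
    # phasor at the donor point: zero fraction, lifetime undefined
    ud, vd = mono_phasor(2.5, OMEGA)
    r = polar_invert(PolarCoordinate(ud, vd), 2.5, OMEGA)
    assert r.no_fret and r.fd == 0.0 and np.isnan(r.tau_f)
    # moments of the pure donor: flagged no-FRET
    rm = moments_invert(MomentPair(2.5, 12.5), 2.5)
    assert rm.no_fret and rm.fd == 0.0
    # first moment above the donor lifetime: out of model
    rm2 = moments_invert(MomentPair(2.7, 16.0), 2.5)
    assert rm2.no_fret and rm2.fd == 0.0


def test_moments_invalid_window_flagged():
    # second moment inconsistent with any tau_f in (0, tau_d): flagged
    r = moments_invert(MomentPair(2.0, 11.9), 2.5)
    assert not r.ok


def test_mfd_bounds_true_fraction_from_below():
    """mf_D <= f_D on the study grid, equal only where tau_f = <tau>/2."""
    for fd in np.arange(0.05, 0.96, 0.05):
        for tau_f in np.arange(0.1, 2.41, 0.1):
            p = DecayParams(fd=float(fd), tau_d=2.5, tau_f=float(tau_f))
            tau_mean = mean_lifetime_model(p)
            mfd, _ = mfd_from_mean_lifetime(tau_mean, 2.5)
            assert mfd <= fd + 1e-12
            if abs(tau_f - tau_mean / 2) > 0.02:
                assert mfd < fd
    # equality case solved self-consistently: tau_f = <tau>/2
    from scipy.optimize import brentq

    fd = 0.5
    f = lambda tf: mean_lifetime_model(
        DecayParams(fd=fd, tau_d=2.5, tau_f=tf)) / 2 - tf
    tf_star = brentq(f, 0.5, 1.5)
    p = DecayParams(fd=fd, tau_d=2.5, tau_f=tf_star)
    mfd, _ = mfd_from_mean_lifetime(mean_lifetime_model(p), 2.5)
    assert mfd == pytest.approx(fd, abs=1e-9)
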