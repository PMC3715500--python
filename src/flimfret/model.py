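"""Continuous-time bi-exponential FRET decay model and its closed-form inversions.

A donor population imaged by time-domain FLIM is modelled as a mixture of two
mono-exponential species: donors engaged in energy transfer, decaying with the
shortened FRET lifetime ``tau_F``, and free donors decaying with the unquenched
lifetime ``tau_D``.  The normalized intensity decay is

    p(t) = phi/tau_F * exp(-t/tau_F) + (1 - phi)/tau_D * exp(-t/tau_D)

where ``phi`` is the *intensity* fraction contributed by the FRET species and
``f_D`` the corresponding *molecular* (amplitude) fraction.  With ``tau_D``
known, three non-fitting routes recover the FRET parameters from integral
statistics of ``p(t)``:

* the **phasor (polar) inversion** from the cosine/sine Fourier transforms
  ``(u, v)`` at the laser repetition angular frequency,
* the **moment inversion** from the first two temporal moments ``E{t}``,
  ``E{t^2}``,
* the **minimal fraction** ``mf_D``: the smallest ``f_D`` compatible with an
  observed mean lifetime, minimized over the unknown ``tau_F``.

All functions here are the ideal continuous-integral, infinite-photon forms;
finite-window and finite-channel effects are handled in
:mod:`flimfret.estimators`, photon-counting statistics in
:mod:`flimfret.theory`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DecayParams",
    "PolarCoordinate",
    "MomentPair",
    "InversionResult",
    "omega_from_rep_rate",
    "phi_from_fd",
    "fd_from_phi",
    "mean_lifetime_model",
    "mfd_from_mean_lifetime",
    "mono_phasor",
    "continuous_polar_of_model",
    "polar_invert",
    "continuous_moments_of_model",
    "moments_invert",
]

#: default laser repetition rate, GHz (80 MHz)
DEFAULT_REP_RATE = 0.08

#: lifetime root-acceptance margin, ns
_EPS_TAU = 1e-6


def omega_from_rep_rate(rep_rate: float = DEFAULT_REP_RATE) -> float:
    """Angular frequency (rad/ns) of the laser fundamental, ``2*pi*rep_rate``."""
    if rep_rate <= 0:
        raise ValueError("repetition rate must be positive")
    return 2.0 * math.pi * rep_rate


@dataclass(frozen=True)
class DecayParams:
    """Ground-truth or estimated FRET triple.

    Parameters
    ----------
    fd : float
        Amplitude (molecular) fraction of donors undergoing FRET, in [0, 1].
    tau_d : float
        Donor-alone lifetime, ns.
    tau_f : float
        FRET (quenched donor) lifetime, ns, with ``0 < tau_f <= tau_d``.
    """

    fd: float
    tau_d: float
    tau_f: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.fd <= 1.0:
            raise ValueError(f"fd must lie in [0, 1], got {self.fd}")
        if self.tau_d <= 0.0:
            raise ValueError(f"tau_d must be positive, got {self.tau_d}")
        if not 0.0 < self.tau_f <= self.tau_d:
            raise ValueError(
                f"tau_f must satisfy 0 < tau_f <= tau_d, got {self.tau_f}"
            )

    @property
    def phi(self) -> float:
        """Intensity fraction of the FRET species."""
        return phi_from_fd(self.fd, self.tau_d, self.tau_f)


@dataclass(frozen=True)
class PolarCoordinate:
    """Phasor coordinates: cosine (``u``) and sine (``v``) transform values."""

    u: float
    v: float


@dataclass(frozen=True)
class MomentPair:
    """First (``m1``, ns) and second (``m2``, ns^2) temporal moments."""

    m1: float
    m2: float


@dataclass(frozen=True)
class InversionResult:
    """Outcome of a closed-form inversion.

    ``fd`` is always defined (0 at the no-FRET boundary); ``tau_f`` is ``nan``
    when undefined.  ``ok`` is False when the observed statistics are
    inconsistent with the two-component model (the documented failure mode of
    the moment route near its validity limits).  ``no_fret`` marks the donor-
    only boundary.
    """

    fd: float
    tau_f: float
    ok: bool
    no_fret: bool = False


def phi_from_fd(fd: float, tau_d: float, tau_f: float) -> float:
    """Intensity fraction of the FRET species from the molecular fraction.

    phi = fd*tau_f / (fd*tau_f + (1-fd)*tau_d); each molecule contributes
    photons in proportion to its lifetime, so the short-lived FRET species is
    under-represented in intensity (phi <= fd).
    """
    num = fd * tau_f
    den = num + (1.0 - fd) * tau_d
    if den == 0.0:  # only reachable at fd in {0, 1} with degenerate lifetimes
        return fd
    return num / den


def fd_from_phi(phi: float, tau_d: float, tau_f: float) -> float:
    """Inverse of :func:`phi_from_fd`: molecular fraction from intensity fraction."""
    num = phi * tau_d
    den = num + (1.0 - phi) * tau_f
    if den == 0.0:
        return phi
    return num / den


def mean_lifetime_model(params: DecayParams) -> float:
    """Intensity-weighted mean lifetime <tau> = phi*tau_f + (1-phi)*tau_d (ns).

    Equals the first moment E{t} of the normalized decay.
    """
    phi = params.phi
    return phi * params.tau_f + (1.0 - phi) * params.tau_d


def mfd_from_mean_lifetime(tau_mean: float, tau_d: float) -> tuple[float, bool]:
    """Minimal fraction of interacting donor from a mean lifetime.

    Given only ``<tau>`` and ``tau_d``, every ``tau_f`` in (0, tau_d) yields a
    candidate f_D = tau_d*(tau_d - <tau>) / [tau_d*(tau_d - <tau>) +
    tau_f*(<tau> - tau_f)]; the minimum over ``tau_f`` is attained at
    ``tau_f = <tau>/2``, giving

        mf_D = tau_d*(tau_d - <tau>) / [tau_d*(tau_d - <tau>) + <tau>^2/4]

    Returns ``(mfd, ok)``; a mean lifetime above ``tau_d`` is outside the
    model (no FRET) and yields ``(0.0, False)``.
    """
    if tau_mean <= 0.0 or tau_d <= 0.0 or not np.isfinite(tau_mean):
        return 0.0, False
    if tau_mean > tau_d:
        return 0.0, False
    a = tau_d * (tau_d - tau_mean)
    return a / (a + 0.25 * tau_mean * tau_mean), True


def mono_phasor(tau: float, omega: float) -> tuple[float, float]:
    """Phasor of a mono-exponential decay: lies on the semicircle u^2+v^2 = u."""
    x = omega * tau
    d = 1.0 + x * x
    return 1.0 / d, x / d


def continuous_polar_of_model(params: DecayParams, omega: float) -> PolarCoordinate:
    """Phasor of the two-component model: intensity-weighted mix of mono phasors."""
    phi = params.phi
    uf, vf = mono_phasor(params.tau_f, omega)
    ud, vd = mono_phasor(params.tau_d, omega)
    return PolarCoordinate(
        u=phi * uf + (1.0 - phi) * ud,
        v=phi * vf + (1.0 - phi) * vd,
    )


def polar_invert(p: PolarCoordinate, tau_d: float, omega: float) -> InversionResult:
    """Recover (f_D, tau_F) from a phasor with the donor lifetime fixed.

    Geometry: the model phasor is a convex combination of the two
    mono-exponential phasors, hence lies on the chord joining the donor point
    P_D (on the universal semicircle) to the FRET point P_F (also on the
    semicircle).  The line through P_D and the measured point intersects the
    circle ``u^2 + v^2 = u`` in exactly one further point; the trivial root at
    P_D is factored out (Vieta), the second intersection gives
    ``tau_F = v_F/(omega*u_F)``, and the mixing ratio along the chord gives the
    intensity fraction, converted to f_D via :func:`fd_from_phi`.
    """
    ud, vd = mono_phasor(tau_d, omega)
    du = p.u - ud
    dv = p.v - vd
    dist2 = du * du + dv * dv
    if dist2 < 1e-24:
        # measured phasor coincides with the donor point: no FRET species
        return InversionResult(fd=0.0, tau_f=math.nan, ok=True, no_fret=True)
    # second intersection of the line P_D + t*(du, dv) with u^2+v^2-u = 0:
    # t^2*|d|^2 + t*(2 P_D.d - du) = 0  ->  t1 = (du - 2 P_D.d)/|d|^2
    t1 = (du - 2.0 * (ud * du + vd * dv)) / dist2
    uf = ud + t1 * du
    vf = vd + t1 * dv
    if uf <= 0.0 or not np.isfinite(uf):
        return InversionResult(fd=0.0, tau_f=math.nan, ok=False)
    tau_f = vf / (omega * uf)
    if not (_EPS_TAU < tau_f < tau_d - _EPS_TAU):
        return InversionResult(fd=0.0, tau_f=tau_f, ok=False)
    # intensity fraction = position of the measured point along the chord
    chord2 = (uf - ud) ** 2 + (vf - vd) ** 2
    phi = (du * (uf - ud) + dv * (vf - vd)) / chord2
    fd = fd_from_phi(phi, tau_d, tau_f)
    return InversionResult(fd=fd, tau_f=tau_f, ok=bool(np.isfinite(fd)))


def continuous_moments_of_model(params: DecayParams) -> MomentPair:
    """Moments of the model decay: m1 = phi*tau_f+(1-phi)*tau_d, m2 = 2*phi*tau_f^2+...

    For a mono-exponential lifetime tau these reduce to ``(tau, 2 tau^2)``.
    """
    phi = params.phi
    m1 = phi * params.tau_f + (1.0 - phi) * params.tau_d
    m2 = 2.0 * (phi * params.tau_f**2 + (1.0 - phi) * params.tau_d**2)
    return MomentPair(m1=m1, m2=m2)


def moments_invert(m: MomentPair, tau_d: float) -> InversionResult:
    """Recover (f_D, tau_F) from the first two moments with the donor lifetime fixed.

    Solving the 2x2 system of the model moments for (phi, tau_F):

        tau_F = (tau_D*m1 - m2/2) / (tau_D - m1)
        phi   = (tau_D - m1) / (tau_D - tau_F)

    A solution is accepted only when ``tau_F`` lies in (0, tau_D) and ``phi``
    in [0, 1]; outside that window the moment route is flagged invalid, which
    is its documented behaviour near limit conditions.
    """
    if m.m1 >= tau_d - _EPS_TAU:
        return InversionResult(fd=0.0, tau_f=math.nan, ok=True, no_fret=True)
    tau_f = (tau_d * m.m1 - 0.5 * m.m2) / (tau_d - m.m1)
    if not (_EPS_TAU < tau_f < tau_d - _EPS_TAU):
        return InversionResult(fd=0.0, tau_f=tau_f, ok=False)
    phi = (tau_d - m.m1) / (tau_d - tau_f)
    if not -1e-9 <= phi <= 1.0 + 1e-9:
        return InversionResult(fd=0.0, tau_f=tau_f, ok=False)
    fd = fd_from_phi(phi, tau_d, tau_f)
    return InversionResult(fd=fd, tau_f=tau_f, ok=True)
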