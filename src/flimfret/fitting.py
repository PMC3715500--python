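"""Least-squares bi-exponential fitting baseline with a fixed donor lifetime.

The conventional route to FRET parameters fits each histogram with the
two-component model, fixing the donor lifetime and adjusting the interacting
fraction and the FRET lifetime by Levenberg–Marquardt-style damped least
squares.  The iteration budget and convergence tolerance are deliberately
those of routine FLIM fitting software (10 iterations, delta-chi2 = 0.001),
which is what makes the fit's dependence on its starting values observable at
low photon counts — the behaviour the non-fitting estimators are designed to
avoid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .model import DecayParams, phi_from_fd
from .simulate import AcquisitionConfig, DecayHistogram, simulate_decays

__all__ = ["FitConfig", "FitResult", "fit_biexp_fixed_donor", "init_sensitivity_sweep"]


@dataclass(frozen=True)
class FitConfig:
    """Fit constraints and algorithmic settings.

    Lifetimes are bounded to [0, tau_d_fixed] ns and the amplitude-ratio
    (interacting fraction) to [0, 1]; the solver stops after
    ``max_iterations`` damped steps or when the relative chi-square decrease
    falls below ``chi2_tolerance``, whichever comes first.
    """

    tau_d_fixed: float = 2.5
    init_fd: float = 0.5
    init_tauf: float = 1.25
    max_iterations: int = 10
    chi2_tolerance: float = 0.001
    weighted: bool = False


@dataclass(frozen=True)
class FitResult:
    fd: float
    tau_f: float
    chi2: float
    converged: bool
    n_evals: int


def _expected_counts(fd: float, tau_f: float, tau_d: float, total: float,
                     config: AcquisitionConfig) -> np.ndarray:
    """Expected per-channel counts of the wrapped, binned two-component decay."""
    k = np.arange(config.n_ch)
    w, T = config.gate_width, config.window

    def p_k(tau):
        if tau < 1e-9:
            out = np.zeros(config.n_ch)
            out[0] = 1.0
            return out
        r = np.exp(-w / tau)
        return np.exp(-k * w / tau) * (1.0 - r) / (1.0 - np.exp(-T / tau))

    phi = phi_from_fd(fd, tau_d, tau_f)
    return total * (phi * p_k(tau_f) + (1.0 - phi) * p_k(tau_d))


def fit_biexp_fixed_donor(
    h: DecayHistogram, cfg: FitConfig | None = None
) -> FitResult:
    """Fit (f_D, tau_F) to one histogram with the donor lifetime fixed.

    Minimizes the (optionally Poisson-weighted) squared residuals between the
    counts and the binned two-exponential model, the total amplitude being
    fixed to the observed total.  Returns the last iterate when the iteration
    cap is hit, flagged as non-converged.
    """
    cfg = cfg or FitConfig()
    total = h.total
    if total <= 0:
        raise ValueError("empty decay: cannot fit an all-zero histogram")
    counts = h.counts
    if cfg.weighted:
        sig = np.sqrt(np.maximum(counts, 1.0))
    else:
        sig = 1.0

    def resid(x):
        return (counts - _expected_counts(x[0], x[1], cfg.tau_d_fixed,
                                          total, h.config)) / sig

    # LM-style damped least squares; bounds as stated require the reflective
    # variant.  max_nfev budgets ~3 evaluations (1 + 2-point Jacobian of 2
    # parameters) per damped iteration.
    max_nfev = 3 * cfg.max_iterations
    res = least_squares(
        resid,
        x0=[cfg.init_fd, cfg.init_tauf],
        bounds=([0.0, 1e-3], [1.0, cfg.tau_d_fixed]),
        method="trf",
        ftol=cfg.chi2_tolerance,
        xtol=None,
        gtol=None,
        max_nfev=max_nfev,
    )
    converged = bool(res.status > 0 and res.nfev < max_nfev)
    return FitResult(fd=float(res.x[0]), tau_f=float(res.x[1]),
                     chi2=float(2.0 * res.cost), converged=converged,
                     n_evals=int(res.nfev))


def init_sensitivity_sweep(
    truth: DecayParams,
    n_photons_list,
    init_grid,
    config: AcquisitionConfig,
    n_decays: int = 256,
    rng: np.random.Generator | int | None = None,
    fit_cfg: FitConfig | None = None,
) -> pd.DataFrame:
    """Median fit outcomes across starting values and photon budgets.

    For each photon count and each ``(init_fd, init_tauf)`` starting point,
    ``n_decays`` replicate histograms are simulated and fitted; the medians
    and interquartile ranges of the fitted parameters quantify how strongly
    the answer depends on the starting point.  The spread across starting
    values shrinks as the photon budget grows.
    """
    rng = np.random.default_rng(rng)
    base = fit_cfg or FitConfig(tau_d_fixed=truth.tau_d)
    rows = []
    for n_photons in n_photons_list:
        counts = simulate_decays(truth, int(n_photons), n_decays, config, rng)
        for init_fd, init_tauf in init_grid:
            cfg = FitConfig(
                tau_d_fixed=base.tau_d_fixed, init_fd=float(init_fd),
                init_tauf=float(init_tauf),
                max_iterations=base.max_iterations,
                chi2_tolerance=base.chi2_tolerance, weighted=base.weighted,
            )
            fits = [fit_biexp_fixed_donor(
                DecayHistogram(counts=c, config=config), cfg) for c in counts]
            fd = np.array([f.fd for f in fits])
            tf = np.array([f.tau_f for f in fits])
            q = lambda x: np.percentile(x, [25, 50, 75])
            fd_q, tf_q = q(fd), q(tf)
            rows.append({
                "n_photons": int(n_photons),
                "init_fd": float(init_fd), "init_tauf": float(init_tauf),
                "fd_median": fd_q[1], "fd_iqr": fd_q[2] - fd_q[0],
                "tauf_median": tf_q[1], "tauf_iqr": tf_q[2] - tf_q[0],
                "converged_frac": float(np.mean([f.converged for f in fits])),
            })
    return pd.DataFrame(rows)
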