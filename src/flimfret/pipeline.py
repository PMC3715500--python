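"""Image-level analysis: calibration, per-pixel maps, ROI series, experiments.

Ties the simulator, the discrete estimators and the fitting baseline together
into the workflows a fast-FLIM user runs: convert camera grey levels to
photons with the S-factor, subtract background, produce per-pixel maps of
``<tau>``, ``mf_D`` and the polar/moment FRET parameters with validity masks,
summarize regions of interest over time, and export phasor scatter plots.

Summary statistics are medians and interquartile ranges throughout: per-pixel
estimate distributions are skewed and occasionally contain wild values near
the validity limits, so quartiles are the appropriate dispersion summary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .estimators import estimate_batch
from .model import DecayParams
from .simulate import (
    AcquisitionConfig,
    FLIMStack,
    gated_config,
    simulate_decays,
    simulate_flim_image,
    tcspc_config,
)

__all__ = [
    "ParameterMaps",
    "estimate_s_factor",
    "analyze_stack",
    "roi_timeseries",
    "polar_plot_export",
    "condition_summary",
    "photon_sweep",
    "gate_sweep",
    "reproduce_experiment",
    "EXPERIMENTS",
]

#: map column -> validity column used when building masks and summaries
_VALID = {
    "tau_mean": None, "mfd": None,
    "fd_polar": "polar_ok", "tauf_polar": "polar_ok",
    "fd_moments": "moments_ok", "tauf_moments": "moments_ok",
    "u": None, "v": None,
}


@dataclass
class ParameterMaps:
    """Per-pixel parameter images with validity masks.

    ``maps[name]`` is an (X, Y) float image (``nan`` where invalid) and
    ``masks[name]`` the matching boolean validity image.  ``table`` keeps the
    underlying per-pixel rows for programmatic use.
    """

    maps: dict[str, np.ndarray]
    masks: dict[str, np.ndarray]
    shape: tuple[int, int]
    table: pd.DataFrame = field(repr=False, default=None)

    def median(self, name: str) -> float:
        return float(np.nanmedian(self.maps[name]))

    def iqr(self, name: str) -> float:
        lo, hi = np.nanpercentile(self.maps[name], [25, 75])
        return float(hi - lo)


def estimate_s_factor(mean_grey: np.ndarray, var_grey: np.ndarray) -> float:
    """Camera gain (grey levels per photon) from a variance-vs-mean fit.

    For Poisson-limited detection the variance of the grey-level signal grows
    linearly with its mean and the slope is the gain S (photons =
    grey / S).  Requires at least three exposure levels.
    """
    mean_grey = np.asarray(mean_grey, dtype=float)
    var_grey = np.asarray(var_grey, dtype=float)
    if mean_grey.size < 3:
        raise ValueError("need at least 3 exposure levels")
    slope, _ = np.polyfit(mean_grey, var_grey, 1)
    if slope <= 0:
        raise ValueError(f"non-positive variance/mean slope ({slope:.3g})")
    return float(slope)


def analyze_stack(
    stack: FLIMStack,
    tau_d: float,
    background: float | np.ndarray | None = None,
    corrected: bool = True,
    mask_threshold: float | None = 0.2,
) -> ParameterMaps:
    """Per-pixel FRET parameter maps from a gate stack.

    Grey levels are converted to photons via the stack's S-factor, the
    background (scalar or per-channel) is subtracted with flooring at zero,
    and the corrected non-fitting estimators are applied pixel-wise.  All
    three strategies need the donor-alone lifetime.
    """
    if tau_d is None or tau_d <= 0:
        raise ValueError("a positive donor lifetime tau_d is required")
    nx, ny, n_ch = stack.data.shape
    counts = stack.photons.reshape(nx * ny, n_ch)
    if background is not None:
        # signed subtraction: the quadrature sums are unbiased on zero-mean
        # residuals, whereas flooring at zero would bias the late channels up
        counts = counts - np.asarray(background, dtype=float)
    df = estimate_batch(counts, stack.config, tau_d,
                        corrected=corrected, mask_threshold=mask_threshold)
    maps, masks = {}, {}
    for name, okcol in _VALID.items():
        img = df[name].to_numpy().reshape(nx, ny)
        ok = np.isfinite(img)
        if okcol is not None:
            ok &= df[okcol].to_numpy().reshape(nx, ny)
        maps[name] = np.where(ok, img, np.nan)
        masks[name] = ok
    return ParameterMaps(maps=maps, masks=masks, shape=(nx, ny), table=df)


def roi_timeseries(maps_list, roi: np.ndarray) -> pd.DataFrame:
    """Median and IQR of each parameter inside an ROI, frame by frame."""
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise ValueError("ROI is empty")
    rows = []
    for frame, pm in enumerate(maps_list):
        if roi.shape != pm.shape:
            raise ValueError("ROI shape must match the maps")
        row = {"frame": frame}
        for name in ("tau_mean", "mfd", "fd_polar", "fd_moments"):
            vals = pm.maps[name][roi]
            vals = vals[np.isfinite(vals)]
            if vals.size:
                q1, med, q3 = np.percentile(vals, [25, 50, 75])
            else:
                q1 = med = q3 = np.nan
            row[f"{name}_median"] = med
            row[f"{name}_iqr"] = q3 - q1
        rows.append(row)
    return pd.DataFrame(rows)


def polar_plot_export(results: pd.DataFrame, path=None, ax=None):
    """Phasor scatter with the universal semicircle reference.

    Mono-exponential decays lie on the semicircle ``u^2 + v^2 = u``;
    two-component mixtures lie on the chord joining their pure phasors, so
    mixture clouds of the same pair are collinear.  Returns the matplotlib
    axes; saves to ``path`` when given.
    """
    import matplotlib
    if path is not None and ax is None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if len(results) == 0:
        raise ValueError("no phasor points to plot")
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3))
    th = np.linspace(0, np.pi, 200)
    ax.plot(0.5 + 0.5 * np.cos(th), 0.5 * np.sin(th), "k-", lw=1,
            label="mono-exponential")
    ax.scatter(results["u"], results["v"], s=4, alpha=0.4)
    ax.set_xlabel("u")
    ax.set_ylabel("v")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 0.6)
    if path is not None:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
    return ax


# ---------------------------------------------------------------------------
# experiment runners
# ---------------------------------------------------------------------------

def condition_summary(df: pd.DataFrame, truth: DecayParams) -> dict:
    """Median/IQR summary of one simulated condition's estimate table."""
    out = {"fd_true": truth.fd, "tau_f_true": truth.tau_f}
    for name, okcol in (("mfd", None), ("tau_mean", None),
                        ("fd_polar", "polar_ok"), ("tauf_polar", "polar_ok"),
                        ("fd_moments", "moments_ok"),
                        ("tauf_moments", "moments_ok")):
        vals = df[name].to_numpy()
        ok = np.isfinite(vals)
        if okcol is not None:
            ok &= df[okcol].to_numpy()
        vals = vals[ok]
        if vals.size:
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
        else:
            q1 = med = q3 = np.nan
        out[f"{name}_median"] = med
        out[f"{name}_iqr"] = q3 - q1
        # quartile deviation: half the quartile spread, the half-length of a
        # median-to-quartile error bar
        out[f"{name}_qdev"] = 0.5 * (q3 - q1)
        out[f"{name}_valid_frac"] = ok.mean()
    return out


def photon_sweep(
    fd_values=(0.25, 0.5, 0.75),
    n_photons_list=(100, 200, 500, 1000),
    tau_d: float = 2.5,
    tau_f: float = 1.5,
    n_decays: int = 4096,
    rng=None,
) -> pd.DataFrame:
    """TCSPC photon-budget study: 64 channels, narrow IRF, no offset.

    Simulates ``n_decays`` independent decays per (f_D, N) condition and
    summarizes the three non-fitting estimates with medians and IQRs.
    """
    rng = np.random.default_rng(rng)
    config = tcspc_config()
    rows = []
    for fd in fd_values:
        truth = DecayParams(fd=fd, tau_d=tau_d, tau_f=tau_f)
        for n in n_photons_list:
            counts = simulate_decays(truth, int(n), n_decays, config, rng)
            df = estimate_batch(counts, config, tau_d)
            rows.append({"fd": fd, "n_photons": int(n), "n_ch": config.n_ch,
                         **condition_summary(df, truth)})
    return pd.DataFrame(rows)


def gate_sweep(
    n_photons: int,
    fd_values=(0.25, 0.5, 0.75),
    n_ch_values=(4, 8, 16, 32, 64),
    tau_d: float = 2.5,
    tau_f: float = 1.5,
    shape=(64, 64),
    corrected: bool = True,
    rng=None,
) -> pd.DataFrame:
    """Time-gated channel-number study with offset and 3x3 smoothing.

    Each condition simulates a ``shape`` image through the gated-camera
    model (Poisson offset, 3x3 average filter), subtracts the mean offset as
    a scalar background and applies the (corrected, by default) estimators
    per pixel.
    """
    rng = np.random.default_rng(rng)
    rows = []
    for n_ch in n_ch_values:
        config = gated_config(n_ch=int(n_ch))
        for fd in fd_values:
            truth = DecayParams(fd=fd, tau_d=tau_d, tau_f=tau_f)
            stack = simulate_flim_image(truth, int(n_photons), config,
                                        shape=shape, rng=rng)
            pm = analyze_stack(stack, tau_d,
                               background=config.offset_mean / config.n_ch,
                               corrected=corrected)
            rows.append({"fd": fd, "n_photons": int(n_photons),
                         "n_ch": int(n_ch),
                         **condition_summary(pm.table, truth)})
    return pd.DataFrame(rows)


def _run_theory_curves(scale, rng):
    from .theory import stats_table

    n_values = np.unique(np.geomspace(50, 5000, 25).astype(int))
    return stats_table((0.25, 0.5, 0.75), n_values)


def _run_photon_sweep(scale, rng):
    n_decays = max(64, int(4096 * scale))
    return photon_sweep(n_decays=n_decays, rng=rng)


def _run_gate_sweep_1000(scale, rng):
    side = max(8, int(64 * np.sqrt(scale)))
    return gate_sweep(1000, shape=(side, side), rng=rng)


def _run_gate_sweep_200(scale, rng):
    side = max(8, int(64 * np.sqrt(scale)))
    return gate_sweep(200, shape=(side, side), rng=rng)


def _run_init_sensitivity(scale, rng):
    from .fitting import init_sensitivity_sweep

    truth = DecayParams(fd=0.5, tau_d=2.5, tau_f=1.5)
    init_grid = [(f, t) for f in (0.1, 0.5, 0.9) for t in (0.25, 1.25, 2.25)]
    n_decays = max(32, int(256 * scale))
    return init_sensitivity_sweep(truth, (200, 1000, 100_000), init_grid,
                                  tcspc_config(), n_decays=n_decays, rng=rng)


EXPERIMENTS = {
    "theory-curves": _run_theory_curves,
    "photon-sweep": _run_photon_sweep,
    "gate-sweep-n1000": _run_gate_sweep_1000,
    "gate-sweep-n200": _run_gate_sweep_200,
    "init-sensitivity": _run_init_sensitivity,
}


def reproduce_experiment(name: str, scale: float = 1.0, seed=None) -> pd.DataFrame:
    """Run one of the named simulation studies at full or reduced scale.

    ``scale`` multiplies the replicate count (pixel count for image-based
    studies), trading precision of the medians/IQRs for runtime.
    """
    if name not in EXPERIMENTS:
        raise ValueError(f"unknown experiment {name!r}; "
                         f"choose from {sorted(EXPERIMENTS)}")
    return EXPERIMENTS[name](scale, np.random.default_rng(seed))
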