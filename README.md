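# flimfret

Non-fitting FRET parameter estimation for time-domain FLIM.

Förster resonance energy transfer (FRET) shortens the fluorescence lifetime
of a donor fluorophore, so per-pixel lifetime imaging (FLIM) can map
protein–protein interactions in living cells. When only a fraction f_D of
donors interacts, each pixel's decay is a two-component mixture

    p(t) = φ/τ_F · e^(−t/τ_F) + (1−φ)/τ_D · e^(−t/τ_D),
    φ = f_D·τ_F / (f_D·τ_F + (1−f_D)·τ_D),

with τ_D the donor-alone lifetime, τ_F the FRET lifetime and φ the intensity
fraction of the FRET species. Iterative fitting of (f_D, τ_F) needs ~10⁵
photons per pixel and depends on its starting values at realistic photon
budgets. This package implements the non-fitting alternatives that make
fast FLIM–FRET practical, together with everything needed to study their
validity domains:

- **Phasor (polar) inversion** — each decay maps to its Fourier cosine/sine
  transforms (u, v) at the laser repetition frequency; with τ_D known, the
  chord geometry of the universal semicircle u² + v² = u gives (f_D, τ_F)
  in closed form.
- **Moment inversion** — the first two temporal moments E{t}, E{t²} are
  solved for (f_D, τ_F) with τ_D fixed; more precise than the phasor route
  but invalid at small fractions (f_D ≲ 0.2) or very few gates.
- **Minimal fraction mf_D** — the smallest f_D compatible with the observed
  mean lifetime, minimized over the unknown τ_F (attained at τ_F = ⟨τ⟩/2):
  mf_D = τ_D(τ_D−⟨τ⟩) / [τ_D(τ_D−⟨τ⟩) + ⟨τ⟩²/4]. A deliberate lower bound,
  but the most precise of the three.

Around the estimators the package provides:

- **finite-gate corrections**: time-gated cameras use as few as 4 wide
  contiguous gates; all three estimators are corrected by inverting the
  discretized forward operator (closed-form discrete curves for a wrapped,
  binned mono-exponential), so noiseless binned decays invert *exactly* at
  any gate count;
- **precision theory**: closed-form means and standard deviations of the
  three fraction estimators versus photon number N (delta-method
  propagation of photon-counting statistics), with a Monte Carlo oracle;
- a seeded **Monte Carlo simulator** of TCSPC (64 channels, 32 ps IRF) and
  time-gated (4–64 gates, 200 ps IRF, Poisson camera offset, 3×3 spatial
  smoothing) acquisitions at 80 MHz repetition (12.5 ns window);
- a bounded **Levenberg–Marquardt-style fitting baseline** with fixed τ_D,
  for the initial-condition sensitivity comparison;
- an **image pipeline**: S-factor (camera gain) calibration, background
  subtraction, per-pixel parameter maps with validity masks, ROI time
  series, phasor-plot export, TIFF + JSON stack I/O, and a CLI.

## Worked example

Simulate a 64×64 time-gated acquisition (8 gates, 1000 photons/pixel,
f_D = 0.5, τ_D = 2.5 ns, τ_F = 1.5 ns) and produce per-pixel maps:

```python
from flimfret import DecayParams, gated_config, simulate_flim_image, analyze_stack

truth = DecayParams(fd=0.5, tau_d=2.5, tau_f=1.5)
config = gated_config(n_ch=8)          # 8 gates, 200 ps IRF, offset, 3x3 smoothing
stack = simulate_flim_image(truth, n_photons=1000, config=config, rng=42)
maps = analyze_stack(stack, tau_d=2.5, background=config.offset_mean / config.n_ch)
for name in ("tau_mean", "mfd", "fd_polar", "tauf_polar", "fd_moments"):
    print(f"{name:12s} median = {maps.median(name):6.3f}   IQR = {maps.iqr(name):.3f}")
```

prints

```
tau_mean     median =  2.108   IQR = 0.052
mfd          median =  0.468   IQR = 0.045
fd_polar     median =  0.509   IQR = 0.121
tauf_polar   median =  1.519   IQR = 0.331
fd_moments   median =  0.507   IQR = 0.150
```

The mean lifetime (2.11 ns vs the continuous 2.125 ns) reflects the small
residual mixture bias of the gate correction; the polar and moment
fractions are centred on the true 0.5 with ~0.12–0.15 interquartile spread
at this photon budget; mf_D sits at 0.468 — below 0.5 by construction
(τ_F = 1.5 ns is not exactly ⟨τ⟩/2) but with a ~3× narrower spread.

The same workflows are scriptable from the shell:

```sh
flimfret simulate --mode gated --nch 8 --nphotons 1000 --fd 0.5 --seed 42 -o stack.tif
flimfret estimate stack.tif --taud 2.5 --background 23.75 -o pixels.csv
flimfret theory --fd 0.25,0.5,0.75 --nmin 50 --nmax 5000 -o theory.csv
flimfret reproduce gate-sweep-n1000 --seed 1 -o sweep.csv
```

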