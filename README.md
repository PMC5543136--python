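# takinetics

Global and target analysis of time-resolved difference-absorption
spectroscopy: compartmental first-order kinetics convolved with a
Gaussian instrument response, variable-projection fitting of
ΔA(t, λ) matrices, pump-dump-probe population accounting, quantum-yield
estimation, and a synthetic-data generator with known ground truth.

The package is built around the photoreaction of the channelrhodopsin
chimera C1C2 as its worked system — femtosecond-to-second transient
absorption of the retinal photoisomerization and photocycle — and is
aimed at spectroscopists who fit multiexponential / compartmental models
to pump-probe, multi-pulse and flash-photolysis data, and at method
developers who need a fully synthetic, ground-truth test bed for such
fits.

## The model

Compartment populations `c(t)` obey `dc/dt = K c + w g(t)`, with `K` the
rate matrix of a kinetic scheme (branching, reversible pairs, absorbing
states), `w` the excitation weights and `g` a Gaussian IRF.  Each
eigenmode contributes an exponentially modified Gaussian
`½ exp(k(µ−t)+k²σ²/2) erfc((µ+kσ²−t)/(σ√2))`.  The data matrix is
bilinear, `ΔA = C(θ) Sᵀ`: spectra `S` are eliminated analytically by
weighted least squares at every step of the nonlinear optimization of
`θ` (lifetimes, IRF, dump fractions) — variable projection.  Sequential
fits yield evolution-associated difference spectra (EADS), the
equivalent parallel description decay-associated spectra (DADS), and
scheme-based target fits species-associated spectra (SADS), with the
photoisomerization quantum yield read from the absorbing-state
probabilities of the fitted scheme.  Dump pulses enter as instantaneous
population transfers; spectral equal-bleach constraints pin yields that
are otherwise degenerate with spectral amplitudes.  See
[docs/methods.md](docs/methods.md) for the full account.

## Worked example

Simulate a pH 8 pump-probe matrix from the six-component sequential
preset (450 fs, 2.0 ps, 11 ps, 630 ps, 490 ns, ∞; 150 fs FWHM IRF; 1%
peak noise; 465–495 nm scatter window masked) and re-fit it:

```python
import numpy as np
from takinetics import (c1c2_presets, simulate_dataset, fit_sequential,
                        linlog_time_axis, default_wavelength_axis, NoiseModel)

p = c1c2_presets(8)
ds = simulate_dataset(p.sequential_scheme, p.sequential_spectra, p.irf,
                      linlog_time_axis(), default_wavelength_axis(),
                      noise=NoiseModel(0.01, seed=42))
fit = fit_sequential(ds, [0.3, 3.0, 15.0, 400.0, 3e5, np.inf],
                     irf_init=p.irf, n_starts=2, seed=0)
print(fit.summary())
```

prints

```
fit: ssq=2.71086, chi2/dof=0.0001532, success=True
  tau1 = 0.443517 +/- 0.0201
  tau2 = 1.98572 +/- 0.0656
  tau3 = 10.9347 +/- 0.0733
  tau4 = 592.259 +/- 31.6
  tau5 = 412235 +/- 3.18e+04
  tau6 = inf +/- nan
  irf_center = 0.000200265 +/- 0.0003
  irf_width = 0.0639038 +/- 0.000369
  lifetimes (ps, ascending): 0.4435, 1.986, 10.93, 592.3, 4.122e+05, inf
  n_starts = 2
  flat_directions = 0
```

— the six time constants back within their ~5–10% statistical scatter
(the reduced χ² equals the noise variance, 1.5·10⁻⁴, because weights are
unity), the fitted IRF width 0.0639 ps ≈ the generating 150 fs FWHM, and
`fit.spectra["EADS"]` / `fit.spectra["DADS"]` holding both spectra sets.
The ratio of the final to the first EADS bleach amplitude (430–465 nm),
`0.27`, foreshadows the ~30% photoproduct quantum yield that the target
analysis then pins exactly: propagating the branched scheme (ES1 → 2.2
ps⁻¹ split 40/30/30 into ES2/K1/GS, ES2 → 0.12/0.38 ps⁻¹, ES3 → 0.09
ps⁻¹, GSI → 1.0 ps⁻¹) gives `terminal_yields(...)["K1"] == 0.30`.

The numbered drivers under `analysis/` run the full study on synthetic
data — `01` simulates all datasets, `02` the sequential global fits,
`03` the joint pump-probe/pump-dump-probe target fit (recovering the
GSI decay rate 1.0 ps⁻¹, the dump efficiencies and the 30% yield under
the equal-bleach constraint), `04` the flash-photolysis fit (20 µs /
15 ms / 100 ms) — writing tables under `results/`.  The same pipelines
are scriptable from the shell:

```sh
takinetics simulate --preset ph8 --seed 1 --out results/demo
takinetics fit-global --data results/demo/pp_matrix.tsv \
    --lifetimes "0.3,3,15,400,3e5,inf" --out results/demo_fit
```

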