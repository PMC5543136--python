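# Methods

`takinetics` models and fits time-resolved difference-absorption data of
photoreceptor proteins, built around the C1C2 channelrhodopsin
photoreaction as its worked system: femtosecond pump-probe and
pump-dump-probe spectroscopy of the retinal photoisomerization, and
flash photolysis of the microsecond-to-second photocycle.

## Kinetic model

Populations of a set of compartments (excited states ES1/ES2/ES3, the
first photoproduct K1, a ground-state intermediate GSI, photocycle
intermediates K/L/M/O, and the recovered ground state GS) evolve by
first-order kinetics,

    dc/dt = K c + w g(t),

where `K` is the compartmental rate matrix (off-diagonal `K[j,i]` the
microscopic rate i→j, diagonal minus the total outflow), `w` the initial
excitation weights and `g(t)` a Gaussian of standard deviation σ
centered at µ — the instrument response (IRF) of the pump pulse.  With
the ground state included as a compartment the columns of `K` sum to
zero and total population is conserved.

For a diagonalizable `K` the solution is a sum over eigenmodes, each an
exponentially modified Gaussian

    ½ · exp(k(µ−t) + k²σ²/2) · erfc((µ + kσ² − t)/(σ√2)),

evaluated through the scaled complementary error function `erfcx` so
that large `k·σ` cannot overflow.  The analytic route is abandoned for
adaptive stiff ODE integration (LSODA, rtol 1e-10) when the eigenbasis
condition number exceeds 1e8 — the relevant failure mode is a nearly
defective eigenbasis, not repeated eigenvalues per se (several absorbing
compartments always share the eigenvalue 0, harmlessly).  On random
small networks the two routes agree to better than 1e-6 and this
equivalence is tested.

### Dump events

A dump pulse is modelled as an instantaneous linear transfer at time
`t_d`: source compartments lose a fraction of their current population
to a destination (ES1, ES2 → GSI in C1C2).  Because the system is
linear, the dumped solution is the undumped one plus a homogeneously
propagated correction,

    c_dump(t) = c(t) + e^{K(t−t_d)} (T − I) c(t_d),   t ≥ t_d,

with `T` the (column-stochastic) transfer matrix — exact, and exactly
population-conserving across the event.  Terminal yields with dump
follow by routing the correction through the absorbing-state
probabilities.  The dump duration is ignored (delta-function transfer);
at the C1C2 conditions (dump at 300 fs ≈ 4.7 σ after the 150 fs FWHM
pump) the approximation is excellent, and a warning is emitted if a dump
is placed within 1 σ of the IRF center.

### Yields and branching

Branching probabilities are edge rate over total outflow; terminal
(absorbing-state) yields solve the first-step equations of the embedded
jump chain.  For the C1C2 target scheme (ES1 draining at 2.2 ps⁻¹ split
40/30/30 into ES2/K1/GS, ES2 at 0.12 + 0.38 ps⁻¹ into ES3/GS, ES3 at
0.09 ps⁻¹, GSI at 1.0 ps⁻¹) the photoproduct yield is 30%.  An
independent Gillespie-type jump sampler (`mc_jump_oracle`) cross-checks
yields and dump accounting in the tests; it is never the production
path.

## Variable-projection global analysis

The measured matrix ΔA(t, λ) is bilinear: concentrations × spectra.
Fits eliminate the linear spectra at every iterate by weighted
per-wavelength least squares (columns sharing a weight pattern are
solved in one factorization) and optimize only the nonlinear parameters
— lifetimes, IRF center/width, dump fractions — with
`scipy.optimize.least_squares`.  Choices that matter:

* **Log/logit parameterization.**  Lifetimes and rates are optimized in
  log space (positive, stable across the 450 fs – 26 µs dynamic range);
  dump fractions in logit space (confined to [0, 1]).
* **Multi-start.**  8 initializations jittered ×/÷3 around the user
  init (fixed seed), best weighted SSQ wins.  Lifetimes are relabelled
  in ascending order at convergence only; the parallel basis is
  order-free, so sorting does not change the fit.
* **Infinity component.**  A non-decaying final compartment is a
  zero-rate terminal, not an additive offset.
* **Masking.**  Zero-weight cells (NaN on file; the 465–495 nm
  pump-scatter window by default) are excluded from every fit and
  statistic; tests assert that arbitrary garbage in masked cells moves
  no parameter by more than 1e-12.
* **Errors.**  Standard errors come from the Jacobian at the optimum
  (delta method back to natural scale); they agree with bootstrap
  refitting within ~30% on the tested cases.  Flat directions are
  flagged as infinite.

Sequential (EADS) and parallel (DADS) descriptions are linked by the
exact triangular basis change `B[j,l] = Π_{m<l} k_m / Π_{m≤l, m≠j}
(k_m − k_j)`; `DADS = B @ EADS`, round-trips to 1e-10, and both
reconstruct the identical model matrix.

### Target analysis and the equal-bleach constraint

Target fits (`fit_target`) free any subset of edge rates, dump fractions
and IRF parameters, over one or several datasets jointly (PP + PDP share
all kinetics and SADS; only dump fractions are PDP-specific).  A
structural screen at the initial point (rank of the concentration
sensitivities) rejects parameter combinations that cannot move the
model, naming the null direction.

One degeneracy deserves emphasis: a branch fraction into a compartment
whose spectrum is free trades *exactly* against that spectrum's
amplitude — the data fix only their product.  The photoproduct yield is
therefore pinned by the spectral equal-bleach constraint: the integrated
SADS amplitude over the bleach window (default 430–465 nm) is penalized
toward equality across the excited states and the photoproduct.  The
penalty is the normalized spread `w·(A_i − Ā)/|Ā|` appended to the
residual vector — dimensionless, gentle on shape-identifiable
directions, decisive on the flat ridge.  Parameter covariances under the
penalty use a sandwich estimator in which the penalty rows carry the
noise covariance of the projected bleach integrals (without this, the
yield uncertainty is underestimated by an order of magnitude; with it,
it matches bootstrap refits to a few percent).

### Residual diagnostics

`svd_residual_diagnostics` compares the first singular value of the
residual matrix with the noise-floor expectation σ(√m + √n).  The noise
σ is estimated from first differences along the wavelength axis — blind
to spectrally smooth structure — so an inadequate fit cannot inflate its
own acceptance threshold.  A ratio above 2 flags unmodelled structure;
mildly under-fitted models (a dropped component spectrally similar to
its neighbours) can sit between 1.2 and 2.

## Synthetic data generator

The generator is the package's test bed and defines its study
conditions.  Species spectra are sums of Gaussian bands; band *centers*
follow the reported features (ESA 541→535→528 nm across ES1–ES3,
photoproduct 523→530 nm, L ≈ 440 nm, M < 400 nm, O ≈ 530 nm, bleach
near 460 nm, stimulated emission beyond 630 nm), while band widths
(45 nm visible, ~38 nm near-UV) and amplitudes are invented calibration
constants chosen once so that bleach/ESA/SE overlap qualitatively as in
the measured spectra, with a clearly decaying ESA/SE amplitude across
the excited-state relaxation.  All product spectra share the
ground-state bleach band of the excited states (the equal-bleach
assumption) and are scaled by the 0.30 photoproduct yield in the
sequential presets, so the final/first EADS bleach ratio comes out near
0.27 — within the 25–30% range such data display.  Absolute amplitudes
are arbitrary (units are never absolute mOD); peak ΔA is of order 1.

Presets: pH 8 carries the sequential constants 450 fs / 2.0 ps / 11 ps /
630 ps / 490 ns / ∞; pH 10 adds 200 ns and 26 µs (650 ps replacing
630 ps); both share the branched target scheme above and a 150 fs FWHM
IRF.  The slow photocycle is a three-stage chain (K/L mixture →
K/L/M equilibrium mixture → O → GS) with 20 µs / 15 ms / 100 ms stages —
stage spectra are mixtures representing the equilibria rather than
explicit reversible edges, which the fitted three-exponential analysis
cannot distinguish anyway.  Delay grids are lin-log (50 fs linear steps
to 1 ps, logarithmic to 125 µs, 169 points — the measurement grid) or
log-spaced 1 µs–10 s for flash photolysis; pump-dump-probe simulations
use 20 fs linear steps, the experiment's minimum step.  Noise is
additive white Gaussian at 1% of peak |ΔA| by default, identical for the
PP/PDP twins (same seed), which makes a zero-dump PDP bitwise equal to
its PP twin.

What the generator does *not* emulate: probe chirp and cross-phase
modulation, wavelength-dependent IRF, scatter bleed-through beyond the
mask, shot-to-shot drift, anisotropy, coherent oscillations.  Passing
recovery tests therefore demonstrate correctness of the estimators under
the stated noise model, not robustness to those instrumental artifacts.

## Numerical conventions and edge cases

* Time unit is picoseconds internally; file I/O declares fs/ps/ns/µs/ms/s
  and converts on read.  Wavelengths are nm.
* Populations below −1e-9 raise; round-off negatives above that are
  clipped to zero.
* Two lifetimes crossing during optimization are handled by the numeric
  propagation fallback and relabelled by sorted order at convergence.
* Per-compartment dump efficiencies are free parameters (the aggregate
  11% excited-state removal does not determine the ES1/ES2 split);
  equality is never assumed.
* The GSI spectrum is reported as fitted, without smoothing or
  regularization.
* The fs-TA 26 µs component (pH 10) and the 20 µs flash-photolysis
  process are treated as independent observations of their respective
  datasets.

## Statistical behaviour of recovered constants

At the study conditions (169×120 matrix, 1% peak noise) the recovered
sequential constants scatter with ~5–8% relative standard deviation per
noise realization — the same order as the 10% standard errors such
analyses conventionally quote.  The error budget is dominated by a soft
common mode along the chain (adjacent components trade amplitude), so
ratios of constants are better determined than the constants themselves.
`scripts/acceptance.py` therefore reports each fit-derived quantity as
the median over nine replicate simulations at identical conditions,
which reduces the readout scatter to ~2–3% without touching the
conditions or the estimator.  The 490 ns (pH 8) stage is the least
determined (~10–15%): its spectral contrast against the neighbouring
components is smallest.

In the joint PP/PDP fit the shared noise realization of the twin
matrices correlates their residuals and biases the GSI rate upward at
coarse delay sampling (≈ +8% at 120 delay points); at the 20 fs-step
grid of 250 points used here the residual bias is ≈ +1–4%, within the
statistical scatter.  Zero-noise closure is exact in all cases.

## Limitations

Second-order kinetics, diffusion, temperature dependence, vibrational
ladders and coherent dynamics are out of scope; no chirp/dispersion
correction is applied (time zero is a single global parameter per
dataset); no Bayesian posterior sampling — uncertainties are linearized
(sandwich) estimates validated against bootstrap on desk-scale cases.
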