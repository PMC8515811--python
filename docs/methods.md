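# Methods

This note records the models behind `nuqspec`, the parameter choices
that matter, and what the built-in toy systems can and cannot show
about real chromophores.

## Nuclear-ensemble estimator

The spectrum is estimated as a per-snapshot average of unit-area
Gaussian kernels placed at the vertical excitations,
`s(x) = (1/N_snap) Σ_i Y_i K_Δ(x − X_i)`.  Averaging per snapshot (not
per stick) makes ensembles of different sizes directly comparable and
gives the exact conservation law *curve integral = per-snapshot mean
total oscillator strength* for every Δ, which the tests assert.  The
estimator deliberately omits the absolute cross-section prefactor:
all comparisons here are between area-normalized shapes, where a global
constant cancels.  Vibronic fine structure and lifetime broadening are
outside the model — the kernel is inhomogeneous broadening only.

## GSTA quantum correction

For a harmonic mode of wavenumber ν at temperature T, the ratio of
quantum to classical average energies is

    w(ν) = (βhν/2)·coth(βhν/2),  β = 1/k_BT,

with w(0) = 1 and w → βhν/2 at high frequency.  The filter is designed
so its *amplitude* response is √w(ν): energy is quadratic in amplitude,
and this is the choice under which filtering a classical harmonic
trajectory reproduces the quantum coordinate variance
(ħ/2mω)·coth(βħω/2) — verified against a Langevin oracle in the test
suite.  Numerically, x·coth(x) is evaluated with an `expm1`-based form,
a series branch below x = 10⁻⁴ (to avoid 0/0) and the x asymptote above
x = 350 (to avoid overflow); the crossover errors are below 1e−8.

The kernel for a centered window of W frames (odd; default 241 at
dt = 0.5 fs, spanning 120 fs) is the inverse DFT of √w sampled on the
window's discrete frequency grid ν_k = k/(W·dt).  By construction the
discrete response is exactly √w(ν_k) at every resolvable frequency and
exactly 1 at DC (taps sum to 1), with no taper applied.  Boundary
policy: the half-window at each trajectory end is discarded — padding
would invent data and bias variance statistics.

Two practical error sources, both quantified by the tests:

* **Interpolation between bins** — the response at off-grid frequencies
  is the trigonometric interpolant of √w; for the default window the
  deviation stays under 2% across 1000–4000 cm⁻¹.
* **Finite linewidth** — a damped oscillator's spectral line has width
  ∝ friction, and the filtered variance is the w-weighted integral over
  that line rather than w(ν₀) at its center.  At γ = 0.05 fs⁻¹ this
  depresses the recovered quantum variance by ~2–4%; at γ = 0.02 fs⁻¹
  by ~1%.  The variance-recovery test therefore runs at low friction
  and averages independent replicas so the Monte Carlo error of the
  variance estimate (≈ √(4/(γ·T_run)) per run) is small against the 5%
  check.

## Harmonic samplers

`sample_wigner` draws each mass-weighted normal coordinate from the
harmonic Wigner coordinate marginal, a zero-mean Gaussian with variance
(ħ/2mω)·coth(βħω/2); coordinates only, since momenta do not enter
vertical-excitation spectra.  `sample_classical` uses the Boltzmann
variance k_BT/mω².  Their per-mode variance ratio is exactly w(ν),
which ties the samplers to the filter algebraically and is asserted in
the tests.  The potential-energy diagnostic reports mean, standard
deviation and a moment-matched gamma fit: a classical ensemble of M
modes gives a gamma(M/2, k_BT) law (a scaled χ²(M)).  Moment matching
is used instead of maximum likelihood because it is deterministic and
closed-form — adequate for a diagnostic.  "Width" always means the
standard deviation here, never FWHM.

## Toy simulators and oracles

* **Langevin (BAOAB)** dynamics replaces thermostated production MD:
  one friction parameter, exact seed reproducibility, and
  well-characterized configurational sampling.  The integrator refuses
  dt above period/5 of the fastest mode and warns above period/10.
  Friction defaults to 0.05 fs⁻¹ — underdamped for every mode treated
  here (ω ≥ 0.3 fs⁻¹), decorrelating positions in ~20 fs.
* **DHO chromophore**: two identical harmonic surfaces offset by the
  displacement d with S = mωd²/2ħ and by the adiabatic energy E00.  The
  vertical gap is linear in the coordinate,
  E(x) = E00 + S·ħω − (mω²d)·x, with constant (Condon) oscillator
  strength.  The Franck–Condon oracle provides the T = 0 Poisson
  progression (weights e^(−S)Sⁿ/n!, truncated at cumulative intensity
  1 − 1e−10) and the exact moments mean = E00 + S·ħω,
  var = S·(ħω)²·coth(βħω/2) — the moments are closed-form, never
  computed from the truncated sticks.
* **Morse oscillator**: the minimal anharmonic surface.  Harmonic
  sampling derived from its minimum curvature over-stretches the bond
  on the dissociative side, and the quantum (Wigner) sampler does so
  far more than the classical one — the qualitative failure mode of
  harmonic Wigner sampling for soft/anharmonic degrees of freedom.
  Only this qualitative ordering is claimed; fragmentation statistics
  of any real molecule are molecule-specific and not modelled.

The central closure property: Langevin sampling of the DHO ground
surface, GSTA filtering, and the linear gap map reproduce the exact FC
mean (within 2%) and standard deviation (within 7%), while the
unfiltered branch is narrower by exactly √w(ω).  Wigner sampling of the
same model gives the identical Gaussian line — for the DHO, Wigner,
GSTA and the exact treatment coincide in their first two moments.

Default study conditions for this pipeline: T = 300 K, dt = 0.5 fs,
2×10⁵ steps, 241-frame window, excitations every 100th frame (~2000
snapshots), ħω = 0.2 eV, S = 1, E00 = 3.0 eV, reduced mass 1 amu.  The
step count is the smallest that keeps the Monte Carlo error of the
ensemble standard deviation a few times below the 7% closure check.

## Bandwidth selection

For a candidate Δ, the amplitude fit is the closed-form least-squares
ratio a(Δ) = Σ Y_i ŝ(X_i) / Σ ŝ(X_i)² (self-term included), and the
leave-one-out loss uses the full-data a(Δ) with ŝ_{−i}(X_i) = ŝ(X_i) −
Y_i·K_Δ(0) — algebraically identical to re-fitting the kernel sum
without record i, and checked against that brute force to 1e−10.  The
kernel is the unit-area Gaussian density, so a(Δ) carries an axis unit;
switching to a unit-height convention rescales a by Δ√2π and leaves the
L_cv argmin unchanged (tested).  The search runs on a log-spaced Δ grid
(default 25 points in [0.005, 0.5] eV) followed by bounded scalar
minimization inside the best bracket; ties break toward smaller Δ.

**Degenerate case.**  If the strengths Y_i are exactly constant —
as for a single Condon chromophore — L_cv decreases monotonically with
Δ: an arbitrarily wide kernel predicts a flat Y perfectly.  The scan
then ends on the boundary and says so (`boundary_warning`).  This is a
property of the statistic, not a bug: bandwidth selection is
informative only when strengths vary across the ensemble.  The
bandwidth tests therefore use sticks whose strengths follow a smooth
Gaussian envelope of energy (`synthetic_envelope_sticks`), and the
kernel-robustness test pools two DHO states of unequal strength so both
branches have interior optima.  On such data the selected Δ* shrinks
with ensemble size, and rebuilding a quantized spectrum with the
*classical* ensemble's Δ* changes it by under 5% — the broadening lives
in the ensemble, not in the kernel.

`single_point_spectrum` (one geometry) defaults to Δ = 0.14 eV, an
empirical literature value for solvated organic chromophores; it is a
documented constant, not something this package computes.  The Marcus
estimate σ = √(2k_BT·E_r) gives the solvent-only Gaussian width from a
reorganization energy.

## Axis handling

λ[nm] = 1239.84198/E[eV] pointwise.  By default intensities are
re-plotted unchanged (shapes are compared after area normalization, so
the Jacobian is a no-op there); an optional Jacobian mode multiplies by
|d(source)/d(target)| = source²/hc for area-conserving conversion.
Window normalization scales the trapezoidal area over a wavelength
interval (default 300–700 nm) to unity.

## Units and constants

Å, fs, eV, amu, cm⁻¹, K throughout; hc = 1.23984198e−4 eV·cm and
k_B = 8.617333e−5 eV/K; all derived prefactors (force constants,
accelerations, coordinate spreads) are computed from CODATA SI values
at import so that identities like var_W/var_cl = w(ν) hold to machine
precision.

## Known limitations

* The GSTA filter acts on coordinates only; filtering velocities or
  forces (needed for thermodynamic state functions) is not implemented.
* The toy chromophores are one-dimensional and Condon; non-Condon
  intensity variation, multiple coupled modes on the excited surface,
  and state crossings are not modelled.
* The synthetic data cannot exhibit solvent-induced peak shifts or
  conformational heterogeneity, so passing tests validate the spectral
  machinery, not the quality of any particular electronic-structure or
  solvation treatment.
* Imaginary-frequency modes are rejected rather than handled.
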