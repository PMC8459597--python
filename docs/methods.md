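# Methods

## Contact model and estimator

Indentation of a cell by a rigid sphere of radius R is modelled with the
paraboloid-approximated Hertz contact law

    F(δ) = (4/3) · E/(1−ν²) · √R · δ^{3/2},

valid for δ ≪ R. The package enforces validity by capping the fit range
at δ ≤ 0.3 R (`FitConfig.max_indentation_fraction`). The Poisson ratio
defaults to ν = 0.5, the standard incompressible-cell assumption; it is
configurable but rarely worth changing for living cells. Canonical units
are µm for lengths, nm for deflection, nN for force and kPa for modulus;
with these the prefactor is exactly 1 (kPa·µm² = nN), which keeps δ^{3/2}
far from underflow and makes hand-checking easy. A dedicated test
verifies that running the estimator in SI units end to end changes the
modulus by less than 1e−9 relative.

For fixed contact point z0 the model is linear in E, so the
least-squares solution is closed-form:

    E = (3/4) · (1−ν²)/√R · Σ F δ^{3/2} / Σ δ³.

This is the production estimator — exact, deterministic and fast — and an
iterative nonlinear least-squares fit is used in the tests only as an
independent cross-check (agreement ≤ 1e−6 relative on noiseless data).

## Contact-point detection

The force onset on soft cells is gradual, so derivative thresholding is
unreliable. Instead z0 is found by grid search (step
`contact_search_grid_um`, default 5 nm) minimizing the residual RMS of
the *piecewise* model: zero force for z < z0, the Hertz law for z ≥ z0,
evaluated over **every** approach sample. Evaluating over the whole
segment — not just the in-range contact window — is essential: residuals
over different candidate windows are not comparable, and on noisy curves
a window of pure-baseline noise would otherwise beat the true contact
point. Ties resolve to the smaller z0 for determinism, and the grid
minimum is polished by bounded scalar minimization between its
neighbouring nodes (xatol 1e−6 µm). A curve whose residual profile never
admits a positive-coefficient fit (pure baseline) raises a detection
error.

A fit is flagged non-converged when fewer than 8 samples fall in range,
when the modulus exceeds `max_modulus_kpa` (default 1000 kPa, two orders
above the stiffest cell line — a rigid substrate, not a cell), or when
the residual RMS exceeds `max_relative_residual` (default 20%) of the
maximal fitted force, meaning the sphere model simply does not describe
the record. On a glass curve one of the latter two always fires.

## Calibration

The spring constant uses time-domain equipartition, k = β·k_B·T/⟨d²⟩,
with the sample variance (ddof = 1) of a baseline-free thermal deflection
series in metres and T defaulting to 310.15 K (37 °C measurement
condition). β is a dimensionless mode-shape correction, default 1.0 and
configurable, since whether a triangular-lever correction was applied
upstream is generally unknowable from the data. Power-spectrum (Sader)
methods are out of scope. The estimator is invariant under sign flip and
mean shift, and its relative error contracts as 1/√n (verified at
n ∈ {10³, 10⁴, 10⁵} over 100 replicates).

Deflection sensitivity comes from a rigid-substrate approach curve: past
contact dz = dd, so the inverse contact slope converts volts to
nanometres. The contact region is taken as samples above 2% of the peak
deflection and the line is fit over its deepest half
(`contact_fraction = 0.5`), keeping the fit away from the rounded
contact-onset region.

## Dose and viability

Areal energy density is intensity × time. The duty cycle of pulsed
operation is carried as metadata and **not** multiplied in: that is the
only convention under which the four quoted dose levels
(2.8/3.3/5.6/6.6 J/cm²) follow from the instrument settings
(0.139/0.164 W/cm² × 20/40 s) at two significant figures, even though the
transducer ran at a 50% duty cycle. The convention is documented on the
function and on `UltrasoundExposure`.

Viability is V = 100·(T̄−B̄)/(Ū−B̄) with group means of treated,
untreated and blank wells. Blank subtraction is standard resazurin usage
and is applied even though normalization is sometimes quoted without it;
passing identical blank values of 0 disables it in effect. Negative
estimates are floored at 0 with an explicit flag, never silently. The
replicate spread is first-order propagation of the three group SEMs.

## Sensitivity model

Viability is regressed on the per-line mean modulus with untransformed
OLS; the lines relating stiffness to survival are visually straight and
no functional form is established, so linear is the minimal declared
choice, with a log-E variant behind a flag for curvature checks. R² is
the squared Pearson correlation (identical to the OLS coefficient of
determination here) and is invariant under E-axis unit changes.
Predictions clamp to [0, 100]% and report when they clamped.

## In-vivo metrics

Tumor volume is V = (π/6)·L·W² — the ellipsoid equation with the depth
taken equal to the smaller caliper diameter; no independent depth input
is accepted, by design. Swapped calipers (W > L) are corrected with a
warning rather than rejected. Growth kinetics are summarized as
per-subject fold change from the day-0 baseline, group mean ± SEM per
day, and a treated/control mean-fold ratio table ready for external
statistics; ANOVA/t-tests themselves are deliberately left to
statsmodels/scipy. Necrosis is consumed as pathologist-delineated
(necrotic, total) area pairs — image segmentation is out of scope — and
reported as AON% = 100·necrotic/total.

## Synthetic data

The generators exist to give every stage a recovery ladder: exact
inversion at zero noise, unbiased recovery within Monte-Carlo tolerance
at realistic noise.

* **Force curves.** The cantilever and the contact obey F = k·d and the
  Hertz law simultaneously, so for each piezo position the generator
  solves k·d = Hertz((z−z0)−d) by 90-step vectorized bisection — this
  self-consistency is what makes noiseless pipeline recovery exact rather
  than approximate. Defaults: R = 1 µm, k = 0.1 N/m, z0 = 2 µm after a
  2 µm baseline run-in, z sampled at 1 nm (typical of instrument ramps at
  0.5–1 µm/s), and the z range chosen so the peak load is 0.4 nN, the
  middle of the 0.2–0.6 nN protocol window. Noise is additive Gaussian on
  deflection; `force_noise_fraction` re-expresses it as a fraction of the
  peak force. Optional linear baseline drift and volt-scaled output (via
  a sensitivity) exercise the preprocessing and calibration paths.
  Per-cell moduli can be drawn lognormally around the line mean for
  aggregation tests.
* **Thermal series.** i.i.d. Gaussian with variance k_B·T/k. Real
  thermal spectra are coloured by the lever's resonance; the equipartition
  estimator only consumes the variance, so whiteness is immaterial to what
  the tests demonstrate.
* **Plates.** Multiplicative noise, well = mean·(1 + CV·ε); the treated
  mean interpolates between blank and untreated by the true viability.
  Defaults: untreated 900, blank 100 (a.u.), CV 2%, triplicates.
* **Tumors.** V(t) = V0·exp(r·(1−e·treated)·t) with V0 = 30 mm³ (a
  3.5–4.5 mm starting tumor), r = 0.15/day, effect e = 0.5 default, and
  lognormal noise (CV 5%) applied to diameters back-solved under a fixed
  L = 1.3·W aspect. The aspect ratio is arbitrary and irrelevant to the
  estimators under test.

What the generators do **not** emulate: instrument drift nonlinearity,
coloured deflection noise, cantilever tilt and bottom-effect artefacts,
adhesion on retract, plate-edge effects, or tumor shape change under
treatment. Passing recovery tests therefore demonstrates correctness of
the estimators under the stated statistical assumptions, not robustness
to every artefact of real acquisitions.

## Numerical choices and degenerate inputs

Baseline correction fits the first 30% of approach samples (the paper's
contact region stays untouched at the protocol loads) and is idempotent
to 1e−9. Grid ties in contact detection go to the smaller z0. Zero
variance in the QC modulus sequence short-circuits to "no drift,
normality 1.0" since Shapiro–Wilk is undefined there. Aggregation
excludes (with a warning, and a count) cells with no converged fit, and
reports SEM as unset for a single-cell line rather than NaN. Problem
sizes in the test suite (60-curve batches, 10⁵ thermal samples, 100-seed
replicate sweeps) were chosen so the full chain exercises the study's
nominal acquisition sizes while the suite stays fast.

## Known limitations

Only spherical probes and the elastic (rate-independent) model are
supported — no conical tips, no viscoelasticity, no finite-thickness
correction, so moduli from thin cell peripheries will be biased stiff.
The dialect reader expects well-formed numeric tables and does not parse
proprietary instrument formats. The sensitivity model is a two-variable
correlation across line means; it makes no causal claim and is only as
good as the handful of (E, V) points that feed it.
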