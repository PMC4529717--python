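# Methods

This note records the models, numerical choices, and open design decisions
behind `ckst`, in the order the computation flows: spin physics → estimation
→ correction → error analysis → synthetic data.

## Two-pool exchange model

The CK system is modelled as two exchanging magnetization pools, PCr (pool a)
and γ-ATP (pool b), with equilibrium magnetizations m0 (PCr/ATP concentration
ratio m0a/m0b), intrinsic longitudinal relaxation times T1a, T1b (the
hypothetical T1s absent exchange), transverse times T2a, T2b, a forward
pseudo-first-order rate k_f, and a chemical-shift separation Δf (130 Hz at
3 T). The reverse rate is never a free parameter: detailed balance fixes
k_r = k_f·m0a/m0b exactly, so equilibrium is a true fixed point of the
longitudinal dynamics.

Closed forms used throughout: with γ-ATP held saturated, PCr relaxes
mono-exponentially with 1/T1′ = 1/T1a + k_f toward M0′ = m0a·T1′/T1a; without
RF, the coupled longitudinal pair is solved exactly via the 2×2 matrix
exponential of the affine system (no time stepping, so step size never enters
the tests).

Defaults describe a healthy heart at 3 T: k_f = 0.32 s⁻¹, T1 = 7.9/2.2 s,
T2 = 0.25/0.05 s, PCr/ATP = 1.5, Δf = 130 Hz. The PCr/ATP ratio entering the
spill-over sweeps is not pinned down by the protocol description (the fitted
range is 1–2); 1.5 is the midpoint and is exposed in configuration.

## Bloch–McConnell simulator

State: the 6-vector (Mx, My, Mz) of both pools in the frame rotating at the
RF carrier; pool p precesses at 2π(f_p − f_rf) and exchange couples all three
components at (k_f, k_r). Each piecewise-constant RF segment is propagated
exactly by the matrix exponential of the homogeneous 7×7 generator
[[A, b], [0, 0]] (the affine drive b carries the T1 recovery inflow).

**Matrix exponentials.** A batched scaling-and-squaring Padé-13
exponential evaluates stacks of these 7×7 generators in single NumPy calls;
it is verified against `scipy.linalg.expm` and against Runge–Kutta
integration at 1e−8 relative tolerance in the unit tests. Generator norms
over a sub-pulse or gap are of order one, so at most a few squarings occur.

**DANTE train.** Saturation is a comb of 100 µs hard pulses separated by a
0.91 ms gap (1.01 ms cycle). The flip of the sub-pulse centred at time t is
β·Σ_k cos(2πkδt) over band indices k ∈ {−(m−1)/2 … (m−1)/2} (a Dirichlet
kernel), so each of the m = 5 bands, spaced δ = 9 Hz around the carrier,
accumulates an average flip of exactly β per sub-pulse cycle; negative lobes
are retained (signed flips). This normalisation is required on physical
grounds: spreading β over a whole modulation period instead would give
per-band saturation rates with ω1²T1T2 ≪ 1, unable to saturate γ-ATP at the
nominal β = 0.9°. The exact envelope of the original hardware sequence is
not public; this surrogate is validated behaviourally — it reproduces the
incomplete-saturation dip at Q > 0.95, the bounded TRiST error at moderate
spill-over, the ~50% TwiST deficit at Q ≈ 0.4, and the parameter-grid error
summaries (see Known limitations).

**Period quantisation.** With a 1.01 ms cycle the 1/δ = 111.1 ms modulation
period spans 110.01 cycles; the simulator uses exactly 110 cycles (an
effective δ of 9.0009 Hz) so that one-period propagators can be composed
once and powered over the TR. The ~0.01% band-spacing shift is far below
every other modelling uncertainty.

**Protocol and readout.** Saturation runs throughout the TR; the readout is
an ideal, pool-nonselective 90° excitation with complete spoiling (the
adiabatic half-passage excitation approximates 90° over the sensitive
volume). The periodic steady state of the spoiled per-TR affine map
therefore starts each TR from zero longitudinal magnetization, and the
signal is the PCr z-component of the map's drive term — no fixed-point
iteration, hence no convergence ambiguity. Per TR the map is assembled as
(full periods)·(remainder cycles)·(remainder free evolution).

Static-field inhomogeneity follows the protocol prescription: the saturation
carrier is offset over −20…+20 Hz in 5 Hz steps and the nine signals are
averaged with 20 Hz-FWHM Gaussian weights (normalised to unit sum). The
four-acquisition protocol is: unsaturated (TR 16 s), control saturation at
+130 Hz (TR 16 s), γ-ATP saturation at −130 Hz (TR 10 s and TR 1.7 s).

## Estimators

All estimators are scale-invariant in the signals. The dual-TR solve for
T1′ brackets the monotone recovery-ratio function on T1′ ∈ [0.05, 50] s
(Brent, xtol 1e−10); signal ratios outside the open feasible interval
(TR_short/TR_long, 1) raise a model-inconsistency error rather than
extrapolate. Q is clipped at 1 inside every Q-corrected formula (noise can
push the raw ratio above 1); the raw value is preserved for diagnostics.
Non-positive rate estimates are returned flagged, not raised, so Monte Carlo
statistics include them without exclusion rules. TwiST deliberately uses
M′(TR_long) for M0′ without truncation compensation — the corrected
coefficients absorb that bias, and quantifying the uncorrected version of it
is one purpose of the bias analysis.

The bundled coefficient set (a–d, f–k, l–n) is the published cardiac 3 T
fit; at Q = 1 the corrected TwiST collapses to a plain TwiST with
equivalent intrinsic T1 = 1/(l(1+n)) = 8.13 s and ratio offset −m = 1.03.
Those coefficients are valid only for this saturation scheme over the fitted
parameter range; `ckst.correction` refits them for any other condition.

## Coefficient fitting and error summaries

The fitting grid spans PCr/ATP 1–2, T1 (PCr) 6.5–9.5 s, T1 (γ-ATP) 2–3.5 s,
k_f 0.1–0.4 s⁻¹, β 0.8–4.0°, with T2 fixed at 0.2/0.05 s. Grid density is a
free choice (the original study does not state one); the default
3×4×3×4×6 = 864 raw points balance fit stability against desk-scale runtime
(~10 s), and points with Q > 0.96 are dropped before fitting because the
incomplete-saturation dip would otherwise contaminate the coefficients.
The objective is the stated one — unweighted sum of squared fractional
differences — minimised by Levenberg–Marquardt from multiple starts (the
published values, a neutral start, and seeded random perturbations); the
product-form parameterisations are only defined up to the overall scale
coefficient, and rank deficiency of the Jacobian at the solution (e.g. from
degenerate record sets) is detected and reported. Error summaries report
mean ± SD and (min, max) of the per-record relative error in percent; the
uncorrected TwiST row uses the fixed assumed intrinsic T1 of 7.9 s while the
grid truth varies, so its spread includes T1 misspecification.

## Monte Carlo noise and bias

Signals are generated spill-over-free from the closed forms; the control
acquisition uses the exact exchange-coupled two-pool recovery (a
mono-exponential with the observed PCr T1 of 5.8 s is available as an
alternative, since the original description does not fix this choice).

Noise: σ = 0.16·M0 per single FID — one average of one phase encode. A
summed acquisition with n averages and 16 phase encodes carries
σ/√(16·n). This is the only reading consistent with the stated scan-time
budget arithmetic (16 × Σ TR·averages ≈ 30 min) and with the magnitude of
the resulting rate SDs; the per-average alternative is available behind a
configuration switch. Estimates use 2000 noise repetitions per grid point,
averaged over k_f ∈ {0.1…0.4} s⁻¹ and intrinsic T1 ∈ {5…9} s; TwiST
repetitions assume the grid point's true intrinsic T1 (isolating noise from
T1 misspecification), TRiST repetitions re-solve the dual-TR system
(vectorised bisection, 52 iterations). Bias runs use the mid-range
T1 = 7 s only and are reported as (est − true)/true; truncation of
M′(TR_long) inflates the rate rapidly below TR_long ≈ 8 s, while at the
human schedule (TR_long 10 s × 8, TR_control 16 s × 2) the bias is within a
few percent.

The schedule search enumerates integer average allocations within 5% of a
fixed scan-time budget for each TR pair and keeps the allocation with the
lowest SD. The TwiST budget is the two-acquisition human protocol
(1792 s ≈ 30 min); the TRiST benchmark uses its own three-acquisition
protocol time (2368 s ≈ 40 min), which is the condition under which the
reference TRiST noise figure was established.

## Synthetic spectra

Spectra are sums of complex Lorentzians (PCr at 0 Hz, γ-ATP at −130 Hz,
default FWHM 12 Hz — typical in vivo ³¹P at 3 T) with a global zero-order
phase and complex Gaussian noise on a uniform axis (default 1025 points over
±600 Hz; the odd count puts a sample exactly on PCr). 1D-CSI spatial
encoding is emulated by per-slice amplitude weights, not k-space physics,
because the analysis consumes per-slice spectra only.

Quantification follows the clinical pipeline: a single zero-order phase is
estimated on the unsaturated reference spectrum and applied identically to
all four acquisitions of a slice; PCr is read as the real-part peak height
minus a baseline averaged over ±3 points around the minima flanking the
peak (the neighbourhood width is a tunable; nothing pins it down). The
phase estimate is the angle of the magnitude-weighted complex sum over a
±20 Hz region around the detected peak after removing a local complex
offset from a 20–35 Hz annulus: the symmetric weighting cancels the
antisymmetric dispersion component (avoiding per-bin phase quantisation of
~11°/bin), and the offset removal keeps the γ-ATP dispersion tail from
tilting the result (residual ≲ 3° at SNR 100 with the neighbour present,
≲ 1° for an isolated peak). Peak location uses a 5-point moving average;
the height is read from the raw spectrum at that point, which keeps the
noisy-height estimator unbiased to ≲ 0.01 at SNR ≈ 6 where a max-over-window
rule would bias high by the noise order statistic.

## Synthetic cohorts

Subjects are drawn per group (healthy n = 12: k_f 0.33 ± 0.08 s⁻¹; heart
failure n = 17: 0.20 ± 0.06 s⁻¹; intrinsic T1 8.4 ± 1.4 s and Q ≈ 0.84–0.85
in both) from Gaussians with hard physiological clipping (k_f to
[0.05, 0.6], T1 to [5, 12] s, Q to [0.4, 1.0]); only means ± SDs are
reported for the human groups, so the Gaussian family is a modelling choice.
Each subject's Q target is inverted to a DANTE amplitude through a Q-vs-β
calibration table simulated once for the group-mean system — Q depends only
weakly on k_f and T1 over the sampled range, and per-subject tables would
multiply simulator cost roughly tenfold for sub-percent changes. Per-slice
noise reuses the Monte Carlo convention (σ = 0.16 per FID with the human
protocol's averages); within-subject slice variance is not reported for the
human study, so this keeps a single noise convention across modules.
Per-subject estimates average the finite per-slice estimates (failed slices
counted); method agreement is summarised by OLS regression, Bland–Altman
bias with ±1.96 SD limits, and Student's t-tests (paired within subjects,
unpaired between groups, Welch variant available).

What passing cohort tests do and do not show: the generator reproduces the
distributional skeleton of a two-group study and the estimator pipeline's
noise/correction behaviour on top of it; it does not model cardiac-gating
TR jitter, per-slice sensitivity gradients beyond scalar weights,
B0/B1 depth profiles beyond a scalar β, or any biological covariance between
k_f, T1 and Q — so agreement statistics on synthetic cohorts bound the
instrumental, not the biological, scatter.

## Known limitations

* The DANTE envelope is a cosine-sum surrogate for the original hardware
  modulation. It reproduces the validation behaviour to within a few
  percentage points, but carries slightly stronger PCr spill-over at matched
  Q near Q ≈ 0.5–0.6: the simulated TRiST error over 0.6 < Q ≤ 0.95 peaks at
  ~11% (against "about 10%"), and the apparent intrinsic T1 at Q ≈ 0.5
  reaches 3.76 s (against a printed band edge of 4 s).
* Refitted coefficients depend on grid density and β range; only behavioural
  equivalence (bias removal, error-band shrinkage, equivalent-T1 within
  ~15%) is claimed, not coefficient-for-coefficient equality.
* No three-pool (Pi ↔ ATP) exchange, no time-dependent ST variants, no
  vendor raw-data readers, and no spatial coil/CSI physics.
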