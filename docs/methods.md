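# Methods

This note documents the models, numerical choices and limitations of the
package; the README gives the usage-level overview.

## Signal model

An FID-CPMG inversion-recovery dataset is modelled as

    M(t_rec, t_acq) = Σ_j A_j · rec_j(t_rec) · dec_j(t_acq) + ε

with the recovery factor `1 − 2 f_inv exp(−t_rec/T1_j)` (inversion, with
inversion efficiency `f_inv ≤ 1`, default 1.0) or `1 − exp(−t_rec/T1_j)`
(saturation), and the acquisition decay `exp(−t_acq/T2_j)` for liquid-like
pools or `exp(−(t_acq/T2_j)²)` for the solid-like pool.  The Gaussian
convention `S(t) = S₀ exp(−(t/T2)²)` is fixed deliberately: it is the shape
typical of strongly dipolar-coupled spins, and with a 15 μs receiver dead
time it loses 43% of a T2 = 20 μs component and 22% of a T2 = 30 μs
component — the quantities `models.deadtime_loss` reports.

The default acquisition scheme is the benchtop T1-T2 experiment: 32
logarithmically spaced recovery times from 1 to 5000 ms, an FID sampled on
a uniform 1 μs grid from just after the 15 μs dead time to the first echo,
then one point per echo top of a CPMG train (250 μs echo spacing, 2000
echoes).  The FID sampling rate is a package default, declared rather than
derived: only the dead time and echo timing are experimentally meaningful,
and the inversion is insensitive to the exact FID grid as long as the
sub-100 μs decade is covered.  Noise is additive Gaussian on one real
channel (phased data), not Rician; all generators are reproducible from an
integer seed.

## 2D inverse Laplace transform

The inversion solves

    min_{F ≥ 0}  ‖K1 F K2ᵀ − M‖² + α‖F‖²

on log-spaced grids, default T1 ∈ [1 ms, 10 s] × 64 and
T2 ∈ [5 μs, 1 s] × 64.  The acquisition kernel is mixed: grid T2 below the
`gaussian_boundary` (default 1 ms) uses the Gaussian decay, above it the
exponential.  The boundary sits in the empty gap between the solid-like
(tens of μs) and liquid-like (ms–s) pools, so its exact value is not
critical.

Numerics, in order:

1. **SVD compression.** Both kernels are truncated to `svd_rank` (default
   16) singular components; the data are projected as `M̃ = U1ᵀ M U2`.
   This is the standard compression for separable 2D Fredholm problems and
   reduces the design matrix to `kron(K̃2, K̃1)` of size 256 × 4096.
2. **α selection.** Generalized cross-validation by default, evaluated in
   the diagonalized (SVD) basis of the compressed operator on the
   compressed data only — the projection residual left by compression is
   α-independent model error and must not enter the GCV numerator (folding
   it in biases α upward by orders of magnitude on clean data).  The
   Butler-Reed-Dawson fixed-point iteration on the compressed residual is
   available (`alpha_method="brd"`), as is a fixed α.  A relative floor of
   `1e-10 · σ_max²` keeps the problem strictly convex.
3. **Solve.** The non-negative Tikhonov problem is solved exactly by
   augmented non-negative least squares (`[A; √α I] f ≈ [b; 0]`, f ≥ 0).
   Because α > 0 the minimizer is unique; on 16×16 grids the compressed
   solve matches an uncompressed full-kernel NNLS to better than 1e-6
   relative (tested).

Intensity is conserved: the total map mass matches the extrapolated,
fully-recovered t = 0 signal within a few percent; rank-16 truncation
inflates the solid-like pool's mass by ~3% on noiseless data (rank 24
reduces this to ~0.3%), which is inside the quoted uncertainties of
two-pool quantification.

## Peak quantification

Peaks are connected components (8-neighbor connectivity on the log grid) of
cells at or above `rel_threshold` (default 0.05) of the map maximum.
Sub-threshold cells are attributed to the nearest labelled component, so a
peak's reported intensity is its full weighted integral including the
regularization skirt; without this completion a weak peak loses several
percent of its mass to the global threshold.  Components below
`min_fraction` (default 0.01 — the practical detection limit of such maps)
are discarded and reported as a residual fraction.  Positions are
amplitude-weighted geometric means of (T1, T2) over the component; for a
narrow peak this coincides with the mode, for a broad ridge it is a
representative center.

The time-domain route fits `A_g exp(−(t/T2g)²) + A_e exp(−t/T2e)` to the
acquisition decay at the longest recovery time (assumed ≥ 5·T1, i.e. fully
recovered).  Both amplitudes are t = 0 extrapolations; fractions are their
shares.  Dead-time correction (`correct_dead_time=True`) additionally
divides A_g by `1 − deadtime_loss(t_dead, T2g)` for the case where the
fitted amplitude still underestimates a partially invisible solid
component.  It is opt-in because tabulated two-pool intensities are
conventionally reported uncorrected.

Map-integral and time-domain intensities are both computed and labelled;
they agree on synthetic data but answer subtly different questions on real
data (the map shares depend on the regularization, the time-domain shares
on the two-shape model).

## RMTD spectral density and dispersion analysis

The RMTD spectral density is the mode integral

    I(ω) = ∫_{k_low}^{k_high} S(k) · τ(k) / (1 + ω² τ(k)²) dk,
    S(k) ∝ k^−χ,  0 < χ < 1,

evaluated by adaptive quadrature in log-k (relative tolerance 1e-10).  The
mode correlation times are `τ(k) = 1/(D k²)` for a Gaussian surface-
diffusion propagator and `τ(k) = 1/(c k)` for Cauchy (Lévy-walk)
statistics — the standard kernels that reproduce the exponent relations
γ = (1+χ)/2 and γ = χ for the T1 dispersion T1(ω) ~ ω^γ.

Default cutoffs are four decades apart (k ∈ [1e4, 1e8] m⁻¹, a molecular-to-
micron roughness range) with a water-like D = 2.3e-9 m²/s.  A numerical
caveat worth knowing: the Cauchy integrand decays only as u^−(1+χ) above
the resonant mode, so the asymptotic power law emerges slowly — for
χ = 0.1 the upper cutoff must sit ~11 decades above the evaluation band
before the local slope is within 0.01 of −χ (analytic tail estimate:
relative truncation error `(k_high c/ω)^−χ/χ` against the full integral
`(π/2)/sin(πχ/2)`).  Parameter-recovery tests therefore use wide Cauchy
cutoffs (k ∈ [1e2, 1e16]); Gaussian statistics need no such widening
because τ ~ k⁻² doubles the effective decade span and the integrand decays
as u^−(3+χ).

Power-law exponents are fitted by ordinary least squares of log10 T1 on
log10 f, with optional exclusion of the dip windows; errors are the OLS
standard errors.  Quadrupolar dips are phenomenological Lorentzians (peak
height, HWHM) added to R1 — no ¹H-¹⁴N quantum-mechanical lineshape is
attempted.  Dip isolation fits a baseline (log-log power law by default,
smoothing spline for curved baselines) on the points outside the dip
windows (defaults [0.45, 0.80], [2.0, 2.6], [2.6, 3.2] MHz) and subtracts;
dip areas are trapezoidal integrals over each window, so only relative
comparisons (ratios, trends across hydration stages) should be treated as
quantitative.  A window must span roughly ±13 HWHM for the clipped
Lorentzian integral to reach 95% of the full π·h·w.

## Hydration modelling

Two parameterizations are fitted side by side, because drying series obey
them to different degrees: the empirical linear dependence of T1/T2 on
total sample weight, and the Brownstein-Tarr fast-exchange form with
`1/T_i − 1/T_bulk` linear in the inverse free-water measure
(weight − dry weight).  The bulk relaxation time defaults to 2 s (brine).
Stages at or below the dry weight are rejected rather than extrapolated —
there the fast-exchange premise (a freely diffusing bulk-like phase) fails.
Trend reports classify stage series as flat when the coefficient of
variation is below 0.2, otherwise as monotone with a 2%-of-span tie
tolerance.

## Isotope bookkeeping

`hdo_intramolecular_factor` returns the bare squared gyromagnetic-ratio
factor (γ_H/γ_D)² ≈ 42.4 for the intramolecular relaxation-rate reduction
on H→D substitution, and `hdo_frequency_shift_factor` the Larmor-frequency
ratio ≈ 6.51.  Spin-quantum-number factors of the I = 1 deuteron are
deliberately omitted — the number quoted is the conventional
order-of-magnitude estimate, not a full second-moment calculation.
γ_H comes from scipy's CODATA table; γ_D is derived from the CODATA
deuteron magnetic moment via γ = μ/(Iħ).  Both are overridable arguments.

The proton-density conversion solves
`f = w·d_pg / (w·d_pg + (1−w)·d_w)` for the weight fraction w, with
defaults d_w = 2/18 and d_pg = 40/640 (heparin-sulfate-like); a 14% signal
fraction maps to 22.4 wt-% PG.  Whether a measured signal fraction has
been dead-time corrected before this conversion is the caller's choice;
the function is agnostic.

## What the synthetic data does and does not emulate

The generator reproduces the two-pool composition, the acquisition timing,
seeded additive noise, power-law dispersions with quadrupolar dips, and
drying/shrinkage depth profiles.  It does **not** emulate: Rician noise,
B1 inhomogeneity or off-resonance effects, stimulated echoes,
magnetization exchange between pools (maps here are correlation, not
exchange), T2 orientation dependence, or distributed (rather than
discrete) relaxation components.  Passing tests therefore demonstrate that
the analysis chain recovers known parameters under the stated signal
model — not that the model captures every feature of instrument data.

## Problem sizes in tests

The shared end-to-end check inverts the full-size noiseless dataset
(32 × 2234 samples) on the default 64 × 64 grids (~4 s).  Unit tests use
reduced schemes (12–16 recovery times, 60–800 echoes) and 16–48 point
grids, which preserve every property being asserted while keeping the
suite under half a minute.
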