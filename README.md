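# cartrelax

Low-field NMR relaxometry analysis of articular cartilage: two-dimensional
T1-T2 correlation mapping, fast-field-cycling T1 dispersion analysis and
fast-exchange hydration modelling, with a synthetic-data generator so every
stage is testable end to end.

## The scientific problem

Healthy articular cartilage holds its water inside an intertwined network of
collagen fibers and proteoglycan (PG) aggregates; osteoarthritis depletes the
PG and raises the water content.  Proton NMR relaxation probes exactly this
water/matrix interaction.  A combined FID-CPMG inversion-recovery experiment
at low field separates two proton pools with very different transverse
relaxation: a liquid-like pool (exponential decay, T2 of tens of
milliseconds) and a solid-like pool of macromolecular protons and strongly
bound water (Gaussian decay, T2 of tens of *micro*seconds), which share
similar T1 (hundreds of ms).  Fast-field-cycling relaxometry adds the
frequency dependence of T1, which in this tissue follows a power law
T1(ω) ~ ω^γ with superimposed ¹H-¹⁴N quadrupolar dips near 0.6, 2.3 and
2.9 MHz.

The package implements, as reusable library code:

* **2D inverse Laplace transform** (`cartrelax.ilt2d`): solves
  `min_{F≥0} ‖K1 F K2ᵀ − M‖² + α‖F‖²` after SVD compression of both
  kernels, with a **mixed acquisition kernel** — `exp(−(t/T2)²)` for grid
  T2 below a boundary (solid-like pool), `exp(−t/T2)` above it — and α
  selected by generalized cross-validation, Butler-Reed-Dawson iteration,
  or fixed.
* **Peak quantification** (`cartrelax.peaks`): connected-component
  segmentation of relaxation maps with amplitude-weighted geometric-mean
  positions and intensity fractions, plus a direct time-domain
  two-component fit `A_g exp(−(t/T2g)²) + A_e exp(−t/T2e)` with optional
  receiver dead-time correction `1 − exp(−(t_dead/T2g)²)`.
* **Relaxation physics** (`cartrelax.models`): the dipolar/quadrupolar rate
  expressions `1/T1 = const·[I(ω) + 4I(2ω)]`,
  `1/T2 = const/2·[3I(0) + 5I(ω) + 2I(2ω)]` and the rotating-frame analogue;
  the RMTD (reorientations mediated by translational displacements)
  spectral density from a power-law surface-mode spectrum S(k) ~ k^−χ,
  which predicts γ = (1+χ)/2 for Gaussian surface diffusion and γ = χ for
  Cauchy (Lévy-walk) statistics; the two-site fast-exchange average
  `1/T = p_a/T_surf + (1−p_a)/T_bulk`; and H→D isotope bookkeeping.
* **Dispersion analysis** (`cartrelax.dispersion`): monoexponential recovery
  fits, log-log power-law fits with dip exclusion, quadrupolar-dip isolation
  by baseline subtraction and trapezoidal dip areas.
* **Hydration trends** (`cartrelax.exchange`): T_i-vs-weight linear fits and
  the fast-exchange surface term from drying series.
* **Synthetic data** (`cartrelax.synthetic`): seeded generators for all of
  the above, defaulting to the benchtop acquisition scheme (32 log-spaced
  recovery times over 1–5000 ms, 250 μs echo time, 2000 echoes, 15 μs dead
  time).

## Worked example

Run the full synthetic pipeline — a two-pool sample (liquid-like pool:
T1 = 635 ms, T2 = 80.8 ms, amplitude 928; solid-like pool: T1 = 666 ms,
T2 = 30 μs, amplitude 134) simulated, inverted and quantified:

```sh
cartrelax demo --seed 7 --out-dir demo_out
```

`demo_out/report.json` then contains (abridged):

```json
{
 "peaks": [
  {"T1_ms": 634.35, "T2_ms": 80.78, "intensity": 928.53, "fraction": 0.8633},
  {"T1_ms": 405.67, "T2_ms": 0.0270, "intensity": 146.97, "fraction": 0.1367}
 ],
 "time_domain": {
  "fraction_short": 0.1261, "T2_gauss_ms": 0.0300, "T2_exp_ms": 80.8
 },
 "dispersion_gamma": 0.2702,
 "alpha": 0.00116
}
```

Reading this: the inversion recovers the liquid-like peak at
(T1, T2) = (634 ms, 80.8 ms) carrying 86.3% of the signal and the
solid-like peak at T2 ≈ 27 μs with 13.7% (true shares 87.4%/12.6%; the
weighted position of the broad solid-like peak is less precise than its
mass).  The independent time-domain fit returns the exact generating
fractions (12.6% short) and T2 values.  The dispersion fit recovers
γ = 0.270 from a Cauchy-statistics RMTD model with χ = 0.27, illustrating
the γ = χ exponent relation.

The other subcommands (`simulate`, `invert`, `peaks`, `dispersion`,
`exchange`) expose the individual stages on CSV/JSON files; see
`cartrelax --help`.

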