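# Methods

This note records the model implemented by `rpgrappa`, the conventions and
numerical choices that shape it, what the synthetic data does and does not
emulate, and the known limitations.

## Data model and conventions

Multi-coil Cartesian k-space is a complex array of shape `(nc, ny, nx)`
with the phase-encode direction fixed as axis 1.  k-space is stored DC at
center (FFT-shifted); the forward DFT is unnormalized and the inverse
carries the `1/N` factor.  Any consistent pair would do — all metrics
compare like with like — but one convention had to be fixed and this is
the common MRI choice.

Retrospective undersampling keeps a centered ACS block of rows
`⌊ny/2⌋ − ⌊acs/2⌋ … ⌊ny/2⌋ + ⌈acs/2⌉ − 1` plus every `A_f`-th row
elsewhere; the lattice offset is chosen so the ACS center row lies on the
acquired lattice.  Acquired samples are stored verbatim and zeros fill the
rest; containers (HDF5 with an NPZ fallback) round-trip data, mask, ACS
interval and acceleration losslessly.

## Calibration

The GRAPPA kernel covers `d_y` acquired lines (spaced `A_f` apart) ×
`d_x` readout taps (odd, centered) × all channels; the fitted targets are
the `A_f − 1` missing lines in the gap between the two central source
lines (`j0 = ⌊d_y/2⌋ − 1`), the symmetric-interpolation convention that
minimizes extrapolation.  One weight matrix with `l = nc·(A_f − 1)`
columns solves all offsets jointly.  Kernel placements slide with stride 1
over the ACS, phase-encode outer / readout inner, readout windows fully
interior, giving

```
m = (acs − ((d_y − 1)·A_f + 1) + 1) · (nx − d_x + 1)
```

rows.  Source columns are ordered `(channel, d_y, d_x)` and target columns
`(channel, offset)`; the ordering is a pure convention, and the tests
assert by permutation that results do not depend on it.

## Dimension reduction

**Random projection.**  `R` is `k × m`, `k = ⌈λ·n⌉` (the ceiling
guarantees `k ≥ n` for every `λ ≥ 1`, including values like 1.01), with
i.i.d. entries `±√s` each with probability `1/(2s)`, zero otherwise, and
`s = √m` by default — so about `k·m/√m` nonzeros and a projection cost of
one sparse–dense product per matrix.  `R` is real and multiplies complex
matrices; the `√s` (= `m^(1/4)`) amplitude is retained for fidelity to the
distribution even though any global scale of `R` cancels in least squares
(asserted by test).  Entries are drawn as a binomial nonzero count plus
uniform positions, which is exactly the i.i.d. three-point law.  A fresh
projection is drawn per reconstruction unless a seed is pinned.

**Channel compression.**  Complex PCA, uncentered, fitted on the ACS
samples only (fully sampled, cheap, representative): the compression
matrix holds the top `n_v` left singular vectors of the `nc × samples` ACS
matrix, applied to the whole k-space before calibration.  Uncentered
because k-space columns have no meaningful mean to remove — energy, not
offset, is what PCA should rank.

## Solvers

* `solve_pinv` — SVD-backed least squares (`numpy.linalg.lstsq`); warns
  and returns the minimum-norm solution on rank deficiency.  An optional
  `normal_equations` mode forms `(SᴴS)⁻¹SᴴT` literally to expose the
  classic pathology `κ(SᴴS) = κ(S)²`.
* `solve_cgls` — standard CGLS recurrences from `x₀ = 0`; per iteration
  one product with `S` and one with `Sᴴ` (`2kn` complex multiplies, two
  n-vectors and two k-vectors of working storage); never forms `SᴴS`.
  Offered in a vectorized block form and a per-column form that perform
  identical arithmetic (asserted to 1e-10).
* `solve_hgd` — steepest descent with step `η = μ/‖e‖` (a step of length
  `μ` along the normalized gradient).  The adaptation rules: `μ ← 1.1·μ`
  after four consecutive residual decreases; `μ ← 0.9·μ` after two
  consecutive increase/decrease alternations (the pattern up, down, up,
  down); rule counters reset after each adjustment.  A `literal` mode
  `η = μ·‖e‖` is provided for comparison; it needs a much smaller `μ₀` to
  be stable.  `μ₀` defaults to 0.1 — the method is insensitive to it as
  long as it is not large.

Both iterative solvers accept arrays or `LinearOperator`s and internally
use only `v ↦ Sv` and `v ↦ Sᴴv`; the test suite counts calls to prove the
two-products-per-iteration contract.  Default stopping is a fixed
iteration budget; a relative-residual tolerance is available and off by
default.  Stationarity is declared when the gradient norm falls below
1e-12 of its `x = 0` magnitude, so starting at the optimum returns
immediately instead of taking a fixed-length step away from it.

## Synthesis and edge handling

Missing samples are synthesized with the calibrated weights from their
source neighborhoods on the acquired lattice; acquired samples, ACS
included, are kept bitwise.  At grid edges the source windows wrap
circularly along both axes — GRAPPA synthesis as a periodic k-space
convolution, the convention of FFT-based implementations.  The clipped
"nearest interior window" alternative was rejected after implementation:
a shifted window places the target off the window center, so the fitted
weights no longer apply and even an exactly kernel-consistent k-space is
reconstructed with O(1) errors in the edge columns.  With circular
windows, wrapped taps land on the near-zero outer rows of real k-space
(negligible energy), and a wrapped phase-encode row that happens to be
unacquired contributes zero.

## Exact-kernel fixtures

Machine-precision tests need k-space for which the kernel relation holds
*exactly at every placement*.  Generic "random acquired lines + computed
missing lines" data cannot do this: stride-1 calibration also places
kernels at off-lattice shifts, which impose constraints such data
violates.  The fixture instead builds the data as a sum of
`n = d_y·d_x·nc` separable grid-harmonic modes `a_cq · z_q^y · w_q^x`
with distinct integer frequencies (so the relation survives circular
wrap; `ny` must be divisible by `A_f`) and random channel amplitudes.
For each mode the kernel relation reduces to one linear equation, so the
embedded `W` is the unique solution of an `n×n` system, the relation is
fully shift invariant, and the source matrix has full column rank —
calibration recovers `W` and synthesis reproduces the ground truth to
~1e-14.  Sketching such a system at any `λ ≥ 1` loses nothing, which the
acceptance suite exploits.

## Synthetic acquisitions

The generator multiplies a Shepp–Logan (or smooth-blob) phantom by
simulated sensitivities — Gaussian-profile coils on an ellipse around the
FOV with smooth phase ramps, or low-order complex polynomials — and
Fourier transforms per channel; the reference is the sum-of-squares of the
noiseless coil images.  Noise is i.i.d. circular complex Gaussian per
k-space sample, no inter-channel correlation, with standard deviation
expressed as a fraction of the noiseless k-space RMS.  The trend studies
use `noise_sigma = 0.01` (≈ 38 dB composite SNR on the 8-channel phantom),
chosen once as a realistic clinical level: it makes conventional GRAPPA
visibly noise-limited without drowning the phantom.

What this emulates: acquisition geometry (matrix size, channel count, ACS
and acceleration protocols), coil encoding redundancy, thermal noise.
What it does not: true B1 receive fields and coil coupling, anatomy and
motion, off-resonance/relaxation effects, non-white noise covariance.
Passing tests therefore establish the algorithmic claims (sketching
fidelity, solver behavior, conditioning, memory) on data whose linear
model is honest, not clinical image quality.

Channel counts, grid sizes, protocols (A_f ∈ {3, 5, 8}, 48 ACS lines,
kernels 4×11 / 4×7 / 4×5) are free parameters; the 30-channel cardiac
geometry defaults to 10 virtual channels under compression.  The
evaluation harness runs scaled-down grids (128² with a 4×7 kernel for the
8-channel protocol studies) so a full sweep completes in minutes on one
core; the calibration rows, not the image grid, carry the phenomena of
interest, and they are in the thousands either way.

## Metrics

RMSE is the normalized Frobenius distance of magnitude images after a
least-squares global scale fit of the reconstruction to the reference
(identical → 0, all-zero → 1); SNR is defined on the same normalized
quantities, so `SNR[dB] = −20·log₁₀(RMSE)` exactly (capped at 300 dB).
Storage is 16 bytes per complex value, reported in MiB (2²⁰ bytes) — the
only convention under which an 8184×600 complex matrix prints as 74.9 MB,
hence treated as the field's implicit one.

The g-factor map uses the standard image-space noise-propagation
formulation with identity channel covariance by default: the fitted
kernel plus the unit pass-through of acquired samples is placed on the
full grid and Fourier transformed into per-pixel unmixing weights
`w[t,s](r)`, combined with sum-of-squares coefficients
`p_t(r) = conj(I_t)/SoS`, giving `g = ‖pᵀw‖_Ψ / (A_f · ‖p‖_Ψ)` — unity
everywhere for an unaccelerated identity kernel, and validated against a
Monte-Carlo noise-propagation oracle through the actual synthesis path
(agreement to a few percent).

## Iteration budgets in the λ-sweeps

The iterative pipelines' quality at a given reduction factor depends on
the iteration budget, and the budget that reaches the quality plateau
varies with `λ`.  `evaluation.converged_iterations` reproduces the
empirical protocol: grow the budget geometrically (×1.5 from 10) and stop
when the next step improves RMSE by less than 2%.
`lambda_sweep(max_iter="auto")` applies it per (pipeline, λ) cell before
seed-averaging.  With per-cell converged budgets the sketched-CGLS RMSE
curve over `λ ∈ [1.01, 4]` is flat to about 1% while the direct-solve
sketch degrades several-fold at `λ ≈ 1` — though a 2-standard-error test
on 10 projection-seed repeats can still resolve the ~1% residual
elevation at `λ ≈ 1`, since projection-seed variance alone makes the
standard errors of the cell means very small; see the sweep tables the
harness emits.

## Known limitations

* 2-D single-slice Cartesian only: no CAIPI patterns, non-Cartesian
  trajectories, SPIRiT-style self-consistency, or multi-slice/3-D.
* No Tikhonov regularization of the calibration fit.
* Reconstruction wall time is logged but never asserted — it is
  hardware-dependent and not a reproducible quantity.
* HGD converges slowly on ill-conditioned sketches (`λ = 1` exactly can
  need ~10⁶ iterations on a κ ≈ 300 system); CGLS is the practical choice
  there, which is the package's central point.
* The g-factor formulation assumes the pure-lattice sampling operator;
  ACS pass-through inside the block is not modeled in the map.
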