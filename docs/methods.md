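# Methods

## Forward model

The measurement chain is modeled as a causal, linear, time-invariant
system at rest before time zero: the recorded concentration is the
convolution of the true input with the system's impulse response.
Sampling at interval `δt` (sample `k` representing the average over
`[kδt, (k+1)δt)`, 0-based), the kernel weight `h(k)` is the integral of
the continuous impulse response over the k-th interval, and the forward
map is the lower-triangular Toeplitz matrix `H` with first column `h`.
When a recorded calibration pulse supplies `h`, the per-interval
integral is approximated by the rectangle rule (`sample × δt`), which is
how a 10 Hz gas-analyzer trace is actually used; kernels are normalized
to unit area so the forward model conserves totals. The kernel's
support ends where the recording ends — no tail is extrapolated, since
calibration recordings are continued until the signal vanishes.

Leading kernel samples with magnitude ≤ 1e-3 × the kernel peak
(configurable) are treated as transport-delay zeros and stored exactly
as zero. Recorded kernels carry baseline noise, so an exact-zero test
would never fire; the relative threshold is the practical reading of
"the delay appears as leading zeros".

## Tikhonov solver

The full-record estimate is
`û = (HᵀH + γQᵀQ)⁻¹Hᵀy`, computed as the least-squares solution of the
stacked system `[H; √γ Q] u ≈ [y; 0]` via economic QR — mathematically
identical to the closed form, numerically stabler, and the factorization
is reusable. `Q` is the identity, first-difference, or
second-difference lower-triangular Toeplitz operator; second differences
are the default (smooth solutions), first differences preserve sharper
transitions. Unregularized solves (γ = 0) are refused when the
estimated condition number exceeds 1e10, with the error naming the
remedy.

### Sequential scheme

Any input over `n` samples only influences outputs within the kernel's
contribution window, so long records are solved in blocks of
`n + n_overlap` samples: solve the block, accept the first `n` estimated
inputs, forward-convolve them and subtract their contribution from the
data still to be processed, advance by `n`. Equal-sized blocks share one
QR factorization (computed once, cached), so the per-block cost is two
triangular solves. Design choices in the open corners:

* The roughness penalty spans each block independently — the literal
  reading of the cycle. Consequence: mild artifacts at block
  boundaries, quantified by the sequential-vs-full consistency test
  (interior relative L2 difference ~1e-4 on noiseless instances, well
  under the 2% the tests require).
* The final partial block is solved whole and all its inputs are kept,
  with the last `n_overlap` samples *flagged* low-confidence rather
  than discarded, preserving length alignment with the record. The
  per-cycle residual is recorded over each cycle's accepted samples, so
  forward-convolving the accepted estimate and subtracting it from the
  original record reproduces the recorded residuals exactly
  (bookkeeping conservation, tested).
* A final block shorter than the difference stencil falls back to an
  identity penalty for that block (degenerate-corner guard).
* Default plan: `n = 780`, `n_overlap = 720` (1500-sample blocks at
  10 Hz), the block sizes used in the validation experiments this
  package reproduces; scale proportionally for other rates. The solver
  warns when `n_overlap` is smaller than the kernel contribution window.

## Dimension-reduction solver

Constraining `m` consecutive inputs to be equal writes `u = Lv` with `L`
the `N × n` block-indicator matrix (`n = N/m`, columns orthogonal with
squared norm `m`). The projected system `HLv ≈ y` is solved by pivoted
QR; columns of `HL` are sums of `m` neighboring columns of `H`, which
restores full column rank on delay-singular instances once `m` exceeds
the delay length and always improves conditioning (both properties are
tested by direct rank/condition computation). The lifted solution is
piecewise constant, so the production solver slides the window: for
each shift `k = 0..m−1` the data are shifted down by `k` (zeros enter at
the top — the system is at rest before time zero), solved, shifted
back up, and the `m` solutions averaged. This equals the explicit
averaged reconstruction map `M̄ = (1/m) Σ_k S_kᵀ M S_k`; the package also
assembles `M` and `M̄` densely for analysis, and the test suite checks
three-way agreement (explicit map, literal loop, production path) to
1e-10. The last kernel-support samples of each solve are flagged
low-confidence rather than silently dropped.

Singularity remedies when the transport delay makes `HL` rank deficient
(`m ≤ delay`):

1. `eliminate_delay` trims the leading zeros from the kernel and the
   same number of samples from the record — this removes the
   singularity without changing the solution (validated numerically
   against the vanishing-ridge limit to 1e-6, and exact to ~1e-11 in
   practice);
2. `dr_solve_regularized` adds `γ‖Qv‖²` to the projected problem, with
   `Q` built at the projected dimension `n` — the only dimensionally
   consistent placement.

When `m` does not divide the record length, the record is zero-padded to
the next multiple and the padded estimates trimmed before return.

## Simulator

The generator reproduces the validation design: a 28 ml chamber flushed
at 250 or 500 ml/min (washout time constant `τ_w = volume/flow`, i.e.
6.72 s and 3.36 s), a 1 s transport delay, 10 Hz sampling,
three-rectangular-pulse inputs at 0.1/0.2/0.5/1/2 Hz with duty 0.5, and
additive zero-mean Gaussian noise at 0.01/0.1/1/2/5/10% of the clean
record's peak (rms reference available; the percentage's reference
amplitude is a package choice). The kernel is a delayed first-order
(well-mixed chamber) washout discretized by exact per-bin integrals and
truncated at `delay + 8 τ_w`; measured kernels from a real rig can be
loaded through `discretize_impulse_response` instead. One master seed
fans out per-instance seeds via a seed sequence, so suites are
reproducible as a whole and per instance.

What the simulator does **not** emulate: analyzer drift and baseline
wander, non-Gaussian or correlated noise, kernel misestimation (the
solvers are handed the exact kernel that generated the data), multiple
gas channels, and the long mixed tails of measured impulse responses.
Passing the synthetic benchmark therefore demonstrates correctness of
the estimators under the stated model, not robustness to kernel error —
on real data the impulse response must be measured carefully, and the
recovered signal is only as good as that calibration.

Record lengths: the full preset is a one-hour virtual experiment
(36,000 samples); tests and the acceptance script use the reduced
10-minute preset (6,000 samples) and a tiny smoke preset (1,200), sizes
chosen so the whole validation runs comfortably on a laptop while still
exercising multi-block sequential solves.

## Tuning

Both methods expose one parameter: `γ` (Tikhonov) and `m` (window
width). Larger values suppress inverted noise at the cost of smearing
fast input changes; smaller values track fast dynamics but admit noise.
`sweep_gamma` and `sweep_m` score a grid by Pearson correlation against
a calibration pair with known input; on noiseless data the optimum sits
at the grid minimum, and it moves up with the noise level (tested).
Useful `m` values in practice fall roughly between 4 and 30; the
default grids span 1e-8…1e2 for `γ` and 1…32 for `m`. With
per-condition tuned parameters the two methods score within 0.05 mean
absolute Pearson-correlation difference of each other on the reduced
synthetic benchmark — the package's calibrated near-equality margin;
with coarse grids and high noise individual conditions can differ by a
few hundredths.

## Numerical choices

* Stacked/pivoted QR everywhere; no explicit inverses in production
  paths (dense inverses appear only in oracle assemblies).
* Numerical rank: pivoted-QR diagonal (or singular values in the dense
  oracle) thresholded at 1e-10 × the largest element.
* Dense operator realizations are capped at N = 20,000; beyond that
  only matrix-free application is offered — the sequential schemes
  exist precisely so that cap never binds.
* Factorization caches (8 entries each) keyed by kernel bytes, block
  size and regularizer make repeated benchmark solves cheap; they are
  transparent to results.
* Text outputs carry 9 significant digits; read-back tolerance for
  uniform sampling is 1e-6 relative on the median step.

## Known limitations

* Single-channel, time-invariant kernels only; no multi-gas coupling.
* The sequential penalty does not couple blocks; with very small `n`
  and strong regularization, boundary artifacts grow.
* No automatic parameter selection (discrepancy principle, L-curve,
  GCV); tuning is an explicit grid sweep against a calibration pair.
* The dimension-reduction estimate inside the first `m − 1` samples
  relies on the at-rest assumption; records that start mid-burst
  violate it.
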