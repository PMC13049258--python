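# Methods

This note documents the models, numerical choices, and known limitations of
the `sero` package: a simulation and reconstruction toolkit for
super-resolution diffusion–relaxation MRI based on **slice excitation with
random overlap (SERO)**.

## Signal model

The scalar model for a sub-voxel measured with repetition time TR (s) and
diffusion weighting b (ms/μm²) is the saturation-recovery cumulant
representation

    S = S0 · (1 − exp(−TR/T1)) · exp(−b·D + b²·V/2)

with baseline signal S0 (a.u.), longitudinal relaxation time T1 (s),
apparent diffusivity D (μm²/ms) and diffusional variance V (μm⁴/ms²).
A thick-slice shot measures the slice-profile-weighted sum of this model
over the k covered sub-voxels, each with its own local TR (the time since
that sub-voxel's previous excitation):

    S_shot = Σ_i W_i · (1 − exp(−TR_i/T1_i)) · exp(−b·D_i + b²·V_i/2) · S0_i

Only the most recent excitation is tracked (long-TR approximation); the
model hook in `sero.model` accepts alternative forward models with the same
signature, so an inversion-aware variant can be substituted without
touching the solver.

**First-excitation convention.** The magnetization is taken to be fully
relaxed at scan start: a sub-voxel's first excitation uses saturation
factor exactly 1 (TR = ∞), and first-coverage entries are excluded from all
TR statistics. This matches the steady-state-free start of a real scan and
keeps the TR quantiles well defined.

**Units.** Seconds for TR/T1, ms/μm² for b, μm²/ms for D, μm⁴/ms² for V.
All exponents are dimensionless by construction.

## Sampling schemes

All schemes live on a 1D grid of n = 50 sub-voxels of 1.5 mm (75 mm FOV)
with m = 1000 shots separated by 150 ms, b ∈ {0.1, 0.5, 0.9, 1.4} ms/μm²;
these defaults are the reference study conditions and are fully
configurable.

* **SERO** — each shot excites k contiguous sub-voxels starting at a
  uniform random index in {0, …, n−k}. A proposal is redrawn while the mean
  over its covered sub-voxels of the elapsed time since last excitation is
  below 1.5 s; never-excited sub-voxels contribute their elapsed time plus
  a 100 s surrogate so that early shots are never rejected. The redraw cap
  is 10 000 per shot, after which the configuration is declared infeasible.
  One seeded generator drives the scheme; per shot, position proposals are
  drawn first, then the b-value (uniform over the levels).
* **Slice shifting** — n_shifts = 4 contiguous blocks; block q tiles the
  grid with ⌊n/k⌋ slices starting at q + j·k, visited cyclically, so the
  FOV shift step is one sub-voxel (0/1.5/3.0/4.5 mm) and the within-block
  revisit interval is ⌊n/k⌋ × 150 ms = 1.8 s for k = 4. We derive the TR
  from the tiling under the matched-scan-time premise (1000 shots × 150 ms)
  rather than fixing it independently. The first two shots of each block
  are excluded from analysis (approach to steady state). Slices extending
  past the FOV are clipped from W. b-values cycle volume-by-volume.
* **Direct high-resolution** — k = 1, positions visited cyclically; the
  revisit interval is n × 150 ms = 7.5 s. b-values cycle volume-by-volume
  (five volumes per b-value at m = 1000).

The slice profile is perfectly rectangular (0/1 weights) by default; an
arbitrary per-slice profile vector is accepted for smoothed profiles.

## Estimation

Per through-slice column, the 4n parameters are estimated by

    x̂ = argmin_x ‖f(x, Θ) − S‖² + λ‖Δp‖²,   Θ = (W, TR, b)

subject to box bounds S0 ∈ [0,4] a.u. (normalized scale), D ∈ [0.3,4]
μm²/ms, V ∈ [0,4] μm⁴/ms², T1 ∈ [0.3,5] s, where Δp stacks the first
spatial differences of each parameter vector and λ = 0.01 by default. The
problem is solved with SciPy's trust-region reflective bound-constrained
least squares with an analytic Jacobian (finite differences available as a
fallback); tolerances default to 1e−8 and the iteration cap to 200.
Signals are first normalized by their global maximum; the fitted S0 is
mapped back to the data scale in the results object. A single scalar λ
multiplies the raw first differences of all four parameter vectors (S0 on
its normalized scale), with optional per-parameter weights defaulting to 1.
Ordinary (unweighted) least squares is used on magnitudes; no Rician
likelihood correction is applied.

**Initialization.** A fast local fit supplies the starting point: for each
position, all analysis-masked shots covering it are gathered, each assigned
its b-value and slice-averaged TR (mean over the covered sub-voxels'
defined TRs), with signals divided by the shot's W row sum to reach the
sub-voxel scale; the scalar model is then fitted within bounds. Positions
with fewer than 4 shots or fewer than 3 distinct b-values fall back to the
bound midpoints and are flagged. Start values are pulled 1% inside the
bounds so trust-region steps never begin on the boundary. The local fit is
a starting point, not an estimator: its slice-averaged-TR approximation
leaves percent-level biases that the full fit removes.

**Single-TR schemes.** With one distinct TR (direct sampling), T1 and S0
are jointly unidentifiable. Schemes whose defined TR spread is below 1 ms
are detected automatically; T1 is frozen at a nominal 1.0 s (configurable,
scalar or per-position) and excluded from the fit and from T1 metrics, with
S0 reported as apparent baseline. First-coverage measurements enter the
data term with saturation factor 1; an option excludes such shots entirely.

**Volumes.** Columns are fitted independently and concatenated; results do
not depend on the processing order. Background columns (all-zero signals)
are skipped.

## Noise

Zero-mean Gaussian noise of standard deviation σ = mean(S0)/SNR is added
independently to the real and imaginary channels of the zero-phase signal
and the magnitude is taken (Rician noise). The S0 mean is taken over the
declared object support (all positions for line phantoms, non-background
labels for volumes). SNR always refers to the isotropic high-resolution
voxel, so thick-slice shots retain their k-fold voxel-volume amplitude
advantage at equal σ, and the long-TR direct scheme benefits from fuller
relaxation — the trade-offs real acquisitions would see. Noise is applied
per shot to the summed thick-slice signal, with a fresh draw per shot and
realization.

## Phantoms

**Line phantoms** emulate piecewise-smooth through-plane profiles: the grid
is split into 2–8 plateaus with geometric lengths; each plateau draws
independent uniform values per parameter from configurable sub-ranges that
sit strictly inside the fit bounds (S0 0.2–3.8 a.u., D 0.4–3.8 μm²/ms,
V 0.05–3.8 μm⁴/ms², T1 0.4–4.8 s), so noiseless recovery is never
bound-limited; a 2-sub-voxel moving average softens a random half of the
edges. Per plateau, V is capped at D/b_max (b_max = 1.4 ms/μm²): without
the cap, independent draws frequently land in the regime V > D/b_max where
the cumulant representation is non-monotone and the synthetic signal
*grows* with diffusion weighting — physically impossible for tissue and
outside the representation's validity. The cap keeps every sub-voxel's
signal monotone-decaying over the sampled b-range (smoothing preserves the
constraint, which is linear in (D, V)). Set `b_max=None` to disable.

**Brain-like volume** — nested, smoothly deformed ellipsoids (background /
CSF shell / cortical ribbon / white-matter core) on a 1.5 mm grid, with a
user-editable per-tissue parameter table whose defaults are plausible
values declared as configuration, not ground truth. Letters are rasterized
from a built-in 5×7 block font into in-plane × through-slice masks and
perturb D and T1 multiplicatively; masks are kept for legibility scoring.
This procedural phantom provides geometry and contrast for qualitative
comparison only; it does not attempt cortical folding, partial-volume
mixtures, or any specific subject's anatomy.

What passing tests on these phantoms do **not** show: robustness to motion,
eddy currents, field inhomogeneity, imperfect slice profiles or flip
angles, anisotropic diffusion (a single scalar b is modelled), or spin
history beyond the most recent excitation — all effects present in real
acquisitions.

## Evaluation

Accuracy is RMSE = √(mean_i (x_i − x̂_i)²) per parameter, computed per
phantom and noise realization and averaged per study cell. Precision is
RMV: the across-realization sample variance (divisor R−1) at each voxel,
averaged over voxels and phantoms, then square-rooted. T1 cells are
reported as undefined for single-TR schemes.

The sweep runs, for each (method, k, λ, SNR) cell, P phantoms × R noise
realizations; the desk-scale default is P = 10, R = 5 (the full-scale study
of P = 50, R = 30 is one configuration field away — runtime scales
linearly, roughly 1 s per column fit). Noisy signals are shared across λ
values within a cell so regularized and unregularized fits see identical
data. All randomness descends from one base seed through named substreams
(`derive_seed(base, purpose, indices…)`), making every run bit-for-bit
reproducible.

The residual-based SNR diagnostic divides the mean fitted baseline
amplitude by a robust residual scale (1.4826 × MAD). It is a best-effort
surrogate (calibrated to ~30% on simulated data), not a noise measurement;
noiseless data report "not estimable" (∞).

Conditioning of the linearized inverse problem is summarized by the ratio
of extreme singular values (above a 1e−12 relative floor) of the
forward-model Jacobian at the true parameters, with T1 free and no
regularization; richer TR diversity yields a smaller ratio.

## Numerical choices and edge cases

* Trust-region reflective solver; non-convergence within the iteration cap
  returns the best iterate with a warning flag rather than raising.
* Analytic Jacobian blocks are assembled densely (≈1200 × 200 for the
  reference column); the first-difference penalty rows are appended with
  weight √λ.
* TR matrices store ∞ at first coverage and NaN where a shot does not cover
  a position; saturation factors are computed with masked arrays so no
  NaN/∞ arithmetic leaks into the objective.
* Scheme statistics pool only defined, non-first-coverage TR entries of
  analysis-masked shots; an empty pool (e.g. a single-cycle direct scan) is
  a degenerate-scheme error.
* CSV floats are read with round-trip precision so scheme files reproduce
  bit-identical matrices; derived W/TR matrices are validated against
  checksums stored at write time.

## Known limitations

* The slice-shifting revisit interval that falls out of matched scan time
  (⌊n/k⌋ × 150 ms = 1.8 s) is used as is; reported reference values quote
  1.9 s for this protocol, a ~5% TR difference that slightly changes its
  T1-weighting but not its qualitative behaviour.
* RMSE levels for V at low SNR depend strongly on the phantom's D
  distribution: plateaus with D ≳ 2.5 μm²/ms attenuate the b = 1.4 signal
  below the noise floor at SNR ≤ 5, making V estimator-noise-limited
  there. With the full-bounds phantom ranges used here, the V error in
  those cells is dominated by such plateaus.
* No Rician-likelihood fitting, no edge-preserving or spatially adaptive
  regularization, no diffusion-tensor generalization — the smoothness
  prior is the single global λ of the reference formulation.
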