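# sero — super-resolution diffusion–relaxation MRI by slice excitation with random overlap

`sero` is a simulation and reconstruction toolkit for **SERO** (slice
excitation with random overlap), an acquisition strategy for quantitative
diffusion MRI in which thick slices are excited at pseudo-random
through-slice positions. Because consecutive slices overlap randomly, each
sub-voxel's repetition time (TR) — the time since its previous excitation —
becomes a heterogeneous, emergent quantity. The resulting variable
T1-weighting, combined with per-shot diffusion weighting, carries enough
encoding diversity to estimate high-resolution parameter maps from
thick-slice data and to recover T1 at no extra scan time.

The package is aimed at MR physicists and methods researchers who want to
design such sampling schemes, simulate their performance under realistic
noise, and reconstruct parameter maps from simulated (or measured)
thick-slice magnitude signal stacks.

## The model

A sub-voxel measured with repetition time TR and diffusion weighting b
gives the saturation-recovery cumulant signal

```
S = S0 (1 − e^{−TR/T1}) e^{−bD + b²V/2}
```

with baseline signal S0 (a.u.), relaxation time T1 (s), apparent
diffusivity D (μm²/ms) and diffusional variance V (μm⁴/ms²). A thick-slice
shot observes the slice-profile-weighted sum over its k covered sub-voxels,
each with its own local TR:

```
S (m×1) ≈ [ W ⊙ (1 − exp(−TR ⊙ R1ᵀ)) ⊙ exp(−b Dᵀ + b⊙² Vᵀ/2) ] · S0
```

The high-resolution parameters of one through-slice column are recovered by
regularized bound-constrained nonlinear least squares

```
x̂ = argmin_x ‖f(x, Θ) − S‖² + λ‖Δp‖² ,   Θ = (W, TR, b)
```

where Δp stacks the first spatial differences of each parameter profile
(a smoothness prior, λ = 0.01 by default), solved with a trust-region
reflective method with analytic Jacobian, initialized by a fast slice-wise
local fit. See `docs/methods.md` for conventions, defaults and limitations.

## Worked example

Generate the reference SERO scheme (75 mm FOV at 1.5 mm resolution, k = 4,
1000 shots at 150 ms spacing), simulate a random piecewise-smooth phantom
column at SNR 10, and reconstruct it:

```sh
$ sero scheme --method sero --seed 7 --out scheme.csv
sero: m=1000 n=50 mean coverage 80.00/position; TR median 1.800 s (min 0.150, max 10.350)

$ sero simulate --scheme scheme.csv --phantom-seed 3 --snr 10 --seed 1 --out signals.csv
wrote 1000 signals to signals.csv (sigma=0.1579)

$ sero fit --signals signals.csv --scheme scheme.csv --lam 0.01 --out fit
Super-resolution column fit
===============================================
scheme: sero   shots used: 1000/1000   positions: 50
lambda: 0.01   normalization constant: 7.55547
converged: True (status 2, 11 evaluations)
residual norm: 6.4347e-01   penalty norm: 2.5787e-01
T1: estimated   fallback inits: 0
-----------------------------------------------
 param       mean        min        max
    s0     1.5015     0.3688     2.8783  [a.u.]
     d     2.2201     0.3927     3.8330  [um2/ms]
     v     1.2541     0.1720     1.9386  [um4/ms2]
    t1     1.6499     0.6204     3.3118  [s]
```

Line by line: the scheme's mean sampling density is 80 shots per
high-resolution position and its emergent TR distribution spans 0.15 s (one
shot spacing, from directly overlapping consecutive slices) to 10.35 s;
σ = 0.158 is the Rician noise scale giving SNR 10 relative to the phantom's
mean baseline; the fit converged in 11 Jacobian evaluations with no
fallback initializations, and all 50 estimates per parameter lie inside the
fit bounds. Comparing `fit/estimates.csv` against the simulated truth
(`signals.truth.csv`) gives RMSE S0 0.30 a.u., D 0.41 μm²/ms,
V 0.53 μm⁴/ms², T1 0.59 s for this column — and, because direct
high-resolution sampling has a single TR, the same fit on such data would
freeze T1 (it is unidentifiable there); T1 recovery is specific to the
variable-TR scheme.

The same machinery is available as a library:

```python
from sero import (SchemeConfig, generate_sero_scheme, generate_line_phantom,
                  LinePhantomConfig, predict_signal, add_rician_noise,
                  sigma_from_snr, SuperResolutionModel, FitConfig)

scheme = generate_sero_scheme(SchemeConfig(seed=7))
truth = generate_line_phantom(LinePhantomConfig(seed=3))
noisy = add_rician_noise(predict_signal(truth, scheme),
                         sigma_from_snr(truth, snr=10), seed=1)
res = SuperResolutionModel(noisy, scheme, FitConfig(lam=0.01)).fit()
print(res.summary())
```

`sero sweep` runs the full accuracy/precision study (RMSE and root mean
variance per method × SNR × λ) and `sero brain-demo` runs the qualitative
three-pipeline comparison on a procedural brain-like phantom with inscribed
letters.

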