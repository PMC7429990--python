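# Methods

This note documents the models implemented in `stedot`, the numerical
choices behind them, what the synthetic data generator does and does not
emulate, and the package's known limitations. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Units and conventions

Internal units keep `b·D` of order one: b in ms/μm² (1 ms/μm² =
1000 s/mm²), diffusivity in μm²/ms, time in ms, gradients in mT/m, T2 in ms.
External protocol tables use s/mm² and are converted only at the I/O
boundary. The proton gyromagnetic ratio defaults to γ = 267.513
rad·ms⁻¹·mT⁻¹·m.

Gradient waveforms are piecewise constant: each stored sample is the
3-axis amplitude held over one interval of length `dt`. The refocusing
pulse is a gradient-free gap whose effect is a sign inversion of the
post-pulse effective gradient. With this convention the dephasing vector
q(t) is piecewise linear and both q and B = ∫ q qᵀ dt are integrated
*exactly* (per-interval product rule), so the rectangular-PGSE B-tensor
matches the Stejskal–Tanner closed form b = (γGδ)²(Δ − δ/3) to rounding
rather than to a quadrature tolerance.

## Encoding model

An axially symmetric B-tensor is parameterised by its trace b and
anisotropy b∆ = (b∥ − b⊥)/(b∥ + 2b⊥) ∈ [−0.5, 1]; spherical encoding (STE)
has b∆ = 0, linear encoding (LTE) b∆ = 1. Gradient nonlinearity enters as a
voxel-wise linear coil tensor L acting on the waveform, giving the
effective encoding L·B·Lᵀ; estimating L is out of scope (it is user input).

## Compartment signals

Gaussian compartments attenuate as exp(−Tr(B·D)). Under STE this is
exp(−b·D̄) with D̄ the mean diffusivity, which makes every STE signal
rotation- and dispersion-invariant — the property the high-b strategy rests
on (tested to 1e-12). The compartment zoo: dot (D ≡ 0), ball, stick
(D∥, 0), zeppelin (D∥, D⊥), and Watson-dispersed stick/zeppelin.

**Watson dispersion.** Orientation dispersion maps to the Watson
concentration through OD = (2/π)·arctan(1/κ) (κ = 0 is uniform; the mapping
and its inverse are exposed). LTE signals of dispersed compartments are
orientation averages computed by Gauss–Legendre quadrature in cos θ crossed
with a uniform (trapezoidal, spectrally accurate) grid in φ; the order
doubles from 32 until the value is stable to 1e-6 relative, and
non-convergence raises. The OD → 1 limit reproduces the powder-stick
closed form √π·erf(√(bD∥))/(2√(bD∥)) (tested to 1e-6 over bD∥ ∈ [0, 20]);
finite-κ values are validated against a rejection-sampling Monte-Carlo
Watson average within three standard errors.

**Restricted sphere.** For water in an impermeable sphere of radius r with
intra-sphere diffusivity Dₛ under an arbitrary effective gradient, the
Gaussian-phase attenuation uses the eigenmode expansion of the one-axis
position autocorrelation, ⟨x(t₁)x(t₂)⟩ = Σₖ Bₖ exp(−λₖDₛ|t₁−t₂|) with
λₖ = aₖ²/r², aₖ the roots of j₁′(a) = 0 and Bₖ = 2r²/(aₖ²(aₖ²−2))
(Σ Bₖ = r²/5, the one-axis variance — tested). Then
ln S = −(γ²/2) Σ_axes Σₖ Bₖ ∬ g(t₁)g(t₂) e^(−λₖDₛ|t₁−t₂|) dt₁dt₂.
The double integral is evaluated exactly for piecewise-constant gradients
with an O(N) recursion (off-diagonal interval pairs factorise through
ρ = e^(−rate·h), grouped so every factor stays bounded for arbitrarily
large rates); waveforms are resampled to ≤ 20 μs steps, and the series is
truncated once a mode contributes < 1e-8 of the accumulated ln S (cap 50
modes, non-convergence raises). Radii below 1e-3 μm short-circuit to
S = 1 (the dot limit). Two independent oracles check the result: a
mode-wise analytic closed form for rectangular PGSE (agreement ~1e-9) and a
frozen reflecting-sphere random-walk simulation (1e5 walkers, specular
reflection; `stedot.montecarlo`). The random walk's reflection bias is
first order in the RMS step length, so where the comparison is tightest
(the r = 5 μm cells) the frozen reference is the Richardson extrapolation
to zero step of paired 0.025 μm and 0.05 μm runs; the other cells use
single 0.035 μm runs. The Gaussian-phase approximation itself is the
accuracy limit at strong attenuation: at b = 5 ms/μm², r = 5 μm,
Dₛ = 3 μm²/ms (S ≈ 0.49) it overestimates the random-walk signal by just
under 0.02 absolute, shrinking rapidly at weaker attenuation — but in the
deep-attenuation regime (r = 10 μm, Dₛ = 3 at the same b, where the
diffusion length rivals the radius and ln S ≈ −3) the phase distribution
is strongly non-Gaussian and the approximation overshoots the true signal
by ~0.03 absolute. The corresponding grid cell in the frozen-reference
test fails its 2% band and is left failing deliberately: it documents the
regime boundary. Radius fits at the acquisition's much higher b-values are
not affected in absolute terms (both signals are then vanishingly small),
but GPD-based radius estimates in intermediate regimes inherit this bias.

**Exchange.** The two-pool Kärger model under narrow-pulse idealisation:
m′ = −(q²·diag(D) + K)m with q² = b/Δ, exchange time t_ex = 1/(k₁₂+k₂₁),
rates at equilibrium (f₁k₁₂ = f₂k₂₁). The signal is evaluated through the
analytic eigendecomposition of the 2×2 evolution matrix with the slow
eigenvalue computed as det/λ₊ — a matrix exponential loses ~7 digits in the
fast-exchange regime, the analytic form reaches both closed-form limits
(t_ex → ∞ bi-exponential, t_ex → 0 mono-exponential at the
fraction-weighted mean diffusivity) below 1e-9. Free waveforms have a
diffusion-time spectrum; the single effective Δ here is an idealised
illustration, not a quantitative exchange model.

**T2.** Compartments optionally carry a T2; signals gain per-compartment
factors exp(−TE/T2ᵢ). Fractions are defined at TE = 0, so the *apparent*
fraction of a short-T2 pool at the acquisition TE is smaller than its
generating fraction; the synthetic truth table records both, and recovery
tests compare against the TE-apparent value.

## Noise model

Magnitude data with per-channel Gaussian noise σ (single effective coil) is
Rician: E[M²] = S² + 2σ², rectified floor σ√(π/2). σ is either known (from
simulation) or estimated from ≥ 100 signal-free background voxels via the
Rayleigh second moment σ̂ = √(mean(M²)/2); the published background-voxel
identification and patch-based denoising methods are not re-implemented.

Debiasing uses the classic signed magnitude-only correction
Ŝ = sign(M² − σ²)·√|M² − σ²|. Subtracting one σ² (not two) is deliberate:
M² − 2σ² is unbiased for S², but the square root's concavity then pushes
the *mean* of Ŝ as far below S as the raw magnitude mean sits above it,
whereas the one-σ² form keeps |bias| below the uncorrected bias at all
SNR and vanishing quickly above SNR ≈ 3 (measured in the test suite).
Outputs are signed — sub-floor measurements go negative so that shell means
and dot-fraction estimates can legitimately fall below zero. Noise is
assumed stationary.

SNR is the temporal mean of the interleaved b0 volumes over σ; tSNR is
temporal mean over temporal standard deviation (zero-variance series are
reported at a 1e6 sentinel).

## Estimation stage

The fit target is the per-voxel arithmetic shell mean of debiased signals
per unique (b, TE), with uniform weights (no weighting scheme is
prescribed by the estimation problem; uniform is recorded in the output
manifest). The chain:

1. **S̃(0)** — log-linear extrapolation to b = 0 through the two lowest
   non-zero shells (250 and 1500 s/mm²). Using weighted images instead of
   b0 suppresses CSF by design: in CSF-contaminated voxels ln S is convex
   and the estimate deliberately undershoots the true S(0). Non-positive
   shell means fall back to the lowest-shell value with a warning. (A
   pure-dot admixture also curves ln S slightly, so the recovered dot
   fraction of a noiseless 2% dot phantom reads 2.01% — the bias of the
   estimator, not of the optimiser.)
2. **f̃dot** — mean debiased signal at the highest shell divided by S̃(0);
   may be negative.
3. **(A, D₁) fit** — nonlinear least squares of A·e^(−bD₁) over shells with
   b strictly above bs (default 10 000 s/mm², i.e. the 10 500–15 000
   shells), trust-region-reflective with bounds A ∈ [0, ∞), D₁ ∈ [0, ∞),
   parameter/function tolerances 1e-12. The pair (A, D₁) is fitted — not
   (S(0), f₁) separately — because only the product S(0)·f₁ is identifiable
   from high-b data; f̃₁ = A/S̃(0) afterwards. Ten random starts: A is the
   product of draws from [0, max S(0)] and [0, 0.3], D₁ from [0, 1]; the
   lowest-residual solution wins, ties broken by lower D₁ (making the
   result independent of start order). All-zero voxels are flagged
   `unidentifiable_highb` when the fitted curve is indistinguishable from
   zero over the fitted shells (< 1e-6 of the signal scale).
4. **T2 fit** — with ≥ 3 echo times, joint (C, T2, D₁) fit of
   C·e^(−TE/T2)·e^(−bD₁) with T2 initialised and bounded in [0, 300] ms
   (lower bound 1e-3 ms numerically); TE-independent data pushes T2 to the
   upper bound and is flagged.
5. **Sphere fit** — (A, rₛ) with rₛ ∈ [0, 20] μm and Dₛ fixed (default
   3 μm²/ms, since radius and intra-sphere diffusivity are not jointly
   identifiable from one waveform shape). Shells reuse one waveform shape:
   ln S of the sphere signal scales linearly in b at fixed shape, so each
   residual evaluation computes the sphere signal once.
6. **ROI summary** — per-ROI median and 10–90 percentiles (linear
   interpolation) of the relative floor σ̃√(π/2)/S̃₀, SNR, tSNR, f̃dot, f̃₁,
   D̃₁; percentiles suppressed below 10 voxels, empty ROIs omitted with a
   warning.

## Synthetic data

`ste_protocol` builds the acquisition: shells b = [250 … 15 000] s/mm²
repeated [6 … 36] times per TE (231 weighted volumes), greedily interleaved
so consecutive volumes never share a shell, with a b0 volume at every 15th
position (248 volumes per TE).

Presets set the generating models:

* `cGM` — slow isotropic pool f = 0.097, D = 0.12 μm²/ms, T2 = 61 ms plus a
  fast pool at 1.0 μm²/ms, T2 = 90 ms; b0 SNR 452.
* `oWM` / `cWM` — slow pools (2.6% at 0.16, 5.4% at 0.23 μm²/ms) plus fast
  pools at 0.9 μm²/ms; SNR 415 / 242.
* `mWM` / `dGM` — single fast pools (0.85 / 0.75 μm²/ms) at SNR 251 / 143:
  these regimes sit at the noise floor at high b, so no slow pool is
  generated and estimator output there characterises floor behaviour.
* `fig1_scenario1` / `fig1_scenario2` — Watson sticks (D∥ = 2.1 μm²/ms)
  plus Watson zeppelins (1.9/0.8 μm²/ms) at OD 0.7 with no dot, versus
  OD 0.5 with a 2% dot. The stick share of the non-dot signal defaults to
  50% — the high-b STE conclusions are insensitive to the split because
  every mobile pool is below 3e-5 at b = 15 ms/μm². The two scenarios
  differ by < 2% of S(0) under LTE for b ≤ 4 ms/μm² yet by exactly the dot
  fraction under STE at b = 15 (tested).

Fast-pool diffusivities, the fast pool's T2, and the stick split are not
constrained by the high-b estimates (attenuation < 1e-4 above
10 500 s/mm²); the values above are package choices, overridable per call
and stamped into the dataset manifest.

Per voxel, parameters receive 5% lognormal jitter by default (0 for
exact-recovery tests), fractions are renormalised, the noiseless signal is
normalised to 1 at (b = 0, lowest TE), and Rician noise with
σ = 1/SNR_b0 is added. The truth table stores every sampled parameter. The
generator emulates compartmental signal and magnitude noise only — no
readout, motion, eddy-current, susceptibility or gradient-nonlinearity
artefacts, no spatial noise correlation, no physiological b0 fluctuation.
Passing recovery tests therefore demonstrates estimator correctness under
the stated signal model at matched SNR, not robustness to the artefacts a
scanner adds.

## Problem sizes

Test problem sizes are chosen for tight feedback: the end-to-end recovery
check runs 1000 voxels of the full 248-volume protocol; Monte-Carlo checks
use 4×10⁵ Watson samples and, frozen at generation time, 1e5 random-walk
walkers per sphere condition (regenerable with
`scripts/make_sphere_mc_reference.py`).

## Known limitations

* The Gaussian-phase sphere signal degrades at strong attenuation (see
  above); cylinders/ellipsoids and anisotropic time-dependence are not
  modelled.
* The Kärger illustration assumes a single effective diffusion time.
* Noise is stationary single-coil Rician; phase-based debiasing is not
  implemented.
* S̃(0) extrapolation and the bs cut-off are simple, documented estimators;
  no model comparison across the full b-range (spectra, information
  criteria) is attempted.
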