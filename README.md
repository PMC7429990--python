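# stedot

Detection and quantification of an isotropically-restricted ("dot-like")
water pool from spherical tensor encoding (STE) diffusion MRI at very high
b-values, with the forward simulations needed to interpret it.

## The problem

In diffusion MRI a *dot compartment* is a conjectured water pool — small
spherical spaces such as cell bodies — whose apparent diffusion coefficient
is zero in every direction and which exchanges with nothing. With
directional (linear tensor) encoding, a dot is hard to tell apart from
dispersed axons measured slightly off-axis. Isotropic (spherical tensor)
encoding removes the orientation confound: for ``n`` non-exchanging Gaussian
compartments the STE signal is

    S(b) = S(0) · Σᵢ fᵢ exp(−b · D̄ᵢ),

with ``D̄ᵢ = Tr(Dᵢ)/3`` the mean diffusivity of compartment ``i``. At
sufficiently high b every pool that is mobile along at least one axis is
crushed (at b = 8500 s/mm² a D = 0.8 μm²/ms pool retains 0.1% of its signal,
a D = 0.1 μm²/ms pool 42%), so the residual high-b signal isolates
near-immobile water. The package implements the resulting estimators:

* the dot-fraction upper limit ``f̃dot = S̃(b_max)/S̃(0)``;
* the relaxed representation ``S(b) ≈ A·exp(−b·D₁)`` for b above a cut-off
  ``bs`` (default 10 000 s/mm²), fitted by bounded multi-start least squares,
  with ``f̃₁ = A/S̃(0)``;
* a joint ``C·exp(−TE/T₂)·exp(−b·D₁)`` fit across echo times;
* a restricted-sphere alternative (Gaussian-phase signal of an impermeable
  sphere under the acquisition waveform) fitting the radius ``r_s`` with
  fixed intra-sphere diffusivity.

Around these sit the forward models used to reason about the measurement:
Gaussian compartments under arbitrary B-tensors, Watson-dispersed sticks and
zeppelins, two-pool exchange of the Kärger type, Rician magnitude noise with
floor ``σ√(π/2)`` and magnitude-only debiasing, and a synthetic-data
generator reproducing the in-vivo acquisition (11 STE shells from 250 to
15 000 s/mm², repetitions 6…36, interleaved b0 volumes, TE ∈ {88, 115, 140,
165} ms) and its per-region signal regimes.

The intended users are diffusion-MRI methods researchers: everything is a
plain Python API over numpy/scipy/pandas/nibabel, plus a small CLI.

## Worked example

```python
import stedot as st

# simulate a cerebellar-GM-like grid: two-pool model, slow isotropic pool
# f1 = 9.7% at D1 = 0.12 um^2/ms (T2 61 ms), b0 SNR 452
ds = st.run_simulation("cGM", grid_shape=(4, 4, 3), seed=42)

res = st.run_analysis(
    ds.volumes, ds.protocol, ds.roi_labels,
    st.PipelineConfig(sigma=ds.sigma, seed=1),
    roi_names={1: "cGM"},
)
row = res.roi_table.iloc[0]
print(f"f_dot = {row['fdot_pct_median']:.2f}%")
print(f"f1    = {row['f1_pct_median']:.2f}%")
print(f"D1    = {row['d1_median']:.3f} um^2/ms")
```

prints (medians over the 48 voxels):

```
f_dot = 1.11%
f1    = 6.48%
D1    = 0.120 um^2/ms
```

``D1`` recovers the generating 0.12 μm²/ms. ``f1`` is the *apparent*
fraction at TE = 88 ms: the slow pool's T2 (61 ms) is shorter than the fast
pool's (90 ms), so its share of the echo-time-attenuated signal drops from
9.7% at TE = 0 to ≈ 6.5% (the generating median here is 6.50%) — the truth
table records both (``ds.truth["f_slow_apparent_te88"]``). ``f_dot`` is the
upper-limit dot fraction: the still-decaying slow pool leaves
6.5% · e^(−15·0.12) ≈ 1.1% of the extrapolated S̃(0) at b = 15 000 s/mm².

The same pipeline runs from the shell, over NIfTI volumes plus a plain-text
protocol table:

```bash
stedot simulate cGM --grid 4,4,3 --seed 42 --out sim/
stedot analyse sim/volumes.nii sim/protocol.txt sim/roi_labels.nii \
    --sigma 0.0022124 --out out/
```

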