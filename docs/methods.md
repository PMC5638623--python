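# Methods

This note documents the model implemented by `gridforge`, the numerical
choices behind it, what the synthetic inputs do and do not emulate, and the
known limitations. It states no result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Model

A single output neuron receives N excitatory spike trains, each an
inhomogeneous Poisson process whose rate follows a spatial tuning curve
along the trajectory of a virtual rat. The output is again Poisson, with
instantaneous rate

    r_out(t) = r_0 + ∫₀^∞ dτ K(τ) Σ_i w_i S_i(t − τ),

where K is the spike-rate adaptation kernel

    K(t) = (1/τ_S) e^{−t/τ_S} − (μ/τ_L) e^{−t/τ_L},  t ≥ 0,

a band-pass filter with integral 1 − μ (negative for μ > 1) and resonance
near 1 Hz for the default parameters. There is no spike reset; adaptation
is entirely feed-forward. An alternative mechanism — after-spike
hyperpolarizing potentials fed back from the output train — is handled by
the equivalent kernel K_eq(ω) = K_in(ω)/(1 − K_out(ω)), which for
exponential in/out kernels is again a difference of two exponentials and
plugs into every downstream computation unchanged.

Plasticity combines a symmetric exponential STDP window
W(Δt) = W_tot/(2τ_W) e^{−|Δt|/τ_W} (applied to all pre/post spike pairs)
with a per-presynaptic-spike normalization Δw_i = η(β − αw_i), under the
hard constraint w_i ≥ 0. Averaging over spike statistics and over the
exploration statistics yields the drift

    η⁻¹ dw_i/dt = Σ_j C_ij w_j − a w_i + b,   w_i ≥ 0,
    a = r_av [α − ∫ W(s) K(−s) ds],   b = r_av (W_tot r_0 + β),

with the window–kernel overlap evaluated in closed form (each kernel
component A e^{−t/θ} contributes (W_tot/2τ_W)·A/(1/τ_W + 1/θ)). For smooth
constant-speed trajectories the input correlation reduces to a circle
average of the spatial cross-correlation of tuning curves, weighted by
K(τ) along circles of radius τv; for Gaussian tuning curves this has a
radial closed form involving the modified Bessel function I₀ and is a
Mexican hat: excitatory at short field separations, inhibitory at
intermediate ones.

On the periodic arena the linearized dynamics diagonalize in the Fourier
basis, giving the dispersion relation

    λ(k) = ρ W_tot (4π²/L²) G̃²(k) K̃_sp(k) − a,

with G̃(k) = (L² r_av/2π) e^{−(2πk)²σ²/2} and
K̃_sp(k) = Σ_c A_c [θ_c⁻² + (2πkv)²]^{−1/2}. All frequency arguments are
cycles per unit (m⁻¹ or s⁻¹); standard Fourier/Bessel transforms are
therefore evaluated at angular frequency 2πk. A positive maximum λ_max at
k_max > 0 is the Turing condition; the pattern forms on the time scale
τ_str = 1/(η λ_max). The k = 0 mode is governed by the normalization terms
instead: the mean weight relaxes to w_av∞ = b/(a − N C_av) with time
constant τ_av = 1/(η (a − N C_av)).

For spatially-irregular inputs (each neuron a normalized sum of M Gaussian
fields with centers uniform on the torus and amplitudes uniform in (0,1)),
the expected spectrum is the regular one attenuated by
Φ(M) = (π/3M)(4/π + 1/(3M)) ≈ 4/(3M) for k > 1/L, derived from the
Rayleigh-distributed resultant of M random phasors over the Irwin–Hall
total amplitude. Φ = 1 at k = 0, so the mean input rate is independent of
M. The closed form neglects the α–β covariance and is an approximation:
the package's Monte-Carlo estimator measures it ~23% below the formula at
M = 2, ~6% at M = 5, and at the few-percent level from M ≈ 10 on; tests
assert exactly this accuracy band, not exact agreement.

## Default parameters

The reference configuration (used throughout tests unless stated): τ_S =
0.1 s, τ_L = 0.16 s, μ = 1.06; σ = 6.25 cm, r_av = 0.4 s⁻¹; L = 1 m,
v = 0.25 m/s, σ_θ = 0.7 rad·s^−1/2, walk step 10 ms; N = 900 (ρ = 900
m⁻²); η = 2·10⁻⁵, τ_W = 0.05 s, W_tot = 1 s, α = 3.56, β = −8.78, r_0 =
10 s⁻¹, neural step 1 ms; weights initialized Normal(5·10⁻³, 10⁻⁴) for
spiking runs and Normal(5·10⁻³, 10⁻³) for averaged runs, clipped at 0. The
multi-field configuration uses N = 3600, M = 10, r_av = 0.8 s⁻¹, r_0 =
4 s⁻¹, η = 5·10⁻⁵, a = 2.5 s⁻¹, b = 2.8 s⁻¹. These values reproduce the
derived constants recomputed by `scripts/acceptance.py` and
`table2_derived()`.

## Numerical choices

**Correlation matrices.** The default construction ("modes") expands each
Gaussian-mixture tuning curve in the torus Fourier basis, where the
circle-averaged, K-weighted correlation becomes
C = B† diag(Ĝ²(k) K̃_sp(k) W_tot/L⁴) B with analytic coefficients; it is
exact (periodization included, no τ quadrature) and fast (BLAS matmul over
the ≲ a-few-thousand modes inside the Gaussian envelope, truncated where
the power envelope falls below ~1e−11 of its peak). The general
construction ("maps") grids the tuning curves, cross-correlates them by
FFT, and averages over circles of radius τv by periodic bilinear
interpolation at 256 angles with 400-node Gauss–Legendre τ quadrature; it
assumes nothing about the tuning shape and serves as the independent
cross-check (the two agree to <1% in tests).

**τ-quadrature horizon.** Wherever the kernel is integrated against slow
ring kernels (radial closed form, maps route), the horizon is 10× the
slowest kernel time constant. The kernel integral is a near-cancellation
of its two lobes (−0.06 against lobes of order 1), so truncating at the
5τ_L support used for spike-train convolution would bias the mean
correlation — and hence τ_av and w_av∞ — by ~10%. The I₀ factor is
evaluated in exponentially scaled form (i0e) for overflow safety; the sign
of its argument is immaterial because I₀ is even.

**Spiking integration.** The adaptation integral is two exact exponential
traces per synapse (one per kernel component); all-to-all STDP pairing
uses exponential pre/post traces, exact for the exponential window.
Input spikes are Bernoulli per 1-ms step (error O((r dt)²)), output spikes
a Poisson count after rectifying the rate at 0 (the linear rate can go
transiently negative; rectification is rare at the default r_0).
Each spike enters the kernel traces with weight e^{−dt/2θ} — its expected
age at the end-of-step rate evaluation is dt/2 — which removes an O(dt)
bias in the effective kernel integral that is material precisely because
that integral is a near-cancellation. Same-step (Δt = 0) pre/post pairs
are counted once. Per step, the Hebbian terms are applied first, then the
normalization at the post-Hebbian weight, then the clamp; the ordering is
irrelevant in the η → 0 limit.

**Averaged integration.** Projected forward Euler (step, then clamp at 0),
default dt = 50 s. A power-iteration estimate of the spectral radius
rejects steps with η·dt·|λ| > 1.5 (divergence occurs at 2); a runaway
guard aborts if any weight exceeds a configurable bound. The irregular
correlation matrix has a strongly damped uniform mode (λ ≈ −140 s⁻¹ at
N = 3600) whose sub-dt transient need not be resolved: it only sets the
normalization level, which is a fixed point of the scheme.

**Peak finding.** The dispersion relation is scanned on k ∈ [0.05, 20]
m⁻¹ in steps of 0.05 with parabolic refinement of the argmax; an argmax at
the lower grid edge is classified as the place-field regime (k_max = 0),
at the upper edge it raises. The kernel resonance is found the same way on
a 1 mHz grid.

**Gridness.** The autocorrelogram is the periodic Pearson autocorrelation
(torus-consistent, computed by FFT). For candidate outer radii R (24
values, linear between 0.7/k_max and 2.5/k_max, in metres), the annulus
(R/2, R) is correlated with itself rotated by 30°–150°, sampling rotated
positions by periodic bilinear interpolation about the zero-lag bin; the
score is max over R of ½[ρ(60)+ρ(120)] − ⅓[ρ(30)+ρ(90)+ρ(150)]. Taking
the max over radii inflates the score's spread on featureless maps (white
noise scores spread roughly ±0.5 around 0 rather than vanishing); the
triangular/square/noise calibration fixtures in `patterns.make_fixture`
quantify this. Grid scale is the argmax of the angularly averaged Fourier
amplitude in rings of width 1/L; orientation is the angle of the nearest
first-quadrant correlogram peak, reduced mod 60°; phase is the nearest
cross-correlogram peak against an ideal three-cosine reference grid at the
measured scale and orientation.

**Output rate maps.** Ψ_out = r_0 + K_sp ⊛ Σ_i w_i Ψ_i with the radial
kernel rasterized on the lag grid; the central bin takes the analytic
radial mass of the (integrable) 1/r singularity over a disc of the bin's
area rather than a pointwise value.

## What the synthetic inputs emulate — and what they do not

The generator reproduces the model's idealized world: circularly symmetric
Gaussian fields, exactly even (regular) or exactly uniform (irregular)
coverage, rates constant in time, periodic boundaries, and a random walk
with constant or OU-modulated speed. Real place and parasubicular fields
have irregular shapes, nonuniform coverage, rate remapping, theta
modulation, and walls rather than a torus; real exploration is anisotropic
and inhomogeneous. Passing tests therefore demonstrate the internal
consistency of the model and its analysis — spiking ↔ averaged ↔ spectral
↔ metrics — not that biological grids form this way. Border effects in
particular are absent by construction: grid orientation statistics here
reflect the torus geometry.

## Scale of the shipped experiments

The pattern-formation runs used in tests are sized for a desktop: the
regular-input run keeps the full published configuration (N = 900, L = 1,
η = 2·10⁻⁵, t = 10⁶ s — the averaged dynamics make this cheap) with 10
weight initializations; the multi-field run keeps N = 3600, M = 10 (the
instability threshold is density-dependent, near ρ ≈ 2000 m⁻² for M = 10,
so density cannot be reduced) and economizes with dt = 150 s, t = 3·10⁵ s
(≈ 33 τ_str), 3 input realizations, and 64-bin maps. Full-scale presets
(`fig5`, `fig7-*`, `fig9`) carry the published durations, resolutions, and
repeat counts and are run explicitly via the CLI, not by the test suite.
The spiking simulator is exercised over minutes of simulated time (drift
matching against the averaged dynamics at 4-SEM Monte-Carlo tolerance),
not over the 10⁶ s weight-development runs, which at 1 ms resolution are a
cluster-scale computation.

## Known limitations

* The circle-average correlation assumes trajectories straight over the
  kernel support; with the default heading diffusion the structured
  (non-mean) part of C carries percent-to-tens-of-percent error, visible
  when comparing spiking drift for strongly non-uniform weight vectors.
* The STDP window's low-pass effect on C is neglected (valid for
  τ_W ≪ σ/v; here 0.05 s vs 0.25 s).
* Φ(M) is a small-covariance approximation (see band above).
* Forward Euler with projection is first-order; dt trades accuracy of the
  transient (not of fixed points) for speed.
* Gridness depends on annulus discretization and interpolation; absolute
  scores are comparable within this package, not across toolboxes.
* The single-cell scope excludes recurrent interactions, border inputs,
  theta oscillations, and reset/refractory dynamics.
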