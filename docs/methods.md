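# Methods

This note records the models, numerical conventions and design choices
behind `interdigit`, in enough detail to reproduce or audit any number the
package computes.

## Interface models and their discretization

All four boundary-dynamics models are integrated with an explicit
(forward) Euler scheme on a uniform periodic 1-D lattice of N sites spaced
dx micrometres. Periodic boundaries avoid edge artifacts in spectra; the
choice is a package convention (experimental segments are finite, but all
spectral statements concern bulk modes well inside the fit window).

**Noise.** Space–time white noise of variance density D is discretized as an
independent Normal(0, D·dt/dx) increment per site per step — the standard
lattice regularization under which the continuum limit is recovered as
dx, dt → 0, and under which every Fourier mode of the Edwards–Wilkinson (EW)
chain is an exactly solvable discrete Ornstein–Uhlenbeck (OU) recursion.
The same-seed run is bit-reproducible; noise is drawn in chunks purely for
speed (the chunked stream is itself deterministic per seed).

**EW model.** h ← h + dt·d_h·Lap(h) + noise, with the three-point periodic
Laplacian. Mode k (eigenvalue λ_k = (2 − 2cos(2πk/N))/dx²) obeys
H ← (1−a)H + Ξ with a = dt·d_h·λ_k and E|Ξ|² = N·D·dt/dx, so the exact
stationary one-sided power in our normalization (below) is
4·D·dt/(dx·N·a·(2−a)); in the continuum limit this is 2D/(N·dx·d_h·λ_k) ∝
D/(d_h k²), hence the log-log slope −2 at steady state and the "upper
shift" equivalence of halving d_h and doubling D. The stability bound
dt ≤ dx²/(2·d_h) is enforced at call time. The inner stepping loop is
compiled with numba; the pre-drawn Gaussian chunk stream makes the kernel
purely deterministic.

**Stationary sampling.** Stationary ensembles are harvested from one chain:
burn-in of 10/(d_h·λ₁) (ten slowest-mode relaxation times), then snapshots
spaced 1/(d_h·λ₂) apart — the relaxation time of the slowest mode (k=2)
inside the default fit window, so fitted modes are effectively decorrelated
between snapshots. This is ~100× cheaper than independent chains and
samples the same stationary law.

**Turing model.** Two-species reaction–diffusion with Schnakenberg kinetics
f = α − u + u²v, g = β − u²v as the default (the activator–substrate
interaction is a modeling stand-in; any classic Turing pair gives the same
qualitative signature — a sharp spectral peak). Default α=0.1, β=0.9 with
d_u=1, d_v=40 satisfies the instability conditions analytically
(tr J = −0.2 < 0, det J = 1 > 0, d_v·f_u + d_u·g_v = 31 > 0, 31² > 4·d_u·d_v·det J).
Runs start at the homogeneous steady state (u\*, v\*) = (α+β, β/(α+β)²)
plus a Normal(0, 10⁻³) seeded perturbation. The oracle for the spectral
peak is the discrete dispersion relation: the largest real eigenvalue of
J − diag(d_u λ_k, d_v λ_k) per integer mode. Stable parameter sets are
rejected by default (`allow_stable=True` runs them with a warning; useful
for decay tests). The downstream coupling of u to the boundary height is
out of scope — the u-field spectrum itself is the compared quantity.

**Buckling model.** Linearized onset dynamics ∂h/∂t = −c·h_xx − d·h_xxxx
(c > 0: boundary elongation under compression; d: bending stiffness).
Discrete growth rate c·λ_k − d·λ_k², continuum argmax k\* = √(c/(2d)) with
peak rate c²/(4d). Biharmonic operator = Laplacian applied twice; stability
bound dt ≤ dx⁴/(8d). Deterministic; the generic initial condition is small
seeded Gaussian noise.

## Boundary quantification

**Standardization.** A polyline is translated so its first point is the
origin and rotated so the endpoint chord lies along +x. If the rotated
x-coordinates are not *strictly* increasing, the segment is not a
single-valued function of chord position and is rejected as overhung — a
deterministic automation of what is otherwise a manual curation step. The
height is linearly interpolated onto n uniform samples (default n = 128,
fixed across an ensemble so per-k averaging is well defined) and the chord
line is subtracted, pinning h(0) = h(L) = 0.

**Spectrum convention.** Since h(0) = h(L) = 0, dropping the duplicate
endpoint leaves one period of the segment's periodic extension; the DFT of
those n−1 mean-subtracted samples is normalized so that A·sin(2πk₀x/L) has
amplitude |ĥ(k₀)| = A, power A². k = 0 is excluded; wavenumbers are integer
cycles per segment, k = 1 … n/2 − 1. Parseval's identity then reads
Σ_k power(k)/2 = mean((h − h̄)²). No window function is applied: chord
detrending already removes the discontinuity of the periodic extension, and
the power-law fits exclude k = 1 (the mode most sensitive to detrending)
and the high-k interpolation tail via the default window k ∈ [2, n/8].

**Scaling fit.** Ordinary least squares of log₁₀ power on log₁₀ k, with a
t-based 95% confidence half-width on the slope. The signed slope is stored;
reports conventionally quote its magnitude (both conventions appear in the
literature), and output metadata says so.

**Ensembles** are unweighted per-k means over segments (segment lengths
vary; weighting by length is a defensible alternative but unweighted
matches the one-line-per-condition way such spectra are plotted).

**Group comparisons.** Two-sided Mann-Whitney; for combined n ≤ 12 the null
is enumerated exactly over all C(n, n₁) labelings (valid under ties, with
p = P(|U − n₁n₂/2| ≥ |u_obs − n₁n₂/2|), U counting a-over-b pairs with ½
for ties), otherwise the normal approximation with tie correction
(scipy). Kruskal-Wallis uses the chi-square approximation. All-identical
pooled samples are a degenerate-input error rather than p = 1.

## d_h estimation

Assuming each boundary point follows the EW equation, the frame-to-frame
displacement is Δh_i = d_h·Lap(h)_i·Δt + ξ_i with ξ zero-mean and
independent of the current profile. Averaging over many data points
eliminates ξ: the pooled least-squares estimator

    d̂_h = Σ_{segments, transitions, interior sites} Lap(h)·Δh
          / (Δt · Σ Lap(h)²)

is unbiased for data generated by the Euler rule at the frame interval, and
for finely-resolved dynamics sampled at interval Δt it carries an O(Δt)
*downward* discretization bias (each mode's mean displacement is
(1 − e^{−d_h λ Δt})·h, smaller in magnitude than d_h λ Δt·h) — which is why
coarsely sampled data underestimate d_h, a property the test suite checks
is monotone in Δt. The Laplacian uses central differences on interior sites
only (experimental segments are not periodic). Standard errors come from a
segment-level bootstrap (sites within a segment are correlated): 1000
resamples, SE = half the central 68.3% percentile interval. Negative
estimates are possible in the noise-dominated regime and are flagged, not
clipped.

The mechanical route d_h = (1/a − 1)·L_h·E/c′ (compression ratio a ∈ (0,1],
boundary thickness L_h, Young's modulus E, drag c′) is dimension-
transparent: the caller supplies consistent units and the result is linear
in L_h and E and decreasing in a, vanishing for an uncompressed boundary.

## Kymograph and puncta analysis

Axis spectra are per-line DFT amplitudes (each line mean-subtracted, so the
spectrum ignores constant offsets) averaged over the other axis, k = 1 up
to just below Nyquist. The cutoff wavenumber formalizes the by-eye rule
"low-k amplitudes are large, higher ones small": k_c is the largest k whose
amplitude still reaches a configurable fraction (default 0.5) of the
maximum, ties breaking to larger k. The smallest punctum unit is half the
cutoff wavelength in physical units,
(window_µm/window_px)·analysis_window_px/(2·k_c); for a 31.9 µm / 207 px
image analysed in a 50 px window with k_c = 4 this is 0.96 µm.

Puncta are counted at a constant absolute threshold with 8-connected
component labeling and a minimum area of 4 px (standard practice for
fluorescent blob counting; both knobs are explicit so counts are
reproducible). The count is monotone non-increasing in the minimum area on
any image, and in the threshold for scenes of unimodal blobs — on arbitrary
images a higher threshold can fragment one large component into several, so
the threshold-monotonicity property is only claimed (and tested) in the
blob regime the counter is meant for.

## Synthetic data: what it emulates, and what it does not

The generators provide every input the pipeline consumes, with ground truth:

* **Segments** draw h(x) from a named model (stationary state for
  white-noise/EW, growth endpoint for Turing/buckling, or a fixed profile),
  sample it at ridge-export point spacing (default 0.2 µm over 20 µm
  segments), embed it in the plane with a random rotation/translation, add
  isotropic Gaussian vertex jitter (default SD 0.02 µm, emulating ridge-
  detection localization noise), and splice a small full-circle loop into a
  chosen fraction of segments — the path direction sweeps 360°, so the
  x-coordinate reverses under any rotation and the segment is rejected by
  standardization with certainty, letting tests pin the rejection set
  exactly. Default EW conditions (d_h = 1, D = 0.2 on a 256-point model
  grid) give sub-micrometre interdigitation amplitudes on 20 µm segments —
  early-maturation-like boundaries. Turing/buckling segment defaults are
  rescaled (d_u=0.05, d_v=2; c=0.243, d=0.049) to place the pattern
  wavelength at a few micrometres on the same segments with tractable
  stability bounds.
* **Profile series** are EW trajectories sampled every Δt from independent
  stationary initial states. With the default `n_substeps=1` each frame is
  one Euler step at the frame interval — the generator *is* the
  discrete-time lattice model the estimator assumes, so recovery tests
  separate estimator correctness from discretization bias; `n_substeps > 1`
  emulates coarse temporal sampling of faster dynamics and drives the bias
  monotonicity test. With D = 0 the series is a deterministic sine
  relaxation with closed-form frame amplitudes.
* **Kymographs/scenes** render Gaussian puncta (σ = radius, default 0.3 µm)
  on a periodic line (or 2-D field), optionally random-walking per frame,
  with clipped additive Gaussian background. Periodic placement with an
  integer number of spacings per analysis window puts the spectral energy
  exactly at the design wavenumber, so the designed smallest-unit size
  (spacing/2) is recovered by the cutoff pipeline.

None of this emulates real microscopy artifacts — uneven illumination,
segmentation failures other than overhangs, correlated localization noise,
finite optical resolution, or boundary dynamics beyond the four models. A
passing suite therefore shows that the pipeline recovers known ground truth
under its own model assumptions, not that those assumptions hold for any
particular dataset; the experimentally reported exponent and d_h values
require the original imaging data and are deliberately out of scope.

## Numerical choices and problem sizes

* Reference EW spectrum runs use n = 256, dx = 1 µm, d_h = 1, D = 1,
  dt = 0.05 (10% of the stability bound), burn-in 10/(d_h λ₁) ≈ 1.7·10⁴
  time units, 100–200 snapshots spaced 1/(d_h λ₂); fit window k ∈ [2, 32].
  These sizes put the Monte-Carlo scatter of the fitted slope near ±0.03
  while keeping a run in seconds.
* Mann-Whitney switches from exact enumeration to the asymptotic path at
  combined n = 12 (1 000 labelings max — exactness where it matters, speed
  elsewhere).
* Tie-breaks: cutoff detection takes the largest qualifying k; the spectral
  argmax takes the lowest index on exact ties (numpy convention).
* Degenerate inputs raise typed errors rather than returning NaN: zero
  chord (tortuosity), flat profiles (d_h), all-zero spectra (cutoff),
  identical pooled samples (group comparison). The CLI downgrades the two
  that occur in legitimate workflows (straight boundaries, static scenes)
  to warnings with null fields.

## Known limitations

* The overhang rule (strict monotonicity after chord rotation) can reject
  segments whose jitter alone reverses a step at very coarse point spacing
  or very large jitter; with the default spacing/jitter ratio (10:1) the
  false-rejection probability is negligible.
* The d_h estimator assumes a common grid and uniform Δt across segments
  and does not estimate D jointly.
* `fit_scaling` reports OLS confidence intervals that treat per-k ensemble
  powers as independent; for strongly correlated snapshot sets the CI is
  optimistic (the tests use decorrelated snapshot spacing for this reason).
* The Turing simulator couples u to the observable only through the u-field
  spectrum; no boundary-height feedback is modeled.
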