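# Methods and design notes

This note records the models implemented in `megre`, the defaults and
why, and the limits of what the synthetic experiments can show.

## Timing model

Echo times follow from four gradient building blocks (all milliseconds):
preparation time `t_prep`, acquisition window `t_acq`, ramp time
`t_ramp`, and — for monopolar trains only — fly-back duration `t_fb`:

```
TE_n(monopolar) = t_prep + (2n−1)(t_acq/2 + t_ramp) + (n−1) t_fb
TE_n(bipolar)   = t_prep + (2n−1)(t_acq/2 + t_ramp)
```

so both schemes share TE₁ and differ in spacing by `t_fb`.  The
acquisition window is `n_x / BW` rounded **up** to a configurable raster
(default 0.01 ms, the usual scanner granularity).  Echo counting in a TE
range uses an inclusive boundary (`TE_n ≤ te_max`); this is the only
convention that reproduces all printed echo counts of the shipped
protocols simultaneously (32/64 at 97 ms and 14/27 at 43 ms for the
801 Hz/px protocol, and 21/31, 29/52, 31/59 for the 342/613/718 Hz/px
protocols).

Scanner protocol sheets print TE₁ and the two ΔTEs but not the timing
blocks themselves.  `timing_from_protocol` inverts the equations with the
convention `t_ramp = (ΔTE_bip − t_acq)/2`, `t_fb = ΔTE_mono − ΔTE_bip`,
`t_prep = TE₁ − t_acq/2 − t_ramp`; this is one consistent decomposition,
not necessarily the scanner's, but it round-trips exactly through the
schedule equations, which is all downstream code needs.  Note the shipped
342 Hz/px monopolar spacing is 4.48 ms (the value consistent with the
printed 21-echo count), and fly-back duration is a free timing field
rather than derived from gradient amplitude/slew limits, which are out of
scope.

## Signal and noise model

The spoiled-GRE signal is mono-exponential in TE with the steady-state
(Ernst) amplitude factor `E(α, TR, T1)`; phase terms (initial phase,
off-resonance) are carried in the complex signal but vanish in the
magnitude, which justifies magnitude-only fitting of the two parameters
(A, T2*) with A = M0·E.  Noise is circularly symmetric complex Gaussian
on a single effective channel with std σ per channel; magnitudes are then
Rician (Rayleigh in the background).  Multi-coil sum-of-squares
statistics, slice profiles, geometric distortion and phase errors are
deliberately not modelled.

Receiver bandwidth couples into the model twice: the acquisition window
(hence ΔTE and echo count) scales as 1/BW, and the noise std as
σ = σ₀·√(BW/BW₀).

Parity-dependent amplitude modulation — e.g. from the receiver frequency
response under alternating readout polarity — is modelled as one
multiplicative factor per parity class (g_odd, g_even), normalised to
geometric mean 1 because the common scale is absorbed into A and only the
ratio is identifiable from magnitude data.  A spatially varying
(exponential-in-column) form would refine this; the scalar-per-parity
model is the minimal version consistent with how the correction is
defined, and it is what the correction estimates.

## Noise-level calibration

Absolute simulation SNR is a free parameter of any digital-phantom study;
protocol sheets never print σ.  The package anchors it once:
σ₀ (at BW₀ = 801 Hz/px × 240 samples) is the unique noise level at which
the monopolar 32-echo, 97 ms-range train at α = 75°, TR = 1200 ms has a
Rician-CRLB T2* std of exactly 1.08 ms in the T2* = 69 ms / T1 = 878 ms
region.  Numerically σ₀ ≈ 0.0128 for M0 = 1, i.e. first-echo SNR ≈ 57 in
that region.  `crlb.calibrate_sigma` solves this by Brent root-finding
(the CRLB std is strictly increasing in σ; a Gaussian-limit linearisation
seeds the bracket; relative tolerance 1e−6).  All sweeps scale σ from
this anchor via the √BW law.

## Estimation

* **Background noise.** σ is estimated from ≥300-voxel noise-only corner
  rectangles using Rayleigh moments: the default is the second moment,
  σ = √(mean(M²)/2); the mean-based estimator σ = mean(M)/√(π/2) is
  provided as a cross-check.  σ is then treated as *known* during
  fitting, so the likelihood has two free parameters.
* **Likelihood.** The Rician negative log-likelihood is evaluated with
  exponentially scaled Bessel functions (`i0e`, `i1e`), keeping it finite
  and monotone up to per-echo SNR ~10⁴.  With σ = 0 (or on request) the
  fit degenerates to ordinary least squares; the two agree within 0.1% in
  T2* whenever every echo sits above SNR ≈ 20.
* **Optimisation.** L-BFGS-B on (A, T2*) with box constraints A ≥ 0,
  T2* ∈ [1, 1000] ms, analytic gradients, initialised from a log-linear
  regression on echoes above 2σ (fallback: half the TE span).  If the
  first run fails or lands on a T2* bound, the fit restarts from
  decay-scale guesses (T2* = span/4 and span) and keeps the best
  likelihood; convergence *on* a bound is flagged `converged = False`.
  Map-level fitting excludes background by a 5σ threshold and writes NaN
  sentinels outside the mask.
* **Low-SNR behaviour.** Below per-echo SNR ≈ 3 the likelihood becomes
  nearly flat in T2* for a few percent of realisations (the data are
  noise-like, and the MLE — invariant under the T2* ↔ R2*
  reparameterisation — may sit at the box bound).  The *median* fitted
  T2* remains nearly unbiased under the Rician likelihood while least
  squares overestimates it (the classic noise-floor bias); the *mean* over
  all voxels is dominated by boundary-clamped outliers for both
  estimators and is not a meaningful bias summary in that regime.  Tests
  therefore check the mean ordering at first-echo SNR 5 and the median
  ordering at SNR 3.
* **Amplitude-modulation correction.** Iteratively: fit (A, T2*) on all
  echoes → synthesise the fitted decay → per parity class, take the
  median measured/synthesised ratio (per voxel by default, pooled over
  the mask optionally) → normalise (g_odd, g_even) to geometric mean 1 →
  divide out; stop at max|g−1| < 1e−4 or 10 iterations.  The correction
  refuses constant-parity trains (monopolar, or bipolar subsampled at an
  even stride), where modulation is an unidentifiable uniform scale.

## Fisher information and CRLB

For the two-parameter model the Fisher matrix under Rician noise is
`I = Σ_n Z(ν_n/σ)/σ² ∇ν_n ∇ν_nᵀ`, where Z(s) is the per-observation
information factor relative to Gaussian noise,
`Z(s) = E[(m·I₁(ms)/I₀(ms) − s)²]` for m ~ Rice(s, 1).  Z is evaluated by
600-node Gauss–Legendre quadrature over m ∈ [0, s+12] (verified against a
brute-force Monte-Carlo second moment of the score); echoes above SNR 50
use the Gaussian value Z = 1 (configurable switch).  Z(0) = 0 — pure
noise carries no information about a vanishing signal — so a zero-signal
train raises a singularity error rather than returning a bound.  The CRLB
std of T2* is `√([I⁻¹]_{T2*,T2*})`.  Parameterisation is in T2*
(milliseconds); a delta-method Jacobian to R2* is provided as a utility.

## Digital phantom and synthetic data

The phantom mimics a spherical five-flask phantom spanning brain-tissue
relaxation times at 3 T: five circles of radius 0.11·m on a ring of
radius 0.25·m inside a disc of radius 0.40·m (m = min matrix dimension),
with four ≥300-voxel noise-only corner rectangles.  At the default
240×240 matrix each region holds ≈2190 voxels, enough for ~2% relative
precision on a sample std.  Exact centres and radii are a geometric
choice; only the (T2*, T1) pairs, region disjointness and background
corners are contractual.  Matrices below ~96×96 cannot host the corners
outside the disc and are rejected.

Subsampling is retrospective on stored stacks (as with acquired data):
`select_first_n` shrinks the TE range at fixed ΔTE; `select_every_nth`
multiplies ΔTE at fixed TE range and preserves source parities, so an
even stride on a bipolar train deliberately yields a constant-parity
train.

What the simulations do **not** emulate: partial-volume mixing at region
borders, spatially varying noise fields, coil combination, parallel
imaging (g-factor) noise amplification, eddy-current phase errors, or
geometric distortion.  Passing tests therefore demonstrate estimator and
bound correctness under the stated model, not robustness to those
experimental effects.

## Experiment scale and reproducibility

ROI statistics are computed across the voxels of a single realisation,
matching how a measured T2* map is summarised; every sweep cell records
its derived seed and regenerates bit-identically.  Problem sizes are
chosen for desk-scale runs: sweeps default to the 240×240 phantom with
fitting restricted to the requested ROIs; the unit-test suite uses a
96×96 phantom (~350 voxels per region) and the end-to-end checks use the
full ROI-3 (~2200 voxels) or equivalent Monte-Carlo batches, where the
sample std carries ≈1.5–2% relative sampling error — assertions on
stochastic quantities state their Monte-Carlo tolerance explicitly
(2σ of the relevant sampling distribution).

## Known limitations

* σ is assumed spatially uniform and known after background estimation;
  spatially varying noise would bias both fits and bounds.
* The amplitude-modulation model is scalar per parity class per voxel;
  the spatial structure of receiver-response modulation along the
  readout axis is not estimated.
* The CRLB uses the true simulation σ; fitting uses estimated σ when run
  through the CLI (`--sigma auto`), so predicted and measured precision
  can differ by the (small) σ-estimation error.
* No complex-valued fitting, field mapping, or multi-compartment decay.
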