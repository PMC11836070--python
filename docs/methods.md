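# Methods

## Swimming model

A multi-flagellated swimmer is reduced to two rigid bodies moving along a
common axis at zero Reynolds number: an effective helical bundle and a
counter-rotating cell body. Three linear equations determine the kinematics
— axial force balance, axial torque balance, and a kinematic constraint that
the rotation rate of the bundle relative to the body (the motor speed) is a
constant ω_m:

    (A + A0_eff)·v = B·ω
    C·ω − B·v      = C0_eff·Ω
    ω + Ω          = 2π·f_m      (angular units internally; Hz reported)

The system is solved densely (`numpy.linalg.solve`) in double precision and
residuals are verified against a 1e-10 relative tolerance; an independent
closed-form elimination serves as the test oracle.

Assumptions worth keeping in mind:

* The N filaments form one rigid effective helix. Thickness grows as
  a·N^0.5 (area-conserving close packing; the exponent is configurable) and
  axial length follows the empirical length-vs-number coupling. Filament
  flexibility, bundling dynamics and inter-filament solid friction are
  neglected; the rigid-helix picture is better for bundles than for a
  single filament.
* The motor speed is constant (default 220 Hz), independent of load and of
  N. No torque–speed curve is modelled.
* The body is a prolate spheroid of fixed size (default 3.0 × 0.9 µm) with
  exact Perrin drag coefficients; the sphere limit is handled analytically
  below eccentricity 1e-5. Wobble enters only through the drag projections
  A0_eff(θ) = A0_par·cos²θ + A0_perp·sin²θ (and likewise C0_eff); θ is an
  input per cell, not predicted from hook mechanics.
* Friction-coefficient variants: Gray–Hancock
  ξ∥ = 2πμ/(ln(2P/a) − ½), ξ⊥ = 4πμ/(ln(2P/a) + ½) and Lighthill
  ξ∥ = 2πμ/ln(0.18P/(a cosψ)), ξ⊥ = 4πμ/(ln(0.18P/(a cosψ)) + ½). Inputs
  thick enough to leave the slender-body ordering 0 < ξ∥ < ξ⊥ ≤ 2ξ∥ raise an
  explicit error. Absolute speeds differ between variants; N=1-normalized
  curves agree within 15%, which is the robustness property the tests pin.

Default geometry (all configurable): helix radius 0.2 µm, pitch 2.2 µm,
filament radius 0.010 µm, left-handed; viscosity 1e-3 Pa·s. The default
length coupling L(N) = 10·N/(2.5 + N) µm gives ~2.9 µm for one filament
rising to 8 µm at N = 10. Units are chosen so no conversion constants
appear: lengths in µm and viscosity in Pa·s make forces come out in pN and
torques in pN·µm directly.

The saturation mechanism is testable in isolation: with body drag sent to
zero, v/ω = B/A is independent of N at fixed filament length, so each added
filament raises thrust and drag in the same proportion.

## Population ensembles, couplings, calibration

Ensembles draw body length and width from lognormal distributions
(mean 3.0 µm, CV 0.15; mean 0.9 µm, CV 0.10) and the wobble angle uniformly
on [0°, 40°], with rejection of draws violating the body invariants; 5000
cells by default, fully determined by one seed. The upper wobble bound
reflects that realistic wobble angles exceed what a hook-free model
predicts.

The expression couplings are deliberately empirical: mean flagellar number
is linear in reporter activity, mean filament length saturates as
L_max·E/(K + E). Fitting uses ordinary least squares for the line and
bounded `curve_fit` for the saturating curve; when the saturating fit
cannot beat a straight line (no curvature, e.g. constant length) or demands
a half-saturation far beyond the data range, the length model degrades to
linear and is flagged. Expression-to-count conversion rounds to integers
with a floor at zero; a mean-field (non-integer) mode serves curve
plotting.

Calibration against an observed (N, v) curve is a single multiplicative
velocity scale with the closed form s = Σv_obs·v_pred / Σv_pred², the least
structural one-parameter adjustment available.

## DDM

The image structure function D(q,τ) = ⟨|FT[I(t+τ)] − FT[I(t)]|²⟩_t is
computed from half-plane FFTs (conjugate-symmetry weights), averaged over up
to 100 evenly spaced start frames per lag, with log-spaced integer lags
(~30 per decade) up to half the stack. Radial averaging uses annular bins
two FFT pixels wide by default: pooling more Fourier modes per bin
suppresses the speckle noise that otherwise biases the downstream nonlinear
fits, at the cost of a negligible within-bin spread of decay rates
(single-pixel bins remain available).

Fitting is per-q, deterministic, over the default window 0.4–2.0 µm⁻¹,
with three safeguards that experience with the estimator showed to matter:

1. **Plateau anchoring.** The long-lag limit of D equals twice the mean
   spectral power 2⟨|F(q)|²⟩, which the full record estimates far more
   precisely than the few independent long-lag couples. A + B is therefore
   fixed to that value and only B is fitted. (A static background inflates
   ⟨|F|²⟩ without contributing to D; remove it with mean subtraction before
   anchoring.) Freeing the plateau instead produces a noise-induced
   downward bias of the fitted diffusivity of several percent at desk-scale
   movie lengths, growing as records shorten.
2. **Nested model selection.** A diffusion-only model (B, D) is fitted
   first; the swimmer component is accepted only if the mixed model cuts
   the residual sum of squares below 0.8 of the diffusion-only fit *and*
   the fitted swimmer phase q·v̄·τ_max reaches at least π. Without the
   phase condition, a degenerate "swimmer" with α → 1 and v̄ below ~1 µm/s
   imitates a slow second relaxation in noise; such speeds are genuinely
   unidentifiable when no sinc oscillation falls inside the lag range, and
   so is any swimmer slower than ~π/(q_max·τ_max) — a documented detection
   floor of the method, not of the physics.
3. **Bin screening.** Aggregated α, v̄, Z, D are medians over q bins whose
   fitted dynamics decorrelate within the lag range (fitted ISF below 0.5
   at τ_max) and whose dynamic amplitude reaches the noise floor (A ≥ B);
   v̄ and Z aggregate only over bins where the swimmer component was
   accepted. Fallbacks keep the estimate defined when fewer than three
   bins survive a screen.

Initialization is deterministic: B from the smallest-lag value, D from a
fixed logarithmic grid prefit, α = 0.5, Z = 2, v̄ from the lag at which the
normalized signal first reaches one half (q·v̄·τ ≈ 2). Bounds: α ∈ [0,1],
v̄ ∈ [0,200] µm/s, Z ∈ [0.5,50] (boundary hits flagged), D ∈ [1e-4,20]
µm²/s. Identical inputs give bitwise-identical estimates.

The closed-form Schulz swimmer ISF,
f_s = (Z+1)/(Z q v̄ τ)·sin(Z arctan λ)/(1+λ²)^{Z/2} with λ = q v̄ τ/(Z+1),
equals the Schulz (Gamma(Z+1, v̄/(Z+1))) speed average of sinc(qvτ); below
q v̄ τ = 1e-4 the second-order series 1 − (qv̄τ)²(Z+2)/(6(Z+1)) avoids
cancellation. The tests verify it against adaptive quadrature of the
defining integral.

## Flicker spectroscopy

Rotation frequencies are read from intensity traces by Welch-averaged,
linearly detrended, Hann-windowed periodograms (segment length 1024, 50%
overlap; resolution = rate/segment). In each band — body 5–40 Hz, flagellar
50–350 Hz, closed intervals, both checked against Nyquist and for
disjointness — the highest local maximum exceeding five times the median
in-band power is reported; absence of such a peak yields an explicit
missing value, and the motor frequency (body + flagellar) is reported only
when both peaks exist. This periodogram readout reproduces the observable
contract of dark-field flicker microscopy (two rotation peaks whose sum is
the motor speed) without modelling the scattering anisotropy of the imaged
cell.

## Synthetic data

Every generator is a pure function of (params, seed) and attaches a ground
truth sufficient to regenerate the dataset bit-exactly.

* **Movies** (default 1000 frames, 256×256 px, 100 fps, 0.7 µm/px, 300
  particles): a fraction α of particles swims ballistically at per-particle
  Schulz speeds along fixed 3-D isotropic headings rendered in-plane; all
  particles carry Brownian jitter with diffusivity D. The 3-D headings are
  what make the in-plane ISF the speed-projected sinc form the Schulz
  swimmer model assumes; purely 2-D headings would give a Bessel ISF
  instead. Particles are Gaussian spots (σ = 2 px) on a periodic box with
  additive Gaussian read noise (σ = 0.05 against unit spot amplitude);
  trajectories are stored unwrapped so MSD oracles work. Run–tumble motion
  is off by default (optional rate parameter); phase-contrast ring
  artifacts, depth of field and photobleaching are not emulated — DDM
  operates on intensity differences and is agnostic to PSF shape, so
  passing recovery tests here validates the estimator, not robustness to
  every optical artifact of real movies.
* **Traces** (default 800 Hz, 10 s): two random-phase sinusoids (body and
  flagellar tones) plus Gaussian noise; Nyquist violations are errors.
* **Flagellation tables**: per-cell counts around the linear mean and
  lengths around the saturating mean. With noise, counts are rounded
  non-negative integers; at zero noise the exact (unrounded) means are
  emitted so the generating parameters are exactly recoverable.

## Problem sizes and determinism

Test and acceptance runs use desk-scale sizes chosen to exercise every code
path at meaningful statistical power: 1000-frame 256×256 movies (the
acquisition geometry of the emulated experiment, shortened from 10,000
frames), 5000-cell ensembles for population curves, 8000-sample traces.
All randomness flows through explicit integer seeds
(`numpy.random.default_rng`); fits contain no stochastic steps, so every
estimate is reproducible bitwise.

## Known limitations

* Absolute model speeds depend on the friction-coefficient variant;
  only normalized trends are variant-robust.
* The DDM swimmer term multiplies the diffusive factor (swimmers diffuse
  too); treating swimmer diffusivity separately is not supported.
* Swimmers slower than the identifiability floor π/(q_max·τ_max) fold into
  the diffusive population by design.
* The wobble-angle distribution and the bundle-thickening exponent are
  phenomenological inputs, not predictions.
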