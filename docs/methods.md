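# Methods

This note documents the model, the numerical choices, and the limits of what
the test suite shows.  Notation follows the README: contour Φ(t, θ) with
normalized arc-length coordinate θ ∈ [0, 2π), normal speed
f = f_prot + f_APCSF + f_AAF.

## Contour representation

Segmented outlines (ordered planar point lists, μm) are smoothed by two
independent periodic Gaussian process regressions, one per coordinate, with
the Poisson-kernel covariance

    k_r(θ, θ′) = (1 − r²) / (1 − 2r cos(θ − θ′) + r²),  0 ≤ r < 1,

plus observation noise σ_noise² on the diagonal (and a fixed 1e-10 jitter for
conditioning; results are insensitive to the jitter at the default
σ_noise = 0.05).  In Fourier terms the kernel weights mode m like r^|m|, so
r_cont sets the rigidity of the curve.  Sample locations on the circle are
assigned by normalized cumulative chord length of the input polygon — the
natural estimator of the arc-length coordinate for raw segmentation points.
Inputs are orientation-normalized to counter-clockwise, so outward normals
are the tangent rotated by −90° and convex segments have positive curvature.

The fitted curve is re-parametrized by true arc length through a dense
trapezoidal table (default 512 points; the periodic trapezoidal rule is
spectrally accurate for smooth curves, and the table's linear interpolation
error is the resolution limit of downstream evaluation).  N virtual markers
are placed equidistantly; N and the table size are resolution knobs with
convergence tests, since no canonical marker count exists.  Arc length, area
(line-integral/shoelace form) and the arc-length–weighted centroid are
computed by quadrature on the dense table; curvature and normals come from
analytic kernel derivatives, which keeps them exact in the internal
parameter.

Self-intersections of the marker polygon are detected by a segment-pair
sweep and reported as warnings, never as errors: the stochastic model
tolerates transient crossings and the curvature flow removes them.

## Retraction flows

APCSF: f = −(κ − 2π/L) per unit weight.  Because a simple closed curve has
∮κ ds = 2π, the discrete area flux vanishes and the flow shortens arc length
at (numerically) constant area; its fixed points are circles.  AAF:
f = −((A − A_ref)/(A_ref·L))·⟨Φ − Φ_CM, n⟩, a pure scaling about the
centroid when used alone, hence shape-preserving, driving A → A_ref.

Propagation is explicit Euler along the outward normal followed by a GPR
re-fit, which acts as the smoother of the two-step scheme; markers are
re-distributed equidistantly after every re-fit.  The tolerance for
"unchanged" comparisons after a re-fit is σ_noise·√2.  The single-flow
driver (`evolve_pure_flow`) adds a CFL-like guard — sub-stepping whenever
max|f|·dt exceeds a quarter of the marker spacing — because the bare
curvature flow is stiff at high resolution.  The full simulator does not
sub-step: at the reference weights (w_APCSF = 0.1 μm²/s, dt = 0.5 s) the
GPR re-fit damps the high-frequency modes faster than the explicit step can
amplify them, and sub-stepping would alter the two-step update scheme itself.

The area functional of a self-intersecting contour is the raw shoelace
value; no signed-area semantics beyond that are attempted.

## Protrusion process

Events (tᵢ, θᵢ) follow a spatio-temporal Hawkes process with background
μ(θ) = λ₀ × wrapped-Cauchy(θ; π, r_pol) (the normalized Poisson kernel
integrates to the wrapped-Cauchy density) and product triggering kernel
g₁(t)·g₂(θ), g₁ = αβ t e^(−βt), g₂ = von Mises(0, κ_M).  Sampling uses the
exact cluster construction: Poisson(λ₀T) ancestors uniform in time with
wrapped-Cauchy angles, each event spawning Poisson(α/β) offspring displaced
by Gamma(2, 1/β) in time and von Mises(0, κ_M) in angle *relative to its
parent* (the kernel in the intensity is stationary, centered on each event).
Subcriticality α/β < 1 is enforced before sampling.  The process is realized
once for the whole horizon — valid because the polarization is fixed in
time — and the simulator's single RNG stream is consumed by this sampler
only, giving bit-reproducible tracks.

Started empty at t = 0, the realized event rate needs a few cluster
lifetimes to reach its stationary value λ₀/(1 − α/β); an optional
`stationary=True` mode roots ancestors in a burn-in window before t = 0 so
that count statistics on [0, T) are stationary.  The simulator itself uses
the empty start (the transient is part of the modeled track).  Field
evaluations truncate the temporal kernel at 60/β seconds, below double
precision of g₁.

The protrusion field is X_prot = c_s(λ − μ)/VMDR, evaluated at each
marker's current coordinate with its current VMDR row.  Under the reference
parameters the stationary pointwise standard deviation of c_s(λ − μ) is
≈ 0.8 (a Campbell-formula calculation for an uncorrelated stream of the
same rate gives 0.42; self-excitation roughly doubles the variance), a fact
that matters for weight inference (below).

An Ornstein-Uhlenbeck field (`ou_protrusion_field`) is provided behind the
same (time × marker) grid contract as a non-canonical alternative: spatially
correlated Gaussian noise relaxing to a positive mean and clipped at zero.
Its parameters are provisional and documented as such; the Hawkes field is
the canonical driver.

## Marker mapping

The regularized mapping between consecutive contours minimizes
F + λ_reg·U, where F is the mean squared marker-trajectory length per dt²
(μm²/s²) and U = N·Σ gapᵢ² penalizes uneven spacing of the mapped markers.
Monotonicity is structural, not penalized: the target coordinates are an
unconstrained offset plus strictly positive gaps obtained from a softmax,
normalized to wind exactly 2π, so topological mapping violations cannot
occur by construction.  Optimization is deterministic L-BFGS-B with analytic
gradients (gradient norm 1e-8, ≤ 500 iterations) from the nearest-point
initialization (or a warm start from the previous frame inside loops);
target positions are linearly interpolated on the receiving contour's dense
arc-length grid.  λ_reg defaults to 10 μm²/s², the upper end of the stable
medium-regularization range; λ_reg = 0 reproduces nearest-point projection
and λ_reg ≫ 1 enforces equidistant markers.  All angular differences are
wrapped into (−π, π].

## Forward simulation

Each step: evaluate geometry and X_prot at the current markers, assemble f,
move markers by f·dt along the normals, re-fit the contour, remap the
markers with the regularized flow, update the VMDR row.  The initial contour
is a circle of area A_ref with θ = 0 at the rightmost point.  A track
aborts if the area falls below 5% of A_ref.  The GPR is re-fitted every
step (the re-fit frequency is not canonical; every step is the conservative
choice and is logged in the track manifest).

Reference parameter set (used throughout the tests):
r_cont = 0.6, σ_noise = 0.05, λ_reg = 10 μm²/s², A_ref = 80 μm²,
λ₀ = 1 s⁻¹, α = 0.4 s⁻¹, β = 0.5 s⁻¹, κ_M = 100, r_pol ∈ {0, 0.5},
w_prot = 7.5 μm²/s, w_APCSF = 0.1 μm²/s, w_AAF = 1 μm/s, dt = 0.5 s.

Problem sizes: simulations in the test suite and the acceptance script use
N = 100 markers with a 384-point dense table; centroid speed and long-run
diffusion were checked to be insensitive to N over 100–400 (< 1% change),
so the smaller grid is used for ensembles.  The library default stays
N = 200.

## Track statistics

The ensemble MSD at absolute lags from t = 0 is the default (it matches the
published root-mean-squared-displacement convention); `time_average=True`
additionally averages over start points within tracks — the statistically
efficient estimator used for parameter recovery, where the absolute-lag
estimator's persistence-time scatter at 50 tracks (±50%) would swamp the
signal.  The diffusion fit divides the linear MSD slope by 2n = 4; its
default window is the upper half of available lags and is a logged
parameter (both window choices remain caller-selectable, since short-window
and long-window fits answer different questions for persistent walks).  The
persistent-random-walk fit MSD = 2nD(t − P(1 − e^(−t/P))) uses bounded
nonlinear least squares, initialized from the terminal slope and intercept,
with residuals weighted relative to the curve value because the MSD's
sampling error scales with the MSD itself; it is exact on noise-free curves
generated by the formula.

## Inference

Given fitted contours and the marker chain, the local motion is the normal
projection of per-step marker displacement over dt.  A_ref is the 1st
percentile (linear interpolation) of the area series.  The weights of the
two deterministic flows are estimated by asymmetric (expectile-type) least
squares over the whole kymograph grid: residuals where the flows fail to
capture a retraction (implied f_prot < 0) carry weight 1, positive residuals
carry weight τ = 1e-3.  Rationale: the protrusion component is non-negative
and vanishes between protrusion events, so the weighted flow sum is the
*lower envelope* of the local motion, attained on a set of positive measure;
the asymmetric loss is a convex, noise-robust relaxation of that envelope
constraint and recovers the generating weights to within ~10% on simulated
tracks.  (A plain non-negative least squares against min(f, 0) was evaluated
and rejected: fitting zero on protruding nodes, where the AAF regressor is
non-zero, biases both weights down by 50–85%.)  The problem is solved by
iteratively reweighted NNLS, which is deterministic.

The initial protrusion component is the local motion minus the weighted
flows; it is then refined per frame by pulling each marker propagated under
the total speed onto the receiving contour, measuring point-to-curve
distance (nearest point on the fitted next contour) along the marker normal
— the residuals decouple across markers, so this solves the least-squares
refinement exactly and marker-wise.  Frames where the correction diverges
keep the initial estimate and are flagged.  The decomposition
f = f_prot + f_APCSF + f_AAF holds exactly on the reported kymographs.

w_prot is set after refinement so the implied process X_prot = f_prot·L /
w_prot has unit sample variance.  This is a reporting convention, not an
estimator of the generating weight: on simulated tracks the estimate equals
w_prot·std(X_prot_true), and since the reference non-polarized parameters
give std(X_prot) ≈ 0.75 (≈ 0.9 polarized), the recovered w_prot sits
correspondingly below the generating 7.5 μm²/s.  The goodness of fit is the
non-negative fraction of the |f_prot| mass; a track is classified fan-shaped
when the estimated APCSF weight falls below 0.005 μm²/s (an order of
magnitude below typical amoeboid estimates; ties go to amoeboid), because a
persistent kidney-shaped (concave) contour is incompatible with any
appreciable curvature-driven rounding.

Membrane fluorescence is sampled per marker as the mean pixel intensity
inside an ellipse centered on the marker, major semi-axis 1.0 μm along the
tangent and 0.5 μm along the normal (the axes are package choices — no
canonical dimensions exist), normalized per frame by the 99th-percentile
pixel value (robust to detector saturation) and clipped to [0, 1]; ellipses
without any covered pixel yield missing values, zero axes degrade to
nearest-pixel sampling.  Kymograph pairs are compared by Pearson correlation
over matched non-missing nodes.

## Synthetic data

The fixture generators produce what the tests need without any microscopy
input: static circles/ellipses/stars with optional boundary noise; a
`translating_amoeboid` track (the polarized reference-parameter simulation,
which develops the persistent zigzag of amoeboid cells); a `fan_shaped`
track — rigid translation of a dimpled limaçon (one persistent concave arc,
area ≈ 190 μm², 0.1 μm/s, frame interval 4 s, 0.05 μm boundary noise),
mimicking the kidney-shaped fan mode; and `fluorescence_band` image stacks
with a Gaussian-cross-section intensity ridge along a given track's contour,
amplitude proportional to a supplied per-marker field (0.2 μm pixels,
0.6 μm ridge width).

What these fixtures do not emulate: segmentation errors with spatially
correlated structure, frame-to-frame segmentation jitter, cell-shape modes
outside the model class, intensity saturation and background fluorescence
beyond a uniform scale, or switching between locomotion types within one
track.  Passing tests therefore demonstrate internal consistency and
parameter recovery under the model's own assumptions, not segmentation
robustness on real microscopy data.

## Known limitations and open observations

* The weight-recovery round trip uses the polarized scenario; on
  non-polarized tracks the unit-variance convention places the recovered
  w_prot ≈ 25% below the generating value (see above) — a property of the
  convention, not an estimator defect.
* With the reference parameters the simulator's non-polarized tracks have
  mean per-step centroid speed ≈ 6 μm/min, long-run diffusion coefficient
  ≈ 0.10 μm²/s and persistence ≈ 12 s; polarized tracks ≈ 9.3 μm/min.  The
  speed, diffusion and persistence are mutually consistent (D ≈ v²P), and
  are insensitive to marker count, time step within 0.25–2 s, and mapping
  regularization within 0.1–10.
* Time-varying polarization (a moving cell front) is deliberately out of
  scope: the background intensity is fixed, which is what allows the event
  set to be realized ahead of the contour evolution.
* The mapping optimization is a local method; for pathological frame pairs
  (large rotations of strongly non-convex shapes) the nearest-point
  initialization could select a suboptimal branch.  Monotonicity is still
  guaranteed; an error is raised rather than markers reordered.
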