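# Methods

This note documents the models, the numerical choices behind them, what the
synthetic-data generators do and do not emulate, and the known limitations.

## Geometry and reduction

A pixel at fractional-pixel distance r from the beam center scatters at
θ = atan(r·pitch/L) and carries q = (4π/λ)sin(θ/2) (λ in nm, q in nm⁻¹).
The azimuth convention is 0° along +horizontal, counter-clockwise positive;
azimuthal sectors always include their Friedel mirror at +180°, since for
the centrosymmetric far-field intensity the two carry the same information.
Azimuthal averaging assigns each pixel to the q bin containing its center
(no pixel splitting); the per-bin uncertainty is the sample standard
deviation over pixels divided by √N, computed in two passes so
near-constant patterns do not suffer cancellation. The instrumental q
resolution Δq (FWHM) is a configuration input: it depends on beam size,
divergence and detector point-spread in a way that is not reconstructible
from the geometry fields alone, so it is never derived internally.

## Form-factor models

Sizes are nm, q is nm⁻¹; model intensities are relative, with a free
`scale` and additive `background` per profile.

**Polydisperse sphere.** The single-sphere form factor
P(q,R) = [3(sin qR − qR cos qR)/(qR)³]² uses a series expansion below
qR = 10⁻² to avoid the (qR)³ cancellation. The size average is
number-weighted with V(R)² intensity weighting — the standard
dilute-suspension convention — over a Gaussian distribution truncated at
R > 0, normalized so that I(0) = scale. Quadrature is 61-node
Gauss–Legendre over R̄ ± 5σ; refining the order changes the result by less
than 10⁻⁵ and a 10⁵-point Riemann sum agrees to 10⁻⁶ (tested). A Gaussian
distribution was chosen because the width is specified as a standard
deviation; it is a poor description for polydispersity ≳ 0.3, where a
warning is emitted.

**Long hollow cylinder.** In the long-tube limit (length ≫ 2π/q) the
orientational average contributes a 1/q prefactor and the cross section
scatters as the annulus amplitude
A_cs = [R_o²·2J₁(qR_o)/(qR_o) − R_i²·2J₁(qR_i)/(qR_i)]/(R_o² − R_i²) with
R_o,i = R_C ± t_W/2. A finite-length average is deliberately not attempted:
no tube length is available and the model is explicitly approximate at
these q. The joint Gaussian average over (R_C, t_W) uses nested 31×61
Gauss–Legendre quadrature; because realistic wall-thickness
polydispersities are large (0.6), the thickness distribution is truncated
at t_W > 0 and wherever R_i ≤ 0 the node is dropped and the weights
renormalized — this keeps the geometry valid at the cost of making the
effective thickness distribution slightly asymmetric, a convention shared
by generator and fitter.

**Resolution smearing.** Gaussian convolution with σ = Δq/2.3548,
implemented by re-evaluating the model on a uniform internal grid extended
6σ beyond both ends of the requested grid (step σ/4 by default) so there
are no edge-padding artefacts, then interpolating back. Tabulated profiles
without a model callback fall back to interpolating the table itself and
smearing is skipped (with a warning) when the table is coarser than Δq/2.

**Lattice pattern and period inversion.** Gaussian reflections at
qₙ = 2πn/d with free per-order amplitudes (the mass-distribution envelope
within the repeat unit is not modelled — the orders' relative intensities
are inputs, not predictions). `peak_spacing` detects maxima with a
prominence criterion, refines each with a 3-point parabolic fit, assigns
integer orders by rounding qₙ/q₁ and returns the mean of 2πn/qₙ, which
uses every detected order as a cross-check of the first.

## Correlation models

Units: q in nm⁻¹; D in µm²/s; v, δv, σ_B in µm-based units; a single
internal conversion layer (nm, s) reconciles them. The Siegert relation
g₂ = baseline + β g₁² links field and intensity correlations; β is the
speckle contrast set by beam coherence and angular resolution.

The driven-suspension g₁ factorizes into diffusive × transit × advective
terms. The three numeric conventions — transit exp(−t²/(2t_T²)), Gaussian
advective exp(−(qδvt)²/2), and the flow-direction sinc argument qδvt/2 —
live in one named-constant block in `xpcs.py`, because different
conventions differ only by O(1) factors that rescale the recovered δv;
generator and fitter share the block, so recovery tests are invariant to
the choice, and changing convention is a one-line edit. With the sinc
argument qδvt/2 the first node of the homodyne flow-direction g₂ sits at
qδvt = 2π. The vertical (gradient-transverse) direction uses the Gaussian
advective form; the transit term is negligible in the shear analysis and
is omitted there.

The Péclet number uses the probe length 1/q by default (the natural XPCS
convention: advection matters once particles traverse 1/q ballistically
faster than diffusively); the length scale is an explicit argument.

## Correlator

The estimator is the symmetric normalization
g₂(k) = ⟨I_t I_{t+k}⟩ / (⟨I_t⟩_{[0,N−k)} ⟨I_{t+k}⟩), chosen over plain
⟨I⟩² normalization to suppress slow-drift bias; the O(N·max_lag) direct
estimator is the in-repo oracle and multi-tau level 0 reproduces it
identically (same estimator, same data). Higher levels average adjacent
frame pairs and evaluate lags n/2+1..n of the averaged series
(n = 16 per level by default), yielding the standard quasi-logarithmic
grid. Ensemble averaging weights each pixel's g₂ by its mean intensity
(photon-statistics weighting); each q bin also records the pixel-mean q²,
which is the correct abscissa for Γ-vs-q² regression with finite-width
bins.

For short traces the per-pixel symmetric normalization is a known biased
estimator: normalizing by windowed trace means removes fluctuation
components slower than the observation window, which suppresses the
baseline and steepens the apparent decay by O(τ_c/T). The decay-rate
extraction (`exponential_decay_rates`) therefore floats the baseline and
restricts the fit to t ≤ 3/Γ (iterated from a data-derived half-decay
start), which removes most of this bias without touching the estimator
itself.

## Synthetic data

The generators emulate the statistical structure the analyses assume, with
ground truth known by construction; all are bit-reproducible given a seed.

**Trajectories.** Brownian steps of std √(2D₀dt) per axis; active motion
adds per-particle ballistic drift with fixed random headings and speeds
drawn Gaussian(v, δv) or Lorentzian(v, δv) — fixed headings match the
ballistic regime the Gaussian transit/advective terms describe, and
rotational diffusion is deliberately absent; shear adds a deterministic
linear profile v_x(y) (the ideal Couette limit of δv constant across the
gap). Positions wrap in a periodic box.

**Speckle rendering.** Per frame, E(q⃗) = Σ_j exp(iq⃗·r_j) on the
detector's transverse (q_x, q_y) grid, evaluated as two complex
outer-product matrices multiplied together (separable phase factors), then
|E|² is scaled to a target mean count rate and Poisson-sampled. The
small-angle limit is taken seriously: the beam-axis coordinate evolves but
never enters the phase. A fully coherent single mode gives exponential
intensity statistics and β = 1; splitting particles into M independent
groups whose intensities add gives β = 1/M. A Gaussian illumination
envelope of width σ_B (the transit effect) can be applied to particle
weights but is off by default, since the Doppler term dominates the active
fits. The box must be commensurate with the q grid
(`commensurate_box_um`): with box = 2π/Δq_pixel and an integer-pixel beam
center, every pixel q is an integer multiple of 2π/box and the phasor sum
is exactly invariant under wrapping; any other box turns each boundary
crossing into a phase jump, i.e. a spurious decorrelation channel.

What the renderer does **not** emulate: detector point-spread and pixel
area integration (each pixel samples one exact q⃗, so single-mode contrast
is 1 rather than the instrumental ≈ 0.3–0.4), dead time, 8-bit saturation
(counts are generated unclipped; a warning flags counts above 255),
module gaps, parasitic background, and hydrodynamic or phoretic
interactions. Passing recovery tests therefore demonstrates correctness of
the correlator and fitting chain under ideal coherent imaging, not
robustness to instrumental artefacts.

**Direct tables.** `synth_g2_curves` evaluates any g₂ model and adds
lag-independent Gaussian noise; `synth_saxs_profile` evaluates a
form-factor model, smears it, and applies multiplicative log-normal noise
(constant fractional error, the natural noise structure for profiles
spanning decades).

## Fitting

All fits are Levenberg–Marquardt (lmfit) weighted least squares and
deterministic given data and starting values. g₂ fits run in linear space;
SAXS fits run in log-intensity space with weights I/σ (the log-space
equivalent of 1/σ² weighting), because the profiles span many decades. In
global g₂ fits the physical parameters (β, D, v, δv) are shared across q
curves by default while baselines may float per curve; the shared set is
configurable, e.g. shear-rate series share only β. Initial values are
closed-form: Γ from the half-decay lag, D₀ from the median of Γ/q², β from
g₂(first lag) − 1, sphere radius from the first deep form-factor minimum
via qR = 4.4934 (minimum detection uses a prominence threshold of 0.3 in
ln I so percent-level noise cannot masquerade as a minimum), thin-wall
tube radius from qR = 2.405. Gaussian-vs-exponential advective model
selection is by reduced-χ² comparison, reported, never silent. During
optimization the tube geometry is clamped to R_C > t_W/2 > 0 so the
optimizer can explore freely without leaving the model's domain.

## Problem sizes

The recovery protocols use: five q curves × 60–200 lags for the g₂ fits;
500-point log-spaced profiles for the SAXS fits; and, for the end-to-end
pipeline, 1000 particles, 2000 frames at 1 ms on a 64×64 detector with a
mean of 5 counts/pixel, reduced into six q bins over 4–12 × 10⁻³ nm⁻¹ —
enough pixels per bin and ≥ 20 correlation times per trace at the slowest
bin to keep the estimator bias discussed above inside the few-percent
level.

## Known limitations

- The hollow-cylinder model omits finite length, multilamellar wall
  structure and any interparticle structure factor.
- The sarcomere model is 1D along the meridian; equatorial structure and
  2D anisotropic fitting are out of scope.
- No heterodyne detection, two-time correlation maps, or fourth-order
  (non-Gaussian) correlation analysis.
- Uncertainties are 1σ from the least-squares covariance; no
  Bayesian/MCMC alternative is provided.
- The correlator normalization is validated against the in-repo direct
  oracle, not against external correlator packages.
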