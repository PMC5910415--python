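# Methods

## Scope and model

`frapfit` estimates effective diffusion coefficients (and, optionally,
uniform production/degradation rates) from FRAP/iFRAP image series by
simulating the experiment rather than fitting a closed-form recovery
law. The concentration obeys pure diffusion with a constant, homogeneous
scalar D and zero-flux Neumann boundaries on the whole sample boundary,
including obstacle surfaces in obstacle-laden domains. The sample is
treated as a closed system; advection, spatially varying D, binding with
explicit on/off kinetics, and photophysics (blinking, reversible
bleaching) are out of scope.

## Image analysis

Frames are single-channel arrays indexed `[row, col]`; a pixel is the
point at its integer centre, membership tests are strict on circle
boundaries, and there is no partial-pixel weighting. The standard ROI
set is a circular *slice* (the usable imaging region, radius r_slice), a
square *bleached* region of side s_bleached centred with the slice, and
a *rim* annulus (slice minus a concentric circle of radius
ρ_rim·r_slice) whose mean in the first post-bleach frame estimates the
fluorophore concentration outside the field of view (c_rim). ρ_rim
defaults to 0.66, the value that works well for in vitro chamber data;
0.4585 suits dome-stage embryo data where less of the slice is reliably
unbleached. Slice centre and radius are configuration inputs; the
package does not auto-detect them from the images.

Preprocessing offers pre-bleach normalisation and flat-field flattening
for uneven illumination, background subtraction, and Gaussian
(σ_gauss = 2) or disc-shaped median (r_median = 5) denoising. Both
division-based corrections add an offset — the larger of the two data
minima, plus one — to numerator and denominator so near-zero
denominators cannot amplify noise; the offset makes the corrections
slightly imperfect (a flat-field frame is flattened to uniformity only
up to offset-induced curvature), which is the accepted cost of
robustness. Corrections operate on raw intensities; denoising, when
enabled, runs last, after background subtraction and
flattening/normalisation.

## Geometry and meshing

Built-in parametric domains: disc and rectangle (2D), cylinder, conical
frustum (in vitro chamber; study defaults r_upper = 317.65 px,
r_lower = 224.25 px, h ≈ 90.33 px) and the dome-stage embryo solid, an
outer hemisphere intersected by an inner sphere 10% larger in radius,
derived from the imaging-plane radius r_imaging and plane depth
h_imaging < 0 via r_outer = (r_imaging² + h_imaging²)/(−2 h_imaging).
Coordinates are image pixels; z = 0 is the imaging plane, negative z
points down into the sample, and the dome is placed so the z = 0 slice
reproduces r_imaging exactly.

Meshing triangulates a graded point cloud with Delaunay (Qhull) and
keeps simplices whose centroids lie inside the domain and outside every
obstacle. Points combine a coarse interior lattice (hexagonal in 2D,
cubic in 3D), a fine lattice inside refinement regions (the slice and a
boundary-layer band of width w_BL = 30 px around the bleached-region
boundary, defaults v = 25 px³ global and v_BL = v_slice = 15 px³
refined, matching the element sizes used throughout the study), explicit
samples of every boundary curve/surface, and — critical for dense
packings — clusters of mid-gap points at every near-contact between
obstacles, out to the neck half-width √(r·δ). Without those, Delaunay
bridges sub-element gaps with effectively blocking elements and the
medium's conductance is grossly underestimated. A deterministic
micro-jitter (seeded, 10⁻⁴ of the spacing, interior points only)
protects Qhull from exactly degenerate lattice configurations, so
meshing is reproducible bit-for-bit for a given seed. Mesh volumes agree
with analytic geometry volumes to ≲1–2% at default sizes and converge as
elements shrink.

Obstacle packings (tortuosity experiments) use equal radii on a square/
cubic lattice (`regular`), a hexagonal/FCC lattice (`packed`, the
near-ideal packing), or random sequential adsorption (`random`,
reproducible from the seed). The lattice pitch is solved by bisection so
the *realised* extracellular volume fraction (EVF), estimated by Monte
Carlo with ~4·10⁵ samples, lands within 0.5 pp of the requested target.
Two placement policies exist because they produce genuinely different
microstructures at the same global EVF: `interior` keeps obstacles
strictly inside the wall (2D default) — at EVF 25% this concentrates the
discs into a near-close-packed core (interior packing fraction ≈ 0.88,
necks ≈ 0.03·diameter) whose thin channels dominate transport — while
`cross` lets obstacles rest against and be clipped by the wall (3D
default), like beads settled in a chamber. In 3D, `cross` is also the
only option: a strictly interior monodisperse FCC packing at EVF 38%
would require an interior packing fraction above the FCC close-packing
limit (0.74), which no arrangement of equal spheres can reach.

## Simulation

Linear (P1) simplex elements with a lumped mass matrix; time integration
is a θ-scheme on a logarithmic grid (t_first = Δt/10, 80 points to
t_end, default t_end = 1680 s for 1 frame/s acquisitions at
D_ref = 50 px²/s). The default θ = ½ (Crank–Nicolson) with two initial
backward-Euler steps (Rannacher smoothing) keeps the transient
second-order accurate while damping under-resolved initial modes; pure
backward Euler (θ = 1) is available but biases recovered diffusivities
by several percent at the default step count because it over-damps the
early transient. Each step solves a sparse LU factorisation with a
residual check at 10⁻⁸ relative. With the lumped mass matrix both
schemes conserve total mass to solver precision because the stiffness
matrix annihilates constants; mass conservation, the discrete maximum
principle (to 0.5% of the initial range), Gaussian second-moment growth
⟨r²⟩(t) = ⟨r²⟩(0) + 4Dt (to 2% pre-boundary), and the uniform long-time
limit are regression-tested.

The initial condition interpolates the first post-bleach frame
bilinearly at each node's (x, y), for every z — the bleach profile is
taken depth-invariant, as the analysis cannot observe axial structure —
and assigns c_rim to nodes outside the visible region Ω₁ (default: the
slice). The logarithmic grid makes the stored reference directly
reusable for any candidate D via self-similarity: because the grid is
geometric, a re-simulation at a different D reproduces the rescaled
curve almost step-for-step, and the rescaling-vs-resimulation
discrepancy stays below 1% of the curve range.

ROI integrals of the solution use element-centroid membership (x–y test
plus, in 3D, a slab of ±1.25 mean element edges around the imaging
plane) and element volume × mean nodal value; dividing by the ROI
volume gives mean concentrations commensurable with mean pixel
intensities.

## Fitting

The `FRAPModel`/`FRAPFitResult` pair follows the statsmodels convention:
the model binds measured curves to a reference simulation and a kinetic
specification; `fit()` returns estimates, per-start diagnostics, R² and
a `summary()`. The objective is the SSD over the bleached and slice
ROIs and all frame times. Reaction kinetics are applied to the
ROI-integrated curve; for uniform rates this is exactly equivalent to
field-level application, because ROI integration is linear. The
production+degradation superposition uses the closed form
c·e^(−k₁t) + (1 − e^(−k₁t))·k₂/k₁, the unique expression consistent
with dc/dt = k₂ − k₁c that reduces to k₂t as k₁ → 0; a variant with the
sign flipped inside the parenthesis (a published formula that does not
satisfy the rate equation) is available behind `as_printed=True` and is
never the default. Equalisation, when enabled, maps simulation and data
onto a shared [0, 1] scale, (value − c̄_min)/(c̄_max·E_i), with c̄_min
the time-minimum of the bleached-ROI integral and c̄_max the
time-maximum of the slice integral, E_i fitted per ROI; it absorbs
immobile fractions, out-of-plane intensity loss and EVF-induced scale
changes.

Minimisation is Nelder–Mead in log-parameter space (positivity without
penalty tuning), multi-started from five initial D values log-spaced
over two orders of magnitude around a pilot estimate from the ratio of
half-recovery times of data and reference; candidate D beyond the
simulation horizon (D > D_ref·t_end/t_data,max) return an effectively
infinite objective, capping the search. Convergence: simplex and
objective tolerances 10⁻⁸ relative, ≤2000 iterations per start; the
minimum-SSD start wins and all starts are retained in the result. On
one-parameter fits the optimum agrees with a dense log-grid brute-force
search to within one grid step; adding a nested parameter never
increases the minimal SSD.

## Model selection and statistics

Two AIC conventions are provided. The default `gaussian` mode,
AIC = n·ln(SSD/n) + 2k, is the standard least-squares form and is
comparable across data sets. The `as_printed` mode, AIC = 2k + 2·SSD,
treats the SSD itself as the negative log-likelihood; it is dimensionful
(scale-dependent) but demands an *absolute* SSD improvement of 2 per
extra parameter. This difference matters: on recovery curves of order
one with n ≈ 600 points, the gaussian form accepts any parameter that
improves the SSD by 0.33% relative — a bar that spurious rates clear by
chance in roughly a fifth of noisy replicates and that even systematic
discretisation residuals clear — whereas the printed form cleanly
separates genuine kinetics (SSD drops by orders of magnitude) from
chance gains (of the order of the squared noise). The model-
identification study therefore runs under `as_printed`; both modes are
exposed, and AICc with the 2k(k+1)/(n−k−1) correction replaces AIC
whenever n/k ≤ 40. k counts D, fitted rates and fitted equalisation
factors. Akaike weights exp(−Δᵢ/2)/Σexp(−Δⱼ/2) are reported alongside.
R² is the standard 1 − Σ(m−d)²/Σ(d−d̄)², per ROI with mean and product
aggregates. Group comparisons of fitted diffusivities wrap Student/Welch
t, Mann–Whitney U and Wilcoxon signed-rank tests with a Shapiro–Wilk
normality gate reported next to the parametric results.

## Synthetic data and what the benchmarks show

The generator never touches the FEM solver. On a disc with a circular
bleach it uses a Neumann eigenfunction (Bessel) series — spectrally
exact for the smooth erf-edged bleach profiles used (edge blur σ = 4 px
by default, emulating diffusion during bleaching and optical blur) —
and for any other geometry (dome, obstacle fields, square bleaches) an
explicit masked-grid finite-difference solver with internal
sub-stepping, which cross-validates against the eigen series to <0.5% at
curve level. Uniform reactions are added in closed form at field level,
which is exactly consistent with the fitted curve-level composition.
Rendering evaluates the solution at pixel centres; regions outside the
sample or inside obstacles are dark. Optional vignette illumination and
additive Gaussian image noise (floor-clipped at zero) complete the
forward model; all randomness flows from a per-dataset seed recorded in
a manifest with an SHA-256 frame checksum.

Study conditions (fixed once):

* **Recovery grid** (accuracy validation): 2D disc (radius 110 px in a
  200×200 view, slice 90 px, circular bleach 40% of the slice diameter),
  four kinetic models × D ∈ {10, 50, 200} px²/s (the biologically
  relevant decade span; at 1 μm/px these read as μm²/s), rates chosen so
  reactions change intensities by tens of percent over the 300 s series
  (k₁ 2–5·10⁻³ s⁻¹, k₂ 1.5–3·10⁻³ s⁻¹), noiseless, 1 frame/s. All
  members share one bleach profile, so a single reference simulation
  serves every fit. Maximal relative error in D ≈ 0.1%, mean ≈ 0.1%.
* **Benchmark suite**: 18 experiments ({2D disc, 3D dome} × bleach
  {5, 10, 50}% of slice diameter × D {10, 50, 200}), 1 frame/s, plus a
  24-member reaction grid (four models × three D × two rate sets).
* **Tortuosity**: FRAP forward-solved by the FEM on the obstacle mesh at
  D_free = 50 px²/s, frames rendered from the imaging plane, then fitted
  as a homogeneous sample. The fitting reference starts from the
  Gaussian-smoothed (σ = obstacle radius) first frame and equalisation
  is on: with the raw dotted frame the dark bead pixels act as a large
  spurious fast-recovering bleached fraction and the fitted effective D
  falls ~3× below the medium's true homogenised diffusivity (as
  measured independently by FD and by mode-decay on the same mesh);
  with the coarse-grained initial condition the fit recovers the oracle
  values. An obstacle-free control run through the identical pipeline
  calibrates out residual bias; reported reduction is
  100·(1 − D_eff/D_ctrl). 2D: disc radius 80 px, disc obstacles r = 6 px,
  hexagonal interior packing to EVF 25%. 3D: cylinder 40×32 px, spheres
  r = 8 px, FCC wall-crossing packing to EVF 38%, contact-zone-refined
  tetrahedral mesh.
* **Geometry-mismatch demonstration**: dome with r_imaging = 36 px and a
  shallow plane depth of 6 px (depth ≈ r_imaging/6, the shallow end of
  realistic confocal depths, where the out-of-view reservoir is
  largest), confocal-like bleach column ending 4 px past the plane,
  bleach {5, 10, 50}% × D {10, 50}, fitted with a 2D disc of the
  imaging-plane radius. The unmodelled axial and lateral replenishment
  makes the disc fit overestimate D, beyond 200% at the largest bleach.
* **Reaction-neglect demonstration**: disc data with rates up to
  k₂ = 6·10⁻³, k₁ = 8·10⁻³ fitted as pure diffusion; production-
  dominant cells push the fitted D to several times the truth (≥200%
  error), degradation-dominant cells drive it toward zero (→100%).
* **Model identification**: D = 20 px²/s, k₁ = 3·10⁻³, k₂ = 1.5–2·10⁻³,
  image noise 5% of the unbleached intensity, ten replicates per
  generator, `as_printed` AIC. Pure diffusion, +production and
  +degradation are identified in ≥9/10 replicates; data generated with
  both production *and* degradation are near-degenerate with simpler
  kinetics and a reduced model may win — an expected property of the
  criterion, not a failure.

What these synthetic benchmarks do **not** show: performance under real
detector noise statistics (shot noise, gain), drift, bleaching during
acquisition, anisotropic or binding-dominated transport, or imperfect
knowledge of the sample geometry; the wet-lab diffusivity values
reported for real probes require the raw microscopy data and are outside
the test scope.

## Numerical choices and limitations

* Desk-scale problem sizes were chosen so the full benchmark set runs in
  minutes on one core: 2D meshes of ~5–15k nodes (element areas 0.6–4
  px²), 3D meshes of ~20k nodes, FD oracles at 1–2.5 px spacing,
  recovery series of 120–300 frames. All are comfortably inside the
  convergence plateaus established by the refinement tests.
* The 2D tortuosity figure depends visibly on the packing
  microstructure, which for beads in a chamber is not fully
  determined by the EVF alone: uniform wall-crossing hexagonal packing
  at cell-EVF 25% gives θ ≈ 0.55 (consistent with lattice conduction
  theory), while the strictly interior near-close-packed arrangement at
  the same global EVF gives θ ≈ 0.38. The interior default reflects the
  near-ideal-packing reading; both are exposed via `placement=`.
* Equalisation factors interact with degradation on long series (both
  scale curves down); fits of the full model with equalisation on short
  or low-contrast series can be weakly identified — the multi-start
  table should be inspected when Akaike weights are close.
* The masked-grid FD oracle has first-order (staircase) boundary
  accuracy; pointwise field errors near curved walls reach ~1% of the
  dynamic range at 1 px spacing while ROI-mean curves agree to <0.1%.
* Obstacle meshes under near-close packing resolve conduction necks with
  only a few elements across; the contact-zone refinement makes the
  effective diffusivity agree with the independent FD ground truth to a
  few percent, which is adequate for the tortuosity benchmarks but not
  for precision homogenisation studies.
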