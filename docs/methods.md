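# Methods

## The model system

`coraloptics` models light transport in a massive faviid coral as a
radiative-transfer problem in a simplified two-layer structure: a
calcium-carbonate skeleton forming ~3 mm wide coenosteum walls and
~10 mm wide, ~8 mm deep corallite cups, draped by a ~2 mm layer of
living tissue, under seawater.  The cross-section is drawn in the x–z
plane and extruded unchanged along y.  Each compartment is a
homogeneous turbid medium described by an absorption coefficient μa
[cm⁻¹], a scattering coefficient μs [cm⁻¹], a Henyey–Greenstein
anisotropy g, and a refractive index n.  Scattering strength is
reported as the reduced scattering coefficient μs′ = μs(1−g); media
are constructed from (μa, μs′) with μs = μs′/(1−g).

Reference properties at 636 nm: skeleton μa = 0.01, μs′ = 3.4 cm⁻¹;
tissue μa = 1.8, μs′ = 10 cm⁻¹; g = 0.9 everywhere (the standard
tissue-optics value for visible light; it is assumed, not fitted).
Water is weakly participating (μa = 0.003, μs′ = 0.05 cm⁻¹) so that
fluence is scored in the water column too.  Refractive indices are
matched across all boundaries; the internal-reflectance utility
(`internal_reflectance`, the empirical polynomial
r_i = 0.668 + 0.0636 n + 0.710/n − 1.440/n², giving 0.08 for
n_rel = 1.38/1.33 and 0.51 for 1.38/1.0) quantifies the error this
assumption hides but is deliberately not wired into the transport
loop.

## Photon transport

The Monte Carlo kernel is the classic multilayer hop/drop/spin loop on
a voxelized 3-D grid:

* free paths are exponential in optical depth; steps are clipped at
  voxel faces so each sub-segment uses that voxel's μt = μa + μs
  (step-through-voxel traversal);
* at each collision a fraction μa/μt of the photon weight is absorbed
  and the remainder is deflected by an inverse-CDF Henyey–Greenstein
  sample with a uniform azimuth;
* photons below weight 10⁻⁴ play Russian roulette (survival 1/10,
  weight ×10); the roulette's debits and credits are tracked in the
  ledger's `residual` term so that absorbed + escaped + residual
  equals the launched power exactly (to float round-off — the suite
  asserts 10⁻⁶);
* boundaries are index-matched: photons crossing the top face are
  scored in an (x, y) escape map; lateral and bottom faces absorb
  (domains are sized so these losses do not reach the observables).

Fluence is scored with a track-length estimator: each voxel
accumulates Σ W·ℓ over path segments, and φ = Σ W·ℓ/(V·N) gives
W cm⁻² per W delivered.  Unlike collision scoring, this has usable
variance in nearly transparent media (the water column), and it is
unbiased for the same quantity.  For plane-wave sources, multiplying
by the illuminated area expresses φ in units of the incident
irradiance.

The RNG is a counter-based splitmix64 with one stream per photon
index, so a (grid, source, n_photons, seed) tuple reproduces
bit-identical results regardless of batching.

Validation oracles in the test suite: Beer–Lambert decay in a pure
absorber (R² > 0.999); the far-field fluence decay rate
μ_eff = √(3 μa(μa+μs′)) in a homogeneous scatterer (±10%); and total
diffuse reflectance of a matched-boundary semi-infinite medium with
μa = 10, μs = 90, g = 0, which must reproduce the classical value
R = 0.415 — the test recomputes the exact answer from Chandrasekhar's
H-function as an independent oracle (our kernel gives 0.4148).

## The measurement and its emulation

The experimental observable is the signal M(r) [a.u.] of a
scalar-irradiance microprobe in contact with the surface at seven
distances (2, 5, 8, 11, 14, 17, 20 mm) from a collimated 636 nm beam
(2.05 mm 1/e² Gaussian) centred on the coenosteum wall.  Because the
geometry is extruded, the probe walks *along* the wall axis; the
simulated observable is the fluence averaged over the top 0.5 mm of
the surface medium, a 1 mm band across the wall crest, and a 1 mm
window along the wall at y = ±r (both sides averaged).  Averaging
over a fixed physical depth and window keeps the observable
independent of voxel size — profiles computed on different grids are
directly comparable — and trades smoothing that is small against the
profile's ~3 mm decay length for severalfold lower Monte Carlo
variance.  An escape-map variant of the profile is available
(`use_escape=True`) for the reading of the observable as escaping
flux rather than in-contact fluence.

The synthetic generator runs the forward model at ground-truth
properties and emits M_i(r) = K_true·φ(r)·ε_i with ε_i lognormal of
mean 1 and CV 0.05 (the laser's ±2% power stability plus positioning
error; the true replicate noise of the original data is unknown), 15
replicates for the bare skeleton and 13 for the intact coral,
K_true = 10⁴ (arbitrary by construction — the fit is exactly
invariant to it).  What the generator does *not* emulate: probe
collection geometry (an 80 μm sphere is treated as a point sampler),
surface topography, tissue heterogeneity, or any wavelength
dependence.  Passing tests therefore demonstrate correctness of the
inverse machinery under the stated noise model, not robustness to
real-world systematics.  Generation uses the 0.25 mm default grid at
10⁶ photons; residual Monte Carlo noise in the far tail of the coral
series (r ≥ 17 mm, where φ has fallen ~4 decades) exceeds the 5%
replicate noise and is the dominant error source of the synthetic
study.

## Inverse procedure

Stage 1 (bare skeleton).  Radial attenuation alone cannot separate
the skeleton's very weak absorption from lateral leakage out of the
wall, so μa is pinned at 0.01 cm⁻¹ and only μs′ (plus the
calibration) is fitted.  A lookup table over the log-spaced screen
grid μs′ ∈ {0.1, 0.562, 3.15, 17.8, 100} cm⁻¹ supplies the starting
point; Nelder–Mead then refines off-grid on log-transformed
parameters (relative tolerances 10⁻³, iteration cap 200).  Every
forward evaluation uses one fixed seed (common random numbers), so
the objective is a deterministic function of the parameters; the
initial simplex spans a factor e^0.4 per parameter so that its first
moves compare points whose objective differences exceed the Monte
Carlo roughness.

Stage 2 (intact coral).  The skeleton keeps its stage-1 properties;
tissue (μa, μs′) are fitted on the full two-layer geometry over the
5×5 screen grid μa ∈ {0.01, 0.056, 0.316, 1.78, 10}, μs′ ∈ {0.1,
0.562, 3.15, 17.8, 100} cm⁻¹ (both log-spaced), followed by ×1.8
bracketing screens around the top candidates and the simplex.
Crucially, the instrument calibration K is *carried over* from the
skeleton stage rather than re-profiled: the same probe and
normalization produced both series, so the coral data sit on a known
absolute fluence scale.  With K free the two tissue properties trade
off along a shape-degenerate ridge and are not identifiable from
seven radii.

Objective space.  The fit M(r) = K·φ(r) is evaluated on log
residuals by default: the attenuation spans ~4 decades, so a linear
SSE is dominated entirely by the 2 mm reference point (discarding the
slope information that constrains μs′), and the surface level is
non-monotone in μs′, which leaves a linear objective with twin
optima.  Matching the curves in log space — their slopes *and*
absolute values — uses all seven radii on an equal footing.  K is
profiled analytically per evaluation (linear least squares in linear
mode; the geometric-mean solution in log mode); zero-tally fluence
values are floored at 10⁻⁸ of the profile maximum, a finite
detection-limit penalty against candidates that predict no light
where signal exists.  Linear SSE remains available
(`log_space=False`).

Calibration constants.  `FitResult.K` is the fitted signal scale
(M ≈ K φ; scaling the data by c scales K by c).  The conversion of a
measured series to absolute fluence is φ = CALIB·M with
CALIB = 1/K = K_ref/M(2 mm), where K_ref = M(2 mm)/K is the fitted
fluence at the reference radius; `calibrate_measurement` applies it,
and noiseless synthetic data calibrate back onto the generating φ(r)
exactly.

Model-resolution-limited radii.  At desk-scale photon budgets the
forward model's own Monte Carlo error in the far tail of the coral
profile (r ≥ 14 mm, where φ has fallen ~4 decades) is 25–45% per
evaluation — an order of magnitude above the 5% replicate noise — and
an unweighted objective over those points just injects that noise
into the soft (μa↓, μs′↑) valley of the tissue fit.  The acceptance
suite therefore fits the tissue stage on the 2–11 mm radii, the
subset the forward model resolves at its evaluation budget; with
larger per-evaluation budgets all seven radii can be used.  In the
acceptance suite the synthetic series are generated on the same grid
family the fit evaluates (0.5 mm voxels; a matched 30 mm extrusion
for the tissue stage), the self-consistency design under which
recovery isolates the inverse machinery from discretization
differences; the acceptance *script* instead generates at high
fidelity (4x10^6 photons) and fits at 10^6 per evaluation.  The
skeleton stage, whose linear objective is head-dominated, always uses
all seven radii on the full 44 mm domain.

Uncertainty is assessed by replicate refitting across seeds (the
acceptance suite uses the median of five), not asymptotic covariance.

## Illumination experiments

Vertical sun: a collimated plane wave over the whole top face at
1× incident irradiance; the report gives the maximum in-tissue
fluence enhancement from the laterally averaged axial profile at the
wall centre (averaging over y and a 1 mm band in x is legitimate for
the extruded geometry and suppresses voxel noise), its depth below
the tissue surface, and the maximum enhancement in the water column.
Per-voxel statistics (95th percentile and raw maximum over the
wall-crest tissue) are reported alongside.  At the reference
properties the model gives ~1.9× in tissue and ~1.5× in water; the
in-tissue maximum is a broad plateau at ~275–350 μm depth
(≈3 transport steps of 1/μt ≈ 98 μm), confirmed on a 10 μm-resolution
layered slab.

Oblique sun (45°, toward +x): the trans-skeletal transport metric is
the mean tissue fluence over the lining of the *shaded* (+x) face of
the central wall.  In the tissue-replaced variant
(`replace_skeleton_with_tissue`) the skeleton voxels carry the tissue
properties; the real skeleton delivers severalfold more light to the
shaded lining.

Absorption sensitivity: normalized bare-skeleton profiles are
compared across skeletal μa ∈ {0.01, 0.316, 0.56} cm⁻¹ at a common
seed.  Note that the *profiles* are not insensitive — photons
reaching r = 20 mm accumulate several cm of path, so μa = 0.56
roughly halves the normalized tail — but the *fitted* μs′ is: re-running
the skeleton fit with μa pinned an order of magnitude high moves the
recovered μs′ by less than 10%.

## Numerical choices and problem sizes

* Grids: 0.25 mm isotropic voxels for measurement-scale runs
  (domain 30 × 44 × 16 mm; the 44 mm extrusion contains the 2–20 mm
  probe walk on both sides); 0.5 mm voxels (`fitting_params()`) for
  forward evaluations inside the fit, the coarsest that resolve the
  2 mm tissue layer — the observable varies over ~3 mm scales, so
  nothing usable is lost and each evaluation's variance drops
  severalfold; dz = 0.05 mm for the illumination experiments, which
  must resolve the near-surface fluence peak.
* Photon budgets: 10⁶ to generate synthetic measurements and for
  experiment figures; 10⁵–4·10⁵ per forward evaluation inside fits
  (the package's desk-scale defaults; the test suite uses the lower
  end so the full suite stays in the tens of minutes).
* Degenerate inputs: μt = 0 voxels are traversed ballistically;
  a photon fully absorbed in one collision terminates without
  roulette; sources exactly on voxel boundaries are handled by the
  observables' half-voxel acceptance windows.
* Tie-breaks: voxel-face crossings resolve by the smallest positive
  face distance with the crossing coordinate snapped to the face.

## Known limitations

* The corallite is a rectangular cup and the skeleton a homogeneous
  medium; real septa, voids and density banding are not represented.
* Index matching everywhere; no Fresnel reflection or refraction.
* Monochromatic per run; no fluorescence, polarization, or
  time-resolved transport.
* The two tissue parameters are near the information limit of a
  seven-point series: single-seed tissue fits can err by tens of
  percent, and only the median over seeds is a stable estimate (see
  the acceptance suite).  The skeleton-stage calibration K feeds the
  tissue stage, coupling their errors.
* Water optical properties are plausible values for red light, not
  fitted; they are configurable, and they matter only for the
  in-water fluence of the illumination experiments, not for the
  surface-contact observables the fits use.
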