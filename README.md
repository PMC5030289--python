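# coraloptics

Monte Carlo radiative transfer for coral tissue optics: a voxelized
photon-transport simulator for a simplified two-layer faviid coral
(living tissue draped over an aragonite skeleton, under water), the
inverse procedure that extracts inherent optical properties from
radial fluence-attenuation measurements, and forward illumination
experiments that predict in-tissue light enhancement and
trans-skeletal light transport.

## Who this is for

Researchers in coral ecophysiology and biophotonics who want to
(1) turn scalar-irradiance microprobe measurements of lateral beam
spread into absorption and reduced scattering coefficients (μa, μs′)
for coral tissue and skeleton, and (2) predict the light
microenvironment of *Symbiodinium* inside the tissue under arbitrary
collimated illumination.

## The model and method

Light transport in each compartment (water, tissue, skeleton) is
governed by the radiative transfer equation with inherent optical
properties μa [cm⁻¹], μs [cm⁻¹], a Henyey–Greenstein phase function
with anisotropy g = 0.9, and matched refractive indices; scattering
strength is reported as μs′ = μs(1−g).  The RTE is solved by Monte
Carlo: photons hop with exponential free paths through the labeled
voxel grid, drop weight μa/μt at each collision, spin by
Henyey–Greenstein, and terminate by Russian roulette, with an energy
ledger that closes exactly.  Fluence rate (scalar irradiance) φ is
tallied per voxel by a track-length estimator in W cm⁻² per W
delivered.

The inverse problem: a 636 nm, 2.05 mm collimated beam is delivered
to the coenosteum wall and the probe signal M(r) [a.u.] is measured
at seven radii r = 2…20 mm along the wall.  The model fits
M(r) = K·φ(r), with the calibration K profiled analytically, by a
lookup-table screen over log-spaced (μa, μs′) grids followed by
Nelder–Mead refinement with common random numbers.  Stage 1 fits the
bare skeleton (μa pinned at 0.01 cm⁻¹); stage 2 carries the skeleton
properties and the calibration into the intact-coral fit and recovers
the tissue (μa, μs′).  See `docs/methods.md` for the estimator and
objective-space details.

## Worked example

`examples/fit_tissue.py` generates synthetic microprobe series at the
reference properties (skeleton μs′ = 3.4, tissue μa = 1.8,
μs′ = 10 cm⁻¹) and runs the two-stage fit:

```
$ python examples/fit_tissue.py
stage 1: skeleton mu_s' = 3.62 cm^-1 (truth 3.40), K = 9445
stage 2: tissue mu_a = 2.02 cm^-1 (truth 1.80), mu_s' = 9.06 cm^-1 (truth 10.0)
```

Stage 1 recovers the skeleton's reduced scattering coefficient within
several percent; the stage-2 tissue properties land within ~10% here,
the uncertainty expected of a two-parameter fit to a short noisy
radial series (single runs scatter; the acceptance suite checks the
median over five seeds against a 20% band).  The recovered
contrast — tissue scattering ~3× the skeleton's, tissue absorption
~200× — is the optical division of labour: strongly scattering tissue
traps light for the symbionts while the clear skeleton redistributes
it to shaded regions.

`examples/vertical_sun.py` illuminates the fitted coral with a
vertical plane wave:

```
$ python examples/vertical_sun.py
max in-tissue fluence: 1.93x incident, at 275 um below the tissue surface
max in-water fluence above the tissue: 1.54x incident
energy ledger: absorbed 0.550, escaped 0.450
```

Multiple scattering makes the in-tissue fluence rate peak near twice
the delivered irradiance, and the escaping backscatter raises the
fluence in the water above the tissue by ~1.5×.
`examples/oblique_sun.py` shows that under 45° illumination the real
skeleton delivers ~1.5× more light to the tissue on the shaded side
of the wall than a hypothetical all-tissue colony.

There is also a thin CLI:

```sh
coraloptics synth --stage skeleton --seed 1 --out skel.csv
coraloptics fit-skeleton --measurement skel.csv --out fit.json
coraloptics experiment --scenario vertical --photons 1000000
coraloptics run-all --seed 0 --out results/
```

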