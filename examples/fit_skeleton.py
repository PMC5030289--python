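"""Recover the coral skeleton's reduced scattering coefficient.

Builds a synthetic bare-skeleton measurement (a 636 nm, 2.05 mm beam
on the coenosteum wall; scalar-irradiance probe at 7 radii out to
2 cm; 15 replicates, 5% noise) with ground truth mu_s' = 3.4 cm^-1,
then runs the lookup-table screen + Nelder-Mead inverse fit with the
skeletal absorption pinned at 0.01 cm^-1.
"""

from coraloptics import (ForwardProfileModel, SyntheticConfig,
                         extract_skeleton_properties, fitting_params,
                         generate_measurement)

config = SyntheticConfig(stage="skeleton", n_photons=300_000, seed=1)
measurement = generate_measurement(config)
print("synthetic M(r) [a.u.]:",
      [f"{v:.3g}" for v in measurement.signal])

forward = ForwardProfileModel("skeleton", measurement.radii_mm,
                              params=fitting_params(),
                              n_photons=200_000, seed=11)
fit = extract_skeleton_properties(measurement, forward=forward)

print(f"recovered mu_s' = {fit.mu_s_prime:.2f} cm^-1 "
      f"(truth {config.skeleton.mu_s_prime:.2f})")
print(f"calibration K = {fit.K:.0f} counts cm^2 (truth {config.K_true:.0f})")
print(f"{fit.n_iter} simplex iterations, converged={fit.converged}")
# mu_s' near 3.4 means the wall transports red light with a transport
# mean free path of ~3 mm -- far clearer than the tissue above it.
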