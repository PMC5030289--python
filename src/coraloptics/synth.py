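"""Synthetic microprobe measurement series.

The original radial-attenuation measurements exist only as figures, so
the inverse pipeline is exercised on synthetic stand-ins with the same
statistical structure: a 636 nm, 2.05 mm Gaussian collimated beam on
the coenosteum wall crest, fluence sampled at seven radial positions
from 2 to 20 mm along the wall, signal proportional to fluence through
an arbitrary instrument constant K_true, and multiplicative lognormal
replicate noise (n = 15 repetitions for the bare skeleton, n = 13 for
the intact coral, as in the source experiment).

The replicate noise magnitude of the original data is unknown; the
default CV of 0.05 reflects the laser's +-2% power stability plus
probe-positioning error, and is a stand-in rather than an estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import (CoralModelParams, OpticalProperties,
                       build_bare_skeleton, build_coral_model, make_medium)
from .inverse import MeasurementSeries
from .transport import SourceSpec, propagate, surface_radial_profile

__all__ = [
    "SyntheticConfig",
    "DEFAULT_RADII_MM",
    "generate_measurement",
    "make_paper_default_configs",
    "SKELETON_TRUTH",
    "TISSUE_TRUTH",
]

#: Seven probe positions [mm]: the reference point at 2 mm out to 2 cm.
DEFAULT_RADII_MM = (2.0, 5.0, 8.0, 11.0, 14.0, 17.0, 20.0)

#: Ground-truth media for the two stages: the best-fit skeleton
#: (mu_a = 0.01, mu_s' = 3.4 cm^-1) and best-choice tissue
#: (mu_a = 1.8, mu_s' = 10 cm^-1), g = 0.9 throughout.
SKELETON_TRUTH = dict(mu_a=0.01, mu_s_prime=3.4)
TISSUE_TRUTH = dict(mu_a=1.8, mu_s_prime=10.0)


@dataclass
class SyntheticConfig:
    """Everything needed to emulate one measurement series."""

    stage: str = "skeleton"  # 'skeleton' | 'coral'
    skeleton: OpticalProperties = field(
        default_factory=lambda: make_medium(**SKELETON_TRUTH))
    tissue: OpticalProperties | None = None
    params: CoralModelParams = field(default_factory=CoralModelParams)
    source: SourceSpec = field(default_factory=lambda: SourceSpec(
        kind="disk", diameter_mm=2.05, profile="gaussian",
        wavelength_nm=636.0))
    radii_mm: tuple = DEFAULT_RADII_MM
    K_true: float = 1e4
    cv: float = 0.05
    n_replicates: int = 15
    n_photons: int = 1_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.stage not in ("skeleton", "coral"):
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.stage == "coral" and self.tissue is None:
            raise ValueError("coral stage needs tissue properties")
        if self.cv < 0:
            raise ValueError("noise CV must be non-negative")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")
        if 2.0 not in tuple(self.radii_mm):
            raise ValueError("radii must include the 2 mm reference point")


def generate_measurement(config: SyntheticConfig) -> MeasurementSeries:
    """Forward-simulate at the true properties and add replicate noise.

    M_i(r) = K_true * phi(r) * eps_i with eps_i lognormal of mean 1 and
    coefficient of variation `cv`.  The returned series carries the
    generating truth in its ``truth`` attribute for test harnesses.
    Same config (incl. seed) -> bit-identical series.
    """
    if config.stage == "skeleton":
        grid = build_bare_skeleton(config.params, skeleton=config.skeleton)
    else:
        grid = build_coral_model(config.params, tissue=config.tissue,
                                 skeleton=config.skeleton)
    result = propagate(grid, config.source, config.n_photons, config.seed)
    prof = surface_radial_profile(result, np.asarray(config.radii_mm),
                                  mode="line")
    if np.any(prof.values <= 0):
        raise ValueError("zero fluence at a probe radius; raise n_photons")

    rng = np.random.default_rng(config.seed)
    if config.cv > 0:
        sigma = np.sqrt(np.log1p(config.cv ** 2))
        eps = rng.lognormal(mean=-sigma ** 2 / 2.0, sigma=sigma,
                            size=(config.n_replicates, len(config.radii_mm)))
    else:
        eps = np.ones((config.n_replicates, len(config.radii_mm)))
    reps = config.K_true * prof.values[None, :] * eps
    target = config.tissue if config.stage == "coral" else config.skeleton
    truth = {
        "mu_a": target.mu_a,
        "mu_s_prime": target.mu_s_prime,
        "K_true": config.K_true,
        "phi": prof.values.copy(),
        "stage": config.stage,
    }
    return MeasurementSeries(radii_mm=np.asarray(config.radii_mm),
                             signal=reps.mean(axis=0), replicates=reps,
                             label=config.stage, truth=truth)


def make_paper_default_configs(params: CoralModelParams | None = None,
                               seed: int = 0,
                               n_photons: int = 1_000_000,
                               ) -> tuple[SyntheticConfig, SyntheticConfig]:
    """Default (skeleton-stage, coral-stage) synthetic configurations.

    Skeleton truth mu_s' = 3.4, mu_a = 0.01 cm^-1 with 15 replicates;
    coral-stage tissue truth mu_a = 1.8, mu_s' = 10 cm^-1 over that
    same skeleton, 13 replicates.
    """
    params = params or CoralModelParams()
    skel = SyntheticConfig(stage="skeleton", params=params,
                           n_replicates=15, seed=seed, n_photons=n_photons)
    coral = SyntheticConfig(stage="coral", params=params,
                            tissue=make_medium(**TISSUE_TRUTH),
                            n_replicates=13, seed=seed, n_photons=n_photons)
    return skel, coral
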