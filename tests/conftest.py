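"""Shared fixtures: small precomputed Monte Carlo runs.

Transport runs are the expensive part of the suite, so anything used
by more than one test is session-scoped.  All randomness is seeded;
every fixture is reproducible bit-for-bit.
"""

import numpy as np
import pytest

from coraloptics.geometry import (OpticalProperties, build_homogeneous_slab,
                                  make_medium)
from coraloptics.transport import SourceSpec, propagate


@pytest.fixture(scope="session")
def absorber_slab_run():
    """Pencil beam into a pure absorber (mu_a=10, mu_s=0): Beer-Lambert."""
    slab = build_homogeneous_slab(OpticalProperties(mu_a=10.0, mu_s=0.0,
                                                    g=0.0),
                                  thickness_mm=5.0)
    res = propagate(slab, SourceSpec(kind="pencil"), 30_000, seed=11)
    return slab, res


@pytest.fixture(scope="session")
def scattering_slab_run():
    """Pencil beam into a tissue-like scatterer (mu_a=1, mu_s'=10, g=0.9)."""
    med = make_medium(1.0, 10.0, g=0.9)
    slab = build_homogeneous_slab(med, thickness_mm=20.0, x_extent=40.0,
                                  y_extent=40.0, dx=0.4, dy=0.4, dz=0.4)
    res = propagate(slab, SourceSpec(kind="pencil"), 150_000, seed=12)
    return slab, res
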