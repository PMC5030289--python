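"""Photon transport: conservation, closed-form attenuation, determinism,
and the surface/axial observables."""

import numpy as np
import pytest

from coraloptics.geometry import (OpticalProperties, VoxelGrid,
                                  build_homogeneous_slab, make_medium)
from coraloptics.transport import (SourceSpec, axial_profile, propagate,
                                   surface_radial_profile)


def ledger_closure(ledger):
    return ledger["absorbed"] + ledger["escaped"] + ledger["residual"]


def test_energy_ledger_closes(absorber_slab_run, scattering_slab_run):
    for _, res in (absorber_slab_run, scattering_slab_run):
        assert ledger_closure(res.ledger) == pytest.approx(1.0, abs=1e-6)
        assert np.all(res.fluence >= 0)


def test_absorbed_fraction_stable_across_seeds():
    med = make_medium(1.0, 10.0, g=0.9)
    slab = build_homogeneous_slab(med, thickness_mm=10.0, dz=0.2)
    n = 30_000
    fractions = [propagate(slab, SourceSpec(kind="pencil"), n,
                           seed=s).ledger["absorbed"] for s in (1, 2)]
    # binomial-type bound on the Monte Carlo standard error
    se = np.sqrt(0.25 / n)
    assert abs(fractions[0] - fractions[1]) < 5 * se


def test_beer_lambert_depth_profile(absorber_slab_run):
    """Pure absorber: absorbed energy density decays as exp(-mu_a z)."""
    _, res = absorber_slab_run
    z, phi = axial_profile(res, 0.0, 0.0)
    mask = phi > 0
    z_cm = z[mask][:80] * 0.1
    y = np.log(phi[mask][:80])
    slope, _ = np.polyfit(z_cm, y, 1)
    resid = y - np.polyval(np.polyfit(z_cm, y, 1), z_cm)
    r2 = 1.0 - resid @ resid / ((y - y.mean()) @ (y - y.mean()))
    assert slope == pytest.approx(-10.0, rel=0.02)
    assert r2 > 0.999


def test_pure_absorber_profile_monotone_with_depth(absorber_slab_run):
    _, res = absorber_slab_run
    z, phi = axial_profile(res, 0.0, 0.0)
    lead = phi[phi > 0][:60]
    assert np.all(np.diff(lead) < 0)


def test_diffusion_far_field_slope(scattering_slab_run):
    """ln(r^2 phi) decays at -mu_eff = -sqrt(3 mu_a (mu_a + mu_s'))."""
    slab, res = scattering_slab_run
    radii = np.arange(4.0, 13.0, 1.0)
    prof = surface_radial_profile(res, radii, mode="annulus", band_mm=0.4)
    mu_eff = np.sqrt(3 * 1.0 * (1.0 + 10.0))
    r_cm = radii * 0.1
    slope = np.polyfit(r_cm, np.log(prof.values * r_cm ** 2), 1)[0]
    assert slope == pytest.approx(-mu_eff, rel=0.10)


def test_radial_profile_decreasing_beyond_beam(scattering_slab_run):
    _, res = scattering_slab_run
    radii = np.arange(0.0, 10.0, 1.0)
    prof = surface_radial_profile(res, radii, mode="annulus", band_mm=0.8)
    assert prof.values[0] == prof.values.max()  # peak under the beam
    beyond = prof.values[2:]
    assert np.all(np.diff(beyond) < 0)


def test_profile_consistent_when_doubling_photons():
    med = make_medium(1.0, 10.0, g=0.9)
    slab = build_homogeneous_slab(med, thickness_mm=10.0, x_extent=30.0,
                                  y_extent=30.0, dx=0.4, dy=0.4, dz=0.4)
    radii = np.array([1.0, 2.0, 4.0])
    vals = []
    for n in (50_000, 100_000):
        res = propagate(slab, SourceSpec(kind="pencil"), n, seed=5)
        vals.append(surface_radial_profile(res, radii, mode="annulus",
                                           band_mm=0.8).values)
    assert np.all(np.abs(vals[1] / vals[0] - 1.0) < 0.15)


def test_bit_identical_for_same_seed():
    med = make_medium(0.5, 5.0, g=0.9)
    slab = build_homogeneous_slab(med, thickness_mm=5.0, dz=0.2)
    src = SourceSpec(kind="disk")
    a = propagate(slab, src, 20_000, seed=42)
    b = propagate(slab, src, 20_000, seed=42)
    assert np.array_equal(a.fluence, b.fluence)
    assert a.ledger == b.ledger
    c = propagate(slab, src, 20_000, seed=43)
    assert not np.array_equal(a.fluence, c.fluence)


def test_vacuum_voxels_traversed_ballistically():
    """mu_t = 0 media are crossed without interaction, not an error."""
    vacuum = OpticalProperties(mu_a=0.0, mu_s=0.0, g=0.0)
    slab = build_homogeneous_slab(vacuum, thickness_mm=5.0, dz=0.5)
    res = propagate(slab, SourceSpec(kind="pencil"), 1_000, seed=1)
    assert res.ledger["escaped"] == pytest.approx(1.0)
    assert res.ledger["absorbed"] == 0.0
    z, phi = axial_profile(res, 0.0, 0.0)
    assert np.all(phi > 0)  # track-length scoring still sees the flight


def test_out_of_domain_requests_rejected(scattering_slab_run):
    _, res = scattering_slab_run
    with pytest.raises(ValueError):
        surface_radial_profile(res, [50.0], mode="annulus")
    with pytest.raises(ValueError):
        axial_profile(res, 100.0, 0.0)


def test_oblique_source_mirrors_fluence():
    """Flipping the incidence tilt mirrors the expected fluence map."""
    med = make_medium(1.0, 10.0, g=0.9)
    slab = build_homogeneous_slab(med, thickness_mm=8.0, x_extent=24.0,
                                  y_extent=16.0, dx=0.4, dy=0.4, dz=0.4)
    n = 100_000
    plus = propagate(slab, SourceSpec(kind="plane", zenith_deg=30.0), n,
                     seed=9)
    minus = propagate(slab, SourceSpec(kind="plane", zenith_deg=-30.0), n,
                      seed=10)
    f_plus = plus.fluence.sum(axis=(1, 2))
    f_minus = minus.fluence.sum(axis=(1, 2))[::-1]
    # interior columns, away from the oblique entry/exit edges
    sel = slice(15, -15)
    rel = np.abs(f_plus[sel] - f_minus[sel]) / f_plus[sel].mean()
    assert rel.mean() < 0.05


def test_invalid_sources_rejected():
    with pytest.raises(ValueError):
        SourceSpec(kind="laser")
    with pytest.raises(ValueError):
        SourceSpec(kind="disk", diameter_mm=0.0)
    with pytest.raises(ValueError):
        SourceSpec(kind="plane", zenith_deg=95.0)
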