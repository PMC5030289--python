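"""Inverse pipeline: normalization algebra, analytic calibration,
lookup-table screening, and self-consistent parameter recovery."""

import numpy as np
import pytest

from coraloptics.geometry import CoralModelParams, make_medium
from coraloptics.inverse import (DEFAULT_MU_S_PRIME_GRID, ForwardProfileModel,
                                 MeasurementSeries, build_lookup_table,
                                 calibrate_measurement,
                                 extract_skeleton_properties,
                                 extract_tissue_properties, fit_measurement,
                                 normalize_at_reference)
from coraloptics.transport import RadialProfile

RADII = np.array([2.0, 5.0, 8.0, 11.0, 14.0, 17.0, 20.0])


def toy_measurement(signal=None, radii=RADII):
    if signal is None:
        signal = 100.0 * np.exp(-0.3 * radii)
    return MeasurementSeries(radii_mm=radii, signal=signal, label="skeleton")


class TestNormalization:
    def test_unit_value_at_reference(self):
        out = normalize_at_reference(toy_measurement())
        assert out.signal_at(2.0) == pytest.approx(1.0)

    def test_scale_invariant_and_idempotent(self):
        m = toy_measurement()
        a = normalize_at_reference(m)
        b = normalize_at_reference(m.scaled(37.5))
        assert np.allclose(a.signal, b.signal)
        assert np.allclose(normalize_at_reference(a).signal, a.signal)

    def test_log_interpolated_reference(self):
        prof = RadialProfile(np.array([1.0, 3.0]), np.array([np.e, 1.0]))
        # log-linear between r=1 and r=3: value at r=2 is e^{1/2}
        out = normalize_at_reference(prof, r_ref=2.0)
        assert out.values[0] == pytest.approx(np.e / np.sqrt(np.e))

    def test_reference_outside_range_rejected(self):
        with pytest.raises(ValueError):
            normalize_at_reference(toy_measurement(), r_ref=30.0)


class TestMeasurementSeries:
    def test_positive_signals_required(self):
        with pytest.raises(ValueError):
            MeasurementSeries(RADII, np.zeros_like(RADII))

    def test_replicate_sd(self):
        reps = np.vstack([np.full(7, 9.0), np.full(7, 11.0)])
        m = MeasurementSeries(RADII, reps.mean(0), replicates=reps)
        assert np.allclose(m.sd, np.sqrt(2.0))


@pytest.fixture(scope="module")
def skeleton_forward():
    """Small shared forward model (coarse grid, few photons)."""
    return ForwardProfileModel("skeleton", RADII, n_photons=60_000, seed=77)


class TestFitMeasurement:
    def test_noiseless_self_consistency(self, skeleton_forward):
        """Data generated by the forward model itself are recovered
        (common random numbers make the optimum exact)."""
        phi = skeleton_forward(0.01, 3.4)
        M = toy_measurement(signal=5000.0 * phi)
        fit = fit_measurement(M, skeleton_forward, free=("mu_s_prime",),
                              init={"mu_s_prime": 5.0}, fixed={"mu_a": 0.01})
        assert fit.mu_s_prime == pytest.approx(3.4, rel=0.05)
        assert fit.K == pytest.approx(5000.0, rel=0.05)

    def test_scaling_data_scales_k_only(self, skeleton_forward):
        phi = skeleton_forward(0.01, 3.4)
        M = toy_measurement(signal=5000.0 * phi)
        f1 = fit_measurement(M, skeleton_forward, free=("mu_s_prime",),
                             init={"mu_s_prime": 3.15}, fixed={"mu_a": 0.01})
        f2 = fit_measurement(M.scaled(3.0), skeleton_forward,
                             free=("mu_s_prime",),
                             init={"mu_s_prime": 3.15}, fixed={"mu_a": 0.01})
        assert f2.K == pytest.approx(3.0 * f1.K, rel=1e-6)
        assert f2.mu_s_prime == pytest.approx(f1.mu_s_prime, rel=1e-6)

    def test_perturbed_init_reaches_same_optimum(self, skeleton_forward):
        phi = skeleton_forward(0.01, 3.4)
        M = toy_measurement(signal=5000.0 * phi)
        fits = [fit_measurement(M, skeleton_forward, free=("mu_s_prime",),
                                init={"mu_s_prime": v}, fixed={"mu_a": 0.01})
                for v in (1.7, 5.1)]  # +-50% around truth
        assert fits[0].mu_s_prime == pytest.approx(fits[1].mu_s_prime,
                                                   rel=0.10)

    def test_missing_init_rejected(self, skeleton_forward):
        with pytest.raises(ValueError):
            fit_measurement(toy_measurement(), skeleton_forward,
                            free=("mu_s_prime",), init={})


class TestLookupTable:
    def test_decay_monotone_in_mus_prime(self, skeleton_forward):
        """Fanned curves: larger mu_s' gives a steeper normalized decay."""
        table = build_lookup_table(skeleton_forward, mu_a_values=(0.01,),
                                   mu_s_prime_values=(0.562, 3.15, 17.8))
        slopes = []
        for msp in (0.562, 3.15, 17.8):
            prof = normalize_at_reference(table.entries[(0.01, msp)])
            slopes.append(np.polyfit(RADII[:4], np.log(prof.values[:4]),
                                     1)[0])
        assert slopes[0] > slopes[1] > slopes[2]

    def test_best_entry_matches_generator(self, skeleton_forward):
        table = build_lookup_table(skeleton_forward, mu_a_values=(0.01,),
                                   mu_s_prime_values=DEFAULT_MU_S_PRIME_GRID)
        phi = skeleton_forward(0.01, 3.15)
        M = toy_measurement(signal=1e4 * phi)
        mu_a0, msp0, sse0 = table.best_entry(M)
        assert msp0 == 3.15
        others = [v for k, v in
                  ((k, _sse(M, p.values)) for k, p in table.entries.items())
                  if k != (0.01, 3.15)]
        assert sse0 < min(others)

    def test_empty_grid_rejected(self, skeleton_forward):
        with pytest.raises(ValueError):
            build_lookup_table(skeleton_forward, mu_a_values=(),
                               mu_s_prime_values=(1.0,))


def _sse(M, phi):
    k = float(M.signal @ phi) / float(phi @ phi)
    r = M.signal - k * phi
    return float(r @ r)


class TestCalibration:
    def test_round_trip_onto_generating_fluence(self, skeleton_forward):
        phi = skeleton_forward(0.01, 3.4)
        M = toy_measurement(signal=2.5e4 * phi)
        fit = fit_measurement(M, skeleton_forward, free=("mu_s_prime",),
                              init={"mu_s_prime": 3.15},
                              fixed={"mu_a": 0.01})
        cal = calibrate_measurement(M, fit)
        assert np.allclose(cal.values, phi, rtol=0.05)
        # calibrated value at the reference radius is the fitted
        # reference fluence K_ref = M(2 mm)/K
        assert cal.values[0] == pytest.approx(M.signal_at(2.0) / fit.K)

    def test_reference_radius_required(self, skeleton_forward):
        radii = np.array([5.0, 8.0, 11.0])
        M = MeasurementSeries(radii, np.array([3.0, 2.0, 1.0]))
        fit = type("F", (), {"K": 2.0, "calib": 0.5})
        with pytest.raises(ValueError):
            calibrate_measurement(M, fit)


class TestStageCoupling:
    def test_tissue_fit_self_consistency_and_skeleton_mismatch(self):
        """Anchored tissue fit recovers its own forward truth; a 10x
        wrong skeleton mu_s' degrades the optimum residual."""
        radii = RADII[:5]  # coral tail beyond 14 mm needs far more photons
        skel = make_medium(0.01, 3.4)
        fw = ForwardProfileModel("coral", radii, skeleton=skel,
                                 n_photons=90_000, seed=55)
        phi = fw(1.8, 10.0)
        M = MeasurementSeries(radii, 1e4 * phi, label="coral")
        fit = extract_tissue_properties(
            M, skeleton_props=skel, forward=fw, K_fixed=1e4,
            mu_a_grid=(0.316, 1.78), mu_s_prime_grid=(3.15, 17.8),
            max_iter=25)
        # the CRN objective is exactly zero at the generating truth but
        # rough on the scale of the per-evaluation Monte Carlo noise, so
        # the recoverable basin at this budget is ~15% wide
        assert fit.mu_a == pytest.approx(1.8, rel=0.15)
        assert fit.mu_s_prime == pytest.approx(10.0, rel=0.15)
        assert fit.fixed["K"] == 1e4

        wrong = make_medium(0.01, 34.0)
        fw_wrong = ForwardProfileModel("coral", radii, skeleton=wrong,
                                       n_photons=90_000, seed=55)
        fit_wrong = extract_tissue_properties(
            M, skeleton_props=wrong, forward=fw_wrong, K_fixed=1e4,
            mu_a_grid=(0.316, 1.78), mu_s_prime_grid=(3.15, 17.8),
            max_iter=12)
        assert fit_wrong.sse > 3.0 * fit.sse

    def test_skeleton_stage_insensitive_to_fixed_mu_a(self):
        fw = ForwardProfileModel("skeleton", RADII, n_photons=40_000, seed=66)
        phi = fw(0.01, 3.4)
        M = MeasurementSeries(RADII, 1e4 * phi, label="skeleton")
        fits = [extract_skeleton_properties(
                    M, forward=ForwardProfileModel("skeleton", RADII,
                                                   n_photons=40_000, seed=66),
                    mu_a_fixed=mu_a, screen_grid=(0.562, 3.15, 17.8),
                    max_iter=40)
                for mu_a in (0.01, 0.316)]
        assert fits[1].mu_s_prime == pytest.approx(fits[0].mu_s_prime,
                                                   rel=0.10)
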