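"""Tests of the synthetic scene and spectrum generators against their ground truth."""

import numpy as np
import pytest

from phbdeg.nmr import MONOMER_REGION, POLYMER_REGION, integrate_peak
from phbdeg.synthetic import (
    SceneParams,
    SpectrumParams,
    TruthTrajectory,
    logistic_trajectory,
    simulate_image_series,
    simulate_kinetic_curves,
    simulate_spectrum,
)


def clean_params(**kwargs):
    defaults = dict(
        image_size=(96, 96),
        n_grains=8,
        grain_radius_range=(2.5, 4.0),
        noise_sd=0.0,
        illumination_gradient=0.0,
        mycelium_growth_rate=0.0,
        seed=1,
    )
    defaults.update(kwargs)
    return SceneParams(**defaults)


class TestSceneParams:
    def test_intensity_ordering_enforced(self):
        with pytest.raises(ValueError, match="grain > mycelium > agar"):
            SceneParams(grain_intensity=0.5, mycelium_intensity=0.6)

    def test_well_must_fit(self):
        with pytest.raises(ValueError, match="well"):
            SceneParams(image_size=(64, 64), well_radius=40.0)

    def test_oversized_grains_rejected(self):
        with pytest.raises(ValueError, match="cannot fit"):
            simulate_image_series(
                clean_params(well_radius=10.0, grain_radius_range=(12.0, 14.0)),
                TruthTrajectory(np.array([0.0]), np.array([1.0])),
            )


class TestTruthTrajectory:
    def test_must_start_at_one(self):
        with pytest.raises(ValueError, match="start"):
            TruthTrajectory(np.array([0.0, 1.0]), np.array([0.9, 0.5]))

    def test_grid_t50_interpolation(self):
        traj = TruthTrajectory(np.array([0.0, 100.0, 200.0]), np.array([1.0, 0.6, 0.2]))
        # linear between (100, 0.6) and (200, 0.2): crosses 0.5 at 125 h
        assert traj.t50_true == pytest.approx(125.0)

    def test_never_crossing_has_no_t50(self):
        traj = TruthTrajectory(np.array([0.0, 10.0]), np.array([1.0, 0.8]))
        assert traj.t50_true is None

    def test_logistic_crosses_half_exactly_at_t50(self):
        times = np.linspace(0.0, 336.0, 1000)
        traj = logistic_trajectory(times, t50=137.0)
        assert traj.t50_true == 137.0
        crossing = np.interp(0.5, traj.remaining_fraction[::-1], traj.times[::-1])
        assert crossing == pytest.approx(137.0, abs=0.5)


class TestImageSeriesGeneration:
    def test_constant_trajectory_freezes_the_scene(self):
        traj = TruthTrajectory(np.array([0.0, 10.0, 20.0]), np.ones(3))
        sim = simulate_image_series(clean_params(), traj)
        for frame in sim.series.frames[1:]:
            assert np.array_equal(frame, sim.series.frames[0])

    def test_total_annihilation_leaves_no_grain_pixels(self):
        traj = TruthTrajectory(np.array([0.0, 50.0]), np.array([1.0, 0.0]))
        sim = simulate_image_series(clean_params(), traj)
        assert sim.truth_table["true_grain_px"].iloc[-1] == 0
        assert not sim.truth_masks[-1].any()
        # frame contains nothing at grain intensity
        assert not np.any(sim.series.frames[-1] == sim.params.grain_intensity)

    def test_half_trajectory_halves_area_within_quantization(self):
        params = clean_params(n_grains=10, grain_radius_range=(2.5, 2.5))
        traj = TruthTrajectory(np.array([0.0, 50.0]), np.array([1.0, 0.5]))
        sim = simulate_image_series(params, traj)
        n0, n1 = sim.truth_table["true_grain_px"]
        # rounding costs at most half a pixel per grain
        assert abs(n1 - 0.5 * n0) <= 0.5 * params.n_grains

    def test_identical_seeds_are_bit_identical(self):
        traj = logistic_trajectory(np.linspace(0.0, 100.0, 5), t50=60.0)
        params = clean_params(noise_sd=0.02, illumination_gradient=0.1, mycelium_growth_rate=0.003)
        a = simulate_image_series(params, traj)
        b = simulate_image_series(params, traj)
        for fa, fb in zip(a.series.frames, b.series.frames):
            assert np.array_equal(fa, fb)

    def test_monotone_consumption(self):
        traj = logistic_trajectory(np.linspace(0.0, 336.0, 12), t50=120.0)
        sim = simulate_image_series(clean_params(seed=4), traj)
        counts = sim.truth_table["true_grain_px"].to_numpy()
        assert np.all(np.diff(counts) <= 0)

    def test_mycelium_growth_is_cumulative(self):
        traj = TruthTrajectory(np.linspace(0.0, 300.0, 6), np.ones(6))
        params = clean_params(mycelium_growth_rate=0.002, seed=2)
        sim = simulate_image_series(params, traj)
        previous = np.zeros_like(sim.series.frames[0], dtype=bool)
        for frame in sim.series.frames:
            myc = frame == params.mycelium_intensity
            assert np.all(previous <= myc)  # earlier colony is a subset
            previous = myc


class TestSyntheticKineticCurves:
    def test_replicates_pin_t0_to_100(self):
        traj = logistic_trajectory(np.linspace(0.0, 336.0, 15), t50=150.0)
        for curve in simulate_kinetic_curves(traj, n_replicates=3, noise_sd=5.0, seed=0):
            assert curve.values[0] == 100.0

    def test_noiseless_replicates_equal_truth(self):
        traj = logistic_trajectory(np.linspace(0.0, 336.0, 15), t50=150.0)
        (curve,) = simulate_kinetic_curves(traj, n_replicates=1, noise_sd=0.0, seed=0)
        assert curve.values == pytest.approx(100.0 * traj.remaining_fraction)


class TestSpectrumGeneration:
    def test_pure_polymer_has_no_monomer_signal(self):
        sim = simulate_spectrum(SpectrumParams(degradation_fraction=0.0, noise_sd=0.0))
        assert sim.true_monomer_integral == 0.0
        assert integrate_peak(sim.spectrum, MONOMER_REGION) == pytest.approx(0.0, abs=1e-6)

    def test_half_degraded_peaks_are_symmetric(self):
        sim = simulate_spectrum(SpectrumParams(degradation_fraction=0.5, noise_sd=0.0))
        mono = integrate_peak(sim.spectrum, MONOMER_REGION)
        poly = integrate_peak(sim.spectrum, POLYMER_REGION)
        # the peaks sit on each other's (curved) tails, so equality holds to
        # discretization accuracy rather than machine precision
        assert mono == pytest.approx(poly, rel=1e-6)

    def test_identical_seeds_are_bit_identical(self):
        p = SpectrumParams(degradation_fraction=0.3, noise_sd=0.01, seed=5)
        a, b = simulate_spectrum(p), simulate_spectrum(p)
        assert np.array_equal(a.spectrum.intensity, b.spectrum.intensity)

    @pytest.mark.parametrize("d", [-0.1, 1.2])
    def test_fraction_outside_unit_interval_rejected(self, d):
        with pytest.raises(ValueError, match="degradation_fraction"):
            SpectrumParams(degradation_fraction=d)

    def test_overlapping_peaks_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            SpectrumParams(monomer_center=5.18, linewidth=0.05)
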