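"""Tests for the layered-tissue photon Monte Carlo."""

import numpy as np
import pytest

from nirsox.exceptions import InsufficientStatisticsError, ValidationError
from nirsox.tissue_mc import (DetectorHits, MCSummary, OpticalLayer,
                              ProbeGeometry, TissueModel, _arc_fraction,
                              _fresnel, mean_pathlength, penetration_stats,
                              separation_scan, simulate)
from _oracles import diffusion_reflectance


def _homogeneous(mu_a=0.02, mu_s=2.0, g=0.5, n=1.4, n_ambient=1.0):
    return TissueModel(
        layers=(OpticalLayer(mu_a=mu_a, mu_s=mu_s, g=g, n=n, thickness_mm=None),),
        n_ambient=n_ambient)


class TestValidation:
    def test_anisotropy_bounds(self):
        with pytest.raises(ValidationError, match="anisotropy"):
            OpticalLayer(mu_a=0.1, mu_s=1.0, g=1.0, n=1.4)

    def test_negative_absorption(self):
        lay = OpticalLayer(mu_a=-0.1, mu_s=1.0, g=0.5, n=1.4, thickness_mm=None)
        with pytest.raises(ValidationError, match="negative mu_a"):
            TissueModel(layers=(lay,)).arrays_at(805.0, 200.0)

    def test_last_layer_must_be_semi_infinite(self):
        lay = OpticalLayer(mu_a=0.1, mu_s=1.0, g=0.5, n=1.4, thickness_mm=1.0)
        with pytest.raises(ValidationError, match="semi-infinite"):
            TissueModel(layers=(lay,))

    def test_zero_interaction_coefficient(self):
        lay = OpticalLayer(mu_a=0.0, mu_s=0.0, g=0.0, n=1.4, thickness_mm=None)
        with pytest.raises(ValidationError, match="zero total interaction"):
            simulate(TissueModel(layers=(lay,)), n_photons=10)

    def test_overlapping_apertures(self):
        with pytest.raises(ValidationError, match="overlap"):
            ProbeGeometry(detector_separations_cm=(2.0, 2.02))

    def test_detector_on_source(self):
        with pytest.raises(ValidationError, match="source"):
            ProbeGeometry(detector_separations_cm=(0.1,), detector_radius_mm=1.5)

    def test_wavelength_not_defined(self):
        lay = OpticalLayer(mu_a={805.0: 0.1}, mu_s={805.0: 1.0}, g=0.5, n=1.4,
                           thickness_mm=None)
        with pytest.raises(ValidationError, match="735"):
            simulate(TissueModel(layers=(lay,)), n_photons=10, wavelength=735.0)


class TestFresnel:
    def test_matched_indices_no_reflection(self):
        assert _fresnel(1.4, 1.4, 0.3) == 0.0

    def test_total_internal_reflection(self):
        # critical angle for 1.4 -> 1.0 is ~45.6 deg; take grazing incidence
        assert _fresnel(1.4, 1.0, 0.1) == 1.0

    def test_normal_incidence_closed_form(self):
        expected = ((1.0 - 1.4) / (1.0 + 1.4)) ** 2
        assert _fresnel(1.0, 1.4, 1.0) == pytest.approx(expected, abs=1e-12)

    def test_arc_fraction_matches_numerical_azimuth_integral(self):
        rho, d, a = 19.5, 20.0, 1.5
        phi = np.linspace(0, 2 * np.pi, 200001)
        inside = (rho ** 2 + d ** 2 - 2 * rho * d * np.cos(phi)) <= a ** 2
        assert _arc_fraction(rho, d, a) == pytest.approx(inside.mean(), abs=1e-3)


class TestConservation:
    @pytest.mark.parametrize("seed", [0, 1, 12345])
    def test_energy_ledger_closes(self, calf_model, seed):
        s = simulate(calf_model, ProbeGeometry(), n_photons=20_000,
                     wavelength=805.0, seed=seed)
        assert s.conservation_error < 1e-6

    def test_no_absorption_pure_conservation(self):
        model = _homogeneous(mu_a=0.0, mu_s=1.0, g=0.0, n=1.0, n_ambient=1.0)
        s = simulate(model, n_photons=5_000, seed=4, kill_depth_mm=20.0)
        assert s.total_absorbed == 0.0
        assert np.all(s.fluence_grid == 0.0)
        assert (s.total_reflected + s.total_transmitted
                == pytest.approx(s.n_launched, rel=1e-9))

    def test_mismatched_boundary_specular_loss(self):
        s = simulate(_homogeneous(n=1.4), n_photons=2_000, seed=0)
        # every launch loses at least the normal-incidence specular fraction
        assert s.total_reflected >= 2_000 * ((0.4 / 2.4) ** 2) * 0.999


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        model = _homogeneous()
        a = simulate(model, n_photons=10_000, seed=77)
        b = simulate(model, n_photons=10_000, seed=77)
        assert a.total_reflected == b.total_reflected
        assert a.total_absorbed == b.total_absorbed
        assert np.array_equal(a.fluence_grid, b.fluence_grid)
        assert np.array_equal(a.detected[0].exit_weight, b.detected[0].exit_weight)
        assert np.array_equal(a.detected[0].max_depth_cm, b.detected[0].max_depth_cm)

    def test_different_seed_differs(self):
        model = _homogeneous()
        a = simulate(model, n_photons=10_000, seed=1)
        b = simulate(model, n_photons=10_000, seed=2)
        assert a.total_absorbed != b.total_absorbed


class TestDiffusionLimit:
    def test_reflectance_matches_dipole_oracle(self, diffusive_medium):
        """mu_s' >= 100 mu_a, matched boundary: MC reflectance around 20 mm
        agrees with the diffusion closed form."""
        s = simulate(diffusive_medium, n_photons=200_000, seed=11)
        band = (s.reflectance_r_mm >= 19.0) & (s.reflectance_r_mm < 21.0)
        mc = s.reflectance_per_mm2[band].mean()
        theory = diffusion_reflectance(s.reflectance_r_mm[band], 0.01, 1.0).mean()
        assert mc == pytest.approx(theory, rel=0.15)


def _manual_summary(weights, depths, paths, separation_cm=2.0):
    hits = DetectorHits(separation_cm=separation_cm,
                        exit_weight=np.asarray(weights, float),
                        exit_radius_cm=np.full(len(weights), separation_cm),
                        max_depth_cm=np.asarray(depths, float),
                        partial_path_mm=np.asarray(paths, float))
    return MCSummary(n_launched=len(weights), seed=0, wavelength=805.0,
                     total_reflected=0.0, total_transmitted=0.0,
                     total_absorbed=0.0, detected=[hits],
                     fluence_grid=np.zeros((1, 1)), grid_dr_mm=0.1,
                     grid_dz_mm=0.1, reflectance_r_mm=np.zeros(1),
                     reflectance_per_mm2=np.zeros(1))


class TestDetectorStatistics:
    def test_constant_depth_median(self):
        s = _manual_summary(np.ones(200), np.full(200, 0.5),
                            np.ones((200, 3)))
        assert penetration_stats(s, 0).median_cm == pytest.approx(0.5)

    def test_single_photon_path_sum(self):
        s = _manual_summary([1.0], [0.5], [[1.0, 2.0, 30.0]])
        pl = mean_pathlength(s, 0, min_detected=1)
        assert pl.total_mm == pytest.approx(33.0)
        assert pl.dpf == pytest.approx(33.0 / 20.0)

    def test_insufficient_statistics_names_count(self):
        s = _manual_summary(np.ones(7), np.full(7, 0.5), np.ones((7, 3)))
        with pytest.raises(InsufficientStatisticsError, match="7"):
            penetration_stats(s, 0)

    def test_partial_paths_sum_to_total_path(self, calf_scan_summary):
        """Per-layer paths of each detected photon are non-negative and at
        least as long as the source-detector chord."""
        hits = calf_scan_summary.detected[1]  # 2 cm aperture
        assert np.all(hits.partial_path_mm >= 0.0)
        totals = hits.partial_path_mm.sum(axis=1)
        assert np.all(totals >= 0.99 * (hits.exit_radius_cm * 10.0))


class TestSeparationScan:
    def test_monotone_depth_and_signal(self, calf_scan_summary):
        s = calf_scan_summary
        idx = {s.detected[d].separation_cm: d for d in (0, 1, 3)}  # 1, 2, 3 cm
        weights = [s.detected[idx[sep]].exit_weight.sum() for sep in (1.0, 2.0, 3.0)]
        assert weights[0] > weights[1] > weights[2]
        depths = [penetration_stats(s, idx[sep]).median_cm for sep in (1.0, 2.0, 3.0)]
        assert depths[0] < depths[1] < depths[2]

    def test_duplicate_separations_identical(self, calf_scan_summary):
        a, b = calf_scan_summary.detected[1], calf_scan_summary.detected[2]
        assert np.array_equal(a.exit_weight, b.exit_weight)
        assert np.array_equal(a.max_depth_cm, b.max_depth_cm)

    def test_scan_matches_dedicated_run(self, calf_model, calf_scan_summary):
        """Detection does not perturb the photon stream: a dedicated
        single-aperture run at the same seed gives identical records."""
        solo = simulate(calf_model, ProbeGeometry(detector_separations_cm=(2.0,)),
                        n_photons=100_000, wavelength=805.0, seed=7)
        shared = calf_scan_summary.detected[1]
        assert np.array_equal(solo.detected[0].exit_weight, shared.exit_weight)
        assert np.array_equal(solo.detected[0].partial_path_mm,
                              shared.partial_path_mm)

    def test_scan_table_shape(self, calf_model):
        df = separation_scan(calf_model, (1.0, 2.0), n_photons=20_000, seed=3)
        assert list(df["separation_cm"]) == [1.0, 2.0]
        assert (df["n_detected"] > 0).all()

    def test_scan_needs_two_separations(self, calf_model):
        with pytest.raises(ValidationError, match="2 separations"):
            separation_scan(calf_model, (2.0,), n_photons=10)
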