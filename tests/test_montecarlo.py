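import numpy as np
import pytest

from spdri import (
    DetectorSpec,
    MCConfig,
    OpticalProperties,
    SourceSpec,
    TissueVolume,
    render_reflectance,
    sample_source_rays,
    simulate,
)
from conftest import uniform_volume
from _oracles import slab_diffuse_reflectance


class TestLaunch:
    def test_positions_confined_to_fiber_core(self, rng):
        src = SourceSpec(center=(0.0, 0.0))
        pos, _ = sample_source_rays(src, 1.0, 100_000, rng)
        r = np.hypot(pos[:, 0], pos[:, 1])
        assert r.max() <= 10.0 + 1e-9

    def test_max_polar_angle_matches_numerical_aperture(self, rng):
        src = SourceSpec(center=(0.0, 0.0))
        n_ext = 1.0
        _, dirs = sample_source_rays(src, n_ext, 100_000, rng)
        theta = np.arccos(dirs[:, 2])
        expected = np.arcsin(0.35 / n_ext)
        assert theta.max() <= expected + 1e-9
        assert theta.max() >= expected * 0.99

    def test_vanishing_aperture_collimates(self, rng):
        src = SourceSpec(center=(0.0, 0.0), numerical_aperture=1e-12)
        _, dirs = sample_source_rays(src, 1.0, 1000, rng)
        assert np.allclose(dirs[:, 2], 1.0, atol=1e-9)

    def test_zero_core_is_point_source(self, rng):
        src = SourceSpec(center=(5.0, 7.0), core_diameter_um=0.0)
        pos, _ = sample_source_rays(src, 1.0, 1000, rng)
        assert np.allclose(pos[:, 0], 5.0) and np.allclose(pos[:, 1], 7.0)

    def test_aperture_exceeding_external_index_rejected(self, rng):
        src = SourceSpec(center=(0.0, 0.0), numerical_aperture=1.2)
        with pytest.raises(ValueError, match="NA"):
            sample_source_rays(src, 1.0, 10, rng)
        vol = uniform_volume((10, 10, 10),
                             OpticalProperties(0.0, 0.0, 0.5, 1.0))
        with pytest.raises(ValueError, match="NA"):
            simulate(vol, src, MCConfig(n_photons=10, seed=1))


class TestPropagation:
    def test_ballistic_limit_everything_transmits(self):
        vol = uniform_volume((50, 50, 60),
                             OpticalProperties(0.0, 0.0, 0.5, 1.0))
        det = simulate(
            vol,
            SourceSpec(center=(25, 25), core_diameter_um=0.0,
                       numerical_aperture=1e-9),
            MCConfig(n_photons=5000, seed=3),
        )
        assert len(det) == 0
        assert det.tallies["transmitted"] == pytest.approx(5000)
        assert det.tallies["reflected"] == 0

    def test_normal_incidence_fresnel_reflectance(self):
        """A non-scattering n = 1.4 half-space in air reflects (0.4/2.4)^2."""
        vol = uniform_volume((50, 50, 60),
                             OpticalProperties(0.0, 0.0, 0.5, 1.4))
        n_phot = 100_000
        det = simulate(
            vol,
            SourceSpec(center=(25, 25), core_diameter_um=0.0,
                       numerical_aperture=1e-9),
            MCConfig(n_photons=n_phot, seed=5, n_external=1.0),
        )
        expected = ((1.4 - 1.0) / (1.4 + 1.0)) ** 2
        se = np.sqrt(expected * (1 - expected) / n_phot)
        assert abs(len(det) / n_phot - expected) < 3 * se

    def test_slab_reflectance_matches_independent_oracle(
            self, scattering_slab_run):
        volume, det = scattering_slab_run
        engine_frac = det.tallies["reflected"] / det.photons_launched
        oracle_frac = slab_diffuse_reflectance(
            mu_a_mm=0.5, mu_s_mm=10.0, g=0.8,
            box_um=(4000.0, 4000.0, 1000.0),
            source_xy_um=(2000.0, 2000.0),
            n_photons=40_000, seed=123,
        )
        # binomial-style standard errors of both estimates
        se = np.sqrt(engine_frac * (1 - engine_frac) / det.photons_launched
                     + oracle_frac * (1 - oracle_frac) / 40_000)
        assert abs(engine_frac - oracle_frac) < 3 * se

    def test_weight_conservation_without_absorption(self):
        """mu_a = 0: reflected + transmitted + side + killed == launched."""
        vol = uniform_volume((60, 60, 40),
                             OpticalProperties(0.0, 30.0, 0.8, 1.4))
        n_phot = 30_000
        det = simulate(
            vol, SourceSpec(center=(30, 30)),
            MCConfig(n_photons=n_phot, seed=9, n_external=1.0),
        )
        total = sum(det.tallies[k] for k in
                    ("reflected", "transmitted", "side_escaped",
                     "roulette_killed"))
        assert total / n_phot == pytest.approx(1.0, rel=1e-9)

    def test_same_seed_bit_identical_stream(self):
        vol = uniform_volume((40, 40, 30),
                             OpticalProperties(1.0, 20.0, 0.8, 1.4))
        cfg = MCConfig(n_photons=5000, seed=21)
        a = simulate(vol, SourceSpec(center=(20, 20)), cfg)
        b = simulate(vol, SourceSpec(center=(20, 20)), cfg)
        assert np.array_equal(a.exit_x, b.exit_x)
        assert np.array_equal(a.pathlengths_um, b.pathlengths_um)
        assert np.array_equal(a.weight_at_exit, b.weight_at_exit)

    def test_image_statistically_symmetric_about_source(self):
        vol = uniform_volume((80, 80, 40),
                             OpticalProperties(0.5, 30.0, 0.8, 1.4))
        det = simulate(
            vol, SourceSpec(center=(40.0, 40.0)),
            MCConfig(n_photons=200_000, seed=33),
            detector=DetectorSpec(numerical_aperture=1.0),
        )
        diffuse = det.pathlengths_um.sum(axis=1) > 0
        for coord in (det.exit_x[diffuse], det.exit_y[diffuse]):
            left = int((coord < 40).sum())
            right = int((coord >= 40).sum())
            n = left + right
            z = (left - right) / np.sqrt(n)
            assert abs(z) < 3.0

    def test_mirror_boundary_eliminates_side_loss(self):
        vol = uniform_volume((40, 40, 30),
                             OpticalProperties(2.0, 20.0, 0.8, 1.0))
        det = simulate(vol, SourceSpec(center=(20, 20)),
                       MCConfig(n_photons=3000, seed=4, boundary="mirror"))
        assert det.tallies["side_escaped"] == 0
        assert det.tallies["transmitted"] == 0


class TestRendering:
    def test_zero_absorption_gives_unit_contributions(
            self, scattering_slab_run):
        _, det = scattering_slab_run
        img = render_reflectance(det, np.zeros(8))
        assert img.grid.sum() == pytest.approx(
            float(det.boost.sum()), rel=1e-12)

    def test_single_medium_closed_form(self):
        """1000 um of path at 1 mm^-1 attenuates by exp(-1)."""
        from spdri.montecarlo import DetectedPhotons

        paths = np.zeros((1, 8))
        paths[0, 0] = 1000.0
        det = DetectedPhotons(
            exit_x=np.array([2], dtype=np.int32),
            exit_y=np.array([3], dtype=np.int32),
            direction=np.array([[0.0, 0.0, -1.0]]),
            pathlengths_um=paths, boost=np.ones(1),
            weight_at_exit=np.array([np.exp(-1.0)]),
            photons_launched=1, grid_shape=(5, 5), voxel_size_um=1.0,
            media_names=tuple(f"m{i}" for i in range(8)), tallies={})
        img = render_reflectance(det, np.array([1.0] + [0.0] * 7))
        assert img.grid[2, 3] == pytest.approx(np.exp(-1.0), rel=1e-12)

    def test_rendered_weight_matches_inflight_weight(
            self, scattering_slab_run):
        volume, det = scattering_slab_run
        mua, _, _, _ = volume.media_arrays()
        w = det.inflight_weight(mua)
        assert np.allclose(w, det.weight_at_exit, rtol=1e-9, atol=0)

    def test_reflectance_monotone_in_any_medium_absorption(
            self, scattering_slab_run):
        _, det = scattering_slab_run
        mua = np.full(8, 0.2)
        base = render_reflectance(det, mua).grid.sum()
        prev = base
        for extra in (0.5, 1.0, 2.0):
            stronger = mua.copy()
            stronger[0] = extra
            total = render_reflectance(det, stronger).grid.sum()
            assert total <= prev
            prev = total

    def test_negative_absorption_rejected(self, scattering_slab_run):
        _, det = scattering_slab_run
        with pytest.raises(ValueError, match=">= 0"):
            render_reflectance(det, np.full(8, -1.0))

    def test_hdf5_round_trip(self, scattering_slab_run, tmp_path):
        _, det = scattering_slab_run
        path = tmp_path / "detected.h5"
        det.to_hdf5(path)
        from spdri.montecarlo import DetectedPhotons

        back = DetectedPhotons.from_hdf5(path)
        assert np.array_equal(back.exit_x, det.exit_x)
        assert np.array_equal(back.pathlengths_um, det.pathlengths_um)
        assert back.photons_launched == det.photons_launched
        assert back.tallies == pytest.approx(det.tallies)
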