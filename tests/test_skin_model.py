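import numpy as np
import pytest

from spdri import (
    BLOOD_LABEL,
    GeometryConfig,
    GeometryError,
    OpticalProperties,
    VesselElement,
    build_tissue_volume,
    desk_preset,
    measure_plexus_cross_section,
    paper_preset,
)
from spdri.presets import default_blood, default_layers
from spdri.skin_model import build_shelled_volume, shell_mu_a_map


def small_geometry(vessels, dims=(100, 100, 200)):
    return GeometryConfig(dims=dims, voxel_size_um=1.0,
                          vessels=tuple(vessels),
                          source_positions=((10.0, 10.0), (10.0, 20.0)))


def single_limb_loop(x=50.0, y=50.0, z=(20.0, 170.0), diameter=10.0):
    return VesselElement("capillary_loop", (x, x), (y, y), z, diameter)


class TestLayers:
    def test_layer_boundaries_are_constant_z_planes(self):
        vol = build_tissue_volume(small_geometry([]), default_layers(),
                                  default_blood())
        # every (x, y) column carries the same layer sequence
        col = vol.labels[0, 0, :]
        assert np.all(vol.labels == col[np.newaxis, np.newaxis, :])
        # labels are non-decreasing with depth (stacked slabs)
        assert np.all(np.diff(col.astype(int)) >= 0)

    def test_deepest_layer_trimmed_to_volume(self):
        vol = build_tissue_volume(small_geometry([]), default_layers(),
                                  default_blood())
        assert vol.layer_boundaries_vox[-1] == vol.dims[2]

    def test_too_thin_stack_rejected(self):
        layers = default_layers()
        thin = [l.__class__(l.name, 1.0, l.props) for l in layers]
        with pytest.raises(ValueError, match="deep"):
            build_tissue_volume(small_geometry([]), thin, default_blood())


class TestVessels:
    def test_plexus_cross_section_is_30_um(self):
        preset = desk_preset()
        vol = build_tissue_volume(preset.geometry(10.0), preset.layers(),
                                  default_blood())
        assert measure_plexus_cross_section(vol) == pytest.approx(30.0)

    def test_zero_diameter_loops_leave_plain_layered_volume(self):
        preset = desk_preset()
        geo = preset.geometry(0.0)
        vol = build_tissue_volume(geo, preset.layers(), default_blood())
        plexus_only = GeometryConfig(
            dims=geo.dims, voxel_size_um=geo.voxel_size_um,
            vessels=tuple(v for v in geo.vessels if v.kind == "plexus_leg"),
            source_positions=geo.source_positions)
        ref = build_tissue_volume(plexus_only, preset.layers(),
                                  default_blood())
        assert np.array_equal(vol.labels, ref.labels)

    def test_cylinder_voxel_count_matches_analytic_volume(self):
        # degenerate loop: a single vertical cylinder, diameter 10, length 150
        vol = build_tissue_volume(small_geometry([single_limb_loop()]),
                                  default_layers(), default_blood())
        count = int(vol.blood_mask().sum())
        analytic = np.pi * 5.0**2 * 150.0
        assert abs(count - analytic) / analytic < 0.10

    def test_labeling_independent_of_insertion_order(self):
        loops = [single_limb_loop(x=30.0), single_limb_loop(x=70.0)]
        a = build_tissue_volume(small_geometry(loops), default_layers(),
                                default_blood())
        b = build_tissue_volume(small_geometry(loops[::-1]), default_layers(),
                                default_blood())
        assert np.array_equal(a.labels, b.labels)

    def test_discretization_convergence_of_blood_fraction(self):
        coarse_geo = GeometryConfig(
            dims=(60, 60, 80), voxel_size_um=1.0,
            vessels=(single_limb_loop(x=30.0, y=30.0, z=(10.0, 70.0),
                                      diameter=10.0),),
            source_positions=((5.0, 5.0), (5.0, 10.0)))
        fine_geo = GeometryConfig(
            dims=(120, 120, 160), voxel_size_um=0.5,
            vessels=(VesselElement("capillary_loop", (60.0, 60.0),
                                   (60.0, 60.0), (20.0, 140.0), 10.0),),
            source_positions=((10.0, 10.0), (10.0, 20.0)))
        coarse = build_tissue_volume(coarse_geo, default_layers(),
                                     default_blood())
        fine = build_tissue_volume(fine_geo, default_layers(),
                                   default_blood())
        f0 = coarse.blood_volume_fraction()
        f1 = fine.blood_volume_fraction()
        assert abs(f1 - f0) / f0 < 0.05

    def test_default_geometry_has_six_loops_and_two_legs(self):
        geo = paper_preset().geometry(10.0)
        kinds = [v.kind for v in geo.vessels]
        assert kinds.count("capillary_loop") == 6
        assert kinds.count("plexus_leg") == 2

    def test_vessel_outside_bounds_rejected(self):
        bad = single_limb_loop(x=99.0)  # radius 5 pokes past x = 100
        with pytest.raises(GeometryError, match="outside"):
            build_tissue_volume(small_geometry([bad]), default_layers(),
                                default_blood())

    def test_overlapping_loops_rejected(self):
        loops = [single_limb_loop(x=50.0), single_limb_loop(x=53.0)]
        with pytest.raises(GeometryError, match="overlap"):
            build_tissue_volume(small_geometry(loops), default_layers(),
                                default_blood())


class TestShelledVolume:
    def test_shells_nest_and_render_maps_switch_at_diameter(self):
        diams = (4.0, 8.0, 12.0)
        geoms = [
            (d, small_geometry([single_limb_loop(diameter=d)]))
            for d in diams
        ]
        vol = build_shelled_volume(geoms, default_layers(), default_blood(),
                                   OpticalProperties(0.5, 35.0, 0.85, 1.39))
        counts = [int((vol.labels == BLOOD_LABEL + 1 + i).sum())
                  for i in range(3)]
        assert all(c > 0 for c in counts)
        # cumulative shell voxels match the plain volumes per diameter
        for i, d in enumerate(diams):
            plain = build_tissue_volume(geoms[i][1], default_layers(),
                                        default_blood())
            shelled = sum(counts[:i + 1])
            assert shelled == int(plain.blood_mask().sum())
        mua = shell_mu_a_map(vol, 8.0, blood_mu_a=150.0,
                             shell_background_mu_a=0.5)
        names = vol.media_names
        assert mua[names.index("capillary_shell_4um")] == 150.0
        assert mua[names.index("capillary_shell_8um")] == 150.0
        assert mua[names.index("capillary_shell_12um")] == 0.5


class TestOpticalProperties:
    def test_reduced_scattering_is_derived_exactly(self):
        p = OpticalProperties(mu_a=1.0, mu_s=10.0, g=0.9, n=1.4)
        assert p.mu_s_prime == 10.0 * (1.0 - 0.9)

    @pytest.mark.parametrize("kwargs", [
        dict(mu_a=-0.1, mu_s=1.0, g=0.5, n=1.4),
        dict(mu_a=0.1, mu_s=-1.0, g=0.5, n=1.4),
        dict(mu_a=0.1, mu_s=1.0, g=1.0, n=1.4),
        dict(mu_a=0.1, mu_s=1.0, g=0.5, n=0.9),
    ])
    def test_invalid_values_rejected(self, kwargs):
        with pytest.raises(ValueError):
            OpticalProperties(**kwargs)
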