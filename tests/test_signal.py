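import numpy as np
import pytest

from spdri import compute_knorm, compute_spdri, extract_profile
from spdri.montecarlo import ReflectanceImage
from spdri.signal import SignalProfile


def image(grid):
    return ReflectanceImage(grid=np.asarray(grid, dtype=float),
                            photons_launched=1, mu_a_used=np.zeros(8))


def dense_image(nx=200, ny=960, base=2.0, seed=0):
    rng = np.random.default_rng(seed)
    return image(base + 0.1 * rng.random((nx, ny)))


def profile_from(vals, mask=None):
    vals = np.asarray(vals, dtype=float)
    if mask is None:
        mask = np.ones(vals.size, dtype=bool)
    return SignalProfile(x_position=0, values=vals, mask=mask,
                         savgol_order=0, savgol_frame=1)


class TestRatioImage:
    def test_identical_images_give_unit_ratio(self):
        img = dense_image()
        out = compute_spdri(img, img, (0, 0), smoothing_sigma=0)
        assert np.allclose(out.ratio[out.mask], 1.0)
        out_s = compute_spdri(img, img, (0, 0), smoothing_sigma=3)
        assert np.allclose(out_s.ratio[out_s.mask], 1.0)

    def test_perturbation_localised_before_smoothing(self):
        a = dense_image()
        b_grid = a.grid.copy()
        cap = np.s_[40:60, 200:260]
        b_grid[cap] *= 1.1
        out = compute_spdri(a, image(b_grid), (0, 0), smoothing_sigma=0)
        dev = np.abs(out.raw_ratio - 1.0) > 1e-12
        expected = np.zeros_like(dev)
        expected[cap] = True
        assert np.array_equal(dev, expected)

    def test_reciprocal_symmetry_of_raw_ratio(self):
        a, b = dense_image(seed=1), dense_image(seed=2)
        ab = compute_spdri(a, b, (0, 30), smoothing_sigma=0)
        ba = compute_spdri(b, a, (0, -30), smoothing_sigma=0)
        # align the two overlap regions: ab[x, y] pairs with ba[x, y + 30]
        prod = ab.raw_ratio[:, :-30] * ba.raw_ratio[:, 30:]
        ok = ab.mask[:, :-30] & ba.mask[:, 30:]
        assert np.allclose(prod[ok], 1.0, rtol=1e-12)

    def test_shift_aligns_source_positions(self):
        # a bright source spot at (10, 20) in a, shifted to (10, 50) in b
        a = np.ones((60, 80))
        b = np.ones((60, 80))
        a[10, 20] = 9.0
        b[10, 50] = 9.0
        out = compute_spdri(image(a), image(b), (0, 30), smoothing_sigma=0)
        assert out.raw_ratio[10, 20] == pytest.approx(1.0)

    def test_dimension_mismatch_and_excess_shift_rejected(self):
        a = dense_image(nx=50, ny=50)
        with pytest.raises(ValueError, match="differ"):
            compute_spdri(a, dense_image(nx=40, ny=50), (0, 0))
        with pytest.raises(ValueError, match="shift"):
            compute_spdri(a, dense_image(nx=50, ny=50), (0, 50))

    def test_sparse_images_stay_defined_through_smoothing(self):
        rng = np.random.default_rng(7)
        a = np.zeros((80, 300))
        b = np.zeros((80, 300))
        # a fraction of a photon per pixel on average
        for g in (a, b):
            idx = rng.integers(0, g.size, size=2000)
            np.add.at(g.ravel(), idx, 1.0)
        out = compute_spdri(image(a), image(b), (0, 20), smoothing_sigma=3)
        assert out.mask.sum() > 0.8 * 80 * 280
        assert np.isfinite(out.ratio[out.mask]).all()


class TestProfileExtraction:
    def test_constant_image_gives_constant_profile(self):
        img = image(np.full((40, 960), 3.0))
        sp = compute_spdri(img, img, (0, 0), smoothing_sigma=0)
        prof = extract_profile(sp, 20, savgol_frame=151)
        assert np.allclose(prof.values[prof.mask], 1.0, rtol=1e-12)

    def test_quintic_polynomial_reproduced_exactly(self):
        y = np.arange(960, dtype=float)
        poly = (100.0 + 1e-12 * (y - 480) ** 5 - 3e-8 * (y - 480) ** 3
                + 2e-2 * y)
        sp_img = compute_spdri(image(np.tile(poly, (10, 1))),
                               image(np.ones((10, 960))), (0, 0),
                               smoothing_sigma=0)
        prof = extract_profile(sp_img, 5, savgol_order=5, savgol_frame=151)
        interior = slice(75, -75)
        assert np.allclose(prof.values[interior], poly[interior],
                           rtol=1e-9, atol=1e-9)

    def test_masked_gap_interpolated_before_filtering(self):
        grid = np.full((10, 400), 2.0)
        grid[5, 100:120] = 0.0  # empty pixels -> masked
        sp = compute_spdri(image(grid), image(np.full((10, 400), 2.0)),
                           (0, 0), smoothing_sigma=0)
        prof = extract_profile(sp, 5, savgol_frame=51)
        assert np.allclose(prof.values[prof.mask], 1.0, rtol=1e-9)

    def test_frame_exceeding_span_rejected(self):
        img = image(np.full((10, 100), 1.0))
        sp = compute_spdri(img, img, (0, 0), smoothing_sigma=0)
        with pytest.raises(ValueError, match="frame length"):
            extract_profile(sp, 5, savgol_frame=151)


def triangle_profile(h=0.5, w=30, apex=200, n=500, baseline=1.0):
    y = np.arange(n, dtype=float)
    vals = np.full(n, baseline)
    rise = (y >= apex - w) & (y <= apex)
    fall = (y > apex) & (y <= apex + w)
    vals[rise] = baseline + h * (y[rise] - (apex - w)) / w
    vals[fall] = baseline + h * ((apex + w) - y[fall]) / w
    return profile_from(vals)


class TestKnorm:
    def test_constant_profile_has_no_extrema(self):
        res = compute_knorm(profile_from(np.ones(300)), [150.0])
        assert res.entries[0].missing
        assert res.n_missing == 1

    def test_triangle_bump_area_closed_form(self):
        h, w = 0.5, 30
        res = compute_knorm(triangle_profile(h=h, w=w), [200.0],
                            search_window=80)
        k = res.entries[0].k_norm
        assert k == pytest.approx(h * w / 2, rel=0.02)

    def test_area_linear_in_modulation_amplitude(self):
        base = triangle_profile(h=1.0, w=30).values
        ks = []
        for c in (0.5, 1.0, 2.0, 3.7):
            scaled = profile_from(1.0 + c * (base - 1.0))
            res = compute_knorm(scaled, [200.0], search_window=80)
            ks.append(res.entries[0].k_norm)
        ratios = np.array(ks) / np.array([0.5, 1.0, 2.0, 3.7])
        assert np.allclose(ratios, ratios[0], rtol=1e-6)

    def test_invariant_under_constant_offset(self):
        p = triangle_profile()
        k0 = compute_knorm(p, [200.0], search_window=80).entries[0].k_norm
        shifted = profile_from(p.values + 5.0)
        k1 = compute_knorm(shifted, [200.0],
                           search_window=80).entries[0].k_norm
        assert k1 == pytest.approx(k0, rel=1e-12)

    def test_strictly_increasing_with_amplitude(self):
        from spdri import generate_surrogate_profile

        ks = []
        for amp in (0.01, 0.02, 0.05, 0.1, 0.2):
            prof = generate_surrogate_profile(
                10.0, [300.0], amplitude_per_um=amp, noise_sd=0.0)
            res = compute_knorm(prof, [300.0], search_window=60)
            ks.append(res.entries[0].k_norm)
        assert np.all(np.diff(ks) > 0)

    def test_max_precedes_min(self):
        from spdri import generate_surrogate_profile

        prof = generate_surrogate_profile(8.0, [300.0, 600.0],
                                          amplitude_per_um=0.05)
        res = compute_knorm(prof, [300.0, 600.0])
        for e in res.entries:
            assert e.max_location < e.min_location

    def test_empty_profile_rejected(self):
        empty = profile_from(np.full(100, np.nan),
                             mask=np.zeros(100, dtype=bool))
        with pytest.raises(ValueError, match="empty"):
            compute_knorm(empty, [50.0])
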