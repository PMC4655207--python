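import numpy as np
import pytest
from scipy.ndimage import distance_transform_edt

import perfseg as ps
import perfseg.geometry as geo
from conftest import circle_contour, ellipse_contour


class TestContour:
    def test_orientation_enforced(self):
        ang = np.linspace(-np.pi, np.pi, 12, endpoint=False)
        cw = np.column_stack([np.cos(-ang), -np.sin(-ang)]) * 10 + 20
        c = ps.Contour(cw)
        assert geo._polygon_area(c.vertices) > 0

    def test_too_few_vertices(self):
        with pytest.raises(geo.GeometryError):
            ps.Contour(np.array([[0, 0], [1, 1]]))

    def test_circle_area_and_centroid(self):
        c = circle_contour(15.0, center=(40, 25))
        assert c.area == pytest.approx(np.pi * 225, rel=1e-3)
        np.testing.assert_allclose(c.centroid, [40, 25], atol=1e-9)


class TestContractAnnulus:
    def test_concentric_circles_closed_form(self):
        en, ep = ps.contract_annulus(circle_contour(20), circle_contour(30), 0.10)
        ang = np.linspace(-np.pi, np.pi, 50)
        np.testing.assert_allclose(en.radii_at(ang), 21.0, rtol=1e-9)
        np.testing.assert_allclose(ep.radii_at(ang), 29.0, rtol=1e-9)

    def test_zero_fraction_identity(self):
        endo, epi = circle_contour(20), circle_contour(30)
        en, ep = ps.contract_annulus(endo, epi, 0.0)
        assert en is endo and ep is epi

    def test_invalid_fraction(self):
        with pytest.raises(geo.GeometryError):
            ps.contract_annulus(circle_contour(20), circle_contour(30), 0.6)

    def test_ellipse_area_vs_rasterization_oracle(self):
        endo = ellipse_contour(14, 10, n=256)
        epi = ellipse_contour(24, 19, n=256)
        en, ep = ps.contract_annulus(endo, epi, 0.10, n_points=720)
        analyzed = en.area, ep.area
        # oracle: dense pixel rasterization by transmural depth along rays
        yy, xx = np.mgrid[0:641, 0:641] / 10.0  # 0.1 px sampling
        c = endo.centroid
        theta = np.arctan2(-(yy - c[1]), xx - c[0])
        r = np.hypot(xx - c[0], yy - c[1])
        r_en = endo.radii_at(theta.ravel(), c).reshape(theta.shape)
        r_ep = epi.radii_at(theta.ravel(), c).reshape(theta.shape)
        depth = (r - r_en) / (r_ep - r_en)
        annulus_area = np.count_nonzero((depth >= 0.1) & (depth <= 0.9)) * 0.01
        assert (analyzed[1] - analyzed[0]) == pytest.approx(annulus_area, rel=0.01)

    def test_contraction_monotone_in_fraction(self):
        endo, epi = ellipse_contour(12, 9), ellipse_contour(20, 17)
        areas = []
        for f in (0.05, 0.10, 0.20, 0.30):
            en, ep = ps.contract_annulus(endo, epi, f)
            areas.append(ep.area - en.area)
        assert np.all(np.diff(areas) < 0)


class TestAhaSectorMasks:
    def test_partition_is_exact(self):
        seg = ps.aha_sector_masks(
            circle_contour(10), circle_contour(16), np.deg2rad(150), "basal", (64, 64)
        )
        union = np.zeros((64, 64), bool)
        total = 0
        for m in seg.masks.values():
            assert not (union & m).any()  # pairwise disjoint
            union |= m
            total += m.sum()
        assert (union == seg.annulus).all()
        assert total == seg.annulus.sum()

    def test_equal_sector_areas_on_circle(self):
        seg = ps.aha_sector_masks(
            circle_contour(14), circle_contour(22), 0.3, "basal", (64, 64)
        )
        areas = np.array([m.sum() for m in seg.masks.values()])
        assert np.all(np.abs(areas - areas.mean()) / areas.mean() < 0.02)

    def test_rotation_permutes_basal_masks(self):
        a = ps.aha_sector_masks(
            circle_contour(10), circle_contour(16), 0.0, "basal", (64, 64)
        )
        b = ps.aha_sector_masks(
            circle_contour(10), circle_contour(16), np.deg2rad(60), "basal", (64, 64)
        )
        # rotating the insertion by one sector shifts each label to the
        # previous bin: bin j of b equals bin j+1 of a
        order = geo.AHA_BIN_IDS["basal"]
        for j, sid in enumerate(order):
            nxt = order[(j + 1) % 6]
            assert (b.masks[sid] == a.masks[nxt]).all()

    def test_star_convex_contours_match_pixel_binning_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            ang = np.linspace(-np.pi, np.pi, 180, endpoint=False)
            wob = 1 + 0.15 * np.sin(3 * ang + rng.uniform(0, 6)) \
                + 0.1 * np.cos(5 * ang + rng.uniform(0, 6))
            c = (32.0, 32.0)
            endo = ps.Contour(np.column_stack(
                [c[0] + 9 * wob * np.cos(ang), c[1] - 9 * wob * np.sin(ang)]))
            epi = ps.Contour(np.column_stack(
                [c[0] + 16 * wob * np.cos(ang), c[1] - 16 * wob * np.sin(ang)]))
            rv = rng.uniform(0, 2 * np.pi)
            seg = ps.aha_sector_masks(endo, epi, rv, "mid", (64, 64))
            ann = geo.annulus_mask(endo, epi, (64, 64))
            # independent pixelwise binning
            ce = endo.centroid
            yy, xx = np.nonzero(ann)
            phi = np.mod(np.arctan2(-(yy - ce[1]), xx - ce[0]) - rv, 2 * np.pi)
            bins = np.minimum((phi / (np.pi / 3)).astype(int), 5)
            for j, sid in enumerate(geo.AHA_BIN_IDS["mid"]):
                expect = np.zeros((64, 64), bool)
                sel = bins == j
                expect[yy[sel], xx[sel]] = True
                assert (seg.masks[sid] == expect).all()

    def test_apical_has_four_sectors(self):
        seg = ps.aha_sector_masks(
            circle_contour(8), circle_contour(13), 0.0, "apical", (64, 64)
        )
        assert seg.segment_ids == (13, 14, 15, 16)


class TestWallThickness:
    def test_uniform_circle_thickness(self):
        prof = ps.wall_thickness_profile(
            circle_contour(20), circle_contour(30), n_rays=90, pixel_spacing=1.0
        )
        np.testing.assert_allclose(prof.thickness, 10.0, rtol=1e-6)
        assert prof.max_ivs == pytest.approx(10.0, rel=1e-6)

    def test_locally_widened_sector(self):
        ang = np.linspace(-np.pi, np.pi, 360, endpoint=False)
        rv = np.deg2rad(150.0)
        phi = np.mod(ang - rv, 2 * np.pi)
        sel = (phi >= np.deg2rad(80)) & (phi < np.deg2rad(120))
        r_ep = np.where(sel, 37.0, 30.0)
        epi = ps.Contour(np.column_stack(
            [32 + r_ep * np.cos(ang), 32 - r_ep * np.sin(ang)]))
        prof = ps.wall_thickness_profile(
            circle_contour(20), epi, n_rays=360, pixel_spacing=1.0,
            rv_insertion_angle=rv,
        )
        assert prof.max_ivs == pytest.approx(17.0, abs=0.2)
        assert prof.max_pw == pytest.approx(10.0, abs=0.2)

    def test_bumped_annulus_vs_distance_transform_oracle(self):
        # smooth bump; compare ray thickness against twice the maximal
        # inscribed-disc radius (EDT) along each ray
        shape = (256, 256)
        ang = np.linspace(-np.pi, np.pi, 720, endpoint=False)
        r_en = np.full_like(ang, 60.0)
        r_ep = 85.0 + 8.0 * np.exp(-((np.mod(ang, 2 * np.pi) - 1.0) ** 2) / 0.18)
        c = (128.0, 128.0)
        endo = ps.Contour(np.column_stack(
            [c[0] + r_en * np.cos(ang), c[1] - r_en * np.sin(ang)]))
        epi = ps.Contour(np.column_stack(
            [c[0] + r_ep * np.cos(ang), c[1] - r_ep * np.sin(ang)]))
        prof = ps.wall_thickness_profile(endo, epi, n_rays=72, pixel_spacing=1.0)
        ann = geo.annulus_mask(endo, epi, shape)
        edt = distance_transform_edt(ann)
        for a, th in zip(prof.angles, prof.thickness):
            r_mid = 0.5 * (endo.radii_at(np.array([a]))[0] + epi.radii_at(np.array([a]))[0])
            x = int(round(c[0] + r_mid * np.cos(a)))
            y = int(round(c[1] - r_mid * np.sin(a)))
            local = 2.0 * edt[max(0, y - 2):y + 3, max(0, x - 2):x + 3].max()
            assert th == pytest.approx(local, abs=2.0)

    def test_rotation_invariance(self):
        ang = np.linspace(-np.pi, np.pi, 360, endpoint=False)
        bump = 30 + 4 * np.cos(2 * ang)
        rot = np.deg2rad(37.0)
        epi0 = ps.Contour(np.column_stack(
            [32 + bump * np.cos(ang), 32 - bump * np.sin(ang)]))
        epi1 = ps.Contour(np.column_stack(
            [32 + bump * np.cos(ang + rot), 32 - bump * np.sin(ang + rot)]))
        p0 = ps.wall_thickness_profile(circle_contour(20), epi0, n_rays=120,
                                       rv_insertion_angle=0.0)
        p1 = ps.wall_thickness_profile(circle_contour(20), epi1, n_rays=120,
                                       rv_insertion_angle=rot)
        assert p0.max_ivs == pytest.approx(p1.max_ivs, abs=0.3)
        assert p0.max_pw == pytest.approx(p1.max_pw, abs=0.3)


class TestVolumesMassBsa:
    def test_single_slice_cylinder(self):
        ed = ps.ContourSet([circle_contour(25)], [circle_contour(30)],
                           pixel_spacing=1.0, slice_thickness=10.0)
        es = ps.ContourSet([circle_contour(25 * 0.8)], [circle_contour(28)],
                           pixel_spacing=1.0, slice_thickness=10.0)
        edv, esv, sv, ef = ps.lv_volumes(ed, es)
        assert edv == pytest.approx(np.pi * 625 * 10 / 1000, rel=2e-3)  # 19.63 ml

    def test_ed_equals_es(self):
        ed = ps.ContourSet([circle_contour(25)], [circle_contour(30)])
        edv, esv, sv, ef = ps.lv_volumes(ed, ed)
        assert sv == 0.0 and ef == 0.0

    def test_stacked_ellipses_vs_voxel_oracle(self):
        endo = [ellipse_contour(20, 14, n=256, slice_index=i) for i in range(3)]
        epi = [ellipse_contour(28, 22, n=256, slice_index=i) for i in range(3)]
        ed = ps.ContourSet(endo, epi, pixel_spacing=1.0, slice_thickness=8.0)
        vox = 0.0
        scale = 4
        for c in endo:
            big = ps.Contour(c.vertices * scale)
            vox += geo.contour_mask(big, (64 * scale, 64 * scale)).sum() / scale**2
        vol_oracle = vox * 8.0 / 1000.0
        edv, *_ = ps.lv_volumes(ed, ed)
        assert edv == pytest.approx(vol_oracle, rel=0.015)

    def test_mass_density_conversion(self):
        # 100 ml myocardial volume -> 105 g at 1.05 g/ml
        r_en = 20.0
        area = 100_000.0 / 10.0  # mm^2 per slice for 100 ml at 10 mm thickness
        r_ep = np.sqrt(area / np.pi + r_en**2)
        cs = ps.ContourSet([circle_contour(r_en, n=4096)],
                           [circle_contour(r_ep, n=4096)],
                           pixel_spacing=1.0, slice_thickness=10.0)
        assert ps.lv_mass(cs) == pytest.approx(105.0, rel=1e-4)

    def test_mass_vanishes_for_thin_annulus(self):
        cs = ps.ContourSet([circle_contour(20)], [circle_contour(20.001)])
        assert ps.lv_mass(cs) < 0.01

    def test_mass_vs_voxel_oracle(self):
        endo = [circle_contour(14, n=256, slice_index=i) for i in range(3)]
        epi = [circle_contour(22, n=256, slice_index=i) for i in range(3)]
        cs = ps.ContourSet(endo, epi, pixel_spacing=1.0, slice_thickness=10.0)
        scale = 4
        vox = 0.0
        for en, ep in zip(endo, epi):
            m = geo.contour_mask(ps.Contour(ep.vertices * scale), (256, 256)) \
                & ~geo.contour_mask(ps.Contour(en.vertices * scale), (256, 256))
            vox += m.sum() / scale**2
        oracle = vox * 10.0 / 1000.0 * 1.05
        assert ps.lv_mass(cs) == pytest.approx(oracle, rel=0.015)

    def test_bsa_mosteller_and_indexing(self):
        assert ps.bsa(180, 72) == pytest.approx(np.sqrt(180 * 72 / 3600), rel=1e-12)
        assert ps.bsa(180, 72) == pytest.approx(1.897, abs=5e-4)
        assert ps.index_by_bsa(190.0, 2.0) == 95.0

    def test_bsa_monotone_in_height_and_weight(self):
        hs = np.linspace(120, 200, 9)
        ws = np.linspace(30, 110, 9)
        for formula in ("mosteller", "dubois"):
            grid = np.array([[ps.bsa(h, w, formula) for w in ws] for h in hs])
            assert np.all(np.diff(grid, axis=0) > 0)
            assert np.all(np.diff(grid, axis=1) > 0)

    def test_bsa_invalid(self):
        with pytest.raises(ValueError):
            ps.bsa(-1, 70)
        with pytest.raises(ValueError):
            ps.bsa(170, 70, "haycock")


class TestMatchSlices:
    def test_identity(self):
        assert ps.match_slices([0, 10, 20], [0, 10, 20]) == [(0, 0), (1, 1), (2, 2)]

    def test_small_offsets_all_paired(self):
        pairs = ps.match_slices([0, 10, 20], [2, 12, 22], tolerance=5.0)
        assert pairs == [(0, 0), (1, 1), (2, 2)]

    def test_beyond_tolerance_unpaired(self):
        pairs = ps.match_slices([0, 10, 40], [0, 10, 20], tolerance=5.0)
        assert (2, 2) not in pairs and len(pairs) == 2

    def test_cost_matches_exhaustive_assignment_on_slice_stacks(self):
        from itertools import permutations

        rng = np.random.default_rng(3)
        for _ in range(20):
            n = int(rng.integers(3, 7))
            base = np.arange(n) * 10.0
            a = base + rng.uniform(-2, 2, n)
            b = base + rng.uniform(-2, 2, n)
            pairs = ps.match_slices(a, b, tolerance=5.0)
            cost = sum(abs(a[i] - b[j]) for i, j in pairs)
            best = min(
                sum(abs(a[i] - b[p[i]]) for i in range(n))
                for p in permutations(range(n))
            )
            assert len(pairs) == n
            assert cost == pytest.approx(best, abs=1e-9)
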