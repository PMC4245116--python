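"""Characteristic extraction: color, geometry, tip color, white region."""

import dataclasses

import numpy as np
import pytest

from ricedeficit import features, registry, synth
from ricedeficit.features import (
    MissingOrgan,
    boundary_chain_counts,
    color_means,
    lightness,
    shape_descriptors,
    tip_color,
    whiteness_area,
)
from ricedeficit.segment import LeafScan, SegmentedObject, segment_object

from conftest import noise_free


def make_object(img, dpi=300, kind="leaf"):
    return segment_object(LeafScan(np.asarray(img, np.uint8), dpi, kind, 1))


def raw_object(mask, img, dpi=300, kind="leaf"):
    """SegmentedObject built directly (bypassing thresholds) for color tests."""
    coords = np.argwhere(mask)
    return SegmentedObject(
        mask=mask,
        source=LeafScan(np.asarray(img, np.uint8), dpi, kind, 1),
        centroid=tuple(coords.mean(axis=0)),
        axis=np.array([0.0, 1.0]),
        tip_end=tuple(coords[coords[:, 1].argmax()]),
        base_end=tuple(coords[coords[:, 1].argmin()]),
    )


def disc_image(r=100, color=(60, 110, 45)):
    n = 2 * r + 21
    yy, xx = np.mgrid[:n, :n]
    mask = (yy - n // 2) ** 2 + (xx - n // 2) ** 2 <= r * r
    img = np.full((n, n, 3), 250, np.uint8)
    img[mask] = color
    return img


def rect_image(h=30, w=300, color=(60, 110, 45)):
    img = np.full((h + 20, w + 20, 3), 250, np.uint8)
    img[10 : 10 + h, 10 : 10 + w] = color
    return img


class TestColor:
    def test_uniform_color_mean(self):
        obj = make_object(rect_image(color=(10, 200, 30)))
        assert color_means(obj) == pytest.approx((10, 200, 30))

    def test_black_white_halves(self):
        mask = np.zeros((10, 10), bool)
        mask[2:8, 2:8] = True
        img = np.zeros((10, 10, 3), np.uint8)
        img[:, 5:] = 255
        obj = raw_object(mask, img)
        assert color_means(obj) == pytest.approx((127.5, 127.5, 127.5))

    def test_gradient_mean_matches_pixel_loop(self, profiles):
        prof = noise_free(profiles["Ndef"])
        scan = synth.render_leaf(prof, 3, 100, np.random.default_rng(0))
        obj = segment_object(scan)
        # independent oracle: explicit loop over masked pixels
        total = np.zeros(3)
        count = 0
        for r, c in np.argwhere(obj.mask):
            total += scan.pixels[r, c]
            count += 1
        assert color_means(obj) == pytest.approx(tuple(total / count))

    @pytest.mark.parametrize(
        "mode,expected", [("mean", 120.0), ("hsl", 120.0)]
    )
    def test_lightness_modes(self, mode, expected):
        obj = make_object(rect_image(color=(60, 120, 180)))
        assert lightness(obj, mode) == pytest.approx(expected)

    def test_lightness_black(self):
        mask = np.zeros((8, 8), bool)
        mask[2:6, 2:6] = True
        obj = raw_object(mask, np.zeros((8, 8, 3)))
        assert lightness(obj) == 0.0


class TestShapeOracles:
    def test_disc_descriptors(self):
        d = shape_descriptors(make_object(disc_image()))
        for key in ("CI", "FF", "AC"):
            assert 0.95 <= d[key] <= 1.05, key
        assert d["RE"] == pytest.approx(np.pi / 4, abs=0.02)

    def test_rectangle_descriptors(self):
        d = shape_descriptors(make_object(rect_image()))
        assert 0.98 <= d["RE"] <= 1.02
        assert d["EC"] == pytest.approx(10.0, rel=0.03)
        assert d["LL"] == pytest.approx(2.54, rel=0.02)
        assert d["LW"] == pytest.approx(0.254, abs=2.54 / 300)

    def test_rotated_rectangle_length(self):
        from scipy.ndimage import rotate

        img = rect_image()
        rot = rotate(img, 45, reshape=True, order=0, mode="constant", cval=250)
        d = shape_descriptors(make_object(rot))
        assert d["LL"] == pytest.approx(2.54, rel=0.03)
        assert d["LW"] == pytest.approx(0.254, rel=0.05)

    def test_dimensionless_exact_under_rot90(self, profiles):
        scan = synth.render_leaf(
            noise_free(profiles["Kdef"]), 3, 75, np.random.default_rng(0)
        )
        a = shape_descriptors(segment_object(scan))
        rot = LeafScan(np.rot90(scan.pixels).copy(), 75, "leaf", 3)
        b = shape_descriptors(segment_object(rot))
        for key in ("RE", "AC", "CI", "FF"):
            assert a[key] == pytest.approx(b[key], rel=1e-9), key

    @staticmethod
    def _rotated_leaf_mask(angle_deg, length=8.0, width=2.5, dpi=75):
        """Rasterize the same analytic leaf outline at a given orientation.

        Rotating a raster image would genuinely lengthen its boundary
        (staircase excursions), so the invariance check rotates the
        geometry before rasterization instead.
        """
        from skimage.draw import polygon as draw_polygon

        from ricedeficit.synth import _leaf_profile, _profile_polygon

        poly = _profile_polygon(*_leaf_profile(length, width))
        pts = np.asarray(poly.exterior.coords)[:-1]
        th = np.radians(angle_deg)
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        pts = pts @ rot.T * (dpi / 2.54)
        pts -= pts.min(axis=0) - 10
        shape = (int(pts[:, 1].max()) + 11, int(pts[:, 0].max()) + 11)
        mask = np.zeros(shape, bool)
        rr, cc = draw_polygon(pts[:, 1], pts[:, 0], shape=shape)
        mask[rr, cc] = True
        img = np.full(shape + (3,), 250, np.uint8)
        img[mask] = (60, 110, 45)
        return img

    def test_dimensionless_stable_under_rot30(self):
        a = shape_descriptors(make_object(self._rotated_leaf_mask(0), dpi=75))
        b = shape_descriptors(make_object(self._rotated_leaf_mask(30), dpi=75))
        for key in ("RE", "AC", "CI", "FF"):
            assert b[key] == pytest.approx(a[key], rel=0.03), key

    def test_convex_mask_area_convexity(self):
        d = shape_descriptors(make_object(disc_image(r=40)))
        assert 0.97 <= d["AC"] <= 1.03

    def test_scale_invariance_across_dpi(self, profiles):
        prof = noise_free(profiles["Pdef"])
        rng = np.random.default_rng(0)
        lo = shape_descriptors(
            segment_object(synth.render_leaf(prof, 3, 75, rng))
        )
        hi = shape_descriptors(
            segment_object(synth.render_leaf(prof, 3, 150, rng))
        )
        for key in ("LL", "LW", "LA", "LP", "EC", "RE", "AC", "CI", "FF"):
            assert hi[key] == pytest.approx(lo[key], rel=0.03), key


def oracle_chain_counts(mask):
    """Brute-force Moore boundary walk, written independently."""
    pad = np.pad(mask, 1)
    fg = {tuple(p) for p in np.argwhere(pad)}
    start = min(fg)
    offs = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]
    cur, back = start, 6
    counts = [0, 0]
    seen_states = set()
    while True:
        nxt = None
        for k in range(1, 9):
            d = (back + k) % 8
            cand = (cur[0] + offs[d][0], cur[1] + offs[d][1])
            if cand in fg:
                nxt = (cand, d)
                break
        if nxt is None:
            return 0, 0
        state = (cur, nxt[1])
        if state in seen_states:
            return counts[0], counts[1]
        seen_states.add(state)
        counts[nxt[1] % 2] += 1
        back = (nxt[1] + 4) % 8
        cur = nxt[0]


class TestPerimeterWalk:
    @pytest.mark.parametrize("shape", ["disc", "rect", "ell"])
    def test_matches_bruteforce_walk(self, shape):
        if shape == "disc":
            mask = disc_image(r=12).min(axis=2) < 235
        elif shape == "rect":
            mask = np.zeros((30, 40), bool)
            mask[5:25, 4:36] = True
        else:
            mask = np.zeros((30, 30), bool)
            mask[5:25, 5:12] = True
            mask[18:25, 5:25] = True
        assert boundary_chain_counts(mask) == oracle_chain_counts(mask)

    def test_hull_area_against_shapely(self):
        from shapely import MultiPoint

        mask = disc_image(r=15).min(axis=2) < 235
        pts = features._boundary_corner_points(mask)
        from scipy.spatial import ConvexHull

        a = ConvexHull(pts).volume
        b = MultiPoint(pts).convex_hull.area
        assert a == pytest.approx(b, rel=1e-9)


class TestTipColor:
    def test_uniform_leaf_equals_color_means(self, profiles):
        scan = synth.render_leaf(
            noise_free(profiles["Normal"]), 3, 75, np.random.default_rng(0)
        )
        obj = segment_object(scan)
        assert tip_color(obj) == pytest.approx(color_means(obj))

    def test_painted_tip_window_recovered(self, profiles):
        scan = synth.render_leaf(
            noise_free(profiles["Normal"]), 3, 100, np.random.default_rng(0)
        )
        obj = segment_object(scan)
        coords = np.argwhere(obj.mask)
        s = coords.astype(float) @ obj.axis
        s_tip = np.asarray(obj.tip_end, float) @ obj.axis
        sel = np.abs(s - s_tip) <= 0.2 * (s.max() - s.min())
        img = scan.pixels.copy()
        img[coords[sel, 0], coords[sel, 1]] = (200, 180, 40)
        obj2 = segment_object(LeafScan(img, 100, "leaf", 3))
        assert tip_color(obj2) == pytest.approx((200, 180, 40), abs=2)

    def test_flip_invariance(self, profiles):
        scan = synth.render_leaf(
            noise_free(profiles["Kdef"]), 3, 75, np.random.default_rng(0)
        )
        a = tip_color(segment_object(scan))
        flipped = LeafScan(scan.pixels[:, ::-1].copy(), 75, "leaf", 3)
        b = tip_color(segment_object(flipped))
        assert a == pytest.approx(b, abs=0.5)


class TestWhiteRegion:
    def test_normal_sheath_zero(self, profiles):
        scan = synth.render_sheath(
            noise_free(profiles["Normal"]), 3, 75, np.random.default_rng(0)
        )
        assert whiteness_area(segment_object(scan)) == 0.0

    def test_truth_recovery(self, profiles):
        prof = dataclasses.replace(
            noise_free(profiles["Ndef"]), white_region_fraction=0.3
        )
        scan = synth.render_sheath(prof, 3, 300, np.random.default_rng(0))
        wra = whiteness_area(segment_object(scan))
        assert wra == pytest.approx(scan.meta["white_area_cm2"], rel=0.05)

    def test_unsatisfiable_threshold(self, profiles):
        scan = synth.render_sheath(
            noise_free(profiles["Ndef"]), 3, 75, np.random.default_rng(0)
        )
        assert whiteness_area(segment_object(scan), tau_white=256) == 0.0


class TestAssembly:
    def test_full_vector_finite_and_in_range(self, small_table):
        t = small_table
        assert list(t.columns[3:]) == registry.COLUMNS
        assert np.isfinite(t[registry.COLUMNS].to_numpy()).all()
        for col in ("f01_LR", "f02_LG", "f03_LB", "f13_LI", "f26_LTR",
                    "f29_LSR", "f30_LSG", "f31_LSB"):
            assert t[col].between(0, 255).all(), col
        for col in ("f04_LL", "f05_LW", "f06_LA", "f07_LP", "f14_LSL",
                    "f32_WRA"):
            assert (t[col] >= 0).all(), col
        assert t["f09_RE"].between(0, 1.05).all()
        assert t["f10_AC"].between(0, 1.05).all()
        assert (t["f08_EC"] >= 1).all()

    def test_cross_leaf_consistency(self, small_table):
        """Cross-leaf entries equal the arithmetic of per-position entries."""
        for sid, grp in small_table.groupby("sample_id"):
            g = grp.set_index("pos")
            ll = g["f04_LL"]
            lsl = g["f14_LSL"]
            row3 = g.loc[3]
            assert row3["f18_L23"] == pytest.approx(ll[2] - ll[3])
            assert row3["f19_L1_3"] == pytest.approx(ll[1] / ll[3])
            assert row3["f23_LS12"] == pytest.approx(lsl[1] - lsl[2])
            assert row3["f24_LS23"] == pytest.approx(lsl[2] - lsl[3])
            assert row3["f25_LS12_LS23"] == pytest.approx(
                row3["f23_LS12"] - row3["f24_LS23"]
            )
            assert row3["f15_L_LS"] == pytest.approx(ll[3] / lsl[3])

    def test_identical_second_and_third_leaf_zero_differences(self, profiles):
        prof = noise_free(profiles["Normal"])
        rng = lambda: np.random.default_rng(11)
        leaves = {
            1: segment_object(synth.render_leaf(prof, 1, 50, rng())),
            2: segment_object(synth.render_leaf(prof, 3, 50, rng())),
            3: segment_object(synth.render_leaf(prof, 3, 50, rng())),
        }
        sheaths = {
            p: segment_object(synth.render_sheath(prof, p, 50, rng()))
            for p in (1, 2, 3)
        }
        fv = features.assemble_sample(leaves, sheaths, 3)
        for idx in (18, 20, 21, 22):
            assert fv[idx] == 0.0

    def test_missing_organ_raises(self, profiles):
        prof = noise_free(profiles["Normal"])
        rng = np.random.default_rng(0)
        leaves = {
            p: segment_object(synth.render_leaf(prof, p, 50, rng))
            for p in (1, 2, 3)
        }
        sheaths = {
            p: segment_object(synth.render_sheath(prof, p, 50, rng))
            for p in (1, 2)
        }
        with pytest.raises(MissingOrgan):
            features.assemble_sample(leaves, sheaths, 3)

    def test_csv_roundtrip_bit_exact(self, small_table, tmp_path):
        path = tmp_path / "features.csv"
        small_table.to_csv(path, index=False)
        back = features.read_table(path)
        assert np.array_equal(
            back[registry.COLUMNS].to_numpy(), small_table[registry.COLUMNS].to_numpy()
        )


class TestRegistry:
    def test_registry_is_complete_and_unique(self):
        assert registry.N_FEATURES == 32
        assert sorted(registry.REGISTRY) == list(range(1, 33))
        assert len(set(registry.COLUMNS)) == 32
        assert registry.columns_for([2, 32]) == ["f02_LG", "f32_WRA"]
        with pytest.raises(KeyError):
            registry.validate_indices([0, 33])
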