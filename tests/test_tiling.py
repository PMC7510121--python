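import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from beadquant.core_io import FluorescenceImage
from beadquant.errors import ParameterError
from beadquant.tiling import extract_tiles, plan_tiles, stitch_and_merge

from conftest import overlap31_candidate, rect_mask


class TestPlanTiles:
    def test_2048_gives_nine_tiles_no_padding(self):
        pad, specs = plan_tiles((2048, 2048), tile=1024, stride=512)
        assert pad == (0, 0, 0, 0)
        assert len(specs) == 9
        origins = {s.origin for s in specs}
        assert origins == {(r, c) for r in (0, 512, 1024) for c in (0, 512, 1024)}

    def test_exact_fit_single_tile(self):
        pad, specs = plan_tiles((1024, 1024), tile=1024, stride=512)
        assert pad == (0, 0, 0, 0) and len(specs) == 1

    def test_2000_pads_to_2048(self):
        pad, specs = plan_tiles((2000, 2000), tile=1024, stride=512)
        assert pad == (24, 24, 24, 24)
        assert len(specs) == 9
        # brute-force union cover of the padded frame
        cover = np.zeros((2048, 2048), dtype=int)
        for s in specs:
            cover[s.origin[0] : s.origin[0] + s.size, s.origin[1] : s.origin[1] + s.size] += 1
        assert cover.min() >= 1

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        h=st.integers(64, 600),
        w=st.integers(64, 600),
        tile=st.integers(32, 256),
        stride_frac=st.floats(0.25, 1.0),
    )
    def test_cover_property(self, h, w, tile, stride_frac):
        stride = max(1, int(tile * stride_frac))
        pad, specs = plan_tiles((h, w), tile=tile, stride=stride)
        ph = h + pad[0] + pad[1]
        pw = w + pad[2] + pad[3]
        cover = np.zeros((ph, pw), dtype=np.int16)
        for s in specs:
            assert s.origin[0] + tile <= ph and s.origin[1] + tile <= pw
            cover[s.origin[0] : s.origin[0] + tile, s.origin[1] : s.origin[1] + tile] += 1
        assert cover.min() >= 1
        if 2 * stride <= tile and min(ph, pw) > tile:
            # interior pixels fall in >= 2 tiles along each covered axis
            interior = cover[tile - stride : ph - (tile - stride), tile - stride : pw - (tile - stride)]
            assert interior.min() >= 2

    def test_parameter_validation(self):
        with pytest.raises(ParameterError):
            plan_tiles((100, 100), tile=0)
        with pytest.raises(ParameterError):
            plan_tiles((100, 100), tile=64, stride=65)


class TestExtractTiles:
    def test_no_pad_tiles_are_crops(self):
        arr = np.arange(2048 * 2048, dtype=np.uint16).reshape(2048, 2048) % 65535
        img = FluorescenceImage(arr)
        plan = plan_tiles((2048, 2048), 1024, 512)
        tiles = extract_tiles(img, plan)
        assert len(tiles) == 9
        spec, t = tiles[4]  # center tile
        np.testing.assert_array_equal(t, arr[512:1536, 512:1536])

    def test_1x1_image_reflects_to_constant(self):
        img = FluorescenceImage(np.array([[7]], dtype=np.uint8))
        plan = plan_tiles((1, 1), tile=4, stride=4)
        tiles = extract_tiles(img, plan)
        assert len(tiles) == 1
        np.testing.assert_array_equal(tiles[0][1], np.full((4, 4), 7))

    def test_border_column_is_mirrored_interior(self):
        arr = np.arange(36, dtype=np.uint8).reshape(6, 6)
        plan = plan_tiles((6, 6), tile=8, stride=8)  # pad (1,1,1,1)
        pad, _ = plan
        assert pad == (1, 1, 1, 1)
        tiles = extract_tiles(FluorescenceImage(arr), plan)
        t = tiles[0][1]
        # mirror reflection: padded col 0 equals source col 0, padded row 0 equals source row 0
        np.testing.assert_array_equal(t[1:7, 0], arr[:, 0])
        np.testing.assert_array_equal(t[0, 1:7], arr[0, :])
        np.testing.assert_array_equal(t[7, 1:7], arr[5, :])


class TestStitchAndMerge:
    def _single_tile_plan(self, shape):
        return plan_tiles(shape, tile=shape[0], stride=shape[0])

    def test_duplicate_across_tiles_suppressed(self):
        shape = (64, 64)
        pad, specs = plan_tiles(shape, tile=48, stride=16)
        # a bead at rows/cols 20..27 lies fully inside several tiles
        per_tile = []
        for spec in specs:
            r0, c0 = spec.origin
            if r0 <= 20 and 28 <= r0 + 48 and c0 <= 20 and 28 <= c0 + 48:
                local = rect_mask((48, 48), 20 - r0, 28 - r0, 20 - c0, 28 - c0, score=0.9)
                per_tile.append((spec, [local]))
            else:
                per_tile.append((spec, []))
        assert sum(len(m) for _, m in per_tile) >= 2
        out = stitch_and_merge(per_tile, shape)
        assert len(out) == 1
        np.testing.assert_array_equal(out.instances[0].mask, rect_mask(shape, 20, 28, 20, 28).mask)

    def test_overlap_boundary_exactly_30pct_kept(self):
        shape = (32, 32)
        pad, specs = plan_tiles(shape, tile=32, stride=32)
        kept = rect_mask(shape, 0, 10, 0, 10, score=0.95, label_id=1)  # area 100
        # candidate area 100, overlapping exactly 30 px of itself
        cand30 = rect_mask(shape, 7, 17, 0, 10, score=0.9, label_id=2)  # rows 7..9 overlap = 30
        cand31 = overlap31_candidate(shape)
        assert kept.intersection_area(cand30) == 30 and cand30.area == 100
        assert kept.intersection_area(cand31) == 31 and cand31.area == 100
        out = stitch_and_merge([(specs[0], [kept, cand30])], shape)
        assert len(out) == 2  # exactly 30% of own area -> kept ("more than 30%" discards)
        out2 = stitch_and_merge([(specs[0], [kept, cand31])], shape)
        assert len(out2) == 1

    def test_score_threshold_strict(self):
        shape = (32, 32)
        _, specs = plan_tiles(shape, tile=32, stride=32)
        low = rect_mask(shape, 0, 5, 0, 5, score=0.65, label_id=1)
        boundary = rect_mask(shape, 10, 15, 10, 15, score=0.70, label_id=2)
        ok = rect_mask(shape, 20, 25, 20, 25, score=0.71, label_id=3)
        out = stitch_and_merge([(specs[0], [low, boundary, ok])], shape)
        assert [m.score for m in out.instances] == [0.71]
        assert out.params["n_dropped_score"] == 2

    def test_disjoint_beads_across_tiles_all_survive(self):
        shape = (64, 64)
        plan = plan_tiles(shape, tile=32, stride=32)  # 4 disjoint tiles
        beads = [(5, 5), (5, 40), (40, 22)]  # third straddles no tile boundary rows
        per_tile = []
        for spec, _ in [(s, None) for s in plan[1]]:
            r0, c0 = spec.origin
            local = []
            for i, (br, bc) in enumerate(beads):
                if r0 <= br and br + 6 <= r0 + 32 and c0 <= bc and bc + 6 <= c0 + 32:
                    local.append(rect_mask((32, 32), br - r0, br - r0 + 6, bc - c0, bc - c0 + 6,
                                           score=0.9, label_id=i + 1))
            per_tile.append((spec, local))
        out = stitch_and_merge(per_tile, shape)
        assert len(out) == 3

    def test_idempotent_on_merged_result(self, young_scene):
        from beadquant.backends import OracleBackend, segment_image

        pred = segment_image(young_scene.rendered, OracleBackend(young_scene.truth),
                             tile=256, stride=128)
        shape = pred.source_shape
        _, specs = plan_tiles(shape, tile=shape[0], stride=shape[0])
        again = stitch_and_merge([(specs[0], pred.instances)], shape,
                                 score_min=0.7, overlap_max=0.30)
        assert len(again) == len(pred)
        for a, b in zip(again.instances, pred.instances):
            assert a.bbox == b.bbox and np.array_equal(a.crop, b.crop)

    def test_pad_removed_and_clipped(self):
        # instance extending into the padded margin is clipped to the source frame
        shape = (30, 30)
        pad, specs = plan_tiles(shape, tile=32, stride=32)
        assert pad == (1, 1, 1, 1)
        inst = rect_mask((32, 32), 0, 5, 0, 5, score=0.9)  # starts inside the pad
        out = stitch_and_merge([(specs[0], [inst])], shape)
        assert len(out) == 1
        assert out.instances[0].bbox == (0, 4, 0, 4)

    def test_inconsistent_tile_rejected(self):
        spec_big = plan_tiles((64, 64), tile=64, stride=64)[1][0]
        with pytest.raises(ParameterError):
            stitch_and_merge([(spec_big, [])], (16, 16))
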