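import json

import numpy as np
import pytest

from histotile.qc import QCMask, compose_masks, thumbnail
from histotile.store import decode_tile, iter_records, read_tiles
from histotile.synth import file_digest
from histotile.tiling import (
    ROI,
    FilterConfig,
    LineageLog,
    TileGrid,
    build_grid,
    extract_tiles,
    grayspace_fraction,
    load_rois_csv,
    load_rois_geojson,
    render_report,
    should_discard,
    whitespace_fraction,
)


def full_qc(pyr, value=False, mpp=16.0):
    h = int(round(pyr.height_um / mpp))
    w = int(round(pyr.width_um / mpp))
    return QCMask(mask=np.full((h, w), value), mpp=mpp)


class TestBuildGrid:
    def test_plain_grid_counts(self, basic_slide):
        pyr, _ = basic_slide
        grid = build_grid(pyr, tile_um=1024, tile_px=128)
        assert grid.n_tiles == 16  # 4096/1024 squared

    def test_overlapping_stride(self, basic_slide):
        pyr, _ = basic_slide
        grid = build_grid(pyr, tile_um=1024, tile_px=128, stride_um=512)
        assert grid.n_tiles == 49  # 7 positions per axis

    def test_full_qc_mask_removes_everything(self, basic_slide):
        pyr, _ = basic_slide
        grid = build_grid(pyr, 1024, 128, qc=full_qc(pyr, True))
        assert grid.n_tiles == 0

    def test_include_roi_center_matches_point_in_polygon_oracle(self, basic_slide):
        """Center-mode ROI filtering equals a per-tile point-in-polygon check."""
        pyr, _ = basic_slide
        # left half of the slide, in level-0 pixel coordinates
        half = ROI("basic", "left", ((0, 0), (2048, 0), (2048, 4096), (0, 4096)))
        grid = build_grid(pyr, 512, 64, rois=[half])
        assert grid.n_tiles > 0
        midline_um = 2048 * pyr.level0_mpp
        for x_um, y_um in grid.coords:
            assert x_um + 256 <= midline_um
        full = build_grid(pyr, 512, 64)
        expected = sum(1 for x, y in full.coords if x + 256 <= midline_um)
        assert grid.n_tiles == expected

    def test_exclude_roi(self, basic_slide):
        pyr, _ = basic_slide
        block = ROI("basic", "cut", ((0, 0), (4096, 0), (4096, 4096), (0, 4096)),
                    role="exclude")
        assert build_grid(pyr, 512, 64, rois=[block]).n_tiles == 0

    def test_fraction_mode(self, basic_slide):
        pyr, _ = basic_slide
        half = ROI("basic", "left", ((0, 0), (2048, 0), (2048, 4096), (0, 4096)))
        grid = build_grid(pyr, 512, 64, rois=[half], roi_method="fraction",
                          roi_fraction_min=0.99)
        for x_um, _ in grid.coords:
            assert x_um + 512 <= 2048 * pyr.level0_mpp + 1e-6

    def test_invalid_polygon_rejected(self, basic_slide):
        from histotile.errors import ROIError

        pyr, _ = basic_slide
        bowtie = ROI("basic", "bad", ((0, 0), (100, 100), (100, 0), (0, 100)))
        with pytest.raises(ROIError):
            build_grid(pyr, 512, 64, rois=[bowtie])

    def test_jitter_stays_in_bounds_and_is_seeded(self, basic_slide):
        pyr, _ = basic_slide
        g1 = build_grid(pyr, 512, 64, jitter_seed=5)
        g2 = build_grid(pyr, 512, 64, jitter_seed=5)
        g3 = build_grid(pyr, 512, 64, jitter_seed=6)
        assert g1.coords == g2.coords
        assert g1.coords != g3.coords
        for x, y in g1.coords:
            assert 0 <= x <= pyr.width_um - 512
            assert 0 <= y <= pyr.height_um - 512


class TestTileFilters:
    @pytest.mark.parametrize(
        "color,expected",
        [((128, 128, 128), 1.0), ((255, 0, 0), 0.0)],
    )
    def test_grayspace_uniform(self, color, expected):
        tile = np.full((16, 16, 3), color, dtype=np.uint8)
        assert grayspace_fraction(tile, 0.05) == expected

    def test_grayspace_half(self):
        tile = np.full((16, 16, 3), (255, 0, 0), dtype=np.uint8)
        tile[:8] = 128
        assert grayspace_fraction(tile, 0.05) == 0.5

    @pytest.mark.parametrize(
        "color,thr,expected",
        [((255, 255, 255), 230, 1.0), ((0, 0, 0), 230, 0.0), ((240, 240, 240), 230, 1.0)],
    )
    def test_whitespace_uniform(self, color, thr, expected):
        tile = np.full((16, 16, 3), color, dtype=np.uint8)
        assert whitespace_fraction(tile, thr) == expected

    def test_should_discard_background_vs_tissue(self, basic_slide):
        pyr, truth = basic_slide
        # pure background corner
        drop, frac = should_discard(pyr, (3200, 200), 512,
                                    methods=("grayspace", "whitespace"))
        assert drop
        assert frac["grayspace"] > 0.6 and frac["whitespace"] > 0.95
        # center of the first tissue blob (radius 900 at 1400,1500)
        drop, frac = should_discard(pyr, (1200, 1300), 512,
                                    methods=("grayspace", "whitespace"))
        assert not drop
        assert frac["grayspace"] < 0.6

    def test_no_methods_always_keeps(self, basic_slide):
        pyr, _ = basic_slide
        drop, frac = should_discard(pyr, (0, 0), 512, methods=())
        assert not drop and frac == {}

    def test_discard_monotone_in_threshold(self, basic_slide):
        pyr, _ = basic_slide
        coord = (2000, 2000)
        decisions = []
        for gf in (0.0, 0.3, 0.6, 0.9, 1.0):
            cfg = FilterConfig(grayspace_fraction=gf)
            drop, _ = should_discard(pyr, coord, 512, cfg, ("grayspace",))
            decisions.append(drop)
        # once kept at some threshold, stays kept at looser thresholds
        assert decisions == sorted(decisions, reverse=True)


class TestExtraction:
    def test_counts_without_filters(self, basic_slide, tmp_path):
        pyr, _ = basic_slide
        grid = build_grid(pyr, 1024, 128)
        n, lineage, report = extract_tiles(pyr, grid, tmp_path / "a.tiles")
        assert n == 16
        assert report["total_written"] == 16

    def test_counts_match_masked_grid(self, basic_slide, tmp_path):
        pyr, _ = basic_slide
        thumb = thumbnail(pyr, 16.0)
        qc = compose_masks(["otsu"], thumb)
        grid = build_grid(pyr, 512, 64, qc=qc, mask_fraction_max=0.5)
        n, _, _ = extract_tiles(pyr, grid, tmp_path / "b.tiles")
        assert n == grid.n_tiles

    def test_png_roundtrip_bit_exact(self, basic_slide, tmp_path):
        from histotile.slide import read_region_um

        pyr, _ = basic_slide
        grid = build_grid(pyr, 1024, 128)
        extract_tiles(pyr, grid, tmp_path / "c.tiles", codec="png")
        for img, sid, x, y in read_tiles(tmp_path / "c.tiles"):
            direct = read_region_um(pyr, x * pyr.level0_mpp, y * pyr.level0_mpp,
                                    1024, 128)
            assert np.array_equal(img, direct)

    def test_deterministic_store_and_lineage(self, basic_slide, tmp_path):
        pyr, _ = basic_slide
        grid = build_grid(pyr, 1024, 128)
        _, l1, _ = extract_tiles(pyr, grid, tmp_path / "d1.tiles", seed=3)
        _, l2, _ = extract_tiles(pyr, grid, tmp_path / "d2.tiles", seed=3)
        assert file_digest(tmp_path / "d1.tiles") == file_digest(tmp_path / "d2.tiles")
        assert l1.digest == l2.digest

    def test_otsu_discards_subset_of_grayspace(self, basic_slide):
        """Tiles removed by slide-level Otsu are (almost) all gray-filtered too."""
        pyr, _ = basic_slide
        thumb = thumbnail(pyr, 16.0)
        qc = compose_masks(["otsu"], thumb)
        full = build_grid(pyr, 512, 64)
        kept_otsu = set(build_grid(pyr, 512, 64, qc=qc, mask_fraction_max=0.6).coords)
        agree = 0
        otsu_removed = [c for c in full.coords if c not in kept_otsu]
        for coord in otsu_removed:
            drop, _ = should_discard(pyr, coord, 512, methods=("grayspace",))
            agree += drop
        assert otsu_removed and agree / len(otsu_removed) >= 0.95

    def test_lineage_roundtrip_digest(self, basic_slide, tmp_path):
        pyr, _ = basic_slide
        grid = build_grid(pyr, 1024, 128)
        _, lineage, _ = extract_tiles(pyr, grid, tmp_path / "e.tiles")
        reloaded = LineageLog.from_json((tmp_path / "e.tiles.lineage.json").read_text())
        assert reloaded.digest == lineage.digest

    def test_report_files_and_render(self, basic_slide, tmp_path):
        from histotile.store import load_index

        pyr, _ = basic_slide
        grid = build_grid(pyr, 1024, 128)
        n, _, report = extract_tiles(pyr, grid, tmp_path / "f.tiles",
                                     methods=("grayspace",))
        on_disk = json.loads((tmp_path / "f.tiles.report.json").read_text())
        assert on_disk["total_written"] == n
        assert len(on_disk["slides"]) == 1
        assert on_disk["slides"][0]["n_written"] + on_disk["slides"][0]["n_discarded"] \
            == grid.n_tiles
        out = render_report(pyr, grid, report, tmp_path / "report.pdf",
                            index=load_index(tmp_path / "f.tiles"))
        assert (tmp_path / "report.pdf").exists()


class TestGridSerialization:
    def test_json_roundtrip(self, basic_slide):
        pyr, _ = basic_slide
        grid = build_grid(pyr, 1024, 128)
        again = TileGrid.from_json(grid.to_json())
        assert again.coords == grid.coords
        assert again.provenance == grid.provenance


class TestROIIO:
    def test_csv_roundtrip(self, tmp_path):
        (tmp_path / "rois.csv").write_text(
            "slide,label,role,x,y\n"
            "s1,tumor,include,0,0\n"
            "s1,tumor,include,100,0\n"
            "s1,tumor,include,100,100\n"
            "s1,artifact,exclude,5,5\n"
            "s1,artifact,exclude,6,5\n"
            "s1,artifact,exclude,6,6\n"
        )
        rois = load_rois_csv(tmp_path / "rois.csv")
        assert len(rois) == 2
        roles = {r.label: r.role for r in rois}
        assert roles == {"tumor": "include", "artifact": "exclude"}

    def test_geojson(self, tmp_path):
        doc = {
            "type": "FeatureCollection",
            "features": [
                {
                    "type": "Feature",
                    "properties": {"label": "tumor"},
                    "geometry": {
                        "type": "Polygon",
                        "coordinates": [[[0, 0], [50, 0], [50, 50], [0, 0]]],
                    },
                }
            ],
        }
        (tmp_path / "r.geojson").write_text(json.dumps(doc))
        rois = load_rois_geojson(tmp_path / "r.geojson", "s1")
        assert len(rois) == 1 and rois[0].label == "tumor"
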