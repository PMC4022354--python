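"""Scan/trait-table IO: round trips, dialect tolerance, validation errors."""

import json

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import lcshoot as lc
from lcshoot.errors import FormatError, MetadataError, ValidationError
from lcshoot.lc_io import read_pnm, write_pnm


def make_scan(grid, **kw):
    defaults = dict(v_pitch=2.5, h_pitch=2.5, speed=0.9)
    defaults.update(kw)
    return lc.ScanMatrix(grid=np.asarray(grid, dtype=np.uint8), **defaults)


def write_sidecar(path, **over):
    doc = {"v_pitch_mm": 2.5, "h_pitch_mm": 2.5, "speed_m_per_min": 0.9}
    doc.update(over)
    path.write_text(json.dumps(doc))
    return path


class TestScanIO:
    def test_csv_example(self, tmp_path):
        (tmp_path / "s.csv").write_text("0,1,0\n0,1,0\n0,0,0\n")
        meta = write_sidecar(tmp_path / "s.json")
        scan = lc.read_scan(tmp_path / "s.csv", meta)
        assert scan.grid.sum() == 2
        assert scan.shape == (3, 3)
        # file top row is the top of the scan; grid row 0 is bench level
        assert scan.grid[0].tolist() == [0, 0, 0]

    @pytest.mark.parametrize("fmt,suffix", [("P5", ".pgm"), ("P1", ".pgm"), ("csv", ".csv")])
    def test_round_trip(self, tmp_path, fmt, suffix):
        rng = np.random.default_rng(0)
        scan = make_scan(
            rng.integers(0, 2, size=(7, 11)),
            pot_centers=(5.0, 20.0),
            speed=1.8,
            h_pitch=5.0,
        )
        f, m = tmp_path / f"s{suffix}", tmp_path / "s.json"
        lc.write_scan(scan, f, m, fmt=fmt)
        assert lc.read_scan(f, m) == scan

    @pytest.mark.parametrize("grid", [[[0]], [[1, 1], [1, 1]]])
    def test_degenerate_grids_round_trip(self, tmp_path, grid):
        scan = make_scan(grid)
        lc.write_scan(scan, tmp_path / "s.pgm", tmp_path / "s.json")
        assert lc.read_scan(tmp_path / "s.pgm", tmp_path / "s.json") == scan

    def test_p1_and_p5_yield_identical_grids(self, tmp_path):
        rng = np.random.default_rng(1)
        arr = rng.integers(0, 2, size=(5, 8)).astype(np.uint8)
        write_pnm(arr, tmp_path / "a.pbm", fmt="P1")
        write_pnm(arr, tmp_path / "a.pgm", fmt="P5")
        np.testing.assert_array_equal(read_pnm(tmp_path / "a.pbm"), read_pnm(tmp_path / "a.pgm"))

    def test_p2_ascii_thresholds_grey_values(self, tmp_path):
        (tmp_path / "g.pgm").write_text("P2\n# comment\n3 2\n255\n0 10 0\n200 0 255\n")
        np.testing.assert_array_equal(read_pnm(tmp_path / "g.pgm"), [[0, 1, 0], [1, 0, 1]])

    def test_missing_speed_is_metadata_error(self, tmp_path):
        (tmp_path / "s.csv").write_text("0,1\n1,0\n")
        (tmp_path / "s.json").write_text(json.dumps({"v_pitch_mm": 2.5}))
        with pytest.raises(MetadataError):
            lc.read_scan(tmp_path / "s.csv", tmp_path / "s.json")

    def test_h_pitch_defaults_to_speed_scaled_reference(self, tmp_path):
        (tmp_path / "s.csv").write_text("1\n")
        (tmp_path / "s.json").write_text(json.dumps({"speed_m_per_min": 9.0}))
        scan = lc.read_scan(tmp_path / "s.csv", tmp_path / "s.json")
        assert scan.h_pitch == pytest.approx(25.0)

    def test_non_binary_csv_is_format_error(self, tmp_path):
        (tmp_path / "s.csv").write_text("0,-1\n1,0\n")
        meta = write_sidecar(tmp_path / "s.json")
        with pytest.raises(FormatError):
            lc.read_scan(tmp_path / "s.csv", meta)

    @settings(max_examples=25, deadline=None)
    @given(
        grid=st.integers(1, 6).flatmap(
            lambda r: st.integers(1, 6).flatmap(
                lambda c: st.lists(
                    st.lists(st.integers(0, 1), min_size=c, max_size=c),
                    min_size=r,
                    max_size=r,
                )
            )
        )
    )
    def test_any_binary_grid_round_trips(self, grid, tmp_path_factory):
        d = tmp_path_factory.mktemp("pnm")
        scan = make_scan(grid)
        for fmt in ("P1", "P5"):
            lc.write_scan(scan, d / "g.pgm", d / "g.json", fmt=fmt)
            assert lc.read_scan(d / "g.pgm", d / "g.json") == scan


class TestScanMatrixInvariants:
    def test_rejects_non_binary(self):
        with pytest.raises(ValidationError):
            make_scan([[0, 2]])

    def test_rejects_nonpositive_pitch(self):
        with pytest.raises(ValidationError):
            make_scan([[0, 1]], h_pitch=0.0)

    def test_rejects_unsorted_pot_centers(self):
        with pytest.raises(ValidationError):
            make_scan([[0, 1]], pot_centers=(4.0, 2.0))

    def test_rejects_pot_center_outside_extent(self):
        with pytest.raises(ValidationError):
            make_scan([[0, 1]], pot_centers=(100.0,))


class TestSilhouetteIO:
    def test_round_trip(self, tmp_path):
        sil = lc.Silhouette(
            pixels={(55, 3), (60, 9), (57, 4)},
            v_pitch=2.5,
            h_pitch=5.0,
            base_row=52,
            ref_col=6,
            plant_id="p1",
        )
        lc.write_silhouette(sil, tmp_path / "s.pgm", tmp_path / "s.json")
        assert lc.read_silhouette(tmp_path / "s.pgm", tmp_path / "s.json") == sil

    def test_empty_round_trip(self, tmp_path):
        sil = lc.Silhouette(pixels=frozenset(), v_pitch=2.5, h_pitch=2.5, base_row=52)
        lc.write_silhouette(sil, tmp_path / "e.pgm", tmp_path / "e.json")
        back = lc.read_silhouette(tmp_path / "e.pgm", tmp_path / "e.json")
        assert back.is_empty and back.base_row == 52


class TestTraitTable:
    def frame(self, **over):
        row = dict(
            plant_id="p1", species="rapeseed", species_group="dicot", view_angle=0,
            speed=0.9, pixel_area=1200, max_height=105.0, measured_leaf_area=np.nan,
        )
        row.update(over)
        return pd.DataFrame([row])

    def test_round_trip_preserves_unknown_columns(self, tmp_path):
        df = self.frame().assign(note="extra")
        lc.write_trait_table(df, tmp_path / "t.csv")
        back = lc.read_trait_table(tmp_path / "t.csv")
        assert "note" in back.columns
        assert back.loc[0, "pixel_area"] == 1200

    def test_parses_example_row(self, tmp_path):
        (tmp_path / "t.csv").write_text(
            "plant_id,species,species_group,view_angle,speed,pixel_area,max_height,"
            "measured_leaf_area,measured_height\n"
            "p1,rapeseed,dicot,0,0.9,1200,105,,\n"
        )
        df = lc.read_trait_table(tmp_path / "t.csv")
        assert df.loc[0, "max_height"] == 105

    def test_invalid_angle_rejected(self, tmp_path):
        with pytest.raises(ValidationError):
            lc.write_trait_table(self.frame(view_angle=175), tmp_path / "t.csv")

    def test_invalid_group_rejected(self, tmp_path):
        with pytest.raises(ValidationError):
            lc.write_trait_table(self.frame(species_group="fern"), tmp_path / "t.csv")
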