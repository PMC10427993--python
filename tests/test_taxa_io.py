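"""Reading, validation and round-trips for the tabular/tree/raster formats."""

import numpy as np
import pytest

from neohybrid import (
    FormatError,
    FootprintGrid,
    TaxonRecord,
    ValidationError,
    normalize_name,
    read_checklist,
    read_hectad_polygons,
    read_occurrences,
    read_raster,
    read_stem_ages,
    read_tree,
    write_checklist,
    write_raster,
)

WCVP_HEADER = "taxon_name,genus,rank,species_hybrid,taxon_status,region_code\n"


def wcvp_file(tmp_path, rows, header=WCVP_HEADER):
    p = tmp_path / "wcvp.csv"
    p.write_text(header + "".join(r + "\n" for r in rows))
    return p


class TestChecklist:
    def test_well_formed_rows_read_one_to_one(self, tmp_path):
        p = wcvp_file(
            tmp_path,
            [
                "Poa alpina,Poa,species,,Accepted,GER",
                "Poa x jemtlandica,Poa,species,×,Accepted,SWE",
                "Poa laxa,Poa,species,,Synonym,AUT",
            ],
        )
        res = read_checklist(p, "wcvp")
        assert len(res.records) == 3
        assert res.report.n_dropped == 0
        assert res.report.n_retained + res.report.n_dropped == res.report.n_rows
        hyb = res.records[1]
        assert hyb.is_hybrid and not hyb.is_artificial_hybrid
        assert res.records[2].name_status == "not_accepted"

    def test_numeric_region_codes_are_dropped_and_counted(self, tmp_path):
        p = wcvp_file(
            tmp_path,
            ["Poa alpina,Poa,species,,Accepted,2", "Poa laxa,Poa,species,,Accepted,NOR"],
        )
        res = read_checklist(p, "wcvp")
        assert len(res.records) == 1
        assert res.report.n_dropped_numeric_region == 1

    def test_missing_hybrid_column_names_the_column(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("taxon_name,genus,rank,taxon_status,region_code\na,b,species,Accepted,GER\n")
        with pytest.raises(FormatError, match="species_hybrid"):
            read_checklist(p, "wcvp")

    def test_empty_file_is_a_format_error(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text("")
        with pytest.raises(FormatError):
            read_checklist(p, "wcvp")
        p.write_text(WCVP_HEADER)
        with pytest.raises(FormatError):
            read_checklist(p, "wcvp")

    def test_glonaf_statuses_map_to_unified_fields(self, tmp_path):
        p = tmp_path / "glonaf.tsv"
        p.write_text(
            "taxon_name\tgenus\tname_status\tstatus\thybrid\tregion_code\n"
            "Acacia dealbata\tAcacia\taccepted\tnaturalized\t0\tSPA\n"
            "Acacia saligna\tAcacia\taccepted\talien\t0\tSPA\n"
            "Fallopia x bohemica\tFallopia\taccepted\tnaturalized\t1\tGRB\n"
        )
        res = read_checklist(p, "glonaf")
        st = [r.naturalization_status for r in res.records]
        assert st == ["naturalized", "alien", "naturalized"]
        assert [r.is_hybrid for r in res.records] == [False, False, True]

    @pytest.mark.parametrize("dialect", ["wcvp", "glonaf"])
    def test_round_trip_preserves_records(self, tmp_path, dialect):
        recs = [
            TaxonRecord("Poa alpina", "Poa", "species", False, False, "accepted", "native", "GER"),
            TaxonRecord(
                "Poa jemtlandica", "Poa", "variety", True, False, "accepted", "naturalized", "SWE"
            ),
            TaxonRecord(
                "Poa laxa", "Poa", "species", False, False, "not_accepted", "alien", "AUT"
            ),
        ]
        p = tmp_path / "rt.csv"
        write_checklist(recs, p, dialect)
        back = read_checklist(p, dialect).records
        if dialect == "glonaf":  # dialect carries no artificial-hybrid info
            assert back == recs
        else:
            assert [r.taxon_name for r in back] == [r.taxon_name for r in recs]
            assert [r.naturalization_status for r in back] == [
                r.naturalization_status for r in recs
            ]

    def test_hybrid_sign_is_stripped_by_normalization(self):
        assert normalize_name("× Agropogon   littoralis ") == "Agropogon littoralis"
        assert normalize_name("x Agropogon littoralis") == "Agropogon littoralis"


class TestTree:
    def test_four_tip_tree_reads_with_total_length(self, four_tip_tree):
        assert four_tip_tree.n_tips == 4
        assert four_tip_tree.total_branch_length() == pytest.approx(6.0)

    def test_duplicate_tips_rejected(self, tmp_path):
        p = tmp_path / "dup.nwk"
        p.write_text("((A:1,A:1):1);\n")
        with pytest.raises(ValidationError, match="duplicate"):
            read_tree(p)

    def test_zero_length_terminal_branch_flagged_not_rejected(self, tmp_path):
        p = tmp_path / "zero.nwk"
        p.write_text("((A:0,B:1):1,C:2);\n")
        res = read_tree(p)
        assert res.records.n_tips == 3
        assert any("zero-length" in n for n in res.report.notes)

    def test_garbage_is_a_format_error(self, tmp_path):
        p = tmp_path / "bad.nwk"
        p.write_text("((A:1,B:1\n")
        with pytest.raises(FormatError):
            read_tree(p)


def asc_file(tmp_path, body, nrows=2, ncols=2, nodata=-9999.0):
    p = tmp_path / "grid.asc"
    p.write_text(
        f"ncols {ncols}\nnrows {nrows}\nxllcorner 0\nyllcorner 0\ncellsize 1\n"
        f"nodata_value {nodata}\n" + body
    )
    return p


class TestRaster:
    def test_uniform_grid(self, tmp_path):
        p = asc_file(tmp_path, "10 10\n10 10\n")
        grid = read_raster(p).records
        assert np.nanmin(grid.values) == np.nanmax(grid.values) == 10

    def test_value_above_scale_rejected(self, tmp_path):
        p = asc_file(tmp_path, "10 51\n10 10\n")
        with pytest.raises(ValidationError):
            read_raster(p)

    def test_missing_cells_excluded_from_range(self, tmp_path):
        p = asc_file(tmp_path, "-9999 50\n0 10\n")
        res = read_raster(p)
        grid = res.records
        assert np.isnan(grid.values[0, 0])
        assert np.nanmax(grid.values) == 50
        assert res.report.n_retained == 3

    def test_non_numeric_cell_is_a_format_error(self, tmp_path):
        p = asc_file(tmp_path, "10 abc\n10 10\n")
        with pytest.raises(FormatError):
            read_raster(p)

    def test_round_trip(self, tmp_path):
        vals = np.array([[1.25, np.nan], [50.0, 0.0]])
        grid = FootprintGrid(vals, cell_size=2.0, origin=(3.0, 4.0), crs_tag="planar-x")
        out = tmp_path / "rt.asc"
        write_raster(grid, out)
        back = read_raster(out).records
        np.testing.assert_array_equal(back.values, vals)
        assert back.cell_size == 2.0
        assert back.origin == (3.0, 4.0)
        assert back.crs_tag == "planar-x"


class TestOccupancyAndTables:
    def test_duplicate_pairs_collapsed(self, tmp_path):
        p = tmp_path / "occ.csv"
        p.write_text("taxon_name,hectad_code\nA,SK58\nA,SK58\nA,SK59\n")
        res = read_occurrences(p)
        assert len(res.records) == 2
        assert res.report.n_dropped_duplicate == 1

    def test_stem_age_table_accepts_rn_bl_column(self, tmp_path):
        p = tmp_path / "ages.csv"
        p.write_text("genus,rn.bl\nPhreatia,0.00371\nPoa,12.5\n")
        df = read_stem_ages(p).records
        assert list(df.columns) == ["genus", "stem_age"]
        assert df["stem_age"].tolist() == [0.00371, 12.5]

    def test_nonpositive_stem_age_rejected(self, tmp_path):
        p = tmp_path / "ages.csv"
        p.write_text("genus,stem_age\nPoa,0\n")
        with pytest.raises(ValidationError):
            read_stem_ages(p)

    def test_degenerate_hectad_rectangle_rejected(self, tmp_path):
        p = tmp_path / "hec.csv"
        p.write_text("hectad_code,xmin,ymin,xmax,ymax\nSK58,0,0,0,10\n")
        with pytest.raises(ValidationError):
            read_hectad_polygons(p)


def test_artificial_flag_requires_hybrid_flag():
    with pytest.raises(ValidationError):
        TaxonRecord("x", "X", is_hybrid=False, is_artificial_hybrid=True)
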