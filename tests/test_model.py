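"""Domain types and CSV round-trips for the plate/screen data model."""

import math

import numpy as np
import pandas as pd
import pytest

from chemogram import (
    CONTROL,
    ClinicalRecord,
    ConcLevel,
    DataError,
    DrugClass,
    DrugEntry,
    DrugPanel,
    ParseError,
    Response,
    WellReading,
    read_clinical_table,
    read_panel,
    read_score_matrix,
    read_well_table,
    write_clinical_table,
    write_panel,
    write_score_matrix,
    write_well_table,
)
from chemogram.model import is_center_well, wells_from_platemap
from tests.conftest import make_score_matrix


class TestDrugPanel:
    def test_default_panel_size_and_composition(self, panel):
        assert len(panel) == 25
        by_class = {}
        for entry in panel:
            by_class.setdefault(entry.drug_class, []).append(entry.name)
        assert len(by_class[DrugClass.chemotherapy]) == 15
        assert len(by_class[DrugClass.kinase_inhibitor]) == 6
        assert len(by_class[DrugClass.epigenetic]) == 2
        assert len(by_class[DrugClass.other]) == 2

    @pytest.mark.parametrize(
        "drug, expected",
        [
            ("Oxaliplatin", (-6.5, -5.75, -5.0)),
            ("Docetaxel", (-9.25, -8.75, -8.25)),
            ("5FU", (-7.0, -6.25, -5.5)),
        ],
    )
    def test_known_concentration_triples(self, panel, drug, expected):
        assert panel[drug].conc_log10M == expected

    def test_lookup_is_case_insensitive_and_strips(self, panel):
        assert panel["  oxaliplatin "].name == "Oxaliplatin"
        assert "GEMCITABINE" in panel
        assert panel.resolve("sn-38") == "SN-38"

    def test_concentrations_strictly_increasing_and_submolar(self, panel):
        for entry in panel:
            lo, mid, hi = entry.conc_log10M
            assert lo < mid < hi < 0

    def test_entry_invariants(self):
        with pytest.raises(DataError):
            DrugEntry("x", DrugClass.other, (-5.0, -5.0, -4.0))
        with pytest.raises(DataError):
            DrugEntry("x", DrugClass.other, (-2.0, -1.0, 0.0))
        with pytest.raises(DataError):
            DrugPanel(
                [
                    DrugEntry("A", DrugClass.other, (-7.0, -6.0, -5.0)),
                    DrugEntry(" a ", DrugClass.other, (-7.0, -6.0, -5.0)),
                ]
            )

    def test_panel_round_trip(self, panel, tmp_path):
        path = tmp_path / "panel.csv"
        write_panel(panel, path)
        again = read_panel(path)
        assert [e for e in again] == [e for e in panel]


class TestWellReading:
    def test_field_mapping_from_csv_row(self, tmp_path):
        path = tmp_path / "wells.csv"
        path.write_text(
            "plate,well,pdo,drug,level,signal\n"
            "P1,D4,CGR0002,5FU,low,8213\n"
            "P1,D5,CGR0002,Control,control,10250\n"
        )
        wells = read_well_table(path)
        assert wells[0] == WellReading("P1", "D4", "CGR0002", "5FU", ConcLevel.low, 8213.0)
        assert wells[1].drug == CONTROL and wells[1].is_control

    @pytest.mark.parametrize(
        "row",
        [
            "P1,Z4,CGR0002,5FU,low,8213",  # malformed well position
            "P1,D4,CGR0002,5FU,low,-5",  # negative signal
            "P1,D4,CGR0002,5FU,ultra,8213",  # unknown level
            "P1,D4,CGR0002,5FU,low,abc",  # non-numeric signal
            "P1,D4,CGR0002,5FU,control,8213",  # control level, non-control drug
        ],
    )
    def test_malformed_rows_raise_naming_the_row(self, tmp_path, row):
        path = tmp_path / "wells.csv"
        path.write_text("plate,well,pdo,drug,level,signal\n" + row + "\n")
        with pytest.raises(ParseError, match="row 2"):
            read_well_table(path)

    def test_missing_header_columns_rejected(self, tmp_path):
        path = tmp_path / "wells.csv"
        path.write_text("plate,well,pdo\nP1,D4,CGR0002\n")
        with pytest.raises(ParseError):
            read_well_table(path)

    def test_edge_wells_warn_but_parse(self, tmp_path):
        path = tmp_path / "wells.csv"
        path.write_text("plate,well,pdo,drug,level,signal\nP1,A1,X,5FU,low,100\n")
        with pytest.warns(UserWarning, match="center wells"):
            wells = read_well_table(path)
        assert len(wells) == 1

    def test_well_table_round_trip(self, tmp_path):
        wells = [
            WellReading("P1", "B2", "X", "5FU", ConcLevel.low, 8213.25),
            WellReading("P1", "B3", "X", CONTROL, ConcLevel.control, 10000.0),
        ]
        path = tmp_path / "wells.csv"
        write_well_table(wells, path)
        assert read_well_table(path) == wells

    def test_center_well_geometry(self):
        assert sum(
            is_center_well(f"{r}{c}") for r in "ABCDEFGH" for c in range(1, 13)
        ) == 60
        assert is_center_well("B2") and is_center_well("G11")
        assert not is_center_well("A1") and not is_center_well("H12")


class TestPlatemapConversion:
    def test_grid_to_long(self):
        layout = pd.DataFrame([[None] * 12] * 8, dtype=object)
        signal = pd.DataFrame([[0.0] * 12] * 8)
        layout.iat[1, 1] = "5FU:low"
        signal.iat[1, 1] = 8000.0
        layout.iat[1, 2] = "control"
        signal.iat[1, 2] = 10000.0
        wells = wells_from_platemap("P1", "X", layout, signal)
        assert [w.well for w in wells] == ["B2", "B3"]
        assert wells[0].drug == "5FU" and wells[0].conc_level == ConcLevel.low
        assert wells[1].is_control

    def test_bad_cell_raises(self):
        layout = pd.DataFrame([["junk"] + [float("nan")] * 11] + [[float("nan")] * 12] * 7)
        signal = pd.DataFrame([[1.0] * 12] * 8)
        with pytest.raises(ParseError, match="A1"):
            wells_from_platemap("P1", "X", layout, signal)


class TestScoreMatrixIO:
    def test_long_csv_shape_and_missing_rows(self, tmp_path):
        matrix = make_score_matrix(
            {"p1": {"d1": 2.0, "d2": 1.0}, "p2": {"d1": float("nan"), "d2": 0.5}}
        )
        path = tmp_path / "scores.csv"
        write_score_matrix(matrix, path)
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 1 + 4  # header + 2x2 grid
        missing = [l for l in lines if l.startswith("p2,d1")]
        assert missing == ["p2,d1,,,,"]

    def test_round_trip_identity(self, tmp_path):
        rng = np.random.default_rng(7)
        final = {
            f"p{i}": {f"d{j}": float(rng.uniform(0, 5)) for j in range(4)}
            for i in range(3)
        }
        final["p0"]["d2"] = float("nan")
        matrix = make_score_matrix(final)
        path = tmp_path / "scores.csv"
        write_score_matrix(matrix, path)
        again = read_score_matrix(path)
        # 12-significant-digit rendering is an identity at this magnitude
        pd.testing.assert_frame_equal(again.final_score, matrix.final_score)
        pd.testing.assert_frame_equal(again.auc_score, matrix.auc_score)
        assert again.hit.equals(matrix.hit)

    def test_component_sum_enforced(self):
        from chemogram import ScoreMatrix

        good = make_score_matrix({"p": {"d": 1.0}})
        with pytest.raises(DataError):
            ScoreMatrix(
                auc_score=good.auc_score,
                sensitivity_score=good.sensitivity_score + 0.5,
                final_score=good.final_score,
                hit=good.hit,
            )


class TestClinicalIO:
    def test_round_trip_and_panel_validation(self, tmp_path, panel):
        records = [
            ClinicalRecord("PT1", "CGR0039", "Oxaliplatin", Response.SD),
            ClinicalRecord("PT2", "CGR0002", "5FU", Response.PD),
        ]
        path = tmp_path / "clinical.csv"
        write_clinical_table(records, path)
        assert read_clinical_table(path, panel) == records

    def test_unknown_drug_or_response_rejected(self, tmp_path, panel):
        path = tmp_path / "clinical.csv"
        path.write_text("patient,pdo,drug,best_response\nPT1,X,NotADrug,PR\n")
        with pytest.raises(ParseError, match="row 2"):
            read_clinical_table(path, panel)
        path.write_text("patient,pdo,drug,best_response\nPT1,X,5FU,CR\n")
        with pytest.raises(ParseError, match="best_response"):
            read_clinical_table(path, panel)
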