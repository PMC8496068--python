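import numpy as np
import pandas as pd
import pytest

from promid.datamodel import (
    AnchorDefinition,
    LongTable,
    Schema,
    read_long_table,
    write_long_table,
    write_results,
)
from promid.exceptions import ValidationError
from promid.mid import MIDEstimate

PS = AnchorDefinition(code="PS", categories=(0, 1, 2, 3, 4), worse_direction=1)


def _write_csv(tmp_path, text):
    p = tmp_path / "data.csv"
    p.write_text(text)
    return p


def _schema():
    return Schema.canonical(score_codes=["PF"], anchor_defs={"PS": PS})


class TestReadLongTable:
    def test_basic_parse(self, tmp_path):
        p = _write_csv(
            tmp_path,
            "patient_id,trial_id,timepoint,PF,PS\nA,t,1,80,0\nA,t,2,70,1\nB,t,1,90,0\n",
        )
        table = read_long_table(p, _schema())
        assert table.n_patients == 2
        a = table.data[table.data.patient_id == "A"]
        assert list(a.time_rank) == [1, 2]

    def test_duplicate_assessment_rejected(self, tmp_path):
        p = _write_csv(
            tmp_path,
            "patient_id,trial_id,timepoint,PF,PS\nA,t,1,80,0\nA,t,1,70,1\n",
        )
        with pytest.raises(ValidationError, match=r"duplicate.*'A'"):
            read_long_table(p, _schema())

    def test_anchor_grade_out_of_range(self, tmp_path):
        p = _write_csv(
            tmp_path,
            "patient_id,trial_id,timepoint,PF,PS\nA,t,1,80,7\n",
        )
        with pytest.raises(ValidationError, match=r"\[0, 1, 2, 3, 4\]"):
            read_long_table(p, _schema())

    def test_non_integer_anchor_token_is_error_not_missing(self, tmp_path):
        p = _write_csv(
            tmp_path,
            "patient_id,trial_id,timepoint,PF,PS\nA,t,1,80,mild\nB,t,1,70,1.5\n",
        )
        with pytest.raises(ValidationError) as err:
            read_long_table(p, _schema())
        assert any("mild" in msg for msg in err.value.problems)
        assert any("1.5" in msg for msg in err.value.problems)

    def test_empty_cell_is_missing(self, tmp_path):
        p = _write_csv(
            tmp_path,
            "patient_id,trial_id,timepoint,PF,PS\nA,t,1,80,\nA,t,2,,1\n",
        )
        table = read_long_table(p, _schema())
        assert table.data["PS"].isna().sum() == 1
        assert table.data["PF"].isna().sum() == 1

    def test_validation_is_total(self, tmp_path):
        # multiple independent problems are all reported in one error
        p = _write_csv(
            tmp_path,
            "patient_id,trial_id,timepoint,PF,PS\nA,t,1,80,7\nB,t,1,70,x\nB,t,1,70,0\n",
        )
        with pytest.raises(ValidationError) as err:
            read_long_table(p, _schema())
        assert len(err.value.problems) >= 3

    def test_column_mapping(self, tmp_path):
        p = _write_csv(tmp_path, "pid,study,visit,pf,ps\nA,t,1,80,0\n")
        schema = Schema.from_dict(
            {
                "columns": {"patient_id": "pid", "trial_id": "study", "timepoint": "visit"},
                "scores": {"PF": "pf"},
                "anchors": {"PS": {"column": "ps", "categories": [0, 1, 2, 3, 4]}},
            }
        )
        table = read_long_table(p, schema)
        assert table.data.at[0, "PF"] == 80
        assert table.anchor_defs["PS"].worse_direction == 1


def test_round_trip_preserves_values(tmp_path):
    df = pd.DataFrame(
        {
            "patient_id": ["A", "A", "B"],
            "trial_id": ["t1", "t1", "t2"],
            "timepoint": [1, 2, 1],
            "PF": [81.25, np.nan, 66.666666666666667],
            "PS": [0, 1, np.nan],
        }
    )
    table = LongTable.from_frame(df, score_columns=["PF"], anchor_defs={"PS": PS})
    out = tmp_path / "round.csv"
    write_long_table(table, out)
    back = read_long_table(out, _schema())
    for col in ("patient_id", "timepoint", "PF", "PS"):
        a, b = table.data[col], back.data[col]
        if a.dtype.kind == "f":
            assert np.allclose(a, b, equal_nan=True, rtol=0, atol=0)
        else:
            assert (a == b).all()


class TestWriteResults:
    @staticmethod
    def _estimate(retained, mid=-7.0, direction="improvement"):
        return MIDEstimate(
            scale_code="PF",
            anchor_code="PS",
            direction=direction,
            kind="within_group",
            mid=mid,
            se=0.5,
            n_records=10,
            n_patients=10,
            es=0.5 if retained else 0.1,
            retained=retained,
        )

    def test_unretained_estimate_prints_no_mid(self, tmp_path):
        out = tmp_path / "summary.csv"
        frame = write_results([self._estimate(retained=False)], [], out)
        assert frame.at[0, "within_improvement"] == "no MID"
        assert "no MID" in out.read_text()

    def test_empty_inputs_header_only(self, tmp_path):
        out = tmp_path / "summary.csv"
        write_results([], [], out)
        lines = out.read_text().strip().splitlines()
        assert len(lines) == 1
        assert lines[0].startswith("scale,")

    def test_retained_estimate_prints_value(self, tmp_path):
        out = tmp_path / "summary.csv"
        frame = write_results([self._estimate(retained=True, mid=-7.0)], [], out)
        assert frame.at[0, "within_improvement"] == "-7.0"


def test_anchor_definition_invariants():
    with pytest.raises(ValidationError):
        AnchorDefinition(code="X", categories=(0,))
    with pytest.raises(ValidationError):
        AnchorDefinition(code="X", categories=(0, 1), worse_direction=2)
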