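import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from rfe_variants.preprocess import (
    LabelColumnError, MissingFileError, NonNumericCellError, SingleClassError,
    TooFewSamplesError, apply_normalization, fit_normalization,
    invert_normalization, load_table, write_table)
from .conftest import make_table


def write(tmp_path, name, text):
    path = tmp_path / name
    path.write_text(text)
    return str(path)


class TestLoadTable:
    def test_csv_roundtrip_shape_and_labels(self, tmp_path):
        path = write(tmp_path, "t.csv",
                     "a,b,class\n1,2,pos\n3,4,neg\n5,6,pos\n7,8,neg\n")
        table = load_table(path, "class", "pos")
        assert table.n_samples == 4 and table.n_features == 2
        assert table.feature_names == ("a", "b")
        assert table.labels.tolist() == [True, False, True, False]

    def test_tsv_delimiter_inferred(self, tmp_path):
        path = write(tmp_path, "t.tsv", "a\tb\tclass\n1\t2\tpos\n3\t4\tneg\n")
        table = load_table(path, "class", "pos")
        assert table.values.tolist() == [[1, 2], [3, 4]]

    def test_nonpositive_labels_all_map_negative(self, tmp_path):
        path = write(tmp_path, "t.csv",
                     "a,class\n1,pos\n2,neg\n3,other\n4,pos\n")
        table = load_table(path, "class", "pos")
        assert table.labels.tolist() == [True, False, False, True]

    @pytest.mark.parametrize("content,error", [
        ("a,class\n1,pos\n2,pos\n", SingleClassError),
        ("a,class\n1,pos\n", TooFewSamplesError),
        ("a,b\n1,2\n3,4\n", LabelColumnError),
    ])
    def test_structural_errors(self, tmp_path, content, error):
        path = write(tmp_path, "t.csv", content)
        with pytest.raises(error):
            load_table(path, "class", "pos")

    def test_missing_file(self, tmp_path):
        with pytest.raises(MissingFileError):
            load_table(str(tmp_path / "absent.csv"), "class", "pos")

    def test_non_numeric_cell_names_row_and_column(self, tmp_path):
        path = write(tmp_path, "t.tsv",
                     "a\tb\tclass\n1\tNA\tpos\n3\t4\tneg\n")
        with pytest.raises(NonNumericCellError, match="'b'"):
            load_table(path, "class", "pos")

    def test_write_then_load_roundtrip(self, tmp_path):
        table = make_table([[1.5, -2.0], [0.0, 3.25], [2.0, 1.0]],
                           [True, False, True])
        path = str(tmp_path / "out.csv")
        write_table(table, path, label_column="class")
        back = load_table(path, "class", "pos", index_column="sample_id")
        np.testing.assert_array_equal(back.values, table.values)
        assert back.labels.tolist() == table.labels.tolist()


class TestNormalization:
    def test_fit_records_column_extremes(self):
        table = make_table([[1, 0, -1], [3, 10, 1], [5, 0, -1]],
                           [True, False, True])
        params = fit_normalization(table)
        assert params.f_min.tolist() == [1, 0, -1]
        assert params.f_max.tolist() == [5, 10, 1]

    def test_endpoints_map_to_unit_interval(self):
        table = make_table([[1], [3], [5]], [True, False, True])
        normalized = apply_normalization(table, fit_normalization(table))
        assert normalized.values[:, 0].tolist() == [-1.0, 0.0, 1.0]

    def test_constant_column_maps_to_zero(self):
        table = make_table([[2], [2], [2]], [True, False, True])
        normalized = apply_normalization(table, fit_normalization(table))
        assert normalized.values[:, 0].tolist() == [0.0, 0.0, 0.0]

    def test_held_out_values_are_not_clipped(self):
        train = make_table([[1], [3], [5]], [True, False, True])
        params = fit_normalization(train)
        test = make_table([[7]], [True])
        out = apply_normalization(test, params)
        assert out.values[0, 0] == pytest.approx(2.0)

    def test_params_missing_feature_rejected(self):
        train = make_table([[1], [2]], [True, False], names=["a"])
        other = make_table([[1], [2]], [True, False], names=["ghost"])
        with pytest.raises(KeyError, match="ghost"):
            apply_normalization(other, fit_normalization(train))

    @given(values=arrays(np.float64, (6, 3),
                         elements=st.floats(-1e6, 1e6, width=64)))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_affine_properties(self, values):
        table = make_table(values, [True, False] * 3)
        params = fit_normalization(table)
        normalized = apply_normalization(table, params)
        for j in range(3):
            col, out = values[:, j], normalized.values[:, j]
            if col.min() < col.max():
                assert out.min() == pytest.approx(-1.0)
                assert out.max() == pytest.approx(1.0)
                # affine per feature: order preserved (monotone map)
                assert np.all(np.diff(out[np.argsort(col, kind="stable")])
                              >= 0)
            else:
                assert np.all(out == 0.0)
        restored = invert_normalization(normalized, params)
        np.testing.assert_allclose(restored.values, values, atol=1e-9 * 1e6)
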