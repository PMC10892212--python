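"""Descriptor-table I/O, the built-in triazole data, and the activity transform."""

import hashlib
from importlib import resources

import numpy as np
import pandas as pd
import pytest

from qsarmlr import (
    DescriptorDataset,
    fit_ols,
    load_descriptor_table,
    pic50_from_ic50,
    random_split,
    read_report,
    write_report,
)
from qsarmlr.datasets import DatasetError

# sha256 of the packaged data files; any edit to the transcription must be deliberate
FIXTURE_SHA256 = {
    "triazole_synthesized.csv": "f2e63e2cf88e7c33683228345230287ec49b18f77a10a151a8910741c517f56b",
    "triazole_designed.csv": "84e5ce142799199b60af39cead170938b33517ab49f4555e149cc46866b90e69",
}


def test_load_small_csv(tmp_path):
    p = tmp_path / "d.csv"
    p.write_text("id,pIC50,split,d1,d2\nA,5.1,train,0.2,1.0\nB,5.6,train,0.4,2.0\nC,,query,0.6,3.0\n")
    ds = load_descriptor_table(p, id_column="id", activity_column="pIC50", split_column="split")
    assert ds.n_compounds == 3
    assert ds.descriptor_names == ["d1", "d2"]
    assert np.isnan(ds.y[2])  # query row may lack activity
    np.testing.assert_allclose(ds.X[:, 1], [1.0, 2.0, 3.0])


def test_duplicate_id_is_named(tmp_path):
    p = tmp_path / "d.csv"
    p.write_text("id,d1\nC1,0.1\nC1,0.2\n")
    with pytest.raises(DatasetError, match="C1"):
        load_descriptor_table(p, id_column="id")


def test_non_numeric_descriptor_locates_cell(tmp_path):
    p = tmp_path / "d.csv"
    p.write_text("id,d1\nA,0.1\nB,oops\n")
    with pytest.raises(DatasetError, match=r"'B'.*'d1'"):
        load_descriptor_table(p, id_column="id")


def test_missing_activity_on_train_row_rejected(tmp_path):
    p = tmp_path / "d.csv"
    p.write_text("id,pIC50,split,d1\nA,5.1,train,0.2\nB,,train,0.4\n")
    with pytest.raises(DatasetError, match="missing activity"):
        load_descriptor_table(p, id_column="id", activity_column="pIC50", split_column="split")


def test_unicode_minus_normalised(tmp_path):
    p = tmp_path / "d.csv"
    p.write_text("id,d1\nA,−0.5\nB,0.5\n")
    ds = load_descriptor_table(p, id_column="id")
    assert ds.X[0, 0] == -0.5


def test_ic50_activity_flag(tmp_path):
    p = tmp_path / "d.csv"
    p.write_text("id,ic50,d1\nA,1e-6,0.1\nB,2e-6,0.2\nC,1.0,0.3\n")
    ds = load_descriptor_table(p, id_column="id", activity_column="ic50", activity_is_ic50=True)
    np.testing.assert_allclose(ds.y, [6.0, 5.6989700043360188, 0.0], rtol=1e-12)


@pytest.mark.parametrize(
    "ic50, expected",
    [
        (1.0, 0.0),
        (1.0e-6, 6.0),
        # frozen from an arbitrary-precision log10 evaluation
        (2.0e-6, 5.6989700043360188),
    ],
)
def test_pic50_values(ic50, expected):
    assert pic50_from_ic50(ic50) == pytest.approx(expected, rel=1e-14, abs=1e-14)


def test_pic50_rejects_nonpositive():
    with pytest.raises(ValueError):
        pic50_from_ic50(0.0)
    with pytest.raises(ValueError):
        pic50_from_ic50(-1e-6)


def test_fixture_files_pinned():
    for name, digest in FIXTURE_SHA256.items():
        data = (resources.files("qsarmlr.data") / name).read_bytes()
        assert hashlib.sha256(data).hexdigest() == digest, name


def test_reference_shapes_and_values(reference):
    syn, des = reference.synthesized, reference.designed
    assert syn.n_compounds == 33 and syn.n_descriptors == 5
    assert int(syn.split_mask("train").sum()) == 27
    assert int(syn.split_mask("test").sum()) == 6
    assert sorted(syn.compound_ids[i] for i in np.where(syn.split_mask("test"))[0]) == [
        "1", "12", "18", "2", "7", "8",
    ]
    assert des.n_compounds == 7 and list(des.split) == ["query"] * 7
    row = des.X[des.compound_ids.index("P10")]
    np.testing.assert_allclose(row, [0.077, -5.263, 0, 0.800, 0.125])
    assert reference.reference_leverages["P14"] == pytest.approx(0.358)
    assert set(reference.reference_predictions) == set(des.compound_ids)
    # activity range of the synthesized series
    assert reference.synthesized.y.max() == pytest.approx(5.680)


def test_dataset_invariants_enforced():
    with pytest.raises(DatasetError, match="duplicate compound id"):
        DescriptorDataset(["A", "A"], ["d1"], np.zeros((2, 1)))
    with pytest.raises(DatasetError, match="non-finite"):
        DescriptorDataset(["A", "B"], ["d1"], np.array([[1.0], [np.inf]]))
    with pytest.raises(DatasetError, match="split"):
        DescriptorDataset(["A", "B"], ["d1"], np.zeros((2, 1)), split=["train", "weird"])


def test_write_read_roundtrip_model(tmp_path, reference_train):
    model = fit_ols(reference_train)
    out = tmp_path / "model.json"
    write_report(model, out)
    back = read_report(out)
    assert back["__type__"] == "ModelFit"
    np.testing.assert_array_equal(back["coefficients"], model.coefficients)
    assert back["intercept"] == model.intercept  # exact float round trip


def test_write_csv_requires_tabular(tmp_path, reference_train):
    model = fit_ols(reference_train)
    with pytest.raises(TypeError):
        write_report(model, tmp_path / "model.csv")


def test_write_report_unwritable_path(reference_train):
    model = fit_ols(reference_train)
    with pytest.raises(FileNotFoundError):
        write_report(model, "/no/such/dir/model.json")


def test_dataset_csv_roundtrip(tmp_path, reference):
    ds = reference.synthesized
    p = tmp_path / "ds.csv"
    ds.to_frame().to_csv(p, index=False)
    back = load_descriptor_table(p, activity_column="pIC50", split_column="split")
    assert back.compound_ids == ds.compound_ids
    assert back.descriptor_names == ds.descriptor_names
    np.testing.assert_array_equal(back.X, ds.X)
    np.testing.assert_array_equal(back.y, ds.y)


def test_random_split_seeded():
    ds = DescriptorDataset(
        [f"C{i}" for i in range(30)], ["d0"], np.arange(30.0).reshape(-1, 1)
    )
    a = random_split(ds, test_fraction=0.2, seed=5)
    b = random_split(ds, test_fraction=0.2, seed=5)
    c = random_split(ds, test_fraction=0.2, seed=6)
    assert list(a.split) == list(b.split)
    assert list(a.split) != list(c.split)
    assert sum(s == "test" for s in a.split) == 6


def test_random_split_bad_fraction():
    ds = DescriptorDataset(["A", "B"], ["d0"], np.zeros((2, 1)))
    with pytest.raises(ValueError):
        random_split(ds, test_fraction=1.2)
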