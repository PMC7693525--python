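import numpy as np
import pandas as pd
import pytest

import qpcrmiss as q
from conftest import make_dataset


def _long_df():
    return pd.DataFrame(
        {
            "gene": ["g1"] * 4 + ["g2"] * 4,
            "sample": ["s1", "s2", "s3", "s4"] * 2,
            "cq": [28.0, 29.0, 30.0, 31.0, 35.0, 40.0, 36.0, 37.0],
            "sample_type": ["A", "A", "B", "B"] * 2,
        }
    )


def test_sentinel_at_limit_becomes_nondetect(tmp_path):
    f = tmp_path / "d.csv"
    _long_df().to_csv(f, index=False)
    ds = q.read_dataset(f, format="long", nondetect_encoding="sentinel", detection_limit=40.0)
    assert ds.detected.sum() == 7
    assert not ds.detected[list(ds.genes).index("g2"), list(ds.samples).index("s2")]
    assert np.isnan(ds.cq[1, 1])


def test_wide_format_all_below_limit_unchanged(tmp_path):
    mat = pd.DataFrame(
        [[28.0, 29.0], [35.0, 36.0]], index=["g1", "g2"], columns=["s1", "s2"]
    )
    mat.index.name = "gene"
    mat.to_csv(tmp_path / "m.csv")
    pd.DataFrame({"sample": ["s1", "s2"], "sample_type": ["A", "A"]}).to_csv(
        tmp_path / "ann.csv", index=False
    )
    ds = q.read_dataset(
        tmp_path / "m.csv", format="wide", annotations=tmp_path / "ann.csv"
    )
    assert ds.detected.all()
    np.testing.assert_array_equal(ds.cq, mat.to_numpy())


def test_all_nondetect_group_is_rejected(tmp_path):
    df = _long_df()
    df.loc[df.gene.eq("g2") & df.sample_type.eq("B"), "cq"] = 40.0
    f = tmp_path / "bad.csv"
    df.to_csv(f, index=False)
    with pytest.raises(q.ValidationError, match=r"g2"):
        q.read_dataset(f)


def test_duplicate_and_malformed_rows_are_named(tmp_path):
    df = _long_df()
    dup = pd.concat([df, df.iloc[[0]]])
    dup.to_csv(tmp_path / "dup.csv", index=False)
    with pytest.raises(q.ValidationError, match="duplicated"):
        q.read_dataset(tmp_path / "dup.csv")
    bad = df.astype({"cq": object})
    bad.loc[2, "cq"] = "not-a-number"
    bad.to_csv(tmp_path / "bad.csv", index=False)
    with pytest.raises(q.ParseError, match="row 2"):
        q.read_dataset(tmp_path / "bad.csv")


def test_round_trip_and_idempotent_validation(tmp_path):
    cq = np.array([[28.0, 29.5, np.nan, 31.0], [35.0, np.nan, 36.0, 37.0]])
    ds = make_dataset(cq, ["A", "A", "B", "B"]).validate()
    for enc in ("sentinel", "na"):
        f = tmp_path / f"{enc}.csv"
        q.write_dataset(ds, f, nondetect_encoding=enc)
        back = q.read_dataset(f, nondetect_encoding=enc)
        np.testing.assert_array_equal(back.detected, ds.detected)
        np.testing.assert_allclose(back.cq[back.detected], ds.cq[ds.detected])
        np.testing.assert_array_equal(back.sample_type, ds.sample_type)
    snap = (ds.cq.copy(), ds.detected.copy())
    ds.validate()
    np.testing.assert_array_equal(ds.detected, snap[1])
    np.testing.assert_allclose(ds.cq[ds.detected], snap[0][ds.detected])


def test_normalize_to_reference():
    cq = np.array([[20.0, 21.0], [25.0, 27.0]])
    ds = make_dataset(cq, ["A", "A"])
    out = q.normalize_to_reference(ds, "g1")
    assert list(out.genes) == ["g2"]
    np.testing.assert_allclose(out.cq[0], [5.0, 6.0])
    # a reference with any non-detect is unusable
    cq2 = np.array([[20.0, np.nan], [25.0, 27.0]])
    with pytest.raises(q.ValidationError, match="non-detect"):
        q.normalize_to_reference(make_dataset(cq2, ["A", "A"]), "g1")


@pytest.mark.parametrize("m", [1, 10])
def test_write_imputed_files_and_manifest(tmp_path, two_group_ds, m):
    ds = two_group_ds.validate()
    if m == 1:
        imps = q.mean_impute(ds)
    else:
        imps = q.mi_impute(ds, m=m, sources=("epsilon",), seed=1)
    files = q.write_imputed(ds, imps, tmp_path / "out")
    assert len(files) == m
    manifest = (tmp_path / "out" / "manifest.json").read_text()
    assert f'"m": {m}' in manifest
    df = pd.read_csv(files[0])
    assert df["imputed"].sum() == 1  # the one non-detect is flagged
    assert np.isfinite(df["cq"]).all()


def test_write_imputed_rejects_empty(tmp_path, two_group_ds):
    imps = q.ImputationSet(completed=[], sources=frozenset(), m=0, seed=None,
                           base_fit=None, base_mech=None)
    with pytest.raises(q.ValidationError):
        q.write_imputed(two_group_ds, imps, tmp_path / "x")
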