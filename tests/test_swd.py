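import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import sdmkit as sk
from sdmkit.swd import SWDFormatError, _round_half_down, holdout_spec


def random_table(seed, n_pres=5, n_bg=7, n_vars=3, with_missing=False):
    rng = np.random.default_rng(seed)
    n = n_pres + n_bg
    data = pd.DataFrame(
        rng.normal(size=(n, n_vars)), columns=[f"v{i}" for i in range(n_vars)]
    )
    if with_missing:
        data.iloc[rng.integers(n), rng.integers(n_vars)] = np.nan
    return sk.SWDTable(
        species="sp",
        coords=rng.uniform(0, 10, size=(n, 2)),
        labels=np.r_[np.ones(n_pres, int), np.zeros(n_bg, int)],
        data=data,
    )


class TestIO:
    @given(seed=st.integers(0, 10_000), with_missing=st.booleans())
    @settings(max_examples=25, deadline=None)
    def test_roundtrip(self, tmp_path_factory, seed, with_missing):
        table = random_table(seed, with_missing=with_missing)
        path = tmp_path_factory.mktemp("swd") / "t.csv"
        sk.write_swd(table, path)
        back = sk.read_swd(path)
        assert back.equals(table)

    def test_identity_read(self, tmp_path):
        path = tmp_path / "toy.csv"
        path.write_text(
            "species,pa,X,Y,temp,rain\n"
            "sp,1,0.5,0.5,1.0,10\n"
            "sp,1,1.5,0.5,2.0,20\n"
            "sp,0,0.5,1.5,3.0,30\n"
            "sp,0,1.5,1.5,4.0,5\n"
        )
        table = sk.read_swd(path)
        assert table.n_records == 4
        assert table.variable_names == ["temp", "rain"]
        assert list(table.labels) == [1, 1, 0, 0]
        assert table.data["temp"].tolist() == [1.0, 2.0, 3.0, 4.0]

    def test_two_file_layout(self, tmp_path):
        (tmp_path / "p.csv").write_text("species,X,Y,v\nsp,0,0,1\nsp,1,1,2\n")
        (tmp_path / "b.csv").write_text("species,X,Y,v\nsp,2,2,3\n")
        table = sk.read_swd(tmp_path / "b.csv", presence_path=tmp_path / "p.csv")
        assert table.n_presence == 2 and table.n_contrast == 1

    def test_ragged_row_cites_line(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("species,pa,X,Y,v\nsp,1,0,0,1\nsp,0,0,0\n")
        with pytest.raises(SWDFormatError, match="line 3"):
            sk.read_swd(path)

    def test_missing_cell_roundtrips_as_na_token(self, tmp_path):
        table = random_table(0, with_missing=True)
        path = tmp_path / "t.csv"
        sk.write_swd(table, path)
        assert "NA" in path.read_text()
        assert sk.read_swd(path).equals(table)

    def test_write_refuses_zero_variables(self, tmp_path):
        table = random_table(0)
        empty = sk.SWDTable(
            species="sp", coords=table.coords, labels=table.labels,
            data=table.data[[]],
        )
        with pytest.raises(SWDFormatError):
            sk.write_swd(empty, tmp_path / "x.csv")
        assert not (tmp_path / "x.csv").exists()


class TestSplits:
    def test_rounding_rule(self):
        assert _round_half_down(10 * 0.2) == 2
        assert _round_half_down(2.5) == 2   # ties go down
        assert _round_half_down(2.51) == 3

    def test_stratified_counts(self):
        table = random_table(1, n_pres=100, n_bg=100)
        train, test = sk.split_holdout(table, 0.2, seed=7)
        assert (train.n_presence, test.n_presence) == (80, 20)
        assert (train.n_contrast, test.n_contrast) == (80, 20)

    def test_partition_exact(self):
        table = random_table(2, n_pres=13, n_bg=29)
        train, test = sk.split_holdout(table, 0.3, seed=3)
        assert train.n_records + test.n_records == table.n_records
        merged = np.sort(
            np.r_[train.data["v0"].to_numpy(), test.data["v0"].to_numpy()]
        )
        assert np.allclose(merged, np.sort(table.data["v0"].to_numpy()))

    def test_ten_presences_fraction_point2(self):
        table = random_table(3, n_pres=10, n_bg=50)
        _, test = sk.split_holdout(table, 0.2, seed=0)
        assert test.n_presence == 2

    def test_deterministic(self):
        table = random_table(4, n_pres=30, n_bg=40)
        a = sk.split_holdout(table, 0.25, seed=11)
        b = sk.split_holdout(table, 0.25, seed=11)
        assert a[0].equals(b[0]) and a[1].equals(b[1])

    def test_bad_fraction(self):
        with pytest.raises(ValueError):
            sk.split_holdout(random_table(0), 1.5, seed=0)


class TestFolds:
    def test_near_equal_stratified_sizes(self):
        table = random_table(5, n_pres=40, n_bg=400)
        spec = sk.random_folds(table, k=4, seed=0)
        for fold in range(4):
            labels = table.labels[spec.assignments == fold]
            assert (labels == 1).sum() == 10
            assert (labels == 0).sum() == 100

    def test_pigeonhole(self):
        table = random_table(6, n_pres=3, n_bg=10)
        spec = sk.random_folds(table, k=2, seed=0)
        sizes = sorted(
            (table.labels[spec.assignments == f] == 1).sum() for f in range(2)
        )
        assert sizes == [1, 2]

    def test_deterministic(self):
        table = random_table(7, n_pres=20, n_bg=20)
        a = sk.random_folds(table, 4, seed=5)
        b = sk.random_folds(table, 4, seed=5)
        assert np.array_equal(a.assignments, b.assignments)

    def test_class_smaller_than_k(self):
        with pytest.raises(ValueError):
            sk.random_folds(random_table(8, n_pres=3, n_bg=30), k=4, seed=0)

    def test_import_external(self):
        table = random_table(9, n_pres=8, n_bg=8)
        ids = np.arange(16) % 4
        spec = sk.import_folds(table, ids)
        assert spec.k == 4

    def test_import_length_mismatch(self):
        with pytest.raises(ValueError):
            sk.import_folds(random_table(0), [0, 1])

    def test_import_fold_missing_class(self):
        table = random_table(10, n_pres=4, n_bg=4)
        ids = np.r_[np.zeros(4, int), np.ones(4, int)]  # fold 0 all presence
        with pytest.raises(ValueError, match="fold 0"):
            sk.import_folds(table, ids)

    def test_holdout_spec_matches_split(self):
        table = random_table(11, n_pres=30, n_bg=50)
        spec = holdout_spec(table, 0.2, seed=2)
        train, val = next(spec.iter_splits(table))
        t2, v2 = sk.split_holdout(table, 0.2, seed=2)
        assert np.allclose(
            np.sort(val.data["v0"]), np.sort(v2.data["v0"])
        )
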