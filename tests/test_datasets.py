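"""Ingestion, merging, QC filters, standardization and censoring class."""

import numpy as np
import pandas as pd
import pytest

from survcoxbench.datasets import (
    DataError,
    SurvivalDataset,
    classify_censoring,
    load_clinical,
    load_dataset,
    load_expression_matrix,
    merge_dataset,
    qc_filter_genes,
    save_dataset,
    standardize,
)


def _write_expr(path, genes, samples, values):
    df = pd.DataFrame(values, index=genes, columns=samples)
    df.to_csv(path, sep="\t", index_label="sample", float_format="%.17g")
    return df


def _make_ds(times, status, X=None, G=None, **kw):
    n = len(times)
    X = np.random.default_rng(0).standard_normal((n, 1)) if X is None else X
    G = np.random.default_rng(1).standard_normal((n, 2)) if G is None else G
    return SurvivalDataset(
        sample_ids=[f"s{i}" for i in range(n)], times=times, status=status,
        X=X, clinical_names=[f"x{j}" for j in range(X.shape[1])],
        G=G, gene_ids=[f"g{j}" for j in range(G.shape[1])], **kw)


class TestExpressionLoading:
    def test_round_trip_genes_by_samples(self, tmp_path):
        genes = ["g1", "g2", "g3"]
        samples = ["A", "B", "C", "D"]
        vals = np.arange(12.0).reshape(3, 4) / 7
        _write_expr(tmp_path / "e.tsv", genes, samples, vals)
        mat = load_expression_matrix(tmp_path / "e.tsv")
        assert mat.shape == (4, 3)
        assert list(mat.index) == samples and list(mat.columns) == genes
        np.testing.assert_array_equal(mat.to_numpy(), vals.T)

    def test_duplicate_gene_ids_rejected(self, tmp_path):
        _write_expr(tmp_path / "e.tsv", ["g1", "g1", "g2"], ["A", "B"], np.ones((3, 2)))
        with pytest.raises(DataError, match="g1"):
            load_expression_matrix(tmp_path / "e.tsv")

    def test_non_numeric_cell_named(self, tmp_path):
        df = pd.DataFrame({"A": [1.0, "oops"], "B": [2.0, 3.0]}, index=["g1", "g2"])
        df.to_csv(tmp_path / "e.tsv", sep="\t", index_label="sample")
        with pytest.raises(DataError, match="A"):
            load_expression_matrix(tmp_path / "e.tsv")


class TestClinicalLoading:
    def _write(self, path, df):
        df.to_csv(path, sep="\t", index=False)

    def test_missing_required_rows_dropped_and_counted(self, tmp_path):
        df = pd.DataFrame({
            "sample": ["a", "b", "c", "d", "e"],
            "OS.time": [10.0, 20.0, None, 40.0, 50.0],
            "OS.event": [1, 0, 1, 0, 1],
            "age": [60, 61, 62, 63, 64],
        })
        self._write(tmp_path / "c.tsv", df)
        out = load_clinical(tmp_path / "c.tsv")
        assert len(out) == 4
        assert out.attrs["n_dropped"] == 1

    def test_status_strings_mapped(self, tmp_path):
        df = pd.DataFrame({"sample": ["a", "b"], "OS.time": [1.0, 2.0],
                           "OS.event": ["Alive", "Dead"]})
        self._write(tmp_path / "c.tsv", df)
        out = load_clinical(tmp_path / "c.tsv")
        assert out["status"].tolist() == [0, 1]

    def test_stage_dummy_coding_drops_reference(self, tmp_path):
        df = pd.DataFrame({"sample": list("abcd"), "OS.time": [1.0] * 4,
                           "OS.event": [1, 0, 1, 0],
                           "stage": ["I", "II", "III", "IV"]})
        self._write(tmp_path / "c.tsv", df)
        out = load_clinical(tmp_path / "c.tsv")
        stage_cols = [c for c in out.columns if c.startswith("stage_")]
        assert len(stage_cols) == 3  # level I absorbed as reference

    def test_stage_ordinal_option(self, tmp_path):
        df = pd.DataFrame({"sample": list("abc"), "OS.time": [1.0] * 3,
                           "OS.event": [1, 1, 0], "stage": ["I", "II", "III"]})
        self._write(tmp_path / "c.tsv", df)
        out = load_clinical(tmp_path / "c.tsv", stage_ordinal=True)
        assert out["stage"].tolist() == [0, 1, 2]

    def test_missing_column_and_bad_times_raise(self, tmp_path):
        self._write(tmp_path / "c.tsv", pd.DataFrame({"sample": ["a"], "OS.time": [1.0]}))
        with pytest.raises(DataError, match="OS.event"):
            load_clinical(tmp_path / "c.tsv")
        self._write(tmp_path / "c2.tsv", pd.DataFrame(
            {"sample": ["a"], "OS.time": [-1.0], "OS.event": [1]}))
        with pytest.raises(DataError, match="a"):
            load_clinical(tmp_path / "c2.tsv")


class TestMerge:
    def test_intersection(self, tmp_path):
        expr = _write_expr(tmp_path / "e.tsv", ["g1", "g2"], ["A", "B", "C"],
                           np.arange(6.0).reshape(2, 3))
        emat = load_expression_matrix(tmp_path / "e.tsv")
        clin = pd.DataFrame({"sample": ["B", "C", "D"], "time": [1.0, 2.0, 3.0],
                             "status": [1, 0, 1]})
        ds = merge_dataset(emat, clin)
        assert ds.n == 2 and ds.sample_ids == ["B", "C"]

    def test_disjoint_sets_error(self, tmp_path):
        _write_expr(tmp_path / "e.tsv", ["g1"], ["A"], [[1.0]])
        emat = load_expression_matrix(tmp_path / "e.tsv")
        clin = pd.DataFrame({"sample": ["Z"], "time": [1.0], "status": [1]})
        with pytest.raises(DataError, match="no samples in common"):
            merge_dataset(emat, clin)

    def test_order_alignment_with_tracer(self, tmp_path):
        # same samples, scrambled order; tracer value must follow its sample
        _write_expr(tmp_path / "e.tsv", ["g1"], ["A", "B", "C"], [[10.0, 20.0, 30.0]])
        emat = load_expression_matrix(tmp_path / "e.tsv")
        clin = pd.DataFrame({"sample": ["C", "A", "B"], "time": [3.0, 1.0, 2.0],
                             "status": [1, 1, 1]})
        ds = merge_dataset(emat, clin)
        tracer = dict(zip(ds.sample_ids, ds.G[:, 0]))
        assert tracer == {"A": 10.0, "B": 20.0, "C": 30.0}


class TestQCFilter:
    @staticmethod
    def _brute_force(G, max_zero_frac, var_quantile):
        """Independent scripted re-implementation of the sequential filter."""
        keep = [j for j in range(G.shape[1])
                if np.mean(G[:, j] == 0) <= max_zero_frac]
        variances = {j: np.var(G[:, j], ddof=1) for j in keep}
        cutoff = np.quantile(list(variances.values()), var_quantile)
        return [j for j in keep if variances[j] >= cutoff]

    def _fixture(self):
        # 10 genes, n=10: 3 genes with 6/10 zeros; the other 7 with variances 1..7
        rng = np.random.default_rng(3)
        n = 10
        G = np.empty((n, 10))
        for j in range(3):
            # zero-heavy AND low-variance: a variance-first ordering would
            # spend its quantile on these instead of the real genes
            col = np.zeros(n)
            col[:4] = 0.05 * rng.standard_normal(4)
            G[:, j] = col
        for j, v in enumerate(range(1, 8)):
            col = rng.standard_normal(n) + 1.0
            col = (col - col.mean()) / col.std(ddof=1) * np.sqrt(v) + 3
            G[:, 3 + j] = col
        times = rng.uniform(1, 5, n)
        status = np.ones(n, dtype=int)
        return _make_ds(times, status, G=G)

    def test_matches_brute_force_oracle(self):
        ds = self._fixture()
        out, report = qc_filter_genes(ds, 0.5, 0.2)
        expected = self._brute_force(ds.G, 0.5, 0.2)
        assert [ds.gene_ids[j] for j in expected] == out.gene_ids
        assert report.n_removed_zero == 3
        assert report.n_genes_out == len(expected)
        assert report.n_genes_in - report.n_removed_zero - report.n_removed_lowvar \
            == report.n_genes_out

    def test_filter_order_matters(self):
        # swapping the filters changes the survivor set on this fixture:
        # zero-heavy genes have large variances, so a variance-first filter
        # would remove different low-variance genes
        ds = self._fixture()
        _, report = qc_filter_genes(ds, 0.5, 0.2)
        variances = ds.G.var(axis=0, ddof=1)
        cutoff_all = np.quantile(variances, 0.2)
        keep_var_first = variances >= cutoff_all
        survivors_swapped = [j for j in np.flatnonzero(keep_var_first)
                             if np.mean(ds.G[:, j] == 0) <= 0.5]
        assert len(survivors_swapped) != report.n_genes_out

    def test_exactly_half_zeros_retained(self):
        rng = np.random.default_rng(5)
        G = rng.standard_normal((10, 2))
        G[:5, 0] = 0.0  # exactly 50% zeros: "more than 50%" is strict
        ds = _make_ds(rng.uniform(1, 2, 10), np.ones(10, dtype=int), G=G)
        out, report = qc_filter_genes(ds, 0.5, 0.0)
        assert report.n_removed_zero == 0 and out.m == 2

    def test_zero_quantile_no_variance_removals(self):
        ds = self._fixture()
        _, report = qc_filter_genes(ds, 0.5, 0.0)
        assert report.n_removed_lowvar == 0

    def test_all_removed_raises(self):
        rng = np.random.default_rng(6)
        G = np.zeros((10, 3))
        ds = _make_ds(rng.uniform(1, 2, 10), np.ones(10, dtype=int), G=G)
        with pytest.raises(DataError, match="relax"):
            qc_filter_genes(ds, 0.4, 0.2)


class TestStandardize:
    def test_columns_become_mean0_var1(self, rng):
        ds = _make_ds(rng.uniform(1, 5, 50), rng.integers(0, 2, 50),
                      X=rng.normal(3, 2, (50, 2)), G=rng.normal(-1, 0.5, (50, 4)))
        out = standardize(ds)
        assert out.standardized
        assert np.abs(out.X.mean(0)).max() < 1e-8
        assert np.abs(out.G.var(0, ddof=1) - 1).max() < 1e-6

    def test_idempotent(self, rng):
        ds = _make_ds(rng.uniform(1, 5, 40), np.ones(40, dtype=int),
                      X=rng.normal(size=(40, 2)), G=rng.normal(size=(40, 3)))
        once = standardize(ds)
        twice = standardize(once.replace(standardized=False))
        np.testing.assert_allclose(once.X, twice.X, atol=1e-8)
        np.testing.assert_allclose(once.G, twice.G, atol=1e-8)

    def test_training_transform_on_new_rows_not_centered(self, rng):
        ds = _make_ds(rng.uniform(1, 5, 60), np.ones(60, dtype=int),
                      X=rng.normal(2, 1, (60, 1)), G=rng.normal(size=(60, 2)))
        out = standardize(ds)
        X_new = rng.normal(5, 1, (30, 1))  # shifted population
        Xs, _ = out.standardizer.apply(X_new, rng.normal(size=(30, 2)))
        assert abs(Xs.mean()) > 0.5

    def test_constant_column_named(self, rng):
        X = np.column_stack([np.ones(30), rng.normal(size=30)])
        ds = _make_ds(rng.uniform(1, 5, 30), np.ones(30, dtype=int), X=X)
        with pytest.raises(DataError, match="x0"):
            standardize(ds)


class TestCensoringClass:
    def _ds(self, n, event_frac):
        rng = np.random.default_rng(9)
        status = (rng.uniform(size=n) < event_frac).astype(int)
        return _make_ds(rng.uniform(1, 10, n), status,
                        X=rng.normal(size=(n, 1)), G=rng.normal(size=(n, 2)))

    def test_rule_application(self):
        ds = self._ds(200, 0.6)
        assert classify_censoring(ds).label == "low_censored"

    def test_small_n_always_high_censored(self):
        ds = self._ds(100, 0.9)
        assert classify_censoring(ds).label == "high_censored"

    def test_n_boundary_is_strict(self):
        for n, expected in [(175, "high_censored"), (176, "low_censored")]:
            ds = self._ds(n, 1.0)
            assert classify_censoring(ds).label == expected

    def test_censored_fraction_criterion(self):
        ds = self._ds(300, 0.95)
        out = classify_censoring(ds, criterion="censored_fraction_lt")
        assert out.label == ("low_censored" if 1 - ds.event_fraction < 0.15
                             else "high_censored")

    def test_invariant_to_row_permutation(self):
        ds = self._ds(200, 0.5)
        perm = np.random.default_rng(1).permutation(ds.n)
        assert classify_censoring(ds).label == classify_censoring(ds.subset(perm)).label


class TestContainerRoundTrip:
    def test_bit_exact(self, tmp_path, small_ds):
        ds, _ = small_ds
        save_dataset(ds, tmp_path / "d.npz")
        back = load_dataset(tmp_path / "d.npz")
        np.testing.assert_array_equal(ds.X, back.X)
        np.testing.assert_array_equal(ds.G, back.G)
        np.testing.assert_array_equal(ds.times, back.times)
        assert ds.sample_ids == back.sample_ids
        assert ds.gene_ids == back.gene_ids
        assert back.standardized == ds.standardized
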