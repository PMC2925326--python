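import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from adipomod import (
    ExpressionMatrix,
    ParseError,
    QCParams,
    quantile_normalize,
    read_expression_matrix,
    read_trait_table,
    sample_qc,
    write_expression_matrix,
    write_trait_table,
    TraitTable,
)
from adipomod.data_io import read_probe_annotation, write_probe_annotation

from conftest import make_matrix


class TestReaders:
    def test_tsv_parses_values_as_printed(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("probe_id\tS1\tS2\nA\t1\t4\nB\t2\t5\nC\t3\t6\n")
        m = read_expression_matrix(p)
        assert m.shape == (3, 2)
        assert m.values.loc["B", "S2"] == 5.0
        assert not m.normalized

    def test_duplicate_probe_id_is_named_in_error(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("probe_id\tS1\nA\t1\nA\t2\n")
        with pytest.raises(ParseError, match="A"):
            read_expression_matrix(p)

    def test_non_numeric_cell_rejected(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("probe_id\tS1\nA\tx\n")
        with pytest.raises(ParseError):
            read_expression_matrix(p)

    def test_expression_round_trip(self, tmp_path, rng):
        m = make_matrix(rng.uniform(1, 100, size=(50, 10)))
        path = tmp_path / "rt.tsv"
        write_expression_matrix(m, path)
        back = read_expression_matrix(path)
        np.testing.assert_array_equal(back.values.to_numpy(), m.values.to_numpy())
        assert back.probe_ids == m.probe_ids
        assert back.sample_ids == m.sample_ids

    def test_geo_series_matrix_dialect(self, tmp_path):
        p = tmp_path / "gse.txt"
        p.write_text(
            "!Series_title\t\"x\"\n"
            "!series_matrix_table_begin\n"
            '"ID_REF"\t"GSM1"\t"GSM2"\n'
            '"ILMN_1"\t1.5\t2.5\n'
            '"ILMN_2"\t3.0\t4.0\n'
            "!series_matrix_table_end\n"
        )
        m = read_expression_matrix(p, format="geo_series_matrix")
        assert m.probe_ids == ["ILMN_1", "ILMN_2"]
        assert m.values.loc["ILMN_2", "GSM1"] == 3.0

    def test_trait_table_missing_and_gender_coding(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("sample_id\tgender\tglucose\nS1\tM\t5.1\nS2\tF\t\nS3\tF\t6.0\n")
        t = read_trait_table(p, gender_labels={"M": 0, "F": 1})
        assert list(t.values["gender"]) == [0.0, 1.0, 1.0]
        assert np.isnan(t.values.loc["S2", "glucose"])
        assert "S2" in t.sample_ids  # sample retained despite missing value

    def test_unknown_gender_label_rejected(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("sample_id\tgender\nS1\tQ\n")
        with pytest.raises(ParseError, match="gender"):
            read_trait_table(p, gender_labels={"M": 0, "F": 1})

    def test_trait_round_trip(self, tmp_path, rng):
        df = pd.DataFrame(
            {"gender": rng.integers(0, 2, 75).astype(float),
             "BMI": rng.uniform(35, 70, 75)},
            index=[f"S{i}" for i in range(75)],
        )
        df.iloc[3, 1] = np.nan
        t = TraitTable(values=df)
        path = tmp_path / "tt.tsv"
        write_trait_table(t, path)
        back = read_trait_table(path)
        pd.testing.assert_frame_equal(back.values, t.values, check_names=False)

    def test_annotation_round_trip(self, tmp_path):
        from adipomod import ProbeAnnotation

        ann = ProbeAnnotation(mapping={"P1": "TNF", "P2": None, "P3": "CD68"})
        path = tmp_path / "ann.tsv"
        write_probe_annotation(ann, path)
        back = read_probe_annotation(path)
        assert back.mapping == ann.mapping


class TestQuantileNormalize:
    def test_hand_computed_order_statistic_means(self):
        m = make_matrix(np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]]))
        out = quantile_normalize(m)
        expected = np.array([[1.5, 1.5], [3.5, 3.5], [5.5, 5.5]])
        np.testing.assert_allclose(out.values.to_numpy(), expected)
        assert out.normalized

    def test_identical_columns_are_fixed_point(self, rng):
        col = rng.uniform(0, 10, 20)
        m = make_matrix(np.column_stack([col, col, col]))
        out = quantile_normalize(m)
        np.testing.assert_allclose(out.values.to_numpy(), m.values.to_numpy())

    def test_matches_sort_and_average_oracle(self, rng):
        X = rng.uniform(0, 100, size=(50, 5))
        out = quantile_normalize(make_matrix(X)).values.to_numpy()
        # oracle: independent sort-and-average
        ref = np.sort(X, axis=0).mean(axis=1)
        for j in range(5):
            order = np.argsort(X[:, j])
            np.testing.assert_allclose(out[order, j], ref)
        # sorted columns identical across samples
        for j in range(1, 5):
            np.testing.assert_allclose(np.sort(out[:, j]), np.sort(out[:, 0]))
        # per-column ranks unchanged
        from scipy.stats import rankdata
        for j in range(5):
            np.testing.assert_array_equal(rankdata(out[:, j]), rankdata(X[:, j]))

    def test_ties_get_mean_of_reference_values(self):
        # column 0 has a tie at ranks 1-2; reference = mean of sorted cols
        X = np.array([[1.0, 10.0], [1.0, 20.0], [5.0, 30.0]])
        out = quantile_normalize(make_matrix(X)).values.to_numpy()
        ref = np.sort(X, axis=0).mean(axis=1)  # [5.5, 10.5, 17.5]
        assert out[0, 0] == out[1, 0] == pytest.approx(ref[:2].mean())
        assert out[2, 0] == pytest.approx(ref[2])

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            quantile_normalize(make_matrix(np.array([[1.0], [2.0]])))

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_idempotent(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.uniform(0, 50, size=(20, 4))
        once = quantile_normalize(make_matrix(X))
        twice = quantile_normalize(
            ExpressionMatrix(values=once.values, tissue=once.tissue, normalized=False)
        )
        np.testing.assert_allclose(
            twice.values.to_numpy(), once.values.to_numpy(), atol=1e-9
        )


class TestSampleQC:
    def _correlated_matrix(self, rng, n_samples=20, n_probes=200):
        base = rng.uniform(2, 12, n_probes)
        return base[:, None] + 0.1 * rng.standard_normal((n_probes, n_samples))

    def test_clean_samples_pass(self, rng):
        m = make_matrix(self._correlated_matrix(rng), normalized=True)
        kept, report = sample_qc(m, QCParams(check_pca=False))
        assert report.flagged_samples == []
        assert kept.shape == m.shape

    def test_permuted_sample_flagged_for_low_correlation(self, rng):
        X = self._correlated_matrix(rng)
        X[:, 7] = rng.permutation(X[:, 7])  # breaks probe structure
        m = make_matrix(X, normalized=True)
        kept, report = sample_qc(
            m, QCParams(check_pca=False, check_median_intensity=False)
        )
        assert report.flagged_samples == ["S7"]
        assert "correlation" in report.flagged["S7"][0]
        assert kept.shape[1] == 19

    def test_all_criteria_disabled_is_identity(self, rng):
        X = rng.standard_normal((50, 10))
        m = make_matrix(X, normalized=True)
        kept, report = sample_qc(
            m,
            QCParams(check_correlation=False, check_median_intensity=False, check_pca=False),
        )
        assert report.flagged_samples == []
        np.testing.assert_array_equal(kept.values.to_numpy(), X)

    def test_flagging_monotone_in_correlation_threshold(self, rng):
        X = self._correlated_matrix(rng)
        X[:, 3] = rng.permutation(X[:, 3])
        m = make_matrix(X, normalized=True)
        flagged_sets = []
        for thr in (0.5, 0.8, 0.95):
            try:
                _, rep = sample_qc(
                    m,
                    QCParams(min_mean_intersample_correlation=thr,
                             check_pca=False, check_median_intensity=False),
                )
                flagged_sets.append(set(rep.flagged_samples))
            except ValueError:
                flagged_sets.append(set(m.sample_ids))
        assert flagged_sets[0] <= flagged_sets[1] <= flagged_sets[2]

    def test_all_samples_flagged_is_error(self, rng):
        X = rng.standard_normal((30, 5))  # mutually near-uncorrelated
        m = make_matrix(X, normalized=True)
        with pytest.raises(ValueError):
            sample_qc(m, QCParams(min_mean_intersample_correlation=1.0,
                                  check_pca=False, check_median_intensity=False))
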