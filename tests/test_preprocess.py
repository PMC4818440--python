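import numpy as np
import pandas as pd
import pytest

from pairedconcord import preprocess as pp
from pairedconcord.core_model import ExpressionMatrix, SampleSheet
from pairedconcord.errors import DomainError

from conftest import make_sheet


def matrix_from_array(arr, detected=None):
    arr = np.asarray(arr, dtype=float)
    values = pd.DataFrame(
        arr,
        index=[f"p{i}" for i in range(arr.shape[0])],
        columns=[f"s{j}" for j in range(arr.shape[1])],
    )
    m = ExpressionMatrix.from_values(values)
    if detected is not None:
        det = pd.DataFrame(np.asarray(detected, bool), index=values.index, columns=values.columns)
        m = ExpressionMatrix(values, det)
    return m


class TestLog2Transform:
    def test_closed_form(self):
        m = matrix_from_array([[8.0]])
        out = pp.log2_transform(m, offset=0.0)
        assert out.values.iloc[0, 0] == 3.0

    def test_offset_one_at_zero(self):
        m = matrix_from_array([[0.0]])
        out = pp.log2_transform(m, offset=1.0)
        assert out.values.iloc[0, 0] == 0.0

    def test_pass_through_mode(self):
        m = matrix_from_array([[5.0, -2.0]])
        out = pp.log2_transform(m, already_log2=True)
        assert out.values.equals(m.values)

    def test_nonpositive_domain_error(self):
        m = matrix_from_array([[-3.0]])
        with pytest.raises(DomainError):
            pp.log2_transform(m, offset=1.0)

    def test_detection_flags_unchanged(self):
        m = matrix_from_array([[1.0, 2.0]], detected=[[True, False]])
        out = pp.log2_transform(m, offset=1.0)
        assert out.detected.equals(m.detected)


class TestSampleDetectionFilter:
    def sheet(self):
        return make_sheet(2)

    def matrix(self, frac_bad=0.25):
        # 8 probes; t0_second detected at frac_bad, everything else fully detected
        det = np.ones((8, 4), bool)
        n_bad = int(round((1 - frac_bad) * 8))
        det[:n_bad, 1] = False  # column order: t0_first, t0_second, t1_first, t1_second
        values = np.full((8, 4), 5.0)
        m = matrix_from_array(values, det)
        m.values.columns = ["t0_first", "t0_second", "t1_first", "t1_second"]
        m.detected.columns = m.values.columns
        return ExpressionMatrix(m.values, m.detected)

    def test_below_threshold_removes_pair(self):
        m = self.matrix(frac_bad=0.25)
        out, report = pp.filter_samples_by_detection(m, self.sheet(), 0.30)
        assert out.sample_ids == ["t1_first", "t1_second"]
        removed = {e["sample_id"] for e in report.excluded_samples}
        assert removed == {"t0_first", "t0_second"}

    def test_all_detected_unchanged(self):
        m = self.matrix(frac_bad=1.0)
        out, report = pp.filter_samples_by_detection(m, self.sheet(), 0.30)
        assert out.sample_ids == m.sample_ids
        assert report.excluded_samples == []

    def test_exactly_at_threshold_retained(self):
        # strict <: a sample with exactly 30 % detected stays
        det = np.zeros((10, 4), bool)
        det[:, [0, 2, 3]] = True
        det[:3, 1] = True  # exactly 0.30
        values = np.full((10, 4), 5.0)
        m = matrix_from_array(values, det)
        m.values.columns = ["t0_first", "t0_second", "t1_first", "t1_second"]
        m.detected.columns = m.values.columns
        m = ExpressionMatrix(m.values, m.detected)
        out, _ = pp.filter_samples_by_detection(m, self.sheet(), 0.30)
        assert out.n_samples == 4


class TestProbeFilter:
    def test_detected_in_one_sample_kept(self):
        det = np.zeros((1, 46), bool)
        det[0, 17] = True
        m = matrix_from_array(np.full((1, 46), 1.0), det)
        out, report = pp.filter_undetected_probes(m)
        assert out.n_probes == 1
        assert report.removed_probes == 0

    def test_detected_nowhere_removed(self):
        det = [[False, False], [True, False]]
        m = matrix_from_array([[1.0, 2.0], [3.0, 4.0]], det)
        out, report = pp.filter_undetected_probes(m)
        assert out.probe_ids == ["p1"]
        assert report.removed_probes == 1

    def test_all_detected_identity(self, tiny_matrix):
        out, report = pp.filter_undetected_probes(tiny_matrix)
        assert out.equals(tiny_matrix)
        assert report.removed_probes == 0

    def test_filters_commute(self, tmp_path):
        rng = np.random.default_rng(0)
        det = rng.random((20, 6)) < 0.4
        m = matrix_from_array(rng.normal(5, 1, (20, 6)), det)
        m.values.columns = [f"t{i}_{tp}" for i in range(3) for tp in ("first", "second")]
        m.detected.columns = m.values.columns
        m = ExpressionMatrix(m.values, m.detected)
        sheet = make_sheet(3)
        a, _ = pp.filter_samples_by_detection(m, sheet, 0.30)
        a, _ = pp.filter_undetected_probes(a)
        b, _ = pp.filter_undetected_probes(m)
        b, _ = pp.filter_samples_by_detection(b, sheet, 0.30)
        b, _ = pp.filter_undetected_probes(b)  # restrict to surviving samples
        assert a.sample_ids == b.sample_ids
        assert a.probe_ids == b.probe_ids


class TestQuantileNormalize:
    def test_identical_samples_unchanged(self):
        m = matrix_from_array([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0]])
        out = pp.quantile_normalize(m)
        np.testing.assert_allclose(out.values.to_numpy(), m.values.to_numpy())

    def test_hand_evaluated_sorted_mean(self):
        # sorted means of ([1,2,3],[4,5,6]) are [2.5,3.5,4.5]
        m = matrix_from_array(np.array([[1.0, 4.0], [2.0, 5.0], [3.0, 6.0]]))
        out = pp.quantile_normalize(m)
        expected = np.array([[2.5, 2.5], [3.5, 3.5], [4.5, 4.5]])
        np.testing.assert_allclose(out.values.to_numpy(), expected)

    def test_constant_sample_gets_mean_of_means(self):
        m = matrix_from_array(np.array([[1.0, 7.0], [2.0, 7.0], [3.0, 7.0]]))
        out = pp.quantile_normalize(m)
        # target vector is mean of sorted columns: [4, 4.5, 5]; constant column
        # ties across all ranks -> mean of target = 4.5 everywhere
        np.testing.assert_allclose(out.values["s1"].to_numpy(), [4.5, 4.5, 4.5])
        np.testing.assert_allclose(out.values["s0"].to_numpy(), [4.0, 4.5, 5.0])

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        m = matrix_from_array(rng.normal(8, 2, (50, 6)))
        once = pp.quantile_normalize(m)
        twice = pp.quantile_normalize(once)
        np.testing.assert_allclose(
            once.values.to_numpy(), twice.values.to_numpy(), atol=1e-12
        )

    def test_ranks_preserved(self):
        rng = np.random.default_rng(4)
        m = matrix_from_array(rng.normal(0, 1, (30, 4)))
        out = pp.quantile_normalize(m)
        for col in m.sample_ids:
            orig = m.values[col].rank()
            new = out.values[col].rank()
            assert (orig == new).all()


class TestBatchCenter:
    def test_single_batch_identity(self):
        m = matrix_from_array(np.arange(12.0).reshape(3, 4))
        m.values.columns = [f"t{i}_{tp}" for i in range(2) for tp in ("first", "second")]
        m.detected.columns = m.values.columns
        m = ExpressionMatrix(m.values, m.detected)
        out = pp.batch_center(m, make_sheet(2))
        np.testing.assert_allclose(out.values.to_numpy(), m.values.to_numpy(), atol=1e-12)

    def test_two_batches_arithmetic(self):
        # one gene; batch means 5 and 7, global 6 -> both batches centered at 6
        values = pd.DataFrame(
            [[4.0, 6.0, 6.0, 8.0]],
            index=["g0"],
            columns=["a1", "a2", "b1", "b2"],
        )
        m = ExpressionMatrix.from_values(values)
        sheet = SampleSheet(pd.DataFrame({
            "sample_id": ["a1", "a2", "b1", "b2"],
            "tumour_id": ["t1", "t1", "t2", "t2"],
            "timepoint": ["first", "second", "first", "second"],
            "study_id": ["S"] * 4,
            "batch_id": ["x", "x", "y", "y"],
            "elapsed_minutes": [None] * 4,
        }))
        out = pp.batch_center(m, sheet)
        np.testing.assert_allclose(out.values.loc["g0", ["a1", "a2"]].mean(), 6.0)
        np.testing.assert_allclose(out.values.loc["g0", ["b1", "b2"]].mean(), 6.0)
        # within-batch offsets preserved
        np.testing.assert_allclose(out.values.loc["g0"].to_numpy(), [5.0, 7.0, 5.0, 7.0])

    def test_batch_main_effects_removed_and_global_mean_kept(self):
        rng = np.random.default_rng(7)
        n_pairs = 6
        sheet_rows = []
        cols = []
        for i in range(n_pairs):
            for tp in ("first", "second"):
                sid = f"t{i}_{tp}"
                cols.append(sid)
                sheet_rows.append({
                    "sample_id": sid, "tumour_id": f"t{i}", "timepoint": tp,
                    "study_id": "S", "batch_id": f"b{i % 2}", "elapsed_minutes": None,
                })
        sheet = SampleSheet(pd.DataFrame(sheet_rows))
        values = pd.DataFrame(rng.normal(8, 1, (40, len(cols))), columns=cols,
                              index=[f"g{i}" for i in range(40)])
        m = ExpressionMatrix.from_values(values)
        out = pp.batch_center(m, sheet)
        global_mean = m.values.mean(axis=1)
        np.testing.assert_allclose(out.values.mean(axis=1), global_mean, atol=1e-12)
        for b in ("b0", "b1"):
            members = [r["sample_id"] for r in sheet_rows if r["batch_id"] == b]
            np.testing.assert_allclose(
                out.values[members].mean(axis=1), global_mean, atol=1e-12
            )

    def test_within_pair_difference_survives_batch_split(self):
        # pairs split across batches (alternating, so batch is not confounded
        # with timepoint): after centering away strong batch effects, the gene
        # with a true 2-fold (1 log2) within-pair difference still ranks top
        rng = np.random.default_rng(11)
        n_pairs, n_genes = 10, 5
        rows, cols = [], []
        for i in range(n_pairs):
            for j, tp in enumerate(("first", "second")):
                sid = f"t{i}_{tp}"
                cols.append(sid)
                rows.append({
                    "sample_id": sid, "tumour_id": f"t{i}", "timepoint": tp,
                    "study_id": "S", "batch_id": f"b{(i + j) % 2}",
                    "elapsed_minutes": None,
                })
        sheet = SampleSheet(pd.DataFrame(rows))
        batch_of = {r["sample_id"]: r["batch_id"] for r in rows}
        base = rng.normal(8, 1, (n_genes, n_pairs))
        shift = np.array([3.0 if b == "b1" else 0.0 for b in batch_of.values()])
        data = np.empty((n_genes, 2 * n_pairs))
        for i in range(n_pairs):
            data[:, 2 * i] = base[:, i]
            data[:, 2 * i + 1] = base[:, i] + rng.normal(0, 0.05, n_genes)
            data[0, 2 * i + 1] = base[0, i] + 1.0  # gene 0: true +1 log2
        data = data + shift[None, :]
        m = ExpressionMatrix.from_values(
            pd.DataFrame(data, index=[f"g{k}" for k in range(n_genes)], columns=cols)
        )
        out = pp.batch_center(m, sheet)
        firsts = [c for c in cols if c.endswith("first")]
        seconds = [c for c in cols if c.endswith("second")]
        mean_diffs = (out.values[seconds].to_numpy() - out.values[firsts].to_numpy()).mean(axis=1)
        assert np.argmax(mean_diffs) == 0
        assert mean_diffs[0] > 0.5


class TestDefaultRecipe:
    def test_report_records_stages(self, default_cohort):
        matrix, sheet, _, _ = default_cohort
        out, report = pp.run_default_recipe(matrix, sheet, do_batch_center=True)
        assert report.normalization == "quantile"
        assert report.batches_centered == ["b0"]
        assert out.n_samples == matrix.n_samples
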