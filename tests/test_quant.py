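"""Normalization, detection flags and differential statistics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp

from rlmatch.io import Condition, DataError, QuantMatrix, SampleMeta
from rlmatch.quant import (
    DetectionClass,
    compute_floor,
    default_marker_panels,
    detection_flags,
    differential,
    marker_panel_summary,
    normalize_ibaq,
    student_t_pvalue,
    volcano_table,
    welch_t_pvalue,
)

from conftest import make_matrix, make_samples


def welch_oracle(a, b):
    """Textbook Welch two-sample t-test, coded independently."""
    from scipy.stats import t as tdist

    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / na + vb / nb
    tstat = (a.mean() - b.mean()) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return 2 * tdist.sf(abs(tstat), df)


def student_oracle(a, b):
    """Textbook pooled-variance two-sample t-test, coded independently."""
    from scipy.stats import t as tdist

    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    tstat = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
    return 2 * tdist.sf(abs(tstat), na + nb - 2)


matrices = hnp.arrays(
    np.float64,
    st.tuples(st.integers(2, 12), st.just(6)),
    elements=st.one_of(st.just(0.0), st.floats(1e-6, 1e9)),
).filter(lambda m: (m.sum(axis=0) > 0).all())


class TestNormalize:
    def test_single_sample_fractions(self):
        qm = QuantMatrix(
            ["P1", "P2", "P3"],
            ["a", "b", "c"],
            np.array([[2.0, 2.0], [3.0, 3.0], [5.0, 5.0]]),
            [SampleMeta("s1", Condition.A, "b1"), SampleMeta("s2", Condition.B, "b1")],
        )
        qn = normalize_ibaq(qm)
        np.testing.assert_allclose(qn.intensities[:, 0], [0.2, 0.3, 0.5], rtol=1e-15)
        assert qn.normalized

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(matrices)
    def test_columns_sum_to_one(self, values):
        qn = normalize_ibaq(make_matrix(values))
        np.testing.assert_allclose(qn.intensities.sum(axis=0), 1.0, rtol=1e-12)
        # zeros are preserved as zeros
        assert ((values == 0) == (qn.intensities == 0)).all()

    def test_global_scale_invariance(self, rng):
        base = 10 ** rng.normal(5, 1, size=(30, 6))
        scaled = base.copy()
        scaled[:, 3] *= 10.0
        a, b = normalize_ibaq(make_matrix(base)), normalize_ibaq(make_matrix(scaled))
        np.testing.assert_allclose(a.intensities, b.intensities, rtol=1e-12)

    def test_all_zero_column_names_sample(self):
        values = np.ones((3, 6))
        values[:, 2] = 0.0
        with pytest.raises(DataError, match="stateA_b3"):
            normalize_ibaq(make_matrix(values))

    def test_double_normalization_rejected(self, random_matrix):
        qn = normalize_ibaq(random_matrix)
        with pytest.raises(DataError, match="already normalized"):
            normalize_ibaq(qn)


class TestDetectionFlags:
    def test_truth_table(self):
        values = np.array(
            [
                [0, 0, 0, 0, 0, 0],  # neither
                [0, 0, 0, 1, 2, 3],  # B_only
                [1, 2, 3, 0, 0, 0],  # A_only
                [1, 2, 3, 4, 5, 6],  # both
            ],
            dtype=float,
        )
        flags = detection_flags(make_matrix(values), min_batches=1)
        assert list(flags["detection_class"]) == ["neither", "B_only", "A_only", "both"]
        assert list(flags["n_detected_A"]) == [0, 0, 3, 3]
        assert list(flags["n_detected_B"]) == [0, 3, 0, 3]

    def test_min_batches_threshold(self):
        values = np.array([[1, 1, 1, 5, 0, 0]], dtype=float)  # 1 of 3 iN batches
        flags = detection_flags(make_matrix(values), min_batches=2)
        assert flags.at[0, "detection_class"] == "A_only"

    @pytest.mark.parametrize("bad", [0, 4, -1])
    def test_min_batches_out_of_range(self, random_matrix, bad):
        with pytest.raises(DataError, match="min_batches"):
            detection_flags(random_matrix, min_batches=bad)


class TestTwoSampleTests:
    @pytest.mark.parametrize(
        "impl,oracle",
        [(welch_t_pvalue, welch_oracle), (student_t_pvalue, student_oracle)],
        ids=["welch", "student"],
    )
    def test_matches_independent_oracle(self, rng, impl, oracle):
        for _ in range(200):
            a = rng.normal(0, 1, size=rng.integers(2, 6))
            b = rng.normal(0.5, 2, size=rng.integers(2, 6))
            assert impl(a, b) == pytest.approx(oracle(a, b), abs=1e-12)

    @pytest.mark.parametrize("impl", [welch_t_pvalue, student_t_pvalue])
    def test_degenerate_equal_groups(self, impl):
        assert impl([3.0, 3.0, 3.0], [3.0, 3.0, 3.0]) == 1.0

    @pytest.mark.parametrize("impl", [welch_t_pvalue, student_t_pvalue])
    def test_degenerate_shifted_groups(self, impl):
        assert impl([3.0, 3.0, 3.0], [4.0, 4.0, 4.0]) == 0.0


class TestDifferential:
    def test_identical_values_null_point(self):
        values = np.tile([[5.0], [3.0], [2.0]], (1, 6))
        recs = differential(normalize_ibaq(make_matrix(values)))
        for r in recs:
            assert r.log2_ratio == 0.0
            assert r.p_value == 1.0

    def test_planted_16_fold_recovered(self, rng):
        n = 200
        values = np.tile(10 ** rng.normal(5, 1, size=(n, 1)), (1, 6))
        values[0, 3:] *= 16.0  # plant 16x in condition B
        noise = 10 ** rng.normal(0, 0.01, size=(n, 6))
        qn = normalize_ibaq(make_matrix(values * noise))
        rec = differential(qn, test="welch")[0]
        assert 3.9 <= rec.log2_ratio <= 4.1
        # p-value equals a brute-force Welch computation on the same logs
        floor = compute_floor(qn)
        va = qn.condition_values(Condition.A)[0]
        vb = qn.condition_values(Condition.B)[0]
        expected = welch_oracle(np.log10(va + floor), np.log10(vb + floor))
        assert rec.p_value == pytest.approx(expected, abs=1e-12)

    def test_antisymmetry_under_label_swap(self, rng):
        values = 10 ** rng.normal(5, 1, size=(40, 6))
        values[rng.random(values.shape) < 0.1] = 0.0
        values[:, 0] += 1  # keep all columns positive
        qm = make_matrix(values)
        swapped = QuantMatrix(
            list(qm.accessions),
            list(qm.gene_symbols),
            qm.intensities.copy(),
            [
                SampleMeta(
                    s.sample_id,
                    Condition.B if s.condition == Condition.A else Condition.A,
                    s.batch,
                )
                for s in qm.samples
            ],
        )
        fwd = {r.accession: r for r in differential(normalize_ibaq(qm))}
        rev = {r.accession: r for r in differential(normalize_ibaq(swapped))}
        assert fwd.keys() == rev.keys()
        for acc, r in fwd.items():
            assert rev[acc].log2_ratio == pytest.approx(-r.log2_ratio, abs=1e-9)
            assert rev[acc].p_value == pytest.approx(r.p_value, abs=1e-12)

    def test_one_sided_detection_finite_ratio(self):
        values = np.ones((5, 6))
        values[0, :3] = 0.0  # detected only in B
        recs = {r.accession: r for r in differential(normalize_ibaq(make_matrix(values)))}
        r = recs["P00000"]
        assert r.detection_class == DetectionClass.B_only
        assert math.isfinite(r.log2_ratio) and r.log2_ratio > 0

    def test_neither_detected_excluded(self):
        values = np.ones((3, 6))
        values[1] = 0.0
        recs = differential(normalize_ibaq(make_matrix(values)))
        assert [r.accession for r in recs] == ["P00000", "P00002"]

    def test_single_batch_p_sentinel(self):
        values = np.array([[1.0, 2.0], [3.0, 4.0]])
        qm = QuantMatrix(
            ["P1", "P2"],
            ["a", "b"],
            values,
            [SampleMeta("s1", Condition.A, "b1"), SampleMeta("s2", Condition.B, "b1")],
        )
        with pytest.warns(UserWarning, match="sentinel"):
            recs = differential(normalize_ibaq(qm))
        assert all(r.p_value == 1.0 for r in recs)
        assert all(math.isfinite(r.log2_ratio) for r in recs)

    def test_bh_adjustment_never_decreases_p(self, random_matrix):
        qn = normalize_ibaq(random_matrix)
        raw = {r.accession: r.p_value for r in differential(qn)}
        adj = {r.accession: r.p_value for r in differential(qn, adjust="bh")}
        assert all(adj[a] >= raw[a] - 1e-15 for a in raw)


class TestVolcano:
    def test_minus_log10_p(self):
        values = 10 ** np.random.default_rng(5).normal(5, 1, size=(10, 6))
        recs = differential(normalize_ibaq(make_matrix(values)))
        table = volcano_table(recs)
        by_acc = {r.accession: r for r in recs}
        for row in table.itertuples():
            assert row.minus_log10_p == pytest.approx(
                -math.log10(by_acc[row.accession].p_value)
            )

    def test_row_count_matches_naive_filter(self, rng):
        values = 10 ** rng.normal(5, 1, size=(60, 6))
        values[rng.random(values.shape) < 0.3] = 0.0
        values[:, 0] += 1
        recs = differential(normalize_ibaq(make_matrix(values)))
        table = volcano_table(recs)
        naive = [
            r
            for r in recs
            if r.detection_class != DetectionClass.neither
            and math.isfinite(r.log2_ratio)
            and r.p_value > 0
        ]
        assert len(table) == len(naive)


class TestMarkerPanels:
    @staticmethod
    def _panel_matrix(rng):
        symbols = ["OCT4", "SOX2", "LIN28A", "SYP", "SHANK2", "SNCA",
                   "ATP5F1A", "TUBA1A", "OTHER1", "OTHER2"]
        base = 10 ** rng.normal(5, 0.3, size=(10, 6))
        base[:3, 3:] *= 1e-3  # pluripotency markers collapse in B
        base[3:6, :3] *= 1e-3  # neuronal markers absent in A
        return make_matrix(base, symbols=symbols)

    def test_panel_calls_match_planted_truth(self, rng):
        qn = normalize_ibaq(self._panel_matrix(rng))
        summary, calls, unresolved = marker_panel_summary(qn)
        assert calls["pluripotency"] == "enriched-in-A"
        assert calls["neuronal_synaptic"] == "enriched-in-B"
        assert calls["housekeeping"] == "balanced"
        assert unresolved == {}
        # summary carries mean +/- SEM per marker and condition
        row = summary[(summary.marker == "SYP") & (summary.condition == "iN")]
        assert len(row) == 1 and row["n"].iloc[0] == 3 and row["sem"].iloc[0] >= 0

    def test_absent_marker_reported_not_fatal(self, rng):
        qn = normalize_ibaq(self._panel_matrix(rng))
        from rlmatch.quant import MarkerPanel

        panels = [MarkerPanel("pluripotency", ("OCT4", "NANOG"))]
        summary, calls, unresolved = marker_panel_summary(qn, panels)
        assert unresolved == {"pluripotency": ["NANOG"]}
        assert calls["pluripotency"] == "enriched-in-A"

    def test_fully_unresolvable_panel_warns(self, rng):
        qn = normalize_ibaq(self._panel_matrix(rng))
        from rlmatch.quant import MarkerPanel

        with pytest.warns(UserWarning, match="empty after symbol resolution"):
            _, calls, _ = marker_panel_summary(qn, [MarkerPanel("x", ("ZZZ",))])
        assert calls["x"] == "unresolved"

    def test_default_panels_members(self):
        names = {p.panel_name: p.members for p in default_marker_panels()}
        assert names["pluripotency"] == ("OCT4", "SOX2", "LIN28A")
        assert names["neuronal_synaptic"] == ("SYP", "SHANK2", "SNCA")
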