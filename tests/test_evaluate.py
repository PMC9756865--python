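"""Confusion counts, PR curves, F1, CDS filtering, decile analysis."""

import numpy as np
import pandas as pd
import pytest

from predpair.evaluate import (
    compare_decile_distributions,
    confusion_at_threshold,
    decile_map,
    decile_trend,
    export_sparse_matrix,
    f1_per_sequence,
    filter_cds,
    import_external_matrix,
    pr_curve,
    predicted_pairs_at,
)
from predpair.synthetic import gen_accessibility_profiles, gen_stretch_sequences


def random_symmetric(rng, n):
    A = rng.random((n, n))
    S = np.minimum(A, A.T)
    np.fill_diagonal(S, 0)
    return S


class TestConfusion:
    def test_threshold_zero_predicts_everything(self):
        rng = np.random.default_rng(0)
        S = random_symmetric(rng, 6) + 0.01
        np.fill_diagonal(S, 0)
        ref = {(0, 5), (1, 4)}
        c = confusion_at_threshold(S, ref, 0.0)
        assert c.fn == 0

    def test_threshold_above_max(self):
        rng = np.random.default_rng(1)
        S = random_symmetric(rng, 6)
        ref = {(0, 5), (1, 4), (2, 3)}
        c = confusion_at_threshold(S, ref, 2.0)
        assert (c.tp, c.fp, c.fn) == (0, 0, 3)

    def test_matches_set_oracle_on_random_instances(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            S = random_symmetric(rng, 8)
            ref = {
                tuple(sorted(rng.choice(8, 2, replace=False).tolist()))
                for _ in range(4)
            }
            thr = float(rng.random())
            pred = {
                (i, j)
                for i in range(8)
                for j in range(i + 1, 8)
                if S[i, j] >= thr
            }
            c = confusion_at_threshold(S, ref, thr)
            assert c.tp == len(pred & ref)
            assert c.fp == len(pred - ref)
            assert c.fn == len(ref - pred)
            assert c.tp + c.fn == len(ref)  # conservation


class TestPRCurve:
    def test_perfect_scorer_contains_perfect_point(self):
        S = np.zeros((6, 6))
        ref = {(0, 5), (1, 4)}
        for i, j in ref:
            S[i, j] = S[j, i] = 1.0
        curve = pr_curve(S, ref, 50)
        assert ((curve["precision"] == 1.0) & (curve["recall"] == 1.0)).any()

    def test_recall_monotone_and_bounded(self):
        rng = np.random.default_rng(3)
        S = random_symmetric(rng, 10)
        ref = {(0, 9), (2, 7), (3, 6)}
        curve = pr_curve(S, ref, 200)
        assert len(curve) <= 200
        rec = curve["recall"].to_numpy()
        assert all(b <= a + 1e-12 for a, b in zip(rec, rec[1:]))
        assert ((curve[["precision", "recall"]] >= 0).all()
                & (curve[["precision", "recall"]] <= 1).all()).all()

    def test_empty_reference_raises(self):
        with pytest.raises(ValueError):
            pr_curve(np.eye(4), set(), 10)


class TestF1:
    def test_perfect(self):
        S = np.zeros((4, 4))
        ref = {(0, 3), (1, 2)}
        for i, j in ref:
            S[i, j] = S[j, i] = 1.0
        assert f1_per_sequence(S, ref, 0.5) == 1.0

    def test_zero_tp_gives_zero(self):
        S = np.zeros((4, 4))
        S[0, 1] = S[1, 0] = 1.0
        assert f1_per_sequence(S, {(2, 3)}, 0.5) == 0.0

    def test_half_half(self):
        # 1 tp, 1 fp, 1 fn -> precision = recall = 0.5 -> F1 = 0.5
        S = np.zeros((6, 6))
        for i, j in [(0, 5), (1, 4)]:
            S[i, j] = S[j, i] = 1.0
        assert f1_per_sequence(S, {(0, 5), (2, 3)}, 0.5) == pytest.approx(0.5)


class TestFilterCds:
    def _records(self):
        return pd.DataFrame(
            {
                "gene": ["a", "b", "c", "d", "e"],
                "feature": ["CDS", "CDS", "gene", "CDS", "CDS"],
                "strand": ["+", "-", "+", "+", "+"],
                "length": [300, 300, 300, 301, 300],
                "coverage": [20.0, 20.0, 20.0, 20.0, 15.0],
            }
        )

    def test_filters(self):
        kept = filter_cds(self._records())
        assert list(kept["gene"]) == ["a"]

    def test_coverage_exactly_15_dropped(self):
        recs = self._records()
        assert "e" not in set(filter_cds(recs)["gene"])

    def test_missing_field_raises(self):
        with pytest.raises(ValueError, match="missing"):
            filter_cds(pd.DataFrame({"feature": ["CDS"]}))


class TestDecileMap:
    def _table(self, n=40):
        # one gene, accessibility equal to position index (ties impossible)
        return pd.DataFrame(
            {
                "sequence_id": "g1",
                "position": np.arange(n),
                "base": ["A"] * n,
                "accessibility": np.arange(n, dtype=float),
                "coverage": 50,
            }
        )

    def test_conservation_of_counts(self):
        table = self._table()
        predicted = {"g1": {0, 5, 17, 39}}
        hist = decile_map(table, predicted)
        assert hist.sum() == 4

    def test_least_accessible_predictions_land_in_decile_one(self):
        table = self._table()
        predicted = {"g1": {0, 1, 2, 3}}  # the 10% least accessible
        hist = decile_map(table, predicted)
        assert hist[0] == 4 and hist[1:].sum() == 0

    def test_equal_count_bins(self):
        table = self._table(43)
        hist = decile_map(table, {"g1": set(range(43))})
        assert hist.sum() == 43
        assert hist.max() - hist.min() <= 1

    def test_short_gene_skipped_with_warning(self):
        table = self._table(5)
        with pytest.warns(UserWarning, match="skipped"):
            hist = decile_map(table, {"g1": {0}})
        assert hist.sum() == 0

    def test_ac_only_restricts_ranking(self):
        table = self._table(40)
        table.loc[20:, "base"] = "G"
        hist_ac = decile_map(table, {"g1": set(range(20))}, ac_only=True)
        assert hist_ac.sum() == 20  # G positions not scored

    def test_synthetic_profiles_show_monotone_trend(self):
        structures = gen_stretch_sequences(60, 50, 7, seed=21)
        table = gen_accessibility_profiles(structures, 0.2, 1.0, 0.25, seed=22)
        predicted = {s.id: s.paired_positions for s in structures}
        hist = decile_map(table, predicted, ac_only=False)
        rho, p = decile_trend(hist)
        assert rho < 0
        assert p < 0.05


class TestMannWhitney:
    def test_identical_histograms_p_near_one(self):
        hist = np.array([10, 9, 8, 7, 6, 5, 4, 3, 2, 1])
        u, p = compare_decile_distributions(hist, hist)
        assert p > 0.9

    def test_separated_distributions_small_p(self):
        a = np.array([50, 40, 5, 3, 1, 1, 0, 0, 0, 0])
        b = np.array([0, 0, 0, 0, 1, 1, 3, 5, 40, 50])
        _, p = compare_decile_distributions(a, b)
        assert p < 1e-10

    def test_matches_closed_form_u_statistic(self):
        rng = np.random.default_rng(5)
        a = rng.integers(0, 10, 10)
        b = rng.integers(0, 10, 10)
        u, _ = compare_decile_distributions(a, b)
        # brute-force U: count pairs (x from A-sample, y from B-sample) with
        # x > y plus half-ties
        xs = np.repeat(np.arange(1, 11), a)
        ys = np.repeat(np.arange(1, 11), b)
        brute = sum((x > y) + 0.5 * (x == y) for x in xs for y in ys)
        assert u == pytest.approx(brute)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            compare_decile_distributions(np.zeros(10, int), np.ones(10, int))


class TestExternalMatrix:
    def test_sparse_roundtrip_and_symmetry(self, tmp_path):
        rng = np.random.default_rng(6)
        S = random_symmetric(rng, 7)
        S[S < 0.3] = 0
        path = tmp_path / "m.psp"
        export_sparse_matrix(S, path)
        back = import_external_matrix(path, "sparse", length=7)
        np.testing.assert_allclose(back, S, atol=1e-6)

    def test_one_based_conversion(self, tmp_path):
        path = tmp_path / "m.psp"
        path.write_text("1 3 0.5\n")
        M = import_external_matrix(path, "sparse")
        assert M[0, 2] == M[2, 0] == 0.5

    def test_dense_roundtrip(self, tmp_path):
        from predpair.postprocess import save_matrix_tsv

        rng = np.random.default_rng(7)
        S = random_symmetric(rng, 5)
        path = tmp_path / "m.tsv"
        save_matrix_tsv(S, path)
        np.testing.assert_allclose(import_external_matrix(path, "dense"), S)

    def test_malformed_line_number_in_error(self, tmp_path):
        path = tmp_path / "bad.psp"
        path.write_text("1 2 0.5\n1 2\n")
        with pytest.raises(ValueError, match="line 2"):
            import_external_matrix(path, "sparse")
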