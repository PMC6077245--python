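"""FPKM, fold changes, the NB test, BH adjustment, ΔΔCt and clustering."""

import math

import numpy as np
import pandas as pd
import pytest

from lactlnc.datasets import load_shared_de_lncrnas
from lactlnc.expression import (
    ExpressionMatrix,
    bh_adjust,
    call_de,
    cluster_features,
    compute_fpkm,
    ddct_fold_change,
    log2_fold_change,
    nb_two_group_test,
)
from lactlnc.synthetic import GROUPS, SAMPLES, simulate_counts

from conftest import bh_step_up


def em(values, libs=None, groups=None):
    df = pd.DataFrame(values, columns=list(SAMPLES)[: len(values[0])] if values
                      else list(SAMPLES))
    df.index = [f"F{i}" for i in range(len(values))]
    libs = libs or [1e6] * df.shape[1]
    return ExpressionMatrix(
        df,
        pd.Series(libs, index=df.columns),
        pd.Series({s: GROUPS[s] for s in df.columns}),
    )


class TestFpkm:
    def test_formula_identity(self):
        m = em([[10, 0, 0, 0, 0, 0]])
        fpkm = compute_fpkm(m, {"F0": 1000})
        assert fpkm.values.iloc[0, 0] == pytest.approx(10.0)
        assert fpkm.values.iloc[0, 1] == 0.0

    def test_random_matrix_matches_elementwise_oracle(self):
        rng = np.random.default_rng(20)
        vals = rng.integers(0, 500, size=(15, 6)).astype(float)
        libs = rng.uniform(5e5, 2e6, size=6)
        lengths = {f"F{i}": int(rng.integers(200, 5000)) for i in range(15)}
        m = em(vals.tolist(), libs=list(libs))
        fpkm = compute_fpkm(m, lengths)
        for i in range(15):
            for j in range(6):
                expect = vals[i, j] * 1e9 / (lengths[f"F{i}"] * libs[j])
                assert fpkm.values.iloc[i, j] == pytest.approx(expect)

    def test_doubling_a_library_halves_its_column(self):
        vals = [[10, 20, 30, 40, 50, 60]]
        a = compute_fpkm(em(vals), {"F0": 1000})
        libs = [1e6] * 6
        libs[2] *= 2
        b = compute_fpkm(em(vals, libs=libs), {"F0": 1000})
        assert b.values.iloc[0, 2] == pytest.approx(a.values.iloc[0, 2] / 2)
        assert b.values.iloc[0, 0] == pytest.approx(a.values.iloc[0, 0])

    def test_missing_length_is_error(self):
        with pytest.raises(KeyError):
            compute_fpkm(em([[1, 1, 1, 1, 1, 1]]), {})


class TestLog2FoldChange:
    def test_published_rows_reproduce_printed_column(self):
        table = load_shared_de_lncrnas()
        for row in table.itertuples():
            assert log2_fold_change(row.hp_fpkm, row.lp_fpkm) == pytest.approx(
                row.log2fc, abs=5e-5
            )

    def test_identical_means_give_zero(self):
        assert log2_fold_change(3.7, 3.7) == 0.0

    def test_zero_mean_is_undefined(self):
        assert log2_fold_change(0.0, 1.52439) is None
        assert log2_fold_change(1.0, 0.0) is None

    def test_antisymmetry(self):
        rng = np.random.default_rng(21)
        for _ in range(50):
            a, b = rng.uniform(0.01, 100, size=2)
            assert log2_fold_change(a, b) == pytest.approx(
                -log2_fold_change(b, a)
            )


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_hand_computed_step_up_example(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert q == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_matches_reference_step_up_oracle(self):
        rng = np.random.default_rng(22)
        for _ in range(30):
            p = rng.uniform(size=int(rng.integers(1, 200)))
            assert np.max(np.abs(bh_adjust(p) - bh_step_up(p))) < 1e-12

    def test_q_at_least_p_and_monotone_in_sorted_order(self):
        rng = np.random.default_rng(23)
        p = rng.uniform(size=100)
        q = bh_adjust(p)
        assert (q >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestNbTest:
    def test_identical_counts_give_p_one(self):
        assert nb_two_group_test([5, 8, 13], [5, 8, 13]) == pytest.approx(
            1.0, abs=1e-9
        )

    def test_all_zero_feature_gives_p_one(self):
        assert nb_two_group_test([0, 0, 0], [0, 0, 0]) == 1.0

    def test_null_type_i_error_within_band(self):
        rng = np.random.default_rng(1)
        r = 1 / 0.1
        rejections = 0
        n = 2000
        for _ in range(n):
            c1 = rng.negative_binomial(r, r / (r + 100), 3)
            c2 = rng.negative_binomial(r, r / (r + 100), 3)
            if nb_two_group_test(c1, c2) < 0.05:
                rejections += 1
        assert 0.03 <= rejections / n <= 0.08

    def test_strong_effect_detected(self):
        rng = np.random.default_rng(2)
        r = 1 / 0.05
        c1 = rng.negative_binomial(r, r / (r + 100), 3)
        c2 = rng.negative_binomial(r, r / (r + 800), 3)
        assert nb_two_group_test(c1, c2) < 0.001

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            nb_two_group_test([1], [2, 3])


class TestCallDe:
    def test_planted_effects_recovered_without_false_positives(self):
        lengths = {f"F{i:04d}": 1000 for i in range(500)}
        planted = {
            f"F{i:04d}": 3.0 * (1 if i % 2 else -1) for i in range(20)
        }
        counts = simulate_counts(
            42, lengths, dispersion=0.1, log2fc=planted, noise="nb"
        )
        res = call_de(counts, lengths)
        sig = {r.feature_id for r in res if r.significant}
        assert sig == set(planted)

    def test_exclusive_statuses_and_directions(self):
        counts = em(
            [
                [50, 60, 55, 0, 0, 0],   # HP-only
                [0, 0, 0, 40, 45, 50],   # LP-only
                [10, 12, 11, 80, 90, 85],  # up in LP
                [0, 0, 0, 0, 0, 0],      # silent
            ]
        )
        res = {r.feature_id: r for r in call_de(counts, {f"F{i}": 1000
                                                         for i in range(4)})}
        assert (res["F0"].status, res["F0"].direction) == ("hp_only", "down")
        assert res["F0"].log2fc is None
        assert (res["F1"].status, res["F1"].direction) == ("lp_only", "up")
        assert (res["F2"].status, res["F2"].direction) == ("both", "up")
        assert res["F3"].status == "not_expressed"
        assert math.isnan(res["F3"].p_value)

    def test_empty_matrix_gives_empty_result(self):
        m = ExpressionMatrix(
            pd.DataFrame(columns=list(SAMPLES)),
            pd.Series([1e6] * 6, index=list(SAMPLES)),
            pd.Series(GROUPS),
        )
        assert call_de(m, {}) == []


class TestDdct:
    def test_zero_ddct_is_fold_change_one(self):
        assert ddct_fold_change(20, 20, [18], [18]) == pytest.approx(1.0)

    def test_minus_one_ddct_doubles(self):
        # case ΔCt one cycle below control → 2^1
        assert ddct_fold_change(19, 20, [18], [18]) == pytest.approx(2.0)

    def test_two_reference_genes_hand_example(self):
        # ΔCt_case = 20 − 18.5 = 1.5; ΔCt_control = 22 − 18.5 = 3.5
        fc = ddct_fold_change(20, 22, [18, 19], [18.5, 18.5])
        assert fc == pytest.approx(4.0)

    def test_empty_reference_list_rejected(self):
        with pytest.raises(ValueError):
            ddct_fold_change(20, 20, [], [18])


class TestClustering:
    def test_identical_rows_merge_first_at_zero_distance(self):
        fpkm = pd.DataFrame(
            [[1, 2, 3, 4, 5, 6], [1, 2, 3, 4, 5, 6], [6, 5, 4, 3, 2, 1]],
            index=["a", "b", "c"], columns=list(SAMPLES),
        )
        leaves, link = cluster_features(fpkm)
        assert sorted(link[0, :2]) == [0, 1]  # a and b first
        assert link[0, 2] == pytest.approx(0.0)
        assert leaves.index("c") in (0, 2)

    def test_anticorrelated_rows_at_distance_two(self):
        x = np.array([1.0, 2, 3, 4, 5, 6])
        y = 7 - x
        fpkm = pd.DataFrame(
            [2**x - 1, 2**y - 1], index=["a", "b"], columns=list(SAMPLES)
        )
        _, link = cluster_features(fpkm)
        assert link[0, 2] == pytest.approx(2.0)

    def test_matches_manual_average_linkage_on_three_rows(self):
        rng = np.random.default_rng(24)
        fpkm = pd.DataFrame(
            rng.uniform(0, 50, size=(3, 6)),
            index=list("abc"), columns=list(SAMPLES),
        )
        x = np.log2(fpkm.to_numpy() + 1)
        d = {}
        for i in range(3):
            for j in range(i + 1, 3):
                r = np.corrcoef(x[i], x[j])[0, 1]
                d[(i, j)] = 1 - r
        _, link = cluster_features(fpkm)
        (i, j), first = min(d.items(), key=lambda kv: kv[1])
        assert sorted(link[0, :2]) == [i, j]
        assert link[0, 2] == pytest.approx(first)
        k = ({0, 1, 2} - {i, j}).pop()
        avg = (d[tuple(sorted((i, k)))] + d[tuple(sorted((j, k)))]) / 2
        assert link[1, 2] == pytest.approx(avg)
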