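import math

import numpy as np
import pandas as pd
import pytest

from deabench import (
    ConfusionCounts,
    GroundTruth,
    WorkflowSpec,
    aggregate_ranks,
    confusion_counts,
    cross_setting_compare,
    f1_mcc,
    gmean,
    kruskal_wallis_ranks,
    label_levels,
    lodocv,
    metric_vector,
    nmcc,
    pairwise_option_compare,
    pauc,
    spearman,
)
from deabench.evaluate import METRIC_NAMES
from deabench.stats import DEAResult

from oracle_helpers import pauc_sweep


def _result(proteins, log2fc, qvalue):
    n = len(proteins)
    table = pd.DataFrame({
        "protein": proteins,
        "log2fc": log2fc,
        "pvalue": qvalue,
        "qvalue": qvalue,
        "flagged": [False] * n,
    })
    return DEAResult(table)


def _truth(de_map):
    return GroundTruth(
        is_de=dict(de_map),
        true_log2fc={p: (1.0 if d else 0.0) for p, d in de_map.items()},
    )


class TestConfusion:
    def test_perfect_calls(self):
        truth = _truth({"a": True, "b": False})
        res = _result(["a", "b"], [1.0, 0.0], [0.001, 0.9])
        c = confusion_counts(res, truth)
        assert (c.tp, c.fp, c.tn, c.fn) == (1, 0, 1, 0)

    def test_all_null_calls_count_fn(self):
        truth = _truth({f"p{i}": i < 3 for i in range(10)})
        res = _result([f"p{i}" for i in range(10)], [0.0] * 10, [1.0] * 10)
        c = confusion_counts(res, truth)
        assert c.fn == 3 and c.tn == 7 and c.tp == 0 and c.fp == 0

    def test_ten_protein_worked_table(self):
        # hand count: calls need |lfc| >= log2(1.5)~0.585 and q < 0.05
        truth = _truth({f"p{i}": i < 5 for i in range(10)})
        lfc = [1.0, 0.9, 0.3, 1.2, 0.7, 0.0, 1.5, 0.1, 0.2, 0.05]
        q = [0.01, 0.2, 0.01, 0.04, 0.03, 0.9, 0.02, 0.5, 0.6, 0.7]
        res = _result([f"p{i}" for i in range(10)], lfc, q)
        c = confusion_counts(res, truth)
        # called: p0 (TP), p3 (TP), p4 (TP), p6 (FP); p2 fails lfc, p1 fails q
        assert (c.tp, c.fp, c.tn, c.fn) == (3, 1, 4, 2)
        assert c.total == 10

    def test_protein_missing_from_truth_is_error(self):
        truth = _truth({"a": True})
        res = _result(["a", "zz"], [1.0, 0.0], [0.01, 0.9])
        with pytest.raises(KeyError):
            confusion_counts(res, truth)


class TestScalarMetrics:
    def test_nmcc_values(self):
        assert nmcc(ConfusionCounts(5, 0, 5, 0)) == 1.0
        assert nmcc(ConfusionCounts(2, 2, 2, 2)) == 0.5
        c = ConfusionCounts(3, 1, 4, 2)
        assert nmcc(c) == pytest.approx(0.5 * (10 / math.sqrt(600) + 1), abs=1e-9)

    def test_gmean_values(self):
        assert gmean(ConfusionCounts(5, 0, 5, 0)) == 1.0
        assert gmean(ConfusionCounts(9, 2, 8, 1)) == pytest.approx(math.sqrt(0.72))
        assert gmean(ConfusionCounts(0, 0, 10, 5)) == 0.0  # recall 0

    def test_f1_values(self):
        f1, mcc = f1_mcc(ConfusionCounts(5, 0, 5, 0))
        assert f1 == 1.0 and mcc == 1.0
        f1, _ = f1_mcc(ConfusionCounts(3, 1, 4, 2))
        assert f1 == pytest.approx(2 * 0.45 / 1.35, abs=1e-9)
        f1, _ = f1_mcc(ConfusionCounts(1, 1, 1, 1))  # precision = recall = 0.5
        assert f1 == pytest.approx(0.5)


class TestPAUC:
    def test_perfect_separation(self):
        truth = _truth({"a": True, "b": True, "c": False, "d": False})
        conf = pd.Series({"a": 0.99, "b": 0.98, "c": 0.1, "d": 0.05})
        assert pauc(conf, truth, 0.05) == pytest.approx(0.05)

    def test_all_equal_confidences_give_diagonal(self):
        truth = _truth({"a": True, "b": True, "c": False, "d": False})
        conf = pd.Series({"a": 0.5, "b": 0.5, "c": 0.5, "d": 0.5})
        assert pauc(conf, truth, 0.05) == pytest.approx(0.05 ** 2 / 2)

    @pytest.mark.parametrize("seed", range(25))
    @pytest.mark.parametrize("fpr_max", [0.01, 0.05, 0.1])
    def test_matches_threshold_sweep_oracle(self, seed, fpr_max):
        rng = np.random.default_rng(seed)
        n = 40
        labels = rng.random(n) < 0.4
        if labels.all() or not labels.any():
            labels[0], labels[1] = True, False
        conf = np.round(rng.random(n), 2)  # rounding forces ties
        truth = _truth({f"p{i}": bool(labels[i]) for i in range(n)})
        series = pd.Series(conf, index=[f"p{i}" for i in range(n)])
        assert pauc(series, truth, fpr_max) == pytest.approx(
            pauc_sweep(conf, labels.astype(int), fpr_max), abs=1e-12
        )

    def test_single_class_truth_rejected(self):
        truth = _truth({"a": True, "b": True})
        with pytest.raises(ValueError):
            pauc(pd.Series({"a": 0.9, "b": 0.8}), truth, 0.05)


class TestMetricVector:
    def test_perfect_workflow(self):
        truth = _truth({f"p{i}": i < 5 for i in range(10)})
        lfc = [1.0] * 5 + [0.0] * 5
        q = [0.001] * 5 + [0.999] * 5
        mv = metric_vector(_result([f"p{i}" for i in range(10)], lfc, q), truth)
        assert mv.as_array() == pytest.approx([0.01, 0.05, 0.1, 1.0, 1.0])

    def test_uninformative_workflow_analytic_paucs(self):
        truth = _truth({f"p{i}": i < 5 for i in range(10)})
        mv = metric_vector(
            _result([f"p{i}" for i in range(10)], [0.0] * 10, [0.5] * 10), truth
        )
        assert mv.pauc001 == pytest.approx(0.5e-4)
        assert mv.pauc005 == pytest.approx(1.25e-3)
        assert mv.pauc01 == pytest.approx(5e-3)


class TestRanking:
    def test_rank_final_is_mean_of_metric_ranks(self):
        metrics = pd.DataFrame(
            [[3, 1, 1, 1, 1], [1, 2, 2, 2, 2], [2, 3, 3, 3, 3]],
            index=["w1", "w2", "w3"], columns=METRIC_NAMES, dtype=float,
        )
        out = aggregate_ranks(metrics)
        # w1: ranks (1,3,3,3,3) -> 2.6; w2: (3,2,2,2,2) -> 2.2; w3: (2,1,1,1,1) -> 1.2
        assert out.loc["w1", "rank_final"] == pytest.approx(2.6)
        assert out.loc["w2", "rank_final"] == pytest.approx(2.2)
        assert out.loc["w3", "rank_final"] == pytest.approx(1.2)
        assert list(out["position"]) == [1, 2, 3]
        assert out.index[0] == "w3"

    def test_dominant_workflow_ranked_first_and_scores(self):
        rng = np.random.default_rng(0)
        metrics = pd.DataFrame(rng.random((10, 5)), columns=METRIC_NAMES,
                               index=[f"w{i}" for i in range(10)])
        metrics.loc["w7"] = 2.0  # best on every metric
        out = aggregate_ranks(metrics)
        assert out.index[0] == "w7"
        assert out.loc["w7", "ranking_score"] == 9  # N - position = 10 - 1

    def test_ties_broken_lexicographically(self):
        metrics = pd.DataFrame(
            [[1.0] * 5, [1.0] * 5], index=["zz", "aa"], columns=METRIC_NAMES
        )
        out = aggregate_ranks(metrics)
        assert list(out.index) == ["aa", "zz"]
        assert out.loc["aa", "rank_final"] == out.loc["zz", "rank_final"]

    def test_mean_rank_identity_without_ties(self):
        rng = np.random.default_rng(1)
        n = 37
        metrics = pd.DataFrame(rng.random((n, 5)), columns=METRIC_NAMES,
                               index=[f"w{i:02d}" for i in range(n)])
        out = aggregate_ranks(metrics)
        assert out["rank_final"].mean() == pytest.approx((n + 1) / 2)


class TestLevels:
    def test_hundred_workflow_partition(self):
        levels = label_levels(100, range(1, 101))
        assert [levels.count(x) for x in ("H", "RH", "RL", "L")] == [5, 20, 25, 50]

    @pytest.mark.parametrize("n, h_expected", [(7852, 393), (4720, 236),
                                               (6284, 315), (1584, 80)])
    def test_published_grid_h_counts(self, n, h_expected):
        levels = label_levels(n, range(1, n + 1))
        assert levels.count("H") == h_expected

    def test_bin_boundaries_ceiling_rule_all_n(self):
        for n in range(1, 10001):
            h = math.ceil(0.05 * n)
            rh = math.ceil(0.25 * n)
            rl = math.ceil(0.50 * n)
            # check boundary positions only; full enumeration is O(n^2)
            positions = sorted({1, h, min(h + 1, n), rh, min(rh + 1, n),
                                rl, min(rl + 1, n), n})
            levels = dict(zip(positions, label_levels(n, positions)))
            assert levels[h] == "H"
            if h + 1 <= rh:
                assert levels[min(h + 1, n)] == "RH"
            if rh + 1 <= rl:
                assert levels[min(rh + 1, n)] == "RL"
            if rl < n:
                assert levels[n] == "L"

    def test_positions_outside_range_rejected(self):
        with pytest.raises(ValueError):
            label_levels(10, [0])
        with pytest.raises(ValueError):
            label_levels(10, [11])


class TestSpearman:
    def test_identical_reversed_and_hand_example(self):
        assert spearman([1, 2, 3, 4], [1, 2, 3, 4]) == pytest.approx(1.0)
        assert spearman([1, 2, 3, 4], [4, 3, 2, 1]) == pytest.approx(-1.0)
        # 1 - 6*4/(4*15) = 0.6
        assert spearman([1, 2, 3, 4], [2, 1, 4, 3]) == pytest.approx(0.6)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            spearman([1, 1, 1], [1, 2, 3])


class TestLODOCV:
    def test_identical_datasets_give_perfect_correlation(self):
        rng = np.random.default_rng(2)
        base = pd.DataFrame(rng.random((8, 5)), columns=METRIC_NAMES,
                            index=[f"w{i}" for i in range(8)])
        r = lodocv({f"d{k}": base.copy() for k in range(4)})
        assert len(r) == 4
        np.testing.assert_allclose(r.to_numpy(), 1.0)

    def test_returns_one_value_per_dataset(self):
        rng = np.random.default_rng(3)
        tables = {
            f"d{k}": pd.DataFrame(rng.random((6, 5)), columns=METRIC_NAMES,
                                  index=[f"w{i}" for i in range(6)])
            for k in range(5)
        }
        assert set(lodocv(tables).index) == set(tables)

    def test_shared_quality_structure_recovers_positive_correlation(self):
        # datasets share one latent workflow-quality vector plus noise
        rng = np.random.default_rng(4)
        quality = rng.random(12)
        tables = {}
        for k in range(6):
            noisy = quality[:, None] + rng.normal(0, 0.15, size=(12, 5))
            tables[f"d{k}"] = pd.DataFrame(
                noisy, columns=METRIC_NAMES, index=[f"w{i:02d}" for i in range(12)]
            )
        assert lodocv(tables).mean() > 0.5


class TestKruskalWallis:
    def test_shifted_group_detected_and_null_uniformish(self):
        rng = np.random.default_rng(5)
        a = list(rng.normal(50, 10, 8))
        b = list(rng.normal(50, 10, 7))
        shifted = list(rng.normal(500, 10, 5))
        h, p = kruskal_wallis_ranks({"g1": a, "g2": b, "g3": shifted})
        assert p < 0.05
        pvals = []
        for s in range(200):
            r2 = np.random.default_rng(s)
            groups = {"a": list(r2.normal(0, 1, 6)), "b": list(r2.normal(0, 1, 6))}
            pvals.append(kruskal_wallis_ranks(groups, min_n=5)[1])
        assert 0.3 < np.mean(np.array(pvals) < 0.5) < 0.7

    def test_undersized_group_rejected(self):
        with pytest.raises(ValueError, match="4 < 5"):
            kruskal_wallis_ranks({"a": [1, 2, 3, 4], "b": [1, 2, 3, 4, 5]})


class TestOptionComparison:
    @staticmethod
    def _grid(options, deas=("ttest", "modt"), imps=("none", "zero")):
        return [
            WorkflowSpec("generic", "LFQ", norm, imp, dea)
            for norm in options for imp in imps for dea in deas
        ]

    def test_winning_option_ranked_first(self):
        specs = self._grid(["center.mean", "center.median"])
        rows = {}
        for s in specs:
            base = 0.8 if s.normalization == "center.mean" else 0.2
            rows[str(s)] = [base] * 5
        metrics = pd.DataFrame.from_dict(rows, orient="index", columns=METRIC_NAMES)
        table = pairwise_option_compare("normalization", specs, metrics)
        assert table.index[0] == "center.mean"
        assert table.loc["center.mean", "rank_final"] == 1.0

    def test_three_option_toy_matches_brute_force(self):
        options = ["none", "center.mean", "center.median"]
        specs = self._grid(options)
        rng = np.random.default_rng(6)
        metrics = pd.DataFrame(
            rng.random((len(specs), 5)),
            index=[str(s) for s in specs], columns=METRIC_NAMES,
        )
        table = pairwise_option_compare("normalization", specs, metrics)
        # brute-force re-computation of win counts for one metric
        m = METRIC_NAMES[0]
        wins = {o: 0 for o in options}
        for i, a in enumerate(options):
            for b in options[i + 1:]:
                diffs = []
                for imp in ("none", "zero"):
                    for dea in ("ttest", "modt"):
                        ka = str(WorkflowSpec("generic", "LFQ", a, imp, dea))
                        kb = str(WorkflowSpec("generic", "LFQ", b, imp, dea))
                        diffs.append(metrics.loc[ka, m] - metrics.loc[kb, m])
                if np.mean(diffs) > 0:
                    wins[a] += 1
                else:
                    wins[b] += 1
        order_oracle = sorted(options, key=lambda o: -wins[o])
        order_table = table[m].sort_values().index.tolist()
        assert order_table[0] == order_oracle[0]

    def test_unmatched_pairs_reported_as_skipped(self):
        specs = [
            WorkflowSpec("generic", "LFQ", "none", "zero", "ttest"),
            WorkflowSpec("generic", "LFQ", "center.mean", "min", "modt"),
        ]
        metrics = pd.DataFrame(
            [[0.5] * 5, [0.6] * 5], index=[str(s) for s in specs],
            columns=METRIC_NAMES,
        )
        table = pairwise_option_compare("normalization", specs, metrics)
        assert table.attrs["skipped_pairs"]


class TestCrossSetting:
    def test_padding_and_multi_protein_removal(self):
        truth = _truth({"de_absent": True, "null_absent": False,
                        "shared": True})
        res_a = _result(["shared", "de_absent", "null_absent", "P1;P2"],
                        [1.0, 1.0, 0.0, 3.0], [0.01, 0.01, 0.9, 0.001])
        res_b = _result(["shared"], [1.0], [0.01])
        counts = cross_setting_compare({"A": res_a, "B": res_b}, truth)
        # setting B never sees de_absent (-> FN) nor null_absent (-> TN);
        # the multi-protein group is dropped everywhere
        assert counts["B"].fn == 1 and counts["B"].tn == 1 and counts["B"].tp == 1
        assert counts["A"].tp == 2 and counts["A"].tn == 1
        assert counts["A"].total == counts["B"].total == 3

    def test_single_setting_rejected(self):
        truth = _truth({"a": True})
        with pytest.raises(ValueError):
            cross_setting_compare({"A": _result(["a"], [1.0], [0.01])}, truth)
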