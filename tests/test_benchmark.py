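"""Perturbation benchmark: metrics oracle, downsampling, permuted baseline."""

import itertools

import numpy as np
import pandas as pd
import pytest

from regulonkit.activity import ActivityMatrix, Signature
from regulonkit.benchmark import (
    PerturbationExperiment,
    filter_experiments,
    global_benchmark,
    per_tf_benchmark,
    permute_network,
    rank_metrics,
    size_bias,
)
from regulonkit.mor import RegulonNetwork, SignedEdge
from regulonkit import synthetic


# ---------------------------------------------------------------------------
# independent oracles

def auroc_pair_counting(scores, labels):
    """Exhaustive pair enumeration; ties count 1/2."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def auprc_rank_precision(scores, labels):
    """Mean precision at each positive's rank, stable descending sort."""
    # stable descending sort: ties keep input order
    order = [i for _, i in sorted(((-scores[i], i) for i in range(len(scores))))]
    hits, precisions = 0, []
    for rank, i in enumerate(order, start=1):
        if labels[i] == 1:
            hits += 1
            precisions.append(hits / rank)
    return sum(precisions) / len(precisions)


def make_experiment(exp_id, tf, direction=-1, lfc=-2.0):
    sig = Signature({"G1": 0.0, "G2": 0.0, "G3": 0.0}, exp_id)
    return PerturbationExperiment(exp_id, tf, direction, sig, lfc)


def matrix_from(df):
    return ActivityMatrix(
        activities=df, pvalues=df * 0.0, n_targets=(df.notna() * 5).astype(float)
    )


class TestFilterExperiments:
    @pytest.mark.parametrize(
        "direction, lfc, kept",
        [
            (-1, -0.5, False),
            (-1, -1.2, True),
            (-1, -1.0, True),   # boundary retained under strict "> -1 excluded"
            (1, 3.0, True),     # overexpression passes unfiltered
            (1, None, True),
        ],
    )
    def test_effective_knockdown_rule(self, direction, lfc, kept):
        exp = make_experiment("e", "TF1", direction, lfc)
        assert (filter_experiments([exp]) == [exp]) is kept

    def test_missing_logfc_knockdown_excluded_with_warning(self, caplog):
        exp = make_experiment("e", "TF1", -1, None)
        with caplog.at_level("WARNING"):
            assert filter_experiments([exp]) == []
        assert "without perturbed-TF logFC" in caplog.text


class TestRankMetrics:
    def test_perfect_separation(self):
        assert rank_metrics([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == (1.0, 1.0)

    def test_interleaved_worked_example(self):
        auroc, auprc = rank_metrics([0.9, 0.6, 0.4, 0.2], [1, 0, 0, 1])
        assert auroc == pytest.approx(0.5)
        assert auprc == pytest.approx(0.75)  # (1/1 + 2/4) / 2

    def test_all_ties_gives_half(self):
        auroc, _ = rank_metrics([1.0, 1.0], [1, 0])
        assert auroc == pytest.approx(0.5)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            rank_metrics([1.0, 2.0], [1, 1])

    @pytest.mark.parametrize(
        "scores",
        [
            [0.9, 0.8, 0.7, 0.6, 0.5, 0.4],
            [0.5, 0.5, 0.3, 0.3, 0.2, 0.1],  # ties
            [1.0, 1.0, 1.0, 0.0, 0.0, 0.0],
            [3.0, -1.0, 2.5, 2.5, 0.0, -2.0],
        ],
    )
    def test_exhaustive_labelings_match_oracles(self, scores):
        n = len(scores)
        for labels in itertools.product([0, 1], repeat=n):
            if sum(labels) in (0, n):
                continue
            auroc, auprc = rank_metrics(scores, list(labels))
            assert auroc == pytest.approx(auroc_pair_counting(scores, labels))
            assert auprc == pytest.approx(auprc_rank_precision(scores, labels))

    def test_cross_check_sklearn_on_distinct_scores(self):
        from sklearn.metrics import average_precision_score, roc_auc_score

        rng = np.random.default_rng(9)
        for _ in range(25):
            n = int(rng.integers(4, 30))
            scores = rng.normal(size=n)
            labels = rng.integers(0, 2, size=n)
            if labels.sum() in (0, n):
                continue
            auroc, auprc = rank_metrics(scores, labels)
            assert auroc == pytest.approx(roc_auc_score(labels, scores))
            assert auprc == pytest.approx(average_precision_score(labels, scores))


class TestGlobalBenchmark:
    def test_perfect_predictor_all_samples_one(self):
        exps = [make_experiment(f"e{i}", f"TF{i}") for i in range(3)]
        df = pd.DataFrame(
            {
                "TF0": [-10.0, 0.0, 0.0],
                "TF1": [0.0, -10.0, 0.0],
                "TF2": [0.0, 0.0, -10.0],
            },
            index=["e0", "e1", "e2"],
        )
        res = global_benchmark(matrix_from(df), exps, n_perm=50, seed=1)
        assert np.all(res.auroc_samples == 1.0)
        assert np.all(res.auprc_samples == 1.0)
        assert res.median_auroc == 1.0 and res.median_auprc == 1.0

    def test_balanced_classes_downsample_is_identity(self):
        # positives (3,2,1) vs negatives (2.5,1.5,0.5): AUROC = 6/9
        exps = [make_experiment(f"e{i}", f"TF{i}", direction=1) for i in range(3)]
        df = pd.DataFrame(
            {
                "TF0": [3.0, 2.5, np.nan],
                "TF1": [np.nan, 2.0, 1.5],
                "TF2": [0.5, np.nan, 1.0],
            },
            index=["e0", "e1", "e2"],
        )
        res = global_benchmark(matrix_from(df), exps, n_perm=30, seed=2)
        assert res.n_positives == res.n_negatives == 3
        assert np.all(res.auroc_samples == pytest.approx(6 / 9))

    def test_knockdown_sign_correction(self):
        # raw activity -3 for the perturbed TF of a knockdown ranks above +2
        exps = [
            make_experiment("e0", "TFA", direction=-1),
            make_experiment("e1", "TFB", direction=-1),
        ]
        df = pd.DataFrame(
            {"TFA": [-3.0, -2.5], "TFB": [2.0, -1.0]}, index=["e0", "e1"]
        )
        res = global_benchmark(matrix_from(df), exps, n_perm=10, seed=0)
        # corrected scores: TFA: (3, 2.5) labels (1, 0); TFB: (-2, 1) labels (0, 1)
        assert res.median_auroc == pytest.approx(
            auroc_pair_counting([3, 2.5, -2, 1], [1, 0, 0, 1])
        )

    def test_experiment_with_unscored_perturbed_tf_dropped(self, caplog):
        exps = [
            make_experiment("e0", "TFA"),
            make_experiment("e1", "MISSING"),
        ]
        df = pd.DataFrame({"TFA": [-5.0, 1.0], "TFB": [0.0, 0.2]}, index=["e0", "e1"])
        with caplog.at_level("WARNING"):
            res = global_benchmark(matrix_from(df), exps, n_perm=10, seed=0)
        assert res.n_positives == 1  # only e0 contributes a positive
        assert "dropped" in caplog.text

    def test_determinism_bit_identical(self):
        net = synthetic.simulate_network(6, 8, 0.3, 60, seed=3)
        exps = synthetic.simulate_compendium(
            net, params=synthetic.PerturbationParams(effect_size=1.0, noise_sd=4.0),
            seed=4,
        )
        from regulonkit.activity import infer_activities

        m = infer_activities(exps, net)
        r1 = global_benchmark(m, exps, n_perm=40, seed=7)
        r2 = global_benchmark(m, exps, n_perm=40, seed=7)
        assert np.array_equal(r1.auroc_samples, r2.auroc_samples)
        assert np.array_equal(r1.auprc_samples, r2.auprc_samples)
        r3 = global_benchmark(m, exps, n_perm=40, seed=8)
        assert not np.array_equal(r1.auroc_samples, r3.auroc_samples)


class TestPerTfBenchmark:
    def _compendium(self):
        exps = []
        # TFA perturbed 5x, TFB 4x, plus TFC once (negatives for both)
        for i in range(5):
            exps.append(make_experiment(f"a{i}", "TFA", direction=1))
        for i in range(4):
            exps.append(make_experiment(f"b{i}", "TFB", direction=1))
        exps.append(make_experiment("c0", "TFC", direction=1))
        rng = np.random.default_rng(0)
        index = [e.id for e in exps]
        df = pd.DataFrame(
            rng.normal(size=(10, 3)), index=index, columns=["TFA", "TFB", "TFC"]
        )
        # make TFA separable: its own experiments score highest
        df.loc[[f"a{i}" for i in range(5)], "TFA"] = [5.0, 4.8, 4.6, 4.4, 4.2]
        return exps, matrix_from(df)

    def test_threshold_excludes_sparse_tfs(self):
        exps, m = self._compendium()
        res = per_tf_benchmark(m, exps, min_experiments=5, n_perm=20, seed=1)
        assert set(res) == {"TFA"}

    def test_separable_tf_gets_auroc_one(self):
        exps, m = self._compendium()
        res = per_tf_benchmark(m, exps, min_experiments=5, n_perm=20, seed=1)
        assert res["TFA"].median_auroc == 1.0

    def test_no_eligible_tf_returns_empty_with_warning(self, caplog):
        exps, m = self._compendium()
        with caplog.at_level("WARNING"):
            res = per_tf_benchmark(m, exps, min_experiments=50, n_perm=5, seed=1)
        assert res == {}


class TestPermuteNetwork:
    def test_degree_and_sign_multiset_preserved(self, tiny_network):
        pm = permute_network(tiny_network, seed=0)
        assert len(pm) == len(tiny_network)
        degree = lambda net: {tf: len(net.regulon(tf)) for tf in net.tfs}
        assert degree(pm) == degree(tiny_network)
        assert sorted((e.target, e.sign) for e in pm.edges) == sorted(
            (e.target, e.sign) for e in tiny_network.edges
        )

    def test_no_duplicate_pairs_after_permutation(self):
        net = synthetic.simulate_network(10, 15, 0.4, 40, seed=5)  # dense: collisions
        pm = permute_network(net, seed=6)
        pairs = [(e.tf, e.target) for e in pm.edges]
        assert len(pairs) == len(set(pairs))

    def test_same_seed_identical(self, tiny_network):
        a = permute_network(tiny_network, seed=42)
        b = permute_network(tiny_network, seed=42)
        assert [(e.tf, e.target, e.sign) for e in a.edges] == [
            (e.tf, e.target, e.sign) for e in b.edges
        ]


class TestSizeBias:
    def _matrix(self, acts, counts, index=("e0", "e1")):
        df = pd.DataFrame(acts, index=list(index))
        nt = pd.DataFrame(counts, index=list(index))
        return ActivityMatrix(activities=df, pvalues=df * 0.0, n_targets=nt)

    def test_perfect_linearity_gives_mean_r_one(self, tiny_network):
        m = self._matrix(
            {"TFA": [1.0, 2.0], "TFB": [-2.0, -4.0], "TFC": [3.0, 6.0]},
            {"TFA": [10, 20], "TFB": [20, 40], "TFC": [30, 60]},
        )
        mean_r, per_exp, _ = size_bias(m, tiny_network, {"TF1"})
        assert mean_r == pytest.approx(1.0)
        assert set(per_exp) == {"e0", "e1"}

    def test_hand_set_pearson_value(self, tiny_network):
        acts = {"TFA": [1.0, 0.5], "TFB": [-2.0, 1.0], "TFC": [0.5, 2.0]}
        counts = {"TFA": [3, 3], "TFB": [10, 10], "TFC": [5, 5]}
        from scipy.stats import pearsonr

        mean_r, per_exp, _ = size_bias(self._matrix(acts, counts), tiny_network, set())
        expected_e0 = pearsonr([1.0, 2.0, 0.5], [3, 10, 5]).statistic
        assert per_exp["e0"] == pytest.approx(expected_e0)

    def test_independent_scores_give_near_zero_mean_r(self):
        rng = np.random.default_rng(11)
        n_tf, n_exp = 60, 30
        tfs = [f"TF{i:02d}" for i in range(n_tf)]
        acts = pd.DataFrame(
            rng.normal(size=(n_exp, n_tf)),
            index=[f"e{i}" for i in range(n_exp)], columns=tfs,
        )
        counts = pd.DataFrame(
            np.tile(rng.integers(5, 50, size=n_tf), (n_exp, 1)),
            index=acts.index, columns=tfs,
        )
        net = RegulonNetwork(edges=[SignedEdge(tf, "G1", 1) for tf in tfs])
        m = ActivityMatrix(activities=acts, pvalues=acts * 0.0, n_targets=counts)
        mean_r, per_exp, _ = size_bias(m, net, set(tfs[:10]))
        # null Pearson r has sd ~ 1/sqrt(n_tf); the mean over n_exp experiments
        # concentrates further
        assert abs(mean_r) < 3 / np.sqrt(n_tf * n_exp) * 3

    def test_constant_activity_skipped_with_warning(self, tiny_network, caplog):
        m = self._matrix(
            {"TFA": [1.0, 1.0], "TFB": [1.0, 2.0], "TFC": [-1.0, 3.0]},
            {"TFA": [3, 3], "TFB": [10, 10], "TFC": [5, 5]},
            index=("e0", "e1"),
        )
        m.activities.loc["e0"] = [1.0, 1.0, -1.0]  # |.| constant
        with caplog.at_level("WARNING"):
            _, per_exp, _ = size_bias(m, tiny_network, set())
        assert "e0" not in per_exp

    def test_target_count_ttest_direction(self):
        edges = []
        for i, tf in enumerate([f"BIG{k}" for k in range(5)]):
            edges += [SignedEdge(tf, f"G{i}_{j}", 1) for j in range(20 + i)]
        for i, tf in enumerate([f"SMALL{k}" for k in range(5)]):
            edges += [SignedEdge(tf, f"H{i}_{j}", 1) for j in range(3 + i)]
        net = RegulonNetwork(edges=edges)
        df = pd.DataFrame(
            {tf: [1.0, 2.0] for tf in net.tfs}, index=["e0", "e1"]
        )
        m = ActivityMatrix(activities=df, pvalues=df * 0.0, n_targets=df * 0 + 5)
        _, _, (t, p) = size_bias(m, net, {f"BIG{k}" for k in range(5)})
        assert t > 0 and p < 0.01
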