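"""PAM clustering, accuracy, AUC, false-positive signs, threshold sweep."""

import itertools

import numpy as np
import pandas as pd
import pytest

import otubench as ob
from otubench.evaluate import ClusteringResult, auc_from_results


def _dist(points):
    points = np.asarray(points, dtype=float)
    return np.sqrt(((points[:, None, :] - points[None, :, :]) ** 2).sum(-1))


class TestPAM:
    def test_recovers_two_tight_pairs(self):
        d = _dist([[0.0, 0], [0.1, 0], [10, 0], [10.1, 0]])
        result = ob.pam(d, k=2)
        ids = sorted(result.cluster_of_sample)
        labels = [result.cluster_of_sample[s] for s in ids]
        assert labels[0] == labels[1] != labels[2] == labels[3]

    def test_matches_brute_force_medoid_enumeration(self):
        # SWAP only guarantees a local optimum, but on small problems it
        # should almost always coincide with the exhaustive-enumeration
        # global optimum, and can never beat it
        rng = np.random.default_rng(0)
        n_exact = 0
        for _ in range(20):
            d = _dist(rng.uniform(0, 1, (6, 2)))
            result = ob.pam(d, k=2)
            best = min(
                d[:, list(meds)].min(axis=1).sum()
                for meds in itertools.combinations(range(6), 2)
            )
            assert result.objective >= best - 1e-9
            n_exact += abs(result.objective - best) < 1e-9
        assert n_exact >= 15

    def test_k_equals_n(self):
        d = _dist([[0, 0], [1, 0], [2, 0]])
        result = ob.pam(d, k=3)
        assert result.objective == 0.0
        assert len(result.medoids) == 3

    def test_local_optimality_of_returned_solution(self):
        rng = np.random.default_rng(1)
        d = _dist(rng.uniform(0, 1, (12, 3)))
        result = ob.pam(pd.DataFrame(d, index=[f"S{j+1:03d}" for j in range(12)],
                                     columns=[f"S{j+1:03d}" for j in range(12)]), k=2)
        ids = list(result.cluster_of_sample)
        med_idx = [ids.index(m) for m in result.medoids]
        for mi in range(2):
            for h in range(12):
                if h in med_idx:
                    continue
                cand = med_idx.copy()
                cand[mi] = h
                assert d[:, cand].min(axis=1).sum() >= result.objective - 1e-9

    def test_deterministic(self):
        rng = np.random.default_rng(2)
        d = _dist(rng.uniform(0, 1, (15, 2)))
        r1 = ob.pam(d, k=2)
        r2 = ob.pam(d, k=2)
        assert r1.cluster_of_sample == r2.cluster_of_sample
        assert r1.medoids == r2.medoids

    def test_objective_trace_non_increasing(self):
        rng = np.random.default_rng(3)
        d = _dist(rng.uniform(0, 1, (20, 2)))
        trace = ob.pam(d, k=2).objective_trace
        assert all(a >= b for a, b in zip(trace, trace[1:]))

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError):
            ob.pam(np.zeros((2, 2)), k=3)


def _result(assignment, discarded=()):
    return ClusteringResult(
        cluster_of_sample=dict(assignment),
        medoids=(),
        objective=0.0,
        discarded_samples=frozenset(discarded),
    )


class TestClusteringAccuracy:
    def test_perfect_recovery(self):
        truth = {"s1": "x", "s2": "x", "s3": "y", "s4": "y"}
        res = _result({"s1": 0, "s2": 0, "s3": 1, "s4": 1})
        assert ob.clustering_accuracy(res, truth, 4) == 1.0

    def test_single_cluster_floor_is_half(self):
        truth = {"s1": "x", "s2": "x", "s3": "y", "s4": "y"}
        res = _result({s: 0 for s in truth})
        assert ob.clustering_accuracy(res, truth, 4) == 0.5

    def test_discarding_pushes_below_half(self):
        truth = {f"s{i}": ("x" if i < 4 else "y") for i in range(8)}
        retained = {"s0": 0, "s1": 0, "s4": 1, "s5": 1}  # half discarded, perfect
        assert ob.clustering_accuracy(_result(retained), truth, 8) == 0.5
        one_wrong = {"s0": 0, "s1": 1, "s4": 1, "s5": 1}
        assert ob.clustering_accuracy(_result(one_wrong), truth, 8) < 0.5

    def test_exhaustive_bound_with_no_discards(self):
        # any 2-partition of n <= 8 balanced samples scores >= 0.5
        for n in (2, 4, 6, 8):
            truth = {f"s{i}": ("x" if i < n // 2 else "y") for i in range(n)}
            for bits in range(2**n):
                assign = {f"s{i}": (bits >> i) & 1 for i in range(n)}
                assert ob.clustering_accuracy(_result(assign), truth, n) >= 0.5


class TestMaxAchievable:
    @pytest.mark.parametrize(
        "discarded,total,expected", [(0, 10, 1.0), (10, 10, 0.0), (3, 20, 0.85)]
    )
    def test_values(self, discarded, total, expected):
        assert ob.max_achievable_accuracy(discarded, total) == expected


class TestROCAUC:
    def test_perfect_and_antiperfect(self):
        truth = [True] * 5 + [False] * 5
        scores = list(range(10, 0, -1))
        assert ob.roc_auc(scores, truth) == 1.0
        assert ob.roc_auc([-s for s in scores], truth) == 0.0

    def test_random_scores_centered_at_half(self):
        rng = np.random.default_rng(4)
        truth = np.array([True] * 10 + [False] * 10)
        aucs = [ob.roc_auc(rng.uniform(size=20), truth) for _ in range(2000)]
        assert abs(np.mean(aucs) - 0.5) < 0.02

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(5)
        truth = rng.uniform(size=30) < 0.4
        if not truth.any() or truth.all():
            truth[0], truth[1] = True, False
        scores = rng.normal(size=30) + truth
        assert ob.roc_auc(scores, truth) == ob.roc_auc(np.exp(scores), truth)

    def test_degenerate_truth_rejected(self):
        with pytest.raises(ValueError):
            ob.roc_auc([1, 2, 3], [True, True, True])


class TestFPSignSummary:
    def _table(self, p_adj, direction, truth):
        n = len(p_adj)
        return pd.DataFrame(
            {
                "otu_id": [f"o{i}" for i in range(n)],
                "statistic": np.asarray(direction, dtype=float),
                "p": np.asarray(p_adj) / 2,
                "p_adj": p_adj,
                "direction": direction,
                "is_true_positive": truth,
            }
        )

    def test_no_detections_is_undefined(self):
        table = self._table([0.9, 0.8], [1, -1], [False, False])
        assert np.isnan(ob.fp_sign_summary(table))

    def test_consistent_false_positive_directions(self):
        table = self._table(
            [0.01, 0.01, 0.01, 0.01], [-1, -1, -1, 1], [False, False, False, True]
        )
        assert ob.fp_sign_summary(table) == 1.0

    def test_strong_effect_proportion_t_signs_point_to_null_class(self):
        # the count-perturbation inflates test-class libraries, so
        # unmodified OTUs look depleted in the test class
        fractions = []
        for rep in range(10):
            template = ob.make_template(200, 0.99, seed=rep)
            libs = ob.sample_library_sizes(20, 2000, 1.0, seed=100 + rep)
            pert = ob.pick_perturbed_otus(template, 0.10, seed=200 + rep)
            counts, design = ob.simulate_experiment_B(
                template, libs, 10.0, pert, n_per_class=10, seed=300 + rep
            )
            from otubench.nb_tests import run_da_experiment

            res = run_da_experiment(counts, design, "welch", "proportion")
            frac = ob.fp_sign_summary(res)
            if not np.isnan(frac):
                fractions.append(frac)
        assert fractions, "expected false positives at effect 10"
        assert np.mean(fractions) > 0.9


class TestThresholdSweep:
    @pytest.fixture
    def easy_experiment(self):
        pair = ob.make_disjoint_pair(50, 0.95, seed=0)
        libs = ob.sample_library_sizes(20, 2000, log_sd=0.3, seed=1)
        return ob.simulate_experiment_A(pair, libs, 20.0, n_per_class=10, seed=2)

    def test_easy_case_all_accurate_at_zero_quantile(self, easy_experiment):
        counts, design = easy_experiment
        sweep = ob.threshold_sweep(counts, design, [0.0], seed=3)
        assert (sweep["accuracy"] == 1.0).all()
        assert (sweep["n_discarded"] == 0).all()

    def test_accuracy_bounded_by_max_achievable(self, easy_experiment):
        counts, design = easy_experiment
        sweep = ob.threshold_sweep(counts, design, [0.0, 0.15, 0.3, 0.6], seed=4)
        assert (sweep["accuracy"] <= sweep["max_achievable_accuracy"] + 1e-12).all()


class TestSimulationAAccuracy:
    def test_trivial_separation_all_normalizations(self):
        pair = ob.make_disjoint_pair(50, 0.95, seed=7)
        libs = ob.sample_library_sizes(20, 2000, log_sd=0.3, seed=8)
        counts, design = ob.simulate_experiment_A(pair, libs, 50.0, n_per_class=10, seed=9)
        for norm, dist in [("proportion", "bray"), ("none", "euclidean"), ("vst", "bray")]:
            out = ob.evaluate.simulation_a_accuracy(counts, design, norm, dist)
            assert out["accuracy"] == 1.0

    def test_unifrac_distances_run_end_to_end(self):
        pair = ob.make_disjoint_pair(20, 0.9, seed=10)
        libs = ob.sample_library_sizes(12, 800, log_sd=0.3, seed=11)
        counts, design = ob.simulate_experiment_A(pair, libs, 30.0, n_per_class=6, seed=12)
        tree = ob.make_random_tree(counts.otu_ids, seed=13)
        for dist in ("unifrac_u", "unifrac_w"):
            out = ob.evaluate.simulation_a_accuracy(counts, design, "none", dist, tree=tree)
            assert out["accuracy"] == 1.0

    def test_auc_from_results_uses_raw_p_ranking(self):
        res = pd.DataFrame(
            {
                "otu_id": list("abcd"),
                "statistic": [3.0, 2.0, 1.0, 0.5],
                "p": [0.001, 0.01, 0.2, 0.9],
                "p_adj": [0.004, 0.02, 0.26, 0.9],
                "direction": [1, 1, 1, -1],
                "is_true_positive": [True, True, False, False],
            }
        )
        assert auc_from_results(res) == 1.0
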