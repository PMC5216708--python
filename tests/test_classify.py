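"""KNN classification, LOOCV mechanics, balancing, exhaustive subset search."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import qustools as q
from qustools.classify import (
    KNNConfig,
    balance_and_evaluate,
    enumerate_subsets,
    exhaustive_feature_search,
    knn_predict,
    loocv,
)
from qustools.clinical import NON_RESPONDER, RESPONDER


def brute_force_knn(X, y, query, k):
    """Independent oracle: full distance scan with the same tie conventions."""
    d = [(float(np.linalg.norm(x - query)), i) for i, x in enumerate(X)]
    d.sort(key=lambda t: (t[0], t[1]))
    nearest = [y[i] for _, i in d[:k]]
    counts = {}
    for lab in nearest:
        counts[lab] = counts.get(lab, 0) + 1
    best = max(counts.values())
    winners = [lab for lab, c in counts.items() if c == best]
    return winners[0] if len(winners) == 1 else nearest[0]


def make_table(X, y, ids=None):
    ids = ids if ids is not None else [f"p{i}" for i in range(len(y))]
    df = pd.DataFrame(X, columns=[f"f{j}" for j in range(X.shape[1])],
                      index=pd.Index(ids, name="patient_id"))
    df.insert(0, "label", y)
    return df


class TestKNNPredict:
    def test_query_on_training_point_k1(self):
        X = np.array([[0.0, 0.0], [5.0, 5.0]])
        y = np.array([RESPONDER, NON_RESPONDER])
        assert knn_predict(X, y, X[1], KNNConfig(k=1)) == NON_RESPONDER

    def test_k2_split_vote_falls_back_to_nearest(self):
        X = np.array([[1.0], [2.5]])
        y = np.array([RESPONDER, NON_RESPONDER])
        assert knn_predict(X, y, np.array([0.0]), KNNConfig(k=2)) == RESPONDER

    def test_exact_distance_tie_prefers_lower_index(self):
        X = np.array([[1.0], [-1.0]])
        y = np.array(["a", "b"])
        assert knn_predict(X, y, np.array([0.0]), KNNConfig(k=1)) == "a"

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            knn_predict(np.empty((0, 2)), np.array([]), np.zeros(2))

    @given(seed=st.integers(0, 500), k=st.integers(1, 5))
    @settings(max_examples=40)
    def test_matches_brute_force_scan(self, seed, k):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(40, 3))
        y = np.array([RESPONDER if b else NON_RESPONDER for b in rng.random(40) < 0.6])
        query = rng.normal(size=3)
        assert knn_predict(X, y, query, KNNConfig(k=k)) == brute_force_knn(X, y, query, k)

    def test_agrees_with_sklearn_when_no_ties(self):
        from sklearn.neighbors import KNeighborsClassifier

        rng = np.random.default_rng(3)
        X = rng.normal(size=(60, 4))
        y = np.array([RESPONDER if b else NON_RESPONDER for b in rng.random(60) < 0.5])
        clf = KNeighborsClassifier(n_neighbors=1).fit(X, y)
        queries = rng.normal(size=(50, 4))
        ours = [knn_predict(X, y, qq, KNNConfig(k=1)) for qq in queries]
        np.testing.assert_array_equal(ours, clf.predict(queries))


class TestLOOCV:
    def test_well_separated_clusters_classified_correctly(self):
        rng = np.random.default_rng(0)
        n = 16
        X = np.vstack([rng.normal(0.0, 0.1, (n, 2)), rng.normal(0.4, 0.1, (n, 2))])
        y = np.array([RESPONDER] * n + [NON_RESPONDER] * n)
        preds = loocv(X, y, KNNConfig(k=2))
        assert np.mean(preds == y) >= 0.95

    def test_permuted_labels_near_chance(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(100, 3))
        y = np.array([RESPONDER, NON_RESPONDER] * 50)
        preds = loocv(X, y, KNNConfig(k=2))
        assert 0.35 <= np.mean(preds == y) <= 0.65

    def test_two_point_loocv_predicts_each_as_the_other(self):
        X = np.array([[0.0], [1.0]])
        y = np.array([RESPONDER, NON_RESPONDER])
        preds = loocv(X, y, KNNConfig(k=1))
        assert np.mean(preds == y) == 0.0

    def test_all_copies_of_held_out_patient_leave_training(self):
        # duplicate patient rows: leakage-free LOOCV cannot match on self-copies
        X = np.array([[0.0], [0.0], [10.0], [10.2], [10.4]])
        y = np.array([RESPONDER, RESPONDER] + [NON_RESPONDER] * 3)
        pids = np.array(["a", "a", "b", "c", "d"])
        preds = loocv(X, y, KNNConfig(k=1), patient_ids=pids)
        assert all(preds[:2] == NON_RESPONDER)  # self-copies removed -> misclassified


class TestBalanceAndEvaluate:
    @staticmethod
    def separable_table(n_resp=20, n_non=16, spread=0.05, seed=0):
        rng = np.random.default_rng(seed)
        X = np.vstack(
            [rng.normal(0, spread, (n_resp, 2)), rng.normal(1.0, spread, (n_non, 2))]
        )
        y = [RESPONDER] * n_resp + [NON_RESPONDER] * n_non
        return make_table(X, np.array(y))

    def test_perfectly_separable_scores_100(self):
        s = balance_and_evaluate(self.separable_table(), n_repeats=5, seed=1)
        assert (s.sensitivity, s.specificity, s.accuracy) == (100.0, 100.0, 100.0)
        assert s.accuracy_sd == 0.0

    def test_uninformative_features_near_chance(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(40, 3))
        y = np.array([RESPONDER] * 24 + [NON_RESPONDER] * 16)
        s = balance_and_evaluate(make_table(X, y), n_repeats=10, seed=2)
        assert 35.0 <= s.accuracy <= 65.0

    def test_seed_determinism(self):
        t = self.separable_table(spread=0.6, seed=3)
        s1 = balance_and_evaluate(t, n_repeats=6, seed=9)
        s2 = balance_and_evaluate(t, n_repeats=6, seed=9)
        assert (s1.accuracy, s1.sensitivity, s1.specificity) == (
            s2.accuracy, s2.sensitivity, s2.specificity
        )

    def test_requesting_more_than_minority_count_errors_with_count(self):
        with pytest.raises(ValueError, match="8"):
            balance_and_evaluate(
                self.separable_table(n_resp=12, n_non=8), n_per_class=16
            )


class TestSubsetSearch:
    def test_seven_features_sizes_2_to_7_is_120_subsets(self):
        assert len(enumerate_subsets(7, (2, 3, 4, 5, 6, 7))) == 120

    def test_three_features_sizes_2_to_3_is_4_subsets(self):
        assert len(enumerate_subsets(3, (2, 3))) == 4

    def test_search_leaderboard_enumerates_all_subsets(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(24, 7))
        y = np.array([RESPONDER] * 14 + [NON_RESPONDER] * 10)
        _, _, board = exhaustive_feature_search(
            make_table(X, y), n_repeats=2, seed=0
        )
        assert len(board) == 120

    def test_planted_informative_pair_is_selected(self):
        """Two informative features among five noise features end up inside
        the winning subset in >= 8 of 10 seeded runs."""
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            n_resp, n_non = 20, 16
            y = np.array([RESPONDER] * n_resp + [NON_RESPONDER] * n_non)
            signal = np.vstack(
                [rng.normal(0, 0.3, (n_resp, 2)), rng.normal(1.0, 0.3, (n_non, 2))]
            )
            noise = rng.normal(size=(n_resp + n_non, 5))
            X = np.hstack([signal, noise])
            table = make_table(X, y)
            best, _, _ = exhaustive_feature_search(
                table, n_repeats=5, seed=seed, subset_sizes=(2, 3)
            )
            if {"f0", "f1"} <= set(best):
                hits += 1
        assert hits >= 8

    def test_paired_baseline_units_keep_enumeration_at_120(self):
        rng = np.random.default_rng(1)
        cols = [f"{n}_wk0" for n in q.FEATURE_NAMES] + [f"d{n}" for n in q.FEATURE_NAMES]
        X = rng.normal(size=(24, 14))
        df = pd.DataFrame(X, columns=cols, index=pd.Index([f"p{i}" for i in range(24)],
                                                          name="patient_id"))
        df.insert(0, "label", [RESPONDER] * 14 + [NON_RESPONDER] * 10)
        best, _, board = exhaustive_feature_search(
            df, n_repeats=1, seed=0, paired_baseline=True, subset_sizes=(2,)
        )
        assert len(board) == 21  # C(7,2): pairs count as single units
        assert len(best) == 4  # two units -> four columns
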