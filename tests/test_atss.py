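import numpy as np
import pytest
from sklearn.metrics import silhouette_samples

import biozscreen as bz
from biozscreen.atss import replay_history, silhouette_widths
from biozscreen.classifier import standardization_params


def brute_force_silhouette(X, y):
    """O(n^2) reference implementation straight from the definition."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y)
    n = len(y)
    s = np.empty(n)
    for i in range(n):
        same = [j for j in range(n) if j != i and y[j] == y[i]]
        other = [j for j in range(n) if y[j] != y[i]]
        a = np.mean([np.linalg.norm(X[i] - X[j]) for j in same])
        b = np.mean([np.linalg.norm(X[i] - X[j]) for j in other])
        if a < b:
            s[i] = 1 - a / b
        elif a > b:
            s[i] = b / a - 1
        else:
            s[i] = 0.0
    return s


def _random_instance(rng, n_max=50):
    n = int(rng.integers(6, n_max + 1))
    d = int(rng.integers(1, 6))
    X = rng.normal(size=(n, d))
    while True:
        y = rng.integers(0, 2, n)
        if min(np.sum(y == 0), np.sum(y == 1)) >= 2:
            return X, y


class TestSilhouetteWidths:
    def test_two_tight_distant_clusters_hand_value(self):
        """1-D {0, 0.1} vs {10, 10.1}: point 0 has a=0.1, b=10.05."""
        X = np.array([[0.0], [0.1], [10.0], [10.1]])
        y = np.array([0, 0, 1, 1])
        sc = silhouette_widths(X, y)
        assert sc.a[0] == pytest.approx(0.1)
        assert sc.b[0] == pytest.approx(10.05)
        assert sc.s[0] == pytest.approx(1 - 0.1 / 10.05)

    def test_equidistant_sample_scores_zero(self):
        X = np.array([[0.0], [2.0], [-2.0], [2.0]])
        y = np.array([0, 0, 1, 1])
        sc = silhouette_widths(X, y)
        assert sc.a[0] == sc.b[0] == 2.0
        assert sc.s[0] == 0.0

    def test_mislabeled_point_scores_negative(self):
        X = np.array([[0.0], [0.1], [0.2], [10.0], [10.1], [0.05]])
        y = np.array([0, 0, 0, 1, 1, 1])
        sc = silhouette_widths(X, y)
        assert sc.s[-1] < 0
        np.testing.assert_allclose(sc.s, brute_force_silhouette(X, y), atol=1e-12)

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(30):
            X, y = _random_instance(rng)
            sc = silhouette_widths(X, y)
            np.testing.assert_allclose(sc.s, brute_force_silhouette(X, y), atol=1e-10)
            assert np.all(sc.s >= -1) and np.all(sc.s <= 1)

    def test_matches_sklearn_silhouette_samples(self, rng):
        """Independent library oracle (identical definition for binary labels)."""
        for _ in range(10):
            X, y = _random_instance(rng)
            np.testing.assert_allclose(
                silhouette_widths(X, y).s, silhouette_samples(X, y), atol=1e-10
            )

    def test_singleton_class_rejected(self):
        with pytest.raises(ValueError):
            silhouette_widths(np.zeros((3, 1)), np.array([0, 1, 1]))


def _make_state(X, y, monitor_frac=0.3, fraction=0.2, capacity=None, seed=0):
    rng = np.random.default_rng(seed)
    n = len(y)
    mon = rng.choice(n, size=max(4, int(monitor_frac * n)), replace=False)
    pool = np.setdiff1d(np.arange(n), mon)
    return bz.select_seed(
        X[pool],
        y[pool],
        fraction=fraction,
        X_monitor=X[mon],
        y_monitor=y[mon],
        capacity=capacity,
    ), pool


class TestSeedSelection:
    def test_seed_size_ceiling_n200(self, rng):
        X = np.vstack([rng.normal(0, 1, (100, 3)), rng.normal(4, 1, (100, 3))])
        y = np.array([0] * 100 + [1] * 100)
        state = bz.select_seed(X, y, fraction=0.10, X_monitor=X[:10], y_monitor=y[:10])
        assert state.population_size == 20

    def test_seed_size_ceiling_n53(self, rng):
        X = np.vstack([rng.normal(0, 1, (33, 2)), rng.normal(4, 1, (20, 2))])
        y = np.array([0] * 33 + [1] * 20)
        state = bz.select_seed(X, y, fraction=0.10, X_monitor=X[:8], y_monitor=y[:8])
        assert state.population_size == 6

    def test_seed_contains_both_classes_under_imbalance(self, rng):
        X = np.vstack([rng.normal(0, 1, (95, 2)), rng.normal(4, 1, (5, 2))])
        y = np.array([0] * 95 + [1] * 5)
        state = bz.select_seed(X, y, fraction=0.10, X_monitor=X[:10], y_monitor=y[:10])
        assert set(np.unique(state.y_pop)) == {0, 1}

    def test_seed_mean_silhouette_at_least_population_mean(self, cohort_arrays):
        X, y, _, _ = cohort_arrays
        mean, sd = standardization_params(X)
        full = silhouette_widths((X - mean) / sd, y).s
        state = bz.select_seed(
            X, y, fraction=0.10, X_monitor=X[:20], y_monitor=y[:20], scaler=(mean, sd)
        )
        assert np.mean(state.sw) >= np.mean(full)


class TestConsiderSample:
    def _clusters(self, rng, n=30):
        X = np.vstack([rng.normal(0, 0.5, (n, 2)), rng.normal(5, 0.5, (n, 2))])
        y = np.array([0] * n + [1] * n)
        return X, y

    def test_low_silhouette_candidate_rejected_without_retraining(self, rng):
        X, y = self._clusters(rng)
        state, _ = _make_state(X, y)
        # midway between clusters: silhouette far below the tight seed's minimum
        decision = bz.consider_sample(state, np.array([2.5, 2.5]), 0)
        assert decision == "rejected"
        assert state.history[-1]["acc_after"] is None  # gate 1 short-circuits

    def test_mislabeled_candidate_rejected_and_accuracy_unchanged(self, rng):
        X, y = self._clusters(rng)
        state, _ = _make_state(X, y)
        acc_before = state.indicators["accuracy"]
        decision = bz.consider_sample(state, np.array([0.0, 0.0]), 1)  # wrong label
        assert decision == "rejected"
        assert state.indicators["accuracy"] == acc_before

    def test_duplicate_with_no_indicator_gain_rejected(self, rng):
        X, y = self._clusters(rng)
        state, _ = _make_state(X, y)
        # a clone of a well-placed member cannot strictly improve any indicator
        # once the monitor indicators are already saturated
        if state.indicators["accuracy"] == 1.0:
            dup = state.X_pop[int(np.argmax(state.sw))].copy()
            label = int(state.y_pop[int(np.argmax(state.sw))])
            assert bz.consider_sample(state, dup, label) == "rejected"

    def test_commit_grows_population_and_logs_indicators(self):
        """On overlapping clusters the seed model is imperfect, so good
        candidates do get committed, and each commit logs its deltas."""
        rng = np.random.default_rng(5)
        X = np.vstack([rng.normal(0, 1.5, (50, 2)), rng.normal(2.5, 1.5, (50, 2))])
        y = np.array([0] * 50 + [1] * 50)
        _, state = bz.run_atss(X, y, order_seed=5)
        committed = [r for r in state.history if r["decision"] != "rejected"]
        assert committed, "expected at least one accepted sample"
        seed_size = 8  # ceil(0.1 * 80-pool) with per-class floor
        assert state.population_size == seed_size + sum(
            1 for r in committed if r["decision"] == "accepted"
        )
        for r in committed:
            assert r["s_candidate"] > r["s_min"]
            assert r["acc_after"] >= r["acc_before"]


class TestRunAtss:
    def test_population_never_exceeds_capacity(self, cohort_arrays):
        X, y, ids, cols = cohort_arrays
        _, state = bz.run_atss(X, y, ids=ids, capacity=30, order_seed=1, attribute_names=cols)
        assert state.population_size <= 30

    def test_capacity_binding_keeps_population_constant(self, rng):
        X = np.vstack([rng.normal(0, 1.5, (40, 2)), rng.normal(3, 1.5, (40, 2))])
        y = np.array([0] * 40 + [1] * 40)
        _, state = bz.run_atss(X, y, capacity=8, fraction=0.12, order_seed=2)
        assert state.population_size <= 8
        committed = [r for r in state.history if r["decision"] != "rejected"]
        assert all(r["decision"] == "replaced" for r in committed if state.population_size == 8)

    def test_history_replay_confirms_both_rules(self, noisy_cohort):
        from biozscreen.features import attribute_columns

        table, _ = noisy_cohort
        cols = attribute_columns(table)
        _, state = bz.run_atss(
            table[cols].to_numpy(float),
            table["label"].to_numpy(int),
            ids=list(table["subject_id"]),
            order_seed=5,
            attribute_names=cols,
        )
        assert replay_history(state)

    def test_monitor_accuracy_non_decreasing(self, noisy_cohort):
        from biozscreen.features import attribute_columns

        table, _ = noisy_cohort
        cols = attribute_columns(table)
        _, state = bz.run_atss(
            table[cols].to_numpy(float),
            table["label"].to_numpy(int),
            order_seed=9,
            attribute_names=cols,
        )
        accs = [state.history[0]["acc_before"]] + [
            r["acc_after"] for r in state.history if r["decision"] != "rejected"
        ]
        assert np.all(np.diff(accs) >= -1e-12)

    def test_clean_cohort_final_accuracy_close_to_traditional(self, default_cohort):
        """On a separable cohort ATSS keeps up with full-data training."""
        from sklearn.model_selection import StratifiedGroupKFold

        from biozscreen.features import attribute_columns

        table, _ = default_cohort
        cols = attribute_columns(table)
        X = table[cols].to_numpy(float)
        y = table["label"].to_numpy(int)
        g = table["subject_id"].to_numpy()
        cv = StratifiedGroupKFold(5, shuffle=True, random_state=0)
        tr, te = next(cv.split(X, y, groups=g))
        trad = bz.train_logistic(X[tr], y[tr], attribute_names=cols)
        atss, _ = bz.run_atss(X[tr], y[tr], ids=list(g[tr]), order_seed=0, attribute_names=cols)
        acc_t = np.mean(trad.predict(X[te]) == y[te])
        acc_a = np.mean(atss.predict(X[te]) == y[te])
        assert acc_a >= acc_t - 0.02

    def test_noisy_cohort_population_cohesion_exceeds_training_set(self, noisy_cohort):
        """Selected population has higher mean silhouette than the raw data."""
        from biozscreen.features import attribute_columns

        table, _ = noisy_cohort
        cols = attribute_columns(table)
        _, state = bz.run_atss(
            table[cols].to_numpy(float),
            table["label"].to_numpy(int),
            ids=list(table["subject_id"]),
            order_seed=11,
            attribute_names=cols,
        )
        assert np.mean(state.sw) > state.train_sw_mean

    def test_capacity_below_seed_rejected(self, cohort_arrays):
        X, y, ids, cols = cohort_arrays
        with pytest.raises(ValueError):
            bz.run_atss(X, y, ids=ids, capacity=2, attribute_names=cols)
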