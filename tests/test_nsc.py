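"""Nearest shrunken centroid core: formulas, shrinkage, CV, serialization."""

import math

import numpy as np
import pytest
from sklearn.neighbors import NearestCentroid

from leukotype import nsc


def brute_force_posteriors(X, y, X_test, delta, priors):
    """Independent loop-based evaluation of the NSC formulas."""
    classes = sorted(set(y))
    n, p = len(X), len(X[0])
    xbar = [sum(X[j][i] for j in range(n)) / n for i in range(p)]
    cent, counts = {}, {}
    for c in classes:
        rows = [X[j] for j in range(n) if y[j] == c]
        counts[c] = len(rows)
        cent[c] = [sum(r[i] for r in rows) / len(rows) for i in range(p)]
    s = []
    for i in range(p):
        sse = sum(
            (X[j][i] - cent[y[j]][i]) ** 2 for j in range(n)
        )
        s.append(math.sqrt(sse / (n - len(classes))))
    s0 = sorted(s)[len(s) // 2] if p % 2 == 1 else 0.5 * (
        sorted(s)[p // 2 - 1] + sorted(s)[p // 2]
    )
    shrunk = {}
    for c in classes:
        mk = math.sqrt(1.0 / counts[c] - 1.0 / n)
        row = []
        for i in range(p):
            d = (cent[c][i] - xbar[i]) / (mk * (s[i] + s0))
            dp = math.copysign(max(abs(d) - delta, 0.0), d)
            row.append(xbar[i] + mk * (s[i] + s0) * dp)
        shrunk[c] = row
    out = []
    for x in X_test:
        deltas = []
        for k, c in enumerate(classes):
            dist = sum(
                (x[i] - shrunk[c][i]) ** 2 / (s[i] + s0) ** 2 for i in range(p)
            )
            deltas.append(dist - 2.0 * math.log(priors[k]))
        m = min(deltas)
        w = [math.exp(-0.5 * (d - m)) for d in deltas]
        tot = sum(w)
        out.append([v / tot for v in w])
    return np.array(out)


def random_instance(rng, n_classes=3, max_features=10, max_samples=30):
    p = rng.integers(2, max_features + 1)
    counts = rng.integers(2, max(3, max_samples // n_classes), size=n_classes)
    X, y = [], []
    for k in range(n_classes):
        mu = rng.normal(0, 2, p)
        X.append(rng.normal(mu, 1.0, size=(counts[k], p)))
        y += [f"c{k}"] * counts[k]
    return np.vstack(X), np.array(y)


class TestFormulas:
    def test_posteriors_match_bruteforce_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            X, y = random_instance(rng)
            X_test = rng.normal(0, 2, size=(5, X.shape[1]))
            delta = float(rng.uniform(0, 2))
            model = nsc.fit_nsc(X, y, delta, "uniform")
            ours = nsc.predict_scores(model, X_test).to_numpy()
            oracle = brute_force_posteriors(
                X.tolist(), y.tolist(), X_test.tolist(), delta, model.priors
            )
            np.testing.assert_allclose(ours, oracle, atol=1e-10)

    def test_hand_computed_two_class_one_feature(self):
        # class A {0, 0.2}, class B {1, 1.2}: centroids 0.1 / 1.1, overall
        # 0.6, pooled sd sqrt(0.02), s0 = that same value, m_k = 0.5
        X = np.array([[0.0], [0.2], [1.0], [1.2]])
        y = np.array(["A", "A", "B", "B"])
        model = nsc.fit_nsc(X, y, 0.0)
        sd = math.sqrt(0.02)
        assert model.stats.overall_centroid[0] == pytest.approx(0.6, abs=1e-12)
        assert model.stats.pooled_sd[0] == pytest.approx(sd, abs=1e-12)
        assert model.stats.s0 == pytest.approx(sd, abs=1e-12)
        np.testing.assert_allclose(model.stats.m_k, [0.5, 0.5], atol=1e-12)
        d = nsc.standardized_offsets(model, delta=0.0)
        expected = 0.5 / (0.5 * 2 * sd)
        np.testing.assert_allclose(d[:, 0], [-expected, expected], atol=1e-12)

    def test_zero_delta_is_identity(self):
        rng = np.random.default_rng(0)
        X, y = random_instance(rng)
        model = nsc.fit_nsc(X, y, 0.0)
        np.testing.assert_allclose(
            model.shrunken_centroids, model.stats.class_centroids, atol=1e-12
        )

    def test_full_shrinkage_gives_prior_posteriors(self):
        rng = np.random.default_rng(1)
        X, y = random_instance(rng)
        d0 = np.abs(nsc.standardized_offsets(nsc.fit_nsc(X, y, 0.0), 0.0)).max()
        for mode in ("uniform", "empirical"):
            model = nsc.fit_nsc(X, y, d0 + 1.0, mode)
            p = nsc.predict_scores(model, rng.normal(size=(4, X.shape[1])))
            np.testing.assert_allclose(
                p.to_numpy(), np.tile(model.priors, (4, 1)), atol=1e-12
            )
            assert nsc.selected_features(model) == []

    def test_matches_sklearn_shrunken_centroids(self):
        rng = np.random.default_rng(5)
        X, y = random_instance(rng, n_classes=4, max_features=30, max_samples=60)
        for delta in (0.0, 0.3, 1.0):
            model = nsc.fit_nsc(X, y, delta)
            ref = NearestCentroid(shrink_threshold=delta or None).fit(X, y)
            np.testing.assert_allclose(
                model.shrunken_centroids, ref.centroids_, atol=1e-10
            )


class TestProperties:
    def test_posterior_rows_sum_to_one(self):
        rng = np.random.default_rng(2)
        X, y = random_instance(rng)
        model = nsc.fit_nsc(X, y, 0.5)
        p = nsc.predict_scores(model, rng.normal(0, 5, size=(20, X.shape[1])))
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-12)
        assert ((p.to_numpy() >= 0) & (p.to_numpy() <= 1)).all()

    def test_feature_count_non_increasing_in_delta(self):
        rng = np.random.default_rng(3)
        X, y = random_instance(rng, max_features=40, max_samples=60)
        counts = [
            len(nsc.selected_features(nsc.fit_nsc(X, y, d)))
            for d in np.linspace(0, 3, 15)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_feature_permutation_bit_identical(self):
        rng = np.random.default_rng(4)
        X, y = random_instance(rng)
        ids = [f"f{i}" for i in range(X.shape[1])]
        model = nsc.fit_nsc(X, y, 0.2, feature_ids=ids)
        X_test = rng.normal(size=(6, X.shape[1]))
        base = nsc.predict_scores(model, X_test, ids).to_numpy()
        perm = rng.permutation(X.shape[1])
        permuted = nsc.predict_scores(
            model, X_test[:, perm], [ids[i] for i in perm]
        ).to_numpy()
        assert np.array_equal(base, permuted)

    def test_zero_delta_equals_plain_nearest_centroid_rule(self):
        rng = np.random.default_rng(6)
        X, y = random_instance(rng)
        model = nsc.fit_nsc(X, y, 0.0)
        X_test = rng.normal(0, 2, size=(15, X.shape[1]))
        labels = nsc.predict_labels(model, X_test)
        # oracle: argmin of standardized squared distance to raw centroids
        inv2 = 1.0 / (model.stats.pooled_sd + model.stats.s0) ** 2
        dist = np.array(
            [
                [((x - c) ** 2 * inv2).sum() for c in model.stats.class_centroids]
                for x in X_test
            ]
        )
        expected = np.array(model.class_labels)[dist.argmin(axis=1)]
        assert (labels == expected).all()

    def test_missing_value_imputation_frozen(self):
        rng = np.random.default_rng(7)
        X, y = random_instance(rng)
        X[0, 0] = np.nan
        model = nsc.fit_nsc(X, y, 0.0)
        med = np.nanmedian(X[:, 0])
        assert model.imputation_values[0] == med
        # a NaN at prediction time uses the stored value
        x = X[1].copy()
        x[0] = np.nan
        with_nan = nsc.predict_scores(model, x[None, :]).to_numpy()
        x[0] = med
        assert np.array_equal(with_nan, nsc.predict_scores(model, x[None, :]).to_numpy())


class TestDeltaSelection:
    def test_single_point_grid(self):
        rng = np.random.default_rng(8)
        X, y = random_instance(rng)
        delta, curve = nsc.select_delta_cv(X, y, [0.0], folds=3, seed=0)
        assert delta == 0.0 and len(curve) == 1

    def test_tie_break_prefers_larger_delta(self):
        rng = np.random.default_rng(9)
        # trivially separable: CV accuracy is 1.0 for small deltas
        X = np.vstack([rng.normal(-3, 0.1, (12, 4)), rng.normal(3, 0.1, (12, 4))])
        y = np.array(["A"] * 12 + ["B"] * 12)
        delta, curve = nsc.select_delta_cv(X, y, [0.0, 0.5], folds=4, seed=0)
        assert curve["balanced_accuracy"].iloc[0] == curve["balanced_accuracy"].iloc[1] == 1.0
        assert delta == 0.5

    def test_separable_two_class_selects_informative_features(self):
        rng = np.random.default_rng(10)
        n_inf = 20
        mu = np.zeros(100)
        Xa = rng.normal(mu, 0.1, (20, 100))
        Xb = rng.normal(mu, 0.1, (20, 100))
        Xa[:, :n_inf] += 1.0
        Xb[:, :n_inf] -= 1.0
        X, y = np.vstack([Xa, Xb]), np.array(["A"] * 20 + ["B"] * 20)
        delta, curve = nsc.select_delta_cv(X, y, folds=5, seed=0)
        model = nsc.fit_nsc(X, y, delta)
        kept = nsc.selected_features(model)
        assert 1 <= len(kept) <= 100
        assert curve["balanced_accuracy"].max() == 1.0

    def test_informative_feature_recovery_across_seeds(self):
        hits, fps = [], []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            p, n_inf = 50, 10
            X_parts, y = [], []
            for k in range(3):
                mu = np.zeros(p)
                mu[k * n_inf // 3 : n_inf] = 0  # informative block below
                block = rng.normal(0, 1.0, (15, p))
                block[:, :n_inf] += rng.choice([-3.0, 3.0], n_inf) * (k - 1)
                X_parts.append(block)
                y += [f"c{k}"] * 15
            X = np.vstack(X_parts)
            y = np.array(y)
            delta, _ = nsc.select_delta_cv(X, y, folds=5, seed=seed)
            kept = set(nsc.selected_features(nsc.fit_nsc(X, y, delta)))
            informative = {f"f{i}" for i in range(n_inf)}
            noise = {f"f{i}" for i in range(n_inf, p)}
            hits.append(len(kept & informative) / n_inf)
            fps.append(len(kept & noise) / len(noise))
        assert np.mean(hits) >= 0.8
        assert np.mean(fps) <= 0.1

    def test_empty_grid_rejected(self):
        rng = np.random.default_rng(11)
        X, y = random_instance(rng)
        with pytest.raises(ValueError, match="empty"):
            nsc.select_delta_cv(X, y, [], folds=2)


class TestValidation:
    def test_small_class_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            nsc.fit_nsc(np.zeros((3, 2)), np.array(["A", "A", "B"]), 0.0)

    def test_negative_delta_rejected(self):
        rng = np.random.default_rng(12)
        X, y = random_instance(rng)
        with pytest.raises(ValueError, match="delta"):
            nsc.fit_nsc(X, y, -0.1)

    def test_excessive_feature_mismatch_rejected(self):
        rng = np.random.default_rng(13)
        X, y = random_instance(rng, max_features=10)
        model = nsc.fit_nsc(X, y, 0.0)
        p = X.shape[1]
        with pytest.raises(ValueError, match="absent"):
            nsc.predict_scores(model, np.zeros((1, 1)), ["nope"])


def test_serialization_round_trips_bit_exactly(tmp_path):
    rng = np.random.default_rng(14)
    X, y = random_instance(rng)
    model = nsc.fit_nsc(X, y, 0.37)
    path = tmp_path / "model.json"
    nsc.save_model(model, path)
    back = nsc.load_model(path)
    assert back.class_labels == model.class_labels
    assert back.feature_ids == model.feature_ids
    for a, b in [
        (back.shrunken_centroids, model.shrunken_centroids),
        (back.priors, model.priors),
        (back.stats.pooled_sd, model.stats.pooled_sd),
        (back.stats.class_centroids, model.stats.class_centroids),
        (back.imputation_values, model.imputation_values),
    ]:
        assert np.array_equal(a, b)
    assert back.delta == model.delta and back.stats.s0 == model.stats.s0
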