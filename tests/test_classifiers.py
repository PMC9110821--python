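import numpy as np
import pytest

from cd_disorder import (
    ClassifierFamily,
    ClassifierSpec,
    DegenerateInputError,
    Label,
    TrainingError,
    all_default_specs,
    cosine_distance,
    predict,
    train,
)

from conftest import feature_matrix


# ---------------------------------------------------------------------------
# Independent brute-force KNN oracle (all-pairs distances + documented votes)
# ---------------------------------------------------------------------------


def brute_knn(X, y, q, k, metric, weighted):
    X = np.asarray(X, float)
    q = np.asarray(q, float)
    if metric == "cosine":
        d = [
            1.0 - float(np.dot(x, q) / (np.linalg.norm(x) * np.linalg.norm(q)))
            for x in X
        ]
    else:
        d = [float(np.linalg.norm(x - q)) for x in X]
    order = sorted(range(len(d)), key=lambda i: (d[i], i))[: min(k, len(d))]
    nd = [d[i] for i in order]
    ny = [y[i] for i in order]
    if weighted and any(v == 0.0 for v in nd):
        zero = [c for v, c in zip(nd, ny) if v == 0.0]
        c1, c0 = zero.count(1), zero.count(0)
        if c1 == c0:
            return ny[0]
        return 1 if c1 > c0 else 0
    if weighted:
        w1 = sum(1.0 / v**2 for v, c in zip(nd, ny) if c == 1)
        w0 = sum(1.0 / v**2 for v, c in zip(nd, ny) if c == 0)
        if w1 == w0:
            return ny[0]
        return 1 if w1 > w0 else 0
    c1, c0 = ny.count(1), ny.count(0)
    if c1 == c0:
        return ny[0]
    return 1 if c1 > c0 else 0


KNN_SPECS = [
    ClassifierSpec.default(f)
    for f in (
        ClassifierFamily.KNN_FINE,
        ClassifierFamily.KNN_MEDIUM,
        ClassifierFamily.KNN_COARSE,
        ClassifierFamily.KNN_WEIGHTED,
        ClassifierFamily.KNN_COSINE,
    )
]


def random_instance(rng, n_max=30, dim=3):
    n = int(rng.integers(4, n_max + 1))
    X = rng.normal(size=(n, dim))
    X[np.all(X == 0, axis=1)] += 1.0
    y = rng.integers(0, 2, size=n)
    y[0], y[1] = 0, 1  # both classes present
    q = rng.normal(size=dim)
    if not np.any(q):
        q[0] = 1.0
    return X, y, q


class TestCosineDistance:
    def test_colinear_positive_scale_is_zero(self):
        x = np.array([1.0, -2.0, 0.5])
        assert cosine_distance(x, 3.7 * x) == pytest.approx(0.0, abs=1e-12)

    def test_antipodal_is_two(self):
        x = np.array([1.0, -2.0, 0.5])
        assert cosine_distance(x, -x) == pytest.approx(2.0, abs=1e-12)

    def test_closed_form_45_degrees(self):
        assert cosine_distance([1.0, 0.0], [1.0, 1.0]) == pytest.approx(
            1.0 - 1.0 / np.sqrt(2.0), abs=1e-12
        )

    def test_zero_vector_rejected(self):
        with pytest.raises(DegenerateInputError):
            cosine_distance([0.0, 0.0], [1.0, 1.0])

    def test_range_and_scale_invariance(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            x, y = rng.normal(size=3), rng.normal(size=3)
            d = cosine_distance(x, y)
            assert 0.0 <= d <= 2.0
            a, b = rng.uniform(0.01, 100, size=2)
            assert cosine_distance(a * x, b * y) == pytest.approx(d, abs=1e-9)


class TestTrainContract:
    def test_single_class_rejected(self):
        fm = feature_matrix([[0.0, 1.0], [1.0, 0.0]], [0, 0])
        for spec in all_default_specs():
            with pytest.raises(TrainingError):
                train(spec, fm)

    def test_knn_k_clamped_to_training_size(self):
        rng = np.random.default_rng(1)
        fm = feature_matrix(rng.normal(size=(20, 3)), [0, 1] * 10)
        model = train(ClassifierSpec.default("knn_coarse"), fm)  # k = 100
        assert model._model.k_eff == 20

    def test_wrong_query_dimension_rejected(self):
        fm = feature_matrix([[0.0, 1.0], [1.0, 0.0], [0.5, 0.5]], [0, 1, 0])
        model = train(ClassifierSpec.default("knn_fine"), fm)
        with pytest.raises(ValueError):
            predict(model, [1.0, 2.0, 3.0])

    def test_deterministic_training_all_families(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(40, 3))
        y = rng.integers(0, 2, size=40)
        y[:2] = [0, 1]
        fm = feature_matrix(X, y)
        queries = rng.normal(size=(20, 3))
        for spec in all_default_specs():
            m1, m2 = train(spec, fm), train(spec, fm)
            for q in queries:
                assert predict(m1, q) == predict(m2, q)


class TestKNNPredict:
    def test_self_match_scores_one(self):
        fm = feature_matrix([[0.0, 1.0], [1.0, 0.0], [2.0, 0.1]], [1, 0, 0])
        model = train(ClassifierSpec.default("knn_fine"), fm)
        label, score = predict(model, [0.0, 1.0])
        assert label is Label.DISORDERED and score == 1.0

    def test_hand_computed_three_neighbor_vote(self):
        # distances from (0.8, 0.2): 0.283, 0.141 (ordered), 0.990, 1.131 (disordered)
        fm = feature_matrix(
            [[1.0, 0.0], [0.9, 0.1], [0.0, 1.0], [0.1, 0.9]], [0, 0, 1, 1]
        )
        spec = ClassifierSpec.from_config({"family": "knn_medium", "k": 3})
        label, score = predict(train(spec, fm), [0.8, 0.2])
        assert label is Label.ORDERED
        assert score == pytest.approx(2.0 / 3.0)

    def test_cosine_scale_invariant_label_and_score(self):
        rng = np.random.default_rng(3)
        fm = feature_matrix(rng.normal(size=(25, 3)), rng.integers(0, 2, size=25))
        model = train(ClassifierSpec.default("knn_cosine"), fm)
        q = rng.normal(size=3)
        assert predict(model, q) == predict(model, 10.0 * q)

    def test_cosine_zero_query_rejected(self):
        fm = feature_matrix([[0.0, 1.0], [1.0, 0.0], [1.0, 1.0]], [0, 1, 0])
        model = train(ClassifierSpec.default("knn_cosine"), fm)
        with pytest.raises(DegenerateInputError):
            predict(model, [0.0, 0.0])

    def test_weighted_exact_match_wins_outright(self):
        # far-away disordered majority cannot outvote a distance-0 ordered point
        fm = feature_matrix(
            [[1.0, 1.0], [5.0, 5.0], [5.1, 5.0], [5.0, 5.1], [1.0, 0.0]],
            [0, 1, 1, 1, 1],
        )
        spec = ClassifierSpec.from_config({"family": "knn_weighted", "k": 5})
        label, score = predict(train(spec, fm), [1.0, 1.0])
        assert label is Label.ORDERED and score == 1.0

    def test_even_k_tie_broken_by_nearest(self):
        fm = feature_matrix([[1.0, 0.0], [3.0, 0.0], [2.5, 0.0], [10.0, 0.0]], [0, 1, 1, 0])
        spec = ClassifierSpec.from_config({"family": "knn_medium", "k": 2})
        # neighbors of 1.2: (1.0, ordered) then (2.5, disordered) -> 1:1 tie
        label, score = predict(train(spec, fm), [1.2, 0.0])
        assert label is Label.ORDERED and score == 0.5

    @pytest.mark.parametrize("spec", KNN_SPECS, ids=lambda s: s.family.value)
    def test_matches_brute_force_oracle(self, spec):
        rng = np.random.default_rng(2024)
        p = spec.params
        for _ in range(250):
            X, y, q = random_instance(rng)
            fm = feature_matrix(X, y)
            label, _ = predict(train(spec, fm), q)
            expected = brute_knn(X, y, q, p["k"], p["metric"], p["weighted"])
            assert (label is Label.DISORDERED) == bool(expected)

    def test_matches_sklearn_knn_on_clean_data(self):
        # independent library cross-check, euclidean and cosine metrics
        from sklearn.neighbors import KNeighborsClassifier

        rng = np.random.default_rng(7)
        X = rng.normal(size=(60, 3))
        y = rng.integers(0, 2, size=60)
        y[:2] = [0, 1]
        fm = feature_matrix(X, y)
        Q = rng.normal(size=(40, 3))
        # odd k: binary votes cannot tie, so both tie-break conventions agree
        for family, metric, k in (
            ("knn_medium", "euclidean", 9),
            ("knn_cosine", "cosine", 9),
        ):
            model = train(ClassifierSpec.from_config({"family": family, "k": k}), fm)
            sk = KNeighborsClassifier(n_neighbors=k, metric=metric).fit(X, y)
            ours = [predict(model, q)[0] is Label.DISORDERED for q in Q]
            theirs = sk.predict(Q).astype(bool)
            assert ours == list(theirs)


class TestMarginFamilies:
    def separable_fm(self):
        rng = np.random.default_rng(11)
        X0 = rng.normal(loc=(-2.0, -2.0), scale=0.3, size=(20, 2))
        X1 = rng.normal(loc=(2.0, 2.0), scale=0.3, size=(20, 2))
        return feature_matrix(np.vstack([X0, X1]), [0] * 20 + [1] * 20)

    @pytest.mark.parametrize(
        "family",
        [f.value for f in ClassifierFamily if f.value.startswith(("svm", "tree", "discr"))],
    )
    def test_separable_data_fit_perfectly(self, family):
        fm = self.separable_fm()
        model = train(ClassifierSpec.default(family), fm)
        for x, lab in zip(fm.X, fm.labels):
            pred_label, score = predict(model, x)
            assert pred_label is lab
            assert 0.0 <= score <= 1.0

    def test_discriminants_match_sklearn_lda_qda(self):
        from sklearn.discriminant_analysis import (
            LinearDiscriminantAnalysis,
            QuadraticDiscriminantAnalysis,
        )

        rng = np.random.default_rng(21)
        # balanced classes, overlapping clouds
        X = np.vstack(
            [
                rng.normal(loc=(0.0, 0.0, 0.0), scale=1.0, size=(40, 3)),
                rng.normal(loc=(1.0, 0.5, -0.5), scale=1.4, size=(40, 3)),
            ]
        )
        y = np.array([0] * 40 + [1] * 40)
        fm = feature_matrix(X, y)
        Q = rng.normal(loc=(0.5, 0.2, -0.2), scale=1.5, size=(200, 3))
        for family, oracle in (
            ("discr_linear", LinearDiscriminantAnalysis()),
            ("discr_quadratic", QuadraticDiscriminantAnalysis(store_covariance=True)),
        ):
            model = train(ClassifierSpec.default(family), fm)
            oracle.fit(X, y)
            ours = np.array(
                [predict(model, q)[0] is Label.DISORDERED for q in Q]
            )
            agreement = np.mean(ours == oracle.predict(Q).astype(bool))
            assert agreement >= 0.99

    def test_diagonal_discriminant_ignores_covariances(self):
        # strongly correlated features: diagonal model must match the
        # axis-independent closed form, not the full-covariance answer
        fm = feature_matrix(
            [[0.0, 0.0], [1.0, 1.0], [0.1, 0.0], [3.0, 3.0], [4.0, 4.0], [3.1, 3.0]],
            [0, 0, 0, 1, 1, 1],
        )
        model = train(
            ClassifierSpec.from_config({"family": "discr_diaglinear", "standardize": False}),
            fm,
        )
        inner = model._model
        for cov in inner.covs:
            off = cov - np.diag(np.diag(cov))
            assert np.allclose(off, 0.0)


class TestSpecConfig:
    def test_round_trip(self):
        spec = ClassifierSpec.from_config({"family": "knn_cosine", "k": 7})
        assert spec.params["k"] == 7
        assert ClassifierSpec.from_config(spec.to_config()) == spec

    def test_unknown_hyperparameter_rejected(self):
        with pytest.raises(ValueError):
            ClassifierSpec.from_config({"family": "knn_fine", "gamma": 2.0})

    def test_all_thirteen_families_enumerated(self):
        assert len(all_default_specs()) == 13
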