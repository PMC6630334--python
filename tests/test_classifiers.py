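"""PLS-DA, LS-SVM and ELM classifiers and the evaluation protocol."""

import numpy as np
import pytest

from seedvigor import PhantomConfig, SpectraTable, simulate_spectra
from seedvigor.classifiers import (
    ELMModel,
    LSSVMModel,
    PLSDAModel,
    _one_hot,
    _solve_lssvm_system,
    _sq_dists,
    evaluate,
    fit_elm,
    fit_lssvm,
    fit_plsda,
    split_train_test,
)


def labelled_table(n_per_class=30, seed=0, classes=("y2017", "y2016", "y2015")):
    cfg = PhantomConfig()
    table, _ = simulate_spectra(cfg, n_per_class=n_per_class, rng_seed=seed,
                                classes=classes)
    keep = np.flatnonzero((table.wavelengths >= 941) & (table.wavelengths <= 1666))
    return table.select_bands(keep)


class TestSplit:
    def test_counts_disjoint_and_deterministic(self):
        table = labelled_table(n_per_class=40)
        train, test = split_train_test(table, 15, 15, rng_seed=3)
        assert train.n_seeds == test.n_seeds == 45
        for cls in np.unique(table.labels):
            assert np.sum(train.labels == cls) == 15
            assert np.sum(test.labels == cls) == 15
        # seed_ids trace provenance: the split is disjoint
        assert not set(train.seed_ids) & set(test.seed_ids)
        train2, test2 = split_train_test(table, 15, 15, rng_seed=3)
        assert np.array_equal(train.spectra, train2.spectra)
        assert np.array_equal(test.spectra, test2.spectra)

    def test_insufficient_rows_names_class(self):
        table = labelled_table(n_per_class=10)
        with pytest.raises(ValueError, match="y201"):
            split_train_test(table, 8, 8)


def separable_clouds(rng, margin=20.0, n=30, dim=4):
    X = np.vstack([rng.normal(size=(n, dim)),
                   rng.normal(size=(n, dim)) + margin])
    y = np.array(["lo"] * n + ["hi"] * n)
    return X, y


class TestPLSDA:
    def test_full_rank_matches_ols_oracle(self, rng):
        """With components = rank(Xc), PLS2 regression equals least squares."""
        X = rng.normal(size=(6, 4))
        y = np.array(["a", "a", "a", "b", "b", "b"])
        model = PLSDAModel(n_components=4).fit(X, y)
        Y = _one_hot(y, model.classes_)
        Xc, Yc = X - X.mean(axis=0), Y - Y.mean(axis=0)
        B = np.linalg.lstsq(Xc, Yc, rcond=None)[0]
        assert np.max(np.abs(model.decision(X) - (Xc @ B + Y.mean(axis=0)))) <= 1e-8

    def test_first_component_matches_eigen_oracle(self, rng):
        """The first PLS weight vector is the dominant eigenvector of
        X'YY'X; the rank-1 prediction built from it must agree."""
        X = rng.normal(size=(25, 10))
        y = rng.choice(["a", "b", "c"], 25)
        model = PLSDAModel(n_components=1).fit(X, y)
        Y = _one_hot(y, model.classes_)
        Xc, Yc = X - X.mean(axis=0), Y - Y.mean(axis=0)
        _, evecs = np.linalg.eigh(Xc.T @ Yc @ Yc.T @ Xc)
        w = evecs[:, -1]
        t = Xc @ w
        q = Yc.T @ t / (t @ t)
        p = Xc.T @ t / (t @ t)
        pred = Xc @ (np.outer(w, q) / (p @ w)) + Y.mean(axis=0)
        assert np.max(np.abs(model.decision(X) - pred)) <= 1e-9

    def test_sklearn_cross_check(self, rng):
        """Independent implementation check at matching component count."""
        from sklearn.cross_decomposition import PLSRegression

        X = rng.normal(size=(30, 12))
        y = rng.choice(["a", "b", "c"], 30)
        model = PLSDAModel(n_components=5).fit(X, y)
        Y = _one_hot(y, model.classes_)
        sk = PLSRegression(n_components=5, scale=False).fit(X, Y)
        assert np.max(np.abs(model.decision(X) - sk.predict(X))) <= 5e-3

    def test_separable_clouds_perfect_training_accuracy(self, rng):
        X, y = separable_clouds(rng)
        model = PLSDAModel(n_components=3).fit(X, y)
        assert np.all(model.predict(X) == y)

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError, match="2 classes"):
            PLSDAModel().fit(rng.normal(size=(5, 3)), np.array(["a"] * 5))

    def test_constant_column_is_harmless(self, rng):
        X = rng.normal(size=(20, 5))
        X[:, 2] = 7.0
        y = rng.choice(["a", "b"], 20)
        model = PLSDAModel(n_components=3).fit(X, y)
        assert np.all(np.isfinite(model.B_))


class TestLSSVM:
    def test_kkt_residual_bound(self, rng):
        X, y = separable_clouds(rng, margin=3.0, n=20)
        model = LSSVMModel(gamma=10.0, sigma2=5.0).fit(X, y)
        assert model.max_kkt_residual <= 1e-8

    def test_linear_system_solution_satisfies_equations(self, rng):
        X = rng.normal(size=(15, 3))
        y = np.sign(rng.normal(size=15))
        K = np.exp(-_sq_dists(X, X) / 2.0)
        sol, residual = _solve_lssvm_system(K, y, gamma=100.0)
        assert residual <= 1e-8 * np.linalg.norm(y)
        # equality constraint: alphas sum to zero
        assert abs(sol[1:].sum()) <= 1e-8

    def test_decision_antisymmetric_under_label_swap(self, rng):
        """Swapping the +/- roles of the two classes flips alpha, b and the
        decision values exactly."""
        X = rng.normal(size=(12, 3))
        y = np.sign(rng.normal(size=12))
        K = np.exp(-_sq_dists(X, X) / 1.0)
        sol_pos, _ = _solve_lssvm_system(K, y, gamma=50.0)
        sol_neg, _ = _solve_lssvm_system(K, -y, gamma=50.0)
        assert np.allclose(sol_pos, -sol_neg, atol=1e-10)

    def test_xor_pattern_learned_with_rbf(self, rng):
        """Linearly inseparable XOR data: the RBF machine must exceed 95% CV
        accuracy."""
        centers = np.array([[1, 1], [-1, -1], [1, -1], [-1, 1]], dtype=float)
        X = np.vstack([c + rng.normal(scale=0.1, size=(25, 2)) for c in centers])
        y = np.array(["a"] * 50 + ["b"] * 50)
        model = LSSVMModel(folds=5, rng_seed=0).fit(X, y)
        assert model.cv_accuracy_ > 0.95

    def test_separable_data_perfect_training_accuracy(self, rng):
        X, y = separable_clouds(rng, margin=10.0, n=25)
        model = LSSVMModel(gamma=1e6, sigma2=100.0).fit(X, y)
        assert np.all(model.predict(X) == y)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            LSSVMModel(gamma_grid=())
        with pytest.raises(ValueError):
            LSSVMModel(gamma_grid=(0.0, 1.0))


class TestELM:
    def test_interpolation_regime(self, rng):
        """With more hidden nodes than samples and full-row-rank H the
        network interpolates the training targets."""
        X = rng.normal(size=(20, 5))
        y = rng.choice(["a", "b", "c"], 20)
        model = ELMModel(n_hidden=100, rng_seed=1).fit(X, y)
        H = model.hidden(X)
        assert np.linalg.matrix_rank(H) == 20
        assert model.training_residual_ <= 1e-6
        assert np.all(model.predict(X) == y)

    def test_same_seed_same_predictions(self, rng):
        X = rng.normal(size=(30, 6))
        y = rng.choice(["a", "b"], 30)
        Xnew = rng.normal(size=(10, 6))
        p1 = ELMModel(n_hidden=40, rng_seed=9).fit(X, y).predict(Xnew)
        p2 = ELMModel(n_hidden=40, rng_seed=9).fit(X, y).predict(Xnew)
        assert np.array_equal(p1, p2)

    def test_phantom_benchmark_accuracy(self):
        """On the phantom's informative bands (the planted dip centers), a
        100-node ELM separates the year classes with >= 90% test accuracy."""
        from seedvigor.synthetic import RAW_SPA_WAVELENGTHS

        # training rows must comfortably exceed the hidden-layer width, else
        # the network interpolates the training noise
        table = labelled_table(n_per_class=120, seed=2)
        dip_bands = [int(np.argmin(np.abs(table.wavelengths - c)))
                     for c in RAW_SPA_WAVELENGTHS]
        table = table.select_bands(np.unique(dip_bands))
        train, test = split_train_test(table, 75, 45, rng_seed=2)
        model = fit_elm(train, n_hidden=100, rng_seed=2)
        accuracy = np.mean(model.predict(test.spectra) == test.labels)
        assert accuracy >= 0.90


class TestEvaluate:
    def test_perfect_predictor(self):
        table = labelled_table(n_per_class=20, seed=1)
        train, test = split_train_test(table, 10, 10, rng_seed=1)

        class Oracle:
            classes_ = np.unique(table.labels)

            def predict(self, X):
                lookup = {x.tobytes(): l for x, l in
                          zip(table.spectra, table.labels)}
                return np.array([lookup[row.tobytes()] for row in X])

        report = evaluate(Oracle(), train, test)
        assert report.accuracy_calibration == 100.0
        assert report.accuracy_prediction == 100.0
        assert np.array_equal(report.confusion_prediction,
                              10 * np.eye(3, dtype=int))

    def test_majority_predictor_on_balanced_classes(self):
        table = labelled_table(n_per_class=12, seed=3,
                               classes=("y2017", "y2016", "y2015", "aged"))
        train, test = split_train_test(table, 6, 6, rng_seed=0)

        class Majority:
            classes_ = np.unique(table.labels)

            def predict(self, X):
                return np.array(["aged"] * len(X))

        report = evaluate(Majority(), train, test)
        assert report.accuracy_prediction == 25.0

    def test_accuracy_equals_confusion_trace_ratio(self):
        table = labelled_table(n_per_class=20, seed=5)
        train, test = split_train_test(table, 10, 10, rng_seed=5)
        report = evaluate(fit_plsda(train, n_components=5), train, test)
        conf = report.confusion_prediction
        assert report.accuracy_prediction == pytest.approx(
            np.trace(conf) / conf.sum() * 100.0, abs=0.005)

    def test_unseen_test_class_rejected(self):
        table = labelled_table(n_per_class=20, seed=5)
        train, test = split_train_test(table, 10, 10, rng_seed=5)
        model = fit_plsda(train, n_components=3)
        bad = SpectraTable(spectra=test.spectra, wavelengths=test.wavelengths,
                           labels=np.array(["mystery"] * test.n_seeds))
        with pytest.raises(ValueError, match="unseen"):
            evaluate(model, train, bad)


class TestRowOrderInvariance:
    @pytest.mark.parametrize("fit", [
        lambda t: fit_plsda(t, n_components=5),
        lambda t: fit_lssvm(t, gamma=100.0, sigma2=10.0),
        lambda t: fit_elm(t, n_hidden=50, rng_seed=4),
    ], ids=["plsda", "lssvm", "elm"])
    def test_training_row_order_irrelevant(self, rng, fit):
        table = labelled_table(n_per_class=15, seed=4)
        perm = rng.permutation(table.n_seeds)
        shuffled = table.subset(perm)
        new_X = labelled_table(n_per_class=5, seed=99).spectra
        assert np.array_equal(fit(table).predict(new_X),
                              fit(shuffled).predict(new_X))


def test_selected_bands_nearly_match_full_bands():
    """Models on SPA-selected wavelengths must stay within 3 accuracy points
    of the same models on all 216 bands (the full-vs-selected comparison)."""
    from seedvigor.spa import spa_select

    table = labelled_table(n_per_class=80, seed=12,
                           classes=("y2017", "y2016", "y2015", "aged"))
    train, test = split_train_test(table, 40, 40, rng_seed=12)
    spa_res = spa_select(train, val_folds=4, k_range=range(2, 13),
                         starts=np.linspace(0, 215, 8).astype(int), rng_seed=12)
    fits = {
        "plsda": lambda t: fit_plsda(t, n_components=min(10, t.n_bands)),
        "lssvm": lambda t: fit_lssvm(t, folds=4, rng_seed=12),
        "elm": lambda t: fit_elm(t, n_hidden=100, rng_seed=12),
    }
    for name, fit in fits.items():
        full = evaluate(fit(train), train, test).accuracy_prediction
        sel_train = train.select_bands(spa_res.selected_indices)
        sel_test = test.select_bands(spa_res.selected_indices)
        sel = evaluate(fit(sel_train), sel_train, sel_test).accuracy_prediction
        assert sel >= full - 3.0, f"{name}: selected {sel} vs full {full}"
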