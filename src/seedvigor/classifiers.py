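"""Multiclass classifiers used on seed-mean spectra: PLS-DA, LS-SVM and ELM.

All three are implemented from first principles on numpy arrays:

* PLS-DA — NIPALS PLS2 regression of one-hot class codes Y on centered
  spectra X (Y = X B + F), decision by argmax of the predicted code row.
  With as many latent components as the rank of X it coincides with
  ordinary least squares.
* LS-SVM — the least-squares SVM replaces the SVM inequality constraints by
  equalities, so training a binary machine reduces to one symmetric linear
  system  [[0, 1^T], [1, K + I/gamma]] [b; alpha] = [0; y]  with an RBF
  kernel K(x, z) = exp(-||x - z||^2 / sigma2).  Multiclass is one-vs-one
  majority voting; (gamma, sigma2) come from a grid search scored by
  stratified cross-validation.
* ELM — a single-hidden-layer network whose input weights and biases are
  random; only the output weights are learned, as the minimum-norm
  least-squares solution beta = pinv(H) T.  Inputs are min-max scaled to
  [-1, 1] with calibration-set ranges (the sigmoid saturates on raw
  reflectance magnitudes).

The table-level helpers (``split_train_test``, ``fit_*``, ``evaluate``)
mirror the study protocol: a stratified 200/200 per-class calibration/
prediction split and accuracy reporting on both sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import confusion_matrix

from .spectra import SpectraTable

DEFAULT_GAMMA_GRID = tuple(10.0**e for e in range(0, 7))     # penalty factor
DEFAULT_SIGMA2_GRID = tuple(10.0**e for e in range(-2, 5))   # RBF width (squared)


def stratified_folds(y: np.ndarray, n_folds: int,
                     rng_seed: int = 0) -> list[tuple[np.ndarray, np.ndarray]]:
    """Deterministic class-stratified folds as (train_idx, val_idx) pairs."""
    y = np.asarray(y)
    rng = np.random.default_rng(rng_seed)
    assignment = np.zeros(y.size, dtype=int)
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        idx = rng.permutation(idx)
        assignment[idx] = np.arange(idx.size) % n_folds
    return [
        (np.flatnonzero(assignment != f), np.flatnonzero(assignment == f))
        for f in range(n_folds)
    ]


def _one_hot(y: np.ndarray, classes: np.ndarray) -> np.ndarray:
    return (y[:, np.newaxis] == classes[np.newaxis, :]).astype(float)


# ---------------------------------------------------------------------------
# PLS-DA


class PLSDAModel:
    """NIPALS PLS2 regression of one-hot class membership; argmax decision."""

    def __init__(self, n_components: int = 10):
        if n_components < 1:
            raise ValueError("need at least one latent component")
        self.n_components = n_components

    def fit(self, X: np.ndarray, y: np.ndarray) -> "PLSDAModel":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if self.classes_.size < 2:
            raise ValueError("PLS-DA needs at least 2 classes in the training set")
        m, n = X.shape
        a_max = min(self.n_components, m - 1, n)

        Y = _one_hot(y, self.classes_)
        self.x_mean_ = X.mean(axis=0)
        self.y_mean_ = Y.mean(axis=0)
        Xc = X - self.x_mean_
        Yc = Y - self.y_mean_

        W, P, Q = [], [], []
        for _ in range(a_max):
            u = Yc[:, int(np.argmax(Yc.var(axis=0)))]
            t = np.zeros(m)
            for _ in range(500):
                w = Xc.T @ u
                w_norm = np.linalg.norm(w)
                if w_norm < 1e-14:
                    break
                w /= w_norm
                t_new = Xc @ w
                tt = t_new @ t_new
                if tt < 1e-14:
                    break
                q = Yc.T @ t_new / tt
                qq = q @ q
                if qq < 1e-14:
                    break
                u = Yc @ q / qq
                if np.linalg.norm(t_new - t) <= 1e-12 * max(1.0, np.linalg.norm(t_new)):
                    t = t_new
                    break
                t = t_new
            tt = t @ t
            if tt < 1e-14 or np.linalg.norm(w) == 0:
                break  # residual X carries no more signal
            p = Xc.T @ t / tt
            q = Yc.T @ t / tt
            Xc = Xc - np.outer(t, p)
            Yc = Yc - np.outer(t, q)
            W.append(w)
            P.append(p)
            Q.append(q)
        if not W:
            raise ValueError("no latent component could be extracted (constant X?)")
        W_, P_, Q_ = np.column_stack(W), np.column_stack(P), np.column_stack(Q)
        self.B_ = W_ @ np.linalg.solve(P_.T @ W_, Q_.T)
        self.residual_F_ = Yc  # training residual, diagnostic
        self.n_components_fitted_ = W_.shape[1]
        return self

    def decision(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return (X - self.x_mean_) @ self.B_ + self.y_mean_

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[np.argmax(self.decision(X), axis=1)]


def choose_plsda_components(X: np.ndarray, y: np.ndarray, max_components: int = 20,
                            folds: int = 10, rng_seed: int = 0) -> int:
    """Pick the component count with lowest stratified-CV misclassification."""
    fold_list = stratified_folds(y, folds, rng_seed)
    best_a, best_err = 1, np.inf
    cap = min(max_components, X.shape[0] - 1, X.shape[1])
    for a in range(1, cap + 1):
        errors = 0
        for tr, va in fold_list:
            model = PLSDAModel(n_components=min(a, len(tr) - 1)).fit(X[tr], y[tr])
            errors += int(np.sum(model.predict(X[va]) != y[va]))
        if errors < best_err:
            best_a, best_err = a, errors
    return best_a


# ---------------------------------------------------------------------------
# LS-SVM


def _solve_lssvm_system(K: np.ndarray, y_signed: np.ndarray,
                        gamma: float) -> tuple[np.ndarray, float]:
    """Solve [[0, 1^T], [1, K + I/gamma]] [b; alpha] = [0; y]."""
    n = y_signed.size
    A = np.zeros((n + 1, n + 1))
    A[0, 1:] = 1.0
    A[1:, 0] = 1.0
    A[1:, 1:] = K + np.eye(n) / gamma
    rhs = np.concatenate(([0.0], y_signed))
    try:
        sol = np.linalg.solve(A, rhs)
    except np.linalg.LinAlgError:
        sol = None
    if sol is None or not np.all(np.isfinite(sol)):
        A[1:, 1:] += 1e-10 * np.eye(n)  # jitter retry on a singular system
        sol = np.linalg.solve(A, rhs)
        if not np.all(np.isfinite(sol)):
            raise np.linalg.LinAlgError("LS-SVM system singular even after jitter")
    residual = float(np.linalg.norm(A @ sol - rhs))
    if residual > 1e-8 * max(1.0, float(np.linalg.norm(rhs))):
        A[1:, 1:] += 1e-10 * np.eye(n)
        sol = np.linalg.solve(A, rhs)
    return sol, float(np.linalg.norm(A @ sol - rhs))


def _sq_dists(X: np.ndarray, Z: np.ndarray) -> np.ndarray:
    d = (X**2).sum(axis=1)[:, None] + (Z**2).sum(axis=1)[None, :] - 2.0 * X @ Z.T
    return np.maximum(d, 0.0)


class LSSVMModel:
    """One-vs-one LS-SVM with RBF kernel and CV grid search over (gamma, sigma2)."""

    def __init__(self, gamma: float | None = None, sigma2: float | None = None,
                 gamma_grid=DEFAULT_GAMMA_GRID, sigma2_grid=DEFAULT_SIGMA2_GRID,
                 folds: int = 10, rng_seed: int = 0):
        self.gamma = gamma
        self.sigma2 = sigma2
        self.gamma_grid = tuple(gamma_grid)
        self.sigma2_grid = tuple(sigma2_grid)
        self.folds = folds
        self.rng_seed = rng_seed
        if not self.gamma_grid or not self.sigma2_grid:
            raise ValueError("hyperparameter grids must be non-empty")
        if min(self.gamma_grid) <= 0 or min(self.sigma2_grid) <= 0:
            raise ValueError("gamma and sigma2 must be positive")

    # -- internals ----------------------------------------------------------

    def _fit_pairs(self, X: np.ndarray, y: np.ndarray, gamma: float,
                   sigma2: float) -> dict:
        """Train one binary machine per class pair on the given data."""
        machines = {}
        for i in range(self.classes_.size):
            for j in range(i + 1, self.classes_.size):
                ci, cj = self.classes_[i], self.classes_[j]
                mask = (y == ci) | (y == cj)
                Xp, yp = X[mask], np.where(y[mask] == ci, 1.0, -1.0)
                K = np.exp(-_sq_dists(Xp, Xp) / sigma2)
                sol, residual = _solve_lssvm_system(K, yp, gamma)
                machines[(i, j)] = {
                    "X": Xp, "b": sol[0], "alpha": sol[1:], "residual": residual,
                }
        return machines

    def _pair_decisions(self, machines: dict, X: np.ndarray,
                        sigma2: float) -> dict:
        return {
            pair: np.exp(-_sq_dists(X, m["X"]) / sigma2) @ m["alpha"] + m["b"]
            for pair, m in machines.items()
        }

    def _vote(self, decisions: dict, n_classes: int) -> np.ndarray:
        n = next(iter(decisions.values())).size
        votes = np.zeros((n, n_classes))
        scores = np.zeros((n, n_classes))
        for (i, j), d in decisions.items():
            votes[:, i] += d > 0
            votes[:, j] += d <= 0
            scores[:, i] += d
            scores[:, j] -= d
        # majority vote; ties go to the class with the larger summed decision
        winners = np.zeros(n, dtype=int)
        for r in range(n):
            top = np.flatnonzero(votes[r] == votes[r].max())
            winners[r] = top[np.argmax(scores[r, top])]
        return winners

    def _cv_accuracy(self, X: np.ndarray, y: np.ndarray, gamma: float,
                     sigma2: float, folds) -> float:
        correct = 0
        for tr, va in folds:
            machines = self._fit_pairs(X[tr], y[tr], gamma, sigma2)
            pred_idx = self._vote(self._pair_decisions(machines, X[va], sigma2),
                                  self.classes_.size)
            correct += int(np.sum(self.classes_[pred_idx] == y[va]))
        return correct / y.size

    # -- public API ---------------------------------------------------------

    def fit(self, X: np.ndarray, y: np.ndarray) -> "LSSVMModel":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if self.classes_.size < 2:
            raise ValueError("LS-SVM needs at least 2 classes")
        if self.gamma is None or self.sigma2 is None:
            folds = stratified_folds(y, self.folds, self.rng_seed)
            best = None
            # iterate gamma ascending, sigma2 descending: on ties the smaller
            # gamma, then the larger sigma2, is kept
            for gamma in sorted(self.gamma_grid):
                for sigma2 in sorted(self.sigma2_grid, reverse=True):
                    acc = self._cv_accuracy(X, y, gamma, sigma2, folds)
                    if best is None or acc > best[0]:
                        best = (acc, gamma, sigma2)
            self.cv_accuracy_, self.gamma_, self.sigma2_ = best
        else:
            self.gamma_, self.sigma2_ = float(self.gamma), float(self.sigma2)
            self.cv_accuracy_ = None
        self.machines_ = self._fit_pairs(X, y, self.gamma_, self.sigma2_)
        return self

    @property
    def max_kkt_residual(self) -> float:
        """Largest linear-system residual over the pairwise machines."""
        return max(m["residual"] for m in self.machines_.values())

    def pair_decision(self, X: np.ndarray, pair: tuple[int, int]) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        m = self.machines_[pair]
        return np.exp(-_sq_dists(X, m["X"]) / self.sigma2_) @ m["alpha"] + m["b"]

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        decisions = self._pair_decisions(self.machines_, X, self.sigma2_)
        return self.classes_[self._vote(decisions, self.classes_.size)]


# ---------------------------------------------------------------------------
# ELM


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


class ELMModel:
    """Extreme learning machine: random hidden layer, least-squares readout."""

    def __init__(self, n_hidden: int = 100, rng_seed: int = 0):
        if n_hidden < 1:
            raise ValueError("need at least one hidden node")
        self.n_hidden = n_hidden
        self.rng_seed = rng_seed

    def _scale(self, X: np.ndarray) -> np.ndarray:
        span = self.x_max_ - self.x_min_
        span = np.where(span > 0, span, 1.0)
        return 2.0 * (X - self.x_min_) / span - 1.0

    def fit(self, X: np.ndarray, y: np.ndarray) -> "ELMModel":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        self.x_min_ = X.min(axis=0)
        self.x_max_ = X.max(axis=0)
        rng = np.random.default_rng(self.rng_seed)
        self.W_in_ = rng.uniform(-1.0, 1.0, size=(X.shape[1], self.n_hidden))
        self.bias_hidden_ = rng.uniform(-1.0, 1.0, size=self.n_hidden)
        H = _sigmoid(self._scale(X) @ self.W_in_ + self.bias_hidden_)
        T = _one_hot(y, self.classes_)
        self.beta_ = np.linalg.pinv(H) @ T  # minimum-norm least squares
        self.training_residual_ = float(np.linalg.norm(H @ self.beta_ - T))
        return self

    def hidden(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return _sigmoid(self._scale(X) @ self.W_in_ + self.bias_hidden_)

    def decision(self, X: np.ndarray) -> np.ndarray:
        return self.hidden(X) @ self.beta_

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[np.argmax(self.decision(X), axis=1)]


# ---------------------------------------------------------------------------
# table-level protocol helpers


def split_train_test(table: SpectraTable, per_class_train: int = 200,
                     per_class_test: int = 200,
                     rng_seed: int = 0) -> tuple[SpectraTable, SpectraTable]:
    """Stratified disjoint calibration/prediction split, deterministic in seed."""
    if table.labels is None:
        raise ValueError("table must carry class labels to split")
    rng = np.random.default_rng(rng_seed)
    train_rows, test_rows = [], []
    for cls in np.unique(table.labels):
        idx = np.flatnonzero(table.labels == cls)
        need = per_class_train + per_class_test
        if idx.size < need:
            raise ValueError(
                f"class {cls!r} has {idx.size} rows but the split needs {need}"
            )
        idx = rng.permutation(idx)
        train_rows.append(idx[:per_class_train])
        test_rows.append(idx[per_class_train:need])
    return (table.subset(np.concatenate(train_rows)),
            table.subset(np.concatenate(test_rows)))


def fit_plsda(train: SpectraTable, n_components: int | str = 10,
              folds: int = 10, rng_seed: int = 0) -> PLSDAModel:
    """Fit PLS-DA on a labelled table; ``n_components="cv"`` tunes by 10-fold CV."""
    if train.labels is None:
        raise ValueError("training table must carry class labels")
    if n_components == "cv":
        n_components = choose_plsda_components(train.spectra, train.labels,
                                               folds=folds, rng_seed=rng_seed)
    return PLSDAModel(n_components=int(n_components)).fit(train.spectra, train.labels)


def fit_lssvm(train: SpectraTable, gamma_grid=DEFAULT_GAMMA_GRID,
              sigma2_grid=DEFAULT_SIGMA2_GRID, folds: int = 10,
              rng_seed: int = 0, gamma: float | None = None,
              sigma2: float | None = None) -> LSSVMModel:
    if train.labels is None:
        raise ValueError("training table must carry class labels")
    model = LSSVMModel(gamma=gamma, sigma2=sigma2, gamma_grid=gamma_grid,
                       sigma2_grid=sigma2_grid, folds=folds, rng_seed=rng_seed)
    return model.fit(train.spectra, train.labels)


def fit_elm(train: SpectraTable, n_hidden: int = 100,
            rng_seed: int = 0) -> ELMModel:
    if train.labels is None:
        raise ValueError("training table must carry class labels")
    return ELMModel(n_hidden=n_hidden, rng_seed=rng_seed).fit(
        train.spectra, train.labels)


def predict_plsda(model: PLSDAModel, X: np.ndarray) -> np.ndarray:
    return model.predict(X)


def predict_lssvm(model: LSSVMModel, X: np.ndarray) -> np.ndarray:
    return model.predict(X)


def predict_elm(model: ELMModel, X: np.ndarray) -> np.ndarray:
    return model.predict(X)


@dataclass
class EvalReport:
    """Calibration/prediction accuracies and confusion matrices for one model."""

    accuracy_calibration: float     # percent on the training (calibration) set
    accuracy_prediction: float      # percent on the held-out (prediction) set
    confusion_calibration: np.ndarray
    confusion_prediction: np.ndarray
    per_class_recall: dict
    class_order: np.ndarray
    model_tag: str = ""
    preprocessing_tag: str = ""
    wavelength_tag: str = ""


def _accuracy_pct(confusion: np.ndarray) -> float:
    return round(float(np.trace(confusion)) / float(confusion.sum()) * 100.0, 2)


def evaluate(model, train: SpectraTable, test: SpectraTable,
             model_tag: str = "", preprocessing_tag: str = "",
             wavelength_tag: str = "") -> EvalReport:
    """Accuracy on calibration and prediction sets, with confusion matrices."""
    if train.labels is None or test.labels is None:
        raise ValueError("both tables must carry class labels")
    classes = model.classes_
    unknown = set(np.unique(test.labels)) - set(classes)
    if unknown:
        raise ValueError(f"test set contains classes unseen in training: {unknown}")
    conf_cal = confusion_matrix(train.labels, model.predict(train.spectra),
                                labels=classes)
    conf_pre = confusion_matrix(test.labels, model.predict(test.spectra),
                                labels=classes)
    row_totals = conf_pre.sum(axis=1)
    recall = {
        str(c): float(conf_pre[i, i] / row_totals[i]) if row_totals[i] else np.nan
        for i, c in enumerate(classes)
    }
    return EvalReport(
        accuracy_calibration=_accuracy_pct(conf_cal),
        accuracy_prediction=_accuracy_pct(conf_pre),
        confusion_calibration=conf_cal,
        confusion_prediction=conf_pre,
        per_class_recall=recall,
        class_order=classes,
        model_tag=model_tag,
        preprocessing_tag=preprocessing_tag,
        wavelength_tag=wavelength_tag,
    )
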