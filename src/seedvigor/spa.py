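"""Successive projections algorithm (SPA) for wavelength selection.

SPA grows a subset of spectral variables greedily: starting from one column
of the (autoscaled) data matrix, each step projects all unselected columns
onto the orthogonal complement of the span of the selected ones and appends
the column with the largest projected norm.  The resulting subset has
minimal collinearity — each new wavelength brings the most information not
already carried by the chain.

For classification use, the free choices (starting column and subset size k)
are scored by cross-validated misclassification of a reference PLS-DA model
on the calibration set; the (start, k) pair with the lowest mean CV error is
returned (ties resolved toward the smallest k, then the smallest start).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .classifiers import PLSDAModel, stratified_folds
from .errors import RankDeficiencyError
from .spectra import SpectraTable


@dataclass
class SPAResult:
    """Outcome of validation-scored SPA selection."""

    selected_indices: np.ndarray      # ordered band indices of the chain
    selected_wavelengths: np.ndarray  # nm, grid[selected_indices]
    chain_norms: np.ndarray           # projected norm at each chain step
    start_index: int
    k: int
    validation_score: float           # mean CV misclassification rate

    def __post_init__(self) -> None:
        self.selected_indices = np.asarray(self.selected_indices, dtype=int)
        self.selected_wavelengths = np.asarray(self.selected_wavelengths, dtype=float)
        self.chain_norms = np.asarray(self.chain_norms, dtype=float)
        if len(np.unique(self.selected_indices)) != self.selected_indices.size:
            raise ValueError("selected indices must be distinct")
        if self.selected_indices.size != self.k:
            raise ValueError("chain length must equal k")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "selected_indices": self.selected_indices.tolist(),
            "selected_wavelengths": self.selected_wavelengths.tolist(),
            "chain_norms": self.chain_norms.tolist(),
            "start_index": int(self.start_index),
            "k": int(self.k),
            "validation_score": float(self.validation_score),
        }, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SPAResult":
        d = json.loads(Path(path).read_text())
        return cls(
            selected_indices=np.array(d["selected_indices"]),
            selected_wavelengths=np.array(d["selected_wavelengths"]),
            chain_norms=np.array(d["chain_norms"]),
            start_index=d["start_index"], k=d["k"],
            validation_score=d["validation_score"],
        )


def spa_chain(X: np.ndarray, start: int, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Greedy SPA projection chain of length k from column ``start``.

    ``X`` is used as given (center/scale beforehand if desired).  Returns the
    ordered selected column indices and the projected norm at each step (the
    first entry is the start column's own norm).  Exact ties go to the lowest
    column index.  If the remaining columns all project to (numerically)
    zero before the chain reaches k, a :class:`RankDeficiencyError` reports
    the achievable length.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be a 2-D matrix")
    m, n = X.shape
    if not 1 <= k <= min(m, n):
        raise ValueError(f"k must lie in [1, {min(m, n)}], got {k}")
    if not 0 <= start < n:
        raise ValueError(f"start column {start} out of range [0, {n})")

    tol = 1e-10 * max(1.0, float(np.linalg.norm(X, axis=0).max()))
    residual = X.copy()
    selected = [start]
    start_norm = float(np.linalg.norm(residual[:, start]))
    if start_norm <= tol:
        raise RankDeficiencyError(
            f"start column {start} has (near-)zero norm", achieved=0
        )
    norms = [start_norm]

    def deflate(idx: int, nrm: float) -> None:
        q = residual[:, idx] / nrm
        residual[:] = residual - np.outer(q, q @ residual)

    deflate(start, start_norm)
    for _ in range(k - 1):
        col_norms = np.linalg.norm(residual, axis=0)
        col_norms[selected] = -np.inf
        best = int(np.argmax(col_norms))  # argmax takes the first (lowest) index on ties
        if col_norms[best] <= tol:
            raise RankDeficiencyError(
                f"column space exhausted after {len(selected)} of {k} selections",
                achieved=len(selected),
            )
        norms.append(float(col_norms[best]))
        selected.append(best)
        deflate(best, col_norms[best])
    return np.array(selected), np.array(norms)


def _autoscale(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (X - mu) / sd


def spa_select(
    train: SpectraTable,
    val_folds: int = 5,
    k_range: range | list | None = None,
    starts: list | np.ndarray | None = None,
    n_components: int = 10,
    rng_seed: int = 0,
) -> SPAResult:
    """Choose an SPA wavelength subset by cross-validated PLS-DA error.

    Columns of the calibration table are autoscaled (train mean/sd) before
    the projections.  One chain of length max(k_range) is built per start
    (greedy chains are nested, so every k-prefix comes for free), and each
    (start, k) candidate is scored by ``val_folds``-fold stratified CV
    misclassification of a PLS-DA model restricted to those bands.  The
    candidate with the lowest mean CV error wins; ties prefer the smallest
    k, then the smallest start index.

    ``starts=None`` scans every column; pass a subset to bound runtime.
    """
    if train.labels is None:
        raise ValueError("calibration table must carry class labels")
    X, y = train.spectra, train.labels
    m, n = X.shape
    if k_range is None:
        k_range = range(2, 21)
    k_list = sorted({int(k) for k in k_range})
    if not k_list:
        raise ValueError("k_range must be non-empty")
    if k_list[0] < 1 or k_list[-1] > min(m, n):
        raise ValueError(f"k_range must lie within [1, {min(m, n)}]")
    start_list = list(range(n)) if starts is None else [int(s) for s in starts]

    Xs = _autoscale(X)
    k_max = k_list[-1]

    # One nested chain per start; rank deficiency just shortens the chain.
    chains: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for s in start_list:
        try:
            chains[s] = spa_chain(Xs, s, k_max)
        except RankDeficiencyError as exc:
            if exc.achieved >= 1:
                chains[s] = spa_chain(Xs, s, exc.achieved)

    folds = stratified_folds(y, val_folds, rng_seed)

    def cv_error(bands: np.ndarray) -> float:
        errors = 0
        for tr_idx, va_idx in folds:
            a = min(n_components, bands.size, len(tr_idx) - 1)
            model = PLSDAModel(n_components=a)
            model.fit(X[np.ix_(tr_idx, bands)], y[tr_idx])
            errors += int(np.sum(model.predict(X[np.ix_(va_idx, bands)]) != y[va_idx]))
        return errors / m

    best: tuple[float, int, int] | None = None  # (score, k, start)
    for k in k_list:
        for s in start_list:
            if s not in chains or chains[s][0].size < k:
                continue
            score = cv_error(chains[s][0][:k])
            if best is None or score < best[0]:
                best = (score, k, s)
    if best is None:
        raise RankDeficiencyError(
            "no start produced a chain long enough for any requested k", achieved=0
        )

    score, k, s = best
    indices, norms = chains[s]
    return SPAResult(
        selected_indices=indices[:k],
        selected_wavelengths=train.wavelengths[indices[:k]],
        chain_norms=norms[:k],
        start_index=s,
        k=k,
        validation_score=score,
    )
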