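"""Spectral pretreatments: Savitzky-Golay smoothing/derivative, MSC, and PCA.

All operators act row-wise on a :class:`~seedvigor.spectra.SpectraTable`
(one seed-mean spectrum per row) and return a new table of the same shape.

* SG: least-squares polynomial smoothing (default cubic, 15-point window);
  edges are handled by evaluating the polynomial fitted to the terminal
  window, so the output keeps the full band count and the filter remains
  exact for polynomials up to the fitted order.
* SG-D1: the first-derivative Savitzky-Golay variant; output is in
  reflectance per band step (divide by the wavelength step for per-nm).
* MSC: per-row ordinary least squares x = a*ref + b against a reference
  spectrum (the set mean unless one is supplied), then inversion
  (x - b) / a.  This exactly removes per-seed affine scatter.
* PCA: column-mean-centered SVD scores with explained-variance percentages,
  for exploratory plots.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .errors import DegenerateFitError
from .spectra import SpectraTable

METHODS = ("raw", "SG", "SG-D1", "MSC")


@dataclass
class PreprocessSpec:
    """Serializable choice of pretreatment for the pipeline config."""

    method: str = "raw"
    sg_order: int = 3
    sg_window: int = 15
    msc_reference: str = "mean_of_set"

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; expected one of {METHODS}")
        _check_sg_params(self.sg_order, self.sg_window)


def _check_sg_params(order: int, window: int) -> None:
    if window % 2 == 0:
        raise ValueError(f"SG window must be odd, got {window}")
    if window <= order:
        raise ValueError(f"SG window ({window}) must exceed the polynomial "
                         f"order ({order})")


def sg_smooth(table: SpectraTable, order: int = 3, window: int = 15) -> SpectraTable:
    """Savitzky-Golay smoothing of every row (polynomial interpolation at edges)."""
    _check_sg_params(order, window)
    if table.n_bands < window:
        raise ValueError(f"need at least {window} bands, got {table.n_bands}")
    smoothed = savgol_filter(table.spectra, window, order, axis=1, mode="interp")
    return table.with_spectra(smoothed)


def sg_first_derivative(table: SpectraTable, order: int = 3,
                        window: int = 15) -> SpectraTable:
    """First-derivative Savitzky-Golay filter, in reflectance per band step."""
    _check_sg_params(order, window)
    if table.n_bands < window:
        raise ValueError(f"need at least {window} bands, got {table.n_bands}")
    deriv = savgol_filter(table.spectra, window, order, deriv=1, delta=1.0,
                          axis=1, mode="interp")
    return table.with_spectra(deriv)


def msc(table: SpectraTable, reference: np.ndarray | None = None) -> SpectraTable:
    """Multiplicative scatter correction against a reference spectrum.

    With ``reference=None`` the mean spectrum of the table is used (store and
    reuse the calibration-set reference when correcting a prediction set).
    """
    if reference is None:
        if table.n_seeds < 2:
            raise ValueError("mean-of-set MSC needs at least 2 spectra")
        reference = table.spectra.mean(axis=0)
    reference = np.asarray(reference, dtype=float)
    if reference.shape != (table.n_bands,):
        raise ValueError("reference length must equal the band count")

    ref_centered = reference - reference.mean()
    denom = float(ref_centered @ ref_centered)
    if denom == 0.0:
        raise DegenerateFitError("MSC reference spectrum is constant")
    X = table.spectra
    a = (X - X.mean(axis=1, keepdims=True)) @ ref_centered / denom
    if np.any(np.abs(a) < 1e-12):
        bad = int(np.argmin(np.abs(a)))
        raise DegenerateFitError(
            f"spectrum {bad} is flat relative to the reference (fitted slope ~ 0)"
        )
    b = X.mean(axis=1) - a * reference.mean()
    corrected = (X - b[:, np.newaxis]) / a[:, np.newaxis]
    return table.with_spectra(corrected)


def msc_reference(table: SpectraTable) -> np.ndarray:
    """The mean spectrum of a calibration set, to reuse on prediction sets."""
    return table.spectra.mean(axis=0)


def pca_scores(table: SpectraTable, n_components: int) -> tuple[np.ndarray, np.ndarray]:
    """Principal-component scores and explained-variance percentages.

    Columns are mean-centered (not scaled); components are ordered by
    decreasing variance.  Returns (scores m x n_components, percentages).
    """
    m, n = table.spectra.shape
    if not 1 <= n_components <= min(m - 1, n):
        raise ValueError(f"n_components must lie in [1, {min(m - 1, n)}]")
    centered = table.spectra - table.spectra.mean(axis=0)
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    scores = u[:, :n_components] * s[:n_components]
    total = float(np.sum(s**2))
    explained = (s[:n_components] ** 2) / total * 100.0 if total > 0 else \
        np.zeros(n_components)
    return scores, explained


def apply_preprocessing(table: SpectraTable, spec: PreprocessSpec,
                        reference: np.ndarray | None = None) -> SpectraTable:
    """Dispatch a PreprocessSpec; ``reference`` overrides mean-of-set MSC."""
    if spec.method == "raw":
        return table
    if spec.method == "SG":
        return sg_smooth(table, spec.sg_order, spec.sg_window)
    if spec.method == "SG-D1":
        return sg_first_derivative(table, spec.sg_order, spec.sg_window)
    return msc(table, reference=reference)
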