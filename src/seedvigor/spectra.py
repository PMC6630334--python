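"""Per-seed mean-spectra tables: the m x n matrix the chemometrics operates on."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class SpectraTable:
    """m seeds by n wavelengths of reflectance, with optional class labels.

    ``seed_ids`` carries provenance (the positive label of each seed region,
    or a synthetic id); ``labels`` the class of each row where known.
    """

    spectra: np.ndarray
    wavelengths: np.ndarray
    labels: np.ndarray | None = None
    seed_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.spectra = np.atleast_2d(np.asarray(self.spectra, dtype=float))
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.spectra.ndim != 2:
            raise ValueError("spectra must be a 2-D (seeds x bands) matrix")
        if self.wavelengths.shape != (self.spectra.shape[1],):
            raise ValueError("wavelengths length must equal the column count")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape != (self.spectra.shape[0],):
                raise ValueError("labels length must equal the row count")
        if self.seed_ids is None:
            self.seed_ids = np.arange(1, self.spectra.shape[0] + 1)
        else:
            self.seed_ids = np.asarray(self.seed_ids)
            if self.seed_ids.shape != (self.spectra.shape[0],):
                raise ValueError("seed_ids length must equal the row count")

    @property
    def n_seeds(self) -> int:
        return self.spectra.shape[0]

    @property
    def n_bands(self) -> int:
        return self.spectra.shape[1]

    def subset(self, rows: np.ndarray) -> "SpectraTable":
        """Row subset (boolean mask or index array), preserving metadata."""
        rows = np.asarray(rows)
        return SpectraTable(
            spectra=self.spectra[rows],
            wavelengths=self.wavelengths.copy(),
            labels=None if self.labels is None else self.labels[rows],
            seed_ids=self.seed_ids[rows],
        )

    def select_bands(self, band_indices: np.ndarray) -> "SpectraTable":
        """Column subset by band index (e.g. an SPA-selected set)."""
        idx = np.asarray(band_indices, dtype=int)
        return SpectraTable(
            spectra=self.spectra[:, idx],
            wavelengths=self.wavelengths[idx],
            labels=None if self.labels is None else self.labels.copy(),
            seed_ids=self.seed_ids.copy(),
        )

    def with_spectra(self, new_spectra: np.ndarray) -> "SpectraTable":
        """Same rows/bands/metadata, new values (used by the preprocessors)."""
        new_spectra = np.asarray(new_spectra, dtype=float)
        if new_spectra.shape != self.spectra.shape:
            raise ValueError("replacement spectra must keep the table shape")
        return SpectraTable(
            spectra=new_spectra,
            wavelengths=self.wavelengths.copy(),
            labels=None if self.labels is None else self.labels.copy(),
            seed_ids=self.seed_ids.copy(),
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.spectra, columns=[f"{w:.6g}" for w in self.wavelengths])
        df.insert(0, "seed_id", self.seed_ids)
        if self.labels is not None:
            df.insert(1, "label", self.labels)
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SpectraTable":
        df = pd.read_csv(path)
        meta = [c for c in ("seed_id", "label") if c in df.columns]
        wavelengths = np.array([float(c) for c in df.columns if c not in meta])
        return cls(
            spectra=df.drop(columns=meta).to_numpy(dtype=float),
            wavelengths=wavelengths,
            labels=df["label"].to_numpy() if "label" in meta else None,
            seed_ids=df["seed_id"].to_numpy() if "seed_id" in meta else None,
        )
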