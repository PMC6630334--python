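"""End-to-end experiment orchestration and reporting.

Runs the whole analysis — phantom (or ENVI) input, reflectance calibration,
spectral trimming, seed segmentation, the four pretreatments (raw, SG,
SG-D1, MSC), SPA wavelength selection per pretreatment, and the three
classifiers on full and selected band sets — and collects a Table-2-style
accuracy grid (calibration and prediction accuracy for every
model x preprocessing x band-set cell).

Two classification tasks are supported:

* IVY — identify the storage year among the three viable-year classes;
* INV — identify non-viable (artificially aged) seeds among viable seeds of
  the three years.  The non-viable group pools aged seeds subsampled per
  year (133/133/134 by default, 400 in total) alongside the three viable
  groups.

Everything is deterministic given the configured seeds; a run manifest
records the config hash, seeds and per-stage sizes.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classifiers import (
    DEFAULT_GAMMA_GRID,
    DEFAULT_SIGMA2_GRID,
    evaluate,
    fit_elm,
    fit_lssvm,
    fit_plsda,
    split_train_test,
)
from .hsi_io import calibrate, trim_spectral
from .preprocessing import PreprocessSpec, apply_preprocessing, msc_reference, pca_scores
from .segmentation import extract_mean_spectra, label_seeds, threshold_mask
from .spa import SPAResult, spa_select
from .spectra import SpectraTable
from .synthetic import PhantomConfig, render_scan, simulate_spectra

VIABLE_CLASSES = ("y2017", "y2016", "y2015")
MODELS = ("PLS-DA", "LS-SVM", "ELM")


@dataclass
class ExperimentConfig:
    """Everything a reproducible experiment run needs."""

    task: str = "IVY"                       # IVY or INV
    source: str = "spectra"                 # "spectra", "cube", or a data path
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    n_per_class: int = 400                  # seeds generated per class
    per_class_train: int = 200
    per_class_test: int = 200
    aged_subsample: tuple = (133, 133, 134)  # non-viable group, per year
    trim_low: float = 941.0
    trim_high: float = 1666.0
    scatter_nonlinearity_sd: float = 0.0    # non-affine scatter stress mode
    preprocess: tuple = ("raw", "SG", "SG-D1", "MSC")
    models: tuple = MODELS
    # SPA settings
    spa_val_folds: int = 5
    spa_k_range: tuple = (2, 20)            # inclusive bounds
    spa_n_starts: int | None = None         # None = every column
    # classifier hyperparameters
    plsda_components: int = 10
    lssvm_gamma_grid: tuple = DEFAULT_GAMMA_GRID
    lssvm_sigma2_grid: tuple = DEFAULT_SIGMA2_GRID
    cv_folds: int = 10
    elm_hidden: int = 100
    # seeds
    data_seed: int = 0
    split_seed: int = 0
    model_seed: int = 0
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.task not in ("IVY", "INV"):
            raise ValueError(f"task must be IVY or INV, got {self.task!r}")
        if self.task == "INV":
            if len(self.aged_subsample) != 3:
                raise ValueError("aged_subsample needs one count per viable year")
            if any(c > self.n_per_class for c in self.aged_subsample):
                raise ValueError("aged subsample counts cannot exceed n_per_class")

    # -- (de)serialisation --------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["phantom"]["absorption_depths"] = {
            k: np.asarray(v, dtype=float).tolist()
            for k, v in d["phantom"]["absorption_depths"].items()
        }
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        d = yaml.safe_load(Path(path).read_text())
        phantom = d.pop("phantom", None)
        cfg = cls(**{k: tuple(v) if isinstance(v, list) else v for k, v in d.items()})
        if phantom is not None:
            for key in ("class_names", "absorption_centers", "seed_axes"):
                if key in phantom:
                    phantom[key] = tuple(phantom[key])
            cfg = replace(cfg, phantom=PhantomConfig(**phantom))
        return cfg


@dataclass
class RunManifest:
    """Traceability record for one experiment run."""

    config_hash: str
    software_version: str
    seeds: dict
    stage_counts: dict
    timestamp: str

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


def reduction_ratio(n_full: int, n_selected: int) -> tuple[float, float]:
    """Wavelength-reduction arithmetic: (percent retained, speed-up fold).

    E.g. 8 of 216 bands -> (3.7, 27.0): the selected set is 3.7% of the full
    set, a 27-fold reduction in per-spectrum data volume.
    """
    if not 0 < n_selected <= n_full:
        raise ValueError("need 0 < n_selected <= n_full")
    return (round(n_selected / n_full * 100.0, 1), round(n_full / n_selected, 1))


# ---------------------------------------------------------------------------
# data assembly


def _trim_table(table: SpectraTable, low: float, high: float) -> SpectraTable:
    keep = np.flatnonzero((table.wavelengths >= low) & (table.wavelengths <= high))
    return table.select_bands(keep)


def _spectra_from_cubes(config: ExperimentConfig, classes: tuple,
                        n_per_class: int, seed: int) -> SpectraTable:
    """Render as many small scans as needed and push them through the image
    stages (calibrate, trim, threshold, label, extract)."""
    phantom = config.phantom
    per_scan = phantom.seeds_per_class
    n_scans = int(np.ceil(n_per_class / per_scan))
    rows, labels = [], []
    for i in range(n_scans):
        cfg = phantom.updated(rng_seed=seed + i,
                              class_names=classes,
                              class_brightness=phantom.class_brightness,
                              absorption_depths=phantom.absorption_depths)
        scan, truth = render_scan(cfg)
        cube = trim_spectral(calibrate(scan), config.trim_low, config.trim_high)
        mask = label_seeds(threshold_mask(cube))
        table = extract_mean_spectra(cube, mask)
        if table.n_seeds != truth.n_seeds:
            raise RuntimeError(
                f"segmentation found {table.n_seeds} seeds but the phantom "
                f"holds {truth.n_seeds}"
            )
        rows.append(table.spectra)
        labels.extend(truth.seed_classes[k] for k in range(1, truth.n_seeds + 1))
        wavelengths = table.wavelengths
    spectra = np.vstack(rows)
    labels = np.array(labels, dtype=object)
    # keep exactly n_per_class per class (scans may overshoot)
    keep = np.concatenate([
        np.flatnonzero(labels == c)[:n_per_class] for c in classes
    ])
    return SpectraTable(spectra=spectra[keep], wavelengths=wavelengths,
                        labels=labels[keep])


def assemble_dataset(config: ExperimentConfig) -> SpectraTable:
    """Build the labelled, spectrally trimmed dataset for the configured task.

    For INV the non-viable group is assembled by per-year subsampling of
    aged seeds (counts from ``aged_subsample``), pooled under the single
    label "aged".
    """
    if config.source == "cube":
        def make(classes, n, seed):
            return _spectra_from_cubes(config, classes, n, seed)
    elif config.source == "spectra":
        def make(classes, n, seed):
            table, _ = simulate_spectra(
                config.phantom, n_per_class=n, rng_seed=seed, classes=classes,
                nonlinearity_sd=config.scatter_nonlinearity_sd)
            return _trim_table(table, config.trim_low, config.trim_high)
    else:
        raise ValueError(f"unknown source {config.source!r}")

    viable = make(VIABLE_CLASSES, config.n_per_class, config.data_seed)
    if config.task == "IVY":
        return viable

    # INV: three per-year batches of aged seeds, subsampled 133/133/134-style
    rng = np.random.default_rng(config.data_seed + 1)
    aged_parts = []
    for year_idx, count in enumerate(config.aged_subsample):
        batch = make(("aged",), config.n_per_class,
                     config.data_seed + 100 + year_idx)
        pick = rng.choice(batch.n_seeds, size=count, replace=False)
        aged_parts.append(batch.spectra[np.sort(pick)])
    aged = SpectraTable(
        spectra=np.vstack(aged_parts),
        wavelengths=viable.wavelengths,
        labels=np.array(["aged"] * sum(config.aged_subsample), dtype=object),
    )
    return SpectraTable(
        spectra=np.vstack([viable.spectra, aged.spectra]),
        wavelengths=viable.wavelengths,
        labels=np.concatenate([viable.labels, aged.labels]),
    )


# ---------------------------------------------------------------------------
# the experiment


def _fit_model(name: str, train: SpectraTable, config: ExperimentConfig):
    if name == "PLS-DA":
        return fit_plsda(train, n_components=min(config.plsda_components,
                                                 train.n_bands,
                                                 train.n_seeds - 1))
    if name == "LS-SVM":
        return fit_lssvm(train, gamma_grid=config.lssvm_gamma_grid,
                         sigma2_grid=config.lssvm_sigma2_grid,
                         folds=config.cv_folds, rng_seed=config.model_seed)
    if name == "ELM":
        return fit_elm(train, n_hidden=config.elm_hidden,
                       rng_seed=config.model_seed)
    raise ValueError(f"unknown model {name!r}")


def run_experiment(config: ExperimentConfig) -> dict:
    """Run the full grid; returns report DataFrame, SPA results, PCA, manifest.

    The report has one row per (preprocessing, model, band-set) with
    calibration and prediction accuracies — the structure of the study's
    accuracy table.  Outputs are written to ``config.output_dir`` when set.
    """
    dataset = assemble_dataset(config)
    per_class_test = config.per_class_test
    if config.task == "INV":
        # the aged group may be smaller than n_per_class; split it evenly
        counts = {c: int(np.sum(dataset.labels == c)) for c in np.unique(dataset.labels)}
        smallest = min(counts.values())
        per_class_train = min(config.per_class_train, smallest // 2)
        per_class_test = min(per_class_test, smallest - per_class_train)
    else:
        per_class_train = config.per_class_train
    train_raw, test_raw = split_train_test(
        dataset, per_class_train=per_class_train, per_class_test=per_class_test,
        rng_seed=config.split_seed,
    )

    n_full = train_raw.n_bands
    k_lo, k_hi = config.spa_k_range
    k_hi = min(k_hi, n_full, train_raw.n_seeds)
    if config.spa_n_starts is None:
        starts = None
    else:
        starts = np.unique(np.linspace(0, n_full - 1, config.spa_n_starts).astype(int))

    rows, spa_results, reports, pca = [], {}, {}, {}
    for method in config.preprocess:
        spec = PreprocessSpec(method=method)
        reference = msc_reference(train_raw) if method == "MSC" else None
        train = apply_preprocessing(train_raw, spec, reference=reference)
        test = apply_preprocessing(test_raw, spec, reference=reference)

        scores, explained = pca_scores(train, n_components=2)
        pca[method] = {"scores": scores, "explained_percent": explained,
                       "labels": train.labels}

        spa_res = spa_select(train, val_folds=config.spa_val_folds,
                             k_range=range(k_lo, k_hi + 1), starts=starts,
                             rng_seed=config.split_seed)
        spa_results[method] = spa_res
        band_sets = {
            "Full": np.arange(n_full),
            "Sel": spa_res.selected_indices,
        }
        for set_name, bands in band_sets.items():
            tr, te = train.select_bands(bands), test.select_bands(bands)
            for model_name in config.models:
                model = _fit_model(model_name, tr, config)
                report = evaluate(model, tr, te, model_tag=model_name,
                                  preprocessing_tag=method,
                                  wavelength_tag=set_name)
                reports[(method, model_name, set_name)] = report
                pct, fold = reduction_ratio(n_full, bands.size)
                rows.append({
                    "task": config.task,
                    "preprocessing": method,
                    "model": model_name,
                    "band_set": set_name,
                    "n_bands": int(bands.size),
                    "percent_of_full": pct,
                    "accuracy_calibration": report.accuracy_calibration,
                    "accuracy_prediction": report.accuracy_prediction,
                })

    report_df = pd.DataFrame(rows)
    manifest = RunManifest(
        config_hash=config.config_hash(),
        software_version=__version__,
        seeds={"data": config.data_seed, "split": config.split_seed,
               "model": config.model_seed},
        stage_counts={
            "dataset_rows": int(dataset.n_seeds),
            "train_rows": int(train_raw.n_seeds),
            "test_rows": int(test_raw.n_seeds),
            "bands_full": int(n_full),
            **{f"bands_selected_{m}": int(r.k) for m, r in spa_results.items()},
        },
        timestamp=datetime.now(timezone.utc).isoformat(),
    )

    result = {"report": report_df, "spa": spa_results, "pca": pca,
              "manifest": manifest}
    if config.output_dir:
        _write_outputs(result, config)
    return result


def _write_outputs(result: dict, config: ExperimentConfig) -> None:
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    result["report"].to_csv(outdir / "accuracy_grid.csv", index=False)
    for method, res in result["spa"].items():
        res.to_json(outdir / f"spa_{method.replace('-', '').lower()}.json")
    result["manifest"].to_json(outdir / "manifest.json")
    try:
        plot_pca(result["pca"], outdir)
    except Exception:  # plotting must never sink a finished run
        pass


def plot_pca(pca: dict, outdir: str | Path) -> None:
    """Score plots (PC1 vs PC2) per preprocessing method, as PNG files."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    for method, d in pca.items():
        fig, ax = plt.subplots(figsize=(5, 4))
        for cls in np.unique(d["labels"]):
            sel = d["labels"] == cls
            ax.scatter(d["scores"][sel, 0], d["scores"][sel, 1], s=12, label=str(cls))
        ev = d["explained_percent"]
        ax.set_xlabel(f"PC1 ({ev[0]:.2f}%)")
        ax.set_ylabel(f"PC2 ({ev[1]:.2f}%)")
        ax.set_title(f"PCA scores — {method}")
        ax.legend(fontsize=8)
        fig.tight_layout()
        fig.savefig(outdir / f"pca_{method.replace('-', '').lower()}.png", dpi=120)
        plt.close(fig)
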