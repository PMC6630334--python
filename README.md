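# seedvigor

Near-infrared hyperspectral imaging (NIR-HSI) analysis of seed vitality:
from raw line-scan hyperspectral cubes to per-seed classification of
storage year and viability, with germination-based vitality metrics.

Seed lots lose vigour in storage, and aged, non-viable seeds are
indistinguishable by eye. NIR reflectance spectra of individual seeds carry
the signature of that loss (water, starch and protein absorption bands),
so a hyperspectral camera plus chemometrics can sort seeds rapidly and
non-destructively. This package implements the full analysis chain for
anyone building or validating such a system:

1. **Calibration** — reflectance from raw counts,
   `I_cal = (I_raw − I_dark)/(I_ref − I_dark)`, then spectral trimming to
   the 941–1666 nm window (216 bands on the instrument grid).
2. **Segmentation** — threshold at 0.15 on the 1301 nm band, 4-connected
   labelling, one mean spectrum per seed.
3. **Pretreatments** — Savitzky–Golay smoothing (order 3, window 15), its
   first derivative, multiplicative scatter correction, and PCA
   exploration.
4. **Wavelength selection** — the successive projections algorithm (SPA):
   greedy selection of minimally collinear bands, with the subset size and
   starting band chosen by cross-validated PLS-DA error.
5. **Classification** — from-scratch PLS-DA (NIPALS, `Y = X·B + F`),
   LS-SVM (RBF kernel, one linear system per class pair, grid-searched
   γ and σ²) and ELM (random hidden layer, pseudoinverse readout), on full
   and SPA-selected bands, reported as calibration/prediction accuracy
   grids.
6. **Germination metrics** — germination rate `GR = GN/(GN+SN)·100` and
   vitality index `VI = S·Σ(Gt/Dt)` from daily count tables.

Because no public seed dataset accompanies this kind of study, the package
ships a **synthetic phantom generator** (`seedvigor.synthetic`) that renders
ENVI-format line-scan cubes with ground-truth seed masks, class labels,
per-seed scatter parameters and planted absorption wavelengths — every
stage is testable end to end without external data. See
`docs/methods.md` for the model and its deliberate limitations.

## Worked example

```python
import numpy as np
from seedvigor import (PhantomConfig, simulate_spectra, trim_spectral)
from seedvigor.classifiers import split_train_test, fit_lssvm, evaluate
from seedvigor.spa import spa_select

# seed-mean spectra for 120 seeds per class (3 storage years + aged)
table, truth = simulate_spectra(PhantomConfig(), n_per_class=120, rng_seed=0)
keep = (table.wavelengths >= 941) & (table.wavelengths <= 1666)
table = table.select_bands(np.flatnonzero(keep))

train, test = split_train_test(table, 60, 60, rng_seed=0)
spa = spa_select(train, val_folds=5, k_range=range(2, 17),
                 starts=np.linspace(0, 215, 16).astype(int), rng_seed=0)
print("selected:", np.sort(spa.selected_wavelengths).round(1))

tr, te = train.select_bands(spa.selected_indices), test.select_bands(spa.selected_indices)
report = evaluate(fit_lssvm(tr, rng_seed=0), tr, te)
print("calibration acc:", report.accuracy_calibration,
      "prediction acc:", report.accuracy_prediction)
```

Output:

```
selected: [ 968.1  988.2 1028.6 1203.3 1300.7 1404.9 1408.2 1411.6 1462.  1566.2
 1630.  1646.8 1656.9 1660.2]
calibration acc: 97.92 prediction acc: 97.08
```

The selected wavelengths cluster around the phantom's nine planted
absorption centres (968, 988, 1204, 1301, 1409, 1463, 1629, 1646,
1659 nm — water/starch/protein overtone bands), and the LS-SVM separates
the four vitality classes with ~97% held-out accuracy from 14 of 216
bands — the wavelength-reduction behaviour such sorting systems rely on.

The same experiment, full grid (4 pretreatments × 3 models × full/selected
bands, both classification tasks), runs from the shell:

```sh
seedvigor synth --out phantom/ --seed 7         # ENVI phantom + ground truth
seedvigor run --config experiment.yaml --out results/
seedvigor germination counts.csv                # GR / VI report
```

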