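"""Phantom generator: wavelength grid, endmembers, rendering, germination."""

import numpy as np
import pytest
from scipy import ndimage

from seedvigor import (
    PhantomConfig,
    calibrate,
    class_endmember,
    make_wavelength_grid,
    render_scan,
    simulate_germination,
    simulate_spectra,
)
from seedvigor.classifiers import PLSDAModel
from seedvigor.errors import PlacementError
from seedvigor.germination import germination_rate


class TestWavelengthGrid:
    def test_instrument_grid(self):
        grid = make_wavelength_grid(874.0, 3.36, 256)
        assert grid.size == 256
        assert grid[-1] == pytest.approx(1730.8)
        assert int(np.sum((grid >= 941.0) & (grid <= 1666.0))) == 216

    def test_identity_case(self):
        assert np.array_equal(make_wavelength_grid(0.0, 1.0, 2), [0.0, 1.0])

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            make_wavelength_grid(874.0, 0.0, 10)
        with pytest.raises(ValueError):
            make_wavelength_grid(874.0, 3.36, 1)


class TestEndmembers:
    def test_class_brightness_ordering(self):
        cfg = PhantomConfig()
        means = {c: class_endmember(c, cfg).mean() for c in cfg.class_names}
        assert means["aged"] > means["y2015"] > means["y2016"] > means["y2017"]

    def test_zero_depths_give_pure_baseline(self):
        cfg = PhantomConfig()
        cfg = cfg.updated(absorption_depths={c: np.zeros(9) for c in cfg.class_names})
        wl = cfg.wavelengths
        u = (wl - wl[0]) / (wl[-1] - wl[0])
        expected = cfg.class_brightness["y2016"] + cfg.baseline_slope * (u - 0.5)
        assert np.allclose(class_endmember("y2016", cfg), expected)

    def test_single_dip_depth_at_center(self):
        cfg = PhantomConfig()
        depth = 0.07
        flat = cfg.updated(absorption_depths={c: np.zeros(1) for c in cfg.class_names},
                           absorption_centers=(1301.0,))
        dipped = flat.updated(
            absorption_depths={c: np.array([depth]) for c in cfg.class_names})
        band = int(np.argmin(np.abs(cfg.wavelengths - 1301.0)))
        diff = class_endmember("y2017", flat)[band] - class_endmember("y2017", dipped)[band]
        offset = cfg.wavelengths[band] - 1301.0
        expected = depth * np.exp(-offset**2 / (2 * cfg.absorption_width_nm**2))
        assert diff == pytest.approx(expected, abs=1e-12)

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError, match="unknown class"):
            class_endmember("y1999", PhantomConfig())

    def test_brightness_ordering_enforced(self):
        with pytest.raises(ValueError, match="ordered"):
            PhantomConfig(class_brightness={"y2017": 0.5, "y2016": 0.45,
                                            "y2015": 0.4, "aged": 0.6})
        with pytest.raises(ValueError, match="background"):
            PhantomConfig(background_reflectance=0.2)


class TestRenderScan:
    def test_deterministic_given_seed(self, small_cfg):
        scan1, _ = render_scan(small_cfg)
        scan2, _ = render_scan(small_cfg)
        assert np.array_equal(scan1.raw, scan2.raw)

    def test_seed_count_matches_connected_components(self, small_cfg):
        _, truth = render_scan(small_cfg)
        assert truth.n_seeds == 12  # 3 seeds x 4 classes
        n_components = ndimage.label(truth.label_image > 0)[1]
        assert n_components == 12
        assert sorted(truth.seed_classes) == list(range(1, 13))

    def test_empty_phantom(self, small_cfg):
        scan, truth = render_scan(small_cfg.updated(seeds_per_class=0))
        assert truth.label_image.max() == 0
        refl = calibrate(scan).reflectance
        assert np.max(np.abs(refl - small_cfg.background_reflectance)) \
            <= 4 * small_cfg.noise_sd + 1e-12

    def test_placement_failure_reports_diagnostic(self):
        cfg = PhantomConfig(image_width=30, image_lines=30, seeds_per_class=20)
        with pytest.raises(PlacementError, match="placed only"):
            render_scan(cfg)

    def test_calibration_recovers_phantom_reflectance(self, clean_cfg):
        """Eq.-style round trip: calibrating the synthetic raw counts gives
        back the phantom reflectance to within the (bounded) noise."""
        noisy = clean_cfg.updated(noise_sd=0.01)
        scan, truth = render_scan(noisy)
        refl = calibrate(scan).reflectance
        expected = np.full(refl.shape, noisy.background_reflectance)
        for sid, cls in truth.seed_classes.items():
            a, b = truth.per_seed_scatter[sid]
            expected[truth.label_image == sid] = \
                a * truth.endmember_spectra[cls] + b
        assert np.max(np.abs(refl - expected)) <= 5 * noisy.noise_sd


def test_separability_monotone_in_brightness_gap():
    """Widening the class-brightness gaps cannot hurt year classification."""
    accuracies = []
    for gap in (0.01, 0.03, 0.06):
        brightness = {"y2017": 0.40, "y2016": 0.40 + gap, "y2015": 0.40 + 2 * gap,
                      "aged": 0.40 + 3.5 * gap}
        cfg = PhantomConfig(
            class_brightness=brightness,
            absorption_depths={c: np.full(9, 0.05) for c in ("y2017", "y2016",
                                                             "y2015", "aged")},
            spectral_noise_sd=0.02,
        )
        table, _ = simulate_spectra(cfg, n_per_class=60, rng_seed=11,
                                    classes=("y2017", "y2016", "y2015"))
        half = np.tile(np.arange(60) < 30, 3)
        train, test = table.subset(half), table.subset(~half)
        model = PLSDAModel(n_components=5).fit(train.spectra, train.labels)
        accuracies.append(np.mean(model.predict(test.spectra) == test.labels))
    assert accuracies[0] <= accuracies[1] <= accuracies[2]


class TestSimulateGermination:
    def test_aged_class_is_nonviable(self):
        rec = simulate_germination("aged", n_seeds=140, p_germ=0.9, rng_seed=0)
        assert rec.GN == 0 and rec.SN == 140
        assert germination_rate(rec) == 0.0

    def test_counts_sum_to_binomial_total(self):
        rec = simulate_germination("y2016", n_seeds=140, rng_seed=3)
        assert rec.daily_counts.sum() == rec.GN
        assert rec.GN + rec.SN == 140
        assert rec.daily_counts.size == 7

    def test_certain_immediate_germination(self):
        rec = simulate_germination("y2017", n_seeds=5, p_germ=1.0, mean_delay=1.0,
                                   germ_length=2.0, rng_seed=0)
        assert rec.GN == 5 and rec.daily_counts[0] == 5
        days = np.arange(1, 8)
        assert float(np.sum(rec.daily_counts / days)) == pytest.approx(5.0)

    def test_mean_rate_tracks_probability(self):
        rates = [
            germination_rate(simulate_germination("y2017", n_seeds=140,
                                                  p_germ=0.95, rng_seed=s))
            for s in range(200)
        ]
        assert abs(np.mean(rates) - 95.0) < 3.0

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            simulate_germination("y2017", n_seeds=0)
        with pytest.raises(ValueError):
            simulate_germination("y2017", n_seeds=10, p_germ=1.5)
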