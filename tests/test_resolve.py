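"""MCR-ALS resolution, predictive resolution, stability validation,
reference-table assembly and area integration."""

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from hmcr.datatypes import TimeWindow
from hmcr.resolve import (
    ConfigurationError,
    InputError,
    build_reference_table,
    choose_rank,
    extract_profiles,
    integrate_areas,
    predict_window,
    prediction_residuals,
    quantify,
    resolve_window,
    split_windows,
    stability_validate,
)
from hmcr.simulate import SimulationConfig, simulate_dataset

from conftest import single_window


def assignment_cosines(recovered: np.ndarray, true: np.ndarray) -> np.ndarray:
    """Cosines of the optimal (Hungarian) pairing of recovered to true spectra."""
    cos = np.array([[abs(a @ b) for b in true] for a in recovered])
    r, c = linear_sum_assignment(-cos)
    return cos[r, c], r, c


class TestSplitWindows:
    def test_flat_tic_gives_exact_widths(self):
        from hmcr.datatypes import GCMSDataset, IonMap
        import pandas as pd

        flat = IonMap("s0", np.ones((120, 10)), np.arange(120.0), np.arange(10.0) + 50)
        ds = GCMSDataset([flat], pd.DataFrame({"sample_id": ["s0"]}))
        wins = split_windows(ds, 30)
        assert [w.scan_range for w in wins] == [(0, 30), (30, 60), (60, 90), (90, 120)]

    def test_tiling_with_remainder(self, noiseless_dataset):
        dataset, _ = noiseless_dataset  # 200 scans
        wins = split_windows(dataset, 70)
        assert wins[0].scan_range[0] == 0
        assert wins[-1].scan_range[1] == 200
        for a, b in zip(wins[:-1], wins[1:]):
            assert a.scan_range[1] == b.scan_range[0]

    def test_no_cut_inside_a_peak(self, noiseless_dataset):
        dataset, truth = noiseless_dataset
        wins = split_windows(dataset, 45)
        cuts = [w.scan_range[0] for w in wins[1:]]
        for apex, width in zip(truth.true_retention, truth.true_widths):
            fwhm = 2.355 * width
            for cut in cuts:
                assert abs(cut - apex) > fwhm / 2

    def test_width_too_small_rejected(self, noiseless_dataset):
        dataset, _ = noiseless_dataset
        with pytest.raises(ConfigurationError):
            split_windows(dataset, 2)


class TestResolveWindow:
    def test_rank_one_exact(self):
        cfg = SimulationConfig(n_samples=4, n_components=1, n_scans=60,
                               mz_channels=40, bio_cv=0.2, seed=17)
        dataset, truth = simulate_dataset(cfg)
        rw = resolve_window(single_window(dataset), 1)
        cos = abs(rw.spectra[0] @ truth.true_spectra[0])
        assert cos == pytest.approx(1.0, abs=1e-10)
        g = truth.elution_profile(0, 60)
        for i, block in enumerate(rw.chrom_profiles):
            prof = block[:, 0]
            scale = prof.max() / g.max()
            np.testing.assert_allclose(prof, scale * g, atol=1e-8 * prof.max())

    def test_three_components_recovered(self, three_component_window):
        _, truth, win = three_component_window
        rw = resolve_window(win, 3)
        cos, _, _ = assignment_cosines(rw.spectra, truth.true_spectra)
        assert (cos >= 0.999).all()
        assert rw.residual_fraction < 1e-10

    def test_auto_rank_matches_svd_gap_oracle(self, three_component_window):
        _, _, win = three_component_window
        s = np.linalg.svd(win.stacked_data, compute_uv=False)
        assert s[3] / s[2] < 0.1  # oracle: clear gap after 3 components
        assert choose_rank(win.stacked_data) == 3
        assert resolve_window(win, "auto").n_components == 3

    def test_residual_monotone_nonincreasing(self, three_component_window):
        _, _, win = three_component_window
        rw = resolve_window(win, 3)
        assert np.all(np.diff(rw.residual_history) <= 1e-10)

    def test_residual_vanishes_as_noise_vanishes(self):
        resids = []
        for sd in (0.5, 0.05, 0.0):
            cfg = SimulationConfig(n_samples=6, n_components=2, n_scans=60,
                                   mz_channels=40, noise_sd=sd, bio_cv=0.2, seed=23)
            dataset, _ = simulate_dataset(cfg)
            resids.append(resolve_window(single_window(dataset), 2).residual_fraction)
        assert resids[0] > resids[1] > resids[2]
        assert resids[2] < 1e-10

    def test_excess_components_reduced_with_warning(self, caplog):
        x = np.outer(np.ones(5), np.ones(3))
        win = TimeWindow(0, (0, 5), x, 1)
        with caplog.at_level("WARNING", logger="hmcr"):
            rw = resolve_window(win, 10)
        assert rw.n_components <= 3
        assert any("reduced" in r.message for r in caplog.records)

    def test_negative_data_rejected(self):
        win = TimeWindow(0, (0, 2), np.array([[1.0, -0.1], [0.2, 0.3]]), 1)
        with pytest.raises(InputError):
            resolve_window(win, 1)


class TestPredictWindow:
    def test_training_set_self_consistency(self, three_component_window):
        _, _, win = three_component_window
        rw = resolve_window(win, 3)
        pred = predict_window(win, rw.spectra)
        c_als = np.vstack(rw.chrom_profiles)
        c_prd = np.vstack(pred)
        rel = np.linalg.norm(c_als - c_prd) / np.linalg.norm(c_als)
        assert rel < 1e-6

    def test_new_sample_concentrations_recovered(self, three_component_window):
        dataset, truth, win = three_component_window
        rw = resolve_window(win, 3)
        cos, rows, cols = assignment_cosines(rw.spectra, truth.true_spectra)
        # fresh samples from the same components, different concentrations
        cfg2 = SimulationConfig(n_samples=6, n_components=3, n_scans=80,
                                mz_channels=60, width_range=(2.0, 3.0),
                                bio_cv=0.5, seed=3)
        new_ds, new_truth = simulate_dataset(cfg2)
        new_win = single_window(new_ds)
        pred = predict_window(new_win, rw.spectra)
        areas = integrate_areas(pred)
        for r_i, c_i in zip(rows, cols):
            r = np.corrcoef(areas[:, r_i], new_truth.true_concentrations[:, c_i])[0, 1]
            assert r == pytest.approx(1.0, abs=1e-6)

    def test_unseen_component_raises_residual_and_flags(self, three_component_window):
        dataset, truth, win = three_component_window
        rw = resolve_window(win, 3)
        # a sample with an extra component the reference never saw
        rng = np.random.default_rng(99)
        extra_spec = np.zeros(60)
        extra_spec[rng.choice(60, 6, replace=False)] = rng.uniform(0.3, 1.0, 6)
        extra_spec /= np.linalg.norm(extra_spec)
        t = np.arange(80.0)
        g = np.exp(-0.5 * ((t - 40.0) / 2.5) ** 2)
        contaminated = dataset.samples[0].intensities + 120.0 * np.outer(g / g.sum(), extra_spec)
        stacked = np.vstack([contaminated] + [s.intensities for s in dataset.samples[1:]])
        win2 = TimeWindow(0, (0, 80), stacked, win.n_samples)
        pred = predict_window(win2, rw.spectra)
        resid = prediction_residuals(win2, rw.spectra, pred)
        assert resid[0] > resid[1:].max() * 5
        flags = prediction_residuals(win2, rw.spectra, pred, threshold=0.01)
        assert flags[0] and not flags[1:].any()

    def test_axis_mismatch_rejected(self, three_component_window):
        _, _, win = three_component_window
        with pytest.raises(InputError):
            predict_window(win, np.ones((2, 10)))


class TestStability:
    def test_duplicated_samples_all_stable(self, three_component_window):
        dataset, _, _ = three_component_window
        doubled = dataset.subset(list(range(10)) + list(range(10)))
        win = single_window(doubled)
        split = (list(range(10)), list(range(10, 20)))  # A is an exact copy of B
        profiles = stability_validate(doubled, win, split=split)
        assert all(p.stable for p in profiles)

    def test_data_driven_split_keeps_shared_components(self, three_component_window):
        dataset, _, win = three_component_window
        profiles = stability_validate(dataset, win)
        assert all(p.stable for p in profiles)

    def test_component_confined_to_set_a_is_unstable(self):
        """A component carried only by the set-A samples cannot be verified
        by the B-side resolution and must fail the criterion."""
        presence = np.ones((10, 4), dtype=bool)
        presence[5:, 3] = False  # component 3 absent from samples 5..9
        cfg = SimulationConfig(n_samples=10, n_components=4, n_scans=100,
                               mz_channels=60, width_range=(2.0, 3.0),
                               bio_cv=0.3, presence=presence, seed=31)
        dataset, truth = simulate_dataset(cfg)
        win = single_window(dataset)
        profiles = stability_validate(
            dataset, win, split=(list(range(5)), list(range(5, 10)))
        )
        spectra = np.vstack([p.spectrum for p in profiles])
        cos, rows, cols = assignment_cosines(spectra, truth.true_spectra)
        status = {c: profiles[r].stable for r, c in zip(rows, cols)}
        assert status[3] is False
        assert all(status[c] for c in (0, 1, 2))

    def test_too_few_samples_flagged_unstable(self, caplog):
        cfg = SimulationConfig(n_samples=3, n_components=2, n_scans=60,
                               mz_channels=30, bio_cv=0.2, seed=5)
        dataset, _ = simulate_dataset(cfg)
        with caplog.at_level("WARNING", logger="hmcr"):
            profiles = stability_validate(dataset, single_window(dataset))
        assert profiles and not any(p.stable for p in profiles)

    def test_default_threshold_is_095(self):
        import inspect

        sig = inspect.signature(stability_validate)
        assert sig.parameters["threshold"].default == 0.95


class TestReferenceTableAssembly:
    def _profiles(self, window_id, n, stable_flags, rt0=10.0):
        from hmcr.datatypes import SpectralProfile

        out = []
        for j in range(n):
            spec = np.zeros(20)
            spec[j + window_id * 3] = 1.0
            out.append(
                SpectralProfile(
                    profile_id=f"w{window_id}_m{j}",
                    spectrum=spec,
                    apex_rt=rt0 + window_id * 30 + 5 * j,
                    window_id=window_id,
                    stable=stable_flags[j],
                )
            )
        return out

    def test_stable_profiles_ordered_by_window_and_rt(self):
        plist = [
            self._profiles(0, 2, [True, True]),
            self._profiles(1, 1, [True]),
            self._profiles(2, 3, [False, False, False]),
        ]
        table = build_reference_table(plist, mz_axis=np.arange(20.0))
        assert len(table) == 3
        keys = [(p.window_id, p.apex_rt) for p in table.profiles]
        assert keys == sorted(keys)

    def test_empty_table_is_explicit_object(self):
        table = build_reference_table([], mz_axis=np.arange(5.0))
        assert len(table) == 0
        assert table.spectra_matrix().shape == (0, 5)

    def test_split_peak_duplicates_retained(self):
        a = self._profiles(0, 1, [True])
        b = self._profiles(1, 1, [True])
        b[0].spectrum = a[0].spectrum.copy()  # same compound, adjacent window
        table = build_reference_table([a, b], mz_axis=np.arange(20.0))
        assert len(table) == 2

    def test_many_component_recovery_into_table(self):
        cfg = SimulationConfig(n_samples=12, n_components=8, n_scans=400,
                               mz_channels=80, bio_cv=0.2, seed=41)
        dataset, truth = simulate_dataset(cfg)
        wins = split_windows(dataset, 60)
        plists = [stability_validate(dataset, w) for w in wins]
        table = build_reference_table(
            plists, dataset.mz_axis,
            window_ranges={w.window_id: w.scan_range for w in wins},
        )
        assert len(table) == 8
        cos, _, _ = assignment_cosines(table.spectra_matrix(), truth.true_spectra)
        assert (cos >= 0.99).all()


class TestAreas:
    def test_constant_unit_profile_trapezoid(self):
        w = 9
        areas = integrate_areas([np.ones((w, 1))])
        assert areas[0, 0] == pytest.approx(w - 1)

    def test_zero_profile_zero_area(self):
        areas = integrate_areas([np.zeros((5, 2))])
        np.testing.assert_array_equal(areas, np.zeros((1, 2)))

    def test_empty_input(self):
        assert integrate_areas([]).size == 0

    def test_areas_proportional_to_concentrations(self, three_component_window):
        dataset, truth, win = three_component_window
        rw = resolve_window(win, 3)
        areas = integrate_areas(rw.chrom_profiles)
        cos, rows, cols = assignment_cosines(rw.spectra, truth.true_spectra)
        for r_i, c_i in zip(rows, cols):
            r = np.corrcoef(areas[:, r_i], truth.true_concentrations[:, c_i])[0, 1]
            assert r == pytest.approx(1.0, abs=1e-8)


def test_quantify_round_trip(three_component_window):
    dataset, truth, win = three_component_window
    plist = stability_validate(dataset, win)
    table = build_reference_table(
        [plist], dataset.mz_axis, window_ranges={0: (0, 80)}
    )
    pt = quantify(dataset, table)
    assert pt.areas.shape == (10, len(table))
    spectra = table.spectra_matrix()
    cos, rows, cols = assignment_cosines(spectra, truth.true_spectra)
    for r_i, c_i in zip(rows, cols):
        r = np.corrcoef(pt.areas[:, r_i], truth.true_concentrations[:, c_i])[0, 1]
        assert r > 0.9999
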