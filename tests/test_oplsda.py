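"""OPLS-DA decomposition, cross-validation, prediction, permutation test,
and longitudinal model updating."""

import numpy as np
import pytest

from hmcr.datatypes import PeakTable
from hmcr.oplsda import (
    InputError,
    cross_validate,
    fit_oplsda,
    permutation_test,
    predict_samples,
    update_and_predict_longitudinal,
)

from conftest import null_peaktable, planted_oplsda


def _in_scaled_space(direction, model):
    """A raw-space direction expressed in the model's scaled variable space."""
    e = direction / model.x_scales
    return e / np.linalg.norm(e)


class TestFit:
    def test_planted_predictive_and_orthogonal_structure(self):
        """One dense y-correlated latent direction plus one dominant
        y-orthogonal confounder: w1 must align with the effect and the
        first OSC loading with the confounder (scaled space)."""
        pt, y, d_pred, d_orth = planted_oplsda(
            seed=0, n=120, effect=3.0, noise_sd=0.3, confounder_sd=12.0,
            n_effect_vars=None,
        )
        model = fit_oplsda(pt, y, n_ortho=1)
        cos_w = abs(model.w1 @ _in_scaled_space(d_pred, model))
        assert cos_w >= 0.99
        p_o = model.ortho_loadings[0] / np.linalg.norm(model.ortho_loadings[0])
        cos_o = abs(p_o @ _in_scaled_space(d_orth, model))
        assert cos_o >= 0.95

    def test_predictive_score_orthogonal_to_osc_scores(self):
        pt, y, _, _ = planted_oplsda(seed=1)
        model = fit_oplsda(pt, y, n_ortho=2)
        for j in range(model.t_ortho.shape[1]):
            assert abs(model.t1 @ model.t_ortho[:, j]) < 1e-8 * (
                np.linalg.norm(model.t1) * np.linalg.norm(model.t_ortho[:, j])
            )

    def test_zero_ortho_reduces_to_pls1(self):
        """With no OSC components the predictive weights equal the
        one-component PLS1 weight vector (sklearn as independent oracle)."""
        from sklearn.cross_decomposition import PLSRegression

        pt, y, _, _ = planted_oplsda(seed=2)
        model = fit_oplsda(pt, y, n_ortho=0)
        sk = PLSRegression(n_components=1, scale=True).fit(pt.areas, y)
        w_sk = sk.x_weights_[:, 0]
        w_sk = w_sk / np.linalg.norm(w_sk)
        assert abs(model.w1 @ w_sk) == pytest.approx(1.0, abs=1e-10)

    def test_null_data_mean_q2_nonpositive(self):
        q2s = []
        for seed in range(20):
            pt, y = null_peaktable(seed)
            _, q2 = cross_validate(pt, y, n_ortho=0)
            q2s.append(q2)
        assert np.mean(q2s) <= 0.0

    def test_r2y_nondecreasing_in_ortho_components(self):
        pt, y, _, _ = planted_oplsda(seed=3)
        r2ys = [fit_oplsda(pt, y, n_ortho=k).r2y for k in range(4)]
        assert all(b >= a - 1e-10 for a, b in zip(r2ys, r2ys[1:]))

    def test_q2_peaks_with_orthogonal_filtering_of_confounder(self):
        """With a strong planted confounder, filtering at least one OSC
        component must beat the unfiltered model in Q2, and the auto rule
        must therefore select n_ortho >= 1."""
        hits = 0
        for seed in range(10):
            pt, y, _, _ = planted_oplsda(seed=seed, confounder_sd=6.0)
            _, q2_0 = cross_validate(pt, y, n_ortho=0)
            _, q2_1 = cross_validate(pt, y, n_ortho=1)
            if q2_1 > q2_0:
                hits += 1
        assert hits >= 9
        model = fit_oplsda(planted_oplsda(seed=0, confounder_sd=6.0)[0],
                           planted_oplsda(seed=0, confounder_sd=6.0)[1],
                           n_ortho="auto")
        assert model.n_ortho >= 1

    def test_single_class_rejected(self):
        pt, _ = null_peaktable(0)
        with pytest.raises(InputError):
            fit_oplsda(pt, np.zeros(len(pt.sample_ids)), n_ortho=0)

    def test_constant_variable_dropped_with_warning(self, caplog):
        pt, y = null_peaktable(1)
        pt.areas[:, 4] = 7.0
        with caplog.at_level("WARNING", logger="hmcr"):
            model = fit_oplsda(pt, y, n_ortho=0)
        assert "v04" not in model.profile_ids
        assert any("constant" in r.message for r in caplog.records)


class TestCrossValidate:
    def test_perfectly_separated_data_100_percent(self):
        pt, y, _, _ = planted_oplsda(seed=4, effect=8.0, noise_sd=0.1)
        report, q2 = cross_validate(pt, y, n_ortho=1)
        assert report.accuracy_cv == 100.0
        assert q2 > 0.8

    def test_permuted_labels_give_chance_accuracy(self):
        """Label-permuted data: pooled CV accuracy over seeds must fall in
        the binomial 95% band around 50%."""
        rng = np.random.default_rng(7)
        correct = total = 0
        for seed in range(20):
            pt, y, _, _ = planted_oplsda(seed=seed)
            yp = rng.permutation(y)
            if len(np.unique(yp)) < 2:
                continue
            report, _ = cross_validate(pt, yp, n_ortho=0)
            correct += (report.predicted_class == yp.astype(int)).sum()
            total += len(yp)
        p = correct / total
        half_width = 1.96 * np.sqrt(0.25 / total)
        assert abs(p - 0.5) <= half_width + 0.05  # CV under the null is slightly pessimistic

    def test_leave_one_out_deterministic(self):
        pt, y, _, _ = planted_oplsda(seed=5, n=14)
        a, q2a = cross_validate(pt, y, n_ortho=0, folds=14)
        b, q2b = cross_validate(pt, y, n_ortho=0, folds=14)
        np.testing.assert_array_equal(a.predicted_y, b.predicted_y)
        assert q2a == q2b

    def test_q2_not_above_r2y(self):
        pt, y, _, _ = planted_oplsda(seed=6)
        model = fit_oplsda(pt, y, n_ortho=1)
        assert model.q2 <= model.r2y + 1e-10


class TestPredict:
    def test_training_data_self_consistent(self):
        pt, y, _, _ = planted_oplsda(seed=8)
        model = fit_oplsda(pt, y, n_ortho=1)
        report = predict_samples(model, pt, y_true=y)
        fitted_class = (model.t1 * model.q_coef + model.y_mean >= 0.5).astype(int)
        np.testing.assert_array_equal(report.predicted_class, fitted_class)

    def test_external_accuracy_tracks_in_model_accuracy(self):
        pt, y, _, _ = planted_oplsda(seed=9, effect=6.0, noise_sd=0.15)
        model = fit_oplsda(pt, y, n_ortho=1)
        in_model, _ = cross_validate(pt, y, n_ortho=1)
        assert in_model.accuracy_cv == 100.0
        pt2, y2, _, _ = planted_oplsda(seed=909, n=40, effect=6.0, noise_sd=0.15)
        report = predict_samples(model, pt2, y_true=y2)
        assert report.accuracy_test >= 95.0

    def test_pure_orthogonal_shift_leaves_prediction_unchanged(self):
        pt, y, _, d_orth = planted_oplsda(seed=10)
        model = fit_oplsda(pt, y, n_ortho=1)
        x = pt.areas[3].copy()
        # shift along the orthogonal loading, expressed in raw units
        shift_scaled = model.ortho_loadings[0] / np.linalg.norm(model.ortho_loadings[0])
        x_shift = x + 5.0 * shift_scaled * model.x_scales
        ya = model.predict_y(x[None, :])[0]
        yb = model.predict_y(x_shift[None, :])[0]
        assert abs(ya - yb) < 1e-6

    def test_column_mismatch_lists_offenders(self):
        pt, y, _, _ = planted_oplsda(seed=11)
        model = fit_oplsda(pt, y, n_ortho=0)
        bad = PeakTable(
            areas=pt.areas[:, :-1],
            sample_ids=pt.sample_ids,
            profile_ids=pt.profile_ids[:-1],
        )
        with pytest.raises(InputError, match="v29"):
            predict_samples(model, bad)


class TestPermutation:
    def test_default_permutation_count(self):
        import inspect

        from hmcr.oplsda import permutation_test as fn

        assert inspect.signature(fn).parameters["n_perm"].default == 10_000

    def test_exhaustive_matches_enumeration_oracle(self):
        """n=5 exhaustive switch: the null quantiles must equal those of a
        direct enumeration of all 120 label orderings."""
        rng = np.random.default_rng(12)
        X = np.clip(5 + rng.normal(size=(5, 6)), 0, None)
        y = np.array([0.0, 0.0, 1.0, 1.0, 1.0])
        pt = PeakTable(areas=X, sample_ids=[f"s{i}" for i in range(5)],
                       profile_ids=[f"v{j}" for j in range(6)])
        res = permutation_test(pt, y, exhaustive=True, alpha=0.05, n_ortho=0)
        assert res.n_perm == 120
        # oracle: |w| = |Z^T y_perm| / ||Z^T y_perm|| for every ordering
        from itertools import permutations

        Z = (X - X.mean(0)) / X.std(0, ddof=1)
        yc = y - y.mean()
        null = []
        for p in permutations(range(5)):
            v = Z.T @ yc[list(p)]
            null.append(np.abs(v / np.linalg.norm(v)))
        expected = np.quantile(np.array(null), 0.95, axis=0)
        np.testing.assert_allclose(res.null_quantile, expected, atol=1e-12)

    def test_type_one_error_calibrated(self):
        """Null data: the per-variable false-positive rate must fall in the
        binomial 99% band around alpha."""
        alpha = 0.05
        fp = total = 0
        for seed in range(20):
            pt, y = null_peaktable(seed, n=16, p=50)
            res = permutation_test(pt, y, n_perm=500, alpha=alpha, seed=seed, n_ortho=0)
            fp += int(res.significant.sum())
            total += len(res.significant)
        rate = fp / total
        half = 2.576 * np.sqrt(alpha * (1 - alpha) / total)
        assert abs(rate - alpha) <= half + 0.01

    def test_power_for_two_sd_effects(self):
        """A sparse regulated pattern (3 of 30 variables, each separated by
        2 pooled SD) at n=16 must be detected with power >= 0.8."""
        hits = total = 0
        for seed in range(10):
            pt, y, d_pred, _ = planted_oplsda(
                seed=seed, n=16, p=30, effect=1.0, n_effect_vars=3,
                confounder_sd=0.0,
            )
            res = permutation_test(pt, y, n_perm=500, alpha=0.05, seed=seed, n_ortho=0)
            effect_vars = np.nonzero(d_pred)[0]
            hits += int(res.significant[effect_vars].sum())
            total += len(effect_vars)
        assert hits / total >= 0.8

    def test_too_few_permutations_rejected(self):
        pt, y = null_peaktable(0)
        with pytest.raises(InputError):
            permutation_test(pt, y, n_perm=10)


class TestLongitudinalUpdate:
    def test_updating_with_training_data_is_idempotent(self):
        pt, y, _, _ = planted_oplsda(seed=13, effect=4.0)
        model = fit_oplsda(pt, y, n_ortho=1)
        report, updated = update_and_predict_longitudinal(model, pt, pt, y_test2=y)
        assert abs(updated.w1 @ model.w1) >= 0.999
        assert report.accuracy_test >= 95.0

    def test_batch_shift_in_nonsignificant_variables_tolerated(self):
        """The longitudinal design claim: restricting the updated model to
        the significant pattern makes stage-3 predictions robust to batch
        shifts confined to non-significant variables."""
        pt, y, d_pred, _ = planted_oplsda(seed=14, n=32, effect=4.0, confounder_sd=0.0)
        model = fit_oplsda(pt, y, n_ortho=0)
        perm = permutation_test(pt, y, n_perm=300, alpha=0.05, seed=14, n_ortho=0)
        stage1 = predict_samples(model, pt, y_true=y)

        sig = set(perm.significant_ids())
        shift_cols = [j for j, pid in enumerate(pt.profile_ids) if pid not in sig]
        pt2, y2, _, _ = planted_oplsda(seed=1414, n=32, effect=4.0, confounder_sd=0.0)
        shifted = pt2.areas.copy()
        shifted[:, shift_cols] += 3.0
        pt2s = PeakTable(areas=shifted, sample_ids=pt2.sample_ids,
                         profile_ids=pt2.profile_ids)
        report, _ = update_and_predict_longitudinal(
            model, pt, pt2s, significant=perm, y_test2=y2
        )
        assert report.accuracy_test >= stage1.accuracy_test - 2.0

    def test_stage3_accuracy_degrades_with_injected_label_errors(self):
        pt, y, _, _ = planted_oplsda(
            seed=15, n=32, effect=0.75, noise_sd=1.0, confounder_sd=0.0
        )
        model = fit_oplsda(pt, y, n_ortho=0)
        pt2, y2, _, _ = planted_oplsda(
            seed=1515, n=32, effect=0.75, noise_sd=1.0, confounder_sd=0.0
        )
        base = predict_samples(model, pt).predicted_class
        rng = np.random.default_rng(15)
        flip_order = rng.permutation(len(base))
        accs = []
        for n_flip in (0, 8, 16, 24):
            labels = base.copy()
            flips = flip_order[:n_flip]
            labels[flips] = 1 - labels[flips]
            report, _ = update_and_predict_longitudinal(
                model, pt, pt2, y_test2=y2, stage1_labels=labels
            )
            accs.append(report.accuracy_test)
        assert all(a >= b - 1e-9 for a, b in zip(accs, accs[1:]))
        assert accs[-1] < accs[0]
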