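"""Marker extraction, metrics, BHS grading and Bland-Altman agreement."""

import numpy as np
import pandas as pd
import pytest

from pulsemorph.evaluation import (
    bhs_grade,
    bland_altman,
    evaluate_predictions,
    evaluate_scenario,
    extract_markers,
    marker_metric_table,
    metrics,
    restore_scale,
)
from pulsemorph.features import TargetScaler


class TestMarkers:
    def test_dbp_and_sbp_rules(self):
        m = extract_markers([80.0, 120, 100, 90, 82], [0, 0, 1, 2, 2])
        assert m.dbp == pytest.approx(81.0)
        assert m.sbp == pytest.approx(120.0)

    def test_duration_and_dn_from_classes(self):
        values = np.linspace(100, 90, 6)
        m = extract_markers(values, [0, 0, 1, 1, 2, 3])
        assert m.duration_ms == pytest.approx(5 / 125 * 1000)
        assert m.dnto_ms == pytest.approx(3 / 125 * 1000)
        assert m.dn_value == pytest.approx(values[3])

    def test_well_ordered_prediction_dnto_before_duration(self):
        classes = [0] * 30 + [1] * 25 + [2] * 45 + [3] * 20
        values = np.concatenate([np.linspace(80, 120, 55), np.linspace(120, 80, 65)])
        m = extract_markers(values, classes)
        assert m.dnto_ms < m.duration_ms

    def test_no_ended_class_uses_full_length(self):
        m = extract_markers(np.linspace(80, 90, 10), [0, 0, 1, 1, 2, 2, 2, 2, 2, 2])
        assert m.duration_ms == pytest.approx(10 / 125 * 1000)

    def test_no_notch_class_leaves_dn_undefined(self):
        m = extract_markers(np.linspace(80, 90, 6), [0, 0, 0, 2, 2, 3])
        assert m.dn_value is None and m.dnto_ms is None


class TestRestoreScale:
    def test_endpoints(self):
        sc = TargetScaler(vmin=50.0, vmax=180.0)
        assert restore_scale(0.0, sc) == pytest.approx(50.0)
        assert restore_scale(1.0, sc) == pytest.approx(180.0)

    def test_roundtrip(self):
        sc = TargetScaler(vmin=60.0, vmax=140.0)
        x = np.linspace(60, 140, 9)
        assert np.allclose(restore_scale(sc.transform(x), sc), x)


class TestMetrics:
    def test_perfect_prediction_ideal_values(self):
        z = np.array([80.0, 90, 100, 110])
        m = metrics(z, z)
        assert m.rmse == 0 and m.mae == 0 and m.r2 == 1 and m.r == 1

    def test_anticorrelated(self):
        z = np.array([-1.0, 0.0, 1.0])
        m = metrics(z, -z)
        assert m.r == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        m = metrics([1.0, 2, 3], [2.0, 2, 2])
        assert m.mae == pytest.approx(2 / 3)
        assert m.rmse == pytest.approx(np.sqrt(2 / 3))
        assert m.r2 == pytest.approx(0.0)

    def test_rmse_at_least_mae(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            z, zh = rng.normal(size=(2, 20))
            m = metrics(z, zh)
            assert m.rmse >= m.mae

    def test_truncates_to_shorter_sequence(self):
        m = metrics(np.arange(10.0), np.arange(6.0))
        assert m.n == 6 and m.rmse == 0.0

    def test_zero_truth_variance_raises(self):
        with pytest.raises(ValueError):
            metrics([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestBhs:
    def test_grade_a_thresholds(self):
        e = np.concatenate([np.full(60, 1.0), np.full(25, 7.0), np.full(10, 12.0),
                            np.full(5, 20.0)])
        rep = bhs_grade(e)
        assert rep.cumulative_pct == pytest.approx((60.0, 85.0, 95.0))
        assert rep.bhs_grade == "A"

    def test_printed_grade_c_percentages(self):
        # cumulative percentages (41.8, 76.6, 92.9) meet the C row only
        rng = np.random.default_rng(0)
        n = 1000
        e = np.empty(n)
        e[:418] = 2.0
        e[418:766] = 7.0
        e[766:929] = 12.0
        e[929:] = 20.0
        rep = bhs_grade(e)
        assert rep.cumulative_pct == pytest.approx((41.8, 76.6, 92.9))
        assert rep.bhs_grade == "C"

    def test_printed_grade_b_percentages(self):
        n = 1000
        e = np.empty(n)
        e[:566] = 2.0
        e[566:860] = 7.0
        e[860:955] = 12.0
        e[955:] = 20.0
        rep = bhs_grade(e)
        assert rep.cumulative_pct == pytest.approx((56.6, 86.0, 95.5))
        assert rep.bhs_grade == "B"

    def test_below_c_fails(self):
        rep = bhs_grade(np.full(10, 30.0))
        assert rep.bhs_grade == "fail"

    def test_monotone_smaller_errors_never_worse(self):
        rng = np.random.default_rng(1)
        order = {"A": 3, "B": 2, "C": 1, "fail": 0}
        for _ in range(20):
            e = np.abs(rng.normal(0, 8, 100))
            shrunk = e * rng.uniform(0.3, 1.0)
            assert order[bhs_grade(shrunk).bhs_grade] >= order[bhs_grade(e).bhs_grade]

    def test_cumulative_percentages_non_decreasing(self):
        rep = bhs_grade(np.abs(np.random.default_rng(2).normal(0, 10, 200)))
        assert rep.cumulative_pct[0] <= rep.cumulative_pct[1] <= rep.cumulative_pct[2]


class TestBlandAltman:
    def test_perfect_agreement(self):
        mu, (lo, hi) = bland_altman([1.0, 2, 3], [1.0, 2, 3])
        assert mu == 0 and lo == 0 and hi == 0

    def test_hand_computed_limits(self):
        # d = [1, -1]: mean 0, sample sd sqrt(2), limits +/- 1.96*sqrt(2)
        mu, (lo, hi) = bland_altman([0.0, 0.0], [1.0, -1.0])
        assert mu == pytest.approx(0.0)
        assert hi == pytest.approx(1.96 * np.sqrt(2))
        assert lo == pytest.approx(-1.96 * np.sqrt(2))

    def test_limits_symmetric_about_mean(self):
        rng = np.random.default_rng(3)
        z, zh = rng.normal(100, 10, (2, 50))
        mu, (lo, hi) = bland_altman(z, zh)
        assert hi - mu == pytest.approx(mu - lo)


class TestScenarioReport:
    def _fake_table(self, seed):
        rng = np.random.default_rng(seed)
        n = 30
        dbp = rng.normal(65, 8, n)
        sbp = rng.normal(130, 15, n)
        return pd.DataFrame(
            {
                "dbp_true": dbp, "dbp_pred": dbp + rng.normal(0, 4, n),
                "sbp_true": sbp, "sbp_pred": sbp + rng.normal(0, 8, n),
                "dn_true": dbp + 20, "dn_pred": dbp + 20 + rng.normal(0, 5, n),
                "dnto_true_ms": rng.normal(300, 20, n),
                "dnto_pred_ms": rng.normal(300, 25, n),
                "duration_true_ms": rng.normal(900, 60, n),
                "duration_pred_ms": rng.normal(900, 70, n),
                "waveform_r": rng.uniform(0.9, 1, n),
                "waveform_rmse": rng.uniform(3, 10, n),
                "waveform_mae": rng.uniform(2, 8, n),
            }
        )

    def test_grid_contains_all_markers(self):
        table = marker_metric_table(self._fake_table(0))
        assert set(table.index) == {"DBP", "DN", "SBP", "DNTO", "duration"}
        assert set(table.columns) >= {"R2", "RMSE", "MAE", "STD"}

    def test_fold_aggregation_matches_hand_mean_sd(self):
        tables = [self._fake_table(s) for s in range(3)]
        report = evaluate_scenario(tables)
        per_fold = [marker_metric_table(t).loc["DBP", "MAE"] for t in tables]
        assert report.loc["DBP", "MAE_mean"] == pytest.approx(np.mean(per_fold))
        assert report.loc["DBP", "MAE_std"] == pytest.approx(np.std(per_fold, ddof=1))

    def test_ground_truth_as_prediction_is_ideal(self, training_setup):
        _samples, _scaler, T, products = training_setup
        tuples = []
        for p in products[:3]:
            v = p.morphology.values
            c = p.morphology.classes
            tuples.append((v, c, v.copy(), c.copy()))
        table = evaluate_predictions(tuples)
        assert np.allclose(table.dbp_true, table.dbp_pred)
        assert np.allclose(table.waveform_r, 1.0)
        assert np.allclose(table.waveform_rmse, 0.0)
        errors = (table.dbp_pred - table.dbp_true).to_numpy()
        assert bhs_grade(errors).bhs_grade == "A"


class TestPlots:
    def test_figures_render_without_error(self, tmp_path, training_setup):
        import matplotlib.pyplot as plt

        from pulsemorph.plots import plot_attention_map, plot_bland_altman, plot_prediction

        _samples, _scaler, _T, products = training_setup
        m = products[0].morphology
        ax = plot_prediction(m.values, m.values + 1.0, m.classes)
        ax.figure.savefig(tmp_path / "pred.png")
        ax2 = plot_attention_map(np.random.default_rng(0).random((20, 30)))
        ax2.figure.savefig(tmp_path / "att.png")
        ax3 = plot_bland_altman([60, 70, 80.0], [62, 69, 83.0])
        ax3.figure.savefig(tmp_path / "ba.png")
        plt.close("all")
        assert (tmp_path / "pred.png").stat().st_size > 0
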