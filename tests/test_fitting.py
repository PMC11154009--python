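"""Response-parameter fitting: anchoring, prediction, NLS, CIs, cohort stats."""

from types import SimpleNamespace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mpndyn import (
    DEFAULT_PARAMETERS,
    PatientSeries,
    TreatmentResponse,
    TreatmentResponseModel,
    approximate_ci,
    baseline_state,
    cohort_summary,
    fit_patient,
    predict_vaf,
    read_patient_series,
    rmse,
    vaf_readout,
    write_patient_series,
)
from mpndyn.fitting import _predict_curve, baseline_anchor

P = DEFAULT_PARAMETERS


class TestRmse:
    def test_hand_arithmetic(self):
        assert rmse([0.5, 0.4], [0.4, 0.5]) == pytest.approx(0.1, rel=1e-12)

    def test_identical_vectors(self):
        assert rmse([0.1, 0.9, 0.4], [0.1, 0.9, 0.4]) == 0.0

    @settings(derandomize=True, max_examples=30)
    @given(st.lists(st.tuples(st.floats(0, 1), st.floats(0, 1)), min_size=1, max_size=12))
    def test_permutation_invariance(self, pairs):
        obs, pred = map(np.array, zip(*pairs))
        perm = np.random.default_rng(0).permutation(len(obs))
        assert rmse(obs, pred) == pytest.approx(rmse(obs[perm], pred[perm]), rel=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rmse([], [])


class TestBaselineState:
    @pytest.mark.parametrize("v", [0.35, 0.5, 0.76, 0.9])
    def test_defining_property(self, v):
        """The anchored state's model VAF equals the requested first VAF."""
        st_ = baseline_state(v, P)
        assert vaf_readout(st_.x2, st_.y2) == pytest.approx(v, abs=1e-6)

    def test_half_vaf_is_reached_near_year_30(self):
        t, _ = baseline_anchor(0.50, P)
        assert t / 365.0 == pytest.approx(30.0, abs=2.0)

    def test_anchor_time_monotone_in_vaf(self):
        times = [baseline_anchor(v, P)[0] for v in (0.35, 0.5, 0.76, 0.9)]
        assert np.all(np.diff(times) > 0)

    def test_unreachable_stage_raises(self):
        """With a non-competitive mutant clone the disease never progresses."""
        losing = P.replace(p_y0=0.80)
        with pytest.raises(ValueError, match="never reaches"):
            baseline_state(0.5, losing)

    @pytest.mark.parametrize("v", [0.0, 1.0, -0.1])
    def test_domain(self, v):
        with pytest.raises(ValueError):
            baseline_state(v, P)


@pytest.fixture(scope="module")
def clean_series():
    """Noiseless series generated by the forward model with known truth."""
    truth = (0.8, 0.15)
    times = np.array([0.0, 90.0, 200.0, 365.0, 580.0, 900.0])
    start = baseline_state(0.7, P)
    clean = _predict_curve(*truth, 35.0, start, times, P)
    series = PatientSeries("clean", tuple(times), tuple(clean), 35.0)
    return series, truth


class TestPrediction:
    def test_first_prediction_anchored_to_first_observation(self, clean_series):
        series, _ = clean_series
        pred = predict_vaf(TreatmentResponse(0.3, 0.1, 35.0), series, P)
        assert pred[0] == pytest.approx(series.vaf[0], abs=1e-6)

    def test_zero_response_prediction_is_nondecreasing(self, clean_series):
        series, _ = clean_series
        pred = predict_vaf(TreatmentResponse(0.0, 0.0, 35.0), series, P)
        assert np.all(np.diff(pred) >= -1e-9)

    def test_progenitor_only_response_dips_then_rises(self):
        start = baseline_state(0.76, P)
        t = np.linspace(0.0, 6 * 365.0, 60)
        curve = _predict_curve(0.0, 0.5, 35.0, start, t, P)
        imin = np.argmin(curve)
        assert curve[imin] < curve[0] - 0.05
        assert curve[-1] > curve[imin] + 0.05


class TestFit:
    def test_noiseless_recovery(self, clean_series):
        series, truth = clean_series
        res = fit_patient(series, P, "both")
        assert res.rho_sy0 == pytest.approx(truth[0], rel=1e-2)
        assert res.rho_dy1 == pytest.approx(truth[1], rel=1e-2)
        assert res.rmse < 1e-6

    def test_nested_model_dominance(self, clean_series):
        series, _ = clean_series
        noisy_vaf = np.clip(
            series.vaf_array + np.random.default_rng(4).normal(0, 0.02, series.m), 0, 1
        )
        noisy = PatientSeries("noisy", series.times, tuple(noisy_vaf), series.dose)
        rmses = {mode: fit_patient(noisy, P, mode).rmse for mode in ("both", "sy0_only", "dy1_only")}
        assert rmses["both"] <= rmses["sy0_only"] + 1e-12
        assert rmses["both"] <= rmses["dy1_only"] + 1e-12

    def test_restricted_mode_pins_excluded_parameter(self, clean_series):
        series, _ = clean_series
        res = fit_patient(series, P, "dy1_only")
        assert res.rho_sy0 == 0.0
        res = fit_patient(series, P, "sy0_only")
        assert res.rho_dy1 == 0.0

    def test_invalid_mode(self, clean_series):
        with pytest.raises(ValueError):
            TreatmentResponseModel(clean_series[0], P, mode="everything")


class TestApproximateCI:
    @pytest.fixture(scope="class")
    def noisy_fit(self, clean_series):
        series, _ = clean_series
        rng = np.random.default_rng(12)
        noisy = PatientSeries(
            "noisy-ci",
            series.times,
            tuple(np.clip(series.vaf_array + rng.normal(0, 0.02, series.m), 0, 1)),
            series.dose,
        )
        return fit_patient(noisy, P, "both")

    def test_no_degrees_of_freedom_rejected(self):
        start = baseline_state(0.7, P)
        times = np.array([0.0, 120.0])
        clean = _predict_curve(0.5, 0.1, 35.0, start, times, P)
        tiny = PatientSeries("tiny", tuple(times), tuple(clean), 35.0)
        res = fit_patient(tiny, P, "both")
        with pytest.raises(ValueError, match="degrees of freedom"):
            approximate_ci(res, n_samples=10)

    def test_seed_reproducibility(self, noisy_fit):
        a = approximate_ci(noisy_fit, n_samples=200, seed=5, compute_band=False)
        ci_a = (a.rho_sy0_ci, a.rho_dy1_ci)
        b = approximate_ci(noisy_fit, n_samples=200, seed=5, compute_band=False)
        assert (b.rho_sy0_ci, b.rho_dy1_ci) == ci_a

    def test_truth_coverage_on_replicates(self, clean_series):
        """The linearised 95% interval should cover the truth on most
        replicate noisy datasets (it is approximate, not exact)."""
        series, truth = clean_series
        rng = np.random.default_rng(99)
        covered = 0
        n_rep = 8
        for _ in range(n_rep):
            noisy = PatientSeries(
                "rep",
                series.times,
                tuple(np.clip(series.vaf_array + rng.normal(0, 0.02, series.m), 0, 1)),
                series.dose,
            )
            res = fit_patient(noisy, P, "both")
            res = approximate_ci(res, n_samples=300, seed=1, compute_band=False)
            lo, hi = res.rho_dy1_ci
            covered += lo <= truth[1] <= hi
        assert covered >= int(0.6 * n_rep)

    def test_plot_smoke(self, noisy_fit):
        import matplotlib

        matplotlib.use("Agg")
        ax = noisy_fit.plot()
        assert ax.get_ylabel().startswith("JAK2")

    def test_summary_renders(self, noisy_fit):
        res = approximate_ci(noisy_fit, n_samples=100, seed=0, compute_band=False)
        text = res.summary()
        assert "rho_sy0" in text and "RMSE" in text and "95% CI" in text


class TestCohortSummary:
    @staticmethod
    def _stub(fold_s, fold_d, r=0.01):
        return SimpleNamespace(fold_sy0=fold_s, fold_dy1=fold_d, rmse=r)

    def test_hand_arithmetic(self):
        out = cohort_summary([self._stub(2, 2), self._stub(4, 4)])
        assert out["fold_sy0_mean"] == pytest.approx(3.0)
        assert out["fold_sy0_sd"] == pytest.approx(np.sqrt(2.0))

    def test_outlier_exclusion(self):
        out = cohort_summary(
            [self._stub(2, 2), self._stub(4, 4), self._stub(3.19e6, 3)],
            outlier_fold_threshold=100,
        )
        assert out["fold_sy0_n_excluded"] == 1
        assert out["fold_sy0_mean"] == pytest.approx(3.0)
        assert out["fold_dy1_n_excluded"] == 0
        assert out["fold_dy1_mean"] == pytest.approx(3.0)

    def test_identical_folds_zero_sd(self):
        out = cohort_summary([self._stub(5, 5)] * 3)
        assert out["fold_sy0_sd"] == 0.0

    def test_rmse_histogram_bins(self):
        fits = [self._stub(1, 1, r) for r in (0.01, 0.03, 0.05)]
        out = cohort_summary(fits)
        assert out["n_rmse_le_0.02"] == 1
        assert out["n_rmse_le_0.04"] == 2

    def test_too_few_fits(self):
        with pytest.raises(ValueError):
            cohort_summary([self._stub(1, 1)])


class TestSeriesIO:
    def test_roundtrip(self, tmp_path):
        s1 = PatientSeries("a", (0.0, 30.0, 90.0), (0.8, 0.6, 0.5), 35.0)
        s2 = PatientSeries("b", (0.0, 60.0), (0.7, 0.65), 20.0)
        path = tmp_path / "series.csv"
        write_patient_series([s1, s2], path)
        back = read_patient_series(path)
        assert back == [s1, s2]

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("patient_id,time_days,vaf\na,0,0.5\na,10,0.4\n")
        with pytest.raises(ValueError, match="missing columns"):
            read_patient_series(path)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(times=(10.0, 20.0), vaf=(0.5, 0.4)),  # first time not 0
            dict(times=(0.0, 0.0), vaf=(0.5, 0.4)),  # not increasing
            dict(times=(0.0, 20.0), vaf=(0.5, 1.4)),  # VAF out of range
            dict(times=(0.0,), vaf=(0.5,)),  # too short
        ],
    )
    def test_series_invariants(self, kwargs):
        with pytest.raises(ValueError):
            PatientSeries("bad", dose=35.0, **kwargs)
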