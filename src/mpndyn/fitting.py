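"""Per-patient fitting of ruxolitinib response parameters to JAK2 VAF series.

The observable is the variant allele frequency g(x2, y2) = y2/(x2 + y2)
under the all-homozygous assumption.  For each patient the two response
strengths (rho_sy0, rho_dy1) — the dose-dependent relative increases of
the malignant stem-cell cytokine half-saturation constant and of the
malignant progenitor death rate — are estimated by bounded ordinary
nonlinear least squares against the measured VAF values, starting the
treated simulation from a disease state whose untreated-progression VAF
matches the first measurement.

The modelling surface follows the Model/Results convention:
``TreatmentResponseModel(series).fit()`` returns a
``TreatmentResponseResults`` carrying estimates, fit quality, effective
treated parameters, and (after ``approximate_ci``) sampling-based
approximate 95% confidence intervals and a pointwise VAF band.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq, least_squares

from .model import (
    STATE_SCALES,
    ModelParameters,
    SystemState,
    TreatmentResponse,
    effective_parameters,
    rhs_array,
    rhs_jacobian_array,
    vaf_readout,
)
from .parameters import DEFAULT_PARAMETERS
from .simulation import DAYS_PER_YEAR, DISEASE_ONSET_STATE, IntegrationError

__all__ = [
    "PatientSeries",
    "TreatmentResponseModel",
    "TreatmentResponseResults",
    "baseline_state",
    "predict_vaf",
    "rmse",
    "fit_patient",
    "approximate_ci",
    "cohort_summary",
    "read_patient_series",
    "write_patient_series",
]

#: Maximum untreated progression horizon searched when anchoring, years.
_ANCHOR_HORIZON_YEARS = 100.0

_SERIES_COLUMNS = ["patient_id", "time_days", "vaf", "dose_mg_per_day"]


@dataclass(frozen=True)
class PatientSeries:
    """Observed JAK2 VAF time series of one patient on a constant dose.

    Times are days since the first measurement (the first time is 0 by
    convention); VAF values are decimals in [0, 1]; dose in mg/day.
    """

    patient_id: str
    times: tuple[float, ...]
    vaf: tuple[float, ...]
    dose: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", tuple(float(t) for t in self.times))
        object.__setattr__(self, "vaf", tuple(float(v) for v in self.vaf))
        t = np.asarray(self.times)
        v = np.asarray(self.vaf)
        if len(t) != len(v) or len(t) < 2:
            raise ValueError("need at least 2 paired (time, VAF) observations")
        if t[0] != 0:
            raise ValueError("first observation time must be 0 (days since first measurement)")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any((v < 0) | (v > 1)):
            raise ValueError("VAF values must lie in [0, 1]")
        if self.dose < 0:
            raise ValueError("dose must be >= 0")

    @property
    def m(self) -> int:
        return len(self.times)

    @property
    def times_array(self) -> np.ndarray:
        return np.asarray(self.times)

    @property
    def vaf_array(self) -> np.ndarray:
        return np.asarray(self.vaf)


# ---------------------------------------------------------------------------
# Anchoring and prediction


@lru_cache(maxsize=8)
def _reference_run(params: ModelParameters):
    """Dense untreated reference trajectory from the disease-onset state."""
    horizon = _ANCHOR_HORIZON_YEARS * DAYS_PER_YEAR
    sol = solve_ivp(
        lambda t, y: rhs_array(y, params),
        (0.0, horizon),
        DISEASE_ONSET_STATE.to_array(),
        method="LSODA",
        jac=lambda t, y: rhs_jacobian_array(y, params),
        rtol=1e-10,
        atol=STATE_SCALES * 1e-14,
        dense_output=True,
    )
    if sol.status != 0:
        raise IntegrationError(sol.message, float(sol.t[-1]))

    def vaf_at(t: float) -> float:
        y = sol.sol(t)
        return float(y[5] / (y[2] + y[5]))

    return sol.sol, vaf_at, horizon


def baseline_anchor(
    first_vaf: float, params: ModelParameters = DEFAULT_PARAMETERS
) -> tuple[float, SystemState]:
    """Anchor time (days of untreated progression) and state for a VAF level.

    The untreated model is run from the disease-onset state (calibrated
    healthy equilibrium plus one malignant stem cell); the returned state
    is the first point along that progression whose model VAF equals
    ``first_vaf``.  It serves as the patient-specific state at the first
    measurement, t = 0.
    """
    if not (0.0 < first_vaf < 1.0):
        raise ValueError("first_vaf must lie strictly between 0 and 1")
    dense, vaf_at, horizon = _reference_run(params)
    # VAF rises monotonically from ~0 towards 1 along the untreated run;
    # bracket on a coarse grid, then refine.
    grid = np.linspace(1.0, horizon, 2400)
    values = np.array([vaf_at(t) for t in grid])
    idx = np.nonzero(values >= first_vaf)[0]
    if len(idx) == 0:
        raise ValueError(
            f"untreated progression never reaches VAF {first_vaf:.3f} "
            f"within {_ANCHOR_HORIZON_YEARS:.0f} years"
        )
    hi = grid[idx[0]]
    lo = grid[idx[0] - 1] if idx[0] > 0 else 1e-6
    t_anchor = brentq(lambda t: vaf_at(t) - first_vaf, lo, hi, xtol=1e-6)
    state = SystemState.from_array(np.clip(dense(t_anchor), 0.0, None))
    return float(t_anchor), state


def baseline_state(
    first_vaf: float, params: ModelParameters = DEFAULT_PARAMETERS
) -> SystemState:
    """State at the first measurement; see :func:`baseline_anchor`."""
    return baseline_anchor(first_vaf, params)[1]


#: RHS evaluation budget per prediction solve.  A well-behaved treated
#: simulation needs a few thousand evaluations; runaway step-size
#: grinding at pathological optimizer iterates is cut off instead of
#: stalling the whole fit.
_MAX_RHS_EVALS = 100_000


class _EvalBudgetExceeded(IntegrationError):
    pass


def _predict_curve(
    rho_sy0: float,
    rho_dy1: float,
    dose: float,
    start: SystemState,
    times: np.ndarray,
    params: ModelParameters,
) -> np.ndarray:
    """Treated-model VAF at the requested times (times[0] may be > 0)."""
    treat = TreatmentResponse(rho_sy0=rho_sy0, rho_dy1=rho_dy1, dose=dose)
    p = effective_parameters(params, treat)
    t_end = float(times[-1]) if times[-1] > 0 else 1.0

    def _attempt(method: str):
        neval = 0

        def f(t, y):
            nonlocal neval
            neval += 1
            if neval > _MAX_RHS_EVALS:
                raise _EvalBudgetExceeded("prediction solve exceeded evaluation budget", t)
            return rhs_array(y, p)

        return solve_ivp(
            f,
            (0.0, t_end),
            start.to_array(),
            method=method,
            jac=lambda t, y: rhs_jacobian_array(y, p),
            rtol=1e-8,
            atol=STATE_SCALES * 1e-12,
            dense_output=True,
        )

    # LSODA first; it occasionally refuses benign starts (near-equilibrium
    # initial steps), in which case BDF picks them up.
    sol = None
    err: Exception | None = None
    for method in ("LSODA", "BDF"):
        try:
            cand = _attempt(method)
        except _EvalBudgetExceeded as exc:
            err = exc
            continue
        if cand.status == 0:
            sol = cand
            break
        err = IntegrationError(cand.message, float(cand.t[-1]) if len(cand.t) else 0.0)
    if sol is None:
        raise err if err is not None else IntegrationError("prediction solve failed", 0.0)
    states = sol.sol(np.asarray(times, dtype=float))
    return np.asarray(vaf_readout(states[2], states[5]))


def predict_vaf(
    treat: TreatmentResponse,
    series: PatientSeries,
    params: ModelParameters = DEFAULT_PARAMETERS,
) -> np.ndarray:
    """Model VAF at the series' observation times under a given response."""
    start = baseline_state(series.vaf[0], params)
    return _predict_curve(
        treat.rho_sy0, treat.rho_dy1, series.dose, start, series.times_array, params
    )


def rmse(observed: np.ndarray, predicted: np.ndarray) -> float:
    """Root mean squared error, in VAF units."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape:
        raise ValueError("observed and predicted must have equal length")
    if observed.size == 0:
        raise ValueError("RMSE of an empty series is undefined")
    return float(np.sqrt(np.mean((observed - predicted) ** 2)))


# ---------------------------------------------------------------------------
# Model / Results

_MODES = {"both": ("rho_sy0", "rho_dy1"), "sy0_only": ("rho_sy0",), "dy1_only": ("rho_dy1",)}


class TreatmentResponseModel:
    """Nonlinear least-squares model of one patient's VAF response.

    Parameters
    ----------
    series : PatientSeries
        Observed (time, VAF) pairs and the constant daily dose.
    params : ModelParameters
        Pre-treatment haematopoiesis parameters (population defaults).
    mode : {"both", "sy0_only", "dy1_only"}
        Which response strengths are free; the excluded one is fixed at 0.
    """

    def __init__(
        self,
        series: PatientSeries,
        params: ModelParameters = DEFAULT_PARAMETERS,
        mode: str = "both",
    ):
        if mode not in _MODES:
            raise ValueError(f"mode must be one of {sorted(_MODES)}")
        self.series = series
        self.params = params
        self.mode = mode
        self.free_names = _MODES[mode]
        self._start = baseline_state(series.vaf[0], params)

    # -- prediction ---------------------------------------------------------

    def _unpack(self, theta: np.ndarray) -> tuple[float, float]:
        d = dict(zip(self.free_names, theta))
        return float(d.get("rho_sy0", 0.0)), float(d.get("rho_dy1", 0.0))

    def predict(
        self, theta: np.ndarray, times: np.ndarray | None = None
    ) -> np.ndarray:
        rho_s, rho_d = self._unpack(np.atleast_1d(theta))
        t = self.series.times_array if times is None else np.asarray(times, float)
        return _predict_curve(rho_s, rho_d, self.series.dose, self._start, t, self.params)

    def _residuals(self, theta: np.ndarray) -> np.ndarray:
        return self.predict(theta) - self.series.vaf_array

    # -- fitting ------------------------------------------------------------

    def fit(
        self,
        n_refine: int = 3,
        grid: np.ndarray | None = None,
    ) -> "TreatmentResponseResults":
        """Bounded multi-start nonlinear least squares.

        A coarse grid of initial guesses (zero plus log-spaced values
        over [1e-3, 1e1] per free parameter) is screened by objective
        value; the best ``n_refine`` starts are polished with a bounded
        trust-region least-squares solver and the overall best optimum is
        returned.  A boundary optimum (rho = 0) is a legitimate result.
        """
        if grid is None:
            grid = np.concatenate([[0.0], np.logspace(-3, 1, 5)])
        k = len(self.free_names)
        starts = np.array(np.meshgrid(*([grid] * k))).reshape(k, -1).T

        screened: list[tuple[float, np.ndarray]] = []
        for theta in starts:
            try:
                sse = float(np.sum(self._residuals(theta) ** 2))
            except IntegrationError:
                continue
            screened.append((sse, theta))
        if not screened:
            raise RuntimeError("all starting points failed to evaluate")
        screened.sort(key=lambda t: t[0])

        best = None
        for sse0, theta0 in screened[:n_refine]:
            try:
                res = least_squares(
                    self._residuals,
                    theta0,
                    bounds=(np.zeros(k), np.full(k, np.inf)),
                    method="trf",
                    ftol=1e-12,
                    xtol=1e-12,
                    gtol=1e-12,
                    diff_step=1e-5,
                    max_nfev=120,
                )
            except IntegrationError:
                continue
            if best is None or res.cost < best.cost:
                best = res
        if best is None:
            raise RuntimeError("no least-squares refinement converged")

        theta_hat = best.x
        # snap numerically-vanishing components onto the boundary when that
        # does not worsen the objective (a dose*rho below ~1e-4 is far below
        # any resolvable effect size)
        near_zero = theta_hat < 1e-6
        if np.any(near_zero) and np.any(theta_hat != 0):
            snapped = np.where(near_zero, 0.0, theta_hat)
            sse_best = 2.0 * best.cost
            try:
                sse_snapped = float(np.sum(self._residuals(snapped) ** 2))
            except IntegrationError:
                sse_snapped = np.inf
            # solver-level noise (rtol 1e-8) separates the two evaluations
            if sse_snapped <= sse_best * (1.0 + 1e-6) + 1e-12:
                theta_hat = snapped
        fitted = self.predict(theta_hat)
        rho_s, rho_d = self._unpack(theta_hat)
        return TreatmentResponseResults(
            model=self,
            rho_sy0=rho_s,
            rho_dy1=rho_d,
            fittedvalues=fitted,
            sse=float(np.sum((fitted - self.series.vaf_array) ** 2)),
        )


@dataclass
class TreatmentResponseResults:
    """Estimates and diagnostics of a per-patient response fit."""

    model: TreatmentResponseModel
    rho_sy0: float
    rho_dy1: float
    fittedvalues: np.ndarray
    sse: float
    # populated by approximate_ci:
    rho_sy0_ci: tuple[float, float] | None = None
    rho_dy1_ci: tuple[float, float] | None = None
    cov: np.ndarray | None = None
    sigma2: float | None = None
    unbounded_ci: bool = False
    band_times: np.ndarray | None = field(default=None, repr=False)
    band_lower: np.ndarray | None = field(default=None, repr=False)
    band_upper: np.ndarray | None = field(default=None, repr=False)
    band_mean_width: float | None = None

    @property
    def mode(self) -> str:
        return self.model.mode

    @property
    def series(self) -> PatientSeries:
        return self.model.series

    @property
    def rmse(self) -> float:
        return rmse(self.series.vaf_array, self.fittedvalues)

    @property
    def s_y0_effective(self) -> float:
        return (1.0 + self.series.dose * self.rho_sy0) * self.model.params.s_y0

    @property
    def d_y1_effective(self) -> float:
        return (1.0 + self.series.dose * self.rho_dy1) * self.model.params.d_y1

    @property
    def fold_sy0(self) -> float:
        return 1.0 + self.series.dose * self.rho_sy0

    @property
    def fold_dy1(self) -> float:
        return 1.0 + self.series.dose * self.rho_dy1

    def conf_int(
        self, n_samples: int = 1000, seed: int | None = 0
    ) -> "TreatmentResponseResults":
        """Attach sampling-based approximate 95% CIs; see :func:`approximate_ci`."""
        return approximate_ci(self, n_samples=n_samples, seed=seed)

    def plot(self, ax=None):
        """Observed VAF, fitted curve and (if computed) the 95% band.

        Returns the matplotlib axes; time in years, VAF in percent.
        """
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        s = self.series
        t_dense = np.linspace(0.0, s.times[-1], 120)
        curve = self.model.predict(
            np.array([getattr(self, n) for n in self.model.free_names]), t_dense
        )
        years = t_dense / DAYS_PER_YEAR
        if self.band_times is not None:
            ax.fill_between(
                self.band_times / DAYS_PER_YEAR,
                100 * self.band_lower,
                100 * self.band_upper,
                alpha=0.25,
                color="tab:orange",
                label="approx. 95% band",
            )
        ax.plot(years, 100 * curve, color="tab:orange", label="model fit")
        ax.plot(s.times_array / DAYS_PER_YEAR, 100 * s.vaf_array, "o", color="tab:red", label="data")
        ax.set_xlabel("time since first measurement (years)")
        ax.set_ylabel("JAK2 VAF (%)")
        ax.set_ylim(0, 100)
        ax.legend(loc="best", frameon=False)
        return ax

    def summary(self) -> str:
        s = self.series
        buf = io.StringIO()
        w = buf.write
        w("Ruxolitinib response fit (ordinary NLS on JAK2 VAF)\n")
        w("=" * 55 + "\n")
        w(f"patient: {s.patient_id}    dose: {s.dose:g} mg/day    mode: {self.mode}\n")
        w(f"observations: {s.m}    window: {s.times[-1] / DAYS_PER_YEAR:.2f} years\n")
        w("-" * 55 + "\n")
        for name, val, ci in (
            ("rho_sy0 /(mg/day)^-1", self.rho_sy0, self.rho_sy0_ci),
            ("rho_dy1 /(mg/day)^-1", self.rho_dy1, self.rho_dy1_ci),
        ):
            line = f"{name:22s} {val:10.4g}"
            if ci is not None:
                line += f"   95% CI ({ci[0]:.3g}, {ci[1]:.3g})"
            w(line + "\n")
        w(f"{'s_y0 effective':22s} {self.s_y0_effective:10.4g}   fold {self.fold_sy0:.3g}\n")
        w(f"{'d_y1 effective /day^-1':22s} {self.d_y1_effective:10.4g}   fold {self.fold_dy1:.3g}\n")
        w("-" * 55 + "\n")
        w(f"RMSE: {self.rmse:.4g} VAF units\n")
        if self.band_mean_width is not None:
            w(f"mean 95% band width: {self.band_mean_width:.4g} VAF units\n")
        if self.unbounded_ci:
            w("warning: near-singular information matrix; CIs are effectively unbounded\n")
        return buf.getvalue()


def fit_patient(
    series: PatientSeries,
    params: ModelParameters = DEFAULT_PARAMETERS,
    mode: str = "both",
) -> TreatmentResponseResults:
    """Convenience wrapper: build a :class:`TreatmentResponseModel` and fit."""
    return TreatmentResponseModel(series, params, mode).fit()


# ---------------------------------------------------------------------------
# Approximate confidence intervals


def _fd_jacobian(model: TreatmentResponseModel, theta: np.ndarray) -> np.ndarray:
    """Residual Jacobian at the optimum; forward step at the 0 boundary."""
    m = model.series.m
    k = len(theta)
    J = np.empty((m, k))
    r0 = model._residuals(theta)
    for j in range(k):
        h = max(1e-6 * abs(theta[j]), 1e-7)
        tp = theta.copy()
        tp[j] += h
        if theta[j] - h >= 0:
            tm = theta.copy()
            tm[j] -= h
            J[:, j] = (model._residuals(tp) - model._residuals(tm)) / (2 * h)
        else:
            J[:, j] = (model._residuals(tp) - r0) / h
    return J


def approximate_ci(
    fit: TreatmentResponseResults,
    n_samples: int = 1000,
    seed: int | None = 0,
    n_band_points: int = 40,
    compute_band: bool = True,
) -> TreatmentResponseResults:
    """Sampling-based approximate 95% CIs and pointwise VAF band.

    The parameter covariance is the linearised least-squares
    approximation sigma^2 (J^T J)^-1 with sigma^2 = SSE/(m - p) and J
    the finite-difference residual Jacobian at the optimum.  ``n_samples``
    parameter pairs are drawn from the corresponding normal; draws with
    a negative component are resampled (the response strengths are
    non-negative by assumption).  Parameter CIs are the 2.5/97.5
    percentiles of the accepted draws; the band is the pointwise middle
    95% of the simulated VAF trajectories over the observation window.
    """
    model = fit.model
    m, p = model.series.m, len(model.free_names)
    if m <= p:
        raise ValueError("no residual degrees of freedom: m <= number of fitted parameters")
    theta_hat = np.array(
        [getattr(fit, name) for name in model.free_names], dtype=float
    )
    J = _fd_jacobian(model, theta_hat)
    sigma2 = fit.sse / (m - p)
    JTJ = J.T @ J
    unbounded = bool(np.linalg.cond(JTJ) > 1e12)
    cov = sigma2 * np.linalg.pinv(JTJ)
    # guard: pinv of a singular JTJ can understate the flat direction
    if unbounded:
        cov = cov + np.eye(p) * sigma2 / max(np.min(np.diag(JTJ)), 1e-300)

    rng = np.random.default_rng(seed)
    samples = np.empty((n_samples, p))
    filled = 0
    for _ in range(10_000):
        need = n_samples - filled
        if need <= 0:
            break
        draw = rng.multivariate_normal(theta_hat, cov, size=need, method="svd")
        ok = draw[np.all(draw >= 0, axis=1)]
        samples[filled : filled + len(ok)] = ok
        filled += len(ok)
    if filled < n_samples:
        raise RuntimeError("resampling failed to produce enough non-negative draws")

    lo, hi = np.percentile(samples, [2.5, 97.5], axis=0)
    lo = np.maximum(lo, 0.0)

    if compute_band:
        t_band = np.linspace(0.0, model.series.times[-1], n_band_points)
        curves = np.empty((n_samples, n_band_points))
        for i, theta in enumerate(samples):
            try:
                curves[i] = model.predict(theta, t_band)
            except IntegrationError:
                curves[i] = np.nan
        band_lo, band_hi = np.nanpercentile(curves, [2.5, 97.5], axis=0)

    ci = dict(zip(model.free_names, zip(lo, hi)))
    fit.rho_sy0_ci = tuple(map(float, ci.get("rho_sy0", (0.0, 0.0))))
    fit.rho_dy1_ci = tuple(map(float, ci.get("rho_dy1", (0.0, 0.0))))
    fit.cov = cov
    fit.sigma2 = float(sigma2)
    fit.unbounded_ci = unbounded
    if compute_band:
        fit.band_times = t_band
        fit.band_lower = band_lo
        fit.band_upper = band_hi
        fit.band_mean_width = float(np.mean(band_hi - band_lo))
    return fit


# ---------------------------------------------------------------------------
# Cohort summaries and file formats


def cohort_summary(
    fits: list[TreatmentResponseResults], outlier_fold_threshold: float = 100.0
) -> dict:
    """Cohort-level fold-change statistics and RMSE histogram counts.

    Fold changes exceeding ``outlier_fold_threshold`` are excluded from
    the mean/sd of the corresponding parameter (patients whose fitted
    s_y0 fold is astronomically large sit on a flat direction of the
    objective: beyond a point the Michaelis-Menten term is insensitive
    to s_y0, so the magnitude of such folds is not meaningful).
    """
    if len(fits) < 2:
        raise ValueError("cohort summary needs at least 2 fits")
    folds_s = np.array([f.fold_sy0 for f in fits])
    folds_d = np.array([f.fold_dy1 for f in fits])
    rmses = np.array([f.rmse for f in fits])
    keep_s = folds_s <= outlier_fold_threshold
    keep_d = folds_d <= outlier_fold_threshold
    if not np.any(keep_s) or not np.any(keep_d):
        raise ValueError("all fits excluded as outliers")
    return {
        "n": len(fits),
        "fold_sy0_mean": float(np.mean(folds_s[keep_s])),
        "fold_sy0_sd": float(np.std(folds_s[keep_s], ddof=1)) if keep_s.sum() > 1 else 0.0,
        "fold_sy0_n_excluded": int((~keep_s).sum()),
        "fold_dy1_mean": float(np.mean(folds_d[keep_d])),
        "fold_dy1_sd": float(np.std(folds_d[keep_d], ddof=1)) if keep_d.sum() > 1 else 0.0,
        "fold_dy1_n_excluded": int((~keep_d).sum()),
        "rmse_mean": float(np.mean(rmses)),
        "n_rmse_le_0.02": int(np.sum(rmses <= 0.02)),
        "n_rmse_le_0.04": int(np.sum(rmses <= 0.04)),
    }


def read_patient_series(path: str | Path | io.IOBase) -> list[PatientSeries]:
    """Read patient series from delimited text.

    Expected header: ``patient_id,time_days,vaf,dose_mg_per_day``.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(_SERIES_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"patient series file missing columns: {sorted(missing)}")
    out = []
    for pid, grp in df.groupby("patient_id", sort=False):
        grp = grp.sort_values("time_days")
        doses = grp["dose_mg_per_day"].unique()
        if len(doses) != 1:
            raise ValueError(f"patient {pid}: dose must be constant")
        out.append(
            PatientSeries(
                patient_id=str(pid),
                times=tuple(grp["time_days"]),
                vaf=tuple(grp["vaf"]),
                dose=float(doses[0]),
            )
        )
    return out


def write_patient_series(series: list[PatientSeries], path: str | Path) -> None:
    """Write patient series as delimited text (see :func:`read_patient_series`)."""
    rows = [
        {
            "patient_id": s.patient_id,
            "time_days": t,
            "vaf": v,
            "dose_mg_per_day": s.dose,
        }
        for s in series
        for t, v in zip(s.times, s.vaf)
    ]
    # %.17g: lossless float round-trip through the text format
    pd.DataFrame(rows, columns=_SERIES_COLUMNS).to_csv(path, index=False, float_format="%.17g")
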