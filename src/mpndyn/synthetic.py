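"""In-silico patient cohorts with the statistical structure of RUX trial VAF data.

Emulates the shape of the JAK2 VAF series available from the two source
trials: sparse follow-up (3-8 measurements over roughly half a year to
four years), a high baseline allele burden (cohort average around 0.76),
a constant daily dose (35 mg/day for a myelofibrosis-trial-like cohort,
20 mg/day for a polycythaemia-vera-trial-like cohort), and additive
homoscedastic Gaussian measurement noise of the order reported for qPCR
VAF assays.  Each generated patient carries known ground-truth response
strengths, so the whole fitting pipeline can be exercised and parameter
recovery quantified without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .fitting import PatientSeries, baseline_state, _predict_curve
from .parameters import DEFAULT_PARAMETERS, ModelParameters
from .simulation import DAYS_PER_YEAR

__all__ = ["CohortSpec", "generate_patient", "generate_cohort", "write_cohort", "read_truth"]

#: Minimum spacing between successive visits, days (trial visits are
#: scheduled weeks apart).
MIN_VISIT_GAP_DAYS = 28.0

_TRUTH_COLUMNS = ["patient_id", "rho_sy0", "rho_dy1", "baseline_vaf", "dose_mg_per_day", "noise_sd"]


@dataclass(frozen=True)
class CohortSpec:
    """Distributional description of a synthetic cohort.

    Defaults mirror the source-trial conditions: baseline VAF centred on
    0.76 and truncated to (0.3, 0.98); 3-8 visits over 0.5-4 years; a
    point mass of ruxolitinib non-stem-responders (rho_sy0 = 0) of about
    a fifth of the cohort; response-strength supports spanning the
    non-outlier fitted ranges, rho_sy0 in [0, 5] and rho_dy1 in
    [0.01, 1.1] (mg/day)^-1; measurement noise sd 0.02 VAF units,
    between the two reported qPCR assay standard deviations.
    """

    n_patients: int = 24
    dose: float = 35.0
    baseline_vaf_mean: float = 0.76
    baseline_vaf_sd: float = 0.10
    baseline_vaf_bounds: tuple[float, float] = (0.3, 0.98)
    points_min: int = 3
    points_max: int = 8
    window_years_min: float = 0.5
    window_years_max: float = 4.0
    p_zero_rho_sy0: float = 5.0 / 24.0
    rho_sy0_range: tuple[float, float] = (0.05, 5.0)
    rho_dy1_range: tuple[float, float] = (0.01, 1.1)
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        lo, hi = self.baseline_vaf_bounds
        if not (0 < lo < hi < 1):
            raise ValueError("baseline VAF bounds must satisfy 0 < lo < hi < 1")
        if not (2 <= self.points_min <= self.points_max):
            raise ValueError("need points_max >= points_min >= 2")
        if not (0 <= self.p_zero_rho_sy0 <= 1):
            raise ValueError("p_zero_rho_sy0 must be a probability")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _draw_times(spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    """Visit times: first at 0, the rest uniform over the window, min gap."""
    window = rng.uniform(spec.window_years_min, spec.window_years_max) * DAYS_PER_YEAR
    n = int(rng.integers(spec.points_min, spec.points_max + 1))
    # a window too short for n visits at the minimum gap caps the count
    n = min(n, int(window // MIN_VISIT_GAP_DAYS) + 1)
    n = max(n, 2)
    for _ in range(200):
        rest = np.sort(rng.uniform(MIN_VISIT_GAP_DAYS, window, size=n - 1))
        times = np.concatenate([[0.0], rest])
        if np.all(np.diff(times) >= MIN_VISIT_GAP_DAYS):
            return times
    # rejection failed (crowded window): fall back to even spacing
    return np.linspace(0.0, window, n)


def _truncated_normal(
    mean: float, sd: float, bounds: tuple[float, float], rng: np.random.Generator
) -> float:
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if bounds[0] < x < bounds[1]:
            return float(x)
    raise RuntimeError("truncated normal rejection sampling failed")


def generate_patient(
    spec: CohortSpec,
    params: ModelParameters = DEFAULT_PARAMETERS,
    rng: np.random.Generator | None = None,
    patient_id: str = "synthetic-1",
) -> tuple[PatientSeries, dict]:
    """One synthetic patient: noisy series plus its ground truth.

    Draws response strengths and a baseline VAF, anchors the treated
    simulation at the untreated-progression state matching that baseline,
    samples the model VAF at the drawn visit times, and adds independent
    Gaussian noise clipped to [0, 1].  The returned truth dict records
    the drawn parameters (and the noiseless VAF values) for recovery
    testing.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    if rng.uniform() < spec.p_zero_rho_sy0:
        rho_sy0 = 0.0
    else:
        lo, hi = spec.rho_sy0_range
        rho_sy0 = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    lo, hi = spec.rho_dy1_range
    rho_dy1 = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    baseline_vaf = _truncated_normal(
        spec.baseline_vaf_mean, spec.baseline_vaf_sd, spec.baseline_vaf_bounds, rng
    )
    times = _draw_times(spec, rng)

    start = baseline_state(baseline_vaf, params)
    clean = _predict_curve(rho_sy0, rho_dy1, spec.dose, start, times, params)
    noisy = np.clip(clean + rng.normal(0.0, spec.noise_sd, size=len(times)), 0.0, 1.0)

    series = PatientSeries(
        patient_id=patient_id, times=tuple(times), vaf=tuple(noisy), dose=spec.dose
    )
    truth = {
        "patient_id": patient_id,
        "rho_sy0": rho_sy0,
        "rho_dy1": rho_dy1,
        "baseline_vaf": baseline_vaf,
        "dose_mg_per_day": spec.dose,
        "noise_sd": spec.noise_sd,
        "clean_vaf": tuple(float(v) for v in clean),
    }
    return series, truth


def generate_cohort(
    spec: CohortSpec,
    params: ModelParameters = DEFAULT_PARAMETERS,
) -> tuple[list[PatientSeries], pd.DataFrame]:
    """A cohort of independent synthetic patients plus its truth table.

    The spec's seed fixes the cohort exactly: the same spec always
    produces the same patients.
    """
    rng = np.random.default_rng(spec.seed)
    series: list[PatientSeries] = []
    truths: list[dict] = []
    for i in range(spec.n_patients):
        s, t = generate_patient(spec, params, rng, patient_id=f"synthetic-{i + 1}")
        series.append(s)
        truths.append(t)
    truth = pd.DataFrame(truths).drop(columns=["clean_vaf"])
    truth["clean_vaf"] = [t["clean_vaf"] for t in truths]
    return series, truth


def write_cohort(
    series: list[PatientSeries],
    truth: pd.DataFrame,
    series_path: str | Path,
    truth_path: str | Path,
) -> None:
    """Write the cohort in the fitting input format plus a truth table."""
    from .fitting import write_patient_series

    write_patient_series(series, series_path)
    truth[_TRUTH_COLUMNS].to_csv(truth_path, index=False, float_format="%.17g")


def read_truth(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(_TRUTH_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"truth table missing columns: {sorted(missing)}")
    return df
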