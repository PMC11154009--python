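"""Trajectory integration, treatment scenarios, return times, basins, sensitivity.

The system is stiff: the debris/cytokine turnover is orders of magnitude
faster than the cell kinetics, and the state components span roughly 12
decades.  Integration therefore uses a stiff-capable solver with tight
relative tolerance and component-wise absolute tolerances scaled to the
characteristic compartment magnitudes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .model import (
    STATE_NAMES,
    STATE_SCALES,
    ModelParameters,
    SystemState,
    TreatmentResponse,
    effective_parameters,
    rhs_array,
    rhs_jacobian_array,
)
from .steady_state import reduced_lineage_steady_states, reduced_rhs_array

__all__ = [
    "Trajectory",
    "ScenarioSpec",
    "IntegrationError",
    "simulate",
    "run_scenario",
    "time_to_return",
    "basin_threshold",
    "local_sensitivity",
    "DISEASE_ONSET_STATE",
    "DAYS_PER_YEAR",
]

DAYS_PER_YEAR = 365.0

#: Calibrated healthy state seeded with a single malignant stem cell —
#: the canonical disease-onset initial condition for scenario runs.
DISEASE_ONSET_STATE = SystemState(
    x0=1.0e5, x1=2.5e6, x2=6.4e11, y0=1.0, y1=0.0, y2=0.0, a=8.1e2, s=1.0
)

_RTOL = 1e-8
_ATOL = STATE_SCALES * 1e-12


class IntegrationError(RuntimeError):
    """Raised when the ODE solver fails; carries the last valid time."""

    def __init__(self, message: str, last_time: float):
        super().__init__(f"{message} (last valid time: {last_time:.3f} days)")
        self.last_time = last_time


@dataclass
class Trajectory:
    """A simulated trajectory: times in days, one 8-component state per time."""

    times: np.ndarray
    states: np.ndarray  # shape (n, 8)
    treatment_start: float | None = None
    dense: object = field(default=None, repr=False)  # scipy OdeSolution, optional

    @property
    def vaf(self) -> np.ndarray:
        """JAK2 VAF series y2/(x2+y2); NaN where no mature cells exist."""
        total = self.states[:, 2] + self.states[:, 5]
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(total > 0, self.states[:, 5] / total, np.nan)

    def series(self, quantity: str) -> np.ndarray:
        if quantity == "VAF":
            return self.vaf
        if quantity == "mMBC":
            return self.states[:, 5]
        if quantity in STATE_NAMES:
            return self.states[:, STATE_NAMES.index(quantity)]
        raise ValueError(f"unknown quantity {quantity!r}")

    def value_at(self, t: float, quantity: str) -> float:
        return float(np.interp(t, self.times, self.series(quantity)))

    @property
    def final_state(self) -> SystemState:
        return SystemState.from_array(np.clip(self.states[-1], 0.0, None))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=[f"{n}_count" if n not in ("a", "s") else n for n in STATE_NAMES])
        df.columns = list(STATE_NAMES)
        df.insert(0, "time_days", self.times)
        df["vaf"] = self.vaf
        return df

    def plot(self, axes=None):
        """Cell counts (log scale) and VAF against time in years.

        Returns the matplotlib figure; a vertical line marks the
        treatment start when set.
        """
        import matplotlib.pyplot as plt

        if axes is None:
            fig, axes = plt.subplots(2, 1, sharex=True, figsize=(7, 6))
        else:
            fig = axes[0].figure
        years = self.times / DAYS_PER_YEAR
        healthy = self.states[:, 0:3].sum(axis=1)
        malignant = self.states[:, 3:6].sum(axis=1)
        axes[0].semilogy(years, np.clip(healthy, 1e-2, None), color="tab:green", label="healthy cells")
        axes[0].semilogy(years, np.clip(malignant, 1e-2, None), color="tab:red", label="malignant cells")
        axes[0].set_ylabel("cells")
        axes[0].legend(loc="best", frameon=False)
        axes[1].plot(years, 100 * self.vaf, color="tab:red")
        axes[1].set_ylabel("JAK2 VAF (%)")
        axes[1].set_xlabel("time (years)")
        axes[1].set_ylim(0, 100)
        if self.treatment_start is not None:
            for ax in axes:
                ax.axvline(self.treatment_start / DAYS_PER_YEAR, color="k", ls="--", lw=0.8)
        return fig


@dataclass(frozen=True)
class ScenarioSpec:
    """A treatment scenario: untreated progression, then folded parameters.

    The scenario letter selects which malignant parameters the drug
    touches at treatment start — a: neither (no response), b: the
    stem-cell cytokine half-saturation s_y0 only, c: the progenitor
    death rate d_y1 only, d: both.
    """

    scenario: str = "d"
    pre_treatment_years: float = 30.0
    post_treatment_years: float = 30.0
    fold_sy0: float = 6.0
    fold_dy1: float = 6.0

    def __post_init__(self) -> None:
        if self.scenario not in "abcd":
            raise ValueError("scenario must be one of 'a', 'b', 'c', 'd'")
        if self.fold_sy0 < 1 or self.fold_dy1 < 1:
            raise ValueError("fold factors must be >= 1")

    @property
    def active_folds(self) -> tuple[float, float]:
        """(fold on s_y0, fold on d_y1) actually applied."""
        return (
            self.fold_sy0 if self.scenario in "bd" else 1.0,
            self.fold_dy1 if self.scenario in "cd" else 1.0,
        )


def _integrate(
    y0: np.ndarray,
    params: ModelParameters,
    t_span: tuple[float, float],
    t_eval: np.ndarray | None,
    rtol: float,
    dense_output: bool = False,
    events=None,
) -> object:
    sol = solve_ivp(
        lambda t, y: rhs_array(y, params),
        t_span,
        y0,
        method="LSODA",
        jac=lambda t, y: rhs_jacobian_array(y, params),
        t_eval=t_eval,
        rtol=rtol,
        atol=_ATOL * (rtol / _RTOL),
        dense_output=dense_output,
        events=events,
    )
    if sol.status == -1:
        raise IntegrationError(sol.message, float(sol.t[-1]) if len(sol.t) else t_span[0])
    return sol


def simulate(
    initial: SystemState | np.ndarray,
    params: ModelParameters,
    horizon: float,
    treat: TreatmentResponse | None = None,
    sampling_days: float = 7.0,
    rtol: float = _RTOL,
    t_offset: float = 0.0,
) -> Trajectory:
    """Integrate the model for ``horizon`` days.

    With ``treat`` given, the drug's effective parameters are in force
    for the whole run.  Output is sampled at least weekly so that event
    detection downstream (return times, anchoring) can interpolate
    safely.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    y0 = initial.to_array() if isinstance(initial, SystemState) else np.asarray(initial, float)
    if np.any(y0 < 0):
        raise ValueError("initial state must be non-negative")
    p = effective_parameters(params, treat) if treat is not None else params
    t_eval = np.arange(0.0, horizon, sampling_days)
    if t_eval[-1] < horizon:
        t_eval = np.append(t_eval, horizon)
    sol = _integrate(y0, p, (0.0, horizon), t_eval, rtol, dense_output=True)
    states = np.clip(sol.y.T, 0.0, None)  # solver jitter below 0 is noise
    return Trajectory(times=sol.t + t_offset, states=states, dense=sol.sol)


def run_scenario(
    spec: ScenarioSpec,
    params: ModelParameters,
    initial: SystemState = DISEASE_ONSET_STATE,
    rtol: float = _RTOL,
) -> Trajectory:
    """Untreated progression followed by treatment with folded parameters.

    Returns the stitched trajectory with ``treatment_start`` marking the
    switch time (days).
    """
    pre_days = spec.pre_treatment_years * DAYS_PER_YEAR
    post_days = spec.post_treatment_years * DAYS_PER_YEAR
    pre = simulate(initial, params, pre_days, rtol=rtol)
    fold_s, fold_d = spec.active_folds
    treated_params = params.replace(
        s_y0=params.s_y0 * fold_s, d_y1=params.d_y1 * fold_d
    )
    post = simulate(pre.final_state, treated_params, post_days, rtol=rtol, t_offset=pre_days)
    times = np.concatenate([pre.times, post.times[1:]])
    states = np.vstack([pre.states, post.states[1:]])
    return Trajectory(times=times, states=states, treatment_start=pre_days)


def time_to_return(
    traj: Trajectory, quantity: str, reference_time: float | None = None
) -> float | None:
    """Days until a quantity first returns to its pre-treatment level.

    Only counts a downward crossing after an excursion strictly above the
    reference level; a monotone decline has no excursion and returns
    ``None``, as does a run whose excursion never comes back within the
    horizon.
    """
    if reference_time is None:
        reference_time = traj.treatment_start
    if reference_time is None:
        raise ValueError("reference_time required for a trajectory without treatment_start")
    values = traj.series(quantity)
    if np.any(np.isnan(values)):
        raise ValueError(f"{quantity} undefined along part of the trajectory")
    ref = float(np.interp(reference_time, traj.times, values))
    mask = traj.times >= reference_time
    t, v = traj.times[mask], values[mask]
    excursion = False
    for i in range(1, len(t)):
        if v[i] > ref:
            excursion = True
        elif excursion and v[i] <= ref:
            # linear interpolation of the downward crossing
            frac = (v[i - 1] - ref) / (v[i - 1] - v[i])
            return float(t[i - 1] + frac * (t[i] - t[i - 1]) - reference_time)
    return None


def _attractor_is_trivial(
    f: float,
    cells_ss: np.ndarray,
    a_ss: float,
    s_ss: float,
    params: ModelParameters,
    lineage: str,
    horizon_years: float,
    rtol: float,
) -> bool:
    y0 = np.concatenate([f * cells_ss, [a_ss, s_ss]])
    cell_scales = STATE_SCALES[:3] if lineage == "healthy" else STATE_SCALES[3:6]
    # BDF: LSODA rejects starts at (or very near) the equilibrium itself
    idx = [0, 1, 2, 6, 7] if lineage == "healthy" else [3, 4, 5, 6, 7]

    def jac5(t, y):
        full = np.zeros(8)
        full[idx] = y
        return rhs_jacobian_array(full, params)[np.ix_(idx, idx)]

    sol = solve_ivp(
        lambda t, y: reduced_rhs_array(y, params, lineage),
        (0.0, horizon_years * DAYS_PER_YEAR),
        y0,
        method="BDF",
        jac=jac5,
        rtol=rtol,
        atol=np.concatenate([cell_scales, STATE_SCALES[6:8]]) * 1e-12,
    )
    if sol.status == -1:
        raise IntegrationError(sol.message, float(sol.t[-1]))
    total_cells = float(np.sum(np.clip(sol.y[:3, -1], 0.0, None)))
    return total_cells < 1.0


def basin_threshold(
    which: str,
    params: ModelParameters,
    horizon_years: float = 200.0,
    rel_width: float = 1e-3,
    rtol: float = _RTOL,
) -> float:
    """Critical start fraction below which a lineage collapses, in percent.

    The three cell compartments of the given lineage are initialised at a
    fraction f of their locally stable single-lineage steady state (the
    other lineage absent; debris and cytokine at their steady values) and
    the reduced system is integrated over a long horizon.  Trajectories
    ending with fewer than one cell in total are classified as having
    reached the cell-free equilibrium; bisection on f localises the
    boundary to the requested relative width.
    """
    stable = [
        r
        for r in reduced_lineage_steady_states(params, which)
        if r.label == which and r.stability == "locally stable"
    ]
    if not stable:
        raise ValueError(f"no locally stable {which} steady state exists")
    arr = stable[0].state.to_array()
    cells = arr[0:3] if which == "healthy" else arr[3:6]
    a_ss, s_ss = arr[6], arr[7]

    def trivial(f: float) -> bool:
        return _attractor_is_trivial(f, cells, a_ss, s_ss, params, which, horizon_years, rtol)

    lo, hi = 1e-6, 1.0
    if not trivial(lo) or trivial(hi):
        raise RuntimeError("bisection bracket failure: both endpoints classify identically")
    while (hi - lo) / hi > rel_width:
        mid = np.sqrt(lo * hi)
        if trivial(mid):
            lo = mid
        else:
            hi = mid
    return float(np.sqrt(lo * hi) * 100.0)


def local_sensitivity(
    params: ModelParameters,
    output: str = "vaf_year30",
    rel_step: float = 0.01,
) -> list[tuple[str, float]]:
    """One-at-a-time normalised parameter sensitivities, ranked descending.

    Each parameter is perturbed by ``±rel_step`` relative; the reported
    sensitivity is the central-difference elasticity
    |d log(output) / d log(parameter)|.  Outputs: ``vaf_year30`` (VAF
    after 30 untreated years from the disease-onset state) or
    ``malignant_steady_state`` (mature-cell count of the stable
    malignant equilibrium).  A perturbed run that fails is reported with
    a NaN sensitivity rather than dropped.
    """
    if not (0 < rel_step <= 0.1):
        raise ValueError("rel_step must be in (0, 0.1]")

    def evaluate(p: ModelParameters) -> float:
        if output == "vaf_year30":
            traj = simulate(DISEASE_ONSET_STATE, p, 30 * DAYS_PER_YEAR, sampling_days=30.0)
            return float(traj.vaf[-1])
        if output == "malignant_steady_state":
            stable = [
                r
                for r in reduced_lineage_steady_states(p, "malignant")
                if r.label == "malignant" and r.stability == "locally stable"
            ]
            if not stable:
                raise RuntimeError("no stable malignant state under perturbation")
            return float(stable[0].state.y2)
        raise ValueError(f"unknown output {output!r}")

    base = evaluate(params)
    results: list[tuple[str, float]] = []
    for name in params.to_dict():
        value = getattr(params, name)
        try:
            up = evaluate(params.replace(**{name: value * (1 + rel_step)}))
            dn = evaluate(params.replace(**{name: value * (1 - rel_step)}))
            sens = abs((up - dn) / (2 * rel_step * base))
        except Exception:
            sens = float("nan")
        results.append((name, sens))
    results.sort(key=lambda kv: (np.isnan(kv[1]), -kv[1]))
    return results
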