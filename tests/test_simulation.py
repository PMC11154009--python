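"""Trajectories, treatment scenarios, return-time detection, basins, sensitivity."""

import numpy as np
import pytest

from mpndyn import (
    DAYS_PER_YEAR,
    DEFAULT_PARAMETERS,
    DISEASE_ONSET_STATE,
    ScenarioSpec,
    TreatmentResponse,
    Trajectory,
    run_scenario,
    simulate,
    time_to_return,
)
from mpndyn.simulation import _attractor_is_trivial
from mpndyn.steady_state import reduced_lineage_steady_states

P = DEFAULT_PARAMETERS


def test_untreated_progression_reaches_half_vaf(untreated_30y):
    """One mutant stem cell takes about three decades to reach VAF 50%."""
    assert untreated_30y.vaf[-1] == pytest.approx(0.50, abs=0.05)
    assert np.all(np.diff(untreated_30y.vaf) >= -1e-12)


def test_zero_response_treatment_identical_to_untreated(untreated_30y):
    treated = simulate(
        DISEASE_ONSET_STATE,
        P,
        30 * DAYS_PER_YEAR,
        treat=TreatmentResponse(0.0, 0.0, dose=35.0),
    )
    np.testing.assert_array_equal(treated.states, untreated_30y.states)


def test_scenario_a_bit_identical_to_plain_continuation(untreated_30y):
    spec = ScenarioSpec(scenario="a", post_treatment_years=5.0)
    scen = run_scenario(spec, P)
    pre = scen.times <= scen.treatment_start
    np.testing.assert_array_equal(scen.states[pre], untreated_30y.states)


class TestReturnTime:
    def _bump(self):
        """Hand-built excursion: rises above 1.0 then decays through it."""
        t = np.linspace(0.0, 100.0, 201)
        v = 1.0 + np.sin(np.pi * t / 50.0)  # above 1 on (0,50), below on (50,100)
        states = np.zeros((len(t), 8))
        states[:, 5] = v
        states[:, 2] = 1.0  # keeps VAF defined
        return Trajectory(times=t, states=states, treatment_start=0.0)

    def test_interpolated_crossing(self):
        traj = self._bump()
        assert time_to_return(traj, "mMBC") == pytest.approx(50.0, abs=0.5)

    def test_monotone_decline_has_no_return(self):
        t = np.linspace(0.0, 100.0, 101)
        states = np.zeros((len(t), 8))
        states[:, 5] = np.exp(-t / 30.0)
        states[:, 2] = 1.0
        traj = Trajectory(times=t, states=states, treatment_start=0.0)
        assert time_to_return(traj, "mMBC") is None

    def test_reference_time_required(self):
        traj = self._bump()
        traj.treatment_start = None
        with pytest.raises(ValueError):
            time_to_return(traj, "mMBC")


class TestScenarios:
    def test_scenario_b_excursion_then_cure(self, scenario_b):
        """Raising s_y0 alone: malignant load overshoots, then long decline."""
        after = scenario_b.times >= scenario_b.treatment_start
        vaf = scenario_b.vaf[after]
        ref = vaf[0]
        assert np.max(vaf) > ref  # initial worsening
        assert vaf[-1] < 0.2 * ref  # deep decline (full cure takes decades)
        mhsc = scenario_b.series("y0")[after]
        assert mhsc[-1] < 0.05 * mhsc[0]  # mutant stem pool collapsing

    def test_scenario_c_dip_then_regrowth(self):
        spec = ScenarioSpec(scenario="c", post_treatment_years=20.0)
        traj = run_scenario(spec, P)
        after = traj.times >= traj.treatment_start
        vaf = traj.vaf[after]
        assert np.min(vaf) < vaf[0] - 0.01  # initial dip
        assert vaf[-1] > vaf[0]  # regrowth beyond the pre-treatment level
        assert time_to_return(traj, "VAF") is None  # no excursion above reference

    def test_scenario_d_monotone_malignant_decline(self):
        spec = ScenarioSpec(scenario="d", post_treatment_years=10.0)
        traj = run_scenario(spec, P)
        after = traj.times >= traj.treatment_start
        for q in ("y0", "y1", "y2", "VAF"):
            series = traj.series(q)[after]
            assert np.all(np.diff(series) <= 1e-9 * np.maximum(series[:-1], 1e-30))
        assert time_to_return(traj, "mMBC") is None


def test_return_times_insensitive_to_solver_tolerance(scenario_b):
    """Halving tolerances moves the detected return times by well under 1%."""
    tight = run_scenario(ScenarioSpec(scenario="b", post_treatment_years=20.0), P, rtol=5e-9)
    for q in ("mMBC", "VAF"):
        t_ref = time_to_return(scenario_b, q)
        t_tight = time_to_return(tight, q)
        assert abs(t_tight - t_ref) / t_ref < 0.01


def test_sensitivity_ranking_dominated_by_self_renewal(params):
    """The stem-cell self-renewal fractions are the most influential
    parameters; the crowding coefficients, the mutant stem-cell
    proliferation rate and s_x0 follow."""
    from mpndyn import local_sensitivity

    sens = local_sensitivity(params)
    names = [n for n, _ in sens]
    assert set(names[:2]) == {"p_x0", "p_y0"}
    assert {"c_xx", "c_yx", "alpha_y0", "s_x0"} <= set(names[:6])


def test_trajectory_plot_smoke(untreated_30y):
    import matplotlib

    matplotlib.use("Agg")
    fig = untreated_30y.plot()
    assert len(fig.axes) == 2


class TestBasin:
    def test_threshold_separates_attractors(self, params):
        """Starting at the stable state stays; far below it collapses."""
        rec = next(
            r
            for r in reduced_lineage_steady_states(params, "healthy")
            if r.label == "healthy" and r.stable
        )
        arr = rec.state.to_array()
        assert not _attractor_is_trivial(
            1.0, arr[0:3], arr[6], arr[7], params, "healthy", 200.0, 1e-8
        )
        assert _attractor_is_trivial(
            1e-4, arr[0:3], arr[6], arr[7], params, "healthy", 200.0, 1e-8
        )

    def test_threshold_is_a_sharp_boundary(self, params):
        """Fractions on either side of the reported threshold classify
        to opposite attractors (monotone separation)."""
        from mpndyn import basin_threshold

        rec = next(
            r
            for r in reduced_lineage_steady_states(params, "malignant")
            if r.label == "malignant" and r.stable
        )
        arr = rec.state.to_array()
        thr = basin_threshold("malignant", params) / 100.0
        for factor in (0.7, 0.9):
            assert _attractor_is_trivial(
                thr * factor, arr[3:6], arr[6], arr[7], params, "malignant", 200.0, 1e-8
            )
        for factor in (1.15, 1.5):
            assert not _attractor_is_trivial(
                thr * factor, arr[3:6], arr[6], arr[7], params, "malignant", 200.0, 1e-8
            )

    def test_sensitivity_of_irrelevant_parameter_is_zero(self, params):
        """The healthy mature-cell death rate cannot move the malignant
        equilibrium size: that equilibrium has no healthy cells."""
        from mpndyn.simulation import local_sensitivity

        def y2_of(p):
            rec = next(
                r
                for r in reduced_lineage_steady_states(p, "malignant")
                if r.label == "malignant" and r.stable
            )
            return rec.state.y2

        base = y2_of(params)
        up = y2_of(params.replace(d_x2=params.d_x2 * 1.01))
        assert abs(up - base) / base < 1e-9
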