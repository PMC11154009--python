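"""Steady-state enumeration and local stability analysis.

At a steady state the stem-cell equations factor into branches: each
lineage either has zero stem cells or satisfies the balance condition
``2 * p * phi * s / (s_half + s) = 1`` (a stem-cell division is equally
likely to self-renew or differentiate).  On an active branch the
progenitor and mature counts follow linearly from the stem-cell influx,
the debris level follows from the cytokine balance, and the remaining
debris-balance equation reduces to a polynomial in the cytokine level s.
Enumerating the polynomial roots of all four branch combinations yields
every steady state of the system, real or complex, feasible or not.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import sympy as sp
from scipy.optimize import brentq

from .model import STATE_SCALES, SystemState, rhs_array
from .parameters import ModelParameters

__all__ = [
    "SteadyStateRecord",
    "find_steady_states",
    "classify_stability",
    "reduced_healthy_steady_states",
    "reduced_lineage_steady_states",
    "numerical_jacobian",
]

#: Residual tolerance: max |rhs| relative to the compartment scale.
RESIDUAL_RTOL = 1e-6
#: Components above -FEASIBILITY_RTOL * scale count as non-negative.
FEASIBILITY_RTOL = 1e-6
#: Eigenvalue real parts within this absolute band of zero (per day) are
#: considered numerically indeterminate ("marginal").  The slow cell-kinetic
#: modes of this system are of order 1e-4..1e-2 per day, well outside it.
MARGINAL_BAND = 1e-8

_LINEAGE_SLICES = {"healthy": slice(0, 3), "malignant": slice(3, 6)}


@dataclass(frozen=True)
class SteadyStateRecord:
    """One steady state with feasibility and stability annotations."""

    state: SystemState
    feasible: bool
    label: str  # trivial | healthy | malignant | mixed
    stability: str | None = None  # locally stable | locally unstable | marginal
    eigenvalue_max_real_part: float | None = None
    branch: tuple[bool, bool] = (False, False)

    @property
    def stable(self) -> bool:
        return self.stability == "locally stable"


def _lineage_gains(params: ModelParameters, lineage: str) -> tuple[float, float, float]:
    """Per-stem-cell steady ratios (x1/x0, x2/x0) and debris-production gain.

    On an active branch the self-renewal probability is exactly 1/2, so
    the progenitor influx is ``A0 * alpha0 * x0``.
    """
    if lineage == "healthy":
        A0, a0, a1, p1, d1, d2, A1 = (
            params.A_x0, params.alpha_x0, params.alpha_x1, params.p_x1,
            params.d_x1, params.d_x2, params.A_x1,
        )
    else:
        A0, a0, a1, p1, d1, d2, A1 = (
            params.A_y0, params.alpha_y0, params.alpha_y1, params.p_y1,
            params.d_y1, params.d_y2, params.A_y1,
        )
    denom = d1 - a1 * (2.0 * p1 - 1.0)
    if denom <= 0:
        raise ValueError(
            "progenitor compartment has no stable steady ratio: "
            "net self-renewal exceeds death"
        )
    g1 = A0 * a0 / denom
    g2 = 2.0 * A1 * a1 * (1.0 - p1) * g1 / d2
    k = d1 * g1 + d2 * g2
    return g1, g2, k


def _branch_roots(params: ModelParameters, active_x: bool, active_y: bool):
    """All roots (in s) of one branch's reduced debris-balance polynomial.

    Returns ``(roots, x0_of_s, y0_of_s)`` where the latter evaluate the
    stem-cell counts implied by the branch conditions at a given s.
    """
    p = params
    s = sp.symbols("s")
    u = 2 * p.p_x0 * s / (p.s_x0 + s) - 1  # c_xx*x0 + c_xy*y0 on active x-branch
    v = 2 * p.p_y0 * s / (p.s_y0 + s) - 1
    if active_x and active_y:
        det = p.c_xx * p.c_yy - p.c_xy * p.c_yx
        x0_expr = (p.c_yy * u - p.c_xy * v) / det
        y0_expr = (p.c_xx * v - p.c_yx * u) / det
    elif active_x:
        x0_expr, y0_expr = u / p.c_xx, sp.Integer(0)
    elif active_y:
        x0_expr, y0_expr = sp.Integer(0), v / p.c_yy
    else:
        # No cells: a*s = 0 and r_s*a - e_s*s + I = 0 has two roots,
        # (a = 0, s = I/e_s) and (s = 0, a = -I/r_s < 0, infeasible).
        return (
            np.array([p.I / p.e_s, 0.0]),
            lambda sv: 0.0,
            lambda sv: 0.0,
        )

    _, _, k_x = _lineage_gains(p, "healthy")
    _, _, k_y = _lineage_gains(p, "malignant")
    eq = k_x * x0_expr + k_y * y0_expr - p.e_a * s * (p.e_s * s - p.I) / p.r_s
    numer, _ = sp.fraction(sp.together(eq))
    coeffs = [float(c) for c in sp.Poly(sp.expand(numer), s).all_coeffs()]
    roots = np.roots(coeffs)

    fx = sp.lambdify(s, x0_expr, "numpy")
    fy = sp.lambdify(s, y0_expr, "numpy")

    def h(sv: float) -> float:  # residual for polishing real roots
        return k_x * fx(sv) + k_y * fy(sv) - p.e_a * sv * (p.e_s * sv - p.I) / p.r_s

    return roots, fx, fy, h


def _assemble_state(params: ModelParameters, s: float, x0: float, y0: float) -> np.ndarray:
    gx1, gx2, _ = _lineage_gains(params, "healthy")
    gy1, gy2, _ = _lineage_gains(params, "malignant")
    # cytokine balance r_s*a - e_s*s + I = 0 fixes the debris level
    a = (params.e_s * s - params.I) / params.r_s
    return np.array([x0, gx1 * x0, gx2 * x0, y0, gy1 * y0, gy2 * y0, a, s])


def _label(arr: np.ndarray) -> str:
    has_x = np.any(arr[0:3] > 0)
    has_y = np.any(arr[3:6] > 0)
    if has_x and has_y:
        return "mixed"
    if has_x:
        return "healthy"
    if has_y:
        return "malignant"
    return "trivial"


def _dedupe(states: list[np.ndarray], rtol: float = 1e-4) -> list[int]:
    """Indices of unique states under relative log1p distance."""
    keep: list[int] = []
    for i, si in enumerate(states):
        zi = np.log1p(np.abs(si))
        dup = False
        for j in keep:
            zj = np.log1p(np.abs(states[j]))
            if np.linalg.norm(zi - zj) <= rtol * max(np.linalg.norm(zj), 1.0):
                dup = True
                break
        if not dup:
            keep.append(i)
    return keep


def find_steady_states(
    params: ModelParameters,
    include_infeasible: bool = False,
    classify: bool = True,
) -> list[SteadyStateRecord]:
    """Enumerate steady states of the full 8-variable system.

    All four stem-cell branch combinations are reduced to polynomials in
    the cytokine level and solved completely; real roots are polished and
    assembled into full states.  Feasible states (all components real and
    non-negative within tolerance, then clamped to zero) are returned
    first; with ``include_infeasible=True`` real-but-negative states are
    included too.  The raw polynomial root count over all branches (the
    census of possible steady states, complex roots included) is exposed
    by :func:`raw_root_census`.
    """
    records: list[SteadyStateRecord] = []
    arrays: list[np.ndarray] = []
    metas: list[tuple[bool, tuple[bool, bool]]] = []
    for active_x, active_y in [(False, False), (True, False), (False, True), (True, True)]:
        out = _branch_roots(params, active_x, active_y)
        if len(out) == 3:
            roots, fx, fy = out
            polish = None
        else:
            roots, fx, fy, polish = out
        real = np.real(roots[np.abs(np.imag(roots)) < 1e-9 * np.maximum(np.abs(roots), 1.0)])
        for s_root in real:
            s_val = float(s_root)
            if polish is not None and s_val > 0:
                try:  # tighten the root with a local bracket
                    lo, hi = s_val * (1 - 1e-3), s_val * (1 + 1e-3)
                    if polish(lo) * polish(hi) < 0:
                        s_val = brentq(polish, lo, hi, xtol=1e-15, rtol=1e-14)
                except ValueError:
                    pass
            x0 = float(fx(s_val)) if active_x else 0.0
            y0 = float(fy(s_val)) if active_y else 0.0
            arr = _assemble_state(params, s_val, x0, y0)
            feas_tol = FEASIBILITY_RTOL * STATE_SCALES
            feasible = bool(np.all(arr >= -feas_tol))
            arrays.append(arr)
            metas.append((feasible, (active_x, active_y)))

    for idx in _dedupe(arrays):
        arr, (feasible, branch) = arrays[idx], metas[idx]
        if not feasible and not include_infeasible:
            continue
        clamped = np.clip(arr, 0.0, None)
        if feasible:
            resid = np.max(np.abs(rhs_array(clamped, params)) / STATE_SCALES)
            if resid > RESIDUAL_RTOL:
                warnings.warn(
                    f"steady-state root on branch {branch} has relative residual {resid:.2e}",
                    stacklevel=2,
                )
        state = SystemState.from_array(clamped)
        records.append(
            SteadyStateRecord(state, feasible, _label(clamped), branch=branch)
        )

    records.sort(key=lambda r: (not r.feasible, r.label, r.state.s))
    if classify:
        records = [
            classify_stability(r, params) if r.feasible else r for r in records
        ]
    return records


def raw_root_census(params: ModelParameters) -> int:
    """Total root count over all branches before any feasibility filtering.

    Counts every polynomial root — complex, negative or repeated — of the
    four branch reductions; this is the number of possible steady states
    of the rational steady-state equations.
    """
    n = 0
    for active_x, active_y in [(False, False), (True, False), (False, True), (True, True)]:
        roots = _branch_roots(params, active_x, active_y)[0]
        n += len(roots)
    return n


def numerical_jacobian(
    fun,
    x: np.ndarray,
    scales: np.ndarray,
    rel_step: float = 1e-6,
) -> np.ndarray:
    """Central finite-difference Jacobian with component-relative steps."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    m = len(np.atleast_1d(fun(x)))
    J = np.empty((m, n))
    for j in range(n):
        h = rel_step * max(abs(x[j]), 1e-3 * scales[j])
        xp, xm = x.copy(), x.copy()
        xp[j] += h
        xm[j] -= h
        J[:, j] = (fun(xp) - fun(xm)) / (2.0 * h)
    return J


def classify_stability(
    record: SteadyStateRecord, params: ModelParameters
) -> SteadyStateRecord:
    """Attach local stability from the eigenvalues of the 8x8 Jacobian.

    Locally stable iff every eigenvalue has negative real part; real
    parts within a small fraction of the spectral radius of zero are
    flagged marginal rather than guessed.
    """
    arr = record.state.to_array()
    J = numerical_jacobian(lambda y: rhs_array(y, params), arr, STATE_SCALES)
    eig = np.linalg.eigvals(J)
    max_re = float(np.max(np.real(eig)))
    if abs(max_re) < MARGINAL_BAND:
        stability = "marginal"
    elif max_re < 0:
        stability = "locally stable"
    else:
        stability = "locally unstable"
    return replace(record, stability=stability, eigenvalue_max_real_part=max_re)


# ---------------------------------------------------------------------------
# Single-lineage reduced systems (the other lineage removed entirely)


def reduced_rhs_array(y5: np.ndarray, params: ModelParameters, lineage: str) -> np.ndarray:
    """RHS of the 5-variable single-lineage system (cells, debris, cytokine)."""
    full = np.zeros(8)
    full[_LINEAGE_SLICES[lineage]] = y5[:3]
    full[6:8] = y5[3:]
    d = rhs_array(full, params)
    return np.concatenate([d[_LINEAGE_SLICES[lineage]], d[6:8]])


def reduced_lineage_steady_states(
    params: ModelParameters, lineage: str = "healthy"
) -> list[SteadyStateRecord]:
    """Steady states of the single-lineage reduced system.

    Structurally these coincide with the full-system steady states that
    have the other lineage at zero, but stability is judged from the 5x5
    Jacobian of the reduced system — removing the invasion direction of
    the absent lineage can stabilise a state that is unstable in the
    full system.
    """
    if lineage not in _LINEAGE_SLICES:
        raise ValueError("lineage must be 'healthy' or 'malignant'")
    sl = _LINEAGE_SLICES[lineage]
    wanted = {"trivial", lineage}
    records = []
    for rec in find_steady_states(params, classify=False):
        if rec.label not in wanted:
            continue
        arr = rec.state.to_array()
        y5 = np.concatenate([arr[sl], arr[6:8]])
        scales5 = np.concatenate([STATE_SCALES[sl], STATE_SCALES[6:8]])
        J = numerical_jacobian(lambda y: reduced_rhs_array(y, params, lineage), y5, scales5)
        eig = np.linalg.eigvals(J)
        max_re = float(np.max(np.real(eig)))
        if abs(max_re) < MARGINAL_BAND:
            stability = "marginal"
        else:
            stability = "locally stable" if max_re < 0 else "locally unstable"
        records.append(replace(rec, stability=stability, eigenvalue_max_real_part=max_re))
    return records


def reduced_healthy_steady_states(params: ModelParameters) -> list[SteadyStateRecord]:
    """Steady states of the healthy-only (malignant-free) reduced system."""
    return reduced_lineage_steady_states(params, "healthy")
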