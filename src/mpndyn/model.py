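"""State, crowding feedback, right-hand side and readouts of the MPN model.

Eight state variables: healthy stem/progenitor/mature counts (x0, x1, x2),
their JAK2-mutant counterparts (y0, y1, y2), cellular debris ``a`` and a
lumped cytokine signal ``s``.  Stem-cell self-renewal is up-regulated by
the cytokine through a Michaelis-Menten term s/(s_half + s) and
down-regulated by niche crowding; dying cells feed the debris pool, which
drives cytokine production.  Time unit is days throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import ModelParameters

__all__ = [
    "SystemState",
    "TreatmentResponse",
    "crowding_phi",
    "effective_parameters",
    "rhs",
    "rhs_array",
    "vaf_readout",
    "homozygous_fraction_bound",
    "STATE_NAMES",
    "STATE_SCALES",
]

STATE_NAMES = ("x0", "x1", "x2", "y0", "y1", "y2", "a", "s")

#: Characteristic magnitudes of the state variables (order-of-magnitude
#: maxima of each compartment), used for finite-difference steps and
#: component-wise solver tolerances.
STATE_SCALES = np.array([1.0e5, 2.5e6, 6.4e11, 1.7e5, 7.6e6, 2.7e12, 1.7e3, 2.0])


@dataclass(frozen=True)
class SystemState:
    """The model state at one instant; all components non-negative."""

    x0: float
    x1: float
    x2: float
    y0: float
    y1: float
    y2: float
    a: float
    s: float

    def __post_init__(self) -> None:
        arr = self.to_array()
        if not np.all(np.isfinite(arr)):
            raise ValueError("state components must be finite")
        if np.any(arr < 0):
            raise ValueError("state components must be non-negative")

    def to_array(self) -> np.ndarray:
        return np.array([self.x0, self.x1, self.x2, self.y0, self.y1, self.y2, self.a, self.s])

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "SystemState":
        return cls(*map(float, arr))


@dataclass(frozen=True)
class TreatmentResponse:
    """Patient-specific ruxolitinib response.

    ``rho_sy0`` and ``rho_dy1`` quantify the dose-dependent increase of
    the malignant stem-cell cytokine half-saturation constant s_y0 and of
    the malignant progenitor death rate d_y1, in (mg/day)^-1.  ``dose``
    is the constant daily dose c_R in mg/day; only relative changes of
    the dose matter, since a rescaling of c_R can be absorbed into the
    rho parameters.
    """

    rho_sy0: float = 0.0
    rho_dy1: float = 0.0
    dose: float = 0.0

    def __post_init__(self) -> None:
        if self.rho_sy0 < 0 or self.rho_dy1 < 0:
            raise ValueError("response strengths rho_sy0, rho_dy1 must be >= 0")
        if self.dose < 0:
            raise ValueError("dose must be >= 0")


def crowding_phi(kind: str, x0: float, y0: float, params: ModelParameters) -> float:
    """Niche-crowding feedback on stem-cell self-renewal, in (0, 1].

    ``phi = 1 / (1 + c_kx * x0 + c_ky * y0)`` with lineage-specific
    inhibition coefficients; monotone decreasing in both counts.
    """
    if x0 < 0 or y0 < 0:
        raise ValueError("cell counts must be non-negative")
    if kind == "healthy":
        return 1.0 / (1.0 + params.c_xx * x0 + params.c_xy * y0)
    if kind == "malignant":
        return 1.0 / (1.0 + params.c_yx * x0 + params.c_yy * y0)
    raise ValueError(f"kind must be 'healthy' or 'malignant', got {kind!r}")


def effective_parameters(params: ModelParameters, treat: TreatmentResponse) -> ModelParameters:
    """Parameters in effect during treatment.

    Ruxolitinib raises the malignant stem-cell half-saturation constant
    and the malignant progenitor death rate dose-dependently:
    ``s_y0 -> (1 + dose * rho_sy0) * s_y0`` and
    ``d_y1 -> (1 + dose * rho_dy1) * d_y1``; all other parameters are
    unchanged.  The treated system is the untreated right-hand side
    evaluated at these effective parameters.
    """
    return params.replace(
        s_y0=(1.0 + treat.dose * treat.rho_sy0) * params.s_y0,
        d_y1=(1.0 + treat.dose * treat.rho_dy1) * params.d_y1,
    )


def rhs_array(y: np.ndarray, params: ModelParameters) -> np.ndarray:
    """Right-hand side on a raw 8-vector; no domain validation.

    Used internally by the integrator and the finite-difference Jacobian,
    where transiently (slightly) negative components may occur.
    """
    x0, x1, x2, y0, y1, y2, a, s = y
    phi_x = 1.0 / (1.0 + params.c_xx * x0 + params.c_xy * y0)
    phi_y = 1.0 / (1.0 + params.c_yx * x0 + params.c_yy * y0)
    sat_x = s / (params.s_x0 + s)
    sat_y = s / (params.s_y0 + s)
    # self-renewal probability of a stem-cell division, in (0, 1)
    ren_x = params.p_x0 * phi_x * sat_x
    ren_y = params.p_y0 * phi_y * sat_y

    dx0 = params.alpha_x0 * (2.0 * ren_x - 1.0) * x0
    influx_x1 = 2.0 * params.A_x0 * params.alpha_x0 * (1.0 - ren_x) * x0
    dx1 = params.alpha_x1 * (2.0 * params.p_x1 - 1.0) * x1 + influx_x1 - params.d_x1 * x1
    dx2 = 2.0 * params.A_x1 * params.alpha_x1 * (1.0 - params.p_x1) * x1 - params.d_x2 * x2

    dy0 = params.alpha_y0 * (2.0 * ren_y - 1.0) * y0
    influx_y1 = 2.0 * params.A_y0 * params.alpha_y0 * (1.0 - ren_y) * y0
    dy1 = params.alpha_y1 * (2.0 * params.p_y1 - 1.0) * y1 + influx_y1 - params.d_y1 * y1
    dy2 = 2.0 * params.A_y1 * params.alpha_y1 * (1.0 - params.p_y1) * y1 - params.d_y2 * y2

    da = (
        params.d_x1 * x1
        + params.d_y1 * y1
        + params.d_x2 * x2
        + params.d_y2 * y2
        - params.e_a * a * s
    )
    ds = params.r_s * a - params.e_s * s + params.I

    return np.array([dx0, dx1, dx2, dy0, dy1, dy2, da, ds])


def rhs_jacobian_array(y: np.ndarray, params: ModelParameters) -> np.ndarray:
    """Analytic 8x8 Jacobian of :func:`rhs_array`.

    Supplied to the implicit integrator: the debris-cytokine turnover is
    orders of magnitude faster than the cell kinetics, and an exact
    Jacobian lets the stiff solver take far larger steps than one built
    from forward differences.
    """
    x0, x1, x2, y0, y1, y2, a, s = y
    p = params
    phi_x = 1.0 / (1.0 + p.c_xx * x0 + p.c_xy * y0)
    phi_y = 1.0 / (1.0 + p.c_yx * x0 + p.c_yy * y0)
    sat_x = s / (p.s_x0 + s)
    sat_y = s / (p.s_y0 + s)
    dsat_x = p.s_x0 / (p.s_x0 + s) ** 2
    dsat_y = p.s_y0 / (p.s_y0 + s) ** 2
    ren_x = p.p_x0 * phi_x * sat_x
    ren_y = p.p_y0 * phi_y * sat_y
    # partials of the self-renewal probabilities
    drenx_dx0 = -p.p_x0 * sat_x * p.c_xx * phi_x**2
    drenx_dy0 = -p.p_x0 * sat_x * p.c_xy * phi_x**2
    drenx_ds = p.p_x0 * phi_x * dsat_x
    dreny_dx0 = -p.p_y0 * sat_y * p.c_yx * phi_y**2
    dreny_dy0 = -p.p_y0 * sat_y * p.c_yy * phi_y**2
    dreny_ds = p.p_y0 * phi_y * dsat_y

    J = np.zeros((8, 8))
    # healthy stem cells
    J[0, 0] = p.alpha_x0 * ((2.0 * ren_x - 1.0) + 2.0 * x0 * drenx_dx0)
    J[0, 3] = p.alpha_x0 * 2.0 * x0 * drenx_dy0
    J[0, 7] = p.alpha_x0 * 2.0 * x0 * drenx_ds
    # healthy progenitors
    cx = 2.0 * p.A_x0 * p.alpha_x0
    J[1, 0] = cx * ((1.0 - ren_x) - x0 * drenx_dx0)
    J[1, 1] = p.alpha_x1 * (2.0 * p.p_x1 - 1.0) - p.d_x1
    J[1, 3] = -cx * x0 * drenx_dy0
    J[1, 7] = -cx * x0 * drenx_ds
    # healthy mature cells
    J[2, 1] = 2.0 * p.A_x1 * p.alpha_x1 * (1.0 - p.p_x1)
    J[2, 2] = -p.d_x2
    # malignant stem cells
    J[3, 0] = p.alpha_y0 * 2.0 * y0 * dreny_dx0
    J[3, 3] = p.alpha_y0 * ((2.0 * ren_y - 1.0) + 2.0 * y0 * dreny_dy0)
    J[3, 7] = p.alpha_y0 * 2.0 * y0 * dreny_ds
    # malignant progenitors
    cy = 2.0 * p.A_y0 * p.alpha_y0
    J[4, 0] = -cy * y0 * dreny_dx0
    J[4, 3] = cy * ((1.0 - ren_y) - y0 * dreny_dy0)
    J[4, 4] = p.alpha_y1 * (2.0 * p.p_y1 - 1.0) - p.d_y1
    J[4, 7] = -cy * y0 * dreny_ds
    # malignant mature cells
    J[5, 4] = 2.0 * p.A_y1 * p.alpha_y1 * (1.0 - p.p_y1)
    J[5, 5] = -p.d_y2
    # debris
    J[6, 1] = p.d_x1
    J[6, 2] = p.d_x2
    J[6, 4] = p.d_y1
    J[6, 5] = p.d_y2
    J[6, 6] = -p.e_a * s
    J[6, 7] = -p.e_a * a
    # cytokine
    J[7, 6] = p.r_s
    J[7, 7] = -p.e_s
    return J


def rhs(state: SystemState | np.ndarray, params: ModelParameters) -> np.ndarray:
    """Rate of change of the 8 state variables, per day."""
    arr = state.to_array() if isinstance(state, SystemState) else np.asarray(state, dtype=float)
    if arr.shape != (8,):
        raise ValueError("state must have 8 components")
    if not np.all(np.isfinite(arr)):
        raise ValueError("state components must be finite")
    return rhs_array(arr, params)


def vaf_readout(x2: float | np.ndarray, y2: float | np.ndarray) -> float | np.ndarray:
    """Model JAK2 VAF estimate ``y2 / (x2 + y2)``.

    Valid under the all-homozygous assumption: every mutant cell carries
    two mutant alleles, so the allele fraction equals the mutant cell
    fraction among mature blood cells.
    """
    total = np.asarray(x2) + np.asarray(y2)
    if np.any(total <= 0):
        raise ValueError("VAF undefined: total mature cell count must be positive")
    out = np.asarray(y2) / total
    return float(out) if out.ndim == 0 else out


def homozygous_fraction_bound(V: float) -> float:
    """Minimum homozygous fraction ``h = 2V - 1`` if all cells are mutated.

    With a fraction h of mutant cells homozygous and the rest
    heterozygous, the VAF is V = (1 - h)/2 + h = (1 + h)/2; inverting at
    an observed VAF in [0.5, 1] gives the smallest h consistent with all
    cells being mutated.
    """
    if not (0.5 <= V <= 1.0):
        raise ValueError("bound defined only for VAF in [0.5, 1]")
    return 2.0 * V - 1.0
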