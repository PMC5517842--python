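"""Pointwise kinetics of the tumour–immune–drug network.

The model tracks, on a growing radially symmetric tumour, six cell species
(dendritic cells D, Th1 cells T1, cytotoxic T cells T8, Tregs Tr, MDSCs M and
cancer cells C), five cytokines (IL-12, IL-2, TGF-beta, IL-6, IL-10), the
checkpoint receptor PD-1 (P) and two drugs: anti-PD-1 (A) and a BRAF/MEK
inhibitor (B).  PD-L1 (L) is slaved algebraically to the cell densities and
the PD-1–PD-L1 complex never appears explicitly — both checkpoint factors are
functions of the product P*L.

This module supplies the reaction right-hand sides for all fields, the
algebraic closures, the dosing source, and the IL-6 chemotaxis divergence.
The spatial transport (diffusion, advection, free boundary) lives in
:mod:`melsim.solver`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._grid import GridOps
from .parameters import ParameterSet

__all__ = [
    "FIELD_NAMES", "CELL_FIELDS", "ADVECTED_FIELDS", "TumorState",
    "DoseSchedule", "dose_rate", "pdl1_level", "checkpoint_factors",
    "reaction_split", "reaction_terms", "chemotactic_divergence",
    "diffusion_coefficients",
]

FIELD_NAMES = ("D", "T1", "T8", "Tr", "M", "C",
               "I12", "I2", "Tb", "I6", "I10", "P", "A", "B")
IDX = {name: i for i, name in enumerate(FIELD_NAMES)}
N_FIELDS = len(FIELD_NAMES)

#: indices of the six cell species whose equations carry the velocity term
#: and whose reaction sum sources the velocity field
CELL_FIELDS = tuple(IDX[n] for n in ("D", "T1", "T8", "Tr", "M", "C"))
#: fields transported by the cell velocity (cells plus membrane-bound PD-1)
ADVECTED_FIELDS = CELL_FIELDS + (IDX["P"],)


def diffusion_coefficients(params: ParameterSet) -> np.ndarray:
    """Per-field diffusivities (cm^2/day), ordered as :data:`FIELD_NAMES`.

    PD-1 rides on T-cell membranes and shares the T-cell diffusivity.
    """
    return np.array([
        params.delta_D, params.delta_T, params.delta_T, params.delta_T,
        params.delta_M, params.delta_C,
        params.delta_I12, params.delta_I2, params.delta_Tb,
        params.delta_I6, params.delta_I10,
        params.delta_T, params.delta_A, params.delta_B,
    ])


@dataclass
class TumorState:
    """All evolving fields on the radial grid, plus the boundary radius.

    ``fields`` has shape ``(14, N)`` in the order of :data:`FIELD_NAMES`;
    ``r`` are the node positions with ``r[0] == 0`` and ``r[-1] == R``.
    """

    fields: np.ndarray
    r: np.ndarray
    t: float = 0.0
    u: np.ndarray | None = None
    clipped_mass: float = 0.0  # cumulative magnitude removed by positivity clamping

    def __post_init__(self) -> None:
        self.fields = np.asarray(self.fields, dtype=float)
        self.r = np.asarray(self.r, dtype=float)
        if self.fields.shape != (N_FIELDS, self.r.size):
            raise ValueError("fields must have shape (14, len(r))")
        if self.r[0] != 0.0 or np.any(np.diff(self.r) <= 0):
            raise ValueError("grid must be strictly increasing from r=0")

    @property
    def R(self) -> float:
        return float(self.r[-1])

    def __getattr__(self, name: str):
        idx = IDX.get(name)
        if idx is None:
            raise AttributeError(name)
        return self.fields[idx]

    def copy(self) -> "TumorState":
        return TumorState(self.fields.copy(), self.r.copy(), self.t,
                          None if self.u is None else self.u.copy(),
                          self.clipped_mass)


@dataclass(frozen=True)
class DoseSchedule:
    """Piecewise-in-time drug source: constant level ``gamma`` up to
    ``t_on`` days, then a linear ramp to zero at ``t_ramp_end``."""

    gamma: float
    t_on: float = 30.0
    t_ramp_end: float = 33.0

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError("dose level gamma must be non-negative")
        if not self.t_on < self.t_ramp_end:
            raise ValueError("t_on must precede t_ramp_end")


def dose_rate(t: float, schedule: DoseSchedule | None) -> float:
    """Source level (g/cm^3/day) of a drug at time ``t`` (days)."""
    if t < 0:
        raise ValueError("time must be non-negative")
    if schedule is None:
        return 0.0
    if t <= schedule.t_on:
        return schedule.gamma
    if t <= schedule.t_ramp_end:
        return schedule.gamma * (schedule.t_ramp_end - t) / (schedule.t_ramp_end - schedule.t_on)
    return 0.0


def pdl1_level(T1, T8, M, C, params: ParameterSet):
    """Algebraic PD-L1 concentration L = rho_L*(T1 + T8 + eps_M*M + eps_C*C)."""
    return params.rho_L * (T1 + T8 + params.eps_M * M + params.eps_C * C)


def checkpoint_factors(P, L, params: ParameterSet):
    """Checkpoint complex factors as functions of the product P*L.

    Returns ``(inhibition, promotion)``: the factor 1/(1 + P*L/Kp_TQ) damping
    effector T-cell activation/proliferation, and the saturating factor
    P*L/(Kp_Q + P*L) promoting Treg activation (0 when no complex forms).
    """
    pl = np.asarray(P, dtype=float) * np.asarray(L, dtype=float)
    inhibition = 1.0 / (1.0 + pl / params.Kp_TQ)
    promotion = pl / (params.Kp_Q + pl)
    return inhibition, promotion


def _hill(x, k):
    return x / (k + x)


def reaction_split(fields: np.ndarray, params: ParameterSet, t: float = 0.0,
                   schedule_A: DoseSchedule | None = None,
                   schedule_B: DoseSchedule | None = None,
                   gamma_I12: float = 0.0,
                   chemo_div_Tr: np.ndarray | None = None):
    """Reaction kinetics split as ``rate = src - loss * X`` per field.

    ``src`` and ``loss`` are evaluated at the supplied (lagged) state, so the
    exact pointwise rate is ``src - loss * fields``.  The split isolates each
    field's own linear loss terms, which the implicit solver folds into its
    tridiagonal diagonal; stiff degradations (TGF-beta turns over ~500/day)
    would destabilise a fully lagged source.

    ``chemo_div_Tr`` is the IL-6 chemotaxis divergence of the Treg field,
    div(chi * Tr * grad I6), needed by the PD-1 equation; zero if omitted.
    """
    p = params
    D, T1, T8, Tr, M, C, I12, I2, Tb, I6, I10, P, A, B = fields
    src = np.zeros_like(fields)
    loss = np.zeros_like(fields)

    L = pdl1_level(T1, T8, M, C, p)
    inhib_q, promo_q = checkpoint_factors(P, L, p)
    f_i12 = _hill(I12, p.K_I12)
    f_i2 = _hill(I2, p.K_I2)
    f_il10 = 1.0 / (1.0 + I10 / p.K_TI10)
    f_treg = 1.0 / (1.0 + Tr / p.K_Tr)

    # dendritic cells: activation driven by tumour-derived danger signals
    src[0] = p.lam_DC * p.D_0 * _hill(C, p.K_C)
    loss[0] = p.d_D

    # effector T cells: IL-12 activation (damped by IL-10, Tregs and the
    # checkpoint complex) plus IL-2-driven proliferation
    act_t1 = p.lam_T1I12 * p.T_10 * f_i12 * f_il10 * f_treg
    act_t8 = p.lam_T8I12 * p.T_80 * f_i12 * f_il10 * f_treg
    src[1] = (act_t1 + p.lam_T1I2 * T1 * f_i2) * inhib_q
    loss[1] = p.d_T1
    src[2] = (act_t8 + p.lam_T8I2 * T8 * f_i2) * inhib_q
    loss[2] = p.d_T8

    # Tregs: TGF-beta-driven differentiation plus checkpoint promotion
    treg_act = p.lam_TrTb * _hill(Tb, p.K_Tb) + p.lam_TrQ * promo_q
    src[3] = p.T_10 * treg_act
    loss[3] = p.d_Tr

    # MDSCs: IL-6-gated recruitment towards the influx level M_0
    f_i6 = _hill(I6, p.K_I6)
    src[4] = p.lam_M * p.M_0 * f_i6
    loss[4] = p.lam_M * f_i6 + p.d_M

    # cancer cells: logistic growth damped by BRAF/MEKi, killed by T cells
    src[5] = p.lam_C * C * (1.0 - C / p.C_M) / (1.0 + B / p.K_CB)
    loss[5] = p.eta_1 * T1 + p.eta_8 * T8 + p.d_C

    # cytokines
    src[6] = p.lam_I12D * D * (1.0 + p.lam_I12B * _hill(B, p.K_B)) + gamma_I12
    loss[6] = p.d_I12
    src[7] = p.lam_I2T1 * T1
    loss[7] = p.d_I2
    src[8] = p.lam_TbC * C + p.lam_TbTr * Tr + p.lam_TbM * M
    loss[8] = p.d_Tb
    src[9] = p.lam_I6C * C
    loss[9] = p.d_I6
    src[10] = p.lam_I10C * C + p.lam_I10M * M
    loss[10] = p.d_I10

    # membrane PD-1: the T-cell activation/death budget scaled by P per unit
    # of PD-1-carrying T-cell mass, minus blocking by anti-PD-1
    t_eff = T1 + T8 + p.eps_T * Tr
    budget = (act_t1 + act_t8 + (p.lam_T1I2 * T1 + p.lam_T8I2 * T8) * f_i2) * inhib_q
    budget = budget + p.eps_T * p.T_10 * treg_act
    budget = budget - (p.d_T1 * T1 + p.d_T8 * T8 + p.eps_T * p.d_Tr * Tr)
    if chemo_div_Tr is not None:
        budget = budget - p.eps_T * chemo_div_Tr
    with np.errstate(divide="ignore", invalid="ignore"):
        q = np.where(t_eff > 0, budget / np.where(t_eff > 0, t_eff, 1.0), 0.0)
    src[11] = P * np.maximum(q, 0.0)
    loss[11] = p.mu_PA * A + np.maximum(-q, 0.0)

    # drugs
    src[12] = dose_rate(t, schedule_A)
    loss[12] = p.mu_PA * P + p.d_A
    src[13] = dose_rate(t, schedule_B)
    loss[13] = p.mu_BC * C / (p.K_B + B) + p.d_B

    return src, loss


def reaction_terms(fields: np.ndarray, params: ParameterSet, t: float = 0.0,
                   schedule_A: DoseSchedule | None = None,
                   schedule_B: DoseSchedule | None = None,
                   gamma_I12: float = 0.0,
                   chemo_div_Tr: np.ndarray | None = None) -> np.ndarray:
    """Pointwise reaction rates (g/cm^3/day) for every field."""
    src, loss = reaction_split(fields, params, t, schedule_A, schedule_B,
                               gamma_I12, chemo_div_Tr)
    return src - loss * fields


def chemotactic_divergence(X: np.ndarray, I6: np.ndarray, r: np.ndarray,
                           chi: float, ops: "GridOps | None" = None) -> np.ndarray:
    """Radial divergence of the chemotactic flux, div(chi * X * grad I6).

    In spherical symmetry div F = (1/r^2) d(r^2 F)/dr with F = chi*X*dI6/dr.
    Centred differences on the (possibly non-uniform) grid; at the origin the
    flux is odd in r so div F -> 3*dF/dr.  ``X`` may be a batch of fields
    (shape ``(..., N)``); a precomputed :class:`~melsim._grid.GridOps` may be
    passed to avoid rebuilding the difference weights.
    """
    r = np.asarray(r, dtype=float)
    X = np.asarray(X, dtype=float)
    if r.size < 3:
        raise ValueError("chemotaxis divergence needs at least 3 grid nodes")
    if chi == 0.0:
        return np.zeros(X.shape)
    if ops is None:
        ops = GridOps(r)
    grad_i6 = ops.deriv(I6)
    grad_i6[0] = 0.0  # symmetry at the origin
    flux = chi * X * grad_i6
    dflux = ops.deriv(flux)
    div = np.empty(flux.shape)
    # div F = dF/dr + 2F/r; the flux is odd in r, so div F -> 3 dF/dr at r = 0
    div[..., 1:] = dflux[..., 1:] + 2.0 * flux[..., 1:] / r[1:]
    div[..., 0] = 3.0 * dflux[..., 0]
    return div
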