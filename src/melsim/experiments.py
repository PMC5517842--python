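"""In-silico therapy experiments: efficacy maps and antagonism profiles.

The efficacy of a dose pair (gamma_B, gamma_A) is the relative reduction of
the day-60 tumour radius against the untreated control,

    E(gamma_B, gamma_A) = (R60(0,0) - R60(gamma_B, gamma_A)) / R60(0,0),

a number in [0, 1].  At low doses the two drugs cooperate (E rises with
either dose); at some high doses they become antagonistic — raising one drug
lowers the effector T-cell populations through the cancer -> danger-signal ->
dendritic-cell -> IL-12 -> T-cell pathway, and E dips.  Injecting even a tiny
direct IL-12 source removes the antagonism.
"""

from __future__ import annotations

from dataclasses import dataclass, field as _dcfield
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .parameters import ParameterSet, baseline_parameters
from .model import DoseSchedule
from .solver import SolverOptions, SimulationResult, simulate

__all__ = [
    "efficacy", "EfficacyMap", "efficacy_map",
    "dose_response_profile", "il12_injection_variant",
    "DEFAULT_GAMMA_B_MAX", "DEFAULT_GAMMA_A_MAX", "is_antagonistic",
]

#: dose ranges explored for the efficacy map (g/cm^3/day)
DEFAULT_GAMMA_B_MAX = 5e-9
DEFAULT_GAMMA_A_MAX = 1.4e-9


def efficacy(r60_control: float, r60_treated: float) -> float:
    """Relative day-60 radius reduction (R_c - R_t)/R_c."""
    if r60_control <= 0:
        raise ValueError("control radius must be positive")
    return (r60_control - r60_treated) / r60_control


def _schedule(gamma: float) -> DoseSchedule | None:
    return None if gamma == 0.0 else DoseSchedule(gamma)


@dataclass
class EfficacyMap:
    """Day-60 radii and efficacies over a grid of dose pairs."""

    gamma_B: np.ndarray                 # sorted levels, g/cm^3/day
    gamma_A: np.ndarray
    R60: np.ndarray                     # shape (len(gamma_B), len(gamma_A)), cm
    E: np.ndarray                       # same shape, dimensionless
    failures: list = _dcfield(default_factory=list)

    @property
    def max_efficacy(self) -> float:
        return float(np.nanmax(self.E))

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        idx = pd.Index(self.gamma_B, name="gamma_B")
        cols = pd.Index(self.gamma_A, name="gamma_A")
        return (pd.DataFrame(self.E, index=idx, columns=cols),
                pd.DataFrame(self.R60, index=idx, columns=cols))


def efficacy_map(gamma_B_levels: Sequence[float], gamma_A_levels: Sequence[float],
                 params: ParameterSet | None = None,
                 options: SolverOptions | None = None,
                 t_end: float = 60.0) -> EfficacyMap:
    """One simulation per dose pair; the control is computed once.

    Individual simulation failures are recorded in ``failures`` (as
    ``(gamma_B, gamma_A, message)``) and leave NaN entries rather than
    aborting the whole map.
    """
    p = params or baseline_parameters()
    g_b = np.asarray(sorted(gamma_B_levels), dtype=float)
    g_a = np.asarray(sorted(gamma_A_levels), dtype=float)
    if g_b.min() < 0 or g_a.min() < 0:
        raise ValueError("dose levels must be non-negative")

    r60_control = simulate(p, None, None, t_end, options).R[-1]
    r60 = np.full((g_b.size, g_a.size), np.nan)
    failures: list = []
    for i, gb in enumerate(g_b):
        for j, ga in enumerate(g_a):
            if gb == 0.0 and ga == 0.0:
                r60[i, j] = r60_control
                continue
            try:
                res = simulate(p, _schedule(ga), _schedule(gb), t_end, options)
                r60[i, j] = res.R[-1]
            except Exception as exc:  # noqa: BLE001 - flagged per cell, not fatal
                failures.append((gb, ga, str(exc)))
    e = (r60_control - r60) / r60_control
    return EfficacyMap(g_b, g_a, r60, e, failures)


def dose_response_profile(fixed_drug: Literal["A", "B"], fixed_level: float,
                          varied_levels: Sequence[float],
                          params: ParameterSet | None = None,
                          options: SolverOptions | None = None,
                          gamma_I12: float = 0.0, t_end: float = 60.0) -> pd.DataFrame:
    """Day-60 average effector T-cell densities along a one-drug dose sweep.

    ``fixed_drug`` names the drug held at ``fixed_level`` while the other
    drug runs over ``varied_levels``.  Returns a frame with columns
    ``dose``, ``T1``, ``T8`` and ``R60``; non-monotone T1/T8 columns signal
    antagonism between the two drugs.
    """
    p = params or baseline_parameters()
    rows = []
    for dose in varied_levels:
        if fixed_drug == "A":
            sched_a, sched_b = _schedule(fixed_level), _schedule(dose)
        elif fixed_drug == "B":
            sched_a, sched_b = _schedule(dose), _schedule(fixed_level)
        else:
            raise ValueError("fixed_drug must be 'A' or 'B'")
        res = simulate(p, sched_a, sched_b, t_end, options, gamma_I12)
        rows.append({"dose": dose,
                     "T1": res.averages["T1"].iloc[-1],
                     "T8": res.averages["T8"].iloc[-1],
                     "R60": res.R[-1]})
    return pd.DataFrame(rows)


def is_antagonistic(values: Sequence[float], rel_tol: float = 1e-3) -> bool:
    """True if any adjacent-dose decrease exceeds ``rel_tol`` relatively."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        return False
    scale = np.max(np.abs(v)) + 1e-300
    return bool(np.any(np.diff(v) < -rel_tol * scale))


def il12_injection_variant(gamma_I12: float,
                           params: ParameterSet | None = None,
                           schedule_A: DoseSchedule | None = None,
                           schedule_B: DoseSchedule | None = None,
                           t_end: float = 60.0,
                           options: SolverOptions | None = None) -> SimulationResult:
    """Therapy simulation with a constant direct IL-12 source in the tumour.

    Adding IL-12 of order 1e-14 g/cm^3/day already decouples T-cell
    activation from the dendritic-cell supply and removes the
    BRAF/MEKi–anti-PD-1 antagonism.
    """
    if gamma_I12 < 0:
        raise ValueError("IL-12 injection rate must be non-negative")
    return simulate(params, schedule_A, schedule_B, t_end, options,
                    gamma_I12=gamma_I12)
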