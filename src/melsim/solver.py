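"""Moving-mesh implicit solver for the free-boundary tumour problem.

The tumour occupies the ball 0 <= r <= R(t).  Because the total cell density
is held at the constant ``theta``, net cell production must be carried away by
a radial velocity field u(r, t):

    theta * div u = S,   S = sum of the six cell-field right-hand sides,

so u(r) = (1/(theta r^2)) * int_0^r s^2 S(s) ds, and the boundary moves with
the cells: dR/dt = u(R, t).

Each field X obeys dX/dt = delta*Lap X - div(u X) + F (cytokines and drugs
omit the advection term).  One time step solves, for every field, the fully
implicit non-uniform-grid discretisation with the spherical Laplacian
X_rr + (2/r) X_r and advection ((2/r) u + u_r) X + u X_r, by Picard iteration:
nonlinear coefficients are lagged at the previous iterate and each iteration
is one tridiagonal solve per field.  At the origin the (2/r) terms are
replaced by their symmetric limits (Laplacian -> 3 X_rr, div u -> 3 u_r).
After convergence the mesh moves with the converged velocity,
r_i <- r_i + u_i * tau, which also advances the free boundary.

Boundary conditions: symmetry at r = 0; at r = R a Robin influx condition for
the effector T cells, dX/dr + sigma_T(I12) (X - Xhat) = 0 with
sigma_T = sigma_0 * I12/(I12 + K_I12), and homogeneous Neumann for all other
fields.
"""

from __future__ import annotations

from dataclasses import dataclass, field as _dcfield
import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.linalg.lapack import dgtsv

from ._grid import GridOps
from .parameters import ParameterSet, baseline_parameters
from .model import (
    FIELD_NAMES, IDX, N_FIELDS, CELL_FIELDS, ADVECTED_FIELDS,
    TumorState, DoseSchedule, diffusion_coefficients,
    reaction_split, chemotactic_divergence,
)

__all__ = [
    "RadialGrid", "SolverOptions", "SimulationResult", "PicardError",
    "compute_velocity", "velocity_from_source", "average_density",
    "initial_state", "step", "simulate",
]

_I_T1, _I_T8, _I_TR, _I_M, _I_I6, _I_I12, _I_P = (
    IDX["T1"], IDX["T8"], IDX["Tr"], IDX["M"], IDX["I6"], IDX["I12"], IDX["P"])


class PicardError(RuntimeError):
    """Picard iteration failed to converge within the iteration cap."""

    def __init__(self, iterations: int, residual: float):
        super().__init__(
            f"Picard iteration did not converge: {iterations} iterations, "
            f"relative residual {residual:.3e}")
        self.iterations = iterations
        self.residual = residual


@dataclass(frozen=True)
class RadialGrid:
    """Strictly increasing node positions from the centre to the boundary."""

    nodes: np.ndarray

    def __post_init__(self) -> None:
        nodes = np.asarray(self.nodes, dtype=float)
        object.__setattr__(self, "nodes", nodes)
        if nodes.size < 16:
            raise ValueError("radial grid needs at least 16 nodes")
        if nodes[0] != 0.0:
            raise ValueError("first node must sit at r = 0")
        if np.any(np.diff(nodes) <= 0):
            raise ValueError("nodes must be strictly increasing")

    @property
    def R(self) -> float:
        return float(self.nodes[-1])

    @classmethod
    def uniform(cls, R: float, n: int) -> "RadialGrid":
        return cls(np.linspace(0.0, R, n))


@dataclass(frozen=True)
class SolverOptions:
    """Discretisation controls (the model itself prescribes none)."""

    n_nodes: int = 101
    tau: float = 0.005            # time step (day)
    picard_tol: float = 1e-8      # relative change between Picard iterates
    picard_max: int = 50
    remesh_ratio: float = 5.0     # max adjacent-spacing ratio before re-gridding
    output_interval: float = 0.5  # cadence of recorded averages (day)
    rescale_initial_c: bool = True  # C(0) = theta - other cells = 0.3747, so the
    #   initial cells satisfy the total-density constraint exactly.  False keeps
    #   the printed 0.3774, whose 0.45% constraint violation is amplified as
    #   e^{3|ln(R_f/R_0)|} whenever the tumour shrinks strongly (the constraint
    #   equilibrium is repelling under contraction) and crashes high-dose runs.
    printed_initial_p: bool = False  # start P at the printed 8.3e-10 instead of
    #   the ratio-consistent rho_P*(T1+T8+eps_T*Tr)(0); the drug-free dynamics
    #   conserve P per unit of PD-1-bearing T-cell mass, so the printed value
    #   permanently weakens checkpoint inhibition (see docs/methods.md)

    def __post_init__(self) -> None:
        if self.tau <= 0 or self.picard_tol <= 0:
            raise ValueError("tau and picard_tol must be positive")


#: reduced-resolution options used for dose maps and sensitivity sweeps
COARSE_OPTIONS = SolverOptions(n_nodes=61, tau=0.01)


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def average_density(field: np.ndarray, r: np.ndarray) -> float:
    """Spatial average: total mass over tumour volume, int r^2 X dr / int r^2 dr.

    Both integrals use the trapezoid rule so a constant field averages to
    itself exactly (the shared quadrature bias cancels).
    """
    r = np.asarray(r, dtype=float)
    if r[-1] <= 0:
        raise ValueError("tumour radius must be positive")
    w = r * r
    return float(np.trapezoid(w * field, r) / np.trapezoid(w, r))


def velocity_from_source(S: np.ndarray, r: np.ndarray, theta: float) -> np.ndarray:
    """Velocity enforcing theta*div u = S: u = (1/(theta r^2)) int_0^r s^2 S ds.

    The source is reconstructed piecewise-linearly between nodes (the
    trapezoidal model) and integrated against s^2 exactly, so a constant S
    yields u = S*r/(3*theta) to machine precision even at the first node.
    """
    a, b = r[:-1], r[1:]
    sa, sb = S[:-1], S[1:]
    db = b - a
    # int_a^b s^2 (b-s) ds and int_a^b s^2 (s-a) ds
    m_a = b * (b ** 3 - a ** 3) / 3.0 - (b ** 4 - a ** 4) / 4.0
    m_b = (b ** 4 - a ** 4) / 4.0 - a * (b ** 3 - a ** 3) / 3.0
    pieces = (sa * m_a + sb * m_b) / db
    u = np.zeros_like(r)
    u[1:] = np.cumsum(pieces) / (theta * r[1:] ** 2)
    return u


def _kinetics(fields: np.ndarray, r: np.ndarray, params: ParameterSet, t: float,
              schedule_A, schedule_B, gamma_I12: float,
              ops: GridOps | None = None):
    """Evaluate reactions, chemotaxis and the velocity for one state."""
    if ops is None:
        ops = GridOps(r)
    chemo = chemotactic_divergence(fields[[_I_TR, _I_M]], fields[_I_I6], r,
                                   params.chi, ops)
    chemo_tr, chemo_m = chemo[0], chemo[1]
    src, loss = reaction_split(fields, params, t, schedule_A, schedule_B,
                               gamma_I12, chemo_div_Tr=chemo_tr)
    src_eff = src.copy()
    src_eff[_I_TR] -= chemo_tr
    src_eff[_I_M] -= chemo_m
    cells = list(CELL_FIELDS)
    S = np.sum(src[cells] - loss[cells] * fields[cells], axis=0) - chemo_tr - chemo_m
    u = velocity_from_source(S, r, params.theta)
    return src_eff, loss, S, u


def compute_velocity(state: TumorState, params: ParameterSet,
                     schedule_A: DoseSchedule | None = None,
                     schedule_B: DoseSchedule | None = None,
                     gamma_I12: float = 0.0) -> np.ndarray:
    """Radial velocity induced by the net cell production of ``state``."""
    _, _, _, u = _kinetics(state.fields, state.r, params, state.t,
                           schedule_A, schedule_B, gamma_I12)
    return u


# ---------------------------------------------------------------------------
# implicit field update
# ---------------------------------------------------------------------------

def _difference_weights(r: np.ndarray):
    """Three-point first/second-derivative weights on a non-uniform grid.

    Returns (w1m, w1c, w1p, w2m, w2c, w2p) for interior nodes 1..N-2, where
    X_r(i) = w1m*X[i-1] + w1c*X[i] + w1p*X[i+1] and likewise X_rr with w2.
    """
    h1 = r[1:-1] - r[:-2]
    h2 = r[2:] - r[1:-1]
    w1m = -h2 / (h1 * (h1 + h2))
    w1c = (h2 - h1) / (h1 * h2)
    w1p = h1 / (h2 * (h1 + h2))
    w2m = 2.0 / (h1 * (h1 + h2))
    w2c = -2.0 / (h1 * h2)
    w2p = 2.0 / (h2 * (h1 + h2))
    return w1m, w1c, w1p, w2m, w2c, w2p


def assemble_field_system(x_old: np.ndarray, r: np.ndarray, tau: float,
                          delta: float, src: np.ndarray, loss: np.ndarray,
                          u: np.ndarray | None, u_r: np.ndarray | None,
                          bc: str = "neumann", sigma_t: float = 0.0,
                          x_hat: float = 0.0):
    """Banded system (ab, rhs) for one implicit field update.

    ``bc`` selects the outer-boundary closure: ``"neumann"`` (no flux) or
    ``"robin"`` (T-cell influx with rate ``sigma_t`` towards ``x_hat``),
    both discretised one-sided at r = R.  ``u``/``u_r`` of None disables
    advection (cytokines and drugs).  Exposed separately so that tests can
    compare the tridiagonal solve against a dense direct solve.
    """
    n = r.size
    w1m, w1c, w1p, w2m, w2c, w2p = _difference_weights(r)
    rin = r[1:-1]
    if u is None:
        u_in = u_rin = 0.0
        u_r0 = 0.0
    else:
        u_in = u[1:-1]
        u_rin = u_r[1:-1]
        u_r0 = u_r[0]

    # linear operator L such that dX/dt = L X + src  (interior rows)
    conv = delta * 2.0 / rin - u_in
    lo_in = delta * w2m + conv * w1m
    di_in = delta * w2c + conv * w1c - (2.0 / rin) * u_in - u_rin - loss[1:-1]
    up_in = delta * w2p + conv * w1p

    ab = np.zeros((3, n))
    rhs = np.empty(n)
    # interior: (1/tau - L) x_new = x_old/tau + src
    ab[0, 2:] = -up_in
    ab[1, 1:-1] = 1.0 / tau - di_in
    ab[2, :-2] = -lo_in
    rhs[1:-1] = x_old[1:-1] / tau + src[1:-1]

    # r = 0: symmetry; Laplacian -> 3 X_rr = 6 (X1 - X0)/h^2, div u -> 3 u_r
    h0 = r[1] - r[0]
    lap0 = 6.0 * delta / (h0 * h0)
    di0 = -lap0 - 3.0 * u_r0 - loss[0]
    ab[0, 1] = -lap0
    ab[1, 0] = 1.0 / tau - di0
    rhs[0] = x_old[0] / tau + src[0]

    # r = R: PDE row with a ghost node eliminated through the flux condition
    # X_r = -beta (X - x_hat); beta = 0 is homogeneous Neumann, beta = sigma_T
    # the Robin T-cell influx.
    if bc == "neumann":
        beta, x_hat = 0.0, 0.0
    elif bc == "robin":
        beta = sigma_t
    else:  # pragma: no cover
        raise ValueError(f"unknown boundary condition {bc!r}")
    hb = r[-1] - r[-2]
    rb = r[-1]
    if u is None:
        ub = urb = 0.0
    else:
        ub, urb = u[-1], u_r[-1]
    lo_b = 2.0 * delta / (hb * hb)
    di_b = (-lo_b - 2.0 * delta * beta * (1.0 / hb + 1.0 / rb)
            + ub * beta - (2.0 / rb) * ub - urb - loss[-1])
    const_b = x_hat * beta * (2.0 * delta * (1.0 / hb + 1.0 / rb) - ub)
    ab[2, -2] = -lo_b
    ab[1, -1] = 1.0 / tau - di_b
    rhs[-1] = x_old[-1] / tau + src[-1] + const_b
    return ab, rhs


_ADV_MASK = np.zeros(N_FIELDS)
for _k in ADVECTED_FIELDS:
    _ADV_MASK[_k] = 1.0
_ADV_MASK = _ADV_MASK[:, None]


def _solve_fields(x_old: np.ndarray, x_lag: np.ndarray, ops: GridOps,
                  tau: float, deltas: np.ndarray, src: np.ndarray,
                  loss: np.ndarray, u: np.ndarray, params: ParameterSet) -> np.ndarray:
    """One Picard sweep: implicit tridiagonal solve for every field.

    Assembly is vectorised over the fields; each system is the same one
    :func:`assemble_field_system` builds (the tests compare the two).
    """
    r = ops.r
    u_r = ops.deriv(u)
    u_r[0] = u[1] / r[1]  # u is odd in r, u(0) = 0
    i12_b = x_lag[_I_I12, -1]
    sigma_t = params.sigma_0 * i12_b / (i12_b + params.K_I12)

    dl = deltas[:, None]
    u_eff = _ADV_MASK * u
    ur_eff = _ADV_MASK * u_r
    rin = r[1:-1]

    # coefficients of X_{i-1}, X_i, X_{i+1} in the linear RHS operator
    conv = dl * (2.0 / rin) - u_eff[:, 1:-1]
    lo = np.zeros_like(x_old)
    di = np.empty_like(x_old)
    up = np.zeros_like(x_old)
    lo[:, 1:-1] = dl * ops.w2m + conv * ops.w1m
    di[:, 1:-1] = (dl * ops.w2c + conv * ops.w1c
                   - (2.0 / rin) * u_eff[:, 1:-1] - ur_eff[:, 1:-1] - loss[:, 1:-1])
    up[:, 1:-1] = dl * ops.w2p + conv * ops.w1p

    # origin row: Laplacian -> 3 X_rr, divergence -> 3 u_r
    h0 = r[1] - r[0]
    lap0 = 6.0 * deltas / (h0 * h0)
    di[:, 0] = -lap0 - 3.0 * ur_eff[:, 0] - loss[:, 0]
    up[:, 0] = lap0

    # outer boundary: ghost-node PDE row (see assemble_field_system)
    hb = r[-1] - r[-2]
    rb = r[-1]
    lo_b = 2.0 * dl[:, 0] / (hb * hb)
    beta = np.zeros(N_FIELDS)
    x_hat = np.zeros(N_FIELDS)
    beta[_I_T1] = beta[_I_T8] = sigma_t
    x_hat[_I_T1], x_hat[_I_T8] = params.That_1, params.That_8
    ub = u_eff[:, -1]
    lo[:, -1] = lo_b
    di[:, -1] = (-lo_b - 2.0 * dl[:, 0] * beta * (1.0 / hb + 1.0 / rb)
                 + ub * beta - (2.0 / rb) * ub - ur_eff[:, -1] - loss[:, -1])
    const_b = x_hat * beta * (2.0 * dl[:, 0] * (1.0 / hb + 1.0 / rb) - ub)

    rhs = x_old / tau + src
    rhs[:, -1] += const_b

    # implicit Euler: (1/tau - L) x = x_old/tau + src
    band_l = -lo
    band_d = 1.0 / tau - di
    band_u = -up

    x_new = np.empty_like(x_old)
    for k in range(N_FIELDS):
        _, _, _, x_new[k], info = dgtsv(band_l[k, 1:], band_d[k], band_u[k, :-1],
                                        rhs[k])
        if info != 0:  # pragma: no cover
            raise RuntimeError(f"tridiagonal solve failed for field {FIELD_NAMES[k]}")
    return x_new


def _remesh(fields: np.ndarray, r: np.ndarray, n: int):
    """Re-grid to a uniform mesh on [0, R] with monotone cubic interpolation."""
    r_new = np.linspace(0.0, r[-1], n)
    out = np.empty((fields.shape[0], n))
    for k in range(fields.shape[0]):
        out[k] = PchipInterpolator(r, fields[k])(r_new)
    return out, r_new


def step(state: TumorState, tau: float, params: ParameterSet,
         schedule_A: DoseSchedule | None = None,
         schedule_B: DoseSchedule | None = None,
         options: SolverOptions | None = None,
         gamma_I12: float = 0.0) -> TumorState:
    """Advance the state by one implicit time step and move the mesh."""
    opts = options or SolverOptions()
    if tau > opts.tau:
        raise ValueError("tau exceeds the configured maximum step")
    r = state.r
    x_old = state.fields
    t_new = state.t + tau
    deltas = diffusion_coefficients(params)
    ops = GridOps(r)

    x = x_old.copy()
    residual = np.inf
    for iteration in range(1, opts.picard_max + 1):
        src, loss, _, u = _kinetics(x, r, params, t_new,
                                    schedule_A, schedule_B, gamma_I12, ops)
        x_next = _solve_fields(x_old, x, ops, tau, deltas, src, loss, u, params)
        scale = np.max(np.abs(x), axis=1) + 1e-300
        residual = float(np.max(np.max(np.abs(x_next - x), axis=1) / scale))
        x = x_next
        if residual < opts.picard_tol:
            break
    else:
        raise PicardError(opts.picard_max, residual)

    # positivity clamp (the scheme is not positivity-preserving)
    clipped = float(-x[x < 0].sum())
    np.clip(x, 0.0, None, out=x)

    # mesh motion with the converged velocity
    _, _, _, u = _kinetics(x, r, params, t_new, schedule_A, schedule_B,
                           gamma_I12, ops)
    r_new = r + u * tau
    r_new[0] = 0.0
    dr = np.diff(r_new)
    if np.any(dr <= 0):
        raise RuntimeError(f"mesh tangling at t = {t_new:.3f} day")
    ratio = float(np.max(dr[1:] / dr[:-1]))
    ratio = max(ratio, float(np.max(dr[:-1] / dr[1:])))
    if ratio > opts.remesh_ratio:
        x, r_new = _remesh(x, r_new, r.size)

    return TumorState(x, r_new, t_new, u, state.clipped_mass + clipped)


# ---------------------------------------------------------------------------
# full simulation
# ---------------------------------------------------------------------------

#: initial cell densities (g/cm^3) — the printed values; they sum to 0.6066,
#: slightly above theta = 0.6039 (see SolverOptions.rescale_initial_c)
INITIAL_CELLS = {"D": 2e-4, "T1": 4e-3, "T8": 2e-3, "Tr": 3e-3,
                 "M": 0.22, "C": 0.3774}
INITIAL_CYTOKINES = {"I12": 4e-10, "I2": 4.74e-11, "Tb": 2.62e-13,
                     "I6": 3.06e-11, "I10": 9.66e-11, "P": 8.3e-10}
INITIAL_RADIUS = 0.01  # cm


def initial_state(params: ParameterSet, options: SolverOptions) -> TumorState:
    """Uniform initial state on [0, 0.01 cm]."""
    grid = RadialGrid.uniform(INITIAL_RADIUS, options.n_nodes)
    fields = np.zeros((N_FIELDS, options.n_nodes))
    values = dict(INITIAL_CELLS, **INITIAL_CYTOKINES)
    if options.rescale_initial_c:
        others = sum(v for k, v in INITIAL_CELLS.items() if k != "C")
        values["C"] = params.theta - others
    if not options.printed_initial_p:
        values["P"] = params.rho_P * (values["T1"] + values["T8"]
                                      + params.eps_T * values["Tr"])
    for name, value in values.items():
        fields[IDX[name]] = value
    return TumorState(fields, grid.nodes, 0.0)


@dataclass
class SimulationResult:
    """Time series of the free boundary and per-species spatial averages."""

    t: np.ndarray
    R: np.ndarray
    averages: pd.DataFrame          # one column per species, indexed by t
    final_state: TumorState
    metadata: dict = _dcfield(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        frame = self.averages.copy()
        frame.insert(0, "R", self.R)
        frame.insert(0, "t", self.t)
        return frame.reset_index(drop=True)

    def radius_at(self, t: float) -> float:
        return float(np.interp(t, self.t, self.R))

    def volume_doubling_time(self) -> float:
        """First time at which the tumour volume (prop. to R^3) has doubled."""
        vol = (self.R / self.R[0]) ** 3
        if vol.max() < 2.0:
            raise ValueError("volume never doubles within the simulated window")
        k = int(np.argmax(vol >= 2.0))
        return float(np.interp(2.0, vol[k - 1:k + 1], self.t[k - 1:k + 1]))

    def exponential_doubling_time(self, t_start: float = 5.0,
                                  t_end: float = 35.0) -> float:
        """Volume doubling time of the exponential growth phase.

        Least-squares slope of log V over [t_start, t_end], skipping the brief
        insertion transient during which the implanted immune-cell load relaxes
        (the printed initial MDSC density exceeds its influx level, so the
        tumour shrinks for about half a day before settling into exponential
        growth).
        """
        mask = (self.t >= t_start) & (self.t <= t_end)
        if mask.sum() < 3:
            raise ValueError("window holds fewer than 3 recorded points")
        log_v = 3.0 * np.log(self.R[mask])
        slope = np.polyfit(self.t[mask], log_v, 1)[0]
        if slope <= 0:
            raise ValueError("no growth in the requested window")
        return float(np.log(2.0) / slope)


def simulate(params: ParameterSet | None = None,
             schedule_A: DoseSchedule | None = None,
             schedule_B: DoseSchedule | None = None,
             t_end: float = 60.0,
             options: SolverOptions | None = None,
             gamma_I12: float = 0.0) -> SimulationResult:
    """Run the free-boundary model from the standard initial state to ``t_end``.

    The default (no schedules) is the untreated control; the tumour radius
    grows from 0.01 cm to about 0.037 cm over 60 days with baseline
    parameters.
    """
    if t_end < 0:
        raise ValueError("t_end must be non-negative")
    p = params or baseline_parameters()
    opts = options or SolverOptions()
    state = initial_state(p, opts)

    times = [0.0]
    radii = [state.R]
    rows = [[average_density(state.fields[k], state.r) for k in range(N_FIELDS)]]
    n_steps = int(round(t_end / opts.tau))
    record_every = max(1, int(round(opts.output_interval / opts.tau)))
    for k in range(1, n_steps + 1):
        state = step(state, opts.tau, p, schedule_A, schedule_B, opts, gamma_I12)
        if k % record_every == 0 or k == n_steps:
            times.append(state.t)
            radii.append(state.R)
            rows.append([average_density(state.fields[j], state.r)
                         for j in range(N_FIELDS)])

    averages = pd.DataFrame(rows, columns=list(FIELD_NAMES))
    meta = {
        "t_end": t_end,
        "gamma_A": 0.0 if schedule_A is None else schedule_A.gamma,
        "gamma_B": 0.0 if schedule_B is None else schedule_B.gamma,
        "gamma_I12": gamma_I12,
        "n_nodes": opts.n_nodes,
        "tau": opts.tau,
        "clipped_mass": state.clipped_mass,
    }
    return SimulationResult(np.array(times), np.array(radii), averages, state, meta)
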