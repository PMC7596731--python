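"""Time integration, steady states under moiety constraints, parameter sweeps.

Steady states are found by damped Newton iteration on the conservation-reduced
system (the state is parameterised on the affine manifold defined by the
moiety totals, so Newton cannot drift off the conserved pools), warm-started
from the previous solution during sweeps and protected against leaving the
non-negative orthant by step halving.  When Newton stalls the solver falls
back to stiff integration towards quiescence and retries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.linalg import lu_factor, lu_solve, null_space

from .network import Network, rate_jacobian, reaction_rates
from .params import ParameterSet
from .thermo import apply_em_b

__all__ = [
    "Trajectory",
    "SteadyState",
    "SweepResult",
    "integrate",
    "solve_steady",
    "sweep",
    "SteadyStateError",
    "SWEEP_AXES",
]

#: recognised sweep axes and how each one modifies the parameter set
SWEEP_AXES = ("succinate", "AA5", "k29", "k1", "k10", "Em_b")

_AXIS_PARAM = {"succinate": "succ", "AA5": "aa5", "k29": "kf29",
               "k1": "kf1", "k10": "kf10"}


class SteadyStateError(RuntimeError):
    """Neither Newton iteration nor relaxation integration converged."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


def axis_params(params: ParameterSet, axis: str, value: float) -> ParameterSet:
    """Parameter set for one point of a sweep axis."""
    if axis == "Em_b":
        return apply_em_b(None, params, value)
    if axis not in _AXIS_PARAM:
        raise ValueError(f"unknown sweep axis {axis!r}; expected one of {SWEEP_AXES}")
    return params.copy(**{_AXIS_PARAM[axis]: float(value)})


# ---------------------------------------------------------------------------
# results containers
# ---------------------------------------------------------------------------
@dataclass
class Trajectory:
    """Concentrations (and lazily computed fluxes) along a time grid."""

    network: Network
    params: ParameterSet
    t: np.ndarray                     # (nt,) seconds
    X: np.ndarray                     # (nt, n_free) uM

    def conc(self, sid: str) -> np.ndarray:
        return self.X[:, self.network.free_index(sid)]

    def fluxes(self) -> np.ndarray:
        """Net flux matrix (nt, n_reactions), uM/s."""
        return np.array(
            [reaction_rates(self.network, x, self.params)[0] for x in self.X]
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.network.free_ids)
        df.insert(0, "time_s", self.t)
        flux = self.fluxes()
        for j, rid in enumerate(self.network.rids):
            df[f"v{rid}"] = flux[:, j]
        return df


@dataclass
class SteadyState:
    """A converged stationary point with per-reaction flux decomposition."""

    network: Network
    params: ParameterSet
    x: np.ndarray                     # free-species concentrations, uM
    net: np.ndarray                   # per-reaction net rates, uM/s
    fwd: np.ndarray
    rev: np.ndarray
    residual: float                   # max |dC/dt| over free species, uM/s
    converged: bool = True
    method: str = "newton"
    n_iter: int = 0

    def conc(self, sid: str) -> float:
        return float(self.x[self.network.free_index(sid)])

    def flux(self, rid: str) -> float:
        return float(self.net[self.network.rid_index(rid)])

    def flux_forward(self, rid: str) -> float:
        return float(self.fwd[self.network.rid_index(rid)])

    def flux_reverse(self, rid: str) -> float:
        return float(self.rev[self.network.rid_index(rid)])


@dataclass
class SweepResult:
    """Steady states along one axis; failed points are flagged, never dropped."""

    axis: str
    values: np.ndarray
    states: list[SteadyState | None]
    errors: list[str | None] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.errors:
            self.errors = [None] * len(self.states)

    @property
    def ok(self) -> bool:
        return all(s is not None and s.converged for s in self.states)

    def observable(self, fn: Callable[[SteadyState], float]) -> np.ndarray:
        return np.array(
            [np.nan if s is None else fn(s) for s in self.states]
        )


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------
def _rhs(network: Network, params: ParameterSet) -> Callable[[float, np.ndarray], np.ndarray]:
    N = network.N

    def fun(t: float, x: np.ndarray) -> np.ndarray:
        net, _, _ = reaction_rates(network, np.maximum(x, 0.0), params)
        return N @ net

    return fun


def _jac(network: Network, params: ParameterSet) -> Callable[[float, np.ndarray], np.ndarray]:
    N = network.N

    def fun(t: float, x: np.ndarray) -> np.ndarray:
        return N @ rate_jacobian(network, np.maximum(x, 0.0), params)

    return fun


def integrate(
    network: Network,
    params: ParameterSet,
    state0: np.ndarray | None = None,
    t_grid: Sequence[float] | np.ndarray = (0.0, 100.0),
    rtol: float = 1e-8,
    atol: float = 1e-12,
) -> Trajectory:
    """Stiff-safe integration of the mass-action ODE system on ``t_grid``."""
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or len(t_grid) < 1 or np.any(np.diff(t_grid) <= 0):
        if not (t_grid.ndim == 1 and len(t_grid) == 1):
            raise ValueError("t_grid must be strictly increasing")
    x0 = network.initial_state(params) if state0 is None else np.asarray(state0, float)
    if len(t_grid) == 1:
        return Trajectory(network, params, t_grid, x0[None, :].copy())
    sol = solve_ivp(
        _rhs(network, params),
        (t_grid[0], t_grid[-1]),
        x0,
        method="BDF",   # electron-transfer constants span ~10 decades
        t_eval=t_grid,
        jac=_jac(network, params),
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise SteadyStateError(
            f"integration failed at t = {sol.t[-1] if len(sol.t) else t_grid[0]:g} s: "
            f"{sol.message}"
        )
    X = np.maximum(sol.y.T, -1e-9)
    X[0] = x0
    return Trajectory(network, params, t_grid, X)


# ---------------------------------------------------------------------------
# steady state
# ---------------------------------------------------------------------------
def _reduction_basis(network: Network) -> np.ndarray:
    """Orthonormal basis of the conservation-constrained tangent space."""
    Z = getattr(network, "_reduction_basis_cache", None)
    if Z is None:
        C = network.conservation_matrix()
        Z = null_space(C) if C.size else np.eye(network.n_free)
        network._reduction_basis_cache = Z
    return Z


def _newton(
    network: Network,
    params: ParameterSet,
    x0: np.ndarray,
    tol: float,
    max_iter: int = 200,
) -> tuple[np.ndarray, float, int, bool]:
    """Damped Newton on the conservation-reduced system.

    The moiety totals of ``x0`` are preserved exactly: updates live in the
    null space of the conservation matrix.  When the full Newton direction
    stalls, the iteration switches to pseudo-transient continuation
    (implicit-Euler steps with an adaptive pseudo time step), which follows
    the stiff relaxation path towards the stationary point and turns back
    into Newton as the time step grows.
    """
    Z = _reduction_basis(network)
    N = network.N
    # the state is iterated in extended precision: near-equilibrium electron
    # transfers make dC/dt so sensitive that the converged update can be
    # smaller than the float64 spacing of the concentrations
    x = np.maximum(np.asarray(x0, dtype=np.longdouble), 0.0)

    def fullres(xv: np.ndarray) -> np.ndarray:
        net, _, _ = reaction_rates(network, xv, params)
        return N @ net

    C = network.conservation_matrix()
    totals0 = C @ np.asarray(x0, dtype=np.longdouble) if C.size else None

    def project_totals(xv: np.ndarray) -> np.ndarray:
        """Minimum-norm correction back onto the moiety-total manifold."""
        if totals0 is None:
            return xv
        err = (C @ xv - totals0).astype(float)
        corr = C.T @ np.linalg.solve(C @ C.T, err)
        return np.maximum(xv - corr, 0.0)

    f = fullres(x)
    lam = 1.0
    for it in range(1, max_iter + 1):
        if np.max(np.abs(f)) < tol:
            # clipping to the non-negative orthant may have nudged the
            # totals; repair and re-check before declaring convergence
            x = project_totals(x)
            f = fullres(x)
            if np.max(np.abs(f)) < tol:
                return x, float(np.max(np.abs(f))), it - 1, True
        J = N @ rate_jacobian(network, x.astype(float), params)
        Jr = Z.T @ J @ Z
        g = (Z.T @ f).astype(float)   # LAPACK path needs float64
        try:
            lu = lu_factor(Jr)
            du = lu_solve(lu, -g)
        except (np.linalg.LinAlgError, ValueError):
            return x, float(np.max(np.abs(f))), it, False
        dx = Z @ du
        norm_du = np.linalg.norm(du)
        # affine-invariant (natural monotonicity) damping: compare the
        # simplified Newton correction at the candidate against |du| --
        # robust where the raw residual norm is dominated by stiff rows
        lam = min(1.0, 4.0 * lam)
        accepted = False
        for _ in range(40):
            x_new = np.maximum(x + lam * dx, 0.0)
            try:
                f_new = fullres(x_new)
            except (ValueError, FloatingPointError):
                lam *= 0.5
                continue
            du_bar = lu_solve(lu, -(Z.T @ f_new).astype(float))
            if np.linalg.norm(du_bar) <= (1.0 - 0.5 * lam) * norm_du or \
                    np.max(np.abs(f_new)) < tol:
                x, f = x_new, f_new
                accepted = True
                break
            lam *= 0.5
        if not accepted:
            return x, float(np.max(np.abs(f))), it, False
    return x, float(np.max(np.abs(f))), max_iter, np.max(np.abs(f)) < tol


def solve_steady(
    network: Network,
    params: ParameterSet,
    guess: np.ndarray | None = None,
    tol: float = 1e-9,
    relax_time: float = 1e6,
) -> SteadyState:
    """Stationary solution with residual max|dC/dt| below ``tol`` (uM/s).

    Without a guess the solver starts from the fully oxidised initial
    convention, relaxes by stiff integration and polishes with Newton; with a
    (warm-start) guess Newton is tried first and integration is the fallback.
    """
    if guess is not None:
        g = np.asarray(guess, float)
        if np.any(g < 0):
            raise ValueError("guess must be non-negative")
        x, res, nit, ok = _newton(network, params, g, tol)
        if ok:
            return _package(network, params, x, res, "newton", nit)
        start = g
    else:
        start = network.initial_state(params)

    # relaxation: integrate towards quiescence, then polish
    x = start
    t_end = 1e3
    last_res = np.inf
    for _ in range(5):
        traj = integrate(network, params, x, (0.0, t_end), rtol=1e-8, atol=1e-12)
        x = np.maximum(traj.X[-1], 0.0)
        xn, res, nit, ok = _newton(network, params, x, tol)
        if ok:
            return _package(network, params, xn, res, "integrate+newton", nit)
        last_res = res
        t_end = min(t_end * 30.0, relax_time)
    raise SteadyStateError(
        f"steady-state search did not converge (residual {last_res:.3e} uM/s)",
        residual=last_res,
    )


def _package(network: Network, params: ParameterSet, x: np.ndarray,
             res: float, method: str, nit: int) -> SteadyState:
    x = np.maximum(x, 0.0)
    net, fwd, rev = reaction_rates(network, x, params)
    return SteadyState(network, params, x, net, fwd, rev, res, True, method, nit)


# ---------------------------------------------------------------------------
# sweeps
# ---------------------------------------------------------------------------
def sweep(
    network: Network,
    params: ParameterSet,
    axis: str,
    values: Sequence[float] | np.ndarray,
    warm_start: bool = True,
    tol: float = 1e-9,
) -> SweepResult:
    """Steady states along an experimental axis with warm-start continuation.

    Axes: succinate and AA5 vary the clamped boundary concentrations; k29,
    k1 and k10 vary the corresponding catalytic constants; Em_b re-derives
    the heme-adjacent equilibrium constants through the Nernst relation.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or len(values) == 0:
        raise ValueError("values must be a non-empty 1-D sequence")
    if not np.all(np.isfinite(values)):
        raise ValueError("axis values must be finite")
    if axis not in SWEEP_AXES:
        raise ValueError(f"unknown sweep axis {axis!r}; expected one of {SWEEP_AXES}")

    states: list[SteadyState | None] = []
    errors: list[str | None] = []
    prev: np.ndarray | None = None
    for v in values:
        p = axis_params(params, axis, v)
        try:
            st = solve_steady(network, p, guess=prev if warm_start else None, tol=tol)
            states.append(st)
            errors.append(None)
            prev = st.x.copy()
        except SteadyStateError as exc:  # flagged, not dropped
            states.append(None)
            errors.append(str(exc))
            prev = None
    return SweepResult(axis, values, states, errors)
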