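"""Derived quantities: site-resolved ROS rates, flux decomposition,
curve-shape classification and apparent Michaelis diagnostics.

The total H2O2 release rate is vH2O2tot = v22 + v22d + v28: hydrogen peroxide
made directly by FADH2 in the assembled and disintegrated subcomplexes plus
dismutation of superoxide (two O2- give one H2O2).  At any steady state the
dismutation rate equals half of the summed superoxide production, so
vH2O2tot also equals the flux of the H2O2 efflux reaction.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .network import Network, NetworkError, reaction_rates
from .params import ParameterSet
from .solver import SteadyState, SweepResult

__all__ = [
    "RosBreakdown",
    "FluxSplit",
    "CurveShape",
    "ros_breakdown",
    "flux_split",
    "classify_curve",
    "inhibition_diagnostics",
    "OBSERVABLES",
    "get_observable",
    "observable_table",
]

#: superoxide-producing reactions (one O2- per event)
SUPEROXIDE_RIDS = ("23", "24", "25", "26", "23d", "24d", "25d", "26d")


@dataclass
class RosBreakdown:
    """Per-site ROS rates (uM/s) at a steady state."""

    v22: float = 0.0     # FADH2 -> H2O2, assembled
    v23: float = 0.0     # FADH2 -> O2-, assembled
    v24: float = 0.0     # FADH. -> O2-
    v25: float = 0.0     # [3Fe-4S]- -> O2-
    v26: float = 0.0     # bound semiquinone -> O2-
    v22d: float = 0.0
    v23d: float = 0.0
    v24d: float = 0.0
    v25d: float = 0.0
    v28: float = 0.0     # dismutation
    vh2o2tot: float = 0.0

    def superoxide_total(self) -> float:
        return self.v23 + self.v24 + self.v25 + self.v26 + \
            self.v23d + self.v24d + self.v25d


@dataclass
class FluxSplit:
    rid: str
    forward: float
    reverse: float
    netto: float


@dataclass
class CurveShape:
    classification: str          # bell | hyperbolic-monotone | sigmoid-monotone
    peak_x: float
    peak_y: float
    vmax: float | None = None
    km: float | None = None
    residual: float | None = None


def _safe_flux(steady: SteadyState, rid: str) -> float:
    try:
        return steady.flux(rid)
    except ValueError:
        return 0.0


def ros_breakdown(steady: SteadyState) -> RosBreakdown:
    """Site-resolved ROS rates; reactions absent from the topology count 0."""
    vals = {
        f.name: _safe_flux(steady, f.name.lstrip("v"))
        for f in fields(RosBreakdown) if f.name.startswith("v2")
    }
    out = RosBreakdown(**vals)
    out.vh2o2tot = out.v22 + out.v22d + out.v28
    return out


def flux_split(network: Network, state: np.ndarray, params: ParameterSet,
               rid: str) -> FluxSplit:
    """Unidirectional forward/reverse decomposition of one reversible rate law."""
    try:
        reaction = network.reaction_by_rid[rid]
    except KeyError:
        raise NetworkError(f"unknown reaction {rid!r}") from None
    if not reaction.reversible:
        raise NetworkError(f"reaction {rid!r} is irreversible; no flux split")
    j = network.rid_index(rid)
    _, fwd, rev = reaction_rates(network, state, params)
    forward, reverse = float(fwd[j]), float(rev[j])
    return FluxSplit(rid, forward, reverse, forward - reverse)


def _mm(x: np.ndarray, vmax: float, km: float) -> np.ndarray:
    return vmax * x / (km + x)


def fit_michaelis(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Nonlinear least-squares Michaelis-Menten fit.

    Initialised from the maximal rate and the half-max crossing (a
    double-reciprocal transform would bias the low-signal points).  Returns
    (vmax, km, relative rms residual).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    v0 = float(np.max(y))
    if v0 <= 0:
        return 0.0, float("nan"), 0.0
    half = np.argmin(np.abs(y - 0.5 * v0))
    km0 = float(max(x[half], x[x > 0].min() if np.any(x > 0) else 1.0))
    popt, _ = curve_fit(_mm, x, y, p0=(v0, km0),
                        bounds=([0.0, 0.0], [np.inf, np.inf]), maxfev=20000)
    resid = float(np.sqrt(np.mean((_mm(x, *popt) - y) ** 2)) / max(v0, 1e-300))
    return float(popt[0]), float(popt[1]), resid


def classify_curve(
    x: Sequence[float] | np.ndarray,
    y: Sequence[float] | np.ndarray,
    bell_threshold: float = 0.05,
    refine_peak: bool = True,
) -> CurveShape:
    """Classify a rate-versus-substrate curve as bell or monotone.

    Bell: an interior maximum exceeding both endpoints by ``bell_threshold``
    relative.  Otherwise a Michaelis-Menten fit is attempted; a relative rms
    misfit above 5 % (an inflected, sub-hyperbolic rise) is reported as
    sigmoid-monotone.  The peak location is the grid argmax with optional
    quadratic refinement.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 5:
        raise ValueError("classification needs at least 5 points")
    if np.any(np.diff(x) <= 0):
        raise ValueError("x must be strictly increasing")
    i = int(np.argmax(y))
    peak_x, peak_y = float(x[i]), float(y[i])
    interior = 0 < i < len(x) - 1
    scale = max(abs(y[0]), abs(y[-1]), 1e-300)
    is_bell = interior and y[i] > (1 + bell_threshold) * y[0] \
        and y[i] > (1 + bell_threshold) * y[-1] and (y[i] - max(y[0], y[-1])) > 0
    if is_bell:
        if refine_peak and interior:
            # quadratic through the three points around the argmax (log-x grid)
            lx = np.log(x[i - 1:i + 2])
            c = np.polyfit(lx, y[i - 1:i + 2], 2)
            if c[0] < 0:
                lpx = -c[1] / (2 * c[0])
                if lx[0] <= lpx <= lx[2]:
                    peak_x = float(np.exp(lpx))
                    peak_y = float(np.polyval(c, lpx))
        return CurveShape("bell", peak_x, peak_y)
    try:
        vmax, km, resid = fit_michaelis(x, y)
    except RuntimeError:
        return CurveShape("sigmoid-monotone", peak_x, peak_y, None, None, None)
    cls = "hyperbolic-monotone" if resid <= 0.05 else "sigmoid-monotone"
    return CurveShape(cls, peak_x, peak_y, vmax, km, resid)


def inhibition_diagnostics(
    sweeps_by_aa5: dict[float, SweepResult],
    observable: str = "v20",
) -> pd.DataFrame:
    """Apparent (Vmax, Km) of an observable vs succinate per AA5 level.

    For a competitive Q-site inhibitor both apparent constants of the
    ubiquinol output decrease with the inhibitor concentration.
    """
    rows = []
    for aa5, sw in sorted(sweeps_by_aa5.items()):
        y = sw.observable(lambda s: get_observable(s, observable))
        try:
            vmax, km, resid = fit_michaelis(sw.values, y)
            rows.append({"aa5": aa5, "vmax": vmax, "km": km,
                         "residual": resid, "ok": True})
        except RuntimeError as exc:
            rows.append({"aa5": aa5, "vmax": np.nan, "km": np.nan,
                         "residual": np.nan, "ok": False})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# observable registry
# ---------------------------------------------------------------------------
def _flux_obs(rid: str) -> Callable[[SteadyState], float]:
    return lambda s: _safe_flux(s, rid)


OBSERVABLES: dict[str, Callable[[SteadyState], float]] = {
    "vH2O2tot": lambda s: ros_breakdown(s).vh2o2tot,
    "superoxide_total": lambda s: ros_breakdown(s).superoxide_total(),
    "b_red": lambda s: s.conc("b_red"),
    "fadh2": lambda s: s.conc("fadh2"),
}
for _rid in ("6", "8", "16", "20", "22", "23", "24", "25", "26", "28", "29", "30",
             "22d", "23d", "24d", "25d"):
    OBSERVABLES[f"v{_rid}"] = _flux_obs(_rid)
OBSERVABLES["v22total"] = lambda s: _safe_flux(s, "22") + _safe_flux(s, "22d")
OBSERVABLES["v23total"] = lambda s: _safe_flux(s, "23") + _safe_flux(s, "23d")


def get_observable(steady: SteadyState, name: str) -> float:
    """Evaluate a named observable; species ids are accepted directly."""
    if name in OBSERVABLES:
        return float(OBSERVABLES[name](steady))
    if name in steady.network.species_by_id and not \
            steady.network.species_by_id[name].clamped:
        return steady.conc(name)
    raise KeyError(f"unknown observable {name!r}")


def observable_table(sw: SweepResult, names: Sequence[str]) -> pd.DataFrame:
    """Tidy table: one row per axis value, one column per observable."""
    data: dict[str, np.ndarray] = {sw.axis: sw.values}
    data["converged"] = np.array([s is not None for s in sw.states])
    for name in names:
        data[name] = sw.observable(lambda s, n=name: get_observable(s, n))
    return pd.DataFrame(data)
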