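"""Least-squares calibration against titration datasets.

A titration dataset holds measured steady-state observables along an
experimental axis (succinate or inhibitor concentration).  The objective is
the weighted sum of squared residuals between measured points and the model's
stationary values.  The experimental points of the original study exist only
as figure symbols, so a bundled synthetic-dataset generator emulates the two
calibration designs (an AA5 titration at fixed succinate and a succinate
titration at fixed AA5) with multiplicative Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .network import Network
from .observables import get_observable
from .params import ParameterSet
from .solver import SteadyStateError, axis_params, solve_steady

__all__ = [
    "TitrationDataset",
    "FitResult",
    "ssr",
    "fit",
    "generate_synthetic_dataset",
]

_COLUMNS = ["axis", "axis_value", "observable", "value", "weight"]


@dataclass
class TitrationDataset:
    """Rows of (axis, axis_value, observable, value, weight) plus metadata.

    ``metadata`` records clamps in effect for the whole design, e.g.
    ``{"succ": 100.0}`` for an AA5 titration at 100 uM succinate.  Any extra
    column whose name is a parameter acts as a per-row clamp, which lets one
    dataset combine several titration designs (an AA5 titration at fixed
    succinate together with a succinate titration at fixed AA5).
    """

    data: pd.DataFrame
    metadata: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in _COLUMNS if c not in self.data.columns]
        if "weight" in missing:
            self.data = self.data.assign(weight=1.0)
            missing.remove("weight")
        if missing:
            raise ValueError(f"dataset is missing columns {missing}")
        if not np.all(np.isfinite(self.data["axis_value"])):
            raise ValueError("axis values must be finite")

    def __len__(self) -> int:
        return len(self.data)

    @classmethod
    def from_csv(cls, path, **metadata: float) -> "TitrationDataset":
        return cls(pd.read_csv(path), dict(metadata))

    def to_csv(self, path) -> None:
        extra = [c for c in self.data.columns if c not in _COLUMNS]
        self.data[_COLUMNS + extra].to_csv(path, index=False)


def _clamped(params: ParameterSet, metadata: Mapping[str, float]) -> ParameterSet:
    return params.copy(**dict(metadata)) if metadata else params


def predict(params: ParameterSet, dataset: TitrationDataset,
            network: Network) -> np.ndarray:
    """Model steady-state value for every dataset row (warm-started per axis)."""
    base = _clamped(params, dataset.metadata)
    extra_cols = [c for c in dataset.data.columns if c not in _COLUMNS]
    out = np.empty(len(dataset))
    cache: dict[tuple, object] = {}
    guess_by_axis: dict[str, np.ndarray] = {}
    order = dataset.data.sort_values(["axis", "axis_value"]).index
    for pos, idx in enumerate(order):
        row = dataset.data.loc[idx]
        clamps = {c: float(row[c]) for c in extra_cols if np.isfinite(row[c])}
        key = (row["axis"], float(row["axis_value"]), tuple(sorted(clamps.items())))
        if key not in cache:
            p = axis_params(base.copy(**clamps) if clamps else base,
                            row["axis"], row["axis_value"])
            try:
                cache[key] = solve_steady(network, p,
                                          guess=guess_by_axis.get(row["axis"]))
            except SteadyStateError as exc:
                raise SteadyStateError(
                    f"steady state failed for dataset row {idx} "
                    f"({row['axis']} = {row['axis_value']:g}): {exc}"
                ) from exc
            guess_by_axis[row["axis"]] = cache[key].x.copy()
        out[dataset.data.index.get_loc(idx)] = get_observable(cache[key], row["observable"])
    return out


def residuals(params: ParameterSet, dataset: TitrationDataset,
              network: Network) -> np.ndarray:
    yhat = predict(params, dataset, network)
    w = np.sqrt(dataset.data["weight"].to_numpy(float))
    return w * (dataset.data["value"].to_numpy(float) - yhat)


def ssr(params: ParameterSet, dataset: TitrationDataset,
        network: Network) -> float:
    """Weighted sum of squared residuals sum_i w_i (y_i - yhat_i)^2."""
    r = residuals(params, dataset, network)
    return float(r @ r)


@dataclass
class FitResult:
    params: ParameterSet
    values: dict[str, float]
    bounds: dict[str, tuple[float, float]]
    ssr: float
    ssr0: float
    n_iter: int
    converged: bool
    residuals: np.ndarray
    start_ssr: list[float] = field(default_factory=list)

    def summary(self) -> dict:
        return {
            "values": {k: float(v) for k, v in self.values.items()},
            "ssr": self.ssr,
            "ssr0": self.ssr0,
            "n_iter": self.n_iter,
            "converged": self.converged,
        }


def fit(
    params0: ParameterSet,
    adjustable: Mapping[str, tuple[float, float]],
    dataset: TitrationDataset,
    network: Network,
    seed: int | None = None,
    n_starts: int = 1,
    xtol: float = 1e-10,
) -> FitResult:
    """Bounded local least squares with optional seeded multistart.

    ``adjustable`` maps parameter names to (lower, upper) bounds.  Start 0 is
    ``params0`` itself; further starts are drawn log-uniformly inside the
    bounds.  The result never has a larger SSR than ``params0``.
    """
    names = list(adjustable)
    ssr0 = ssr(params0, dataset, network)
    if not names:
        return FitResult(params0, {}, {}, ssr0, ssr0, 0, True,
                         residuals(params0, dataset, network))
    lo = np.array([adjustable[n][0] for n in names], float)
    hi = np.array([adjustable[n][1] for n in names], float)
    if not (np.all(np.isfinite(lo)) and np.all(np.isfinite(hi))):
        raise ValueError("bounds must be finite")

    def resid_vec(theta: np.ndarray) -> np.ndarray:
        p = params0.copy(**dict(zip(names, theta)))
        return residuals(p, dataset, network)

    rng = np.random.default_rng(seed)
    theta0 = np.clip([params0[n] for n in names], lo, hi)
    starts = [theta0]
    for _ in range(max(0, n_starts - 1)):
        starts.append(np.exp(rng.uniform(np.log(np.maximum(lo, 1e-12)),
                                         np.log(hi))))

    best = None
    start_ssr: list[float] = []
    failures: list[str] = []
    for s in starts:
        try:
            res = least_squares(resid_vec, s, bounds=(lo, hi), xtol=xtol)
        except (SteadyStateError, ValueError) as exc:
            failures.append(str(exc))
            continue
        start_ssr.append(float(res.cost * 2))
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise SteadyStateError(
            "all fit starts failed to converge: " + "; ".join(failures[:3])
        )
    values = dict(zip(names, best.x))
    fitted = params0.copy(**values)
    fit_ssr = float(best.cost * 2)
    if fit_ssr > ssr0:  # never worse than the starting point
        fitted, values, fit_ssr = params0, {n: params0[n] for n in names}, ssr0
    return FitResult(
        fitted, values, {n: adjustable[n] for n in names}, fit_ssr, ssr0,
        int(best.nfev), bool(best.success),
        residuals(fitted, dataset, network), start_ssr,
    )


def generate_synthetic_dataset(
    params_true: ParameterSet,
    design: Mapping[str, object],
    noise_sd: float = 0.05,
    seed: int | None = None,
    network: Network | None = None,
) -> TitrationDataset:
    """Noisy titration data generated from the model itself.

    ``design`` needs keys ``axis``, ``values`` and ``observable`` and may add
    ``clamps`` (dict of boundary overrides).  Measured values are
    y * (1 + N(0, noise_sd)), clipped at zero; a fixed seed reproduces the
    dataset exactly.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    from .network import build_network

    network = network or build_network("assembled_only", params_true)
    axis = str(design["axis"])
    values = np.asarray(design["values"], float)
    observable = str(design["observable"])
    clamps = dict(design.get("clamps", {}))
    rows = pd.DataFrame({
        "axis": axis,
        "axis_value": values,
        "observable": observable,
        "value": np.nan,
        "weight": 1.0,
    })
    for name, val in clamps.items():   # per-row clamps: datasets stay mergeable
        rows[name] = float(val)
    ds = TitrationDataset(rows)
    y = predict(params_true, ds, network)
    rng = np.random.default_rng(seed)
    noisy = np.maximum(y * (1.0 + rng.normal(0.0, noise_sd, size=y.shape))
                       if noise_sd > 0 else y, 0.0)
    ds.data["value"] = noisy
    return ds
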