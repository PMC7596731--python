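"""Thermodynamic helpers: Nernst arithmetic and detailed-balance checks.

Electron-transfer equilibrium constants obey Keq = exp(n * dEm * F / RT)
with dEm the acceptor-minus-donor midpoint potential difference.  Around any
closed reaction cycle the product of (signed) equilibrium constants must be
one (Wegscheider condition); the [3Fe-4S] <-> heme b <-> bound quinone cycle
is checked through reactions (9, 11, 13) for the first electron and
(17, 18, 21) for the second.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import product as _iproduct
from typing import Sequence

from .network import Network, NetworkError
from .params import ParameterSet

__all__ = [
    "nernst_keq",
    "rescale_keq_for_em_shift",
    "check_detailed_balance",
    "apply_em_b",
    "CycleReport",
    "HEME_CYCLES",
]

#: the two three-reaction loops of the heme-b thermodynamic cycle
HEME_CYCLES: tuple[tuple[str, ...], ...] = (("9", "11", "13"), ("17", "18", "21"))


def nernst_keq(em_donor: float, em_acceptor: float, n_electrons: int = 1,
               rt_over_f: float = 25.0) -> float:
    """Equilibrium constant of an n-electron transfer between two couples.

    Returns ``exp(n * (em_acceptor - em_donor) / rt_over_f)``; greater than
    one exactly when the acceptor potential exceeds the donor potential.
    """
    if rt_over_f <= 0:
        raise ValueError("rt_over_f must be positive")
    if n_electrons < 1:
        raise ValueError("n_electrons must be >= 1")
    return math.exp(n_electrons * (em_acceptor - em_donor) / rt_over_f)


def rescale_keq_for_em_shift(keq_old: float, delta_em: float, side: str,
                             rt_over_f: float = 25.0) -> float:
    """Rescale an equilibrium constant for a midpoint-potential shift.

    Shifting the *acceptor* couple by +delta_em multiplies Keq by
    exp(+delta_em/rt_over_f); shifting the *donor* divides by the same
    factor.  Applying +delta then -delta is the identity.
    """
    if keq_old <= 0:
        raise ValueError("keq_old must be positive")
    if rt_over_f <= 0:
        raise ValueError("rt_over_f must be positive")
    if side == "acceptor-shift":
        return keq_old * math.exp(delta_em / rt_over_f)
    if side == "donor-shift":
        return keq_old * math.exp(-delta_em / rt_over_f)
    raise ValueError("side must be 'acceptor-shift' or 'donor-shift'")


@dataclass
class CycleReport:
    cycle: tuple[str, ...]
    signs: tuple[int, ...]
    product: float
    log_product: float
    violated: bool


def _net_stoichiometry(network: Network, rids: Sequence[str],
                       signs: Sequence[int]) -> dict[str, int]:
    net: dict[str, int] = {}
    for rid, s in zip(rids, signs):
        r = network.reaction_by_rid[rid]
        for sid, c in r.reactants:
            net[sid] = net.get(sid, 0) - s * c
        for sid, c in r.products:
            net[sid] = net.get(sid, 0) + s * c
    return {k: v for k, v in net.items() if v != 0}


def check_detailed_balance(
    network: Network,
    cycles: Sequence[Sequence[str]] = HEME_CYCLES,
    params: ParameterSet | None = None,
    tol: float = 1e-6,
) -> list[CycleReport]:
    """Evaluate the Wegscheider product along each reaction-id loop.

    Reaction ids may carry a ``-`` prefix to traverse them backwards; for
    unsigned cycles the traversal directions are inferred as the (unique up
    to global inversion) sign assignment with zero net stoichiometry.  A
    loop through an irreversible reaction is a structural error.
    """
    params = params if params is not None else ParameterSet()
    reports = []
    for cycle in cycles:
        rids, fixed = [], []
        for item in cycle:
            if item.startswith("-"):
                rids.append(item[1:])
                fixed.append(-1)
            else:
                rids.append(item)
                fixed.append(+1 if any(i.startswith("-") for i in cycle) else 0)
        for rid in rids:
            if rid not in network.reaction_by_rid:
                raise NetworkError(f"cycle references unknown reaction {rid!r}")
            if not network.reaction_by_rid[rid].reversible:
                raise NetworkError(
                    f"cycle {tuple(cycle)} contains irreversible reaction {rid!r}"
                )
        if all(f == 0 for f in fixed):  # infer directions
            signs = None
            for trial in _iproduct((1, -1), repeat=len(rids) - 1):
                cand = (1, *trial)
                if not _net_stoichiometry(network, rids, cand):
                    signs = cand
                    break
            if signs is None:
                raise NetworkError(
                    f"no traversal of cycle {tuple(cycle)} closes stoichiometrically"
                )
        else:
            signs = tuple(fixed)
            if _net_stoichiometry(network, rids, signs):
                raise NetworkError(
                    f"signed cycle {tuple(cycle)} has non-zero net stoichiometry"
                )
        log_prod = sum(
            s * math.log(network.reaction_by_rid[rid].keq(params))
            for rid, s in zip(rids, signs)
        )
        reports.append(
            CycleReport(tuple(rids), signs, math.exp(log_prod), log_prod,
                        abs(log_prod) > tol)
        )
    return reports


def apply_em_b(network: Network, params: ParameterSet,
               em_b_new: float) -> ParameterSet:
    """Parameter set with the heme-b midpoint potential moved to ``em_b_new``.

    Keq9, Keq11, Keq17 and Keq18 rescale through the Nernst relation (heme b
    is the acceptor in 9/17 and the donor in 11/18) while Keq13 and Keq21,
    which do not involve heme b, are untouched — so both three-reaction
    cycles stay detail-balanced for any value of ``em_b_new``.
    """
    if not math.isfinite(em_b_new):
        raise ValueError("em_b_new must be finite")
    return params.copy(em_b=float(em_b_new))
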