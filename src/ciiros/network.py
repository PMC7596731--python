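"""Reaction network of Complex II in assembled and disintegrated states.

The network follows the two-branch electron path of succinate:quinone
oxidoreductase.  Succinate reduces the covalently bound flavin (reactions
1-5), the two electrons travel one at a time through the [2Fe-2S], [4Fe-4S]
and [3Fe-4S] clusters (6-8 first electron, 14-16 second electron) and reach
the ubiquinone bound at the Q site either via heme b (9, 11 and 17, 18) or
directly from [3Fe-4S] (13 and 21).  Bound semiquinone is protonated (12),
the quinolate is protonated (19) and ubiquinol is released to the pool (20),
where a lumped Complex III reaction (29) re-oxidises it.  Atpenin A5 competes
with quinone for the Q site (27).  Bypass reactions 22-26 reduce molecular
oxygen at the flavin, [3Fe-4S] and semiquinone sites; superoxide dismutates
(28) and hydrogen peroxide leaves the matrix (30).

Disintegration splits the enzyme into a soluble SDHA/SDHB subcomplex that
keeps the flavin/cluster chemistry and its ROS bypasses (suffix "d":
1d-8d, 14d-16d, 22d-25d) but has lost the quinone acceptor, and a membrane
SDHC/SDHD anchor that keeps heme b and the Q site (10d-12d, 18d-20d, 26d,
27d) but has no electron source.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np

from .params import ParameterSet

__all__ = [
    "Species",
    "Reaction",
    "Network",
    "build_network",
    "conserved_moieties",
    "reaction_rates",
    "rate_jacobian",
    "CLAMPED_PARAM_BY_SPECIES",
    "NetworkError",
]


class NetworkError(ValueError):
    """Structural problem in a network definition or query."""


# clamped boundary species and the parameter that holds their concentration
CLAMPED_PARAM_BY_SPECIES = {
    "succ": "succ",
    "fum": "fum",
    "aa5": "aa5",
    "o2": "o2",
    "h": "h",
}

MATRIX = "matrix"
MEMBRANE = "inner-membrane"


@dataclass(frozen=True)
class Species:
    id: str
    description: str = ""
    compartment: str = MATRIX
    clamped: bool = False
    concentration: float = 0.0   # initial (free) or fixed (clamped) value, uM

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError(f"species {self.id!r}: concentration must be >= 0")


@dataclass(frozen=True)
class Reaction:
    """One kinetic process with a reversible or irreversible rate law.

    ``kind`` selects how the constants are resolved from a
    :class:`~ciiros.params.ParameterSet`:

    * ``redox``        -- kf from ``kf<rid>``, Keq from the Nernst relation on
      the donor/acceptor couples, kr = kf/Keq.
    * ``binding``      -- kf from ``kf<rid>``, kr from ``kr<rid>``.
    * ``irreversible`` -- kf from ``kf<rid>``, kr = 0.
    * ``michaelis``    -- irreversible saturating law
      v = kf*[S]/(km + [S]) with km from ``km<rid>`` (single substrate).

    A ``keq<rid>`` entry in the parameter set overrides the derived
    equilibrium constant of any reversible reaction.
    """

    rid: str
    reactants: tuple[tuple[str, int], ...]
    products: tuple[tuple[str, int], ...]
    kind: str = "binding"
    donor: str | None = None       # midpoint-potential couple of the e- donor
    acceptor: str | None = None    # couple of the e- acceptor
    n_electrons: int = 1
    fwd_orders: tuple[tuple[str, int], ...] | None = None
    rev_orders: tuple[tuple[str, int], ...] | None = None
    family: str = "assembled"      # assembled | shared | ab | cd
    description: str = ""

    @property
    def reversible(self) -> bool:
        return self.kind in ("redox", "binding")

    def keq(self, params: ParameterSet) -> float:
        """Equilibrium constant (units set by molecularity)."""
        if not self.reversible:
            raise NetworkError(f"reaction {self.rid} is irreversible; no Keq")
        override = params.get(f"keq{self.rid}")
        if override is not None:
            return float(override)
        if self.kind == "redox":
            rtf = params["rt_over_f"]

            def em(couple: str) -> float:
                if couple == "flavin2e":  # two-electron FAD/FADH2 couple
                    return 0.5 * (params["em_flavin1"] + params["em_flavin2"])
                return params[f"em_{couple}"]

            d_em = em(self.acceptor) - em(self.donor)
            return float(np.exp(self.n_electrons * d_em / rtf))
        return params[f"kf{self.rid}"] / params[f"kr{self.rid}"]

    def constants(self, params: ParameterSet) -> tuple[float, float]:
        """Resolved (kf, kr) pair."""
        kf = params[f"kf{self.rid}"]
        if self.kind == "irreversible" or self.kind == "michaelis":
            return kf, 0.0
        return kf, kf / self.keq(params)


def _rx(
    rid: str,
    reactants: Sequence[tuple[str, int]],
    products: Sequence[tuple[str, int]],
    kind: str = "binding",
    donor: str | None = None,
    acceptor: str | None = None,
    n_electrons: int = 1,
    fwd_orders: Sequence[tuple[str, int]] | None = None,
    rev_orders: Sequence[tuple[str, int]] | None = None,
    family: str = "assembled",
    description: str = "",
) -> Reaction:
    return Reaction(
        rid,
        tuple(reactants),
        tuple(products),
        kind,
        donor,
        acceptor,
        n_electrons,
        tuple(fwd_orders) if fwd_orders is not None else None,
        tuple(rev_orders) if rev_orders is not None else None,
        family,
        description,
    )


# ---------------------------------------------------------------------------
# species catalogue
# ---------------------------------------------------------------------------
def _species_catalogue() -> list[Species]:
    sp: list[Species] = []

    def add(sid: str, desc: str, comp: str = MATRIX, clamped: bool = False) -> None:
        sp.append(Species(sid, desc, comp, clamped))

    # assembled flavin / dicarboxylate site
    add("fad", "oxidised FAD, dicarboxylate site unoccupied")
    add("fad_s", "FAD with succinate bound")
    add("fad_f", "FAD with fumarate bound (dead-end)")
    add("fadh2_f", "FADH2 with fumarate bound (product complex)")
    add("fadh2", "FADH2, dicarboxylate site unoccupied")
    add("fadh2_s", "FADH2 with succinate bound (occupied)")
    add("fadhsq", "flavin semiquinone radical FADH., unoccupied")
    # assembled iron-sulfur relay
    add("fes2_ox", "[2Fe-2S] oxidised")
    add("fes2_red", "[2Fe-2S]- reduced")
    add("fes4_ox", "[4Fe-4S] oxidised")
    add("fes4_red", "[4Fe-4S]- reduced")
    add("fes3_ox", "[3Fe-4S] oxidised")
    add("fes3_red", "[3Fe-4S]- reduced")
    # heme b
    add("b_ox", "heme b oxidised", MEMBRANE)
    add("b_red", "heme b reduced (b-)", MEMBRANE)
    # Q-binding site of assembled CII
    add("cii", "Q site empty", MEMBRANE)
    add("cii_q", "CII.Q bound quinone", MEMBRANE)
    add("cii_qm", "CII.Q- bound semiquinone anion", MEMBRANE)
    add("cii_qh", "CII.QH bound protonated semiquinone", MEMBRANE)
    add("cii_qhm", "CII.QH- bound quinolate anion", MEMBRANE)
    add("cii_qh2", "CII.QH2 bound ubiquinol", MEMBRANE)
    add("cii_aa5", "CII.AA5 inhibited Q site", MEMBRANE)
    # shared pools
    add("q", "free ubiquinone", MEMBRANE)
    add("qh2", "free ubiquinol", MEMBRANE)
    add("o2m", "superoxide anion O2-")
    add("h2o2", "hydrogen peroxide (matrix)")
    # disintegrated SDHA/SDHB subcomplex (matrix)
    add("fad_d", "oxidised FAD, disintegrated subcomplex")
    add("fad_s_d", "FAD.succinate, disintegrated")
    add("fad_f_d", "FAD.fumarate dead-end, disintegrated")
    add("fadh2_f_d", "FADH2.fumarate, disintegrated")
    add("fadh2_d", "FADH2 unoccupied, disintegrated")
    add("fadh2_s_d", "FADH2.succinate, disintegrated")
    add("fadhsq_d", "FADH. semiquinone, disintegrated")
    add("fes2_ox_d", "[2Fe-2S] oxidised, disintegrated")
    add("fes2_red_d", "[2Fe-2S]- reduced, disintegrated")
    add("fes4_ox_d", "[4Fe-4S] oxidised, disintegrated")
    add("fes4_red_d", "[4Fe-4S]- reduced, disintegrated")
    add("fes3_ox_d", "[3Fe-4S] oxidised, disintegrated")
    add("fes3_red_d", "[3Fe-4S]- reduced, disintegrated")
    # disintegrated SDHC/SDHD membrane anchor
    add("cd", "anchor Q site empty", MEMBRANE)
    add("cd_q", "anchor-bound quinone", MEMBRANE)
    add("cd_qm", "anchor-bound semiquinone anion", MEMBRANE)
    add("cd_qh", "anchor-bound protonated semiquinone", MEMBRANE)
    add("cd_qhm", "anchor-bound quinolate anion", MEMBRANE)
    add("cd_qh2", "anchor-bound ubiquinol", MEMBRANE)
    add("cd_aa5", "anchor Q site blocked by AA5", MEMBRANE)
    add("bd_ox", "heme b oxidised, disintegrated anchor", MEMBRANE)
    add("bd_red", "heme b reduced, disintegrated anchor", MEMBRANE)
    # clamped boundary species
    add("succ", "succinate (clamped)", MATRIX, True)
    add("fum", "fumarate (clamped)", MATRIX, True)
    add("aa5", "atpenin A5 (clamped)", MEMBRANE, True)
    add("o2", "molecular oxygen (clamped)", MATRIX, True)
    add("h", "proton (clamped)", MATRIX, True)
    return sp


# ---------------------------------------------------------------------------
# reaction catalogue
# ---------------------------------------------------------------------------
def _reaction_catalogue() -> list[Reaction]:
    rxns: list[Reaction] = []
    A = rxns.append

    # -- assembled CII ------------------------------------------------------
    A(_rx("1", [("succ", 1), ("fad", 1)], [("fad_s", 1)],
          description="succinate binding to FAD"))
    A(_rx("2", [("fad_s", 1)], [("fadh2_f", 1)], kind="redox",
          donor="succ_fum", acceptor="flavin2e", n_electrons=2,
          description="hydride transfer: succinate oxidised to fumarate"))
    A(_rx("3", [("fadh2_f", 1)], [("fadh2", 1), ("fum", 1)],
          description="fumarate release from FADH2"))
    A(_rx("4", [("fad", 1), ("fum", 1)], [("fad_f", 1)],
          description="dead-end fumarate binding to FAD"))
    A(_rx("5", [("fadh2", 1), ("succ", 1)], [("fadh2_s", 1)],
          description="succinate binding to FADH2 (site occupancy)"))
    A(_rx("6", [("fadh2", 1), ("fes2_ox", 1)], [("fadhsq", 1), ("fes2_red", 1)],
          kind="redox", donor="flavin2", acceptor="fes2",
          description="first electron: FADH2 -> [2Fe-2S]"))
    A(_rx("7", [("fes2_red", 1), ("fes4_ox", 1)], [("fes2_ox", 1), ("fes4_red", 1)],
          kind="redox", donor="fes2", acceptor="fes4",
          description="first electron: [2Fe-2S]- -> [4Fe-4S]"))
    A(_rx("8", [("fes4_red", 1), ("fes3_ox", 1)], [("fes4_ox", 1), ("fes3_red", 1)],
          kind="redox", donor="fes4", acceptor="fes3",
          description="first electron: [4Fe-4S]- -> [3Fe-4S]"))
    A(_rx("9", [("fes3_red", 1), ("b_ox", 1)], [("fes3_ox", 1), ("b_red", 1)],
          kind="redox", donor="fes3", acceptor="b",
          description="first electron: [3Fe-4S]- -> heme b"))
    A(_rx("10", [("cii", 1), ("q", 1)], [("cii_q", 1)],
          description="ubiquinone binding to the Q site"))
    A(_rx("11", [("b_red", 1), ("cii_q", 1)], [("b_ox", 1), ("cii_qm", 1)],
          kind="redox", donor="b", acceptor="sq1",
          description="first electron: heme b -> bound Q"))
    A(_rx("12", [("cii_qm", 1), ("h", 1)], [("cii_qh", 1)],
          description="protonation of bound semiquinone"))
    A(_rx("13", [("fes3_red", 1), ("cii_q", 1)], [("fes3_ox", 1), ("cii_qm", 1)],
          kind="redox", donor="fes3", acceptor="sq1",
          description="first electron: direct [3Fe-4S]- -> bound Q"))
    A(_rx("14", [("fadhsq", 1), ("fes2_ox", 1)], [("fad", 1), ("fes2_red", 1)],
          kind="redox", donor="flavin1", acceptor="fes2",
          description="second electron: FADH. -> [2Fe-2S]"))
    A(_rx("15", [("fes2_red", 1), ("fes4_ox", 1)], [("fes2_ox", 1), ("fes4_red", 1)],
          kind="redox", donor="fes2", acceptor="fes4",
          description="second electron: [2Fe-2S]- -> [4Fe-4S]"))
    A(_rx("16", [("fes4_red", 1), ("fes3_ox", 1)], [("fes4_ox", 1), ("fes3_red", 1)],
          kind="redox", donor="fes4", acceptor="fes3",
          description="second electron: [4Fe-4S]- -> [3Fe-4S]"))
    A(_rx("17", [("fes3_red", 1), ("b_ox", 1)], [("fes3_ox", 1), ("b_red", 1)],
          kind="redox", donor="fes3", acceptor="b",
          description="second electron: [3Fe-4S]- -> heme b"))
    A(_rx("18", [("b_red", 1), ("cii_qh", 1)], [("b_ox", 1), ("cii_qhm", 1)],
          kind="redox", donor="b", acceptor="sq2",
          description="second electron: heme b -> bound QH"))
    A(_rx("19", [("cii_qhm", 1), ("h", 1)], [("cii_qh2", 1)],
          description="protonation of bound quinolate"))
    A(_rx("20", [("cii_qh2", 1)], [("cii", 1), ("qh2", 1)],
          description="ubiquinol release to the pool (SQR output)"))
    A(_rx("21", [("fes3_red", 1), ("cii_qh", 1)], [("fes3_ox", 1), ("cii_qhm", 1)],
          kind="redox", donor="fes3", acceptor="sq2",
          description="second electron: direct [3Fe-4S]- -> bound QH"))
    A(_rx("22", [("fadh2", 1), ("o2", 1)], [("fad", 1), ("h2o2", 1)],
          kind="irreversible",
          description="two-electron O2 reduction by unoccupied FADH2"))
    A(_rx("23", [("fadh2", 1), ("o2", 1)], [("fadhsq", 1), ("o2m", 1)],
          kind="redox", donor="flavin2", acceptor="o2",
          description="superoxide formation by unoccupied FADH2"))
    A(_rx("24", [("fadhsq", 1), ("o2", 1)], [("fad", 1), ("o2m", 1)],
          kind="redox", donor="flavin1", acceptor="o2",
          description="superoxide formation by FADH."))
    A(_rx("25", [("fes3_red", 1), ("o2", 1)], [("fes3_ox", 1), ("o2m", 1)],
          kind="redox", donor="fes3", acceptor="o2",
          description="superoxide formation by [3Fe-4S]-"))
    A(_rx("26", [("cii_qm", 1), ("o2", 1)], [("cii_q", 1), ("o2m", 1)],
          kind="redox", donor="sq1", acceptor="o2",
          description="superoxide formation by bound semiquinone"))
    A(_rx("27", [("cii", 1), ("aa5", 1)], [("cii_aa5", 1)],
          description="AA5 binding to the Q site (competes with Q)"))
    # -- shared sinks --------------------------------------------------------
    A(_rx("28", [("o2m", 2), ("h", 2)], [("h2o2", 1), ("o2", 1)],
          kind="irreversible", fwd_orders=[("o2m", 2)], family="shared",
          description="superoxide dismutation (2 O2- -> H2O2 + O2)"))
    A(_rx("29", [("qh2", 1)], [("q", 1)], kind="irreversible", family="shared",
          description="lumped Complex III: QH2 oxidation"))
    A(_rx("30", [("h2o2", 1)], [], kind="irreversible", family="shared",
          description="H2O2 release from the matrix"))

    # -- disintegrated SDHA/SDHB subcomplex ----------------------------------
    def ab(rid: str, base: Reaction) -> Reaction:
        ren = {
            "fad": "fad_d", "fad_s": "fad_s_d", "fad_f": "fad_f_d",
            "fadh2_f": "fadh2_f_d", "fadh2": "fadh2_d", "fadh2_s": "fadh2_s_d",
            "fadhsq": "fadhsq_d",
            "fes2_ox": "fes2_ox_d", "fes2_red": "fes2_red_d",
            "fes4_ox": "fes4_ox_d", "fes4_red": "fes4_red_d",
            "fes3_ox": "fes3_ox_d", "fes3_red": "fes3_red_d",
        }
        rn = lambda pairs: tuple((ren.get(s, s), n) for s, n in pairs)
        return _rx(rid, rn(base.reactants), rn(base.products), base.kind,
                   base.donor, base.acceptor, base.n_electrons,
                   None, None, "ab", base.description + " (disintegrated)")

    by_rid = {r.rid: r for r in rxns}
    for num in ("1", "2", "3", "4", "5", "6", "7", "8",
                "14", "15", "16", "22", "23", "24", "25"):
        A(ab(num + "d", by_rid[num]))

    # -- disintegrated SDHC/SDHD membrane anchor -----------------------------
    def cd(rid: str, base: Reaction) -> Reaction:
        ren = {
            "cii": "cd", "cii_q": "cd_q", "cii_qm": "cd_qm",
            "cii_qh": "cd_qh", "cii_qhm": "cd_qhm", "cii_qh2": "cd_qh2",
            "cii_aa5": "cd_aa5", "b_ox": "bd_ox", "b_red": "bd_red",
        }
        rn = lambda pairs: tuple((ren.get(s, s), n) for s, n in pairs)
        return _rx(rid, rn(base.reactants), rn(base.products), base.kind,
                   base.donor, base.acceptor, base.n_electrons,
                   None, None, "cd", base.description + " (anchor)")

    for num in ("10", "11", "12", "18", "19", "20", "26", "27"):
        A(cd(num + "d", by_rid[num]))

    return rxns


# ---------------------------------------------------------------------------
# Network
# ---------------------------------------------------------------------------
class Network:
    """Species + reactions + stoichiometry + conservation analysis."""

    def __init__(self, species: Iterable[Species], reactions: Iterable[Reaction],
                 topology: str = "custom"):
        self.topology = topology
        self.species = list(species)
        self.reactions = list(reactions)
        ids = [s.id for s in self.species]
        if len(set(ids)) != len(ids):
            raise NetworkError("species ids must be unique")
        rids = [r.rid for r in self.reactions]
        if len(set(rids)) != len(rids):
            raise NetworkError("reaction ids must be unique")
        self.species_by_id = {s.id: s for s in self.species}
        self.reaction_by_rid = {r.rid: r for r in self.reactions}
        self.free_ids = [s.id for s in self.species if not s.clamped]
        self.clamped_ids = [s.id for s in self.species if s.clamped]
        self._free_index = {sid: i for i, sid in enumerate(self.free_ids)}
        self.rids = rids

        # net stoichiometry over free species (n_free x n_reactions)
        n_free, n_rx = len(self.free_ids), len(self.reactions)
        N = np.zeros((n_free, n_rx))
        for j, r in enumerate(self.reactions):
            for sid, coeff in r.reactants:
                if sid in self._free_index:
                    N[self._free_index[sid], j] -= coeff
            for sid, coeff in r.products:
                if sid in self._free_index:
                    N[self._free_index[sid], j] += coeff
        self.N = N
        self._moieties: list[dict[str, Fraction]] | None = None

        # per-reaction evaluation plans: (free_idx or -1, clamp key, order,
        # fallback value).  Clamped species mapped to a parameter read it
        # from the ParameterSet; other clamped species use their fixed value.
        def plan(pairs: tuple[tuple[str, int], ...]) -> list[tuple[int, str | None, int, float]]:
            out = []
            for sid, order in pairs:
                if sid not in self.species_by_id:
                    raise NetworkError(f"reaction references unknown species {sid!r}")
                if sid in self._free_index:
                    out.append((self._free_index[sid], None, order, 0.0))
                elif sid in CLAMPED_PARAM_BY_SPECIES:
                    out.append((-1, CLAMPED_PARAM_BY_SPECIES[sid], order, 0.0))
                else:
                    out.append((-1, None, order, self.species_by_id[sid].concentration))
            return out

        self._fwd_plan = []
        self._rev_plan = []
        for r in self.reactions:
            fwd = r.fwd_orders if r.fwd_orders is not None else r.reactants
            rev = r.rev_orders if r.rev_orders is not None else r.products
            self._fwd_plan.append(plan(tuple(fwd)))
            self._rev_plan.append(plan(tuple(rev)) if r.reversible else [])

        # dense kinetic-order matrices over free species (vectorised rate path)
        self._Af = np.zeros((n_rx, n_free))
        self._Ar = np.zeros((n_rx, n_free))
        self._michaelis_idx = [j for j, r in enumerate(self.reactions)
                               if r.kind == "michaelis"]
        for j in range(n_rx):
            for idx, _, order, _ in self._fwd_plan[j]:
                if idx >= 0:
                    self._Af[j, idx] += order
            for idx, _, order, _ in self._rev_plan[j]:
                if idx >= 0:
                    self._Ar[j, idx] += order
        self._const_cache: tuple[int, np.ndarray, np.ndarray] | None = None

    def _resolved_constants(self, params: ParameterSet) -> tuple[np.ndarray, np.ndarray]:
        """Effective (kf, kr) per reaction with clamped factors folded in.

        Cached against the identity of the parameter set (ParameterSet is
        immutable by convention; every modification goes through ``copy``).
        """
        if self._const_cache is not None and self._const_cache[0] is params:
            return self._const_cache[1], self._const_cache[2]
        kf_eff = np.zeros(self.n_reactions)
        kr_eff = np.zeros(self.n_reactions)
        for j, r in enumerate(self.reactions):
            kf, kr = r.constants(params)
            for idx, clamp, order, fallback in self._fwd_plan[j]:
                if idx < 0:
                    kf *= (params[clamp] if clamp is not None else fallback) ** order
            for idx, clamp, order, fallback in self._rev_plan[j]:
                if idx < 0:
                    kr *= (params[clamp] if clamp is not None else fallback) ** order
            kf_eff[j], kr_eff[j] = kf, kr
        self._const_cache = (params, kf_eff, kr_eff)
        return kf_eff, kr_eff

    # -- indices -------------------------------------------------------------
    def free_index(self, sid: str) -> int:
        return self._free_index[sid]

    def rid_index(self, rid: str) -> int:
        return self.rids.index(rid)

    @property
    def n_free(self) -> int:
        return len(self.free_ids)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    # -- conservation analysis ------------------------------------------------
    def conserved_moieties(self) -> list[dict[str, Fraction]]:
        """Rational basis of the left null space of the stoichiometry matrix.

        Each returned mapping ``{species_id: coefficient}`` satisfies
        ``sum_i coeff_i * dC_i/dt = 0`` exactly for every reaction.
        """
        if self._moieties is None:
            rows = _rational_left_nullspace(self.N)
            self._moieties = [
                {self.free_ids[i]: c for i, c in enumerate(row) if c != 0}
                for row in rows
            ]
        return self._moieties

    def conservation_matrix(self) -> np.ndarray:
        moieties = self.conserved_moieties()
        C = np.zeros((len(moieties), self.n_free))
        for k, m in enumerate(moieties):
            for sid, c in m.items():
                C[k, self._free_index[sid]] = float(c)
        return C

    def n_odes(self) -> int:
        """Number of independent differential equations (rank of N)."""
        return self.n_free - len(self.conserved_moieties())

    # -- initial state ---------------------------------------------------------
    def initial_state(self, params: ParameterSet) -> np.ndarray:
        """Fully oxidised pools at their totals, zero ROS (default convention).

        Custom (imported) networks fall back to the per-species initial
        concentrations stored on the :class:`Species` objects.
        """
        if self.topology == "custom":
            return np.array(
                [self.species_by_id[sid].concentration for sid in self.free_ids]
            )
        init = {
            "fad": params["CIIt"], "fes2_ox": params["CIIt"],
            "fes4_ox": params["CIIt"], "fes3_ox": params["CIIt"],
            "b_ox": params["CIIt"], "cii": params["CIIt"],
            "q": params["Qt"],
            "fad_d": params["ABt"], "fes2_ox_d": params["ABt"],
            "fes4_ox_d": params["ABt"], "fes3_ox_d": params["ABt"],
            "cd": params["CDt"], "bd_ox": params["CDt"],
        }
        x0 = np.zeros(self.n_free)
        for sid, val in init.items():
            if sid in self._free_index:
                x0[self._free_index[sid]] = val
        return x0


def conserved_moieties(network: Network) -> list[dict[str, Fraction]]:
    """Exact rational basis of the network's conserved moieties."""
    return network.conserved_moieties()


def _rational_left_nullspace(N: np.ndarray) -> list[list[Fraction]]:
    """Basis of {y : y @ N == 0} in exact rational arithmetic.

    Gauss-Jordan elimination of N^T over Fraction; the free columns of the
    reduced system parameterise the null space.  Stoichiometric coefficients
    are integers, so the conversion to Fraction is exact.
    """
    A = [[Fraction(int(round(N[i, j]))) for i in range(N.shape[0])]
         for j in range(N.shape[1])]           # A = N^T, shape (n_rx, n_free)
    n_rows = len(A)
    n_cols = N.shape[0]
    pivots: list[int] = []
    r = 0
    for c in range(n_cols):
        piv = next((i for i in range(r, n_rows) if A[i][c] != 0), None)
        if piv is None:
            continue
        A[r], A[piv] = A[piv], A[r]
        inv = A[r][c]
        A[r] = [v / inv for v in A[r]]
        for i in range(n_rows):
            if i != r and A[i][c] != 0:
                f = A[i][c]
                A[i] = [vi - f * vr for vi, vr in zip(A[i], A[r])]
        pivots.append(c)
        r += 1
        if r == n_rows:
            break
    free_cols = [c for c in range(n_cols) if c not in pivots]
    basis = []
    for fc in free_cols:
        y = [Fraction(0)] * n_cols
        y[fc] = Fraction(1)
        for prow, pc in enumerate(pivots):
            y[pc] = -A[prow][fc]
        basis.append(y)
    return basis


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------
_TOPOLOGIES = {
    "assembled_only": {"assembled", "shared"},
    "disintegrated_only": {"ab", "cd", "shared"},
    "mixed": {"assembled", "shared", "ab", "cd"},
}


def build_network(topology: str, params: ParameterSet) -> Network:
    """Assemble the built-in Complex II network for the given topology.

    ``assembled_only`` keeps reactions 1-30, ``disintegrated_only`` the
    d-suffixed families plus the shared pool sinks, ``mixed`` everything
    (the full 53-reaction network sharing the Q pool, O2, superoxide, H2O2
    and the dicarboxylates).
    """
    if topology not in _TOPOLOGIES:
        raise NetworkError(
            f"unknown topology {topology!r}; expected one of {sorted(_TOPOLOGIES)}"
        )
    if topology == "assembled_only" and (params["ABt"] > 0 or params["CDt"] > 0):
        raise ValueError("assembled_only topology requires ABt = CDt = 0")
    if topology == "disintegrated_only" and params["CIIt"] > 0:
        raise ValueError("disintegrated_only topology requires CIIt = 0")

    families = _TOPOLOGIES[topology]
    reactions = [r for r in _reaction_catalogue() if r.family in families]
    used = {sid for r in reactions for sid, _ in (*r.reactants, *r.products)}
    species = [s for s in _species_catalogue() if s.id in used or s.clamped]
    return Network(species, reactions, topology=topology)


# ---------------------------------------------------------------------------
# rate laws
# ---------------------------------------------------------------------------
def _concentration(term: tuple[int, str | None, int, float], state: np.ndarray,
                   params: ParameterSet) -> float:
    idx, clamp, _, fallback = term
    if idx >= 0:
        return state[idx]
    return params[clamp] if clamp is not None else fallback


def reaction_rates(
    network: Network, state: np.ndarray, params: ParameterSet
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-reaction (net, forward, reverse) rates in uM/s.

    Mass-action products use the reaction's kinetic orders (stoichiometric
    coefficients unless overridden).  Michaelis reactions use the saturating
    single-substrate form.
    """
    state = np.asarray(state)
    if state.dtype != np.longdouble:
        state = state.astype(float)
    if state.shape != (network.n_free,):
        raise ValueError(
            f"state has shape {state.shape}, expected ({network.n_free},)"
        )
    if np.any(state < -1e-9):
        worst = network.free_ids[int(np.argmin(state))]
        raise ValueError(f"negative concentration for species {worst!r}")
    state = np.maximum(state, 0.0)
    out_dtype = np.longdouble if state.dtype == np.longdouble else float

    # fast near-equilibrium electron transfers make the net rate a tiny
    # difference of huge unidirectional terms; extended precision keeps the
    # cancellation error of (forward - reverse) below the steady-state
    # residual tolerance
    ld = np.longdouble
    state_ld = state.astype(ld)
    kf_eff, kr_eff = network._resolved_constants(params)
    fwd = kf_eff.astype(ld) * np.prod(state_ld[None, :] ** network._Af, axis=1)
    rev = kr_eff.astype(ld) * np.prod(state_ld[None, :] ** network._Ar, axis=1)
    for j in network._michaelis_idx:
        r = network.reactions[j]
        (term,) = network._fwd_plan[j]
        s = state_ld[term[0]] if term[0] >= 0 else ld(_concentration(term, state, params))
        km = params[f"km{r.rid}"]
        fwd[j] = ld(params[f"kf{r.rid}"]) * s / (ld(km) + s)
        rev[j] = 0.0
    return (np.asarray(fwd - rev, dtype=out_dtype),
            np.asarray(fwd, dtype=out_dtype),
            np.asarray(rev, dtype=out_dtype))


def rate_jacobian(
    network: Network, state: np.ndarray, params: ParameterSet
) -> np.ndarray:
    """d(net rate)/d(free concentrations), shape (n_reactions, n_free)."""
    state = np.maximum(np.asarray(state, dtype=float), 0.0)
    kf_eff, kr_eff = network._resolved_constants(params)
    J = np.zeros((network.n_reactions, network.n_free))
    zero = state == 0.0
    safe = np.where(zero, 1.0, state)
    for sign, k_eff, A in ((1.0, kf_eff, network._Af), (-1.0, kr_eff, network._Ar)):
        P = safe[None, :] ** A
        # zero concentrations: a factor with order>=1 kills the product
        if np.any(zero):
            P = np.where(zero[None, :] & (A > 0), 0.0, P)
        full = k_eff * np.prod(P, axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            Jpart = A * (full[:, None] / np.where(zero[None, :], 1.0, state[None, :]))
        if np.any(zero):
            # d/dc_j at c_j = 0 is non-zero only for first-order factors:
            # the derivative is the product of the remaining factors
            rows, cols = np.nonzero(zero[None, :] & (A == 1.0) & (k_eff[:, None] != 0))
            for j, i in zip(rows, cols):
                others = np.prod(np.delete(P[j], i))
                Jpart[j, i] = k_eff[j] * others
            Jpart[:, zero] = np.where((A[:, zero] == 1.0), Jpart[:, zero], 0.0)
        J += sign * Jpart
    for j in network._michaelis_idx:
        r = network.reactions[j]
        (term,) = network._fwd_plan[j]
        J[j, :] = 0.0
        if term[0] >= 0:
            km = params[f"km{r.rid}"]
            s = state[term[0]]
            J[j, term[0]] = params[f"kf{r.rid}"] * km / (km + s) ** 2
    return J
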