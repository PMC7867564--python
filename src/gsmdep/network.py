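"""Metabolic networks, gene-removal sub-models and viability scoring.

A :class:`MetabolicNetwork` is a stoichiometric model: metabolites,
reactions with flux bounds and GPR boolean rules, a set of biomass
components (metabolites the cell must be able to synthesise) and a set
of exchange reactions (the only reactions allowed to carry mass across
the system boundary).  Removing a set of genes deactivates every
reaction whose GPR evaluates false, after which reactions that can no
longer carry flux in any steady state are pruned; the surviving network
is a :class:`SubModel`.

Viability is scored by *fitness*: the fraction of biomass components
that remain producible at steady state, so fitness 1 means the
sub-network is as viable as the comprehensive model and fitness 0 a
totally degraded one.  ``fitness* = (1 - i/k) * fitness`` additionally
discounts by the fraction ``i/k`` of removed genes and is the x-axis of
depletion curves.  The scoring function is pluggable
(``fitness_fn`` argument of :func:`extract_submodel`) so alternative
viability definitions can be swapped in.

All producibility and blocked-reaction questions are decided by linear
feasibility (scipy's HiGHS-based ``linprog``): a metabolite is
producible iff some steady-state flux vector within bounds delivers it
to a demand sink at flux >= ``eps`` (default 1e-6).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import linprog

from .gpr import GprNode, evaluate_gpr, format_gpr, gpr_genes, parse_gpr

#: minimum demand flux for a metabolite to count as producible
DEFAULT_EPS = 1e-6
#: LP numerical tolerance handed to HiGHS
DEFAULT_LP_TOL = 1e-9
#: capacity of the implicit biomass demand sinks
DEFAULT_SINK_BOUND = 1000.0


class NetworkError(ValueError):
    """Raised for structurally invalid networks or infeasible LP setups."""


@dataclass(frozen=True)
class Reaction:
    """A single reaction: stoichiometry, flux bounds and a GPR rule."""

    id: str
    stoichiometry: Mapping[str, float]
    reversible: bool = False
    lower_bound: float = 0.0
    upper_bound: float = 1000.0
    gpr: Optional[GprNode] = None

    def __post_init__(self):
        if not self.reversible and self.lower_bound < 0:
            raise NetworkError(
                f"reaction {self.id!r}: negative lower bound on an irreversible reaction"
            )
        if self.lower_bound > self.upper_bound:
            raise NetworkError(f"reaction {self.id!r}: lower bound exceeds upper bound")

    @property
    def genes(self) -> FrozenSet[str]:
        return gpr_genes(self.gpr)


@dataclass(frozen=True)
class MetabolicNetwork:
    """The comprehensive genome-scale metabolic model (k genes)."""

    metabolites: Tuple[str, ...]
    reactions: Tuple[Reaction, ...]
    biomass_components: Tuple[str, ...]
    exchanges: FrozenSet[str] = field(default_factory=frozenset)

    def __post_init__(self):
        declared = set(self.metabolites)
        for rxn in self.reactions:
            missing = set(rxn.stoichiometry) - declared
            if missing:
                raise NetworkError(
                    f"reaction {rxn.id!r} references undeclared metabolites: {sorted(missing)}"
                )
        if not self.biomass_components:
            raise NetworkError("biomass_components must be non-empty")
        missing = set(self.biomass_components) - declared
        if missing:
            raise NetworkError(f"undeclared biomass components: {sorted(missing)}")
        ids = [r.id for r in self.reactions]
        if len(set(ids)) != len(ids):
            raise NetworkError("duplicate reaction ids")
        unknown = set(self.exchanges) - set(ids)
        if unknown:
            raise NetworkError(f"exchanges name unknown reactions: {sorted(unknown)}")
        if not self.genes:
            raise NetworkError("network has no genes (k must be >= 1)")

    @property
    def genes(self) -> FrozenSet[str]:
        out = frozenset()
        for r in self.reactions:
            out |= r.genes
        return out

    @property
    def k(self) -> int:
        """Number of genes in the comprehensive model."""
        return len(self.genes)

    def reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    # -- JSON dialect -------------------------------------------------
    #
    # {"metabolites": [...],
    #  "reactions": [{"id":…, "stoich": {met: coef}, "rev": bool,
    #                 "lb": …, "ub": …, "gpr": "(gA and gB) or gC"}],
    #  "biomass": [...], "exchanges": [...]}

    @classmethod
    def from_dict(cls, d: Mapping) -> "MetabolicNetwork":
        reactions = tuple(
            Reaction(
                id=r["id"],
                stoichiometry=dict(r["stoich"]),
                reversible=bool(r.get("rev", False)),
                lower_bound=float(r.get("lb", -1000.0 if r.get("rev") else 0.0)),
                upper_bound=float(r.get("ub", 1000.0)),
                gpr=parse_gpr(r.get("gpr", "")),
            )
            for r in d["reactions"]
        )
        return cls(
            metabolites=tuple(d["metabolites"]),
            reactions=reactions,
            biomass_components=tuple(d["biomass"]),
            exchanges=frozenset(d.get("exchanges", ())),
        )

    @classmethod
    def from_json(cls, path) -> "MetabolicNetwork":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_dict(self) -> Dict:
        return {
            "metabolites": list(self.metabolites),
            "reactions": [
                {
                    "id": r.id,
                    "stoich": dict(r.stoichiometry),
                    "rev": r.reversible,
                    "lb": r.lower_bound,
                    "ub": r.upper_bound,
                    "gpr": format_gpr(r.gpr),
                }
                for r in self.reactions
            ],
            "biomass": list(self.biomass_components),
            "exchanges": sorted(self.exchanges),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


@dataclass(frozen=True)
class SubModel:
    """A gene-removal sub-network of a comprehensive model.

    ``active_reactions`` are the reactions surviving GPR evaluation and
    blocked-reaction pruning; ``present_genes`` the non-removed genes
    still supporting at least one active reaction (pruning can silence
    genes beyond the removed set — propagation).
    """

    parent: MetabolicNetwork
    removed_genes: FrozenSet[str]
    active_reactions: Tuple[str, ...]
    present_genes: FrozenSet[str]
    fitness: float

    @property
    def i(self) -> int:
        """Number of removed genes."""
        return len(self.removed_genes)

    @property
    def fitness_star(self) -> float:
        """(1 - i/k) * fitness — the depletion-curve x coordinate."""
        return (1.0 - self.i / self.parent.k) * self.fitness


# ---------------------------------------------------------------------
# linear-programming machinery


def _lp_matrix(network: MetabolicNetwork, active: Sequence[Reaction],
               extra_mets: Iterable[str] = ()) -> Tuple[np.ndarray, Dict[str, int], np.ndarray, np.ndarray]:
    """Stoichiometric matrix restricted to metabolites touched by ``active``."""
    mets: Dict[str, int] = {}
    for r in active:
        for m in r.stoichiometry:
            mets.setdefault(m, len(mets))
    for m in extra_mets:
        mets.setdefault(m, len(mets))
    S = np.zeros((len(mets), len(active)))
    for j, r in enumerate(active):
        for m, c in r.stoichiometry.items():
            S[mets[m], j] = c
    lb = np.array([r.lower_bound for r in active])
    ub = np.array([r.upper_bound for r in active])
    return S, mets, lb, ub


def _solve(c, A_eq, b_eq, bounds, tol):
    return linprog(
        c, A_eq=A_eq, b_eq=b_eq, bounds=bounds, method="highs",
        options={"primal_feasibility_tolerance": tol, "dual_feasibility_tolerance": tol},
    )


def producible_components(
    network: MetabolicNetwork,
    active_reactions: Optional[Iterable[str]] = None,
    components: Optional[Sequence[str]] = None,
    eps: float = DEFAULT_EPS,
    lp_tol: float = DEFAULT_LP_TOL,
) -> Dict[str, bool]:
    """Decide producibility of several metabolites on one network state.

    All demands are maximised jointly in a single LP, each capped at
    ``eps``; a metabolite counts producible iff its demand reaches
    ``eps/2``.  Because the feasible set is convex and the caps are tiny
    relative to flux bounds, every individually producible component
    reaches its cap in the joint optimum; any demand landing in the
    ambiguous band is re-decided by an individual LP.
    """
    comps = list(components if components is not None else network.biomass_components)
    unknown = [m for m in comps if m not in network.metabolites]
    if unknown:
        raise NetworkError(f"undeclared metabolites: {unknown}")
    rxn_by_id = {r.id: r for r in network.reactions}
    if active_reactions is None:
        active = list(network.reactions)
    else:
        active = [rxn_by_id[rid] for rid in active_reactions]
    if not active:
        return {m: False for m in comps}

    S, mets, lb, ub = _lp_matrix(network, active, extra_mets=comps)
    n, p = len(active), len(comps)
    # decision demands (capped at eps) for the queried metabolites plus
    # relief sinks for all biomass components: steady state must allow
    # biomass to drain, otherwise terminal pathways could carry no flux
    relief = [m for m in network.biomass_components if m in mets]
    q = len(relief)
    A = np.hstack([S, np.zeros((S.shape[0], p + q))])
    for j, m in enumerate(comps):
        A[mets[m], n + j] = -1.0  # demand sink
    for j, m in enumerate(relief):
        A[mets[m], n + p + j] = -1.0
    c = np.concatenate([np.zeros(n), -np.ones(p), np.zeros(q)])
    bounds = (
        [(l, u) for l, u in zip(lb, ub)]
        + [(0.0, eps)] * p
        + [(0.0, DEFAULT_SINK_BOUND)] * q
    )
    res = _solve(c, A, np.zeros(A.shape[0]), bounds, lp_tol)
    if res.status not in (0, 2):  # optimal or infeasible
        raise NetworkError(f"producibility LP failed for {comps}: {res.message}")
    if res.status == 2:
        # S v = 0 with v = 0 is always feasible; reaching here means a
        # numerically broken model
        raise NetworkError(f"producibility LP infeasible for {comps}: {res.message}")

    out: Dict[str, bool] = {}
    demands = res.x[n:]
    for j, m in enumerate(comps):
        d = demands[j]
        if d >= 0.5 * eps:
            out[m] = True
        elif d <= 1e-2 * eps:
            out[m] = False
        else:  # ambiguous under joint maximisation: decide alone
            cj = np.zeros(n + p + q)
            cj[n + j] = -1.0
            rj = _solve(cj, A, np.zeros(A.shape[0]), bounds, lp_tol)
            if rj.status != 0:
                raise NetworkError(f"producibility LP failed for {m}: {rj.message}")
            out[m] = rj.x[n + j] >= 0.5 * eps
    return out


def producible(
    network: MetabolicNetwork,
    metabolite: str,
    active_reactions: Optional[Iterable[str]] = None,
    eps: float = DEFAULT_EPS,
    lp_tol: float = DEFAULT_LP_TOL,
) -> bool:
    """True iff a steady-state flux within bounds delivers ``metabolite``
    to a demand sink at flux >= ``eps`` on the given network state."""
    return producible_components(
        network, active_reactions, components=[metabolite], eps=eps, lp_tol=lp_tol
    )[metabolite]


def find_blocked(
    network: MetabolicNetwork,
    active_reactions: Sequence[str],
    eps: float = DEFAULT_EPS,
    lp_tol: float = DEFAULT_LP_TOL,
    known_unblocked: Optional[Iterable[str]] = None,
) -> FrozenSet[str]:
    """Reactions of ``active_reactions`` that cannot carry flux >= eps
    (in absolute value) in any feasible steady state of that set.

    Resolution is batched: maximising the summed flux of unresolved
    reactions certifies many at once from a single LP solution; the
    stragglers get individual two-sided feasibility LPs.  The answer is
    a property of the flux polytope, hence independent of visit order.
    """
    rxn_by_id = {r.id: r for r in network.reactions}
    active = [rxn_by_id[rid] for rid in active_reactions]
    if not active:
        return frozenset()
    S, mets, lb, ub = _lp_matrix(network, active)
    # biomass demand sinks keep terminal pathways flux-capable
    relief = [m for m in network.biomass_components if m in mets]
    S = np.hstack([S, np.zeros((S.shape[0], len(relief)))])
    for j, m in enumerate(relief):
        S[mets[m], len(active) + j] = -1.0
    bounds = list(zip(lb, ub)) + [(0.0, DEFAULT_SINK_BOUND)] * len(relief)
    b = np.zeros(S.shape[0])
    ids = [r.id for r in active]
    idx = {rid: j for j, rid in enumerate(ids)}
    unblocked = set(known_unblocked or ()) & set(ids)
    unresolved = [rid for rid in ids if rid not in unblocked]

    def mark(x):
        newly = [rid for rid in unresolved if abs(x[idx[rid]]) >= eps]
        unblocked.update(newly)
        return bool(newly)

    n_cols = S.shape[1]
    while unresolved:
        c = np.zeros(n_cols)
        for rid in unresolved:
            c[idx[rid]] = -1.0
        res = _solve(c, S, b, bounds, lp_tol)
        if res.status != 0:
            raise NetworkError(f"flux LP failed: {res.message}")
        progressed = mark(res.x)
        unresolved = [rid for rid in unresolved if rid not in unblocked]
        if not progressed:
            break
    for rid in list(unresolved):
        if rid in unblocked:
            continue
        j = idx[rid]
        for sense in (-1.0, 1.0):
            if sense > 0 and lb[j] >= 0:
                continue  # irreversible: only the forward direction exists
            c = np.zeros(n_cols)
            c[j] = sense
            res = _solve(c, S, b, bounds, lp_tol)
            if res.status != 0:
                raise NetworkError(f"flux LP failed for {rid}: {res.message}")
            if mark(res.x):
                break
    return frozenset(rid for rid in ids if rid not in unblocked)


def biomass_fitness(
    network: MetabolicNetwork,
    active_reactions: Optional[Iterable[str]] = None,
    eps: float = DEFAULT_EPS,
    lp_tol: float = DEFAULT_LP_TOL,
) -> float:
    """Fitness = fraction of biomass components producible at steady state."""
    prod = producible_components(network, active_reactions, eps=eps, lp_tol=lp_tol)
    return sum(prod.values()) / len(network.biomass_components)


FitnessFn = Callable[[MetabolicNetwork, Sequence[str]], float]


def extract_submodel(
    network: MetabolicNetwork,
    removed: Iterable[str],
    fitness_fn: Optional[FitnessFn] = None,
    candidates: Optional[Sequence[str]] = None,
    eps: float = DEFAULT_EPS,
    lp_tol: float = DEFAULT_LP_TOL,
) -> SubModel:
    """Build the sub-model obtained by removing a gene set.

    Reactions whose GPR evaluates false on the surviving genes are
    deactivated, then blocked reactions are pruned iteratively to a
    fixed point.  ``candidates`` optionally restricts the starting
    reaction set (used to walk a removal series incrementally: the
    active set only shrinks as genes are removed).
    """
    removed = frozenset(removed)
    extra = removed - network.genes
    if extra:
        raise NetworkError(f"removed genes not in the network: {sorted(extra)}")
    present = network.genes - removed
    pool = (
        [network.reaction(rid) for rid in candidates]
        if candidates is not None
        else list(network.reactions)
    )
    active = [r.id for r in pool if evaluate_gpr(r.gpr, present)]

    known_unblocked: set = set()
    while True:
        blocked = find_blocked(network, active, eps=eps, lp_tol=lp_tol,
                               known_unblocked=known_unblocked)
        if not blocked:
            break
        active = [rid for rid in active if rid not in blocked]
        # certificates from the larger set stay valid: blocked reactions
        # carry zero flux in every solution, so solutions restrict
        known_unblocked = set(active)

    present_genes = frozenset()
    for rid in active:
        present_genes |= network.reaction(rid).genes
    present_genes &= present

    fit_fn = fitness_fn or (lambda net, act: biomass_fitness(net, act, eps=eps, lp_tol=lp_tol))
    fit = float(fit_fn(network, active))
    return SubModel(
        parent=network,
        removed_genes=removed,
        active_reactions=tuple(active),
        present_genes=present_genes,
        fitness=fit,
    )
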