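"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the package's LP / vectorised code paths:
producibility is decided by scope expansion (valid for the unit-
coefficient, acyclic toy networks the suite generates), multiple-testing
adjustment by a literal step-up, and interval algebra by per-base-pair
boolean masks.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Sequence, Set, Tuple

import numpy as np

from gsmdep.gpr import evaluate_gpr
from gsmdep.network import MetabolicNetwork


def expansion_producible(
    network: MetabolicNetwork,
    removed: Iterable[str],
    metabolite: str,
) -> bool:
    """Scope-expansion reachability: a metabolite is producible iff some
    chain of GPR-active reactions, each firing only once all its
    substrates are available, reaches it from an imported nutrient.
    Exact for unit-stoichiometry acyclic networks with open exchanges."""
    present = network.genes - frozenset(removed)
    active = [r for r in network.reactions if evaluate_gpr(r.gpr, present)]
    available: Set[str] = set()
    for r in active:
        if r.id in network.exchanges:
            available |= {m for m, c in r.stoichiometry.items() if c > 0}
    changed = True
    while changed:
        changed = False
        for r in active:
            subs = {m for m, c in r.stoichiometry.items() if c < 0}
            prods = {m for m, c in r.stoichiometry.items() if c > 0}
            if subs and subs <= available and not prods <= available:
                available |= prods
                changed = True
            if r.reversible and prods <= available and not subs <= available:
                available |= subs
                changed = True
    return metabolite in available


def expansion_fitness(network: MetabolicNetwork, removed: Iterable[str]) -> float:
    comps = network.biomass_components
    return sum(expansion_producible(network, removed, m) for m in comps) / len(comps)


def bh_stepup(pvals: Sequence[float]) -> np.ndarray:
    """Literal Benjamini–Hochberg step-up adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


def brute_merge(
    intervals: Sequence[Tuple[str, int, int]], max_gap: int = 1
) -> List[Tuple[str, int, int]]:
    """Gap-merge via per-bp boolean masks (gap < max_gap joins pieces)."""
    chroms = sorted({c for c, _, _ in intervals})
    out: List[Tuple[str, int, int]] = []
    for chrom in chroms:
        ivs = [(s, e) for c, s, e in intervals if c == chrom and e > s]
        if not ivs:
            continue
        hi = max(e for _, e in ivs)
        mask = np.zeros(hi + max_gap + 1, dtype=bool)
        for s, e in ivs:
            mask[s:e] = True
        # close gaps shorter than max_gap
        pos = 0
        while pos < len(mask):
            if not mask[pos]:
                nxt = pos
                while nxt < len(mask) and not mask[nxt]:
                    nxt += 1
                if 0 < pos and nxt < len(mask) and (nxt - pos) < max_gap:
                    mask[pos:nxt] = True
                pos = nxt
            else:
                pos += 1
        # the mask is padded with trailing False, so roll-based edge
        # detection is safe at both ends
        starts = np.flatnonzero(mask & ~np.roll(mask, 1))
        ends = np.flatnonzero(mask & ~np.roll(mask, -1)) + 1
        out.extend((chrom, int(s), int(e)) for s, e in zip(starts, ends))
    return sorted(out)


def brute_intersect(
    a: Sequence[Tuple[str, int, int]], b: Sequence[Tuple[str, int, int]]
) -> List[Tuple[str, int, int]]:
    chroms = sorted({c for c, _, _ in list(a) + list(b)})
    out: List[Tuple[str, int, int]] = []
    for chrom in chroms:
        hi = max([e for c, _, e in list(a) + list(b) if c == chrom], default=0)
        if hi == 0:
            continue
        ma = np.zeros(hi + 1, dtype=bool)  # trailing False pads the edges
        mb = np.zeros(hi + 1, dtype=bool)
        for c, s, e in a:
            if c == chrom:
                ma[s:e] = True
        for c, s, e in b:
            if c == chrom:
                mb[s:e] = True
        mask = ma & mb
        starts = np.flatnonzero(mask & ~np.roll(mask, 1))
        ends = np.flatnonzero(mask & ~np.roll(mask, -1)) + 1
        out.extend((chrom, int(s), int(e)) for s, e in zip(starts, ends))
    return sorted(out)
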