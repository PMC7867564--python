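"""Synthetic fixtures with planted ground truth.

Three generator families, all pure functions of a seed:

* toy viable metabolic networks — branched chains from imported
  nutrients to biomass components, with AND/OR GPRs and shared genes so
  that some gene removals propagate;
* replicate expression designs emulating a multi-condition study
  (defaults: 8 conditions × 6 replicates, as in a 2-tissue × 2-diet ×
  2-time-point design) in which a planted gene set is down-shifted in
  one target condition so its genes rank early for removal; effect 0
  gives a fully exchangeable null;
* strand-split ChIP tag piles — uniform Poisson INPUT, ChIP = the same
  background plus fragments centred in planted enriched regions, 5'
  positions offset by the fragment length between strands.  One planted
  region is short and centred on a phase-0 bin boundary, the case the
  half-bin-shifted repeat exists for.

Truth tables accompany every fixture so downstream recovery tests never
re-derive anything.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .chip import RegionSet, TagTrack, merge_intervals
from .depletion import ExpressionDesign, GeneSet
from .gpr import parse_gpr
from .network import MetabolicNetwork, Reaction, biomass_fitness, extract_submodel

# ---------------------------------------------------------------------
# toy metabolic networks


def make_network(
    seed: int = 0,
    n_genes: int = 30,
    n_biomass: int = 6,
    chain_length: Tuple[int, int] = (3, 6),
    branch_prob: float = 0.35,
    complex_prob: float = 0.2,
    isozyme_prob: float = 0.2,
    two_substrate_prob: float = 0.15,
    isozyme_spares: int = 8,
) -> MetabolicNetwork:
    """A small viable metabolic model with branched topology.

    Each biomass component sits at the end of a reaction chain; chains
    start either from a freshly imported nutrient or (with
    ``branch_prob``) from an intermediate of an earlier chain, so that
    upstream gene removals propagate into several branches.  GPRs mix
    single genes, two-gene complexes (``and``) and isozyme pairs
    (``or``); every gene is used by at least one reaction.  Up to
    ``isozyme_spares`` genes (capped at a third of the pool) are
    attached purely as OR-alternatives to existing rules, so the model
    always carries a population of dispensable isozyme genes — as real
    metabolic models do.  The comprehensive model has fitness exactly 1
    by construction.
    """
    rng = np.random.default_rng(seed)
    genes = [f"g{i:03d}" for i in range(1, n_genes + 1)]
    n_spare = min(isozyme_spares, n_genes // 3)
    spare_genes = [str(g) for g in rng.choice(genes, n_spare, replace=False)]
    primary_genes = [g for g in genes if g not in spare_genes]
    metabolites: List[str] = []
    reactions: List[Reaction] = []
    exchanges: List[str] = []
    biomass: List[str] = []
    intermediates: List[str] = []  # branchable metabolites

    # reaction skeletons first; gene slots are filled afterwards so that
    # every gene is guaranteed an assignment
    skeletons: List[Tuple[str, Dict[str, float]]] = []

    for j in range(n_biomass):
        L = int(rng.integers(chain_length[0], chain_length[1] + 1))
        if j > 0 and intermediates and rng.random() < branch_prob:
            head = str(rng.choice(intermediates))
        else:
            nutrient = f"N{j + 1}"
            metabolites.append(nutrient)
            ex_id = f"EX_{nutrient}"
            reactions.append(Reaction(id=ex_id, stoichiometry={nutrient: 1.0},
                                      reversible=False, lower_bound=0.0,
                                      upper_bound=1000.0, gpr=None))
            exchanges.append(ex_id)
            head = nutrient
        prev = head
        for s in range(L):
            last = s == L - 1
            met = f"B{j + 1}" if last else f"M{j + 1}_{s + 1}"
            metabolites.append(met)
            stoich = {prev: -1.0, met: 1.0}
            if intermediates and rng.random() < two_substrate_prob:
                co = str(rng.choice(intermediates))
                if co not in (prev, met):
                    stoich[co] = -1.0
            skeletons.append((f"R{j + 1}_{s + 1}", stoich))
            if not last:
                intermediates.append(met)
            prev = met
        biomass.append(f"B{j + 1}")

    # gene slots: single gene, complex (and) or isozymes (or)
    patterns = []
    for rid, _ in skeletons:
        u = rng.random()
        if u < complex_prob:
            patterns.append(("and", 2))
        elif u < complex_prob + isozyme_prob:
            patterns.append(("or", 2))
        else:
            patterns.append(("lit", 1))
    n_primary = len(primary_genes)
    n_slots = sum(n for _, n in patterns)
    while n_slots < n_primary:  # widen isozyme families until all genes fit
        i = int(rng.integers(len(patterns)))
        op, n = patterns[i]
        patterns[i] = ("or" if op == "lit" else op, n + 1)
        n_slots += 1
    slot_genes = list(rng.permutation(primary_genes))
    slot_genes += [str(g) for g in rng.choice(primary_genes, size=n_slots - n_primary)]
    rng.shuffle(slot_genes)

    rules = []
    pos = 0
    for (_, _), (op, n) in zip(skeletons, patterns):
        assigned = slot_genes[pos:pos + n]
        pos += n
        if op == "lit" or len(set(assigned)) == 1:
            rules.append(assigned[0])
        else:
            rules.append(f" {op} ".join(sorted(set(assigned))))
    # spare isozymes: each added as a pure OR-alternative to one rule,
    # so its knockout can never deactivate a reaction
    for g, i in zip(spare_genes,
                    rng.choice(len(rules), size=n_spare, replace=n_spare > len(rules))):
        rules[i] = f"({rules[i]}) or {g}"
    for (rid, stoich), rule in zip(skeletons, rules):
        reactions.append(Reaction(id=rid, stoichiometry=stoich, reversible=False,
                                  lower_bound=0.0, upper_bound=1000.0,
                                  gpr=parse_gpr(rule)))

    network = MetabolicNetwork(
        metabolites=tuple(dict.fromkeys(metabolites)),
        reactions=tuple(reactions),
        biomass_components=tuple(biomass),
        exchanges=frozenset(exchanges),
    )
    fit = biomass_fitness(network)
    if fit != 1.0:
        raise AssertionError(f"generated network is not viable (fitness {fit})")
    return network


# ---------------------------------------------------------------------
# expression designs


@dataclass(frozen=True)
class ExpressionTruth:
    planted_set: Optional[str]
    target_condition: Optional[str]
    effect: float
    noise_sd: float


def make_expression(
    network: MetabolicNetwork,
    seed: int = 0,
    n_conditions: int = 8,
    n_replicates: int = 6,
    planted: Optional[GeneSet] = None,
    target_condition: Optional[str] = None,
    effect: float = 3.0,
    noise_sd: float = 0.25,
    baseline_log_mean: float = 4.0,
    baseline_log_sd: float = 1.0,
    extra_genes: int = 20,
) -> Tuple[ExpressionDesign, ExpressionTruth]:
    """Replicate expression profiles with an optional planted signal.

    Baselines are log-normal and shared across samples; replicates
    differ only by log-normal noise (sd ``noise_sd`` on the log scale).
    In the target condition the planted set's genes are down-shifted by
    ``effect`` log units, so they rank early for removal there; with
    ``effect=0`` all conditions are exchangeable (the null fixture).

    Planted genes are drawn above-median baselines (half-normal above
    the log-mean): the planted signal is "ranked low in the target
    condition only", which requires the genes not to sit at the bottom
    of the ranking everywhere to begin with.
    """
    rng = np.random.default_rng(seed)
    conditions = [f"C{i + 1}" for i in range(n_conditions)]
    if planted is not None and target_condition is None:
        target_condition = conditions[0]
    gene_list = sorted(network.genes) + [f"x{i:03d}" for i in range(1, extra_genes + 1)]
    baselines = np.exp(rng.normal(baseline_log_mean, baseline_log_sd, len(gene_list)))
    samples, condition_of = [], {}
    columns = {}
    planted_mask = np.array(
        [planted is not None and g in planted.members for g in gene_list]
    )
    if planted_mask.any():
        n_planted = int(planted_mask.sum())
        baselines[planted_mask] = np.exp(
            baseline_log_mean
            + np.abs(rng.normal(0.0, baseline_log_sd, n_planted))
        )
    for cond in conditions:
        for r in range(n_replicates):
            sample = f"{cond}_r{r + 1}"
            samples.append(sample)
            condition_of[sample] = cond
            vals = baselines * np.exp(rng.normal(0.0, noise_sd, len(gene_list)))
            if planted is not None and cond == target_condition:
                vals = np.where(planted_mask, vals * np.exp(-effect), vals)
            columns[sample] = vals
    design = ExpressionDesign(
        values=pd.DataFrame(columns, index=gene_list),
        condition_of=condition_of,
    )
    truth = ExpressionTruth(
        planted_set=planted.name if planted is not None else None,
        target_condition=target_condition if planted is not None else None,
        effect=effect,
        noise_sd=noise_sd,
    )
    return design, truth


def make_gene_sets(
    network: MetabolicNetwork,
    seed: int = 0,
    n_sets: int = 30,
    size_range: Tuple[int, int] = (4, 10),
    planted_size: int = 6,
    planted_name: str = "GS_PLANTED",
    include_planted: bool = True,
) -> Tuple[List[GeneSet], Optional[GeneSet]]:
    """A random gene-set collection over the network's genes; the first
    set is the designated planted set (when requested).

    Planted members are chosen to be fitness-redundant (isozymes or
    otherwise dispensable genes, found by actual knockout scoring, with
    the joint removal checked greedily): their early removal in the
    target condition then crashes the depletion curve at high fitness*
    without degrading the model — the signature of a genuinely
    condition-discrepant gene set.  If a member's removal also sank
    fitness, fitness* itself would collapse and the curve would hug the
    diagonal in every condition, hiding the planted contrast.  Decoy
    sets are plain random draws.
    """
    rng = np.random.default_rng(seed)
    genes = sorted(network.genes)
    sets: List[GeneSet] = []
    planted = None
    if include_planted:
        single = {g: extract_submodel(network, {g}).fitness for g in genes}
        # most dispensable first; rng breaks ties so the set varies by seed
        order = sorted(genes, key=lambda g: (-single[g], rng.random()))
        picks: List[str] = []
        current = 1.0
        for g in order:
            if len(picks) >= planted_size:
                break
            joint = extract_submodel(network, set(picks) | {g}).fitness
            if joint >= current - 1e-12 or len(picks) < 2:
                picks.append(g)
                current = joint
        for g in order:  # top up if strict neutrality ran out of genes
            if len(picks) >= planted_size:
                break
            if g not in picks:
                picks.append(g)
        planted = GeneSet(planted_name, frozenset(picks),
                          description="planted discrepant set")
        sets.append(planted)
    n_decoys = n_sets - len(sets)
    for i in range(n_decoys):
        size = int(rng.integers(size_range[0], size_range[1] + 1))
        members = frozenset(str(g) for g in rng.choice(genes, size, replace=False))
        sets.append(GeneSet(f"GS{i + 1:04d}", members, description="decoy set"))
    return sets, planted


# ---------------------------------------------------------------------
# causal-gene fixture


@dataclass(frozen=True)
class CausalFixture:
    network: MetabolicNetwork
    design: ExpressionDesign
    gene_set: GeneSet
    causal_gene: str


def make_causal_fixture(
    seed: int = 0,
    n_conditions: int = 4,
    n_replicates: int = 3,
    noise_sd: float = 0.1,
) -> CausalFixture:
    """A hand-built network in which exactly one gene is a high-impact
    cause of the tracked gene set's depletion.

    The gene set's members sit on a metabolic branch gated by a single
    upstream gene (the planted cause, itself outside the set); that
    gene is expressed lowest everywhere, so its removal comes first and
    prunes all member reactions in one large, early, consistent
    descent.  Ten ungated parallel biomass branches keep the fitness
    loss of that removal moderate, so the descent is steep (Δy ≫ Δx)
    rather than merely early.  The set's remaining member lives on one
    of the parallel branches and is expressed highest, so its own
    descent happens at fitness* ≈ 0 and fails the position filter.
    """

    def rxn(rid, stoich, gpr=None):
        return Reaction(id=rid, stoichiometry=stoich, reversible=False,
                        lower_bound=0.0, upper_bound=1000.0, gpr=parse_gpr(gpr))

    members = [f"gM{i}" for i in range(1, 6)]
    others = [f"gO{i:02d}" for i in range(1, 11)]
    causal = "gCAUSAL"
    outlier = "gOUT"  # member on a parallel branch, removed last

    mets = (["X0", "X1"] + [f"Y{i}" for i in range(1, 6)]
            + ["Z0"] + [f"BZ{i:02d}" for i in range(1, 11)] + ["BZout"])
    reactions = [
        Reaction(id="EX_X0", stoichiometry={"X0": 1.0}),
        Reaction(id="EX_Z0", stoichiometry={"Z0": 1.0}),
        rxn("R_head", {"X0": -1.0, "X1": 1.0}, causal),
    ]
    biomass = []
    for i, g in enumerate(members, start=1):
        reactions.append(rxn(f"R_Y{i}", {"X1": -1.0, f"Y{i}": 1.0}, g))
        biomass.append(f"Y{i}")
    for i, g in enumerate(others, start=1):
        reactions.append(rxn(f"R_Z{i:02d}", {"Z0": -1.0, f"BZ{i:02d}": 1.0}, g))
        biomass.append(f"BZ{i:02d}")
    reactions.append(rxn("R_BZout", {"Z0": -1.0, "BZout": 1.0}, outlier))
    biomass.append("BZout")

    network = MetabolicNetwork(
        metabolites=tuple(mets),
        reactions=tuple(reactions),
        biomass_components=tuple(biomass),
        exchanges=frozenset(["EX_X0", "EX_Z0"]),
    )

    gene_set = GeneSet("GS_BRANCH", frozenset(members + [outlier]),
                       description="branch gene set with one outside cause")

    base = {causal: 1.0, outlier: 50000.0}
    for i, g in enumerate(members):
        base[g] = 100.0 * (i + 1)
    for i, g in enumerate(others):
        base[g] = 2000.0 * (i + 1)

    rng = np.random.default_rng(seed)
    genes = sorted(network.genes)
    columns, condition_of = {}, {}
    for c in range(n_conditions):
        cond = f"C{c + 1}"
        for r in range(n_replicates):
            sample = f"{cond}_r{r + 1}"
            condition_of[sample] = cond
            columns[sample] = [
                base[g] * float(np.exp(rng.normal(0.0, noise_sd))) for g in genes
            ]
    design = ExpressionDesign(
        values=pd.DataFrame(columns, index=genes), condition_of=condition_of
    )
    return CausalFixture(network=network, design=design, gene_set=gene_set,
                         causal_gene=causal)


# ---------------------------------------------------------------------
# ChIP fixtures


@dataclass(frozen=True)
class ChipSim:
    chip_tracks: Dict[str, TagTrack]
    input_of: Dict[str, TagTrack]
    condition_of: Dict[str, str]
    truth_regions: RegionSet
    fragment_length: int
    fold: float


def make_chip(
    seed: int = 0,
    chrom_sizes: Optional[Mapping[str, int]] = None,
    fragment_length: int = 200,
    depth: int = 300_000,
    n_regions: int = 12,
    region_width: int = 5000,
    straddle_width: int = 400,
    fold: float = 10.0,
    n_conditions: int = 1,
    n_replicates: int = 2,
    bin_size: int = 500,
) -> ChipSim:
    """Planted-region ChIP tracks plus matched uniform INPUTs.

    INPUT tags are uniform with Poisson depth.  ChIP tags are the same
    background plus fragments centred uniformly inside the truth
    regions at ``fold`` times the background rate; each fragment
    contributes one 5' tag offset by ±fragment_length/2 from the centre
    according to its strand.  The first truth region is short and
    centred exactly on a phase-0 bin boundary.  With ``fold=1`` ChIP
    and INPUT are exchangeable (the null fixture).
    """
    if chrom_sizes is None:
        chrom_sizes = {"chrA": 700_000, "chrB": 300_000}
    rng = np.random.default_rng(seed)
    genome = sum(chrom_sizes.values())
    chroms = sorted(chrom_sizes)

    # --- truth regions: the straddler first, then wide regions
    regions: List[Tuple[str, int, int]] = []
    c0 = chroms[0]
    boundary = int(rng.integers(20, chrom_sizes[c0] // bin_size - 20)) * bin_size
    regions.append((c0, boundary - straddle_width // 2, boundary + straddle_width // 2))
    attempts = 0
    while len(regions) < n_regions and attempts < 10_000:
        attempts += 1
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(5_000, chrom_sizes[chrom] - region_width - 5_000))
        cand = (chrom, start, start + region_width)
        if all(c != chrom or start >= e + 2_000 or start + region_width <= s - 2_000
               for c, s, e in regions):
            regions.append(cand)
    truth = RegionSet(regions=tuple(merge_intervals(regions)))

    def uniform_tags(n: int) -> Tuple[Dict[str, np.ndarray], Dict[str, np.ndarray]]:
        per = rng.multinomial(n, [chrom_sizes[c] / genome for c in chroms])
        pos = {c: rng.integers(0, chrom_sizes[c], size=m) for c, m in zip(chroms, per)}
        strand = {c: rng.random(m) < 0.5 for c, m in zip(chroms, per)}
        return pos, strand

    def chip_sample(sid: str) -> TagTrack:
        pos, strand = uniform_tags(rng.poisson(depth))
        lam = depth / genome
        half = fragment_length // 2
        for chrom, s, e in truth.regions:
            extra = rng.poisson(max(fold - 1.0, 0.0) * lam * (e - s))
            centers = rng.integers(s, e, size=extra)
            plus = rng.random(extra) < 0.5
            five = np.where(plus, centers - half, centers + half)
            five = np.clip(five, 0, chrom_sizes[chrom] - 1)
            pos[chrom] = np.concatenate([pos[chrom], five])
            strand[chrom] = np.concatenate([strand[chrom], plus])
        return TagTrack(sample_id=sid, role="chip", chrom_sizes=dict(chrom_sizes),
                        positions={c: p.astype(np.int64) for c, p in pos.items()},
                        is_plus=strand)

    chip_tracks, input_of, condition_of = {}, {}, {}
    for c in range(n_conditions):
        cond = f"K{c + 1}"
        for r in range(n_replicates):
            sid = f"{cond}_r{r + 1}"
            condition_of[sid] = cond
            chip_tracks[sid] = chip_sample(sid)
            ipos, istrand = uniform_tags(rng.poisson(depth))
            input_of[sid] = TagTrack(
                sample_id=f"{sid}_input", role="input", chrom_sizes=dict(chrom_sizes),
                positions={c_: p.astype(np.int64) for c_, p in ipos.items()},
                is_plus=istrand,
            )
    return ChipSim(chip_tracks=chip_tracks, input_of=input_of,
                   condition_of=condition_of, truth_regions=truth,
                   fragment_length=fragment_length, fold=fold)
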