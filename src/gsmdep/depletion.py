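"""Depletion curves of gene sets along expression-ranked gene removal.

For each expression sample, genes are ranked by expression (lowest
first) and removed cumulatively from the comprehensive metabolic model,
giving a series of sub-models.  For a gene set *g*, the depletion curve
D(x) is the fraction of *g*'s genes still present in the sub-model,
plotted against x = fitness* of that sub-model.  Curves of replicates
are averaged pointwise per condition, and condition pairs are contrasted
through two area statistics on x in [0, 1]:

* ``abs_area``  (Ā)  — integral of |D̄_U(x) − D̄_V(x)|,
* ``auc_delta`` (Δ)  — AUC_U − AUC_V, the signed counterpart,

so that |Δ| <= Ā always.  Curves are step functions; they are
materialised on a shared uniform grid (1001 points by default) with a
right-continuous step convention, and the integrals are the exact
rectangle sums of the materialised step function.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .network import MetabolicNetwork, SubModel, extract_submodel

DEFAULT_GRID_POINTS = 1001


def make_grid(n_points: int = DEFAULT_GRID_POINTS) -> np.ndarray:
    """Uniform fitness* grid on [0, 1]."""
    return np.linspace(0.0, 1.0, n_points)


# ---------------------------------------------------------------------
# gene sets


@dataclass(frozen=True)
class GeneSet:
    name: str
    members: FrozenSet[str]
    description: str = ""

    def __post_init__(self):
        if not self.members:
            raise ValueError(f"gene set {self.name!r} is empty")


def read_gmt(path) -> List[GeneSet]:
    """Read a GMT file: tab-separated name, description, member genes."""
    sets = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line: {line!r}")
            sets.append(GeneSet(fields[0], frozenset(g for g in fields[2:] if g),
                                description=fields[1]))
    return sets


def write_gmt(sets: Iterable[GeneSet], path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.description, *sorted(s.members)]) + "\n")


def prepare_gene_sets(
    collection: Iterable[GeneSet],
    network: MetabolicNetwork,
    universe: Optional[Iterable[str]] = None,
    min_size: int = 3,
    max_size: int = 50,
    enrich_p: float = 0.1,
) -> List[GeneSet]:
    """Restrict gene sets to network genes and apply the size filter.

    Sets keeping between ``min_size`` and ``max_size`` network genes
    (inclusive) survive.  When a genome ``universe`` is supplied, an
    additional one-sided hypergeometric over-representation pre-filter
    keeps sets whose network-gene count is enriched at p < ``enrich_p``
    (a stand-in for the GO-enrichment pre-selection such collections
    typically undergo).
    """
    net_genes = network.genes
    out: List[GeneSet] = []
    if universe is not None:
        universe = frozenset(universe)
        pop = len(universe)
        hits_in_pop = len(net_genes & universe)
    for s in collection:
        members = s.members & net_genes
        if not (min_size <= len(members) <= max_size):
            continue
        if universe is not None:
            drawn = len(s.members & universe)
            p = hypergeom.sf(len(members) - 1, pop, hits_in_pop, drawn)
            if not p < enrich_p:
                continue
        out.append(replace(s, members=members))
    if not out:
        warnings.warn("no gene sets survive preparation filters", stacklevel=2)
    return out


# ---------------------------------------------------------------------
# expression design


@dataclass(frozen=True)
class ExpressionDesign:
    """A genes x samples expression matrix with a condition assignment."""

    values: pd.DataFrame
    condition_of: Mapping[str, str]

    def __post_init__(self):
        missing = set(self.values.columns) - set(self.condition_of)
        if missing:
            raise ValueError(f"samples without a condition: {sorted(missing)}")
        if (self.values.values < 0).any():
            raise ValueError("expression values must be non-negative")

    @property
    def samples(self) -> List[str]:
        return list(self.values.columns)

    @property
    def conditions(self) -> List[str]:
        seen: Dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(self.condition_of[s], None)
        return list(seen)

    def replicates(self, condition: str) -> List[str]:
        return [s for s in self.samples if self.condition_of[s] == condition]

    @classmethod
    def from_tsv(cls, expression_path, design_path) -> "ExpressionDesign":
        values = pd.read_csv(expression_path, sep="\t", index_col=0)
        design = pd.read_csv(design_path, sep="\t")
        cond = dict(zip(design["sample"].astype(str), design["condition"].astype(str)))
        return cls(values=values, condition_of=cond)

    def to_tsv(self, expression_path, design_path) -> None:
        self.values.to_csv(expression_path, sep="\t")
        pd.DataFrame(
            {"sample": self.samples,
             "condition": [self.condition_of[s] for s in self.samples]}
        ).to_csv(design_path, sep="\t", index=False)

    def align_to_network(self, network: MetabolicNetwork) -> "ExpressionDesign":
        """Ensure every network gene has a row; missing genes are imputed
        at 0 (removed first) with a warning."""
        missing = sorted(network.genes - set(self.values.index))
        if not missing:
            return self
        warnings.warn(
            f"{len(missing)} network genes absent from the expression matrix; "
            f"imputed at 0 (removed first): {missing[:5]}...",
            stacklevel=2,
        )
        pad = pd.DataFrame(0.0, index=missing, columns=self.values.columns)
        return replace(self, values=pd.concat([self.values, pad]))


def rank_genes(values: Mapping[str, float]) -> List[str]:
    """Order genes for removal: ascending expression, ties broken by
    lexicographic gene id (lowest-expressed genes are removed first)."""
    items = values.items() if hasattr(values, "items") else values.to_dict().items()
    return [g for g, _ in sorted(items, key=lambda kv: (kv[1], kv[0]))]


# ---------------------------------------------------------------------
# removal series


def build_series(
    network: MetabolicNetwork,
    ranking: Sequence[str],
    step: int = 1,
    **extract_kwargs,
) -> List[SubModel]:
    """Sub-models at cumulative removal counts i = 0, step, 2·step, …, k.

    ``ranking`` must be a permutation of the network's genes.  The walk
    is incremental: each extraction starts from the previous sub-model's
    active reactions (removal can only shrink the active set).
    """
    if step < 1:
        raise ValueError("step must be >= 1")
    if set(ranking) != set(network.genes) or len(ranking) != network.k:
        raise ValueError("ranking must be a permutation of the network genes")
    k = network.k
    counts = list(range(0, k, step))
    if counts[-1] != k:
        counts.append(k)
    series: List[SubModel] = []
    candidates: Optional[Sequence[str]] = None
    for i in counts:
        sub = extract_submodel(network, ranking[:i], candidates=candidates, **extract_kwargs)
        series.append(sub)
        candidates = sub.active_reactions
    return series


def series_by_sample(
    network: MetabolicNetwork,
    design: ExpressionDesign,
    step: int = 1,
    **extract_kwargs,
) -> Dict[str, List[SubModel]]:
    """One removal series per expression sample (the expensive step;
    downstream permutation tests only relabel these cached series)."""
    design = design.align_to_network(network)
    expr = design.values.loc[sorted(network.genes)]
    return {
        sample: build_series(network, rank_genes(expr[sample]), step=step, **extract_kwargs)
        for sample in design.samples
    }


# ---------------------------------------------------------------------
# curves


@dataclass(frozen=True)
class DepletionCurve:
    """Fraction of a gene set remaining vs fitness*, as a step function.

    ``knots`` hold the exact (fitness*, fraction) pairs of the series in
    removal order (x non-increasing); ``values`` is the curve evaluated
    on the shared uniform ``grid``.  Averaged (condition) curves carry
    grid values only.
    """

    label: str
    grid: np.ndarray
    values: np.ndarray
    knots: Optional[Tuple[np.ndarray, np.ndarray]] = None

    def __post_init__(self):
        if self.values.shape != self.grid.shape:
            raise ValueError("grid/values length mismatch")

    @staticmethod
    def evaluate_knots(knot_x: np.ndarray, knot_y: np.ndarray, x: np.ndarray) -> np.ndarray:
        """Step evaluation: y(x) = y of the most-degraded sub-model whose
        fitness* is still >= x; x above the first knot holds the first y."""
        asc = -np.asarray(knot_x, dtype=float)  # ascending
        count = np.searchsorted(asc, -np.asarray(x, dtype=float), side="right")
        idx = np.clip(count - 1, 0, len(knot_x) - 1)
        return np.asarray(knot_y, dtype=float)[idx]

    @classmethod
    def from_series(
        cls,
        series: Sequence[SubModel],
        gene_set: GeneSet,
        grid: Optional[np.ndarray] = None,
        label: str = "",
    ) -> "DepletionCurve":
        if grid is None:
            grid = make_grid()
        size = len(gene_set.members)
        knot_x = np.array([sub.fitness_star for sub in series], dtype=float)
        knot_y = np.array(
            [len(sub.present_genes & gene_set.members) / size for sub in series],
            dtype=float,
        )
        values = cls.evaluate_knots(knot_x, knot_y, grid)
        return cls(label=label or gene_set.name, grid=grid, values=values,
                   knots=(knot_x, knot_y))

    @classmethod
    def average(cls, curves: Sequence["DepletionCurve"], label: str = "") -> "DepletionCurve":
        """Pointwise mean of replicate curves on the shared grid."""
        if not curves:
            raise ValueError("no curves to average")
        grid = curves[0].grid
        for c in curves[1:]:
            if c.grid.shape != grid.shape or not np.array_equal(c.grid, grid):
                raise ValueError("curves must share the same grid")
        values = np.mean([c.values for c in curves], axis=0)
        return cls(label=label, grid=grid, values=values)


def average_curve(curves: Sequence[DepletionCurve], label: str = "") -> DepletionCurve:
    return DepletionCurve.average(curves, label=label)


def curves_by_sample(
    series_map: Mapping[str, Sequence[SubModel]],
    gene_set: GeneSet,
    grid: Optional[np.ndarray] = None,
) -> Dict[str, DepletionCurve]:
    if grid is None:
        grid = make_grid()
    return {
        sample: DepletionCurve.from_series(series, gene_set, grid=grid,
                                           label=f"{gene_set.name}:{sample}")
        for sample, series in series_map.items()
    }


# ---------------------------------------------------------------------
# area statistics


def step_integral(values: np.ndarray, grid: np.ndarray) -> float:
    """Exact integral of the grid-materialised step function: the value
    on each cell (x_j, x_{j+1}] is the sample at the right edge."""
    return float(np.sum(values[1:] * np.diff(grid)))


def _check_pair(u: DepletionCurve, v: DepletionCurve) -> None:
    if u.grid.shape != v.grid.shape or not np.array_equal(u.grid, v.grid):
        raise ValueError("curves must share the same grid")


def abs_area(curve_u: DepletionCurve, curve_v: DepletionCurve) -> float:
    """Ā — integral over [0, 1] of |D̄_U(x) − D̄_V(x)|."""
    _check_pair(curve_u, curve_v)
    return step_integral(np.abs(curve_u.values - curve_v.values), curve_u.grid)


def auc_delta(curve_u: DepletionCurve, curve_v: DepletionCurve) -> Tuple[float, float, float]:
    """(AUC_U, AUC_V, Δ = AUC_U − AUC_V); |Δ| <= Ā by construction."""
    _check_pair(curve_u, curve_v)
    auc_u = step_integral(curve_u.values, curve_u.grid)
    auc_v = step_integral(curve_v.values, curve_v.grid)
    return auc_u, auc_v, auc_u - auc_v


@dataclass(frozen=True)
class ContrastStatistics:
    """Area statistics of one condition pair (U, V)."""

    pair: Tuple[str, str]
    abs_area: float
    auc_u: float
    auc_v: float

    @property
    def delta(self) -> float:
        return self.auc_u - self.auc_v

    @classmethod
    def from_curves(cls, curve_u: DepletionCurve, curve_v: DepletionCurve,
                    pair: Tuple[str, str]) -> "ContrastStatistics":
        a = abs_area(curve_u, curve_v)
        auc_u, auc_v, _ = auc_delta(curve_u, curve_v)
        return cls(pair=pair, abs_area=a, auc_u=auc_u, auc_v=auc_v)
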