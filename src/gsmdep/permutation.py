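"""Permutation tests for gene-set depletion discrepancy across conditions.

The omnibus statistic for a gene set is E = A*, the maximum absolute
area Ā between condition-averaged depletion curves over all condition
pairs.  Significance is assessed by permuting replicates between
conditions while keeping each condition's replicate count fixed;
replicate curves are cached, so resampling only relabels them (the
expensive sub-model series are never recomputed).  The p-value uses the
add-one estimator

    p = (#{null E >= E_obs} + 1) / (N + 1),

with ties counted in the numerator (conservative).  Post-hoc tests run
the same scheme restricted to each condition pair, with the pair's Ā as
the statistic and the signed AUC difference Δ reported alongside; the
matrix of sign(Δ)·Ā per gene set and contrast feeds clustered-heatmap
summaries.  An exhaustive mode enumerates all distinct relabelings when
their number is small; there the identity relabeling plays the role of
the add-one term.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .depletion import ContrastStatistics, DepletionCurve, abs_area, average_curve


class DesignError(ValueError):
    """Raised for replicate/condition designs unusable for permutation."""


def add_one_pvalue(null_stats: np.ndarray, observed: float) -> float:
    """p = (#{null >= observed} + 1) / (N + 1); ties count as exceedances."""
    null_stats = np.asarray(null_stats, dtype=float)
    return (int(np.sum(null_stats >= observed)) + 1) / (null_stats.size + 1)


def condition_curves(
    curves: Mapping[str, DepletionCurve],
    condition_of: Mapping[str, str],
) -> Dict[str, DepletionCurve]:
    """Average replicate curves per condition (conditions keep the order
    of first appearance over sorted sample ids)."""
    out: Dict[str, List[DepletionCurve]] = {}
    for sample in sorted(curves):
        out.setdefault(condition_of[sample], []).append(curves[sample])
    return {cond: average_curve(reps, label=cond) for cond, reps in out.items()}


def discrepancy_stat(cond_curves: Mapping[str, DepletionCurve]) -> float:
    """A* — the maximum Ā over all unordered condition pairs."""
    conds = list(cond_curves)
    if len(conds) < 2:
        raise DesignError("discrepancy statistic needs at least 2 conditions")
    return max(
        abs_area(cond_curves[u], cond_curves[v])
        for u, v in itertools.combinations(conds, 2)
    )


@dataclass(frozen=True)
class DiscrepancyResult:
    """Omnibus permutation-test result for one gene set."""

    gene_set: str
    e_obs: float
    n_resamples: int
    null_stats: np.ndarray
    p_value: float
    contrasts: Tuple[ContrastStatistics, ...]
    method: str = "sampled"
    seed: Optional[int] = None

    @property
    def a_star(self) -> float:
        return self.e_obs

    def signed_entries(self) -> Dict[str, float]:
        """sign(Δ_{U,V}) · Ā_{U,V} keyed by contrast label 'U_vs_V'."""
        return {
            f"{c.pair[0]}_vs_{c.pair[1]}": float(np.sign(c.delta)) * c.abs_area
            for c in self.contrasts
        }


@dataclass(frozen=True)
class PairwiseResult:
    """Post-hoc permutation test for one condition pair."""

    gene_set: str
    pair: Tuple[str, str]
    abs_area: float
    delta: float
    p_value: float
    n_resamples: int
    method: str = "sampled"


# ---------------------------------------------------------------------
# fast array core


class _CurveMatrix:
    """Replicate curves stacked as a matrix for fast relabeled statistics."""

    def __init__(self, curves: Mapping[str, DepletionCurve], condition_of: Mapping[str, str]):
        self.samples = sorted(curves)
        missing = [s for s in self.samples if s not in condition_of]
        if missing:
            raise DesignError(f"samples without a condition: {missing}")
        self.grid = curves[self.samples[0]].grid
        self.matrix = np.vstack([curves[s].values for s in self.samples])
        conds: Dict[str, None] = {}
        for s in self.samples:
            conds.setdefault(condition_of[s], None)
        self.conditions = list(conds)
        if len(self.conditions) < 2:
            raise DesignError("need at least 2 conditions")
        self.labels = np.array(
            [self.conditions.index(condition_of[s]) for s in self.samples]
        )
        counts = np.bincount(self.labels, minlength=len(self.conditions))
        if (counts < 1).any():
            raise DesignError("every condition needs at least one replicate")
        if (counts < 2).any():
            warnings.warn("conditions with a single replicate make the permutation "
                          "test degenerate", stacklevel=3)
        self.dx = np.diff(self.grid)
        self.pairs = list(itertools.combinations(range(len(self.conditions)), 2))

    def group_means(self, labels: np.ndarray) -> np.ndarray:
        return np.vstack([
            self.matrix[labels == c].mean(axis=0) for c in range(len(self.conditions))
        ])

    def _area(self, diff_values: np.ndarray) -> float:
        return float(np.sum(np.abs(diff_values[1:]) * self.dx))

    def a_star(self, labels: np.ndarray) -> float:
        means = self.group_means(labels)
        return max(self._area(means[u] - means[v]) for u, v in self.pairs)

    def observed_contrasts(self) -> Tuple[ContrastStatistics, ...]:
        means = self.group_means(self.labels)
        aucs = np.sum(means[:, 1:] * self.dx, axis=1)
        return tuple(
            ContrastStatistics(
                pair=(self.conditions[u], self.conditions[v]),
                abs_area=self._area(means[u] - means[v]),
                auc_u=float(aucs[u]),
                auc_v=float(aucs[v]),
            )
            for u, v in self.pairs
        )


def count_distinct_relabelings(group_sizes: Sequence[int]) -> int:
    """Number of distinct assignments of n samples to labelled groups of
    the given sizes: the multinomial coefficient n!/∏ n_c!."""
    n = sum(group_sizes)
    count = math.factorial(n)
    for s in group_sizes:
        count //= math.factorial(s)
    return count


def _enumerate_labelings(sizes: Sequence[int]) -> List[np.ndarray]:
    n = sum(sizes)
    out: List[np.ndarray] = []
    labels = np.empty(n, dtype=int)

    def rec(free: Tuple[int, ...], cond: int):
        if cond == len(sizes) - 1:
            for i in free:
                labels[i] = cond
            out.append(labels.copy())
            return
        for chosen in itertools.combinations(free, sizes[cond]):
            for i in chosen:
                labels[i] = cond
            rec(tuple(i for i in free if i not in chosen), cond + 1)

    rec(tuple(range(n)), 0)
    return out


def _null_stats(
    cm: _CurveMatrix,
    stat,
    n_resamples: int,
    rng: np.random.Generator,
    method: str,
    exhaustive_cap: int,
) -> Tuple[np.ndarray, str]:
    sizes = np.bincount(cm.labels, minlength=len(cm.conditions))
    if method == "auto":
        method = (
            "exhaustive"
            if count_distinct_relabelings(sizes) <= exhaustive_cap
            else "sampled"
        )
    if method == "exhaustive":
        total = count_distinct_relabelings(sizes)
        if total > exhaustive_cap:
            raise DesignError(
                f"{total} distinct relabelings exceed the exhaustive cap {exhaustive_cap}"
            )
        stats = np.array([stat(lab) for lab in _enumerate_labelings(list(sizes))])
        return stats, "exhaustive"
    if method != "sampled":
        raise ValueError(f"unknown method {method!r}")
    stats = np.array([stat(rng.permutation(cm.labels)) for _ in range(n_resamples)])
    return stats, "sampled"


def _finalise_p(null: np.ndarray, observed: float, method: str) -> Tuple[float, int]:
    if method == "exhaustive":
        # the identity relabeling is part of the enumeration and plays
        # the role of the add-one term
        return float(np.mean(null >= observed)), null.size
    return add_one_pvalue(null, observed), null.size


def permutation_pvalue(
    curves: Mapping[str, DepletionCurve],
    condition_of: Mapping[str, str],
    n_resamples: int = 99,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    method: str = "sampled",
    exhaustive_cap: int = 20000,
    gene_set: str = "",
) -> DiscrepancyResult:
    """Omnibus test: is the gene set's depletion discrepant across
    conditions?  Resampling permutes replicates between conditions while
    keeping each condition's replicate count unchanged."""
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    cm = _CurveMatrix(curves, condition_of)
    e_obs = cm.a_star(cm.labels)
    if rng is None:
        rng = np.random.default_rng(seed)
    null, used = _null_stats(cm, cm.a_star, n_resamples, rng, method, exhaustive_cap)
    p, n_used = _finalise_p(null, e_obs, used)
    return DiscrepancyResult(
        gene_set=gene_set,
        e_obs=e_obs,
        n_resamples=n_used,
        null_stats=null,
        p_value=p,
        contrasts=cm.observed_contrasts(),
        method=used,
        seed=seed,
    )


def pairwise_tests(
    curves: Mapping[str, DepletionCurve],
    condition_of: Mapping[str, str],
    n_resamples: int = 99,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    method: str = "sampled",
    exhaustive_cap: int = 20000,
    gene_set: str = "",
) -> List[PairwiseResult]:
    """Post-hoc tests for every unordered condition pair; the statistic
    is the pair's Ā, resampled among the pair's replicates only."""
    cm = _CurveMatrix(curves, condition_of)
    if rng is None:
        rng = np.random.default_rng(seed)
    contrasts = cm.observed_contrasts()
    results: List[PairwiseResult] = []
    for (u, v), obs in zip(cm.pairs, contrasts):
        keep = np.isin(cm.labels, (u, v))
        sub_samples = [s for s, k in zip(cm.samples, keep) if k]
        sub_curves = {s: curves[s] for s in sub_samples}
        sub_cm = _CurveMatrix(sub_curves, condition_of)
        null, used = _null_stats(
            sub_cm, sub_cm.a_star, n_resamples, rng, method, exhaustive_cap
        )
        p, n_used = _finalise_p(null, obs.abs_area, used)
        results.append(
            PairwiseResult(
                gene_set=gene_set,
                pair=obs.pair,
                abs_area=obs.abs_area,
                delta=obs.delta,
                p_value=p,
                n_resamples=n_used,
                method=used,
            )
        )
    return results


# ---------------------------------------------------------------------
# exports


def export_signed_matrix(results: Sequence[DiscrepancyResult]) -> pd.DataFrame:
    """Gene sets x contrasts matrix of sign(Δ)·Ā for heatmap summaries."""
    rows = {r.gene_set: r.signed_entries() for r in results}
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "gene_set"
    return df


def cluster_orders(matrix: pd.DataFrame) -> Tuple[List[str], List[str]]:
    """Row/column dendrogram leaf orders (Euclidean distance, average
    linkage) for rendering the signed matrix as a clustered heatmap."""
    from scipy.cluster.hierarchy import leaves_list, linkage

    def order(frame: pd.DataFrame) -> List[str]:
        if frame.shape[0] < 2:
            return list(frame.index)
        return [frame.index[i] for i in leaves_list(linkage(frame.values, method="average"))]

    return order(matrix), order(matrix.T)


def results_table(
    results: Sequence[DiscrepancyResult],
    pairwise: Optional[Mapping[str, Sequence[PairwiseResult]]] = None,
) -> pd.DataFrame:
    """Flat results table: gene_set, n_pairs, A_star, p, then per-pair
    Ā/Δ (and the pairwise p when post-hoc results are supplied)."""
    records = []
    for r in results:
        rec: Dict[str, object] = {
            "gene_set": r.gene_set,
            "n_pairs": len(r.contrasts),
            "A_star": r.e_obs,
            "p": r.p_value,
        }
        for c in r.contrasts:
            tag = f"{c.pair[0]}_vs_{c.pair[1]}"
            rec[f"{tag}:abs_area"] = c.abs_area
            rec[f"{tag}:delta"] = c.delta
        if pairwise and r.gene_set in pairwise:
            for pr in pairwise[r.gene_set]:
                rec[f"{pr.pair[0]}_vs_{pr.pair[1]}:p"] = pr.p_value
        records.append(rec)
    return pd.DataFrame.from_records(records)
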