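"""Nomination of genes causing descents in a depletion curve.

With unit-step removal, every drop of a gene set's depletion curve is
attributable to exactly one removed gene (which need not belong to the
set: removal can silence set members through network propagation).
Each descent is characterised geometrically in the unit square spanned
by fitness* (x) and fraction-remaining (y):

* descent angle  — arctan(Δy/Δx) in degrees (90° for a vertical drop),
  the influence of the gene;
* descent position — the fitness* at which the curve lands, the
  degradation status of the sub-network at that point.

Candidate causal genes are filtered by (a) a replicate-majority rule —
in at least one condition, strictly more than half of the replicates
show a descent with position and angle above thresholds (defaults 0.1
and 45°) — and (b) cross-condition consistency: RSD of the
per-condition mean position and mean angle both above 0.2.  RSD is
computed as mean/sd by default, as printed in the source method; the
conventional sd/mean is available via ``rsd_convention``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .depletion import GeneSet
from .network import SubModel


class StepError(ValueError):
    """Raised when descent attribution is attempted on a non-unit-step series."""


@dataclass(frozen=True)
class Descent:
    """One drop of a sample's depletion curve, credited to one gene."""

    gene: str
    dy: float          # fraction of the gene set lost (incl. propagation)
    dx: float          # fitness* decrement across the step
    position: float    # fitness* where the curve lands
    sample: str = ""

    @property
    def angle(self) -> float:
        return descent_angle(self.dy, self.dx)


def descent_angle(dy: float, dx: float) -> float:
    """arctan(Δy/Δx) in degrees on the unit-square curve geometry;
    a vertical drop (Δx = 0) is 90°."""
    if dy < 0 or dx < 0:
        raise ValueError("descent increments must be non-negative")
    return math.degrees(math.atan2(dy, dx))


def attribute_descents(
    series: Sequence[SubModel], gene_set: GeneSet, sample: str = ""
) -> List[Descent]:
    """Credit every drop of the depletion curve to the gene removed at
    that step.  Requires a unit-step series (consecutive removal sets
    differing by exactly one gene), otherwise attribution is ambiguous."""
    size = len(gene_set.members)
    descents: List[Descent] = []
    for prev, cur in zip(series, series[1:]):
        added = cur.removed_genes - prev.removed_genes
        if len(added) != 1:
            raise StepError(
                "descent attribution needs a unit-step removal series; "
                "re-run build_series with step=1"
            )
        y_prev = len(prev.present_genes & gene_set.members) / size
        y_cur = len(cur.present_genes & gene_set.members) / size
        dy = y_prev - y_cur
        if dy <= 0:
            continue
        dx = max(prev.fitness_star - cur.fitness_star, 0.0)
        descents.append(
            Descent(gene=next(iter(added)), dy=dy, dx=dx,
                    position=cur.fitness_star, sample=sample)
        )
    return descents


def rsd(values: Sequence[float], convention: str = "mean_over_sd") -> float:
    """Dispersion ratio over per-condition means.

    ``mean_over_sd`` follows the printed definition RSD(x) =
    mean(x)/sd(x); ``sd_over_mean`` is the conventional relative
    standard deviation.  Fewer than two values give NaN; a zero
    denominator gives +inf.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        return float("nan")
    mean, sd = float(np.mean(arr)), float(np.std(arr, ddof=1))
    if convention == "mean_over_sd":
        num, den = mean, sd
    elif convention == "sd_over_mean":
        num, den = sd, mean
    else:
        raise ValueError(f"unknown RSD convention {convention!r}")
    return float("inf") if den == 0 else num / den


@dataclass(frozen=True)
class CausalGeneMetrics:
    """Per-gene descent summaries across samples and conditions."""

    gene: str
    descents: Tuple[Descent, ...]
    condition_means: Mapping[str, Tuple[float, float]]  # cond -> (position, angle)
    rsd_position: float
    rsd_angle: float
    rsd_convention: str = "mean_over_sd"


def collect_causal_metrics(
    series_map: Mapping[str, Sequence[SubModel]],
    gene_set: GeneSet,
    condition_of: Mapping[str, str],
    rsd_convention: str = "mean_over_sd",
) -> Dict[str, CausalGeneMetrics]:
    """Attribute descents in every sample and aggregate them per gene.

    Condition means are taken over the replicates in which the gene
    actually caused a descent; RSDs are taken across those condition
    means.  Genes with descents in zero samples do not appear.
    """
    per_gene: Dict[str, List[Descent]] = {}
    for sample in sorted(series_map):
        for d in attribute_descents(series_map[sample], gene_set, sample=sample):
            per_gene.setdefault(d.gene, []).append(d)

    out: Dict[str, CausalGeneMetrics] = {}
    for gene in sorted(per_gene):
        descents = per_gene[gene]
        by_cond: Dict[str, List[Descent]] = {}
        for d in descents:
            by_cond.setdefault(condition_of[d.sample], []).append(d)
        cond_means = {
            cond: (
                float(np.mean([d.position for d in ds])),
                float(np.mean([d.angle for d in ds])),
            )
            for cond, ds in sorted(by_cond.items())
        }
        out[gene] = CausalGeneMetrics(
            gene=gene,
            descents=tuple(descents),
            condition_means=cond_means,
            rsd_position=rsd([m[0] for m in cond_means.values()], rsd_convention),
            rsd_angle=rsd([m[1] for m in cond_means.values()], rsd_convention),
            rsd_convention=rsd_convention,
        )
    return out


@dataclass(frozen=True)
class CausalThresholds:
    min_position: float = 0.1
    min_angle: float = 45.0
    min_rsd: float = 0.2


@dataclass(frozen=True)
class CausalVerdict:
    gene: str
    majority_ok: bool    # position/angle criteria in a strict majority of
                         # some condition's replicates
    rsd_ok: bool         # both RSD criteria exceeded

    @property
    def passes(self) -> bool:
        return self.majority_ok and self.rsd_ok


def causal_verdicts(
    metrics: Mapping[str, CausalGeneMetrics],
    condition_of: Mapping[str, str],
    replicate_counts: Mapping[str, int],
    thresholds: Optional[CausalThresholds] = None,
) -> Dict[str, CausalVerdict]:
    """Apply the position/angle majority rule and the RSD consistency
    rule.  ``replicate_counts`` gives each condition's replicate total
    (descent-free replicates count in the denominator)."""
    th = thresholds or CausalThresholds()
    out: Dict[str, CausalVerdict] = {}
    for gene in sorted(metrics):
        m = metrics[gene]
        hits: Dict[str, int] = {}
        for d in m.descents:
            if d.position > th.min_position and d.angle > th.min_angle:
                cond = condition_of[d.sample]
                hits[cond] = hits.get(cond, 0) + 1
        majority = any(
            2 * n_hit > replicate_counts[cond] for cond, n_hit in hits.items()
        )
        rsd_ok = bool(m.rsd_position > th.min_rsd and m.rsd_angle > th.min_rsd)
        out[gene] = CausalVerdict(gene=gene, majority_ok=majority, rsd_ok=rsd_ok)
    return out


def filter_causal(
    metrics: Mapping[str, CausalGeneMetrics],
    condition_of: Mapping[str, str],
    replicate_counts: Mapping[str, int],
    thresholds: Optional[CausalThresholds] = None,
) -> List[str]:
    """Genes passing both filter families, sorted by id."""
    verdicts = causal_verdicts(metrics, condition_of, replicate_counts, thresholds)
    return sorted(g for g, v in verdicts.items() if v.passes)


def causal_report(
    metrics: Mapping[str, CausalGeneMetrics],
    condition_of: Mapping[str, str],
    replicate_counts: Mapping[str, int],
    thresholds: Optional[CausalThresholds] = None,
) -> pd.DataFrame:
    """Flat per-gene report: condition means, RSDs and per-criterion
    verdicts (TSV-ready)."""
    verdicts = causal_verdicts(metrics, condition_of, replicate_counts, thresholds)
    records = []
    for gene in sorted(metrics):
        m, v = metrics[gene], verdicts[gene]
        rec: Dict[str, object] = {
            "gene": gene,
            "n_descents": len(m.descents),
            "rsd_position": m.rsd_position,
            "rsd_angle": m.rsd_angle,
            "majority_ok": v.majority_ok,
            "rsd_ok": v.rsd_ok,
            "passes": v.passes,
        }
        for cond, (pos, ang) in m.condition_means.items():
            rec[f"{cond}:mean_position"] = pos
            rec[f"{cond}:mean_angle"] = ang
        records.append(rec)
    return pd.DataFrame.from_records(records)
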