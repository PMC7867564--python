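# gsmdep

Gene-set depletion-curve discrepancy analysis on genome-scale metabolic
networks (GSMNs), with a bin-based ChIP-seq differential-region caller.

## The problem

Differential-expression lists say little about whether a metabolic
*capability* differs between conditions. A complementary question is:
if we degrade a genome-scale metabolic model gene by gene, removing the
least-expressed genes first, how quickly does a given gene set (e.g., a
GO term's genes) disappear from the surviving model — and does that
disappearance behave differently across experimental conditions?

`gsmdep` implements that analysis as a reusable pipeline:

1. **Sub-model series** (`gsmdep.network`, `gsmdep.depletion`). For each
   sample, genes are ranked by expression (ascending; ties by gene id)
   and removed cumulatively from the comprehensive model. After each
   removal, reactions whose gene–protein–reaction (GPR) boolean rule
   fails are deactivated, reactions that can no longer carry steady-state
   flux are pruned (linear feasibility, HiGHS), and the sub-model is
   scored by a **fitness** in [0, 1] — the fraction of biomass
   components still producible — so 1 means full viability and 0 a
   totally degraded model. The x-axis of everything downstream is

   `fitness* = (1 − i/k) · fitness`,

   where `i` genes of `k` were removed.
2. **Depletion curves**. For a gene set *g*, `D(x)` is the fraction of
   *g*'s genes still present in the sub-model with fitness* = x.
   Replicate curves are averaged pointwise per condition.
3. **Discrepancy statistics and permutation tests**
   (`gsmdep.permutation`). For conditions U, V:
   `Ā_U,V = ∫₀¹ |D̄_U − D̄_V| dx` (absolute area between curves) and
   `Δ_U,V = AUC_U − AUC_V` (signed). The omnibus statistic is
   `A* = max_{U,V} Ā_U,V`; significance comes from permuting replicates
   between conditions (group sizes fixed) with the add-one estimator
   `p = (#{E ≥ E_obs} + 1)/(N + 1)`. Post-hoc pairwise tests and the
   `sign(Δ)·Ā` gene-set × contrast matrix (with average-linkage
   clustering orders) are exported for heatmap summaries.
4. **Causal-gene nomination** (`gsmdep.causal`). With unit-step removal,
   every curve descent is attributable to one removed gene (not
   necessarily a member of *g* — pruning propagates). Descents are
   characterised by angle `arctan(Δy/Δx)` and position (fitness* at the
   drop); genes pass if position > 0.1 and angle > 45° in a strict
   majority of some condition's replicates, and the mean/sd dispersion
   ratios of per-condition mean position and angle both exceed 0.2.
5. **ChIP-seq regions** (`gsmdep.chip`). Independently of the metabolic
   pipeline: tags (BED6) are centre-shifted by half the
   cross-correlation-estimated fragment length, counted in 500-nt bins
   (plus a half-bin-shifted phase), tested per bin against matched INPUT
   with a one-sided binomial (library-size expected proportion),
   BH-adjusted (significant at q < 0.05), intersected across biological
   replicates per condition, pooled across conditions, and merged when
   separated by < 500 nt. Per-region densities are normalised by region
   width and library size.
6. **Synthetic data** (`gsmdep.synthetic`). Seeded generators for viable
   toy GSMNs, replicate expression designs with a planted discrepant
   gene set (or an exchangeable null), and strand-split ChIP tag piles
   over planted regions with Poisson background — each with truth
   tables, so every recovery claim in the test suite is scored against
   known ground truth.

## Worked example

```python
from gsmdep import synthetic as synth
from gsmdep import depletion as dep
from gsmdep.permutation import permutation_pvalue, results_table

net = synth.make_network(seed=0)                      # 30 genes, 31 reactions
sets, planted = synth.make_gene_sets(net, seed=1, n_sets=5)
design, truth = synth.make_expression(net, seed=2, n_conditions=4,
                                      n_replicates=6, planted=planted,
                                      effect=3.0)     # planted set low in C1
series = dep.series_by_sample(net, design, step=1)    # the expensive step
results = [
    permutation_pvalue(dep.curves_by_sample(series, gs), design.condition_of,
                       n_resamples=99, seed=0, gene_set=gs.name)
    for gs in sets
]
print(results_table(results)[["gene_set", "n_pairs", "A_star", "p"]].round(3))
```

prints

```
  gene_set  n_pairs  A_star    p
GS_PLANTED        6   0.653 0.01
    GS0001        6   0.081 0.01
    GS0002        6   0.130 0.01
    GS0003        6   0.154 0.01
    GS0004        6   0.084 0.01
```

The planted set's most discrepant pair is `('C1', 'C2')` with
`Ā = 0.653` and `Δ = −0.653`: its depletion curve in C1 (where its genes
rank low and are removed first) lies entirely below the C2 curve, and
two thirds of the unit square separates them. Note that every set
reaches the permutation floor `p = 1/(N+1)` here: a strong planted
shift also perturbs the fitness* trajectory of the target condition
globally, so even unrelated sets become mildly discrepant — it is the
magnitude `A*` (0.653 vs ≤ 0.16) and the pairwise contrasts that single
out the planted set. The planted set attains the minimum p (ties at the
floor included).

A command-line interface mirrors the library
(`gsmdep simulate | discrepancy | causal | chip-regions`); see
`gsmdep --help`.

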