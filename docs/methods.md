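# Methods

This note records the model, the numerical choices, and what the
synthetic fixtures do and do not establish.

## Metabolic model and fitness

A network is metabolites, reactions (stoichiometry, bounds, reversible
flag) and GPR boolean rules (`and`/`or`/identifiers; empty =
spontaneous), with a declared set of biomass components and of exchange
reactions. The JSON dialect is deliberately minimal; SBML import is out
of scope.

**Flux space.** All feasibility questions are posed on
`S·v = 0` with box bounds, *augmented with a non-negative demand sink
(capacity 1000, `DEFAULT_SINK_BOUND`) for every biomass component
present in the active sub-network*. Without these sinks a steady state
could never drain biomass, and every terminal pathway would be
vacuously "blocked". The sinks are part of the network-state
definition, used identically in producibility and blocked-reaction
detection.

**Producibility.** A metabolite is producible iff some feasible flux
delivers it to an additional demand sink at rate ≥ ε (default 1e-6; LP
tolerance 1e-9, both configurable). All queried components are decided
in a single LP maximising the summed demands, each capped at ε: the
feasible set is convex, so if each component is individually producible
their certificates average into a joint solution, and because ε is tiny
relative to the bounds the averaged solution scales back up to the
caps. Any demand landing between 1e-2·ε and ε/2 (possible only under
unusually tight bounds) is re-decided by an individual LP.

**Fitness** of a sub-model is the producible fraction of biomass
components: 1 for the comprehensive model, 0 when nothing is
producible. This is a deliberate, contract-compatible definition (the
score is only pinned down by its endpoints in the method it follows);
`extract_submodel(..., fitness_fn=...)` accepts any alternative scorer.

**Sub-model extraction.** Removing genes deactivates reactions whose
GPR fails; blocked reactions (|flux| < ε in every feasible state) are
then pruned to a fixed point. Blockedness is a property of the flux
polytope, so the result is independent of reaction order (tested).
Detection is batched: maximising the summed flux of unresolved
reactions certifies many per LP solution; stragglers get individual
two-sided LPs. Along a removal series the active set only shrinks, so
each extraction starts from the previous step's active set, and
certificates survive pruning (a blocked reaction is at zero in every
solution). `present_genes` are the non-removed genes appearing in the
GPR of at least one surviving reaction; pruning can therefore silence
genes that were never removed (propagation), which is what makes
causal-gene attribution non-trivial.

## Depletion curves and area statistics

Genes are ranked ascending by expression (lowest removed first; ties by
gene id). This direction is an explicit reading of "expression-based
ranking": the least-supported reactions should be the first to go.
Network genes missing from the matrix are imputed at 0 — removed first
— with a warning.

A curve's knots are `(fitness*_i, |present ∩ g| / |g|)` along the
series. Curves are materialised on a fixed uniform 1001-point grid on
[0, 1] with a step convention: the value at x is that of the
most-degraded sub-model whose fitness* is still ≥ x (ties resolved
toward more degradation; x above the first knot holds 1, x below the
last holds the final value). Condition curves are pointwise means of
replicate curves on the shared grid.

Integration (`Ā`, AUC, `Δ`) is the exact rectangle sum of the
grid-materialised step function (cell value = right-edge sample), so a
10×-refined evaluation of the same function agrees to machine
precision, and grid refinement 1001 → 10001 moves `Ā` by < 1e-3 on
series-derived curves. `Ā` is a pseudometric and `|Δ| ≤ Ā` up to
1e-12 float slack.

Gene-set preparation keeps sets with 3–50 network genes (inclusive) and
optionally applies a one-sided hypergeometric over-representation
pre-filter (p < 0.1) against a supplied genome universe. That filter is
a stand-in for the GO-enrichment pre-selection such collections
normally undergo; it is not a re-implementation of any specific GO
machinery.

## Permutation testing

The omnibus statistic is `A* = max pairs Ā`. Resampling permutes the
sample→condition assignment uniformly while preserving group sizes;
replicate curves are cached, so a resample costs one regrouping of
grid rows. The p-value is the add-one estimator
`(#{null ≥ observed} + 1)/(N + 1)`, ties counted (conservative); it is
bounded below by `1/(N+1)` and reproducible bit-for-bit given a seed.
When the number of distinct label vectors (the multinomial coefficient)
is below a cap, an exhaustive mode enumerates them all and reports
`#{E ≥ E_obs}/M` — the identity assignment plays the add-one role.
Pairwise post-hoc tests rerun the same scheme on each pair's replicates
with the pair's `Ā` as statistic, and report `Δ` alongside. Raw
p-values are reported; no multiplicity correction across gene sets.

A caveat the worked example makes visible: the permutation test is
exact per gene set, but gene sets analysed on the same samples are
correlated — a condition whose ranking is globally perturbed shifts the
fitness* trajectory for *every* set. Calibration statements therefore
concern the marginal rejection rate over independent data draws
(measured at 0.025 for α = 0.05 in this package's null simulations);
on any single fixture the realised rate can deviate substantially in
either direction.

## Causal genes

Unit-step series make every curve drop attributable to exactly one
removed gene; attribution at coarser steps raises an error rather than
guessing. A descent records `Δy` (fraction lost, including propagation
losses — per sample the `Δy` sum equals the curve's total loss to
1e-9), `Δx` (fitness* decrement) and its position, defined as the
fitness* *after* the removal (the knot where the curve lands). The
angle is `atan2(Δy, Δx)` in degrees on the unit square, 90° for a
vertical drop; both axes span [0, 1] so the 45° threshold is
scale-free.

Filters: (a) in at least one condition, a strict majority of replicates
(`2·hits > n`) shows a descent with position > 0.1 and angle > 45°;
(b) the dispersion ratios RSD(mean position) and RSD(mean angle) across
per-condition means both exceed 0.2. RSD is mean/sd by default — as
printed in the method this follows, which is the reciprocal of the
conventional relative standard deviation; `rsd_convention="sd_over_mean"`
switches to the conventional form, and the choice is recorded in the
metrics. Condition means are taken over replicates in which the gene
actually caused a descent; a gene with descents in fewer than two
conditions has undefined RSD (NaN) and fails (b), while zero spread
yields +inf and passes — perfectly consistent behaviour is the
strongest consistency evidence.

## ChIP-seq binning

Fragment length is the argmax (ties → smallest) of the Pearson
cross-correlation between plus- and minus-strand 5′ profiles binned at
the shift step (default 5 bp) over shifts 0–400; a peak correlation
below 0.05 triggers an "unreliable" warning (uniform tags have no
strand structure). Tags are shifted by half the fragment length toward
the fragment centre before binning and density counting.

Bins are 500 nt, phases 0 and 250 (the half-bin repeat exists so that
enrichment split across a phase-0 boundary is still seen whole by the
other phase); with a nonzero phase the first and last bins are partial.
Scaling is counts-per-10-million plus 30 pseudo-counts, log2 — the
scale target and the count scale of the pseudo-counts are explicit
configuration (`scale_to`, `pseudocount`), not claims about any
particular external tool. The per-bin test is a one-sided binomial on
the ChIP count among ChIP+INPUT with expected proportion the library
size ratio — a standard count-enrichment stand-in for an unspecified
"MA-plot" test — BH-adjusted across all bins of the phase (statsmodels;
an independent literal step-up verifies it in the tests), significant
at q < 0.05. Per sample the two phases' significant bins are unioned;
per condition, replicate interval sets are intersected; conditions are
pooled and gaps < 500 nt merged. Coordinates are 0-based half-open
throughout. Region densities are `count / width / total_tags × 1e9`
(tags per bp per 10⁹ library tags; the constant is configurable).

## Synthetic fixtures

Defaults emulate the study design the pipeline targets: 8 conditions ×
6 expression replicates; ChIP with 2 replicates per condition at
300,000 tags over a 1 Mb two-chromosome genome, fragment length 200 bp,
12 planted regions at 10× enrichment — eleven 5 kb regions plus one
400 bp region centred exactly on a phase-0 bin boundary. The 5 kb width
follows from an edge-extension analysis: merged significant bins
overrun each true edge by up to ~500 bp (phase union), so base-pair
Jaccard ≥ 0.8 against truth requires regions ≳ 3 kb.

Toy networks are branched chains from imported nutrients to biomass
components with mixed AND/OR GPRs; every gene is used, generation is a
pure function of the seed, and viability (fitness exactly 1) is
asserted at generation time. A capped fraction of the gene pool
(default 8 of 30) is attached purely as OR-alternatives to existing
rules — guaranteed-dispensable isozymes, mirroring the redundancy real
metabolic models carry, and guaranteeing the planted-set selection
below always has fitness-neutral genes to draw from. Expression is log-normal with shared
baselines and replicate noise (sd 0.25 log units); the planted set's
genes are down-shifted by `effect` log units (default 3) in one target
condition, and `effect=0` yields a fully exchangeable null. Two
properties of the planted set are enforced by construction, because the
planted contrast does not exist without them: members get above-median
baselines (the signal is "ranked low in the target condition *only*"),
and members are fitness-redundant, selected by actual knockout scoring
with a greedy joint check (if planted removals sank fitness, fitness*
would collapse along with the curve and the curve would hug the
diagonal in every condition). The causal-gene fixture is a hand-built
17-gene network in which one upstream gene gates a five-member biomass
branch while ten ungated parallel branches keep its removal's fitness
cost moderate: the gated branch's loss is then a steep (67°), early
(fitness* ≈ 0.65), perfectly consistent descent, and no other gene can
satisfy the filters.

What the fixtures do **not** emulate: real transcriptome covariance
structure, batch or tissue-contamination effects, GC or mappability
bias in ChIP background (Poisson only), realistic GSMN scale
(desk-scale networks of ≤ 50 genes; the reference-scale model has
~1,400). Passing recovery tests therefore demonstrates correctness of
the machinery under its stated assumptions, not field performance on
real data.

## Problem sizes

The shipped tests and the acceptance script run, per design, removal
series for 12–24 samples on 30-gene networks at unit step (a few
seconds each on one CPU), 200 null gene sets at N = 99 resamples for
calibration, 30 sets for recovery, and ~0.9 M simulated ChIP tags —
sizes chosen so the whole acceptance run completes in minutes while
every statistic keeps enough resolution to be meaningful.

## Known limitations

- Fitness is producible-fraction-of-biomass; no claim of numerical
  compatibility with any other implementation of a fitness score.
- The expansion-reachability oracle used by the tests is exact only for
  the unit-stoichiometry acyclic toys generated here; the LP route is
  the general implementation.
- Exhaustive permutation is enumerated only below a configurable cap on
  the multinomial count.
- The ChIP caller assumes single-end tags with strand information and
  matched INPUTs; no duplicate filtering, no local background model
  beyond the matched INPUT.
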