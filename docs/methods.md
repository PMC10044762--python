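# Methods

This note documents the models and procedures implemented in `phenonet`,
the choices made where the design was genuinely open, and what the
synthetic benchmarks do and do not establish.

## The interaction map model

A molecular interaction map is a signed digraph with two node classes.
*Gene* nodes stand for any regulating species — in curated atlases these
include proteins, metabolites and non-coding RNAs, which we deliberately
collapse to a single class because every downstream computation treats
non-phenotype species identically (a signed edge is a signed edge).
*Phenotype* nodes are process readouts (e.g. "NETosis") and are strict
sinks: edges leaving a phenotype are dropped at load with a warning rather
than rejected, so curated files with stray edges still load.  The SIF
vocabulary is fixed to `activates`/`inhibits`; anything else is an error,
because the propagation and motif mathematics consume only a binary sign.
Gene symbols are matched to expression tables case-insensitively after
trimming; unmatched measured genes are counted and logged, never fatal.

## Influence and upstream enrichment

Influence uses attenuated **simple-path** sums rather than walk-based
propagation (matrix powers): interaction maps of inflammation are rich in
feedback loops, on which walk sums diverge or require spectral damping,
while simple paths with a depth cap stay finite and are exactly checkable
against brute-force enumeration.  Paths through other phenotype nodes are
inadmissible, so each phenotype is explained only by molecular routes.

Two parameters matter:

* `alpha` (default 0.5, dimensionless): per-edge attenuation.  At 1.0 all
  path lengths count equally; at small values influence is dominated by
  direct regulators.  0.5 halves each extra step — a middle ground that
  keeps 2–3-step regulation visible without letting long paths swamp
  direct edges.
* `max_depth` (default 5 edges): the horizon of regulation considered.
  Five steps cover typical receptor → adapter → kinase → TF → target
  cascades; the cost of enumeration grows quickly beyond that.

The upstream enrichment score of gene *i* averages significant upstream
genes' |log2FC|, attenuated by shortest-path distance, over the *entire*
depth-D upstream universe (not only its significant members), so a gene
with many silent regulators scores lower than one whose few regulators all
respond.

The phenotype-activity statistic is the influence-weighted signed sum of
significant fold changes.  A signed statistic (rather than
over-representation of a gene set) is required to call a process *up* or
*down*.  Normalization to [−1, +1] is per (contrast, time point) across
phenotypes; consequently normalized activities support within-phenotype
reading across time, and comparing magnitudes *between* phenotypes is
discouraged — different phenotypes have incomparable upstream universes.
The permutation null shuffles (log2FC, p_adj) tuples across all measured
mapped genes — not the whole genome — preserving the map-coverage
structure of the data; p-values use add-one smoothing, so the smallest
attainable p is 1/(n_perm+1).

Whether such scoring should use signed or absolute fold changes is an open
design point; we use signed values throughout because directional readouts
are the purpose of the analysis.

## Perturbation semantics

Perturbation predictions are linear superpositions of influence columns:
`L_p = Σ_g I(g,p)·v_g` with `v_g ∈ {+1, −1}`.  This is a deliberate
modeling simplification — no fixed-point iteration, saturation or Boolean
update — chosen because a static linear readout is exactly additive,
antisymmetric and verifiable against path enumeration, and because the
downstream interpretation (which processes move, in which direction) needs
ranks and signs, not equilibrium trajectories.  Interactions between
simultaneous perturbations are therefore not modeled.

## DEG overlays and the opposite-direction rule

Significance is per (gene, time point) at `p_adj < τ` (default 0.05);
uniqueness of a gene to one contrast means "significant at some time in A
and at *no* time in B".  A common gene is called oppositely regulated when
some shared time point has both contrasts significant with opposite
log2FC signs; when the contrasts are significant only at disjoint time
points, we compare the signs of each contrast's maximum-|log2FC|
significant estimate.  This two-branch rule is a concrete choice — the
underlying notion ("up in one treatment, down in the other, across the
time course") does not fix a shared-time requirement — and genes called
opposite by the fallback branch are flagged in the output.

The induction filter keeps genes significant and upregulated at a focal
time (default 120 h) whose base-mean count there strictly exceeds every
earlier time point's, separating genuine late induction from fold changes
driven by a falling control; genes missing a base mean at any earlier time
are excluded because the comparison is unavailable.

## Differential expression stand-in

`simple_de` is intentionally simple: Welch's t-test on
log2(normalized count + 0.5) with Benjamini–Hochberg correction per
(contrast, time) stratum, and median-of-ratios library-size factors.  It
is *not* a negative-binomial GLM and does not shrink dispersions or fold
changes; externally computed tables (DESeq2, edgeR, limma) are accepted as
first-class input, and the pipeline contract downstream of the DEG table
is engine-agnostic.  Pseudo-counts: +1 inside the PCA log-transform, +0.5
inside the DE log-transform.

PCA outlier screening works per (group, time) stratum on gene-centered
log2(normalized + 1) profiles projected to the top two principal
components; a sample is flagged when its distance to the stratum centroid
exceeds median + 3×MAD.  Strata with fewer than four samples are skipped.
The criterion is deliberately lax (a per-sample false-flag rate of a few
percent on clean replicates) since flags are a screen for human review,
not an automatic exclusion; tests assert the false-flag *rate*, not
per-stratum absence of flags.

## Motif ranking and the Pareto set

A feedback loop is read strictly as a directed simple cycle; the motif
size is fixed at three genes (exposed as the cycle length bound in the
enumeration).  Features are min–max normalized over the candidate
population; a feature constant across the population maps to 0.5, giving
it a scenario-independent, non-discriminating contribution.  The weight
grid is the full 27-point product of {0.33, 0.66, 1.0}³ and selection is a
single pass: the union of each scenario's top-m motifs (default m = 5,
deterministic lexicographic tie-breaks).  We do not re-rank after removing
selected motifs; the union already contains every motif that excels under
at least one weighting, which is the Pareto-set reading we adopt.  A
candidate cap (default 20 000, by descending influence feature) guards
against combinatorial blow-up on dense maps and is a documented deviation
knob.

## The synthetic benchmark

The generator emulates the statistical structure of a two-arm, seven-time-
point (12–192 h), seven-replicate bulk RNA-seq design analysed on a curated
map, with treatment effects planted at 120 h:

* **Map**: preferential-attachment background digraph (150 genes, mean
  out-degree 2, 30% inhibiting edges), four phenotype sinks each with an
  eight-gene directly-activating regulator module planted up or down
  (|log2FC| = 3), one all-activating planted 3-cycle whose members
  directly activate the target phenotype and carry the top fold changes
  (|log2FC| = 4), and ten random-signed decoy 3-cycles.
* **Counts**: negative-binomial with log-normal gene baselines
  (log-mean 5, log-sd 1), gene-wise log-normal dispersions around 0.05,
  log-normal library sizes (log-sd 0.2), and optional outlier samples
  distorted by a large factor on a random 30% of genes.
* **Markers**: 13 disjoint cell-type sets of 7 genes (91 markers); the
  first cell type carries a planted +1.5 log2FC shift.
* **DEG tables** can also be generated directly from the planted truth
  (null genes: FC ~ N(0, 0.25²), uniform p_adj; planted genes: target FC
  ± N(0, 0.3²), small p_adj), since the pipeline accepts DE results as
  input and benchmarks downstream of DE need not pay for count simulation.

Everything is deterministic given the config seed.  What passing recovery
tests shows: the pipeline's statistics point at planted signal of
realistic effect size under realistic count noise, and its exact contracts
(path sums, linearity, selection dominance) hold.  What it does not show:
performance on a real curated atlas (orders of magnitude larger and
denser, with correlated annotation), on correlated gene-gene expression
noise, or on DE engines with shrinkage — the generator plants independent
per-gene effects and an idealized null.

## Problem sizes and numerics

Benchmarks sweep 20 seeds with 200 permutations per test on the default
150-gene map — sizes chosen so the full suite and the acceptance script
each run in well under a minute while keeping binomial bands on the
recovery rates informative.  Degenerate cases are fixed by convention:
all-zero genes get log2FC 0 and p 1; identical-variance genes get p 1;
all-zero activity vectors normalize to 0; a single-motif population
normalizes to 0.5 on every feature.  Oracle comparisons (influence versus
exhaustive enumeration, perturbation versus influence columns) are exact
to 1e-12.

## Known limitations

* Influence depends on the attenuated-simple-path contract above; other
  propagation schemes (random walks, heat diffusion) would give different
  absolute scores, though `alpha` and `max_depth` allow rough
  approximation.  All downstream phenotype levels inherit this contract.
* Marker averaging is not deconvolution: bulk fold changes conflate cell
  abundance with per-cell expression, which the method mitigates only by
  the opposing-marker exclusion and by averaging uniquely expressed
  markers.
* Linear perturbation ignores saturation and feedback dynamics.
* The DE stand-in loses power relative to NB GLMs at low counts; use a
  dedicated DE engine for real data and import its table.
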