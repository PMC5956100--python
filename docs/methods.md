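# Methods

## Scope and model

`devcoexpr` reconstructs a developmental co-expression analysis as a
reusable, testable pipeline.  The input is a gene × sample matrix of raw
read counts and a mapping of samples to ordered developmental stages
(the default design has four stages with 6/7/9/6 biological replicates,
28 samples).  The pipeline stages and the statistical choices behind
them are described below, followed by the synthetic data model used to
benchmark every stage.

## Normalization and differential expression

Counts are normalized to `log2(CPM + pseudocount)` with pseudocount 1
(zeros map to 0; the transform is invariant to per-sample sequencing
depth).  Differential expression between each consecutive pair of
stages is a per-gene Welch two-sample t-test on the normalized values,
with Benjamini–Hochberg adjustment within each stage pair; the log2 fold
change is the difference of stage means.  A gene enters the DE list if,
for at least one consecutive pair, q ≤ 0.05 **and** |log2FC| ≥
log2(1.5).  The fold-change filter is two-sided: "fold change ≥ 1.5"
without a stated direction is read as magnitude.

This filter is a deliberately transparent stand-in for a count-model DE
fit (dispersion-shrunk negative-binomial Wald tests and median-of-ratio
size factors are out of scope): the downstream analysis depends on the
*filter semantics* (threshold, adjustment family, consecutive-pair
union), not on which well-calibrated test produced the p-values.  The
test suite verifies the stand-in's type-I control on null simulations
(called fraction within binomial error of 0.05 over 20 simulations) and
its power on planted log2FC = 2 blocks (sensitivity ≥ 0.9, observed
FDR ≤ 0.1).

"FDR adjusted" is implemented as Benjamini–Hochberg throughout (the
conventional default); the implementation wraps
`statsmodels.stats.multitest.multipletests` and is tested exactly
against a brute-force transcription of the step-up definition.

## Signed difference ratios

For each gene the per-sample log2-CPM values are centered by the gene's
mean over all samples and rescaled by the maximum absolute centered
value:

    c_gs  = x_gs − mean_s' x_gs'
    sdr_gs = c_gs / max_s' |c_gs'|      (0 for constant genes)

Every non-constant gene therefore attains |sdr| = 1 in at least one
sample and its centered values sum to zero.  The choice of the max
|centered| denominator (rather than, say, a standard deviation) is a
documented design decision: the stage-classification thresholds (0.4
level, 0.3 additive margin) presuppose a statistic bounded in [−1, 1] on
a common scale for every gene.

Stage profiles are the arithmetic means of SDR over each stage's
samples.

## Stage-specificity rules

With stage-mean SDR values `v_s`, a gene is called specific to

* a single stage `s` iff `v_s ≥ 0.4` and `v_s ≥ v_t + 0.3` for every
  other stage `t`;
* a consecutive pair `(s, s+1)` iff `v_s ≥ 0.3`, `v_{s+1} ≥ 0.3`, their
  mean is ≥ 0.4, and that mean is ≥ v_t + 0.3 for every other stage `t`.

All comparisons are inclusive ("at least").  The single-stage rule is
evaluated first, in stage order; only if no stage qualifies are the
consecutive pairs tried, in order, first match winning.  Because the
margin is strictly positive, at most one single stage can ever qualify
(asserted over random profiles in the tests).  Only consecutive pairs
are tested; non-adjacent pairs are never called.  The margin inequality
is evaluated in the form `v_s ≥ v_t + margin` (not `v_s − v_t ≥
margin`), and the test oracle transcribes the same form, since the two
differ for boundary values under IEEE arithmetic.

## Co-expression network

Pearson correlations are computed for every unordered pair of DE genes
over **all** samples (a single network for the whole time course, not
per-stage networks), on log2-CPM values.  Correlation on the log scale
rather than on SDR is a design decision: the SDR transform is per-gene
affine except for the shared rescaling, so PCC is essentially unchanged,
and log space is the natural working scale of the expression values.

Significance of r uses the exact t transform `t = r √((n−2)/(1−r²))`
with n−2 degrees of freedom, two-sided (|r| = 1 maps to p = 0), which
keeps extreme cutoffs such as 1e-16 meaningful in double precision
without resampling.  BH adjustment is pooled over all C(m, 2) tested
pairs at once; pairs involving a zero-variance gene are recorded as
undefined and excluded from testing.  Edges are pairs with q ≤ cutoff;
network nodes exist only via surviving edges, so isolated genes are not
counted as nodes.

### Scale-free threshold scan

The build cutoff is selected by scanning a grid of candidate cutoffs
(default 1e-2 … 1e-16 in decade steps of 100×).  For each cutoff the
degree distribution of the resulting network is fit by ordinary least
squares in log10–log10 space and scored by R²; the selected cutoff is
the most lenient one whose R² meets the requirement (default 0.88), with
a flagged fallback to the best-R² cutoff when none qualifies.

The fit pools degrees into logarithmic bins (3 bins per decade, count
density against geometric bin center) by default.  The alternative —
regressing log10 count on log10 k for every distinct degree — gives
every sparse tail degree a count of 1 (log-count 0) and lets a single
stray minimum-degree node dominate the regression; on 500-node
preferential-attachment graphs this occasionally halves the R² of a
genuinely heavy-tailed network.  The unbinned per-degree fit remains
available (`bins_per_decade=None`).  With the binned default,
preferential-attachment graphs (n = 500, 2 edges per arrival) score
R² ≈ 0.93–1.0 while degree-matched uniform-random graphs score ≈
0.1–0.4, so the criterion separates the two topologies cleanly.

## Markov clustering

MCL is implemented from scratch (dense NumPy): the column-stochastic
transition matrix of the network (unit edge weights, self-loop weight
1.0) is repeatedly **expanded** (matrix power, default 2), **inflated**
(elementwise power, default 2.0, then column renormalization) and
**pruned** (entries below 1e-5 zeroed, then renormalized) until the
largest entrywise change falls below 1e-8 or 100 iterations pass
(non-convergence is flagged, not fatal).  Clusters are read from the
attractors of the converged flow matrix: rows with positive diagonal
mass are attractors, attractors supporting one another merge into one
attractor system, and every node joins the system holding the largest
share of its column mass.  Masses are rounded to 9 decimals before the
argmax and ties break toward the smallest cluster id, making the
partition deterministic and robust to float noise; each gene receives
exactly one module.  Modules with at least nine nodes are retained
("more than eight"); the threshold is configurable.

The implementation is verified against an independently coded,
loop-based reference MCL (identical algorithm contract, no shared code)
on random graphs, and against planted-module recovery on synthetic data.

## Over-representation

Each retained module is tested against each gene set of a user-supplied
GMT collection by the upper-tail hypergeometric probability
P(X ≥ k overlap | universe N, set K, module n), with sets first
restricted to the universe and BH pooled across all module × set tests.
The universe defaults to the DE gene list — the pool the modules were
drawn from — and is configurable to all genes.  Only over-representation
is tested.  Reproducing any external annotation database's numerical
results is a non-goal; the collection is caller-supplied.

## Synthetic data model

Counts are drawn NB(μ_gs, α) with Var = μ + αμ², parameterized by a
log2-scale mean:

    log2 μ_gs = b_g + Δ_g·1[stage(s) ∈ affected]         (DE blocks)
              + w_m · f_m(s)                              (modules)
              + log2 L_s                                  (library size)

* baseline `b_g ~ N(7, 1.5²)` (log2 counts; ~128 expected reads);
* DE blocks shift a contiguous gene block by Δ (default 2 log2 units) in
  one stage or a run of consecutive stages; one single-stage block per
  stage (40 genes) and one block per consecutive pair (20 genes) in the
  default design, which double as ground-truth stage-specific genes;
* each module m has a latent factor `f_m(s) = a_m(stage(s)) + ε_s`,
  ε ~ N(0, 0.6²), one draw per sample shared by all member genes; the
  default design has three 30-gene modules with loading w = 1.8 and
  activity a = 2 in one stage each (E11, E13, E14);
* library sizes L_s are log-uniform within a 2-fold range;
* dispersion α defaults to 0.05 generically and 0.01 in the default
  study configuration; α = 0 degrades to Poisson.

Two constraints drove the default effect sizes, and both are worth
knowing about because they are real phenomena, not simulation artifacts.
First, module genes must not own a visible share of the library:
because CPM renormalizes by the per-sample total, a module whose
activity swings the totals by tens of percent depresses every other
gene's CPM in its active stage — compositional bias — planting false DE
calls and corrupting SDR profiles genome-wide.  The defaults keep the
modules' expected share of any library small (≈ 10–20%), below the
1.5-fold DE filter.  Second, for module edges to survive even the most
stringent scanned cutoff (q ≤ 1e-16 after BH over ~50,000 pairs at
n = 28 samples) within-module correlations must exceed ≈ 0.98, which
fixes the loading/jitter/dispersion combination.  With these defaults
the planted modules are recovered with adjusted Rand index 1.0 at both
the scanned and the most stringent cutoff across seeds, DE sensitivity
is ≥ 0.9 with observed FDR ≤ 0.1, and stage-call accuracy on planted
profiles is ≥ 0.95.

What the generator does **not** emulate: batch effects, GC/length
biases, dropout, isoform-level variation, overlapping modules, or
between-module correlation.  Passing recovery tests on this model shows
the pipeline's inference machinery is correct and calibrated under its
own assumptions; it does not certify performance on real data, where
dispersion is gene-dependent and modules overlap.

## Determinism, problem sizes and degenerate inputs

Every simulation derives from a single integer seed; identical
configurations give byte-identical outputs, and all writers sort rows
canonically (edges store the lexicographically smaller gene first).
Default benchmark sizes — 1,200 genes × 28 samples, ~300 DE genes,
~50,000 correlation pairs, networks of a few hundred nodes — keep a full
pipeline run in seconds on one core while leaving every statistical
property measurable; all sizes scale via configuration.

Degenerate inputs degrade gracefully rather than crash: an empty DE
list skips the network stages with a warning; an empty network reports
an undefined giant-component fraction; a cutoff scan where no cutoff
meets the R² requirement falls back, flagged, to the best-scoring
cutoff; constant genes get all-zero SDR and are excluded from
correlation testing; MCL hitting the iteration cap returns the current
partition with `converged=False`.

## Known limitations

* The Welch/log-CPM DE stand-in is less powerful than count-model tests
  at very low counts and does not shrink dispersions.
* The hard-threshold network discards edge-weight information below the
  cutoff; soft-threshold (weighted) networks are out of scope.
* MCL assigns each gene to exactly one module, which rarely reflects
  overlapping biological membership.
* The scale-free R² criterion is a goodness-of-linear-fit heuristic, not
  a likelihood-based test of power-law degree distributions; at very
  lenient cutoffs dense networks can still score a high R² and be
  selected.
* Enrichment p-values depend strongly on the chosen universe; the DE
  default is conservative for modules drawn from DE genes.
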