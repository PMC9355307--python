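# Methods

`circdosage` implements a circular-transcriptome analysis for sex-chromosome
aneuploidy cohorts (45,X Turner-type, 47,XXY Klinefelter-type, and 46,XX /
46,XY controls) together with a synthetic study generator that carries the
statistical structure the analysis assumes. This note describes the models,
the parameters that matter, the numerical choices, and what the synthetic
data do and do not establish about real data.

## Backsplice identity and coordinate conventions

A circRNA is identified by the genomic endpoints of its backsplice junction
(BSJ), keyed `chrom:start-end:strand`. Internally all coordinates are
0-based half-open; conversions happen only at I/O. The primary-caller table
dialect is 1-based inclusive (shifted on read), BED is native. Junctions
with `start >= end` in the caller's frame are rejected and counted, not
fatal. Strand is part of the key by default because callers disagree on
strand more than on coordinates; an unstranded-matching toggle collapses
`+/-/.`.

## Consensus quantification

The multi-caller consensus rule keeps a junction only if the count-bearing
primary caller reports it and at least `consensus_min_secondary` (default 1)
of the detection-only secondary callers confirm it. Matching is exact
coordinate equality by default (`coord_slack_bp = 0`); no tolerance is
applied because none is established for these callers. Filtering order is
consensus first, then circCPM on the consensus set, then the expression
filter.

circCPM divides a sample's backsplice counts by that sample's **total
backsplice reads** and multiplies by 1e6. The denominator is the sum of
reads, not the number of distinct circRNA species: counts-per-million
semantics require a read total. A species-count denominator is available
behind a flag for sensitivity analysis only. All-zero columns stay zero. The expression filter keeps junctions at
>= 25 circCPM in >= 7 samples, both comparisons inclusive.

The circular-to-linear ratio is CTL = 2c/(2c + l) with c backsplice reads
and l linear reads over the same junction; CTL is 0 exactly when c = 0
(including c = l = 0) and 1 exactly when c > 0 and l = 0.

## Annotation

Origin classification: a junction is *exonic* when both endpoints fall
at/within exons of overlapping host genes (boundary tolerance 0 bp by
default, configurable), *intronic* when inside a gene but not exonic,
*intergenic* otherwise. Junctions spanning two adjacent genes report both
hosts and count once per host in isoform tallies. Exon count is the number
of host exons (union over hosts, since the choice of transcript at
multi-transcript loci is ambiguous) fully inside the junction interval.

PAR membership uses the fixed intervals PAR1 = 10,001–2,781,479 and
PAR2 = 155,701,383–156,030,895 (1-based inclusive). Containment is
evaluated in that printed frame so the boundary numbers hold exactly, and
requires **both** endpoints inside the same interval. Catalogue matching is
exact on harmonized coordinates (the catalogue is assumed to be on the same
genome build; liftover is out of scope).

## Copy-number model and dosage expectations

Copy numbers per region class and karyotype:

| class          | copies      | 45,X | 46,XY | 46,XX | 47,XXY |
|----------------|-------------|------|-------|-------|--------|
| PAR1 / PAR2    | nX + nY     | 1    | 2     | 2     | 3      |
| chrX escape    | nX          | 1    | 1     | 2     | 2      |
| chrX inactive  | constant 2  | –    | –     | –     | –      |
| chrY           | nY          | 0    | 1     | 0     | 1      |

This is the classical 1:2:2:3 stoichiometry for PAR expression and yields
the theoretical contrast lines log2(3/2) = 0.585 (47,XXY vs 46,XY) and
log2(1/2) = −1 (45,X vs 46,XX). `expected_dosage_log2fc` is antisymmetric
under contrast reversal and errors when the control copy number is zero
(e.g. chrY in a female control).

The collective PAR shift is a two-sided one-sample t-test of the mean
log2FC over **all** PAR-assigned circRNAs with estimates, not only the
significant ones — sub-threshold features carry the collective signal. The
null mean is 0 (configurable `mu`); testing against the theoretical line
instead is a one-line change of `mu`. PAR2 circRNAs, which lack escape
annotation, are profiled separately and excluded from dosage expectations
by default. Zero-variance inputs are flagged degenerate rather than
returning a spurious p-value.

Attenuation is quantified by pairing each PAR circRNA's log2FC with its
host gene's log2FC and fitting a least-squares slope **through the origin**
(both axes are contrasts of the same groups, so a zero mRNA effect should
imply a zero circRNA effect); an ordinary intercept fit is available behind
a flag. Under the generator's model the slope estimates the attenuation
exponent alpha.

## Moderated differential expression

One internally implemented precision-weighted moderated linear model serves
both circRNAs and genes (the upstream tools it replaces — voom-style
weighting for circRNAs, a count GLM for genes — are not re-implemented
verbatim; the acceptance surface here is synthetic-data recovery, not
numerical identity with any specific package). The stage:

1. **Transform**: y = log2((count + 0.5) / (libsize + 1) × 1e6), libsize
   being the per-sample column sum of the input matrix (for circRNAs the
   circRNA-read total, consistent with circCPM).
2. **Design**: intercept, group indicator (case = 1), reference-coded batch
   indicators; aliased columns are dropped with a warning; each group needs
   >= 2 samples. Paired subjects can enter as fixed subject covariates when
   both groups share subjects (a random-effect correlation structure is out
   of scope).
3. **Weights**: per-feature OLS residual SD^(1/2) is regressed on mean
   log-CPM with lowess (span 0.5, configurable); each observation's SD is
   predicted at its fitted value; weight = predicted-sqrt-SD^(−4). Per-sample
   quality weights (inverse mean squared standardized residual, two
   moment-iteration passes, geometric mean 1) downweight heterogeneous
   libraries. SDs are floored at 1e-6 to guard degenerate input.
4. **Moderation**: per-feature weighted least squares; residual variances
   are shrunk by closed-form empirical Bayes — method of moments on
   log s² (the excess of its variance over trigamma(d/2) gives the prior
   df via an inverse-trigamma Newton solve), posterior
   s̃² = (d0·s0² + d·s²)/(d0 + d), moderated t with d0 + d df. With unit
   weights this reproduces limma's `eBayes` t-statistics to machine
   precision (verified against Rscript/limma in the test suite, which acts
   as the independent oracle, never as the implementation).

Benjamini–Hochberg adjustment is the step-up rule implemented directly and
cross-checked against statsmodels. Call rules: circRNAs need adjusted
p < 0.05 **and** |log2FC| > 1 (both strict); genes need adjusted p < 0.05.
The gene prefilter keeps genes with >= 20 counts in more than three
(i.e. >= 4) samples; "at least" thresholds are inclusive, "below/above/more
than" strict.

## ceRNA networks

The tripartite graph runs differentially expressed circRNAs (restricted to
those with known catalogue ids, since interaction databases are keyed on
them) → miRNAs with >= 2 AGO CLIP-seq supporting experiments → target mRNAs
restricted to DEGs of the contrast plus expressed PAR genes ("expressed"
operationalized as passing the gene prefilter, since no other definition is
available). miRNAs without a retained target, and endpoints left isolated,
are pruned.

The sign-consistency rule codifies sponge logic into a deterministic
filter: sponging derepresses targets, so a path is retained only when the
circRNA and mRNA directions agree; miRNA direction is unobserved (no
miRNA-seq) and plays no role. The rule is an interpretation of manually
curated networks and can be toggled off. Over-representation of gene sets
among network genes uses a one-sided hypergeometric test with BH
correction; the universe is the set of genes passing the prefilter in that
tissue (an expression-matched background). Exports are Cytoscape-ingestible
SIF, node/edge attribute TSVs and GraphML; the edge list round-trips.

## Synthetic study generator

The generator emulates the data structure the analysis consumes; it makes
no claim of biological fidelity beyond that structure.

* **Annotation**: one host gene per circRNA (region classes by the
  configured fractions, remainder autosomal) plus background autosomal
  genes. PAR genes are placed wholly inside the printed PAR intervals with
  compact gene geometry (3–8 exons of 100–400 bp, introns 200–1,000 bp) so
  PAR2's ~330 kb window cannot overflow silently (overflow raises).
* **Cohort**: one sample per subject × tissue with stable subject ids
  (enabling paired designs), batches round-robin over samples.
* **Counts**: negative binomial via gamma–Poisson with mean =
  baseline × tissue effect × batch effect × library factor × dosage
  multiplier, where the multiplier is (copies/reference)^alpha for circRNAs
  and copies/reference for mRNAs (`mrna_dosage_full`). `dispersion = 0`
  degenerates to Poisson. Defaults: 500 circRNAs, 10 subjects per
  karyotype group (the order of the study's muscle/fat group sizes), two
  batches, log-normal baselines around 60 reads (circ) / 400 (genes),
  dispersion 0.1, tissue effect SD 0.5, batch SD 0.1, alpha 0.5 (a middle
  value encoding the qualitative observation that mRNA dosage responses
  exceed circRNA responses), catalogue coverage 0.36, ~88% exonic.
  Tissue effects are free log-normal multipliers: no per-tissue circRNA
  abundance model is claimed.
* **Linear counts**: each circRNA gets a CTL target (10% exactly 1 — the
  all-or-nothing pattern — otherwise Beta(2,5) clipped to [0.02, 0.95],
  placing most mass below 0.5); the linear mean is l = 2c(1 − CTL)/CTL, so
  the target holds in expectation and CTL-1 features draw zero linear
  counts always.
* **Caller outputs**: the primary table reports every junction with nonzero
  reads, preserving counts exactly (per-sample sums are conserved).
  Secondary callers drop true detections at `fn_rate_per_caller` and inject
  novel junctions at `fp_rate_per_caller` (one Bernoulli trial per true
  junction); injected keys are disjoint from truth and recorded. Primary
  false positives are off by default — the consensus rule makes
  secondary-caller errors the interesting case.
* **Interactions**: sponge triplets are planted at the label level — the
  truth records direction tables (up/down) for the involved circRNAs and
  genes — because under the copy model all PAR features move the same way
  within one contrast, so sign-inconsistent decoys cannot arise from counts
  alone. Decoys are sign-inconsistent but otherwise pass every filter;
  low-evidence edges carry exactly one experiment; noise miRNAs target only
  background genes.
* **Determinism**: every stage draws from a substream spawned from the
  single seed (`SeedSequence(seed, spawn_key=(stage, ...))`); identical
  config + seed reproduces byte-identical written output.

### What the synthetic data do not show

Passing recovery tests demonstrates internal consistency — the analysis
recovers what the generator plants under its assumptions (independent NB
counts, log-linear effects, a single shared attenuation exponent, exact
caller coordinates). Real data add alignment artifacts, coordinate
disagreement between callers, correlated features, mosaicism and
cell-composition effects that are not modeled; conclusions about real
cohorts require real data.

## Numerical notes and known limitations

* **Compositional compression**: CPM-style normalization makes log2FCs
  relative to the per-sample total. When dosage-affected features are a
  large share of the library, their apparent effects compress toward zero
  (visible in both directions of the attenuation slope). At the study-like
  defaults (PAR ≈ 5–10% of features) the bias is below ~0.05 log2 units;
  validation scenarios keep PAR a minority share for this reason.
* Collective-shift calibration across features assumes roughly comparable
  per-feature variances; heavy variance heterogeneity makes the one-sample
  t conservative.
* The moderated model operates on log-CPM and does not implement count
  GLMs, fold-change shrinkage, surrogate-variable adjustment, or
  random-effect duplicate correlation.
* Validation problem sizes (e.g. 1,000 junctions × 20 samples for the
  consensus oracle; 1,000 features for DE calibration; 50 PAR pairs for
  attenuation recovery) are chosen so the full suite runs in seconds while
  keeping Monte-Carlo error well inside the asserted tolerances.
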