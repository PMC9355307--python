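# circdosage

Circular-RNA analysis for sex-chromosome aneuploidy cohorts: multi-caller
consensus quantification of backsplice junctions, circCPM normalization,
circular-to-linear ratios, pseudoautosomal-region (PAR) dosage analysis
against copy-number expectations, moderated differential expression, and
evidence-filtered circRNA–miRNA–mRNA (ceRNA) network construction — plus a
synthetic cohort generator with planted ground truth for validating every
stage.

**Who it is for.** Transcriptomics researchers comparing circRNA profiles
across karyotypes (45,X; 46,XX; 46,XY; 47,XXY) and tissues who have
per-sample circRNA caller outputs (one count-bearing primary table plus
detection-only secondary tables), linear junction counts, a gene count
matrix and sample metadata — and anyone who needs a ground-truthed sandbox
for methods work on circRNA dosage analysis.

## The core models

A circRNA is identified by its backsplice junction `chrom:start-end:strand`.
A junction is kept when the primary caller reports it and at least one
secondary caller confirms it; counts are normalized to circular counts per
million (circCPM = reads / per-sample backsplice-read total × 1e6) and
filtered at ≥ 25 circCPM in ≥ 7 samples. The circular-to-linear ratio is

    CTL = 2c / (2c + l)  ∈ [0, 1],

0 when no circular reads, 1 when circular-only.

PAR genes sit on both X and Y and escape X inactivation, so their copy
number is nX + nY — the 1:2:2:3 stoichiometry over 45,X : 46,XY : 46,XX :
47,XXY — giving theoretical contrast lines log2(3/2) = 0.585 (47,XXY vs
46,XY) and log2(1/2) = −1 (45,X vs 46,XX). Collective PAR shifts are tested
with a one-sample t on the mean log2FC of all PAR circRNAs; the circRNA
dosage response relative to mRNA is summarized by a through-origin slope of
circRNA on host-gene log2FCs (slope < 1 = attenuation).

Differential expression uses one precision-weighted moderated linear model
for both circRNAs and genes: log2-CPM transform, lowess mean–variance trend
weights with per-sample quality weights, weighted least squares with batch
covariates, and closed-form empirical-Bayes variance shrinkage giving a
moderated t (verified to reproduce limma's `eBayes` on unit weights).
CircRNAs are called at BH-adjusted p < 0.05 and |log2FC| > 1; genes at
adjusted p < 0.05.

ceRNA networks connect differentially expressed circRNAs (with known
catalogue ids) to miRNAs supported by ≥ 2 AGO CLIP-seq experiments and on
to target mRNAs restricted to DEGs and expressed PAR genes, with a
sign-consistency filter encoding sponge logic (an up circRNA derepresses,
hence explains, an up target). Over-representation uses a one-sided
hypergeometric test with BH correction. See `docs/methods.md` for the full
account.

## Worked example

`examples/04_par_dosage.py` simulates a 45,X vs 46,XX blood cohort (20
subjects per group, attenuation alpha = 0.5), runs DE for circRNAs and
genes and performs the dosage analysis:

```
$ python examples/04_par_dosage.py
theoretical PAR log2FC: 47,XXY vs 46,XY -> 0.585 | 45,X vs 46,XX -> -1.0

collective PAR1 circRNA shift: mean log2FC = -0.440 (n=48), t = -20.00, p = 1.26e-24 ***
the mean sits between 0 and the mRNA line (-1): the circRNA dosage response is attenuated

circ-vs-mRNA attenuation over 48 PAR pairs: slope = 0.50 (true alpha = 0.5), r = -0.15
```

The theoretical lines are the pure copy-ratio expectations; the collective
shift of −0.44 shows PAR circRNAs moving about half as far as their hosts
(the planted alpha = 0.5, recovered by the slope of 0.50); the one-sample
t-test rejects a zero collective shift. The other examples cover the
generator (`01`), consensus filtering and CTL ratios (`02`), moderated DE
(`03`) and ceRNA network recovery (`05`).

A full file-based pipeline is available as a thin CLI over the same
functions:

```bash
circdosage all --config config.yaml     # simulate -> consensus -> annotate
                                        # -> de -> dosage -> network -> report
```

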