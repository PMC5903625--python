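# mtxprof

**Taxon-stratified functional profiling of gut metatranscriptomes.**

`mtxprof` is a reusable, tested implementation of the analysis pipeline used
to study how dietary protein levels reshape the activity of the murine caecal
microbiota: from read alignments on assembled contigs, through per-ORF
aligned-nucleotide quantification and best-hit family annotation, to
KEGG-module enrichment between diet groups, short-chain fatty acid (SCFA)
statistics, family-stratified pathway attribution, hierarchical clustering and
redundancy analysis. A first-class synthetic study generator with planted,
recoverable ground truth makes every statistical step testable end to end.

It is aimed at microbiome researchers who have the standard upstream products
of a metatranscriptome experiment — assembled contigs, predicted ORFs,
protein-database hit tables, KO assignments, read alignments, sample metadata
— and want a transparent, scriptable route to the downstream statistics.

## The analysis in brief

- **Quantification.** The expression of ORF *o* in sample *s* is the total
  number of read nucleotides aligned within *o*'s interval (a read spanning
  two ORFs contributes its overlap to each; only aligned match/mismatch bases
  count). Normalized activity is
  *x(o,s) = counts(o,s) / Σₒ counts(o,s)*, so each sample's activities sum
  to 1.
- **Taxonomy and function.** Each ORF inherits the taxonomic family of its
  highest-bit-score protein hit (ties: lower e-value, then subject id); KO
  identifiers attach function. Category activity (peptidases, amino-acid
  metabolism, amino-acid transporters, SCFA-production pathways) is the summed
  activity of ORFs whose KO is in the category set, optionally stratified by
  family. The three SCFA pathway sets are the published enzyme sets — note
  K01895 belongs to both the acetate and propionate sets, and this overlap is
  preserved.
- **Differential modules.** Per KO, a two-sided Welch t-test compares
  normalized activity between normal-protein (NP) and high-protein (HP)
  samples. Significantly higher KOs of each direction are pooled, and each
  KEGG module *M* with *n* detected KOs, *k* of them significant, is scored by
  the hypergeometric tail *P[X ≥ k]* with *X* ~ Hypergeom(*N*, *S*, *n*) over
  the universe of *N* detected KOs containing *S* significant ones.
- **Univariate tests.** SCFA concentrations (μmol/g) are compared per acid by
  Welch t-tests within matching fat levels; category activities by the exact
  Wilcoxon rank-sum test.
- **Multivariate.** Samples are clustered by Ward's minimum-variance method on
  Pearson distances *d = 1 − r* of log10-transformed activity. Redundancy
  analysis (RDA) projects the feature-centered activity matrix onto diet
  indicators, mouse weight and SCFA concentrations; the constrained variance
  fraction is tested by Monte Carlo permutation of the explanatory rows, and
  features with ≥ 50 % of their variance on the first two canonical axes are
  flagged for display.

## Worked example

The bundled synthetic mode simulates a 4-diet × 4-replicate study
(NPLF/NPHF/HPLF/HPHF: normal/high protein × low/high fat) with known ground
truth: *Erysipelotrichaceae* rises and *Lachnospiraceae* falls under HP,
three sugar modules are 4-fold up under NP, three protein-metabolism modules
4-fold up under HP, and branched-chain acids are elevated under HP.

```yaml
# config.yaml
outdir: demo_out
mode: synthetic
seed: 7
depth: 100000
n_permutations: 999
```

```sh
mtxprof run-all -c config.yaml
```

`demo_out/diff/module_enrichment.tsv` then contains (p-values rounded):

```
enriched_in module_id  n_kos_in_module  n_kos_detected  n_kos_found  p_value
         NP    M00377               10              10           10 2.08e-06
         NP    M00422                5               5            5   0.0019
         NP    M00196                4               4            4  0.00692
         HP    M00018               10              10           10 0.000332
         HP    M00299                4               4            4   0.0457
         HP    M00236                3               3            3      0.1
         ...
```

All three planted NP (sugar) modules and two of three planted HP
(protein-metabolism) modules reach *p* < 0.05 in their own direction block;
M00236, with only 3 KOs, illustrates the granularity limit of a
hypergeometric tail on very small modules (its minimum attainable p here is
0.1). `ordinate/rda_report.json` reports a constrained variance fraction of
0.955 (89.3 % shown on the first two axes) with permutation *p* = 0.001, and
`diff/scfa_tests.tsv` flags valerate and iso-butyrate as significantly
elevated under high protein in both fat backgrounds — the planted
protein-fermentation signature.

Each stage can also be run individually (`mtxprof simulate | quantify |
annotate | diff | strata | ordinate`) against the plain-TSV checkpoints in
the output directory, and `files` mode accepts user-supplied GFF3 / SAM /
TSV inputs in place of the simulator.

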