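# Methods

This note documents the models, numerical conventions and design choices
behind `mtxprof`, and what the synthetic-data experiments do and do not
demonstrate about real data.

## Quantification model

Expression is measured in *aligned nucleotides*: the contribution of a read
to an ORF is the number of reference positions covered by match/mismatch
CIGAR operations that fall inside the ORF interval. Insertions, clips and
reference skips contribute nothing; a read overlapping two ORFs contributes
its overlap to each; multi-mapped records are counted wherever they are
reported (no fractional splitting — the simplest auditable rule). Strand is
ignored, consistent with an unstranded random-hexamer double-stranded cDNA
protocol. Coordinates are 0-based half-open internally; GFF3 I/O converts to
1-based inclusive.

Normalization divides each ORF's count by the sample's total ORF-mapped
nucleotides, giving per-sample compositional activities that sum to 1. There
is deliberately **no** gene-length normalization by default — the sample-total
rule means longer genes legitimately carry more weight; an optional
per-kilobase mode exists for users who want length-corrected activities.
A sample with zero ORF-mapped nucleotides is an error (it is unusable), not a
silent NaN column.

## Taxonomic and functional annotation

Family assignment is best-hit: descending bit score, then ascending e-value,
then lexicographic subject id — a total order, so assignment is invariant to
hit-table order. No similarity cutoff is applied by default; an e-value
ceiling is available. The 0.5 % plotting filter retains a family if its
*diet-group mean* activity exceeds the threshold in at least one of the four
diets (group means, not individual samples, define "conditions").

Function categories are editable KO sets. The three SCFA-production sets are
fixed to the published enzyme lists (acetate: K00925, K00625, K01895, K13788;
propionate: K01895, K01026; butyrate: K01034, K01035, K01896, K00929,
K00634). K01895 (acetyl-CoA synthase) genuinely appears in both the acetate
and propionate sets; category activities are computed independently per set,
so the shared KO is counted in both, as printed in the source material. A
flag (`merge_shared_kos_to_acetate`) reassigns shared KOs to acetate only for
users who prefer disjoint attribution. The bundled peptidase / amino-acid
metabolism / amino-acid transporter sets are synthetic defaults (the original
lists are not public); they are configuration data, not code, and should be
replaced by project-specific KEGG BRITE selections for real analyses.

## Differential statistics

- **Per-KO tests** are two-sided Welch (unequal-variance) t-tests between the
  protein-level groups. Welch is chosen as the safer default where the
  historical convention is unstated. A KO constant and equal in both groups
  gets t = 0, p = 1 and a degeneracy flag.
- **Module enrichment** formalizes "k of the module's n detected KOs are
  significant" as the one-sided hypergeometric tail over the universe of
  *detected* KOs (nonzero activity in ≥ 1 sample) — undetected KOs cannot be
  "found", so they are excluded from the universe; both the full module size
  and the detected count are reported. NP-enriched and HP-enriched analyses
  run separately on the corresponding significant sets. A binomial
  approximation is available. No multiple-testing correction is applied by
  default (raw p < 0.05 convention); Benjamini–Hochberg is available via a
  flag.
- **Calibration caveat.** The hypergeometric tail is a *discrete* conditional
  test. For realistic module sizes (3–10 KOs) its attainable p-values near
  0.05 are coarse, so its null rejection rate at α = 0.05 is conservative —
  about 0.01 in the package's null simulations rather than 0.05. This is a
  property of the test itself, not of the implementation (which matches
  exhaustive enumeration to 1e-12): users should read module p-values as
  valid but conservative.
- **SCFA tests** are Welch t-tests per acid between protein levels within
  matching fat backgrounds (NPLF vs HPLF, NPHF vs HPHF), flagged at α = 0.05.
- **Wilcoxon category tests** use the exact rank-sum null distribution when
  both groups have ≤ 8 samples and there are no ties, otherwise the
  asymptotic approximation; all-tied data give p = 1 by convention. At 4 vs 4
  the exact test's smallest two-sided p is 2/70 ≈ 0.029, so near-0.05
  calibration is only meaningful at the pooled NP-vs-HP size (8 vs 8), which
  is where the package's calibration experiment runs.

## Multivariate analysis

Clustering uses Pearson distance *d(i,j) = 1 − r(i,j)* between sample
columns of the log10-transformed activity matrix, with Ward's
minimum-variance update applied to the given dissimilarities (the
"ward.D2-style" convention — the standard Lance–Williams recurrence on
squared input distances). This is stated explicitly because "Ward" on
non-Euclidean distances is ambiguous across software; the choice here is
deterministic and is verified against a greedy objective-recomputation
oracle. The log10 pseudocount defaults to half the smallest nonzero entry —
scale-aware on fractional data, where a fixed +1 would crush all structure.

RDA centers the response per feature, projects onto the column space of the
encoded explanatory variables (nominal variables as one-hot indicators with
the first level dropped; continuous covariates standardized), and takes the
canonical axes from the SVD of the fitted values. The constrained fraction is
trace(fitted covariance)/trace(total covariance). Perfectly collinear
explanatory columns are dropped with a warning; with ≥ n−1 independent
columns the projection saturates at 1 (warned). The permutation test permutes
explanatory rows jointly and uses the add-one estimator
p = (1 + #{permuted ≥ observed}) / (1 + B), B = 999 by default, so p is never
zero; samples are put in a canonical sorted order before permuting, making
the Monte Carlo p exactly invariant to joint reordering of the inputs. The
species filter retains features whose centered profile has ≥ 50 % of its
squared norm in the span of the first two canonical sample axes. Biplot
scaling conventions of legacy ordination software are not reproduced; scores
are reported in the natural SVD scaling.

Pathway-map line widths are log10(1 + group-summed read count) per KO — the
+1 handles zero-adjacent counts while leaving decades intact — aggregated per
diet group by default, with zero-count KOs omitted from the selection file.

## Synthetic community model

The generator emulates the structure of a 4-diet caecal metatranscriptome
study with six bacterial families. Each ORF sits on its own contig (length a
multiple of 3, 300–3000 nt, with 60 nt flanks), carries exactly one family
and at most one KO; every module KO is carried by ORFs in at least two
families; the hit table's best hit carries the true family above
lower-scoring decoys. Background ORFs draw only non-module KOs, so module
expression is controlled exactly by the designated carriers.

Expected activity factorizes as family fraction × within-family length
share. Planted module effects multiply the expectation of carrier ORFs by the
fold in the favored protein-level group; ORFs of any planted module are
protected from renormalization and only the pure background rescales to
restore the unit column sum. Consequently the between-group expectation ratio
of a planted KO equals its fold *exactly* (when family fractions are flat),
which is what makes ±10 % fold-recovery a meaningful test rather than a
tolerance for model distortion.

Noise: per ORF and sample, a mean-one log-normal factor
exp(N(−σ²/2, σ²)) with σ = `dispersion` multiplies the expectation, then the
sample's depth is allocated by a single multinomial draw — one parameter
yields overdispersed compositional integer counts with a closed-form
expectation. Default study conditions: 4 replicates per diet (a 3-mouse NPLF
group is supported), depth 2×10⁵ nucleotides/sample, dispersion 0.2, fold 4
for planted modules, *Erysipelotrichaceae* 0.10→0.25 and *Lachnospiraceae*
0.40→0.25 from NP to HP. Effect sizes are synthetic conventions chosen for
desk-scale statistical power with directions taken from the motivating
findings; they are not measured biological values. SCFA panels are truncated
Gaussians (clipped at 0) around per-diet means in μmol/g, with branched
acids 2 orders of magnitude below acetate and elevated under HP.

Alignment simulation tiles each ORF's count with fixed-length reads fully
inside the ORF plus one remainder read, so re-counting reproduces the count
matrix exactly — the round-trip identity used in testing. An optional
boundary-read mode lets reads overhang ORF ends, in which case re-counts
equal the per-base overlap (verified against a brute-force oracle).

**What the synthetic data does not emulate:** sequencing errors and quality
structure, rRNA contamination, assembly artefacts, multi-ORF contigs with
shared reads, annotation errors (mislabeled families/KOs), phylogenetic
correlation between families, and compositional effects of unmapped reads.
Passing recovery tests therefore demonstrates the correctness and power of
the statistical machinery under the stated generative model, not robustness
to upstream annotation noise.

## Problem sizes in the bundled experiments

The calibration and recovery studies run on a 4-family × 120-ORF community
(≈100 detected KOs, six modules) at depth 10⁵, sizes chosen so the full
simulation battery (3000 null datasets, 200 recovery runs, 100 clustering
runs, 500 × 999 permutation draws) completes in a few minutes on one CPU
while keeping every per-test group at the study's replicate counts. The
pipeline's own synthetic default is larger (6 families × 80 ORFs).

## Known limitations

- The enrichment p-value's conservativeness at small module sizes (above).
- Family assignment below/above the family rank, KO prediction and read
  mapping are out of scope; the package consumes their outputs.
- `ExpressionMatrix` is dense; catalogs far beyond ~10⁶ ORFs would warrant a
  sparse backend.
- RDA assumes linear responses (no unimodal/CCA ordination).
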