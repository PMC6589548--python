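# Methods

## Scope and data model

The package re-implements a multi-omic A-to-I editome analysis at desk
scale. It consumes call-level evidence — per-site stranded pileups from
RNA alignments, and DNA variant calls from WGS and WGBS — rather than
reads; alignment and upstream variant calling are out of scope, as are GO
enrichment, secondary-structure folding, and web-database construction.
All in-memory coordinates are 1-based inclusive; BED is converted at the
I/O boundary.

## Site calling

A pileup record carries, per allele, a list of (base quality, offset from
read start, read length) observations. A candidate variant requires:

* raw depth ≥ `min_depth` (10);
* exactly one alternative allele *observed*, where "observed" means at
  least one read with base quality > 25 that survives the read-end
  exclusion (offset > 6 and distance to the 3′ end > 6);
* ≥ `min_alt_reads` (3) such high-quality, end-excluded alternative reads;
* site quality (mean quality of those reads, the proxy used when no
  upstream caller quality is available) strictly > 25.

Counting the allele census on end-excluded, high-quality observations is
deliberate: end-biased error reads otherwise convert a real editing site
into a "multi-allelic" rejection in ~16% of site-samples at the default
error rate, which would contradict the cascade's own purpose. The ≥ 3
supporting reads are counted after the read-end exclusion (the stricter
reading).

Candidates are pooled across samples (one row per position; if samples
disagree on the alternative allele the majority allele wins) and passed
through pure, order-independent predicates:

1. **DNA evidence** — removed if WGS or WGBS genotypes the same
   substitution het or hom-alt (a DNA-level substitution is germline, so
   hom-alt is treated like het); WGBS genotypes flagged unknown
   (bisulfite-blind C>T/G>A) are ignored; removed if the position is in
   the known-SNP catalog.
2. **Splice proximity** — intronic sites ≤ 4 bp from an exon boundary are
   removed (boundary inclusive); a site exonic in any overlapping
   transcript is exempt.
3. **Homopolymer** — removed if the reference base lies in a
   single-nucleotide run of length ≥ 5 (the run length is a package
   choice; common practice in editing detection).
4. **Mappability mask** (optional) — a BED of low-uniqueness regions
   stands in for an aligner-based paralog check; recorded in the filter
   trace as `paralog_mask`.

Strand is resolved from overlapping gene models. A>G on + and T>C on −
become A-to-I; C-to-U and G-to-A on the transcribed strand are purged
because bisulfite conversion makes the corresponding DNA genotypes
unobservable; the purge extends to unstranded C>T/G>A (the confound does
not depend on knowing the strand). Unstranded T>C (and A>G) calls are
retained as *putative* A-to-I under the antisense-transcription
assumption. Sites under genes on both strands resolve to the strand whose
type is A-to-I if exactly one qualifies, else they are dropped.

Clusters: a 100-bp window starting at p spans p..p+99, so "within a
100-bp window" is max − min ≤ 99; qualifying windows (≥ 3 sites) sharing
sites are merged. The implementation is checked against an O(n²)
enumeration of all windows. Hyper-edited genes have ≥ 5 assigned sites
and ≥ 1 cluster fully inside the gene span; the cluster is not restricted
to exons.

## Quantification

Level = G/(A+G) over end-excluded reads (the same evidence that made the
site callable); a cell is missing when A+G = 0 or raw depth < 10. The
overall rate pools reads (ΣG/Σ(A+G)) — read-weighted, not a mean of
levels; the two differ whenever coverage varies across sites. Sites
missing in more than ⌊n/3⌋ samples (27 of 81) are dropped. Missing cells
are imputed by the per-site mean (deterministic; a kNN-over-samples
option exists); a random-forest imputer was deliberately not reproduced —
mean imputation is documented, order-free, and only feeds MDS and network
construction, never the regression. Classical (Torgerson) MDS
double-centres −½D², eigendecomposes, and scales eigenvectors by √λ;
variance fractions are eigenvalues over the positive-eigenvalue sum. The
MDS default excludes intergenic sites (transcript-region analysis).

## Differential editing

Per site: OLS of level on [1, stage, sex], stage encoded as continuous
days post-conception (embryonic day d → d; postnatal day d → 114 + d,
the gestation length; a stage-index encoding is available). Missing cells
are dropped row-wise and imputed values are never used in the regression
(anti-conservative p-values otherwise). A single observed sex makes the
design rank-deficient: the sex coefficient is NA, stage is still fit.
Sites sharing the complete-case design are fit in one vectorised pass;
the per-site path is cross-checked against statsmodels OLS in the tests.
Multiplicity is controlled with Benjamini–Hochberg (NaN p-values excluded
from the test count), tested against a brute-force step-up oracle.

Enrichment of significant sites in a group: percent = 100·sig/total;
point enrichment = (sig_g/total_g)/(sig_all/total_all); 95% CI from the
Wald interval on the log risk ratio of group vs complement; p from the
two-sided Fisher exact test. No standard estimator (ratio-to-overall,
complement risk ratio, odds ratio) reproduces the published enrichment
column exactly from the published counts, so only the percent columns are
asserted; the estimator here is fixed and documented.

## Co-editing networks

Network sites: no missing values and level > 0 in more than 10 samples
(strict). Unsigned adjacency |cor|^β; the soft power is the lowest β whose
scale-free fit (signed R² of log p(k) vs log k over 10 equal-width degree
bins; positive-slope fits count negative) exceeds 0.9, falling back to the
argmax with a warning. TOM_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i,k_j) + 1 −
a_ij), diagonal 1, verified against a triple-loop oracle. Modules come
from average-linkage clustering of 1 − TOM with a *static* height cut; the
default cut is the midpoint of the largest jump in the sorted merge
heights, a deterministic calibration that recovers planted partitions
(a fixed low quantile of merge heights fragments planted blocks below the
minimum module size and was rejected). Clusters under 30 sites are
unassigned; modules whose eigengenes (first PC of the row-standardised
submatrix, sign fixed to positive mean member correlation) correlate
above 0.8 merge iteratively — the count strictly decreases, so merging
terminates. Dynamic tree cutting was not reproduced; module *counts* are
therefore not comparable to any particular published analysis and are not
asserted anywhere.

## miRNA rewiring

For each 3′-UTR site, ±50 nt genomic flanks on the sense strand (minus
genes reverse-complemented), reference and edited (A→G) versions.
Prediction is a canonical seed matcher: Watson–Crick complement of miRNA
positions 2–7 (6mer core), extended by an m8 match and/or an A opposite
position 1 to give 7mer-m8 / 7mer-A1 / 8mer; score = class weight
(4/3/2/1) + A/U fraction of the 10-nt context. A thermodynamics engine is
intentionally not wrapped: the predictor is deterministic and exhaustively
testable, and a hook accepts an external per-pair energy table. Rewiring
compares the two prediction sets per miRNA with span-overlap matching:
identical (class, span) → unchanged — the AU-context bonus is a ranking
tie-break, not a rewiring signal, which preserves the invariant that only
pairs whose span covers the edited base can change — otherwise
score_changed; unmatched pairs are gained/lost.

## Synthetic data generator

The generator emulates the study design: 27 stages (E33–E105, D0–D180; 15
prenatal + 12 postnatal) × 3 replicates; sex alternates by stage (the real
per-animal sexes are not public) and is configurable. Defaults: 2
chromosomes × 500 kb, 40 multi-exon genes (CDS patched to translate
cleanly), 260 SINE-like repeats placed outside CDS with genic hosts
up-weighted so the editome is predominantly intronic, ≥ 1 homopolymer
tract per chromosome, 2,000 editing sites (95% inside repeats, 70%
allocated to ≥3-site/≤100-bp clusters, a small CDS quota for consequence
annotation), 150 het + 100 hom SNPs (70% in the catalog), 1,000
reference-only background positions, read length 150, mean depth 50
(negative-binomial, dispersion 10 — depth < 10 creates realistic
missingness), error rate 0.002 with a 10× multiplier within 6 bp of read
ends, genuine base qualities ~N(37, 3) and error qualities ~N(28, 6).

Editing levels: baseline Beta with mean 0.046 — the average editing rate
reported for skeletal muscle — and concentration 4. The concentration is
set by the binomial noise bound: for the estimated level at depth ~50–60
to correlate ≥ 0.95 with truth, the between-site level SD must exceed
≈ 0.09, which fixes the concentration once the mean is given. Ten percent
of sites are developmental: their midpoint levels draw from Beta(mean
0.25, conc 8) ("strong" trends), the trend is logistic in days
post-conception with logit amplitude ±1.5, and 70% decrease (editing
declines with development). Sequence context is planted: 50% G one base
downstream, 4.4% G one base upstream, matching the deaminase substrate
preference.

Emission is exactly attributable: every alternative read in an RNA pileup
is an editing read (Binomial(depth, level)), a SNP read (0.5 het / 1.0
hom), or an error read, and the truth tables record every planted
feature. WGBS genotypes for C>T and G>A SNPs are written unknown
(bisulfite-blind); WGS sees everything. Determinism is by spawned
per-component integer RNG streams from one seed; identical configurations
produce byte-identical outputs.

What the generator does **not** emulate: alignment artefacts and mapping
ambiguity (the mappability mask is exercised only structurally), PCR
duplicates, strand-specific library noise, overdispersed (non-binomial)
allele sampling, hyper-editing read rescue, and real repeat sequence
content. Passing tests therefore certify the arithmetic and the filter
logic under the stated noise model, not performance on real alignments.

## Problem sizes and numerical choices

The default synthetic study (2 × 500 kb, 2,000 sites, 81 samples, depth
50) is the package's chosen desk-scale condition: large enough for stable
recovery statistics, small enough that the full pipeline runs in tens of
seconds. Null calibration uses 20 replicates of 2,000 sites × 81 samples.
Oracle tests run at n ≤ 200 (clusters), 6 × 6 (TOM), 10 × 20 (MDS, 1e-8
distance tolerance), 50-bp chains (exhaustive per-base liftover), and
50 sites × 20 miRNAs (rewiring set algebra). Ties and degenerate inputs:
zero-variance correlation returns NaN and is flagged; repeat overlap
breaks ties by longest overlap then leftmost; MDS pads degenerate
dimensions with zeros; the soft-power search warns and returns the best
fit when nothing reaches the threshold.

## Known limitations

* Candidate pooling keeps one alternative allele per position across
  samples; a genuine multi-allelic RNA position would be collapsed.
* The per-site mean imputer ignores sample-sample structure; kNN is the
  richer option but still no substitute for model-based imputation.
* The static tree cut trades the adaptive module boundaries of dynamic
  cutting for determinism; real data with nested module structure will
  under-split.
* The seed matcher scores no pairing thermodynamics; "score_changed" is a
  class change, not an energy difference.
* Liftover handles point positions only (sufficient for editing sites).
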