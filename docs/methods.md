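# Methods

## Scope and model

`mirreg` analyses the three-layer readout of a transcription-factor (TF)
knockdown in one or more cell lines: differential miRNA expression,
differential gene expression, and TF ChIP binding near miRNA promoters. Its
central inference is the *master-regulator* call: a deregulated miRNA whose
predicted targets are over-represented among the genes deregulated in the
opposite direction, relative to a resampling null. The underlying assumption
is that miRNA activity is visible at the transcript level — most
miRNA-mediated repression acts through mRNA degradation — so a miRNA that
rose after knockdown should depress its targets and vice versa. The
pipeline asserts nothing about translational repression, which is invisible
to it.

## Differential-expression filtering

DE tables are consumed as computed upstream (array or RNA-seq modelling is
out of scope). Inclusion thresholds are inclusive exactly as conventionally
printed: miRNAs at raw p ≤ 0.05 (`mirna_p_max`); genes at |fold| ≥ 2
(`gene_min_fold`, linear), p ≤ 0.01 and FDR ≤ 0.05. The miRNA rule is
applied to raw per-test p-values — array batch software typically reports
these unadjusted — and the threshold is configurable if a corrected column
is supplied instead. Where an FDR column is required but absent the filter
fails loudly rather than guessing.

Fold changes are internally log2. External tables may use the signed-linear
dialect (−3.63 means 3.63-fold down); values in (−1, 1) are illegal there
and rejected with the offending row. Both +1 and −1 denote "unchanged" and
map to log2fc 0; the inverse conversion returns +1.

miRNA identifiers are harmonised case-insensitively with the species
prefix stripped; star strands and arm suffixes are preserved verbatim and
never fuzzily merged, because miR-X and miR-X* are distinct molecules with
potentially opposite regulation. Cross-cell-line concordance uses the sign
of log2fc only: magnitudes from different platforms/batches are not
comparable, directions are.

FDR control is Benjamini–Hochberg step-up (via statsmodels), chosen as the
standard procedure when only an "FDR ≤ x" criterion is stated.

## Target catalog and consensus filter

The catalog is file-based (no live database queries) and versionless: site
tables exported from TargetScan-class tools are converted to one row per
predicted 3′UTR site with 0-based offsets, a seed-match type (8mer,
7mer-m8, 7mer-A1, 6mer), a site-conservation flag and optional co-predictor
scores.

*Conservation matching*: broadly conserved miRNAs keep only conserved
sites; mammal-conserved and primate-specific miRNAs (e.g. the C19MC
cluster) keep all sites. This is the permissive reading of "sites of equal
conservation" — a strict mode restricting specific miRNAs to nonconserved
sites only is available (`restrict_specific_to_nonconserved`) but off by
default, since a primate-specific miRNA binding a deeply conserved site is
biologically unremarkable.

*Consensus*: a miRNA–gene pair survives iff it has a TargetScan site and at
least one co-predictor agrees on some site — microT-CDS ≥ 0.4 ("medium-
good") or mirSVR magnitude ≥ 0.1 ("good"). Published mirSVR scores are
negative for effective sites while thresholds are quoted as positive
numbers, so the default criterion is |score| ≥ 0.1 (`mirsvr_sign =
"magnitude"`); `le_negative` / `ge_positive` enforce one sign convention.
Pairs passing both co-predictors are the high-confidence tier. Absent
scores never predict. Matching operates at site level before pair collapse:
a pair survives if any of its sites survives.

## Monte Carlo master-regulator test

For each significant miRNA, the inverse gene group is chosen by sign
(down-miRNA vs up-genes; up-miRNA vs down-genes). The background universe
is every catalog gene carrying ≥ 1 TargetScan site. B gene sets of the
group's size are sampled uniformly without replacement (implemented by
row-wise `argpartition` of uniform variates, chunked to bound memory at
roughly 32 MB); the statistic per draw is either the number of sampled
genes in the miRNA's consensus target set (`target_count`, default) or the
summed weighted UTR score over sampled targets (`weighted_score`).

Because site counts scale with 3′UTR length, the observed statistic is
corrected multiplicatively: T\* = T · L̄_bg / L̄_group, where L̄_bg is the
mean UTR length pooled over all sampled genes and L̄_group the group mean.
Only the observed side is corrected; the null values stay raw
(`normalise="none"` disables the correction). The empirical p-value uses
the add-one pseudo-count, p = (1 + #{T_b ≥ T\*}) / (B + 1), so it is never
0 and floors at 1/(B+1); ties count as exceedances (conservative).
Benjamini–Hochberg adjustment is applied within each (cell line, direction)
block and `is_master` marks adjusted p ≤ 0.05 (`mr_alpha`).

The weighted score's coefficients — 1.0 / 0.75 / 0.5 / 0.25 over
8mer / 7mer-m8 / 7mer-A1 / 6mer, +0.2 per consecutive site pair with a
13–46 nt start-offset gap — follow the canonical ordering of seed-match
efficacy and the classical cooperativity window; only the ingredients, not
the coefficients, are externally fixed, so they live in one constant table.

*Reproducibility*: one master seed per run; each (cell line, miRNA) gets a
child stream derived by SHA-256 hashing of its identifiers into a
`SeedSequence` spawn key, so results are bit-identical across runs and
invariant to iteration order. `mc_iterations` defaults to 10,000.

*Degenerate inputs*: an empty inverse gene group is skipped with a warning
(no result row); a miRNA without consensus targets yields p = 1; a group
larger than the universe is an error; genes absent from the catalog gene
table are dropped from the group with a warning (their UTR length is
unknown).

## Promoter proximity

miRNA-TSS and host-gene-TSS sources are unioned and deduplicated on
(precursor, chrom, position, strand), keeping distinct TSSs of one
precursor. Peaks are intersected with ±`proximity_window_nt` (default
5,000 nt, boundary inclusive) windows via an interval tree per chromosome.
The peak anchor is its midpoint, floor((start+end)/2) — ChIP peak lists
rarely ship summits, and a single scalar distance per peak is wanted; a
nearest-edge anchor (0 inside the peak) is available. Distances are signed
along the direction of transcription (negative = upstream) and mirrored on
the minus strand. A precursor reachable via several of its TSSs is reported
once per distinct peak with the smallest-|distance| TSS (ties broken
deterministically: miRNA TSS before host TSS, then position). Multiple ChIP
datasets are unioned without peak merging; the dataset tag is carried
through. The DE join reports one row per (cell line, significant mature
miRNA) whose precursor has ≥ 1 hit, with the smallest-|distance| peak,
sorted by cell line then fold change descending.

## Network assembly and counting

TF→miRNA edges are created for significant miRNAs with a proximal peak;
the sign is inferred from the knockdown response only (down after TF
knockdown ⇒ the TF was activating), with `unknown` when cell lines
disagree. miRNA→gene edges require a flagged master regulator, a consensus
target pair and inverse deregulation in the same cell line; they always
repress. Self-edges and duplicates are impossible by construction.

Interaction summaries count distinct (miRNA-group, gene) pairs, where an
explicit grouping map may merge miRNAs published with one shared target
list (the four C19MC miR-518 members in the curated example); group-level
counting is what reproduces published totals. High-confidence counts
restrict to the high tier. Validation flags come from a strong-evidence
subset of a validated-interaction table (reporter assay, Western blot,
qPCR; case-insensitive). Feedback loops classify miRNAs validated to
repress the TF itself: down after knockdown ⇒ negative loop, up ⇒ positive.

## Synthetic data generator

The generator emulates exactly the statistical structure the analysis
assumes: log-normal 3′UTR lengths (`utr_log_mean` 7.0, `utr_log_sd` 0.6 on
the natural-log nt scale — median ≈ 1.1 kb, matching genome-wide UTR-length
summaries; floor 50 nt); per-(miRNA, gene) site counts Poisson with rate
`site_rate_per_kb` × UTR-kb (default 0.05, i.e. each miRNA hits ≈ 6% of
genes — a deliberately dense desk-scale regime); canonical site-type
frequencies 0.15/0.35/0.35/0.15; and two-component (true-site vs decoy)
Gaussian score models for microT and mirSVR whose defaults let most true
sites pass the consensus thresholds. Deregulated fractions default to 10%
up and 10% down with |log2fc| ~ |N(1.5, 0.5)| and p ~ U(0, 0.005) (null
genes: log2fc ~ N(0, 0.2), p ~ U(0, 1); FDR by BH over the full p-vector).
Planted masters are significantly down-regulated and have their consensus
targets' membership in the up-group resampled to `enrichment_factor` × the
base rate, holding the group size fixed; infeasible plantings (required
count exceeding the group) are errors, not silent truncation. Genomic
features place one TSS per precursor on a synthetic chromosome with
alternating strands; planted-proximal precursors get one 200 nt peak whose
midpoint sits at a uniform signed in-window offset, all others a peak at
2.5× the window.

What passing tests show: the statistics, filters and seeded machinery are
correct on data with known truth. What they do not show: performance on
real catalogs, where target predictions are noisy and correlated across
miRNA families, UTR annotations disagree between databases, expression
changes are compositional, and ChIP peaks cluster in CpG-dense promoters.
The generator draws sites independently across miRNAs and genes given UTR
length, which understates the between-miRNA correlation of real predictions.

## Benchmarks and problem sizes

The shipped checks run at desk scale, chosen to finish in about a minute on
one CPU while keeping each estimate's Monte Carlo error well below its
acceptance margin: exact-enumeration agreement on 6-gene universes at
B = 50,000 (10 random catalogs); null calibration over 200 miRNAs × 20
seeds at B = 1,000 with a 600-gene universe and 100-gene groups (the
99% binomial band around 0.05 at n = 4,000 is ±0.0089); planted recovery at
2,000 genes, 30 miRNAs (3 planted), enrichment 5, B = 2,000, 20 seeds. The
published genome-scale master-regulator and binding-site lists depend on
the full TargetScan 6.0 and ChIP datasets and are deliberately not
reproduced; the curated example tables cover the published summary counts
instead.

## Known limitations

* The enrichment test treats target predictions as fixed truth; prediction
  error propagates directly into the statistic.
* The UTR-length correction is a first-order ratio adjustment applied to
  the observed statistic only; it does not reweight the null draws.
* Concordance classification is sign-based and ignores magnitude and
  platform batch effects.
* Promoter assignment is distance-based; enhancer-mediated or long-range
  regulation is out of scope, as are peak calling and TSS prediction.
* With 0 < |log2fc| thresholds applied per cell line, a gene just under
  2-fold in one line and just over in the other will appear discordant in
  network assembly even if its response is biologically identical.
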