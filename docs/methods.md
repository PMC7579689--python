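# Methods

## The analysis

The pipeline asks whether somatic mutations are distributed non-uniformly
with respect to genomic elements and epigenomic marks, using three
complementary views.

**Composite profiles.** For a feature set (gene bodies, miRNAs, or peaks),
each feature contributes a window of upstream flank, body and downstream
flank. Flanks are cut into fixed bins (default 50 bp over ±5 kb); the body —
whose length varies — is cut into a fixed number of equal fractions (default
40 bins, standing in for the usual normalise-to-2-kb display), so features of
different lengths are averaged on a common TSS→TES (or PSS→PES) axis.
Minus-strand features are mirrored so bin 0 is always biologically upstream.
A mutation contributes one count per feature window containing it; features
may overlap, and the composite is explicitly a per-feature average, so this
multiple counting is intended and is what the count-conservation tests check.
Frequency is count / (aggregate bin bp × n_samples) × 10⁶, i.e. mutations
per megabase per sample. The axis unit is a package decision — composite
plots in the literature rarely state theirs — and the cohort object carries
a full sample roster so mutation-free samples still enter the denominator.
Counts are stratified by substitution class: `ref_CT` (reference pyrimidine),
`ref_GA` (reference purine), `indel`, with "all" their union; the three
classes partition any cohort. An alternative "literal" classification
(requiring the alternate allele to cross the pyrimidine/purine divide) is
available behind a switch but does not partition SNVs and is not used by
default.

**Enrichment tests.** Per-region mutation rate is pooled events / region
length. Three nulls are provided: each region's own flanks (unpaired),
chromosome- and length-matched random regions (the default; matching is by
chromosome and length only, not GC — a known limitation), and a paired
flank comparison via the Wilcoxon signed-rank test. The rank test is the
Mann-Whitney U with average ranks; for samples of at most 8 observations
each the p-value is the exact permutation tail of U over all C(m+n, m)
assignments (ties handled by midranks), otherwise the tie-corrected normal
approximation with continuity correction (scipy). Fold change is the ratio
of pooled rates, deliberately decoupled from the rank statistic (no
pseudocounts; NA on a zero-rate null). All region sets tested in one report
share a single Benjamini-Hochberg family; raw p-values are always printed
alongside q-values.

**Sequence and methylation covariates.** The CpG observed/expected ratio of
a window is OE = (n_CpG / (n_C·n_G)) · N²/(N−1) with N the window size
(default 400, stepped 1 bp). The default "inflated" convention uses the
N²/(N−1) factor; the textbook convention (·N) is a switch
(`oe_convention="classic"`), and the two differ by a factor
N/(N−1) ≈ 1.0025 at N=400. Sliding tracks are computed from exact integer
cumulative counts, so the incremental track equals a per-window recount
identically. "Mutation occurrence" is defined operationally as the number of
mutation events (pooled over samples) within ±window/2 of a mutated site,
inclusive of itself. The occurrence-vs-metric correlation (Spearman) is
computed over one representative per recurrence cluster (sites linked when
closer than the window width; the representative is the highest-occurrence,
leftmost site): sites within one cluster share their occurrence and almost
their entire metric window, and using all of them pseudo-replicates
observations — measured on null data, per-site rho had standard deviation
0.071 against 0.050 expected under independence, and the p-values were
grossly non-uniform. With cluster representatives the null p-values are
uniform (KS p ≈ 0.4 over 200 replicates), which is the property the
calibration test enforces. The per-occurrence bin table still summarises
all sites. The C→T rate ratio compares C→T events per CpG cytosine between
methylation strata split at level 0.5; CpG context is taken from the
reference genome (not the methylation file), and a G→A event at the G of a
CpG counts as the minus-strand C→T.

## Annotation conventions

Ten mutually exclusive categories, resolved by priority (default: miRNA >
exonic > 5'UTR > 3'UTR > promoter > TTS > ncRNA > pseudogene > intronic >
intergenic — most specific element first, mirroring common peak-annotation
tools). "Exonic" means coding exon (CDS), since the UTRs are separate
categories; introns are each gene's span minus all exonic sub-elements.
Promoter windows default to TSS−1000..TSS+100 and TTS windows to
TES−100..TES+1000, computed on the feature strand (strandless features are
treated as '+'); both windows and the priority order are configurable and
are declared conventions, not inferences. miRNA host context uses any-bp
overlap with CDS taking precedence over intron, so the three classes
(intron/CDS/intergenic miRNA) partition any miRNA set.

Internally all coordinates are 0-based half-open; 1-based MAF/VCF input is
converted at the parsing boundary only. Multi-allelic VCF rows are split per
alternate allele; padded indels are normalised to a `-` allele at the first
changed base; equal-length multi-nucleotide substitutions are classified by
their first reference base.

## Hypermutator exclusion and sub-sampling

Per-sample burden outliers are removed by a Tukey fence, count > Q3 + k·IQR
with k = 3 (an "absolute" threshold mode exists); the cutoff and removed
samples are logged and echoed in the report header. The down-sampling
analysis used with large cohorts is exposed as `subsample_stability`:
repeated seeded draws of n samples (default 10), re-running the enrichment
test per draw and summarising the fold distribution and the fraction of
significant draws.

## The synthetic-data generator

The generator states a desk-scale world whose structure matches the
analysis assumptions; its defaults are the conditions the validation suite
runs under.

- **Genome**: 2 chromosomes × 1 Mb of i.i.d. sequence at GC 0.41, then CpG
  erosion — the C of 80% of non-island CpGs is deaminated to T — so the
  background O/E lands near 0.2 while 30 planted 600 bp CpG islands
  (CpG-rich construction) stay near 1. Erosion is compensated in the initial
  draw so realized GC still matches the configured value. Without erosion an
  i.i.d. genome has O/E ≈ 1 and the island-vs-background contrast the
  analysis relies on would be vacuous.
- **Annotation**: 120 genes (UTRs, 3 coding exons, 2 introns, random
  strand), 300 miRNAs of 80–150 bp placed into intronic/CDS/intergenic host
  contexts at 55%/6.6%/38.4% (the proportions reported for annotated human
  miRNAs), ncRNAs and pseudogenes in intergenic space, and per-class peak
  sets (CTCF 400 × 150–400 bp; H3K27me3/H3K4me3/H3K27ac 300 × 0.5–2 kb;
  DNase 400 × 150–600 bp), non-overlapping within each class.
- **Methylation**: one record per CpG cytosine (both strands share the CpG's
  level). Island CpGs are hypomethylated (Beta(1.5, 10)); background CpGs
  are bimodal — 88% Beta(10, 2), 12% drawn from the hypomethylated
  component — giving the ≈80/20 methylated/unmethylated split seen in
  mammalian tissue. A "tumour" condition multiplies levels by 0.7 (global
  hypomethylation).
- **Mutations**: per sample and base, SNV probability mu0 (5×10⁻⁵) times
  the product of the fold enrichments of all covering feature classes
  (miRNA 3.0, CTCF 2.0, H3K27me3 1.5, promoter 0.5; others 1.0) —
  multiplicative composition is the simplest identifiable model for
  recovery tests — times a C→T channel boost at methylated CpGs (level ≥
  0.5): the C→T channel rate is multiplied by 10, i.e. total rate ×(2+10)/3
  with the transition drawn with probability 10/12. The boost applies on
  either strand (minus-strand events are emitted as G→A at the CpG's G).
  Alternate alleles are otherwise uniform over the three non-reference
  bases. Indels are added at 8% of the SNV count (the proportion reported
  for somatic indels relative to SNVs), split evenly between 1 bp deletions
  and insertions. Two hypermutator samples mutate at 20× mu0. Events are
  independent across samples and positions; recurrent-site structure arises
  only from rate heterogeneity. An optional `oe_coupling_beta` multiplies
  the rate by exp(−beta·(OE−mean OE)) of the local 400 bp window, planting
  the occurrence/O/E anti-correlation; it is off by default.

Every artifact is a pure function of (config, seed); regenerating with the
same seed is byte-identical, which the determinism tests assert end to end
through the report TSVs.

### What a green validation does and does not establish

The generator emulates rate heterogeneity, strand handling, methylation
bimodality and burden outliers. It does not emulate trinucleotide mutational
signatures, replication timing, GC- or mappability-dependent calling bias,
clustered mutational processes (kataegis), or correlated placement of peaks
with genes beyond uniform placement. Recovery of a planted fold therefore
establishes correctness of the measurement machinery, not robustness to the
confounders of real tumour data; in particular the random-region null is
matched by chromosome and length only.

### Depth choices in the validation suite

Two checks use dedicated configurations rather than the 2 Mb/40-sample
default, because their estimators are not identifiable at default depth:

- the C→T multiplier recovery runs at mu0 = 10⁻³ so the unmethylated
  stratum (a minority of CpGs, as in real tissue) collects ~10² events and
  the ratio's CV drops to ~8%;
- the planted occurrence/O/E coupling runs on a 600 kb chromosome at
  moderate density (mu0 = 1.5×10⁻⁴, 15 samples): at high density recurrence
  clusters chain together and the number of independent cluster
  representatives — the correlation's effective sample size — collapses.

In both cases the planted parameter and the pass bands are those of the
stated world; only the observation depth is designed for power.

## Numerical and degenerate-input choices

- Body bins use exact integer arithmetic (floor((pos−start)·bins/len)), so
  oracle comparisons are exact; features shorter than the bin count occupy a
  subset of body bins and are noted in the log.
- Metric windows truncated by a chromosome end are dropped, not padded;
  random-region sampling rejects candidates containing an N-run of at least
  half the region length and can optionally exclude overlap with the source
  set (error after 1000 retries).
- Complete ties in a rank test return p = 1; a zero/zero fold is NA.
- Spearman correlations with fewer than 3 distinct occurrence values or a
  constant metric are reported NA with a log note.
- bedGraph methylation values must lie in [0,1]; files on a 0–100 scale are
  accepted only behind an explicit percent flag. BED intervals with
  start ≥ end and FASTA records with characters outside {A,C,G,T,N} are
  format errors naming the line or record.
- Report outputs are written atomically (temp file + rename); reads are
  order-stable and sub-sampling is a pure function of (cohort, n, seed).

## Known limitations

GC-matched null sampling, covariate-adjusted enrichment models, GTF/GFF
gene-model parsing, bigWig/heatmap output and real-data-scale performance
tuning (the interval machinery targets ≤10⁵ features × ≤10⁶ events) are out
of scope. The paired/unpaired choice between the two provided rank tests is
the analyst's; reports name which null and which test produced each row.
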