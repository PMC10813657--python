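# Methods

## Scope and data model

The package consumes the output side of a split-read eccDNA caller: one
table per sample of circle intervals (`chrom, start, end`) with split-read
support. It does not map reads or call circles from FASTQ/BAM; library
chemistry (tagmentation vs rolling-circle amplification) is carried only as
a sample label in the cohort manifest. All intervals are held 0-based
half-open (BED convention); GTF gene input is converted on read by a single
start-decrement and never shifted again. Strand is read but ignored by all
overlap logic. Duplicate rows in an input circle table are kept — they are
legitimate pre-merge records.

## Circle preprocessing

**Coalescing.** Callers report the same circle with small breakpoint
jitter. Two records of one sample are treated as the same molecule when
both |Δstart| < D_min and |Δend| < D_min (default D_min = 10 bp, strict
inequality); clusters are the transitive closure of this relation
(single linkage). Requiring proximity of *both* breakpoints, rather than
any single distance, matches how split-read jitter arises: both junction
sides wobble independently by a few bases. Each cluster collapses onto the
coordinates of its best-supported member (ties: smallest start, then
smallest end) and sums the members' split reads, so total split-read
support is conserved exactly. Merging is per sample; merging across
samples would conflate biological replicates. The operation is idempotent
and invariant to input order (ties are broken deterministically).

**Filtering**, applied after merging in this order: drop records with
fewer than 2 split reads (the support filter therefore applies to
post-merge sums), drop excluded chromosomes (chrM by default), drop
records longer than 10 kb. The 10 kb boundary itself is kept. The length
cutoff is applied globally — quantification and length statistics see the
same record set — because a single small-circle regime keeps every
downstream count comparable.

## Count and length statistics

Per-sample "unique eccDNAs" are the post-merge, post-filter record counts;
groups are summarized as mean ± sem (sd/√n with the n−1 sd). Group
differences in counts use the two-sided Wilcoxon rank-sum test: exact by
full enumeration of rank assignments when n_x + n_y ≤ 16 and the pooled
data are tie-free, otherwise a normal approximation with tie correction
and a 0.5 continuity correction. The exactness threshold and the
continuity correction are implementation choices; the exact branch is an
in-package subset-sum recursion checked in the tests against brute-force
enumeration and against an independent library implementation on the
asymptotic branch. Length distributions are reported as per-sample
cumulative-percentage curves over user bins with a group mean and
across-sample sd band.

## PpGC quantification

A circle contributes its full split-read count to every gene it overlaps
by ≥ 1 bp on half-open intervals (abutting intervals do not overlap);
there is no apportioning between genes, because a circle that carries a
fragment of a gene is evidence of excision from that gene regardless of
what else it carries. Gene-level models only: a circle hitting several
isoforms of one gene counts once. The per-gene per-sample sums `raw` are
scaled by L_Max/L_i and equalized:

    PpGC = log2(raw · L_Max / L_i + 1)

L_Max is by default the longest gene with ≥ 1 split read in the dataset
("longest gene found in the dataset"); a switch takes the maximum over all
annotated genes instead. Because L_Max is dataset-relative, PpGC values
are comparable only within one run; the run manifest records the L_Max
used. Gene lengths must be positive; zero-raw entries map to exactly 0;
all-zero gene rows are retained but flagged droppable. Overlap queries use
an interval tree per chromosome and are property-checked against a
brute-force all-pairs scan.

## Differential calling (DifCir)

Per gene, the two group means of PpGC are compared; `delta = mean_A −
mean_B` is the log2 fold change. Selection requires |delta| ≥ θ (default
1.0) **and** t-test p ≤ α (default 0.05). Both thresholds are inclusive so
boundary cases are kept. The test is the classical equal-variance
two-sample Student t-test; a Welch switch is provided since some datasets
have strongly unequal group variances. No multiple-testing correction is
applied by default (raw p at α = 0.05); a Benjamini–Hochberg option
exists but is off, to keep the default definition of a DPpGC a raw-p
panel. Genes with all-zero raw counts in both compared groups are excluded
before testing. Degenerate genes (zero variance in both groups) get p = 0
when the means differ and p = 1 when they coincide, and are flagged.
Selected genes are ranked per direction by ascending p, ties by
descending |delta|, then symbol. The full per-gene table (means, delta,
p, −log10 p, direction, rank) is exported for volcano-style plotting.

## Enrichment statistics

All category tests are upper-tail hypergeometric with the mid-p-value
P(X > k) + ½·P(X = k), which removes most of the conservativeness of the
discrete exact test. Only enrichment is tested; depletion is reported
descriptively via negative Δc, not a lower-tail p. Star labels follow
decade brackets (k stars for 10^−(k+2) < p ≤ 10^−(k+1)).

**Chromosome landscape.** Δc = 100·(Nd_c/N_c − Nd_g/N_g) with Nd_c the
DPpGC genes on chromosome c and N_c the eccDNA records on c, counted
cohort-wide over post-filter records (each record once, not unique loci).
The statistic deliberately mixes units — genes in the numerator share,
eccDNAs in the denominator share — and the companion mid-p uses the same
counts (population N_g, successes N_c, draws Nd_g, observed Nd_c). A
genes-as-units mode is available behind a flag for users who prefer
homogeneous units. The identity Σ_c N_c·Δc = 0 holds by construction and
is enforced in the tests. Chromosomes with zero eccDNAs are omitted.

**Set over-representation** (fragile sites, GWAS traits, GMT sets):
k = |hits ∩ target|, n = |hits|, K = |universe ∩ target|, N = |universe|;
the reported percentage is 100·k/n. The default universe is the set of
genes with nonzero raw PpGC in the compared samples — the
"eccDNA-producing" genes — since only those could have been called.
Fragile-site membership is pooled over the five inducing agents
(aphidicolin, folic acid, BrdU, 5-azacytidine, distamycinA) for the test,
with per-agent annotations retained for display. Cross-species gene
matching goes through a homolog symbol map, case-insensitively; GWAS trait
matching is exact-string (catalog trait labels are controlled vocabulary)
and mapped-gene cells are split on comma, semicolon, or spaced hyphen.

## Synthetic cohorts

The generator emulates plasma circulomics cohorts, not reads: a genome of
5 chromosomes × 40 non-overlapping genes with log-uniform lengths in
20–200 kb (typical mammalian genes up to the large fragile-site genes),
uniform intergenic gaps of 5–25 kb. Per sample, Poisson(300) background
circles fall uniformly over the genome; knockout samples additionally draw,
for each of 20 effect genes, Poisson(λ_g · m) circles inside the gene
body, with λ_g = 300·L_g/G the gene's expected background load and m = 8
the effect multiplier — so the planted effect is interpretable as a rate
multiple of background. Group sizes default to 12 wild-type vs 11
knockout, the plasma design the pipeline targets. Circle lengths follow a
two-component truncated normal mixture at 180 bp (sd 40) and 360 bp
(sd 60) with weights 0.7/0.3 on [50, 10000] bp — a mono-/di-nucleosomal
profile qualitatively matching plasma eccDNA, with no claim of matching
any particular empirical curve. Split reads are 2 + Poisson(2). With
probability 0.1 a circle is re-emitted with both breakpoints jittered by
< D_min, exercising the coalescing step. A 15% fraction of genes gets a
synthetic fragile-site label with a random agent, independent of the
effect panel, so fragile-site enrichment is null by construction. All
randomness flows through one seed; per-sample substreams are keyed by
(seed, stage, sample index), making cohorts byte-reproducible and
independent of iteration order.

What passing tests on these cohorts do show: the pipeline recovers planted
rate elevations of this magnitude at the stated design size with high
sensitivity and a bounded false-discovery proportion, and the enrichment
test is calibrated under a true null. What they do not show: robustness to
mapper artifacts, GC or accessibility biases in circle formation,
protocol differences (Tn vs RCA), overdispersion beyond Poisson, or
correlated excision across neighboring genes — none of which the
generator models.

## Numerical choices and edge cases

- Exact rank-sum p-values use a subset-sum count in float64 (exact for
  the supported n ≤ 16); mid-p values come from the scipy hypergeometric
  sf/pmf and are validated against rational-arithmetic enumeration.
- Empty samples are legal: they count 0 circles, are skipped (with a
  warning) in length CDFs, and contribute zero columns to PpGC.
- A comparison group needs ≥ 2 samples; otherwise the differential call
  rejects.
- Empty hit panels give percentage 0 and mid-p 1, flagged, rather than an
  error, so batch summaries stay rectangular.
- The one-chromosome landscape degenerates to Δc = 0 with mid-p 0.5.

## Limitations

Quantification does not normalize for sequencing depth (none is applied by
design; PpGC compares like-prepared samples). The DPpGC definition uses
raw p-values, so panel sizes inflate with the number of tested genes
unless the BH option is enabled. L_Max coupling means PpGC values from
different runs are not directly comparable. The synthetic generator is a
study-design emulator, not a biophysical model of eccDNA formation.
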