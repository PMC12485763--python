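# Methods

## Model and procedure

epimosaic analyses per-CpG methylation count tracks (bedmethyl-style,
optionally haplotype-resolved) and per-read binary CpG call tables. All
coordinates are 0-based half-open (BED convention); both strands of a CpG
are collapsed onto the forward-strand C by summing counts, matching the
CpG-symmetry of 5mC. Chromosome names are compared as exact strings.

The pipeline has five stages:

1. **Aggregation.** Interval summaries use coverage-weighted means
   (meth_sum / total_sum), never means of per-CpG fractions, so deep CpGs
   dominate proportionally. Zero-coverage intervals yield a missing value,
   not 0, so "unmethylated" and "unobserved" stay distinguishable.
2. **DMRs and hotspots.** The DMR caller is an explicit stand-in for
   smoothed beta-binomial callers: per-CpG two-sided Fisher tests on
   (meth, unmeth) counts, BH across tested CpGs, significant CpGs
   (q < 0.05, per-CpG |Δ| ≥ 0.1) merged within 300 bp, regions kept with
   ≥ 3 significant CpGs, coverage-weighted |Δ| > 0.3 and region-level
   FDR < 0.05. It is validated only on synthetic data; the scientific
   payload is the recurrence layer: per-sample DMR sets are
   multi-intersected, segments covered by ≥ 25 samples (each sample counted
   once per base) and containing ≥ 5 CpGs of the pooled-normal track are
   hotspots. Sex chromosomes are excluded before testing.
3. **Blocks.** Adjacent-CpG mLD r² is the squared Pearson correlation of
   binary call vectors over reads covering both CpGs, undefined below 10
   shared reads or at zero variance (a constitutively uniform CpG carries
   no linkage information and therefore *breaks* runs rather than joining
   them with r² = 0). Blocks are maximal runs of ≥ 4 consecutive CpGs with
   all adjacent r² ≥ 0.5; block intervals cover the CpG dinucleotides
   (last position + 2). IMR blocks additionally have weighted methylation
   in [0.3, 0.7] — bounds inclusive, applied consistently everywhere the
   range appears — in every normal sample.
4. **Block calls.** ASM: Fisher on call counts between haplotypes,
   FDR < 0.05 and |Δ| > 0.4. Epimutation: Fisher of combined counts vs the
   pooled normal, FDR < 0.05 and |Δ| > 0.3. Both require ≥ 4 covered CpGs
   and adjusted CpG coverage (total calls / block CpGs) ≥ 5 per haplotype
   resp. per sample. BH families are one batch per invocation (per sample).
   State labels apply the precedence ASM > epimutation > intermediate
   (mean in [0.3, 0.7]) > indeterminate: ASM is the more specific claim
   when both tests fire. Candidate ASM regions are excluded when on a sex
   chromosome, overlapping a known imprinted interval, within 1,000 bp of a
   structural-variant breakpoint, or inside a 10-kb window whose SNP count
   is strictly above the genome-wide 99th percentile (computed over all
   tiled windows, so a flat density masks nothing).
5. **Cross-sample analyses.** Switching: blocks with ASM in ≥ 4 clones are
   informative; concordant iff all ASM clones methylate the same haplotype.
   Haplotype frames are arbitrary per phasing run, so cross-sample matrices
   must be built in a common frame (the CloneBlockMatrix accepts explicit
   per-sample flips). Timepoint concordance conditions on significance at
   both timepoints. Allelic-block fractions are reported against both the
   fixed block universe and the evaluable subset, since the two denominators
   answer different questions.

Tissue-specific IMRs: blocks present (≥ 1 bp overlap; exact-coordinate
matching would retain almost nothing given per-sample boundary jitter) in
all normal samples of a tissue are merged across tissues (min size 50 bp,
min gap 50 bp) and kept when the matched-tissue mean is in [0.3, 0.7] with
coefficient of variation ≤ 0.5 (sample sd, n−1 — the conservative choice at
small n) and differs by ≥ 0.2 from the average of per-sample means of
non-matched tissues (sample-level averaging so deep samples do not
dominate). The ≥ 0.2 delta is what removes germline-imprint-like blocks
that are intermediate in every tissue.

## Read-level metrics

Fragment metrics over a region use reads with ≥ 2 in-region calls. PDR is
the fraction of reads carrying both M and U; CHALM the fraction with ≥ 1 M;
entropy is pattern-based Shannon entropy in bits averaged over sliding
4-CpG windows; MHL weights fully-methylated substring frequencies linearly
(w_l = l); MCR is the concordant fraction of within-read adjacent call
pairs; MBS averages per-read sums of squared methylated-run lengths
normalized by read length. CHALM/MCR/MBS definitions vary across the
literature; the variants above are this package's reimplementation choices
and are frozen by the test suite.

## Synthetic data: what it emulates, and what it does not

The generator plants blocks of 4–20 CpGs (uniform, mean 12) spanning
~186 bp (CpG gaps 2 + Poisson) on a 10 Mb contig `chrS` plus a 1 Mb `chrX`
decoy. Per-cell behaviour per block label:

* **random-ASM** (and the ASM-like confounders SV-adjacent, SNP-dense,
  chrX): each cell/clone independently methylates haplotype 1 with
  probability π (default 0.5), independent across blocks — no spatial
  correlation between blocks;
* **imprinted**: haplotype 1 methylated in every cell (parental-style);
* **constitutive methylated/unmethylated**: both haplotypes at 1−ε resp. ε;
* **epimutated**: direction drawn once per block (hyper with probability
  0.7, reflecting the observed excess of hypermethylated epimutations) and
  shared by all clones; an independent `epimutation_rate` knob lets
  individual clones convert an ASM block into an epimutation;
* **independent-null**: every call an independent fair coin — the
  negative control for block discovery.

Per-call error ε defaults to 0.02 (no measured per-cell stability rate
exists for these blocks; ε is a free parameter). Clone track depth is
Poisson(coverage/2) per haplotype per CpG with binomial methylated counts;
long reads span whole blocks with haplotype tags; short fragments span 6
consecutive CpGs and carry ref/alt allele tags when they cover the block's
planted het SNP. Reads for block discovery are pooled across the 4 normal
donors (coverage_scale = 4), matching how blocks are discovered from pooled
samples; at single-sample 30× the per-block read-state split is occasionally
unbalanced enough that an adjacent pair's r² dips below 0.5.

The SNP background is a deterministic lattice (one SNP per 10-kb window,
plus one het SNP per block); dense windows receive 100 extra SNPs. This
makes the top-1% density mask exactly the planted dense windows by
construction — real SNP density is irregular, so on real data the filter's
boundary behaviour is less crisp than these tests suggest.

Not emulated: sequence context, bisulfite conversion chemistry, mapping
artifacts, copy-number variation, spatially correlated noise between
blocks, per-clone epimutation direction switching, and cell-type mixtures
within a "normal" sample. Passing tests therefore demonstrate correctness
of the statistical machinery under the stated generative model, not
robustness to every artifact of real sequencing data.

## Numerical choices

* Fisher exact tests via scipy; the suite verifies them against exact
  integer hypergeometric enumeration for all tables with margins ≤ 30
  (|Δp| < 1e-10).
* BH adjustment computes p·m/j with a suffix minimum; the suite requires
  bitwise equality with a naive quadratic oracle, which is why the
  expression is fixed rather than delegated to a library.
* merge semantics: intervals merge when they overlap/bookend or when the
  gap is strictly smaller than `max_gap` (a minimum allowed distance);
  merging is idempotent. Multi-intersect splits at every breakpoint and
  counts each input set once per segment.
* Quantile ties in the SNP-density mask use strictly-greater comparison
  against the (1 − 0.01) empirical quantile (numpy linear interpolation),
  so degenerate flat inputs mask nothing.
* Degenerate inputs: zero-coverage intervals are missing, zero-variance
  CpG pairs undefined, reads without in-region calls excluded rather than
  classified, empty p-vectors return empty q-vectors.

## Problem sizes

The analysis drivers and validation studies run at desk scale: 200–400
planted blocks, 1–30 clones, 30× coverage (120× pooled for block
discovery), 2,000 blocks for null calibration, 10,000 random instances for
the numerical oracles. These sizes give binomial standard errors well below
every margin asserted (e.g. switching SE ≈ 0.002 at 200 blocks) while
keeping each study to seconds or a few minutes.

## Known limitations

* The DMR stand-in has no smoothing and less power than beta-binomial
  callers on shallow data; recurrence logic is unaffected because it
  consumes interval sets from any caller.
* Per-sample BH families mean q-values are not comparable across samples
  tested in separate invocations.
* The hotspot CpG filter counts CpGs present in the supplied pooled-normal
  track; a sample-track count would differ where coverage differs.
* Haplotype synchronization across samples is the caller's responsibility;
  the tools validate only that a common frame is declared.
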