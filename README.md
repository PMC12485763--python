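# epimosaic

Analysis toolkit for **intermediately methylated regions (IMRs)** as
epimutation hotspots in clonal cell populations.

Normal tissues contain short blocks of CpGs whose aggregate methylation sits
between 0.3 and 0.7. In a polyclonal population this intermediate signal can
hide a surprisingly structured state: each individual cell methylates one of
its two haplotypes at random, so single-cell-derived clones show clean
allele-specific methylation (ASM) whose methylated haplotype *switches*
between clones. When such a region loses this balanced state in a clonal
population — becoming fully methylated or unmethylated on both haplotypes —
it is an **epimutation**. epimosaic implements the statistical machinery to
find these blocks, call their states, and quantify their clonal dynamics,
together with a seeded synthetic-data generator that provides ground truth
for every caller. It is aimed at methylation analysts working with
haplotype-resolved long-read or bisulfite data who want a tested, fully
synthetic-validated reference implementation of this analysis.

## The statistics at the core

* **Methylation LD blocks.** For adjacent CpGs *a*, *b*, the methylation
  linkage disequilibrium is r² = corr(X_a, X_b)², the squared Pearson
  correlation of the binary per-read calls over reads covering both
  (≥ 10 reads required). A methylation haplotype block (MHB) is a maximal
  run of ≥ 4 consecutive CpGs with every adjacent-pair r² ≥ 0.5; an **IMR
  block** is an MHB whose coverage-weighted methylation lies in [0.3, 0.7]
  in every normal sample.
* **Block ASM test.** Fisher's exact test on methylated/unmethylated CpG
  call counts summed over the block, hap1 vs hap2; evaluable when ≥ 4 CpGs
  are covered and the adjusted CpG coverage (total calls / block CpGs) is
  ≥ 5 per haplotype; significant at BH-FDR < 0.05 with |Δ methylation| > 0.4.
* **Block epimutation test.** The same Fisher construction, combined counts
  of the sample vs a pooled normal; FDR < 0.05 and |Δ| > 0.3, hyper/hypo by
  the sign of Δ.
* **Read-level ASM (short reads).** Reads spanning ≥ 4 region CpGs are
  classified methylated (≥ 70% of calls M) / unmethylated (≤ 30%) /
  undetermined; Fisher on classified read counts between SNP alleles with
  ≥ 8 classified reads per allele.
* **Recurrence hotspots.** Per-sample DMR sets are multi-intersected;
  segments overlapped by DMRs from ≥ 25 samples with ≥ 5 CpGs are hotspots.
* **Clone switching.** Among blocks with ASM in ≥ 4 clones, a block is
  *switched* when clones disagree on the methylated haplotype; under
  independent random choice (π = 0.5) the expected switched fraction is
  1 − 2^(1−m) for m informative clones.

## Worked example

```bash
epimosaic simulate --preset clones --seed 7 --outdir work --n-asm-blocks 30 --n-clones 5
epimosaic blocks --reads work/reads.normal.tsv --out-bed work/blocks.bed
epimosaic asm-ont --blocks work/blocks.bed \
    --hap1 work/clone01.hap1.bedmethyl --hap2 work/clone01.hap2.bedmethyl \
    --imprinted work/imprinted.bed --sv work/sv_breakpoints.bed \
    --snps work/snps.bed --out work/asm.clone01.tsv
# ... repeat asm-ont for clone02..clone05 ...
epimosaic switching --out work/switching.tsv work/asm.clone0*.tsv
```

The final command prints

```
switched fraction: 0.9333 (28/30)
```

meaning 28 of the 30 blocks with ASM in ≥ 4 of the 5 clones changed their
methylated haplotype between clones — the signature of random
allele-specific methylation. At π = 0.5 the chance that all 5 clones pick
the same haplotype is 2⁻⁴ ≈ 6%, so ~2 concordant blocks out of 30 is
exactly what independence predicts. `work/asm.clone01.tsv` holds the
per-block Fisher tables, q-values and methylated haplotype; the
`epimutation` subcommand adds per-block state labels (`ASM_hap1_meth`,
`hyper`, `intermediate`, ...) against the pooled normal.

The numbered drivers under `analysis/` run the full narrative on larger
synthetic cohorts — DMR hotspots (02), block discovery (03), per-clone
state calls (04), clonal dynamics (05) and tissue-specific IMR rates
(06) — writing their tables to `results/`.

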