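# snpdiscover

Reference-free discovery of single-nucleotide variants from shotgun
reads, for species without an assembled genome.

Conservation genomics and genotyping-array design routinely need a few
hundred to a few thousand reliable SNPs from species that have no
reference sequence — endangered mammals, non-model organisms, pooled
transcriptomes.  `snpdiscover` finds single-base differences directly
from overlapping shotgun reads (454-style long reads or Illumina-style
short reads), works at coverages far below what de novo assembly needs,
and ships the closed-form coverage model that tells you how much
sequencing a target SNP yield requires and how many false calls
segmental duplications will contribute.

## Method

The pipeline is incremental: reads arrive in *sets* (a lane, a quadrant,
any user-defined increment) and SNPs are re-called after every set, so
sequencing can stop as soon as the yield is adequate.  Each increment
passes through:

1. **Duplicate collapsing** — reads with identical bases (PCR/optical
   clones) are collapsed via an MD5 prefilter plus exact comparison.
2. **Repeat masking** — a three-pass scan derives a k-mer size K (the
   largest K with N/4^K > 5) and percentile cutoffs
   T_low ≤ T_extend ≤ T_threshold ≤ T_high from the set's k-mer
   frequency spectrum, soft-masks sliding 5-k-mer windows whose mean
   clamped k-mer score exceeds T_threshold (bridging runs above
   T_extend), masks whole reads dominated by a local repeat, and
   unmasks any masked run under 40 bp.
3. **Overlap detection** — seed-and-extend alignment: perfect unmasked
   seeds (40 bp for long reads, 32 bp for short) are extended with
   banded affine-gap dynamic programming terminated by an x-drop rule;
   a pair is *aligned* at ≥100 bp/96% identity (454) or ≥50 bp/96%
   (Illumina).
4. **Clustering** — every read seeds a cluster holding the reads that
   align to it and their observed differences.  A cluster exceeding the
   pile-up cap C_threshold (the 99.5th Poisson percentile of coverage
   depth at the current cumulative λ) or D_threshold = 10 distinct
   difference positions is frozen as a *candidate repeat*.
5. **SNP determination** — clusters with a substitution supported by at
   least two reads per allele (and ≤3 differences, none within 50 bp)
   are selected greedily so no read supports two calls, purged of
   repeat-adjacent members, micro-assembled (layout + quality-weighted
   consensus; external ACE assemblies can be imported instead), and
   filtered: one SNP per contig, ≥50/40 bp flanks, base quality ≥20 per
   supporting read, no homopolymer >4 bp in the 13 bp window around the
   site.

### The coverage model

With reads dropped uniformly at λ-fold coverage, per-base depth is
Poisson(λ).  Requiring each allele twice makes a heterozygous site
detectable with probability `f(λ/2)²` where `f(λ) = 1 − e^{−λ}(1+λ)`;
at 1× coverage that is **0.0081** of the genome.  Adding the pile-up cap
x, the calling probability is the truncated Poisson–binomial sum

    P(λ, x) = Σ_{k=4..x}  e^{−λ} λ^k / k! · Pr(2 ≤ Bin(k, p) ≤ k−2),

with allele proportions p = q = ½ for one diploid individual.  A
collapsed column of a t-copy segmental duplication sees coverage λt, so
inter-copy differences masquerade as SNPs with probability P(λt) — the
dominant false-positive source at low coverage, and the reason the
pile-up cap exists.  `theory.table1()` tabulates expected correct calls
and the duplication false-positive percentage over a (λ, x) grid;
`theory.plan_coverage()` inverts the model for experiment planning.

## Worked example

Simulate a 200 kb diploid genome (≈1 het site/kb, 250 bp reads, two 2×
increments), then run the incremental pipeline:

```
$ snpdiscover simulate --config sim.json --out-prefix demo --sets 2
2 set(s), 3200 reads, 119 het sites
$ snpdiscover init --state run --genome-length 200000
$ snpdiscover add-set --state run --in demo.set0.fastq
set 0: λ=1.996  C_threshold=6  calls=5
$ snpdiscover add-set --state run --in demo.set1.fastq
set 1: λ=3.986  C_threshold=10  calls=43
```

After the first 2× increment the pile-up cap is 6 and only 5 sites have
both alleles seen twice; doubling the coverage raises the cap to 10 and
the cumulative report to 43 calls — close to the model's expectation
`119 · P(4, 10) ≈ 42`.  `snpdiscover report` prints the calls with
their assembled contigs, offsets, alleles and per-allele support.

The model itself:

```
$ snpdiscover theory table1 | head -3
lambda\x        4       5       6       7       8
0.5     473/54.8%       552/65.0%       561/68.3%       561/69.0%       561/69.1%
1.0     4,598/28.6%     6,131/37.9%     6,450/43.5%     6,501/45.9%     6,508/46.7%
$ snpdiscover theory plan --target-snps 1000 --snp-density 1e-3 --genome-size 3e9
{
  "coverage": 0.425,
  "total_bases": 1275064182,
  "pileup_cap_x": 4,
  "expected_snps": 1000
}
```

Reading the table: at 1.0× coverage with cap x = 5, a genome with
800,000 true single-copy SNPs yields 6,131 expected correct calls, and
duplication-induced false positives amount to 37.9% of them; raising
coverage to 2.5× drops that to single digits.  The `plan` call shows a
thousand-SNP genotyping array needs only ~0.4× coverage of a
mammalian-sized genome.

## Layout

| module | role |
|---|---|
| `snpdiscover.io` | FASTA/FASTQ/ACE input, soft-masked FASTA output, cluster-store text format |
| `snpdiscover.dedup` | exact-duplicate collapsing |
| `snpdiscover.masker` | three-pass k-mer repeat masking |
| `snpdiscover.overlap` | seed-and-extend x-drop alignment (numba kernel) |
| `snpdiscover.clusters` | cumulative cluster store, pile-up/difference caps |
| `snpdiscover.assembly` | layout-consensus micro-assembly |
| `snpdiscover.snpcall` | SNP determination steps and final filters |
| `snpdiscover.theory` | Poisson detection model, planning, sensitivity/specificity |
| `snpdiscover.simulate` | synthetic diploid genomes, duplications, reads |
| `snpdiscover.run` / `cli` | incremental orchestration and the `snpdiscover` command |
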