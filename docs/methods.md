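# Methods

This note records the models, the tunable parameters, the design
decisions taken where the design was genuinely open, and what the
simulation-based tests do and do not demonstrate.

## Coverage model and its assumptions

Reads of length l are assumed to start uniformly and independently over
a genome of size L, so the depth at a position is Binomial(n, l/L) ≈
Poisson(λ) with λ = n·l/L.  Correlation of depth between nearby
positions is ignored (it does not change per-site marginals, which is
all the model uses), as are read-length variation, GC bias and mapping
ambiguity.  SNPs are assumed biallelic and sparse relative to l.

Under the two-observations rule the probability that a position is
sequenced at least twice from one parental chromosome is
f(λ/2) = 1 − e^{−λ/2}(1 + λ/2); a heterozygous site is detectable with
probability f(λ/2)².  With the pile-up cap x (sites covered by more
than x reads are distrusted as collapsed repeats) the calling
probability becomes

    P(λ, x; p, q) = Σ_{k=4}^{x} e^{−λ} λ^k/k! · Pr(2 ≤ Bin(k, p) ≤ k−2),

which for p = q = ½ has the inner term 1 − (2 + 2k)/2^k.  For two
individuals at equal coverage the relevant allele proportions are
(½, ½) when both are heterozygous or opposite homozygotes and (¾, ¼)
for a heterozygote plus a homozygote; `detect_prob_rule1` implements
the uncapped f(λp)·f(λq) form and is cross-checked by simulation.

For a duplication with t near-identical copies the collapsed column is
covered at λt, so an inter-copy difference is called with probability
P(λt).  For t ≤ 2 the two variant forms are balanced (p = q = ½); for
t > 2 a star-topology mutation model puts each difference on one copy,
giving (1 − 1/t, 1/t).  The expected-yield table (`theory.table1`)
additionally follows the convention that the aggregate false-positive
class is evaluated at an *effective* coverage of mean-copy-number × λ
with balanced proportions; with its default assumptions (800,000 true
single-copy SNPs, 30,000 duplication differences, 2.3 mean copies —
rough human-genome figures) the 25 grid cells are fixed test vectors.
Expected counts are floored, percentages rounded to one decimal.

`sensitivity_specificity` uses N(t) = p_t·l_t·P(λt): sensitivity is
P(λ), specificity N(1)/Σ_t N(t); the true-positive proportion evaluates
the same ratio with the per-class star-tree proportions.

## Pipeline parameters

| parameter | default | meaning |
|---|---|---|
| K | largest K with N/4^K > 5 | k-mer size per set (N = bases in set) |
| T_low…T_high | F[int(q·C)]+1, q ∈ {.9, .99, .995, .998} | percentile cutoffs over the ascending frequency array F (0-based, truncating) |
| window | 5 k-mers, step 1 | masking window; a masked window covers its K+4 bases |
| unmask run | < 40 bp | pass-3 removal of short masked runs |
| seed | 40 bp (454) / 32 bp (Illumina) | perfect unmasked match required to anchor extension |
| scores | 1/−3, gaps 1+3g (454); 1/−10, gaps 10+10g (Illumina) | match/mismatch and affine gap cost for gap length g |
| x-drop | 10 (454) / 20 (Illumina) | extension stops when score falls this far below its maximum |
| overlap filter | ≥100 bp & ≥96% (454); ≥50 bp & ≥96% (Illumina) | definition of "aligned" |
| band | 11 diagonals | DP band around the seed diagonal (substitution-dominated data drifts little) |
| C_threshold | Poisson⁻¹(0.995; λ) | cluster member cap, recomputed from cumulative coverage each increment |
| D_threshold | 10 | distinct difference positions per cluster |
| allele support | ≥2 reads per allele at base quality ≥20 | the two core calling rules |
| cluster filters | ≤3 substitution positions; no two qualifying positions within 50 bp | step-1 conservatism |
| final filters | 1 SNP/contig; flanks ≥50/40 bp; homopolymer ≤4 bp in a 13 bp window | genotyping suitability |

Decisions taken where the procedure was open:

- **k-mer canonicalisation.**  Counts merge a k-mer with its reverse
  complement (reads sample both strands); k-mers containing N are
  skipped, and alignment columns containing N never support an allele.
- **k-mer score.**  Frequencies are clamped into [T_low, T_high]
  (two-sided), damping extreme repeats and flattening the rare-k-mer
  tail; the rule is isolated in `masker.score_kmer` so it can be
  swapped.
- **Short-read seed.**  A 40 bp exact seed would miss legitimate 50 bp
  short-read overlaps containing a central error, so the Illumina seed
  is 32 bp (configurable).
- **"Exceeds" is strict** for both cluster caps, and for the pass-3
  local-repeat rule.
- **Difference counting.**  D_threshold counts *distinct positions*
  projected onto the seed read, so the cap does not scale with depth.
- **Step-1 spacing rule** applies to the qualifying (two-per-allele)
  positions; the ≤3 cap applies to all substitution positions in the
  cluster (the conservative reading).
- **Cluster processing order** for the disjoint-selection step:
  descending best allele support, ties by seed id — deterministic and
  favours the best-supported call when clusters share reads.
- **Micro-assembly** is a layout-consensus: members are placed by their
  seed-frame offsets, the contig is the per-column quality-weighted
  majority (ties alphabetical), and a member whose anchors disagree on
  its offset by >5 bp aborts the cluster.  Clusters are at most a
  pile-up cap of single-locus reads, so de-Bruijn/OLC machinery is
  unnecessary; external assemblers remain usable through the ACE
  import.
- **Homopolymer filter** measures, inside the 13 bp window, the maximal
  run of either allele base through the SNP position and suppresses the
  call when it exceeds 4 — so an allele that *extends* an adjacent run
  is caught even when the consensus shows the other base.
- **Cross-set clones.**  Duplicate collapsing is per-set (matching how
  duplicate rates are reported), but the pipeline also refuses reads
  whose exact base string arrived in an earlier set, so no call can owe
  its two-per-allele support to clones straddling set boundaries.
- **Quality defaults.**  FASTQ is Phred+33 (Phred+64 behind a flag);
  FASTA input receives quality 20 everywhere — exactly the calling
  threshold, so unscored input neither passes nor fails filter (c) by
  accident.  SFF containers are not parsed; convert to FASTQ upstream.

## The synthetic-data generator

`simulate` produces exactly the structure the model assumes: a uniform
random genome; heterozygous sites planted at a stated density (optionally
with a minimum spacing) outside duplicated sequence; t-copy duplication
blocks whose copies differ at a stated per-bp density, each difference
assigned to one copy (star topology); optional high-copy interspersed
repeat units; reads sampled uniformly from random haplotypes and
strands at coverage λ; independent per-base substitution errors; and
optional exact PCR clones.  One seeded generator drives all draws, so
fixtures are byte-reproducible.

Base qualities are *calibrated*: correct bases get Phred 40, miscalled
bases get Phred 5–19 — a base caller that knows when it is unsure.  The
`error_qual_high_frac` parameter (default 0) reassigns a fraction of
miscalls to Phred ≥ 20 for exercising the quality filter.  What the
generator does **not** emulate: context-dependent and homopolymer
errors, quality miscalibration, indels, chimeras, coverage bias,
paired-end structure.  Tests passing on these fixtures therefore show
the machinery is correct under the model's assumptions, not that real
454/Illumina data will behave as cleanly; on real data the quality
filter and homopolymer filter carry weight that the simulation does not
measure.

## Tying the pipeline to the theory

The model counts *reads covering a position*; the pipeline can only use
reads that align pairwise.  Two covering reads overlap each other
detectably only when their starts differ by less than l − min_overlap,
so with the 454 default (min_overlap 100 on 250 bp reads) ~16% of
covering pairs are invisible and the pipeline must undershoot the
model.  The theory-tie experiments therefore lower min_overlap to 50 bp
on 250 bp reads (a documented score-set override), under which ~96% of
covering pairs are detectable; residual undershoot (a few percent)
comes from x-drop endpoint trimming at overlap edges and from reads
excised because their own cluster crossed the member cap — the member
count watches the whole read span (mean ≈ 1.6λ) while the cap is set
from point coverage (λ).  These are properties of the pipeline the
model deliberately idealises away.

Problem sizes used by the test suite (chosen so the full suite runs in
a couple of minutes while keeping binomial error bars meaningful):
0.5 Mb genomes at λ ∈ {1, 2, 4} for the detection-rate comparison
(~320 planted sites); 0.4 Mb at λ = 4 with 1% error for the precision
check; 1.5 Mb with a 150 kb two-copy duplication (0.5% divergence) and
five 0.5× increments for the duplication trend; 3 Mb for the
repeat-masking calibration (the repeat family must occupy well under
0.5% of distinct k-mers, or it contaminates its own percentile
cutoffs).  The duplication-trend fixture's difference density (0.5%/bp
in duplicated sequence vs 0.1%/bp heterozygosity) makes the
false-positive fraction large at low coverage by construction; it is
the *decline* with coverage that is the reproduced phenomenon.

## Numerical and degenerate-input choices

- Poisson quantiles and binomial tails come from scipy; the calling
  probability uses log-space Poisson terms (stable to λ ≈ 700).
- The x-drop kernel prunes cells more than `xdrop` below the running
  maximum and reports the maximum-score endpoint, so overlaps never end
  in a mismatch or gap; traceback is exact within the band.
- Empty sets are accepted (state unchanged); reads shorter than K+4
  skip window masking; reads with under 40 unmasked bp are treated as
  fully masked and excluded from anchoring and from calling.
- λ = 0 gives a pile-up cap of 0 and calling probability 0 rather than
  an error.

## Known limitations

Indels are not called (differences containing gaps are counted against
cluster caps but never become alleles).  Paired-end information is
unused.  The duplication model in `theory` assumes copy numbers are
known when computing specificity; the pipeline itself never knows t and
relies on the pile-up cap.  The member-count cap is an upward-biased
proxy for point coverage (factor ≈ 2(l − min_overlap)/l), so real runs
freeze slightly more clusters than the model predicts; this is
conservative.  Transcriptome mode disables only the member cap — highly
expressed paralogue families are still caught by the difference cap.
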