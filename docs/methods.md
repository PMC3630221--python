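# Methods

## The analysis model

`pooltag` analyses parallel tagged amplicon sequencing of population
pools of a haploid locus (mitochondrial genes are the motivating case).
Each population pool mixes equimolar PCR products from N individuals
under one 8-bp barcode; a read's first eight bases identify its pool
and the rest is a fragment of one individual's amplicon. Because the
locus is haploid and the pool equimolar, the read frequency of an
allele estimates its carrier frequency m/N, so integer carrier counts
— and from them population haplotypes — can be reconstructed from read
frequencies alone. The chain is:

1. exact-match demultiplexing (a read is used only if its first
   tag-length bases equal a pool tag exactly; the tag is stripped);
2. semi-global alignment to the amplicon reference with cost 0 for a
   match and 2 for mismatch, insertion and deletion, keeping reads with
   more than 90% similarity over at least 75% of their length;
3. pooled SNP calling from the pileup: a variant allele is reported
   when site depth ≥ 20 reads, its mean Phred quality and the mean
   quality of the neighbouring columns are ≥ 20, and its read frequency
   is ≥ 5% (a conservative floor approximating the lowest expected real
   haplotype frequency; the largest supported pool, N = 13, has an
   expected singleton frequency of 100/13 ≈ 7.69% > 5%);
4. largest-remainder allocation of frequencies to integer counts
   summing to N, and phasing of multi-site haplotypes from reads that
   span several called sites;
5. per-pool nucleotide diversity π, pairwise Hudson F_ST, and a
   single-level AMOVA Φ_ST with a permutation test;
6. a concordance report against the same quantities computed from
   per-individual sequences (the validation arm): OLS of pooled on
   individual values with the β = 1 slope-CI check and R²,
   zero/non-zero interpretation agreement, and Mann–Whitney tests on
   per-pool SNP counts.

Assumptions: haploid locus; equimolar pools unless pipetting noise is
modelled explicitly; primer-anchored amplicon reads (reads start at an
amplicon terminus on their strand); substitution-only variation between
haplotypes (indels are not called); one reference per locus.

## Key parameters

| parameter | default | units | rationale |
|---|---|---|---|
| tag length / min distance | 8 / 3 | bp / substitutions | three substitutions cannot convert one tag into another silently under exact matching |
| mismatch, insertion, deletion cost | 2 each | — | the analysis cost scheme; equal costs make optimal cost = 2 × Levenshtein distance |
| length fraction / similarity | 0.75 / 0.9 | — | mapping acceptance thresholds |
| min central+neighbour quality | Q20 | Phred | 1% per-base error ceiling for evidence bases |
| neighbourhood radius | 5 | bp | "neighbouring" quality window; configurable |
| min coverage (pooled / individual) | 20 reads / 2 sequences | — | pooled depth floor; individual floor equals the smallest pool size |
| variant frequency floor | 0.05 | fraction | below the expected singleton frequency of every supported pool; `adjust_per_pool` switches to max(0.05, c/N) |
| min spanning reads | 3 | reads | a site-pair linkage is only trusted with ≥ 3 reads covering both sites |
| modal read length / sd | 477 / 40 | bp | pyrosequencing-era modal length; sd chosen so most reads sit near the mode |
| AMOVA permutations | 1000 | — | permutation resolution ~0.001 |

## Numerical and algorithmic choices

**Similarity definition.** The mapping filters are stated relative to a
"read length" whose exact accounting differs between toolchains. Fixed
here: after alignment, terminal non-match columns are trimmed; the
similarity is matches divided by *all* columns of the trimmed region
(read bases plus read gaps), and the aligned-read fraction is the read
bases inside the region divided by the read length.

**Alignment engine.** `align_semi_global` is the explicit dynamic
programme (free end-gaps on the reference, deterministic tie-breaking:
match/mismatch preferred over deletion over insertion, smallest
reference end position). Because all edit costs equal 2, the optimum
equals twice the Levenshtein distance, so the production path uses
edlib's infix mode and only falls back to DP where it matters: a pair
of nearby substitutions admits a co-optimal insertion+deletion
rendering, which would displace alleles off their true positions, so
any edlib path containing indels has small windows around the indel
columns realigned with the canonical DP (cost is unchanged; the
canonical form restores substitutions at their positions). Candidates
whose edit distance already exceeds what the similarity and length
filters could accept are rejected without computing a path.

**Frequency → count allocation.** Largest-remainder allocation
minimises the L1 distance between counts and freq·N subject to the
counts summing to N; ties in the fractional remainders break by
lexicographic allele order. Verified against exhaustive search for
N ≤ 10 on a 5% frequency grid.

**Phasing.** Sites are processed in reference order, maintaining
partial haplotypes (prefixes) with integer multiplicities. To link the
next site, every read covering it and at least one processed site
votes for the (prefix, allele) combinations it is consistent with — a
read supports a prefix only if it matches the prefix at *all*
processed sites the read covers. Each prefix's multiplicity is split
across next-site alleles by largest-remainder allocation of its
support proportions, then single units are moved (by smallest support
loss) until the site's marginal counts are met exactly, so the
haplotype set always reproduces the allele-count table. Pure pairwise
co-occurrence linking was rejected: prefixes sharing an allele at the
linking site are indistinguishable to it, and it provably cannot
recover the truth even from error-free full-length reads. Site-pairs
with fewer than `min_span_reads` covering reads are linked by
frequency rank (largest with largest) and flagged ambiguous, so
downstream estimates can be recomputed under alternative phasings.
Note that π, F_ST and Φ_ST as implemented depend only on per-site
marginals (difference counts are additive over sites), so phasing
quality affects haplotype reports and downstream external analyses,
not these estimators.

**Hudson F_ST.** F_ST = 1 − Hw/Hb with Hb the mean difference count
over all between-population pairs. Hw defaults to the mean of the two
per-population mean pairwise differences (populations weighted
equally), following Hudson, Slatkin and Maddison's definition; the
alternative that pools all within-pairs (pairs weighted equally) is
available via `weighting="pooled"`. The distinction matters with
unequal pool sizes: pair-pooling makes a small pool's diversity nearly
invisible in Hw while its between-pool differences keep full weight in
Hb, which reverses the sign of the bias that coverage loss induces.
Hb = 0 (identical monomorphic pools) reports F_ST = 0. The
finite-sample estimator can be slightly negative (identical
polymorphic pools give Hw > Hb because within-means divide by C(n,2));
negative values are reported as computed and classified as "no
differentiation" in the interpretation-agreement statistics
(zero tolerance 1e−12).

**AMOVA.** Single-level variance partitioning on squared distances
(= pairwise difference counts): SSD(within) sums per-pool pair
distances over pool size, σ²_within = SSD(within)/(n−K), σ²_among =
(SSD(among)/(K−1) − σ²_within)/n_c with n_c = (n − Σn_k²/n)/(K−1), and
Φ_ST = σ²_among/(σ²_among+σ²_within). The permutation test shuffles
individuals among pools with sizes fixed and reports
p = (hits+1)/(n_perm+1); all-identical sequences give NaN.

**Site harmonisation across pools.** Each pool's haplotypes cover its
own called sites. For cross-pool statistics the union of called sites
is used, filling the reference allele at sites a pool has no call for
— which is exactly how an undetected variant biases the estimates, and
is therefore also the mechanism the failure-mode simulations probe.
Individual-mode haplotypes are full-length sequences, so no filling is
needed there.

## What the simulator emulates — and what it does not

The generator draws structured populations by giving each population a
private block of reference positions: Binomial(n_site_pool,
between_div) of them become private fixed differences and
Binomial(n_site_pool, within_div) become segregating sites with a
derived-allele count uniform on 1..N−1. This produces strong,
permutation-detectable structure with realistic within-pool diversity,
and guarantees fixed differences are private by construction. Reads
are primer-anchored, strand-uniform, truncated-normal in length and
capped at the amplicon; substitution errors are uniform with a
constant quality string Q = −10·log₁₀(rate) (erroneous bases are *not*
marked by lower quality, modelling undetected miscalls); homopolymer
±1-bp indels occur per run with probability rate × (run length − 1);
pipetting noise, when enabled, draws per-individual lognormal weights
with the given coefficient of variation.

Not modelled: coalescent genealogies (sites are independent and
population-private), PCR chimeras and duplicates, quality-score decay
along reads, flowgram-level error structure, diploid genotypes, and
contamination. Passing tests therefore demonstrate the pipeline's
correctness and its qualitative failure modes under controlled
conditions — not calibrated error rates on any particular instrument's
real data.

## Test problem sizes

The deep-recovery check runs 20 pools (93 individuals, sizes 2–13) at
a 420-bp locus with 2000 error-free reads per pool: at that depth the
binomial standard error of a read frequency (~0.011) is far below the
1/(2N) ≈ 0.038 rounding margin of the largest pool, so allocation is
exact and the pooled pipeline reproduces the individual-mode truth
exactly (β = 1, R² = 1, 100% agreement). The failure-mode check runs
20 replicate experiments of the two-amplicon 570/830-bp locus at modal
read length 477 with within_div = 0.27 (≈ 8 segregating sites per
pool), 40 reads per individual, substitution rate 0.004 and
homopolymer base rate 0.002: only reverse-strand reads of the long
amplicon reach positions beyond 570, so tail depth is about a quarter
of the input and sits near the 20-read floor for the smallest pools,
losing low-frequency tail variants — mean pooled π falls below the
truth and mean pooled F_ST rises above it, while coverage before
position 477 stays high. Statistical calibration uses 200 null AMOVA
replicates (5 pools × 6 individuals, 99 permutations; Kolmogorov–
Smirnov screen) and 1000 OLS replicates (n = 20, Gaussian noise) for
the 95% slope-CI coverage.

## Known limitations

- Indels are never called; true indel variation between haplotypes
  would be misread as substitution noise near the indel.
- The pooled caller assumes one reference per locus; reads from a
  mixture of strongly diverged lineages may fail the 90% similarity
  filter and silently drop a lineage.
- Phasing is greedy; with sparse spanning coverage and more than ~10
  called sites it can settle on a marginal-consistent but untrue
  arrangement (flagged ambiguous pairs bound the affected regions).
- The AMOVA permutation p-value is discrete (resolution 1/(n_perm+1))
  and conservative under heavy distance ties.
- Largest-remainder allocation is unbiased only for equimolar pools;
  with strong pipetting noise the integer counts inherit the molarity
  distortion.
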