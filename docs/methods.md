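# Methods

This note documents the models, conventions, parameter choices, and known
limitations of the package. It states nothing that the test suite or
`scripts/acceptance.py` does not itself compute.

## Coordinates and formats

All coordinates exposed by the package are 0-based half-open on the query
sequence. RepeatMasker-style `.out` files (1-based inclusive, `C` for minus
strand) and `.align` files are converted at the format boundary only.
Soft-masked lower-case residues are upper-cased on read; masking state is
not preserved. Divergence values stated in `.align` files are treated as
advisory: K2P is always recomputed from the gapped alignment pair so that
every downstream number is self-consistent, and a warning is logged when
the stated and recomputed values differ by more than one percentage point.

## K2P distance

`k2p_distance` implements the plain two-parameter model,
K = −½ln(1−2P−Q) − ¼ln(1−2Q), assuming equal base frequencies and
homogeneous rates across sites, without CpG adjustment. When either log
argument is non-positive the distance is *saturated* and reported as
undefined (`None`); saturated copies are routed to the landscape's overflow
bucket rather than dropped, so bp conservation holds exactly.

Alignment columns containing a gap or a non-ACGT symbol in either sequence
are excluded from the compared sites. Insertions therefore do not inflate
divergence, and a copy's bp is its aligned query bases excluding query
gaps, which is what makes the landscape conservation law
(sum of binned bp + overflow = total masked bp) exact rather than
approximate.

In the equal-rate limit (one transition and two transversion targets per
site, so Q = 2P) the formula reduces analytically to the Jukes–Cantor
distance on p = P + Q; the suite verifies agreement to 1e−12 and checks the
general formula against a 30-digit arbitrary-precision evaluation to 1e−10.

## Landscapes and recent copies

Landscapes use 51 half-open 1% bins [i, i+1)% for i = 0..50. A copy
contributes its full bp to the single bin indexed by floor(100·K2P);
"recent" (< 5%) and "very recent" (< 1%) are strict thresholds, so a copy
at exactly 5.0% is not recent. Copies at ≥ 51% or saturated go to the
overflow bucket, which is excluded from plots but retained in totals.

## The read masker

Abundance quantification needs a homology search over reads. The package
uses a deterministic seed-and-extend masker: 11-mer seeds (both strands of
every library sequence are indexed), seeds grouped by alignment diagonal,
ungapped extension to the maximum-scoring segment under match +1 /
mismatch −1 (among tied-score segments the longest is taken, which makes
masked bp invariant under reverse-complementing the reads), merging of
same-target hits on nearby diagonals through a gapped edit-distance
realignment, and best-score-per-base overlap resolution (ties broken by
hit length, then consensus name). Tandem monomers are internally expanded
to concatemers of at least max(2 monomers, 400 bp) so a read of any phase
aligns on a single diagonal — the same rationale as mapping reads to
dimer/concatemer satDNA references.

Defaults are min_identity 0.7 and min_hit_bp 30, chosen so copies
~15% diverged from the consensus are still detected. The satDNA library
pipeline raises these to 0.8 / 40, matching the 80% homology floor of the
80-80-80 rule and suppressing chance seed extensions on non-repetitive
reads, which matters because family presence is called at a genome
proportion of only 1e−5. This masker trades the scoring matrices and
sensitivity machinery of a production masker for testability; externally
produced RepeatMasker `.out`/`.align` annotations are accepted wherever
masking output is consumed, so genome-scale runs can reuse external
masking.

## satDNA families

Monomer comparisons must be phase- and strand-free. `canonicalize_monomer`
returns the lexicographically minimal rotation over the sequence and its
reverse complement. `pairwise_homology` aligns the shorter monomer (and its
reverse complement) end-to-end against the doubled longer monomer, which
captures any rotation phase; identity is matches over alignment columns and
coverage is relative to the shorter monomer. For equal-length monomers both
role assignments are evaluated and the better kept, making the edge
symmetric. This is a semi-global formulation rather than a local
Smith–Waterman: full-query alignment directly encodes the
coverage-over-the-shorter-monomer meaning of the 80-80-80 rule, and the
identity term penalizes non-homologous overhang. An independent
substitution-matrix aligner (Bio.Align.PairwiseAligner) serves as the
cross-check oracle in the tests.

Families are connected components of the thresholded edge graph
(single linkage), mirroring an all-against-all merge of per-sample
consensus libraries; the suite verifies equality with a brute-force
transitive closure on random instances. The literal 80 bp aligned-length
rule is relaxed to 0.8× the shorter monomer for monomers under 100 bp,
since monomers down to 7 bp occur and could never satisfy a fixed 80 bp
requirement.

Family abundance in a sample sums the masked bp of *all* member monomer
variants (the attribution when several within-sample variants join one
cross-sample family is not standardized; summing is the choice here).
Families are numbered satDNA-1, satDNA-2, … by descending pooled genome
proportion, ties broken by member name. Presence is called at
GP ≥ 1e−5 (0.001% of sampled bp) — below the ~0.01% detection floor of
read-clustering discovery, above masking noise; the threshold is a
reported, configurable parameter.

The coefficient of variation uses the sample standard deviation
(ddof = 1), which is material at four samples; it is exposed as
`--cv-ddof`. Differential amplification is cv > 80% strictly, assessed over
families present in all samples. The Kruskal–Wallis test takes samples as
groups and the per-bin GP values of the 51-bin divergence profile as
observations, with tie correction and a chi-square p (a seeded permutation
p is available for small samples). Kruskal–Wallis p-values are reported
raw; Benjamini–Hochberg correction is available behind a flag but off by
default to match the raw-threshold reporting convention of the
library-hypothesis literature.

## Tandem-repeat structure

The fundamental monomer period of a sequence is the smallest
self-alignment lag whose mean per-position identity reaches 0.7. A
higher-order repeat is reported as the smallest integer multiple of the
fundamental period whose lag identity exceeds the fundamental's by at
least 5 percentage points — a numeric stand-in for what is usually judged
by eye from dotplots. Array counting tiles a contig with best-phase
monomer alignments; runs tolerate gaps up to 0.2× the monomer length and a
terminal partial copy counts iff at least half the monomer aligns.
Dotplots use window 10 with ≥ 8 matching positions by default; both are
flags. Classification of tandem repeats against labeled seeds (telomere
(TTAGG)n, rRNA/snRNA/histone gene seeds) is similarity-only at ≥ 80%
identity and coverage; internal structure of multigene families is not
modeled. satDNA naming is Vv + sample label + rank by descending genome
proportion.

## TE expression

The recent-TE annotation keeps copies with K2P strictly below 5%. Read
counting replaces a pseudo-genome two-pass strategy with direct
interval-overlap counting: a read overlapping (≥ 20 bp) copies of exactly
one subfamily contributes 1, a read overlapping k subfamilies contributes
1/k to each, and unassigned reads are tallied so total read mass is
conserved. Normalization is median-of-ratios over subfamilies with
all-positive counts; subfamilies with total raw count below 10 are removed
(the operationalization of low-count filtering);
log2FC = log2((meanA+0.5)/(meanB+0.5)). The built-in test is a two-sided
exact rank-sum across replicates with BH adjustment — a distribution-free
stand-in for a negative-binomial Wald test; externally computed p-values
are accepted so an external count-model pipeline can be reproduced
exactly. MBTE/FBTE labels require a non-zero log2FC sign and adjusted
P < 0.05.

## Synthetic repeatomes

The generator's substitution process *is* the K2P model: each site mutates
at most once, to a transition with odds κ:1 over a transversion
(default κ = 2), with per-site probabilities solved numerically so the
expected K2P equals the requested target. This makes divergence recovery a
clean closed loop — generator and estimator share only the K2P formula —
and the simulated transition/transversion count ratio converges to κ.
There is no rate heterogeneity across sites, no sequencing error by
default (an error-rate flag adds uniform mismatches), and indels are off
by default so masking identity thresholds stay interpretable. Concerted
evolution is modeled only as low intra-race divergence of satDNA copies,
not as an explicit recombination process.

Race genomes are i.i.d. random backgrounds with TE copies placed dispersed
at uniform non-overlapping positions and satDNA copies placed as tandem
arrays (optionally interleaving two monomer variants as a HOR block), on
random strands. Reads are 150 bp pairs with normal insert sizes (mean 400,
sd 25) and uniform fragment starts. Every planted copy is recorded with
its realized K2P.

### Closed-loop experiment sizes

The standard recovery experiment uses four races of 1 Mb each, 50,000 read
pairs per race (15 Mb, ~15× of each genome), 12 satDNA families with
monomer lengths 50–200 bp, per-family target GP 0.4%, 9 families shared by
all races, and one family amplified 5-fold in race 1 at 2% divergence
(the remaining families draw divergence uniformly in 2–12%). These sizes
were chosen as the smallest panel at which family sharing, the cv > 80%
flag (5-fold amplification gives an expected cv of 100% across four
races), and the landscape mode are all comfortably identifiable; the test
suite runs it over five seeds. The expression experiment uses 50
subfamilies (10 with 4-fold male bias), negative-binomial counts with
dispersion size 10, and 5 replicates per group over 20 seeds.

## What passing tests do and do not show

The synthetic generator emulates the statistical structure the analysis
assumes — shared library, controlled divergence, differential
amplification, tandem organization — but not sequencing error profiles,
GC or coverage bias, nested or fragmented repeat copies, satDNA
homogenization dynamics, or assembly collapse of arrays. Recovery results
on synthetic panels therefore validate the correctness of the computation,
not the sensitivity of the masker on real genomic reads, and absolute GP
values from the internal masker will differ from those of a production
masker with curated scoring matrices.
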