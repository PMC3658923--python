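# Methods

This note documents the models, algorithms, parameter choices and known
limitations of motifweave, in the spirit of a statistical package's methods
appendix.  Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Promoters and coordinates

Promoters are the ≤1 kb immediately upstream of the annotated gene start
(a TSS proxy; annotations rarely distinguish TSS from translation start, and
the gene feature is used).  Internally all coordinates are 0-based
half-open; GFF3 is read 1-based inclusive and BED 0-based half-open, so the
conversions are bit-exact.  Minus-strand promoters are reverse-complemented,
so every stored promoter reads 5'→3' toward its gene.  Promoters are
truncated at chromosome edges; genes whose upstream window is empty are
dropped.  Soft-masked (lowercase) and N bases are preserved: scanners skip
windows containing N, and discovery engines accept masked windows as match
targets but never seed a motif from a lowercase-containing window.
Repeat-masking itself is out of scope — inputs are used as given.
First-intron search is not implemented; promoters only.

## PWMs and scanning

A motif is a 4×w count matrix with a pseudocount; column probabilities are
(count + pc) / (n + 4·pc).  Defaults: pc = 0.25 for discovery (avoids −∞
log-odds in scans), 0 for exact arithmetic in examples.  The IUPAC consensus
rule per column: the top base if its probability ≥ 0.5, a two-base code if
the top two jointly reach 0.75, else N.  This rule is a package convention,
not an external standard.

Scanning uses log2 odds against an order-0 background (default: base
frequencies of the set being scanned, or uniform).  P-values are exact for
the integerized score (×1000, rounded): a dynamic-programming convolution
builds the full null score distribution column by column, and tail
probabilities are read from it.  Both strands are scanned with the motif and
its reverse complement; the default retrieval threshold is p ≤ 1e-4, the de
facto standard for PWM retrieval.  One scanner serves discovery filters,
MNCP, genome retrieval and the multi-motif intersection query; no separate
best-score-normalized scanning modes are provided.

An important consequence of exact per-window p-values: instances *sampled*
from a PWM have random scores.  For a width-10 motif of ~12 bits with one
dominant base per column at 0.87, about a third of sampled instances carry
≥2 non-dominant bases and legitimately score above p = 1e-4.  Perfect
site-level recovery at a fixed p cut is only expected for low-entropy
motifs; tests of exact retrieval therefore use near-deterministic implants.

## The three discovery engines

All engines: up to `n_motifs` = 10 motifs, widths within 6–10, both strands,
ties broken by score (desc), then leftmost start, then input order.

**EM (ZOOPS).**  A two-component finite mixture per sequence: with
probability γ the sequence carries exactly one motif occurrence at a
uniformly chosen window, else it is pure background.  Seeds are the
`n_seeds` = 10 distinct words with the highest occurrence count within one
mismatch (computed by a masked-key trick in O(w·n log n)); each seed
initializes θ at 0.7 on the seed base and is refined by EM (tolerance 1e-4
on the log-likelihood, ≤100 iterations); the best seed's fit is accepted.
Sites are the argmax-responsibility window of every sequence whose occupancy
posterior exceeds 1/2; accepted sites are erased (set to N) and the search
repeats.  The engine score is the ZOOPS log-likelihood ratio against
background-only.  Deterministic given input order and seed.

**Gibbs site sampler.**  One candidate site per sequence (OOPS); each sweep
resamples every sequence's site from the posterior given the PWM built from
all other sites (pseudocount 0.5).  100 burn-in plus 200 sampling sweeps;
the maximum-joint-score configuration seen after burn-in is reported, then
masked, and the procedure repeats.  Two additions beyond the textbook
sampler, both standard practice: a joint phase-shift move every 10 sweeps
(try shifting all sites by ±1…w/2 in motif orientation, keep improvements) —
without it the sampler frequently locks one or two columns off phase — and
data-driven initialization at each sequence's closest window to the top
seed word, which removes dependence on a lucky random start.  Stochastic:
runs agree only under equal seeds.

**Consensus enumeration.**  (length, mismatch) budgets (6,1), (8,2), (10,3)
— a declared mapping of a "medium" 6–10 nt search.  At length 6 all 4^6
words are enumerated; at 8 and 10 the candidates are the words actually
occurring in the input (both strands, reverse-complement-canonicalized),
which necessarily include any planted word.  A word is a candidate if it
occurs within its mismatch budget in ≥50% of sequences.  Score: the exact
binomial upper tail of the total occurrence count at stringency d' against
the expected count under the order-0 background (per-word match probability
by a Poisson-binomial DP), maximized over d' = 0…d and reported as −log10 p.
Scoring across stringencies matters: at d = 3 a word's neighbourhood is so
large that exact planted occurrences would drown in it.  Selected words
suppress shifted/substring variants: a word whose occurrences mostly lie on
positions already claimed by a higher-scoring word is skipped (this is
within-engine redundancy control; cross-engine duplicates are deliberately
*not* merged).  Adjacent-base extension of accepted words is not
implemented.  Fully deterministic.

Mismatch counting packs words two bits per base into uint64 and uses
XOR + popcount, so candidate-versus-window distances are a few vectorized
passes even at ten thousand windows.

## Filters

A motif survives only if its occurrence among the n input promoters is
unlikely under background, where "occurrence" means ≥1 scanner hit at
p ≤ 1e-4 on either strand (promoter count, not total site count).  Gibbs and
consensus motifs use an exact binomial upper tail p_B with the per-promoter
background rate estimated from a seeded random sample of B = 1000 genome
promoters (the whole database if smaller); EM motifs use an exact
hypergeometric upper tail p_H with the whole promoter database as the
population.  Cutoffs: p_B ≤ 0.7 (gibbs), p_B ≤ 0.3 (consensus), p_H ≤ 0.05
(em).  These cutoffs are fixed constants of the pipeline (they came out of a
benchmark optimization; the sweep machinery is not re-run here).  Exact tail
sums are used throughout — at n of a few hundred there is no reason to
approximate.  Failing motifs are retained in the filter report, flagged.

## MNCP ranking

All surviving motifs are ranked by MNCP against one shared seeded random
sample of genome promoters (default size: max(1000 capped at availability,
10·n), excluding input gene ids).  Promoters are ordered by per-promoter
match count, ties by best site score, then gene id; promoters with identical
(count, score) keys form genuine tie groups and receive mid-ranks, so id
naming conventions cannot bias the statistic (with distinct keys this is the
plain rank).  NCP_i = (i/r_i)/(n/N); MNCP is the mean over input promoters.
Two properties worth knowing: MNCP of an uninformative motif concentrates
near 1 only for moderately large n — its small-sample expectation is
approximately (n+1)N/(n(N+1)) ≈ 1 + 1/n — and the occurrence *count* (not a
summed score) is the ranking statistic, a declared choice.

Positional preference histograms bin each site by its 5'-most base's
distance upstream of the TSS (promoter 3' end = position −1), in 20 nt bins
half-open toward the TSS: a site exactly 60 bases upstream falls in
[−60,−40), not [−80,−60).

## Genome retrieval, intersection and GO enrichment

Genome-wide retrieval returns every promoter with ≥1 hit and its copy
number.  The multi-motif query intersects per-motif gene sets, optionally
restricted to hits within the final R bp before the TSS (default R = 200).
GO enrichment is an exact hypergeometric upper tail per term over the
annotated universe (genes without any GO annotation are excluded from N and
from the effective list), with Benjamini–Hochberg adjustment across the
tested terms; both raw and adjusted p are reported.

## Nucleotide benchmark

Evaluation labels every nucleotide by the union of site intervals,
strand-agnostically (a site on either strand covers its positions), giving
nTP/nFP/nFN/nTN per dataset; nSn = nTP/(nTP+nFN), nFDR = nFP/(nFP+nTP), and
nCC is the Matthews correlation of the two indicator vectors.  Undefined
denominators yield "not available", never a silent zero.  Cross-dataset
aggregation is the unweighted mean; count means are additionally shown
rounded to integers, and percent changes are reported to one decimal.  The
true-positive partition attributes each truth-overlapping predicted
nucleotide to exactly one engine (if predicted by one) or to "shared" (if by
two or more).

The benchmark harness runs every engine alone (unfiltered and filtered),
plus the unfiltered and filtered unions.  When no genome database is given,
a background promoter set of 200 implant-free sequences is generated from
the dataset flavor to serve as the filter background — sized for desk-scale
runs; larger backgrounds sharpen the binomial rate estimate but change
nothing qualitatively.

## Synthetic data

The generator emulates three planted-motif benchmark flavors: `markov`
(order-0 uniform background), `semi_synthetic` (order-3 Markov chain with
add-one smoothing trained on supplied seed sequences), and `real_like`
(50 nt fragments of supplied promoters recombined in random order and
orientation).  Implants are sampled column-wise from the PWM, placed
uniformly without overlap on a uniform strand, at most one per sequence
(ZOOPS; a multi-site mode exists for occurrence-count tests), and recorded
exactly.  Identical seeds give identical datasets.  The default strong
implant is a width-10 PWM with one dominant base per column at probability
0.87 (IC ≈ 12.4 bits).

What the generator does *not* emulate: repeat structure, local GC
heterogeneity beyond order 3, co-occurring motif modules, and positional
preference of real binding sites.  Passing benchmarks on these data
therefore demonstrate algorithmic correctness and the directional value of
filtering and combining — not performance on real promoters.

The toy genome fixture plants one GO term on a designated 10% of genes as an
enrichment positive control; background terms annotate each gene with
probability 0.3.  Background terms are deliberately not sparser: very rare
terms are genuinely enrichable by chance in small gene lists, which would
contaminate the negative control of any implementation.

## Benchmark study conditions used in tests and the acceptance script

Directional replication runs 25 seeded datasets of 10 sequences × 500 nt
with one width-10 implant per sequence, all engines at their defaults, and
asserts: filtered-union nSn ≥ every standalone engine's nSn; filtered-union
nFDR < unfiltered-union nFDR; and a relative nFP reduction exceeding the
relative nTP reduction.  The three-implant complementarity fixture
(20 × 400 nt) carries a diffuse width-10 PWM (dominant 0.8) in every
sequence, an exact 6-mer in every sequence, and an exact 10-mer in only 4 of
20 sequences — below the consensus quorum's reach for PWM engines but a
beacon for exact-count word scoring — so the union of engines recovers all
three implants while no single engine does.  MNCP calibration uses 20
replicates of 10 implanted promoters against 100 background promoters; the
planted motif must exceed 1 in every replicate and a column-shuffled version
must average in [0.8, 1.2].

## Known limitations

* The EM engine fits a single fixed width (default 10) rather than
  optimizing width per motif.
* The consensus engine's candidate restriction at lengths 8 and 10 to
  occurring words means a never-occurring word can in principle outscore all
  occurring ones only through its mismatch neighbourhood; such words are not
  considered (they cannot be planted words).
* The binomial occurrence model treats overlapping windows as independent;
  self-overlapping words (e.g. homopolymer runs) are therefore modestly
  over-scored by the consensus engine.  The filters remove most of them.
* MNCP depends on the random-sample seed; the pipeline records the seed in
  every output and uses one shared sample across motifs so ranks are
  comparable.
* Motif widths are capped at 10 in pipeline use; longer elements appear as
  truncated cores.
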