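# Methods

## Problem and approach

Prokaryotic chromosomes carry oligonucleotide composition biases far beyond
what G+C content alone dictates. `oligosurvey` implements a genome-wide
survey for abundant, overrepresented mid-length words (8–14 bp), the
machinery needed to call a word exceptional under explicit null models, and
the localization analyses that ask whether such words are a coding-sequence
phenomenon (they are not expected to be, for structurally selected words
such as A-tract-like homopurine runs).

The survey has four stages:

1. **Per-chromosome scan.** All overlapping k-mers (k = 8–14, one strand,
   reverse complements kept distinct) are counted; a word qualifies when it
   is frequent — at least `min_cpm` copies per Mb, default 31 — and
   overrepresented under the zero-order model — one-cell Pearson level
   χ² = (C_obs − C_exp)²/C_exp ≥ 100 with C_obs > C_exp.
2. **Cross-taxon selection.** Qualifying word sets from phylogenetically
   distant genomes are intersected (`select_common_oligomers`); words
   surviving the intersection across several such sets are candidates for
   universal enrichment.
3. **Candidate family.** Because the shared words are homopurine /
   homopyrimidine tracts, the exhaustive candidate family is all 512
   octamers over {A,G} plus all over {C,T} (`enumerate_homo_octamers`).
4. **Cohort summary.** Every candidate is re-scored on every chromosome
   under both null models; the summary holds, per word, the number of
   chromosomes where it qualifies (order 0), an order-2 overrepresentation
   index, ranks under both models, and copy-number quantiles.

## Null models and statistics

**Zero order.** C_exp(w) = N·∏_b p_b^(count of b in w), with N the full
chromosome length in nucleotides and p_b the mononucleotide proportions
(computed over unambiguous bases). Using N rather than N−k+1 keeps the
analytic benchmark exact: a random octamer is expected 10⁶/4⁸ ≈ 15.26
times per Mb under equiprobable bases, and the retention threshold is twice
that, rounded up to a whole copy count: 31/Mb. The χ² level is explicitly
*not* a significance test — it is a magnitude-of-departure scale, so no
multiple-testing correction is applied, and calls require the sign of
C_obs − C_exp as well as the level.

**Second order.** The plug-in estimator
Ê(w) = ∏᷈ᵢ N₃(wᵢwᵢ₊₁wᵢ₊₂) / ∏ᵢ N₂(wᵢwᵢ₊₁) (numerator over all k−2
trinucleotide windows, denominator over the k−3 internal dinucleotides)
factors out enrichment inherited from embedded mono- and dinucleotides; it
is exact for trinucleotides. Departure is scored as a Gaussian
z = (C_obs − Ê)/σ̂.

**Variance of z.** σ̂² = Ê·(1 + 2·Σ_p a_p), summing over the word's
self-overlap periods p, where a_p is the probability under the fitted
order-2 chain of re-extending the word by its last p bases. This is the
clump correction: self-overlapping words (A-tracts, period-3 repeats like
GAAGAAGA) occur in overlapping runs, which inflates the count variance
above Poisson. The plug-in estimation covariances are of order Ê²/N₃ —
about 1% of σ² for octamers on a megabase — and are neglected. A pure
Poisson variance (σ̂² = Ê) is available via configuration; both variants
are gated by a calibration test requiring z over random octamers on i.i.d.
megabases to have per-sequence spread in [0.7, 1.3] and replicate-averaged
mean within ±0.15. Exact word-count distributions and full compound-Poisson
clump corrections are out of scope.

**Classification.** Order 0: over/under when χ² ≥ 100 and C_obs is
above/below C_exp; order 2: |z| ≥ 1.96 (two-sided 5%, a configuration knob
recorded in every report header). Degenerate expectations (a base or an
internal dinucleotide absent from the chromosome) yield flagged neutral
calls.

**Index and ranks.** The overrepresentation index is n_over₂ − n_under₂
(default, `index_mode=subtract`); the alternative reading — chromosomes
where the word is over and therefore not under — is `index_mode=exclude`
(n_over₂). Ranks are ordinal, descending on n_over₀ (rank 0) and on the
index (rank 2); ties break lexicographically on the oligomer. Copy-number
quantiles use linear interpolation (numpy default), so reports are
bit-reproducible.

## Counting conventions

Occurrences are counted with overlap, on a single strand, with reverse
complements as distinct words — complement pairs in real genomes differ
slightly through strand biases, and that signal is only visible under
single-strand counting. A `--both-strands` mode is provided: observed
counts sum both strands, the expectation uses N = 2L over the
strand-symmetrized composition, and copies/Mb keeps the chromosome length
L as denominator. Windows containing ambiguity codes are skipped;
`usable_positions` records the effective number of windows, while
copies/Mb deliberately uses total chromosome length. Circularity is
ignored (at most k−1 windows lost per replicon). The scan iterates k
ascending and stops when no word reaches the copy threshold, since a
k-mer's count is bounded by its prefix's count and the threshold is
k-independent.

## Coding localization

An occurrence is coding only when fully contained in a single CDS interval
(a frame is undefined for straddling words); containment in overlapping
genes is resolved to the first CDS in annotation order so totals are
conserved. Frame = ((offset of the word's 5′ end from the translation
start, in coding orientation) mod 3) + 1; on the '−' strand the 5′ end in
coding orientation is the word's last base, measured from the interval
end. This convention is pinned down by a testable property: frame counts
are invariant under reverse-complementing the chromosome and flipping the
annotation strands. Frame uniformity is assessed with a Pearson χ² against
(⅓,⅓,⅓) on 2 df.

## Window profiles

Occurrences are binned into fixed windows (default 50 kb); the clustering
statistic is the variance/mean ratio over full windows. Uniformly spread
occurrences give dispersion ≈ 1 (Poisson); a profile is flagged as
clustered above dispersion 2 — a deliberately simple quantitative proxy
for a visual no-clustering judgement.

## Synthetic data

The generator produces what the analysis assumes: i.i.d. backgrounds with
P(G)=P(C)=gc/2; planted copies of chosen words, Poisson in number at a
rate per Mb, at uniform non-overlapping positions, *overwriting* background
(chromosome length and hence N stay fixed); and non-overlapping gene-like
CDS intervals — exponential lengths (mean 900 bp, a typical prokaryotic
gene) rounded to codon multiples, alternating strands, exponential gaps
balanced to hit a coverage target (default 86%, the typical prokaryotic
coding fraction; ±2% on a megabase). Frame-restricted planting places
words only at positions of a chosen frame within CDS, for frame-bias
positive controls. All randomness flows from one spec-level seed through
`SeedSequence` child streams (background, annotation, one per planted
word), so fixtures are bit-reproducible.

What the generator does *not* emulate: codon usage, repeat families, GC
skew, restriction-site avoidance, or phylogenetic correlation between
chromosomes. Passing recovery tests therefore demonstrates that the
statistics detect planted enrichment against an i.i.d. background at
realistic rates — not that real-genome tallies are reproduced. Cohort
tallies over real RefSeq collections depend on the collection snapshot and
are out of scope.

## Problem sizes and test design

The package's own checks use: a 6 Mb, 50% G+C control chromosome (100
replicates must yield no qualifying word in ≥99%); 20 × 1 Mb cohorts with
a word planted at 60 copies/Mb in 15 chromosomes for recovery (n_over₀
within ±1, rank 1); 1 Mb sequences for null-model agreement (order-2 vs
order-0 octamer expectations within 10%); 300 kb chromosomes × 50 seeds at
200 planted copies/Mb for frame uniformity (no bias at the 5% level in
≥90% of seeds). Planting at 60/Mb on a megabase gives ≈75 observed copies
against ≈15 expected — χ² ≈ 240 — comfortably above both thresholds, while
sub-threshold planting (10/Mb) stays below the 31/Mb retention cut.

## Numerical and degenerate-input choices

Expected-count products are evaluated in double precision (safe through
k = 14 on gigabase inputs). Zero proportions or missing internal
dinucleotides yield expectation 0 and flagged, neutral scores rather than
errors. Dispersion is NaN-flagged with fewer than two full windows or no
occurrences. CDS intervals with non-codon lengths are kept but flagged
with a warning. GFF3 is converted from 1-based inclusive to 0-based
half-open at the boundary; GenBank compound (join) locations are
decomposed into independent parts.

## Known limitations

- The Gaussian variance omits plug-in estimation covariances (≈1% for
  octamers at 1 Mb; grows for shorter chromosomes or longer words).
- Copies/Mb uses total length, so heavily ambiguous sequences understate
  rates; `usable_positions` is reported alongside for correction.
- The cross-taxon selection operates on whatever per-genome sets it is
  given; assembling a phylogenetically balanced cohort is the caller's
  responsibility.
- No wraparound counting on circular replicons.
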