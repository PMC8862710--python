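# Methods

This note documents the models and procedures implemented in `genarch`,
the parameters that matter, what the synthetic-data generator emulates
(and does not), and the design choices made where the design was
genuinely open.

## Coordinate conventions

All in-memory coordinates are 0-based half-open `[start, end)`.  BLAST
tabular and VCF are 1-based inclusive on disk; conversion happens only
in the readers/writers.  Sequences are upper-cased on read; only
maximal runs of `N` define assembly gaps — other IUPAC ambiguity codes
are treated as literal bases, because the gap-flank exclusion rule in
SNP calling refers specifically to assembly gaps.  Window grids tile
each chromosome exactly once; the final partial window is retained and
density metrics are expressed per actual window length, since no
convention for chromosome tails is forced by the analyses themselves.

## Tandem-repeat canonicalization

Tandem-repeat finders report a monomer with arbitrary phase and strand,
splitting one satellite family across many monomer strings and
deflating each string's apparent frequency.  Instead of re-aligning
monomers, we canonicalize: `canonical(m) = min(rot(m), rot(revcomp(m)))`
where `rot` is the lexicographically least cyclic rotation (computed
with Booth's algorithm, O(n)).  Two monomers share a canonical form
exactly when they are phase/strand variants of the same unit, so the
merge is deterministic, idempotent, and conserves total copy number.
An optional approximate mode additionally merges equal-length canonical
forms with normalized edit distance ≤ 0.1 (edlib), absorbing
point-mutated variants; it is off by default because it is no longer
frequency-conserving per family.

Telomere calling merges canonical-family matches (default family
`AAACCCT`, i.e. TTTAGGG) lying within `end_zone` (default 100 kb) of a
terminus and calls the end present when the merged array totals
`min_array_bp` (default 1 kb).  Both defaults are package choices —
long enough to exclude isolated interstitial motifs, short enough to
accept partially assembled telomeres — and are CLI-configurable.

Centromere calling scans, per chromosome, all placements of a
`cluster_window` (default 1 Mb) window over records whose canonical
monomer length is in `{79, 80}` bp, keeping the placement with maximal
contained copy number (records count by their start position; ties go
to the leftmost placement).  Copies outside the chosen window are
reported as scattered, reflecting the empirical pattern that
centromeric satellites also occur dispersed.  The two monomer-length
families can be called jointly (default) or separately via the
`monomer_lengths` argument, since the two families need not coincide
spatially.

`find_exact_tandem_arrays` is an internal stand-in for a repeat finder
on synthetic, mutation-free arrays: maximal runs with `s[i] == s[i+p]`,
smallest explaining period, `N` never matches.  It is not a general
tandem-repeat finder (no mismatches, no indels) and is used only on
perfect arrays and small fixtures.

## Organelle insertions

Hits are filtered per-hit (identity ≥ 95 %, alignment length ≥ 100 bp,
e-value ≤ 1e-10) and then merged into events wherever their nuclear
target intervals overlap or abut within `max_gap` (default 0).
Per-hit filtering with per-event reporting of the maximum member
identity was chosen because a merged event's "identity" is otherwise
ill-defined.  Merging abutting hits prevents one biological insertion
fragmented by the aligner from being double-counted; `max_gap` can be
raised for fragmented alignments.  Window counts are *event* counts,
and an event contributes to every window it overlaps rather than being
assigned by midpoint; a brute-force overlap oracle in the tests pins
this behavior.  Tier columns count events at least as long as the
threshold, so counts are monotonically non-increasing across the tier
ladder {100 bp, 1 kb, 5 kb, 10 kb}.

Anomaly screens, all threshold-parameterized rather than claims:

* **hotspot** — maximal runs of consecutive windows with pooled
  event-coverage fraction ≥ 0.5, reported from 1 Mb span up.  The
  coverage-fraction formulation makes the screen independent of how
  insertions are split into events.
* **tandem_like** — ≥ 3 same-organelle events within a 200 kb
  neighborhood chain whose source spans pairwise reciprocally overlap
  ≥ 0.5 of the shorter span.  Note that a dense integration hotspot
  that re-uses organelle spans (unavoidable for the small chloroplast
  genome) is *also* tandem-like by this definition; the two screens are
  intentionally not mutually exclusive.
* **end_proximal** — a chromosome end with ≥ 1 chloroplast *and* ≥ 1
  mitochondrial event within 500 kb of the terminus.
* **co_localized** — single windows, more than 500 kb from both
  termini, holding at least one event of each organelle.

## SNP classification

The allele-balance rule is implemented on the alternate-allele
*fraction* `alt/(ref+alt)`: heterozygous on [0.25, 0.75),
homozygous-alternate at ≥ 0.75, reference below 0.25, with half-open
boundaries taken literally (0.25 and 0.75 exactly are heterozygous and
homozygous respectively).  A literal alternate-to-reference *ratio*
would classify a perfectly balanced site (ratio 1.0) as homozygous,
which contradicts the rule's purpose; the literal reading stays
available as `ratio_mode="alt_ref"`.  Gates come first: depth < 10
(including 0) is a no-call (`low_depth`), and positions within 3 bp of
an assembly gap are no-calls (`near_gap`).  All non-reference bases are
pooled into the alternate count, as multi-allelic sites are not broken
down further.  Inter-individual homozygous SNPs require the first
individual to be homozygous (reference or alternate) with the second
individual's consensus base differing; the second individual's
consensus is taken as given (its own depth filtering is upstream).

Window profiling counts heterozygous and homozygous SNPs per window
with a genic/intergenic split; "genic" means anywhere within the gene
span (introns included) with half-open containment, and a CDS-only
alternative is available (`genic_mode="cds"`).

### Landscape screens

* **low_het** — windows with het counts at or below the genome-wide
  10 % quantile *and strictly below the genome median* are "low";
  maximal runs ≥ 1 Mb are reported and runs ≥ 5 Mb are flagged
  extended.  The median guard exists because a pure quantile always
  labels 10 % of windows low, so a perfectly flat genome would
  otherwise report its entire length as one low run.  A run whose mean
  hom count is also in the low hom tail is typed `low_both` — the
  signature of the repeat-region anomaly — otherwise `low_het`, which
  on real data typically coincides with *elevated* homozygous
  divergence.
* **decoupled_genic** — windows strictly in the top quartile of total
  het counts but strictly in the bottom quartile of genic het counts
  despite at-or-above-median gene fraction (conserved-gene signature),
  plus the homozygous mirror (diversifying-gene signature).  This is a
  rank screen: even homogeneous stochastic genomes will flag a handful
  of tail windows, so its output is a candidate list, not a call set.
* **repeat_rich / dup_gene_cluster** — repeat-rich regions are runs of
  windows above 70 % repeat coverage, greedily merged across dips while
  the pooled above-threshold window fraction stays ≥ 0.9, reported from
  5 Mb; duplicated-gene clusters come from a sliding 1 Mb window (one
  grid-window step) where the fraction of duplication-flagged genes
  exceeds 0.2, with overlapping placements merged.  The duplication
  flag is consumed from the gene annotation (`duplication=1`), never
  computed.

## Segregation filter and paternity

Step 1 of the four-step filter reassigns heterozygous genotypes with
depth < 20 to homozygous ("set to monomorphic"); reassignment to
missing is available as `low_depth_to="missing"`.  Step 2's denominator
is the non-missing individuals by default, with the absolute-population
reading behind `het_fraction_denominator="all"`.  Step 3 uses the
Pearson statistic `Σ(obs−exp)²/exp` with expectation half the
informative total and no continuity correction, against the printed
critical value 6.635.  That value is the upper 1 % point of χ²(1) —
`scipy.stats.chi2.ppf(0.99, 1)` = 6.635 — although the filter it comes
from describes it as a 90 % confidence bound; the numeric value is
taken as authoritative and the label discrepancy noted here for users.
Step 4 keeps one locus per contig (fewest missing genotypes, ties to
the smallest position — ties are possible and the tie-break is a
package choice).  The filter is idempotent on its retained set and its
per-step counts never increase.

Paternity uses Mendelian exclusion instead of likelihood machinery:
the paternal-allele set at a locus is every offspring allele whose
partner allele could have come from the mother (both alleles when the
mother shares both), and a candidate mismatches the locus when none of
his alleles is in that set.  Mother-offspring incompatible loci are
skipped as genotyping errors rather than paternal evidence.  An
offspring is assigned iff exactly one candidate attains the minimum
mismatch count and that minimum is ≤ `max_mismatch` (default 0); two
candidates at the minimum give `ambiguous`, never an arbitrary pick.
The mother is included among candidates by default (`allow_self`),
covering self-pollination.  Likelihood ratios, simulated confidence
levels and typing-error models of full pedigree software are out of
scope; exclusion with `max_mismatch` ∈ {0, 1} covers the operating
points of interest.

## The synthetic-data generator

The generator's default layout *is* the study condition for all
recovery tests: three chromosomes (16, 16, 10 Mb) of i.i.d. uniform
ACGT background carrying planted telomeric arrays (12 kb of TTTAGGG at
five of the six ends), one 500-copy centromeric cluster per chromosome
(79/80 bp monomers, ~20 scattered copies), organelle insertions at
95–100 % identity in tiered lengths — including an end-proximal cp+mt
pair, a co-localized mid-chromosome window, a three-event tandem-like
cluster re-using one chloroplast span, and a 2 Mb hotspot at 0.55 event
coverage — a 6 Mb heterozygosity desert with elevated homozygous
differences (het 0 vs background 50 per 100 kb window; hom 40 vs 25), a
6 Mb repeat-rich region (75 % coverage with sparse 50 % dips, ~97 % of
windows above threshold) and a 1.5 Mb duplicated-gene cluster (40 %
flagged vs 5 % background).  Depths are Poisson(30) and heterozygous
alternate counts Binomial(depth, 0.5) — the standard sampling model;
a `noiseless` switch fixes depth at 30 with exactly balanced alleles
for exact end-to-end equality tests.  Alignment hits are synthesized
from the planted insertions (the substitution count actually applied
determines the reported identity), so no aligner runs; sub-threshold
noise hits exercise the filters.  TRF-dialect records are emitted with
deliberately rotated/strand-flipped monomers, plus over-long monomers
the parser must drop.

The mapping population plants exact genotype ratios (100:100 for 1:1
loci, 130:70 distorted, 80:120 under-heterozygous across 40 contigs of
3 loci) with depths 20 + Poisson(20); genotyping error and missingness
are configurable and zero by default.  The paternity panel (36 loci, 19
candidates plus the mother, 50 offspring including selfings) emulates
assay markers pre-screened for exclusion power: candidates are
homozygous at the 24 mother-homozygous loci and their allele codes are
redrawn until every candidate pair differs at ≥ 2 such loci, which
guarantees unique exclusion-based assignment at zero error; ~2.5 % of
genotypes are untyped, mirroring realistic typing rates.

What the generator does **not** emulate — and hence what passing
recovery tests do not show about real data: realistic base composition
and repeat landscapes (uniform background maximizes feature contrast),
alignment and mapping artifacts (hits are synthesized, not aligned),
monomer mutation within satellite arrays, linkage between loci,
population structure among candidate fathers, and reference bias in
pileups.  Problem sizes (42 Mb genome, ~30k SNP sites, 200 offspring,
120 loci) were chosen so the full suite and the acceptance script each
run in seconds on one CPU while every detector still faces multi-Mb
features at the thresholds above.

## Numerical and degenerate-input choices

Ties break leftmost/smallest everywhere (centromere windows, step-4
positions, canonical strings sort lexicographically).  Quantiles use
numpy's default linear interpolation.  Chi-square with zero informative
genotypes, empty FASTA files, records before a TRF `Sequence:` header,
unknown chromosomes in window counting, and mismatched summary-table
lengths all raise with the offending item named; an empty region list
still writes a header-only file.  All randomness flows from a single
integer seed through `numpy.random.default_rng`; identical seeds give
byte-identical outputs, and the pipeline embeds a config hash in every
output header so runs are attributable.

## Known limitations

Telomere array length is summed over merged records without clipping
to the end zone; overlapping TRF records of one family could
double-count coverage (the generator never emits overlaps, but real TRF
output can).  The tandem-like screen grows groups greedily from each
seed event, which is not guaranteed maximal for adversarial overlap
structures.  The hotspot screen operates at window resolution, so its
reported boundaries are quantized to the grid.  `find_exact_tandem_arrays`
handles exact arrays only.  The decoupled-window screen is a ranking
aid, not a calibrated test.
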