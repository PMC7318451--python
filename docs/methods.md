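# Methods

## Depth model and CN_index

Read depth is summarised in non-overlapping windows (default 250 bp); a
trailing partial window is averaged over its actual length rather than
padded, so chromosome ends are not artificially depressed. The per-bin
copy-number index is the bin depth divided by the chromosome's mean bin
depth, which makes the signal invariant to library size and to uniform
mapping-rate differences. An optional GC correction rescales each bin by
the ratio of the global median depth to the median of its 1% GC stratum;
strata with fewer than 20 bins are left untouched. It is off by default
because the simulator produces GC-neutral depth; on real libraries it
should be applied before calling.

All coordinates are 0-based half-open internally; 1-based closed
coordinates appear only when parsing `show-coords`-style tables and GFF3.

## Contig depth projection

When depth is measured on de novo contigs, alignment blocks carry it to
the reference. Redundant blocks are resolved first: a block fully
contained in another (on reference coordinates — the natural side for a
reference-projection step) is dropped when its length is less than 0.8 of
the container; partially overlapping blocks are both kept when the overlap
is at least 0.7 of the longer block, and otherwise the shorter is dropped
only when it is under 0.2 of the longer. The keep-both rule at *heavy*
overlap is deliberate and admittedly counter-intuitive (heavier overlap =>
both retained); it is applied as specified and exposed as a parameter. The
sweep runs left to right per chromosome so chains of overlaps resolve
deterministically, and the filter is idempotent.

Projection treats each surviving block as a linear map. A contig base
aligned into k blocks contributes depth/k to each target (equal
subdivision of multiply-aligned sequence), and reference bases accumulate
contributions from all contigs, so total depth mass is conserved for fully
retained contigs. Reference bases with no aligned contig have depth 0,
which downstream appears as deletion-like signal — alignment-block
coverage (`algn_cvrg`) in the filter step is what separates true deletions
from unassembled sequence.

## Calling and boundary extension

Bins with CN_index < 0.5 (deletions) or >= 1.5 (duplications, closed on
the left) seed candidates; maximal same-type runs become intervals.
Boundary refinement absorbs flanking bins one at a time per side while the
*flanking bin's own* CN_index stays beyond a relaxed threshold — 0.75 for
deletions, 1.25 for duplications, i.e. halfway back toward normal copy —
stopping at the first rejection. An interval-mean acceptance rule was
considered and rejected: a run of k near-zero bins keeps its mean under
0.75 while absorbing up to 3k normal bins, so the interval-mean criterion
systematically triples deletion spans; the per-bin rule keeps boundaries
within one bin of the implanted truth in simulation. Extension never
crosses a bin seeded by an opposite-type candidate. Same-type intervals
separated by at most one bin are merged when the merged mean still passes
the *candidate* threshold (candidate-grade signal, not merely
extension-grade). Calls shorter than 1000 bp are discarded. The integer
copy-number estimate is the half-up rounding of the mean CN_index; for
deletions the raw mean is also reported, since the removal bands of the
filter step operate on the depth ratio.

## Evidence filtering

Three profiles mirror the three call sources. Read-depth calls (`rd`) drop
the ambiguous copy-ratio band (0.8, 1.4), then require for deletions
pooled breakpoint support of at least 5 split reads plus discordant pairs
within ±500 bp of the two breakpoints, and coverage and depth>=10 coverage
both at most 50%; duplications require coverage and depth>=10 coverage at
least 80% and at least 50% of bases with CN_index >= 1.4. The
paired-end/split-read profile (`pe_sr_del`) handles deletions only and
additionally requires a depth ratio below 0.5. The contig-projection
profile (`ctgref`) widens the removal band to (0.4, 1.7) and adds
alignment-block coverage: < 50% for deletions, >= 90% for duplications.
Bands are open intervals; breakpoint support is pooled over both
breakpoints rather than required per breakpoint (configurable); a
discordant pair counts when its insert size is within max(100 bp, 10%) of
the interval length — the simulator uses the same convention.

Merging treats two calls as the same SV when they share type and >= 50%
reciprocal overlap (the field-standard criterion; configurable). Records
collapse to the union interval; integration across accessions produces one
row per core CNV with 0/1 presence per accession. Canonical sorting before
the sweep makes the output order-independent.

Weighted accuracy types each locus by its validated copy number — DUP
(CN >= 2), DEL (CN = 0), CN1 — and averages per-type credit: exact match
for DEL/CN1; for DUP, 0 when called CN <= 1, otherwise CN_min/CN_maj of
the called/validated pair (1 when equal). R_w is the type-fraction-weighted
sum.

## Gene annotation and dosage analysis

Transposon genes are excluded up front. A gene takes a CNV's copy number
when same-type calls cover at least half of its gene body (the
largest-overlap call supplies the CN); genes at CN 0 are rescued to 1 when
at least half the gene body has reads and the mean CN_index is >= 0.5 —
zero-copy assignments over well-covered sequence are treated as artifacts.
Missing matrix entries default to CN 1. Genotype encodings are 1 when the
accession carries a duplication (CN >= 2), and separately 1 for deletions
(CN = 0).

The correlation pipeline applies, in order: copy-number change fold
(max/min over *positive* CNs, so all-0/1 genes fall out automatically at
the >= 1.1 cutoff); one-pass per-gene TPM outlier removal at mean ± 3 sd;
removal of copy-number groups with fewer than three accessions; discarding
genes left with exactly two CN types whose smaller type is 0 (those
contrasts confound deletion with absence of expression); and a V_ST cap of
0.4 over user-supplied population labels to avoid correlations driven by
population structure. V_ST = (V_T − V_S)/V_T with sample variances and
size-weighted within-population variance, clamped to [0, 1], defined as 0
when total variance is 0. The coefficient is Pearson's r with its t-test
p-value (the relationship is modelled as a linear trend; Spearman is
available), Benjamini–Hochberg adjusted across all tested genes; classes
are positive/negative at adjusted p < 0.05 by the sign of r. Expression
increase rates use the CN = 1 group as denominator for both statistics:
DupCN1(k) compares the CN = k mean to the CN = 1 mean, and AddCN1(k) is the
increment from CN = k−1 to k on the same denominator (a per-previous-level
denominator is available; the common-denominator form keeps the two
statistics on one scale). Duplicated genes are tandem when any two copies
lie within 25 kb on one chromosome (configurable).

## Ka/Ks, ages, and fates

Ka/Ks is the unweighted Nei–Gojobori method: per-codon synonymous site
fractions from single-nucleotide change enumeration (changes to stop
codons count as nonsynonymous sites), site counts averaged over the two
sequences, observed differences averaged with equal weight over all
minimal substitution pathways between differing codons, pathways through
stop codons excluded (with a fall-back to all pathways when every one is
blocked), and Jukes–Cantor correction d = −(3/4)ln(1 − (4/3)p) applied to
both proportions. Proportions at or beyond 3/4 raise a saturation error
rather than returning a number. yn00-style codon-frequency weighting is
deliberately not replicated; the implementation is checked against an
independent exact-arithmetic enumeration oracle to 1e-9. CDSs shorter than
150 bp are rejected.

Divergence time is T = Ks/2μ with μ = 6.5x10⁻⁹ synonymous
substitutions/site/year (grass Adh calibration). Stages: I is Ks = 0
exactly ("recent"); II–V cover (0, 0.0072], (0.0072, 0.0313],
(0.0313, 0.0879], (0.0879, 0.195]; VI is Ks > 0.195 — half-open on the
left so each boundary value belongs to the younger stage.

Fate classification: any pseudogene flag gives Gene-Ψ (one copy) or Ψ-Ψ
(both). Otherwise each copy's protein-domain *multiset* is compared with
its reference counterpart: a domain absent from the reference or a larger
multiset is neofunctionalization; a smaller one subfunctionalization;
equality is recorded as undifferentiated, with the caveat that identical
domain content cannot distinguish true non-differentiation from
regulatory divergence — per-copy outcomes are preserved in
`DuplicatePair.copy_fates` so the indeterminacy stays visible. A pair with
one Neo and one Sub copy is labelled Neo by default (configurable). The
per-stage table reports differentiated-pair rates and the Neo share among
differentiated pairs as percentages rounded to two decimals; a stage with
zero differentiated pairs reports a Neo share of 0.00.

Parent/offspring assignment uses flanking-gene collinearity: a copy is in
the ancestral block when at least two of the four flanking reference genes
co-assemble with it in more than 10 accessions; exactly one qualifying
copy is the parent, and ties, no-support cases and tandem pairs are
indistinguishable. Copy-specific expression uses mismatch columns of a
global pairwise CDS alignment as diagnostic sites; reads are assigned by
exact substring match to exactly one copy, reads matching both copies are
uninformative, and reads matching neither (conflicting alleles or errors)
are discarded. The higher-count copy is the major copy (ties have none),
and dominance requires strictly more than twice the minor count.

## Synthetic data

The simulator generates what the pipeline consumes, not reads: depth is
drawn per bin as Poisson(mean_depth x CN x bin_size)/bin_size, which
reproduces the mean/variance structure of binned mapped depth at a
fraction of the cost and keeps the test suite seconds-fast. Deletions are
implanted homozygous (CN 0), duplications at CN >= 2, tandem copies
adjacent to the source and dispersed copies at distant loci; implants
stay >= 2 kb from chromosome ends and >= 2 bins apart so boundary tests
are unambiguous. Breakpoint evidence is simulated as counts (>= 5 split
reads per deletion breakpoint, discordant pairs for deletions only),
because the filter rules operate on counts. TPM matrices follow
TPM = max(0, baseline + slope x CN + N(0, sd)) per gene. CDS pairs are
mutated with exactly the requested numbers of synonymous and
nonsynonymous single-nucleotide substitutions, each in a distinct codon
and verified against the codon table, so downstream Ka/Ks has a known
generating process.

What the simulator does *not* model: GC bias (the GC-correction test
injects a known bias vector instead), mapping ambiguity and repeat
mismapping, heterozygous CNVs, insert-size distributions, sequencing
error, and read-level alignment. Recovery results on this synthetic data
therefore demonstrate correctness of the algorithms under their own
assumptions — clean Poisson depth with exact breakpoints — not calling
performance on real libraries, where boundary noise and mapping artifacts
dominate.

## Problem sizes and determinism

Default test and acceptance runs use 20 simulated samples of a 300 kb
single-chromosome genome with 8 implants of 2–10 kb at 50x (caller
recovery), 200 random CDS pairs of 60–200 codons (Ka/Ks oracle
equivalence), and a 200-gene x 93-accession dosage matrix with 30%
positive, 10% negative and 60% null genes at slope ±10 TPM/copy and noise
sd 2 — sizes at which every stochastic check is stable across seeds while
the whole suite runs in seconds. All randomness flows through
`numpy.random.default_rng` with explicit seeds; fixed seeds give
byte-identical outputs.

## Known limitations

- The caller assumes diploid-normalised depth; aneuploidy or whole-arm
  events would shift the chromosome mean and bias CN_index.
- Deletion copy-number estimates are depth ratios, not genotypes; the
  pipeline does not distinguish heterozygous from homozygous loss.
- The projection step's equal subdivision of multiply-aligned contigs is
  unbiased only when true copies are equally covered.
- Ka/Ks equivalence with PAML's yn00 is not asserted; the implementation
  is classic Nei–Gojobori.
- Native caller output formats (CNVnator/Delly) are not parsed; calls
  enter through the BED-like TSV contract.
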