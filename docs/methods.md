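# Methods

This note documents the models behind `promoterpop`, the defaults that
matter, what the synthetic-data generator does and does not emulate, and the
design choices made where the design was genuinely open.

## The quantities

**Promoter types.** A haplotype's promoter type is the ordered allele
triplet at rs3759916/rs3759915/rs3759914. TGT is ancestral; TCT, CGT and CGC
are derived; any other combination, or any missing call, is OTHER. Relative
promoter activities (dimensionless, CGC-referenced) default to TGT 3.6,
CGT 2.9, TCT 2.1, CGC 1.0.

**PPA.** Individual promoter activity is the mean of the two allelic
activities, (a₁+a₂)/2; population promoter activity (PPA) is the population
mean of individual activities. Because every allele appears in exactly one
individual, PPA over any pairing of a fixed allele pool equals the
allele-frequency-weighted mean activity Σfᵢaᵢ — so the random-mating PPA is
computed directly from frequencies. Individuals carrying an unscored (OTHER)
type are excluded and counted; the observed rare-type share is ~0.6% so the
exclusion is negligible at population scale.

**Credible bound.** Observing n alleles of one type and m alternatives
gives, under a uniform prior, the posterior Beta(n+1, m+1); the one-sided
lower bound f₀ solves P(f > f₀) = level. With m = 0 this reduces to
f₀ = (1−level)^(1/(n+1)); eight CGT alleles and level 0.95 give 71.7%.

**Distances.** Site-difference matrices count raw mismatches with missing
sites deleted pairwise. Jukes–Cantor correction −(3/4)·ln(1−4p/3) is applied
only for display trees; the screen uses raw counts, as the matrices it
thresholds are integer difference ranges. Diploid–diploid (or
haploid–diploid) distance scores each site by the better of the two allele
pairings: a homozygous mismatch contributes 1, a heterozygous one 1/2.

**Tract statistics.** The probability that a tract of m bp descends
unrecombined through t years is exp(−m·r·t/g) with r the local
recombination rate per bp per generation and g the generation time; small
values reject an incomplete-lineage-sorting origin of a long shared tract.
Identical-tract scans measure bp spans between flanking mismatches
(exclusive); missing sites never terminate a run. Homozygosity tract
lengths (HTLs) are measured pairwise among carriers outward from a core
interval, and convert to an age as t = g/(k·r·mean HTL) with k = 1
(one-sided) or k = 2 (two-sided); both constants are exposed because the
published constant for this estimator cannot be reverse-engineered
unambiguously, and HTL ages are therefore reported as indicative only (see
Limitations).

**Clade ages.** On a star genealogy with n branches of length t over L bp,
the within-clade mutation count is S ~ Poisson(n·L·μ·t), giving
t̂ = S/(n·L·μ) with 95% CI t̂·(1 ± 1.96/√S) truncated at zero (exact Poisson
upper bound when S = 0). The normal-approximation interval has ~94% true
coverage at the mutation-count scale of these data (verified exactly from
the Poisson pmf in the acceptance suite).

## Archaic reconstruction and the five-step screen

Archaic diploids arrive unphased with missing (N) calls. One individual is
fully homozygous over the region; phasing assigns, at every heterozygous
site of another individual, the reference-matching allele to haplotype
"-2" and the other to "-1", so all "-2" haplotypes share the reference
haplotype. Sites where the reference is missing remain unresolved (N).

The screen takes a region panel, its archaic diploids and a variant-age
table, and proceeds:

1. The modern–archaic site-difference range is measured between African
   haplotype groups of the focal type and the phased archaic haplotypes,
   after excluding archaic recombinants (flagged automatically by mosaic
   segmentation against modern type representatives and the archaic
   consensus). Distances are computed over *archaic-informative* sites:
   the MAF filter alone would drop modern/archaic fixed differences (they
   are monomorphic among moderns), which would collapse the range.
2. Groups showing at least one pairwise difference inside the range are
   selected.
3. An NJ tree of the selected groups is built and its two-cluster partition
   (the bipartition of the longest internal edge) recorded for audit.
4. Groups present in ≥ 2 African subpopulations (configurable) are
   rejected, together with relatives at fewer than min(range) differences.
5. Remaining candidates are checked against the variant-age table: the
   median age of variants shared only by the candidates (or, failing that,
   private to each candidate) must fall inside the introgression window,
   default 30–80 kyr — a bracket around the ages estimated for the variants
   shared between archaic genomes and the introgressed modern haplotypes
   (63–82 kyr). Candidates with no age information are flagged
   `age-unknown` and kept, never silently rejected.

## Evolutionary constants

| parameter | default | meaning |
|---|---|---|
| r | 3.3×10⁻⁸ /bp/gen (3.3 cM/Mb) | local recombination rate of the region |
| μ | 0.5×10⁻⁹ /site/yr | mutation rate |
| g | 29 yr | generation time |
| modern–archaic split | 550–765 kyr | bracketing divergence times |
| Neanderthal–Denisovan split | 450 kyr | |
| introgression time | 50 kyr | |

## The synthetic-data generator

The generator emulates the *structure* of the study inputs, not their
demography. A 40-kb window holds an 18-kb hotspot-flanked core with the
three promoter SNPs at its centre. Within each promoter type, haplotype
diversity is a star genealogy over discrete **lineages** (depth 200 kyr by
default, type templates splitting at 300 kyr); copies of a lineage are
identical, which reproduces the haplotype-group structure (many identical
sequences shared across subpopulations) that the enumeration, the
African-widespread test and the group naming all rely on. Per-population
type frequencies default to the observed five-meta-population compositions;
lineage popularity per meta-population is Dirichlet-distributed, and a small
template-crossover rate (0.03/copy) introduces occasional recombinants.

The donor lineage branches from the focal type's template with a trunk of
2·t_split − t_introgression − t_lineage years so that the expected
modern–donor divergence equals 2·t_split·μ·L, matching the
expected-pairwise-differences formula the analyses use. Archaic haplotypes
are donor-lineage draws with short private branches (20 kyr); one individual
is forced fully homozygous, one Denisovan haplotype is optionally a
TGT–CGT–TGT mosaic, and sites are N-masked at 2% per individual.
Introgression draws a Binomial number of recipient haplotypes (default
frequency 0.1 in South Asia — at the scaled-down sample size of ~120
haplotypes this plants ~12 carriers, matching the order of the 11
introgressed sequences observed in the real South-Asian sample) and gives
each a donor tract of total length Exponential(g/(r·t_introgression)),
centred on the promoter SNPs and clipped to the window.

Variant ages emulate a genealogy-based dating resource built from modern
genomes: a variant delivered by introgression coalesces within moderns at
the introgression event, so its *estimated* age clusters near
t_introgression (lognormal noise, σ = 0.2) regardless of its older true
mutation time on the donor branch; all other variants are dated near their
true mutation times. Variants never observed in moderns are absent from the
table, as they are from the real resource.

What the generator does **not** emulate: coalescent genealogies (star trees
match the estimators' assumptions and keep oracles closed-form), realistic
site-frequency spectra, linkage disequilibrium decay within lineages,
sequencing error, or archaic sample ages. Passing tests therefore
demonstrate correctness of the statistics and the screen's logic under the
stated model, not robustness to demographic misspecification.

## Problem sizes

Default synthetic panels use 332 diploid individuals (664 haplotypes, ~200
segregating sites) across 26 subpopulations — about an eighth of the real
panel — which keeps a full pipeline run under a second and the planted-truth
acceptance battery (20 positive + 20 negative seeded screens) under ten
seconds, while leaving every frequency estimate enough counts to be stable.
Monte-Carlo oracles use 10⁵ replicates; estimator recovery uses 2000
replicates to pin coverage estimates to ~0.5% error.

## Numerical choices and tie-breaks

- NJ ties in the Q criterion break on the lexicographically smallest pair of
  cluster labels (a cluster is labelled by its smallest leaf); negative
  branch lengths are clamped to zero with the deficit logged. skbio's NJ is
  the independent cross-check, never the implementation.
- MAF filtering keeps sites with MAF ≥ threshold, computed over all
  populations pooled, missing calls excluded; a `keep_positions` escape
  retains archaic-informative sites.
- Bootstrap resamples site columns of the filtered set with replacement;
  support is attached only to bipartitions of the point-estimate tree.
- The fold-difference envelope is a *population* interval (mean ± z·sd, z =
  2.576 at 99%), not a standard-error interval — that is what reproduces the
  printed envelope width from its mean; normality is checked with a
  one-sample KS test and failures flag the result rather than abort.
- Ancestral-frequency inference uses the multiplicative convention
  (focal frequency × median fold), capped at 1 and labelled approximate.
- Composition enumeration sweeps f_CGT from the credible bound to 1 and the
  TGT/TCT split at the same step (default 0.001), with f_TGT ≥ f_TCT; the
  extremes provably sit on the grid boundary (minimum at an even TGT/TCT
  split because a_TGT > a_CGT > a_TCT; maximum at f_TCT = 0).

## Limitations

- HTL-based ages are biased upward under the exponential tract-erosion
  model: the pairwise-minimum of two exponential tract lengths halves the
  mean, so the printed HTL age can exceed the true event time severalfold.
  The pipeline reports it for continuity but dates clades with the
  Poisson-ML estimator, whose calibration is verified by parameter
  recovery.
- The screen presumes the focal promoter type segregates in Africa (step 1
  anchors on African groups) and that introgressed tracts still span most
  of the core region; heavily eroded tracts are missed by design.
- The diploid distance takes the per-site best pairing, a lower bound on
  any globally consistent phasing; over the short region considered the
  two coincide in practice.
- Exact Fisher tests are used for proportion comparisons; at the largest
  panel counts a chi-square would be indistinguishable and faster, but
  exactness matters for the small haplotype-group counts.
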