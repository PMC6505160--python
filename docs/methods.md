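# Methods

## Data model and conventions

The central object is a dosage matrix: accessions × biallelic SNPs with
entries 0/1/2 (count of the alternate allele) and a dedicated missing
sentinel that is never conflated with dosage 0 (per-accession missing
proportions are themselves a reported quantity).  Coordinates are
1-based inclusive everywhere (VCF/GFF convention); BED input is
converted on read (`start+1`, `end`) and cut sites are written back to
BED as 0-based half-open.  Genotypes are treated as unphased throughout:
phase separators in VCF are read and discarded, because every statistic
here is defined on dosages and two-locus r² is estimated by EM.  Alleles
are stored as given, with no strand normalisation — a single reference
genome is assumed, with no cross-platform merging.

## In-silico RAD design

Digestion scans each upper-cased sequence for the restriction motif on
the forward strand; ambiguity codes never match, and overlapping
occurrences are all reported.  For palindromic motifs (PstI's `CTGCAG`
equals its own reverse complement) the forward scan finds every site;
this is asserted as a property test.  The site anchor is the first motif
base, not the staggered cut position — the 5-bp offset is immaterial at
the kb scales of every downstream use, and it keeps the local-LD
x-coordinate ("the left cut site") unambiguous.

A *sequencing unit* is the region a single-end read library captures
around a cut site.  With the default `read_span = 93` bp per side
(100-bp reads minus ~7 bp of barcode/overhang) a unit spans 186 bp
(end − start), matching the library design this models.  Each SNP is
assigned to the nearest cut site whose candidate interval contains it,
with distance ties resolved to the left (lower-position) site; only
sites with ≥ 1 assigned SNP become units, and SNPs inside no interval
stay unit-less (they are retained by all filters and flagged in
reports).  Read depth is unavailable without raw reads, so "deeply
sequenced" regions are proxied by units containing retained SNPs when no
depth input exists.

Site classification is interval membership of the anchor base in the
merged heterochromatin track; chromosomes absent from the track (e.g.
an unanchored pseudo-chromosome with no genetic-map assignment) default
to euchromatin with a logged warning.  In the overlap report a gene
counts as "sequenced" if it intersects ≥ 1 unit by ≥ 1 bp — no
minimum-overlap rule is imposed because none is defined for this design.

## Marker filtering

Stage order is fixed and logged: presence filter, then MAF, then
redundancy pruning, so surviving counts per stage can be audited on real
data.  Defaults: presence in ≥ 75/99 of accessions (the original filter
counted "populations", but each accession was its own population in
that design, so the semantics generalise exactly to a presence
fraction), and MAF ≥ 0.05.  The boundary keeps MAF = 0.05: the
operative phrasing of the rule is that markers *below* 0.05 are
excluded; the threshold is configurable.

Redundancy pruning scans each unit's SNPs in ascending position and
drops a SNP iff its r² equals 1 (tolerance 1e−9) against **any
already-retained** SNP of the same unit — greedy, so the first SNP of a
unit is never removed.  With missing data, r² on pairwise-complete
observations is not transitive, which is why the comparison set is the
retained SNPs rather than all predecessors.  SNPs in different units are
never compared; unit-less SNPs are kept.

## Diversity

Per-locus Ho is the fraction of heterozygotes among called individuals;
a population's Ho is the mean over loci with ≥ 1 call.  Hs uses the
Nei–Chesser unbiased estimator
`Hs_l = n/(n−1) · (1 − p² − (1−p)² − Ho_l/(2n))`, skipping loci with
n < 2 in that population.  The pooled row of the diversity table is
reported both ways — the whole collection as one population ("Total")
and the average of per-population values ("Mean over pops") — because
either convention is defensible for a pooled summary and they diverge
under structure.

## Weir–Cockerham Fst

Per-locus variance components for r populations follow the standard
a/b/c decomposition (among populations, among individuals within, and
within individuals), and θ is the **ratio of sums** over loci, not the
average of per-locus ratios.  Loci where any population has zero calls,
or where n̄ ≤ 1 or n_c = 0, are excluded from both sums; a zero
denominator (no variation anywhere) yields an explicitly undefined θ.
A percentile CI over a locus bootstrap (default 1,000 draws, seeded) is
available.  Note the estimator's known small-sample behaviour: on data
with no true differentiation it is slightly *negative* (with s² = 0 the
a-component reduces to −(p̄(1−p̄) − h̄/4)/(n̄−1) < 0), shrinking toward
zero as samples grow; the tests assert this behaviour rather than an
exact zero.

## AMOVA

One level (among/within populations), on squared Euclidean distances
between dosage vectors scaled for missingness:
`δ²_ij = Σ_l (d_il − d_jl)² · L / L_ij` over loci called in both
individuals (L total loci, L_ij shared).  SSD(total) is the sum of
pairwise δ² over all pairs divided by N; SSD(within) sums the analogous
per-group quantities; SSD(among) is the difference (additivity is
asserted to 1e−8 relative).  Variance components use
`n0 = (N − Σn_k²/N)/(K−1)`; Φ_ST = σ²_a/(σ²_a+σ²_w).  Significance
permutes individuals among groups with sizes fixed and applies the
add-one rule `p = (1 + #{Φ_perm ≥ Φ_obs})/(1 + n_perm)` so p is never
zero.  The reference analysis for this statistic does not print its
distance convention, so numeric parity with a published percentage is a
tolerance comparison, not a bit-exact one; single-individual groups are
allowed but flagged.

## PCA, geographic distance and IBD

PCA mean-imputes missing dosages per marker, centres columns (no
variance scaling — common for dosage data, and it keeps percent-variance
interpretable), and takes the SVD; percent variance per component is the
squared singular value over the total.  Geographic distances are
haversine great circles (Earth radius 6,371 km).  The Mantel statistic
is the Pearson correlation of strictly-lower-triangle distance vectors;
p permutes the accession order of the genetic matrix, one-sided upper,
add-one rule.  The default genetic distance is 1 − allele-sharing
(mean |d_i − d_j|/2 over shared loci), but any square symmetric matrix
is accepted since the upstream choice of metric varies between studies.

## Linkage disequilibrium

Haplotype frequencies for a locus pair come from an EM over the 3×3
joint genotype table on pairwise-complete individuals: all genotype
classes except the double heterozygote determine their two haplotypes;
the double-het count is split between coupling and repulsion phase by
the E-step odds `pAB·pab / (pAB·pab + pAb·paB)` (a degenerate 0/0 splits
equally), and iteration stops at max |Δfreq| < 1e−10 or 1,000 rounds.
Because the observed-data likelihood can be bimodal in the coupling
frequency, the EM runs from three starts — linkage equilibrium and the
two phase extremes — and keeps the highest-likelihood solution; a
no-double-het table shortcuts to the closed-form counts.  Within each
run the observed-data log-likelihood is non-decreasing (asserted as a
property).  Then `r² = D²/(pA(1−pA)pB(1−pB))` with `D = pAB − pA·pB`,
clipped to [0,1]; pairs monomorphic in the complete subset are
undefined and skipped (and counted).  A composite-LD alternative
(squared dosage correlation, no phase model) is available behind a
flag but is not the default.

Windowed LD takes every intra-chromosome pair with 0 < distance ≤ 1 Mb.
The decay fit minimises squared residuals of the Hill–Weir drift
expectation in the single parameter ρ (C = ρ·d), after a coarse log-grid
scan to avoid the flat shoulders of the SSE surface; `n` in the
expectation is fixed **before** fitting at twice the median
pairwise-complete individual count (chromosomes sampled), keeping the
fit one-parameter and reproducible since the upstream convention is not
printed.  Fitting defaults to raw pairs; per-bin mean fitting is
available for plotting parity.  The decay distance solves
E(r²)(d) = baseline (default 0.1) by bisection to 1 bp over
[1, 10·max distance]; a curve already at or below baseline at d = 0
reports 0, and a curve that never reaches it reports "not reached"
rather than an extrapolated number.  Useful analytic anchors, asserted
in tests: E(r²) at C = 0 is (10/22)(1 + 36/(22n)) → 5/11 as n → ∞, and
the large-distance asymptote is 1/n.

The local profile averages all defined r² between SNPs of each pair of
consecutive sequencing units on a chromosome, keyed to the left unit's
cut position, and tallies means ≥ baseline vs < baseline per chromosome
and overall; unit pairs with no defined r² are excluded from the tallies
and logged.

## Synthetic data

The generators define the conditions every statistical test runs under;
all take a mandatory seed and are fully deterministic.

*Structured genotypes* follow Balding–Nichols: ancestral frequency
p_l ~ U(0.05, 0.95); population frequency Beta(p_l(1−F)/F,
(1−p_l)(1−F)/F) so that F is the expected Fst (F < 1e−12 collapses to
exact panmixia — the Beta shapes overflow and the limit is exact);
individual ancestry is one-hot per home population by default or
Dirichlet(α) when admixture is requested; genotypes are
Binomial(2, Σ_k q_ik p_kl); missingness is an independent Bernoulli mask
(default 6%, matching a typical few-percent call-failure rate).  Default
scale is 3 populations × 33 accessions ≈ the ~99-accession collection
this package emulates, at 2,000 loci — enough for stable estimates at
desk runtimes.  This closed-form model was chosen over coalescent
simulation precisely because its truth (F) is analytic, enabling
estimator-recovery acceptance tests (K = 2, F = 0.15, 50/population,
1,000 loci: mean θ over 50 replicates within ±0.02).

*LD genotypes* are founder mosaics: M founder haplotypes drawn site-wise
from the population frequencies; each gamete copies a founder and
switches to a random founder between adjacent markers with probability
1 − exp(−c·spacing); two gametes per individual.  LD decays with
distance because founder identity persists locally; the background level
is set by the finite pool (~1/M under tight linkage, falling to
sampling noise ~1/n under complete switching).  The model is
phenomenological — the fitted Hill–Weir ρ is not analytically tied to
c — so LD acceptance is based on monotonicity (decay distance shrinks as
c grows; binned mean r² decreases with distance) and on recovery of ρ
from curve-sampled data, not on equality to c.

*The toy genome* plants motif copies into random ACGT background (ground
truth re-derived by an independent scan of the final sequence, so chance
background occurrences are included), puts a central heterochromatin
block over 30% of each chromosome, and places genes with a 4:1
euchromatin:heterochromatin density ratio — a cartoon of gene-rich arms
and gene-poor pericentromeres.  *Coordinates* put population centroids
on a north–south transect with Gaussian individual jitter, so isolation
by distance holds by construction.

What passing on these generators does **not** show about real data: no
LD within the structured generator (loci are conditionally independent),
no selfing/inbreeding (genotypes are HWE within populations, so the
strongly selfing collections this mirrors will show far lower Ho than
the simulator), no allele-frequency spectrum realism, no depth-driven
genotyping error, and no correlation between missingness and genotype.

## Problem sizes and reproducibility

Test and acceptance runs use desk-scale problems chosen as the package's
own defaults: hundreds of loci and tens of accessions for exactness
checks, 1,000–2,000 loci × 100–200 accessions × 50 replicates for the
recovery studies, ~150-site toy genomes for the design stages.  Every
stochastic routine takes an explicit seed (defaults: 999 permutations,
1,000 bootstraps); pipeline reruns with the same inputs and seed are
byte-identical, which is asserted in the tests.

## Known limitations

- One stratification level in AMOVA (no region/population nesting).
- Ancestry fractions are consumed, never estimated (no admixture-model
  fitting or cross-validation).
- r² assumes biallelic SNPs; no D′, no phased-haplotype LD.
- The EM multi-start makes the global optimum overwhelmingly likely but
  is not a certificate of global optimality.
- Percentage reporting rounds half-up to 2 decimals to match printed
  tables; downstream arithmetic should use the integer counts, which
  every report writes alongside the percentages.
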