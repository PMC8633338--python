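# Methods

`mhscreen` implements two workflows around rare variants in the malignant-
hyperthermia (MH) susceptibility genes *RYR1* and *CACNA1S*: a population
screen for actionable (pathogenic / likely pathogenic) variants, and a
family analysis that determines whether a variant arose de novo as a
somatic + germline mosaic and in whom.  This note records the models, the
parameters that matter, the synthetic-data design and the numerical
choices, as the package's own account of its science.

## Population screen

The screen consumes a multi-sample VCF (GT per sample), gene regions and
externally produced consequence annotations; alignment, calling and
consequence prediction are explicitly upstream.  Per alternate allele it
computes

* allele count `AC` (alt alleles among called genotypes), allele number
  `AN` (called alleles only — missing genotypes shrink the denominator,
  standard VCF semantics),
* minor allele frequency `MAF = min(AC, AN − AC) / AN`,
* the carrier set (individuals with ≥ 1 alt allele, matching
  autosomal-dominant actionability reporting).

Multiallelic sites are decomposed into biallelic records; ref/alt pairs
are reduced to minimal representation (shared suffix then prefix trimmed,
one anchor base kept) so joins with classification tables are
deterministic without a reference sequence.  Chromosome names are
normalised to the `chr` prefix.

The rare-variant filter keeps records with `MAF < threshold` (strict
inequality; default 0.1%) and a protein-altering or splice-disrupting
consequence (everything except `synonymous`/`other` by default).

Carrier frequency for a variant set is `|union of carrier sets| / N`;
an individual carrying two actionable variants counts once.  Reports
render the frequency to two significant figures as a percentage and the
reciprocal ("1 in N") rounded to the nearest 10 — e.g. 43 carriers among
62,240 genomes prints as 0.069% and "1 in 1450".

## Actionability aggregation

ClinVar-style submission tallies per variant (`pathogenic`,
`likely_pathogenic`, `drug_response_pathogenic`, `uncertain`,
`likely_benign`, `benign`) collapse into a verdict
(`actionable` / `conflicting_excluded` / `not_actionable`) under one of
two conflict rules:

* **majority** (default): actionable iff the pathogenic-side tally is
  ≥ 1 and strictly exceeds the benign-side tally; a tie or benign excess
  with pathogenic support is a conflict.  Uncertain-significance
  submissions are neutral.  This keeps a 10-vs-1
  pathogenic/likely-benign variant actionable, which is how published
  actionable sets in this domain behave in practice.
* **strict**: any benign-side or uncertain submission alongside
  pathogenic support is a conflict.  The strict actionable set is
  provably a subset of the majority set.

`drug_response_pathogenic` counts pathogenic-side: in the MH context
these submissions flag diagnostic anaesthesia-risk variants.
Imputation-derived carriers can be added to a sequencing-based report via
a dosage threshold (default 0.9, configurable), recomputing the frequency
against the extended cohort size.

## Allelic balance and mosaicism

A constitutional heterozygote yields alternate-read fractions around 0.5;
an individual carrying the variant in a fraction *m* of cells (mosaic)
yields an expected fraction *m*/2.  For observed depths (ref, alt) the
package computes the allelic ratio `alt/(ref+alt)` (full precision
internally, two decimals in reports) and an exact two-sided binomial test
against 0.5 by the minimum-likelihood method — the sum of Pr(x | n, 0.5)
over all outcomes no more probable than the observed one.  Depths at a
single site are small (tens of reads), so no normal approximation is
used.  The implementation delegates to `scipy.stats.binomtest`; the test
suite checks it against an independent exact-fraction enumeration oracle
for every (k, n) with n ≤ 60 at 1e-12.

Carrier states are called with four thresholds (defaults in
parentheses): `alpha` (0.01) significance of the balance test, `min_alt`
(3 reads) to consider the variant observed at all, `min_depth` (10) below
which the state is indeterminate, and `mosaic_ratio_max` (0.35) so that
only a significantly *low* ratio is labelled `mosaic_candidate`;
significant deviations towards the alternate allele are left
indeterminate rather than over-interpreted.  A genotype called
heterozygous with zero alternate reads is flagged as conflicting input.

At 30× depth these defaults give a false mosaic-candidate rate of about
0.3% on true heterozygotes and a detection rate of about 0.68 for
*m* = 0.4 mosaics (expected read fraction 0.2) — single-site mosaic
detection at standard WGS depth is power-limited, which matters for the
origin benchmark below.

## Haplotype tracing and origin inference

Inputs are phased haplotypes with parent-of-origin labels over a marker
map that includes the focal variant site (population-scale long-range
phasing is an input contract, not reimplemented).  Coordinates are
1-based inclusive; BED export converts.

* **Shared segment.** Starting at the focal marker, the segment extends
  outward while every carrier's variant-bearing haplotype agrees.
  Missing alleles are wildcards, but more than `max_missing_run` (10)
  consecutive uninformative comparisons stop the extension at the last
  informative marker, so matching cannot coast through no-call deserts.
  A single carrier's segment spans the whole map.  Every reported
  segment passes an independent agreement re-check, and extension by one
  marker past either bound breaks agreement unless the map ends.
* **Transmission tracing.** Each member haplotype's parental-origin
  label identifies the transmitting parent; member-to-member edges form
  the transmission chain, whose unique root is the topmost carrier.
  Equally senior members (e.g. sibling carriers without their parent)
  leave the topmost undetermined — never guessed.
* **Discordant sharers.** Non-carrier relatives with a haplotype
  matching the segment consensus at every informative marker except the
  focal site itself.  Such a relative proves the haplotype background
  predates the variant.
* **Origin inference**, rules in order for topmost carrier T:
  1. T mosaic candidate + a discordant sharer on T's variant-haplotype
     lineage → de novo germline + somatic mosaic in T;
  2. T heterozygous + any discordant sharer → constitutional de novo in T;
  3. T heterozygous, no discordant sharer, T's parents untyped →
     inherited or arising at/above T, unresolved;
  4. otherwise ambiguous.  The evidence list records every rule
     evaluated; the inference is deterministic and invariant to member
     ordering.

## Synthetic data

The generator produces everything the pipeline reads, plus a ground-truth
ledger (a separate artifact — generated files never contain the truth).
Key design choices:

* **Marker panel**: `n_markers` (200) evenly spaced positions over a
  59 Mb chromosome with the focal site (38,496,455) inserted; founder
  marker alleles are drawn at frequency 0.5 (maximally informative
  biallelic markers, as on an ascertained genotyping array).  The focal
  site is the rare variant itself and stays at the reference allele in
  all founders until a mutation is planted.
* **Transmission**: crossovers per meiosis are Poisson(`recomb_rate`,
  default 1.0 per chromosome — the human genome-wide per-chromosome
  scale) with uniform positions and no interference; every meiosis'
  breakpoints are recorded in the ledger.
* **Mutation planting**: the variant goes on one named haplotype of the
  origin; descendants who (per the ledger) inherited that haplotype at
  the focal position carry it — with probability
  `germline_transmission_fraction` (0.5) per transmission out of a
  mosaic origin, probability 1 otherwise.  Inheritors of the background
  without the variant are recorded as background sharers (the discordant
  sharers the tracing must find).
* **Reads**: depth ~ Poisson(`depth_mean`, 30 — standard WGS target
  depth); alternate reads ~ Binomial(depth, q) with q = `error_rate`
  (0.002), 0.5, or m/2 for non-carriers, heterozygotes and mosaics.
  `mosaic_cell_fraction` defaults to 0.4, the regime of the index case
  (observed ratio ≈ 0.2).
* **Cohort**: planted variants in the two gene regions with carrier sets
  drawn directly (mostly below the MAF threshold, 15% common to exercise
  the filter), genotype missingness (0.2%) on non-carriers only so
  carrier truth stays exact, and classification profiles cycled from a
  mix that includes the canonical conflict cases ({P:10, LB:1} and
  {P:1, B:1}).  A fixed seed yields byte-identical files; each operation
  draws from its own seed-plus-tag random stream.
* **Index-family fixture**: a deterministic 16-member pedigree matching
  the index family's carrier topology (mosaic grandmother II-5; carriers
  III-5, IV-1, IV-4; sister II-2 sharing the grandmaternal background
  without the variant; generation I untyped).  Transmissions are fixed
  and recombination-free, observed depths are the reported ones (18/19,
  22/6, ...), so the whole family analysis is reproducible to the digit.

What the generator does **not** emulate: linkage disequilibrium and
realistic allele-frequency spectra, crossover interference and sex-
specific recombination maps, sequencing-error asymmetries beyond a flat
rate, phasing errors, and relatedness inside the population cohort.
Passing tests therefore show the pipeline's logic is correct under its
stated model, not that real phasing or calling artefacts are handled.

## Benchmarks and their problem sizes

All benchmarks are seeded and run in seconds on one CPU; sizes were
chosen as the smallest that make the Monte-Carlo bounds meaningful.

* **Calibration**: 10,000 heterozygous and 10,000 mosaic read draws at
  depth 30; false mosaic rate ≤ 1.5%, detection ≥ 50% at m = 0.4.
* **Origin recovery**: 100 gene-dropping replicates through an
  11-member, 3-generation pedigree in which the planted mosaic origin
  (II-2) has typed parents and a typed sibling; carrier states come from
  the simulated reads.  The planted individual is never *mis*identified,
  but strict recovery (correct individual *and* the germline-mosaic
  mode) is capped by the read-level detection power (~0.69) times the
  probability that a discordant sharer matches the full carrier segment,
  and measures ≈ 0.4–0.5.  The whole-segment match requirement is the
  second loss: a non-carrier relative's transmission block does not
  always contain the carriers' shared segment.
* **Segment recovery**: parent→child meioses on a panel where the
  parent's two haplotypes differ at every marker, so recovered bounds
  are comparable to the recorded breakpoints at marker resolution.  On
  random-frequency panels identity-by-state extension past a breakpoint
  is expected (probability 1/4 per side of overshooting by more than one
  marker at allele frequency 0.5), which is why the boundary benchmark
  uses the informative panel.
* **End-to-end screen**: 2,000 samples × 50 variants; loader, filter and
  both conflict rules must match the ledger exactly.

## Numerical choices and degenerate inputs

* Two-sided p-values are computed by scipy's minimum-likelihood method;
  ties in outcome probability are included (matches exact enumeration to
  < 1e-12 for n ≤ 60).
* Zero total reads → no ratio (explicit error / indeterminate state);
  `AN = 0` → MAF undefined (error); zero carriers → frequency 0 and no
  "1 in N".
* Rounding: "1 in N" to the nearest 10; percentages to two significant
  figures; ratios to two decimals — all at the reporting layer only.
* Pedigree validation rejects cycles and parent-sex inconsistencies;
  segment members not connected through the pedigree raise an error
  naming the components.

## Known limitations

* Single-site evidence only: no multi-site mosaic-fraction estimation,
  no mutation-age estimation in generations/years beyond naming the
  originating individual.
* The conflict rules are deliberately simple tally comparisons, not an
  ACMG criteria engine; submission provenance and review status are not
  modelled.
* Discordant-sharer detection requires a full-segment consensus match;
  with long carrier segments this is conservative and can miss true
  background sharers (quantified in the origin benchmark).
* Sex chromosomes, ploidy exceptions and genome-build liftover are out
  of scope.
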