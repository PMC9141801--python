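# Methods

`triotdt` implements family-based association analysis for targeted
(fine-mapping) sequencing of affected child-parent trios: genotype QC, de
novo detection, single-variant and rare-variant transmission
disequilibrium tests, and a leave-one-out procedure that partitions trios
by the locus driving their signal. This note describes the models, the
numerical choices, and what the bundled simulator does and does not
emulate.

## The transmission disequilibrium test

For a biallelic variant, every heterozygous parent in a complete trio
contributes exactly one scored transmission to the affected child: the
alternate allele was transmitted (T) or not (U). Scoring per trio:

* one parent heterozygous, the other homozygous — the homozygote's gamete
  is forced, so the transmitted allele is the child's dosage minus that
  contribution;
* both parents heterozygous — child dosage 2 gives T += 2, dosage 0 gives
  U += 2, dosage 1 gives one count to each (the transmitting parent is
  unidentifiable without phase, but the aggregate counts are exact);
* two homozygous parents are uninformative and contribute nothing.

Under the null of no association (in the presence of linkage) each
transmission is a fair coin, so McNemar's statistic

    chi^2 = (T - U)^2 / (T + U)

is chi-square with 1 df; the transmission odds ratio is OR = T/U
(reported 0 when T = 0 and infinite when U = 0, matching how such rows
are printed in association tables). Because only within-family
transmissions enter, the test is immune to population stratification.
If a heterozygous parent transmits the risk allele with probability tau,
then E[T]/E[U] = tau/(1 - tau), which the simulator uses as a closed-form
check (tau = 0.8 gives OR 4).

p-values are computed with `scipy.stats.chi2.sf`, which evaluates the
complementary error function directly; it is accurate to well below
p ~ 1e-16 (no `1 - cdf` subtraction, which would underflow near machine
epsilon). Reporting thresholds default to 1e-5 (suggestive, appropriate
for a targeted panel's reduced variant count) and 5e-8 (genome-wide).

Minor/major allele orientation — used for transmission-direction labels
and the genotype profiles — is always taken from *founder* (parental)
allele frequencies, never from ref/alt labels or from the children, so
transmission distortion in the probands cannot flip the reference frame.

## Genotype QC

The cascade runs: region restriction → multiallelic split → per-call
filters → variant filters → Mendelian policy. Per-call filters blank the
individual genotype (DP < 15, GQ < 20, or allele balance outside the
genotype class's window: hom-ref passes below 0.15, het within
[0.30, 0.70], hom-alt above 0.85); the subsequent variant filters drop
variants with missing rate above 0.20 (strict inequality) or that are
monomorphic among surviving calls. All boundaries are strict as stated:
DP 15 and GQ 20 pass, a missing rate of exactly 0.20 passes, het allele
balance of exactly 0.30 or 0.70 passes, hom-ref balance of exactly 0.15
fails. DP/GQ/allele-balance filtering is per *call*, not per variant —
these are per-sample FORMAT fields, and the missingness filter is only
meaningful on a per-call basis; the QC log records survivors after every
stage so the whole-variant reading can be compared if desired. A call
without the relevant payload (no DP, no GQ, no AD) is exempt from that
filter: what is not measured cannot be tested.

Multiallelic records are split into one biallelic record per alternate
allele. On a split record, a genotype carrying a *different* alternate is
set missing rather than recoded as reference — recoding would
systematically inflate reference transmissions. Half-called genotypes
(one allele missing) are set fully missing at ingest. Indels are
first-class variants; no left-normalization is attempted beyond what the
input VCF provides (a warning flags suspicious alleles).

Coordinates: user-facing positions are 1-based inclusive; internal
interval arithmetic is 0-based half-open; conversion happens exactly once
at ingest.

## Mendelian errors and de novo calling

Of the 27 ordered dosage triples, 12 are inconsistent with biparental
inheritance (verified in the tests against brute-force gamete
enumeration). Inconsistencies with both parents homozygous reference and
a carrier child form the *de novo pattern*; all others (e.g. child 0 with
a parent 2) are treated as genotyping errors and never reported as de
novo. A trio with any missing member is skipped, not counted as an error
— counting missingness as error would conflate QC with inheritance.

Policy: variants with two or more inconsistencies are dropped from
association analyses; a variant with exactly one has the offending trio's
three genotypes blanked at that variant only. De novo calling runs
*before* the zero-out (which would otherwise erase its signal), on a copy
of the cohort restricted to variants with missing rate at most 2% — de
novo claims need near-complete typing. Each call reports the cohort
minor-allele frequency and the number of trios sharing the pattern;
recurrent "de novos" at one site usually indicate an alignment or calling
artifact, and interpretation is left to the user.

## Leave-one-out (jackknife) partitioning

Given per-locus index variants (by default each region's top full-cohort
TDT hit, fixed before the scan and not re-selected inside the loop), the
influence of trio i on locus L is

    influence(i, L) = [-log10 p at L, full cohort]
                    - [-log10 p at L, cohort minus trio i]

so positive influence means the trio strengthens the signal. Removing an
uninformative trio changes nothing (influence exactly 0); if removal
makes the index variant untestable, the trio is credited with the locus's
full -log10 p. Each trio is assigned to the locus of its maximal
influence provided that influence is positive; ties and all-non-positive
rows stay unassigned, and unassigned trios enter no per-group re-test.
The scan is deterministic.

This single-variant influence rule has an intrinsic accuracy ceiling: a
trio that happens to be heterozygous-informative at a locus it does *not*
drive transmits a fair coin there, and a lucky transmission yields
positive influence indistinguishable in kind from a true contributor's.
Partition accuracy is therefore reported over *assigned* trios (the rule
has an abstain option), and the heterogeneity study conditions (below)
use carrier ascertainment, which concentrates informativeness on each
trio's own locus.

## Rare-variant collapsing TDT

Variants with founder minor-allele frequency at or below 0.01 (estimated
from the cohort's parents, not an external database — rarity should
reflect the analyzed founders) are collapsed per region. The atomic unit
is the transmission event: one heterozygous parent at one rare variant
either transmitted the rare allele or did not. Statistics:

* **CMC** — (trios transmitting >= 1 rare allele) − (trios
  un-transmitting >= 1), a carrier-level McNemar contrast;
* **BRV** — T_rare − U_rare over all events;
* **WSS** — sum_v w_v (T_v − U_v) with w_v = 1/sqrt(n_v q_v (1 − q_v)),
  q_v estimated from the untransmitted parental alleles (the
  within-family pseudo-control) with a +1/+2 pseudocount;
* **VT** — the BRV statistic maximized over the distinct founder-MAF
  thresholds present in the region.

The null flips each event's transmission independently with probability
1/2 — exact under Mendel's law for unlinked variants and structure-proof,
since founder genotypes are held fixed. The WSS weights and the VT
maximization are recomputed inside every permutation, so the observed
statistic is never favoured. p = (1 + #{permuted >= observed}) /
(1 + permutations) never equals 0. Default 10,000 permutations; a seed is
required for reproducibility.

Two caveats, both verified empirically in the test suite's calibration:

* BRV and CMC live on an integer lattice (T − U steps by 2), so their
  permutation p-values carry an irreducible tie atom and are slightly
  conservative; the KS uniformity calibration therefore targets the
  effectively continuous WSS statistic.
* The per-event flip null treats events as independent. Strongly linked
  rare variants share a single per-haplotype transmission, inflating the
  observed burden's variance relative to that null (anti-conservative).
  Transmissions are deliberately counted per variant — the data are
  unphased and no haplotype reconstruction is attempted — so regionwide
  rare-variant LD is the main situation in which these p-values should be
  read cautiously.

## Transmission profiles

For a chosen variant set, pooled fractions of homozygous-major,
heterozygous and homozygous-minor genotypes are computed separately for
children and parents (founder-oriented, non-missing calls only; an
exclusion list allows removing the variant the cohort was ascertained
on). Under major-allele over-transmission the children's homozygous-major
fraction exceeds the parents', the signature of a protective minor
allele. A companion scan reports variants significant in two cohorts with
*opposite* over-transmitted alleles — the cross-phenotype discordance
pattern.

## The synthetic cohort generator

The generator produces what the analyses assume, with ground truth for
every stage:

* **Founder haplotypes, blockwise LD.** Within a block of
  `ld_block_length` variants (default 10), each variant copies a shared
  per-block ancestor draw with probability c = `ld_strength` (default
  0.9), else an independent Bernoulli of its own frequency. Marginals
  follow the configured MAF spectrum exactly (default: 30% rare mass on
  [0.002, 0.01], the rest uniform on [0.05, 0.5]); for equal within-block
  marginals the pairwise correlation is c^2, giving the analytic
  within-block r^2 = c^4 that the tests check. Blocks are independent.
* **Transmission.** Parents transmit per block (free recombination
  between blocks, none within). At a risk locus, a parent heterozygous at
  the index variant transmits the haplotype carrying the risk allele with
  probability tau — so linked variants inherit the distortion, as in real
  fine-mapping data. tau = 0.5 is the null.
* **Subgroups and ascertainment.** Disjoint trio subgroups are each
  distorted at their own locus only. Optional ascertainment redraws a
  trio until the child carries a risk allele (globally, or per subgroup),
  mirroring proband-based selection; it is a rejection filter, so its
  enrichment side effects are exactly the ones the profile analyses
  detect.
* **Noise.** Poisson read depth (mean 60), clipped-normal GQ (mean 80,
  sd 10), Beta-distributed het allele balance (concentration 50), AD
  fields consistent with depth and balance, uniform random missingness
  (default 2%), plus deliberately planted QC failures (low DP, low GQ,
  skewed balance) and Mendelian inconsistencies for bookkeeping tests.
  `clean_payload` disables the stochastic noise for exact-count fixtures.
  Injected de novos are placed on cleanly genotyped calls of otherwise
  hom-ref trios so that their recoverability reflects the caller, not the
  noise model.

What the generator does **not** emulate: coalescent genealogy (LD decays
blockwise, not smoothly), sequencing reads (no BAMs; depth and balance
are drawn, not piled up), indel alleles, sex chromosomes,
batch/platform effects, or genotype-calling error modes beyond the
planted ones. Passing tests therefore demonstrate the statistical
machinery under the stated model, not robustness to every real-data
pathology.

## Study conditions used by the tests and acceptance script

* *Null calibration*: 80 trios, 2,000 unlinked common variants for the
  single-variant type-I rate; 200 unlinked rare-variant regions (45
  variants each), 1,000 permutations, WSS, for the KS uniformity check.
* *Parameter recovery*: tau = 0.8 at a MAF 0.3 risk variant, 500 trios,
  10 replicates; the replicate-mean OR is compared with tau/(1−tau) = 4.
* *Locus heterogeneity*: 80 trios split 60/20 between a chromosome 7 and
  a chromosome 20 locus; founder risk-haplotype frequency 0.04, LD copy
  probability 0.98, tau 0.90 (60-trio locus) and 0.95 (20-trio locus,
  whose real-data analogue showed near-complete distortion), each
  subgroup carrier-ascertained at its own locus. Low population frequency
  plus ascertainment keeps trios informative at their own locus and
  rarely informative at the other, which is what makes the
  influence-argmax rule separate the groups.
* *Bookkeeping*: 60 trios, 200 variants, clean payload, planted failures
  (12 low-DP, 9 low-GQ, 7 bad-balance calls; 4 single- and 3 double-error
  Mendelian variants; 8 de novos) recovered exactly.

These sizes keep the full test suite and the acceptance script each
within a few seconds to a couple of minutes on one CPU while leaving the
Monte-Carlo error small relative to every asserted tolerance.

## Known limitations

* No parent-of-origin, X-chromosome, or sibship extensions; no covariate
  adjustment.
* The jackknife rule is the deterministic argmax described above, not a
  mixture model or likelihood-based heterogeneity test; its parameters
  (index variants, positivity threshold) are configurable so alternative
  readings can be compared.
* Rare-variant p-values assume unlinked rare variants (see above).
* Cohort-level counts from any particular real study (numbers of
  significant variants, of de novos, published rare-variant p-values)
  depend on unavailable genotypes and are not reproduction targets; the
  pipeline's correctness is established on worked examples and
  ground-truth simulations instead.
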