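# Methods

## The filtering model

The package assumes the standard induced-mutation discovery design for
selfed mutant populations: a bulk of seed is irradiated, lines are
propagated by single-panicle descent to M₇ (so most induced loci are
fixed homozygous), and each selected line is whole-genome sequenced as
two biological replicates alongside non-irradiated controls grown from
the same seed bulk. Under that design:

- anything the controls carry is founder polymorphism, not an induced
  hit (step 1);
- a variant carried by more than one mutant line is overwhelmingly more
  likely to be segregating founder variation than two independent hits
  at the same base (step 2);
- a genuine germ-line mutation must appear in both sibling replicates
  (step 3);
- species-wide catalog variants are natural (step 4).

Per-sample calls are prepared first: a minimum depth of 20 reads
(inclusive — a 20-read call passes) and zygosity recalibration of
heterozygous calls whose alt-allele read fraction is below 20% or above
80% (strict bounds; a call at exactly 20% stays heterozygous). The
recalibration models the known failure mode of short-read callers that
emit heterozygous genotypes on a handful of stray reads; re-scoring to
homozygous reference removes the call from the carrier set and is
logged with its own reason code.

Decisions the published procedure leaves open, resolved here:

- **Step ordering.** Cross-line sharing (step 2) is evaluated on each
  line's carrier set *before* replicate intersection: any
  post-recalibration non-reference call in any sample of another line
  disqualifies the key everywhere. This is the maximally conservative
  reading and matches the order the steps are listed in. Because steps
  1, 2 and 4 are set subtractions and step 3 a per-key predicate over
  fixed carrier sets, the accepted set is invariant to evaluation order
  (property-tested).
- **Depth filtering is per sample,** not per site: a low-coverage call
  in one replicate breaks concordance for that line without erasing the
  site elsewhere.
- **Missing genotypes count as discordant,** not as wildcards.
- **Variant identity** is exact `(chrom, pos, ref, alt)` after
  splitting multi-allelic records and left-normalizing indels against
  the reference, the same identity `bcftools isec`-style set operations
  use.
- **SNV/indel boundary:** both alleles length 1 → SNV; everything else
  (including MNVs) is counted with indels, since small variants are
  reported in only those two classes.

## Structural variants

Callers disagree on breakpoints, so records are matched by
single-linkage clustering: two same-type calls on the same chromosome
pair link when both breakpoints differ by at most the tolerance
(default ±2000 bp, the published translocation merging window, applied
to all SV types for lack of any other stated tolerance). Cluster
consensus takes support-weighted mean coordinates and maximum support.
Canonical pre-sorting makes clustering independent of input order.

Support thresholds: translocations need strictly more than 100
supporting reads; BreakDancer-style callers at least 50 read pairs;
Lumpy-style callers at least 50 (10 as the documented alternative);
other callers a configurable floor. Consensus requires a configurable
number of distinct callers (default 1 — no cross-caller consensus
requirement is stated for the modeled study) and presence in both
replicates. Records matching an SV in another line or a control within
the tolerance are removed as natural variation; because the published
PCR-validation table contains identical deletions verified in several
lines, this cross-line filter is configurable (`strict`, the default,
vs `report`, which keeps but flags shared records).

The read-depth bin scan computes, per bin, the ratio
`(mutant + ε) / (control + ε)` with pseudodepth ε = 0.5 on
library-size-normalized binned depths (bin sizes 1/5/10/100 kb).
Maximal runs at or below 0.25 become deletion candidates, runs at or
above 1.75 duplication candidates. The 0.25/1.75 thresholds are this
package's choice, placed to separate homozygous events from Poisson
noise at ~30× coverage; both are configurable.

Accounting convention: a translocation is also recorded as a deletion
at its origin locus, so the reported deletion column includes ITX/CTX
events and the SV total is DEL + DUP + INV + INS after that accounting
(the ITX/CTX columns are informational, not added again). The
convention is toggleable in `build_report`.

## Effect classification

A deliberately small SNPeff-style annotator. SNVs in coding sequence
are resolved to their codon on the coding strand and classified through
the standard genetic code (silent/LOW, missense/MODERATE,
nonsense/HIGH, start- and stop-loss/HIGH). Indels overlapping coding
sequence are frameshift/HIGH when the net coding-length change is not a
multiple of 3; in-frame indels are MODERATE unless the reconstructed
mutant coding sequence translates to a premature stop or loses its stop
codon (HIGH). Non-coding variants map to intronic, upstream,
downstream (5 kb flanks each, the common annotation default) or
intergenic, all MODIFIER. Splice-site classes are deliberately
omitted; variants within 2 bp of an intron boundary are labeled
intronic with a `near_splice` warning flag.

Counting is per variant-annotation pair: a variant inside the footprint
or flank of two genes contributes two annotations. This mirrors how
annotation tools report, and is why published impact-tier totals exceed
per-variant counts. Percentages are computed within two families —
functional (missense/nonsense/silent) and impact
(HIGH/LOW/MODERATE/MODIFIER) — each over its own family total; an
all-zero family yields no percentages rather than a division error.

The classifier is verified against an independent brute-force oracle
that edits the chromosome, re-splices, translates reference and mutant
coding sequences and diffs the proteins, over ≥1000 random coding
variants on both strands.

## Spectrum report

Mutation frequency is `genome_size / n_events` in bp per event
(smaller = denser), reported to 2 decimals; undefined (absent, not 0)
for zero events. The default genome size is 430 Mbp — the rice value
used by the modeled study — overridable for synthetic genomes. Shares
are rounded to 2 decimals.

## The synthetic population generator

What it emulates and why:

- **Population design:** the default population is the modeled study's —
  11 mutant lines (gamma 150/300/450 Gy; X-ray 75/150 Gy), two
  replicates each, two non-irradiated controls. Per-line induced
  SNV/indel/SV counts are the published counts scaled by 1/150 so a
  full run takes seconds; the scale preserves relative loads across
  treatments (e.g. the densest X-ray line stays ~3× the sparsest).
- **Genome:** 2 × 300 kb chromosomes with 20 two-exon genes whose
  spliced CDS starts with ATG, ends with a stop, contains no internal
  stop and has length divisible by 3; ~20% of genes are flagged
  transposon-related.
- **Founder variation** at 10⁻³ variants/bp (desk-scale stand-in for
  the ~2.1 M founder variants the real controls carried), fixed
  homozygous in every sample including controls.
- **Induced variants** are line-unique, homozygous-alternative with a
  5% heterozygous residual (selfing to M₇ fixes most loci; the true
  residual is not published — this is a modeling choice). Cross-line
  collisions are injectable on demand to exercise the sharing filter.
- **Depth noise:** per sample and site DP ~ Poisson(30), alt reads
  ~ Binomial(DP, p) with p = 0.5 for het, 1−0.005 for hom-alt, 0.005
  for hom-ref (sequencing error). The emitted genotype is re-called
  from the read ratio like a naive caller and flipped with probability
  10⁻³ (label error). Most flips are repaired downstream by
  recalibration — the same mechanism the real pipeline relies on.
- **SV call sets:** four simulated callers; each truth SV is reported
  per replicate by each caller with probability 0.9 (at least one
  guaranteed), with Normal(0, 150 bp) breakpoint jitter, support
  ~ Poisson(200), plus Poisson false positives at a low rate. Distinct
  truth SVs keep breakpoints ≥ 4.5 kb apart so that identity under the
  ±2 kb matching tolerance is unambiguous; deliberate collisions are a
  config option, not an accident of placement.
- **Noiseless mode** fixes DP, honors allele fractions exactly and
  disables every error source; in that regime the pipeline must (and
  does) recover truth with precision = recall = 1.0.

What it does **not** emulate — and what passing tests therefore do not
show about real data: read-level artifacts (mapping bias, duplicates,
indel realignment), segregation distortion, residual heterozygosity
from outcrossing, M₁ chimerism, clustered breakpoints at repeats, or
caller-specific systematic error. The generator validates the
*filtering logic*, not upstream variant calling.

## Numerical choices

- All randomness flows from one integer seed through per-stage
  `SeedSequence` children; identical seeds give byte-identical output
  files.
- Single-linkage clustering sorts records canonically first, so results
  are independent of input order; consensus coordinates round
  support-weighted means.
- Frequencies and percentages use Python's round-half-even at 2–3
  decimals, which reproduces all published printed values.
- Degenerate inputs: zero controls is an error (step 1 undefined);
  zero-depth heterozygous calls become missing; zero-event frequencies
  are absent; an all-zero percentage family is omitted.

## Known limitations

- Effect annotation reconstructs mutant proteins only for indels fully
  contained in one CDS exon; edits spanning an exon boundary fall back
  to the net-coding-length frame rule.
- GFF3 phase on minus-strand CDS features is written as 0; the
  annotator derives frame from interval arithmetic and ignores phase.
- The SV consensus treats an insertion's size as the first cluster
  member's size rather than a weighted consensus.
- Depth-bin scanning assumes near-uniform coverage; GC-dependent
  coverage waves in real data would need normalization upstream.
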