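# Methods

## Data model

A genotype is an unordered pair of positive integer allele codes per
locus; codes are opaque labels (fragment lengths or arbitrary ids) and
no size ordering is ever used — parentage inference only tests allele
identity. A locus call is all-or-nothing: half-calls are rejected at
read time rather than coerced, because the inclusion criteria count
loci "successfully genotyped", a per-locus notion. Loci can be flagged
excluded (e.g. for a non-negligible null-allele frequency); excluded
loci keep their calls in the table but are invisible to every counting
operation downstream.

Two file dialects are supported. The native tabular format
(`id,generation,mother_id,<locus>_a,<locus>_b,...` plus a YAML panel
sidecar with exclusion flags) is lossless and round-trips exactly.
GenePop is supported as the community exchange format for
microsatellites; since it carries no generation or pedigree fields,
those are supplied by the caller on read and dropped on write, and the
round-trip guarantee covers ids and calls only. Generation labels are
data, never inferred from id strings.

## Paternity assignment

For each juvenile–mother pair, every shared locus (called in both,
excluded loci ignored) is classified:

* **outcross-consistent** — exactly one juvenile allele is absent from
  the mother; the paternal allele set is that singleton;
* **maternal mismatch** — the juvenile shares no allele with the
  mother; treated as a tolerated genotyping error or null allele, with
  paternal allele set equal to both juvenile alleles (the least
  assuming rule: the non-maternal allele is paternal or erroneous);
* otherwise the sire allele is ambiguous and the paternal set is the
  juvenile's own allele pair.

Inclusion criteria: ≥ 6 shared loci, ≤ 2 maternal mismatches, and at
exactly 6 shared loci ≤ 1 mismatch. Failing juveniles are reported as
excluded with the criterion named.

Each candidate sire is scored on the loci called in juvenile, mother
and candidate: a mismatch is a locus where the candidate carries no
allele of the paternal set. Selfing is modelled as the mother being her
own candidate, which unifies the verdict into a single ranking over
hypotheses: at outcross-consistent and maternal-mismatch loci the
mother lacks the required allele by construction, so those loci count
against the selfing hypothesis with no special-casing. The unique
minimal-mismatch hypothesis with at most `max_mismatch` (default 2,
matching the largest mismatch count ever accepted in validated
assignments) wins; no usable hypothesis within tolerance means
*unassigned*. Equal-mismatch ties are broken by the product Mendelian
transmission likelihood when reference allele frequencies are supplied
(zero-probability loci floored at 10⁻³ so tied hypotheses stay
comparable), and otherwise reported as *ambiguous* — determinism and
honesty about ambiguity, never a coin flip.

`selfing_probability` supplies a per-juvenile posterior: the selfing
hypothesis (prior 0.5 by default) against the named candidates plus an
optional random sire drawn from the reference allele frequencies, with
exact Mendelian segregation likelihoods and a 10⁻³ frequency floor for
unseen alleles. It is an explicit, documented definition of "probability
of being selfed" internal to this package, not an emulation of any
external sibship-reconstruction program.

## Selfing rates and classification

A family's selfing rate is s = selfed / (selfed + outcrossed);
ambiguous, unassigned and excluded juveniles are reported but never
enter the denominator, and a family with no assigned offspring has s
undefined (never imputed 0). The confidence interval is Wilson by
default (Clopper–Pearson optional); nothing downstream depends on the
CI choice. Sire counts treat the mother as one sire when any offspring
is selfed, so a selfed-plus-outcrossed array of a once-paired mother
shows multiple paternity.

Mating-system bands use the conventional thresholds t_low = 0.2 and
t_high = 0.8, with boundaries inclusive outward (s = 0.2 is primary
outcrossing, s = 0.8 primary selfing). Propensity classes map
(selfed-in-isolation, post-isolation s) as: (no, 0) outcrosser;
(yes, 0) plastic switcher; (yes, 0 < s ≤ 0.2) plastic mixer; s ≥ 0.8
selfer. Two categories close the logic: `intermediate_unclassified`
(0.2 < s < 0.8 — a pattern absent from the motivating data but
logically possible) and `latent_anomaly` (selfing post-isolation
without selfing in isolation). Both are flagged so the four-class
scheme is recovered exactly whenever they are empty. Apparent classes
for individuals without genotyped offspring use developed embryos per
phase and whether the individual ever copulated as a female; lifetime
female-infertile individuals are excluded as unknowable.

The five treatment tables have fixed row order (once-paired,
repeatedly paired) and documented column orders (multiple/single;
selfing present/absent; selfed/outcrossed; apparent selfer/plastic/
outcrosser; selfer/mixer/switcher/outcrosser). χ² is
layout-invariant, so the column conventions affect only presentation.
Yates' continuity correction is applied by default only to the 2×2
multiple-paternity table — the one place it is conventional at these
sample sizes — and is configurable per table.

## Population statistics

Pearson χ² uses expected counts from the margins
(`scipy.stats.chi2_contingency`); Yates is restricted to 2×2 tables
and zero margins are errors. Proportion intervals come from
`statsmodels` (Wilson score, exact). F_IS is the Weir–Cockerham
within-population f computed as a ratio of sums of per-allele variance
components over loci, with a percentile bootstrap over loci (default
1000 replicates; 200 inside the pipeline where it is a diagnostic) for
the 95% CI. The estimator is exactly −1 for a fully heterozygous
sample, ≈ 0 under random mating, and → 1 for a long-selfed, fully
homozygous sample; monomorphic panels yield an undefined, flagged
value.

## The simulator

The generator emulates the mating-trial experiment end to end.
Defaults are the study conditions: 9 active + 1 excluded (null-allele)
loci with 10 alleles each and Dirichlet(1) frequencies — highly
polymorphic, as progeny-array power requires; 38 P0 mothers and 274 F1
snails; a 50/50 split between one mating opportunity and six sequential
ones; 56 genotyped families with progeny arrays capped at 22 juveniles
(target 16 ± 2); candidate-father windows of 3–5 partners for
repeatedly paired broods (eggs laid before the later opportunities);
propensity class mixture 0.31 / 0.27 / 0.10 / 0.32 for outcrosser /
switcher / mixer / selfer — the 0.37 mixed-mating share split between
switchers and mixers in the ~3:1 ratio observed among genotyped
snails; true selfing rates s_mixer = 0.1 and s_selfer = 0.95, chosen
inside the defining bands (class bounds are all the motivating data
constrain); embryo development 0.79 (outcrossed) vs 0.72 (selfed) and
juvenile death 0.534 vs 0.695 — the two measured stages of inbreeding
depression; dropout 0.05 and a 0.15 null-allele frequency at the
excluded locus.

F1 sires are drawn from an unobserved founder pool, so F1 snails are
outcrossed but their fathers are absent from the genotype table,
exactly as when mothers are field-inseminated. Each family provisions
eggs so that an outcrossing family yields ~16 survivors; each egg is
independently selfed (class rate), develops, and survives with
selfed/outcrossed probabilities. Selfed eggs therefore survive to
genotyping less often, and realized ("secondary") selfing rates among
survivors sit below the rates at fertilization — the simulator
reproduces the bias a progeny-array design inherits, and the
closed-form expectation in `expected_selfed_fraction` accounts for it.
Genotyped families are sampled uniformly among families with ≥ 3
survivors: sampling by productivity would deselect selfer families
(smaller arrays) and distort the class mixture the generator is
specified to deliver. Sibling pairings are excluded by default
(`allow_sibling_pairing` enables them for robustness work). One global
seed expands into named substreams (frequencies, pedigree, thinning,
noise), so outputs are byte-identical for identical configurations.

What the simulator does *not* model: allosperm storage depletion, body
growth, waiting times, dominance/load genetics behind inbreeding
depression (thinning is Bernoulli at two stages), or locus-specific
genotyping error beyond dropout and the one null-allele locus. Passing
recovery tests therefore validate the inference machinery under
idealized Mendelian noise, not the full error structure of real
fragment data.

## Numerical and design choices

* A single 56-family cohort has sd ≈ 0.05 around the closed-form
  selfed-fraction expectation (class sampling noise), so the
  simulator's calibration check averages replicate cohorts rather than
  judging one draw.
* Classification recovery is scored against the class implied by an
  individual's realized behaviour (true isolation selfing plus the true
  selfed fraction among its assigned offspring), not the latent
  generative class: a mixer with s = 0.1 produces zero selfed juveniles
  in a 14-offspring array ~40% of the time, so latent-class recovery is
  information-theoretically capped at these array sizes. Classification
  itself is defined on realized rates, so this is the quantity the
  classifier can and should recover.
* Likelihood ties within a relative tolerance of 10⁻⁹ are treated as
  exact ties (ambiguous); the frequency floor for unseen alleles is
  10⁻³.
* Degenerate inputs fail loudly and early: empty candidate lists,
  all-excluded panels, zero table margins, undefined selfing rates and
  monomorphic F_IS panels all raise or flag rather than returning
  silent zeros.
* The pipeline's per-juvenile audit table records every exclusion with
  its criterion, and every family satisfies
  genotyped = excluded + unassigned + ambiguous + assigned.

## Problem sizes used in validation

The test suite and acceptance script run at sizes chosen to make the
statistical checks well powered while staying quick on one CPU:
brute-force oracle equivalence on 500 random families (≤ 10 candidates,
≤ 10 loci); selfing-rate recovery on 30 families × 16 juveniles at
s ∈ {0, 0.1, 0.5, 0.9, 1}; classification recovery and assignment-rate
checks on two full 274-individual experiments; Wilson coverage on 2000
binomial draws; Hardy–Weinberg and F_IS checks on 500 founders; and
eight replicate cohorts for the closed-form calibration check.
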