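# Methods

## Problem and model

`domainage` analyses how recently emerged protein domains behave inside a
proteome: how old each domain family is, whether young (lineage-specific)
domains live in young genes or were gained by older proteins, where in the
protein they were inserted, and how fast they evolve relative to the old
domains they share a protein with.

The dating model is phylostratigraphic. Species are grouped into ranked
clades ordered by divergence from a reference lineage (default: mammals <
other vertebrates < other metazoans < other eukaryotes, with the reference
species — human in the motivating study design — implicit). A domain type is
assigned the age of the **oldest clade containing at least one species with a
detectable homologue**. Absences in younger clades are interpreted as
secondary losses and never lower the age; this makes the rule robust to
patchy presence but means the estimate is a lower bound on true age only
when the oldest occupied clade is itself a false negative. A protein is as
old as its oldest domain; domainless proteins are dated by the same rule
applied to a whole-protein sequence-similarity presence profile. The two
oldest classes (Metazoan, Eukarya — both older than roughly 550 My) are
merged into a single "Old" class **at reporting time only**; the full
four-level ordinal is preserved internally.

A profile with no hits outside the reference lineage has no observable
oldest clade; we assign the youngest age (reference-lineage-specific) and
treat this as a convention, not an inference — the rule is isolated in
`assign_domain_age` and trivial to change.

## Architectures and arrangement scenarios

An architecture is the ordered tuple of domain types along the protein after
E-value filtering (default keep E <= 1e-5) and overlap resolution. Overlaps
are resolved greedily: hits ranked by (E-value, longer first, type id), each
kept only if it does not overlap an already-kept hit (configurable overlap
fraction, default zero). Pfam-style hit tables rarely document a canonical
resolution rule; E-value priority is the natural one and is exercised
against a brute-force oracle in the tests.

A type's **configuration set** is the set of distinct architectures (as
ordered tuples) of the proteins containing it; a type is *independent* if
that set has at least two elements. Tandem runs of the same type collapse to
one element for configuration identity, so copy-number variation of repeat
arrays (Zn-finger cassettes being the canonical case) does not make nearly
every repeat protein look independent. Both choices — ordered tuples, tandem
collapse — are configurable (`ordered=`, `collapse_tandem=`).

For each young-old type pair co-occurring in a protein:

| class | old independent | young independent | reading |
|---|---|---|---|
| 1 gain-dependent | yes | no | young domain gained inside an existing protein |
| 2 mutual dependence | no | no | single-context pair |
| 3 fusion | yes | yes | two pre-existing units fused |
| 4 complex | — | — | >2 domains, pairs disagree |

Classes 1 and 2 are jointly "gain-compatible". The symmetric case (young
independent, old not) is tracked separately as `REVERSE_DEPENDENT`; the
study design predicts it to be empty and the generator never produces it. A
protein takes the class its pairs agree on, else class 4.

**Positional bias.** Young-domain positions (N-terminal / internal /
C-terminal by tuple index) are tested against a uniform-insertion null with
a chi-square goodness-of-fit test, stratified by protein size. For 2-domain
proteins the null is an even N/C split; for k-domain proteins the young
domain is equally likely in any of the k slots, giving expected cell
probabilities 1/k, (k-2)/k, 1/k aggregated over the observed k distribution.
The null model is the minimal symmetric one; any expected cell below 5
raises a small-sample flag on the result rather than an error.

## Rate estimation (NG86)

Divergence is estimated per domain region from pairwise codon alignments of
1:1 orthologous coding sequences (reference species first, gaps in codon
multiples), using Nei-Gojobori (1986) counting:

* **Sites.** For each codon position, the synonymous site fraction is the
  share of the single-nucleotide changes that preserve the amino acid, with
  stop-creating changes excluded from the denominator; per sense codon the
  nonsynonymous and synonymous site counts always sum to 3. Totals average
  the two sequences.
* **Differences.** Codon pairs differing at several positions are averaged
  over all minimal mutational pathways with equal weights; pathways through
  stops are excluded, and a pair whose every pathway passes a stop is
  skipped entirely (sites and differences alike). Columns gapped in either
  sequence and codons with ambiguous bases are skipped.
* **Rates.** pN = Nd/N, pS = Sd/S are corrected for multiple hits with
  Jukes-Cantor, d = -3/4 ln(1 - 4p/3); omega = dN/dS, undefined (NaN) when
  dS = 0, and such estimates are excluded from distributional comparisons.
  Proportions at or beyond 3/4 raise a saturation error.

Reliability filter: keep regions with length >= 60 aa, dN <= 0.5 and
dS <= 2 (the discard conditions are strict inequalities, so the boundaries
are inclusive on the keep side). Filtered estimates are flagged, never
deleted.

NG86 counting was chosen over maximum-likelihood codon models (codeml-style
GY94) deliberately: it is deterministic, dependency-free, exactly testable
against hand enumeration, and its known biases are bounded and measured here
(worst median relative bias of omega over the grid omega in {0.05, 0.2,
0.5, 1.0} x dS in {0.1, 0.5, 1.0}, 500-codon regions, 100 replicates: about
11%, inside the +-20% band the recovery tests assert). No claim is made that
NG86 point estimates match ML estimates on real data.

## Young-vs-old comparisons

* **Independent groups**: pairwise two-sample Kolmogorov-Smirnov tests on
  passing omega values per merged age class, plus medians and quartiles, and
  an optional per-domain-type median aggregation that removes the weight of
  very abundant families.
* **Within proteins**: a paired Wilcoxon signed-rank test on (young, old)
  omega pairs, and the bounded relative difference
  (w_young - w_old) / max(w_young, w_old).
* **Per pair**: a two-sided exact binomial test on the young domain's
  substitution spectrum. Successes = round(Nd_young) (half-up), trials =
  round(Nd_young + Sd_young); the null probability projects the old domain's
  per-site rates onto the young domain's site composition:

      p0 = N_y (Nd_o/N_o) / (N_y (Nd_o/N_o) + S_y (Sd_o/S_o)).

  The unadjusted p0 = Nd_o/(Nd_o + Sd_o) is available via option. Verdicts
  at alpha = 0.01: young_faster / old_faster / no_difference; degenerate
  inputs (no trials, p0 at 0 or 1) give a flagged no_difference. When a
  protein carries several young or old domains, every young-old occurrence
  pair is tested; pooling counts per age within the protein would be the
  alternative reading and is not implemented.

All p-values are raw; no multiple-testing correction is applied across the
handful of global tests, and the report labels them as such.

## Synthetic data generator

The generator's defaults define the study conditions used throughout the
tests and the acceptance script: a 4-clade / 15-species ranking; 120
young-only, 120 old-only and 60 combined proteins (plus ~38 domainless
ones), the combined proteins split across scenario regimes in the
proportions 243:16:40:31; secondary-loss probability 0.2 with the
origin-clade guarantee on; N-terminal insertion bias 0.75; duplication rate
0.05; per-age omega log-normal with medians 0.33 (Mammalian), 0.18
(Vertebrate), 0.09/0.08 (Metazoan/Eukarya) and sigma 0.5; background linker
omega 0.25; target dS 0.5 per orthologue pair (a mammalian-ortholog-like
synonymous divergence); domain region lengths log-normal with median 110 aa
clipped to [60, 400]; linkers uniform 5-50 aa; 10% of regions deliberately
drawn short (20-59 aa) to exercise the length filter.

Scenario regimes are guaranteed **by construction**, which is what makes the
end-to-end ledger comparison exact: gain-dependent young types occur in one
configuration while their old partner also occurs in an old-only protein;
mutual pairs use private types on both sides; fusion young types get a
young-only partner protein; complex proteins carry one shared and one
private old domain so their two pairs disagree (classes 1 and 2). Whole-
protein duplication adds copies without changing any configuration set, so
classes are stable under it.

Sequence evolution is a per-site independent substitution process: Poisson
numbers of synonymous and nonsynonymous events with expectations
dS x S_sites and omega x dS x N_sites (sites counted on the ancestor),
applied by rejection sampling (stop-creating changes rejected). This matches
NG86's counting assumptions by design, so recovery tests measure the
estimator, not a model mismatch. Consequences worth knowing: it is not a
continuous-time codon model (no transition/transversion bias, no codon
frequencies); omega is homogeneous within a region; alignments are ungapped
(no indels); two synonymous hits in one codon can yield codon pairs whose
pathway average ascribes a fractional Nd even though the protein sequence
was preserved at every step. Real data violate all of these, plus the
profiles' independence of losses across species; passing tests therefore
demonstrate internal correctness and calibration, not field accuracy on
real alignments.

Determinism: with the same parameters and seed the emitted bundle is
byte-identical (hash-checked in the tests).

## Numerical and reporting choices

* Report percentages round half-up to 1 decimal, ratios to 2 decimals
  (Python's bankers' rounding would give 78.4 for 259/330). One published
  figure, 234/363, prints as 64.4 although the exact ratio 64.46% rounds to
  64.5 under any standard rule; the package reports 64.5 and the acceptance
  checks compare the underlying ratio at printed precision.
* Fractional substitution counts are rounded half-up for the binomial test.
* The fraction of young domain types that "arose in newly formed genes" is
  reported on two bases — distinct types, and occurrences — because the two
  differ whenever abundant types span both contexts; the report emits both
  without asserting either as canonical.
* Ties in overlap resolution break by longer hit, then lexicographic type id,
  making the pipeline order-independent and reproducible.

## Known limitations

* **Paired binomial calibration.** Because the null probability is estimated
  from the old domain's finite counts, the test is anticonservative when the
  two regions are of comparable size: at 120-codon regions, equal true omega
  0.2 and dS 0.5, the measured type-I error at nominal alpha = 0.01 is about
  0.05-0.06 (site-adjusted and unadjusted variants alike). The level
  approaches nominal only when the old region is several-fold longer (about
  0.006 at 1000 codons). The binomial machinery itself is exact: drawing
  young counts from the null p0 gives rejection below alpha (unit-tested).
  Verdict tallies should therefore be read as a descriptive classification,
  not as a strictly calibrated test; a conditional 2x2 exact test would be
  the calibrated alternative at the cost of no longer being a binomial test
  on the young domain's spectrum.
* The oldest-hit rule cannot overestimate age but underestimates it whenever
  the origin clade is entirely unobserved (quantified by the generator with
  the guarantee off).
* NG86's pathway weighting is uniform; transition-biased weighting and ML
  codon models would shift estimates on real data.
* Domainless proteins are dated and counted but carry no rate estimates.

## Problem sizes

Test-suite and acceptance-script experiments use scaled-down sizes chosen as
the package's own study conditions: 500-codon regions x 100 replicates per
grid cell for recovery, 1000 replicates for binomial calibration, 200/100
replicates for positional size/power, ~350-protein bundles for the
end-to-end checks and 100 small seeded bundles for the ordering stability
measure. All are stated where used and deterministic given the seed.
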