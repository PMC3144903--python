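# Methods

`domseg` re-implements, as a tested library, the computational chain used to
pinpoint a fully penetrant autosomal dominant disease mutation in a sequenced
candidate gene, with Bull Terrier polycystic kidney disease (BTPKD) and the
canine *Pkd1* orthologue as the packaged worked example. This note records
the models, the numerical choices, and what the synthetic tests do and do
not establish.

## Segregation model

The inheritance model is autosomal dominant with full penetrance and
embryonic-lethal homozygotes. Its genotype-level consequence at the causal
site is exact, not statistical: every affected individual carries exactly
one copy of the causal allele, and no unaffected individual carries it. The
filter (`segregation.dominant_candidate`) applies that rule per site to a
genotype matrix of affected and unaffected individuals; a site admitting
such an allele is a CANDIDATE, and every other site is excluded with a
descriptive pattern label P1–P5 (all-homozygous, all-identically-
heterozygous, single-affected-het over a non-reference homozygous
background, single-unaffected-het, single-affected-het over a wild-type
homozygous background).

Two deliberate boundaries:

* Candidacy never consults the database reference alleles. The packaged
  data carry discordant references for 19 of the 37 variants (different
  public databases, different source breeds), so any rule keyed on "the"
  reference would be ill-defined. References only separate the descriptive
  labels P3 and P5, and an ambiguous reference containing the shared
  homozygous allele resolves to P5 (wild type is whatever allele is fixed
  in the unaffecteds).
* With two affected and two unaffected samples the filter has meaningful
  specificity but no multiplicity correction: the chance that an unlinked
  Hardy–Weinberg site of alternate-allele frequency p survives is
  (2p(1−p))^nA · ((1−p)²)^nU, ≈ 4.4% per site at p = 0.25, nA = nU = 2
  (`simulate.expected_null_pass_rate`). This is the quantity the
  Monte-Carlo tests check. The genotype-only rule can in principle also
  fire on the *reference* allele (all affected het, all unaffected
  homozygous alternate, probability (2p(1−p))^nA · p^(2nU)); that event is
  excluded from the null-rate comparison by conditioning on the returned
  candidate being the simulated alternate, which is what the closed form
  describes.

## Parsimony haplotyping

`haplotype.min_parsimony_phase` finds a phasing of the unphased matrix that
minimises the number of distinct haplotypes across all chromosomes — pure
parsimony, no recombination, mutation or frequency model; alleles
(including indel and repeat-length alleles) are opaque symbols. The search
is exact:

1. Columns with the same cross-sample genotype pattern up to allele
   relabelling are collapsed to one representative (identical columns phase
   identically in some optimum; a property test compares collapsed against
   uncollapsed search on random tables).
2. Each sample's phase choices over the h heterozygous collapsed columns
   are the 2^(h−1) unordered splits; a depth-first search over samples
   prunes any branch whose running distinct-haplotype count exceeds the
   best complete solution.
3. Ties are broken by the lexicographically smallest sorted tuple of
   rendered haplotypes, then by the per-sample assignments, so output is
   deterministic. Labels Hap1, Hap2, … are assigned by descending
   chromosome frequency, then rendering.

A guard (default: 16 heterozygous collapsed columns per sample) rejects
inputs whose search space could not be enumerated; the packaged four-dog
matrix collapses from 37 sites to 5 pattern columns and phases in
milliseconds. The published five-haplotype assignment is verified
separately by `check_phasing`, which is pure bookkeeping (site-wise
multiset comparison) and does not depend on the search. Equally
parsimonious five-haplotype solutions exist that differ from the published
one in how the all-heterozygous repeat columns pair; the package reports
its deterministic optimum and verifies the published assignment as given.

## Consequence mapping

CDS coordinate arithmetic is the standard one: position 1 is the first base
of the initiation codon, residue = ⌈p/3⌉, offset = ((p−1) mod 3)+1; cDNA
9772 therefore falls on the first base of codon 3258. Translation uses the
standard genetic code (Biopython). Charge deltas use D,E = −1 and K,R = +1
with histidine neutral at physiological pH, so the glutamic-acid-to-lysine
change scores +2 — a charge reversal. Non-exonic variants are not
annotated (no splice or regulatory model). The exon's implied CDS start
(9731) is carried as metadata only, since feature-relative and CDS
coordinates are both used in the packaged table.

## Grantham GV/GD scoring and classification

The Grantham distance combines side-chain composition, polarity and volume:
D(x,y) = ρ·sqrt(α Δc² + β Δp² + γ Δv²), α = 1.833, β = 0.1018,
γ = 0.000399. The package ships the 1974 property table and uses the
conventional scale constant ρ = 50.723, defined by the requirement that the
mean over the 190 unordered residue pairs be 100. Recomputing that
calibration from the shipped (rounded) property table gives ρ = 50.790 —
a 0.13% drift; `calibrate_rho()` exposes the recomputation and a test pins
the agreement. The conventional constant is the default because it
reproduces the published distances to printed precision, D(E,K) = 56.87 in
particular.

For an alignment column, GV applies the same form to the per-property
ranges of the observed residues (0 for an invariant column), and GD to the
variant's per-property deviation from those ranges (0 inside the range,
distance to the nearer bound outside). A (GV, GD) pair is graded into
seven classes by GD ≥ x + tan(10°)·GV² for x ∈ {15, 25, 35, 45, 55, 65};
the label is the largest x satisfied, else C0. The printed classifier rule
is stated only for the C55 boundary; the other six reuse the same
functional form, and "Tan(10)" is read as degrees with GV squared — for an
invariant column (GV = 0) every reading coincides, which is the only case
asserted. E→K against an invariant glutamic-acid column scores
(GV, GD) = (0, 56.87) → C55, the second-highest severity grade.

Column conservation (`conservation_fraction`) is the fraction of gap-free
columns at which all sequences agree — the asterisk convention of published
alignment figures — not average pairwise identity. The cross-species
homology percentages reported for the real protein (74/84/89%) require
external sequence downloads and are deliberately not recomputed; the
published PolyPhen-2 and SIFT scores are likewise carried as metadata
constants only, as both tools are trained/database-backed.

## In-silico allelic discrimination

The TaqMan-style assay is modelled combinatorially. An amplicon is the
substring from an exact forward-primer match through the reverse complement
of the reverse primer (both template strands searched; multiple possible
amplicons are an error, not a choice). Each chromosome is typed by exact
containment of exactly one of the two probes — which differ at the single
variant base (GAG vs AAG core) — on either strand; both-or-neither is
ambiguous and the sample becomes a no-call, never a guess. No melting
temperature, mismatch tolerance or fluorescence intensity is modelled:
for probes differing at one interior base, exact containment reproduces
the discrimination logic, and the wet-lab physics is out of scope.
Cosegregation is summarised as a status × carrier-state contingency table
with a concordance fraction (affected het carriers plus unaffected
non-carriers over called samples; no-calls excluded from the denominator).

## Synthetic cohort generator

`simulate.simulate_cohort` draws cohorts with the structure the filter
assumes, so every stage is testable without any external download:

* Affected individuals are heterozygous carriers with the causal allele on
  a chromosome labelled as the shared founder haplotype (identity by
  descent from a common ancestor); unaffected individuals are non-carriers
  at full penetrance, or heterozygous carriers with probability
  1 − penetrance below it. Causal homozygotes are never generated
  (embryonic lethality), regardless of penetrance.
* Background sites are biallelic, unlinked and independent across sites
  and chromosomes, drawn under Hardy–Weinberg at per-site alternate-allele
  frequencies: either one fixed value or per-site Beta(a, b) draws. The
  default Beta(1, 1) (uniform) reflects background polymorphisms of
  unknown frequency; statistical tests use fixed frequencies so closed
  forms apply. Founder sharing is modelled only through the causal allele's
  chromosome label — background alleles are not copied between affecteds,
  which keeps null sites exactly Hardy–Weinberg.
* Genotyping error, when enabled, is a symmetric per-allele flip at the
  stated rate — the simplest mechanism that exercises the filter's failure
  modes (sensitivity decreases monotonically in the rate, as the trend
  test checks).
* One master seed; each stage derives an independent stream from a fixed
  stage offset, so adding a stage never perturbs earlier ones and the same
  seed reproduces a cohort bit for bit.

`simulate_amplicons` embeds the wild-type or mutant probe core between the
printed primers according to each chromosome's true causal allele, inside
random flanks that are rejection-sampled to contain no spurious primer or
probe match.

What passing the synthetic tests shows: the filter, phasing, scorer and
assay logic are each correct against independent oracles (closed forms,
exhaustive enumeration, construction invariants) under the model's own
assumptions. What they do not show: robustness to missing genotypes,
genotype-quality uncertainty, linkage between background sites, population
structure, or reduced penetrance in the ascertainment itself — none of
which the model covers.

## Problem sizes and runtime

The default test suite and the acceptance script are desk-scale: the
Monte-Carlo null-rate check uses 10,000 sites per frequency, planted-variant
recovery 1,000 replicate cohorts, the assay cross-check one 149-sample
cohort, the phasing oracle 200 random tables, and the lethality invariant
10,000 simulated individuals; everything completes in well under a minute
on one core.

## Known limitations

* The genotype-table dialect models exactly the observed data shapes
  (point and range positions, base-string / run-length / deletion /
  segment-presence tokens); there is no missing-call state — an empty cell
  is a parse error.
* VCF export renders run-length alleles as literal base runs and the
  unrecorded 59-bp deletion as a placeholder N run, so VCF round-trips are
  lossless only for literal-allele tables.
* The two-adjacent-nucleotide substitution in the packaged table is
  represented as two single-nucleotide rows, matching the per-nucleotide
  haplotype encoding; a general MNV model is out of scope.
* Parsimony phasing is exponential in the worst case and guarded, not
  approximated; statistical phasing is a non-goal.
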