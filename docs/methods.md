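# Methods

This note documents the models, formulas, numerical choices and
limitations behind each `captivekin` module, in the order data flows
through the pipeline.

## Data model

A studbook row is (id, sire, dam, sex, birth year, alive); unknown
parents are `None` (accepted as empty or `UNK` on input). Microsatellite
genotypes are unordered pairs of positive-integer allele labels
(fragment sizes treated as opaque categories — no binning), stored
smaller-first, with a call either fully present or fully missing; a
half-missing call is rejected at parse time rather than silently
dropped, because a lone allele cannot be distinguished from a phantom
second allele. Sequence panels are pre-aligned haplotypes plus
per-individual assignments (one label for the haploid mitochondrial
marker, an unordered pair for the diploid MHC locus).

## Sequence diversity (`seqdiv`)

Sites carrying an ambiguity code or gap in any assigned copy are
excluded from all distance and polymorphism computations (complete
deletion); for collapsing, `N` acts as a wildcard so an ambiguous copy
merges with a compatible resolved one. Over the n assigned gene copies:

* k = mean pairwise difference count over all C(n, 2) copy pairs;
  π = k / (sites analysed).
* π(JC) applies the Jukes–Cantor correction per pair,
  d = −(3/4) ln(1 − 4p/3), then averages. Correcting each pair before
  averaging (rather than correcting the mean p) matches the per-site
  diversity notion; at within-population divergences the difference is
  far below reporting precision. p ≥ 0.75 raises an error.
* H_d = n/(n−1) (1 − Σ p_i²) over collapsed-haplotype frequencies.
* Mutation counts per polymorphic site are the parsimony minimum
  (distinct bases − 1), assigned to transitions within {A,G}/{C,T}
  first; hence transitions + transversions ≥ S when sites carry more
  than two bases.

Tajima's D uses the classical constants (a1, a2, b1, b2, c1, c2, e1,
e2 as functions of n) with S segregating sites and k as above. Fu &
Li's D* uses total mutations η and singletons η_s (alleles carried by
exactly one sequence) with the corrected variance constants in common
software use; the widely known misprint in the original constants is
avoided. Both statistics are validated against independent coalescent
machinery in the test suite: per-replicate Tajima's D agrees with
tskit's implementation, and over msprime genealogies at n = 20 the
null mean of D is within ±0.1 of zero and D* has near-zero mean and
near-unit spread.

Significance flags come from a built-in Kingman-coalescent simulator:
genealogies for n tips, a fixed number of mutations scattered on
branches proportionally to length, two-tailed empirical p-values with
(b+1)/(m+1) smoothing. The internal engine is itself cross-checked
against msprime in the tests.

### Haplotype phasing

Individuals are typed as per-site base sets (what Sanger sequencing of
both alleles together shows). Resolution proceeds: homozygotes and
signatures matching exactly one panel pair (probability 1) → pedigree
transmission constraints using already-resolved parents (a pair no
parental assignment can produce is eliminated) → EM on panel haplotype
frequencies for the rest. Pairs with posterior below 0.9 are reported
unresolved, never guessed — mirroring the >90 % reconstruction
threshold used when this locus is phased in practice.

### Minimum spanning network

Kruskal's algorithm over raw pairwise difference counts with
deterministic tie-breaking (edges sorted by weight, then label pair).
Raw counts are used for edge weights because the network's hatch marks
denote integer mutational events; a Tamura–Nei (1993) distance matrix
is also emitted for reference. MST weight is verified against
exhaustive spanning-tree enumeration for panels of ≤ 7 haplotypes.

## Microsatellite diversity (`msatdiv`)

Per locus over typed individuals: H_O is the heterozygote fraction;
H_E is Nei's unbiased gene diversity (2n/(2n−1))(1 − Σ p_i²);
F_IS = 1 − H_O/H_E — the definitional form used in the field's
reporting rather than Weir–Cockerham's variance-components estimator,
so negative values directly read as heterozygote excess. Allelic
richness R_S(g) = Σ_a [1 − C(N−N_a, g)/C(N, g)] rarefies to g gene
copies; g defaults to twice the minimum number of typed individuals
over loci (the FSTAT convention). P(ID) = Σp_i⁴ + Σ_{i<j}(2p_ip_j)² and
P(ID)sib = 0.25 + 0.5Σp_i² + 0.5(Σp_i²)² − 0.25Σp_i⁴, multiplied across
loci under independence.

HWE and LD tests are Monte-Carlo permutation tests (default 10,000
replicates): HWE shuffles the locus's gene copies into new pairs and
uses the heterozygote-count tails (the deficit tail doubles as the
homozygote-excess/null-allele diagnostic; a dedicated null-allele
algorithm is out of scope); LD permutes one locus's genotypes across
individuals with Σ Δ² over allele pairs (Burrows composite) as the
statistic. All Monte-Carlo p-values use (b+1)/(m+1) smoothing. Type-I
error is verified at 0.05 ± 0.02 over 200 null tables in the tests.

## Relatedness (`relatedness`)

Single-locus likelihood P(g1, g2 | k) = k0 P0 + k1 P1 + k2 P2, with P1
computed by conditioning on the shared IBD allele drawn from the
population frequencies; the table is validated against an exact
enumeration oracle to 1e−12. Estimation maximizes the summed
log-likelihood over the (k0, k1, k2) simplex by grid search at step
0.01 plus a 0.001-step local refinement (r is reported to 2–3
decimals, so finer optimization buys nothing). The search is
restricted by default to the genetically feasible cone
k1² ≥ 4 k0 k2: every relationship realizable by a pedigree lies inside
it, and the infeasible region only admits spurious finite-sample
maxima — without the restriction the estimator's boundary bias at true
r = 0 (≈ +0.05–0.06 at 14 loci) breaches the package's ±0.05
parameter-recovery contract. `feasible_only=False` restores the
unrestricted estimator. Genotyping error is deliberately ignored here
(it enters only the parentage likelihoods).

Classification evaluates the likelihood at U = (1,0,0),
HS = (½,½,0), FS = (¼,½,¼), PO = (0,1,0); ties break toward the less
related category. Confidence sets are parametric bootstrap: dyads are
simulated under each non-best category (restricted to the observed
dyad's co-typed loci), and a category is rejected when the observed
log-likelihood gap to the best category exceeds the simulated 95th
percentile. The production default is 100,000 randomizations; the test
suite uses 1,000–2,000, which is ample to separate PO from U at 14
loci. Category-wise comparisons use one-way ANOVA plus Tukey HSD with
Q and p taken from the studentized-range distribution
(cross-checked against statsmodels in the tests).

Parameter recovery under the synthetic-data frequency profile (1,000
dyads per category, 14 loci): mean r̂ within ±0.05 of 0 / 0.25 / 0.5 /
0.5 for U / HS / FS / PO.

## Parentage (`parentage`)

The transition probability of an offspring genotype given one or two
parents is exact Mendelian enumeration of gametes, with an untyped
parent integrated over the population under HWE (verified to sum to 1
over offspring genotypes). Genotyping error enters as the per-locus
mixture L = (1−ε)T + ε P_HW(offspring) — the classic single-parameter
simplification — applied identically to the candidate and unrelated
hypotheses; ε defaults to 0.01 (no error rate is fixed by the study
this emulates, so it is configurable and echoed in output). LOD is the
summed natural-log ratio; mismatches count loci with T = 0; with ε = 0
one mismatch excludes. Delta is the LOD gap between the top two
candidates; genotypically identical candidates give Delta = 0 and an
ambiguous decision.

The MHC trio check asks whether a bijective assignment of the two
offspring haplotypes to the two parents exists, each haplotype present
in the assigned parent's pair (an untyped parent accepts anything);
the transmitted haplotypes are reported when unique. Case resolution
runs Mendelian exclusion → LOD/Delta ranking → MHC veto/confirmation,
returning `supported`, `ambiguous`, or `true parent unsampled` when
every candidate is excluded. Detection power: at 14 loci, an injected
recorded-dam error (true dam's full sister) is flagged in well over
80 % of simulated cases.

## Effective population size (`ne`)

Burrows composite disequilibrium per allele pair,
Δ̂ = [mean(X·Y)/2 − 2 p̂_A p̂_B] · S/(S−1), normalized by
(p_A(1−p_A) + D_A)(p_B(1−p_B) + D_B) where D is the within-locus
departure from HWE — the composite-correlation denominator, which makes
no random-mating assumption and equals Var(dose)/2. The S/(S−1) factor
matters: without it the estimator's pure-sampling expectation sits 5 %
below the published calibration E(r²_sample) = 1/S + 3.19/S²
(0.0018 + 0.907/S + 4.44/S² for S < 30), which propagates into ~50 %
upward bias in N̂_e at S = 50. r² is clipped at 1 (a squared
correlation cannot exceed it; only near-perfectly associated pairs are
affected). Alleles rarer than P_crit (default 0.006) are dropped
before forming comparisons; each allele-pair comparison carries equal
weight, so locus pairs contribute proportionally to their comparison
counts, and S is the comparison-weighted harmonic mean sample size.

Inversion of r2' = mean r² − E(r²_sample):
N̂_e = (1/3 + √(1/9 − 2.76 r2'))/(2 r2') under random mating and
(2/3 + √(4/9 − 7.2 r2'))/(2 r2') under monogamy; r2' ≤ 0 yields an
infinite estimate. The same sampling expectation serves both mating
systems — the published monogamy-specific sampling constants are not
restated in the source this emulates, and the mating system already
enters through the inversion; the monogamous estimate therefore always
exceeds the random-mating one on identical input, matching the
published pattern. Exact numeric agreement with archival N̂_e values is
expected to be approximate since the original software's allele-pair
weighting is not fully documented.

The 95 % CI is a delete-one-individual jackknife converted to an
effective chi-square df, n' = 2/CV², on the mean r² — the published
jackknife form for this estimator — giving asymmetric intervals;
endpoints pass through the monotone r2' → N̂_e map. Under Wright–Fisher
simulation at true N_e = 50 (S = 50, 14 loci × 8 alleles, 100
replicates) the median estimate is within 30 % and CI coverage is
≥ 85 %; the residual ≈ +20 % median bias under whole-population
sampling is a known property of this estimator class, not corrected
post hoc.

## Pedigree and reconciliation (`pedigree`)

Kinship is the standard recursion f(i,i) = (1 + F_i)/2,
f(i,j) = (f(sire_i, j) + f(dam_i, j))/2 recursing on the later
generation, founders mutually unrelated and non-inbred — the studbook
convention whose violations the reconciliation machinery exists to
surface. It is verified against 50,000-replicate gene-dropping IBD
simulation to within 0.01. Dyads classify as
PO/FS/HS/AV/GP/FC/U by the closest category (highest expected r) when
several apply; kinship always retains the full path sum, so
classification is reporting, kinship is arithmetic.

The consistency report maps studbook categories onto the 4-category
genetic classifier: PO↔PO, FS↔FS, HS↔HS, U↔U, and AV/GP/FC accepted as
genetic HS or U (a 4-category likelihood cannot name them; their
expected r of 0.25/0.25/0.125 lands them in those bins). Dyads with
r̂ > 0.6 are flagged as unexpectedly high relatedness. Marker overlay
flags an offspring whose mtDNA differs from its recorded dam's and any
trio failing the MHC check. On noise-free synthetic data the
consistent fraction is 1.0 and zero violations are flagged.

## Synthetic data (`simulate`)

The generator's default profile reproduces the structure of the
population the pipeline was built to audit: 28 founders, two
descendant generations of monogamous non-inbred pairings (litters
Poisson with mean 3, or negative binomial when a dispersion is set),
giving ~110–160 individuals across three generational layers; 14
unlinked microsatellite loci with 4–14 alleles and symmetric
Dirichlet(1.0) frequency priors — chosen because that prior reproduces
the published per-locus gene-diversity profile (mean H_E ≈ 0.78,
SD ≈ 0.10, against 0.746 ± 0.086) for this allele-count range; two
mitochondrial haplotypes near 0.596/0.404; ten MHC haplotypes at the
published North American frequency profile with one dominant (~0.43)
haplotype. Gene dropping transmits one uniformly chosen allele per
parent per locus, the dam's mtDNA, and one MHC haplotype per parent.
No microsatellite mutation is simulated (3–4 generations; mutation is
negligible at that depth).

Corruption operators are separate and ledgered: per-allele genotyping
error (frequency-weighted replacement), per-call missingness, and
studbook errors (recorded dam → her full sister; recorded sire → his
brother; recorded sire → an unsampled external male). The ledger
records every alteration so tests assert against injected truth, never
against re-derived truth. The Wright–Fisher sampler provides
constant-size populations under random or monogamous pairing for N_e
validation. All generators are deterministic given their seed.

What the generator does **not** emulate: allele dropout/stutter
structure in the error model (errors are symmetric replacements),
age-structured or overlapping generations, reproductive skew beyond
monogamous litters, population subdivision across institutions, and
microsatellite mutation. Passing tests therefore demonstrate
correctness of the estimators under idealized Mendelian transmission
with simple noise, not robustness to every artifact of real
fragment-calling pipelines.

## Problem sizes in the validation suite

The heavy checks run at: 2,000 neutral coalescent replicates (Tajima
calibration), 1,000 dyads per relationship category (recovery), 200
null tables for HWE (5,000 permutations each) and LD (2,000 each), 100
Wright–Fisher replicates with full jackknife CIs (N_e), 200
dam-swap-injection replicates (error detection), 50,000 gene drops
(kinship oracle), and exhaustive spanning-tree enumeration to 7
haplotypes. These sizes keep the full suite to a few minutes on one
core while leaving Monte-Carlo error well below every tolerance
asserted.

## Known limitations

* Relatedness ignores inbreeding (no triadic/accounting-for-F
  estimator) and genotyping error; both are documented scope bounds.
* The LD N̂_e estimator inherits the known positive median bias of its
  class when the sample is the whole population.
* Phasing assumes the haplotype panel is complete; a genotype
  incompatible with every panel pair is an error, not a novel-haplotype
  call.
* F_IS is the definitional 1 − H_O/H_E, not a variance-components
  estimator; per-locus means across loci are reported, not a weighted
  global estimate.
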