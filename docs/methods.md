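# Methods

## Scope and data model

`sploshkit` operates on unphased biallelic SNP calls (states AA, AB, BB,
missing) for diploid individuals, positioned on a genetic map in
centiMorgans. The default map is 17 chromosomes of equal span summing to
a 1280 cM haploid length (the apple consensus map scale), with SNPs
evenly spaced; SNP count is a free parameter (default 2000). All
coordinates are chromosome-local cM; no physical positions are used.
Phase is never assumed from input — it is only ever deduced (from a
known parent) or known by construction (in simulation).

Metadata assigns each individual a recorded species label and a
reference group: `cultivar` (the domestic reference panel), `exotic`
(a verified exotic-*Malus* reference), `wild`, or `unknown`. Accessions
outside the two reference groups are the audited set.

Curation is call-rate filtering only: SNPs below a call-rate threshold
(default 0.95) are removed first, then individuals (default 0.90).
Cluster-level re-calling of raw array intensities is out of scope; the
package starts from called genotypes.

## SPLoSH

For a pair of genotypes, a SNP is *opposing* when one is AA and the
other BB; every other combination — including anything involving a
missing call — is compatible. Per chromosome, maximal runs of compatible
SNPs are found; a run's span is the cM distance from its first to its
last SNP, a deliberately conservative dialect (no extension toward
flanking opposing SNPs), chosen because it is deterministic and matches
a brute-force run enumeration exactly. Runs with span ≥ `threshold_cM`
and at least `min_snps_per_segment` SNPs (default 2, which drops
zero-span single-SNP runs) are retained and summed genome-wide.

`error_tolerance` (default 0) allows up to that many *isolated* opposing
SNPs (both neighbours compatible) to be forgiven per run — a guard
against undetected null alleles and genotyping error. The default keeps
segmentation exactly equal to the enumeration oracle; a tolerance of
about 1 per 20 SNPs is reasonable for noisy panels and only ever
increases sums (monotonicity is property-tested).

A sum of *S* cM corresponds to *S* / (2 × total map length) of the
diploid genome. The self-sharing diagonal of the all-pairs matrix is set
to the SNP-covered map span and is never consumed by downstream rules.

Background levels matter for interpretation: between species pools
(F<sub>ST</sub> ≈ 0.3) unrelated pairs score tens of cM at the 20 cM
threshold, far below every rule threshold; *within* a pool, reduced
heterozygosity makes long compatible runs common (hundreds of cM between
unrelated individuals), which is exactly why the relationship rules are
only interpreted for audited-accession-versus-cultivar pairs and why
thresholds sit well above cross-pool background but below true
relationship signal.

## Relationship inference

Precedence is total and exclusive: duplicate ≻ parent–offspring ≻
grandparent-level; no pair appears under two types.

* **Duplicates**: non-missing concordance ≥ 0.995. With a 0.2% per-call
  error rate the expected clone-pair concordance is ≈ 0.996, so the
  default sits just below it; duplicate groups are connected components
  over called pairs, labelled with stable `UG....` codes.
* **Parent–offspring**: opposing-homozygote rate ≤ 0.005 over co-called
  SNPs. Direction is not inferred — the genotype evidence is symmetric.
  Unrelated same-pool pairs have OH rates two orders of magnitude above
  the threshold at 2000 SNPs.
* **Grandparent-level**: SPLoSH(20 cM) ≥ 512 cM. The theoretical sharing
  after two meioses is 25% (640 cM); 20% is used so that threshold
  attrition of short IBD segments and meiotic variance do not exclude
  real cases. Half-sib and comparable second-degree relationships
  produce the same signal; calls are therefore labelled
  `grandparent_level`, not resolved further.

**Deduced gametes.** Where one parent is known, the allele the offspring
received from the *other* parent is determined per SNP (offspring
homozygous → that allele; offspring heterozygous with homozygous parent
→ the other allele; both heterozygous → ambiguous; missing or opposing
→ unknown, the latter counted as a possible null/error). Scanning the
deduced gamete against candidate individuals (a candidate is
incompatible where it is homozygous for the allele the gamete excludes)
and summing compatible segments at 20 cM ranks likely second parents;
the true parent is recovered as rank 1 in ≥ 95% of zero-noise trials
with 50 candidates.

**Imputation of ungenotyped parents** pools deduced gametes across a
full-sib family per SNP: both alleles observed → heterozygous; a single
allele with ≥ `min_support` (default 2) unambiguous observations →
homozygous; else unresolved. The imputed fraction counts resolved allele
slots out of 2 × n<sub>SNPs</sub>. The known limitation of per-SNP
pooling without cross-offspring phasing: at SNPs where every informative
offspring happens to carry the same transmitted allele, a truly
heterozygous parent is called homozygous (probability (3/4)<sup>8</sup>
per both-parents-heterozygous SNP in an 8-offspring family). Accuracy is
therefore reported per resolved allele slot — the same units as the
imputed fraction — and converges to 100% as families grow; raising
`min_support` trades imputed fraction for accuracy.

**Null-allele flagging**: a SNP at which an individual shows an opposing
homozygote against ≥ 2 distinct confirmed first-degree relatives cannot
be a single genotyping error and is flagged as candidate null-homozygous.
This repeated-inconsistency rule is a deliberate simplification of full
descendant-based curation.

## Classification

Applied per audited accession against the cultivar reference, in strict
precedence: (1) duplicate of a cultivar, or ≥ 2 cultivar parent–
offspring partners ("both identified parents cultivars") → fully
domestic; (2) one cultivar parent or any cultivar grandparent-level call
→ hybrid; (3) SPLoSH(20) > 256 cM (10%) with any *single* cultivar
(maximum, not sum, over cultivars) → species with a domestic component;
(4) SPLoSH within 192–256 cM (7.5–10%) against ≥ 3 distinct cultivars →
flagged, not called admixed; (5) otherwise pure, pending ordination.
An exotic component (SPLoSH(20) > 256 cM with the exotic reference,
whose members must themselves lack cultivar SPLoSH above the flag band)
annotates any status and becomes the primary status only when nothing
else fires. Threshold coherence (256 = 10% and 512 = 20% of the diploid
map) is asserted at pipeline start, with a 2% relative tolerance to
absorb chromosome-end coverage lost to SNP curation.

Deeper all-cultivar pedigrees without genotyped parents legitimately
fall to rule (3) and are surfaced for review rather than auto-called
fully domestic. Summaries report, per recorded label, n and the
percentage pure / hybrid-admixed / fully cultivar.

## Ordination and outlier flagging

Accessions still presumed pure are ordinated by PCA on their vectors of
SPLoSH(5 cM) sums against the other audited (wild) accessions — not raw
SNPs — which equalises SNP informativeness across chromosomes and
absorbs linkage. Rows are used directly as features (mean-centered by
the decomposition), not double-centered into a kernel. Declared full-sib
families are replaced by their (possibly imputed) parents before
ordination so family structure does not masquerade as species structure.

Outliers are flagged per labelled species cluster on the first two
components using a robust distance: median center and MAD-scaled spread
per component (PCA components are orthogonal, so diagonal scaling
suffices; median/MAD have a 50% breakdown point, so a few mislabeled
admixed individuals cannot mask themselves). The flagging cutoff is the
0.995 quantile of the *null* distribution of within-cluster distances,
calibrated by Monte Carlo on standard-normal clusters of the same size
and dimension — at genebank cluster sizes (tens of accessions) the
chi-square approximation is badly miscalibrated for any robust distance,
and minimum-covariance-determinant estimates are additionally unstable
(their small-sample null quantile varies several-fold across
calibration runs), which is why the simpler median/MAD rule was chosen.
Clusters smaller than 4 or with zero spread are skipped with a warning.
In simulation this yields no false flags on pure clusters of 12–20 and
flags ≥ 80% of individuals carrying 25% foreign ancestry.

## Simulator

The generator defines the study conditions all recovery claims refer to:

* **Gene pools**: per SNP, an ancestral frequency Uniform(0.05, 0.95)
  and pool frequencies from a Balding–Nichols Beta with F<sub>ST</sub>
  = 0.3 by default — strong differentiation appropriate for distinct
  *Malus* species; the Hudson estimator recovers the parameter within
  ±0.05 in tests.
* **Founders**: Hardy–Weinberg draws within their pool; each founder
  haplotype is a tracked ancestry unit.
* **Meiosis**: crossover count per chromosome Poisson(span/100), uniform
  positions, random starting homolog — Haldane's no-interference model,
  the simplest consistent with cM arithmetic. Every descendant haplotype
  is a founder-haplotype mosaic, so true IBD sharing, ancestry fractions
  and transmitted gametes are exact, not estimated.
* **Cultivar endogamy**: the cultivar panel can be given second-
  generation depth (cultivars crossed from cultivar founders, default 4
  offspring from 10 founders in the canned audit scenario), reproducing
  the inflated within-cultivar sharing background of real collections —
  and giving clones of those cultivars genotyped parents, as is typical
  for documented cultivars.
* **Noise**: null alleles are a third, silent founder allele (A∅
  displays AA, ∅∅ displays missing) applied per founder haplotype and
  *inherited*, so they create the apparent Mendelian inconsistencies the
  null detector looks for; genotype errors flip to a uniformly chosen
  other non-missing state (default 0.2%); missingness is applied last
  (default 1%).

What the simulator does **not** emulate: within-pool linkage
disequilibrium beyond pedigree structure, selection, mutation, array
ascertainment bias, sex chromosomes, and batch effects. Passing recovery
tests therefore demonstrate correctness of the inference machinery under
the stated model, not field performance on any particular array.

All randomness flows through one explicit seed (`numpy` Generators);
identical seeds give byte-identical outputs, and the pipeline derives
per-stage child seeds from the global seed by a fixed CRC-based fan-out.

## Problem sizes and numerical choices

Recovery checks run at 2000 SNPs on the default map: duplicate and
parent–offspring recall are exact (100%, zero false positives) at zero
noise; grandparent-level recall ≥ 90% over 200 replicate pedigrees; the
classification confusion matrix uses 50 replicate 32-individual panels
at default noise (per-class recall ≥ 90% for pure, F1 hybrid and
cultivar clone); imputation quality uses 30 replicate 8-offspring
families; the grandparent-sharing expectation (25%) is estimated over
≥ 1000 replicates of two meioses, for which a sparse 2-SNP-per-
chromosome map is used since the truth is segment-based and independent
of SNP density. Segment detection is verified exactly against a
brute-force maximal-run enumerator on 1000 random ≤ 50-SNP chromosomes.

Tie-breaks and degenerate inputs: equal-position SNPs are ordered by
SNP id; zero-span chromosomes never recombine; candidate rankings break
ties alphabetically; an all-ambiguous deduced gamete is reported
uninformative rather than ranked; an empty exotic reference disables the
exotic check with a warning.
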