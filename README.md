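# sploshkit

Genebank collections of crop wild relatives — for apple, *Malus
sieversii*, *M. orientalis* and *M. sylvestris* alongside the domestic
*M. domestica* — accumulate mislabeled material: clones of cultivars
deposited under wild names, undeclared cultivar × wild hybrids, and
deeper admixture. `sploshkit` audits the recorded species label of each
accession from unphased biallelic SNP-array genotypes, using shared-
haplotype evidence rather than model-based ancestry estimation (which is
unreliable under the heavy pedigree structure typical of such panels).

## Method

The core statistic is **SPLoSH** (Summed Potential Lengths of Shared
Haplotypes). Two unphased genotypes *could* share a haplotype wherever
they show no *opposing homozygotes* (one individual AA, the other BB).
Per chromosome, maximal runs of compatible SNPs are measured in cM on a
genetic map (17 chromosomes, 1280 cM haploid by default) and runs at
least *t* cM long are summed genome-wide; missing calls can never
contradict sharing. At *t* = 20 cM the sum feeds relationship inference;
at *t* = 5 cM it is the input feature space for ordination. A sum of
*S* cM represents *S* / (2 × 1280) of the diploid genome: 256 cM = 10%,
512 cM = 20%.

On this evidence the pipeline applies, in order of precedence:

1. **Duplicates** — non-missing genotype concordance ≥ 0.995; duplicate
   groups get stable unique-genotype codes.
2. **Parent–offspring** — opposing-homozygote rate ≤ 0.005 (direction is
   resolved from provenance, not genotypes). Where one parent is known,
   the gamete from the unknown parent is deduced per SNP and scanned
   against the panel to find likely second parents; ungenotyped parents
   of full-sib families are imputed by pooling deduced gametes.
3. **Grandparent-level** — SPLoSH(20 cM) ≥ 512 cM, i.e. ≥ 20% of the
   diploid genome, deliberately below the theoretical 25% sharing after
   two meioses so that segment-length attrition and meiotic variance do
   not exclude real relationships (half-sibs are indistinguishable at
   this evidence level).
4. **Classification** — fully domestic (duplicate of a cultivar or both
   identified parents cultivars), hybrid (a cultivar parent or
   grandparent), cultivar component/admixed (> 256 cM SPLoSH with any
   single cultivar), a 7.5–10% flag band against numerous cultivars, an
   exotic-*Malus* component check against a verified exotic reference
   panel, else pure.
5. **Ordination** — accessions still presumed pure are ordinated by PCA
   on their SPLoSH(5 cM) profiles; individuals far outside their labeled
   species cluster (robust distance beyond a calibrated null quantile)
   are flagged as possible hybrids/admixed.

A forward simulator (Balding–Nichols gene pools, Hardy–Weinberg
founders, Poisson/no-interference meiosis on the cM map, clones, null
alleles, genotype error and missingness) provides panels with exact
ancestry truth, so every stage is testable against known answers.

## Worked example

```python
import sploshkit as sk

# a simulated audit: 14 reference cultivars, 10 wild accessions,
# 5 F1 hybrids and 3 cultivar clones filed under the wild label
panel, truth = sk.simulate_audit_panel(seed=7)
results, summary = sk.classify_panel(panel)
print(summary.to_string(index=False))

m20 = sk.splosh_matrix(panel, sk.SploshConfig())
s = m20.value("f1_000", "domestica_000")
print(f"SPLoSH(20) F1 vs its cultivar parent: {s:.0f} cM "
      f"= {100 * sk.genome_fraction(s, panel.gmap):.1f}% of the diploid genome")
```

prints

```
    label  n  n_pure  n_hybrid_admixed  n_cultivar  pct_pure  pct_hybrid_admixed  pct_cultivar
sieversii 18      10                 5           3      55.6                27.8          16.7
SPLoSH(20) F1 vs its cultivar parent: 1227 cM = 47.9% of the diploid genome
```

The 18 audited accessions recorded as *M. sieversii* resolve into the 10
truly pure ones, the 5 hybrids (each with its cultivar parent named in
the per-accession table) and the 3 cultivar clones; the F1 shares about
half its diploid genome with its cultivar parent, as expected for a
parent–offspring pair.

A CLI mirrors the library: `sploshkit simulate | convert | splosh |
relate | impute | classify | pca | run` (see `sploshkit --help`).

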