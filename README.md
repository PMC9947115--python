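# cellhap

Trio-anchored fetal haplotype inference and quality control for
**cell-based noninvasive prenatal testing** (cbNIPT).

## The problem

A handful of circulating trophoblast cells (cTBs) in maternal blood carry a
complete, maternal-DNA-free copy of the fetal genome. Sequencing a single
such cell could diagnose a monogenic disease without amniocentesis — but
single-cell whole-genome amplification (WGA) corrupts genotypes with
allele dropout (ADO, a heterozygous site amplifying only one allele) and
genotype errors, so the pathogenic variant cannot be read directly off the
cell. The standard remedy is **haplotype analysis**: instead of trusting
one site, infer which parental chromosome segment the fetus inherited from
many surrounding SNPs, using the genotypes of the father, mother and an
affected child (the proband) to phase the parents.

`cellhap` implements that analysis for families with a characterized
monogenic disease locus, plus the surrounding machinery:

* **STR confirmation** that a candidate cell is fetal (paternal-specific
  short-tandem-repeat alleles: present in the cell and father, absent from
  the mother);
* **QC metrics** — ADO ratio, false-positive ratio (FPR, genotype
  discordance against a matched reference sample), site/panel coverage,
  haplotypable-gene counts, and a subsampled depth-gradient analysis
  (1×–35×);
* a **synthetic family and single-cell generator** with an explicit WGA
  artifact model, so the whole pipeline is testable without any sequencing
  data.

## The method

Within a window (default ±2 Mb) around the disease locus:

1. **Informative SNPs.** A site is *IFF* (informative from father) when the
   father is heterozygous (AB) and the mother is not (non-AB); *IFM* is the
   mirror case. At such sites the allele the heterozygous parent
   transmitted to a child is read off the child's genotype by subtracting
   the homozygous parent's obligate allele.
2. **Phasing through the proband.** The carrier parent's haplotype that the
   proband inherited together with the pathogenic allele is labelled **P1**
   (paternal) / **M1** (maternal); the other is P2/M2. Assuming at most one
   crossover per transmitted chromosome (and none inside the window), every
   informative SNP's allele on haplotype 1 is then known.
3. **Key SNPs.** An informative SNP is *key* when the cell's observed
   genotype contains the allele the other parent cannot supply — an
   observation no single allele dropout could fake under the competing
   transmission. Other observations are non-key and abstain.
4. **Flank voting.** Key SNPs upstream and downstream of the locus vote for
   haplotype 1 or 2. Each flank decides by majority (vote fraction ≥ 0.8,
   ≥ 1 key SNP by default); the call requires both flanks to agree.
   Discordant flanks raise a recombination flag and yield *ambiguous* —
   never a forced call.
5. **Verdict.** P1/M1 → affected, P1/M2 → carrier (paternal),
   P2/M1 → carrier (maternal), P2/M2 → normal. For an X-linked locus and a
   male fetus only the maternal side exists: M1 → affected, M2 → normal.

The WGA noise model yields a useful closed form: with per-allele dropout
rate *d*, the probability that a truly heterozygous, called site reads
homozygous is `2d/(1+d)`, and with genotype-error rate *e* the observed
ADO ratio is `(2d(1−e)+e)/(1+d)` — which `cellhap.recover_artifact_rates`
inverts to estimate *(d, e)* from cell/reference concordance.

## Worked example

```python
import cellhap as ch

cfg = ch.SimulationConfig(n_snps=400, mean_depth=15, ado_rate=0.15,
                          fp_rate=0.05, seed=4)
truth = ch.simulate_family(cfg)          # autosomal recessive, both parents carriers
family = ch.merge_tables(truth.to_genotype_table(include_reference=True),
                         ch.observe_single_cell(truth))
results = ch.FetalHaplotypeModel(family, truth.locus).fit()
print(results.summary())
```

```
          Fetal Haplotype Inheritance
======================================================
Gene: GENE_A   Locus: chr7:100000000
Inheritance: autosomal_recessive   Fetal sex: female
Window: +/- 2,000,000 bp   Key mode: observed   Vote threshold: 0.8
------------------------------------------------------
Informative SNPs: 164   Key SNPs: 58

Parent    Haplotype   Up (1/2)    Down (1/2)  Recomb
father    P1          15/3         11/1         no
mother    M1          11/1         16/0         no
------------------------------------------------------
Verdict: affected
======================================================
```

Reading it: 164 trio-informative SNPs fell in the ±2 Mb window; 58 survived
as dropout-proof key SNPs. The paternal call is P1 (15 of 18 upstream and
11 of 12 downstream key SNPs vote for the pathogenic paternal haplotype;
the few against-votes are genotype errors from the 5% injected error
rate), the maternal call is M1 — so this fetus inherited both pathogenic
haplotypes and the verdict is *affected*, matching the planted truth
(`truth.fetal_transmissions`). With the same family,
`ch.ado_ratio(family, family)` ≈ 0.37 and
`ch.false_positive_ratio(family, family)` ≈ 0.16 quantify the injected
WGA noise against the clean REFERENCE sample.

The same analysis runs from files:

```bash
cellhap simulate --out-dir demo --seed 4
cellhap str-confirm --cell demo/str_cell.tsv --father demo/str_father.tsv \
                    --mother demo/str_mother.tsv
cellhap haplotype --vcf demo/family.vcf --locus demo/locus.yaml
cellhap run --config run.yaml        # full pipeline; exit code 2 = ambiguous
```

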