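# Methods

This note documents the models behind `cellhap`: what the synthetic data
generator emulates, how the haplotype caller decides, the parameter
defaults and why, the numerical corner cases, and what the tests do and
do not demonstrate about real sequencing data.

## Family and transmission model

A family is simulated around a monogenic disease locus on one chromosome:

* `n_snps` biallelic SNPs are placed uniformly at random in a window of
  `region_span` bp (default 4 Mb — 2 Mb per flank) centred on the locus
  anchor. Per-site minor allele frequencies are drawn uniformly on
  (0.05, `minor_allele_freq`] with default upper bound 0.5; real panels
  would show an ascertainment-driven MAF spectrum, which we do not model.
* Each parent is an explicit pair of haplotypes with alleles drawn
  independently per site from the site's MAF. A hemizygous father
  (X-linked mode) has a single X haplotype.
* The pathogenic variant of each carrier parent is a planted site where
  that parent is heterozygous with the ALT allele on haplotype 1 and the
  other parent is homozygous reference. A compound-heterozygous family
  needs two distinct sites (one biallelic site cannot make both parents
  heterozygous while keeping the other parent homozygous); by default
  they sit 1 kb either side of the anchor.
* Each meiosis transmits one haplotype with at most one crossover: a
  crossover occurs with probability `crossover_prob` (default 0.04,
  roughly 1 cM/Mb over a 4 Mb window) at a breakpoint uniform in the
  window. The proband is conditioned to inherit haplotype 1 from every
  carrier parent — it is the affected child that anchors phasing — by
  relabelling the drawn transmission when necessary, which preserves the
  crossover structure. Fetal meioses are unconstrained unless the config
  forces them (used by the verdict truth-table checks).

Parent, proband and reference (amniotic-fluid surrogate = true fetal
genotypes) samples are "gDNA quality": Poisson depth around `gdna_depth`
(default 30×, floored just above the caller threshold) with allele depths
split deterministically in proportion to the true allele copies, so their
genotypes are exact. All sampling-noise modelling is confined to the
single cell, which is the artifact the method must survive; bulk gDNA
genotyping error is far below the scale of WGA artifacts and is ignored.

## Single-cell observation model

Observing the fetus through WGA applies, per site:

1. total depth ~ Poisson(`mean_depth`) (negative binomial with shape
   `depth_dispersion` if set, for WGA-like overdispersion);
2. each true allele copy drops independently with probability `ado_rate`;
   the site's reads are then split binomially among surviving copies —
   dropout *reassigns* depth to the surviving allele, reflecting that the
   WGA reaction amplifies whatever template survived;
3. genotype calling with the strict caller (below);
4. with probability `fp_rate` a called genotype is replaced by a
   uniformly chosen *different* genotype. This overlay is a call-level
   error: allele depths are left untouched, and re-calling after depth
   thinning therefore washes it out (the depth-gradient analysis probes
   depth effects, not the error overlay).

Because dropout reassigns rather than removes depth, missingness is
independent of dropout and the probability that a truly heterozygous,
called site reads homozygous is exactly

    ado = (2 d (1 - e) + e) / (1 + d),

while discordance at reference-homozygous sites equals `e` (dropout
cannot change a homozygote). `recover_artifact_rates` inverts these:
`e_hat` = reference-hom discordance, `d_hat = (ado - e_hat) / (2 - 2
e_hat - ado)`. The inversion is exact up to one caller-noise term: near
the calling threshold a balanced heterozygote can read homozygous by
binomial read sampling (~1.7% of called hets at 15×, <1e-6 at 60×). The
closed-form checks therefore run at 60× mean depth; at the study depth
of ~15× the measured ADO sits slightly above the closed form, as real
data would.

## Genotype caller

A reads-based pipeline is out of scope; the caller is a transparent
surrogate. A site is **missing** unless total depth is *strictly greater*
than `min_call_depth` (default 10, matching the strict "coverage > 10"
filter convention for single-cell data). A diploid call is heterozygous
when both alleles reach `min_alt_fraction` (default 0.2) of the total —
a stand-in for quality-based het sensitivity, since base qualities do not
exist here — otherwise homozygous for the majority allele. Hemizygous
samples take the majority allele; ties fall to the reference allele
(deterministic, and only reachable through noise). Depth-gradient rows
re-call with `min_call_depth = 0` so ADO/FPR remain defined at 1×.

## Haplotype caller

* **Informative SNPs** require both parents called, exactly one parent
  heterozygous, the other homozygous (or hemizygous), and a proband
  genotype consistent with the obligate transmission; inconsistent sites
  (possible genotyping error) are dropped. For a male X proband only the
  mother constrains transmission, so IFM sites need only a maternal het.
* **Key marking** defaults to the observation-based rule: key iff the
  cell's genotype contains the distinguishing allele. The literal
  criterion "may be affected by ADO" is only decidable per observation —
  any informative site *could* be hit by dropout a priori. A `trio` mode
  is provided as the permissive alternative (only missing calls are
  dropout-affected; shared-allele homozygotes vote for the shared-allele
  transmission); it yields more votes but those votes are dropout-fragile,
  and the default remains `observed`.
* **Voting** is per flank (upstream/downstream of the locus anchor; a
  site exactly at the anchor counts as upstream, which can only occur for
  compound-het loci whose anchor is not itself a variant site). A flank
  decides when it has ≥ `min_key_snps` (default 1) votes, a strict
  majority, and a vote fraction ≥ `vote_threshold` (default 0.8). The
  threshold is a design choice: supporting counts are reported, but no
  published decision rule exists, so the default demands strong
  concordance and is configurable and logged in every report. Discordant
  flanks set the recombination flag and abstain — a conservative clinical
  posture, since a crossover between the flanks genuinely changes which
  haplotype spans the gene.
* A proband crossover *inside* the window is undetectable with a single
  proband: it silently mis-phases one side and surfaces as an ambiguous
  (flank-discordant) or, rarely, wrong call. The simulator's
  `crossover_prob` quantifies this error mode; the caller does not try
  to correct it.

## QC metrics

ADO ratio = hom-observed fraction among reference-het, cell-called sites;
FPR = discordant fraction among co-called sites. The denominators differ
deliberately (each metric conditioned on its informative subset) and both
are reported so other normalisations can be recomputed. An ADO-induced
het→hom change also counts toward FPR — any genotype difference is a
discordance — and the report annotates the overlap (`n_ado_in_fp`).
Genome coverage is the fraction of sites with ≥1 read, a site-level
surrogate for base-level coverage; panel coverage over intervals uses
exact merged-interval arithmetic (`region_overlap`), and a gene is
*haplotypable* when both its upstream and downstream flank windows
(default 2 Mb) contain at least one key SNP. Depth gradients use nested
binomial thinning (35× → 30× → …) so per-seed coverage is exactly
monotone in target depth.

## STR confirmation

The 16-locus forensic identity panel (15 STRs + amelogenin, X=0/Y=1) is
simulated with integer repeat alleles from a common pool; the cell
inherits one paternal and one maternal allele and each cell locus fails
to amplify with probability 1 − `detection_rate`. Scoring counts alleles
present in cell ∩ father − mother; "multiple" paternal-specific alleles
(threshold ≥ 2, configurable) confirms fetal origin. Amelogenin counts
toward the detection rate but never toward paternal-specific scoring;
alleles found in neither parent are flagged, not counted. Allele identity
is exact integer match — single-repeat PCR stutter is not modelled.

## What the synthetic data does not capture

Read-level artifacts (GC bias, chimeras, mapping error), linkage
disequilibrium and realistic MAF spectra, PCR stutter in STRs, maternal
cell contamination, and fetoplacental mosaicism. Passing tests therefore
demonstrate the *inference logic* — phasing correctness, dropout-robust
key selection, calibrated abstention, metric bookkeeping — under a
faithful artifact model, not performance on any particular sequencing
platform. Published per-cell metric values from real cells depend on
deposited reads and are not reproduction targets here.

## Problem sizes and determinism

Closed-form and rate-recovery checks use 100k sites; haplotype recovery
uses 200 families of 600 SNPs at dropout 0.2 / error 0.05; gradient
trends use 20 replicate cells of 2,500 SNPs across the 1×–35× ladder —
sizes chosen so every Monte-Carlo assertion has comfortable statistical
power while the whole suite stays interactive. All randomness flows from
`numpy.random.default_rng` seeded by the config (separate streams for
family, cell, STR and thinning draws); identical configs give
byte-identical VCFs and reports, and pipeline reports deliberately
exclude timestamps and output paths.
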