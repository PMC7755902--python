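# Methods notes

## The analysis model

The package implements the bespoke statistics of a two-population breast
tumour comparison as a chain of stages over standard tabular inputs
(MAF-like mutation tables, TPM/count matrices, purity/copy-number tables,
clinical tables).  Each stage is independent and library-first; the CLI and
`pipeline.headline_findings` only wire them together.

### Somatic filter cascade

Candidate calls are judged by fixed per-record rules, then by a cohort
recurrence rule.  Bound conventions follow the rule statements literally:

* depth floors inclusive (tumour ≥ 10 reads, normal ≥ 5);
* OxoG artefact metric strictly below 0.8;
* VAF floor inclusive at 0.075;
* two-sided Fisher exact test on the [[alt_fwd, alt_rev], [ref_fwd,
  ref_rev]] table, retained at p ≥ 0.05; an all-zero table yields p = 1 by
  convention (logged);
* S_AF strictly above 0.75 — the score has no public definition and is
  consumed as a caller-supplied column, never computed;
* gnomAD population frequency: removed when ≥ 0.01;
* ≥ 4 alternate reads with ≥ 2 per strand; indels additionally need the
  second caller's support.

Recurrence: positions seen in ≥ 5 samples are removed unless any record at
the position carries the COSMIC flag.  Exome pipelines often remove specific
recurrent artefact positions ad hoc; here that practice is generalised into
the "remove recurrent non-COSMIC positions" rule, and the
single-tandem-repeat flag is carried but unused by default.  A whitelist file (empty by default) reproduces manual
salvage of individual variants.  Coordinates are 1-based closed (MAF
convention).

### Driver scores

ONC = 100 × (missense count at the most recurrent amino-acid position) /
(all mutations of the gene in the stratum), defined only when the top
position has ≥ 5 missense hits.  TSG = 100 × (nonsense + frameshift +
essential-splice) / (all mutations), defined at ≥ 5 inactivating events.
"Inactivating" follows the 20/20-rule convention (nonsense, frameshift,
essential splice).  The denominator counts *mutations*, not mutated samples, and
includes whatever classes the input table carries (the filtered table
upstream is nonsynonymous).  Selection is strict: score > 20.  Ties at the
top position are irrelevant (only the maximum count enters).

### Mutual exclusivity

Gene × sample binarisation (any nonsynonymous mutation), top-k = 15 genes by
frequency, two-sided Fisher exact test per pair (two-sided so that co-occurrence
and exclusivity are tested symmetrically).  Sample odds ratio with no
Haldane correction — zero cells give OR 0 or ∞, and the log2 OR used for
plotting caps at ±10.  Bonferroni over the tested pairs.

### Signature refitting

Spectra are tallied into the standard 96 pyrimidine-centred channels;
purine-reference records are reverse-complemented.  Exposures solve a
non-negative least-squares problem on the normalised spectrum against the
catalog; weights below 0.06 are zeroed and survivors rescaled so that
weights + unexplained = 1 (the deconstructSigs convention), with
`unexplained` = max(0, 1 − Σw) taken before the floor.  Samples under 15
SNVs are ineligible.  Carrier status (weight > 0.06, strict) uses the same
floor by default but is configurable; carrier fractions are compared between
populations by two-sided t-tests over per-dataset fractions, with
zero-variance and single-dataset groups flagged rather than tested.
Per-sample refits are the default; a pooled-spectrum refit can be obtained
by summing spectra before the call.

The packaged catalog is **synthetic**: 13 profiles with the labels, shape,
channel order and qualitative peak structure of the breast-cancer COSMIC v2
set (CpG C>T clock-like, TpCpN APOBEC-like pair, flat HRD-like, MMR-like
C>T family, TpTpT T>G, …), generated once with a fixed seed and frozen.
Any 96 × K TSV in the same format substitutes for it.  All recovery tests
draw truth *from* the catalog in use, so they validate the refitting
machinery, not the catalog's biological accuracy.

### Immune scoring

One ssGSEA engine (genes ranked within a sample, ties broken by gene
identifier; running-sum weights = rank-from-bottom^0.25) serves every gene
set, standing in for both ESTIMATE and GSVA: the original tools differ from
it by monotone/affine rescalings, and every downstream use here is rank- or
comparison-based.  IMPRES counts strictly satisfied checkpoint-pair
inequalities; the published pair list is not redistributable, so a
representative synthetic 15-pair file ships with 14 active features
(matching the "14 of 15 available" situation); the score is bounded by the
active-feature count and classified high at ≥ 9.  ER status is a
two-component univariate Gaussian EM on log2(TPM+1) — the log scale is
the default for EM stability; raw-TPM fitting is a flag — initialised from the 25th/75th percentiles, converged when the
log-likelihood gain drops below 1e-8, with variances floored at 1e-6.  The
higher-mean component is ER+; fits whose component means are within 0.5
pooled sd are flagged unreliable.  Covariate adjustment is plain OLS with
indicator-expanded categoricals and an explicit rank check that names
collinear columns.

### Clonality

CCF = vaf·(p·CNt + (1−p)·2)/(p·m); multiplicity m = max(1, round(vaf/p ·
(p·CNt + (1−p)·2))).  These closed forms are the standard purity/ploidy
adjustment used throughout the clonality literature.  CCFs are capped at
1.0 with the pre-clip value retained.  Total copy number is used (the
stand-in does not model major/minor alleles).  MATH =
100·1.4826·MAD/median of a sample's VAFs.  The subclone counter is a
deliberately simple stand-in for Dirichlet-process clustering: binomial
mixtures in CCF space fitted by EM for k = 1…8, initialised from quantiles
of the per-variant CCF estimates, selected by BIC with 2k−1 parameters —
adequate because only the cluster *count* is consumed downstream.  The
immune–heterogeneity association bins samples into 20 equal-size immune-
score groups and correlates bin index with mean log2 cluster count
(Spearman).

### Cohort comparison

Pearson chi-square without continuity correction; per-subtype tests are subtype-vs-rest 2×2 tables,
with raw and Bonferroni-adjusted p both reported.  Gene-by-ER comparisons
switch to Fisher's exact test when any expected cell is below 5.  Survival
uses lifelines: Kaplan–Meier, K-group log-rank, Cox PH with Efron ties.
Inclusion requires ≥ 2 years of survival data; whether deaths before two
years should count is a genuine design fork, so the default excludes them
symmetrically and `include_early_events=True` switches the rule.

## The synthetic generator

The generator emulates exactly the statistical structure the comparison
assumes: cohort A vs B differ in (a) subtype prevalence (IC5-like 13.1% vs
7.9%, an ER-negative IC4-like 9.1% vs 4.6%), (b) TP53 rate within ER+
samples (0.25 vs 0.15; equal at 0.60 in ER−), (c) a 0.5-sd mean shift of a
per-sample immune latent factor added to immune-set (and, attenuated,
checkpoint) gene expression, (d) per-subtype Dirichlet signature mixtures
(clock-like mass in luminal-like subtypes, APOBEC-like in the IC5-like,
flat HRD-like in the basal-like), (e) 1–3 clones per sample with binomially
sampled read counts at expected VAF = ccf·m·p/(p·CNt + (1−p)·2), and (f)
exponential survival with hazard h0 · 2^TP53 · 0.5^immune-high and
administrative censoring U(2, 10) years.

Distributional choices are the simplest forms with the required moments:
negative-binomial mutation counts (mean 45/sample, a typical breast-exome
burden, dispersion 5), Poisson read depths (mean 75×, typical exome
coverage), Gaussian log2 expression around uniform per-gene baselines,
uniform purity on (0.3, 0.9) (mirroring the ≥30% tumour-content inclusion
rule).  Trinucleotide context is attached directly to each simulated SNV,
so tallying never needs a reference genome.  The baseline hazard 0.08/yr
was set by an a-priori power calculation: with U(2,10) censoring and the
2-year inclusion rule it yields ~25% observed events, the level at which
the configured hazard ratios (2.0 for TP53, 0.5 for immune-high) are
detectable by log-rank at 500 patients/cohort.  Default seed 17; identical
seeds give byte-identical bundles; the CLI logs the seed.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: no reference-genome sequence or mappability
structure, no germline variants or BAM-level reads, no copy-number
aberrations (total CN is 2 genome-wide, so CCF behaviour under CNAs is
exercised only through the closed-form unit tests), no subtype-specific
expression programs beyond ESR1 and the immune factor, no correlation
between mutation burden and subtype, and per-subtype ER+ fractions are
plausible defaults rather than calibrated to any cohort.

## Problem sizes and validation design

The acceptance-style checks use: 10,000 variant records (half artifact,
plus a deterministic boundary panel) against an independently coded
rule-by-rule checker; all ~23k symmetry-distinct 2×2 tables with margins
≤ 30 against enumeration/hand-coded oracles at 1e-10; a 9×9 two-signature
weight grid × 50 seeds at 1000 mutations (pairs rotated so all 13
signatures are exercised); 1000-replicate null calibrations of the four
comparison tests; and 100 generator seeds at 500 patients/cohort for the
end-to-end direction rates.  ER-EM accuracy is checked at 4-pooled-sd
component separation, since the two-component Bayes-optimal accuracy at
3 sd is Φ(1.5) ≈ 93.3% and no estimator can reach 95% there.

## Known limitations

* The subclone counter is a model-selection stand-in, not a posterior over
  clusterings; it underestimates k for closely spaced clones at low depth.
* ssGSEA scores are on the engine's own scale; only ranks/comparisons are
  comparable across tools.
* The synthetic catalog and IMPRES pair list are structural stand-ins;
  conclusions about specific real signatures or checkpoint features require
  the corresponding reference files.
* With the default inclusion rule, deaths before two years are excluded
  from survival analyses, which biases absolute survival estimates upward;
  the comparison tests are unaffected in direction.
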