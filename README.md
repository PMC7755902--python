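# cohortcompare

A tested, reusable pipeline for comparing the somatic and transcriptomic
landscape of breast tumours between two populations — the kind of analysis
run when an Asian cohort is profiled by WES/RNA-seq and compared against
Caucasian reference cohorts.  Real cohort data of this kind are controlled
access, so the package ships a first-class synthetic two-cohort generator
with known ground truth; every analysis stage is exercised and validated
end-to-end against that truth.

## Who it is for

Cancer-genomics analysts who have (or want to emulate) per-cohort MAF-like
somatic mutation tables, TPM/count expression matrices, purity/copy-number
estimates and clinical tables, and need the bespoke statistics of a
population comparison: variant post-filtering, driver scoring, exclusivity,
signature refitting, immune scoring, clonality and survival.

## Stages and the statistics at their core

| Stage | Core method |
|---|---|
| `variant_filter` | Somatic SNV/indel filter cascade: panel-of-normals (sites in ≥2 normals), depth ≥10 tumour / ≥5 normal, OxoG metric < 0.8, VAF ≥ 0.075, two-sided Fisher strand test p ≥ 0.05, S_AF > 0.75, gnomAD AF < 0.01, ≥4 alt reads with ≥2 per strand, second caller for indels, and a ≥5-sample recurrence filter with COSMIC rescue |
| `drivers` | ONC score = 100·r/M (r = missense count at the most recurrent codon, M = all mutations; needs r ≥ 5); TSG score = 100·I/M (I = nonsense+frameshift+splice; needs I ≥ 5); candidate drivers have either score > 20 and ≥1% mutated samples in some stratum |
| `comut` | Pairwise Fisher exact tests and odds ratios among the top-15 mutated genes; OR < 1 = mutual exclusivity; Bonferroni over tested pairs |
| `signatures` | Per-sample exposures over a 13-signature 96-channel catalog by non-negative least squares on the normalised spectrum, with the 0.06 floor-and-renormalise rule; eligible at ≥15 SNVs; carrier at weight > 0.06 |
| `immune` | ssGSEA (weighted running-sum rank enrichment, exponent 0.25) for immune gene sets; IMPRES = count of satisfied checkpoint-pair inequalities in [0,14], high at ≥9; ER status by a two-component Gaussian EM on log2(ESR1 TPM + 1) |
| `clonality` | CCF = vaf·(p·CNt + (1−p)·2)/(p·m); MATH = 100·1.4826·MAD/median of VAFs; subclone count by BIC-selected binomial-mixture EM |
| `compare` | Pearson chi-square (no Yates) subtype-vs-rest prevalence tests, gene-by-ER comparisons (Fisher when expected cells < 5), Kaplan–Meier / log-rank / Cox PH (Efron ties) |
| `synthetic` | Two cohorts with configurable subtype prevalences, ER-dependent TP53 rates, an immune-infiltration expression shift, Dirichlet signature mixtures, binomially sampled clonal VAFs and exponential survival with TP53/immune hazard ratios |

The packaged signature catalog and IMPRES feature list are synthetic
stand-ins (`data/*_synthetic*.tsv`) with the shape and structure of the real
reference objects; both are replaceable by files in the same format.

## Worked example

```python
from cohortcompare.pipeline import headline_findings
from cohortcompare.synthetic import CohortConfig

findings = headline_findings(config=CohortConfig(seed=17))
for k, v in findings.items():
    print(f"{k:16s} diff={v['diff']:+.3f}  p={v['p']:.3g}")
```

prints

```
subtype          diff=+0.054  p=0.00497
gene_er_pos      diff=+0.089  p=0.00373
immune           diff=+81.681  p=1.95e-21
survival_tp53    diff=-0.060  p=0.0292
survival_immune  diff=+0.097  p=9.67e-05
```

Reading: with the default two-cohort configuration (500 patients per
cohort), the IC5-like subtype is 5.4 points more prevalent in cohort A
(chi-square p = 0.005); TP53 mutations are 8.9 points more frequent in
cohort A's ER+ tumours (p = 0.004); cohort A's mean immune ssGSEA score is
higher (one-way ANOVA p ≈ 2e-21); TP53 carriers have 6-point worse and
immune-high patients 9.7-point better 5-year survival (log-rank p = 0.029
and 1e-4).

The same stages are available from the shell:

```bash
cohortcompare simulate --out sim/ --seed 17
cohortcompare filter --maf sim/mutations.maf.tsv --out filtered.maf.tsv
cohortcompare signatures --maf filtered.maf.tsv --out exposures.tsv
cohortcompare compare --cohort sim/cohort.tsv --maf filtered.maf.tsv --out report/
```

## Layout

```
src/cohortcompare/    library (one module per stage) + packaged data
tests/                pytest suite incl. acceptance tests and oracles
scripts/acceptance.py reproduction script
docs/methods.md       model and design notes
```
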