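"""End-to-end pipeline: generator bundle -> headline cohort comparisons.

Binds the stages together the way the full analysis runs on real cohorts:
subtype-prevalence chi-square, gene-by-ER mutation comparison, immune-score
cohort comparison (one-way ANOVA on ssGSEA scores), and survival stratified
by TP53 and immune class.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import compare, immune
from .synthetic import CohortBundle, CohortConfig, default_immune_gene_sets, generate_cohorts


def immune_score_table(bundle: CohortBundle, gene_sets=None) -> pd.DataFrame:
    """Per-sample ssGSEA immune scores on the retained genes."""
    gene_sets = gene_sets or default_immune_gene_sets()
    expr = bundle.expression
    kept = immune.filter_genes(expr.counts, expr.tpm)
    return immune.ssgsea_matrix(expr.tpm.loc[kept], gene_sets)


def headline_findings(config: CohortConfig | None = None,
                      bundle: CohortBundle | None = None,
                      subtype: str = "IC5", gene: str = "TP53") -> dict:
    """Run the four headline comparisons on a generated bundle.

    Returns a dict with, for each finding, the effect direction
    (cohort A minus cohort B, or hazard ordering) and the p value:

    * ``subtype``: subtype-vs-rest prevalence chi-square between cohorts.
    * ``gene_er_pos``: gene mutation prevalence within ER+ samples.
    * ``immune``: one-way ANOVA of the first immune score between cohorts.
    * ``survival_tp53`` / ``survival_immune``: log-rank among ER+ patients
      for TP53 status, and among all patients for immune class (latent-truth
      median split stands in for the IMPRES high/low call).
    """
    if bundle is None:
        bundle = generate_cohorts(config)
    ct = bundle.cohort_table
    out = {}

    prev = compare.subtype_prevalence_tests(ct)
    row = prev.set_index("subtype").loc[subtype]
    frac_a = row["n_A"] / row["total_A"]
    frac_b = row["n_B"] / row["total_B"]
    out["subtype"] = {"diff": float(frac_a - frac_b), "p": float(row["p"])}

    by_er = compare.mutation_prevalence_by_er(bundle.mutation_table, ct, [gene])
    row = by_er[(by_er["gene"] == gene) & (by_er["er_status"] == "pos")].iloc[0]
    out["gene_er_pos"] = {"diff": float(row["frac_A"] - row["frac_B"]),
                          "p": float(row["p"])}

    scores = immune_score_table(bundle)
    first = scores.columns[0]
    a = scores.loc[ct.loc[ct["cohort"] == "A", "patient_id"], first]
    b = scores.loc[ct.loc[ct["cohort"] == "B", "patient_id"], first]
    f, p = stats.f_oneway(a.to_numpy(), b.to_numpy())
    out["immune"] = {"diff": float(a.mean() - b.mean()), "p": float(p)}

    surv = compare.survival_inclusion(ct)
    truth = bundle.truth.samples
    er_pos = surv[surv["er_status"] == "pos"]
    tp53 = truth.loc[er_pos["patient_id"], "tp53"].to_numpy()
    _, p = compare.logrank_test(er_pos["survival_time"], er_pos["event"], tp53)
    km_pos = compare.km_estimate(er_pos.loc[tp53, "survival_time"],
                                 er_pos.loc[tp53, "event"])
    km_neg = compare.km_estimate(er_pos.loc[~tp53, "survival_time"],
                                 er_pos.loc[~tp53, "event"])
    out["survival_tp53"] = {
        "diff": float(compare.survival_at(km_pos, 5.0) - compare.survival_at(km_neg, 5.0)),
        "p": float(p),
    }

    imm_high = truth.loc[surv["patient_id"], "immune_high"].to_numpy()
    _, p = compare.logrank_test(surv["survival_time"], surv["event"], imm_high)
    km_hi = compare.km_estimate(surv.loc[imm_high, "survival_time"],
                                surv.loc[imm_high, "event"])
    km_lo = compare.km_estimate(surv.loc[~imm_high, "survival_time"],
                                surv.loc[~imm_high, "event"])
    out["survival_immune"] = {
        "diff": float(compare.survival_at(km_hi, 5.0) - compare.survival_at(km_lo, 5.0)),
        "p": float(p),
    }
    return out


def findings_match_expected(findings: dict, alpha: float = 0.05) -> bool:
    """True when every headline effect is significant in the expected
    direction: subtype and ER+ gene prevalence higher in cohort A, immune
    scores higher in A, TP53 carriers with worse and immune-high patients
    with better 5-year survival."""
    f = findings
    return (f["subtype"]["p"] < alpha and f["subtype"]["diff"] > 0
            and f["gene_er_pos"]["p"] < alpha and f["gene_er_pos"]["diff"] > 0
            and f["immune"]["p"] < alpha and f["immune"]["diff"] > 0
            and f["survival_tp53"]["p"] < alpha and f["survival_tp53"]["diff"] < 0
            and f["survival_immune"]["p"] < alpha and f["survival_immune"]["diff"] > 0)
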