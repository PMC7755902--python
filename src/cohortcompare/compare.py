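"""Cohort-level prevalence comparisons and survival analysis.

Subtype prevalences are compared per subtype as subtype-vs-rest 2x2 tables
with Pearson's chi-square (no continuity correction); gene mutation
prevalences are compared within ER strata, switching to Fisher's exact test
when any expected cell drops below 5.  Survival uses the Kaplan-Meier
product-limit estimator, the K-group log-rank test and Cox proportional
hazards (Efron ties), all through lifelines.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

logger = logging.getLogger(__name__)


def subtype_prevalence(table: pd.DataFrame, stratify_age: bool = False,
                       age_cutoff: float = 50.0) -> pd.DataFrame:
    """Counts and fractions per cohort x subtype, optionally within age
    strata (<cutoff strictly below, >=cutoff otherwise)."""
    df = table.copy()
    group_cols = ["cohort", "subtype"]
    if stratify_age:
        df["age_stratum"] = np.where(df["age"] < age_cutoff,
                                     f"<{age_cutoff:g}", f">={age_cutoff:g}")
        group_cols = ["age_stratum"] + group_cols
    counts = df.groupby(group_cols, observed=True).size().rename("count").reset_index()
    denom_cols = [c for c in group_cols if c != "subtype"]
    totals = counts.groupby(denom_cols, observed=True)["count"].transform("sum")
    counts["fraction"] = counts["count"] / totals
    return counts


def prevalence_test(table2x2) -> tuple[float, float]:
    """Pearson chi-square (no Yates correction) on a 2x2 table.

    Returns (statistic, p); a zero margin gives (NaN, NaN) with a warning.
    """
    t = np.asarray(table2x2, dtype=float)
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        warnings.warn("prevalence_test: zero margin, p undefined", stacklevel=2)
        return float("nan"), float("nan")
    chi2, p, _, _ = stats.chi2_contingency(t, correction=False)
    return float(chi2), float(p)


def subtype_prevalence_tests(table: pd.DataFrame) -> pd.DataFrame:
    """Per-subtype subtype-vs-rest chi-square between two cohorts."""
    cohorts = sorted(table["cohort"].unique())
    if len(cohorts) != 2:
        raise ValueError("expected exactly two cohorts")
    rows = []
    for subtype in sorted(table["subtype"].unique()):
        cells = []
        for cohort in cohorts:
            sub = table[table["cohort"] == cohort]
            k = int((sub["subtype"] == subtype).sum())
            cells.append([k, len(sub) - k])
        chi2, p = prevalence_test(cells)
        rows.append((subtype, cells[0][0], cells[0][0] + cells[0][1],
                     cells[1][0], cells[1][0] + cells[1][1], chi2, p))
    out = pd.DataFrame(rows, columns=[
        "subtype", f"n_{cohorts[0]}", f"total_{cohorts[0]}",
        f"n_{cohorts[1]}", f"total_{cohorts[1]}", "chi2", "p"])
    out["p_bonferroni"] = (out["p"] * len(out)).clip(upper=1.0)
    return out


def mutation_prevalence_by_er(maf: pd.DataFrame, cohort_table: pd.DataFrame,
                              genes) -> pd.DataFrame:
    """Per (gene, ER stratum) mutated-sample fractions and cohort comparison.

    Chi-square without correction, or Fisher's exact test when any expected
    cell is below 5.  Strata with zero samples in a cohort are skipped;
    all-absent genes give p = NaN.
    """
    cohorts = sorted(cohort_table["cohort"].unique())
    if len(cohorts) != 2:
        raise ValueError("expected exactly two cohorts")
    mutated = maf[["sample", "gene"]].drop_duplicates()
    rows = []
    for er in ("pos", "neg"):
        strat = cohort_table[cohort_table["er_status"] == er]
        n_by_cohort = strat.groupby("cohort").size()
        if any(c not in n_by_cohort.index or n_by_cohort[c] == 0 for c in cohorts):
            logger.info("mutation_prevalence_by_er: skipping ER %s (empty stratum)", er)
            continue
        for gene in genes:
            carriers = set(mutated.loc[mutated["gene"] == gene, "sample"])
            cells = []
            for cohort in cohorts:
                ids = strat.loc[strat["cohort"] == cohort, "patient_id"]
                k = int(ids.isin(carriers).sum())
                cells.append([k, len(ids) - k])
            t = np.asarray(cells, dtype=float)
            frac = [c[0] / (c[0] + c[1]) for c in cells]
            if t[:, 0].sum() == 0:
                rows.append((gene, er, frac[0], frac[1], np.nan, "none"))
                continue
            expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()
            if (expected < 5).any():
                _, p = stats.fisher_exact(t)
                test = "fisher"
            else:
                _, p, _, _ = stats.chi2_contingency(t, correction=False)
                test = "chi2"
            rows.append((gene, er, frac[0], frac[1], float(p), test))
    return pd.DataFrame(rows, columns=[
        "gene", "er_status", f"frac_{cohorts[0]}", f"frac_{cohorts[1]}", "p", "test"])


def survival_inclusion(table: pd.DataFrame, min_follow_up: float = 2.0,
                       include_early_events: bool = False) -> pd.DataFrame:
    """Keep patients with at least ``min_follow_up`` years of survival data.

    By default both early-censored and early-death patients (<2 years) are
    excluded; ``include_early_events=True`` switches to keeping deaths that
    occur before the cutoff.
    """
    keep = table["follow_up_years"] >= min_follow_up
    if include_early_events:
        keep |= table["event"] == 1
    return table[keep].copy()


def km_estimate(times, events) -> KaplanMeierFitter:
    """Product-limit survival estimator (right censoring handled)."""
    if len(np.asarray(times)) == 0:
        raise ValueError("need at least one subject")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    return kmf


def survival_at(kmf: KaplanMeierFitter, t: float) -> float:
    return float(kmf.predict(t))


def logrank_test(times, events, groups) -> tuple[float, float]:
    """K-group log-rank test; returns (chi-square statistic, p).

    Zero events overall gives (NaN, NaN) with a warning.
    """
    events = np.asarray(events)
    if events.sum() == 0:
        warnings.warn("logrank_test: no events, p undefined", stacklevel=2)
        return float("nan"), float("nan")
    res = multivariate_logrank_test(np.asarray(times), np.asarray(groups), events)
    return float(res.test_statistic), float(res.p_value)


def cox_fit(times, events, covariates: pd.DataFrame) -> pd.DataFrame:
    """Cox proportional-hazards fit (Efron tie handling via lifelines).

    Returns hazard ratios with 95% Wald CIs and p values per covariate.
    Raises on no-event data or zero-variance covariates.
    """
    events = np.asarray(events)
    if events.sum() == 0:
        raise ValueError("cannot fit a Cox model with zero events")
    zero_var = [c for c in covariates.columns if covariates[c].nunique() <= 1]
    if zero_var:
        raise ValueError(f"zero-variance covariates: {zero_var}")
    df = covariates.copy().reset_index(drop=True)
    df["_time"] = np.asarray(times)
    df["_event"] = events
    cph = CoxPHFitter()
    cph.fit(df, duration_col="_time", event_col="_event")
    summary = cph.summary
    out = pd.DataFrame({
        "hr": np.exp(summary["coef"]),
        "hr_lower95": np.exp(summary["coef lower 95%"]),
        "hr_upper95": np.exp(summary["coef upper 95%"]),
        "p": summary["p"],
    })
    return out
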