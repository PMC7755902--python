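"""Recovery, calibration and end-to-end evaluation routines.

Shared by the acceptance tests and the reproduction script: each function
regenerates its inputs from a seed, runs the relevant pipeline stage, and
returns summary statistics (recovery error, rejection rate, direction rate).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import compare, pipeline
from .signatures import (
    compare_carrier_fractions,
    load_catalog,
    quartile_signature_test,
    refit_exposures,
)
from .synthetic import CohortConfig, generate_mutation_catalog


def signature_grid_recovery(n_mutations: int = 1000, n_seeds: int = 50,
                            weight_floor: float = 0.06, seed: int = 0) -> dict:
    """Two-signature mixture recovery over the 9x9 weight grid.

    For each cell (i, j) of the grid the two mixture weights are
    (w_i, w_j) / (w_i + w_j) with w in {0.1, ..., 0.9}; the signature pair is
    rotated deterministically through the catalog so every signature is
    exercised.  Returns the mean absolute error of the recovered weights of
    the two true signatures and the fraction of runs where every zero-truth
    signature stays below the floor.
    """
    catalog = load_catalog()
    grid = np.arange(0.1, 0.95, 0.1)
    pairs = [(a, b) for a in range(13) for b in range(a + 1, 13)]
    errors = []
    zero_ok = 0
    runs = 0
    base = np.random.default_rng(seed).integers(0, 2**31 - 1)
    for gi, wa in enumerate(grid):
        for gj, wb in enumerate(grid):
            si, sj = pairs[(gi * 9 + gj) % len(pairs)]
            w = np.zeros(13)
            w[si] = wa / (wa + wb)
            w[sj] = wb / (wa + wb)
            for s in range(n_seeds):
                spec = generate_mutation_catalog(
                    w, n_mutations, catalog, int((base + gi * 9 + gj) * n_seeds + s) % 2**31)
                out = refit_exposures(
                    pd.DataFrame([spec.values], columns=list(catalog.index)),
                    catalog, weight_floor=weight_floor).iloc[0]
                w_hat = out[list(catalog.columns)].to_numpy(float)
                errors.append(abs(w_hat[si] - w[si]))
                errors.append(abs(w_hat[sj] - w[sj]))
                zeros = np.delete(np.arange(13), [si, sj])
                zero_ok += bool((w_hat[zeros] < weight_floor).all())
                runs += 1
    return {"mae": float(np.mean(errors)), "zero_below_floor_rate": zero_ok / runs,
            "n_runs": runs}


def prevalence_chi2_calibration(n_reps: int = 1000, n: int = 500, p: float = 0.1,
                                alpha: float = 0.05, seed: int = 0) -> float:
    """Type-I error of the subtype-vs-rest chi-square under the null."""
    rng = np.random.default_rng(seed)
    rej = 0
    for _ in range(n_reps):
        ka, kb = rng.binomial(n, p, 2)
        _, pval = compare.prevalence_test([[ka, n - ka], [kb, n - kb]])
        rej += pval < alpha
    return rej / n_reps


def carrier_ttest_calibration(n_reps: int = 1000, n_datasets: int = 4,
                              n_per_dataset: int = 100, p: float = 0.3,
                              alpha: float = 0.05, seed: int = 1) -> float:
    """Type-I error of the per-signature carrier-fraction t-test under the null."""
    rng = np.random.default_rng(seed)
    groups = {f"d{i}": ("asian" if i < n_datasets else "cauc")
              for i in range(2 * n_datasets)}
    rej = 0
    for _ in range(n_reps):
        fr = pd.DataFrame(
            {"Signature_1": rng.binomial(n_per_dataset, p, 2 * n_datasets) / n_per_dataset},
            index=list(groups))
        out = compare_carrier_fractions(fr, groups)
        rej += out.loc["Signature_1", "p"] < alpha
    return rej / n_reps


def quartile_wilcoxon_calibration(n_reps: int = 1000, n: int = 100,
                                  alpha: float = 0.05, seed: int = 2) -> float:
    """Type-I error of the top-vs-bottom-quartile rank-sum test under the null."""
    rng = np.random.default_rng(seed)
    idx = [f"S{i}" for i in range(n)]
    rej = 0
    for _ in range(n_reps):
        exp = pd.DataFrame({"Signature_3": rng.random(n)}, index=idx)
        scores = pd.Series(rng.random(n), index=idx)
        rej += quartile_signature_test(exp, scores)["Signature_3"] < alpha
    return rej / n_reps


def logrank_calibration(n_reps: int = 1000, n_per_group: int = 100,
                        hazard: float = 0.2, alpha: float = 0.05,
                        seed: int = 3) -> float:
    """Type-I error of the log-rank test under HR = 1 exponential survival."""
    rng = np.random.default_rng(seed)
    groups = np.repeat([0, 1], n_per_group)
    rej = 0
    for _ in range(n_reps):
        t = rng.exponential(1 / hazard, 2 * n_per_group)
        c = rng.uniform(2, 10, 2 * n_per_group)
        _, p = compare.logrank_test(np.minimum(t, c), (t <= c).astype(int), groups)
        rej += p < alpha
    return rej / n_reps


def cox_hr_recovery(n: int = 1000, hr: float = 2.0, hazard: float = 0.1,
                    seed: int = 4) -> float:
    """Estimated hazard ratio for a planted binary covariate."""
    rng = np.random.default_rng(seed)
    x = rng.integers(0, 2, n)
    t = rng.exponential(1 / (hazard * hr ** x))
    c = rng.uniform(2, 10, n)
    out = compare.cox_fit(np.minimum(t, c), (t <= c).astype(int),
                          pd.DataFrame({"x": x}))
    return float(out.loc["x", "hr"])


def end_to_end_direction_rates(n_seeds: int = 100, n_per_cohort: int = 500,
                               alpha: float = 0.05, seed: int = 0) -> dict:
    """Fraction of generator seeds where each headline finding (and all of
    them jointly) is significant in the expected direction."""
    keys = ("subtype", "gene_er_pos", "immune", "survival_tp53", "survival_immune")
    hits = {k: 0 for k in keys}
    joint = 0
    for i in range(n_seeds):
        cfg = CohortConfig(n_samples_per_cohort=n_per_cohort, seed=(seed + i) % 2**31)
        f = pipeline.headline_findings(config=cfg)
        ok = {
            "subtype": f["subtype"]["p"] < alpha and f["subtype"]["diff"] > 0,
            "gene_er_pos": f["gene_er_pos"]["p"] < alpha and f["gene_er_pos"]["diff"] > 0,
            "immune": f["immune"]["p"] < alpha and f["immune"]["diff"] > 0,
            "survival_tp53": f["survival_tp53"]["p"] < alpha
                             and f["survival_tp53"]["diff"] < 0,
            "survival_immune": f["survival_immune"]["p"] < alpha
                               and f["survival_immune"]["diff"] > 0,
        }
        for k in keys:
            hits[k] += ok[k]
        # the four headline figures: subtype prevalence, gene-by-ER, immune
        # shift, and the TP53 survival penalty (the immune survival benefit
        # is tracked separately)
        joint += all(ok[k] for k in ("subtype", "gene_er_pos", "immune", "survival_tp53"))
    out = {k: v / n_seeds for k, v in hits.items()}
    out["all_four"] = joint / n_seeds
    out["n_seeds"] = n_seeds
    return out
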