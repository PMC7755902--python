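"""Independent oracles used by the test suite.

These deliberately re-derive results from first principles (full
hypergeometric enumeration, hand-coded chi-square, a rule-by-rule filter
checker) so they share no code path with the package implementation.
"""

from __future__ import annotations

import math


def fisher_exact_enum(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by full hypergeometric enumeration.

    Sums, over all tables with the observed margins, the probabilities no
    larger than the observed table's (standard relative tolerance 1e-7 for
    floating-point ties).
    """
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if n == 0:
        return 1.0

    def log_p(x):
        # P(X = x) for X ~ Hypergeom(n, r1, c1)
        return (math.lgamma(r1 + 1) - math.lgamma(x + 1) - math.lgamma(r1 - x + 1)
                + math.lgamma(r2 + 1) - math.lgamma(c1 - x + 1)
                - math.lgamma(r2 - c1 + x + 1)
                - (math.lgamma(n + 1) - math.lgamma(c1 + 1) - math.lgamma(n - c1 + 1)))

    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    p_obs = math.exp(log_p(a))
    total = 0.0
    for x in range(lo, hi + 1):
        px = math.exp(log_p(x))
        if px <= p_obs * (1 + 1e-7):
            total += px
    return min(total, 1.0)


def pearson_chi2_p(table) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) on an R x C table,
    coded from the definition."""
    import numpy as np
    from scipy.stats import chi2 as chi2_dist

    t = np.asarray(table, dtype=float)
    row = t.sum(axis=1, keepdims=True)
    col = t.sum(axis=0, keepdims=True)
    expected = row @ col / t.sum()
    stat = float(((t - expected) ** 2 / expected).sum())
    dof = (t.shape[0] - 1) * (t.shape[1] - 1)
    return stat, float(chi2_dist.sf(stat, dof))


def reference_filter_verdict(rec: dict, pon: set, cfg) -> bool:
    """Rule-by-rule re-implementation of the somatic filter cascade,
    independent of the package (Fisher via enumeration above)."""
    if (rec["chrom"], rec["pos"], rec["alt"]) in pon:
        return False
    if rec["t_depth"] < cfg.min_t_depth:
        return False
    if rec["n_depth"] < cfg.min_n_depth:
        return False
    if not rec["oxog_metric"] < cfg.max_oxog:
        return False
    if rec["vaf"] < cfg.min_vaf:
        return False
    p = fisher_exact_enum(rec["alt_fwd"], rec["alt_rev"], rec["ref_fwd"], rec["ref_rev"])
    if p < cfg.min_strand_p:
        return False
    if not rec["s_af"] > cfg.min_s_af:
        return False
    if rec["gnomad_af"] >= cfg.max_gnomad_af:
        return False
    if rec["alt_fwd"] + rec["alt_rev"] < cfg.min_alt_reads:
        return False
    if rec["alt_fwd"] < cfg.min_alt_per_strand or rec["alt_rev"] < cfg.min_alt_per_strand:
        return False
    if rec["variant_type"] == "indel" and not rec["second_caller"]:
        return False
    return True
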