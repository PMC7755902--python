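"""Pairwise co-occurrence / mutual-exclusivity of mutated genes.

Samples are binarised per gene (carries >= 1 nonsynonymous mutation or not);
for every unordered pair among the top-k most frequently mutated genes a 2x2
contingency table is built, tested with a two-sided Fisher exact test, and
summarised by the sample odds ratio.  OR < 1 reads as mutual exclusivity,
OR > 1 as co-occurrence.  Zero cells give OR 0 or inf without a Haldane
correction; the log2 odds ratio used for plotting caps infinities at
+/- ``LOG2_OR_CAP``.  Bonferroni correction over the tested pairs controls
family-wise error.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

LOG2_OR_CAP = 10.0


def gene_sample_matrix(maf: pd.DataFrame, genes=None, samples=None) -> pd.DataFrame:
    """Binary samples x genes matrix: 1 iff the sample carries >= 1 mutation
    in the gene.  Genes absent from the table give all-zero columns."""
    if samples is None:
        samples = sorted(pd.unique(maf["sample"]))
    if genes is None:
        genes = sorted(pd.unique(maf["gene"]))
    mat = pd.DataFrame(0, index=pd.Index(samples, name="sample"),
                       columns=pd.Index(genes, name="gene"), dtype=int)
    hits = maf[maf["gene"].isin(genes) & maf["sample"].isin(samples)]
    for s, g in hits[["sample", "gene"]].drop_duplicates().itertuples(index=False):
        mat.loc[s, g] = 1
    return mat


def _odds_ratio(n11: int, n10: int, n01: int, n00: int) -> float:
    if n10 == 0 or n01 == 0:
        return np.inf if n11 * n00 > 0 else (0.0 if n11 == 0 or n00 == 0 else np.inf)
    return (n11 * n00) / (n10 * n01)


def pairwise_association(matrix: pd.DataFrame, top_k: int = 15) -> pd.DataFrame:
    """Fisher exact association for each unordered pair among the ``top_k``
    most frequently mutated genes.

    Degenerate all-zero genes are skipped with a log entry.  Returns a
    DataFrame (gene_a, gene_b, n11, n10, n01, n00, odds_ratio, log2_or, p,
    direction).
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least two genes")
    freq = matrix.sum(axis=0).sort_values(ascending=False, kind="mergesort")
    top = list(freq.index[:top_k])
    rows = []
    for i, ga in enumerate(top):
        for gb in top[i + 1:]:
            a = matrix[ga].to_numpy(bool)
            b = matrix[gb].to_numpy(bool)
            if not a.any() or not b.any():
                logger.info("pairwise_association: skipping degenerate pair (%s, %s)", ga, gb)
                continue
            n11 = int((a & b).sum())
            n10 = int((a & ~b).sum())
            n01 = int((~a & b).sum())
            n00 = int((~a & ~b).sum())
            odds = _odds_ratio(n11, n10, n01, n00)
            _, p = stats.fisher_exact([[n11, n10], [n01, n00]])
            if odds == 0.0:
                log2_or = -LOG2_OR_CAP
            elif np.isinf(odds):
                log2_or = LOG2_OR_CAP
            else:
                log2_or = float(np.log2(odds))
            direction = "exclusive" if odds < 1 else "co-occurring"
            rows.append((ga, gb, n11, n10, n01, n00, odds, log2_or, float(p), direction))
    return pd.DataFrame(rows, columns=[
        "gene_a", "gene_b", "n11", "n10", "n01", "n00",
        "odds_ratio", "log2_or", "p", "direction",
    ])


def bonferroni_filter(results: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Keep pairs significant after Bonferroni correction over the tested
    pairs (p * m < alpha); adds a ``p_bonferroni`` column (capped at 1)."""
    if results.empty:
        out = results.copy()
        out["p_bonferroni"] = pd.Series(dtype=float)
        return out
    m = len(results)
    out = results.copy()
    out["p_bonferroni"] = (out["p"] * m).clip(upper=1.0)
    return out[out["p"] * m < alpha].reset_index(drop=True)
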