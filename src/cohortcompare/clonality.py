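"""Cancer cell fractions, MATH heterogeneity, and subclone counting.

For a mutation observed at variant allele fraction ``vaf`` in a tumour of
purity ``p`` with local total copy number ``CNt`` and mutated-copy
multiplicity ``m``, the cancer cell fraction is

    CCF = vaf * (p * CNt + (1 - p) * 2) / (p * m)

i.e. the fraction of tumour cells carrying the mutation after correcting the
allele fraction for normal-cell contamination and copy state.  Multiplicity
is estimated from the same quantities rounded to the nearest supported copy
count.  CCFs are clipped at a cap (default 1.0) with the pre-clip value
retained so over-unity artefacts stay inspectable.

MATH (mutant-allele tumour heterogeneity) summarises a sample's VAF spread as
100 * 1.4826 * MAD / median.

Subclone counting is a BIC-selected binomial-mixture EM over CCF space: a
deliberately simple stand-in for Dirichlet-process clustering, adequate here
because only the *number* of clusters is consumed downstream.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

logger = logging.getLogger(__name__)


def multiplicity(vaf: float, p: float, cn_total: int) -> int:
    """Mutated-copy multiplicity: max(1, round(vaf/p * (p*CNt + (1-p)*2)))."""
    if not 0 < p <= 1:
        raise ValueError("purity must lie in (0, 1]")
    if cn_total == 0 and vaf > 0:
        raise ValueError("inconsistent record: CNt = 0 with vaf > 0")
    if cn_total < 1:
        raise ValueError("cn_total must be >= 1")
    return max(1, round(vaf / p * (p * cn_total + (1 - p) * 2)))


def ccf(vaf: float, p: float, cn_total: int, m: int, cap: float = 1.0,
        return_raw: bool = False):
    """Cancer cell fraction, clipped to ``cap``.

    With ``return_raw=True`` returns ``(clipped, raw)`` so over-unity values
    remain inspectable.
    """
    if p == 0:
        raise ValueError("purity must be positive")
    if m < 1:
        raise ValueError("multiplicity must be >= 1")
    raw = vaf * (p * cn_total + (1 - p) * 2) / (p * m)
    clipped = min(raw, cap)
    return (clipped, raw) if return_raw else clipped


def ccf_table(df: pd.DataFrame, cap: float = 1.0) -> pd.DataFrame:
    """Vectorised CCF annotation of a per-variant table with columns
    ``vaf``, ``purity``, ``cn_total`` (and optional ``multiplicity``)."""
    out = df.copy()
    if "multiplicity" not in out.columns:
        out["multiplicity"] = [
            multiplicity(v, p, c)
            for v, p, c in zip(out["vaf"], out["purity"], out["cn_total"])
        ]
    raw = (
        out["vaf"] * (out["purity"] * out["cn_total"] + (1 - out["purity"]) * 2)
        / (out["purity"] * out["multiplicity"])
    )
    out["ccf_raw"] = raw
    out["ccf"] = raw.clip(upper=cap)
    return out


def math_score(vafs) -> float:
    """MATH = 100 * 1.4826 * MAD(vafs) / median(vafs).

    Requires >= 3 VAFs; returns NaN (with a warning) when the median is 0.
    """
    v = np.asarray(vafs, dtype=float)
    if v.size < 3:
        raise ValueError("MATH requires at least 3 VAFs")
    med = np.median(v)
    if med == 0:
        warnings.warn("MATH undefined: median VAF is 0", stacklevel=2)
        return float("nan")
    mad = np.median(np.abs(v - med))
    return float(100.0 * 1.4826 * mad / med)


class SubcloneModel(BaseEstimator):
    """Binomial-mixture EM over CCF space with BIC model selection.

    Each variant i contributes alt_i ~ Binomial(depth_i, c_i * ccf_k) where
    c_i = p * m_i / (p * CNt_i + (1-p) * 2) converts a cluster CCF into the
    expected VAF of that variant.  For k = 1..max_k clusters the EM fits
    cluster CCFs and weights; the returned cluster count minimises
    BIC = -2 logL + (2k - 1) ln n.

    Fitted attributes: ``n_clusters_``, ``ccfs_``, ``weights_``, ``labels_``,
    ``bic_`` (per candidate k).
    """

    def __init__(self, max_k: int = 8, max_iter: int = 300, tol: float = 1e-8,
                 random_state: int = 0):
        self.max_k = max_k
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    @staticmethod
    def _conversion(p, cn_total, m):
        return p * m / (p * cn_total + (1 - p) * 2)

    def _em(self, alt, depth, c, k, init_ccfs):
        eps = 1e-6
        ccfs = np.clip(np.asarray(init_ccfs, dtype=float), eps, 1.0)
        w = np.full(k, 1.0 / k)
        prev_ll = -np.inf
        for _ in range(self.max_iter):
            prob = np.clip(c[:, None] * ccfs[None, :], eps, 1 - eps)
            logpmf = stats.binom.logpmf(alt[:, None], depth[:, None], prob)
            logpost = logpmf + np.log(w)[None, :]
            m_ = logpost.max(axis=1, keepdims=True)
            lse = m_[:, 0] + np.log(np.exp(logpost - m_).sum(axis=1))
            ll = float(lse.sum())
            gamma = np.exp(logpost - lse[:, None])
            if ll - prev_ll < self.tol and np.isfinite(prev_ll):
                break
            prev_ll = ll
            w = gamma.mean(axis=0)
            denom = (gamma * (depth * c)[:, None]).sum(axis=0)
            num = (gamma * alt[:, None]).sum(axis=0)
            ccfs = np.clip(num / np.maximum(denom, eps), eps, 1.0)
        return ll, ccfs, w, gamma

    def fit(self, alt_counts, depths, purity, cn_total=2, multiplicity=1):
        alt = np.asarray(alt_counts, dtype=int)
        depth = np.asarray(depths, dtype=int)
        n = alt.size
        if n < 10:
            raise ValueError("need at least 10 variants to estimate subclone count")
        cn = np.broadcast_to(np.asarray(cn_total), alt.shape)
        m = np.broadcast_to(np.asarray(multiplicity), alt.shape)
        c = self._conversion(purity, cn.astype(float), m.astype(float))
        ccf_hat = np.clip(alt / np.maximum(depth, 1) / c, 1e-6, 1.0)
        bics, fits = {}, {}
        for k in range(1, self.max_k + 1):
            qs = np.linspace(0.1, 0.9, k)
            init = np.quantile(ccf_hat, qs)
            try:
                ll, ccfs, w, gamma = self._em(alt, depth, c, k, init)
            except FloatingPointError:  # pragma: no cover - defensive
                logger.warning("subclone EM failed to converge at k=%d; skipped", k)
                continue
            n_params = 2 * k - 1
            bics[k] = -2.0 * ll + n_params * np.log(n)
            fits[k] = (ccfs, w, gamma)
        best_k = min(bics, key=bics.get)
        ccfs, w, gamma = fits[best_k]
        order = np.argsort(ccfs)[::-1]
        self.n_clusters_ = best_k
        self.ccfs_ = ccfs[order]
        self.weights_ = w[order]
        self.labels_ = np.argmax(gamma[:, order], axis=1)
        self.bic_ = bics
        return self


def subclone_count(alt_counts, depths, purity, cn_total=2, multiplicity=1,
                   max_k: int = 8) -> int:
    """Number of subclonal clusters by BIC-selected binomial-mixture EM."""
    model = SubcloneModel(max_k=max_k).fit(alt_counts, depths, purity, cn_total, multiplicity)
    return model.n_clusters_


def heterogeneity_summary(sample_id: str, vafs, n_clusters: int) -> dict:
    """Per-sample record: MATH, cluster count and its log2."""
    return {
        "sample": sample_id,
        "math": math_score(vafs),
        "n_clusters": n_clusters,
        "log2_clusters": float(np.log2(n_clusters)),
    }


def heterogeneity_immune_association(immune_scores: pd.Series,
                                     log2_clusters: pd.Series,
                                     n_bins: int = 20) -> tuple[float, float]:
    """Spearman correlation between immune-score bins and mean heterogeneity.

    Samples are split into ``n_bins`` equal-size groups by immune score; the
    per-bin mean log2 cluster count is correlated (Spearman) against the bin
    index.  Requires at least ``2 * n_bins`` paired samples.
    """
    common = immune_scores.index.intersection(log2_clusters.index)
    if len(common) < 2 * n_bins:
        raise ValueError(f"need at least {2 * n_bins} paired samples")
    s = immune_scores.loc[common]
    ranks = s.rank(method="first")
    bins = pd.qcut(ranks, n_bins, labels=False)
    means = log2_clusters.loc[common].groupby(bins).mean()
    rho, p = stats.spearmanr(means.index.to_numpy(), means.to_numpy())
    return float(rho), float(p)
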