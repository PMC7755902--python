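"""Mutational-signature spectra and exposure refitting.

A mutational signature is a probability profile over the 96 pyrimidine-centred
trinucleotide substitution channels (C>A, C>G, C>T, T>A, T>C, T>G, each in 16
flanking contexts).  Given a fixed catalog of K signatures, per-sample
*exposures* are the non-negative mixture weights that best reconstruct a
sample's observed spectrum.  The refit here is constrained least squares on
the normalised spectrum with a floor-and-renormalise rule: fitted weights
below ``weight_floor`` are zeroed and the survivors rescaled, and the mass the
catalog could not explain is reported separately so that
``weights + unexplained == 1`` for every eligible sample.

The packaged default catalog is a synthetic stand-in with the shape, channel
order and signature labels of the 13 breast-cancer COSMIC v2 signatures
(1, 2, 13, 3, 8, 6, 15, 20, 26, 5, 17, 18, 30); see
``data/signature_catalog_synthetic_cosmicv2_like.tsv``.
"""

from __future__ import annotations

import logging
import warnings
from importlib import resources

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator, TransformerMixin

logger = logging.getLogger(__name__)

SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_BASES = "ACGT"
#: The 96 channels in standard order: substitution blocks, contexts sorted
#: alphabetically by (5' flank, 3' flank).
CHANNELS: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}" for sub in SUBSTITUTIONS for five in _BASES for three in _BASES
)
_CHANNEL_INDEX = {c: i for i, c in enumerate(CHANNELS)}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

SIGNATURE_LABELS = ("1", "2", "13", "3", "8", "6", "15", "20", "26", "5", "17", "18", "30")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def mutation_channel(ref: str, alt: str, context: str) -> str:
    """Map an SNV with its reference-strand trinucleotide context to a channel.

    Purine-reference mutations are reverse-complemented into the
    pyrimidine-centred convention.  Raises ``ValueError`` for malformed input.
    """
    if len(ref) != 1 or len(alt) != 1 or len(context) != 3:
        raise ValueError(f"malformed mutation ({ref}, {alt}, {context})")
    if context[1] != ref:
        raise ValueError(f"context {context} does not centre on ref {ref}")
    if ref in "GA":
        ref, alt, context = revcomp(ref), revcomp(alt), revcomp(context)
    channel = f"{context[0]}[{ref}>{alt}]{context[2]}"
    if channel not in _CHANNEL_INDEX:
        raise ValueError(f"invalid channel {channel}")
    return channel


def channel_to_mutation(channel: str) -> tuple[str, str, str]:
    """Inverse of :func:`mutation_channel` (pyrimidine-strand representation)."""
    five, rest = channel.split("[")
    sub, three = rest.split("]")
    ref, alt = sub.split(">")
    return ref, alt, five + ref + three


def load_catalog(path=None) -> pd.DataFrame:
    """Load a 96 x K signature catalog (channels x signatures) from TSV.

    Without ``path``, loads the packaged synthetic COSMIC-v2-like 13-signature
    catalog.  Columns are validated to be non-negative and sum to 1.
    """
    if path is None:
        ref = resources.files("cohortcompare.data").joinpath(
            "signature_catalog_synthetic_cosmicv2_like.tsv"
        )
        with resources.as_file(ref) as p:
            cat = pd.read_csv(p, sep="\t", index_col=0)
    else:
        cat = pd.read_csv(path, sep="\t", index_col=0)
    if list(cat.index) != list(CHANNELS):
        raise ValueError("catalog channels do not match the standard 96-channel order")
    if (cat.values < 0).any():
        raise ValueError("catalog contains negative entries")
    colsums = cat.sum(axis=0)
    if not np.allclose(colsums, 1.0, atol=1e-6):
        raise ValueError("catalog columns must sum to 1")
    return cat


def tally_96(mutations: pd.DataFrame, sample_col: str = "sample") -> pd.DataFrame:
    """Tally SNVs into per-sample 96-channel spectra.

    ``mutations`` needs columns ``ref``, ``alt``, ``context`` (reference-strand
    trinucleotide) and ``sample_col``.  Malformed records are skipped with a
    log entry.  Returns a samples x 96 count DataFrame.
    """
    samples = pd.unique(mutations[sample_col])
    out = pd.DataFrame(0, index=pd.Index(samples, name=sample_col), columns=list(CHANNELS))
    n_skipped = 0
    for row in mutations.itertuples(index=False):
        try:
            ch = mutation_channel(
                getattr(row, "ref"), getattr(row, "alt"), getattr(row, "context")
            )
        except (ValueError, TypeError):
            n_skipped += 1
            continue
        out.loc[getattr(row, sample_col), ch] += 1
    if n_skipped:
        logger.warning("tally_96: skipped %d malformed records", n_skipped)
    return out


class SignatureRefitter(BaseEstimator, TransformerMixin):
    """Refit per-sample signature exposures by non-negative least squares.

    Parameters
    ----------
    catalog : DataFrame or None
        96 x K signature matrix; defaults to the packaged synthetic catalog.
    min_snvs : int
        Samples with fewer SNVs are flagged ineligible (weights reported as 0,
        ``unexplained`` as NaN).
    weight_floor : float
        Fitted weights below this are zeroed; survivors are rescaled so that
        weights plus ``unexplained`` sum to 1.
    """

    def __init__(self, catalog: pd.DataFrame | None = None, min_snvs: int = 15,
                 weight_floor: float = 0.06):
        self.catalog = catalog
        self.min_snvs = min_snvs
        self.weight_floor = weight_floor

    def fit(self, X=None, y=None):
        cat = self.catalog if self.catalog is not None else load_catalog()
        if (cat.values < 0).any() or not np.allclose(cat.sum(axis=0), 1.0, atol=1e-6):
            raise ValueError("catalog columns must be non-negative and sum to 1")
        self.catalog_ = cat
        self.signature_names_ = list(cat.columns)
        return self

    def _refit_one(self, counts: np.ndarray) -> tuple[np.ndarray, float]:
        total = counts.sum()
        v = counts / total
        w, _ = optimize.nnls(self.catalog_.values, v)
        unexplained = max(0.0, 1.0 - w.sum())
        w = np.where(w < self.weight_floor, 0.0, w)
        s = w.sum()
        if s == 0.0:
            return w, 1.0
        w = w * (1.0 - unexplained) / s
        return w, unexplained

    def transform(self, spectra: pd.DataFrame) -> pd.DataFrame:
        """Return exposures: samples x (signatures + unexplained/total/eligible)."""
        if not hasattr(self, "catalog_"):
            self.fit()
        if list(spectra.columns) != list(self.catalog_.index):
            raise ValueError("spectra channels do not match catalog channels")
        rows = []
        for sample, counts in spectra.iterrows():
            c = counts.to_numpy(dtype=float)
            total = int(c.sum())
            if total < self.min_snvs:
                rows.append([0.0] * len(self.signature_names_) + [np.nan, total, False])
                continue
            w, unexplained = self._refit_one(c)
            rows.append(list(w) + [unexplained, total, True])
        out = pd.DataFrame(
            rows, index=spectra.index,
            columns=self.signature_names_ + ["unexplained", "total_snvs", "eligible"],
        )
        out["total_snvs"] = out["total_snvs"].astype(int)
        out["eligible"] = out["eligible"].astype(bool)
        return out

    def fit_transform(self, X, y=None, **kwargs):
        return self.fit().transform(X)


def refit_exposures(spectra: pd.DataFrame, catalog: pd.DataFrame | None = None,
                    min_snvs: int = 15, weight_floor: float = 0.06) -> pd.DataFrame:
    """Functional wrapper over :class:`SignatureRefitter`."""
    return SignatureRefitter(catalog, min_snvs, weight_floor).fit().transform(spectra)


def exposure_columns(exposures: pd.DataFrame) -> list[str]:
    return [c for c in exposures.columns if c not in ("unexplained", "total_snvs", "eligible")]


def carrier_calls(exposures: pd.DataFrame, carrier_floor: float = 0.06) -> pd.DataFrame:
    """Binary sample x signature carrier matrix: carrier iff weight strictly
    exceeds ``carrier_floor``.  Ineligible samples are all-False."""
    sig_cols = exposure_columns(exposures)
    carriers = exposures[sig_cols].gt(carrier_floor)
    carriers.loc[~exposures["eligible"], :] = False
    return carriers


def compare_carrier_fractions(fractions: pd.DataFrame, groups: dict[str, str]) -> pd.DataFrame:
    """Two-sided t-test per signature on per-dataset carrier fractions.

    ``fractions`` is datasets x signatures; ``groups`` maps each dataset to one
    of two population labels.  Groups with fewer than two datasets, or pairs
    with zero variance in both groups, give ``p = NaN`` with ``flag`` set.
    """
    labels = sorted(set(groups.values()))
    if len(labels) != 2:
        raise ValueError("exactly two population labels required")
    a = fractions.loc[[d for d in fractions.index if groups[d] == labels[0]]]
    b = fractions.loc[[d for d in fractions.index if groups[d] == labels[1]]]
    rows = []
    for sig in fractions.columns:
        if len(a) < 2 or len(b) < 2:
            rows.append((sig, np.nan, np.nan, "fewer_than_2_datasets"))
            continue
        xa, xb = a[sig].to_numpy(), b[sig].to_numpy()
        if np.var(xa) == 0 and np.var(xb) == 0:
            if np.allclose(xa.mean(), xb.mean()):
                rows.append((sig, 0.0, 1.0, "identical"))
            else:
                rows.append((sig, np.nan, np.nan, "degenerate_zero_variance"))
            continue
        t, p = stats.ttest_ind(xa, xb)
        rows.append((sig, t, p, ""))
    return pd.DataFrame(rows, columns=["signature", "t", "p", "flag"]).set_index("signature")


def quartile_signature_test(exposures: pd.DataFrame, immune_scores: pd.Series) -> pd.Series:
    """One-sided Wilcoxon rank-sum per signature: top vs bottom immune quartile.

    Samples are ranked by immune score; the alternative is that signature
    weights are *greater* in the top quartile.  Midrank tie handling via the
    Mann-Whitney U statistic.
    """
    common = exposures.index.intersection(immune_scores.index)
    if len(common) < 8:
        raise ValueError("need at least 8 samples with both exposures and immune scores")
    scores = immune_scores.loc[common].sort_values(kind="mergesort")
    q = len(common) // 4
    bottom, top = scores.index[:q], scores.index[-q:]
    out = {}
    for sig in exposure_columns(exposures):
        hi = exposures.loc[top, sig].to_numpy()
        lo = exposures.loc[bottom, sig].to_numpy()
        if np.all(hi == hi[0]) and np.all(lo == lo[0]) and hi[0] == lo[0]:
            out[sig] = 1.0
            continue
        _, p = stats.mannwhitneyu(hi, lo, alternative="greater")
        out[sig] = p
    return pd.Series(out, name="p_top_vs_bottom")


def signature_immune_correlation(exposures: pd.DataFrame,
                                 score_sets: pd.DataFrame) -> pd.DataFrame:
    """Spearman rho (midrank ties) for each (signature, immune score) pair.

    Constant vectors give NaN.
    """
    common = exposures.index.intersection(score_sets.index)
    sig_cols = exposure_columns(exposures)
    out = pd.DataFrame(index=sig_cols, columns=score_sets.columns, dtype=float)
    for sig in sig_cols:
        x = exposures.loc[common, sig].to_numpy()
        for sc in score_sets.columns:
            y = score_sets.loc[common, sc].to_numpy()
            if np.all(x == x[0]) or np.all(y == y[0]):
                out.loc[sig, sc] = np.nan
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rho, _ = stats.spearmanr(x, y)
            out.loc[sig, sc] = rho
    return out
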