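"""Oncogene / tumour-suppressor driver-gene scoring (20/20-rule style).

For each gene within a population x ER stratum:

* ONC score — percentage of the gene's mutations that are missense hits at
  its single most recurrent amino-acid position; evidence that a gene is
  activated at a hotspot.  Undefined unless the top position carries at least
  ``min_recurrent`` missense mutations.
* TSG score — percentage of the gene's mutations that are protein
  inactivating (nonsense, frameshift, essential splice); evidence of
  loss-of-function selection.  Undefined below ``min_inactivating`` events.

Genes enter the analysis when mutated in at least 1% of samples of any
stratum; candidate drivers are genes with either score strictly above 20.
The denominator is the gene's mutation count in the stratum (the upstream
filtered table is nonsynonymous).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

INACTIVATING = frozenset({"nonsense", "frameshift", "splice"})


@dataclass
class GeneMutationSet:
    """All mutations of one gene within one stratum."""

    gene: str
    stratum: str
    mutations: list  # of (consequence, protein_pos)
    n_samples_in_stratum: int
    n_mutated_samples: int

    def __post_init__(self):
        if self.n_mutated_samples > self.n_samples_in_stratum:
            raise ValueError("more mutated samples than samples in stratum")


@dataclass
class DriverScore:
    gene: str
    stratum: str = ""
    onc: float | None = None
    tsg: float | None = None
    selected: bool = False


def gene_inclusion(tables: dict[str, pd.DataFrame], n_samples: dict[str, int],
                   min_fraction: float = 0.01) -> list[str]:
    """Genes mutated in >= ``min_fraction`` of samples in at least one stratum.

    ``tables`` maps stratum label to a mutation table with ``sample`` and
    ``gene`` columns; ``n_samples`` gives each stratum's denominator.
    """
    for stratum, n in n_samples.items():
        if n <= 0:
            raise ValueError(f"stratum {stratum!r} has zero samples")
    included: set[str] = set()
    for stratum, table in tables.items():
        if table.empty:
            continue
        frac = table.groupby("gene")["sample"].nunique() / n_samples[stratum]
        included.update(frac.index[frac >= min_fraction])
    return sorted(included)


def onc_score(ms: GeneMutationSet, min_recurrent: int = 5) -> float | None:
    """Percentage of mutations at the most recurrent missense position.

    Undefined (None) when that position has fewer than ``min_recurrent``
    missense mutations, or when there are no mutations at all.
    """
    total = len(ms.mutations)
    if total == 0:
        return None
    pos_counts: dict = {}
    for consequence, protein_pos in ms.mutations:
        if consequence == "missense" and protein_pos is not None and not pd.isna(protein_pos):
            pos_counts[protein_pos] = pos_counts.get(protein_pos, 0) + 1
    r = max(pos_counts.values(), default=0)
    if r < min_recurrent:
        return None
    return 100.0 * r / total


def tsg_score(ms: GeneMutationSet, min_inactivating: int = 5) -> float | None:
    """Percentage of mutations that are inactivating (nonsense, frameshift,
    splice).  Undefined below ``min_inactivating`` inactivating events."""
    total = len(ms.mutations)
    if total == 0:
        return None
    n_inact = sum(1 for consequence, _ in ms.mutations if consequence in INACTIVATING)
    if n_inact < min_inactivating:
        return None
    return 100.0 * n_inact / total


def select_drivers(scores: list[DriverScore], threshold: float = 20.0) -> list[str]:
    """Genes with ONC or TSG strictly above ``threshold``; sets ``selected``."""
    selected = []
    for s in scores:
        s.selected = (s.onc is not None and s.onc > threshold) or (
            s.tsg is not None and s.tsg > threshold
        )
        if s.selected:
            selected.append(s.gene)
    return selected


def score_stratum(maf: pd.DataFrame, stratum: str, n_samples_in_stratum: int,
                  min_recurrent: int = 5, min_inactivating: int = 5,
                  threshold: float = 20.0) -> pd.DataFrame:
    """Score every gene of one stratum's mutation table.

    ``maf`` needs columns ``sample``, ``gene``, ``consequence``,
    ``protein_pos``.  Returns a DataFrame (gene, n_mutations,
    n_mutated_samples, onc, tsg, selected).
    """
    rows = []
    for gene, sub in maf.groupby("gene"):
        ms = GeneMutationSet(
            gene=gene, stratum=stratum,
            mutations=list(zip(sub["consequence"], sub["protein_pos"])),
            n_samples_in_stratum=n_samples_in_stratum,
            n_mutated_samples=sub["sample"].nunique(),
        )
        onc = onc_score(ms, min_recurrent)
        tsg = tsg_score(ms, min_inactivating)
        sel = (onc is not None and onc > threshold) or (tsg is not None and tsg > threshold)
        rows.append((gene, len(ms.mutations), ms.n_mutated_samples, onc, tsg, sel))
    return pd.DataFrame(
        rows, columns=["gene", "n_mutations", "n_mutated_samples", "onc", "tsg", "selected"]
    ).set_index("gene")
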