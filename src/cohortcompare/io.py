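"""Plain-text input/output: MAF-like TSV tables, gene sets (GMT), configs."""

from __future__ import annotations

import pandas as pd
import yaml

from .synthetic import CohortConfig, GeneSet


def read_maf(path) -> pd.DataFrame:
    """Read a MAF-like TSV (1-based closed coordinates)."""
    return pd.read_csv(path, sep="\t")


def write_maf(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(table: pd.DataFrame, path, index: bool = False) -> None:
    table.to_csv(path, sep="\t", index=index)


def read_pon(path) -> set[tuple]:
    """Panel of normals as a 3-column TSV (chrom, pos, alt)."""
    df = pd.read_csv(path, sep="\t")
    return set(zip(df["chrom"].astype(str), df["pos"].astype(int), df["alt"]))


def write_pon(sites, path) -> None:
    pd.DataFrame(sorted(sites), columns=["chrom", "pos", "alt"]).to_csv(
        path, sep="\t", index=False)


def read_gmt(path) -> list[GeneSet]:
    """GMT: one set per line, tab-separated (name, description, genes...)."""
    sets = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets.append(GeneSet(parts[0], [g for g in parts[2:] if g]))
    return sets


def write_gmt(gene_sets, path) -> None:
    with open(path, "w") as fh:
        for gs in gene_sets:
            fh.write("\t".join([gs.name, "na"] + list(gs.members)) + "\n")


def read_config(path) -> CohortConfig:
    """Cohort-generator configuration from YAML (keys = CohortConfig fields)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "purity_range" in raw:
        raw["purity_range"] = tuple(raw["purity_range"])
    return CohortConfig(**raw)
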