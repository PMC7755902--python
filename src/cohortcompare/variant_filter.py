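"""Somatic SNV/indel post-calling filter cascade.

Candidate calls (one row per variant, with read-level evidence columns) are
judged against a fixed cascade: panel-of-normals exclusion, minimum tumour and
normal depth, an oxidative-artefact (OxoG) metric, a variant-allele-fraction
floor, a Fisher exact test on read strandedness, a caller-supplied S_AF score,
population-frequency (gnomAD) exclusion, minimum alternate-read support with
per-strand balance, and a second-caller requirement for indels.  A cohort-wide
recurrence filter then removes positions seen in many samples unless they are
known somatic hotspots (COSMIC).  Every record gets a per-rule audit trail.

Coordinates are 1-based fully closed (MAF convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: Columns a candidate call must carry.
REQUIRED_COLUMNS = (
    "sample", "chrom", "pos", "ref", "alt", "variant_type",
    "t_depth", "n_depth", "alt_fwd", "alt_rev", "ref_fwd", "ref_rev",
    "vaf", "oxog_metric", "s_af", "gnomad_af", "in_cosmic", "in_str",
    "second_caller",
)

#: Cascade rule names in evaluation (and audit) order.
RULE_ORDER = (
    "pon", "min_t_depth", "min_n_depth", "max_oxog", "min_vaf",
    "strand_bias", "min_s_af", "max_gnomad", "min_alt_reads",
    "min_alt_per_strand", "indel_second_caller",
)


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the cascade.  Bounds follow the stated rules literally:
    depth and VAF floors are inclusive, OxoG and gnomAD cutoffs exclusive on
    retention, S_AF strictly greater-than."""

    min_t_depth: int = 10
    min_n_depth: int = 5
    max_oxog: float = 0.8
    min_vaf: float = 0.075
    min_strand_p: float = 0.05
    min_s_af: float = 0.75
    recurrence_threshold: int = 5
    max_gnomad_af: float = 0.01
    min_alt_reads: int = 4
    min_alt_per_strand: int = 2
    pon_min_normals: int = 2

    def __post_init__(self):
        for f in fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"threshold {f.name} must be strictly positive")


def build_panel_of_normals(normal_calls, pon_min_normals: int = 2) -> set[tuple]:
    """Sites (chrom, pos, alt) called in at least ``pon_min_normals`` distinct
    normal samples.

    ``normal_calls``: iterable of (normal_sample_id, chrom, pos, alt) or a
    DataFrame with those columns.  Duplicate (sample, site) entries count once.
    """
    if isinstance(normal_calls, pd.DataFrame):
        rows = normal_calls[["normal_sample", "chrom", "pos", "alt"]].itertuples(index=False)
    else:
        rows = normal_calls
    seen: dict[tuple, set] = {}
    for sample, chrom, pos, alt in rows:
        seen.setdefault((chrom, pos, alt), set()).add(sample)
    return {site for site, samples in seen.items() if len(samples) >= pon_min_normals}


def strand_bias_p(alt_fwd: int, alt_rev: int, ref_fwd: int, ref_rev: int) -> float:
    """Two-sided Fisher exact p for the 2x2 strandedness table
    [[alt_fwd, alt_rev], [ref_fwd, ref_rev]].  An all-zero table returns 1
    by convention."""
    if min(alt_fwd, alt_rev, ref_fwd, ref_rev) < 0:
        raise ValueError("read counts must be non-negative")
    if alt_fwd + alt_rev + ref_fwd + ref_rev == 0:
        logger.debug("strand_bias_p: all-zero table, returning 1 by convention")
        return 1.0
    _, p = stats.fisher_exact([[alt_fwd, alt_rev], [ref_fwd, ref_rev]])
    return float(p)


def _evaluate_record(row, pon: set, config: FilterConfig) -> list[tuple[str, bool]]:
    """Per-rule outcomes for one validated record, in RULE_ORDER."""
    outcomes = [
        ("pon", (row["chrom"], row["pos"], row["alt"]) not in pon),
        ("min_t_depth", row["t_depth"] >= config.min_t_depth),
        ("min_n_depth", row["n_depth"] >= config.min_n_depth),
        ("max_oxog", row["oxog_metric"] < config.max_oxog),
        ("min_vaf", row["vaf"] >= config.min_vaf),
        ("strand_bias",
         strand_bias_p(row["alt_fwd"], row["alt_rev"], row["ref_fwd"], row["ref_rev"])
         >= config.min_strand_p),
        ("min_s_af", row["s_af"] > config.min_s_af),
        ("max_gnomad", row["gnomad_af"] < config.max_gnomad_af),
        ("min_alt_reads", row["alt_fwd"] + row["alt_rev"] >= config.min_alt_reads),
        ("min_alt_per_strand",
         min(row["alt_fwd"], row["alt_rev"]) >= config.min_alt_per_strand),
        ("indel_second_caller",
         row["variant_type"] != "indel" or bool(row["second_caller"])),
    ]
    return outcomes


def apply_snv_filters(records: pd.DataFrame, pon: set | None = None,
                      config: FilterConfig | None = None,
                      whitelist: set | None = None
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the per-record cascade.

    Returns ``(retained, audit)``.  ``audit`` has one row per (record, rule)
    with the rule outcome, plus a ``verdict`` rule summarising the record.
    Records with missing required fields are excluded with rule
    ``missing_field`` and the run continues.  ``whitelist`` sites
    (chrom, pos, alt) bypass the cascade (manual-salvage mechanism, empty by
    default).
    """
    pon = pon or set()
    config = config or FilterConfig()
    whitelist = whitelist or set()
    missing_cols = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if missing_cols:
        raise ValueError(f"records table missing columns {missing_cols}")

    audit_rows = []
    keep_idx = []
    for idx, row in records.iterrows():
        vals = row[list(REQUIRED_COLUMNS)]
        if vals.isna().any():
            bad = vals.index[vals.isna()].tolist()
            audit_rows.append((idx, "missing_field", False))
            audit_rows.append((idx, "verdict", False))
            logger.warning("record %s excluded: missing fields %s", idx, bad)
            continue
        if (row["chrom"], row["pos"], row["alt"]) in whitelist:
            audit_rows.append((idx, "whitelist", True))
            audit_rows.append((idx, "verdict", True))
            keep_idx.append(idx)
            continue
        outcomes = _evaluate_record(row, pon, config)
        verdict = all(ok for _, ok in outcomes)
        audit_rows.extend((idx, rule, ok) for rule, ok in outcomes)
        audit_rows.append((idx, "verdict", verdict))
        if verdict:
            keep_idx.append(idx)
    audit = pd.DataFrame(audit_rows, columns=["record", "rule", "passed"])
    return records.loc[keep_idx].copy(), audit


def recurrence_filter(retained: pd.DataFrame, threshold: int = 5,
                      rescue_cosmic: bool = True
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove positions recurrent in >= ``threshold`` samples cohort-wide,
    unless flagged as COSMIC hotspots (the rescue is the default
    interpretation of the recurrence exception; the in_str flag is carried but
    unused by default).

    Returns ``(filtered, removed_log)`` where the log lists each removed
    position with its sample count.
    """
    if retained.empty:
        return retained.copy(), pd.DataFrame(columns=["chrom", "pos", "n_samples"])
    grp = retained.groupby(["chrom", "pos"])
    n_samples = grp["sample"].nunique()
    any_cosmic = grp["in_cosmic"].any()
    recurrent = n_samples[n_samples >= threshold]
    to_remove = [
        site for site in recurrent.index
        if not (rescue_cosmic and any_cosmic.loc[site])
    ]
    if not to_remove:
        return retained.copy(), pd.DataFrame(columns=["chrom", "pos", "n_samples"])
    removed_log = pd.DataFrame(
        [(c, p, int(n_samples.loc[(c, p)])) for c, p in to_remove],
        columns=["chrom", "pos", "n_samples"],
    )
    key = retained.set_index(["chrom", "pos"]).index
    mask = ~key.isin(to_remove)
    logger.info("recurrence_filter: removed %d positions (%d records)",
                len(to_remove), int((~mask).sum()))
    return retained.loc[mask].copy(), removed_log


def filter_pipeline(records: pd.DataFrame, pon: set | None = None,
                    config: FilterConfig | None = None,
                    whitelist: set | None = None
                    ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Full cascade: per-record rules then cohort recurrence.

    Returns (filtered table, per-record audit, removed-position log).
    """
    config = config or FilterConfig()
    retained, audit = apply_snv_filters(records, pon, config, whitelist)
    filtered, removed = recurrence_filter(retained, config.recurrence_threshold)
    return filtered, audit, removed
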