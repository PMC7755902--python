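"""Synthetic two-cohort generator.

Emulates the statistical structure a two-population breast-cancer comparison
assumes, so every downstream stage is testable without controlled-access
data: two cohorts ("A", Asian-like; "B", Caucasian-like) differing in
molecular-subtype prevalence (an IntClust-5-like subtype at 13.1% vs 7.9%),
TP53 mutation prevalence within ER+ samples, a cohort-wide immune-infiltration
shift in expression, per-sample signature mixtures over a 13-signature
catalog, clonal architecture producing binomially sampled VAFs, and
exponential survival with hazards depending on TP53 and immune status.

All distributional choices (negative-binomial mutation counts, Gaussian
log-expression, exponential survival, Dirichlet exposure priors) are the
generator's own documented defaults, chosen as the simplest forms with the
required moments.  Trinucleotide context is attached directly to each
simulated mutation, so signature tallying never needs a reference genome.

Determinism: identical seeds give identical bundles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .signatures import CHANNELS, SIGNATURE_LABELS, channel_to_mutation, load_catalog


class ConfigError(ValueError):
    """Invalid generator configuration; the message names the offending field."""


@dataclass
class GeneSet:
    name: str
    members: list

    def __post_init__(self):
        if not self.members:
            raise ValueError(f"gene set {self.name!r} is empty")
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"gene set {self.name!r} has duplicate members")


def _default_subtype_prevalences() -> dict:
    # IC5-like subtype at 13.1% vs 7.9%; an ER-negative IC4-like subtype at
    # 9.1% vs 4.6%; remainder spread over common luminal/basal-like labels.
    return {
        "A": {"IC3": 0.15, "IC4neg": 0.091, "IC5": 0.131, "IC8": 0.18,
              "IC10": 0.12, "Other": 0.328},
        "B": {"IC3": 0.17, "IC4neg": 0.046, "IC5": 0.079, "IC8": 0.20,
              "IC10": 0.12, "Other": 0.385},
    }


def _default_er_rates() -> dict:
    return {"IC3": 0.95, "IC4neg": 0.0, "IC5": 0.5, "IC8": 0.95,
            "IC10": 0.1, "Other": 0.75}


def _default_signature_priors() -> dict:
    # Dirichlet alphas over the 13 signatures in catalog order
    # (1, 2, 13, 3, 8, 6, 15, 20, 26, 5, 17, 18, 30): clock-like signatures
    # dominate luminal-like subtypes, the APOBEC pair the IC5-like subtype,
    # the flat HRD-like signature the basal-like subtype.
    idx = {name: i for i, name in enumerate(SIGNATURE_LABELS)}

    def alphas(**kw):
        a = np.full(13, 0.2)
        for name, v in kw.items():
            a[idx[name.lstrip("s")]] = v
        return a.tolist()

    return {
        "IC3": alphas(s1=6.0, s5=2.0),
        "IC8": alphas(s1=6.0, s5=2.0),
        "Other": alphas(s1=4.0, s5=2.0, s2=0.5),
        "IC5": alphas(s2=4.0, s13=4.0, s1=1.0),
        "IC10": alphas(s3=5.0, s1=1.0),
        "IC4neg": alphas(s1=2.0, s3=2.0, s2=1.0),
    }


@dataclass
class CohortConfig:
    """Study conditions for the two synthetic cohorts (defaults emulate the
    comparison's reported structure; seed 17 by default)."""

    n_samples_per_cohort: int = 500
    subtype_prevalences: dict = field(default_factory=_default_subtype_prevalences)
    er_positive_rate: dict = field(default_factory=_default_er_rates)
    tp53_rate_er_pos: dict = field(default_factory=lambda: {"A": 0.25, "B": 0.15})
    tp53_rate_er_neg: dict = field(default_factory=lambda: {"A": 0.60, "B": 0.60})
    immune_shift: float = 0.5
    signature_exposure_priors: dict = field(default_factory=_default_signature_priors)
    mean_mutations_per_sample: float = 45.0
    mutation_dispersion: float = 5.0
    depth_mean: float = 75.0
    purity_range: tuple = (0.3, 0.9)
    survival_baseline_hazard: float = 0.08
    hazard_ratio_tp53: float = 2.0
    hazard_ratio_immune_high: float = 0.5
    followup_min_years: float = 2.0
    followup_max_years: float = 10.0
    seed: int = 17

    def validate(self) -> None:
        if self.n_samples_per_cohort <= 0:
            raise ConfigError("n_samples_per_cohort must be positive")
        for cohort, prev in self.subtype_prevalences.items():
            vals = np.array(list(prev.values()), dtype=float)
            if ((vals < 0) | (vals > 1)).any():
                raise ConfigError(f"subtype_prevalences[{cohort!r}] has entries outside [0,1]")
            if abs(vals.sum() - 1.0) > 1e-9:
                raise ConfigError(f"subtype_prevalences[{cohort!r}] does not sum to 1")
        for name, d in (("er_positive_rate", self.er_positive_rate),
                        ("tp53_rate_er_pos", self.tp53_rate_er_pos),
                        ("tp53_rate_er_neg", self.tp53_rate_er_neg)):
            for k, v in d.items():
                if not 0 <= v <= 1:
                    raise ConfigError(f"{name}[{k!r}] outside [0,1]")
        lo, hi = self.purity_range
        if not (0 < lo <= hi <= 1):
            raise ConfigError("purity_range must lie in (0,1] with lo <= hi")
        for name in ("mean_mutations_per_sample", "depth_mean",
                     "survival_baseline_hazard", "hazard_ratio_tp53",
                     "hazard_ratio_immune_high"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        for subtype, alphas in self.signature_exposure_priors.items():
            if len(alphas) != 13 or any(a <= 0 for a in alphas):
                raise ConfigError(
                    f"signature_exposure_priors[{subtype!r}] must be 13 positive alphas")


@dataclass
class SyntheticTruth:
    """Ground truth: per-sample labels/latents, per-sample exposures, and
    per-variant clone assignments (aligned with the mutation table index)."""

    samples: pd.DataFrame
    exposures: pd.DataFrame
    variants: pd.DataFrame


@dataclass
class ExpressionMatrix:
    """Gene x sample TPM matrix with a matching pseudo-count matrix."""

    tpm: pd.DataFrame
    counts: pd.DataFrame


@dataclass
class CohortBundle:
    cohort_table: pd.DataFrame
    mutation_table: pd.DataFrame
    expression: ExpressionMatrix
    purity_cn: pd.DataFrame
    truth: SyntheticTruth


def default_immune_gene_sets() -> list[GeneSet]:
    """Three disjoint synthetic immune gene sets standing in for the usual
    infiltration / immune-cell / IFN-gamma collections."""
    return [
        GeneSet("IMMUNE_ESTIMATE_LIKE", [f"IMM{i:04d}" for i in range(1, 41)]),
        GeneSet("IMMUNE_CELLS_COMBINED", [f"IMM{i:04d}" for i in range(41, 71)]),
        GeneSet("IFNG_EXPANDED", [f"IMM{i:04d}" for i in range(71, 91)]),
    ]


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def generate_mutation_catalog(exposures, n_mutations: int, catalog: pd.DataFrame,
                              seed: int) -> pd.Series:
    """Multinomial 96-channel count vector from an exposure-weighted mixture
    of signature profiles."""
    w = np.asarray(exposures, dtype=float)
    if (w < 0).any():
        raise ConfigError("exposures must be non-negative")
    if abs(w.sum() - 1.0) > 1e-6:
        raise ConfigError("exposures must sum to 1 within 1e-6")
    if n_mutations < 0:
        raise ConfigError("n_mutations must be >= 0")
    p = catalog.values @ w
    p = p / p.sum()
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_mutations, p) if n_mutations > 0 else np.zeros(96, dtype=int)
    return pd.Series(counts, index=list(catalog.index), name="count")


def expected_vaf(ccf: float, purity: float, cn_total: int, m: int = 1) -> float:
    return ccf * m * purity / (purity * cn_total + (1 - purity) * 2)


def generate_clonal_vafs(clone_ccfs, clone_weights, purity: float, cn_total: int,
                         depth: int, n_variants: int, seed: int,
                         multiplicity: int = 1) -> pd.DataFrame:
    """Per-variant (alt_count, depth, clone id) under the binomial read model."""
    ccfs = np.asarray(clone_ccfs, dtype=float)
    w = np.asarray(clone_weights, dtype=float)
    if not 0 < purity <= 1:
        raise ConfigError("purity must lie in (0,1]")
    if cn_total < 1 or depth < 1:
        raise ConfigError("cn_total and depth must be >= 1")
    if abs(w.sum() - 1.0) > 1e-9 or (w < 0).any():
        raise ConfigError("clone_weights must be a probability vector")
    evaf = np.array([expected_vaf(c, purity, cn_total, multiplicity) for c in ccfs])
    if (evaf > 1).any():
        raise ConfigError("configuration yields expected VAF > 1")
    rng = np.random.default_rng(seed)
    clone_id = rng.choice(len(ccfs), size=n_variants, p=w)
    alt = rng.binomial(depth, evaf[clone_id])
    return pd.DataFrame({
        "alt_count": alt, "depth": depth, "clone_id": clone_id,
        "expected_vaf": evaf[clone_id],
    })


def generate_expression(cohort_table: pd.DataFrame, immune_gene_sets: list[GeneSet],
                        immune_shift: float, esr1_params=((2.0, 1.0), (6.0, 1.0)),
                        seed: int = 17, latent=None,
                        n_background: int = 1100) -> ExpressionMatrix:
    """Gene x sample expression with an immune latent factor and bimodal ESR1.

    Log2 expression is Gaussian around per-gene baselines; genes of the
    immune sets additionally receive a per-sample latent infiltration factor
    whose mean is ``immune_shift`` higher in cohort "A".  ESR1 is drawn from
    the mixture component matching each sample's true ER label
    (``esr1_params`` = ((mean_neg, sd_neg), (mean_pos, sd_pos)) on the
    log2(TPM+1)-like scale).  Returns TPM-like positive values and a matching
    Poisson pseudo-count matrix.
    """
    immune_genes: list[str] = []
    for gs in immune_gene_sets:
        if "ESR1" in gs.members:
            raise ConfigError(f"gene set {gs.name!r} must not contain ESR1")
        immune_genes.extend(gs.members)
    immune_genes = list(dict.fromkeys(immune_genes))
    rng = np.random.default_rng(seed)
    samples = cohort_table["patient_id"].tolist()
    n = len(samples)
    if latent is None:
        shift = np.where(cohort_table["cohort"].to_numpy() == "A", immune_shift, 0.0)
        latent = rng.normal(shift, 1.0)
    latent = np.asarray(latent, dtype=float)

    # checkpoint-gene panel so IMPRES is computable on simulated matrices;
    # checkpoint expression partially tracks infiltration
    from .immune import load_impres_features

    feats = load_impres_features(active_only=False)
    # the favourable gene of each checkpoint pair loads more strongly on the
    # infiltration factor, so the pairwise-inequality score tracks it
    loading: dict[str, float] = {}
    for row in feats.itertuples(index=False):
        hi, lo = (row.gene_a, row.gene_b) if row.relation == "greater" else \
            (row.gene_b, row.gene_a)
        loading.setdefault(hi, 0.9)
        loading.setdefault(lo, 0.1)
    checkpoint = [g for g in loading if g not in immune_genes]
    genes = (immune_genes + checkpoint + ["ESR1"]
             + [f"BG{i:04d}" for i in range(1, n_background + 1)])
    baseline = rng.uniform(2.0, 8.0, size=len(genes))
    n_imm = len(immune_genes)
    baseline[n_imm:n_imm + len(checkpoint)] = rng.uniform(4.0, 6.0, len(checkpoint))
    log_expr = baseline[:, None] + rng.normal(0.0, 1.0, size=(len(genes), n))
    log_expr[:n_imm, :] += latent[None, :]
    ckpt_loading = np.array([loading[g] for g in checkpoint])
    log_expr[n_imm:n_imm + len(checkpoint), :] += ckpt_loading[:, None] * latent[None, :]
    (mu_neg, sd_neg), (mu_pos, sd_pos) = esr1_params
    er_pos = (cohort_table["er_status"].to_numpy() == "pos")
    esr1 = np.where(er_pos, rng.normal(mu_pos, sd_pos, n), rng.normal(mu_neg, sd_neg, n))
    log_expr[genes.index("ESR1"), :] = esr1

    tpm = np.clip(2.0 ** log_expr - 1.0, 0.0, None)
    counts = rng.poisson(tpm * 5.0)
    gi = pd.Index(genes, name="gene")
    si = pd.Index(samples, name="sample")
    return ExpressionMatrix(
        tpm=pd.DataFrame(tpm, index=gi, columns=si),
        counts=pd.DataFrame(counts, index=gi, columns=si),
    )


# ---------------------------------------------------------------------------
# variant-record generator for the filter cascade
# ---------------------------------------------------------------------------

ARTIFACT_TAGS = (
    "low_depth_tumour", "low_depth_normal", "oxog", "low_vaf", "strand_bias",
    "low_s_af", "gnomad", "low_alt_reads", "single_strand", "indel_single_caller",
)

_RECORD_COLUMNS = [
    "sample", "chrom", "pos", "ref", "alt", "variant_type", "gene",
    "consequence", "protein_pos", "t_depth", "n_depth", "alt_fwd", "alt_rev",
    "ref_fwd", "ref_rev", "vaf", "oxog_metric", "s_af", "gnomad_af",
    "in_cosmic", "in_str", "second_caller", "truth", "violation",
]


def _passing_record(rng, depth_mean: float, sample: str, pos: int) -> dict:
    depth = max(30, int(rng.poisson(depth_mean)))
    alt = int(rng.binomial(depth, rng.uniform(0.15, 0.45)))
    alt = min(max(alt, max(8, math.ceil(0.09 * depth))), depth - 8)
    ref_reads = depth - alt
    is_indel = rng.random() < 0.1
    return {
        "sample": sample, "chrom": "1", "pos": pos, "ref": "C", "alt": "T",
        "variant_type": "indel" if is_indel else "SNV",
        "gene": f"GENE{int(rng.integers(1, 400)):04d}",
        "consequence": "missense", "protein_pos": int(rng.integers(1, 800)),
        "t_depth": depth, "n_depth": max(10, int(rng.poisson(40))),
        "alt_fwd": alt // 2 + alt % 2, "alt_rev": alt // 2,
        "ref_fwd": ref_reads // 2 + ref_reads % 2, "ref_rev": ref_reads // 2,
        "vaf": alt / depth,
        "oxog_metric": float(rng.uniform(0.0, 0.7)),
        "s_af": float(rng.uniform(0.8, 1.0)),
        "gnomad_af": float(rng.uniform(0.0, 0.005)),
        "in_cosmic": bool(rng.random() < 0.2), "in_str": False,
        "second_caller": True, "truth": "somatic", "violation": "",
    }


def _set_alt(rec: dict, alt_fwd: int, alt_rev: int, depth: int | None = None) -> None:
    if depth is not None:
        rec["t_depth"] = depth
    alt = alt_fwd + alt_rev
    ref_reads = rec["t_depth"] - alt
    rec.update(alt_fwd=alt_fwd, alt_rev=alt_rev,
               ref_fwd=ref_reads // 2 + ref_reads % 2, ref_rev=ref_reads // 2,
               vaf=alt / rec["t_depth"])


def _inject_violation(rec: dict, tag: str, rng) -> dict:
    rec = dict(rec)
    rec["truth"] = "artifact"
    rec["violation"] = tag
    if tag == "low_depth_tumour":
        depth = int(rng.integers(4, 10))  # < 10 reads in tumour
        alt = max(2, int(depth * 0.4))
        _set_alt(rec, alt // 2 + alt % 2, alt // 2, depth)
    elif tag == "low_depth_normal":
        rec["n_depth"] = int(rng.integers(0, 5))
    elif tag == "oxog":
        rec["oxog_metric"] = float(rng.uniform(0.8, 1.0))
    elif tag == "low_vaf":
        alt = max(1, int(0.074 * rec["t_depth"]))
        _set_alt(rec, alt // 2 + alt % 2, alt // 2)
    elif tag == "strand_bias":
        depth = max(60, rec["t_depth"])
        rec["t_depth"] = depth
        rec.update(alt_fwd=18, alt_rev=2, ref_fwd=5, ref_rev=depth - 25,
                   vaf=20 / depth)
    elif tag == "low_s_af":
        rec["s_af"] = float(rng.uniform(0.0, 0.75))
    elif tag == "gnomad":
        rec["gnomad_af"] = float(rng.uniform(0.01, 0.3))
    elif tag == "low_alt_reads":
        _set_alt(rec, 2, 1, 30)
    elif tag == "single_strand":
        _set_alt(rec, 8, 0, max(40, rec["t_depth"]))
    elif tag == "indel_single_caller":
        rec["variant_type"] = "indel"
        rec["second_caller"] = False
    else:
        raise ValueError(f"unknown artifact tag {tag!r}")
    return rec


def generate_variant_records(n_true: int, n_artifact: int, depth_mean: float = 75.0,
                             seed: int = 17, tags=None) -> pd.DataFrame:
    """Candidate variant calls with truth labels for the filter cascade.

    True somatic records pass every cascade rule by construction; artifact
    records each carry an injected-violation tag naming the rule they break
    (cycled over ``tags``, default :data:`ARTIFACT_TAGS`).  The special tag
    ``recurrent_noncosmic`` emits groups of five same-position non-COSMIC
    records across distinct samples, which pass the per-record cascade but
    fall to the cohort recurrence filter.
    """
    if n_true < 0 or n_artifact < 0:
        raise ValueError("n_true and n_artifact must be >= 0")
    tags = list(tags) if tags is not None else list(ARTIFACT_TAGS)
    rng = np.random.default_rng(seed)
    rows = []
    pos = 10_000
    for i in range(n_true):
        pos += int(rng.integers(10, 1000))
        rows.append(_passing_record(rng, depth_mean, f"S{i % 50:03d}", pos))
    k = 0
    while k < n_artifact:
        tag = tags[k % len(tags)]
        if tag == "recurrent_noncosmic":
            pos += int(rng.integers(10, 1000))
            group = min(5, n_artifact - k)
            for j in range(group):
                rec = _passing_record(rng, depth_mean, f"R{k + j:04d}", pos)
                rec.update(in_cosmic=False, truth="artifact",
                           violation="recurrent_noncosmic")
                rows.append(rec)
            k += group
            continue
        pos += int(rng.integers(10, 1000))
        base = _passing_record(rng, depth_mean, f"A{k:04d}", pos)
        rows.append(_inject_violation(base, tag, rng))
        k += 1
    if not rows:
        return pd.DataFrame(columns=_RECORD_COLUMNS)
    return pd.DataFrame(rows, columns=_RECORD_COLUMNS)


def boundary_records() -> pd.DataFrame:
    """Deterministic records at the exact cascade thresholds (both sides):
    tumour depth 9/10, normal depth 4/5, OxoG 0.8, VAF 0.075, S_AF 0.75,
    gnomAD 0.01, 4 alternate reads, 2 reads per strand."""
    base = {
        "sample": "B000", "chrom": "2", "ref": "C", "alt": "T",
        "variant_type": "SNV", "gene": "GENE0001", "consequence": "missense",
        "protein_pos": 100, "n_depth": 40, "oxog_metric": 0.3, "s_af": 0.9,
        "gnomad_af": 0.0, "in_cosmic": False, "in_str": False,
        "second_caller": True, "truth": "boundary", "violation": "",
    }
    rows = []
    pos = 1000

    def add(t_depth, alt_fwd, alt_rev, **kw):
        nonlocal pos
        pos += 7
        ref_reads = t_depth - alt_fwd - alt_rev
        rec = dict(base, pos=pos, t_depth=t_depth, alt_fwd=alt_fwd, alt_rev=alt_rev,
                   ref_fwd=ref_reads // 2 + ref_reads % 2, ref_rev=ref_reads // 2,
                   vaf=(alt_fwd + alt_rev) / t_depth, **kw)
        rows.append(rec)

    add(10, 2, 2)                      # depth exactly at the floor: pass
    add(9, 2, 2)                       # one below: fail
    add(40, 5, 5, n_depth=5)           # normal depth at floor
    add(40, 5, 5, n_depth=4)
    add(40, 5, 5, oxog_metric=0.8)     # OxoG exactly at cutoff: fail (<0.8)
    add(40, 5, 5, oxog_metric=0.7999)
    add(200, 8, 7)                     # VAF 0.075 exactly: pass (inclusive)
    add(200, 8, 6)                     # VAF 0.07: fail
    add(40, 5, 5, s_af=0.75)           # S_AF must be strictly greater
    add(40, 5, 5, s_af=0.7501)
    add(40, 5, 5, gnomad_af=0.01)      # at 0.01: removed
    add(40, 5, 5, gnomad_af=0.0099)
    add(40, 2, 2)                      # exactly 4 alt reads, 2 per strand
    add(40, 2, 1)                      # 3 alt reads
    add(40, 3, 1)                      # 4 alt reads but single-strand deficit
    add(40, 5, 5, variant_type="indel", second_caller=True)
    add(40, 5, 5, variant_type="indel", second_caller=False)
    return pd.DataFrame(rows, columns=_RECORD_COLUMNS)


# ---------------------------------------------------------------------------
# full cohort bundle
# ---------------------------------------------------------------------------

_TP53_HOTSPOTS = (175, 245, 248, 273, 282)
_PIK3CA_HOTSPOTS = (542, 545, 1047)
_BACKGROUND_CONSEQUENCES = ("missense", "nonsense", "frameshift", "splice", "silent", "other")
_BACKGROUND_CONSEQUENCE_P = (0.62, 0.08, 0.05, 0.04, 0.12, 0.09)


def _sample_clones(rng) -> tuple[np.ndarray, np.ndarray]:
    n_clones = rng.choice([1, 2, 3], p=[0.5, 0.35, 0.15])
    ccfs = [1.0] + sorted(rng.uniform(0.2, 0.7, size=n_clones - 1), reverse=True)
    weights = rng.dirichlet(np.full(n_clones, 2.0))
    return np.array(ccfs), weights


def _driver_mutation(rng, gene: str, chrom: str, consequence: str,
                     protein_pos: int) -> dict:
    return {
        "gene": gene, "chrom": chrom,
        "pos": int(1_000_000 + protein_pos * 3 + rng.integers(0, 3)),
        "consequence": consequence, "protein_pos": protein_pos, "in_cosmic": True,
    }


_CHANNEL_REF = np.array([channel_to_mutation(c)[0] for c in CHANNELS])
_CHANNEL_ALT = np.array([channel_to_mutation(c)[1] for c in CHANNELS])
_CHANNEL_CTX = np.array([channel_to_mutation(c)[2] for c in CHANNELS])


def _sample_mutations(rng, patient: str, tp53: bool, exposure: np.ndarray,
                      purity: float, config: CohortConfig,
                      catalog: pd.DataFrame) -> tuple[dict, np.ndarray, np.ndarray]:
    """Vectorised per-sample mutation draw; returns column arrays."""
    r = config.mutation_dispersion
    mean = config.mean_mutations_per_sample
    n_mut = max(3, int(rng.negative_binomial(r, r / (r + mean))))
    mix = catalog.values @ exposure
    mix = mix / mix.sum()
    channel_ids = rng.choice(96, size=n_mut, p=mix)
    ccfs, weights = _sample_clones(rng)
    clone_ids = rng.choice(len(ccfs), size=n_mut, p=weights)

    specials = []
    if tp53:
        if rng.random() < 0.6:
            specials.append(_driver_mutation(
                rng, "TP53", "17", "missense", int(rng.choice(_TP53_HOTSPOTS))))
        else:
            cons = str(rng.choice(["nonsense", "frameshift", "splice"], p=[0.5, 0.35, 0.15]))
            specials.append(_driver_mutation(rng, "TP53", "17", cons,
                                             int(rng.integers(50, 390))))
    if rng.random() < 0.28:
        specials.append(_driver_mutation(
            rng, "PIK3CA", "3", "missense", int(rng.choice(_PIK3CA_HOTSPOTS))))
    if rng.random() < 0.097:
        specials.append(_driver_mutation(rng, "GATA3", "10", "frameshift",
                                         int(rng.integers(300, 440))))
    clone_ids[:len(specials)] = 0  # driver mutations are clonal

    gene = np.array([f"GENE{g:04d}" for g in rng.integers(1, 400, size=n_mut)])
    chrom = rng.integers(1, 23, size=n_mut).astype(str)
    pos = rng.integers(1_000_000, 200_000_000, size=n_mut)
    consequence = rng.choice(_BACKGROUND_CONSEQUENCES, size=n_mut,
                             p=_BACKGROUND_CONSEQUENCE_P)
    protein_pos = rng.integers(1, 800, size=n_mut)
    in_cosmic = np.zeros(n_mut, dtype=bool)
    for i, info in enumerate(specials):
        gene[i] = info["gene"]
        chrom[i] = info["chrom"]
        pos[i] = info["pos"]
        consequence[i] = info["consequence"]
        protein_pos[i] = info["protein_pos"]
        in_cosmic[i] = True

    sample_ccf = ccfs[clone_ids]
    evaf = expected_vaf(sample_ccf, purity, 2, 1)
    depth = np.maximum(8, rng.poisson(config.depth_mean, size=n_mut))
    alt = rng.binomial(depth, evaf)
    alt[:len(specials)] = np.maximum(alt[:len(specials)], 1)
    keep = alt > 0
    (channel_ids, clone_ids, gene, chrom, pos, consequence, protein_pos,
     in_cosmic, sample_ccf, depth, alt) = (
        a[keep] for a in (channel_ids, clone_ids, gene, chrom, pos, consequence,
                          protein_pos, in_cosmic, sample_ccf, depth, alt))
    n = int(keep.sum())
    is_indel = consequence == "frameshift"
    ref = _CHANNEL_REF[channel_ids].copy()
    alt_base = _CHANNEL_ALT[channel_ids].copy()
    context = _CHANNEL_CTX[channel_ids].astype(object)
    alt_base[is_indel] = ref[is_indel]
    ref = np.where(is_indel, np.char.add(ref, "A"), ref)
    context[is_indel] = None
    alt_fwd = rng.binomial(alt, 0.5)
    ref_reads = depth - alt
    ref_fwd = rng.binomial(ref_reads, 0.5)
    cols = {
        "sample": np.repeat(patient, n), "gene": gene, "chrom": chrom, "pos": pos,
        "ref": ref, "alt": alt_base,
        "variant_type": np.where(is_indel, "indel", "SNV"),
        "consequence": consequence, "protein_pos": protein_pos, "context": context,
        "t_depth": depth, "n_depth": np.maximum(5, rng.poisson(40.0, size=n)),
        "alt_fwd": alt_fwd, "alt_rev": alt - alt_fwd,
        "ref_fwd": ref_fwd, "ref_rev": ref_reads - ref_fwd,
        "vaf": alt / depth,
        "oxog_metric": rng.uniform(0.0, 0.6, size=n),
        "s_af": rng.uniform(0.8, 1.0, size=n),
        "gnomad_af": np.zeros(n), "in_cosmic": in_cosmic,
        "in_str": np.zeros(n, dtype=bool), "second_caller": np.ones(n, dtype=bool),
        "clone_id": clone_ids, "clone_ccf": sample_ccf,
    }
    return cols, ccfs, weights


def generate_cohorts(config: CohortConfig | None = None) -> CohortBundle:
    """Generate the full two-cohort bundle (clinical table, mutation table,
    expression, purity/copy-number, truth).  Deterministic in ``config.seed``."""
    config = config or CohortConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    catalog = load_catalog()

    clin_rows, exposure_rows, mut_rows, truth_rows = [], [], [], []
    age_means = {"A": 49.0, "B": 61.0}
    for cohort in ("A", "B"):
        prev = config.subtype_prevalences[cohort]
        subtype_labels = list(prev.keys())
        probs = np.array([prev[s] for s in subtype_labels], dtype=float)
        n = config.n_samples_per_cohort
        subtypes = rng.choice(subtype_labels, size=n, p=probs / probs.sum())
        shift = config.immune_shift if cohort == "A" else 0.0
        latent = rng.normal(shift, 1.0, size=n)
        for i in range(n):
            patient = f"{cohort}{i:04d}"
            subtype = subtypes[i]
            er_pos = rng.random() < config.er_positive_rate.get(subtype, 0.5)
            tp53_rate = (config.tp53_rate_er_pos if er_pos else config.tp53_rate_er_neg)[cohort]
            tp53 = rng.random() < tp53_rate
            immune_high = latent[i] > config.immune_shift / 2.0
            purity = float(rng.uniform(*config.purity_range))
            age = float(np.clip(rng.normal(age_means[cohort], 11.0), 25, 90))
            hazard = (config.survival_baseline_hazard
                      * config.hazard_ratio_tp53 ** tp53
                      * config.hazard_ratio_immune_high ** immune_high)
            t_event = rng.exponential(1.0 / hazard)
            t_censor = rng.uniform(config.followup_min_years, config.followup_max_years)
            time = min(t_event, t_censor)
            event = int(t_event <= t_censor)

            exposure = rng.dirichlet(np.asarray(
                config.signature_exposure_priors[subtype], dtype=float))
            cols, ccfs, weights = _sample_mutations(
                rng, patient, tp53, exposure, purity, config, catalog)
            mut_rows.append(cols)
            clin_rows.append({
                "patient_id": patient, "cohort": cohort, "age": age,
                "er_status": "pos" if er_pos else "neg", "subtype": subtype,
                "survival_time": time, "event": event, "follow_up_years": time,
            })
            truth_rows.append({
                "patient_id": patient, "subtype": subtype,
                "er_true": "pos" if er_pos else "neg", "tp53": tp53,
                "immune_latent": float(latent[i]), "immune_high": bool(immune_high),
                "purity": purity,
                "clone_ccfs": ",".join(f"{c:.4f}" for c in ccfs),
                "clone_weights": ",".join(f"{w:.4f}" for w in weights),
            })
            exposure_rows.append(exposure)

    cohort_table = pd.DataFrame(clin_rows)
    lengths = [len(chunk["pos"]) for chunk in mut_rows]
    total = int(np.sum(lengths))
    offsets = np.concatenate([[0], np.cumsum(lengths)])
    mut_cols = {}
    for k in mut_rows[0]:
        first = mut_rows[0][k]
        # string widths vary per chunk; object dtype avoids truncation
        dtype = object if first.dtype.kind in "OUS" else first.dtype
        arr = np.empty(total, dtype=dtype)
        for j, chunk in enumerate(mut_rows):
            arr[offsets[j]:offsets[j + 1]] = chunk[k]
        mut_cols[k] = arr
    mutation_table = pd.DataFrame(mut_cols)
    truth_samples = pd.DataFrame(truth_rows).set_index("patient_id")
    exposures = pd.DataFrame(np.vstack(exposure_rows), columns=list(catalog.columns),
                             index=truth_samples.index.copy())

    truth_variants = mutation_table[["sample", "clone_id", "clone_ccf"]].copy()
    truth_variants["label"] = "somatic"
    mutation_table = mutation_table.drop(columns=["clone_id", "clone_ccf"])

    expression = generate_expression(
        cohort_table.assign(er_status=truth_samples.loc[
            cohort_table["patient_id"], "er_true"].to_numpy()),
        default_immune_gene_sets(), config.immune_shift,
        seed=int(rng.integers(0, 2**31 - 1)),
        latent=truth_samples.loc[cohort_table["patient_id"], "immune_latent"].to_numpy(),
    )
    purity_cn = pd.DataFrame({
        "sample": truth_samples.index,
        "purity": truth_samples["purity"].to_numpy(),
        "chrom": "*", "start": 1, "end": 3_000_000_000, "cn_total": 2,
    })
    truth = SyntheticTruth(samples=truth_samples, exposures=exposures,
                           variants=truth_variants)
    return CohortBundle(cohort_table, mutation_table, expression, purity_cn, truth)
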