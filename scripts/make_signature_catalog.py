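"""Regenerate the packaged synthetic 96x13 signature catalog (fixed seed).

The output TSV is frozen in src/cohortcompare/data/; rerunning reproduces it
byte-identically."""
import numpy as np
import pandas as pd

SUBS = ["C>A", "C>G", "C>T", "T>A", "T>C", "T>G"]
BASES = "ACGT"
channels = [f"{f}[{s}]{t}" for s in SUBS for f in BASES for t in BASES]
assert len(channels) == 96

rng = np.random.default_rng(20201222)
sig_names = ["1", "2", "13", "3", "8", "6", "15", "20", "26", "5", "17", "18", "30"]


def block(sub):
    return [i for i, c in enumerate(channels) if f"[{sub}]" in c]


def ch(name):
    return channels.index(name)


profiles = {}

# clock-like: C>T at NpCpG
p = np.zeros(96)
for f in BASES:
    p[ch(f"{f}[C>T]G")] = 0.2
profiles["1"] = p

# APOBEC-like C>T at TpCpN
p = np.zeros(96)
p[ch("T[C>T]A")] = 0.35
p[ch("T[C>T]T")] = 0.35
p[ch("T[C>T]C")] = 0.1
profiles["2"] = p

# APOBEC-like C>G at TpCpN
p = np.zeros(96)
p[ch("T[C>G]A")] = 0.35
p[ch("T[C>G]T")] = 0.35
p[ch("T[C>G]C")] = 0.1
profiles["13"] = p

# HRD-like: near-flat over all channels
p = np.ones(96) * (1.0 / 96)
profiles["3"] = p

# broad C>A
p = np.zeros(96)
p[block("C>A")] = 1.0
profiles["8"] = p

# MMR-like: C>T at GpCpN
p = np.zeros(96)
for t in BASES:
    p[ch(f"G[C>T]{t}")] = 0.18
p[block("C>T")] += 0.01
profiles["6"] = p

# MMR-like: C>T at ApCpN plus some T>A
p = np.zeros(96)
for t in BASES:
    p[ch(f"A[C>T]{t}")] = 0.15
p[block("T>A")] = 0.02
profiles["15"] = p

# MMR-like: C>T at CpCpN plus broad T>C tail
p = np.zeros(96)
for t in BASES:
    p[ch(f"C[C>T]{t}")] = 0.12
p[block("T>C")] = 0.02
profiles["20"] = p

# MMR-like: broad T>C
p = np.zeros(96)
p[block("T>C")] = 1.0
profiles["26"] = p

# flat-ish clock-like variant: T>C at ApTpN with low-level C>T background
p = np.zeros(96)
for t in BASES:
    p[ch(f"A[T>C]{t}")] = 0.12
p[block("C>T")] += 0.02
profiles["5"] = p

# T>G at NpTpT (classic CTT/TTT peaks)
p = np.zeros(96)
p[ch("C[T>G]T")] = 0.4
p[ch("T[T>G]T")] = 0.4
p[ch("G[T>G]T")] = 0.1
profiles["17"] = p

# C>A at NpCpA / NpCpT peaks
p = np.zeros(96)
p[ch("T[C>A]A")] = 0.25
p[ch("T[C>A]T")] = 0.25
p[ch("G[C>A]A")] = 0.2
profiles["18"] = p

# broad non-CpG C>T
p = np.zeros(96)
p[block("C>T")] = 1.0
for f in BASES:
    p[ch(f"{f}[C>T]G")] = 0.0
profiles["30"] = p

mat = np.zeros((96, 13))
for j, name in enumerate(sig_names):
    base = profiles[name].astype(float)
    base = base / base.sum()
    noise = rng.dirichlet(np.ones(96) * 0.5)
    col = 0.9 * base + 0.1 * noise
    mat[:, j] = col / col.sum()

df = pd.DataFrame(np.round(mat, 8), index=pd.Index(channels, name="channel"),
                  columns=[f"Signature_{n}" for n in sig_names])
# renormalise after rounding so columns sum to 1 within 1e-6
df = df / df.sum(axis=0)
df = df.round(10)
print("condition number:", np.linalg.cond(df.values))
df.to_csv("src/cohortcompare/data/signature_catalog_synthetic_cosmicv2_like.tsv", sep="\t")
print(df.shape, df.sum(axis=0).min(), df.sum(axis=0).max())
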