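"""Packaged reference tables.

``table2_mutations.tsv`` is the study's published list of the 25 de novo
mutations found in 32 drones (23 single-nucleotide mutations, 2 deletions),
with 1-based positions on the reference linkage groups.  It serves as the
fixture for spectrum, dispersion and report-format checks.
"""

from __future__ import annotations

from importlib.resources import files

import numpy as np
import pandas as pd

COLONY_SIZES = {"I": 22, "II": 10}


def load_mutation_table() -> pd.DataFrame:
    """The published mutation list (number, sample, chrom, pos, change, kind)."""
    path = files("dronehap.data").joinpath("table2_mutations.tsv")
    with path.open() as fh:
        df = pd.read_csv(fh, sep="\t")
    return df


def mutation_calls() -> pd.DataFrame:
    """The published list in the caller's output format (0-based positions)."""
    from .mutations import snm_class

    df = load_mutation_table()
    rows = []
    for _, r in df.iterrows():
        if r["kind"] == "SNM":
            ref, alt = r["change"].split("->")
        else:
            deleted = r["change"].split("_")[0]
            ref, alt = "N" + deleted, "N"  # anchor base unknown from the table
        rows.append({
            "colony": r["sample"].split("-")[0],
            "drone": r["sample"], "chrom": r["chrom"], "pos": int(r["pos"]) - 1,
            "ref": ref, "alt": alt, "kind": r["kind"],
            "snm_class": snm_class(ref, alt) if r["kind"] == "SNM" else "",
            "near_gap": False, "homopolymer": False,
        })
    return pd.DataFrame(rows)


def per_drone_snm_counts(colony_sizes: dict[str, int] | None = None) -> pd.Series:
    """Published SNM counts per drone, zeros included for unmutated drones.

    Drones never named in the mutation list are padded per colony to the
    study's colony sizes (22 + 10); their identifiers are placeholders, which
    is immaterial for count statistics.
    """
    sizes = colony_sizes or COLONY_SIZES
    df = load_mutation_table()
    snm = df[df["kind"] == "SNM"]
    counts = snm.groupby("sample").size()
    out = {}
    for colony, size in sizes.items():
        named = sorted({s for s in counts.index if s.startswith(f"{colony}-")})
        padded = list(named)
        k = 0
        while len(padded) < size:
            k += 1
            cand = f"{colony}-pad{k}"
            if cand not in padded:
                padded.append(cand)
        for d in padded[:size]:
            out[d] = int(counts.get(d, 0))
    return pd.Series(out)


def observed_variance(counts: pd.Series | None = None) -> float:
    """Unbiased (n-1) sample variance of per-drone SNM counts."""
    c = per_drone_snm_counts() if counts is None else counts
    return float(np.var(np.asarray(c, dtype=float), ddof=1))
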