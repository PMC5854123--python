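"""Genotype data model and marker screening for haploid drone cohorts.

The central container is :class:`GenotypeMatrix`: per-site, per-drone haploid
calls with depth, genotype quality and strand support.  Calls are stored as
small integer codes indexing a per-site allele table (``alleles[site][0]`` is
always the reference allele); ``-1`` marks a missing call and ``-2`` an
artifactual "heterozygous" call in a haploid sample.

Marker screening applies three rules, in a fixed order, to identify the
queen's heterozygous sites from her drones:

1. drop any site with a "heterozygous" call in any drone (mapping or
   copy-number artifact);
2. keep only sites with exactly two distinct alleles among called drones in
   the colony;
3. require the site to be called with quality >= 30 in >= 90% of the colony's
   drones.

Drop counts are attributed to the first failing rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError, UndefinedResultError

CODE_MISSING = -1
CODE_HET = -2


@dataclass
class GenotypeMatrix:
    """Per-colony haploid genotype calls at candidate sites.

    Attributes
    ----------
    sites
        DataFrame with columns ``chrom``, ``pos`` (0-based), ``ref``; sorted
        by (chrom in given order, pos) and unique.
    alleles
        Per-site tuple of allele strings; index 0 is the reference allele.
    drones, colonies
        Ordered drone identifiers and their colony labels.
    calls
        ``(n_sites, n_drones)`` int16 array of allele codes (see module doc).
    depth, quality
        Same-shape read depth (int) and phred-like genotype quality (float).
    strand_fwd, strand_rev
        Same-shape booleans: support on the forward / reverse strand.
    """

    sites: pd.DataFrame
    alleles: list[tuple[str, ...]]
    drones: list[str]
    colonies: dict[str, str]
    calls: np.ndarray
    depth: np.ndarray
    quality: np.ndarray
    strand_fwd: np.ndarray
    strand_rev: np.ndarray

    def __post_init__(self):
        n_sites, n_drones = len(self.sites), len(self.drones)
        for name in ("calls", "depth", "quality", "strand_fwd", "strand_rev"):
            arr = getattr(self, name)
            if arr.shape != (n_sites, n_drones):
                raise InputError(
                    f"{name} has shape {arr.shape}, expected {(n_sites, n_drones)}")
        if len(self.alleles) != n_sites:
            raise InputError("alleles length does not match sites")
        if (self.depth < 0).any():
            raise InputError("negative read depth")
        order = {c: i for i, c in enumerate(pd.unique(self.sites["chrom"]))}
        key = list(zip(self.sites["chrom"].map(order), self.sites["pos"]))
        if key != sorted(key) or len(set(key)) != len(key):
            raise InputError("sites must be sorted by (chrom, pos) and unique")
        missing = set(self.drones) - set(self.colonies)
        if missing:
            raise InputError(f"drones without colony labels: {sorted(missing)}")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_drones(self) -> int:
        return len(self.drones)

    @property
    def colony_names(self) -> list[str]:
        seen = []
        for d in self.drones:
            c = self.colonies[d]
            if c not in seen:
                seen.append(c)
        return seen

    def drone_index(self, drone: str) -> int:
        try:
            return self.drones.index(drone)
        except ValueError:
            raise InputError(f"unknown drone {drone!r}") from None

    def colony_drone_indices(self, colony: str) -> np.ndarray:
        idx = [i for i, d in enumerate(self.drones) if self.colonies[d] == colony]
        if not idx:
            raise InputError(f"unknown colony {colony!r}")
        return np.asarray(idx)

    def subset_sites(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            sites=self.sites.iloc[index].reset_index(drop=True),
            alleles=[self.alleles[i] for i in index],
            drones=list(self.drones),
            colonies=dict(self.colonies),
            calls=self.calls[index],
            depth=self.depth[index],
            quality=self.quality[index],
            strand_fwd=self.strand_fwd[index],
            strand_rev=self.strand_rev[index],
        )

    def allele_string(self, site_index: int, code: int) -> str:
        if code == CODE_MISSING:
            return "."
        if code == CODE_HET:
            return "H"
        return self.alleles[site_index][code]


@dataclass
class MarkerSet:
    """Sites passing marker screening for one colony.

    ``table`` columns: ``site_idx`` (row in the source matrix), ``chrom``,
    ``pos``, ``ref``, ``allele_a``/``allele_b`` (the colony's two observed
    alleles; ``a`` is the reference allele when the reference is among them,
    else the alphabetically smaller), and their codes ``code_a``/``code_b``.
    """

    colony: str
    table: pd.DataFrame
    drop_counts: dict[str, int] = field(default_factory=dict)
    thresholds: dict[str, float] = field(default_factory=dict)

    @property
    def n_markers(self) -> int:
        return len(self.table)


def screen_markers(
    matrix: GenotypeMatrix,
    colony: str,
    min_quality: float = 30.0,
    min_call_fraction: float = 0.9,
    min_carriers_per_allele: int = 1,
) -> MarkerSet:
    """Apply the three marker rules to one colony of a genotype matrix.

    ``min_carriers_per_allele`` optionally tightens rule 2 so each of the two
    genotypes must be seen in that many drones.  With the default (1) any
    biallelic site qualifies; the pipeline uses 2, which keeps drone-unique
    alleles (candidate de novo mutations) out of the marker map and hence out
    of haplotype blocks.
    """
    cols = matrix.colony_drone_indices(colony)
    if len(cols) < 2:
        raise InputError(f"colony {colony!r} has fewer than 2 drones")
    sub = matrix.calls[:, cols]
    qual = matrix.quality[:, cols]

    rule1_fail = (sub == CODE_HET).any(axis=1)

    called = sub >= 0
    max_code = int(sub.max(initial=0))
    n_distinct = np.zeros(matrix.n_sites, dtype=np.int16)
    n_passing = np.zeros(matrix.n_sites, dtype=np.int16)
    for code in range(max_code + 1):
        carriers = (called & (sub == code)).sum(axis=1)
        n_distinct += carriers > 0
        n_passing += carriers >= min_carriers_per_allele
    rule2_fail = (n_distinct != 2) | (n_passing != 2)

    ok = called & (qual >= min_quality)
    rule3_fail = ok.mean(axis=1) < min_call_fraction

    keep = ~(rule1_fail | rule2_fail | rule3_fail)
    drop_counts = {
        "het_artifact": int(rule1_fail.sum()),
        "not_biallelic": int((rule2_fail & ~rule1_fail).sum()),
        "low_quality_or_callrate": int(
            (rule3_fail & ~rule1_fail & ~rule2_fail).sum()),
    }

    rows = []
    for i in np.flatnonzero(keep):
        codes = sorted({int(c) for c in sub[i] if c >= 0})
        a_code, b_code = codes
        a = matrix.alleles[i][a_code]
        b = matrix.alleles[i][b_code]
        ref = matrix.sites["ref"].iat[i]
        if b == ref or (ref not in (a, b) and b < a):
            a_code, b_code, a, b = b_code, a_code, b, a
        rows.append((i, matrix.sites["chrom"].iat[i], matrix.sites["pos"].iat[i],
                     ref, a, b, a_code, b_code))
    table = pd.DataFrame(
        rows, columns=["site_idx", "chrom", "pos", "ref",
                       "allele_a", "allele_b", "code_a", "code_b"])
    return MarkerSet(
        colony=colony, table=table, drop_counts=drop_counts,
        thresholds={"min_quality": min_quality,
                    "min_call_fraction": min_call_fraction},
    )


def marker_density(markers: MarkerSet, genome_length: int | None = None) -> float:
    """Mean successive same-chromosome inter-marker distance in bp."""
    if markers.n_markers < 2:
        raise UndefinedResultError("marker density needs at least 2 markers")
    gaps = []
    for _, grp in markers.table.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        if len(pos) >= 2:
            gaps.append(np.diff(pos))
    if not gaps:
        raise UndefinedResultError("no chromosome has 2 or more markers")
    return float(np.mean(np.concatenate(gaps)))
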