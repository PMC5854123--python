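"""Queen haplotype reconstruction from haploid drone genotypes.

Because each drone is a single meiotic product of the queen, two adjacent
markers are almost always inherited without an intervening recombination
event.  The linkage of adjacent marker pairs is therefore decided by majority
vote over drones called at both markers, and the per-pair orientations are
chained into chromosome-scale haplotypes.

Ties and zero-information pairs (no drone called at both markers) are bridged
by linking the new marker to the nearest *earlier* marker of the current phase
set that yields an informative vote; if no marker within the bridging window
is informative, a new phase set begins rather than fabricating linkage.

Within each phase set the labelling convention is that haplotype 0 carries
the colony's ``allele_a`` at the first marker (the reference allele when the
reference is among the pair, else the alphabetically smaller allele).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError
from .genotypes import GenotypeMatrix, MarkerSet


@dataclass
class QueenPhase:
    """The queen's two reconstructed haplotypes at marker resolution.

    ``table`` columns: ``site_idx``, ``chrom``, ``pos``, ``hap0``, ``hap1``
    (allele strings), ``code0``, ``code1`` (matrix allele codes) and
    ``phase_set`` (non-decreasing along each chromosome).
    """

    colony: str
    table: pd.DataFrame

    @property
    def n_markers(self) -> int:
        return len(self.table)

    @property
    def n_phase_sets(self) -> int:
        return self.table["phase_set"].nunique()

    def subset(self, marker_indices: np.ndarray) -> "QueenPhase":
        """Restrict the phase to a subset of its marker rows (for marker
        downsampling experiments); phase-set labels are preserved."""
        sub = self.table.iloc[np.sort(np.asarray(marker_indices))]
        return QueenPhase(colony=self.colony, table=sub.reset_index(drop=True))


def _marker_calls_01(markers: MarkerSet, matrix: GenotypeMatrix) -> np.ndarray:
    """Drone calls at marker sites recoded to 0 (allele_a) / 1 (allele_b) /
    -1 (missing, artifact, or an allele matching neither — e.g. a mutation)."""
    cols = matrix.colony_drone_indices(markers.colony)
    site_idx = markers.table["site_idx"].to_numpy()
    sub = matrix.calls[np.ix_(site_idx, cols)]
    a = markers.table["code_a"].to_numpy()[:, None]
    b = markers.table["code_b"].to_numpy()[:, None]
    out = np.full(sub.shape, -1, dtype=np.int8)
    out[sub == a] = 0
    out[sub == b] = 1
    return out


def phase_queen(
    markers: MarkerSet,
    matrix: GenotypeMatrix,
    max_bridge: int = 50,
) -> QueenPhase:
    """Reconstruct the queen's haplotype pair by adjacent-marker majority vote.

    ``max_bridge`` bounds how far back (in markers) a tie or zero-information
    pair may reach for an informative linkage before a new phase set starts.
    """
    if markers.n_markers < 1:
        raise InputError("phase_queen requires at least one marker")
    cols = matrix.colony_drone_indices(markers.colony)
    if len(cols) < 2:
        raise InputError("phasing requires at least 2 drones")
    M = _marker_calls_01(markers, matrix)

    table = markers.table
    rel = np.zeros(len(table), dtype=np.int8)       # orientation vs phase-set anchor
    phase_set = np.zeros(len(table), dtype=np.int64)
    next_ps = 0

    def vote(i: int, j: int) -> int:
        """+1: same-index linkage (a_i with a_j), -1: crossed, 0: uninformative."""
        valid = (M[i] >= 0) & (M[j] >= 0)
        n = int(valid.sum())
        if n == 0:
            return 0
        same = int((M[i][valid] == M[j][valid]).sum())
        diff = n - same
        if same > diff:
            return 1
        if diff > same:
            return -1
        return 0

    chrom_arr = table["chrom"].to_numpy()
    start = 0
    for chrom in pd.unique(chrom_arr):
        idx = np.flatnonzero(chrom_arr == chrom)
        first = idx[0]
        phase_set[first] = next_ps
        rel[first] = 0
        for j in idx[1:]:
            v = vote(j - 1, j)
            p = j - 1
            back = 2
            while v == 0 and back <= max_bridge and (j - back) >= idx[0] \
                    and phase_set[j - back] == phase_set[j - 1]:
                p = j - back
                v = vote(p, j)
                back += 1
            if v == 0:
                next_ps += 1
                phase_set[j] = next_ps
                rel[j] = 0
            else:
                phase_set[j] = phase_set[p]
                rel[j] = rel[p] if v > 0 else 1 - rel[p]
        next_ps += 1
        start = idx[-1] + 1

    code_a = table["code_a"].to_numpy()
    code_b = table["code_b"].to_numpy()
    code0 = np.where(rel == 0, code_a, code_b)
    code1 = np.where(rel == 0, code_b, code_a)
    hap0 = np.where(rel == 0, table["allele_a"], table["allele_b"])
    hap1 = np.where(rel == 0, table["allele_b"], table["allele_a"])
    out = pd.DataFrame({
        "site_idx": table["site_idx"].to_numpy(),
        "chrom": chrom_arr,
        "pos": table["pos"].to_numpy(),
        "hap0": hap0,
        "hap1": hap1,
        "code0": code0,
        "code1": code1,
        "phase_set": phase_set,
    })
    return QueenPhase(colony=markers.colony, table=out)


def assign_blocks(
    drone: str,
    phase: QueenPhase,
    matrix: GenotypeMatrix,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Map one drone's marker calls onto the queen haplotypes.

    Returns ``(blocks, mismatches)``.  ``blocks`` holds maximal same-haplotype
    runs per (chromosome, phase set) with first/last marker positions and bp
    span; ``mismatches`` lists called markers matching neither haplotype
    allele (candidate mutation sites, excluded from blocks).  Missing and
    artifact calls are transparent: they neither extend nor break runs.
    """
    j = matrix.drone_index(drone)
    t = phase.table
    site_idx = t["site_idx"].to_numpy()
    calls = matrix.calls[site_idx, j]
    state = np.full(len(t), -1, dtype=np.int8)
    state[calls == t["code0"].to_numpy()] = 0
    state[calls == t["code1"].to_numpy()] = 1
    mismatch = (calls >= 0) & (state == -1)

    mismatches = t.loc[mismatch, ["site_idx", "chrom", "pos"]].copy()
    mismatches.insert(0, "drone", drone)

    rows = []
    for (chrom, ps), grp_idx in t.groupby(["chrom", "phase_set"], sort=False).groups.items():
        gi = np.asarray(grp_idx)
        st = state[gi]
        informative = st >= 0
        if not informative.any():
            continue
        gi = gi[informative]
        st = st[informative]
        pos = t["pos"].to_numpy()[gi]
        sidx = site_idx[gi]
        change = np.flatnonzero(np.diff(st)) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [len(st)]])
        for s, e in zip(starts, ends):
            rows.append({
                "drone": drone, "chrom": chrom, "phase_set": ps,
                "hap": int(st[s]),
                "start_pos": int(pos[s]), "end_pos": int(pos[e - 1]),
                "start_idx": int(sidx[s]), "end_idx": int(sidx[e - 1]),
                "n_markers": int(e - s),
                "span": int(pos[e - 1] - pos[s]),
            })
    blocks = pd.DataFrame(rows, columns=["drone", "chrom", "phase_set", "hap",
                                         "start_pos", "end_pos", "start_idx",
                                         "end_idx", "n_markers", "span"])
    return blocks, mismatches


def assign_blocks_all(
    phase: QueenPhase, matrix: GenotypeMatrix
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """:func:`assign_blocks` for every drone of the phase's colony."""
    cols = matrix.colony_drone_indices(phase.colony)
    blocks, mism = [], []
    for i in cols:
        b, m = assign_blocks(matrix.drones[i], phase, matrix)
        blocks.append(b)
        mism.append(m)
    return (pd.concat(blocks, ignore_index=True),
            pd.concat(mism, ignore_index=True))
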