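"""Crossover / noncrossover classification and recombination-rate summaries.

A drone's chromosome is a mosaic of maximal same-haplotype marker runs
("blocks").  Blocks spanning more than ``threshold_bp`` (default 10 kb) are
*anchors*; transitions between anchors of different haplotype are crossovers
(CO).  Short blocks embedded between same-haplotype anchors are noncrossover
conversion tracts (NCO); short blocks on the near side of a crossover are
CO-associated conversions.  Block span is measured between first and last
marker positions, and breakpoints are localized to the inter-marker interval
— the resolution limit the marker map imposes.

Crossovers at identical flanking-marker intervals in several drones are
"shared"; a shared CO adjacent to another shared CO in the same drone and
chromosome (within the double-CO window) is the signature of a translocation
or mis-assembly and is excluded from rate estimates (category 2); isolated
shared COs (category 1) are kept, since independent events inside a long
assembly gap legitimately collapse onto the same marker interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError, ParameterError
from .genotypes import GenotypeMatrix, MarkerSet
from .phasing import QueenPhase, assign_blocks

EVENT_COLUMNS = ["drone", "chrom", "phase_set", "kind", "left", "right",
                 "tract_start", "tract_end", "n_converted",
                 "shared_group", "category", "excluded", "reason", "gap_overlap"]


def _empty_events() -> pd.DataFrame:
    return pd.DataFrame(columns=EVENT_COLUMNS)


def classify_events(
    blocks: pd.DataFrame,
    threshold_bp: int = 10_000,
    terminal_short_as_co: bool = True,
) -> pd.DataFrame:
    """Classify haplotype blocks into CO / NCO / CO-associated conversions.

    ``blocks`` is the output of :func:`dronehap.phasing.assign_blocks` (one or
    many drones).  Within each (drone, chromosome, phase set) the blocks must
    be position-ordered and strictly alternate in haplotype; a chromosome with
    a single block yields no events.  Chromosome-terminal short blocks are
    counted as crossovers (a terminal switch has only one flank) when
    ``terminal_short_as_co`` is set, the package default.
    """
    if threshold_bp <= 0:
        raise ParameterError("threshold_bp must be positive")
    if blocks.empty:
        return _empty_events()
    events = []

    def add(drone, chrom, ps, kind, left=np.nan, right=np.nan,
            tract=None, n_conv=0):
        events.append({
            "drone": drone, "chrom": chrom, "phase_set": ps, "kind": kind,
            "left": left, "right": right,
            "tract_start": tract[0] if tract else np.nan,
            "tract_end": tract[1] if tract else np.nan,
            "n_converted": n_conv,
            "shared_group": -1, "category": 0, "excluded": False,
            "reason": "", "gap_overlap": False,
        })

    for (drone, chrom, ps), grp in blocks.groupby(["drone", "chrom", "phase_set"],
                                                  sort=False):
        g = grp.sort_values("start_pos").reset_index(drop=True)
        if not g["start_pos"].is_monotonic_increasing:
            raise InputError("blocks are not position-ordered")
        if (g["hap"].diff().iloc[1:] == 0).any():
            raise InputError("adjacent blocks share a haplotype; runs not maximal")
        spans = g["span"].to_numpy()
        haps = g["hap"].to_numpy()
        long = spans > threshold_bp
        anchors = np.flatnonzero(long)

        if len(anchors) == 0:
            # no anchor at all: every haplotype switch is a terminal-style CO
            if terminal_short_as_co:
                for i in range(1, len(g)):
                    add(drone, chrom, ps, "CO",
                        left=int(g["end_pos"].iat[i - 1]),
                        right=int(g["start_pos"].iat[i]))
            continue

        # terminal regions
        if terminal_short_as_co:
            for i in range(1, anchors[0] + 1):
                add(drone, chrom, ps, "CO",
                    left=int(g["end_pos"].iat[i - 1]),
                    right=int(g["start_pos"].iat[i]))
            for i in range(anchors[-1] + 1, len(g)):
                add(drone, chrom, ps, "CO",
                    left=int(g["end_pos"].iat[i - 1]),
                    right=int(g["start_pos"].iat[i]))

        for ai, bi in zip(anchors[:-1], anchors[1:]):
            hap_a, hap_b = haps[ai], haps[bi]
            between = range(ai + 1, bi)
            if hap_a == hap_b:
                for i in between:
                    if haps[i] != hap_a:
                        add(drone, chrom, ps, "NCO",
                            left=int(g["end_pos"].iat[i - 1]),
                            right=int(g["start_pos"].iat[i + 1]),
                            tract=(int(g["start_pos"].iat[i]),
                                   int(g["end_pos"].iat[i])),
                            n_conv=int(g["n_markers"].iat[i]))
            else:
                # breakpoint at the last hap_a -> hap_b transition; short
                # hap_b islands before it are CO-associated conversions
                last_a = max(i for i in range(ai, bi) if haps[i] == hap_a)
                add(drone, chrom, ps, "CO",
                    left=int(g["end_pos"].iat[last_a]),
                    right=int(g["start_pos"].iat[last_a + 1]))
                for i in between:
                    if i <= last_a and haps[i] == hap_b:
                        add(drone, chrom, ps, "CO_conversion",
                            left=int(g["end_pos"].iat[i - 1]),
                            right=int(g["start_pos"].iat[i + 1]),
                            tract=(int(g["start_pos"].iat[i]),
                                   int(g["end_pos"].iat[i])),
                            n_conv=int(g["n_markers"].iat[i]))
    if not events:
        return _empty_events()
    return pd.DataFrame(events, columns=EVENT_COLUMNS)


def group_shared_cos(
    events: pd.DataFrame,
    gap_intervals: list[tuple[str, int, int]] | None = None,
    double_co_window: int = 700_000,
) -> pd.DataFrame:
    """Annotate shared crossovers and exclude category-2 double-CO artifacts.

    Crossovers from different drones with the *exact* same flanking-marker
    interval form one shared group.  A shared CO whose nearest neighbouring
    shared CO in the same drone and chromosome lies within
    ``double_co_window`` bp is category 2 and excluded; other shared COs are
    category 1 and kept.  Breakpoint intervals overlapping an assembly gap
    are annotated but not excluded on that basis alone.
    """
    ev = events.copy().reset_index(drop=True)
    if ev.empty:
        return ev
    is_co = ev["kind"] == "CO"
    key = list(zip(ev["chrom"], ev["left"], ev["right"]))
    group_of: dict[tuple, int] = {}
    counts: dict[tuple, set] = {}
    for i in np.flatnonzero(is_co):
        counts.setdefault(key[i], set()).add(ev["drone"].iat[i])
    next_id = 0
    for k, drones in counts.items():
        if len(drones) >= 2:
            group_of[k] = next_id
            next_id += 1
    ev["shared_group"] = [group_of.get(k, -1) if co else -1
                          for k, co in zip(key, is_co)]
    shared = ev["shared_group"] >= 0
    ev.loc[shared, "category"] = 1

    mid = (ev["left"] + ev["right"]) / 2.0
    for (_drone, _chrom), grp in ev[shared].groupby(["drone", "chrom"], sort=False):
        if len(grp) < 2:
            continue
        order = grp.index[np.argsort(mid[grp.index].to_numpy())]
        m = mid[order].to_numpy()
        sep_prev = np.diff(m, prepend=np.inf)
        sep_next = np.diff(m, append=np.inf)
        close = np.minimum(np.abs(sep_prev), np.abs(sep_next)) <= double_co_window
        for idx in order[close]:
            ev.loc[idx, "category"] = 2
            ev.loc[idx, "excluded"] = True
            ev.loc[idx, "reason"] = "shared_double_co"

    if gap_intervals:
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for c, s, e in gap_intervals:
            by_chrom.setdefault(c, []).append((s, e))
        overlaps = []
        for _, row in ev.iterrows():
            hit = False
            if row["kind"] == "CO" and np.isfinite(row["left"]):
                for s, e in by_chrom.get(row["chrom"], []):
                    if row["left"] < e and row["right"] > s:
                        hit = True
                        break
            overlaps.append(hit)
        ev["gap_overlap"] = overlaps
    return ev


@dataclass
class RateSummary:
    """Genome-wide crossover-rate summary.

    ``cm_per_mb`` uses kept crossovers only; ``cm_per_mb_raw`` restores the
    excluded category-2 events.  By construction
    ``cm_per_mb = 100 * cos_per_drone / genome_mb``.
    """

    n_kept: int
    n_excluded: int
    n_drones: int
    genome_mb: float
    cos_per_drone: float
    cm_per_mb: float
    cm_per_mb_raw: float
    per_drone: pd.Series
    per_chromosome: pd.Series

    @property
    def n_raw(self) -> int:
        return self.n_kept + self.n_excluded

    def to_dict(self) -> dict:
        return {
            "n_kept": self.n_kept, "n_excluded": self.n_excluded,
            "n_raw": self.n_raw, "n_drones": self.n_drones,
            "genome_mb": self.genome_mb,
            "cos_per_drone": self.cos_per_drone,
            "cm_per_mb": self.cm_per_mb, "cm_per_mb_raw": self.cm_per_mb_raw,
        }


def crossover_rate(
    events: pd.DataFrame, genome_mb: float, n_drones: int,
    drones: list[str] | None = None,
) -> RateSummary:
    """Crossover rate in cM/Mb: ``100 * (kept COs / drone) / genome_Mb``."""
    if n_drones < 1:
        raise InputError("n_drones must be >= 1")
    if genome_mb <= 0:
        raise ParameterError("genome_mb must be positive")
    cos = events[events["kind"] == "CO"] if not events.empty else events
    kept = cos[~cos["excluded"]] if not cos.empty else cos
    n_kept, n_raw = len(kept), len(cos)
    per_drone = kept.groupby("drone").size() if n_kept else pd.Series(dtype=int)
    if drones is not None:
        per_drone = per_drone.reindex(drones, fill_value=0)
    per_chrom = kept.groupby("chrom").size() if n_kept else pd.Series(dtype=int)
    cos_per_drone = n_kept / n_drones
    return RateSummary(
        n_kept=n_kept, n_excluded=n_raw - n_kept, n_drones=n_drones,
        genome_mb=genome_mb,
        cos_per_drone=cos_per_drone,
        cm_per_mb=100.0 * cos_per_drone / genome_mb,
        cm_per_mb_raw=100.0 * (n_raw / n_drones) / genome_mb,
        per_drone=per_drone, per_chromosome=per_chrom,
    )


def window_rates(
    events: pd.DataFrame,
    chrom_lengths: dict[str, int],
    n_drones: int,
    window_bp: int = 500_000,
    hotspot_multiple: float = 5.0,
) -> pd.DataFrame:
    """Per-window crossover rates and hotspot calls.

    Kept crossovers are assigned to the nonoverlapping window containing their
    breakpoint-interval midpoint; a window is a hotspot when its rate is at
    least ``hotspot_multiple`` times the genome-wide mean rate.
    """
    if window_bp <= 0:
        raise ParameterError("window_bp must be positive")
    rows = []
    kept = events[(events["kind"] == "CO") & (~events["excluded"])] \
        if not events.empty else events
    genome_mb = sum(chrom_lengths.values()) / 1e6
    mean_rate = 100.0 * (len(kept) / n_drones) / genome_mb if genome_mb else 0.0
    for chrom, length in chrom_lengths.items():
        n_windows = int(np.ceil(length / window_bp))
        counts = np.zeros(n_windows, dtype=int)
        if not kept.empty:
            sub = kept[kept["chrom"] == chrom]
            if len(sub):
                mids = ((sub["left"] + sub["right"]) / 2.0).to_numpy()
                w = np.clip((mids // window_bp).astype(int), 0, n_windows - 1)
                np.add.at(counts, w, 1)
        for i in range(n_windows):
            start = i * window_bp
            end = min(start + window_bp, length)
            w_mb = (end - start) / 1e6
            rate = 100.0 * (counts[i] / n_drones) / w_mb
            rows.append({"chrom": chrom, "start": start, "end": end,
                         "n_co": int(counts[i]), "cm_per_mb": rate,
                         "hotspot": mean_rate > 0 and rate >= hotspot_multiple * mean_rate})
    return pd.DataFrame(rows)


def genetic_length_downsample(
    markers: MarkerSet,
    matrix: GenotypeMatrix,
    phase: QueenPhase,
    m: int = 516,
    reps: int = 100,
    seed: int | None = None,
    threshold_bp: int = 10_000,
) -> tuple[float, float, np.ndarray]:
    """Genetic length (cM) re-estimated from ``m`` randomly sampled markers.

    Per replicate the phase is restricted to the sampled markers, events are
    re-detected for every drone, and the genetic length is 100 x mean kept
    crossovers per drone.  Returns ``(mean, sd, lengths)`` over replicates.
    With ``m`` equal to the full marker count the estimate equals the
    full-marker genetic length exactly.
    """
    if m < 2:
        raise ParameterError("m must be >= 2")
    if m > phase.n_markers:
        raise ParameterError(f"m={m} exceeds marker count {phase.n_markers}")
    if reps < 1:
        raise ParameterError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    cols = matrix.colony_drone_indices(phase.colony)
    lengths = np.empty(reps)
    for r in range(reps):
        pick = rng.choice(phase.n_markers, size=m, replace=False)
        sub = phase.subset(pick)
        all_blocks = [assign_blocks(matrix.drones[i], sub, matrix)[0] for i in cols]
        ev = classify_events(pd.concat(all_blocks, ignore_index=True),
                             threshold_bp=threshold_bp)
        ev = group_shared_cos(ev)
        total_cos = int(((ev["kind"] == "CO") & (~ev["excluded"])).sum()) \
            if not ev.empty else 0
        lengths[r] = 100.0 * total_cos / len(cols)
    sd = float(np.std(lengths, ddof=1)) if reps > 1 else 0.0
    return float(np.mean(lengths)), sd, lengths
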