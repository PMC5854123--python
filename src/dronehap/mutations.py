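"""De novo mutation calling, callable sites, and Poisson rate estimation.

A de novo candidate in a haploid drone cohort is a site where exactly one
drone carries an allele absent from every other called drone of the same
colony.  Candidates are filtered on read depth (>= 5), genotype quality
(>= 30) and support on both strands; candidates at queen-heterozygous marker
sites are excluded (a segregating site cannot yield a drone-unique allele).
The study's manual review is replaced by deterministic proximity-to-gap and
homopolymer flags which are reported rather than silently applied.

The rate denominator is the drone-summed count of callable sites (depth >= 5,
mapping quality >= 20, unambiguous reference).  Confidence intervals are exact
Poisson (Garwood) intervals from chi-square quantiles, as computed by the
standard Poisson exact test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError, ParameterError
from .genotypes import CODE_HET, CODE_MISSING, GenotypeMatrix, MarkerSet

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
GC = {"G", "C"}


def snm_class(ref: str, alt: str) -> str:
    """Classify a single-nucleotide mutation by direction and type."""
    if (ref, alt) in TRANSITIONS:
        return "GC_to_AT" if ref in GC else "AT_to_GC"
    if ref in GC and alt not in GC:
        return "transversion_GC_to_AT"
    if ref not in GC and alt in GC:
        return "transversion_AT_to_GC"
    return "transversion_neutral"


@dataclass
class CallabilityMask:
    """Per-drone callable-site counts and the thresholds that define them."""

    per_drone: pd.Series
    genome_length: int
    min_depth: int = 5
    min_quality: float = 20.0
    site_masks: dict[str, np.ndarray] | None = None  # drone -> boolean array

    def __post_init__(self):
        if (self.per_drone > self.genome_length).any():
            raise InputError("callable count exceeds genome length")

    @property
    def total(self) -> int:
        return int(self.per_drone.sum())

    @property
    def mean_fraction(self) -> float:
        return float(self.per_drone.mean() / self.genome_length)


def callable_sites(
    depths: np.ndarray,
    qualities: np.ndarray,
    reference: np.ndarray | None = None,
    drones: list[str] | None = None,
    min_depth: int = 5,
    min_quality: float = 20.0,
    keep_masks: bool = False,
) -> CallabilityMask:
    """Count callable sites per drone over aligned per-site arrays.

    ``depths`` and ``qualities`` are ``(n_sites, n_drones)``; ``reference``
    is an optional length-``n_sites`` array of reference bases — sites whose
    base is ``'N'`` are never callable.
    """
    depths = np.asarray(depths)
    qualities = np.asarray(qualities)
    if depths.shape != qualities.shape:
        raise InputError("depths and qualities shapes differ")
    n_sites, n_drones = depths.shape
    ok = (depths >= min_depth) & (qualities >= min_quality)
    if reference is not None:
        reference = np.asarray(reference)
        if len(reference) != n_sites:
            raise InputError("reference length does not match depths")
        ok &= (reference != "N")[:, None]
    names = drones if drones is not None else [f"D{i+1}" for i in range(n_drones)]
    per_drone = pd.Series(ok.sum(axis=0), index=names)
    masks = {names[j]: ok[:, j] for j in range(n_drones)} if keep_masks else None
    return CallabilityMask(per_drone=per_drone, genome_length=n_sites,
                           min_depth=min_depth, min_quality=min_quality,
                           site_masks=masks)


_FILTER_COLS = ["unique", "others_monomorphic", "depth_ok", "quality_ok",
                "strand_ok", "not_marker", "hap_support_ok", "not_clustered"]


def call_denovo(
    matrix: GenotypeMatrix,
    min_depth: int = 5,
    min_quality: float = 30.0,
    require_strand: bool = True,
    markers: dict[str, MarkerSet] | MarkerSet | None = None,
    phases: dict | None = None,
    gap_intervals: list[tuple[str, int, int]] | None = None,
    flag_window_bp: int = 1_000,
    cluster_window_bp: int = 100_000,
    cluster_max: int = 2,
    reference: dict[str, np.ndarray] | None = None,
    return_candidates: bool = False,
    max_indel_bp: int = 19,
):
    """Call drone-unique de novo mutations per colony.

    A candidate is an allele carried by exactly one called drone and absent
    from every other called drone of the colony, at a site that is otherwise
    monomorphic among those drones.  Candidates are filtered on the carrier's
    depth, genotype quality and dual-strand support, and excluded at known
    marker (queen-heterozygous) sites when a marker set is given.

    Two haplotype-aware safeguards separate true mutations from sites where
    one drone merely carries a locally unique queen haplotype — the one
    configuration a genotype-only test cannot distinguish:

    * with ``phases`` (colony -> QueenPhase), a candidate requires at least
      one other drone that shares the carrier's haplotype at the flanking
      markers yet is called at the site without the allele; a queen-
      heterozygous site cannot satisfy this, a genuine mutation almost always
      does (``hap_support_ok``);
    * candidates clustered on one drone and chromosome (more than
      ``cluster_max`` within ``cluster_window_bp``) are rejected as a
      haplotype-block artifact rather than independent mutations
      (``not_clustered``).

    Returns the passing calls (drone, chrom, pos, ref, alt, kind, snm_class,
    near_gap, homopolymer) or, with ``return_candidates``, a ``(calls,
    candidates)`` pair where ``candidates`` carries the full filter trail.
    Strand filtering is skipped when the matrix carries no strand information
    (all flags identically False), as plain genotype tables do.
    """
    marker_by_colony: dict[str, set[int]] = {}
    if isinstance(markers, MarkerSet):
        markers = {markers.colony: markers}
    if markers:
        for colony, ms in markers.items():
            marker_by_colony[colony] = set(ms.table["site_idx"].tolist())

    have_strand = bool(matrix.strand_fwd.any() or matrix.strand_rev.any())
    gap_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for c, s, e in gap_intervals or []:
        gap_by_chrom.setdefault(c, []).append((s, e))

    candidates = []
    for colony in matrix.colony_names:
        cols = matrix.colony_drone_indices(colony)
        if len(cols) < 2:
            raise InputError(f"colony {colony!r} has fewer than 2 drones")
        phase = (phases or {}).get(colony)
        sub = matrix.calls[:, cols]
        called = sub >= 0
        max_code = int(sub.max(initial=0))
        # allele carrier counts per site via one pass per observed code
        carrier_counts = np.zeros((matrix.n_sites, max_code + 1), dtype=np.int32)
        for code in range(max_code + 1):
            carrier_counts[:, code] = (called & (sub == code)).sum(axis=1)
        unique_mask = carrier_counts == 1
        n_alleles = (carrier_counts > 0).sum(axis=1)
        n_called = called.sum(axis=1)
        cand_sites = np.flatnonzero(unique_mask.any(axis=1) & (n_called >= 2))

        for si in cand_sites:
            chrom = matrix.sites["chrom"].iat[si]
            pos = int(matrix.sites["pos"].iat[si])
            for code in np.flatnonzero(unique_mask[si]):
                j_local = int(np.flatnonzero(called[si] & (sub[si] == code))[0])
                j = int(cols[j_local])
                drone = matrix.drones[j]
                ref = matrix.sites["ref"].iat[si]
                alt = matrix.alleles[si][code]
                if alt == ref:
                    continue  # the singleton allele is the reference itself
                if max(len(ref), len(alt)) - 1 > max_indel_bp:
                    continue
                depth_ok = matrix.depth[si, j] >= min_depth
                quality_ok = matrix.quality[si, j] >= min_quality
                strand_ok = (not require_strand or not have_strand
                             or (matrix.strand_fwd[si, j] and matrix.strand_rev[si, j]))
                not_marker = si not in marker_by_colony.get(colony, ())
                others_monomorphic = bool(n_alleles[si] == 2)
                hap_support = True if phase is None else _hap_support(
                    matrix, phase, si, chrom, pos, j, cols)
                near_gap = any(s - flag_window_bp <= pos < e + flag_window_bp
                               for s, e in gap_by_chrom.get(chrom, ()))
                homopolymer = _in_homopolymer(reference, chrom, pos) \
                    if reference is not None else False
                kind = "SNM" if len(ref) == 1 and len(alt) == 1 else "indel"
                candidates.append({
                    "colony": colony, "drone": drone, "chrom": chrom, "pos": pos,
                    "ref": ref, "alt": alt, "kind": kind,
                    "snm_class": snm_class(ref, alt) if kind == "SNM" else "",
                    "unique": True, "others_monomorphic": others_monomorphic,
                    "depth_ok": bool(depth_ok),
                    "quality_ok": bool(quality_ok), "strand_ok": bool(strand_ok),
                    "not_marker": not_marker, "hap_support_ok": bool(hap_support),
                    "near_gap": near_gap, "homopolymer": homopolymer,
                })

    cand_df = pd.DataFrame(candidates, columns=[
        "colony", "drone", "chrom", "pos", "ref", "alt", "kind", "snm_class",
        *_FILTER_COLS[:-1], "near_gap", "homopolymer"])

    # cluster filter among candidates passing everything else
    pre = cand_df[_FILTER_COLS[:-1]].all(axis=1)
    not_clustered = np.ones(len(cand_df), dtype=bool)
    for (_d, _c), grp in cand_df[pre].groupby(["drone", "chrom"], sort=False):
        if len(grp) <= cluster_max:
            continue
        p = grp["pos"].to_numpy()
        order = np.argsort(p)
        p_sorted = p[order]
        for k, pk in enumerate(p_sorted):
            near = np.abs(p_sorted - pk) <= cluster_window_bp
            if near.sum() > cluster_max:
                not_clustered[grp.index[order[near]]] = False
    cand_df["not_clustered"] = not_clustered

    passing = cand_df[cand_df[_FILTER_COLS].all(axis=1)]
    calls = passing.drop(columns=_FILTER_COLS).reset_index(drop=True)
    if return_candidates:
        return calls, cand_df
    return calls


def _hap_support(matrix, phase, si, chrom, pos, j, cols,
                 n_flank: int = 3) -> bool:
    """True if some other drone shares the carrier's flanking haplotype but,
    called at the candidate site, does not carry the candidate allele."""
    t = phase.table
    sel = t["chrom"].to_numpy() == chrom
    if not sel.any():
        return False
    tpos = t["pos"].to_numpy()[sel]
    tidx = t["site_idx"].to_numpy()[sel]
    code0 = t["code0"].to_numpy()[sel]
    code1 = t["code1"].to_numpy()[sel]
    k = np.searchsorted(tpos, pos)
    take = [i for i in range(max(0, k - n_flank), min(len(tpos), k + n_flank))
            if tidx[i] != si]
    if not take:
        return False
    flank_sites = tidx[take]
    f0, f1 = code0[take], code1[take]
    carrier = matrix.calls[flank_sites, j]
    carrier_hap = np.full(len(take), -1, dtype=np.int8)
    carrier_hap[carrier == f0] = 0
    carrier_hap[carrier == f1] = 1
    informative = carrier_hap >= 0
    if not informative.any():
        return False
    for jo in cols:
        if jo == j or matrix.calls[si, jo] < 0:
            continue
        other = matrix.calls[flank_sites, jo]
        other_hap = np.full(len(take), -1, dtype=np.int8)
        other_hap[other == f0] = 0
        other_hap[other == f1] = 1
        both = informative & (other_hap >= 0)
        if both.any() and (carrier_hap[both] == other_hap[both]).all() \
                and (carrier_hap[both] >= 0).any():
            return True
    return False


def _in_homopolymer(reference, chrom, pos, run_length: int = 5) -> bool:
    seq = reference.get(chrom)
    if seq is None:
        return False
    lo = max(0, pos - run_length)
    hi = min(len(seq), pos + run_length + 1)
    window = seq[lo:hi]
    run = best = 1
    for i in range(1, len(window)):
        run = run + 1 if window[i] == window[i - 1] else 1
        best = max(best, run)
    return best >= run_length


def exact_poisson_ci(count: int, conf: float = 0.95) -> tuple[float, float]:
    """Garwood exact Poisson confidence interval on the mean count.

    ``low = chi2(alpha/2, 2k)/2`` (0 for k = 0) and
    ``high = chi2(1 - alpha/2, 2k + 2)/2``.
    """
    if not (0.0 < conf < 1.0):
        raise ParameterError(f"conf {conf} not in (0, 1)")
    if count < 0 or int(count) != count:
        raise ParameterError("count must be a non-negative integer")
    alpha = 1.0 - conf
    low = 0.0 if count == 0 else float(stats.chi2.ppf(alpha / 2, 2 * count) / 2)
    high = float(stats.chi2.ppf(1 - alpha / 2, 2 * count + 2) / 2)
    return low, high


@dataclass
class RateEstimate:
    """A mutation-rate estimate with exact Poisson confidence limits."""

    count: int
    total_callable: int
    rate: float
    ci_count: tuple[float, float]
    ci_rate: tuple[float, float]
    conf: float

    def per_genome(self, genome_bp: float) -> float:
        """Expected new mutations per haploid genome per generation."""
        return self.rate * genome_bp

    def to_dict(self) -> dict:
        return {
            "count": self.count, "total_callable": self.total_callable,
            "rate": self.rate,
            "ci_count_low": self.ci_count[0], "ci_count_high": self.ci_count[1],
            "ci_rate_low": self.ci_rate[0], "ci_rate_high": self.ci_rate[1],
            "conf": self.conf,
        }


def estimate_rate(count: int, mask: CallabilityMask, conf: float = 0.95) -> RateEstimate:
    """Per-bp per-haploid-genome per-generation rate with exact Poisson CI."""
    total = mask.total
    if total <= 0:
        raise InputError("total callable sites must be positive")
    if count < 0:
        raise ParameterError("count must be >= 0")
    lo, hi = exact_poisson_ci(count, conf)
    return RateEstimate(
        count=int(count), total_callable=total, rate=count / total,
        ci_count=(lo, hi), ci_rate=(lo / total, hi / total), conf=conf,
    )


def spectrum_summary(calls: pd.DataFrame, gc_fraction: float) -> dict:
    """Mutation-spectrum tally with GC-content-normalized direction ratio.

    The normalized pair divides GC->AT transitions by the genomic GC fraction
    and AT->GC transitions by the AT fraction, so the two numbers are
    comparable per available base.
    """
    if not (0.0 < gc_fraction < 1.0):
        raise ParameterError("gc_fraction must be in (0, 1)")
    snm = calls[calls["kind"] == "SNM"] if len(calls) else calls
    counts = {"GC_to_AT": 0, "AT_to_GC": 0, "transversion": 0, "indel": 0}
    if len(calls):
        counts["indel"] = int((calls["kind"] == "indel").sum())
    if len(snm):
        cls = snm["snm_class"]
        counts["GC_to_AT"] = int((cls == "GC_to_AT").sum())
        counts["AT_to_GC"] = int((cls == "AT_to_GC").sum())
        counts["transversion"] = int(cls.str.startswith("transversion").sum())
    return {
        "counts": counts,
        "n_transitions": counts["GC_to_AT"] + counts["AT_to_GC"],
        "gc_to_at_per_gc": counts["GC_to_AT"] / gc_fraction,
        "at_to_gc_per_at": counts["AT_to_GC"] / (1.0 - gc_fraction),
    }


def spike_in_recovery(
    matrix: GenotypeMatrix,
    n_spikes: int,
    mask: CallabilityMask,
    seed: int,
    chrom_lengths: dict[str, int] | None = None,
    min_depth: int = 5,
    min_quality: float = 30.0,
) -> tuple[float, float]:
    """Genotype-level spike-in false-negative estimate.

    Spikes ``n_spikes`` drone-unique alleles at uniformly random genome
    positions, re-runs the mutation caller, and reports ``(fraction callable,
    fraction detected among callable)``.  Per-site observation statistics for
    spiked entries are resampled from the matrix's own entries, so the spike
    channel matches the empirical one; callability per spike uses the mask's
    per-site arrays when present and otherwise a Bernoulli draw at the
    drone's callable fraction.
    """
    if n_spikes < 1:
        raise ParameterError("n_spikes must be >= 1")
    rng = np.random.default_rng(seed)
    drones = matrix.drones
    lengths = chrom_lengths or {}
    if not lengths:
        # fall back to the observed span per chromosome
        for chrom, grp in matrix.sites.groupby("chrom", sort=False):
            lengths[chrom] = int(grp["pos"].max()) + 1
    chroms = list(lengths)
    chrom_p = np.array([lengths[c] for c in chroms], dtype=float)
    chrom_p /= chrom_p.sum()

    # draw spike targets (unique positions) and their callability
    spikes: list[tuple[str, str, int, bool]] = []
    seen: set[tuple[str, int]] = set()
    while len(spikes) < n_spikes:
        j = int(rng.integers(0, len(drones)))
        drone = drones[j]
        chrom = chroms[int(rng.choice(len(chroms), p=chrom_p))]
        pos = int(rng.integers(0, lengths[chrom]))
        if (chrom, pos) in seen:
            continue
        seen.add((chrom, pos))
        if mask.site_masks is not None:
            site_mask = mask.site_masks[drone]
            callable_here = bool(site_mask[min(pos, len(site_mask) - 1)])
        else:
            frac = mask.per_drone[drone] / mask.genome_length
            callable_here = bool(rng.random() < frac)
        spikes.append((drone, chrom, pos, callable_here))

    # assemble a matrix of only the spiked sites, with channel statistics
    # resampled per entry from the source matrix, and re-run the caller
    order = {c: i for i, c in enumerate(chroms)}
    spikes.sort(key=lambda s: (order[s[1]], s[2]))
    n = len(spikes)
    n_d = len(drones)
    resample = rng.integers(0, matrix.n_sites, size=(n, n_d))
    cols = np.broadcast_to(np.arange(n_d), (n, n_d))
    calls = np.where(matrix.calls[resample, cols] >= 0, 0,
                     matrix.calls[resample, cols]).astype(np.int16)
    depth = matrix.depth[resample, cols].copy()
    quality = matrix.quality[resample, cols].copy()
    fwd = matrix.strand_fwd[resample, cols].copy()
    rev = matrix.strand_rev[resample, cols].copy()
    for i, (drone, _chrom, _pos, _c) in enumerate(spikes):
        j = matrix.drone_index(drone)
        if calls[i, j] >= 0:
            calls[i, j] = 1  # the spiked drone-unique allele
    spiked = GenotypeMatrix(
        sites=pd.DataFrame([(c, p, "A") for _d, c, p, _cb in spikes],
                           columns=["chrom", "pos", "ref"]),
        alleles=[("A", "G")] * n,
        drones=list(drones),
        colonies=dict(matrix.colonies),
        calls=calls, depth=depth, quality=quality,
        strand_fwd=fwd, strand_rev=rev,
    )
    # spikes are deliberately dense, so the same-drone cluster filter (which
    # targets haplotype-block artifacts) is disabled for the re-call
    found = call_denovo(spiked, min_depth=min_depth, min_quality=min_quality,
                        cluster_max=n + 1)
    found_keys = set(zip(found["drone"], found["chrom"], found["pos"]))
    n_callable = sum(1 for s in spikes if s[3])
    n_detected = sum(1 for d, c, p, cb in spikes
                     if cb and (d, c, p) in found_keys)
    frac_callable = n_callable / n_spikes
    frac_detected = n_detected / n_callable if n_callable else float("nan")
    return frac_callable, frac_detected
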