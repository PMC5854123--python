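"""Synthetic social-bee colony generator.

Emulates the data-generating process behind a drone-sequencing study of a
bumblebee colony: a diploid queen whose genome carries heterozygous sites at a
given per-bp rate, haploid drones produced by meiosis with Poisson crossovers
and geometric gene-conversion tracts (with GC-biased resolution at A/T vs G/C
heterozygous sites), de novo point mutations and short indels with a
transition/GC->AT-skewed spectrum, and a per-site observation channel with
depth, quality, strand support, missing calls and artifactual "heterozygous"
calls in haploid samples.

Everything is seeded and returns full ground truth, so every downstream stage
(marker screening, phasing, crossover calling, mutation calling, rate
estimation) can be validated by parameter recovery.

Coordinates are 0-based, half-open throughout; conversion to 1-based happens
only at I/O boundaries (see :mod:`dronehap.io`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError, ParameterError
from .genotypes import CODE_HET, CODE_MISSING, GenotypeMatrix

# Base encoding used internally: A=0, C=1, G=2, T=3, N=4.
BASE_CHARS = np.array(list("ACGTN"))
_GC_CODES = frozenset({1, 2})


def _is_gc(code: int) -> bool:
    return code in _GC_CODES


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomeSpec:
    """Chromosome layout of the simulated reference assembly.

    Parameters
    ----------
    chromosomes
        ``(name, length_bp)`` pairs; lengths must be positive.
    gc_content
        Stationary G+C fraction of the simulated reference (study genome:
        0.375).
    gap_intervals
        ``(chrom, start, end)`` runs of assembly ``N``s.  Markers and
        mutations are never placed inside gaps; recombination events may span
        them, which is what creates apparent shared crossovers at gap edges.
    """

    chromosomes: tuple[tuple[str, int], ...]
    gc_content: float = 0.375
    gap_intervals: tuple[tuple[str, int, int], ...] = ()

    def __post_init__(self):
        if not self.chromosomes:
            raise ParameterError("at least one chromosome is required")
        lengths = dict(self.chromosomes)
        if len(lengths) != len(self.chromosomes):
            raise ParameterError("duplicate chromosome names")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ParameterError(f"chromosome {name!r} has length {length}")
        if not (0.0 <= self.gc_content <= 1.0):
            raise ParameterError(f"gc_content {self.gc_content} not in [0, 1]")
        merged = []
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in self.gap_intervals:
            if chrom not in lengths:
                raise ParameterError(f"gap on unknown chromosome {chrom!r}")
            if not (0 <= start < end <= lengths[chrom]):
                raise ParameterError(f"gap ({chrom}, {start}, {end}) out of bounds")
            by_chrom.setdefault(chrom, []).append((start, end))
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            cur_s, cur_e = ivs[0]
            for s, e in ivs[1:]:
                if s <= cur_e:  # overlapping/adjacent gaps merge
                    cur_e = max(cur_e, e)
                else:
                    merged.append((chrom, cur_s, cur_e))
                    cur_s, cur_e = s, e
            merged.append((chrom, cur_s, cur_e))
        merged.sort(key=lambda g: ([c for c, _ in self.chromosomes].index(g[0]), g[1]))
        object.__setattr__(self, "gap_intervals", tuple(merged))

    @property
    def names(self) -> list[str]:
        return [name for name, _ in self.chromosomes]

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    @property
    def total_length(self) -> int:
        return sum(length for _, length in self.chromosomes)

    def gaps_for(self, chrom: str) -> list[tuple[int, int]]:
        return [(s, e) for c, s, e in self.gap_intervals if c == chrom]

    def nongap_length(self, chrom: str | None = None) -> int:
        if chrom is None:
            return sum(self.nongap_length(c) for c in self.names)
        gap = sum(e - s for s, e in self.gaps_for(chrom))
        return self.lengths[chrom] - gap

    @classmethod
    def bumblebee_like(
        cls,
        total_mb: float = 50.0,
        n_chromosomes: int = 18,
        gc_content: float = 0.375,
        gap_fraction: float = 0.0,
        gaps_per_chromosome: int = 2,
    ) -> "GenomeSpec":
        """A scaled-down 18-chromosome karyotype with a linear length taper.

        Chromosome lengths taper from 1.5x to 0.5x the mean, mimicking the
        broad size spread of a real karyotype without copying one.  Optional
        gaps are placed deterministically at fixed relative positions so a
        spec is fully determined by its arguments.
        """
        total = int(total_mb * 1e6)
        weights = np.linspace(1.5, 0.5, n_chromosomes)
        lengths = np.round(weights / weights.sum() * total).astype(int)
        chroms = tuple((f"LG{i + 1}", int(L)) for i, L in enumerate(lengths))
        gaps: list[tuple[str, int, int]] = []
        if gap_fraction > 0:
            for name, L in chroms:
                glen = int(L * gap_fraction / gaps_per_chromosome)
                for k in range(gaps_per_chromosome):
                    start = int(L * (k + 1) / (gaps_per_chromosome + 1))
                    gaps.append((name, start, min(start + glen, L)))
        return cls(chromosomes=chroms, gc_content=gc_content, gap_intervals=tuple(gaps))


@dataclass(frozen=True)
class MeiosisParams:
    """Recombination model for one meiosis.

    ``co_rate_cM_per_Mb`` sets the Poisson crossover mean per chromosome as
    ``rate * length_Mb / 100`` (map length in cM = 100 x mean crossovers per
    gamete).  Noncrossover conversion tracts are geometric with mean
    ``nco_tract_mean_bp``; a fraction ``co_gc_conversion_prob`` of crossovers
    carry an adjacent conversion tract.  ``gc_bias`` is the probability that a
    converted heterozygous site with one A/T and one G/C allele resolves
    toward the G/C allele.
    """

    co_rate_cM_per_Mb: float = 8.73
    nco_rate_per_gamete: float = 0.7
    nco_tract_mean_bp: float = 300.0
    co_gc_conversion_prob: float = 3 / 606
    gc_bias: float = 23 / 36

    def __post_init__(self):
        if not (math.isfinite(self.co_rate_cM_per_Mb) and self.co_rate_cM_per_Mb >= 0):
            raise ParameterError("co_rate_cM_per_Mb must be finite and >= 0")
        if self.nco_rate_per_gamete < 0:
            raise ParameterError("nco_rate_per_gamete must be >= 0")
        if self.nco_tract_mean_bp <= 0:
            raise ParameterError("nco_tract_mean_bp must be > 0")
        for name in ("co_gc_conversion_prob", "gc_bias"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ParameterError(f"{name} {v} not in [0, 1]")


@dataclass(frozen=True)
class MutationParams:
    """De novo mutation model per gamete.

    The default spectrum mirrors the observed study counts: all substitutions
    are transitions, 20/23 of them originate at G/C sites (hence GC->AT), and
    2 of 25 events are short indels.
    """

    mu_per_bp: float = 3.58e-9
    p_transition: float = 1.0
    p_gc_to_at_given_transition: float = 20 / 23
    indel_fraction: float = 2 / 25
    max_indel_bp: int = 19

    def __post_init__(self):
        if not (math.isfinite(self.mu_per_bp) and self.mu_per_bp >= 0):
            raise ParameterError("mu_per_bp must be finite and >= 0")
        for name in ("p_transition", "p_gc_to_at_given_transition", "indel_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ParameterError(f"{name} {v} not in [0, 1]")
        if not (1 <= self.max_indel_bp < 20):
            raise ParameterError("max_indel_bp must be in [1, 19]")


@dataclass(frozen=True)
class ObservationModel:
    """Per-site, per-drone genotype observation channel.

    Models the *post-variant-calling* genotype table: read depth is Poisson
    around ``mean_depth`` and splits binomially between strands; genotype
    quality is drawn from ``quality_distribution`` (``("normal", mean, sd)``
    or ``("constant", q)``); a fraction ``missing_rate`` of calls are dropped
    (no-call sites are emitted with sub-threshold depth, as real no-calls are
    low-coverage sites); ``het_artifact_rate`` of calls are emitted as
    spurious "heterozygous" genotypes in the haploid sample (the mapping /
    copy-number artifact that marker rule 1 removes); ``genotype_error_rate``
    of calls are replaced by a wrong allele carrying degraded quality and
    predominantly single-strand support (the signal the mutation filters
    remove).
    """

    mean_depth: float = 26.0
    missing_rate: float = 0.02
    genotype_error_rate: float = 0.0
    het_artifact_rate: float = 0.001
    quality_distribution: tuple = ("normal", 60.0, 10.0)
    error_quality_mean: float = 10.0
    error_single_strand_prob: float = 0.9

    def __post_init__(self):
        if self.mean_depth <= 0:
            raise ParameterError("mean_depth must be > 0")
        for name in ("missing_rate", "genotype_error_rate", "het_artifact_rate",
                     "error_single_strand_prob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ParameterError(f"{name} {v} not in [0, 1]")
        kind = self.quality_distribution[0]
        if kind not in ("normal", "constant"):
            raise ParameterError(f"unknown quality distribution {kind!r}")

    def draw_quality(self, rng: np.random.Generator, size) -> np.ndarray:
        kind, *params = self.quality_distribution
        if kind == "constant":
            return np.full(size, float(params[0]))
        mean, sd = params
        return np.clip(rng.normal(mean, sd, size=size), 1.0, 99.0)


# ---------------------------------------------------------------------------
# Queen / gamete containers
# ---------------------------------------------------------------------------


@dataclass
class Queen:
    """A diploid queen: reference sequence plus her heterozygous sites.

    The two haplotypes are identical to the reference except at
    ``het_positions``, where haplotype ``h`` carries base code
    ``het_alleles[chrom][i, h]``.  One of the two alleles always equals the
    reference base.
    """

    spec: GenomeSpec
    reference: dict[str, np.ndarray]          # uint8 base codes, N = 4 in gaps
    het_positions: dict[str, np.ndarray]      # sorted int64 per chromosome
    het_alleles: dict[str, np.ndarray]        # (n_het, 2) uint8: hap0, hap1

    @property
    def n_het(self) -> int:
        return sum(len(p) for p in self.het_positions.values())

    def haplotype_base(self, chrom: str, het_index: int, hap: int) -> int:
        return int(self.het_alleles[chrom][het_index, hap])

    def marker_truth(self) -> pd.DataFrame:
        """True heterozygous sites as a table (chrom, pos, ref, hap0, hap1)."""
        rows = []
        for chrom in self.spec.names:
            pos = self.het_positions[chrom]
            if len(pos) == 0:
                continue
            ref = BASE_CHARS[self.reference[chrom][pos]]
            al = self.het_alleles[chrom]
            rows.append(pd.DataFrame({
                "chrom": chrom, "pos": pos, "ref": ref,
                "hap0": BASE_CHARS[al[:, 0]], "hap1": BASE_CHARS[al[:, 1]],
            }))
        if not rows:
            return pd.DataFrame(columns=["chrom", "pos", "ref", "hap0", "hap1"])
        return pd.concat(rows, ignore_index=True)


@dataclass
class Gamete:
    """One recombinant haploid meiotic product of a queen."""

    drone: str
    # haplotype of origin (0/1) at every queen heterozygous site
    hap_at_het: dict[str, np.ndarray]
    # actual base code carried at every queen het site (conversions applied)
    allele_at_het: dict[str, np.ndarray]
    co_breakpoints: dict[str, np.ndarray]
    mutations: list[dict] = field(default_factory=list)


@dataclass
class SimTruth:
    """Ground truth emitted by the simulator for recovery testing."""

    queen: Queen
    cos: pd.DataFrame          # drone, chrom, pos
    ncos: pd.DataFrame         # drone, chrom, kind, start, end, n_converted
    mutations: pd.DataFrame    # drone, chrom, pos, ref, alt, kind

    def validate(self) -> None:
        lengths = self.queen.spec.lengths
        for _, row in self.cos.iterrows():
            if not (0 <= row.pos < lengths[row.chrom]):
                raise AssertionError(f"CO truth {row.chrom}:{row.pos} out of bounds")
        for drone, grp in self.cos.groupby("drone"):
            for chrom, sub in grp.groupby("chrom"):
                if not sub.pos.is_monotonic_increasing:
                    raise AssertionError(f"unsorted CO truth for {drone}/{chrom}")
        gap_trees = {c: self.queen.spec.gaps_for(c) for c in lengths}
        for _, row in self.mutations.iterrows():
            if not (0 <= row.pos < lengths[row.chrom]):
                raise AssertionError("mutation truth out of bounds")
            for s, e in gap_trees[row.chrom]:
                if s <= row.pos < e:
                    raise AssertionError("mutation truth inside a gap interval")


# ---------------------------------------------------------------------------
# Sampling helpers
# ---------------------------------------------------------------------------


def _nongap_segments(length: int, gaps: list[tuple[int, int]]):
    """Return (starts, lens, cumlens) of the non-gap segments of a chromosome."""
    starts, lens = [], []
    prev = 0
    for s, e in gaps:
        if s > prev:
            starts.append(prev)
            lens.append(s - prev)
        prev = e
    if prev < length:
        starts.append(prev)
        lens.append(length - prev)
    starts = np.asarray(starts, dtype=np.int64)
    lens = np.asarray(lens, dtype=np.int64)
    return starts, lens, np.cumsum(lens)


def sample_nongap_positions(
    rng: np.random.Generator, length: int, gaps: list[tuple[int, int]], n: int
) -> np.ndarray:
    """Draw ``n`` positions uniformly over the non-gap part of a chromosome."""
    if n == 0:
        return np.empty(0, dtype=np.int64)
    starts, lens, cum = _nongap_segments(length, gaps)
    total = int(cum[-1])
    u = rng.integers(0, total, size=n)
    seg = np.searchsorted(cum, u, side="right")
    offset = u - (cum[seg] - lens[seg])
    return starts[seg] + offset


def _sample_unique_nongap(rng, length, gaps, n) -> np.ndarray:
    """Like :func:`sample_nongap_positions` but without replacement."""
    pos = np.unique(sample_nongap_positions(rng, length, gaps, n))
    while len(pos) < n:
        extra = sample_nongap_positions(rng, length, gaps, n - len(pos))
        pos = np.unique(np.concatenate([pos, extra]))
    return np.sort(pos[:n]) if len(pos) > n else pos


# ---------------------------------------------------------------------------
# Core operations
# ---------------------------------------------------------------------------


def simulate_queen(
    spec: GenomeSpec, heterozygosity: float = 0.0026, seed: int | np.random.Generator = 0
) -> Queen:
    """Simulate a reference assembly and a diploid queen over it.

    Heterozygous sites are a Bernoulli process per non-gap bp at rate
    ``heterozygosity`` (study estimate: 0.26%).  At each, one haplotype keeps
    the reference base and the other carries a uniformly chosen different
    base; which haplotype carries the reference is random per site.
    """
    if not (isinstance(heterozygosity, (int, float)) and math.isfinite(heterozygosity)):
        raise ParameterError("heterozygosity must be a finite number")
    if not (0.0 <= heterozygosity <= 0.05):
        raise ParameterError(f"heterozygosity {heterozygosity} not in [0, 0.05]")
    rng = np.random.default_rng(seed)

    reference, het_positions, het_alleles = {}, {}, {}
    gc = spec.gc_content
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    thresholds = np.cumsum(probs)
    for chrom, length in spec.chromosomes:
        gaps = spec.gaps_for(chrom)
        # base composition via one uniform draw per bp
        seq = np.searchsorted(thresholds, rng.random(length), side="right").astype(np.uint8)
        for s, e in gaps:
            seq[s:e] = 4  # N
        n_het = rng.binomial(spec.nongap_length(chrom), heterozygosity)
        pos = _sample_unique_nongap(rng, length, gaps, int(n_het))
        ref_bases = seq[pos]
        alt = (ref_bases + rng.integers(1, 4, size=len(pos))) % 4
        alleles = np.empty((len(pos), 2), dtype=np.uint8)
        ref_on_hap0 = rng.integers(0, 2, size=len(pos)).astype(bool)
        alleles[ref_on_hap0, 0] = ref_bases[ref_on_hap0]
        alleles[ref_on_hap0, 1] = alt[ref_on_hap0]
        alleles[~ref_on_hap0, 0] = alt[~ref_on_hap0]
        alleles[~ref_on_hap0, 1] = ref_bases[~ref_on_hap0]
        reference[chrom] = seq
        het_positions[chrom] = pos
        het_alleles[chrom] = alleles
    return Queen(spec=spec, reference=reference,
                 het_positions=het_positions, het_alleles=het_alleles)


def simulate_drone(
    queen: Queen,
    params: MeiosisParams,
    seed: int | np.random.Generator,
    drone: str = "D1",
    hotspot_map: dict[str, tuple[np.ndarray, np.ndarray]] | None = None,
) -> tuple[Gamete, dict]:
    """Simulate one meiosis: a recombinant haploid gamete plus truth records.

    Crossover counts per chromosome are Poisson with mean
    ``co_rate_cM_per_Mb * L_Mb / 100``; positions are uniform unless a
    ``hotspot_map`` (``chrom -> (bin_edges_bp, weights)``) supplies a
    piecewise-constant intensity.  Conversion tracts flip the donor haplotype
    at covered heterozygous sites, with GC-biased resolution at A/T-G/C sites.
    """
    rng = np.random.default_rng(seed)
    spec = queen.spec
    hap_at_het, allele_at_het, co_breakpoints = {}, {}, {}
    truth = {"cos": [], "ncos": [], "mutations": []}

    for chrom, length in spec.chromosomes:
        het_pos = queen.het_positions[chrom]
        alleles = queen.het_alleles[chrom]
        mean_co = params.co_rate_cM_per_Mb * (length / 1e6) / 100.0
        n_co = rng.poisson(mean_co)
        if hotspot_map and chrom in hotspot_map:
            edges, weights = hotspot_map[chrom]
            widths = np.diff(edges).astype(float)
            p = weights * widths
            p = p / p.sum()
            seg = rng.choice(len(widths), size=n_co, p=p)
            co_pos = np.sort(edges[seg] + rng.random(n_co) * widths[seg]).astype(np.int64)
        else:
            co_pos = np.sort(rng.integers(0, length, size=n_co))
        start_hap = int(rng.integers(0, 2))
        hap = (start_hap + np.searchsorted(co_pos, het_pos, side="right")) % 2
        hap = hap.astype(np.uint8)
        for p_ in co_pos:
            truth["cos"].append({"drone": drone, "chrom": chrom, "pos": int(p_)})

        allele = alleles[np.arange(len(het_pos)), hap].copy()

        # conversion tracts: spontaneous NCOs plus CO-associated tracts
        tracts: list[tuple[int, int, str]] = []
        mean_nco = params.nco_rate_per_gamete * length / spec.total_length
        for _ in range(rng.poisson(mean_nco)):
            t_len = int(rng.geometric(1.0 / params.nco_tract_mean_bp))
            t_start = int(rng.integers(0, length))
            tracts.append((t_start, min(t_start + t_len, length), "NCO"))
        for p_ in co_pos:
            if rng.random() < params.co_gc_conversion_prob:
                t_len = int(rng.geometric(1.0 / params.nco_tract_mean_bp))
                gap_bp = int(rng.geometric(1.0 / params.nco_tract_mean_bp))
                t_start = max(0, int(p_) - gap_bp - t_len)
                tracts.append((t_start, max(t_start + t_len, t_start + 1), "CO_conversion"))

        for t_start, t_end, kind in sorted(tracts):
            lo = np.searchsorted(het_pos, t_start, side="left")
            hi = np.searchsorted(het_pos, t_end, side="left")
            n_conv = 0
            for i in range(lo, hi):
                donor = 1 - hap[i]
                a, b = int(alleles[i, 0]), int(alleles[i, 1])
                if _is_gc(a) != _is_gc(b):  # one A/T, one G/C allele
                    gc_allele = a if _is_gc(a) else b
                    at_allele = b if _is_gc(a) else a
                    new = gc_allele if rng.random() < params.gc_bias else at_allele
                else:
                    new = int(alleles[i, donor])
                if new != allele[i]:
                    n_conv += 1
                allele[i] = new
                hap[i] = donor
            truth["ncos"].append({
                "drone": drone, "chrom": chrom, "kind": kind,
                "start": int(t_start), "end": int(t_end), "n_converted": int(n_conv),
            })

        hap_at_het[chrom] = hap
        allele_at_het[chrom] = allele
        co_breakpoints[chrom] = co_pos.astype(np.int64)

    gamete = Gamete(drone=drone, hap_at_het=hap_at_het,
                    allele_at_het=allele_at_het, co_breakpoints=co_breakpoints)
    return gamete, truth


def apply_mutations(
    queen: Queen,
    gamete: Gamete,
    params: MutationParams,
    seed: int | np.random.Generator,
) -> list[dict]:
    """Superimpose de novo mutations on a gamete; returns the truth records.

    Counts are Poisson(``mu_per_bp`` x non-gap genome length); positions are
    uniform over non-gap sequence (resampled away from queen heterozygous
    sites so truth stays unambiguous); the spectrum follows the transition /
    GC-origin / indel parameters.
    """
    rng = np.random.default_rng(seed)
    spec = queen.spec
    n_mut = rng.poisson(params.mu_per_bp * spec.nongap_length())
    chrom_names = spec.names
    weights = np.array([spec.nongap_length(c) for c in chrom_names], dtype=float)
    weights /= weights.sum()
    records = []
    taken: set[tuple[str, int]] = set()
    for _ in range(n_mut):
        is_indel = rng.random() < params.indel_fraction
        want_gc = None
        if not is_indel:
            is_transition = rng.random() < params.p_transition
            if is_transition:
                want_gc = rng.random() < params.p_gc_to_at_given_transition
        for _attempt in range(1000):
            chrom = chrom_names[rng.choice(len(chrom_names), p=weights)]
            pos = int(sample_nongap_positions(
                rng, spec.lengths[chrom], spec.gaps_for(chrom), 1)[0])
            ref_code = int(queen.reference[chrom][pos])
            if (chrom, pos) in taken or ref_code == 4:
                continue
            idx = np.searchsorted(queen.het_positions[chrom], pos)
            if idx < len(queen.het_positions[chrom]) and queen.het_positions[chrom][idx] == pos:
                continue  # collides with a queen heterozygous site
            if want_gc is not None and _is_gc(ref_code) != want_gc:
                continue  # resample until the origin base class matches
            break
        else:  # pragma: no cover - pathological parameter corner
            continue
        taken.add((chrom, pos))
        ref_char = str(BASE_CHARS[ref_code])
        if is_indel:
            k = min(int(rng.geometric(0.5)), params.max_indel_bp)
            if rng.random() < 0.5 and pos + k + 1 <= spec.lengths[chrom]:
                seg = queen.reference[chrom][pos:pos + k + 1]
                if (seg == 4).any():
                    continue
                ref_str = "".join(BASE_CHARS[seg])
                alt_str = ref_char  # deletion of k bases after the anchor
            else:
                ins = BASE_CHARS[rng.integers(0, 4, size=k)]
                ref_str = ref_char
                alt_str = ref_char + "".join(ins)
            kind = "indel"
        else:
            if is_transition:
                alt_code = (ref_code + 2) % 4  # A<->G, C<->T
            else:
                others = [b for b in range(4)
                          if b != ref_code and b != (ref_code + 2) % 4]
                alt_code = others[rng.integers(0, 2)]
            ref_str, alt_str, kind = ref_char, str(BASE_CHARS[alt_code]), "SNM"
        rec = {"drone": gamete.drone, "chrom": chrom, "pos": pos,
               "ref": ref_str, "alt": alt_str, "kind": kind}
        gamete.mutations.append(rec)
        records.append(rec)
    return records


def observe_colony(
    queen: Queen,
    gametes: list[Gamete],
    model: ObservationModel,
    seed: int | np.random.Generator,
    colony: str = "I",
) -> GenotypeMatrix:
    """Push gametes through the observation channel to a genotype matrix.

    With all noise rates zero the emitted calls equal the gametes exactly.
    Sites are the union of queen heterozygous positions and mutated positions.
    """
    if len(gametes) < 2:
        raise InputError("observe_colony requires at least 2 gametes")
    rng = np.random.default_rng(seed)
    spec = queen.spec
    drones = [g.drone for g in gametes]
    if len(set(drones)) != len(drones):
        raise InputError("duplicate drone identifiers")

    site_rows = []
    alleles: list[tuple[str, ...]] = []
    call_cols = []
    mut_by_site: dict[tuple[str, int], list[tuple[int, str, str]]] = {}
    for j, g in enumerate(gametes):
        for m in g.mutations:
            mut_by_site.setdefault((m["chrom"], m["pos"]), []).append(
                (j, m["ref"], m["alt"]))

    per_chrom_rows = {}
    for chrom in spec.names:
        het_pos = queen.het_positions[chrom]
        mut_pos = sorted({p for (c, p) in mut_by_site if c == chrom})
        all_pos = np.union1d(het_pos, np.asarray(mut_pos, dtype=np.int64))
        per_chrom_rows[chrom] = all_pos
    n_sites = sum(len(v) for v in per_chrom_rows.values())
    n_drones = len(gametes)
    calls = np.zeros((n_sites, n_drones), dtype=np.int16)

    row = 0
    for chrom in spec.names:
        all_pos = per_chrom_rows[chrom]
        het_pos = queen.het_positions[chrom]
        het_alleles = queen.het_alleles[chrom]
        ref_codes = queen.reference[chrom][all_pos]
        is_het = np.isin(all_pos, het_pos)
        het_idx_of_row = np.searchsorted(het_pos, all_pos[is_het])
        het_rows = row + np.flatnonzero(is_het)

        # allele tables
        for k, pos in enumerate(all_pos):
            ref_char = str(BASE_CHARS[ref_codes[k]])
            if is_het[k]:
                i = np.searchsorted(het_pos, pos)
                a0 = str(BASE_CHARS[het_alleles[i, 0]])
                a1 = str(BASE_CHARS[het_alleles[i, 1]])
                alt = a1 if a0 == ref_char else a0
                alleles.append((ref_char, alt))
            else:
                _, mref, malt = mut_by_site[(chrom, int(pos))][0]
                alleles.append((mref, malt))
            site_rows.append((chrom, int(pos), alleles[-1][0]))

        # haploid calls: code 0 = ref allele, 1 = alt
        if len(het_rows):
            for j, g in enumerate(gametes):
                carried = g.allele_at_het[chrom][het_idx_of_row]
                code = (carried != ref_codes[is_het]).astype(np.int16)
                calls[het_rows, j] = code
        for k, pos in enumerate(all_pos):
            if not is_het[k]:
                for j, _mref, _malt in mut_by_site[(chrom, int(pos))]:
                    calls[row + k, j] = 1
        # mutations at heterozygous sites are excluded at placement time
        row += len(all_pos)

    sites = pd.DataFrame(site_rows, columns=["chrom", "pos", "ref"])

    shape = calls.shape
    depth = rng.poisson(model.mean_depth, size=shape).astype(np.int32)
    fwd = rng.binomial(depth, 0.5)
    strand_fwd = fwd > 0
    strand_rev = (depth - fwd) > 0
    quality = model.draw_quality(rng, shape).astype(np.float32)

    if model.genotype_error_rate > 0:
        err = rng.random(shape) < model.genotype_error_rate
        err_sites, err_drones = np.nonzero(err)
        for s, j in zip(err_sites, err_drones):
            wrong = [b for b in "ACGT" if b not in alleles[s]]
            if not wrong:
                continue
            base = wrong[rng.integers(0, len(wrong))]
            alleles[s] = alleles[s] + (base,)
            calls[s, j] = len(alleles[s]) - 1
            quality[s, j] = min(99.0, rng.exponential(model.error_quality_mean))
            if rng.random() < model.error_single_strand_prob:
                if rng.random() < 0.5:
                    strand_fwd[s, j], strand_rev[s, j] = True, False
                else:
                    strand_fwd[s, j], strand_rev[s, j] = False, True

    if model.het_artifact_rate > 0:
        het_mask = rng.random(shape) < model.het_artifact_rate
        calls[het_mask] = CODE_HET
    if model.missing_rate > 0:
        miss = rng.random(shape) < model.missing_rate
        calls[miss] = CODE_MISSING
        depth[miss] = rng.integers(0, 5, size=int(miss.sum()))

    return GenotypeMatrix(
        sites=sites,
        alleles=alleles,
        drones=list(drones),
        colonies={d: colony for d in drones},
        calls=calls,
        depth=depth,
        quality=quality,
        strand_fwd=strand_fwd,
        strand_rev=strand_rev,
    )


# ---------------------------------------------------------------------------
# Convenience drivers
# ---------------------------------------------------------------------------


@dataclass
class ColonySim:
    colony: str
    queen: Queen
    gametes: list[Gamete]
    matrix: GenotypeMatrix
    truth: SimTruth


def simulate_colony(
    spec: GenomeSpec,
    n_drones: int,
    seed: int,
    colony: str = "I",
    heterozygosity: float = 0.0026,
    meiosis: MeiosisParams | None = None,
    mutation: MutationParams | None = None,
    observation: ObservationModel | None = None,
    queen: Queen | None = None,
) -> ColonySim:
    """Simulate one colony end to end: queen, drones, mutations, observation."""
    meiosis = meiosis or MeiosisParams()
    mutation = mutation or MutationParams()
    observation = observation or ObservationModel()
    ss = np.random.SeedSequence(seed)
    seeds = ss.spawn(2 * n_drones + 2)
    if queen is None:
        queen = simulate_queen(spec, heterozygosity, np.random.default_rng(seeds[0]))
    gametes, cos, ncos, muts = [], [], [], []
    for i in range(n_drones):
        drone = f"{colony}-D{i + 1}"
        g, truth = simulate_drone(queen, meiosis, np.random.default_rng(seeds[1 + i]),
                                  drone=drone)
        recs = apply_mutations(queen, g, mutation,
                               np.random.default_rng(seeds[1 + n_drones + i]))
        gametes.append(g)
        cos.extend(truth["cos"])
        ncos.extend(truth["ncos"])
        muts.extend(recs)
    matrix = observe_colony(queen, gametes, observation,
                            np.random.default_rng(seeds[-1]), colony=colony)
    truth = SimTruth(
        queen=queen,
        cos=pd.DataFrame(cos, columns=["drone", "chrom", "pos"]),
        ncos=pd.DataFrame(ncos, columns=["drone", "chrom", "kind", "start", "end",
                                         "n_converted"]),
        mutations=pd.DataFrame(muts, columns=["drone", "chrom", "pos", "ref", "alt",
                                              "kind"]),
    )
    return ColonySim(colony=colony, queen=queen, gametes=gametes,
                     matrix=matrix, truth=truth)


def estimate_callable(
    model: ObservationModel,
    drones: list[str],
    nongap_length: int,
    seed: int,
    n_probe: int = 50_000,
    min_depth: int = 5,
    min_quality: float = 20.0,
):
    """Estimate per-drone callable-site counts by probing the channel.

    Depth and quality are i.i.d. across sites under the observation model, so
    the genome-wide callable fraction per drone is estimated on ``n_probe``
    simulated channel draws and scaled to the non-gap genome length.
    """
    from .mutations import CallabilityMask

    rng = np.random.default_rng(seed)
    counts = {}
    for d in drones:
        depth = rng.poisson(model.mean_depth, size=n_probe)
        miss = rng.random(n_probe) < model.missing_rate
        depth[miss] = rng.integers(0, 5, size=int(miss.sum()))
        qual = model.draw_quality(rng, n_probe)
        frac = float(np.mean((depth >= min_depth) & (qual >= min_quality)))
        counts[d] = int(round(frac * nongap_length))
    return CallabilityMask(
        per_drone=pd.Series(counts),
        genome_length=nongap_length,
        min_depth=min_depth,
        min_quality=min_quality,
    )
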