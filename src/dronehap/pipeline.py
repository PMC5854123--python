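"""End-to-end colony analysis: screen -> phase -> events -> rates -> mutations
-> randomization statistics.

The in-memory entry point is :func:`analyze_study` (one genotype matrix per
colony plus a callable-site mask); :func:`run_pipeline` is the file-driven
wrapper that reads the interface formats, runs the analysis, and writes
BED/VCF/TSV/JSON outputs plus a human-readable summary.  Every run echoes its
resolved configuration next to the outputs, and identical (inputs, seed)
produce byte-identical JSON reports.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as dio
from .errors import InputError
from .genotypes import GenotypeMatrix, marker_density, screen_markers
from .mutations import CallabilityMask, call_denovo, estimate_rate, spectrum_summary
from .phasing import assign_blocks_all, phase_queen
from .recombination import (classify_events, crossover_rate, group_shared_cos,
                            window_rates)
from .stats import (colony_heterogeneity, conversion_bias_test, dispersion_test,
                    proximity_test)


@dataclass
class PipelineConfig:
    """Thresholds, seeds and replicate counts for a pipeline run.

    Defaults are the study's operating values: marker quality 30 at 90% call
    rate, 10-kb CO/NCO threshold, mutation depth 5 / quality 30, callable
    depth 5 / mapping quality 20, 1-kb proximity window, 100-kb correlate
    windows, 500-kb rate windows, 700-kb double-CO window.
    """

    marker_min_quality: float = 30.0
    marker_min_call_fraction: float = 0.9
    marker_min_carriers: int = 2
    co_nco_threshold_bp: int = 10_000
    mutation_min_depth: int = 5
    mutation_min_quality: float = 30.0
    callable_min_depth: int = 5
    callable_min_quality: float = 20.0
    proximity_window_bp: int = 1_000
    corr_window_bp: int = 100_000
    rate_window_bp: int = 500_000
    n_bins: int = 23
    double_co_window_bp: int = 700_000
    hotspot_multiple: float = 5.0
    genome_mb: float = 216.85
    genome_bp_unassembled: float = 274e6  # full genome size for per-genome rates
    gc_content: float = 0.375
    seed: int = 0
    dispersion_reps: int = 10_000
    proximity_reps: int = 10_000
    conversion_reps: int = 10_000
    paths: dict = field(default_factory=dict)

    def __post_init__(self):
        for name in ("co_nco_threshold_bp", "mutation_min_depth",
                     "proximity_window_bp", "corr_window_bp", "rate_window_bp",
                     "double_co_window_bp"):
            if getattr(self, name) <= 0:
                raise InputError(f"{name} must be positive")

    @classmethod
    def from_toml(cls, path) -> "PipelineConfig":
        raw = dio.load_config_toml(path)
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ColonyResult:
    colony: str
    markers: object
    phase: object
    blocks: pd.DataFrame
    mismatches: pd.DataFrame
    events: pd.DataFrame


@dataclass
class StudyResult:
    colonies: dict
    events: pd.DataFrame
    rates: object
    windows: pd.DataFrame
    calls: pd.DataFrame
    rate_estimate: object
    indel_estimate: object
    spectrum: dict
    stats: dict
    summary: dict


def analyze_colony(matrix: GenotypeMatrix, colony: str,
                   config: PipelineConfig,
                   gap_intervals=None) -> ColonyResult:
    """Marker screening, phasing and event classification for one colony."""
    markers = screen_markers(matrix, colony,
                             min_quality=config.marker_min_quality,
                             min_call_fraction=config.marker_min_call_fraction,
                             min_carriers_per_allele=config.marker_min_carriers)
    phase = phase_queen(markers, matrix)
    blocks, mismatches = assign_blocks_all(phase, matrix)
    events = classify_events(blocks, threshold_bp=config.co_nco_threshold_bp)
    events = group_shared_cos(events, gap_intervals=gap_intervals,
                              double_co_window=config.double_co_window_bp)
    return ColonyResult(colony=colony, markers=markers, phase=phase,
                        blocks=blocks, mismatches=mismatches, events=events)


def analyze_study(
    matrices: list[GenotypeMatrix],
    callable_mask: CallabilityMask,
    config: PipelineConfig | None = None,
    gap_intervals=None,
    chrom_lengths: dict[str, int] | None = None,
) -> StudyResult:
    """Run the full analysis over one or more colony matrices.

    ``callable_mask`` supplies the per-drone mutation-rate denominators; the
    matrices must have disjoint drone sets.  ``chrom_lengths`` (needed for
    window rates and proximity nulls) defaults to the observed marker span.
    """
    config = config or PipelineConfig()
    if not matrices:
        raise InputError("no genotype matrices supplied")
    all_drones: list[str] = []
    for m in matrices:
        overlap = set(all_drones) & set(m.drones)
        if overlap:
            raise InputError(f"drone sets overlap between matrices: {sorted(overlap)}")
        all_drones.extend(m.drones)
    missing = set(all_drones) - set(callable_mask.per_drone.index)
    if missing:
        raise InputError(f"callable mask lacks drones: {sorted(missing)}")

    if chrom_lengths is None:
        chrom_lengths = {}
        for m in matrices:
            for chrom, grp in m.sites.groupby("chrom", sort=False):
                chrom_lengths[chrom] = max(chrom_lengths.get(chrom, 0),
                                           int(grp["pos"].max()) + 1)

    colony_results: dict[str, ColonyResult] = {}
    all_events = []
    all_calls = []
    for m in matrices:
        for colony in m.colony_names:
            res = analyze_colony(m, colony, config, gap_intervals=gap_intervals)
            colony_results[colony] = res
            all_events.append(res.events)
        calls = call_denovo(
            m, min_depth=config.mutation_min_depth,
            min_quality=config.mutation_min_quality,
            markers={c: colony_results[c].markers for c in m.colony_names},
            phases={c: colony_results[c].phase for c in m.colony_names},
            gap_intervals=gap_intervals)
        all_calls.append(calls)
    events = pd.concat(all_events, ignore_index=True)
    calls = pd.concat(all_calls, ignore_index=True)

    n_drones = len(all_drones)
    rates = crossover_rate(events, config.genome_mb, n_drones, drones=all_drones)
    windows = window_rates(events, chrom_lengths, n_drones,
                           window_bp=config.rate_window_bp,
                           hotspot_multiple=config.hotspot_multiple)

    snm = calls[calls["kind"] == "SNM"]
    indel = calls[calls["kind"] == "indel"]
    rate_estimate = estimate_rate(len(snm), callable_mask)
    indel_estimate = estimate_rate(len(indel), callable_mask)
    spectrum = spectrum_summary(calls, config.gc_content)

    ss = np.random.SeedSequence(config.seed)
    s_disp, s_prox, s_conv = [s.generate_state(1)[0] % (2**31)
                              for s in ss.spawn(3)]
    per_drone_counts = snm.groupby("drone").size().reindex(all_drones, fill_value=0)
    stats_out: dict = {
        "dispersion": dispersion_test(per_drone_counts.to_numpy(),
                                      reps=config.dispersion_reps,
                                      seed=int(s_disp)).to_dict(),
    }
    colony_sizes = pd.Series({c: len([d for d in all_drones
                                      for m in matrices
                                      if d in m.drones and m.colonies[d] == c])
                              for c in colony_results})
    if len(colony_sizes) >= 2:
        per_colony = snm.groupby("drone").size().groupby(
            lambda d: _colony_of(d, matrices)).sum()
        per_colony = per_colony.reindex(colony_sizes.index, fill_value=0)
        het = colony_heterogeneity(per_colony.to_numpy(),
                                   colony_sizes.to_numpy())
        stats_out["colony_heterogeneity"] = {
            "observed": per_colony.to_dict(),
            "expected": {c: float(e) for c, e in
                         zip(colony_sizes.index, het["expected"])},
            "chi2": het["chi2"], "df": het["df"], "p": het["p"],
        }
    if len(snm) and not events.empty:
        stats_out["proximity"] = proximity_test(
            snm, events, chrom_lengths,
            window_bp=config.proximity_window_bp,
            reps=config.proximity_reps, seed=int(s_prox)).to_dict()
    conversions = _conversion_directions(colony_results, matrices)
    if len(conversions):
        stats_out["conversion_bias"] = conversion_bias_test(
            conversions, reps=config.conversion_reps,
            seed=int(s_conv)).to_dict()

    nco = events[events["kind"] == "NCO"] if not events.empty else events
    n_chrom = len(chrom_lengths)
    summary = {
        "n_drones": n_drones,
        "n_markers": {c: r.markers.n_markers for c, r in colony_results.items()},
        "marker_density_bp": {c: (marker_density(r.markers)
                                  if r.markers.n_markers >= 2 else None)
                              for c, r in colony_results.items()},
        "co_rate_cm_per_mb": rates.cm_per_mb,
        "co_rate_cm_per_mb_raw": rates.cm_per_mb_raw,
        "cos_per_drone": rates.cos_per_drone,
        "cos_per_chromosome_per_drone": rates.cos_per_drone / n_chrom,
        "ncos_per_drone": len(nco) / n_drones,
        "converted_markers_per_drone": float(nco["n_converted"].sum()) / n_drones
            if len(nco) else 0.0,
        "n_snm": int(len(snm)), "n_indel": int(len(indel)),
        "mutation_rate_per_bp": rate_estimate.rate,
        "mutation_rate_ci": list(rate_estimate.ci_rate),
        "indel_rate_per_bp": indel_estimate.rate,
        "per_genome_rate": rate_estimate.per_genome(config.genome_bp_unassembled),
        "n_hotspot_windows": int(windows["hotspot"].sum()),
    }
    return StudyResult(colonies=colony_results, events=events, rates=rates,
                       windows=windows, calls=calls,
                       rate_estimate=rate_estimate,
                       indel_estimate=indel_estimate, spectrum=spectrum,
                       stats=stats_out, summary=summary)


def _colony_of(drone: str, matrices) -> str:
    for m in matrices:
        if drone in m.colonies:
            return m.colonies[drone]
    raise InputError(f"unknown drone {drone!r}")


def _conversion_directions(colony_results, matrices) -> pd.DataFrame:
    """Per converted marker, the (from, to) alleles of each NCO tract.

    The donor haplotype's allele is what the drone carries; the other
    haplotype's allele at the same marker is what was replaced.
    """
    rows = []
    by_colony = {m.colonies[d]: m for m in matrices for d in m.drones}
    for colony, res in colony_results.items():
        ev = res.events
        if ev.empty:
            continue
        matrix = by_colony[colony]
        t = res.phase.table
        j_of = {d: matrix.drone_index(d) for d in set(ev["drone"])}
        conv = ev[ev["kind"].isin(["NCO", "CO_conversion"])]
        for _, e in conv.iterrows():
            in_tract = ((t["chrom"] == e["chrom"])
                        & (t["pos"] >= e["tract_start"])
                        & (t["pos"] <= e["tract_end"]))
            for _, mk in t[in_tract].iterrows():
                call = matrix.calls[int(mk["site_idx"]), j_of[e["drone"]]]
                if call == mk["code0"]:
                    frm, to = mk["hap1"], mk["hap0"]
                elif call == mk["code1"]:
                    frm, to = mk["hap0"], mk["hap1"]
                else:
                    continue
                rows.append({"chrom": e["chrom"], "pos": int(mk["pos"]),
                             "drone": e["drone"],
                             "from_allele": frm, "to_allele": to})
    return pd.DataFrame(rows, columns=["chrom", "pos", "drone",
                                       "from_allele", "to_allele"])


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """File-driven pipeline: read interface formats, analyze, write reports.

    ``config.paths`` must contain ``genotypes`` (list of genotype TSV paths,
    one per colony) and ``callable`` (callable-count TSV); optional keys:
    ``gaps`` (BED of assembly gaps) and ``chrom_lengths`` (two-column TSV).
    Writes events BED, mutation VCF+TSV, summary JSON and the resolved
    configuration into ``out_dir``.
    """
    paths = config.paths
    for key in ("genotypes", "callable"):
        if key not in paths:
            raise InputError(f"config.paths missing {key!r}")
    for p in list(paths["genotypes"]) + [paths["callable"]]:
        if not Path(p).exists():
            raise InputError(f"missing input file: {p}")
    matrices = [dio.read_genotype_tsv(p) for p in paths["genotypes"]]
    if not any(m.n_sites for m in matrices):
        raise InputError("no genotype sites found in inputs")
    mask = dio.read_callable_tsv(paths["callable"])
    gaps = dio.read_bed_intervals(paths["gaps"]) if paths.get("gaps") else None
    chrom_lengths = None
    if paths.get("chrom_lengths"):
        df = pd.read_csv(paths["chrom_lengths"], sep="\t",
                         names=["chrom", "length"], comment="#")
        chrom_lengths = dict(zip(df["chrom"], df["length"].astype(int)))

    result = analyze_study(matrices, mask, config, gap_intervals=gaps,
                           chrom_lengths=chrom_lengths)

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dio.write_events_bed(result.events, out / "events.bed")
    dio.write_mutations_tsv(result.calls, out / "mutations.tsv")
    if len(result.calls):
        _write_calls_vcf(result.calls, matrices, chrom_lengths,
                         out / "mutations.vcf")
    report = {
        "summary": result.summary,
        "spectrum": result.spectrum,
        "stats": result.stats,
        "rates": result.rates.to_dict(),
        "rate_estimate": result.rate_estimate.to_dict(),
        "indel_estimate": result.indel_estimate.to_dict(),
        "marker_drop_counts": {c: r.markers.drop_counts
                               for c, r in result.colonies.items()},
    }
    dio.dump_json(report, out / "report.json")
    dio.dump_json(config.to_dict(), out / "config_resolved.json")
    return report


def _write_calls_vcf(calls, matrices, chrom_lengths, path) -> None:
    drones = [d for m in matrices for d in m.drones]
    colonies = {d: m.colonies[d] for m in matrices for d in m.drones}
    order = {c: i for i, c in enumerate(pd.unique(calls["chrom"]))}
    calls = calls.sort_values(["chrom", "pos"],
                              key=lambda s: s.map(order) if s.name == "chrom" else s)
    n = len(calls)
    calls_arr = np.zeros((n, len(drones)), dtype=np.int16)
    for i, (_, c) in enumerate(calls.iterrows()):
        calls_arr[i, drones.index(c["drone"])] = 1
    matrix = GenotypeMatrix(
        sites=pd.DataFrame({"chrom": calls["chrom"].to_numpy(),
                            "pos": calls["pos"].to_numpy(),
                            "ref": calls["ref"].to_numpy()}),
        alleles=[(r, a) for r, a in zip(calls["ref"], calls["alt"])],
        drones=drones, colonies=colonies, calls=calls_arr,
        depth=np.full_like(calls_arr, 26, dtype=np.int32),
        quality=np.full_like(calls_arr, 60, dtype=np.float32),
        strand_fwd=np.ones_like(calls_arr, dtype=bool),
        strand_rev=np.ones_like(calls_arr, dtype=bool),
    )
    dio.write_vcf(matrix, path, chrom_lengths=chrom_lengths)
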