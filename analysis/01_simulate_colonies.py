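#!/usr/bin/env python
"""Simulate the two-colony drone study at a 50 Mb genome scale.

Writes the observed genotype tables (one per colony), the callable-site
counts, and the full ground truth (queen haplotypes, recombination events,
mutations) under scratch/sim/ for the downstream analysis scripts.  The
mutation rate is scaled up by the genome-size ratio so the expected mutation
count (~25) matches the study's, giving the mutation pipeline something to
find at this genome size.
"""

import argparse
import json
from pathlib import Path

import dronehap as dh
from dronehap import io as dio

GENOME_MB = 50.0
COLONIES = {"I": 22, "II": 10}
MU = 3.6e-9 * 216.85 / GENOME_MB


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("scratch/sim"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    spec = dh.GenomeSpec.bumblebee_like(total_mb=GENOME_MB, n_chromosomes=18,
                                        gap_fraction=0.005)
    mut = dh.MutationParams(mu_per_bp=MU)
    sims = {}
    drones = []
    for i, (colony, n) in enumerate(COLONIES.items()):
        sim = dh.simulate_colony(spec, n, seed=args.seed * 1000 + i,
                                 colony=colony, mutation=mut)
        sims[colony] = sim
        drones += sim.matrix.drones
        dio.write_genotype_tsv(sim.matrix, args.out / f"colony_{colony}.tsv")
        sim.queen.marker_truth().to_csv(
            args.out / f"truth_markers_{colony}.tsv", sep="\t", index=False)
        sim.truth.cos.to_csv(args.out / f"truth_cos_{colony}.tsv",
                             sep="\t", index=False)
        sim.truth.ncos.to_csv(args.out / f"truth_ncos_{colony}.tsv",
                              sep="\t", index=False)
        sim.truth.mutations.to_csv(args.out / f"truth_mutations_{colony}.tsv",
                                   sep="\t", index=False)
        print(f"colony {colony}: {n} drones, {sim.queen.n_het} queen het sites, "
              f"{len(sim.truth.cos)} true COs, {len(sim.truth.ncos)} conversion "
              f"tracts, {len(sim.truth.mutations)} true mutations")

    mask = dh.estimate_callable(dh.ObservationModel(), drones,
                                spec.nongap_length(), seed=args.seed * 1000 + 99)
    dio.write_callable_tsv(mask, args.out / "callable.tsv")
    with (args.out / "chrom_lengths.tsv").open("w") as fh:
        for c, L in spec.lengths.items():
            fh.write(f"{c}\t{L}\n")
    dio.write_bed_intervals(spec.gap_intervals, args.out / "gaps.bed")
    meta = {"seed": args.seed, "genome_mb": GENOME_MB,
            "genome_bp": spec.total_length, "mu_per_bp": MU,
            "colonies": COLONIES}
    (args.out / "meta.json").write_text(json.dumps(meta, indent=2) + "\n")
    print(f"mean callable fraction {mask.mean_fraction:.4f}; "
          f"inputs written to {args.out}")


if __name__ == "__main__":
    main()
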