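#!/usr/bin/env python
"""Randomization statistics over the simulated study and the published counts.

Runs the Poisson-dispersion Monte Carlo (simulated per-drone counts and the
packaged published mutation table), the colony-heterogeneity chi-square, the
mutation-to-breakpoint proximity randomization, the conversion GC-bias test,
and — as a demonstration on a random split of the simulated drones — the
between-groups rate-difference permutation.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

import dronehap as dh
from dronehap import io as dio
from dronehap.datasets import per_drone_snm_counts


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--sim", type=Path, default=Path("scratch/sim"))
    ap.add_argument("--results", type=Path, default=Path("results"))
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--reps", type=int, default=10_000)
    args = ap.parse_args()
    args.results.mkdir(parents=True, exist_ok=True)
    rng = np.random.SeedSequence(args.seed)
    seeds = [int(s.generate_state(1)[0] % 2**31) for s in rng.spawn(5)]

    matrices = [dio.read_genotype_tsv(args.sim / f"colony_{c}.tsv")
                for c in ("I", "II")]
    mask = dio.read_callable_tsv(args.sim / "callable.tsv")
    lengths = dict(pd.read_csv(args.sim / "chrom_lengths.tsv", sep="\t",
                               names=["chrom", "length"]).to_numpy())
    lengths = {c: int(L) for c, L in lengths.items()}
    cfg = dh.PipelineConfig(genome_mb=sum(lengths.values()) / 1e6,
                            seed=seeds[0], dispersion_reps=args.reps,
                            proximity_reps=args.reps, conversion_reps=args.reps)
    res = dh.analyze_study(matrices, mask, cfg, chrom_lengths=lengths)

    out = {"simulated_study": res.stats}
    print("simulated study:")
    for name, st in res.stats.items():
        p = st.get("p")
        print(f"  {name}: p = {p if p is None else round(p, 4)}")

    pub = dh.dispersion_test(per_drone_snm_counts().to_numpy(),
                             reps=100_000, seed=seeds[1])
    out["published_counts_dispersion"] = pub.to_dict()
    print(f"published per-drone counts: variance {pub.observed:.3f}, "
          f"null mean {pub.extra['null_mean_variance']:.3f}, "
          f"over-dispersion p = {pub.p:.3f}")

    # rate-difference permutation demonstrated on a random drone split
    drones = list(res.rates.per_drone.index)
    snm = res.calls[res.calls["kind"] == "SNM"]
    per_ind = snm.groupby("drone").size().reindex(drones, fill_value=0)
    rates = per_ind.to_numpy() / mask.per_drone.reindex(drones).to_numpy()
    perm = np.random.default_rng(seeds[2]).permutation(len(rates))
    split = dh.rate_difference_permutation(rates[perm[:22]], rates[perm[22:]],
                                           reps=args.reps, seed=seeds[3])
    out["rate_difference_random_split"] = split.to_dict()
    print(f"random-split rate-difference permutation: p = {split.p:.3f} "
          f"(null split, expected non-significant)")

    def clean(o):
        if isinstance(o, dict):
            return {k: clean(v) for k, v in o.items() if k != "null"}
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        if isinstance(o, (list, tuple)):
            return [clean(v) for v in o]
        return o

    (args.results / "randomization.json").write_text(
        json.dumps(clean(out), indent=2, default=str) + "\n")


if __name__ == "__main__":
    main()
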