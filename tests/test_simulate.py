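"""Simulator behaviour: degenerate limits, distributional oracles, truth
conservation and seed determinism."""

import numpy as np
import pytest
from scipy import stats as sps

import dronehap as dh
from dronehap.errors import InputError, ParameterError
from dronehap.simulate import BASE_CHARS


class TestGenomeSpec:
    def test_gap_normalization_merges_and_sorts(self):
        spec = dh.GenomeSpec(
            chromosomes=(("c1", 1000),),
            gap_intervals=(("c1", 500, 600), ("c1", 100, 200), ("c1", 550, 700)))
        assert spec.gap_intervals == (("c1", 100, 200), ("c1", 500, 700))
        assert spec.nongap_length() == 1000 - 100 - 200

    @pytest.mark.parametrize("bad", [
        {"chromosomes": ()},
        {"chromosomes": (("c1", 0),)},
        {"chromosomes": (("c1", 100),), "gc_content": 1.2},
        {"chromosomes": (("c1", 100),), "gap_intervals": (("c1", 50, 200),)},
        {"chromosomes": (("c1", 100),), "gap_intervals": (("cX", 0, 10),)},
    ])
    def test_invalid_specs_rejected(self, bad):
        with pytest.raises(ParameterError):
            dh.GenomeSpec(**bad)


class TestSimulateQueen:
    def test_zero_heterozygosity_gives_identical_haplotypes(self):
        spec = dh.GenomeSpec(chromosomes=(("c1", 100_000),))
        q = dh.simulate_queen(spec, heterozygosity=0.0, seed=1)
        assert q.n_het == 0

    def test_het_count_matches_binomial_oracle(self):
        # 10 Mb at 0.26% -> Binomial(1e7, 0.0026): mean 26000, sd ~161
        spec = dh.GenomeSpec(chromosomes=(("c1", 10_000_000),))
        q = dh.simulate_queen(spec, heterozygosity=0.0026, seed=2)
        mean, sd = 26_000, np.sqrt(1e7 * 0.0026 * 0.9974)
        assert abs(q.n_het - mean) < 4 * sd

    def test_base_composition_matches_gc_within_binomial_error(self):
        spec = dh.GenomeSpec(chromosomes=(("c1", 2_000_000),), gc_content=0.375)
        q = dh.simulate_queen(spec, heterozygosity=0.0, seed=3)
        seq = q.reference["c1"]
        gc = float(((seq == 1) | (seq == 2)).mean())
        sd = np.sqrt(0.375 * 0.625 / 2e6)
        assert abs(gc - 0.375) < 5 * sd

    def test_one_queen_allele_is_always_the_reference(self):
        spec = dh.GenomeSpec(chromosomes=(("c1", 500_000),))
        q = dh.simulate_queen(spec, 0.003, seed=4)
        ref = q.reference["c1"][q.het_positions["c1"]]
        al = q.het_alleles["c1"]
        assert (((al[:, 0] == ref) | (al[:, 1] == ref))
                & (al[:, 0] != al[:, 1])).all()

    def test_markers_never_inside_gaps(self):
        spec = dh.GenomeSpec(chromosomes=(("c1", 1_000_000),),
                             gap_intervals=(("c1", 200_000, 400_000),))
        q = dh.simulate_queen(spec, 0.003, seed=5)
        pos = q.het_positions["c1"]
        assert not ((pos >= 200_000) & (pos < 400_000)).any()

    @pytest.mark.parametrize("h", [-0.1, 0.2, float("nan"), float("inf")])
    def test_out_of_range_heterozygosity_rejected(self, h):
        spec = dh.GenomeSpec(chromosomes=(("c1", 1000),))
        with pytest.raises(ParameterError):
            dh.simulate_queen(spec, heterozygosity=h, seed=0)


class TestSimulateDrone:
    def test_no_recombination_gives_a_whole_parental_haplotype(self):
        spec = dh.GenomeSpec(chromosomes=(("c1", 500_000), ("c2", 500_000)))
        q = dh.simulate_queen(spec, 0.003, seed=6)
        params = dh.MeiosisParams(co_rate_cM_per_Mb=0.0, nco_rate_per_gamete=0.0,
                                  co_gc_conversion_prob=0.0)
        g, truth = dh.simulate_drone(q, params, seed=7)
        assert not truth["cos"] and not truth["ncos"]
        for chrom in spec.names:
            hap = g.hap_at_het[chrom]
            assert len(np.unique(hap)) <= 1  # one whole haplotype per chromosome
            h = int(hap[0]) if len(hap) else 0
            expect = q.het_alleles[chrom][:, h]
            assert (g.allele_at_het[chrom] == expect).all()

    def test_mean_co_count_matches_poisson_oracle(self):
        # 8.73 cM/Mb x 216.85 Mb / 100 = 18.93 expected crossovers per gamete
        spec = dh.GenomeSpec.bumblebee_like(total_mb=216.85, n_chromosomes=18)
        q = dh.simulate_queen(spec, heterozygosity=0.0, seed=8)
        params = dh.MeiosisParams(co_rate_cM_per_Mb=8.73)
        rng = np.random.default_rng(9)
        n_gametes = 1000
        counts = np.empty(n_gametes)
        for i in range(n_gametes):
            _, truth = dh.simulate_drone(q, params, seed=rng)
            counts[i] = len(truth["cos"])
        mean = 8.73 * 216.85 / 100
        assert abs(counts.mean() - mean) < 3 * np.sqrt(mean / n_gametes)

    def test_co_counts_pass_poisson_goodness_of_fit(self):
        spec = dh.GenomeSpec(chromosomes=(("c1", 20_000_000),))
        q = dh.simulate_queen(spec, 0.0, seed=10)
        params = dh.MeiosisParams(co_rate_cM_per_Mb=10.0)  # mean 2 per gamete
        rng = np.random.default_rng(11)
        counts = np.array([len(dh.simulate_drone(q, params, seed=rng)[1]["cos"])
                           for _ in range(600)])
        mean = 2.0
        edges = np.arange(0, 7)
        obs = np.array([(counts == k).sum() for k in edges[:-1]]
                       + [(counts >= edges[-1]).sum()])
        exp = np.array([sps.poisson.pmf(k, mean) for k in edges[:-1]]
                       + [sps.poisson.sf(edges[-1] - 1, mean)]) * len(counts)
        _, p = sps.chisquare(obs, exp)
        assert p > 0.005

    def test_nco_rate_scales_with_parameter(self):
        spec = dh.GenomeSpec(chromosomes=(("c1", 5_000_000),))
        q = dh.simulate_queen(spec, 0.0026, seed=12)
        params = dh.MeiosisParams(co_rate_cM_per_Mb=0.0, nco_rate_per_gamete=0.7,
                                  co_gc_conversion_prob=0.0)
        rng = np.random.default_rng(13)
        n = 800
        total = sum(len(dh.simulate_drone(q, params, seed=rng)[1]["ncos"])
                    for _ in range(n))
        assert abs(total / n - 0.7) < 3 * np.sqrt(0.7 / n)


class TestApplyMutations:
    def test_zero_rate_gives_no_mutations(self):
        spec = dh.GenomeSpec(chromosomes=(("c1", 100_000),))
        q = dh.simulate_queen(spec, 0.0026, seed=14)
        g, _ = dh.simulate_drone(q, dh.MeiosisParams(), seed=15)
        recs = dh.apply_mutations(q, g, dh.MutationParams(mu_per_bp=0.0), seed=16)
        assert recs == [] and g.mutations == []

    def test_expected_count_matches_poisson_oracle(self):
        # 32 gametes x 3.58e-9/bp x 200.82 Mb ~ 23 mutations
        spec = dh.GenomeSpec(chromosomes=(("c1", 200_820_000),))
        q = dh.simulate_queen(spec, 0.0, seed=17)
        params = dh.MutationParams(mu_per_bp=3.58e-9, indel_fraction=0.0)
        rng = np.random.default_rng(18)
        reps, gametes = 10, 32
        total = 0
        for _ in range(reps * gametes):
            g = dh.Gamete(drone="d", hap_at_het={"c1": np.empty(0, np.uint8)},
                          allele_at_het={"c1": np.empty(0, np.uint8)},
                          co_breakpoints={"c1": np.empty(0, np.int64)})
            total += len(dh.apply_mutations(q, g, params, seed=rng))
        mean = 3.58e-9 * 200.82e6 * gametes * reps
        assert abs(total - mean) < 4 * np.sqrt(mean)

    def test_spectrum_follows_gc_origin_parameter(self):
        spec = dh.GenomeSpec(chromosomes=(("c1", 2_000_000),), gc_content=0.375)
        q = dh.simulate_queen(spec, 0.0, seed=19)
        params = dh.MutationParams(mu_per_bp=2e-4, p_transition=1.0,
                                   p_gc_to_at_given_transition=20 / 23,
                                   indel_fraction=0.0)
        g = dh.Gamete(drone="d", hap_at_het={"c1": np.empty(0, np.uint8)},
                      allele_at_het={"c1": np.empty(0, np.uint8)},
                      co_breakpoints={"c1": np.empty(0, np.int64)})
        recs = dh.apply_mutations(q, g, params, seed=20)
        gc_origin = sum(1 for r in recs if r["ref"] in "GC")
        frac = gc_origin / len(recs)
        sd = np.sqrt((20 / 23) * (3 / 23) / len(recs))
        assert abs(frac - 20 / 23) < 4 * sd
        # transitions only, so direction is determined by the origin base
        assert all((r["ref"], r["alt"]) in
                   {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")} for r in recs)

    def test_mutations_avoid_gaps_and_het_sites(self):
        spec = dh.GenomeSpec(chromosomes=(("c1", 1_000_000),),
                             gap_intervals=(("c1", 100_000, 500_000),))
        q = dh.simulate_queen(spec, 0.01, seed=21)
        g, _ = dh.simulate_drone(q, dh.MeiosisParams(), seed=22)
        recs = dh.apply_mutations(q, g, dh.MutationParams(mu_per_bp=2e-4), seed=23)
        het = set(q.het_positions["c1"].tolist())
        assert recs
        for r in recs:
            assert not (100_000 <= r["pos"] < 500_000)
            assert r["pos"] not in het


class TestObserveColony:
    def test_noiseless_channel_is_identity(self, noiseless_colony):
        sim = noiseless_colony
        m = sim.matrix
        assert (m.calls >= 0).all()
        # spot-check every gamete allele against the emitted call
        for j, g in enumerate(sim.gametes):
            for chrom in sim.queen.spec.names:
                rows = np.flatnonzero(
                    (m.sites["chrom"] == chrom).to_numpy()
                    & m.sites["pos"].isin(sim.queen.het_positions[chrom]).to_numpy())
                carried = BASE_CHARS[g.allele_at_het[chrom]]
                emitted = np.array([m.alleles[i][m.calls[i, j]] for i in rows])
                assert (emitted == carried).all()

    def test_spurious_het_count_matches_binomial_oracle(self):
        spec = dh.GenomeSpec(chromosomes=(("c1", 20_000_000),))
        model = dh.ObservationModel(het_artifact_rate=0.001, missing_rate=0.0)
        sim = dh.simulate_colony(spec, n_drones=20, seed=30, observation=model)
        n_entries = sim.matrix.calls.size
        n_het = int((sim.matrix.calls == dh.CODE_HET).sum())
        mean = n_entries * 0.001
        assert abs(n_het - mean) < 4 * np.sqrt(mean)

    def test_rejects_fewer_than_two_gametes(self, spec_small):
        q = dh.simulate_queen(spec_small, 0.0026, seed=31)
        g, _ = dh.simulate_drone(q, dh.MeiosisParams(), seed=32)
        with pytest.raises(InputError):
            dh.observe_colony(q, [g], dh.ObservationModel(), seed=33)


class TestColonyLevel:
    def test_seed_determinism_is_bitwise(self, spec_small):
        a = dh.simulate_colony(spec_small, 5, seed=99)
        b = dh.simulate_colony(spec_small, 5, seed=99)
        assert (a.matrix.calls == b.matrix.calls).all()
        assert (a.matrix.depth == b.matrix.depth).all()
        assert (a.matrix.quality == b.matrix.quality).all()
        assert a.truth.cos.equals(b.truth.cos)
        assert a.truth.mutations.equals(b.truth.mutations)
        c = dh.simulate_colony(spec_small, 5, seed=100)
        assert (a.matrix.calls.shape != c.matrix.calls.shape
                or not (a.matrix.calls == c.matrix.calls).all())

    def test_truth_conservation_and_bounds(self, sim_colony):
        sim_colony.truth.validate()
        # every mutation appears exactly once
        keys = list(zip(sim_colony.truth.mutations["drone"],
                        sim_colony.truth.mutations["chrom"],
                        sim_colony.truth.mutations["pos"]))
        assert len(keys) == len(set(keys))
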