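"""Mutation calling filters, exact Poisson intervals, spectrum, spike-ins."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize
from scipy import stats as sps

import dronehap as dh
from dronehap.errors import InputError, ParameterError

from conftest import make_matrix


class TestCallDenovo:
    def test_noiseless_colony_recovers_exactly_the_true_mutations(
            self, noiseless_colony):
        sim = noiseless_colony
        ms = dh.screen_markers(sim.matrix, "I", min_carriers_per_allele=2)
        ph = dh.phase_queen(ms, sim.matrix)
        calls = dh.call_denovo(sim.matrix, markers=ms, phases={"I": ph})
        got = set(zip(calls["drone"], calls["chrom"], calls["pos"]))
        want = set(zip(sim.truth.mutations["drone"],
                       sim.truth.mutations["chrom"],
                       sim.truth.mutations["pos"]))
        assert want  # the fixture carries mutations
        assert got == want

    def test_allele_shared_by_two_drones_is_rejected(self):
        m = make_matrix([[0, 1, 1, 0, 0, 0]], alleles=[("C", "T")])
        assert len(dh.call_denovo(m)) == 0

    def test_unique_allele_passes_all_filters(self):
        m = make_matrix([[0, 1, 0, 0, 0, 0]], alleles=[("C", "T")])
        calls = dh.call_denovo(m)
        assert len(calls) == 1
        c = calls.iloc[0]
        assert (c["drone"], c["ref"], c["alt"], c["snm_class"]) == \
            ("I-D2", "C", "T", "GC_to_AT")

    @pytest.mark.parametrize("field,value,n_expected", [
        ("depth", 4, 0), ("depth", 5, 1),
        ("quality", 29.0, 0), ("quality", 30.0, 1),
    ])
    def test_carrier_depth_and_quality_thresholds(self, field, value, n_expected):
        m = make_matrix([[0, 1, 0, 0]], alleles=[("C", "T")])
        getattr(m, field)[0, 1] = value
        assert len(dh.call_denovo(m)) == n_expected

    def test_single_strand_support_is_rejected(self):
        m = make_matrix([[0, 1, 0, 0]], alleles=[("C", "T")])
        m.strand_rev[0, 1] = False
        assert len(dh.call_denovo(m)) == 0
        # but passes when the matrix carries no strand information at all
        m.strand_fwd[:] = False
        m.strand_rev[:] = False
        assert len(dh.call_denovo(m)) == 1

    def test_marker_sites_are_excluded(self):
        calls = np.array([[0, 1, 1, 0], [0, 1, 0, 0]])
        m = make_matrix(calls, alleles=[("C", "T")] * 2)
        ms = dh.screen_markers(m, "I", min_carriers_per_allele=2)
        assert ms.n_markers == 1  # only the 2:2 site
        out = dh.call_denovo(m, markers=ms)
        assert len(out) == 1 and int(out["pos"].iloc[0]) == 1000

    def test_clustered_candidates_are_rejected_as_block_artifact(self):
        # one drone unique at 5 nearby sites: a singleton haplotype, not
        # five independent mutations
        calls = np.tile([0, 1, 0, 0], (5, 1))
        m = make_matrix(calls, alleles=[("C", "T")] * 5,
                        positions=np.arange(5) * 10_000)
        out, cands = dh.call_denovo(m, return_candidates=True)
        assert len(out) == 0
        assert (~cands["not_clustered"]).all()

    def test_hap_support_rejects_locally_unique_haplotype(self, noiseless_colony):
        # forge a region where one drone opposes every other drone: a locally
        # unique queen haplotype, indistinguishable site-by-site from a run
        # of mutations but rejected because no other drone shares the
        # carrier's flanking haplotype
        sim = noiseless_colony
        ms = dh.screen_markers(sim.matrix, "I", min_carriers_per_allele=2)
        ph = dh.phase_queen(ms, sim.matrix)
        m = sim.matrix
        run = ms.table.iloc[100:105]
        assert run["chrom"].nunique() == 1
        sis = run["site_idx"].to_numpy()
        keep = m.calls[sis].copy()
        m.calls[np.ix_(sis, np.arange(m.n_drones))] = 0
        m.calls[sis, 3] = 1
        try:
            forged = set(zip(run["chrom"], run["pos"]))
            # cluster filter disabled to isolate the haplotype-support check
            calls = dh.call_denovo(m, phases={"I": ph}, cluster_max=10_000)
            got = set(zip(calls["chrom"], calls["pos"]))
            assert not (forged & got)
            # without phase information the same sites would be called
            calls2 = dh.call_denovo(m, cluster_max=10_000)
            got2 = set(zip(calls2["chrom"], calls2["pos"]))
            assert forged <= got2
        finally:
            m.calls[sis] = keep

    def test_filter_monotonicity_in_depth_and_quality(self, sim_colony):
        base = len(dh.call_denovo(sim_colony.matrix, min_depth=5, min_quality=30))
        for md, mq in [(10, 30), (5, 50), (15, 60)]:
            assert len(dh.call_denovo(sim_colony.matrix, min_depth=md,
                                      min_quality=mq)) <= base

    def test_requires_two_drones(self):
        m = make_matrix([[0, 1]])
        m.drones = m.drones[:1]
        m.colonies = {m.drones[0]: "I"}
        m.calls = m.calls[:, :1]
        m.depth = m.depth[:, :1]
        m.quality = m.quality[:, :1]
        m.strand_fwd = m.strand_fwd[:, :1]
        m.strand_rev = m.strand_rev[:, :1]
        with pytest.raises(InputError):
            dh.call_denovo(m)


class TestCallableSites:
    def test_zero_depth_means_nothing_callable(self):
        mask = dh.callable_sites(np.zeros((100, 3)), np.full((100, 3), 60.0))
        assert mask.total == 0

    def test_uniform_good_depth_makes_everything_callable(self):
        mask = dh.callable_sites(np.full((100, 3), 26), np.full((100, 3), 60.0))
        assert mask.total == 300 and mask.mean_fraction == 1.0

    def test_ambiguous_reference_never_callable(self):
        ref = np.array(["A"] * 50 + ["N"] * 50)
        mask = dh.callable_sites(np.full((100, 2), 26), np.full((100, 2), 60.0),
                                 reference=ref)
        assert mask.per_drone.tolist() == [50, 50]


class TestExactPoissonCI:
    def test_published_count_interval(self):
        lo, hi = dh.exact_poisson_ci(23)
        assert round(lo, 1) == 14.6 and round(hi, 1) == 34.5

    def test_zero_count_closed_form(self):
        lo, hi = dh.exact_poisson_ci(0)
        assert lo == 0.0
        assert hi == pytest.approx(-np.log(0.025), abs=5e-4)  # 3.689

    def test_count_two_matches_chi_square_oracle(self):
        lo, hi = dh.exact_poisson_ci(2)
        assert lo == pytest.approx(0.2422, abs=5e-5)
        assert hi == pytest.approx(7.2247, abs=5e-5)

    @pytest.mark.parametrize("count", [0, 1, 3, 7, 23, 50])
    def test_matches_brute_force_tail_inversion(self, count):
        lo, hi = dh.exact_poisson_ci(count)
        if count > 0:
            f = lambda lam: sps.poisson.sf(count - 1, lam) - 0.025
            lo_bf = optimize.brentq(f, 1e-12, 200)
            assert lo == pytest.approx(lo_bf, abs=1e-6)
        g = lambda lam: sps.poisson.cdf(count, lam) - 0.025
        hi_bf = optimize.brentq(g, 1e-12, 200)
        assert hi == pytest.approx(hi_bf, abs=1e-6)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ParameterError):
            dh.exact_poisson_ci(-1)
        with pytest.raises(ParameterError):
            dh.exact_poisson_ci(5, conf=1.5)


class TestEstimateRate:
    TOTAL = 6_426_135_514

    def _mask(self, total):
        return dh.CallabilityMask(per_drone=pd.Series({"all": total}),
                                  genome_length=total)

    def test_published_rate_and_interval(self):
        est = dh.estimate_rate(23, self._mask(self.TOTAL))
        assert round(est.rate * 1e9, 2) == 3.58
        # bounds are the count limits divided by the callable total
        assert round(est.ci_rate[0] * 1e9, 2) == round(14.6e9 / self.TOTAL, 2)
        assert round(est.ci_rate[1] * 1e9, 2) == 5.37

    def test_zero_count(self):
        est = dh.estimate_rate(0, self._mask(1000))
        assert est.rate == 0.0
        assert est.ci_rate[1] == pytest.approx(3.689 / 1000, rel=1e-3)

    def test_per_genome_rate(self):
        est = dh.estimate_rate(23, self._mask(self.TOTAL))
        assert round(est.per_genome(274e6), 2) == 0.98

    def test_ci_bounds_enclose_the_estimate(self):
        est = dh.estimate_rate(10, self._mask(10_000))
        assert est.ci_rate[0] <= est.rate <= est.ci_rate[1]

    def test_zero_callable_rejected(self):
        with pytest.raises(InputError):
            dh.estimate_rate(3, self._mask(0))


class TestSpectrum:
    def _calls(self, gc_at, at_gc):
        rows = ([{"kind": "SNM", "snm_class": "GC_to_AT"}] * gc_at
                + [{"kind": "SNM", "snm_class": "AT_to_GC"}] * at_gc)
        return pd.DataFrame(rows)

    def test_published_gc_normalized_ratio(self):
        s = dh.spectrum_summary(self._calls(20, 3), gc_fraction=0.375)
        assert round(s["gc_to_at_per_gc"], 1) == 53.3
        assert round(s["at_to_gc_per_at"], 1) == 4.8

    def test_empty_calls_all_zero(self):
        s = dh.spectrum_summary(pd.DataFrame(columns=["kind", "snm_class"]), 0.375)
        assert s["counts"]["GC_to_AT"] == 0 and s["n_transitions"] == 0

    def test_symmetry_at_equal_gc(self):
        s = dh.spectrum_summary(self._calls(5, 5), gc_fraction=0.5)
        assert s["gc_to_at_per_gc"] == s["at_to_gc_per_at"]


class TestSpikeInRecovery:
    def test_fully_callable_noiseless_spikes_all_detected(self, noiseless_colony):
        sim = noiseless_colony
        L = sim.queen.spec.total_length
        mask = dh.CallabilityMask(
            per_drone=pd.Series({d: L for d in sim.matrix.drones}),
            genome_length=L)
        frac_callable, frac_detected = dh.spike_in_recovery(
            sim.matrix, n_spikes=300, mask=mask, seed=1,
            chrom_lengths=sim.queen.spec.lengths)
        assert frac_callable == 1.0 and frac_detected == 1.0

    def test_callable_fraction_matches_mask_binomial_oracle(self, sim_colony):
        sim = sim_colony
        L = sim.queen.spec.total_length
        frac = 0.7
        mask = dh.CallabilityMask(
            per_drone=pd.Series({d: int(L * frac) for d in sim.matrix.drones}),
            genome_length=L)
        n = 4000
        frac_callable, _ = dh.spike_in_recovery(
            sim.matrix, n_spikes=n, mask=mask, seed=2,
            chrom_lengths=sim.queen.spec.lengths)
        assert abs(frac_callable - frac) < 4 * np.sqrt(frac * (1 - frac) / n)
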