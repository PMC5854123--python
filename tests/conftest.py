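"""Shared fixtures: small simulated colonies generated at test time."""

import numpy as np
import pytest

import dronehap as dh


@pytest.fixture(scope="session")
def spec_small():
    return dh.GenomeSpec.bumblebee_like(total_mb=12.0, n_chromosomes=4)


@pytest.fixture(scope="session")
def noiseless_model():
    return dh.ObservationModel(
        mean_depth=26, missing_rate=0.0, genotype_error_rate=0.0,
        het_artifact_rate=0.0, quality_distribution=("constant", 60.0))


@pytest.fixture(scope="session")
def sim_colony(spec_small):
    """A noisy 10-drone colony with an inflated mutation rate so the
    mutation path has events to find."""
    return dh.simulate_colony(
        spec_small, n_drones=10, seed=42,
        mutation=dh.MutationParams(mu_per_bp=5e-8))


@pytest.fixture(scope="session")
def noiseless_colony(spec_small, noiseless_model):
    return dh.simulate_colony(
        spec_small, n_drones=10, seed=43, observation=noiseless_model,
        mutation=dh.MutationParams(mu_per_bp=5e-8))


@pytest.fixture(scope="session")
def phased(sim_colony):
    ms = dh.screen_markers(sim_colony.matrix, "I", min_carriers_per_allele=2)
    ph = dh.phase_queen(ms, sim_colony.matrix)
    blocks, mism = dh.assign_blocks_all(ph, sim_colony.matrix)
    return ms, ph, blocks, mism


@pytest.fixture(scope="session")
def events(phased):
    _, _, blocks, _ = phased
    return dh.group_shared_cos(dh.classify_events(blocks))


def make_matrix(calls, alleles=None, chrom="LG1", positions=None, colony="I",
                depth=26, quality=60.0, strand=True):
    """Hand-build a GenotypeMatrix from a (sites x drones) code array."""
    import pandas as pd

    calls = np.asarray(calls, dtype=np.int16)
    n_sites, n_drones = calls.shape
    positions = positions if positions is not None else np.arange(n_sites) * 1000
    if alleles is None:
        alleles = [("A", "T")] * n_sites
    drones = [f"{colony}-D{i+1}" for i in range(n_drones)]
    shape = calls.shape
    return dh.GenotypeMatrix(
        sites=pd.DataFrame({"chrom": chrom, "pos": positions,
                            "ref": [a[0] for a in alleles]}),
        alleles=list(alleles),
        drones=drones,
        colonies={d: colony for d in drones},
        calls=calls,
        depth=np.full(shape, depth, dtype=np.int32),
        quality=np.full(shape, quality, dtype=np.float32),
        strand_fwd=np.full(shape, strand, dtype=bool),
        strand_rev=np.full(shape, strand, dtype=bool),
    )
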